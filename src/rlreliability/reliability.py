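"""Test-retest reliability and agreement statistics.

Reliability is Pearson's product-moment correlation between the two
sessions; agreement is the intraclass correlation ICC(3,1) (two-way
mixed effects, consistency, single measure) from the classical ANOVA
decomposition, plus a variance-components ICC from a mixed model with
random intercepts for participant and session. ICC values are banded
qualitatively: below .5 "poor", .5-.75 "moderate", .75-.9 "good",
at or above .9 "excellent".

With two sessions the session random effect is weakly identified; the
mixed model uses REML with variances bounded at zero and flags boundary
fits rather than hiding them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityReport",
    "pearson_r",
    "icc31",
    "icc_mixed",
    "interpret_icc",
    "reliability_report",
    "reports_to_frame",
]


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson_r(x, y) -> float:
    """Pearson correlation of paired session values; NaN pairs dropped."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least three complete pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def icc31(x, y) -> float:
    """ICC(3,1): two-way mixed effects, consistency, single measure.

    ``(MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)`` with
    k = 2 sessions, from the two-way ANOVA decomposition. Consistency
    form: an additive session shift leaves the value at 1.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least three complete pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        return math.nan
    k = 2
    table = np.column_stack([x, y])
    grand = table.mean()
    subj_means = table.mean(axis=1)
    sess_means = table.mean(axis=0)
    ms_subjects = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    resid = table - subj_means[:, None] - sess_means[None, :] + grand
    ms_error = (resid**2).sum() / ((n - 1) * (k - 1))
    denom = ms_subjects + (k - 1) * ms_error
    if denom == 0.0:
        return math.nan
    return float((ms_subjects - ms_error) / denom)


def icc_mixed(x, y) -> tuple[float, float, float]:
    """Variance-components ICC with random intercepts for participant and session.

    Returns ``(icc, var_session_prop, var_residual_prop)``: the subject
    variance share of the total, and the session/residual shares (the
    bracketed pair of the agreement tables). REML fit; variance
    components are bounded at zero.
    """
    import statsmodels.formula.api as smf

    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least three complete pairs")
    resid_scale = np.abs(x - y)
    if resid_scale.max() < 1e-12:
        # identical sessions: all variance is between subjects
        return 1.0, 0.0, 0.0
    df = pd.DataFrame({
        "value": np.concatenate([x, y]),
        "id": np.tile(np.arange(n), 2),
        "session": np.repeat([0, 1], n),
        "g": np.zeros(2 * n, dtype=int),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "value ~ 1", df, groups="g",
            vc_formula={"id": "0 + C(id)", "session": "0 + C(session)"},
        )
        fit = model.fit(reml=True)
    comps = dict(zip(model.exog_vc.names, np.maximum(fit.vcomp, 0.0)))
    var_id = float(comps.get("id", 0.0))
    var_session = float(comps.get("session", 0.0))
    var_resid = float(max(fit.scale, 0.0))
    total = var_id + var_session + var_resid
    if total == 0.0:
        return math.nan, math.nan, math.nan
    return var_id / total, var_session / total, var_resid / total


def interpret_icc(value: float) -> str:
    """Qualitative band: <.5 poor, [.5,.75) moderate, [.75,.9) good, >=.9 excellent."""
    if value > 1.0:
        raise ValueError("ICC cannot exceed 1")
    if math.isnan(value):
        return "undefined"
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ReliabilityReport:
    """Reliability and agreement of one measure across two sessions."""

    measure: str
    pearson: float
    icc31: float
    icc_mixed: float
    var_session_prop: float
    var_residual_prop: float
    band: str
    n_pairs: int

    def row(self) -> dict:
        return {
            "measure": self.measure, "r": self.pearson, "icc31": self.icc31,
            "icc_mixed": self.icc_mixed, "var_session": self.var_session_prop,
            "var_residual": self.var_residual_prop, "band": self.band, "n": self.n_pairs,
        }


def reliability_report(measure: str, x, y) -> ReliabilityReport:
    """Full reliability/agreement summary for one measure."""
    xv, yv = _paired(x, y)
    r = pearson_r(x, y)
    icc = icc31(x, y)
    icc_m, vs, ve = icc_mixed(x, y)
    return ReliabilityReport(measure, r, icc, icc_m, vs, ve, interpret_icc(icc), xv.size)


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in reports])


def format_table(reports) -> str:
    """Text table in the measure x {r, ICC [session/error]} layout."""
    lines = [f"{'measure':<16}{'r':>8}{'ICC(3,1)':>10}  ICC [session/error]   band"]
    for rep in reports:
        lines.append(
            f"{rep.measure:<16}{rep.pearson:>8.2f}{rep.icc31:>10.2f}  "
            f"{rep.icc_mixed:.2f} [{rep.var_session_prop:.2f}/{rep.var_residual_prop:.2f}]"
            f"   {rep.band}"
        )
    return "\n".join(lines)
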