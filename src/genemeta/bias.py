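"""Small-study / publication-bias diagnostics.

Egger's linear regression test (classic form: OLS of the standardized
effect y_i/se_i on precision 1/se_i; a non-zero intercept signals funnel
asymmetry), the Begg-Mazumdar adjusted rank-correlation test (Kendall's tau
between variance-stabilized deviations from the fixed-effect pool and the
study variances), and plain-data funnel-plot export.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .effects import EffectSize, _z_crit
from .meta import MetaResult, fixed_effect

__all__ = ["BiasTestResult", "egger_test", "begg_test", "funnel_data"]

_VAR_EPS = 1e-12


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of a publication-bias test.

    ``statistic`` is the intercept t (Egger) or the normal-approximation z
    from Kendall's tau (Begg); ``intercept`` is Egger-only.
    """

    method: str
    statistic: float
    p: float
    k: int
    intercept: float | None = None
    intercept_se: float | None = None
    tau: float | None = None

    @property
    def suggests_bias(self) -> bool:
        """Annotation at the conventional p > 0.1 screening threshold."""
        return self.p <= 0.1


def egger_test(effects: Sequence[EffectSize]) -> BiasTestResult:
    """Egger's regression test for funnel-plot asymmetry.

    Fits z_i = y_i/se_i = a + b * (1/se_i) by OLS; the intercept a is the
    bias statistic, tested with a t distribution on k - 2 df (two-sided).
    Requires k >= 3 and at least two distinct SEs (a constant precision
    column makes the design degenerate).
    """
    effects = list(effects)
    k = len(effects)
    if k < 3:
        raise ValueError("Egger's test needs at least 3 studies")
    se = np.array([e.se for e in effects])
    if np.ptp(se) == 0:
        raise ValueError("all standard errors equal: Egger design is degenerate")
    y = np.array([e.estimate for e in effects])
    z = y / se
    x = sm.add_constant(1.0 / se)
    fit = sm.OLS(z, x).fit()
    intercept = float(fit.params[0])
    se_int = float(fit.bse[0])
    t = intercept / se_int
    p = float(2.0 * stats.t.sf(abs(t), df=k - 2))
    return BiasTestResult(method="egger", statistic=t, p=p, k=k,
                          intercept=intercept, intercept_se=se_int)


def _kendall_counts(u: np.ndarray, v: np.ndarray) -> tuple[int, int, int]:
    """Concordant, discordant, and tied pair counts between two sequences."""
    conc = disc = tied = 0
    k = len(u)
    for i in range(k):
        for j in range(i + 1, k):
            s = (u[i] - u[j]) * (v[i] - v[j])
            if s > 0:
                conc += 1
            elif s < 0:
                disc += 1
            else:
                tied += 1
    return conc, disc, tied


def begg_test(effects: Sequence[EffectSize], method: str = "normal") -> BiasTestResult:
    """Begg-Mazumdar rank-correlation test for publication bias.

    Computes Kendall's tau between the standardized deviations
    (y_i - y_FE) / sqrt(se_i^2 - se_FE^2) and the study variances se_i^2.
    ``method="normal"`` (default) uses the continuity-corrected normal
    approximation z = (|P - Q| - 1) / sqrt(k(k-1)(2k+5)/18);
    ``method="exact"`` enumerates all permutations (k <= 8 only).
    Variances numerically at or below the pooled variance are floored at a
    small epsilon.
    """
    effects = list(effects)
    k = len(effects)
    if k < 3:
        raise ValueError("Begg's test needs at least 3 studies")
    fe = fixed_effect(effects)
    y = np.array([e.estimate for e in effects])
    var = np.array([e.se**2 for e in effects])
    vstar = np.maximum(var - fe.se**2, _VAR_EPS)
    dev = (y - fe.estimate) / np.sqrt(vstar)
    conc, disc, _ = _kendall_counts(dev, var)
    n_pairs = k * (k - 1) // 2
    tau = (conc - disc) / n_pairs
    diff = conc - disc
    if method == "exact":
        if k > 8:
            raise ValueError("exact permutation p only available for k <= 8")
        ranks_v = var
        count = total = 0
        for perm in itertools.permutations(range(k)):
            c, d, _ = _kendall_counts(dev[list(perm)], ranks_v)
            if abs(c - d) >= abs(diff):
                count += 1
            total += 1
        p = count / total
        z = float("nan")
    elif method == "normal":
        var_s = k * (k - 1) * (2 * k + 5) / 18.0
        z = max(0.0, (abs(diff) - 1.0)) / math.sqrt(var_s)
        p = float(2.0 * stats.norm.sf(z))
    else:
        raise ValueError(f"method must be 'normal' or 'exact', got {method!r}")
    return BiasTestResult(method="begg", statistic=z, p=min(1.0, p), k=k, tau=tau)


def funnel_data(effects: Sequence[EffectSize], result: MetaResult,
                n_boundary: int = 50) -> pd.DataFrame:
    """Plain-data export for a funnel plot.

    One ``kind="study"`` row per study (estimate on the reporting scale,
    se), plus ``kind="boundary"`` rows tracing the pseudo-95% funnel
    estimate +/- z_crit * se around the pooled estimate from se = 0 (the
    apex) to the largest observed se.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("no effects supplied")
    rows = []
    tf = math.exp if result.scale == "log" else (lambda v: v)
    for e in effects:
        rows.append({"kind": "study", "label": e.label, "estimate": tf(e.estimate),
                     "se": e.se, "lower": None, "upper": None})
    zc = _z_crit(result.level)
    se_max = max(e.se for e in effects)
    for s in np.linspace(0.0, se_max, n_boundary):
        rows.append({
            "kind": "boundary", "label": None, "estimate": tf(result.estimate),
            "se": float(s),
            "lower": tf(result.estimate - zc * s),
            "upper": tf(result.estimate + zc * s),
        })
    return pd.DataFrame(rows)
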