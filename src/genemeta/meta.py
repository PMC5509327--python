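"""Inverse-variance meta-analysis with DerSimonian-Laird random effects.

The central object is :class:`MetaAnalysis`, a model built from per-study
effect sizes whose :meth:`~MetaAnalysis.fit` returns a :class:`MetaResult`
carrying the pooled estimate, its uncertainty, Cochran's Q, the
DerSimonian-Laird between-study variance tau^2, I^2 with a test-based
confidence interval, H^2, and the normalized study weights.  Module-level
functions (:func:`fixed_effect`, :func:`dersimonian_laird`,
:func:`heterogeneity`, :func:`leave_one_out`, :func:`subgroup_meta`,
:func:`pooled_raf`) expose the same computations functionally.

Model
-----
Study i supplies an estimate y_i with standard error se_i on a common scale
(log for odds ratios, raw units for regression slopes and standardized mean
differences).  The fixed-effect fit weights by w_i = 1/se_i^2.  The
random-effects model assumes y_i ~ N(theta_i, se_i^2) with
theta_i ~ N(mu, tau^2); tau^2 is the DerSimonian-Laird moment estimate

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)),   df = k - 1,

truncated at zero, and pooling proceeds with weights 1/(se_i^2 + tau^2).
Whenever Q <= df the two fits coincide exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .effects import EffectSize, GeneticModel, _z_crit, derive_case_control_effect, derive_quant_effect

__all__ = [
    "MetaAnalysis",
    "MetaResult",
    "Heterogeneity",
    "SubgroupSpec",
    "SubgroupResult",
    "fixed_effect",
    "dersimonian_laird",
    "heterogeneity",
    "subgroup_meta",
    "leave_one_out",
    "pooled_raf",
]


@dataclass(frozen=True)
class Heterogeneity:
    """Q-derived heterogeneity summaries.

    ``h2`` is the excess-variation form max(0, (Q-df)/df) (the headline
    value); ``h2_classical`` is Q/df.  ``i2_ci`` comes from the test-based
    interval on ln H with H truncated at 1.
    """

    q: float
    df: int
    i2: float
    i2_ci: tuple[float, float]
    h2: float
    h2_classical: float

    @property
    def p(self) -> float:
        """P-value of Cochran's Q against chi-square(df)."""
        return float(stats.chi2.sf(self.q, self.df))


def heterogeneity(q: float, df: int, level: float = 0.95) -> Heterogeneity:
    """Heterogeneity statistics from Cochran's Q and its degrees of freedom.

    I^2 = max(0, (Q-df)/Q) * 100.  The I^2 interval transforms a normal
    interval for ln H, H = max(1, sqrt(Q/df)), with

        SE(ln H) = 0.5 * (ln Q - ln df) / (sqrt(2Q) - sqrt(2 df - 1))

    when Q > df + 1, and the small-Q approximation
    sqrt(1/(2(df-1)) * (1 - 1/(3 (df-1)^2))) otherwise (df >= 2).  For
    df = 1 with Q <= 2 neither form applies and the vacuous (0, 100) is
    returned.  Endpoints are clamped to [0, 100].
    """
    if df < 1:
        raise ValueError(f"heterogeneity needs df >= 1, got {df}")
    if q < 0:
        raise ValueError(f"Q must be non-negative, got {q}")
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    h2_classical = q / df
    h2 = max(0.0, (q - df) / df)

    h = max(1.0, math.sqrt(q / df)) if q > 0 else 1.0
    ln_h = math.log(h)
    if q > df + 1:
        se_ln_h = 0.5 * (math.log(q) - math.log(df)) / (math.sqrt(2 * q) - math.sqrt(2 * df - 1))
    elif df >= 2:
        se_ln_h = math.sqrt(1.0 / (2 * (df - 1)) * (1.0 - 1.0 / (3 * (df - 1) ** 2)))
    else:
        se_ln_h = None
    if se_ln_h is None:
        i2_ci = (0.0, 100.0)
    else:
        zc = _z_crit(level)
        bounds = []
        for sign in (-1.0, 1.0):
            hb = math.exp(ln_h + sign * zc * se_ln_h)
            i2b = max(0.0, min(100.0, (hb * hb - 1.0) / (hb * hb) * 100.0)) if hb > 0 else 0.0
            bounds.append(i2b)
        i2_ci = (min(bounds), max(bounds))
    return Heterogeneity(q=q, df=df, i2=i2, i2_ci=i2_ci, h2=h2, h2_classical=h2_classical)


@dataclass
class MetaResult:
    """Results of a meta-analytic fit.

    ``estimate``/``se``/``z`` are on the pooling scale; ``ci`` is
    back-transformed to the reporting scale (exp for log-scale pooling).
    Heterogeneity fields are ``None`` for single-study fits.  ``weights``
    are normalized to sum to 1 in input order.  ``snp``/``subgroup``/
    ``model`` are free-text tags used by the results writer.
    """

    method: str
    scale: str
    k: int
    estimate: float
    se: float
    level: float = 0.95
    n_total: int | None = None
    tau2: float = 0.0
    het: Heterogeneity | None = None
    weights: np.ndarray = field(default_factory=lambda: np.array([]))
    labels: tuple = ()
    snp: str = ""
    subgroup: str = ""
    model: str = ""

    @property
    def z(self) -> float:
        return self.estimate / self.se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    @property
    def df(self) -> int:
        return self.k - 1

    @property
    def ci(self) -> tuple[float, float]:
        zc = _z_crit(self.level)
        lo, hi = self.estimate - zc * self.se, self.estimate + zc * self.se
        if self.scale == "log":
            return (math.exp(lo), math.exp(hi))
        return (lo, hi)

    # heterogeneity pass-throughs
    @property
    def Q(self) -> float | None:
        return self.het.q if self.het else None

    @property
    def i2(self) -> float | None:
        return self.het.i2 if self.het else None

    @property
    def i2_ci(self) -> tuple[float, float] | None:
        return self.het.i2_ci if self.het else None

    @property
    def h2(self) -> float | None:
        return self.het.h2 if self.het else None

    @property
    def h2_classical(self) -> float | None:
        return self.het.h2_classical if self.het else None

    def tagged(self, snp: str = "", subgroup: str = "", model: str = "") -> "MetaResult":
        return replace(self, snp=snp or self.snp, subgroup=subgroup or self.subgroup,
                       model=model or self.model)

    def to_row(self) -> dict:
        """Row dict matching the results-table schema."""
        lo, hi = self.ci
        est = math.exp(self.estimate) if self.scale == "log" else self.estimate
        return {
            "snp": self.snp or None,
            "subgroup": self.subgroup or None,
            "model": self.model or None,
            "k": self.k,
            "n": self.n_total,
            "estimate": est,
            "ci_low": lo,
            "ci_high": hi,
            "p": self.p,
            "Q": self.Q,
            "I2": self.i2,
            "I2_ci": (None if self.i2_ci is None
                      else f"{_short(self.i2_ci[0])};{_short(self.i2_ci[1])}"),
            "H2": self.h2,
            "tau2": self.tau2 if self.het is not None else None,
        }

    def summary(self) -> str:
        """Plain-text summary table."""
        lo, hi = self.ci
        est = math.exp(self.estimate) if self.scale == "log" else self.estimate
        unit = "OR" if self.scale == "log" else "estimate"
        lines = [
            f"Meta-analysis ({self.method}-effects), k = {self.k} studies"
            + (f", n = {self.n_total}" if self.n_total else ""),
            f"  pooled {unit}: {est:.4g}  (95% CI {lo:.4g}, {hi:.4g})",
            f"  z = {self.z:.3f}, p = {self.p:.3g}",
        ]
        if self.het is not None:
            lines.append(
                f"  Q = {self.het.q:.3f} (df = {self.het.df}, p = {self.het.p:.3g}), "
                f"tau2 = {self.tau2:.4g}"
            )
            lo2, hi2 = self.het.i2_ci
            lines.append(
                f"  I2 = {self.het.i2:.1f}% (95% CI {lo2:.0f}%, {hi2:.0f}%), "
                f"H2 = {self.het.h2:.2f} (classical Q/df = {self.het.h2_classical:.2f})"
            )
        return "\n".join(lines)


def _short(v: float) -> str:
    return repr(float(v))


def _as_arrays(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray, str, tuple, int | None]:
    effects = list(effects)
    if not effects:
        raise ValueError("no effects to pool")
    scales = {e.scale for e in effects}
    if len(scales) > 1:
        raise ValueError(f"effects mix scales {scales}; convert to a common scale first")
    y = np.array([e.estimate for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    labels = tuple(e.label for e in effects)
    ns = [e.n for e in effects]
    n_total = sum(ns) if all(n is not None for n in ns) else None
    return y, se, scales.pop(), labels, n_total


class MetaAnalysis:
    """Inverse-variance meta-analysis model over per-study effect sizes.

    Parameters
    ----------
    estimates, ses : array-like
        Per-study effects and standard errors on a common scale.
    scale : {"identity", "log"}
        Reporting transform for CIs.
    labels : sequence of str, optional
    n : sequence of int, optional
        Per-study person counts (summed into ``n_total``).

    Examples
    --------
    >>> m = MetaAnalysis([0.0, 2.0], [1.0, 1.0])
    >>> res = m.fit(method="random")
    >>> round(res.tau2, 10)
    1.0
    """

    def __init__(self, estimates, ses, scale: str = "identity", labels=None, n=None,
                 level: float = 0.95):
        self.y = np.asarray(estimates, dtype=float)
        self.se = np.asarray(ses, dtype=float)
        if self.y.ndim != 1 or self.y.shape != self.se.shape:
            raise ValueError("estimates and ses must be 1-d and the same length")
        if self.y.size == 0:
            raise ValueError("no studies supplied")
        if np.any(~np.isfinite(self.y)) or np.any(~np.isfinite(self.se)) or np.any(self.se <= 0):
            raise ValueError("estimates must be finite and ses finite and positive")
        if scale not in ("identity", "log"):
            raise ValueError(f"scale must be 'identity' or 'log', got {scale!r}")
        self.scale = scale
        self.labels = tuple(labels) if labels is not None else tuple(range(self.y.size))
        if len(self.labels) != self.y.size:
            raise ValueError("labels length mismatch")
        self.n = None if n is None else [None if v is None else int(v) for v in n]
        self.level = level

    @classmethod
    def from_effects(cls, effects: Sequence[EffectSize], level: float = 0.95) -> "MetaAnalysis":
        y, se, scale, labels, _ = _as_arrays(effects)
        n = [e.n for e in effects]
        return cls(y, se, scale=scale, labels=labels, n=n, level=level)

    @classmethod
    def from_dataframe(cls, df, estimate: str = "estimate", se: str = "se",
                       scale: str = "identity", label: str | None = None,
                       n: str | None = None, level: float = 0.95) -> "MetaAnalysis":
        labels = df[label] if label else None
        ns = df[n] if n else None
        return cls(df[estimate].to_numpy(), df[se].to_numpy(), scale=scale,
                   labels=labels, n=ns, level=level)

    @property
    def k(self) -> int:
        return int(self.y.size)

    @property
    def n_total(self) -> int | None:
        if self.n is None or any(v is None for v in self.n):
            return None
        return int(sum(self.n))

    def _fe(self) -> tuple[float, float, float, np.ndarray]:
        w = 1.0 / self.se**2
        est = float(np.sum(w * self.y) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        q = float(np.sum(w * (self.y - est) ** 2))
        return est, se, q, w

    def fit(self, method: str = "random") -> MetaResult:
        """Fit the model.

        ``method="fixed"`` accepts k >= 1; ``method="random"``
        (DerSimonian-Laird) requires k >= 2 and reduces to the fixed fit
        whenever Q <= k - 1.
        """
        if method not in ("fixed", "random"):
            raise ValueError(f"method must be 'fixed' or 'random', got {method!r}")
        est_fe, se_fe, q, w = self._fe()
        het = heterogeneity(q, self.k - 1, self.level) if self.k >= 2 else None
        if method == "fixed":
            return MetaResult(
                method="fixed", scale=self.scale, k=self.k, estimate=est_fe, se=se_fe,
                level=self.level, n_total=self.n_total, tau2=0.0, het=het,
                weights=w / np.sum(w), labels=self.labels,
            )
        if self.k < 2:
            raise ValueError("random-effects pooling needs at least 2 studies")
        df = self.k - 1
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        w_star = 1.0 / (self.se**2 + tau2)
        est = float(np.sum(w_star * self.y) / np.sum(w_star))
        se = float(np.sum(w_star) ** -0.5)
        return MetaResult(
            method="random", scale=self.scale, k=self.k, estimate=est, se=se,
            level=self.level, n_total=self.n_total, tau2=tau2, het=het,
            weights=w_star / np.sum(w_star), labels=self.labels,
        )

    def leave_one_out(self, method: str = "random") -> list[MetaResult]:
        """Re-fit k times, omitting each study in turn (needs k >= 3)."""
        if self.k < 3:
            raise ValueError("leave-one-out needs at least 3 studies")
        out = []
        for i in range(self.k):
            keep = np.arange(self.k) != i
            sub = MetaAnalysis(
                self.y[keep], self.se[keep], scale=self.scale,
                labels=[l for j, l in enumerate(self.labels) if j != i],
                n=None if self.n is None else [v for j, v in enumerate(self.n) if j != i],
                level=self.level,
            )
            out.append(sub.fit(method=method))
        return out


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------


def fixed_effect(effects: Sequence[EffectSize], level: float = 0.95) -> MetaResult:
    """Inverse-variance fixed-effect pool (k >= 1)."""
    return MetaAnalysis.from_effects(effects, level=level).fit(method="fixed")


def dersimonian_laird(effects: Sequence[EffectSize], level: float = 0.95) -> MetaResult:
    """DerSimonian-Laird random-effects pool (k >= 2)."""
    return MetaAnalysis.from_effects(effects, level=level).fit(method="random")


def leave_one_out(effects: Sequence[EffectSize], method: str = "random",
                  level: float = 0.95) -> list[MetaResult]:
    """Leave-one-out sensitivity re-pools, same method as the parent call."""
    return MetaAnalysis.from_effects(effects, level=level).leave_one_out(method=method)


@dataclass(frozen=True)
class SubgroupSpec:
    """Grouping of studies by a record field (default: ethnicity)."""

    grouping: str = "ethnicity"
    levels: tuple[str, ...] | None = None


@dataclass
class SubgroupResult:
    """One subgroup level: membership counts plus the pooled fit.

    ``k`` counts records in the level; ``k_used`` counts those that yielded
    an effect size.  ``result`` is ``None`` when no effect was derivable,
    and a pass-through single-study result (heterogeneity undefined) when
    exactly one was.
    """

    level: str
    k: int
    n_total: int
    k_used: int
    result: MetaResult | None
    excluded: list[str] = field(default_factory=list)


def _derive(record, table_outcome: str, model, contrast: str):
    if table_outcome == "T2D":
        return derive_case_control_effect(record, model=model)
    return derive_quant_effect(record, contrast=contrast)


def subgroup_meta(table, spec: SubgroupSpec | None = None,
                  model: GeneticModel | str = GeneticModel.ADDITIVE,
                  method: str = "random", contrast: str = "additive",
                  level: float = 0.95) -> list[SubgroupResult]:
    """Pool a study table overall and within subgroup levels.

    Returns one :class:`SubgroupResult` per level in first-appearance order,
    preceded by the ``"overall"`` pool.  Records that yield no effect size
    are counted in ``k``/``n_total`` but listed in ``excluded``; levels with
    one usable effect are passed through with heterogeneity undefined.
    """
    spec = spec or SubgroupSpec()
    groups: dict[str, list] = {"overall": list(table)}
    for rec in table:
        levelname = getattr(rec, spec.grouping)
        groups.setdefault(str(levelname), []).append(rec)
    if spec.levels is not None:
        wanted = {"overall", *spec.levels}
        groups = {k: v for k, v in groups.items() if k in wanted}
    out = []
    for levelname, recs in groups.items():
        effects, excluded = [], []
        for rec in recs:
            derived = _derive(rec, table.outcome, model, contrast)
            if derived is None:
                excluded.append(rec.study_id)
            else:
                effects.append(derived[0])
        n_total = sum(
            (r.n_case + r.n_control) if table.outcome == "T2D" else r.n for r in recs
        )
        if not effects:
            result = None
        elif len(effects) == 1:
            result = fixed_effect(effects, level=level)
        else:
            ma = MetaAnalysis.from_effects(effects, level=level)
            result = ma.fit(method=method)
        if result is not None:
            result = result.tagged(subgroup=levelname,
                                   model=model.value if isinstance(model, GeneticModel) else str(model))
        out.append(SubgroupResult(level=levelname, k=len(recs), n_total=n_total,
                                  k_used=len(effects), result=result, excluded=excluded))
    return out


def pooled_raf(studies: Iterable[tuple[float, float]], method: str = "inverse_variance"
               ) -> float:
    """Pooled risk-allele frequency across studies of (f, n).

    ``inverse_variance`` weights each study by the reciprocal binomial
    variance of its allele count, w = 2n / (f (1-f)); monomorphic studies
    (f of 0 or 1) carry no variance information and are excluded.  ``mean``
    is the unweighted arithmetic mean.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("no studies supplied")
    for f, n in studies:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"allele frequency must be in [0,1], got {f}")
        if n <= 0:
            raise ValueError(f"study size must be positive, got {n}")
    if method == "mean":
        return float(np.mean([f for f, _ in studies]))
    if method != "inverse_variance":
        raise ValueError(f"method must be 'inverse_variance' or 'mean', got {method!r}")
    usable = [(f, n) for f, n in studies if 0.0 < f < 1.0]
    if not usable:
        raise ValueError("all studies are monomorphic; no inverse-variance pool exists")
    w = np.array([2.0 * n / (f * (1.0 - f)) for f, n in usable])
    fs = np.array([f for f, _ in usable])
    return float(np.sum(w * fs) / np.sum(w))
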