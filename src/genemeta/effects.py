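"""Per-study effect sizes for genetic association studies.

Converts study-level summaries into a common :class:`EffectSize` currency:
odds ratios under the classic genetic contrasts (allele, dominant, recessive,
additive/per-allele) from genotype counts or from Hardy-Weinberg-reconstructed
counts, standardized mean differences for quantitative traits, and standard
errors recovered from confidence intervals or p-values when a study reports
only those.  Also hosts the chi-square goodness-of-fit test for
Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Sequence

from scipy import stats

__all__ = [
    "EffectSize",
    "GeneticModel",
    "HweResult",
    "genotype_freqs_from_raf",
    "reconstruct_counts",
    "or_from_counts",
    "smd",
    "se_from_ci",
    "se_from_p",
    "hwe_test",
    "derive_case_control_effect",
    "derive_quant_effect",
]


def _z_crit(level: float) -> float:
    """Exact two-sided normal critical value (1.959964... at 95%)."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2.0))


@dataclass(frozen=True)
class EffectSize:
    """A point estimate with its standard error on the estimation scale.

    Parameters
    ----------
    estimate : float
        Effect on the estimation scale: log odds ratio when ``scale="log"``,
        raw units (mmol/l per allele, or an SMD) when ``scale="identity"``.
    se : float
        Standard error of ``estimate`` on the same scale; must be positive.
    scale : {"identity", "log"}
        Reporting transform: CIs are exponentiated back to the OR scale when
        ``scale="log"``.
    label : str, optional
        Study identifier carried through pooling and diagnostics.
    n : int, optional
        Persons contributing to this estimate (used for totals only).

    ``z``, ``p`` and ``ci()`` are derived, so the defining identities
    (CI = estimate +/- z_crit * se on the estimation scale, p the two-sided
    normal tail of z) hold by construction.
    """

    estimate: float
    se: float
    scale: str = "identity"
    label: str | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.estimate):
            raise ValueError(f"estimate must be finite, got {self.estimate}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"se must be finite and > 0, got {self.se}")
        if self.scale not in ("identity", "log"):
            raise ValueError(f"scale must be 'identity' or 'log', got {self.scale!r}")

    @property
    def z(self) -> float:
        return self.estimate / self.se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval on the natural reporting scale."""
        zc = _z_crit(level)
        lo = self.estimate - zc * self.se
        hi = self.estimate + zc * self.se
        if self.scale == "log":
            return (math.exp(lo), math.exp(hi))
        return (lo, hi)

    def with_label(self, label: str) -> "EffectSize":
        return replace(self, label=label)


class GeneticModel(enum.Enum):
    """Genotype-collapse contrasts for a biallelic risk variant.

    Genotype triples are ordered (hom-risk, het, hom-other) throughout.
    """

    ALLELE = "allele"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    ADDITIVE = "additive"

    @property
    def contrast(self) -> str:
        return {
            GeneticModel.ALLELE: "risk allele vs other allele (allele-count 2x2)",
            GeneticModel.DOMINANT: "hom-risk + het carriers vs hom-other",
            GeneticModel.RECESSIVE: "hom-risk vs het + hom-other",
            GeneticModel.ADDITIVE: "crude per-allele OR from the allele-count 2x2",
        }[self]


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg chi-square goodness of fit (df = 1)."""

    chi2: float
    p: float
    f_hat: float
    monomorphic: bool = False

    @property
    def hwe_ok(self) -> bool:
        """Conventional flag: in equilibrium when p >= 0.05."""
        return self.p >= 0.05


def genotype_freqs_from_raf(f: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies (f^2, 2f(1-f), (1-f)^2)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele frequency must be in [0,1], got {f}")
    return (f * f, 2.0 * f * (1.0 - f), (1.0 - f) ** 2)


def reconstruct_counts(f: float, n: int) -> tuple[float, float, float]:
    """Expected genotype counts n*(f^2, 2f(1-f), (1-f)^2).

    Counts are kept fractional: rounding would break exact recovery of the
    allele frequency by allele counting.
    """
    if n <= 0:
        raise ValueError(f"sample size must be positive, got {n}")
    p2, p1, p0 = genotype_freqs_from_raf(f)
    return (n * p2, n * p1, n * p0)


def _collapse_2x2(
    case: Sequence[float], control: Sequence[float], model: GeneticModel
) -> tuple[float, float, float, float]:
    """Return (a, b, c, d): case exposed/unexposed, control exposed/unexposed."""
    c2, c1, c0 = case
    d2, d1, d0 = control
    if model in (GeneticModel.ALLELE, GeneticModel.ADDITIVE):
        return (2 * c2 + c1, 2 * c0 + c1, 2 * d2 + d1, 2 * d0 + d1)
    if model is GeneticModel.DOMINANT:
        return (c2 + c1, c0, d2 + d1, d0)
    return (c2, c1 + c0, d2, d1 + d0)  # recessive


def or_from_counts(
    case: Sequence[float],
    control: Sequence[float],
    model: GeneticModel | str = GeneticModel.ALLELE,
    correction: float | None = 0.5,
) -> EffectSize:
    """Odds ratio from genotype-count triples under a genetic contrast.

    Triples are (hom-risk, het, hom-other); counts may be fractional (as
    produced by :func:`reconstruct_counts`).  The log-OR carries the Woolf
    standard error sqrt(sum 1/cell).  When any cell of the collapsed 2x2 is
    zero, ``correction`` (default 0.5, Haldane-Anscombe) is added to every
    cell; pass ``correction=None`` to disable.
    """
    model = GeneticModel(model) if not isinstance(model, GeneticModel) else model
    for triple, name in ((case, "case"), (control, "control")):
        if len(triple) != 3 or any(v < 0 for v in triple):
            raise ValueError(f"{name} genotype triple must be 3 non-negative counts")
        if sum(triple) <= 0:
            raise ValueError(f"{name} group has zero total")
    a, b, c, d = _collapse_2x2(case, control, model)
    if min(a, b, c, d) == 0 and correction is not None:
        a, b, c, d = (a + correction, b + correction, c + correction, d + correction)
    if min(a, b, c, d) <= 0:
        raise ZeroDivisionError(
            f"degenerate 2x2 under the {model.value} model: cells {(a, b, c, d)}"
        )
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectSize(estimate=log_or, se=se, scale="log")


def smd(
    n1: int,
    m1: float,
    sd1: float,
    n0: int,
    m0: float,
    sd0: float,
    flavor: str = "cohen",
) -> EffectSize:
    """Standardized mean difference (m1 - m0) / pooled SD.

    ``flavor="hedges"`` applies the small-sample correction
    J = 1 - 3/(4(n1+n0-2) - 1); its SE is J times Cohen's SE
    sqrt(1/n1 + 1/n0 + d^2/(2(n1+n0))).
    """
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 subjects for an SMD")
    if sd1 <= 0 or sd0 <= 0:
        raise ValueError("group SDs must be positive")
    if flavor not in ("cohen", "hedges"):
        raise ValueError(f"flavor must be 'cohen' or 'hedges', got {flavor!r}")
    s_pooled = math.sqrt(((n1 - 1) * sd1**2 + (n0 - 1) * sd0**2) / (n1 + n0 - 2))
    d = (m1 - m0) / s_pooled
    se_d = math.sqrt(1 / n1 + 1 / n0 + d * d / (2 * (n1 + n0)))
    if flavor == "hedges":
        j = 1.0 - 3.0 / (4.0 * (n1 + n0 - 2) - 1.0)
        return EffectSize(estimate=j * d, se=j * se_d, scale="identity")
    return EffectSize(estimate=d, se=se_d, scale="identity")


def se_from_ci(
    lower: float, upper: float, level: float = 0.95, scale: str = "identity"
) -> float:
    """Standard error recovered from a symmetric confidence interval.

    SE = (t(upper) - t(lower)) / (2 z_crit) with t = log for ratio measures
    reported on the OR scale, identity otherwise.
    """
    if lower >= upper:
        raise ValueError(f"need lower < upper, got ({lower}, {upper})")
    if scale == "log":
        if lower <= 0:
            raise ValueError("log-scale bounds must be positive")
        lower, upper = math.log(lower), math.log(upper)
    elif scale != "identity":
        raise ValueError(f"scale must be 'identity' or 'log', got {scale!r}")
    return (upper - lower) / (2.0 * _z_crit(level))


def se_from_p(estimate: float, p: float) -> float:
    """Standard error from a point estimate and its two-sided p-value.

    SE = |estimate| / z with z the upper-tail normal quantile at p/2.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0,1), got {p}")
    if estimate == 0:
        raise ValueError("cannot recover an SE from a null estimate")
    z = float(stats.norm.isf(p / 2.0))
    return abs(estimate) / z


def hwe_test(counts: Sequence[float]) -> HweResult:
    """Chi-square test of Hardy-Weinberg equilibrium on a genotype triple.

    No continuity correction; 1 degree of freedom (three classes, one
    estimated allele frequency).  A monomorphic sample returns chi2 = 0,
    p = 1 with the ``monomorphic`` flag set.
    """
    if len(counts) != 3 or any(v < 0 for v in counts):
        raise ValueError("genotype triple must be 3 non-negative counts")
    n = sum(counts)
    if n <= 0:
        raise ValueError("total count must be positive")
    c2, c1, c0 = counts
    f_hat = (2 * c2 + c1) / (2.0 * n)
    if f_hat in (0.0, 1.0):
        return HweResult(chi2=0.0, p=1.0, f_hat=f_hat, monomorphic=True)
    expected = reconstruct_counts(f_hat, n)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, p=p, f_hat=f_hat)


# ---------------------------------------------------------------------------
# Record -> EffectSize derivation used by the pipeline.
# Pathway precedence for case-control records: reported OR/CI, then genotype
# counts, then Hardy-Weinberg reconstruction from case+control frequencies.
# ---------------------------------------------------------------------------


def derive_case_control_effect(
    record,
    model: GeneticModel | str = GeneticModel.ALLELE,
    correction: float | None = 0.5,
) -> tuple[EffectSize, str] | None:
    """Best-available effect size for a case-control study record.

    Returns ``(effect, pathway)`` with pathway one of ``"reported"``,
    ``"counts"``, ``"raf-reconstruction"``, or ``None`` when the record
    carries no usable information (the caller logs these).
    Reported ORs take precedence because they embed the original covariate
    adjustment; count pathways yield crude ORs.
    """
    model = GeneticModel(model) if not isinstance(model, GeneticModel) else model
    if record.reported_or is not None and record.reported_ci is not None:
        lo, hi = record.reported_ci
        se = se_from_ci(lo, hi, scale="log")
        eff = EffectSize(
            estimate=math.log(record.reported_or),
            se=se,
            scale="log",
            label=record.study_id,
            n=record.n_case + record.n_control,
        )
        return eff, "reported"
    if record.genotype_counts_case is not None and record.genotype_counts_control is not None:
        eff = or_from_counts(
            record.genotype_counts_case, record.genotype_counts_control, model, correction
        )
        return (
            replace(eff, label=record.study_id, n=record.n_case + record.n_control),
            "counts",
        )
    raf_case = getattr(record, "raf_case", None)
    if raf_case is not None and record.raf_control is not None:
        case = reconstruct_counts(raf_case, record.n_case)
        control = reconstruct_counts(record.raf_control, record.n_control)
        eff = or_from_counts(case, control, model, correction)
        return (
            replace(eff, label=record.study_id, n=record.n_case + record.n_control),
            "raf-reconstruction",
        )
    return None


def derive_quant_effect(
    record,
    contrast: str = "additive",
    flavor: str = "cohen",
) -> tuple[EffectSize, str] | None:
    """Effect size for a quantitative-trait study record.

    ``contrast="additive"`` yields the per-allele slope (reported beta with
    SE recovered from its CI or p-value when needed, else the grouped-dose
    regression over per-genotype means).  ``"het_vs_ref"``/``"hom_vs_ref"``
    yield SMDs of the het / hom-risk genotype against the hom-other
    reference.  Returns ``(effect, pathway)`` or ``None``.
    """
    if contrast == "additive":
        if record.beta is not None:
            if record.beta_se is not None:
                se = record.beta_se
                path = "beta-se"
            elif record.beta_ci is not None:
                se = se_from_ci(*record.beta_ci)
                path = "beta-ci"
            elif record.beta_p is not None:
                se = se_from_p(record.beta, record.beta_p)
                path = "beta-p"
            else:  # pragma: no cover - blocked by record validation
                return None
            return (
                EffectSize(record.beta, se, "identity", record.study_id, record.n),
                path,
            )
        if record.per_genotype is not None:
            eff = _dose_slope(record.per_genotype)
            if eff is None:
                return None
            return replace(eff, label=record.study_id, n=record.n), "genotype-means"
        return None
    if contrast in ("het_vs_ref", "hom_vs_ref"):
        if record.per_genotype is None:
            return None
        hom_risk, het, ref = record.per_genotype
        grp = het if contrast == "het_vs_ref" else hom_risk
        n1, m1, sd1 = grp
        n0, m0, sd0 = ref
        if n1 < 2 or n0 < 2:
            return None
        eff = smd(n1, m1, sd1, n0, m0, sd0, flavor=flavor)
        return replace(eff, label=record.study_id, n=record.n), "smd"
    raise ValueError(f"unknown contrast {contrast!r}")


def _dose_slope(per_genotype) -> EffectSize | None:
    """Per-allele OLS slope from per-genotype (n, mean, sd) summaries.

    Regressing the trait on allele dose with a categorical dose predictor is
    exactly recoverable from group summaries: the slope is the weighted LS
    fit through the group means, and the residual sum of squares decomposes
    into the within-group SS plus lack-of-fit of the means.
    """
    doses = (2.0, 1.0, 0.0)
    groups = [(g[0], g[1], g[2], x) for g, x in zip(per_genotype, doses) if g[0] > 0]
    if len(groups) < 2:
        return None
    n = sum(g[0] for g in groups)
    if n < 4:
        return None
    xbar = sum(g[0] * g[3] for g in groups) / n
    sxx = sum(g[0] * (g[3] - xbar) ** 2 for g in groups)
    if sxx <= 0:
        return None
    ybar = sum(g[0] * g[1] for g in groups) / n
    slope = sum(g[0] * (g[3] - xbar) * g[1] for g in groups) / sxx
    intercept = ybar - slope * xbar
    ss_within = sum((g[0] - 1) * g[2] ** 2 for g in groups if g[0] > 1)
    ss_lof = sum(g[0] * (g[1] - (intercept + slope * g[3])) ** 2 for g in groups)
    sigma2 = (ss_within + ss_lof) / (n - 2)
    if sigma2 <= 0:
        return None
    return EffectSize(estimate=slope, se=math.sqrt(sigma2 / sxx), scale="identity")
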