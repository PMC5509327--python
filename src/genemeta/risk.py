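"""Population attributable risk and case-control / quantitative-trait power.

PAR follows the multiplicative genotype model: with risk-allele frequency f
and per-allele odds ratio gamma, the mean population relative risk is

    X = (1-f)^2 + 2 f (1-f) gamma + f^2 gamma^2 = (1 + f (gamma - 1))^2

and PAR = (X - 1)/X.  The formula presupposes gamma > 1 for the named
allele; :func:`orient_risk_allele` flips a protective allele to its
complement (gamma -> 1/gamma, f -> 1-f) so PAR refers to a genuine risk
allele.

Power uses closed-form approximations for the 1-df per-allele trend test:
a normal approximation to the allele-count log-OR Wald test for
case-control designs, and the noncentral chi-square tail with
noncentrality n * 2 f (1-f) * beta^2 / sigma^2 for quantitative traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .effects import GeneticModel, _z_crit

__all__ = [
    "ParResult",
    "PowerSpec",
    "par_multiplicative",
    "orient_risk_allele",
    "power_case_control",
    "power_quantitative",
]


@dataclass(frozen=True)
class ParResult:
    """Population attributable risk under the multiplicative model."""

    f: float
    gamma: float
    X: float
    par: float

    @property
    def percent(self) -> float:
        return 100.0 * self.par


def par_multiplicative(f: float, gamma: float) -> ParResult:
    """PAR = (X-1)/X with X = (1 + f (gamma-1))^2.

    ``gamma`` must be oriented so the named allele is the risk allele
    (PAR is negative when gamma < 1; use :func:`orient_risk_allele` first
    if the reported OR is protective).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele frequency must be in [0,1], got {f}")
    if gamma <= 0:
        raise ValueError(f"per-allele OR must be positive, got {gamma}")
    x = (1.0 + f * (gamma - 1.0)) ** 2
    return ParResult(f=f, gamma=gamma, X=x, par=(x - 1.0) / x)


def orient_risk_allele(f: float, gamma: float) -> tuple[float, float, bool]:
    """Return (f, gamma, flipped) with gamma >= 1.

    When the named allele is protective (gamma < 1) the complementary
    allele is the risk allele: gamma inverts and f complements.
    """
    if gamma < 1.0:
        return (1.0 - f, 1.0 / gamma, True)
    return (f, gamma, False)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a power calculation.

    ``effect`` is the per-allele OR (case-control) or the per-allele trait
    slope in trait units (quantitative); ``f`` the risk-allele frequency;
    ``prevalence`` the population disease risk (case-control only);
    ``trait_sd`` the residual trait SD (quantitative only).
    """

    design: str
    effect: float
    f: float
    n_case: int | None = None
    n_control: int | None = None
    n: int | None = None
    prevalence: float | None = None
    trait_sd: float | None = None
    alpha: float = 0.05
    model: GeneticModel = GeneticModel.ADDITIVE

    def __post_init__(self) -> None:
        if self.design not in ("case_control", "quantitative"):
            raise ValueError(f"design must be 'case_control' or 'quantitative', got {self.design!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"allele frequency must be in (0,1), got {self.f}")
        if self.design == "case_control":
            if self.effect <= 0:
                raise ValueError("per-allele OR must be positive")
            if not (self.n_case and self.n_control and self.n_case > 0 and self.n_control > 0):
                raise ValueError("case_control design needs positive n_case and n_control")
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ValueError("case_control design needs a prevalence in (0,1)")
        else:
            if not (self.n and self.n > 0):
                raise ValueError("quantitative design needs a positive n")
            if self.trait_sd is None or self.trait_sd <= 0:
                raise ValueError("quantitative design needs a positive trait_sd")


def expected_allele_freqs(f: float, gamma: float, prevalence: float) -> tuple[float, float]:
    """Expected risk-allele frequencies in (cases, unaffected controls).

    Under HWE at population frequency f and multiplicative penetrance
    r0 * gamma^dose scaled to the stated prevalence: case genotype
    frequencies are HWE at f*gamma/s with s = 1 + f(gamma-1); unaffected
    controls deplete the risk allele according to 1 - r0 gamma^dose.
    """
    s = 1.0 + f * (gamma - 1.0)
    f_case = f * gamma / s
    f_ctrl = f * (1.0 - prevalence * gamma / s) / (1.0 - prevalence)
    return f_case, f_ctrl


def power_case_control(spec: PowerSpec) -> float:
    """Two-sided power of the per-allele (allele-count trend) test.

    Expected allele frequencies in cases and controls are derived from
    (f, gamma, prevalence); power is the normal-approximation power of the
    allele-count log-OR Wald test at the implied counts.
    """
    if spec.design != "case_control":
        raise ValueError("spec.design must be 'case_control'")
    gamma = spec.effect
    f1, f0 = expected_allele_freqs(spec.f, gamma, spec.prevalence)
    if not (0.0 < f1 < 1.0 and 0.0 < f0 < 1.0):
        raise ValueError("implied allele frequencies degenerate; check f, gamma, prevalence")
    log_or = math.log(f1 * (1.0 - f0) / ((1.0 - f1) * f0))
    a1, a0 = 2.0 * spec.n_case, 2.0 * spec.n_control
    se = math.sqrt(
        1.0 / (a1 * f1) + 1.0 / (a1 * (1.0 - f1)) + 1.0 / (a0 * f0) + 1.0 / (a0 * (1.0 - f0))
    )
    zc = _z_crit(1.0 - spec.alpha)
    ncp = abs(log_or) / se
    return float(stats.norm.cdf(ncp - zc) + stats.norm.cdf(-ncp - zc))


def power_quantitative(spec: PowerSpec) -> float:
    """Power of the per-allele linear trend test for a quantitative trait.

    Noncentrality lambda = n * 2 f (1-f) * beta^2 / sigma^2 (the allele
    dose has variance 2f(1-f) under HWE); power is the noncentral
    chi-square(1, lambda) mass above the central chi-square alpha cutoff.
    """
    if spec.design != "quantitative":
        raise ValueError("spec.design must be 'quantitative'")
    lam = spec.n * 2.0 * spec.f * (1.0 - spec.f) * spec.effect**2 / spec.trait_sd**2
    crit = stats.chi2.isf(spec.alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam)) if lam > 0 else spec.alpha
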