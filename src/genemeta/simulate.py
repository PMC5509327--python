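"""Synthetic multi-study datasets with the structure the pipeline assumes.

Each scenario draws per-study true effects theta_i ~ Normal(mu, tau^2)
(the random-effects model), study-specific risk-allele frequencies and
sizes, and genotype data under Hardy-Weinberg equilibrium, then emits
records in the exact schemas the readers validate.

Case-control studies use multiplicative penetrance: case genotype
frequencies are proportional to p_g * gamma^dose (gamma = exp(theta_i)),
which is again HWE at f*gamma/(1 + f(gamma-1)); prevalence cancels in that
normalization.  Controls are drawn from the population genotype
distribution by default (``control_source="population"``), which makes the
study-level allele-count log-OR equal theta_i exactly in expectation;
``control_source="unaffected"`` excludes cases at the stated prevalence
instead, as in a classic case-control sample, at the cost of a small
upward distortion of the allele OR relative to gamma.

Quantitative studies sample genotype counts multinomially under HWE and
then draw the per-genotype sample means and SDs from their exact sampling
distributions (Normal and scaled chi-square) around baseline +
theta_i * dose; the per-allele slope and SE reported per study are
algebraically identical to the subject-level OLS fit on allele dose.

Randomness contract: one integer seed determines everything; study i uses
the substream seeded by (seed, i), so growing k never reshuffles earlier
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .effects import genotype_freqs_from_raf, hwe_test
from .io import CaseControlStudy, QuantStudy, SnpRaf, StudyTable

__all__ = [
    "SimScenario",
    "simulate_case_control_meta",
    "simulate_quant_meta",
    "scenario_library",
    "get_scenario",
]


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one synthetic meta-analysis.

    ``mu`` is the true pooled effect (log-OR for case-control, trait units
    per allele for quantitative); ``tau`` the between-study SD of true
    effects; ``raf_range``/``n_range`` the uniform supports of per-study
    risk-allele frequencies and per-group (case-control) or total
    (quantitative) sizes.  ``baseline`` is the genotype-0 trait mean
    (5.0 mmol/l, a typical normoglycemic fasting glucose).
    """

    design: str
    k: int
    mu: float
    tau: float
    raf_range: tuple[float, float] = (0.6, 0.97)
    n_range: tuple[int, int] = (500, 5000)
    prevalence: float = 0.088
    trait_sd: float = 0.8
    baseline: float = 5.0
    seed: int = 0
    snp_id: str = "simSNP"
    control_source: str = "population"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.design not in ("case_control", "quantitative"):
            raise ValueError(f"design must be 'case_control' or 'quantitative', got {self.design!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        lo, hi = self.raf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError(f"raf_range must satisfy 0 < lo <= hi < 1, got {self.raf_range}")
        if self.n_range[0] > self.n_range[1] or self.n_range[0] < 4:
            raise ValueError(f"n_range must be ordered with lo >= 4, got {self.n_range}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        if self.trait_sd < 0:
            raise ValueError("trait_sd must be >= 0")
        if self.control_source not in ("population", "unaffected"):
            raise ValueError("control_source must be 'population' or 'unaffected'")


def _study_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))


def _draw_common(sc: SimScenario, i: int):
    rng = _study_rng(sc.seed, i)
    theta = sc.mu + sc.tau * rng.standard_normal()
    f = rng.uniform(*sc.raf_range)
    return rng, theta, f


def simulate_case_control_meta(scenario: SimScenario) -> StudyTable:
    """Generate a case-control study table under the scenario."""
    if scenario.design != "case_control":
        raise ValueError("scenario.design must be 'case_control'")
    records = []
    for i in range(scenario.k):
        rng, theta, f = _draw_common(scenario, i)
        gamma = math.exp(theta)
        n_case = int(rng.integers(scenario.n_range[0], scenario.n_range[1] + 1))
        n_control = int(rng.integers(scenario.n_range[0], scenario.n_range[1] + 1))
        pop = genotype_freqs_from_raf(f)  # (hom-risk, het, hom-other)
        x = (1.0 + f * (gamma - 1.0)) ** 2
        case_p = (pop[0] * gamma**2 / x, pop[1] * gamma / x, pop[2] / x)
        if scenario.control_source == "population":
            ctrl_p = pop
        else:
            r0 = scenario.prevalence / x
            raw = (pop[0] * (1 - r0 * gamma**2), pop[1] * (1 - r0 * gamma), pop[2] * (1 - r0))
            tot = sum(raw)
            ctrl_p = tuple(v / tot for v in raw)
        case_counts = tuple(int(v) for v in rng.multinomial(n_case, case_p))
        ctrl_counts = tuple(int(v) for v in rng.multinomial(n_control, ctrl_p))
        f_ctrl_hat = (2 * ctrl_counts[0] + ctrl_counts[1]) / (2.0 * n_control)
        records.append(CaseControlStudy(
            study_id=f"sim{i:03d}",
            ethnicity="mixed",
            snp_id=scenario.snp_id,
            risk_allele="R",
            n_case=n_case,
            n_control=n_control,
            raf_control=f_ctrl_hat,
            genotype_counts_case=case_counts,
            genotype_counts_control=ctrl_counts,
            hwe_ok=hwe_test(ctrl_counts).hwe_ok,
        ))
    warnings = []
    for r in records:
        warnings.extend(r.validate())
    return StudyTable(records, outcome="T2D", snp_id=scenario.snp_id, warnings=warnings)


def _grouped_slope(counts, means, sds):
    """Weighted LS slope/SE through per-genotype means (doses 2, 1, 0)."""
    doses = (2.0, 1.0, 0.0)
    groups = [(n, m, s, x) for n, m, s, x in zip(counts, means, sds, doses) if n > 0]
    n = sum(g[0] for g in groups)
    xbar = sum(g[0] * g[3] for g in groups) / n
    sxx = sum(g[0] * (g[3] - xbar) ** 2 for g in groups)
    ybar = sum(g[0] * g[1] for g in groups) / n
    slope = sum(g[0] * (g[3] - xbar) * g[1] for g in groups) / sxx
    intercept = ybar - slope * xbar
    ss_within = sum((g[0] - 1) * g[2] ** 2 for g in groups if g[0] > 1)
    ss_lof = sum(g[0] * (g[1] - (intercept + slope * g[3])) ** 2 for g in groups)
    sigma2 = (ss_within + ss_lof) / (n - 2)
    se = math.sqrt(sigma2 / sxx) if sigma2 > 0 else 0.0
    return slope, se


def simulate_quant_meta(scenario: SimScenario) -> StudyTable:
    """Generate a quantitative-trait study table under the scenario.

    Studies in which every genotype class has at least 2 subjects (and
    trait_sd > 0) carry full per-genotype (n, mean, sd) summaries alongside
    the per-allele slope; otherwise the study is emitted as a beta-only
    record — the degenerate-class rule, since rare-homozygote classes are
    routinely empty at high risk-allele frequencies.
    """
    if scenario.design != "quantitative":
        raise ValueError("scenario.design must be 'quantitative'")
    records = []
    for i in range(scenario.k):
        rng, theta, f = _draw_common(scenario, i)
        n = int(rng.integers(scenario.n_range[0], scenario.n_range[1] + 1))
        probs = genotype_freqs_from_raf(f)
        counts = tuple(int(v) for v in rng.multinomial(n, probs))
        tries = 0
        while sum(c > 0 for c in counts) < 2:  # need 2 dose classes for a slope
            counts = tuple(int(v) for v in rng.multinomial(n, probs))
            tries += 1
            if tries > 1000:
                raise RuntimeError("cannot draw a polymorphic study; raf_range too extreme")
        doses = (2.0, 1.0, 0.0)
        means, sds = [], []
        for c, dose in zip(counts, doses):
            mu_g = scenario.baseline + theta * dose
            if c == 0:
                means.append(0.0)
                sds.append(0.0)
                continue
            m = mu_g + scenario.trait_sd * rng.standard_normal() / math.sqrt(c)
            if c > 1 and scenario.trait_sd > 0:
                ss = scenario.trait_sd**2 * rng.chisquare(c - 1)
                sds.append(math.sqrt(ss / (c - 1)))
            else:
                sds.append(0.0)
            means.append(m)
        slope, se = _grouped_slope(counts, means, sds)
        f_hat = (2 * counts[0] + counts[1]) / (2.0 * n)
        hwe_ok = hwe_test(counts).hwe_ok
        full = all(c >= 2 for c in counts) and scenario.trait_sd > 0
        per_genotype = (
            tuple((c, m, s) for c, m, s in zip(counts, means, sds)) if full else None
        )
        records.append(QuantStudy(
            study_id=f"sim{i:03d}",
            ethnicity="mixed",
            snps=(SnpRaf(scenario.snp_id, "R", f_hat),),
            n=n,
            per_genotype=per_genotype,
            beta=slope,
            beta_se=max(se, 1e-12),
            hwe_ok=hwe_ok,
        ))
    warnings = []
    for r in records:
        warnings.extend(r.validate())
    return StudyTable(records, outcome="FG", snp_id=scenario.snp_id, warnings=warnings)


def scenario_library() -> dict[str, SimScenario]:
    """Named preset scenarios.

    A ``g6pc2-fg-like``: 32 fasting-glucose studies, mu = 0.07 mmol/l per
    allele, tau = 0.01, allele frequencies 0.6-0.97 — the shape of the
    large rs560887/FG meta-analysis.
    B ``null-symmetric``: mu = 0, tau = 0 quantitative studies with varied
    sizes, for type-I-error checks of the bias tests.
    C ``hetero-or``: 15 case-control studies, mu = ln 0.96, tau = 0.05,
    prevalence 8.8%.
    """
    return {
        "A": SimScenario(design="quantitative", k=32, mu=0.07, tau=0.01,
                         raf_range=(0.6, 0.97), n_range=(500, 5000), trait_sd=0.8,
                         baseline=5.0, name="g6pc2-fg-like"),
        "B": SimScenario(design="quantitative", k=15, mu=0.0, tau=0.0,
                         raf_range=(0.6, 0.97), n_range=(500, 5000), trait_sd=0.8,
                         baseline=5.0, name="null-symmetric"),
        "C": SimScenario(design="case_control", k=15, mu=math.log(0.96), tau=0.05,
                         raf_range=(0.69, 0.97), n_range=(1000, 4000),
                         prevalence=0.088, name="hetero-or"),
    }


def get_scenario(name: str, seed: int | None = None, **overrides) -> SimScenario:
    """Fetch a preset by letter, optionally re-seeded / tweaked."""
    lib = scenario_library()
    if name not in lib:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(lib)}")
    sc = lib[name]
    if seed is not None:
        overrides["seed"] = seed
    return replace(sc, **overrides) if overrides else sc
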