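"""Cohort simulation under the liability-threshold and logit risk models.

An individual's liability is ``L = A + R + e``: ``A`` is the polygenic
burden (a calibrated sum over standardized common-variant dosages, with
variance ``h2_pb``), ``R = beta_lev * G_lev`` is the contribution of the
large-effect variant, and ``e`` is a Gaussian residual topping the
variance up to 1.  Under the liability-threshold model an individual is
a case iff ``L > t = Phi^-1(1-K)``; under the logit risk model case
status is a Bernoulli draw with probability ``logit^-1(u1*(A+R) + u0)``,
with ``u0`` calibrated so the population prevalence is ``K``.

Genotypes are independent biallelic variants in Hardy-Weinberg
proportions (a post-LD-pruning panel); the only LD supported is an
optional D' = 1 coupling between the LEV and the largest-effect common
variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Optional, Tuple

import numpy as np
from scipy import optimize, special, stats

from . import _kernels
from .architectures import (
    ArchitectureSpec,
    EffectSizeSet,
    LevSpec,
    ParameterError,
    PgsWeightSet,
    VariantPanel,
    draw_effect_sizes,
    make_pgs_weights,
)

__all__ = [
    "TraitModel",
    "SimulatedCohort",
    "GenotypeBlock",
    "simulate_genotypes",
    "simulate_lev_genotype",
    "compute_pb",
    "compute_pgs",
    "assign_cases_liability",
    "calibrate_logit_intercept",
    "assign_cases_logit",
    "map_logit_to_liability_score",
    "simulate_cohort",
    "carrier_case_risk",
]

LiabilityModel = Literal["liability_threshold", "logit"]
DependenceMode = Literal["independent", "dprime_one"]


class DegenerateScoreError(ValueError):
    """The scoring instrument has zero variance."""


@dataclass(frozen=True)
class TraitModel:
    """All generative parameters of one simulated trait."""

    h2_pb: float
    lev: LevSpec
    prevalence: float
    liability_model: LiabilityModel = "liability_threshold"
    pi0: float = 0.0
    pgs_mode: str = "dropped_causals"
    subtype_lambda: float = 0.0
    subtype_minor_proportion: float = 0.0
    interaction_h2: float = 0.0
    dependence: DependenceMode = "independent"
    logit_slope: float = 1.0
    threshold_mode: Literal["calibrated", "nominal"] = "calibrated"

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ParameterError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not 0.0 <= self.h2_pb < 1.0:
            raise ParameterError(f"h2_pb must be in [0, 1), got {self.h2_pb}")
        if self.interaction_h2 < 0:
            raise ParameterError("interaction_h2 must be nonnegative")
        if not 0.0 <= self.subtype_minor_proportion <= 0.5:
            raise ParameterError("minor-subtype proportion must be in [0, 0.5]")
        if self.subtype_lambda < 0:
            raise ParameterError("subtype lambda must be nonnegative")
        if self.residual_variance <= 0:
            raise ParameterError(
                "h2_pb + h2_lev + interaction_h2 must be < 1 "
                f"(residual variance {self.residual_variance:.4g})"
            )
        if self.liability_model not in ("liability_threshold", "logit"):
            raise ParameterError(f"unknown liability model {self.liability_model!r}")

    @property
    def residual_variance(self) -> float:
        return 1.0 - self.h2_pb - self.lev.h2_lev - self.interaction_h2

    @property
    def nominal_threshold(self) -> float:
        """The textbook threshold Phi^-1(1 - K), exact when the liability
        is Gaussian (no LEV)."""
        return float(stats.norm.ppf(1.0 - self.prevalence))

    @property
    def threshold(self) -> float:
        """Liability threshold.

        In ``calibrated`` mode (default) t is solved so the population
        case rate equals K exactly under the LEV-mixture liability,
        honoring K = E[p]; a strong rare LEV skews the liability
        distribution, so the nominal Phi^-1(1-K) would inflate the case
        rate.  ``nominal`` mode returns Phi^-1(1-K) regardless.  The two
        coincide when h2_lev = 0.
        """
        if self.threshold_mode == "nominal":
            return self.nominal_threshold
        return _calibrated_threshold(
            self.prevalence, self.lev.beta_lev, self.lev.freq, self.lev.h2_lev
        )

    @property
    def subtype_active(self) -> bool:
        return self.subtype_lambda != 0.0 and self.subtype_minor_proportion > 0.0


@lru_cache(maxsize=4096)
def _calibrated_threshold(k: float, beta: float, f: float, h2_lev: float) -> float:
    """Solve P(A + beta*G + e > t) = K with A + e ~ N(0, 1 - h2_lev) and
    G ~ HWE(f)."""
    nominal = float(stats.norm.ppf(1.0 - k))
    if beta == 0.0 or f == 0.0:
        return nominal
    sd = np.sqrt(1.0 - h2_lev)
    pg = np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2])
    geno = np.array([0.0, 1.0, 2.0])

    def case_rate(t: float) -> float:
        return float((pg * stats.norm.sf((t - beta * geno) / sd)).sum())

    # the mixture has a heavier right tail, so the root lies at or above
    # the nominal threshold
    lo, hi = nominal - 1.0, nominal + 8.0 * (1.0 + beta)
    return float(optimize.brentq(lambda t: case_rate(t) - k, lo, hi, xtol=1e-12))


@dataclass
class SimulatedCohort:
    """One simulated sample of N individuals."""

    n: int
    lev_genotype: np.ndarray
    pb_true: np.ndarray
    pgs: np.ndarray
    case: np.ndarray
    trait: TraitModel
    liability: Optional[np.ndarray] = None
    risk_prob: Optional[np.ndarray] = None
    residual: Optional[np.ndarray] = None
    threshold: Optional[float] = None
    dosages: Optional[np.ndarray] = None

    @property
    def carrier(self) -> np.ndarray:
        """Dominant coding: an LEV carrier holds >= 1 risk allele."""
        return self.lev_genotype >= 1

    @property
    def n_cases(self) -> int:
        return int(self.case.sum())


@dataclass
class GenotypeBlock:
    """Raw allele counts for a panel of independent HWE variants."""

    counts: np.ndarray  # n x m, int8, values 0/1/2
    panel: VariantPanel
    monomorphic: np.ndarray  # per-variant flag: still monomorphic after one resample

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def standardized(self, mode: str = "empirical") -> np.ndarray:
        """Column-standardized dosages.

        ``empirical`` centres/scales by sample moments (monomorphic
        columns are zeroed); ``population`` uses the HWE moments
        2f and sqrt(2f(1-f)) at the 16-bit-quantized frequency.
        """
        g = self.counts.astype(np.float64)
        if mode == "empirical":
            mu = g.mean(axis=0)
            sd = g.std(axis=0)
            sd[sd == 0] = np.inf  # monomorphic -> zero column
            return (g - mu) / sd
        if mode == "population":
            f = _effective_maf(self.panel.maf)
            return (g - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
        raise ParameterError(f"unknown standardization mode {mode!r}")


def _effective_maf(maf: np.ndarray) -> np.ndarray:
    """The frequency actually realized by the 16-bit draw thresholds."""
    return _kernels.maf_to_threshold(maf) / _kernels.U16_SCALE


def simulate_genotypes(panel: VariantPanel, n: int, rng: np.random.Generator) -> GenotypeBlock:
    """Draw raw allele counts ~ Binomial(2, maf), independent across
    variants and individuals.  Columns that come out monomorphic are
    resampled once and flagged if still monomorphic."""
    if n < 2:
        raise ParameterError(f"need at least 2 individuals, got {n}")
    counts = _kernels.simulate_genotype_matrix(rng, panel.maf, n)
    mono = (counts == counts[0]).all(axis=0)
    if mono.any():
        idx = np.flatnonzero(mono)
        redraw = _kernels.simulate_genotype_matrix(rng, panel.maf[idx], n)
        counts[:, idx] = redraw
        mono = np.zeros(panel.n_variants, dtype=bool)
        mono[idx] = (redraw == redraw[0]).all(axis=0)
        if mono.any():
            warnings.warn(
                f"{int(mono.sum())} variant(s) monomorphic after one resample",
                stacklevel=2,
            )
    return GenotypeBlock(counts, panel, mono)


def simulate_lev_genotype(
    lev: LevSpec,
    n: int,
    rng: np.random.Generator,
    dependence: DependenceMode = "independent",
    partner_haplotypes: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    partner_freq: Optional[float] = None,
) -> np.ndarray:
    """LEV allele counts (0/1/2).

    ``independent``: two Bernoulli(f) haplotype draws per individual.
    ``dprime_one``: the LEV allele is placed only on haplotypes carrying
    the partner variant's effect allele, with conditional frequency
    ``f / f_partner``, which realizes D' = 1 in expectation.  The LEV
    column is never resampled: absence of carriers is meaningful.
    """
    f = lev.freq
    if f == 0.0:
        return np.zeros(n, dtype=np.int8)
    if dependence == "independent":
        hap1 = rng.random(n) < f
        hap2 = rng.random(n) < f
        return (hap1.astype(np.int8) + hap2.astype(np.int8)).astype(np.int8)
    if dependence == "dprime_one":
        if partner_haplotypes is None or partner_freq is None:
            raise ParameterError("dprime_one mode requires partner haplotypes and frequency")
        if f > partner_freq:
            raise ParameterError(
                f"LEV frequency {f} exceeds partner frequency {partner_freq}; D'=1 impossible"
            )
        cond = f / partner_freq
        a, b = partner_haplotypes
        hap1 = a & (rng.random(n) < cond)
        hap2 = b & (rng.random(n) < cond)
        return (hap1.astype(np.int8) + hap2.astype(np.int8)).astype(np.int8)
    raise ParameterError(f"unknown dependence mode {dependence!r}")


def compute_pb(dosages_std: np.ndarray, effects: EffectSizeSet) -> np.ndarray:
    """True polygenic burden: the effect-weighted sum of standardized
    dosages (expected variance h2_pb)."""
    if dosages_std.shape[1] != effects.n_variants:
        raise ParameterError(
            f"dosage block has {dosages_std.shape[1]} variants, effects {effects.n_variants}"
        )
    return dosages_std @ effects.beta_pb


def compute_pgs(dosages_std: np.ndarray, weights: PgsWeightSet) -> np.ndarray:
    """Estimated score: z-scored weighted sum over the scored columns."""
    if dosages_std.shape[1] != weights.n_scored:
        raise ParameterError(
            f"dosage block has {dosages_std.shape[1]} columns, weight set {weights.n_scored}"
        )
    raw = dosages_std @ weights.weights
    sd = raw.std()
    if sd == 0:
        raise DegenerateScoreError("PGS has zero variance (all weights zero?)")
    return (raw - raw.mean()) / sd


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise DegenerateScoreError("score has zero variance")
    return (x - x.mean()) / sd


def assign_cases_liability(
    pb_true: np.ndarray,
    lev_genotype: np.ndarray,
    lev: LevSpec,
    trait: TraitModel,
    rng: np.random.Generator,
    interaction_dosage: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Liability-threshold case assignment.

    Returns (liability, threshold, case, residual).  With disease
    subtypes, a Bernoulli(minor_proportion) subset of individuals gets
    its PB scaled by (1 + lambda); the liability is not re-normalized.
    With an interaction term, the standardized product of the top
    common variant's dosage and the LEV genotype enters scaled to
    contribute exactly ``interaction_h2`` to var(L).
    """
    n = len(pb_true)
    a = pb_true
    if trait.subtype_active:
        minor = rng.random(n) < trait.subtype_minor_proportion
        a = np.where(minor, (1.0 + trait.subtype_lambda) * pb_true, pb_true)
    inter = 0.0
    if trait.interaction_h2 > 0:
        if interaction_dosage is None:
            raise ParameterError("interaction_h2 > 0 requires the top-variant dosage column")
        prod = interaction_dosage * lev_genotype
        sd = prod.std()
        if sd == 0:
            warnings.warn("interaction term degenerate (no LEV carriers); omitted", stacklevel=2)
        else:
            inter = np.sqrt(trait.interaction_h2) * (prod - prod.mean()) / sd
    resid_var = trait.residual_variance
    e = rng.standard_normal(n) * np.sqrt(resid_var)
    liability = a + lev.beta_lev * lev_genotype + inter + e
    t = trait.threshold
    case = liability > t
    return liability, t, case, e


def calibrate_logit_intercept(
    trait: TraitModel,
    n_quad: int = 201,
    tol: float = 1e-9,
) -> float:
    """Solve for the logit intercept u0 with E[logit^-1(u1*x + u0)] = K.

    The expectation is over x = A + R with A ~ N(0, h2_pb) and the LEV
    genotype in HWE; evaluated by Gauss-Hermite quadrature and solved by
    bracketed root-finding.  |E[p] - K| < 1e-6 at the returned u0.
    """
    k = trait.prevalence
    u1 = trait.logit_slope
    f = trait.lev.freq
    beta = trait.lev.beta_lev
    nodes, w = np.polynomial.hermite_e.hermegauss(n_quad)
    w = w / w.sum()
    a = nodes * np.sqrt(trait.h2_pb) if trait.h2_pb > 0 else np.zeros_like(nodes)
    geno = np.array([0.0, 1.0, 2.0])
    pg = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])

    def mean_risk(u0: float) -> float:
        z = u1 * (a[:, None] + beta * geno[None, :]) + u0
        return float((w[:, None] * pg[None, :] * special.expit(z)).sum())

    lo, hi = -60.0, 60.0
    if not mean_risk(lo) < k < mean_risk(hi):
        raise ParameterError(
            f"cannot bracket logit intercept for K={k} (E[p] range "
            f"[{mean_risk(lo):.3g}, {mean_risk(hi):.3g}])"
        )
    u0 = optimize.brentq(lambda u: mean_risk(u) - k, lo, hi, xtol=tol)
    assert abs(mean_risk(u0) - k) < 1e-6
    return float(u0)


def assign_cases_logit(
    x: np.ndarray,
    u0: float,
    u1: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Bernoulli case draw: p = logit^-1(u1*x + u0)."""
    p = special.expit(u1 * np.asarray(x, dtype=np.float64) + u0)
    case = rng.random(len(p)) < p
    return p, case


def map_logit_to_liability_score(
    x_logit: np.ndarray,
    u0: float,
    u1: float,
    trait: TraitModel,
) -> np.ndarray:
    """Map a logit-model genetic risk score to the liability-model score
    carrying the same disease risk probability: (Phi*)^-1(logit^-1(.))."""
    p = special.expit(u1 * np.asarray(x_logit, dtype=np.float64) + u0)
    eps = 1e-15
    if np.any(p <= eps) or np.any(p >= 1 - eps):
        warnings.warn("risk probabilities at the boundary were clipped", stacklevel=2)
        p = np.clip(p, eps, 1 - eps)
    sd = np.sqrt(1.0 - trait.h2_pb - trait.lev.h2_lev)
    return trait.threshold + sd * stats.norm.ppf(p)


def carrier_case_risk(trait: TraitModel, g: int) -> float:
    """Closed-form P(case | G_LEV = g) under the liability-threshold
    model: Phi((g*beta - t)/sqrt(1 - h2_lev)), the conditional variance
    collecting PB plus residual."""
    sd = np.sqrt(1.0 - trait.lev.h2_lev)
    return float(stats.norm.cdf((g * trait.lev.beta_lev - trait.threshold) / sd))


def simulate_cohort(
    trait: TraitModel,
    arch: ArchitectureSpec,
    panel: VariantPanel,
    n: int,
    n_pb: int = 2000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    keep_dosages: bool = False,
) -> SimulatedCohort:
    """Simulate one full cohort: causal-variant sampling, effect draws,
    genotypes, PGS construction, and case assignment.

    All randomness flows from a single generator.  The default path
    accumulates PB and PGS in a fused pass without materializing the
    dosage matrix; ``keep_dosages=True`` materializes it (same draws,
    same genotypes) for downstream inspection.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n < 2:
        raise ParameterError(f"need at least 2 individuals, got {n}")

    causal = panel.sample(n_pb, rng)
    effects = draw_effect_sizes(causal, arch, trait.h2_pb, rng)
    pgs_w = make_pgs_weights(
        effects, trait.pi0, mode=trait.pgs_mode, panel_nulls=panel, rng=rng if trait.pi0 > 0 else None
    )

    # column layout: causal panel first, then any null columns
    if pgs_w.null_panel is not None:
        maf_cols = np.concatenate([causal.maf, pgs_w.null_panel.maf])
    else:
        maf_cols = causal.maf
    m = len(maf_cols)
    f_eff = _effective_maf(maf_cols)
    sd_cols = np.sqrt(2.0 * f_eff * (1.0 - f_eff))

    w_pb = np.zeros(m)
    w_pb[: effects.n_variants] = effects.beta_pb
    w_pgs = np.zeros(m)
    w_pgs[pgs_w.causal_indices] = pgs_w.weights[: len(pgs_w.causal_indices)]
    if pgs_w.null_panel is not None:
        w_pgs[effects.n_variants :] = pgs_w.null_weights

    need_special = trait.dependence == "dprime_one" or trait.interaction_h2 > 0
    special_j = int(np.argmax(np.abs(effects.beta_pb))) if need_special else -1

    dosages = None
    if keep_dosages:
        counts = _kernels.simulate_genotype_matrix(rng, maf_cols, n)
        g = counts.astype(np.float64)
        z = (g - 2.0 * f_eff) / sd_cols
        pb = z @ w_pb
        pgs_raw = z @ w_pgs
        hap_a = hap_b = None
        if need_special:
            # haplotype phase is not recoverable from counts; dependence
            # mode therefore requires the fused path
            if trait.dependence == "dprime_one":
                raise ParameterError("dprime_one requires the fused path (keep_dosages=False)")
            z_special = z[:, special_j]
        dosages = counts
    else:
        pb_raw, pgs_raw, hap_a, hap_b = _kernels.simulate_scores(
            rng, maf_cols, w_pb / sd_cols, w_pgs / sd_cols, n, special_j
        )
        pb = pb_raw - float((2.0 * f_eff / sd_cols) @ w_pb)
        pgs_raw = pgs_raw - float((2.0 * f_eff / sd_cols) @ w_pgs)
        if need_special:
            g_special = hap_a.astype(np.float64) + hap_b.astype(np.float64)
            z_special = (g_special - 2.0 * f_eff[special_j]) / sd_cols[special_j]

    if trait.dependence == "dprime_one":
        lev_geno = simulate_lev_genotype(
            trait.lev,
            n,
            rng,
            dependence="dprime_one",
            partner_haplotypes=(hap_a, hap_b),
            partner_freq=float(f_eff[special_j]),
        )
    else:
        lev_geno = simulate_lev_genotype(trait.lev, n, rng)

    if trait.liability_model == "liability_threshold":
        liability, t, case, resid = assign_cases_liability(
            pb,
            lev_geno,
            trait.lev,
            trait,
            rng,
            interaction_dosage=z_special if trait.interaction_h2 > 0 else None,
        )
        risk_prob = None
    else:
        u0 = calibrate_logit_intercept(trait)
        x = pb + trait.lev.beta_lev * lev_geno
        if trait.subtype_active:
            minor = rng.random(n) < trait.subtype_minor_proportion
            x = np.where(minor, (1.0 + trait.subtype_lambda) * pb, pb) + trait.lev.beta_lev * lev_geno
        risk_prob, case = assign_cases_logit(x, u0, trait.logit_slope, rng)
        liability = None
        t = None
        resid = None

    return SimulatedCohort(
        n=n,
        lev_genotype=lev_geno,
        pb_true=pb,
        pgs=_zscore(pgs_raw),
        case=case,
        trait=trait,
        liability=liability,
        risk_prob=risk_prob,
        residual=resid,
        threshold=t,
        dosages=dosages,
    )
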