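"""Effect-size architectures for the common-variant polygenic burden (PB)
and the large-effect variant (LEV).

Three architectures for the per-variant effect variance on standardized
genotypes are supported:

``polygenic``
    every causal variant explains the same expected variance,
    ``h2_pb / N_PB`` (the alpha model at alpha = -1);
``negative_selection``
    variance proportional to ``[f(1-f)]**(1+alpha)`` with alpha = -0.37
    by default: rare variants carry larger per-allele effects than under
    neutrality, but relative to the equal-share alpha = -1 baseline the
    per-variant variance share scales with heterozygosity;
``ldak``
    the negative-selection form additionally weighted by
    ``w = 1/(1+ld_score)`` (alpha = -0.25 by default), shifting signal
    toward low-LD regions.

The proportionality constant is computed, not sampled: effects are drawn
``beta_i ~ N(0, C * s_i)`` with ``C = h2_pb / sum(s_i)``, so the summed
expected variance contributions equal ``h2_pb`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "VariantPanel",
    "ArchitectureSpec",
    "EffectSizeSet",
    "LevSpec",
    "PgsWeightSet",
    "DEFAULT_ALPHA",
    "draw_effect_sizes",
    "compute_lev_beta",
    "lev_h2_from_or",
    "select_top_lev",
    "make_pgs_weights",
    "synthetic_panel",
]

ArchitectureName = Literal["polygenic", "negative_selection", "ldak"]
PgsNoiseMode = Literal["weighted_nulls", "dropped_causals"]

DEFAULT_ALPHA: dict = {"polygenic": -1.0, "negative_selection": -0.37, "ldak": -0.25}

#: scored-variant count used in desk-scale runs; the full-scale panel of the
#: reference analyses had 95,593 LD-pruned common variants.
N_PB_DESK = 2000
N_PB_FULL = 95_593


class ParameterError(ValueError):
    """A model parameter is outside its valid domain."""


@dataclass(frozen=True)
class VariantPanel:
    """Per-variant MAF and LD score defining the common-variant universe."""

    variant_id: np.ndarray
    maf: np.ndarray
    ld_score: np.ndarray

    def __post_init__(self):
        vid = np.asarray(self.variant_id, dtype=object)
        maf = np.asarray(self.maf, dtype=np.float64)
        ld = np.asarray(self.ld_score, dtype=np.float64)
        object.__setattr__(self, "variant_id", vid)
        object.__setattr__(self, "maf", maf)
        object.__setattr__(self, "ld_score", ld)
        if not (len(vid) == len(maf) == len(ld)):
            raise ParameterError("panel columns have unequal lengths")
        if len(maf) < 1:
            raise ParameterError("panel must contain at least one variant")
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ParameterError("all MAFs must lie in (0, 0.5]")
        if np.any(ld < 0) or np.any(~np.isfinite(ld)):
            raise ParameterError("LD scores must be finite and nonnegative")
        if len(set(vid)) != len(vid):
            raise ParameterError("variant ids must be unique")

    @property
    def n_variants(self) -> int:
        return len(self.maf)

    def sample(self, n: int, rng: np.random.Generator, replace: bool = True) -> "VariantPanel":
        """Resample ``n`` variants (with replacement by default).

        Resampled ids are suffixed to keep the uniqueness invariant.
        """
        idx = rng.choice(self.n_variants, size=n, replace=replace)
        ids = np.array(
            [f"{self.variant_id[i]}#{k}" for k, i in enumerate(idx)], dtype=object
        )
        return VariantPanel(ids, self.maf[idx], self.ld_score[idx])


def synthetic_panel(
    n_variants: int = N_PB_DESK,
    seed: int = 0,
    maf_range: Tuple[float, float] = (0.01, 0.5),
    ld_shape: float = 1.5,
    ld_scale: float = 20.0,
    maf_distribution: Literal["uniform", "sfs"] = "uniform",
) -> VariantPanel:
    """Built-in synthetic panel mimicking an LD-pruned common-variant set.

    MAF is Uniform over the common range by default; ``sfs`` draws it
    with density proportional to 1/f (a neutral-spectrum shape closer to
    a real common-variant panel, relevant when contrasting MAF-dependent
    architectures).  LD scores are 1 + Gamma(shape, scale), mean ~ 30.
    """
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    if maf_distribution == "uniform":
        maf = rng.uniform(lo, hi, n_variants)
    elif maf_distribution == "sfs":
        maf = lo * (hi / lo) ** rng.random(n_variants)
    else:
        raise ParameterError(f"unknown maf_distribution {maf_distribution!r}")
    ld = 1.0 + rng.gamma(ld_shape, ld_scale, n_variants)
    ids = np.array([f"snp{i}" for i in range(n_variants)], dtype=object)
    return VariantPanel(ids, maf, ld)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Which effect-size distribution to draw from, and its alpha exponent."""

    model: ArchitectureName = "polygenic"
    alpha: Optional[float] = None

    def __post_init__(self):
        if self.model not in DEFAULT_ALPHA:
            raise ParameterError(f"unknown architecture model {self.model!r}")
        if self.alpha is None:
            object.__setattr__(self, "alpha", DEFAULT_ALPHA[self.model])

    def variance_shape(self, panel: VariantPanel) -> np.ndarray:
        """Unnormalized per-variant effect-variance shape ``s_i``."""
        if self.model == "polygenic":
            return np.ones(panel.n_variants)
        s = (panel.maf * (1.0 - panel.maf)) ** (1.0 + self.alpha)
        if self.model == "ldak":
            s = s * self.ldak_weights(panel)
        return s

    @staticmethod
    def ldak_weights(panel: VariantPanel) -> np.ndarray:
        """LDAK variant weights ``w = 1/(1+l)`` in (0, 1]."""
        return 1.0 / (1.0 + panel.ld_score)


@dataclass
class EffectSizeSet:
    """Calibrated per-variant effects on standardized genotypes."""

    beta_pb: np.ndarray
    proportionality_constant: float
    h2_pb_target: float
    panel: VariantPanel
    arch: ArchitectureSpec

    @property
    def n_variants(self) -> int:
        return len(self.beta_pb)


def draw_effect_sizes(
    panel: VariantPanel,
    arch: ArchitectureSpec,
    h2_pb: float,
    rng: np.random.Generator,
) -> EffectSizeSet:
    """Draw causal effects ``beta_i ~ N(0, C * s_i)`` with C calibrated so
    the expected variance contributions sum exactly to ``h2_pb``."""
    if not 0.0 <= h2_pb < 1.0:
        raise ParameterError(f"h2_pb must be in [0, 1), got {h2_pb}")
    if h2_pb == 0.0:
        return EffectSizeSet(np.zeros(panel.n_variants), 0.0, 0.0, panel, arch)
    s = arch.variance_shape(panel)
    c = h2_pb / s.sum()
    beta = rng.normal(0.0, 1.0, panel.n_variants) * np.sqrt(c * s)
    return EffectSizeSet(beta, c, h2_pb, panel, arch)


def compute_lev_beta(h2_lev: float, f: float, var_y: float = 1.0) -> float:
    """Per-allele liability effect of an LEV explaining ``h2_lev`` of a
    trait with variance ``var_y``: sqrt(h2_lev * var_y / (2 f (1-f)))."""
    if not 0.0 <= h2_lev < 1.0:
        raise ParameterError(f"h2_lev must be in [0, 1), got {h2_lev}")
    if not 0.0 < f <= 0.5:
        raise ParameterError(f"allele frequency must be in (0, 0.5], got {f}")
    return float(np.sqrt(h2_lev * var_y / (2.0 * f * (1.0 - f))))


def lev_h2_from_or(odds_ratio: float, f: float, scale: str = "probit") -> float:
    """Liability-scale variance explained by an LEV, from its allelic odds
    ratio and frequency.

    With allelic genotype variance 2f(1-f) and v = (ln OR)^2 * 2f(1-f):
    probit scale -> v/(v+1); logit scale -> v/(v+pi^2/3) = v/(v+3.29).
    """
    if odds_ratio <= 0:
        raise ParameterError(f"odds ratio must be positive, got {odds_ratio}")
    if not 0.0 < f <= 0.5:
        raise ParameterError(f"allele frequency must be in (0, 0.5], got {f}")
    v = np.log(odds_ratio) ** 2 * 2.0 * f * (1.0 - f)
    if scale == "probit":
        return float(v / (v + 1.0))
    if scale == "logit":
        return float(v / (v + 3.29))
    raise ParameterError(f"scale must be 'probit' or 'logit', got {scale!r}")


@dataclass(frozen=True)
class LevSpec:
    """A single large-effect variant: frequency, per-allele liability
    effect, and the trait variance it explains (unit-variance trait)."""

    freq: float
    beta_lev: float
    h2_lev: float
    candidates: Optional[Tuple[Tuple[float, float], ...]] = None

    def __post_init__(self):
        if not 0.0 <= self.freq <= 0.5:
            raise ParameterError(f"LEV frequency must be in [0, 0.5], got {self.freq}")
        if self.beta_lev < 0:
            raise ParameterError("beta_lev must be nonnegative")
        if self.freq > 0:
            implied = 2.0 * self.beta_lev**2 * self.freq * (1.0 - self.freq)
            if not np.isclose(implied, self.h2_lev, rtol=1e-8, atol=1e-12):
                raise ParameterError(
                    f"inconsistent LevSpec: 2*beta^2*f*(1-f)={implied:.6g} != h2_lev={self.h2_lev:.6g}"
                )

    @classmethod
    def from_h2(cls, h2_lev: float, f: float) -> "LevSpec":
        return cls(f, compute_lev_beta(h2_lev, f), h2_lev)

    @classmethod
    def from_or(cls, odds_ratio: float, f: float, scale: str = "probit") -> "LevSpec":
        return cls.from_h2(lev_h2_from_or(odds_ratio, f, scale), f)

    @classmethod
    def null(cls, f: float) -> "LevSpec":
        """An inert LEV (present in the cohort, no liability effect)."""
        return cls(f, 0.0, 0.0)


def select_top_lev(candidates: Sequence[Tuple[float, float]]) -> LevSpec:
    """Pick, among (effect, frequency) candidates, the LEV with the largest
    causal contribution ``beta^2 f (1-f)``; ties broken toward the lowest
    frequency.  The resulting ``h2_lev`` is a lower bound for the total
    heritability of a heterogeneous LEV set."""
    cand = list(candidates)
    if not cand:
        raise ParameterError("candidate list is empty")
    best = None
    best_key = None
    for beta, f in cand:
        if not 0.0 < f <= 0.5:
            raise ParameterError(f"candidate frequency {f} outside (0, 0.5]")
        key = (beta**2 * f * (1.0 - f), -f)  # larger contribution, then lower f
        if best_key is None or key > best_key:
            best, best_key = (beta, f), key
    beta, f = best
    h2 = 2.0 * beta**2 * f * (1.0 - f)
    return LevSpec(f, abs(beta), h2, candidates=tuple((b, fr) for b, fr in cand))


@dataclass
class PgsWeightSet:
    """Weights of the scoring instrument (PGS) over the scored variants.

    ``weights`` aligns with the scored panel: first the retained causal
    variants (original order), then—in ``weighted_nulls`` mode—the null
    variants that replaced the dropped causals.  ``causal_indices`` maps
    the retained entries back into the causal effect set.
    """

    weights: np.ndarray
    causal_mask: np.ndarray
    pi0: float
    mode: PgsNoiseMode
    causal_indices: np.ndarray
    null_panel: Optional[VariantPanel] = None
    null_weights: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_scored(self) -> int:
        return len(self.weights)


def make_pgs_weights(
    effects: EffectSizeSet,
    pi0: float,
    mode: PgsNoiseMode = "dropped_causals",
    panel_nulls: Optional[VariantPanel] = None,
    rng: Optional[np.random.Generator] = None,
) -> PgsWeightSet:
    """Build a PGS in which a fraction ``pi0`` of scored variants is
    noncausal.

    ``weighted_nulls``: the scored panel keeps the size of the causal set;
    ``round((1-pi0)*N_PB)`` causal variants keep their true weights and the
    remainder are replaced by null variants (no effect on the trait)
    carrying fresh weights drawn from the same architecture distribution.
    The expected corr(PGS, PB) is ``1 - pi0``.

    ``dropped_causals``: the score is restricted to the retained causal
    subset; expected corr(PGS, PB) is ``sqrt(1 - pi0)``.
    """
    if not 0.0 <= pi0 < 1.0:
        raise ParameterError(f"pi0 must be in [0, 1), got {pi0}")
    n_pb = effects.n_variants
    if pi0 == 0.0:
        return PgsWeightSet(
            weights=effects.beta_pb.copy(),
            causal_mask=np.ones(n_pb, dtype=bool),
            pi0=0.0,
            mode=mode,
            causal_indices=np.arange(n_pb),
        )
    if rng is None:
        raise ParameterError("rng is required when pi0 > 0")
    n_keep = int(round((1.0 - pi0) * n_pb))
    keep = np.sort(rng.choice(n_pb, size=n_keep, replace=False))
    if mode == "dropped_causals":
        return PgsWeightSet(
            weights=effects.beta_pb[keep].copy(),
            causal_mask=np.ones(n_keep, dtype=bool),
            pi0=pi0,
            mode=mode,
            causal_indices=keep,
        )
    if mode != "weighted_nulls":
        raise ParameterError(f"unknown PGS noise mode {mode!r}")
    n_null = n_pb - n_keep
    if panel_nulls is None:
        raise ParameterError("weighted_nulls mode requires a panel to draw null variants from")
    null_panel = panel_nulls.sample(n_null, rng)
    # fresh weights from the same architecture distribution, using the
    # calibration constant of the causal set
    s_null = effects.arch.variance_shape(null_panel)
    null_w = rng.normal(0.0, 1.0, n_null) * np.sqrt(effects.proportionality_constant * s_null)
    return PgsWeightSet(
        weights=np.concatenate([effects.beta_pb[keep], null_w]),
        causal_mask=np.concatenate([np.ones(n_keep, dtype=bool), np.zeros(n_null, dtype=bool)]),
        pi0=pi0,
        mode="weighted_nulls",
        causal_indices=keep,
        null_panel=null_panel,
        null_weights=null_w,
    )
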