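"""The PB-LEV statistical battery.

Central statistic: among *cases*, is the polygenic score of LEV carriers
stochastically lower than that of noncarriers (one-sided Wilcoxon
rank-sum)?  "Utility" is the fraction of simulation replicates where
this test rejects at P < 0.05 with all causal variants known; "power" is
the same fraction when the score carries a proportion pi0 of noncausal
variants.  Replicates in which the test cannot be formed (no carriers,
or no noncarriers, among cases) count as non-significant: the inability
to find carriers is part of the operating characteristic, not missing
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .architectures import ArchitectureSpec, ParameterError, VariantPanel
from .cohort import SimulatedCohort, TraitModel, simulate_cohort

__all__ = [
    "UtilityResult",
    "OrEstimate",
    "ScreeningTable",
    "wilcoxon_one_sided",
    "pb_lev_test",
    "estimate_utility",
    "estimate_power",
    "or_of_lev",
    "or_of_pb_topq",
    "or_per_sd_by_carrier",
    "carriers_per_1000_by_bin",
    "carrier_proportion_by_median_split",
]

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


@dataclass
class UtilityResult:
    """Proportion of replicates with a significant PB-LEV test."""

    n_replicates: int
    n_significant: int
    pvalues: np.ndarray
    alpha: float = 0.05

    @property
    def utility(self) -> float:
        return self.n_significant / self.n_replicates

    @property
    def mc_se(self) -> float:
        """Binomial Monte-Carlo standard error of the utility."""
        u = self.utility
        return float(np.sqrt(u * (1.0 - u) / self.n_replicates))


@dataclass
class OrEstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self):
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("confidence bounds do not bracket the estimate")


@dataclass
class ScreeningTable:
    """Expected LEV-carrier yield per polygenic-score stratum of cases."""

    n_bins: int
    bin_mean: np.ndarray  # mean carriers per 1000 cases, lowest PGS bin first
    bin_sd: np.ndarray
    low_proportions: np.ndarray  # per replicate: carrier proportion below case-PGS median
    high_proportions: np.ndarray
    n_replicates: int
    n_skipped: int = 0

    @property
    def low_mean(self) -> float:
        return float(self.low_proportions.mean())

    @property
    def high_mean(self) -> float:
        return float(self.high_proportions.mean())


def wilcoxon_one_sided(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """One-sided rank-sum p-value for H1: group_a stochastically smaller.

    Exact enumeration when the smaller group has <= 8 untied
    observations (where the normal approximation is visibly
    conservative); otherwise the normal approximation with continuity
    and tie correction.  Returns NaN (untestable) if either group is
    empty.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="less", method=method)
    return float(res.pvalue)


def pb_lev_test(cohort: SimulatedCohort) -> float:
    """The PB-LEV correlation test: among cases, one-sided Wilcoxon of
    the PGS of LEV carriers against noncarriers.  NaN when untestable."""
    case = cohort.case
    if not case.any():
        return float("nan")
    carrier = cohort.carrier[case]
    score = cohort.pgs[case]
    return wilcoxon_one_sided(score[carrier], score[~carrier])


def estimate_utility(
    trait: TraitModel,
    arch: ArchitectureSpec,
    panel: VariantPanel,
    n: int,
    n_pb: int = 2000,
    n_replicates: int = 500,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> UtilityResult:
    """Replicate the cohort simulation and count significant PB-LEV tests.

    Replicate ``r`` draws everything (causal variants, effects, subjects)
    from seed ``base_seed + r``; results are bit-reproducible for a
    given base seed.
    """
    if n_replicates < 1:
        raise ParameterError("need at least one replicate")
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        cohort = simulate_cohort(trait, arch, panel, n, n_pb=n_pb, seed=base_seed + r)
        pvals[r] = pb_lev_test(cohort)
    n_sig = int(np.nansum(pvals < alpha))
    n_untestable = int(np.isnan(pvals).sum())
    if n_untestable:
        logger.warning("%d of %d replicates untestable (counted non-significant)",
                       n_untestable, n_replicates)
    return UtilityResult(n_replicates, n_sig, pvals, alpha)


def estimate_power(
    trait: TraitModel,
    arch: ArchitectureSpec,
    panel: VariantPanel,
    n: int,
    n_pb: int = 2000,
    n_replicates: int = 500,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> UtilityResult:
    """Power of the PB-LEV test with a contaminated score.

    Identical machinery to :func:`estimate_utility`; the contamination
    level and mode live on the trait model (``pi0``, ``pgs_mode``).  At
    pi0 = 0 this reduces exactly to the utility for the same seed.
    """
    return estimate_utility(
        trait, arch, panel, n, n_pb=n_pb, n_replicates=n_replicates,
        base_seed=base_seed, alpha=alpha,
    )


def _woolf_or(a: float, b: float, c: float, d: float, method: str) -> OrEstimate:
    """2x2 odds ratio with Haldane-Anscombe correction and Woolf CI."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OrEstimate(
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - Z975 * se)),
        ci_high=float(np.exp(np.log(or_) + Z975 * se)),
        method=method,
    )


def or_of_lev(cohort: SimulatedCohort) -> Optional[OrEstimate]:
    """Odds ratio of the LEV: carriers vs noncarriers as exposed vs
    unexposed.  None (untestable) for an all-case or all-control cohort."""
    case = cohort.case
    if case.all() or not case.any():
        return None
    carrier = cohort.carrier
    a = float(np.sum(case & carrier))
    b = float(np.sum(~case & carrier))
    c = float(np.sum(case & ~carrier))
    d = float(np.sum(~case & ~carrier))
    return _woolf_or(a, b, c, d, "table_2x2")


def or_of_pb_topq(cohort: SimulatedCohort, q: float) -> Optional[OrEstimate]:
    """Odds ratio of a high polygenic score: the top ``q`` fraction of the
    PGS-ranked sample is the exposed group.  Ties at the cut are broken
    deterministically by sample index (stable sort)."""
    n = cohort.n
    k = int(round(n * q))
    if k < 1:
        raise ParameterError(f"n*q = {n * q:.3g} < 1; top-{q:g} group is empty")
    case = cohort.case
    if case.all() or not case.any():
        return None
    order = np.argsort(cohort.pgs, kind="stable")
    exposed = np.zeros(n, dtype=bool)
    exposed[order[-k:]] = True
    a = float(np.sum(case & exposed))
    b = float(np.sum(~case & exposed))
    c = float(np.sum(case & ~exposed))
    d = float(np.sum(~case & ~exposed))
    return _woolf_or(a, b, c, d, "table_2x2")


def _logistic_or_per_sd(score: np.ndarray, case: np.ndarray) -> Optional[OrEstimate]:
    if case.all() or not case.any() or len(case) < 3:
        return None
    x = sm.add_constant(score)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(case.astype(float), x).fit(disp=0, maxiter=200)
        slope = fit.params[1]
        se = fit.bse[1]
        if not (np.isfinite(slope) and np.isfinite(se)) or se > 50:
            return None  # separation
    except Exception:
        return None
    return OrEstimate(
        odds_ratio=float(np.exp(slope)),
        ci_low=float(np.exp(slope - Z975 * se)),
        ci_high=float(np.exp(slope + Z975 * se)),
        method="logistic_per_sd",
    )


def or_per_sd_by_carrier(
    cohort: SimulatedCohort,
) -> Tuple[Optional[OrEstimate], Optional[OrEstimate]]:
    """OR of the PGS per SD, separately in LEV carriers and noncarriers.

    Logistic regression of case status on the cohort-standardized score
    within each stratum; (carriers, noncarriers).  An untestable stratum
    (empty, single-outcome, or separated) yields None.
    """
    carrier = cohort.carrier
    res_carrier = (
        _logistic_or_per_sd(cohort.pgs[carrier], cohort.case[carrier]) if carrier.any() else None
    )
    res_noncarrier = (
        _logistic_or_per_sd(cohort.pgs[~carrier], cohort.case[~carrier]) if (~carrier).any() else None
    )
    return res_carrier, res_noncarrier


def _bin_sizes(n_cases: int, n_bins: int) -> np.ndarray:
    base, rem = divmod(n_cases, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1  # remainder spread from the lowest bin up
    return sizes


def carriers_per_1000_by_bin(
    cohorts: Iterable[SimulatedCohort],
    n_bins: int = 10,
) -> ScreeningTable:
    """Carrier yield per case-PGS bin, summarized across replicates.

    Per replicate, cases are ranked by PGS and split into ``n_bins``
    equal-size groups (lowest scores first); the statistic per bin is
    carriers/cases*1000.  Replicates with fewer cases than bins are
    skipped (logged).  Also records, per replicate, the carrier
    proportion among cases below vs above the case-PGS median (the
    lower/upper halves; the middle case is dropped when odd).
    """
    per_bin: List[np.ndarray] = []
    lows: List[float] = []
    highs: List[float] = []
    n_skipped = 0
    for cohort in cohorts:
        case_idx = np.flatnonzero(cohort.case)
        nc = len(case_idx)
        if nc < max(n_bins, 2):
            n_skipped += 1
            continue
        order = case_idx[np.argsort(cohort.pgs[case_idx], kind="stable")]
        carrier_sorted = cohort.carrier[order]
        sizes = _bin_sizes(nc, n_bins)
        edges = np.concatenate([[0], np.cumsum(sizes)])
        rates = np.array(
            [
                1000.0 * carrier_sorted[edges[i] : edges[i + 1]].mean()
                for i in range(n_bins)
            ]
        )
        per_bin.append(rates)
        half = nc // 2
        lows.append(float(carrier_sorted[:half].mean()))
        highs.append(float(carrier_sorted[nc - half :].mean()))
    if n_skipped:
        logger.warning("skipped %d replicate(s) with fewer cases than bins", n_skipped)
    if not per_bin:
        raise ParameterError("no replicate had enough cases to form the screening table")
    mat = np.vstack(per_bin)
    return ScreeningTable(
        n_bins=n_bins,
        bin_mean=mat.mean(axis=0),
        bin_sd=mat.std(axis=0, ddof=1) if len(per_bin) > 1 else np.zeros(n_bins),
        low_proportions=np.array(lows),
        high_proportions=np.array(highs),
        n_replicates=len(per_bin),
        n_skipped=n_skipped,
    )


def carrier_proportion_by_median_split(
    cohorts: Iterable[SimulatedCohort],
) -> Tuple[np.ndarray, np.ndarray]:
    """Carrier proportion among cases below vs above the case-PGS median,
    one value per replicate (for box-plot style summaries)."""
    lows: List[float] = []
    highs: List[float] = []
    n_skipped = 0
    for cohort in cohorts:
        case_idx = np.flatnonzero(cohort.case)
        nc = len(case_idx)
        if nc < 2:
            n_skipped += 1
            continue
        order = case_idx[np.argsort(cohort.pgs[case_idx], kind="stable")]
        carrier_sorted = cohort.carrier[order]
        half = nc // 2
        lows.append(float(carrier_sorted[:half].mean()))
        highs.append(float(carrier_sorted[nc - half :].mean()))
    if n_skipped:
        logger.warning("skipped %d replicate(s) with fewer than 2 cases", n_skipped)
    if not lows:
        raise ParameterError("no replicate had at least 2 cases")
    return np.array(lows), np.array(highs)
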