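"""Parameter-grid orchestration and biobank-style trait screening.

``run_grid`` sweeps the full cartesian grid of generative parameters
(heritabilities, LEV frequency, prevalence, sample size) for a chosen
liability model and architecture, computing the utility/power of the
PB-LEV test per combination.  ``screen_trait`` takes one empirical
trait row (heritability, prevalence, biobank sample size, LEV odds
ratio and frequency), converts the odds ratio to a liability-scale
``h2_lev``, and predicts LEV-carrier yield per polygenic-score decile
of cases — the sequencing-prioritization application.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .architectures import (
    ArchitectureSpec,
    LevSpec,
    ParameterError,
    VariantPanel,
    lev_h2_from_or,
)
from .cohort import TraitModel, simulate_cohort
from .metrics import (
    ScreeningTable,
    UtilityResult,
    carriers_per_1000_by_bin,
    estimate_utility,
    pb_lev_test,
)

__all__ = [
    "GridSpec",
    "TraitRow",
    "run_grid",
    "qq_expected_observed",
    "filter_traits",
    "screen_trait",
    "DEFAULT_GRID",
]

logger = logging.getLogger(__name__)

#: the reference parameter grid: 5 x 5 x 5 x 5 x 6 = 3750 combinations
#: per liability model.
DEFAULT_GRID = {
    "h2_pb": (0.1, 0.2, 0.3, 0.4, 0.5),
    "h2_lev": (0.01, 0.02, 0.03, 0.05, 0.10),
    "f": (1e-4, 0.001, 0.005, 0.01, 0.05),
    "K": (0.001, 0.005, 0.01, 0.02, 0.05),
    "N": (500, 1000, 2000, 3000, 5000, 10000),
}


@dataclass(frozen=True)
class GridSpec:
    """Value lists for the parameter sweep."""

    h2_pb: Tuple[float, ...] = DEFAULT_GRID["h2_pb"]
    h2_lev: Tuple[float, ...] = DEFAULT_GRID["h2_lev"]
    f: Tuple[float, ...] = DEFAULT_GRID["f"]
    K: Tuple[float, ...] = DEFAULT_GRID["K"]
    N: Tuple[int, ...] = DEFAULT_GRID["N"]
    liability_model: str = "liability_threshold"
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    pi0: Tuple[float, ...] = (0.0,)
    n_replicates: int = 500
    n_pb: int = 2000
    base_seed: int = 0

    @property
    def size(self) -> int:
        return (
            len(self.h2_pb) * len(self.h2_lev) * len(self.f)
            * len(self.K) * len(self.N) * len(self.pi0)
        )

    def combinations(self) -> Iterator[dict]:
        i = 0
        for h2_pb in self.h2_pb:
            for h2_lev in self.h2_lev:
                for f in self.f:
                    for k in self.K:
                        for n in self.N:
                            for pi0 in self.pi0:
                                yield {
                                    "index": i,
                                    "h2_pb": h2_pb,
                                    "h2_lev": h2_lev,
                                    "f": f,
                                    "K": k,
                                    "N": n,
                                    "pi0": pi0,
                                }
                                i += 1


def _combo_key(combo: dict, grid: GridSpec) -> str:
    """Stable checkpoint key for one grid combination."""
    payload = {
        k: combo[k] for k in ("h2_pb", "h2_lev", "f", "K", "N", "pi0")
    }
    payload.update(
        model=grid.liability_model,
        arch=grid.architecture.model,
        alpha=grid.architecture.alpha,
        n_replicates=grid.n_replicates,
        n_pb=grid.n_pb,
        base_seed=grid.base_seed,
    )
    blob = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_grid(
    grid: GridSpec,
    panel: VariantPanel,
    checkpoint: Optional[Path] = None,
) -> pd.DataFrame:
    """Compute utility/power for every grid combination.

    One output row per combination; combinations whose parameters leave
    no residual variance are emitted with status ``invalid_parameters``
    rather than dropped.  Deterministic given ``grid.base_seed``
    (replicate seeds are ``base_seed + index * n_replicates + r``).
    With a ``checkpoint`` path, completed combinations are appended as
    they finish and skipped on rerun.
    """
    done: dict = {}
    if checkpoint is not None and Path(checkpoint).exists():
        prev = pd.read_csv(checkpoint, sep="\t")
        done = {row["combo_key"]: row for _, row in prev.iterrows()}
        logger.info("checkpoint: %d combination(s) already done", len(done))

    rows: List[dict] = []
    for combo in grid.combinations():
        key = _combo_key(combo, grid)
        if key in done:
            rows.append(dict(done[key]))
            continue
        row = dict(combo)
        row["combo_key"] = key
        row["n_replicates"] = grid.n_replicates
        row["base_seed"] = grid.base_seed
        try:
            trait = TraitModel(
                h2_pb=combo["h2_pb"],
                lev=LevSpec.from_h2(combo["h2_lev"], combo["f"]),
                prevalence=combo["K"],
                liability_model=grid.liability_model,
                pi0=combo["pi0"],
            )
        except ParameterError as exc:
            row.update(status="invalid_parameters", utility=np.nan, mc_se=np.nan,
                       n_untestable=np.nan, error=str(exc))
            rows.append(row)
            continue
        res = estimate_utility(
            trait,
            grid.architecture,
            panel,
            n=combo["N"],
            n_pb=grid.n_pb,
            n_replicates=grid.n_replicates,
            base_seed=grid.base_seed + combo["index"] * grid.n_replicates,
        )
        row.update(
            status="ok",
            utility=res.utility,
            mc_se=res.mc_se,
            n_untestable=int(np.isnan(res.pvalues).sum()),
            error="",
        )
        rows.append(row)
        if checkpoint is not None:
            header = not Path(checkpoint).exists()
            pd.DataFrame([row]).to_csv(checkpoint, sep="\t", mode="a",
                                       header=header, index=False)
    return pd.DataFrame(rows)


def qq_expected_observed(pvalues: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p for a QQ plot.

    Observed p-values are sorted ascending and paired with the uniform
    order-statistic means i/(n+1).
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if len(p) == 0:
        raise ParameterError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    exp = np.arange(1, len(p) + 1) / (len(p) + 1.0)
    return -np.log10(exp), -np.log10(obs)


@dataclass(frozen=True)
class TraitRow:
    """One empirical trait: biobank summary parameters plus its LEV."""

    trait: str
    h2_pb: float
    h2_p_value: float
    prevalence: float
    n: int
    lev_or: float
    lev_maf: float
    model: str = "liability_threshold"

    def __post_init__(self):
        if not 0.0 <= self.h2_pb < 1.0:
            raise ParameterError(f"{self.trait}: h2_pb outside [0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ParameterError(f"{self.trait}: prevalence outside (0, 1)")
        if not 0.0 < self.lev_maf <= 0.5:
            raise ParameterError(f"{self.trait}: LEV MAF outside (0, 0.5]")
        if self.lev_or <= 0:
            raise ParameterError(f"{self.trait}: odds ratio must be positive")
        if self.n < 1:
            raise ParameterError(f"{self.trait}: sample size must be >= 1")


def filter_traits(rows: Sequence[TraitRow]) -> List[TraitRow]:
    """Retain heritable traits with a large-effect LEV: significant
    heritability (P <= 0.05), h2_pb >= 0.05, and OR >= 1.5.  Order is
    preserved."""
    return [
        r for r in rows
        if r.h2_p_value <= 0.05 and r.h2_pb >= 0.05 and r.lev_or >= 1.5
    ]


@dataclass
class ScreenResult:
    trait: TraitRow
    status: str
    h2_lev: float
    n_simulated: int
    screening: Optional[ScreeningTable] = None
    utility: Optional[UtilityResult] = None

    def to_frame(self) -> pd.DataFrame:
        """Per-bin table (bin, mean_per_1000, sd)."""
        if self.screening is None:
            return pd.DataFrame(columns=["bin", "mean_per_1000", "sd"])
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.screening.n_bins + 1),
                "mean_per_1000": self.screening.bin_mean,
                "sd": self.screening.bin_sd,
            }
        )


def screen_trait(
    row: TraitRow,
    panel: VariantPanel,
    arch: ArchitectureSpec = ArchitectureSpec("negative_selection"),
    n_replicates: int = 500,
    n_pb: int = 2000,
    base_seed: int = 0,
    scale_down_n: Optional[int] = None,
    n_bins: int = 10,
    pi0: float = 0.0,
) -> ScreenResult:
    """Predict per-decile LEV-carrier yield and utility for one trait.

    The LEV odds ratio is converted to liability-scale ``h2_lev`` on
    the probit scale under the liability-threshold model and on the
    logit scale under the logit risk model.  Cohorts of ``row.n``
    individuals (or ``scale_down_n``, recorded in the result) are
    simulated; case counts are emergent from the prevalence.  The
    carrier-yield statistic is a proportion, so a scale-down changes
    only its Monte-Carlo error, not its expectation.
    """
    scale = "probit" if row.model == "liability_threshold" else "logit"
    h2_lev = lev_h2_from_or(row.lev_or, row.lev_maf, scale=scale)
    n = int(scale_down_n) if scale_down_n else int(row.n)
    try:
        trait = TraitModel(
            h2_pb=row.h2_pb,
            lev=LevSpec.from_h2(h2_lev, row.lev_maf),
            prevalence=row.prevalence,
            liability_model=row.model,
            pi0=pi0,
        )
    except ParameterError:
        return ScreenResult(row, "invalid_parameters", h2_lev, n)

    pvals = np.empty(n_replicates)

    def cohorts():
        for r in range(n_replicates):
            c = simulate_cohort(trait, arch, panel, n, n_pb=n_pb, seed=base_seed + r)
            pvals[r] = pb_lev_test(c)
            yield c

    table = carriers_per_1000_by_bin(cohorts(), n_bins=n_bins)
    util = UtilityResult(n_replicates, int(np.nansum(pvals < 0.05)), pvals)
    return ScreenResult(row, "ok", h2_lev, n, table, util)
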