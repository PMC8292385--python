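"""Readers, writers, fixture generation, and run configuration.

All tabular interfaces are tab-separated UTF-8 text with a mandatory
header.  Missing numeric values must be spelled ``NA`` (a bare ``.`` is
rejected).  Readers never coerce silently: every rejected, dropped, or
imputed record is counted and reported.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .architectures import ParameterError, VariantPanel, synthetic_panel
from .scan import TraitRow

__all__ = [
    "ParseError",
    "RunConfig",
    "read_variant_panel",
    "write_variant_panel",
    "read_trait_table",
    "write_trait_table",
    "read_traw_dosages",
    "TrawResult",
    "generate_fixtures",
    "write_manifest",
    "file_checksum",
]

logger = logging.getLogger(__name__)

TRAW_FIXED_COLS = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]


class ParseError(ValueError):
    """A tabular input failed validation; the message lists offending lines."""


@dataclass
class RunConfig:
    """Configuration of one CLI run; every output artifact records the seed."""

    seed: int = 0
    n_replicates: int = 500
    panel_path: Optional[str] = None
    trait_table_path: Optional[str] = None
    output_dir: str = "pblev_out"
    architecture_model: str = "polygenic"
    architecture_alpha: Optional[float] = None
    liability_model: str = "liability_threshold"
    pgs_noise_mode: str = "dropped_causals"
    n_pb: int = 2000
    scale_down_n: Optional[int] = None

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        arch = raw.pop("architecture", {})
        if arch:
            raw["architecture_model"] = arch.get("model", "polygenic")
            raw["architecture_alpha"] = arch.get("alpha")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require_columns(df: pd.DataFrame, required: List[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def read_variant_panel(path: Path) -> VariantPanel:
    """Read a variant panel TSV (columns variant_id, maf, ld_score).

    Out-of-range or non-numeric rows raise with their line numbers
    (line 1 = header).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["variant_id", "maf", "ld_score"], path)
    bad: List[str] = []
    maf = np.empty(len(df))
    ld = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            m = float(row.maf)
            l = float(row.ld_score)
        except ValueError:
            bad.append(f"line {line}: non-numeric field")
            continue
        if not 0.0 < m <= 0.5:
            bad.append(f"line {line}: maf {m} outside (0, 0.5]")
        if l < 0 or not np.isfinite(l):
            bad.append(f"line {line}: ld_score {row.ld_score} invalid")
        maf[i] = m
        ld[i] = l
    if bad:
        raise ParseError(f"{path}: {len(bad)} invalid row(s): " + "; ".join(bad[:20]))
    ids = df["variant_id"].to_numpy(dtype=object)
    dup = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
    if len(dup):
        raise ParseError(f"{path}: duplicate variant id(s): {list(dup[:10])}")
    return VariantPanel(ids, maf, ld)


def write_variant_panel(panel: VariantPanel, path: Path) -> None:
    pd.DataFrame(
        {"variant_id": panel.variant_id, "maf": panel.maf, "ld_score": panel.ld_score}
    ).to_csv(path, sep="\t", index=False)


TRAIT_COLS = ["trait", "h2_pb", "h2_p", "prevalence", "n", "lev_or", "lev_maf"]


def read_trait_table(path: Path) -> List[TraitRow]:
    """Read a trait-parameter TSV (columns trait, h2_pb, h2_p, prevalence,
    n, lev_or, lev_maf, optional model)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, TRAIT_COLS, path)
    rows: List[TraitRow] = []
    errors: List[str] = []
    for i, rec in df.iterrows():
        try:
            rows.append(
                TraitRow(
                    trait=str(rec["trait"]),
                    h2_pb=float(rec["h2_pb"]),
                    h2_p_value=float(rec["h2_p"]),
                    prevalence=float(rec["prevalence"]),
                    n=int(rec["n"]),
                    lev_or=float(rec["lev_or"]),
                    lev_maf=float(rec["lev_maf"]),
                    model=str(rec.get("model", "liability_threshold"))
                    if "model" in df.columns
                    else "liability_threshold",
                )
            )
        except (ParameterError, ValueError) as exc:
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise ParseError(f"{path}: {len(errors)} invalid row(s): " + "; ".join(errors[:20]))
    return rows


def write_trait_table(rows: List[TraitRow], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "trait": r.trait,
                "h2_pb": r.h2_pb,
                "h2_p": r.h2_p_value,
                "prevalence": r.prevalence,
                "n": r.n,
                "lev_or": r.lev_or,
                "lev_maf": r.lev_maf,
                "model": r.model,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class TrawResult:
    """Dosages read from a PLINK .traw text file."""

    dosages: np.ndarray  # individuals x variants, float64 in [0, 2]
    variant_ids: List[str]
    sample_ids: List[str]
    maf: np.ndarray  # inferred from dosage means
    n_imputed: int
    n_dropped: int


def read_traw_dosages(path: Path) -> TrawResult:
    """Read a PLINK .traw transposed dosage file (one variant per row).

    Missing cells (``NA``) are mean-imputed with a logged count;
    all-missing variants are dropped with a warning.  MAFs are inferred
    from dosage means (folded to the minor allele).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if list(df.columns[:6]) != TRAW_FIXED_COLS:
        raise ParseError(
            f"{path}: malformed .traw header; expected leading columns "
            f"{TRAW_FIXED_COLS}, got {list(df.columns[:6])}"
        )
    sample_ids = list(df.columns[6:])
    if not sample_ids:
        raise ParseError(f"{path}: no sample columns")
    values = df[sample_ids].to_numpy(dtype=np.float64)  # variants x samples
    if np.nanmin(values, initial=0) < 0 or np.nanmax(values, initial=0) > 2:
        raise ParseError(f"{path}: dosages outside [0, 2]")
    keep = ~np.isnan(values).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d all-missing variant(s)", path, n_dropped)
    values = values[keep]
    variant_ids = df.loc[keep, "SNP"].astype(str).tolist()
    n_imputed = int(np.isnan(values).sum())
    if n_imputed:
        means = np.nanmean(values, axis=1)
        idx = np.where(np.isnan(values))
        values[idx] = means[idx[0]]
        logger.info("%s: mean-imputed %d missing cell(s)", path, n_imputed)
    freq = values.mean(axis=1) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    return TrawResult(values.T, variant_ids, sample_ids, maf, n_imputed, n_dropped)


def panel_from_traw(res: TrawResult, ld_score: float = 0.0) -> VariantPanel:
    """Variant panel for a real dosage matrix (MAFs inferred from dosage
    means; a constant LD score unless the caller supplies real ones).
    Monomorphic variants are excluded (counted by the caller via shapes)."""
    keep = res.maf > 0
    return VariantPanel(
        np.asarray(res.variant_ids, dtype=object)[keep],
        res.maf[keep],
        np.full(int(keep.sum()), float(ld_score)),
    )


#: synthetic placeholder rows for the biobank screening demo.  OR and MAF
#: for the two exemplar LEVs (a MYOC-like stop gain, a NOD2-like
#: frameshift) are as published; h2_pb, prevalence and n stand in for the
#: per-trait biobank estimates, which are not distributed with this
#: package (values chosen from the published literature for these traits).
SYNTHETIC_TRAIT_ROWS = [
    TraitRow("glaucoma_synthetic", 0.10, 1e-10, 0.01, 361194, 5.1, 0.0013),
    TraitRow("crohns_synthetic", 0.25, 1e-10, 0.005, 361194, 3.2, 0.02),
    TraitRow("lowherit_excluded", 0.04, 0.001, 0.01, 361194, 5.0, 0.001),
    TraitRow("smallor_excluded", 0.20, 0.001, 0.01, 361194, 1.4, 0.001),
]


def generate_fixtures(
    kind: str,
    out_path: Path,
    seed: int = 0,
    n_variants: int = 100,
    n_samples: int = 3,
) -> Path:
    """Write a deterministic small fixture file (panel, traw or trait_table)."""
    out_path = Path(out_path)
    rng = np.random.default_rng(seed)
    if kind == "panel":
        write_variant_panel(synthetic_panel(n_variants, seed=seed), out_path)
    elif kind == "traw":
        maf = rng.uniform(0.1, 0.5, n_variants)
        dos = rng.binomial(2, maf[:, None], size=(n_variants, n_samples)).astype(float)
        df = pd.DataFrame(
            {
                "CHR": 1,
                "SNP": [f"snp{i}" for i in range(n_variants)],
                "(C)M": 0,
                "POS": np.arange(1, n_variants + 1) * 1000,
                "COUNTED": "A",
                "ALT": "G",
            }
        )
        for j in range(n_samples):
            df[f"sample{j}"] = dos[:, j]
        df.to_csv(out_path, sep="\t", index=False)
    elif kind == "trait_table":
        write_trait_table(SYNTHETIC_TRAIT_ROWS, out_path)
    else:
        raise ParameterError(f"unknown fixture kind {kind!r}")
    return out_path


def file_checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, config: RunConfig, inputs: List[Path]) -> Path:
    """Emit a JSON manifest (seed, config hash, input checksums) that
    suffices to reproduce the run byte-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    manifest = {
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path
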