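"""Readers, writers, run configuration and logging.

All tabular artifacts are comma-separated UTF-8 text with a mandatory
header row; well labels are alphanumeric 384-well style strings (A01 ..
P24, case-normalized on read). Every pipeline run writes a JSON manifest
(config echo, seeds, drop log) so a run can be reconstructed exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    EffectParams,
    SeedConfig,
    GroundTruth,
    NUCLEOTIDES,
    SEQUENCE_LENGTH,
)

__all__ = [
    "RunConfig",
    "DesignConfig",
    "LayoutConfig",
    "AnalysisConfig",
    "read_cell_table",
    "write_cell_table",
    "read_metadata",
    "write_metadata",
    "read_well_exclusions",
    "write_ground_truth",
    "read_ground_truth",
    "write_manifest",
    "setup_logging",
]

logger = logging.getLogger("seedfx")

METADATA_COLUMNS = [
    "Plate", "Well", "Layout", "TreatmentID", "Gene", "Sequence", "Seed",
    "ReplicateIndex", "IsUntreated", "IsControl",
]


def setup_logging(log_file: str | Path | None = None, level: int = logging.INFO) -> None:
    """Timestamped, leveled logging to stderr and optionally a run log file."""
    root = logging.getLogger("seedfx")
    root.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    root.handlers = []
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(fmt)
    root.addHandler(stream)
    if log_file is not None:
        fh = logging.FileHandler(log_file, encoding="utf-8")
        fh.setFormatter(fmt)
        root.addHandler(fh)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class DesignConfig:
    n_genes: int = 20
    shrnas_per_gene: int = 5
    n_seed_pairs: int = 12
    n_controls: int = 4
    design_seed: int = 0


@dataclass(frozen=True)
class LayoutConfig:
    n_layout_replicates: int = 2
    plate_size: int = 384
    n_untreated_per_plate: int = 8
    layout_seed: int = 0


@dataclass(frozen=True)
class AnalysisConfig:
    variance_threshold: float = 0.99
    percentile: float = 95.0
    percentile_method: str = "linear"
    cross_layout_only: bool = False
    controls_only: bool = False
    #: where replicate wells are median-aggregated: "pca" or "feature"
    sequence_space: str = "pca"


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the simulate -> profile -> analyze chain."""

    design: DesignConfig = DesignConfig()
    layout: LayoutConfig = LayoutConfig()
    effects: EffectParams = EffectParams()
    seed_window: SeedConfig = SeedConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @staticmethod
    def from_master_seed(seed: int, **overrides) -> "RunConfig":
        """Derive all stage seeds deterministically from one master seed."""
        ss = np.random.SeedSequence(seed)
        design_seed, layout_seed, loading_seed, sampling_seed = (
            int(s) % (2**31) for s in ss.generate_state(4)
        )
        cfg = RunConfig(
            design=DesignConfig(design_seed=design_seed),
            layout=LayoutConfig(layout_seed=layout_seed),
            effects=EffectParams(loading_seed=loading_seed, sampling_seed=sampling_seed),
        )
        return dataclasses.replace(cfg, **overrides) if overrides else cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "design": DesignConfig, "layout": LayoutConfig,
            "effects": EffectParams, "seed_window": SeedConfig,
            "analysis": AnalysisConfig,
        }
        unknown = set(data) - set(sections)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        kwargs = {}
        for name, typ in sections.items():
            sub = data.get(name, {})
            allowed = {f.name for f in fields(typ)}
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown key(s) in '{name}': {sorted(bad)}")
            kwargs[name] = typ(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# tabular artifacts

def _normalize_well(label: str) -> str:
    return str(label).strip().upper()


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell feature table (Plate, Well[, Cell], numeric features).

    Non-numeric entries in feature columns fail loudly, naming the first
    offending row and column.
    """
    df = pd.read_csv(path, dtype={"Plate": str, "Well": str},
                     float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty cell table")
    missing = {"Plate", "Well"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing key column(s) {sorted(missing)}")
    df["Well"] = df["Well"].map(_normalize_well)
    feats = [c for c in df.columns if c not in ("Plate", "Well", "Cell")]
    for col in feats:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in feature column {col!r}, row {row}"
            )
        df[col] = converted
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-well treatment metadata table.

    Untreated rows may have blank Gene/Sequence/Seed; treated rows must
    carry a valid 21-nt ACGT sense sequence. Duplicate (Plate, Well)
    keys are rejected.
    """
    df = pd.read_csv(path, dtype={"Plate": str, "Well": str, "Gene": str,
                                  "Sequence": str, "Seed": str})
    required = set(METADATA_COLUMNS) - {"Seed", "IsControl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {sorted(missing)}")
    df["Well"] = df["Well"].map(_normalize_well)
    for col in ("Gene", "Sequence", "Seed"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    if "IsControl" not in df.columns:
        df["IsControl"] = False
    df["IsUntreated"] = df["IsUntreated"].astype(bool)
    df["IsControl"] = df["IsControl"].astype(bool)
    dup = df.duplicated(subset=["Plate", "Well"])
    if dup.any():
        keys = df.loc[dup, ["Plate", "Well"]].apply(tuple, axis=1).tolist()
        raise ValueError(f"{path}: duplicate well key(s) {keys[:5]}")
    treated = ~df["IsUntreated"]
    for seq in df.loc[treated, "Sequence"]:
        if len(seq) != SEQUENCE_LENGTH or set(seq) - set(NUCLEOTIDES):
            raise ValueError(
                f"{path}: invalid sense sequence {seq!r} "
                f"(need {SEQUENCE_LENGTH} nt over ACGT)"
            )
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index=False)


def read_well_exclusions(path: str | Path, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a QC well-exclusion list (Plate, Well[, Reason]); dedup keys.

    If metadata is given, keys not present in it are rejected.
    """
    df = pd.read_csv(path, dtype={"Plate": str, "Well": str})
    missing = {"Plate", "Well"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df["Well"] = df["Well"].map(_normalize_well)
    if "Reason" not in df.columns:
        df["Reason"] = ""
    df = df.drop_duplicates(subset=["Plate", "Well"]).reset_index(drop=True)
    if metadata is not None:
        known = set(map(tuple, metadata[["Plate", "Well"]].to_numpy()))
        bad = [k for k in map(tuple, df[["Plate", "Well"]].to_numpy()) if k not in known]
        if bad:
            raise ValueError(f"{path}: excluded well(s) not in metadata: {bad[:5]}")
    return df


# ---------------------------------------------------------------------------
# ground truth and manifests

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist the simulator's latent effects as structured key-value text."""
    payload = {
        "params": dataclasses.asdict(truth.params),
        "gene_effects": {k: v.tolist() for k, v in truth.gene_effects.items()},
        "seed_effects": {k: v.tolist() for k, v in truth.seed_effects.items()},
        "sequence_effects": {k: v.tolist() for k, v in truth.sequence_effects.items()},
        "treatment_effects": {k: v.tolist() for k, v in truth.treatment_effects.items()},
        "loadings": truth.loadings.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True),
                          encoding="utf-8")


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(
        gene_effects={k: np.asarray(v) for k, v in payload["gene_effects"].items()},
        seed_effects={k: np.asarray(v) for k, v in payload["seed_effects"].items()},
        sequence_effects={k: np.asarray(v)
                          for k, v in payload["sequence_effects"].items()},
        treatment_effects={k: np.asarray(v)
                           for k, v in payload["treatment_effects"].items()},
        loadings=np.asarray(payload["loadings"]),
        params=EffectParams(**payload["params"]),
    )


def write_manifest(path: str | Path, config: RunConfig, stage: str,
                   extra: dict | None = None) -> None:
    import seedfx
    payload = {
        "stage": stage,
        "version": seedfx.__version__,
        "config": config.to_dict(),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True),
                          encoding="utf-8")
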