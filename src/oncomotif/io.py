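"""Shared readers/writers, run configuration and logging.

All tabular interchange is tab-separated with a header row and a row-label
first column; matrices are written with features (genes/miRNAs) as rows and
samples as columns, the transpose of the in-memory sample x feature
orientation used by the cohort analyses.  Randomness for a whole run flows
from one top-level seed, expanded per stage through
``numpy.random.SeedSequence`` spawning (see :func:`stage_seeds`).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .motif import MiRNACatalogue

log = logging.getLogger("oncomotif")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def read_matrix(path) -> pd.DataFrame:
    """Read a labelled TSV matrix (first column = row labels).

    Duplicate row labels, ragged rows and empty files are errors; decimal
    points only (no locale commas).
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row label(s) in {path}: {dupes}")
    if df.isna().all(axis=None) and df.shape[1] == 0:
        raise ValueError(f"no data columns in {path}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_fasta(path) -> MiRNACatalogue:
    """FASTA reader for mature miRNA catalogues (T coerced to U)."""
    return MiRNACatalogue.from_fasta(path)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with the column contract of the simulator."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    required = {"is_tumor", "TP53_mut", "MYC_gain", "rfs_time", "rfs_event"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    return meta


def stage_seeds(master_seed: int, stages) -> dict[str, int]:
    """Derive one sub-seed per named stage from a single master seed.

    Children are spawned in stage order from ``SeedSequence(master_seed)``
    and reduced to ints below 2**31, so one number reproduces the run.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(stages))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(stages, children)
    }


# --------------------------------------------------------------------------
# run configuration


_STAGES = ("screen_sim", "omics_sim", "cohort_sim")


@dataclass
class RunConfig:
    """Resolved parameters for an end-to-end simulate-and-analyze run.

    Stage blocks mirror the analysis defaults; unknown keys in a YAML file
    are rejected.  The resolved config (including derived stage seeds) is
    written alongside every run's outputs for provenance.
    """

    seed: int = 0
    screen_sim: dict = field(default_factory=dict)
    omics_sim: dict = field(default_factory=dict)
    cohort_sim: dict = field(default_factory=dict)
    screen: dict = field(
        default_factory=lambda: {
            "min_reads": 300,
            "lfc_threshold": 1.5,
            "p_threshold": 0.05,
            "pseudocount": 0.5,
        }
    )
    motif: dict = field(default_factory=lambda: {"k": 6})
    targets: dict = field(
        default_factory=lambda: {"p_threshold": 0.05, "min_predictions": 5}
    )
    signature: dict = field(
        default_factory=lambda: {
            "pct": 5.0,
            "fdr_threshold": 1e-5,
            "lfc_threshold": 1.0,
        }
    )
    network: dict = field(
        default_factory=lambda: {"threshold": -0.15, "log_scale": True}
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        base = cls()
        for key, value in raw.items():
            if isinstance(value, dict):
                merged = dict(getattr(base, key))
                merged.update(value)
                setattr(base, key, merged)
            else:
                setattr(base, key, value)
        return base

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def sim_seeds(self) -> dict[str, int]:
        return stage_seeds(self.seed, _STAGES)
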