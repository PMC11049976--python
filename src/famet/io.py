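"""File I/O, run configuration and reproducibility metadata for the pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_phenotypes", "write_phenotypes", "write_run_metadata"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the analysis constants.

    QC drops markers with over 40% missing calls and minor-allele frequency
    lower than 5%; cross-validation is 5-fold.
    """

    markers: str = ""
    phenotypes: str = ""
    output_dir: str = "famet_out"
    max_missing: float = 0.40
    min_maf: float = 0.05
    models: list = field(default_factory=lambda: ["FA", "FA+G", "FA+GG", "FA+G+GG"])
    fa_order: int = 1
    cv_scheme: str = "CV1"
    cv_opts: dict = field(default_factory=dict)
    n_folds: int = 5
    seed: int = 0
    imputation_rank: int | None = None
    imputation_tol: float = 1e-4
    stabilization_eps: float = 1e-6
    n_restarts: int = 1
    max_iter: int = 300

    def __post_init__(self) -> None:
        for name in ("max_missing", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory for any stochastic step")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_phenotypes(path) -> PhenotypeTable:
    """Read and validate a long-format phenotype CSV (genotype,site,rep,yield).

    Errors name the offending rows (1-based file rows, header excluded).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("genotype", "site", "rep", "yield") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    y = pd.to_numeric(df["yield"], errors="coerce")
    if y.isna().any():
        rows = (df.index[y.isna()] + 2).tolist()  # +1 header, +1 1-based
        raise ValueError(f"{path}: non-numeric yield at file row(s) {rows[:5]}")
    df["yield"] = y
    dup = df.duplicated(subset=["genotype", "site", "rep"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicate (genotype, site, rep) at file row(s) {rows[:5]}")
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.to_csv(path)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_metadata(out_dir, config: RunConfig, inputs: list | None = None,
                       extra: dict | None = None) -> Path:
    """Write a JSON log with the config echo, seed, input checksums and versions."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {"famet": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "python": platform.python_version()},
        "input_checksums": {str(p): _sha256(p) for p in (inputs or []) if Path(p).exists()},
    }
    if extra:
        meta.update(extra)
    path = out_dir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, default=str))
    logger.info("run metadata written to %s", path)
    return path
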