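"""Long-format multi-environment trial phenotype records."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PhenotypeTable"]

REQUIRED_COLUMNS = ("genotype", "site", "rep", "yield")


@dataclass
class PhenotypeTable:
    """Trial records: one row per (genotype, site, replicate) with a yield in t/ha.

    The table implies the design matrices of the mixed model: site fixed
    effects, replicate-within-site random effects and the genotype-within-site
    incidence.  Site and genotype orderings follow first appearance and are
    stable under row subsetting, so fold-masked training tables index sites
    identically to the full table.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing column(s): {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["site"] = df["site"].astype(str)
        df["rep"] = df["rep"].astype(str)
        y = pd.to_numeric(df["yield"], errors="coerce")
        if y.isna().any():
            bad = df.index[y.isna()].tolist()
            raise ValueError(f"non-numeric yield at row(s) {bad[:5]}")
        df["yield"] = y.astype(float)
        dup = df.duplicated(subset=["genotype", "site", "rep"])
        if dup.any():
            rows = df.index[dup].tolist()
            raise ValueError(f"duplicate (genotype, site, rep) key(s) at row(s) {rows[:5]}")
        self.data = df.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.data["genotype"]))

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.data["site"]))

    def subset(self, row_mask: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[np.asarray(row_mask)].reset_index(drop=True))

    def cell_means(self) -> pd.DataFrame:
        """Genotype x site matrix of replicate means (NaN for unobserved cells)."""
        wide = self.data.groupby(["genotype", "site"], sort=False)["yield"].mean().unstack("site")
        return wide.reindex(index=self.genotypes, columns=self.sites)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, dtype={"genotype": str, "site": str, "rep": str}))
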