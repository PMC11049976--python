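"""Marker quality control, numeric coding, allele frequencies, and EM imputation.

SNP genotypes are coded numerically: ``1`` homozygous for the most frequent
allele, ``0`` heterozygous, ``-1`` homozygous for the least frequent allele.
Missing calls are ``NaN``.  Inbred wheat panels are almost entirely
``{1, -1}`` with a small residual heterozygosity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "AlleleFrequencySet",
    "allele_frequencies",
    "polarize",
    "qc_filter",
    "impute_em",
    "read_marker_csv",
    "write_marker_csv",
    "read_vcf",
    "EmptyPanelError",
]


class EmptyPanelError(ValueError):
    """Raised when quality control removes every marker."""


@dataclass
class MarkerMatrix:
    """Genotypes x markers numeric SNP matrix.

    Parameters
    ----------
    values
        Float array of shape ``(n_genotypes, n_markers)``.  Before imputation
        every non-missing entry is in ``{1, 0, -1}``; after imputation entries
        are real-valued in ``[-1, 1]`` and no NaN remains.
    genotype_ids, marker_ids
        Unique ordered labels for rows and columns.
    is_imputed
        True once missing entries have been filled.
    """

    values: np.ndarray
    genotype_ids: list[str]
    marker_ids: list[str]
    is_imputed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        n, p = self.values.shape
        if len(self.genotype_ids) != n or len(self.marker_ids) != p:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.genotype_ids)) != n:
            raise ValueError("genotype_ids must be unique")
        if len(set(self.marker_ids)) != p:
            raise ValueError("marker_ids must be unique")
        if not self.is_imputed:
            obs = self.values[~np.isnan(self.values)]
            if obs.size and not np.isin(obs, (-1.0, 0.0, 1.0)).all():
                raise ValueError("non-missing entries must be in {1, 0, -1}")

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.values).mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids, columns=self.marker_ids)


@dataclass
class AlleleFrequencySet:
    """Per-marker minor-allele frequencies and the kernel centering constants.

    ``minor_freqs[j]`` is :math:`p_j \\le 0.5`; ``centering[j]`` is the
    expected code under Hardy-Weinberg equilibrium,
    :math:`\\mu_{E,j} = 1 - 2 p_j`; ``denom`` is :math:`2\\sum_j p_j (1-p_j)`.
    ``flip_mask[j]`` records markers whose coding was negated so the minor
    allele is the one counted.
    """

    minor_freqs: np.ndarray
    flip_mask: np.ndarray
    marker_ids: list[str] = field(default_factory=list)

    @property
    def centering(self) -> np.ndarray:
        return 1.0 - 2.0 * self.minor_freqs

    @property
    def denom(self) -> float:
        return float(2.0 * np.sum(self.minor_freqs * (1.0 - self.minor_freqs)))


def allele_frequencies(markers: MarkerMatrix) -> AlleleFrequencySet:
    """Minor-allele frequency per marker, with automatic polarization.

    Code ``1`` carries 0 minor alleles, ``0`` carries 1 and ``-1`` carries 2,
    so ``p_j = (n_het + 2 n_hom_minor) / (2 n_obs)``.  If the raw frequency
    exceeds 0.5 the allele labelling is flipped (codes negated) and
    ``flip_mask`` records it.  Markers with zero observed calls get
    ``p_j = NaN`` and a warning; they are expected to be removed by QC.
    """
    if markers.n_markers == 0:
        raise EmptyPanelError("marker matrix has no markers")
    x = markers.values
    obs = ~np.isnan(x)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        # minor-allele count per entry is 1 - code
        counts = np.nansum(1.0 - x, axis=0)
        p = counts / (2.0 * n_obs)
    flip = p > 0.5
    p = np.where(flip, 1.0 - p, p)
    if (n_obs == 0).any():
        bad = [markers.marker_ids[j] for j in np.flatnonzero(n_obs == 0)]
        warnings.warn(f"{len(bad)} marker(s) with no observed calls: {bad[:5]}...")
        logger.warning("markers with zero observed calls flagged: %d", len(bad))
    return AlleleFrequencySet(minor_freqs=p, flip_mask=flip, marker_ids=list(markers.marker_ids))


def polarize(markers: MarkerMatrix) -> tuple[MarkerMatrix, AlleleFrequencySet]:
    """Return the matrix with flipped markers negated, plus its frequencies.

    Idempotent: re-running on the output changes nothing (all ``p_j <= 0.5``
    already).
    """
    freqs = allele_frequencies(markers)
    values = markers.values.copy()
    values[:, freqs.flip_mask] = -values[:, freqs.flip_mask]
    out = replace(markers, values=values)
    return out, AlleleFrequencySet(
        minor_freqs=freqs.minor_freqs,
        flip_mask=np.zeros_like(freqs.flip_mask),
        marker_ids=freqs.marker_ids,
    )


def qc_filter(
    markers: MarkerMatrix,
    max_missing: float = 0.40,
    min_maf: float = 0.05,
) -> MarkerMatrix:
    """Remove markers with too many missing calls, then low-MAF markers.

    A marker is dropped if its missing fraction is strictly greater than
    ``max_missing`` (the "over 40% missing" rule), and then, with frequencies
    recomputed on the survivors, if its minor-allele frequency is strictly
    lower than ``min_maf`` — a marker at exactly the threshold survives.
    Missingness is filtered first because MAF estimates on heavily missing
    markers are unreliable; both counts are logged.  Genotype rows are never
    removed.
    """
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = markers.missing_fraction()
    keep_miss = miss <= max_missing
    n_drop_miss = int((~keep_miss).sum())
    stage1 = MarkerMatrix(
        markers.values[:, keep_miss],
        markers.genotype_ids,
        [m for m, k in zip(markers.marker_ids, keep_miss) if k],
        is_imputed=markers.is_imputed,
    )
    if stage1.n_markers == 0:
        raise EmptyPanelError("all markers removed by the missingness filter")
    freqs = allele_frequencies(stage1)
    keep_maf = ~(freqs.minor_freqs < min_maf)  # NaN frequencies are kept here; all-missing already gone
    n_drop_maf = int((~keep_maf).sum())
    logger.info(
        "qc_filter: %d markers removed for missingness > %.2f, then %d for MAF < %.3f",
        n_drop_miss, max_missing, n_drop_maf, min_maf,
    )
    out = MarkerMatrix(
        stage1.values[:, keep_maf],
        stage1.genotype_ids,
        [m for m, k in zip(stage1.marker_ids, keep_maf) if k],
        is_imputed=stage1.is_imputed,
    )
    if out.n_markers == 0:
        raise EmptyPanelError("all markers removed by quality control")
    return out


def _choose_rank(x_filled: np.ndarray, explained: float = 0.80, cap: int = 20) -> int:
    """Number of leading components explaining `explained` of the variance."""
    s = np.linalg.svd(x_filled - x_filled.mean(axis=0), compute_uv=False)
    var = s**2
    tot = var.sum()
    if tot <= 0:
        return 0
    frac = np.cumsum(var) / tot
    k = int(np.searchsorted(frac, explained) + 1)
    return min(k, cap, min(x_filled.shape))


def impute_em(
    markers: MarkerMatrix,
    tol: float = 1e-4,
    max_iter: int = 100,
    rank: int | None = None,
) -> MarkerMatrix:
    """EM imputation of missing calls via iterative low-rank approximation.

    Missing cells are initialised at the marker mean; then the column-centered
    matrix is approximated by its leading ``rank`` singular vectors and the
    missing cells are replaced by the approximation, iterating until the
    largest absolute change in an imputed cell drops below ``tol`` or
    ``max_iter`` is reached (non-convergence is a warning, not a failure).
    Imputed values are clipped to ``[-1, 1]`` and left fractional; observed
    cells are never altered.  With ``rank=0`` the marker mean is the fixed
    point.  ``rank=None`` picks the number of components explaining 80% of
    the variance, capped at 20.
    """
    miss = markers.missing_mask
    if not miss.any():
        return replace(markers, values=markers.values.copy(), is_imputed=True)
    if (miss.all(axis=0)).any():
        raise ValueError("every marker must have at least one observed call")
    x = markers.values.copy()
    col_mean = np.nanmean(x, axis=0)
    x[miss] = np.broadcast_to(col_mean, x.shape)[miss]
    if rank is None:
        rank = _choose_rank(x)
    if rank > 0:
        for _ in range(max_iter):
            mu = x.mean(axis=0)
            xc = x - mu
            u, s, vt = np.linalg.svd(xc, full_matrices=False)
            approx = (u[:, :rank] * s[:rank]) @ vt[:rank] + mu
            new = np.clip(approx[miss], -1.0, 1.0)
            delta = np.max(np.abs(new - x[miss]))
            x[miss] = new
            if delta < tol:
                break
        else:
            warnings.warn(f"impute_em did not converge in {max_iter} iterations")
    x[miss] = np.clip(x[miss], -1.0, 1.0)
    return replace(markers, values=x, is_imputed=True)


# ---------------------------------------------------------------------------
# I/O

def read_marker_csv(path) -> MarkerMatrix:
    """Read a genotype x marker CSV (rows labelled by genotype ID)."""
    df = pd.read_csv(path, index_col=0)
    return MarkerMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        is_imputed=not df.isna().any().any() and not df.isin((-1.0, 0.0, 1.0)).all().all(),
    )


def write_marker_csv(markers: MarkerMatrix, path) -> None:
    markers.to_dataframe().to_csv(path, float_format="%.10g", index_label="genotype")


def read_vcf(path) -> MarkerMatrix:
    """Read biallelic SNPs from a VCF into the {1, 0, -1} coding.

    REF-homozygotes map to 1, heterozygotes to 0, ALT-homozygotes to -1 and
    missing genotypes to NaN, prior to minor-allele polarization.
    Multi-allelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    n_skipped = 0
    code = np.array([1.0, 0.0, np.nan, -1.0])  # cyvcf2 gt_types: HOM_REF, HET, UNKNOWN, HOM_ALT
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        rows.append(code[var.gt_types])
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic record(s)", n_skipped)
    if not rows:
        raise EmptyPanelError("no biallelic SNP records in VCF")
    return MarkerMatrix(np.column_stack(rows), samples, ids)
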