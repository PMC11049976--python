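"""Genomic relationship kernels: additive (VanRaden-type) and additive x additive epistatic.

The additive kernel is ``G_A = (X - mu_E)(X - mu_E)' / (2 * sum_j p_j (1 - p_j))``
with ``mu_E_j = 1 - 2 p_j`` the Hardy-Weinberg expectation of the {1, 0, -1}
code, and the first-order epistatic kernel is the Hadamard (elementwise)
square ``G_A # G_A``, which is positive semidefinite whenever ``G_A`` is
(Schur product theorem).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .markers import AlleleFrequencySet, MarkerMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicKernel",
    "identity_kernel",
    "additive_kernel",
    "epistatic_kernel",
    "stabilize",
    "read_kernel_csv",
    "write_kernel_csv",
    "KernelError",
]


class KernelError(ValueError):
    """Raised when a relationship matrix cannot be constructed."""


@dataclass
class GenomicKernel:
    """Symmetric genotype x genotype relationship matrix.

    ``kind`` is one of ``{"identity", "additive", "epistatic"}``;
    ``stabilization_eps`` records any diagonal jitter actually added.
    """

    matrix: np.ndarray
    genotype_ids: list[str]
    kind: str = "additive"
    stabilization_eps: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        n = len(self.genotype_ids)
        if self.matrix.shape != (n, n):
            raise KernelError("matrix shape does not match genotype_ids")
        if len(set(self.genotype_ids)) != n:
            raise KernelError("genotype_ids must be unique")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise KernelError("kernel matrix must be symmetric to 1e-10")

    @property
    def n_genotypes(self) -> int:
        return self.matrix.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def subset(self, genotype_ids: list[str]) -> "GenomicKernel":
        """Rows/columns for the requested genotypes, in the requested order."""
        pos = {g: i for i, g in enumerate(self.genotype_ids)}
        missing = [g for g in genotype_ids if g not in pos]
        if missing:
            raise KernelError(f"genotypes absent from kernel: {missing[:5]}")
        idx = np.array([pos[g] for g in genotype_ids])
        return replace(self, matrix=self.matrix[np.ix_(idx, idx)], genotype_ids=list(genotype_ids))


def identity_kernel(genotype_ids: list[str]) -> GenomicKernel:
    """Identity relationship (independent genotypes); the kernel of the plain FA model."""
    return GenomicKernel(np.eye(len(genotype_ids)), list(genotype_ids), kind="identity")


def additive_kernel(markers: MarkerMatrix, freqs: AlleleFrequencySet | None = None) -> GenomicKernel:
    """Additive genomic relationship matrix from an imputed marker matrix.

    Columns are centered by ``mu_E_j = 1 - 2 p_j`` (after negating any marker
    whose coding had to be flipped so that ``p_j`` counts the minor allele)
    and the cross-product is scaled by ``2 * sum_j p_j (1 - p_j)``.
    """
    from .markers import allele_frequencies

    if np.isnan(markers.values).any():
        raise KernelError("markers must be imputed (no missing values) before kernel construction")
    if freqs is None:
        freqs = allele_frequencies(markers)
    x = markers.values.copy()
    if freqs.flip_mask.any():
        x[:, freqs.flip_mask] = -x[:, freqs.flip_mask]
    denom = freqs.denom
    if denom <= 0:
        raise KernelError("all markers monomorphic: 2*sum p(1-p) is not positive")
    w = x - freqs.centering
    g = (w @ w.T) / denom
    g = (g + g.T) / 2.0  # enforce exact symmetry against round-off
    return GenomicKernel(g, list(markers.genotype_ids), kind="additive")


def epistatic_kernel(g: GenomicKernel) -> GenomicKernel:
    """First-order additive x additive kernel: the elementwise square of G_A."""
    if g.kind != "additive":
        raise KernelError(f"epistatic kernel requires an additive input, got kind={g.kind!r}")
    return GenomicKernel(g.matrix * g.matrix, list(g.genotype_ids), kind="epistatic")


def stabilize(g: GenomicKernel, eps: float = 1e-6) -> GenomicKernel:
    """Add ``eps`` to the diagonal iff the minimum eigenvalue is below 1e-8.

    A kernel from duplicated genotypes is exactly singular; the shift keeps
    downstream Cholesky factorizations well posed.  With ``eps=0`` a singular
    kernel is returned unchanged with a logged warning.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    lam_min = g.min_eigenvalue()
    if lam_min >= 1e-8:
        return replace(g, stabilization_eps=0.0)
    if eps == 0.0:
        logger.warning("stabilize: kernel min eigenvalue %.3e < 1e-8 but eps=0; returned unchanged", lam_min)
        return replace(g, stabilization_eps=0.0)
    return replace(g, matrix=g.matrix + eps * np.eye(g.n_genotypes), stabilization_eps=eps)


def write_kernel_csv(g: GenomicKernel, path) -> None:
    """Write with genotype IDs as header row and first column (lossless to 1e-12)."""
    pd.DataFrame(g.matrix, index=g.genotype_ids, columns=g.genotype_ids).to_csv(
        path, float_format="%.17g", index_label="genotype"
    )


def read_kernel_csv(path, kind: str = "additive") -> GenomicKernel:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise KernelError("kernel CSV row and column labels differ")
    return GenomicKernel(df.to_numpy(dtype=float), [str(i) for i in df.index], kind=kind)
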