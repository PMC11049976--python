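"""Synthetic inbred-wheat multi-environment trial generator.

Emulates the data a factor-analytic genomic-prediction analysis assumes:
near-fully-inbred SNP genotypes in {1, 0, -1} coding, a few field sites with
two replicates each, and genetic values driven by additive QTL plus pairwise
additive x additive epistatic QTL through latent environmental factors.
Ground truth (genetic values, the generating site covariance, the causal
marker model) is retained for parameter-recovery testing.

The generative site covariance is the factor-analytic form
``Lambda Lambda' + Psi``: per-genotype factor scores are linear combinations
of causal marker codes (and marker-pair products), standardised to unit
variance, so the realised between-site genetic covariance matches the
configured loadings; the site-specific deviation ``d_ij ~ N(0, psi_j)``
supplies the diagonal remainder.  Epistatic genetic values are built from
explicit marker-pair products — not from the analysis kernel — so generator
and analysis stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import MarkerMatrix
from .phenotypes import PhenotypeTable

__all__ = ["SimConfig", "SimTruth", "simulate_markers", "simulate_genetic_values",
           "simulate_trial", "simulate_dataset", "ConfigError"]


class ConfigError(ValueError):
    """Raised for inconsistent simulation settings."""


def _per_site(value, n_sites: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_sites,)).copy()
    if (arr < 0).any():
        raise ConfigError(f"{name} must be >= 0")
    return arr


@dataclass
class SimConfig:
    """Settings for one synthetic trial series.

    Defaults mirror a single wheat target population of environments:
    162 lines, six sites with two replicates, site mean yields between
    4.5 and 5.9 t/ha, per-site genetic standard deviation around 0.33 t/ha
    (a genetic coefficient of variation of ~6%), and a plot residual variance
    giving a line-mean heritability near 0.6.

    ``loadings`` is the sites x q matrix of true latent-factor loadings and
    ``psi`` the site-specific genetic variances, so the generating genetic
    covariance between sites is ``loadings @ loadings.T + diag(psi)``.
    ``rep_var``/``res_var`` may be scalars or per-site arrays.
    """

    n_genotypes: int = 162
    n_markers: int = 1000
    n_sites: int = 6
    n_reps: int = 2
    maf_low: float = 0.05
    maf_high: float = 0.5
    residual_het_rate: float = 0.01
    missing_rate: float = 0.0
    n_qtl_add: int | None = None  # default: a fifth of the markers, capped at 200
    n_qtl_pairs_epi: int = 0
    loadings: np.ndarray | None = None
    psi: np.ndarray | None = None
    site_means: np.ndarray | None = None
    rep_var: float | np.ndarray = 0.02
    res_var: float | np.ndarray = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        s = self.n_sites
        if self.loadings is None:
            # one latent factor; loadings vary mildly across sites (G x E)
            scale = np.linspace(0.85, 1.15, s)
            self.loadings = (np.sqrt(0.10) * scale).reshape(s, 1)
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        if self.loadings.shape[0] != s:
            raise ConfigError("loadings must have n_sites rows")
        if self.psi is None:
            self.psi = np.full(s, 0.02)
        self.psi = _per_site(self.psi, s, "psi")
        if self.site_means is None:
            self.site_means = np.linspace(4.5, 5.9, s)
        self.site_means = np.broadcast_to(np.asarray(self.site_means, dtype=float), (s,)).copy()
        self.rep_var = _per_site(self.rep_var, s, "rep_var")
        self.res_var = _per_site(self.res_var, s, "res_var")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigError("require 0 < maf_low <= maf_high <= 0.5")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (0 <= self.residual_het_rate <= 1):
            raise ConfigError("residual_het_rate must be in [0, 1]")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        for name in ("n_genotypes", "n_markers", "n_sites"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_qtl_add is None:
            self.n_qtl_add = max(10, min(200, self.n_markers // 5))
        if self.n_qtl_add > self.n_markers:
            raise ConfigError("n_qtl_add exceeds the marker count")
        if 2 * self.n_qtl_pairs_epi > self.n_markers * (self.n_markers - 1):
            raise ConfigError("n_qtl_pairs_epi exceeds available marker pairs")

    @property
    def q(self) -> int:
        return self.loadings.shape[1]

    def site_covariance(self) -> np.ndarray:
        """The generating genetic covariance over sites, Lambda Lambda' + diag(psi)."""
        return self.loadings @ self.loadings.T + np.diag(self.psi)

    # independent RNG streams so e.g. changing missing_rate never perturbs
    # the genetic values
    def _rng(self, component: str) -> np.random.Generator:
        names = ("markers", "het", "missing", "effects", "specific", "trial")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return np.random.default_rng(children[names.index(component)])


@dataclass
class SimTruth:
    """Ground truth behind a simulated trial series.

    ``true_genetic_values = true_additive_values + true_epistatic_values``
    holds elementwise.  The site-specific deviation (``true_specific_values``,
    drawn N(0, psi_j) independently of markers) is counted inside
    ``true_additive_values``; it is exposed separately so callers can remove
    it.  ``qtl_indices``/``qtl_effects`` record the causal marker model:
    additive marker indices and per-factor effects, and epistatic marker
    pairs with per-factor interaction effects.
    """

    true_genetic_values: np.ndarray
    true_additive_values: np.ndarray
    true_epistatic_values: np.ndarray
    true_specific_values: np.ndarray
    true_site_covariance: np.ndarray
    qtl_indices: dict = field(default_factory=dict)
    qtl_effects: dict = field(default_factory=dict)
    genotype_ids: list[str] = field(default_factory=list)
    site_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.true_genetic_values, index=self.genotype_ids, columns=self.site_ids)


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_markers(config: SimConfig) -> MarkerMatrix:
    """Draw an inbred-line SNP panel in {1, 0, -1} coding with optional missingness.

    Per marker j an allele frequency ``p_j ~ U(maf_low, maf_high)`` is drawn;
    each genotype is homozygous minor (-1) with probability ``p_j`` and
    homozygous major (1) otherwise, then flipped to heterozygous (0) with
    probability ``residual_het_rate``; entries are set missing independently
    with probability ``missing_rate``.
    """
    n, m = config.n_genotypes, config.n_markers
    rng = config._rng("markers")
    p = rng.uniform(config.maf_low, config.maf_high, size=m)
    codes = np.where(rng.random((n, m)) < p, -1.0, 1.0)
    if config.residual_het_rate > 0:
        het = config._rng("het").random((n, m)) < config.residual_het_rate
        codes[het] = 0.0
    if config.missing_rate > 0:
        miss = config._rng("missing").random((n, m)) < config.missing_rate
        codes[miss] = np.nan
    return MarkerMatrix(codes, _ids("G", n), _ids("M", m))


def _factor_scores(x: np.ndarray, config: SimConfig, rng: np.random.Generator):
    """Additive and epistatic per-genotype factor scores, before standardisation."""
    n = x.shape[0]
    q = config.q
    s_add = np.zeros((n, q))
    s_epi = np.zeros((n, q))
    idx_add = np.array([], dtype=int)
    pairs = np.zeros((0, 2), dtype=int)
    eff_add = np.zeros((0, q))
    eff_epi = np.zeros((0, q))
    if config.n_qtl_add > 0:
        idx_add = rng.choice(config.n_markers, size=config.n_qtl_add, replace=False)
        eff_add = rng.standard_normal((config.n_qtl_add, q)) / np.sqrt(config.n_qtl_add)
        s_add = x[:, idx_add] @ eff_add
    if config.n_qtl_pairs_epi > 0:
        flat = rng.choice(config.n_markers * config.n_markers, size=4 * config.n_qtl_pairs_epi, replace=False)
        i, j = flat // config.n_markers, flat % config.n_markers
        keep = i < j
        i, j = i[keep][: config.n_qtl_pairs_epi], j[keep][: config.n_qtl_pairs_epi]
        if len(i) < config.n_qtl_pairs_epi:
            raise ConfigError("could not draw enough distinct epistatic marker pairs")
        pairs = np.column_stack([i, j])
        eff_epi = rng.standard_normal((len(i), q)) / np.sqrt(len(i))
        s_epi = (x[:, i] * x[:, j]) @ eff_epi
    return s_add, s_epi, idx_add, pairs, eff_add, eff_epi


def simulate_genetic_values(markers: MarkerMatrix, config: SimConfig) -> SimTruth:
    """Build genotype x site genetic values from causal markers and latent factors.

    Factor scores (additive QTL combinations plus epistatic pair-product
    combinations) are standardised to exactly unit sample variance and zero
    cross-factor correlation, so the genotype-level variance of
    ``sum_k lambda_jk delta_i(k)`` matches ``(Lambda Lambda')_jj``; the FA
    specific deviation ``d_ij ~ N(0, psi_j)`` is then added per site.
    Requires a complete (or imputed) marker matrix.
    """
    x = markers.values
    if np.isnan(x).any():
        raise ValueError("markers must be complete (impute first)")
    if x.shape != (config.n_genotypes, config.n_markers):
        raise ConfigError("marker matrix shape does not match config")
    n, s, q = config.n_genotypes, config.n_sites, config.q
    rng = config._rng("effects")
    s_add, s_epi, idx_add, pairs, eff_add, eff_epi = _factor_scores(x, config, rng)
    s_add = s_add - s_add.mean(axis=0)
    s_epi = s_epi - s_epi.mean(axis=0)
    total = s_add + s_epi
    if config.n_qtl_add + config.n_qtl_pairs_epi > 0:
        # whiten so the sample covariance of the scores is exactly I_q
        cov = total.T @ total / n
        try:
            tinv = np.linalg.inv(np.linalg.cholesky(cov)).T
        except np.linalg.LinAlgError as exc:
            raise ConfigError("factor scores are rank deficient; increase n_qtl or reduce q") from exc
        s_add = s_add @ tinv
        s_epi = s_epi @ tinv
    lam = config.loadings
    add = s_add @ lam.T
    epi = s_epi @ lam.T
    spec = config._rng("specific").standard_normal((n, s)) * np.sqrt(config.psi)
    add = add + spec
    return SimTruth(
        true_genetic_values=add + epi,
        true_additive_values=add,
        true_epistatic_values=epi,
        true_specific_values=spec,
        true_site_covariance=config.site_covariance(),
        qtl_indices={"additive": idx_add, "epistatic_pairs": pairs},
        qtl_effects={"additive": eff_add, "epistatic_pairs": eff_epi},
        genotype_ids=list(markers.genotype_ids),
        site_ids=_ids("S", s),
    )


def simulate_trial(truth: SimTruth, config: SimConfig) -> PhenotypeTable:
    """One record per genotype x site x replicate.

    ``y = site_mean_j + rep_effect_{r(j)} + g_ij + e_ijr`` with replicate
    effects drawn once per (site, replicate) from N(0, rep_var_j) and plot
    residuals from N(0, res_var_j) per record.
    """
    g = truth.true_genetic_values
    n, s = g.shape
    if s != config.n_sites or n != config.n_genotypes:
        raise ConfigError("truth dimensions do not match config")
    r = config.n_reps
    rng = config._rng("trial")
    rep_eff = rng.standard_normal((s, r)) * np.sqrt(config.rep_var)[:, None]
    resid = rng.standard_normal((n, s, r)) * np.sqrt(config.res_var)[None, :, None]
    y = config.site_means[None, :, None] + rep_eff[None, :, :] + g[:, :, None] + resid
    gi, si, ri = np.meshgrid(np.arange(n), np.arange(s), np.arange(r), indexing="ij")
    df = pd.DataFrame({
        "genotype": np.asarray(truth.genotype_ids)[gi.ravel()],
        "site": np.asarray(truth.site_ids)[si.ravel()],
        "rep": (ri.ravel() + 1).astype(str),
        "yield": y.ravel(),
    })
    return PhenotypeTable(df)


def simulate_dataset(config: SimConfig) -> tuple[MarkerMatrix, SimTruth, PhenotypeTable]:
    """Markers, truth and phenotypes in one call (markers imputed trivially if complete)."""
    markers = simulate_markers(config)
    if config.missing_rate > 0:
        # genetic values are driven by the true underlying calls; the missing
        # stream is independent, so the same seed with missing_rate=0
        # reproduces the pre-missingness panel exactly
        clean_cfg = replace(config, missing_rate=0.0)
        truth = simulate_genetic_values(simulate_markers(clean_cfg), clean_cfg)
    else:
        truth = simulate_genetic_values(markers, config)
    pheno = simulate_trial(truth, config)
    return markers, truth, pheno
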