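"""Factor-analytic multi-environment mixed model: REML estimation and BLUP.

Model, for yield record ``y_{ijr}`` of genotype *i* at site *j*, replicate *r*:

    y_ijr = b_j + r_{jr} + u_ij + e_ijr

with fixed site effects ``b``, replicate-within-site effects
``r_{jr} ~ N(0, sigma2_r[j])``, residuals ``e ~ N(0, sigma2_e[j])`` and a
genotype-within-site genetic effect ``u_ij`` that sums one or two kernel
terms.  Term *t* has covariance ``Cov(u_t[i,j], u_t[i',j']) =
Sigma_t[j,j'] * K_t[i,i']`` where ``Sigma_t = Delta_t Delta_t' + D_t`` is a
factor-analytic (low-rank plus diagonal) site covariance and ``K_t`` is a
genomic relationship kernel (identity, additive, or epistatic).  A single
genotype-within-site effect per kernel term subsumes the separate genotype
main effect and G x E interaction: a common-loading FA structure absorbs the
main effect, which avoids a non-identifiable split.

Restricted likelihood (Harville form, constants included)::

    -2 l_R = (N - p) log 2*pi + log|V| + log|X' V^-1 X| + y' P y

The phenotypic covariance ``V`` is handled through a Woodbury factorization:
residuals are diagonal, and the genetic part enters through the Cholesky
factor of the covariance among *observed* genotype-site cells, so each
evaluation costs one Cholesky of (n_cells + n_rep_levels) plus O(N * m)
products.  Gradients are analytic, via site-block aggregation of the REML
projection matrix, which makes quasi-Newton iteration practical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .kernels import GenomicKernel, identity_kernel
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "FAStructure",
    "VarianceComponents",
    "ModelSpec",
    "ModelFit",
    "FitOptions",
    "model_from_name",
    "reml_loglik",
    "fit",
    "predict_genetic_values",
    "fitted_site_covariance",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_D_FLOOR = 1e-8  # keeps Sigma invertible without a visible variance


@dataclass
class FAStructure:
    """Factor-analytic site covariance ``Sigma = loadings @ loadings.T + diag(specific_vars)``.

    Identifiability: for q >= 2 the elements above the diagonal of the first
    q rows of the loading matrix are zero, and the first nonzero entry of
    each column is nonnegative (sign convention).
    """

    loadings: np.ndarray
    specific_vars: np.ndarray

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        if self.loadings.shape[0] < self.loadings.shape[1] and self.loadings.size > 0:
            # interpret a 1-D row as a single-factor column
            if self.loadings.shape[0] == 1:
                self.loadings = self.loadings.T
        self.specific_vars = np.asarray(self.specific_vars, dtype=float).ravel()
        if self.specific_vars.shape[0] != self.loadings.shape[0]:
            raise ValueError("specific_vars length must equal number of sites")
        if (self.specific_vars < 0).any():
            raise ValueError("specific variances must be >= 0")

    @property
    def n_sites(self) -> int:
        return self.loadings.shape[0]

    @property
    def order_q(self) -> int:
        return self.loadings.shape[1]

    def site_covariance(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.specific_vars)

    def canonicalized(self) -> "FAStructure":
        """Rotate to the identifiable representative (same Sigma)."""
        lam = self.loadings
        if lam.shape[1] > 1:
            # LQ rotation: Delta' = Q R  =>  Delta R'^-1-free representative is R',
            # which leaves Delta Delta' = R'R unchanged and zeroes the upper triangle
            _, rmat = np.linalg.qr(lam.T)
            lam = rmat.T
        lam = lam.copy()
        for k in range(lam.shape[1]):
            col = lam[:, k]
            nz = np.flatnonzero(np.abs(col) > 1e-12)
            if nz.size and col[nz[0]] < 0:
                lam[:, k] = -col
        return FAStructure(lam, self.specific_vars.copy())


@dataclass
class VarianceComponents:
    """Per-site replicate and residual variances (the diagonals of Sigma_r, Sigma_e)."""

    rep_vars: np.ndarray
    res_vars: np.ndarray

    def __post_init__(self) -> None:
        self.rep_vars = np.asarray(self.rep_vars, dtype=float).ravel()
        self.res_vars = np.asarray(self.res_vars, dtype=float).ravel()
        if self.rep_vars.shape != self.res_vars.shape:
            raise ValueError("rep_vars and res_vars must have equal length")
        if (self.rep_vars < 0).any():
            raise ValueError("replicate variances must be >= 0")
        if (self.res_vars <= 0).any():
            raise ValueError("residual variances must be strictly positive")


@dataclass
class ModelSpec:
    """Which kernel terms enter the model, and the FA order per term.

    Named variants: FA -> [identity], FA+G -> [G_A], FA+GG -> [G_A#G_A],
    FA+G+GG -> [G_A, G_A#G_A].  Each term carries its own independent FA
    structure.
    """

    kernel_terms: list[GenomicKernel]
    fa_order: int | list[int] = 1
    include_reps: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.kernel_terms) <= 2:
            raise ValueError("1 or 2 kernel terms supported")
        if isinstance(self.fa_order, int):
            self.fa_order = [self.fa_order] * len(self.kernel_terms)
        if len(self.fa_order) != len(self.kernel_terms):
            raise ValueError("fa_order must match the number of kernel terms")
        if any(q < 1 for q in self.fa_order):
            raise ValueError("fa_order must be >= 1 per term")

    @property
    def n_terms(self) -> int:
        return len(self.kernel_terms)


MODEL_NAMES = ("FA", "FA+G", "FA+GG", "FA+G+GG")


def model_from_name(
    name: str,
    g_additive: GenomicKernel | None = None,
    g_epistatic: GenomicKernel | None = None,
    genotype_ids: list[str] | None = None,
    fa_order: int = 1,
    include_reps: bool = True,
) -> ModelSpec:
    """Build the spec for one of the four named model variants."""
    key = name.replace(" ", "").upper()
    if key == "FA":
        if genotype_ids is None:
            genotype_ids = (g_additive or g_epistatic).genotype_ids
        terms = [identity_kernel(genotype_ids)]
    elif key == "FA+G":
        terms = [g_additive]
    elif key == "FA+GG":
        terms = [g_epistatic]
    elif key == "FA+G+GG":
        terms = [g_additive, g_epistatic]
    else:
        raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")
    if any(t is None for t in terms):
        raise ValueError(f"model {name!r} requires the corresponding kernel(s)")
    return ModelSpec(kernel_terms=terms, fa_order=fa_order, include_reps=include_reps, name=name)


@dataclass
class FitOptions:
    max_iter: int = 600
    tol: float = 1.0  # convergence: max |projected gradient of -2l_R| below this
    n_restarts: int = 3
    seed: int = 0


@dataclass
class ModelFit:
    """Fitted model: fixed effects, FA structures, variances, BLUPs, REML log-likelihood."""

    fixed_site_effects: pd.Series
    fa_per_term: list[FAStructure]
    varcomp: VarianceComponents
    blup_values: dict
    reml_loglik: float
    converged: bool
    n_iter: int
    spec: ModelSpec
    genotype_ids: list[str]
    site_ids: list[str]
    grad_norm: float = np.nan

    def summary_frames(self) -> dict:
        """Serializable bundle: fixed effects, loadings, variances, BLUPs, metadata."""
        out = {"fixed_effects": self.fixed_site_effects.rename("estimate").to_frame()}
        for t, fa in enumerate(self.fa_per_term):
            lam = pd.DataFrame(
                fa.loadings, index=self.site_ids,
                columns=[f"factor{k + 1}" for k in range(fa.order_q)],
            )
            lam["specific_var"] = fa.specific_vars
            out[f"term{t + 1}_fa"] = lam
        out["varcomp"] = pd.DataFrame(
            {"rep_var": self.varcomp.rep_vars, "res_var": self.varcomp.res_vars},
            index=self.site_ids,
        )
        out["blup_total"] = self.blup_values["total"]
        out["meta"] = pd.DataFrame(
            {"value": [self.reml_loglik, self.converged, self.n_iter, self.grad_norm]},
            index=["reml_loglik", "converged", "n_iter", "grad_norm"],
        )
        return out


# ---------------------------------------------------------------------------
# internal problem representation


class _Problem:
    """Preprocessed design: record indices, observed cells, kernel blocks."""

    def __init__(self, data: PhenotypeTable, spec: ModelSpec):
        df = data.data
        if df.empty:
            raise ValueError("empty phenotype table")
        master = list(spec.kernel_terms[0].genotype_ids)
        pheno_g = set(df["genotype"])
        absent = sorted(pheno_g - set(master))
        if absent:
            raise ValueError(f"genotypes in phenotypes but absent from kernel: {absent[:5]}")
        self.genotypes = master
        self.sites = list(dict.fromkeys(df["site"]))
        self.kernels = [k.subset(master) for k in spec.kernel_terms]
        g_pos = {g: i for i, g in enumerate(master)}
        s_pos = {s: j for j, s in enumerate(self.sites)}
        self.y = df["yield"].to_numpy(dtype=float)
        self.N = len(self.y)
        self.site_idx = df["site"].map(s_pos).to_numpy()
        self.geno_idx = df["genotype"].map(g_pos).to_numpy()
        self.s = len(self.sites)
        per_site_counts = np.bincount(self.site_idx, minlength=self.s)
        if (per_site_counts < 2).any():
            low = [self.sites[j] for j in np.flatnonzero(per_site_counts < 2)]
            raise ValueError(f"site(s) with fewer than 2 records: {low}")
        for q in spec.fa_order:
            if q > self.s:
                raise ValueError(f"fa_order q={q} exceeds the number of sites ({self.s})")

        # observed cells
        cell_key = self.geno_idx.astype(np.int64) * self.s + self.site_idx
        uniq, self.cell_idx = np.unique(cell_key, return_inverse=True)
        self.n_cells = uniq.size
        self.cell_geno = (uniq // self.s).astype(int)
        self.cell_site = (uniq % self.s).astype(int)

        # replicate-within-site columns; a site with a single replicate level
        # has its replicate variance pinned to zero (no column)
        self.include_reps = spec.include_reps
        self.rep_col = np.full(self.N, -1)
        self.rep_col_site: np.ndarray = np.zeros(0, dtype=int)
        self.rep_free_sites: np.ndarray = np.zeros(0, dtype=int)
        if spec.include_reps:
            grp = df.groupby(["site", "rep"], sort=True)
            inv = grp.ngroup().to_numpy()
            levels = list(grp.groups.keys())
            lvl_site = np.array([s_pos[site] for site, _rep in levels])
            n_levels_per_site = np.bincount(lvl_site, minlength=self.s)
            keep = n_levels_per_site[lvl_site] >= 2
            remap = -np.ones(len(levels), dtype=int)
            remap[keep] = np.arange(keep.sum())
            self.rep_col = remap[inv]
            self.rep_col_site = lvl_site[keep]
            self.rep_free_sites = np.flatnonzero(n_levels_per_site >= 2)

        # kernel blocks among observed cells (theta-independent)
        self.K_cells = [k.matrix[np.ix_(self.cell_geno, self.cell_geno)] for k in self.kernels]
        # site-block indicator over cells, for gradient aggregation
        self.S_cells = np.zeros((self.n_cells, self.s))
        self.S_cells[np.arange(self.n_cells), self.cell_site] = 1.0
        self.X = np.zeros((self.N, self.s))
        self.X[np.arange(self.N), self.site_idx] = 1.0
        self.jitter = 1e-10 * max(float(np.var(self.y)), 1e-6)

    # ---- parameter packing -------------------------------------------------

    def param_layout(self, spec: ModelSpec):
        """Free-parameter slices: per-term loading masks, log D, log rep, log res."""
        layout = []
        pos = 0
        for t, q in enumerate(spec.fa_order):
            mask = np.ones((self.s, q), dtype=bool)
            for i in range(min(q, self.s)):
                mask[i, i + 1:] = False  # upper triangle of the first q rows fixed at 0
            n_l = int(mask.sum())
            d_free = self.s > 1  # single-site D is not identifiable next to Delta
            n_d = self.s if d_free else 0
            layout.append({"lmask": mask, "l_slice": slice(pos, pos + n_l),
                           "d_free": d_free, "d_slice": slice(pos + n_l, pos + n_l + n_d)})
            pos += n_l + n_d
        n_rep = len(self.rep_free_sites)
        rep_slice = slice(pos, pos + n_rep)
        pos += n_rep
        res_slice = slice(pos, pos + self.s)
        pos += self.s
        return layout, rep_slice, res_slice, pos

    def unpack(self, theta, spec: ModelSpec):
        layout, rep_slice, res_slice, _ = self.param_layout(spec)
        fas = []
        for t, lay in enumerate(layout):
            lam = np.zeros((self.s, spec.fa_order[t]))
            lam[lay["lmask"]] = theta[lay["l_slice"]]
            d = np.exp(theta[lay["d_slice"]]) if lay["d_free"] else np.full(self.s, _D_FLOOR)
            fas.append(FAStructure(lam, d))
        rep_vars = np.zeros(self.s)
        if rep_slice.stop > rep_slice.start:
            rep_vars[self.rep_free_sites] = np.exp(theta[rep_slice])
        res_vars = np.exp(theta[res_slice])
        return fas, VarianceComponents(rep_vars, res_vars)

    def pack(self, fas: list[FAStructure], vc: VarianceComponents, spec: ModelSpec):
        layout, rep_slice, res_slice, n = self.param_layout(spec)
        theta = np.zeros(n)
        for t, lay in enumerate(layout):
            theta[lay["l_slice"]] = fas[t].loadings[lay["lmask"]]
            if lay["d_free"]:
                theta[lay["d_slice"]] = np.log(np.maximum(fas[t].specific_vars, _D_FLOOR))
        if rep_slice.stop > rep_slice.start:
            theta[rep_slice] = np.log(np.maximum(vc.rep_vars[self.rep_free_sites], 1e-10))
        theta[res_slice] = np.log(np.maximum(vc.res_vars, 1e-10))
        return theta


def _neg2_reml(prob: _Problem, spec: ModelSpec, fas, vc, theta=None, want_grad=False):
    """-2 restricted log-likelihood (and optionally its gradient in theta)."""
    s, N = prob.s, prob.N
    sigmas = [fa.site_covariance() for fa in fas]
    gamma = np.zeros((prob.n_cells, prob.n_cells))
    for sig, kc in zip(sigmas, prob.K_cells):
        gamma += sig[np.ix_(prob.cell_site, prob.cell_site)] * kc
    gamma[np.diag_indices_from(gamma)] += prob.jitter
    l_gamma = np.linalg.cholesky(gamma)

    e_inv = 1.0 / vc.res_vars[prob.site_idx]
    # low-rank columns: genetic cell factor + replicate indicators
    u_cols = [l_gamma[prob.cell_idx, :]]
    n_rep_cols = int(prob.rep_col.max() + 1) if prob.rep_col.size and prob.rep_col.max() >= 0 else 0
    if n_rep_cols:
        z_rep = np.zeros((N, n_rep_cols))
        valid = prob.rep_col >= 0
        z_rep[np.flatnonzero(valid), prob.rep_col[valid]] = 1.0
        z_rep *= np.sqrt(vc.rep_vars[prob.rep_col_site])[None, :]
        u_cols.append(z_rep)
    u = np.hstack(u_cols)
    m = u.shape[1]
    eiu = e_inv[:, None] * u
    a = u.T @ eiu
    a[np.diag_indices_from(a)] += 1.0
    ca = cho_factor(a, lower=True, check_finite=False)

    def solve_v(x):
        return e_inv[..., None] * x - eiu @ cho_solve(ca, eiu.T @ x, check_finite=False) if x.ndim == 2 else \
            e_inv * x - eiu @ cho_solve(ca, eiu.T @ x, check_finite=False)

    logdet_v = float(np.sum(np.log(vc.res_vars[prob.site_idx]))) + \
        2.0 * float(np.sum(np.log(np.diag(ca[0]))))
    vix = solve_v(prob.X)
    w_x = prob.X.T @ vix
    cw = cho_factor(w_x, lower=True, check_finite=False)
    logdet_wx = 2.0 * float(np.sum(np.log(np.diag(cw[0]))))
    viy = solve_v(prob.y)
    bhat = cho_solve(cw, prob.X.T @ viy, check_finite=False)
    w = viy - vix @ bhat  # P y
    ypy = float(prob.y @ w)
    neg2 = (N - s) * _LOG2PI + logdet_v + logdet_wx + ypy
    if not want_grad:
        return neg2, None, (bhat, w, solve_v)

    layout, rep_slice, res_slice, n_par = prob.param_layout(spec)
    grad = np.zeros(n_par)

    # diag(P) for residual-variance gradients
    b_mat = cho_solve(ca, eiu.T, check_finite=False).T           # N x m
    diag_vi = e_inv - np.einsum("am,am->a", eiu, b_mat)
    txw = cho_solve(cw, vix.T, check_finite=False).T             # N x s
    diag_p = diag_vi - np.einsum("as,as->a", vix, txw)
    sum_diag_p = np.bincount(prob.site_idx, weights=diag_p, minlength=s)
    sum_w2 = np.bincount(prob.site_idx, weights=w * w, minlength=s)
    grad[res_slice] = vc.res_vars * (sum_diag_p - sum_w2)

    # replicate-variance gradients: trace/quadratic over the indicator columns
    if rep_slice.stop > rep_slice.start:
        z = np.zeros((N, n_rep_cols))
        valid = prob.rep_col >= 0
        z[np.flatnonzero(valid), prob.rep_col[valid]] = 1.0
        pz = solve_v(z) - vix @ cho_solve(cw, vix.T @ z, check_finite=False)
        ztpz = np.einsum("am,am->m", z, pz)
        ztw = z.T @ w
        per_col = ztpz - ztw**2
        per_site = np.bincount(prob.rep_col_site, weights=per_col, minlength=s)
        grad[rep_slice] = vc.rep_vars[prob.rep_free_sites] * per_site[prob.rep_free_sites]

    # genetic gradients through the cell-aggregated projection matrix
    c1 = np.zeros((prob.n_cells, m))
    np.add.at(c1, prob.cell_idx, eiu)
    p_cells = -c1 @ cho_solve(ca, c1.T, check_finite=False)
    d_c = np.bincount(prob.cell_idx, weights=e_inv, minlength=prob.n_cells)
    p_cells[np.diag_indices_from(p_cells)] += d_c
    vx_cells = np.zeros((prob.n_cells, s))
    np.add.at(vx_cells, prob.cell_idx, vix)
    p_cells -= vx_cells @ cho_solve(cw, vx_cells.T, check_finite=False)
    w_cells = np.bincount(prob.cell_idx, weights=w, minlength=prob.n_cells)
    for t, lay in enumerate(layout):
        kc = prob.K_cells[t]
        diff = p_cells * kc - (w_cells[:, None] * kc) * w_cells[None, :]
        f_minus_q = prob.S_cells.T @ diff @ prob.S_cells   # s x s site-block sums
        g_lam = 2.0 * f_minus_q @ fas[t].loadings
        grad[lay["l_slice"]] = g_lam[lay["lmask"]]
        if lay["d_free"]:
            grad[lay["d_slice"]] = fas[t].specific_vars * np.diag(f_minus_q)
    return neg2, grad, (bhat, w, solve_v)


def reml_loglik(
    fa_per_term: list[FAStructure] | FAStructure,
    varcomp: VarianceComponents,
    data: PhenotypeTable,
    spec: ModelSpec,
) -> float:
    """Restricted log-likelihood at an explicit parameter point (pure function)."""
    if isinstance(fa_per_term, FAStructure):
        fa_per_term = [fa_per_term]
    if len(fa_per_term) != spec.n_terms:
        raise ValueError("one FAStructure required per kernel term")
    prob = _Problem(data, spec)
    neg2, _, _ = _neg2_reml(prob, spec, fa_per_term, varcomp)
    return -0.5 * neg2


def _moment_init(prob: _Problem, spec: ModelSpec) -> tuple[list[FAStructure], VarianceComponents]:
    """Data-driven starting values from cell means and within-cell spread."""
    df = pd.DataFrame({"y": prob.y, "site": prob.site_idx, "cell": prob.cell_idx})
    within = df.groupby("cell")["y"].var(ddof=1)
    cell_site = pd.Series(prob.cell_site, index=np.arange(prob.n_cells))
    res0 = np.full(prob.s, np.nan)
    for j in range(prob.s):
        v = within[cell_site[within.index] == j].dropna()
        if len(v):
            res0[j] = max(float(v.mean()), 1e-6)
    site_var = df.groupby("site")["y"].var(ddof=1).reindex(range(prob.s)).to_numpy()
    res0 = np.where(np.isnan(res0), np.maximum(site_var, 1e-6) * 0.5, res0)
    rep0 = np.zeros(prob.s)
    rep0[prob.rep_free_sites] = 0.1 * res0[prob.rep_free_sites]

    means = df.groupby(["cell"])["y"].mean()
    wide = np.full((len(prob.genotypes), prob.s), np.nan)
    wide[prob.cell_geno[means.index], prob.cell_site[means.index]] = means.to_numpy()
    emp = pd.DataFrame(wide).cov(min_periods=2).to_numpy()
    emp = np.where(np.isnan(emp), 0.0, emp)
    reps_per_cell = np.bincount(prob.cell_idx, minlength=prob.n_cells)
    rbar = max(float(reps_per_cell.mean()), 1.0)
    emp[np.diag_indices_from(emp)] = np.maximum(np.diag(emp) - res0 / rbar, 1e-4)
    fas = []
    for t in range(spec.n_terms):
        kbar = max(float(np.mean(np.diag(prob.K_cells[t]))), 1e-8)
        target = emp / (spec.n_terms * kbar)
        evals, evecs = np.linalg.eigh((target + target.T) / 2.0)
        q = spec.fa_order[t]
        lam = np.zeros((prob.s, q))
        for k in range(q):
            lam[:, k] = evecs[:, -1 - k] * np.sqrt(max(evals[-1 - k], 1e-6))
        d0 = np.maximum(np.diag(target) - np.sum(lam**2, axis=1), 0.05 * np.maximum(np.diag(target), 1e-4))
        # zero the structurally fixed entries; keep Sigma roughly intact
        for i in range(min(q, prob.s)):
            lam[i, i + 1:] = 0.0
        fas.append(FAStructure(lam, np.maximum(d0, _D_FLOOR)))
    return fas, VarianceComponents(rep0, res0)


def fit(data: PhenotypeTable, spec: ModelSpec, opts: FitOptions | None = None) -> ModelFit:
    """Maximize the restricted likelihood and compute BLUPs for every genotype x site cell.

    Variances are log-parameterized (positivity), loadings constrained to the
    identifiable lower-triangular pattern; L-BFGS-B with analytic gradients
    and seeded multi-start.  Cells never observed still receive genuine
    predictions through the kernels.  Non-convergence yields a flagged fit,
    not an exception.
    """
    opts = opts or FitOptions()
    prob = _Problem(data, spec)
    # optimize on standardized phenotypes (unit variance) for uniform
    # parameter scaling; estimates are mapped back afterwards
    y_orig = prob.y.copy()
    y_mean = float(y_orig.mean())
    y_sd = float(y_orig.std())
    if y_sd <= 0:
        y_sd = 1.0
    prob.y = (y_orig - y_mean) / y_sd
    prob.jitter = 1e-10
    fas0, vc0 = _moment_init(prob, spec)
    theta0 = prob.pack(fas0, vc0, spec)
    layout, rep_slice, res_slice, n_par = prob.param_layout(spec)
    v_y = 1.0
    lo, hi = np.full(n_par, -np.inf), np.full(n_par, np.inf)
    lam_bound = 30.0 * np.sqrt(v_y)
    for lay in layout:
        lo[lay["l_slice"]], hi[lay["l_slice"]] = -lam_bound, lam_bound
        if lay["d_free"]:
            lo[lay["d_slice"]], hi[lay["d_slice"]] = np.log(_D_FLOOR), np.log(1e3 * v_y)
    if rep_slice.stop > rep_slice.start:
        lo[rep_slice], hi[rep_slice] = np.log(1e-10 * v_y), np.log(1e3 * v_y)
    lo[res_slice], hi[res_slice] = np.log(1e-8 * v_y), np.log(1e3 * v_y)
    bounds = list(zip(lo, hi))

    def objective(theta):
        fas, vc = prob.unpack(theta, spec)
        try:
            neg2, grad, _ = _neg2_reml(prob, spec, fas, vc, want_grad=True)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(theta)
        if not np.isfinite(neg2):
            return 1e12, np.zeros_like(theta)
        return neg2, grad

    rng = np.random.default_rng(opts.seed)
    best = None
    for restart in range(max(opts.n_restarts, 1)):
        start = theta0.copy()
        if restart > 0:
            start = start + rng.normal(scale=0.3, size=n_par)
        start = np.clip(start, lo, hi)
        res = minimize(objective, start, jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": opts.max_iter, "ftol": 1e-11, "gtol": 1e-5,
                                "maxcor": 25})
        if best is None or res.fun < best.fun:
            best = res
    theta = np.clip(best.x, lo, hi)
    # projected gradient at the optimum (scaled space): components pushing
    # past an active bound are ignored
    fas_s, vc_s = prob.unpack(theta, spec)
    _, grad_s, _ = _neg2_reml(prob, spec, fas_s, vc_s, want_grad=True)
    proj = grad_s.copy()
    proj[(theta <= lo + 1e-12) & (proj > 0)] = 0.0
    proj[(theta >= hi - 1e-12) & (proj < 0)] = 0.0
    grad_norm = float(np.max(np.abs(proj))) if proj.size else 0.0
    converged = bool(best.success) and grad_norm < opts.tol

    # back to the original phenotype scale: loadings x sd, variances x sd^2
    for lay in layout:
        theta[lay["l_slice"]] *= y_sd
        if lay["d_free"]:
            theta[lay["d_slice"]] += 2.0 * np.log(y_sd)
    if rep_slice.stop > rep_slice.start:
        theta[rep_slice] += 2.0 * np.log(y_sd)
    theta[res_slice] += 2.0 * np.log(y_sd)
    prob.y = y_orig
    prob.jitter = 1e-10 * max(y_sd**2, 1e-6)
    fas, vc = prob.unpack(theta, spec)
    neg2, _, (bhat, w, _) = _neg2_reml(prob, spec, fas, vc)

    # BLUPs: u_t = C_t Z' V^-1 (y - X bhat); w aggregated to cells, then
    # propagated through K_t per site and the site covariance Sigma_t
    w_cells = np.bincount(prob.cell_idx, weights=w, minlength=prob.n_cells)
    n_g = len(prob.genotypes)
    blups = {}
    total = np.zeros((n_g, prob.s))
    for t, fa in enumerate(fas):
        r_t = np.zeros((n_g, prob.s))
        kt = prob.kernels[t].matrix
        for j in range(prob.s):
            sel = prob.cell_site == j
            if sel.any():
                r_t[:, j] = kt[:, prob.cell_geno[sel]] @ w_cells[sel]
        blup_t = r_t @ fa.site_covariance()
        blups[f"term{t + 1}"] = pd.DataFrame(blup_t, index=prob.genotypes, columns=prob.sites)
        total += blup_t
    blups["total"] = pd.DataFrame(total, index=prob.genotypes, columns=prob.sites)

    fit_out = ModelFit(
        fixed_site_effects=pd.Series(bhat, index=prob.sites, name="site_effect"),
        fa_per_term=[fa.canonicalized() for fa in fas],
        varcomp=vc,
        blup_values=blups,
        reml_loglik=-0.5 * neg2,
        converged=converged,
        n_iter=int(best.nit),
        spec=spec,
        genotype_ids=prob.genotypes,
        site_ids=prob.sites,
        grad_norm=grad_norm,
    )
    if not converged:
        logger.warning("fit (%s): not converged (grad_norm=%.3g, n_iter=%d)",
                       spec.name or "model", grad_norm, fit_out.n_iter)
    return fit_out


def predict_genetic_values(fit: ModelFit, genotype_ids=None, site_ids=None) -> pd.DataFrame:
    """Total predicted genetic value (sum over kernel terms) for requested cells."""
    total = fit.blup_values["total"]
    genotype_ids = list(genotype_ids) if genotype_ids is not None else list(total.index)
    site_ids = list(site_ids) if site_ids is not None else list(total.columns)
    unknown_g = [g for g in genotype_ids if g not in total.index]
    unknown_s = [s for s in site_ids if s not in total.columns]
    if unknown_g or unknown_s:
        raise KeyError(f"unknown genotype(s) {unknown_g[:5]} or site(s) {unknown_s[:5]}")
    return total.loc[genotype_ids, site_ids]


def fitted_site_covariance(fit: ModelFit, term: int = 0) -> np.ndarray:
    """Sigma_t = Delta Delta' + D for the requested kernel term."""
    return fit.fa_per_term[term].site_covariance()
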