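"""CV1/CV2/CV3 cross-validation schemes and per-site Pearson prediction accuracy.

CV1 predicts brand-new genotypes: each fold's test genotypes are masked at
every site.  CV2 predicts genotypes evaluated at some sites but not others:
test genotypes are masked at a designated subset of sites and remain in
training at the rest.  CV3 is sparse testing at one focal site: a small
training set of genotypes is kept at the focal site and everyone else is
predicted there, with all genotypes observed at the other sites.  Accuracy
is the Pearson correlation, per site and fold, between predicted and
observed breeding values of the test set, averaged over folds.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .famm import FitOptions, ModelFit, fit as fit_model, model_from_name, predict_genetic_values
from .kernels import GenomicKernel, additive_kernel, epistatic_kernel, stabilize
from .markers import MarkerMatrix, allele_frequencies, impute_em, qc_filter
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["FoldPlan", "make_folds", "mask_records", "observed_values", "accuracy", "run_cv"]

SCHEMES = ("CV1", "CV2", "CV3")


@dataclass
class FoldPlan:
    """Masked (genotype, site) cells per fold, and the cells scored.

    ``masks[f]`` is the set of cells removed from training in fold ``f``;
    ``test_sets[f]`` (a subset of the mask) is scored.  Here the two
    coincide: every masked cell is scored.
    """

    scheme: str
    n_folds: int
    masks: list[set]
    test_sets: list[set]
    seed: int
    scheme_opts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mask, test in zip(self.masks, self.test_sets):
            if not test <= mask:
                raise ValueError("test cells must be a subset of masked cells")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": f, "genotype": g, "site": s}
            for f, mask in enumerate(self.masks)
            for (g, s) in sorted(mask)
        ]
        return pd.DataFrame(rows, columns=["fold", "genotype", "site"])


def make_folds(
    scheme: str,
    genotype_ids: list[str],
    site_ids: list[str],
    n_folds: int = 5,
    seed: int = 0,
    scheme_opts: dict | None = None,
) -> FoldPlan:
    """Construct the fold plan for one of the three schemes.

    Genotypes are shuffled once under ``seed`` and split into near-equal
    groups (sizes differ by at most 1).  CV2 masks each fold's test
    genotypes at ``scheme_opts["masked_sites"]`` if given, else at a rotating
    subset of ceil(s/2) sites per fold.  CV3 is a single fold with exactly
    ``scheme_opts["n_train_focal"]`` genotypes (default 20) kept at
    ``scheme_opts["focal_site"]`` (default: first site).
    """
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    opts = dict(scheme_opts or {})
    genotype_ids = [str(g) for g in genotype_ids]
    site_ids = [str(s) for s in site_ids]
    if n_folds < 2 and scheme != "CV3":
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(genotype_ids, dtype=object)[rng.permutation(len(genotype_ids))])

    if scheme == "CV3":
        focal = str(opts.get("focal_site", site_ids[0]))
        if focal not in site_ids:
            raise ValueError(f"focal_site {focal!r} not among sites")
        n_train = int(opts.get("n_train_focal", 20))
        if not 1 <= n_train < len(genotype_ids):
            raise ValueError("n_train_focal must be in [1, n_genotypes)")
        test_g = shuffled[n_train:]
        mask = {(g, focal) for g in test_g}
        return FoldPlan(scheme, 1, [mask], [set(mask)], seed,
                        {"focal_site": focal, "n_train_focal": n_train})

    groups = np.array_split(np.array(shuffled, dtype=object), n_folds)
    masks, tests = [], []
    if scheme == "CV1":
        for grp in groups:
            cells = {(g, s) for g in grp for s in site_ids}
            masks.append(cells)
            tests.append(set(cells))
        return FoldPlan(scheme, n_folds, masks, tests, seed, opts)

    # CV2
    fixed = opts.get("masked_sites")
    if fixed is not None:
        fixed = [str(s) for s in fixed]
        bad = [s for s in fixed if s not in site_ids]
        if bad:
            raise ValueError(f"masked_sites not among sites: {bad}")
        if len(fixed) == 0 or set(fixed) == set(site_ids):
            raise ValueError("CV2 masked_sites must be a proper nonempty subset of sites "
                             "(masking every site is CV1)")
    site_order = list(np.array(site_ids, dtype=object)[rng.permutation(len(site_ids))])
    k = math.ceil(len(site_ids) / 2)
    if k == len(site_ids):  # two-site trials: mask one
        k = len(site_ids) - 1
    for f, grp in enumerate(groups):
        if fixed is not None:
            masked_sites = fixed
        else:
            masked_sites = [site_order[(f + i) % len(site_order)] for i in range(k)]
        cells = {(g, s) for g in grp for s in masked_sites}
        masks.append(cells)
        tests.append(set(cells))
    return FoldPlan(scheme, n_folds, masks, tests, seed, {**opts, "n_masked_sites": k if fixed is None else len(fixed)})


def mask_records(data: PhenotypeTable, plan: FoldPlan, fold: int) -> PhenotypeTable:
    """Training records for a fold: every record whose cell is not masked."""
    mask = plan.masks[fold]
    if not mask:
        return PhenotypeTable(data.data.copy())
    keys = list(zip(data.data["genotype"], data.data["site"]))
    keep = np.array([k not in mask for k in keys])
    return data.subset(keep)


def observed_values(data: PhenotypeTable, center: bool = True) -> pd.DataFrame:
    """Genotype x site matrix of replicate means, site-centered by default.

    The "observed breeding value" of a cell is the mean of its replicate
    yields, centered by the mean over genotypes at that site (two-stage
    practice); ``center=False`` returns raw cell means.  Unobserved cells
    are NaN.
    """
    wide = data.cell_means().sort_index().sort_index(axis=1)
    if center:
        wide = wide - wide.mean(axis=0)
    return wide


def accuracy(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    cells: set,
    scheme: str = "",
    model_name: str = "",
    fold: int = 0,
    min_test: int = 3,
) -> pd.DataFrame:
    """Per-site Pearson correlation between predicted and observed test values.

    Only cells present in ``cells`` with both values non-missing enter; a
    site with fewer than ``min_test`` such cells, or with zero variance in
    either vector, is reported as missing (NaN) with a warning.
    """
    by_site: dict[str, list] = {}
    for g, s in cells:
        by_site.setdefault(s, []).append(g)
    rows = []
    for site, genos in sorted(by_site.items()):
        genos = [g for g in genos if g in predicted.index and g in observed.index]
        p = predicted.loc[genos, site].to_numpy(dtype=float)
        o = observed.loc[genos, site].to_numpy(dtype=float)
        ok = ~(np.isnan(p) | np.isnan(o))
        p, o = p[ok], o[ok]
        r = np.nan
        if p.size < min_test:
            warnings.warn(f"site {site}: only {p.size} test cells (<{min_test}); correlation omitted")
        elif np.std(p) == 0 or np.std(o) == 0:
            warnings.warn(f"site {site}: zero variance in predictions or observations")
        else:
            r = float(np.corrcoef(p, o)[0, 1])
        rows.append({"scheme": scheme, "model": model_name, "site": site,
                     "fold": fold, "pearson_r": r, "n_test": int(p.size)})
    return pd.DataFrame(rows, columns=["scheme", "model", "site", "fold", "pearson_r", "n_test"])


def summarize_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Per (scheme, model, site): mean and sd of the fold correlations."""
    grp = table.dropna(subset=["pearson_r"]).groupby(["scheme", "model", "site"])["pearson_r"]
    out = grp.agg(mean_r="mean", sd_r="std", n_folds="count").reset_index()
    return out


def _prepare_kernels(markers: MarkerMatrix, qc: bool, stabilization_eps: float,
                     imputation_rank: int | None) -> tuple[GenomicKernel, GenomicKernel]:
    m = markers
    if qc:
        m = qc_filter(m)
    if np.isnan(m.values).any():
        m = impute_em(m, rank=imputation_rank)
    freqs = allele_frequencies(m)
    g_a = stabilize(additive_kernel(m, freqs), stabilization_eps)
    g_aa = stabilize(epistatic_kernel(additive_kernel(m, freqs)), stabilization_eps)
    return g_a, g_aa


def run_cv(
    data: PhenotypeTable,
    markers: MarkerMatrix,
    scheme: str,
    model_names: list[str] = ("FA+G",),
    n_folds: int = 5,
    seed: int = 0,
    scheme_opts: dict | None = None,
    fit_opts: FitOptions | None = None,
    fa_order: int = 1,
    qc: bool = True,
    stabilization_eps: float = 1e-6,
    imputation_rank: int | None = None,
    truth: pd.DataFrame | None = None,
    center_observed: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cross-validation: kernels once, then per-fold fits and accuracies.

    Returns ``(table, summary)``: the tidy per-(scheme, model, site, fold)
    accuracy table and its per-site mean +/- sd across folds.  If ``truth``
    (a genotype x site matrix of true genetic values) is given, a second set
    of rows with model name suffixed ``:truth`` reports correlation against
    it.  Fully reproducible under ``seed``; a fold fit that does not converge
    is logged and its correlations excluded (reported NaN).
    """
    fit_opts = fit_opts or FitOptions(n_restarts=1)
    g_a, g_aa = _prepare_kernels(markers, qc, stabilization_eps, imputation_rank)
    plan = make_folds(scheme, data.genotypes, data.sites, n_folds=n_folds,
                      seed=seed, scheme_opts=scheme_opts)
    obs = observed_values(data, center=center_observed)
    tables = []
    n_excluded = 0
    for f in range(plan.n_folds):
        train = mask_records(data, plan, f)
        # leakage guard: no masked cell may appear in the training table
        train_cells = set(zip(train.data["genotype"], train.data["site"]))
        leaked = train_cells & plan.masks[f]
        if leaked:
            raise AssertionError(f"fold {f}: masked cells leaked into training: {sorted(leaked)[:3]}")
        for name in model_names:
            spec = model_from_name(name, g_additive=g_a, g_epistatic=g_aa,
                                   genotype_ids=g_a.genotype_ids, fa_order=fa_order)
            try:
                mfit = fit_model(train, spec, fit_opts)
            except Exception as exc:  # a model failing on a fold: run continues
                logger.warning("fold %d model %s failed: %s", f, name, exc)
                continue
            if not mfit.converged:
                n_excluded += 1
                logger.warning("fold %d model %s: not converged; excluded from averages", f, name)
                tbl = accuracy(predict_genetic_values(mfit), obs, plan.test_sets[f],
                               scheme=plan.scheme, model_name=name, fold=f)
                tbl["pearson_r"] = np.nan
                tables.append(tbl)
                continue
            pred = predict_genetic_values(mfit)
            tables.append(accuracy(pred, obs, plan.test_sets[f],
                                   scheme=plan.scheme, model_name=name, fold=f))
            if truth is not None:
                tables.append(accuracy(pred, truth - truth.mean(axis=0), plan.test_sets[f],
                                       scheme=plan.scheme, model_name=f"{name}:truth", fold=f))
    if n_excluded:
        logger.info("run_cv: %d non-converged fold fits excluded from averages", n_excluded)
    if not tables:
        raise RuntimeError("every model failed on every fold")
    table = pd.concat(tables, ignore_index=True)
    return table, summarize_accuracy(table)
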