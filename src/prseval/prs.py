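"""Polygenic-score training, scoring and the final prediction model.

The scores here are deliberately simple stand-ins for production PRS
methodology, sufficient to produce realistic cross-population miscalibration:

* ``prune_and_threshold`` — classic C+T: marginal GWAS, greedy correlation
  pruning in p-value order, p-value cutoff chosen to minimise MSPE on a
  validation set;
* ``ridge_trainer`` — closed-form ridge regression on standardized dosages,
  penalty chosen on the validation set (a second, non-sparse method so that
  method-ranking experiments have at least two competitors).

Scoring follows ``plink --score`` semantics: the per-individual score is the
weighted sum of effect-allele dosages, with missing dosages replaced by twice
the effect-allele frequency observed in the scored cohort, and with dosages
flipped (``2 - d``) for variants stored with the opposite allele orientation.

The final prediction model mirrors standard practice: a multivariable OLS
regression of the phenotype on the PRS, sex, age and the first ten genotype
principal components, fitted on the combined training and validation data.
The training-phenotype mean is retained on the model because the
training-referenced R^2 definition needs it at evaluation time.

:class:`PolygenicModel` / :class:`PolygenicResults` package the whole
procedure in the familiar model/results idiom: construct the model from data,
call ``fit()``, inspect ``params`` / ``bse`` / ``summary()``, then
``predict()`` on new cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import TruncatedSVD

from .synth import GenotypeMatrix

__all__ = [
    "WeightVector",
    "PredictionModel",
    "PCBasis",
    "filter_variants",
    "marginal_gwas",
    "prune_and_threshold",
    "ridge_trainer",
    "score",
    "fit_pc_basis",
    "fit_final_model",
    "predict",
    "PolygenicModel",
    "PolygenicResults",
]

DEFAULT_P_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.1)
DEFAULT_LAMBDA_GRID = (1.0, 10.0, 100.0, 1000.0, 10000.0)


@dataclass(frozen=True)
class WeightVector:
    """Per-variant effect-allele weights defining a polygenic score."""

    variant_ids: np.ndarray
    effect_alleles: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        vids = np.asarray(self.variant_ids)
        if len(set(map(str, vids))) != len(vids):
            raise ValueError("weight vector has duplicate variant ids")
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "variant_ids", vids)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass(frozen=True)
class PredictionModel:
    """PRS weights plus the fitted covariate regression.

    ``covariate_coefficients`` maps covariate name (sex, age, PC1..PCk) to its
    coefficient.  ``train_mean`` is the phenotype mean on the data the final
    regression was fitted on, retained for the training-referenced R^2.
    """

    weights: WeightVector
    intercept: float
    prs_coefficient: float
    covariate_coefficients: Mapping[str, float]
    train_mean: float

    def __post_init__(self):
        if not np.isfinite(self.train_mean):
            raise ValueError("train_mean must be finite")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariate_coefficients)


def filter_variants(
    g: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.001,
    individuals: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Variant QC: keep variants with call rate and MAF above thresholds.

    Both statistics are computed on ``individuals`` (typically the training
    set) and thresholds are inclusive.  Returns the filtered matrix and a
    per-variant report with the removal reason.  Raises if nothing survives.
    """
    for name, thr in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")
    call_rate = g.call_rate(individuals)
    with np.errstate(invalid="ignore"):
        maf = g.maf(individuals)
    maf = np.where(np.isnan(maf), 0.0, maf)  # fully missing variant: MAF 0

    low_cr = call_rate < min_call_rate
    low_maf = maf < min_maf
    keep = ~(low_cr | low_maf)
    reasons = []
    for cr_bad, maf_bad in zip(low_cr, low_maf):
        parts = []
        if cr_bad:
            parts.append(f"call_rate<{min_call_rate}")
        if maf_bad:
            parts.append(f"maf<{min_maf}")
        reasons.append(";".join(parts))
    report = pd.DataFrame(
        {
            "variant_id": g.variant_ids,
            "call_rate": call_rate,
            "maf": maf,
            "kept": keep,
            "reason": reasons,
        }
    )
    if not keep.any():
        raise ValueError(
            f"all {g.n_variants} variants removed by filters "
            f"(call rate >= {min_call_rate}, MAF >= {min_maf})"
        )
    return g.subset(variants=keep), report


def _imputed_dosages(
    g: GenotypeMatrix, individuals: np.ndarray | None = None
) -> np.ndarray:
    """Dosages with missing entries replaced by the per-variant mean."""
    d = g.dosages if individuals is None else g.dosages[individuals]
    if not np.isnan(d).any():
        return d.astype(float, copy=True)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    d = d.copy()
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    return d


def marginal_gwas(
    g: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    individuals: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant least-squares association scan.

    For each variant, fits ``phenotype ~ intercept + dosage (+ covariates)``
    by OLS on mean-imputed dosages (equivalently, by the
    Frisch-Waugh partialling-out of the covariates) and returns the slope,
    its standard error and the two-sided t-test p-value.  Variants
    monomorphic after imputation get NaN results with a note.
    """
    X = _imputed_dosages(g, individuals)
    y = np.asarray(phenotype, dtype=float)
    if individuals is not None:
        y = y[individuals]
    n = y.size
    if X.shape[0] != n:
        raise ValueError("phenotype length does not match genotype rows")

    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if individuals is not None and C.shape[0] != n:
            C = C[individuals]
        design = np.column_stack([np.ones(n), C])
    else:
        design = np.ones((n, 1))
    k = design.shape[1]  # intercept + covariates
    Q, _ = np.linalg.qr(design)
    yr = y - Q @ (Q.T @ y)
    Xr = X - Q @ (Q.T @ X)

    sxx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = Xr.T @ yr
    mono = sxx <= 1e-12
    dof = n - k - 1
    if dof <= 0:
        raise ValueError(f"not enough observations (n={n}) for the GWAS model")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, np.nan, sxy / np.where(mono, 1.0, sxx))
        sse = np.maximum(float(yr @ yr) - beta * sxy, 0.0)
        se = np.sqrt(sse / dof / np.where(mono, np.nan, sxx))
        tstat = beta / se
    p = np.where(
        np.isnan(tstat),
        np.nan,
        2.0 * stats.t.sf(np.abs(np.where(np.isnan(tstat), 0.0, tstat)), dof),
    )
    # exact fits: se == 0 -> t = inf -> p = 0
    p = np.where(np.isinf(tstat), 0.0, p)
    return pd.DataFrame(
        {
            "variant_id": g.variant_ids,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
            "note": np.where(mono, "monomorphic", ""),
        }
    )


def _prs_mspe_selector(
    prs_train: np.ndarray,
    y_train: np.ndarray,
    prs_val: np.ndarray,
    y_val: np.ndarray,
) -> float:
    """Validation MSPE of ``y ~ 1 + PRS`` fitted on the training split."""
    v = prs_train - prs_train.mean()
    denom = float(v @ v)
    if denom <= 0.0:
        return np.inf
    b = float(v @ (y_train - y_train.mean())) / denom
    a = float(y_train.mean() - b * prs_train.mean())
    resid = y_val - (a + b * prs_val)
    return float(resid @ resid) / y_val.size


def prune_and_threshold(
    gwas: pd.DataFrame,
    g_train: GenotypeMatrix,
    y_train: np.ndarray,
    g_val: GenotypeMatrix,
    y_val: np.ndarray,
    r2_prune: float = 0.5,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
) -> tuple[WeightVector, dict]:
    """Pruning-and-thresholding trainer.

    Variants are visited in (p-value, variant id) order; a variant is pruned
    when its squared dosage correlation with an already-kept variant exceeds
    ``r2_prune`` (computed on the training individuals).  The p-value cutoff
    is then chosen from ``p_grid`` to minimise the validation-set MSPE of a
    simple ``phenotype ~ PRS`` calibration fitted on the training set; ties
    prefer the smaller cutoff.  Deterministic for fixed input order.
    """
    grid = sorted(set(float(t) for t in p_grid))
    if not grid:
        raise ValueError("p_grid must not be empty")
    cand = gwas[np.isfinite(gwas["p"]) & (gwas["p"] <= max(grid))]
    if cand.empty:
        raise ValueError("no variant passes any p-value threshold in the grid")
    cand = cand.sort_values(["p", "variant_id"], kind="mergesort")

    vid_to_col = {v: j for j, v in enumerate(g_train.variant_ids)}
    cols = np.array([vid_to_col[v] for v in cand["variant_id"]])

    if r2_prune >= 1.0:
        kept_mask = np.ones(len(cand), dtype=bool)
    else:
        Z = _imputed_dosages(g_train)[:, cols]
        Z = Z - Z.mean(axis=0)
        norms = np.sqrt(np.einsum("ij,ij->j", Z, Z))
        norms[norms == 0] = 1.0
        Z = Z / norms
        kept_mask = np.zeros(len(cand), dtype=bool)
        kept_cols: list[int] = []
        K = np.empty_like(Z)
        for j in range(len(cand)):
            if kept_cols:
                corr = K[:, : len(kept_cols)].T @ Z[:, j]
                if np.max(corr**2) > r2_prune:
                    continue
            K[:, len(kept_cols)] = Z[:, j]
            kept_cols.append(j)
            kept_mask[j] = True

    kept = cand[kept_mask]
    kept_cols_idx = cols[kept_mask]
    w_all = kept["beta"].to_numpy()
    p_all = kept["p"].to_numpy()

    D_train = _imputed_dosages(g_train)[:, kept_cols_idx]
    D_val = _imputed_dosages(g_val)[
        :, [vid_to_col_val(g_val, v) for v in kept["variant_id"]]
    ]

    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    mspe_by_threshold: dict[float, float] = {}
    best_t, best_mspe = None, np.inf
    for t in grid:
        sel = p_all <= t
        if not sel.any():
            continue
        prs_tr = D_train[:, sel] @ w_all[sel]
        prs_va = D_val[:, sel] @ w_all[sel]
        m = _prs_mspe_selector(prs_tr, y_train, prs_va, y_val)
        mspe_by_threshold[t] = m
        if m < best_mspe:
            best_mspe, best_t = m, t
    if best_t is None:
        raise ValueError("no variant passes any p-value threshold in the grid")

    sel = p_all <= best_t
    weights = WeightVector(
        variant_ids=kept["variant_id"].to_numpy()[sel],
        effect_alleles=g_train.effect_alleles[kept_cols_idx[sel]],
        weights=w_all[sel],
    )
    report = {
        "method": "pt",
        "selected_p_threshold": best_t,
        "validation_mspe": mspe_by_threshold,
        "n_candidates": int(len(cand)),
        "n_pruned": int(len(cand) - kept_mask.sum()),
        "n_selected": int(sel.sum()),
    }
    return weights, report


def vid_to_col_val(g: GenotypeMatrix, vid: str) -> int:
    cache = getattr(g, "_vid_cache", None)
    if cache is None:
        cache = {v: j for j, v in enumerate(g.variant_ids)}
        object.__setattr__(g, "_vid_cache", cache)
    if vid not in cache:
        raise ValueError(f"variant {vid!r} absent from genotype matrix")
    return cache[vid]


def ridge_trainer(
    g_train: GenotypeMatrix,
    y_train: np.ndarray,
    g_val: GenotypeMatrix,
    y_val: np.ndarray,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> tuple[WeightVector, dict]:
    """Closed-form ridge regression on standardized dosages.

    Solves ``min ||y_c - Z w||^2 + lambda ||w||^2`` via one SVD of the
    standardized training dosage matrix, maps the weights back to per-allele
    scale, and picks ``lambda`` by validation MSPE (same selection criterion
    as the C+T trainer).  ``lambda = 0`` on a rank-deficient design is
    recorded as singular in the report and skipped.
    """
    grid = sorted(set(float(l) for l in lambda_grid))
    if not grid:
        raise ValueError("lambda_grid must not be empty")
    if any(l < 0 for l in grid):
        raise ValueError("ridge penalties must be nonnegative")

    X = _imputed_dosages(g_train)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all training variants are monomorphic")
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    yc = y_train - y_train.mean()

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    uy = U.T @ yc
    rank_deficient = s.min() < 1e-10 * s.max() or Z.shape[0] < Z.shape[1]

    D_val = _imputed_dosages(g_val)[
        :, [vid_to_col_val(g_val, v) for v in g_train.variant_ids[keep]]
    ]
    mspe_by_lambda: dict[float, float] = {}
    singular: list[float] = []
    best_l, best_mspe, best_w = None, np.inf, None
    for lam in grid:
        if lam == 0.0 and rank_deficient:
            singular.append(lam)
            continue
        shrink = s / (s**2 + lam)
        w_std = Vt.T @ (shrink * uy)
        w_allele = w_std / sd[keep]
        prs_tr = Z @ w_std
        prs_va = D_val @ w_allele
        m = _prs_mspe_selector(prs_tr, y_train, prs_va, y_val)
        mspe_by_lambda[lam] = m
        if m < best_mspe:
            best_mspe, best_l, best_w = m, lam, w_allele
    if best_w is None:
        raise ValueError(
            f"no usable ridge penalty: lambdas {singular} are singular "
            "(rank-deficient design at lambda = 0)"
        )
    weights = WeightVector(
        variant_ids=g_train.variant_ids[keep],
        effect_alleles=g_train.effect_alleles[keep],
        weights=best_w,
    )
    report = {
        "method": "ridge",
        "selected_lambda": best_l,
        "validation_mspe": mspe_by_lambda,
        "singular_lambdas": singular,
        "n_selected": int(keep.sum()),
    }
    return weights, report


def _oriented_dosages(g: GenotypeMatrix, w: WeightVector) -> np.ndarray:
    """Dosages of the weight vector's variants, counted on its effect alleles.

    Missing dosages are replaced by twice the effect-allele frequency in the
    scored cohort (plink --score mean-imputation semantics).
    """
    cols, flip = [], []
    for vid, allele in zip(w.variant_ids, w.effect_alleles):
        j = vid_to_col_val(g, str(vid))
        if str(allele) == str(g.effect_alleles[j]):
            flip.append(False)
        elif str(allele) == str(g.other_alleles[j]):
            flip.append(True)
        else:
            raise ValueError(
                f"variant {vid!r}: weight-file allele {allele!r} matches neither "
                f"stored allele ({g.effect_alleles[j]!r}/{g.other_alleles[j]!r})"
            )
        cols.append(j)
    D = g.dosages[:, cols].copy()
    flip = np.asarray(flip)
    if flip.any():
        D[:, flip] = 2.0 - D[:, flip]
    missing = np.isnan(D)
    if missing.any():
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(D, axis=0) / 2.0
        if np.isnan(freq).any():
            bad = np.asarray(w.variant_ids)[np.isnan(freq)]
            raise ValueError(
                f"cannot impute: variants entirely missing in scored cohort: "
                f"{list(bad[:5])}"
            )
        idx = np.where(missing)
        D[idx] = 2.0 * freq[idx[1]]
    return D


def score(g: GenotypeMatrix, w: WeightVector) -> np.ndarray:
    """Per-individual PRS: weighted sum of effect-allele dosages.

    Implements plink --score semantics (allele orientation checks, cohort
    frequency mean-imputation of missing dosages).
    """
    if len(w) == 0:
        return np.zeros(g.n_samples)
    return _oriented_dosages(g, w) @ w.weights


@dataclass(frozen=True)
class PCBasis:
    """Genotype principal-component basis fitted on the training cohort.

    Standardization uses training effect-allele frequencies:
    ``z = (d - 2 p) / sqrt(2 p (1 - p))`` with missing dosages set to ``2 p``.
    Out-of-training individuals are *projected* onto this basis — nothing is
    refitted on target populations.
    """

    components: np.ndarray  # k x m
    freqs: np.ndarray
    variant_ids: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, g: GenotypeMatrix) -> np.ndarray:
        if not np.array_equal(g.variant_ids, self.variant_ids):
            raise ValueError("genotype variants do not match the PC basis")
        Z = _standardize_by_freq(g.dosages, self.freqs)
        return Z @ self.components.T


def _standardize_by_freq(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    denom = np.sqrt(2.0 * freqs * (1.0 - freqs))
    ok = denom > 0
    Z = dosages - 2.0 * freqs
    Z = np.where(np.isnan(Z), 0.0, Z)  # missing -> standardized 0 (mean)
    Z[:, ~ok] = 0.0
    Z[:, ok] = Z[:, ok] / denom[ok]
    return Z


def fit_pc_basis(
    g: GenotypeMatrix,
    individuals: np.ndarray | None = None,
    n_components: int = 10,
    random_state: int = 0,
) -> PCBasis:
    """Truncated SVD of the frequency-standardized training dosage matrix."""
    freqs = g.effect_allele_frequency(individuals)
    freqs = np.where(np.isnan(freqs), 0.5, freqs)
    d = g.dosages if individuals is None else g.dosages[individuals]
    Z = _standardize_by_freq(d, freqs)
    k = min(n_components, min(Z.shape) - 1)
    svd = TruncatedSVD(n_components=k, random_state=random_state)
    svd.fit(Z)
    comp = svd.components_
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(comp.shape[0]):
        j = np.argmax(np.abs(comp[i]))
        if comp[i, j] < 0:
            comp[i] = -comp[i]
    return PCBasis(components=comp, freqs=freqs, variant_ids=g.variant_ids.copy())


def fit_final_model(
    prs: np.ndarray,
    covariates: pd.DataFrame,
    phenotype: np.ndarray,
    weights: WeightVector,
    train_mean: float | None = None,
):
    """OLS of phenotype on PRS + covariates; the deployable prediction model.

    Returns ``(PredictionModel, statsmodels RegressionResults)``.  The stored
    ``train_mean`` defaults to the mean of the fitted phenotype (the combined
    training + validation data in the standard workflow).  Rank-deficient
    designs are rejected with the offending columns named.
    """
    y = np.asarray(phenotype, dtype=float)
    design = pd.DataFrame({"const": 1.0, "PRS": np.asarray(prs, dtype=float)})
    design = pd.concat([design, covariates.reset_index(drop=True)], axis=1)
    X = design.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("final model requires complete cases (no NaN/inf)")

    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * diag.max()
    deficient = [design.columns[i] for i in np.where(diag <= tol)[0]]
    if deficient:
        raise ValueError(f"rank-deficient design; offending columns: {deficient}")

    res = sm.OLS(y, design).fit()
    params = res.params
    model = PredictionModel(
        weights=weights,
        intercept=float(params["const"]),
        prs_coefficient=float(params["PRS"]),
        covariate_coefficients={
            c: float(params[c]) for c in covariates.columns
        },
        train_mean=float(np.mean(y)) if train_mean is None else float(train_mean),
    )
    return model, res


def predict(
    model: PredictionModel, g: GenotypeMatrix, covariates: pd.DataFrame
) -> np.ndarray:
    """Apply a fitted model to new individuals (no refitting of any kind)."""
    missing = [c for c in model.covariate_names if c not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    prs = score(g, model.weights)
    yhat = model.intercept + model.prs_coefficient * prs
    for name, coef in model.covariate_coefficients.items():
        yhat = yhat + coef * covariates[name].to_numpy(dtype=float)
    return yhat


class PolygenicModel:
    """End-to-end polygenic prediction model, statsmodels style.

    Construct from a genotype matrix and an aligned phenotype table (columns
    ``phenotype``, ``sex``, ``age``), with explicit training and validation
    row indices; ``fit()`` runs variant QC, PC computation, GWAS, weight
    training and the final covariate regression, and returns a
    :class:`PolygenicResults`.

    Parameters
    ----------
    method : ``"pt"`` (pruning + thresholding) or ``"ridge"``.
    gwas_covariates : ``"none"`` or ``"pcs"`` — whether the association scan
        adjusts for the genotype PCs (both modes are legitimate; neither is
        privileged).
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        table: pd.DataFrame,
        train_idx: np.ndarray,
        val_idx: np.ndarray,
        method: str = "pt",
        n_pcs: int = 10,
        min_call_rate: float = 0.90,
        min_maf: float = 0.001,
        p_grid: Sequence[float] = DEFAULT_P_GRID,
        r2_prune: float = 0.5,
        lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
        gwas_covariates: str = "none",
        seed: int = 0,
    ):
        if method not in ("pt", "ridge"):
            raise ValueError(f"unknown method {method!r}; use 'pt' or 'ridge'")
        if gwas_covariates not in ("none", "pcs"):
            raise ValueError("gwas_covariates must be 'none' or 'pcs'")
        for col in ("phenotype", "sex", "age"):
            if col not in table.columns:
                raise ValueError(f"phenotype table lacks column {col!r}")
        if len(table) != genotypes.n_samples:
            raise ValueError("phenotype table and genotypes differ in length")
        train_idx = np.asarray(train_idx)
        val_idx = np.asarray(val_idx)
        if np.intersect1d(train_idx, val_idx).size:
            raise ValueError("training and validation indices overlap")
        self.genotypes = genotypes
        self.table = table.reset_index(drop=True)
        self.train_idx = train_idx
        self.val_idx = val_idx
        self.method = method
        self.n_pcs = n_pcs
        self.min_call_rate = min_call_rate
        self.min_maf = min_maf
        self.p_grid = tuple(p_grid)
        self.r2_prune = r2_prune
        self.lambda_grid = tuple(lambda_grid)
        self.gwas_covariates = gwas_covariates
        self.seed = seed

    def fit(self) -> "PolygenicResults":
        g, filter_report = filter_variants(
            self.genotypes, self.min_call_rate, self.min_maf, self.train_idx
        )
        basis = fit_pc_basis(
            g, self.train_idx, n_components=self.n_pcs, random_state=self.seed
        )
        y = self.table["phenotype"].to_numpy(dtype=float)

        g_train = g.subset(individuals=self.train_idx)
        g_val = g.subset(individuals=self.val_idx)
        y_train, y_val = y[self.train_idx], y[self.val_idx]

        gw_cov = None
        if self.gwas_covariates == "pcs":
            gw_cov = basis.project(g_train)
        gwas = marginal_gwas(g_train, y_train, covariates=gw_cov)

        if self.method == "pt":
            weights, selection = prune_and_threshold(
                gwas, g_train, y_train, g_val, y_val,
                r2_prune=self.r2_prune, p_grid=self.p_grid,
            )
        else:
            weights, selection = ridge_trainer(
                g_train, y_train, g_val, y_val, lambda_grid=self.lambda_grid
            )

        tv_idx = np.concatenate([self.train_idx, self.val_idx])
        g_tv = g.subset(individuals=tv_idx)
        covars = self._covariate_frame(g_tv, self.table.iloc[tv_idx], basis)
        prs_tv = score(g_tv, weights)
        model, res = fit_final_model(prs_tv, covars, y[tv_idx], weights)
        return PolygenicResults(
            model=model,
            sm_results=res,
            pc_basis=basis,
            filtered_genotypes=g,
            filter_report=filter_report,
            gwas=gwas,
            selection_report=selection,
            method=self.method,
            spec=self,
        )

    @staticmethod
    def _covariate_frame(
        g: GenotypeMatrix, table: pd.DataFrame, basis: PCBasis
    ) -> pd.DataFrame:
        pcs = basis.project(g)
        frame = pd.DataFrame(
            {
                "sex": table["sex"].to_numpy(dtype=float),
                "age": table["age"].to_numpy(dtype=float),
            }
        )
        for i in range(basis.n_components):
            frame[f"PC{i + 1}"] = pcs[:, i]
        return frame


class PolygenicResults:
    """Fitted polygenic prediction model with estimates and diagnostics.

    ``params`` / ``bse`` expose the final regression coefficients and their
    standard errors; ``prediction_model`` is the deployable
    :class:`PredictionModel`; ``predict`` applies it to a new cohort.
    """

    def __init__(
        self, model, sm_results, pc_basis, filtered_genotypes, filter_report,
        gwas, selection_report, method, spec,
    ):
        self.prediction_model: PredictionModel = model
        self.sm_results = sm_results
        self.pc_basis: PCBasis = pc_basis
        self.filtered_genotypes: GenotypeMatrix = filtered_genotypes
        self.filter_report = filter_report
        self.gwas = gwas
        self.selection_report = selection_report
        self.method = method
        self._spec = spec

    @property
    def params(self) -> pd.Series:
        return self.sm_results.params

    @property
    def bse(self) -> pd.Series:
        return self.sm_results.bse

    @property
    def train_mean(self) -> float:
        return self.prediction_model.train_mean

    @property
    def weights(self) -> WeightVector:
        return self.prediction_model.weights

    def align(self, genotypes: GenotypeMatrix) -> GenotypeMatrix:
        """Restrict a cohort to the QC-surviving variant set."""
        if np.array_equal(genotypes.variant_ids, self.pc_basis.variant_ids):
            return genotypes
        keep = np.isin(genotypes.variant_ids, self.pc_basis.variant_ids)
        g = genotypes.subset(variants=keep)
        if not np.array_equal(g.variant_ids, self.pc_basis.variant_ids):
            raise ValueError("cohort lacks variants required by the model")
        return g

    def predict(self, genotypes: GenotypeMatrix, table: pd.DataFrame) -> np.ndarray:
        """Predicted phenotypes for a new cohort (scores + linear predictor)."""
        g = self.align(genotypes)
        covars = PolygenicModel._covariate_frame(g, table, self.pc_basis)
        return predict(self.prediction_model, g, covars)

    def summary(self):
        """Coefficient table of the final regression plus PRS metadata."""
        summ = self.sm_results.summary()
        summ.add_extra_txt(
            [
                f"PRS method: {self.method}, "
                f"{len(self.weights)} variants with nonzero weight",
                f"training-phenotype mean retained for R2_1A: "
                f"{self.train_mean:.6g}",
            ]
        )
        return summ

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PolygenicResults method={self.method!r} "
            f"n_weights={len(self.weights)} train_mean={self.train_mean:.4g}>"
        )
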