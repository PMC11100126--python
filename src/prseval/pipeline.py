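"""Study orchestration: simulate, train, predict, evaluate per population.

This module reproduces the evaluation structure of a cross-ancestry PRS
portability study on synthetic cohorts: per-(population, method) metric
tables covering all three test-set R^2 definitions, calibration slopes and
intercepts from regressing observed on predicted values, residual-summary
tables, scatter/density diagnostics, and method rankings under each metric
with conflict detection.

The headline phenomenon the default scenario reproduces: on an out-of-target
population a model can retain substantial squared correlation (r^2 > 0) while
its test-referenced MSPE-based R^2 goes negative — pure miscalibration that
correlation cannot see.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as mt
from .ancestry import ReferenceCenters, assign_clusters
from .prs import PolygenicModel, PolygenicResults, fit_pc_basis
from .synth import ArchitectureSpec, GenotypeMatrix, PopulationSpec, simulate_cohort

__all__ = [
    "EvaluationResult",
    "RankingTable",
    "StudyConfig",
    "StudyResult",
    "evaluation_from_pairs",
    "evaluate_by_population",
    "rank_methods",
    "report",
    "run_study",
    "default_scenario",
]

#: metrics where larger is better / smaller is better, used for rankings
RANKED_METRICS = ("r_squared", "r2_1a", "r2_1b", "mspe")


@dataclass(frozen=True)
class EvaluationResult:
    """Metric set and calibration diagnostics for one (population, method).

    ``calibration_slope``/``calibration_intercept`` are the OLS coefficients
    of observed regressed on predicted values within the population (a
    perfectly calibrated model has slope 1, intercept 0).  Residuals follow
    the observed - predicted sign convention.  The raw pairs are retained for
    plotting.
    """

    population: str
    method: str
    metrics: mt.MetricSet
    calibration_intercept: float
    calibration_slope: float
    residual_mean: float
    residual_q25: float
    residual_median: float
    residual_q75: float
    observed: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)

    def row(self) -> dict:
        d = {"population": self.population, "method": self.method}
        d.update(self.metrics.as_dict())
        d.update(
            calibration_intercept=self.calibration_intercept,
            calibration_slope=self.calibration_slope,
            residual_mean=self.residual_mean,
            residual_q25=self.residual_q25,
            residual_median=self.residual_median,
            residual_q75=self.residual_q75,
        )
        return d


def evaluation_from_pairs(
    population: str,
    method: str,
    observed: np.ndarray,
    predicted: np.ndarray,
    train_mean: float | None = None,
) -> EvaluationResult:
    """Build an :class:`EvaluationResult` from raw (observed, predicted) pairs."""
    ev = mt.EvalVectors(observed, predicted)
    ref = mt.ReferenceMeans.for_test_data(ev, train_mean=train_mean)
    mset = mt.evaluate(ev, ref)

    pc = ev.predicted - ev.predicted.mean()
    spp = float(pc @ pc)
    if spp > 0:
        slope = float(pc @ (ev.observed - ev.observed.mean())) / spp
        intercept = float(ev.observed.mean() - slope * ev.predicted.mean())
    else:
        warnings.warn(
            f"{population}/{method}: constant predictions, calibration "
            "regression undefined",
            stacklevel=2,
        )
        slope, intercept = np.nan, np.nan

    resid = ev.residuals
    q25, q50, q75 = np.quantile(resid, [0.25, 0.5, 0.75])
    return EvaluationResult(
        population=population,
        method=method,
        metrics=mset,
        calibration_intercept=intercept,
        calibration_slope=slope,
        residual_mean=float(resid.mean()),
        residual_q25=float(q25),
        residual_median=float(q50),
        residual_q75=float(q75),
        observed=ev.observed,
        predicted=ev.predicted,
    )


def evaluate_by_population(
    models: Mapping[str, PolygenicResults],
    genotypes: GenotypeMatrix,
    table: pd.DataFrame,
    populations: np.ndarray | None = None,
) -> list[EvaluationResult]:
    """One :class:`EvaluationResult` per (population, method) on test data.

    ``table`` must align row-wise with ``genotypes`` and contain ``phenotype``,
    ``sex`` and ``age``.  Each model's stored training-phenotype mean feeds
    the training-referenced R^2; nothing is refitted on test data.
    Populations with fewer than two individuals are skipped with a warning.
    """
    if populations is None:
        populations = genotypes.population_labels
    populations = np.asarray(populations)
    y = table["phenotype"].to_numpy(dtype=float)

    results: list[EvaluationResult] = []
    for pop in pd.unique(populations):
        sel = populations == pop
        if sel.sum() < 2:
            warnings.warn(
                f"population {pop!r} has fewer than 2 test individuals; skipped",
                stacklevel=2,
            )
            continue
        g_pop = genotypes.subset(individuals=sel)
        t_pop = table.loc[sel].reset_index(drop=True)
        for method, res in models.items():
            yhat = res.predict(g_pop, t_pop)
            results.append(
                evaluation_from_pairs(
                    str(pop), method, y[sel], yhat, train_mean=res.train_mean
                )
            )
    return results


@dataclass(frozen=True)
class RankingTable:
    """Per-population method orderings under each metric.

    ``orderings[(population, metric)]`` lists methods best-first (descending
    for the R^2-type metrics, ascending for MSPE).  ``conflict_flags`` lists
    populations where the r^2 ordering differs from the R2_1B ordering — the
    discrimination-vs-calibration ranking conflict.  ``incomplete`` marks
    (population, metric) pairs where some method's metric was absent.
    """

    orderings: Mapping[tuple[str, str], tuple[str, ...]]
    conflict_flags: tuple[str, ...]
    incomplete: tuple[tuple[str, str], ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pop, metric), order in sorted(self.orderings.items()):
            rows.append(
                {
                    "population": pop,
                    "metric": metric,
                    "ranking": " > ".join(order),
                    "conflict": pop in self.conflict_flags,
                    "complete": (pop, metric) not in self.incomplete,
                }
            )
        return pd.DataFrame(rows)


def rank_methods(results: Sequence[EvaluationResult]) -> RankingTable:
    """Rank methods per population under each metric; flag conflicts.

    The orderings under R2_1A, R2_1B and (negated) MSPE coincide whenever the
    methods are evaluated on the same test pairs and share a training mean —
    both R^2 variants are monotone rescalings of the MSPE; the r^2 ordering
    can genuinely disagree with them.
    """
    by_pop: dict[str, list[EvaluationResult]] = {}
    for r in results:
        by_pop.setdefault(r.population, []).append(r)

    orderings: dict[tuple[str, str], tuple[str, ...]] = {}
    incomplete: list[tuple[str, str]] = []
    conflicts: list[str] = []
    for pop, rs in by_pop.items():
        methods = [r.method for r in rs]
        if len(set(methods)) != len(methods):
            raise ValueError(f"duplicate method entries for population {pop!r}")
        if len(methods) < 2:
            raise ValueError("ranking requires at least two methods")
        for metric in RANKED_METRICS:
            values = {r.method: r.metrics.as_dict()[metric] for r in rs}
            if any(v is None for v in values.values()):
                incomplete.append((pop, metric))
                present = {m: v for m, v in values.items() if v is not None}
            else:
                present = values
            sign = 1.0 if metric == "mspe" else -1.0
            order = tuple(sorted(present, key=lambda m: (sign * present[m], m)))
            orderings[(pop, metric)] = order
        o_r2 = orderings.get((pop, "r_squared"))
        o_b = orderings.get((pop, "r2_1b"))
        if o_r2 and o_b and o_r2 != o_b:
            conflicts.append(pop)
    return RankingTable(
        orderings=orderings,
        conflict_flags=tuple(sorted(conflicts)),
        incomplete=tuple(incomplete),
    )


_SUMMARY_NOTE = """\
R-squared definitions used in this report:
  r_squared : squared Pearson correlation between observed and predicted
              phenotypes (discrimination only, in [0, 1]).
  r2_1a     : 1 - SSE / sum (y - mean_train)^2, the MSPE relative to the
              intercept model fitted on the TRAINING data (can be negative).
  r2_1b     : 1 - SSE / sum (y - mean_test)^2, the MSPE relative to the
              intercept model fitted on the TEST data (can be negative).
Rankings under r2_1a, r2_1b and MSPE agree by construction on shared test
data; the r_squared ranking may conflict with them (conflict column).
Always state which definition a reported R-squared refers to.
"""


def report(
    results: Sequence[EvaluationResult],
    rankings: RankingTable | None,
    out_dir,
    seed: int | None = None,
    make_plots: bool = True,
    float_format: str = "%.6g",
) -> list[Path]:
    """Write metric/ranking/residual tables, plots and a run log.

    TSV outputs are deterministic byte-for-byte for identical inputs.  With
    empty ``results`` a header-only metric table is written with a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = [r.row() for r in results]
    columns = list(
        rows[0].keys()
        if rows
        else EvaluationResult(
            "p", "m", mt.MetricSet(1, 1, 1, 1, 0, 0, 2),
            0, 1, 0, 0, 0, 0, np.zeros(2), np.zeros(2),
        ).row().keys()
    )
    metrics_path = out / "metrics.tsv"
    pd.DataFrame(rows, columns=columns).to_csv(
        metrics_path, sep="\t", index=False, float_format=float_format
    )
    written.append(metrics_path)

    resid_cols = [
        "population", "method", "residual_mean", "residual_q25",
        "residual_median", "residual_q75",
    ]
    resid_path = out / "residuals.tsv"
    pd.DataFrame(
        [{k: row[k] for k in resid_cols} for row in rows], columns=resid_cols
    ).to_csv(resid_path, sep="\t", index=False, float_format=float_format)
    written.append(resid_path)

    if rankings is not None:
        rank_path = out / "rankings.tsv"
        rankings.to_frame().to_csv(rank_path, sep="\t", index=False)
        written.append(rank_path)

    summary_path = out / "summary.txt"
    summary_path.write_text(_SUMMARY_NOTE)
    written.append(summary_path)

    log_path = out / "run_log.txt"
    log_path.write_text(
        f"seed: {seed if seed is not None else 'not recorded'}\n"
        f"n_results: {len(results)}\n"
    )
    written.append(log_path)

    if not results:
        warnings.warn("no evaluation results; header-only tables written",
                      stacklevel=2)
        return written

    if make_plots:
        written.extend(_plots(results, out))
    return written


def _plots(results: Sequence[EvaluationResult], out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    pops = sorted({r.population for r in results})
    for pop in pops:
        rs = [r for r in results if r.population == pop]
        fig, axes = plt.subplots(
            2, len(rs), figsize=(4 * len(rs), 7), squeeze=False
        )
        for j, r in enumerate(rs):
            ax = axes[0][j]
            ax.scatter(r.predicted, r.observed, s=4, alpha=0.4)
            lims = [
                min(r.predicted.min(), r.observed.min()),
                max(r.predicted.max(), r.observed.max()),
            ]
            ax.plot(lims, lims, "k--", lw=0.8, label="identity")
            xs = np.array(lims)
            ax.plot(
                xs,
                r.calibration_intercept + r.calibration_slope * xs,
                "r-", lw=1.0, label="calibration fit",
            )
            r2s = (
                "r2=?" if r.metrics.r_squared is None
                else f"r2={r.metrics.r_squared:.3f}"
            )
            ax.set_title(f"{pop} / {r.method} ({r2s})", fontsize=9)
            ax.set_xlabel("predicted")
            ax.set_ylabel("observed")
            ax.legend(fontsize=7)

            ax = axes[1][j]
            resid = r.observed - r.predicted
            ax.hist(resid, bins=30, density=True, alpha=0.6)
            ax.axvline(0.0, color="k", lw=0.8)
            ax.axvline(resid.mean(), color="r", lw=1.0, label="mean residual")
            parts = []
            if r.metrics.r2_1a is not None:
                parts.append(f"R2_1A={r.metrics.r2_1a:.3f}")
            if r.metrics.r2_1b is not None:
                parts.append(f"R2_1B={r.metrics.r2_1b:.3f}")
            ax.set_title(", ".join(parts) or "MSPE-based R2 absent", fontsize=9)
            ax.set_xlabel("observed - predicted")
            ax.legend(fontsize=7)
        fig.tight_layout()
        path = out / f"diagnostics_{pop}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written


@dataclass(frozen=True)
class StudyConfig:
    """Full configuration of one synthetic portability study."""

    populations: tuple[PopulationSpec, ...]
    architecture: ArchitectureSpec
    methods: tuple[str, ...] = ("pt", "ridge")
    min_call_rate: float = 0.90
    min_maf: float = 0.001
    split: tuple[float, float, float] = (0.50, 0.25, 0.25)
    n_pcs: int = 10
    gwas_covariates: str = "none"
    assign_ancestry: bool = True
    ancestry_reference_size: int = 50

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split proportions must sum to 1")
        if len(self.populations) < 1:
            raise ValueError("at least one population required")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        pops = tuple(PopulationSpec(**p) for p in d.pop("populations"))
        arch = ArchitectureSpec(**d.pop("architecture"))
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "split" in d:
            d["split"] = tuple(d["split"])
        return cls(populations=pops, architecture=arch, **d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["populations"] = [asdict(p) for p in self.populations]
        d["architecture"] = asdict(self.architecture)
        return d


def default_scenario(
    seed: int = 0,
    n_train: int = 2000,
    n_target: int = 500,
    m: int = 5000,
    heritability: float = 0.5,
    causal_fraction: float = 0.01,
    methods: tuple[str, ...] = ("pt", "ridge"),
) -> StudyConfig:
    """The package's reference study conditions.

    One training population and three targets of increasing divergence; the
    middle target (F_ST 0.1, effect correlation 0.9, environmental shift of
    one trait SD) is the canonical out-of-target scenario in which r^2 stays
    positive while the test-referenced R^2 goes negative.
    """
    populations = (
        PopulationSpec("train_pop", n_train),
        PopulationSpec(
            "target_near", n_target, fst=0.05, effect_correlation=0.95,
            env_shift=-0.5,
        ),
        PopulationSpec(
            "target_mid", n_target, fst=0.10, effect_correlation=0.90,
            env_shift=-1.0,
        ),
        PopulationSpec(
            "target_far", n_target, fst=0.20, effect_correlation=0.80,
            env_shift=-1.5,
        ),
    )
    arch = ArchitectureSpec(
        m=m,
        causal_fraction=causal_fraction,
        heritability=heritability,
        missing_rate=0.02,
        seed=seed,
    )
    return StudyConfig(populations=populations, architecture=arch,
                       methods=methods)


@dataclass
class StudyResult:
    """Everything one study run produced."""

    config: StudyConfig
    seed: int
    results: list[EvaluationResult]
    rankings: RankingTable
    models: dict[str, PolygenicResults]
    ancestry_agreement: float | None

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.row() for r in self.results])

    def get(self, population: str, method: str) -> EvaluationResult:
        for r in self.results:
            if r.population == population and r.method == method:
                return r
        raise KeyError((population, method))

    def report(self, out_dir, make_plots: bool = True) -> list[Path]:
        return report(
            self.results, self.rankings, out_dir, seed=self.seed,
            make_plots=make_plots,
        )


def _split_indices(
    labels: np.ndarray, train_pop: str, split: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.where(labels == train_pop)[0]
    perm = rng.permutation(idx)
    n = len(idx)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def run_study(config: StudyConfig, seed: int | None = None) -> StudyResult:
    """Simulate, train every configured method, and evaluate per population.

    ``seed`` overrides ``config.architecture.seed`` and drives every random
    stage (simulation, splits, PC solver).  Test data are the held-out
    training-population split plus the entirety of each target population;
    target individuals never touch training, validation or model selection.
    """
    if seed is None:
        seed = config.architecture.seed
    else:
        from dataclasses import replace

        config = replace(
            config, architecture=replace(config.architecture, seed=seed)
        )
    geno, table = simulate_cohort(list(config.populations), config.architecture)
    rng = np.random.default_rng(seed + 1)
    train_pop = config.populations[0].name
    train_idx, val_idx, test_idx = _split_indices(
        geno.population_labels, train_pop, config.split, rng
    )

    models: dict[str, PolygenicResults] = {}
    for method in config.methods:
        models[method] = PolygenicModel(
            geno,
            table,
            train_idx=train_idx,
            val_idx=val_idx,
            method=method,
            n_pcs=config.n_pcs,
            min_call_rate=config.min_call_rate,
            min_maf=config.min_maf,
            gwas_covariates=config.gwas_covariates,
            seed=seed,
        ).fit()

    is_target = geno.population_labels != train_pop
    eval_mask = is_target.copy()
    eval_mask[test_idx] = True
    g_eval = geno.subset(individuals=eval_mask)
    t_eval = table.loc[eval_mask].reset_index(drop=True)

    results = evaluate_by_population(models, g_eval, t_eval)
    rankings = rank_methods(results) if len(config.methods) > 1 else None

    agreement = None
    if config.assign_ancestry:
        agreement = _ancestry_agreement(geno, config, rng)

    if rankings is None:
        # ranking needs >= 2 methods; synthesise an empty table for 1 method
        rankings = RankingTable(orderings={}, conflict_flags=(), incomplete=())
    return StudyResult(
        config=config,
        seed=seed,
        results=results,
        rankings=rankings,
        models=models,
        ancestry_agreement=agreement,
    )


def _ancestry_agreement(
    geno: GenotypeMatrix, config: StudyConfig, rng: np.random.Generator,
    n_pcs: int = 4,
) -> float:
    """Fraction of individuals re-assigned to their generating population.

    Uses a global PC space (all populations contribute to the SVD), matching
    how reference-panel ancestry assignment works in practice; a PCA of the
    homogeneous training population alone need not separate target clusters.
    """
    basis = fit_pc_basis(geno, individuals=None, n_components=n_pcs,
                         random_state=int(rng.integers(0, 2**31 - 1)))
    pcs = basis.project(geno)
    labels = geno.population_labels
    ref_rows = []
    for pop in pd.unique(labels):
        pop_idx = np.where(labels == pop)[0]
        take = min(config.ancestry_reference_size, len(pop_idx))
        ref_rows.append(rng.choice(pop_idx, size=take, replace=False))
    ref_idx = np.concatenate(ref_rows)
    refs = ReferenceCenters.from_labelled(pcs[ref_idx], labels[ref_idx])
    assigned = assign_clusters(pcs, refs, sample_ids=geno.sample_ids)
    return float((assigned["cluster"].to_numpy() == labels).mean())
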