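"""Plain-text I/O: PLINK .raw dosage tables, score weight files, pair files.

Only text formats are used.  Genotypes travel as PLINK ``--recode A`` style
.raw tables (``FID IID PAT MAT SEX PHENOTYPE`` then one ``VARIANT_ALLELE``
dosage column per variant, ``NA`` for missing); weights as the three-column
whitespace format accepted by ``plink --score`` (variant id, effect allele,
weight); fitted prediction models as a flat JSON record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import EvalVectors
from .synth import GenotypeMatrix

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_raw(g: GenotypeMatrix, path, phenotype: np.ndarray | None = None,
              sex: np.ndarray | None = None) -> None:
    """Write dosages as a PLINK .raw-compatible whitespace table."""
    n = g.n_samples
    cols = {
        "FID": g.population_labels,
        "IID": g.sample_ids,
        "PAT": np.zeros(n, dtype=int),
        "MAT": np.zeros(n, dtype=int),
        # plink codes male=1 female=2; synthetic sex {0,1} maps to {1,2}
        "SEX": (np.asarray(sex) + 1) if sex is not None else np.zeros(n, dtype=int),
        "PHENOTYPE": phenotype if phenotype is not None else np.full(n, -9),
    }
    df = pd.DataFrame(cols)
    dos = pd.DataFrame(
        g.dosages,
        columns=[f"{v}_{a}" for v, a in zip(g.variant_ids, g.effect_alleles)],
    )
    out = pd.concat([df, dos], axis=1)
    out.to_csv(path, sep=" ", index=False, na_rep="NA")


def read_raw(path) -> GenotypeMatrix:
    """Read a PLINK .raw dosage table (header layout as written by plink)."""
    df = pd.read_csv(path, sep=r"\s+")
    missing_meta = [c for c in _RAW_META if c not in df.columns]
    if missing_meta:
        raise ValueError(f".raw file lacks metadata columns: {missing_meta}")
    var_cols = [c for c in df.columns if c not in _RAW_META]
    vids, alleles = [], []
    for c in var_cols:
        vid, _, allele = c.rpartition("_")
        if not vid:
            raise ValueError(f"dosage column {c!r} is not VARIANT_ALLELE formatted")
        vids.append(vid)
        alleles.append(allele)
    return GenotypeMatrix(
        dosages=df[var_cols].to_numpy(dtype=float),
        variant_ids=np.array(vids),
        effect_alleles=np.array(alleles),
        other_alleles=np.array(["0"] * len(vids)),  # unknown from .raw
        sample_ids=df["IID"].astype(str).to_numpy(),
        population_labels=df["FID"].astype(str).to_numpy(),
    )


def write_weights(weights, path) -> None:
    """Write a WeightVector in plink --score 3-column whitespace format."""
    pd.DataFrame(
        {
            "variant": weights.variant_ids,
            "allele": weights.effect_alleles,
            "weight": weights.weights,
        }
    ).to_csv(path, sep="\t", index=False, header=False)


def read_weights(path):
    """Read a plink --score style 3-column weight file."""
    from .prs import WeightVector

    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["variant", "allele", "weight"]
    )
    return WeightVector(
        variant_ids=df["variant"].astype(str).to_numpy(),
        effect_alleles=df["allele"].astype(str).to_numpy(),
        weights=df["weight"].to_numpy(dtype=float),
    )


def read_pairs(path) -> EvalVectors:
    """Read an (observed, predicted) two-column TSV with header."""
    df = pd.read_csv(path, sep="\t")
    for col in ("observed", "predicted"):
        if col not in df.columns:
            raise ValueError(f"pairs file must have an {col!r} column")
    return EvalVectors(df["observed"].to_numpy(), df["predicted"].to_numpy())


def write_pairs(ev: EvalVectors, path, sample_ids=None) -> None:
    df = pd.DataFrame({"observed": ev.observed, "predicted": ev.predicted})
    if sample_ids is not None:
        df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False)


def write_model(model, path) -> None:
    """Serialize a PredictionModel as a flat JSON text record."""
    record = {
        "intercept": model.intercept,
        "prs_coefficient": model.prs_coefficient,
        "covariate_coefficients": dict(model.covariate_coefficients),
        "train_mean": model.train_mean,
        "weights": {
            "variant_ids": [str(v) for v in model.weights.variant_ids],
            "effect_alleles": [str(a) for a in model.weights.effect_alleles],
            "weights": [float(w) for w in model.weights.weights],
        },
    }
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True) + "\n")


def read_model(path):
    from .prs import PredictionModel, WeightVector

    record = json.loads(Path(path).read_text())
    w = record["weights"]
    return PredictionModel(
        weights=WeightVector(
            variant_ids=np.array(w["variant_ids"]),
            effect_alleles=np.array(w["effect_alleles"]),
            weights=np.array(w["weights"], dtype=float),
        ),
        intercept=float(record["intercept"]),
        prs_coefficient=float(record["prs_coefficient"]),
        covariate_coefficients=dict(record["covariate_coefficients"]),
        train_mean=float(record["train_mean"]),
    )
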