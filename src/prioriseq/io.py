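"""Readers and writers for the tab-delimited interchange formats.

- variant-effects table: columns ID, EFFECT_ALLELE, OTHER_ALLELE, FREQ,
  EFFECT, EFFECT_TYPE (logOR or beta);
- dosage matrix: loci x individuals, locus IDs in column 1, sample IDs
  in the header row, missing coded NA;
- prediction table: per-individual yhat (and delta when phenotypes were
  supplied).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .risk_model import GenotypeMatrix, Prediction, VariantPanel

_EFFECTS_COLUMNS = ["ID", "EFFECT_ALLELE", "OTHER_ALLELE", "FREQ", "EFFECT", "EFFECT_TYPE"]


def read_effects_table(path: str | Path) -> VariantPanel:
    """Read a variant-effects table into a :class:`VariantPanel`."""
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "EFFECT_ALLELE": str, "OTHER_ALLELE": str})
    missing = [c for c in _EFFECTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"effects table {path} lacks columns: {', '.join(missing)}")
    types = set(df["EFFECT_TYPE"])
    if len(types) != 1:
        raise ValueError("effects table mixes logOR and beta effect types")
    return VariantPanel(
        variant_id=df["ID"].tolist(),
        effect_allele=df["EFFECT_ALLELE"].tolist(),
        other_allele=df["OTHER_ALLELE"].tolist(),
        freq=df["FREQ"].to_numpy(float),
        effect=df["EFFECT"].to_numpy(float),
        effect_type=types.pop(),
    )


def write_effects_table(panel: VariantPanel, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "ID": panel.variant_id,
            "EFFECT_ALLELE": panel.effect_allele,
            "OTHER_ALLELE": panel.other_allele,
            "FREQ": panel.freq,
            "EFFECT": panel.effect,
            "EFFECT_TYPE": panel.effect_type,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_dosage_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a loci x individuals dosage matrix (NA = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        dosages=df.to_numpy(float),
        locus_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
    )


def write_dosage_matrix(G: GenotypeMatrix, path: str | Path) -> None:
    n_loci, n_ind = G.dosages.shape
    loci = G.locus_ids or [f"locus{i+1}" for i in range(n_loci)]
    samples = G.sample_ids or [f"sample{j+1}" for j in range(n_ind)]
    df = pd.DataFrame(G.dosages, index=pd.Index(loci, name="ID"), columns=samples)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def write_predictions(
    pred: Prediction, path: str | Path, sample_ids: list[str] | None = None
) -> None:
    n = pred.yhat.size
    ids = sample_ids or [f"sample{j+1}" for j in range(n)]
    data = {"ID": ids, "YHAT": pred.yhat}
    if pred.delta is not None:
        data["DELTA"] = pred.delta
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.8g")
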