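"""Assembly of encoded training/prediction arrays from tabular inputs.

Joins a curated peptide-allele table with its per-pair feature table
(IC50 nM, TAP score, TPM), one-hot encodes both sequence partners, and
min-max-scales the scalar features with constants fitted on the training
split only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import (
    Alphabet, DEFAULT_ALPHABET, PseudoSequenceTable,
    encode_allele, encode_peptide, normalize_allele_name,
)
from .features import NormalizationConstants, apply_minmax, fit_minmax

#: Default pre-transforms for min-max scaling of the two model scalars.
#: IC50 spans ~1-50,000 nM, so it is scaled on the log10 scale; TAP scores
#: live on a bounded additive scale and are scaled raw.
DEFAULT_FEATURE_TRANSFORMS = {"ic50_nm": "log10", "tap": "identity"}

FEATURE_COLUMNS = ("ic50_nm", "tap")


@dataclass
class EncodedDataset:
    """Arrays ready for the classifier, plus the bookkeeping to reuse them."""

    arrays: dict
    norm_constants: dict[str, NormalizationConstants]
    table: pd.DataFrame  # joined rows, aligned with the arrays


def join_features(curated: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Inner-join curated rows with per-(peptide, allele) features."""
    feats = features.copy()
    feats["allele"] = feats["allele"].map(normalize_allele_name)
    merged = curated.merge(feats, on=["peptide", "allele"], how="inner",
                           validate="many_to_one")
    if merged.empty:
        raise ValueError("no (peptide, allele) pairs shared between tables")
    return merged


def fit_feature_scalers(
    train_rows: pd.DataFrame,
    transforms: dict[str, str] | None = None,
) -> dict[str, NormalizationConstants]:
    """Fit per-feature min-max constants on the training split only."""
    transforms = {**DEFAULT_FEATURE_TRANSFORMS, **(transforms or {})}
    return {
        col: fit_minmax(train_rows[col].to_numpy(), transform=transforms[col])
        for col in FEATURE_COLUMNS
    }


def encode_table(
    table: pd.DataFrame,
    pseudo_table: PseudoSequenceTable,
    norm_constants: dict[str, NormalizationConstants],
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> dict:
    """Encode a joined table into the classifier's input arrays.

    Returns a dict with ``peptide`` (N,11,21), ``mhc`` (N,P,21), ``scalars``
    (N,2: scaled IC50 then TAP), and ``label``/``split`` when present.
    Allele matrices are cached per allele.
    """
    mhc_cache = {
        a: encode_allele(a, pseudo_table, alphabet)
        for a in table["allele"].unique()
    }
    pep = np.stack([encode_peptide(p, alphabet) for p in table["peptide"]])
    mhc = np.stack([mhc_cache[a] for a in table["allele"]])
    scalars = np.column_stack([
        apply_minmax(table[col].to_numpy(), norm_constants[col])
        for col in FEATURE_COLUMNS
    ])
    arrays = {"peptide": pep, "mhc": mhc, "scalars": scalars}
    if "label" in table.columns:
        arrays["label"] = table["label"].to_numpy(dtype=int)
    if "split" in table.columns:
        arrays["split"] = table["split"].to_numpy(dtype=object)
    return arrays


def build_encoded_dataset(
    curated: pd.DataFrame,
    features: pd.DataFrame,
    pseudo_table: PseudoSequenceTable,
    alphabet: Alphabet = DEFAULT_ALPHABET,
    transforms: dict[str, str] | None = None,
) -> EncodedDataset:
    """Join, fit scalers on the train split, and encode everything."""
    merged = join_features(curated, features)
    if "split" in merged.columns:
        train_rows = merged[merged["split"] == "train"]
        if train_rows.empty:
            raise ValueError("no rows assigned to the train split")
    else:
        train_rows = merged
    norm = fit_feature_scalers(train_rows, transforms)
    arrays = encode_table(merged, pseudo_table, norm, alphabet)
    return EncodedDataset(arrays=arrays, norm_constants=norm,
                          table=merged.reset_index(drop=True))


def flattened_features(arrays: dict) -> np.ndarray:
    """Flatten the one-hot matrices and append the scalars.

    This is the feature representation consumed by the classical baseline
    models: identical information to the convolutional network's input,
    as one vector per pair.
    """
    n = arrays["peptide"].shape[0]
    return np.hstack([
        arrays["peptide"].reshape(n, -1),
        arrays["mhc"].reshape(n, -1),
        arrays["scalars"],
    ])
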