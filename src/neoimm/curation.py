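"""Curation of T-cell immunogenicity assay tables.

Public immune-epitope databases mix assay technologies of very different
evidentiary value.  Only assays that measure direct T-cell contact are kept
here (ELISPOT, chromium-51 release, intracellular cytokine staining,
multimer/tetramer staining, ELISA).  The remaining filters enforce
protein-level (4-digit) HLA typing, class I peptide lengths, and a minimum
of experimental support for negative calls: a negative result backed by
fewer than four tested subjects is weak evidence of non-immunogenicity and
is discarded.

The filter chain, applied in order:

1. keep only the five allowed assay methods;
2. drop records whose HLA allele is not resolvable to 4-digit form;
3. drop exact duplicate (peptide, allele, outcome) records;
4. keep peptides of length 8-11;
5. drop negative records with missing subject counts or fewer than four
   tested subjects;
6. collapse residual (peptide, allele) duplicates -- a conflicting
   positive/negative pair collapses to positive, since any validated T-cell
   response is direct evidence of immunogenicity.

Per-stage removal counts are recorded as provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import is_four_digit_allele, normalize_allele_name

#: Assay methods accepted as direct evidence of T-cell (non-)response.
ALLOWED_ASSAYS = ("ELISPOT", "51 CHROMIUM", "ICS", "MULTIMER/TETRAMER", "ELISA")

#: Substring aliases matched case-insensitively against assay descriptions,
#: so dialect strings like "IFNg ELISPOT" or "tetramer staining" pass.
_ASSAY_ALIASES = {
    "ELISPOT": ("ELISPOT",),
    "51 CHROMIUM": ("51 CHROMIUM", "CHROMIUM", "51CR", "51 CR"),
    "ICS": ("ICS", "INTRACELLULAR CYTOKINE"),
    "MULTIMER/TETRAMER": ("MULTIMER", "TETRAMER"),
    "ELISA": ("ELISA",),
}

#: Minimum tested subjects for a negative record to count as evidence.
MIN_NEGATIVE_SUBJECTS = 4

FILTER_STAGES = (
    "assay_method",
    "allele_resolution",
    "exact_duplicate",
    "peptide_length",
    "thin_negative",
    "pair_collapse",
)


@dataclass(frozen=True)
class AssayRecord:
    """One row of an immunogenicity assay table, pre-curation."""

    peptide: str
    allele_raw: str
    assay_method: str
    qualitative_outcome: bool  # True = positive T-cell response
    n_subjects_tested: int | None = None
    n_subjects_responded: int | None = None
    mhc_class: str = "I"
    host: str = "human"

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("peptide must be non-empty")


@dataclass
class CuratedDataset:
    """Filtered, deduplicated, labelled peptide-allele dataset.

    ``rows`` is a DataFrame with columns ``peptide``, ``allele``, ``label``
    and (after :func:`assign_splits`) ``split``.  ``provenance`` maps each
    filter stage to the number of records it removed.
    """

    rows: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_positive(self) -> int:
        return int((self.rows["label"] == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.rows["label"] == 0).sum())


class SplitConfigError(ValueError):
    """Split fractions do not form a valid partition."""


def assay_method_allowed(method: str) -> bool:
    """Case-insensitive substring match against the five canonical assay names."""
    m = method.upper()
    return any(alias in m for aliases in _ASSAY_ALIASES.values() for alias in aliases)


def _is_missing_count(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def curate(records: list[AssayRecord]) -> CuratedDataset:
    """Apply the six-stage filter chain and return a labelled dataset.

    An empty input yields an empty dataset with zeroed provenance.  The
    operation is idempotent: re-curating the survivors (re-expressed as
    records) removes nothing further.
    """
    provenance = {stage: 0 for stage in FILTER_STAGES}

    stage1 = []
    for rec in records:
        if assay_method_allowed(rec.assay_method):
            stage1.append(rec)
        else:
            provenance["assay_method"] += 1

    stage2 = []
    for rec in stage1:
        if is_four_digit_allele(rec.allele_raw):
            stage2.append(rec)
        else:
            provenance["allele_resolution"] += 1

    stage3, seen = [], set()
    for rec in stage2:
        key = (rec.peptide, normalize_allele_name(rec.allele_raw), rec.qualitative_outcome)
        if key in seen:
            provenance["exact_duplicate"] += 1
        else:
            seen.add(key)
            stage3.append(rec)

    stage4 = []
    for rec in stage3:
        if 8 <= len(rec.peptide) <= 11:
            stage4.append(rec)
        else:
            provenance["peptide_length"] += 1

    stage5 = []
    for rec in stage4:
        if not rec.qualitative_outcome and (
            _is_missing_count(rec.n_subjects_tested)
            or rec.n_subjects_tested < MIN_NEGATIVE_SUBJECTS
        ):
            provenance["thin_negative"] += 1
        else:
            stage5.append(rec)

    # Conflicting labels for a surviving (peptide, allele) pair collapse to
    # positive: a validated T-cell response trumps a negative assay.
    labels: dict[tuple[str, str], int] = {}
    order: list[tuple[str, str]] = []
    for rec in stage5:
        key = (rec.peptide, normalize_allele_name(rec.allele_raw))
        label = int(rec.qualitative_outcome)
        if key not in labels:
            labels[key] = label
            order.append(key)
        else:
            provenance["pair_collapse"] += 1
            labels[key] = max(labels[key], label)

    rows = pd.DataFrame(
        [(p, a, labels[(p, a)]) for p, a in order],
        columns=["peptide", "allele", "label"],
    )
    return CuratedDataset(rows=rows, provenance=provenance)


def curate_dataframe(df: pd.DataFrame, column_map: dict[str, str] | None = None
                     ) -> CuratedDataset:
    """Curate a raw assay table given a column mapping.

    ``column_map`` maps canonical field names (``peptide``, ``allele``,
    ``assay_method``, ``outcome``, ``n_subjects_tested``,
    ``n_subjects_responded``) to the table's column names; identity by default.
    The outcome column accepts Positive/Negative strings (case-insensitive,
    prefix "pos"/"neg") or 1/0.
    """
    cmap = {k: k for k in ("peptide", "allele", "assay_method", "outcome",
                           "n_subjects_tested", "n_subjects_responded")}
    cmap.update(column_map or {})
    records = []
    for _, row in df.iterrows():
        outcome = row[cmap["outcome"]]
        if isinstance(outcome, str):
            positive = outcome.strip().lower().startswith("pos")
        else:
            positive = bool(outcome)
        def _count(col):
            if col not in df.columns:
                return None
            v = row[col]
            return None if _is_missing_count(v) else int(v)
        records.append(AssayRecord(
            peptide=str(row[cmap["peptide"]]).strip(),
            allele_raw=str(row[cmap["allele"]]).strip(),
            assay_method=str(row[cmap["assay_method"]]).strip(),
            qualitative_outcome=positive,
            n_subjects_tested=_count(cmap["n_subjects_tested"]),
            n_subjects_responded=_count(cmap["n_subjects_responded"]),
        ))
    return curate(records)


DEFAULT_SPLIT_FRACTIONS = (0.7, 0.2, 0.1)
SPLIT_NAMES = ("train", "test", "validation")


def assign_splits(
    dataset: CuratedDataset,
    fractions: tuple[float, float, float] = DEFAULT_SPLIT_FRACTIONS,
    seed: int = 0,
) -> CuratedDataset:
    """Randomly partition rows into train/test/validation splits.

    Counts are floor-based per split with the remainder assigned to train,
    so n=1000 at the default (0.7, 0.2, 0.1) gives exactly 700/200/100.
    Assignment is uniform random by record, deterministic given ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitConfigError(f"split fractions must sum to 1, got {fractions}")
    n = len(dataset)
    n_test = int(n * fractions[1])
    n_val = int(n * fractions[2])
    n_train = n - n_test - n_val
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    split = np.empty(n, dtype=object)
    split[perm[:n_train]] = "train"
    split[perm[n_train:n_train + n_test]] = "test"
    split[perm[n_train + n_test:]] = "validation"
    rows = dataset.rows.copy()
    rows["split"] = split
    return CuratedDataset(rows=rows, provenance=dict(dataset.provenance))
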