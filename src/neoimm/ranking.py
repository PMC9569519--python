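"""Filtering and ranking of candidate neoepitopes.

A candidate must clear four criteria to be shortlisted: its peptide must be
transportable (TAP score > 0, strict), bind its HLA allele (IC50 <= 500 nM,
inclusive), come from an expressed transcript (TPM > 0, strict) and be
predicted immunogenic (score > 0.5, strict).  Survivors are ranked by
descending immunogenicity with a deterministic tie-break chain (ascending
IC50, then descending TAP, then lexicographic peptide) and reported with a
1-based rank and a rank-percentage (rank / total x 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

IC50_MAX_NM = 500.0
IMMUNOGENICITY_MIN = 0.5

#: (name, predicate-passes) pairs, checked in order; the first failure names
#: the rejecting criterion.
_CRITERIA = (
    ("tap", lambda c: c.tap > 0.0),
    ("ic50", lambda c: c.ic50 <= IC50_MAX_NM),
    ("tpm", lambda c: c.tpm > 0.0),
    ("immunogenicity", lambda c: c.immunogenicity > IMMUNOGENICITY_MIN),
)


@dataclass
class NeoCandidate:
    """A scored candidate neoepitope."""

    peptide: str
    allele: str
    ic50: float
    tap: float
    tpm: float
    immunogenicity: float
    source_variant: str = ""

    def __post_init__(self) -> None:
        for name in ("ic50", "tap", "tpm", "immunogenicity"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if not 0.0 <= self.immunogenicity <= 1.0:
            raise ValueError(f"immunogenicity must lie in [0, 1], got "
                             f"{self.immunogenicity}")


def first_failed_criterion(candidate: NeoCandidate) -> str | None:
    """Name of the first selection criterion the candidate fails, or None."""
    for name, passes in _CRITERIA:
        if not passes(candidate):
            return name
    return None


def filter_candidates(
    candidates: list[NeoCandidate],
    rejects: list[tuple[NeoCandidate, str]] | None = None,
) -> list[NeoCandidate]:
    """Keep candidates meeting all four selection criteria, order preserved.

    If ``rejects`` is supplied, each dropped candidate is appended to it
    together with the first criterion it failed.
    """
    kept = []
    for cand in candidates:
        failed = first_failed_criterion(cand)
        if failed is None:
            kept.append(cand)
        elif rejects is not None:
            rejects.append((cand, failed))
    return kept


def _sort_key(cand: NeoCandidate):
    return (-cand.immunogenicity, cand.ic50, -cand.tap, cand.peptide, cand.allele)


def rank_candidates(candidates: list[NeoCandidate]) -> pd.DataFrame:
    """Order candidates and attach 1-based ranks and rank-percentages.

    The tie-break chain (immunogenicity desc, IC50 asc, TAP desc, peptide
    then allele lexicographic) makes the ordering a total order, so output
    is identical for any input permutation.
    """
    ordered = sorted(candidates, key=_sort_key)
    total = len(ordered)
    rows = [
        {
            "rank": i,
            "peptide": c.peptide,
            "allele": c.allele,
            "ic50": c.ic50,
            "tap": c.tap,
            "tpm": c.tpm,
            "immunogenicity": c.immunogenicity,
            "rank_percentage": 100.0 * i / total,
            "source_variant": c.source_variant,
        }
        for i, c in enumerate(ordered, start=1)
    ]
    columns = ["rank", "peptide", "allele", "ic50", "tap", "tpm",
               "immunogenicity", "rank_percentage", "source_variant"]
    return pd.DataFrame(rows, columns=columns)


def candidates_from_frame(df: pd.DataFrame) -> list[NeoCandidate]:
    """Build candidates from a table with the NeoCandidate columns."""
    return [
        NeoCandidate(
            peptide=row["peptide"], allele=row["allele"],
            ic50=float(row["ic50"]), tap=float(row["tap"]),
            tpm=float(row["tpm"]), immunogenicity=float(row["immunogenicity"]),
            source_variant=str(row.get("source_variant", "") or ""),
        )
        for _, row in df.iterrows()
    ]


def rejects_frame(rejects: list[tuple[NeoCandidate, str]]) -> pd.DataFrame:
    rows = [
        {"peptide": c.peptide, "allele": c.allele, "ic50": c.ic50, "tap": c.tap,
         "tpm": c.tpm, "immunogenicity": c.immunogenicity,
         "failed_criterion": why}
        for c, why in rejects
    ]
    return pd.DataFrame(rows, columns=["peptide", "allele", "ic50", "tap", "tpm",
                                       "immunogenicity", "failed_criterion"])
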