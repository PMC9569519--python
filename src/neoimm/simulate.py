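"""Synthetic assay and feature tables with a planted immunogenicity rule.

The generator emulates the schema of a curated T-cell assay extract
(peptide 8-11-mer, 4-digit HLA allele, assay method, qualitative outcome,
subject counts) together with a per-pair feature table (IC50 nM, TAP score,
TPM), so the whole curation -> encoding -> training -> ranking chain is
exercisable without any external download.

The planted rule. Each synthetic allele receives a random pseudo-sequence
and a preferred anchor residue pair (peptide position 2 and the C-terminus,
the canonical class I anchors).  For each record the latent immunogenicity
probability is

    p_true = sigmoid(b_anchor * anchor_match + b_ba * (1 - ba_norm)
             + b_tap * tap_norm + intercept + eps),   eps ~ N(0, noise_sd)

where ba_norm is the log-scale min-max of the IC50 draw (log-uniform on
[1, 50000] nM, so ba_norm is uniform on [0, 1]) and tap_norm is the normal
CDF of the TAP draw.  Stronger binders (low IC50) and efficiently
transported peptides trend immunogenic, matching the separation observed in
real assay data.  Labels are Bernoulli(p_true); p_true is returned
separately as the Bayes-optimal reference scorer.

The intercept is calibrated per dataset so the realized mean of p_true hits
the configured positive fraction (default 0.405, the positive share of the
curated extract the model family was built for).

Contamination fractions inject records that violate each curation filter
(disallowed assay, 2-digit allele, wrong peptide length, thin negatives,
exact duplicates) on disjoint record subsets, so provenance counts are
predictable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr

from .alphabet import PSEUDO_POSITIONS, PseudoSequenceTable
from .curation import ALLOWED_ASSAYS

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

IC50_RANGE_NM = (1.0, 50_000.0)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the standard conditions."""

    n_records: int = 2000
    n_alleles: int = 6
    peptide_length_range: tuple[int, int] = (8, 11)
    positive_fraction_target: float = 0.405
    rule_coefficients: tuple[float, float, float] = (8.0, 8.0, 4.0)  # anchor, ba, tap
    noise_sd: float = 0.3
    anchor_plant_fraction: float = 0.5
    contamination: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.peptide_length_range
        if not (8 <= lo <= hi <= 11):
            raise ValueError("peptide lengths must lie within [8, 11]")
        if not 0.0 < self.positive_fraction_target < 1.0:
            raise ValueError("positive_fraction_target must be in (0, 1)")
        bad = set(self.contamination) - set(CONTAMINATION_KINDS)
        if bad:
            raise ValueError(f"unknown contamination kinds: {sorted(bad)}")
        if any(not 0.0 <= f <= 1.0 for f in self.contamination.values()):
            raise ValueError("contamination fractions must lie in [0, 1]")
        if sum(self.contamination.values()) > 1.0:
            raise ValueError("contamination fractions must sum to at most 1")


CONTAMINATION_KINDS = (
    "bad_assay", "two_digit_allele", "wrong_length", "thin_negatives", "duplicates",
)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset, kept apart from the tables."""

    p_true: np.ndarray  # latent probability per clean record
    record_ids: np.ndarray  # id column values aligned with p_true
    anchor_preferences: dict[str, tuple[str, str]]
    intercept: float
    config: SimulationConfig

    def to_dict(self) -> dict:
        return {
            "p_true": self.p_true.tolist(),
            "record_ids": self.record_ids.tolist(),
            "anchor_preferences": {k: list(v) for k, v in self.anchor_preferences.items()},
            "intercept": self.intercept,
            "config": asdict(self.config),
        }


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_STANDARD_RESIDUES), size=length))


def simulate_pseudo_table(n_alleles: int, rng: np.random.Generator
                          ) -> tuple[PseudoSequenceTable, dict[str, tuple[str, str]]]:
    """Random alleles with random pseudo-sequences and anchor preferences."""
    entries: dict[str, str] = {}
    anchors: dict[str, tuple[str, str]] = {}
    loci = ["A", "B", "C"]
    while len(entries) < n_alleles:
        locus = loci[len(entries) % 3]
        name = f"HLA-{locus}*{rng.integers(1, 100):02d}:{rng.integers(1, 100):02d}"
        if name in entries:
            continue
        entries[name] = "".join(rng.choice(list(_STANDARD_RESIDUES),
                                           size=len(PSEUDO_POSITIONS)))
        anchors[name] = (str(rng.choice(list(_STANDARD_RESIDUES))),
                         str(rng.choice(list(_STANDARD_RESIDUES))))
    return PseudoSequenceTable(entries=entries), anchors


def _anchor_match(peptide: str, preference: tuple[str, str]) -> int:
    """1 if both canonical anchors (position 2 and C-terminus) match."""
    return int(peptide[1] == preference[0] and peptide[-1] == preference[1])


def simulate_assays(config: SimulationConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth,
                               PseudoSequenceTable]:
    """Generate an assay table, a feature table, and the ground truth.

    Returns ``(assays, features, truth, pseudo_table)``.  The assay table
    has columns id, peptide, allele, assay_method, outcome,
    n_subjects_tested, n_subjects_responded, mhc_class, host; the feature
    table has peptide, allele, ic50_nm, tap, tpm.  Fully deterministic for a
    fixed config (byte-identical tables across runs).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    b_anchor, b_ba, b_tap = config.rule_coefficients

    pseudo_table, anchors = simulate_pseudo_table(config.n_alleles, rng)
    alleles = sorted(pseudo_table.entries)

    n = config.n_records
    lo, hi = config.peptide_length_range
    allele_draw = rng.choice(alleles, size=n)
    lengths = rng.integers(lo, hi + 1, size=n)
    plant = rng.random(n) < config.anchor_plant_fraction

    peptides, seen_pairs = [], set()
    for i in range(n):
        while True:
            pep = _random_peptide(rng, lengths[i])
            if plant[i]:
                pref = anchors[allele_draw[i]]
                pep = pep[0] + pref[0] + pep[2:-1] + pref[1]
            if (pep, allele_draw[i]) not in seen_pairs:
                seen_pairs.add((pep, allele_draw[i]))
                break
        peptides.append(pep)

    log_lo, log_hi = math.log(IC50_RANGE_NM[0]), math.log(IC50_RANGE_NM[1])
    ic50 = np.exp(rng.uniform(log_lo, log_hi, size=n))
    ba_norm = (np.log(ic50) - log_lo) / (log_hi - log_lo)
    tap_raw = rng.normal(0.0, 1.0, size=n)
    tap_norm = ndtr(tap_raw)  # population CDF -> uniform [0, 1]
    tpm = np.exp(rng.normal(1.0, 1.0, size=n))
    match = np.array([_anchor_match(p, anchors[a])
                      for p, a in zip(peptides, allele_draw)])

    eps = rng.normal(0.0, config.noise_sd, size=n)
    raw_logit = b_anchor * match + b_ba * (1.0 - ba_norm) + b_tap * tap_norm + eps
    intercept = _calibrate_intercept(raw_logit, config.positive_fraction_target)
    p_true = expit(raw_logit + intercept)
    labels = rng.random(n) < p_true

    tested = rng.integers(4, 51, size=n)
    responded = np.where(labels, rng.integers(1, tested + 1), 0)
    assay_methods = rng.choice(ALLOWED_ASSAYS, size=n)

    assays = pd.DataFrame({
        "id": np.arange(n),
        "peptide": peptides,
        "allele": allele_draw,
        "assay_method": assay_methods,
        "outcome": np.where(labels, "Positive", "Negative"),
        "n_subjects_tested": tested.astype(object),
        "n_subjects_responded": responded,
        "mhc_class": "I",
        "host": "Homo sapiens",
    })
    features = pd.DataFrame({
        "peptide": peptides,
        "allele": allele_draw,
        "ic50_nm": ic50,
        "tap": tap_raw,
        "tpm": tpm,
    })

    assays = _contaminate(assays, config, rng)

    truth = SyntheticTruth(
        p_true=p_true,
        record_ids=np.arange(n),
        anchor_preferences=anchors,
        intercept=float(intercept),
        config=config,
    )
    return assays, features, truth, pseudo_table


def _calibrate_intercept(raw_logit: np.ndarray, target: float) -> float:
    def gap(c: float) -> float:
        return float(np.mean(expit(raw_logit + c))) - target
    return brentq(gap, -50.0, 50.0)


def _contaminate(assays: pd.DataFrame, config: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Corrupt disjoint record subsets so each curation filter fires once."""
    if not config.contamination:
        return assays
    n = len(assays)
    pool = rng.permutation(n)
    cursor = 0
    assays = assays.copy()
    extra_rows = []
    for kind in CONTAMINATION_KINDS:
        frac = config.contamination.get(kind, 0.0)
        count = int(round(frac * n))
        idx = pool[cursor:cursor + count]
        cursor += count
        if count == 0:
            continue
        if kind == "bad_assay":
            assays.loc[assays.index[idx], "assay_method"] = "proliferation assay"
        elif kind == "two_digit_allele":
            assays.loc[assays.index[idx], "allele"] = [
                f"HLA-A{rng.integers(1, 10)}" for _ in idx
            ]
        elif kind == "wrong_length":
            assays.loc[assays.index[idx], "peptide"] = [
                _random_peptide(rng, int(rng.choice([6, 7, 12, 13]))) for _ in idx
            ]
        elif kind == "thin_negatives":
            rows = assays.index[idx]
            assays.loc[rows, "outcome"] = "Negative"
            assays.loc[rows, "n_subjects_tested"] = [
                None if rng.random() < 0.5 else int(rng.integers(1, 4)) for _ in idx
            ]
        elif kind == "duplicates":
            extra_rows.append(assays.iloc[idx])
    if extra_rows:
        assays = pd.concat([assays, *extra_rows], ignore_index=True)
    return assays


def oracle_scores(truth: SyntheticTruth, records: pd.DataFrame) -> np.ndarray:
    """Bayes-optimal latent probabilities aligned with ``records``.

    ``records`` must carry the generator's ``id`` column; unknown ids raise,
    guarding against pairing a truth object with tables from another run.
    """
    lookup = dict(zip(truth.record_ids.tolist(), truth.p_true))
    try:
        return np.array([lookup[int(i)] for i in records["id"]])
    except KeyError as exc:
        raise ValueError(f"record id {exc} not generated by this truth object") from exc


def oracle_frame(truth: SyntheticTruth, assays: pd.DataFrame) -> pd.DataFrame:
    """Per-pair Bayes-optimal probabilities keyed by (peptide, allele).

    Joins the truth back onto the assay table via the generator's ``id``
    column and deduplicates pairs, so curated tables (which no longer carry
    ids) can be merged against it.
    """
    base = assays[assays["id"].isin(set(truth.record_ids.tolist()))]
    out = base[["id", "peptide", "allele"]].copy()
    out["p_true"] = oracle_scores(truth, base)
    return out.drop_duplicates(subset=["peptide", "allele"]).drop(columns="id")
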