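"""Amino-acid alphabet and one-hot encoding of peptides and MHC pseudo-sequences.

Class I HLA molecules present short peptides (8-11 residues) to CD8+ T cells.
Both partners of a peptide-MHC pair are represented here as binary matrices:
each residue becomes a 21-dimensional one-hot vector over the alphabet
``ACDEFGHIKLMNPQRSTVWYX``, where ``X`` doubles as the padding character and
the unknown-residue symbol.  Peptides are padded to a fixed 11 rows so that
every pair has a constant shape -- the input contract of the downstream
convolutional model.

MHC alleles are represented by *pseudo-sequences*: the residues at a fixed
set of peptide-contacting positions of the mature HLA chain (the NetMHCpan
convention).  Pseudo-sequences are supplied as a two-column text table and
are not derived from IMGT alignments here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: The 21-symbol alphabet: 20 standard residues plus 'X' (padding / unknown).
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

#: Fixed padded peptide length (class I 8-11-mers, padded with 'X').
MAX_PEPTIDE_LENGTH = 11
MIN_PEPTIDE_LENGTH = 8

#: HLA heavy-chain positions whose residues form the pseudo-sequence.
PSEUDO_POSITIONS = (
    79, 24, 45, 59, 62, 63, 66, 67, 69, 70, 73, 74, 76, 77, 80, 81, 84,
    95, 97, 99, 114, 116, 118, 143, 147, 150, 152, 156, 158, 159, 163,
    167, 171,
)


class InvalidResidueError(ValueError):
    """Input is not a single residue character."""


class PeptideLengthError(ValueError):
    """Peptide length outside the supported 8-11-mer range."""


class AlleleFormatError(ValueError):
    """HLA allele name cannot be parsed into 4-digit nomenclature."""


class MissingAlleleError(KeyError):
    """Allele absent from the pseudo-sequence table."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet with a designated padding/unknown symbol."""

    symbols: str = AMINO_ALPHABET
    pad_symbol: str = "X"

    def __post_init__(self) -> None:
        if len(self.symbols) != 21:
            raise ValueError(f"alphabet must have 21 symbols, got {len(self.symbols)}")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if self.pad_symbol not in self.symbols:
            raise ValueError("pad symbol must be a member of the alphabet")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, residue: str) -> int:
        """Alphabet index of ``residue``; unknown residues map to the pad symbol."""
        if len(residue) != 1:
            raise InvalidResidueError(f"expected a single character, got {residue!r}")
        residue = residue.upper()
        pos = self.symbols.find(residue)
        if pos < 0:
            logger.warning("unknown residue %r mapped to %r", residue, self.pad_symbol)
            pos = self.symbols.index(self.pad_symbol)
        return pos


DEFAULT_ALPHABET = Alphabet()


def encode_residue(residue: str, alphabet: Alphabet = DEFAULT_ALPHABET) -> np.ndarray:
    """One-hot encode a single residue as a length-21 binary vector."""
    vec = np.zeros(alphabet.size, dtype=np.float32)
    vec[alphabet.index(residue)] = 1.0
    return vec


def encode_peptide(
    peptide: str,
    alphabet: Alphabet = DEFAULT_ALPHABET,
    pad_side: str = "center",
) -> np.ndarray:
    """One-hot encode an 8-11-mer peptide as a constant-shape 11x21 matrix.

    Peptides shorter than 11 residues are padded with the alphabet's pad
    symbol.  ``pad_side`` splits the pads around the middle (``"center"``,
    default) or places them at the C-terminus (``"right"``) or N-terminus
    (``"left"``).  Center padding keeps both canonical class I anchor
    positions -- peptide position 2 and the C-terminal residue -- at fixed
    matrix rows for every peptide length, the convention of pan-allele
    binding predictors; terminal padding fixes only one of them.
    """
    peptide = peptide.strip()
    if not MIN_PEPTIDE_LENGTH <= len(peptide) <= MAX_PEPTIDE_LENGTH:
        raise PeptideLengthError(
            f"peptide {peptide!r} has length {len(peptide)}; "
            f"supported range is {MIN_PEPTIDE_LENGTH}-{MAX_PEPTIDE_LENGTH}"
        )
    n_pad = MAX_PEPTIDE_LENGTH - len(peptide)
    pad = alphabet.pad_symbol
    if pad_side == "right":
        padded = peptide + pad * n_pad
    elif pad_side == "left":
        padded = pad * n_pad + peptide
    elif pad_side == "center":
        half = len(peptide) // 2
        padded = peptide[:half] + pad * n_pad + peptide[half:]
    else:
        raise ValueError(f"unknown pad_side {pad_side!r}")
    return np.stack([encode_residue(r, alphabet) for r in padded])


def decode_peptide(matrix: np.ndarray, alphabet: Alphabet = DEFAULT_ALPHABET) -> str:
    """Argmax-decode an encoded peptide, dropping pad symbols.

    Assumes the peptide contains no genuine unknown residues (which share
    the pad symbol).
    """
    chars = [alphabet.symbols[i] for i in np.asarray(matrix).argmax(axis=1)]
    return "".join(chars).replace(alphabet.pad_symbol, "")


_ALLELE_RE = re.compile(
    r"^(?:HLA-?\s*)?([A-Z]+\d?)\s*\*?\s*(\d{2,3}):(\d{2,3})(?::\d+[A-Z]*)*[A-Z]?$",
    re.IGNORECASE,
)
# Compact legacy form, e.g. "A0201" or "B*4402".
_COMPACT_RE = re.compile(r"^(?:HLA-?)?([A-Z])\s*\*?\s*(\d{2})(\d{2})$", re.IGNORECASE)


def normalize_allele_name(raw: str) -> str:
    """Normalize an HLA class I allele name to 4-digit form, e.g. ``HLA-A*02:01``.

    Accepts colon-delimited names with or without the ``HLA-`` prefix or the
    ``*`` separator, names carrying higher-resolution fields (truncated), and
    the compact legacy 4-digit form (``A0201``).  Raises
    :class:`AlleleFormatError` for anything else (including 2-digit names
    such as ``HLA-A2``, which are not resolvable to protein level).
    """
    if not raw or not raw.strip():
        raise AlleleFormatError("empty allele name")
    name = raw.strip()
    m = _ALLELE_RE.match(name)
    if m:
        locus, group, protein = m.group(1).upper(), m.group(2), m.group(3)
        return f"HLA-{locus}*{int(group):02d}:{int(protein):02d}"
    m = _COMPACT_RE.match(name)
    if m:
        locus, group, protein = m.group(1).upper(), m.group(2), m.group(3)
        return f"HLA-{locus}*{group}:{protein}"
    raise AlleleFormatError(f"cannot parse HLA allele name {raw!r}")


def is_four_digit_allele(raw: str) -> bool:
    """True if ``raw`` normalizes to a 4-digit allele name."""
    try:
        normalize_allele_name(raw)
        return True
    except AlleleFormatError:
        return False


@dataclass
class PseudoSequenceTable:
    """Map from normalized allele names to fixed-length pseudo-sequences.

    The expected file format is MHC_pseudo.dat-style two-column whitespace-
    delimited text (allele name, residue string); ``#`` lines are comments.
    All residue strings must share one length, by default the 33 contact
    positions listed in :data:`PSEUDO_POSITIONS`.
    """

    entries: dict[str, str]
    positions: tuple[int, ...] = field(default=PSEUDO_POSITIONS)
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        normalized = {}
        for allele, seq in self.entries.items():
            key = normalize_allele_name(allele)
            seq = seq.strip().upper()
            if len(seq) != self.length:
                raise ValueError(
                    f"pseudo-sequence for {key} has length {len(seq)}, "
                    f"expected {self.length}"
                )
            normalized[key] = seq
        self.entries = normalized

    @property
    def length(self) -> int:
        return len(self.positions)

    @property
    def alleles(self) -> list[str]:
        return sorted(self.entries)

    def __contains__(self, allele: str) -> bool:
        try:
            return normalize_allele_name(allele) in self.entries
        except AlleleFormatError:
            return False

    def lookup(self, allele: str) -> str:
        key = normalize_allele_name(allele)
        try:
            return self.entries[key]
        except KeyError:
            raise MissingAlleleError(
                f"allele {key} not in pseudo-sequence table "
                f"({len(self.entries)} alleles known)"
            ) from None

    @classmethod
    def from_file(cls, path: str | Path, positions: tuple[int, ...] | None = None
                  ) -> "PseudoSequenceTable":
        entries: dict[str, str] = {}
        length: int | None = None
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            allele, seq = parts
            if length is None:
                length = len(seq)
            entries[allele] = seq
        if not entries:
            raise ValueError(f"{path}: no pseudo-sequence entries found")
        if positions is None:
            # Residue strings declare their own fixed length; fall back to the
            # canonical 33 positions when the length matches, else synthesize
            # placeholder position labels.
            positions = (PSEUDO_POSITIONS if length == len(PSEUDO_POSITIONS)
                         else tuple(range(1, length + 1)))
        return cls(entries=entries, positions=positions)

    def to_file(self, path: str | Path) -> None:
        lines = ["# allele\tpseudo_sequence"]
        lines += [f"{a}\t{s}" for a, s in sorted(self.entries.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def encode_allele(
    allele_name: str,
    table: PseudoSequenceTable,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> np.ndarray:
    """One-hot encode an allele's pseudo-sequence as a (pseudo-length x 21) matrix."""
    seq = table.lookup(allele_name)
    return np.stack([encode_residue(r, alphabet) for r in seq])


@dataclass(frozen=True)
class EncodedPair:
    """A single CNN input unit: encoded peptide, encoded MHC, scaled scalars.

    ``ba_norm`` and ``tap_norm`` are the min-max-scaled binding affinity and
    TAP transport-efficiency features, both in [0, 1].
    """

    peptide_matrix: np.ndarray
    mhc_matrix: np.ndarray
    ba_norm: float
    tap_norm: float

    def __post_init__(self) -> None:
        for name, m in (("peptide", self.peptide_matrix), ("mhc", self.mhc_matrix)):
            if not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError(f"{name} matrix rows must be one-hot")
        for name, v in (("ba_norm", self.ba_norm), ("tap_norm", self.tap_norm)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
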