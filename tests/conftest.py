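import numpy as np
import pytest

from neoimm.alphabet import PseudoSequenceTable
from neoimm.curation import AssayRecord


@pytest.fixture(scope="session")
def pseudo_table() -> PseudoSequenceTable:
    """Small deterministic pseudo-sequence table for encoding tests."""
    rng = np.random.default_rng(42)
    residues = list("ACDEFGHIKLMNPQRSTVWY")
    entries = {
        name: "".join(rng.choice(residues, size=33))
        for name in ("HLA-A*02:01", "HLA-A*01:01", "HLA-B*07:02", "HLA-C*04:01")
    }
    entries["HLA-A*02:01"] = "A" * 33  # uniform sequence, handy for assertions
    return PseudoSequenceTable(entries=entries)


@pytest.fixture()
def toy_assay_records() -> list[AssayRecord]:
    """Six records covering each curation filter exactly once.

    Hand-derivation: record 1 passes everything; 2 is a thin negative
    (n=2 < 4); 3 is a 12-mer; 4 has a 2-digit allele; 5 passes (negative
    with n=5); 6 uses a disallowed assay.  Expected survivors: 1 and 5.
    """
    return [
        AssayRecord("KLANVILKV", "HLA-A*02:01", "IFNg ELISPOT", True,
                    n_subjects_tested=10, n_subjects_responded=4),
        AssayRecord("LLDNRVAEV", "HLA-A*02:01", "ELISA", False,
                    n_subjects_tested=2),
        AssayRecord("SLYNTVATLYYV", "HLA-B*07:02", "ICS", True,
                    n_subjects_tested=8, n_subjects_responded=3),
        AssayRecord("GILGFVFTL", "HLA-A2", "multimer/tetramer staining", True,
                    n_subjects_tested=12, n_subjects_responded=9),
        AssayRecord("RAKFKQLLQV", "HLA-B*07:02", "51 chromium release", False,
                    n_subjects_tested=5),
        AssayRecord("NLVPMVATV", "HLA-A*01:01", "proliferation assay", True,
                    n_subjects_tested=6, n_subjects_responded=2),
    ]
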