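"""Shared fixtures: deterministic weight tables and sequence helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from codonstate.cai import WeightTable, reference_weights
from codonstate.codon_metrics import CodonCounts
from codonstate.genetic_code import FAMILIES, SENSE_CODONS
from codonstate.sequence_io import CdsRecord

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_counts(overrides: dict[str, int] | None = None, base: int = 1) -> CodonCounts:
    """Counts with ``base`` for every sense codon plus overrides."""
    counts = {c: base for c in SENSE_CODONS}
    counts.update(overrides or {})
    return CodonCounts("fixture", counts)


@pytest.fixture(scope="session")
def skewed_weights() -> WeightTable:
    """A deterministic, non-trivial weight table.

    Within each family the lexicographically sorted codons get counts
    40, 18, 8, 3, 1, 1 — so family maxima are unique and weights span
    (0, 1].
    """
    ladder = [40, 18, 8, 3, 1, 1]
    counts: dict[str, int] = {}
    for family in FAMILIES.values():
        for codon, n in zip(family, ladder):
            counts[codon] = n
    return reference_weights(CodonCounts("ladder reference", counts), pseudocount=0.5)


@pytest.fixture(scope="session")
def best_codons(skewed_weights) -> dict[str, str]:
    """Amino acid -> codon with w = 1 under ``skewed_weights``."""
    out = {}
    for aa, family in FAMILIES.items():
        out[aa] = max(family, key=lambda c: skewed_weights[c])
    return out


@pytest.fixture(scope="session")
def worst_codons(skewed_weights) -> dict[str, str]:
    out = {}
    for aa, family in FAMILIES.items():
        out[aa] = min(family, key=lambda c: skewed_weights[c])
    return out


def random_cds(rng: np.random.Generator, n_codons: int, tid: str = "rand") -> CdsRecord:
    """A random CDS: ATG + random sense codons + TAA."""
    body = rng.choice(len(SENSE_CODONS), size=max(0, n_codons - 2))
    seq = "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"
    return CdsRecord(tid, "", seq)
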