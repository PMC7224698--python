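"""Weight tables, CAI scoring, ranking and rare-codon profiles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from codonstate.cai import (
    WeightTable,
    cai_distribution,
    cai_score,
    percentile_rank,
    rare_codon_profile,
    reference_weights,
    scored_codons,
)
from codonstate.codon_metrics import CodonCounts
from codonstate.errors import ValidationError
from codonstate.genetic_code import AA_OF, FAMILIES, SENSE_CODONS
from codonstate.sequence_io import CdsRecord

from conftest import make_counts, random_cds

scorable = sorted(set(SENSE_CODONS) - {"ATG", "TGG"})


def brute_force_cai(seq: str, weights: WeightTable) -> float:
    """Independent oracle: product of weights, then the n-th root."""
    codons = scored_codons(seq)
    prod = 1.0
    for c in codons:
        prod *= weights[c]
    return prod ** (1.0 / len(codons))


def test_reference_weights_formula():
    # Ile family (ATA, ATC, ATT) with counts 5, 5, 10 and no pseudocount
    counts = make_counts({"ATT": 10, "ATC": 5, "ATA": 5})
    w = reference_weights(counts, pseudocount=0.0)
    assert w["ATT"] == 1.0
    assert w["ATC"] == pytest.approx(0.5)
    assert w["ATA"] == pytest.approx(0.5)
    # Cys family (TGT 10, TGC 0) with pseudocount 0.5
    counts = make_counts({"TGT": 10, "TGC": 0})
    w = reference_weights(counts, pseudocount=0.5)
    assert w["TGT"] == 1.0
    assert w["TGC"] == pytest.approx(0.5 / 10.5)


def test_reference_weights_match_brute_force_family_normalization():
    rng = np.random.default_rng(5)
    counts = CodonCounts(
        "random", {c: int(n) for c, n in zip(SENSE_CODONS, rng.integers(0, 500, 61))}
    )
    w = reference_weights(counts, pseudocount=0.5)
    for family in FAMILIES.values():
        adj = {c: counts.get(c) + 0.5 for c in family}
        top = max(adj.values())
        for c in family:
            assert w[c] == pytest.approx(adj[c] / top, rel=1e-12)
    assert max(w[c] for c in family) == 1.0


def test_zero_family_without_pseudocount_is_an_error():
    counts = CodonCounts("sparse", {"GCT": 10})  # every other family empty
    with pytest.raises(ValidationError, match="undefined"):
        reference_weights(counts, pseudocount=0.0)


def test_cai_of_all_optimal_sequence_is_one(skewed_weights, best_codons):
    seq = "".join(best_codons[aa] for aa in "ACDEFGHIKLNPQRSTVY")
    assert cai_score(seq, skewed_weights).cai == pytest.approx(1.0, abs=1e-12)


def test_cai_two_codon_closed_form():
    # Cys counts 10 vs 5 without pseudocount give w exactly 1.0 and 0.5
    weights = reference_weights(make_counts({"TGT": 10, "TGC": 5}), pseudocount=0.0)
    assert weights["TGC"] == pytest.approx(0.5, abs=0)
    one, half = "GCT", "TGC"  # Ala family is uniform, so GCT has w = 1
    res = cai_score(one + half, weights)
    assert res.n_scored == 2
    assert res.cai == pytest.approx(math.sqrt(0.5), abs=1e-12)


def test_scoring_excludes_stops_met_trp_and_n_codons(skewed_weights):
    seq = "ATG" + "TGG" + "GCN" + "GCT" + "TGA"
    res = cai_score(seq, skewed_weights)
    assert res.n_scored == 1
    assert res.cai == pytest.approx(skewed_weights["GCT"])
    with pytest.raises(ValidationError, match="no scorable"):
        cai_score("ATGTGA", skewed_weights)


@given(st.lists(st.sampled_from(scorable), min_size=1, max_size=30))
def test_cai_equals_brute_force_oracle(skewed_weights, codons):
    seq = "".join(codons)
    assert cai_score(seq, skewed_weights).cai == pytest.approx(
        brute_force_cai(seq, skewed_weights), abs=1e-12
    )


@given(st.lists(st.sampled_from(scorable), min_size=2, max_size=40),
       st.randoms(use_true_random=False))
def test_cai_invariances(skewed_weights, codons, rnd):
    seq = "".join(codons)
    base = cai_score(seq, skewed_weights).cai
    shuffled = list(codons)
    rnd.shuffle(shuffled)
    assert cai_score("".join(shuffled), skewed_weights).cai == pytest.approx(
        base, abs=1e-12
    )
    assert cai_score(seq + seq, skewed_weights).cai == pytest.approx(base, abs=1e-12)


@given(st.lists(st.sampled_from(scorable), min_size=1, max_size=30),
       st.data())
def test_cai_monotone_under_better_synonym(skewed_weights, codons, data):
    i = data.draw(st.integers(0, len(codons) - 1))
    family = FAMILIES[AA_OF[codons[i]]]
    better = [c for c in family if skewed_weights[c] >= skewed_weights[codons[i]]]
    replacement = data.draw(st.sampled_from(better))
    before = cai_score("".join(codons), skewed_weights).cai
    codons = codons[:i] + [replacement] + codons[i + 1 :]
    after = cai_score("".join(codons), skewed_weights).cai
    assert after >= before - 1e-12


def test_percentile_rank_midrank_convention():
    scores = np.array([0.2, 0.5, 0.8])
    assert percentile_rank(scores, 0.1) == 0.0
    assert percentile_rank(scores, 0.5) == pytest.approx(50.0)
    assert percentile_rank(scores, 0.9) == pytest.approx(100.0)
    # ties: below=1, equal=2 -> 100 * (1 + 1) / 4 = 50
    assert percentile_rank(np.array([0.1, 0.5, 0.5, 0.9]), 0.5) == pytest.approx(50.0)


def test_distribution_of_identical_sequences_has_zero_spread(skewed_weights):
    rec = CdsRecord("t1", "G", "ATGGCTCTGTGA")
    dist = cai_distribution([rec] * 5, skewed_weights)
    s = dist.summary()
    assert s["min"] == s["max"] == s["median"]
    assert s["n"] == 5


def test_rare_codon_profile_windows(skewed_weights, best_codons, worst_codons):
    optimal = "".join(best_codons[aa] for aa in "ACDEFGHIK" * 4)
    prof = rare_codon_profile(optimal, skewed_weights, window=9)
    assert (prof["mean_w"] == 1.0).all()
    assert (prof["n_rare"] == 0).all() and (prof["n_extreme"] == 0).all()

    # a rare-codon block placed mid-sequence is localized to its windows
    rare_block = "".join(worst_codons[aa] for aa in "LRSV" * 5)
    seq = optimal + rare_block + optimal
    prof = rare_codon_profile(seq, skewed_weights, window=36)
    n_bad = (prof["n_rare"] + prof["n_extreme"]).to_numpy()
    assert n_bad[1] == 20
    assert n_bad[0] == 0 and n_bad[2] == 0

    # one full-length window reproduces the CAI (geometric-mean relation)
    whole = rare_codon_profile(seq, skewed_weights, window=10**6)
    assert whole.shape[0] == 1
    assert whole["mean_w"].iloc[0] == pytest.approx(
        cai_score(seq, skewed_weights).cai, abs=1e-12
    )


def test_weight_table_csv_round_trip(tmp_path, skewed_weights):
    path = tmp_path / "w.csv"
    skewed_weights.to_csv(path)
    back = WeightTable.from_csv(path)
    for c in SENSE_CODONS:
        assert back[c] == pytest.approx(skewed_weights[c], rel=1e-12)
        assert back.reference_counts[c] == skewed_weights.reference_counts[c]
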