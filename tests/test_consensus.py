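"""Consensus profiles, information content and progressive alignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from talscan.align import alignment_identity, global_align
from talscan.consensus import (
    MAX_BITS,
    align_members,
    build_profile,
    locate_family_motifs,
)
from talscan.motifs import GH23_1P_CONSENSUS, family_1a_reference


def test_identical_sequences_hit_information_ceiling():
    """Zero column entropy gives log2(20) ≈ 4.3219 bits everywhere."""
    prof = build_profile(["ACDEFGHIKL"] * 10, "toy")
    assert prof.info_bits == pytest.approx([MAX_BITS] * 10)
    assert prof.consensus == "ACDEFGHIKL"
    assert MAX_BITS == pytest.approx(math.log2(20))


def test_uniform_column_carries_zero_bits():
    seqs = [aa for aa in "ACDEFGHIKLMNPQRSTVWY"]
    prof = build_profile(seqs, "toy")
    assert prof.info_bits[0] == pytest.approx(0.0, abs=1e-12)


def test_mixed_column_entropy_hand_computed():
    """Column {E,E,E,D}: top frequency 0.75 (below the 0.9 conservation
    threshold) and bits = log2(20) − H(0.75, 0.25)."""
    prof = build_profile(["E", "E", "E", "D"], "toy")
    h = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
    assert prof.info_bits[0] == pytest.approx(MAX_BITS - h)
    assert prof.conserved_positions == []
    prof2 = build_profile(["E"] * 10, "toy")
    assert prof2.conserved_positions == [(0, "E", 1.0)]


def test_profile_frequencies_sum_to_one(small_cohort):
    genomes, truth = small_cohort
    seqs = []
    for g in genomes:
        by_id = {f.gene_id: f for f in g.features}
        for lg in truth.genomes[g.genome_id].lysins.values():
            if lg.tal_class == "TAEP":
                seqs.append(by_id[lg.gene_id].translation[:120])
    assert len(seqs) >= 2
    prof = build_profile(align_members(seqs[:4]), "TAEP")
    sums = prof.columns.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert all(0 <= b <= MAX_BITS + 1e-12 for b in prof.info_bits)


def test_build_profile_input_validation():
    with pytest.raises(ValueError):
        build_profile(["AA", "AAA"], "bad")
    with pytest.raises(ValueError):
        build_profile(["AAA"], "single")


def test_align_identical_pair_has_no_gaps():
    out = align_members(["ACDEFGHIKL", "ACDEFGHIKL"])
    assert out == ["ACDEFGHIKL", "ACDEFGHIKL"]
    assert alignment_identity(*out) == 1.0


def test_classic_toy_pair_matches_dp_oracle():
    """HEAGAWGHEE vs PAWHEAE: score equals an independent affine-gap DP."""
    score, ga, gb = global_align("HEAGAWGHEE", "PAWHEAE")
    oracle = _affine_dp_oracle("HEAGAWGHEE", "PAWHEAE")
    assert score == pytest.approx(oracle)
    assert len(ga) == len(gb)
    assert ga.replace("-", "") == "HEAGAWGHEE"
    assert gb.replace("-", "") == "PAWHEAE"


def test_prefix_sequence_fully_aligned_with_gapped_suffix():
    seqs = ["MKLVVTADEQ", "MKLVVTADEQGHILKWQ", "MKLVVSADEQGHILKWQ"]
    out = align_members(seqs)
    assert len({len(s) for s in out}) == 1
    # the shorter sequence is padded with exactly the missing 7 columns and
    # the full-length members need no gaps at all
    assert out[0].replace("-", "") == seqs[0]
    assert out[0].count("-") == 7
    assert out[1] == seqs[1] and out[2] == seqs[2]


def test_msa_column_count_stable_under_input_order():
    seqs = ["MKLVVTADEQ", "MKLVVTADEQGHILKWQ", "MKLVVSADEQGHILKWQ"]
    a = align_members(seqs)
    b = align_members(seqs[::-1])
    ids_a = sorted(alignment_identity(a[i], a[j]) for i in range(3) for j in range(i + 1, 3))
    ids_b = sorted(alignment_identity(b[i], b[j]) for i in range(3) for j in range(i + 1, 3))
    assert ids_a == pytest.approx(ids_b)


def _affine_dp_oracle(a, b, open_=11.0, extend=1.0):
    """Independent Gotoh recursion, written plainly for small inputs."""
    from Bio.Align import substitution_matrices

    B = substitution_matrices.load("BLOSUM62")
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_ + (i - 1) * extend)
    for j in range(1, m + 1):
        Y[0][j] = -(open_ + (j - 1) * extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = B[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - extend)
            Y[i][j] = max(M[i][j - 1] - open_, X[i][j - 1] - open_, Y[i][j - 1] - extend)
    return max(M[n][m], X[n][m], Y[n][m])


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=15, deadline=None)
def test_pairwise_score_equals_oracle_on_random_short_pairs(seed):
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    a = "".join(rng.choice(aas, size=int(rng.integers(3, 13))))
    b = "".join(rng.choice(aas, size=int(rng.integers(3, 13))))
    score, _, _ = global_align(a, b)
    assert score == pytest.approx(_affine_dp_oracle(a, b))


def test_family_motifs_found_in_order_on_1a_reference():
    prof = build_profile([family_1a_reference()] * 3, "GH23_LT")
    results = locate_family_motifs(prof)
    assert [r[0] for r in results] == ["I", "II", "III", "IV"]
    assert all(matched for _, _, matched in results)
    spans = [span for _, span, _ in results]
    assert all(spans[i][1] <= spans[i + 1][0] + 1 for i in range(3))


def test_family_motif_ii_unmatched_without_downstream_q():
    seq = GH23_1P_CONSENSUS.replace("Q", "A")
    prof = build_profile([seq] * 3, "GH23_LT")
    results = {label: matched for label, _, matched in locate_family_motifs(prof)}
    assert results["II"] is False


def test_shuffled_consensus_rarely_matches_motifs():
    rng = np.random.default_rng(321)
    spurious = []
    for _ in range(20):
        letters = list(GH23_1P_CONSENSUS)
        rng.shuffle(letters)
        prof = build_profile(["".join(letters)] * 3, "shuffled")
        matched = sum(1 for _, _, m in locate_family_motifs(prof) if m)
        spurious.append(matched)
    assert np.mean(spurious) <= 1.5
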