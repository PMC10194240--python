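"""Motif scanning, domain-architecture groups and TAL classification."""

import numpy as np
import pytest

from talscan.genome_io import GeneFeature
from talscan.lysins import (
    CLASS_PRIORITY,
    DomainHit,
    assign_gdpd_da,
    assign_nlpc_da,
    assign_taep_da,
    classify_lt_family,
    classify_lysin,
    scan_domains,
    shuffle_null_fpr,
    verify_catalytic,
)
from talscan.modules import TailModuleLayout
from talscan.motifs import (
    ENDOPEPTIDASE_CONSENSUS,
    FAMILY_1P_EXTRAS,
    GDPD_CONSENSUS,
    GH23_1P_CONSENSUS,
    MotifDefinition,
    default_library,
    family_1a_reference,
    get_motif,
)


def _hit(name, start, end, region, region_ok=True, score=1.0):
    return DomainHit(name, start, end, score, region, region_ok)


def test_consensus_self_match_scores_maximal():
    """Each motif's own consensus yields one covering hit with score 1."""
    for motif in default_library():
        hits = [h for h in scan_domains(motif.consensus, [motif])]
        assert len(hits) == 1
        h = hits[0]
        assert (h.start_aa, h.end_aa) == (0, len(motif))
        assert h.score == pytest.approx(1.0)


def test_shuffled_decoys_produce_no_hits():
    """Uniform-composition decoys stay below every default threshold."""
    rng = np.random.default_rng(99)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    library = default_library()
    for _ in range(50):
        decoy = "".join(rng.choice(aas, size=400))
        assert scan_domains(decoy, library) == []


def test_planted_lt_at_c_terminus_of_long_tmp():
    rng = np.random.default_rng(5)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    protein = "".join(rng.choice(aas, size=1420)) + GH23_1P_CONSENSUS
    hits = scan_domains(protein, [get_motif("GH23_LT")])
    assert len(hits) == 1
    assert hits[0].region == "C_terminal" and hits[0].region_ok


def test_merged_hits_of_one_motif_never_overlap(small_cohort):
    genomes, _ = small_cohort
    library = default_library()
    checked = 0
    for g in genomes[:4]:
        for f in g.features:
            if f.kind != "CDS" or len(f.translation) < 30:
                continue
            hits = scan_domains(f.translation, library)
            by_motif: dict = {}
            for h in hits:
                by_motif.setdefault(h.motif_name, []).append(h)
            for same in by_motif.values():
                same.sort(key=lambda h: h.start_aa)
                for a, b in zip(same, same[1:]):
                    assert a.end_aa <= b.start_aa
            checked += 1
    assert checked > 10


def test_empty_library_is_an_error():
    with pytest.raises(ValueError):
        scan_domains("A" * 100, [])


@pytest.mark.parametrize(
    "extra_hits, expected",
    [
        ([], "TAEP-DA1"),
        ([_hit("lysozyme", 200, 240, "central"), _hit("CHAP", 250, 290, "central")], "TAEP-DA2"),
        ([_hit("lysozyme", 200, 240, "central"), _hit("M23_peptidase", 400, 440, "C_terminal")], "TAEP-DA3"),
        ([_hit("lysozyme", 200, 240, "central"), _hit("amidase", 400, 440, "C_terminal")], "TAEP-DA4"),
        ([_hit("endosialidase_chaperone", 200, 240, "central")], "TAEP-DA5"),
        ([_hit("GDPD", 200, 260, "central")], "TAEP-DA-other"),
    ],
)
def test_assign_taep_da(extra_hits, expected):
    hits = [_hit("endopeptidase", 5, 45, "N_terminal")] + extra_hits
    assert assign_taep_da(hits, 500) == expected


def test_assign_taep_da_requires_n_terminal_endopeptidase():
    with pytest.raises(ValueError):
        assign_taep_da([_hit("lysozyme", 10, 50, "N_terminal")], 500)


@pytest.mark.parametrize(
    "hits, expected",
    [
        ([_hit("NLPC_P60", 150, 198, "central")], "NLPC-DA1"),
        ([_hit("NLPC_P60", 10, 58, "N_terminal")], "NLPC-DA4"),
        ([_hit("NLPC_P60", 150, 198, "central"), _hit("lysozyme", 250, 290, "C_terminal")], "NLPC-DA2"),
        ([_hit("NLPC_P60", 150, 198, "central"), _hit("M23_peptidase", 250, 290, "C_terminal")], "NLPC-DA5"),
    ],
)
def test_assign_nlpc_da(hits, expected):
    assert assign_nlpc_da(hits) == expected


@pytest.mark.parametrize(
    "hits, expected",
    [
        ([_hit("GDPD", 90, 150, "central")], "GDPD-DA1"),
        ([_hit("GDPD", 90, 150, "central"), _hit("membrane", 280, 310, "C_terminal")], "GDPD-DA2"),
        ([_hit("baseplate_upper", 5, 45, "N_terminal"), _hit("GDPD", 400, 460, "C_terminal")], "GDPD-DA3"),
    ],
)
def test_assign_gdpd_da(hits, expected):
    assert assign_gdpd_da(hits) == expected


def _gene(gene_id="tal1", aa=500):
    return GeneFeature(gene_id=gene_id, start=0, end=3 * (aa + 1), product="tail protein",
                       translation="M" * aa)


def test_classify_tmp_lt_call():
    layout = TailModuleLayout(tail_gene_ids=["tmp1"], tmp_id="tmp1")
    call = classify_lysin(_gene("tmp1", 1500), layout,
                          [_hit("GH23_LT", 1400, 1480, "C_terminal")])
    assert call.tal_class == "TMP_LT" and call.in_tmp


def test_classify_taep_in_tal_position():
    layout = TailModuleLayout(tail_gene_ids=["tmp1", "dit1", "tal1"],
                              tmp_id="tmp1", dit_id="dit1", tal_id="tal1")
    call = classify_lysin(_gene("tal1"), layout, [_hit("endopeptidase", 5, 45, "N_terminal")])
    assert call.tal_class == "TAEP" and call.da_group == "TAEP-DA1"
    assert call.in_tal_position and not call.in_tmp


def test_classify_no_hits_is_none():
    layout = TailModuleLayout(tail_gene_ids=["tal1"])
    call = classify_lysin(_gene(), layout, [])
    assert call.tal_class == "none" and call.da_group == ""


def test_class_priority_is_total_and_single_class():
    """A protein with hits from two classes gets exactly one class and keeps
    the loser as a secondary class."""
    layout = TailModuleLayout(tail_gene_ids=["tal1"])
    call = classify_lysin(_gene(), layout,
                          [_hit("endopeptidase", 5, 45, "N_terminal"),
                           _hit("GDPD", 200, 260, "central")])
    assert call.tal_class == "TAEP"
    assert call.secondary_classes == ["GDPD"]
    assert len(CLASS_PRIORITY) == len(set(CLASS_PRIORITY))


def test_verify_catalytic_gdpd_consensus_true_and_mutated_false():
    layout = TailModuleLayout(tail_gene_ids=["g"])
    gene = GeneFeature("g", 0, 3 * (len(GDPD_CONSENSUS) + 1), product="tail protein",
                       translation=GDPD_CONSENSUS)
    call = classify_lysin(gene, layout, scan_domains(GDPD_CONSENSUS))
    assert call.tal_class == "GDPD"
    assert verify_catalytic(GDPD_CONSENSUS, call) is True

    mutated = list(GDPD_CONSENSUS)
    mutated[7] = "A"  # first catalytic histidine
    mutated = "".join(mutated)
    call2 = classify_lysin(gene, layout, scan_domains(mutated))
    assert verify_catalytic(mutated, call2) is False


def test_verify_catalytic_planted_tmp_lt():
    rng = np.random.default_rng(8)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    protein = "".join(rng.choice(aas, size=1300)) + GH23_1P_CONSENSUS
    layout = TailModuleLayout(tail_gene_ids=["tmp"], tmp_id="tmp")
    gene = GeneFeature("tmp", 0, 3 * (len(protein) + 1), product="tape measure protein",
                       translation=protein)
    call = classify_lysin(gene, layout, scan_domains(protein))
    assert call.tal_class == "TMP_LT"
    assert verify_catalytic(protein, call) is True


def test_lt_family_1p_and_boundary_to_1a():
    assert classify_lt_family(GH23_1P_CONSENSUS) == "1P"
    # mutate the extra conserved positions but keep motifs I–IV intact
    mutated = list(GH23_1P_CONSENSUS)
    for col, _aa in FAMILY_1P_EXTRAS:
        mutated[col - 1] = "K"
    assert classify_lt_family("".join(mutated)) == "1A"
    assert classify_lt_family(family_1a_reference()) == "1A"


def test_lt_family_requires_catalytic_glutamate():
    mutated = list(GH23_1P_CONSENSUS)
    mutated[5] = "A"
    assert classify_lt_family("".join(mutated)) == "unassigned"


def test_every_1p_satisfies_1a_criteria(small_results):
    """Family 1P is a refinement of 1A: its members pass the 1A motif checks."""
    results, _ = small_results
    n_1p = 0
    for r in results:
        for c in r.lysin_calls():
            if c.lt_family == "1P":
                n_1p += 1
    assert n_1p > 0  # the planted TMP-LTs


def test_region_constraints_reported(small_results):
    """TAEP endopeptidase hits are N-terminal; TMP-LT hits are C-terminal."""
    results, _ = small_results
    for r in results:
        for c in r.lysin_calls():
            if c.tal_class == "TAEP":
                ep = [h for h in c.hits if h.motif_name == "endopeptidase"]
                assert ep and all(h.region == "N_terminal" and h.region_ok for h in ep)
            if c.tal_class == "TMP_LT":
                lt = [h for h in c.hits if h.motif_name == "GH23_LT"]
                assert lt and all(h.region == "C_terminal" and h.region_ok for h in lt)


def test_shuffle_null_fpr_quick():
    """Reduced-size shuffle null stays within the calibrated 1% bound."""
    assert shuffle_null_fpr(n_decoys=100, decoy_length=400, seed=7) <= 0.01
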