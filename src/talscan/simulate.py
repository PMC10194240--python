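"""Synthetic annotated phage/prophage genomes with planted ground truth.

Each simulated genome follows the canonical functional-module order
(Packaging – Head – Tail – Lysis – [Lysogeny] – DNA metabolism) with
morphotype-specific tail contents:

* sipho1 (21–43 kb): TMP carrying a C-terminal GH23 LT + a TAEP in the Tal
  position (both-lysin arrangement);
* sipho2 (55–86 kb): TMP without an LT, TAEP in the Tal position;
* myo (130.9–156.5 kb): TMP-LT plus an adjacent NLPC/P60 tail protein;
* podo (17.9–30.5 kb): no TMP/Dit/Tal unit; an NLPC/P60 tailspike-like gene
  sits between the head and lysis modules.

Planted lysin translations embed the packaged class consensus at the class's
declared protein region; all other protein sequence is uniform-random and
intergenic DNA is uniform-random at a configurable GC (default 0.35, near
the enterococcal cohort average).  Annotation noise (hypothetical renaming,
product shuffling, Dit dropping) is applied after planting.  Everything is
reproducible from the seed, and every planted element is recorded in a
machine-readable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from talscan.genome_io import GeneFeature, GenomeRecord
from talscan.landscape import assign_size_group
from talscan.motifs import (
    AMIDASE_CONSENSUS,
    AMINO_ACIDS,
    BASEPLATE_UPPER_CONSENSUS,
    CHAP_CONSENSUS,
    ENDOPEPTIDASE_CONSENSUS,
    ENDOSIALIDASE_CHAPERONE_CONSENSUS,
    GDPD_CONSENSUS,
    GH23_1P_CONSENSUS,
    LYSOZYME_CONSENSUS,
    M23_CONSENSUS,
    MEMBRANE_CONSENSUS,
    NLPC_CONSENSUS,
    PECTINESTERASE_CONSENSUS,
)

MORPHOTYPES = ("podo", "sipho1", "sipho2", "myo")
SIZE_RANGES_KB = {
    "podo": (17.9, 30.5),
    "sipho1": (21.0, 43.0),
    "sipho2": (55.0, 86.0),
    "myo": (130.9, 156.5),
}
MORPH_HINT = {
    "podo": "podovirus",
    "sipho1": "siphovirus",
    "sipho2": "siphovirus",
    "myo": "myovirus",
}
MORPH_ARRANGEMENT = {
    "podo": "no_tal",
    "sipho1": "tmplt_and_taep",
    "sipho2": "taep_in_tal_only",
    "myo": "tmplt_only",
}

# Cohort composition defaults: the study set is 18% podoviruses, 64%
# siphoviruses (split ~40/24 between size groups 1 and 2) and 18% myoviruses.
DEFAULT_MORPHOTYPE_MIX = {"podo": 0.18, "sipho1": 0.40, "sipho2": 0.24, "myo": 0.18}
# Class mix defaults follow the published census (383/98/34/22/7 of 544).
DEFAULT_CLASS_MIX = {
    "TAEP": 383 / 544,
    "TMP_LT": 98 / 544,
    "NLPC_P60": 34 / 544,
    "GDPD": 22 / 544,
    "PECTINESTERASE": 7 / 544,
}
# TAEP domain-architecture mix: DA1 dominates (60.5% of TAEPs), the
# remainder spread over DA2–DA5.
TAEP_DA_MIX = {"TAEP-DA1": 0.605, "TAEP-DA2": 0.099, "TAEP-DA3": 0.099,
               "TAEP-DA4": 0.099, "TAEP-DA5": 0.098}
GDPD_DA_MIX = {"GDPD-DA1": 0.6, "GDPD-DA2": 0.2, "GDPD-DA3": 0.2}
NLPC_PODO_DA_MIX = {"NLPC-DA1": 0.6, "NLPC-DA4": 0.3, "NLPC-DA2": 0.1}
NLPC_MYO_DA_MIX = {"NLPC-DA1": 0.5, "NLPC-DA5": 0.5}

TMP_LT_LENGTH_RANGE = (1180, 2254)  # aa, TMP-LT proteins
GDPD_PROTEIN_LENGTH = 240  # aa, typical bare-GDPD protein


@dataclass
class NoiseConfig:
    p_hypothetical: float = 0.0  # per-gene product → "hypothetical protein"
    p_shuffle: float = 0.0  # fraction of genes whose products are permuted
    p_drop_dit: float = 0.0  # per-genome chance of losing the Dit gene

    def __post_init__(self) -> None:
        for name in ("p_hypothetical", "p_shuffle", "p_drop_dit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class SimConfig:
    n_genomes: int = 50
    morphotype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOTYPE_MIX)
    )
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    temperate_fraction: float = 0.16
    gc: float = 0.35
    source_kind: str = "phage"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        for mix, keys in ((self.morphotype_mix, MORPHOTYPES), (self.class_mix, tuple(DEFAULT_CLASS_MIX))):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"mix proportions must sum to 1: {mix}")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"negative proportion in {mix}")
            unknown = set(mix) - set(keys)
            if unknown:
                raise ValueError(f"unknown mix keys {unknown}")
        if not 0.0 <= self.temperate_fraction <= 1.0:
            raise ValueError("temperate_fraction must be in [0,1]")


@dataclass
class LysinTruth:
    gene_id: str
    tal_class: str
    da_group: str
    lt_family: str = "not_applicable"


@dataclass
class GenomeTruth:
    genome_id: str
    morphotype: str
    size_group: str
    module_order: list[str]
    tmp_id: str | None
    dit_id: str | None
    tal_id: str | None
    temperate: bool
    arrangement: str
    lysins: dict[str, LysinTruth] = field(default_factory=dict)


@dataclass
class GroundTruth:
    genomes: dict[str, GenomeTruth] = field(default_factory=dict)

    def genome_rows(self) -> list[dict]:
        return [
            {
                "genome_id": t.genome_id,
                "morphotype": t.morphotype,
                "size_group": t.size_group,
                "module_order": ",".join(t.module_order),
                "tmp_id": t.tmp_id or "",
                "dit_id": t.dit_id or "",
                "tal_id": t.tal_id or "",
                "temperate": str(t.temperate),
                "arrangement": t.arrangement,
            }
            for t in self.genomes.values()
        ]

    def lysin_rows(self) -> list[dict]:
        return [
            {
                "genome_id": t.genome_id,
                "gene_id": l.gene_id,
                "tal_class": l.tal_class,
                "da_group": l.da_group,
                "lt_family": l.lt_family,
            }
            for t in self.genomes.values()
            for l in t.lysins.values()
        ]


# ------------------------- sequence building blocks -------------------------

_AA_ARRAY = np.array(list(AMINO_ACIDS))

# codon table 11 (bacterial), one codon list per amino acid
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}.items():
    _CODONS.setdefault(_aa, []).append(_codon)
_STOPS = ["TAA", "TAG", "TGA"]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_ARRAY, size=length))


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("AGCT")), size=length, p=probs))


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [_CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein]
    codons.append(_STOPS[int(rng.integers(len(_STOPS)))])
    return "".join(codons)


def _embed(rng: np.random.Generator, length: int, inserts: list[tuple[str, str]]) -> str:
    """Random protein of ``length`` with consensus blocks at named regions.

    ``inserts`` pairs (region, consensus) with region one of N_terminal /
    central / C_terminal; blocks are placed at the centre of the requested
    tercile so the scanner's midpoint-tercile check holds.
    """
    seq = list(_random_protein(rng, length))
    for region, block in inserts:
        L = len(block)
        if region == "N_terminal":
            lo, hi = 0, length // 3
        elif region == "central":
            lo, hi = length // 3, 2 * length // 3
        else:
            lo, hi = 2 * length // 3, length
        start = max(lo, (lo + hi - L) // 2)
        if start + L > length:
            start = length - L
        seq[start : start + L] = list(block)
    return "".join(seq)


def _choose(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = list(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


# ----------------------------- gene planning --------------------------------


@dataclass
class _GenePlan:
    product: str
    translation: str
    kind: str = "CDS"
    role: str = ""  # tmp | dit | tal | lysin-bearing marker for ground truth


def _plan_taep(rng: np.random.Generator, da: str) -> str:
    """Tal-position protein translation for a given TAEP architecture."""
    length = int(rng.integers(380, 620))
    inserts = [("N_terminal", ENDOPEPTIDASE_CONSENSUS)]
    if da == "TAEP-DA2":
        inserts += [("central", LYSOZYME_CONSENSUS + "GS" + CHAP_CONSENSUS)]
    elif da == "TAEP-DA3":
        inserts += [("central", LYSOZYME_CONSENSUS), ("C_terminal", M23_CONSENSUS)]
    elif da == "TAEP-DA4":
        inserts += [("central", LYSOZYME_CONSENSUS), ("C_terminal", AMIDASE_CONSENSUS)]
    elif da == "TAEP-DA5":
        inserts += [("central", ENDOSIALIDASE_CHAPERONE_CONSENSUS)]
    return _embed(rng, length, inserts)


def _plan_nlpc(rng: np.random.Generator, da: str) -> str:
    length = int(rng.integers(260, 420))
    if da == "NLPC-DA4":
        inserts = [("N_terminal", NLPC_CONSENSUS)]
    elif da == "NLPC-DA2":
        inserts = [("central", NLPC_CONSENSUS), ("C_terminal", LYSOZYME_CONSENSUS)]
    elif da == "NLPC-DA5":
        inserts = [("central", NLPC_CONSENSUS), ("C_terminal", M23_CONSENSUS)]
    else:
        inserts = [("central", NLPC_CONSENSUS)]
    return _embed(rng, length, inserts)


def _plan_gdpd(rng: np.random.Generator, da: str) -> str:
    if da == "GDPD-DA2":
        length = int(rng.integers(280, 360))
        inserts = [("central", GDPD_CONSENSUS), ("C_terminal", MEMBRANE_CONSENSUS)]
    elif da == "GDPD-DA3":
        length = int(rng.integers(420, 560))
        inserts = [("N_terminal", BASEPLATE_UPPER_CONSENSUS), ("C_terminal", GDPD_CONSENSUS)]
    else:
        length = GDPD_PROTEIN_LENGTH
        inserts = [("central", GDPD_CONSENSUS)]
    return _embed(rng, length, inserts)


_DNA_PRODUCTS = (
    "DNA polymerase",
    "DNA helicase",
    "DNA primase",
    "exonuclease",
    "HNH homing endonuclease",
    "DNA ligase",
    "ribonucleotide reductase",
    "DNA methyltransferase",
)


def _simulate_genome(
    rng: np.random.Generator, cfg: SimConfig, morphotype: str, genome_id: str
) -> tuple[GenomeRecord, GenomeTruth]:
    lo, hi = SIZE_RANGES_KB[morphotype]
    # leave headroom so filler genes cannot push the genome past its range
    target_bp = int(rng.uniform(lo + 0.5, hi - 2.5) * 1000)

    temperate = bool(rng.random() < cfg.temperate_fraction)
    plans: list[_GenePlan] = []
    lysin_plans: dict[int, LysinTruth] = {}  # index into plans

    # packaging + head
    plans.append(_GenePlan("terminase small subunit", _random_protein(rng, int(rng.integers(140, 180)))))
    plans.append(_GenePlan("terminase large subunit", _random_protein(rng, int(rng.integers(380, 460)))))
    plans.append(_GenePlan("portal protein", _random_protein(rng, int(rng.integers(360, 440)))))
    plans.append(_GenePlan("scaffolding protein", _random_protein(rng, int(rng.integers(180, 260)))))
    plans.append(_GenePlan("major capsid protein", _random_protein(rng, int(rng.integers(300, 380)))))
    plans.append(_GenePlan("head-tail connector protein", _random_protein(rng, int(rng.integers(110, 160)))))

    tmp_idx = dit_idx = tal_idx = None
    if morphotype == "podo":
        # short-tailed: no TMP/Dit/Tal; NLPC tailspike between head and lysis
        da = _choose(rng, NLPC_PODO_DA_MIX)
        plans.append(_GenePlan("tailspike protein", _plan_nlpc(rng, da), role="nlpc"))
        lysin_plans[len(plans) - 1] = LysinTruth("", "NLPC_P60", da)
        plans.append(_GenePlan("tail fiber protein", _random_protein(rng, int(rng.integers(250, 380)))))
    else:
        plans.append(_GenePlan("major tail protein", _random_protein(rng, int(rng.integers(160, 220)))))
        has_lt = morphotype in ("sipho1", "myo")
        if has_lt:
            tmp_len = int(rng.integers(*TMP_LT_LENGTH_RANGE))
            tmp_seq = _embed(rng, tmp_len, [("C_terminal", GH23_1P_CONSENSUS)])
        else:
            tmp_len = int(rng.integers(900, 1400))
            tmp_seq = _random_protein(rng, tmp_len)
        plans.append(_GenePlan("tail tape measure protein", tmp_seq, role="tmp"))
        tmp_idx = len(plans) - 1
        if has_lt:
            lysin_plans[tmp_idx] = LysinTruth("", "TMP_LT", "TMPLT-DA1", "1P")
        # Dit: frequently annotated only as a hypothetical protein
        dit_product = "distal tail protein" if rng.random() < 0.5 else "hypothetical protein"
        plans.append(_GenePlan(dit_product, _random_protein(rng, int(rng.integers(100, 150))), role="dit"))
        dit_idx = len(plans) - 1
        if morphotype == "myo":
            plans.append(_GenePlan("tail protein", _random_protein(rng, int(rng.integers(300, 500))), role="tal"))
            tal_idx = len(plans) - 1
            da = _choose(rng, NLPC_MYO_DA_MIX)
            plans.append(_GenePlan("tail protein", _plan_nlpc(rng, da), role="nlpc"))
            lysin_plans[len(plans) - 1] = LysinTruth("", "NLPC_P60", da)
            plans.append(_GenePlan("baseplate protein", _random_protein(rng, int(rng.integers(220, 320)))))
        else:
            da = _choose(rng, TAEP_DA_MIX)
            plans.append(_GenePlan("tail protein", _plan_taep(rng, da), role="tal"))
            tal_idx = len(plans) - 1
            lysin_plans[tal_idx] = LysinTruth("", "TAEP", da)
            # optional extras at rates tied to the class mix (per-TAEP odds)
            p_gdpd = cfg.class_mix.get("GDPD", 0.0) / max(cfg.class_mix.get("TAEP", 1.0), 1e-9)
            p_pe = cfg.class_mix.get("PECTINESTERASE", 0.0) / max(cfg.class_mix.get("TAEP", 1.0), 1e-9)
            if rng.random() < p_pe:
                plans.append(_GenePlan(
                    "tail protein",
                    _embed(rng, int(rng.integers(320, 420)), [("central", PECTINESTERASE_CONSENSUS)]),
                    role="pe"))
                lysin_plans[len(plans) - 1] = LysinTruth("", "PECTINESTERASE", "PE-DA1")
            if rng.random() < p_gdpd:
                gda = _choose(rng, GDPD_DA_MIX)
                plans.append(_GenePlan("tail protein", _plan_gdpd(rng, gda), role="gdpd"))
                lysin_plans[len(plans) - 1] = LysinTruth("", "GDPD", gda)
        plans.append(_GenePlan("tail fiber protein", _random_protein(rng, int(rng.integers(250, 400)))))

    # lysis
    plans.append(_GenePlan("holin", _random_protein(rng, int(rng.integers(70, 110)))))
    plans.append(_GenePlan("endolysin", _random_protein(rng, int(rng.integers(240, 320)))))

    module_order = ["packaging", "head", "tail", "lysis"]
    if temperate:
        plans.append(_GenePlan("integrase", _random_protein(rng, int(rng.integers(340, 420)))))
        if rng.random() < 0.5:
            plans.append(_GenePlan("CI repressor", _random_protein(rng, int(rng.integers(180, 240)))))
        module_order.append("lysogeny")
    module_order.append("dna_metabolism")

    # DNA metabolism fillers up to the target size
    approx_bp = sum(3 * (len(p.translation) + 1) + 80 for p in plans) + 200
    k = 0
    while approx_bp < target_bp:
        product = _DNA_PRODUCTS[k % len(_DNA_PRODUCTS)]
        aa = int(rng.integers(150, 450))
        plans.append(_GenePlan(product, _random_protein(rng, aa)))
        approx_bp += 3 * (aa + 1) + 80
        k += 1
    if k == 0:  # always close with a DNA-metabolism module
        plans.append(_GenePlan(_DNA_PRODUCTS[0], _random_protein(rng, 200)))

    # tRNAs: larger genomes carry more (podoviruses none)
    n_trna = {"podo": 0, "sipho1": int(rng.integers(0, 3)),
              "sipho2": int(rng.integers(2, 7)), "myo": int(rng.integers(8, 16))}[morphotype]

    # ---- apply annotation noise (sequences untouched) ----
    noise = cfg.noise
    drop_dit = dit_idx is not None and rng.random() < noise.p_drop_dit
    products = [p.product for p in plans]
    if noise.p_shuffle > 0:
        idxs = [i for i in range(len(plans)) if rng.random() < noise.p_shuffle]
        if len(idxs) > 1:
            shuffled = [products[i] for i in idxs]
            perm = rng.permutation(len(idxs))
            for slot, src in zip(idxs, perm):
                products[slot] = shuffled[int(src)]
    if noise.p_hypothetical > 0:
        for i in range(len(plans)):
            if rng.random() < noise.p_hypothetical:
                products[i] = "hypothetical protein"

    # ---- lay out the genome ----
    features: list[GeneFeature] = []
    seq_parts: list[str] = []
    cursor = 0
    gene_num = 0
    truth_lysins: dict[str, LysinTruth] = {}
    tmp_id = dit_id = tal_id = None
    for i, plan in enumerate(plans):
        if i == dit_idx and drop_dit:
            continue
        gap = int(rng.integers(20, 120))
        seq_parts.append(_random_dna(rng, gap, cfg.gc))
        cursor += gap
        nt = _reverse_translate(rng, plan.translation)
        gene_num += 1
        gid = f"{genome_id}_g{gene_num:03d}"
        features.append(
            GeneFeature(gene_id=gid, start=cursor, end=cursor + len(nt),
                        strand="forward", kind="CDS", product=products[i],
                        translation=plan.translation)
        )
        seq_parts.append(nt)
        cursor += len(nt)
        if i == tmp_idx:
            tmp_id = gid
        elif i == dit_idx:
            dit_id = gid
        elif i == tal_idx:
            tal_id = gid
        if i in lysin_plans:
            lt = replace(lysin_plans[i], gene_id=gid)
            truth_lysins[gid] = lt
    for _ in range(n_trna):
        gap = int(rng.integers(10, 40))
        seq_parts.append(_random_dna(rng, gap, cfg.gc))
        cursor += gap
        nt = _random_dna(rng, 76, cfg.gc)
        gene_num += 1
        gid = f"{genome_id}_g{gene_num:03d}"
        features.append(GeneFeature(gene_id=gid, start=cursor, end=cursor + 76,
                                    strand="forward", kind="tRNA",
                                    product="tRNA", translation=""))
        seq_parts.append(nt)
        cursor += 76
    tail_gap = int(rng.integers(50, 200))
    seq_parts.append(_random_dna(rng, tail_gap, cfg.gc))
    cursor += tail_gap

    genome = GenomeRecord(
        genome_id=genome_id,
        length_bp=cursor,
        features=features,
        sequence="".join(seq_parts),
        topology="linear",
        source_kind=cfg.source_kind,
        morphology_hint=MORPH_HINT[morphotype],
    )
    size_group = assign_size_group(cursor / 1000.0, MORPH_HINT[morphotype]).value
    truth = GenomeTruth(
        genome_id=genome_id,
        morphotype=morphotype,
        size_group=size_group,
        module_order=module_order,
        tmp_id=tmp_id,
        dit_id=None if drop_dit else dit_id,
        tal_id=tal_id,
        temperate=temperate,
        arrangement=MORPH_ARRANGEMENT[morphotype],
        lysins=truth_lysins,
    )
    return genome, truth


def simulate_cohort(cfg: SimConfig) -> tuple[list[GenomeRecord], GroundTruth]:
    """Generate a seeded cohort of annotated genomes with ground truth."""
    rng = np.random.default_rng(cfg.seed)
    morphs = [_choose(rng, cfg.morphotype_mix) for _ in range(cfg.n_genomes)]
    genomes: list[GenomeRecord] = []
    truth = GroundTruth()
    for i, morph in enumerate(morphs):
        gid = f"SYN-{morph}-{i:03d}"
        g, t = _simulate_genome(rng, cfg, morph, gid)
        genomes.append(g)
        truth.genomes[gid] = t
    return genomes, truth


def mutate_motif(
    protein: str, positions: list[int], rate: float, seed: int
) -> tuple[str, list[tuple[int, str, str]]]:
    """Seeded substitutions at given 0-based positions.

    Each listed position is substituted with probability ``rate`` by a
    residue different from the original.  Returns the mutated sequence and
    the realized substitution list (position, old, new).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    seq = list(protein)
    subs: list[tuple[int, str, str]] = []
    for pos in positions:
        if rng.random() < rate:
            old = seq[pos]
            choices = [a for a in AMINO_ACIDS if a != old]
            new = choices[int(rng.integers(len(choices)))]
            seq[pos] = new
            subs.append((pos, old, new))
    return "".join(seq), subs
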