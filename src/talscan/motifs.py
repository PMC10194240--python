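"""Packaged motif library for tail-associated lysin domain detection.

The five TAL classes and their accessory domains are detected with
position-constrained residue patterns rather than live Pfam/CDD queries.
Each :class:`MotifDefinition` carries a consensus-derived pattern (a set of
allowed residues per column), a region constraint (which tercile of the
protein the domain is expected in), and a calibrated score threshold.

The consensus backbones below are SYNTHETIC: outside the positions whose
residues are fixed by published domain knowledge (the GH23 lytic
transglycosylase motifs I–IV and family-1P extras, the GDPD catalytic
His/His and metal-binding Glu/Glu/Asp, the NLPC/P60 catalytic Cys…His
dyad), columns were filled once with seeded random residues and frozen.
They stand in for family alignments that would normally come from curated
databases; an external domain-hit table can bypass this scanner entirely
(see :func:`talscan.lysins.read_domain_hit_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = frozenset("AILVFMW")

# Similar-residue groups used to widen pattern columns one step beyond the
# consensus residue (BLOSUM-positive neighbourhoods, coarse).
_SIMILAR = {
    "A": "AG", "G": "GA", "S": "ST", "T": "TS", "C": "C",
    "D": "DE", "E": "ED", "N": "NQ", "Q": "QN",
    "K": "KR", "R": "RK", "H": "H",
    "I": "ILV", "L": "LIV", "V": "VIL", "M": "MIL",
    "F": "FY", "Y": "YF", "W": "W", "P": "P",
}


@dataclass
class MotifDefinition:
    """A position-constrained residue pattern with a region constraint."""

    name: str
    pattern: list[frozenset[str]]
    region: str = "any"  # N_terminal | central | C_terminal | any
    min_score: float = 0.8
    consensus: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name}: empty pattern")
        if self.region not in ("N_terminal", "central", "C_terminal", "any"):
            raise ValueError(f"motif {self.name}: bad region {self.region!r}")
        if not self.consensus:
            self.consensus = "".join(sorted(col)[0] for col in self.pattern)

    def __len__(self) -> int:
        return len(self.pattern)


def _pattern_from_consensus(consensus: str, widen: bool = True) -> list[frozenset[str]]:
    cols = []
    for aa in consensus:
        allowed = _SIMILAR.get(aa, aa) if widen else aa
        cols.append(frozenset(allowed))
    return cols


# --- GH23 lytic transglycosylase (TMP-LT) reference, family 1P frame -------
# 1-based feature columns in this 80-column frame:
#   motif I  : E6 (catalytic glutamate, proton donor), S7
#   motif II : G25-L26-M27-Q28 (GxxQ core at 25/28)
#   motif III: A40-Y41-N42 (A/G tolerated at 40)
#   motif IV : Y74 flanked by hydrophobic L73/I75
#   family-1P extras: T46, F47, G54, I59, L67, A68
GH23_1P_CONSENSUS = (
    "YYLSLESDQAHIVLWDIRAKGNYSGLMQIGTQICWMIQSAYNPFETFQYIHSCGRNDDIHFNQWWILAAGWVLYITVTLW"
)
GH23_MOTIF_I = (6, 7)            # E, S
GH23_MOTIF_II = (25, 26, 27, 28)  # G, l, M, Q — G and Q (GxxQ) required
GH23_MOTIF_III = (40, 41, 42)     # A/G, Y, N
GH23_MOTIF_IV = 74                # Y, hydrophobic flank at 73/75
GH23_CATALYTIC_E = 6
FAMILY_1P_EXTRAS = ((46, "T"), (47, "F"), (54, "G"), (59, "I"), (67, "L"), (68, "A"))

# Family 1E reference (N-terminal LT of podovirus-style outliers, T7-gp16-like):
# shares motifs I–IV columns but diverges elsewhere, including the 1P extras.
GH23_1E_CONSENSUS = (
    "KCVGMESCGDQKSWLAAAWAPRRGGIAQAPMQLGDSFGRGYNLLKDRCSNDISNFHHWISWSIWRESQSQRHVYLFQIFP"
)

# --- GDPD (glycerophosphodiester phosphodiesterase) ------------------------
# 1-based columns: catalytic H8 and H25 (general acid/base); metal-binding
# E12, E40, D48 (two glutamates and an aspartate).
GDPD_CONSENSUS = "TFQLTQSHSYHESQAGMENVCWNAHESYIRTVPFKTMEGEGLINGQMDLMQMAYAEMLMK"
GDPD_CATALYTIC_H = (8, 25)
GDPD_METAL = ((12, "E"), (40, "E"), (48, "D"))

# --- NLPC/P60 papain-like peptidase ----------------------------------------
# catalytic N-terminal cysteine (col 6) and C-terminal histidine (col 44)
NLPC_CONSENSUS = "MEDFFCDIVPGSFGESEHIGIVGICYGWYSFLQGDSVGLGQSDHARPH"

# --- remaining domains: synthetic placeholder consensuses ------------------
ENDOPEPTIDASE_CONSENSUS = "WGFACIDMLITTRPSIVLQSRHPTSFSFRRLEAVFIEHTP"
LYSOZYME_CONSENSUS = "YNQDKEIGVRDQTQIHIRQGGVAPGREEKEKKASMDLANN"
CHAP_CONSENSUS = "THVSYDMYAMCNVTDRYRCLSPNEPTCGLLFVLHVAHRMN"
M23_CONSENSUS = "SNSFPGEMWPQPDEATCRKYRFMRDDVHNESQPHGIEEFK"
AMIDASE_CONSENSUS = "MCVPCYFVCEPLKGASWQDPVATYVHRMPDSPRLSLDVFN"
ENDOSIALIDASE_CHAPERONE_CONSENSUS = "KPESYSYYAQDNHGIEPTAKKQVDASCFTEDTYLSASQNT"
PECTINESTERASE_CONSENSUS = "QFGVRFDEAHSLEAPCDRPCSNYFLPHPHEWELIAGKDVI"
BASEPLATE_UPPER_CONSENSUS = "TGGKHQHECCCPWQNICVVTVMTLIETWFAWYARSFDGEC"
MEMBRANE_CONSENSUS = "VWWFWALWIAAWVFAWFWLIMFMFLAIFLW"


def default_library() -> list[MotifDefinition]:
    """The packaged motif library.

    ``min_score`` defaults (0.8 for consensus patterns, 0.9 for the
    low-complexity hydrophobic membrane pattern) were calibrated against a
    seeded shuffle null so that fewer than 1% of length-matched shuffled
    decoys produce a hit (see :func:`talscan.lysins.shuffle_null_fpr`).
    """
    lib = [
        MotifDefinition("endopeptidase", _pattern_from_consensus(ENDOPEPTIDASE_CONSENSUS),
                        region="N_terminal", consensus=ENDOPEPTIDASE_CONSENSUS),
        MotifDefinition("lysozyme", _pattern_from_consensus(LYSOZYME_CONSENSUS),
                        region="any", consensus=LYSOZYME_CONSENSUS),
        MotifDefinition("CHAP", _pattern_from_consensus(CHAP_CONSENSUS),
                        region="any", consensus=CHAP_CONSENSUS),
        MotifDefinition("M23_peptidase", _pattern_from_consensus(M23_CONSENSUS),
                        region="C_terminal", consensus=M23_CONSENSUS),
        MotifDefinition("amidase", _pattern_from_consensus(AMIDASE_CONSENSUS),
                        region="C_terminal", consensus=AMIDASE_CONSENSUS),
        MotifDefinition("endosialidase_chaperone",
                        _pattern_from_consensus(ENDOSIALIDASE_CHAPERONE_CONSENSUS),
                        region="any", consensus=ENDOSIALIDASE_CHAPERONE_CONSENSUS),
        MotifDefinition("NLPC_P60", _pattern_from_consensus(NLPC_CONSENSUS),
                        region="any", consensus=NLPC_CONSENSUS),
        MotifDefinition("GH23_LT", _pattern_from_consensus(GH23_1P_CONSENSUS),
                        region="C_terminal", consensus=GH23_1P_CONSENSUS),
        MotifDefinition("GDPD", _pattern_from_consensus(GDPD_CONSENSUS),
                        region="any", consensus=GDPD_CONSENSUS),
        MotifDefinition("membrane",
                        [HYDROPHOBIC] * len(MEMBRANE_CONSENSUS),
                        region="any", min_score=0.9, consensus=MEMBRANE_CONSENSUS),
        MotifDefinition("baseplate_upper", _pattern_from_consensus(BASEPLATE_UPPER_CONSENSUS),
                        region="N_terminal", consensus=BASEPLATE_UPPER_CONSENSUS),
        MotifDefinition("pectinesterase", _pattern_from_consensus(PECTINESTERASE_CONSENSUS),
                        region="central", consensus=PECTINESTERASE_CONSENSUS),
    ]
    return lib


def get_motif(name: str, library: list[MotifDefinition] | None = None) -> MotifDefinition:
    for m in library or default_library():
        if m.name == name:
            return m
    raise KeyError(name)


@dataclass
class ResidueRule:
    """Class-specific conserved residues, in the class alignment frame.

    ``required`` pairs (residue letter, 1-based consensus column).  Columns
    refer to the packaged class consensus, not absolute protein coordinates.
    """

    class_name: str
    required: list[tuple[str, int]]
    description: str = ""


def default_residue_rules() -> list[ResidueRule]:
    return [
        ResidueRule(
            "GH23_LT",
            [("E", GH23_CATALYTIC_E)],
            "GH23 catalytic glutamate, active-site proton donor",
        ),
        ResidueRule(
            "GDPD",
            [("H", GDPD_CATALYTIC_H[0]), ("H", GDPD_CATALYTIC_H[1])]
            + [(aa, col) for col, aa in GDPD_METAL],
            "two catalytic histidines plus Glu/Glu/Asp metal-binding residues",
        ),
    ]


def family_1a_reference() -> str:
    """GH23 family-1A reference: motifs I–IV intact, 1P extras reverted."""
    s = list(GH23_1P_CONSENSUS)
    for col, _aa in FAMILY_1P_EXTRAS:
        s[col - 1] = "K" if s[col - 1] != "K" else "R"
    return "".join(s)
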