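"""Detect and classify tail-associated lysins (TALs).

Tail-module protein translations are scanned against the packaged motif
library (:mod:`talscan.motifs`); hits are merged per motif, region-checked
against the expected protein tercile, combined into domain architectures
(DA groups), and resolved to one of the five TAL classes:

* TAEP — tail protein with an N-terminal phage endopeptidase domain;
* TMP-LT — tape measure protein carrying a C-terminal GH23 lytic
  transglycosylase;
* NLPC/P60 — papain-like peptidase (endopeptidase/amidase activities);
* GDPD — glycerophosphodiester phosphodiesterase (teichoic-acid targeting);
* pectinesterase — central-domain protein hypothesized to target the
  enterococcal polysaccharide antigen.

Class priority when several domain families hit one protein: TMP-LT (only
for the TMP gene), then TAEP, NLPC/P60, GDPD, pectinesterase.  Each protein
receives exactly one class; secondary hits are retained on the call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from talscan.align import map_columns
from talscan.genome_io import GeneFeature, read_tsv
from talscan.modules import TailModuleLayout
from talscan.motifs import (
    AMINO_ACIDS,
    FAMILY_1P_EXTRAS,
    GH23_1E_CONSENSUS,
    GH23_1P_CONSENSUS,
    GH23_MOTIF_I,
    GH23_MOTIF_II,
    GH23_MOTIF_III,
    GH23_MOTIF_IV,
    MotifDefinition,
    ResidueRule,
    default_library,
    default_residue_rules,
)

logger = logging.getLogger(__name__)

MIN_PROTEIN_LENGTH = 30
TAL_CLASSES = ("TAEP", "TMP_LT", "NLPC_P60", "GDPD", "PECTINESTERASE")
CLASS_PRIORITY = ("TMP_LT", "TAEP", "NLPC_P60", "GDPD", "PECTINESTERASE")
HYDROPHOBIC = set("AILVFMWY")
FAMILY_1E_IDENTITY = 0.7  # aligned identity to the 1E reference signature


@dataclass
class DomainHit:
    """One merged motif match on a protein (0-based half-open aa coords)."""

    motif_name: str
    start_aa: int
    end_aa: int
    score: float
    region: str  # tercile of the hit midpoint: N_terminal | central | C_terminal
    region_ok: bool


@dataclass
class LysinCall:
    """Classification result for one tail-module protein."""

    gene_id: str
    tal_class: str = "none"
    da_group: str = ""
    catalytic_ok: bool = False
    lt_family: str = "not_applicable"  # 1A | 1P | 1E | unassigned | not_applicable
    in_tal_position: bool = False
    in_tmp: bool = False
    hits: list[DomainHit] = field(default_factory=list)
    secondary_classes: list[str] = field(default_factory=list)


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _encode(protein: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(a, -1) for a in protein.upper()], dtype=np.int64)


def _tercile(midpoint: float, length: int) -> str:
    frac = midpoint / length
    if frac < 1 / 3:
        return "N_terminal"
    if frac < 2 / 3:
        return "central"
    return "C_terminal"


def scan_domains(
    protein: str, library: list[MotifDefinition] | None = None
) -> list[DomainHit]:
    """Slide every motif pattern over the protein and report scoring windows.

    The window score is the fraction of pattern columns whose allowed-residue
    set contains the protein residue.  Windows at or above the motif's
    ``min_score`` are hits; overlapping hits of the same motif merge, keeping
    the best-scoring window.  ``region_ok`` is True when the hit midpoint
    falls in the motif's declared protein tercile (``any`` always passes).
    """
    if library is None:
        library = default_library()
    if not library:
        raise ValueError("scan_domains: empty motif library")
    if len(protein) < MIN_PROTEIN_LENGTH:
        return []
    encoded = _encode(protein)
    n = len(encoded)
    hits: list[DomainHit] = []
    for motif in library:
        L = len(motif)
        if L > n:
            continue
        allowed = np.zeros((L, len(AMINO_ACIDS) + 1), dtype=bool)
        for i, col in enumerate(motif.pattern):
            for aa in col:
                allowed[i, _AA_INDEX[aa]] = True
        windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
        match = allowed[np.arange(L)[None, :], windows]  # (n-L+1, L)
        scores = match.mean(axis=1)
        idx = np.flatnonzero(scores >= motif.min_score)
        if idx.size == 0:
            continue
        # merge overlapping windows of the same motif, keep the best score
        merged: list[tuple[int, int, float]] = []
        for k in idx:
            s, e, sc = int(k), int(k) + L, float(scores[k])
            if merged and s < merged[-1][1]:
                ps, pe, psc = merged[-1]
                if sc > psc:
                    merged[-1] = (s, e, sc)
                else:
                    merged[-1] = (ps, pe, psc)
            else:
                merged.append((s, e, sc))
        for s, e, sc in merged:
            region = _tercile((s + e) / 2, n)
            hits.append(
                DomainHit(
                    motif_name=motif.name,
                    start_aa=s,
                    end_aa=e,
                    score=sc,
                    region=region,
                    region_ok=(motif.region == "any") or region == motif.region,
                )
            )
    hits.sort(key=lambda h: (h.start_aa, h.motif_name))
    return hits


def read_domain_hit_table(path: str | Path, protein_lengths: dict[str, int],
                          library: list[MotifDefinition] | None = None) -> dict[str, list[DomainHit]]:
    """Load externally computed domain hits (e.g. a profile-HMM scan).

    Expects a TSV with columns gene_id, motif_name, start_aa, end_aa, score.
    Hits bypass the packaged scanner but still get region terciles/flags from
    the library's declared regions.
    """
    if library is None:
        library = default_library()
    regions = {m.name: m.region for m in library}
    out: dict[str, list[DomainHit]] = {}
    for row in read_tsv(path):
        gid = row["gene_id"]
        length = protein_lengths[gid]
        s, e = int(row["start_aa"]), int(row["end_aa"])
        region = _tercile((s + e) / 2, length)
        declared = regions.get(row["motif_name"], "any")
        out.setdefault(gid, []).append(
            DomainHit(
                motif_name=row["motif_name"],
                start_aa=s,
                end_aa=e,
                score=float(row["score"]),
                region=region,
                region_ok=(declared == "any") or region == declared,
            )
        )
    return out


def _names(hits: list[DomainHit]) -> set[str]:
    return {h.motif_name for h in hits}


def assign_taep_da(hits: list[DomainHit], protein_length: int) -> str:
    """Domain-architecture group for a TAEP protein.

    All groups carry an N-terminal phage endopeptidase domain; DA1 has
    nothing else, DA2 adds lysozyme + CHAP, DA3 lysozyme + C-terminal M23
    peptidase, DA4 lysozyme + C-terminal amidase, DA5 an endosialidase
    chaperone.  Anything else is reported as TAEP-DA-other.
    """
    ep = [h for h in hits if h.motif_name == "endopeptidase" and h.region == "N_terminal"]
    if not ep:
        raise ValueError("assign_taep_da requires an N-terminal endopeptidase hit")
    others = _names(hits) - {"endopeptidase"}
    if not others:
        return "TAEP-DA1"
    if others == {"lysozyme", "CHAP"}:
        return "TAEP-DA2"
    if others == {"lysozyme", "M23_peptidase"} and all(
        h.region == "C_terminal" for h in hits if h.motif_name == "M23_peptidase"
    ):
        return "TAEP-DA3"
    if others == {"lysozyme", "amidase"} and all(
        h.region == "C_terminal" for h in hits if h.motif_name == "amidase"
    ):
        return "TAEP-DA4"
    if others == {"endosialidase_chaperone"}:
        return "TAEP-DA5"
    return "TAEP-DA-other"


def assign_nlpc_da(hits: list[DomainHit]) -> str:
    """Domain-architecture group for an NLPC/P60 protein.

    DA1 is the bare domain; DA2 adds a lysozyme; DA4 is a bare N-terminal
    domain (the podovirus subgroup-1C pattern); DA5 adds an M23 peptidase
    (the myovirus subgroup-2B pattern).
    """
    nl = [h for h in hits if h.motif_name == "NLPC_P60"]
    if not nl:
        raise ValueError("assign_nlpc_da requires an NLPC_P60 hit")
    others = _names(hits) - {"NLPC_P60"}
    if not others:
        if all(h.region == "N_terminal" for h in nl):
            return "NLPC-DA4"
        return "NLPC-DA1"
    if others == {"lysozyme"}:
        return "NLPC-DA2"
    if others == {"M23_peptidase"}:
        return "NLPC-DA5"
    return "NLPC-DA-other"


def assign_gdpd_da(hits: list[DomainHit]) -> str:
    """Domain-architecture group for a GDPD protein.

    DA1 is the bare domain (most common, typically ~240 aa proteins); DA2
    adds a predicted membrane domain; DA3 pairs an N-terminal baseplate
    upper protein with a C-terminal GDPD (baseplate-lyase pattern).
    """
    gd = [h for h in hits if h.motif_name == "GDPD"]
    if not gd:
        raise ValueError("assign_gdpd_da requires a GDPD hit")
    others = _names(hits) - {"GDPD"}
    if not others:
        return "GDPD-DA1"
    if others == {"membrane"}:
        return "GDPD-DA2"
    if others == {"baseplate_upper"} and all(
        h.region == "N_terminal" for h in hits if h.motif_name == "baseplate_upper"
    ) and all(h.region == "C_terminal" for h in gd):
        return "GDPD-DA3"
    return "GDPD-DA-other"


_CLASS_MOTIF = {
    "TAEP": "endopeptidase",
    "TMP_LT": "GH23_LT",
    "NLPC_P60": "NLPC_P60",
    "GDPD": "GDPD",
    "PECTINESTERASE": "pectinesterase",
}


def classify_lysin(
    gene: GeneFeature, layout: TailModuleLayout, hits: list[DomainHit]
) -> LysinCall:
    """Resolve one tail-module protein to a single TAL class and DA group.

    A GH23 LT hit on the TMP gene wins (TMP-LT); otherwise endopeptidase,
    NLPC/P60, GDPD, pectinesterase in that priority.  Domain families that
    hit but lose the priority are kept in ``secondary_classes``.
    """
    call = LysinCall(gene_id=gene.gene_id, hits=hits)
    call.in_tmp = gene.gene_id == layout.tmp_id
    call.in_tal_position = gene.gene_id == layout.tal_id
    present = _names(hits)

    matching = []
    for cls in CLASS_PRIORITY:
        if cls == "TMP_LT":
            if call.in_tmp and "GH23_LT" in present:
                matching.append(cls)
        elif _CLASS_MOTIF[cls] in present:
            matching.append(cls)
    if not matching:
        return call

    call.tal_class = matching[0]
    call.secondary_classes = matching[1:]
    length = gene.length_aa or (len(gene.translation) if gene.translation else 0)
    class_hits = [h for h in hits if h.motif_name != "GH23_LT" or call.tal_class == "TMP_LT"]
    if call.tal_class == "TAEP":
        ep_hits = [h for h in class_hits if h.motif_name in
                   ("endopeptidase", "lysozyme", "CHAP", "M23_peptidase", "amidase",
                    "endosialidase_chaperone")]
        try:
            call.da_group = assign_taep_da(ep_hits, length)
        except ValueError:
            call.da_group = "TAEP-DA-other"
    elif call.tal_class == "NLPC_P60":
        nl_hits = [h for h in class_hits if h.motif_name in
                   ("NLPC_P60", "lysozyme", "M23_peptidase")]
        call.da_group = assign_nlpc_da(nl_hits)
    elif call.tal_class == "GDPD":
        gd_hits = [h for h in class_hits if h.motif_name in
                   ("GDPD", "membrane", "baseplate_upper")]
        call.da_group = assign_gdpd_da(gd_hits)
    elif call.tal_class == "TMP_LT":
        call.da_group = "TMPLT-DA1"
    elif call.tal_class == "PECTINESTERASE":
        call.da_group = "PE-DA1"
    if call.tal_class != "TMP_LT" and "GH23_LT" not in present:
        call.lt_family = "not_applicable"
    return call


def verify_catalytic(
    protein: str,
    call: LysinCall,
    rules: list[ResidueRule] | None = None,
    class_consensus: str | None = None,
) -> bool:
    """Check class-specific conserved catalytic residues.

    The protein's hit span is aligned to the class consensus; the rule's
    alignment-frame columns are then mapped onto the protein and every
    required residue must be present.  GH23 LT requires the catalytic
    glutamate; GDPD requires both catalytic histidines and the Glu/Glu/Asp
    metal-binding triplet.  A failed alignment yields False with a logged
    reason.
    """
    if rules is None:
        rules = default_residue_rules()
    class_name = {"TMP_LT": "GH23_LT", "GDPD": "GDPD"}.get(call.tal_class)
    if class_name is None:
        raise ValueError(f"verify_catalytic does not apply to class {call.tal_class}")
    rule = next((r for r in rules if r.class_name == class_name), None)
    if rule is None:
        raise ValueError(f"no residue rule for class {class_name}")
    if class_consensus is None:
        from talscan.motifs import GDPD_CONSENSUS
        class_consensus = GH23_1P_CONSENSUS if class_name == "GH23_LT" else GDPD_CONSENSUS

    segment = _hit_segment(protein, call, _CLASS_MOTIF[call.tal_class] if call.tal_class != "TMP_LT" else "GH23_LT")
    if segment is None:
        logger.info("verify_catalytic: no %s hit segment on %s", class_name, call.gene_id)
        return False
    try:
        mapping = map_columns(class_consensus, segment)
    except ValueError as exc:
        logger.info("verify_catalytic: alignment failed for %s: %s", call.gene_id, exc)
        return False
    ok = all(mapping.get(col) == aa for aa, col in rule.required)
    call.catalytic_ok = ok
    return ok


def _hit_segment(protein: str, call: LysinCall, motif_name: str, margin: int = 10) -> str | None:
    spans = [h for h in call.hits if h.motif_name == motif_name]
    if not spans:
        return None
    best = max(spans, key=lambda h: h.score)
    s = max(0, best.start_aa - margin)
    e = min(len(protein), best.end_aa + margin)
    return protein[s:e]


def classify_lt_family(
    protein: str,
    class_consensus: str = GH23_1P_CONSENSUS,
    *,
    lt_hit: DomainHit | None = None,
    in_tmp: bool = True,
) -> str:
    """Assign the GH23 lytic transglycosylase sequence family.

    The LT region is aligned to the packaged class consensus and the four
    canonical GH23 motifs are checked in the alignment frame: motif I
    (catalytic E–S), motif II (GxxQ core, G-l-M-Q preferred), motif III
    (A/G-Y-N), motif IV (conserved Y with a hydrophobic flank).  Family 1A
    requires motifs I–IV; family 1P additionally requires the six extra
    conserved alignment columns (T46, F47, G54, I59, L67, A68); family 1E is
    the N-terminal LT of a non-TMP protein matching the packaged 1E
    signature.  Anything else is unassigned.
    """
    if lt_hit is not None:
        s = max(0, lt_hit.start_aa - 10)
        e = min(len(protein), lt_hit.end_aa + 10)
        segment = protein[s:e]
    else:
        segment = protein
    mapping = map_columns(class_consensus, segment)

    def col(c: int) -> str:
        return mapping.get(c, "-")

    motif_i = col(GH23_MOTIF_I[0]) == "E" and col(GH23_MOTIF_I[1]) == "S"
    motif_ii = col(GH23_MOTIF_II[0]) == "G" and col(GH23_MOTIF_II[3]) == "Q"
    motif_iii = col(GH23_MOTIF_III[0]) in ("A", "G") and col(GH23_MOTIF_III[1]) == "Y" and col(GH23_MOTIF_III[2]) == "N"
    motif_iv = col(GH23_MOTIF_IV) == "Y" and (
        col(GH23_MOTIF_IV - 1) in HYDROPHOBIC or col(GH23_MOTIF_IV + 1) in HYDROPHOBIC
    )
    family_1a = motif_i and motif_ii and motif_iii and motif_iv

    n_terminal_lt = lt_hit is not None and lt_hit.region == "N_terminal"
    if not in_tmp and n_terminal_lt:
        from talscan.align import alignment_identity, global_align

        _, ga, gb = global_align(GH23_1E_CONSENSUS, segment)
        if alignment_identity(ga, gb) >= FAMILY_1E_IDENTITY:
            return "1E"

    if family_1a:
        extras_ok = all(col(c) == aa for c, aa in FAMILY_1P_EXTRAS)
        return "1P" if extras_ok else "1A"
    return "unassigned"


def shuffle_null_fpr(
    library: list[MotifDefinition] | None = None,
    n_decoys: int = 1000,
    decoy_length: int = 500,
    seed: int = 0,
) -> float:
    """False-positive rate of the scanner on shuffled-composition decoys.

    Decoys are uniform-composition random proteins of the given length; the
    returned rate is the fraction of decoys with at least one hit from any
    motif at the library's default thresholds.
    """
    if library is None:
        library = default_library()
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    n_hit = 0
    for _ in range(n_decoys):
        decoy = "".join(rng.choice(aas, size=decoy_length))
        if scan_domains(decoy, library):
            n_hit += 1
    return n_hit / n_decoys
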