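"""Per-class consensus profiles and conserved-position reporting.

Given aligned member sequences of one lysin class, build a column-frequency
profile with WebLogo-style information content (uniform 20-letter background,
gaps tracked as a 21st symbol but excluded from the information-content
denominator), report highly conserved positions, and scan the consensus for
the four canonical GH23 lytic transglycosylase motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from talscan.align import GAP, align_members  # re-exported: alignment lives in talscan.align
from talscan.motifs import AMINO_ACIDS

__all__ = [
    "ConsensusProfile",
    "build_profile",
    "align_members",
    "locate_family_motifs",
    "MAX_BITS",
]

MAX_BITS = math.log2(20)
CONSERVATION_THRESHOLD = 0.9
GAP_MAJORITY = 0.5

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class ConsensusProfile:
    """Column-wise residue frequencies, information content and consensus."""

    class_name: str
    columns: np.ndarray  # (n_cols, 21): 20 residues + gap, rows sum to 1
    info_bits: list[float]
    consensus: str
    conserved_positions: list[tuple[int, str, float]]
    n_members: int = 0
    gap_fractions: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.consensus)


def build_profile(
    aligned_sequences: list[str],
    class_name: str,
    conservation_threshold: float = CONSERVATION_THRESHOLD,
) -> ConsensusProfile:
    """Build a consensus profile from ≥2 equal-length gapped sequences.

    Information content per column is log2(20) minus the Shannon entropy of
    the gap-excluded residue distribution; an all-gap column carries 0 bits.
    The consensus residue is the most frequent residue (ties broken
    lexicographically).  ``conserved_positions`` lists columns whose top
    residue frequency (gap-excluded) reaches the threshold, skipping columns
    that are majority gap.
    """
    if len(aligned_sequences) < 2:
        raise ValueError("build_profile requires at least two sequences")
    lengths = {len(s) for s in aligned_sequences}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences must have equal lengths, got {sorted(lengths)}")
    (n_cols,) = lengths
    n_seq = len(aligned_sequences)

    counts = np.zeros((n_cols, 21))
    for seq in aligned_sequences:
        for i, aa in enumerate(seq.upper()):
            if aa == GAP:
                counts[i, 20] += 1
            elif aa in _AA_INDEX:
                counts[i, _AA_INDEX[aa]] += 1
            else:
                raise ValueError(f"unknown symbol {aa!r} in aligned sequence")
    freqs = counts / n_seq

    info_bits: list[float] = []
    consensus_chars: list[str] = []
    conserved: list[tuple[int, str, float]] = []
    gap_fracs: list[float] = []
    for i in range(n_cols):
        res_counts = counts[i, :20]
        total = res_counts.sum()
        gap_frac = counts[i, 20] / n_seq
        gap_fracs.append(gap_frac)
        if total == 0:
            info_bits.append(0.0)
            consensus_chars.append(GAP)
            continue
        p = res_counts / total
        nz = p[p > 0]
        entropy = -(nz * np.log2(nz)).sum()
        info_bits.append(MAX_BITS - float(entropy))
        best = int(np.argmax(res_counts))  # argmax ties → lowest index = lexicographic
        consensus_chars.append(AMINO_ACIDS[best])
        top_freq = float(p[best])
        if top_freq >= conservation_threshold and gap_frac <= GAP_MAJORITY:
            conserved.append((i, AMINO_ACIDS[best], top_freq))

    return ConsensusProfile(
        class_name=class_name,
        columns=freqs,
        info_bits=info_bits,
        consensus="".join(consensus_chars),
        conserved_positions=conserved,
        n_members=n_seq,
        gap_fractions=gap_fracs,
    )


def locate_family_motifs(profile: ConsensusProfile) -> list[tuple[str, tuple[int, int], bool]]:
    """Scan a GH23-class consensus for motifs I–IV in N→C order.

    Motif I is the catalytic E followed by S; motif II a GxxQ core (with the
    G-l-M-Q arrangement preferred); motif III A/G-Y-N; motif IV a conserved Y
    flanked by a hydrophobic residue.  Returns (label, 0-based half-open
    column span, matched) triples; an unmatched motif reports the span where
    the search gave up.
    """
    cons = profile.consensus
    hydrophobic = set("AILVFMWY")
    results: list[tuple[str, tuple[int, int], bool]] = []
    pos = 0

    # motif I: E-S
    i = cons.find("ES", pos)
    if i >= 0:
        results.append(("I", (i, i + 2), True))
        pos = i + 2
    else:
        results.append(("I", (pos, len(cons)), False))

    # motif II: G..Q within a 4-residue window (GxxQ core)
    found = False
    for j in range(pos, len(cons) - 3):
        if cons[j] == "G" and cons[j + 3] == "Q":
            results.append(("II", (j, j + 4), True))
            pos = j + 4
            found = True
            break
    if not found:
        results.append(("II", (pos, len(cons)), False))

    # motif III: A/G-Y-N
    found = False
    for j in range(pos, len(cons) - 2):
        if cons[j] in ("A", "G") and cons[j + 1] == "Y" and cons[j + 2] == "N":
            results.append(("III", (j, j + 3), True))
            pos = j + 3
            found = True
            break
    if not found:
        results.append(("III", (pos, len(cons)), False))

    # motif IV: conserved Y with a hydrophobic neighbour
    found = False
    for j in range(pos, len(cons)):
        if cons[j] == "Y":
            left = cons[j - 1] if j > 0 else ""
            right = cons[j + 1] if j + 1 < len(cons) else ""
            if left in hydrophobic or right in hydrophobic:
                results.append(("IV", (j, j + 1), True))
                found = True
                break
    if not found:
        results.append(("IV", (pos, len(cons)), False))
    return results


def profile_to_rows(profile: ConsensusProfile) -> list[dict]:
    """Flatten a profile for TSV export (column, frequencies, bits, consensus)."""
    rows = []
    for i in range(len(profile)):
        row: dict = {"column": i}
        for k, aa in enumerate(AMINO_ACIDS):
            row[f"freq_{aa}"] = round(float(profile.columns[i, k]), 6)
        row["gap_fraction"] = round(float(profile.columns[i, 20]), 6)
        row["info_bits"] = round(profile.info_bits[i], 6)
        row["consensus"] = profile.consensus[i]
        rows.append(row)
    return rows
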