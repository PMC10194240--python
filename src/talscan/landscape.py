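"""Cohort-level landscape summaries.

Aggregates per-genome results into the survey outputs: the class census
(counts and one-decimal percentages of all classified lysins), genome-size /
morphotype groups, tail-module lysin arrangement patterns, and Spearman
correlations of genome size against ORF count, tRNA count and GC content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
from scipy import stats

from talscan.lysins import TAL_CLASSES, LysinCall
from talscan.modules import TailModuleLayout

SIZE_GROUPS = ("podo_small", "sipho_group1", "sipho_group2", "myo_large", "unclassified")
ARRANGEMENTS = ("taep_in_tal_only", "tmplt_only", "tmplt_and_taep", "no_tal")

# genome-size group boundaries in kb
PODO_MAX = 30.5
SIPHO1_RANGE = (21.0, 43.0)
SIPHO2_RANGE = (55.0, 86.0)
MYO_MIN = 130.0


@dataclass
class SizeGroup:
    value: str
    morphology_hint: str = "unknown"

    def __post_init__(self) -> None:
        if self.value not in SIZE_GROUPS:
            raise ValueError(f"unknown size group {self.value!r}")


@dataclass
class LandscapeSummary:
    class_counts: dict[str, int]
    class_percentages: dict[str, float]
    total_sequences: int
    da_counts: dict[str, int] = field(default_factory=dict)
    size_group_counts: dict[str, int] = field(default_factory=dict)
    arrangement_counts: dict[str, int] = field(default_factory=dict)
    arrangement_percentages: dict[str, float] = field(default_factory=dict)
    correlations: list[dict] = field(default_factory=list)
    source_counts: dict[str, int] = field(default_factory=dict)


def round_half_even(x: float, ndigits: int = 1) -> float:
    """Round with ties to even (6.25 → 6.2, 6.35 → 6.4), matching the
    printed precision of the published class table."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def percentage(count: int, total: int) -> float:
    """One-decimal percentage, ties to even; 0.0 when total is 0."""
    if total == 0:
        return 0.0
    return round_half_even(100.0 * count / total, 1)


def assign_size_group(length_kb: float, morphology_hint: str = "unknown") -> SizeGroup:
    """Map genome size (and an optional morphology hint) to a size group.

    Size rules alone: <30.5 kb podoviruses, 31–43 kb siphovirus group 1,
    55–86 kb siphovirus group 2, ≥130 kb myoviruses; the gaps between the
    published ranges stay unclassified.  A known morphology hint dominates:
    e.g. a 16.9 kb siphovirus lands in group 1 rather than with the
    podoviruses, and a small genome with a podovirus hint is podo_small even
    above 30.5 kb.
    """
    if length_kb <= 0:
        raise ValueError("length_kb must be positive")
    if morphology_hint == "podovirus":
        return SizeGroup("podo_small", morphology_hint)
    if morphology_hint == "myovirus":
        return SizeGroup("myo_large", morphology_hint)
    if morphology_hint == "siphovirus":
        if length_kb <= SIPHO1_RANGE[1]:
            return SizeGroup("sipho_group1", morphology_hint)
        if SIPHO2_RANGE[0] <= length_kb <= SIPHO2_RANGE[1]:
            return SizeGroup("sipho_group2", morphology_hint)
        return SizeGroup("unclassified", morphology_hint)
    # no hint: pure size rules
    if length_kb < PODO_MAX:
        return SizeGroup("podo_small", morphology_hint)
    if 31.0 <= length_kb <= SIPHO1_RANGE[1]:
        return SizeGroup("sipho_group1", morphology_hint)
    if SIPHO2_RANGE[0] <= length_kb <= SIPHO2_RANGE[1]:
        return SizeGroup("sipho_group2", morphology_hint)
    if length_kb >= MYO_MIN:
        return SizeGroup("myo_large", morphology_hint)
    return SizeGroup("unclassified", morphology_hint)


def classify_arrangement(calls: list[LysinCall], layout: TailModuleLayout) -> str:
    """Tail-module lysin arrangement pattern for one genome.

    ``tmplt_and_taep`` when both a TMP-LT and a TAEP call exist,
    ``taep_in_tal_only`` / ``tmplt_only`` when only one of the two does,
    ``no_tal`` when neither.
    """
    has_tmplt = any(c.tal_class == "TMP_LT" for c in calls)
    has_taep = any(c.tal_class == "TAEP" for c in calls)
    if has_tmplt and has_taep:
        return "tmplt_and_taep"
    if has_taep:
        return "taep_in_tal_only"
    if has_tmplt:
        return "tmplt_only"
    return "no_tal"


def census(calls: list[LysinCall] | dict[str, int]) -> LandscapeSummary:
    """Class census: one row per TAL class with count and percentage.

    Accepts either classified calls or pre-tallied per-class counts.  Each
    protein counts once, in its (single) assigned class; percentages are of
    all classified lysins, printed to one decimal, half away from zero.
    """
    if isinstance(calls, dict):
        counts = {cls: int(calls.get(cls, 0)) for cls in TAL_CLASSES}
        da_counts: dict[str, int] = {}
    else:
        counts = {cls: 0 for cls in TAL_CLASSES}
        da_counts = {}
        for c in calls:
            if c.tal_class in counts:
                counts[c.tal_class] += 1
                if c.da_group:
                    da_counts[c.da_group] = da_counts.get(c.da_group, 0) + 1
    total = sum(counts.values())
    percentages = {cls: percentage(n, total) for cls, n in counts.items()}
    return LandscapeSummary(
        class_counts=counts,
        class_percentages=percentages,
        total_sequences=total,
        da_counts=dict(sorted(da_counts.items())),
    )


def arrangement_summary(
    patterns: list[str], include_no_tal_denominator: bool = True
) -> dict[str, dict[str, float]]:
    """Tally arrangement patterns under both denominators.

    The published arrangement percentages have an ambiguous denominator
    (genomes with a TAL vs all genomes with a located tail module), so both
    are reported: ``of_with_tal`` excludes ``no_tal`` genomes from the
    denominator, ``of_all`` includes them.
    """
    counts = {a: patterns.count(a) for a in ARRANGEMENTS}
    with_tal = sum(n for a, n in counts.items() if a != "no_tal")
    out: dict[str, dict[str, float]] = {}
    for a in ARRANGEMENTS:
        entry = {"count": counts[a], "pct_of_all": percentage(counts[a], len(patterns))}
        if a != "no_tal":
            entry["pct_of_with_tal"] = percentage(counts[a], with_tal)
        out[a] = entry
    return out


def cohort_totals(source_counts: dict[str, int]) -> dict[str, int]:
    """Bookkeeping over declared input sources.

    Sums every ``prophage*`` key into a prophage total and everything into
    the grand total of genomes examined.
    """
    prophage = sum(v for k, v in source_counts.items() if k.startswith("prophage"))
    phage = sum(v for k, v in source_counts.items() if not k.startswith("prophage"))
    return {
        "phage_genomes": phage,
        "prophage_genomes": prophage,
        "genomes_examined": phage + prophage,
    }


def correlate(
    stats_rows: list[dict],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> list[dict]:
    """Spearman correlations of genome size with ORF count, tRNA count, GC%.

    Significance is a two-sided seeded permutation p-value on the Spearman
    rho.  A constant variable yields an undefined coefficient with a reason
    rather than an error.
    """
    if len(stats_rows) < 3:
        raise ValueError("correlate requires at least 3 genomes")
    size = np.array([r["length_kb"] for r in stats_rows], dtype=float)
    rng = np.random.default_rng(seed)
    results = []
    for var in ("orf_count", "trna_count", "gc_percent"):
        y = np.array([r[var] for r in stats_rows], dtype=float)
        if np.ptp(size) == 0 or np.ptp(y) == 0:
            results.append(
                {"pair": f"size_vs_{var}", "method": "spearman", "rho": None,
                 "p_value": None, "note": "undefined: constant variable"}
            )
            continue
        rho, _ = stats.spearmanr(size, y)
        # permutation null on the rank scale: permuting y permutes its ranks,
        # so the null rhos are correlations of fixed rank vectors
        rx = stats.rankdata(size)
        ry = stats.rankdata(y)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        null_rhos = np.empty(n_permutations)
        for k in range(n_permutations):
            null_rhos[k] = rx_c @ rng.permutation(ry_c) / denom
        null_hits = int((np.abs(null_rhos) >= abs(rho) - 1e-12).sum())
        p = (null_hits + 1) / (n_permutations + 1)
        results.append(
            {"pair": f"size_vs_{var}", "method": "spearman",
             "rho": round(float(rho), 4), "p_value": round(p, 6), "note": ""}
        )
    return results
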