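"""End-to-end orchestration: genome in, lysin calls and summaries out."""

from __future__ import annotations

from dataclasses import dataclass, field

from talscan.genome_io import GenomeRecord, genome_stats
from talscan.landscape import (
    LandscapeSummary,
    arrangement_summary,
    assign_size_group,
    census,
    classify_arrangement,
    correlate,
)
from talscan.lysins import (
    DomainHit,
    LysinCall,
    classify_lt_family,
    classify_lysin,
    scan_domains,
    verify_catalytic,
)
from talscan.modules import (
    ModuleSegment,
    TailModuleLayout,
    TemperateFlags,
    detect_temperate,
    locate_tail_module,
    partition_modules,
    resolve_tmp_dit_tal,
)
from talscan.motifs import MotifDefinition, default_library


@dataclass
class GenomeResult:
    """Everything the pipeline derives from one genome."""

    genome_id: str
    stats: dict
    segments: list[ModuleSegment]
    layout: TailModuleLayout | None
    temperate: TemperateFlags
    calls: list[LysinCall] = field(default_factory=list)
    arrangement: str = "no_tal"
    size_group: str = "unclassified"

    def module_order(self) -> list[str]:
        """Recovered functional-module order, skipping filler segments."""
        return [
            s.category
            for s in self.segments
            if s.category not in ("other", "hypothetical")
        ]

    def lysin_calls(self) -> list[LysinCall]:
        return [c for c in self.calls if c.tal_class != "none"]


def analyze_genome(
    g: GenomeRecord,
    library: list[MotifDefinition] | None = None,
    domain_hits: dict[str, list[DomainHit]] | None = None,
) -> GenomeResult:
    """Run the full per-genome analysis.

    Partitions the genome into module segments, locates the tail module
    between the head and lysis modules, resolves TMP/Dit/Tal, scans every
    tail-module translation (the TMP included) for lysin domains, classifies
    each into a TAL class + DA group, verifies catalytic residues for the
    classes with residue rules, and assigns the GH23 family for LT carriers.
    ``domain_hits`` may supply externally computed hits per gene_id,
    bypassing the packaged scanner for those genes.
    """
    if library is None:
        library = default_library()
    segments = partition_modules(g)
    layout = locate_tail_module(segments)
    if layout is not None:
        layout = resolve_tmp_dit_tal(layout, g)
    temperate = detect_temperate(g)
    stats = genome_stats(g)

    calls: list[LysinCall] = []
    if layout is not None:
        by_id = {f.gene_id: f for f in g.features}
        scan_ids = list(layout.tail_gene_ids)
        if layout.tmp_id and layout.tmp_id not in scan_ids:
            scan_ids.append(layout.tmp_id)
        for gid in scan_ids:
            gene = by_id[gid]
            if gene.kind != "CDS" or not gene.translation:
                continue
            if domain_hits is not None and gid in domain_hits:
                hits = domain_hits[gid]
            else:
                hits = scan_domains(gene.translation, library)
            call = classify_lysin(gene, layout, hits)
            if call.tal_class in ("TMP_LT", "GDPD"):
                verify_catalytic(gene.translation, call)
            lt_hits = [h for h in hits if h.motif_name == "GH23_LT"]
            if lt_hits:
                call.lt_family = classify_lt_family(
                    gene.translation,
                    lt_hit=max(lt_hits, key=lambda h: h.score),
                    in_tmp=call.in_tmp,
                )
            calls.append(call)

    result = GenomeResult(
        genome_id=g.genome_id,
        stats=stats,
        segments=segments,
        layout=layout,
        temperate=temperate,
        calls=calls,
        size_group=assign_size_group(stats["length_kb"], g.morphology_hint).value,
    )
    result.arrangement = (
        classify_arrangement(calls, layout) if layout is not None else "no_tal"
    )
    return result


@dataclass
class CohortResult:
    genomes: list[GenomeResult]
    summary: LandscapeSummary


def analyze_cohort(
    genomes: list[GenomeRecord],
    library: list[MotifDefinition] | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> CohortResult:
    """Analyze a cohort and aggregate the landscape summary.

    The census covers every classified lysin across genomes; arrangement
    tallies are reported under both denominators (all genomes with a located
    tail module, and only those with at least one TAL).  Correlations are
    computed when the cohort has ≥3 genomes.
    """
    if library is None:
        library = default_library()
    results = [analyze_genome(g, library) for g in genomes]
    all_calls = [c for r in results for c in r.lysin_calls()]
    summary = census(all_calls)
    summary.size_group_counts = _tally(r.size_group for r in results)
    patterns = [r.arrangement for r in results if r.layout is not None]
    arr = arrangement_summary(patterns)
    summary.arrangement_counts = {a: int(v["count"]) for a, v in arr.items()}
    summary.arrangement_percentages = {
        a: v.get("pct_of_with_tal", v["pct_of_all"]) for a, v in arr.items()
    }
    summary.source_counts = _tally(g.source_kind for g in genomes)
    if len(results) >= 3:
        summary.correlations = correlate(
            [r.stats for r in results], n_permutations=n_permutations, seed=seed
        )
    return CohortResult(genomes=results, summary=summary)


def _tally(items) -> dict[str, int]:
    out: dict[str, int] = {}
    for it in items:
        out[it] = out.get(it, 0) + 1
    return dict(sorted(out.items()))


def calls_to_rows(results: list[GenomeResult]) -> list[dict]:
    """Flatten per-gene lysin calls for TSV export."""
    rows = []
    for r in results:
        for c in r.calls:
            rows.append(
                {
                    "genome_id": r.genome_id,
                    "gene_id": c.gene_id,
                    "tal_class": c.tal_class,
                    "da_group": c.da_group,
                    "lt_family": c.lt_family,
                    "catalytic_ok": str(c.catalytic_ok),
                    "in_tal_position": str(c.in_tal_position),
                    "in_tmp": str(c.in_tmp),
                    "secondary_classes": ",".join(c.secondary_classes),
                }
            )
    return rows


def layout_rows(results: list[GenomeResult]) -> list[dict]:
    rows = []
    for r in results:
        lay = r.layout or TailModuleLayout()
        rows.append(
            {
                "genome_id": r.genome_id,
                "tail_genes": ",".join(lay.tail_gene_ids),
                "tmp_id": lay.tmp_id or "",
                "dit_id": lay.dit_id or "",
                "tal_id": lay.tal_id or "",
                "estimated_tail_length_nm": (
                    "" if lay.estimated_tail_length_nm is None else lay.estimated_tail_length_nm
                ),
                "conforms_tmp_dit_tal": str(lay.conforms_tmp_dit_tal),
                "arrangement": r.arrangement,
                "is_temperate": str(r.temperate.is_temperate),
                "size_group": r.size_group,
            }
        )
    return rows
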