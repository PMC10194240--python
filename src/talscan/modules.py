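"""Functional-module partitioning and tail-unit resolution.

Phage genomes are organised in functional modules — packaging, head, tail,
lysis, DNA metabolism — with related genes grouped together.  This module
assigns each gene a category from its product annotation, merges runs of
same-category genes into segments, locates the tail module between the head
and lysis modules, and resolves the canonical siphovirus tail unit
TMP–Dit–Tal (tape measure protein, distal tail protein, tail-associated
lysin).  The TMP's amino-acid length estimates the physical tail length at
0.15 nm per residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from talscan.genome_io import GeneFeature, GenomeRecord

logger = logging.getLogger(__name__)

NM_PER_AA = 0.15  # physical tail length contributed per TMP residue

MODULE_CATEGORIES = (
    "packaging",
    "head",
    "tail",
    "lysis",
    "dna_metabolism",
    "lysogeny",
    "hypothetical",
    "other",
)

# Keyword vocabulary, matched case-insensitively as substrings against the
# product annotation.  Priority order prevents composite annotations such as
# "tail fiber protein, phage head" from flapping between categories.
# User-overridable: pass a custom vocabulary to categorize_gene.
DEFAULT_VOCABULARY: tuple[tuple[str, str], ...] = (
    # lysogeny first: integrase/repressor outrank everything
    ("anti-repressor", "other"),  # explicitly NOT a temperate marker
    ("antirepressor", "other"),
    ("integrase", "lysogeny"),
    ("recombinase", "lysogeny"),
    ("repressor", "lysogeny"),
    ("excisionase", "lysogeny"),
    # packaging
    ("terminase", "packaging"),
    ("packaging", "packaging"),
    # head
    ("portal", "head"),
    ("capsid", "head"),
    ("scaffold", "head"),
    ("head", "head"),
    ("prohead", "head"),
    ("protease, maturation", "head"),
    # tail
    ("tape measure", "tail"),
    ("tape-measure", "tail"),
    ("distal tail", "tail"),
    ("tail", "tail"),
    ("baseplate", "tail"),
    ("fiber", "tail"),
    ("fibre", "tail"),
    ("tailspike", "tail"),
    ("spike", "tail"),
    # lysis
    ("holin", "lysis"),
    ("endolysin", "lysis"),
    ("lysin", "lysis"),
    ("amidase", "lysis"),
    ("lysozyme", "lysis"),
    ("spanin", "lysis"),
    # DNA metabolism
    ("polymerase", "dna_metabolism"),
    ("helicase", "dna_metabolism"),
    ("primase", "dna_metabolism"),
    ("nuclease", "dna_metabolism"),
    ("ligase", "dna_metabolism"),
    ("methyltransferase", "dna_metabolism"),
    ("thymidylate", "dna_metabolism"),
    ("ribonucleotide reductase", "dna_metabolism"),
    ("single-stranded dna-binding", "dna_metabolism"),
    ("recombination", "dna_metabolism"),
    # fallback buckets
    ("hypothetical protein", "hypothetical"),
    ("hypothetical", "hypothetical"),
    ("unknown function", "hypothetical"),
)

TMP_KEYWORDS = ("tape measure", "tape-measure", "tapemeasure")
DIT_KEYWORDS = ("distal tail", "dit protein")
LONG_GENE_AA = 800  # minimum length for the longest-gene TMP fallback


@dataclass(frozen=True)
class ModuleCategory:
    value: str

    def __post_init__(self) -> None:
        if self.value not in MODULE_CATEGORIES:
            raise ValueError(f"unknown module category {self.value!r}")


@dataclass
class ModuleSegment:
    """A maximal run of same-category genes, in gene-index half-open coords."""

    category: str
    gene_ids: list[str]
    start_index: int
    end_index: int


@dataclass
class TailModuleLayout:
    """The located tail module and its resolved TMP/Dit/Tal roles."""

    tail_gene_ids: list[str] = field(default_factory=list)
    tmp_id: str | None = None
    dit_id: str | None = None
    tal_id: str | None = None
    estimated_tail_length_nm: float | None = None
    conforms_tmp_dit_tal: bool = False


@dataclass
class TemperateFlags:
    has_integrase: bool
    has_repressor: bool

    @property
    def is_temperate(self) -> bool:
        return self.has_integrase or self.has_repressor


def categorize_gene(
    product: str, vocabulary: tuple[tuple[str, str], ...] = DEFAULT_VOCABULARY
) -> str:
    """Case-insensitive keyword lookup; first matching rule wins.

    Products matching no rule fall back to ``other``; an empty product is
    ``hypothetical``.
    """
    text = (product or "").lower().strip()
    if not text:
        return "hypothetical"
    for keyword, category in vocabulary:
        if keyword in text:
            return category
    return "other"


def partition_modules(
    g: GenomeRecord, vocabulary: tuple[tuple[str, str], ...] = DEFAULT_VOCABULARY
) -> list[ModuleSegment]:
    """Greedy left-to-right segmentation of the gene order into module runs.

    Consecutive genes sharing a category merge.  Runs of hypothetical/other
    genes flanked by the same category on both sides are absorbed into that
    category's segment; otherwise they form their own segment.  The output
    covers every gene exactly once.
    """
    genes = g.features
    if not any(f.kind == "CDS" for f in genes):
        raise ValueError(f"{g.genome_id}: partition_modules requires at least one CDS")
    cats = [
        categorize_gene(f.product, vocabulary) if f.kind == "CDS" else "other"
        for f in genes
    ]

    # absorb hypothetical/other runs flanked by the same category on both sides
    effective = list(cats)
    i = 0
    n = len(genes)
    while i < n:
        if effective[i] in ("hypothetical", "other"):
            j = i
            while j < n and effective[j] in ("hypothetical", "other"):
                j += 1
            left = effective[i - 1] if i > 0 else None
            right = effective[j] if j < n else None
            if left is not None and left == right:
                for k in range(i, j):
                    effective[k] = left
            i = j
        else:
            i += 1

    segments: list[ModuleSegment] = []
    i = 0
    while i < n:
        j = i
        while j < n and effective[j] == effective[i]:
            j += 1
        segments.append(
            ModuleSegment(
                category=effective[i],
                gene_ids=[genes[k].gene_id for k in range(i, j)],
                start_index=i,
                end_index=j,
            )
        )
        i = j
    return segments


def locate_tail_module(segments: list[ModuleSegment]) -> TailModuleLayout | None:
    """Return the tail-module genes lying between the head and lysis modules.

    Uses the last head segment and the first lysis segment after it (mosaic
    genomes may carry several).  If no tail-category segment lies between
    them but uncategorized genes do, those genes become the candidate tail
    module with ``conforms_tmp_dit_tal`` False.  Returns None when either
    flanking module is missing.
    """
    head_idxs = [i for i, s in enumerate(segments) if s.category == "head"]
    if not head_idxs:
        logger.info("no head module found; tail module not located")
        return None
    head_i = head_idxs[-1]
    lysis_idxs = [i for i, s in enumerate(segments) if s.category == "lysis" and i > head_i]
    if not lysis_idxs:
        logger.info("no lysis module after head; tail module not located")
        return None
    lysis_i = lysis_idxs[0]

    between = segments[head_i + 1 : lysis_i]
    tail_ids = [gid for s in between if s.category == "tail" for gid in s.gene_ids]
    if tail_ids:
        return TailModuleLayout(tail_gene_ids=tail_ids)
    fallback = [
        gid
        for s in between
        if s.category in ("hypothetical", "other")
        for gid in s.gene_ids
    ]
    if fallback:
        return TailModuleLayout(tail_gene_ids=fallback, conforms_tmp_dit_tal=False)
    logger.info("no candidate tail genes between head and lysis")
    return None


def resolve_tmp_dit_tal(layout: TailModuleLayout, g: GenomeRecord) -> TailModuleLayout:
    """Assign TMP, Dit and Tal within the located tail module.

    TMP is the tail gene with a tape-measure keyword, else the longest tail
    CDS above 800 aa (ties to the first in genomic order).  Dit is the gene
    immediately after the TMP — a distal-tail keyword is preferred, but a
    small unannotated gene is accepted, since Dit is frequently annotated
    only as a hypothetical protein.  Tal is the gene after Dit.  Short-tailed
    (podovirus-style) genomes with neither keyword nor a long gene leave the
    TMP unset and do not conform; lysin scanning still covers all tail genes.
    """
    if not layout.tail_gene_ids:
        raise ValueError("resolve_tmp_dit_tal requires a non-empty tail module")
    by_id = {f.gene_id: f for f in g.features}
    tail_genes = [by_id[gid] for gid in layout.tail_gene_ids]

    tmp_gene: GeneFeature | None = None
    for f in tail_genes:
        if any(k in f.product.lower() for k in TMP_KEYWORDS):
            tmp_gene = f
            break
    if tmp_gene is None:
        candidates = [f for f in tail_genes if f.kind == "CDS" and f.length_aa > LONG_GENE_AA]
        if candidates:
            tmp_gene = max(candidates, key=lambda f: f.length_aa)
            # ties: max() keeps the first in genomic order (list is sorted)

    layout.tmp_id = tmp_gene.gene_id if tmp_gene else None
    layout.dit_id = None
    layout.tal_id = None
    if tmp_gene is not None:
        layout.estimated_tail_length_nm = round(NM_PER_AA * tmp_gene.length_aa, 4)
        idx = layout.tail_gene_ids.index(tmp_gene.gene_id)
        rest = tail_genes[idx + 1 :]
        if rest:
            dit = rest[0]
            preferred = [f for f in rest if any(k in f.product.lower() for k in DIT_KEYWORDS)]
            if preferred:
                dit = preferred[0]
            layout.dit_id = dit.gene_id
            dit_idx = layout.tail_gene_ids.index(dit.gene_id)
            if dit_idx + 1 < len(tail_genes):
                layout.tal_id = layout.tail_gene_ids[dit_idx + 1]
    layout.conforms_tmp_dit_tal = (
        layout.tmp_id is not None and layout.dit_id is not None and layout.tal_id is not None
    )
    return layout


def detect_temperate(g: GenomeRecord) -> TemperateFlags:
    """Keyword scan for lysogeny markers (integrase/recombinase, repressor).

    'anti-repressor' alone is not counted as a repressor.
    """
    has_integrase = False
    has_repressor = False
    for f in g.features:
        p = f.product.lower()
        if "integrase" in p or "recombinase" in p:
            has_integrase = True
        stripped = p.replace("anti-repressor", "").replace("antirepressor", "")
        if "repressor" in stripped:
            has_repressor = True
    return TemperateFlags(has_integrase=has_integrase, has_repressor=has_repressor)
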