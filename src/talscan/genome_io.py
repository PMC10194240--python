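"""Read and write annotated genomes and derived tables.

Genomes arrive as multi-record GenBank flat files (or are built in memory by
:mod:`talscan.simulate`).  Internally every coordinate is 0-based half-open;
GenBank's 1-based inclusive spans are converted on read and restored on
write.  Reverse-strand features keep genomic ``start < end``; their
``translation`` is of the reverse complement.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

TSV_HEADER_COMMENT = "# coordinates: 0-based half-open"


@dataclass
class GeneFeature:
    """One annotated gene.

    ``start``/``end`` are 0-based half-open genomic coordinates with
    ``start < end`` regardless of strand.  ``translation`` is empty for
    non-CDS features.  On a circular genome a feature spanning the origin
    has ``end > length_bp`` of its genome (unwrapped representation).
    """

    gene_id: str
    start: int
    end: int
    strand: str = "forward"  # forward | reverse
    kind: str = "CDS"  # CDS | tRNA | other
    product: str = ""
    translation: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"feature {self.gene_id}: bad strand {self.strand!r}")
        max_aa = math.ceil((self.end - self.start) / 3)
        if self.translation and len(self.translation) > max_aa:
            raise ValueError(
                f"feature {self.gene_id}: translation length {len(self.translation)} "
                f"exceeds span capacity {max_aa}"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def length_aa(self) -> int:
        return len(self.translation)


@dataclass
class GenomeRecord:
    """One annotated genome: ordered features plus basic sequence metadata."""

    genome_id: str
    length_bp: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str = ""
    gc_fraction: float = 0.0
    topology: str = "linear"  # linear | circular
    source_kind: str = "phage"  # phage | prophage
    morphology_hint: str = "unknown"  # podovirus | siphovirus | myovirus | unknown

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.genome_id}: length_bp must be positive")
        if self.sequence:
            if len(self.sequence) != self.length_bp:
                raise ValueError(
                    f"{self.genome_id}: sequence length {len(self.sequence)} "
                    f"!= length_bp {self.length_bp}"
                )
            self.gc_fraction = _gc_fraction(self.sequence)
        self.features.sort(key=lambda f: (f.start, f.end, f.gene_id))
        seen: set[str] = set()
        for f in self.features:
            if f.gene_id in seen:
                raise ValueError(f"{self.genome_id}: duplicate gene_id {f.gene_id}")
            seen.add(f.gene_id)

    def cds(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]


def _gc_fraction(sequence: str) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded from the denominator."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    total = gc + at
    return gc / total if total else 0.0


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Parse a (possibly multi-record) GenBank flat file.

    One :class:`GenomeRecord` per LOCUS, input order preserved.  CDS
    translations are taken from the ``/translation`` qualifier when present,
    otherwise translated from the coordinates with the bacterial code
    (translation table 11).  A CDS with neither translation nor sequence is
    kept with an empty translation and a logged warning.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # pragma: no cover - biopython error text varies
        raise ValueError(f"unparseable GenBank file {path}: {exc}") from exc
    if not seq_records:
        raise ValueError(f"no LOCUS records found in {path}")
    for rec in seq_records:
        try:
            records.append(_convert_record(rec))
        except Exception as exc:
            raise ValueError(f"unparseable record at LOCUS {rec.id}: {exc}") from exc
    return records


def _convert_record(rec: SeqRecord) -> GenomeRecord:
    sequence = str(rec.seq) if len(rec.seq) else ""
    if sequence and set(sequence.upper()) <= {"N"}:
        sequence = ""  # feature-table-only records ship an all-N placeholder
    length_bp = len(rec.seq)
    topology = rec.annotations.get("topology", "linear")
    source_kind = "prophage" if "prophage" in (rec.description or "").lower() else "phage"
    features: list[GeneFeature] = []
    counter = 0
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA"):
            continue
        counter += 1
        kind = feat.type if feat.type in ("CDS", "tRNA") else "other"
        quals = feat.qualifiers
        gene_id = (
            quals.get("locus_tag", [None])[0]
            or quals.get("protein_id", [None])[0]
            or f"{rec.id}_f{counter:04d}"
        )
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "reverse" if feat.location.strand == -1 else "forward"
        product = quals.get("product", [""])[0]
        translation = quals.get("translation", [""])[0]
        if kind == "CDS" and not translation:
            if sequence:
                translation = _translate_span(sequence, start, end, strand)
            else:
                logger.warning(
                    "CDS %s in %s has no translation and no sequence; kept empty",
                    gene_id,
                    rec.id,
                )
        features.append(
            GeneFeature(
                gene_id=gene_id,
                start=start,
                end=end,
                strand=strand,
                kind=kind,
                product=product,
                translation=translation,
            )
        )
    return GenomeRecord(
        genome_id=rec.id,
        length_bp=length_bp,
        features=features,
        sequence=sequence,
        topology=topology,
        source_kind=source_kind,
    )


def _translate_span(sequence: str, start: int, end: int, strand: str) -> str:
    nt = Seq(sequence[start:end])
    if strand == "reverse":
        nt = nt.reverse_complement()
    nt = nt[: 3 * (len(nt) // 3)]
    aa = str(nt.translate(table=11))
    return aa.rstrip("*")


def write_genbank(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    """Serialize genomes back to a multi-record GenBank flat file."""
    out: list[SeqRecord] = []
    for g in genomes:
        seq = Seq(g.sequence if g.sequence else "N" * g.length_bp)
        rec = SeqRecord(seq, id=g.genome_id, name=g.genome_id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = g.topology
        if g.source_kind == "prophage":
            rec.description = "prophage region"
        for f in g.features:
            quals: dict[str, list[str]] = {"locus_tag": [f.gene_id]}
            if f.product:
                quals["product"] = [f.product]
            if f.translation:
                quals["translation"] = [f.translation]
            rec.features.append(
                SeqFeature(
                    FeatureLocation(f.start, f.end, strand=-1 if f.strand == "reverse" else 1),
                    type=f.kind if f.kind in ("CDS", "tRNA") else "misc_feature",
                    qualifiers=quals,
                )
            )
        out.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "genbank")


def genome_stats(g: GenomeRecord) -> dict:
    """Basic per-genome statistics: size in kb, ORF count, tRNA count, GC%."""
    return {
        "genome_id": g.genome_id,
        "length_kb": round(g.length_bp / 1000.0, 3),
        "orf_count": sum(1 for f in g.features if f.kind == "CDS"),
        "trna_count": sum(1 for f in g.features if f.kind == "tRNA"),
        "gc_percent": round(100.0 * g.gc_fraction, 2),
    }


def write_tsv(rows: Sequence[Mapping], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write flat records as a UTF-8 TSV with a stable column order.

    Emits a header comment documenting the coordinate convention, then the
    column header, then one row per record.  An empty row list produces a
    header-only file (columns must then be given or the header is empty).
    """
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    if rows:
        keys = set(columns)
        for r in rows:
            if set(r.keys()) != keys:
                raise ValueError("write_tsv requires homogeneous keys across rows")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(TSV_HEADER_COMMENT + "\n")
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t")
        writer.writeheader()
        for r in rows:
            writer.writerow(dict(r))


def read_tsv(path: str | Path) -> list[dict]:
    """Read back a TSV written by :func:`write_tsv` (values stay strings)."""
    with open(path, newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return [dict(row) for row in reader]
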