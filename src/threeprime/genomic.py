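"""Domain types and I/O for strand-specific 3'-end sequencing data.

All coordinates are 0-based, half-open ``[start, end)`` internally. GTF input
(1-based, closed) is converted on read; bedGraph and BED are emitted natively.
A transcript 3' end is recorded at its last transcribed nucleotide, so for a
minus-strand transcript the 3' end sits at the interval's genomic start.

Strand is mandatory everywhere: 3'-end sequencing is strand-specific, and all
overlap queries in this package are strand-matched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-")

BIOTYPES = ("protein_coding", "lncRNA", "PROMPT", "eRNA", "snoRNA", "not_annotated")

#: per-strand bedGraph suffixes used throughout the package
PLUS_SUFFIX = ".plus.bedgraph"
MINUS_SUFFIX = ".minus.bedgraph"


class ParseError(ValueError):
    """Malformed input file (carries the offending line number where known)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Same-strand, same-chromosome intersection of >= 1 nt."""
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class Intron:
    """An intron derived as the gap between consecutive exons of one gene.

    ``sa_pos`` is the splice-acceptor position: the first nucleotide of the
    downstream exon in transcription orientation. On the plus strand this is
    ``interval.end``; on the minus strand it is ``interval.start - 1``.
    Intron 3' ends accumulate immediately upstream (orientation-wise) of it.
    """

    interval: GenomicInterval
    sa_pos: int
    snoRNA_hosting: bool = False
    hosted_snorna: Optional[GenomicInterval] = None
    branchpoint: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class Gene:
    gene_id: str
    biotype: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    introns: list[Intron] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """First transcribed nucleotide."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def pa_site(self) -> int:
        """Last transcribed nucleotide (the annotated 3'-end position)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def last_exon(self) -> Optional[GenomicInterval]:
        """The 3'-most exon in transcription orientation."""
        if not self.exons:
            return None
        return self.exons[-1] if self.strand == "+" else self.exons[0]


def derive_introns(gene: Gene) -> list[Intron]:
    """Introns are the gaps between consecutive (sorted) exons of one gene."""
    introns = []
    exons = sorted(gene.exons, key=lambda e: e.start)
    for left, right in zip(exons, exons[1:]):
        if right.start < left.end:
            raise ValidationError(f"overlapping exons in gene {gene.gene_id}")
        if right.start == left.end:
            continue
        iv = GenomicInterval(gene.interval.chrom, left.end, right.start, gene.strand)
        sa = iv.end if gene.strand == "+" else iv.start - 1
        introns.append(Intron(interval=iv, sa_pos=sa))
    return introns


class Annotation:
    """A transcriptome annotation: genes with exons, derived introns,
    splice-acceptor positions, hosted snoRNAs and last exons."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}
        self._link_snornas()
        self._index: Optional[AnnotationIndex] = None

    def _link_snornas(self) -> None:
        """Flag introns that strictly contain a same-strand snoRNA gene."""
        snornas = [g for g in self.genes if g.biotype == "snoRNA"]
        for sno in snornas:
            si = sno.interval
            for g in self.genes:
                if g.biotype != "protein_coding" or g.strand != si.strand:
                    continue
                if g.interval.chrom != si.chrom:
                    continue
                for intr in g.introns:
                    ii = intr.interval
                    if ii.start < si.start and si.end < ii.end:
                        intr.snoRNA_hosting = True
                        intr.hosted_snorna = si

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def protein_coding(self) -> list[Gene]:
        return [g for g in self.genes if g.biotype == "protein_coding"]

    def index(self) -> "AnnotationIndex":
        if self._index is None:
            self._index = AnnotationIndex(self.genes)
        return self._index


class AnnotationIndex:
    """Strand-aware interval index over gene bodies for overlap queries."""

    def __init__(self, genes: Iterable[Gene]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            key = (g.interval.chrom, g.strand)
            tree = self._trees.setdefault(key, IntervalTree())
            tree.addi(g.interval.start, g.interval.end, g)

    def overlapping(self, query: GenomicInterval) -> list[Gene]:
        tree = self._trees.get((query.chrom, query.strand))
        if tree is None:
            return []
        hits = tree.overlap(query.start, query.end)
        return sorted((h.data for h in hits), key=lambda g: (g.interval.start, g.gene_id))


def overlap_any(query: GenomicInterval, subjects: AnnotationIndex) -> list[Gene]:
    """All same-strand subject genes with >= 1 nt intersection (half-open)."""
    return subjects.overlapping(query)


# ---------------------------------------------------------------------------
# Library metadata

TARGETS = ("ctrl", "ZCCHC8", "ZFC3H1", "EXOSC3", "EXOSC10", "PARN")
METHODS = ("AID", "RNAi")
PA_MODES = ("pA+", "pA+/-")


@dataclass(frozen=True)
class LibraryMeta:
    """One sequencing library: what was depleted, how, when, and which
    polyadenylation mode was captured (in-vivo pA+ only, or pA+/- after
    in-vitro polyadenylation)."""

    library_id: str
    target: str
    method: str
    timepoint_h: Optional[float]  # hours of IAA for AID; None for RNAi
    pA_mode: str
    replicate: int
    batch: Optional[str] = None

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValidationError(f"unknown depletion target {self.target!r}")
        if self.method not in METHODS:
            raise ValidationError(f"method must be AID or RNAi, got {self.method!r}")
        if self.pA_mode not in PA_MODES:
            raise ValidationError(f"pA_mode must be pA+ or pA+/-, got {self.pA_mode!r}")
        if self.method == "AID" and self.timepoint_h is None:
            raise ValidationError("AID libraries require a timepoint")


def read_metadata(path: str | Path) -> list[LibraryMeta]:
    df = pd.read_csv(path, sep="\t")
    metas = []
    for _, row in df.iterrows():
        tp = row.get("timepoint_h")
        if pd.isna(tp):
            tp = None
        else:
            tp = float(tp)
        batch = row.get("batch")
        if pd.isna(batch):
            batch = None
        metas.append(
            LibraryMeta(
                library_id=str(row["library_id"]),
                target=str(row["target"]),
                method=str(row["method"]),
                timepoint_h=tp,
                pA_mode=str(row["pA_mode"]),
                replicate=int(row["replicate"]),
                batch=None if batch is None else str(batch),
            )
        )
    return metas


def write_metadata(metas: Iterable[LibraryMeta], path: str | Path) -> None:
    rows = [
        {
            "library_id": m.library_id,
            "target": m.target,
            "method": m.method,
            "timepoint_h": "" if m.timepoint_h is None else m.timepoint_h,
            "pA_mode": m.pA_mode,
            "replicate": m.replicate,
            "batch": "" if m.batch is None else m.batch,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# End tracks


class EndTrack:
    """Sparse per-position transcript 3'-end coverage for one library.

    Positions absent from the map read as zero. Raw tracks hold non-negative
    integer counts; size-factor-normalized tracks hold non-negative reals and
    are flagged ``normalized``.
    """

    def __init__(self, library_id: str, normalized: bool = False):
        self.library_id = library_id
        self.normalized = normalized
        self.data: dict[tuple[str, str], dict[int, float]] = {}

    def add(self, chrom: str, strand: str, pos: int, value: float) -> None:
        if value < 0:
            raise ValidationError("3'-end counts must be non-negative")
        if value == 0:
            return
        self.data.setdefault((chrom, strand), {})[pos] = (
            self.data.get((chrom, strand), {}).get(pos, 0) + value
        )

    def get(self, chrom: str, strand: str, pos: int) -> float:
        return self.data.get((chrom, strand), {}).get(pos, 0.0)

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Sum of values in [start, end)."""
        sub = self.data.get((chrom, strand))
        if not sub:
            return 0.0
        if end - start < len(sub):
            return sum(sub.get(p, 0.0) for p in range(start, end))
        return sum(v for p, v in sub.items() if start <= p < end)

    def total(self) -> float:
        return sum(sum(sub.values()) for sub in self.data.values())

    def scaled(self, factor: float) -> "EndTrack":
        """Return a normalized copy with every value divided by ``factor``."""
        if factor <= 0:
            raise ValidationError("scaling factor must be positive")
        out = EndTrack(self.library_id, normalized=True)
        for key, sub in self.data.items():
            out.data[key] = {p: v / factor for p, v in sub.items()}
        return out

    def items(self) -> Iterator[tuple[str, str, int, float]]:
        for (chrom, strand), sub in self.data.items():
            for pos, val in sub.items():
                yield chrom, strand, pos, val


def read_endtrack(
    path: str | Path, strand: str, library_id: Optional[str] = None, normalized: bool = False
) -> EndTrack:
    """Read a single-strand bedGraph into an :class:`EndTrack`.

    Intervals must be sorted and non-overlapping; values must be >= 0.
    """
    if strand not in STRANDS:
        raise ValidationError(f"strand must be + or -, got {strand!r}")
    path = Path(path)
    if library_id is None:
        library_id = path.name.split(".")[0]
    track = EndTrack(library_id, normalized=normalized)
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative value {value}")
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if chrom in last and start < last[chrom]:
                raise ValidationError(
                    f"{path}:{lineno}: intervals overlap or are unsorted"
                )
            last[chrom] = end
            if value == 0:
                continue
            for pos in range(start, end):
                track.add(chrom, strand, pos, value)
    return track


def write_endtrack_strand(track: EndTrack, strand: str, path: str | Path) -> None:
    """Write one strand of a track as a sorted single-nucleotide bedGraph,
    merging runs of equal adjacent values (canonical form)."""
    lines = []
    for (chrom, s), sub in sorted(track.data.items()):
        if s != strand:
            continue
        run_start = run_end = None
        run_val = None
        for pos in sorted(sub):
            val = sub[pos]
            if run_start is not None and pos == run_end and val == run_val:
                run_end = pos + 1
                continue
            if run_start is not None:
                lines.append(f"{chrom}\t{run_start}\t{run_end}\t{run_val:g}")
            run_start, run_end, run_val = pos, pos + 1, val
        if run_start is not None:
            lines.append(f"{chrom}\t{run_start}\t{run_end}\t{run_val:g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_endtrack(track: EndTrack, prefix: str | Path) -> tuple[Path, Path]:
    """Write both strands as ``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph``."""
    prefix = Path(prefix)
    plus = prefix.parent / (prefix.name + PLUS_SUFFIX)
    minus = prefix.parent / (prefix.name + MINUS_SUFFIX)
    write_endtrack_strand(track, "+", plus)
    write_endtrack_strand(track, "-", minus)
    return plus, minus


def read_endtrack_pair(
    prefix: str | Path, library_id: Optional[str] = None, normalized: bool = False
) -> EndTrack:
    """Read a ``.plus.bedgraph``/``.minus.bedgraph`` pair into one track."""
    prefix = Path(prefix)
    if library_id is None:
        library_id = prefix.name
    track = EndTrack(library_id, normalized=normalized)
    for strand, suffix in (("+", PLUS_SUFFIX), ("-", MINUS_SUFFIX)):
        path = prefix.parent / (prefix.name + suffix)
        if not path.exists():
            continue
        part = read_endtrack(path, strand, library_id=library_id, normalized=normalized)
        for chrom, s, pos, val in part.items():
            track.add(chrom, s, pos, val)
    return track


# ---------------------------------------------------------------------------
# Annotation I/O

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_annotation(path: str | Path) -> Annotation:
    """Read a GTF (or BED12) annotation and derive introns, SA positions and
    last exons.

    GTF: ``gene`` and ``exon`` features are used; biotype comes from the
    ``gene_biotype`` attribute (default ``not_annotated``). BED12: one gene
    per line, blocks are exons, and the name field may carry the biotype as
    ``gene_id:biotype``.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12(path)
    return _read_gtf(path)


def _read_gtf(path: Path) -> Annotation:
    _validate_gtf_lines(path)
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    if "gene_biotype" not in df.columns:
        df["gene_biotype"] = "not_annotated"
    df["gene_biotype"] = df["gene_biotype"].fillna("not_annotated")
    genes: list[Gene] = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        exon_rows = grp[grp.Feature == "exon"]
        gene_rows = grp[grp.Feature == "gene"]
        strand = str(grp.Strand.iloc[0])
        chrom = str(grp.Chromosome.iloc[0])
        biotype = str(grp.gene_biotype.iloc[0])
        exons = [
            GenomicInterval(chrom, int(r.Start), int(r.End), strand)
            for r in exon_rows.sort_values("Start").itertuples()
        ]
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(f"overlapping exons in gene {gene_id}")
        if len(gene_rows):
            start, end = int(gene_rows.Start.iloc[0]), int(gene_rows.End.iloc[0])
        else:
            start, end = exons[0].start, exons[-1].end
        gene = Gene(
            gene_id=str(gene_id),
            biotype=biotype,
            interval=GenomicInterval(chrom, start, end, strand),
            exons=exons or [GenomicInterval(chrom, start, end, strand)],
        )
        gene.introns = derive_introns(gene)
        genes.append(gene)
    return Annotation(genes)


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates")
            if fields[6] not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: bad strand {fields[6]!r}")


def _read_bed12(path: Path) -> Annotation:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            gene_id, _, biotype = name.partition(":")
            biotype = biotype or "not_annotated"
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for s, o in zip(sizes, offsets)
            ]
            gene = Gene(
                gene_id=gene_id,
                biotype=biotype,
                interval=GenomicInterval(chrom, start, end, strand),
                exons=exons,
            )
            gene.introns = derive_introns(gene)
            genes.append(gene)
    return Annotation(genes)


def write_annotation_gtf(ann: Annotation, path: str | Path) -> None:
    """Write gene + exon features (GTF, converting back to 1-based closed)."""
    lines = []
    for g in sorted(ann.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        iv = g.interval
        lines.append(
            f"{iv.chrom}\tthreeprime\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}"
        )
        for ex in g.exons:
            lines.append(
                f"{ex.chrom}\tthreeprime\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
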