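"""3'-end cluster calling, per-library quantification and annotation.

Clusters aggregate proximal 3'-end positions: positions whose pooled
(cross-library) count reaches a seed threshold are single-linkage merged
along each strand when separated by at most ``max_gap`` nucleotides. Each
cluster is then assigned one biotype and, within protein-coding transcription
units, at most one feature label, by fixed most-specific-first priorities so
composition percentages are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genomic import (
    Annotation,
    EndTrack,
    Gene,
    GenomicInterval,
    ValidationError,
    overlap_any,
)

BIOTYPE_PRIORITY = ("PROMPT", "eRNA", "snoRNA", "lncRNA", "protein_coding")
FEATURE_PRIORITY = (
    "SA_snoRNA_host",
    "SA_regular",
    "PAS",
    "TSS_proximal",
    "exonic",
    "intronic",
)

#: summits within this many nt downstream of a TSS (sense) are TSS-proximal
TSS_PROXIMAL_SPAN = 3000
#: summits within this many nt upstream of the annotated pA site count as PAS
PAS_WINDOW = 25


@dataclass
class Cluster:
    id: str
    interval: GenomicInterval
    summit: int
    pooled_count: float = 0.0
    counts: dict[str, int] = field(default_factory=dict)


def call_clusters(
    tracks: Iterable[EndTrack], min_pos_count: float = 3, max_gap: int = 25
) -> list[Cluster]:
    """Pool counts across libraries per position/strand, seed positions with
    pooled count >= ``min_pos_count``, and merge same-strand seeds separated
    by <= ``max_gap`` nt. The summit is the (leftmost) max-pooled-signal
    nucleotide."""
    pooled: dict[tuple[str, str], dict[int, float]] = {}
    for t in tracks:
        for chrom, strand, pos, val in t.items():
            sub = pooled.setdefault((chrom, strand), {})
            sub[pos] = sub.get(pos, 0.0) + val

    clusters: list[Cluster] = []
    for (chrom, strand), sub in sorted(pooled.items()):
        seeds = sorted(p for p, v in sub.items() if v >= min_pos_count)
        if not seeds:
            continue
        run = [seeds[0]]
        for p in seeds[1:]:
            if p - run[-1] <= max_gap:
                run.append(p)
            else:
                clusters.append(_make_cluster(chrom, strand, run, sub))
                run = [p]
        clusters.append(_make_cluster(chrom, strand, run, sub))

    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.strand, c.interval.start))
    for i, c in enumerate(clusters, 1):
        c.id = f"cl{i:05d}"
    return clusters


def _make_cluster(chrom: str, strand: str, seeds: list[int], sub: dict[int, float]) -> Cluster:
    start, end = seeds[0], seeds[-1] + 1
    summit = max(range(start, end), key=lambda p: (sub.get(p, 0.0), -p))
    pooled = sum(sub.get(p, 0.0) for p in range(start, end))
    return Cluster("", GenomicInterval(chrom, start, end, strand), summit, pooled)


def count_matrix(clusters: Sequence[Cluster], tracks: Iterable[EndTrack]) -> pd.DataFrame:
    """Integer sums of raw 3'-end counts within each cluster per library.

    Also fills each cluster's per-library ``counts`` map.
    """
    _check_disjoint(clusters)
    tracks = list(tracks)
    data = {}
    for c in clusters:
        iv = c.interval
        row = []
        for t in tracks:
            v = t.window_sum(iv.chrom, iv.strand, iv.start, iv.end)
            iv_count = int(round(v))
            c.counts[t.library_id] = iv_count
            row.append(iv_count)
        data[c.id] = row
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[t.library_id for t in tracks]
    )


def _check_disjoint(clusters: Sequence[Cluster]) -> None:
    by_key: dict[tuple[str, str], list[Cluster]] = {}
    for c in clusters:
        by_key.setdefault((c.interval.chrom, c.interval.strand), []).append(c)
    for key, group in by_key.items():
        group = sorted(group, key=lambda c: c.interval.start)
        for a, b in zip(group, group[1:]):
            if b.interval.start < a.interval.end:
                raise ValidationError(
                    f"overlapping same-strand clusters {a.id} and {b.id}"
                )


# ---------------------------------------------------------------------------
# Annotation of clusters


def _sa_offset(pos: int, sa: int, strand: str) -> int:
    """Transcription-orientation offset of ``pos`` relative to an SA anchor
    (negative = intronic/upstream side)."""
    return pos - sa if strand == "+" else sa - pos


def annotate_clusters(
    clusters: Sequence[Cluster], ann: Annotation, sa_window: int = 10
) -> pd.DataFrame:
    """Assign each cluster one biotype and, for protein-coding clusters, at
    most one intra-genic feature label.

    Biotype priority: PROMPT > eRNA > snoRNA > lncRNA > protein_coding >
    not_annotated (overlap of >= 1 nt, strand-matched). Feature priority:
    SA_snoRNA_host > SA_regular > PAS > TSS_proximal > exonic > intronic.
    A cluster sits "at an SA" when its summit lies within ``sa_window`` nt
    upstream of the splice acceptor in transcription orientation.
    """
    index = ann.index()
    rows = []
    for c in clusters:
        hits = overlap_any(c.interval, index)
        biotype = _assign_biotype(hits)
        feature = None
        if biotype == "protein_coding":
            pc_hits = [g for g in hits if g.biotype == "protein_coding"]
            feature = _assign_feature(c, pc_hits, sa_window)
        rows.append({"cluster_id": c.id, "biotype": biotype, "feature": feature})
    return pd.DataFrame(rows).set_index("cluster_id")


def _assign_biotype(hits: list[Gene]) -> str:
    present = {g.biotype for g in hits}
    for bt in BIOTYPE_PRIORITY:
        if bt in present:
            return bt
    return "not_annotated"


def _assign_feature(c: Cluster, genes: list[Gene], sa_window: int) -> Optional[str]:
    labels = set()
    s = c.summit
    for g in genes:
        strand = g.strand
        for intr in g.introns:
            off = _sa_offset(s, intr.sa_pos, strand)
            if -sa_window <= off < 0:
                labels.add("SA_snoRNA_host" if intr.snoRNA_hosting else "SA_regular")
        off_pas = _sa_offset(s, g.pa_site, strand)
        if -PAS_WINDOW <= off_pas <= 0:
            labels.add("PAS")
        # TSS-proximal: summit within TSS_PROXIMAL_SPAN downstream of the TSS
        downstream = s - g.tss if strand == "+" else g.tss - s
        if 0 <= downstream <= TSS_PROXIMAL_SPAN:
            labels.add("TSS_proximal")
        if any(ex.contains_pos(s) for ex in g.exons):
            labels.add("exonic")
        elif g.interval.contains_pos(s):
            labels.add("intronic")
    for lab in FEATURE_PRIORITY:
        if lab in labels:
            return lab
    return None
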