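"""Anchor-point metagene profiles and the 3'-end trimming read-out.

Metagenes summarize normalized 3'-end coverage at single-nucleotide
resolution around oriented anchors (splice acceptors, TSSs, pA sites, ...).
Coverage is summed across anchors per orientation offset for the treated and
reference tracks separately, then displayed as one log2 ratio per offset
with a pseudocount — robust to per-anchor zeros. A mean-of-per-anchor-log-
ratios alternative is available behind ``aggregate='mean'``.

The trimming read-out quantifies nonprocessive 3'-5' exonucleolytic
trimming upstream of splice acceptors: distal signal surviving while
proximal signal is lost yields ratios above 1, both for qPCR amplicon pairs
and for the in-silico window index on sequencing tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genomic import Annotation, EndTrack, ValidationError
from .targeting import intron_length_class

ANCHOR_KINDS = ("SA", "TSS", "PAS", "branchpoint", "snoRNA_3prime")


def sa_anchor_table(
    ann: Annotation,
    snorna_hosting: Optional[bool] = None,
) -> pd.DataFrame:
    """Splice-acceptor anchors with intron metadata.

    Columns: chrom, pos, strand, kind, intron_length, length_class,
    snoRNA_hosting. ``snorna_hosting`` filters to hosting (True) or regular
    (False) introns; None keeps all.
    """
    rows = []
    for g in ann.protein_coding():
        for intr in g.introns:
            if snorna_hosting is not None and intr.snoRNA_hosting != snorna_hosting:
                continue
            rows.append(
                {
                    "chrom": intr.interval.chrom,
                    "pos": intr.sa_pos,
                    "strand": g.strand,
                    "kind": "SA",
                    "intron_length": intr.length,
                    "length_class": intron_length_class(intr.length),
                    "snoRNA_hosting": intr.snoRNA_hosting,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "kind",
            "intron_length", "length_class", "snoRNA_hosting",
        ],
    )


@dataclass
class MetageneProfile:
    """log2-ratio profile over orientation offsets -upstream..downstream-1
    (anchor at offset 0)."""

    offsets: np.ndarray
    values: np.ndarray
    upstream: int
    downstream: int
    pseudocount: float
    n_anchors: int
    n_skipped: int
    treated_id: str
    reference_id: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "log2_ratio": self.values})


def _window_coverage(
    track: EndTrack, chrom: str, strand: str, pos: int, upstream: int, downstream: int
) -> np.ndarray:
    """Coverage over orientation offsets [-upstream, downstream) around an
    anchor; for minus-strand anchors the genomic window is reversed so
    upstream/downstream follow transcription orientation."""
    offsets = np.arange(-upstream, downstream)
    if strand == "+":
        positions = pos + offsets
    else:
        positions = pos - offsets
    return np.array([track.get(chrom, strand, int(p)) for p in positions])


def metagene(
    treated: EndTrack,
    reference: EndTrack,
    anchors: pd.DataFrame,
    upstream: int = 150,
    downstream: int = 100,
    pseudocount: float = 1.0,
    aggregate: str = "sum",
) -> MetageneProfile:
    """Single-nucleotide metagene of treated vs reference around anchors.

    Both tracks must be normalized under the same size-factor scheme.
    Anchors whose window would cross the chromosome start are skipped (and
    counted), keeping per-offset denominators uniform.
    """
    if not (treated.normalized and reference.normalized):
        raise ValidationError("metagene expects normalized tracks")
    if aggregate not in ("sum", "mean"):
        raise ValidationError("aggregate must be 'sum' or 'mean'")
    offsets = np.arange(-upstream, downstream)
    t_sum = np.zeros(len(offsets))
    r_sum = np.zeros(len(offsets))
    per_anchor: list[np.ndarray] = []
    n_used = n_skipped = 0
    for row in anchors.itertuples():
        lo = row.pos - upstream if row.strand == "+" else row.pos - downstream + 1
        if lo < 0:
            n_skipped += 1
            continue
        t = _window_coverage(treated, row.chrom, row.strand, row.pos, upstream, downstream)
        r = _window_coverage(reference, row.chrom, row.strand, row.pos, upstream, downstream)
        if aggregate == "sum":
            t_sum += t
            r_sum += r
        else:
            per_anchor.append(np.log2((t + pseudocount) / (r + pseudocount)))
        n_used += 1
    if aggregate == "sum":
        values = np.log2((t_sum + pseudocount) / (r_sum + pseudocount))
    else:
        values = (
            np.mean(per_anchor, axis=0) if per_anchor else np.zeros(len(offsets))
        )
    return MetageneProfile(
        offsets=offsets,
        values=values,
        upstream=upstream,
        downstream=downstream,
        pseudocount=pseudocount,
        n_anchors=n_used,
        n_skipped=n_skipped,
        treated_id=treated.library_id,
        reference_id=reference.library_id,
    )


def qpcr_normalize(ct_target: float, ct_reference: float) -> float:
    """Relative quantity 2^-(Ct_target - Ct_reference)."""
    return 2.0 ** -(ct_target - ct_reference)


def trimming_factor(distal_q: float, proximal_q: float) -> float:
    """Ratio of SA-distal to SA-proximal amplicon quantities.

    Values > 1 indicate 3'-trimmed species retaining the distal but not the
    proximal region; a uniform k-fold change of both amplicons cancels.
    """
    if proximal_q <= 0:
        raise ValidationError("proximal quantity must be positive")
    return distal_q / proximal_q


def insilico_trimming_index(
    track: EndTrack,
    sa_anchors: pd.DataFrame,
    proximal_window: tuple[int, int] = (-10, 0),
    distal_window: tuple[int, int] = (-150, -20),
    pseudocount: float = 1.0,
) -> float:
    """Sequencing-track analogue of the trimming factor at SA anchors.

    Windows are inclusive orientation-offset ranges relative to the SA
    (offset 0 = first exonic nucleotide; the SA 3'-end peak sits at -1).
    Index = (distal signal + pc) / (proximal signal + pc), summed over all
    anchors. Sharp SA peaks give indices < 1; an upstream trimming smear
    pushes the index above 1.
    """
    p_lo, p_hi = proximal_window
    d_lo, d_hi = distal_window
    if p_lo > p_hi or d_lo > d_hi:
        raise ValidationError("window bounds must be (low, high)")
    if not (d_hi < p_lo or p_hi < d_lo):
        raise ValidationError("proximal and distal windows overlap")
    prox = dist = 0.0
    for row in sa_anchors.itertuples():
        for off in range(p_lo, p_hi + 1):
            pos = row.pos + off if row.strand == "+" else row.pos - off
            prox += track.get(row.chrom, row.strand, int(pos))
        for off in range(d_lo, d_hi + 1):
            pos = row.pos + off if row.strand == "+" else row.pos - off
            dist += track.get(row.chrom, row.strand, int(pos))
    return (dist + pseudocount) / (prox + pseudocount)
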