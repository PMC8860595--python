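"""Library-size normalization anchored on protein-coding last exons.

Bulk mRNA 3'-end signal in last exons is assumed insensitive to nuclear
exosome depletion, so summed last-exon counts provide the invariant set for
median-of-ratios size-factor estimation. One estimator is used for all
libraries (AID and RNAi alike).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genomic import Annotation, EndTrack, ValidationError

SizeFactors = Mapping[str, float]


def last_exon_matrix(tracks: Iterable[EndTrack], ann: Annotation) -> pd.DataFrame:
    """Sum raw 3'-end counts within each protein-coding last exon, per library.

    Rows are gene ids, columns library ids; counting is strand-matched.
    """
    tracks = list(tracks)
    if any(t.normalized for t in tracks):
        raise ValidationError("last_exon_matrix expects raw (unnormalized) tracks")
    pc = ann.protein_coding()
    if not pc:
        raise ValidationError("annotation contains no protein-coding genes")
    rows = {}
    for g in pc:
        le = g.last_exon
        if le is None:
            continue
        rows[g.gene_id] = [
            t.window_sum(le.chrom, le.strand, le.start, le.end) for t in tracks
        ]
    mat = pd.DataFrame.from_dict(
        rows, orient="index", columns=[t.library_id for t in tracks]
    )
    return mat


def filter_expressed(matrix: pd.DataFrame, min_reads: int = 100) -> pd.DataFrame:
    """Keep rows with more than ``min_reads`` in at least one library
    (strict inequality)."""
    kept = matrix[matrix.max(axis=1) > min_reads]
    if kept.empty:
        raise ValidationError(
            f"no rows exceed {min_reads} reads in any library; lower min_reads"
        )
    return kept


def _lower_median(values: np.ndarray) -> float:
    """Median with the lower-of-two convention on even counts, for
    bit-reproducibility."""
    v = np.sort(np.asarray(values, dtype=float))
    return float(v[(len(v) - 1) // 2])


def size_factors(matrix: pd.DataFrame, pseudocount: float = 1.0) -> dict[str, float]:
    """Median-of-ratios size factors on pseudocounted counts.

    Per row, the reference is the geometric mean across libraries of the
    pseudocounted counts; a library's factor is the (lower-)median over rows
    of its pseudocounted count divided by that reference.
    """
    if matrix.shape[0] < 1 or matrix.shape[1] < 2:
        raise ValidationError("size_factors needs >=1 row and >=2 libraries")
    x = matrix.to_numpy(dtype=float) + pseudocount
    if np.any(x <= 0):
        raise ValidationError("counts + pseudocount must be positive")
    ref = np.exp(np.mean(np.log(x), axis=1))
    factors = {}
    for j, lib in enumerate(matrix.columns):
        ratios = x[:, j] / ref
        f = _lower_median(ratios)
        if not np.isfinite(f) or f <= 0:
            raise ValidationError(f"degenerate size factor for library {lib}")
        factors[lib] = f
    return factors


def normalize_counts(counts: pd.DataFrame, sf: SizeFactors) -> pd.DataFrame:
    """Divide each library column by its size factor."""
    missing = [c for c in counts.columns if c not in sf]
    if missing:
        raise ValidationError(f"no size factor for libraries: {missing}")
    return counts / pd.Series(dict(sf))[counts.columns]


def normalize_track(track: EndTrack, sf: SizeFactors) -> EndTrack:
    """Return the track scaled by 1/size-factor, flagged as normalized."""
    if track.library_id not in sf:
        raise ValidationError(f"no size factor for library {track.library_id}")
    return track.scaled(sf[track.library_id])
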