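"""Depletion-sensitivity scoring and NEXT/PAXT target classification.

The sensitivity statistic summarizes a cluster's response to a depletion as

    sensitivity = (treated - ctrl) / max(ctrl, treated, 1)

on replicate-averaged, size-factor-normalized cluster counts. It is bounded
in [-1, 1]: 1 means signal exclusive to the depletion sample, -1 exclusive
to the reference, 0 equal signal. The unit floor in the denominator keeps
near-zero signals from saturating the scale.

Targeting classes intersect upregulated-cluster calls from long-term (RNAi)
and rapid (AID, 6 h) depletions of the NEXT component ZCCHC8 and the PAXT
component ZFC3H1, then enforce mutual exclusion, distinguishing direct
pathway targets from clusters responding to either or both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genomic import ValidationError

LENGTH_CLASS_BOUNDS = (700, 4000)  # <700 short; 700-4000 medium; >4000 long


def sensitivity(treated: float, ctrl: float) -> float:
    """(treated - ctrl) / max(ctrl, treated, 1) on non-negative signals."""
    if treated < 0 or ctrl < 0:
        raise ValidationError("sensitivity inputs must be non-negative")
    return (treated - ctrl) / max(ctrl, treated, 1.0)


@dataclass
class Contrast:
    """Named treated-vs-reference library grouping for sensitivity maps."""

    name: str
    treated_libs: Sequence[str]
    reference_libs: Sequence[str]


def sensitivity_matrix(
    norm_counts: pd.DataFrame, contrasts: Sequence[Contrast]
) -> pd.DataFrame:
    """Cluster x contrast sensitivity values from normalized counts.

    Replicates are arithmetic-averaged per group before the ratio. The AID
    reference is the 0 h library group of the same tagged line; the RNAi
    reference is the control-siRNA group.
    """
    cols = {}
    for ct in contrasts:
        if not len(ct.treated_libs) or not len(ct.reference_libs):
            raise ValidationError(f"contrast {ct.name} has an empty group")
        missing = [
            c for c in (*ct.treated_libs, *ct.reference_libs)
            if c not in norm_counts.columns
        ]
        if missing:
            raise ValidationError(f"contrast {ct.name}: unknown libraries {missing}")
        t = norm_counts[list(ct.treated_libs)].mean(axis=1).to_numpy()
        r = norm_counts[list(ct.reference_libs)].mean(axis=1).to_numpy()
        cols[ct.name] = (t - r) / np.maximum.reduce([r, t, np.ones_like(t)])
    return pd.DataFrame(cols, index=norm_counts.index)


@dataclass
class TargetClass:
    pathway: str  # NEXT | PAXT
    definition: str  # RNAi | RNAi+AID
    members: set[str] = field(default_factory=set)


def classify_targets(
    up_rnai_zcchc8: set[str],
    up_aid6_zcchc8: set[str],
    up_rnai_zfc3h1: set[str],
    up_aid6_zfc3h1: set[str],
    mode: str = "RNAi+AID",
) -> tuple[TargetClass, TargetClass]:
    """Mutually exclusive NEXT and PAXT targeting classes.

    In ``RNAi+AID`` mode candidates are the RNAi/AID-6h intersections per
    factor; in ``RNAi`` mode the RNAi sets alone. Clusters in both candidate
    sets are excluded from both classes.
    """
    if mode == "RNAi+AID":
        next_cand = up_rnai_zcchc8 & up_aid6_zcchc8
        paxt_cand = up_rnai_zfc3h1 & up_aid6_zfc3h1
    elif mode == "RNAi":
        next_cand = set(up_rnai_zcchc8)
        paxt_cand = set(up_rnai_zfc3h1)
    else:
        raise ValidationError(f"unknown classification mode {mode!r}")
    next_cls = TargetClass("NEXT", mode, next_cand - paxt_cand)
    paxt_cls = TargetClass("PAXT", mode, paxt_cand - next_cand)
    return next_cls, paxt_cls


def union_pa_modes(up_sets: Mapping[str, set[str]]) -> set[str]:
    """Combine upregulated calls across pA+ and pA+/- libraries of one
    method (union by default; the two modes probe complementary 3'-end
    populations)."""
    out: set[str] = set()
    for s in up_sets.values():
        out |= s
    return out


def composition(
    cls: TargetClass, annot: pd.DataFrame, level: str = "biotype"
) -> pd.Series:
    """Percentage of class members per biotype (or feature) label; sums
    to 100 within rounding. Unannotated members count as ``not_annotated``."""
    if level not in ("biotype", "feature"):
        raise ValidationError("level must be 'biotype' or 'feature'")
    if not cls.members:
        import warnings

        warnings.warn(f"empty {cls.pathway} class; empty composition")
        return pd.Series(dtype=float)
    labels = []
    for cid in sorted(cls.members):
        lab = annot[level].get(cid) if cid in annot.index else None
        if lab is None or (isinstance(lab, float) and np.isnan(lab)):
            lab = "not_annotated"
        labels.append(lab)
    counts = pd.Series(labels).value_counts()
    return counts / counts.sum() * 100.0


def intron_length_class(length_nt: int) -> str:
    """short (<700), medium (700-4000, inclusive) or long (>4000)."""
    if length_nt <= 0:
        raise ValidationError("intron length must be positive")
    lo, hi = LENGTH_CLASS_BOUNDS
    if length_nt < lo:
        return "short"
    if length_nt <= hi:
        return "medium"
    return "long"


def sa_overlap_fraction(
    sa_anchors: pd.DataFrame,
    up_sets: Mapping[str, set[str]],
    clusters: Mapping[str, "object"],
    sa_window: int = 10,
    denominator: str = "all",
) -> pd.DataFrame:
    """Per length class and condition, the percentage of SA sites with at
    least one upregulated cluster whose summit lies within ``sa_window`` nt
    upstream of the SA (transcription orientation).

    ``sa_anchors`` needs columns chrom, pos, strand, length_class.
    ``clusters`` maps cluster_id -> Cluster. ``denominator='all'`` uses every
    anchor in the stratum; ``'expressed'`` restricts to anchors having at
    least one called cluster in the window, whatever its regulation status.
    """
    if denominator not in ("all", "expressed"):
        raise ValidationError("denominator must be 'all' or 'expressed'")
    # index cluster summits by (chrom, strand)
    summits: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for cid, c in clusters.items():
        summits.setdefault((c.interval.chrom, c.interval.strand), []).append(
            (c.summit, cid)
        )

    def hit_ids(row) -> set[str]:
        found = set()
        for pos, cid in summits.get((row.chrom, row.strand), []):
            off = pos - row.pos if row.strand == "+" else row.pos - pos
            if -sa_window <= off < 0:
                found.add(cid)
        return found

    anchor_hits = [hit_ids(r) for r in sa_anchors.itertuples()]
    out = {}
    order = [c for c in ("short", "medium", "long") if c in set(sa_anchors.length_class)]
    for cond, up in up_sets.items():
        fracs = {}
        for lc in order:
            idx = [i for i, r in enumerate(sa_anchors.itertuples()) if r.length_class == lc]
            if denominator == "expressed":
                idx = [i for i in idx if anchor_hits[i]]
            if not idx:
                fracs[lc] = np.nan
                continue
            n_hit = sum(1 for i in idx if anchor_hits[i] & up)
            fracs[lc] = 100.0 * n_hit / len(idx)
        out[cond] = fracs
    return pd.DataFrame(out).reindex(order)
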