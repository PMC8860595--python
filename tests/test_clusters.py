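"""Cluster calling, counting and annotation against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from threeprime import (
    Annotation,
    EndTrack,
    SimConfig,
    ValidationError,
    annotate_clusters,
    call_clusters,
    count_matrix,
    default_design,
    simulate_annotation,
    simulate_tracks,
)
from threeprime.clusters import Cluster
from threeprime.genomic import GenomicInterval
from tests.test_genomic import make_gene


def track_from(positions: dict, strand="+", lib="lib"):
    t = EndTrack(lib)
    for pos, v in positions.items():
        t.add("chr1", strand, pos, v)
    return t


def brute_force_single_linkage(positions: list[int], max_gap: int) -> list[tuple[int, int]]:
    """O(n^2) single-linkage merge of seed positions."""
    if not positions:
        return []
    groups = [[p] for p in sorted(positions)]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups) - 1):
            if min(abs(a - b) for a in groups[i] for b in groups[i + 1]) <= max_gap:
                groups[i] += groups.pop(i + 1)
                changed = True
                break
    return [(min(g), max(g) + 1) for g in groups]


class TestCallClusters:
    def test_merge_within_gap(self):
        t = track_from({100: 5, 110: 4})
        cl = call_clusters([t], min_pos_count=3, max_gap=25)
        assert len(cl) == 1
        assert (cl[0].interval.start, cl[0].interval.end) == (100, 111)

    def test_split_beyond_gap(self):
        t = track_from({100: 5, 200: 4})
        cl = call_clusters([t], min_pos_count=3, max_gap=25)
        assert len(cl) == 2

    def test_below_seed_threshold_yields_nothing(self):
        t = track_from({100: 2, 110: 2})
        assert call_clusters([t], min_pos_count=3) == []

    def test_pooling_across_libraries_reaches_threshold(self):
        t1, t2 = track_from({100: 2}, lib="a"), track_from({100: 2}, lib="b")
        assert len(call_clusters([t1, t2], min_pos_count=3)) == 1

    def test_strands_never_merge(self):
        t = EndTrack("l")
        t.add("chr1", "+", 100, 5)
        t.add("chr1", "-", 105, 5)
        assert len(call_clusters([t])) == 2

    def test_summit_is_max_position(self):
        t = track_from({100: 3, 105: 9, 110: 3})
        (c,) = call_clusters([t])
        assert c.summit == 105

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_matches_brute_force_single_linkage(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**20)))
        gap = data.draw(st.integers(1, 40))
        positions = {
            int(p): int(rng.integers(1, 10))
            for p in rng.integers(0, 2000, size=rng.integers(0, 60))
        }
        t = track_from(positions)
        got = [
            (c.interval.start, c.interval.end)
            for c in call_clusters([t], min_pos_count=3, max_gap=gap)
        ]
        seeds = [p for p, v in positions.items() if v >= 3]
        assert got == sorted(brute_force_single_linkage(seeds, gap))


class TestCountMatrix:
    def test_single_position(self):
        t = track_from({100: 7})
        cl = [Cluster("c1", GenomicInterval("chr1", 100, 101, "+"), 100)]
        mat = count_matrix(cl, [t])
        assert mat.loc["c1", "lib"] == 7

    def test_conservation_under_partition(self):
        t = track_from({i: 2 for i in range(100, 120)})
        cl = [
            Cluster("c1", GenomicInterval("chr1", 100, 110, "+"), 100),
            Cluster("c2", GenomicInterval("chr1", 110, 120, "+"), 110),
        ]
        mat = count_matrix(cl, [t])
        assert mat["lib"].sum() == t.total()

    def test_overlapping_clusters_rejected(self):
        cl = [
            Cluster("c1", GenomicInterval("chr1", 100, 110, "+"), 100),
            Cluster("c2", GenomicInterval("chr1", 105, 120, "+"), 110),
        ]
        with pytest.raises(ValidationError):
            count_matrix(cl, [track_from({})])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**20))
    def test_equals_per_nucleotide_sum(self, seed):
        rng = np.random.default_rng(seed)
        positions = {
            int(p): int(rng.integers(1, 20))
            for p in rng.integers(0, 1000, size=50)
        }
        t = track_from(positions)
        bounds = sorted(rng.choice(1001, size=6, replace=False))
        cl = [
            Cluster(f"c{i}", GenomicInterval("chr1", int(a), int(b), "+"), int(a))
            for i, (a, b) in enumerate(zip(bounds[::2], bounds[1::2]))
            if a < b
        ]
        mat = count_matrix(cl, [t])
        for c in cl:
            brute = sum(
                v for p, v in positions.items()
                if c.interval.start <= p < c.interval.end
            )
            assert mat.loc[c.id, "lib"] == brute


class TestAnnotateClusters:
    @pytest.fixture
    def ann(self):
        host = make_gene("host", "chr1", "+", [(1000, 1200), (2000, 2200), (5000, 5400)])
        sno = make_gene("sno", "chr1", "+", [(1400, 1500)], biotype="snoRNA")
        prompt = make_gene("pro", "chr1", "-", [(200, 700)], biotype="PROMPT")
        lnc = make_gene("lnc", "chr1", "-", [(100, 800)], biotype="lncRNA")
        return Annotation([host, sno, prompt, lnc])

    def _annot(self, ann, chrom, summit, strand, width=4):
        c = Cluster("c1", GenomicInterval(chrom, summit - width + 1, summit + 1, strand)
                    if strand == "+" else GenomicInterval(chrom, summit, summit + width, strand),
                    summit)
        return annotate_clusters([c], ann).loc["c1"]

    def test_sa_of_hosting_intron(self, ann):
        # first intron [1200,2000) hosts the snoRNA; SA at 2000
        row = self._annot(ann, "chr1", 1996, "+")
        assert row.biotype == "protein_coding"
        assert row.feature == "SA_snoRNA_host"

    def test_sa_of_regular_intron(self, ann):
        # second intron [2200,5000) has no snoRNA; SA at 5000
        row = self._annot(ann, "chr1", 4995, "+")
        assert row.feature == "SA_regular"

    def test_prompt_priority_over_lncrna(self, ann):
        row = self._annot(ann, "chr1", 500, "-")
        assert row.biotype == "PROMPT"

    def test_unknown_chromosome(self, ann):
        row = self._annot(ann, "chrUn", 500, "+")
        assert row.biotype == "not_annotated" and row.feature is None

    def test_pas_at_annotated_three_prime_end(self, ann):
        row = self._annot(ann, "chr1", 5399, "+")
        assert row.feature == "PAS"

    def test_tss_proximal(self, ann):
        row = self._annot(ann, "chr1", 1100, "+")
        assert row.feature in ("TSS_proximal",)


class TestPlantedRecovery:
    def test_planted_clusters_recovered_with_high_jaccard(self):
        # smear-free conditions: the caller must recover planted footprints
        cfg = SimConfig(seed=13, n_genes=15, n_ernas=4, n_lncrnas=2, smear_fraction=0.0)
        ann = simulate_annotation(cfg)
        design = default_design()
        tracks, truth = simulate_tracks(ann, cfg, design)
        clusters = call_clusters(tracks.values())
        jaccards = []
        for t in truth.itertuples():
            best = 0.0
            for c in clusters:
                iv = c.interval
                if iv.chrom != t.chrom or iv.strand != t.strand:
                    continue
                inter = min(iv.end, t.end) - max(iv.start, t.start)
                if inter <= 0:
                    continue
                union = max(iv.end, t.end) - min(iv.start, t.start)
                best = max(best, inter / union)
            jaccards.append(best)
        recovered = sum(1 for j in jaccards if j >= 0.8)
        assert recovered / len(jaccards) >= 0.95

    def test_feature_composition_matches_truth(self, sim_bundle):
        truth = sim_bundle["truth"]
        ann = sim_bundle["ann"]
        clusters = sim_bundle["clusters"]
        annot = annotate_clusters(clusters, ann)
        # map called clusters back to planted ones by summit containment
        by_pos = {}
        for c in clusters:
            by_pos[(c.interval.chrom, c.interval.strand, c.summit)] = c.id
        matched = 0
        agree = 0
        for t in truth.itertuples():
            cid = by_pos.get((t.chrom, t.strand, t.summit))
            if cid is None:
                continue
            matched += 1
            called = annot.loc[cid]
            if t.feature in ("PROMPT", "eRNA", "lncRNA"):
                agree += called.biotype == t.feature
            elif t.feature == "ptRNA":
                agree += called.feature == "TSS_proximal"
            elif t.feature in ("SA_regular", "SA_snoRNA_host", "PAS"):
                agree += called.feature == t.feature
        assert matched / len(truth) > 0.9
        assert agree / matched > 0.95
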