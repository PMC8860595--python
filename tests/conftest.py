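import pandas as pd
import pytest

from threeprime import (
    SimConfig,
    call_clusters,
    call_upregulated,
    count_matrix,
    default_design,
    filter_expressed,
    last_exon_matrix,
    nb_wald,
    normalize_counts,
    simulate_annotation,
    simulate_tracks,
    size_factors,
)
from threeprime.pipeline import _contrast_groups, _design_for


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def sim_bundle(sim_cfg):
    """Full synthetic experiment analyzed end-to-end, shared across tests."""
    ann = simulate_annotation(sim_cfg)
    metas = default_design()
    tracks, truth = simulate_tracks(ann, sim_cfg, metas)
    le = filter_expressed(last_exon_matrix(tracks.values(), ann))
    sf = size_factors(le)
    clusters = call_clusters(tracks.values())
    counts = count_matrix(clusters, tracks.values())
    norm = normalize_counts(counts, sf)
    up_sets = {}
    results = {}
    for name, trts, refs, batch in _contrast_groups(metas):
        design = _design_for(name, trts, refs, batch)
        res = nb_wald(counts[trts + refs], sf, design)
        results[name] = res
        up_sets[name] = call_upregulated(res)
    return {
        "cfg": sim_cfg,
        "ann": ann,
        "metas": metas,
        "tracks": tracks,
        "truth": truth,
        "sf": sf,
        "clusters": clusters,
        "counts": counts,
        "norm": norm,
        "results": results,
        "up_sets": up_sets,
    }


def truth_overlapping_calls(truth_row, clusters) -> list[str]:
    """Called cluster ids overlapping a planted truth interval (>=1 nt,
    strand-matched)."""
    return [
        c.id
        for c in clusters
        if c.interval.chrom == truth_row.chrom
        and c.interval.strand == truth_row.strand
        and c.interval.start < truth_row.end
        and truth_row.start < c.interval.end
    ]
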