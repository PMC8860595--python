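"""End-to-end orchestration of the 3'-end-seq analysis stages.

``run_all`` executes (optionally) simulate -> normalize -> cluster ->
differential expression -> sensitivity/classification -> composition and
SA-overlap summaries -> metagene/trimming -> PCA, writing TSV outputs whose
header comment names the producing stage and a parameter hash, plus a
reproducibility manifest (config, versions, output checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .genomic import (
    Annotation,
    EndTrack,
    LibraryMeta,
    ValidationError,
    read_annotation,
    read_endtrack_pair,
    read_metadata,
    write_annotation_gtf,
    write_endtrack,
    write_metadata,
)
from .simulate import SimConfig, default_design, simulate_annotation, simulate_tracks
from .normalize import (
    filter_expressed,
    last_exon_matrix,
    normalize_counts,
    normalize_track,
    size_factors,
)
from .clusters import annotate_clusters, call_clusters, count_matrix
from .diffexp import DesignInfo, call_upregulated, nb_wald, pca_top_variance
from .targeting import (
    Contrast,
    classify_targets,
    composition,
    sa_overlap_fraction,
    sensitivity_matrix,
    union_pa_modes,
)
from .profiles import insilico_trimming_index, metagene, sa_anchor_table

log = logging.getLogger("threeprime")


@dataclass
class RunConfig:
    """Single configuration for a full pipeline run; serialized verbatim
    into the output manifest."""

    outdir: str = "threeprime_out"
    tracks_dir: Optional[str] = None  # holds <library_id>.plus/.minus.bedgraph
    annotation: Optional[str] = None
    metadata: Optional[str] = None
    simulate: bool = False
    seed: int = 0
    min_reads: int = 100
    pseudocount: float = 1.0
    lfc_min: float = 1.0
    padj_max: float = 0.1
    n_top: int = 2000
    metagene_upstream: int = 150
    metagene_downstream: int = 100
    sa_window: int = 10
    min_pos_count: float = 3
    max_gap: int = 25
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def params_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded: the hash
        identifies the computation, not where it ran)."""
        d = dataclasses.asdict(self)
        for path_field in ("outdir", "tracks_dir", "annotation", "metadata"):
            d.pop(path_field, None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg: RunConfig,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} params={cfg.params_hash()} threeprime={__version__}\n")
        df.to_csv(fh, sep="\t", index=index)


def _contrast_groups(metas: Sequence[LibraryMeta]):
    """Canonical contrasts: each AID (target, timepoint>0, pA mode) vs the
    same line's 0 h libraries; each RNAi (target != ctrl, pA mode) vs the
    ctrl-siRNA libraries of the same mode."""
    out = []
    aid = [m for m in metas if m.method == "AID"]
    for target in sorted({m.target for m in aid}):
        for mode in sorted({m.pA_mode for m in aid}):
            refs = [m.library_id for m in aid
                    if m.target == target and m.pA_mode == mode and m.timepoint_h == 0]
            if not refs:
                continue
            for tp in sorted({m.timepoint_h for m in aid if m.target == target} - {0.0}):
                trts = [m.library_id for m in aid
                        if m.target == target and m.pA_mode == mode and m.timepoint_h == tp]
                if trts:
                    mtag = "pApm" if mode == "pA+/-" else "pAp"
                    out.append((f"{target}_AID_{tp:g}h_{mtag}", trts, refs, None))
    rnai = [m for m in metas if m.method == "RNAi"]
    ctrl = {mode: [m.library_id for m in rnai if m.target == "ctrl" and m.pA_mode == mode]
            for mode in {m.pA_mode for m in rnai}}
    batch = {m.library_id: m.batch for m in rnai}
    for target in sorted({m.target for m in rnai} - {"ctrl"}):
        for mode in sorted({m.pA_mode for m in rnai}):
            trts = [m.library_id for m in rnai if m.target == target and m.pA_mode == mode]
            refs = ctrl.get(mode, [])
            if trts and refs:
                mtag = "pApm" if mode == "pA+/-" else "pAp"
                use_batch = any(batch.get(l) for l in trts + refs)
                out.append((f"{target}_RNAi_{mtag}", trts, refs,
                            batch if use_batch else None))
    return out


def _design_for(name: str, trts: list[str], refs: list[str],
                batch: Optional[dict]) -> DesignInfo:
    libs = trts + refs
    cond = pd.Series({l: ("trt" if l in trts else "ref") for l in libs})
    b = None
    if batch is not None:
        vals = {l: (batch.get(l) or "b?") for l in libs}
        if len(set(vals.values())) > 1:
            b = pd.Series(vals)
    return DesignInfo(condition=cond, treated="trt", reference="ref", batch=b)


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to
    ``<outdir>/manifest.json``). Raises with the failing stage named;
    partial outputs are retained."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": dataclasses.asdict(cfg),
                      "stages": []}
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        if cfg.simulate:
            stage = "simulate"
            sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
            ann = simulate_annotation(sim_cfg)
            metas = default_design()
            tracks, truth = simulate_tracks(ann, sim_cfg, metas)
            write_annotation_gtf(ann, outdir / "annotation.gtf")
            write_metadata(metas, outdir / "metadata.tsv")
            _write_tsv(truth, outdir / "truth.tsv", stage, cfg, index=False)
            tdir = outdir / "tracks"
            tdir.mkdir(exist_ok=True)
            for lid, tr in tracks.items():
                write_endtrack(tr, tdir / lid)
            manifest["stages"].append(stage)
        else:
            stage = "load"
            if not (cfg.annotation and cfg.metadata and cfg.tracks_dir):
                raise ValidationError(
                    "annotation, metadata and tracks_dir are required unless simulate=true"
                )
            ann = read_annotation(cfg.annotation)
            metas = read_metadata(cfg.metadata)
            tracks = {
                m.library_id: read_endtrack_pair(Path(cfg.tracks_dir) / m.library_id)
                for m in metas
            }
            truth = None
            manifest["stages"].append(stage)

        # --------------------------------------------------------- normalize
        stage = "normalize"
        le = last_exon_matrix(tracks.values(), ann)
        le = filter_expressed(le, cfg.min_reads)
        sf = size_factors(le, cfg.pseudocount)
        _write_tsv(pd.Series(sf, name="size_factor").to_frame(),
                   outdir / "size_factors.tsv", stage, cfg)
        norm_tracks = {lid: normalize_track(t, sf) for lid, t in tracks.items()}
        manifest["stages"].append(stage)

        # ----------------------------------------------------------- cluster
        stage = "cluster"
        clusters = call_clusters(tracks.values(), cfg.min_pos_count, cfg.max_gap)
        counts = count_matrix(clusters, tracks.values())
        _write_tsv(counts, outdir / "cluster_counts.tsv", stage, cfg)
        bed = pd.DataFrame(
            [
                (c.interval.chrom, c.interval.start, c.interval.end, c.id,
                 c.pooled_count, c.interval.strand)
                for c in clusters
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        bed.to_csv(outdir / "clusters.bed", sep="\t", index=False, header=False)
        annot = annotate_clusters(clusters, ann, cfg.sa_window)
        _write_tsv(annot, outdir / "cluster_annotation.tsv", stage, cfg)
        manifest["stages"].append(stage)

        # ----------------------------------------------------------- diffexp
        stage = "diffexp"
        norm = normalize_counts(counts, sf)
        contrasts = _contrast_groups(metas)
        results = {}
        up_sets: dict[str, set] = {}
        for name, trts, refs, batch in contrasts:
            design = _design_for(name, trts, refs, batch)
            res = nb_wald(counts[trts + refs], sf, design)
            results[name] = res
            up_sets[name] = call_upregulated(res, cfg.lfc_min, cfg.padj_max)
            _write_tsv(res, outdir / f"de_{name}.tsv", stage, cfg)
        manifest["stages"].append(stage)

        # ----------------------------------------- sensitivity and classify
        stage = "sensitivity"
        sens_contrasts = [
            Contrast(name, trts, refs) for name, trts, refs, _ in contrasts
        ]
        sens = sensitivity_matrix(norm, sens_contrasts)
        _write_tsv(sens, outdir / "sensitivity.tsv", stage, cfg)
        manifest["stages"].append(stage)

        stage = "classify"

        def up_union(target: str, method: str) -> set:
            if method == "AID":
                keys = [k for k in up_sets if k.startswith(f"{target}_AID_6h")]
            else:
                keys = [k for k in up_sets if k.startswith(f"{target}_RNAi")]
            return union_pa_modes({k: up_sets[k] for k in keys})

        next_cls, paxt_cls = classify_targets(
            up_union("ZCCHC8", "RNAi"), up_union("ZCCHC8", "AID"),
            up_union("ZFC3H1", "RNAi"), up_union("ZFC3H1", "AID"),
            mode="RNAi+AID",
        )
        classes = pd.DataFrame(
            [(cid, cls.pathway, cls.definition)
             for cls in (next_cls, paxt_cls) for cid in sorted(cls.members)],
            columns=["cluster_id", "pathway", "definition"],
        )
        _write_tsv(classes, outdir / "target_classes.tsv", stage, cfg, index=False)
        comp_rows = {}
        for cls in (next_cls, paxt_cls):
            if cls.members:
                comp_rows[cls.pathway] = composition(cls, annot, "biotype")
        if comp_rows:
            _write_tsv(pd.DataFrame(comp_rows).fillna(0.0),
                       outdir / "composition_biotype.tsv", stage, cfg)
        manifest["stages"].append(stage)

        # -------------------------------------------------------- sa-overlap
        stage = "sa-overlap"
        sa_regular = sa_anchor_table(ann, snorna_hosting=False)
        if len(sa_regular):
            cluster_map = {c.id: c for c in clusters}
            sa_tab = sa_overlap_fraction(
                sa_regular, up_sets, cluster_map, cfg.sa_window
            )
            _write_tsv(sa_tab, outdir / "sa_overlap.tsv", stage, cfg)
        manifest["stages"].append(stage)

        # ---------------------------------------------- metagene / trimming
        stage = "metagene"
        sa_host = sa_anchor_table(ann, snorna_hosting=True)
        pooled_norm = _pooled_condition_tracks(norm_tracks, metas)
        trim_rows = []
        for cond, (trt_tr, ref_tr) in pooled_norm.items():
            prof = metagene(
                trt_tr, ref_tr, sa_host,
                cfg.metagene_upstream, cfg.metagene_downstream, cfg.pseudocount,
            )
            _write_tsv(prof.to_frame(), outdir / f"metagene_SAhost_{cond}.tsv",
                       stage, cfg, index=False)
            trim_rows.append(
                {"condition": cond,
                 "trimming_index": insilico_trimming_index(trt_tr, sa_host)}
            )
        if trim_rows:
            _write_tsv(pd.DataFrame(trim_rows), outdir / "trimming_index.tsv",
                       stage, cfg, index=False)
        manifest["stages"].append(stage)

        # --------------------------------------------------------------- pca
        stage = "pca"
        aid_libs = [m.library_id for m in metas if m.method == "AID"]
        if len(aid_libs) >= 3:
            coords, var_exp = pca_top_variance(counts[aid_libs], sf, cfg.n_top)
            coords["pct_var_PC1"] = 100 * var_exp[0]
            coords["pct_var_PC2"] = 100 * var_exp[1] if len(var_exp) > 1 else 0.0
            _write_tsv(coords, outdir / "pca.tsv", stage, cfg)
        manifest["stages"].append(stage)

    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["outputs"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.rglob("*")) if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _pooled_condition_tracks(
    norm_tracks: dict[str, EndTrack], metas: Sequence[LibraryMeta]
) -> dict[str, tuple[EndTrack, EndTrack]]:
    """Replicate-pooled normalized pA+/- tracks per 6 h AID condition paired
    with the matching 0 h reference pool (for metagene/trimming summaries)."""

    def pool(ms: list[LibraryMeta], name: str) -> EndTrack:
        out = EndTrack(name, normalized=True)
        for m in ms:
            for chrom, strand, pos, val in norm_tracks[m.library_id].items():
                out.add(chrom, strand, pos, val / len(ms))
        return out

    out = {}
    aid = [m for m in metas if m.method == "AID" and m.pA_mode == "pA+/-"]
    for target in sorted({m.target for m in aid}):
        trts = [m for m in aid if m.target == target and m.timepoint_h == 6]
        refs = [m for m in aid if m.target == target and m.timepoint_h == 0]
        if trts and refs:
            out[f"{target}_AID_6h"] = (
                pool(trts, f"{target}_6h"), pool(refs, f"{target}_0h")
            )
    return out
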