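"""Synthetic annotations, 3'-end tracks and ground truth.

The generator emulates a 4sU 3'-end sequencing experiment over rapid (AID)
and long-term (RNAi) depletions of the NEXT component ZCCHC8, the PAXT
component ZFC3H1 and the exosome core subunit EXOSC3, in paired pA+ and
pA+/- libraries. It plants, per cluster:

* a decay-pathway membership (NEXT, PAXT, both, none) driving log2
  fold changes under the matching depletions,
* a kinetic profile over the AID time course — plateau (effect fully
  reached at 2 h and held, the NEXT behaviour under rapid ZCCHC8 loss) or
  progressive (log2FC growing linearly in time, the PAXT/EXOSC3 behaviour),
* optional pA-status handover: a nonadenylated NEXT substrate whose pA+
  signal rises under ZCCHC8 depletion while the pA+/- signal persists,
* an RNAi-only extra effect at splice-acceptor clusters of regular introns,
  scaled by intron length class (the long-term-depletion indirect
  phenotype),
* an EXOSC3-specific trimming smear: a Gaussian scatter of 3' ends
  centered ~50 nt upstream of snoRNA-hosting splice acceptors replacing
  the sharp SA peak.

Counts are negative binomial with variance mu + alpha*mu^2. Everything is
deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genomic import (
    Annotation,
    EndTrack,
    Gene,
    GenomicInterval,
    Intron,
    LibraryMeta,
    ValidationError,
)

#: canonical contrast grid recorded in the truth table
TRUTH_CONTRASTS = [
    ("ZCCHC8", "AID", 2.0),
    ("ZCCHC8", "AID", 6.0),
    ("ZCCHC8", "RNAi", None),
    ("ZFC3H1", "AID", 2.0),
    ("ZFC3H1", "AID", 6.0),
    ("ZFC3H1", "RNAi", None),
    ("EXOSC3", "AID", 2.0),
    ("EXOSC3", "AID", 6.0),
    ("EXOSC3", "RNAi", None),
]

FEATURE_LABELS = ("PROMPT", "eRNA", "SA_regular", "SA_snoRNA_host", "PAS", "ptRNA")


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Length-class bounds (<700 / 700-4000 / >4000 nt) and the smear geometry
    (center 50 nt upstream of the SA, sd 30 nt) mirror the experimental
    read-outs this package analyses; effect sizes and depths are realistic
    defaults for a 4sU 3'-end-seq depletion series and are freely
    configurable.
    """

    seed: int = 0
    n_genes: int = 60
    n_ernas: int = 20
    n_lncrnas: int = 10
    prompt_fraction: float = 0.8
    ptRNA_fraction: float = 0.3
    intron_length_mix: tuple[float, float, float] = (0.34, 0.33, 0.33)
    snorna_host_fraction: float = 0.3
    effect_lfc: float = 2.0
    nb_alpha: float = 0.05
    base_mean: float = 200.0
    base_sigma: float = 0.8
    depth: dict[str, float] = field(default_factory=dict)  # library_id -> depth factor
    rnai_indirect_slope: tuple[float, float, float] = (0.0, 0.7, 1.5)
    smear_center: float = -50.0
    smear_sd: float = 30.0
    smear_fraction: float = 0.8
    handover_fraction: float = 0.3
    pathway_mix: tuple[float, float, float, float] = (0.4, 0.4, 0.1, 0.1)  # NEXT/PAXT/both/none
    batch_log2_offset: float = 0.3

    def __post_init__(self) -> None:
        if abs(sum(self.intron_length_mix) - 1.0) > 1e-9:
            raise ValidationError("intron_length_mix must sum to 1")
        if abs(sum(self.pathway_mix) - 1.0) > 1e-9:
            raise ValidationError("pathway_mix must sum to 1")
        if self.base_mean <= 0 or self.nb_alpha < 0:
            raise ValidationError("rates and depths must be positive")
        if any(v <= 0 for v in self.depth.values()):
            raise ValidationError("depth factors must be positive")


def default_design(pa_modes: Sequence[str] = ("pA+", "pA+/-"), replicates: int = 2,
                   rnai_targets: Sequence[str] = ("ctrl", "ZCCHC8", "ZFC3H1", "EXOSC3"),
                   aid_targets: Sequence[str] = ("ZCCHC8", "ZFC3H1", "EXOSC3"),
                   timepoints: Sequence[float] = (0.0, 2.0, 6.0)) -> list[LibraryMeta]:
    """The full AID time-course + RNAi design the analyses expect.

    AID contrasts are referenced to the 0 h library of the same tagged line;
    RNAi contrasts to the control-siRNA libraries. RNAi libraries carry a
    two-level batch label to exercise the batch covariate.
    """
    design: list[LibraryMeta] = []
    for target in aid_targets:
        for tp in timepoints:
            for mode in pa_modes:
                for rep in range(1, replicates + 1):
                    mtag = "pApm" if mode == "pA+/-" else "pAp"
                    lid = f"{target}_AID_{tp:g}h_{mtag}_r{rep}"
                    design.append(LibraryMeta(lid, target, "AID", tp, mode, rep))
    for target in rnai_targets:
        for mode in pa_modes:
            for rep in range(1, replicates + 1):
                mtag = "pApm" if mode == "pA+/-" else "pAp"
                lid = f"{target}_RNAi_{mtag}_r{rep}"
                design.append(
                    LibraryMeta(lid, target, "RNAi", None, mode, rep, batch=f"b{rep}")
                )
    return design


# ---------------------------------------------------------------------------
# Annotation simulation


def simulate_annotation(cfg: SimConfig) -> Annotation:
    """Lay out a synthetic chromosome: multi-intron protein-coding genes (a
    configurable fraction of introns hosting a snoRNA), antisense PROMPT
    regions upstream of TSSs, and intergenic eRNA and lncRNA loci.

    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes: list[Gene] = []
    cursor = 5000
    chrom = "chr1"
    sno_i = 0
    for gi in range(cfg.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_introns = int(rng.integers(3, 7))
        exon_lens = rng.integers(150, 301, size=n_introns + 1)
        intron_lens = [_draw_intron_length(rng, cfg.intron_length_mix) for _ in range(n_introns)]
        total = int(exon_lens.sum() + sum(intron_lens))
        start = cursor
        end = start + total
        exons = []
        pos = start
        for k in range(n_introns + 1):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k])
            if k < n_introns:
                pos += intron_lens[k]
        gene = Gene(
            gene_id=f"g{gi:04d}",
            biotype="protein_coding",
            interval=GenomicInterval(chrom, start, end, strand),
            exons=exons,
        )
        from .genomic import derive_introns

        gene.introns = derive_introns(gene)
        genes.append(gene)

        # plant snoRNAs inside sufficiently long introns
        for intr in gene.introns:
            if intr.length >= 450 and rng.random() < cfg.snorna_host_fraction:
                genes.append(_make_snorna(chrom, strand, intr, sno_i))
                sno_i += 1

        # antisense PROMPT upstream of the TSS
        if rng.random() < cfg.prompt_fraction:
            p_strand = "-" if strand == "+" else "+"
            if strand == "+":
                p_iv = GenomicInterval(chrom, start - 1600, start - 100, p_strand)
            else:
                p_iv = GenomicInterval(chrom, end + 100, end + 1600, p_strand)
            genes.append(
                Gene(f"pro_g{gi:04d}", "PROMPT", p_iv, exons=[p_iv])
            )
        cursor = end + int(rng.integers(3000, 6001))

    for ei in range(cfg.n_ernas):
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, cursor, cursor + 400, strand)
        genes.append(Gene(f"eRNA{ei:03d}", "eRNA", iv, exons=[iv]))
        cursor += 400 + int(rng.integers(1500, 3001))

    for li in range(cfg.n_lncrnas):
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, cursor, cursor + 1200, strand)
        genes.append(Gene(f"lnc{li:03d}", "lncRNA", iv, exons=[iv]))
        cursor += 1200 + int(rng.integers(1500, 3001))

    return Annotation(genes)


def _draw_intron_length(rng: np.random.Generator, mix: tuple[float, float, float]) -> int:
    cls = rng.choice(3, p=np.asarray(mix) / sum(mix))
    if cls == 0:
        return int(rng.integers(100, 700))
    if cls == 1:
        return int(rng.integers(700, 4001))
    return int(rng.integers(4001, 10001))


def _make_snorna(chrom: str, strand: str, intr: Intron, idx: int) -> Gene:
    """Place a 100-nt snoRNA so its 3' end sits ~250 nt upstream of the SA,
    leaving room for the trimming zone between snoRNA and splice acceptor."""
    iv = intr.interval
    gap = min(250, intr.length - 150)
    if strand == "+":
        sno_end = iv.end - gap
        sno = GenomicInterval(chrom, sno_end - 100, sno_end, strand)
    else:
        sno_start = iv.start + gap
        sno = GenomicInterval(chrom, sno_start, sno_start + 100, strand)
    return Gene(f"SNO{idx:03d}", "snoRNA", sno, exons=[sno])


# ---------------------------------------------------------------------------
# Track simulation


@dataclass
class _PlantedCluster:
    cluster_id: str
    interval: GenomicInterval
    summit: int
    feature: str
    pathway: str  # NEXT | PAXT | both | none
    kinetic: str  # plateau | progressive | none
    base_mean: float
    pa_frac: float
    pA_handover: bool = False
    trimming_target: bool = False
    rnai_extra: float = 0.0
    intron_length: Optional[int] = None
    sa_pos: Optional[int] = None
    smear_lo: Optional[int] = None  # orientation offset bounds for the smear


def intron_length_label(length: int) -> str:
    if length < 700:
        return "short"
    if length <= 4000:
        return "medium"
    return "long"


def simulate_tracks(
    ann: Annotation, cfg: SimConfig, design: Sequence[LibraryMeta]
) -> tuple[dict[str, EndTrack], pd.DataFrame]:
    """Generate one raw :class:`EndTrack` per library plus the truth table.

    Returns ``(tracks, truth)`` where ``truth`` is a DataFrame with one row
    per planted cluster carrying its interval, feature label, pathway,
    kinetic profile, handover/trimming flags, host-intron length and the
    true log2FC for every canonical (target, method, timepoint) contrast.
    """
    _check_design(design)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    planted = _plant_clusters(ann, cfg, rng)

    tracks: dict[str, EndTrack] = {}
    for meta in design:
        tracks[meta.library_id] = _simulate_library(meta, planted, cfg, rng)

    truth = _truth_frame(planted, cfg)
    return tracks, truth


def _check_design(design: Sequence[LibraryMeta]) -> None:
    aid_lines = {m.target for m in design if m.method == "AID" and m.timepoint_h != 0}
    aid_refs = {m.target for m in design if m.method == "AID" and m.timepoint_h == 0}
    missing = aid_lines - aid_refs
    if missing:
        raise ValidationError(f"design lacks 0 h reference for AID lines: {sorted(missing)}")
    if any(m.method == "RNAi" and m.target != "ctrl" for m in design) and not any(
        m.method == "RNAi" and m.target == "ctrl" for m in design
    ):
        raise ValidationError("design lacks ctrl reference for RNAi contrasts")


def _plant_clusters(
    ann: Annotation, cfg: SimConfig, rng: np.random.Generator
) -> list[_PlantedCluster]:
    planted: list[_PlantedCluster] = []
    cid = 0
    pathways = np.array(["NEXT", "PAXT", "both", "none"])

    def new_id() -> str:
        nonlocal cid
        cid += 1
        return f"t{cid:04d}"

    def base() -> float:
        return float(rng.lognormal(math.log(cfg.base_mean), cfg.base_sigma))

    for g in sorted(ann.genes, key=lambda g: (g.interval.start, g.gene_id)):
        if g.biotype in ("PROMPT", "eRNA"):
            pw = str(rng.choice(pathways, p=cfg.pathway_mix))
            iv, summit = _end_cluster(g)
            handover = pw == "NEXT" and rng.random() < cfg.handover_fraction
            pa_frac = 0.9 if pw == "PAXT" else (0.05 if handover else 0.15 if pw == "NEXT" else 0.5)
            planted.append(
                _PlantedCluster(
                    new_id(), iv, summit, g.biotype, pw,
                    _kinetic_for(pw), base(), pa_frac, pA_handover=handover,
                )
            )
        elif g.biotype == "lncRNA":
            pw = str(rng.choice(pathways, p=cfg.pathway_mix))
            iv, summit = _end_cluster(g)
            planted.append(
                _PlantedCluster(new_id(), iv, summit, "lncRNA", pw,
                                _kinetic_for(pw), base(), 0.7)
            )
        elif g.biotype == "protein_coding":
            # PAS cluster in the last exon: exosome-insensitive, carries the
            # bulk-mRNA signal the normalization is anchored on
            iv, summit = _end_cluster(g)
            planted.append(
                _PlantedCluster(new_id(), iv, summit, "PAS", "none", "none",
                                5.0 * base(), 0.95)
            )
            # occasional TSS-proximal prematurely terminated RNA, NEXT-sensitive
            if rng.random() < cfg.ptRNA_fraction:
                iv, summit = _pt_cluster(g)
                planted.append(
                    _PlantedCluster(new_id(), iv, summit, "ptRNA", "NEXT",
                                    "plateau", base(), 0.15)
                )
            for intr in g.introns:
                iv, summit = _sa_cluster(g, intr)
                if intr.snoRNA_hosting:
                    lo = _smear_lower_bound(g, intr)
                    planted.append(
                        _PlantedCluster(
                            new_id(), iv, summit, "SA_snoRNA_host", "NEXT",
                            "plateau", base(), 0.3, trimming_target=True,
                            intron_length=intr.length, sa_pos=intr.sa_pos,
                            smear_lo=lo,
                        )
                    )
                else:
                    label = intron_length_label(intr.length)
                    slope = dict(zip(("short", "medium", "long"), cfg.rnai_indirect_slope))[label]
                    planted.append(
                        _PlantedCluster(
                            new_id(), iv, summit, "SA_regular", "none", "none",
                            base(), 0.3, rnai_extra=slope,
                            intron_length=intr.length, sa_pos=intr.sa_pos,
                        )
                    )
    return planted


def _kinetic_for(pathway: str) -> str:
    if pathway == "NEXT":
        return "plateau"
    if pathway in ("PAXT", "both"):
        return "progressive"
    return "none"


def _end_cluster(g: Gene) -> tuple[GenomicInterval, int]:
    """10-nt cluster ending at the gene's annotated 3'-end position."""
    pa = g.pa_site
    if g.strand == "+":
        iv = GenomicInterval(g.interval.chrom, pa - 9, pa + 1, "+")
    else:
        iv = GenomicInterval(g.interval.chrom, pa, pa + 10, "-")
    return iv, pa


def _pt_cluster(g: Gene) -> tuple[GenomicInterval, int]:
    """Sense-strand cluster ~300 nt downstream of the TSS."""
    if g.strand == "+":
        summit = g.tss + 300
        iv = GenomicInterval(g.interval.chrom, summit - 9, summit + 1, "+")
    else:
        summit = g.tss - 300
        iv = GenomicInterval(g.interval.chrom, summit, summit + 10, "-")
    return iv, summit


def _sa_cluster(g: Gene, intr: Intron) -> tuple[GenomicInterval, int]:
    """10-nt cluster immediately upstream (orientation) of the SA; summit at
    offset -1, the last intronic nucleotide."""
    sa = intr.sa_pos
    if g.strand == "+":
        iv = GenomicInterval(g.interval.chrom, sa - 10, sa, "+")
        summit = sa - 1
    else:
        iv = GenomicInterval(g.interval.chrom, sa + 1, sa + 11, "-")
        summit = sa + 1
    return iv, summit


def _smear_lower_bound(g: Gene, intr: Intron) -> int:
    """Most-negative orientation offset the trimming smear may reach: the 3'
    end of the hosted snoRNA (trimming stalls on the snoRNP)."""
    sno = intr.hosted_snorna
    if sno is None:
        return -(intr.length - 1)
    if g.strand == "+":
        return -(intr.sa_pos - sno.end) - 1
    return -(sno.start - intr.sa_pos) - 1


def true_log2fc(pc: _PlantedCluster, target: str, method: str,
                timepoint_h: Optional[float], cfg: SimConfig) -> float:
    """The planted log2 fold change of cluster ``pc`` in a (target, method,
    timepoint) condition, relative to its matched reference."""
    if target in ("ctrl", None):
        return 0.0
    hit = (
        (pc.pathway == "NEXT" and target in ("ZCCHC8", "EXOSC3"))
        or (pc.pathway == "PAXT" and target in ("ZFC3H1", "EXOSC3"))
        or (pc.pathway == "both" and target in ("ZCCHC8", "ZFC3H1", "EXOSC3"))
    )
    lfc = 0.0
    if hit:
        e = cfg.effect_lfc
        if method == "RNAi":
            lfc = e
        else:
            t = timepoint_h or 0.0
            if t <= 0:
                lfc = 0.0
            elif pc.kinetic == "plateau" and target != "EXOSC3":
                lfc = e  # reached by 2 h and held
            else:
                lfc = e * min(t, 6.0) / 6.0  # progressive accumulation
    if method == "RNAi" and target == "ZCCHC8" and pc.feature == "SA_regular":
        lfc += pc.rnai_extra
    return lfc


def _pa_fraction(pc: _PlantedCluster, target: str, method: str,
                 timepoint_h: Optional[float]) -> float:
    """Adenylated fraction of the cluster's signal in a given condition.

    Handover clusters switch from nearly fully nonadenylated to mostly
    adenylated when NEXT (or the exosome core) is lost: escaping substrates
    are post-transcriptionally adenylated and become PAXT-visible."""
    if pc.pA_handover and target in ("ZCCHC8", "EXOSC3"):
        depleted = method == "RNAi" or (timepoint_h or 0) > 0
        if depleted:
            return 0.6
    return pc.pa_frac


def _simulate_library(
    meta: LibraryMeta,
    planted: list[_PlantedCluster],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> EndTrack:
    track = EndTrack(meta.library_id, normalized=False)
    depth = cfg.depth.get(meta.library_id, 1.0)
    batch_mult = 1.0
    if meta.batch is not None and cfg.batch_log2_offset:
        batch_mult = 2.0 ** (cfg.batch_log2_offset if meta.batch == "b2" else 0.0)

    exosc3_depleted = meta.target == "EXOSC3" and (
        meta.method == "RNAi" or (meta.timepoint_h or 0) > 0
    )

    for pc in planted:
        lfc = true_log2fc(pc, meta.target, meta.method, meta.timepoint_h, cfg)
        pa = _pa_fraction(pc, meta.target, meta.method, meta.timepoint_h)
        mode_frac = pa if meta.pA_mode == "pA+" else 1.0
        mean_base = pc.base_mean * depth * batch_mult * mode_frac
        mean_extra = mean_base * (2.0 ** lfc - 1.0)
        # baseline signal spreads over the cluster footprint; the effect
        # (stabilized decay intermediates) piles up sharply at the summit
        count_base = _nb_draw(rng, mean_base, cfg.nb_alpha)
        count_extra = _nb_draw(rng, mean_extra, cfg.nb_alpha)
        smear = pc.trimming_target and exosc3_depleted and cfg.smear_fraction > 0
        for count, decay in ((count_base, 0.5), (count_extra, 0.25)):
            if count == 0:
                continue
            smeared = int(rng.binomial(count, cfg.smear_fraction)) if smear else 0
            _scatter_peak(track, pc, count - smeared, rng, decay)
            if smeared:
                _scatter_smear(track, pc, smeared, cfg, rng)
    return track


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if mean <= 0:
        return 0
    if alpha <= 0:
        return int(rng.poisson(mean))
    n = 1.0 / alpha
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def _orientation_positions(pc: _PlantedCluster) -> list[int]:
    """Cluster positions ordered 3'-most first (i.e. nearest the summit)."""
    if pc.interval.strand == "+":
        return list(range(pc.interval.end - 1, pc.interval.start - 1, -1))
    return list(range(pc.interval.start, pc.interval.end))


def _scatter_peak(track: EndTrack, pc: _PlantedCluster, count: int,
                  rng: np.random.Generator, decay: float = 0.5) -> None:
    """Distribute a cluster's 3' ends with geometric decay away from the
    summit, multinomially."""
    if count <= 0:
        return
    positions = _orientation_positions(pc)
    w = np.array([decay ** i for i in range(len(positions))])
    w /= w.sum()
    draws = rng.multinomial(count, w)
    for pos, k in zip(positions, draws):
        if k:
            track.add(pc.interval.chrom, pc.interval.strand, pos, int(k))


def _scatter_smear(track: EndTrack, pc: _PlantedCluster, count: int,
                   cfg: SimConfig, rng: np.random.Generator) -> None:
    """The EXOSC3 trimming phenotype: heterogeneous 3' ends drawn from a
    Gaussian in orientation offsets upstream of the SA, truncated to the
    region between the hosted snoRNA 3' end and the SA."""
    sa = pc.sa_pos
    assert sa is not None
    lo = pc.smear_lo if pc.smear_lo is not None else -200
    offsets = np.arange(lo, -1)  # offsets lo .. -2
    pdf = np.exp(-0.5 * ((offsets - cfg.smear_center) / cfg.smear_sd) ** 2)
    pdf /= pdf.sum()
    draws = rng.multinomial(count, pdf)
    strand = pc.interval.strand
    for off, k in zip(offsets, draws):
        if not k:
            continue
        pos = sa + off if strand == "+" else sa - off
        track.add(pc.interval.chrom, strand, int(pos), int(k))


def _truth_frame(planted: list[_PlantedCluster], cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for pc in planted:
        row = {
            "cluster_id": pc.cluster_id,
            "chrom": pc.interval.chrom,
            "start": pc.interval.start,
            "end": pc.interval.end,
            "strand": pc.interval.strand,
            "summit": pc.summit,
            "feature": pc.feature,
            "pathway": pc.pathway,
            "kinetic": pc.kinetic,
            "pA_handover": pc.pA_handover,
            "trimming_target": pc.trimming_target,
            "intron_length": pc.intron_length,
            "length_class": (
                intron_length_label(pc.intron_length) if pc.intron_length else None
            ),
            "sa_pos": pc.sa_pos,
            "base_mean": pc.base_mean,
            "pa_frac": pc.pa_frac,
        }
        for target, method, tp in TRUTH_CONTRASTS:
            tag = f"{target}_{method}" + (f"_{tp:g}h" if tp is not None else "")
            row[f"lfc_{tag}"] = true_log2fc(pc, target, method, tp, cfg)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Matrix-level simulation (no tracks) for statistical validation


def simulate_count_matrix(
    n_clusters: int,
    n_per_group: int,
    lfc: np.ndarray | float,
    base_mean: float = 200.0,
    base_sigma: float = 1.0,
    alpha: float = 0.05,
    depth: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an NB cluster x library count matrix for a two-group design.

    Libraries are ordered reference group first, then treated. ``lfc`` may
    be scalar or per-cluster. Returns ``(counts, truth)`` with truth holding
    the per-cluster base mean and planted log2FC.
    """
    rng = np.random.default_rng(seed)
    lfc = np.broadcast_to(np.asarray(lfc, dtype=float), (n_clusters,)).copy()
    mu0 = rng.lognormal(math.log(base_mean), base_sigma, size=n_clusters)
    n_libs = 2 * n_per_group
    if depth is None:
        depth = np.ones(n_libs)
    depth = np.asarray(depth, dtype=float)
    cols = [f"ref_{i+1}" for i in range(n_per_group)] + [
        f"trt_{i+1}" for i in range(n_per_group)
    ]
    mu = np.outer(mu0, depth)
    mu[:, n_per_group:] *= (2.0 ** lfc)[:, None]
    if alpha > 0:
        n = 1.0 / alpha
        counts = rng.negative_binomial(n, n / (n + mu))
    else:
        counts = rng.poisson(mu)
    ids = [f"c{i:05d}" for i in range(n_clusters)]
    counts_df = pd.DataFrame(counts, index=ids, columns=cols)
    truth = pd.DataFrame({"base_mean": mu0, "lfc": lfc}, index=ids)
    return counts_df, truth
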