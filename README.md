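# threeprime

Analysis of strand-specific RNA 3′-end sequencing for nuclear RNA decay
studies: which transcript 3′ ends accumulate when the RNA exosome or one of
its nucleoplasmic adaptors — the NEXT complex (ZCCHC8) for nonadenylated
ends, the PAXT connection (ZFC3H1) for polyadenylated ends — is depleted,
and which of those responses are *direct* (visible within hours of rapid
auxin-degron depletion) rather than indirect consequences of long-term RNAi
knockdown.

The package is aimed at computational biologists working with 3′-end-seq
depletion series (paired pA⁺ / pA⁺/⁻ libraries, AID time courses, RNAi
endpoints). It provides, as a library and a CLI:

* **Normalization** anchored on protein-coding last exons (assumed
  exosome-insensitive): median-of-ratios size factors on pseudocounted
  last-exon counts, applied to tracks and cluster counts.
* **3′-end cluster calling** (seed-and-merge on pooled tracks), per-library
  quantification and single-label biotype/feature annotation.
* **Differential expression** by a per-cluster negative-binomial GLM
  (var = μ + αμ², trend-shrunken moment dispersions, Wald test, BH
  correction, optional batch covariate) with strict up-calls
  (log₂FC > 1, p_adj < 0.1), plus top-variance PCA.
* **The sensitivity statistic**

      sensitivity = (treated − ctrl) / max(ctrl, treated, 1)

  on replicate-averaged normalized counts — bounded in [−1, 1], equal to
  +1 / 0 / −1 for depletion-exclusive, equal, and reference-exclusive
  signal respectively.
* **Target classification**: intersection of RNAi and 6 h AID up-calls per
  factor, then mutual exclusion, yielding disjoint NEXT and PAXT targeting
  classes; composition summaries and intron-length-stratified
  splice-acceptor (SA) overlap tables.
* **Metagene profiles** at single-nucleotide resolution around oriented
  anchors (log₂ ratio of summed coverage, pseudocount 1, 150 nt
  upstream / 100 nt downstream by default) and a **trimming read-out**
  (distal/proximal signal ratio upstream of SAs) that detects nonprocessive
  3′–5′ trimming intermediates.
* **A synthetic-data generator** planting all of the above structure —
  NB counts, plateau vs progressive kinetics, pA⁻→pA⁺ handover,
  RNAi-specific intron-length-scaled effects, and an EXOSC3-specific
  trimming smear — with a ground-truth table, so the whole pipeline is
  testable without any downloads.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a full 52-library experiment (3 AID lines × 0/2/6 h × pA⁺ and
pA⁺/⁻ × 2 replicates, plus RNAi), then run the analysis:

```python
from threeprime import *
from threeprime.pipeline import _contrast_groups, _design_for

cfg = SimConfig(seed=1)
ann = simulate_annotation(cfg)
design = default_design()
tracks, truth = simulate_tracks(ann, cfg, design)

sf = size_factors(filter_expressed(last_exon_matrix(tracks.values(), ann)))
clusters = call_clusters(tracks.values())
counts = count_matrix(clusters, tracks.values())

up = {}
for name, trts, refs, batch in _contrast_groups(design):
    res = nb_wald(counts[trts + refs], sf, _design_for(name, trts, refs, batch))
    up[name] = call_upregulated(res)

nxt, paxt = classify_targets(
    union_pa_modes({k: v for k, v in up.items() if k.startswith("ZCCHC8_RNAi")}),
    union_pa_modes({k: v for k, v in up.items() if k.startswith("ZCCHC8_AID_6h")}),
    union_pa_modes({k: v for k, v in up.items() if k.startswith("ZFC3H1_RNAi")}),
    union_pa_modes({k: v for k, v in up.items() if k.startswith("ZFC3H1_AID_6h")}),
)
```

This prints (via the surrounding report code):

```
433 clusters quantified across 52 libraries
NEXT class: 125 clusters, PAXT class: 35 clusters
NEXT biotypes: {'protein_coding': 76.8, 'PROMPT': 15.2, 'eRNA': 5.6, 'lncRNA': 2.4}
sensitivity(37, 0) = 1.0
trimming index ZCCHC8 6 h: 0.000
trimming index EXOSC3 6 h: 3.041
```

Reading the numbers: the NEXT and PAXT classes are disjoint by
construction; the NEXT class is dominated by protein-coding-overlapping
clusters (snoRNA-hosting intron SAs and TSS-proximal ends) plus PROMPTs and
eRNAs, matching what was planted. A depletion-exclusive signal saturates the
sensitivity statistic at 1. The in-silico trimming index — distal (−150..−20)
over proximal (−10..0) signal at snoRNA-hosting SA anchors — is ≪ 1 under
ZCCHC8 depletion (one sharp SA peak, nothing upstream) but > 3 under EXOSC3
depletion, whose planted smear of nonprocessively trimmed 3′ ends sits
~50 nt upstream of the SA.

The same pipeline runs from the shell:

```bash
threeprime run-all --simulate --seed 1 --outdir out/ --evaluate-truth
threeprime metagene --treated out/tracks/EXOSC3_AID_6h_pApm_r1 \
    --reference out/tracks/EXOSC3_AID_0h_pApm_r1 \
    --annotation out/annotation.gtf --out profile.tsv
```

`run-all` writes size factors, cluster counts/annotation, per-contrast
differential tables, the sensitivity matrix, target classes, composition
and SA-overlap summaries, metagene profiles, trimming indices, PCA
coordinates and a manifest with parameter hashes and output checksums;
`--evaluate-truth` scores class recovery against the planted truth table.

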