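# polystate

Quantitative comparison of protein occupancy on chromatin between
RNAi-depleted and control conditions, from probe-level tiling-array ChIP
enrichment tracks.

The package is aimed at regulatory-genomics analyses of the kind used to
dissect cohesin–Polycomb interplay in *Drosophila*: paired control/depletion
ChIP-chip tracks for cohesin (Rad21, Nipped-B), PRC1 subunits (Pc, Ph, Psc),
H3K27me3, and RNA polymerase II (Rpb3, Ser2P), together with gene
annotations and mRNA levels.  It provides, as a tested reusable library:

- **Binding calls** — threshold segmentation of enrichment tracks into bound
  intervals, gene-level binding matrices, Venn overlap counts, and
  genome-wide track correlations.
- **Differential occupancy** — both an *integrated-delta* measurement
  (summed score per gene region, depleted − control) and a *delta-null
  interval caller*: subtract scores probe-wise, estimate the genome-wide
  median *m* and standard deviation *σ* of the Δ distribution, and call
  maximal runs of ≥ 3 consecutive features (≥ 105 bp) with Δ beyond
  *m* ± 2*σ* as increase/decrease intervals, then classify genes UP/DOWN per
  promoter (200 bp around the TSS) and gene body.
- **Pausing statistics** — the pause index PI = median promoter signal /
  median gene-body signal (400 bp promoter window), and the elongation
  ratio R = median Ser2P / median Rpb3 in gene bodies.
- **Chromatin states** — classification of genes into the three
  cohesin–PcG states (PcG-**silenced**, cohesin–H3K27me3 **restrained**,
  cohesin–PRC1 **active**) or **other**, from binding calls, domain
  overlaps, PRE annotations and expression.
- **3C normalization** — qPCR quantities normalized against a randomly
  religated BAC control (I = mean(replicates)/BAC), anchor-centric
  interaction profiles with replicate standard errors, and condition
  comparison with propagated errors.
- **Synthetic data** — a generator that emulates the 35-bp probe grid,
  near-normal per-probe noise, promoter-peaked vs broad-domain binding
  architectures, planted depletion effects and correlated mRNA, exporting
  ground truth for every stage.

## Worked example

Simulate a depletion experiment in which 30% of active cohesin-bound genes
lose Pc occupancy body-wide (a 3-delta-SD decrease), then fit the
differential-occupancy model:

```python
import numpy as np
from polystate import (SimConfig, EffectSpec, simulate_dataset,
                       DifferentialOccupancy, category_percentages)

effect = EffectSpec(factor="Pc", fraction=0.30, delta_sd=-3.0 * np.sqrt(2),
                    region="body", target="active")
ds = simulate_dataset(SimConfig(seed=7, n_genes=400,
                                factors=("cohesin", "Pc", "H3K27me3"),
                                effects=(effect,)))
res = DifferentialOccupancy(ds.track("Pc", "control"),
                            ds.track("Pc", "depleted"), ds.genes).fit()
print(res.summary())
```

```
Differential occupancy (depleted - control)
===============================================
shared probes            85367
dropped (control only)   0
dropped (depleted only)  0
null median              -0.1948 (SE 0.0068)
null mean                -0.4026
null SD                   1.5763 (SE 0.0038)
thresholds               median +/- 2.0 SD, >= 3 features, >= 105 bp
increase intervals       0
decrease intervals       676
promoter classes         UP=0  DOWN=0  AMBIGUOUS=0  NONE=400
body     classes         UP=0  DOWN=72  AMBIGUOUS=0  NONE=328
```

The null median/SD summarize the genome-wide Δ distribution that sets the
call thresholds; 676 decrease intervals were called and 72 of the 400 genes
are classified DOWN in their bodies.  Tabulating against the active cohort:

```python
active = ds.truth.genes["state"] == "active"
print(category_percentages(res.gene_classes, {"active": active})
      .to_string(float_format="%.1f"))
```

```
        n_genes  n_up  n_down  n_ambiguous  pct_up  pct_down  defined
group
active      240     0      72            0     0.0      30.0     True
```

The measured 30.0% DOWN recovers the planted 30% exactly in this draw.

A command-line interface mirrors the library
(`polystate simulate | call | diff | states | threec | run`); `run` drives
the full pipeline from a YAML config and writes BED/TSV tables plus a
manifest with parameters and input checksums.

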