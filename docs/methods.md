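# Methods

This note documents the models, conventions and design choices behind the
package, and what the synthetic-data tests do and do not establish about
real tiling-array data.

## Data model and coordinates

All coordinates are 0-based half-open (BED convention); GFF3 input is
converted on read.  A probe ("microarray feature") at start *s* measures the
tile [*s*, *s* + *w*) with *w* = 35 bp by default, so three contiguous
features span 105 bp.  Enrichment scores have MAT-score semantics: they are
linear in the log2 IP/control ratio, which is why additive shifts on the
score scale model fold-changes and why all differential statistics work by
subtraction.  Duplicate probe positions are rejected rather than averaged —
silent averaging would shrink the spread of the delta distribution that the
change caller is calibrated on.  A probe counts as *inside* a region when
its whole tile is contained in it; interval–interval intersection (binding
assignment, change classification) instead requires only ≥ 1 bp overlap,
ignoring strand, since ChIP signal is unstranded.

The TSS is derived from the transcription-unit span: `tx_start` on the plus
strand, `tx_end − 1` on the minus strand.  Two promoter windows are used,
both centered on the TSS: 200 bp for UP/DOWN region classification and
400 bp for the pause index.  The gene body is the rest of the transcription
unit in either case.

## Binding calls

Bound intervals are maximal runs of at least `min_run` = 3 consecutive
probes with score ≥ τ whose tile-union spans at least `min_span` = 105 bp.
τ is a score-space stand-in for a p-value cutoff from a model-based
enrichment caller; it is deliberately config-exposed, and when reproducing
published calls it should be calibrated so the genome-wide bound-gene count
matches the deposited interval files.  Both `min_run` and `min_span` are
enforced because "three features / 105 bp" admits either reading; with the
default tile they are equivalent on a gap-free grid.

Contiguity tolerates genomic gaps up to one missing probe (start-to-start
spacing ≤ 2*w*; `merge_gap` configurable): tiling arrays mask repetitive
probes, and breaking a run on every masked probe would shatter real
domains.  A probe that is *present* but fails the threshold always breaks
the run, which preserves the invariant that every probe inside an emitted
interval passes.  A gene is bound when any interval overlaps its
transcription unit by ≥ 1 bp, with no promoter extension.

## Differential occupancy

Two measurements are implemented, and they are complementary: the
integrated delta is sensitive to diffuse changes spread over a whole gene,
the interval caller localizes strong contiguous changes and controls false
calls via run length.

**Method 1 (integrated deltas).**  Scores of shared probes are summed over a
gene region per condition and subtracted (depleted − control).  Regions
containing no shared probes return a `no_data` flag, distinct from a true
zero.  The pause index divides the median promoter score by the median body
score (the median form is the primary definition; a summed-signal-per-bp
"density" variant is available behind a flag).  PI is invariant under
positive rescaling of the track, undefined when the body median is ≤ 0 —
medians of enrichment scores can be negative in empty regions, and a
ratio to a non-positive denominator carries no pausing information.  The
elongation ratio applies the same construction to two factors: median
Ser2P over median Rpb3 in the body, on probes shared by both tracks.

**Method 2 (delta-null interval calling).**  Scores are subtracted
probe-wise on the shared grid; probes present in only one track are dropped
and counted.  The genome-wide median *m*, mean and sample SD *σ* (ddof = 1;
no outlier trimming is applied, and none is claimed) of the Δ array define
an empirical null.  The estimator SEs reported with the fit are the
normal-approximation forms (1.2533 σ/√n for the median, σ/√(2(n−1)) for the
SD).  A diagnostic warning fires when |*m*| > 0.25 σ, flagging
normalization drift between conditions.  Change intervals are maximal runs
of ≥ 3 consecutive same-sign probes with Δ ≥ *m* + 2σ or Δ ≤ *m* − 2σ,
span ≥ 105 bp, with the same one-missing-probe gap tolerance as the binding
caller.  Because the null is estimated from all probes — including
genuinely affected ones — a dataset with many strong effects inflates σ
and shifts *m* toward the effect sign; this is inherent to the
empirical-null design and visible in the fit summary.

Genes are classified per region: UP if only increases overlap, DOWN if
only decreases, AMBIGUOUS if both, NONE otherwise.  AMBIGUOUS calls carry
an automatic resolution — the sign with the larger Σ|mean Δ| × span over
overlapping intervals — replacing manual browser inspection with a
reproducible, auditable rule; the AMBIGUOUS flag itself is retained, and a
tie leaves the call unresolved.  Percentage tables count AMBIGUOUS genes
by their resolution and report them separately; empty groups are flagged
rather than reported as 0%.

## Chromatin states

Decision list, applied in order so every gene gets exactly one state:

1. **RESTRAINED** — cohesin and H3K27me3 both bound and their domains
   intersect over ≥ 2,000 bp of the transcription unit.  "Several
   kilobases" has no published operational value; 2 kb is a conservative
   default and a single config knob.
2. **SILENCED** — H3K27me3 and Pc bound, expression below the cutoff
   (cohort median by default), and cohesin absent from the transcription
   unit outside annotated PREs.  Without a PRE annotation the cohesin
   condition degrades to the gene-level bound flag, and the output records
   the degradation.
3. **ACTIVE** — cohesin and Pc bound, H3K27me3 absent.
4. **OTHER** — everything else.

RESTRAINED does not require Pc binding (observed examples have it, but no
stated rule demands it); the Pc flag is kept in the evidence columns.  The
"active gene" predicate used for percentage denominators (no H3K27me3, and
Pol II bound or expression ≥ cutoff) is explicitly replaceable — any
boolean gene mask can be passed — because the published cohort-membership
rule is not fully specified.

## 3C quantification

Interaction frequency I = mean(reaction quantities) / BAC-control quantity.
The BAC control — the same primer pair run on a randomly religated template
containing every junction at equal molarity — measures amplification
efficiency, so I is invariant under joint rescaling of a pair's quantities
and control.  The SE is taken over all PCR reactions pooled (each divided
by the control); when biological-replicate labels are present, the SE over
biological means is reported alongside.  Condition ratios use first-order
error propagation, and a fragment is flagged "decreased" only when
ratio + SE < 1.  No distance-decay background model is fitted, and no
reference-pair rescaling is applied by default.

## Synthetic data

The generator is the ground-truth instrument for every recovery test.
Defaults are fixed study conditions, not tuning knobs:

- 35-bp probe grid over one synthetic chromosome; gene lengths uniform on
  2–8 kb (4–8 kb for restrained genes, which are defined by multi-kb
  domains), intergenic gaps 1–4 kb.
- Per-probe noise iid N(0, σ₀) with σ₀ = 0.8 score units per condition.
  The Δ of two pure-noise tracks then has SD σ₀√2 ≈ 1.13.  When a planted
  effect is meant as "k SDs on the delta scale" — the scale the caller
  thresholds on — it is passed as `delta_sd = k·√2`.
- State architectures: active genes get cohesin/Pc/Rpb3 promoter peaks
  (Gaussian, sd 150 bp, amplitudes 3.5–4) plus Rpb3/Ser2P body shelves
  (1.5); silenced genes get broad H3K27me3/Pc domains (3.0) and a narrow
  cohesin PRE peak (sd 80 bp) 300 bp downstream of the TSS, with the PRE
  exported as a ±400 bp interval; restrained genes get full-unit cohesin
  (3.5) and H3K27me3 (3.0) domains.  Amplitudes sit 2–4 noise SDs above
  threshold so binding calls are reliable but not trivial.
- Expression per state: log2 means 4 (active), 1 (restrained), −2
  (silenced), 0 (other), SD 1–1.5 — active genes separate cleanly from
  silenced ones around the cohort median.
- State fractions default to 60% active / 25% other / 10% silenced /
  5% restrained; exact-count mode makes category sizes deterministic for
  percentage-recovery tests.
- Effects are additive shifts over promoter/body/whole-unit regions of an
  exact fraction of a target category; effects sharing a key hit the same
  genes, which expresses promoter-to-body signal transfers.
- 3C tables: reaction quantity = I × efficiency × lognormal(CV), with the
  lognormal mean-corrected so CV = 0 recovers the truth exactly.

All randomness flows from a single seeded generator, so a seed reproduces
a dataset bit for bit.

**What passing these tests shows — and does not.**  The generator matches
the analysis' own statistical assumptions: independent, homoscedastic,
near-normal probe noise and additive effects.  Real tiling arrays violate
them in known ways — probe-sequence affinity effects, spatially correlated
noise, saturation at high enrichment, partial RNAi depletion producing
graded rather than uniform effects, and mixtures of cell states.  Recovery
on synthetic data therefore validates the *implementation* of the method
and its calibration under its stated model, not robustness to those
artifacts.  The null-calibration test in particular shows the run-length
rule's false-call behaviour under independence; correlated noise would
raise the false-call rate for any run-length rule.

## Problem sizes and numerical choices

Recovery analyses run at 1,000–2,000 genes (≈ 0.2–0.5 M probes), null
calibration at 10⁵ probes with a 50-replicate Monte-Carlo, and oracle
equivalence over 200 random tracks of up to 1,000 probes — sizes chosen so
the full suite completes in seconds while keeping binomial standard errors
well inside the asserted tolerances.  Interval callers are exact
algorithms (no heuristics), verified against an independent window-scan
oracle; floating-point equality is asserted only where computations are
identical by construction (file round-trips use `repr` serialization for
this reason).  Ties in the AMBIGUOUS resolution remain AMBIGUOUS; degenerate
inputs (empty tracks, regions without probes, zero-variance nulls,
zero BAC controls) are flagged or rejected explicitly rather than coerced.

## Known limitations

- τ-threshold binding calls are a stand-in for model-based p-value calls;
  absolute bound-gene counts depend on calibrating τ against reference
  calls.
- The empirical null conflates true effects with noise when effects are
  pervasive; only the median/SD diagnostics, not a correction, are
  provided.
- No FDR control beyond the fixed-SD run-length rule; no replicate-level
  variance modeling (inputs are replicate-averaged tracks); no HMM or
  smoothing segmentation.
- State classification at real loci depends on annotation quality (PREs,
  transcription units) in ways the synthetic tests do not probe.
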