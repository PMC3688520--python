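"""Synthetic tiling-array datasets with exported ground truth.

The generator emulates the statistical structure the analysis assumes: a
regular 35-bp probe grid, per-probe noise that is independent and normal on
the enrichment-score scale (SD 0.8 score units by default, inside the
0.6-1.0 range typical of replicate-averaged tiling-array deltas), and three
binding architectures layered on a flat baseline:

* ``promoter_peak`` — a Gaussian bump centered on the TSS (cohesin, PRC1 and
  paused polymerase at active genes);
* ``body_plateau`` — a constant shelf over the transcription unit
  (elongating polymerase);
* ``broad_domain`` — a constant domain over the unit plus flanks
  (H3K27me3 over silenced chromatin).

Genes are laid out sequentially on one synthetic chromosome and assigned a
chromatin state (silenced / restrained / active / other); the state decides
which factors bind and at what amplitude, the expression level, and for
silenced genes the position of a Polycomb Response Element where cohesin
peaks despite the silenced surroundings.  Depletion effects are additive
shifts of ``delta_sd`` noise-SD units over a designated gene region in the
depleted condition, applied to an exact (or sampled) fraction of a target
gene category.  Additive shifts on this scale model fold-changes, because
the enrichment score is linear in the log2 IP/control ratio.

Everything is drawn from a single seeded generator: the same seed always
reproduces the same dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SimulationError
from .genome import GenomeBuild, GeneModel, Interval, ProbeTrack
from .threec import QpcrMeasurement

CONDITIONS = ("control", "depleted")

#: architecture elements per state: factor -> list of (kind, amplitude, width)
#: widths: sd in bp for peaks, flank in bp for domains, ignored for plateaus
DEFAULT_ARCHITECTURES: dict[str, dict[str, tuple[tuple[str, float, int], ...]]] = {
    "active": {
        "cohesin": (("promoter_peak", 4.0, 150),),
        "Pc": (("promoter_peak", 3.5, 150),),
        "Rpb3": (("promoter_peak", 4.0, 150), ("body_plateau", 1.5, 0)),
        "Ser2P": (("body_plateau", 1.5, 0),),
    },
    "silenced": {
        "H3K27me3": (("broad_domain", 3.0, 1000),),
        "Pc": (("broad_domain", 3.0, 0),),
        "cohesin": (("pre_peak", 4.0, 80),),
    },
    "restrained": {
        "cohesin": (("broad_domain", 3.5, 0),),
        "H3K27me3": (("broad_domain", 3.0, 0),),
        "Pc": (("broad_domain", 3.0, 0),),
        "Rpb3": (("promoter_peak", 2.0, 150),),
    },
    "other": {},
}

#: log2 mRNA (mean, sd) per state: active genes high, silenced genes low
DEFAULT_EXPRESSION = {
    "active": (4.0, 1.0),
    "restrained": (1.0, 1.0),
    "silenced": (-2.0, 1.0),
    "other": (0.0, 1.5),
}


@dataclass(frozen=True)
class EffectSpec:
    """One depletion effect: an additive shift on the depleted track.

    ``delta_sd`` is signed and in units of the per-probe noise SD.
    ``fraction`` of the genes in ``target`` (a state name, ``"all"``, or
    ``"<factor>_bound"``) are affected over ``region`` (promoter / body /
    whole).  Effects sharing a ``key`` hit the same genes, which is how a
    promoter-to-body signal transfer is expressed (one negative promoter
    effect plus one positive body effect, same key).
    """

    factor: str
    fraction: float
    delta_sd: float
    region: str = "body"
    target: str = "all"
    key: str | None = None
    promoter_width: int = 400

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise SimulationError(f"effect fraction must be in [0,1], got {self.fraction}")
        if self.region not in ("promoter", "body", "whole"):
            raise SimulationError(f"unknown effect region {self.region!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic dataset.

    Defaults mirror the assay being emulated: 35-bp tiles, 0.8 score-unit
    probe noise, and a gene cohort dominated by active cohesin-PRC1 genes
    with small silenced and restrained minorities.
    """

    seed: int = 0
    n_genes: int = 500
    tile_width: int = 35
    noise_sd: float = 0.8
    chrom_name: str = "chrSim"
    chrom_length: int | None = None          # None: derived from the layout
    gene_length: tuple[int, int] = (2000, 8000)
    restrained_length: tuple[int, int] = (4000, 8000)
    intergenic: tuple[int, int] = (1000, 4000)
    state_fractions: dict[str, float] = field(default_factory=lambda: {
        "silenced": 0.10, "restrained": 0.05, "active": 0.60, "other": 0.25})
    exact_counts: bool = True
    factors: tuple[str, ...] = ("cohesin", "Pc", "H3K27me3", "Rpb3", "Ser2P")
    effects: tuple[EffectSpec, ...] = ()

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be > 0")
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        total = sum(self.state_fractions.values())
        if total > 1 + 1e-9:
            raise SimulationError(f"state fractions sum to {total} > 1")
        unknown = set(self.state_fractions) - set(DEFAULT_ARCHITECTURES)
        if unknown:
            raise SimulationError(f"unknown states in fractions: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery scoring.

    ``genes`` has one row per gene: true state, true per-factor bound flags
    (``bound_<factor>``), expression, and one column per planted effect
    (``change_<factor>_<region>`` with values UP/DOWN/NONE).
    """

    genes: pd.DataFrame
    pre_intervals: list[Interval]
    effect_intervals: list[Interval]
    noise_sd: float


@dataclass
class SimulatedDataset:
    """Tracks, annotation, expression and ground truth of one simulation."""

    config: SimConfig
    build: GenomeBuild
    genes: list[GeneModel]
    tracks: dict[tuple[str, str], ProbeTrack]   # (factor, condition) -> track
    expression: pd.Series
    truth: GroundTruth

    def track(self, factor: str, condition: str = "control") -> ProbeTrack:
        return self.tracks[(factor, condition)]


def _assign_states(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    names = list(config.state_fractions)
    fracs = np.array([config.state_fractions[s] for s in names])
    n = config.n_genes
    if config.exact_counts:
        counts = np.floor(fracs * n).astype(int)
        remainder = n - counts.sum() - round((1 - fracs.sum()) * n)
        # distribute leftovers (rounding residue) by largest fractional part
        residue = fracs * n - np.floor(fracs * n)
        for idx in np.argsort(-residue):
            if remainder <= 0:
                break
            counts[idx] += 1
            remainder -= 1
        labels = np.concatenate([np.repeat(s, c) for s, c in zip(names, counts)]
                                + [np.repeat("other", n - counts.sum())])
    else:
        pool = names + ["other"]
        probs = np.append(fracs, max(0.0, 1 - fracs.sum()))
        labels = rng.choice(pool, size=n, p=probs / probs.sum())
    return rng.permutation(labels)


def _layout_genes(config: SimConfig, states: np.ndarray,
                  rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    pos = int(rng.integers(*config.intergenic))
    for k, state in enumerate(states):
        lo, hi = (config.restrained_length if state == "restrained"
                  else config.gene_length)
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{k:05d}", config.chrom_name, strand,
                               pos, pos + length))
        pos += length + int(rng.integers(*config.intergenic))
    if config.chrom_length is not None and pos > config.chrom_length:
        raise SimulationError(
            f"{config.n_genes} genes need {pos} bp but chrom_length is "
            f"{config.chrom_length}")
    return genes


def _effect_region(gene: GeneModel, region: str, promoter_width: int) -> list[Interval]:
    if region == "whole":
        return [Interval(gene.chrom, gene.tx_start, gene.tx_end)]
    if region == "promoter":
        return [gene.promoter_window(promoter_width)]
    return gene.body_intervals(promoter_width)


def _target_mask(target: str, states: np.ndarray, truth_bound: dict[str, np.ndarray]) -> np.ndarray:
    if target == "all":
        return np.ones(states.size, dtype=bool)
    if target in DEFAULT_ARCHITECTURES:
        return states == target
    if target.endswith("_bound"):
        factor = target[:-len("_bound")]
        if factor in truth_bound:
            return truth_bound[factor].astype(bool)
    raise SimulationError(f"unknown effect target {target!r}")


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate paired-condition tracks with known binding and effects."""
    rng = np.random.default_rng(config.seed)
    states = _assign_states(config, rng)
    genes = _layout_genes(config, states, rng)
    chrom_len = config.chrom_length or (genes[-1].tx_end
                                        + int(rng.integers(*config.intergenic)))
    build = GenomeBuild({config.chrom_name: chrom_len})
    starts = np.arange(0, chrom_len - config.tile_width + 1, config.tile_width,
                       dtype=np.int64)
    centers = starts + config.tile_width / 2.0

    # --- clean (noise-free) signal per factor, shared by both conditions
    clean: dict[str, np.ndarray] = {f: np.zeros(starts.size) for f in config.factors}
    truth_bound = {f: np.zeros(config.n_genes, dtype=np.int8) for f in config.factors}
    pre_intervals: list[Interval] = []
    for k, (gene, state) in enumerate(zip(genes, states)):
        architecture = DEFAULT_ARCHITECTURES[state]
        for factor, elements in architecture.items():
            if factor not in clean:
                continue
            for kind, amplitude, width in elements:
                if kind in ("promoter_peak", "pre_peak"):
                    if kind == "promoter_peak":
                        center = gene.tss
                    else:
                        # cohesin confined to a PRE inside the silenced unit
                        center = gene.tss + (300 if gene.strand == "+" else -300)
                        pre_intervals.append(Interval(gene.chrom,
                                                      int(center) - 400,
                                                      int(center) + 400))
                    lo = np.searchsorted(centers, center - 6 * width)
                    hi = np.searchsorted(centers, center + 6 * width)
                    clean[factor][lo:hi] += amplitude * np.exp(
                        -0.5 * ((centers[lo:hi] - center) / width) ** 2)
                elif kind == "body_plateau":
                    lo = np.searchsorted(centers, gene.tx_start)
                    hi = np.searchsorted(centers, gene.tx_end)
                    clean[factor][lo:hi] += amplitude
                elif kind == "broad_domain":
                    lo = np.searchsorted(centers, gene.tx_start - width)
                    hi = np.searchsorted(centers, gene.tx_end + width)
                    clean[factor][lo:hi] += amplitude
                else:
                    raise SimulationError(f"unknown architecture kind {kind!r}")
                truth_bound[factor][k] = 1

    # --- depletion effects on the depleted condition
    effect_shift: dict[str, np.ndarray] = {f: np.zeros(starts.size)
                                           for f in config.factors}
    change_cols: dict[str, np.ndarray] = {}
    effect_intervals: list[Interval] = []
    selected_by_key: dict[str, np.ndarray] = {}
    for effect in config.effects:
        if effect.factor not in clean:
            raise SimulationError(f"effect factor {effect.factor!r} not simulated")
        mask = _target_mask(effect.target, states, truth_bound)
        key = effect.key or f"{effect.factor}:{effect.region}:{effect.target}"
        if key in selected_by_key:
            chosen = selected_by_key[key]
        else:
            candidates = np.flatnonzero(mask)
            n_affected = int(round(effect.fraction * candidates.size))
            chosen = rng.choice(candidates, size=n_affected, replace=False)
            selected_by_key[key] = chosen
        col = f"change_{effect.factor}_{effect.region}"
        labels = change_cols.setdefault(
            col, np.array(["NONE"] * config.n_genes, dtype=object))
        shift = effect.delta_sd * config.noise_sd
        sign = 1 if effect.delta_sd > 0 else -1
        for k in chosen:
            labels[k] = "UP" if sign > 0 else "DOWN"
            for piece in _effect_region(genes[k], effect.region,
                                        effect.promoter_width):
                lo = np.searchsorted(centers, piece.start)
                hi = np.searchsorted(centers, piece.end)
                effect_shift[effect.factor][lo:hi] += shift
                effect_intervals.append(replace(piece, sign=sign))

    # --- noise and track assembly
    tracks: dict[tuple[str, str], ProbeTrack] = {}
    for factor in config.factors:
        for condition in CONDITIONS:
            signal = clean[factor].copy()
            if condition == "depleted":
                signal += effect_shift[factor]
            signal += rng.normal(0.0, config.noise_sd, size=starts.size)
            tracks[(factor, condition)] = ProbeTrack(
                {config.chrom_name: (starts, signal)}, tile_width=config.tile_width)

    expr_values = np.empty(config.n_genes)
    for k, state in enumerate(states):
        mean, sd = DEFAULT_EXPRESSION[state]
        expr_values[k] = rng.normal(mean, sd)
    gene_ids = pd.Index([g.gene_id for g in genes], name="gene_id")
    expression = pd.Series(expr_values, index=gene_ids, name="log2_mrna")

    truth_frame = pd.DataFrame({"state": states.astype(object)}, index=gene_ids)
    for factor in config.factors:
        truth_frame[f"bound_{factor}"] = truth_bound[factor]
    for col, labels in change_cols.items():
        truth_frame[col] = labels
    truth_frame["expression"] = expr_values

    truth = GroundTruth(truth_frame, pre_intervals, effect_intervals,
                        noise_sd=config.noise_sd)
    return SimulatedDataset(config, build, genes, tracks, expression, truth)


def simulate_null_delta(n_probes: int, noise_sd: float = 0.8, seed: int = 0,
                        tile_width: int = 35) -> ProbeTrack:
    """Pure-null delta track: the probe-wise difference of two tracks that
    differ only by iid normal noise (delta SD = noise_sd * sqrt(2))."""
    rng = np.random.default_rng(seed)
    starts = np.arange(n_probes, dtype=np.int64) * tile_width
    delta = (rng.normal(0.0, noise_sd, n_probes)
             - rng.normal(0.0, noise_sd, n_probes))
    return ProbeTrack({"chrSim": (starts, delta)}, tile_width=tile_width)


def simulate_3c(loop_strengths: dict[tuple[str, str], float],
                cv: float = 0.1, n_biological: int = 2, n_reactions: int = 2,
                seed: int = 0,
                bac_range: tuple[float, float] = (0.5, 2.0),
                ) -> tuple[list[QpcrMeasurement], dict[tuple[str, str], float]]:
    """Simulate a 3C qPCR table with known interaction frequencies.

    Each (anchor, fragment) pair gets a random primer efficiency (the BAC
    control quantity) and ``n_biological * n_reactions`` reaction quantities
    ``true_I * bac * lognormal(cv)``; with ``cv = 0`` the quantities are
    exact and normalization recovers the truth identically.
    """
    if any(v < 0 for v in loop_strengths.values()):
        raise SimulationError("loop strengths must be >= 0")
    if cv < 0:
        raise SimulationError("replicate noise CV must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv ** 2))  # lognormal with unit mean, given CV
    measurements = []
    for (anchor, fragment), true_i in sorted(loop_strengths.items()):
        bac = float(rng.uniform(*bac_range))
        quantities, bio_ids = [], []
        for b in range(n_biological):
            for _ in range(n_reactions):
                noise = (np.exp(rng.normal(-0.5 * sigma ** 2, sigma))
                         if cv > 0 else 1.0)
                quantities.append(true_i * bac * noise)
                bio_ids.append(f"bio{b + 1}")
        measurements.append(QpcrMeasurement(anchor, fragment, tuple(quantities),
                                            bac, tuple(bio_ids)))
    return measurements, dict(loop_strengths)


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, str]:
    """Write a simulated dataset in the formats the pipeline reads.

    Returns a mapping of logical names to file paths (tracks, genes,
    expression, ground truth, PREs).
    """
    import os

    from . import io

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for (factor, condition), track in sorted(dataset.tracks.items()):
        path = os.path.join(outdir, f"{factor}_{condition}.bedGraph")
        io.write_track(track, path)
        paths[f"track:{factor}:{condition}"] = path
    genes_path = os.path.join(outdir, "genes.tsv")
    io.write_genes_tsv(dataset.genes, genes_path)
    paths["genes"] = genes_path
    expr_path = os.path.join(outdir, "expression.tsv")
    io.write_expression(dataset.expression, expr_path)
    paths["expression"] = expr_path
    truth_path = os.path.join(outdir, "ground_truth.tsv")
    dataset.truth.genes.to_csv(truth_path, sep="\t", float_format="%.6g")
    paths["ground_truth"] = truth_path
    if dataset.truth.pre_intervals:
        pre_path = os.path.join(outdir, "pres.bed")
        io.write_bed(dataset.truth.pre_intervals, pre_path)
        paths["pres"] = pre_path
    return paths
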