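"""Binding-interval calling, gene assignment, overlap counts and correlations.

The upstream study called bound regions from MAT p-values; here a bound
region is a run of probes whose enrichment score clears a threshold ``tau``
(score space stands in for the p-value cutoff; when reproducing published
calls, ``tau`` is calibrated so the genome-wide bound-gene count matches the
deposited calls).  A gene is "bound" when any called interval overlaps its
transcription unit by at least 1 bp — no promoter extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._segment import threshold_runs
from .errors import UndefinedCorrelationError, ValidationError
from .genome import GeneModel, Interval, ProbeTrack, align_tracks, validate_binding_matrix


@dataclass(frozen=True)
class BindingCallParams:
    """Parameters of the score-threshold binding caller.

    ``min_run`` probes (default 3) must each score at least ``tau`` and the
    tile-union of the run must span at least ``min_span`` bp (default 105,
    i.e. three contiguous 35-bp features).  Runs separated by at most
    ``merge_gap`` bp beyond the tiling (default: one tile width) are merged,
    which bridges single missing probes but never a probe that fails ``tau``.
    """

    tau: float
    min_run: int = 3
    min_span: int = 105
    merge_gap: int | None = None  # None -> tile width of the track

    def __post_init__(self):
        if not np.isfinite(self.tau):
            raise ValidationError("tau must be finite")
        if self.min_run < 1:
            raise ValidationError("min_run must be >= 1")


def call_bound_intervals(track: ProbeTrack, params: BindingCallParams) -> list[Interval]:
    """Call bound intervals: maximal runs of >=min_run probes with score >= tau."""
    if params.min_span < track.tile_width:
        raise ValidationError("min_span must be >= tile_width")
    merge_gap = track.tile_width if params.merge_gap is None else params.merge_gap
    max_gap = track.tile_width + merge_gap
    intervals: list[Interval] = []
    for chrom, starts, scores in track.iter_chromosomes():
        passing = scores >= params.tau
        for i, j in threshold_runs(starts, passing, tile_width=track.tile_width,
                                   max_gap=max_gap, min_run=params.min_run,
                                   min_span=params.min_span):
            intervals.append(Interval(chrom, int(starts[i]),
                                      int(starts[j - 1]) + track.tile_width,
                                      sign=0, score=float(scores[i:j].mean())))
    return intervals


def _interval_forest(intervals: list[Interval]) -> dict[str, IntervalTree]:
    forest: dict[str, IntervalTree] = {}
    for iv in intervals:
        forest.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return forest


def assign_gene_binding(intervals: list[Interval], genes: list[GeneModel],
                        factor: str = "bound") -> pd.Series:
    """0/1 per gene: 1 iff any interval overlaps the transcription unit >= 1 bp."""
    forest = _interval_forest(intervals)
    flags = np.zeros(len(genes), dtype=np.int8)
    for k, gene in enumerate(genes):
        tree = forest.get(gene.chrom)
        if tree is not None and tree.overlap(gene.tx_start, gene.tx_end):
            flags[k] = 1
    return pd.Series(flags, index=pd.Index([g.gene_id for g in genes], name="gene_id"),
                     name=factor)


def binding_matrix(calls: dict[str, list[Interval]], genes: list[GeneModel]) -> pd.DataFrame:
    """Gene x factor binary matrix from per-factor interval calls."""
    columns = {factor: assign_gene_binding(ivs, genes, factor)
               for factor, ivs in calls.items()}
    return validate_binding_matrix(pd.DataFrame(columns))


@dataclass(frozen=True)
class VennCounts:
    """Exact gene counts for every presence/absence combination of factors."""

    factors: tuple[str, ...]
    counts: dict[tuple[bool, ...], int]
    n_genes: int

    def count(self, *present: str) -> int:
        """Count of genes bound by exactly the named factors (and no others)."""
        pattern = tuple(f in present for f in self.factors)
        return self.counts.get(pattern, 0)

    def bound_by(self, *factors: str) -> int:
        """Count of genes bound by at least the named factors (marginal)."""
        sel = [self.factors.index(f) for f in factors]
        return sum(c for pattern, c in self.counts.items() if all(pattern[i] for i in sel))

    @property
    def n_unbound(self) -> int:
        return self.n_genes - sum(
            c for pattern, c in self.counts.items() if any(pattern))


def overlap_counts(matrix: pd.DataFrame, factors: list[str]) -> VennCounts:
    """Venn-region gene counts over the listed binding-matrix columns."""
    missing = [f for f in factors if f not in matrix.columns]
    if missing:
        raise KeyError(f"factors not in binding matrix: {missing}")
    sub = matrix[factors].astype(bool)
    counts: dict[tuple[bool, ...], int] = {}
    for pattern in product((False, True), repeat=len(factors)):
        mask = np.ones(len(sub), dtype=bool)
        for f, p in zip(factors, pattern):
            mask &= sub[f].to_numpy() == p
        n = int(mask.sum())
        if n:
            counts[pattern] = n
    return VennCounts(tuple(factors), counts, n_genes=len(matrix))


@dataclass(frozen=True)
class CorrelationResult:
    """Genome-wide Pearson correlation over shared probes."""

    r: float
    n_probes: int


def genomewide_correlation(a: ProbeTrack, b: ProbeTrack) -> CorrelationResult:
    """Pearson r over all probe positions the two tracks share."""
    aligned = align_tracks(a, b)
    if aligned.a.size < 2:
        raise UndefinedCorrelationError(
            f"need >=2 shared probes, got {aligned.a.size}")
    if np.ptp(aligned.a) == 0 or np.ptp(aligned.b) == 0:
        raise UndefinedCorrelationError("zero variance in one of the tracks")
    r = stats.pearsonr(aligned.a, aligned.b).statistic
    return CorrelationResult(r=float(r), n_probes=int(aligned.a.size))
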