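"""Core genomic containers for tiling-array occupancy analysis.

All coordinates throughout the package are 0-based, half-open ``[start, end)``
(BED convention).  A tiling-array probe ("microarray feature") at position
``s`` covers the tile ``[s, s + tile_width)``; with the default 35 bp tile,
three contiguous features span 105 bp.

Enrichment scores have MAT-score semantics: they measure ChIP enrichment
relative to an input control and scale linearly with the log2 IP/control
ratio, so additive shifts on the score scale model fold-changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import (
    DuplicateProbeError,
    EmptyIntersectionWarning,
    ValidationError,
)

DEFAULT_TILE_WIDTH = 35


def validate_region(start: int, end: int) -> None:
    """Enforce the half-open coordinate invariant ``start < end``."""
    if start >= end:
        raise ValidationError(f"invalid half-open region [{start}, {end}): start must be < end")


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome names and lengths of the genome the tracks live on."""

    lengths: dict[str, int]

    def __post_init__(self):
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)


@dataclass(frozen=True)
class Interval:
    """A signed genomic interval.

    ``sign`` distinguishes occupancy increases (+1) from decreases (-1);
    plain binding regions carry sign 0.  ``score`` is an optional summary
    (mean enrichment or mean delta) of the probes the interval was built from.
    """

    chrom: str
    start: int
    end: int
    sign: int = 0
    score: float | None = None

    def __post_init__(self):
        validate_region(self.start, self.end)
        if self.sign not in (-1, 0, 1):
            raise ValidationError(f"interval sign must be -1, 0 or +1, got {self.sign}")

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if this interval overlaps ``[start, end)`` on ``chrom`` by >= 1 bp."""
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class GeneModel:
    """An annotated transcription unit.

    The TSS is derived from the span and strand: it equals ``tx_start`` on the
    plus strand and ``tx_end - 1`` on the minus strand (the last base inside
    the half-open span).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self):
        validate_region(self.tx_start, self.tx_end)
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start

    def promoter_window(self, width: int) -> Interval:
        """The ``width``-bp window centered on the TSS (strand-agnostic)."""
        if width <= 0:
            raise ValidationError(f"promoter width must be positive, got {width}")
        half = width // 2
        return Interval(self.chrom, self.tss - half, self.tss - half + width)

    def body_intervals(self, promoter_width: int) -> list[Interval]:
        """The transcription unit minus the promoter window (0-2 pieces)."""
        prom = self.promoter_window(promoter_width)
        pieces = []
        if self.tx_start < prom.start:
            pieces.append(Interval(self.chrom, self.tx_start, min(prom.start, self.tx_end)))
        if prom.end < self.tx_end:
            pieces.append(Interval(self.chrom, max(prom.end, self.tx_start), self.tx_end))
        return pieces


class AlignedScores(NamedTuple):
    """Paired score vectors at the probe positions two tracks share."""

    chroms: np.ndarray   # chromosome of each shared probe
    starts: np.ndarray   # start of each shared probe
    a: np.ndarray        # scores of the first track at shared probes
    b: np.ndarray        # scores of the second track at shared probes
    n_dropped_a: int     # probes present only in the first track
    n_dropped_b: int     # probes present only in the second track


class ProbeTrack:
    """Per-chromosome sorted probe positions with enrichment scores.

    Parameters
    ----------
    data
        Mapping chromosome -> ``(starts, scores)``.  Starts are sorted on
        construction; duplicate positions are an error (silently averaging
        duplicates would distort the delta null downstream).
    tile_width
        Width in bp of the tile each probe measures.
    meta
        Free-form provenance (e.g. counts of probes dropped while pairing).
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray]],
                 tile_width: int = DEFAULT_TILE_WIDTH,
                 meta: dict | None = None):
        if tile_width <= 0:
            raise ValidationError(f"tile_width must be positive, got {tile_width}")
        self.tile_width = int(tile_width)
        self.meta = dict(meta or {})
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, scores) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            scores = np.asarray(scores, dtype=np.float64)
            if starts.shape != scores.shape:
                raise ValidationError(
                    f"{chrom}: {starts.size} starts but {scores.size} scores")
            order = np.argsort(starts, kind="stable")
            starts, scores = starts[order], scores[order]
            if starts.size > 1 and np.any(np.diff(starts) == 0):
                dup = int(starts[np.nonzero(np.diff(starts) == 0)[0][0]])
                raise DuplicateProbeError(f"duplicate probe position {chrom}:{dup}")
            self._data[chrom] = (starts, scores)

    @classmethod
    def from_records(cls, chroms, starts, scores,
                     tile_width: int = DEFAULT_TILE_WIDTH) -> "ProbeTrack":
        """Build a track from parallel record arrays (any order)."""
        chroms = np.asarray(chroms)
        starts = np.asarray(starts, dtype=np.int64)
        scores = np.asarray(scores, dtype=np.float64)
        data = {}
        for chrom in pd.unique(chroms):
            sel = chroms == chrom
            data[str(chrom)] = (starts[sel], scores[sel])
        return cls(data, tile_width=tile_width)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    @property
    def n_probes(self) -> int:
        return sum(starts.size for starts, _ in self._data.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._data

    def starts(self, chrom: str) -> np.ndarray:
        return self._data[chrom][0]

    def scores(self, chrom: str) -> np.ndarray:
        return self._data[chrom][1]

    def iter_chromosomes(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for chrom in self.chromosomes:
            starts, scores = self._data[chrom]
            yield chrom, starts, scores

    def all_scores(self) -> np.ndarray:
        """All scores genome-wide, in chromosome-then-coordinate order."""
        if not self._data:
            return np.empty(0)
        return np.concatenate([self.scores(c) for c in self.chromosomes])

    def probes_in(self, region: Interval) -> tuple[np.ndarray, np.ndarray]:
        """Probes whose tile is fully contained in ``region``.

        A feature at start ``s`` is "contained within" the region when
        ``[s, s + tile_width) `` lies inside ``[region.start, region.end)``.
        """
        if region.chrom not in self._data:
            return np.empty(0, dtype=np.int64), np.empty(0)
        starts, scores = self._data[region.chrom]
        lo = np.searchsorted(starts, region.start, side="left")
        hi = np.searchsorted(starts, region.end - self.tile_width, side="right")
        return starts[lo:hi], scores[lo:hi]

    def scores_in_regions(self, regions: list[Interval]) -> np.ndarray:
        """Scores of probes contained in any of ``regions`` (assumed disjoint)."""
        parts = [self.probes_in(r)[1] for r in regions]
        return np.concatenate(parts) if parts else np.empty(0)


def align_tracks(a: ProbeTrack, b: ProbeTrack) -> AlignedScores:
    """Pair two tracks at the intersection of their probe positions.

    Returns score vectors over the shared (chromosome, start) positions in
    genome order (chromosomes sorted by name, positions ascending), together
    with counts of probes dropped from each side.  An empty intersection is
    legal but emits :class:`EmptyIntersectionWarning`.
    """
    chroms_out, starts_out, a_out, b_out = [], [], [], []
    shared_chroms = sorted(set(a.chromosomes) & set(b.chromosomes))
    for chrom in shared_chroms:
        sa, va = a.starts(chrom), a.scores(chrom)
        sb, vb = b.starts(chrom), b.scores(chrom)
        common, ia, ib = np.intersect1d(sa, sb, assume_unique=True, return_indices=True)
        if common.size:
            chroms_out.append(np.full(common.size, chrom, dtype=object))
            starts_out.append(common)
            a_out.append(va[ia])
            b_out.append(vb[ib])
    if starts_out:
        chroms_cat = np.concatenate(chroms_out)
        starts_cat = np.concatenate(starts_out)
        a_cat = np.concatenate(a_out)
        b_cat = np.concatenate(b_out)
    else:
        chroms_cat = np.empty(0, dtype=object)
        starts_cat = np.empty(0, dtype=np.int64)
        a_cat = np.empty(0)
        b_cat = np.empty(0)
        warnings.warn("tracks share no probe positions", EmptyIntersectionWarning,
                      stacklevel=2)
    n_shared = starts_cat.size
    return AlignedScores(chroms_cat, starts_cat, a_cat, b_cat,
                         n_dropped_a=a.n_probes - n_shared,
                         n_dropped_b=b.n_probes - n_shared)


def validate_expression(expression: pd.Series) -> pd.Series:
    """Validate a gene -> log2 mRNA level table (unique gene ids)."""
    if not expression.index.is_unique:
        dups = expression.index[expression.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in expression table: {dups[:5]}")
    return expression.astype(float)


def validate_binding_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene x factor binary binding matrix (values 0/1)."""
    if not matrix.index.is_unique:
        raise ValidationError("duplicate gene ids in binding matrix")
    values = matrix.to_numpy()
    if values.size and not np.isin(values, (0, 1)).all():
        raise ValidationError("binding matrix values must be 0 or 1")
    return matrix.astype(np.int8)
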