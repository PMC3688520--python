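"""Differential occupancy between paired control and depleted ChIP tracks.

Two complementary measurements are implemented.

*Integrated deltas* (method 1): probe scores are summed over a gene region in
each condition and the control total is subtracted from the depleted total.
The pause index — median promoter score over median gene-body score, with a
400 bp promoter window around the TSS — and the elongating/total polymerase
ratio in gene bodies are computed from the same per-region score extraction.

*Delta-null interval calling* (method 2): scores are subtracted probe-wise
(depleted minus control) to form a genome-wide array of delta values.  The
genome-wide median and standard deviation of that array define an empirical
null; maximal runs of at least three consecutive features (105 bp) that all
deviate from the median by at least ``k_sd`` standard deviations, with the
same sign throughout, are called as increase/decrease intervals.  Genes are
then classified UP/DOWN per region (200 bp promoter window; body = the rest
of the transcription unit) by intersection with the called intervals.

The :class:`DifferentialOccupancy` model wraps the whole of method 2 plus the
per-gene integrated deltas; :meth:`DifferentialOccupancy.fit` returns a
:class:`DifferentialOccupancyResults` carrying the null estimates with their
standard errors, the signed intervals, per-gene classes and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._segment import threshold_runs
from .errors import DegenerateNullError, NoSharedProbesError, NullShiftWarning, ValidationError
from .genome import GeneModel, Interval, ProbeTrack, align_tracks

PROMOTER_WIDTH_CHANGE = 200   # promoter window for UP/DOWN classification
PROMOTER_WIDTH_PAUSE = 400    # promoter window for the pause index


class Measurement(NamedTuple):
    """A per-gene quantity with a status flag.

    ``status`` is ``"ok"``, ``"no_data"`` (no shared probes in the region —
    distinct from a value of 0) or ``"undefined"`` (denominator <= 0).
    """

    value: float
    status: str = "ok"


@dataclass(frozen=True)
class GeneRegions:
    """Promoter window and gene-body pieces of one transcription unit."""

    gene_id: str
    promoter: Interval
    body: tuple[Interval, ...]

    @classmethod
    def of(cls, gene: GeneModel, promoter_width: int) -> "GeneRegions":
        return cls(gene.gene_id, gene.promoter_window(promoter_width),
                   tuple(gene.body_intervals(promoter_width)))


@dataclass(frozen=True)
class NullStats:
    """Genome-wide summary of the per-probe delta distribution.

    The median and standard deviation define the change-call thresholds;
    the mean is kept as the distribution-shape diagnostic.  Standard errors
    assume approximate normality: ``se_median = 1.2533 sd / sqrt(n)`` and
    ``se_sd = sd / sqrt(2 (n - 1))``.
    """

    median: float
    mean: float
    sd: float
    n: int

    @property
    def se_median(self) -> float:
        return 1.2533 * self.sd / np.sqrt(self.n)

    @property
    def se_sd(self) -> float:
        return self.sd / np.sqrt(2.0 * max(self.n - 1, 1))


@dataclass(frozen=True)
class ChangeCallParams:
    """Thresholds of the delta-null interval caller.

    ``k_sd`` standard deviations from the genome-wide median (default 2),
    sustained over at least ``min_run`` consecutive features (default 3)
    spanning at least ``min_span`` bp (default 105).  ``max_gap`` is the
    largest start-to-start spacing treated as consecutive; the default
    (None) is twice the tile width, which tolerates one missing probe.
    """

    k_sd: float = 2.0
    min_run: int = 3
    min_span: int = 105
    max_gap: int | None = None

    def __post_init__(self):
        if self.k_sd <= 0:
            raise ValidationError("k_sd must be > 0")
        if self.min_run < 1:
            raise ValidationError("min_run must be >= 1")


def delta_track(control: ProbeTrack, depleted: ProbeTrack) -> ProbeTrack:
    """Per-probe delta (depleted - control) at shared probe positions.

    Probes present in only one track are dropped; their counts are recorded
    in ``meta['n_dropped_control']`` / ``meta['n_dropped_depleted']``.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty intersection raised as error below
        aligned = align_tracks(control, depleted)
    if aligned.starts.size == 0:
        raise NoSharedProbesError("control and depleted tracks share no probes")
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    delta = aligned.b - aligned.a
    for chrom in np.unique(aligned.chroms):
        sel = aligned.chroms == chrom
        data[str(chrom)] = (aligned.starts[sel], delta[sel])
    return ProbeTrack(data, tile_width=control.tile_width,
                      meta={"n_dropped_control": aligned.n_dropped_a,
                            "n_dropped_depleted": aligned.n_dropped_b})


def null_stats(delta: ProbeTrack) -> NullStats:
    """Genome-wide median, mean and sample SD of the delta distribution.

    Warns (:class:`NullShiftWarning`) when the median sits more than a
    quarter SD away from zero — the analysis assumes a shift-free,
    near-normal null, and a shifted median indicates a global normalization
    problem between the two conditions.
    """
    values = delta.all_scores()
    if values.size < 3:
        raise ValidationError(f"need >=3 delta values, got {values.size}")
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise DegenerateNullError("all delta values identical; null SD is zero")
    stats = NullStats(median=float(np.median(values)), mean=float(values.mean()),
                      sd=sd, n=int(values.size))
    if abs(stats.median) > 0.25 * stats.sd:
        warnings.warn(
            f"delta median {stats.median:.3g} exceeds 0.25 SD ({stats.sd:.3g}); "
            "the conditions may not be comparably normalized",
            NullShiftWarning, stacklevel=2)
    return stats


def call_change_intervals(delta: ProbeTrack, null: NullStats,
                          params: ChangeCallParams | None = None,
                          ) -> tuple[list[Interval], list[Interval]]:
    """Call signed change intervals from a delta track against its null.

    Returns ``(increases, decreases)``: maximal runs of >= ``min_run``
    consecutive probes with delta >= median + k*sd (sign +1) or
    delta <= median - k*sd (sign -1), same sign throughout, spanning
    >= ``min_span`` bp.  Interval scores carry the mean delta of the run.
    """
    params = params or ChangeCallParams()
    max_gap = 2 * delta.tile_width if params.max_gap is None else params.max_gap
    hi = null.median + params.k_sd * null.sd
    lo = null.median - params.k_sd * null.sd
    increases: list[Interval] = []
    decreases: list[Interval] = []
    for chrom, starts, values in delta.iter_chromosomes():
        for sign, passing, out in ((1, values >= hi, increases),
                                   (-1, values <= lo, decreases)):
            for i, j in threshold_runs(starts, passing, tile_width=delta.tile_width,
                                       max_gap=max_gap, min_run=params.min_run,
                                       min_span=params.min_span):
                out.append(Interval(chrom, int(starts[i]),
                                    int(starts[j - 1]) + delta.tile_width,
                                    sign=sign, score=float(values[i:j].mean())))
    return increases, decreases


# ---------------------------------------------------------------------------
# method 1: integrated per-gene quantities


def integrated_gene_delta(control: ProbeTrack, depleted: ProbeTrack,
                          region: Interval) -> Measurement:
    """Summed depleted score minus summed control score over shared probes
    contained in ``region``."""
    starts_c, scores_c = control.probes_in(region)
    starts_d, scores_d = depleted.probes_in(region)
    common, ic, id_ = np.intersect1d(starts_c, starts_d, assume_unique=True,
                                     return_indices=True)
    if common.size == 0:
        return Measurement(np.nan, "no_data")
    return Measurement(float(scores_d[id_].sum() - scores_c[ic].sum()))


def _region_stat(values: np.ndarray, method: str, span: int) -> float:
    if method == "median":
        return float(np.median(values))
    if method == "density":  # summed signal per bp
        return float(values.sum() / span)
    raise ValueError(f"unknown pause-index method {method!r}")


def pause_index(track: ProbeTrack, gene: GeneModel,
                promoter_width: int = PROMOTER_WIDTH_PAUSE,
                method: str = "median") -> Measurement:
    """Promoter-proximal pausing index of one gene.

    Median promoter score divided by median gene-body score ("median", the
    default); ``method="density"`` uses summed signal per bp instead.  The
    promoter is the ``promoter_width`` window centered on the TSS; the body
    is the rest of the transcription unit.  Invariant under rescaling of all
    scores by a positive constant.
    """
    regions = GeneRegions.of(gene, promoter_width)
    prom_scores = track.probes_in(regions.promoter)[1]
    body_scores = track.scores_in_regions(list(regions.body))
    if prom_scores.size == 0 or body_scores.size == 0:
        return Measurement(np.nan, "no_data")
    body_span = sum(iv.span for iv in regions.body)
    num = _region_stat(prom_scores, method, regions.promoter.span)
    den = _region_stat(body_scores, method, body_span)
    if den <= 0:
        return Measurement(np.nan, "undefined")
    return Measurement(num / den)


def elongation_ratio(ser2p: ProbeTrack, rpb3: ProbeTrack, gene: GeneModel,
                     promoter_width: int = PROMOTER_WIDTH_PAUSE) -> Measurement:
    """Ratio of elongating (Ser2-phosphorylated) to total polymerase in the
    gene body: median Ser2P body score over median Rpb3 body score, computed
    over probes the two tracks share."""
    body = gene.body_intervals(promoter_width)
    parts_s, parts_r = [], []
    for piece in body:
        s_starts, s_scores = ser2p.probes_in(piece)
        r_starts, r_scores = rpb3.probes_in(piece)
        common, i_s, i_r = np.intersect1d(s_starts, r_starts, assume_unique=True,
                                          return_indices=True)
        if common.size:
            parts_s.append(s_scores[i_s])
            parts_r.append(r_scores[i_r])
    if not parts_s:
        return Measurement(np.nan, "no_data")
    med_r = float(np.median(np.concatenate(parts_r)))
    if med_r <= 0:
        return Measurement(np.nan, "undefined")
    return Measurement(float(np.median(np.concatenate(parts_s))) / med_r)


# ---------------------------------------------------------------------------
# per-gene classification and percentage tables

CLASSES = ("UP", "DOWN", "AMBIGUOUS", "NONE")


def _overlap_weight(tree: IntervalTree | None, region: Interval) -> tuple[int, float]:
    """(number of overlapping intervals, summed |mean delta| x span weight)."""
    if tree is None:
        return 0, 0.0
    hits = tree.overlap(region.start, region.end)
    weight = sum(abs(h.data.score or 0.0) * h.data.span for h in hits)
    return len(hits), weight


def classify_gene_changes(increases: list[Interval], decreases: list[Interval],
                          genes: list[GeneModel],
                          promoter_width: int = PROMOTER_WIDTH_CHANGE) -> pd.DataFrame:
    """Per-gene, per-region UP/DOWN classification against called intervals.

    For each gene and each region (promoter, body): UP if only increase
    intervals overlap the region, DOWN if only decreases, AMBIGUOUS if both,
    NONE if neither.  AMBIGUOUS genes carry an automatic resolution — the
    sign with the larger summed |mean delta| x span — in the ``*_resolved``
    column (the AMBIGUOUS flag itself is retained).  Interval/region overlap
    requires >= 1 bp; strand is ignored (ChIP signal is unstranded).
    """
    inc_forest: dict[str, IntervalTree] = {}
    dec_forest: dict[str, IntervalTree] = {}
    for iv in increases:
        inc_forest.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    for iv in decreases:
        dec_forest.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    rows = []
    for gene in genes:
        regions = GeneRegions.of(gene, promoter_width)
        row: dict[str, object] = {"gene_id": gene.gene_id}
        for name, pieces in (("promoter", (regions.promoter,)),
                             ("body", regions.body)):
            n_inc = n_dec = 0
            w_inc = w_dec = 0.0
            for piece in pieces:
                ni, wi = _overlap_weight(inc_forest.get(gene.chrom), piece)
                nd, wd = _overlap_weight(dec_forest.get(gene.chrom), piece)
                n_inc += ni
                n_dec += nd
                w_inc += wi
                w_dec += wd
            if n_inc and n_dec:
                cls = "AMBIGUOUS"
                resolved = "UP" if w_inc > w_dec else ("DOWN" if w_dec > w_inc else "AMBIGUOUS")
            elif n_inc:
                cls = resolved = "UP"
            elif n_dec:
                cls = resolved = "DOWN"
            else:
                cls = resolved = "NONE"
            row[f"{name}_class"] = cls
            row[f"{name}_resolved"] = resolved
            row[f"{name}_up_weight"] = w_inc
            row[f"{name}_down_weight"] = w_dec
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.set_index("gene_id") if rows else pd.DataFrame(
        columns=["promoter_class", "promoter_resolved", "body_class", "body_resolved"])


def category_percentages(classes: pd.DataFrame, groups: dict[str, pd.Series],
                         region: str = "body") -> pd.DataFrame:
    """Percent of genes UP and DOWN within each gene group.

    ``groups`` maps group name -> boolean Series over gene ids.  AMBIGUOUS
    genes count toward their automatic resolution in ``pct_up``/``pct_down``
    and are also reported separately (``n_ambiguous``).  An empty group is
    flagged (``defined = False``) rather than reported as 0%.
    """
    raw = classes[f"{region}_class"]
    resolved = classes[f"{region}_resolved"]
    rows = []
    for name, mask in groups.items():
        mask = mask.reindex(classes.index, fill_value=False).astype(bool)
        n = int(mask.sum())
        if n == 0:
            rows.append({"group": name, "n_genes": 0, "n_up": 0, "n_down": 0,
                         "n_ambiguous": 0, "pct_up": np.nan, "pct_down": np.nan,
                         "defined": False})
            continue
        res = resolved[mask]
        n_up = int((res == "UP").sum())
        n_down = int((res == "DOWN").sum())
        n_amb = int((raw[mask] == "AMBIGUOUS").sum())
        rows.append({"group": name, "n_genes": n, "n_up": n_up, "n_down": n_down,
                     "n_ambiguous": n_amb, "pct_up": 100.0 * n_up / n,
                     "pct_down": 100.0 * n_down / n, "defined": True})
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# model / results surface


class DifferentialOccupancy:
    """Paired-condition differential occupancy model for one factor.

    Parameters
    ----------
    control, depleted
        Probe tracks of the same factor in mock-treated and RNAi-depleted
        cells, on a shared probe grid.
    genes
        Transcription units to classify (optional; interval calling alone
        needs no annotation).
    params
        :class:`ChangeCallParams`; defaults follow the two-SD / three-feature
        / 105 bp rule.
    promoter_width
        Promoter window for UP/DOWN region classification (default 200 bp).
    """

    def __init__(self, control: ProbeTrack, depleted: ProbeTrack,
                 genes: list[GeneModel] | None = None,
                 params: ChangeCallParams | None = None,
                 promoter_width: int = PROMOTER_WIDTH_CHANGE):
        self.control = control
        self.depleted = depleted
        self.genes = list(genes) if genes else []
        self.params = params or ChangeCallParams()
        self.promoter_width = promoter_width

    @classmethod
    def from_files(cls, control_path, depleted_path, genes_path=None,
                   track_format: str = "bedGraph", **kwargs) -> "DifferentialOccupancy":
        from . import io

        genes = io.read_genes(genes_path) if genes_path else None
        return cls(io.read_track(control_path, track_format),
                   io.read_track(depleted_path, track_format), genes, **kwargs)

    def fit(self) -> "DifferentialOccupancyResults":
        delta = delta_track(self.control, self.depleted)
        null = null_stats(delta)
        increases, decreases = call_change_intervals(delta, null, self.params)
        if self.genes:
            classes = classify_gene_changes(increases, decreases, self.genes,
                                            self.promoter_width)
            deltas = {}
            status = {}
            for gene in self.genes:
                m = integrated_gene_delta(
                    self.control, self.depleted,
                    Interval(gene.chrom, gene.tx_start, gene.tx_end))
                deltas[gene.gene_id] = m.value
                status[gene.gene_id] = m.status
            gene_deltas = pd.DataFrame(
                {"delta_total": pd.Series(deltas), "status": pd.Series(status)})
            gene_deltas.index.name = "gene_id"
        else:
            classes = pd.DataFrame()
            gene_deltas = pd.DataFrame(columns=["delta_total", "status"])
        return DifferentialOccupancyResults(self, delta, null, increases,
                                            decreases, classes, gene_deltas)


class DifferentialOccupancyResults:
    """Fitted differential-occupancy results.

    Attributes
    ----------
    delta : ProbeTrack
        Per-probe delta track (depleted - control) on shared probes.
    null : NullStats
        Genome-wide delta null (median, mean, SD) with standard errors.
    increases, decreases : list of Interval
        Signed change intervals.
    gene_classes : DataFrame
        Per-gene promoter/body UP-DOWN classification (if genes were given).
    gene_deltas : DataFrame
        Integrated whole-gene delta totals with status flags.
    """

    def __init__(self, model, delta, null, increases, decreases,
                 gene_classes, gene_deltas):
        self.model = model
        self.delta = delta
        self.null = null
        self.increases = increases
        self.decreases = decreases
        self.gene_classes = gene_classes
        self.gene_deltas = gene_deltas

    @property
    def intervals(self) -> list[Interval]:
        """All signed change intervals sorted by genome coordinate."""
        return sorted(self.increases + self.decreases,
                      key=lambda iv: (iv.chrom, iv.start, iv.end))

    def class_counts(self, region: str = "body") -> pd.Series:
        if self.gene_classes.empty:
            return pd.Series(dtype=int)
        return self.gene_classes[f"{region}_class"].value_counts().reindex(
            CLASSES, fill_value=0)

    def percentages(self, groups: dict[str, pd.Series],
                    region: str = "body") -> pd.DataFrame:
        return category_percentages(self.gene_classes, groups, region=region)

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Differential occupancy (depleted - control)",
            "=" * 47,
            f"shared probes            {self.null.n}",
            f"dropped (control only)   {self.delta.meta.get('n_dropped_control', 0)}",
            f"dropped (depleted only)  {self.delta.meta.get('n_dropped_depleted', 0)}",
            f"null median              {self.null.median: .4f} "
            f"(SE {self.null.se_median:.4f})",
            f"null mean                {self.null.mean: .4f}",
            f"null SD                  {self.null.sd: .4f} (SE {self.null.se_sd:.4f})",
            f"thresholds               median +/- {p.k_sd} SD, "
            f">= {p.min_run} features, >= {p.min_span} bp",
            f"increase intervals       {len(self.increases)}",
            f"decrease intervals       {len(self.decreases)}",
        ]
        if not self.gene_classes.empty:
            for region in ("promoter", "body"):
                counts = self.class_counts(region)
                lines.append(f"{region:<9}classes         " + "  ".join(
                    f"{c}={counts[c]}" for c in CLASSES))
        return "\n".join(lines)

    def plot_delta_histogram(self, ax=None, bins: int = 100):
        """Histogram of the delta null with the call thresholds marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        values = self.delta.all_scores()
        ax.hist(values, bins=bins, color="0.6")
        k = self.model.params.k_sd
        for x, style in ((self.null.median, "-"),
                         (self.null.median + k * self.null.sd, "--"),
                         (self.null.median - k * self.null.sd, "--")):
            ax.axvline(x, linestyle=style, color="firebrick")
        ax.set_xlabel("per-probe delta (enrichment units)")
        ax.set_ylabel("features")
        return ax
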