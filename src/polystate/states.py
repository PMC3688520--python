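"""Cohesin-Polycomb chromatin-state classification.

Genes fall into one of three cohesin-PcG states, or "other":

* ``RESTRAINED`` — cohesin and the H3K27me3 silencing mark overlap over a
  multi-kilobase stretch of the transcription unit.  Such genes are
  expressed at moderate levels and strongly derepressed when either complex
  is depleted.  "Several kilobases" is operationalized as a configurable
  minimum overlap (default 2,000 bp).
* ``SILENCED`` — classic PcG silencing: H3K27me3 and the PRC1 subunit Pc are
  both present, expression is low, and cohesin is confined to Polycomb
  Response Elements (PREs).  When a PRE annotation is supplied, cohesin
  intervals inside the transcription unit must be contained in PREs; without
  one, the rule degrades to "cohesin not bound at the gene level" and the
  evidence records the degradation.
* ``ACTIVE`` — cohesin and Pc bound, no H3K27me3: the cohesin-PRC1 active
  state with promoter-proximal paused polymerase.

Rules are applied in the order RESTRAINED, SILENCED, ACTIVE, OTHER, so every
gene receives exactly one state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome import GeneModel, Interval

STATES = ("SILENCED", "RESTRAINED", "ACTIVE", "OTHER")


@dataclass(frozen=True)
class StateParams:
    """Knobs of the state classifier.

    ``expression_cutoff`` separates "low" from "high" mRNA (log2 units); when
    None, the cohort median of the supplied expression table is used.
    Factor names refer to columns of the binding matrix / keys of the
    per-factor interval dict.
    """

    restrained_min_overlap: int = 2000
    expression_cutoff: float | None = None
    cohesin_factor: str = "cohesin"
    pc_factor: str = "Pc"
    k27_factor: str = "H3K27me3"
    pre_intervals: tuple[Interval, ...] = ()

    def __post_init__(self):
        if self.restrained_min_overlap <= 0:
            raise ValidationError("restrained_min_overlap must be > 0")


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(p) for p in merged]


def _clip(intervals: list[Interval], chrom: str, lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    for iv in intervals:
        if iv.chrom == chrom and iv.start < hi and lo < iv.end:
            out.append((max(iv.start, lo), min(iv.end, hi)))
    return out


def cohesin_k27_overlap_span(cohesin_intervals: list[Interval],
                             k27_intervals: list[Interval],
                             gene: GeneModel) -> int:
    """Total bp where cohesin and H3K27me3 domains intersect, clipped to the
    transcription unit."""
    a = _union(_clip(cohesin_intervals, gene.chrom, gene.tx_start, gene.tx_end))
    b = _union(_clip(k27_intervals, gene.chrom, gene.tx_start, gene.tx_end))
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _cohesin_outside_pres(cohesin_intervals: list[Interval], gene: GeneModel,
                          pres: tuple[Interval, ...]) -> bool:
    """True if any cohesin interval overlapping the transcription unit is not
    fully contained in the union of PRE intervals."""
    pre_union = _union([(p.start, p.end) for p in pres if p.chrom == gene.chrom])
    for iv in cohesin_intervals:
        if not iv.overlaps(gene.chrom, gene.tx_start, gene.tx_end):
            continue
        if not any(lo <= iv.start and iv.end <= hi for lo, hi in pre_union):
            return True
    return False


def classify_state(gene: GeneModel, bound: pd.Series,
                   intervals: dict[str, list[Interval]],
                   expression: float, cutoff: float,
                   params: StateParams) -> dict:
    """Classify one gene; returns the state with its evidence fields."""
    for factor in (params.cohesin_factor, params.pc_factor, params.k27_factor):
        if factor not in bound.index:
            raise KeyError(f"factor {factor!r} missing from binding matrix")
    cohesin_b = bool(bound[params.cohesin_factor])
    pc_b = bool(bound[params.pc_factor])
    k27_b = bool(bound[params.k27_factor])
    cohesin_ivs = intervals.get(params.cohesin_factor, [])
    k27_ivs = intervals.get(params.k27_factor, [])

    overlap = cohesin_k27_overlap_span(cohesin_ivs, k27_ivs, gene)
    pre_degraded = not params.pre_intervals
    if pre_degraded:
        cohesin_outside_pre = cohesin_b
    else:
        cohesin_outside_pre = _cohesin_outside_pres(cohesin_ivs, gene,
                                                    params.pre_intervals)

    if cohesin_b and k27_b and overlap >= params.restrained_min_overlap:
        state = "RESTRAINED"
    elif k27_b and pc_b and not cohesin_outside_pre and expression < cutoff:
        state = "SILENCED"
    elif cohesin_b and pc_b and not k27_b:
        state = "ACTIVE"
    else:
        state = "OTHER"
    return {"gene_id": gene.gene_id, "state": state,
            "cohesin_k27_overlap_bp": overlap,
            "cohesin_bound": int(cohesin_b), "pc_bound": int(pc_b),
            "k27_bound": int(k27_b),
            "cohesin_outside_pre": int(cohesin_outside_pre),
            "pre_rule_degraded": int(pre_degraded),
            "expression": expression}


def classify_states(genes: list[GeneModel], matrix: pd.DataFrame,
                    intervals: dict[str, list[Interval]],
                    expression: pd.Series,
                    params: StateParams | None = None) -> pd.DataFrame:
    """State calls with evidence for every gene (exactly one state each)."""
    params = params or StateParams()
    cutoff = (float(expression.median()) if params.expression_cutoff is None
              else params.expression_cutoff)
    # pre-bin intervals by chromosome once; per-gene clipping stays cheap
    rows = []
    for gene in genes:
        if gene.gene_id not in matrix.index:
            raise KeyError(f"gene {gene.gene_id!r} missing from binding matrix")
        expr = float(expression.get(gene.gene_id, np.nan))
        rows.append(classify_state(gene, matrix.loc[gene.gene_id], intervals,
                                   expr, cutoff, params))
    frame = pd.DataFrame(rows).set_index("gene_id")
    frame.attrs["expression_cutoff"] = cutoff
    return frame


def active_gene_mask(matrix: pd.DataFrame, expression: pd.Series,
                     params: StateParams | None = None,
                     polii_factor: str | None = None) -> pd.Series:
    """Default "active gene" predicate for percentage denominators.

    A gene is active when it lacks the H3K27me3 mark and either binds
    polymerase (if a Pol II column is available) or is expressed at or above
    the cutoff.  The published membership rule for the ~7,000-gene active
    cohort is not fully specified, so this predicate is deliberately
    replaceable: any boolean Series can be passed wherever a group is needed.
    """
    params = params or StateParams()
    cutoff = (float(expression.median()) if params.expression_cutoff is None
              else params.expression_cutoff)
    not_k27 = matrix[params.k27_factor] == 0
    expressed = expression.reindex(matrix.index) >= cutoff
    if polii_factor and polii_factor in matrix.columns:
        return not_k27 & ((matrix[polii_factor] == 1) | expressed.fillna(False))
    return not_k27 & expressed.fillna(False)
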