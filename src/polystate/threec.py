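"""Chromosome conformation capture (3C) quantification.

Ligation products between an anchor restriction fragment and each test
fragment are quantified by qPCR.  Because primer pairs amplify with very
different efficiencies, each pair is normalized against the same products
amplified from a randomly religated BAC template covering the locus, which
contains every ligation junction at equal molarity: the BAC quantity is the
amplification efficiency of the pair, and the crosslinking frequency is

    I = mean(replicate quantities) / bac_control.

The standard error is computed over all PCR reaction replicates pooled
(each reaction's quantity divided by the BAC control); when biological
replicate labels are supplied, the SE over biological-replicate means is
reported alongside.  No distance-decay background model is fitted — profiles
are presented as raw BAC-normalized frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FragmentMapError, ProfileMismatchError, UnusablePairError, ValidationError
from .genome import Interval


@dataclass(frozen=True)
class QpcrMeasurement:
    """Raw qPCR quantities for one anchor-fragment primer pair.

    ``replicates`` holds all reaction-level quantities pooled; the optional
    ``biological_ids`` (same length) label which biological replicate each
    reaction came from.
    """

    anchor_id: str
    fragment_id: str
    replicates: tuple[float, ...]
    bac_control: float
    biological_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if any(q < 0 for q in self.replicates):
            raise ValidationError("qPCR quantities must be >= 0")
        if self.bac_control < 0:
            raise ValidationError("BAC control quantity must be >= 0")
        if self.biological_ids and len(self.biological_ids) != len(self.replicates):
            raise ValidationError("biological_ids must match replicates in length")


@dataclass(frozen=True)
class InteractionPoint:
    """BAC-normalized interaction frequency with its standard error."""

    anchor_id: str
    fragment_id: str
    frequency: float
    se: float
    n_replicates: int
    se_biological: float = np.nan   # SE over biological-replicate means
    status: str = "ok"              # "ok" | "se_undefined" (single replicate)


def normalize_interaction(m: QpcrMeasurement) -> InteractionPoint:
    """Normalize one primer pair against its BAC control.

    Scaling a pair's replicate quantities and its BAC control by a common
    factor (a primer-efficiency change) leaves the result unchanged.
    """
    if m.bac_control == 0:
        raise UnusablePairError(
            f"pair ({m.anchor_id}, {m.fragment_id}): BAC control is zero")
    if not m.replicates:
        raise ValidationError(
            f"pair ({m.anchor_id}, {m.fragment_id}): no replicate quantities")
    ratios = np.asarray(m.replicates, dtype=float) / m.bac_control
    frequency = float(ratios.mean())
    if ratios.size < 2:
        return InteractionPoint(m.anchor_id, m.fragment_id, frequency,
                                se=np.nan, n_replicates=1, status="se_undefined")
    se = float(ratios.std(ddof=1) / np.sqrt(ratios.size))
    se_bio = np.nan
    if m.biological_ids:
        means = pd.Series(ratios).groupby(list(m.biological_ids)).mean()
        if len(means) >= 2:
            se_bio = float(means.std(ddof=1) / np.sqrt(len(means)))
    return InteractionPoint(m.anchor_id, m.fragment_id, frequency, se=se,
                            n_replicates=int(ratios.size), se_biological=se_bio)


def normalize_table(qpcr: pd.DataFrame, bac: pd.Series) -> list[InteractionPoint]:
    """Normalize a whole qPCR table (columns anchor_id, fragment_id,
    replicate, quantity) against a BAC-control Series indexed by
    (anchor_id, fragment_id)."""
    points = []
    for (anchor, fragment), grp in qpcr.groupby(["anchor_id", "fragment_id"],
                                                sort=True):
        if (anchor, fragment) not in bac.index:
            raise UnusablePairError(f"pair ({anchor}, {fragment}): no BAC control")
        m = QpcrMeasurement(anchor, fragment,
                            tuple(grp["quantity"].tolist()),
                            float(bac[(anchor, fragment)]),
                            tuple(grp["replicate"].astype(str).tolist()))
        points.append(normalize_interaction(m))
    return points


def interaction_profile(points: list[InteractionPoint], anchor_id: str,
                        fragment_coords: dict[str, Interval]) -> pd.DataFrame:
    """Anchor-centric profile ordered by fragment midpoint.

    The anchor's own fragment, if measured, is retained and flagged as the
    self-ligation position.  Fragments without coordinates raise
    :class:`FragmentMapError` listing the offending ids.
    """
    mine = [p for p in points if p.anchor_id == anchor_id]
    unmapped = sorted({p.fragment_id for p in mine} - set(fragment_coords))
    if unmapped:
        raise FragmentMapError(unmapped)
    rows = []
    for p in mine:
        coord = fragment_coords[p.fragment_id]
        rows.append({"fragment_id": p.fragment_id, "chrom": coord.chrom,
                     "midpoint": (coord.start + coord.end) // 2,
                     "frequency": p.frequency, "se": p.se,
                     "n_replicates": p.n_replicates,
                     "is_self_ligation": p.fragment_id == anchor_id,
                     "status": p.status})
    frame = pd.DataFrame(rows, columns=["fragment_id", "chrom", "midpoint",
                                        "frequency", "se", "n_replicates",
                                        "is_self_ligation", "status"])
    if not frame.empty:
        frame = frame.sort_values(["chrom", "midpoint"], kind="stable")
        frame = frame.set_index("fragment_id")
    else:
        frame = frame.set_index("fragment_id")
    anchor_coord = fragment_coords.get(anchor_id)
    frame.attrs["anchor_id"] = anchor_id
    frame.attrs["anchor_midpoint"] = (
        (anchor_coord.start + anchor_coord.end) // 2 if anchor_coord else None)
    return frame


def compare_conditions(control: pd.DataFrame, depleted: pd.DataFrame) -> pd.DataFrame:
    """Per-fragment depleted/control frequency ratio with a "decreased" flag.

    The flag is set when the ratio plus its propagated SE still falls below 1
    (first-order error propagation of the two SEs).  Fragments with zero
    control frequency get an undefined ratio and status "undefined".
    """
    if control.attrs.get("anchor_id") != depleted.attrs.get("anchor_id"):
        raise ProfileMismatchError("profiles have different anchors")
    if set(control.index) != set(depleted.index):
        raise ProfileMismatchError("profiles cover different fragment sets")
    depleted = depleted.reindex(control.index)
    rows = []
    for frag in control.index:
        ic, sc = control.loc[frag, "frequency"], control.loc[frag, "se"]
        id_, sd = depleted.loc[frag, "frequency"], depleted.loc[frag, "se"]
        if ic == 0:
            rows.append({"fragment_id": frag, "ratio": np.nan, "se": np.nan,
                         "decreased": False, "status": "undefined"})
            continue
        ratio = id_ / ic
        rel = 0.0
        if np.isfinite(sc) and ic != 0:
            rel += (sc / ic) ** 2
        if np.isfinite(sd) and id_ != 0:
            rel += (sd / id_) ** 2
        se = abs(ratio) * np.sqrt(rel)
        rows.append({"fragment_id": frag, "ratio": float(ratio), "se": float(se),
                     "decreased": bool(ratio + se < 1.0), "status": "ok"})
    return pd.DataFrame(rows).set_index("fragment_id")
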