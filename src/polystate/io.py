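"""Readers and writers for the plain-text interchange formats.

Tracks come in as bedGraph or fixed-step wiggle and are held as
:class:`~polystate.genome.ProbeTrack`.  Intervals go out as BED6 with the
sign of a change region encoded in the name ("increase"/"decrease"/"region")
and strand column.  Gene annotations are read from GFF3 (1-based inclusive,
converted to 0-based half-open on the fly) or from a 5-column TSV
``gene_id  chrom  strand  start  end`` already in BED-style coordinates.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnnotationError, TrackParseError, ValidationError
from .genome import DEFAULT_TILE_WIDTH, GeneModel, Interval, ProbeTrack, validate_expression

_SKIP_PREFIXES = ("#", "track", "browser")


def read_track(path, format: str = "bedGraph",
               tile_width: int = DEFAULT_TILE_WIDTH) -> ProbeTrack:
    """Read an enrichment track into a :class:`ProbeTrack`.

    Unsorted records are sorted; a duplicate probe position raises
    :class:`DuplicateProbeError`; a malformed line raises
    :class:`TrackParseError` carrying its line number.
    """
    if format == "bedGraph":
        return _read_bedgraph(path, tile_width)
    if format in ("wiggle-fixed-step", "wig"):
        return _read_fixed_step_wiggle(path, tile_width)
    raise ValueError(f"unknown track format {format!r}")


def _read_bedgraph(path, tile_width: int) -> ProbeTrack:
    chroms, starts, scores = [], [], []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise TrackParseError(path, lineno, f"expected 4 bedGraph columns, got {len(fields)}")
            try:
                start = int(fields[1])
                int(fields[2])  # end column, validated but implied by tile_width
                score = float(fields[3])
            except ValueError as exc:
                raise TrackParseError(path, lineno, str(exc)) from None
            chroms.append(fields[0])
            starts.append(start)
            scores.append(score)
    if not chroms:
        return ProbeTrack({}, tile_width=tile_width)
    return ProbeTrack.from_records(chroms, starts, scores, tile_width=tile_width)


def _read_fixed_step_wiggle(path, tile_width: int) -> ProbeTrack:
    chroms, starts, scores = [], [], []
    chrom, pos, step = None, None, None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                header = dict(part.split("=", 1) for part in line.split()[1:])
                try:
                    chrom = header["chrom"]
                    pos = int(header["start"]) - 1  # wiggle is 1-based
                    step = int(header.get("step", tile_width))
                except (KeyError, ValueError) as exc:
                    raise TrackParseError(path, lineno, f"bad fixedStep header: {exc}") from None
                continue
            if chrom is None:
                raise TrackParseError(path, lineno, "value line before fixedStep header")
            try:
                score = float(line)
            except ValueError as exc:
                raise TrackParseError(path, lineno, str(exc)) from None
            chroms.append(chrom)
            starts.append(pos)
            scores.append(score)
            pos += step
    if not chroms:
        return ProbeTrack({}, tile_width=tile_width)
    return ProbeTrack.from_records(chroms, starts, scores, tile_width=tile_width)


def write_track(track: ProbeTrack, path) -> None:
    """Write a track as bedGraph.  Scores are written with ``repr`` so that a
    read/write cycle round-trips them bit-identically."""
    with open(path, "w") as handle:
        for chrom, starts, scores in track.iter_chromosomes():
            for start, score in zip(starts.tolist(), scores.tolist()):
                handle.write(f"{chrom}\t{start}\t{start + track.tile_width}\t{score!r}\n")


_SIGN_TO_NAME = {1: "increase", -1: "decrease", 0: "region"}
_SIGN_TO_STRAND = {1: "+", -1: "-", 0: "."}
_STRAND_TO_SIGN = {"+": 1, "-": -1, ".": 0}


def write_bed(intervals: list[Interval], path) -> None:
    """Write intervals as BED6; the sign rides in the name and strand columns."""
    with open(path, "w") as handle:
        handle.write("# BED6: chrom start end name score strand; "
                     "name/strand encode change sign\n")
        for iv in intervals:
            score = "0" if iv.score is None else repr(float(iv.score))
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_SIGN_TO_NAME[iv.sign]}\t"
                         f"{score}\t{_SIGN_TO_STRAND[iv.sign]}\n")


def read_bed(path) -> list[Interval]:
    """Read intervals from BED (3-6 columns); inverse of :func:`write_bed`."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise TrackParseError(path, lineno, f"expected >=3 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                sign = _STRAND_TO_SIGN[fields[5]] if len(fields) >= 6 else 0
                score = float(fields[4]) if len(fields) >= 5 else None
            except (ValueError, KeyError) as exc:
                raise TrackParseError(path, lineno, str(exc)) from None
            intervals.append(Interval(fields[0], start, end, sign=sign, score=score))
    return intervals


def read_genes(path, format: str | None = None) -> list[GeneModel]:
    """Read transcription units from GFF3 or 5-column TSV.

    The format is inferred from the extension when not given.  GFF3
    coordinates (1-based inclusive) are converted to 0-based half-open.
    """
    path = Path(path)
    if format is None:
        format = "GFF3" if path.suffix.lower() in (".gff", ".gff3") else "TSV"
    if format.upper() == "GFF3":
        return _read_genes_gff3(path)
    if format.upper() == "TSV":
        return _read_genes_tsv(path)
    raise ValueError(f"unknown gene annotation format {format!r}")


def _read_genes_tsv(path) -> list[GeneModel]:
    genes = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise AnnotationError(f"{path}:{lineno}: expected 5 columns "
                                      f"(id chrom strand start end), got {len(fields)}")
            gene_id, chrom, strand = fields[0], fields[1], fields[2]
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
            try:
                genes.append(GeneModel(gene_id, chrom, strand, start, end))
            except ValidationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
    return genes


def _read_genes_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for feature in db.features_of_type("gene", order_by=("seqid", "start")):
        if feature.strand not in ("+", "-"):
            raise AnnotationError(f"gene {feature.id!r}: missing strand")
        gene_id = feature.attributes.get("ID", [feature.id])[0]
        try:
            genes.append(GeneModel(gene_id, feature.seqid, feature.strand,
                                   feature.start - 1, feature.end))
        except ValidationError as exc:
            raise AnnotationError(str(exc)) from None
    return genes


def write_genes_tsv(genes: list[GeneModel], path) -> None:
    with open(path, "w") as handle:
        handle.write("# gene_id\tchrom\tstrand\ttx_start\ttx_end\n")
        for g in genes:
            handle.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\n")


def read_expression(path) -> pd.Series:
    """Read a 2-column TSV ``gene_id  log2_mrna`` into a Series."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["gene_id", "log2_mrna"], dtype={"gene_id": str})
    series = table.set_index("gene_id")["log2_mrna"]
    return validate_expression(series)


def write_expression(expression: pd.Series, path) -> None:
    expression.rename("log2_mrna").rename_axis("gene_id").to_csv(
        path, sep="\t", header=False, float_format="%.6g")


def read_binding_matrix(path) -> pd.DataFrame:
    from .genome import validate_binding_matrix

    matrix = pd.read_csv(path, sep="\t", index_col=0)
    return validate_binding_matrix(matrix)


def write_binding_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("gene_id").to_csv(path, sep="\t")


def read_qpcr_table(path) -> pd.DataFrame:
    """Read a 3C qPCR table: ``anchor_id fragment_id replicate quantity``."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["anchor_id", "fragment_id", "replicate", "quantity"],
                        dtype={"anchor_id": str, "fragment_id": str, "replicate": str})
    if (table["quantity"] < 0).any():
        raise ValidationError("negative qPCR quantity in table")
    return table


def read_bac_table(path) -> pd.Series:
    """Read BAC-control quantities: ``anchor_id fragment_id quantity``."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["anchor_id", "fragment_id", "quantity"],
                        dtype={"anchor_id": str, "fragment_id": str})
    return table.set_index(["anchor_id", "fragment_id"])["quantity"]


def read_fragments(path) -> dict[str, Interval]:
    """Read restriction fragments from BED4 (name column holds the fragment id)."""
    fragments = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise TrackParseError(path, lineno, "fragment BED needs 4 columns")
            fragments[fields[3]] = Interval(fields[0], int(fields[1]), int(fields[2]))
    return fragments


def sha256_of(path) -> str:
    import hashlib

    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()
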