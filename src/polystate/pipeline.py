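"""Config-driven orchestration: binding calls -> differential -> states -> reports.

The pipeline reads one YAML config naming the track files per factor and
condition plus the stage parameters, runs every applicable stage, and writes
plain-text tables (TSV/BED) together with a machine-readable run manifest
(parameters and SHA-256 checksums of every input).  Re-running with the same
inputs produces byte-identical outputs.

Config layout (all stage parameters optional, shown with defaults)::

    genes: genes.tsv                # TSV or GFF3
    expression: expression.tsv      # optional
    pres: pres.bed                  # optional PRE annotation
    tracks:
      cohesin: {control: cohesin_control.bedGraph,
                depleted: cohesin_depleted.bedGraph}
      H3K27me3: {control: k27_control.bedGraph}
    binding: {tau: 2.0, min_run: 3, min_span: 105}
    change: {k_sd: 2.0, min_run: 3, min_span: 105}
    states: {restrained_min_overlap: 2000,
             cohesin_factor: cohesin, pc_factor: Pc, k27_factor: H3K27me3}
    venn_factors: [cohesin, Pc, H3K27me3]
    promoter_width_change: 200
    promoter_width_pause: 400
    pause_factors: [Rpb3]           # factors to compute pause indices for
    elongation: {ser2p: Ser2P, rpb3: Rpb3}
    outdir: results/
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .differential import (
    PROMOTER_WIDTH_CHANGE,
    PROMOTER_WIDTH_PAUSE,
    ChangeCallParams,
    DifferentialOccupancy,
    elongation_ratio,
    pause_index,
)
from .errors import ConfigError, StageError
from .genome import GeneModel, ProbeTrack
from .occupancy import BindingCallParams, binding_matrix, call_bound_intervals, overlap_counts
from .states import StateParams, active_gene_mask, classify_states

logger = logging.getLogger("polystate")

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    genes: str
    tracks: dict[str, dict[str, str]]
    outdir: str
    expression: str | None = None
    pres: str | None = None
    binding: BindingCallParams = field(default_factory=lambda: BindingCallParams(tau=2.0))
    change: ChangeCallParams = field(default_factory=ChangeCallParams)
    states: StateParams = field(default_factory=StateParams)
    venn_factors: list[str] = field(default_factory=list)
    promoter_width_change: int = PROMOTER_WIDTH_CHANGE
    promoter_width_pause: int = PROMOTER_WIDTH_PAUSE
    pause_factors: list[str] = field(default_factory=list)
    elongation: dict[str, str] = field(default_factory=dict)
    track_format: str = "bedGraph"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str | Path = ".") -> "PipelineConfig":
        base = Path(base_dir)

        def resolve(p):
            return str(p) if os.path.isabs(str(p)) else str(base / str(p))

        try:
            tracks = {str(factor): {str(cond): resolve(path)
                                    for cond, path in conds.items()}
                      for factor, conds in raw["tracks"].items()}
            config = cls(
                genes=resolve(raw["genes"]),
                tracks=tracks,
                outdir=resolve(raw.get("outdir", "polystate_out")),
                expression=resolve(raw["expression"]) if raw.get("expression") else None,
                pres=resolve(raw["pres"]) if raw.get("pres") else None,
                binding=BindingCallParams(**raw.get("binding", {"tau": 2.0})),
                change=ChangeCallParams(**raw.get("change", {})),
                venn_factors=list(raw.get("venn_factors", [])),
                promoter_width_change=int(raw.get("promoter_width_change",
                                                  PROMOTER_WIDTH_CHANGE)),
                promoter_width_pause=int(raw.get("promoter_width_pause",
                                                 PROMOTER_WIDTH_PAUSE)),
                pause_factors=list(raw.get("pause_factors", [])),
                elongation=dict(raw.get("elongation", {})),
                track_format=raw.get("track_format", "bedGraph"),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc}") from None
        states_raw = dict(raw.get("states", {}))
        config.states = StateParams(**states_raw)
        for factor in config.venn_factors:
            if factor not in config.tracks:
                raise ConfigError(f"venn factor {factor!r} has no track entry")
        for role, factor in config.elongation.items():
            if factor not in config.tracks:
                raise ConfigError(f"elongation {role} factor {factor!r} has no track entry")
        for factor in config.pause_factors:
            if factor not in config.tracks:
                raise ConfigError(f"pause factor {factor!r} has no track entry")
        missing = [p for p in config._input_paths() if not os.path.exists(p)]
        if missing:
            raise ConfigError(f"input files not found: {missing}")
        return config

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    def _input_paths(self) -> list[str]:
        paths = [self.genes]
        if self.expression:
            paths.append(self.expression)
        if self.pres:
            paths.append(self.pres)
        for conds in self.tracks.values():
            paths.extend(conds.values())
        return paths


@dataclass
class PipelineReport:
    """In-memory bundle of everything the pipeline computed."""

    matrix: pd.DataFrame
    bound_intervals: dict[str, list]
    venn: object | None
    diff_results: dict[str, object]
    states: pd.DataFrame | None
    percentages: dict[str, pd.DataFrame]
    pause_tables: dict[str, pd.DataFrame]
    manifest: dict


def _write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage the config enables and write the report bundle."""
    os.makedirs(config.outdir, exist_ok=True)
    out = Path(config.outdir)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # --- inputs -----------------------------------------------------------
    name = stage("read_inputs")
    try:
        genes = io.read_genes(config.genes)
        expression = io.read_expression(config.expression) if config.expression else None
        pres = tuple(io.read_bed(config.pres)) if config.pres else ()
        control_tracks: dict[str, ProbeTrack] = {}
        depleted_tracks: dict[str, ProbeTrack] = {}
        for factor, conds in config.tracks.items():
            if "control" not in conds:
                raise ConfigError(f"factor {factor!r} has no control track")
            control_tracks[factor] = io.read_track(conds["control"], config.track_format)
            if "depleted" in conds:
                depleted_tracks[factor] = io.read_track(conds["depleted"],
                                                        config.track_format)
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- binding calls ----------------------------------------------------
    name = stage("binding_calls")
    try:
        bound: dict[str, list] = {}
        for factor, track in control_tracks.items():
            intervals = call_bound_intervals(track, config.binding)
            bound[factor] = intervals
            io.write_bed(intervals, out / f"bound_{factor}.bed")
        matrix = binding_matrix(bound, genes)
        io.write_binding_matrix(matrix, out / "binding_matrix.tsv")
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- venn overlap counts ---------------------------------------------
    name = stage("overlap_counts")
    venn = None
    try:
        if config.venn_factors:
            venn = overlap_counts(matrix, config.venn_factors)
            rows = [{"combination": "&".join(f for f, p in zip(venn.factors, pattern) if p)
                                    or "(none)",
                     "n_genes": count}
                    for pattern, count in sorted(venn.counts.items(), reverse=True)]
            _write_tsv(pd.DataFrame(rows).set_index("combination"), out / "venn_counts.tsv")
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- differential occupancy per depleted factor -----------------------
    name = stage("differential_occupancy")
    diff_results: dict[str, object] = {}
    try:
        for factor, depleted in depleted_tracks.items():
            model = DifferentialOccupancy(control_tracks[factor], depleted, genes,
                                          params=config.change,
                                          promoter_width=config.promoter_width_change)
            res = model.fit()
            diff_results[factor] = res
            logger.info("delta null for %s: median=%.4g sd=%.4g (n=%d)", factor,
                        res.null.median, res.null.sd, res.null.n)
            io.write_bed(res.intervals, out / f"change_{factor}.bed")
            _write_tsv(res.gene_classes, out / f"gene_classes_{factor}.tsv")
            _write_tsv(res.gene_deltas, out / f"gene_deltas_{factor}.tsv")
            with open(out / f"summary_{factor}.txt", "w") as handle:
                handle.write(res.summary() + "\n")
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- chromatin states -------------------------------------------------
    name = stage("chromatin_states")
    states_frame = None
    try:
        sp = config.states
        needed = {sp.cohesin_factor, sp.pc_factor, sp.k27_factor}
        if expression is not None and needed <= set(matrix.columns):
            if pres and not sp.pre_intervals:
                sp = StateParams(**{**sp.__dict__, "pre_intervals": pres})
            states_frame = classify_states(genes, matrix, bound, expression, sp)
            _write_tsv(states_frame, out / "states.tsv")
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- category percentage tables --------------------------------------
    name = stage("category_percentages")
    percentages: dict[str, pd.DataFrame] = {}
    try:
        groups: dict[str, pd.Series] = {"all": pd.Series(True, index=matrix.index)}
        for factor in config.venn_factors:
            groups[f"{factor}+"] = matrix[factor] == 1
            groups[f"{factor}-"] = matrix[factor] == 0
        if expression is not None and config.states.k27_factor in matrix.columns:
            active = active_gene_mask(matrix, expression, config.states)
            groups["active"] = active
            for factor in config.venn_factors:
                if factor != config.states.k27_factor:
                    groups[f"active:{factor}+"] = active & (matrix[factor] == 1)
                    groups[f"active:{factor}-"] = active & (matrix[factor] == 0)
        if states_frame is not None:
            for state in states_frame["state"].unique():
                groups[f"state:{state}"] = states_frame["state"] == state
        for factor, res in diff_results.items():
            for region in ("promoter", "body"):
                table = res.percentages(groups, region=region)
                percentages[f"{factor}:{region}"] = table
                _write_tsv(table, out / f"percent_{factor}_{region}.tsv")
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- pause index / elongation ratio distributions ---------------------
    name = stage("pausing_metrics")
    pause_tables: dict[str, pd.DataFrame] = {}
    try:
        for factor in config.pause_factors:
            rows = {}
            for condition, track in (("control", control_tracks.get(factor)),
                                     ("depleted", depleted_tracks.get(factor))):
                if track is None:
                    continue
                values = {}
                for gene in genes:
                    m = pause_index(track, gene, config.promoter_width_pause)
                    values[gene.gene_id] = m.value if m.status == "ok" else np.nan
                rows[f"pause_index_{condition}"] = pd.Series(values)
            if rows:
                table = pd.DataFrame(rows)
                table.index.name = "gene_id"
                pause_tables[factor] = table
                _write_tsv(table, out / f"pause_index_{factor}.tsv")
        if {"ser2p", "rpb3"} <= set(config.elongation):
            s_name, r_name = config.elongation["ser2p"], config.elongation["rpb3"]
            rows = {}
            for condition, pair in (
                    ("control", (control_tracks.get(s_name), control_tracks.get(r_name))),
                    ("depleted", (depleted_tracks.get(s_name), depleted_tracks.get(r_name)))):
                ser2p, rpb3 = pair
                if ser2p is None or rpb3 is None:
                    continue
                values = {}
                for gene in genes:
                    m = elongation_ratio(ser2p, rpb3, gene, config.promoter_width_pause)
                    values[gene.gene_id] = m.value if m.status == "ok" else np.nan
                rows[f"elongation_ratio_{condition}"] = pd.Series(values)
            if rows:
                table = pd.DataFrame(rows)
                table.index.name = "gene_id"
                pause_tables["elongation_ratio"] = table
                _write_tsv(table, out / "elongation_ratio.tsv")
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- manifest ---------------------------------------------------------
    name = stage("manifest")
    try:
        manifest = {
            "parameters": {
                "binding": config.binding.__dict__,
                "change": config.change.__dict__,
                "states": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in config.states.__dict__.items()
                           if k != "pre_intervals"},
                "promoter_width_change": config.promoter_width_change,
                "promoter_width_pause": config.promoter_width_pause,
            },
            "inputs": {path: io.sha256_of(path) for path in sorted(config._input_paths())},
            "null_diagnostics": {
                factor: {"median": res.null.median, "mean": res.null.mean,
                         "sd": res.null.sd, "n": res.null.n}
                for factor, res in sorted(diff_results.items())
            },
        }
        with open(out / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")
    except Exception as exc:
        raise StageError(name, exc) from exc

    return PipelineReport(matrix, bound, venn, diff_results, states_frame,
                          percentages, pause_tables, manifest)
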