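"""Config-driven pipeline runs with a reproducibility manifest.

A YAML run-config declares the stages (simulate, normalize, stats, evaluate)
and their parameters; :func:`run_from_config` executes them in order and
writes a ``manifest.json`` recording the full effective config (defaults
included), the package version, the seed, and a SHA-256 digest of every
input and output file — identical config + inputs give identical digests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError
from .genome import LocusSet
from .io import (
    read_chrom_sizes,
    read_coverage_bins,
    read_locus_set,
    write_bedgraph,
    write_locus_set,
)
from .normalize import ReplicateSet, RNConfig, run_rn_pipeline
from .simulate import (
    CONDITIONS,
    SimulationConfig,
    build_truth,
    evaluate_recovery,
    simulate_replicates,
)
from .stats import distribution_summary, mann_whitney_enrichment

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """What ran: effective config, seeds, factors, and file digests."""

    schema_version: int
    tool_version: str
    seed: int
    config: dict[str, Any]
    started: str
    finished: str = ""
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    scale_factors: dict[str, float] = field(default_factory=dict)
    background_values: dict[str, float] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _expect(cfg: dict, key: str, types, path: str, default=None, required=False):
    if key not in cfg:
        if required:
            raise SchemaError(f"missing required field: {path}.{key}")
        return default
    value = cfg[key]
    if types is not None and not isinstance(value, types):
        raise SchemaError(
            f"field {path}.{key}: expected {getattr(types, '__name__', types)}, "
            f"got {type(value).__name__}"
        )
    return value


def _check_unknown(cfg: dict, allowed: set[str], path: str) -> None:
    unknown = set(cfg) - allowed
    if unknown:
        raise SchemaError(f"unknown field(s) under {path}: {sorted(unknown)}")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and schema-validate a YAML run-config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("run config must be a YAML mapping")
    _check_unknown(
        cfg,
        {"schema_version", "seed", "out_dir", "genome", "simulate", "normalize",
         "stats", "evaluate"},
        "<root>",
    )
    version = _expect(cfg, "schema_version", int, "<root>", default=SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"schema_version {version} unsupported (this version reads {SCHEMA_VERSION})"
        )
    _expect(cfg, "seed", int, "<root>", default=0)
    _expect(cfg, "out_dir", str, "<root>", required=True)
    if "simulate" not in cfg and "normalize" not in cfg:
        raise SchemaError("config declares no stages (need simulate and/or normalize)")
    if "simulate" in cfg:
        sim = _expect(cfg, "simulate", dict, "<root>", required=True)
        _check_unknown(sim, {"conditions", "replicates", "config"}, "simulate")
        conds = _expect(sim, "conditions", list, "simulate",
                        default=["target_decoy", "decoy_only"])
        for c in conds:
            if c not in CONDITIONS:
                raise SchemaError(
                    f"simulate.conditions: unknown condition {c!r} "
                    f"(expected subset of {list(CONDITIONS)})"
                )
        _expect(sim, "replicates", int, "simulate", default=3)
        _expect(sim, "config", dict, "simulate", default={})
    if "normalize" in cfg:
        norm = cfg["normalize"]
        _check_unknown(
            norm,
            {"exp", "ctrl", "exp_files", "ctrl_files", "window", "percentile",
             "pseudocount", "control_floor", "keep_intermediates"},
            "normalize",
        )
        from_sim = "exp" in norm or "ctrl" in norm
        from_files = "exp_files" in norm or "ctrl_files" in norm
        if from_sim and from_files:
            raise SchemaError(
                "normalize: use exp/ctrl (simulated conditions) or "
                "exp_files/ctrl_files, not both"
            )
        if from_sim and "simulate" not in cfg:
            raise SchemaError("normalize.exp/ctrl name simulated conditions but "
                              "there is no simulate stage")
        if from_files:
            if "genome" not in cfg or "chrom_sizes" not in cfg.get("genome", {}):
                raise SchemaError(
                    "missing required field: genome.chrom_sizes "
                    "(needed to read coverage files)"
                )
        if not (from_sim or from_files):
            raise SchemaError("normalize: missing exp/ctrl or exp_files/ctrl_files")
    if "genome" in cfg:
        _check_unknown(cfg["genome"], {"chrom_sizes", "bin_size"}, "genome")
    if "stats" in cfg:
        _check_unknown(cfg["stats"], {"agg_bin", "loci"}, "stats")
    if "evaluate" in cfg:
        _check_unknown(cfg["evaluate"], {"alpha", "min_fold", "peak_threshold"},
                       "evaluate")
        if "simulate" not in cfg:
            raise SchemaError("evaluate stage requires a simulate stage (ground truth)")
    return cfg


def run_from_config(config_path: str | Path) -> RunManifest:
    """Execute the stages declared in a YAML run-config; returns the manifest."""
    cfg = load_config(config_path)
    seed = cfg.get("seed", 0)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        schema_version=SCHEMA_VERSION,
        tool_version=__version__,
        seed=seed,
        config=cfg,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.inputs[str(config_path)] = _sha256(Path(config_path))

    def emit(path: Path) -> None:
        manifest.outputs[path.name] = _sha256(path)

    truth = None
    sim_reps: dict[str, ReplicateSet] = {}
    if "simulate" in cfg:
        sim = cfg["simulate"]
        sim_config = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in sim.get("config", {}).items()
        })
        truth = build_truth(sim_config, seed=seed)
        for label, loci in truth.locus_sets().items():
            p = out_dir / f"truth_{label}.bed"
            write_locus_set(loci, p)
            emit(p)
        for cond in sim.get("conditions", ["target_decoy", "decoy_only"]):
            reps = simulate_replicates(
                truth, cond, n_replicates=sim.get("replicates", 3), seed=seed
            )
            sim_reps[cond] = reps
            for i, t in enumerate(reps):
                p = out_dir / f"sim_{cond}_rep{i + 1}.bedgraph"
                write_bedgraph(t, p)
                emit(p)

    rn_result = None
    if "normalize" in cfg:
        norm = cfg["normalize"]
        rn_cfg = RNConfig(
            smooth_window=norm.get("window", 500),
            background_percentile=norm.get("percentile", 20),
            pseudocount=norm.get("pseudocount", 0.01),
            control_floor=norm.get("control_floor", 0.1),
        )
        if "exp" in norm or "ctrl" in norm:
            exp_reps = sim_reps[norm.get("exp", "target_decoy")]
            ctrl_reps = sim_reps[norm.get("ctrl", "decoy_only")]
        else:
            genome = cfg["genome"]
            assembly = read_chrom_sizes(
                genome["chrom_sizes"], bin_size=genome.get("bin_size", 50)
            )
            for f in norm["exp_files"] + norm["ctrl_files"]:
                manifest.inputs[f] = _sha256(Path(f))
            exp_reps = ReplicateSet(
                [read_coverage_bins(f, assembly) for f in norm["exp_files"]]
            )
            ctrl_reps = ReplicateSet(
                [read_coverage_bins(f, assembly) for f in norm["ctrl_files"]]
            )
        rn_result = run_rn_pipeline(exp_reps, ctrl_reps, rn_cfg)
        manifest.scale_factors = rn_result.scale_factors
        manifest.background_values = rn_result.background_values
        p = out_dir / "rn.bedgraph"
        write_bedgraph(rn_result.rn, p)
        emit(p)
        if norm.get("keep_intermediates", False):
            for name, t in (("exp_avg", rn_result.exp_avg),
                            ("ctrl_avg", rn_result.ctrl_avg)):
                p = out_dir / f"{name}.bedgraph"
                write_bedgraph(t, p)
                emit(p)

    if "stats" in cfg and rn_result is not None:
        st = cfg["stats"]
        agg = st.get("agg_bin", 500)
        rows = []
        summary = distribution_summary(rn_result.rn, agg_bin=agg)
        rows.append({
            "set": "<genome>", "statistic": "outlier_fraction_high",
            "value": summary.outlier_fraction_high, "p_value": float("nan"),
            "direction": "", "n_set": summary.n_bins,
        })
        loci_sets: list[LocusSet] = []
        if truth is not None:
            loci_sets += [truth.artifact_loci, truth.true_sites]
        for f in st.get("loci", []):
            manifest.inputs[f] = _sha256(Path(f))
            loci_sets.append(read_locus_set(f, rn_result.rn.assembly))
        for loci in loci_sets:
            res = mann_whitney_enrichment(rn_result.rn, loci, agg_bin=agg)
            rows.append({
                "set": res.set_name, "statistic": "mann_whitney_U",
                "value": res.u_statistic, "p_value": res.p_value,
                "direction": res.direction, "n_set": res.n_set,
            })
        p = out_dir / "stats.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        emit(p)

    if "evaluate" in cfg and rn_result is not None and truth is not None:
        ev = cfg["evaluate"]
        kwargs = dict(
            alpha=ev.get("alpha", 0.01),
            min_fold=ev.get("min_fold", 1.5),
            peak_threshold=ev.get("peak_threshold", 2.0),
        )
        rec_rn = evaluate_recovery(rn_result.rn, truth, **kwargs)
        rec_raw = evaluate_recovery(rn_result.exp_avg, truth, **kwargs)
        manifest.metrics.update({
            "rn_artifact_removal_rate": rec_rn.artifact_removal_rate,
            "rn_true_site_retention": rec_rn.true_site_retention,
            "rn_peak_false_positive_rate": rec_rn.peak_false_positive_rate,
            "uncontrolled_artifact_removal_rate": rec_raw.artifact_removal_rate,
            "uncontrolled_true_site_retention": rec_raw.true_site_retention,
        })
        p = out_dir / "recovery.tsv"
        rec_rn.per_locus.to_csv(p, sep="\t", index=False)
        emit(p)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out_dir / "manifest.json")
    return manifest
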