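"""End-to-end orchestration from one YAML config.

Stages run in dependency order — simulate -> hotspots -> label -> rank ->
train -> screen — each stage writing its outputs under the configured
output directory.  A run manifest records the config, the per-stage seeds,
and a SHA-256 digest of every output file, so a run is reproducible (and
verifiably reproduced) from the manifest alone.  The single global seed is
fanned out to per-stage seeds by hashing ``"{seed}:{stage}"``, so toggling
one stage never perturbs another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .criteria import (BEST_WORST_THRESHOLDS, LabelThresholds, PoseRecord,
                       filter_and_count, label_best_worst, rank_molecules)
from .descriptors import DescriptorTable
from .errors import ConfigurationError, PPIScreenError
from .ise import ISEParams, cross_validate, enrichment_curve, score_table, select_cutoff
from .structures import EnergyParams, call_hot_spots, parse_complex, scan_interface
from .synthetic import LearningSetSpec, make_learning_set

log = logging.getLogger("ppiscreen")

_STAGE_ORDER = ("simulate", "hotspots", "label", "rank", "train", "screen")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _thresholds(cfg: dict) -> LabelThresholds:
    block = cfg.get("thresholds")
    return LabelThresholds(**block) if block else BEST_WORST_THRESHOLDS


def _read_records(path: Path) -> list[PoseRecord]:
    frame = pd.read_csv(path, comment="#")
    return [
        PoseRecord(str(r.molecule_id), float(r.docking_score),
                   int(r.vdw_contacts), float(r.bsa))
        for r in frame.itertuples()
    ]


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a YAML mapping")
    return config


def validate_config(config: dict) -> None:
    """Check stage names, the seed, and every referenced input path up front."""
    stages = config.get("stages", {})
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
    enabled = [s for s in _STAGE_ORDER if stages.get(s, {}).get("enabled")]
    if not enabled:
        raise ConfigurationError("no stage enabled")
    if "seed" not in config and any(s in ("simulate", "train") for s in enabled):
        raise ConfigurationError("a seed is required when stochastic stages run")
    for stage in enabled:
        for key in ("pdb", "records", "table", "labels"):
            path = stages[stage].get(key)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"stage {stage}: input {key}={path!r} not found")
    if ("train" in enabled and stages["train"].get("table") is None
            and "simulate" not in enabled):
        raise ConfigurationError("train needs a table or an enabled simulate stage")


def run_pipeline(config: dict) -> dict:
    """Execute enabled stages; return (and write) the run manifest."""
    validate_config(config)
    out_dir = Path(config.get("output_dir", "ppiscreen_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {})
    seed = int(config.get("seed", 0))
    manifest: dict = {"version": __version__, "seed": seed, "config": config,
                      "stages": [], "outputs": {}}
    state: dict = {}

    def emit(name: str, text: str) -> Path:
        path = out_dir / name
        path.write_text(text)
        manifest["outputs"][name] = _sha256(path)
        return path

    for stage in _STAGE_ORDER:
        cfg = stages.get(stage, {})
        if not cfg.get("enabled"):
            continue
        sseed = stage_seed(seed, stage)
        log.info("stage %s (seed %d)", stage, sseed)
        try:
            if stage == "simulate":
                spec = LearningSetSpec(
                    n_best=cfg.get("n_best", 68),
                    n_worst=cfg.get("n_worst", 69),
                    n_descriptors=cfg.get("n_descriptors", 50),
                    n_informative=cfg.get("n_informative", 3),
                    effect_size=cfg.get("effect_size", 2.0),
                    seed=sseed,
                )
                table, informative = make_learning_set(spec)
                state["table"] = table
                frame = table.values.copy()
                frame.insert(0, "label", table.labels)
                emit("learning_set.csv", frame.to_csv(index_label="molecule_id"))
                emit("learning_set_truth.json", json.dumps(
                    {"informative_descriptors": informative,
                     "n_best": spec.n_best, "n_worst": spec.n_worst}, indent=1))
            elif stage == "hotspots":
                text = Path(cfg["pdb"]).read_text()
                complex_ = parse_complex(text, cfg["receptor_chains"],
                                         cfg["partner_chains"])
                params = EnergyParams(
                    hot_spot_threshold=cfg.get("threshold", 4.0))
                scan = scan_interface(complex_, params,
                                      cfg.get("interface_cutoff", 4.5))
                hot = set(call_hot_spots(scan, params.hot_spot_threshold))
                rows = ["chain,resnum,resname,delta_affinity,is_hot_spot"]
                rows += [f"{r.residue[0]},{r.residue[1]},{r.residue[2]},"
                         f"{r.delta_affinity:.6f},{r.residue in hot}"
                         for r in scan]
                emit("hotspots.csv", "\n".join(rows) + "\n")
                state["hot_spots"] = sorted(hot)
            elif stage == "label":
                records = _read_records(Path(cfg["records"]))
                thr = _thresholds(cfg)
                rows = ["molecule_id,docking_score,vdw_contacts,bsa,label"]
                rows += [f"{r.molecule_id},{r.docking_score},{r.vdw_contacts},"
                         f"{r.bsa},{label_best_worst(r, thr)}" for r in records]
                emit("labels.csv", "\n".join(rows) + "\n")
                state["label_counts"] = filter_and_count(records, thr)
            elif stage == "rank":
                records = _read_records(Path(cfg["records"]))
                ranked = rank_molecules(records)
                top = cfg.get("top") or len(ranked)
                rows = ["rank,molecule_id,docking_score,vdw_contacts,bsa"]
                rows += [f"{i},{r.molecule_id},{r.docking_score},"
                         f"{r.vdw_contacts},{r.bsa}"
                         for i, r in enumerate(ranked[:top], 1)]
                emit("ranking.csv", "\n".join(rows) + "\n")
            elif stage == "train":
                table = state.get("table")
                if cfg.get("table"):
                    frame = pd.read_csv(cfg["table"], index_col=0, comment="#")
                    labels = frame.pop("label")
                    table = DescriptorTable(values=frame, labels=labels)
                params = ISEParams(**cfg.get("params", {}))
                result = cross_validate(table, cfg.get("k", 5), params, sseed)
                state["cv"] = result
                state["table"] = table
                emit("model.json", result.final_model.to_json())
                emit("cv_scores.csv", result.scores.to_csv(index_label="molecule_id"))
            elif stage == "screen":
                result = state.get("cv")
                if result is None:
                    raise ConfigurationError("screen stage requires a trained model")
                curve = enrichment_curve(result.scores["index"],
                                         result.scores["label"])
                cutoff = cfg.get("cutoff")
                if cutoff is None:
                    cutoff = select_cutoff(curve, cfg.get("min_ratio", 3.0))
                rows = ["threshold,tp,fp,ratio"]
                rows += [f"{t:.6f},{tp},{fp},{'inf' if fp == 0 else f'{tp / fp:.4f}'}"
                         for t, tp, fp in zip(curve.thresholds, curve.tp, curve.fp)]
                emit("enrichment.csv", "\n".join(rows) + "\n")
                scored = score_table(result.final_model, state["table"].values)
                hits = scored[scored["index"] >= cutoff]
                emit("screen_hits.csv", hits.to_csv(index_label="molecule_id"))
                state["cutoff"] = cutoff
                state["n_hits"] = int(len(hits))
            manifest["stages"].append({"name": stage, "seed": sseed,
                                       "params": cfg})
        except PPIScreenError as exc:
            manifest["stages"].append({"name": stage, "seed": sseed,
                                       "failed": str(exc)})
            emit("manifest.json", json.dumps(manifest, indent=1, sort_keys=True,
                                             default=str))
            raise PPIScreenError(f"stage {stage!r} failed: {exc}") from exc

    for key in ("hot_spots", "label_counts", "cutoff", "n_hits"):
        if key in state:
            manifest[key] = state[key]
    emit("manifest.json", json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest
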