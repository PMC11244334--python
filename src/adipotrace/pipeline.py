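"""End-to-end run orchestration: simulate -> segment -> gate -> summarize -> stats -> model.

A run is described by a single :class:`RunConfig` (usually loaded from YAML).
One global seed fans out to per-field child seeds through
``numpy.random.SeedSequence``, so identical config + seed reproduces every
output byte-for-byte, and each stage can be re-run independently.  A
:class:`RunManifest` (config hash, software version, per-stage file lists,
timestamps) is written even when a stage fails part-way.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from .io import (
    read_field_from_paths,
    write_field,
    write_ground_truth,
    write_json,
    write_label_map,
    write_records,
    write_summaries,
)
from .popmodel import PopulationModelParams, simulate_composition, sweep_doubling_times
from .quantify import (
    GateConfig,
    gate_cells,
    suggest_cutoff,
    summarize_wells,
    timecourse_table,
    two_sample_t_test,
)
from .segmentation import (
    CHANNEL_ROLES,
    FieldImage,
    FieldMetadata,
    SegmentationParams,
    measure_nuclei,
    segment_nuclei,
)
from .simulate import DesignEntry, SimulationConfig, simulate_field

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "StageError", "run_pipeline", "config_hash"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to (re)produce one pipeline run.

    ``simulate`` holds a base :class:`SimulationConfig` override dict and a
    design list (well / timepoint_h / condition / n_fields / overrides).  When
    ``input_fields`` is given instead, the simulate stage is skipped and each
    entry must map every channel role to a TIFF path.  Exactly one
    :class:`GateConfig` applies to the whole run.
    """

    outdir: str
    seed: int = 0
    simulate: dict[str, Any] = field(default_factory=dict)
    input_fields: Optional[list[dict[str, Any]]] = None
    segmentation: dict[str, Any] = field(default_factory=dict)
    gate: dict[str, Any] = field(default_factory=dict)
    model: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def config_hash(config: RunConfig) -> str:
    """SHA-256 over the canonical JSON form of the config.

    Semantically identical configs hash equal; any parameter change changes
    the hash.
    """
    canonical = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one run."""

    config_hash: str
    version: str
    seed: int
    started: str
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    finished: Optional[str] = None
    failed_stage: Optional[str] = None

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def _child_seed(seq: np.random.SeedSequence) -> int:
    # keep derived seeds in the signed-31-bit range for portability
    return int(seq.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _build_design(config: RunConfig) -> list[DesignEntry]:
    sim_spec = dict(config.simulate)
    base = dict(sim_spec.get("base", {}))
    design_spec = sim_spec.get(
        "design", [{"well": "A1", "timepoint_h": 0.0, "condition": "control"}]
    )
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(design_spec))
    entries = []
    for spec, child in zip(design_spec, children):
        spec = dict(spec)
        overrides = dict(spec.pop("overrides", {}))
        n_fields = int(spec.pop("n_fields", 1))
        cfg_kwargs = {**base, **overrides, "seed": _child_seed(child)}
        entries.append(
            DesignEntry(
                well=str(spec["well"]),
                timepoint_h=float(spec.get("timepoint_h", 0.0)),
                condition=str(spec.get("condition", "control")),
                config=SimulationConfig(**cfg_kwargs),
                n_fields=n_fields,
            )
        )
    return entries


def _load_input_fields(config: RunConfig) -> list[FieldImage]:
    fields = []
    for entry in config.input_fields or []:
        paths = entry.get("paths", {})
        missing = [r for r in CHANNEL_ROLES if r not in paths]
        if missing:
            raise ValueError(
                f"input field {entry.get('well', '?')} is missing channel "
                f"role(s) {missing}; required roles are {list(CHANNEL_ROLES)}"
            )
        md = FieldMetadata(
            well=str(entry.get("well", "A1")),
            field=str(entry.get("field", "f0")),
            timepoint_h=float(entry.get("timepoint_h", 0.0)),
            condition=str(entry.get("condition", "control")),
        )
        fields.append(read_field_from_paths(paths, md))
    return fields


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; returns the manifest (also written to the outdir).

    Stage order: simulate (skipped when ``input_fields`` is set) -> segment ->
    gate -> summarize -> stats -> model.  On failure the partial manifest is
    written before a :class:`StageError` propagates.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config),
        version=__version__,
        seed=config.seed,
        started=_now(),
    )
    current_stage = "setup"

    def record_stage(name: str, inputs: list[str], outputs: list[str], t0: float):
        manifest.stages[name] = {
            "inputs": inputs,
            "outputs": outputs,
            "n_inputs": len(inputs),
            "n_outputs": len(outputs),
            "elapsed_s": round(time.time() - t0, 3),
        }
        logger.info(
            "stage %s: %d inputs -> %d outputs (%.2fs)",
            name, len(inputs), len(outputs), time.time() - t0,
        )

    try:
        # validate input role maps before any computation
        if config.input_fields is not None:
            current_stage = "validate_inputs"
            for entry in config.input_fields:
                missing = [r for r in CHANNEL_ROLES if r not in entry.get("paths", {})]
                if missing:
                    raise ValueError(
                        f"input field {entry.get('well', '?')}: missing channel "
                        f"role(s) {missing}"
                    )

        # ---- simulate ---------------------------------------------------
        fields: list[FieldImage] = []
        if config.input_fields is None:
            current_stage = "simulate"
            t0 = time.time()
            fields_dir = outdir / "fields"
            fields_dir.mkdir(exist_ok=True)
            outputs = []
            for entry in _build_design(config):
                children = np.random.SeedSequence(entry.config.seed).spawn(entry.n_fields)
                for i, child in enumerate(children):
                    md = FieldMetadata(
                        well=entry.well,
                        field=f"f{i}",
                        timepoint_h=entry.timepoint_h,
                        condition=entry.condition,
                    )
                    fimg, truth = simulate_field(
                        entry.config, md, rng=np.random.default_rng(child)
                    )
                    stem = f"{entry.well}_t{entry.timepoint_h:g}_{md.field}"
                    outputs.append(str(write_field(fimg, fields_dir / f"{stem}.tif")))
                    lp, cp = write_ground_truth(truth, fields_dir / stem)
                    outputs.extend([str(lp), str(cp)])
                    fields.append(fimg)
            record_stage("simulate", [], outputs, t0)
        else:
            current_stage = "load_inputs"
            t0 = time.time()
            fields = _load_input_fields(config)
            record_stage(
                "load_inputs",
                [str(p) for e in config.input_fields for p in e["paths"].values()],
                [],
                t0,
            )

        # ---- segment + measure ------------------------------------------
        current_stage = "segment"
        t0 = time.time()
        params = SegmentationParams(**config.segmentation)
        labels_dir = outdir / "labels"
        labels_dir.mkdir(exist_ok=True)
        records = []
        outputs = []
        for fimg in fields:
            labels = segment_nuclei(fimg.channel("nuclear"), params)
            md = fimg.metadata
            stem = f"{md.well}_t{md.timepoint_h:g}_{md.field}"
            outputs.append(str(write_label_map(labels, labels_dir / f"{stem}_labels.tif")))
            recs = measure_nuclei(labels, fimg)
            # nucleus ids are per-field; qualify with the field for uniqueness
            records.extend(recs)
        records_path = outdir / "nuclei.csv"
        write_records(records, records_path)
        outputs.append(str(records_path))
        record_stage("segment", [], outputs, t0)

        # ---- gate --------------------------------------------------------
        current_stage = "gate"
        t0 = time.time()
        gate_spec = dict(config.gate)
        mode = gate_spec.pop("mode", "manual")
        if mode in ("auto_log_valley", "auto_otsu"):
            ratio_cut = suggest_cutoff([r.ratio for r in records], method=mode)
            marker_cut = suggest_cutoff(
                [r.integrated_marker for r in records if r.integrated_marker > 0],
                method=mode,
            )
            gate = GateConfig(
                gfp_ratio_cutoff=ratio_cut, marker_cutoff=marker_cut, provenance=mode
            )
            logger.info(
                "auto gate (%s): gfp_ratio_cutoff=%.4g marker_cutoff=%.4g",
                mode, ratio_cut, marker_cut,
            )
        else:
            gate = GateConfig(provenance="manual", **gate_spec)
        gated = gate_cells(records, gate)
        gated_path = outdir / "nuclei_gated.csv"
        write_records(gated, gated_path)
        gate_path = write_json(dataclasses.asdict(gate), outdir / "gate.json")
        record_stage("gate", [str(records_path)], [str(gated_path), str(gate_path)], t0)

        # ---- summarize ---------------------------------------------------
        current_stage = "summarize"
        t0 = time.time()
        summaries = summarize_wells(gated)
        summaries_path = write_summaries(summaries, outdir / "well_summaries.csv")
        record_stage("summarize", [str(gated_path)], [str(summaries_path)], t0)

        # ---- stats -------------------------------------------------------
        current_stage = "stats"
        t0 = time.time()
        tc = timecourse_table(summaries)
        tc_path = outdir / "timecourse.csv"
        tc.to_csv(tc_path, index=False)
        tests = []
        for tp, cond in sorted({(s.timepoint_h, s.condition) for s in summaries}):
            pos = [
                s.pct_marker_in_gfp_pos for s in summaries
                if s.timepoint_h == tp and s.condition == cond
                and s.pct_marker_in_gfp_pos is not None
            ]
            neg = [
                s.pct_marker_in_gfp_neg for s in summaries
                if s.timepoint_h == tp and s.condition == cond
                and s.pct_marker_in_gfp_neg is not None
            ]
            if len(pos) >= 2 and len(neg) >= 2:
                res = two_sample_t_test(pos, neg)
                tests.append(
                    {
                        "timepoint_h": tp,
                        "condition": cond,
                        "comparison": "pct_marker gfp_pos vs gfp_neg",
                        **dataclasses.asdict(res),
                    }
                )
        stats_path = write_json(tests, outdir / "stats.json")
        record_stage("stats", [str(summaries_path)], [str(tc_path), str(stats_path)], t0)

        # ---- model -------------------------------------------------------
        current_stage = "model"
        t0 = time.time()
        model_spec = dict(config.model)
        division_times = model_spec.pop("division_times", [12.0, 24.0, 48.0, 72.0, 96.0])
        f0 = model_spec.pop("f0", None)
        if f0 is not None:
            model_spec.setdefault("other_0", f0)
            model_spec.setdefault("adipocyte_0", 1.0 - f0)
        params_model = PopulationModelParams(**model_spec)
        traj = simulate_composition(params_model)
        traj_path = outdir / "composition_trajectory.csv"
        traj.to_frame().to_csv(traj_path, index=False)
        sweep = sweep_doubling_times(
            division_times,
            f0=params_model.initial_fraction,
            survival=params_model.survival,
            n_days=params_model.n_days,
        )
        sweep_path = outdir / "doubling_time_sweep.csv"
        sweep.to_csv(sweep_path, index=False)
        record_stage("model", [], [str(traj_path), str(sweep_path)], t0)

        manifest.finished = _now()
        return manifest
    except Exception as exc:
        manifest.failed_stage = current_stage
        manifest.finished = _now()
        raise StageError(current_stage, exc) from exc
    finally:
        write_json(manifest.to_dict(), outdir / "manifest.json")
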