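"""End-to-end pipeline: simulate or ingest -> detect -> features -> reports.

A single PipelineConfig drives the whole run. All randomness flows from one
master seed through named, stage-scoped substreams (SeedSequence spawn keyed
by stage name), so a run is byte-reproducible while stages stay isolated. The
run manifest records the package version, a hash of the effective config, the
seeds used, and the path of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from meaburst import __version__
from meaburst.distributions import (
    basal_exceedance_threshold,
    exceedance_fraction,
    pool_durations,
)
from meaburst.electrode_bursts import ElectrodeBurstParams, detect_electrode_bursts
from meaburst.features import DEFAULT_CATALOGUE, FeatureCatalogue, aggregate_table
from meaburst.fingerprint import FingerprintConfig, fingerprint
from meaburst.network_bursts import (
    NetworkBurstParams,
    classify_fragmented,
    detect_network_bursts,
)
from meaburst.spike_io import SpikeRecording, read_spike_table
from meaburst.synthetic import SimulationConfig, simulate_plate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "detect_all"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    ``mode`` is ``simulate`` (groups of SimulationConfigs) or ``ingest`` (a
    canonical spike CSV). Analysis toggles switch the fingerprint and
    distribution stages on or off.
    """

    mode: str = "simulate"  # simulate | ingest
    spike_table: str | None = None  # ingest mode
    groups: dict[str, SimulationConfig] = field(default_factory=dict)  # simulate mode
    wells_per_group: int = 4
    electrode_params: ElectrodeBurstParams = field(default_factory=ElectrodeBurstParams)
    network_params: NetworkBurstParams = field(default_factory=NetworkBurstParams)
    catalogue: FeatureCatalogue = field(default_factory=lambda: DEFAULT_CATALOGUE)
    fingerprint_config: FingerprintConfig = field(default_factory=FingerprintConfig)
    run_fingerprint: bool = True
    run_distributions: bool = True
    out_dir: str = "meaburst_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest" and not self.spike_table:
            raise ValueError("ingest mode requires spike_table")
        if self.mode == "ingest" and not Path(self.spike_table).exists():
            raise FileNotFoundError(self.spike_table)
        if self.mode == "simulate" and not self.groups:
            raise ValueError("simulate mode requires at least one group")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        groups = {
            name: SimulationConfig(**params)
            for name, params in (raw.pop("groups", {}) or {}).items()
        }
        eb = ElectrodeBurstParams(**raw.pop("electrode_params", {}))
        nb = NetworkBurstParams(**raw.pop("network_params", {}))
        fp = FingerprintConfig(**raw.pop("fingerprint_config", {}))
        cat_names = raw.pop("catalogue", None)
        cat = FeatureCatalogue(tuple(cat_names)) if cat_names else DEFAULT_CATALOGUE
        return cls(groups=groups, electrode_params=eb, network_params=nb,
                   fingerprint_config=fp, catalogue=cat, **raw)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (set, frozenset, tuple)):
                return sorted(map(str, o)) if isinstance(o, (set, frozenset)) else list(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = int(hashlib.sha256(f"{master}:{stage}".encode()).hexdigest(), 16)
    return h % (2**31)


def detect_all(
    recordings: list[SpikeRecording],
    electrode_params: ElectrodeBurstParams,
    network_params: NetworkBurstParams,
) -> list[tuple[SpikeRecording, dict, list]]:
    """Run both detectors on every well.

    Wells where network-burst detection is impossible (entirely silent) get an
    empty burst list with a log note rather than aborting the plate.
    """
    out = []
    for rec in recordings:
        ebursts = {
            e: detect_electrode_bursts(rec.spike_times[e], electrode_params, electrode=e)
            for e in rec.electrode_ids
        }
        try:
            nbursts = classify_fragmented(
                detect_network_bursts(rec, network_params), network_params
            )
        except ValueError as exc:
            logger.info("well %s: no network bursts (%s)", rec.well_id, exc)
            nbursts = []
        out.append((rec, ebursts, nbursts))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    Outputs written to ``config.out_dir``: electrode_bursts.csv,
    network_bursts.csv, features.csv, loadings.csv / explained_variance.csv /
    embedding.csv / selected_parameters.json when fingerprinting runs,
    durations.csv / exceedance_report.json when the distribution stage runs,
    and run_manifest.json with full provenance.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _stage(name: str):
        logger.info("pipeline stage: %s", name)

    # ---- acquire recordings ---------------------------------------------
    _stage("input")
    try:
        if config.mode == "simulate":
            recordings, _truths = simulate_plate(
                config.groups, config.wells_per_group,
                seed=_stage_seed(config.seed, "simulate"),
            )
        else:
            recordings = read_spike_table(config.spike_table)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'input' failed: {exc}") from exc

    # ---- detection -------------------------------------------------------
    _stage("detection")
    try:
        detections = detect_all(recordings, config.electrode_params, config.network_params)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'detection' failed: {exc}") from exc

    eb_rows = [
        {"well_id": rec.well_id, "electrode_id": e, "start_s": b.start,
         "end_s": b.end, "n_spikes": b.spike_count}
        for rec, ebursts, _ in detections
        for e, blist in ebursts.items()
        for b in blist
    ]
    eb_path = out_dir / "electrode_bursts.csv"
    pd.DataFrame(eb_rows, columns=["well_id", "electrode_id", "start_s", "end_s",
                                   "n_spikes"]).to_csv(eb_path, index=False)
    outputs["electrode_bursts"] = str(eb_path)

    nb_rows = [
        {"well_id": rec.well_id, "start_s": b.start, "end_s": b.end, "class": b.klass,
         "anchor_index": b.anchor if b.anchor is not None else "",
         "n_participating": len(b.participating_electrodes)}
        for rec, _, nbursts in detections
        for b in nbursts
    ]
    nb_path = out_dir / "network_bursts.csv"
    pd.DataFrame(nb_rows, columns=["well_id", "start_s", "end_s", "class",
                                   "anchor_index", "n_participating"]).to_csv(nb_path, index=False)
    outputs["network_bursts"] = str(nb_path)

    # ---- features --------------------------------------------------------
    _stage("features")
    try:
        table = aggregate_table(detections, config.catalogue)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'features' failed: {exc}") from exc
    feat_path = out_dir / "features.csv"
    table.to_csv(feat_path, index=False)
    outputs["features"] = str(feat_path)

    # ---- fingerprint -----------------------------------------------------
    if config.run_fingerprint:
        _stage("fingerprint")
        try:
            fp_cfg = dataclasses.replace(
                config.fingerprint_config, seed=_stage_seed(config.seed, "fingerprint")
            )
            result = fingerprint(table[list(config.catalogue.names)], fp_cfg)
        except ValueError as exc:
            logger.warning("fingerprint stage skipped: %s", exc)
            result = None
        if result is not None:
            n_pcs = result.loadings.shape[1]
            pc_names = [f"PC{i + 1}" for i in range(n_pcs)]
            load_path = out_dir / "loadings.csv"
            pd.DataFrame(result.loadings, index=result.parameters,
                         columns=pc_names).to_csv(load_path, index_label="parameter")
            outputs["loadings"] = str(load_path)
            ev_path = out_dir / "explained_variance.csv"
            pd.DataFrame({"pc": pc_names,
                          "explained_variance_ratio": result.explained_variance_ratio}
                         ).to_csv(ev_path, index=False)
            outputs["explained_variance"] = str(ev_path)
            if result.embedding is not None:
                emb_path = out_dir / "embedding.csv"
                pd.DataFrame(result.embedding, columns=["umap1", "umap2"]
                             ).to_csv(emb_path, index=False)
                outputs["embedding"] = str(emb_path)
            sel_path = out_dir / "selected_parameters.json"
            with open(sel_path, "w") as fh:
                json.dump({"retained_pcs": [f"PC{i + 1}" for i in result.retained_pcs],
                           "variable": sorted(result.variable_set),
                           "stable": sorted(result.stable_set),
                           "exclusive_stable": sorted(result.stable_set - result.variable_set)},
                          fh, indent=2)
            outputs["selected_parameters"] = str(sel_path)

    # ---- duration distributions -----------------------------------------
    if config.run_distributions:
        _stage("distributions")
        groups = sorted({rec.metadata.get("group") for rec, _, _ in detections
                         if rec.metadata.get("group") is not None}) or [None]
        det_pairs = [(rec, nb) for rec, _, nb in detections]
        dur_rows = []
        samples = {}
        for g in groups:
            if g is None:
                durs = np.array([b.duration for _, nb in det_pairs for b in nb
                                 if b.klass == "main"])
                label = "all"
            else:
                sample = pool_durations(det_pairs, g)
                durs, label = sample.durations, g
            samples[label] = durs
            dur_rows.extend({"group": label, "condition": "basal", "duration_s": d}
                            for d in durs)
        dur_path = out_dir / "durations.csv"
        pd.DataFrame(dur_rows, columns=["group", "condition", "duration_s"]
                     ).to_csv(dur_path, index=False)
        outputs["durations"] = str(dur_path)

        nonempty = {g: d for g, d in samples.items() if d.size}
        report: dict[str, object] = {}
        if nonempty:
            thr = basal_exceedance_threshold(nonempty)
            report = {"threshold_s": thr,
                      "basal_exceedance_pct": {g: exceedance_fraction(d, thr)
                                               for g, d in nonempty.items()}}
        exc_path = out_dir / "exceedance_report.json"
        with open(exc_path, "w") as fh:
            json.dump(report, fh, indent=2)
        outputs["exceedance_report"] = str(exc_path)

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in ("simulate", "fingerprint")},
        "n_wells": len(recordings),
        "outputs": outputs,
    }
    man_path = out_dir / "run_manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest_path"] = str(man_path)
    return manifest
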