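"""Config-driven orchestration: profile → distances → cross-link prediction →
concordance → comparison/clustering, with machine-readable reports.

A single :class:`RunConfig` (usually loaded from YAML) names the input
structures per conformational state and the analysis parameters; every stage
writes TSV/JSON artifacts under the output directory and the final
:class:`RunReport` collects the per-stage summaries together with a
provenance block (config hash, package version, seed).  Outputs carry no
timestamps, so re-running an identical config reproduces byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crosslink_model import (
    calls_to_frame,
    concordance,
    default_panel,
    predict_pair,
    read_observations_tsv,
    read_panel_tsv,
)
from .distance_analysis import pair_distances, read_pairs_tsv, write_distances_tsv
from .model_compare import (
    CorrespondenceMap,
    align_and_rmsd,
    cluster_frames,
    detect_equilibration,
    rmsd_timeseries,
)
from .pore_profile import (
    ConductanceCriteria,
    ProfileParams,
    ensemble_profile,
    profile_summary,
    write_profile_tsv,
)
from .structure_io import SegmentMap, read_structure

__all__ = ["RunConfig", "RunReport", "ConfigError", "run_pipeline", "load_config"]

log = logging.getLogger("porexlink")


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every problem found."""


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    ``structures`` maps a state label (e.g. OWF/IWF) to a multi-model PDB
    path.  Optional inputs (pair list, panel, observations, segment map)
    switch their stages on.
    """

    structures: dict  # state -> pdb path
    output_dir: str
    segment_map: str | None = None
    pairs: str | None = None
    panel: str | None = None
    observations: str | None = None
    seed: int = 0
    z_step: float = 0.5
    conductance_window: tuple | None = None
    cluster_threshold: float = 2.0
    cluster_selection: str = "backbone"
    equilibration_window: int = 20
    equilibration_slope_tol: float = 0.02
    use_min_distance: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        problems = []
        if not self.structures:
            problems.append("no input structures given")
        for state, path in self.structures.items():
            if not Path(path).is_file():
                problems.append(f"structure for state {state!r} not found: {path}")
        for name in ("segment_map", "pairs", "panel", "observations"):
            path = getattr(self, name)
            if path is not None and not Path(path).is_file():
                problems.append(f"{name} file not found: {path}")
        if self.z_step <= 0:
            problems.append("z_step must be positive")
        if self.cluster_threshold <= 0:
            problems.append("cluster_threshold must be positive")
        if problems:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "conductance_window" in raw and raw["conductance_window"] is not None:
        raw["conductance_window"] = tuple(raw["conductance_window"])
    return RunConfig(**raw)


@dataclass
class RunReport:
    profiles: dict = field(default_factory=dict)  # state -> summary dict
    distances: dict = field(default_factory=dict)  # state -> tidy records
    calls: list = field(default_factory=list)
    concordance: dict | None = None
    comparison: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    equilibration: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage the configuration enables; see the module docstring.

    Missing optional inputs skip their dependent stages with a logged
    reason; hard failures (unreadable structures, invalid config) raise.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": asdict(config),
    }

    segmap = SegmentMap.from_yaml(config.segment_map) if config.segment_map else None
    ensembles = {state: read_structure(path) for state, path in config.structures.items()}

    # ---- stage 1: pore profiles ------------------------------------------
    criteria = ConductanceCriteria()
    for state, ens in ensembles.items():
        log.info("profiling state %s (%d frames)", state, ens.n_frames)
        params = ProfileParams(z_step=config.z_step, seed=config.seed)
        prof = ensemble_profile(ens, params, segment_map=segmap)
        write_profile_tsv(prof, out / f"profile_{state}.tsv")
        summary = profile_summary(prof, criteria, config.conductance_window)
        report.profiles[state] = summary
        (out / f"profile_{state}.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    # ---- stage 2: pair distances -----------------------------------------
    series_by_pair: dict = {}
    if config.pairs:
        pairs = read_pairs_tsv(config.pairs)
        all_series = []
        for state, ens in ensembles.items():
            series = pair_distances(ens, pairs, state=state)
            all_series.extend(series)
            for s in series:
                series_by_pair.setdefault(s.pair.id, {})[state] = s
        df = write_distances_tsv(all_series, out / "distances.tsv")
        report.distances = df.to_dict(orient="records")
    else:
        report.skipped.append(("distances", "no pair list configured"))

    # ---- stage 3: cross-link prediction + concordance --------------------
    if series_by_pair:
        panel = read_panel_tsv(config.panel) if config.panel else default_panel()
        predictions = [
            predict_pair(by_state, panel, use_min=config.use_min_distance)
            for by_state in series_by_pair.values()
        ]
        calls = calls_to_frame(predictions)
        calls.to_csv(out / "crosslink_calls.tsv", sep="\t", index=False)
        report.calls = calls.to_dict(orient="records")
        if config.observations:
            obs = read_observations_tsv(config.observations)
            summary = concordance(predictions, obs)
            report.concordance = {
                "n_tested": summary["n_tested"],
                "n_concordant": summary["n_concordant"],
                "concordance": summary["concordance"],
                "per_reagent_confusion": summary["per_reagent_confusion"],
            }
            summary["per_pair"].to_csv(out / "concordance.tsv", sep="\t", index=False)
            (out / "concordance.json").write_text(
                json.dumps(report.concordance, indent=2, sort_keys=True)
            )
        else:
            report.skipped.append(("concordance", "no observation table configured"))
    elif config.pairs:
        report.skipped.append(("crosslink", "distance stage produced nothing"))
    else:
        report.skipped.append(("crosslink", "no pair list configured"))

    # ---- stage 4: comparison / equilibration / clustering ----------------
    states = list(ensembles)
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            a, b = states[i], states[j]
            cmap = CorrespondenceMap.from_structures(ensembles[a], ensembles[b])
            sup = align_and_rmsd(ensembles[a], ensembles[b], cmap)
            report.comparison[f"{a}_vs_{b}"] = {
                "rmsd": sup.rmsd,
                "n_atoms": sup.n_atoms,
                "coverage": sup.coverage,
            }
    for state, ens in ensembles.items():
        if ens.n_frames >= 2:
            series = rmsd_timeseries(ens, "first-frame", selection="CA")
            pd.DataFrame({"frame": series.frame_labels, "rmsd": series.rmsd}).to_csv(
                out / f"rmsd_{state}.tsv", sep="\t", index=False
            )
            if config.equilibration_window < ens.n_frames:
                onset = detect_equilibration(
                    series,
                    window=config.equilibration_window,
                    slope_tol=config.equilibration_slope_tol,
                )
                report.equilibration[state] = onset
            clusters = cluster_frames(
                ens, threshold=config.cluster_threshold, selection=config.cluster_selection
            )
            pd.DataFrame(
                {"frame": ens.frame_labels, "cluster": clusters.assignment}
            ).to_csv(out / f"clusters_{state}.tsv", sep="\t", index=False)
            report.clustering[state] = {
                "n_clusters": clusters.n_clusters,
                "centroids": clusters.centroids,
            }
        else:
            report.skipped.append((f"ensemble_analysis[{state}]", "single frame"))

    (out / "report.json").write_text(
        json.dumps(_jsonable(asdict(report)), indent=2, sort_keys=True)
    )
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
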