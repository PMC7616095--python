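"""End-to-end orchestration: simulate -> encode -> firing stats -> cluster
-> photometry -> distributional TD, with validated configuration, per-stage
timing, and a reproducible JSON report.

The master seed feeds a hierarchical ``numpy.random.SeedSequence``; every
stage and unit draws from its own substream, so the whole run is a pure
function of (config, seed).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as did_io
from .distributional_td import TDConfig, build_projection_agents, evaluate_agent
from .firing_statistics import iti_firing_summary
from .photometry_processing import process_recording
from .population_clustering import (
    PSTHMatrix,
    cut_dendrogram,
    dendrogram_to_newick,
    extract_pcs,
    hcluster_average_euclidean,
    modal_cluster_fractions,
    population_enrichment,
)
from .spike_encoding import (
    REGRESSORS,
    build_design_matrix,
    classify_encoding,
    compute_psth,
    event_window_rate,
    fit_poisson_encoding_glm,
)
from .task_synth import (
    DEFAULT_TEMPLATES,
    POPULATIONS,
    BehaviorParams,
    PhotometryParams,
    SyntheticSession,
    TaskConfig,
    build_population_session,
    simulate_photometry,
)

__all__ = ["RunConfig", "RunReport", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists the offending fields."""


@dataclass(frozen=True)
class AnalysisConfig:
    n_neurons_per_population: int = 10
    cluster_k: int = 4
    glm_alpha: float = 0.05
    rgs_alpha: float = 0.05
    reward_window_s: tuple[float, float] = (0.04, 0.24)
    cue_window_s: tuple[float, float] = (0.0, 0.24)
    n_shuffles: int = 200

    def __post_init__(self) -> None:
        if self.n_neurons_per_population < 3:
            raise ConfigError("n_neurons_per_population must be >= 3")
        if not 0 < self.glm_alpha < 1:
            raise ConfigError("glm_alpha must be in (0, 1)")
        if self.cluster_k < 1:
            raise ConfigError("cluster_k must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    photometry: PhotometryParams = field(default_factory=PhotometryParams)
    td: TDConfig = field(default_factory=TDConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _build_dataclass(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    errors = []
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            errors.append(f"{path}.{key}: unknown key")
            continue
        default = fields[key].default
        if isinstance(default, bool):
            if not isinstance(value, bool):
                errors.append(f"{path}.{key}: expected a boolean, got {type(value).__name__}")
                continue
        elif isinstance(default, (int, float)):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                errors.append(f"{path}.{key}: expected a number, got {type(value).__name__}")
                continue
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    if errors:
        raise ConfigError("; ".join(errors))
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def validate_config(raw: dict | None) -> RunConfig:
    """Typed, defaulted, range-checked configuration from a plain document
    (e.g. parsed YAML/JSON).  Unknown keys and out-of-range values raise a
    ConfigError naming the offending path."""
    raw = dict(raw or {})
    sections = {
        "task": TaskConfig,
        "behavior": BehaviorParams,
        "analysis": AnalysisConfig,
        "photometry": PhotometryParams,
        "td": TDConfig,
    }
    kwargs: dict[str, Any] = {}
    errors = []
    for key, value in raw.items():
        if key == "seed":
            if isinstance(value, bool) or not isinstance(value, int):
                errors.append("seed: expected an integer")
            else:
                kwargs["seed"] = value
        elif key in sections:
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a mapping")
                continue
            try:
                kwargs[key] = _build_dataclass(sections[key], value, key)
            except ConfigError as exc:
                errors.append(str(exc))
        else:
            errors.append(f"{key}: unknown key")
    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(**kwargs)


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: dict[str, dict]
    invariants: dict[str, bool]
    timing_s: dict[str, float]

    def checksum(self) -> str:
        """Hash of the deterministic report content (timings excluded)."""
        payload = {"config": self.config_hash, "seed": self.seed,
                   "stages": self.stages, "invariants": self.invariants}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self) | {"checksum": self.checksum()},
                          indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# stages (importable individually by the analysis scripts)
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig) -> dict[str, SyntheticSession]:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(POPULATIONS))
    sessions = {}
    for pop, child in zip(POPULATIONS, children):
        rng = np.random.default_rng(child)
        sessions[pop] = build_population_session(
            pop, config.analysis.n_neurons_per_population, config.task,
            rng=rng, behavior=config.behavior)
    return sessions


def encode_stage(config: RunConfig, sessions: dict[str, SyntheticSession]) -> pd.DataFrame:
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    for pop, session in sessions.items():
        for train in session.spike_trains:
            psth = compute_psth(train, session.events)
            design = build_design_matrix(train, session.events)
            fit = fit_poisson_encoding_glm(design)
            cls = classify_encoding(fit, config.analysis.glm_alpha)
            rr, rr_p = event_window_rate(
                train, session.events, "reward", config.analysis.reward_window_s,
                shuffles=max(config.analysis.n_shuffles, 100), rng=rng)
            cr, cr_p = event_window_rate(
                train, session.events, "cue", config.analysis.cue_window_s,
                shuffles=max(config.analysis.n_shuffles, 100), rng=rng)
            baseline = psth.baseline_mean_hz
            row = {
                "unit_id": train.unit_id, "population": pop,
                "dominant": cls.dominant, "multiplexing": cls.multiplexing_count,
                "gof_p": fit.gof_p, "deviance": fit.deviance,
                "reward_window_hz": rr, "reward_shuffle_p": rr_p,
                "cue_window_hz": cr, "cue_shuffle_p": cr_p,
                "baseline_hz": baseline,
                "true_dominant": session.ground_truth[train.unit_id].dominant,
                "true_encoded": ",".join(sorted(session.ground_truth[train.unit_id].encoded)),
            }
            for k in REGRESSORS:
                row[f"beta_{k}"] = fit.coef[k]
                row[f"p_{k}"] = fit.pvalues[k]
                row[f"sig_{k}"] = k in cls.significant
            rows.append(row)
    return pd.DataFrame(rows)


def firing_stage(config: RunConfig, sessions: dict[str, SyntheticSession]) -> pd.DataFrame:
    rows = []
    for pop, session in sessions.items():
        for train in session.spike_trains:
            s = iti_firing_summary(train, session.events, alpha=config.analysis.rgs_alpha)
            rows.append({"unit_id": s.unit_id, "population": pop,
                         "iti_rate_hz": s.iti_rate_hz, "mean_cv2": s.mean_cv2,
                         "burst_fraction": s.burst_fraction,
                         "pause_count": s.pause_count,
                         "median_pause_s": s.median_pause_duration_s})
    return pd.DataFrame(rows)


def cluster_stage(config: RunConfig, sessions: dict[str, SyntheticSession]):
    traces, unit_ids, labels = [], [], {}
    for pop, session in sessions.items():
        for train in session.spike_trains:
            psth = compute_psth(train, session.events)
            if psth.silent:
                continue
            traces.append(psth.mean_z)
            unit_ids.append(train.unit_id)
            labels[train.unit_id] = pop
    matrix = PSTHMatrix(np.vstack(traces), unit_ids, [labels[u] for u in unit_ids])
    scores = extract_pcs(matrix)
    dendro = hcluster_average_euclidean(scores, unit_ids)
    assignment = cut_dendrogram(dendro, config.analysis.cluster_k)
    enrichment = population_enrichment(assignment, labels)
    modal = modal_cluster_fractions(assignment, labels)
    return matrix, scores, dendro, assignment, enrichment, modal


def photometry_stage(config: RunConfig, sessions: dict[str, SyntheticSession]) -> pd.DataFrame:
    ss = np.random.SeedSequence(config.seed + 1)
    rows = []
    for pop, child in zip(POPULATIONS, ss.spawn(len(POPULATIONS))):
        rng = np.random.default_rng(child)
        rec, truth = simulate_photometry(
            sessions[pop].events, DEFAULT_TEMPLATES[pop], config.photometry, rng)
        processed, sweeps, peak = process_recording(
            rec, reward_delay_s=config.task.cue_reward_delay_s)
        artifact_corr = float(np.corrcoef(processed.dff, truth.artifact)[0, 1])
        rows.append({"population": pop, "peak_reward_dff": peak,
                     "dff_artifact_corr": artifact_corr,
                     "max_precue_sweep_mean": float(np.abs(
                         sweeps.sweeps[:, : int(sweeps.fs_hz)].mean(axis=1)).max())})
    return pd.DataFrame(rows)


def td_stage(config: RunConfig, encoding: pd.DataFrame):
    """Build per-population activity samples (baseline-subtracted reward
    window rates standardized by the pooled SD) and fit/evaluate agents."""
    resp = encoding["reward_window_hz"] - encoding["baseline_hz"]
    pooled_sd = float(resp.std(ddof=1))
    if pooled_sd == 0:
        raise ValueError("degenerate reward responses")
    samples = {pop: (resp[encoding.population == pop] / pooled_sd).to_numpy()
               for pop in POPULATIONS}
    rng = np.random.default_rng(np.random.SeedSequence(config.seed + 2))
    agents = build_projection_agents(samples, config.td, rng)
    rows = []
    for label, (agent, fit) in agents.items():
        ev = evaluate_agent(agent, config.td, rng)
        rows.append({"agent": label,
                     "mean_asymmetry": float(fit.asymmetry.mean()),
                     "mean_value": float(agent.converged_V[:, config.td.reward_state].mean()),
                     "mean_mse": ev.mean_mse, "bias": ev.bias})
    return agents, pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute all stages, optionally writing tables under ``outdir``;
    returns a report whose checksum is reproducible under a fixed seed."""
    stages: dict[str, dict] = {}
    timing: dict[str, float] = {}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    sessions = simulate_stage(config)
    timing["simulate"] = time.perf_counter() - t0
    first = sessions[POPULATIONS[0]]
    delays = (np.asarray(first.events.reward_times_s)
              - np.asarray(first.events.cue_onsets_s))
    stages["simulate"] = {
        "n_units": sum(len(s.spike_trains) for s in sessions.values()),
        "n_rewards": int(len(first.events.reward_times_s)),
        "max_delay_error_s": float(np.abs(delays - config.task.cue_reward_delay_s).max()),
    }
    if out is not None:
        did_io.write_events_csv(first.events, out / "events.csv")
        for pop, session in sessions.items():
            did_io.write_spike_trains_hdf5(session, out / f"spikes_{pop}.h5")

    t0 = time.perf_counter()
    encoding = encode_stage(config, sessions)
    timing["encode"] = time.perf_counter() - t0
    stages["encode"] = {
        "n_fit": int(len(encoding)),
        "frac_gof_reject": float((encoding.gof_p < 0.05).mean()),
        "dominant_counts": encoding.dominant.value_counts().to_dict(),
    }
    if out is not None:
        encoding.to_csv(out / "encoding.csv", index=False)

    t0 = time.perf_counter()
    firing = firing_stage(config, sessions)
    timing["firing"] = time.perf_counter() - t0
    stages["firing"] = {
        "mean_rate_by_population": firing.groupby("population")["iti_rate_hz"]
        .mean().round(4).to_dict(),
        "median_pause_by_population": firing.groupby("population")["median_pause_s"]
        .median().round(4).to_dict(),
    }
    if out is not None:
        firing.to_csv(out / "firing.csv", index=False)

    t0 = time.perf_counter()
    matrix, scores, dendro, assignment, enrichment, modal = cluster_stage(config, sessions)
    timing["cluster"] = time.perf_counter() - t0
    stages["cluster"] = {"k": assignment.k,
                         "modal_cluster_fraction": {k: round(v, 4) for k, v in modal.items()}}
    if out is not None:
        pd.DataFrame(scores, columns=["pc1", "pc2"], index=matrix.unit_ids)\
            .to_csv(out / "pc_scores.csv")
        enrichment.to_csv(out / "enrichment.csv", index=False)
        (out / "dendrogram.nwk").write_text(dendrogram_to_newick(dendro))

    t0 = time.perf_counter()
    phot = photometry_stage(config, sessions)
    timing["photometry"] = time.perf_counter() - t0
    stages["photometry"] = {
        "peak_reward_dff": phot.set_index("population")["peak_reward_dff"]
        .round(5).to_dict(),
    }
    if out is not None:
        phot.to_csv(out / "photometry.csv", index=False)

    t0 = time.perf_counter()
    agents, td_table = td_stage(config, encoding)
    timing["td"] = time.perf_counter() - t0
    stages["td"] = {r["agent"]: {"mean_asymmetry": round(r["mean_asymmetry"], 4),
                                 "mean_mse": round(r["mean_mse"], 4),
                                 "bias": round(r["bias"], 4)}
                    for r in td_table.to_dict("records")}
    if out is not None:
        td_table.to_csv(out / "td_agents.csv", index=False)

    invariants = {
        "reward_delay_exact": stages["simulate"]["max_delay_error_s"] == 0.0,
        "n_rewards_default": stages["simulate"]["n_rewards"] == config.task.n_trials,
        "sweep_normalization": bool((phot.max_precue_sweep_mean < 1e-9).all()),
    }
    report = RunReport(config.hash(), config.seed, stages, invariants, timing)
    if out is not None:
        (out / "report.json").write_text(report.to_json())
    return report
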