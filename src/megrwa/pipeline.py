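"""End-to-end pipeline: simulate -> models -> searchlight -> RWA -> stats.

Every run is reproducible from (config, seed) alone: all randomness flows
from a single seed sequence, and outputs (maps, tables, figures) are
written together with a provenance record (config hash, child seeds,
library versions, per-stage runtimes).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .config import RunConfig
from .containers import EpsilonMap, GroupStatMap, ModelRDM, StimulusSet
from .features import compute_model_rdms, model_intercorrelation
from .group_stats import bin_significance, group_rank_test, subject_null_epsilon
from .preprocessing import average_pseudo_trials
from .rwa import searchlight_rwa
from .searchlight import searchlight_rdms, sensor_adjacency, spatial_neighbors
from .synthetic import (
    PlantedEffect,
    PlantedSignalSpec,
    SyntheticStimulusSpec,
    generate_meg_dataset,
    generate_sensor_layout,
    generate_stimuli,
)

__all__ = [
    "run_full_pipeline",
    "run_recovery_experiment",
    "run_type1_experiment",
    "RecoveryReport",
    "posterior_sensor_group",
]


def posterior_sensor_group(layout, n: int) -> np.ndarray:
    """Indices of the n most posterior sensors (lowest layout y)."""
    return np.argsort(layout.positions[:, 1])[:n]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _simulate(config: RunConfig, seed_stim: int, seed_meg: int):
    spec = SyntheticStimulusSpec(
        n_categories=config.stimuli.n_categories,
        n_per_category=config.stimuli.n_per_category,
        image_size=config.stimuli.image_size,
        jitter=config.stimuli.jitter,
        collinear=config.stimuli.collinear,
        seed=seed_stim,
    )
    stimuli = generate_stimuli(spec)
    models = compute_model_rdms(
        stimuli,
        n_scales=config.models.gist_scales,
        n_orientations=config.models.gist_orientations,
        grid=config.models.gist_grid,
        gist_normalize=config.models.gist_normalize,
        prefilter=config.models.gist_prefilter,
        radius_weight=config.models.shape_radius_weight,
        branch_penalty=config.models.shape_branch_penalty,
    )
    sim = config.simulation
    layout = generate_sensor_layout(sim.n_sensors)
    group = posterior_sensor_group(layout, sim.plant_n_sensors)
    plants = []
    if any(w > 0 for w in sim.plant_weights):
        plants = [
            PlantedEffect(
                sensor_indices=group,
                time_window=sim.plant_window,
                weights=np.asarray(sim.plant_weights),
            )
        ]
    plant = PlantedSignalSpec(
        sensor_layout=layout,
        plants=plants,
        noise_sd=sim.noise_sd,
        n_subjects=sim.n_subjects,
        n_trials_per_stimulus=sim.n_trials_per_stimulus,
        sfreq=sim.sfreq,
        epoch_window=sim.epoch_window,
        seed=seed_meg,
    )
    datasets = generate_meg_dataset(stimuli, models, plant)
    return stimuli, models, layout, group, plant, datasets


def _subject_epsilon(
    epochs, stimuli: StimulusSet, models: list[ModelRDM], config: RunConfig, seed: int
) -> EpsilonMap:
    pseudo = average_pseudo_trials(epochs, stimulus_order=stimuli.stimulus_ids)
    neural = searchlight_rdms(pseudo, k=config.searchlight.k, r=config.searchlight.r)
    emap = searchlight_rwa(
        neural,
        models,
        orthogonalization=config.rwa.orthogonalization,
        rank_transform=config.rwa.rank_transform,
    )
    if config.rwa.baseline == "null_mean":
        null_mean, _ = subject_null_epsilon(
            neural,
            models,
            n_null=config.rwa.n_null,
            seed=seed,
            orthogonalization=config.rwa.orthogonalization,
        )
        emap = EpsilonMap(
            epsilon=emap.epsilon - null_mean,
            model_names=emap.model_names,
            sensor_ids=emap.sensor_ids,
            times=emap.times,
        )
    return emap


def _group_stats(subject_maps, layout, config: RunConfig, seed: int) -> GroupStatMap:
    adjacency = sensor_adjacency(layout, config.searchlight.adjacency_neighbors)
    return group_rank_test(
        subject_maps,
        adjacency,
        n_permutations=config.stats.n_permutations,
        seed=seed,
        alpha=config.stats.alpha,
        E=config.stats.tfce_E,
        H=config.stats.tfce_H,
        n_steps=config.stats.tfce_steps,
    )


def run_full_pipeline(config: RunConfig, out_dir: str | Path) -> GroupStatMap:
    """Execute the whole workflow on synthetic data and write all outputs.

    Writes model RDM CSVs, per-subject epsilon containers and long-format
    CSVs, group z/p maps, the binned-significance table, topography PNGs
    per 50-ms bin and a provenance JSON.  Returns the group statistics.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runtimes: dict[str, float] = {}
    seeds = _child_seeds(config.seed, 4 + config.simulation.n_subjects)
    tic = time.perf_counter()
    stimuli, models, layout, group, plant, datasets = _simulate(config, seeds[0], seeds[1])
    runtimes["simulate+models"] = time.perf_counter() - tic

    io.write_stimulus_set(out_dir / "stimuli", stimuli)
    np.save(out_dir / "sensor_pos.npy", layout.positions)
    for m in models:
        io.write_model_rdm(out_dir / f"rdm_{m.name}.csv", m)
    inter = model_intercorrelation(models)
    np.savetxt(out_dir / "model_intercorrelation.csv", inter, delimiter=",", fmt="%.6f")

    tic = time.perf_counter()
    subject_maps = []
    frames = []
    for s, epochs in enumerate(datasets):
        emap = _subject_epsilon(epochs, stimuli, models, config, seeds[4 + s])
        subject_maps.append(emap)
        io.write_epsilon_map(out_dir / f"epsilon_sub{s:02d}.h5", emap)
        frames.append(io.epsilon_map_to_frame(emap, subject=s))
    import pandas as pd

    pd.concat(frames, ignore_index=True).to_csv(out_dir / "epsilon_long.csv", index=False)
    runtimes["searchlight+rwa"] = time.perf_counter() - tic

    tic = time.perf_counter()
    stats = _group_stats(subject_maps, layout, config, seeds[2])
    runtimes["group_stats"] = time.perf_counter() - tic

    np.save(out_dir / "group_z.npy", stats.z)
    np.save(out_dir / "group_p_corrected.npy", stats.p_corrected)
    binned = bin_significance(stats, config.stats.bin_ms)
    rows = []
    for b_idx, (b0, b1) in enumerate(binned.bins):
        for name in binned.model_names:
            for sid in binned.sensors(name, b_idx):
                rows.append({"bin_start": b0, "bin_end": b1, "model": name, "sensor_id": sid})
    pd.DataFrame(rows, columns=["bin_start", "bin_end", "model", "sensor_id"]).to_csv(
        out_dir / "binned_significance.csv", index=False
    )
    plot_bin_topographies(stats, binned, layout, out_dir / "topographies")

    config_dump = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    provenance = {
        "config_sha256": hashlib.sha256(config_dump.encode()).hexdigest(),
        "seed": config.seed,
        "child_seeds": seeds,
        "versions": _versions(),
        "runtimes_s": {k: round(v, 3) for k, v in runtimes.items()},
        "n_permutations_used": stats.n_permutations,
        "exhaustive_permutations": stats.exhaustive,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return stats


def _versions() -> dict[str, str]:
    import matplotlib
    import numpy
    import scipy
    import skimage
    import sklearn

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
        "matplotlib": matplotlib.__version__,
    }


def plot_bin_topographies(stats: GroupStatMap, binned, layout, out_dir: str | Path) -> None:
    """Topographic z-maps per model and 50-ms bin; black dots mark sensors
    significant across the entire bin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    times_ms = np.asarray(stats.times) * 1000.0
    pos = layout.positions
    for j, name in enumerate(stats.model_names):
        n_bins = len(binned.bins)
        fig, axes = plt.subplots(1, max(n_bins, 1), figsize=(2.2 * max(n_bins, 1), 2.6))
        axes = np.atleast_1d(axes)
        vmax = max(np.abs(stats.z[j]).max(), 1e-6)
        for b_idx, (b0, b1) in enumerate(binned.bins):
            ax = axes[b_idx]
            in_bin = (times_ms >= b0) & (times_ms < b1)
            mean_z = stats.z[j][:, in_bin].mean(axis=1) if in_bin.any() else np.zeros(len(pos))
            ax.scatter(pos[:, 0], pos[:, 1], c=mean_z, cmap="RdBu_r", vmin=-vmax, vmax=vmax, s=40)
            sig = set(np.asarray(binned.sensors(name, b_idx)).tolist())
            mask = [str(s) in {str(x) for x in sig} for s in stats.sensor_ids]
            if any(mask):
                ax.scatter(pos[mask, 0], pos[mask, 1], c="k", s=8)
            ax.set_title(f"{int(b0)}-{int(b1)} ms", fontsize=8)
            ax.set_aspect("equal")
            ax.axis("off")
        fig.suptitle(name)
        fig.tight_layout()
        fig.savefig(out_dir / f"topography_{name}.png", dpi=100)
        plt.close(fig)


@dataclass
class RecoveryReport:
    """Outcome of a planted-weight recovery experiment."""

    planted_weights: np.ndarray
    recovery_fraction: float  # fraction of planted searchlights with correct ordering
    n_planted: int
    mean_epsilon_planted: np.ndarray  # group-mean per model inside the plant
    outside_significant: dict  # model -> count of significant clean searchlights
    n_outside: int
    stats: GroupStatMap = field(repr=False, default=None)


def run_recovery_experiment(config: RunConfig) -> RecoveryReport:
    """Plant known weights, run the pipeline, report ordering recovery.

    Recovery is assessed at the directly planted searchlights (center
    sensor in the planted group, center time inside the planted window):
    the group-mean chance-centered weights must have the same ordering as
    the planted weight vector.  False positives are counted over *clean*
    searchlights — those whose sensor set and time window share no
    feature with the plant (overlapping searchlights genuinely contain
    planted signal).
    """
    seeds = _child_seeds(config.seed, 4 + config.simulation.n_subjects)
    stimuli, models, layout, group, plant, datasets = _simulate(config, seeds[0], seeds[1])
    subject_maps = [
        _subject_epsilon(epochs, stimuli, models, config, seeds[4 + s])
        for s, epochs in enumerate(datasets)
    ]
    stats = _group_stats(subject_maps, layout, config, seeds[2])

    mean_map = np.mean([m.epsilon for m in subject_maps], axis=0)  # sensors x times x p
    t_idx = plant.time_indices(config.simulation.plant_window)
    w = np.asarray(config.simulation.plant_weights)
    order = np.argsort(w)[::-1]
    planted = mean_map[np.ix_(group, t_idx)]  # (len(group), len(t_idx), p)
    ordering_ok = np.zeros(planted.shape[:2], dtype=bool)
    ranked = np.argsort(planted, axis=2)[..., ::-1]
    ordering_ok = (ranked == order[None, None, :]).all(axis=2)
    recovery = float(ordering_ok.mean())

    # Clean searchlights: sensor set disjoint from the plant AND time
    # window disjoint from the planted interval.
    neighbors = spatial_neighbors(layout, config.searchlight.k)
    overlap_sensor = np.array([np.isin(neighbors[s], group).any() for s in range(layout.n_sensors)])
    n_times = mean_map.shape[1]
    r = config.searchlight.r
    t_overlap = np.zeros(n_times, dtype=bool)
    if t_idx.size:
        lo, hi = t_idx.min() - r, t_idx.max() + r
        t_overlap[max(lo, 0) : min(hi + 1, n_times)] = True
    clean = ~overlap_sensor[:, None] & ~t_overlap[None, :]
    sig = stats.significant()
    outside = {
        name: int((sig[j] & clean).sum()) for j, name in enumerate(stats.model_names)
    }
    return RecoveryReport(
        planted_weights=w,
        recovery_fraction=recovery,
        n_planted=int(ordering_ok.size),
        mean_epsilon_planted=planted.mean(axis=(0, 1)),
        outside_significant=outside,
        n_outside=int(clean.sum()),
        stats=stats,
    )


def run_type1_experiment(
    config: RunConfig, n_replicates: int = 200, seed: int | None = None
) -> dict:
    """Family-wise error of the corrected test under the global null.

    Runs ``n_replicates`` independent noise-only datasets through
    searchlight -> RWA -> group test and reports, per model, the fraction
    of replicates with any corrected-significant point.
    """
    base_seed = config.seed if seed is None else seed
    rep_seeds = _child_seeds(base_seed, n_replicates + 1)
    cfg = config.model_copy(deep=True)
    cfg.simulation.plant_weights = (0.0, 0.0, 0.0)
    # Stimuli and model RDMs are fixed across replicates (they are inputs,
    # not noise); only the sensor data vary.
    stimuli, models, layout, group, plant, _ = _simulate(cfg, rep_seeds[-1], rep_seeds[-1])
    adjacency = sensor_adjacency(layout, cfg.searchlight.adjacency_neighbors)
    p = len(models)
    any_sig = np.zeros((n_replicates, p), dtype=bool)
    for rep in range(n_replicates):
        rng = np.random.default_rng(rep_seeds[rep])
        spec = PlantedSignalSpec(
            sensor_layout=layout,
            plants=[],
            noise_sd=cfg.simulation.noise_sd,
            n_subjects=cfg.simulation.n_subjects,
            n_trials_per_stimulus=cfg.simulation.n_trials_per_stimulus,
            sfreq=cfg.simulation.sfreq,
            epoch_window=cfg.simulation.epoch_window,
            seed=int(rng.integers(2**31 - 1)),
        )
        datasets = generate_meg_dataset(stimuli, models, spec)
        maps = [
            _subject_epsilon(e, stimuli, models, cfg, int(rng.integers(2**31 - 1)))
            for e in datasets
        ]
        stats = group_rank_test(
            maps,
            adjacency,
            n_permutations=cfg.stats.n_permutations,
            seed=int(rng.integers(2**31 - 1)),
            alpha=cfg.stats.alpha,
            E=cfg.stats.tfce_E,
            H=cfg.stats.tfce_H,
            n_steps=cfg.stats.tfce_steps,
        )
        any_sig[rep] = stats.significant().any(axis=(1, 2))
    fwer = any_sig.mean(axis=0)
    return {
        "n_replicates": n_replicates,
        "fwer_per_model": {m.name: float(f) for m, f in zip(models, fwer)},
        "alpha": cfg.stats.alpha,
        "binomial_se": float(np.sqrt(cfg.stats.alpha * (1 - cfg.stats.alpha) / n_replicates)),
    }
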