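"""Synthetic stimuli and multi-subject sensor data with planted geometry.

The study conditions this generator emulates: 30 object stimuli drawn from
6 semantic categories of 5, each picture presented 24 times (8 runs x 3
blocks, every picture once per block), and per-subject sensor x time data
whose local representational geometry inside chosen (sensor-group,
time-window) plants is a weighted mixture of the three model RDMs plus
i.i.d. Gaussian sensor noise.

Stimulus construction induces model collinearity *by construction*:
each category is assigned both a parametric silhouette family (blob, bar,
star, cross, ring, wedge) and a spectral bias (a preferred grating
orientation and spatial frequency painted inside the silhouette), so
category membership correlates with both shape and low-level structure.
``category_strength`` sets the probability that a stimulus adopts its
category's assignments rather than a random category's; the default is
calibrated so the pairwise model rank correlations fall in the weak
regime (roughly 0.1) that natural object photographs exhibit.  A
``collinear=False`` mode decouples the assignments from category
entirely, for control experiments.

Planting mechanism: for each model RDM D, the similarity matrix
C = 1 - D is eigendecomposed with negative eigenvalues clipped to zero
and rows renormalized, giving a factor L with unit-norm rows such that
(L L^T)_ij ~= C_ij.  Each planted feature (one sensor-time point inside a
plant) receives, per model, an independent Gaussian loading g so that the
stimulus-indexed signal (L g)_i has across-stimulus correlation C in
expectation; model contributions are scaled by sqrt(w_j) and summed.  The
three model RDMs are variance-equalized before factorization so the
weight vector w is expressed on a common scale across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochedData, ModelRDM, SensorArray, StimulusSet, upper_triangle

__all__ = [
    "SyntheticStimulusSpec",
    "PlantedEffect",
    "PlantedSignalSpec",
    "generate_stimuli",
    "generate_sensor_layout",
    "presentation_design",
    "generate_meg_dataset",
    "planted_correlation_factor",
    "mixture_rdm",
    "exact_mixture_patterns",
]

SHAPE_FAMILIES = ("blob", "bar", "star", "cross", "ring", "wedge")


@dataclass
class SyntheticStimulusSpec:
    """Parameters of the toy stimulus set (defaults = the emulated design)."""

    n_categories: int = 6
    n_per_category: int = 5
    image_size: int = 128
    shape_family_per_category: tuple[str, ...] = SHAPE_FAMILIES
    spectral_bias_per_category: tuple[tuple[float, float], ...] | None = None
    jitter: float = 0.3
    collinear: bool = True
    category_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32 to render a silhouette")
        if self.n_categories < 1 or self.n_per_category < 1:
            raise ValueError("counts must be positive")
        if len(self.shape_family_per_category) < self.n_categories:
            raise ValueError("need one shape family per category")
        if self.spectral_bias_per_category is None:
            # (orientation radians, cycles per image) per category
            self.spectral_bias_per_category = tuple(
                (np.pi * c / self.n_categories, 6.0 + 4.0 * (c % 3))
                for c in range(self.n_categories)
            )

    @property
    def n_stimuli(self) -> int:
        return self.n_categories * self.n_per_category


def _render_silhouette(family: str, size: int, params: dict) -> np.ndarray:
    """Binary silhouette of a parametric shape family, centered in the image."""
    half = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    x = (xx - half + 0.5) / half
    y = (yy - half + 0.5) / half
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    R = params.get("radius", 0.6)
    phi = params.get("phase", 0.0)
    if family == "blob":
        a2 = params.get("a2", 0.15)
        a3 = params.get("a3", 0.1)
        boundary = R * (1 + a2 * np.cos(2 * theta + phi) + a3 * np.cos(3 * theta + 2 * phi))
        return r <= boundary
    if family == "bar":
        aspect = params.get("aspect", 0.25)
        ang = params.get("angle", 0.3) + phi
        xr = x * np.cos(ang) + y * np.sin(ang)
        yr = -x * np.sin(ang) + y * np.cos(ang)
        return (np.abs(xr) <= R) & (np.abs(yr) <= R * aspect)
    if family == "star":
        depth = params.get("depth", 0.45)
        boundary = R * (1 - depth / 2 + depth / 2 * np.cos(5 * (theta + phi)))
        return r <= boundary
    if family == "cross":
        width = params.get("width", 0.22)
        ang = phi * 0.3
        xr = x * np.cos(ang) + y * np.sin(ang)
        yr = -x * np.sin(ang) + y * np.cos(ang)
        armx = (np.abs(xr) <= R) & (np.abs(yr) <= R * width)
        army = (np.abs(yr) <= R) & (np.abs(xr) <= R * width)
        return armx | army
    if family == "ring":
        inner = params.get("inner", 0.55)
        return (r <= R) & (r >= R * inner)
    if family == "wedge":
        opening = params.get("opening", 1.1)
        return (r <= R) & (np.abs(np.angle(np.exp(1j * (theta - phi)))) <= opening / 2)
    raise ValueError(f"unknown shape family {family!r}")


def generate_stimuli(spec: SyntheticStimulusSpec) -> StimulusSet:
    """Render the toy stimulus set described by ``spec``.

    Category membership correlates with both silhouette family and the
    oriented texture painted inside the silhouette with probability
    ``spec.category_strength`` (zero when ``spec.collinear`` is False,
    decoupling all three models).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_stimuli
    size = spec.image_size
    labels = np.repeat(np.arange(spec.n_categories), spec.n_per_category)
    strength = spec.category_strength if spec.collinear else 0.0
    # Partial category coupling: each stimulus follows its own category's
    # shape family / spectral bias with probability `strength`, otherwise
    # a randomly drawn category's.  This sets the model collinearity.
    shape_cat = np.where(
        rng.random(n) < strength, labels, rng.integers(0, spec.n_categories, n)
    )
    spectral_cat = np.where(
        rng.random(n) < strength, labels, rng.integers(0, spec.n_categories, n)
    )
    shape_assign = np.array([spec.shape_family_per_category[c] for c in shape_cat])
    spectral_assign = np.array([spec.spectral_bias_per_category[c] for c in spectral_cat])

    yy, xx = np.mgrid[0:size, 0:size]
    images = np.zeros((n, size, size, 3))
    masks = np.zeros((n, size, size), dtype=bool)
    # Per-stimulus color, independent of category (so luminance carries no
    # categorical signal); variation scales with jitter like every other
    # within-category perturbation.
    tints = np.clip(
        np.array([0.85, 0.75, 0.65]) + spec.jitter * rng.uniform(-0.6, 0.6, (n, 3)), 0.2, 1.0
    )
    for i in range(n):
        j = spec.jitter
        params = {
            "radius": 0.6 + j * 0.15 * rng.standard_normal(),
            "phase": j * rng.standard_normal(),
            "a2": 0.15 + j * 0.1 * rng.standard_normal(),
            "a3": 0.1 + j * 0.08 * rng.standard_normal(),
            "aspect": 0.25 + j * 0.08 * rng.standard_normal(),
            "angle": 0.3 + j * rng.standard_normal(),
            "depth": 0.45 + j * 0.1 * rng.standard_normal(),
            "width": 0.22 + j * 0.06 * rng.standard_normal(),
            "inner": 0.55 + j * 0.1 * rng.standard_normal(),
            "opening": 1.1 + j * 0.3 * rng.standard_normal(),
        }
        params = {k: float(np.clip(v, 0.05, 2.0)) for k, v in params.items()}
        mask = _render_silhouette(str(shape_assign[i]), size, params)
        if not mask.any():  # degenerate jitter draw; fall back to a disc
            mask = (xx - size / 2) ** 2 + (yy - size / 2) ** 2 <= (0.4 * size) ** 2
        ori, cycles = spectral_assign[i]
        ori = float(ori) + j * 0.2 * rng.standard_normal()
        cycles = float(cycles) * (1 + j * 0.1 * rng.standard_normal())
        phase = j * rng.standard_normal() * 2 * np.pi
        carrier = np.cos(
            2 * np.pi * cycles / size * (xx * np.cos(ori) + yy * np.sin(ori)) + phase
        )
        texture = 0.5 + 0.35 * carrier
        img = np.full((size, size, 3), 0.5)
        tint = tints[i]
        img[mask] = (texture[mask, None]) * tint[None, :]
        images[i] = np.clip(img, 0.0, 1.0)
        masks[i] = mask
    stimulus_ids = np.array([f"stim{i:03d}" for i in range(n)])
    return StimulusSet(images=images, masks=masks, labels=labels, stimulus_ids=stimulus_ids)


def generate_sensor_layout(n_sensors: int) -> SensorArray:
    """2-D sensor positions on a head disc (sunflower lattice, unique points).

    The default 102 sites mirror the combined planar-gradiometer layout of
    a whole-head system.  Positions fill the unit disc quasi-uniformly;
    negative y is the posterior half.
    """
    if n_sensors < 2:
        raise ValueError("need at least 2 sensors")
    i = np.arange(n_sensors)
    golden = np.pi * (3 - np.sqrt(5))
    r = np.sqrt((i + 0.5) / n_sensors)
    theta = golden * i
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    ids = np.array([f"S{k:03d}" for k in i])
    return SensorArray(ids, pos)


def presentation_design(
    n_stimuli: int, n_runs: int = 8, n_blocks_per_run: int = 3, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Trial order of the emulated design: every picture once per block.

    With the default 8 runs x 3 blocks each picture is presented exactly
    24 times.  Returns stimulus indices in presentation order, blocks
    individually randomized.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks = [rng.permutation(n_stimuli) for _ in range(n_runs * n_blocks_per_run)]
    return np.concatenate(blocks)


@dataclass
class PlantedEffect:
    """One planted (sensor-group, time-window) with per-model weights w_j >= 0."""

    sensor_indices: np.ndarray
    time_window: tuple[float, float]  # seconds, [start, end)
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.sensor_indices = np.asarray(self.sensor_indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.sensor_indices.size == 0:
            raise ValueError("planted sensor group must be non-empty")
        if not np.isfinite(self.weights).all() or (self.weights < 0).any():
            raise ValueError("weights must be finite and non-negative")


@dataclass
class PlantedSignalSpec:
    """Multi-subject dataset parameters (defaults = the emulated acquisition)."""

    sensor_layout: SensorArray
    plants: list[PlantedEffect] = field(default_factory=list)
    noise_sd: float = 1.0
    n_subjects: int = 16
    n_trials_per_stimulus: int = 24
    sfreq: float = 400.0
    epoch_window: tuple[float, float] = (-0.5, 1.0)
    exact_geometry: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_window
        if t1 <= t0:
            raise ValueError("epoch window must have positive length")
        for plant in self.plants:
            w0, w1 = plant.time_window
            if w0 < t0 or w1 > t1:
                raise ValueError("planted time window must lie inside the epoch window")
            if plant.sensor_indices.max() >= self.sensor_layout.n_sensors:
                raise ValueError("planted sensor index out of range")

    @property
    def n_times(self) -> int:
        return int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sfreq))

    def time_indices(self, window: tuple[float, float]) -> np.ndarray:
        t = self.epoch_window[0] + np.arange(self.n_times) / self.sfreq
        return np.nonzero((t >= window[0]) & (t < window[1]))[0]


def _equalize_rdm(matrix: np.ndarray, target_sd: float = 0.3) -> np.ndarray:
    """Rescale an RDM's off-diagonal entries to mean 1, sd ``target_sd``.

    Puts all model RDMs on a common dispersion scale so that planted
    weights are directly comparable across models.
    """
    vec = upper_triangle(matrix)
    sd = vec.std()
    if sd == 0:
        return np.ones_like(matrix) - np.eye(matrix.shape[0])
    z = (matrix - vec.mean()) / sd * target_sd + 1.0
    z = np.clip(z, 0.0, 2.0)
    np.fill_diagonal(z, 0.0)
    return 0.5 * (z + z.T)


def planted_correlation_factor(
    rdm: ModelRDM, equalize: bool = True
) -> tuple[np.ndarray, float]:
    """Factor L with unit-norm rows such that L L^T approximates 1 - RDM.

    The similarity matrix C = 1 - D is eigendecomposed; negative
    eigenvalues are clipped to zero (D need not be Euclidean) and rows are
    renormalized to unit norm.  Returns (L, distortion) where distortion
    is the relative Frobenius mass of the clipped spectrum.
    """
    D = _equalize_rdm(rdm.matrix) if equalize else rdm.matrix
    C = 1.0 - D
    np.fill_diagonal(C, 1.0)
    evals, evecs = np.linalg.eigh(C)
    clipped = np.clip(evals, 0.0, None)
    distortion = float(np.sqrt(np.sum((evals - clipped) ** 2) / np.sum(evals**2)))
    L = evecs * np.sqrt(clipped)[None, :]
    norms = np.linalg.norm(L, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return L / norms, distortion


def mixture_rdm(model_rdms: list[ModelRDM], weights: np.ndarray) -> np.ndarray:
    """Correlation-distance RDM of the planted w-weighted model mixture."""
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total == 0:
        raise ValueError("at least one positive weight required")
    C = np.zeros_like(model_rdms[0].matrix)
    for w, rdm in zip(weights, model_rdms):
        L, _ = planted_correlation_factor(rdm)
        C += w * (L @ L.T)
    C /= total
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return D


def exact_mixture_patterns(
    model_rdms: list[ModelRDM],
    weights: np.ndarray,
    n_features: int,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Patterns whose correlation-distance RDM equals the mixture exactly.

    Each model's factor rows are expanded on disjoint rows of an
    orthonormal zero-mean basis (the non-constant rows of a discrete
    cosine basis of length ``n_features``), so the returned
    ``(n_stimuli, n_features)`` pattern matrix has across-stimulus Pearson
    correlation exactly ``sum_j w_j C_j / sum_j w_j`` up to float error.
    Used as the construction oracle for searchlight/RWA tests.

    Returns ``(patterns, rdm)`` with ``rdm`` the implied correlation
    distance matrix.
    """
    weights = np.asarray(weights, dtype=float)
    factors = [planted_correlation_factor(r)[0] for r in model_rdms]
    ranks = [f.shape[1] for f in factors]
    if sum(ranks) + 1 > n_features:
        raise ValueError("n_features too small for an exact embedding")
    # DCT-II style orthonormal rows, excluding the constant row.
    k = np.arange(1, sum(ranks) + 1)[:, None]
    t = np.arange(n_features)[None, :]
    basis = np.sqrt(2.0 / n_features) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_features))
    patterns = np.zeros((model_rdms[0].n, n_features))
    C_mix = np.zeros((model_rdms[0].n, model_rdms[0].n))
    offset = 0
    for w, L in zip(weights, factors):
        rows = basis[offset : offset + L.shape[1]]
        patterns += np.sqrt(w) * (L @ rows)
        C_mix += w * (L @ L.T)
        offset += L.shape[1]
    total = weights.sum()
    if total > 0:
        C_mix /= total
    D = 1.0 - C_mix
    np.fill_diagonal(D, 0.0)
    return patterns, D


def generate_meg_dataset(
    stimuli: StimulusSet,
    model_rdms: list[ModelRDM],
    plant: PlantedSignalSpec,
) -> list[EpochedData]:
    """Simulate one epoched dataset per subject with planted geometry.

    Inside each planted (sensor-group, time-window) the expected
    across-stimulus pattern geometry is the w-weighted mixture of the
    model RDMs; elsewhere the data are pure white Gaussian noise.  Signal
    loadings are drawn independently per subject and per planted feature;
    trial noise is i.i.d. across trials, sensors, time and subjects.
    """
    n = stimuli.n_stimuli
    for rdm in model_rdms:
        if rdm.n != n:
            raise ValueError(f"model RDM {rdm.name!r} has {rdm.n} stimuli, expected {n}")
    rng = np.random.default_rng(plant.seed)
    layout = plant.sensor_layout
    n_times = plant.n_times
    factors = [planted_correlation_factor(r)[0] for r in model_rdms]
    datasets = []
    for _ in range(plant.n_subjects):
        order = presentation_design(
            n, n_runs=plant.n_trials_per_stimulus, n_blocks_per_run=1, seed=rng
        )
        n_trials = order.size
        data = rng.normal(0.0, plant.noise_sd, size=(n_trials, layout.n_sensors, n_times))
        for effect in plant.plants:
            t_idx = plant.time_indices(effect.time_window)
            s_idx = effect.sensor_indices
            n_feat = s_idx.size * t_idx.size
            if plant.exact_geometry:
                # deterministic embedding: a searchlight covering the whole
                # plant sees the mixture geometry to float precision
                signal, _ = exact_mixture_patterns(model_rdms, effect.weights, n_feat)
            else:
                signal = np.zeros((n, n_feat))
                for w, L in zip(effect.weights, factors):
                    if w == 0:
                        continue
                    g = rng.standard_normal((L.shape[1], n_feat))
                    signal += np.sqrt(w) * (L @ g)
            signal = signal.reshape(n, s_idx.size, t_idx.size)
            ix = np.ix_(np.arange(n_trials), s_idx, t_idx)
            data[ix] += signal[order]
        datasets.append(
            EpochedData(
                data=data,
                sfreq=plant.sfreq,
                t0=plant.epoch_window[0],
                trial_stimulus_id=stimuli.stimulus_ids[order],
                sensor_ids=layout.sensor_ids,
                sensor_pos=layout.positions,
            )
        )
    return datasets
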