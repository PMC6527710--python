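"""Core data containers shared across the pipeline.

The lingua franca of the analysis is the representational dissimilarity
matrix (RDM): a symmetric, hollow matrix of pairwise dissimilarities
between stimulus-evoked patterns (neural RDMs) or between model-based
stimulus descriptions (model RDMs).  Containers here are thin, validated
dataclasses around numpy arrays; all heavy lifting lives in the stage
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSet",
    "ModelRDM",
    "SensorArray",
    "EpochedData",
    "PseudoTrials",
    "NeuralRDMSeries",
    "EpsilonMap",
    "GroupStatMap",
    "BinnedSignificance",
    "upper_triangle",
    "squareform_rdm",
]


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a square matrix (row-major)."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    return matrix[iu]


def squareform_rdm(vector: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`upper_triangle` for a hollow symmetric matrix."""
    out = np.zeros((n, n), dtype=float)
    iu = np.triu_indices(n, k=1)
    out[iu] = vector
    return out + out.T


@dataclass
class StimulusSet:
    """Images, binary object masks and category labels for n stimuli.

    ``images`` is ``(n, H, W)`` grayscale or ``(n, H, W, 3)`` RGB in [0, 1];
    ``masks`` is boolean ``(n, H, W)`` with the object marked True.
    """

    images: np.ndarray
    masks: np.ndarray
    labels: np.ndarray
    stimulus_ids: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.masks = np.asarray(self.masks, dtype=bool)
        self.labels = np.asarray(self.labels)
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        n = self.images.shape[0]
        if not (self.masks.shape[0] == self.labels.shape[0] == self.stimulus_ids.shape[0] == n):
            raise ValueError("images, masks, labels and stimulus_ids must have equal counts")
        if n < 2:
            raise ValueError("a stimulus set needs at least 2 stimuli")
        if self.masks.shape[1:3] != self.images.shape[1:3]:
            raise ValueError("masks must match the spatial size of the images")
        if not self.masks.reshape(n, -1).any(axis=1).all():
            raise ValueError("every stimulus must have a non-empty mask")

    @property
    def n_stimuli(self) -> int:
        return self.images.shape[0]


@dataclass
class ModelRDM:
    """A named n x n model dissimilarity matrix over an ordered stimulus set."""

    name: str
    matrix: np.ndarray
    stimulus_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be a square matrix")
        if not np.isfinite(m).all():
            raise ValueError("RDM must be finite")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM must have a zero diagonal")
        self.matrix = m
        if self.stimulus_ids is not None:
            self.stimulus_ids = np.asarray(self.stimulus_ids)
            if self.stimulus_ids.shape[0] != m.shape[0]:
                raise ValueError("stimulus_ids length must match RDM size")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def vector(self) -> np.ndarray:
        """Strict upper triangle, length n(n-1)/2."""
        return upper_triangle(self.matrix)


@dataclass
class SensorArray:
    """Sensor identifiers and their 2-D layout positions (head-disc plane)."""

    sensor_ids: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.sensor_ids = np.asarray(self.sensor_ids)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n_sensors, 2)")
        if self.sensor_ids.shape[0] != self.positions.shape[0]:
            raise ValueError("sensor_ids and positions must have equal length")
        if len(np.unique(self.sensor_ids)) != len(self.sensor_ids):
            raise ValueError("sensor ids must be unique")
        if len(np.unique(self.positions, axis=0)) != len(self.positions):
            raise ValueError("sensor positions must be unique")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass
class EpochedData:
    """Epoched multi-sensor time series: ``data`` is trials x sensors x time."""

    data: np.ndarray
    sfreq: float
    t0: float
    trial_stimulus_id: np.ndarray
    sensor_ids: np.ndarray
    sensor_pos: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x time")
        if not np.isfinite(self.data).all():
            raise ValueError("data must be finite")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        self.trial_stimulus_id = np.asarray(self.trial_stimulus_id)
        if self.trial_stimulus_id.shape[0] != self.data.shape[0]:
            raise ValueError("one stimulus id per trial required")
        self.sensor_ids = np.asarray(self.sensor_ids)
        self.sensor_pos = np.asarray(self.sensor_pos, dtype=float)
        if self.sensor_ids.shape[0] != self.data.shape[1]:
            raise ValueError("sensor_ids must match the sensor axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_times) / self.sfreq

    @property
    def sensors(self) -> SensorArray:
        return SensorArray(self.sensor_ids, self.sensor_pos)


@dataclass
class PseudoTrials:
    """One averaged pattern per stimulus: ``data`` is stimuli x sensors x time."""

    data: np.ndarray
    stimulus_ids: np.ndarray
    sfreq: float
    t0: float
    sensor_ids: np.ndarray
    sensor_pos: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be stimuli x sensors x time")
        if self.stimulus_ids.shape[0] != self.data.shape[0]:
            raise ValueError("exactly one pseudo-trial per stimulus required")
        if len(np.unique(self.stimulus_ids)) != len(self.stimulus_ids):
            raise ValueError("stimulus ids must be unique")
        self.sensor_ids = np.asarray(self.sensor_ids)
        self.sensor_pos = np.asarray(self.sensor_pos, dtype=float)

    @property
    def n_stimuli(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_times) / self.sfreq

    @property
    def sensors(self) -> SensorArray:
        return SensorArray(self.sensor_ids, self.sensor_pos)


@dataclass
class NeuralRDMSeries:
    """Vectorized neural RDM per (center sensor, center time).

    ``rdms`` has shape ``(n_sensors, n_times, n_pairs)`` with
    ``n_pairs = n(n-1)/2`` for n stimuli, upper-triangle order.
    """

    rdms: np.ndarray
    sensor_ids: np.ndarray
    times: np.ndarray
    stimulus_ids: np.ndarray

    def __post_init__(self) -> None:
        self.rdms = np.asarray(self.rdms, dtype=float)
        if self.rdms.ndim != 3:
            raise ValueError("rdms must be sensors x times x pairs")
        if not np.isfinite(self.rdms).all():
            raise ValueError("neural RDMs must be finite")
        n = len(self.stimulus_ids)
        if self.rdms.shape[2] != n * (n - 1) // 2:
            raise ValueError("pair axis must have length n(n-1)/2")

    @property
    def n_sensors(self) -> int:
        return self.rdms.shape[0]

    @property
    def n_times(self) -> int:
        return self.rdms.shape[1]


@dataclass
class EpsilonMap:
    """Per-subject relative weights: ``epsilon`` is sensors x times x models."""

    epsilon: np.ndarray
    model_names: list[str]
    sensor_ids: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.ndim != 3:
            raise ValueError("epsilon must be sensors x times x models")
        if not np.isfinite(self.epsilon).all():
            raise ValueError("epsilon must be finite")
        if self.epsilon.shape[2] != len(self.model_names):
            raise ValueError("model axis must match model_names")


@dataclass
class GroupStatMap:
    """Group-level z and corrected p per model, sensors x times."""

    z: np.ndarray  # (n_models, n_sensors, n_times)
    p_corrected: np.ndarray
    model_names: list[str]
    sensor_ids: np.ndarray
    times: np.ndarray
    alpha: float = 0.05
    n_permutations: int = 0
    exhaustive: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.p_corrected = np.asarray(self.p_corrected, dtype=float)
        if self.z.shape != self.p_corrected.shape:
            raise ValueError("z and p maps must share a shape")
        if ((self.p_corrected < 0) | (self.p_corrected > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")

    def significant(self) -> np.ndarray:
        """Boolean map of corrected one-tailed significance at ``alpha``."""
        return self.p_corrected < self.alpha


@dataclass
class BinnedSignificance:
    """Sensors significant across *every* sample of each 50-ms bin."""

    bins: list[tuple[float, float]]  # (start_ms, end_ms)
    model_names: list[str]
    sensors_per_bin: dict = field(default_factory=dict)  # (model, bin_idx) -> sensor id array

    def sensors(self, model: str, bin_idx: int) -> np.ndarray:
        return self.sensors_per_bin.get((model, bin_idx), np.array([], dtype=object))
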