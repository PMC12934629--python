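"""Synthetic paired BOLD-like cohorts with block-structured covariance.

The generator emulates the study design the pipeline is meant for: for each of
nine altered states of consciousness (four psychedelic agents, two non-REM
sleep stages, three propofol effect-site concentrations) a separate cohort of
subjects is simulated, each subject contributing a baseline recording and one
altered-state recording.  State effects are encoded as signed shifts of the
within-network and between-network block correlations — coupling *up* between
networks and *down* within networks for psychedelics, down on both for sleep
and sedation, with dose-graded magnitudes — plus a state-specific AR(1)
temporal-smoothness coefficient that carries the slowing (sedation/sleep) or
acceleration (psychedelics) of the dynamics that the windowed complexity
statistic is sensitive to.

All recordings are standardized per ROI (zero mean, unit variance), mirroring
the preprocessing contract of parcellated resting-state data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .partition import NetworkPartition, make_partition

PSYCHEDELIC = "psychedelic"
SLEEP = "sleep"
SEDATION = "sedation"
BASELINE = "baseline"

#: jitter ceiling when enforcing positive definiteness
_MAX_JITTER = 1e-6


class SimulationError(RuntimeError):
    """Raised when a state covariance cannot be made positive definite."""


@dataclass(frozen=True)
class StateSpec:
    """One altered state: coupling shifts and dynamical parameters.

    ``delta_within`` / ``delta_between`` shift the baseline block correlations;
    ``ar_coef`` is the lag-1 autocorrelation of the latent dynamics (higher =
    slower dynamics, lowering windowed interaction complexity); ``noise_scale``
    adds white observation noise of variance ``noise_scale**2 - 1`` on top of
    the unit-variance signal (1.0 = none; the infinite-noise limit drives all
    correlations to zero).
    """

    name: str
    state_class: str
    delta_within: float = 0.0
    delta_between: float = 0.0
    noise_scale: float = 1.0
    ar_coef: float = 0.30

    def __post_init__(self) -> None:
        if self.state_class not in (PSYCHEDELIC, SLEEP, SEDATION, BASELINE):
            raise ValueError(f"unknown state class {self.state_class!r}")
        if self.state_class == BASELINE and (self.delta_within or self.delta_between):
            raise ValueError("baseline must have zero coupling deltas")
        if self.noise_scale < 1.0:
            raise ValueError("noise_scale must be >= 1")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must be in [0, 1)")


#: baseline wakefulness condition shared by every cohort
BASELINE_STATE = StateSpec("baseline", BASELINE, 0.0, 0.0, 1.0, 0.30)


def default_states() -> tuple[StateSpec, ...]:
    """The nine altered states with dose-graded coupling shifts.

    Psychedelics: between-network coupling up, within-network down, faster
    dynamics.  Sleep and propofol sedation: both couplings down — the
    between-network drop proportionally larger, so the network topology
    becomes relatively more segregated — and dynamics slower, with magnitudes
    graded by depth (N1 < N2) and effect-site concentration
    (1.9 < 2.4 < 2.7 ug/mL).
    """
    return (
        StateSpec("LSD", PSYCHEDELIC, -0.11, +0.16, ar_coef=0.13),
        StateSpec("PSIL", PSYCHEDELIC, -0.08, +0.12, ar_coef=0.18),
        StateSpec("KTM", PSYCHEDELIC, -0.055, +0.08, ar_coef=0.23),
        StateSpec("N2O", PSYCHEDELIC, -0.035, +0.05, ar_coef=0.27),
        StateSpec("N1", SLEEP, -0.02, -0.05, ar_coef=0.34),
        StateSpec("N2", SLEEP, -0.03, -0.075, ar_coef=0.42),
        StateSpec("PPF1.9", SEDATION, -0.04, -0.095, ar_coef=0.50),
        StateSpec("PPF2.4", SEDATION, -0.048, -0.112, ar_coef=0.58),
        StateSpec("PPF2.7", SEDATION, -0.055, -0.128, ar_coef=0.66),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults describe a compact cohort (70 ROIs in seven 10-ROI networks,
    150 frames, 20 subjects per state) whose effects mirror the directions and
    gradings of the full-scale study.
    """

    seed: int
    n_rois: int = 70
    network_sizes: tuple[int, ...] | None = None
    n_frames: int = 150
    n_subjects_per_state: int = 20
    w_base: float = 0.50
    b_base: float = 0.15
    subject_sd: float = 0.03
    frame_interval: float = 2.0
    states: tuple[StateSpec, ...] = field(default_factory=default_states)

    def __post_init__(self) -> None:
        if self.network_sizes is not None and sum(self.network_sizes) != self.n_rois:
            raise ValueError("network_sizes must sum to n_rois")
        if not 0.0 <= self.b_base < self.w_base < 1.0:
            raise ValueError("require 0 <= b_base < w_base < 1")
        if self.n_frames < 10:
            raise ValueError("n_frames must cover at least two complexity windows")
        if self.n_subjects_per_state < 3:
            raise ValueError("paired tests need at least 3 subjects per state")

    def partition(self) -> NetworkPartition:
        sizes = list(self.network_sizes) if self.network_sizes else None
        return make_partition(self.n_rois, sizes)


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """frames x ROIs standardized BOLD-like series."""

    values: np.ndarray
    roi_ids: tuple[str, ...]
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValueError("time series must be a frames x ROIs matrix, >= 2 frames")
        if v.shape[1] != len(self.roi_ids):
            raise ValueError("column count must match roi_ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class Recording:
    subject: str
    state: str
    state_class: str
    series: TimeSeriesMatrix


@dataclass(frozen=True)
class CohortDataset:
    """All recordings of a multi-state cohort plus their provenance.

    ``config`` is None for cohorts loaded from external files.
    """

    config: SimulationConfig | None
    partition: NetworkPartition
    recordings: tuple[Recording, ...]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"subject": r.subject, "state": r.state, "class": r.state_class}
                for r in self.recordings
            ]
        )

    def baseline_of(self, subject: str) -> Recording:
        hits = [
            r for r in self.recordings if r.subject == subject and r.state_class == BASELINE
        ]
        if len(hits) != 1:
            raise ValueError(
                f"subject {subject!r} has {len(hits)} baseline recordings, expected 1"
            )
        return hits[0]


def state_covariance(
    config: SimulationConfig, state: StateSpec, subject_effect: float = 0.0
) -> np.ndarray:
    """Block-constant correlation matrix for one subject in one state.

    Within-network entries are ``w_base + delta_within + subject_effect`` and
    between-network entries ``b_base + delta_between + subject_effect``, both
    clipped into (-0.99, 0.99).  Positive definiteness is verified, with a
    diagonal jitter fallback capped at 1e-6 so that large silent jitter can
    never distort the target correlations.
    """
    w = float(np.clip(config.w_base + state.delta_within + subject_effect, -0.99, 0.99))
    b = float(np.clip(config.b_base + state.delta_between + subject_effect, -0.99, 0.99))
    n = config.n_rois
    if config.network_sizes:
        sizes = list(config.network_sizes)
    else:
        base, extra = divmod(n, 7)
        sizes = [base + (1 if i < extra else 0) for i in range(7)]
    cov = np.full((n, n), b)
    start = 0
    for size in sizes:
        cov[start : start + size, start : start + size] = w
        start += size
    np.fill_diagonal(cov, 1.0)
    jitter = 0.0
    while True:
        try:
            np.linalg.cholesky(cov + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0.0 else jitter * 10.0
            if jitter > _MAX_JITTER:
                raise SimulationError(
                    f"state {state.name!r}: covariance not positive definite "
                    f"(w={w:.3f}, b={b:.3f}) even with jitter {_MAX_JITTER:g}"
                )
    if jitter:
        cov = cov + jitter * np.eye(n)
    return cov


def _stream(seed: int, *labels: str) -> np.random.Generator:
    """Independent, label-addressed RNG stream derived from the master seed."""
    digest = hashlib.sha256("/".join(labels).encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def _sample_series(
    cov: np.ndarray,
    n_frames: int,
    ar_coef: float,
    noise_scale: float,
    roi_ids: tuple[str, ...],
    frame_interval: float,
    rng: np.random.Generator,
) -> TimeSeriesMatrix:
    n = cov.shape[0]
    chol = np.linalg.cholesky(cov)
    innov = rng.standard_normal((n_frames, n)) @ chol.T
    if ar_coef > 0.0:
        # stationary AR(1): x[t] = phi x[t-1] + sqrt(1-phi^2) innov[t], x[0] = innov[0]
        damp = np.sqrt(1.0 - ar_coef**2)
        zi = ((1.0 - damp) * innov[0])[None, :]
        x, _ = lfilter([damp], [1.0, -ar_coef], innov, axis=0, zi=zi)
    else:
        x = innov
    if noise_scale > 1.0:
        x = x + np.sqrt(noise_scale**2 - 1.0) * rng.standard_normal(x.shape)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return TimeSeriesMatrix(x, roi_ids, frame_interval)


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Simulate every subject x condition recording of the configured cohort.

    Each altered state receives its own cohort of ``n_subjects_per_state``
    subjects; every subject contributes a baseline recording and one
    altered-state recording.  A scalar per-subject coupling effect (drawn once
    and shared across that subject's two conditions) induces the paired
    correlation structure that makes within-subject contrasts more powerful
    than unpaired ones.  Reproducible bit-for-bit from ``config.seed``.
    """
    partition = config.partition()
    recordings: list[Recording] = []
    for state in config.states:
        eff_rng = _stream(config.seed, "subject_effects", state.name)
        effects = eff_rng.normal(0.0, config.subject_sd, config.n_subjects_per_state)
        # truncate at +-2.5 sd: extreme draws could push the between-network
        # coupling negative enough to break positive definiteness
        effects = np.clip(effects, -2.5 * config.subject_sd, 2.5 * config.subject_sd)
        for i, subj_eff in enumerate(effects):
            subject = f"{state.name}_s{i + 1:02d}"
            for spec in (BASELINE_STATE, state):
                cov = state_covariance(config, spec, float(subj_eff))
                rng = _stream(config.seed, "series", state.name, subject, spec.name)
                series = _sample_series(
                    cov,
                    config.n_frames,
                    spec.ar_coef,
                    spec.noise_scale,
                    partition.roi_ids,
                    config.frame_interval,
                    rng,
                )
                recordings.append(
                    Recording(subject, spec.name, spec.state_class, series)
                )
    return CohortDataset(config, partition, tuple(recordings))


def zero_delta_config(seed: int, **overrides) -> SimulationConfig:
    """A null cohort: all states keep baseline coupling and dynamics."""
    base = SimulationConfig(seed=seed, **overrides)
    null_states = tuple(
        replace(s, delta_within=0.0, delta_between=0.0, ar_coef=BASELINE_STATE.ar_coef)
        for s in base.states
    )
    return replace(base, states=null_states)
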