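"""Synthetic MEG epoch generator with known spatial patterns and dynamics.

Each simulated subject mimics the retro-cue study design: a ``perception``
segment (stimulus-locked), a paired ``imagery`` segment (cue-locked, same
trials in the same order, weaker signal), a 2-channel ``eyetrack`` segment,
and per-trial vividness ratings on the study's [-150, 150] scale.

Class information is injected as signed spatial patterns: trials of class 1
("face") add ``+snr * envelope(t) * pattern`` to the sensor noise and class 0
("house") trials add the mirrored ``-snr * ...``, so chance level is exactly
0.5 and the Bayes-optimal accuracy has a closed form
(:func:`oracle_accuracy`). Temporal dynamics are selected by scenario:

``sequential``
    ``n_patterns`` orthogonal patterns in disjoint consecutive windows, each
    with a Hann-shaped transient envelope (transient evoked components wax
    and wane rather than switching on and off).
``sustained``
    one pattern with a long plateau (boxcar envelope).
``reactivation``
    one pattern active in two disjoint windows.
``jittered``
    the sequential dynamics with a per-trial onset shift; the shift is
    non-negative (half-normal, scaled so its SD equals ``jitter_sd_s``)
    because it models the variable latency of a cue-triggered process.
``null``
    sensor noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.cluster import KMeans

from .epochs import EpochsArray, TimeWindow
from .source import LeadField

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SubjectData",
    "simulate_subject",
    "simulate_group",
    "make_leadfield",
    "oracle_accuracy",
]

_HALF_NORMAL_SD = np.sqrt(1.0 - 2.0 / np.pi)  # SD of |N(0,1)|


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Ground-truth description of a simulated study.

    Defaults reproduce the study conditions: 270 sensors at 300 Hz, 107
    trials per class and condition, 25 subjects, imagery signal at 0.4 of
    the perception amplitude.
    """

    scenario: str = "sustained"
    n_sensors: int = 270
    fs: float = 300.0
    n_trials_per_class: int = 107
    epoch_window: TimeWindow = field(default_factory=lambda: TimeWindow(-0.2, 1.0))
    pattern_times: list[TimeWindow] | None = None
    n_patterns: int | None = None
    snr: float = 0.7
    imagery_snr_factor: float = 0.4
    imagery_patterns: list[int] | None = None
    imagery_window: TimeWindow | None = None
    jitter_sd_s: float = 0.0
    jitter_dist: str = "halfnormal"  # or "normal"
    noise_spatial_corr: float = 0.0
    eye_effect: float = 0.0
    vividness_mean: float = 50.0
    vividness_between_sd: float = 25.0
    vividness_trial_sd: float = 30.0
    vividness_snr_corr: float = 0.0
    snr_subject_sd: float = 0.15
    source_space: bool = False
    n_sources: int = 50
    seed: int = 0
    n_subjects: int = 25

    def __post_init__(self) -> None:
        if self.scenario not in {"sequential", "sustained", "reactivation", "jittered", "null"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.jitter_sd_s < 0:
            raise ValueError("jitter_sd_s must be >= 0")
        if self.jitter_sd_s > 0 and self.scenario != "jittered":
            raise ValueError("jitter_sd_s > 0 requires scenario='jittered'")
        if not 0 <= self.noise_spatial_corr < 1:
            raise ValueError("noise_spatial_corr must be in [0, 1)")
        if self.pattern_times is None:
            self.pattern_times = self._default_pattern_times()
        else:
            self.pattern_times = [
                tw if isinstance(tw, TimeWindow) else TimeWindow(*tw) for tw in self.pattern_times
            ]
        if self.n_patterns is None:
            self.n_patterns = self._default_n_patterns()
        for tw in self.pattern_times:
            if tw.start_s < self.epoch_window.start_s - 1e-9 or tw.end_s > self.epoch_window.end_s + 1e-9:
                raise ValueError(f"pattern window {tw} outside epoch window {self.epoch_window}")
        if self.scenario in ("sequential", "jittered"):
            ordered = sorted(self.pattern_times, key=lambda w: w.start_s)
            for a, b in zip(ordered, ordered[1:]):
                if b.start_s < a.end_s - 1e-9:
                    raise ValueError(
                        f"sequential pattern windows must be disjoint; {a} overlaps {b}"
                    )
            if len(self.pattern_times) != self.n_patterns:
                raise ValueError("sequential scenario needs one window per pattern")
        if self.imagery_window is None:
            self.imagery_window = TimeWindow(0.1, self.epoch_window.end_s - 0.1)

    def _default_pattern_times(self) -> list[TimeWindow]:
        if self.scenario == "null":
            return []
        # active span: 100 ms after onset up to 0.7 s (clipped to the epoch)
        s0 = 0.1
        s1 = min(0.7, self.epoch_window.end_s - 0.05)
        if s1 - s0 < 0.05:
            raise ValueError("epoch window too short for default pattern times")
        span = s1 - s0
        if self.scenario == "sustained":
            return [TimeWindow(s0, s1)]
        if self.scenario == "reactivation":
            return [
                TimeWindow(s0, s0 + 0.3 * span),
                TimeWindow(s0 + 0.6 * span, s0 + 0.9 * span),
            ]
        # sequential / jittered
        k = self.n_patterns or 3
        edges = s0 + span * np.linspace(0.0, 1.0, k + 1)
        return [TimeWindow(edges[i], edges[i + 1]) for i in range(k)]

    def _default_n_patterns(self) -> int:
        if self.scenario == "null":
            return 0
        if self.scenario in ("sustained", "reactivation"):
            return 1
        return len(self.pattern_times)

    @property
    def envelope_shape(self) -> str:
        return "hann" if self.scenario in ("sequential", "jittered") else "boxcar"

    def times(self) -> np.ndarray:
        n = int(round(self.epoch_window.duration * self.fs))
        return self.epoch_window.start_s + np.arange(n) / self.fs

    def pattern_windows(self) -> list[list[TimeWindow]]:
        """Windows per pattern (a reactivating pattern owns several windows)."""
        if self.scenario == "reactivation":
            return [list(self.pattern_times)]
        return [[tw] for tw in self.pattern_times]


@dataclass
class GroundTruth:
    """What the generator injected, for recovery tests."""

    patterns: np.ndarray  # (n_patterns, n_sensors), unit-norm rows
    envelopes: np.ndarray  # (n_patterns, n_samples) at zero onset shift
    onsets: np.ndarray  # per-trial onset shift, seconds (perception segment)
    imagery_onsets: np.ndarray
    shared_patterns: list[int]  # pattern indices present in the imagery segment
    pattern_windows: list[list[TimeWindow]]
    active_sources: list[int] | None = None  # source index per pattern (source-space mode)


@dataclass
class SubjectData:
    perception: EpochsArray
    imagery: EpochsArray
    eyetrack: EpochsArray
    vividness: np.ndarray  # per-trial, in [-150, 150]
    truth: GroundTruth
    leadfield: "LeadField | None" = None  # rank-reduced, set in source-space mode

    def __post_init__(self) -> None:
        for seg in (self.imagery, self.eyetrack):
            if seg.n_trials != self.perception.n_trials or not np.array_equal(
                seg.labels, self.perception.labels
            ):
                raise ValueError("condition segments must be trial-paired (same labels order)")

    def save(self, directory) -> None:
        """Write the subject as a directory of epoch sets plus ground truth."""
        import json as _json
        from pathlib import Path as _Path

        d = _Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.perception.save(d / "perception")
        self.imagery.save(d / "imagery")
        self.eyetrack.save(d / "eyetrack")
        np.save(d / "vividness.npy", self.vividness)
        t = self.truth
        np.savez(
            d / "truth.npz",
            patterns=t.patterns,
            envelopes=t.envelopes,
            onsets=t.onsets,
            imagery_onsets=t.imagery_onsets,
        )
        meta = {
            "shared_patterns": list(t.shared_patterns),
            "pattern_windows": [
                [[w.start_s, w.end_s] for w in ws] for ws in t.pattern_windows
            ],
            "active_sources": t.active_sources,
        }
        (d / "truth.json").write_text(_json.dumps(meta, sort_keys=True))
        if self.leadfield is not None:
            np.savez(
                d / "leadfield.npz",
                gains=self.leadfield.gains,
                surface_normals=self.leadfield.surface_normals,
                region_labels=self.leadfield.region_labels,
            )

    @classmethod
    def load(cls, directory) -> "SubjectData":
        import json as _json
        from pathlib import Path as _Path

        d = _Path(directory)
        meta = _json.loads((d / "truth.json").read_text())
        arrays = np.load(d / "truth.npz")
        truth = GroundTruth(
            patterns=arrays["patterns"],
            envelopes=arrays["envelopes"],
            onsets=arrays["onsets"],
            imagery_onsets=arrays["imagery_onsets"],
            shared_patterns=list(meta["shared_patterns"]),
            pattern_windows=[
                [TimeWindow(*w) for w in ws] for ws in meta["pattern_windows"]
            ],
            active_sources=meta.get("active_sources"),
        )
        leadfield = None
        if (d / "leadfield.npz").exists():
            lf = np.load(d / "leadfield.npz")
            leadfield = LeadField(
                gains=lf["gains"],
                surface_normals=lf["surface_normals"],
                region_labels=lf["region_labels"],
            )
        return cls(
            perception=EpochsArray.load(d / "perception"),
            imagery=EpochsArray.load(d / "imagery"),
            eyetrack=EpochsArray.load(d / "eyetrack"),
            vividness=np.load(d / "vividness.npy"),
            truth=truth,
            leadfield=leadfield,
        )


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

def _envelope(times: np.ndarray, windows: Sequence[TimeWindow], shape: str,
              shifts: np.ndarray) -> np.ndarray:
    """Per-trial activation envelope, (n_trials, n_samples), values in [0, 1]."""
    t = times[None, :] - shifts[:, None]
    env = np.zeros_like(t)
    for w in windows:
        inside = (t >= w.start_s) & (t < w.end_s)
        if shape == "hann":
            phase = (t - w.start_s) / w.duration
            env = np.where(inside, np.maximum(env, np.sin(np.pi * phase) ** 2), env)
        else:
            env = np.where(inside, 1.0, env)
    return env


def _draw_patterns(rng: np.random.Generator, n_patterns: int, n_sensors: int) -> np.ndarray:
    if n_patterns == 0:
        return np.zeros((0, n_sensors))
    g = rng.standard_normal((n_sensors, n_patterns))
    q, _ = np.linalg.qr(g)
    return q.T  # orthonormal rows


def _draw_onsets(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    if config.scenario != "jittered" or config.jitter_sd_s == 0:
        return np.zeros(n)
    if config.jitter_dist == "halfnormal":
        scale = config.jitter_sd_s / _HALF_NORMAL_SD
        return np.abs(rng.normal(0.0, scale, size=n))
    if config.jitter_dist == "normal":
        return rng.normal(0.0, config.jitter_sd_s, size=n)
    raise ValueError(f"unknown jitter_dist {config.jitter_dist!r}")


def _noise(rng: np.random.Generator, shape: tuple, corr: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if corr > 0:
        # equicorrelated sensors: x -> sqrt(1-c) e + sqrt(c) shared
        shared = rng.standard_normal((shape[0], 1, shape[2]))
        noise = np.sqrt(1 - corr) * noise + np.sqrt(corr) * shared
    return noise


# ---------------------------------------------------------------------------
# subject / group simulation
# ---------------------------------------------------------------------------

def simulate_subject(config: SimulationConfig, subject_seed: int,
                     leadfield: LeadField | None = None,
                     active_sources: list[int] | None = None) -> SubjectData:
    """Generate one subject's paired perception / imagery / eyetrack segments.

    In source-space mode a shared (template) ``leadfield`` and the pattern's
    ``active_sources`` may be supplied so that atlas regions correspond
    across the subjects of a group; the dipole moment directions are still
    drawn per subject.
    """
    rng = np.random.default_rng(subject_seed)
    times = config.times()
    n_samples = times.size
    n_trials = 2 * config.n_trials_per_class

    labels = rng.permutation(
        np.repeat(np.array([0, 1]), config.n_trials_per_class)
    )
    signs = (2 * labels - 1).astype(np.float64)

    if not config.source_space:
        leadfield = None
        active_sources = None
    if config.source_space:
        # patterns are fields of tangential dipoles at distinct random sources
        from .source import rank_reduce  # local import avoids cycle at module load

        if leadfield is None:
            lf_seed = int(rng.integers(0, 2**31 - 1))
            leadfield = rank_reduce(
                make_leadfield(config.n_sources, config.n_sensors, lf_seed)
            )
        elif leadfield.n_orientations != 2:
            leadfield = rank_reduce(leadfield)
        if active_sources is None:
            active_sources = rng.choice(
                config.n_sources, size=config.n_patterns, replace=False
            ).tolist()
        patterns = np.empty((config.n_patterns, config.n_sensors))
        for k, s in enumerate(active_sources):
            moment = rng.standard_normal(2)
            moment /= np.linalg.norm(moment)
            v = moment @ leadfield.gains[s]
            patterns[k] = v / np.linalg.norm(v)
    else:
        patterns = _draw_patterns(rng, config.n_patterns, config.n_sensors)
    per_pattern_windows = config.pattern_windows()

    subject_id = f"S{subject_seed % 10_000:04d}"

    # ---- perception ----
    onsets = _draw_onsets(rng, config, n_trials)
    data_p = _noise(rng, (n_trials, config.n_sensors, n_samples), config.noise_spatial_corr)
    for k, windows in enumerate(per_pattern_windows):
        env = _envelope(times, windows, config.envelope_shape, onsets)
        data_p += config.snr * signs[:, None, None] * env[:, None, :] * patterns[k][None, :, None]
    perception = EpochsArray(
        data=data_p, labels=labels, times=times, fs=config.fs,
        condition="perception", subject_id=subject_id,
    )

    # ---- imagery: shared patterns re-expressed in a broad sustained window ----
    shared = (
        list(range(config.n_patterns))
        if config.imagery_patterns is None
        else list(config.imagery_patterns)
    )
    imagery_onsets = _draw_onsets(rng, config, n_trials)
    data_i = _noise(rng, (n_trials, config.n_sensors, n_samples), config.noise_spatial_corr)
    ima_amp = config.snr * config.imagery_snr_factor
    for k in shared:
        env = _envelope(times, [config.imagery_window], "boxcar", imagery_onsets)
        data_i += ima_amp * signs[:, None, None] * env[:, None, :] * patterns[k][None, :, None]
    imagery = EpochsArray(
        data=data_i, labels=labels, times=times, fs=config.fs,
        condition="imagery", subject_id=subject_id,
    )

    # ---- eye tracker: X/Y gaze position, class effect only if configured ----
    data_e = rng.standard_normal((n_trials, 2, n_samples))
    if config.eye_effect > 0 and per_pattern_windows:
        all_windows = [w for ws in per_pattern_windows for w in ws]
        env = _envelope(times, all_windows, "boxcar", onsets)
        data_e[:, 0, :] += config.eye_effect * signs[:, None] * env
    eyetrack = EpochsArray(
        data=data_e, labels=labels, times=times, fs=config.fs,
        channels=["EYE_X", "EYE_Y"], condition="eyetrack", subject_id=subject_id,
    )

    vividness = np.clip(
        rng.normal(config.vividness_mean, config.vividness_trial_sd, size=n_trials),
        -150.0, 150.0,
    )

    env0 = np.zeros((config.n_patterns, n_samples))
    for k, windows in enumerate(per_pattern_windows):
        env0[k] = _envelope(times, windows, config.envelope_shape, np.zeros(1))[0]
    truth = GroundTruth(
        patterns=patterns, envelopes=env0, onsets=onsets, imagery_onsets=imagery_onsets,
        shared_patterns=shared, pattern_windows=per_pattern_windows,
        active_sources=active_sources,
    )
    return SubjectData(perception, imagery, eyetrack, vividness, truth,
                       leadfield=leadfield)


def simulate_group(config: SimulationConfig) -> list[SubjectData]:
    """Simulate ``config.n_subjects`` independent subjects.

    Subject seeds, between-subject SNR variation (log-normal) and subject
    mean vividness are all derived deterministically from ``config.seed``.
    ``vividness_snr_corr`` couples vividness to SNR at the subject level to
    exercise median-split analyses.
    """
    if config.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=config.n_subjects)
    z_snr = root.standard_normal(config.n_subjects)
    z_viv = root.standard_normal(config.n_subjects)
    rho = config.vividness_snr_corr
    leadfield = None
    active_sources = None
    if config.source_space:
        # one template anatomy per group so atlas regions correspond
        from .source import rank_reduce

        leadfield = rank_reduce(
            make_leadfield(config.n_sources, config.n_sensors,
                           int(root.integers(0, 2**31 - 1)))
        )
        active_sources = root.choice(
            config.n_sources, size=config.n_patterns, replace=False
        ).tolist()
    subjects = []
    for i in range(config.n_subjects):
        snr_i = config.snr * np.exp(config.snr_subject_sd * z_snr[i])
        viv_i = config.vividness_mean + config.vividness_between_sd * (
            rho * z_snr[i] + np.sqrt(max(0.0, 1 - rho**2)) * z_viv[i]
        )
        cfg_i = replace(config, snr=snr_i, vividness_mean=viv_i)
        subj = simulate_subject(cfg_i, int(seeds[i]), leadfield=leadfield,
                                active_sources=active_sources)
        subj.perception.subject_id = subj.imagery.subject_id = subj.eyetrack.subject_id = f"S{i:02d}"
        subjects.append(subj)
    return subjects


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def make_leadfield(n_sources: int, n_sensors: int, seed: int,
                   n_regions: int | None = None) -> LeadField:
    """Random smooth forward model for source-reconstruction tests.

    Sources sit on an upper hemisphere with radial surface normals; sensors
    on a surrounding cap. Gains are spatially smooth random fields with a
    distance fall-off, scaled to equal per-source norms. Atlas regions are
    contiguous azimuthal sectors of sources.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    rng = np.random.default_rng(seed)

    def hemisphere(n: int, radius: float) -> np.ndarray:
        z = rng.uniform(0.15, 1.0, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        r = np.sqrt(1 - z**2)
        return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    src = hemisphere(n_sources, 0.8)
    sens = hemisphere(n_sensors, 1.1)

    # smoothing kernel over the sensor array; scales chosen so that each
    # source projects a focal, spatially coherent field distinguishable
    # from non-neighbouring sources
    d2 = ((sens[:, None, :] - sens[None, :, :]) ** 2).sum(-1)
    smooth = np.exp(-d2 / (2 * 0.15**2))

    gains = np.empty((n_sources, 3, n_sensors))
    for s in range(n_sources):
        falloff = np.exp(-((sens - src[s]) ** 2).sum(-1) / (2 * 0.35**2))
        raw = rng.standard_normal((3, n_sensors)) @ smooth
        block = raw * falloff[None, :]
        norm = np.linalg.norm(block)
        if norm < 1e-12:
            raise ValueError(f"degenerate (all-zero) gains for source {s}")
        # orthonormalize the three orientation fields (spans and smoothness
        # preserved) so every source has a well-conditioned gain block, as
        # physical forward models do
        q, _ = np.linalg.qr(block.T)
        gains[s] = q.T

    normals = src / np.linalg.norm(src, axis=1, keepdims=True)

    if n_regions is None:
        n_regions = max(1, min(74, n_sources // 5 or 1))
    if n_regions >= n_sources:
        region_labels = np.arange(1, n_sources + 1, dtype=np.int64)
    else:
        # contiguous spatial patches (neighbouring sources share leakage)
        km = KMeans(n_clusters=n_regions, random_state=int(seed) % (2**32), n_init=4)
        region_labels = km.fit_predict(src).astype(np.int64) + 1

    return LeadField(
        gains=gains,
        surface_normals=normals,
        source_ids=[f"src{s:03d}" for s in range(n_sources)],
        region_labels=region_labels,
    )


# ---------------------------------------------------------------------------
# closed-form decoding oracle
# ---------------------------------------------------------------------------

def oracle_accuracy(delta_mu: np.ndarray, sigma: np.ndarray) -> float:
    """Bayes accuracy for two equal-prior Gaussians: Phi(d/2).

    ``d`` is the Mahalanobis distance between the class means under the
    common covariance ``sigma``.
    """
    delta_mu = np.atleast_1d(np.asarray(delta_mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    try:
        factor = cho_factor(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sigma must be symmetric positive definite") from exc
    d = float(np.sqrt(delta_mu @ cho_solve(factor, delta_mu)))
    return float(sp_stats.norm.cdf(d / 2.0))
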