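"""Synthetic MEG generator: narrow-band cortical sources through a toy lead field.

The generator emulates the statistical structure the analysis pipeline
assumes: stimulus-locked narrow-band bursts at a handful of cortical
patches, mixed into sensors by a smooth distance-decaying gain matrix,
on top of spatially structured 1/f background activity plus white sensor
noise.  The reference configuration (:func:`three_source_spec`) places
two 3 Hz delta sources at the left and right supramarginal gyri and one
7 Hz theta source at the right inferior frontal gyrus, sampled at 200 Hz
over -100...1000 ms epochs for a 16-participant cohort — the setting
used throughout the validation suite.

No anatomical realism is attempted: patches are points on a unit sphere
and gains are Gaussian in sensor-to-patch distance.  The physics kept is
what the downstream linear inverse actually relies on — linearity,
smooth spatial mixing, and structured noise covariance.

All randomness flows from explicit integer seeds; identical spec + seed
gives identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import Epochs

__all__ = [
    "SourceSpec",
    "Envelope",
    "LeadField",
    "NoiseModel",
    "SimulationSpec",
    "make_toy_lead_field",
    "simulate_participant",
    "simulate_cohort",
    "three_source_spec",
    "default_patches",
    "simulate_null_auc_cohort",
    "simulate_effect_auc_cohort",
    "one_over_f_noise",
]


@dataclass(frozen=True)
class Envelope:
    """Raised-cosine burst envelope, times in ms post stimulus onset."""

    onset: float = 80.0
    rise: float = 50.0
    fall: float = 50.0
    end: float = 480.0

    def __call__(self, times_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(times_ms, dtype=float)
        env = np.zeros_like(t)
        up = (t >= self.onset) & (t < self.onset + self.rise)
        env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - self.onset) / self.rise))
        flat = (t >= self.onset + self.rise) & (t < self.end - self.fall)
        env[flat] = 1.0
        down = (t >= self.end - self.fall) & (t < self.end)
        env[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - (self.end - self.fall)) / self.fall))
        return env


@dataclass(frozen=True)
class SourceSpec:
    """One oscillatory cortical source."""

    label: str
    freq: float  # Hz
    amplitude: float = 1.0
    envelope: Envelope = field(default_factory=Envelope)
    hemisphere: str = "left"

    def validate(self, fs: float, epoch_window: tuple[float, float]) -> None:
        if not 0 < self.freq < fs / 2:
            raise ValueError(f"source {self.label}: freq {self.freq} outside (0, fs/2)")
        if self.envelope.end > epoch_window[1] or self.envelope.onset < epoch_window[0]:
            raise ValueError(
                f"source {self.label}: envelope {self.envelope.onset}-{self.envelope.end} ms "
                f"outside epoch window {epoch_window}"
            )


@dataclass
class LeadField:
    """Forward operator: sensors x sources gain matrix."""

    gain: np.ndarray
    source_labels: list[str]
    sensor_ids: list[str]
    sensor_positions: np.ndarray | None = None
    patch_positions: np.ndarray | None = None

    def __post_init__(self):
        if self.gain.shape != (len(self.sensor_ids), len(self.source_labels)):
            raise ValueError("gain shape inconsistent with label lists")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field must be finite")
        if np.any(np.all(self.gain == 0, axis=0)):
            raise ValueError("lead field has an all-zero column")

    def column(self, label: str) -> np.ndarray:
        return self.gain[:, self.source_labels.index(label)]


@dataclass(frozen=True)
class NoiseModel:
    """Sensor white noise + spatially structured 1/f^alpha background."""

    sensor_white_sd: float = 0.5
    background_exponent: float = 1.0
    background_scale: float = 1.5
    n_background_patches: int = 20

    def __post_init__(self):
        if self.sensor_white_sd < 0:
            raise ValueError("sensor_white_sd must be >= 0")
        if not 0 <= self.background_exponent <= 2:
            raise ValueError("background exponent must lie in [0, 2]")


@dataclass
class SimulationSpec:
    """Complete recipe for one simulated cohort."""

    sources: list[SourceSpec]
    lead_field: LeadField
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_trials_per_condition: int = 60
    n_participants: int = 16
    fs: float = 200.0
    epoch_window: tuple[float, float] = (-100.0, 1000.0)
    # condition -> {source_label: amplitude multiplier}; every key defines a condition
    condition_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"A": {}, "B": {}}
    )
    phase_locked: bool = True
    participant_amp_sd: float = 0.2  # lognormal sigma of per-participant gain

    def validate(self) -> None:
        for s in self.sources:
            s.validate(self.fs, self.epoch_window)
        for cond, effects in self.condition_effects.items():
            unknown = set(effects) - {s.label for s in self.sources}
            if unknown:
                raise ValueError(f"condition {cond}: unknown source labels {unknown}")


# ---------------------------------------------------------------------------
# toy geometry


def _fibonacci_hemisphere(n: int, radius: float = 1.1) -> np.ndarray:
    """Roughly uniform sensor positions on the upper hemisphere."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = i / max(n - 1, 1)  # 0..1 -> upper half
    r = np.sqrt(np.clip(1 - z**2, 0, 1))
    theta = 2 * np.pi * i / golden
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_toy_lead_field(
    n_sensors: int,
    patches: list[tuple[str, np.ndarray]],
    geometry_seed: int = 0,
    decay: float = 0.6,
) -> LeadField:
    """Gaussian distance-decay gain from point patches to hemisphere sensors.

    Column j is ``exp(-d_ij^2 / (2 decay^2))`` for sensor-to-patch
    distances d; a seeded jitter (2% of radius) makes distinct geometry
    seeds give distinct but reproducible arrays.
    """
    if n_sensors < 3:
        raise ValueError("need at least 3 sensors")
    labels = [p[0] for p in patches]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate patch labels")
    pos = np.array([np.asarray(p[1], dtype=float) for p in patches])
    if len(pos) > 1:
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        if np.any(d[np.triu_indices(len(pos), 1)] == 0):
            raise ValueError("patch positions must be distinct")
    rng = np.random.default_rng(geometry_seed)
    sens = _fibonacci_hemisphere(n_sensors)
    sens = sens + 0.02 * rng.standard_normal(sens.shape)
    dist = np.linalg.norm(sens[:, None, :] - pos[None, :, :], axis=-1)
    gain = np.exp(-(dist**2) / (2 * decay**2))
    return LeadField(
        gain=gain,
        source_labels=labels,
        sensor_ids=[f"MEG{i:03d}" for i in range(n_sensors)],
        sensor_positions=sens,
        patch_positions=pos,
    )


#: nominal patch positions on the unit sphere (x: left->right, y: back->front)
DEFAULT_PATCH_POSITIONS = {
    "supramarginal-lh": np.array([-0.75, -0.35, 0.56]),
    "supramarginal-rh": np.array([0.75, -0.35, 0.56]),
    "inferiorfrontal-rh": np.array([0.62, 0.60, 0.50]),
}


def default_patches() -> list[tuple[str, np.ndarray]]:
    return [(k, v.copy()) for k, v in DEFAULT_PATCH_POSITIONS.items()]


def three_source_spec(
    n_sensors: int = 102,
    geometry_seed: int = 0,
    n_trials_per_condition: int = 60,
    n_participants: int = 16,
    condition_effects: dict[str, dict[str, float]] | None = None,
    noise: NoiseModel | None = None,
) -> SimulationSpec:
    """The reference three-source simulation.

    Two phase-locked 3 Hz (delta) evoked sources at the left and right
    supramarginal patches and one 7 Hz (theta) source at the right
    inferior frontal patch.
    """
    lf = make_toy_lead_field(n_sensors, default_patches(), geometry_seed)
    sources = [
        SourceSpec("supramarginal-lh", 3.0, hemisphere="left"),
        SourceSpec("supramarginal-rh", 3.0, hemisphere="right"),
        SourceSpec("inferiorfrontal-rh", 7.0, hemisphere="right"),
    ]
    return SimulationSpec(
        sources=sources,
        lead_field=lf,
        noise=noise or NoiseModel(),
        n_trials_per_condition=n_trials_per_condition,
        n_participants=n_participants,
        condition_effects=condition_effects or {"A": {}, "B": {}},
    )


# ---------------------------------------------------------------------------
# noise


def one_over_f_noise(
    shape: tuple[int, ...], fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit variance."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2)
    scale[0] = 0.0
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1) * scale
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


# ---------------------------------------------------------------------------
# simulation


def _source_traces(
    spec: SimulationSpec,
    cond: str,
    rng: np.random.Generator,
    amp_scale: float,
) -> np.ndarray:
    """Noise-free source traces for one trial: (n_sources, n_samples)."""
    tmin, tmax = spec.epoch_window
    n = int(round((tmax - tmin) * spec.fs / 1000.0)) + 1
    times = tmin + 1000.0 * np.arange(n) / spec.fs
    effects = spec.condition_effects.get(cond, {})
    traces = np.zeros((len(spec.sources), n))
    for j, src in enumerate(spec.sources):
        mult = effects.get(src.label, 1.0)
        phase = 0.0 if spec.phase_locked else rng.uniform(0, 2 * np.pi)
        carrier = np.sin(
            2 * np.pi * src.freq * (times - src.envelope.onset) / 1000.0 + phase
        )
        traces[j] = amp_scale * mult * src.amplitude * src.envelope(times) * carrier
    return traces


def simulate_participant(
    spec: SimulationSpec,
    participant_seed: int,
    participant_id: str = "",
    amp_scale: float = 1.0,
) -> tuple[Epochs, np.ndarray]:
    """Simulate one participant's epochs.

    Returns ``(epochs, truth)`` where ``truth`` has shape (n_trials,
    n_sources, n_samples) holding the noise-free source time courses of
    every trial (for oracle checks and inverse validation).
    """
    spec.validate()
    rng = np.random.default_rng(participant_seed)
    lf = spec.lead_field
    n_sens = lf.gain.shape[0]
    tmin, tmax = spec.epoch_window
    n = int(round((tmax - tmin) * spec.fs / 1000.0)) + 1

    # nuisance patches for structured background, fixed per participant
    nuis_pos = rng.standard_normal((spec.noise.n_background_patches, 3))
    nuis_pos /= np.linalg.norm(nuis_pos, axis=1, keepdims=True)
    if lf.sensor_positions is not None:
        d = np.linalg.norm(
            lf.sensor_positions[:, None, :] - nuis_pos[None, :, :], axis=-1
        )
        nuis_gain = np.exp(-(d**2) / (2 * 0.6**2))
    else:  # externally supplied lead field without geometry: random smooth maps
        nuis_gain = rng.standard_normal((n_sens, spec.noise.n_background_patches))

    # map each source to its lead-field column by label
    if spec.sources:
        mix = np.column_stack([lf.column(s.label) for s in spec.sources])
    else:
        mix = np.zeros((n_sens, 0))

    conditions = list(spec.condition_effects)
    data, labels, truths = [], [], []
    for cond in conditions:
        for _ in range(spec.n_trials_per_condition):
            truth = _source_traces(spec, cond, rng, amp_scale)
            x = mix @ truth
            if spec.noise.background_scale > 0:
                bg = one_over_f_noise(
                    (spec.noise.n_background_patches, n),
                    spec.fs,
                    spec.noise.background_exponent,
                    rng,
                )
                x = x + spec.noise.background_scale * (nuis_gain @ bg) / np.sqrt(
                    spec.noise.n_background_patches
                )
            if spec.noise.sensor_white_sd > 0:
                x = x + spec.noise.sensor_white_sd * rng.standard_normal((n_sens, n))
            data.append(x)
            labels.append(cond)
            truths.append(truth)

    # deterministic interleave of conditions (labels carry the information)
    epochs = Epochs(
        data=np.stack(data),
        fs=spec.fs,
        tmin=tmin,
        labels=np.array(labels),
        participant_id=participant_id,
        channel_ids=list(lf.sensor_ids),
    )
    return epochs, np.stack(truths)


def simulate_cohort(
    spec: SimulationSpec, master_seed: int
) -> list[tuple[Epochs, np.ndarray]]:
    """Simulate every participant with seeds derived from ``master_seed``.

    Inter-participant variability is a lognormal amplitude multiplier
    (sigma = ``spec.participant_amp_sd``) applied to all sources.
    """
    if spec.n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(spec.n_participants + 1)
    amp_rng = np.random.default_rng(children[-1])
    out = []
    for p in range(spec.n_participants):
        amp = float(np.exp(amp_rng.normal(0.0, spec.participant_amp_sd)))
        seed = int(children[p].generate_state(1)[0] % (2**31))
        out.append(
            simulate_participant(spec, seed, participant_id=f"sub-{p + 1:02d}", amp_scale=amp)
        )
    return out


# ---------------------------------------------------------------------------
# chance-level effect-series generators (group-statistics calibration)


def simulate_null_auc_cohort(
    n_participants: int,
    n_timepoints: int,
    seed: int,
    sd: float = 0.03,
    smooth: float = 2.0,
) -> np.ndarray:
    """Chance-level AUC time series: 0.5 + smooth symmetric noise.

    Temporal autocorrelation (Gaussian kernel, ``smooth`` samples) mimics
    the smoothness of real decoding traces; the distribution is symmetric
    about 0.5 per participant, the exchangeability the sign-flip test
    requires.  Returns (n_participants, n_timepoints).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_participants, n_timepoints + 40))
    if smooth > 0:
        k = np.exp(-0.5 * (np.arange(-10, 11) / smooth) ** 2)
        k /= k.sum()
        x = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), -1, x)
        x /= x.std(axis=-1, keepdims=True)
    return 0.5 + sd * x[:, 20 : 20 + n_timepoints]


def simulate_effect_auc_cohort(
    n_participants: int,
    n_timepoints: int,
    seed: int,
    window: tuple[int, int],
    effect: float = 0.1,
    sd: float = 0.03,
    smooth: float = 2.0,
) -> np.ndarray:
    """Null cohort plus a constant AUC elevation inside ``window`` (samples)."""
    auc = simulate_null_auc_cohort(n_participants, n_timepoints, seed, sd, smooth)
    lo, hi = window
    auc[:, lo:hi] += effect
    return auc
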