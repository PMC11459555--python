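"""Synthetic multi-user discrete-gesture EMG cohort generator.

Surface EMG is modelled as amplitude-modulated zero-mean Gaussian noise: the
raw signal on channel ``c`` at sample ``t`` is

    s[c, t] = round(clip(gain[c] * envelope[c](t) * z + rest_sigma * z'))

with ``z, z'`` independent standard normal draws, quantized to signed 8-bit
integers (the Myo armband's raw sample range) at 200 Hz on 8 channels.  The
per-channel activation envelope of each gesture is a sum of raised-cosine
bumps placed inside an active segment whose duration is drawn from a normal
distribution (mean 1.3 s by default) and embedded in a longer rest-padded
recording (5 s by default), mirroring screen-guided discrete gesture
collections.

Inter-user variability is produced by per-user log-normal channel gains, a
log-normal elicitation-speed factor and a continuous circular rotation of the
channel activation pattern (an electrode-placement proxy).  Confounds (day,
limb position, speed) and demographic effects (systematic duration / rotation
shifts for a configured group) are optional and off by default.

All randomness flows from one root seed through named substreams, so every
profile and recording is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dataio import EMGRecording, ManifestEntry, DatasetManifest, write_cohort

__all__ = [
    "GestureSpec",
    "Condition",
    "UserProfile",
    "CohortConfig",
    "default_gesture_specs",
    "out_of_set_gesture_specs",
    "make_user_profile",
    "synthesize_recording",
    "inject_confound",
    "generate_cohort",
    "enumerate_manifest",
    "Cohort",
]

FS_HZ = 200
N_CHANNELS = 8
INT_MIN, INT_MAX = -128, 127

# substream tags so modules can be regenerated independently
_STREAM_USER = 1
_STREAM_RECORDING = 2
_STREAM_EFFECTS = 3


@dataclass(frozen=True)
class GestureSpec:
    """Generative description of one discrete gesture class.

    ``channel_amplitudes`` is the peak noise-amplitude per channel (raw
    integer units); ``bumps`` is a tuple of (center, width) pairs, both as
    fractions of the active-segment duration, of raised-cosine activation
    bumps shared across channels.  The rest class has all amplitudes zero.
    """

    gesture_id: str
    channel_amplitudes: tuple[float, ...]
    bumps: tuple[tuple[float, float], ...] = ((0.5, 0.9),)
    nominal_duration_mean: float = 1.3  # seconds
    nominal_duration_sd: float = 0.25  # seconds
    out_of_set: bool = False

    def __post_init__(self) -> None:
        if len(self.channel_amplitudes) != N_CHANNELS:
            raise ValueError("channel_amplitudes must have 8 entries")
        if any(a < 0 for a in self.channel_amplitudes):
            raise ValueError("peak amplitudes must be >= 0")


@dataclass(frozen=True)
class Condition:
    """A recording condition: day / limb-position level and speed multiplier.

    ``speed`` multiplies the gesture duration (1.5 = 50% slower, i.e. longer;
    2/3 = 50% faster).
    """

    name: str = "base"
    day: int = 1
    position: int = 1
    speed: float = 1.0


DEFAULT_CONDITION = Condition()


@dataclass(frozen=True)
class UserProfile:
    """A synthetic user's generative parameters."""

    user_id: str
    channel_gains: np.ndarray  # (8,) positive
    speed_factor: float
    channel_rotation: float  # fractional electrode rotation, in channels
    demographics: dict[str, str]
    day_effects: dict[int, np.ndarray]  # day level -> (8,) gain perturbation
    position_effects: dict[int, np.ndarray]
    rest_sigma: float = 2.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.channel_gains) <= 0):
            raise ValueError("channel_gains must be positive")
        if self.speed_factor <= 0 or self.rest_sigma <= 0:
            raise ValueError("speed_factor and rest_sigma must be positive")


def _amp_pattern(peaks: list[float]) -> tuple[float, ...]:
    return tuple(peaks)


def default_gesture_specs(amplitude: float = 35.0) -> list[GestureSpec]:
    """The six in-set classes with distinct channel-synergy patterns.

    Patterns loosely follow forearm flexor/extensor topography under an
    8-channel circumferential band; double tap has a two-bump time course.
    """
    a = amplitude
    return [
        GestureSpec("rest", _amp_pattern([0.0] * 8), bumps=()),
        GestureSpec(
            "wave_in",  # wrist flexion: flexor-side channels
            _amp_pattern([1.0 * a, 0.9 * a, 0.5 * a, 0.15 * a,
                          0.05 * a, 0.05 * a, 0.15 * a, 0.5 * a]),
        ),
        GestureSpec(
            "wave_out",  # wrist extension: extensor-side channels
            _amp_pattern([0.1 * a, 0.2 * a, 0.55 * a, 0.95 * a,
                          1.0 * a, 0.6 * a, 0.2 * a, 0.05 * a]),
        ),
        GestureSpec(
            "hand_open",  # broad moderate activation
            _amp_pattern([0.5 * a, 0.55 * a, 0.7 * a, 0.6 * a,
                          0.55 * a, 0.65 * a, 0.6 * a, 0.5 * a]),
        ),
        GestureSpec(
            "hand_close",  # strong mixed flexor + ulnar pattern
            _amp_pattern([0.7 * a, 0.3 * a, 0.2 * a, 0.5 * a,
                          0.8 * a, 1.0 * a, 0.8 * a, 0.4 * a]),
        ),
        GestureSpec(
            "double_tap",  # two short bumps, radial channels
            _amp_pattern([0.8 * a, 1.0 * a, 0.5 * a, 0.1 * a,
                          0.05 * a, 0.1 * a, 0.3 * a, 0.6 * a]),
            bumps=((0.28, 0.38), (0.72, 0.38)),
        ),
    ]


def out_of_set_gesture_specs(amplitude: float = 35.0) -> list[GestureSpec]:
    """Extra gesture classes excluded from training (open-set inputs)."""
    a = amplitude
    return [
        GestureSpec(
            "finger_snap",
            _amp_pattern([0.4 * a, 0.7 * a, 1.0 * a, 0.7 * a,
                          0.3 * a, 0.1 * a, 0.1 * a, 0.2 * a]),
            bumps=((0.4, 0.25), (0.62, 0.25)),
            out_of_set=True,
        ),
        GestureSpec(
            "thumbs_up",
            _amp_pattern([0.3 * a, 0.5 * a, 0.4 * a, 0.3 * a,
                          0.6 * a, 0.7 * a, 1.0 * a, 0.7 * a]),
            out_of_set=True,
        ),
        GestureSpec(
            "index_point",
            _amp_pattern([0.2 * a, 0.35 * a, 0.8 * a, 1.0 * a,
                          0.5 * a, 0.3 * a, 0.5 * a, 0.25 * a]),
            out_of_set=True,
        ),
        GestureSpec(
            "finger_gun",
            _amp_pattern([0.6 * a, 0.9 * a, 0.9 * a, 0.6 * a,
                          0.7 * a, 0.4 * a, 0.2 * a, 0.4 * a]),
            bumps=((0.35, 0.5), (0.75, 0.3)),
            out_of_set=True,
        ),
    ]


@dataclass(frozen=True)
class GroupEffect:
    """Systematic generative shift attached to one demographic value.

    Emulates physiological / behavioural group differences: a duration scale
    (behaviour) and an extra electrode-pattern rotation (physiology proxy).
    """

    duration_scale: float = 1.0
    extra_rotation: float = 0.0


@dataclass
class CohortConfig:
    """Everything needed to generate one reproducible cohort."""

    n_users: int
    n_reps: int
    gesture_specs: list[GestureSpec] = field(default_factory=default_gesture_specs)
    demographic_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"group": {"A": 0.66, "B": 0.34}}
    )
    group_effects: dict[str, dict[str, GroupEffect]] = field(default_factory=dict)
    inter_user_gain_sd: float = 0.35  # log-sd of channel gains
    speed_factor_sd: float = 0.15  # log-sd of per-user speed factor
    rotation_sd: float = 0.75  # sd of electrode rotation, in channels
    day_effect_sd: float = 0.15  # log-sd of per-day gain perturbations
    position_effect_sd: float = 0.15
    conditions: list[Condition] = field(
        default_factory=lambda: [DEFAULT_CONDITION]
    )
    recording_length: float = 5.0  # seconds
    sampling_rate: int = FS_HZ
    rest_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate != FS_HZ:
            raise ValueError("sampling_rate is fixed at 200 Hz")
        for attr, mix in self.demographic_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"demographic_mix[{attr!r}] proportions sum to {total}, "
                    "expected 1"
                )
        for bad in ("inter_user_gain_sd", "speed_factor_sd", "rotation_sd",
                    "day_effect_sd", "position_effect_sd"):
            if getattr(self, bad) < 0:
                raise ValueError(f"{bad} must be >= 0")
        if self.rest_sigma <= 0:
            raise ValueError("rest_sigma must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Build a config from a YAML or JSON file mirroring the field names.

        ``gesture_specs`` entries, ``conditions`` entries and ``group_effects``
        leaves may be plain mappings; ``gesture_specs`` may also be the string
        "default" (optionally "default+out_of_set").
        """
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        if "gesture_specs" in doc:
            gs = doc["gesture_specs"]
            if isinstance(gs, str):
                specs = default_gesture_specs()
                if "out_of_set" in gs:
                    specs += out_of_set_gesture_specs()
                doc["gesture_specs"] = specs
            else:
                doc["gesture_specs"] = [
                    GestureSpec(
                        gesture_id=g["gesture_id"],
                        channel_amplitudes=tuple(g["channel_amplitudes"]),
                        bumps=tuple(tuple(b) for b in g.get("bumps",
                                                            [(0.5, 0.9)])),
                        nominal_duration_mean=g.get("nominal_duration_mean",
                                                    1.3),
                        nominal_duration_sd=g.get("nominal_duration_sd", 0.25),
                        out_of_set=g.get("out_of_set", False),
                    )
                    for g in gs
                ]
        if "conditions" in doc:
            doc["conditions"] = [Condition(**c) for c in doc["conditions"]]
        if "group_effects" in doc:
            doc["group_effects"] = {
                attr: {val: GroupEffect(**eff) for val, eff in effs.items()}
                for attr, effs in doc["group_effects"].items()
            }
        return cls(**doc)

    @property
    def in_set_specs(self) -> list[GestureSpec]:
        return [g for g in self.gesture_specs if not g.out_of_set]

    @property
    def out_of_set_specs(self) -> list[GestureSpec]:
        return [g for g in self.gesture_specs if g.out_of_set]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def make_user_profile(config: CohortConfig, user_index: int) -> UserProfile:
    """Draw one user's generative parameters; deterministic in (seed, index)."""
    if not 0 <= user_index < config.n_users:
        raise ValueError(f"user_index {user_index} out of range")
    rng = _rng(config.seed, _STREAM_USER, user_index)
    gains = np.exp(rng.normal(0.0, config.inter_user_gain_sd, N_CHANNELS)) \
        if config.inter_user_gain_sd > 0 else np.ones(N_CHANNELS)
    speed = float(np.exp(rng.normal(0.0, config.speed_factor_sd))) \
        if config.speed_factor_sd > 0 else 1.0
    rotation = float(rng.normal(0.0, config.rotation_sd)) \
        if config.rotation_sd > 0 else 0.0
    demographics = {}
    for attr, mix in sorted(config.demographic_mix.items()):
        values = sorted(mix)
        probs = np.array([mix[v] for v in values])
        demographics[attr] = values[int(rng.choice(len(values), p=probs))]
    # apply configured group effects
    for attr, effects in sorted(config.group_effects.items()):
        eff = effects.get(demographics.get(attr, ""))
        if eff is not None:
            speed *= eff.duration_scale
            rotation += eff.extra_rotation
    erng = _rng(config.seed, _STREAM_EFFECTS, user_index)
    days = sorted({c.day for c in config.conditions})
    positions = sorted({c.position for c in config.conditions})
    day_effects = {
        d: np.ones(N_CHANNELS) if d == 1 or config.day_effect_sd == 0
        else np.exp(erng.normal(0.0, config.day_effect_sd, N_CHANNELS))
        for d in days
    }
    position_effects = {
        p: np.ones(N_CHANNELS) if p == 1 or config.position_effect_sd == 0
        else np.exp(erng.normal(0.0, config.position_effect_sd, N_CHANNELS))
        for p in positions
    }
    return UserProfile(
        user_id=f"user{user_index:04d}",
        channel_gains=gains,
        speed_factor=speed,
        channel_rotation=rotation,
        demographics=demographics,
        day_effects=day_effects,
        position_effects=position_effects,
        rest_sigma=config.rest_sigma,
    )


def inject_confound(profile: UserProfile, kind: str, level: int) -> UserProfile:
    """Return a copy of ``profile`` with the (kind, level) gain perturbation.

    Perturbations are absolute per level (re-applying the same level is
    idempotent relative to the base profile); the base profile is unchanged.
    """
    tables = {"day": profile.day_effects, "position": profile.position_effects}
    if kind not in tables:
        raise ValueError(f"unknown confound kind {kind!r}")
    table = tables[kind]
    if level not in table:
        raise ValueError(f"unknown {kind} level {level}")
    return replace(
        profile, channel_gains=profile.channel_gains * table[level]
    )


def _rotate_pattern(amps: np.ndarray, shift: float) -> np.ndarray:
    """Circularly shift a per-channel amplitude pattern by a real offset."""
    if shift == 0.0:
        return amps
    n = len(amps)
    lo = int(np.floor(shift))
    frac = shift - lo
    return (1 - frac) * np.roll(amps, lo) + frac * np.roll(amps, lo + 1)


def _envelope(
    spec: GestureSpec, profile: UserProfile, active_len: int
) -> np.ndarray:
    """Per-channel raised-cosine activation envelope, (8, active_len)."""
    amps = _rotate_pattern(
        np.asarray(spec.channel_amplitudes, dtype=float),
        profile.channel_rotation,
    )
    u = (np.arange(active_len) + 0.5) / active_len  # fraction of duration
    time_course = np.zeros(active_len)
    for center, width in spec.bumps:
        in_bump = np.abs(u - center) <= width / 2
        time_course[in_bump] += 0.5 * (
            1 + np.cos(2 * np.pi * (u[in_bump] - center) / width)
        )
    return amps[:, None] * time_course[None, :]


def synthesize_recording(
    profile: UserProfile,
    spec: GestureSpec,
    condition: Condition = DEFAULT_CONDITION,
    *,
    config: CohortConfig | None = None,
    rep: int = 0,
    rng: np.random.Generator | None = None,
) -> EMGRecording:
    """Synthesize one rest-padded recording of one gesture repetition.

    The active segment's true bounds are recorded in the result's metadata
    (0-based, half-open).  The rest class produces a pure-noise recording
    whose nominal "active" bounds still follow the duration model, so rest
    templates can be segmented like any other class.
    """
    fs = config.sampling_rate if config else FS_HZ
    rec_len = config.recording_length if config else 5.0
    T = int(round(rec_len * fs))
    if rng is None:
        seed = config.seed if config else 0
        gi = hash(spec.gesture_id) & 0x7FFF
        rng = _rng(seed, _STREAM_RECORDING,
                   int(profile.user_id[-4:]) if profile.user_id[-4:].isdigit()
                   else 0,
                   gi, rep, condition.day, condition.position,
                   int(condition.speed * 1000))

    prof = profile
    if condition.day in profile.day_effects and condition.day != 1:
        prof = inject_confound(prof, "day", condition.day)
    if condition.position in profile.position_effects and condition.position != 1:
        prof = inject_confound(prof, "position", condition.position)

    dur_mean = spec.nominal_duration_mean
    dur = rng.normal(dur_mean, spec.nominal_duration_sd)
    dur = max(dur, 0.3 * dur_mean)  # truncate to stay strictly positive
    dur *= prof.speed_factor * condition.speed
    active_len = int(round(dur * fs))
    if active_len >= T:
        raise ValueError(
            f"active duration {active_len} samples >= recording length {T}"
        )
    start = int(rng.integers(0, T - active_len + 1))
    end = start + active_len

    signal = prof.rest_sigma * rng.standard_normal((N_CHANNELS, T))
    if spec.bumps and any(a > 0 for a in spec.channel_amplitudes):
        env = _envelope(spec, prof, active_len)
        signal[:, start:end] += (
            prof.channel_gains[:, None] * env * rng.standard_normal(
                (N_CHANNELS, active_len)
            )
        )
    samples = np.clip(np.rint(signal), INT_MIN, INT_MAX).astype(np.int8)
    return EMGRecording(
        samples=samples,
        fs=fs,
        user_id=prof.user_id,
        gesture=spec.gesture_id,
        rep=rep,
        condition=condition.name,
        start_index=start,
        end_index=end,
        demographics=dict(prof.demographics),
    )


def enumerate_manifest(config: CohortConfig) -> list[ManifestEntry]:
    """List every (user, gesture, rep, condition) entry without synthesis.

    Useful as a dry run: e.g. a 306-user, 50-rep, 6-gesture, one-condition
    plan enumerates 91,800 templates.
    """
    entries = []
    for ui in range(config.n_users):
        uid = f"user{ui:04d}"
        for spec in config.gesture_specs:
            for rep in range(config.n_reps):
                for cond in config.conditions:
                    entries.append(
                        ManifestEntry(
                            path=f"{uid}/{spec.gesture_id}_r{rep:02d}_"
                                 f"{cond.name}.csv",
                            user_id=uid,
                            gesture=spec.gesture_id,
                            rep=rep,
                            condition=cond.name,
                            demographics={},
                            start_index=None,
                            end_index=None,
                        )
                    )
    return entries


@dataclass
class Cohort:
    """An in-memory generated cohort."""

    config: CohortConfig
    profiles: list[UserProfile]
    recordings: list[EMGRecording]

    def subset(self, **filters) -> list[EMGRecording]:
        """Recordings matching all given attribute filters.

        Values may be scalars or collections, e.g.
        ``cohort.subset(condition="base", gesture=("rest", "wave_in"))``.
        """
        out = []
        for rec in self.recordings:
            ok = True
            for key, want in filters.items():
                have = getattr(rec, key)
                if isinstance(want, (list, tuple, set, frozenset)):
                    ok = have in want
                else:
                    ok = have == want
                if not ok:
                    break
            if ok:
                out.append(rec)
        return out


def generate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> Cohort | DatasetManifest:
    """Generate every recording of the cohort.

    With ``out_dir`` None the cohort is returned in memory; otherwise each
    recording is written as one CSV plus a JSON manifest, and the manifest is
    returned.  Both paths are fully reproducible from ``config.seed``.
    """
    profiles = [make_user_profile(config, i) for i in range(config.n_users)]
    recordings = []
    for ui, prof in enumerate(profiles):
        for gi, spec in enumerate(config.gesture_specs):
            for rep in range(config.n_reps):
                for ci, cond in enumerate(config.conditions):
                    rng = _rng(config.seed, _STREAM_RECORDING, ui, gi, rep, ci)
                    recordings.append(
                        synthesize_recording(
                            prof, spec, cond, config=config, rep=rep, rng=rng
                        )
                    )
    cohort = Cohort(config=config, profiles=profiles, recordings=recordings)
    if out_dir is None:
        return cohort
    return write_cohort(cohort.recordings, out_dir, fs_hz=config.sampling_rate)
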