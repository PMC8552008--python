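"""Seeded synthetic lower-limb gait kinematics.

The generator produces multichannel joint-angle time series with the three
kinds of structure the downstream analyses probe:

* **cyclicity** — each channel is a sum of 2-3 harmonics of the stride
  frequency plus a static offset, so noise-free trajectories are exactly
  periodic with an integer-frame period;
* **class structure** — a flat-ground template, a stair template whose
  parameters alternate between ascent-like and descent-like sub-modes
  (roughly 13 stride cycles each, as on a real staircase with a landing),
  and a "natural" template mixing cyclic, non-cyclic and idle segments with
  a pelvic-speed envelope that is exactly zero while idle;
* **individuality** — each subject perturbs the template's amplitudes,
  offsets and relative channel phases, and walks at their own cadence.

The harmonic phases of the templates are deliberately non-degenerate so a
stride and its time reversal are *not* related by a phase shift; temporal
direction is therefore learnable in principle, which the movement
autoencoder's time-reversal tests rely on.

All randomness flows from one integer seed through ``numpy.random
.SeedSequence`` with a documented splitting scheme: profile draws use
``SeedSequence([seed, CLASS_CODE, subject_index])`` and recording noise uses
``SeedSequence([seed, CLASS_CODE, subject_index, 1])``, so regeneration with
identical parameters is bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelSchema, full_schema
from .recording import KinematicRecording, write_recording

CLASS_CODES = {"flat": 0, "stair": 1, "natural": 2}


class UnknownTemplateError(ValueError):
    """Raised for a movement-class name outside {flat, stair, natural}."""


# --------------------------------------------------------------------------
# templates


@dataclass
class ClassTemplate:
    """Population-level movement-class parameters.

    ``base_offset`` / ``base_amplitude`` are per-channel degrees;
    ``base_phase`` are per-channel *time-shift* phases in radians of the
    fundamental (harmonic h is shifted by h x phase, so the waveform shape
    is preserved and the right side lags the left by half a stride).
    ``harmonic_phases`` are per-harmonic shape phases shared by all
    channels; unequal values make the waveform time-asymmetric.
    """

    name: str
    base_offset: np.ndarray  # (18,) degrees
    base_amplitude: np.ndarray  # (18,) degrees
    base_phase: np.ndarray  # (18,) radians
    harmonic_weights: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.45, 0.20])
    )
    harmonic_phases: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.1, 2.6])
    )
    noise_sd: float = 1.0  # degrees
    # stair sub-modes: per-channel deltas blended over the stride sequence
    submode_offset_delta: np.ndarray | None = None  # ascent(+)/descent(-) (18,)
    submode_amplitude_delta: np.ndarray | None = None
    strides_per_submode: int = 13
    ramp_strides: int = 1
    # natural mixture
    segment_weights: tuple[float, float, float] = (0.4, 0.3, 0.3)  # cyclic/noncyclic/idle
    segment_length_s: tuple[float, float] = (3.0, 8.0)
    walk_speed: float = 1.2  # pelvic-speed envelope while cyclic
    fidget_speed: float = 0.5  # pelvic-speed envelope while non-cyclic


def _channel_table(schema: ChannelSchema, table: dict) -> np.ndarray:
    # side enters via the half-stride phase lag, not the magnitude tables
    out = np.empty(len(schema))
    for i, ch in enumerate(schema):
        out[i] = table[(ch.joint, ch.plane)]
    return out


def _base_phase(schema: ChannelSchema, rel: dict) -> np.ndarray:
    out = np.empty(len(schema))
    for i, ch in enumerate(schema):
        out[i] = rel[(ch.joint, ch.plane)] + (np.pi if ch.side == "right" else 0.0)
    return out


# per-channel relative timing within the stride (radians of the fundamental)
_REL_PHASE = {
    ("hip", "sagittal"): 0.0,
    ("hip", "frontal"): 0.7,
    ("hip", "transverse"): 1.9,
    ("knee", "sagittal"): 0.9,
    ("knee", "frontal"): 1.4,
    ("knee", "transverse"): 2.3,
    ("ankle", "sagittal"): 1.6,
    ("ankle", "frontal"): 2.8,
    ("ankle", "transverse"): 0.4,
}

_FLAT_OFFSET = {
    ("hip", "sagittal"): 12.0,
    ("hip", "frontal"): 4.0,
    ("hip", "transverse"): 0.0,
    ("knee", "sagittal"): 22.0,
    ("knee", "frontal"): 2.0,
    ("knee", "transverse"): 1.0,
    ("ankle", "sagittal"): 0.0,
    ("ankle", "frontal"): 2.0,
    ("ankle", "transverse"): -3.0,
}
_FLAT_AMP = {
    ("hip", "sagittal"): 28.0,
    ("hip", "frontal"): 7.0,
    ("hip", "transverse"): 6.0,
    ("knee", "sagittal"): 32.0,
    ("knee", "frontal"): 3.0,
    ("knee", "transverse"): 2.0,
    ("ankle", "sagittal"): 14.0,
    ("ankle", "frontal"): 5.0,
    ("ankle", "transverse"): 6.0,
}

# Stair means/excursions: more hip and knee flexion, ankle strategy differs.
# Some of the class contrast is placed in the low-amplitude frontal and
# transverse channels, which a 2-D linear projection of poses tends to drop.
_STAIR_OFFSET = {
    ("hip", "sagittal"): 20.0,
    ("hip", "frontal"): 8.0,
    ("hip", "transverse"): -4.0,
    ("knee", "sagittal"): 42.0,
    ("knee", "frontal"): 3.0,
    ("knee", "transverse"): 2.0,
    ("ankle", "sagittal"): 2.0,
    ("ankle", "frontal"): 6.0,
    ("ankle", "transverse"): 3.0,
}
_STAIR_AMP = {
    ("hip", "sagittal"): 34.0,
    ("hip", "frontal"): 9.0,
    ("hip", "transverse"): 7.0,
    ("knee", "sagittal"): 46.0,
    ("knee", "frontal"): 4.0,
    ("knee", "transverse"): 3.0,
    ("ankle", "sagittal"): 18.0,
    ("ankle", "frontal"): 7.0,
    ("ankle", "transverse"): 7.0,
}
# ascent adds the delta, descent subtracts it
_STAIR_DELTA_OFF = {
    ("hip", "sagittal"): 5.0,
    ("hip", "frontal"): 1.0,
    ("hip", "transverse"): 2.0,
    ("knee", "sagittal"): -3.0,
    ("knee", "frontal"): 0.5,
    ("knee", "transverse"): 0.5,
    ("ankle", "sagittal"): 8.0,
    ("ankle", "frontal"): 1.5,
    ("ankle", "transverse"): -2.0,
}
_STAIR_DELTA_AMP = {
    ("hip", "sagittal"): 4.0,
    ("hip", "frontal"): 1.0,
    ("hip", "transverse"): 1.0,
    ("knee", "sagittal"): -5.0,
    ("knee", "frontal"): 0.5,
    ("knee", "transverse"): 0.5,
    ("ankle", "sagittal"): 3.0,
    ("ankle", "frontal"): 1.0,
    ("ankle", "transverse"): 1.0,
}


def default_template(name: str, schema: ChannelSchema | None = None) -> ClassTemplate:
    """The bundled flat / stair / natural class templates."""
    if name not in CLASS_CODES:
        raise UnknownTemplateError(f"unknown movement class {name!r}")
    schema = schema or full_schema()
    phase = _base_phase(schema, _REL_PHASE)
    if name == "flat":
        return ClassTemplate(
            name="flat",
            base_offset=_channel_table(schema, _FLAT_OFFSET),
            base_amplitude=_channel_table(schema, _FLAT_AMP),
            base_phase=phase,
        )
    if name == "stair":
        return ClassTemplate(
            name="stair",
            base_offset=_channel_table(schema, _STAIR_OFFSET),
            base_amplitude=_channel_table(schema, _STAIR_AMP),
            base_phase=phase,
            submode_offset_delta=_channel_table(schema, _STAIR_DELTA_OFF),
            submode_amplitude_delta=_channel_table(schema, _STAIR_DELTA_AMP),
        )
    # natural: cyclic portions look flat-like; the rest is slow aperiodic
    # drift or idle standing
    return ClassTemplate(
        name="natural",
        base_offset=_channel_table(schema, _FLAT_OFFSET),
        base_amplitude=_channel_table(schema, _FLAT_AMP),
        base_phase=phase,
    )


# --------------------------------------------------------------------------
# subject profiles


@dataclass
class GaitProfile:
    """One subject's idiosyncratic gait signature around a class template."""

    subject_id: str
    cadence: float  # strides / second; chosen so 1/cadence is an integer frame count
    amplitude: np.ndarray  # (18,) degrees, >= 0
    offset: np.ndarray  # (18,) degrees
    phase: np.ndarray  # (18,) radians, time-shift phase of the fundamental
    harmonic_weights: np.ndarray
    harmonic_phases: np.ndarray
    left_right_lag: float = np.pi  # radians (already folded into phase)
    noise_sd: float = 1.0  # degrees

    def period_frames(self, rate: float) -> int:
        period = rate / self.cadence
        if abs(period - round(period)) > 1e-9:
            raise ValueError("cadence does not divide the frame rate evenly")
        return int(round(period))


def make_profile(
    template: ClassTemplate | str,
    subject_index: int,
    seed: int,
    rate: float = 60.0,
) -> GaitProfile:
    """Draw a subject-specific profile around a class template.

    Deterministic in (template name, subject_index, seed).  The cadence is
    drawn from [0.8, 1.2] strides/s and snapped so the stride period is an
    integer number of frames at ``rate``.
    """
    if isinstance(template, str):
        template = default_template(template)
    if template.name not in CLASS_CODES:
        raise UnknownTemplateError(f"unknown movement class {template.name!r}")
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, CLASS_CODES[template.name], subject_index])
    )
    n_ch = template.base_offset.shape[0]
    amp = template.base_amplitude * np.clip(
        1.0 + rng.normal(0.0, 0.12, n_ch), 0.3, None
    )
    off = template.base_offset + rng.normal(0.0, 2.5, n_ch)
    # global phase shift is uninformative for steady gait (it slides along
    # the cycle); per-channel jitter changes relative timing and is a real
    # individual signature
    phase = template.base_phase + rng.uniform(0.0, 2 * np.pi) + rng.normal(
        0.0, 0.15, n_ch
    )
    weights = template.harmonic_weights * np.clip(
        1.0 + rng.normal(0.0, 0.15, template.harmonic_weights.shape[0]), 0.05, None
    )
    hphases = template.harmonic_phases + rng.normal(
        0.0, 0.25, template.harmonic_phases.shape[0]
    )
    cadence_raw = rng.uniform(0.8, 1.2)
    period = int(round(rate / cadence_raw))
    cadence = rate / period
    return GaitProfile(
        subject_id=f"{template.name[0].upper()}{subject_index:02d}",
        cadence=cadence,
        amplitude=amp,
        offset=off,
        phase=phase,
        harmonic_weights=weights,
        harmonic_phases=hphases,
        noise_sd=template.noise_sd,
    )


# --------------------------------------------------------------------------
# trajectory synthesis


def _harmonic_sum(
    t: np.ndarray,
    cadence: float,
    amplitude: np.ndarray,
    phase: np.ndarray,
    weights: np.ndarray,
    hphases: np.ndarray,
) -> np.ndarray:
    """Noise-free harmonic trajectory, shape (len(t), channels).

    x_c(t) = A_c * sum_h w_h sin(2 pi h f t + h phi_c + psi_h)
    """
    out = np.zeros((t.shape[0], amplitude.shape[0]))
    for h, (w, psi) in enumerate(zip(weights, hphases), start=1):
        arg = 2 * np.pi * h * cadence * t[:, None] + h * phase[None, :] + psi
        out += w * np.sin(arg)
    return out * amplitude[None, :]


def _stair_blend(t: np.ndarray, cadence: float, template: ClassTemplate) -> np.ndarray:
    """Ascent/descent blending factor in [-1, 1] over time.

    Holds +1 (ascent-like) for ``strides_per_submode`` strides, ramps
    linearly over ``ramp_strides`` strides to -1 (descent-like), and
    alternates.
    """
    strides = t * cadence
    hold, ramp = template.strides_per_submode, template.ramp_strides
    cycle = 2 * (hold + ramp)
    s = np.mod(strides, cycle)
    blend = np.empty_like(s)
    # piecewise: hold +1, ramp down, hold -1, ramp up
    blend[:] = 1.0
    m = (s >= hold) & (s < hold + ramp)
    blend[m] = 1.0 - 2.0 * (s[m] - hold) / ramp
    m = (s >= hold + ramp) & (s < 2 * hold + ramp)
    blend[m] = -1.0
    m = s >= 2 * hold + ramp
    blend[m] = -1.0 + 2.0 * (s[m] - (2 * hold + ramp)) / ramp
    return blend


def _pelvic_envelope(t: np.ndarray, cadence: float, speed: float) -> np.ndarray:
    return speed * (1.0 + 0.1 * np.sin(2 * np.pi * 2 * cadence * t))


def generate_recording(
    profile: GaitProfile,
    template: ClassTemplate | str,
    duration: float,
    rate: float = 60.0,
    seed: int = 0,
) -> KinematicRecording:
    """Synthesize one recording of ``duration`` seconds at ``rate`` Hz.

    With ``profile.noise_sd == 0`` the trajectory is a pure harmonic sum and
    (for flat-ground templates) exactly periodic with period
    ``rate / cadence`` frames.
    """
    if isinstance(template, str):
        template = default_template(template)
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(np.random.SeedSequence([seed]))

    if template.name == "natural":
        angles, pelvic = _natural_stream(profile, template, t, rate, rng)
    else:
        angles = profile.offset[None, :] + _harmonic_sum(
            t,
            profile.cadence,
            profile.amplitude,
            profile.phase,
            profile.harmonic_weights,
            profile.harmonic_phases,
        )
        if template.submode_offset_delta is not None:
            blend = _stair_blend(t, profile.cadence, template)[:, None]
            angles = angles + blend * template.submode_offset_delta[None, :]
            # amplitude modulation applied multiplicatively on the harmonic part
            rel = np.divide(
                template.submode_amplitude_delta,
                template.base_amplitude,
                out=np.zeros_like(template.base_amplitude),
                where=template.base_amplitude > 0,
            )
            harm = angles - profile.offset[None, :] - blend * (
                template.submode_offset_delta[None, :]
            )
            angles = (
                profile.offset[None, :]
                + blend * template.submode_offset_delta[None, :]
                + harm * (1.0 + blend * rel[None, :])
            )
        pelvic = _pelvic_envelope(t, profile.cadence, template.walk_speed)

    if profile.noise_sd > 0:
        angles = angles + rng.normal(0.0, profile.noise_sd, angles.shape)

    schema = full_schema()
    return KinematicRecording(
        subject_id=profile.subject_id,
        activity=template.name,
        rate=rate,
        schema=schema,
        angles=angles,
        pelvic_speed=pelvic,
        meta={
            "seed": seed,
            "cadence": profile.cadence,
            "noise_sd": profile.noise_sd,
            "template": template.name,
        },
    )


def _natural_stream(
    profile: GaitProfile,
    template: ClassTemplate,
    t: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate cyclic / non-cyclic / idle segments with a speed trace."""
    n = t.shape[0]
    n_ch = profile.offset.shape[0]
    angles = np.empty((n, n_ch))
    pelvic = np.empty(n)
    lo, hi = template.segment_length_s
    weights = np.asarray(template.segment_weights, dtype=float)
    weights = weights / weights.sum()
    pos = 0
    while pos < n:
        seg_len = min(n - pos, int(round(rng.uniform(lo, hi) * rate)))
        seg_t = t[pos : pos + seg_len]
        kind = rng.choice(3, p=weights)
        if kind == 0:  # cyclic walking bout
            angles[pos : pos + seg_len] = profile.offset[None, :] + _harmonic_sum(
                seg_t,
                profile.cadence,
                profile.amplitude,
                profile.phase,
                profile.harmonic_weights,
                profile.harmonic_phases,
            )
            pelvic[pos : pos + seg_len] = _pelvic_envelope(
                seg_t, profile.cadence, template.walk_speed
            )
        elif kind == 1:  # slow aperiodic movement (reaching, turning, fidgeting)
            freqs = rng.uniform(0.1, 0.6, 3)
            phases = rng.uniform(0, 2 * np.pi, (3, n_ch))
            amps = 0.5 * profile.amplitude
            seg = np.zeros((seg_len, n_ch))
            for f, ph in zip(freqs, phases):
                seg += np.sin(2 * np.pi * f * seg_t[:, None] + ph[None, :])
            angles[pos : pos + seg_len] = profile.offset[None, :] + seg * (
                amps[None, :] / 3.0
            )
            pelvic[pos : pos + seg_len] = _pelvic_envelope(
                seg_t, profile.cadence, template.fidget_speed
            )
        else:  # idle: static pose, pelvis still
            angles[pos : pos + seg_len] = profile.offset[None, :]
            pelvic[pos : pos + seg_len] = 0.0
        pos += seg_len
    return angles, pelvic


# --------------------------------------------------------------------------
# whole studies


@dataclass
class SyntheticDataset:
    recordings: list[KinematicRecording]
    seed: int
    profiles: list[GaitProfile]
    templates: dict[str, ClassTemplate]

    def by_activity(self, activity: str) -> list[KinematicRecording]:
        return [r for r in self.recordings if r.activity == activity]


def generate_study(
    n_subjects_flat: int,
    n_subjects_stair: int,
    n_subjects_natural: int,
    duration: float = 60.0,
    seed: int = 0,
    rate: float = 60.0,
) -> SyntheticDataset:
    """One recording per subject per assigned class; ids unique across classes."""
    counts = {
        "flat": n_subjects_flat,
        "stair": n_subjects_stair,
        "natural": n_subjects_natural,
    }
    if any(c < 0 for c in counts.values()):
        raise ValueError("subject counts must be >= 0")
    recordings: list[KinematicRecording] = []
    profiles: list[GaitProfile] = []
    templates = {name: default_template(name) for name in counts}
    for name, count in counts.items():
        for idx in range(count):
            profile = make_profile(templates[name], idx, seed, rate=rate)
            noise_seed_seq = np.random.SeedSequence(
                [seed, CLASS_CODES[name], idx, 1]
            )
            noise_seed = int(noise_seed_seq.generate_state(1)[0] % (2**31))
            recordings.append(
                generate_recording(
                    profile, templates[name], duration, rate=rate, seed=noise_seed
                )
            )
            profiles.append(profile)
    return SyntheticDataset(
        recordings=recordings, seed=seed, profiles=profiles, templates=templates
    )


def write_study(dataset: SyntheticDataset, directory) -> None:
    for rec in dataset.recordings:
        write_recording(rec, directory)
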