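"""Synthetic subjects: cyclic knee motion with matching 4-channel surface EMG.

Real recordings pair a 100 Hz knee-angle trajectory (motion capture) with
1928 Hz surface EMG from two knee extensors (rectus femoris RF, vastus
medialis VM) and two flexors (biceps femoris BF, semitendinosus SE).  The
generator reproduces the statistical structure that the estimation pipeline
relies on:

* a smooth periodic angle trajectory spanning [angle_min, angle_max], one
  extension and one flexion excursion per cycle (squat or seated
  flexion-extension);
* four activation envelopes in [0, 1] — extensors rise with extension
  demand, flexors mirror them — advanced in time by the electromechanical
  lead with which muscle activity precedes movement;
* raw EMG as an envelope-modulated 10-400 Hz Gaussian carrier plus 50 Hz
  line interference and white sensor noise at a configured SNR;
* marker triples (A, B, C) constructed so the marker-derived knee angle
  reproduces the generated trajectory exactly.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

__all__ = [
    "SyntheticConfig",
    "SyntheticRecording",
    "generate_angle_trajectory",
    "generate_activation_envelopes",
    "synthesize_emg",
    "generate_subject",
]

CHANNEL_NAMES = ("RF", "VM", "BF", "SE")

#: segment lengths used for marker synthesis, mm
_THIGH_MM = 400.0
_SHANK_MM = 420.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic subject.

    Defaults mirror the acquisition protocol the pipeline targets: 1928 Hz
    EMG, 100 Hz angle, 20 movement cycles of 4 s each spanning 0-90 deg,
    and an electromechanical lead of 50 ms (muscle activity precedes limb
    motion by roughly 30-150 ms).  ``envelope_gains`` scales the four
    per-muscle activation amplitudes (order RF, VM, BF, SE) and is the knob
    used to emulate between-subject differences.
    """

    motion_mode: str = "flex_ext"
    fs_emg: float = 1928.0
    fs_angle: float = 100.0
    n_cycles: int = 20
    cycle_period: float = 4.0
    angle_min: float = 0.0
    angle_max: float = 90.0
    snr_db: float = 10.0
    line_amplitude: float = 0.2
    emd_lead: float = 0.05
    envelope_gains: tuple = (1.0, 0.85, 1.0, 0.85)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motion_mode not in ("squat", "flex_ext"):
            raise ValueError(f"unknown motion_mode {self.motion_mode!r}")
        if self.fs_emg <= 2 * 400.0:
            raise ValueError("fs_emg must exceed twice the 400 Hz carrier band edge")
        if self.angle_min > self.angle_max:
            raise ValueError("angle_min must not exceed angle_max")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")
        if len(self.envelope_gains) != 4 or not all(
            0.0 <= g <= 1.0 for g in self.envelope_gains
        ):
            raise ValueError("envelope_gains must be four values in [0, 1]")

    @property
    def n_angle_samples(self) -> int:
        return int(round(self.n_cycles * self.cycle_period * self.fs_angle))

    @property
    def n_emg_samples(self) -> int:
        return int(round(self.n_cycles * self.cycle_period * self.fs_emg))


@dataclass
class SyntheticRecording:
    """One synthetic subject: raw EMG, angle labels and ground truth."""

    emg: np.ndarray  # (4, n_emg), arbitrary voltage units
    angle: np.ndarray  # (n_angle,), deg at fs_angle
    envelopes: np.ndarray  # (4, n_angle), ground-truth activations in [0, 1]
    config: SyntheticConfig
    markers: Optional[np.ndarray] = None  # (n_angle, 3, 3) A/B/C positions, mm

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.envelopes = np.asarray(self.envelopes, dtype=float)
        if self.emg.ndim != 2 or self.emg.shape[0] != 4:
            raise ValueError("emg must have exactly 4 channel rows")
        if self.angle.shape != (self.config.n_angle_samples,):
            raise ValueError("angle length inconsistent with config")
        if self.envelopes.min() < 0.0 or self.envelopes.max() > 1.0:
            raise ValueError("envelopes must lie in [0, 1]")


def generate_angle_trajectory(config: SyntheticConfig) -> np.ndarray:
    """Periodic knee-angle series in degrees, sampled at ``fs_angle``.

    Both motion modes are raised-cosine cycles (extension over the first
    half cycle, flexion over the second); the squat adds a brief hold at
    the deepest position, emulating the pause at the bottom of a squat.
    The sampled series is affinely rescaled so its minimum and maximum are
    exactly ``angle_min`` and ``angle_max``.
    """
    n = config.n_angle_samples
    t = np.arange(n) / config.fs_angle
    base = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / config.cycle_period))
    if config.motion_mode == "squat":
        base = np.clip(1.15 * base, 0.0, 1.0)
    ptp = base.max() - base.min()
    if ptp > 0.0:
        base = (base - base.min()) / ptp
    else:
        base = np.zeros(n)
    return config.angle_min + (config.angle_max - config.angle_min) * base


def _extension_demand(angle: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Normalized extension effort: monotone in angle and angular velocity."""
    span = config.angle_max - config.angle_min
    if span > 0.0:
        a = (angle - config.angle_min) / span
    else:
        a = np.full(angle.shape, 0.5)
    vel = np.gradient(angle) * config.fs_angle  # deg/s
    vmax = np.abs(vel).max()
    v = vel / vmax if vmax > 0.0 else np.zeros_like(vel)
    # position-dominant mix: a large velocity share would fold the rising
    # and falling phases of the cycle onto one demand value and make the
    # angle unidentifiable from a memoryless feature window
    demand = 0.9 * a + 0.1 * (v + 1.0) / 2.0
    ptp = demand.max() - demand.min()
    if ptp > 0.0:
        demand = (demand - demand.min()) / ptp
    return np.clip(demand, 0.0, 1.0)


def generate_activation_envelopes(
    angle: np.ndarray, config: SyntheticConfig
) -> np.ndarray:
    """Four muscle-activation envelopes in [0, 1] at ``fs_angle``.

    RF and VM (extensors) follow the extension-demand signal; BF and SE
    (flexors) follow its complement.  All four are advanced circularly by
    ``emd_lead`` seconds so electrical activity precedes the motion, as it
    does physiologically.
    """
    angle = np.asarray(angle, dtype=float)
    if angle.min() < config.angle_min - 1e-9 or angle.max() > config.angle_max + 1e-9:
        raise ValueError("angle outside configured bounds")
    demand = _extension_demand(angle, config)
    shift = int(round(config.emd_lead * config.fs_angle))
    # trajectory is periodic, so a circular shift realizes the lead exactly
    lead = np.roll(demand, -shift)
    g = config.envelope_gains
    return np.vstack([g[0] * lead, g[1] * lead, g[2] * (1.0 - lead), g[3] * (1.0 - lead)])


def synthesize_emg(
    envelopes: np.ndarray, config: SyntheticConfig
) -> np.ndarray:
    """Raw 4-channel surface EMG at ``fs_emg`` from activation envelopes.

    Each channel is ``envelope x carrier + line + sensor noise`` where the
    carrier is unit-RMS zero-mean Gaussian noise band-limited to 10-400 Hz,
    the line term is a 50 Hz sinusoid scaled to ``line_amplitude`` times
    the modulated-signal RMS, and the sensor noise is white Gaussian at
    ``snr_db`` relative to the modulated signal power.
    """
    envelopes = np.asarray(envelopes, dtype=float)
    if envelopes.min() < 0.0 or envelopes.max() > 1.0:
        raise ValueError("envelopes must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n = config.n_emg_samples
    t = np.arange(n) / config.fs_emg
    t_env = np.arange(envelopes.shape[1]) / config.fs_angle

    sos = sps.butter(4, [10.0, 400.0], btype="bandpass", fs=config.fs_emg, output="sos")
    white = rng.standard_normal((4, n))
    carrier = sps.sosfiltfilt(sos, white, axis=-1)
    # unit-RMS carrier so envelope amplitude sets the signal scale
    crms = np.sqrt(np.mean(carrier**2, axis=1, keepdims=True))
    carrier = np.divide(carrier, crms, out=carrier, where=crms > 0)

    env_up = np.vstack([np.interp(t, t_env, e) for e in envelopes])
    emg = env_up * carrier

    sig_rms = np.sqrt(np.mean(emg**2, axis=1, keepdims=True))
    if config.line_amplitude > 0.0:
        emg = emg + config.line_amplitude * sig_rms * np.sin(2.0 * np.pi * 50.0 * t)

    if np.isfinite(config.snr_db):
        noise_rms = sig_rms * 10.0 ** (-config.snr_db / 20.0)
        emg = emg + noise_rms * rng.standard_normal((4, n))
    return emg


def _synthesize_markers(angle: np.ndarray) -> np.ndarray:
    """Sagittal-plane marker triples whose knee angle equals ``angle``.

    B sits at the origin, A is fixed along the thigh axis (+y) and C is the
    shank endpoint rotated about B so the angle between the thigh extension
    line and the shank equals the target (z = 0 throughout).
    """
    n = angle.size
    rad = np.radians(angle)
    markers = np.zeros((n, 3, 3))
    markers[:, 0, 1] = _THIGH_MM  # A
    markers[:, 2, 0] = _SHANK_MM * np.sin(rad)  # C
    markers[:, 2, 1] = -_SHANK_MM * np.cos(rad)
    return markers


def generate_subject(config: SyntheticConfig) -> SyntheticRecording:
    """Compose a full synthetic recording: angle, envelopes, EMG, markers."""
    angle = generate_angle_trajectory(config)
    envelopes = generate_activation_envelopes(angle, config)
    emg = synthesize_emg(envelopes, config)
    markers = _synthesize_markers(angle)
    return SyntheticRecording(
        emg=emg, angle=angle, envelopes=envelopes, config=config, markers=markers
    )
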