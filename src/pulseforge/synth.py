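"""Synthetic pulsatile facial video with known ground truth.

Real rPPG corpora are large video datasets; for development and testing this
module generates the same *signal structure* at arbitrary size: a
quasi-periodic blood-volume-pulse wave (fundamental + one harmonic, 40-180
BPM) drives a faint skin-color modulation confined to cheek/forehead-weighted
regions of a smooth skin-toned face field, corrupted by global illumination
drift, per-pixel sensor noise, and small integer-pixel motion jitter — the
low-SNR regime the estimation network is designed for.

Everything is reproducible from a single seed: per-subject generators are
spawned as ``default_rng([seed, subject_index])`` and per-clip generators as
``default_rng([seed, subject_index, clip_index])``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clipio import BVPRecord, FrameClip

__all__ = ["SynthConfig", "SynthSample", "synth_bvp", "synth_clip", "synth_dataset"]

HR_RANGE = (40.0, 180.0)


@dataclass
class SynthConfig:
    hr_bpm: float | None = None            # None -> sampled from hr_range
    hr_range: tuple[float, float] = HR_RANGE
    fps: float = 30.0
    d: int = 160
    h: int = 128
    w: int = 128
    harmonic_ratio: float = 0.3            # amplitude of the 2f component
    amp_mod_sd: float = 0.1                # lognormal beat-amplitude variability
    pulse_amp: float = 0.01                # peak modulation, fraction of range
    channel_gains: tuple[float, float, float] = (0.6, 1.0, 0.4)  # green-dominant
    noise_sd: float = 0.02                 # per-pixel Gaussian sensor noise
    illum_amp: float = 0.01                # global illumination drift amplitude
    illum_freq: float = 0.1                # Hz, well below the pulse band
    jitter_px: int = 1                     # max translation per clip (random walk)
    seed: int = 0

    def __post_init__(self):
        if self.hr_bpm is not None and not (HR_RANGE[0] <= self.hr_bpm <= HR_RANGE[1]):
            raise ValueError(f"hr_bpm must be within {HR_RANGE}, got {self.hr_bpm}")
        if self.pulse_amp < 0 or self.noise_sd < 0:
            raise ValueError("pulse_amp and noise_sd must be non-negative")
        hr_max = self.hr_bpm if self.hr_bpm is not None else self.hr_range[1]
        if 2.0 * hr_max / 60.0 >= self.fps / 2:
            raise ValueError("first harmonic exceeds Nyquist at this fps")
        if self.illum_freq >= 0.3:
            raise ValueError("illumination drift must stay below 0.3 Hz")


@dataclass
class SynthSample:
    clip: FrameClip
    bvp: BVPRecord
    hr_bpm: float
    config: SynthConfig = field(repr=False, default=None)


def synth_bvp(hr_bpm: float, fps: float, d: int, harmonic_ratio: float = 0.3,
              amp_mod_sd: float = 0.1, seed: int = 0) -> BVPRecord:
    """Quasi-periodic pulse wave: modulated fundamental plus one harmonic.

    ``wave[t] = a(t) · [sin(2πf t/fps) + harmonic_ratio · sin(4πf t/fps + φ)]``
    with f = hr/60, a slowly varying lognormal amplitude a(t) (log-SD
    ``amp_mod_sd``, ~1 s correlation length) and a seeded harmonic phase φ.
    """
    f = hr_bpm / 60.0
    if 2.0 * f >= fps / 2:
        raise ValueError("harmonic above Nyquist")
    rng = np.random.default_rng(seed)
    t = np.arange(d)
    phi = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * f * t / fps)
    if harmonic_ratio:
        wave = wave + harmonic_ratio * np.sin(4 * np.pi * f * t / fps + phi)
    if amp_mod_sd > 0:
        # coarse log-amplitude knots every ~second, linearly interpolated
        n_knots = max(int(np.ceil(d / fps)) + 2, 4)
        knots = rng.normal(0.0, amp_mod_sd, n_knots)
        pos = np.linspace(0, d - 1, n_knots)
        wave = wave * np.exp(np.interp(t, pos, knots))
    return BVPRecord(wave=wave, fps=fps, hr_ref=hr_bpm)


def _face_field(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth skin-toned base frame (3, H, W): skin color + low-order shading."""
    yy, xx = np.mgrid[0:h, 0:w]
    y, x = yy / max(h - 1, 1), xx / max(w - 1, 1)
    shading = (0.08 * np.sin(np.pi * x + rng.uniform(0, 1))
               + 0.08 * np.cos(np.pi * y + rng.uniform(0, 1)))
    skin = np.array([0.72, 0.55, 0.45])
    base = skin[:, None, None] * (1.0 + shading)[None]
    oval = (((x - 0.5) / 0.42) ** 2 + ((y - 0.5) / 0.48) ** 2) <= 1.0
    base = np.where(oval[None], base, 0.18)   # dark background outside the face
    return np.clip(base, 0.0, 1.0)


def _pulse_map(h: int, w: int) -> np.ndarray:
    """Perfusion weight field: two cheek blobs plus one forehead band."""
    yy, xx = np.mgrid[0:h, 0:w]
    y, x = yy / max(h - 1, 1), xx / max(w - 1, 1)

    def blob(cx, cy, sx, sy):
        return np.exp(-(((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2) / 2.0)

    m = blob(0.30, 0.62, 0.10, 0.10) + blob(0.70, 0.62, 0.10, 0.10) \
        + blob(0.50, 0.22, 0.22, 0.07)
    oval = (((x - 0.5) / 0.42) ** 2 + ((y - 0.5) / 0.48) ** 2) <= 1.0
    m = np.where(oval, m, 0.0)
    return (m / m.max()).astype(np.float64)


def _roll2d(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    if dy == 0 and dx == 0:
        return img
    return np.roll(np.roll(img, dy, axis=-2), dx, axis=-1)


def synth_clip(config: SynthConfig) -> SynthSample:
    """Render one clip: pulse-modulated face field plus noise, drift, jitter."""
    rng = np.random.default_rng(config.seed)
    hr = config.hr_bpm if config.hr_bpm is not None else float(
        rng.uniform(*config.hr_range))
    bvp = synth_bvp(hr, config.fps, config.d, config.harmonic_ratio,
                    config.amp_mod_sd, seed=int(rng.integers(2 ** 31)))
    base = _face_field(config.h, config.w, rng)
    pmap = _pulse_map(config.h, config.w)
    gains = np.asarray(config.channel_gains, np.float64)
    modulation = gains[:, None, None] * pmap[None]      # (3, H, W)

    # bounded integer-pixel random walk for translational jitter
    if config.jitter_px > 0:
        steps = rng.integers(-1, 2, size=(config.d, 2))
        walk = np.clip(np.cumsum(steps, axis=0), -config.jitter_px, config.jitter_px)
    else:
        walk = np.zeros((config.d, 2), int)

    illum_phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(config.d)
    illum = config.illum_amp * np.sin(
        2 * np.pi * config.illum_freq * t / config.fps + illum_phase)

    frames = np.empty((config.d, 3, config.h, config.w), np.float32)
    clipped = 0
    for k in range(config.d):
        dy, dx = int(walk[k, 0]), int(walk[k, 1])
        frame = (_roll2d(base, dy, dx)
                 + config.pulse_amp * bvp.wave[k] * _roll2d(modulation, dy, dx)
                 + illum[k])
        if config.noise_sd > 0:
            frame = frame + rng.normal(0.0, config.noise_sd, frame.shape)
        clipped += int(((frame < 0) | (frame > 1)).sum())
        frames[k] = np.clip(frame, 0.0, 1.0)
    frac = clipped / frames.size
    if frac > 0.01:
        warnings.warn(f"{100 * frac:.1f}% of pixels clipped; "
                      "pulse_amp/illum_amp may be too large", stacklevel=2)

    clip = FrameClip(frames=frames, fps=config.fps,
                     subject_id=f"s{config.seed}", clip_id=f"c{config.seed}")
    return SynthSample(clip=clip, bvp=bvp, hr_bpm=hr, config=config)


def synth_dataset(n_subjects: int, clips_per_subject: int,
                  config: SynthConfig | None = None, seed: int = 0
                  ) -> tuple[list[SynthSample], pd.DataFrame]:
    """Generate a subject-structured corpus plus a manifest table.

    Each subject draws one heart rate (held across their clips, with small
    per-clip variation) from ``config.hr_range``; clip-level noise/phase/
    jitter realizations differ per clip.  The manifest lists subject_id,
    clip_id, and the ground-truth HR, in generation order.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    config = config or SynthConfig()
    samples: list[SynthSample] = []
    rows = []
    for si in range(n_subjects):
        srng = np.random.default_rng([seed, si])
        hr_subject = float(srng.uniform(*config.hr_range))
        for ci in range(clips_per_subject):
            crng = np.random.default_rng([seed, si, ci])
            hr = float(np.clip(hr_subject + crng.normal(0.0, 1.5),
                               *config.hr_range))
            cseed = int(crng.integers(2 ** 31))
            cfg = replace(config, hr_bpm=hr, seed=cseed)
            sample = synth_clip(cfg)
            sample.clip.subject_id = f"subj{si:03d}"
            sample.clip.clip_id = f"subj{si:03d}_clip{ci:03d}"
            samples.append(sample)
            rows.append({"subject_id": sample.clip.subject_id,
                         "clip_id": sample.clip.clip_id,
                         "hr_bpm": hr, "noise_sd": config.noise_sd})
    return samples, pd.DataFrame(rows)
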