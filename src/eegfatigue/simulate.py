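"""Synthetic two-state EEG cohorts and the MIX(p) validation process.

Real driver-fatigue recordings are not publicly deposited, so the
pipeline is exercised on surrogate data built from 1/f-shaped ("pink")
broadband noise, the canonical coarse model of resting EEG spectra:

* the *normal* state draws pink noise with spectral exponent ``beta``
  (power ~ 1/f^beta, default 1.0);
* the *fatigue* state draws the same process with the exponent
  steepened to ``beta + slope_gain * effect_size``, scaled by a small
  per-subject random gain.  A steeper slope shifts relative power from
  fast (beta-band) activity toward slow and alpha-band activity — the
  classic spectral signature of fatigue — which makes fatigue windows
  smoother at the sample scale and lowers their fuzzy / sample /
  approximate entropies.

At ``effect_size = 0`` the two states are draws from the identical
process, giving an exact null for calibration checks.  Both states are
band-pass filtered to 0.15-45 Hz before being returned.

The MIX(p) family interpolates between a deterministic period-12
sinusoid (p=0) and i.i.d. uniform noise (p=1) and is the standard
fixture for validating that regularity statistics increase with p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator

import numpy as np

from .recording import EEGRecording, bandpass_filter, write_recording

__all__ = ["SynthConfig", "mix_process", "synth_recording", "synth_cohort",
           "iter_cohort", "write_cohort"]


def mix_process(L: int, p: float, seed: int) -> np.ndarray:
    """MIX(p): (1-z_j) * sqrt(2) sin(2 pi j / 12) + z_j * V_j.

    ``z_j ~ Bernoulli(p)`` and ``V_j ~ Uniform(-sqrt(3), sqrt(3))``, so
    both the pure sinusoid (p=0) and the pure noise (p=1) limits have
    unit variance.  Deterministic under ``seed``.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if L < 12:
        raise ValueError("L must cover at least one sinusoid period (12)")
    rng = np.random.default_rng(seed)
    j = np.arange(1, L + 1)
    base = np.sqrt(2.0) * np.sin(2.0 * np.pi * j / 12.0)
    z = rng.random(L) < p
    noise = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=L)
    return np.where(z, noise, base)


@dataclass(frozen=True)
class SynthConfig:
    """Cohort design parameters.

    Defaults mirror the reference experimental design — 28 subjects,
    30 channels, 5 minutes per state — at a reduced 250 Hz sampling
    rate (duration-preserving, so unit counts are unchanged; 1 kHz is
    available by configuration).  ``effect_size`` (delta, >= 0)
    controls how much steeper the fatigue-state spectral slope is than
    the normal-state slope; 0 makes the two states statistically
    identical.
    """

    n_subjects: int = 28
    n_channels: int = 30
    fs: float = 250.0
    minutes_per_state: float = 5.0
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    spectral_exponent: float = 1.0
    slope_gain: float = 0.5
    band: tuple[float, float] = (0.15, 45.0)

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_channels) < 1:
            raise ValueError("counts must be positive")
        if self.fs <= 0 or self.minutes_per_state <= 0 or self.noise_sd <= 0:
            raise ValueError("fs, minutes_per_state and noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    @property
    def n_timepoints(self) -> int:
        return int(round(self.fs * 60.0 * self.minutes_per_state))


def _pink_noise(rng: np.random.Generator, n_channels: int, n_t: int,
                exponent: float, sd: float) -> np.ndarray:
    """Spectrally shaped white noise with power ~ 1/f^exponent per channel."""
    white = rng.standard_normal((n_channels, n_t))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_t)
    f[0] = f[1]  # avoid the DC singularity; DC is filtered out downstream
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n_t, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x *= sd / x.std(axis=1, keepdims=True)
    return x


def synth_recording(
    state: str,
    cfg: SynthConfig,
    subject_id: str,
    rng: np.random.Generator,
    subject_gain: float = 1.0,
) -> EEGRecording:
    """One multichannel recording of the given state.

    ``subject_gain`` multiplies the fatigue slope increment, modelling
    between-subject variability in how strongly fatigue expresses.
    """
    exponent = cfg.spectral_exponent
    if state == "fatigue":
        exponent += cfg.slope_gain * cfg.effect_size * subject_gain
    samples = _pink_noise(rng, cfg.n_channels, cfg.n_timepoints, exponent,
                          cfg.noise_sd)
    rec = EEGRecording(samples=samples, fs=cfg.fs, subject_id=subject_id,
                       state=state)
    return bandpass_filter(rec, cfg.band[0], cfg.band[1])


def iter_cohort(cfg: SynthConfig) -> Iterator[EEGRecording]:
    """Lazily generate one normal and one fatigue recording per subject.

    Subject-level seeds are derived deterministically from ``cfg.seed``
    via a seed sequence, so distinct subjects get independent streams
    and the whole cohort is reproducible.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        subject_id = f"S{i:02d}"
        gain = float(rng.uniform(0.8, 1.2))
        yield synth_recording("normal", cfg, subject_id, rng, gain)
        yield synth_recording("fatigue", cfg, subject_id, rng, gain)


def synth_cohort(cfg: SynthConfig) -> list[EEGRecording]:
    """Materialized cohort: ``2 * n_subjects`` recordings."""
    return list(iter_cohort(cfg))


def write_cohort(cfg: SynthConfig, out_dir: str | Path) -> Path:
    """Write the cohort as delimited files plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in iter_cohort(cfg):
        name = f"{rec.subject_id}_{rec.state}.txt"
        write_recording(rec, out_dir / name)
        entries.append({
            "file": name,
            "subject_id": rec.subject_id,
            "state": rec.state,
            "n_channels": rec.n_channels,
            "n_timepoints": rec.n_timepoints,
        })
    manifest = {
        "config": asdict(cfg),
        "recordings": entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
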