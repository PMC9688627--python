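"""Synthetic resting-state EEG cohorts with class-dependent complexity.

Each channel is 1/f^beta colored noise (spectrally shaped white Gaussian
noise) plus a 10 Hz alpha oscillation, a shared low-rank background common to
all channels of a subject (a crude stand-in for volume conduction), and white
sensor noise. Class effects are injected only at a small set of
"discriminative" frontal channels (FC2, AFz, F2 by default): for DEP subjects
those channels use ``beta_dep`` / ``alpha_amp_dep`` instead of the shared
background parameters. Steeper beta means smoother, more persistent signals —
higher DFA exponent, lower spectral entropy — so the downstream region/feature
selection has a recoverable ground truth.

The generator makes no attempt at biophysical realism (no head model, no
artifact taxonomy); an optional blink injector exists for robustness checks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import CTL, DEP, Recording, canonical_label, write_edf

__all__ = [
    "CohortSpec",
    "DEFAULT_CHANNELS",
    "generate_cohort",
    "generate_subject",
    "save_cohort",
    "inject_blinks",
]

# 32 standard 10-20/10-10 labels covering the frontal discriminative set and
# a dozen fully-covered regions of the shipped association table.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp2", "Fpz", "AF3", "AF4", "AF8", "AFz", "F2", "F5", "F6",
    "FC2", "FC3", "FC4", "FC5", "FC6",
    "C1", "C2", "C3", "C4", "Cz", "Cpz", "CP1",
    "P1", "P2", "Pz",
    "PO3", "PO4", "PO7", "PO8", "POz",
    "O1", "O2", "Oz",
)


@dataclass
class CohortSpec:
    """Study-condition parameters for a synthetic cohort.

    Defaults mirror the emulated study: 24 controls and 26 depressive
    subjects, 32 channels at 500 Hz, an eyes-closed trigger 1 s into the
    recording, and a class contrast carried by the 1/f spectral exponent at
    FC2/AFz/F2 only.
    """

    n_ctl: int = 24
    n_dep: int = 26
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    fs: float = 500.0
    duration: float = 180.0
    beta_ctl: float = 1.0
    beta_dep: float = 1.5
    alpha_amp_ctl: float = 2.0
    alpha_amp_dep: float = 2.0
    discriminative_channels: tuple[str, ...] = ("FC2", "AFz", "F2")
    signal_rms: float = 10.0
    shared_gain: float = 0.3
    noise_sd: float = 1.0
    trigger_time: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_ctl < 1 or self.n_dep < 1:
            raise ValueError("n_ctl and n_dep must be >= 1")
        if self.beta_ctl < 0 or self.beta_dep < 0:
            raise ValueError("spectral exponents must be >= 0")
        if self.duration - self.trigger_time < 17.0:
            raise ValueError(
                "need >= 17 s of signal after the eyes-closed trigger "
                f"(duration {self.duration}, trigger at {self.trigger_time})"
            )
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")
        self.channels = tuple(canonical_label(c) for c in self.channels)
        self.discriminative_channels = tuple(
            canonical_label(c) for c in self.discriminative_channels
        )
        from .io import _canonical_1020_names

        table = _canonical_1020_names()
        unknown = [c for c in self.channels if c.lower() not in table]
        if unknown:
            raise ValueError(f"unknown electrode names: {unknown}")
        known = {c.lower() for c in self.channels}
        for ch in self.discriminative_channels:
            if ch.lower() not in known:
                raise ValueError(
                    f"discriminative channel {ch!r} not in the cohort montage"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        return cls(**json.loads(Path(path).read_text()))


def _colored_noise(rng: np.random.Generator, n: int, fs: float, beta: float) -> np.ndarray:
    """Unit-SD 1/f^beta noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_subject(
    spec: CohortSpec, subject_id: str, y: int, rng: np.random.Generator
) -> Recording:
    """Generate one subject's Recording under the cohort spec."""
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    shared = _colored_noise(rng, n, spec.fs, spec.beta_ctl)
    alpha_freq = 10.0 + rng.normal(0.0, 0.3)
    disc = {c.lower() for c in spec.discriminative_channels}
    data = np.empty((len(spec.channels), n))
    for i, ch in enumerate(spec.channels):
        effect = y == DEP and ch.lower() in disc
        beta = spec.beta_dep if effect else spec.beta_ctl
        alpha_amp = spec.alpha_amp_dep if effect else spec.alpha_amp_ctl
        x = spec.signal_rms * _colored_noise(rng, n, spec.fs, beta)
        x += spec.shared_gain * spec.signal_rms * shared
        x += alpha_amp * np.sin(2 * np.pi * alpha_freq * t + rng.uniform(0, 2 * np.pi))
        x += rng.normal(0.0, spec.noise_sd, size=n)
        data[i] = x
    trigger = int(round(spec.trigger_time * spec.fs))
    return Recording(
        channel_names=list(spec.channels),
        fs=spec.fs,
        data=data,
        events=[(trigger, "eyes_closed")],
        subject_id=subject_id,
        y=y,
    )


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate ``n_ctl + n_dep`` labeled Recordings, deterministically.

    The same spec (including ``seed``) reproduces byte-identical signals;
    each subject draws from an independent child seed, so cohort size changes
    do not perturb earlier subjects.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_ctl + spec.n_dep)
    cohort = []
    for i in range(spec.n_ctl):
        rng = np.random.default_rng(seeds[i])
        cohort.append(generate_subject(spec, f"sub-{i + 1:03d}", CTL, rng))
    for j in range(spec.n_dep):
        k = spec.n_ctl + j
        rng = np.random.default_rng(seeds[k])
        cohort.append(generate_subject(spec, f"sub-{k + 1:03d}", DEP, rng))
    return cohort


def save_cohort(cohort: list[Recording], directory: str | Path) -> list[Path]:
    """Write each Recording as ``<subject_id>.edf`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [write_edf(rec, directory / f"{rec.subject_id}.edf") for rec in cohort]


def inject_blinks(
    recording: Recording,
    rate_hz: float = 0.25,
    amplitude: float = 80.0,
    width: float = 0.2,
    frontal_prefixes: tuple[str, ...] = ("Fp", "AF", "F"),
    seed: int = 0,
) -> Recording:
    """Add stereotyped blink transients to frontal channels (robustness tool).

    Blinks are Gaussian-shaped deflections at Poisson times, scaled down for
    channels further from the eyes. Not part of the default generator: the
    artifact-removal stage is a pass-through hook and baseline cohorts are
    clean.
    """
    rng = np.random.default_rng(seed)
    n = recording.n_samples
    t = np.arange(n) / recording.fs
    n_blinks = rng.poisson(rate_hz * recording.duration)
    onsets = rng.uniform(0, recording.duration, size=n_blinks)
    pulse = np.zeros(n)
    for onset in onsets:
        pulse += np.exp(-0.5 * ((t - onset) / width) ** 2)
    data = recording.data.copy()
    for i, ch in enumerate(recording.channel_names):
        for scale, prefix in zip((1.0, 0.6, 0.35), frontal_prefixes):
            if ch.startswith(prefix):
                data[i] += scale * amplitude * pulse
                break
    out = Recording(
        channel_names=list(recording.channel_names),
        fs=recording.fs,
        data=data,
        events=list(recording.events),
        subject_id=recording.subject_id,
        y=recording.y,
    )
    return out
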