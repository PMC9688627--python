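"""EEG preprocessing: filtering, referencing, cropping, resampling, windowing.

The chain applied to each subject is: optional artifact-removal hook
(pass-through by default), 0.1-120 Hz band-pass, 50 Hz notch, 90 Hz low-pass,
average reference; then the segment after the eyes-closed trigger is cropped
to the chosen span and resampled to 200 Hz, split into consecutive
non-overlapping one-second (200-sample) windows, and each channel row of each
window is scaled to unit L2 norm.

Filters are zero-phase (forward-backward) order-4 Butterworth, notch Q=30.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = [
    "WindowVector",
    "filter_chain",
    "crop_and_resample",
    "vectorize",
    "preprocess_recording",
]

TARGET_FS = 200.0
WINDOW_SAMPLES = 200


@dataclass
class WindowVector:
    """One 1-s multichannel window: ``x`` is (n_channels, 200), unit-norm rows."""

    x: np.ndarray
    y: int
    channel_names: list[str]
    subject_id: str = "sub-000"
    window_index: int = 0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.ndim != 2 or self.x.shape[1] != WINDOW_SAMPLES:
            raise ValueError(f"window must be (channels, {WINDOW_SAMPLES})")


def filter_chain(
    recording: Recording,
    band: tuple[float, float] = (0.1, 120.0),
    notch: float = 50.0,
    lowpass: float = 90.0,
    order: int = 4,
    notch_q: float = 30.0,
    artifact_hook=None,
) -> Recording:
    """Band-pass, notch, low-pass and average-reference a recording.

    ``artifact_hook`` is an optional callable Recording -> Recording run
    before filtering (slot for an artifact-subspace-reconstruction style
    cleaner); the default is a pass-through.
    """
    fs = recording.fs
    if fs <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {band[1]} Hz band edge "
            f"(need fs > {2 * band[1]})"
        )
    if artifact_hook is not None:
        recording = artifact_hook(recording)
    data = recording.data
    # the 0.1 Hz edge has a multi-second impulse response; pad generously so
    # forward-backward filtering does not smear edge transients inward
    padlen = int(min(data.shape[1] - 1, 10 * fs))
    sos_band = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    data = sps.sosfiltfilt(sos_band, data, axis=1, padlen=padlen)
    b, a = sps.iirnotch(notch, notch_q, fs=fs)
    data = sps.filtfilt(b, a, data, axis=1, padlen=padlen)
    sos_low = sps.butter(order, lowpass, btype="lowpass", fs=fs, output="sos")
    data = sps.sosfiltfilt(sos_low, data, axis=1, padlen=padlen)
    data = data - data.mean(axis=0, keepdims=True)  # average reference
    return replace(recording, data=data, events=list(recording.events))


def crop_and_resample(
    recording: Recording,
    span: float,
    target_fs: float = TARGET_FS,
    trigger_label: str = "eyes_closed",
) -> Recording:
    """Crop ``span`` seconds after the eyes-closed trigger, resample to 200 Hz.

    The output starts at the trigger and has exactly ``span * target_fs``
    samples (polyphase resampling with an exact rational rate ratio).
    """
    t0 = recording.trigger_sample(trigger_label)
    n_need = int(round(span * recording.fs))
    if t0 + n_need > recording.n_samples:
        raise ValueError(
            f"subject {recording.subject_id}: needs {n_need} samples after the "
            f"trigger at {t0}, recording has {recording.n_samples}"
        )
    chunk = recording.data[:, t0 : t0 + n_need]
    ratio = Fraction(target_fs / recording.fs).limit_denominator(10000)
    if ratio != 1:
        chunk = sps.resample_poly(chunk, ratio.numerator, ratio.denominator, axis=1)
    n_out = int(round(span * target_fs))
    chunk = chunk[:, :n_out]
    return replace(
        recording,
        data=chunk,
        fs=float(target_fs),
        events=[(0, trigger_label)],
    )


def vectorize(
    recording: Recording, selected_channels: list[str] | None = None
) -> list[WindowVector]:
    """Split a 200 Hz recording into unit-norm 200-sample window vectors.

    Consecutive non-overlapping windows; any trailing remainder shorter than
    200 samples is dropped. Each channel row is scaled to unit L2 norm; a
    flat (zero-norm) channel raises, naming the channel.
    """
    if abs(recording.fs - TARGET_FS) > 1e-9:
        raise ValueError(
            f"vectorize expects a {TARGET_FS:.0f} Hz recording, got {recording.fs}"
        )
    rec = recording.pick(selected_channels) if selected_channels else recording
    if rec.y is None:
        raise ValueError(f"subject {rec.subject_id}: class label unknown")
    n_windows = rec.n_samples // WINDOW_SAMPLES
    windows = []
    for k in range(n_windows):
        x = rec.data[:, k * WINDOW_SAMPLES : (k + 1) * WINDOW_SAMPLES].copy()
        norms = np.linalg.norm(x, axis=1)
        flat = np.where(norms == 0)[0]
        if flat.size:
            names = [rec.channel_names[i] for i in flat]
            raise ValueError(
                f"subject {rec.subject_id}, window {k}: flat channel(s) {names}"
            )
        x /= norms[:, None]
        windows.append(
            WindowVector(
                x=x,
                y=rec.y,
                channel_names=list(rec.channel_names),
                subject_id=rec.subject_id,
                window_index=k,
            )
        )
    return windows


def preprocess_recording(
    recording: Recording,
    span: float,
    selected_channels: list[str] | None = None,
    filter: bool = True,
    artifact_hook=None,
) -> list[WindowVector]:
    """Full chain: filter -> crop/resample -> vectorize."""
    rec = filter_chain(recording, artifact_hook=artifact_hook) if filter else recording
    rec = crop_and_resample(rec, span)
    return vectorize(rec, selected_channels)
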