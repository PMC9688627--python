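"""Recording container and EDF(+)/FIF input-output.

Voltages are held in microvolts, channels x samples. Events are
``(sample_index, label)`` pairs; the eyes-closed trigger and the subject class
travel as annotations so that both survive an EDF or FIF round-trip.

The EDF writer is a minimal EDF+C implementation (16-bit samples, one-second
data records, a single annotations signal). Reading goes through MNE, which
also serves as an independent check on the writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Recording", "read_recording", "write_edf", "write_fif", "canonical_label"]

CLASS_ANNOTATION = {0: "class/DEP", 1: "class/CTL"}
_CLASS_FROM_ANNOTATION = {v: k for k, v in CLASS_ANNOTATION.items()}

DEP, CTL = 0, 1


def _canonical_1020_names() -> dict[str, str]:
    """lowercase -> canonical 10-20/10-05 label, e.g. 'afz' -> 'AFz'."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        names = mne.channels.make_standard_montage("standard_1005").ch_names
    table = {n.lower(): n for n in names}
    # nonstandard labels used by the shipped region table
    for extra in ("N1", "N2", "F9", "F10", "Cpz"):
        table.setdefault(extra.lower(), extra)
    return table


_CANONICAL_CACHE: dict[str, str] | None = None


def canonical_label(name: str) -> str:
    """Canonicalize a channel label to 10-20 nomenclature when known.

    Unknown labels are returned stripped but otherwise untouched.
    """
    global _CANONICAL_CACHE
    if _CANONICAL_CACHE is None:
        _CANONICAL_CACHE = _canonical_1020_names()
    return _CANONICAL_CACHE.get(name.strip().lower(), name.strip())


@dataclass
class Recording:
    """Labeled multichannel EEG segment.

    Parameters
    ----------
    channel_names
        10-20 electrode labels, one per data row.
    fs
        Sampling rate in Hz.
    data
        Voltage matrix in microvolts, shape ``(n_channels, n_samples)``.
    events
        ``(sample_index, label)`` pairs; the eyes-closed trigger is the event
        labeled ``"eyes_closed"``.
    subject_id
        Identifier used in file names and error messages.
    y
        Subject class: 0 = DEP, 1 = CTL, ``None`` = unknown.
    """

    channel_names: list[str]
    fs: float
    data: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)
    subject_id: str = "sub-000"
    y: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data must be (n_channels, n_samples) with "
                f"{len(self.channel_names)} rows, got {self.data.shape}"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        n = self.data.shape[1]
        for sample, label in self.events:
            if not 0 <= sample < max(n, 1):
                raise ValueError(f"event {label!r} at sample {sample} out of bounds")
        if len(set(self.channel_names)) != len(self.channel_names):
            dupes = sorted(
                {c for c in self.channel_names if self.channel_names.count(c) > 1}
            )
            raise ValueError(f"duplicate channel labels: {dupes}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def trigger_sample(self, label: str = "eyes_closed") -> int:
        for sample, lab in self.events:
            if lab == label:
                return sample
        raise ValueError(
            f"subject {self.subject_id}: no event labeled {label!r} "
            f"(events: {[lab for _, lab in self.events]})"
        )

    def pick(self, channels: list[str]) -> "Recording":
        """Subset channels (case-insensitive), preserving requested order."""
        lower = {c.lower(): i for i, c in enumerate(self.channel_names)}
        idx = []
        for ch in channels:
            if ch.lower() not in lower:
                raise KeyError(
                    f"subject {self.subject_id}: channel {ch!r} not in montage"
                )
            idx.append(lower[ch.lower()])
        return replace(
            self,
            channel_names=[self.channel_names[i] for i in idx],
            data=self.data[idx],
            events=list(self.events),
        )


# ---------------------------------------------------------------------------
# EDF+ writer
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii")
    if len(raw) > width:
        raise ValueError(f"EDF header field too long: {text!r} (> {width})")
    return raw.ljust(width)


def _annotation_payload(recording: Recording) -> list[bytes]:
    """One TAL byte string per event, onsets in seconds."""
    tals = []
    for sample, label in recording.events:
        onset = sample / recording.fs
        tals.append(f"+{onset:.7g}\x14{label}\x14\x00".encode("ascii"))
    if recording.y is not None:
        tals.append(f"+0\x14{CLASS_ANNOTATION[recording.y]}\x14\x00".encode("ascii"))
    return tals


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a Recording as an EDF+C file with an annotations signal.

    The recording length must be a whole number of seconds at an integer
    sampling rate (EDF data records are one second long here). Signals are
    quantized to 16 bits over a per-channel symmetric physical range; events
    and the class label are stored as EDF+ annotations.
    """
    if recording.n_samples == 0:
        raise ValueError("cannot write an empty recording")
    fs = recording.fs
    if not float(fs).is_integer():
        raise ValueError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs = int(fs)
    n = recording.n_samples
    if n % fs != 0:
        raise ValueError(
            f"recording length {n} is not a whole number of seconds at {fs} Hz"
        )
    n_records = n // fs
    n_sig = len(recording.channel_names)

    # symmetric physical range; quantize with the same affine map readers use,
    # against the (precision-limited) header strings
    raw_max = np.maximum(np.abs(recording.data).max(axis=1), 1e-6)
    pmax_str = [f"{m:.6g}"[:8] for m in raw_max]
    pmin_str = [f"{-m:.6g}"[:8] for m in raw_max]
    pmax = np.array([float(s) for s in pmax_str])
    pmin = np.array([float(s) for s in pmin_str])
    dig_min, dig_max = -32768, 32767
    gain = (pmax - pmin)[:, None] / (dig_max - dig_min)
    digital = np.round((recording.data - pmin[:, None]) / gain) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    tals = _annotation_payload(recording)
    annot_bytes = sum(len(t) for t in tals) + 16
    annot_len = max(60, (annot_bytes + 1) // 2)  # samples (2 bytes each)

    labels = list(recording.channel_names) + ["EDF Annotations"]
    spr = [fs] * n_sig + [annot_len]

    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"{recording.subject_id} X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (n_sig + 2)), 8),
            _pad("EDF+C", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_sig + 1), 4),
        ]
    )

    def sig_field(values, width):
        return b"".join(_pad(v, width) for v in values)

    header += sig_field(labels, 16)
    header += sig_field([""] * (n_sig + 1), 80)  # transducer
    header += sig_field(["uV"] * n_sig + [""], 8)
    header += sig_field(pmin_str + ["-1"], 8)
    header += sig_field(pmax_str + ["1"], 8)
    header += sig_field([str(dig_min)] * (n_sig + 1), 8)
    header += sig_field([str(dig_max)] * (n_sig + 1), 8)
    header += sig_field([""] * (n_sig + 1), 80)  # prefiltering
    header += sig_field([str(s) for s in spr], 8)
    header += sig_field([""] * (n_sig + 1), 32)

    path = Path(path)
    try:
        fh = open(path, "wb")
    except OSError as err:
        raise OSError(f"cannot write EDF to {path}: {err}") from err
    with fh:
        fh.write(header)
        remaining_tals = list(tals)
        for rec_i in range(n_records):
            start = rec_i * fs
            for ch in range(n_sig):
                fh.write(digital[ch, start : start + fs].tobytes())
            annot = f"+{rec_i}\x14\x14\x00".encode("ascii")
            if rec_i == 0:
                annot += b"".join(remaining_tals)
            annot = annot.ljust(annot_len * 2, b"\x00")
            if len(annot) > annot_len * 2:
                raise ValueError("annotation block overflow")
            fh.write(annot)
    return path


def write_fif(recording: Recording, path: str | Path) -> Path:
    """Write a Recording as a FIF file via MNE (annotations carry events)."""
    import mne

    info = mne.create_info(
        list(recording.channel_names), recording.fs, ch_types="eeg", verbose="error"
    )
    raw = mne.io.RawArray(recording.data * 1e-6, info, verbose="error")
    raw.info["subject_info"] = {"his_id": recording.subject_id}
    onsets = [s / recording.fs for s, _ in recording.events]
    labels = [lab for _, lab in recording.events]
    if recording.y is not None:
        onsets.append(0.0)
        labels.append(CLASS_ANNOTATION[recording.y])
    raw.set_annotations(
        mne.Annotations(onset=onsets, duration=[0.0] * len(onsets), description=labels)
    )
    path = Path(path)
    raw.save(path, overwrite=True, verbose="error")
    return path


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.upper()
        if fmt not in {"EDF", "FIF"}:
            raise ValueError(f"unsupported format {fmt!r}; use 'EDF' or 'FIF'")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "EDF"
    if suffix == ".fif":
        return "FIF"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read an EDF(+) or FIF file into a Recording.

    Channel names are canonicalized to 10-20 nomenclature; annotations become
    events, with ``class/DEP`` / ``class/CTL`` parsed into the class label.
    Duplicate channel labels (after canonicalization) raise an error naming
    the offenders.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "EDF":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")

    names = [canonical_label(n) for n in raw.ch_names]
    lowered = [n.lower() for n in names]
    dupes = sorted({n for n in lowered if lowered.count(n) > 1})
    if dupes:
        raise ValueError(f"{path.name}: duplicate channel labels {dupes}")

    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # V -> uV

    events: list[tuple[int, str]] = []
    y = None
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc in _CLASS_FROM_ANNOTATION:
            y = _CLASS_FROM_ANNOTATION[desc]
            continue
        events.append((int(round(onset * fs)), str(desc)))

    subject_id = path.stem.replace("_raw", "")
    info_subject = raw.info.get("subject_info")
    if isinstance(info_subject, dict):
        # EDF+ patient code (first token of the patient field)
        his = str(info_subject.get("his_id", "")).strip()
        if his and his not in {"X", ""}:
            subject_id = his.split()[0]

    return Recording(
        channel_names=names,
        fs=fs,
        data=data,
        events=events,
        subject_id=subject_id,
        y=y,
    )
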