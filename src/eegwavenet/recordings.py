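"""EEG recording data model, channel-label normalization, and EDF I/O.

A :class:`Recording` is the package's in-memory unit: a channels-by-samples
float array in microvolts, its sampling rate, ordered channel labels, a
subject id, and a recording-level class label (``normal``/``abnormal``/
``unknown``).  Class labels never live inside the EDF file; they come from a
sidecar manifest CSV (``path,label``) or from the synthetic generator.

Clinical EDF headers label channels in styles such as ``"EEG FP1-REF"`` or
``"EEG T7-LE"``; :func:`normalize_label` reduces these to canonical upper-case
10-20 electrode names, mapping the modern temporal-chain names (T7/T8/P7/P8)
back to the legacy names (T3/T4/T5/T6) that bipolar montage definitions use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EEGError, FormatError, InvalidRecordingError

CLASS_LABELS = ("normal", "abnormal", "unknown")

#: Modern 10-20 temporal-chain names mapped to the legacy names used by
#: bipolar montage definitions. Anything outside this map passes through.
LABEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

#: Prefixes/suffixes commonly found in clinical EDF channel labels.
_PREFIXES = ("EEG ",)
_SUFFIXES = ("-REF", "-LE")


def normalize_label(raw: str) -> str:
    """Reduce a raw channel label to a canonical 10-20 electrode name.

    Strips the ``"EEG "`` modality prefix and ``-REF``/``-LE`` reference
    suffixes, trims whitespace, upper-cases, and maps modern temporal-chain
    aliases to legacy names (T7->T3, T8->T4, P7->T5, P8->T6).  Unknown labels
    pass through normalized; the montage step flags genuinely missing
    electrodes downstream.
    """
    if not raw:
        raise ValueError("channel label must be non-empty")
    name = raw.strip().upper()
    for pre in _PREFIXES:
        if name.startswith(pre):
            name = name[len(pre):]
    for suf in _SUFFIXES:
        if name.endswith(suf):
            name = name[: -len(suf)]
    name = name.strip()
    return LABEL_ALIASES.get(name, name)


@dataclass
class Recording:
    """One multichannel EEG recording.

    Attributes
    ----------
    signal
        ``(n_channels, n_samples)`` float array in microvolts.
    fs
        Sampling rate in Hz, strictly positive.
    labels
        Ordered channel names, one per signal row, unique after
        normalization.
    subject_id
        Opaque identifier.
    class_label
        ``"normal"``, ``"abnormal"``, or ``"unknown"``.
    """

    signal: np.ndarray
    fs: float
    labels: list[str]
    subject_id: str = ""
    class_label: str = "unknown"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise InvalidRecordingError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] == 0:
            raise InvalidRecordingError("recording has zero channels")
        if len(self.labels) != self.signal.shape[0]:
            raise InvalidRecordingError(
                f"{len(self.labels)} labels for {self.signal.shape[0]} channels"
            )
        if not self.fs > 0:
            raise InvalidRecordingError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.signal)):
            raise InvalidRecordingError("signal contains non-finite samples")
        normed = [normalize_label(l) for l in self.labels]
        if len(set(normed)) != len(normed):
            raise InvalidRecordingError("channel labels not unique after normalization")
        if self.class_label not in CLASS_LABELS:
            raise InvalidRecordingError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def normalized_labels(self) -> list[str]:
        return [normalize_label(l) for l in self.labels]

    def with_signal(self, signal: np.ndarray, fs: float | None = None,
                    labels: list[str] | None = None) -> "Recording":
        """Copy of this recording with signal (and optionally fs/labels) replaced."""
        return replace(
            self,
            signal=signal,
            fs=self.fs if fs is None else fs,
            labels=list(self.labels) if labels is None else list(labels),
        )


def read_recording(path: str | Path, fmt: str = "autodetect",
                   class_label: str = "unknown") -> Recording:
    """Read one EEG recording from disk (EDF), normalizing channel labels.

    Signal values are returned in microvolts using the file's physical
    scaling. ``class_label`` defaults to ``unknown``; supply it from a
    manifest when known.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt not in ("edf", "autodetect"):
        raise ValueError(f"unknown format {fmt!r}")
    if fmt == "autodetect" and path.suffix.lower() not in (".edf", ".rec"):
        raise FormatError(f"cannot autodetect EEG format of {path}")
    try:
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except EEGError:
        raise
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"could not read {path} as EDF: {exc}") from exc
    data = raw.get_data() * 1e6  # mne returns volts; we keep microvolts
    labels = [normalize_label(name) for name in raw.ch_names]
    return Recording(
        signal=data,
        fs=float(raw.info["sfreq"]),
        labels=labels,
        subject_id=path.stem,
        class_label=class_label,
    )


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as a 16-bit EDF file.

    A deliberately small writer used for round-trip fixtures and for the
    ``simulate`` CLI output; it emits classic EDF (not EDF+) with one-second
    data records and per-channel physical scaling in microvolts.  The
    sampling rate must be a whole number of samples per second, and the
    signal is truncated to whole seconds.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1-s record
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    nchan = rec.n_channels
    sig = rec.signal[:, : n_records * spr]

    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    flat = phys_max - phys_min < 1e-9
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = bytearray()
    header += _pad("0", 8)
    header += _pad(rec.subject_id or "X", 80)
    header += _pad("synthetic", 80)
    now = datetime(2000, 1, 1)
    header += _pad(now.strftime("%d.%m.%y"), 8)
    header += _pad(now.strftime("%H.%M.%S"), 8)
    header += _pad(str(256 * (1 + nchan)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)  # record duration, seconds
    header += _pad(str(nchan), 4)

    def field_block(values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in values)

    header += field_block([str(l) for l in rec.labels], 16)
    header += field_block([""] * nchan, 80)  # transducer
    header += field_block(["uV"] * nchan, 8)
    header += field_block([f"{v:.6g}" for v in phys_min], 8)
    header += field_block([f"{v:.6g}" for v in phys_max], 8)
    header += field_block([str(dig_min)] * nchan, 8)
    header += field_block([str(dig_max)] * nchan, 8)
    header += field_block([""] * nchan, 80)  # prefiltering
    header += field_block([str(spr)] * nchan, 8)
    header += field_block([""] * nchan, 32)

    # physical -> digital, per channel
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((sig - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sidecar label manifest: CSV with header ``path,label``."""
    df = pd.read_csv(path)
    if not {"path", "label"}.issubset(df.columns):
        raise FormatError(f"manifest {path} must have columns 'path' and 'label'")
    bad = set(df["label"]) - {"normal", "abnormal"}
    if bad:
        raise FormatError(f"manifest labels must be normal/abnormal, found {sorted(bad)}")
    return df[["path", "label"]]


def load_dataset(manifest_path: str | Path) -> list[Recording]:
    """Read every recording listed in a manifest, attaching its class label.

    Relative paths in the manifest resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    recs = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        recs.append(read_recording(p, class_label=row.label))
    return recs
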