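"""Clinical-EEG preprocessing: filtering, TCP montage, resampling, segments.

The TUAB-style pipeline is: fourth-order Butterworth high-pass at 1 Hz, a
60 Hz notch against power-line interference, derivation of the 20-channel
Transverse Central Parietal (TCP) bipolar montage, resampling to 250 Hz,
extraction of the first 60-s segment plus a time-reversed copy of the second
60 s (time-reverse augmentation), and per-segment per-channel
standardization.  The TUEP-style pipeline instead applies a second-order
0.5-49 Hz bandpass, keeps the first 30 channels, and uses the first 30 s
with no augmentation.

All filtering is zero-phase (forward-backward), so the effective magnitude
response is the squared single-pass response and no group delay is
introduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import MontageError, ParameterError, TooShortError
from .recordings import Recording, normalize_label

# --------------------------------------------------------------------------
# filter specification


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth high-pass/bandpass or an IIR notch.

    ``order`` is the Butterworth order (ignored for notch); ``cutoff_hz`` is
    one frequency (highpass, notch) or a (low, high) pair (bandpass);
    ``notch_q`` is the notch quality factor.
    """

    kind: str  # highpass | bandpass | notch
    cutoff_hz: tuple[float, ...]
    order: int = 4
    notch_q: float = 30.0

    def __post_init__(self):
        if self.kind not in ("highpass", "bandpass", "notch"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        cut = tuple(float(c) for c in (
            self.cutoff_hz if np.iterable(self.cutoff_hz) else (self.cutoff_hz,)
        ))
        object.__setattr__(self, "cutoff_hz", cut)
        if self.kind == "bandpass":
            if len(cut) != 2 or not cut[0] < cut[1]:
                raise ParameterError(f"bandpass needs low < high, got {cut}")
        elif len(cut) != 1:
            raise ParameterError(f"{self.kind} takes one cutoff, got {cut}")
        if self.kind != "notch" and self.order < 1:
            raise ParameterError("filter order must be >= 1")

    def validate_for_fs(self, fs: float) -> None:
        for c in self.cutoff_hz:
            if not 0 < c < fs / 2:
                raise ParameterError(
                    f"cutoff {c} Hz outside (0, {fs / 2}) for fs={fs}"
                )


#: Standard TUAB preprocessing filters.
HIGHPASS_1HZ = FilterSpec("highpass", (1.0,), order=4)
NOTCH_60HZ = FilterSpec("notch", (60.0,), notch_q=30.0)
BANDPASS_05_49 = FilterSpec("bandpass", (0.5, 49.0), order=2)


def apply_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Apply a filter zero-phase (forward-backward) to every channel.

    Length and sampling rate are preserved.
    """
    spec.validate_for_fs(rec.fs)
    if spec.kind == "notch":
        b, a = sps.iirnotch(spec.cutoff_hz[0], spec.notch_q, fs=rec.fs)
        out = sps.filtfilt(b, a, rec.signal, axis=1)
    else:
        wn = spec.cutoff_hz if spec.kind == "bandpass" else spec.cutoff_hz[0]
        sos = sps.butter(spec.order, wn, btype=spec.kind, fs=rec.fs, output="sos")
        out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return rec.with_signal(out)


# --------------------------------------------------------------------------
# montage


@dataclass(frozen=True)
class MontageSpec:
    """Ordered anode/cathode electrode pairs defining a bipolar montage."""

    pairs: tuple[tuple[str, str], ...]
    name: str = ""

    def __post_init__(self):
        pairs = tuple((normalize_label(a), normalize_label(c)) for a, c in self.pairs)
        if len(set(pairs)) != len(pairs):
            raise ParameterError(f"duplicate pairs in montage {self.name!r}")
        object.__setattr__(self, "pairs", pairs)

    @property
    def electrodes(self) -> set[str]:
        return {e for pair in self.pairs for e in pair}

    @property
    def channel_names(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.pairs]


#: The 20-channel TCP bipolar montage: the standard TUH TCP chain layout with
#: the two ear-reference chains omitted (the unique standard variant with
#: exactly 20 derived channels).
TCP_20 = MontageSpec(
    pairs=(
        ("FP1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
        ("FP2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
        ("T3", "C3"), ("C3", "CZ"), ("CZ", "C4"), ("C4", "T4"),
        ("FP1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
        ("FP2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ),
    name="tcp20",
)


def derive_tcp_montage(rec: Recording, spec: MontageSpec = TCP_20) -> Recording:
    """Derive a bipolar montage: output channel i = anode_i - cathode_i.

    Raises :class:`MontageError` listing *all* missing electrodes if any
    electrode named in the spec is absent from the recording.
    """
    labels = rec.normalized_labels()
    index = {name: i for i, name in enumerate(labels)}
    missing = sorted(spec.electrodes - set(labels))
    if missing:
        raise MontageError(missing)
    rows = np.empty((len(spec.pairs), rec.n_samples), dtype=np.float64)
    for i, (a, c) in enumerate(spec.pairs):
        rows[i] = rec.signal[index[a]] - rec.signal[index[c]]
    return rec.with_signal(rows, labels=spec.channel_names)


# --------------------------------------------------------------------------
# resampling


def resample(rec: Recording, target_fs: float) -> Recording:
    """Band-limited (polyphase, anti-aliased) resampling to ``target_fs``.

    The output length follows ``round(n * target_fs / fs)``.  When the rate
    is already ``target_fs`` the identical signal is returned.
    """
    if not target_fs > 0:
        raise ParameterError(f"target_fs must be positive, got {target_fs}")
    if target_fs == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = sps.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=1)
    n_target = int(round(rec.n_samples * target_fs / rec.fs))
    if out.shape[1] > n_target:
        out = out[:, :n_target]
    elif out.shape[1] < n_target:
        out = np.pad(out, ((0, 0), (0, n_target - out.shape[1])), mode="edge")
    return rec.with_signal(out, fs=target_fs)


# --------------------------------------------------------------------------
# segments


@dataclass
class SegmentSet:
    """Fixed-length, model-ready segments with labels and provenance.

    ``data`` is ``(n_segments, n_channels, n_samples)``; ``provenance`` marks
    each segment ``original`` or ``reversed``; ``sources`` carries the source
    recording id so a segment and its time-reversed twin can be kept in the
    same training fold.
    """

    data: np.ndarray
    labels: list[str]
    fs: float
    provenance: list[str]
    channel_names: list[str]
    sources: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("segment data must be 3-D")
        n = self.data.shape[0]
        if not self.sources:
            self.sources = [""] * n
        for name, seq in (("labels", self.labels), ("provenance", self.provenance),
                          ("sources", self.sources)):
            if len(seq) != n:
                raise ValueError(f"{name} length {len(seq)} != {n} segments")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length mismatch")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Integer class vector: normal=0, abnormal=1."""
        return np.array([1 if l == "abnormal" else 0 for l in self.labels])

    def subset(self, idx) -> "SegmentSet":
        idx = np.asarray(idx)
        return SegmentSet(
            data=self.data[idx],
            labels=[self.labels[i] for i in idx],
            fs=self.fs,
            provenance=[self.provenance[i] for i in idx],
            channel_names=list(self.channel_names),
            sources=[self.sources[i] for i in idx],
        )

    @classmethod
    def concatenate(cls, sets: list["SegmentSet"]) -> "SegmentSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        first = sets[0]
        for s in sets[1:]:
            if s.fs != first.fs or s.channel_names != first.channel_names:
                raise ValueError("incompatible segment sets")
        return cls(
            data=np.concatenate([s.data for s in sets], axis=0),
            labels=sum((s.labels for s in sets), []),
            fs=first.fs,
            provenance=sum((s.provenance for s in sets), []),
            channel_names=list(first.channel_names),
            sources=sum((s.sources for s in sets), []),
        )

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            data=self.data,
            labels=np.array(self.labels),
            fs=np.array(self.fs),
            provenance=np.array(self.provenance),
            channel_names=np.array(self.channel_names),
            sources=np.array(self.sources),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SegmentSet":
        z = np.load(path, allow_pickle=False)
        return cls(
            data=z["data"],
            labels=[str(x) for x in z["labels"]],
            fs=float(z["fs"]),
            provenance=[str(x) for x in z["provenance"]],
            channel_names=[str(x) for x in z["channel_names"]],
            sources=[str(x) for x in z["sources"]],
        )


def extract_segments(rec: Recording, seg_seconds: float,
                     augment_reverse: bool = True) -> SegmentSet:
    """Cut the leading fixed-length segment, optionally adding a reversed one.

    Segment 1 is the first ``seg_seconds`` of the recording.  With
    ``augment_reverse`` and at least twice that duration available, segment 2
    is the *second* ``seg_seconds`` played backwards (time-reverse
    augmentation); recordings shorter than two segment lengths yield one
    segment only.
    """
    n_seg = int(round(seg_seconds * rec.fs))
    if rec.n_samples < n_seg:
        raise TooShortError(rec.duration_s, seg_seconds)
    chunks = [rec.signal[:, :n_seg]]
    provenance = ["original"]
    if augment_reverse and rec.n_samples >= 2 * n_seg:
        chunks.append(rec.signal[:, n_seg: 2 * n_seg][:, ::-1])
        provenance.append("reversed")
    return SegmentSet(
        data=np.stack(chunks, axis=0),
        labels=[rec.class_label] * len(chunks),
        fs=rec.fs,
        provenance=provenance,
        channel_names=list(rec.labels),
        sources=[rec.subject_id] * len(chunks),
    )


def standardize(segs: SegmentSet) -> SegmentSet:
    """Per segment, per channel: subtract the mean, divide by the SD.

    A zero-variance channel would divide by zero; the guard substitutes a
    unit denominator and emits a warning, leaving that channel at zero.
    """
    mean = segs.data.mean(axis=2, keepdims=True)
    sd = segs.data.std(axis=2, keepdims=True)
    zero = sd < 1e-15
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance channel-segment(s); "
            "unit denominator substituted",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = np.where(zero, 1.0, sd)
    return SegmentSet(
        data=(segs.data - mean) / sd,
        labels=list(segs.labels),
        fs=segs.fs,
        provenance=list(segs.provenance),
        channel_names=list(segs.channel_names),
        sources=list(segs.sources),
    )


# --------------------------------------------------------------------------
# profiles

PROFILES = ("tuab", "tuep")


def preprocess_pipeline(rec: Recording, profile: str = "tuab",
                        seg_seconds: float | None = None,
                        target_fs: float = 250.0) -> SegmentSet:
    """Run the full per-recording preprocessing for a named profile.

    ``tuab``: high-pass (4th order, 1 Hz) -> 60 Hz notch -> TCP-20 montage ->
    resample to 250 Hz -> 60-s segments with time-reverse augmentation ->
    standardize.

    ``tuep``: bandpass (2nd order, 0.5-49 Hz) -> first 30 channels ->
    resample to 250 Hz -> first 30 s only, no augmentation -> standardize.

    ``seg_seconds`` overrides the profile's segment length (used for
    scaled-down experiments).
    """
    if profile == "tuab":
        seg_s = 60.0 if seg_seconds is None else seg_seconds
        rec = apply_filter(rec, HIGHPASS_1HZ)
        rec = apply_filter(rec, NOTCH_60HZ)
        rec = derive_tcp_montage(rec, TCP_20)
        rec = resample(rec, target_fs)
        segs = extract_segments(rec, seg_s, augment_reverse=True)
    elif profile == "tuep":
        seg_s = 30.0 if seg_seconds is None else seg_seconds
        rec = apply_filter(rec, BANDPASS_05_49)
        if rec.n_channels < 30:
            raise ParameterError(
                f"tuep profile needs >=30 channels, recording has {rec.n_channels}"
            )
        rec = rec.with_signal(rec.signal[:30], labels=rec.labels[:30])
        rec = resample(rec, target_fs)
        segs = extract_segments(rec, seg_s, augment_reverse=False)
    else:
        raise ParameterError(f"unknown profile {profile!r}; choose from {PROFILES}")
    return standardize(segs)


def preprocess_dataset(recs: list[Recording], profile: str = "tuab",
                       seg_seconds: float | None = None,
                       target_fs: float = 250.0) -> SegmentSet:
    """Preprocess a list of recordings and concatenate their segments."""
    return SegmentSet.concatenate(
        [preprocess_pipeline(r, profile, seg_seconds, target_fs) for r in recs]
    )
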