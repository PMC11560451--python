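"""Preprocessing: channel selection, band-pass filtering, windowing, splits.

The pipeline is: select and order the 22 montage channels, band-pass
0.5-70 Hz with a fifth-order Butterworth (applied forward-backward, so zero
phase), window into 3-s segments with 50% overlap inside seizures and no
overlap outside, discard the rarer ictal class's windows that straddle an
onset/offset, rebalance the interictal pool to 5:1, and split either by
stratified 5-fold (patient-specific) or leave-one-subject-out
(patient-independent).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from sklearn.model_selection import StratifiedKFold

from .data import EEGRecording, SegmentSet
from .montage import CANONICAL_CHANNELS, normalize_channel_name


def select_channels(
    rec: EEGRecording, wanted: tuple[str, ...] = CANONICAL_CHANNELS
) -> EEGRecording:
    """Reorder (and deduplicate) channels to the requested canonical list.

    Matching is case-insensitive and whitespace/duplicate-suffix normalized;
    if a derivation appears more than once the first occurrence wins.
    Missing derivations raise, naming every absent one — no silent zero-fill.
    """
    index: dict[str, int] = {}
    for i, name in enumerate(rec.channel_names):
        index.setdefault(normalize_channel_name(name), i)
    rows, missing = [], []
    for name in wanted:
        key = normalize_channel_name(name)
        if key in index:
            rows.append(index[key])
        else:
            missing.append(name)
    if missing:
        raise KeyError(f"recording lacks derivations: {', '.join(missing)}")
    return EEGRecording(
        signal=rec.signal[rows],
        fs=rec.fs,
        channel_names=[normalize_channel_name(w) for w in wanted],
        seizure_intervals=list(rec.seizure_intervals),
        patient_id=rec.patient_id,
    )


def bandpass(
    rec: EEGRecording,
    low_hz: float = 0.5,
    high_hz: float = 70.0,
    order: int = 5,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, each channel independently.

    The filter is applied forward and backward (``sosfiltfilt``), which
    squares the magnitude response (effective order doubles) and removes
    phase distortion — standard practice for offline EEG.
    """
    nyq = rec.fs / 2.0
    if not 0.0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return EEGRecording(
        signal=filtered,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        seizure_intervals=list(rec.seizure_intervals),
        patient_id=rec.patient_id,
    )


def _interictal_stretches(
    intervals: list[tuple[float, float]], duration: float
) -> list[tuple[float, float]]:
    out, prev = [], 0.0
    for onset, offset in sorted(intervals):
        if onset > prev:
            out.append((prev, onset))
        prev = max(prev, offset)
    if duration > prev:
        out.append((prev, duration))
    return out


def segment(
    rec: EEGRecording, window_s: float = 3.0, ictal_overlap: float = 0.5
) -> SegmentSet:
    """Window the record into fixed-length labeled segments.

    Ictal stretches are windowed with stride ``window_s * (1 - ictal_overlap)``
    (overlap oversamples the rare class); interictal stretches with stride
    ``window_s``. A window is ictal iff it lies entirely inside a seizure
    interval; windows that would straddle an onset/offset are not generated.
    """
    w = window_s * rec.fs
    if abs(w - round(w)) > 1e-9:
        raise ValueError("window_s * fs must be an integer number of samples")
    w = int(round(w))
    if not 0.0 <= ictal_overlap < 1.0:
        raise ValueError("ictal_overlap must be in [0, 1)")
    if rec.n_samples < w:
        warnings.warn("record shorter than one window; empty segment set")
        return SegmentSet(
            np.empty((0, rec.n_channels, w)),
            np.empty(0, dtype=int),
            np.empty(0, dtype=object),
            rec.fs,
            window_s,
        )

    stride_ictal = max(int(round(w * (1.0 - ictal_overlap))), 1)
    segs, labels = [], []

    def harvest(t0: float, t1: float, stride: int, label: int) -> None:
        i0, i1 = int(round(t0 * rec.fs)), int(round(t1 * rec.fs))
        i1 = min(i1, rec.n_samples)
        start = i0
        while start + w <= i1:
            segs.append(rec.signal[:, start : start + w])
            labels.append(label)
            start += stride

    for onset, offset in sorted(rec.seizure_intervals):
        harvest(onset, offset, stride_ictal, 1)
    for t0, t1 in _interictal_stretches(rec.seizure_intervals, rec.duration_s):
        harvest(t0, t1, w, 0)

    n = len(segs)
    return SegmentSet(
        np.stack(segs) if n else np.empty((0, rec.n_channels, w)),
        np.asarray(labels, dtype=int),
        np.full(n, rec.patient_id, dtype=object),
        rec.fs,
        window_s,
    )


def rebalance_pool(
    segs: SegmentSet, interictal_to_ictal: float = 5.0, seed: int = 0
) -> SegmentSet:
    """Subsample the interictal pool to at most ``ratio`` per ictal segment.

    All ictal segments are kept; interictal segments are drawn uniformly
    without replacement (seeded). The relative order of retained segments is
    preserved.
    """
    n0, n1 = segs.class_counts()
    if n1 == 0:
        raise ValueError("no ictal segments; cannot rebalance")
    keep_inter = min(n0, int(interictal_to_ictal * n1))
    rng = np.random.default_rng(seed)
    inter_idx = np.flatnonzero(segs.labels == 0)
    chosen = rng.choice(inter_idx, size=keep_inter, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(segs.labels == 1), chosen]))
    return segs.subset(keep)


def make_splits(
    segs: SegmentSet,
    mode: str,
    n_folds: int = 5,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Build (train, val, test) index triples for either evaluation protocol.

    ``patient_specific``: stratified ``n_folds``-fold over one subject's
    segments; fold i uses fold i as test, the next fold as validation and the
    rest as training. ``patient_independent``: leave-one-subject-out — each
    patient in turn is the test set, one randomly chosen (seeded) held-in
    patient is the validation set, the rest train.
    """
    patients = np.unique(segs.patient_ids)
    if mode == "patient_specific":
        if len(patients) != 1:
            raise ValueError(
                f"patient_specific mode needs exactly one patient, got {len(patients)}"
            )
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [test for _, test in skf.split(np.zeros(len(segs)), segs.labels)]
        out = []
        for i in range(n_folds):
            test = folds[i]
            val = folds[(i + 1) % n_folds]
            train = np.concatenate(
                [folds[j] for j in range(n_folds) if j not in (i, (i + 1) % n_folds)]
            )
            out.append((np.sort(train), np.sort(val), np.sort(test)))
        return out
    if mode == "patient_independent":
        if len(patients) < 3:
            raise ValueError("leave-one-subject-out needs at least 3 patients")
        rng = np.random.default_rng(seed)
        out = []
        for p in patients:
            test = np.flatnonzero(segs.patient_ids == p)
            held_in = [q for q in patients if q != p]
            val_patient = held_in[rng.integers(len(held_in))]
            val = np.flatnonzero(segs.patient_ids == val_patient)
            train = np.flatnonzero(
                (segs.patient_ids != p) & (segs.patient_ids != val_patient)
            )
            out.append((train, val, test))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def prepare_recording(
    rec: EEGRecording,
    wanted: tuple[str, ...] | None = None,
    low_hz: float = 0.5,
    high_hz: float = 70.0,
    order: int = 5,
    window_s: float = 3.0,
    ictal_overlap: float = 0.5,
) -> SegmentSet:
    """Convenience chain: select channels -> band-pass -> segment."""
    if wanted is not None:
        rec = select_channels(rec, wanted)
    elif rec.n_channels == len(CANONICAL_CHANNELS):
        rec = select_channels(rec, CANONICAL_CHANNELS)
    rec = bandpass(rec, low_hz, high_hz, order)
    return segment(rec, window_s, ictal_overlap)
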