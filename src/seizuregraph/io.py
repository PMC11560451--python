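"""File I/O: EDF read/write, seizure-annotation sidecars, segment bundles.

EDF reading goes through MNE. Writing uses a minimal plain-EDF writer
(16-bit samples, one-second data records) so synthetic recordings can
exercise the EDF reading path end-to-end. Seizure intervals travel in a
plain-text sidecar — one line per seizure, ``record_id<TAB>onset_s<TAB>
offset_s`` — mirroring how CHB-MIT ships seizure times in per-subject
summary text files rather than inside the EDF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .data import EEGRecording, SegmentSet


# -- EDF ---------------------------------------------------------------------


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field too long: {text!r} > {width}")
    return b.ljust(width)


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as plain EDF (16-bit, one-second data records).

    The sampling rate must be a positive integer; the signal is zero-padded
    to a whole number of records. Amplitudes are scaled per channel to the
    full 16-bit range (physical dimension recorded as uV).
    """
    fs = rec.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_ch, n_samp = rec.signal.shape
    n_rec = -(-n_samp // fs)  # ceil
    sig = np.zeros((n_ch, n_rec * fs))
    sig[:, :n_samp] = rec.signal

    pmax = np.maximum(np.abs(sig).max(axis=1), 1e-6)
    dmax = 32767
    digital = np.round(sig / pmax[:, None] * dmax).astype("<i2")

    head = b"".join(
        [
            _field("0", 8),
            _field(rec.patient_id, 80),
            _field("seizuregraph synthetic", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (n_ch + 1)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    per = b"".join(
        [
            b"".join(_field(name[:16], 16) for name in rec.channel_names),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{-p:.6g}"[:8], 8) for p in pmax),
            b"".join(_field(f"{p:.6g}"[:8], 8) for p in pmax),
            b"".join(_field(str(-dmax), 8) for _ in range(n_ch)),
            b"".join(_field(str(dmax), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(fs), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as f:
        f.write(head + per)
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            f.write(block.astype("<i2").tobytes())


def read_edf(
    path,
    seizure_intervals: list[tuple[float, float]] | None = None,
    patient_id: str | None = None,
) -> EEGRecording:
    """Read an EDF/EDF+ file via MNE; amplitudes returned in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # MNE is in volts
    return EEGRecording(
        signal=signal,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        seizure_intervals=list(seizure_intervals or []),
        patient_id=patient_id or Path(path).stem,
    )


# -- annotations -------------------------------------------------------------


def write_annotations(intervals_by_record: dict[str, list[tuple[float, float]]],
                      path) -> None:
    """One line per seizure: ``record_id<TAB>onset_s<TAB>offset_s``."""
    lines = [
        f"{rid}\t{onset:.6g}\t{offset:.6g}"
        for rid, intervals in intervals_by_record.items()
        for onset, offset in intervals
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_annotations(path) -> dict[str, list[tuple[float, float]]]:
    out: dict[str, list[tuple[float, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        rid, onset, offset = parts
        out.setdefault(rid, []).append((float(onset), float(offset)))
    return out


# -- segment bundles ---------------------------------------------------------


def save_segments(segs: SegmentSet, path) -> Path:
    """Compressed array bundle plus a JSON sidecar (fs, window, patients)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    np.savez_compressed(
        path,
        segments=segs.segments,
        labels=segs.labels,
        patient_ids=segs.patient_ids.astype(str),
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "fs": segs.fs,
                "window_s": segs.window_s,
                "n_segments": len(segs),
                "patients": sorted(set(segs.patient_ids.astype(str).tolist())),
            },
            indent=2,
        )
        + "\n"
    )
    return path


def load_segments(path) -> SegmentSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with np.load(path, allow_pickle=False) as z:
        return SegmentSet(
            z["segments"],
            z["labels"],
            z["patient_ids"].astype(object),
            float(sidecar["fs"]),
            float(sidecar["window_s"]),
        )
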