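"""Synthetic multichannel scalp EEG with controllable seizure structure.

The generator emulates the gross statistical structure of CHB-MIT-style
records that the downstream pipeline is sensitive to: 22 channels at 256 Hz,
pink (1/f) interictal background with a controllable level of inter-channel
correlation, and ictal stretches carrying a frequency-jittered rhythmic
oscillation that is shared across channels (raising cross-channel Pearson
correlation) and strongest on a focal subset of channels. It makes no
attempt at physiological realism beyond that (no artifacts, no spike
morphology, arbitrary amplitude units).

The key contrast the generator is built to create is the one the functional
connectivity graph is designed to detect: pairwise correlation during
seizures exceeds the interictal baseline whenever ``ictal_sync`` exceeds
``background_corr`` and ``ictal_gain`` exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import EEGRecording
from .montage import CANONICAL_CHANNELS


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording.

    Parameters
    ----------
    background_corr
        Target pairwise Pearson correlation of the interictal background,
        in ``[0, 1)``; realized by mixing a shared pink-noise component into
        every channel at this weight.
    ictal_freq_hz
        Center frequency of the seizure rhythm, in ``[3, 12]`` (theta/alpha
        band where scalp seizure rhythms are typically most visible).
    ictal_sync
        Fraction of the added ictal power that is common across channels,
        ``>= background_corr``; equality (with ``ictal_gain == 1``) is the
        degenerate no-effect case.
    ictal_gain
        Amplitude multiplier of the seizure rhythm relative to the
        background RMS; the rhythm is added with amplitude
        ``(ictal_gain - 1)`` times the background RMS, so ``1`` adds nothing.
    focal_channels
        Indices carrying the full-strength rhythm; the remaining channels
        receive it attenuated. ``None`` selects the left temporal chain
        (channels 0-3).
    """

    duration_s: float
    n_channels: int = 22
    fs: float = 256.0
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    background_corr: float = 0.2
    ictal_freq_hz: float = 6.0
    ictal_sync: float = 0.8
    ictal_gain: float = 3.0
    focal_channels: tuple[int, ...] | None = None
    patient_id: str = "P00"
    seed: int = 0

    #: rhythm attenuation on non-focal channels
    nonfocal_gain: float = 0.4
    #: relative frequency jitter of the seizure rhythm
    freq_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0 or self.n_channels < 2:
            raise ValueError("need positive duration and fs and >=2 channels")
        if not 0.0 <= self.background_corr < 1.0:
            raise ValueError("background_corr must be in [0, 1)")
        if not 3.0 <= self.ictal_freq_hz <= 12.0:
            raise ValueError("ictal_freq_hz must be in [3, 12]")
        if not self.background_corr <= self.ictal_sync <= 1.0:
            raise ValueError("ictal_sync must be in [background_corr, 1]")
        if self.ictal_gain < 1.0:
            raise ValueError("ictal_gain must be >= 1")
        ivs = sorted(self.seizure_intervals)
        for onset, offset in ivs:
            if not (0.0 <= onset < offset <= self.duration_s):
                raise ValueError(f"invalid seizure interval ({onset}, {offset})")
        for (_, off0), (on1, _) in zip(ivs, ivs[1:]):
            if on1 < off0:
                raise ValueError("seizure intervals must be disjoint")
        self.seizure_intervals = ivs
        if self.focal_channels is None:
            self.focal_channels = tuple(range(min(4, self.n_channels)))
        if any(not 0 <= c < self.n_channels for c in self.focal_channels):
            raise ValueError("focal_channels out of range")


def _pink_noise(rng: np.random.Generator, n: int, ncols: int = 1) -> np.ndarray:
    """Unit-variance noise with ~1/f power spectral slope, shape (ncols, n)."""
    white = rng.standard_normal((ncols, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    # flat below a small knee so the variance is not dominated by
    # near-DC power (keeps short-window statistics well-behaved)
    knee = 4.0 / n
    shape = 1.0 / np.sqrt(np.maximum(f, knee))
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x


def _smooth_jitter(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Slow random modulation in [-1, 1] (≈0.3 Hz bandwidth)."""
    coarse_n = max(int(n / fs * 0.3) + 2, 4)
    coarse = rng.standard_normal(coarse_n)
    t = np.linspace(0, coarse_n - 1, n)
    m = np.interp(t, np.arange(coarse_n), coarse)
    m /= max(np.abs(m).max(), 1e-12)
    return m


def generate_recording(spec: SyntheticSpec) -> EEGRecording:
    """Generate one synthetic recording; bit-identical under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    nch = spec.n_channels

    shared = _pink_noise(rng, n)[0]
    private = _pink_noise(rng, n, nch)
    b = spec.background_corr
    signal = np.sqrt(1.0 - b) * private + np.sqrt(b) * shared

    ramp_s = 0.5
    chan_gain = np.full(nch, spec.nonfocal_gain)
    chan_gain[list(spec.focal_channels)] = 1.0
    amp = (spec.ictal_gain - 1.0) * chan_gain  # background RMS is 1

    for onset, offset in spec.seizure_intervals:
        i0, i1 = int(round(onset * spec.fs)), int(round(offset * spec.fs))
        m = i1 - i0
        if m <= 0:
            continue
        # frequency-jittered common rhythm, random phase per seizure
        jitter = _smooth_jitter(rng, m, spec.fs)
        inst_freq = spec.ictal_freq_hz * (1.0 + spec.freq_jitter * jitter)
        phase = 2 * np.pi * np.cumsum(inst_freq) / spec.fs
        phase += rng.uniform(0, 2 * np.pi)
        rhythm = np.sqrt(2.0) * np.sin(phase)  # unit variance
        # independent per-channel part in the same band
        priv = _pink_noise(rng, m, nch) if m >= 8 else rng.standard_normal((nch, m))
        s = spec.ictal_sync
        comp = np.sqrt(s) * rhythm[None, :] + np.sqrt(1.0 - s) * priv
        env = np.ones(m)
        k = min(int(ramp_s * spec.fs), m // 2)
        if k > 0:
            up = 0.5 * (1 - np.cos(np.linspace(0, np.pi, k)))
            env[:k] = up
            env[-k:] = up[::-1]
        signal[:, i0:i1] += amp[:, None] * env[None, :] * comp

    names = (
        list(CANONICAL_CHANNELS)
        if nch == len(CANONICAL_CHANNELS)
        else [f"CH{i:02d}" for i in range(nch)]
    )
    return EEGRecording(
        signal=signal,
        fs=spec.fs,
        channel_names=names,
        seizure_intervals=list(spec.seizure_intervals),
        patient_id=spec.patient_id,
    )


def evenly_spaced_seizures(
    duration_s: float, n_seizures: int, seizure_s: float = 40.0
) -> list[tuple[float, float]]:
    """Place ``n_seizures`` seizures of ``seizure_s`` seconds evenly through
    the record, centered in equal-width slots, leaving interictal margins."""
    if n_seizures < 1:
        return []
    slot = duration_s / n_seizures
    if seizure_s >= slot:
        raise ValueError("seizures too long for the requested duration")
    return [
        (round(i * slot + (slot - seizure_s) / 2, 3),
         round(i * slot + (slot + seizure_s) / 2, 3))
        for i in range(n_seizures)
    ]


def generate_cohort(
    n_patients: int,
    base: SyntheticSpec,
    variability: float,
    seed: int,
) -> list[EEGRecording]:
    """Generate a cohort of recordings with per-patient parameter jitter.

    Each patient perturbs ``ictal_freq_hz`` and ``ictal_gain`` by a relative
    uniform factor of width ``variability`` and (for ``variability > 0``)
    re-draws the focal channel subset; noise seeds always differ between
    patients.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    if variability < 0:
        raise ValueError("variability must be nonnegative")
    ss = np.random.SeedSequence(seed)
    recs = []
    for i, child in enumerate(ss.spawn(n_patients)):
        state = np.random.default_rng(child)
        freq = float(
            np.clip(
                base.ictal_freq_hz * (1 + variability * state.uniform(-1, 1)),
                3.0,
                12.0,
            )
        )
        gain = max(1.0, base.ictal_gain * (1 + variability * state.uniform(-1, 1)))
        if variability > 0:
            k = len(base.focal_channels)
            focal = tuple(
                sorted(state.choice(base.n_channels, size=k, replace=False).tolist())
            )
        else:
            focal = base.focal_channels
        spec = replace(
            base,
            ictal_freq_hz=freq,
            ictal_gain=gain,
            focal_channels=focal,
            patient_id=f"P{i:02d}",
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        recs.append(generate_recording(spec))
    return recs
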