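"""Signal conditioning ahead of feature extraction.

The classification path conditions a single channel as: decimate to
200 Hz → segment into 30-s epochs → drop epochs whose absolute amplitude
exceeds ±400 µV → zero-phase 4th-order Butterworth band-pass (0.5–30 Hz)
per surviving epoch.  Amplitude rejection is applied before the band-pass
by default (``reject_stage="pre_filter"``); the alternative order is
config-gated since filtering first can shrink artifact amplitudes below
the threshold.

Zero-phase (forward–backward) filtering is used throughout so oscillatory
landmarks such as spindles are not shifted in time; the corner frequencies
quoted in :class:`PreprocessConfig` refer to the −3 dB points of the
underlying single-pass design (the forward–backward cascade doubles the
attenuation to −6 dB at those corners).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import Epoch
from .errors import DegenerateDataError, InputError


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters for scoring-display and classification paths.

    ``scoring_band`` is the display band used when emulating manual
    scoring preparation (per-subject low cutoff of 1 or 2 Hz is set via
    this pair); ``classify_band`` is applied before feature extraction.
    """

    scoring_band: tuple[float, float] = (1.0, 20.0)
    classify_band: tuple[float, float] = (0.5, 30.0)
    filter_order: int = 4
    fs_target: float = 200.0
    epoch_duration: float = 30.0
    reject_threshold: float = 400.0
    reject_stage: str = "pre_filter"  # or "post_filter"

    def __post_init__(self) -> None:
        for name, (low, high) in (
            ("scoring_band", self.scoring_band),
            ("classify_band", self.classify_band),
        ):
            if not (0 < low < high < self.fs_target / 2):
                raise InputError(
                    f"{name} ({low}, {high}) must satisfy "
                    f"0 < low < high < fs_target/2 = {self.fs_target / 2}"
                )
        if self.filter_order < 1:
            raise InputError("filter_order must be >= 1")
        if self.reject_threshold <= 0:
            raise InputError("reject_threshold must be > 0")
        if self.reject_stage not in ("pre_filter", "post_filter"):
            raise InputError(
                f"reject_stage must be 'pre_filter' or 'post_filter', "
                f"got {self.reject_stage!r}"
            )


@dataclass
class EpochSet:
    """Surviving epochs plus the boolean keep-mask over original indices.

    ``epochs[k]`` corresponds to the k-th true entry of ``kept_mask``;
    rejection never reorders survivors.
    """

    epochs: list[Epoch]
    kept_mask: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if len(self.epochs) != int(self.kept_mask.sum()):
            raise InputError(
                f"{len(self.epochs)} epochs but kept_mask keeps "
                f"{int(self.kept_mask.sum())}"
            )

    @property
    def n_total(self) -> int:
        return self.kept_mask.size

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kept_mask)


def bandpass_filter(
    signal: np.ndarray,
    fs: float,
    low: float,
    high: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the stated order.

    The (low, high) corners are the −3 dB points of the one-pass design;
    forward–backward application squares the magnitude response.
    """
    if not (0 < low < high):
        raise InputError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise InputError(
            f"upper corner {high} Hz not below Nyquist {fs / 2} Hz"
        )
    x = np.asarray(signal, dtype=np.float64)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def downsample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias filter and decimate by the integer factor fs_in/fs_out.

    Decimation uses scipy's zero-phase Chebyshev-I design, whose stopband
    attenuation at the output Nyquist exceeds 40 dB.  Non-integer factors
    raise (resampling is out of scope).
    """
    if fs_out > fs_in:
        raise InputError(f"fs_out {fs_out} exceeds fs_in {fs_in}")
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise InputError(
            f"fs_in/fs_out = {factor:.6g} is not an integer decimation factor"
        )
    factor = int(round(factor))
    x = np.asarray(signal, dtype=np.float64)
    if factor == 1:
        return x.copy()
    return sps.decimate(x, factor, ftype="iir", zero_phase=True, axis=-1)


def segment_epochs(
    signal: np.ndarray, fs: float, epoch_duration: float = 30.0
) -> EpochSet:
    """Cut a 1-D signal into consecutive non-overlapping epochs.

    A trailing partial window is discarded; a signal shorter than one
    epoch raises.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    spe = int(round(fs * epoch_duration))
    if spe <= 0:
        raise InputError("epoch_duration * fs must be a positive sample count")
    n_epochs = x.size // spe
    if n_epochs == 0:
        raise InputError(
            f"signal of {x.size} samples shorter than one {epoch_duration}-s "
            f"epoch ({spe} samples) at {fs} Hz"
        )
    epochs = [
        Epoch(x[i * spe : (i + 1) * spe], fs=fs, index=i) for i in range(n_epochs)
    ]
    return EpochSet(epochs, np.ones(n_epochs, dtype=bool), fs=fs)


def reject_epochs(epochset: EpochSet, threshold: float = 400.0) -> EpochSet:
    """Drop epochs whose absolute amplitude exceeds ±threshold µV.

    The inequality is strict — an epoch peaking at exactly the threshold
    is kept.  The keep-mask is combined with the incoming one so indices
    keep referring to the original segmentation.
    """
    if threshold <= 0:
        raise InputError(f"threshold must be > 0, got {threshold}")
    kept = [
        ep for ep in epochset.epochs if np.max(np.abs(ep.samples)) <= threshold
    ]
    mask = epochset.kept_mask.copy()
    for ep, orig in zip(epochset.epochs, epochset.kept_indices):
        if np.max(np.abs(ep.samples)) > threshold:
            mask[orig] = False
    return EpochSet(kept, mask, fs=epochset.fs)


def filter_epochs(
    epochset: EpochSet,
    low: float,
    high: float,
    order: int = 4,
) -> EpochSet:
    """Apply the zero-phase band-pass to every epoch independently."""
    filtered = [
        Epoch(
            bandpass_filter(ep.samples, epochset.fs, low, high, order),
            fs=epochset.fs,
            label=ep.label,
            index=ep.index,
        )
        for ep in epochset.epochs
    ]
    return EpochSet(filtered, epochset.kept_mask.copy(), fs=epochset.fs)


def normalize_amplitude_range(
    ear: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Affinely rescale ``ear`` so its robust range matches ``reference``.

    The robust range is the 2nd–98th percentile span (a min–max span would
    be dominated by single artifact samples).  The output is ``a*ear + b``
    with the median mapped onto the reference median, so the waveform
    shape is preserved exactly.
    """
    ear = np.asarray(ear, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    lo_e, mid_e, hi_e = np.percentile(ear, [2, 50, 98])
    lo_r, mid_r, hi_r = np.percentile(reference, [2, 50, 98])
    span_e = hi_e - lo_e
    if span_e <= 0:
        raise DegenerateDataError(
            "ear signal has zero robust amplitude range; cannot normalise"
        )
    scale = (hi_r - lo_r) / span_e
    return (ear - mid_e) * scale + mid_r


def preprocess_for_classification(
    signal: np.ndarray,
    fs: float,
    config: PreprocessConfig = PreprocessConfig(),
) -> EpochSet:
    """Full conditioning chain for one channel.

    decimate → segment → amplitude-reject → band-pass (default order), or
    with rejection after the band-pass when
    ``config.reject_stage == "post_filter"``.
    """
    x = downsample(signal, fs, config.fs_target)
    epochs = segment_epochs(x, config.fs_target, config.epoch_duration)
    low, high = config.classify_band
    if config.reject_stage == "pre_filter":
        epochs = reject_epochs(epochs, config.reject_threshold)
        epochs = filter_epochs(epochs, low, high, config.filter_order)
    else:
        epochs = filter_epochs(epochs, low, high, config.filter_order)
        epochs = reject_epochs(epochs, config.reject_threshold)
    return epochs
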