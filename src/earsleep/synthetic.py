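"""Stage-labelled synthetic EEG generator.

Real overnight or nap recordings scored by a clinician are rarely shareable,
so every downstream component of this package is exercised against synthetic
single-channel EEG whose spectral structure follows the classical AASM
stage signatures: a clear alpha rhythm (8–13 Hz) over broadband
beta/EMG-like activity in wake, attenuated alpha with low-voltage mixed
2–7 Hz activity in N1, sleep spindles (12–14 Hz bursts) over a
theta/delta background in N2, and high-voltage (> 75 µV peak) sub-2-Hz
slow waves in N3.

The signal model is deliberately phenomenological: each stage is a sum of
band-limited Gaussian oscillations (white noise shaped by a 4th-order
Butterworth band-pass, scaled to a target RMS), a 1/f^β background, and —
for N2 — Hann-windowed spindle bursts.  The default per-stage amplitudes
are tuned fixtures chosen so the stage-discriminating band-power orderings
hold for every seed; they are not estimates of any real dataset.

Determinism: an epoch is a pure function of ``(stage, config, seed)``, and
a recording derives one sub-seed per epoch from the master seed, so any
epoch of a recording can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .containers import STAGES, Epoch, Hypnogram, Recording
from .errors import InputError

#: Frequency extent (Hz) of each named oscillatory component.
GENERATOR_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 2.0),
    "theta": (2.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (16.0, 30.0),
}


@dataclass(frozen=True)
class SpindleParams:
    """Sleep-spindle burst model: amplitude-modulated sinusoid bursts.

    ``rate`` is the expected number of bursts per epoch (Poisson count),
    ``duration`` the burst length in seconds (Hann envelope), ``centre_freq``
    the carrier frequency in Hz and ``amplitude`` the envelope peak in µV.
    """

    rate: float = 4.0
    duration: float = 1.0
    centre_freq: float = 13.0
    amplitude: float = 30.0

    def __post_init__(self) -> None:
        if self.rate < 0 or self.duration <= 0 or self.amplitude < 0:
            raise InputError("spindle rate/duration/amplitude must be non-negative")


@dataclass(frozen=True)
class StageParams:
    """Spectral recipe for one sleep stage.

    ``band_amplitudes`` maps component names from :data:`GENERATOR_BANDS`
    to RMS amplitudes in µV; ``noise_exponent`` is the β of the 1/f^β
    background and ``noise_amplitude`` its RMS in µV.  ``spindles`` is only
    set for N2-type recipes in the shipped defaults.
    """

    stage: str
    band_amplitudes: Mapping[str, float]
    noise_exponent: float = 1.0
    noise_amplitude: float = 10.0
    spindles: SpindleParams | None = None

    def __post_init__(self) -> None:
        for name, amp in self.band_amplitudes.items():
            if name not in GENERATOR_BANDS:
                raise InputError(f"unknown band {name!r}")
            if amp < 0:
                raise InputError(f"band amplitude for {name!r} must be >= 0")
        if self.noise_amplitude <= 0:
            raise InputError("noise_amplitude must be > 0")


def _default_stage_params() -> dict[str, StageParams]:
    return {
        "W": StageParams(
            "W",
            {"delta": 3.0, "theta": 4.0, "alpha": 16.0, "beta": 24.0},
            noise_exponent=0.0,
            noise_amplitude=34.0,
        ),
        "N1": StageParams(
            "N1",
            {"delta": 8.0, "theta": 18.0, "alpha": 8.0, "beta": 3.0},
            noise_exponent=1.0,
            noise_amplitude=12.0,
        ),
        "N2": StageParams(
            "N2",
            {"delta": 18.0, "theta": 12.0, "alpha": 4.0, "beta": 2.0},
            noise_exponent=1.0,
            noise_amplitude=10.0,
            spindles=SpindleParams(),
        ),
        "N3": StageParams(
            "N3",
            {"delta": 45.0, "theta": 8.0, "alpha": 3.0, "beta": 1.5},
            noise_exponent=1.2,
            noise_amplitude=10.0,
        ),
    }


#: Shipped per-stage recipes (synthetic fixtures, not fitted values).
DEFAULT_STAGE_PARAMS: dict[str, StageParams] = _default_stage_params()


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling geometry and per-stage recipes for the generator."""

    fs: float = 1200.0
    epoch_duration: float = 30.0
    stage_params: Mapping[str, StageParams] = field(
        default_factory=_default_stage_params
    )

    def __post_init__(self) -> None:
        n = self.fs * self.epoch_duration
        if self.fs <= 0 or self.epoch_duration <= 0:
            raise InputError("fs and epoch_duration must be positive")
        if abs(n - round(n)) > 1e-9:
            raise InputError(
                f"fs * epoch_duration must be an integer sample count, got {n}"
            )

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.fs * self.epoch_duration))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float, amp: float
) -> np.ndarray:
    """Gaussian noise band-passed to (low, high) Hz and scaled to RMS amp.

    The filter is run on a padded draw and only the settled central
    section is kept: the band-pass edge transient (several periods of the
    low corner) would otherwise leave spurious high-amplitude excursions
    at the epoch boundaries.
    """
    pad = int(round(fs * max(2.0, 4.0 / low)))
    white = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)[pad : pad + n]
    r = _rms(shaped)
    return shaped * (amp / r) if r > 0 else shaped


def _background_noise(
    rng: np.random.Generator, n: int, fs: float, beta: float, amp: float
) -> np.ndarray:
    """1/f^β background, spectrally shaped white noise scaled to RMS amp.

    The shaping is flattened below 0.5 Hz to keep the variance finite.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.maximum(freqs, 0.5) ** (-beta / 2.0)
    shape[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shape, n)
    r = _rms(shaped)
    return shaped * (amp / r) if r > 0 else shaped


def _add_spindles(
    rng: np.random.Generator, x: np.ndarray, fs: float, p: SpindleParams
) -> None:
    n_burst = int(rng.poisson(p.rate))
    dur = int(round(p.duration * fs))
    if dur >= x.size:
        raise InputError("spindle duration exceeds epoch length")
    t = np.arange(dur) / fs
    for _ in range(n_burst):
        start = int(rng.integers(0, x.size - dur))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        burst = (
            p.amplitude
            * np.hanning(dur)
            * np.sin(2.0 * np.pi * p.centre_freq * t + phase)
        )
        x[start : start + dur] += burst


def generate_epoch(
    stage: str, config: GeneratorConfig | None = None, seed: int = 0
) -> Epoch:
    """Generate one 30-s (by default) epoch of stage-typical EEG.

    Identical ``(stage, config, seed)`` triples give bit-identical output.

    Parameters
    ----------
    stage : str
        One of ``W``, ``N1``, ``N2``, ``N3``.
    config : GeneratorConfig, optional
        Sampling geometry and stage recipes; defaults are the shipped
        fixtures.
    seed : int
        Seed for this epoch's random draws.

    Returns
    -------
    Epoch
        µV sample vector of ``fs × epoch_duration`` samples, labelled with
        ``stage``.
    """
    config = config or GeneratorConfig()
    if stage not in config.stage_params:
        raise InputError(
            f"unknown stage label {stage!r}; expected one of "
            f"{sorted(config.stage_params)}"
        )
    params = config.stage_params[stage]
    rng = np.random.default_rng(seed)
    n = config.samples_per_epoch
    x = _background_noise(
        rng, n, config.fs, params.noise_exponent, params.noise_amplitude
    )
    for name, amp in params.band_amplitudes.items():
        if amp > 0:
            low, high = GENERATOR_BANDS[name]
            x += _band_noise(rng, n, config.fs, low, high, amp)
    if params.spindles is not None:
        _add_spindles(rng, x, config.fs, params.spindles)
    return Epoch(x, fs=config.fs, label=stage)


def epoch_seeds(master_seed: int, n_epochs: int) -> np.ndarray:
    """Per-epoch sub-seeds derived deterministically from a master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n_epochs)


def generate_recording(
    stage_sequence: Sequence[str],
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> tuple[Recording, Hypnogram]:
    """Generate a continuous single-channel recording plus aligned hypnogram.

    Epoch ``i`` of the result is exactly ``generate_epoch(stage_sequence[i],
    config, epoch_seeds(seed, n)[i])``, so recordings are reproducible
    epoch-wise.
    """
    config = config or GeneratorConfig()
    stages = list(stage_sequence)
    if not stages:
        raise InputError("stage sequence must be non-empty")
    seeds = epoch_seeds(seed, len(stages))
    chunks = [
        generate_epoch(st, config, int(s)).samples for st, s in zip(stages, seeds)
    ]
    rec = Recording(
        np.concatenate(chunks)[np.newaxis, :], fs=config.fs, channel_labels=["EL1"]
    )
    hyp = Hypnogram(stages, epoch_duration=config.epoch_duration)
    return rec, hyp


def inject_artifacts(
    recording: Recording,
    n_epochs: int,
    amplitude: float = 500.0,
    seed: int = 0,
    epoch_duration: float = 30.0,
    artifact_duration: float = 0.5,
) -> tuple[Recording, np.ndarray]:
    """Plant high-amplitude artifacts into randomly chosen epochs.

    A flat plateau of ``amplitude`` µV lasting ``artifact_duration`` s is
    added to the centre of each chosen epoch (its low-frequency content
    survives anti-alias decimation, so downstream amplitude rejection sees
    it at full height).  All other epochs are untouched.

    Returns
    -------
    (Recording, ndarray)
        A new recording and the sorted indices of the affected epochs.
    """
    if amplitude <= 0:
        raise InputError(f"artifact amplitude must be > 0, got {amplitude}")
    spe = int(round(recording.fs * epoch_duration))
    total_epochs = recording.n_samples // spe
    if n_epochs < 0 or n_epochs > total_epochs:
        raise InputError(
            f"n_epochs={n_epochs} outside [0, {total_epochs}] available epochs"
        )
    samples = recording.samples.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total_epochs, size=n_epochs, replace=False))
    dur = int(round(artifact_duration * recording.fs))
    for i in idx:
        start = i * spe + (spe - dur) // 2
        samples[:, start : start + dur] = amplitude
    out = Recording(samples, fs=recording.fs, channel_labels=list(recording.channel_labels))
    return out, idx


#: Class mix of the reference 293-epoch pool (W:67, N1:46, N2:140, N3:40),
#: used to draw stage sequences with a realistic imbalance.
REFERENCE_STAGE_MIX: dict[str, int] = {"W": 67, "N1": 46, "N2": 140, "N3": 40}

#: A deterministic 90-epoch nap-like sequence with stage transitions.
NAP90: tuple[str, ...] = tuple(
    ["W"] * 8 + ["N1"] * 6 + ["N2"] * 14 + ["N3"] * 10 + ["N2"] * 10
    + ["N1"] * 4 + ["W"] * 4 + ["N1"] * 4 + ["N2"] * 16 + ["N3"] * 6
    + ["N2"] * 6 + ["W"] * 2
)


def stage_mix_sequence(
    n_epochs: int,
    mix: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> list[str]:
    """Stage sequence of length ``n_epochs`` matching a class mix.

    Counts are apportioned by largest remainder from ``mix`` (default
    :data:`REFERENCE_STAGE_MIX`).  With a seed the sequence order is
    shuffled; otherwise stages appear in blocks.
    """
    if n_epochs <= 0:
        raise InputError("n_epochs must be positive")
    mix = dict(mix or REFERENCE_STAGE_MIX)
    total = sum(mix.values())
    quotas = {s: n_epochs * c / total for s, c in mix.items()}
    counts = {s: int(np.floor(q)) for s, q in quotas.items()}
    short = n_epochs - sum(counts.values())
    for s in sorted(mix, key=lambda s: quotas[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    seq = [s for s in STAGES if s in counts for _ in range(counts[s])]
    if seed is not None:
        np.random.default_rng(seed).shuffle(seq)
    return seq
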