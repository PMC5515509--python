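"""Readers and writers for the formats the pipeline touches.

* EDF (European Data Format) for signals — read via :mod:`mne`, written by
  a minimal built-in EDF writer (16-bit, one data record per second).
* A plain-text hypnogram dialect: an optional ``epoch_duration_s=30``
  header line followed by one stage label per line.
* Tab-separated feature tables with the canonical 30-column header
  (15 SEF + 15 MSFE features).

All readers reject malformed input rather than coercing it; all writers
round-trip (EDF to within 16-bit quantisation, text formats exactly).
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .complexity import MSFE_FEATURE_NAMES
from .containers import ALL_LABELS, Hypnogram, Recording
from .errors import InputError
from .spectral import SEF_FEATURE_NAMES

#: Canonical feature-table columns: 15 SEF features then 15 MSFE features.
FEATURE_NAMES: tuple[str, ...] = SEF_FEATURE_NAMES + MSFE_FEATURE_NAMES

_EDF_HEADER_LEN = 256
_HYPNOGRAM_HEADER_RE = re.compile(r"^epoch_duration_s\s*=\s*(\S+)$")


def _edf_field(value: str, width: int) -> bytes:
    """An ASCII EDF header field, left-justified and space-padded."""
    s = str(value)
    if len(s) > width:
        raise InputError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as EDF (16-bit, physical dimension uV).

    The sampling rate must be a positive integer and the recording length a
    whole number of seconds (one data record per second).  Quantisation
    maps the per-channel absolute maximum onto the 16-bit digital range, so
    round-trip error is below ``max|x| / 32767`` per channel.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise InputError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_ch, n_samp = recording.samples.shape
    if n_samp % fs != 0:
        raise InputError(
            f"recording length {n_samp} is not a whole number of seconds "
            f"at {fs} Hz"
        )
    n_records = n_samp // fs

    phys_max = np.maximum(np.abs(recording.samples).max(axis=1), 1.0)
    phys_max = np.ceil(phys_max)
    digital = np.empty((n_ch, n_samp), dtype="<i2")
    for c in range(n_ch):
        scaled = np.round(recording.samples[c] / phys_max[c] * 32767.0)
        digital[c] = np.clip(scaled, -32768, 32767).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.01", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(_EDF_HEADER_LEN * (1 + n_ch)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in recording.channel_labels),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
            b"".join(_edf_field(f"{-pm:.0f}", 8) for pm in phys_max),
            b"".join(_edf_field(f"{pm:.0f}", 8) for pm in phys_max),
            b"".join(_edf_field("-32768", 8) for _ in range(n_ch)),
            b"".join(_edf_field("32767", 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field(str(fs), 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        # data records: per second, channel-major int16 blocks
        for rec in range(n_records):
            sl = slice(rec * fs, (rec + 1) * fs)
            for c in range(n_ch):
                fh.write(digital[c, sl].tobytes())


def _validate_edf_size(path: Path) -> None:
    """Reject truncated or inconsistent EDF files before parsing."""
    size = path.stat().st_size
    if size < _EDF_HEADER_LEN:
        raise InputError(f"{path}: too small to hold an EDF header")
    with open(path, "rb") as fh:
        head = fh.read(_EDF_HEADER_LEN)
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            n_ch = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise InputError(f"{path}: malformed EDF header ({exc})") from None
        if n_ch <= 0:
            raise InputError(f"{path}: EDF header reports {n_ch} signals")
        sig_head = fh.read(_EDF_HEADER_LEN * n_ch)
    if len(sig_head) < 216 * n_ch + 8 * n_ch:
        raise InputError(f"{path}: truncated EDF signal header")
    off = 216 * n_ch
    try:
        samples_per_record = [
            int(sig_head[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
            for i in range(n_ch)
        ]
    except (UnicodeDecodeError, ValueError) as exc:
        raise InputError(f"{path}: malformed EDF signal header ({exc})") from None
    if n_records >= 0:
        expected = _EDF_HEADER_LEN * (1 + n_ch) + n_records * 2 * sum(
            samples_per_record
        )
        if size != expected:
            raise InputError(
                f"{path}: EDF size {size} B does not match header "
                f"({expected} B expected); truncated or corrupt file"
            )


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a µV :class:`Recording`.

    The file size is validated against the header before parsing, so a
    truncated file raises rather than yielding a silent partial read.
    Channels whose physical dimension is mV are converted to µV with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    _validate_edf_size(path)
    import mne  # deferred: mne import is slow and only needed here

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for bad files
        raise InputError(f"{path}: failed to parse EDF ({exc})") from exc
    data = raw.get_data() * 1e6  # mne returns SI volts
    with open(path, "rb") as fh:
        head = fh.read(_EDF_HEADER_LEN)
        n_ch = int(head[252:256].decode("ascii").strip())
        sig_head = fh.read(_EDF_HEADER_LEN * n_ch)
    dims = [
        sig_head[96 * n_ch + 8 * i : 96 * n_ch + 8 * (i + 1)]
        .decode("ascii", "replace")
        .strip()
        for i in range(n_ch)
    ]
    for i, dim in enumerate(dims[: data.shape[0]]):
        if dim.lower() == "mv":
            warnings.warn(
                f"channel {raw.ch_names[i]!r} recorded in mV; converting to µV",
                stacklevel=2,
            )
    return Recording(data, fs=float(raw.info["sfreq"]), channel_labels=list(raw.ch_names))


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    """Write the line-per-epoch text dialect with its duration header."""
    dur = hypnogram.epoch_duration
    dur_str = f"{int(dur)}" if float(dur).is_integer() else f"{dur}"
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"epoch_duration_s={dur_str}\n")
        for lab in hypnogram.labels:
            fh.write(f"{lab}\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Parse a plain-text hypnogram (one label per line, case-insensitive).

    An ``epoch_duration_s=`` header line is honoured if present (default
    30 s).  Unknown tokens raise an :class:`InputError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    labels: list[str] = []
    epoch_duration = 30.0
    with open(path, encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            m = _HYPNOGRAM_HEADER_RE.match(token)
            if m:
                if lineno != 1:
                    raise InputError(
                        f"{path}:{lineno}: duration header allowed only on line 1"
                    )
                try:
                    epoch_duration = float(m.group(1))
                except ValueError:
                    raise InputError(
                        f"{path}:{lineno}: bad epoch duration {m.group(1)!r}"
                    ) from None
                continue
            upper = token.upper()
            if upper not in ALL_LABELS:
                raise InputError(
                    f"{path}:{lineno}: unknown stage label {token!r}; "
                    f"expected one of {ALL_LABELS}"
                )
            labels.append(upper)
    if not labels:
        raise InputError(f"{path}: no epochs found")
    return Hypnogram(labels, epoch_duration=epoch_duration)


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as TSV with the canonical column header.

    ``table`` must contain every canonical feature column (extras such as
    ``stage`` are preserved).  Numbers are written with shortest-round-trip
    precision, so :func:`read_features` recovers them exactly.
    """
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise InputError(
            f"feature table missing {len(missing)} canonical columns, "
            f"first: {missing[0]!r}"
        )
    table.to_csv(path, sep="\t", index=True, index_label="epoch_index")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a TSV feature table written by :func:`write_features`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    try:
        table = pd.read_csv(
            path, sep="\t", index_col="epoch_index", float_precision="round_trip"
        )
    except Exception as exc:
        raise InputError(f"{path}: failed to parse feature table ({exc})") from exc
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise InputError(
            f"{path}: missing {len(missing)} canonical feature columns, "
            f"first: {missing[0]!r}"
        )
    return table
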