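"""Signal and feature-table I/O.

Multichannel EEG comes in as European Data Format (EDF, the container
clinical corpora distribute) or as delimited text; a labels manifest maps
``(file, channel_id)`` to the seizure-type label and, optionally, the
onset second within the record. Feature tables round-trip through CSV at
full decimal precision.

The EDF codec here is deliberately minimal: classic EDF, 16-bit samples,
one data record per file, header sampling rate respected. It exists
because the pipeline needs a self-contained writer for fixtures and a
symmetric reader; it is not an EDF+ implementation (no annotations, no
discontinuous records).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    InvalidArgumentError,
    MissingChannelError,
    ShortSegmentError,
)
from .segment import SEIZURE_LABELS, SignalSegment

__all__ = [
    "LabelManifest",
    "read_signals",
    "write_edf",
    "read_edf",
    "write_feature_table",
    "read_feature_table",
]

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class LabelManifest:
    """Mapping ``(file, channel_id) -> (label, onset_s)``.

    CSV layout: ``file,channel_id,label[,onset_s]``; onset defaults to 0.
    """

    entries: dict = field(default_factory=dict)

    def add(self, file: str, channel_id: str, label: str, onset_s: float = 0.0):
        key = (str(file), str(channel_id))
        if key in self.entries:
            raise InvalidArgumentError(f"duplicate manifest key {key}")
        if label not in SEIZURE_LABELS:
            raise InvalidArgumentError(f"unknown label {label!r}")
        self.entries[key] = (label, float(onset_s))

    def channels_for(self, file: str) -> dict:
        name = Path(file).name
        return {
            ch: val
            for (f, ch), val in self.entries.items()
            if f == str(file) or Path(f).name == name
        }

    @classmethod
    def from_csv(cls, path) -> "LabelManifest":
        frame = pd.read_csv(path, dtype={"file": str, "channel_id": str})
        required = {"file", "channel_id", "label"}
        if not required.issubset(frame.columns):
            raise FormatError(
                f"manifest needs columns {sorted(required)}, got {list(frame.columns)}"
            )
        manifest = cls()
        for _, row in frame.iterrows():
            onset = float(row["onset_s"]) if "onset_s" in frame.columns else 0.0
            manifest.add(row["file"], row["channel_id"], row["label"], onset)
        return manifest

    def to_csv(self, path) -> None:
        rows = [
            {"file": f, "channel_id": ch, "label": lab, "onset_s": onset}
            for (f, ch), (lab, onset) in self.entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def _pad(text: str, width: int) -> bytes:
    encoded = text.encode("ascii")[:width]
    return encoded + b" " * (width - len(encoded))


def write_edf(path, segments: list[SignalSegment]) -> None:
    """Write channels to a classic 16-bit EDF file (one data record).

    All channels must share one sampling rate and length. Physical
    min/max per channel are taken from the data, so the quantization step
    is (max - min) / 2**16.
    """
    if not segments:
        raise InvalidArgumentError("no segments to write")
    rate = segments[0].sampling_rate_hz
    length = len(segments[0])
    for seg in segments:
        if seg.sampling_rate_hz != rate or len(seg) != length:
            raise InvalidArgumentError("channels differ in rate or length")
    n_signals = len(segments)
    duration = length / rate
    header_bytes = 256 * (1 + n_signals)

    buf = _io.BytesIO()
    buf.write(_pad("0", 8))
    buf.write(_pad("synthetic", 80))
    buf.write(_pad("seiztype", 80))
    buf.write(_pad("01.01.00", 8))
    buf.write(_pad("00.00.00", 8))
    buf.write(_pad(str(header_bytes), 8))
    buf.write(_pad("", 44))
    buf.write(_pad("1", 8))  # one data record
    buf.write(_pad(f"{duration:g}", 8))
    buf.write(_pad(str(n_signals), 4))

    phys_ranges = []
    for seg in segments:
        lo, hi = float(seg.samples.min()), float(seg.samples.max())
        if hi <= lo:
            hi = lo + 1.0  # constant channel: give a nonzero span
        phys_ranges.append((lo, hi))

    for field_maker in (
        lambda s: _pad(s.channel_id or "chan", 16),
        lambda s: _pad("synthetic", 80),
        lambda s: _pad("uV", 8),
    ):
        for seg in segments:
            buf.write(field_maker(seg))
    for lo, hi in phys_ranges:
        buf.write(_pad(f"{lo:.8g}"[:8], 8))
    for lo, hi in phys_ranges:
        buf.write(_pad(f"{hi:.8g}"[:8], 8))
    for _ in segments:
        buf.write(_pad(str(_DIG_MIN), 8))
    for _ in segments:
        buf.write(_pad(str(_DIG_MAX), 8))
    for _ in segments:
        buf.write(_pad("", 80))
    for _ in segments:
        buf.write(_pad(str(length), 8))
    for _ in segments:
        buf.write(_pad("", 32))

    for seg, (lo, hi) in zip(segments, phys_ranges):
        # physical value read back from 8-char header fields, so quantize
        # against the same rounded bounds the reader will see
        lo_r = float(f"{lo:.8g}"[:8])
        hi_r = float(f"{hi:.8g}"[:8])
        gain = (hi_r - lo_r) / (_DIG_MAX - _DIG_MIN)
        digital = np.round((seg.samples - lo_r) / gain + _DIG_MIN)
        digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
        buf.write(digital.tobytes())

    Path(path).write_bytes(buf.getvalue())


def read_edf(path) -> list[SignalSegment]:
    """Read a classic EDF file written by :func:`write_edf` (or compatible)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError("truncated EDF header")

    def text(offset, width):
        return raw[offset : offset + width].decode("ascii", "replace").strip()

    try:
        n_records = int(text(236, 8))
        duration = float(text(244, 8))
        n_signals = int(text(252, 4))
    except ValueError as exc:
        raise FormatError(f"malformed EDF header: {exc}") from exc
    base = 256

    def signal_field(width, start, cast=str):
        out = []
        for i in range(n_signals):
            out.append(cast(text(start + i * width, width)))
        return out, start + n_signals * width

    pos = base
    labels, pos = signal_field(16, pos)
    _, pos = signal_field(80, pos)  # transducer
    _, pos = signal_field(8, pos)  # physical dimension
    phys_min, pos = signal_field(8, pos, float)
    phys_max, pos = signal_field(8, pos, float)
    dig_min, pos = signal_field(8, pos, int)
    dig_max, pos = signal_field(8, pos, int)
    _, pos = signal_field(80, pos)  # prefilter
    samples_per_record, pos = signal_field(8, pos, int)
    _, pos = signal_field(32, pos)

    segments = []
    offset = 256 * (1 + n_signals)
    record_stride = sum(samples_per_record) * 2
    per_channel = [[] for _ in range(n_signals)]
    for _ in range(n_records):
        for i in range(n_signals):
            count = samples_per_record[i]
            chunk = raw[offset : offset + 2 * count]
            if len(chunk) < 2 * count:
                raise FormatError("EDF data shorter than header promises")
            per_channel[i].append(np.frombuffer(chunk, dtype="<i2"))
            offset += 2 * count
    for i in range(n_signals):
        digital = np.concatenate(per_channel[i]).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        physical = (digital - dig_min[i]) * gain + phys_min[i]
        rate = samples_per_record[i] / duration * 1.0 if duration > 0 else 0.0
        segments.append(
            SignalSegment(
                samples=physical,
                sampling_rate_hz=rate,
                channel_id=labels[i],
            )
        )
    return segments


def read_signals(
    path,
    manifest: LabelManifest,
    onset_window_s: float = 4.0,
    sampling_rate_hz: float | None = None,
) -> list[SignalSegment]:
    """Read the manifest's channels from an EDF or CSV file, clipped to the
    onset window.

    EDF takes its rate from the header and its onset from the manifest's
    ``onset_s``; CSV needs ``sampling_rate_hz`` and starts at the series
    head (columns are channels, header row holds channel ids).
    Raises :class:`ShortSegmentError` when fewer than
    ``onset_window_s * rate`` samples remain after the onset.
    """
    path = Path(path)
    wanted = manifest.channels_for(str(path))
    if not wanted:
        raise MissingChannelError(f"manifest names no channels in {path.name}")
    if path.suffix.lower() == ".edf":
        channels = {seg.channel_id: seg for seg in read_edf(path)}
        rates = {seg.sampling_rate_hz for seg in channels.values()}
        if len(rates) > 1:
            raise FormatError(f"channels of {path.name} disagree on rate: {rates}")
    else:
        if sampling_rate_hz is None:
            raise InvalidArgumentError("CSV input needs sampling_rate_hz")
        frame = pd.read_csv(path)
        channels = {
            str(col): SignalSegment(
                frame[col].to_numpy(dtype=float), sampling_rate_hz, str(col)
            )
            for col in frame.columns
        }
    out = []
    for channel_id, (label, onset_s) in sorted(wanted.items()):
        if channel_id not in channels:
            raise MissingChannelError(
                f"channel {channel_id!r} not found in {path.name}"
            )
        seg = channels[channel_id]
        rate = seg.sampling_rate_hz
        start = int(round(onset_s * rate))
        count = int(round(onset_window_s * rate))
        if start + count > len(seg):
            raise ShortSegmentError(
                f"{channel_id}: need {count} samples from onset {start}, "
                f"have {len(seg) - start}"
            )
        out.append(
            SignalSegment(
                samples=seg.samples[start : start + count],
                sampling_rate_hz=rate,
                channel_id=channel_id,
                label=label,
            )
        )
    return out


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Persist a feature table to CSV losslessly (17 significant digits)."""
    if table.empty:
        raise InvalidArgumentError("refusing to write an empty feature table")
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if "channel_id" not in frame.columns or "label" not in frame.columns:
        raise FormatError(
            "feature table must start with channel_id and label columns"
        )
    return frame
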