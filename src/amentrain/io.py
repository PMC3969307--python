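"""File I/O: WAV audio, event tables, Praat TextGrid annotations, tidy tables.

Time is seconds in all files; delimited text uses 12 significant digits so
reruns diff byte-identically.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .am_hierarchy import Waveform
from .errors import InvalidInputError
from .perception import EventSeries

logger = logging.getLogger(__name__)

__all__ = [
    "read_wav",
    "write_wav",
    "read_events",
    "read_event_table",
    "write_events",
    "write_table",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.12g"

_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31, np.dtype("uint8"): 2**7}


def read_wav(path) -> Waveform:
    """Read a WAV file (PCM or float) as a mono float waveform in [-1, 1].

    Stereo input is mixed down to mono with a warning.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        logger.warning("%s is stereo; mixing to mono", path.name)
        data = data.mean(axis=1)
    dtype = data.dtype
    if dtype in _PCM_SCALE:
        scale = _PCM_SCALE[dtype]
        data = data.astype(float)
        if dtype == np.dtype("uint8"):
            data -= scale
        data /= scale
    else:
        data = data.astype(float)
    return Waveform(samples=data, rate=float(rate), label=path.stem)


def write_wav(path, w: Waveform) -> None:
    """Write a waveform as 32-bit float WAV."""
    wavfile.write(path, int(round(w.rate)), w.samples.astype(np.float32))


def _dedupe_sorted(times: np.ndarray, source: str) -> np.ndarray:
    if times.size and np.any(np.diff(times) < 0):
        logger.warning("%s: times unsorted; sorting", source)
        times = np.sort(times)
    uniq = np.unique(times)
    if uniq.size < times.size:
        logger.warning("%s: %d duplicate timestamps removed", source, times.size - uniq.size)
    return uniq


def _parse_textgrid(text: str) -> list[tuple[str, float]]:
    """Extract (tier_name, time) event pairs from a Praat TextGrid.

    Handles the long ("ooTextFile") format: point tiers contribute their
    point times; interval tiers contribute the start (xmin) of every
    non-empty-labelled interval.
    """
    events: list[tuple[str, float]] = []
    tier_class = None
    tier_name = ""
    in_interval = False
    pending_xmin: float | None = None
    header_done = False
    for raw in text.splitlines():
        line = raw.strip()
        m = re.match(r'class\s*=\s*"(.+)"', line)
        if m:
            tier_class = m.group(1)
            header_done = False
            continue
        m = re.match(r'name\s*=\s*"(.*)"', line)
        if m:
            tier_name = m.group(1)
            continue
        if re.match(r"(points|intervals)\s*(\[|:)", line):
            header_done = True
            in_interval = line.startswith("intervals [")
            continue
        if not header_done:
            continue
        if tier_class == "TextTier":
            m = re.match(r"(?:number|time)\s*=\s*([-\d.eE+]+)", line)
            if m:
                events.append((tier_name, float(m.group(1))))
        elif tier_class == "IntervalTier":
            m = re.match(r"xmin\s*=\s*([-\d.eE+]+)", line)
            if m and in_interval:
                pending_xmin = float(m.group(1))
                continue
            m = re.match(r'text\s*=\s*"(.*)"', line)
            if m and pending_xmin is not None:
                if m.group(1).strip():
                    events.append((tier_name, pending_xmin))
                pending_xmin = None
    return events


def read_events(path, dialect: str = "csv", kind: str = "vowel_onset",
                time_column: str = "time_s", max_bad_fraction: float = 0.05,
                **labels) -> EventSeries:
    """Read point events from delimited text or a Praat TextGrid.

    CSV needs a ``time_s`` column (or a single unnamed column of times).
    Times are sorted and deduplicated with a warning. Malformed rows are
    collected; the read fails if they exceed ``max_bad_fraction``.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    if dialect == "praat_point_tier":
        events = _parse_textgrid(path.read_text())
        times = np.asarray([t for _, t in events], dtype=float)
    elif dialect == "csv":
        df = pd.read_csv(path)
        col = time_column if time_column in df.columns else df.columns[0]
        raw = pd.to_numeric(df[col], errors="coerce")
        bad = int(raw.isna().sum())
        if bad:
            logger.warning("%s: %d malformed rows", path.name, bad)
            if bad > max_bad_fraction * len(raw):
                raise InvalidInputError(
                    f"{path}: {bad}/{len(raw)} malformed rows exceeds "
                    f"{max_bad_fraction:.0%} tolerance"
                )
        times = raw.dropna().to_numpy(dtype=float)
    else:
        raise InvalidInputError(f"unknown dialect {dialect!r}")
    times = _dedupe_sorted(times, str(path))
    return EventSeries(times=times, kind=kind, **labels)


def read_event_table(path) -> pd.DataFrame:
    """Read a multi-participant event table (tap/onset logs) as a DataFrame."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise InvalidInputError(f"{path}: expected a 'time_s' column")
    return df


def write_events(path, series: EventSeries | list[EventSeries]) -> None:
    """Write event series as tidy delimited text."""
    series = [series] if isinstance(series, EventSeries) else series
    rows = []
    for s in series:
        for t in s.times:
            rows.append(
                {
                    "participant": s.participant,
                    "group": s.group,
                    "sentence": s.sentence,
                    "metre": s.metre,
                    "repetition": s.repetition,
                    "kind": s.kind,
                    "time_s": t,
                }
            )
    write_table(path, pd.DataFrame(rows))


def write_table(path, df: pd.DataFrame) -> None:
    """Write a tidy table with fixed numeric formatting (reproducible diffs)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
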