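"""Reading, validation and resampling of fundamental-frequency contours.

A howl enters the pipeline as a digitised f0 trace: an irregular series of
(time, frequency) points traced along the lowest band of a spectrogram.
Everything downstream assumes a uniform 0.1 s sampling grid, so this module
owns the conversion from the digitiser's dialect (sorted or unsorted delimited
text, occasional duplicate time stamps) onto that grid.

Durations are always measured from the raw trace endpoints, not from the
resampled grid, so sub-step tail time is never lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ContourParseError,
    ContourValidationError,
    DegenerateContourError,
)

logger = logging.getLogger(__name__)

#: Uniform sampling interval (seconds) assumed by the feature definitions.
GRID_STEP = 0.1


@dataclass
class F0Contour:
    """A single howl's fundamental-frequency trace.

    Parameters
    ----------
    howl_id
        Unique identifier for the howl (defaults to the file stem on read).
    times
        Strictly increasing sample times in seconds.
    freqs
        Fundamental frequency in Hz at each sample time; all positive.
    individual_label
        Identity of the caller, if known; ``None`` for unknown howls.
    session_date
        Recording-session identifier (free-form text, typically a date).
    t_start, t_end
        Raw trace endpoints.  After resampling the grid may stop short of
        ``t_end``; the raw endpoints are preserved so that the duration
        feature reflects the full trace.
    """

    howl_id: str
    times: np.ndarray
    freqs: np.ndarray
    individual_label: str | None = None
    session_date: str | None = None
    t_start: float = field(default=None)  # type: ignore[assignment]
    t_end: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.times.ndim != 1 or self.freqs.ndim != 1:
            raise ContourValidationError(
                f"{self.howl_id}: times and freqs must be 1-D"
            )
        if len(self.times) != len(self.freqs):
            raise ContourValidationError(
                f"{self.howl_id}: times ({len(self.times)}) and freqs "
                f"({len(self.freqs)}) differ in length"
            )
        if len(self.times) < 2:
            raise DegenerateContourError(
                f"{self.howl_id}: a contour needs at least 2 points, "
                f"got {len(self.times)}"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ContourValidationError(
                f"{self.howl_id}: times must be strictly increasing"
            )
        if not np.all(self.freqs > 0):
            raise ContourValidationError(
                f"{self.howl_id}: all frequencies must be positive"
            )
        if self.t_start is None:
            self.t_start = float(self.times[0])
        if self.t_end is None:
            self.t_end = float(self.times[-1])

    @property
    def duration(self) -> float:
        """Howl duration in seconds, from the raw trace endpoints."""
        return float(self.t_end - self.t_start)

    @property
    def n_points(self) -> int:
        return len(self.times)

    def is_on_grid(self, step: float = GRID_STEP, atol: float = 1e-6) -> bool:
        """True if consecutive sample times differ by exactly ``step``."""
        return bool(np.allclose(np.diff(self.times), step, atol=atol))

    def with_label(
        self, individual_label: str | None, session_date: str | None = None
    ) -> "F0Contour":
        return replace(
            self,
            individual_label=individual_label,
            session_date=session_date if session_date is not None else self.session_date,
        )


def _sniff_delimiter(line: str) -> str | None:
    """Return ',' or '\\t' if present in a data line, else None (whitespace)."""
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None


def read_contour(
    path: str | Path,
    howl_id: str | None = None,
    individual_label: str | None = None,
    session_date: str | None = None,
) -> F0Contour:
    """Read a digitised contour from a two-column delimited text file.

    The delimiter (comma or tab/whitespace) is auto-detected, an optional
    header row is skipped, rows are sorted by time and duplicate time stamps
    (a common digitiser artefact) are collapsed by averaging their
    frequencies.

    Raises
    ------
    ContourParseError
        If a row has the wrong number of fields or non-numeric values
        (the error message names the offending line).
    DegenerateContourError
        If fewer than two distinct time points remain.
    ContourValidationError
        If any frequency is non-positive.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    records: list[tuple[float, float]] = []
    t_start = t_end = None
    header_seen = False
    for lineno, line in enumerate(raw, start=1):
        stripped = line.strip()
        if stripped.startswith("#"):
            # optional raw-endpoint headers preserve the duration tail
            # beyond the last sampled point
            for key in ("t_start", "t_end"):
                if stripped.startswith(f"# {key}="):
                    try:
                        value = float(stripped.split("=", 1)[1])
                    except ValueError:
                        raise ContourParseError(
                            f"{path.name}, line {lineno}: bad {key} header"
                        ) from None
                    if key == "t_start":
                        t_start = value
                    else:
                        t_end = value
            continue
        if not stripped:
            continue
        delim = _sniff_delimiter(stripped)
        cells = [c for c in (stripped.split(delim) if delim else stripped.split()) if c != ""]
        if len(cells) != 2:
            raise ContourParseError(
                f"{path.name}, line {lineno}: expected 2 columns, got {len(cells)}"
            )
        try:
            t, f = float(cells[0]), float(cells[1])
        except ValueError:
            if not records and not header_seen:
                header_seen = True  # single header row before the data
                continue
            raise ContourParseError(
                f"{path.name}, line {lineno}: non-numeric value in {cells!r}"
            ) from None
        records.append((t, f))

    if len(records) < 2:
        raise DegenerateContourError(
            f"{path.name}: fewer than 2 data points"
        )

    records.sort(key=lambda tf: tf[0])
    times: list[float] = []
    freqs: list[float] = []
    i = 0
    while i < len(records):
        j = i
        while j < len(records) and records[j][0] == records[i][0]:
            j += 1
        times.append(records[i][0])
        freqs.append(float(np.mean([records[k][1] for k in range(i, j)])))
        i = j

    if len(times) < 2:
        raise DegenerateContourError(
            f"{path.name}: fewer than 2 distinct time points"
        )

    return F0Contour(
        howl_id=howl_id if howl_id is not None else path.stem,
        times=np.array(times),
        freqs=np.array(freqs),
        individual_label=individual_label,
        session_date=session_date,
        t_start=t_start,
        t_end=t_end,
    )


def resample_contour(contour: F0Contour, step: float = GRID_STEP) -> F0Contour:
    """Resample a contour onto a uniform grid by linear interpolation.

    The grid starts at the raw ``t_start`` and extends in multiples of
    ``step`` up to the last grid point not beyond ``t_end``; any trailing
    fraction of a step is excluded from the grid but remains part of the
    duration via the preserved raw endpoints.  Frequencies between input
    points are linearly interpolated, so resampled values never leave the
    range of the input frequencies.  The operation is idempotent.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    span = contour.t_end - contour.t_start
    n_grid = int(np.floor(span / step + 1e-9)) + 1
    if n_grid < 2:
        raise DegenerateContourError(
            f"{contour.howl_id}: contour spans {span:.4f} s, "
            f"shorter than one {step} s step"
        )
    grid = contour.t_start + step * np.arange(n_grid)
    freqs = np.interp(grid, contour.times, contour.freqs)
    return F0Contour(
        howl_id=contour.howl_id,
        times=grid,
        freqs=freqs,
        individual_label=contour.individual_label,
        session_date=contour.session_date,
        t_start=contour.t_start,
        t_end=contour.t_end,
    )


def write_contour(contour: F0Contour, path: str | Path) -> None:
    """Write a contour as comma-delimited text with a header row.

    When the raw trace endpoints extend beyond the sampled points (a
    resampled contour's sub-step duration tail), they are recorded as
    comment headers so the duration survives a round-trip.
    """
    path = Path(path)
    lines = ["time_s,frequency_hz"]
    if contour.t_start != contour.times[0] or contour.t_end != contour.times[-1]:
        lines.insert(0, f"# t_end={contour.t_end:.10g}")
        lines.insert(0, f"# t_start={contour.t_start:.10g}")
    lines += [f"{t:.10g},{f:.10g}" for t, f in zip(contour.times, contour.freqs)]
    path.write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the howl metadata table (howl_id, individual_label, session_date).

    Blank individual labels mark howls of unknown identity.
    """
    meta = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "howl_id" not in meta.columns:
        raise ContourParseError(f"{path}: metadata table lacks a 'howl_id' column")
    for col in ("individual_label", "session_date"):
        if col not in meta.columns:
            meta[col] = None
    meta = meta.where(pd.notna(meta), None)
    return meta[["howl_id"] + [c for c in meta.columns if c != "howl_id"]]


def attach_metadata(
    contours: Iterable[F0Contour], metadata: pd.DataFrame
) -> list[F0Contour]:
    """Attach individual labels and session dates to contours by howl_id."""
    lookup = {
        row["howl_id"]: (row.get("individual_label"), row.get("session_date"))
        for _, row in metadata.iterrows()
    }
    out = []
    for c in contours:
        if c.howl_id in lookup:
            label, date = lookup[c.howl_id]
            out.append(replace(c, individual_label=label, session_date=date))
        else:
            out.append(c)
    return out


def read_contour_dir(
    directory: str | Path,
    metadata: pd.DataFrame | None = None,
    patterns: Sequence[str] = ("*.csv", "*.tsv", "*.txt"),
) -> list[F0Contour]:
    """Read every contour file in a directory, sorted by file name."""
    directory = Path(directory)
    paths: list[Path] = []
    for pat in patterns:
        paths.extend(directory.glob(pat))
    paths = sorted(p for p in set(paths) if p.stem != "metadata")
    if not paths:
        raise FileNotFoundError(f"no contour files found in {directory}")
    contours = [read_contour(p) for p in paths]
    if metadata is not None:
        contours = attach_metadata(contours, metadata)
    logger.info("read %d contours from %s", len(contours), directory)
    return contours
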