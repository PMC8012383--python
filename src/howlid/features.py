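"""The thirteen scalar variables measured on a resampled f0 contour.

Each howl is summarised by thirteen numbers describing the level, spread and
shape of its fundamental-frequency trace on the 0.1 s grid:

==============  ================================================================
Min f           minimum of f0 (Hz)
Max f           maximum of f0 (Hz)
Range f         Max f - Min f (Hz)
Mean f          arithmetic mean of the 0.1 s grid samples (Hz)
Duration        t_end - t_start from the raw trace endpoints (s)
Abrupt_0.025    number of grid steps where |Δf0| exceeds 25 Hz
Abrupt_0.05     number of grid steps where |Δf0| exceeds 50 Hz
Abrupt_0.1      number of grid steps where |Δf0| exceeds 100 Hz
Stdv            standard deviation of the grid samples (Hz)
Co fm           coefficient of frequency modulation:
                Σ|f(t)-f(t+1)| / (n-1) x 100 / Mean f
Co fv           coefficient of frequency variation: (Stdv / Mean f) x 100
Pos Min         (time of Min f - t_start) / Duration, first occurrence
Pos Max         (time of Max f - t_start) / Duration, first occurrence
==============  ================================================================

Abrupt-change comparisons are strict (> threshold); positions are measured
from the raw start so every feature is invariant to time translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contours import GRID_STEP, F0Contour
from .exceptions import DegenerateContourError, HowlIdError

logger = logging.getLogger(__name__)

#: Canonical variable names, in fixed column order.
FEATURE_NAMES: tuple[str, ...] = (
    "Min f",
    "Max f",
    "Range f",
    "Mean f",
    "Duration",
    "Abrupt_0.025",
    "Abrupt_0.05",
    "Abrupt_0.1",
    "Stdv",
    "Co fm",
    "Co fv",
    "Pos Min",
    "Pos Max",
)

#: Abrupt-change thresholds in Hz, matched to the Abrupt_* columns.
ABRUPT_THRESHOLDS_HZ: tuple[float, ...] = (25.0, 50.0, 100.0)


@dataclass(frozen=True)
class HowlFeatures:
    """The thirteen feature values for one howl."""

    min_f: float
    max_f: float
    range_f: float
    mean_f: float
    duration: float
    abrupt_025: int
    abrupt_05: int
    abrupt_01: int
    stdv: float
    co_fm: float
    co_fv: float
    pos_min: float
    pos_max: float

    def as_dict(self) -> dict[str, float]:
        """Values keyed by the canonical column names."""
        return dict(zip(FEATURE_NAMES, self.as_array()))

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.min_f,
                self.max_f,
                self.range_f,
                self.mean_f,
                self.duration,
                self.abrupt_025,
                self.abrupt_05,
                self.abrupt_01,
                self.stdv,
                self.co_fm,
                self.co_fv,
                self.pos_min,
                self.pos_max,
            ],
            dtype=float,
        )


def extract_features(
    contour: F0Contour,
    step: float = GRID_STEP,
    sd_mode: str = "sample",
) -> HowlFeatures:
    """Compute the thirteen variables from a contour on the uniform grid.

    Parameters
    ----------
    contour
        Contour already resampled to the ``step`` grid.
    step
        Expected grid spacing (seconds).
    sd_mode
        ``"sample"`` (n-1 denominator, default) or ``"population"`` (n) for
        the standard-deviation variable.
    """
    if contour.n_points < 2:
        raise DegenerateContourError(
            f"{contour.howl_id}: need at least 2 grid points"
        )
    if not contour.is_on_grid(step):
        raise HowlIdError(
            f"{contour.howl_id}: contour is not on the {step} s grid; "
            "resample it first"
        )
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")

    f = contour.freqs
    t = contour.times
    duration = contour.duration

    i_min = int(np.argmin(f))  # argmin/argmax take the first occurrence
    i_max = int(np.argmax(f))
    min_f = float(f[i_min])
    max_f = float(f[i_max])
    mean_f = float(np.mean(f))
    ddof = 1 if sd_mode == "sample" else 0
    stdv = float(np.std(f, ddof=ddof))

    steps = np.abs(np.diff(f))
    counts = [int(np.sum(steps > thr)) for thr in ABRUPT_THRESHOLDS_HZ]

    co_fm = float(np.mean(steps) * 100.0 / mean_f)
    co_fv = float(stdv / mean_f * 100.0)

    return HowlFeatures(
        min_f=min_f,
        max_f=max_f,
        range_f=max_f - min_f,
        mean_f=mean_f,
        duration=duration,
        abrupt_025=counts[0],
        abrupt_05=counts[1],
        abrupt_01=counts[2],
        stdv=stdv,
        co_fm=co_fm,
        co_fv=co_fv,
        pos_min=float((t[i_min] - contour.t_start) / duration),
        pos_max=float((t[i_max] - contour.t_start) / duration),
    )


def duration_filter(
    contours: Iterable[F0Contour], min_duration: float = 5.0
) -> list[F0Contour]:
    """Keep contours strictly longer than ``min_duration`` seconds.

    Short vocalisations (squeak-like calls) mimic howls but carry little
    identity information, hence the default 5 s cut-off.  Order is preserved
    and the number discarded is logged.
    """
    contours = list(contours)
    kept = [c for c in contours if c.duration > min_duration]
    n_dropped = len(contours) - len(kept)
    if n_dropped:
        logger.warning(
            "duration filter (> %.3g s) discarded %d of %d contours",
            min_duration,
            n_dropped,
            len(contours),
        )
    if not kept:
        logger.warning("duration filter left no contours")
    return kept


def build_feature_table(
    contours: Sequence[F0Contour],
    step: float = GRID_STEP,
    sd_mode: str = "sample",
) -> pd.DataFrame:
    """Assemble the per-howl feature table.

    Returns a DataFrame indexed by ``howl_id`` with the thirteen canonical
    feature columns followed by ``individual_label`` and ``session_date``
    (``None`` where unknown).  Rows keep the input order.
    """
    ids = [c.howl_id for c in contours]
    dupes = {h for h in ids if ids.count(h) > 1}
    if dupes:
        raise HowlIdError(f"duplicate howl_id(s): {sorted(dupes)}")

    rows = []
    for c in contours:
        rec = extract_features(c, step=step, sd_mode=sd_mode).as_dict()
        rec["individual_label"] = c.individual_label
        rec["session_date"] = c.session_date
        rows.append(rec)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="howl_id"))
    return table[list(FEATURE_NAMES) + ["individual_label", "session_date"]]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Export the feature table as CSV with the canonical header names."""
    table.to_csv(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    table = pd.read_csv(path, index_col="howl_id")
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise HowlIdError(f"feature table at {path} lacks columns: {missing}")
    for col in ("individual_label", "session_date"):
        if col not in table.columns:
            table[col] = None
    table = table.where(pd.notna(table), None)
    return table
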