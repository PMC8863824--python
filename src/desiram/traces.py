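"""Per-cell rotation records and ensemble CW-bias traces.

A tethered *E. coli* cell rotates its body CW or CCW as the flagellar motor
switches direction.  Recordings are frame-indexed (10-ms frames by default);
each frame carries a signed angle increment in degrees.  Frames whose
increment magnitude exceeds a threshold (7.5 deg/frame, more than twice the
measurement noise) are labelled CW or CCW by sign; the rest are NONE.

The ensemble CW bias in a time bin is the fraction of counted rotational
motion that is CW, pooled over all cells::

    bias = (# CW frames) / (# CW frames + # CCW frames)

NONE frames enter neither numerator nor denominator.  Bins with no counted
frames are MISSING (stored as NaN), never zero-filled: during the excitation
phase all motion is CCW but some cells pause, and fabricating a bias there
would corrupt the downstream template fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import BadConfigError, InvalidDataError

# Direction codes (int8): CW and CCW are the two rotation senses, NONE marks
# a frame whose angular motion fell below the counting threshold.
CW: int = 1
CCW: int = -1
NONE: int = 0

#: Counting threshold in degrees/frame; motion beyond this is a rotation.
DEFAULT_THRESHOLD = 7.5

#: Maximum observation time in seconds (no nutrient in the motility buffer,
#: so recordings are capped).
MAX_DURATION = 600.0

_LABEL_TO_STR = {CW: "CW", CCW: "CCW", NONE: "NONE"}
_STR_TO_LABEL = {v: k for k, v in _LABEL_TO_STR.items()}


def label_to_str(code: int) -> str:
    return _LABEL_TO_STR[int(code)]


def str_to_label(s: str) -> int:
    try:
        return _STR_TO_LABEL[s.upper()]
    except KeyError:
        raise InvalidDataError(f"unknown direction label {s!r}") from None


@dataclass
class FrameAngleSeries:
    """Signed per-frame angle increments (degrees) for one cell."""

    cell_id: str
    angle_increments: np.ndarray
    frame_interval: float = 0.01
    t0: float = 0.0

    def __post_init__(self):
        self.angle_increments = np.asarray(self.angle_increments, dtype=float)
        if self.frame_interval <= 0:
            raise BadConfigError(f"frame_interval must be > 0, got {self.frame_interval}")
        if self.angle_increments.size < 1:
            raise InvalidDataError(f"cell {self.cell_id}: empty angle series")
        bad = np.flatnonzero(~np.isfinite(self.angle_increments))
        if bad.size:
            raise InvalidDataError(
                f"cell {self.cell_id}: non-finite angle increment at frame {bad[0]}"
            )

    def __len__(self) -> int:
        return self.angle_increments.size


@dataclass
class DirectionSeries:
    """Per-frame rotation labels (CW / CCW / NONE) for one cell.

    Labels are stored as an int8 array with codes ``CW=1``, ``CCW=-1``,
    ``NONE=0``; use :func:`label_to_str` for display.
    """

    cell_id: str
    labels: np.ndarray
    frame_interval: float = 0.01
    t0: float = 0.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.frame_interval <= 0:
            raise BadConfigError(f"frame_interval must be > 0, got {self.frame_interval}")
        if not np.isin(self.labels, (CW, CCW, NONE)).all():
            raise InvalidDataError(f"cell {self.cell_id}: labels outside {{CW, CCW, NONE}}")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def frame_times(self) -> np.ndarray:
        """Time of each frame relative to recording start (seconds)."""
        return self.t0 + np.arange(len(self)) * self.frame_interval


@dataclass
class CWBiasTrace:
    """Ensemble CW-bias time course in fixed-width bins.

    ``values[k]`` is the pooled CW fraction in ``[k*bin_width, (k+1)*bin_width)``
    relative to recording start; MISSING bins are NaN.
    """

    values: np.ndarray
    stimulus_time: float
    bin_width: float = 1.0
    n_cells: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_width <= 0:
            raise BadConfigError(f"bin_width must be > 0, got {self.bin_width}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise InvalidDataError("CW-bias values must lie in [0, 1]")
        if self.duration > MAX_DURATION + 1e-9:
            raise InvalidDataError(
                f"trace duration {self.duration:.1f} s exceeds the {MAX_DURATION:.0f} s cap"
            )
        if not (0 <= self.stimulus_time <= self.duration):
            raise BadConfigError(
                f"stimulus_time {self.stimulus_time} outside [0, {self.duration}]"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size * self.bin_width

    @property
    def times(self) -> np.ndarray:
        """Bin centres (seconds); the natural abscissa for fitting."""
        return (np.arange(len(self)) + 0.5) * self.bin_width

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(len(self)) * self.bin_width

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


def classify_directions(
    angles: FrameAngleSeries,
    threshold: float = DEFAULT_THRESHOLD,
    cw_sign: int = -1,
) -> DirectionSeries:
    """Label each frame CW, CCW or NONE from its angle increment.

    A frame is NONE iff ``|increment| <= threshold`` (the boundary is
    excluded from counting).  ``cw_sign`` states which increment sign is CW;
    the default (-1) calls negative increments CW.  The microscope's camera
    orientation fixes the true mapping, so this is a configuration choice.
    """
    if threshold <= 0:
        raise BadConfigError(f"threshold must be > 0, got {threshold}")
    if cw_sign not in (-1, 1):
        raise BadConfigError(f"cw_sign must be -1 or +1, got {cw_sign}")
    inc = angles.angle_increments
    labels = np.zeros(inc.size, dtype=np.int8)
    moving = np.abs(inc) > threshold
    cw = moving & (np.sign(inc) == cw_sign)
    labels[cw] = CW
    labels[moving & ~cw] = CCW
    return DirectionSeries(
        cell_id=angles.cell_id,
        labels=labels,
        frame_interval=angles.frame_interval,
        t0=angles.t0,
    )


def ensemble_cw_bias(
    cells: Sequence[DirectionSeries],
    bin_width: float = 1.0,
    stimulus_time: float = 0.0,
) -> CWBiasTrace:
    """Pool direction labels over cells into a binned CW-bias trace.

    Frames fall into half-open bins ``[k*bin_width, (k+1)*bin_width)``
    relative to recording start; the bias of a bin is the CW fraction of
    counted (CW+CCW) frames pooled over all cells, and a bin with no counted
    frame is MISSING (NaN).
    """
    if not cells:
        raise InvalidDataError("ensemble_cw_bias needs at least one cell")
    dt = cells[0].frame_interval
    for c in cells[1:]:
        if not np.isclose(c.frame_interval, dt):
            raise InvalidDataError(
                f"mismatched frame intervals: {dt} (cell {cells[0].cell_id}) vs "
                f"{c.frame_interval} (cell {c.cell_id})"
            )
    ratio = bin_width / dt
    if bin_width <= 0 or abs(ratio - round(ratio)) > 1e-9:
        raise BadConfigError(
            f"bin_width {bin_width} must be a positive multiple of frame_interval {dt}"
        )

    end_time = max(c.t0 + len(c) * c.frame_interval for c in cells)
    n_bins = int(np.ceil(end_time / bin_width - 1e-9))
    cw_counts = np.zeros(n_bins, dtype=np.int64)
    tot_counts = np.zeros(n_bins, dtype=np.int64)
    for c in cells:
        counted = c.labels != NONE
        if not counted.any():
            continue
        bins = np.floor(c.frame_times[counted] / bin_width).astype(np.int64)
        bins = np.clip(bins, 0, n_bins - 1)
        lab = c.labels[counted]
        cw_counts += np.bincount(bins[lab == CW], minlength=n_bins)
        tot_counts += np.bincount(bins, minlength=n_bins)

    with np.errstate(invalid="ignore"):
        values = np.where(tot_counts > 0, cw_counts / np.maximum(tot_counts, 1), np.nan)
    return CWBiasTrace(
        values=values,
        stimulus_time=stimulus_time,
        bin_width=bin_width,
        n_cells=len(cells),
    )
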