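"""Lethal-fraction cell-death kinetics from live-cell imaging counts.

In the STACK imaging framework live cells constitutively express a nuclear
red marker (mKate2+) and dead cells take up SYTOX Green (SG+); an object
positive for both (double positive) is a dying/dead cell still carrying
the live marker.  For a time course sampled at frames t = 0..n the lethal
fraction at frame n is

    live_n = mKate2+_n - double+_n          (clamped at 0)
    LF_n   = 1 - live_n / (live_n + max_{t<=n} SG+_t)

i.e. the dead-cell term is the *running maximum* of the SG+ count, which
makes LF robust to late-course disintegration of dead cells.  LF is 0
when everything is alive and 1 when nothing is.  Cell lines without the
live marker support an SG-only mode that reports the dead-count
trajectory and its running maximum without computing LF.

Counts are accepted as non-negative reals rather than strict integers so
that noise-free model-expected trajectories (which are real-valued) flow
through the same code path as measured object counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("palmkit")


@dataclass(frozen=True)
class DeathTimepoint:
    """Object counts at one frame.  ``double_pos`` is None in SG-only mode."""

    t: float
    mkate2_pos: float | None = None
    sg_pos: float = 0.0
    double_pos: float | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("time must be >= 0")
        for attr in ("mkate2_pos", "sg_pos", "double_pos"):
            v = getattr(self, attr)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{attr} must be a non-negative finite count")


@dataclass(frozen=True)
class DeathTimecourse:
    """Strictly time-ordered frames in dual-channel or SG-only mode."""

    timepoints: tuple[DeathTimepoint, ...]
    mode: str = "dual"

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", tuple(self.timepoints))
        if self.mode not in ("dual", "sg-only"):
            raise ValueError("mode must be 'dual' or 'sg-only'")
        times = [tp.t for tp in self.timepoints]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("timepoints must be strictly increasing in t")
        if self.mode == "dual":
            for tp in self.timepoints:
                if tp.mkate2_pos is None or tp.double_pos is None:
                    raise ValueError(
                        "dual mode requires mkate2_pos and double_pos at every frame"
                    )

    @property
    def times(self) -> np.ndarray:
        return np.array([tp.t for tp in self.timepoints])


def lethal_fraction_series(tc: DeathTimecourse) -> np.ndarray:
    """Lethal fraction at every frame of a dual-channel time course.

    Frames where the double-positive count exceeds the mKate2+ count (a
    segmentation artifact) clamp the live term at zero, with the number of
    clamped frames warned once.  Frames with no live signal and no SG
    history (empty field of view) are flagged undefined as NaN.
    """
    if tc.mode != "dual":
        raise ValueError("lethal fraction requires a dual-channel time course")
    if not tc.timepoints:
        raise ValueError("time course is empty")
    mkate2 = np.array([tp.mkate2_pos for tp in tc.timepoints], dtype=float)
    sg = np.array([tp.sg_pos for tp in tc.timepoints], dtype=float)
    double = np.array([tp.double_pos for tp in tc.timepoints], dtype=float)
    live = mkate2 - double
    n_clamped = int((live < 0).sum())
    if n_clamped:
        logger.warning(
            "%d frame(s) with double+ exceeding mKate2+; live clamped to 0",
            n_clamped,
        )
        live = np.maximum(live, 0.0)
    sgmax = np.maximum.accumulate(sg)
    denom = live + sgmax
    with np.errstate(invalid="ignore", divide="ignore"):
        lf = np.where(denom > 0, sgmax / denom, np.nan)
    return lf


def sg_only_series(tc: DeathTimecourse) -> tuple[np.ndarray, np.ndarray]:
    """SG+ trajectory and its running maximum for marker-free cell lines."""
    if tc.mode != "sg-only":
        if any(
            tp.mkate2_pos is not None or tp.double_pos is not None
            for tp in tc.timepoints
        ):
            logger.warning("dual-channel fields present in sg-only call; ignored")
    sg = np.array([tp.sg_pos for tp in tc.timepoints], dtype=float)
    return sg, np.maximum.accumulate(sg)


def endpoint_summary(lf: Sequence[float], times: Sequence[float]) -> dict:
    """Max LF, time to LF >= 0.5, and area under the LF curve.

    Time-to-half is found by linear interpolation at the first upward
    crossing of 0.5 and is None if the series never reaches 0.5.  AUC is
    trapezoidal in LF-hours over the defined (non-NaN) points; undefined
    frames are omitted pointwise.  An all-undefined series is an error.
    """
    lf = np.asarray(lf, dtype=float)
    times = np.asarray(times, dtype=float)
    if lf.shape != times.shape:
        raise ValueError("lf and times must have equal length")
    defined = ~np.isnan(lf)
    if not defined.any():
        raise ValueError("lethal-fraction series is entirely undefined")
    lfd, td = lf[defined], times[defined]
    max_lf = float(lfd.max())
    t_half = None
    for i, v in enumerate(lfd):
        if v >= 0.5:
            if i == 0:
                t_half = float(td[0])
            else:
                lo, hi = lfd[i - 1], v
                t_half = float(
                    td[i - 1] + (0.5 - lo) / (hi - lo) * (td[i] - td[i - 1])
                )
            break
    auc = float(np.trapezoid(lfd, td)) if len(lfd) >= 2 else None
    return {"max_lf": max_lf, "t_half": t_half, "auc": auc}


def read_counts_csv(path, mode: str = "dual") -> dict[str, DeathTimecourse]:
    """Read a counts CSV (well, t_hours, mkate2_pos, sg_pos, double_pos)
    into one time course per well."""
    df = pd.read_csv(path)
    required = {"well", "t_hours", "sg_pos"}
    if mode == "dual":
        required |= {"mkate2_pos", "double_pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    out = {}
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("t_hours")
        tps = [
            DeathTimepoint(
                t=row["t_hours"],
                mkate2_pos=row["mkate2_pos"] if mode == "dual" else None,
                sg_pos=row["sg_pos"],
                double_pos=row["double_pos"] if mode == "dual" else None,
            )
            for _, row in grp.iterrows()
        ]
        out[str(well)] = DeathTimecourse(
            timepoints=tuple(tps), mode="dual" if mode == "dual" else "sg-only"
        )
    return out
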