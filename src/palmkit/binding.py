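"""Co-IP band densitometry and normalized binding quantities.

Scanned immunoblots show dark bands on a light background, so the raw
pixel mean of a band *decreases* with protein amount.  Quantification
inverts against the image bit depth and subtracts a local background
region measured the same way; the two inversions cancel, leaving

    net = background_mean - raw_mean

which may be negative for bands below background.  Net intensities then
feed three normalizations: percent of prey recovered (pull-down / input),
reference-normalized relative binding ((prey_pd/bait_pd) divided by the
same ratio in the reference-bait lane), and bait-normalized recovery
relative to a wild-type control lane, where signals at or below
background are assigned a fixed floor (default 0.01) rather than zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("palmkit")

BAND_ROLES = ("prey_input", "prey_pd", "bait_input", "bait_pd")


class BelowDetection:
    """Marker for a lane whose prey pull-down signal is at/below background."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "BELOW_DETECTION"


#: Singleton below-detection marker returned instead of a number.
BELOW_DETECTION = BelowDetection()


@dataclass(frozen=True)
class BandMeasurement:
    """Raw and local-background mean pixel intensity of one band."""

    raw_mean: float
    background_mean: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        top = 2**self.bit_depth - 1
        for attr in ("raw_mean", "background_mean"):
            v = getattr(self, attr)
            if not 0 <= v <= top:
                raise ValueError(
                    f"{attr}={v} outside [0, {top}] for {self.bit_depth}-bit image"
                )


@dataclass(frozen=True)
class CoIPLane:
    """Net band intensities for one co-IP lane.

    Net intensities may be <= 0 (below background); downstream operations
    flag such lanes rather than silently producing values.
    """

    lane_id: str
    bait_id: str
    prey_input: float
    prey_pd: float
    bait_input: float
    bait_pd: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for attr in ("prey_input", "prey_pd", "bait_input", "bait_pd"):
            if not math.isfinite(getattr(self, attr)):
                raise ValueError(f"{attr} must be finite")


def net_band_intensity(band: BandMeasurement) -> float:
    """Inverted, background-subtracted band intensity.

    ((2^bits - 1) - raw) - ((2^bits - 1) - background) = background - raw.
    Negative values (band below background) are returned as-is.
    """
    net = band.background_mean - band.raw_mean
    if net < 0:
        logger.debug("band below background: net=%.3f", net)
    return net


def percent_prey_recovered(lane: CoIPLane) -> float:
    """Fraction of input prey recovered in the pull-down.

    Undefined (NaN, with a warning) when the prey input is not above
    background.
    """
    if lane.prey_input <= 0:
        logger.warning(
            "lane %s: prey input not above background; recovery undefined",
            lane.lane_id,
        )
        return float("nan")
    return lane.prey_pd / lane.prey_input


def relative_binding(lane: CoIPLane, reference: CoIPLane):
    """Prey occupancy of the bait, normalized to the reference-bait lane.

    (prey_pd / bait_pd) / (prey_pd_ref / bait_pd_ref).  Returns the
    :data:`BELOW_DETECTION` marker when the lane's prey pull-down signal is
    at or below background.  The reference lane itself maps to exactly 1.0.
    """
    if lane.bait_pd <= 0 or reference.bait_pd <= 0:
        raise ValueError("bait pull-down must be above background in both lanes")
    if reference.prey_pd <= 0:
        raise ValueError("reference lane prey pull-down must be above background")
    if lane.prey_pd <= 0:
        return BELOW_DETECTION
    return (lane.prey_pd / lane.bait_pd) / (reference.prey_pd / reference.bait_pd)


def bait_normalized_recovery(
    lane: CoIPLane, wt_reference: CoIPLane, floor: float = 0.01
) -> float:
    """Prey/bait ratio relative to a wild-type control lane (WT = 1.0).

    Lanes whose background-subtracted prey signal is <= 0 are assigned the
    floor value, and no output ever falls strictly between 0 and the floor.
    A WT reference itself below background is a configuration error.
    """
    if wt_reference.prey_pd <= 0 or wt_reference.bait_pd <= 0:
        raise ValueError("WT reference lane is below background")
    if lane.bait_pd <= 0:
        raise ValueError(f"lane {lane.lane_id}: bait pull-down below background")
    if lane.prey_pd <= 0:
        return floor
    value = (lane.prey_pd / lane.bait_pd) / (
        wt_reference.prey_pd / wt_reference.bait_pd
    )
    return max(value, floor)


@dataclass(frozen=True)
class BindingMatrix:
    """Reference-normalized binding values, baits x replicates.

    ``values`` holds the relative binding per bait and replicate (NaN for
    missing lanes, 0.0 where flagged below detection); ``below_detection``
    is a parallel boolean mask distinguishing true zeros from
    below-detection cells.  ``mean`` averages available cells per bait with
    below-detection rendered as 0, mirroring heatmap presentation.
    """

    values: pd.DataFrame
    below_detection: pd.DataFrame
    reference_bait: str

    @property
    def mean(self) -> pd.Series:
        return self.values.mean(axis=1, skipna=True)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out["mean"] = self.mean
        return out


def build_binding_matrix(
    lanes: Sequence[CoIPLane], reference_bait: str
) -> BindingMatrix:
    """Per-replicate relative binding for a panel of bait lanes.

    Every replicate must contain a lane for the reference bait; a bait
    absent from a replicate is a missing (NaN) cell, distinct from a
    below-detection cell (0.0 with mask set).
    """
    reps = sorted({ln.replicate for ln in lanes})
    baits: list[str] = []
    for ln in lanes:
        if ln.bait_id not in baits:
            baits.append(ln.bait_id)
    by_rep: dict[int, dict[str, CoIPLane]] = {r: {} for r in reps}
    for ln in lanes:
        by_rep[ln.replicate][ln.bait_id] = ln
    values = pd.DataFrame(np.nan, index=baits, columns=reps, dtype=float)
    mask = pd.DataFrame(False, index=baits, columns=reps, dtype=bool)
    for rep in reps:
        ref = by_rep[rep].get(reference_bait)
        if ref is None:
            raise ValueError(f"replicate {rep} lacks reference bait {reference_bait!r}")
        for bait, lane in by_rep[rep].items():
            rb = relative_binding(lane, ref)
            if rb is BELOW_DETECTION:
                values.loc[bait, rep] = 0.0
                mask.loc[bait, rep] = True
            else:
                values.loc[bait, rep] = rb
    return BindingMatrix(
        values=values, below_detection=mask, reference_bait=reference_bait
    )


def read_band_table(path) -> list[CoIPLane]:
    """Read a densitometry TSV into lanes.

    Columns: ``lane_id, bait_id, replicate, band_role, raw_mean,
    background_mean, bit_depth`` with one row per band and the four roles
    prey_input / prey_pd / bait_input / bait_pd per lane.
    """
    df = pd.read_csv(path, sep="\t")
    required = {
        "lane_id", "bait_id", "replicate", "band_role", "raw_mean",
        "background_mean", "bit_depth",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    lanes = []
    for (lane_id, bait_id, rep), grp in df.groupby(
        ["lane_id", "bait_id", "replicate"], sort=False
    ):
        nets = {}
        for _, row in grp.iterrows():
            role = row["band_role"]
            if role not in BAND_ROLES:
                raise ValueError(f"unknown band role {role!r} in lane {lane_id}")
            nets[role] = net_band_intensity(
                BandMeasurement(
                    raw_mean=row["raw_mean"],
                    background_mean=row["background_mean"],
                    bit_depth=int(row["bit_depth"]),
                )
            )
        absent = set(BAND_ROLES) - set(nets)
        if absent:
            raise ValueError(f"lane {lane_id} missing bands: {sorted(absent)}")
        lanes.append(
            CoIPLane(
                lane_id=str(lane_id),
                bait_id=str(bait_id),
                replicate=int(rep),
                prey_input=nets["prey_input"],
                prey_pd=nets["prey_pd"],
                bait_input=nets["bait_input"],
                bait_pd=nets["bait_pd"],
            )
        )
    return lanes


def write_band_table(
    bands: Mapping[tuple[str, str, int, str], BandMeasurement], path
) -> None:
    """Write bands keyed by (lane_id, bait_id, replicate, band_role) as TSV."""
    rows = [
        {
            "lane_id": lane_id,
            "bait_id": bait_id,
            "replicate": rep,
            "band_role": role,
            "raw_mean": band.raw_mean,
            "background_mean": band.background_mean,
            "bit_depth": band.bit_depth,
        }
        for (lane_id, bait_id, rep, role), band in bands.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
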