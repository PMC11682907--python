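"""AOI dwell extraction and QC for 60 Hz free-viewing gaze data.

Samples are sorted into the left or right image rectangle (areas of
interest).  Successive same-AOI samples are grouped into bins; a bin is
split whenever the inter-sample interval reaches the gap threshold
(33 ms at clean 60 Hz timing, i.e. two or more missing samples; 66 or
133 ms for recordings with degraded timing precision), whenever the AOI
changes, and whenever an off-AOI sample intervenes.  Only bins spanning at
least 100 ms (last-minus-first timestamp) contribute to dwell time.

Trial-level exclusions: a trial is dropped if its first recorded sample is
already inside an AOI (the task required fixation between the images at
trial onset), if the first-saccade latency exceeds the cohort mean + 3 SD,
or if its sample count falls below the cohort mean - 3 SD.  A subject is
dropped when more than a third of their trials are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import TrialSpec
from .synth import FIX_X, FIX_Y, IMG_H, IMG_W, SCREEN_H, SCREEN_W

AOI_NONE, AOI_LEFT, AOI_RIGHT = 0, 1, 2
_AOI_NAMES = {AOI_NONE: "none", AOI_LEFT: "left", AOI_RIGHT: "right"}

ALLOWED_GAP_MS = (33, 66, 133)


class PreprocError(ValueError):
    pass


@dataclass(frozen=True)
class AoiGeometry:
    """Left/right AOI rectangles (x0, y0, x1, y1) on the screen.

    Rectangles are half-open: a point belongs to a rectangle when
    x0 <= x < x1 and y0 <= y < y1, which makes edge samples deterministic.
    """

    left_rect: tuple[float, float, float, float]
    right_rect: tuple[float, float, float, float]
    screen_w: int = SCREEN_W
    screen_h: int = SCREEN_H

    def __post_init__(self) -> None:
        for name, (x0, y0, x1, y1) in (("left_rect", self.left_rect), ("right_rect", self.right_rect)):
            if not (x0 < x1 and y0 < y1):
                raise PreprocError(f"{name} is degenerate: {(x0, y0, x1, y1)}")
            if x0 < 0 or y0 < 0 or x1 > self.screen_w or y1 > self.screen_h:
                raise PreprocError(f"{name} extends off screen: {(x0, y0, x1, y1)}")
        if not (self.left_rect[2] <= self.right_rect[0] or self.right_rect[2] <= self.left_rect[0]):
            raise PreprocError("AOI rectangles overlap")


def default_geometry() -> AoiGeometry:
    """Two 576x346 rectangles horizontally centered in each screen half,
    vertically centered on the 1280x1024 screen."""
    cy0, cy1 = FIX_Y - IMG_H / 2, FIX_Y + IMG_H / 2
    lcx, rcx = SCREEN_W / 4, 3 * SCREEN_W / 4
    return AoiGeometry(
        left_rect=(lcx - IMG_W / 2, cy0, lcx + IMG_W / 2, cy1),
        right_rect=(rcx - IMG_W / 2, cy0, rcx + IMG_W / 2, cy1),
    )


@dataclass(frozen=True)
class QcThresholds:
    """Binning and exclusion thresholds.

    ``gap_ms`` is the bin-split threshold (33 default; 66/133 for the
    degraded-timing dialect).  ``min_bin_ms`` is the minimum bin span that
    contributes dwell.  Latency and sample-count cutoffs are derived from
    cohort statistics (mean + ``latency_sd_mult``*SD, mean -
    ``samples_sd_mult``*SD).  Subjects lose more than
    ``max_trial_loss_fraction`` of trials -> excluded.
    """

    gap_ms: float = 33.0
    min_bin_ms: float = 100.0
    latency_sd_mult: float = 3.0
    samples_sd_mult: float = 3.0
    max_trial_loss_fraction: float = 1.0 / 3.0
    count_invalid_samples: bool = False

    def __post_init__(self) -> None:
        if int(self.gap_ms) not in ALLOWED_GAP_MS:
            raise PreprocError(f"gap_ms must be one of {ALLOWED_GAP_MS}, got {self.gap_ms}")
        if self.min_bin_ms <= 0:
            raise PreprocError("min_bin_ms must be > 0")


@dataclass(frozen=True)
class DwellBin:
    aoi: str  # "left" or "right"
    t_start_ms: float
    t_end_ms: float
    n_samples: int

    @property
    def duration_ms(self) -> float:
        return self.t_end_ms - self.t_start_ms


@dataclass
class TrialDwell:
    """Per-trial dwell summary with QC flags."""

    subject_id: str
    trial_id: int
    condition: str
    emotional_side: str
    dwell_left_ms: float
    dwell_right_ms: float
    first_saccade_latency_ms: float | None
    n_samples_total: int
    start_in_aoi: bool

    @property
    def dwell_emotional_ms(self) -> float | None:
        if self.emotional_side == "left":
            return self.dwell_left_ms
        if self.emotional_side == "right":
            return self.dwell_right_ms
        return None

    @property
    def dwell_neutral_ms(self) -> float | None:
        if self.emotional_side == "left":
            return self.dwell_right_ms
        if self.emotional_side == "right":
            return self.dwell_left_ms
        return None


# ---------------------------------------------------------------------------


def assign_aoi_codes(
    x: np.ndarray, y: np.ndarray, valid: np.ndarray, geometry: AoiGeometry
) -> np.ndarray:
    """Vectorized AOI assignment: 0=none, 1=left, 2=right.

    Half-open rectangle membership; invalid samples map to none.
    """
    codes = np.zeros(len(x), dtype=np.int8)
    for code, (x0, y0, x1, y1) in ((AOI_LEFT, geometry.left_rect), (AOI_RIGHT, geometry.right_rect)):
        inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        codes[inside] = code
    codes[~np.asarray(valid, dtype=bool)] = AOI_NONE
    return codes


def assign_aoi(x: float, y: float, geometry: AoiGeometry, valid: bool = True) -> str:
    """Classify a single gaze sample as 'left', 'right' or 'none'."""
    code = assign_aoi_codes(np.array([x]), np.array([y]), np.array([valid]), geometry)[0]
    return _AOI_NAMES[int(code)]


def bin_samples(
    trial_samples: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    geometry: AoiGeometry | None = None,
) -> list[DwellBin]:
    """Group one trial's samples into gap-tolerant same-AOI bins.

    A new bin starts at an AOI change or when the inter-sample interval is
    >= ``gap_ms``; off-AOI and invalid samples terminate the current bin.
    Raises on unsorted timestamps.
    """
    thr = thresholds or QcThresholds()
    geom = geometry or default_geometry()
    t = trial_samples["t_ms"].to_numpy(dtype=float)
    if len(t) == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise PreprocError("trial samples are not sorted by t_ms")
    codes = assign_aoi_codes(
        trial_samples["x_px"].to_numpy(dtype=float),
        trial_samples["y_px"].to_numpy(dtype=float),
        trial_samples["valid"].to_numpy(),
        geom,
    )
    in_aoi = codes != AOI_NONE
    idx = np.flatnonzero(in_aoi)
    if len(idx) == 0:
        return []
    # A break before in-AOI sample k (relative to the previous in-AOI sample):
    # AOI change, timing gap >= gap_ms, or any intervening off-AOI sample.
    prev = idx[:-1]
    cur = idx[1:]
    breaks = (
        (codes[cur] != codes[prev])
        | ((t[cur] - t[prev]) >= thr.gap_ms)
        | (cur - prev > 1)
    )
    starts = np.concatenate([[0], np.flatnonzero(breaks) + 1])
    ends = np.concatenate([np.flatnonzero(breaks), [len(idx) - 1]])
    bins = []
    for s, e in zip(starts, ends):
        members = idx[s : e + 1]
        bins.append(
            DwellBin(
                aoi=_AOI_NAMES[int(codes[members[0]])],
                t_start_ms=float(t[members[0]]),
                t_end_ms=float(t[members[-1]]),
                n_samples=len(members),
            )
        )
    return bins


def filter_bins(bins: Iterable[DwellBin], min_bin_ms: float = 100.0) -> list[DwellBin]:
    """Keep bins spanning at least ``min_bin_ms`` (last minus first sample).

    Boundary inclusive; single-sample bins span 0 ms and are dropped.
    """
    return [b for b in bins if b.duration_ms >= min_bin_ms]


def compute_trial_dwell(
    trial_samples: pd.DataFrame,
    trial: TrialSpec,
    geometry: AoiGeometry | None = None,
    thresholds: QcThresholds | None = None,
    subject_id: str | None = None,
) -> TrialDwell:
    """Compose binning, the 100 ms filter, latency and the start-in-AOI flag
    into one trial's dwell record."""
    thr = thresholds or QcThresholds()
    geom = geometry or default_geometry()
    subj = subject_id if subject_id is not None else (
        str(trial_samples["subject_id"].iloc[0]) if len(trial_samples) else "unknown"
    )

    if thr.count_invalid_samples:
        recorded = trial_samples
    else:
        recorded = trial_samples.loc[trial_samples["valid"].astype(bool)]
    n_total = len(recorded)

    bins = bin_samples(trial_samples, thr, geom)
    kept = filter_bins(bins, thr.min_bin_ms)
    dwell = {"left": 0.0, "right": 0.0}
    for b in kept:
        dwell[b.aoi] += b.duration_ms

    if n_total:
        codes = assign_aoi_codes(
            recorded["x_px"].to_numpy(dtype=float),
            recorded["y_px"].to_numpy(dtype=float),
            recorded["valid"].to_numpy(),
            geom,
        )
        hits = np.flatnonzero(codes != AOI_NONE)
        latency = float(recorded["t_ms"].iloc[hits[0]]) if len(hits) else None
        start_in_aoi = bool(codes[0] != AOI_NONE)
    else:
        latency = None
        start_in_aoi = False

    return TrialDwell(
        subject_id=subj,
        trial_id=int(trial.trial_id),
        condition=trial.condition,
        emotional_side=trial.emotional_side,
        dwell_left_ms=dwell["left"],
        dwell_right_ms=dwell["right"],
        first_saccade_latency_ms=latency,
        n_samples_total=n_total,
        start_in_aoi=start_in_aoi,
    )


def dwell_to_frame(records: Sequence[TrialDwell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "trial_id": [r.trial_id for r in records],
            "condition": [r.condition for r in records],
            "emotional_side": [r.emotional_side for r in records],
            "dwell_left_ms": [r.dwell_left_ms for r in records],
            "dwell_right_ms": [r.dwell_right_ms for r in records],
            "dwell_emotional_ms": [r.dwell_emotional_ms if r.dwell_emotional_ms is not None else np.nan for r in records],
            "dwell_neutral_ms": [r.dwell_neutral_ms if r.dwell_neutral_ms is not None else np.nan for r in records],
            "first_saccade_latency_ms": [
                r.first_saccade_latency_ms if r.first_saccade_latency_ms is not None else np.nan for r in records
            ],
            "n_samples_total": [r.n_samples_total for r in records],
            "start_in_aoi": [r.start_in_aoi for r in records],
        }
    )


def preprocess_dataset(
    samples: pd.DataFrame,
    trials: pd.DataFrame,
    geometry: AoiGeometry | None = None,
    thresholds: QcThresholds | None = None,
) -> pd.DataFrame:
    """Compute one TrialDwell row per (subject, trial) in the trials table.

    Trials with no recorded samples yield zero dwell and a zero sample
    count, leaving them eligible for the low-sample-count exclusion.
    """
    records = []
    grouped = dict(tuple(samples.groupby(["subject_id", "trial_id"], sort=False)))
    for row in trials.itertuples(index=False):
        key = (row.subject_id, row.trial_id)
        g = grouped.get(key)
        if g is None:
            g = samples.iloc[0:0]
        spec = TrialSpec(
            trial_id=int(row.trial_id),
            condition=row.condition,
            left_image=row.left_image,
            right_image=row.right_image,
            emotional_side=row.emotional_side,
        )
        records.append(
            compute_trial_dwell(g, spec, geometry, thresholds, subject_id=str(row.subject_id))
        )
    return dwell_to_frame(records)


# ---------------------------------------------------------------------------
# Cohort-level QC


@dataclass
class QcResult:
    kept: pd.DataFrame
    excluded_trials: pd.DataFrame  # with a 'reasons' column
    excluded_subjects: list[str]
    cohort_stats: dict[str, float]


def qc_exclude(dwell: pd.DataFrame, thresholds: QcThresholds | None = None) -> QcResult:
    """Apply the two-pass cohort exclusion rules.

    Pass 1 pools all trials of all subjects to estimate the latency and
    sample-count distributions; pass 2 excludes trials flagged start-in-AOI,
    with latency above mean + 3 SD, with sample count below mean - 3 SD, or
    with no defined latency (never entered an AOI).  Subjects exceeding the
    trial-loss fraction are removed entirely.  Zero-variance cohort
    statistics disable the corresponding criterion.
    """
    thr = thresholds or QcThresholds()
    lat = dwell["first_saccade_latency_ms"].to_numpy(dtype=float)
    defined = ~np.isnan(lat)
    if defined.sum() < 2:
        raise PreprocError("need at least 2 trials with defined latency to estimate cohort SD")
    lat_mean = float(lat[defined].mean())
    lat_sd = float(lat[defined].std(ddof=1))
    cnt = dwell["n_samples_total"].to_numpy(dtype=float)
    cnt_mean = float(cnt.mean())
    cnt_sd = float(cnt.std(ddof=1)) if len(cnt) > 1 else 0.0

    lat_limit = lat_mean + thr.latency_sd_mult * lat_sd if lat_sd > 0 else np.inf
    cnt_floor = cnt_mean - thr.samples_sd_mult * cnt_sd if cnt_sd > 0 else -np.inf

    reasons = []
    for row in dwell.itertuples(index=False):
        r = []
        if row.start_in_aoi:
            r.append("start_in_aoi")
        if np.isnan(row.first_saccade_latency_ms):
            r.append("no_aoi_entry")
        elif row.first_saccade_latency_ms > lat_limit:
            r.append("slow_latency")
        if row.n_samples_total < cnt_floor:
            r.append("low_sample_count")
        reasons.append(",".join(r))
    flagged = pd.Series(reasons, index=dwell.index)
    excluded = dwell.loc[flagged != ""].copy()
    excluded["reasons"] = flagged[flagged != ""]
    kept = dwell.loc[flagged == ""].copy()

    loss = (flagged != "").groupby(dwell["subject_id"]).mean()
    excluded_subjects = sorted(loss.index[loss > thr.max_trial_loss_fraction].tolist())
    kept = kept.loc[~kept["subject_id"].isin(excluded_subjects)].reset_index(drop=True)

    stats_out = {
        "latency_mean_ms": lat_mean,
        "latency_sd_ms": lat_sd,
        "latency_limit_ms": float(lat_limit),
        "samples_mean": cnt_mean,
        "samples_sd": cnt_sd,
        "samples_floor": float(cnt_floor),
        "n_trials": float(len(dwell)),
        "n_trials_excluded": float(len(excluded)),
        "n_subjects_excluded": float(len(excluded_subjects)),
    }
    return QcResult(kept=kept, excluded_trials=excluded.reset_index(drop=True), excluded_subjects=excluded_subjects, cohort_stats=stats_out)
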