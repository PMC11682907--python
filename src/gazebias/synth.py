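"""Synthetic cohorts and 60 Hz gaze streams with planted moderation structure.

The generator stands in for raw free-viewing data: each subject views 48
ten-second image pairs while gaze alternates between the two image regions
(AOIs) in gamma-distributed episodes — a semi-Markov process.  At every
episode boundary the emotional AOI is chosen with probability
``logistic(eta)``, where ``eta`` accumulates a baseline, a condition offset,
and (standardized) age, emotion-regulation-preference and depression terms
that mirror the moderation structure the analysis estimates.  The stationary
emotional dwell share therefore equals ``logistic(eta)``, which makes planted
effects recoverable in closed form.

Trait sampling emulates the study cohort: ages 35-75; control-group BDI 0-8
versus MDD 10-47; ten 1-7 ERQ items (6 reappraisal, 4 suppression) drawn from
latent group means with a configurable within-group reappraisal/suppression
correlation, so that only the control group shows the negative coupling
between the two strategies.

Acquisition artifacts (sample dropout, trials starting inside an AOI, slow
first saccades, truncated trials) are injected separately with a ground-truth
manifest so the preprocessing QC rules can be tested exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import ImageItem, TrialSpec, build_trial_lists, synthetic_image_set, trials_to_frame

N_REAPPRAISAL_ITEMS = 6
N_SUPPRESSION_ITEMS = 4

SAMPLE_COLUMNS = ["subject_id", "trial_id", "t_ms", "x_px", "y_px", "valid"]


class SynthError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class ParticipantProfile:
    """One synthetic participant's trait record."""

    subject_id: str
    group: str  # "control" or "mdd"
    age: float
    bdi_sum: int
    erq_items: tuple[int, ...]  # 6 reappraisal then 4 suppression items, each 1-7

    def __post_init__(self) -> None:
        if self.group not in ("control", "mdd"):
            raise SynthError(f"group must be 'control' or 'mdd', got {self.group!r}")
        if len(self.erq_items) != N_REAPPRAISAL_ITEMS + N_SUPPRESSION_ITEMS:
            raise SynthError(f"erq_items must have 10 entries, got {len(self.erq_items)}")
        if any(not 1 <= v <= 7 for v in self.erq_items):
            raise SynthError(f"erq_items outside 1-7: {self.erq_items}")


@dataclass(frozen=True)
class TraitConfig:
    """Distributional targets for the trait sampler.

    Latent reappraisal/suppression means are bivariate normal per group with
    the configured correlation; item scores add independent noise and round
    to the 1-7 Likert scale, which mildly attenuates the realized
    correlation.  Defaults place the control group's preference distribution
    (mean ~2.2, SD ~1.8) and BDI ranges where the study cohort sat.
    """

    age_range: tuple[float, float] = (35.0, 75.0)
    control_bdi_range: tuple[int, int] = (0, 8)
    mdd_bdi_range: tuple[int, int] = (10, 47)
    control_bdi_mean: float = 1.8
    control_bdi_sd: float = 1.9
    mdd_bdi_mean: float = 27.3
    mdd_bdi_sd: float = 9.3
    control_reappraisal_mean: float = 5.0
    control_suppression_mean: float = 2.82
    mdd_reappraisal_mean: float = 4.0
    mdd_suppression_mean: float = 4.0
    latent_sd: float = 0.9
    control_reapp_supp_r: float = -0.476
    mdd_reapp_supp_r: float = 0.0
    item_noise_sd: float = 0.7

    def validate(self) -> None:
        for name in ("age_range", "control_bdi_range", "mdd_bdi_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SynthError(f"{name}: min {lo} > max {hi}")
        for name in ("control_reapp_supp_r", "mdd_reapp_supp_r"):
            r = getattr(self, name)
            if not -1.0 < r < 1.0:
                raise SynthError(f"{name}={r} outside (-1, 1)")
        if self.latent_sd <= 0 or self.item_noise_sd < 0:
            raise SynthError("latent_sd must be > 0 and item_noise_sd >= 0")


@dataclass(frozen=True)
class GenerativeCoefficients:
    """Logit-scale coefficients of the emotional-side dwell propensity.

    ``eta`` for a positive-neutral trial is
    ``b0 + b_pos + b_age_pos*age_z + b_agexpref_pos*age_z*pref_z (+ u_subject)``
    and analogously for negative-neutral trials, which additionally carry
    ``b_bdi_neg*bdi_z``.  Neutral-neutral trials use ``eta = b0`` with the
    left image playing the "emotional" role.  Episode durations within an AOI
    are gamma distributed; ``offscreen_rate`` inserts center-fixation gaps.
    """

    b0: float = 0.0
    b_pos: float = 0.45
    b_neg: float = 0.30
    b_age_pos: float = 0.0
    b_age_neg: float = 0.0
    b_agexpref_pos: float = 0.25
    b_agexpref_neg: float = -0.25
    b_bdi_neg: float = 0.15
    subject_sd: float = 0.4
    episode_shape: float = 2.0
    episode_mean_ms: float = 500.0
    offscreen_rate: float = 0.10
    latency_mean_ms: float = 310.0
    latency_sd_ms: float = 250.0

    def validate(self) -> None:
        if self.episode_mean_ms <= 0 or self.episode_shape <= 0:
            raise SynthError("episode_mean_ms and episode_shape must be > 0")
        if not 0.0 <= self.offscreen_rate < 1.0:
            raise SynthError(f"offscreen_rate={self.offscreen_rate} outside [0, 1)")
        if self.subject_sd < 0 or self.latency_sd_ms < 0:
            raise SynthError("subject_sd and latency_sd_ms must be >= 0")

    def eta(self, condition: str, age_z: float = 0.0, pref_z: float = 0.0, bdi_z: float = 0.0) -> float:
        """Logit of the emotional-side choice probability for one trial."""
        if condition == "positive-neutral":
            return self.b0 + self.b_pos + self.b_age_pos * age_z + self.b_agexpref_pos * age_z * pref_z
        if condition == "negative-neutral":
            return (
                self.b0
                + self.b_neg
                + self.b_age_neg * age_z
                + self.b_agexpref_neg * age_z * pref_z
                + self.b_bdi_neg * bdi_z
            )
        if condition == "neutral-neutral":
            return self.b0
        raise SynthError(f"unknown condition label {condition!r}")


@dataclass(frozen=True)
class ArtifactSpec:
    """Controllable acquisition artifacts, all off by default.

    ``slow_latency_ms`` should sit well above the cohort's latency
    mean + 3 SD so injected trials are guaranteed to violate the QC rule;
    injection rates much above ~5% inflate the cohort SD enough to swallow
    the artifacts.
    """

    dropout_rate: float = 0.0
    p_start_in_aoi: float = 0.0
    p_slow_latency: float = 0.0
    p_short_trial: float = 0.0
    slow_latency_ms: float = 3000.0
    short_trial_fraction: float = 0.4
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("dropout_rate", "p_start_in_aoi", "p_slow_latency", "p_short_trial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.short_trial_fraction <= 1.0:
            raise SynthError(f"short_trial_fraction={self.short_trial_fraction} outside (0, 1]")


# ---------------------------------------------------------------------------
# Cohort generation


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_group(
    rng: np.random.Generator,
    n: int,
    group: str,
    cfg: TraitConfig,
) -> list[ParticipantProfile]:
    if group == "control":
        bdi_lo, bdi_hi = cfg.control_bdi_range
        bdi_mean, bdi_sd = cfg.control_bdi_mean, cfg.control_bdi_sd
        mu = np.array([cfg.control_reappraisal_mean, cfg.control_suppression_mean])
        r = cfg.control_reapp_supp_r
    else:
        bdi_lo, bdi_hi = cfg.mdd_bdi_range
        bdi_mean, bdi_sd = cfg.mdd_bdi_mean, cfg.mdd_bdi_sd
        mu = np.array([cfg.mdd_reappraisal_mean, cfg.mdd_suppression_mean])
        r = cfg.mdd_reapp_supp_r

    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], n)
    bdi = np.clip(np.rint(_truncnorm(rng, bdi_mean, bdi_sd, bdi_lo - 0.49, bdi_hi + 0.49, n)), bdi_lo, bdi_hi)
    # Item noise plus Likert rounding (variance ~1/12) attenuate the
    # correlation of the item means; pre-compensate so the realized
    # reappraisal/suppression correlation hits the configured target.
    per_item = cfg.item_noise_sd**2 + 1.0 / 12.0
    att = 1.0
    for n_items in (N_REAPPRAISAL_ITEMS, N_SUPPRESSION_ITEMS):
        att *= cfg.latent_sd / np.sqrt(cfg.latent_sd**2 + per_item / n_items)
    r = float(np.clip(r / att, -0.99, 0.99))
    cov = cfg.latent_sd**2 * np.array([[1.0, r], [r, 1.0]])
    latent = rng.multivariate_normal(mu, cov, size=n)

    profiles = []
    for i in range(n):
        reapp = latent[i, 0] + rng.normal(0.0, cfg.item_noise_sd, N_REAPPRAISAL_ITEMS)
        supp = latent[i, 1] + rng.normal(0.0, cfg.item_noise_sd, N_SUPPRESSION_ITEMS)
        items = tuple(int(v) for v in np.clip(np.rint(np.concatenate([reapp, supp])), 1, 7))
        profiles.append(
            ParticipantProfile(
                subject_id=f"{'c' if group == 'control' else 'm'}{i + 1:03d}",
                group=group,
                age=float(ages[i]),
                bdi_sum=int(bdi[i]),
                erq_items=items,
            )
        )
    return profiles


def generate_cohort(
    n_control: int,
    n_mdd: int,
    trait_config: TraitConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[ParticipantProfile]:
    """Draw a reproducible cohort of control and MDD participant profiles."""
    if n_control < 0 or n_mdd < 0:
        raise SynthError(f"group sizes must be >= 0, got n_control={n_control}, n_mdd={n_mdd}")
    cfg = trait_config or TraitConfig()
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _draw_group(rng, n_control, "control", cfg) + _draw_group(rng, n_mdd, "mdd", cfg)


def cohort_to_frame(cohort: Sequence[ParticipantProfile]) -> pd.DataFrame:
    cols = [f"erq_r{i + 1}" for i in range(N_REAPPRAISAL_ITEMS)] + [
        f"erq_s{i + 1}" for i in range(N_SUPPRESSION_ITEMS)
    ]
    rows = []
    for p in cohort:
        row = {"subject_id": p.subject_id, "group": p.group, "age": p.age, "bdi_sum": p.bdi_sum}
        row.update(dict(zip(cols, p.erq_items)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "group", "age", "bdi_sum"] + cols)


# ---------------------------------------------------------------------------
# Gaze simulation

#: screen and AOI geometry defaults shared with preprocessing
SCREEN_W, SCREEN_H = 1280, 1024
IMG_W, IMG_H = 576, 346
FIX_X, FIX_Y = SCREEN_W / 2, SCREEN_H / 2


def _default_rects() -> tuple[tuple[float, float, float, float], tuple[float, float, float, float]]:
    cy0, cy1 = FIX_Y - IMG_H / 2, FIX_Y + IMG_H / 2
    lcx, rcx = SCREEN_W / 4, 3 * SCREEN_W / 4
    left = (lcx - IMG_W / 2, cy0, lcx + IMG_W / 2, cy1)
    right = (rcx - IMG_W / 2, cy0, rcx + IMG_W / 2, cy1)
    return left, right


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling-rate and trial-duration settings of the simulated tracker."""

    sampling_hz: float = 60.0
    trial_duration_ms: float = 10_000.0
    min_latency_ms: float = 80.0

    def validate(self) -> None:
        if self.sampling_hz <= 0:
            raise SynthError(f"sampling_hz must be > 0, got {self.sampling_hz}")
        if self.trial_duration_ms <= 0:
            raise SynthError("trial_duration_ms must be > 0")


def simulate_trial_gaze(
    profile: ParticipantProfile,
    trial: TrialSpec,
    coeffs: GenerativeCoefficients | None = None,
    seed: int | np.random.Generator = 0,
    *,
    age_z: float = 0.0,
    pref_z: float = 0.0,
    bdi_z: float = 0.0,
    subject_effect: float = 0.0,
    acquisition: AcquisitionConfig | None = None,
) -> pd.DataFrame:
    """Simulate one trial's 60 Hz gaze stream.

    Gaze starts on the central fixation cross, enters the first AOI after a
    truncated-normal latency, then alternates between AOIs (or brief center
    gaps) in gamma-distributed episodes.  The standardized covariates enter
    the per-episode choice logit; pass the cohort-standardized values when
    simulating a full dataset.
    """
    coeffs = coeffs or GenerativeCoefficients()
    coeffs.validate()
    acq = acquisition or AcquisitionConfig()
    acq.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    eta = coeffs.eta(trial.condition, age_z=age_z, pref_z=pref_z, bdi_z=bdi_z) + subject_effect
    p_emotional = special.expit(eta)

    period = 1000.0 / acq.sampling_hz
    n_samples = int(round(acq.trial_duration_ms / period))
    t = np.arange(n_samples) * period

    latency = float(
        _truncnorm(
            rng, coeffs.latency_mean_ms, coeffs.latency_sd_ms, acq.min_latency_ms, acq.trial_duration_ms, 1
        )[0]
    )

    # Episode schedule from the latency onward: state 0=center gap, 1=left, 2=right.
    # The "emotional" role is the emotional side, or the left image on
    # neutral-neutral trials (sides exchangeable at b0 = 0).
    emo_state = 1 if trial.emotional_side in ("left", "none") else 2
    neu_state = 2 if emo_state == 1 else 1
    scale = coeffs.episode_mean_ms / coeffs.episode_shape
    budget = acq.trial_duration_ms - latency
    n_guess = max(8, int(3 * budget / coeffs.episode_mean_ms) + 8)
    starts, states, elapsed = [latency], [], 0.0
    while True:
        durs = rng.gamma(coeffs.episode_shape, scale, n_guess)
        gaps = rng.random(n_guess) < coeffs.offscreen_rate
        emo = rng.random(n_guess) < p_emotional
        for d, g, e in zip(durs, gaps, emo):
            states.append(0 if g else (emo_state if e else neu_state))
            elapsed += d
            starts.append(latency + elapsed)
            if elapsed >= budget:
                break
        if elapsed >= budget:
            break

    bounds = np.array(starts)
    state_at = np.zeros(n_samples, dtype=int)
    in_episode = t >= latency
    idx = np.searchsorted(bounds, t[in_episode], side="right") - 1
    state_at[in_episode] = np.asarray(states)[idx]

    x = np.empty(n_samples)
    y = np.empty(n_samples)
    left_rect, right_rect = _default_rects()
    center = state_at == 0
    x[center] = np.clip(rng.normal(FIX_X, 8.0, center.sum()), left_rect[2] + 1, right_rect[0] - 1)
    y[center] = rng.normal(FIX_Y, 8.0, center.sum())
    for state, rect in ((1, left_rect), (2, right_rect)):
        m = state_at == state
        x[m] = rng.uniform(rect[0] + 5, rect[2] - 5, m.sum())
        y[m] = rng.uniform(rect[1] + 5, rect[3] - 5, m.sum())

    return pd.DataFrame(
        {
            "subject_id": profile.subject_id,
            "trial_id": trial.trial_id,
            "t_ms": t,
            "x_px": np.round(x, 1),
            "y_px": np.round(y, 1),
            "valid": True,
        }
    )


# ---------------------------------------------------------------------------
# Artifact injection


def inject_artifacts(
    samples: pd.DataFrame, spec: ArtifactSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a clean sample table; return (samples, artifact manifest).

    The manifest has one row per injected trial-level artifact
    (subject_id, trial_id, artifact) and is the ground truth against which
    the QC exclusion rules are tested.  All rates 0 reproduces the input.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    left_rect, right_rect = _default_rects()
    out = []
    manifest_rows = []
    for (subj, trial), g in samples.groupby(["subject_id", "trial_id"], sort=True):
        g = g.sort_values("t_ms").reset_index(drop=True)
        if spec.p_short_trial and rng.random() < spec.p_short_trial:
            keep = max(1, int(len(g) * spec.short_trial_fraction))
            g = g.iloc[:keep].reset_index(drop=True)
            manifest_rows.append((subj, trial, "short_trial"))
        if spec.p_slow_latency and rng.random() < spec.p_slow_latency:
            m = g["t_ms"] < spec.slow_latency_ms
            g.loc[m, "x_px"] = np.round(np.clip(rng.normal(FIX_X, 8.0, int(m.sum())), left_rect[2] + 1, right_rect[0] - 1), 1)
            g.loc[m, "y_px"] = np.round(rng.normal(FIX_Y, 8.0, int(m.sum())), 1)
            manifest_rows.append((subj, trial, "slow_latency"))
        if spec.p_start_in_aoi and rng.random() < spec.p_start_in_aoi:
            rect = left_rect if rng.random() < 0.5 else right_rect
            g.loc[0, "x_px"] = round((rect[0] + rect[2]) / 2, 1)
            g.loc[0, "y_px"] = round((rect[1] + rect[3]) / 2, 1)
            manifest_rows.append((subj, trial, "start_in_aoi"))
        if spec.dropout_rate:
            keep_mask = rng.random(len(g)) >= spec.dropout_rate
            keep_mask[0] = True  # keep trial onset so the start-in-AOI flag stays meaningful
            g = g.loc[keep_mask].reset_index(drop=True)
        out.append(g)
    manifest = pd.DataFrame(manifest_rows, columns=["subject_id", "trial_id", "artifact"])
    result = pd.concat(out, ignore_index=True) if out else samples.copy()
    return result, manifest


# ---------------------------------------------------------------------------
# Whole-dataset simulation


@dataclass
class SimulatedDataset:
    """All tables produced by one simulation run."""

    participants: pd.DataFrame
    trials: pd.DataFrame
    samples: pd.DataFrame
    manifest: pd.DataFrame
    standardization: pd.DataFrame  # cohort means/SDs used for the planted effects


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def simulate_dataset(
    n_control: int = 44,
    n_mdd: int = 28,
    trait_config: TraitConfig | None = None,
    coeffs: GenerativeCoefficients | None = None,
    artifacts: ArtifactSpec | None = None,
    images: Sequence[ImageItem] | None = None,
    acquisition: AcquisitionConfig | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate a full study: cohort, per-subject trial lists, gaze streams.

    Age, ERQ preference and BDI are standardized within the generated cohort
    before entering the dwell-propensity logit, matching the analysis-side
    standardization.  Artifacts are injected last, with a manifest.
    """
    coeffs = coeffs or GenerativeCoefficients()
    coeffs.validate()
    master = np.random.SeedSequence(seed)
    cohort_rng, trial_rng, gaze_rng_seq, artifact_seed = (
        np.random.default_rng(master.spawn(1)[0]),
        None,
        master.spawn(1)[0],
        int(master.generate_state(1)[0] % (2**31)),
    )
    cohort = generate_cohort(n_control, n_mdd, trait_config, seed=cohort_rng)
    participants = cohort_to_frame(cohort)
    images = list(images) if images is not None else synthetic_image_set(seed=np.random.default_rng(gaze_rng_seq.spawn(1)[0]))

    if cohort:
        ages = _zscore(participants["age"].to_numpy())
        reapp = participants[[f"erq_r{i+1}" for i in range(N_REAPPRAISAL_ITEMS)]].mean(axis=1)
        supp = participants[[f"erq_s{i+1}" for i in range(N_SUPPRESSION_ITEMS)]].mean(axis=1)
        pref = _zscore((reapp - supp).to_numpy())
        bdi = _zscore(participants["bdi_sum"].to_numpy().astype(float))
    else:
        ages = pref = bdi = np.array([])

    std = pd.DataFrame(
        {
            "variable": ["age", "preference", "bdi_sum"],
            "mean": [
                participants["age"].mean() if len(cohort) else np.nan,
                float((reapp - supp).mean()) if len(cohort) else np.nan,
                participants["bdi_sum"].mean() if len(cohort) else np.nan,
            ],
            "sd": [
                participants["age"].std(ddof=1) if len(cohort) > 1 else np.nan,
                float((reapp - supp).std(ddof=1)) if len(cohort) > 1 else np.nan,
                participants["bdi_sum"].std(ddof=1) if len(cohort) > 1 else np.nan,
            ],
        }
    )

    trial_frames, sample_frames = [], []
    subject_seeds = gaze_rng_seq.spawn(len(cohort))
    for i, profile in enumerate(cohort):
        srng = np.random.default_rng(subject_seeds[i])
        u = srng.normal(0.0, coeffs.subject_sd) if coeffs.subject_sd > 0 else 0.0
        trials = build_trial_lists(images, srng)
        trial_frames.append(trials_to_frame(trials, subject_id=profile.subject_id))
        for trial in trials:
            sample_frames.append(
                simulate_trial_gaze(
                    profile,
                    trial,
                    coeffs,
                    srng,
                    age_z=float(ages[i]),
                    pref_z=float(pref[i]),
                    bdi_z=float(bdi[i]),
                    subject_effect=u,
                    acquisition=acquisition,
                )
            )

    trials_df = (
        pd.concat(trial_frames, ignore_index=True)
        if trial_frames
        else pd.DataFrame(columns=["subject_id", "trial_id", "condition", "emotional_side", "left_image", "right_image"])
    )
    samples_df = (
        pd.concat(sample_frames, ignore_index=True) if sample_frames else pd.DataFrame(columns=SAMPLE_COLUMNS)
    )

    art = artifacts if artifacts is not None else ArtifactSpec()
    if len(samples_df):
        art = dataclasses.replace(art, rng_seed=art.rng_seed if artifacts is not None else artifact_seed)
        samples_df, manifest = inject_artifacts(samples_df, art)
    else:
        manifest = pd.DataFrame(columns=["subject_id", "trial_id", "artifact"])
    return SimulatedDataset(participants, trials_df, samples_df, manifest, std)
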