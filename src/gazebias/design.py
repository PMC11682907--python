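"""Paired-image task design: trial-list construction and stimulus-set validation.

The free-viewing task shows 48 image pairs for 10 s each: 16 positive-neutral,
16 negative-neutral and 16 neutral-neutral pairs drawn from a 96-item stimulus
set (16 positive, 16 negative, 64 neutral images).  Pair lists are built per
participant: one list of 48 randomly ordered neutral images, a second list of
the remaining 16 neutral plus all 32 emotional images in random order, paired
index-wise with random left/right assignment.

`validate_stimulus_set` reproduces the normative-rating checks used to vet
such a set: one-way ANOVAs across the three categories on valence and arousal,
all pairwise contrasts from a pooled-error linear model (df = N - 3) with
Bonferroni correction (factor 3), and per-feature ANOVAs on low-level image
features (color, luminosity, contrast, complexity) that must all be
non-significant for the set to pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("positive", "negative", "neutral")
CONDITIONS = ("positive-neutral", "negative-neutral", "neutral-neutral")

#: category counts required of a full stimulus set
SET_COMPOSITION = {"positive": 16, "negative": 16, "neutral": 64}

N_TRIALS = 48


class DesignError(ValueError):
    """Raised for invalid stimulus sets or trial-list requests."""


@dataclass(frozen=True)
class ImageItem:
    """One stimulus image with optional normative ratings (1-9 scales)."""

    image_id: str
    category: str
    valence: float | None = None
    arousal: float | None = None
    low_level: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise DesignError(f"unknown category {self.category!r} for image {self.image_id!r}")
        for name, value in (("valence", self.valence), ("arousal", self.arousal)):
            if value is not None and not (1.0 <= value <= 9.0):
                raise DesignError(f"{name}={value} outside the 1-9 rating scale for image {self.image_id!r}")


@dataclass(frozen=True)
class TrialSpec:
    """One image pair: condition, left/right identity, and emotional side."""

    trial_id: int
    condition: str
    left_image: str
    right_image: str
    emotional_side: str  # "left", "right" or "none"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DesignError(f"unknown condition {self.condition!r}")
        if (self.emotional_side == "none") != (self.condition == "neutral-neutral"):
            raise DesignError(
                f"trial {self.trial_id}: emotional_side={self.emotional_side!r} "
                f"inconsistent with condition {self.condition!r}"
            )
        if self.emotional_side not in ("left", "right", "none"):
            raise DesignError(f"invalid emotional_side {self.emotional_side!r}")


def _check_composition(images: Sequence[ImageItem]) -> dict[str, list[ImageItem]]:
    ids = [im.image_id for im in images]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DesignError(f"duplicate image_ids: {dupes}")
    by_cat: dict[str, list[ImageItem]] = {c: [] for c in CATEGORIES}
    for im in images:
        by_cat[im.category].append(im)
    for cat, want in SET_COMPOSITION.items():
        if len(by_cat[cat]) != want:
            raise DesignError(
                f"stimulus set needs {want} {cat} images, got {len(by_cat[cat])}"
            )
    return by_cat


def build_trial_lists(images: Sequence[ImageItem], seed: int | np.random.Generator) -> list[TrialSpec]:
    """Build one participant's 48-trial list from a 16/16/64 image set.

    List A holds 48 randomly ordered neutral images; list B holds the
    remaining 16 neutral plus the 16 positive and 16 negative images in
    random order.  Index-wise pairing yields 16 trials per condition; the
    left/right placement of each pair is randomized.  Every image is used
    exactly once.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_cat = _check_composition(images)

    neutral = list(by_cat["neutral"])
    rng.shuffle(neutral)
    list_a = neutral[:48]
    list_b = neutral[48:] + by_cat["positive"] + by_cat["negative"]
    rng.shuffle(list_b)

    trials = []
    for a, b in zip(list_a, list_b):
        if b.category == "neutral":
            condition = "neutral-neutral"
        else:
            condition = f"{b.category}-neutral"
        a_on_left = bool(rng.integers(2))
        left, right = (a, b) if a_on_left else (b, a)
        if condition == "neutral-neutral":
            side = "none"
        else:
            side = "right" if a_on_left else "left"
        trials.append((condition, left.image_id, right.image_id, side))
    rng.shuffle(trials)
    return [
        TrialSpec(trial_id=i + 1, condition=c, left_image=l, right_image=r, emotional_side=s)
        for i, (c, l, r, s) in enumerate(trials)
    ]


def trials_to_frame(trials: Sequence[TrialSpec], subject_id: str | None = None) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "condition": [t.condition for t in trials],
            "emotional_side": [t.emotional_side for t in trials],
            "left_image": [t.left_image for t in trials],
            "right_image": [t.right_image for t in trials],
        }
    )
    if subject_id is not None:
        frame.insert(0, "subject_id", subject_id)
    return frame


# ---------------------------------------------------------------------------
# Stimulus-set validation


@dataclass(frozen=True)
class ContrastResult:
    """A two-category mean difference tested against a pooled error term."""

    dimension: str
    category_a: str
    category_b: str
    estimate: float
    t: float
    df: float
    p_uncorrected: float
    p_bonferroni: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AnovaLine:
    dimension: str
    f: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class StimulusValidationReport:
    anovas: list[AnovaLine]
    contrasts: list[ContrastResult]
    feature_tests: list[AnovaLine]
    low_level_pass: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dimension": c.dimension,
                "contrast": f"{c.category_a} - {c.category_b}",
                "estimate": c.estimate,
                "t": c.t,
                "df": c.df,
                "p_bonferroni": c.p_bonferroni,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
            }
            for c in self.contrasts
        ]
        return pd.DataFrame(rows)


def _oneway_pooled(values: dict[str, np.ndarray]) -> tuple[float, int, int, float, float]:
    """One-way ANOVA with a pooled error term; returns (F, df1, df2, p, mse)."""
    groups = list(values.values())
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_total - k
    mse = ss_within / df2
    if mse == 0.0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df1) / mse
        p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p, float(mse)


_PAIRS = (("positive", "neutral"), ("negative", "neutral"), ("positive", "negative"))


def validate_stimulus_set(images: Sequence[ImageItem], alpha: float = 0.05) -> StimulusValidationReport:
    """Test that normative ratings dissociate the categories on valence and
    arousal while low-level features do not differ.

    Pairwise contrasts use the pooled ANOVA error (df = N - k), Bonferroni
    corrected by 3 per rating dimension.  Low-level features pass when every
    per-feature ANOVA p exceeds ``alpha``.
    """
    by_cat: dict[str, list[ImageItem]] = {c: [] for c in CATEGORIES}
    for im in images:
        by_cat[im.category].append(im)
    for cat, members in by_cat.items():
        if len(members) < 2:
            raise DesignError(f"need at least 2 images per category, {cat} has {len(members)}")

    anovas: list[AnovaLine] = []
    contrasts: list[ContrastResult] = []
    for dim in ("valence", "arousal"):
        vals: dict[str, np.ndarray] = {}
        for cat, members in by_cat.items():
            x = np.array([getattr(im, dim) for im in members], dtype=float)
            if np.isnan(x).any() or any(getattr(im, dim) is None for im in members):
                raise DesignError(f"missing {dim} ratings in category {cat!r}")
            vals[cat] = x
        f, df1, df2, p, mse = _oneway_pooled(vals)
        anovas.append(AnovaLine(dim, f, df1, df2, p))
        for a, b in _PAIRS:
            est = float(vals[a].mean() - vals[b].mean())
            se = np.sqrt(mse * (1 / len(vals[a]) + 1 / len(vals[b])))
            if se == 0.0:
                t = np.inf if est != 0 else 0.0
                p_unc = 0.0 if est != 0 else 1.0
                half = 0.0
            else:
                t = est / se
                p_unc = float(2 * stats.t.sf(abs(t), df2))
                half = float(stats.t.ppf(0.975, df2) * se)
            contrasts.append(
                ContrastResult(
                    dimension=dim,
                    category_a=a,
                    category_b=b,
                    estimate=est,
                    t=float(t),
                    df=df2,
                    p_uncorrected=p_unc,
                    p_bonferroni=min(1.0, 3 * p_unc),
                    ci_low=est - half,
                    ci_high=est + half,
                )
            )

    feature_names = sorted({name for im in images for name in im.low_level})
    feature_tests: list[AnovaLine] = []
    for name in feature_names:
        vals = {
            cat: np.array([im.low_level[name] for im in members if name in im.low_level], dtype=float)
            for cat, members in by_cat.items()
        }
        if any(len(v) < 2 for v in vals.values()):
            continue
        f, df1, df2, p, _ = _oneway_pooled(vals)
        feature_tests.append(AnovaLine(name, f, df1, df2, p))
    low_level_pass = all(line.p > alpha for line in feature_tests)
    return StimulusValidationReport(anovas, contrasts, feature_tests, low_level_pass)


# ---------------------------------------------------------------------------
# Synthetic stimulus sets

#: normative category means used when generating synthetic rating tables
DEFAULT_VALENCE_MEANS = {"positive": 7.58, "neutral": 4.97, "negative": 2.61}
DEFAULT_AROUSAL_MEANS = {"positive": 5.24, "neutral": 4.31, "negative": 4.85}


def synthetic_image_set(
    seed: int | np.random.Generator = 0,
    valence_means: Mapping[str, float] = DEFAULT_VALENCE_MEANS,
    arousal_means: Mapping[str, float] = DEFAULT_AROUSAL_MEANS,
    rating_sd: float = 1.0,
    low_level_features: Sequence[str] = ("color", "luminosity", "contrast", "complexity"),
) -> list[ImageItem]:
    """Generate a synthetic 96-image stimulus set with normative-style ratings.

    Ratings are drawn around the configured category means with a common SD;
    low-level features are drawn from one distribution shared by all
    categories so a valid set passes the low-level checks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    images = []
    for cat, n in SET_COMPOSITION.items():
        val = np.clip(rng.normal(valence_means[cat], rating_sd, n), 1.0, 9.0)
        aro = np.clip(rng.normal(arousal_means[cat], rating_sd, n), 1.0, 9.0)
        feats = {name: rng.normal(0.0, 1.0, n) for name in low_level_features}
        for i in range(n):
            images.append(
                ImageItem(
                    image_id=f"{cat[:3]}{i + 1:02d}",
                    category=cat,
                    valence=float(val[i]),
                    arousal=float(aro[i]),
                    low_level={name: float(feats[name][i]) for name in low_level_features},
                )
            )
    return images
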