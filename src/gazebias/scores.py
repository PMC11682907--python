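"""Derived quantities: emotional bias scores, ERQ scoring, correlation
comparisons, and design power.

The emotional bias score for a trial is the proportion of dwell time spent
on the emotional image of an emotional-neutral pair:
``bias = dwell_emotional / (dwell_emotional + dwell_neutral)``.  Values above
0.5 indicate an attentional bias toward the emotional image.

The ERQ preference score is the mean of the six reappraisal items minus the
mean of the four suppression items (1-7 Likert scales); positive values
indicate a habitual preference for reappraisal over suppression.

``fisher_r_to_z_test`` compares two independent Pearson correlations via the
variance-stabilizing atanh transform; ``rm_interaction_power`` computes the
noncentral-F power of a repeated-measures within-between interaction under
the Cohen noncentrality convention (lambda = f^2 * N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import N_REAPPRAISAL_ITEMS, N_SUPPRESSION_ITEMS

logger = logging.getLogger(__name__)


class ScoreError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Emotional bias


@dataclass(frozen=True)
class BiasObservation:
    subject_id: str
    trial_id: int
    condition: str
    bias: float
    dwell_total_ms: float


def bias_score(
    subject_id: str,
    trial_id: int,
    condition: str,
    dwell_emotional_ms: float,
    dwell_neutral_ms: float,
) -> BiasObservation | None:
    """Proportion of dwell on the emotional image of an emotional-neutral pair.

    Returns None (and logs) when neither image accumulated any dwell.
    Neutral-neutral trials have no emotional image and are rejected.
    """
    if condition not in ("positive-neutral", "negative-neutral"):
        raise ScoreError(f"bias score undefined for condition {condition!r}")
    total = dwell_emotional_ms + dwell_neutral_ms
    if total <= 0:
        logger.info("bias undefined for subject %s trial %s: zero total dwell", subject_id, trial_id)
        return None
    return BiasObservation(subject_id, int(trial_id), condition, dwell_emotional_ms / total, total)


def bias_table(dwell: pd.DataFrame) -> pd.DataFrame:
    """Per-trial bias observations for all emotional-pair trials with
    positive total dwell; zero-dwell trials are dropped and logged."""
    emo = dwell.loc[dwell["condition"].isin(["positive-neutral", "negative-neutral"])].copy()
    total = emo["dwell_emotional_ms"] + emo["dwell_neutral_ms"]
    n_dropped = int((total <= 0).sum())
    if n_dropped:
        logger.info("dropping %d emotional-pair trials with zero total dwell", n_dropped)
    emo = emo.loc[total > 0]
    out = emo[["subject_id", "trial_id", "condition"]].copy()
    out["bias"] = emo["dwell_emotional_ms"] / (emo["dwell_emotional_ms"] + emo["dwell_neutral_ms"])
    out["dwell_total_ms"] = emo["dwell_emotional_ms"] + emo["dwell_neutral_ms"]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ERQ


@dataclass(frozen=True)
class ErqScores:
    subject_id: str
    reappraisal: float
    suppression: float

    @property
    def preference(self) -> float:
        return self.reappraisal - self.suppression


def erq_scores(subject_id: str, erq_items: Sequence[float]) -> ErqScores:
    """Reappraisal (6-item) and suppression (4-item) means and their
    difference, the preference score."""
    items = list(erq_items)
    if len(items) != N_REAPPRAISAL_ITEMS + N_SUPPRESSION_ITEMS:
        raise ScoreError(f"need 10 ERQ items, got {len(items)} for subject {subject_id!r}")
    if any(v is None or not 1 <= v <= 7 for v in items):
        raise ScoreError(f"ERQ items outside 1-7 (or missing) for subject {subject_id!r}: {items}")
    reapp = float(np.mean(items[:N_REAPPRAISAL_ITEMS]))
    supp = float(np.mean(items[N_REAPPRAISAL_ITEMS:]))
    return ErqScores(subject_id, reapp, supp)


def erq_table(participants: pd.DataFrame) -> pd.DataFrame:
    """Per-subject ERQ scores from a participants table with erq_r1..r6 and
    erq_s1..s4 columns."""
    r_cols = [f"erq_r{i + 1}" for i in range(N_REAPPRAISAL_ITEMS)]
    s_cols = [f"erq_s{i + 1}" for i in range(N_SUPPRESSION_ITEMS)]
    missing = [c for c in r_cols + s_cols if c not in participants.columns]
    if missing:
        raise ScoreError(f"participants table missing ERQ columns: {missing}")
    out = participants[["subject_id"]].copy()
    out["reappraisal"] = participants[r_cols].mean(axis=1)
    out["suppression"] = participants[s_cols].mean(axis=1)
    out["erq_preference"] = out["reappraisal"] - out["suppression"]
    return out


# ---------------------------------------------------------------------------
# Correlations


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z_statistic: float
    p_two_tailed: float


def fisher_r_to_z_test(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Compare two independent Pearson correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed normal p.
    """
    for label, n in (("n1", n1), ("n2", n2)):
        if n <= 3:
            raise ScoreError(f"{label}={n} too small: atanh variance undefined for n <= 3")
    for label, r in (("r1", r1), ("r2", r2)):
        if not -1.0 < r < 1.0:
            raise ScoreError(f"{label}={r} must be strictly inside (-1, 1)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return CorrelationComparison(r1, n1, r2, n2, float(z), p)


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-tailed t-test p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ScoreError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ScoreError(f"need n >= 3 observations, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ScoreError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return r, float(2 * stats.t.sf(abs(t), n - 2))


def sd_levels(mean: float, sd: float, multipliers: Sequence[float]) -> list[float]:
    """Moderator levels mean + k*SD for each multiplier k."""
    if sd < 0:
        raise ScoreError(f"sd must be >= 0, got {sd}")
    return [float(mean + k * sd) for k in multipliers]


# ---------------------------------------------------------------------------
# Power


def rm_interaction_power(
    eta_squared: float,
    n_total: int,
    n_groups: int,
    n_measurements: int,
    alpha: float = 0.05,
    noncentrality: str = "cohen",
) -> float:
    """Power of the within-between interaction F test in a repeated-measures
    design with ``n_groups`` groups and ``n_measurements`` measurements.

    Converts eta-squared to Cohen's f^2 = eta^2 / (1 - eta^2) and evaluates
    the noncentral F beyond the central-F critical value with
    df1 = (g-1)(m-1), df2 = (N-g)(m-1).  The default "cohen" convention sets
    lambda = f^2 * N; "multiplied" additionally scales lambda by the number
    of measurements (lambda = f^2 * N * m), the alternative convention some
    power tools expose.
    """
    if not 0.0 < eta_squared < 1.0:
        raise ScoreError(f"eta_squared={eta_squared} must be in (0, 1)")
    if n_groups < 2 or n_measurements < 2:
        raise ScoreError("need at least 2 groups and 2 measurements")
    if n_total <= n_groups:
        raise ScoreError(f"n_total={n_total} must exceed n_groups={n_groups}")
    if not 0.0 < alpha < 1.0:
        raise ScoreError(f"alpha={alpha} outside (0, 1)")
    f2 = eta_squared / (1.0 - eta_squared)
    if noncentrality == "cohen":
        lam = f2 * n_total
    elif noncentrality == "multiplied":
        lam = f2 * n_total * n_measurements
    else:
        raise ScoreError(f"unknown noncentrality convention {noncentrality!r}")
    df1 = (n_groups - 1) * (n_measurements - 1)
    df2 = (n_total - n_groups) * (n_measurements - 1)
    crit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))
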