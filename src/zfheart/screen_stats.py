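"""Screen-level statistics for high-content heart-rate screens.

Per-embryo heart rates are normalized to fold changes against the mean of
the DMSO vehicle controls of the same experiment, the fold changes of
compound-treated embryos are z-scored across the screen (sample SD, n−1),
and hits are flagged against the two-sided standard-normal critical values:
±1.64 for a 90% confidence threshold (fewer false negatives, used for
primary screening) and ±1.96 for 95% (α = 0.05).

A composite 0–5 ToxScore summarizes embryo-level toxicity observations
(pericardial edema, developmental delay, cardiac arrest, significant HR
deviation); embryos recorded as deceased score the maximum of 5.

:func:`validation_correlation` computes the Pearson correlation between two
measurement series after discarding extreme outliers whose residual from the
least-squares regression line exceeds 3 standard deviations — the rule used
when validating automated against manual heart-rate counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Required columns of a screen table.
SCREEN_COLUMNS = ("embryo_id", "compound", "replicate", "experiment_id", "role", "hr_bpm")
CONTROL_ROLE = "control"

#: |z| at or above the 1.64 critical value adds the HR term of the ToxScore.
TOX_HR_Z_THRESHOLD = 1.64
TOX_SCORE_MAX = 5.0


def ci_threshold(ci_level: int) -> float:
    """Two-sided standard-normal critical value for a CI level in percent,
    rounded to two decimals (90 -> 1.64, 95 -> 1.96)."""
    if not 0 < ci_level < 100:
        raise ValueError("ci_level must be a percentage in (0, 100)")
    alpha = 1.0 - ci_level / 100.0
    return round(float(stats.norm.isf(alpha / 2.0)), 2)


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in SCREEN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"screen table is missing columns: {missing}")


def fold_change(table: pd.DataFrame) -> pd.Series:
    """Per-row HR fold change vs the mean of same-experiment DMSO controls."""
    _validate_table(table)
    control_means = (
        table[table["role"] == CONTROL_ROLE].groupby("experiment_id")["hr_bpm"].mean()
    )
    for exp in table["experiment_id"].unique():
        if exp not in control_means.index:
            raise ValueError(f"experiment {exp!r} has no control rows")
        if control_means[exp] == 0:
            raise ValueError(f"experiment {exp!r} has zero control-mean HR")
    return table["hr_bpm"] / table["experiment_id"].map(control_means)


def zscore(values: Sequence[float]) -> np.ndarray:
    """z = (x − mean)/SD with the sample (n−1) standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("z-scoring needs >= 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("z-scoring needs non-zero spread")
    return (values - values.mean()) / sd


def flag_hits(z: Sequence[float], ci_level: int = 90) -> np.ndarray:
    """Boolean hit flags: |z| at or above the two-sided critical value."""
    if ci_level not in (90, 95):
        raise ValueError("ci_level must be 90 or 95")
    z = np.asarray(z, dtype=float)
    return np.abs(z) >= ci_threshold(ci_level)


def add_screen_statistics(table: pd.DataFrame) -> pd.DataFrame:
    """Append fold_change, zscore, hit_90, hit_95 columns to a screen table.

    The z-score population is the fold changes of all compound (non-control)
    rows of the screen; control rows are standardized against the same mean
    and SD so their columns are comparable, but they never define the scale.
    """
    _validate_table(table)
    out = table.copy()
    out["fold_change"] = fold_change(out)
    compound_rows = out["role"] != CONTROL_ROLE
    fc = out.loc[compound_rows, "fold_change"].to_numpy()
    z_compound = zscore(fc)
    mean, sd = fc.mean(), fc.std(ddof=1)
    out["zscore"] = (out["fold_change"] - mean) / sd
    out.loc[compound_rows, "zscore"] = z_compound
    out["hit_90"] = flag_hits(out["zscore"].to_numpy(), 90)
    out["hit_95"] = flag_hits(out["zscore"].to_numpy(), 95)
    return out


@dataclass
class ToxObservation:
    """Per-condition toxicity observation for a group of embryos."""

    n_total: int
    n_pericardial_edema: int = 0
    n_developmental_delay: int = 0
    n_cardiac_arrest: int = 0
    hr_zscore: float = 0.0
    deceased: bool = False

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        for name in ("n_pericardial_edema", "n_developmental_delay", "n_cardiac_arrest"):
            value = getattr(self, name)
            if not 0 <= value <= self.n_total:
                raise ValueError(f"{name} must lie in [0, n_total]")


def tox_score(obs: ToxObservation) -> float:
    """Composite 0–5 toxicity score.

    score = edema fraction + delay fraction + 1[|hr z| ≥ 1.64]
            + 2 x cardiac-arrest fraction, capped at 5.
    Deceased embryos score the maximum of 5 outright.
    """
    if obs.deceased:
        return TOX_SCORE_MAX
    score = (
        obs.n_pericardial_edema / obs.n_total
        + obs.n_developmental_delay / obs.n_total
        + (1.0 if abs(obs.hr_zscore) >= TOX_HR_Z_THRESHOLD else 0.0)
        + 2.0 * obs.n_cardiac_arrest / obs.n_total
    )
    return min(TOX_SCORE_MAX, score)


def validation_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, int]:
    """Pearson r between two series after 3-SD regression-outlier removal.

    A least-squares line of y on x is fitted, points whose residual exceeds
    three residual standard deviations are excluded, and Pearson r is
    computed on the remainder.  Returns (r, n_excluded).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need >= 3 paired points")
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    sd = residuals.std(ddof=1)
    # guard against float jitter on (near-)perfectly collinear data
    negligible = sd <= 1e-9 * max(1.0, float(np.ptp(y)))
    keep = np.ones_like(x, dtype=bool) if negligible else np.abs(residuals) <= 3.0 * sd
    if keep.sum() < 3:
        raise ValueError("fewer than 3 points remain after outlier exclusion")
    r = float(stats.pearsonr(x[keep], y[keep])[0])
    return r, int((~keep).sum())
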