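"""Frequency-dependent prey preference from two-prey trials.

Quantifies selectivity with Manly's index adjusted for non-replacement of
prey.  For two prey types (invader i, native n) with starting counts
``n_i0, n_n0`` and kills ``r_i, r_n``:

    alpha_i = ln((n_i0 - r_i) / n_i0) / [ ln((n_i0 - r_i)/n_i0) + ln((n_n0 - r_n)/n_n0) ]

Indices range over [0, 1]; 0.5 is neutral, values above 0.5 indicate
preference for the invader at the offered availability.  Because the
estimator degenerates when a prey type is fully consumed, extreme trials
use the analytic limit (complete depletion of one type pins alpha at that
type's extreme) or a half-count continuity correction when both types are
wiped out.  Prior to inference, indices are shrunk off the boundary with
the standard extreme-value transformation

    alpha_t = (alpha_i * (n - 1) + 0.5) / n

with n the number of indices entering the analysis.

A lack of prey switching shows up as preference that does not track
availability: the null (no-preference) expectation is that the proportion
of a prey type in the diet equals its proportion offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "manly_alpha",
    "manly_alpha_trial",
    "transform_alpha",
    "null_expectation",
    "PreferenceSummary",
    "summarize_preferences",
    "preference_bootstrap_test",
    "ZeroConsumptionError",
]


class ZeroConsumptionError(ValueError):
    """Trial with no prey of either type consumed: the index is undefined."""


def manly_alpha(n_i0: int, r_i: int, n_n0: int, r_n: int) -> float:
    """Manly selectivity index for the invader, non-replacement form.

    Raises :class:`ZeroConsumptionError` when nothing was eaten.  Complete
    depletion of exactly one prey type returns that type's analytic limit
    (1.0 if the invader was wiped out, 0.0 if the native was); complete
    depletion of both applies a half-count continuity correction so the
    estimator stays total on extreme but observable data.
    """
    if not (0 <= r_i <= n_i0 and 0 <= r_n <= n_n0):
        raise ValueError("kills must lie within [0, initial count] for each prey type")
    if n_i0 == 0 or n_n0 == 0:
        raise ValueError("both prey types must be offered (initial counts > 0)")
    if r_i + r_n == 0:
        raise ZeroConsumptionError("no prey consumed; selectivity undefined")

    full_i = r_i == n_i0
    full_n = r_n == n_n0
    if full_i and full_n:
        ri, rn = n_i0 - 0.5, n_n0 - 0.5
    elif full_i:
        return 1.0
    elif full_n:
        return 0.0
    else:
        ri, rn = r_i, r_n
    log_i = math.log((n_i0 - ri) / n_i0)
    log_n = math.log((n_n0 - rn) / n_n0)
    return log_i / (log_i + log_n)


def manly_alpha_trial(trial) -> float:
    """Index for one trial record (mapping or row with the schema columns)."""
    return manly_alpha(
        int(trial["n_invader_0"]),
        int(trial["eaten_invader"]),
        int(trial["n_native_0"]),
        int(trial["eaten_native"]),
    )


def transform_alpha(alpha_i: float, n: int) -> float:
    """Extreme-value transformation pulling {0, 1} strictly inside (0, 1)."""
    if not 0 <= alpha_i <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    return (alpha_i * (n - 1) + 0.5) / n


def null_expectation(proportion_available: float) -> float:
    """Expected diet proportion under no preference: tracks availability."""
    p = float(proportion_available)
    if not 0 <= p <= 1:
        raise ValueError("proportion must lie in [0, 1]")
    return p


@dataclass
class PreferenceSummary:
    """Per-availability and overall Manly indices for one predator."""

    predator: str
    table: pd.DataFrame  # prop_invader, mean_alpha, se_alpha, n_trials, mean_alpha_t
    overall_mean_alpha: float
    n_excluded: int

    def __post_init__(self):
        if not np.isclose(
            self.overall_mean_alpha, self.table["mean_alpha"].mean(), equal_nan=True
        ):
            raise ValueError("overall mean must be the unweighted mean of per-proportion means")


def _trial_alphas(group: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Per-trial alphas for one group; zero-consumption trials dropped."""
    alphas = []
    excluded = 0
    for _, row in group.iterrows():
        try:
            alphas.append(manly_alpha_trial(row))
        except ZeroConsumptionError:
            excluded += 1
    return np.asarray(alphas), excluded


def summarize_preferences(
    switch_trials: pd.DataFrame, logger=None
) -> dict[str, PreferenceSummary]:
    """Summarise selectivity per predator and availability proportion.

    Returns one :class:`PreferenceSummary` per predator.  Per proportion:
    the arithmetic mean and standard error of per-trial raw alphas (SE 0
    by convention for a single trial).  The overall mean preference is the
    unweighted mean of the per-proportion means, so every availability
    level contributes equally regardless of exclusions.  Transformed means
    use n = number of valid trials for the predator.  Zero-consumption
    trials are excluded and counted (and reported to ``logger`` if given).
    """
    trials = switch_trials[switch_trials.get("is_control", 0) == 0]
    summaries: dict[str, PreferenceSummary] = {}
    for predator, pred_grp in trials.groupby("predator", sort=True):
        n_valid_total = 0
        per_prop = []
        n_excluded = 0
        for prop, grp in pred_grp.groupby("prop_invader", sort=True):
            alphas, excluded = _trial_alphas(grp)
            n_excluded += excluded
            if alphas.size == 0:
                if logger is not None:
                    logger.warning(
                        "predator %s, availability %.2f: no valid trials, group skipped",
                        predator,
                        prop,
                    )
                continue
            se = float(alphas.std(ddof=1) / math.sqrt(alphas.size)) if alphas.size > 1 else 0.0
            per_prop.append(
                {
                    "prop_invader": float(prop),
                    "mean_alpha": float(alphas.mean()),
                    "se_alpha": se,
                    "n_trials": int(alphas.size),
                }
            )
            n_valid_total += alphas.size
        if not per_prop:
            if logger is not None:
                logger.warning("predator %s: no valid switching trials at all", predator)
            continue
        if n_excluded and logger is not None:
            logger.info(
                "predator %s: excluded %d zero-consumption trial(s)", predator, n_excluded
            )
        table = pd.DataFrame(per_prop)
        n_t = max(n_valid_total, 1)
        table["mean_alpha_t"] = [transform_alpha(v, n_t) for v in table["mean_alpha"]]
        summaries[predator] = PreferenceSummary(
            predator=predator,
            table=table,
            overall_mean_alpha=float(table["mean_alpha"].mean()),
            n_excluded=n_excluded,
        )
    return summaries


@dataclass(frozen=True)
class PreferenceTestResult:
    predator: str
    n_trials: int
    mean_alpha_t: float
    ci: tuple[float, float] | None
    prefers_invader: bool
    conclusive: bool


def preference_bootstrap_test(
    switch_trials: pd.DataFrame,
    null: float = 0.5,
    n_boot: int = 2000,
    conf: float = 0.95,
    seed=None,
) -> dict[str, PreferenceTestResult]:
    """Percentile-bootstrap test of invader preference against neutrality.

    Per predator: per-trial alphas (extreme-value transformed with the
    number of valid trials as n) are resampled with replacement ``n_boot``
    times; the predator is flagged as preferring the invader when the
    whole CI of the mean transformed index lies above ``null``.  Groups
    with fewer than two valid trials return an inconclusive result rather
    than raising.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    trials = switch_trials[switch_trials.get("is_control", 0) == 0]
    out: dict[str, PreferenceTestResult] = {}
    for predator, grp in trials.groupby("predator", sort=True):
        alphas, _ = _trial_alphas(grp)
        n = alphas.size
        if n < 2:
            mean_t = transform_alpha(float(alphas.mean()), max(n, 1)) if n else float("nan")
            out[predator] = PreferenceTestResult(
                predator, n, mean_t, None, prefers_invader=False, conclusive=False
            )
            continue
        alpha_t = np.array([transform_alpha(v, n) for v in alphas])
        means = np.array(
            [alpha_t[rng.integers(0, n, size=n)].mean() for _ in range(n_boot)]
        )
        lo_q, hi_q = 100 * (1 - conf) / 2, 100 * (1 + conf) / 2
        ci = (float(np.percentile(means, lo_q)), float(np.percentile(means, hi_q)))
        out[predator] = PreferenceTestResult(
            predator,
            n,
            float(alpha_t.mean()),
            ci,
            prefers_invader=ci[0] > null,
            conclusive=True,
        )
    return out
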