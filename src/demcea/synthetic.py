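"""Synthetic data generators emulating the model's two source datasets.

Neither source dataset is publicly deposited, so the pipeline is exercised
end to end on generated stand-ins:

* a trial-like end-of-study cohort (dependence state, a BADLS score drawn
  within the state's band, and a noisy utility index for alive subjects),
  whose state distribution and state-wise utility means match the model's
  entry parameters; and
* a longitudinal BADLS panel whose latent dependence state evolves in
  3-month steps under known transition probabilities, observed at irregular
  visit times with dropout -- the structure the progression estimator is
  designed for.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .derivation import PanelDataset, badls_range
from .engine import build_transition_matrix
from .parameters import (
    ALIVE_LEVELS,
    STATE_ORDER,
    UTILITY_CEIL,
    UTILITY_FLOOR,
    DependenceLevel,
    ParameterError,
    TransitionModel,
)

__all__ = ["TrialCohortSpec", "PanelSpec", "generate_trial_cohort", "generate_panel"]


@dataclass(frozen=True)
class TrialCohortSpec:
    """End-of-study trial cohort generator settings.

    Defaults mirror the trial the model's entry parameters derive from:
    354 randomised participants, end-of-study distribution 60/24/10/6
    (low/moderate/high/dead) and state utility means 0.788/0.750/0.714.
    The utility dispersion (sd 0.15, truncated to the valid index range) is
    a generator choice, not a source value.
    """

    n_subjects: int = 354
    target_distribution: tuple[float, float, float, float] = (0.60, 0.24, 0.10, 0.06)
    utility_means: tuple[float, float, float] = (0.788, 0.750, 0.714)
    utility_sd: float = 0.15
    allocation: str = "multinomial"  # or "exact" (largest-remainder quotas)
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        t = np.asarray(self.target_distribution)
        if abs(t.sum() - 1.0) > 1e-9 or (t < 0).any():
            errs.append("target distribution must be non-negative and sum to 1")
        if self.n_subjects < 4:
            errs.append("n_subjects must be >= 4")
        if self.allocation not in ("multinomial", "exact"):
            errs.append(f"unknown allocation mode {self.allocation!r}")
        if self.utility_sd < 0:
            errs.append("utility_sd must be >= 0")
        return errs


@dataclass(frozen=True)
class PanelSpec:
    """Longitudinal BADLS panel generator settings.

    Defaults mirror the source panel's scale: 565 subjects followed up to 55
    months at varying intervals with incomplete attendance.  The visit
    schedule (mean interval 6 months, +/-2 months uniform jitter) and the
    per-visit dropout probability are generator choices; the source's true
    visit-interval distribution is not published.
    """

    n_subjects: int = 565
    transitions: TransitionModel = field(
        default_factory=lambda: TransitionModel(0.15, 0.07, 0.02, 0.038, 0.05)
    )
    mean_interval_months: float = 6.0
    interval_jitter_months: float = 2.0
    max_follow_up_months: float = 55.0
    dropout_per_visit: float = 0.05
    initial_distribution: tuple[float, float, float] = (0.70, 0.25, 0.05)
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if self.mean_interval_months - self.interval_jitter_months <= 0:
            errs.append("visit intervals must stay > 0 after jitter")
        if not (0.0 <= self.dropout_per_visit <= 1.0):
            errs.append("dropout_per_visit must be in [0, 1]")
        init = np.asarray(self.initial_distribution)
        if abs(init.sum() - 1.0) > 1e-9 or (init < 0).any():
            errs.append("initial alive-state distribution must sum to 1")
        errs += self.transitions.validate()
        return errs


def _draw_badls(rng: np.random.Generator, level: DependenceLevel, size=None):
    lo, hi = badls_range(level)
    return rng.integers(lo, hi + 1, size=size)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Truncated-Gaussian draws on the valid utility index range.

    The underlying location is shifted so that the *truncated* distribution's
    mean equals ``mean`` (plain truncation would drag state means below their
    targets, since the ceiling at 1 clips far more mass than the floor).
    """
    if sd == 0:
        return np.full(size, mean)

    def trunc_mean(loc: float) -> float:
        a, b = (UTILITY_FLOOR - loc) / sd, (UTILITY_CEIL - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    loc = brentq(lambda m: trunc_mean(m) - mean, UTILITY_FLOOR, UTILITY_CEIL + 5 * sd)
    a, b = (UTILITY_FLOOR - loc) / sd, (UTILITY_CEIL - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_trial_cohort(spec: TrialCohortSpec) -> pd.DataFrame:
    """Generate an end-of-study cohort table.

    Columns: ``subject``, ``state`` (level name, including ``dead``),
    ``badls`` (empty for dead subjects), ``utility`` (empty for dead
    subjects).  Realized state proportions converge to the target as the
    cohort grows (exactly, under ``allocation='exact'``), and every BADLS
    score lies within its state's band.
    """
    errs = spec.validate()
    if errs:
        raise ParameterError(errs)
    rng = np.random.default_rng(spec.seed)
    target = np.asarray(spec.target_distribution)
    n = spec.n_subjects
    if spec.allocation == "exact":
        quotas = np.floor(target * n).astype(int)
        remainder = target * n - quotas
        for i in np.argsort(-remainder)[: n - quotas.sum()]:
            quotas[i] += 1
        states = np.repeat(np.arange(4), quotas)
    else:
        states = rng.choice(4, size=n, p=target)

    means = dict(zip(ALIVE_LEVELS, spec.utility_means))
    rows = []
    badls = np.full(n, np.nan)
    utility = np.full(n, np.nan)
    for i, level in enumerate(STATE_ORDER):
        mask = states == i
        if level.is_alive and mask.any():
            badls[mask] = _draw_badls(rng, level, int(mask.sum()))
            utility[mask] = _truncated_normal(
                rng, means[level], spec.utility_sd, int(mask.sum())
            )
    return pd.DataFrame(
        {
            "subject": np.arange(1, n + 1),
            "state": [STATE_ORDER[s].value for s in states],
            "badls": badls,
            "utility": utility,
        }
    )


def trial_cohort_to_utility_records(cohort: pd.DataFrame) -> pd.DataFrame:
    """Alive rows of a generated cohort as utility records for estimation."""
    alive = cohort[cohort["state"] != DependenceLevel.DEAD.value]
    return alive[["subject", "state", "utility"]].reset_index(drop=True)


def generate_panel(spec: PanelSpec) -> PanelDataset:
    """Generate an irregular longitudinal BADLS panel.

    Each subject's latent state evolves on the model's own 3-month clock
    (forward-only, with state-specific death probabilities); visits sample
    the latent state at jittered times rounded to whole months, and each
    emitted score is drawn uniformly within the current state's band.
    Follow-up ends at death, dropout, or the maximum follow-up time.
    """
    errs = spec.validate()
    if errs:
        raise ParameterError(errs)
    rng = np.random.default_rng(spec.seed)
    matrix = build_transition_matrix(spec.transitions)
    cum = np.cumsum(matrix, axis=1)
    n_steps = int(np.ceil(spec.max_follow_up_months / 3.0)) + 1

    records = []
    for subject in range(1, spec.n_subjects + 1):
        # latent 3-month trajectory
        state = int(rng.choice(3, p=np.asarray(spec.initial_distribution)))
        path = [state]
        for _ in range(n_steps):
            if state == 3:
                path.append(3)
                continue
            state = int(np.searchsorted(cum[state], rng.random(), side="right"))
            path.append(state)
        # irregular visit schedule
        t = 0.0
        while t <= spec.max_follow_up_months:
            month = int(round(t))
            latent = path[min(month // 3, n_steps)]
            if latent == 3:
                break  # died before this visit; no further records
            records.append(
                {
                    "subject": subject,
                    "time_months": month,
                    "badls": int(_draw_badls(rng, STATE_ORDER[latent])),
                }
            )
            if rng.random() < spec.dropout_per_visit:
                break
            jitter = rng.uniform(-spec.interval_jitter_months, spec.interval_jitter_months)
            step = max(1.0, spec.mean_interval_months + jitter)
            t += step
    df = pd.DataFrame(records, columns=["subject", "time_months", "badls"])
    df = df.drop_duplicates(subset=["subject", "time_months"])
    return PanelDataset(df)


def write_with_metadata(df: pd.DataFrame, path: str | Path, spec) -> None:
    """Write a generated dataset as CSV with a JSON sidecar echoing its spec."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta = asdict(spec)
    meta["generator"] = type(spec).__name__
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
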