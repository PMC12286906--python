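"""Parameter derivation from source data.

Four derivation stages feed the cohort model:

* BADLS total scores (0-60) are banded into dependence levels
  (low < 15, moderate 15-29, high >= 30).
* Per-cycle progression probabilities are estimated from an irregularly
  sampled longitudinal BADLS panel.  Consecutive within-subject assessment
  pairs are stratified by interval length; each stratum's empirical move
  proportion is rescaled to the 3-month cycle under a constant-hazard
  assumption, and strata are combined by an exposure-weighted average.
* Interval survival probabilities from published mortality studies are
  converted to per-cycle death probabilities, again under constant hazard.
* State utility values are arithmetic means of individual utility indices
  grouped by dependence level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    ALIVE_LEVELS,
    DependenceLevel,
    ParameterError,
    UtilitySet,
)

__all__ = [
    "BADLS_MIN",
    "BADLS_MAX",
    "categorize_badls",
    "death_prob_per_cycle",
    "survival_from_cycle_prob",
    "PanelDataset",
    "TransitionEstimate",
    "estimate_transitions",
    "estimate_state_utilities",
]

BADLS_MIN, BADLS_MAX = 0, 60
_LOW_UPPER = 14   # low dependence: scores 0..14
_MOD_UPPER = 29   # moderate: 15..29; high: 30+

PANEL_COLUMNS = ("subject", "time_months", "badls")
UTILITY_COLUMNS = ("subject", "state", "utility")


def categorize_badls(score) -> DependenceLevel:
    """Band a BADLS total score into a dependence level.

    Partition of [0, 60]: low for 0-14, moderate for 15-29, high for 30-60.
    Non-integer or out-of-range scores are rejected.
    """
    s = float(score)
    if not s.is_integer():
        raise ParameterError([f"BADLS score must be an integer (got {score!r})"])
    s = int(s)
    if not (BADLS_MIN <= s <= BADLS_MAX):
        raise ParameterError([f"BADLS score out of range [0, 60] (got {s})"])
    if s <= _LOW_UPPER:
        return DependenceLevel.LOW
    if s <= _MOD_UPPER:
        return DependenceLevel.MODERATE
    return DependenceLevel.HIGH


def badls_range(level: DependenceLevel) -> tuple[int, int]:
    """Inclusive score range emitting the given dependence level."""
    return {
        DependenceLevel.LOW: (BADLS_MIN, _LOW_UPPER),
        DependenceLevel.MODERATE: (_LOW_UPPER + 1, _MOD_UPPER),
        DependenceLevel.HIGH: (_MOD_UPPER + 1, BADLS_MAX),
    }[level]


def death_prob_per_cycle(
    survival_prob: float, interval_years: float, cycle_length_years: float = 0.25
) -> float:
    """Convert an interval survival probability to a per-cycle death probability.

    Assumes a constant hazard over the source interval:
    ``p_cycle = 1 - survival_prob ** (cycle_length / interval)``.
    """
    if interval_years <= 0 or cycle_length_years <= 0:
        raise ParameterError(["durations must be > 0"])
    if not (0.0 < survival_prob <= 1.0):
        raise ParameterError(
            [f"survival probability must be in (0, 1] (got {survival_prob!r})"]
        )
    return 1.0 - survival_prob ** (cycle_length_years / interval_years)


def survival_from_cycle_prob(
    p_cycle: float, interval_years: float, cycle_length_years: float = 0.25
) -> float:
    """Inverse of :func:`death_prob_per_cycle`: interval survival from a per-cycle probability."""
    if interval_years <= 0 or cycle_length_years <= 0:
        raise ParameterError(["durations must be > 0"])
    if not (0.0 <= p_cycle < 1.0):
        raise ParameterError([f"per-cycle probability must be in [0, 1) (got {p_cycle!r})"])
    return (1.0 - p_cycle) ** (interval_years / cycle_length_years)


@dataclass(frozen=True)
class PanelDataset:
    """Longitudinal BADLS panel: (subject, assessment time in months, score).

    Times are months from baseline, non-negative and strictly increasing
    within subject; duplicate (subject, time) pairs are rejected.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ParameterError([f"panel missing column(s) {missing}"])
        if (df["time_months"] < 0).any():
            raise ParameterError(["panel has negative assessment times"])
        if df.duplicated(subset=["subject", "time_months"]).any():
            raise ParameterError(["panel has duplicate (subject, time) pairs"])
        grp = df.sort_values(["subject", "time_months"]).groupby("subject")["time_months"]
        if (grp.diff().dropna() <= 0).any():
            raise ParameterError(["assessment times must be strictly increasing per subject"])
        df["badls"].map(categorize_badls)  # validates every score

    @classmethod
    def from_csv(cls, path: str | Path) -> "PanelDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class StratumEstimate:
    """Per interval-length stratum: empirical move proportion and its rescaling."""

    interval_months: int
    n_pairs: int
    n_events: int
    p_interval: float
    p_cycle: float


@dataclass
class TransitionEstimate:
    """Progression-probability estimates with auditable pair counts."""

    p_low_to_mod: float
    p_mod_to_high: float
    strata_low: list[StratumEstimate] = field(default_factory=list)
    strata_mod: list[StratumEstimate] = field(default_factory=list)
    n_backward_moves: int = 0
    n_skipped_state: int = 0

    def to_config_fragment(self) -> dict:
        """Fragment mergeable into a model configuration's ``transitions`` section."""
        return {
            "transitions": {
                "low_to_moderate": self.p_low_to_mod,
                "moderate_to_high": self.p_mod_to_high,
            }
        }


def _estimate_for_state(
    pairs: pd.DataFrame, cycle_length_months: float
) -> tuple[float, list[StratumEstimate]]:
    strata = []
    for interval, grp in pairs.groupby("interval_rounded"):
        n = len(grp)
        events = int(grp["event"].sum())
        p_int = events / n
        if p_int >= 1.0:
            p_cyc = 1.0
        else:
            p_cyc = 1.0 - (1.0 - p_int) ** (cycle_length_months / interval)
        strata.append(
            StratumEstimate(
                interval_months=int(interval),
                n_pairs=n,
                n_events=events,
                p_interval=p_int,
                p_cycle=p_cyc,
            )
        )
    # exposure weights: pairs x interval length (total observed person-months)
    weights = np.array([s.n_pairs * s.interval_months for s in strata], dtype=float)
    values = np.array([s.p_cycle for s in strata])
    return float(np.average(values, weights=weights)), strata


def estimate_transitions(
    panel: PanelDataset, cycle_length_months: float = 3.0
) -> TransitionEstimate:
    """Estimate per-cycle progression probabilities from an irregular panel.

    For each consecutive within-subject assessment pair the start state is
    classified from the first score; a move to any higher category is a
    transition event (a two-level jump counts as an event for the start
    state's stratum and is tallied separately).  Observed backward moves are
    counted as non-transitions, consistent with the model's irreversible
    structure, and reported.  Pairs are stratified by interval length rounded
    to the nearest month; each stratum's empirical proportion is rescaled to
    the cycle length under constant hazard and strata are combined by
    exposure weighting.
    """
    df = panel.data.sort_values(["subject", "time_months"]).copy()
    df["state"] = df["badls"].map(categorize_badls)
    df["next_state"] = df.groupby("subject")["state"].shift(-1)
    df["next_time"] = df.groupby("subject")["time_months"].shift(-1)
    pairs = df.dropna(subset=["next_time"]).copy()
    if pairs.empty:
        raise ParameterError(["no eligible assessment pairs in panel"])
    pairs["interval_rounded"] = (
        (pairs["next_time"] - pairs["time_months"]).round().astype(int).clip(lower=1)
    )
    order = {
        DependenceLevel.LOW: 0,
        DependenceLevel.MODERATE: 1,
        DependenceLevel.HIGH: 2,
    }
    pairs["start_rank"] = pairs["state"].map(order)
    pairs["end_rank"] = pairs["next_state"].map(order)
    pairs["event"] = pairs["end_rank"] > pairs["start_rank"]

    n_backward = int((pairs["end_rank"] < pairs["start_rank"]).sum())
    n_skipped = int(
        (
            (pairs["state"] == DependenceLevel.LOW)
            & (pairs["next_state"] == DependenceLevel.HIGH)
        ).sum()
    )

    results = {}
    strata_by_state = {}
    for level in (DependenceLevel.LOW, DependenceLevel.MODERATE):
        sub = pairs[pairs["state"] == level]
        if sub.empty:
            warnings.warn(
                f"no eligible pairs starting in {level.value}; estimate omitted",
                stacklevel=2,
            )
            results[level] = np.nan
            strata_by_state[level] = []
            continue
        p, strata = _estimate_for_state(sub, cycle_length_months)
        results[level] = p
        strata_by_state[level] = strata
    if all(np.isnan(v) for v in results.values()):
        raise ParameterError(["no eligible pairs for any progression stratum"])

    return TransitionEstimate(
        p_low_to_mod=results[DependenceLevel.LOW],
        p_mod_to_high=results[DependenceLevel.MODERATE],
        strata_low=strata_by_state[DependenceLevel.LOW],
        strata_mod=strata_by_state[DependenceLevel.MODERATE],
        n_backward_moves=n_backward,
        n_skipped_state=n_skipped,
    )


def estimate_state_utilities(records: pd.DataFrame) -> UtilitySet:
    """Arithmetic mean utility index per alive dependence state.

    ``records`` needs columns ``subject``, ``state`` (level names) and
    ``utility``.  Every alive state must have at least one record.
    """
    missing = [c for c in UTILITY_COLUMNS if c not in records.columns]
    if missing:
        raise ParameterError([f"utility records missing column(s) {missing}"])
    states = records["state"].map(
        lambda s: s if isinstance(s, DependenceLevel) else DependenceLevel(str(s))
    )
    if (states == DependenceLevel.DEAD).any():
        raise ParameterError(["utility records must not include the dead state"])
    values = {}
    for level in ALIVE_LEVELS:
        sub = records.loc[states == level, "utility"]
        if sub.empty:
            raise ParameterError([f"no utility records for state {level.value}"])
        values[level] = float(sub.mean())
    values[DependenceLevel.DEAD] = 0.0
    return UtilitySet(values=values)
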