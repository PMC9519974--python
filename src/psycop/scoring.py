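"""Derived behavioral variables from operant event streams and raw trial data.

Every score here reduces a per-mouse record (corner visits, arm entries,
startle amplitudes, tracked summaries) to one number of the profiling
battery.  The functions are deliberately small and side-effect free; the
assembly into the mice x variables matrix lives in :func:`build_variable_matrix`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SprtConfig",
    "VARIABLE_ROSTER",
    "DEFAULT_RDOC_MAP",
    "RDOC_DOMAINS",
    "preference_score",
    "place_preference_score",
    "sprt_trials_to_criterion",
    "serial_reversal_auc",
    "success_rate",
    "rewarded_trial_rate",
    "mean_phase_rate",
    "spontaneous_alternation_rate",
    "instantaneous_frequency",
    "circadian_profile",
    "nocturnality_score",
    "ppi_percent",
    "trials_from_events",
    "build_variable_matrix",
    "zscore_profile",
]

#: The 19-variable battery, grouped by RDoC domain in display order.
VARIABLE_ROSTER = [
    "Alt", "Chc", "RvL", "SrL", "Cue", "Ctx",
    "PpiBs", "Ppi70", "Ppi75", "Ppi80",
    "ScP", "PcP",
    "Rot", "CtrT", "BsF", "Imm",
    "Act", "Nct", "MnSp",
]

RDOC_DOMAINS = (
    "cognitive systems",
    "sensorimotor systems",
    "positive valence",
    "negative valence",
    "arousal/regulatory",
    "social processes",
)

#: Default variable -> RDoC domain assignment used throughout the pipeline.
DEFAULT_RDOC_MAP = {
    "Alt": "cognitive systems",
    "RvL": "cognitive systems",
    "SrL": "cognitive systems",
    "Cue": "cognitive systems",
    "Ctx": "cognitive systems",
    "PpiBs": "sensorimotor systems",
    "Ppi70": "sensorimotor systems",
    "Ppi75": "sensorimotor systems",
    "Ppi80": "sensorimotor systems",
    "ScP": "positive valence",
    "PcP": "positive valence",
    "Rot": "positive valence",
    "CtrT": "negative valence",
    "BsF": "negative valence",
    "Imm": "negative valence",
    "Act": "arousal/regulatory",
    "Nct": "arousal/regulatory",
    "Chc": "arousal/regulatory",
    "MnSp": "arousal/regulatory",
}


@dataclass(frozen=True)
class SprtConfig:
    """Sequential probability ratio test parameters for the learning criterion.

    ``p0`` is the chance success probability (0.25 for one correct corner out
    of four), ``p1`` the success probability of a learned animal.  The
    criterion is one-sided acceptance of H1 (learned): the cumulative
    log-likelihood ratio must reach ``ln((1 - beta) / alpha)``.
    """

    p0: float = 0.25
    p1: float = 0.75
    alpha: float = 0.05
    beta: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < self.p1 < 1.0):
            raise ValueError(f"require 0 < p0 < p1 < 1, got p0={self.p0}, p1={self.p1}")
        if not (0.0 < self.alpha < 0.5 and 0.0 < self.beta < 0.5):
            raise ValueError(f"alpha/beta must lie in (0, 0.5), got {self.alpha}, {self.beta}")

    @property
    def llr_correct(self) -> float:
        return math.log(self.p1 / self.p0)

    @property
    def llr_incorrect(self) -> float:
        return math.log((1.0 - self.p1) / (1.0 - self.p0))

    @property
    def upper_boundary(self) -> float:
        return math.log((1.0 - self.beta) / self.alpha)


def preference_score(a: float, b: float) -> float:
    """Preference score (A - B)/(A + B) in [-1, 1].

    +1 means exclusive preference for option A, -1 absolute avoidance.
    With no observations at all the score is undefined and NaN is returned
    (a missing value, deliberately not zero).
    """
    total = a + b
    if total <= 0:
        return float("nan")
    return (a - b) / total


def place_preference_score(correct: float, incorrect: float,
                           n_incorrect_options: int = 3) -> float:
    """Chance-weighted corner preference.

    Incorrect visits are down-weighted by the number of incorrect corners
    (three wrong corners for one correct one), so a mouse choosing corners
    uniformly at random scores 0 in expectation:
    ``(A - B/3) / (A + B/3)``.
    """
    if correct + incorrect <= 0:
        return float("nan")
    b = incorrect / n_incorrect_options
    return (correct - b) / (correct + b)


def sprt_trials_to_criterion(correct: Sequence[bool] | np.ndarray,
                             cfg: SprtConfig = SprtConfig()) -> tuple[int, bool]:
    """Trials needed to reach the SPRT learning criterion.

    Accumulates the Bernoulli log-likelihood ratio of "learned" (p1) against
    chance (p0) over the trial sequence and returns the first trial index
    (1-based count) at which the H1 boundary ``ln((1-beta)/alpha)`` is
    reached.  The lower (H0) boundary is ignored: the criterion is one-sided,
    a mouse can only *reach* the criterion or run out of trials.

    Returns ``(n_trials, censored)``; if the boundary is never crossed the
    sequence length is returned with ``censored=True``.
    """
    x = np.asarray(correct, dtype=bool)
    if x.size == 0:
        raise ValueError("empty trial sequence")
    inc = np.where(x, cfg.llr_correct, cfg.llr_incorrect)
    llr = np.cumsum(inc)
    hits = np.nonzero(llr >= cfg.upper_boundary)[0]
    if hits.size:
        return int(hits[0]) + 1, False
    return int(x.size), True


def serial_reversal_auc(criteria: Sequence[float]) -> float:
    """Area under the learning curve across serial reversal phases.

    Sum of the rolling mean of neighboring per-phase trials-to-criterion,
    i.e. the trapezoidal sum ``sum((c_i + c_{i+1})/2)``.  Lower values mean
    faster re-learning.  Order-sensitive for three or more phases.
    """
    c = np.asarray(criteria, dtype=float)
    if c.size < 2:
        raise ValueError("serial reversal AUC needs at least two phases")
    return float(np.sum((c[:-1] + c[1:]) / 2.0))


def success_rate(correct: Sequence[bool]) -> float:
    """Fraction of correct trials in one learning phase; NaN if no trials."""
    x = np.asarray(correct, dtype=bool)
    if x.size == 0:
        return float("nan")
    return float(x.mean())


def rewarded_trial_rate(rewarded: Sequence[bool]) -> float:
    """Fraction of trials with licks (the animal actually drank)."""
    x = np.asarray(rewarded, dtype=bool)
    if x.size == 0:
        return float("nan")
    return float(x.mean())


def mean_phase_rate(per_phase_rates: Iterable[float]) -> float:
    """Mean across per-phase fractions (not the pooled fraction)."""
    r = np.asarray(list(per_phase_rates), dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        return float("nan")
    return float(r.mean())


def spontaneous_alternation_rate(arms: Sequence[str]) -> float:
    """Y-maze spontaneous alternation rate.

    A sliding window of three consecutive arm entries counts as an
    alternation iff all three arms are distinct (full sequence without
    repetition, e.g. A-B-C).  Rate = alternations / (entries - 2).
    """
    arms = list(arms)
    if len(arms) < 3:
        return float("nan")
    wins = [len({arms[i], arms[i + 1], arms[i + 2]}) == 3 for i in range(len(arms) - 2)]
    return float(np.mean(wins))


def instantaneous_frequency(visit_starts_s: Sequence[float],
                            method: str = "instantaneous") -> float:
    """Mean instantaneous visit frequency in 1/h.

    Each visit after the first carries an instantaneous frequency equal to
    the reciprocal of the interval to the previous visit; the activity value
    is the mean of these (a harmonic-type statistic, distinct from
    1/mean-interval).  ``method="counts"`` switches to plain visits per hour
    over the observed span.  Needs at least two visits, else NaN.
    """
    t = np.sort(np.asarray(visit_starts_s, dtype=float))
    if t.size < 2:
        return float("nan")
    if method == "counts":
        span_h = (t[-1] - t[0]) / 3600.0
        return float((t.size - 1) / span_h) if span_h > 0 else float("nan")
    if method != "instantaneous":
        raise ValueError(f"unknown method {method!r}")
    dt_h = np.diff(t) / 3600.0
    return float(np.mean(1.0 / dt_h))


@dataclass(frozen=True)
class LightCycle:
    """Light schedule anchored to the experiment clock (t=0 is lights-on)."""

    light_on: float = 0.0   # clock hour lights go on
    light_hours: float = 12.0

    def is_dark(self, t_s: np.ndarray | float) -> np.ndarray | bool:
        clock = (np.asarray(t_s, dtype=float) / 3600.0 - self.light_on) % 24.0
        return clock >= self.light_hours


def circadian_profile(visit_starts_s: Sequence[float],
                      light_cycle: LightCycle = LightCycle()) -> np.ndarray:
    """24 x 1-h binned mean instantaneous visit frequency (1/h).

    Visits are binned by clock hour of their start time; each bin holds the
    mean instantaneous frequency of the visits falling in it, pooled across
    days.  Empty bins are NaN.
    """
    t = np.sort(np.asarray(visit_starts_s, dtype=float))
    out = np.full(24, np.nan)
    if t.size < 2:
        return out
    freq = 1.0 / (np.diff(t) / 3600.0)
    hours = np.floor((t[1:] / 3600.0) % 24.0).astype(int)
    for h in range(24):
        m = hours == h
        if m.any():
            out[h] = freq[m].mean()
    return out


def nocturnality_score(visit_starts_s: Sequence[float],
                       light_cycle: LightCycle = LightCycle()) -> float:
    """Preference score contrasting dark-phase vs light-phase visits.

    +1 = all activity at night (lights off), -1 = all by day.
    """
    t = np.asarray(visit_starts_s, dtype=float)
    if t.size == 0:
        return float("nan")
    night = int(np.count_nonzero(light_cycle.is_dark(t)))
    return preference_score(night, t.size - night)


def ppi_percent(baseline: Sequence[float], prepulse: Sequence[float]) -> float:
    """Percent prepulse inhibition: ``100 * (1 - mean(prepulse)/mean(baseline))``.

    Negative values indicate startle facilitation.  NaN when either
    condition has no trials or the baseline mean is zero.
    """
    b = np.asarray(baseline, dtype=float)
    p = np.asarray(prepulse, dtype=float)
    if b.size == 0 or p.size == 0:
        return float("nan")
    mb = b.mean()
    if mb == 0:
        return float("nan")
    return float(100.0 * (1.0 - p.mean() / mb))


# ---------------------------------------------------------------------------
# Event-table reduction


def trials_from_events(events: pd.DataFrame, phase_row: Mapping,
                       assigned: Mapping[str, int] | None) -> pd.DataFrame:
    """Extract the trial sequence of one learning phase from an event table.

    Only visits with at least one nosepoke count as trials.  ``correct`` is a
    visit to the mouse's assigned corner, ``rewarded`` a trial with licks.
    Returns a frame with columns mouse_tag, t_start, correct, rewarded in
    time order.
    """
    m = (events["t_start"] >= phase_row["t_start"]) & (events["t_start"] < phase_row["t_end"])
    ev = events.loc[m & (events["nosepokes"] >= 1)].sort_values(["mouse_tag", "t_start"])
    licks = ev["licks_left"] + ev["licks_right"]
    corr = pd.Series(False, index=ev.index)
    if assigned:
        tags = ev["mouse_tag"].map(assigned)
        corr = ev["corner"] == tags
    return pd.DataFrame({
        "mouse_tag": ev["mouse_tag"].to_numpy(),
        "t_start": ev["t_start"].to_numpy(),
        "correct": corr.to_numpy(dtype=bool),
        "rewarded": (licks > 0).to_numpy(dtype=bool),
    })


def _phase_events(events: pd.DataFrame, phase_row) -> pd.DataFrame:
    m = (events["t_start"] >= phase_row["t_start"]) & (events["t_start"] < phase_row["t_end"])
    return events.loc[m]


def build_variable_matrix(events: pd.DataFrame,
                          schedule,
                          design: pd.DataFrame,
                          arms: pd.DataFrame,
                          startle: pd.DataFrame,
                          summaries: pd.DataFrame,
                          sprt: SprtConfig = SprtConfig(),
                          light_cycle: LightCycle = LightCycle(),
                          rdoc_map: Mapping[str, str] | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a full cohort into the mice x 19 VariableMatrix.

    Parameters mirror the on-disk cohort bundle: the IntelliCage event table,
    the phase schedule (with per-mouse corner assignments), the 2x2 design,
    Y-maze arm-entry sequences, per-trial startle amplitudes and the
    tracking-software summary table (Rot, CtrT, BsF, Imm, MnSp, Cue, Ctx).

    Returns ``(matrix, diagnostics)`` where matrix has one row per mouse in
    the design (NaN where a test is missing) and diagnostics holds per-phase
    success/rewarded rates and trials-to-criterion.
    """
    rdoc = dict(DEFAULT_RDOC_MAP if rdoc_map is None else rdoc_map)
    missing = [v for v in VARIABLE_ROSTER if v not in rdoc]
    if missing:
        raise ValueError(f"variables without an RDoC domain: {missing}")

    mice = list(design.index)
    mat = pd.DataFrame(np.nan, index=pd.Index(mice, name="mouse_tag"),
                       columns=VARIABLE_ROSTER, dtype=float)

    phases = schedule.phases
    learning = phases[phases["kind"] == "learning"]
    reversal_names = [p for p in learning["phase"] if p.startswith("reversal")]
    diag_rows = []

    # per-phase trial reductions
    crits: dict[str, dict[str, float]] = {}
    succ: dict[str, dict[str, float]] = {}
    for _, prow in learning.iterrows():
        assigned = schedule.assigned_corners(prow["phase"])
        tr = trials_from_events(events, prow, assigned)
        crits[prow["phase"]] = {}
        succ[prow["phase"]] = {}
        for tag, grp in tr.groupby("mouse_tag", sort=False):
            n, cens = sprt_trials_to_criterion(grp["correct"].to_numpy(), sprt)
            crits[prow["phase"]][tag] = n
            succ[prow["phase"]][tag] = success_rate(grp["correct"].to_numpy())
            diag_rows.append({
                "mouse_tag": tag, "phase": prow["phase"],
                "n_trials": len(grp),
                "trials_to_criterion": n, "censored": cens,
                "success_rate": succ[prow["phase"]][tag],
                "rewarded_trial_rate": rewarded_trial_rate(grp["rewarded"].to_numpy()),
            })

    place = learning[~learning["phase"].str.startswith("reversal")]
    place_name = place["phase"].iloc[0] if len(place) else None

    for tag in mice:
        ev_m = events[events["mouse_tag"] == tag]

        # IntelliCage activity scores come from the free-exploration
        # (acclimatization) phase, where corner access is unconstrained.
        free = phases[phases["kind"] == "free"]
        if len(free):
            fe = _phase_events(ev_m, free.iloc[0])
            mat.at[tag, "Act"] = instantaneous_frequency(fe["t_start"].to_numpy())
            mat.at[tag, "Nct"] = nocturnality_score(fe["t_start"].to_numpy(), light_cycle)

        if place_name is not None:
            assigned = schedule.assigned_corners(place_name)
            prow = learning[learning["phase"] == place_name].iloc[0]
            pe = _phase_events(ev_m, prow)
            pe = pe[pe["nosepokes"] >= 1]
            if len(pe) and tag in assigned:
                n_corr = int((pe["corner"] == assigned[tag]).sum())
                mat.at[tag, "PcP"] = place_preference_score(n_corr, len(pe) - n_corr)

        if reversal_names and tag in crits.get(reversal_names[0], {}):
            mat.at[tag, "RvL"] = crits[reversal_names[0]][tag]
            cs = [crits[p].get(tag, np.nan) for p in reversal_names]
            if len(cs) >= 2 and not any(np.isnan(cs)):
                mat.at[tag, "SrL"] = serial_reversal_auc(cs)

        suc = phases[phases["kind"] == "sucrose"]
        if len(suc):
            se = _phase_events(ev_m, suc.iloc[0])
            mat.at[tag, "ScP"] = preference_score(float(se["licks_left"].sum()),
                                                  float(se["licks_right"].sum()))

        arm_seq = arms[arms["mouse_tag"] == tag].sort_values("entry_index")["arm"]
        if len(arm_seq):
            mat.at[tag, "Alt"] = spontaneous_alternation_rate(list(arm_seq))
            mat.at[tag, "Chc"] = float(len(arm_seq))

        st = startle[startle["mouse_tag"] == tag]
        if len(st):
            base = st.loc[st["condition"] == "baseline", "amplitude"].to_numpy()
            mat.at[tag, "PpiBs"] = float(base.mean()) if base.size else np.nan
            for var, cond in (("Ppi70", "pp70"), ("Ppi75", "pp75"), ("Ppi80", "pp80")):
                pp = st.loc[st["condition"] == cond, "amplitude"].to_numpy()
                mat.at[tag, var] = ppi_percent(base, pp)

        if tag in summaries.index:
            for var in ("Rot", "CtrT", "BsF", "Imm", "MnSp", "Cue", "Ctx"):
                if var in summaries.columns:
                    mat.at[tag, var] = summaries.at[tag, var]

    diagnostics = pd.DataFrame(diag_rows)
    return mat, diagnostics


def zscore_profile(matrix: pd.DataFrame, design: pd.DataFrame,
                   reference_cell: tuple[str, str] = ("placebo", "placebo"),
                   ) -> pd.DataFrame:
    """Group-mean Z-score profile centered on the reference (placebo) group.

    Each column is standardized with the pooled mean/SD over all mice
    (missing values ignored), group means are taken per design cell, and the
    reference cell's row is subtracted so the profile reads as treatment
    effect in pooled-SD units.  Rows are labeled ``S-level/A-level``.
    """
    zero_var = [c for c in matrix.columns
                if matrix[c].notna().sum() < 2 or np.nanstd(matrix[c].to_numpy(), ddof=1) == 0]
    if zero_var:
        raise ValueError(f"zero-variance or under-observed columns: {zero_var}")
    z = (matrix - matrix.mean()) / matrix.std(ddof=1)
    cells = design.loc[matrix.index]
    key = cells.iloc[:, 0].astype(str) + "/" + cells.iloc[:, 1].astype(str)
    gm = z.groupby(key).mean()
    ref = f"{reference_cell[0]}/{reference_cell[1]}"
    if ref not in gm.index:
        raise ValueError(f"reference cell {ref!r} not present in design")
    return gm.sub(gm.loc[ref], axis=1)
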