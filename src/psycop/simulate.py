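"""Synthetic mouse cohorts with the statistical structure the pipeline assumes.

The generator emulates a 2x2 factorial treatment cohort (two drugs, four
cells) passing through the full battery: an automated home-cage (corner
visit / nosepoke / lick) experiment with acclimatization, place learning,
five serial reversals and a sucrose-preference day; a Y-maze session;
per-trial acoustic startle with three prepulse levels; and tracked summary
measures (open field, fear conditioning, tail suspension).

Each mouse carries latent traits sampled from population distributions;
treatment effects are injected as additive shifts of the trait means on a
transformed scale (log for rates, logit for probabilities), so parameters
always stay in-domain.  Corner choice follows a softmax over delta-rule
action values — the minimal reinforcement-learning model that yields
criterion-reachable learning curves; visit times follow an inhomogeneous
Poisson process with sinusoidal circadian intensity peaking mid-dark-phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PhaseSchedule
from .scoring import LightCycle, SprtConfig, serial_reversal_auc, sprt_trials_to_criterion

__all__ = [
    "Phase", "DEFAULT_PHASES", "CohortDesign", "MouseLatentTraits", "EffectSpec",
    "TRAIT_NAMES", "CROSSOVER_LEARNING_EFFECT", "Cohort", "sample_traits",
    "simulate_intellicage_events",
    "simulate_arm_sequence", "simulate_summary_tests", "simulate_trial_sequences",
    "generate_cohort", "simulate_reversal_auc_table",
]


@dataclass(frozen=True)
class Phase:
    name: str
    kind: str              # "free" | "learning" | "sucrose"
    duration_days: float

    def __post_init__(self):
        if self.duration_days <= 0:
            raise ValueError(f"phase {self.name!r} has non-positive duration")
        if self.kind not in ("free", "learning", "sucrose"):
            raise ValueError(f"unknown phase kind {self.kind!r}")


#: Study schedule: 5 d acclimatization, 2 d place learning, 5 x 1 d serial
#: reversal, 1 d sucrose preference.
DEFAULT_PHASES = (
    Phase("acclimatization", "free", 5.0),
    Phase("place_learning", "learning", 2.0),
    Phase("reversal1", "learning", 1.0),
    Phase("reversal2", "learning", 1.0),
    Phase("reversal3", "learning", 1.0),
    Phase("reversal4", "learning", 1.0),
    Phase("reversal5", "learning", 1.0),
    Phase("sucrose", "sucrose", 1.0),
)

# Cells in reporting order: Plc-Plc, Apz-Plc, Plc-Spl, Apz-Spl
_CELLS = (
    ("placebo", "placebo"),
    ("placebo", "aripiprazole"),
    ("spironolactone", "placebo"),
    ("spironolactone", "aripiprazole"),
)


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout: cell sizes, light cycle, phase schedule and seed."""

    group_sizes: tuple[int, int, int, int] = (19, 19, 30, 30)
    seed: int = 0
    light_cycle: LightCycle = field(default_factory=LightCycle)
    phases: tuple[Phase, ...] = DEFAULT_PHASES
    missing_rate: float = 0.06   # chance a non-home-cage test record is lost per mouse

    def __post_init__(self):
        if len(self.group_sizes) != 4 or any(n < 2 for n in self.group_sizes):
            raise ValueError("need four cell sizes of at least 2 mice each")
        if not self.phases:
            raise ValueError("empty phase schedule")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    def design_frame(self) -> pd.DataFrame:
        rows, k = [], 0
        for (s, a), n in zip(_CELLS, self.group_sizes):
            for _ in range(n):
                k += 1
                rows.append({"mouse_tag": f"M{k:03d}", "S": s, "A": a})
        return pd.DataFrame(rows).set_index("mouse_tag")


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# trait -> (transform, population mean on natural scale, SD on transformed scale)
_TRAIT_SPECS: dict[str, tuple[str, float, float]] = {
    "base_visit_rate":     ("log",   3.0,  0.25),  # visits per hour
    "circadian_amplitude": ("logit", 0.60, 0.50),
    "learning_rate":       ("logit", 0.12, 0.40),
    "choice_temperature":  ("log",   0.30, 0.20),
    "sucrose_bias":        ("logit", 0.50, 0.60),
    "startle_gain":        ("log",   150., 0.35),  # arbitrary startle units
    "ppi_attenuation":     ("logit", 0.40, 0.35),  # mid (+10 dB) prepulse level
    "freeze_baseline":     ("logit", 0.10, 0.40),
    "freeze_cue":          ("logit", 0.35, 0.40),
    "freeze_ctx":          ("logit", 0.30, 0.40),
    "immobility":          ("logit", 0.45, 0.35),
    "of_speed_mean":       ("log",   5.0,  0.20),  # cm/s
    "of_center_time":      ("log",   90.,  0.35),  # s of a 10-min session
    "of_rotation_rate":    ("log",   2.0,  0.30),  # rotations/min
    "ym_alternation":      ("logit", 0.30, 0.50),  # bias beyond chance, see docs
    "ym_choice_rate":      ("log",   45.,  0.20),  # arm entries per session
}

TRAIT_NAMES = tuple(_TRAIT_SPECS)


@dataclass(frozen=True)
class MouseLatentTraits:
    """Per-mouse latent behavioral parameters (natural scale)."""

    base_visit_rate: float = 3.0
    circadian_amplitude: float = 0.6
    learning_rate: float = 0.12
    choice_temperature: float = 0.30
    sucrose_bias: float = 0.50
    startle_gain: float = 150.0
    ppi_attenuation: float = 0.40
    freeze_baseline: float = 0.10
    freeze_cue: float = 0.35
    freeze_ctx: float = 0.30
    immobility: float = 0.45
    of_speed_mean: float = 5.0
    of_center_time: float = 90.0
    of_rotation_rate: float = 2.0
    ym_alternation: float = 0.30
    ym_choice_rate: float = 45.0
    #: logit offsets of the three prepulse levels (+5/+10/+15 dB) from the
    #: mid-level attenuation trait
    ppi_level_offsets: tuple[float, float, float] = (-0.7, 0.0, 0.4)

    def ppi_level_attenuation(self) -> tuple[float, float, float]:
        a = self.ppi_attenuation
        if a <= 0.0:
            return (0.0, 0.0, 0.0)
        if a >= 1.0:
            return (1.0, 1.0, 1.0)
        la = _logit(a)
        return tuple(_expit(la + off) for off in self.ppi_level_offsets)

    def __post_init__(self):
        for name, (tf, _, _) in _TRAIT_SPECS.items():
            v = getattr(self, name)
            if tf == "log" and v <= 0:
                raise ValueError(f"trait {name} must be positive, got {v}")
            if tf == "logit" and not (0.0 <= v <= 1.0):
                raise ValueError(f"trait {name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class EffectSpec:
    """Treatment shifts of trait means on the transformed scale.

    ``shifts`` maps trait name -> {"S": b_s, "A": b_a, "SxA": b_i}; the
    transformed trait mean of a mouse in cell (x_s, x_a) with sum-to-zero
    codes x in {-1, +1} is ``mu + b_s*x_s + b_a*x_a + b_i*x_s*x_a``.  A zero
    spec makes all four cells exchangeable in distribution.
    """

    shifts: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for trait, terms in self.shifts.items():
            if trait not in _TRAIT_SPECS:
                raise ValueError(f"unknown trait {trait!r}; known: {sorted(_TRAIT_SPECS)}")
            bad = set(terms) - {"S", "A", "SxA"}
            if bad:
                raise ValueError(f"unknown effect terms {sorted(bad)} for trait {trait!r}")

    def shift(self, trait: str, x_s: float, x_a: float) -> float:
        t = self.shifts.get(trait)
        if not t:
            return 0.0
        return (t.get("S", 0.0) * x_s + t.get("A", 0.0) * x_a
                + t.get("SxA", 0.0) * x_s * x_a)


#: Crossover interaction on learning speed used by the power studies: the
#: spironolactone factor raises the delta-rule learning rate in
#: placebo-aripiprazole mice and lowers it under aripiprazole (pure
#: interaction on the logit scale).  Size fixed at 0.3 after pilot power
#: runs; see docs/methods.md.
CROSSOVER_LEARNING_EFFECT = EffectSpec({"learning_rate": {"SxA": -0.3}})

#: A study-like treatment scenario for demonstrations: the aripiprazole-type
#: factor dampens activity and circadian amplitude, raises freezing,
#: immobility, prepulse inhibition and rotation; the spironolactone-type
#: factor nudges activity up; learning speed and sucrose preference carry
#: crossover interactions.  Magnitudes are moderate (0.1-0.35 on the
#: transformed scales).
STUDY_LIKE_EFFECT = EffectSpec({
    "learning_rate": {"SxA": -0.3},
    "sucrose_bias": {"SxA": 0.3},
    "base_visit_rate": {"A": -0.15, "S": 0.08},
    "circadian_amplitude": {"A": -0.3},
    "freeze_baseline": {"A": 0.3},
    "freeze_cue": {"A": 0.35},
    "freeze_ctx": {"A": 0.3},
    "immobility": {"A": 0.25},
    "ppi_attenuation": {"A": 0.3},
    "ym_alternation": {"A": 0.2},
    "ym_choice_rate": {"A": -0.15},
    "of_rotation_rate": {"A": 0.3},
    "of_speed_mean": {"A": -0.2},
})


def sample_traits(rng: np.random.Generator, x_s: float = -1.0, x_a: float = -1.0,
                  effects: EffectSpec | None = None) -> MouseLatentTraits:
    """Draw one mouse's latent traits, with treatment shifts applied."""
    eff = effects or EffectSpec()
    vals = {}
    for name, (tf, mean_nat, sigma) in _TRAIT_SPECS.items():
        mu = math.log(mean_nat) if tf == "log" else _logit(mean_nat)
        x = mu + eff.shift(name, x_s, x_a) + sigma * rng.standard_normal()
        vals[name] = math.exp(x) if tf == "log" else _expit(x)
    return MouseLatentTraits(**vals)


# ---------------------------------------------------------------------------
# Home-cage event stream


#: visit duration model: exponential tail on a short minimum stay (seconds)
_VISIT_DUR_MIN_S = 10.0
_VISIT_DUR_MEAN_S = 110.0


def _visit_times_hours(traits: MouseLatentTraits, total_h: float,
                       light: LightCycle, rng: np.random.Generator,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Visit start times (hours) and durations (seconds).

    Corner approaches follow an inhomogeneous Poisson process with intensity
    ``lambda(t) = base * (1 + amp*cos(2*pi*(t - t_peak)/24))`` (peak at
    mid-dark-phase, i.e. trough in the light phase), realized by thinning.
    A visit occupies the animal: approaches arriving before the current
    visit ends are discarded, so visits never overlap and inter-visit
    intervals are bounded below by the visit duration.
    """
    lam_max = traits.base_visit_rate * (1.0 + traits.circadian_amplitude)
    n = rng.poisson(lam_max * total_h)
    t = np.sort(rng.uniform(0.0, total_h, size=n))
    t_peak = light.light_on + light.light_hours + (24.0 - light.light_hours) / 2.0
    lam = 1.0 + traits.circadian_amplitude * np.cos(2 * np.pi * (t - t_peak) / 24.0)
    keep = rng.uniform(0.0, 1.0 + traits.circadian_amplitude, size=n) < lam
    t = t[keep]
    dur_s = _VISIT_DUR_MIN_S + rng.exponential(_VISIT_DUR_MEAN_S, size=t.size)
    starts, durs = [], []
    busy_until = -np.inf
    for ti, di in zip(t, dur_s):
        if ti * 3600.0 >= busy_until:
            starts.append(ti)
            durs.append(di)
            busy_until = ti * 3600.0 + di
    return np.asarray(starts), np.asarray(durs)


def simulate_intellicage_events(traits: MouseLatentTraits, schedule: PhaseSchedule,
                                mouse_tag: str, rng: np.random.Generator,
                                light_cycle: LightCycle = LightCycle(),
                                ) -> pd.DataFrame:
    """One mouse's corner-visit event table over the full phase schedule.

    Corner choice is a softmax over four delta-rule action values; reward
    (door opening, hence licks) is delivered at the assigned corner in
    learning phases, at every corner during free phases, and with a
    sucrose-biased bottle side on the sucrose day.
    """
    phases = schedule.phases
    if not len(phases):
        raise ValueError("empty schedule")
    total_h = float(phases["t_end"].iloc[-1]) / 3600.0
    t_h, dur = _visit_times_hours(traits, total_h, light_cycle, rng)
    n = t_h.size
    if n == 0:
        return pd.DataFrame(columns=["mouse_tag", "t_start", "t_end", "corner",
                                     "nosepokes", "licks_left", "licks_right"])
    t_s = t_h * 3600.0

    bounds = phases["t_start"].to_numpy()
    phase_idx = np.searchsorted(bounds, t_s, side="right") - 1
    kinds = phases["kind"].to_list()
    names = phases["phase"].to_list()
    assigned_by_phase = [
        (schedule.assigned_corners(names[i]) or {}).get(mouse_tag)
        if kinds[i] == "learning" else None
        for i in range(len(names))
    ]

    lr = traits.learning_rate
    tau = max(traits.choice_temperature, 0.05)
    Q = [0.25, 0.25, 0.25, 0.25]
    ws = [math.exp(q / tau) for q in Q]
    tot = sum(ws)
    u = rng.random(n)
    corners = np.empty(n, dtype=np.int64)
    rewarded = np.empty(n, dtype=bool)
    for i in range(n):
        r = u[i] * tot
        c = 0
        acc = ws[0]
        while acc < r and c < 3:
            c += 1
            acc += ws[c]
        corners[i] = c + 1
        ph = phase_idx[i]
        kind = kinds[ph]
        if kind == "learning":
            rew = 1.0 if assigned_by_phase[ph] == c + 1 else 0.0
        else:
            rew = 1.0   # all doors open in free exploration / sucrose phases
        rewarded[i] = rew > 0.5
        dq = lr * (rew - Q[c])
        if dq != 0.0:
            Q[c] += dq
            old = ws[c]
            ws[c] = math.exp(Q[c] / tau)
            tot += ws[c] - old

    nosepokes = 1 + rng.poisson(1.0, size=n)
    licks_left = np.zeros(n, dtype=np.int64)
    licks_right = np.zeros(n, dtype=np.int64)
    kind_arr = np.array([kinds[i] for i in phase_idx])
    p_left_sucrose = (1.0 + traits.sucrose_bias) / 2.0
    drink_free = rng.random(n) < 0.5
    drink_suc = rng.random(n) < 0.8
    drinks = np.where(kind_arr == "learning", rewarded,
                      np.where(kind_arr == "sucrose", drink_suc, drink_free))
    n_licks = rng.poisson(25.0, size=n) + 1
    side_left = np.where(kind_arr == "sucrose",
                         rng.random(n) < p_left_sucrose,
                         rng.random(n) < 0.5)
    licks_left[drinks & side_left] = n_licks[drinks & side_left]
    licks_right[drinks & ~side_left] = n_licks[drinks & ~side_left]

    return pd.DataFrame({
        "mouse_tag": mouse_tag,
        "t_start": t_s,
        "t_end": t_s + dur,
        "corner": corners,
        "nosepokes": nosepokes,
        "licks_left": licks_left,
        "licks_right": licks_right,
    })


def simulate_arm_sequence(traits: MouseLatentTraits, rng: np.random.Generator,
                          ) -> list[str]:
    """Y-maze arm entries: never the current arm; alternation-biased beyond that.

    With probability ``ym_alternation`` the mouse picks the arm distinct from
    its last *two* entries (completing a full alternation); otherwise it
    picks uniformly between the two arms other than the current one.  The
    expected alternation rate is therefore ``(1 + bias)/2``.
    """
    arms = ("A", "B", "C")
    n = max(3, int(rng.poisson(traits.ym_choice_rate)))
    seq = [arms[rng.integers(3)]]
    others = [a for a in arms if a != seq[0]]
    seq.append(others[rng.integers(2)])
    for _ in range(n - 2):
        last, prev = seq[-1], seq[-2]
        alt = next(a for a in arms if a not in (last, prev))
        if rng.random() < traits.ym_alternation:
            seq.append(alt)
        else:
            opts = [a for a in arms if a != last]
            seq.append(opts[rng.integers(2)])
    return seq


#: scored intervals in seconds: fear-conditioning windows and tail suspension
_FC_INTERVAL = 120.0
_TST_INTERVAL = 360.0
_STARTLE_TRIALS = 10
# lognormal sigma of per-trial startle amplitude; kept moderate so the
# PPI ratio estimator's convexity bias (~cv^2/n_trials) stays below 1%
_STARTLE_NOISE_SD = 0.3


def _beta_draw(rng: np.random.Generator, mean: float, conc: float = 30.0) -> float:
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    return float(rng.beta(mean * conc, (1.0 - mean) * conc))


def simulate_summary_tests(traits: MouseLatentTraits, rng: np.random.Generator,
                           n_trials: int = _STARTLE_TRIALS,
                           ) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-mouse summary values plus the per-trial startle table.

    Startle amplitude is lognormal around ``startle_gain``, attenuated
    multiplicatively by ``1 - attenuation(level)`` on prepulse trials
    (levels +5/+10/+15 dB over the 65 dBA background, 10 trials each,
    115 dBA pulse).  Freezing/immobility proportions are Beta draws around
    the propensity traits, converted to seconds of the scored interval.
    """
    summaries = {
        "BsF": _beta_draw(rng, traits.freeze_baseline) * _FC_INTERVAL,
        "Cue": _beta_draw(rng, traits.freeze_cue) * _FC_INTERVAL,
        "Ctx": _beta_draw(rng, traits.freeze_ctx) * _FC_INTERVAL,
        "Imm": _beta_draw(rng, traits.immobility) * _TST_INTERVAL,
        "MnSp": traits.of_speed_mean * math.exp(0.1 * rng.standard_normal()),
        "CtrT": traits.of_center_time * math.exp(0.1 * rng.standard_normal()),
        "Rot": traits.of_rotation_rate * math.exp(0.1 * rng.standard_normal()),
    }
    atts = traits.ppi_level_attenuation()
    rows = []
    for cond, att in (("baseline", 0.0), ("pp70", atts[0]),
                      ("pp75", atts[1]), ("pp80", atts[2])):
        amp = (traits.startle_gain * (1.0 - att)
               * np.exp(_STARTLE_NOISE_SD * rng.standard_normal(n_trials)))
        for k in range(n_trials):
            rows.append({"condition": cond, "trial": k + 1, "amplitude": amp[k]})
    return summaries, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fast trial-sequence path (no event timing), used for calibration studies


def simulate_trial_sequences(traits: MouseLatentTraits, phases: tuple[Phase, ...],
                             assigned: dict[str, int], rng: np.random.Generator,
                             ) -> dict[str, np.ndarray]:
    """Correct/incorrect trial sequences per learning phase.

    Runs the same softmax/delta-rule corner-choice model as the event
    simulator but draws only the trial count per phase (Poisson at the base
    visit rate), skipping visit timing.  Action values carry over between
    phases, so reversals start from the previously learned preference.
    """
    lr = traits.learning_rate
    tau = max(traits.choice_temperature, 0.05)
    Q = [0.25, 0.25, 0.25, 0.25]
    ws = [math.exp(q / tau) for q in Q]
    tot = sum(ws)
    out: dict[str, np.ndarray] = {}
    for ph in phases:
        n = int(rng.poisson(traits.base_visit_rate * ph.duration_days * 24.0))
        if ph.kind != "learning":
            # free phases still update values (reward everywhere)
            u = rng.random(n)
            for i in range(n):
                r = u[i] * tot
                c, acc = 0, ws[0]
                while acc < r and c < 3:
                    c += 1
                    acc += ws[c]
                dq = lr * (1.0 - Q[c])
                if dq != 0.0:
                    Q[c] += dq
                    old = ws[c]
                    ws[c] = math.exp(Q[c] / tau)
                    tot += ws[c] - old
            continue
        target = assigned[ph.name]
        corr = np.empty(n, dtype=bool)
        u = rng.random(n)
        for i in range(n):
            r = u[i] * tot
            c, acc = 0, ws[0]
            while acc < r and c < 3:
                c += 1
                acc += ws[c]
            hit = (c + 1) == target
            corr[i] = hit
            dq = lr * ((1.0 if hit else 0.0) - Q[c])
            if dq != 0.0:
                Q[c] += dq
                old = ws[c]
                ws[c] = math.exp(Q[c] / tau)
                tot += ws[c] - old
        out[ph.name] = corr
    return out


def _assign_corners(phases: tuple[Phase, ...], tags: list[str],
                    rng: np.random.Generator) -> pd.DataFrame:
    """Assigned corner per mouse per learning phase; reversals always switch."""
    rows = []
    current: dict[str, int] = {}
    for ph in phases:
        if ph.kind != "learning":
            continue
        for tag in tags:
            if tag not in current:
                current[tag] = int(rng.integers(1, 5))
            else:
                choices = [c for c in (1, 2, 3, 4) if c != current[tag]]
                current[tag] = int(choices[rng.integers(3)])
            rows.append({"phase": ph.name, "mouse_tag": tag, "corner": current[tag]})
    return pd.DataFrame(rows)


def _build_schedule(design: CohortDesign, tags: list[str],
                    rng: np.random.Generator) -> PhaseSchedule:
    t = 0.0
    rows = []
    for ph in design.phases:
        dt = ph.duration_days * 86400.0
        rows.append({"phase": ph.name, "kind": ph.kind, "t_start": t, "t_end": t + dt})
        t += dt
    return PhaseSchedule(pd.DataFrame(rows), _assign_corners(design.phases, tags, rng))


@dataclass
class Cohort:
    """Complete synthetic dataset of one cohort run."""

    design: pd.DataFrame          # mouse_tag -> S, A levels
    schedule: PhaseSchedule
    events: pd.DataFrame
    arms: pd.DataFrame            # mouse_tag, entry_index, arm
    startle: pd.DataFrame         # mouse_tag, condition, trial, amplitude
    summaries: pd.DataFrame       # mouse_tag x summary variables
    light_cycle: LightCycle = field(default_factory=LightCycle)
    seed: int | None = None

    def variable_matrix(self, sprt: SprtConfig = SprtConfig(),
                        rdoc_map=None) -> tuple[pd.DataFrame, pd.DataFrame]:
        from .scoring import build_variable_matrix
        return build_variable_matrix(self.events, self.schedule, self.design,
                                     self.arms, self.startle, self.summaries,
                                     sprt=sprt, light_cycle=self.light_cycle,
                                     rdoc_map=rdoc_map)

    def save(self, directory) -> None:
        from . import io
        io.save_cohort(self, directory)

    @classmethod
    def load(cls, directory) -> "Cohort":
        from . import io
        return io.load_cohort(directory)


def generate_cohort(design: CohortDesign = CohortDesign(),
                    effects: EffectSpec | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate the full synthetic dataset for one cohort.

    ``seed`` overrides ``design.seed``.  Identical design + seed yields an
    identical dataset (per-mouse child RNGs are spawned deterministically).
    A fraction ``design.missing_rate`` of the out-of-home-cage test records
    (Y-maze, startle, each tracked summary) is dropped per mouse to mimic
    lost sessions; home-cage event data are always complete.
    """
    eff = effects or EffectSpec()
    root_seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    rng = np.random.default_rng(ss)
    dframe = design.design_frame()
    tags = list(dframe.index)
    schedule = _build_schedule(design, tags, rng)

    child_seeds = ss.spawn(len(tags))
    ev_parts, arm_rows, startle_parts, summary_rows = [], [], [], []
    for tag, child in zip(tags, child_seeds):
        mrng = np.random.default_rng(child)
        x_s = 1.0 if dframe.at[tag, "S"] != "placebo" else -1.0
        x_a = 1.0 if dframe.at[tag, "A"] != "placebo" else -1.0
        traits = sample_traits(mrng, x_s, x_a, eff)
        ev = simulate_intellicage_events(traits, schedule, tag, mrng,
                                         design.light_cycle)
        ev_parts.append(ev)
        seq = simulate_arm_sequence(traits, mrng)
        summ, st = simulate_summary_tests(traits, mrng)
        st.insert(0, "mouse_tag", tag)

        # session loss: each non-home-cage test independently
        mr = design.missing_rate
        if mrng.random() >= mr:
            arm_rows.extend({"mouse_tag": tag, "entry_index": i + 1, "arm": a}
                            for i, a in enumerate(seq))
        if mrng.random() >= mr:
            startle_parts.append(st)
        row = {"mouse_tag": tag}
        for var, val in summ.items():
            row[var] = val if mrng.random() >= mr else np.nan
        summary_rows.append(row)

    events = pd.concat(ev_parts, ignore_index=True)
    arms = pd.DataFrame(arm_rows, columns=["mouse_tag", "entry_index", "arm"])
    startle = (pd.concat(startle_parts, ignore_index=True) if startle_parts
               else pd.DataFrame(columns=["mouse_tag", "condition", "trial", "amplitude"]))
    summaries = pd.DataFrame(summary_rows).set_index("mouse_tag")
    return Cohort(design=dframe, schedule=schedule, events=events, arms=arms,
                  startle=startle, summaries=summaries,
                  light_cycle=design.light_cycle, seed=root_seed)


def simulate_reversal_auc_table(design: CohortDesign = CohortDesign(),
                                effects: EffectSpec | None = None,
                                seed: int | None = None,
                                sprt: SprtConfig = SprtConfig()) -> pd.DataFrame:
    """Fast path: serial-reversal learning outcomes without event timing.

    Returns a frame indexed by mouse with columns ``RvL`` (first-reversal
    trials-to-criterion), ``SrL`` (serial-reversal AUC), ``S`` and ``A``.
    Used for replicate calibration studies where only the reversal-learning
    summary is needed.
    """
    eff = effects or EffectSpec()
    root_seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    rng = np.random.default_rng(ss)
    dframe = design.design_frame()
    tags = list(dframe.index)
    assigned_df = _assign_corners(design.phases, tags, rng)
    reversal_names = [p.name for p in design.phases
                      if p.kind == "learning" and p.name.startswith("reversal")]
    rows = []
    for tag, child in zip(tags, ss.spawn(len(tags))):
        mrng = np.random.default_rng(child)
        x_s = 1.0 if dframe.at[tag, "S"] != "placebo" else -1.0
        x_a = 1.0 if dframe.at[tag, "A"] != "placebo" else -1.0
        traits = sample_traits(mrng, x_s, x_a, eff)
        assigned = {r["phase"]: r["corner"]
                    for _, r in assigned_df[assigned_df["mouse_tag"] == tag].iterrows()}
        seqs = simulate_trial_sequences(traits, design.phases, assigned, mrng)
        crits = []
        for name in reversal_names:
            s = seqs.get(name, np.zeros(0, dtype=bool))
            if s.size == 0:
                crits = []
                break
            crits.append(sprt_trials_to_criterion(s, sprt)[0])
        row = {"mouse_tag": tag, "S": dframe.at[tag, "S"], "A": dframe.at[tag, "A"],
               "RvL": crits[0] if crits else np.nan,
               "SrL": serial_reversal_auc(crits) if len(crits) >= 2 else np.nan}
        rows.append(row)
    return pd.DataFrame(rows).set_index("mouse_tag")
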