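"""Readers, writers and validation for all tabular inputs and configs.

All tables are UTF-8 CSV with header and "." decimal; timestamps are float
seconds since experiment start (the light cycle is anchored by config, which
sidesteps the timezone ambiguity of vendor exports).  Vendor column-name
variation is absorbed by a *dialect*: a mapping from canonical column names
to the names found in the file.  The RDoC variable-domain map and run
configuration are YAML.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .scoring import RDOC_DOMAINS

__all__ = [
    "ValidationError", "PhaseSchedule",
    "read_event_table", "write_event_table", "validate_event_table",
    "read_design", "write_design",
    "read_schedule", "write_schedule",
    "read_rdoc_map", "write_rdoc_map",
    "read_variable_matrix", "write_variable_matrix",
    "save_cohort", "load_cohort",
]

EVENT_COLUMNS = ["mouse_tag", "t_start", "t_end", "corner",
                 "nosepokes", "licks_left", "licks_right"]
_FLOAT_FMT = "%.6f"


class ValidationError(ValueError):
    """Input failed validation; ``problems`` lists human-readable findings."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def _apply_dialect(df: pd.DataFrame, dialect: Mapping[str, str] | None,
                   required: list[str], path) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError([f"{path}: missing column(s) {missing}"])
    return df


def validate_event_table(df: pd.DataFrame) -> list[str]:
    """Return the list of invariant violations (empty = valid).

    Checks: t_end >= t_start (per row, reported with row numbers), corner in
    1..4, non-negative counts, and non-overlapping time-sorted visits per
    mouse (offending tags listed).
    """
    problems = []
    bad_t = df.index[df["t_end"] < df["t_start"]]
    for i in bad_t[:20]:
        problems.append(f"row {i}: t_end < t_start")
    bad_c = df.index[~df["corner"].isin([1, 2, 3, 4])]
    for i in bad_c[:20]:
        problems.append(f"row {i}: corner {df.at[i, 'corner']!r} not in 1..4")
    for col in ("nosepokes", "licks_left", "licks_right"):
        neg = df.index[df[col] < 0]
        for i in neg[:20]:
            problems.append(f"row {i}: negative {col}")
    overlapping = []
    for tag, grp in df.sort_values("t_start").groupby("mouse_tag", sort=False):
        starts = grp["t_start"].to_numpy()
        ends = grp["t_end"].to_numpy()
        if np.any(starts[1:] < ends[:-1] - 1e-9):
            overlapping.append(str(tag))
    if overlapping:
        problems.append(f"overlapping visits for mouse tag(s): {sorted(overlapping)}")
    return problems


def read_event_table(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a corner-visit event table."""
    df = pd.read_csv(path)
    df = _apply_dialect(df, dialect, EVENT_COLUMNS, path)[EVENT_COLUMNS]
    df["mouse_tag"] = df["mouse_tag"].astype(str)
    problems = validate_event_table(df)
    if problems:
        raise ValidationError(problems)
    return df.sort_values(["mouse_tag", "t_start"], kind="mergesort").reset_index(drop=True)


def write_event_table(df: pd.DataFrame, path) -> None:
    df[EVENT_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_design(path) -> pd.DataFrame:
    """Factorial design: mouse_tag -> (S, A) treatment levels."""
    df = pd.read_csv(path)
    df = _apply_dialect(df, None, ["mouse_tag", "S", "A"], path)
    df["mouse_tag"] = df["mouse_tag"].astype(str)
    dup = df["mouse_tag"][df["mouse_tag"].duplicated()]
    problems = [f"duplicate mouse tag {t!r}" for t in dup[:20]]
    for col in ("S", "A"):
        levels = sorted(df[col].astype(str).unique())
        if len(levels) > 2:
            problems.append(f"factor {col} has more than two levels: {levels}")
    if problems:
        raise ValidationError(problems)
    return df.set_index("mouse_tag")[["S", "A"]]


def write_design(design: pd.DataFrame, path) -> None:
    design.reset_index().to_csv(path, index=False)


@dataclass
class PhaseSchedule:
    """Ordered experiment phases plus per-mouse corner assignments.

    ``phases``: columns phase, kind, t_start, t_end (seconds, contiguous).
    ``assigned``: long table (phase, mouse_tag, corner) for learning phases.
    """

    phases: pd.DataFrame
    assigned: pd.DataFrame

    def __post_init__(self):
        self.phases = self.phases.reset_index(drop=True)
        problems = self.validate()
        if problems:
            raise ValidationError(problems)

    def validate(self) -> list[str]:
        problems = []
        ph = self.phases
        for i in range(len(ph)):
            if ph.at[i, "t_end"] <= ph.at[i, "t_start"]:
                problems.append(f"phase {ph.at[i, 'phase']!r}: non-positive duration")
        for i in range(1, len(ph)):
            gap = ph.at[i, "t_start"] - ph.at[i - 1, "t_end"]
            if abs(gap) > 1e-6:
                problems.append(
                    f"schedule gap of {gap:.1f}s between {ph.at[i-1, 'phase']!r} "
                    f"and {ph.at[i, 'phase']!r}")
        # consecutive learning phases must switch the assigned corner
        learn = list(ph.loc[ph["kind"] == "learning", "phase"])
        for a, b in zip(learn[:-1], learn[1:]):
            ca = self.assigned_corners(a)
            cb = self.assigned_corners(b)
            same = [t for t in cb if t in ca and ca[t] == cb[t]]
            if same:
                problems.append(
                    f"assigned corner unchanged from {a!r} to {b!r} for tag(s) "
                    f"{sorted(same)[:10]}")
        return problems

    def assigned_corners(self, phase: str) -> dict[str, int]:
        sub = self.assigned[self.assigned["phase"] == phase]
        return dict(zip(sub["mouse_tag"].astype(str), sub["corner"].astype(int)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for _, prow in self.phases.iterrows():
            sub = self.assigned[self.assigned["phase"] == prow["phase"]]
            if len(sub):
                for _, arow in sub.iterrows():
                    rows.append({**prow.to_dict(),
                                 "mouse_tag": arow["mouse_tag"],
                                 "assigned_corner": int(arow["corner"])})
            else:
                rows.append({**prow.to_dict(), "mouse_tag": "", "assigned_corner": ""})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhaseSchedule":
        phases = (df[["phase", "kind", "t_start", "t_end"]]
                  .drop_duplicates("phase").sort_values("t_start").reset_index(drop=True))
        with_m = df[df["mouse_tag"].astype(str).str.len() > 0]
        assigned = pd.DataFrame({
            "phase": with_m["phase"].to_numpy(),
            "mouse_tag": with_m["mouse_tag"].astype(str).to_numpy(),
            "corner": pd.to_numeric(with_m["assigned_corner"]).astype(int).to_numpy(),
        })
        return cls(phases, assigned)


def read_schedule(path) -> PhaseSchedule:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"mouse_tag": str, "assigned_corner": str})
    df = _apply_dialect(df, None, ["phase", "kind", "t_start", "t_end"], path)
    if "mouse_tag" not in df.columns:
        df["mouse_tag"] = ""
        df["assigned_corner"] = ""
    df["t_start"] = pd.to_numeric(df["t_start"])
    df["t_end"] = pd.to_numeric(df["t_end"])
    return PhaseSchedule.from_frame(df)


def write_schedule(schedule: PhaseSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_rdoc_map(path) -> dict[str, str]:
    """Variable -> RDoC domain mapping (YAML); duplicate keys are an error."""
    text = Path(path).read_text(encoding="utf-8")
    node = yaml.compose(text)
    problems = []
    if node is not None:
        seen = set()
        for key_node, _ in node.value:
            k = key_node.value
            if k in seen:
                problems.append(f"duplicate variable {k!r} in RDoC map")
            seen.add(k)
    mapping = yaml.safe_load(text) or {}
    for var, dom in mapping.items():
        if dom not in RDOC_DOMAINS:
            problems.append(f"variable {var!r}: unknown domain {dom!r} "
                            f"(expected one of {list(RDOC_DOMAINS)})")
    if problems:
        raise ValidationError(problems)
    return dict(mapping)


def write_rdoc_map(mapping: Mapping[str, str], path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dict(mapping), sort_keys=True, allow_unicode=True),
        encoding="utf-8")


def read_variable_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _apply_dialect(df, None, ["mouse_tag"], path)
    df["mouse_tag"] = df["mouse_tag"].astype(str)
    return df.set_index("mouse_tag").astype(float)


def write_variable_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True, index_label="mouse_tag", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Cohort bundle (directory of CSVs)


def save_cohort(cohort, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_event_table(cohort.events, d / "events.csv")
    write_design(cohort.design, d / "design.csv")
    write_schedule(cohort.schedule, d / "schedule.csv")
    cohort.arms.to_csv(d / "arms.csv", index=False)
    cohort.startle.to_csv(d / "startle.csv", index=False, float_format=_FLOAT_FMT)
    cohort.summaries.to_csv(d / "summaries.csv", index=True,
                            index_label="mouse_tag", float_format=_FLOAT_FMT)
    meta = {"light_cycle": {"light_on": cohort.light_cycle.light_on,
                            "light_hours": cohort.light_cycle.light_hours},
            "seed": cohort.seed}
    (d / "cohort.yaml").write_text(yaml.safe_dump(meta, sort_keys=True),
                                   encoding="utf-8")


def load_cohort(directory):
    from .scoring import LightCycle
    from .simulate import Cohort
    d = Path(directory)
    meta = yaml.safe_load((d / "cohort.yaml").read_text(encoding="utf-8")) or {}
    lc = meta.get("light_cycle", {})
    arms = pd.read_csv(d / "arms.csv", dtype={"mouse_tag": str})
    startle = pd.read_csv(d / "startle.csv", dtype={"mouse_tag": str})
    summaries = pd.read_csv(d / "summaries.csv", dtype={"mouse_tag": str}
                            ).set_index("mouse_tag")
    return Cohort(
        design=read_design(d / "design.csv"),
        schedule=read_schedule(d / "schedule.csv"),
        events=read_event_table(d / "events.csv"),
        arms=arms,
        startle=startle,
        summaries=summaries,
        light_cycle=LightCycle(light_on=lc.get("light_on", 0.0),
                               light_hours=lc.get("light_hours", 12.0)),
        seed=meta.get("seed"),
    )
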