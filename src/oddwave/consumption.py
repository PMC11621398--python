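"""Drinking phenotypes: baseline intake, alcohol-deprivation effect, relapse intensity.

Long-term four-bottle drinking data (water plus 5/10/20 % v/v ethanol) are
summarised per animal into the three scalars the correlation analyses consume:

* **BL** — baseline consumption: mean daily intake (g EtOH per kg body weight)
  over the last 7 days of each drinking phase, averaged over phases.
* **ADE** — alcohol-deprivation effect: intake on the first day of renewed
  access after each deprivation period, averaged over cycles.
* **relapse intensity** — per deprivation cycle, ADE minus the baseline of the
  immediately preceding drinking phase, averaged over cycles.

Each metric is computed per solution and as the across-solution total, which is
additive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SOLUTIONS = ("5%", "10%", "20%")

#: phase calendar entry: ("drinking" | "deprivation", number of days)
Phase = tuple[str, int]

#: default calendar: an initial 8-week drinking phase, then 4–6-week drinking
#: phases alternating with 2–3-week deprivations (several cycles, ~1 year).
DEFAULT_CALENDAR: tuple[Phase, ...] = (
    ("drinking", 56),
    ("deprivation", 14),
    ("drinking", 42),
    ("deprivation", 21),
    ("drinking", 35),
    ("deprivation", 14),
    ("drinking", 42),
    ("deprivation", 18),
    ("drinking", 28),
    ("deprivation", 21),
    ("drinking", 35),
    ("deprivation", 14),
    ("drinking", 42),
    ("deprivation", 16),
    ("drinking", 28),
)


@dataclass
class DrinkingProfile:
    """Daily intake records for a cohort plus the phase calendar that produced them.

    ``intake`` is a long-format table with columns
    ``animal, day, solution, g_per_kg`` (day is a 0-based integer index into the
    calendar). Deprivation days carry explicit zero rows.
    """

    intake: pd.DataFrame
    calendar: tuple[Phase, ...] = DEFAULT_CALENDAR

    def __post_init__(self) -> None:
        required = {"animal", "day", "solution", "g_per_kg"}
        missing = required - set(self.intake.columns)
        if missing:
            raise ValueError(f"intake table missing columns: {sorted(missing)}")
        if (self.intake["g_per_kg"] < 0).any():
            raise ValueError("negative intake values")

    @property
    def animals(self) -> list:
        return sorted(self.intake["animal"].unique())

    def phase_table(self) -> pd.DataFrame:
        """One row per phase: kind, start day, end day (exclusive)."""
        rows, start = [], 0
        for kind, n_days in self.calendar:
            rows.append({"kind": kind, "start": start, "end": start + n_days})
            start += n_days
        return pd.DataFrame(rows)


def infer_calendar(intake: pd.DataFrame) -> tuple[Phase, ...]:
    """Reconstruct the phase calendar from the intake table.

    A day is classified as deprivation when total alcohol intake across all
    animals and solutions is exactly zero. Suitable for noiseless or
    externally recorded profiles where deprivation days are true zeros.
    """
    daily = intake.groupby("day")["g_per_kg"].sum().sort_index()
    phases: list[Phase] = []
    for day in daily.index:
        kind = "deprivation" if daily.loc[day] == 0 else "drinking"
        if phases and phases[-1][0] == kind:
            phases[-1] = (kind, phases[-1][1] + 1)
        else:
            phases.append((kind, 1))
    return tuple(phases)


def compute_metrics(
    profile: DrinkingProfile,
    baseline_days: int = 7,
) -> pd.DataFrame:
    """Per-animal drinking metrics, tidy: (animal, solution, metric, value).

    Solutions include the three ethanol concentrations plus ``total`` (their
    sum). Metrics are ``BL``, ``ADE`` and ``relapse_intensity`` as defined in
    the module docstring.

    Raises ``ValueError`` if any drinking phase that precedes a deprivation is
    shorter than ``baseline_days`` (the baseline window would be undefined).
    """
    phases = profile.phase_table()
    drinking = phases[phases["kind"] == "drinking"].reset_index()
    if drinking.empty:
        raise ValueError("calendar contains no drinking phase")
    for _, ph in drinking.iterrows():
        if ph["end"] - ph["start"] < baseline_days:
            raise ValueError(
                f"drinking phase at days [{ph['start']}, {ph['end']}) shorter than "
                f"the {baseline_days}-day baseline window"
            )

    df = profile.intake
    wide = df.pivot_table(
        index=["animal", "day"], columns="solution", values="g_per_kg", aggfunc="sum"
    )
    rows = []
    for animal in profile.animals:
        sub = wide.loc[animal]
        # per-phase baselines (mean over the final `baseline_days` days)
        bls = []
        for _, ph in drinking.iterrows():
            days = range(int(ph["end"]) - baseline_days, int(ph["end"]))
            bls.append(sub.reindex(days).mean())
        bl_by_phase = pd.DataFrame(bls)
        # ADE: first day of each drinking phase that follows a deprivation
        ades, relapses = [], []
        for i, (_, ph) in enumerate(drinking.iterrows()):
            idx = int(ph["index"])
            if idx > 0 and profile.calendar[idx - 1][0] == "deprivation":
                ade = sub.loc[int(ph["start"])]
                ades.append(ade)
                relapses.append(ade - bl_by_phase.iloc[i - 1])
        metric_frames = {"BL": bl_by_phase.mean()}
        if ades:
            metric_frames["ADE"] = pd.DataFrame(ades).mean()
            metric_frames["relapse_intensity"] = pd.DataFrame(relapses).mean()
        for metric, per_solution in metric_frames.items():
            for sol in SOLUTIONS:
                rows.append(
                    {"animal": animal, "solution": sol, "metric": metric,
                     "value": float(per_solution.get(sol, np.nan))}
                )
            rows.append(
                {"animal": animal, "solution": "total", "metric": metric,
                 "value": float(per_solution.reindex(list(SOLUTIONS)).sum())}
            )
    return pd.DataFrame(rows)


def group_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Across-animal mean and SD for each (solution, metric)."""
    return (
        metrics.groupby(["solution", "metric"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
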