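"""Experimental-style gait event streams -> per-cycle metrics and state comparisons.

Event streams carry, per limb, paw-contact times and stance-end times.  Cycle
duration is the interval between successive contacts; stance is contact to
stance-end; swing is cycle minus stance.  Summaries group per-cycle metrics
by (state, condition, limb, speed) and comparisons pair intact against
hemisected cells, including the swing/stance crossing speed per limb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sim_engine import find_crossing

__all__ = [
    "GaitEventSeries",
    "EventOrderingError",
    "durations_from_events",
    "durations_table",
    "summarize_by_speed",
    "compare_states",
    "read_events_csv",
    "write_events_csv",
]

LIMBS = ("left", "right")
STATES = ("intact", "hemisected")

EVENT_CSV_COLUMNS = ["subject", "state", "condition", "speed_mps", "limb", "contact_s", "stance_end_s"]

#: duty-factor band outside which a cycle is flagged as a tracking artifact
DUTY_BAND = (0.05, 0.95)


class EventOrderingError(ValueError):
    """Raised when contact / stance-end timestamps violate ordering."""


@dataclass
class GaitEventSeries:
    """One pass of one subject in one condition: per-limb event timestamps.

    ``speed_mps`` is the condition speed (the common belt speed for tied
    protocols, the fast-belt speed for split protocols).
    """

    subject: str
    state: str  # "intact" | "hemisected"
    condition: str  # "tied" | "split_Ls_Rf" | "split_Lf_Rs"
    speed_mps: float
    contacts: dict[str, np.ndarray] = field(default_factory=dict)
    stance_ends: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for limb in self.contacts:
            c = np.asarray(self.contacts[limb], dtype=float)
            s = np.asarray(self.stance_ends[limb], dtype=float)
            if np.any(np.diff(c) <= 0):
                i = int(np.flatnonzero(np.diff(c) <= 0)[0])
                raise EventOrderingError(
                    f"{self.subject}/{limb}: contacts not strictly increasing at t={c[i + 1]:.4f}"
                )
            n = min(s.size, c.size - 1)
            for i in range(n):
                if not (c[i] < s[i] < c[i + 1]):
                    raise EventOrderingError(
                        f"{self.subject}/{limb}: stance end t={s[i]:.4f} outside "
                        f"({c[i]:.4f}, {c[i + 1]:.4f})"
                    )


def durations_from_events(series: GaitEventSeries) -> pd.DataFrame:
    """Per-cycle temporal metrics for every limb of one event series.

    The last contact closes the final cycle; a trailing stance-end without a
    following contact is dropped (partial cycle).  Cycles with duty factor
    outside ``DUTY_BAND`` are kept but flagged ``artifact=True``.
    """
    series.validate()
    rows = []
    for limb, c in series.contacts.items():
        c = np.asarray(c, dtype=float)
        s = np.asarray(series.stance_ends[limb], dtype=float)
        n = min(c.size - 1, s.size)
        for i in range(n):
            cycle = c[i + 1] - c[i]
            stance = s[i] - c[i]
            swing = cycle - stance
            duty = stance / cycle
            rows.append(
                {
                    "subject": series.subject,
                    "state": series.state,
                    "condition": series.condition,
                    "speed_mps": series.speed_mps,
                    "limb": limb,
                    "cycle_index": i,
                    "cycle_s": cycle,
                    "stance_s": stance,
                    "swing_s": swing,
                    "duty_factor": duty,
                    "artifact": not (DUTY_BAND[0] < duty < DUTY_BAND[1]),
                }
            )
    return pd.DataFrame(rows)


def durations_table(series_list) -> pd.DataFrame:
    """Concatenate per-cycle metrics over a collection of event series."""
    frames = [durations_from_events(s) for s in series_list]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def summarize_by_speed(
    metrics: pd.DataFrame,
    grouping=("state", "condition", "limb", "speed_mps"),
    min_cycles: int = 3,
    drop_artifacts: bool = True,
) -> pd.DataFrame:
    """Mean/SD/n of cycle, stance, swing and duty per grouping cell.

    Cells with fewer than ``min_cycles`` cycles are omitted with a warning.
    """
    df = metrics[~metrics["artifact"]] if drop_artifacts and "artifact" in metrics else metrics
    out = []
    for key, sub in df.groupby(list(grouping)):
        if len(sub) < min_cycles:
            warnings.warn(f"cell {key}: only {len(sub)} cycles, omitted", stacklevel=2)
            continue
        row = dict(zip(grouping, key))
        for col in ("cycle_s", "stance_s", "swing_s", "duty_factor"):
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1))
        row["n_cycles"] = int(len(sub))
        out.append(row)
    return pd.DataFrame(out)


def compare_states(summary: pd.DataFrame) -> pd.DataFrame:
    """Pair intact vs hemisected summary cells and report differences/ratios.

    Rows appear only where both states contributed >= the summary's minimum
    cycle count.  The crossing speed of swing vs stance (per condition, limb
    and state) is attached in the ``crossing_speed`` column of matching rows.
    """
    have = set(summary["state"].unique())
    partial = not ({"intact", "hemisected"} <= have)
    if partial:
        warnings.warn(f"missing state(s) {set(STATES) - have}; partial comparison", stacklevel=2)

    crossings: dict[tuple, float | None] = {}
    for (state, cond, limb), sub in summary.groupby(["state", "condition", "limb"]):
        sub = sub.sort_values("speed_mps")
        if len(sub) >= 2:
            res = find_crossing(
                sub["speed_mps"].to_numpy(),
                sub["swing_s_mean"].to_numpy(),
                sub["stance_s_mean"].to_numpy(),
            )
            crossings[(state, cond, limb)] = res.value
        else:
            crossings[(state, cond, limb)] = None

    rows = []
    idx = ["condition", "limb", "speed_mps"]
    pivots = {}
    for state in have:
        pivots[state] = summary[summary["state"] == state].set_index(idx)
    keys = sorted(set().union(*(set(p.index) for p in pivots.values())))
    for key in keys:
        cond, limb, speed = key
        row = dict(condition=cond, limb=limb, speed_mps=speed)
        for col in ("cycle_s", "stance_s", "swing_s", "duty_factor"):
            vals = {}
            for state in STATES:
                p = pivots.get(state)
                vals[state] = float(p.loc[key, f"{col}_mean"]) if p is not None and key in p.index else np.nan
                row[f"{col}_{state}"] = vals[state]
            row[f"{col}_diff"] = vals["hemisected"] - vals["intact"]
            row[f"{col}_ratio"] = vals["hemisected"] / vals["intact"] if vals["intact"] else np.nan
        for state in STATES:
            row[f"crossing_speed_{state}"] = crossings.get((state, cond, limb))
        row["complete"] = np.isfinite(row["cycle_s_intact"]) and np.isfinite(row["cycle_s_hemisected"])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def write_events_csv(series_list, path) -> None:
    """Write event series in the long CSV dialect (one row per contact).

    The final contact of a limb has an empty ``stance_end_s`` field when no
    stance end followed it.
    """
    rows = []
    for s in series_list:
        for limb in sorted(s.contacts):
            c = np.asarray(s.contacts[limb], dtype=float)
            se = np.asarray(s.stance_ends[limb], dtype=float)
            for i, ci in enumerate(c):
                rows.append(
                    {
                        "subject": s.subject,
                        "state": s.state,
                        "condition": s.condition,
                        "speed_mps": s.speed_mps,
                        "limb": limb,
                        "contact_s": ci,
                        "stance_end_s": se[i] if i < se.size else np.nan,
                    }
                )
    df = pd.DataFrame(rows, columns=EVENT_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_events_csv(path) -> list[GaitEventSeries]:
    """Read event series from the long CSV dialect."""
    df = pd.read_csv(path)
    missing = set(EVENT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    out = []
    for (subj, state, cond, speed), sub in df.groupby(["subject", "state", "condition", "speed_mps"]):
        series = GaitEventSeries(subject=str(subj), state=state, condition=cond, speed_mps=float(speed))
        for limb, ls in sub.groupby("limb"):
            ls = ls.sort_values("contact_s")
            series.contacts[limb] = ls["contact_s"].to_numpy(dtype=float)
            series.stance_ends[limb] = ls["stance_end_s"].dropna().to_numpy(dtype=float)
        series.validate()
        out.append(series)
    return out
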