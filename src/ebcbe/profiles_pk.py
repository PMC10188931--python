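"""Interval-collected concentration-time profiles and non-compartmental PK metrics.

Exhaled breath condensate (EBC) is collected over discrete windows (here six
4-minute windows spanning 0-74 min after dosing), so a "sample time" is a
convention rather than an observation: each window is reduced to a
representative time (midpoint by default) before any time-weighted
calculation. The metrics computed are purely non-compartmental: Cmax with its
window, and the linear-trapezoid AUC over the sampled interval only (no
extrapolation to t=0 or to infinity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CollectionWindow",
    "ConcentrationProfile",
    "PKResult",
    "assign_window_time",
    "compute_cmax",
    "compute_auc_trapezoid",
    "compute_pk",
    "read_profiles_csv",
    "pk_table",
]

TimeConvention = Literal["midpoint", "start", "end"]
LLOQPolicy = Literal["drop", "half", "zero"]


@dataclass(frozen=True)
class CollectionWindow:
    """One collection interval with its measured concentration.

    ``concentration`` is in ng/mL; ``None`` marks a missing measurement.
    ``below_lloq`` flags a value reported below the assay's lower limit of
    quantification; how such windows enter the PK calculation is decided by
    the LLOQ policy at computation time, not here.
    """

    start_min: float
    end_min: float
    concentration: float | None
    below_lloq: bool = False

    def __post_init__(self) -> None:
        if not self.end_min > self.start_min:
            raise ValueError(
                f"collection window must have end > start, got "
                f"[{self.start_min}, {self.end_min}]"
            )
        if self.concentration is not None and self.concentration < 0:
            raise ValueError(
                f"negative concentration {self.concentration} in window "
                f"[{self.start_min}, {self.end_min}]"
            )


def assign_window_time(
    window: CollectionWindow, convention: TimeConvention = "midpoint"
) -> float:
    """Representative time (minutes) of a collection window.

    The midpoint convention maps the six standard windows 0-4 ... 70-74 min
    onto the 2-72 min grid used for AUC.
    """
    if convention == "midpoint":
        return 0.5 * (window.start_min + window.end_min)
    if convention == "start":
        return window.start_min
    if convention == "end":
        return window.end_min
    raise ValueError(f"unknown time convention {convention!r}")


@dataclass(frozen=True)
class ConcentrationProfile:
    """All collection windows for one subject under one treatment.

    Windows are sorted by start time on construction and must not overlap.
    """

    subject_id: str
    treatment_id: str
    windows: tuple[CollectionWindow, ...]
    period: int = 1

    def __init__(
        self,
        subject_id: str,
        treatment_id: str,
        windows: Iterable[CollectionWindow],
        period: int = 1,
    ) -> None:
        ordered = tuple(sorted(windows, key=lambda w: w.start_min))
        if not ordered:
            raise ValueError("profile requires at least one collection window")
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.start_min < prev.end_min:
                raise ValueError(
                    f"overlapping windows [{prev.start_min}, {prev.end_min}] and "
                    f"[{cur.start_min}, {cur.end_min}] in subject {subject_id}"
                )
        object.__setattr__(self, "subject_id", str(subject_id))
        object.__setattr__(self, "treatment_id", str(treatment_id))
        object.__setattr__(self, "windows", ordered)
        object.__setattr__(self, "period", int(period))

    def usable_windows(
        self, lloq_policy: LLOQPolicy = "drop", lloq: float | None = None
    ) -> list[tuple[CollectionWindow, float]]:
        """Windows with a usable concentration under the given LLOQ policy.

        ``drop`` treats below-LLOQ values as missing; ``half`` substitutes
        LLOQ/2 (requires ``lloq``); ``zero`` substitutes 0. Missing
        concentrations are always dropped.
        """
        out: list[tuple[CollectionWindow, float]] = []
        for w in self.windows:
            if w.concentration is None:
                continue
            if w.below_lloq:
                if lloq_policy == "drop":
                    continue
                if lloq_policy == "half":
                    if lloq is None:
                        raise ValueError("lloq value required for policy 'half'")
                    out.append((w, lloq / 2.0))
                    continue
                if lloq_policy == "zero":
                    out.append((w, 0.0))
                    continue
                raise ValueError(f"unknown LLOQ policy {lloq_policy!r}")
            out.append((w, w.concentration))
        return out


@dataclass(frozen=True)
class PKResult:
    """Non-compartmental metrics for one profile."""

    subject_id: str
    treatment_id: str
    cmax: float
    tmax_window: CollectionWindow
    auc: float
    auc_span: tuple[float, float]
    n_windows_used: int
    period: int = 1


def compute_cmax(
    profile: ConcentrationProfile,
    lloq_policy: LLOQPolicy = "drop",
    lloq: float | None = None,
) -> tuple[float, CollectionWindow]:
    """Maximum observed concentration and the window in which it occurred.

    Ties are broken in favour of the earliest window. Raises ``ValueError``
    when no window carries a quantifiable concentration.
    """
    usable = profile.usable_windows(lloq_policy, lloq)
    if not usable:
        raise ValueError(
            f"no quantifiable concentrations for subject {profile.subject_id}, "
            f"treatment {profile.treatment_id}"
        )
    # max() keeps the first maximum among ties; windows are time-ordered.
    best_w, best_c = max(usable, key=lambda wc: wc[1])
    return best_c, best_w


def compute_auc_trapezoid(
    profile: ConcentrationProfile,
    convention: TimeConvention = "midpoint",
    lloq_policy: LLOQPolicy = "drop",
    lloq: float | None = None,
) -> float:
    """AUC (ng*min/mL) by the linear trapezoidal rule over usable windows.

    Representative times come from ``assign_window_time``; the integral runs
    from the first to the last usable window with no extrapolation. A missing
    interior window simply widens the trapezoid spanning it (logged as a
    warning).
    """
    usable = profile.usable_windows(lloq_policy, lloq)
    if len(usable) < 2:
        raise ValueError(
            f"AUC requires at least 2 usable windows, got {len(usable)} "
            f"(subject {profile.subject_id})"
        )
    if len(usable) < len(profile.windows):
        n_gap = len(profile.windows) - len(usable)
        warnings.warn(
            f"{n_gap} window(s) dropped for subject {profile.subject_id}; "
            "trapezoids bridge the gaps",
            stacklevel=2,
        )
    t = np.array([assign_window_time(w, convention) for w, _ in usable])
    c = np.array([conc for _, conc in usable])
    return float(np.trapezoid(c, t))


def compute_pk(
    profile: ConcentrationProfile,
    convention: TimeConvention = "midpoint",
    lloq_policy: LLOQPolicy = "drop",
    lloq: float | None = None,
) -> PKResult:
    """Cmax, Tmax window and trapezoid AUC for one profile."""
    cmax, tmax_window = compute_cmax(profile, lloq_policy, lloq)
    usable = profile.usable_windows(lloq_policy, lloq)
    auc = compute_auc_trapezoid(profile, convention, lloq_policy, lloq)
    t_first = assign_window_time(usable[0][0], convention)
    t_last = assign_window_time(usable[-1][0], convention)
    return PKResult(
        subject_id=profile.subject_id,
        treatment_id=profile.treatment_id,
        cmax=cmax,
        tmax_window=tmax_window,
        auc=auc,
        auc_span=(t_first, t_last),
        n_windows_used=len(usable),
        period=profile.period,
    )


# ---------------------------------------------------------------------------
# CSV I/O

_REQUIRED_COLS = [
    "subject_id",
    "treatment_id",
    "window_start_min",
    "window_end_min",
    "concentration_ng_per_ml",
]


def read_profiles_csv(path: str | Path) -> list[ConcentrationProfile]:
    """Read long-format concentration windows into profiles.

    Required columns: subject_id, treatment_id, window_start_min,
    window_end_min, concentration_ng_per_ml; optional: period, lloq_flag.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    has_period = "period" in df.columns
    has_flag = "lloq_flag" in df.columns
    profiles = []
    for (subj, treat), grp in df.groupby(["subject_id", "treatment_id"], sort=True):
        windows = [
            CollectionWindow(
                start_min=row.window_start_min,
                end_min=row.window_end_min,
                concentration=None
                if pd.isna(row.concentration_ng_per_ml)
                else float(row.concentration_ng_per_ml),
                below_lloq=bool(row.lloq_flag) if has_flag else False,
            )
            for row in grp.itertuples()
        ]
        period = int(grp["period"].iloc[0]) if has_period else 1
        profiles.append(ConcentrationProfile(subj, treat, windows, period=period))
    return profiles


def pk_table(
    profiles: Sequence[ConcentrationProfile],
    convention: TimeConvention = "midpoint",
    lloq_policy: LLOQPolicy = "drop",
    lloq: float | None = None,
) -> pd.DataFrame:
    """Per-profile PK summary table (one row per subject x treatment)."""
    rows = []
    for p in profiles:
        r = compute_pk(p, convention, lloq_policy, lloq)
        rows.append(
            {
                "subject_id": r.subject_id,
                "treatment_id": r.treatment_id,
                "period": r.period,
                "cmax": r.cmax,
                "tmax_window": f"{r.tmax_window.start_min:g}-{r.tmax_window.end_min:g}",
                "auc": r.auc,
                "n_windows_used": r.n_windows_used,
            }
        )
    return pd.DataFrame(rows)
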