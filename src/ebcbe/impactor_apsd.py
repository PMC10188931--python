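"""Aerodynamic particle-size-distribution metrics from cascade-impactor data.

A next-generation impactor (NGI) fractionates the emitted aerosol into
stages by aerodynamic cut-size diameter at a fixed flow rate. The induction
throat collects the coarse, non-sized fraction and is excluded from the
sized distribution; the micro-orifice collector (MOC) is the terminal
collector whose mass counts as below every cut size. From the stage masses
this module builds the cumulative percent-undersize curve and derives:

* MMAD - the diameter splitting the sized mass 50/50, interpolated on the
  percent vs ln(diameter) curve (log-linear, the default) or from a probit
  regression of the whole curve;
* GSD  - sqrt(d(84.1%) / d(15.9%)) with the same interpolation choices;
* FPD  - the fine particle dose, mass with aerodynamic diameter below a
  cutoff (5 um by convention), on a per-actuation or per-dose basis;
* FPF  - FPD as a percentage of a chosen dose denominator.

Stage amounts may be masses (ug) or assay concentrations (mg/L) with a
recovery volume; mg/L x mL = ug.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StageDeposit",
    "ImpactorRun",
    "APSDMetrics",
    "FPDComparison",
    "cumulative_undersize",
    "estimate_mmad",
    "estimate_gsd",
    "compute_fpd",
    "compute_fpf",
    "fine_particle_percent",
    "compare_fpd",
    "apsd_metrics",
    "read_impactor_csv",
]

InterpMethod = Literal["loglinear", "probit"]
FPFDenominator = Literal["metered_dose", "delivered_dose", "total_recovered"]
DEFAULT_FPD_CUTOFF_UM = 5.0


@dataclass(frozen=True)
class StageDeposit:
    """Drug recovered from one impactor segment.

    ``cut_size_um`` is ``None`` for the throat (not a sized stage). When
    ``amount_unit`` is ``mg_per_L`` the mass is amount x recovery volume
    (mg/L of a recovery solvent volume in mL gives ug).
    """

    stage_label: str
    cut_size_um: float | None
    amount: float
    amount_unit: Literal["ug", "mg_per_L"] = "ug"
    recovery_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"negative amount on {self.stage_label}")
        if self.cut_size_um is not None and self.cut_size_um <= 0:
            raise ValueError(f"non-positive cut size on {self.stage_label}")
        if self.amount_unit == "mg_per_L" and self.recovery_volume_ml is None:
            raise ValueError(
                f"{self.stage_label}: recovery_volume_ml required for mg_per_L amounts"
            )

    @property
    def mass_ug(self) -> float:
        if self.amount_unit == "ug":
            return float(self.amount)
        return float(self.amount) * float(self.recovery_volume_ml)

    @property
    def is_throat(self) -> bool:
        return self.cut_size_um is None


@dataclass(frozen=True)
class ImpactorRun:
    """One impactor experiment: throat plus sized stages in decreasing cut order."""

    formulation_id: str
    deposits: tuple[StageDeposit, ...]
    flow_rate_lpm: float = 30.0
    n_actuations: int = 1
    label_claim_ug_per_actuation: float | None = None

    def __init__(
        self,
        formulation_id: str,
        deposits: Sequence[StageDeposit],
        flow_rate_lpm: float = 30.0,
        n_actuations: int = 1,
        label_claim_ug_per_actuation: float | None = None,
    ) -> None:
        deposits = tuple(deposits)
        if n_actuations < 1:
            raise ValueError("n_actuations must be >= 1")
        throats = [d for d in deposits if d.is_throat]
        if len(throats) > 1:
            raise ValueError("at most one throat deposit allowed")
        sized = [d for d in deposits if not d.is_throat]
        cuts = [d.cut_size_um for d in sized]
        if any(b >= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("sized stages must have strictly decreasing cut sizes")
        object.__setattr__(self, "formulation_id", str(formulation_id))
        object.__setattr__(self, "deposits", deposits)
        object.__setattr__(self, "flow_rate_lpm", float(flow_rate_lpm))
        object.__setattr__(self, "n_actuations", int(n_actuations))
        object.__setattr__(
            self, "label_claim_ug_per_actuation", label_claim_ug_per_actuation
        )

    @property
    def sized_stages(self) -> tuple[StageDeposit, ...]:
        return tuple(d for d in self.deposits if not d.is_throat)

    @property
    def throat_mass_ug(self) -> float:
        return sum(d.mass_ug for d in self.deposits if d.is_throat)

    @property
    def sized_mass_ug(self) -> float:
        return sum(d.mass_ug for d in self.sized_stages)

    @property
    def total_recovered_ug(self) -> float:
        return self.throat_mass_ug + self.sized_mass_ug


@dataclass(frozen=True)
class APSDMetrics:
    """Summary metrics of one impactor run."""

    formulation_id: str
    mmad_um: float
    gsd: float
    fpd_ug: float
    fpf_percent: float
    total_recovered_ug: float
    sized_mass_ug: float
    cumulative_curve: tuple[tuple[float, float], ...]


def cumulative_undersize(run: ImpactorRun) -> list[tuple[float, float]]:
    """Cumulative percent-undersize curve over the sized stages.

    For each sized-stage cut size d, the curve gives 100 x (mass on all
    stages with cut size below d, MOC included) / (total sized mass). The
    throat is excluded throughout. Returned in decreasing cut-size order;
    the smallest cut carries 0% (nothing is collected below the MOC).
    """
    sized = run.sized_stages
    if len(sized) < 1:
        raise ValueError("run has no sized stages")
    masses = np.array([d.mass_ug for d in sized])
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero sized mass; undersize curve undefined")
    below = np.concatenate([np.cumsum(masses[::-1])[::-1][1:], [0.0]])
    return [
        (float(d.cut_size_um), float(100.0 * b / total))
        for d, b in zip(sized, below)
    ]


def _loglinear_with_band(
    curve: Sequence[tuple[float, float]], target_percent: float
) -> tuple[float, int | None]:
    """Diameter at a target percent-undersize by interpolating percent vs ln(d).

    Also returns the index of the band (pair of adjacent cuts, ascending
    order) the interpolation used, or ``None`` when the target sits exactly
    on a stage cut.
    """
    cuts = np.array([c for c, _ in curve])
    pct = np.array([p for _, p in curve])
    # curve is in decreasing cut order -> pct decreasing; flip to ascending d
    d_asc, p_asc = cuts[::-1], pct[::-1]
    if not (p_asc[0] <= target_percent <= p_asc[-1]):
        raise ValueError(
            f"distribution not resolved: {target_percent}% undersize not "
            f"bracketed by the stage curve ({p_asc[0]:.1f}-{p_asc[-1]:.1f}%)"
        )
    hi = int(np.searchsorted(p_asc, target_percent))
    if p_asc[hi] == target_percent:
        return float(d_asc[hi]), None
    lo = hi - 1
    frac = (target_percent - p_asc[lo]) / (p_asc[hi] - p_asc[lo])
    d = math.exp(
        math.log(d_asc[lo]) + frac * (math.log(d_asc[hi]) - math.log(d_asc[lo]))
    )
    return float(d), lo


def _loglinear_diameter(
    curve: Sequence[tuple[float, float]], target_percent: float
) -> float:
    return _loglinear_with_band(curve, target_percent)[0]


def _probit_diameter(
    curve: Sequence[tuple[float, float]], target_percent: float
) -> float:
    """Diameter at a target percent from a probit(percent) vs ln(d) regression.

    Uses all interior curve points (0 < percent < 100); needs at least two.
    """
    pts = [(c, p) for c, p in curve if 0.0 < p < 100.0]
    if len(pts) < 2:
        raise ValueError("probit fit requires >= 2 interior curve points")
    ln_d = np.log([c for c, _ in pts])
    z = stats.norm.ppf([p / 100.0 for _, p in pts])
    slope, intercept, *_ = stats.linregress(ln_d, z)
    if slope <= 0:
        raise ValueError("probit fit has non-positive slope; curve not usable")
    z_target = stats.norm.ppf(target_percent / 100.0)
    return float(math.exp((z_target - intercept) / slope))


def _diameter_at(
    curve: Sequence[tuple[float, float]],
    target_percent: float,
    method: InterpMethod,
) -> float:
    if method == "loglinear":
        return _loglinear_diameter(curve, target_percent)
    if method == "probit":
        return _probit_diameter(curve, target_percent)
    raise ValueError(f"unknown interpolation method {method!r}")


def estimate_mmad(
    curve: Sequence[tuple[float, float]], method: InterpMethod = "loglinear"
) -> float:
    """Mass median aerodynamic diameter: the 50% point of the undersize curve."""
    return _diameter_at(curve, 50.0, method)


def estimate_gsd(
    curve: Sequence[tuple[float, float]], method: InterpMethod = "loglinear"
) -> float:
    """Geometric standard deviation sqrt(d(84.1%) / d(15.9%)) of the curve.

    With the log-linear method, both tail quantiles landing inside the same
    stage band (as for a near-monodisperse aerosol with all mass on one
    stage) means the impactor did not resolve the distribution's spread, and
    an error is raised rather than an interpolated guess returned.
    """
    if method == "loglinear":
        d84, band84 = _loglinear_with_band(curve, 84.1)
        d16, band16 = _loglinear_with_band(curve, 15.9)
        if band84 is not None and band84 == band16:
            raise ValueError(
                "distribution not resolved: 15.9% and 84.1% quantiles fall "
                "within a single stage band"
            )
    else:
        d84 = _diameter_at(curve, 84.1, method)
        d16 = _diameter_at(curve, 15.9, method)
    if d84 < d16:
        raise ValueError("d(84.1%) < d(15.9%); curve is not monotone in size")
    return math.sqrt(d84 / d16)


def _dose_basis_factor(run: ImpactorRun, dose_basis) -> float:
    """Scale from whole-run mass to the requested dose basis."""
    if dose_basis is None:
        return 1.0
    if dose_basis == "per_actuation":
        return 1.0 / run.n_actuations
    if (
        isinstance(dose_basis, tuple)
        and len(dose_basis) == 2
        and dose_basis[0] == "per_dose"
    ):
        return float(dose_basis[1]) / run.n_actuations
    raise ValueError(f"unknown dose basis {dose_basis!r}")


def compute_fpd(
    run: ImpactorRun,
    cutoff_um: float = DEFAULT_FPD_CUTOFF_UM,
    dose_basis="per_actuation",
) -> float:
    """Fine particle dose: sized mass below ``cutoff_um`` (ug, on the dose basis).

    The sub-cutoff fraction is read off the cumulative undersize curve: full
    stages below the cutoff plus the log-linearly interpolated share of the
    band containing it. When the cutoff exceeds the largest cut size the
    whole sized mass is returned with a warning. ``dose_basis`` is
    ``None`` (whole run), ``"per_actuation"``, or ``("per_dose", n)``.
    """
    curve = cumulative_undersize(run)
    cuts = [c for c, _ in curve]
    factor = _dose_basis_factor(run, dose_basis)
    if cutoff_um > max(cuts):
        warnings.warn(
            f"FPD cutoff {cutoff_um} um above largest cut size {max(cuts)} um; "
            "returning total sized mass",
            stacklevel=2,
        )
        return run.sized_mass_ug * factor
    for c, p in curve:
        if c == cutoff_um:
            return run.sized_mass_ug * p / 100.0 * factor
    d_asc = np.array(cuts[::-1])
    p_asc = np.array([p for _, p in curve])[::-1]
    if cutoff_um < d_asc[0]:
        raise ValueError(
            f"cutoff {cutoff_um} um below smallest cut size {d_asc[0]} um"
        )
    pct = float(np.interp(math.log(cutoff_um), np.log(d_asc), p_asc))
    return run.sized_mass_ug * pct / 100.0 * factor


def fine_particle_percent(fpd_ug: float, dose_ug: float) -> float:
    """FPD expressed as a percentage of a dose mass on the same basis."""
    if dose_ug <= 0:
        raise ValueError("dose mass must be positive")
    return 100.0 * fpd_ug / dose_ug


def compute_fpf(
    fpd_ug: float,
    run: ImpactorRun,
    denominator: FPFDenominator = "total_recovered",
    dose_basis="per_actuation",
) -> float:
    """Fine particle fraction (%): FPD over a dose denominator on the same basis.

    ``metered_dose`` uses the label claim (ex-valve); ``delivered_dose`` and
    ``total_recovered`` both use the total mass recovered from the impactor
    (ex-device) - they coincide here because every measured deposit is
    downstream of the device.
    """
    factor = _dose_basis_factor(run, dose_basis)
    if denominator == "metered_dose":
        if run.label_claim_ug_per_actuation is None:
            raise ValueError("metered_dose denominator requires a label claim")
        denom = run.label_claim_ug_per_actuation * run.n_actuations * factor
    elif denominator in ("delivered_dose", "total_recovered"):
        denom = run.total_recovered_ug * factor
    else:
        raise ValueError(f"unknown FPF denominator {denominator!r}")
    return fine_particle_percent(fpd_ug, denom)


@dataclass(frozen=True)
class FPDComparison:
    """Two-sample t-test summary of replicate FPD values for two products."""

    statistic: float
    df: float
    p_value: float
    significant: bool
    alpha: float
    mean_a: float
    mean_b: float


def compare_fpd(
    fpd_a: Sequence[float],
    fpd_b: Sequence[float],
    equal_var: bool = False,
    alpha: float = 0.05,
) -> FPDComparison:
    """Welch (default) or pooled two-sample t-test on replicate FPD values."""
    a = np.asarray(fpd_a, dtype=float)
    b = np.asarray(fpd_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("compare_fpd requires n >= 2 replicates per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return FPDComparison(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        alpha=alpha,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def apsd_metrics(
    run: ImpactorRun,
    cutoff_um: float = DEFAULT_FPD_CUTOFF_UM,
    method: InterpMethod = "loglinear",
    fpf_denominator: FPFDenominator = "total_recovered",
    dose_basis="per_actuation",
) -> APSDMetrics:
    """All APSD summary metrics for one run."""
    curve = cumulative_undersize(run)
    fpd = compute_fpd(run, cutoff_um, dose_basis)
    return APSDMetrics(
        formulation_id=run.formulation_id,
        mmad_um=estimate_mmad(curve, method),
        gsd=estimate_gsd(curve, method),
        fpd_ug=fpd,
        fpf_percent=compute_fpf(fpd, run, fpf_denominator, dose_basis),
        total_recovered_ug=run.total_recovered_ug,
        sized_mass_ug=run.sized_mass_ug,
        cumulative_curve=tuple(curve),
    )


def read_impactor_csv(path: str | Path) -> list[ImpactorRun]:
    """Read stage-deposition CSV into one run per formulation_id.

    Columns: formulation_id, stage_label, cut_size_um (blank for the
    throat), amount, amount_unit {ug, mg_per_L}, recovery_volume_ml,
    n_actuations, flow_rate_lpm; optional label_claim_ug_per_actuation.
    """
    df = pd.read_csv(path)
    needed = {"formulation_id", "stage_label", "cut_size_um", "amount"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    runs = []
    for fid in df["formulation_id"].drop_duplicates():
        grp = df[df["formulation_id"] == fid]
        deposits = [
            StageDeposit(
                stage_label=str(row.stage_label),
                cut_size_um=None if pd.isna(row.cut_size_um) else float(row.cut_size_um),
                amount=float(row.amount),
                amount_unit=getattr(row, "amount_unit", "ug"),
                recovery_volume_ml=(
                    None
                    if not hasattr(row, "recovery_volume_ml")
                    or pd.isna(row.recovery_volume_ml)
                    else float(row.recovery_volume_ml)
                ),
            )
            for row in grp.itertuples()
        ]
        label = None
        if "label_claim_ug_per_actuation" in grp.columns and not pd.isna(
            grp["label_claim_ug_per_actuation"].iloc[0]
        ):
            label = float(grp["label_claim_ug_per_actuation"].iloc[0])
        runs.append(
            ImpactorRun(
                formulation_id=str(fid),
                deposits=deposits,
                flow_rate_lpm=float(grp["flow_rate_lpm"].iloc[0])
                if "flow_rate_lpm" in grp.columns
                else 30.0,
                n_actuations=int(grp["n_actuations"].iloc[0])
                if "n_actuations" in grp.columns
                else 1,
                label_claim_ug_per_actuation=label,
            )
        )
    return runs
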