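"""Synthetic study-data generators with known ground truth.

Two generators mirror the structure of the data the analysis consumes:

* a two-treatment crossover EBC study - each subject's reference profile
  is a mono-exponentially declining concentration series over the six
  standard 4-minute collection windows, with log-normal between-subject
  variability on the baseline and log-normal within-subject (per
  administration) error; the test arm is scaled so the true geometric mean
  ratios of both Cmax and AUC are controlled independently (the test arm's
  decline half-life is solved so the AUC ratio lands where requested);

* a cascade-impactor run - stage masses are the band probabilities of a
  log-normal aerodynamic size distribution (parameters MMAD and GSD)
  partitioned at the stage cut sizes, a throat fraction held out of the
  sized distribution, and optional multiplicative log-normal stage noise.

Every generator is deterministic given its seed. Defaults are set to
resemble the bundled eight-subject salbutamol study: geometric mean Cmax
near 17.5 ng/mL with ~35% between-subject CV, AUC/Cmax ratio near
43 min (half-life 45 min over the 2-72 min grid), and an impactor run with
~78% throat fraction at 30 L/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .be_analysis import CrossoverDataset, gmr_with_ci
from .impactor_apsd import ImpactorRun, StageDeposit
from .profiles_pk import CollectionWindow, ConcentrationProfile

__all__ = [
    "EBCSimConfig",
    "ImpactorSimConfig",
    "DEFAULT_WINDOWS",
    "DEFAULT_CUT_SIZES_UM",
    "simulate_crossover_ebc",
    "simulate_crossover_metrics",
    "simulate_impactor_run",
    "simulate_impactor_runs",
    "power_surface",
]

DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = (
    (0, 4),
    (14, 18),
    (28, 32),
    (42, 46),
    (56, 60),
    (70, 74),
)
# NGI cut sizes (um) at 30 L/min, stages 1-7 plus the micro-orifice collector
DEFAULT_CUT_SIZES_UM: tuple[float, ...] = (11.8, 6.4, 4.0, 2.3, 1.4, 0.8, 0.5, 0.4)


def _lognormal_sigma(cv: float) -> float:
    """Log-scale sd of a log-normal with the given coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv))


@dataclass(frozen=True)
class EBCSimConfig:
    """Ground-truth parameters of a simulated crossover EBC study."""

    n_subjects: int = 8
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    true_gmr_cmax: float = 0.94
    true_gmr_auc: float = 0.84
    gm_cmax_reference: float = 17.5
    between_subject_cv: float = 0.35
    within_subject_cv: float = 0.30
    decline_halflife_min: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.true_gmr_cmax <= 0 or self.true_gmr_auc <= 0:
            raise ValueError("true GMRs must be positive")
        if self.gm_cmax_reference <= 0:
            raise ValueError("gm_cmax_reference must be positive")
        if self.between_subject_cv < 0 or self.within_subject_cv < 0:
            raise ValueError("CVs must be non-negative")
        if self.decline_halflife_min <= 0:
            raise ValueError("decline half-life must be positive")
        if len(self.windows) < 2:
            raise ValueError("at least 2 collection windows required")


def _shape_auc(halflife: float, t: np.ndarray) -> float:
    """Trapezoid AUC of the unit-peak decline 2**(-(t - t0)/h) on grid t."""
    shape = np.power(2.0, -(t - t[0]) / halflife)
    return float(np.trapezoid(shape, t))


def _solve_test_halflife(
    config: EBCSimConfig, t: np.ndarray
) -> float:
    """Half-life of the test arm such that AUC_test/AUC_ref hits its target.

    With the test baseline scaled by true_gmr_cmax, the required shape-AUC
    ratio is true_gmr_auc / true_gmr_cmax; the shape AUC is strictly
    increasing in the half-life, so a bracketed root always exists for
    ratios achievable on the window grid.
    """
    ratio = config.true_gmr_auc / config.true_gmr_cmax
    target = ratio * _shape_auc(config.decline_halflife_min, t)
    span = float(t[-1] - t[0])

    def f(h: float) -> float:
        return _shape_auc(h, t) - target

    lo, hi = 1e-3, 1e6
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"AUC/Cmax GMR ratio {ratio:.3g} not achievable on a "
            f"{span:g}-minute mono-exponential grid"
        )
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def simulate_crossover_ebc(config: EBCSimConfig) -> list[ConcentrationProfile]:
    """Simulate concentration profiles for both arms of a crossover study.

    Returns two profiles per subject (treatments ``reference`` and
    ``test``), with subjects alternating between the two administration
    sequences. Cmax falls in the first window for every subject because the
    decline is monotone from the first window onward.
    """
    rng = np.random.default_rng(config.seed)
    t = np.array([(a + b) / 2.0 for a, b in config.windows])
    sigma_b = _lognormal_sigma(config.between_subject_cv)
    sigma_w = _lognormal_sigma(config.within_subject_cv)
    h_ref = config.decline_halflife_min
    h_test = _solve_test_halflife(config, t)
    shape_ref = np.power(2.0, -(t - t[0]) / h_ref)
    shape_test = np.power(2.0, -(t - t[0]) / h_test)

    profiles: list[ConcentrationProfile] = []
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        c0 = config.gm_cmax_reference * math.exp(sigma_b * rng.standard_normal())
        e_ref = math.exp(sigma_w * rng.standard_normal()) if sigma_w > 0 else 1.0
        e_test = math.exp(sigma_w * rng.standard_normal()) if sigma_w > 0 else 1.0
        conc_ref = c0 * e_ref * shape_ref
        conc_test = c0 * config.true_gmr_cmax * e_test * shape_test
        # alternate sequence: even-index subjects get reference first
        ref_period, test_period = (1, 2) if i % 2 == 0 else (2, 1)
        for treatment, conc, period in (
            ("reference", conc_ref, ref_period),
            ("test", conc_test, test_period),
        ):
            windows = [
                CollectionWindow(start, end, float(c))
                for (start, end), c in zip(config.windows, conc)
            ]
            profiles.append(
                ConcentrationProfile(subject, treatment, windows, period=period)
            )
    return profiles


def simulate_crossover_metrics(
    n_subjects: int,
    true_gmr: float,
    rng: np.random.Generator,
    gm_reference: float = 17.5,
    between_subject_cv: float = 0.35,
    within_subject_cv: float = 0.30,
    metric_name: str = "cmax",
) -> CrossoverDataset:
    """Simulate paired metric values directly (no profile construction).

    Same generative model as :func:`simulate_crossover_ebc` at the metric
    level: subject baseline log-normal around ``gm_reference``, one
    multiplicative within-subject error per administration, test arm scaled
    by ``true_gmr``. Used for Monte-Carlo studies (power, size, coverage)
    where building full window profiles would add nothing.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    sigma_b = _lognormal_sigma(between_subject_cv)
    sigma_w = _lognormal_sigma(within_subject_cv)
    base = gm_reference * np.exp(sigma_b * rng.standard_normal(n_subjects))
    ref = base * np.exp(sigma_w * rng.standard_normal(n_subjects))
    test = base * true_gmr * np.exp(sigma_w * rng.standard_normal(n_subjects))
    return CrossoverDataset(
        metric_name,
        tuple(f"S{i + 1:03d}" for i in range(n_subjects)),
        tuple(float(v) for v in ref),
        tuple(float(v) for v in test),
    )


@dataclass(frozen=True)
class ImpactorSimConfig:
    """Ground-truth parameters of a simulated impactor run."""

    true_mmad_um: float = 3.0
    true_gsd: float = 2.0
    throat_fraction: float = 0.78
    total_mass_ug: float = 2200.0
    cut_sizes_um: tuple[float, ...] = DEFAULT_CUT_SIZES_UM
    noise_cv: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    flow_rate_lpm: float = 30.0
    n_actuations: int = 10
    label_claim_ug_per_actuation: float = 100.0

    def __post_init__(self) -> None:
        if self.true_mmad_um <= 0:
            raise ValueError("true_mmad_um must be positive")
        if self.true_gsd <= 1.0:
            raise ValueError("true_gsd must exceed 1")
        if not 0.0 <= self.throat_fraction < 1.0:
            raise ValueError("throat_fraction must be in [0, 1)")
        if self.total_mass_ug <= 0:
            raise ValueError("total_mass_ug must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        cuts = self.cut_sizes_um
        if len(cuts) < 3 or any(b >= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut sizes must be >= 3 values, strictly decreasing")


def _band_fractions(config: ImpactorSimConfig) -> np.ndarray:
    """Probability mass per stage band of the log-normal size distribution.

    Stage bands run from each cut size up to the next larger one; the top
    band extends to infinity and the terminal collector's band extends down
    to zero (its nominal cut size sets no lower bound on what it collects).
    """
    mu = math.log(config.true_mmad_um)
    sigma = math.log(config.true_gsd)
    cuts = np.asarray(config.cut_sizes_um)
    cdf_at_cut = norm.cdf((np.log(cuts) - mu) / sigma)
    upper = np.concatenate([[1.0], cdf_at_cut[:-1]])  # CDF at each band's top edge
    lower = np.concatenate([cdf_at_cut[:-1], [0.0]])  # terminal band reaches size 0
    return upper - lower


def simulate_impactor_run(
    config: ImpactorSimConfig, rng: np.random.Generator | None = None
) -> ImpactorRun:
    """One impactor run with stage masses from the configured log-normal APSD."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fractions = _band_fractions(config)
    sized_total = config.total_mass_ug * (1.0 - config.throat_fraction)
    masses = sized_total * fractions
    throat_mass = config.total_mass_ug * config.throat_fraction
    if config.noise_cv > 0:
        sigma = _lognormal_sigma(config.noise_cv)
        masses = masses * np.exp(sigma * rng.standard_normal(masses.size))
        throat_mass *= math.exp(sigma * rng.standard_normal())
    labels = [f"Stage {i + 1}" for i in range(len(config.cut_sizes_um) - 1)] + ["MOC"]
    deposits = [StageDeposit("Throat", None, float(throat_mass))]
    deposits += [
        StageDeposit(label, float(cut), float(mass))
        for label, cut, mass in zip(labels, config.cut_sizes_um, masses)
    ]
    return ImpactorRun(
        formulation_id=f"sim-mmad{config.true_mmad_um:g}-gsd{config.true_gsd:g}",
        deposits=deposits,
        flow_rate_lpm=config.flow_rate_lpm,
        n_actuations=config.n_actuations,
        label_claim_ug_per_actuation=config.label_claim_ug_per_actuation,
    )


def simulate_impactor_runs(config: ImpactorSimConfig) -> list[ImpactorRun]:
    """``n_replicates`` independent runs sharing one seed stream."""
    rng = np.random.default_rng(config.seed)
    return [simulate_impactor_run(config, rng) for _ in range(config.n_replicates)]


def power_surface(
    n_subjects_grid: Sequence[int],
    true_gmr_grid: Sequence[float],
    n_reps: int = 500,
    within_subject_cv: float = 0.30,
    between_subject_cv: float = 0.35,
    ci_level: float = 0.90,
    margin: tuple[float, float] = (0.80, 1.25),
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical probability of declaring BE over a (n, true GMR) grid.

    Each cell simulates ``n_reps`` crossover trials and records the
    fraction whose GMR confidence interval falls inside the margin. At a
    true GMR of 1 power increases with n; at a margin boundary the
    declaration rate approaches the one-sided test size.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable estimate")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_subjects_grid:
        for gmr in true_gmr_grid:
            declared = 0
            for _ in range(n_reps):
                ds = simulate_crossover_metrics(
                    n,
                    gmr,
                    rng,
                    between_subject_cv=between_subject_cv,
                    within_subject_cv=within_subject_cv,
                )
                res = gmr_with_ci(ds, ci_level, margin)
                declared += res.verdict == "bioequivalent"
            rows.append(
                {"n_subjects": n, "true_gmr": gmr, "power": declared / n_reps}
            )
    return pd.DataFrame(rows)
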