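"""Crossover bioequivalence statistics on log-transformed PK metrics.

The analysis is the paired subject-ratio construction standard for
two-treatment crossover BE when no period/sequence decomposition is wanted:
for each subject i, d_i = ln(test_i / reference_i); the geometric mean ratio
(GMR) is exp(mean d) and its 100*(1-2*alpha)% confidence interval is

    exp( mean(d) +/- t_{1-alpha, n-1} * sd(d) / sqrt(n) ),

with the sample standard deviation (n-1 denominator). Bioequivalence is
declared when the 90% CI lies entirely within the 0.80-1.25 margin, which is
equivalent to the two one-sided tests (TOST) procedure at alpha = 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CrossoverDataset",
    "BEResult",
    "BEReport",
    "geometric_mean",
    "gmr_with_ci",
    "tost_pvalues",
    "be_report",
    "read_wide_metrics_csv",
]

DEFAULT_MARGIN = (0.80, 1.25)
Verdict = Literal["bioequivalent", "not_bioequivalent"]


@dataclass(frozen=True)
class CrossoverDataset:
    """Paired PK metric values (one pair per subject) for two treatments."""

    metric_name: str
    subject_ids: tuple[str, ...]
    reference: tuple[float, ...]
    test: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(self.reference) != n or len(self.test) != n:
            raise ValueError("subject_ids, reference and test must have equal length")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject_id in crossover dataset")
        if n < 2:
            raise ValueError("crossover dataset requires n >= 2 subjects")
        if any(v <= 0 for v in self.reference + self.test):
            raise ValueError(
                "all metric values must be strictly positive (log scale analysis)"
            )

    @classmethod
    def from_pairs(
        cls, metric_name: str, pairs: Iterable[tuple[str, float, float]]
    ) -> "CrossoverDataset":
        """Build from (subject_id, reference_value, test_value) triples."""
        subj, ref, test = zip(*[(str(s), float(r), float(t)) for s, r, t in pairs])
        return cls(metric_name, subj, ref, test)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def log_ratios(self) -> np.ndarray:
        return np.log(np.asarray(self.test) / np.asarray(self.reference))

    def swapped(self) -> "CrossoverDataset":
        """Same data with the roles of test and reference exchanged."""
        return CrossoverDataset(
            self.metric_name, self.subject_ids, self.test, self.reference
        )


@dataclass(frozen=True)
class BEResult:
    """Bioequivalence summary for one PK metric."""

    metric_name: str
    n: int
    gm_reference: float
    gm_test: float
    gmr: float
    ci_low: float
    ci_high: float
    ci_level: float
    margin: tuple[float, float]
    verdict: Verdict


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(ln x)) of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty sequence")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def gmr_with_ci(
    dataset: CrossoverDataset,
    ci_level: float = 0.90,
    margin: tuple[float, float] = DEFAULT_MARGIN,
) -> BEResult:
    """Geometric mean ratio with its t-based CI and the TOST margin verdict.

    The margin comparison is inclusive: a CI endpoint exactly equal to a
    margin bound still passes. A zero-variance dataset yields a degenerate
    CI at the point estimate (with a warning) rather than an error.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    if dataset.n < 2:
        raise ValueError("CI undefined for n < 2")
    d = dataset.log_ratios
    n = dataset.n
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if sd_d == 0.0:
        warnings.warn(
            f"zero variance in log ratios for {dataset.metric_name}; "
            "CI degenerates to the point estimate",
            stacklevel=2,
        )
    tq = float(stats.t.ppf(1.0 - (1.0 - ci_level) / 2.0, df=n - 1))
    half_width = tq * sd_d / math.sqrt(n)
    gmr = math.exp(mean_d)
    ci_low = math.exp(mean_d - half_width)
    ci_high = math.exp(mean_d + half_width)
    verdict: Verdict = (
        "bioequivalent"
        if margin[0] <= ci_low and ci_high <= margin[1]
        else "not_bioequivalent"
    )
    return BEResult(
        metric_name=dataset.metric_name,
        n=n,
        gm_reference=geometric_mean(dataset.reference),
        gm_test=geometric_mean(dataset.test),
        gmr=gmr,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_level=ci_level,
        margin=margin,
        verdict=verdict,
    )


def tost_pvalues(
    dataset: CrossoverDataset, margin: tuple[float, float] = DEFAULT_MARGIN
) -> tuple[float, float]:
    """One-sided p-values of the two TOST hypotheses on the log scale.

    Returns (p_lower, p_upper): p_lower tests H0: GMR <= margin_low against
    GMR > margin_low, p_upper tests H0: GMR >= margin_high. Equivalence is
    concluded at level alpha when max(p_lower, p_upper) <= alpha, which
    matches the CI-inclusion rule of :func:`gmr_with_ci` at
    alpha = (1 - ci_level) / 2.
    """
    d = dataset.log_ratios
    n = dataset.n
    se = float(np.std(d, ddof=1)) / math.sqrt(n)
    if se == 0.0:
        inside = math.log(margin[0]) < float(np.mean(d)) < math.log(margin[1])
        return (0.0, 0.0) if inside else (1.0, 1.0)
    t_low = (float(np.mean(d)) - math.log(margin[0])) / se
    t_high = (float(np.mean(d)) - math.log(margin[1])) / se
    p_low = float(stats.t.sf(t_low, df=n - 1))
    p_high = float(stats.t.cdf(t_high, df=n - 1))
    return p_low, p_high


@dataclass(frozen=True)
class BEReport:
    """Per-metric BE results and the all-metrics overall verdict."""

    results: tuple[BEResult, ...]
    overall_verdict: Verdict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metric": r.metric_name,
                    "n": r.n,
                    "gm_reference": r.gm_reference,
                    "gm_test": r.gm_test,
                    "gmr": r.gmr,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "ci_level": r.ci_level,
                    "margin_low": r.margin[0],
                    "margin_high": r.margin[1],
                    "verdict": r.verdict,
                }
                for r in self.results
            ]
        )

    def to_text(self) -> str:
        """Human-readable report: GM, GMR, CI per metric, then the verdict."""
        lines = []
        for r in self.results:
            lines.append(f"{r.metric_name} (n={r.n}):")
            lines.append(
                f"  GM reference = {r.gm_reference:.3g}, GM test = {r.gm_test:.3g}"
            )
            lines.append(
                f"  GMR (test/reference) = {r.gmr:.3g}, "
                f"{r.ci_level:.0%} CI = {r.ci_low:.3g}-{r.ci_high:.3g}"
            )
            lines.append(
                f"  margin {r.margin[0]:g}-{r.margin[1]:g}: {r.verdict}"
            )
        lines.append(f"overall verdict: {self.overall_verdict}")
        return "\n".join(lines)


def be_report(
    datasets: Sequence[CrossoverDataset],
    ci_level: float = 0.90,
    margin: tuple[float, float] = DEFAULT_MARGIN,
) -> BEReport:
    """Run :func:`gmr_with_ci` per metric; overall BE requires all metrics to pass."""
    if not datasets:
        raise ValueError("be_report requires at least one dataset")
    results = tuple(gmr_with_ci(ds, ci_level, margin) for ds in datasets)
    overall: Verdict = (
        "bioequivalent"
        if all(r.verdict == "bioequivalent" for r in results)
        else "not_bioequivalent"
    )
    return BEReport(results=results, overall_verdict=overall)


def read_wide_metrics_csv(
    path, reference_col: str = "value_mdi1", test_col: str = "value_mdi2"
) -> list[CrossoverDataset]:
    """Read a wide metrics CSV (subject_id, metric, value_mdi1, value_mdi2).

    ``reference_col``/``test_col`` select which formulation column plays
    which role; one dataset is returned per distinct metric, in file order.
    """
    df = pd.read_csv(path)
    needed = {"subject_id", "metric", reference_col, test_col}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    datasets = []
    for metric in df["metric"].drop_duplicates():
        grp = df[df["metric"] == metric]
        datasets.append(
            CrossoverDataset.from_pairs(
                str(metric),
                zip(grp["subject_id"], grp[reference_col], grp[test_col]),
            )
        )
    return datasets
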