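"""Seeded synthetic screening cohorts and Monte Carlo validation.

A cohort emulates one round of population screening: each subject
either has an occult tumor (Bernoulli at the configured prevalence) or
not; tumor diameters are drawn from a configurable size distribution;
the number of tumor genome copies captured by the subject's blood draw
is Poisson with mean given by the biophysical model.

Test positivity supports two regimes:

* ``sampling`` (default) — a case tests positive when its draw captured
  at least ``criterion.min_molecules`` tumor genome copies, i.e. the
  mechanistic molecule-counting model; controls test positive only via
  the assay false-positive rate (1 - specificity) when a
  :class:`~ctdna_screen.screening.TestPerformance` is attached.
* ``test`` — positivity is Bernoulli(sensitivity) for cases and
  Bernoulli(1 - specificity) for controls, reproducing a purely
  sensitivity/specificity-defined screening scenario.

Everything is driven by one NumPy generator seeded from the config, so
identical configs produce byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .detection import DetectionCriterion
from .model import (
    DrawSpec,
    ShedModel,
    diameter_to_volume,
    maf_from_volume,
    total_genome_equivalents,
)
from .screening import TestPerformance

__all__ = [
    "CohortConfig",
    "MetricEstimate",
    "generate_cohort",
    "empirical_metrics",
    "sensitivity_by_size",
    "confusion_counts",
    "TABLE1_DIAMETERS_MM",
]

#: Fixed column order of a cohort frame / CSV.
SUBJECT_COLUMNS = [
    "id",
    "has_cancer",
    "tumor_diameter",
    "expected_genomes",
    "sampled_genomes",
    "test_positive",
]

#: The twelve printed diameters of the reference table (mm), used by the
#: ``table1_grid`` size distribution.
TABLE1_DIAMETERS_MM = (27.0, 12.5, 10.0, 8.0, 6.0, 5.0, 4.0, 3.0, 2.4, 2.0, 1.5, 1.1)


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for one synthetic screening cohort.

    The default size distribution is lognormal with median 8 mm and
    log-sd 0.5, chosen to straddle the 10–15 mm detectability band so
    that simulated cohorts exercise both sides of the detection limit;
    it makes no claim of epidemiological realism and is fully
    configurable.
    """

    n: int = 10_000
    prevalence: float = 0.01
    size_distribution: Literal["lognormal", "fixed", "table1_grid"] = "lognormal"
    median_mm: float = 8.0
    log_sd: float = 0.5
    fixed_diameter_mm: float = 10.0
    seed: int = 0
    draw: DrawSpec = field(default_factory=DrawSpec)
    model: ShedModel = field(default_factory=ShedModel)
    criterion: DetectionCriterion = field(default_factory=DetectionCriterion)
    test: TestPerformance | None = None
    positivity: Literal["sampling", "test"] = "sampling"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if self.size_distribution not in ("lognormal", "fixed", "table1_grid"):
            raise ValueError(f"unknown size_distribution {self.size_distribution!r}")
        if self.size_distribution == "lognormal" and self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        if self.size_distribution == "fixed" and self.fixed_diameter_mm < 0:
            raise ValueError("fixed_diameter_mm must be non-negative")
        if self.positivity == "test" and self.test is None:
            raise ValueError("positivity='test' requires a TestPerformance")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass(frozen=True)
class MetricEstimate:
    """A binomial rate with its Wilson 95 % interval.

    ``defined`` is False (and the numeric fields None) when the
    denominator is empty — e.g. specificity in an all-case cohort — so
    undefined metrics are flagged rather than propagated as NaN.
    """

    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: int
    defined: bool = True

    def covers(self, value: float) -> bool:
        if not self.defined:
            return False
        return self.ci_low <= value <= self.ci_high


def _case_diameters(config: CohortConfig, n_cases: int, rng: np.random.Generator):
    if config.size_distribution == "fixed":
        return np.full(n_cases, config.fixed_diameter_mm)
    if config.size_distribution == "table1_grid":
        return rng.choice(TABLE1_DIAMETERS_MM, size=n_cases)
    # lognormal parameterised by its median: mu = ln(median)
    return rng.lognormal(mean=np.log(config.median_mm), sigma=config.log_sd, size=n_cases)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate one screening cohort; deterministic given ``config.seed``.

    Returns a frame with one row per subject and the fixed column order
    ``id, has_cancer, tumor_diameter, expected_genomes, sampled_genomes,
    test_positive``.  Non-cancer subjects shed zero tumor genomes (clonal
    hematopoiesis is out of scope); their positives, if any, come from
    the assay false-positive rate.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    has_cancer = rng.random(n) < config.prevalence
    n_cases = int(has_cancer.sum())

    diameters = np.zeros(n)
    diameters[has_cancer] = _case_diameters(config, n_cases, rng)

    total = total_genome_equivalents(config.draw, config.model)
    volumes = np.array([diameter_to_volume(d) for d in diameters[has_cancer]])
    mafs = np.array([maf_from_volume(v, config.model) for v in volumes])
    expected = np.zeros(n)
    expected[has_cancer] = total * mafs

    sampled = np.zeros(n, dtype=np.int64)
    sampled[has_cancer] = rng.poisson(expected[has_cancer])

    positive = np.zeros(n, dtype=bool)
    if config.positivity == "test":
        u = rng.random(n)
        positive[has_cancer] = u[has_cancer] < config.test.sensitivity
        positive[~has_cancer] = u[~has_cancer] < (1 - config.test.specificity)
    else:
        positive[has_cancer] = sampled[has_cancer] >= config.criterion.min_molecules
        if config.test is not None:
            fp = rng.random(n) < (1 - config.test.specificity)
            positive[~has_cancer] = fp[~has_cancer]

    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "has_cancer": has_cancer,
            "tumor_diameter": diameters,
            "expected_genomes": expected,
            "sampled_genomes": sampled,
            "test_positive": positive,
        },
        columns=SUBJECT_COLUMNS,
    )


def _wilson(numerator: int, denominator: int) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(None, None, None, numerator, 0, defined=False)
    lo, hi = proportion_confint(numerator, denominator, alpha=0.05, method="wilson")
    return MetricEstimate(
        estimate=numerator / denominator,
        ci_low=float(lo),
        ci_high=float(hi),
        numerator=int(numerator),
        denominator=int(denominator),
    )


def confusion_counts(cohort: pd.DataFrame) -> tuple[int, int, int, int]:
    """Observed (TP, FP, TN, FN); always sums to the cohort size."""
    cancer = cohort["has_cancer"].to_numpy()
    pos = cohort["test_positive"].to_numpy()
    tp = int((cancer & pos).sum())
    fp = int((~cancer & pos).sum())
    tn = int((~cancer & ~pos).sum())
    fn = int((cancer & ~pos).sum())
    return tp, fp, tn, fn


def empirical_metrics(cohort: pd.DataFrame) -> dict[str, MetricEstimate]:
    """Counts-based sensitivity, specificity, PPV and NPV with Wilson 95 % CIs."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    tp, fp, tn, fn = confusion_counts(cohort)
    return {
        "sensitivity": _wilson(tp, tp + fn),
        "specificity": _wilson(tn, tn + fp),
        "ppv": _wilson(tp, tp + fp),
        "npv": _wilson(tn, tn + fn),
    }


def sensitivity_by_size(
    cohort: pd.DataFrame, bin_edges: "list[float] | np.ndarray"
) -> pd.DataFrame:
    """Per-diameter-bin detection fraction among cases.

    Bins are half-open ``[lo, hi)`` over tumor diameter in mm and must be
    strictly increasing.  Empty bins are reported with NaN fractions
    (missing, not zero).  Because expected copy number grows with
    diameter, the underlying true curve is monotone non-decreasing.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D sequence")
    cases = cohort[cohort["has_cancer"]]
    idx = np.digitize(cases["tumor_diameter"].to_numpy(), edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n_bin = int(mask.sum())
        n_det = int(cases["test_positive"].to_numpy()[mask].sum())
        rows.append(
            {
                "bin_low_mm": edges[b],
                "bin_high_mm": edges[b + 1],
                "n_cases": n_bin,
                "n_detected": n_det,
                "fraction_detected": (n_det / n_bin) if n_bin else np.nan,
            }
        )
    return pd.DataFrame(rows)
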