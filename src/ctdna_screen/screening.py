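"""Analytic screening-programme performance: PPV, NPV, confusion counts.

Standard Bayes arithmetic on a test with known sensitivity and
specificity applied to a population with known disease prevalence.  The
numbers that matter for multi-cancer early detection are stark: a test
with 10 % sensitivity for early cancers and 99.5 % specificity screening
a population with 1 % cancer prevalence has a positive predictive value
of only ~17 %, and roughly five false positives for every true positive.

Published stage-stratified sensitivities from a large targeted-
methylation case-control validation study are packaged as the reference
scenario ``grail-ccga3``; they are external trial results carried as
constants, never recomputed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .model import _ConfigMixin, round_sig

__all__ = [
    "TestPerformance",
    "ScreeningScenario",
    "ReferenceSensitivities",
    "ConfusionCounts",
    "UndefinedMetricError",
    "GRAIL_CCGA3",
    "ppv",
    "npv",
    "expected_confusion",
    "percent_str",
    "reference_scenario",
]


class UndefinedMetricError(ZeroDivisionError):
    """A predictive value has an empty denominator (no positives/negatives)."""


@dataclass(frozen=True)
class TestPerformance(_ConfigMixin):
    sensitivity: float
    specificity: float
    label: str = ""

    __test__ = False  # not a pytest class, despite the name

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ScreeningScenario(_ConfigMixin):
    """A test applied to a population of known prevalence."""

    test: TestPerformance
    prevalence: float
    n_screened: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.n_screened is not None and (
            self.n_screened < 0 or self.n_screened != int(self.n_screened)
        ):
            raise ValueError("n_screened must be a non-negative integer")

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if isinstance(d.get("test"), dict):
            d["test"] = TestPerformance(**d["test"])
        return cls(**d)


@dataclass(frozen=True)
class ReferenceSensitivities:
    """Stage-stratified sensitivities packaged as printed in the source trial."""

    by_stage: dict[str, float]
    overall: float
    specificity: float

    def __post_init__(self) -> None:
        for v in (*self.by_stage.values(), self.overall, self.specificity):
            if not 0 <= v <= 1:
                raise ValueError("all probabilities must be in [0, 1]")


#: Stage-stratified sensitivities and specificity of the third (final)
#: CCGA validation of the Grail multi-cancer methylation test.
GRAIL_CCGA3 = ReferenceSensitivities(
    by_stage={
        "Stage I": 0.17,
        "Stage II": 0.40,
        "Stages I-II": 0.28,
        "Stages III-VI": 0.84,
    },
    overall=0.52,
    specificity=0.995,
)


class ConfusionCounts(NamedTuple):
    tp: float
    fp: float
    tn: float
    fn: float


def ppv(scenario: ScreeningScenario) -> float:
    """Positive predictive value: P(disease | positive test)."""
    sens, spec = scenario.test.sensitivity, scenario.test.specificity
    prev = scenario.prevalence
    denom = sens * prev + (1 - spec) * (1 - prev)
    if denom == 0:
        raise UndefinedMetricError(
            "PPV undefined: the test never returns a positive result"
        )
    return sens * prev / denom


def npv(scenario: ScreeningScenario) -> float:
    """Negative predictive value: P(no disease | negative test)."""
    sens, spec = scenario.test.sensitivity, scenario.test.specificity
    prev = scenario.prevalence
    denom = spec * (1 - prev) + (1 - sens) * prev
    if denom == 0:
        raise UndefinedMetricError(
            "NPV undefined: the test never returns a negative result"
        )
    return spec * (1 - prev) / denom


def expected_confusion(scenario: ScreeningScenario) -> ConfusionCounts:
    """Expected TP/FP/TN/FN counts; they sum to ``n_screened`` exactly."""
    if scenario.n_screened is None:
        raise ValueError("expected_confusion requires n_screened")
    n = scenario.n_screened
    sens, spec = scenario.test.sensitivity, scenario.test.specificity
    prev = scenario.prevalence
    return ConfusionCounts(
        tp=n * prev * sens,
        fp=n * (1 - prev) * (1 - spec),
        tn=n * (1 - prev) * spec,
        fn=n * prev * (1 - sens),
    )


def percent_str(p: float) -> str:
    """Display convention for probabilities: integer percent at >=10 %,
    two significant figures below (0.16807 -> '17%', 0.0196 -> '2.0%')."""
    pct = p * 100
    if pct >= 10:
        return f"{round(pct):d}%"
    if pct == 0:
        return "0.0%"
    r = round_sig(pct, 2)
    decimals = max(0, 1 - math.floor(math.log10(abs(r))))
    return f"{r:.{decimals}f}%"


def reference_scenario(
    name: str = "grail-ccga3",
    stage: str = "overall",
    prevalence: float = 0.01,
    n_screened: int | None = None,
) -> ScreeningScenario:
    """Build a scenario from a packaged reference test by name and stage."""
    if name != "grail-ccga3":
        raise KeyError(f"unknown reference scenario {name!r}")
    ref = GRAIL_CCGA3
    if stage == "overall":
        sens = ref.overall
    else:
        try:
            sens = ref.by_stage[stage]
        except KeyError:
            raise KeyError(
                f"unknown stage {stage!r}; options: "
                f"{['overall', *ref.by_stage]}"
            ) from None
    test = TestPerformance(sens, ref.specificity, label=f"{name} {stage}")
    return ScreeningScenario(test=test, prevalence=prevalence, n_screened=n_screened)
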