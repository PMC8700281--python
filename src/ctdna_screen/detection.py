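"""Detection probabilities and detection limits for a single blood draw.

Genome copies enter the sampled plasma essentially independently at a
tiny per-molecule probability, so the number of tumor genome copies in a
draw is modelled as Poisson with mean equal to the expected copy number
from :mod:`ctdna_screen.model`.  Two notions of "detected" are offered:

* ``expected_value`` — the draw is informative iff the *expected* copy
  number reaches ``min_molecules`` (the argument "fewer than one cancer
  genome in the tube renders diagnosis impossible");
* ``probabilistic`` — the draw is informative iff the Poisson
  probability of observing at least ``min_molecules`` copies reaches
  ``prob_threshold``.

Inverting either criterion over tumor volume yields a minimum detectable
tumor size; dividing the required copy number by the total genome
equivalents in the draw yields a MAF detection limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import stats

from .model import (
    _ConfigMixin,
    DrawSpec,
    ShedModel,
    TumorSpec,
    expected_cancer_genomes,
    maf_from_volume,
    total_genome_equivalents,
    volume_to_diameter,
)

__all__ = [
    "DetectionCriterion",
    "DetectionResult",
    "DetectionUnsatisfiableError",
    "detection_probability",
    "evaluate_detection",
    "min_detectable_volume",
    "maf_detection_limit",
    "maf_decade_floor",
]

#: Bisection tolerance for volume inversion in probabilistic mode (cm³).
BISECT_TOL_CM3 = 1e-6


class DetectionUnsatisfiableError(ValueError):
    """The detection criterion cannot be met by any tumor volume."""


@dataclass(frozen=True)
class DetectionCriterion(_ConfigMixin):
    """What counts as a positive single-draw detection.

    ``min_molecules`` is the minimum number of tumor genome copies that
    must be present in the draw (k).  ``mode`` selects between the
    expected-value rule and the Poisson probabilistic rule;
    ``prob_threshold`` applies only to the latter.
    """

    min_molecules: int = 1
    mode: Literal["expected_value", "probabilistic"] = "expected_value"
    prob_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_molecules < 0 or self.min_molecules != int(self.min_molecules):
            raise ValueError("min_molecules must be a non-negative integer")
        if self.mode not in ("expected_value", "probabilistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must be in (0, 1)")


@dataclass(frozen=True)
class DetectionResult:
    expected_genomes: float
    p_detect: float
    detectable: bool


def detection_probability(
    expected_genomes: float, criterion: DetectionCriterion | None = None
) -> float:
    """P(at least ``min_molecules`` copies in the draw) under Poisson sampling.

    Equals ``1 - exp(-lam)`` for the default single-molecule criterion.
    """
    criterion = criterion or DetectionCriterion()
    lam = expected_genomes
    if lam < 0:
        raise ValueError(f"expected_genomes must be non-negative, got {lam}")
    k = criterion.min_molecules
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(stats.poisson.sf(k - 1, lam))


def _detectable(lam: float, criterion: DetectionCriterion) -> bool:
    if criterion.mode == "expected_value":
        return lam >= criterion.min_molecules
    return detection_probability(lam, criterion) >= criterion.prob_threshold


def evaluate_detection(
    tumor: TumorSpec,
    draw: DrawSpec | None = None,
    model: ShedModel | None = None,
    criterion: DetectionCriterion | None = None,
    total_genomes: float | None = None,
) -> DetectionResult:
    """Expected copies, detection probability and the criterion's verdict."""
    criterion = criterion or DetectionCriterion()
    lam = expected_cancer_genomes(tumor, draw, model, total_genomes=total_genomes)
    return DetectionResult(
        expected_genomes=lam,
        p_detect=detection_probability(lam, criterion),
        detectable=_detectable(lam, criterion),
    )


def _required_lambda(criterion: DetectionCriterion, lam_max: float) -> float:
    """Smallest Poisson mean satisfying the criterion (may raise)."""
    if criterion.mode == "expected_value":
        return float(criterion.min_molecules)
    if criterion.min_molecules == 0:
        return 0.0
    if not _detectable(lam_max, criterion):
        raise DetectionUnsatisfiableError(
            f"criterion unsatisfiable: P(X >= {criterion.min_molecules}) "
            f"< {criterion.prob_threshold} even at lambda = {lam_max:g}"
        )
    lo, hi = 0.0, lam_max
    # p_detect is continuous and strictly increasing in lambda, so plain
    # bisection to the volume tolerance (applied by the caller's scale).
    while hi - lo > BISECT_TOL_CM3 * 1e-3:
        mid = 0.5 * (lo + hi)
        if _detectable(mid, criterion):
            hi = mid
        else:
            lo = mid
    return hi


def min_detectable_volume(
    draw: DrawSpec | None = None,
    model: ShedModel | None = None,
    criterion: DetectionCriterion | None = None,
    total_genomes: float | None = None,
) -> float:
    """Smallest tumor volume (cm³) the criterion calls detectable.

    Closed form ``k / (G * maf_per_cm3)`` in expected-value mode, where
    G is the draw's total genome equivalents; bisection to 1e-6 cm³ in
    probabilistic mode.  Raises :class:`DetectionUnsatisfiableError`
    when no volume below the MAF cap satisfies the criterion.
    """
    model = model or ShedModel()
    criterion = criterion or DetectionCriterion()
    if total_genomes is None:
        total_genomes = total_genome_equivalents(draw, model)
    if total_genomes <= 0:
        raise DetectionUnsatisfiableError("draw contains no genome equivalents")
    lam_max = total_genomes  # MAF capped at 1
    lam_req = _required_lambda(criterion, lam_max)
    if lam_req > lam_max:
        raise DetectionUnsatisfiableError(
            f"required {lam_req:g} copies exceeds the draw's {lam_max:g} genomes"
        )
    if criterion.mode == "expected_value":
        return lam_req / (total_genomes * model.maf_per_cm3)
    # translate the lambda bracket into a volume bisection at 1e-6 cm³
    v_hi = lam_req / (total_genomes * model.maf_per_cm3)
    lo, hi = 0.0, max(v_hi * 2, BISECT_TOL_CM3)
    while not _detectable(total_genomes * maf_from_volume(hi, model), criterion):
        hi *= 2
    while hi - lo > BISECT_TOL_CM3:
        mid = 0.5 * (lo + hi)
        if _detectable(total_genomes * maf_from_volume(mid, model), criterion):
            hi = mid
        else:
            lo = mid
    return hi


def min_detectable_diameter(
    draw: DrawSpec | None = None,
    model: ShedModel | None = None,
    criterion: DetectionCriterion | None = None,
    total_genomes: float | None = None,
) -> float:
    """Diameter (mm) of the smallest detectable spherical tumor."""
    return volume_to_diameter(
        min_detectable_volume(draw, model, criterion, total_genomes)
    )


def maf_detection_limit(
    draw: DrawSpec | None = None,
    model: ShedModel | None = None,
    criterion: DetectionCriterion | None = None,
    total_genomes: float | None = None,
) -> float:
    """Smallest mutant allele fraction the criterion calls detectable.

    In expected-value mode this is ``min_molecules / G``: with 6000
    genome equivalents per draw and k = 1 the limit is 1.667e-4, whose
    decade floor is the canonical "0.01 %" figure (see
    :func:`maf_decade_floor`).  Doubling the plasma volume halves it.
    """
    model = model or ShedModel()
    criterion = criterion or DetectionCriterion()
    if total_genomes is None:
        total_genomes = total_genome_equivalents(draw, model)
    if total_genomes <= 0:
        raise DetectionUnsatisfiableError("draw contains no genome equivalents")
    lam_req = _required_lambda(criterion, lam_max=total_genomes)
    if lam_req > total_genomes:
        raise DetectionUnsatisfiableError(
            f"required {lam_req:g} copies exceeds the draw's {total_genomes:g} genomes"
        )
    return lam_req / total_genomes


def maf_decade_floor(maf_limit: float) -> float:
    """Largest power-of-ten MAF strictly below a detection limit.

    Every tumor whose MAF sits at or below this decade goes undetected;
    for the default limit of 1.667e-4 the decade is 1e-4, i.e. 0.01 %.
    """
    if maf_limit <= 0:
        raise ValueError("maf_limit must be positive")
    exponent = math.floor(math.log10(maf_limit))
    decade = 10.0 ** exponent
    # exact powers of ten must round *down* a decade ("strictly below")
    if decade >= maf_limit * (1 - 1e-12):
        decade /= 10.0
    return decade
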