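"""Deterministic biophysical chain from tumor size to circulating tumor DNA.

The model links four quantities:

1. tumor geometry — a spherical nodule of diameter *d* mm has volume
   ``(pi/6) * (d/10)**3`` cm³, wet weight 1 g/cm³ and 10⁹ cells/cm³;
2. shedding — the mutant allele fraction (MAF) of plasma cell-free DNA is
   proportional to tumor volume, anchored at MAF 1:10,000 per cm³;
3. plasma cfDNA content — a cfDNA concentration in ng/mL divided by the
   mass of one haploid genome (≈2 × 10¹² Da ≈ 3.3 pg) gives genome
   equivalents per mL of plasma (≈1500/mL at 5 ng/mL);
4. sampling — a blood draw of *B* mL yields ``B * plasma_per_blood`` mL of
   plasma, so the expected number of tumor-derived genome copies in the
   draw is ``total genome equivalents × MAF``.

All units are fixed here and never converted elsewhere: diameter mm,
volume cm³, weight mg, cell counts absolute, plasma mL, cfDNA ng/mL.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Any

import yaml

__all__ = [
    "AVOGADRO_DA_PER_G",
    "CELLS_PER_CM3",
    "MG_PER_CM3",
    "PAPER_GENOMES_PER_DRAW",
    "TumorSpec",
    "ShedModel",
    "DrawSpec",
    "diameter_to_volume",
    "volume_to_diameter",
    "volume_to_cells",
    "maf_from_volume",
    "volume_from_maf",
    "genome_equivalents_per_ml",
    "total_genome_equivalents",
    "expected_cancer_genomes",
    "round_sig",
]

#: Avogadro's number expressed as daltons per gram.
AVOGADRO_DA_PER_G = 6.02214e23

#: Cell density of solid tumor tissue (cells per cm³).
CELLS_PER_CM3 = 1e9

#: Wet-tissue density, 1 g/cm³ expressed in mg per cm³.
MG_PER_CM3 = 1000.0

#: The rounded "6000 genome equivalents per 10 mL blood draw" convention
#: used throughout the reference table; the exact value from the default
#: shedding constants is ≈6022 (see :func:`total_genome_equivalents`).
PAPER_GENOMES_PER_DRAW = 6000.0


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


class _ConfigMixin:
    """JSON/YAML (de)serialization with the dataclass field names."""

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)  # type: ignore[call-overload]

    @classmethod
    def from_dict(cls, d: dict[str, Any]):
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str):
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, s: str):
        return cls.from_dict(yaml.safe_load(s))


@dataclass(frozen=True)
class ShedModel(_ConfigMixin):
    """Constants linking tumor volume to MAF and plasma cfDNA to genomes.

    Parameters
    ----------
    maf_per_cm3
        Mutant allele fraction contributed per cm³ of tumor.  The default
        1e-4 encodes the proportionality anchor "1 cm³ tumor → MAF
        1:10,000" (equivalently 10 cm³ → 1:1000).
    genome_mass_da
        Mass of one complete haploid human genome in daltons.
    cfdna_conc_ng_per_ml
        Total cell-free DNA concentration in plasma (ng/mL); healthy
        individuals fall in the 1–10 ng/mL range, average 5.
    plasma_per_blood
        Plasma fraction of whole blood (mL plasma per mL blood); the
        default 0.4 turns a 10 mL blood draw into 4 mL of plasma.
    """

    maf_per_cm3: float = 1e-4
    genome_mass_da: float = 2e12
    cfdna_conc_ng_per_ml: float = 5.0
    plasma_per_blood: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.maf_per_cm3 <= 1:
            raise ValueError(f"maf_per_cm3 must be in (0, 1], got {self.maf_per_cm3}")
        if self.genome_mass_da <= 0:
            raise ValueError("genome_mass_da must be positive")
        if self.cfdna_conc_ng_per_ml < 0:
            raise ValueError("cfdna_conc_ng_per_ml must be non-negative")
        if not 0 < self.plasma_per_blood < 1:
            raise ValueError("plasma_per_blood must be in (0, 1)")

    @property
    def genome_mass_ng(self) -> float:
        """Mass of one haploid genome in nanograms (≈3.3e-3 ng)."""
        return self.genome_mass_da / AVOGADRO_DA_PER_G * 1e9


@dataclass(frozen=True)
class DrawSpec(_ConfigMixin):
    """A single blood draw.

    ``plasma_ml`` may be given explicitly; when left ``None`` it is
    derived from the governing :class:`ShedModel`'s plasma fraction at
    the point of use (the default 10 mL of blood yields 4 mL of plasma).
    """

    blood_ml: float = 10.0
    plasma_ml: float | None = None

    def __post_init__(self) -> None:
        if self.blood_ml < 0:
            raise ValueError("blood_ml must be non-negative")
        if self.plasma_ml is not None and self.plasma_ml < 0:
            raise ValueError("plasma_ml must be non-negative")

    def resolve_plasma_ml(self, model: ShedModel) -> float:
        if self.plasma_ml is not None:
            return self.plasma_ml
        return self.blood_ml * model.plasma_per_blood


@dataclass(frozen=True)
class TumorSpec:
    """Geometric and cellular description of a single tumor.

    Use :meth:`from_diameter` or :meth:`from_volume` to build a
    self-consistent spherical tumor ("exact" mode), or :meth:`tabulated`
    to carry a row of literature values verbatim, whose printed
    diameter/weight pairs follow rounding conventions that do not match
    exact sphere arithmetic.
    """

    diameter_mm: float
    volume_cm3: float
    weight_mg: float
    cell_count: float

    def __post_init__(self) -> None:
        fields = (self.diameter_mm, self.volume_cm3, self.weight_mg, self.cell_count)
        if any(f < 0 for f in fields):
            raise ValueError("tumor dimensions must be non-negative")
        if any(f == 0 for f in fields) and any(f > 0 for f in fields):
            raise ValueError("tumor fields must be all zero or all positive")

    @classmethod
    def from_diameter(cls, diameter_mm: float) -> "TumorSpec":
        v = diameter_to_volume(diameter_mm)
        return cls(
            diameter_mm=diameter_mm,
            volume_cm3=v,
            weight_mg=MG_PER_CM3 * v,
            cell_count=volume_to_cells(v),
        )

    @classmethod
    def from_volume(cls, volume_cm3: float) -> "TumorSpec":
        return cls(
            diameter_mm=volume_to_diameter(volume_cm3),
            volume_cm3=volume_cm3,
            weight_mg=MG_PER_CM3 * volume_cm3,
            cell_count=volume_to_cells(volume_cm3),
        )

    @classmethod
    def tabulated(
        cls,
        diameter_mm: float,
        weight_mg: float,
        volume_cm3: float,
        cell_count: float,
    ) -> "TumorSpec":
        """Accept printed (rounded) values verbatim, skipping consistency."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "diameter_mm", diameter_mm)
        object.__setattr__(obj, "volume_cm3", volume_cm3)
        object.__setattr__(obj, "weight_mg", weight_mg)
        object.__setattr__(obj, "cell_count", cell_count)
        return obj


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def diameter_to_volume(diameter_mm: float) -> float:
    """Volume (cm³) of a spherical nodule of the given diameter (mm)."""
    if diameter_mm < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter_mm}")
    return math.pi / 6.0 * (diameter_mm / 10.0) ** 3


def volume_to_diameter(volume_cm3: float) -> float:
    """Diameter (mm) of a sphere with the given volume (cm³)."""
    if volume_cm3 < 0:
        raise ValueError(f"volume must be non-negative, got {volume_cm3}")
    return 10.0 * (6.0 * volume_cm3 / math.pi) ** (1.0 / 3.0)


def volume_to_cells(volume_cm3: float) -> float:
    """Cell count at the standard density of 10⁹ cells per cm³."""
    if volume_cm3 < 0:
        raise ValueError(f"volume must be non-negative, got {volume_cm3}")
    return CELLS_PER_CM3 * volume_cm3


# ---------------------------------------------------------------------------
# Shedding: tumor volume <-> mutant allele fraction
# ---------------------------------------------------------------------------

def maf_from_volume(volume_cm3: float, model: ShedModel | None = None) -> float:
    """Mutant allele fraction for a tumor volume, capped at 1.

    Linear in volume: 1 cm³ → 1:10,000 and 10 cm³ → 1:1000 under the
    default anchor.  The cap only matters for absurdly large volumes
    (≥10⁴ cm³ at the default anchor).
    """
    if volume_cm3 < 0:
        raise ValueError(f"volume must be non-negative, got {volume_cm3}")
    model = model or ShedModel()
    return min(1.0, model.maf_per_cm3 * volume_cm3)


def volume_from_maf(maf: float, model: ShedModel | None = None) -> float:
    """Tumor volume (cm³) implied by a mutant allele fraction below the cap."""
    if not 0 <= maf < 1:
        raise ValueError(f"maf must be in [0, 1), got {maf}")
    model = model or ShedModel()
    return maf / model.maf_per_cm3


# ---------------------------------------------------------------------------
# Plasma genome-equivalents accounting
# ---------------------------------------------------------------------------

def genome_equivalents_per_ml(model: ShedModel | None = None) -> float:
    """Whole-genome equivalents per mL of plasma.

    cfDNA concentration divided by the mass of one haploid genome; the
    defaults (5 ng/mL, 2e12 Da) give ≈1505.5, i.e. the familiar "1500
    genomes per mL" at two significant figures.
    """
    model = model or ShedModel()
    return model.cfdna_conc_ng_per_ml / model.genome_mass_ng


def total_genome_equivalents(
    draw: DrawSpec | None = None, model: ShedModel | None = None
) -> float:
    """Genome equivalents in the plasma of one blood draw (≈6022 for 10 mL)."""
    draw = draw or DrawSpec()
    model = model or ShedModel()
    return genome_equivalents_per_ml(model) * draw.resolve_plasma_ml(model)


def expected_cancer_genomes(
    tumor: TumorSpec,
    draw: DrawSpec | None = None,
    model: ShedModel | None = None,
    total_genomes: float | None = None,
) -> float:
    """Expected number of tumor-derived genome copies in one draw.

    ``total genome equivalents × MAF``; may be fractional, in which case
    a typical draw contains no complete cancer genome.  Pass
    ``total_genomes=PAPER_GENOMES_PER_DRAW`` to use the rounded 6000-
    genomes-per-draw convention of the reference table instead of the
    exact concentration-derived value.
    """
    model = model or ShedModel()
    if total_genomes is None:
        total_genomes = total_genome_equivalents(draw, model)
    return total_genomes * maf_from_volume(tumor.volume_cm3, model)
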