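"""Machine-readable reproduction of the reference table and summary report.

``generate_table1`` reproduces the canonical tumor-size table: for each
of twelve diameters from 27 mm down to 1.1 mm, the tumor's weight,
volume, cell count, mutant allele fraction and the expected number of
cancer genomes in a 10 mL blood draw (at the 6000-genomes-per-draw
convention), alongside two literature columns (chance of progression,
mammographic screen sensitivity) that are packaged static data, never
computed.

Printed mode carries the published diameter/weight/volume/cell values
verbatim — they follow a rounded halving series rather than exact sphere
arithmetic — and computes the derived MAF and genome-count columns from
the tabulated volumes, which reproduces the printed genome counts
(6, 0.6, 0.3, 0.15, then "<0.1") exactly.  Exact mode recomputes every
column from the sphere model at the same diameters and flags cells that
disagree with print at two significant figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .detection import (
    DetectionCriterion,
    maf_decade_floor,
    maf_detection_limit,
    min_detectable_diameter,
    min_detectable_volume,
)
from .model import (
    DrawSpec,
    ShedModel,
    diameter_to_volume,
    genome_equivalents_per_ml,
    round_sig,
    total_genome_equivalents,
    volume_to_cells,
    PAPER_GENOMES_PER_DRAW,
    MG_PER_CM3,
)
from .screening import ScreeningScenario, expected_confusion, npv, percent_str, ppv

__all__ = ["Table1Row", "generate_table1", "table1_frame", "summary_report",
           "PRINTED_TABLE1"]

logger = logging.getLogger("ctdna_screen")

#: Display threshold below which the genome-count column prints "<0.1".
GENOME_DISPLAY_FLOOR = 0.1

# Published rows: diameter mm, weight mg, volume cm3, cell count,
# printed MAF ratio string, chance of progression, mammographic screen
# sensitivity.  The last three and the first four are packaged verbatim
# (literature values with their own rounding conventions, e.g. the 5 mm
# row lists 62 mg where the sphere gives 65.4 mg, and the 1.1 mm row's
# diameter does not match the halving series at any standard rounding).
PRINTED_TABLE1: list[tuple[float, float, float, float, str, str | None, str | None]] = [
    (27.0, 10_000, 10.0, 10_000_000_000, "1:1000", None, None),
    (12.5, 1_000, 1.0, 1_000_000_000, "1:10,000", None, None),
    (10.0, 500, 0.5, 500_000_000, "1:20,000", "50%", "91%"),
    (8.0, 250, 0.25, 250_000_000, "1:40,000", "25%", None),
    (6.0, 125, 0.12, 125_000_000, "1:80,000", None, None),
    (5.0, 62, 0.06, 62_000_000, "1:160,000", "6%", "26%"),
    (4.0, 31, 0.03, 32_000_000, "1:320,000", None, None),
    (3.0, 16, 0.015, 16_000_000, "1:640,000", None, None),
    (2.4, 8, 0.007, 8_000_000, "1:1,300,000", None, None),
    (2.0, 4, 0.0035, 4_000_000, "1:2,600,000", None, None),
    (1.5, 2, 0.0017, 2_000_000, "1:5,200,000", None, None),
    (1.1, 1, 0.0008, 1_000_000, "1:10,000,000", "0.05%", None),
]


@dataclass(frozen=True)
class Table1Row:
    diameter_mm: float
    weight_mg: float
    volume_cm3: float
    cell_count: float
    maf: float
    maf_ratio: str
    genomes_per_draw: float
    genomes_display: str
    progression_chance: str | None
    mammography_sensitivity: str | None
    flags: tuple[str, ...] = ()


def _genome_display(value: float) -> str:
    if value < GENOME_DISPLAY_FLOOR:
        return "<0.1"
    return f"{round(value, 10):g}"


def _maf_ratio(maf: float) -> str:
    return f"1:{round(1.0 / maf):,}"


def generate_table1(
    mode: Literal["printed", "exact"] = "printed",
    model: ShedModel | None = None,
    total_genomes: float = PAPER_GENOMES_PER_DRAW,
) -> list[Table1Row]:
    """Build the twelve-row reference table.

    In printed mode the geometry columns and the MAF ratio strings are
    the published values; ``maf`` and ``genomes_per_draw`` are computed
    from the tabulated volume (MAF = 1e-4/cm³ × volume; genomes =
    ``total_genomes`` × MAF).  In exact mode every column is recomputed
    from the sphere model at the printed diameter and the ``flags``
    field lists columns whose exact value differs from print at 2
    significant figures.
    """
    if mode not in ("printed", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    model = model or ShedModel()
    rows: list[Table1Row] = []
    for d, w, v, cells, ratio_printed, prog, mammo in PRINTED_TABLE1:
        if mode == "printed":
            maf = model.maf_per_cm3 * v
            genomes = round(total_genomes * maf, 10)  # strip fp noise for stable TSV
            rows.append(
                Table1Row(
                    diameter_mm=d,
                    weight_mg=w,
                    volume_cm3=v,
                    cell_count=cells,
                    maf=maf,
                    maf_ratio=ratio_printed,
                    genomes_per_draw=genomes,
                    genomes_display=_genome_display(genomes),
                    progression_chance=prog,
                    mammography_sensitivity=mammo,
                )
            )
        else:
            v_exact = diameter_to_volume(d)
            w_exact = MG_PER_CM3 * v_exact
            cells_exact = volume_to_cells(v_exact)
            maf = model.maf_per_cm3 * v_exact
            genomes = total_genomes * maf
            flags = tuple(
                name
                for name, exact, printed in [
                    ("weight_mg", w_exact, w),
                    ("volume_cm3", v_exact, v),
                    ("cell_count", cells_exact, cells),
                ]
                if round_sig(exact, 2) != round_sig(printed, 2)
            )
            rows.append(
                Table1Row(
                    diameter_mm=d,
                    weight_mg=w_exact,
                    volume_cm3=v_exact,
                    cell_count=cells_exact,
                    maf=maf,
                    maf_ratio=_maf_ratio(maf),
                    genomes_per_draw=genomes,
                    genomes_display=_genome_display(genomes),
                    progression_chance=prog,
                    mammography_sensitivity=mammo,
                    flags=flags,
                )
            )
    return rows


def table1_frame(
    mode: Literal["printed", "exact"] = "printed", **kwargs
) -> pd.DataFrame:
    """The table as a DataFrame with a stable column order (TSV/CSV ready)."""
    rows = generate_table1(mode, **kwargs)
    df = pd.DataFrame([vars(r) for r in rows])
    df["flags"] = df["flags"].map(lambda f: ";".join(f))
    return df


def summary_report(
    draw: DrawSpec | None = None,
    model: ShedModel | None = None,
    criterion: DetectionCriterion | None = None,
    scenario: ScreeningScenario | None = None,
    total_genomes: float | None = None,
) -> dict:
    """Deterministic headline-numbers report.

    Contains the genome-equivalents accounting, the detection limits
    (minimum detectable tumor volume/diameter, MAF limit and its decade
    floor) and, when a screening scenario is supplied, the PPV/NPV block
    with expected confusion counts.  All governing constants are echoed
    under ``"constants"`` for provenance.
    """
    draw = draw or DrawSpec()
    model = model or ShedModel()
    criterion = criterion or DetectionCriterion()

    per_ml = genome_equivalents_per_ml(model)
    total_exact = total_genome_equivalents(draw, model)
    total = total_exact if total_genomes is None else total_genomes

    v_min = min_detectable_volume(draw, model, criterion, total_genomes=total)
    d_min = min_detectable_diameter(draw, model, criterion, total_genomes=total)
    maf_min = maf_detection_limit(draw, model, criterion, total_genomes=total)
    decade = maf_decade_floor(maf_min)

    report: dict = {
        "constants": {
            "model": model.to_dict(),
            "draw": {
                "blood_ml": draw.blood_ml,
                "plasma_ml": draw.resolve_plasma_ml(model),
            },
            "criterion": {
                "min_molecules": criterion.min_molecules,
                "mode": criterion.mode,
                "prob_threshold": criterion.prob_threshold,
            },
        },
        "genome_equivalents": {
            "per_ml_plasma": per_ml,
            "per_ml_plasma_2sf": round_sig(per_ml, 2),
            "per_draw": total_exact,
            "per_draw_2sf": round_sig(total_exact, 2),
            "per_draw_used": total,
        },
        "detection": {
            "min_detectable_volume_cm3": v_min,
            "min_detectable_diameter_mm": round(d_min, 1),
            "maf_detection_limit": maf_min,
            "maf_decade_limit": decade,
            "maf_decade_limit_pct": f"{decade * 100:g}%",
        },
    }
    if scenario is not None:
        block = {
            "sensitivity": scenario.test.sensitivity,
            "specificity": scenario.test.specificity,
            "prevalence": scenario.prevalence,
            "ppv": ppv(scenario),
            "ppv_pct": percent_str(ppv(scenario)),
            "npv": npv(scenario),
            "npv_pct": percent_str(npv(scenario)),
        }
        if scenario.n_screened is not None:
            tp, fp, tn, fn = expected_confusion(scenario)
            block["expected_counts"] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
        report["screening"] = block
    logger.info(
        "summary: %.0f genomes/draw, detection limit %.1f mm / MAF %s",
        total,
        d_min,
        report["detection"]["maf_decade_limit_pct"],
    )
    return report
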