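"""Published group summaries for the NHE6-null (Christianson syndrome)
mouse study, keyed in as analysis inputs.

The study reports its data as per-cell (mean, SEM, n) summaries; those
printed summaries are the inputs from which every downstream quantity —
growth/degeneration coefficients, atrophy percentages, test statistics —
is recomputed at run time.  Nothing in this module stores a fitted
coefficient or a p-value.

Groups:

* gross brain areas (cm²) for whole brain, cortex, cerebellum and
  cerebellum+midbrain at P0, 1, 2, 6 and 23 mo (the 23–26 mo pooled group
  is recorded at 23 mo);
* histology thickness/area cells (mm or mm²) at 2 and 22 mo;
* Purkinje-cell linear densities (cells/100 µm) and calbindin signal
  fractions (%) per cerebellar subregion;
* microglia counts per tiled region set and CD68 puncta sizes (µm²).
"""

from __future__ import annotations

from .records import Genotype, MeasureKind, SummaryCell

__all__ = [
    "gross_area_cells",
    "gross_area_anchors",
    "histology_cells",
    "pc_density_cells",
    "calbindin_signal_cells",
    "microglia_count_cells",
    "puncta_size_cells",
    "GROWTH_PHASE_END",
    "PHASE_BOUNDARIES",
]

PHASE_BOUNDARIES = (0.0, 1.0, 2.0, 6.0, 23.0)
GROWTH_PHASE_END = 6.0

# region, age_months, WT (mean, sem, n), MUT (mean, sem, n) — gross areas, cm^2
_GROSS_AREAS = [
    ("whole_brain", 0.0, (0.376, 0.021, 9), (0.394, 0.011, 12)),
    ("whole_brain", 1.0, (1.015, 0.012, 11), (1.030, 0.030, 7)),
    ("whole_brain", 2.0, (1.257, 0.033, 8), (1.112, 0.042, 6)),
    ("whole_brain", 6.0, (1.326, 0.011, 7), (1.243, 0.011, 6)),
    ("whole_brain", 23.0, (1.105, 0.013, 4), (1.0068, 0.0073, 5)),
    ("cortex", 0.0, (0.244, 0.013, 9), (0.2499, 0.0083, 12)),
    ("cortex", 1.0, (0.7527, 0.0074, 11), (0.766, 0.020, 7)),
    ("cortex", 2.0, (0.908, 0.027, 8), (0.808, 0.030, 6)),
    ("cortex", 6.0, (0.949, 0.011, 7), (0.907, 0.012, 6)),
    ("cortex", 23.0, (0.7723, 0.0089, 4), (0.7501, 0.0031, 5)),
    ("cerebellum", 0.0, (0.0316, 0.0024, 9), (0.0323, 0.0016, 12)),
    ("cerebellum", 1.0, (0.2188, 0.0050, 11), (0.2210, 0.0088, 7)),
    ("cerebellum", 2.0, (0.2913, 0.0056, 8), (0.254, 0.011, 6)),
    ("cerebellum", 6.0, (0.3006, 0.0037, 7), (0.2590, 0.0059, 6)),
    ("cerebellum", 23.0, (0.2483, 0.0078, 4), (0.1760, 0.0057, 5)),
    ("cerebellum_midbrain", 0.0, (0.153, 0.014, 9), (0.1441, 0.0029, 12)),
    ("cerebellum_midbrain", 1.0, (0.2619, 0.0062, 11), (0.264, 0.010, 7)),
    ("cerebellum_midbrain", 2.0, (0.3484, 0.0083, 8), (0.304, 0.016, 6)),
    ("cerebellum_midbrain", 6.0, (0.3776, 0.0012, 7), (0.3365, 0.0078, 6)),
    ("cerebellum_midbrain", 23.0, (0.3124, 0.0064, 4), (0.2368, 0.0068, 5)),
]

# region, measure_kind, age, WT, MUT — histology sections (Nissl)
_HISTOLOGY = [
    ("cortex", MeasureKind.thickness, 2.0, (1.154, 0.018, 3), (1.126, 0.029, 3)),
    ("cortex", MeasureKind.thickness, 22.0, (1.210, 0.029, 3), (1.090, 0.018, 3)),
    ("striatum", MeasureKind.tissue_area, 2.0, (4.060, 0.077, 3), (3.83, 0.12, 3)),
    ("striatum", MeasureKind.tissue_area, 22.0, (4.689, 0.030, 3), (4.062, 0.045, 3)),
    ("hippocampus", MeasureKind.tissue_area, 2.0, (2.199, 0.011, 3), (2.113, 0.062, 3)),
    ("hippocampus", MeasureKind.tissue_area, 22.0, (2.455, 0.047, 3), (2.074, 0.068, 3)),
    ("cerebellum", MeasureKind.tissue_area, 2.0, (6.53, 0.15, 3), (5.91, 0.16, 3)),
    ("cerebellum", MeasureKind.tissue_area, 22.0, (7.128, 0.014, 2), (4.586, 0.089, 4)),
    ("spinal_cord", MeasureKind.width, 22.0, (1.890, 0.073, 2), (1.491, 0.073, 2)),
    ("other:spinal_cord_region2", MeasureKind.width, 22.0, (1.987, 0.080, 2), (1.845, 0.033, 2)),
]

# cerebellar subregion, age (11-13 mo recorded as 12), WT, MUT — cells/100 um
# (the 6-mo rows are from the exons 2/3 null line; the rest from the exon 6 line)
_PC_DENSITY = [
    ("other:primary_fissure", 5.0, (2.94, 0.13, 3), (1.99, 0.24, 3)),
    ("other:primary_fissure", 12.0, (3.28, 0.28, 5), (0.77, 0.26, 4)),
    ("other:anterior_lobe", 5.0, (3.27, 0.24, 3), (0.74, 0.44, 4)),
    ("other:anterior_lobe", 12.0, (3.22, 0.30, 4), (0.21, 0.13, 3)),
    ("other:flocculonodular_lobe", 5.0, (3.49, 0.36, 3), (2.42, 0.52, 3)),
    ("other:flocculonodular_lobe", 12.0, (3.31, 0.43, 4), (2.78, 0.51, 3)),
    ("other:primary_fissure", 6.0, (3.25, 0.07, 2), (1.02, 0.38, 3)),
    ("other:anterior_lobe", 6.0, (3.80, 0.12, 2), (0.84, 0.58, 3)),
    ("other:flocculonodular_lobe", 6.0, (3.51, 0.43, 2), (3.24, 0.54, 3)),
]

# calbindin-positive area fraction (%) in the vermal primary fissure
_CALBINDIN = [
    ("other:primary_fissure", 5.0, (32.9, 2.8, 4), (15.5, 1.7, 4)),
    ("other:primary_fissure", 12.0, (30.7, 3.6, 6), (8.80, 0.92, 4)),
]

# Iba1-positive microglia summed over the tiled fields per region, 22 mo
_MICROGLIA = [
    ("cortex", (159.0, 15.0, 3), (219.0, 10.0, 4)),
    ("striatum", (398.7, 5.6, 3), (568.0, 30.0, 4)),
    ("hippocampus_CA", (74.0, 4.4, 3), (100.0, 3.4, 4)),
    ("hippocampus_DG", (56.0, 6.7, 3), (67.3, 3.9, 4)),
]

# CD68 puncta size inside Iba1-positive cells (um^2), 22 mo
_PUNCTA = [
    ("cortex", (19.76, 0.49, 3), (28.0, 2.0, 3)),
    ("striatum", (20.5, 2.0, 3), (29.9, 4.0, 3)),
    ("hippocampus_DG", (7.2, 2.2, 3), (10.8, 2.5, 3)),
]


def _cells(rows, kind: MeasureKind, age_index=None) -> list[SummaryCell]:
    out = []
    for row in rows:
        if age_index is None:
            region, wt, mut = row
            age = 22.0
        else:
            region, age, wt, mut = row
        for genotype, (mean, sem, n) in (("WT", wt), ("MUT", mut)):
            out.append(
                SummaryCell(
                    genotype=genotype,
                    age_months=float(age),
                    region=region,
                    measure_kind=kind,
                    mean=mean,
                    sem=sem,
                    n=n,
                    age_range="23-26" if (kind is MeasureKind.gross_area and age == 23.0)
                    else ("11-13" if age == 12.0 else ""),
                )
            )
    return out


def gross_area_cells() -> list[SummaryCell]:
    """Gross-area summary cells (cm²) per region x genotype x age."""
    rows = [(r, a, wt, mut) for r, a, wt, mut in _GROSS_AREAS]
    return _cells(rows, MeasureKind.gross_area, age_index=1)


def gross_area_anchors(region: str, genotype: str) -> list[tuple[float, float]]:
    """(age, mean area) anchors for one region x genotype trajectory."""
    genotype = Genotype(genotype)
    out = [
        (age, (wt if genotype is Genotype.WT else mut)[0])
        for r, age, wt, mut in _GROSS_AREAS
        if r == region
    ]
    if not out:
        raise KeyError(f"no gross-area data for region {region!r}")
    return sorted(out)


def histology_cells(age_months: float | None = None) -> list[SummaryCell]:
    """Sectioned thickness/area cells; optionally restricted to one age."""
    cells = []
    for region, kind, age, wt, mut in _HISTOLOGY:
        if age_months is not None and age != age_months:
            continue
        cells.extend(_cells([(region, age, wt, mut)], kind, age_index=1))
    return cells


def pc_density_cells(age_months: float | None = None) -> list[SummaryCell]:
    """Purkinje-cell linear densities per cerebellar subregion."""
    rows = [r for r in _PC_DENSITY if age_months is None or r[1] == age_months]
    return _cells(rows, MeasureKind.pc_density, age_index=1)


def calbindin_signal_cells() -> list[SummaryCell]:
    return _cells(_CALBINDIN, MeasureKind.signal_fraction, age_index=1)


def microglia_count_cells() -> list[SummaryCell]:
    return _cells(_MICROGLIA, MeasureKind.cell_count)


def puncta_size_cells() -> list[SummaryCell]:
    return _cells(_PUNCTA, MeasureKind.puncta_area)
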