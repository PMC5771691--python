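"""Animal-level measurement records, group summaries, and tabular I/O.

The study design is cross-sectional: each (genotype, age, region, measure)
cell is observed in a different set of animals, and the published data are
the per-cell mean, standard error of the mean (SEM), and animal count *n*.
This module defines the row-level record type, the (mean, SEM, n) summary
cell, and readers/writers for the TSV/CSV/JSON interchange formats used by
the rest of the package.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "Sex",
    "MeasureKind",
    "MeasurementRecord",
    "SummaryCell",
    "MeasurementParseError",
    "CANONICAL_REGIONS",
    "EXPECTED_UNITS",
    "validate_region",
    "read_measurements",
    "summarize_groups",
    "write_table",
    "read_summary_cells",
]


class Genotype(str, enum.Enum):
    WT = "WT"
    MUT = "MUT"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class MeasureKind(str, enum.Enum):
    gross_area = "gross_area"
    tissue_area = "tissue_area"
    thickness = "thickness"
    width = "width"
    pc_density = "pc_density"
    signal_fraction = "signal_fraction"
    cell_count = "cell_count"
    puncta_area = "puncta_area"


#: Canonical region labels.  Free-form labels are allowed with an
#: ``other:`` prefix (e.g. ``other:anterior_lobe``).
CANONICAL_REGIONS = frozenset(
    {
        "whole_brain",
        "cortex",
        "cerebellum",
        "cerebellum_midbrain",
        "striatum",
        "hippocampus",
        "hippocampus_CA",
        "hippocampus_DG",
        "spinal_cord",
    }
)

#: Unit expected for each measure kind (canonical ASCII spelling).
EXPECTED_UNITS: dict[MeasureKind, str] = {
    MeasureKind.gross_area: "cm^2",
    MeasureKind.tissue_area: "mm^2",
    MeasureKind.thickness: "mm",
    MeasureKind.width: "mm",
    MeasureKind.pc_density: "cells/100um",
    MeasureKind.signal_fraction: "%",
    MeasureKind.cell_count: "count",
    MeasureKind.puncta_area: "um^2",
}

# Accepted spelling variants -> canonical unit string.
_UNIT_ALIASES = {
    "cm2": "cm^2",
    "cm^2": "cm^2",
    "cm²": "cm^2",
    "mm2": "mm^2",
    "mm^2": "mm^2",
    "mm²": "mm^2",
    "mm": "mm",
    "cells/100um": "cells/100um",
    "cells/100µm": "cells/100um",
    "cells/100μm": "cells/100um",
    "%": "%",
    "percent": "%",
    "count": "count",
    "um^2": "um^2",
    "um2": "um^2",
    "µm^2": "um^2",
    "µm²": "um^2",
    "μm^2": "um^2",
    "μm²": "um^2",
}


def normalize_unit(unit: str) -> str:
    """Map a unit spelling (incl. Unicode superscripts/micro signs) to its
    canonical ASCII form, or raise ``ValueError`` for an unknown unit."""
    key = unit.strip()
    try:
        return _UNIT_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r}") from None


def validate_region(label: str) -> str:
    label = label.strip()
    if label in CANONICAL_REGIONS or label.startswith("other:"):
        return label
    raise ValueError(
        f"unknown region {label!r}; expected one of {sorted(CANONICAL_REGIONS)} "
        "or an 'other:<label>' tag"
    )


@dataclass(frozen=True)
class MeasurementRecord:
    """One quantitative observation from one animal."""

    subject_id: str
    genotype: Genotype
    sex: Sex
    age_months: float
    region: str
    measure_kind: MeasureKind
    value: float
    units: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "measure_kind", MeasureKind(self.measure_kind))
        object.__setattr__(self, "region", validate_region(self.region))
        object.__setattr__(self, "units", normalize_unit(self.units))
        if not math.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value!r}")
        if not (self.age_months >= 0):
            raise ValueError(f"age_months must be >= 0, got {self.age_months!r}")
        expected = EXPECTED_UNITS[self.measure_kind]
        if self.units != expected:
            raise ValueError(
                f"measure kind {self.measure_kind.value!r} carries unit "
                f"{expected!r}, got {self.units!r}"
            )


@dataclass(frozen=True)
class SummaryCell:
    """(mean, SEM, n) for one genotype x age x region x measure cell.

    ``sem`` is the sample SD (n-1 denominator) divided by sqrt(n); it is 0
    when n = 1 (flagged via ``n_of_one``) or when all values coincide.
    ``age_range`` optionally annotates pooled age groups (e.g. "23-26"
    recorded at age 23).
    """

    genotype: Genotype
    age_months: float
    region: str
    measure_kind: MeasureKind
    mean: float
    sem: float
    n: int
    n_of_one: bool = False
    age_range: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        object.__setattr__(self, "measure_kind", MeasureKind(self.measure_kind))
        object.__setattr__(self, "region", validate_region(self.region))
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")

    @property
    def sd(self) -> float:
        """Sample SD reconstructed as SEM * sqrt(n)."""
        return self.sem * math.sqrt(self.n)

    def key(self) -> tuple:
        return (self.genotype.value, self.age_months, self.region, self.measure_kind.value)


MEASUREMENT_COLUMNS = [
    "subject_id",
    "genotype",
    "sex",
    "age_months",
    "region",
    "measure_kind",
    "value",
    "units",
]


class MeasurementParseError(ValueError):
    """Raised when a measurement table contains malformed rows.

    ``errors`` is a list of (line_number, message) pairs; line numbers are
    1-based positions in the file (the header is line 1).
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "\n".join(f"  line {ln}: {msg}" for ln, msg in errors)
        super().__init__(f"{len(errors)} malformed row(s):\n{lines}")


def _sep_for(path: pathlib.Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_measurements(
    path: str | pathlib.Path, delimiter: str | None = None
) -> list[MeasurementRecord]:
    """Read animal-level measurements from a TSV/CSV file.

    The delimiter is inferred from the extension (``.csv`` -> comma,
    anything else -> tab) unless given explicitly.  Every row either parses
    into a :class:`MeasurementRecord` or contributes a line-numbered entry
    to a single :class:`MeasurementParseError`.
    """
    path = pathlib.Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, delimiter), dtype=str)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    records: list[MeasurementRecord] = []
    errors: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2  # header occupies line 1
        try:
            records.append(
                MeasurementRecord(
                    subject_id=str(row["subject_id"]),
                    genotype=row["genotype"],
                    sex=row["sex"],
                    age_months=float(row["age_months"]),
                    region=row["region"],
                    measure_kind=row["measure_kind"],
                    value=float(row["value"]),
                    units=row["units"],
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append((line_no, str(exc)))
    if errors:
        raise MeasurementParseError(errors)
    return records


def summarize_groups(
    records: Iterable[MeasurementRecord],
    keys: Sequence[str] = ("genotype", "age_months", "region", "measure_kind"),
) -> list[SummaryCell]:
    """Reduce records to (mean, SEM, n) cells, one per unique key.

    SEM uses the n-1 sample SD; a single-animal cell gets sem = 0 and is
    flagged ``n_of_one``.  Output order is deterministic (sorted by key)
    and independent of input order.
    """
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return []
    frame = pd.DataFrame(rows)
    for col in ("genotype", "sex", "measure_kind"):
        frame[col] = frame[col].map(lambda v: v.value if isinstance(v, enum.Enum) else v)
    cells: list[SummaryCell] = []
    for key_vals, grp in sorted(frame.groupby(list(keys)), key=lambda kv: str(kv[0])):
        info = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        vals = grp["value"].to_numpy(dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        cells.append(
            SummaryCell(
                genotype=info.get("genotype", "WT"),
                age_months=float(info.get("age_months", 0.0)),
                region=info.get("region", "whole_brain"),
                measure_kind=info.get("measure_kind", "gross_area"),
                mean=float(np.mean(vals)),
                sem=sem,
                n=n,
                n_of_one=(n == 1),
            )
        )
    return cells


def _format_value(x, precision: int) -> str:
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, float) or isinstance(x, np.floating):
        return f"{x:.{precision}g}"
    if isinstance(x, enum.Enum):
        return str(x.value)
    return str(x)


def _to_plain_rows(objects: Iterable) -> list[dict]:
    rows = []
    for obj in objects:
        if dataclasses.is_dataclass(obj):
            d = dataclasses.asdict(obj)
        elif isinstance(obj, dict):
            d = dict(obj)
        else:
            raise TypeError(f"cannot tabulate object of type {type(obj)!r}")
        rows.append({k: (v.value if isinstance(v, enum.Enum) else v) for k, v in d.items()})
    return rows


def write_table(
    objects: Iterable,
    path: str | pathlib.Path,
    fmt: str | None = None,
    precision: int = 6,
) -> pathlib.Path:
    """Write dataclass instances (records, cells, results) as TSV/CSV/JSON.

    Floats are rendered with ``precision`` significant digits in the
    delimited formats; JSON keeps native numbers and mirrors field names.
    An empty collection yields a header-only file (records/cells) or an
    empty JSON array.
    """
    path = pathlib.Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "tsv"
    rows = _to_plain_rows(objects)
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2, default=float) + "\n", encoding="utf-8")
        return path
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    header = list(rows[0].keys()) if rows else MEASUREMENT_COLUMNS
    lines = [sep.join(header)]
    for row in rows:
        lines.append(sep.join(_format_value(row[c], precision) for c in header))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_summary_cells(path: str | pathlib.Path, delimiter: str | None = None) -> list[SummaryCell]:
    """Read a (mean, SEM, n) summary table written by :func:`write_table`."""
    path = pathlib.Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, delimiter))
    cells = []
    for _, row in frame.iterrows():
        cells.append(
            SummaryCell(
                genotype=row["genotype"],
                age_months=float(row["age_months"]),
                region=row["region"],
                measure_kind=row["measure_kind"],
                mean=float(row["mean"]),
                sem=float(row["sem"]),
                n=int(row["n"]),
                n_of_one=bool(row.get("n_of_one", False)),
                age_range=str(row.get("age_range", "") or ""),
            )
        )
    return cells
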