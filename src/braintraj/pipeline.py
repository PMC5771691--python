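"""Pipeline orchestration: configuration, staged execution, and reporting.

Stages run in a fixed order — input, summaries, growth model,
counterfactuals, statistics, morphometry, report — and each stage's
outputs are written before the next begins, so a failed run leaves its
completed stages on disk together with a machine-readable error record.
Numeric tables are rendered with a fixed precision and deterministic row
order, so two runs with the same configuration and seed produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import reference
from .kinetics import (
    ModelVariant,
    TrajectoryFit,
    fit_baseline,
    fit_counterfactual,
    percent_decrease,
)
from .records import (
    MeasureKind,
    SummaryCell,
    read_measurements,
    summarize_groups,
    write_table,
)
from .stats import p_stars, t_test_two_sample
from .synthetic import CohortSpec, ImageSpec, default_cohort_spec, gen_cohort

__all__ = ["PipelineConfig", "run", "report", "PipelineError"]

log = logging.getLogger("braintraj")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Validated run configuration; serialized into every output directory.

    ``source`` selects the input stage: ``reference`` (the packaged
    published group summaries), ``simulate`` (a synthetic cohort), or
    ``file`` (a measurement TSV/CSV named by ``input_path``).
    """

    source: str = "reference"
    input_path: str = ""
    outdir: str = "braintraj_out"
    seed: int = 0
    regions: tuple[str, ...] = ("cortex", "cerebellum")
    growth_phase_end: float = 6.0
    welch: bool = False
    alpha: float = 0.05
    precision: int = 6
    cohort_n_per_age: int = 8
    cohort_cv: float = 0.05
    image_specs: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if self.source not in ("reference", "simulate", "file"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "file" and not self.input_path:
            raise ValueError("source 'file' requires input_path")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.regions = tuple(self.regions)
        self.image_specs = tuple(dict(s) for s in self.image_specs)

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "PipelineConfig":
        d = yaml.safe_load(pathlib.Path(path).read_text(encoding="utf-8")) or {}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = list(self.regions)
        d["image_specs"] = [dict(s) for s in self.image_specs]
        return d

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _fit_frame(fits: list[TrajectoryFit]) -> list[dict]:
    rows = []
    for fit in fits:
        for ph in fit.phases:
            rows.append(
                {
                    "region": fit.region,
                    "genotype": fit.genotype.value,
                    "variant": ph.model_variant.value,
                    "t_start": ph.t_start,
                    "t_end": ph.t_end,
                    "rate": ph.rate,
                    "G": ph.G,
                    "D": ph.D,
                    "feasible": ph.feasible,
                }
            )
    return rows


def _cells_by_key(cells: list[SummaryCell]) -> dict[tuple, SummaryCell]:
    return {c.key(): c for c in cells}


def _stage_input(config: PipelineConfig, outdir: pathlib.Path) -> list[SummaryCell]:
    if config.source == "reference":
        cells = (
            reference.gross_area_cells()
            + reference.histology_cells()
            + reference.pc_density_cells()
            + reference.calbindin_signal_cells()
            + reference.microglia_count_cells()
            + reference.puncta_size_cells()
        )
        return cells
    if config.source == "simulate":
        spec = default_cohort_spec(
            seed=config.seed, n_per_age=config.cohort_n_per_age, cv=config.cohort_cv
        )
        records, truth = gen_cohort(spec)
        write_table(records, outdir / "records.tsv", precision=config.precision)
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2), encoding="utf-8")
        return summarize_groups(records)
    records = read_measurements(config.input_path)
    if not records:
        raise ValueError("input file contains no records")
    write_table(records, outdir / "records.tsv", precision=config.precision)
    return summarize_groups(records)


def _stage_growth_model(
    config: PipelineConfig, cells: list[SummaryCell], outdir: pathlib.Path
) -> list[TrajectoryFit]:
    by_key = _cells_by_key(cells)

    def anchors(region: str, genotype: str) -> list[tuple[float, float]]:
        out = sorted(
            (c.age_months, c.mean)
            for c in cells
            if c.region == region
            and c.genotype.value == genotype
            and c.measure_kind is MeasureKind.gross_area
        )
        return out

    fits: list[TrajectoryFit] = []
    for region in config.regions:
        wt = anchors(region, "WT")
        mut = anchors(region, "MUT")
        if len(wt) < 2 or len(mut) != len(wt):
            log.warning("skipping region %s: incomplete gross-area anchors", region)
            continue
        base = fit_baseline(
            wt, growth_phase_end=config.growth_phase_end, region=region, genotype="WT"
        )
        fits.append(base)
        for variant in (ModelVariant.undergrowth_only, ModelVariant.degeneration_only):
            fits.append(fit_counterfactual(mut, base, variant))
    write_table(_fit_frame(fits), outdir / "coefficients.tsv", precision=config.precision)
    return fits


def _stage_stats(
    config: PipelineConfig, cells: list[SummaryCell], outdir: pathlib.Path
) -> tuple[list[dict], list[dict]]:
    by_key = _cells_by_key(cells)
    test_rows: list[dict] = []
    atrophy_rows: list[dict] = []
    for key in sorted(by_key):
        genotype, age, region, kind = key
        if genotype != "WT":
            continue
        mut = by_key.get(("MUT", age, region, kind))
        wt = by_key[key]
        if mut is None or (wt.n == 1 and mut.n == 1):
            continue
        res = t_test_two_sample(wt, mut, equal_var=not config.welch)
        test_rows.append(
            {
                "region": region,
                "measure_kind": kind,
                "age_months": age,
                "wt_mean": wt.mean,
                "mut_mean": mut.mean,
                "t": res.statistic,
                "df": res.df,
                "p": res.p,
                "stars": p_stars(res.p),
                "method": res.method,
            }
        )
        if kind in ("tissue_area", "thickness", "width") and age >= 22.0:
            est = percent_decrease(wt, mut)
            atrophy_rows.append(
                {
                    "region": region,
                    "measure_kind": kind,
                    "age_months": age,
                    "percent_decrease": est.percent_decrease,
                    "uncertainty": est.uncertainty,
                    "p": res.p,
                    "stars": p_stars(res.p),
                }
            )
    write_table(test_rows, outdir / "stats.tsv", precision=config.precision)
    write_table(atrophy_rows, outdir / "atrophy.tsv", precision=config.precision)
    return test_rows, atrophy_rows


def _stage_morphometry(config: PipelineConfig, outdir: pathlib.Path) -> list[dict]:
    from . import morphometry as morph
    from .synthetic import gen_cell_field_image, gen_coverage_image, gen_pc_layer_image

    rows: list[dict] = []
    for i, spec_dict in enumerate(config.image_specs):
        spec_dict = dict(spec_dict)
        spec_dict.setdefault("seed", config.seed + i)
        if "shape" in spec_dict:
            spec_dict["shape"] = tuple(spec_dict["shape"])
        spec = ImageSpec(**spec_dict)
        if spec.scene == "pc_layer":
            image, truth = gen_pc_layer_image(spec)
            value = morph.pc_linear_density(
                truth.soma_centers,
                truth.layer_path,
                spec.pixel_size_um,
                soma_radius_um=spec.soma_radius_um,
            )
            rows.append({"scene": spec.scene, "index": i, "measure": "pc_density_per_100um", "value": value})
        elif spec.scene == "coverage":
            image, truth = gen_coverage_image(spec)
            value = morph.signal_area_fraction(image)
            rows.append({"scene": spec.scene, "index": i, "measure": "signal_fraction_pct", "value": value})
        elif spec.scene == "cell_field":
            images, truth = gen_cell_field_image(spec)
            rows.append(
                {"scene": spec.scene, "index": i, "measure": "cell_count", "value": float(len(truth.cell_centers))}
            )
            if "cd68" in images:
                labels = (images["iba1"].pixels > spec.background).astype(int)
                from skimage import measure as skmeasure

                stats = morph.puncta_size_stats(
                    images["cd68"], skmeasure.label(labels, connectivity=2), spec.pixel_size_um
                )
                rows.append(
                    {
                        "scene": spec.scene,
                        "index": i,
                        "measure": "puncta_mean_area_um2",
                        "value": stats.mean_area_um2,
                    }
                )
        else:
            raise ValueError(f"unknown scene {spec.scene!r}")
    write_table(rows, outdir / "morphometry.tsv", precision=config.precision)
    return rows


def run(config: PipelineConfig) -> pathlib.Path:
    """Execute all stages; returns the output directory.

    On stage failure a machine-readable ``error.json`` is written next to
    whatever outputs already completed, and :class:`PipelineError` is
    raised.
    """
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )
    import braintraj

    run_log = {
        "package": "braintraj " + getattr(braintraj, "__version__", "0"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages_completed": [],
    }

    stage = "input"
    try:
        cells = _stage_input(config, outdir)
        if not cells:
            raise ValueError("no summary cells produced from input")
        write_table(cells, outdir / "summaries.tsv", precision=config.precision)
        run_log["stages_completed"].append("input")

        stage = "growth_model"
        _stage_growth_model(config, cells, outdir)
        run_log["stages_completed"].append("growth_model")

        stage = "stats"
        _stage_stats(config, cells, outdir)
        run_log["stages_completed"].append("stats")

        stage = "morphometry"
        _stage_morphometry(config, outdir)
        run_log["stages_completed"].append("morphometry")

        stage = "report"
        report(outdir)
        run_log["stages_completed"].append("report")
    except Exception as exc:
        (outdir / "error.json").write_text(
            json.dumps({"stage": stage, "error": str(exc)}, indent=2), encoding="utf-8"
        )
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2), encoding="utf-8")
        raise PipelineError(stage, exc) from exc

    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2), encoding="utf-8")
    return outdir


def _fmt(x, nd=4) -> str:
    if isinstance(x, float):
        return f"{x:.{nd}g}"
    return str(x)


def report(outdir: str | pathlib.Path) -> pathlib.Path:
    """Assemble a human-readable markdown report from the stage tables."""
    outdir = pathlib.Path(outdir)
    lines = ["# Brain trajectory analysis report", ""]

    coeff_path = outdir / "coefficients.tsv"
    if coeff_path.exists():
        frame = pd.read_csv(coeff_path, sep="\t")
        lines += ["## Growth/degeneration coefficients (per month)", ""]
        lines += ["| region | variant | phase (mo) | rate | G | D | |", "|---|---|---|---|---|---|---|"]
        for _, r in frame.iterrows():
            marker = "" if bool(r["feasible"]) else "INFEASIBLE (negative coefficient)"
            lines.append(
                f"| {r['region']} | {r['variant']} | {_fmt(r['t_start'])}-{_fmt(r['t_end'])} "
                f"| {_fmt(r['rate'])} | {_fmt(r['G'])} | {_fmt(r['D'])} | {marker} |"
            )
        lines.append("")

    atrophy_path = outdir / "atrophy.tsv"
    if atrophy_path.exists():
        frame = pd.read_csv(atrophy_path, sep="\t")
        if len(frame):
            lines += ["## Percent decrease vs wild type", ""]
            lines += ["| region | measure | % decrease | ± | p | |", "|---|---|---|---|---|---|"]
            for _, r in frame.iterrows():
                lines.append(
                    f"| {r['region']} | {r['measure_kind']} | {_fmt(r['percent_decrease'], 3)} "
                    f"| {_fmt(r['uncertainty'], 2)} | {_fmt(r['p'], 2)} | {r['stars']} |"
                )
            lines.append("")

    stats_path = outdir / "stats.tsv"
    if stats_path.exists():
        frame = pd.read_csv(stats_path, sep="\t")
        if len(frame):
            lines += ["## Group comparisons (two-tailed t)", ""]
            lines += ["| region | measure | age (mo) | WT | MUT | t | p | |", "|---|---|---|---|---|---|---|---|"]
            for _, r in frame.iterrows():
                lines.append(
                    f"| {r['region']} | {r['measure_kind']} | {_fmt(r['age_months'])} "
                    f"| {_fmt(r['wt_mean'])} | {_fmt(r['mut_mean'])} | {_fmt(r['t'], 3)} "
                    f"| {_fmt(r['p'], 2)} | {r['stars']} |"
                )
            lines.append("")

    morph_path = outdir / "morphometry.tsv"
    if morph_path.exists():
        frame = pd.read_csv(morph_path, sep="\t")
        if len(frame):
            lines += ["## Morphometry (synthetic scenes)", ""]
            lines += ["| scene | measure | value |", "|---|---|---|"]
            for _, r in frame.iterrows():
                lines.append(f"| {r['scene']} | {r['measure']} | {_fmt(r['value'], 4)} |")
            lines.append("")

    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
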