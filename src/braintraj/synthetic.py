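"""Synthetic cohorts and microscopy scenes with known ground truth.

The cohort generator draws per-animal regional areas around a true
piecewise exponential trajectory (the same discrete-time model the fitting
code inverts), so that the full pipeline can be calibrated end to end:
at zero noise the fit recovers the generating coefficients exactly, and
under multiplicative noise the recovery bias can be measured by Monte
Carlo.  The image generators lay out idealized stained scenes — a
Purkinje-cell layer along a folium-like path, Poisson-scattered cell
fields, and phagosome puncta inside cells — and emit the exact object
lists used to score the morphometry operators.

All randomness flows from a single integer seed through numpy's seed
sequence (PCG64); substreams are spawned per group in sorted key order, so
output is reproducible across platforms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml
from skimage.draw import disk as _disk

from .morphometry import GroundTruth, SyntheticImage
from .records import MeasurementRecord, MeasureKind, EXPECTED_UNITS

__all__ = [
    "TrueTrajectory",
    "CohortSpec",
    "ImageSpec",
    "default_cohort_spec",
    "gen_cohort",
    "gen_pc_layer_image",
    "gen_coverage_image",
    "gen_cell_field_image",
]


@dataclass(frozen=True)
class TrueTrajectory:
    """Generating truth for one region x genotype: per-phase G and D and
    the birth-area anchor, advanced by the discrete rule
    A_end = A_start / (1 − (G−D)·Δt)."""

    A0: float
    G: tuple[float, ...]
    D: tuple[float, ...]
    boundaries: tuple[float, ...] = (0.0, 1.0, 2.0, 6.0, 23.0)

    def __post_init__(self) -> None:
        if len(self.G) != len(self.D) or len(self.G) != len(self.boundaries) - 1:
            raise ValueError("need one (G, D) pair per interval between boundaries")
        if not self.A0 > 0:
            raise ValueError("A0 must be positive")

    def anchors(self) -> list[tuple[float, float]]:
        out = [(self.boundaries[0], self.A0)]
        a = self.A0
        for g, d, t0, t1 in zip(self.G, self.D, self.boundaries, self.boundaries[1:]):
            k = g - d
            denom = 1.0 - k * (t1 - t0)
            if denom <= 0:
                raise ValueError("k*dt >= 1: trajectory not representable by the discrete rule")
            a = a / denom
            out.append((t1, a))
        return out

    def area_at(self, t: float) -> float:
        for tb, a in self.anchors():
            if math.isclose(tb, t):
                return a
        raise KeyError(f"t = {t} is not a phase boundary")


@dataclass(frozen=True)
class CohortSpec:
    """Cross-sectional cohort layout: one truth per (region, genotype),
    ``n_per_age`` animals per boundary age, multiplicative noise with the
    stated coefficient of variation."""

    trajectories: Mapping[tuple[str, str], TrueTrajectory]
    n_per_age: int = 8
    noise: str = "normal_cv"  # or "lognormal"
    cv: float = 0.05
    seed: int = 0
    measure_kind: MeasureKind = MeasureKind.gross_area

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_per_age < 1:
            raise ValueError("n_per_age must be >= 1")
        if self.noise not in ("normal_cv", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        object.__setattr__(self, "measure_kind", MeasureKind(self.measure_kind))

    def spec_hash(self) -> str:
        payload = {
            "trajectories": {
                f"{r}|{g}": dataclasses.asdict(t) for (r, g), t in sorted(self.trajectories.items())
            },
            "n_per_age": self.n_per_age,
            "noise": self.noise,
            "cv": self.cv,
            "seed": self.seed,
            "measure_kind": self.measure_kind.value,
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True, default=list).encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "CohortSpec":
        d = yaml.safe_load(pathlib.Path(path).read_text(encoding="utf-8"))
        trajs = {}
        for key, t in d["trajectories"].items():
            region, genotype = key.split("|")
            trajs[(region, genotype)] = TrueTrajectory(
                A0=float(t["A0"]),
                G=tuple(float(x) for x in t["G"]),
                D=tuple(float(x) for x in t["D"]),
                boundaries=tuple(float(x) for x in t.get("boundaries", (0, 1, 2, 6, 23))),
            )
        return cls(
            trajectories=trajs,
            n_per_age=int(d.get("n_per_age", 8)),
            noise=d.get("noise", "normal_cv"),
            cv=float(d.get("cv", 0.05)),
            seed=int(d.get("seed", 0)),
            measure_kind=d.get("measure_kind", "gross_area"),
        )


def default_cohort_spec(seed: int = 0, n_per_age: int = 8, cv: float = 0.05) -> CohortSpec:
    """Cortex and cerebellum truths at the scale of the mouse study:
    strong first-month growth, tapering growth to 6 mo, and slow
    degeneration thereafter, with the mutant undergrowing and (in
    cerebellum) degenerating faster."""
    trajs = {
        ("cortex", "WT"): TrueTrajectory(
            A0=0.244, G=(0.676, 0.171, 0.011, 0.0), D=(0.0, 0.0, 0.0, 0.0134)
        ),
        ("cortex", "MUT"): TrueTrajectory(
            A0=0.250, G=(0.674, 0.051, 0.027, 0.0), D=(0.0, 0.0, 0.0, 0.0123)
        ),
        ("cerebellum", "WT"): TrueTrajectory(
            A0=0.0316, G=(0.856, 0.249, 0.008, 0.0), D=(0.0, 0.0, 0.0, 0.0124)
        ),
        ("cerebellum", "MUT"): TrueTrajectory(
            A0=0.0323, G=(0.854, 0.131, 0.005, 0.0), D=(0.0, 0.0, 0.0, 0.0277)
        ),
    }
    return CohortSpec(trajectories=trajs, n_per_age=n_per_age, cv=cv, seed=seed)


def gen_cohort(spec: CohortSpec) -> tuple[list[MeasurementRecord], dict]:
    """Draw a cross-sectional cohort; returns (records, truth).

    ``truth`` maps "region|genotype" to the noise-free anchors and carries
    the seed and spec hash.  Per-animal value = A_true(age) × noise, with
    noise either 1 + cv·z (normal_cv) or a mean-one lognormal.
    """
    units = EXPECTED_UNITS[spec.measure_kind]
    root = np.random.SeedSequence(spec.seed)
    keys = sorted(spec.trajectories)
    streams = {k: np.random.default_rng(s) for k, s in zip(keys, root.spawn(len(keys)))}
    records: list[MeasurementRecord] = []
    truth: dict = {"seed": spec.seed, "spec_hash": spec.spec_hash(), "prng": "numpy PCG64", "groups": {}}
    sigma = math.sqrt(math.log1p(spec.cv**2))
    for (region, genotype) in keys:
        traj = spec.trajectories[(region, genotype)]
        rng = streams[(region, genotype)]
        anchors = traj.anchors()
        truth["groups"][f"{region}|{genotype}"] = {
            "anchors": anchors,
            "G": list(traj.G),
            "D": list(traj.D),
        }
        for age, a_true in anchors:
            for i in range(spec.n_per_age):
                if spec.cv == 0:
                    factor = 1.0
                elif spec.noise == "normal_cv":
                    factor = 1.0 + spec.cv * rng.standard_normal()
                else:
                    factor = math.exp(sigma * rng.standard_normal() - sigma**2 / 2.0)
                records.append(
                    MeasurementRecord(
                        subject_id=f"{region}-{genotype}-{age:g}mo-{i:02d}",
                        genotype=genotype,
                        sex="M",
                        age_months=age,
                        region=region,
                        measure_kind=spec.measure_kind,
                        value=a_true * factor,
                        units=units,
                    )
                )
    return records, truth


# ---------------------------------------------------------------------------
# image scenes

@dataclass(frozen=True)
class ImageSpec:
    """Parameters for one synthetic stained scene.

    Scene types: ``pc_layer`` (somata along a folium-like path),
    ``coverage`` (stain painted to an exact area fraction), ``cell_field``
    (Poisson-scattered cells, optionally with per-cell puncta).
    """

    shape: tuple[int, int] = (256, 512)
    pixel_size_um: float = 1.0
    scene: str = "pc_layer"
    seed: int = 0
    background: float = 20.0
    foreground: float = 200.0
    noise_sd: float = 0.0
    bit_depth: int = 8
    # pc_layer
    density_per_100um: float = 3.3
    dropout: float = 0.0
    soma_radius_um: float = 10.0
    # coverage
    coverage_fraction: float = 0.307
    # cell_field
    expected_cells: float = 159.0
    cell_radius_um: float = 7.0
    puncta_per_cell: int = 0
    puncta_mean_area_um2: float = 19.8
    puncta_area_shape: float = 4.0

    def __post_init__(self) -> None:
        top = 2**self.bit_depth - 1
        if not (0 <= self.background <= top and 0 <= self.foreground <= top):
            raise ValueError("intensities must fit the bit depth")
        if self.density_per_100um < 0 or self.expected_cells < 0:
            raise ValueError("densities must be >= 0")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be a fraction")

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "ImageSpec":
        d = yaml.safe_load(pathlib.Path(path).read_text(encoding="utf-8"))
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(**d)


def _finalize(canvas: np.ndarray, spec: ImageSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    top = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    return np.clip(np.rint(canvas), 0, top).astype(dtype)


def _folium_path(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """A gently curving left-to-right polyline emulating a folium profile."""
    h, w = shape
    cols = np.arange(5, w - 5, 4, dtype=float)
    amp = 0.18 * h
    phase = rng.uniform(0, 2 * math.pi)
    rows = h / 2 + amp * np.sin(2 * math.pi * cols / w + phase)
    return np.column_stack([rows, cols])


def gen_pc_layer_image(spec: ImageSpec) -> tuple[SyntheticImage, GroundTruth]:
    """Somata placed along a folium-like path at a target linear density.

    Spacing along the path is 100/density µm with ±20% jitter and a small
    perpendicular offset; a ``dropout`` fraction of somata is removed
    (emulating cell loss).  Placement enforces non-overlap; truth lists the
    surviving centers and the path.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    path = _folium_path(spec.shape, rng)
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total_px = float(cum[-1])

    centers: list[tuple[float, float]] = []
    soma_r_px = spec.soma_radius_um / spec.pixel_size_um
    if spec.density_per_100um > 0:
        spacing_px = (100.0 / spec.density_per_100um) / spec.pixel_size_um
        s = spacing_px * 0.5
        attempts = 0
        while s < total_px:
            idx = int(np.searchsorted(cum, s, side="right")) - 1
            idx = min(idx, len(seg) - 1)
            frac = (s - cum[idx]) / seg_len[idx]
            pt = path[idx] + frac * seg[idx]
            normal = np.array([-seg[idx][1], seg[idx][0]]) / seg_len[idx]
            pt = pt + normal * rng.normal(0.0, 1.0)
            if rng.random() >= spec.dropout:
                ok = all(
                    (pt[0] - c[0]) ** 2 + (pt[1] - c[1]) ** 2 > (1.6 * soma_r_px) ** 2
                    for c in centers
                )
                if ok and 0 <= pt[0] < spec.shape[0] and 0 <= pt[1] < spec.shape[1]:
                    centers.append((float(pt[0]), float(pt[1])))
                else:
                    attempts += 1
                    if attempts > 10 * total_px / spacing_px:
                        raise ValueError("non-overlap placement failed: density too high")
            s += spacing_px * (1.0 + rng.uniform(-0.2, 0.2))

    canvas = np.full(spec.shape, spec.background, dtype=float)
    for r, c in centers:
        rr, cc = _disk((r, c), soma_r_px, shape=spec.shape)
        canvas[rr, cc] = spec.foreground
    image = SyntheticImage(
        pixels=_finalize(canvas, spec, rng),
        pixel_size_um=spec.pixel_size_um,
        channel="calbindin",
    )
    truth = GroundTruth(
        soma_centers=centers,
        soma_radius_px=soma_r_px,
        layer_path=[tuple(p) for p in path],
    )
    image.ground_truth = truth
    return image, truth


def gen_coverage_image(spec: ImageSpec) -> tuple[SyntheticImage, GroundTruth]:
    """Stain painted to an exact area fraction.

    A smoothed random field is thresholded at the quantile that yields
    precisely ``coverage_fraction`` foreground pixels, giving organic blob
    shapes with exactly known coverage.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    fld = gaussian_filter(rng.standard_normal(spec.shape), sigma=8.0)
    thr = np.quantile(fld, 1.0 - spec.coverage_fraction)
    mask = fld >= thr
    actual = float(mask.mean())
    canvas = np.where(mask, spec.foreground, spec.background).astype(float)
    image = SyntheticImage(
        pixels=_finalize(canvas, spec, rng),
        pixel_size_um=spec.pixel_size_um,
        channel="calbindin",
    )
    truth = GroundTruth(coverage_fraction=actual)
    image.ground_truth = truth
    return image, truth


def _place_puncta(
    rng: np.random.Generator,
    center: tuple[float, float],
    cell_r_px: float,
    spec: ImageSpec,
    canvas: np.ndarray,
    occupied: np.ndarray,
) -> list[float]:
    """Draw non-overlapping gamma-area puncta inside one cell; returns the
    rasterized areas in µm²."""
    areas = []
    shape_k = spec.puncta_area_shape
    scale = spec.puncta_mean_area_um2 / shape_k
    for _ in range(spec.puncta_per_cell):
        area_um2 = rng.gamma(shape_k, scale)
        target_px = area_um2 / spec.pixel_size_um**2
        r_px = max(math.sqrt(target_px / math.pi), 1.0)
        # puncta may overhang the cell edge; the operator only requires
        # the component to overlap the cell mask
        for _try in range(100):
            rho = rng.uniform(0, cell_r_px - 0.5)
            ang = rng.uniform(0, 2 * math.pi)
            pr = center[0] + rho * math.sin(ang)
            pc = center[1] + rho * math.cos(ang)
            rr, cc = _disk((pr, pc), r_px, shape=canvas.shape)
            if rr.size and abs(rr.size - target_px) > 0.1 * target_px:
                # one-step radius correction for rasterization error
                r_adj = r_px * math.sqrt(target_px / rr.size)
                rr, cc = _disk((pr, pc), max(r_adj, 1.0), shape=canvas.shape)
            # a 2-px halo keeps adjacent puncta from merging into one
            # connected component
            hr, hc = _disk((pr, pc), r_px + 2.0, shape=canvas.shape)
            if hr.size and not occupied[hr, hc].any():
                canvas[rr, cc] = spec.foreground
                occupied[hr, hc] = True
                areas.append(float(rr.size) * spec.pixel_size_um**2)
                break
    return areas


def gen_cell_field_image(
    spec: ImageSpec,
) -> tuple[dict[str, SyntheticImage], GroundTruth]:
    """Poisson-scattered cells, optionally with phagosome puncta.

    The cell count is Poisson(``expected_cells``) with centers uniform in
    the image; cells are drawn as disks into an "iba1" channel.  With
    ``puncta_per_cell`` > 0 a "cd68" channel receives non-overlapping
    puncta whose areas follow a gamma distribution with the stated mean.
    Truth lists cell centers and the as-rasterized puncta areas.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    h, w = spec.shape
    n_cells = int(rng.poisson(spec.expected_cells))
    cell_r_px = spec.cell_radius_um / spec.pixel_size_um
    margin = cell_r_px + 1
    centers = [
        (float(rng.uniform(margin, h - margin)), float(rng.uniform(margin, w - margin)))
        for _ in range(n_cells)
    ]

    cell_canvas = np.full(spec.shape, spec.background, dtype=float)
    for r, c in centers:
        rr, cc = _disk((r, c), cell_r_px, shape=spec.shape)
        cell_canvas[rr, cc] = spec.foreground

    images = {
        "iba1": SyntheticImage(
            pixels=_finalize(cell_canvas, spec, rng),
            pixel_size_um=spec.pixel_size_um,
            channel="iba1",
        )
    }
    puncta_areas: list[float] = []
    if spec.puncta_per_cell > 0:
        puncta_canvas = np.full(spec.shape, spec.background, dtype=float)
        occupied = np.zeros(spec.shape, dtype=bool)
        for center in centers:
            puncta_areas.extend(
                _place_puncta(rng, center, cell_r_px, spec, puncta_canvas, occupied)
            )
        images["cd68"] = SyntheticImage(
            pixels=_finalize(puncta_canvas, spec, rng),
            pixel_size_um=spec.pixel_size_um,
            channel="cd68",
        )
    truth = GroundTruth(cell_centers=centers, puncta_areas_um2=puncta_areas)
    for img in images.values():
        img.ground_truth = truth
    return images, truth
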