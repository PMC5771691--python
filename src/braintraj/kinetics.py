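"""Piecewise exponential growth/degeneration kinetics for cross-sectional
brain-size trajectories.

The model is dA/dt = G·A − D·A, where A(t) is the regional area, G the
growth coefficient (per month) and D the degeneration coefficient (per
month).  Coefficients are identified from group-mean anchors at the phase
boundaries under two structural assumptions: in the control genotype
degeneration is negligible before the growth-phase end (D = 0 for
t < growth_phase_end) and growth is negligible after it (G = 0 for
t > growth_phase_end).

Discretization: the per-interval net coefficient k = G − D is defined by
the end-anchored rule k = (ΔA/Δt) / A(t_end), i.e. the interval rate is
referred to the area at the *end* of the interval.  The logarithmic form
k = ln(A_end/A_start)/Δt is available via ``convention="log"``.

Two counterfactual variants repartition the same net coefficient:

* ``undergrowth_only`` — the mutant deficit is explained entirely by
  reduced growth: in growth phases D is held at the control value (0 by
  construction) and G absorbs the net coefficient.  After the growth phase
  the shared structural assumption G = 0 applies and D is fit to the
  mutant data.
* ``degeneration_only`` — the mutant deficit is explained entirely by
  enhanced degeneration: G is held at the control value in every phase and
  D = G_control − k.  A negative fitted D is reported verbatim and flagged
  infeasible; infeasibility is the model-comparison diagnostic.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .records import Genotype, SummaryCell

__all__ = [
    "ModelVariant",
    "PhaseFit",
    "TrajectoryFit",
    "AtrophyEstimate",
    "interval_rate",
    "net_coefficient",
    "fit_baseline",
    "fit_counterfactual",
    "simulate_trajectory",
    "percent_decrease",
]


class ModelVariant(str, enum.Enum):
    baseline = "baseline"
    undergrowth_only = "undergrowth_only"
    degeneration_only = "degeneration_only"


def interval_rate(a_start: float, a_end: float, t_start: float, t_end: float) -> float:
    """Rate of change of area over an interval, (A_end − A_start)/Δt.

    Units follow the anchors (e.g. cm²/mo); the sign is preserved.
    """
    if not t_end > t_start:
        raise ValueError(f"t_end ({t_end}) must exceed t_start ({t_start})")
    return (a_end - a_start) / (t_end - t_start)


def net_coefficient(
    a_start: float,
    a_end: float,
    t_start: float,
    t_end: float,
    convention: str = "end_anchored",
) -> float:
    """Net per-month coefficient k = G − D for an interval.

    ``end_anchored`` (default): k = interval_rate / A_end, so that
    rate = k·A(t_end).  ``log``: k = ln(A_end/A_start)/Δt, the exact
    exponential-solution coefficient.
    """
    if a_end <= 0:
        raise ValueError(f"A_end must be positive, got {a_end}")
    if convention == "end_anchored":
        return interval_rate(a_start, a_end, t_start, t_end) / a_end
    if convention == "log":
        if a_start <= 0:
            raise ValueError("log convention requires A_start > 0")
        if not t_end > t_start:
            raise ValueError(f"t_end ({t_end}) must exceed t_start ({t_start})")
        return math.log(a_end / a_start) / (t_end - t_start)
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class PhaseFit:
    """Fitted coefficients for one inter-anchor phase."""

    t_start: float
    t_end: float
    rate: float
    G: float
    D: float
    model_variant: ModelVariant = ModelVariant.baseline

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("phase must have t_end > t_start")
        object.__setattr__(self, "model_variant", ModelVariant(self.model_variant))

    @property
    def feasible(self) -> bool:
        """A phase is feasible iff both coefficients are non-negative."""
        return self.G >= 0 and self.D >= 0

    @property
    def net(self) -> float:
        return self.G - self.D


@dataclass(frozen=True)
class TrajectoryFit:
    """Ordered phase fits for one region x genotype trajectory.

    ``anchors`` are the (t, A) pairs at phase boundaries; there is one more
    anchor than phases and the phases tile the anchor grid contiguously.
    """

    region: str
    genotype: Genotype
    phases: tuple[PhaseFit, ...]
    anchors: tuple[tuple[float, float], ...]
    growth_phase_end: float = 6.0
    model_variant: ModelVariant = ModelVariant.baseline

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        object.__setattr__(self, "model_variant", ModelVariant(self.model_variant))
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "anchors", tuple((float(t), float(a)) for t, a in self.anchors))
        if len(self.anchors) != len(self.phases) + 1:
            raise ValueError("anchor count must equal phase count + 1")
        for ph, (t0, _), (t1, _) in zip(self.phases, self.anchors, self.anchors[1:]):
            if not (math.isclose(ph.t_start, t0) and math.isclose(ph.t_end, t1)):
                raise ValueError("phases must be contiguous on the anchor grid")

    @property
    def feasible(self) -> bool:
        return all(ph.feasible for ph in self.phases)

    def phase_at(self, t_start: float) -> PhaseFit:
        for ph in self.phases:
            if math.isclose(ph.t_start, t_start):
                return ph
        raise KeyError(f"no phase starting at t = {t_start}")


def _check_anchors(anchors: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    anchors = [(float(t), float(a)) for t, a in anchors]
    if len(anchors) < 2:
        raise ValueError("need at least two (t, A) anchors")
    times = [t for t, _ in anchors]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("anchor times must be strictly increasing")
    return anchors


def fit_baseline(
    anchors: Sequence[tuple[float, float]],
    growth_phase_end: float = 6.0,
    region: str = "whole_brain",
    genotype: Genotype | str = Genotype.WT,
    convention: str = "end_anchored",
) -> TrajectoryFit:
    """Fit per-phase G and D under the structural identifying assumptions.

    Intervals ending at or before ``growth_phase_end`` are growth phases
    (D = 0, G = net coefficient); intervals starting at or after it are
    degeneration phases (G = 0, D = −net coefficient).  An interval
    straddling the boundary is an error — the anchor grid must align with
    the assumed phase structure.
    """
    anchors = _check_anchors(anchors)
    phases = []
    for (t0, a0), (t1, a1) in zip(anchors, anchors[1:]):
        if t0 < growth_phase_end < t1:
            raise ValueError(
                f"interval [{t0}, {t1}] straddles growth_phase_end = {growth_phase_end}"
            )
        rate = interval_rate(a0, a1, t0, t1)
        k = net_coefficient(a0, a1, t0, t1, convention=convention)
        if t1 <= growth_phase_end:
            g, d = k, 0.0
        else:
            g, d = 0.0, -k
        phases.append(PhaseFit(t0, t1, rate, g, d, ModelVariant.baseline))
    return TrajectoryFit(
        region=region,
        genotype=Genotype(genotype),
        phases=tuple(phases),
        anchors=tuple(anchors),
        growth_phase_end=growth_phase_end,
        model_variant=ModelVariant.baseline,
    )


def fit_counterfactual(
    anchors: Sequence[tuple[float, float]],
    control: TrajectoryFit,
    variant: ModelVariant | str,
    region: str | None = None,
    genotype: Genotype | str = Genotype.MUT,
    convention: str = "end_anchored",
) -> TrajectoryFit:
    """Fit a counterfactual single-mechanism model to mutant anchors.

    The mutant anchor grid must coincide with the control phase grid.
    Both variants preserve the interval's net coefficient (G − D = k); they
    differ only in which coefficient is pinned to the control value.
    Negative fitted coefficients are reported verbatim; the phase's
    ``feasible`` flag marks them.
    """
    variant = ModelVariant(variant)
    if variant is ModelVariant.baseline:
        raise ValueError("variant must be undergrowth_only or degeneration_only")
    anchors = _check_anchors(anchors)
    ctrl_times = [t for t, _ in control.anchors]
    if len(anchors) != len(ctrl_times) or any(
        not math.isclose(t, ct) for (t, _), ct in zip(anchors, ctrl_times)
    ):
        raise ValueError("mutant anchors must align with control phase boundaries")

    gpe = control.growth_phase_end
    phases = []
    for (t0, a0), (t1, a1), ctrl_ph in zip(anchors, anchors[1:], control.phases):
        rate = interval_rate(a0, a1, t0, t1)
        k = net_coefficient(a0, a1, t0, t1, convention=convention)
        in_growth = t1 <= gpe
        if variant is ModelVariant.undergrowth_only and in_growth:
            # growth absorbs the net coefficient; D stays at the control
            # level (0 by the structural assumption during growth)
            d = ctrl_ph.D
            g = k + d
        else:
            # G pinned to control; D absorbs the residual.  After the
            # growth phase G_control = 0, so both variants refit D here.
            g = ctrl_ph.G
            d = g - k
        phases.append(PhaseFit(t0, t1, rate, g, d, variant))
    return TrajectoryFit(
        region=region if region is not None else control.region,
        genotype=Genotype(genotype),
        phases=tuple(phases),
        anchors=tuple(anchors),
        growth_phase_end=gpe,
        model_variant=variant,
    )


def simulate_trajectory(
    fit: TrajectoryFit,
    a0: float | None = None,
    mode: str = "discrete",
) -> list[tuple[float, float]]:
    """Forward-simulate anchors from a fitted (or constructed) trajectory.

    ``discrete`` inverts the end-anchored fitting rule exactly:
    A_end = A_start / (1 − k·Δt), which requires k·Δt < 1.  ``continuous``
    integrates the exponential solution A_end = A_start · exp(k·Δt) and is
    the exact inverse of the ``log`` fitting convention.
    """
    if a0 is None:
        a0 = fit.anchors[0][1]
    if not a0 > 0:
        raise ValueError("A0 must be positive")
    if mode not in ("discrete", "continuous"):
        raise ValueError(f"unknown mode {mode!r}")
    out = [(fit.phases[0].t_start, float(a0))]
    a = float(a0)
    for ph in fit.phases:
        dt = ph.t_end - ph.t_start
        k = ph.net
        if mode == "discrete":
            denom = 1.0 - k * dt
            if denom <= 0:
                raise ValueError(
                    f"singular inversion: k*dt = {k * dt:.4g} >= 1 on phase "
                    f"[{ph.t_start}, {ph.t_end}]"
                )
            a = a / denom
        else:
            a = a * math.exp(k * dt)
        out.append((ph.t_end, a))
    return out


@dataclass(frozen=True)
class AtrophyEstimate:
    """Percent decrease of a test group relative to a reference group."""

    percent_decrease: float
    uncertainty: float
    reference_mean: float
    test_mean: float
    region: str = ""
    measure_kind: str = ""

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


def percent_decrease(
    ref: SummaryCell,
    test: SummaryCell,
    uncertainty: str = "test_sem",
) -> AtrophyEstimate:
    """Percent decrease 100·(ref − test)/ref with a reported uncertainty.

    ``uncertainty="test_sem"`` (default) scales the test group's SEM by
    the reference mean: 100·SEM_test/mean_ref — the convention that
    matches the published "± x%" figures.  ``"delta"`` propagates both
    SEMs through the ratio by the delta method.
    """
    if ref.mean <= 0:
        raise ValueError("reference mean must be positive")
    pct = 100.0 * (ref.mean - test.mean) / ref.mean
    if uncertainty == "test_sem":
        unc = 100.0 * test.sem / ref.mean
    elif uncertainty == "delta":
        # var of 100*(1 - m_t/m_r) by first-order propagation
        r = test.mean / ref.mean
        unc = 100.0 * r * math.sqrt(
            (test.sem / test.mean) ** 2 + (ref.sem / ref.mean) ** 2
        )
    else:
        raise ValueError(f"unknown uncertainty convention {uncertainty!r}")
    return AtrophyEstimate(
        percent_decrease=pct,
        uncertainty=unc,
        reference_mean=ref.mean,
        test_mean=test.mean,
        region=ref.region,
        measure_kind=ref.measure_kind.value,
    )
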