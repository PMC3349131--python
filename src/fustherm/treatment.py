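"""Sonication trajectories, multi-insonation schedules, and power control.

A treatment steps the focus through a 2 mm-pitch point set in the axial
midplane of the block, 56 insonations of 20 s each separated by 5 s cooling
(no cooling after the last: total 56*20 + 55*5 = 1395 s). Three delivery
methods are provided:

* ``sequential`` — row-major raster starting from the top-left point;
* ``random`` — seeded permutation with consecutive foci at least 8 mm apart
  (to avoid thermal build-up), drawn by rejection;
* ``spiral`` — outward Archimedean spiral from the domain centre with 2 mm
  turn spacing and 2 mm arc-length stepping.

Power is either fixed for the whole treatment or adjusted per insonation by
:class:`DoseController`, which emulates a feedback situation: the event is
trial-simulated from a checkpoint and its peak incremental midplane dose
driven into a target band (230-250 equivalent minutes) by a monotone search
on the peak power density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .grid import Grid
from .scenarios import Scenario
from .solver import Simulation, SolverConfig
from .source import SourceSpec, treatment_source

__all__ = [
    "SonicationEvent",
    "SonicationPlan",
    "make_trajectory",
    "make_plan",
    "DoseController",
    "control_power",
    "run_treatment",
    "TreatmentResult",
    "TRAJECTORY_KINDS",
]

TRAJECTORY_KINDS = ("random", "sequential", "spiral")

#: schedule defaults: 56 insonations, 20 s on, 5 s cool, 2 mm pitch, >= 8 mm
#: consecutive separation for the random delivery.
N_EVENTS = 56
ON_SECONDS = 20.0
COOL_SECONDS = 5.0
PITCH = 2e-3
MIN_RANDOM_SEPARATION = 8e-3


@dataclass(frozen=True)
class SonicationEvent:
    """One insonation: focus (m), on/cool durations (s), peak power (W/m^3)."""

    focus: tuple[float, float, float]
    on_s: float
    cool_s: float
    p0: float


@dataclass(frozen=True)
class SonicationPlan:
    """Ordered insonation schedule."""

    events: tuple[SonicationEvent, ...]
    trajectory_kind: str
    seed: Optional[int] = None

    @property
    def total_time(self) -> float:
        return sum(e.on_s + e.cool_s for e in self.events)

    def with_power(self, p0: float) -> "SonicationPlan":
        return replace(self, events=tuple(replace(e, p0=p0) for e in self.events))


def _raster_points(extent_xy, pitch: float) -> np.ndarray:
    """The 2 mm grid of candidate foci, centred in the midplane.

    For the default 21 x 21 mm midplane and 2 mm pitch this is an 8 x 7
    lattice (56 points): 8 columns spanning 14 mm in x, 7 rows spanning 12 mm
    in y.
    """
    ex, ey = extent_xy
    nx = int(ex / pitch) - 2  # keep >= 1.5 pitch margin to the faces
    ny = int(ey / pitch) - 2
    if nx * ny < N_EVENTS:
        raise ValueError("midplane too small for the 56-point schedule")
    # canonical layout: shrink to exactly 56 points, one more column than rows
    while nx * ny > N_EVENTS:
        if nx * (ny - 1) >= N_EVENTS and ny >= nx:
            ny -= 1
        elif (nx - 1) * ny >= N_EVENTS:
            nx -= 1
        else:
            break
    xs = (np.arange(nx) - (nx - 1) / 2) * pitch + ex / 2
    ys = (np.arange(ny) - (ny - 1) / 2) * pitch + ey / 2
    return xs, ys


def make_trajectory(kind: str, extent_xy, pitch: float = PITCH,
                    n_points: int = N_EVENTS, seed: Optional[int] = None,
                    min_separation: float = MIN_RANDOM_SEPARATION,
                    max_tries: int = 10_000) -> np.ndarray:
    """Ordered (x, y) focus positions (m) in the midplane.

    Parameters
    ----------
    kind : {"random", "sequential", "spiral"}
    extent_xy : (float, float)
        Transverse domain size in metres; points are centred within it.
    seed : int
        Required for the random kind; ignored otherwise.

    Returns
    -------
    ndarray, shape (n_points, 2)
    """
    if kind not in TRAJECTORY_KINDS:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    if kind == "spiral":
        return _spiral_points(extent_xy, pitch, n_points)
    xs, ys = _raster_points(extent_xy, pitch)
    # row-major from the top-left square: highest y first, x ascending
    pts = np.array([(x, y) for y in ys[::-1] for x in xs])
    if kind == "sequential":
        return pts[:n_points]
    if seed is None:
        raise ValueError("random trajectory needs a seed")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        # order the full lattice, then truncate: short plans keep the same
        # statistics as prefixes of full treatments
        order = _greedy_separated_order(pts, rng, min_separation)
        if order is not None:
            return pts[order][:n_points]
    raise RuntimeError(
        f"could not draw a random order with >= {min_separation * 1e3:g} mm "
        f"consecutive separation in {max_tries} tries"
    )


def _greedy_separated_order(pts, rng, min_sep):
    """One attempt at a random visit order with a consecutive-distance floor."""
    n = len(pts)
    remaining = list(rng.permutation(n))
    order = [remaining.pop(0)]
    while remaining:
        cur = pts[order[-1]]
        d = np.linalg.norm(pts[remaining] - cur, axis=1)
        ok = np.nonzero(d >= min_sep - 1e-12)[0]
        if ok.size == 0:
            return None
        pick = ok[rng.integers(ok.size)]
        order.append(remaining.pop(pick))
    return order


def _spiral_points(extent_xy, pitch, n_points):
    """Outward Archimedean spiral r = (pitch/2pi) theta, 2 mm arc steps."""
    a = pitch / (2 * math.pi)
    cx, cy = extent_xy[0] / 2, extent_xy[1] / 2
    pts = [(cx, cy)]
    theta = 2 * math.pi * 0.5  # leave the centre by half a turn
    while len(pts) < n_points:
        r = a * theta
        pts.append((cx + r * math.cos(theta), cy + r * math.sin(theta)))
        # advance by one arc-length step: ds = sqrt(a^2 + r^2) dtheta
        theta += pitch / math.hypot(a, a * theta)
    return np.array(pts[:n_points])


def make_plan(kind: str, scenario: Scenario, p0: float,
              seed: Optional[int] = None, n_events: int = N_EVENTS,
              on_s: float = ON_SECONDS, cool_s: float = COOL_SECONDS,
              pitch: float = PITCH) -> SonicationPlan:
    """Build the insonation schedule for a scenario.

    Foci lie in the axial midplane (z = Lz/2). The final event has no cooling
    period, which makes the default schedule exactly 1395 s long.
    """
    traj = make_trajectory(kind, scenario.domain_size[:2], pitch=pitch,
                           n_points=n_events, seed=seed)
    z_mid = scenario.domain_size[2] / 2
    events = []
    for i, (x, y) in enumerate(traj):
        cool = cool_s if i < len(traj) - 1 else 0.0
        events.append(SonicationEvent(focus=(x, y, z_mid), on_s=on_s,
                                      cool_s=cool, p0=p0))
    return SonicationPlan(events=tuple(events), trajectory_kind=kind, seed=seed)


@dataclass
class DoseController:
    """Per-insonation power search keeping peak incremental dose in a band.

    The observed quantity is the maximum over midplane nodes of the dose
    accrued during one event (insonation + cooling), in equivalent minutes.
    Dose is monotone in the peak power density, so a bracketing secant search
    on log(P0) vs log(dose) converges in a few trials; ``max_iter`` caps the
    number of trial simulations per event.
    """

    band: tuple[float, float] = (230.0, 250.0)
    max_iter: int = 8
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.band[0] < self.band[1]:
            raise ValueError("band must be (low, high) with low < high")

    @property
    def target(self) -> float:
        return 0.5 * (self.band[0] + self.band[1])

    def propose(self, p0: float, observed: float,
                prev: Optional[tuple[float, float]] = None) -> float:
        """Next power to try after ``observed`` peak incremental dose at ``p0``.

        Uses a secant step on (log P0, log dose) when a second point is
        available, else a damped proportional guess; always moves in the
        direction monotonicity dictates and never more than a factor of 2.
        """
        lo, hi = self.band
        if lo <= observed <= hi:
            return p0
        target = self.target
        if observed <= 0:
            return p0 * 2.0
        if prev is not None and prev[1] > 0 and not np.isclose(prev[0], p0):
            num = math.log(target / observed)
            den = math.log(observed / prev[1])
            if abs(den) > 1e-12:
                step = num * math.log(p0 / prev[0]) / den
                step = float(np.clip(step, -math.log(2), math.log(2)))
                cand = p0 * math.exp(step)
                if (observed > hi and cand < p0) or (observed < lo and cand > p0):
                    return cand
        # first trial: damped power-law guess (dose is super-linear in P0)
        ratio = (target / observed) ** (1.0 / 3.0)
        return p0 * float(np.clip(ratio, 0.5, 2.0))


def control_power(ctrl: DoseController, p0: float, observed: float,
                  prev: Optional[tuple[float, float]] = None) -> float:
    """Functional wrapper: power to use next given an observed peak dose."""
    return ctrl.propose(p0, observed, prev)


@dataclass
class TreatmentResult:
    """Final state, dose field and per-event log of a treatment run."""

    sim: Simulation
    plan: SonicationPlan
    log: pd.DataFrame

    @property
    def normalized_midplane_dose(self) -> np.ndarray:
        return self.sim.normalized_midplane_dose()

    @property
    def mean_power(self) -> float:
        """Mean accepted peak power density over events, W/m^3."""
        return float(self.log["p0"].mean())


def run_treatment(scenario: Scenario, grid: Grid, plan: SonicationPlan,
                  cfg: Optional[SolverConfig] = None,
                  controller: Optional[DoseController] = None,
                  source_template: Optional[SourceSpec] = None,
                  sim: Optional[Simulation] = None) -> TreatmentResult:
    """Execute a sonication plan event by event.

    For each event the source is placed at the event focus, integrated for
    the on-duration, then removed for the cool-duration; dose accumulates
    throughout, cooling included. With a ``controller``, each event is first
    trial-simulated from a checkpoint and its power adjusted until the peak
    incremental midplane dose falls inside the controller band (iteration
    capped; nearest accepted on cap).

    Returns a :class:`TreatmentResult` whose log has one row per event:
    focus, accepted p0, peak incremental midplane dose (eq-min), peak
    midplane temperature at the end of the on-phase and of the cool-phase,
    and the number of trial simulations used.
    """
    cfg = cfg or SolverConfig()
    if sim is None:
        sim = Simulation(scenario, grid, cfg)
    template = source_template or treatment_source((0.0, 0.0, 0.0))
    rows = []
    mid = grid.midplane_index
    for i, ev in enumerate(plan.events):
        if controller is None:
            p0, trials, accepted = ev.p0, 0, None
        else:
            p0, trials, accepted = _controlled_power(sim, ev, template,
                                                     controller)
        if accepted is not None:
            # the accepted power equals the last trial's: adopt its end state
            # instead of re-simulating the event (bit-identical, cheaper)
            sim.restore(accepted["state"])
            inc = accepted["inc"]
            peak_T_on = accepted["peak_T_on"]
        else:
            dose_before = sim.dose[..., mid].copy()
            sim.set_source(template.at(ev.focus).with_power(p0))
            sim.run_for(ev.on_s)
            peak_T_on = float(sim.T[..., mid].max())
            sim.set_source(None)
            if ev.cool_s > 0:
                sim.run_for(ev.cool_s)
            inc = float((sim.dose[..., mid] - dose_before).max())
        rows.append({
            "event": i,
            "focus_x": ev.focus[0], "focus_y": ev.focus[1], "focus_z": ev.focus[2],
            "p0": p0,
            "peak_incremental_dose_min": inc,
            "peak_T_end_on": peak_T_on,
            "peak_T_end_cool": float(sim.T[..., mid].max()),
            "n_trials": trials,
        })
    return TreatmentResult(sim=sim, plan=plan, log=pd.DataFrame(rows))


def _controlled_power(sim, ev, template, ctrl):
    """Search the event power from a checkpoint.

    Returns ``(p0, n_trials, accepted)`` where ``accepted`` carries the last
    trial's end state and log quantities when that trial used the accepted
    power (so the caller can adopt it), else ``None`` with ``sim`` restored
    to the pre-event checkpoint.
    """
    lo, hi = ctrl.band
    mid = sim.grid.midplane_index
    p0 = ctrl.history[-1] if ctrl.history else ev.p0
    chk = sim.checkpoint()
    prev = None
    best = (math.inf, p0)
    trials = 0
    accepted = None
    for _ in range(ctrl.max_iter):
        sim.restore(chk)
        dose_before = sim.dose[..., mid].copy()
        sim.set_source(template.at(ev.focus).with_power(p0))
        sim.run_for(ev.on_s)
        peak_T_on = float(sim.T[..., mid].max())
        sim.set_source(None)
        if ev.cool_s > 0:
            sim.run_for(ev.cool_s)
        observed = float((sim.dose[..., mid] - dose_before).max())
        trials += 1
        miss = abs(observed - ctrl.target)
        if miss < best[0]:
            best = (miss, p0)
        if lo <= observed <= hi:
            accepted = {"state": sim.checkpoint(), "inc": observed,
                        "peak_T_on": peak_T_on}
            break
        nxt = ctrl.propose(p0, observed, prev)
        prev = (p0, observed)
        p0 = nxt
    else:
        import warnings

        warnings.warn(
            f"dose controller hit the iteration cap; using nearest power "
            f"{best[1]:.3g} W/m^3", stacklevel=2)
        p0 = best[1]
    sim.restore(chk)
    ctrl.history.append(p0)
    return p0, trials, accepted
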