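"""Mass-action ODE model of the eight-component nutrient transition counter.

The circuit records directed nutrient switches (Glu->Gal and Gal->Glu)
in the plateau levels of two slowly degrading "memory" species — the
count statistics a cell would need for collapsed Bayesian inference
over its environment.  Architecture (two mirrored branches):

* glucose catalytically produces a *galactose* sensor;
* Gal_Sensor + Gal  <=>  Gal_Activator (reversible binding);
* Gal_Activator catalytically produces the GluToGal counter.

The mirrored branch (galactose produces the glucose sensor, etc.) feeds
the GalToGlu counter.  Because each sensor is produced by the *other*
sugar, an activator — and hence a counter spike — can only form when
the environment actually switches.  Sensors and activators turn over
quickly relative to the input pulse length; counters degrade orders of
magnitude more slowly, so their levels accumulate one near-constant
increment per switch.

Inputs (Glu, Gal) are clamped species driven by a piecewise-constant
schedule; all other species follow mass-action kinetics integrated with
a stiff-capable adaptive solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Reaction",
    "CircuitModel",
    "InputSchedule",
    "TransitionCount",
    "DEFAULT_RATES",
    "build_transition_counter",
    "simulate_circuit",
    "calibrate_increment",
    "count_transitions",
    "pulse_schedule",
    "alternating_dose_schedule",
]

SPECIES = (
    "Glu",
    "Gal",
    "Glu_Sensor",
    "Gal_Sensor",
    "Glu_Activator",
    "Gal_Activator",
    "GluToGal_Counter",
    "GalToGlu_Counter",
)

REACTION_KINDS = ("catalytic_production", "reversible_binding", "production", "degradation")

# Default rate constants (arbitrary units, time in the same units as the
# input schedule).  Chosen so sensor/activator turnover (time constants
# of a few units) is fast relative to the 50-unit input pulses, the two
# branches are symmetric, and counter degradation is slow enough that
# counter levels are effectively stable over a 200-unit simulation.
DEFAULT_RATES: dict[str, float] = {
    "k_sensor_production": 0.5,  # sugar -> opposite sensor (catalytic)
    "k_sensor_degradation": 0.2,
    "k_bind": 1.0,  # sensor + sugar -> activator
    "k_unbind": 0.1,
    "k_activator_degradation": 0.2,
    "k_counter_production": 0.5,  # activator -> counter (catalytic)
    "k_counter_degradation": 1e-4,
}


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    Rate laws by kind:

    * ``catalytic_production``: rate = k_f * prod(modifiers); products
      are produced, modifiers untouched (and consumed reactants, if any,
      would appear in the rate — none do in the default circuit).
    * ``reversible_binding``: forward k_f * prod(reactants), reverse
      k_r * prod(products).
    * ``production``: constant rate k_f into the products.
    * ``degradation``: rate k_f * [species] out of the single reactant.
    """

    kind: str
    reactants: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    modifiers: tuple[str, ...] = ()
    k_f: float = 1.0
    k_r: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.k_f <= 0:
            raise ValueError(f"rate constant must be positive, got {self.k_f}")
        if self.kind == "reversible_binding":
            if self.k_r is None or self.k_r <= 0:
                raise ValueError("reversible_binding needs a positive reverse rate")
        if self.kind == "degradation" and len(self.reactants) != 1:
            raise ValueError("degradation must target a single species")


@dataclass
class CircuitModel:
    """Species, reactions and initial concentrations of a reaction network."""

    species: tuple[str, ...]
    reactions: list[Reaction]
    initial_concentrations: dict[str, float]
    clamped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        known = set(self.species)
        for rxn in self.reactions:
            for name in (*rxn.reactants, *rxn.products, *rxn.modifiers):
                if name not in known:
                    raise ValueError(f"reaction references unknown species {name!r}")

    def index(self, name: str) -> int:
        return self.species.index(name)


@dataclass(frozen=True)
class InputSchedule:
    """Piecewise-constant (Glu, Gal) input levels over contiguous segments."""

    segments: tuple[tuple[float, float, float, float], ...]  # (t0, t1, glu, gal)

    def __post_init__(self) -> None:
        segs = tuple(tuple(map(float, s)) for s in self.segments)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        for t0, t1, glu, gal in segs:
            if t1 <= t0:
                raise ValueError(f"segment ({t0}, {t1}) is empty or reversed")
            if glu < 0 or gal < 0:
                raise ValueError("input levels must be nonnegative")
        for (_, t1a, *_), (t0b, *_) in zip(segs, segs[1:]):
            if abs(t1a - t0b) > 1e-12:
                raise ValueError("segments must be contiguous and non-overlapping")
        object.__setattr__(self, "segments", segs)

    @property
    def t_start(self) -> float:
        return self.segments[0][0]

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def levels(self, t: float) -> tuple[float, float]:
        for t0, t1, glu, gal in self.segments:
            if t0 <= t < t1:
                return glu, gal
        t0, t1, glu, gal = self.segments[-1]
        if t == t1:
            return glu, gal
        raise ValueError(f"time {t} outside schedule [{self.t_start}, {self.t_end}]")

    def swapped(self) -> "InputSchedule":
        """Schedule with the glucose and galactose doses exchanged."""
        return InputSchedule(tuple((t0, t1, gal, glu) for t0, t1, glu, gal in self.segments))


def alternating_dose_schedule(
    pulse_len: float = 50.0, n_pulses: int = 4, level: float = 1.0, start: str = "Glu"
) -> InputSchedule:
    """Alternating single-sugar doses (default: Glu/Gal switching every 50 units)."""
    order = ("Glu", "Gal") if start == "Glu" else ("Gal", "Glu")
    return pulse_schedule([(order[i % 2], pulse_len) for i in range(n_pulses)], level=level)


def pulse_schedule(blocks: list[tuple[str, float]], level: float = 1.0) -> InputSchedule:
    """Build a schedule from ('Glu'|'Gal'|'none', duration) blocks."""
    segs = []
    t = 0.0
    for sugar, dur in blocks:
        glu = level if sugar == "Glu" else 0.0
        gal = level if sugar == "Gal" else 0.0
        if sugar not in ("Glu", "Gal", "none"):
            raise ValueError(f"unknown sugar {sugar!r}")
        segs.append((t, t + dur, glu, gal))
        t += dur
    return InputSchedule(tuple(segs))


def build_transition_counter(**rate_overrides: float) -> CircuitModel:
    """The eight-species Glu/Gal transition-counter network.

    Keyword overrides replace entries of ``DEFAULT_RATES`` (all must be
    positive).  The two branches use identical constants, so the circuit
    is exactly mirror-symmetric under a Glu<->Gal swap.
    """
    rates = dict(DEFAULT_RATES)
    for key, value in rate_overrides.items():
        if key not in rates:
            raise ValueError(f"unknown rate constant {key!r}; valid: {sorted(rates)}")
        if value <= 0:
            raise ValueError(f"rate constant {key} must be positive, got {value}")
        rates[key] = float(value)

    reactions = []
    for sugar, other, activator, sensor, counter in (
        ("Glu", "Gal", "Gal_Activator", "Gal_Sensor", "GluToGal_Counter"),
        ("Gal", "Glu", "Glu_Activator", "Glu_Sensor", "GalToGlu_Counter"),
    ):
        reactions += [
            # sugar catalytically produces the sensor for the *other* sugar
            Reaction("catalytic_production", products=(sensor,), modifiers=(sugar,),
                     k_f=rates["k_sensor_production"]),
            Reaction("degradation", reactants=(sensor,), k_f=rates["k_sensor_degradation"]),
            # sensor + its sugar reversibly form the activator
            Reaction("reversible_binding", reactants=(sensor, other), products=(activator,),
                     k_f=rates["k_bind"], k_r=rates["k_unbind"]),
            Reaction("degradation", reactants=(activator,), k_f=rates["k_activator_degradation"]),
            # activator catalytically produces the transition counter
            Reaction("catalytic_production", products=(counter,), modifiers=(activator,),
                     k_f=rates["k_counter_production"]),
            Reaction("degradation", reactants=(counter,), k_f=rates["k_counter_degradation"]),
        ]
    return CircuitModel(
        species=SPECIES,
        reactions=reactions,
        initial_concentrations={name: 0.0 for name in SPECIES},
        clamped=("Glu", "Gal"),
    )


def _rhs_factory(model: CircuitModel):
    n = len(model.species)
    idx = {name: i for i, name in enumerate(model.species)}
    clamped = np.array([name in model.clamped for name in model.species])

    terms = []  # (rate_constant, multiplicative indices, stoichiometry vector)
    for rxn in model.reactions:
        if rxn.kind == "catalytic_production":
            mult = [idx[m] for m in (*rxn.modifiers, *rxn.reactants)]
            stoich = np.zeros(n)
            for r in rxn.reactants:
                stoich[idx[r]] -= 1
            for p in rxn.products:
                stoich[idx[p]] += 1
            terms.append((rxn.k_f, mult, stoich))
        elif rxn.kind == "production":
            stoich = np.zeros(n)
            for p in rxn.products:
                stoich[idx[p]] += 1
            terms.append((rxn.k_f, [], stoich))
        elif rxn.kind == "degradation":
            stoich = np.zeros(n)
            stoich[idx[rxn.reactants[0]]] -= 1
            terms.append((rxn.k_f, [idx[rxn.reactants[0]]], stoich))
        elif rxn.kind == "reversible_binding":
            fwd = np.zeros(n)
            for r in rxn.reactants:
                fwd[idx[r]] -= 1
            for p in rxn.products:
                fwd[idx[p]] += 1
            terms.append((rxn.k_f, [idx[r] for r in rxn.reactants], fwd))
            terms.append((rxn.k_r, [idx[p] for p in rxn.products], -fwd))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n)
        for k, mult, stoich in terms:
            rate = k
            for i in mult:
                rate *= max(y[i], 0.0)
            dy += rate * stoich
        dy[clamped] = 0.0
        return dy

    return rhs


def simulate_circuit(
    model: CircuitModel,
    schedule: InputSchedule,
    dt: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate the network under the clamped input schedule.

    Integrates segment by segment (inputs are discontinuous at segment
    boundaries) with LSODA at tight tolerances; returns a DataFrame with
    a ``t`` column and one column per species, sampled every ``dt``.
    """
    rhs = _rhs_factory(model)
    y = np.array([model.initial_concentrations.get(s, 0.0) for s in model.species])
    i_glu, i_gal = model.index("Glu"), model.index("Gal")
    frames = []
    for seg_no, (t0, t1, glu, gal) in enumerate(schedule.segments):
        y[i_glu], y[i_gal] = glu, gal
        n_out = max(2, int(round((t1 - t0) / dt)) + 1)
        t_eval = np.linspace(t0, t1, n_out)
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"integrator failed in segment {seg_no} [{t0}, {t1}]: {sol.message}; "
                f"state at failure: {dict(zip(model.species, y))}"
            )
        y = sol.y[:, -1].copy()
        # drop the duplicated segment-boundary sample except for the first segment
        start = 1 if frames else 0
        frames.append(
            pd.DataFrame(
                {"t": sol.t[start:], **{s: sol.y[j, start:] for j, s in enumerate(model.species)}}
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out[out.columns[1:]] = out[out.columns[1:]].clip(lower=0.0)
    return out


def calibrate_increment(
    model: CircuitModel, direction: str = "GluToGal", pulse_len: float = 50.0, level: float = 1.0
) -> float:
    """Final counter level after exactly one switch: the single-spike increment."""
    if direction == "GluToGal":
        schedule = pulse_schedule([("Glu", pulse_len), ("Gal", pulse_len)], level=level)
        column = "GluToGal_Counter"
    elif direction == "GalToGlu":
        schedule = pulse_schedule([("Gal", pulse_len), ("Glu", pulse_len)], level=level)
        column = "GalToGlu_Counter"
    else:
        raise ValueError("direction must be 'GluToGal' or 'GalToGlu'")
    traj = simulate_circuit(model, schedule)
    return float(traj[column].iloc[-1])


@dataclass(frozen=True)
class TransitionCount:
    """Integer transition count read from a counter trajectory."""

    count: int
    spike_times: tuple[float, ...]
    final_level: float
    increment: float


def count_transitions(
    times: np.ndarray,
    counter: np.ndarray,
    single_spike_increment: float,
    spike_threshold: float = 0.1,
) -> TransitionCount:
    """Read an integer switch count off a counter trajectory.

    The count is the final plateau level divided by the calibrated
    single-switch increment, rounded.  Spike times are where the
    production rate d[counter]/dt exceeds ``spike_threshold`` times its
    maximum (contiguous crossings grouped, time of peak rate reported).
    """
    if single_spike_increment <= 0:
        raise ValueError("single_spike_increment must be positive")
    times = np.asarray(times, dtype=float)
    counter = np.asarray(counter, dtype=float)
    final = float(counter[-1])
    count = int(round(final / single_spike_increment))

    rate = np.gradient(counter, times)
    spikes: list[float] = []
    peak = rate.max(initial=0.0)
    if peak > 0:
        above = rate > spike_threshold * peak
        edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
        starts = ([0] if above[0] else []) + list(edges)
        for s in starts:
            e = s
            while e < above.size and above[e]:
                e += 1
            seg = slice(s, e)
            spikes.append(float(times[seg][np.argmax(rate[seg])]))
    return TransitionCount(
        count=count,
        spike_times=tuple(spikes),
        final_level=final,
        increment=float(single_spike_increment),
    )
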