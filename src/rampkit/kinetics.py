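"""First-order kinetic model of pre-rRNA processing.

The orthogonal-cleavage picture of ITS1 separation is made quantitative
here as a linear reaction network: transcription feeds the PTP pool at a
constant rate rho, and every processing or disposal step consumes its
substrate with a first-order rate constant.  The rate constants of the two
separating cleavages (2b on the SSU side, 2c on the LSU side) embody the
kinetic competition between subunit assembly programs: whichever side of
the transcript completes early maturation first triggers the cleavage
proximal to it.  Knockdowns are multiplicative inhibition factors applied
to every reaction carrying a given factor tag.

Because the network is linear, the steady state solves a (triangular,
since the pathway is a DAG) linear system; an explicit time-course
integrator from empty initial conditions provides an independent oracle.
Mature rRNAs are terminal sinks: they have no outflow, their inflow is
counted as terminal flux, and nucleotide-weighted flux conservation
(rho x len(45S) equals the summed terminal flux x length) closes the
balance.

The module also generates synthetic quantification tables that emulate the
northern-blot measurement process the ratio analysis is designed to be
robust to: per-lane loading factors, per-blot probe-efficiency factors and
multiplicative lognormal signal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pathway import PathwayGraph, ReactionKind, build_default_mouse_pathway, species_length
from .quantio import COLUMNS, QuantTable
from .ramp import RAMPProfile, RatioPanel, aggregate_replicates, build_profile, default_mouse_panel

__all__ = [
    "RateModel",
    "SteadyState",
    "Perturbation",
    "Scenario",
    "NoiseSpec",
    "BlotDesign",
    "MeasurementDesign",
    "KineticsError",
    "SingularModelError",
    "UnstableStepError",
    "DEFAULT_RATE_CONSTANTS",
    "default_rate_model",
    "steady_state",
    "timecourse",
    "apply_perturbation",
    "synthesize_quant_table",
    "default_design",
    "scenario_battery",
    "simulate_scenario_profile",
    "random_models",
    "random_scenarios",
    "PERTURBABLE_TAGS",
]


class KineticsError(ValueError):
    pass


class SingularModelError(KineticsError):
    """A species accumulates without bound (inflow but zero outflow)."""


class UnstableStepError(KineticsError):
    """Integration step too large for the fastest rate in the model."""


#: default first-order rate constants (1/h) for the canonical mouse model.
#: Chosen once to reflect steady-state precursor patterns of rapidly
#: dividing 3T3 cells: the 2b route is moderately favoured (k_2b/k_2c =
#: 1.2/0.8, ~60% of transcripts split at 2b first), 32S is an abundant,
#: long-lived precursor (slow 4b cleavage), the ITS1 remnant of 32.5S is
#: removed rapidly by Xrn2, and discarded spacer fragments are disposed of
#: at ten times the fastest processing constant.
DEFAULT_RATE_CONSTANTS: dict[str, float] = {
    "2b@PTP": 1.2,
    "2c@PTP": 0.8,
    "A0@34S": 0.8,
    "1@29S": 1.0,
    "2b@20S": 1.0,
    "1@SSU-2b-pre": 1.0,
    "2c@36S": 1.2,
    "xrn2@32.5S": 5.0,
    "4b@32S": 0.4,
    "mat@18SE": 1.0,
    "mat@12S": 0.8,
    "mat@28.5S": 4.0,
    "decay@19S": 2.0,
    "decay@frag:5ETS-A0": 50.0,
    "decay@frag:5ETS-A1": 50.0,
    "decay@frag:ITS1-internal": 50.0,
}

DEFAULT_TRANSCRIPTION_RATE = 100.0

#: tags that make sense as knockdown targets (have processing reactions)
PERTURBABLE_TAGS: tuple[str, ...] = ("2b", "2c", "SSU-A0", "site1", "ITS2", "late-18SE", "xrn2")


@dataclass(frozen=True)
class RateModel:
    """Transcription rate plus per-reaction first-order rate constants."""

    graph: PathwayGraph
    transcription_rate: float
    rate_constants: dict[str, float]
    degradation_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcription_rate > 0:
            raise KineticsError("transcription rate must be positive")
        for r in self.graph.reactions:
            if r.kind is ReactionKind.TRANSCRIPTION:
                continue
            k = self.rate_constants.get(r.id)
            if k is None:
                raise KineticsError(f"no rate constant for reaction {r.id!r}")
            if not k > 0:
                raise KineticsError(f"rate constant for {r.id!r} must be positive, got {k}")
        for sp, d in self.degradation_rates.items():
            if d < 0:
                raise KineticsError(f"negative degradation rate for {sp!r}")


def default_rate_model(
    graph: PathwayGraph | None = None,
    transcription_rate: float = DEFAULT_TRANSCRIPTION_RATE,
    overrides: dict[str, float] | None = None,
) -> RateModel:
    graph = graph or build_default_mouse_pathway()
    rates = dict(DEFAULT_RATE_CONSTANTS)
    if overrides:
        rates.update(overrides)
    return RateModel(graph, transcription_rate, rates)


# ---------------------------------------------------------------------------
# steady state and time course


def _assemble(model: RateModel):
    """Linear system pieces: solved species, M (dx/dt = b + M x), inflow b."""
    graph = model.graph
    names = [sp for sp in graph.species if not graph.species[sp].is_pseudo or sp == "PTP"]
    # PTP is the kinetic node; its members are not separate kinetic species
    names = [n for n in names if not graph.species[n].ptp_member]
    outflow = {n: model.degradation_rates.get(n, 0.0) for n in names}
    for r in graph.reactions:
        if r.kind is ReactionKind.TRANSCRIPTION or r.substrate is None:
            continue
        outflow[r.substrate] = outflow.get(r.substrate, 0.0) + model.rate_constants[r.id]
    solved = [n for n in names if outflow[n] > 0]
    sinks = [n for n in names if outflow[n] == 0]
    idx = {n: i for i, n in enumerate(solved)}
    m = np.zeros((len(solved), len(solved)))
    b = np.zeros(len(solved))
    for r in graph.reactions:
        if r.kind is ReactionKind.TRANSCRIPTION:
            for p in r.products:
                if p in idx:
                    b[idx[p]] += model.transcription_rate
            continue
        k = model.rate_constants[r.id]
        j = idx[r.substrate]
        m[j, j] -= k
        for p in r.products:
            if p in idx:
                m[idx[p], j] += k
    for n, d in model.degradation_rates.items():
        if n in idx and d > 0:
            m[idx[n], idx[n]] -= d
    return solved, sinks, idx, m, b, outflow


def steady_state(model: RateModel) -> "SteadyState":
    """Solve inflow = outflow for every non-terminal species.

    Mature rRNAs (and any other zero-outflow species) are terminal sinks;
    a *non-mature* species with inflow but no outflow makes the system
    singular and is reported by name.
    """
    solved, sinks, idx, m, b, outflow = _assemble(model)
    graph = model.graph
    x = np.linalg.solve(m, -b)
    if np.any(x < -1e-9 * max(1.0, float(np.max(np.abs(x))))):
        raise KineticsError("negative steady-state abundance (inconsistent model)")
    x = np.clip(x, 0.0, None)
    resid = m @ x + b
    scale = max(1.0, float(np.max(np.abs(b))))
    if float(np.max(np.abs(resid))) > 1e-10 * scale:
        raise KineticsError("steady-state solve did not converge to tolerance")

    abundances = {n: float(x[idx[n]]) for n in solved}
    fluxes: dict[str, float] = {}
    sink_fluxes: dict[str, float] = {n: 0.0 for n in sinks}
    for r in graph.reactions:
        if r.kind is ReactionKind.TRANSCRIPTION:
            fluxes[r.id] = model.transcription_rate
            for p in r.products:
                if p in sink_fluxes:
                    sink_fluxes[p] += model.transcription_rate
            continue
        fluxes[r.id] = model.rate_constants[r.id] * abundances[r.substrate]
        for p in r.products:
            if p in sink_fluxes:
                sink_fluxes[p] += fluxes[r.id]
    for n in sinks:
        if sink_fluxes[n] > 0 and not graph.species[n].is_mature:
            raise SingularModelError(
                f"species {n!r} has inflow but zero outflow (not a mature sink)"
            )
    # degradation flux counts as terminal
    degradation_fluxes = {
        n: d * abundances[n]
        for n, d in model.degradation_rates.items()
        if n in abundances and d > 0
    }
    return SteadyState(model, abundances, fluxes, sink_fluxes, degradation_fluxes)


@dataclass(frozen=True)
class SteadyState:
    """Abundances of all non-terminal species plus per-reaction fluxes."""

    model: RateModel
    abundances: dict[str, float]
    fluxes: dict[str, float]
    sink_fluxes: dict[str, float]
    degradation_fluxes: dict[str, float] = field(default_factory=dict)

    def abundance(self, species: str) -> float:
        try:
            return self.abundances[species]
        except KeyError:
            raise KineticsError(
                f"{species!r} has no steady-state abundance (terminal sink or unknown)"
            ) from None

    def nucleotide_balance(self) -> tuple[float, float]:
        """(transcribed nt/time, terminal nt/time) - equal at steady state.

        Transcription is weighted by the PTP proxy extent (45S); terminal
        fluxes by each sink/disposed species' length.
        """
        graph = self.model.graph
        lengths = graph.lengths
        rho_len = self.model.transcription_rate * species_length(
            graph.substrate_extent("PTP"), lengths
        )
        out = 0.0
        for n, f in self.sink_fluxes.items():
            out += f * species_length(graph.species[n], lengths)
        for r in graph.reactions:
            if r.kind is ReactionKind.TERMINAL:
                out += self.fluxes[r.id] * species_length(graph.species[r.substrate], lengths)
            elif r.kind is ReactionKind.EXONUCLEOLYTIC:
                # residues nibbled away by the exonuclease leave the system here
                trimmed = species_length(graph.species[r.substrate], lengths) - species_length(
                    graph.species[r.products[0]], lengths
                )
                out += self.fluxes[r.id] * trimmed
        for n, f in self.degradation_fluxes.items():
            out += f * species_length(graph.species[n], lengths)
        return rho_len, out


def timecourse(
    model: RateModel,
    t_end: float,
    dt: float | None = None,
    n_save: int = 201,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Explicit RK4 integration from empty initial abundances.

    Returns (times, trajectory[t, species], species names).  The default
    step is 0.5 / (fastest total outflow); steps beyond the RK4 stability
    bound (~2.78 / fastest outflow) are rejected with a suggested dt.
    Because the network is linear, the integrator's fixed point coincides
    with the true steady state, so at ``t_end`` much larger than the
    slowest timescale the end point matches :func:`steady_state` to
    solver precision.
    """
    solved, _, idx, m, b, outflow = _assemble(model)
    lam = max(outflow[n] for n in solved)
    if dt is None:
        dt = 0.5 / lam
    if dt <= 0:
        raise UnstableStepError("dt must be positive")
    if dt * lam > 2.78:
        raise UnstableStepError(
            f"dt={dt:g} unstable for fastest total outflow {lam:g}; try dt <= {2.0 / lam:g}"
        )
    if t_end < 0:
        raise KineticsError("t_end must be >= 0")
    if t_end == 0:
        x0 = np.zeros(len(solved))
        return np.array([0.0]), x0[None, :], list(solved)
    n_steps = max(1, math.ceil(t_end / dt))
    h = t_end / n_steps
    x = np.zeros(len(solved))
    save_every = max(1, n_steps // max(1, n_save - 1))
    times = [0.0]
    traj = [x.copy()]

    def f(v: np.ndarray) -> np.ndarray:
        return b + m @ v

    for s in range(1, n_steps + 1):
        k1 = f(x)
        k2 = f(x + 0.5 * h * k1)
        k3 = f(x + 0.5 * h * k2)
        k4 = f(x + h * k3)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if s % save_every == 0 or s == n_steps:
            times.append(s * h)
            traj.append(x.copy())
    return np.array(times), np.array(traj), list(solved)


# ---------------------------------------------------------------------------
# perturbations and scenarios


@dataclass(frozen=True)
class Perturbation:
    """Multiplicative rate modifiers keyed by factor tag.

    Factors in (0, 1) inhibit; factors above 1 stimulate (used by the
    growth-state scenario).  A reaction carrying several mapped tags is
    scaled by the product of their factors, so composing perturbations is
    multiplicative.
    """

    name: str
    factors: dict[str, float]

    def __post_init__(self) -> None:
        for tag, f in self.factors.items():
            if not f > 0:
                raise KineticsError(f"perturbation {self.name!r}: factor for {tag!r} must be > 0")


def apply_perturbation(model: RateModel, perturbation: Perturbation) -> RateModel:
    """Scale every reaction carrying a mapped factor tag; copy, not mutate."""
    known = model.graph.factor_tags()
    unknown = [t for t in perturbation.factors if t not in known]
    if unknown:
        raise KineticsError(f"unknown factor tag(s) {unknown} in perturbation {perturbation.name!r}")
    rates = dict(model.rate_constants)
    for r in model.graph.reactions:
        scale = 1.0
        for tag in r.factor_tags:
            scale *= perturbation.factors.get(tag, 1.0)
        if scale != 1.0:
            rates[r.id] = rates[r.id] * scale
    return replace(model, rate_constants=rates)


@dataclass(frozen=True)
class Scenario:
    """A named perturbation plus its expected qualitative profile signs.

    ``expected_signs`` maps panel ratio labels to -1/0/+1 at the default
    study conditions (inhibition factor 0.25, mild factor 0.7, default rate
    constants) with the standard 1.5-fold interpretation threshold.
    """

    name: str
    perturbation: Perturbation
    expected_signs: dict[str, int] = field(default_factory=dict)


def scenario_battery(f: float = 0.25, f_mild: float = 0.7) -> list[Scenario]:
    """Knockdown and growth-state scenarios with expected sign patterns.

    The SSU-early factors couple a 5'ETS step with site 2b (Rcl1-like:
    site 1 + 2b; Fcf1-like: A0 + 2b); Utp23-like blocks the late 18SE
    maturation step with mild effects on A0/site 1; the LSU factors
    (Pes1/Nog1-like) couple site 2c with ITS2 processing.  The growth
    scenarios move the SSU-side maturation constant feeding 2b down
    (quiescence) or up (rapid growth), shifting which ITS1 site is cleaved
    first.  Expected signs are the steady-state predictions of the default
    model at f=0.25; they include the experimentally reported directions
    (34S/36S and 36S/PTP for SSU-early knockdowns, 18SE/PTP for Utp23-like,
    12S/32S, 36S/PTP and 34S/36S for LSU knockdowns).
    """
    return [
        Scenario(
            "rcl1_like",
            Perturbation("rcl1_like", {"site1": f, "2b": f}),
            {
                "34S/PTP": 0, "36S/PTP": -1, "29S/PTP": +1, "20S/PTP": +1, "19S/PTP": 0,
                "18SE/PTP": -1, "32S/PTP": -1, "12S/PTP": -1,
                "34S/36S": +1, "29S/34S": +1, "20S/34S": +1, "18SE/34S": -1,
                "18SE/20S": -1, "32S/36S": +1, "12S/32S": 0,
            },
        ),
        Scenario(
            "fcf1_like",
            Perturbation("fcf1_like", {"SSU-A0": f, "2b": f}),
            {
                "34S/PTP": +1, "36S/PTP": -1, "29S/PTP": 0, "20S/PTP": +1, "19S/PTP": 0,
                "18SE/PTP": -1, "32S/PTP": -1, "12S/PTP": -1,
                "34S/36S": +1, "29S/34S": -1, "20S/34S": 0, "18SE/34S": -1,
                "18SE/20S": -1, "32S/36S": +1, "12S/32S": 0,
            },
        ),
        Scenario(
            "utp23_like",
            Perturbation("utp23_like", {"late-18SE": f, "SSU-A0": f_mild, "site1": f_mild}),
            {
                "34S/PTP": 0, "36S/PTP": 0, "29S/PTP": 0, "20S/PTP": 0, "19S/PTP": 0,
                "18SE/PTP": +1, "32S/PTP": 0, "12S/PTP": 0,
                "34S/36S": 0, "29S/34S": 0, "20S/34S": 0, "18SE/34S": +1,
                "18SE/20S": +1, "32S/36S": 0, "12S/32S": 0,
            },
        ),
        Scenario(
            "pes1_like",
            Perturbation("pes1_like", {"2c": f, "ITS2": f}),
            {
                "34S/PTP": -1, "36S/PTP": +1, "29S/PTP": -1, "20S/PTP": -1, "19S/PTP": -1,
                "18SE/PTP": 0, "32S/PTP": +1, "12S/PTP": 0,
                "34S/36S": -1, "29S/34S": 0, "20S/34S": 0, "18SE/34S": +1,
                "18SE/20S": +1, "32S/36S": 0, "12S/32S": -1,
            },
        ),
        Scenario(
            "nog1_like",
            Perturbation("nog1_like", {"2c": f, "ITS2": f}),
            {
                "34S/PTP": -1, "36S/PTP": +1, "29S/PTP": -1, "20S/PTP": -1, "19S/PTP": -1,
                "18SE/PTP": 0, "32S/PTP": +1, "12S/PTP": 0,
                "34S/36S": -1, "29S/34S": 0, "20S/34S": 0, "18SE/34S": +1,
                "18SE/20S": +1, "32S/36S": 0, "12S/32S": -1,
            },
        ),
        Scenario(
            "quiescence_like",
            Perturbation("quiescence_like", {"2b": f}),
            {
                "34S/PTP": 0, "36S/PTP": -1, "29S/PTP": 0, "20S/PTP": +1, "19S/PTP": 0,
                "18SE/PTP": -1, "32S/PTP": -1, "12S/PTP": -1,
                "34S/36S": +1, "29S/34S": 0, "20S/34S": +1, "18SE/34S": -1,
                "18SE/20S": -1, "32S/36S": +1, "12S/32S": 0,
            },
        ),
        Scenario(
            "growth_like",
            Perturbation("growth_like", {"2b": 1.0 / f}),
            {
                "34S/PTP": 0, "36S/PTP": +1, "29S/PTP": 0, "20S/PTP": -1, "19S/PTP": 0,
                "18SE/PTP": +1, "32S/PTP": +1, "12S/PTP": +1,
                "34S/36S": -1, "29S/34S": 0, "20S/34S": -1, "18SE/34S": +1,
                "18SE/20S": +1, "32S/36S": 0, "12S/32S": 0,
            },
        ),
    ]


# ---------------------------------------------------------------------------
# synthetic measurement tables


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-process emulation.

    ``sigma_log`` is the SD of multiplicative lognormal signal noise (in
    natural log units).  Lane and probe factors model uneven sample loading
    and variable hybridization efficiency; they are drawn lognormally with
    the given SDs unless explicit dictionaries are supplied.  All of them
    cancel exactly in within-lane ratios - that is the point of RAMP.
    """

    sigma_log: float = 0.0
    lane_factor_sd: float = 0.0
    probe_factor_sd: float = 0.0
    lane_factors: dict[tuple[str, int], float] | None = None
    probe_factors: dict[str, float] | None = None


@dataclass(frozen=True)
class BlotDesign:
    """One hybridization: a membrane probed with one oligo."""

    blot_id: str
    probe: str
    species: tuple[str, ...]


@dataclass(frozen=True)
class LaneSpec:
    sample_id: str
    experiment_id: str
    condition: str  # "reference" or "knockdown:<factor>"


@dataclass(frozen=True)
class MeasurementDesign:
    blots: tuple[BlotDesign, ...]
    lanes: dict[int, LaneSpec]  # same lane layout on every blot


def default_design(lanes: dict[int, LaneSpec]) -> MeasurementDesign:
    """Four-blot design covering the whole default panel.

    Species lists follow probe-target containment (see seqannot): the probe
    3' of site 2b (ITS1-85) sees 36S but not 18SE; the probe 5' of 2b
    (ITS1-54) sees 18SE but not 36S; an ITS2 probe 5' of 4b covers the LSU
    intermediates; a 5'ETS probe between A0 and site 1 covers 19S.
    """
    return MeasurementDesign(
        (
            BlotDesign("B-ITS1-85", "ITS1-85", ("PTP", "34S", "36S", "29S", "20S")),
            BlotDesign("B-ITS1-54", "ITS1-54", ("PTP", "34S", "29S", "20S", "18SE")),
            BlotDesign("B-ITS2-100", "ITS2-100", ("PTP", "36S", "32.5S", "32S", "12S")),
            BlotDesign("B-ETS-3000", "5ETS-3000", ("PTP", "34S", "29S", "19S")),
        ),
        dict(lanes),
    )


def synthesize_quant_table(
    states: dict[str, SteadyState] | SteadyState,
    design: MeasurementDesign,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> QuantTable:
    """Emit a noisy quant table from steady-state abundances.

    signal = abundance x lane_factor x probe_factor x exp(N(0, sigma^2)),
    reproducibly under ``seed``.  ``states`` maps sample ids (as referenced
    by the design's lanes) to steady states; a bare SteadyState is accepted
    when all lanes show the same sample.
    """
    if isinstance(states, SteadyState):
        sample_ids = {spec.sample_id for spec in design.lanes.values()}
        states = {sid: states for sid in sample_ids}
    rng = np.random.default_rng(seed)
    lane_keys = [(b.blot_id, lane) for b in design.blots for lane in sorted(design.lanes)]
    if noise.lane_factors is not None:
        lane_factors = dict(noise.lane_factors)
    else:
        draws = rng.lognormal(0.0, noise.lane_factor_sd, size=len(lane_keys))
        lane_factors = dict(zip(lane_keys, draws))
    if noise.probe_factors is not None:
        probe_factors = dict(noise.probe_factors)
    else:
        draws = rng.lognormal(0.0, noise.probe_factor_sd, size=len(design.blots))
        probe_factors = {b.blot_id: d for b, d in zip(design.blots, draws)}

    rows = []
    for blot in design.blots:
        for lane in sorted(design.lanes):
            spec = design.lanes[lane]
            state = states[spec.sample_id]
            for sp in blot.species:
                try:
                    ab = state.abundance(sp)
                except KineticsError:
                    raise KineticsError(
                        f"design assigns species {sp!r} to blot {blot.blot_id!r} but the "
                        "steady state has no abundance for it"
                    ) from None
                eps = math.exp(rng.normal(0.0, noise.sigma_log)) if noise.sigma_log > 0 else 1.0
                signal = ab * lane_factors[(blot.blot_id, lane)] * probe_factors[blot.blot_id] * eps
                rows.append(
                    (
                        blot.blot_id,
                        blot.probe,
                        spec.sample_id,
                        lane,
                        sp,
                        signal,
                        spec.experiment_id,
                        spec.condition,
                    )
                )
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    return QuantTable(frame)


def simulate_scenario_profile(
    perturbation: Perturbation,
    model: RateModel | None = None,
    panel: RatioPanel | None = None,
    n_replicates: int = 1,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> RAMPProfile:
    """Full in-silico RAMP experiment for one perturbation.

    Each replicate solves the reference and perturbed steady states, lays
    them out as paired lanes of the default four-blot design, synthesizes a
    noisy table and builds a single-experiment profile; replicates are then
    averaged.  The result carries the perturbation name as ``factor``
    metadata.
    """
    model = model or default_rate_model()
    panel = panel or default_mouse_panel(model.graph)
    ref_state = steady_state(model)
    kd_state = steady_state(apply_perturbation(model, perturbation))
    profiles = []
    for rep in range(n_replicates):
        exp = f"E{rep + 1}"
        lanes = {
            1: LaneSpec(f"ref-{exp}", exp, "reference"),
            2: LaneSpec(f"kd-{exp}", exp, f"knockdown:{perturbation.name}"),
        }
        design = default_design(lanes)
        table = synthesize_quant_table(
            {f"ref-{exp}": ref_state, f"kd-{exp}": kd_state},
            design,
            noise,
            seed=seed * 100003 + rep,
        )
        prof = build_profile(table, f"kd-{exp}", f"ref-{exp}", panel, model.graph)
        prof.metadata["factor"] = perturbation.name
        profiles.append(prof)
    if n_replicates == 1:
        return profiles[0]
    agg = aggregate_replicates(profiles)
    agg.metadata["factor"] = perturbation.name
    return agg


# ---------------------------------------------------------------------------
# randomized inputs for oracle and recovery experiments


def random_models(n: int, seed: int, graph: PathwayGraph | None = None) -> list[RateModel]:
    """Random valid rate models on the canonical graph (for oracle checks)."""
    graph = graph or build_default_mouse_pathway()
    rng = np.random.default_rng(seed)
    models = []
    reaction_ids = [r.id for r in graph.reactions if r.kind is not ReactionKind.TRANSCRIPTION]
    for _ in range(n):
        rates = {rid: float(rng.uniform(0.3, 3.0)) for rid in reaction_ids}
        rho = float(rng.uniform(10.0, 200.0))
        models.append(RateModel(graph, rho, rates))
    return models


def random_scenarios(
    n: int,
    seed: int,
    tags: tuple[str, ...] = ("2b", "2c", "SSU-A0", "site1", "ITS2", "late-18SE"),
    factors: tuple[float, ...] = (0.5, 0.25, 0.1),
) -> list[Perturbation]:
    """Random knockdown scenarios: 1-2 distinct tags, factors from ``factors``."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        k = int(rng.integers(1, 3))
        chosen = rng.choice(len(tags), size=k, replace=False)
        fmap = {tags[j]: float(factors[rng.integers(0, len(factors))]) for j in chosen}
        out.append(Perturbation(f"rand-{i}", fmap))
    return out
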