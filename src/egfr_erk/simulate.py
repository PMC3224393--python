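"""Stiff ODE simulation of cell-line variants and western-blot observables.

``simulate`` integrates a :class:`~egfr_erk.network.ModelVariant` under a
:class:`StimulusProtocol` with a stiff-capable multistep solver (LSODA by
default, BDF available), then ``observables``/``normalize_panel`` turn raw
trajectories into the normalized phospho readouts that densitometry panels
report: per protein, the t = 0 level is subtracted and the panel-wide maximum
is scaled to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import (
    DIMER_OBSERVABLE_WEIGHT,
    ModelVariant,
    ParameterSet,
    RateLaw,
    ReactionNetwork,
    rate as reaction_rate,
)

__all__ = [
    "StimulusProtocol",
    "Trajectory",
    "ObservableSeries",
    "SolverConfig",
    "SimulationError",
    "DEFAULT_TIME_GRID",
    "ESTIMATION_TIME_POINTS",
    "PHOSPHO_PROTEINS",
    "RAW_READOUTS",
    "build_rhs",
    "simulate",
    "observables",
    "observable_values",
    "normalize_panel",
    "dose_response",
]

#: Sampling grid of the time-course experiments (min).
DEFAULT_TIME_GRID = (0.0, 1.0, 5.0, 10.0, 30.0, 120.0, 360.0)
#: Subset entering the estimation objective (min).
ESTIMATION_TIME_POINTS = (1.0, 5.0, 10.0, 30.0)

PHOSPHO_PROTEINS = ("pEGFR", "pShc", "pMEK", "pERK")
#: Raw single-species readouts used by the perturbation analyses.
RAW_READOUTS = (
    "E11P_ShcP_GS", "RasGTP", "Raf1A", "MEKP", "MEKPP", "ERKP", "ERKPP",
)

#: Antibody-to-species mapping. The phospho-EGFR antibody detects every
#: complex containing a phosphorylated dimer (weighted once per dimer by
#: default); phospho-Shc detects free and complexed ShcP; the phospho-MEK
#: antibody (Ser217/221) detects singly and doubly phosphorylated MEK; the
#: phospho-ERK antibody detects only doubly phosphorylated p44/42.
OBSERVABLE_DEFINITIONS: dict[str, dict[str, float]] = {
    "pEGFR": {
        sid: float(DIMER_OBSERVABLE_WEIGHT)
        for sid in ("E11P", "E11P_Cbl", "E11P_GAP", "E11P_Shc",
                    "E11P_ShcP", "E11P_ShcP_GS")
    },
    "pShc": {"ShcP": 1.0, "E11P_ShcP": 1.0, "E11P_ShcP_GS": 1.0, "ShcP_GS": 1.0},
    "pMEK": {"MEKP": 1.0, "MEKPP": 1.0},
    "pERK": {"ERKPP": 1.0},
}


class SimulationError(RuntimeError):
    """Solver failure, annotated with the failing variant and protocol."""


@dataclass(frozen=True)
class StimulusProtocol:
    """EGF stimulation protocol.

    ``gefitinib_alpha`` multiplies the receptor autophosphorylation rate
    constant k3 for the whole run (alpha = 1 means no drug).
    ``pre_equilibration`` integrates the unstimulated system for the given
    duration before EGF is applied — a no-op for the reference model, whose
    resting state is stationary, but meaningful for perturbed initials.
    """

    egf_dose: float = 10.0
    gefitinib_alpha: float = 1.0
    pre_equilibration: float = 0.0
    t_outputs: tuple[float, ...] = DEFAULT_TIME_GRID

    def __post_init__(self) -> None:
        if self.egf_dose < 0:
            raise ValueError("egf_dose must be >= 0")
        if not 0 < self.gefitinib_alpha <= 1:
            raise ValueError("gefitinib_alpha must lie in (0, 1]")
        t = tuple(float(x) for x in self.t_outputs)
        if not t or t[0] != 0.0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("t_outputs must be strictly ascending from 0")
        object.__setattr__(self, "t_outputs", t)


@dataclass(frozen=True)
class SolverConfig:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12  # resolves deeply inhibited states far below 1 nM
    max_step: float = np.inf


@dataclass(frozen=True)
class Trajectory:
    """Raw ODE solution on the protocol's output grid."""

    times: np.ndarray
    states: np.ndarray  # (n_species, n_times), full species order
    species_ids: tuple[str, ...]
    variant: str
    protocol: StimulusProtocol

    def __getitem__(self, species_id: str) -> np.ndarray:
        return self.states[self.species_ids.index(species_id)]


@dataclass(frozen=True)
class ObservableSeries:
    """One protein readout over time for one (variant, protocol)."""

    protein: str
    times: np.ndarray
    values: np.ndarray
    variant: str
    normalized: bool = False
    label: str | None = None  # panel key, e.g. a dose tag

    def replaced(self, **kw) -> "ObservableSeries":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def build_rhs(
    network: ReactionNetwork,
    params: ParameterSet,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the ODE right-hand side dx/dt = S v(x).

    The 27 flux expressions and their stoichiometric sums are unrolled into
    generated source and compiled once per (network, parameter) combination,
    which keeps the multistep solvers' many repeated evaluations cheap.
    Constant species get a zero derivative. The generated function is
    cross-checked against the per-reaction :func:`rhs_reference` interpreter
    in the test suite.
    """
    idx = {sid: i for i, sid in enumerate(network.species_ids)}
    dynamic = {s.id for s in network.species if s.is_dynamic}
    flux_lines: list[str] = []
    contribs: dict[int, list[str]] = {}
    for r in network.reactions:
        j = r.step_index
        if r.law is RateLaw.MICHAELIS_MENTEN:
            Km = params[r.parameters["Km"]]
            if Km <= 0:
                raise ValueError(f"step {r.step_index}: Km <= 0")
            sub = idx[next(iter(r.reactants))]
            if "kcat" in r.parameters:
                V = f"{float(params[r.parameters['kcat']])!r}*x[{idx[r.modifier]}]"
            else:
                V = repr(float(params[r.parameters["V"]]))
            expr = f"{V}*x[{sub}]/({float(Km)!r}+x[{sub}])"
        else:
            fwd = [repr(float(params[r.parameters["kf"]]))]
            if r.modifier is not None:
                # forward-rate multiplier (the EGF ligand bath in step 1)
                fwd.append(f"x[{idx[r.modifier]}]")
            for sid, nu in r.reactants.items():
                fwd.extend([f"x[{idx[sid]}]"] * nu)
            expr = "*".join(fwd)
            if "kr" in r.parameters:
                rev = [repr(float(params[r.parameters["kr"]]))]
                for sid, nu in r.products.items():
                    rev.extend([f"x[{idx[sid]}]"] * nu)
                expr += " - " + "*".join(rev)
        flux_lines.append(f"    v{j} = {expr}")
        for sid, nu in r.reactants.items():
            if sid in dynamic:
                contribs.setdefault(idx[sid], []).append(
                    f"-{nu}*v{j}" if nu != 1 else f"-v{j}"
                )
        for sid, nu in r.products.items():
            if sid in dynamic:
                contribs.setdefault(idx[sid], []).append(
                    f"+{nu}*v{j}" if nu != 1 else f"+v{j}"
                )
    dy_lines = [
        f"    dy[{i}] = {' '.join(parts)}" for i, parts in sorted(contribs.items())
    ]
    src = "\n".join(
        [
            "def _rhs(t, y, _np=_np):",
            "    x = _np.maximum(y, 0.0)",
            f"    dy = _np.zeros({len(network.species)})",
            *flux_lines,
            *dy_lines,
            "    return dy",
        ]
    )
    namespace: dict = {"_np": np}
    exec(compile(src, "<egfr-erk-rhs>", "exec"), namespace)
    return namespace["_rhs"]


def rhs_reference(
    network: ReactionNetwork,
    params: ParameterSet,
    state: Mapping[str, float],
) -> dict[str, float]:
    """Straightforward per-reaction RHS used as an independent cross-check
    of the compiled closure."""
    dy = {sid: 0.0 for sid in network.species_ids}
    dynamic = {s.id for s in network.species if s.is_dynamic}
    for r in network.reactions:
        v = reaction_rate(r, state, params)
        for sid, nu in r.reactants.items():
            if sid in dynamic:
                dy[sid] -= nu * v
        for sid, nu in r.products.items():
            if sid in dynamic:
                dy[sid] += nu * v
    return dy


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(
    variant: ModelVariant,
    protocol: StimulusProtocol,
    solver: SolverConfig = SolverConfig(),
) -> Trajectory:
    """Integrate one variant under one protocol on the protocol's grid.

    EGF is set to the protocol dose at t = 0 and k3 is multiplied by the
    gefitinib factor for the whole run.
    """
    net = variant.network
    params = variant.effective_parameters()
    if protocol.gefitinib_alpha != 1.0:
        params = params.scaled({"k3": protocol.gefitinib_alpha})
    init = variant.effective_initials()
    init["EGF"] = 0.0
    y0 = np.array([init[sid] for sid in net.species_ids])
    rhs = build_rhs(net, params)
    if protocol.pre_equilibration > 0:
        settle = solve_ivp(
            rhs,
            (0.0, float(protocol.pre_equilibration)),
            y0,
            method=solver.method,
            rtol=solver.rtol,
            atol=solver.atol,
        )
        if not settle.success:
            raise SimulationError(
                f"pre-equilibration failed for variant {variant.name!r}: "
                f"{settle.message}"
            )
        y0 = settle.y[:, -1]
    y0[net.index_of("EGF")] = protocol.egf_dose
    t_out = np.asarray(protocol.t_outputs)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_out[-1])),
        y0,
        method=solver.method,
        t_eval=t_out,
        rtol=solver.rtol,
        atol=solver.atol,
        max_step=solver.max_step,
    )
    if not sol.success:
        raise SimulationError(
            f"solver failed for variant {variant.name!r} "
            f"(EGF={protocol.egf_dose} nM, alpha={protocol.gefitinib_alpha}): "
            f"{sol.message}"
        )
    if not np.all(np.isfinite(sol.y)):
        raise SimulationError(
            f"non-finite state for variant {variant.name!r}"
        )
    return Trajectory(
        times=sol.t,
        states=sol.y,
        species_ids=tuple(net.species_ids),
        variant=variant.name,
        protocol=protocol,
    )


# ---------------------------------------------------------------------------
# Observables and normalization
# ---------------------------------------------------------------------------

def observable_values(
    traj: Trajectory,
    name: str,
    definitions: Mapping[str, Mapping[str, float]] | None = None,
) -> np.ndarray:
    """Time series of one observable (antibody sum or raw species)."""
    defs = OBSERVABLE_DEFINITIONS if definitions is None else definitions
    if name in defs:
        out = np.zeros_like(traj.times, dtype=float)
        for sid, w in defs[name].items():
            out = out + w * traj[sid]
        return out
    if name in traj.species_ids:
        return np.array(traj[name], dtype=float)
    raise KeyError(f"unknown observable {name!r}")


def observables(
    traj: Trajectory,
    names: Sequence[str] = PHOSPHO_PROTEINS,
    definitions: Mapping[str, Mapping[str, float]] | None = None,
    label: str | None = None,
) -> list[ObservableSeries]:
    """Raw (un-normalized) observable series for one trajectory."""
    return [
        ObservableSeries(
            protein=name,
            times=traj.times,
            values=observable_values(traj, name, definitions),
            variant=traj.variant,
            normalized=False,
            label=label,
        )
        for name in names
    ]


def normalize_panel(series: Iterable[ObservableSeries]) -> list[ObservableSeries]:
    """Normalize a panel of series the way western-blot panels are scaled.

    Per protein: subtract each series' own t = 0 value, then divide all
    series of that protein jointly by the panel-wide maximum, so exactly the
    largest excursion reaches 1. An all-zero panel stays zero.
    """
    series = list(series)
    if not series:
        raise ValueError("empty panel")
    by_protein: dict[str, list[ObservableSeries]] = {}
    for s in series:
        by_protein.setdefault(s.protein, []).append(s)
    out: dict[int, ObservableSeries] = {}
    for protein, group in by_protein.items():
        shifted = []
        for s in group:
            if s.times[0] != 0.0:
                raise ValueError(
                    f"series for {protein!r} must include t = 0 for normalization"
                )
            shifted.append(s.values - s.values[0])
        panel_max = max(float(np.max(v)) for v in shifted)
        scale = panel_max if panel_max > 0 else 1.0
        for s, v in zip(group, shifted):
            out[id(s)] = s.replaced(values=v / scale, normalized=True)
    return [out[id(s)] for s in series]


def dose_response(
    variant: ModelVariant,
    doses: Sequence[float],
    t_read: float = 5.0,
    proteins: Sequence[str] = PHOSPHO_PROTEINS,
    gefitinib_alpha: float = 1.0,
    solver: SolverConfig = SolverConfig(),
) -> dict[str, np.ndarray]:
    """Raw observable values at ``t_read`` for each EGF dose.

    One simulation per dose; no monotonicity is assumed.
    """
    grid = (0.0, t_read) if t_read > 0 else (0.0,)
    results: dict[str, list[float]] = {p: [] for p in proteins}
    for dose in doses:
        if dose < 0:
            raise ValueError("EGF doses must be >= 0")
        proto = StimulusProtocol(
            egf_dose=dose, gefitinib_alpha=gefitinib_alpha, t_outputs=grid
        )
        traj = simulate(variant, proto, solver)
        for p in proteins:
            results[p].append(float(observable_values(traj, p)[-1]))
    return {p: np.array(v) for p, v in results.items()}
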