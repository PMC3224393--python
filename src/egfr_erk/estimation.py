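"""Parameter estimation against normalized phospho time-course data.

The objective is the summed squared error

    ERR = sum_{cell type} sum_{protein} sum_{time point} (data - simulated)^2

over normalized values at t in {1, 5, 10, 30} min, with the simulated values
passed through the same panel normalization as the data. The estimation
problem is decomposed into two subproblems solved in order: stage A frees
parameters of the receptor-proximal steps 1-17 against the upstream readouts
(pEGFR, pShc); stage B then freezes the stage-A winners and frees parameters
of the kinase-cascade steps 18-27 against pMEK and pERK. The decomposition
is valid because downstream reactions feed back on nothing upstream.

The minimizer is a real-coded genetic algorithm on log10 parameters with
tournament selection, blend crossover, per-gene Gaussian mutation, periodic
Nelder-Mead polish of the incumbent, and archive-based diversity rejection
(offspring landing within a fixed radius of an already-archived solution are
discarded, independent of the scale of individual coordinates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .network import (
    MIG6_PARAMETERS,
    DEFAULT_VARIANT_SETTINGS,
    ModelVariant,
    ReactionNetwork,
    build_reference_network,
    make_variant,
)
from .simulate import (
    ESTIMATION_TIME_POINTS,
    PHOSPHO_PROTEINS,
    SimulationError,
    SolverConfig,
    StimulusProtocol,
    normalize_panel,
    observables,
    simulate,
)

__all__ = [
    "ObjectiveSpec",
    "GAConfig",
    "FitResult",
    "VARIANT_FREE_PARAMETERS",
    "err_objective",
    "objective_residuals",
    "decompose",
    "ga_minimize",
    "fit",
    "simulate_panel",
]

#: Pseudo-parameters describing variant settings, fitted in stage A.
#: EGFR_init: shared initial EGFR concentration of the overexpressing lines;
#: Cbl_factor: L858R model B's Cbl fold-increase; mult_*: L858R model A's
#: Mig6 multipliers.
VARIANT_FREE_PARAMETERS = (
    "EGFR_init", "Cbl_factor", "mult_k3", "mult_k5", "mult_k7", "mult_k8",
)

#: Objective value substituted for failed integrations: large but finite so
#: GA ranking stays usable.
SOLVER_FAILURE_PENALTY = 1e6

STAGE_TARGETS = {"A": ("pEGFR", "pShc"), "B": ("pMEK", "pERK")}
STAGE_STEPS = {"A": range(1, 18), "B": range(18, 28)}


@dataclass(frozen=True)
class ObjectiveSpec:
    """What to fit: cells, proteins, time points, data, and free parameters.

    ``data`` is a tidy table with columns cell_line, protein, dose, time,
    value (normalized). ``free_parameters`` maps each free name (a kinetic
    constant or a variant pseudo-parameter) to its (low, high) search range.
    """

    data: pd.DataFrame
    free_parameters: Mapping[str, tuple[float, float]]
    cell_types: tuple[str, ...] = ("WT", "EGFR_WT", "L858R_A")
    proteins: tuple[str, ...] = PHOSPHO_PROTEINS
    time_points: tuple[float, ...] = ESTIMATION_TIME_POINTS
    doses: tuple[float, ...] = (10.0,)
    stage: str = "joint"
    solver: SolverConfig = SolverConfig(rtol=1e-6, atol=1e-9)

    def __post_init__(self) -> None:
        required = {"cell_line", "protein", "dose", "time", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"data table lacks columns {sorted(missing)}")
        for name, (lo, hi) in self.free_parameters.items():
            if not (0 < lo < hi):
                raise ValueError(f"bad bounds for {name!r}: ({lo}, {hi})")
        if self.stage not in ("A", "B", "joint"):
            raise ValueError(f"stage must be A, B or joint, got {self.stage!r}")


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 24
    generations: int = 20
    crossover_rate: float = 0.9
    mutation_rate: float = 0.25
    mutation_sigma: float = 0.3  # log10 units
    local_search_steps: int = 60  # Nelder-Mead evaluations per polish
    local_search_every: int = 5  # generations between polishes
    diversity_radius: float = 0.02  # log10-space L2 radius
    seed: int = 0
    n_workers: int = 1

    def __post_init__(self) -> None:
        for name in ("population_size", "generations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FitResult:
    parameters: dict[str, float]
    objective: float
    residuals: pd.DataFrame
    trace: pd.DataFrame  # columns: generation, best, median
    config: GAConfig
    stage: str = "joint"
    n_evaluations: int = 0


# ---------------------------------------------------------------------------
# candidate -> model
# ---------------------------------------------------------------------------

def _split_candidate(
    params: Mapping[str, float],
) -> tuple[dict[str, float], dict[str, float]]:
    kinetic = {k: v for k, v in params.items() if k not in VARIANT_FREE_PARAMETERS}
    variant = {k: v for k, v in params.items() if k in VARIANT_FREE_PARAMETERS}
    return kinetic, variant


def _variant_settings(variant_params: Mapping[str, float]) -> dict[str, dict]:
    settings = {k: dict(v) for k, v in DEFAULT_VARIANT_SETTINGS.items()}
    settings["L858R_A"]["multipliers"] = dict(
        DEFAULT_VARIANT_SETTINGS["L858R_A"]["multipliers"]
    )
    if "EGFR_init" in variant_params:
        egfr = float(variant_params["EGFR_init"])
        for name in ("EGFR_WT", "L858R_A", "L858R_B"):
            settings[name]["EGFR"] = egfr
    if "Cbl_factor" in variant_params:
        settings["L858R_B"]["Cbl_factor"] = float(variant_params["Cbl_factor"])
    for pname in MIG6_PARAMETERS:
        key = f"mult_{pname}"
        if key in variant_params:
            settings["L858R_A"]["multipliers"][pname] = float(variant_params[key])
    return settings


def simulate_panel(
    params: Mapping[str, float],
    spec: ObjectiveSpec,
    network: ReactionNetwork | None = None,
) -> pd.DataFrame:
    """Normalized simulated values for every (cell, protein, dose, time).

    Candidate values override the reference kinetic constants; variant
    pseudo-parameters override the reference variant settings. Normalization
    is per protein jointly across the spec's cell types at fixed dose,
    matching the measurement procedure.
    """
    kinetic, variant_params = _split_candidate(params)
    net = network if network is not None else build_reference_network()
    if kinetic:
        net = net.with_parameters(net.parameters.updated(kinetic))
    settings = _variant_settings(variant_params)
    t_grid = (0.0,) + tuple(sorted(set(spec.time_points)))
    rows = []
    for dose in spec.doses:
        panel = []
        for cell in spec.cell_types:
            v = make_variant(cell, net, settings[cell])
            proto = StimulusProtocol(egf_dose=dose, t_outputs=t_grid)
            traj = simulate(v, proto, spec.solver)
            panel.extend(observables(traj, spec.proteins, label=str(dose)))
        for s in normalize_panel(panel):
            for t, val in zip(s.times, s.values):
                if t == 0.0:
                    continue
                rows.append(
                    {
                        "cell_line": s.variant,
                        "protein": s.protein,
                        "dose": dose,
                        "time": float(t),
                        "simulated": float(val),
                    }
                )
    return pd.DataFrame(rows)


def objective_residuals(
    params: Mapping[str, float],
    spec: ObjectiveSpec,
    network: ReactionNetwork | None = None,
) -> pd.DataFrame:
    """Residual table data - simulated over the spec's scope."""
    sim = simulate_panel(params, spec, network)
    data = spec.data
    mask = (
        data["cell_line"].isin(spec.cell_types)
        & data["protein"].isin(spec.proteins)
        & data["time"].isin(spec.time_points)
        & data["dose"].isin(spec.doses)
    )
    merged = data.loc[mask].merge(
        sim, on=["cell_line", "protein", "dose", "time"], how="left",
        validate="one_to_one",
    )
    if merged["simulated"].isna().any():
        bad = merged.loc[merged["simulated"].isna()].iloc[0]
        raise ValueError(
            f"no simulable observable for ({bad['cell_line']}, "
            f"{bad['protein']}, {bad['dose']}, {bad['time']})"
        )
    merged["residual"] = merged["value"] - merged["simulated"]
    return merged


def err_objective(
    params: Mapping[str, float],
    spec: ObjectiveSpec,
    network: ReactionNetwork | None = None,
) -> float:
    """Summed squared error; solver failures return the penalty value."""
    try:
        res = objective_residuals(params, spec, network)
    except SimulationError:
        return SOLVER_FAILURE_PENALTY
    return float(np.sum(res["residual"].to_numpy() ** 2))


# ---------------------------------------------------------------------------
# problem decomposition
# ---------------------------------------------------------------------------

def _parameter_stage_map(network: ReactionNetwork) -> dict[str, int]:
    """Kinetic parameter name -> reaction step index."""
    out: dict[str, int] = {}
    for r in network.reactions:
        for pname in r.parameters.values():
            out[pname] = r.step_index
    return out


def decompose(
    spec: ObjectiveSpec,
    network: ReactionNetwork | None = None,
) -> tuple[ObjectiveSpec, ObjectiveSpec]:
    """Split a joint spec into the upstream (A) and downstream (B) stages.

    Stage A frees only parameters of steps 1-17 (plus variant
    pseudo-parameters) against pEGFR/pShc; stage B frees only parameters of
    steps 18-27 against pMEK/pERK. The stages partition the free set; a
    parameter mapping to both stages is a configuration error.
    """
    net = network if network is not None else build_reference_network()
    step_of = _parameter_stage_map(net)
    split: dict[str, dict[str, tuple[float, float]]] = {"A": {}, "B": {}}
    for name, bounds in spec.free_parameters.items():
        if name in VARIANT_FREE_PARAMETERS:
            split["A"][name] = bounds
            continue
        if name not in step_of:
            raise ValueError(f"free parameter {name!r} not used by any reaction")
        stage = "A" if step_of[name] <= 17 else "B"
        split[stage][name] = bounds
    overlap = set(split["A"]) & set(split["B"])
    if overlap:
        raise ValueError(f"parameters in both stages: {sorted(overlap)}")
    spec_a = replace(
        spec, free_parameters=split["A"], proteins=STAGE_TARGETS["A"], stage="A"
    )
    spec_b = replace(
        spec, free_parameters=split["B"], proteins=STAGE_TARGETS["B"], stage="B"
    )
    return spec_a, spec_b


# ---------------------------------------------------------------------------
# GA minimizer
# ---------------------------------------------------------------------------

def ga_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: GAConfig = GAConfig(),
) -> tuple[np.ndarray, float, pd.DataFrame, int]:
    """Minimize a black-box objective over a positive box by a real-coded GA.

    The search runs in log10 space. Returns (best point in original scale,
    best value, per-generation trace, evaluation count). Deterministic for
    a fixed config (including seed).
    """
    if not bounds:
        raise ValueError("empty bounds")
    lo = np.log10([b[0] for b in bounds])
    hi = np.log10([b[1] for b in bounds])
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("bounds must be finite and positive")
    span = hi - lo
    rng = np.random.default_rng(config.seed)
    n_dim = len(bounds)
    n_eval = 0

    def evaluate(z: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return float(objective(10.0 ** z))

    def evaluate_batch(points: list[np.ndarray]) -> list[float]:
        nonlocal n_eval
        n_eval += len(points)
        if config.n_workers > 1 and len(points) > 1:
            from joblib import Parallel, delayed

            return Parallel(n_jobs=config.n_workers)(
                delayed(objective)(10.0 ** z) for z in points
            )
        return [float(objective(10.0 ** z)) for z in points]

    pop = lo + rng.uniform(size=(config.population_size, n_dim)) * span
    fitness = np.array(evaluate_batch(list(pop)))
    archive: list[np.ndarray] = []
    trace_rows = []

    def diverse(z: np.ndarray) -> bool:
        zn = (z - lo) / np.where(span > 0, span, 1.0)
        for a in archive:
            if np.linalg.norm(zn - a) < config.diversity_radius:
                return False
        return True

    def archive_add(z: np.ndarray) -> None:
        zn = (z - lo) / np.where(span > 0, span, 1.0)
        archive.append(zn)

    for gen in range(config.generations):
        order = np.argsort(fitness, kind="stable")
        best_i = order[0]
        archive_add(pop[best_i])
        children = [pop[best_i].copy()]  # elitism
        attempts = 0
        # children depend only on the previous generation's fitness, so the
        # whole brood can be evaluated as one (optionally parallel) batch
        while (
            len(children) < config.population_size
            and attempts < 20 * config.population_size
        ):
            attempts += 1
            i, j = rng.integers(config.population_size, size=2)
            p1 = pop[i] if fitness[i] <= fitness[j] else pop[j]
            i, j = rng.integers(config.population_size, size=2)
            p2 = pop[i] if fitness[i] <= fitness[j] else pop[j]
            if rng.uniform() < config.crossover_rate:
                # BLX-0.5 blend crossover
                low = np.minimum(p1, p2)
                high = np.maximum(p1, p2)
                d = high - low
                child = rng.uniform(low - 0.5 * d, high + 0.5 * d)
            else:
                child = p1.copy()
            mask = rng.uniform(size=n_dim) < config.mutation_rate
            child = child + mask * rng.normal(0.0, config.mutation_sigma, n_dim)
            child = np.clip(child, lo, hi)
            if not diverse(child):
                continue
            children.append(child)
        while len(children) < config.population_size:
            # diversity rejection exhausted the attempt budget: refill randomly
            children.append(lo + rng.uniform(size=n_dim) * span)
        child_fit = [fitness[best_i]] + evaluate_batch(children[1:])
        pop = np.array(children)
        fitness = np.array(child_fit)
        if (
            config.local_search_steps > 0
            and (gen + 1) % config.local_search_every == 0
        ):
            b = int(np.argmin(fitness))
            res = minimize(
                lambda z: evaluate(np.clip(z, lo, hi)),
                pop[b],
                method="Nelder-Mead",
                options={
                    "maxfev": config.local_search_steps,
                    "xatol": 1e-4,
                    "fatol": 1e-12,
                },
            )
            z_pol = np.clip(res.x, lo, hi)
            f_pol = evaluate(z_pol)
            if f_pol < fitness[b]:
                pop[b], fitness[b] = z_pol, f_pol
        trace_rows.append(
            {
                "generation": gen,
                "best": float(np.min(fitness)),
                "median": float(np.median(fitness)),
            }
        )
    best = int(np.argmin(fitness))
    trace = pd.DataFrame(trace_rows)
    # enforce a non-increasing best-so-far trace
    trace["best"] = trace["best"].cummin()
    return 10.0 ** pop[best], float(fitness[best]), trace, n_eval


# ---------------------------------------------------------------------------
# staged fitting pipeline
# ---------------------------------------------------------------------------

def _fit_single(
    spec: ObjectiveSpec,
    config: GAConfig,
    frozen: Mapping[str, float],
    network: ReactionNetwork | None,
) -> FitResult:
    names = list(spec.free_parameters)
    bounds = [spec.free_parameters[n] for n in names]

    def objective(x: np.ndarray) -> float:
        cand = dict(frozen)
        cand.update(zip(names, x))
        return err_objective(cand, spec, network)

    best_x, best_f, trace, n_eval = ga_minimize(objective, bounds, config)
    params = dict(frozen)
    params.update(zip(names, best_x))
    residuals = objective_residuals(params, spec, network)
    return FitResult(
        parameters=params,
        objective=best_f,
        residuals=residuals,
        trace=trace,
        config=config,
        stage=spec.stage,
        n_evaluations=n_eval,
    )


def fit(
    spec: ObjectiveSpec,
    config: GAConfig = GAConfig(),
    network: ReactionNetwork | None = None,
    stages: str = "both",
) -> FitResult:
    """Fit free parameters to the spec's data.

    ``stages='both'`` runs the upstream/downstream decomposition in order
    (A, then B with A frozen); ``'A'``/``'B'`` run a single stage;
    ``'joint'`` fits everything at once. The returned objective is the ERR
    over the full protein set with the final parameters.
    """
    net = network if network is not None else build_reference_network()
    if stages == "joint":
        return _fit_single(replace(spec, stage="joint"), config, {}, net)
    spec_a, spec_b = decompose(spec, net)
    if stages == "A":
        return _fit_single(spec_a, config, {}, net)
    if stages == "B":
        return _fit_single(spec_b, config, {}, net)
    if stages != "both":
        raise ValueError(f"stages must be A, B, both or joint, got {stages!r}")
    result_a = _fit_single(spec_a, config, {}, net)
    config_b = replace(config, seed=config.seed + 1)
    result_b = _fit_single(spec_b, config_b, result_a.parameters, net)
    final = dict(result_b.parameters)
    full_spec = replace(spec, stage="joint")
    residuals = objective_residuals(final, full_spec, net)
    objective = float(np.sum(residuals["residual"].to_numpy() ** 2))
    trace = pd.concat(
        [result_a.trace.assign(stage="A"), result_b.trace.assign(stage="B")],
        ignore_index=True,
    )
    return FitResult(
        parameters=final,
        objective=objective,
        residuals=residuals,
        trace=trace,
        config=config,
        stage="both",
        n_evaluations=result_a.n_evaluations + result_b.n_evaluations,
    )
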