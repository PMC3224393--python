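"""Gefitinib dose scans, Mig6 sensitivity-ratio indices, and synergy analysis.

Gefitinib is modeled as a multiplicative factor alpha on the receptor
autophosphorylation rate constant k3; the Mig6 effect as multiplicative
reductions of k3, k5, k7, k8. The R-ratio index of a readout X is

    R_X = X(alpha = alpha_on) / X(alpha = alpha_off)

at t = 5 min under 10 nM EGF (alpha_on = 0.0005 is the strong-inhibition
surrogate, alpha_off = 1 no drug). Ratios of such ratios, e.g.
R_Shc / R_ERK, quantify how much more strongly inhibition registers
downstream than upstream. Combined Mig6+gefitinib perturbations are
classified as additive, antagonistic, or synergistic by whether two solo
perturbations that each achieve X/2 % ERKPP inhibition jointly achieve
exactly, less than, or more than X %.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import (
    MIG6_PARAMETERS,
    DEFAULT_VARIANT_SETTINGS,
    ModelVariant,
    ReactionNetwork,
    build_reference_network,
    make_variant,
)
from .simulate import (
    PHOSPHO_PROTEINS,
    RAW_READOUTS,
    SolverConfig,
    StimulusProtocol,
    observable_values,
    simulate,
)

__all__ = [
    "PerturbationSpec",
    "RIndexResult",
    "SynergyResult",
    "UndefinedIndexError",
    "InversionError",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_X_GRID",
    "ALPHA_ON",
    "alpha_scan",
    "r_index",
    "pairwise_index_grid",
    "downstream_amplification",
    "inhibition_percent",
    "invert_inhibition",
    "classify_combination",
]

#: Gefitinib surrogate grid of the dose-scan simulations.
DEFAULT_ALPHA_GRID = (1.0, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001, 0.0005)
#: Inhibition intensities (percent) of the synergy classification.
DEFAULT_X_GRID = (0, 10, 20, 30, 40, 50, 60, 70, 80, 90)
#: Strong-inhibition surrogate used by the R indices.
ALPHA_ON = 0.0005

#: Upstream readout of the downstream-amplification analysis.
UPSTREAM_COMPLEX = "E11P_ShcP_GS"
DOWNSTREAM_READOUTS = ("RasGTP", "Raf1A", "MEKP", "MEKPP", "ERKP", "ERKPP")


class UndefinedIndexError(ZeroDivisionError):
    """R index denominator vanished (readout zero without inhibition)."""


class InversionError(RuntimeError):
    """Target inhibition unreachable or bracket not monotone."""


@dataclass(frozen=True)
class PerturbationSpec:
    """Parameter-multiplier perturbation applied on top of a base variant."""

    multipliers: Mapping[str, float] = field(default_factory=dict)
    readout: str = "ERKPP"
    read_time: float = 5.0
    egf_dose: float = 10.0
    base_variant: str = "EGFR_WT"

    def __post_init__(self) -> None:
        for name, f in self.multipliers.items():
            if not f > 0:
                raise ValueError(f"multiplier for {name!r} must be positive")


@dataclass(frozen=True)
class RIndexResult:
    """Grid of ratio-of-ratio index values over two parameter factor axes."""

    pair: tuple[str, str]
    grids: tuple[tuple[float, ...], tuple[float, ...]]
    matrix: np.ndarray  # shape (len(grid0), len(grid1))
    definition: str  # e.g. "R_Shc/R_ERK" or "R_E11P/ShcP/Grb2/SOS/R_ERKPP"
    alpha_on: float = ALPHA_ON


@dataclass(frozen=True)
class SynergyRow:
    X: float
    k3_factor: float
    k8_factor: float
    combined_readout: float
    combined_inhibition: float
    classification: str


@dataclass(frozen=True)
class SynergyResult:
    rows: tuple[SynergyRow, ...]
    epsilon: float
    baseline_readout: float

    def classes(self) -> dict[float, str]:
        return {r.X: r.classification for r in self.rows}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _reference_base(
    base_variant: str, network: ReactionNetwork | None
) -> ModelVariant:
    net = network if network is not None else build_reference_network()
    return make_variant(base_variant, net)


def _perturbed(base: ModelVariant, multipliers: Mapping[str, float]) -> ModelVariant:
    merged = dict(base.parameter_multipliers)
    for k, f in multipliers.items():
        merged[k] = merged.get(k, 1.0) * f
    return ModelVariant(
        base.name, base.network, base.initial_overrides, merged
    )


def _readout_at(
    variant: ModelVariant,
    readout: str,
    alpha: float,
    egf_dose: float,
    t_read: float,
    solver: SolverConfig,
) -> float:
    proto = StimulusProtocol(
        egf_dose=egf_dose, gefitinib_alpha=alpha, t_outputs=(0.0, t_read)
    )
    traj = simulate(variant, proto, solver)
    return float(observable_values(traj, readout)[-1])


# ---------------------------------------------------------------------------
# alpha scan
# ---------------------------------------------------------------------------

def alpha_scan(
    variant: ModelVariant,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    t_read: float = 5.0,
    egf_dose: float = 10.0,
    proteins: Sequence[str] = PHOSPHO_PROTEINS,
    solver: SolverConfig = SolverConfig(),
) -> dict[str, np.ndarray]:
    """Per-protein response at ``t_read`` versus the gefitinib factor alpha.

    Responses are normalized to the no-drug (alpha = 1) value per protein,
    which is always simulated even if absent from ``alphas``.
    """
    if any(not 0 < a <= 1 for a in alphas):
        raise ValueError("alpha values must lie in (0, 1]")
    proto0 = StimulusProtocol(
        egf_dose=egf_dose, gefitinib_alpha=1.0, t_outputs=(0.0, t_read)
    )
    base_traj = simulate(variant, proto0, solver)
    base = {p: float(observable_values(base_traj, p)[-1]) for p in proteins}
    rows: dict[str, list[float]] = {p: [] for p in proteins}
    for a in alphas:
        if a == 1.0:
            traj = base_traj
        else:
            traj = simulate(
                variant,
                StimulusProtocol(
                    egf_dose=egf_dose, gefitinib_alpha=a, t_outputs=(0.0, t_read)
                ),
                solver,
            )
        for p in proteins:
            denom = base[p]
            if denom <= 0:
                raise UndefinedIndexError(
                    f"no-drug response of {p!r} is zero; cannot normalize"
                )
            rows[p].append(float(observable_values(traj, p)[-1]) / denom)
    return {p: np.array(v) for p, v in rows.items()}


# ---------------------------------------------------------------------------
# R indices
# ---------------------------------------------------------------------------

def r_index(
    readout: str,
    alpha_on: float = ALPHA_ON,
    alpha_off: float = 1.0,
    context: PerturbationSpec = PerturbationSpec(),
    network: ReactionNetwork | None = None,
    solver: SolverConfig = SolverConfig(),
) -> float:
    """R_X = [readout at alpha_on] / [readout at alpha_off].

    The context multipliers (e.g. Mig6 factors) are applied in both the
    numerator and denominator simulations.
    """
    base = _reference_base(context.base_variant, network)
    v = _perturbed(base, context.multipliers)
    num = _readout_at(
        v, readout, alpha_on, context.egf_dose, context.read_time, solver
    )
    den = _readout_at(
        v, readout, alpha_off, context.egf_dose, context.read_time, solver
    )
    if den <= 0:
        raise UndefinedIndexError(
            f"denominator readout {readout!r} at alpha={alpha_off} is zero"
        )
    return num / den


def _ratio_of_ratios(
    upstream: str,
    downstream: str,
    multipliers: Mapping[str, float],
    alpha_on: float,
    network: ReactionNetwork | None,
    solver: SolverConfig,
    base_variant: str = "EGFR_WT",
    egf_dose: float = 10.0,
    t_read: float = 5.0,
) -> float:
    """R_upstream / R_downstream from one cached trajectory pair."""
    base = _reference_base(base_variant, network)
    v = _perturbed(base, multipliers)
    vals: dict[float, dict[str, float]] = {}
    for a in (alpha_on, 1.0):
        proto = StimulusProtocol(
            egf_dose=egf_dose, gefitinib_alpha=a, t_outputs=(0.0, t_read)
        )
        traj = simulate(v, proto, solver)
        vals[a] = {
            name: float(observable_values(traj, name)[-1])
            for name in (upstream, downstream)
        }
    for name in (upstream, downstream):
        if vals[1.0][name] <= 0:
            raise UndefinedIndexError(
                f"no-drug readout {name!r} is zero; index undefined"
            )
    R_up = vals[alpha_on][upstream] / vals[1.0][upstream]
    R_dn = vals[alpha_on][downstream] / vals[1.0][downstream]
    if R_dn <= 0:
        raise UndefinedIndexError(f"R_{downstream} is zero; ratio undefined")
    return R_up / R_dn


MIG6_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(MIG6_PARAMETERS, 2)
)


def default_factor_grid(parameter: str, n_intermediate: int = 3) -> tuple[float, ...]:
    """Grid {L858R_A fitted factor, log-spaced intermediates, 1}."""
    fitted = DEFAULT_VARIANT_SETTINGS["L858R_A"]["multipliers"][parameter]
    pts = np.logspace(np.log10(fitted), 0.0, n_intermediate + 2)
    pts[0], pts[-1] = fitted, 1.0
    return tuple(float(x) for x in pts)


def pairwise_index_grid(
    pair: tuple[str, str],
    grids: tuple[Sequence[float], Sequence[float]] | None = None,
    fixed: Mapping[str, float] | None = None,
    upstream: str = "pShc",
    downstream: str = "pERK",
    alpha_on: float = ALPHA_ON,
    network: ReactionNetwork | None = None,
    solver: SolverConfig = SolverConfig(),
) -> RIndexResult:
    """Matrix of R_Shc/R_ERK over factor grids for two Mig6 parameters.

    The remaining two Mig6 parameters are held at the values in ``fixed``
    (default: EGFR-WT values, factor 1). The (1, 1) corner therefore equals
    the EGFR-WT model's index; with ``fixed`` at the L858R_A factors and the
    fitted corner of the grid, the full L858R model A index is recovered.
    """
    p0, p1 = pair
    if p0 == p1 or p0 not in MIG6_PARAMETERS or p1 not in MIG6_PARAMETERS:
        raise ValueError(f"pair must be two distinct Mig6 parameters, got {pair}")
    if grids is None:
        grids = (default_factor_grid(p0), default_factor_grid(p1))
    g0 = tuple(float(x) for x in grids[0])
    g1 = tuple(float(x) for x in grids[1])
    fixed = dict(fixed or {})
    for name in MIG6_PARAMETERS:
        if name not in pair:
            fixed.setdefault(name, 1.0)
    M = np.empty((len(g0), len(g1)))
    for i, f0 in enumerate(g0):
        for j, f1 in enumerate(g1):
            mult = dict(fixed)
            mult[p0], mult[p1] = f0, f1
            M[i, j] = _ratio_of_ratios(
                upstream, downstream, mult, alpha_on, network, solver
            )
    return RIndexResult(
        pair=(p0, p1),
        grids=(g0, g1),
        matrix=M,
        definition=f"R_{upstream[1:] if upstream.startswith('p') else upstream}"
        f"/R_{downstream[1:] if downstream.startswith('p') else downstream}",
        alpha_on=alpha_on,
    )


def downstream_amplification(
    k3_grid: Sequence[float] | None = None,
    k8_grid: Sequence[float] | None = None,
    alpha_on: float = ALPHA_ON,
    network: ReactionNetwork | None = None,
    solver: SolverConfig = SolverConfig(),
) -> dict[str, RIndexResult]:
    """R_E11P/ShcP/Grb2/SOS / R_Y over k3 x k8 factor grids.

    Y runs over RasGTP, Raf1A, MEKP, MEKPP, ERKP and ERKPP; k5 and k7 stay
    at their EGFR-WT values. Index values far above 1 at the fitted L858R_A
    corner mark the steps where gefitinib sensitivity is amplified.
    """
    g3 = tuple(k3_grid or default_factor_grid("k3"))
    g8 = tuple(k8_grid or default_factor_grid("k8"))
    out: dict[str, RIndexResult] = {}
    for y in DOWNSTREAM_READOUTS:
        M = np.empty((len(g3), len(g8)))
        for i, f3 in enumerate(g3):
            for j, f8 in enumerate(g8):
                M[i, j] = _ratio_of_ratios(
                    UPSTREAM_COMPLEX, y, {"k3": f3, "k8": f8},
                    alpha_on, network, solver,
                )
        out[y] = RIndexResult(
            pair=("k3", "k8"),
            grids=(g3, g8),
            matrix=M,
            definition=f"R_{UPSTREAM_COMPLEX}/R_{y}",
            alpha_on=alpha_on,
        )
    return out


# ---------------------------------------------------------------------------
# Inhibition inversion and synergy classification
# ---------------------------------------------------------------------------

def inhibition_percent(
    multipliers: Mapping[str, float],
    readout: str = "ERKPP",
    base_variant: str = "EGFR_WT",
    egf_dose: float = 10.0,
    t_read: float = 5.0,
    network: ReactionNetwork | None = None,
    solver: SolverConfig = SolverConfig(),
    _baseline: float | None = None,
) -> float:
    """100 * (1 - readout_perturbed / readout_baseline) at ``t_read``."""
    base = _reference_base(base_variant, network)
    if _baseline is None:
        _baseline = _readout_at(base, readout, 1.0, egf_dose, t_read, solver)
    if _baseline <= 0:
        raise UndefinedIndexError("baseline readout is zero")
    v = _perturbed(base, multipliers)
    val = _readout_at(v, readout, 1.0, egf_dose, t_read, solver)
    return 100.0 * (1.0 - val / _baseline)


def invert_inhibition(
    parameter: str,
    target_inhibition: float,
    readout: str = "ERKPP",
    base_variant: str = "EGFR_WT",
    egf_dose: float = 10.0,
    t_read: float = 5.0,
    tol_points: float = 0.05,
    log10_range: tuple[float, float] = (-6.0, 0.0),
    network: ReactionNetwork | None = None,
    solver: SolverConfig = SolverConfig(),
) -> tuple[float, float]:
    """Factor on one parameter achieving a target % readout inhibition.

    Bisection on log10(factor) in ``log10_range`` until the achieved
    inhibition is within ``tol_points`` percentage points of the target.
    Returns (factor, achieved inhibition). Raises :class:`InversionError`
    when the target is unreachable in range or the bracket is not monotone.
    """
    if parameter not in ("k3", "k8"):
        raise ValueError("inversion supports the k3 and k8 perturbations")
    if not 0 <= target_inhibition < 100:
        raise ValueError("target inhibition must lie in [0, 100)")
    if target_inhibition == 0:
        return 1.0, 0.0
    base = _reference_base(base_variant, network)
    baseline = _readout_at(base, readout, 1.0, egf_dose, t_read, solver)

    def inhib(log_f: float) -> float:
        return inhibition_percent(
            {parameter: 10.0 ** log_f}, readout, base_variant,
            egf_dose, t_read, network, solver, _baseline=baseline,
        )

    lo, hi = log10_range
    inh_lo, inh_hi = inhib(lo), inhib(hi)
    if inh_hi > inh_lo:
        scan = {f: inhib(f) for f in np.linspace(lo, hi, 13)}
        raise InversionError(
            f"inhibition not monotone decreasing in {parameter} factor; "
            f"diagnostic scan: {scan}"
        )
    if not (inh_hi <= target_inhibition <= inh_lo):
        raise InversionError(
            f"target {target_inhibition}% outside achievable range "
            f"[{inh_hi:.3f}, {inh_lo:.3f}]% for {parameter} factor in "
            f"10^[{lo}, {hi}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        inh_mid = inhib(mid)
        if abs(inh_mid - target_inhibition) < tol_points:
            return 10.0 ** mid, inh_mid
        if inh_mid > target_inhibition:
            lo = mid  # too much inhibition -> raise the factor
        else:
            hi = mid
    raise InversionError(
        f"bisection failed to reach {target_inhibition}% within tolerance"
    )


def classify_combination(
    X_grid: Sequence[float] = DEFAULT_X_GRID,
    epsilon: float = 0.5,
    readout: str = "ERKPP",
    base_variant: str = "EGFR_WT",
    egf_dose: float = 10.0,
    t_read: float = 5.0,
    network: ReactionNetwork | None = None,
    solver: SolverConfig = SolverConfig(),
) -> SynergyResult:
    """Classify the combined k3 & k8 perturbation at each inhibition level X.

    For each X: find the k3 factor and the k8 factor that individually give
    X/2 % ERKPP inhibition, apply both together, and compare the combined
    inhibition to X. Equal within ``epsilon`` percentage points -> additive;
    below -> antagonistic; above -> synergistic.
    """
    net = network if network is not None else build_reference_network()
    base = _reference_base(base_variant, net)
    baseline = _readout_at(base, readout, 1.0, egf_dose, t_read, solver)
    rows: list[SynergyRow] = []
    for X in X_grid:
        f3, _ = invert_inhibition(
            "k3", X / 2.0, readout, base_variant, egf_dose, t_read,
            network=net, solver=solver,
        )
        f8, _ = invert_inhibition(
            "k8", X / 2.0, readout, base_variant, egf_dose, t_read,
            network=net, solver=solver,
        )
        v = _perturbed(base, {"k3": f3, "k8": f8})
        combined = _readout_at(v, readout, 1.0, egf_dose, t_read, solver)
        inhib = 100.0 * (1.0 - combined / baseline)
        if abs(inhib - X) <= epsilon:
            cls = "additive"
        elif inhib < X:
            cls = "antagonistic"
        else:
            cls = "synergistic"
        rows.append(SynergyRow(float(X), f3, f8, combined, inhib, cls))
    return SynergyResult(tuple(rows), epsilon, baseline)
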