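"""Random sequential networks and worst-case curvature maximization.

Two numerical experiments probe how non-linear a chain of Arrhenius
reactions can look in the Arrhenius plot:

* :func:`random_network` draws per-reaction activation energies uniformly
  from a literature-plausible range (20-100 kJ/mol) and per-reaction times
  1/k at a reference temperature log-uniformly between 1 second and 3 days,
  back-solving each prefactor.  Large random chains are nearly perfectly
  linear in the Arrhenius plot.
* :func:`optimize_worst_case` maximizes the curvature of the composite
  ln k vs 1/T curve at a target temperature over a 2-reaction chain subject
  to the same bounds (multi-start bounded local optimization), then expands
  the lower-Ea reaction into 999 identical steps so the worst case is
  realized by a 1,000-reaction network with identical composite behavior
  at the target temperature.

Curvature is evaluated in the normative Arrhenius axes (x = 1/T in K^-1,
y = natural-log rate); it is not invariant to axis rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .constants import (
    MINUTES_PER_DAY,
    MINUTES_PER_SECOND,
    R_J_PER_MOL_K,
    kelvin_to_celsius,
)
from .network import CompositePrediction, Reaction, SequentialNetwork, expand_reaction

#: Literature range of enzyme activation energies, kJ/mol.
DEFAULT_EA_BOUNDS = (20.0, 100.0)

#: Plausible per-state times 1/k, minutes (1 second to 3 days).
DEFAULT_TIME_BOUNDS_MIN = (MINUTES_PER_SECOND, 3.0 * MINUTES_PER_DAY)

#: Reference/target temperature for sampling and curvature, Kelvin.
DEFAULT_T_TARGET_K = 295.15


@dataclass
class OptimizationSpec:
    """Configuration of the worst-case curvature search.

    ``time_bounds_min`` bounds each reaction's time 1/k_i evaluated at
    ``T_target_K`` (normative interpretation).  ``expand_to`` is the final
    network size after expanding the lower-Ea reaction.
    """

    n_reactions: int = 2
    Ea_bounds: tuple[float, float] = DEFAULT_EA_BOUNDS
    time_bounds_min: tuple[float, float] = DEFAULT_TIME_BOUNDS_MIN
    T_target_K: float = DEFAULT_T_TARGET_K
    n_starts: int = 64
    seed: int | None = None
    expand_to: int = 1000

    def __post_init__(self):
        if self.Ea_bounds[0] > self.Ea_bounds[1]:
            raise ValueError("Ea bounds out of order")
        if self.time_bounds_min[0] > self.time_bounds_min[1]:
            raise ValueError("time bounds out of order")
        if self.n_starts < 1:
            raise ValueError("need at least one start")
        if self.n_reactions != 2:
            raise ValueError("only 2-parameter-reaction optimization is supported")


@dataclass
class OptimizationResult:
    """Best feasible worst-case network found by the multi-start search."""

    network: SequentialNetwork
    expanded_network: SequentialNetwork
    curvature_at_target: float
    converged: bool
    starts_tried: int
    Ea_low_kJ_per_mol: float = field(init=False)
    Ea_high_kJ_per_mol: float = field(init=False)

    def __post_init__(self):
        Ea = np.sort(self.network.Ea_kJ_per_mol)
        self.Ea_low_kJ_per_mol = float(Ea[0])
        self.Ea_high_kJ_per_mol = float(Ea[-1])


def _lnA_from_time(Ea_kJ_per_mol, time_min, T_ref_K):
    """Prefactor of a reaction with given Ea and time 1/k at T_ref."""
    b = np.asarray(Ea_kJ_per_mol, dtype=float) * 1000.0 / R_J_PER_MOL_K
    return b / T_ref_K - np.log(time_min)


def random_network(
    n: int,
    Ea_bounds=DEFAULT_EA_BOUNDS,
    time_bounds_min=DEFAULT_TIME_BOUNDS_MIN,
    T_ref_K: float = DEFAULT_T_TARGET_K,
    rng=None,
) -> SequentialNetwork:
    """Draw a random feasible sequential network.

    Ea_i uniform on ``Ea_bounds``; per-reaction time 1/k_i(T_ref)
    log-uniform on ``time_bounds_min``; A_i back-solved.  Reproducible
    given a seeded ``rng`` (int seeds accepted).
    """
    if n < 1:
        raise ValueError("need at least one reaction")
    rng = np.random.default_rng(rng)
    Ea = rng.uniform(*Ea_bounds, size=n)
    log_t = rng.uniform(np.log(time_bounds_min[0]), np.log(time_bounds_min[1]), size=n)
    return SequentialNetwork(Ea, _lnA_from_time(Ea, np.exp(log_t), T_ref_K))


def _curvature_of_theta(theta, T_target_K):
    """Curvature at target of the 2-reaction chain (Ea1, Ea2, ln t1, ln t2)."""
    Ea = np.asarray(theta[:2], dtype=float)
    lnt = np.asarray(theta[2:], dtype=float)
    net = SequentialNetwork(Ea, _lnA_from_time(Ea, np.exp(lnt), T_target_K))
    return float(net.curvature(kelvin_to_celsius(T_target_K)))


def optimize_worst_case(spec: OptimizationSpec) -> OptimizationResult:
    """Maximize composite-curve curvature at the target temperature.

    Parameters are (Ea_1, Ea_2, ln t_1, ln t_2) with t_i the per-reaction
    time at T_target; bounds per ``spec``.  Multi-start L-BFGS-B from
    seeded uniform starts; the best feasible solution is returned and its
    lower-Ea reaction expanded to ``expand_to - 1`` identical steps.
    """
    rng = np.random.default_rng(spec.seed)
    log_t_bounds = (np.log(spec.time_bounds_min[0]), np.log(spec.time_bounds_min[1]))
    bounds = [spec.Ea_bounds, spec.Ea_bounds, log_t_bounds, log_t_bounds]

    def objective(theta):
        # log-curvature: spans orders of magnitude, so the log keeps the
        # gradient well scaled for the bounded quasi-Newton steps
        kappa = _curvature_of_theta(theta, spec.T_target_K)
        return -np.log(kappa + 1e-300)

    best_theta, best_val, converged = None, np.inf, False
    for _ in range(spec.n_starts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_val:
            best_theta, best_val, converged = res.x, res.fun, bool(res.success)
    if best_theta is None or not np.isfinite(best_val):
        raise RuntimeError("no feasible optimization start succeeded")

    # independent constraint check at the returned optimum
    tol = 1e-8
    Ea = best_theta[:2]
    t = np.exp(best_theta[2:])
    if np.any(Ea < spec.Ea_bounds[0] - tol) or np.any(Ea > spec.Ea_bounds[1] + tol):
        raise RuntimeError("optimum violates Ea bounds")
    if (np.any(t < spec.time_bounds_min[0] * (1 - 1e-8))
            or np.any(t > spec.time_bounds_min[1] * (1 + 1e-8))):
        raise RuntimeError("optimum violates time bounds")

    network = SequentialNetwork(Ea, _lnA_from_time(Ea, t, spec.T_target_K))
    low, high = (0, 1) if Ea[0] <= Ea[1] else (1, 0)
    reactions = network.reactions
    expanded = SequentialNetwork.from_reactions(
        expand_reaction(reactions[low], spec.expand_to - 1, spec.T_target_K)
        + [reactions[high]]
    )
    return OptimizationResult(
        network=network,
        expanded_network=expanded,
        curvature_at_target=_curvature_of_theta(best_theta, spec.T_target_K),
        converged=converged,
        starts_tried=spec.n_starts,
    )


def tangent_align(
    prediction_a: CompositePrediction,
    prediction_b: CompositePrediction,
    T_ref_K: float | None = None,
) -> tuple[float, float]:
    """Vertical offset aligning two composite predictions' tangent lines.

    Returns ``(offset, slope_mismatch_K)``: adding ``offset`` to
    prediction_b's ln k makes the two curves' least-squares lines (over
    their shared core range) coincide at a reference abscissa -- 1/T_ref
    when ``T_ref_K`` is given, else the centre of the core range in 1/T.
    The difference in line slopes is reported, never altered.  Both
    predictions must share the temperature grid and core range.
    """
    if prediction_a.temperatures_C.shape != prediction_b.temperatures_C.shape or \
            not np.allclose(prediction_a.temperatures_C, prediction_b.temperatures_C):
        raise ValueError("predictions are on different temperature grids")
    if prediction_a.core_range_C != prediction_b.core_range_C:
        raise ValueError("predictions use different core ranges")
    sa = -prediction_a.tangent_Ea_kJ_per_mol * 1000.0 / R_J_PER_MOL_K
    sb = -prediction_b.tangent_Ea_kJ_per_mol * 1000.0 / R_J_PER_MOL_K
    if T_ref_K is not None:
        x_ref = 1.0 / T_ref_K
    else:
        lo, hi = prediction_a.core_range_C
        x_ref = 0.5 * (1.0 / (lo + 273.15) + 1.0 / (hi + 273.15))
    value_a = prediction_a.tangent_intercept + sa * x_ref
    value_b = prediction_b.tangent_intercept + sb * x_ref
    return float(value_a - value_b), float(sa - sb)
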