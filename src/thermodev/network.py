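"""Sequential multi-reaction relaxation model in Arrhenius coordinates.

A chain of n irreversible first-order transitions, each Arrhenius with
activation energy Ea_i and prefactor A_i, relaxes with total time

    tau(T) = sum_i exp(+Ea_i * 1000 / (R T)) / A_i        (sum of 1/k_i)

so the composite pseudo-rate in Arrhenius coordinates is

    ln k(T) = -ln sum_i exp(Ea_i * 1000 / (R T)) / A_i.

Writing b_i = Ea_i * 1000 / R (Kelvin) and x = 1/T, the composite curve
y(x) = -ln sum_i exp(b_i x - ln A_i) has analytic derivatives in terms of
the time-fraction weights w_i = tau_i / tau:

    y'(x)  = -<b>_w            (weighted mean of b_i)
    y''(x) = -Var_w(b)  <=  0  (weighted variance; always concave down)

A single reaction reduces exactly to the Arrhenius line; reactions sharing
one Ea collapse exactly into a single reaction with A_eff = (sum 1/A_i)^-1.
All sums are evaluated in log space (log-sum-exp) to avoid overflow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import R_J_PER_MOL_K, celsius_to_kelvin


@dataclass(frozen=True)
class Reaction:
    """One Arrhenius step: Ea in kJ/mol, prefactor A in min^-1."""

    Ea_kJ_per_mol: float
    A_per_min: float

    def __post_init__(self):
        if not self.A_per_min > 0:
            raise ValueError("prefactor A must be positive")
        if not np.isfinite(self.Ea_kJ_per_mol):
            raise ValueError("Ea must be finite")

    @property
    def b_K(self) -> float:
        """Arrhenius slope magnitude Ea*1000/R, in Kelvin."""
        return self.Ea_kJ_per_mol * 1000.0 / R_J_PER_MOL_K

    def tau_min(self, temperature_c):
        """Per-step time 1/k(T) in minutes."""
        x = 1.0 / celsius_to_kelvin(np.asarray(temperature_c, dtype=float))
        return np.exp(self.b_K * x - np.log(self.A_per_min))


class SequentialNetwork:
    """An ordered chain of Arrhenius reactions.

    Parameters are stored as arrays ``Ea_kJ_per_mol`` and ``lnA`` (A in
    min^-1); the order is preserved but does not affect tau.
    """

    def __init__(self, Ea_kJ_per_mol, lnA):
        Ea = np.atleast_1d(np.asarray(Ea_kJ_per_mol, dtype=float))
        lnA = np.atleast_1d(np.asarray(lnA, dtype=float))
        if Ea.size == 0:
            raise ValueError("a network needs at least one reaction")
        if Ea.shape != lnA.shape:
            raise ValueError("Ea and lnA arrays differ in shape")
        self.Ea_kJ_per_mol = Ea
        self.lnA = lnA

    # construction helpers ---------------------------------------------------
    @classmethod
    def from_reactions(cls, reactions: Iterable[Reaction]) -> "SequentialNetwork":
        rs = list(reactions)
        return cls([r.Ea_kJ_per_mol for r in rs], np.log([r.A_per_min for r in rs]))

    @property
    def reactions(self) -> list[Reaction]:
        return [Reaction(float(e), float(a))
                for e, a in zip(self.Ea_kJ_per_mol, np.exp(self.lnA))]

    def __len__(self) -> int:
        return self.Ea_kJ_per_mol.size

    def concat(self, other: "SequentialNetwork") -> "SequentialNetwork":
        return SequentialNetwork(
            np.concatenate([self.Ea_kJ_per_mol, other.Ea_kJ_per_mol]),
            np.concatenate([self.lnA, other.lnA]),
        )

    @property
    def b_K(self) -> np.ndarray:
        return self.Ea_kJ_per_mol * 1000.0 / R_J_PER_MOL_K

    # evaluation -------------------------------------------------------------
    def _ln_tau_terms(self, temperature_c):
        """ln tau_i for each reaction; shape (n_temps, n_reactions)."""
        x = 1.0 / celsius_to_kelvin(np.atleast_1d(
            np.asarray(temperature_c, dtype=float)))
        return np.outer(x, self.b_K) - self.lnA

    def ln_tau(self, temperature_c):
        out = logsumexp(self._ln_tau_terms(temperature_c), axis=1)
        return out if np.ndim(temperature_c) else float(out[0])

    def tau_min(self, temperature_c):
        """Total relaxation time in minutes (sum of per-step times)."""
        return np.exp(self.ln_tau(temperature_c))

    def composite_lnk(self, temperature_c):
        """ln of the composite pseudo-rate, -ln tau(T)."""
        out = -logsumexp(self._ln_tau_terms(temperature_c), axis=1)
        return out if np.ndim(temperature_c) else float(out[0])

    def lnk_derivatives(self, temperature_c):
        """(y, y', y'') of y = composite ln k as a function of x = 1/T.

        Uses the weighted-mean identities: y' = -<b>_w, y'' = -Var_w(b)
        with time-fraction weights w_i = tau_i / tau.
        """
        terms = self._ln_tau_terms(temperature_c)
        ln_tau = logsumexp(terms, axis=1, keepdims=True)
        w = np.exp(terms - ln_tau)
        mean_b = w @ self.b_K
        # two-pass weighted variance: immune to the cancellation that the
        # E[b^2] - E[b]^2 form suffers when one weight dominates
        dev = self.b_K[np.newaxis, :] - mean_b[:, np.newaxis]
        var_b = np.sum(w * dev**2, axis=1)
        y = -ln_tau[:, 0]
        if np.ndim(temperature_c):
            return y, -mean_b, -np.maximum(var_b, 0.0)
        return float(y[0]), float(-mean_b[0]), float(-max(var_b[0], 0.0))

    def curvature(self, temperature_c):
        """Standard curvature of y = ln k vs x = 1/T (K^-1).

        kappa = |y''| / (1 + y'^2)^(3/2); zero for a single reaction.
        Not scale-invariant: the (K^-1, natural-log) axes are normative.
        """
        _, yp, ypp = self.lnk_derivatives(temperature_c)
        return np.abs(ypp) / (1.0 + yp**2) ** 1.5

    # serialization ----------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps([
            {"Ea_kJ_per_mol": float(e), "A_per_min": float(a)}
            for e, a in zip(self.Ea_kJ_per_mol, np.exp(self.lnA))
        ])

    @classmethod
    def from_json(cls, text: str) -> "SequentialNetwork":
        data = json.loads(text)
        return cls([d["Ea_kJ_per_mol"] for d in data],
                   np.log([d["A_per_min"] for d in data]))


# ---------------------------------------------------------------------------
# functional wrappers

def tau(network: SequentialNetwork, temperature_c):
    """Relaxation time (minutes) of a sequential network at T (degC)."""
    return network.tau_min(temperature_c)


def composite_lnk(network: SequentialNetwork, temperature_c):
    """Composite ln rate, -ln tau; equals the Arrhenius line for one reaction."""
    return network.composite_lnk(temperature_c)


def curvature_at(network: SequentialNetwork, temperature_c):
    """Curvature of the composite ln k vs 1/T curve at the given temperature."""
    return network.curvature(temperature_c)


def expand_reaction(reaction: Reaction, m: int, T_ref_K: float) -> list[Reaction]:
    """Split one reaction into ``m`` identical steps, matching tau at T_ref.

    Each sub-step keeps the prefactor A and lowers the activation energy by
    R * T_ref * ln(m) / 1000 kJ/mol, so each runs m-fold faster at T_ref
    and the m-chain's total time equals the original reaction's time
    exactly at T = T_ref (and only there, unless m == 1).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m == 1:
        return [reaction]
    Ea_new = reaction.Ea_kJ_per_mol - R_J_PER_MOL_K * T_ref_K * np.log(m) / 1000.0
    return [Reaction(float(Ea_new), reaction.A_per_min) for _ in range(m)]


@dataclass(frozen=True)
class CompositePrediction:
    """Composite ln-rate curve predicted from empirical sub-interval fits."""

    temperatures_C: np.ndarray
    lnk: np.ndarray
    tangent_Ea_kJ_per_mol: float
    tangent_intercept: float
    core_range_C: tuple[float, float]


def predict_composite_from_fits(
    fits: Sequence, temperatures_C, core_range_C,
) -> CompositePrediction:
    """Predict a span's Arrhenius curve by chaining its sub-interval fits.

    Each sub-interval's fitted (Ea, lnA) becomes one reaction of a
    sequential network; the composite ln k is evaluated on the temperature
    grid, and ``tangent_Ea`` is -R/1000 times the slope of the
    least-squares line through (1/T, ln k) over the core range.

    Non-contiguous sub-intervals (end code of one fit differing from the
    start code of the next) produce a warning, not an error.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no sub-interval fits supplied")
    codes = [(f.start_code, f.end_code) for f in fits]
    if all(c[0] is not None and c[1] is not None for c in codes):
        for (s0, e0), (s1, e1) in zip(codes, codes[1:]):
            if e0 != s1:
                warnings.warn(
                    f"sub-intervals not contiguous: {s0}-{e0} then {s1}-{e1}",
                    stacklevel=2,
                )
                break
    network = SequentialNetwork(
        [f.Ea_kJ_per_mol for f in fits], [f.intercept for f in fits]
    )
    temps = np.asarray(temperatures_C, dtype=float)
    lnk = network.composite_lnk(temps)
    lo, hi = core_range_C
    mask = (temps >= lo) & (temps <= hi)
    if mask.sum() < 2:
        raise ValueError("core range must contain at least 2 grid temperatures")
    x = 1.0 / celsius_to_kelvin(temps[mask])
    slope, intercept = np.polyfit(x, lnk[mask], 1)
    return CompositePrediction(
        temperatures_C=temps,
        lnk=lnk,
        tangent_Ea_kJ_per_mol=float(-slope * R_J_PER_MOL_K / 1000.0),
        tangent_intercept=float(intercept),
        core_range_C=(float(lo), float(hi)),
    )
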