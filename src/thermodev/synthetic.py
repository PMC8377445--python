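"""Synthetic embryo-timing tables and enzyme traces with known ground truth.

The generator emulates the statistical structure of staged-event timing
experiments: an ordered list of scored events, per-interval temperature
dependence that is Arrhenius (or concave-quadratic in Arrhenius
coordinates), multiplicative lognormal replicate noise of a chosen CV,
optional clutch effects (shared-mother offsets applied to all embryos at a
temperature), and viability-window missingness (embryos at extreme
temperatures never reach late scores).

Every draw is reproducible from the design's seed, and the true
per-interval parameters are returned alongside the data so recovery can be
tested at every pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import R_J_PER_MOL_K, celsius_to_kelvin
from .timings import EmbryoTimeline


@dataclass(frozen=True)
class IntervalTruth:
    """True temperature dependence of one adjacent interval.

    ln k(x) = c2 * x^2 - (Ea*1000/R) * x + lnA with x = 1/T (K^-1);
    ``c2 = 0`` is exact Arrhenius, ``c2 < 0`` concave-down.
    """

    Ea_kJ_per_mol: float
    lnA: float
    c2: float = 0.0

    def ln_rate(self, temperature_c):
        x = 1.0 / celsius_to_kelvin(np.asarray(temperature_c, dtype=float))
        b = self.Ea_kJ_per_mol * 1000.0 / R_J_PER_MOL_K
        return self.c2 * x**2 - b * x + self.lnA

    def mean_duration_min(self, temperature_c):
        return np.exp(-self.ln_rate(temperature_c))


def lnA_for_duration(Ea_kJ_per_mol: float, duration_min: float,
                     temperature_c: float) -> float:
    """Prefactor giving the requested mean duration at one temperature."""
    b = Ea_kJ_per_mol * 1000.0 / R_J_PER_MOL_K
    return b / celsius_to_kelvin(temperature_c) - math.log(duration_min)


@dataclass
class GeneratorDesign:
    """Study design for a synthetic timing experiment.

    Defaults emulate the fly experiments: one embryo per mother (no clutch
    effects), ~5% duration CV, replicates at each of several controlled
    temperatures with a small measured-temperature jitter, and a viability
    window outside which only the first half of the scores is reached.
    """

    organism: str = "fly"
    scores: Sequence[str] = ("A", "B", "C", "D", "E", "F", "G")
    interval_truths: Sequence[IntervalTruth] = ()
    temperatures_C: Sequence[float] = (10.0, 14.0, 17.0, 20.0, 23.0, 26.0, 29.0, 33.0)
    temperature_jitter_sd_C: float = 0.0
    replicates: int = 5
    duration_cv: float = 0.05
    clutch_effect_sd: float = 0.0
    viability_window_C: tuple[float, float] = (-math.inf, math.inf)
    #: scores with ordinal > this index are withheld outside the window
    truncate_at_index: int | None = None
    start_time_min: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if len(self.scores) < 2:
            raise ValueError("need at least two scores")
        if not self.temperatures_C:
            raise ValueError("empty temperature list")
        if self.duration_cv < 0:
            raise ValueError("duration CV must be >= 0")
        if self.viability_window_C[0] > self.viability_window_C[1]:
            raise ValueError("viability window out of order")
        if not self.interval_truths:
            # one shared Arrhenius truth per adjacent interval: Ea 64 kJ/mol,
            # lnA set so each interval lasts 60 min at 25 degC
            default = IntervalTruth(64.0, lnA_for_duration(64.0, 60.0, 25.0))
            self.interval_truths = tuple(default for _ in self.scores[:-1])
        if len(self.interval_truths) != len(self.scores) - 1:
            raise ValueError(
                f"{len(self.scores) - 1} adjacent intervals need truths, "
                f"got {len(self.interval_truths)}"
            )


def generate_timelines(design: GeneratorDesign):
    """Draw per-embryo timelines from the design.

    Returns ``(timelines, truth)`` where ``truth`` maps each adjacent
    interval ``(start, end)`` to its :class:`IntervalTruth` and records the
    realized per-embryo temperatures.

    Per embryo and interval the mean duration is 1/k(T) from the true
    model; the realized duration multiplies it by a unit-mean lognormal
    factor with the design CV and, when enabled, by a clutch factor shared
    by all embryos at the same nominal temperature.  Absolute times are
    cumulative sums from the origin (first) score.  When the nominal
    temperature lies outside the viability window, scores beyond the
    truncation index are withheld.
    """
    rng = np.random.default_rng(design.seed)
    scores = list(design.scores)
    n_int = len(scores) - 1
    truncate_at = (
        design.truncate_at_index
        if design.truncate_at_index is not None
        else max(1, len(scores) // 2)
    )
    sigma = math.sqrt(math.log(1.0 + design.duration_cv**2))
    mu = -0.5 * sigma**2  # unit-mean lognormal
    timelines: list[EmbryoTimeline] = []
    embryo_temps: dict[str, float] = {}
    counter = 0
    for nominal_T in design.temperatures_C:
        lo, hi = design.viability_window_C
        viable = lo <= nominal_T <= hi
        clutch = (
            math.exp(rng.normal(0.0, design.clutch_effect_sd))
            if design.clutch_effect_sd > 0
            else 1.0
        )
        for _ in range(design.replicates):
            counter += 1
            embryo_id = f"syn{counter:04d}"
            T = nominal_T
            if design.temperature_jitter_sd_C > 0:
                T += rng.normal(0.0, design.temperature_jitter_sd_C)
            durations = np.empty(n_int)
            for i, truth in enumerate(design.interval_truths):
                mean = float(truth.mean_duration_min(T))
                noise = math.exp(rng.normal(mu, sigma)) if sigma > 0 else 1.0
                durations[i] = mean * noise * clutch
            times = {scores[0]: design.start_time_min}
            cumulative = design.start_time_min
            last = len(scores) - 1 if viable else truncate_at
            for i in range(n_int):
                cumulative += durations[i]
                if i + 1 <= last:
                    times[scores[i + 1]] = cumulative
            timelines.append(
                EmbryoTimeline(
                    embryo_id=embryo_id,
                    organism=design.organism,
                    temperature_C=T,
                    times=times,
                )
            )
            embryo_temps[embryo_id] = T
    truth = {
        "intervals": {
            (scores[i], scores[i + 1]): design.interval_truths[i]
            for i in range(n_int)
        },
        "embryo_temperatures_C": embryo_temps,
        "seed": design.seed,
    }
    return timelines, truth


def generate_absorbance_trace(
    rate_AU_per_min: float,
    intercept_AU: float = 0.0,
    duration_min: float = 5.0,
    sampling_s: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Linear absorbance-vs-time trace with Gaussian noise.

    Emulates a spectrophotometer time course sampled every ``sampling_s``
    seconds for ``duration_min`` minutes; columns ``time_min`` and
    ``absorbance``.  Seed-reproducible.
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + 1e-12, sampling_s / 60.0)
    a = intercept_AU + rate_AU_per_min * t
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame({"time_min": t, "absorbance": a})
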