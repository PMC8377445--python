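"""Shared fixtures: tiny hand-built timelines and seeded synthetic designs."""

import numpy as np
import pytest

from thermodev import EmbryoTimeline, GeneratorDesign, IntervalTruth, lnA_for_duration


@pytest.fixture
def simple_timelines():
    """Three embryos, scores A/B/C, known durations; one embryo missing C."""
    return [
        EmbryoTimeline("e1", "fly", 20.0, {"A": 0.0, "B": 20.0, "C": 50.0}),
        EmbryoTimeline("e2", "fly", 20.0, {"A": 10.0, "B": 35.0, "C": 75.0}),
        EmbryoTimeline("e3", "fly", 20.0, {"A": 5.0, "B": 35.0}),
    ]


@pytest.fixture
def arrhenius_points():
    """Noise-free rates from Ea = 64 kJ/mol, lnA = 5 at eight temperatures."""
    T = np.array([10.0, 14.0, 17.0, 20.0, 23.0, 26.0, 29.0, 33.0])
    rate = np.exp(5.0 - 64.0e3 / (8.314 * (T + 273.15)))
    return T, rate


@pytest.fixture
def fly_like_design():
    """8 temperatures x 5 replicates, 5% CV, distinct true Ea per interval."""
    truths = (
        IntervalTruth(60.0, lnA_for_duration(60.0, 45.0, 25.0)),
        IntervalTruth(75.0, lnA_for_duration(75.0, 80.0, 25.0)),
        IntervalTruth(85.0, lnA_for_duration(85.0, 120.0, 25.0)),
    )
    return GeneratorDesign(
        organism="fly",
        scores=("A", "B", "C", "D"),
        interval_truths=truths,
        temperatures_C=(12.0, 15.0, 18.0, 21.0, 24.0, 27.0, 30.0, 33.0),
        replicates=5,
        duration_cv=0.05,
        viability_window_C=(14.0, 31.0),
        seed=42,
    )
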