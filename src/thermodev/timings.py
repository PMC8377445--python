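"""Staged event-timing tables: intervals, rates, and score selection.

This module turns raw per-embryo scored-event times (absolute minutes at a
measured temperature) into per-embryo interval durations and per-temperature
rate summaries, and implements the coefficient-of-variation procedure used
to keep only reproducibly scorable developmental events.

Scored events are identified by single-character codes ordered by a
developmental ordinal.  The canonical fly and frog score tables ship as
:data:`FLY_SCORES` and :data:`FROG_SCORES`; candidate events that were
evaluated but dropped for poor reproducibility carry digit codes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Header of the long-format timing-table CSV.
LONG_COLUMNS = ["embryo_id", "organism", "temperature_C", "score_code", "time_min"]


@dataclass(frozen=True)
class EventScore:
    """A scorable developmental event.

    Parameters
    ----------
    code : str
        Single-letter (retained) or single-digit (dropped candidate) label.
    name : str
        Human-readable event name.
    organism : str
        ``"fly"`` or ``"frog"``.
    ordinal : int
        Rank of the event in developmental order; strictly increasing.
    """

    code: str
    name: str
    organism: str
    ordinal: int


FLY_SCORES = (
    EventScore("Z", "13th cleavage", "fly", 0),
    EventScore("A", "14th cleavage", "fly", 1),
    EventScore("B", "beginning of cellularization", "fly", 2),
    EventScore("C", "end of cell elongation", "fly", 3),
    EventScore("D", "beginning of pole cell migration", "fly", 4),
    EventScore("E", "horizontal posterior midgut", "fly", 5),
    EventScore("F", "closure of the posterior midgut", "fly", 6),
    EventScore("G", "beginning of germ band retraction", "fly", 7),
    EventScore("H", "end of germ band retraction", "fly", 8),
    EventScore("I", "yolk retraction", "fly", 9),
    EventScore("J", "yolk segregation", "fly", 10),
    EventScore("K", "first breath", "fly", 11),
)

FROG_SCORES = (
    EventScore("A", "3rd cleavage", "frog", 0),
    EventScore("B", "4th cleavage", "frog", 1),
    EventScore("C", "5th cleavage", "frog", 2),
    EventScore("D", "6th cleavage", "frog", 3),
    EventScore("E", "7th cleavage", "frog", 4),
    EventScore("F", "8th cleavage", "frog", 5),
    EventScore("G", "9th cleavage", "frog", 6),
    EventScore("H", "10th cleavage", "frog", 7),
    EventScore("I", "early gastrulation", "frog", 8),
    EventScore("J", "late gastrulation", "frog", 9),
    EventScore("K", "early neurulation", "frog", 10),
    EventScore("L", "late neurulation", "frog", 11),
)

SCORE_TABLES = {"fly": FLY_SCORES, "frog": FROG_SCORES}


def score_order(scores: Sequence[EventScore] | Sequence[str]) -> dict[str, int]:
    """Map score codes to ordinals, accepting EventScore lists or raw codes."""
    if scores and isinstance(scores[0], EventScore):
        return {s.code: s.ordinal for s in scores}
    return {code: i for i, code in enumerate(scores)}


@dataclass
class EmbryoTimeline:
    """Absolute scored-event times (minutes) of one embryo at one temperature.

    ``times`` is partial: embryos that die or stop developing lack late
    scores.  Times must be non-decreasing with developmental ordinal; this
    is validated lazily via :meth:`validate` because the score order is not
    always known at construction.
    """

    embryo_id: str
    organism: str
    temperature_C: float
    times: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not math.isfinite(self.temperature_C):
            raise ValueError(f"non-finite temperature for embryo {self.embryo_id!r}")

    def validate(self, order: Mapping[str, int]) -> None:
        """Check times are non-decreasing with score ordinal."""
        known = sorted(
            (code for code in self.times if code in order), key=order.__getitem__
        )
        ts = [self.times[c] for c in known]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError(
                f"embryo {self.embryo_id!r}: scored times decrease with "
                "developmental order"
            )


@dataclass(frozen=True)
class IntervalObservation:
    """Duration and pseudo-rate of one developmental interval in one embryo."""

    embryo_id: str
    start_code: str
    end_code: str
    temperature_C: float
    duration_min: float

    def __post_init__(self):
        if not self.duration_min > 0:
            raise ValueError(
                f"embryo {self.embryo_id!r}: non-positive duration "
                f"{self.duration_min} for {self.start_code}-{self.end_code}"
            )

    @property
    def rate_per_min(self) -> float:
        """Pseudo-reaction rate, the inverse of the interval duration."""
        return 1.0 / self.duration_min


@dataclass(frozen=True)
class RateSummary:
    """Per-temperature summary of ln(rate) across biological replicates."""

    start_code: str
    end_code: str
    temperature_C: float
    n: int
    mean_ln_rate: float
    se_ln_rate: float | None
    mean_duration_min: float


@dataclass
class SkipReport:
    """Diagnostics from interval extraction.

    ``missing`` counts embryos lacking the start or end score;
    ``nonpositive`` lists embryo ids rejected for a scoring-order violation
    (duration <= 0).
    """

    start_code: str = ""
    end_code: str = ""
    missing: int = 0
    nonpositive: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "start_code": self.start_code,
                "end_code": self.end_code,
                "missing": self.missing,
                "nonpositive": list(self.nonpositive),
            }
        )


# ---------------------------------------------------------------------------
# long-format I/O

def read_timing_table(path_or_buffer) -> list[EmbryoTimeline]:
    """Read a long-format timing CSV into per-embryo timelines.

    Expected header: ``embryo_id,organism,temperature_C,score_code,time_min``,
    one row per scored event.
    """
    df = pd.read_csv(path_or_buffer, dtype={"embryo_id": str, "score_code": str})
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"timing table lacks columns: {sorted(missing)}")
    return timelines_from_frame(df)


def timelines_from_frame(df: pd.DataFrame) -> list[EmbryoTimeline]:
    """Convert a long-format DataFrame into EmbryoTimeline objects."""
    out = []
    for (embryo_id, organism, temp), grp in df.groupby(
        ["embryo_id", "organism", "temperature_C"], sort=False
    ):
        times = dict(zip(grp["score_code"].astype(str), grp["time_min"].astype(float)))
        out.append(
            EmbryoTimeline(
                embryo_id=str(embryo_id),
                organism=str(organism),
                temperature_C=float(temp),
                times=times,
            )
        )
    return out


def timelines_to_frame(timelines: Iterable[EmbryoTimeline]) -> pd.DataFrame:
    """Inverse of :func:`timelines_from_frame`."""
    rows = [
        (tl.embryo_id, tl.organism, tl.temperature_C, code, t)
        for tl in timelines
        for code, t in tl.times.items()
    ]
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def observations_to_frame(observations: Iterable[IntervalObservation]) -> pd.DataFrame:
    rows = [
        (o.embryo_id, o.start_code, o.end_code, o.temperature_C, o.duration_min,
         o.rate_per_min)
        for o in observations
    ]
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "start_code", "end_code", "temperature_C",
                 "duration_min", "rate_per_min"],
    )


# ---------------------------------------------------------------------------
# interval extraction

def compute_intervals(
    timelines: Iterable[EmbryoTimeline],
    start_code: str,
    end_code: str,
    order: Mapping[str, int] | None = None,
) -> tuple[list[IntervalObservation], SkipReport]:
    """Extract one interval duration per embryo that has both scores.

    Embryos missing either score are skipped and counted in the returned
    :class:`SkipReport`; embryos whose end time does not exceed their start
    time are rejected as scoring errors (never clamped) and listed there.
    """
    if order is not None and order[start_code] >= order[end_code]:
        raise ValueError(
            f"start score {start_code!r} must precede end score {end_code!r}"
        )
    observations: list[IntervalObservation] = []
    report = SkipReport(start_code=start_code, end_code=end_code)
    for tl in timelines:
        if start_code not in tl.times or end_code not in tl.times:
            report.missing += 1
            continue
        duration = tl.times[end_code] - tl.times[start_code]
        if duration <= 0:
            logger.warning(
                "embryo %s: non-positive duration %.3f for %s-%s; excluded",
                tl.embryo_id, duration, start_code, end_code,
            )
            report.nonpositive.append(tl.embryo_id)
            continue
        observations.append(
            IntervalObservation(
                embryo_id=tl.embryo_id,
                start_code=start_code,
                end_code=end_code,
                temperature_C=tl.temperature_C,
                duration_min=duration,
            )
        )
    return observations, report


def relative_times(
    timelines: Iterable[EmbryoTimeline], origin_code: str
) -> list[EmbryoTimeline]:
    """Re-zero every timeline at the origin score.

    The origin score's absolute time is subtracted from all other score
    times, so earlier events get negative times.  Pairwise differences are
    unchanged.  Timelines lacking the origin score are dropped with a
    logged diagnostic.
    """
    out = []
    for tl in timelines:
        if origin_code not in tl.times:
            logger.warning(
                "embryo %s lacks origin score %r; dropped", tl.embryo_id, origin_code
            )
            continue
        t0 = tl.times[origin_code]
        out.append(
            EmbryoTimeline(
                embryo_id=tl.embryo_id,
                organism=tl.organism,
                temperature_C=tl.temperature_C,
                times={code: t - t0 for code, t in tl.times.items()},
            )
        )
    return out


# ---------------------------------------------------------------------------
# CV-based score selection

def cv_matrix(
    timelines: Sequence[EmbryoTimeline],
    scores: Sequence[EventScore] | Sequence[str],
    temperature_decimals: int | None = None,
) -> pd.DataFrame:
    """Mean coefficient of variation (%) for every ordered score pair.

    For each (start, end) pair with start ordinal < end ordinal, interval
    durations are grouped by temperature; at each temperature with at least
    two replicates the CV is ``sample sd / mean * 100`` (n-1 denominator),
    and the matrix cell is the unweighted mean of the per-temperature CVs.
    Pairs with no qualifying temperature are NaN.  Per-temperature groups
    with a single replicate are skipped, not treated as zero.

    ``temperature_decimals`` optionally rounds measured temperatures before
    grouping (nominal-temperature grouping for display summaries).
    """
    order = score_order(scores)
    codes = sorted(order, key=order.__getitem__)
    mat = pd.DataFrame(np.nan, index=codes, columns=codes, dtype=float)
    grouped: dict[float, list[EmbryoTimeline]] = {}
    for tl in timelines:
        key = tl.temperature_C
        if temperature_decimals is not None:
            key = round(key, temperature_decimals)
        grouped.setdefault(key, []).append(tl)
    for i, start in enumerate(codes):
        for end in codes[i + 1:]:
            cvs = []
            for tls in grouped.values():
                durations = [
                    tl.times[end] - tl.times[start]
                    for tl in tls
                    if start in tl.times and end in tl.times
                ]
                if len(durations) < 2:
                    continue
                mean = float(np.mean(durations))
                if mean == 0:
                    logger.warning(
                        "zero mean duration for %s-%s; temperature skipped",
                        start, end,
                    )
                    continue
                sd = float(np.std(durations, ddof=1))
                cvs.append(sd / mean * 100.0)
            if cvs:
                mat.loc[start, end] = float(np.mean(cvs))
    return mat


def _adjacent_cv(matrix: pd.DataFrame, codes: list[str], code: str) -> float:
    """Mean CV of the intervals joining ``code`` to its current neighbours."""
    i = codes.index(code)
    vals = []
    if i > 0:
        v = matrix.loc[codes[i - 1], code]
        if not pd.isna(v):
            vals.append(float(v))
    if i < len(codes) - 1:
        v = matrix.loc[code, codes[i + 1]]
        if not pd.isna(v):
            vals.append(float(v))
    # a score with no measured adjacent interval is maximally unreliable
    return float(np.mean(vals)) if vals else math.inf


def select_scores(matrix: pd.DataFrame, k: int) -> list[str]:
    """Retain the ``k`` most reproducibly scorable events.

    Scores are dropped one at a time: at each step the score whose
    adjacent-interval mean CV (against its *current* neighbours) is largest
    is removed, ties broken by developmental ordinal (the earlier score is
    kept, i.e. the later of tied scores is dropped).  Deterministic.
    """
    codes = list(matrix.index)
    if k > len(codes):
        raise ValueError(f"k={k} exceeds {len(codes)} candidate scores")
    while len(codes) > k:
        badness = [_adjacent_cv(matrix, codes, c) for c in codes]
        worst = max(badness)
        # drop the later (largest-ordinal) of the tied worst scores
        drop_idx = max(i for i, b in enumerate(badness) if b == worst)
        del codes[drop_idx]
    return codes


# ---------------------------------------------------------------------------
# rate summaries

def summarize_rates(
    observations: Sequence[IntervalObservation],
    temperature_decimals: int | None = None,
) -> list[RateSummary]:
    """Per-temperature mean and standard error of ln(rate).

    The per-embryo ln rate is computed first; the standard error is over
    replicates and is ``None`` for a single replicate.
    """
    if not observations:
        return []
    pairs = {(o.start_code, o.end_code) for o in observations}
    if len(pairs) != 1:
        raise ValueError(f"observations span multiple intervals: {sorted(pairs)}")
    (start, end), = pairs
    grouped: dict[float, list[IntervalObservation]] = {}
    for o in observations:
        key = o.temperature_C
        if temperature_decimals is not None:
            key = round(key, temperature_decimals)
        grouped.setdefault(key, []).append(o)
    out = []
    for temp in sorted(grouped):
        obs = grouped[temp]
        ln_rates = np.log([o.rate_per_min for o in obs])
        n = len(obs)
        se = float(np.std(ln_rates, ddof=1) / math.sqrt(n)) if n >= 2 else None
        out.append(
            RateSummary(
                start_code=start,
                end_code=end,
                temperature_C=temp,
                n=n,
                mean_ln_rate=float(np.mean(ln_rates)),
                se_ln_rate=se,
                mean_duration_min=float(np.mean([o.duration_min for o in obs])),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[RateSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.start_code, s.end_code, s.temperature_C, s.n, s.mean_ln_rate,
             np.nan if s.se_ln_rate is None else s.se_ln_rate,
             s.mean_duration_min)
            for s in summaries
        ],
        columns=["start_code", "end_code", "temperature_C", "n", "mean_ln_rate",
                 "se_ln_rate", "mean_duration_min"],
    )
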