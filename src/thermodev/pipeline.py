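"""End-to-end analysis: tables in, figure-analogue reports out.

:func:`run_full_analysis` orchestrates the full chain deterministically:
interval extraction for every ordered score pair, Arrhenius linear fits
over the core range and quadratic fits over all temperatures, an all-pairs
linear-vs-quadratic BIC log-ratio matrix, an all-pairs slope-comparison
(ANCOVA) matrix with raw and Holm-adjusted p-values, and a composite
prediction chaining adjacent-interval fits across a chosen span.  Every
number lands in a JSON-serializable manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import timings
from .arrhenius import bic_compare, compare_slopes_ancova, fit_interval, fit_quadratic
from .constants import CORE_RANGE_C, ORIGIN_SCORE, VIABLE_RANGE_C
from .network import predict_composite_from_fits
from .timings import compute_intervals, relative_times, score_order


@dataclass
class AnalysisConfig:
    """Configuration of a full timing-table analysis."""

    organism: str = "fly"
    origin_score: str | None = None
    core_range_C: tuple[float, float] | None = None
    viable_range_C: tuple[float, float] | None = None
    scores: Sequence[str] | None = None
    min_points_fit: int = 3
    min_points_bic: int = 5
    composite_span: tuple[str, str] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.origin_score is None:
            self.origin_score = ORIGIN_SCORE.get(self.organism, "A")
        if self.core_range_C is None:
            self.core_range_C = CORE_RANGE_C.get(self.organism)
        if self.viable_range_C is None:
            self.viable_range_C = VIABLE_RANGE_C.get(self.organism)
        for rng in (self.core_range_C, self.viable_range_C):
            if rng is not None and rng[0] > rng[1]:
                raise ValueError("temperature range out of order")


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits) if math.isfinite(obj) else obj
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_full_analysis(config: AnalysisConfig, table: pd.DataFrame) -> dict:
    """Run the deterministic analysis bundle on a long-format timing table.

    Returns a dict with keys ``intervals`` (per-pair observation tables),
    ``linear_fits``, ``quadratic_fits``, ``bic_matrix``, ``slope_tests``
    (raw and Holm-adjusted p-values), ``composite`` and ``manifest`` (a
    JSON string capturing every reported number; reruns on identical
    inputs produce a byte-identical manifest).
    """
    timelines = timings.timelines_from_frame(table)
    if config.scores is not None:
        scores = list(config.scores)
    else:
        seen = {c for tl in timelines for c in tl.times}
        table_scores = [s.code for s in timings.SCORE_TABLES.get(config.organism, ())]
        scores = [c for c in table_scores if c in seen] or sorted(seen)
    order = score_order(scores)
    if config.origin_score not in order:
        raise ValueError(f"origin score {config.origin_score!r} not in score set")
    timelines = relative_times(timelines, config.origin_score)

    observations = {}
    skip_reports = {}
    for i, start in enumerate(scores):
        for end in scores[i + 1:]:
            obs, report = compute_intervals(timelines, start, end, order=order)
            observations[(start, end)] = obs
            skip_reports[(start, end)] = report

    linear_fits = {}
    quadratic_fits = {}
    bic = {}
    for pair, obs in observations.items():
        T = np.array([o.temperature_C for o in obs])
        r = np.array([o.rate_per_min for o in obs])
        lo, hi = config.core_range_C
        n_core = int(((T >= lo) & (T <= hi)).sum())
        if n_core >= config.min_points_fit:
            linear_fits[pair] = fit_interval(obs, core_range_C=config.core_range_C)
        if len(obs) >= max(4, config.min_points_bic):
            quadratic_fits[pair] = fit_quadratic(T, r)
            bic[pair] = bic_compare(T, r)

    # all-pairs slope comparison between intervals with a core-range fit
    fitted_pairs = sorted(linear_fits, key=lambda p: (order[p[0]], order[p[1]]))
    slope_rows = []
    for i, pa in enumerate(fitted_pairs):
        for pb in fitted_pairs[i + 1:]:
            oa, ob = observations[pa], observations[pb]
            try:
                cmpres = compare_slopes_ancova(
                    [o.temperature_C for o in oa], [o.rate_per_min for o in oa],
                    [o.temperature_C for o in ob], [o.rate_per_min for o in ob],
                    core_range_C=config.core_range_C,
                )
            except ValueError:
                continue
            slope_rows.append({
                "interval_a": "-".join(pa), "interval_b": "-".join(pb),
                "F": cmpres.F, "p": cmpres.p, "power": cmpres.power,
                "df_num": cmpres.df_num, "df_den": cmpres.df_den,
            })
    if slope_rows:
        raw_p = [row["p"] for row in slope_rows]
        # Holm adjustment is an extension beyond the raw pairwise p-values
        _, adj, _, _ = multipletests(raw_p, method="holm")
        for row, p_adj in zip(slope_rows, adj):
            row["p_holm"] = float(p_adj)

    composite = None
    span = config.composite_span
    if span is None and scores:
        span = (scores[0], scores[-1])
    if span is not None:
        chain = [
            linear_fits[(a, b)]
            for a, b in zip(scores, scores[1:])
            if (a, b) in linear_fits
            and order[span[0]] <= order[a] and order[b] <= order[span[1]]
        ]
        if chain:
            temps = sorted({o.temperature_C
                            for pair in observations
                            for o in observations[pair]})
            if len(temps) >= 2:
                composite = predict_composite_from_fits(
                    chain, temps, core_range_C=config.core_range_C
                )

    manifest = {
        "organism": config.organism,
        "origin_score": config.origin_score,
        "core_range_C": list(config.core_range_C),
        "viable_range_C": list(config.viable_range_C) if config.viable_range_C else None,
        "scores": scores,
        "seed": config.seed,
        "n_timelines": len(timelines),
        "skip_reports": {
            "-".join(pair): {"missing": rep.missing,
                             "nonpositive": list(rep.nonpositive)}
            for pair, rep in sorted(skip_reports.items(),
                                    key=lambda kv: (order[kv[0][0]], order[kv[0][1]]))
        },
        "linear_fits": {
            "-".join(pair): {
                "Ea_kJ_per_mol": f.Ea_kJ_per_mol,
                "ci68_Ea_kJ_per_mol": f.ci68_Ea_kJ_per_mol,
                "lnA": f.intercept,
                "n": f.n,
            }
            for pair, f in sorted(linear_fits.items(),
                                  key=lambda kv: (order[kv[0][0]], order[kv[0][1]]))
        },
        "quadratic_fits": {
            "-".join(pair): {"c2": q.c2, "c1": q.c1, "c0": q.c0,
                             "concavity": q.concavity, "n": q.n}
            for pair, q in sorted(quadratic_fits.items(),
                                  key=lambda kv: (order[kv[0][0]], order[kv[0][1]]))
        },
        "bic_log_ratio": {
            "-".join(pair): m.log_ratio
            for pair, m in sorted(bic.items(),
                                  key=lambda kv: (order[kv[0][0]], order[kv[0][1]]))
        },
        "slope_tests": slope_rows,
        "composite": None if composite is None else {
            "span": list(span),
            "tangent_Ea_kJ_per_mol": composite.tangent_Ea_kJ_per_mol,
            "temperatures_C": list(composite.temperatures_C),
            "lnk": list(composite.lnk),
        },
    }
    return {
        "intervals": observations,
        "skip_reports": skip_reports,
        "linear_fits": linear_fits,
        "quadratic_fits": quadratic_fits,
        "bic": bic,
        "slope_tests": slope_rows,
        "composite": composite,
        "manifest": json.dumps(_round_floats(manifest), sort_keys=True, indent=1),
    }
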