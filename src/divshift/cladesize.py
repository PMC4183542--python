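"""Observed vs expected clade richness at shift events.

For each accepted shift, the observed richness of the shifted clade is
compared with the size expected for a clade of the same stem age evolving
under the *parental* regime.  Nested shifts are corrected for: terminals
governed by a deeper nested shift are excluded from the observed count, and
each immediately nested shift contributes a single lineage (its stem) in
their place.  Expectations and 95% intervals come from the
survival-conditioned clade-size distribution (geometric with parameter
beta(t)): mean ``e^{rt} / (1 - alpha(t))`` and closed-form quantiles.  The
interval on the ratio is the clade-size interval transformed, i.e.
``observed / q_{97.5}`` to ``observed / q_{2.5}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bdcore import BDParams, expected_richness, richness_quantile
from .shiftsearch import ShiftModel

__all__ = ["RichnessRatio", "corrected_richness", "richness_ratio", "ratio_timeline"]


@dataclass(frozen=True)
class RichnessRatio:
    """The observed/expected richness statistic for one shift clade."""

    leafset: frozenset
    age: float  # stem age of the shift, Myr
    observed_n: int  # corrected for nested shifts
    expected_mean: float
    ci_low_n: int
    ci_high_n: int
    ratio: float
    ratio_ci_low: float
    ratio_ci_high: float


def corrected_richness(model: ShiftModel, shift_node: int) -> int:
    """Observed richness of a shift clade, corrected for nested shifts.

    Sums richness over terminals governed by the focal regime itself and adds
    one lineage for each shift immediately nested inside it (each nested
    radiation counts as a single lineage at its origin).
    """
    if shift_node not in model.shift_nodes:
        raise ValueError(f"node {shift_node} is not a shift in this model")
    focal = model.shift_nodes.index(shift_node) + 1
    regime = model.regime_of()
    rt = model.richness_tree
    total = sum(
        rt.tip_richness[tid]
        for tid in rt.chronogram.tip_ids
        if regime[tid] == focal
    )
    # immediately nested shifts: shifts whose surrounding (parent) regime is
    # the focal one; each counts as a single stem lineage
    for other in model.shift_nodes:
        if other != shift_node and model.parent_regime(other) == focal:
            total += 1
    return total


def richness_ratio(model: ShiftModel, shift_node: int,
                   parent_params: BDParams | None = None,
                   ci: float = 0.95) -> RichnessRatio:
    """Observed/expected richness ratio of a shift clade under the parental
    regime, with the clade-size CI transformed onto the ratio."""
    if parent_params is None:
        parent_params = model.params[model.parent_regime(shift_node)]
    chrono = model.richness_tree.chronogram
    parent = chrono.parent(shift_node)
    stem_age = chrono.age(parent) if parent is not None else chrono.root_age
    observed = corrected_richness(model, shift_node)
    mean = expected_richness(stem_age, parent_params, conditioned=True)
    tail = (1.0 - ci) / 2.0
    lo = richness_quantile(tail, stem_age, parent_params)
    hi = richness_quantile(1.0 - tail, stem_age, parent_params)
    return RichnessRatio(
        leafset=chrono.leafset(shift_node),
        age=stem_age,
        observed_n=observed,
        expected_mean=mean,
        ci_low_n=lo,
        ci_high_n=hi,
        ratio=observed / mean,
        ratio_ci_low=observed / hi,
        ratio_ci_high=observed / lo,
    )


def ratio_timeline(model: ShiftModel) -> pd.DataFrame:
    """One row per accepted shift (sorted by stem age, oldest first):
    age, observed (corrected), expected, CI bounds, ratio, direction."""
    if not model.shift_nodes:
        raise ValueError("model has no shifts")
    rows = []
    for nid in model.shift_nodes:
        rr = richness_ratio(model, nid)
        rows.append({
            "node_id": int(nid),
            "age_ma": rr.age,
            "n_terminals": len(rr.leafset),
            "observed_n": rr.observed_n,
            "expected_mean": rr.expected_mean,
            "ci_low_n": rr.ci_low_n,
            "ci_high_n": rr.ci_high_n,
            "ratio": rr.ratio,
            "ratio_ci_low": rr.ratio_ci_low,
            "ratio_ci_high": rr.ratio_ci_high,
            "direction": "up" if rr.ratio > 1 else "down",
        })
    return pd.DataFrame(rows).sort_values("age_ma", ascending=False).reset_index(drop=True)
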