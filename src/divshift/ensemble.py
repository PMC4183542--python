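"""Robustness of inferred shifts across an ensemble of dated trees.

Node ages estimated by Bayesian dating are uncertain; rerunning the stepwise
shift search over many dated-tree samples with a fixed topology shows which
shifts survive that uncertainty.  Shifts are matched across trees by exact
terminal leafset (well defined because the topology is shared); recovery
fractions are binned with the conventional thresholds 80/50/30%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .shiftsearch import ShiftModel, stepwise_search
from .treedata import Chronogram, RichnessTable, RichnessTree

__all__ = [
    "EnsembleRobustness",
    "search_ensemble",
    "tally",
    "robustness_bin",
    "near_miss_diagnostics",
]

BINS = ((0.8, ">80%"), (0.5, ">50%"), (0.3, ">30%"))


def robustness_bin(fraction: float) -> str:
    for threshold, name in BINS:
        if fraction > threshold:
            return name
    return "<30%"


@dataclass(frozen=True)
class EnsembleRobustness:
    """Recovery statistics of one candidate shift clade over the ensemble."""

    leafset: frozenset
    recovery_count: int
    ensemble_size: int

    @property
    def recovery_fraction(self) -> float:
        return self.recovery_count / self.ensemble_size

    @property
    def bin(self) -> str:
        return robustness_bin(self.recovery_fraction)


def _check_shared_topology(trees: list[Chronogram]) -> None:
    ref = trees[0]
    ref_clades = {ref.leafset(nid) for nid in ref.internal_ids}
    ref_tips = frozenset(ref.tip_labels())
    for k, tree in enumerate(trees[1:], start=1):
        if frozenset(tree.tip_labels()) != ref_tips:
            raise ValueError(f"tree {k} has a different terminal label set")
        clades = {tree.leafset(nid) for nid in tree.internal_ids}
        diff = clades ^ ref_clades
        if diff:
            example = sorted(next(iter(diff)))
            raise ValueError(
                f"tree {k} topology differs from tree 0; first discordant clade: {example[:6]}"
            )


def search_ensemble(
    trees: list[Chronogram],
    richness: RichnessTable,
    aic_threshold: float | None = None,
    max_shifts: int | None = None,
    fixed_eps: float | None = None,
    cache_dir=None,
) -> list[set]:
    """Run the stepwise shift search independently on every tree.

    All trees must share terminal labels and topology.  Returns, per tree, the
    set of shift clades as frozensets of terminal labels.  ``cache_dir`` makes
    the scan resumable: per-tree results are stored as JSON and reloaded on a
    rerun with the same directory.
    """
    if not trees:
        raise ValueError("ensemble must contain at least one tree")
    _check_shared_topology(trees)
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    results = []
    for k, tree in enumerate(trees):
        if cache:
            f = cache / f"tree_{k:05d}.json"
            if f.exists():
                results.append({frozenset(ls) for ls in json.loads(f.read_text())})
                continue
        rt = RichnessTree(tree, richness)
        models = stepwise_search(rt, aic_threshold=aic_threshold,
                                 max_shifts=max_shifts, fixed_eps=fixed_eps)
        shifts = {ls for ls in models[-1].shift_leafsets()}
        if cache:
            (cache / f"tree_{k:05d}.json").write_text(
                json.dumps([sorted(ls) for ls in shifts])
            )
        results.append(shifts)
    return results


def tally(per_tree_shifts: list[set], reference: ShiftModel | list | None = None) -> pd.DataFrame:
    """Recovery fraction per candidate shift clade over the ensemble.

    Candidates are every clade that is a shift in the reference model (if
    given) or in any ensemble tree; reference shifts recovered nowhere still
    appear with fraction 0.  Rows are ranked by recovery fraction (then by
    clade size, largest first).  Order of trees does not matter.
    """
    n = len(per_tree_shifts)
    if n == 0:
        raise ValueError("empty ensemble")
    ref_sets: list[frozenset] = []
    if reference is not None:
        ref_sets = list(reference.shift_leafsets()) if isinstance(reference, ShiftModel) \
            else [frozenset(ls) for ls in reference]
    candidates = set(ref_sets)
    for shifts in per_tree_shifts:
        candidates |= set(shifts)
    rows = []
    for clade in candidates:
        count = sum(1 for shifts in per_tree_shifts if clade in shifts)
        rob = EnsembleRobustness(leafset=clade, recovery_count=count, ensemble_size=n)
        rows.append({
            "leafset": tuple(sorted(clade)),
            "n_terminals": len(clade),
            "recovery_count": count,
            "ensemble_size": n,
            "recovery_fraction": rob.recovery_fraction,
            "bin": rob.bin,
            "in_reference": clade in ref_sets,
        })
    columns = ["leafset", "n_terminals", "recovery_count", "ensemble_size",
               "recovery_fraction", "bin", "in_reference"]
    df = pd.DataFrame(rows, columns=columns).sort_values(
        ["recovery_fraction", "n_terminals"], ascending=[False, False]
    ).reset_index(drop=True)
    return df


def near_miss_diagnostics(per_tree_shifts: list[set], reference: ShiftModel) -> pd.DataFrame:
    """For each reference shift, how often the ensemble placed a shift exactly
    there versus at its parent or a child clade instead (matching is otherwise
    exact-leafset only)."""
    chrono = reference.richness_tree.chronogram
    n = len(per_tree_shifts)
    rows = []
    for nid in reference.shift_nodes:
        clade = chrono.leafset(nid)
        parent = chrono.parent(nid)
        neighbours = []
        if parent is not None:
            neighbours.append(chrono.leafset(parent))
        neighbours.extend(chrono.leafset(c) for c in chrono.children(nid))
        exact = sum(1 for s in per_tree_shifts if clade in s)
        near = sum(
            1 for s in per_tree_shifts
            if clade not in s and any(nb in s for nb in neighbours)
        )
        rows.append({
            "leafset": tuple(sorted(clade)),
            "exact_fraction": exact / n,
            "near_miss_fraction": near / n,
        })
    return pd.DataFrame(rows)
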