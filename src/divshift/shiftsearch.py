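"""Stepwise detection of diversification-rate shifts (MEDUSA-style).

The tree is partitioned into rate regimes.  A shift placed at a node uses the
"cut at stem" convention by default: the new regime owns the shifted clade's
stem branch, the split at the shifted node and everything below it, except
where a more deeply nested shift takes over.  Forward selection adds, at each
step, the single shift whose refitted model most improves AIC, and stops when
the improvement drops below a threshold (default 4 AIC units) or a shift cap
is reached.  Each accepted shift adds three parameters (r, eps, location), so
a model with ``s`` shifts has ``k = 2 + 3s``.

Because the combined likelihood is additive over branches, jointly refitting
all regimes decomposes into independent per-regime fits; after adding a shift
only the donor regime (the one that lost branches) and the new regime need
re-optimisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .bdcore import BDParams, FitError, LikelihoodBreakdown, RegimeData, fit_params
from .treedata import RichnessTree

__all__ = [
    "ShiftModel",
    "build_regimes",
    "fit_homogeneous",
    "try_shift",
    "stepwise_search",
    "classify_direction",
    "DEFAULT_AIC_THRESHOLD",
]

DEFAULT_AIC_THRESHOLD = 4.0


class _TreeArrays:
    """Per-tree flat arrays for fast regime slicing (cached on the tree)."""

    def __init__(self, rt: RichnessTree):
        chrono = rt.chronogram
        n = len(chrono.nodes)
        self.ids = np.arange(n)
        self.age = np.array([chrono.age(i) for i in range(n)])
        parent = np.array([chrono.parent(i) if chrono.parent(i) is not None else -1
                           for i in range(n)])
        self.parent = parent
        self.parent_age = np.where(parent >= 0, self.age[np.maximum(parent, 0)], np.nan)
        self.is_tip = np.array([not chrono.children(i) for i in range(n)])
        self.is_root = self.ids == chrono.root_id
        rich = np.zeros(n)
        for tid in chrono.tip_ids:
            rich[tid] = rt.tip_richness[tid]
        self.richness = rich
        self.subtree = {i: np.array(chrono.subtree_ids(i)) for i in range(n)}
        self.preorder = list(reversed(chrono.postorder()))


def _tree_arrays(rt: RichnessTree) -> _TreeArrays:
    arr = getattr(rt, "_divshift_arrays", None)
    if arr is None:
        arr = _TreeArrays(rt)
        rt._divshift_arrays = arr
    return arr


def _regime_of_nodes(rt: RichnessTree, shift_nodes, placement: str = "stem") -> np.ndarray:
    """Regime index per node: 0 for the root regime, 1 + position in
    ``shift_nodes`` for nodes governed by that shift (nearest shift ancestor
    wins; under stem placement the shift node itself switches, under node
    placement only its strict descendants do)."""
    if placement not in ("stem", "node"):
        raise ValueError(f"placement must be 'stem' or 'node', got {placement!r}")
    arr = _tree_arrays(rt)
    chrono = rt.chronogram
    shift_idx = {nid: i + 1 for i, nid in enumerate(shift_nodes)}
    regime = np.zeros(len(arr.ids), dtype=int)
    for nid in arr.preorder:
        p = chrono.parent(nid)
        if placement == "stem":
            inherited = int(regime[p]) if p is not None else 0
            regime[nid] = shift_idx.get(nid, inherited)
        else:  # the shift node's own stem branch/split stay with the parent
            if p is None:
                regime[nid] = 0
            elif p in shift_idx:
                regime[nid] = shift_idx[p]
            else:
                regime[nid] = regime[p]
    return regime


def _regime_data_from_mask(arr: _TreeArrays, mask: np.ndarray) -> RegimeData:
    internal_mask = mask & ~arr.is_tip & ~arr.is_root
    tips_mask = mask & arr.is_tip
    return RegimeData(
        split_ages=arr.age[internal_mask],
        branch_spans=np.column_stack([arr.parent_age[internal_mask], arr.age[internal_mask]]),
        richness=arr.richness[tips_mask],
        stem_ages=arr.parent_age[tips_mask],
    )


def build_regimes(rt: RichnessTree, shift_nodes, placement: str = "stem"):
    """Partition the tree: returns (list of RegimeData, regime index per node).

    Regime 0 is the root regime; regime ``i+1`` belongs to ``shift_nodes[i]``.
    The global root contributes no term in any regime (crown conditioning).
    """
    arr = _tree_arrays(rt)
    regime = _regime_of_nodes(rt, shift_nodes, placement)
    data = [_regime_data_from_mask(arr, regime == k) for k in range(len(shift_nodes) + 1)]
    return data, regime


@dataclass(frozen=True)
class ShiftModel:
    """A fitted multi-regime diversification model.

    ``shift_nodes`` are node ids in acceptance order; ``params[k]`` governs
    regime ``k`` (0 = root regime).  ``degenerate_regimes`` lists regimes that
    carried too little information to fit and kept inherited parameters.
    """

    richness_tree: RichnessTree
    shift_nodes: tuple
    params: tuple
    breakdown: LikelihoodBreakdown
    placement: str = "stem"
    degenerate_regimes: tuple = ()

    @property
    def n_shifts(self) -> int:
        return len(self.shift_nodes)

    @property
    def lnL(self) -> float:
        return self.breakdown.lnL_total

    @property
    def k(self) -> int:
        return 2 + 3 * self.n_shifts

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.lnL

    def regime_of(self):
        return _regime_of_nodes(self.richness_tree, self.shift_nodes, self.placement)

    def shift_leafsets(self):
        chrono = self.richness_tree.chronogram
        return [chrono.leafset(nid) for nid in self.shift_nodes]

    def parent_regime(self, shift_node) -> int:
        """Index of the regime governing the shift's stem surroundings."""
        pos = self.shift_nodes.index(shift_node)
        chrono = self.richness_tree.chronogram
        regime = self.regime_of()
        p = chrono.parent(shift_node)
        return int(regime[p]) if p is not None else 0

    def directions(self):
        """Per accepted shift: 'up' or 'down' (see :func:`classify_direction`)."""
        return {nid: classify_direction(self, nid) for nid in self.shift_nodes}

    def to_report(self) -> dict:
        chrono = self.richness_tree.chronogram
        return {
            "n_shifts": self.n_shifts,
            "lnL": self.lnL,
            "lnL_internal": self.breakdown.lnL_internal,
            "lnL_terminal": self.breakdown.lnL_terminal,
            "k": self.k,
            "AIC": self.aic,
            "placement": self.placement,
            "degenerate_regimes": list(self.degenerate_regimes),
            "regimes": [
                {"regime": i, "r": p.r, "eps": p.eps}
                for i, p in enumerate(self.params)
            ],
            "shifts": [
                {
                    "order": i + 1,
                    "node_id": int(nid),
                    "stem_age": chrono.age(chrono.parent(nid)) if chrono.parent(nid) is not None else None,
                    "crown_age": chrono.age(nid),
                    "n_terminals": len(chrono.leafset(nid)),
                    "leafset": sorted(chrono.leafset(nid)),
                    "direction": classify_direction(self, nid),
                }
                for i, nid in enumerate(self.shift_nodes)
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2)


def _fit_model(rt, shift_nodes, placement="stem", fixed_eps=None,
               inits=None, quick=False, refit=None):
    """Fit the regimes of a shift configuration independently (= jointly, by
    additivity).  ``refit`` restricts optimisation to the given regime
    indices; the others must have ``inits`` and keep them (their data did not
    change).  Uninformative regimes keep their ``inits`` parameters and are
    flagged degenerate."""
    data, _ = build_regimes(rt, shift_nodes, placement)
    params, degenerate = [], []
    for k, d in enumerate(data):
        init = inits[k] if inits and k < len(inits) and inits[k] is not None else None
        if refit is not None and k not in refit:
            if init is None:
                raise ValueError(f"regime {k} excluded from refit but has no parameters")
            params.append(init)
            continue
        try:
            p, _ = fit_params(d, fixed_eps=fixed_eps, init=init, quick=quick)
        except FitError:
            if init is None:
                raise
            p = init
            degenerate.append(k)
        params.append(p)
    from .bdcore import combined_loglik

    breakdown = combined_loglik(data, params)
    return ShiftModel(
        richness_tree=rt,
        shift_nodes=tuple(shift_nodes),
        params=tuple(params),
        breakdown=breakdown,
        placement=placement,
        degenerate_regimes=tuple(degenerate),
    )


def fit_homogeneous(rt: RichnessTree, fixed_eps: float | None = None) -> ShiftModel:
    """Single-regime (no shift) model with free r and eps; k = 2."""
    return _fit_model(rt, (), fixed_eps=fixed_eps)


def try_shift(model: ShiftModel, node: int, fixed_eps: float | None = None,
              quick: bool = True) -> ShiftModel | None:
    """Candidate model with one additional shift at ``node``.

    Re-optimises the regime donating branches and the new regime (the joint
    optimum, by additivity).  Returns None for infeasible candidates (already
    a shift, or the new regime carries no rate information).
    """
    if node in model.shift_nodes:
        return None
    rt = model.richness_tree
    chrono = rt.chronogram
    shift_nodes = model.shift_nodes + (node,)
    new_idx = len(shift_nodes)  # regime index of the added shift
    inits = list(model.params)
    donor = int(model.regime_of()[node]) if chrono.parent(node) is not None else 0
    inits.append(model.params[donor])
    try:
        cand = _fit_model(rt, shift_nodes, placement=model.placement,
                          fixed_eps=fixed_eps, inits=inits, quick=quick,
                          refit={donor, new_idx})
    except FitError:
        return None
    if new_idx in cand.degenerate_regimes:
        return None  # the candidate clade carries no rate information
    return cand


def default_aic_threshold(n_candidates: int, alpha: float = 0.05, df: int = 3) -> float:
    """Size-corrected acceptance threshold for the stepwise search.

    With ``m`` candidate placements per step, the best spurious AIC gain on a
    shift-free tree behaves like the maximum of ~m chi-squared(df) improvements
    minus the 2*df parameter penalty; this returns its upper ``alpha``
    quantile under independence, ``qchisq((1-alpha)^(1/m), df) - 2*df``
    (floored at the conventional 4).  Correlation between nested candidates
    makes the bound conservative.
    """
    from scipy.stats import chi2 as _chi2

    if n_candidates < 1:
        return 4.0
    q = _chi2.ppf((1.0 - alpha) ** (1.0 / n_candidates), df)
    return max(4.0, float(q) - 2.0 * df)


def _shortlist(model: ShiftModel, candidates, fixed_eps, size: int):
    """Rank candidates by a cheap lower bound on their lnL gain: fit only the
    prospective new regime, leaving the donor regime at its current
    parameters.  Exact two-regime refits are then run on the best ``size``
    candidates only."""
    rt = model.richness_tree
    arr = _tree_arrays(rt)
    regime = model.regime_of()
    scored = []
    for nid in candidates:
        if nid in model.shift_nodes:
            continue
        donor = int(regime[nid]) if rt.chronogram.parent(nid) is not None else 0
        sub = arr.subtree[nid]
        mask = np.zeros(len(arr.ids), dtype=bool)
        mask[sub] = True
        mask &= regime == donor
        if model.placement == "node":
            mask[nid] = False
        new_data = _regime_data_from_mask(arr, mask)
        try:
            _, bk = fit_params(new_data, fixed_eps=fixed_eps,
                               init=model.params[donor], quick=True)
        except FitError:
            continue
        bound_gain = bk.lnL_total - new_data.loglik(model.params[donor]).lnL_total
        scored.append((-bound_gain, nid))
    scored.sort()
    return [nid for _, nid in scored[:size]]


def stepwise_search(
    rt: RichnessTree,
    aic_threshold: float | None = None,
    max_shifts: int | None = None,
    fixed_eps: float | None = None,
    placement: str = "stem",
    shortlist_size: int = 25,
) -> list[ShiftModel]:
    """Greedy forward selection of diversification shifts.

    Returns the accepted-model sequence, starting with the homogeneous model.
    At each step every node (root excluded, current shifts excluded) is a
    candidate; a donor-fixed profile shortlists the most promising
    ``shortlist_size`` placements, which are then refitted exactly, and the
    candidate with the best AIC is accepted if it improves the current AIC by
    at least ``aic_threshold`` (default: :func:`default_aic_threshold`, which
    corrects for the number of candidate placements).  Ties break towards the
    smallest node id, so the outcome does not depend on evaluation order.
    """
    model = fit_homogeneous(rt, fixed_eps=fixed_eps)
    if model.placement != placement:
        model = replace(model, placement=placement)
    sequence = [model]
    chrono = rt.chronogram
    candidates = [nid for nid in sorted(chrono.nodes) if nid != chrono.root_id]
    if aic_threshold is None:
        aic_threshold = default_aic_threshold(len(candidates))
    elif aic_threshold <= 0:
        raise ValueError("AIC threshold must be positive")
    while max_shifts is None or model.n_shifts < max_shifts:
        short = _shortlist(model, candidates, fixed_eps, shortlist_size)
        best = None
        best_nid = None
        for nid in short:
            cand = try_shift(model, nid, fixed_eps=fixed_eps, quick=True)
            if cand is None:
                continue
            if best is None or cand.aic < best.aic - 1e-9 or (
                abs(cand.aic - best.aic) <= 1e-9 and nid < best_nid
            ):
                best, best_nid = cand, nid
        if best is None:
            break
        # polish the two regimes the accepted shift touched, full multi-start
        donor = int(model.regime_of()[best_nid]) if chrono.parent(best_nid) is not None else 0
        polished = _fit_model(rt, best.shift_nodes, placement=placement,
                              fixed_eps=fixed_eps, inits=list(best.params),
                              quick=False, refit={donor, len(best.shift_nodes)})
        if polished.lnL < best.lnL:
            polished = best
        if model.aic - polished.aic < aic_threshold:
            break
        model = polished
        sequence.append(model)
    return sequence


def classify_direction(model: ShiftModel, shift_node: int) -> str:
    """'up' if the clade's corrected richness exceeds its expectation under the
    parental regime at the clade's stem age, else 'down'."""
    from .cladesize import richness_ratio

    parent_params = model.params[model.parent_regime(shift_node)]
    rr = richness_ratio(model, shift_node, parent_params)
    return "up" if rr.ratio > 1.0 else "down"
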