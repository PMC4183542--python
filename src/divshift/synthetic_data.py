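"""Simulation of the inputs the diversification analyses consume.

Three generators cover the statistical structure the method assumes:

* :func:`simulate_bd` / :func:`simulate_with_shift` — continuous-time
  constant-rate birth-death chronograms (optionally with one lineage switching
  to a second regime at a set time), with extinct lineages pruned to yield the
  reconstructed tree;
* :func:`collapse` — conversion of a species-level chronogram into a
  higher-taxon tree: every lineage crossing a collapse age becomes a terminal
  carrying the extant richness of its descendants, which is exactly the
  "family-level tips with species counts" data shape of the analyses;
* :func:`pseudo_posterior` — an ensemble of node-age perturbations on a fixed
  topology, standing in for dated-tree samples from a Bayesian dating chain.

All randomness flows through ``numpy.random.Generator`` objects derived from
an integer seed; identical seeds give identical trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bdcore import BDParams
from .treedata import Chronogram, RichnessTable, RichnessTree, _Node

__all__ = [
    "SimulationError",
    "simulate_bd",
    "simulate_with_shift",
    "collapse",
    "pseudo_posterior",
    "simulate_collapsed_tree",
]

MAX_ATTEMPTS = 10_000
MAX_LINEAGES = 2_000_000


class SimulationError(RuntimeError):
    pass


@dataclass
class _SimNode:
    """Node of the full (extinct-inclusive) simulated tree; ages in Myr."""

    birth_age: float
    death_age: float  # 0.0 if extant at the present
    children: list = field(default_factory=list)
    extant: bool = False
    regime: int = 0


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _simulate_lineage_forest(params, start_age, rng, shift=None, n_start=1):
    """Gillespie simulation forward in time from ``n_start`` lineages at
    ``start_age`` down to the present.  Returns the list of root `_SimNode`s
    and the total extant count.

    ``shift``: optional (shift_age, BDParams); at the first event boundary
    crossing the shift age, one uniformly chosen alive lineage (and all its
    later descendants) switches regime.  Returns also the shifted node.
    """
    roots = [_SimNode(birth_age=start_age, death_age=start_age) for _ in range(n_start)]
    # one alive-list per regime; within a regime all lineages share rates, so
    # the next event needs only group sizes (O(1) per event, swap-removal)
    alive = {0: list(roots), 1: []}
    t = start_age
    n_extant = 0
    shifted_node = None
    shift_pending = shift is not None
    rates = {0: (params.lam, params.mu)}
    if shift is not None:
        rates[1] = (shift[1].lam, shift[1].mu)

    while alive[0] or alive[1]:
        group_rate = {g: len(alive[g]) * sum(rates.get(g, (0, 0))) for g in (0, 1)}
        total = group_rate[0] + group_rate[1]
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        t_next = t - wait
        if shift_pending and t_next <= shift[0] < t:
            # apply the regime switch at the shift age before the next event
            t = shift[0]
            pool = alive[0]
            idx = int(rng.integers(len(pool)))
            shifted_node = pool[idx]
            _switch_regime(shifted_node, 1)
            pool[idx] = pool[-1]
            pool.pop()
            alive[1].append(shifted_node)
            shift_pending = False
            continue
        if t_next <= 0:
            break
        t = t_next
        g = 0 if rng.random() < group_rate[0] / total else 1
        pool = alive[g]
        idx = int(rng.integers(len(pool)))
        nd = pool[idx]
        lam, mu = rates[g]
        if rng.random() < lam / (lam + mu):
            left = _SimNode(birth_age=t, death_age=t, regime=g)
            right = _SimNode(birth_age=t, death_age=t, regime=g)
            nd.children = [left, right]
            nd.death_age = t
            pool[idx] = left
            pool.append(right)
        else:
            nd.death_age = t
            pool[idx] = pool[-1]
            pool.pop()
        if len(alive[0]) + len(alive[1]) > MAX_LINEAGES:
            raise SimulationError("simulation exceeded the lineage cap")

    for pool in alive.values():
        for nd in pool:
            nd.death_age = 0.0
            nd.extant = True
            n_extant += 1
    if shift_pending:
        shifted_node = None  # no lineage was alive at the shift age
    return roots, n_extant, shifted_node


def _switch_regime(node: _SimNode, regime: int) -> None:
    stack = [node]
    while stack:
        nd = stack.pop()
        nd.regime = regime
        stack.extend(nd.children)


def _mark_survivors(root: _SimNode) -> bool:
    """Set ``extant`` on internal nodes meaning 'has extant descendants'."""
    stack, post = [root], []
    while stack:
        nd = stack.pop()
        post.append(nd)
        stack.extend(nd.children)
    for nd in reversed(post):
        if nd.children:
            nd.extant = any(c.extant for c in nd.children)
    return root.extant


def _reconstructed_chronogram(roots, labeler=None):
    """Prune extinct lineages and suppress unifurcations; return a Chronogram
    plus a map tip label -> extant _SimNode for truth bookkeeping."""
    survivors = [r for r in roots if _mark_survivors(r)]
    if not survivors:
        raise SimulationError("no extant survivors to reconstruct")
    if len(survivors) > 1:
        raise SimulationError("reconstruction requires a single surviving root")
    root = survivors[0]

    def prune(nd):
        """Return the reconstructed (age, children, sim_node) for nd's subtree."""
        while True:
            live = [c for c in nd.children if c.extant]
            if len(live) == 1:
                nd = live[0]
                continue
            break
        if not nd.children or not live:
            return (0.0, [], nd)
        return (nd.death_age, [prune(c) for c in live], nd)

    rec = prune(root)
    nodes: list[_Node] = []
    tip_sim: dict[str, _SimNode] = {}
    counter = [0]

    def emit(rec_node):
        age, children, sim = rec_node
        child_ids = [emit(c) for c in children]
        nid = len(nodes)
        label = None
        if not child_ids:
            counter[0] += 1
            label = labeler(counter[0], sim) if labeler else f"T{counter[0]:04d}"
            tip_sim[label] = sim
        nodes.append(_Node(id=nid, parent=None, children=tuple(child_ids), label=label, age=age))
        for cid in child_ids:
            nodes[cid].parent = nid
        return nid

    root_id = emit(rec)
    chrono = _canonicalise(Chronogram(nodes, root_id))
    return chrono, tip_sim


def _canonicalise(chrono: Chronogram) -> Chronogram:
    """Renumber a chronogram so node ids follow the deterministic
    label-sorted post-order convention used by the file readers."""
    minlab: dict[int, str] = {}
    for nid in chrono.postorder():
        nd = chrono.nodes[nid]
        minlab[nid] = nd.label if not nd.children else min(minlab[c] for c in nd.children)

    nodes: list[_Node] = []

    def build(old_id):
        nd = chrono.nodes[old_id]
        child_ids = [build(c) for c in sorted(nd.children, key=lambda c: minlab[c])]
        new_id = len(nodes)
        nodes.append(_Node(id=new_id, parent=None, children=tuple(child_ids),
                           label=nd.label, age=nd.age))
        for cid in child_ids:
            nodes[cid].parent = new_id
        return new_id

    import sys

    limit = sys.getrecursionlimit()
    if len(chrono.nodes) + 100 > limit:
        sys.setrecursionlimit(len(chrono.nodes) + 1000)
    try:
        root_id = build(chrono.root_id)
    finally:
        sys.setrecursionlimit(limit)
    out = Chronogram(nodes, root_id)
    out.validate()
    return out


def _simulate_to_ntips(params, ntips, rng, max_attempts=MAX_ATTEMPTS):
    """Forward-time Gillespie from two crown lineages until the extant count
    first reaches ``ntips``; the stopping moment becomes the present (simple
    first-passage sampling).  Resimulates on extinction."""
    lam, mu = params.lam, params.mu
    for _ in range(max_attempts):
        root = _SimNode(birth_age=0.0, death_age=0.0)
        left = _SimNode(birth_age=0.0, death_age=0.0)
        right = _SimNode(birth_age=0.0, death_age=0.0)
        root.children = [left, right]
        alive = [left, right]
        t = 0.0
        events = []  # (node, forward event time)
        events.append((root, 0.0))
        ok = False
        while alive:
            if len(alive) >= ntips:
                ok = True
                break
            total = len(alive) * (lam + mu)
            t += rng.exponential(1.0 / total)
            idx = int(rng.integers(len(alive)))
            nd = alive[idx]
            if rng.random() < lam / (lam + mu):
                a = _SimNode(birth_age=t, death_age=t)
                b = _SimNode(birth_age=t, death_age=t)
                nd.children = [a, b]
                events.append((nd, t))
                alive[idx] = a
                alive.append(b)
            else:
                events.append((nd, t))
                alive[idx] = alive[-1]
                alive.pop()
        if not ok:
            continue
        # rewrite forward event times as ages before the stopping moment
        fwd = {id(nd): ft for nd, ft in events}
        alive_set = {id(x) for x in alive}
        todo = [root]
        while todo:
            nd = todo.pop()
            nd.birth_age = t - nd.birth_age
            if id(nd) in alive_set:
                nd.death_age = 0.0
                nd.extant = True
            else:
                nd.death_age = t - fwd[id(nd)]
                nd.extant = False
            todo.extend(nd.children)
        return [root], len(alive)
    raise SimulationError(f"no surviving tree reached {ntips} tips in {max_attempts} attempts")


def simulate_bd(
    params: BDParams,
    crown_age: float | None = None,
    stem_age: float | None = None,
    ntips: int | None = None,
    seed=None,
    condition: str = "auto",
    max_attempts: int = MAX_ATTEMPTS,
):
    """Simulate a reconstructed birth-death chronogram.

    Exactly one stopping rule must be given: ``crown_age`` (two lineages from
    the crown split), ``stem_age`` (a single stem lineage), or ``ntips``
    (crown simulation stopped when the extant count first reaches ``ntips``).
    ``condition`` is ``"auto"`` (crown trees conditioned on both crown
    lineages surviving, stem trees on >= 1 survivor, by resimulation),
    or ``"none"`` (a stem simulation may return ``None`` if the clade dies).

    Returns ``(chronogram_or_None, n_extant)``; ``chronogram`` is None only
    under ``condition="none"`` with no (or a single) survivor.
    """
    if sum(x is not None for x in (crown_age, stem_age, ntips)) != 1:
        raise ValueError("give exactly one of crown_age, stem_age or ntips")
    rng = _rng(seed)
    if ntips is not None:
        roots, n_extant = _simulate_to_ntips(params, ntips, rng, max_attempts)
        chrono, _ = _reconstructed_chronogram(roots)
        return chrono, n_extant
    start = crown_age if crown_age is not None else stem_age
    n_start = 2 if crown_age is not None else 1
    for attempt in range(1, max_attempts + 1):
        roots, n_extant, _ = _simulate_lineage_forest(params, start, rng, n_start=n_start)
        if crown_age is not None:
            ok = all(_mark_survivors(r) for r in roots)
        else:
            ok = _mark_survivors(roots[0])
        if condition == "none":
            if not ok or n_extant < 2:
                return None, n_extant
            chrono, _ = _reconstructed_chronogram(_as_single_root(roots, start))
            return chrono, n_extant
        if ok and n_extant >= 2:
            chrono, _ = _reconstructed_chronogram(_as_single_root(roots, start))
            return chrono, n_extant
    raise SimulationError(
        f"no surviving tree in {max_attempts} attempts (r={params.r}, eps={params.eps}, t={start})"
    )


def _as_single_root(roots, start_age):
    if len(roots) == 1:
        return roots
    joint = _SimNode(birth_age=start_age, death_age=start_age)
    joint.children = list(roots)
    return [joint]


def simulate_with_shift(
    root_params: BDParams,
    shift_params: BDParams,
    shift_age: float,
    crown_age: float,
    seed=None,
    max_attempts: int = MAX_ATTEMPTS,
):
    """Simulate a crown tree in which one lineage alive at ``shift_age``
    switches to ``shift_params`` (its descendants inherit the new regime).

    Conditioned, by resimulation, on: both crown lineages surviving, a lineage
    being alive at the shift age, and the shifted lineage leaving >= 2 extant
    species (so the true shift clade exists in the reconstructed tree).

    Returns ``(chronogram, true_shift_leafset, n_extant)``.
    """
    if not (0 < shift_age < crown_age):
        raise ValueError("shift age must fall inside the crown age interval")
    rng = _rng(seed)
    for attempt in range(1, max_attempts + 1):
        roots, n_extant, shifted = _simulate_lineage_forest(
            root_params, crown_age, rng, shift=(shift_age, shift_params), n_start=2
        )
        if shifted is None or n_extant < 2:
            continue
        if not all(_mark_survivors(r) for r in roots):
            continue
        if not shifted.extant:
            continue
        chrono, tip_sim = _reconstructed_chronogram(_as_single_root(roots, crown_age))
        # the true shift clade: extant tips descending from the shifted lineage
        shifted_tips = set()
        stack = [shifted]
        while stack:
            nd = stack.pop()
            if not nd.children and nd.extant:
                shifted_tips.add(id(nd))
            stack.extend(nd.children)
        leafset = frozenset(
            label for label, sim in tip_sim.items() if id(sim) in shifted_tips
        )
        if len(leafset) < 2:
            continue
        return chrono, leafset, n_extant
    raise SimulationError(f"no usable shifted tree in {max_attempts} attempts")


def collapse(chronogram: Chronogram, collapse_age: float):
    """Collapse a species-level chronogram into a higher-taxon RichnessTree.

    Terminals of the collapsed tree are the lineages crossing ``collapse_age``
    (branches spanning it, or tips younger than it hanging from older parents);
    each carries the number of extant species it subtends.  Structure older
    than the collapse age is kept untouched.  Labels are assigned
    deterministically (T0001... in the canonical node order).

    Returns ``(richness_tree, membership)`` where ``membership`` maps each new
    terminal label to the frozenset of original species labels inside it.
    """
    if not (0 < collapse_age < chronogram.root_age):
        raise ValueError("collapse age must lie strictly inside the tree depth")

    nodes: list[_Node] = []
    counts: dict[str, int] = {}
    membership: dict[str, frozenset] = {}
    counter = [0]

    def build(nid):
        nd = chronogram.nodes[nid]
        if nd.children and nd.age > collapse_age:
            child_ids = [build(c) for c in nd.children]
            new_id = len(nodes)
            nodes.append(_Node(id=new_id, parent=None, children=tuple(child_ids),
                               label=None, age=nd.age))
            for cid in child_ids:
                nodes[cid].parent = new_id
            return new_id
        # lineage crossing the collapse age -> one terminal
        counter[0] += 1
        label = f"T{counter[0]:04d}"
        tips = chronogram.leafset(nid)
        counts[label] = len(tips)
        membership[label] = tips
        new_id = len(nodes)
        nodes.append(_Node(id=new_id, parent=None, children=(), label=label, age=0.0))
        return new_id

    root_id = build(chronogram.root_id)
    if not nodes[root_id].children:
        raise ValueError("collapse age leaves a single terminal; no tree structure remains")
    collapsed = _canonicalise(Chronogram(nodes, root_id))
    rt = RichnessTree(collapsed, RichnessTable(counts))
    return rt, membership


def simulate_collapsed_tree(
    params: BDParams,
    crown_age: float,
    collapse_age: float,
    seed=None,
    min_terminals: int = 3,
    max_attempts: int = MAX_ATTEMPTS,
):
    """Convenience pipeline: crown birth-death simulation + higher-taxon
    collapse, resimulating until the collapsed tree has at least
    ``min_terminals`` terminals.  Returns a RichnessTree."""
    rng = _rng(seed)
    for _ in range(max_attempts):
        chrono, _ = simulate_bd(params, crown_age=crown_age, seed=rng)
        try:
            rt, _ = collapse(chrono, collapse_age)
        except ValueError:
            continue
        if rt.n_terminals >= min_terminals:
            return rt
    raise SimulationError("could not produce a collapsed tree of the requested size")


def simulate_taxon_tree(
    params: BDParams,
    crown_age: float,
    family_prob: float = 0.5,
    seed=None,
    min_terminals: int = 4,
    max_attempts: int = MAX_ATTEMPTS,
) -> RichnessTree:
    """Exact sampler of the higher-taxon data model the likelihood assumes.

    The backbone follows the reconstructed birth-death process (a pure birth
    with per-lineage rate ``lambda * P_s(u)`` at age ``u``, simulated by
    thinning).  At each backbone split the new lineage becomes a terminal
    higher taxon with probability ``family_prob`` — an exogenous taxonomic
    decision, independent of the realised diversification — in which case its
    extant richness is drawn from the survival-conditioned geometric
    clade-size distribution at its stem age; otherwise it stays on the
    backbone.  Backbone lineages reaching the present are monotypic terminals
    (n = 1).  Because terminal status is assigned at birth, the combined
    phylogenetic + taxonomic likelihood is the exact density of the output
    (up to the constant ``family_prob`` factors), which makes this the right
    generator for parameter-recovery oracles.  Contrast with :func:`collapse`,
    whose age-threshold terminals condition on the absence of older splits.
    """
    if not (0.0 <= family_prob < 1.0):
        raise ValueError("family_prob must be in [0, 1)")
    rng = _rng(seed)
    lam = params.lam
    for _ in range(max_attempts):
        # each backbone lineage: (birth_age, node_record)
        nodes: list[_Node] = []
        counts: dict[str, int] = {}
        counter = [0]

        def new_tip(stem_age, richness):
            counter[0] += 1
            label = f"T{counter[0]:04d}"
            counts[label] = richness
            nodes.append(_Node(id=len(nodes), parent=None, children=(),
                               label=label, age=0.0))
            return nodes[-1].id

        from .bdcore import transients

        def draw_richness(stem_age):
            beta = transients(stem_age, params).beta
            return int(rng.geometric(1.0 - beta)) if beta > 0 else 1

        def grow(birth_age):
            """Simulate one backbone lineage from birth_age to 0; returns its
            reconstructed subtree node id."""
            t = birth_age
            while True:
                t -= rng.exponential(1.0 / lam)
                if t <= 0:
                    return new_tip(birth_age, 1)
                if rng.random() >= transients(t, params).p_survival:
                    continue  # thinning: proposed split rejected
                # reconstructed split at age t
                if rng.random() < family_prob:
                    child = new_tip(t, draw_richness(t))
                else:
                    child = grow(t)
                # focal lineage continues below t
                cont = grow(t)
                nid = len(nodes)
                nodes.append(_Node(id=nid, parent=None, children=(child, cont),
                                   label=None, age=t))
                nodes[child].parent = nid
                nodes[cont].parent = nid
                return nid

        import sys

        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(100_000)
        try:
            left = grow(crown_age)
            right = grow(crown_age)
        finally:
            sys.setrecursionlimit(limit)
        root_id = len(nodes)
        nodes.append(_Node(id=root_id, parent=None, children=(left, right),
                           label=None, age=crown_age))
        nodes[left].parent = root_id
        nodes[right].parent = root_id
        if len(counts) < min_terminals:
            continue
        chrono = _canonicalise(Chronogram(nodes, root_id))
        return RichnessTree(chrono, RichnessTable(counts))
    raise SimulationError("could not produce a taxon tree of the requested size")


def pseudo_posterior(
    chronogram: Chronogram,
    n_samples: int,
    jitter_scale: float,
    seed=None,
) -> list[Chronogram]:
    """Ensemble of dated trees on a fixed topology: each sample multiplies every
    internal node age by an independent lognormal factor ``exp(sigma * Z)``
    (median-unbiased), then restores ``parent_age > child_age`` top-down by
    shrinking violating children back to their original fraction of the parent
    age.  ``jitter_scale = 0`` returns copies identical to the input."""
    if jitter_scale < 0:
        raise ValueError("jitter scale must be >= 0")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = _rng(seed)
    internal = [nid for nid in chronogram.internal_ids]
    samples = []
    preorder = [nid for nid in reversed(chronogram.postorder())]
    for _ in range(n_samples):
        factors = np.exp(jitter_scale * rng.standard_normal(len(internal)))
        new_ages = {nid: chronogram.age(nid) * f for nid, f in zip(internal, factors)}
        for nid in preorder:
            if nid not in new_ages:
                continue
            pid = chronogram.parent(nid)
            if pid is None:
                continue
            pnew = new_ages.get(pid, chronogram.age(pid))
            if new_ages[nid] >= pnew:
                ratio = chronogram.age(nid) / chronogram.age(pid)
                new_ages[nid] = pnew * ratio
        samples.append(chronogram.with_ages(new_ages))
    return samples
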