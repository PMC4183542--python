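"""Single-shift placement comparisons by likelihood-ratio test.

The procedure mirrors the classic two-rate analysis on a dated higher-taxon
tree: turnover ``eps`` is first estimated once under the homogeneous
(no-shift) model and then held fixed; for each named candidate clade a
two-regime model is fitted in which only the net diversification rates are
free — ``r_root`` for the partition containing the root and ``r_clade`` for
the focal clade (stem placement).  Candidate models are compared with
likelihood-ratio tests; degrees of freedom are supplied by the caller
(conventionally 3 against the uniform model, 1 between alternative
placements).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2 as _chi2

from .bdcore import FitError
from .shiftsearch import _fit_model, fit_homogeneous
from .treedata import RichnessTree

__all__ = [
    "PlacementResult",
    "single_shift_fit",
    "lrt",
    "placement_scan",
    "parse_candidate_file",
]


@dataclass(frozen=True)
class PlacementResult:
    """One candidate single-shift model."""

    name: str
    node_id: int
    leafset: frozenset
    lnL: float
    r_root: float
    r_clade: float
    eps: float
    error: str | None = None


def single_shift_fit(rt: RichnessTree, node: int, eps_fixed: float,
                     name: str | None = None, placement: str = "stem") -> PlacementResult:
    """Two-regime model with a shift at ``node``; both regimes share the fixed
    turnover and fit only their net rates."""
    chrono = rt.chronogram
    if node == chrono.root_id:
        raise ValueError("a shift at the root leaves no root-side partition")
    model = _fit_model(rt, (node,), placement=placement, fixed_eps=eps_fixed)
    return PlacementResult(
        name=name or f"node{node}",
        node_id=node,
        leafset=chrono.leafset(node),
        lnL=model.lnL,
        r_root=model.params[0].r,
        r_clade=model.params[1].r,
        eps=eps_fixed,
    )


def lrt(lnL_better: float, lnL_worse: float, df: int = 1):
    """Likelihood-ratio test: ``chi2 = 2 (lnL_better - lnL_worse)`` (clipped at
    zero) against the chi-squared upper tail with ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    chi2 = max(0.0, 2.0 * (lnL_better - lnL_worse))
    p = float(_chi2.sf(chi2, df))
    return chi2, p


def placement_scan(
    rt: RichnessTree,
    candidates: dict,
    eps_fixed: float | None = None,
    df_vs_best: int = 1,
    df_vs_uniform: int = 3,
) -> pd.DataFrame:
    """Fit a single-shift model at every named candidate clade and rank them.

    ``candidates`` maps a clade name to an iterable of terminal labels; each
    clade is resolved to the MRCA of its labels.  ``eps_fixed`` defaults to
    the homogeneous-model estimate.  The returned table is sorted by lnL
    (best first) and carries, per row, the LRT against the uniform model
    (``df_vs_uniform``) and against the best placement (``df_vs_best``);
    unresolvable candidates appear with an error status.
    """
    uniform = fit_homogeneous(rt)
    if eps_fixed is None:
        eps_fixed = uniform.params[0].eps
    chrono = rt.chronogram
    results: list[PlacementResult] = []
    for name, labels in candidates.items():
        try:
            node = chrono.mrca(labels)
            if node == chrono.root_id:
                raise ValueError("candidate resolves to the whole tree")
            results.append(single_shift_fit(rt, node, eps_fixed, name=name))
        except (KeyError, ValueError, FitError) as err:
            results.append(PlacementResult(name=name, node_id=-1, leafset=frozenset(),
                                           lnL=float("nan"), r_root=float("nan"),
                                           r_clade=float("nan"), eps=eps_fixed,
                                           error=str(err)))
    ok = [r for r in results if r.error is None]
    ok.sort(key=lambda r: -r.lnL)
    best_lnL = ok[0].lnL if ok else float("nan")
    rows = []
    for rank, r in enumerate(ok + [r for r in results if r.error is not None]):
        if r.error is None:
            chi2_u, p_u = lrt(r.lnL, uniform.lnL, df_vs_uniform)
            chi2_b, p_b = lrt(best_lnL, r.lnL, df_vs_best)
            rows.append({
                "name": r.name, "rank": rank + 1, "lnL": r.lnL,
                "r_root": r.r_root, "r_clade": r.r_clade, "eps": r.eps,
                "n_terminals": len(r.leafset),
                "chi2_vs_uniform": chi2_u, "p_vs_uniform": p_u,
                "chi2_vs_best": chi2_b, "p_vs_best": p_b,
                "is_best": rank == 0, "is_second_best": rank == 1,
                "error": None,
            })
        else:
            rows.append({"name": r.name, "rank": None, "lnL": None, "r_root": None,
                         "r_clade": None, "eps": r.eps, "n_terminals": 0,
                         "chi2_vs_uniform": None, "p_vs_uniform": None,
                         "chi2_vs_best": None, "p_vs_best": None,
                         "is_best": False, "is_second_best": False, "error": r.error})
    df = pd.DataFrame(rows)
    df.attrs["uniform_lnL"] = uniform.lnL
    df.attrs["uniform_r"] = uniform.params[0].r
    df.attrs["eps_fixed"] = eps_fixed
    return df


def parse_candidate_file(path) -> dict:
    """Read a candidate-clade file: one ``name: label1, label2, ...`` per line
    (``#`` comments allowed).  Returns {name: [labels]}."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"malformed candidate line: {line!r}")
            name, rest = line.split(":", 1)
            labels = [tok.strip() for tok in rest.split(",") if tok.strip()]
            if not labels:
                raise ValueError(f"candidate {name.strip()!r} lists no labels")
            out[name.strip()] = labels
    return out
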