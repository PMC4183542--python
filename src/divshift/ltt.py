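"""Lineage-through-time curves with ensemble envelopes.

An LTT curve counts reconstructed lineages of a clade as a step function of
age: 1 lineage on the stem, 2 from the crown split, +1 at every subsequent
split, reaching the number of terminals at the present.  Envelopes evaluate
the curves of a fixed-topology ensemble on a common age grid and take
quantiles across trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treedata import Chronogram

__all__ = ["LTTCurve", "ltt_curve", "ltt_envelope", "yule_slope"]


@dataclass(frozen=True)
class LTTCurve:
    """Step function of reconstructed lineage count vs age for one clade."""

    leafset: frozenset
    breakpoints: np.ndarray  # split ages, decreasing (crown age first)
    counts: np.ndarray  # lineage count from each breakpoint to the next

    @property
    def crown_age(self) -> float:
        return float(self.breakpoints[0])

    @property
    def present_count(self) -> int:
        return int(self.counts[-1])

    def at(self, ages) -> np.ndarray:
        """Lineage count at the given ages (0 before the crown split's stem)."""
        ages = np.asarray(ages, dtype=float)
        # counts[i] applies on [breakpoints[i+1], breakpoints[i]); vectorise
        # by counting how many breakpoints are strictly older than each age
        idx = np.searchsorted(-self.breakpoints, -ages, side="right") - 1
        out = np.where(idx >= 0, self.counts[np.clip(idx, 0, None)], 1.0)
        return np.where(ages > self.crown_age, 1.0, out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_ma": self.breakpoints, "lineages": self.counts})


def _clade_node(chronogram: Chronogram, clade) -> int:
    if isinstance(clade, (int, np.integer)):
        return int(clade)
    node = chronogram.mrca(clade)
    if chronogram.leafset(node) != frozenset(clade):
        extra = sorted(chronogram.leafset(node) - frozenset(clade))
        raise ValueError(
            f"labels do not form a clade; their MRCA also contains e.g. {extra[:5]}"
        )
    return node


def ltt_curve(chronogram: Chronogram, clade=None) -> LTTCurve:
    """LTT curve of a clade (node id, or an iterable of terminal labels that
    must form an exact clade; default the whole tree)."""
    node = chronogram.root_id if clade is None else _clade_node(chronogram, clade)
    ages = sorted(
        (chronogram.age(nid) for nid in chronogram.subtree_ids(node)
         if chronogram.children(nid)),
        reverse=True,
    )
    if not ages:
        raise ValueError("clade has a single terminal; no LTT curve")
    counts = np.arange(2, len(ages) + 2, dtype=float)
    return LTTCurve(
        leafset=chronogram.leafset(node),
        breakpoints=np.array(ages),
        counts=counts,
    )


def ltt_envelope(
    trees: list[Chronogram],
    clade=None,
    n_grid: int = 200,
    quantiles=(0.025, 0.5, 0.975),
) -> pd.DataFrame:
    """Quantile band of lineage counts across a fixed-topology ensemble.

    The grid spans the oldest crown age in the ensemble down to the present;
    returns a DataFrame with ``age_ma`` and one ``q<level>`` column per
    requested quantile.
    """
    if not trees:
        raise ValueError("empty ensemble")
    curves = [ltt_curve(t, clade) for t in trees]
    top = max(c.crown_age for c in curves)
    grid = np.linspace(top, 0.0, n_grid)
    values = np.vstack([c.at(grid) for c in curves])
    out = {"age_ma": grid}
    for q in quantiles:
        out[f"q{q:g}".replace("0.", "")] = np.quantile(values, q, axis=0)
    return pd.DataFrame(out)


def yule_slope(curve: LTTCurve) -> float:
    """Least-squares slope of log lineage count against elapsed time — for a
    pure-birth clade this estimates the net diversification rate."""
    t = curve.crown_age - curve.breakpoints  # elapsed time since crown
    y = np.log(curve.counts)
    A = np.vstack([t, np.ones_like(t)]).T
    slope, _ = np.linalg.lstsq(A, y, rcond=None)[0]
    return float(slope)
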