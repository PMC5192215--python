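"""Branch-painted trees: a discrete selective regime evolving along a phylogeny.

A :class:`RegimeHistory` is a phylogeny whose every branch carries an ordered
list of ``(state, start, end)`` segments in branch-local time (0 at the
parent node).  Histories come from two places — the forward simulator in
:mod:`phyloenv.synthetic` and the conditional sampler in
:mod:`phyloenv.regimes` — and both must satisfy the same invariants: segments
tile each branch exactly and the state is continuous across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = ["RegimeHistory", "summarize_transitions", "TransitionSummary"]


@dataclass
class RegimeHistory:
    tree: Phylogeny
    state_labels: list[str]
    # per node: (n_segments, 3) float array [state_id, t_start, t_end],
    # branch-local times; the root's entry is a single zero-length segment
    # holding the root state.
    segments: list[np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.segments) != self.tree.n_nodes:
            raise ValueError("one segment list per node required")

    def validate(self, atol: float = 1e-9) -> None:
        """Check tiling and node-to-node state continuity (hard invariants)."""
        for v in range(self.tree.n_nodes):
            seg = self.segments[v]
            b = self.tree.branch_lengths[v]
            if v == self.tree.root:
                continue
            if abs(seg[0, 1]) > atol or abs(seg[-1, 2] - b) > atol:
                raise ValueError(f"segments on node {v} do not tile its branch")
            if np.any(seg[1:, 1] - seg[:-1, 2] > atol):
                raise ValueError(f"gap between segments on node {v}")
            p = self.tree.parent[v]
            if int(seg[0, 0]) != self.node_state(p):
                raise ValueError(f"state discontinuity at node {p} -> {v}")

    def node_state(self, v: int) -> int:
        """State id at the *end* of node v's branch (at the node itself)."""
        return int(self.segments[v][-1, 0])

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def tip_states(self) -> pd.Series:
        """Observed state label per tip, keyed by tip label."""
        vals = [self.state_labels[self.node_state(i)] for i in range(self.tree.n_tips)]
        return pd.Series(vals, index=list(self.tree.tip_labels), name="state")

    def count_transitions(self) -> np.ndarray:
        """Ordered (from, to) change counts over the whole tree."""
        k = self.n_states
        counts = np.zeros((k, k), dtype=np.int64)
        for v in range(self.tree.n_nodes):
            seg = self.segments[v]
            for a, b in zip(seg[:-1, 0], seg[1:, 0]):
                counts[int(a), int(b)] += 1
        return counts

    def time_in_state(self) -> np.ndarray:
        """Total branch time spent in each state."""
        out = np.zeros(self.n_states)
        for seg in self.segments:
            np.add.at(out, seg[:, 0].astype(int), seg[:, 2] - seg[:, 1])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flat table (node, state, t_start, t_end) — the on-disk format."""
        rows = []
        for v, seg in enumerate(self.segments):
            for s, t0, t1 in seg:
                rows.append((v, self.state_labels[int(s)], t0, t1))
        return pd.DataFrame(rows, columns=["node", "state", "t_start", "t_end"])

    @classmethod
    def from_frame(
        cls, tree: Phylogeny, frame: pd.DataFrame, state_labels: list[str]
    ) -> "RegimeHistory":
        idx = {s: i for i, s in enumerate(state_labels)}
        segs: list[np.ndarray] = [np.empty((0, 3))] * tree.n_nodes
        for v, grp in frame.groupby("node"):
            grp = grp.sort_values("t_start")
            segs[int(v)] = np.column_stack(
                [grp["state"].map(idx).to_numpy(float), grp["t_start"], grp["t_end"]]
            )
        return cls(tree, list(state_labels), segs)


@dataclass
class TransitionSummary:
    """Median and 2.5/97.5% quantiles of ordered-pair transition counts
    across a collection of sampled histories."""

    state_labels: list[str]
    median: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    n_maps: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.state_labels)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append(
                    (
                        self.state_labels[i],
                        self.state_labels[j],
                        self.median[i, j],
                        self.q025[i, j],
                        self.q975[i, j],
                    )
                )
        return pd.DataFrame(rows, columns=["from", "to", "median", "q2.5", "q97.5"])


def summarize_transitions(maps: list[RegimeHistory]) -> TransitionSummary:
    """Per ordered state pair: median and 2.5/97.5 percentiles (linear
    interpolation) of the change count across maps."""
    if not maps:
        raise ValueError("need at least one map")
    labels = maps[0].state_labels
    counts = np.stack([m.count_transitions() for m in maps])  # (maps, k, k)
    return TransitionSummary(
        state_labels=list(labels),
        median=np.median(counts, axis=0),
        q025=np.percentile(counts, 2.5, axis=0),
        q975=np.percentile(counts, 97.5, axis=0),
        n_maps=len(maps),
    )
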