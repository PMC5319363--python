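"""Regime paintings: assignment of a discrete niche state to every
branch segment of a dated tree.

A painting stores, for every non-root node, the ordered list of
``(duration_My, state)`` segments along the branch from its parent down
to it, plus the state at the root.  Segments tile each branch exactly;
the last segment of a tip branch carries the observed tip state.
Paintings come from a marginal ancestral-state reconstruction (one
state per branch, no mid-branch change) or from stochastic character
maps (mid-branch changes allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import DatedTree, Node

__all__ = ["RegimePaint"]


@dataclass
class RegimePaint:
    """Per-branch segment painting of a discrete character."""

    tree: DatedTree
    #: node.index -> [(duration, state), ...] ordered parent -> child
    segments: dict
    root_state: str
    states: tuple
    source: str = "marginal-ASR"  # or "stochastic-map"

    def __post_init__(self):
        for node in self.tree.postorder:
            if node.parent is None:
                continue
            segs = self.segments.get(node.index)
            if segs is None:
                raise ValueError(f"branch above node index {node.index} unpainted")
            total = sum(d for d, _ in segs)
            if not np.isclose(total, node.length, rtol=1e-6, atol=1e-9):
                raise ValueError(
                    f"segments above node {node.index} sum to {total:g}, "
                    f"branch length is {node.length:g}"
                )
            for _, s in segs:
                if s not in self.states:
                    raise ValueError(f"unknown state {s!r}")

    def node_state(self, node: Node) -> str:
        """State at the bottom (child end) of the node's branch."""
        if node.parent is None:
            return self.root_state
        return self.segments[node.index][-1][1]

    def tip_states(self) -> dict:
        return {t.name: self.node_state(t) for t in self.tree.tips}

    def observed_states(self) -> tuple:
        """States appearing anywhere in the painting, in declared order."""
        seen = {self.root_state}
        for segs in self.segments.values():
            seen.update(s for _, s in segs)
        return tuple(s for s in self.states if s in seen)

    def n_changes(self) -> int:
        changes = 0
        for node in self.tree.preorder():
            if node.parent is None:
                continue
            prev = self.node_state(node.parent)
            for _, s in self.segments[node.index]:
                if s != prev:
                    changes += 1
                prev = s
        return changes

    def time_in_states(self) -> dict:
        out = {s: 0.0 for s in self.states}
        for segs in self.segments.values():
            for d, s in segs:
                out[s] += d
        return out

    @classmethod
    def uniform(cls, tree: DatedTree, state: str, states: tuple | None = None) -> "RegimePaint":
        """Single-regime painting (every branch in one state)."""
        states = states or (state,)
        segs = {
            n.index: [(n.length, state)]
            for n in tree.postorder
            if n.parent is not None
        }
        return cls(tree, segs, state, tuple(states), source="uniform")

    @classmethod
    def from_node_states(
        cls, tree: DatedTree, node_states: dict, states: tuple,
        source: str = "marginal-ASR",
    ) -> "RegimePaint":
        """Paint each branch with its *parent* node's state (no mid-branch
        change).  ``node_states`` maps node.index -> state."""
        segs = {}
        for n in tree.postorder:
            if n.parent is None:
                continue
            segs[n.index] = [(n.length, node_states[n.parent.index])]
        # tip branches must end in the tip's own state: split at midpoint
        # when parent and tip states disagree
        for tip in tree.tips:
            parent_state = node_states[tip.parent.index]
            tip_state = node_states[tip.index]
            if tip_state != parent_state and tip.length > 0:
                half = tip.length / 2.0
                segs[tip.index] = [(half, parent_state), (half, tip_state)]
        return cls(tree, segs, node_states[tree.root.index], states, source=source)
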