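"""Phage-bacteria infection networks (PBINs) and Expected Importance.

A PBIN is the directed bipartite network obtained from a binary host-range
matrix: one source node per phage, one target node per bacterium, and an
edge phage -> bacterium for every lytic interaction.

Each node carries a degree-based score called Expected Importance (EI):

* phages:     ``EI_p = 100 * out_d / |B|`` — the percentage of bacterial
  strains the phage lyses.  Broad-host-range (generalist) phages score
  high and are the natural first picks for a cocktail.
* bacteria:   ``EI_b = -100 * (1 - in_d / |P|)`` — zero for a strain lysed
  by every phage, -100 for a fully resistant strain.  Strains lysed by few
  phages score strongly negative and are the problematic targets.

The opposite signs of the two scores separate source and target nodes when
the network is rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

from .io import HostRangeMatrix

__all__ = ["PBIN", "build_pbin", "ei_phage", "ei_bacterium", "network_descriptors"]


def ei_phage(out_d: int, n_bacteria: int) -> float:
    """Expected Importance of a phage: percent of bacteria it lyses.

    Ranges from 0 (infects nothing) to 100 (infects every strain).
    """
    if n_bacteria < 1:
        raise ValueError("n_bacteria must be >= 1")
    if not 0 <= out_d <= n_bacteria:
        raise ValueError(f"out-degree {out_d} outside [0, {n_bacteria}]")
    return 100.0 * out_d / n_bacteria

def ei_bacterium(in_d: int, n_phages: int) -> float:
    """Expected Importance of a bacterium, in [-100, 0].

    ``-100 * (1 - in_d/|P|)``: -100 for a strain resistant to every phage,
    0 for one lysed by all of them.  More negative means fewer phage
    options, i.e. a more problematic target strain.
    """
    if n_phages < 1:
        raise ValueError("n_phages must be >= 1")
    if not 0 <= in_d <= n_phages:
        raise ValueError(f"in-degree {in_d} outside [0, {n_phages}]")
    return -100.0 * (1.0 - in_d / n_phages)


@dataclass(frozen=True)
class PBIN:
    """Directed bipartite phage-bacteria infection network."""

    matrix: HostRangeMatrix
    out_degree: np.ndarray  # per phage: number of bacteria lysed
    in_degree: np.ndarray   # per bacterium: number of lysing phages
    ei_phages: np.ndarray   # per phage, percent in [0, 100]
    ei_bacteria: np.ndarray  # per bacterium, percent in [-100, 0]
    graph: nx.DiGraph = field(repr=False)

    @property
    def bacteria_ids(self) -> tuple[str, ...]:
        return self.matrix.bacteria_ids

    @property
    def phage_ids(self) -> tuple[str, ...]:
        return self.matrix.phage_ids

    @property
    def n_bacteria(self) -> int:
        return self.matrix.n_bacteria

    @property
    def n_phages(self) -> int:
        return self.matrix.n_phages

    @property
    def n_nodes(self) -> int:
        return self.n_bacteria + self.n_phages

    @property
    def n_interactions(self) -> int:
        return self.matrix.n_interactions

    @property
    def fill(self) -> float:
        """Fraction of realized phage-host interactions, in [0, 1]."""
        return self.n_interactions / (self.n_bacteria * self.n_phages)

    @property
    def susceptible_bacteria(self) -> tuple[str, ...]:
        """Strains lysed by at least one phage."""
        return tuple(
            b for b, d in zip(self.bacteria_ids, self.in_degree) if d >= 1
        )

    @property
    def resistant_bacteria(self) -> tuple[str, ...]:
        """Strains with in-degree 0; they sit outside any cocktail network."""
        return tuple(
            b for b, d in zip(self.bacteria_ids, self.in_degree) if d == 0
        )

    @property
    def inert_phages(self) -> tuple[str, ...]:
        """Phages with out-degree 0; kept in the network, ignored by search."""
        return tuple(p for p, d in zip(self.phage_ids, self.out_degree) if d == 0)

    def host_set(self, phage_id: str) -> frozenset[str]:
        """The set of strains a phage lyses (its host range)."""
        j = self.phage_ids.index(phage_id)
        mask = self.matrix.binary[:, j] == 1
        return frozenset(b for b, m in zip(self.bacteria_ids, mask) if m)


def build_pbin(matrix: HostRangeMatrix) -> PBIN:
    """Build the directed infection network for a host-range matrix.

    Non-infecting phages and resistant bacteria are kept as isolated
    nodes: they are part of the experimental dataset and appear in
    network renderings, even though cocktail search ignores them.
    """
    binary = matrix.binary
    out_d = binary.sum(axis=0).astype(int)  # per phage (column)
    in_d = binary.sum(axis=1).astype(int)   # per bacterium (row)
    n_b, n_p = matrix.n_bacteria, matrix.n_phages
    ei_p = np.array([ei_phage(d, n_b) for d in out_d])
    ei_b = np.array([ei_bacterium(d, n_p) for d in in_d])

    graph = nx.DiGraph()
    for j, phage in enumerate(matrix.phage_ids):
        graph.add_node(phage, bipartite="phage", ei=ei_p[j], out_degree=int(out_d[j]))
    for i, bact in enumerate(matrix.bacteria_ids):
        graph.add_node(bact, bipartite="bacterium", ei=ei_b[i], in_degree=int(in_d[i]))
    rows, cols = np.nonzero(binary)
    graph.add_edges_from(
        (matrix.phage_ids[j], matrix.bacteria_ids[i]) for i, j in zip(rows, cols)
    )
    return PBIN(matrix, out_d, in_d, ei_p, ei_b, graph)


def network_descriptors(pbin: PBIN) -> dict[str, Any]:
    """Summary record for a PBIN: size, symmetry, fill, susceptibility.

    Symmetry is reported as a three-way category (``more_bacteria``,
    ``square``, ``more_phages``) because the distinction that matters for
    network complexity is square versus non-square.
    """
    n_b, n_p = pbin.n_bacteria, pbin.n_phages
    symmetry = (
        "more_bacteria" if n_b > n_p else "square" if n_b == n_p else "more_phages"
    )
    return {
        "n_bacteria": n_b,
        "n_phages": n_p,
        "n_nodes": pbin.n_nodes,
        "n_interactions": pbin.n_interactions,
        "fill_percent": 100.0 * pbin.fill,
        "symmetry": symmetry,
        "n_susceptible": len(pbin.susceptible_bacteria),
        "ei_phage": {p: float(e) for p, e in zip(pbin.phage_ids, pbin.ei_phages)},
        "ei_bacterium": {
            b: float(e) for b, e in zip(pbin.bacteria_ids, pbin.ei_bacteria)
        },
    }
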