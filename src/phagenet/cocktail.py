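"""Minimum-sized phage cocktail selection.

Two search strategies over a phage-bacteria infection network:

* ``heuristic_cocktail`` — the network-metrics greedy.  Phages that are
  the unique lyser of some strain are mandatory; the remainder are added
  in descending Expected Importance order whenever they lyse at least one
  still-uncovered strain, until every susceptible strain is covered.
* ``exhaustive_cocktail`` — enumerates all phage combinations of size
  1, 2, ... and stops at the first size whose best combination covers
  every susceptible strain.  That size is the Minimum Cocktail Size (MCS),
  the optimum of the underlying set-cover problem.

Host sets are packed into integer bitmasks so coverage of a combination
is a few bitwise ORs and a popcount.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Any, Literal

import numpy as np

from .network import PBIN

__all__ = [
    "Cocktail",
    "heuristic_cocktail",
    "exhaustive_cocktail",
    "compare_methods",
]


@dataclass(frozen=True)
class Cocktail:
    """A selected set of phages and what it covers.

    ``size`` equals the Minimum Cocktail Size when ``method`` is
    ``exhaustive`` and ``complete`` is true.  ``per_size_trace`` records,
    for the exhaustive search, the best coverage found at each candidate
    size from 1 up to the returned size.
    """

    method: Literal["heuristic", "exhaustive"]
    phages: tuple[str, ...]
    covered_bacteria: frozenset[str]
    n_susceptible: int
    complete: bool
    per_size_trace: tuple[int, ...] = ()

    @property
    def size(self) -> int:
        return len(self.phages)

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "phages": list(self.phages),
            "size": self.size,
            "complete": self.complete,
            "n_covered": len(self.covered_bacteria),
            "n_susceptible": self.n_susceptible,
            "per_size_trace": list(self.per_size_trace),
        }


def _host_masks(pbin: PBIN) -> tuple[list[int], list[int], int]:
    """Bitmask host set per active phage (out-degree >= 1).

    Returns (masks, active phage column indices, full susceptible mask).
    Bit i corresponds to the i-th bacterium row.
    """
    binary = pbin.matrix.binary
    masks: list[int] = []
    active: list[int] = []
    for j in range(pbin.n_phages):
        mask = 0
        for i in np.nonzero(binary[:, j])[0]:
            mask |= 1 << int(i)
        if mask:
            masks.append(mask)
            active.append(j)
    full = 0
    for m in masks:
        full |= m
    return masks, active, full


def heuristic_cocktail(pbin: PBIN) -> Cocktail:
    """Greedy network-metrics cocktail.

    Stage 1: every strain lysed by exactly one phage (in-degree 1) forces
    that phage into the cocktail.  Stage 2: remaining phages are visited
    in descending EI order (ties broken by input column order) and added
    only if they lyse at least one not-yet-covered strain.  The greedy
    always terminates with all susceptible strains covered, since the
    union of all phage host sets is exactly the susceptible set.
    """
    masks, active, full = _host_masks(pbin)
    susceptible = set(pbin.susceptible_bacteria)

    selected: list[int] = []  # positions into `active`
    covered = 0

    # stage 1: unique lysers are mandatory
    binary = pbin.matrix.binary
    mandatory: set[int] = set()
    for i, in_d in enumerate(pbin.in_degree):
        if in_d == 1:
            j = int(np.nonzero(binary[i, :])[0][0])
            mandatory.add(active.index(j))
    for pos in sorted(mandatory):
        selected.append(pos)
        covered |= masks[pos]

    # stage 2: descending EI_p, stable input order on ties
    if covered != full:
        order = sorted(
            (pos for pos in range(len(active)) if pos not in mandatory),
            key=lambda pos: (-pbin.ei_phages[active[pos]], pos),
        )
        for pos in order:
            if covered == full:
                break
            if masks[pos] & ~covered:
                selected.append(pos)
                covered |= masks[pos]

    phage_ids = tuple(pbin.phage_ids[active[pos]] for pos in selected)
    covered_ids = frozenset(
        b for i, b in enumerate(pbin.bacteria_ids) if covered >> i & 1
    )
    return Cocktail(
        method="heuristic",
        phages=phage_ids,
        covered_bacteria=covered_ids,
        n_susceptible=len(susceptible),
        complete=True,
    )


def _best_of_size(
    masks: list[int], k: int, full: int, prune: bool
) -> tuple[int, tuple[int, ...]]:
    """Best coverage over all k-subsets; ties go to the first combination
    in lexicographic order of phage indices."""
    if not prune:
        best_cov, best_combo = -1, ()
        for combo in combinations(range(len(masks)), k):
            union = 0
            for pos in combo:
                union |= masks[pos]
            cov = union.bit_count()
            if cov > best_cov:
                best_cov, best_combo = cov, combo
                if union == full:
                    # no k-subset can do better; lexicographically first winner
                    return best_cov, best_combo
        return best_cov, best_combo

    # branch and bound: identical result, provably — the optimistic bound
    # (current coverage plus the k - depth largest remaining degrees) is
    # admissible, so only subsets that cannot win are skipped, and the >
    # comparison keeps the lexicographically first maximum.
    n = len(masks)
    degrees = [m.bit_count() for m in masks]
    # suffix_top[i][r]: sum of the r largest degrees among masks[i:]
    best_cov, best_combo = -1, ()
    stack: list[tuple[int, int, tuple[int, ...]]] = [(0, 0, ())]

    def search(start: int, union: int, chosen: tuple[int, ...]) -> None:
        nonlocal best_cov, best_combo
        depth = len(chosen)
        if depth == k:
            cov = union.bit_count()
            if cov > best_cov:
                best_cov, best_combo = cov, chosen
            return
        remaining = k - depth
        for pos in range(start, n - remaining + 1):
            if best_cov == full.bit_count():
                return
            top = sorted(degrees[pos:], reverse=True)[:remaining]
            if union.bit_count() + sum(top) <= best_cov:
                break  # even the optimistic bound cannot beat the incumbent
            search(pos + 1, union | masks[pos], chosen + (pos,))

    search(0, 0, ())
    return best_cov, best_combo


def exhaustive_cocktail(pbin: PBIN, max_size: int = 12, prune: bool = False) -> Cocktail:
    """Exhaustive combinatorial search for the Minimum Cocktail Size.

    For k = 1, 2, ... enumerate every k-subset of phages with at least one
    host, keep the subset lysing the most strains, and stop at the first k
    whose best subset covers all susceptible strains; that k is the MCS.
    If no subset of size <= ``max_size`` achieves full coverage the best
    ``max_size``-subset is returned with ``complete=False``.

    ``max_size`` defaults to 12 phages, a practical ceiling beyond which
    cocktails stop being realistic formulations; empirical corpora rarely
    require more than 11.  ``prune=True`` switches to a branch-and-bound
    enumeration with an admissible bound — same result, fewer subsets
    visited.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    masks, active, full = _host_masks(pbin)
    n_susceptible = full.bit_count()

    if not masks:  # no phage lyses anything
        return Cocktail(
            method="exhaustive",
            phages=(),
            covered_bacteria=frozenset(),
            n_susceptible=0,
            complete=True,
        )

    trace: list[int] = []
    best_combo: tuple[int, ...] = ()
    for k in range(1, min(max_size, len(masks)) + 1):
        best_cov, best_combo = _best_of_size(masks, k, full, prune)
        trace.append(best_cov)
        if best_cov == n_susceptible:
            break

    union = 0
    for pos in best_combo:
        union |= masks[pos]
    covered_ids = frozenset(
        b for i, b in enumerate(pbin.bacteria_ids) if union >> i & 1
    )
    return Cocktail(
        method="exhaustive",
        phages=tuple(pbin.phage_ids[active[pos]] for pos in best_combo),
        covered_bacteria=covered_ids,
        n_susceptible=n_susceptible,
        complete=union == full,
        per_size_trace=tuple(trace),
    )


def compare_methods(pbin: PBIN, max_size: int = 12) -> dict[str, Any]:
    """Run both searches and report sizes, coverages and the size gap.

    The gap (heuristic minus exhaustive size) is non-negative whenever the
    exhaustive search completes, since the MCS is the optimum.
    """
    heur = heuristic_cocktail(pbin)
    exh = exhaustive_cocktail(pbin, max_size=max_size)
    return {
        "heuristic": heur.to_dict(),
        "exhaustive": exh.to_dict(),
        "heuristic_size": heur.size,
        "exhaustive_size": exh.size,
        "size_gap": heur.size - exh.size,
        "exhaustive_complete": exh.complete,
    }
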