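"""Phage cocktail networks (PCNs) and redundancy-variation analysis.

A PCN is the subnetwork of an infection network restricted to the
cocktail's phages and all susceptible bacteria.  Within it, each strain
has a cocktail in-degree ``in_dc``: how many cocktail phages lyse it,
i.e. how much coinfection pressure the formulation puts on that strain.

Redundancy of a strain is the fraction of a network's phages that lyse
it: ``r = in_d / |P|`` in the parent network, ``r = in_dc / MCS`` in the
cocktail network.  Redundancy variation compares the two on a log scale:

    rv = log10(r_PCN / r_PBIN)

with analytic bounds reached when exactly one cocktail phage lyses the
strain (rv_min = log10(|P| / (MCS * in_d))) and when in_dc equals its
ceiling (rv_max = log10(|P| / MCS)).  The bound gap rv_max - rv_min is
log10(in_d) for every strain.  A positive rv means the cocktail is
relatively more redundant on that strain than the source network was.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Iterable, Literal

import numpy as np
import pandas as pd

from .cocktail import Cocktail
from .network import PBIN

__all__ = [
    "PCN",
    "RedundancyRecord",
    "extract_pcn",
    "efficacy",
    "coinfection_distribution",
    "redundancy_variation",
    "pcn_redundancy_records",
    "rv_by_group",
    "fold_change",
]


@dataclass(frozen=True)
class PCN:
    """Cocktail subnetwork: cocktail phages x all susceptible bacteria."""

    parent: PBIN
    cocktail: Cocktail
    bacteria: tuple[str, ...]          # susceptible strains of the parent
    cocktail_indegree: dict[str, int]  # in_dc per strain

    @property
    def mcs(self) -> int:
        return self.cocktail.size


@dataclass(frozen=True)
class RedundancyRecord:
    """Per-strain redundancy bookkeeping for a PBIN/PCN pair."""

    bacterium_id: str
    in_d: int
    in_dc: int
    r_pbin: float
    r_pcn: float
    rv: float
    rv_min: float
    rv_max: float


def extract_pcn(pbin: PBIN, cocktail: Cocktail) -> PCN:
    """Restrict a PBIN to the cocktail phages and susceptible bacteria.

    Resistant strains (in-degree 0) are excluded: the cocktail network
    only contains strains that some phage can lyse.
    """
    unknown = set(cocktail.phages) - set(pbin.phage_ids)
    if unknown:
        raise ValueError(f"cocktail phages not in network: {sorted(unknown)}")
    cols = [pbin.phage_ids.index(p) for p in cocktail.phages]
    binary = pbin.matrix.binary
    susceptible = pbin.susceptible_bacteria
    in_dc = {}
    for b in susceptible:
        i = pbin.bacteria_ids.index(b)
        in_dc[b] = int(binary[i, cols].sum()) if cols else 0
    return PCN(parent=pbin, cocktail=cocktail, bacteria=tuple(susceptible), cocktail_indegree=in_dc)


def efficacy(pbin: PBIN, cocktail: Cocktail) -> float:
    """Expected cocktail efficacy: percent of ALL bacteria covered.

    Resistant strains count in the denominator, so efficacy reaches 100%
    only for a complete cocktail on a network with no resistant strain —
    a fully successful formulation.
    """
    return 100.0 * len(cocktail.covered_bacteria) / pbin.n_bacteria


def coinfection_distribution(pcns: Iterable[PCN]) -> pd.DataFrame:
    """Percent of strains lysed by k cocktail phages, grouped by MCS.

    Rows are cocktail-size (MCS) groups, pooled over the networks of that
    size; columns are k = 1..max MCS.  Each row sums to 100%.  Groups with
    no strains are omitted.
    """
    groups: dict[int, list[int]] = {}
    for pcn in pcns:
        if not pcn.cocktail.complete:
            raise ValueError("coinfection distribution requires complete cocktails")
        groups.setdefault(pcn.mcs, []).extend(
            pcn.cocktail_indegree[b] for b in pcn.bacteria
        )
    groups = {m: counts for m, counts in groups.items() if counts}
    if not groups:
        return pd.DataFrame()
    max_k = max(max(c) for c in groups.values())
    table = pd.DataFrame(
        0.0,
        index=pd.Index(sorted(groups), name="mcs"),
        columns=pd.Index(range(1, max_k + 1), name="n_lysing_phages"),
    )
    for m, counts in groups.items():
        arr = np.bincount(counts, minlength=max_k + 1)[1:]
        table.loc[m] = 100.0 * arr / len(counts)
    return table


def redundancy_variation(
    in_d: int, in_dc: int, n_phages: int, mcs: int
) -> RedundancyRecord:
    """Redundancy variation of one strain between a PBIN and its PCN.

    Raises for a resistant strain (``in_d == 0``): redundancy variation is
    undefined where the source network shows no lysis at all.
    """
    if in_d < 1:
        raise ValueError("resistant strain (in_d = 0) has no redundancy variation")
    if mcs < 1 or n_phages < mcs:
        raise ValueError("need 1 <= mcs <= n_phages")
    if not 1 <= in_dc <= min(in_d, mcs):
        raise ValueError(f"in_dc {in_dc} outside [1, min({in_d}, {mcs})]")
    r_pbin = in_d / n_phages
    r_pcn = in_dc / mcs
    return RedundancyRecord(
        bacterium_id="",
        in_d=in_d,
        in_dc=in_dc,
        r_pbin=r_pbin,
        r_pcn=r_pcn,
        rv=math.log10(r_pcn / r_pbin),
        rv_min=math.log10(n_phages / (mcs * in_d)),
        rv_max=math.log10(n_phages / mcs),
    )


def pcn_redundancy_records(pcn: PCN) -> list[RedundancyRecord]:
    """Redundancy records for every strain the cocktail lyses."""
    pbin = pcn.parent
    n_phages, mcs = pbin.n_phages, pcn.mcs
    records = []
    for b in pcn.bacteria:
        in_dc = pcn.cocktail_indegree[b]
        if in_dc == 0:  # strain missed by an incomplete cocktail
            continue
        i = pbin.bacteria_ids.index(b)
        rec = redundancy_variation(int(pbin.in_degree[i]), in_dc, n_phages, mcs)
        records.append(
            RedundancyRecord(bacterium_id=b, **{
                f: getattr(rec, f) for f in (
                    "in_d", "in_dc", "r_pbin", "r_pcn", "rv", "rv_min", "rv_max"
                )
            })
        )
    return records


def _median(values: list[float]) -> float:
    # midpoint convention for even counts
    return float(np.median(values))


def rv_by_group(
    records: Iterable[tuple[RedundancyRecord, int]],
    group_by: Literal["mcs", "n_lysing_phages"] = "mcs",
) -> pd.DataFrame:
    """Summarize redundancy variation per group.

    ``records`` pairs each record with the MCS of its cocktail.  Grouping
    is either by that MCS or by the strain's number of lysing cocktail
    phages (``in_dc``).  Returns median rv, rv range and count per group.
    """
    buckets: dict[int, list[float]] = {}
    for rec, mcs in records:
        key = mcs if group_by == "mcs" else rec.in_dc
        buckets.setdefault(key, []).append(rec.rv)
    if not buckets:
        raise ValueError("no redundancy records to group")
    rows = []
    for key in sorted(buckets):
        vals = buckets[key]
        rows.append(
            {
                group_by: key,
                "median_rv": _median(vals),
                "min_rv": min(vals),
                "max_rv": max(vals),
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows).set_index(group_by)


def fold_change(rv: float) -> float:
    """Convert a redundancy variation (log10 units) to a fold change."""
    return 10.0 ** rv


def records_frame(records: Iterable[RedundancyRecord]) -> pd.DataFrame:
    """Tabulate redundancy records for TSV export."""
    return pd.DataFrame(
        [
            {
                "bacterium": r.bacterium_id,
                "in_d": r.in_d,
                "in_dc": r.in_dc,
                "r_pbin": r.r_pbin,
                "r_pcn": r.r_pcn,
                "rv": r.rv,
                "rv_min": r.rv_min,
                "rv_max": r.rv_max,
            }
            for r in records
        ]
    )


def summary_record(pcn: PCN) -> dict[str, Any]:
    """JSON-ready per-network redundancy summary."""
    records = pcn_redundancy_records(pcn)
    rvs = [r.rv for r in records]
    return {
        "mcs": pcn.mcs,
        "n_bacteria": len(pcn.bacteria),
        "median_rv": _median(rvs) if rvs else float("nan"),
        "rv_min_bound": min((r.rv_min for r in records), default=float("nan")),
        "rv_max_bound": max((r.rv_max for r in records), default=float("nan")),
    }
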