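"""Corpus summaries, batch pipelines and cross-dataset correlations."""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cocktail import exhaustive_cocktail, heuristic_cocktail
from .io import DatasetMetadata, HostRangeMatrix, read_matrix
from .network import build_pbin
from .redundancy import efficacy, extract_pcn, pcn_redundancy_records

__all__ = [
    "DatasetSummary",
    "summarize_corpus_metadata",
    "batch_analyze",
    "analyze_matrix",
    "correlate_summaries",
]

logger = logging.getLogger("phagenet")


@dataclass(frozen=True)
class DatasetSummary:
    """One row of a batch report: network shape, cocktail sizes, efficacy."""

    dataset_name: str
    n_bacteria: int
    n_phages: int
    fill_percent: float
    mcs: int
    heuristic_size: int
    efficacy_percent: float
    median_rv: float
    exhaustive_complete: bool = True


def summarize_corpus_metadata(records: Sequence[DatasetMetadata]) -> dict[str, Any]:
    """Aggregate a corpus metadata table.

    Means are reported both at full precision and rounded to the nearest
    integer for display.
    """
    hosts = np.array([r.n_hosts for r in records])
    phages = np.array([r.n_phages for r in records])
    sizes = np.array([r.matrix_size for r in records])
    nodes = hosts + phages
    return {
        "n_datasets": len(records),
        "total_hosts": int(hosts.sum()),
        "total_phages": int(phages.sum()),
        "total_interactions_evaluated": int(sizes.sum()),
        "percent_more_bacteria": 100.0 * float(np.mean(hosts > phages)),
        "min_nodes": int(nodes.min()),
        "max_nodes": int(nodes.max()),
        "mean_hosts": float(hosts.mean()),
        "mean_phages": float(phages.mean()),
        "mean_hosts_rounded": int(round(hosts.mean())),
        "mean_phages_rounded": int(round(phages.mean())),
    }


def analyze_matrix(
    matrix: HostRangeMatrix, name: str = "matrix", max_size: int = 12, prune: bool = True
) -> DatasetSummary:
    """Full pipeline on one matrix: network, both searches, PCN, rv."""
    pbin = build_pbin(matrix)
    heur = heuristic_cocktail(pbin)
    exh = exhaustive_cocktail(pbin, max_size=max_size, prune=prune)
    if not exh.complete:
        logger.warning(
            "%s: exhaustive search incomplete at cap %d (covered %d/%d)",
            name, max_size, len(exh.covered_bacteria), exh.n_susceptible,
        )
    pcn = extract_pcn(pbin, exh)
    records = pcn_redundancy_records(pcn)
    rvs = [r.rv for r in records]
    return DatasetSummary(
        dataset_name=name,
        n_bacteria=pbin.n_bacteria,
        n_phages=pbin.n_phages,
        fill_percent=100.0 * pbin.fill,
        mcs=exh.size,
        heuristic_size=heur.size,
        efficacy_percent=efficacy(pbin, exh),
        median_rv=float(np.median(rvs)) if rvs else float("nan"),
        exhaustive_complete=exh.complete,
    )


def batch_analyze(
    paths: Iterable[str | Path], max_size: int = 12, threshold: float = 0.0
) -> list[DatasetSummary]:
    """Run the pipeline over a collection of matrix files.

    Inputs are processed in sorted path order for determinism.  A file
    that fails to parse is logged and skipped; only zero readable inputs
    is fatal.
    """
    summaries = []
    sorted_paths = sorted(Path(p) for p in paths)
    if not sorted_paths:
        raise ValueError("no input files")
    for path in sorted_paths:
        try:
            matrix = read_matrix(path, threshold=threshold)
        except Exception as exc:  # noqa: BLE001 — skip unreadable inputs
            logger.warning("skipping %s: %s", path, exc)
            continue
        summaries.append(analyze_matrix(matrix, name=path.stem, max_size=max_size))
    if not summaries:
        raise ValueError("no readable matrix among inputs")
    return summaries


def summaries_frame(summaries: Sequence[DatasetSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def correlate_summaries(
    summaries: Sequence[DatasetSummary],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Spearman rank correlations between dataset descriptors.

    Ties receive average ranks (the scipy convention).  Pairs involving
    a constant descriptor are omitted with a warning, since their rank
    correlation is undefined.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 summaries to correlate")
    frame = summaries_frame(summaries)
    numeric = frame.select_dtypes("number")
    if pairs is None:
        cols = list(numeric.columns)
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i:]]
    rows = []
    for a, b in pairs:
        x, y = numeric[a], numeric[b]
        if x.nunique() <= 1 or y.nunique() <= 1:
            warnings.warn(f"descriptor pair ({a}, {b}) has a constant column; omitted")
            continue
        mask = x.notna() & y.notna()
        r, p = stats.spearmanr(x[mask], y[mask])
        rows.append({"x": a, "y": b, "spearman_r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)
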