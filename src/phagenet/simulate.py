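"""Synthetic host-range matrix generation.

Three structures are available:

* ``random`` — each phage-strain pair is lytic independently with
  probability ``fill`` (an Erdős–Rényi bipartite network);
* ``nested`` — phage host sets are totally ordered by inclusion, the
  idealized hierarchy where every narrower host range is a subset of
  every broader one.  Its defining consequence: the broadest phage alone
  covers every susceptible strain, so the minimum cocktail size is 1;
* ``noisy_nested`` — a nested matrix degraded by swapping a fraction of
  (lytic, non-lytic) cell pairs, which erodes the hierarchy while
  holding the interaction count (fill) exactly constant.

``corpus_like_sample`` draws batches whose shapes mimic published
host-range surveys: about 80% of matrices with more bacteria than
phages, node counts from ten up to several hundred, and sparser fill on
larger matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import HostRangeMatrix

__all__ = [
    "GeneratorConfig",
    "random_matrix",
    "nested_matrix",
    "generate",
    "corpus_like_sample",
]

DEFAULT_SEED = 20220214


@dataclass(frozen=True)
class GeneratorConfig:
    n_bacteria: int
    n_phages: int
    fill: float = 0.3
    structure: Literal["random", "nested", "noisy_nested"] = "random"
    noise: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_bacteria < 1 or self.n_phages < 1:
            raise ValueError("need at least one bacterium and one phage")
        if not 0.0 <= self.fill <= 1.0:
            raise ValueError("fill must be in [0, 1]")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")


def _labels(config: GeneratorConfig) -> tuple[tuple[str, ...], tuple[str, ...]]:
    bacteria = tuple(f"b{i + 1}" for i in range(config.n_bacteria))
    phages = tuple(f"p{j + 1}" for j in range(config.n_phages))
    return bacteria, phages


def random_matrix(config: GeneratorConfig) -> HostRangeMatrix:
    """Bernoulli matrix: each cell lytic with probability ``fill``."""
    if config.structure != "random":
        raise ValueError(f"config.structure is {config.structure!r}, not 'random'")
    rng = np.random.default_rng(config.seed)
    binary = (rng.random((config.n_bacteria, config.n_phages)) < config.fill)
    bacteria, phages = _labels(config)
    return HostRangeMatrix(bacteria, phages, binary.astype(float))


def nested_matrix(config: GeneratorConfig) -> HostRangeMatrix:
    """Inclusion-ordered matrix, optionally degraded by pair swaps.

    Phage j lyses the first k_j bacteria with k_1 >= k_2 >= ...; prefix
    host sets are totally ordered by inclusion by construction.  The k_j
    follow a linear ramp scaled so the realized fill approximates the
    target.  With ``structure == 'noisy_nested'``, ``noise`` times the
    number of swappable pairs of (lytic, non-lytic) cells are exchanged
    at random; each swap moves one interaction to an empty cell, so the
    total interaction count never changes.
    """
    if config.structure not in ("nested", "noisy_nested"):
        raise ValueError(f"config.structure is {config.structure!r}, not nested")
    n_b, n_p = config.n_bacteria, config.n_phages
    rng = np.random.default_rng(config.seed)

    # linear ramp k_j ∝ (n_p - j), scaled to hit target fill on average
    ramp = np.arange(n_p, 0, -1, dtype=float)
    ramp *= config.fill * n_b * n_p / ramp.sum()
    k = np.clip(np.rint(ramp), 0, n_b).astype(int)

    binary = np.zeros((n_b, n_p))
    for j, kj in enumerate(k):
        binary[:kj, j] = 1.0

    if config.structure == "noisy_nested" and config.noise > 0:
        lytic = np.flatnonzero(binary.ravel() == 1)
        empty = np.flatnonzero(binary.ravel() == 0)
        n_swaps = int(round(config.noise * min(len(lytic), len(empty))))
        if n_swaps:
            src = rng.choice(lytic, size=n_swaps, replace=False)
            dst = rng.choice(empty, size=n_swaps, replace=False)
            flat = binary.ravel()
            flat[src] = 0.0
            flat[dst] = 1.0
            binary = flat.reshape(n_b, n_p)

    bacteria, phages = _labels(config)
    return HostRangeMatrix(bacteria, phages, binary)


def generate(config: GeneratorConfig) -> HostRangeMatrix:
    """Dispatch on ``config.structure``."""
    if config.structure == "random":
        return random_matrix(config)
    return nested_matrix(config)


def corpus_like_sample(
    n_datasets: int,
    seed: int = DEFAULT_SEED,
    max_nodes: int = 900,
    asymmetry: float = 0.8,
) -> list[HostRangeMatrix]:
    """Draw matrices shaped like an empirical host-range corpus.

    Node counts (bacteria plus phages) are log-uniform between 10 and
    ``max_nodes``; a fraction ``asymmetry`` of matrices have strictly
    more bacteria than phages; fill is drawn sparser for larger
    matrices, echoing the weak negative size-fill association seen in
    published surveys.  Structures alternate between random and noisy
    nested so batches exercise both regimes.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    rng = np.random.default_rng(seed)
    matrices = []
    for i in range(n_datasets):
        nodes = int(round(10 ** rng.uniform(1.0, np.log10(max_nodes))))
        nodes = max(nodes, 10)
        if rng.random() < asymmetry:
            n_b = int(np.ceil(nodes * rng.uniform(0.55, 0.95)))
            n_b = min(max(n_b, nodes // 2 + 1), nodes - 1)
        else:
            n_b = int(np.floor(nodes * rng.uniform(0.1, 0.5)))
            n_b = min(max(n_b, 1), nodes // 2)
        n_p = nodes - n_b
        # sparser fill for larger matrices
        fill = float(np.clip(rng.uniform(0.1, 0.7) * (50.0 / nodes) ** 0.25, 0.02, 0.9))
        structure = "random" if i % 2 == 0 else "noisy_nested"
        config = GeneratorConfig(
            n_bacteria=n_b,
            n_phages=n_p,
            fill=fill,
            structure=structure,
            noise=0.2 if structure == "noisy_nested" else 0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        matrices.append(generate(config))
    return matrices
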