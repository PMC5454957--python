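"""Permutation test screening walk-selected genes for disease specificity.

A gene can score high under the walk purely because of network topology
(hubs attract mass from any seed set).  The test re-runs the walk on many
random seed sets of the same size and, for each selected gene, counts the
fraction of random runs that score it strictly higher than the true seeds
did:

    p(g) = Theta(g) / n_permutations

Theta uses a strict ``>``; ties do not count against the gene, which is
mildly anti-conservative (see docs/methods.md).  p-values therefore live on
the grid {0, 1/n, ..., 1}; a p of exactly zero is rendered as ``<1/n`` in
reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network_io import SeedSet, TransitionModel, WeightedNetwork
from .rwr import RwrConfig, rwr_batch

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    """Per-gene empirical p-values plus the audit trail that produced them."""

    pvalues: dict[str, float]
    n_perm: int
    rng_seed: int
    #: the drawn node sets, kept for audit at desk scale
    seed_sets: list[tuple[str, ...]] = field(default_factory=list, repr=False)

    def __getitem__(self, gene: str) -> float:
        return self.pvalues[gene]


def draw_permutation_seed_sets(
    nodes: list[str], n_seeds: int, n_perm: int, rng_seed: int
) -> list[tuple[str, ...]]:
    """Draw ``n_perm`` uniform without-replacement node sets of size ``n_seeds``.

    One RNG stream seeded from ``rng_seed`` drives all draws, so the sets are
    reproducible and independently re-derivable for audit.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_seeds > len(nodes):
        raise ValueError("more seeds requested than network nodes")
    rng = np.random.default_rng(rng_seed)
    n = len(nodes)
    return [
        tuple(nodes[i] for i in rng.choice(n, size=n_seeds, replace=False))
        for _ in range(n_perm)
    ]


def permutation_pvalues(
    net: WeightedNetwork,
    model: TransitionModel,
    seeds: SeedSet,
    rwr_genes: list[tuple[str, float]],
    cfg: RwrConfig,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> PermutationResult:
    """Empirical p-value for each selected gene against random seed sets.

    Every permutation re-runs the full walk on the *same* transition model
    (the network is fixed; only the restart vector changes).  The walks are
    batched column-wise; each column is frozen at its own convergence, so the
    result is identical to re-running the walk one permutation at a time.
    """
    seed_sets = draw_permutation_seed_sets(model.nodes, len(seeds), n_perm, rng_seed)
    index = model.index
    n = len(model.nodes)
    p0_matrix = np.zeros((n, n_perm))
    mass = 1.0 / len(seeds)
    for j, ids in enumerate(seed_sets):
        for g in ids:
            p0_matrix[index[g], j] = mass
    perm_probs = rwr_batch(model, p0_matrix, cfg)

    pvalues: dict[str, float] = {}
    for gene, true_prob in rwr_genes:
        theta = int((perm_probs[index[gene], :] > true_prob).sum())
        pvalues[gene] = theta / n_perm
    logger.info("permutation test: %d permutations over %d genes", n_perm, len(pvalues))
    return PermutationResult(
        pvalues=pvalues, n_perm=n_perm, rng_seed=rng_seed, seed_sets=seed_sets
    )


def filter_candidates(
    rwr_genes: list[tuple[str, float]],
    pvals: PermutationResult,
    alpha: float = 0.05,
) -> list[tuple[str, float, float]]:
    """Keep genes with p strictly below ``alpha``.

    Returns ``(gene, probability, p_value)`` triples ordered by p ascending,
    then probability descending, then ID.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    kept = [
        (g, prob, pvals.pvalues[g])
        for g, prob in rwr_genes
        if pvals.pvalues[g] < alpha
    ]
    kept.sort(key=lambda t: (t[2], -t[1], t[0]))
    return kept


def format_pvalue(p: float, n_perm: int) -> str:
    """Report-style rendering: a p of exactly zero prints as ``<1/n_perm``."""
    if p == 0.0:
        return f"<{1.0 / n_perm:g}"
    return f"{p:g}"
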