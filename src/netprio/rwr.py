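"""Random walk with restart on a weighted interaction network.

The walker's probability vector is updated as

    p_{t+1} = (1 - r) * A @ p_t + r * p_0

where ``A`` is the column-stochastic transition matrix, ``r`` the restart
probability, and ``p_0`` the uniform distribution over the seed genes.
Because ``A`` is column-stochastic and ``p_0`` sums to one, every iterate is
a probability distribution; the iteration is a contraction with factor
``1 - r`` and converges geometrically to the unique fixed point of
``(I - (1-r) A) p = r p_0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network_io import SeedSet, TransitionModel, WeightedNetwork


class ConvergenceError(RuntimeError):
    """The iteration failed to reach the tolerance within max_iterations."""


@dataclass
class RwrConfig:
    """Walker settings; the defaults are the published operating point.

    restart
        Probability mass teleported back to the seeds each step (0.8).
    tolerance
        L1 convergence criterion between successive iterates (1e-6).
    probability_threshold
        Stationary probability above which a gene is kept (1e-5, strict).
    max_iterations
        Safety cap; the contraction converges long before this.
    """

    restart: float = 0.8
    tolerance: float = 1e-6
    probability_threshold: float = 1e-5
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ValueError("restart must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.probability_threshold <= 0:
            raise ValueError("probability_threshold must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ProbabilityVector:
    """Per-node probability mass on a fixed node ordering (sums to one)."""

    nodes: list[str]
    values: np.ndarray

    def __getitem__(self, node: str) -> float:
        return float(self.values[self.nodes.index(node)])

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.nodes, self.values)}

    def write_tsv(self, stream) -> None:
        stream.write("gene\tprobability\n")
        order = np.argsort(self.values)[::-1]
        for i in order:
            stream.write(f"{self.nodes[i]}\t{self.values[i]:.6e}\n")


def build_initial_vector(net: WeightedNetwork, seeds: SeedSet) -> ProbabilityVector:
    """Uniform restart distribution: each seed gets 1/|seeds|, others zero."""
    if len(seeds) == 0:
        raise ValueError("seed set is empty")
    nodes = net.node_ordering()
    index = {n: i for i, n in enumerate(nodes)}
    values = np.zeros(len(nodes))
    mass = 1.0 / len(seeds)
    for s in seeds.ids:
        values[index[s]] = mass
    return ProbabilityVector(nodes=nodes, values=values)


def random_walk_with_restart(
    model: TransitionModel, p0: ProbabilityVector, cfg: RwrConfig | None = None
) -> ProbabilityVector:
    """Iterate to the stationary distribution of the restarted walk.

    Returns the first iterate whose L1 distance to its predecessor is below
    ``cfg.tolerance``; that iterate satisfies the fixed-point residual
    ``||p - (1-r) A p - r p0||_1 < 10 * tolerance``.  Deterministic: there is
    no randomness in this module.
    """
    cfg = cfg or RwrConfig()
    if model.nodes != p0.nodes:
        raise ValueError("transition model and initial vector orderings differ")
    r = cfg.restart
    a = model.matrix
    p0v = p0.values
    p = p0v
    diff = np.inf
    for _ in range(cfg.max_iterations):
        p_next = (1.0 - r) * (a @ p) + r * p0v
        diff = float(np.abs(p_next - p).sum())
        if diff < cfg.tolerance:
            return ProbabilityVector(nodes=p0.nodes, values=p_next)
        p = p_next
    raise ConvergenceError(
        f"no convergence in {cfg.max_iterations} iterations (last residual {diff:g})"
    )


def rwr_batch(model: TransitionModel, p0_matrix: np.ndarray, cfg: RwrConfig) -> np.ndarray:
    """Run many walks at once: column j of ``p0_matrix`` is one restart vector.

    Each column is frozen at its own first convergence, so every column equals
    the result of a solo :func:`random_walk_with_restart` on that restart
    vector (same matrix-vector products, same stopping rule).
    """
    r = cfg.restart
    a = model.matrix
    p = p0_matrix
    out = np.empty_like(p0_matrix)
    done = np.zeros(p0_matrix.shape[1], dtype=bool)
    for _ in range(cfg.max_iterations):
        p_next = (1.0 - r) * (a @ p) + r * p0_matrix
        diffs = np.abs(p_next - p).sum(axis=0)
        newly = ~done & (diffs < cfg.tolerance)
        if newly.any():
            out[:, newly] = p_next[:, newly]
            done |= newly
        if done.all():
            return out
        p = p_next
    raise ConvergenceError(
        f"{int((~done).sum())} walk(s) unconverged after {cfg.max_iterations} iterations"
    )


def select_rwr_genes(
    p: ProbabilityVector,
    seeds: SeedSet,
    threshold: float = 1e-5,
    exclude_seeds: bool = True,
) -> list[tuple[str, float]]:
    """Genes with stationary probability strictly above ``threshold``.

    Sorted by probability descending, ties broken by ID ascending.  Seed
    genes are removed by default (the method hunts for novel genes).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    seed_ids = set(seeds.ids) if exclude_seeds else set()
    picked = [
        (n, float(v))
        for n, v in zip(p.nodes, p.values)
        if v > threshold and n not in seed_ids
    ]
    picked.sort(key=lambda t: (-t[1], t[0]))
    return picked
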