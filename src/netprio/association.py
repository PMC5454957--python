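"""Association filters selecting core genes among the significant candidates.

Two criteria capture "closeness to a validated disease gene":

* MIS, the maximum interaction score — the largest edge weight between a
  candidate and any seed gene.  A high MIS means the candidate directly
  interacts with a validated gene at high confidence (STRING calls >= 900
  "highest confidence").
* MFS, the maximum function score — the largest cosine similarity between
  the candidate's enrichment-score vector and any seed's.  The enrichment
  vector ES(g) scores, for every annotation term, how over-represented the
  term is among g's direct network neighbors, as the -log10 upper-tail
  hypergeometric probability (the classic ``phyper(numWdrawn - 1, numW,
  numB, numDrawn, lower.tail = FALSE)`` enrichment score).

Core genes are candidates with MIS >= 900 and MFS strictly > 0.8 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .network_io import AnnotationMap, SeedSet, WeightedNetwork

logger = logging.getLogger(__name__)

#: tail probabilities are floored here before -log10 so scores stay finite
MIN_TAIL_PROBABILITY = 1e-300


@dataclass
class EnrichmentVector:
    """Per-term -log10 upper-tail hypergeometric scores for one gene."""

    terms: tuple[str, ...]
    scores: np.ndarray

    def norm(self) -> float:
        return float(np.linalg.norm(self.scores))


@dataclass
class CandidateRecord:
    """One gene's full scorecard across the pipeline stages."""

    gene: str
    probability: float
    p_value: float | None = None
    mis: int | None = None
    mfs: float | None = None
    is_core: bool = False
    stage: str = "rwr_gene"


def max_interaction_score(g: str, seeds: SeedSet, net: WeightedNetwork) -> int:
    """Largest edge score between ``g`` and any seed; 0 when none exists."""
    if g not in net:
        raise KeyError(f"gene {g!r} not in network")
    best = 0
    for s in seeds.ids:
        if net.graph.has_edge(g, s):
            best = max(best, net.score(g, s))
    return best


def annotated_universe(net: WeightedNetwork, ann: AnnotationMap) -> set[str]:
    """Enrichment universe: network nodes carrying at least one annotation."""
    return net.nodes & ann.annotated_genes()


def enrichment_vector(
    g: str,
    net: WeightedNetwork,
    ann: AnnotationMap,
    universe: set[str],
) -> EnrichmentVector:
    """Score over-representation of each term among ``g``'s direct neighbors.

    For a term annotating ``numW`` of the ``numW + numB`` universe genes,
    with ``numDrawn`` of g's neighbors in the universe and ``numWdrawn`` of
    them annotated, the score is ``-log10 P(X >= numWdrawn)`` under the
    hypergeometric null.  Terms with ``numWdrawn == 0`` (no annotated
    neighbor, hence no over-representation signal) score zero, as do terms
    annotating no universe gene.  A gene with zero in-universe neighbors
    yields the all-zero vector (logged, not an error).
    """
    if g not in net:
        raise KeyError(f"gene {g!r} not in network")
    if not universe:
        raise ValueError("universe is empty")
    terms = tuple(ann.terms)
    total = len(universe)
    neighbors = set(net.graph[g]) & universe
    num_drawn = len(neighbors)
    scores = np.zeros(len(terms))
    if num_drawn == 0:
        logger.info("gene %s has no annotated network neighbor; ES is all-zero", g)
        return EnrichmentVector(terms=terms, scores=scores)
    for t, term in enumerate(terms):
        annotated = ann.term_genes[term] & universe
        num_w = len(annotated)
        if num_w == 0:
            continue
        num_wdrawn = len(neighbors & annotated)
        if num_wdrawn == 0:
            continue
        tail = float(hypergeom.sf(num_wdrawn - 1, total, num_w, num_drawn))
        scores[t] = -np.log10(max(tail, MIN_TAIL_PROBABILITY))
    return EnrichmentVector(terms=terms, scores=scores)


def cosine_relatedness(a: EnrichmentVector, b: EnrichmentVector) -> float:
    """Cosine of two enrichment vectors; 0 when either is all-zero.

    Scores are nonnegative, so the value lies in [0, 1].
    """
    if a.terms != b.terms:
        raise ValueError("enrichment vectors use different term orderings")
    na, nb = a.norm(), b.norm()
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a.scores, b.scores) / (na * nb))


def max_function_score(
    g: str,
    seeds: SeedSet,
    es_cache: dict[str, EnrichmentVector],
) -> float:
    """Largest cosine relatedness between ``g`` and any seed gene."""
    if g not in es_cache:
        raise KeyError(f"no enrichment vector cached for {g!r}")
    missing = [s for s in seeds.ids if s not in es_cache]
    if missing:
        raise KeyError(f"no enrichment vector cached for seed(s) {missing[:3]!r}")
    eg = es_cache[g]
    return max((cosine_relatedness(eg, es_cache[s]) for s in seeds.ids), default=0.0)


def select_core_genes(
    candidates: list[CandidateRecord],
    mis_threshold: int = 900,
    mfs_threshold: float = 0.8,
) -> list[CandidateRecord]:
    """Candidates with MIS >= ``mis_threshold`` and MFS > ``mfs_threshold``.

    The MIS bound is inclusive, the MFS bound strict.  Survivors get
    ``is_core`` set and are ordered by p-value ascending, then probability
    descending, then ID.
    """
    core = [
        rec
        for rec in candidates
        if rec.mis is not None
        and rec.mfs is not None
        and rec.mis >= mis_threshold
        and rec.mfs > mfs_threshold
    ]
    for rec in core:
        rec.is_core = True
    core.sort(key=lambda rec: (rec.p_value, -rec.probability, rec.gene))
    return core
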