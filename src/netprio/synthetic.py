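"""Desk-scale synthetic fixtures with the structure the method assumes.

Real disease modules sit inside a large interactome as locally dense,
high-confidence, functionally coherent neighborhoods.  The generator plants
exactly that: an Erdős–Rényi background of low-confidence edges plus one
densely wired module whose edges draw from the high-confidence score range
and whose genes share dedicated annotation terms.  Splitting the module
into a seeded half and a held-out half then mirrors the cross-validation
design: a working pipeline should pull the held-out half out of the
background.

Fixtures are written in the exact external formats (STRING-style links,
seed list, GMT), so end-to-end tests exercise the real parsers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network_io import (
    AnnotationMap,
    WeightedNetwork,
    write_annotations,
    write_string_links,
)


@dataclass
class SyntheticSpec:
    """Generator settings; defaults state the fixture world used throughout.

    The module is densely connected (intra_p 0.8) with highest-confidence
    scores (850–999, straddling the 900 core-gene cutoff), on a sparse
    low-confidence background (p 0.05, scores 150–500).
    """

    n_nodes: int = 60
    module_size: int = 10
    intra_p: float = 0.8
    intra_scores: tuple[int, int] = (850, 999)
    background_p: float = 0.05
    background_scores: tuple[int, int] = (150, 500)
    n_terms: int = 30
    n_module_terms: int = 6
    module_term_fraction: float = 0.9
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0 < self.module_size < self.n_nodes):
            raise ValueError("module_size must be in (0, n_nodes)")
        for lo, hi in (self.intra_scores, self.background_scores):
            if not (150 <= lo <= hi <= 999):
                raise ValueError("score ranges must lie within [150, 999]")
        for p in (self.intra_p, self.background_p):
            if not (0.0 < p <= 1.0):
                raise ValueError("edge probabilities must be in (0, 1]")
        if self.n_module_terms > self.n_terms:
            raise ValueError("n_module_terms cannot exceed n_terms")
        if not (0.0 < self.module_term_fraction <= 1.0):
            raise ValueError("module_term_fraction must be in (0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth of one fixture: the module and its seed/held-out split."""

    module: list[str]
    module_terms: list[str] = field(default_factory=list)
    seeded: list[str] = field(default_factory=list)
    held_out: list[str] = field(default_factory=list)


def _node_id(i: int) -> str:
    # STRING-shaped IDs so fixtures round-trip through the real parser
    return f"9606.ENSP{i:05d}"


def generate_network(spec: SyntheticSpec) -> tuple[WeightedNetwork, PlantedTruth]:
    """Erdős–Rényi background plus one planted high-confidence module.

    The module additionally gets a spanning cycle, guaranteeing it is
    connected; any node left isolated by the background draw receives one
    background edge, so the result always satisfies the network invariants.
    Deterministic per ``spec.rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    nodes = [_node_id(i) for i in range(spec.n_nodes)]
    module = sorted(
        nodes[i] for i in rng.choice(spec.n_nodes, size=spec.module_size, replace=False)
    )
    module_set = set(module)

    def draw(score_range: tuple[int, int]) -> int:
        return int(rng.integers(score_range[0], score_range[1] + 1))

    edges: dict[tuple[str, str], int] = {}

    def add(u: str, v: str, s: int) -> None:
        key = (u, v) if u < v else (v, u)
        edges.setdefault(key, s)

    for i in range(spec.n_nodes):
        for j in range(i + 1, spec.n_nodes):
            u, v = nodes[i], nodes[j]
            intra = u in module_set and v in module_set
            p = spec.intra_p if intra else spec.background_p
            if rng.random() < p:
                add(u, v, draw(spec.intra_scores if intra else spec.background_scores))
    # spanning cycle keeps the module connected
    for a, b in zip(module, module[1:] + module[:1]):
        add(a, b, draw(spec.intra_scores))
    # no singleton nodes: attach stragglers with one background edge
    touched = {n for e in edges for n in e}
    for u in nodes:
        if u not in touched:
            v = nodes[int(rng.integers(spec.n_nodes))]
            while v == u:
                v = nodes[int(rng.integers(spec.n_nodes))]
            add(u, v, draw(spec.background_scores))
            touched.update((u, v))

    net = WeightedNetwork.from_edges((u, v, s) for (u, v), s in sorted(edges.items()))
    return net, PlantedTruth(module=module)


def generate_annotations(
    net: WeightedNetwork, truth: PlantedTruth, spec: SyntheticSpec
) -> AnnotationMap:
    """Module terms annotate most module genes; background terms are random.

    Each module term covers ``module_term_fraction`` of the module (at least
    one gene) plus two random background genes (real annotations are never
    perfectly clean); background terms annotate 3–8 random genes.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    nodes = sorted(net.nodes)
    background = [n for n in nodes if n not in set(truth.module)]
    term_genes: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    module_terms: list[str] = []
    n_cover = max(1, int(round(spec.module_term_fraction * len(truth.module))))
    for t in range(spec.n_module_terms):
        term = f"MOD{t:04d}"
        covered = [
            truth.module[i]
            for i in rng.choice(len(truth.module), size=n_cover, replace=False)
        ]
        leak = (
            [background[i] for i in rng.choice(len(background), size=2, replace=False)]
            if len(background) >= 2
            else []
        )
        term_genes[term] = frozenset(covered + leak)
        descriptions[term] = f"planted module term {t}"
        module_terms.append(term)
    for t in range(spec.n_terms - spec.n_module_terms):
        term = f"BG{t:04d}"
        size = int(rng.integers(3, 9))
        members = [nodes[i] for i in rng.choice(len(nodes), size=min(size, len(nodes)), replace=False)]
        term_genes[term] = frozenset(members)
        descriptions[term] = f"background term {t}"
    truth.module_terms = module_terms
    return AnnotationMap(term_genes=term_genes, descriptions=descriptions)


def split_module_seeds(
    truth: PlantedTruth, fraction: float, rng_seed: int
) -> tuple[list[str], list[str]]:
    """Random seeded/held-out split of the module at the given fraction.

    The seeded side gets ``floor(fraction * module_size)`` genes, clamped so
    both sides keep at least one gene.  Deterministic per ``rng_seed``.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    m = len(truth.module)
    n_seed = int(fraction * m)
    n_seed = min(max(n_seed, 1), m - 1)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(m)
    seeded = sorted(truth.module[i] for i in order[:n_seed])
    held = sorted(truth.module[i] for i in order[n_seed:])
    truth.seeded, truth.held_out = seeded, held
    return seeded, held


def write_fixtures(
    outdir: Path | str,
    net: WeightedNetwork,
    truth: PlantedTruth,
    ann: AnnotationMap,
    seeds: list[str],
) -> dict[str, Path]:
    """Write links/seeds/GMT/truth files in their external formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "links": outdir / "protein_links.txt",
        "seeds": outdir / "seeds.txt",
        "annotations": outdir / "annotations.gmt",
        "truth": outdir / "truth.json",
    }
    with open(paths["links"], "w") as fh:
        write_string_links(net, fh)
    with open(paths["seeds"], "w") as fh:
        fh.write("# synthetic seed genes\n")
        for s in seeds:
            fh.write(s + "\n")
    with open(paths["annotations"], "w") as fh:
        write_annotations(ann, fh)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "module": truth.module,
                "module_terms": truth.module_terms,
                "seeded": truth.seeded,
                "held_out": truth.held_out,
            },
            fh,
            indent=1,
        )
        fh.write("\n")
    return paths
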