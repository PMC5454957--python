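"""End-to-end prioritization: walk, threshold, permutation test, MIS/MFS filter.

The four stages run in a fixed order and every intermediate gene set is
retained, so a run's shape (how many genes survive each stage) is visible
from the logs and the result table without re-running anything:

1. random walk with restart from the seed genes;
2. keep genes with stationary probability > probability_threshold
   ("rwr genes");
3. permutation test, keep genes with p < alpha ("candidates");
4. keep candidates with MIS >= mis_threshold and MFS > mfs_threshold
   ("core genes").
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import IO, Mapping

from .association import (
    CandidateRecord,
    annotated_universe,
    enrichment_vector,
    max_function_score,
    max_interaction_score,
    select_core_genes,
)
from .network_io import AnnotationMap, SeedSet, WeightedNetwork, column_normalize
from .rwr import RwrConfig, build_initial_vector, random_walk_with_restart, select_rwr_genes
from .significance import filter_candidates, format_pvalue, permutation_pvalues

logger = logging.getLogger(__name__)

STAGE_ORDER = ("rwr_gene", "candidate", "core")


@dataclass
class PipelineConfig:
    """All tunables of the four-stage run; defaults are the published settings."""

    restart: float = 0.8
    tolerance: float = 1e-6
    probability_threshold: float = 1e-5
    n_permutations: int = 1000
    alpha: float = 0.05
    mis_threshold: int = 900
    mfs_threshold: float = 0.8
    rng_seed: int = 0
    exclude_seeds: bool = True

    def rwr_config(self) -> RwrConfig:
        return RwrConfig(
            restart=self.restart,
            tolerance=self.tolerance,
            probability_threshold=self.probability_threshold,
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**dict(mapping))  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, object]:
        return asdict(self)


@dataclass
class ResultTable:
    """Scorecards for every walk-selected gene, with stage flags.

    Stage sets are nested: core genes are candidates, candidates are rwr
    genes.  Candidates (including core) come first, ordered by p-value
    ascending then probability descending then ID; the remaining rwr genes
    follow by probability descending.
    """

    records: list[CandidateRecord]
    n_perm: int

    def by_stage(self, stage: str) -> list[CandidateRecord]:
        rank = STAGE_ORDER.index(stage)
        return [r for r in self.records if STAGE_ORDER.index(r.stage) >= rank]

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(self.by_stage(s)) for s in STAGE_ORDER}

    def genes(self, stage: str) -> set[str]:
        return {r.gene for r in self.by_stage(stage)}


def run_prioritization(
    cfg: PipelineConfig,
    net: WeightedNetwork,
    seeds: SeedSet,
    ann: AnnotationMap,
    artifacts_dir: Path | None = None,
) -> ResultTable:
    """Run the four-stage prioritization and return every gene's scorecard.

    Deterministic given ``cfg.rng_seed``: the permutation test is the only
    random stage and draws from one seeded stream.  When ``artifacts_dir``
    is given, the stationary probability vector, the per-gene permutation
    p-values and the result table are written there.
    """
    if len(seeds) == 0:
        raise ValueError("seed set is empty")
    rwr_cfg = cfg.rwr_config()

    model = column_normalize(net)
    p0 = build_initial_vector(net, seeds)
    stationary = random_walk_with_restart(model, p0, rwr_cfg)

    rwr_genes = select_rwr_genes(
        stationary, seeds, cfg.probability_threshold, exclude_seeds=cfg.exclude_seeds
    )
    logger.info("stage rwr_gene: %d genes above %g", len(rwr_genes), cfg.probability_threshold)

    perm = permutation_pvalues(
        net, model, seeds, rwr_genes, rwr_cfg,
        n_perm=cfg.n_permutations, rng_seed=cfg.rng_seed,
    )
    candidates = filter_candidates(rwr_genes, perm, cfg.alpha)
    logger.info("stage candidate: %d genes at alpha=%g", len(candidates), cfg.alpha)

    # MIS/MFS are only needed for candidates; enrichment vectors are computed
    # lazily for candidates plus seeds.
    universe = annotated_universe(net, ann)
    es_cache = {}
    if universe:
        for g in [g for g, _, _ in candidates] + list(seeds.ids):
            if g not in es_cache:
                es_cache[g] = enrichment_vector(g, net, ann, universe)

    candidate_records: dict[str, CandidateRecord] = {}
    for gene, prob, pval in candidates:
        mis = max_interaction_score(gene, seeds, net)
        mfs = max_function_score(gene, seeds, es_cache) if universe else 0.0
        candidate_records[gene] = CandidateRecord(
            gene=gene, probability=prob, p_value=pval,
            mis=mis, mfs=mfs, stage="candidate",
        )
    core = select_core_genes(
        list(candidate_records.values()), cfg.mis_threshold, cfg.mfs_threshold
    )
    for rec in core:
        rec.stage = "core"
    logger.info("stage core: %d genes (MIS>=%d, MFS>%g)", len(core), cfg.mis_threshold, cfg.mfs_threshold)

    ordered: list[CandidateRecord] = sorted(
        candidate_records.values(), key=lambda r: (r.p_value, -r.probability, r.gene)
    )
    for gene, prob in rwr_genes:
        if gene not in candidate_records:
            ordered.append(
                CandidateRecord(gene=gene, probability=prob, p_value=perm.pvalues[gene])
            )
    table = ResultTable(records=ordered, n_perm=cfg.n_permutations)

    if artifacts_dir is not None:
        artifacts_dir = Path(artifacts_dir)
        artifacts_dir.mkdir(parents=True, exist_ok=True)
        with open(artifacts_dir / "rwr_probabilities.tsv", "w") as fh:
            stationary.write_tsv(fh)
        with open(artifacts_dir / "permutation_pvalues.tsv", "w") as fh:
            fh.write("gene\tprobability\tp_value\n")
            for gene, prob in rwr_genes:
                fh.write(f"{gene}\t{prob:.6e}\t{perm.pvalues[gene]:g}\n")
        write_results(table, artifacts_dir / "results.tsv")
    return table


def _format_record(rec: CandidateRecord, n_perm: int) -> str:
    prob = f"{rec.probability:.2e}"
    pval = format_pvalue(rec.p_value, n_perm) if rec.p_value is not None else "NA"
    mis = str(rec.mis) if rec.mis is not None else "NA"
    mfs = f"{rec.mfs:.3f}" if rec.mfs is not None else "NA"
    return f"{rec.gene}\t{prob}\t{pval}\t{mis}\t{mfs}\t{rec.stage}"


def write_results(table: ResultTable, path: Path | str) -> None:
    """Write the result table as TSV.

    Probabilities are printed in scientific notation with three significant
    digits; a p-value of exactly zero renders as ``<1/n_perm``; the stage
    column carries the largest attained stage.
    """
    if not table.records:
        raise ValueError("result table is empty")
    with open(path, "w") as fh:
        fh.write("gene\tprobability\tp_value\tMIS\tMFS\tstage\n")
        for rec in table.records:
            fh.write(_format_record(rec, table.n_perm) + "\n")


def export_subnetwork(
    net: WeightedNetwork, genes: set[str], stream: IO[str]
) -> int:
    """Write the induced edge list over ``genes`` (e.g. seeds + core genes).

    Returns the number of edges written.  This is the plain-text stand-in
    for a network figure.
    """
    n = 0
    for u, v, s in sorted(net.edges()):
        if u in genes and v in genes:
            stream.write(f"{u}\t{v}\t{s}\n")
            n += 1
    return n
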