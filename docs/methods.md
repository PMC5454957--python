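# Methods

## Model

The toolkit ranks genes by proximity to a validated disease-gene set under
a restarted random walk on a weighted, undirected PPI network. Edge weights
are STRING-style integer combined scores in [150, 999]; the transition
matrix A is column-stochastic, A[i, j] = S(i, j) / Σ_k S(k, j), so a walker
on gene j steps to neighbor i in proportion to their interaction
confidence. The update

    p_{t+1} = (1 − r) · A · p_t + r · p₀

is a contraction with factor (1 − r): it converges geometrically to the
unique solution of (I − (1 − r)A) p = r p₀, conserves probability mass
exactly (column-stochastic A, Σp₀ = 1), and is independent of starting
point. We iterate from p₀ and stop at the first L1 step below the
tolerance; the returned vector then satisfies the fixed-point residual
bound ‖p − (1−r)Ap − rp₀‖₁ < 10·tolerance.

A note on the operator: the update is sometimes written with Aᵀ applied to
a "column-normalized" matrix. For a symmetric weight matrix that transpose
is row-stochastic and does not conserve probability mass; this
implementation multiplies by the column-stochastic matrix itself, which
reproduces the standard network-propagation fixed points (e.g. a star
seeded at the center yields 0.83333 / 0.05556 per leaf at r = 0.8).

## Parameters

| parameter | default | meaning |
|---|---|---|
| restart r | 0.8 | teleport mass per step; larger keeps mass near seeds |
| tolerance | 1e-6 | L1 convergence criterion (dimensionless probability) |
| probability_threshold | 1e-5 | strict cutoff defining RWR genes |
| n_permutations | 1000 | permutation count; p-value resolution 1/n |
| alpha | 0.05 | strict p-value cutoff for candidates |
| mis_threshold | 900 | inclusive cutoff on the max seed-edge score |
| mfs_threshold | 0.8 | strict cutoff on the max enrichment cosine |
| exclude_seeds | on | drop seeds from the ranked output (novel-gene focus) |

Boundary semantics are deliberate and configurable: the probability and
alpha cutoffs are strict, MIS is inclusive ("no less than 900" — STRING's
highest-confidence band starts at 900), MFS is strict. A candidate at
exactly (MIS 900, MFS 0.800) is kept by MIS and rejected by MFS.

## Permutation test

Null seed sets are drawn uniformly without replacement from **all** network
nodes (the true seeds are not excluded), each permutation re-running the
walk on the same transition matrix with only the restart vector changed.
Θ counts permutations whose probability for the gene strictly exceeds the
true-seed probability; ties favor the gene (anti-conservative, documented
rather than corrected). p-values therefore lie on the grid {0, 1/n, …, 1};
an exact 0 renders as "<1/n" in reports. One seeded generator stream drives
all draws and the drawn sets are retained on the result object for audit.
No multiple-testing correction is applied — candidates are filtered on raw
permutation p-values by design.

The production path batches all permutations as columns of one matrix
iteration, freezing each column at its own first convergence; this is
bitwise identical to re-running the walk per permutation (verified in the
acceptance suite against an explicit loop).

Implied regime constraint: a gene belongs to a uniform random seed set
with probability |seeds|/|nodes|, and while it is a seed its probability
(≥ r/|seeds|) dwarfs any non-seed stationary probability. The expected
null p-value of *any* gene is therefore at least |seeds|/|nodes|, and the
screen can only pass genes when |seeds|/|nodes| ≪ alpha (0.7% at the
method's original scale). Desk-scale fixtures must preserve that ratio:
at 60 nodes with 5 seeds (8.3% > alpha) the screen rejects everything, so
recovery experiments use 200-node fixtures (2.5% < alpha).

## Enrichment vectors, MIS and MFS

ES(g) scores, for every annotation term (GO terms and KEGG pathways are
concatenated on one axis), the over-representation of the term among g's
direct network neighbors: −log₁₀ P(X ≥ numWdrawn) with X hypergeometric
(universe = all network nodes carrying ≥ 1 annotation; numW annotated,
numDrawn neighbors in the universe). Conventions: numWdrawn = 0 scores 0
(no signal); a term annotating no universe gene scores 0; tail
probabilities are floored at 1e-300 before the log so scores stay finite;
a gene with no annotated neighbor gets the all-zero vector, and the cosine
of an all-zero vector is defined as 0 — such genes simply fail the MFS
filter instead of erroring. Neighborhood membership ignores edge weights
(no weight cutoff for "neighbor"). Enrichment vectors are computed lazily
for candidates plus seeds only. The hypergeometric tail comes from
scipy.stats.hypergeom; an exact combinatorial enumeration serves as the
independent test oracle.

## Cross-validation and baseline

The seed list is shuffled once per RNG seed and split into k near-equal
folds (sizes differ by at most one). Within each fold the *entire*
pipeline — walk, permutation test, MIS, MFS — sees only the training-fold
seeds; held-out IDs enter only the scoring. Zero-denominator metrics are
defined as 0. Per-fold and mean metrics are reported half-even at 3
decimals; raw values are retained internally. The guilt-by-association
baseline ranks each training seed's neighbors by edge weight (ties at the
k-th rank break by ID ascending), truncates to k, takes the union minus
the seeds, and grid-searches k over {1..10, 20..100}; F1 ties go to the
smallest k. The same partition object is reused so both methods see
identical folds.

## Synthetic fixtures

The generator emulates the one structural assumption the method exploits:
a disease module that is locally dense, high-confidence and functionally
coherent inside a sparse low-confidence background. Defaults (60 nodes,
10-gene module, intra-module edge probability 0.8 with scores 850–999
straddling the 900 cutoff, background probability 0.05 with scores
150–500) follow the stated fixture scale; values the stated world leaves
open were fixed once: 30 terms of which 6 are module terms covering 90% of
the module (disease annotations are coherent but not universal), each
leaking to 2 background genes (annotations are never clean), background
terms annotating 3–8 random genes. A spanning cycle guarantees module
connectivity and stray isolated nodes receive one background edge, so
every fixture satisfies the network invariants by construction. Scores are
integers, matching STRING. Fixtures are written in the real external
formats (links file, seed list, GMT) so end-to-end tests exercise the
actual parsers.

What a green planted-module test establishes: the pipeline concentrates
walk mass in a dense high-weight neighborhood of the seeds and the filters
retain functionally coherent direct interactors. What it does not
establish: behavior under scale-free degree distributions, annotation
bias, or the identifier noise of real interactomes — none of which the
generator attempts to mimic.

## Numerical choices

- Dense vs sparse: the transition matrix is stored sparse (CSR); at desk
  scale the matvec cost is negligible either way and the contract is
  identical.
- Determinism: identical inputs and RNG seed give bit-identical outputs
  end-to-end; all randomness flows through numpy Generator streams seeded
  from the config.
- Orderings are total and documented: RWR genes by probability descending
  then ID; candidates and core genes by p ascending, probability
  descending, ID; GBA neighbor ranks by weight descending then ID.
- Conflicting duplicate edge records are an error, not averaged; self-loop
  records are dropped with a warning (restart mass should not idle on a
  node, and self-interactions carry no association signal here).

## Known limitations

- Raw permutation p-values; no FDR control (faithful to the screened
  design, anti-conservative at the tie boundary).
- The permutation screen is uninformative when |seeds|/|nodes| ≥ alpha
  (see above) — a property of the test, not of this implementation.
- No GO-graph ancestor propagation; annotations are taken as given.
- Single homogeneous network only; no heterogeneous/multiplex walks.
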