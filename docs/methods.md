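# Methods

## Model

`pwcda` treats circRNA–disease association prediction as link prediction
on a two-layer heterogeneous network. The working hypothesis is
guilt-by-association: circRNAs with similar function (and diseases with
similar genetic basis) tend to share association partners, so unobserved
links are supported by short weighted paths through similarity
neighborhoods.

The network's three edge blocks are built as follows.

**Annotation (Jaccard) similarity.** For circRNAs, similarity is the
Jaccard index over the GO-term sets of their target genes; for diseases,
over their disease-gene annotation sets. Two conventions are fixed here:

* `jaccard(∅, ∅) = 0`, not 1 — an entity with no annotations carries no
  evidence of similarity, and a zero is exactly what routes the pair to
  the kernel fallback below.
* Diagonals are 1 for annotated entities and 0 for unannotated ones.
  This choice is immaterial for scoring: self-loops are masked at
  network assembly and paths are node-simple, so diagonals are never
  traversed, and after fusion the diagonal is 1 everywhere (the GIP
  diagonal is 1).

**GIP kernel similarity.** The Gaussian Interaction Profile kernel
`K(i,j) = exp(−γ ‖p_i − p_j‖²)` on binary association profiles (a
circRNA's profile is its column of `M` over diseases; a disease's its
row over circRNAs). The bandwidth `γ = γ′ / mean_i ‖p_i‖²` normalizes by
the mean squared profile norm over *all* entities, zero profiles
included; `γ′ = 1` by default for both entity classes. If the
association matrix is entirely zero (possible on tiny cross-validation
fixtures) the bandwidth is undefined; the identity kernel is substituted
with a warning, preserving "no evidence → no off-diagonal similarity"
rather than crashing.

**Fusion.** Integrated similarity keeps the annotation score wherever it
is non-zero and falls back to the kernel elsewhere. Annotation catalogs
are typically sparse — most pairs share no terms — and the fallback
gives every entity a usable similarity neighborhood, which is the
motivation for computing the kernel at all.

**Thresholding.** All three blocks pass through a uniform edge threshold
`γ_thr` (default 0.5): weights `< γ_thr` become 0, weights `≥ γ_thr` are
kept unchanged. The comparator is `≥`, so a weight exactly at the
threshold survives. Association edges weigh 1 and always survive;
`γ_thr` is restricted to [0, 1] so known associations cannot be deleted
silently. Thresholding is idempotent and monotone (edge sets are nested
as `γ_thr` grows), which the tests assert.

**Path scoring.** The score of a pair sums, over every node-simple path
of at most `η` edges (default 3) connecting them, the product of the
path's edge weights divided by `α·e^len`. The division realizes the
intended semantics — longer, more tenuous chains of evidence contribute
exponentially less. Because `α` rescales every score by the same
constant, rankings and any AUC computed from them are exactly
`α`-invariant; the test suite asserts bitwise-identical CV AUC across
`α ∈ {0.5, 1, 2, 5}`. The decay lives in a single function
(`pathscore.decay`) so alternative decays can be swapped in for
comparison.

All node-type sequences are admitted (c–d, c–c–d, c–d–d, c–c–c–d,
c–c–d–d, c–d–d–d at `η = 3`); the only exclusion rule is the length
bound.

## Numerical and algorithmic choices

* **Closed form for η ≤ 3.** With a zero diagonal, every length-1 and
  length-2 walk between distinct endpoints is automatically node-simple,
  and the non-simple length-3 walks are exactly those revisiting the
  source (`A²[u,u]·A[u,v]`) or passing through the target
  (`A[u,v]·A²[v,v]`), double-counting the `u→v→u→v` walk (`A[u,v]³`).
  The full score matrix therefore comes from three matrix products plus
  an inclusion–exclusion correction. The depth-first search the method
  describes (mark on entry, unmark on backtrack, neighbors in ascending
  node index for determinism) remains the implementation of
  `enumerate_paths` and the fallback for `η > 3`; tests assert the two
  routes agree with an independent exhaustive enumerator to 1e−12.
* Scores use ordinary double precision; at `η = 3` path counts are
  bounded by degree³, so no log-space arithmetic is needed.
* Similarity matrices are symmetrized exactly (`(K + Kᵀ)/2`, diagonal
  forced to 1) to keep downstream symmetry assertions exact.
* ROC curves sweep the distinct score values (scikit-learn's sweep with
  no points dropped); the trapezoidal AUC equals the Mann–Whitney
  statistic with tied scores counted 1/2, which the tests verify against
  brute-force concordant-pair counting.
* Ranked outputs break score ties by (disease id, circRNA id) so files
  are byte-reproducible.

## Cross-validation protocol

Positives are verified associations. LOOCV removes one association at a
time; diseases with a single known association are skipped and reported.
k-fold partitions positives uniformly at random under a caller-supplied
seed. Per fold, the GIP kernels, fused similarities and thresholded
network are recomputed from the training matrix only — a kernel that saw
the held-out edge would leak the label into its own score. Jaccard
similarities never touch associations and are computed once.

Negative pairs (never held out) are by default rescored under the fold
training models and averaged — over the folds of their own disease in
LOOCV, over all k folds in k-fold. The rationale: a held-out positive is
scored on a network where both its endpoints have lost one degree;
pooling it against negatives scored on the full-degree network
systematically underranks positives when degrees are small (on the
bundled synthetic data this bias pushed positives *below* matched
same-block negatives). Rescoring negatives under the same training
models removes the asymmetry at no extra cost, since the full score
matrix is computed per fold anyway. The simpler convention — negatives
scored once under the all-data model — remains available as
`negative_scoring="full"`.

## Synthetic data: what it emulates, and what it does not

The generator plants latent blocks: associations are drawn independently
with probability 0.35 within a block and 0.03 between blocks (40
circRNAs × 12 diseases, 3 blocks by default), and annotated entities
draw term sets mostly from a block-specific pool so within-block Jaccard
overlap is high. This is the minimal statistical regime under which
guilt-by-association provably helps, and it makes every pipeline stage
exercisable offline, including the kernel fallback (5% of entities carry
no annotations by default).

Free parameters were chosen so the planted structure survives the
pipeline's own operating point: term pools hold
`n_terms/(n_blocks+1) = 12` terms and entities draw a full pool-sized
set with 90% of draws from their own block pool, putting expected
within-block Jaccard well above the 0.5 edge threshold while
between-block overlap stays near zero. Under these defaults LOOCV AUC
exceeds 0.8 for generator seeds 1–5 (asserted in the test suite,
deterministically). Default sizes keep a full LOOCV with per-fold
rebuilds under a second on one CPU; the acceptance script uses the same
sizes.

What passing on this generator does **not** show: real curated data has
heavy-tailed degree distributions (many circRNAs with a single known
association), hierarchical rather than flat disease structure,
annotation sets of widely varying size and quality, and alias/curation
noise. Results on the synthetic benchmark demonstrate correctness and
recoverability of planted structure, not expected performance on a
specific curated database.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `α` | decay constraint factor | 1 | rescales all scores; AUC-invariant |
| `η` | maximum path length (edges) | 3 | longer paths add noise and cost |
| `γ_thr` | edge-weight threshold | 0.5 | applied uniformly to all blocks |
| `γ′` | GIP bandwidth scale (per entity class) | 1 | bandwidth = `γ′`/mean ‖profile‖² |
| `k` | folds in k-fold CV | 5 | seeded partition |

## Known limitations

* Identifier normalization is trim + casefold only; aliases
  (`circpvt1` vs `hsa_circ_0001821`) are distinct entities unless the
  input resolves them.
* Entities with no verified association cannot be scored (they have no
  kernel profile and drop out of the association table).
* Species filtering is the only curation rule exposed; curated datasets
  produced with additional unstated filters will not be reproduced
  exactly from raw extracts.
* The method favors well-connected neighborhoods; predictions for
  single-association entities rest on similarity edges alone and are
  correspondingly weaker.
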