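# Methods

`trntopo` analyzes directed, signed, evidence-annotated transcriptional
regulatory networks (TRNs) at three scales: mesoscale community
structure, 3-node motif statistics, and the link-level interplay between
topology and experimental evidence. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Data model and projections

A network is a set of nodes (genes or operons) with a mandatory
regulatory role (`transcription_factor`, `sigma_factor`, `target_only`)
and an optional functional-category label, plus at most one directed
edge per ordered pair. Edges carry a sign in {+1, −1, unknown} and a set
of evidence tags, each tag classified as a binding assay (`BA`) or a
target-expression-level comparison (`TELC`). Self-regulations
(self-loops) are legal and book-kept separately from ordinary links.

Three views project the same network: **DS** (directed signed — only
known-sign edges, weight = sign), **DU** (directed unsigned — every edge
at weight 1), **UU** (undirected unsigned — OR-symmetrized, so a mutual
dyad collapses to one undirected link). Unknown-sign edges appear in
DU/UU but never in DS: signs are data, not something to impute.
Duplicate rows in an edge list merge by unioning evidence; duplicate
rows with contradictory signs are an error rather than silently
resolved.

## Signed, directed, multi-resolution modularity

Partition quality is the signed modularity

    Q = w⁺/(w⁺+w⁻) · Q⁺ − w⁻/(w⁺+w⁻) · Q⁻ ,

where Q± accumulates, over same-community ordered pairs (i, j), the
deviation of the positive (negative) weights from a strength-preserving
null: for directed matrices the null term is
out-strength(i)·in-strength(j)/w±, which reduces exactly to the
familiar undirected k_i k_j / 2w form on symmetric matrices — one
formula serves DS, DU and UU. Positive links pull nodes together;
negative links push them apart. Diagonal entries (self-loops and the
resolution rescaling below) enter both the strengths and the internal
sums. Q of the single-community partition is identically 0, which
anchors the scale.

Resolution is controlled by a uniform self-loop: `A_r = A + I·r`.
Negative `r` zooms out (coarser modules), positive `r` zooms in. A
**screen** optimizes Q on an `r`-grid (default 200 points; each point
gets a deterministic child seed of the master seed) and records
(r, normalized r, partition, Q); a **plateau** is a maximal run of at
least `min_run` grid points (default 5% of the grid — "persistent" is
a convention, not a derived quantity) with identical module count.
When rescaling signed matrices, positive `r` contributes to w⁺ and
negative `r` to w⁻.

The optimizer seeds each restart with greedy pair-merging
agglomeration, refines it with a stochastic extremal-optimization-style
stage that preferentially relocates low-fitness nodes, and finishes
with exhaustive single-node sweeps. The returned partition is
guaranteed locally optimal: no single node can move to any existing or
empty community and increase Q. Accepted steps never decrease Q; ties
break toward the lowest community index; all randomness flows from the
seed, so results are reproducible. Three restarts are the default —
on every ≤8-node instance we test, the result matches exhaustive
search over all partitions.

Partitions are compared with the **Asymmetric Wallace index**

    AW(A, B) = Σ_αβ M_αβ(M_αβ−1) / Σ_α M_α·(M_α·−1) ,

the probability that a pair co-clustered in A is co-clustered in B
(M is the confusion matrix on the common node set). The denominator is
the number of co-clustered ordered pairs of A, which makes AW(A, A)=1
and makes the index meaningful when A is much more divisive than B —
the normal situation when a ~200-module topological partition is
compared against a 7-category functional classification. AW is
undefined (returned as `None`, never a number) when A has only
singleton clusters. Functional comparisons first drop unannotated
genes and the transversal labels (`conserved_hypothetical`, `unknown`,
`regulatory_proteins`, `information_pathways`).

## Triad statistics

The 13 connected 3-node digraph classes are fixed package data,
verified by exhaustively enumerating all 2⁶ labelled 3-node digraphs
and grouping by isomorphism. Index anchors: 1 divergence, 2
convergence, 3 cascade (A→B→C), 7 feed-forward loop, 8 directed
3-cycle; the eight classes containing at least one mutual dyad occupy
{4, 5, 6, 9, 10, 11, 12, 13}, ordered by (number of mutual dyads,
number of arcs).

The census is computed in closed form from dyad-type matrix products
(mutual part M = A∧Aᵀ, single part S = A−M, null part): every class
count is a handful of dense O(n³)-flop BLAS products, which keeps
1000-sample null ensembles at n≈500 inside desk runtime. The
implementation is continuously checked against two independent routes:
`networkx.triadic_census` and brute-force isomorphism classification of
every triple. Self-loops are stripped before any triad computation,
and signs are ignored (triad statistics live on directed unsigned
structure).

**Null model.** Degree-preserving edge switching that randomizes
single (non-reciprocated) edges and mutual dyads by *separate* swap
moves, rejecting any proposal that would create a self-loop, a
duplicate edge, or convert singles into mutuals. Every node therefore
keeps its (single-out, single-in, mutual) degree triple and the global
mutual-dyad count is conserved — in particular a feedback-free network
stays feedback-free in every sample. Defaults: ensemble size R = 1000
and 100 attempted switches per edge, conventions of the motif
literature; the tests and pipeline use smaller values (stated below)
after checking the ensembles are well mixed (original/sample edge
overlap ≈ 25% at 10 switches per edge).

**Z-scores and TSP.** Z_h = (n_h − ⟨n_rand,h⟩)/σ_rand,h with the
sample standard deviation (ddof = 1). σ = 0 — compared exactly, which
integer counts make unambiguous — yields an *undefined* entry,
reported as such and propagated (NaN internally). This is the
mechanism behind the degenerate profiles of feedback-free networks:
the null ensemble can never produce a mutual-containing triad, so all
eight such classes are undefined. The triad significance profile (TSP)
divides the defined entries by their Euclidean norm; profiles are
compared by Pearson correlation over mutually defined indices,
undefined when fewer than three are shared.

## Suspicious links, WCLs, and the correction

Expression-based inference cannot distinguish a direct regulation
u→w from an indirect influence through a secondary pathway. An edge
u→w is **suspicious** when some two-link cascade u→v→w (v distinct
from both endpoints) exists with sign(u→v)·sign(v→w) = sign(u→w);
only two-link pathways are considered, unknown-sign edges neither
flag nor serve as legs, and witnesses are recorded per edge. A link is
**well-characterized** (WCL) iff its evidence contains at least one BA
and at least one TELC tag.

Every signed non-self-loop link is cross-classified into the 2×2 table
(suspicious vs not) × (WCL vs not) = (a, b, c, d). The hypothesis that
suspicious links are depleted of WCLs is tested one-sided: p =
P(X ≤ a) for hypergeometric X with the table's margins, evaluated in
log space (`scipy.stats.hypergeom.logcdf`), exact for arbitrarily
small tails. A zero margin returns p = 1 with a `degenerate` flag.
The one-sided direction is a deliberate choice: the depletion
hypothesis is directional, and the test is exposed as such.

The **correction** deletes the largest x ≤ b with

    a/(a+b−x) ≤ (a+c)/(a+b+c+d),

computed in exact integer arithmetic — deleting x poorly characterized
suspicious links pairs the WCL fraction among the remaining suspicious
links to the whole-network background. On the three published
contingency tables this rule gives x = 324 (E. coli), 59
(B. subtilis) and 114 (M. tuberculosis). `apply_correction` deletes x
uniformly random non-WCL suspicious links (seeded) and recomputes
Z-scores and TSPs before and after. A sigma-excluded variant reruns
the contingency analysis after removing sigma-factor nodes and their
incident edges, flagging the result non-conclusive when the suspicious
set collapses.

## Synthetic benchmark

The generator emulates what bacterial TRNs look like at large scale,
with planted ground truth so each analysis stage has a recoverable
target:

| parameter | default | rationale |
|---|---|---|
| `n_nodes` | 1000 | E. coli-operon scale |
| `regulator_fraction` | 0.08 | regulators are a small minority |
| `out_degree_exponent` | 2.0 | heavy-tailed out-degrees (global hubs) |
| `out_degree_cap_fraction` | 0.25 | even the largest regulons cover a minority of the genome |
| `mean_in_degree` | 2.5 | E. coli 2011-scale L/N ≈ 2.5 |
| `n_modules`, `p_in`, `p_out` | 5, 0.3, 0.01 | planted community structure |
| `negative_sign_fraction` | 0.35 | a substantial minority of inhibitions |
| `n_planted_ffl` / `cascades` / `mutual` | 250 / 100 / 12 | planted motif content; 12 matches the scale of curated feedback counts |
| `wcl_background_rate` | 0.26 | E. coli WCL fraction ≈ 0.255 |
| `wcl_suspicious_deficit` | 0.10 | intermediate among the three curated systems |
| `functional_mixing` | 0.10 | functional labels disagree with modules 10% of the time |
| `sigma_fraction` | 0.15 | some regulators are sigma factors |

Construction: out-degrees are drawn from a truncated discrete power
law and rescaled (capped water-filling) so the expected link total is
`mean_in_degree · n_nodes`; each regulator's targets are sampled
without replacement with weights proportional to `p_in` within its
module and `p_out` outside. The three published constraints —
power-law out-degrees, Bernoulli module-biased placement, and a fixed
mean in-degree — cannot all hold verbatim simultaneously; this
two-stage construction keeps the degree heterogeneity and the module
assortativity while hitting the in-degree target (realized mean within
10% over 20 seeds). Planted FFLs/cascades/mutual dyads are added as
exact subgraphs; mutual dyads are planted among a small pool of hub
regulators, mirroring the concentration of feedback loops on globally
acting, cross-regulating regulators — endpoint sharing is also what
lets the 2- and 3-mutual triad classes fluctuate in the null ensemble
at all. `forbid_feedback=True` emits a strictly reciprocation-free
topology for degenerate-ensemble studies.

Signs are i.i.d. negative with probability `negative_sign_fraction`,
except the direct edge of each planted FFL, which is set to the product
of its path signs — planted FFLs are therefore sign-coherent and land
in the suspicious set by construction. Evidence is assigned per link by
a single Bernoulli draw on WCL status at rate `wcl_background_rate`
(minus the deficit inside the suspicious set), then tags consistent
with that status; this hits the target rates exactly, which a pair of
independently tuned BA/TELC flags would only approximate. Every link
carries at least one tag.

**What the synthetic data do not emulate:** curated evidence is not
independent across links from one study; real degree sequences, operon
structure, autoregulation and condition-dependent signs are absent;
functional categories are module-derived rather than ontology-derived.
Passing the recovery tests therefore shows the *methods* are correct
and well-calibrated, not that any specific biological conclusion
transfers to a particular database release.

## Problem sizes and numerical choices

- Resolution screens in tests: 20–100 grid points, 100 at acceptance;
  plateau `min_run` 5% of the grid.
- Null ensembles in tests: R = 30–200, 5–10 switches per edge; the
  correction experiment uses R = 80 per side over 10 seeds. These sizes
  were chosen after checking mixing and Monte-Carlo noise (std of the
  FFL Z-score across master seeds < 0.75 at R = 200 on the planted-FFL
  fixture).
- Motif-analysis synthetics use `out_degree_exponent = 3.0` and
  `out_degree_cap_fraction = 0.15` at n = 500 with 120 planted FFLs:
  under heavier-tailed hub distributions the degree-sequence null
  already expects hundreds of FFLs and a planted excess of desk-scale
  size would sit below ensemble noise. The evidence-bias experiments
  keep the heavier default tail, whose hub-generated two-paths supply
  the realistic suspicious-link background (~1100 suspicious of ~2900
  signed links at the defaults).
- Type-I error / power of the full bias pipeline: over 200 seeds the
  one-sided test fires at 4–5% with no planted deficit and at 100%
  with a 0.15 deficit (≥300 suspicious links per run).
- The correction experiment (10 seeds): mean |Z| of cascades and FFLs
  shrinks after deletion while the mean before/after TSP correlation
  stays ≥ 0.9 — individual seeds range ~0.84–0.98, so the profile
  claim is an ensemble statement, not a per-realization guarantee.
- Modularity identity Q = (w⁺Q⁺ − w⁻Q⁻)/(w⁺+w⁻) is asserted to 1e-12;
  optimizer acceptance threshold 1e-12; exhaustive-search agreement to
  1e-9.
- Float32 BLAS in the census is exact: all counts are integers far
  below 2²⁴.

## Known limitations

- Modularity optimization is heuristic; for n in the thousands the
  O(n²)-per-sweep moves and O(n³) agglomeration dominate runtime, and
  the global optimum is not certified beyond exhaustive-search scale.
- The switching null is a Markov chain; mixing is checked empirically
  (edge overlap), not by a theoretical bound.
- The suspicious-link rule considers only two-link secondary pathways
  and cannot identify *which* flagged links are truly spurious — the
  correction is statistical, deleting uniformly at random among the
  poorly characterized suspicious links.
- Parsers accept only the package's TSV dialects; native dumps of
  curated databases must be converted externally, and no
  gene-identifier normalization or operon mapping is attempted.
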