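# Methods

## Scope and model

`dream` evaluates the druggability of a two-condition disease dataset and
searches for drug combinations. The pipeline's layers are deliberately
decoupled — each writes plain TSV consumed by the next — so any layer can
be replaced by user-supplied data (e.g. a protein–protein interactome
instead of the inferred co-expression network, or externally built drug
perturbational networks).

### Disease-gene selection

Per gene, two independent two-sided tests between disease and control
samples:

* **Location.** Wilcoxon rank-sum. The null distribution is exact
  (enumeration-equivalent) when min(n₁, n₂) ≤ 8 and the pooled values have
  no ties; otherwise the normal approximation with midranks, tie-corrected
  variance and continuity correction is used. A gene constant across all
  samples is reported with p = 1 and flagged. The exact/approximate switch
  at 8 keeps the exact path within a few hundred enumerable arrangements.
* **Stability.** Variance-ratio F = s²_disease / s²_control with sample
  variances (denominator n − 1) and two-sided
  p = 2·min{P(F ≤ f), P(F ≥ f)} capped at 1. A zero variance in either
  group makes the ratio degenerate; such genes are flagged and excluded
  from multiplicity adjustment rather than given an arbitrary p.

P-values are Benjamini–Hochberg adjusted **within each test family**, and a
gene is selected when its adjusted p falls below the FDR level α (default
0.05) under a configurable combination rule. The default is the **union**
(significant in level OR stability): the two tests probe complementary
alterations and either is disease-relevant. Intersection and single-test
modes are provided because the opposite reading — using the F-test to
*remove* unstable genes — is also defensible; users choose via `--mode`.

Assumptions: expression is already normalized (log scale); samples are
exchangeable within condition; no covariates or pairing.

### Consensus co-expression network

Each of five methods ranks every unordered gene pair (rank 1 = strongest):

* Pearson and Spearman, ranked by |correlation|;
* CLR, ARACNE and MRNET on a shared mutual-information matrix estimated by
  equal-width binning with ⌈√n⌉ bins per gene (parameter-free and exactly
  reproducible; no density estimation bandwidths to tune).

CLR scores an edge by √(max(0,zᵢ)² + max(0,zⱼ)²) where zᵢ is the MI
z-scored against gene i's off-diagonal background. MRNET uses
max-relevance-min-redundancy forward selection per target gene, scoring
each pair by the larger of its two directional selection scores. ARACNE
applies the data-processing inequality with tolerance 0: in every triangle
the weakest edge (strictly below the minimum of the other two on the raw
MI matrix) is pruned. One design choice deviates from the common "set
pruned edges to zero" formulation: a pruned edge is demoted strictly below
every kept edge but pruned edges remain ordered by their MI. Collapsing
~95% of the pair universe into a single tied score would make the ARACNE
ranking almost uninformative to rank aggregation, and indirect-but-strong
dependencies are still more plausible edges than pure noise; the demotion
preserves exactly which edges DPI rejects while keeping the ranking
usable as an ensemble vote.

Rankings are combined by Borda aggregation (consensus score = mean of
per-method ranks; ties broken lexicographically by edge label, so the
consensus is deterministic). The consensus is cut to a network by `top_k`
or `top_frac` (default top 5% of pairs); kept edges get weight
1 − (rank−1)/E ∈ (0, 1] and isolated genes are dropped.

Known behavior: ARACNE and MRNET are structurally weak on clique-like
modules (DPI prunes triangle edges by design; MRNET penalizes redundancy),
so their standalone precision on dense blocks is low. The consensus is
dominated by the methods that rank block edges highly, which is the point
of the ensemble.

### Mechanism-of-action distance (HIM)

Two perturbational networks are first aligned on the union of their node
sets (nodes absent from one network are isolated in it); a `binarize` flag
thresholds weights at > 0 (off by default — weights carry information).
Then, over the common N nodes:

* **Hamming** H = Σ_{i<j} |a_ij − b_ij| / C(N,2): the local, edge-wise
  term, in [0, 1] by construction.
* **Ipsen–Mikhailov** IM: each graph's Laplacian L = D − W yields
  frequencies ω_i = √λ_i (the null mode λ₁ = 0 is dropped; eigenvalues
  above −10⁻⁹ are clipped to zero, anything lower is an error). The
  spectral density is a sum of Lorentzians of half-width γ,
  ρ(ω) = K Σ_{i≥2} γ/((ω−ω_i)² + γ²), normalized analytically on [0, ∞)
  via K⁻¹ = Σ_i (π/2 + arctan(ω_i/γ)). IM is the L2 distance between the
  two densities, integrated by adaptive quadrature on [0, ω_max + 20γ]
  with absolute tolerance 10⁻⁸ (beyond that point both densities are in
  their common 1/ω² tails and the squared difference is negligible).
* **Width calibration.** γ is the unique width at which
  IM(empty_N, complete_N) = 1, found by Brent root-finding on
  [10⁻⁴, 10] to 10⁻¹⁰ and cached per N. This anchors IM (and hence HIM)
  to [0, 1] for every pair of N-node graphs.
* **HIM** = √(H² + ξ·IM²)/√(1+ξ). The mixing weight defaults to ξ = 1
  (equal local/global contribution) and is exposed as a parameter since no
  canonical value exists; ξ → 0 recovers H and ξ → ∞ recovers IM.

### Chemical similarity

All comparisons canonicalize SMILES first, so results are properties of
the molecule, not of its encoding. Defaults follow common practice: ECFP
radius 2 (ECFP4-equivalent), 1024 bits. Tanimoto is |A∩B|/|A∪B| on on-bit
sets, with the both-empty pair defined as similarity 1 (identical objects;
logged as degenerate). MCS uses a connected common substructure under
element and exact bond-order/aromaticity matching (an aromatic ring never
matches its saturated counterpart), similarity = mcs/(a₁+a₂−mcs), with a
10 s timeout that flags results as approximate. Levenshtein is unit-cost
edit distance on canonical SMILES, normalized by the longer string by
default; the raw-string operator is exposed for testing. Distances are
1 − similarity.

### Disease-network topology

* Area of action = |(targets ∩ V) ∪ neighbors| / |V|. Targets outside the
  network are ignored (libraries routinely exceed the disease gene
  universe); their count is reported.
* Target-pair distance between two drugs = mean unweighted shortest-path
  length over all cross pairs of in-network targets (a shared target
  contributes 0; within-drug pairs are never counted). Unreachable pairs
  are excluded from the mean and counted (default) or penalized with |V|;
  hop counts are the default because edge weights are confidence scores,
  not distances, but a flag switches to 1 − weight lengths.
* Combination coverage = area of action of the pooled target set (no
  double counting).

### Combination search (NSGA-II)

Chromosomes are membership bit-vectors over the library; repair keeps
2 ≤ |S| ≤ max_size (default 4) by seeded random add/drop. Objectives:
f₁ = |S| (minimize), f₂ = mean pairwise HIM, f₃ = mean pairwise chemical
distance (Tanimoto-based by default; MCS or Levenshtein matrices can be
substituted), f₄ = combination coverage, f₅ = mean pairwise target
distance. Directions default to minimize size and maximize the rest —
parsimony plus complementary mechanisms, chemotypes and exposure — and
every direction is individually flippable because no canonical orientation
exists; "maximize f₅" follows the network-pharmacology rationale that
effective combinations hit separated neighborhoods of the disease network.

The engine is standard elitist NSGA-II: fast non-dominated sorting,
crowding distance, binary tournament on (rank, crowding), uniform
crossover (p = 0.9), per-bit mutation (p = 1/L), μ+λ survival. Defaults
pop = 100, generations = 200 are sized for libraries up to ~100 drugs on a
desktop. All randomness flows from one seeded generator; identical
configuration and seed give byte-identical output. The reported front is
the final population's first front, deduplicated by subset — adequate
whenever the true front fits the population (see fixtures below); an
external archive would be needed beyond that.

## Synthetic fixtures: what they emulate and what they do not

`make_expression` plants three disjoint structures in i.i.d. standard
normal background: co-expression blocks (multivariate normal, constant
within-block correlation ρ, present in both conditions), location-shifted
genes (disease mean + δ·SD) and variance genes (disease variance × κ).
Defaults — 150 genes, 20 samples per condition, three 8-gene blocks with
ρ = 0.9, 25 shifted genes at δ = 2, 20 variance genes at κ = 4 — give a
mid-sized study in which both tests have realistic (not saturated) power.
Calibration and recovery checks use explicitly stated sizes: 1000 genes at
10+10 samples for null calibration, and 40 genes / three 6-gene blocks at
100 samples per condition for ensemble recovery (consortium-scale panels).

`make_drug_library` draws real small-molecule SMILES from a fixed list and
derives drug i's perturbational network by i·3 seeded edge rewires of the
base network, giving a monotone HIM ground truth. Targets are assigned
round-robin over network nodes. The **disease-network fixture** is the
planted cliques plus one bridging edge between consecutive blocks: real
co-expression networks are largely connected, and a connected base keeps
every topological distance defined (on the disconnected clique-only truth
network, many drug pairs have no reachable target pairs, their distances
are undefined, and nearly all subsets become mutually incomparable). The
clique-only network remains the inference ground truth.

What passing tests do **not** show: real transcriptomics has heavier tails,
batch structure and correlated noise none of which the generator emulates;
real perturbational networks differ from a disease network by biology, not
by uniform rewires; and the toy library's 24 molecules do not probe MCS
scalability on large ring systems.

## Numerical choices and degenerate inputs

* TSV floats are written as `%.17g` and parsed in round-trip mode, so
  writer/reader pairs are exact for float64.
* Distance matrices store labels in lexicographic order; equal objects
  have identical on-disk representations.
* Duplicate gene rows keep the maximum-variance row; duplicate edges keep
  the maximum weight; self-loops are dropped with a logged count.
* Constant genes: rank-sum p = 1 (flagged); F-test excluded from BH.
* CLR rows with zero MI spread use σ = 1 to avoid division by zero.
* Mean-rank ties in the consensus break lexicographically by edge label.
* GA evaluation is cached by chromosome, and subsets are deduplicated
  before reporting.

## Problem sizes

The shipped test-suite and acceptance-script sizes (150–1000 genes, 10–100
samples per condition, 8–12 drugs, GA populations of 100 over 200
generations, exhaustive enumeration over the 375 feasible subsets of a
10-drug library) were chosen so every ground-truth comparison — including
brute-force oracles — runs comfortably on a single CPU while leaving the
statistical properties measurable.

## Known limitations

* No probe-to-gene mapping, normalization, covariate adjustment or paired
  designs; inputs are assumed analysis-ready.
* Network inference is undirected and non-causal; no bootstrapping.
* MOA comparison requires pre-built perturbational networks (built with
  this package's inference on profile matrices, or supplied as edge
  lists); no LINCS/PubChem/Zenodo retrieval.
* No dose modeling, synergy scoring or toxicity objectives in the GA.
* The γ calibration makes IM values comparable only within a common N;
  alignment enforces a common N per pair, but HIM values for pairs of very
  different sizes reflect the padded union graphs.
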