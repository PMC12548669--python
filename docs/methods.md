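# Methods

## Model and procedure

`mbnet` treats a group's PET data as a matrix `X ∈ ℝ^{N×d}` of SUVR values
(N subjects, d VOIs) and defines the group's metabolic brain network as a
weighted undirected graph on the VOIs whose edge weights are intersubject
Pearson correlations.  Two constructions are provided.

**Conventional.**  One Pearson adjacency on the full table; two-sided
p-values from the exact t-transform `t = r√((N−2)/(1−r²))` with N−2 degrees
of freedom; Benjamini–Hochberg FDR over the d(d−1)/2 upper-triangle edge
tests at level α; rejected edges are zeroed.  Weights stay signed in
[−1, 1]; the diagonal is zero by convention (self-correlations are not
edges, and graph measures assume no self-loops).

**Multiple sampling (MS).**  `n` resampled datasets are drawn — bootstrap
(size N, with replacement) or subsample (fraction of N, without
replacement; default fraction 0.8) — and one FDR-corrected network is built
per draw.  A representative is then *selected from the ensemble* (never
averaged):

* `mean` / `median` criterion — the member minimizing the Frobenius
  distance to the elementwise mean / median matrix;
* `mode` criterion — the member of maximum estimated density in matrix
  space, scored by the mean Frobenius distance to its ⌈√n⌉ nearest members
  (a k-NN density surrogate; the three criteria are statistically
  interchangeable in the stability experiments, so the surrogate's
  simplicity costs nothing).

Ties in every argmin break to the lowest ensemble index, for determinism.

**Pmap threshold.**  The ensemble also yields a probability map: per edge,
the fraction of members in which the edge survived FDR (every entry an
exact count k/n).  With θ = 1 − α, edges whose occurrence is *strictly*
above θ are retained and all others zeroed (Hadamard mask).  The combined
FDR + Pmap correction is provably never less conservative than FDR alone on
the representative, since masking can only remove edges.

## Outlier-attack stability protocol

An attack appends L = round(p_o/100 · N) rows (minimum 1 when p_o > 0) to
the table that produced the network, sampled without replacement from the
two other diagnostic groups, split half/half (odd L resolved by a seeded
draw).  For the conventional method the rows are appended to `X`; for MS
methods they are appended to the representative's own source sample `Y^q`
(recovered from the recorded draw indices) — no new ensemble is built.
The perturbed table is then re-run through Pearson + FDR at the same α and
the displacement is measured by dF, dH (matrices) and dE, dC
(graph-feature vectors).  Attack q's outlier draw depends only on
(seed, q), so experiments differing only in construction method see
identical transplanted rows: matched perturbation pairs.

**Correction depth under attack.**  By default the Pmap mask computed from
the *unperturbed* ensemble is applied to both the representative and each
perturbed network (`apply_pmap=True`).  The mask is part of the proposed
network definition, and applying the same fixed mask to both sides compares
the same object before and after the attack; masking only one side would
measure the depth difference between corrections, not stability.  Setting
`apply_pmap=False` compares both sides at FDR-only depth — used in the
size-sweep experiment so that MS and conventional curves are at equal
correction depth (at small N the consensus mask empties and would flatten
the MS curve to zero trivially).  Either way the conventional method is
FDR-only, as its definition prescribes.

Graph features follow the standard weighted-network conventions: global
efficiency uses shortest paths on edge lengths 1/|w| (signed weights enter
via magnitude, keeping lengths positive); degree, clustering and
assortativity are computed on the binarized nonzero-edge graph; strength
averages per-node sums of |w|.  Degenerate cases: the empty graph reports
all-zero features; an undefined assortativity (no degree variance) is
reported as 0 with a warning flag.  Canberra terms with both entries zero
contribute 0.  The Hausdorff distance reads the matrices as sets of row
vectors (rows equal columns by symmetry), so it is invariant to node
reordering and zero iff the row sets coincide.

## Imbalance handling

Random undersampling draws every larger group down to the smallest group's
size, without replacement — no synthetic values are introduced.  ADASYN
oversampling grows each minority group to the majority size: each minority
point's generation budget is proportional to the fraction of out-of-group
points among its k = 5 nearest pooled neighbours (largest-remainder
apportionment, so the deficit is met exactly — naive rounding collapses
small budgets to zero), and each synthetic row is `x_i + λ(x_z − x_i)`,
λ ~ U(0,1), with `x_z` one of `x_i`'s k nearest *within-group* neighbours;
synthetic rows therefore lie on segments between original same-group rows
and are flagged by a `syn|` id prefix.  A perfectly separated minority
(no out-of-group neighbours anywhere) falls back to a uniform budget.

## Ensemble-size tuning

The only free parameter of the MS scheme is n.  `tune_n` walks a grid of k
values, builds independent ensembles at n = k and n = k + 100 (fresh child
seeds), and records the Bhattacharyya distance `dB = −ln Σ√(p_i q_i)`
between their degree distributions (shared integer bins 0..d−1; dB capped
at 700 for disjoint supports so traces stay finite).  The selected n is the
k minimizing dB, ties to the smallest k.

By default the degree distribution is *pooled over all ensemble members*
(one observation per node per member).  The pooled histogram converges at
the ensemble's Monte-Carlo rate, giving the asymptotic dB decay the
convergence criterion relies on; measured on the desk cohort, the pooled
trace decays cleanly (Spearman ≈ −0.9 over k = 100..1000) whereas the
representative-only variant (`distribution="representative"`, also
provided) does not decay over that range, because the fluctuations of a
single selected member shrink far more slowly in n.

## Synthetic cohort generator

The generator emulates group-structured SUVR tables with a multivariate
normal per group: VOIs partitioned into blocks (modules), block-constant
correlation (ρ_in within, ρ_out between; positive definite whenever
0 ≤ ρ_out ≤ ρ_in < 1), common marginal SD, and per-group per-block mean
offsets.  Pearson networks are exactly parameterized by this family, which
is what makes parameter-recovery tests meaningful.  Positivity of SUVR is
obtained by the baseline offset, not truncation (truncation would distort
the correlations being recovered).

Committed default study conditions (chosen once, as plausible for
pons-referenced FDG-PET, and not revisited):

| parameter | default | rationale |
|---|---|---|
| baseline | 1.2 | plausible pons-referenced SUVR level |
| noise SD | 0.12 | ~10% coefficient of variation |
| blocks | 6 equal | lobe-like modular structure |
| ρ_in / ρ_out | 0.75 / 0.25 | strong modular vs weak background coupling |
| group offsets | MCI −0.05 (blocks 1–2), AD −0.12 (blocks 1–3) | graded hypometabolia, ~0.4–1 SD: subtle enough to evade outlier screening |
| group sizes | 352 / 641 / 234 (CU/MCI/AD) | canonical imbalanced AD-continuum cohort |
| desk scale | 150/group, d = 30, n = 500, Q = 64, α = 0.01 | test-suite problem sizes |

α = 0.01 at desk scale because d = 30 gives 435 edge tests (a large-d study
would use α = 10⁻⁴, but θ = 1 − α then requires (1 − θ)·n ≥ 1, i.e.
n ~ 10⁴ ensemble members, beyond desk problem sizes).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: PET image noise, partial-volume effects, scanner
harmonization, covariate structure (age/sex enter only through the
residualization API), heavy-tailed subjects, and — most consequentially — a
*continuous spectrum* of correlation strengths.  Block-constant correlation
puts every between-block edge at one shared significance boundary; as the
cohort size crosses that boundary (around N ≈ 60–160 at α = 0.01 for
ρ_out = 0.25) all those edges churn simultaneously, producing a bump in
density-sensitive quantities (average degree/strength, hence the feature
distance dE) in the middle of size-sweep experiments.  Real SUVR data
spreads such boundaries across the whole size range, so its stability-vs-N
curves decay smoothly; with this generator the matrix distances (dF, dH)
and dC decay as expected over N = 10..200 but dE does not, and the
size-sweep acceptance test records that limitation rather than masking it.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] and symmetrized against float noise;
  |r| = 1 maps to p = 0.
* Zero-variance columns are rejected with the VOI named (the correlation is
  undefined); degenerate bootstrap draws (possible only at tiny N) are
  redrawn up to 100 times so the ensemble size is preserved without biasing
  typical draws.
* CSV round trips are bit-exact: shortest-repr floats on write,
  correctly-rounded parsing on read.
* All randomness flows through `numpy.random.SeedSequence` children of one
  master seed, keyed by stage; pipeline manifests record per-stage seeds
  and SHA-256 checksums of every artifact, so reruns are verifiably
  bit-identical.

## Known limitations

* The mode criterion is a k-NN density surrogate, not a full Bayesian mode
  estimate; justified empirically by the criteria-equivalence experiment.
* The Pmap mask is computed once from the unperturbed ensemble; the attack
  protocol deliberately does not rebuild the ensemble from perturbed data
  (the alternative — full re-construction per attack — answers a different,
  more expensive question).
* ANOVA-style group comparisons of attack distances are out of scope; the
  report writer emits tidy per-attack tables that any statistics package
  can consume.
* Synthetic-data caveats above: conclusions about dE size-convergence on
  real cohorts should not be drawn from the generator's block-constant
  correlation model.
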