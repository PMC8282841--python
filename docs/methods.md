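# Methods

`issrpop` analyses dominant-marker band matrices: individuals × loci tables of
0/1 presence/absence scores, grouped by amplifying primer, with a population
label per individual. This note records the models, estimators, numerical
choices and limitations behind each stage.

## Dominant markers and allele-frequency estimation

A dominant locus has a band (presence) allele and a recessive null allele; the
band-present phenotype cannot distinguish homozygous from heterozygous
carriers. Under Hardy–Weinberg equilibrium the null-allele frequency is
estimated from the band-absent phenotype frequency `b0` as `q̂ = sqrt(b0)`,
`p̂ = 1 − q̂`. The Lynch–Milligan small-sample correction
`q̂ = sqrt(b0) / (1 − Var(b0)/(8 b0²))`, with `Var(b0) = b0(1−b0)/n`, is
available behind a flag (`lynch_milligan=True`) and off by default: whether
the classical desktop programs applied it to any given published table is
generally unknowable, and the plain estimator is the transparent default.

## Marker-efficiency indices (per primer)

- **TSB / PB / PPB** — scored loci, polymorphic loci (both states observed
  among non-missing entries; an optional minor-frequency threshold exists but
  defaults to 0), and `PPB = 100·PB/TSB`.
- **Pooled band frequency** `p̄` — 1-entries over non-missing entries across
  the primer's *polymorphic* loci. H and PIC are computed from this single
  pooled frequency, not from per-locus averages: with one bi-allelic
  frequency, `H = 2p̄(1−p̄)` and the Botstein PIC reduces exactly to
  `PIC = H − H²/2`. Published per-primer tables produced by the popular
  online marker-efficiency calculators satisfy this identity row by row,
  which per-locus averaging would not; the bundled reference panel confirms
  it within printed rounding. The general multi-allele Botstein form is
  provided separately (`pic_multiallelic`).
- **EMR** `= n·β` with `n` the mean number of fragments per individual at the
  primer's loci and `β = PB/TSB`. When an individual has missing cells its
  band fraction over observed loci is rescaled to the full locus set, so
  missingness does not deflate `n`.
- **Havp** — the mean of per-locus `2p(1−p)` over polymorphic loci, i.e. the
  literal "Σ Hn / np" formula. Note that some published tables print Havp
  values four orders of magnitude smaller than this formula can produce; the
  bundled reference table carries those printed values untouched, but they
  are excluded from any numeric check.
- **MI** `= PIC × EMR`.
- **D** (discriminating power) — individuals are grouped by their full
  multi-locus banding pattern at the primer; with pattern frequencies `p_i`
  among `N` individuals, `D = 1 − Σ p_i (N p_i − 1)/(N − 1)`.
- **RP** — `Σ_b (1 − 2|0.5 − p_b|)` over the primer's bands, `p_b` the
  fraction of individuals showing band `b`.

## Diversity statistics

Per locus from `p̂`: `Na ∈ {1,2}`, `Ne = 1/(p²+q²)`, Nei's `h = 1 − p² − q²`,
Shannon's `I = −p ln p − q ln q` (natural log, the POPGENE convention; zero
terms contribute 0). For a partition into populations, frequencies are
estimated within groups; `Hs` is the equally-weighted mean of within-group
`2pq` (a size-weighted variant is available), `Ht = 2p̄q̄` with `p̄` the mean
of group frequencies, and `Gst = (Ht − Hs)/Ht`. The headline Gst is the
ratio of locus means (Nei's definition, more stable); the mean of per-locus
ratios is also reported. Loci monomorphic overall are excluded from Gst but
kept in the bookkeeping columns. Gene flow is `Nm = 0.5(1 − Gst)/Gst`.

## Distances and trees

Nei's normalized identity `I = Jxy/√(Jx Jy)` with `Jxy` the locus-mean of
`p_x p_y + q_x q_y`; distance `GD = −ln I`. At population level the
frequencies are HWE estimates; at individual level the 0/1 band states are
used directly as frequencies (the GenAlEx dominant-data convention). "Nei's
unbiased" (1978) correction is meaningful only where sample sizes exist, so
it is an option at population level and not offered between individuals.
Identity 0 gives an infinite distance; reported matrices keep the `inf`,
and tree building requires an explicit cap (`DistanceMatrix.capped`,
default ceiling 10).

UPGMA merges the closest pair with size-weighted average linkage; node
height is half the merge distance, so cophenetic distances reproduce any
ultrametric input exactly. Ward linkage uses the Lance–Williams update on
*unsquared* distances (the `ward.D` variant common for binary-data heatmap
ordering). Merge ties are broken by the lexicographically smallest pair of
cluster tags (a cluster's tag is its smallest member label), making tree
topology and Newick output platform-independent.

## Ordination

PCA is the eigen-decomposition (via SVD) of the covariance of the centered
0/1 columns, divisor `n − 1`; missing cells are mean-imputed per locus before
centering. On binary data this keeps eigenvalues on the familiar sub-unit
scale of the classical numerical-taxonomy programs. Axis signs follow a
deterministic convention (largest-magnitude loading positive). The
per-accession Shannon index treats the presence profile as an equal-weight
composition, so `H′ = log10(bands present)`; this reduction is a
reconstruction of a convention that published tables use without defining,
and it is kept out of numeric acceptance.

## Admixture model

The core model is K-cluster admixture with correlated allele frequencies for
dominant diploid phenotypes. Individual `i` has `Q_i` on the K-simplex
(symmetric Dirichlet(α) prior) and two latent allele copies per locus; a
copy's cluster is Categorical(Q_i), its state Bernoulli(P_kl), and a band is
scored iff at least one copy is a presence allele:
`P(band absent) = (Σ_k Q_ik (1−P_kl))²`. Under the correlated model
`P_kl ~ Beta(p_l(1−F_k)/F_k, (1−p_l)(1−F_k)/F_k)` (Balding–Nichols) around
an ancestral frequency `p_l`, with per-cluster differentiation `F_k` — the
fixation index reported per cluster. A haploid mode (band = single copy)
covers panels coded that way; an independent-frequencies model (Beta(1,1))
is available.

Gibbs sweep: (a) each copy's (cluster, state) from its exact joint full
conditional given the band — for a present band the state pattern of the two
copies is drawn from {(1,1),(1,0),(0,1)} with probabilities ∝ s1², s1·s0,
s0·s1 where s1/s0 are the mixture weights of presence/null copies; (b) `P`
from its conjugate Beta conditional; (c) `Q` from Dirichlet(α + copy
counts); (d) `F_k`, `p_l` and α by random-walk Metropolis (logit scale for
the probabilities, log scale for α, with the appropriate Jacobians);
(e) the observed-data log-likelihood is recorded. Missing cells are skipped
everywhere. Posterior means over post-burn-in sweeps are reported.

α is *inferred* by default (bounds 0.02–10). This matters: with α fixed at 1
the flat Dirichlet prior over-smooths Q for near-pure individuals, latent
copies cross-assign between clusters, and per-cluster F is inflated by
roughly +0.1 at study scale. With α inferred it shrinks below 0.15 on pure
data, Q locks, and F recovery is within ±0.05 of simulated truth. The
sampler's conditional machinery was validated exactly against a closed-form
beta-binomial posterior on a fixture with Q pinned.

Numerical guards: P is clipped to [1e−6, 1−1e−6], Q components floored at
1e−12 before the α update, and the F walk is bounded to (0.001, 0.999) so
that differentiation up to ~0.4 is reachable quickly at desk scale (a prior
concentrated near 0.01 would not be).

Model choice: per run, `ln P(D) = mean(lnL) − var(lnL)/2` over the recorded
trace; across ≥2 runs per K on a contiguous K range, the Evanno statistic
`ΔK = |L″(K)|/sd(L(K))` with best K its argmax. ΔK is undefined at the range
ends and where the run sd is zero (warned). Because the variance penalty in
ln P(D) punishes non-stationary traces harshly, Evanno runs need a burn-in
long enough for every chain to settle; the pipeline defaults use 500–600
burn-in sweeps at the 44 × ~500 scale, which removed all spurious ΔK spikes
in validation.

Cluster summaries: within-cluster expected heterozygosity
`het_k = mean_l 2P_kl(1−P_kl)`; between clusters the net nucleotide distance
`d_AB = π_AB − (het_A + het_B)/2` with `π_AB = mean_l (P_Al + P_Bl −
2P_Al P_Bl)`. Membership is called pure in cluster k iff `Q_ik > 0.60`
(strictly; the boundary value is admixed). F values are annotated with the
Hartl–Clark verbal scale (cut-points 0.05/0.15/0.25). Label switching across
runs is resolved by Hungarian assignment of columns onto the first run,
minimizing squared disagreement.

## Synthetic data generator

The generator draws: locus counts per primer (uniform on a range), ancestral
frequencies `p_l ~ Uniform(0.1, 0.9)` (avoiding near-fixed loci that the
sqrt estimator handles poorly; configurable), cluster frequencies from
Balding–Nichols, admixture rows as symmetric Dirichlet draws or one-hot
vectors from a population→cluster map, and diploid dominant phenotypes under
HWE, with optional uniform missingness. One `SeedSequence` per run is split
into named sub-streams (frequencies, admixture, bands, missingness) in a
fixed order, so identical config + seed is bit-identical regardless of
caller state.

Defaults mirror the study design this package targets: 11 populations × 4
individuals, 32 primers × 11–22 loci (~510 loci), K = 3 with
F = (0.19, 0.37, 0.40), populations mapped contiguously to clusters
(4 + 3 + 4), no missingness. What the generator does *not* emulate: linkage
between loci, selfing/inbreeding (real inbred lines violate HWE sampling),
genotyping/scoring error, and band-size homoplasy. Tests passing on this
generator therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to those real-data features.

## Problem sizes used in validation

Recovery checks run at desk scale as the package's own test design: Gst on
2 × 100 individuals × 500 loci (20 replicates, error vs a closed-form oracle
on the true cluster frequencies < 0.06 observed ~0.02); fixation-index
recovery on 60 × 300 at F ∈ {0.2, 0.4} with 300/700 burn-in/sweeps (±0.08
tolerance, observed ≤ ~0.05); Evanno on 44 × ~170 panels, K = 1..5, with
3–5 runs per K; UPGMA cluster agreement and purity classification at the
full 44 × ~510 study scale. The MCMC defaults in `AdmixtureConfig`
(2,000/10,000) suit real analyses; tests and the acceptance script pass
smaller, explicitly stated values.

## Known limitations

- Individual-level "Nei" distances on 0/1 profiles are a convention, not an
  estimator; identities can hit 0 (infinite distance) for complementary
  profiles.
- The Evanno statistic cannot select K = 1 and is noisy when chains are
  under-burned; inspect `mean_lnpd`/`sd_lnpd` alongside ΔK.
- Havp as printed in some published tables is irreconcilable with its own
  formula; this package computes the formula.
- The admixture sampler reports posterior means from a single chain per run;
  within-chain label switching is not corrected (it was never observed at
  the differentiation levels tested, F ≥ 0.19).
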