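# issrpop

Population genetics for **dominant-marker band matrices** — the 0/1
presence/absence tables produced by ISSR, RAPD and AFLP fingerprinting.
Plant-diversity surveys with these markers traditionally stitch together half
a dozen desktop programs (a marker-efficiency calculator, POPGENE, GenAlEx,
a tree viewer, STRUCTURE, Structure Harvester). `issrpop` implements that
entire workflow as one tested Python library with a command-line front end,
plus a synthetic-data generator with known ground truth so every stage can be
verified.

## What it computes

Given a band matrix (individuals × loci, entries 0/1/NA, loci grouped by
primer, individuals labelled by population):

- **Marker efficiency per primer** — scored/polymorphic band counts (TSB,
  PB, PPB), expected heterozygosity `H = 2p̄(1−p̄)`, polymorphic information
  content `PIC = H − H²/2` (bi-allelic Botstein), effective multiplex ratio
  `EMR = n·β`, marker index `MI = PIC·EMR`, Tessier's discriminating power
  `D`, Prevost–Wilkinson resolving power `RP`, and `Havp`.
- **Diversity statistics** — dominant allele frequencies under HWE
  (`q̂ = sqrt(1 − band freq)`, optional Lynch–Milligan correction), per-locus
  `Na`, `Ne = 1/(p²+q²)`, Nei's `h = 1−p²−q²`, Shannon's
  `I = −p ln p − q ln q`, and for any population partition `Ht`, `Hs`,
  `Gst = (Ht−Hs)/Ht` and gene flow `Nm = 0.5(1−Gst)/Gst`.
- **Genetic relationships** — Nei identity `I = Jxy/√(JxJy)` and distance
  `GD = −ln I` between individuals or populations, UPGMA trees (ultrametric,
  deterministic tie-breaking, Newick output) and Ward (`ward.D`, unsquared
  distances) linkage for heatmap ordering.
- **Ordination** — covariance PCA of the centered 0/1 matrix (eigenvalues,
  percent and cumulative variation, case scores) and the per-accession
  Shannon index `H′ = log10(bands present)`.
- **Bayesian admixture** — a STRUCTURE-style Gibbs sampler for dominant
  diploid phenotypes under the admixture model with Balding–Nichols
  correlated allele frequencies: `P(band absent) = (Σ_k Q_ik(1−P_kl))²`.
  Returns posterior-mean membership `Q`, cluster band-allele frequencies
  `P`, and a per-cluster fixation index `F_k`, with `ln P(D) = mean(lnL) −
  var(lnL)/2` per run, Evanno `ΔK = |L″(K)|/sd(L(K))` model selection,
  net nucleotide distances between clusters, and pure/admixed calls at the
  `Q > 0.60` threshold.
- **Synthetic panels** — Dirichlet or one-hot ancestry, Balding–Nichols
  cluster frequencies around Uniform(0.1, 0.9) ancestral frequencies,
  diploid dominant phenotype sampling, configurable missingness; defaults
  mirror a 44-accession / 11-population / 32-primer (~510 locus) study
  design with K = 3 and F = (0.19, 0.37, 0.40).

See `docs/methods.md` for estimators, priors, update steps and limitations.

## Worked example

```python
import issrpop as ip

# a study-scale synthetic panel with known truth: 44 individuals in 11
# populations, 32 primers, K_true = 3, F = (0.19, 0.37, 0.40)
m, truth = ip.simulate_dataset(ip.SimulationConfig(seed=1))

ip.panel_metrics(m).head(4)[["TSB", "PB", "PPB", "H", "PIC", "EMR", "MI", "D", "RP"]]
#         TSB  PB     PPB      H    PIC     EMR     MI      D     RP
# primer
# P01      11   9  81.818  0.473  0.361   6.174  2.230  0.975  5.091
# P02      19  18  94.737  0.380  0.308  13.651  4.202  0.994  6.636
# P03      20  18  90.000  0.473  0.361  11.782  4.255  0.957  6.545
# P04      13  12  92.308  0.489  0.369   6.378  2.355  0.992  6.091

ip.partition_diversity(m).summary()
# Ht                0.3137
# Hs                0.1570
# Gst               0.4995
# Gst_locus_mean    0.4684
# Nm                0.5009

res = ip.AdmixtureModel(m, 3, ip.AdmixtureConfig(burnin=300, sweeps=700)).fit(seed=1)
print(res.summary())
# Admixture model, K = 3 (dominant-diploid, correlated frequencies)
# sweeps: 300 burn-in + 700 recorded
# ln P(D) = -7762.9   mean lnL = -7435.5   var lnL = 654.7
#
# cluster   Fst      interpretation          exp. het.
#   1       0.3595   very great differentiation  0.2589
#   2       0.3476   very great differentiation  0.2506
#   3       0.1763   great differentiation   0.3280
#
# membership at Q > 0.60: pure(3): 16, pure(2): 16, pure(1): 12
```

The three recovered fixation indices (0.18, 0.35, 0.36 after aligning
cluster labels to the simulation truth) sit within sampling error of the
simulated F = (0.19, 0.37, 0.40); all 44 simulated-pure individuals are
called pure at the Q > 0.60 threshold. The high Gst (~0.5) is expected: the
partition statistic here contrasts 11 labelled populations that map onto 3
strongly differentiated clusters.

The same stages are available from the shell:

```sh
issrpop simulate --seed 1 --out sim/
issrpop metrics   sim/band_matrix.csv sim/popmap.csv
issrpop diversity sim/band_matrix.csv sim/popmap.csv
issrpop tree      sim/band_matrix.csv sim/popmap.csv --out upgma.nwk
issrpop evanno    sim/band_matrix.csv sim/popmap.csv --k-min 1 --k-max 6
issrpop pipeline  --seed 1 --out run/     # everything, with a manifest
```

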