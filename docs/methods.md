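# Methods

## Model

A ribosome waiting at sense codon *i* is resolved by the first of three
competing exponential processes: correct elongation, missense elongation,
or premature termination. Arrival of a tRNA species at the A-site is
proportional to its gene copy number (GCN), the standard proxy for cellular
tRNA abundance in bacteria. Each arriving species is accepted with a
per-entry probability set by its pairing class, giving class elongation
rates

    R_c(i) = a ( Σ_{j∈C} w_ij P_c GCN_j + Σ_{j∈P} P_p GCN_j )
    R_n(i) = a Σ_{j∈N} P_n GCN_j

and branching-fraction error probabilities per elongation event
(dimensionless, not per unit time)

    ε_M = R_n / (R_c + R_n + d),   ε_N = d / (R_c + R_n + d).

These satisfy ε_M + ε_N + R_c/(R_c+R_n+d) = 1 identically; ε_N is strictly
decreasing in both R_c and R_n, and ε_M is decreasing in R_c and increasing
in R_n. For a synonymous pair ordered by R_c, ε_M is *higher* for the
higher-R_c codon exactly when R_n2 (R_c1 + d) > R_n1 (R_c2 + d) — the
closed form used by `missense_order_condition` and verified against direct
evaluation in the tests.

## Pairing classes and wobble

Codon position k pairs anticodon position 4−k; the codon's third position
pairs anticodon position 34, the wobble position. Classification of a
(codon, anticodon) pair is purely structural:

* 0 mismatches → Watson-Crick cognate, w = 1.
* 1 mismatch at the wobble position, same amino acid → accepted wobble
  cognate. Penalty multipliers: G·U, U·G and A·C reads 0.64 (acceptance
  reduced by 36%), purine-purine / pyrimidine-pyrimidine reads 0.60
  (reduced by 40%). Anticodon-C34 reads (C·U, C·A) are stereochemically
  non-standard: the tRNA delivers the right amino acid but only at the
  near-cognate acceptance probability — a *pseudo-cognate*.
* 1 mismatch, different amino acid → near-cognate (missense route),
  wherever the mismatch sits.
* 1 internal mismatch (codon position 1–2), same amino acid → treated as
  pseudo-cognate by default (possible only within leucine and arginine
  boxes); configurable, and immaterial to the headline results (toggling it
  changes none of the E. coli counts).
* ≥2 mismatches → non-cognate, discarded (rejected too fast to compete).

All penalties and toggles live in `WobbleRules` / the YAML config rather
than code. Whether the paired-down set of same-chemistry wobbles should all
sit at 0.60 is genuinely open; the table is overridable and the sensitivity
sweep (below) shows the sign structure does not depend on it.

Serine is split into two identities (Ser4 = UCN, Ser2 = AGC/AGU): its two
codon families differ at two positions, so no anticodon of one family is
within one mismatch of a codon of the other, and they behave as two
independent amino acids of degeneracy 4 and 2 (21 sense identities, D
summing to 61). A tRNA's amino acid is translate(revcomp(anticodon)); the
known exception (bacterial tRNA-Ile2, lysidine-modified CAU read as Ile at
AUA) is available as a per-anticodon identity override, off by default
since GCN tables keyed by anticodon cannot separate it from elongator Met.
Anticodons complementary to stop codons are rejected at input (suppressor
tRNAs sit outside the sense-codon model).

## Selection kinetics

`P_c`, `P_n`, `P_p` are per-entry acceptance probabilities. The kinetics
module computes them as the absorption probability of a branching scheme —
ordered steps with forward, backward and rejection rates, backward from the
first step meaning dissociation — via the birth-death first-passage
recursion α_i = f_i / (f_i + r_i + b_i (1 − α_{i−1})), P = Π α_i, validated
to 1e-12 against an independent absorbing-Markov-chain linear solve on
random schemes. Defaults are explicit values on the ensemble-kinetics scale
of the Gromadski–Rodnina selection measurements, P_c = 0.99 and
P_n = P_p = 0.0045 (pseudo-cognates are accepted at the near-cognate
probability). The missense sign analyses depend on P_n/P_c only through the
overall scale of R_n, so their qualitative results are insensitive to the
exact pair; wobble penalties act as multipliers on P_c in R_c rather than
as perturbed rate constants, matching the w·P_c form of the rate equation.

## Calibration and drop-off

The scaling constant a is fit per genome so that the harmonic mean of R_c
over the 61 sense codons equals a bulk elongation-rate target, default
10 codons/s (the classic E. coli ensemble range is ~10–20 aa/s; the
harmonic mean is the right average because per-codon dwell times add). The
harmonic mean is taken over R_c — pseudo-cognate contributions are part of
R_c by construction — with an R_c+R_n option. Codons with an empty cognate
set under strict rules get R_c = 0 and are reported; calibration then fails
naming them rather than silently dropping codons.

The drop-off rate d is codon-independent. The default, d ≈ 4.0e-3 /s,
inverts d/(R + d) = q for a measured per-codon nonsense frequency
q = 4e-4 at the R = 10 /s reference rate (`derive_dropoff`). At these
defaults the predicted E. coli ε_N median is ~3e-4 per codon, consistent
with the input measurement, and ε_M ranges 0–0.07 with median ~1.6e-2 —
predicted *total* missense rates, necessarily above single-substitution
measurements.

## Panel analyses

For each present species, t_F is its GCN and t_N the summed GCN of its
Hamming-distance-1 anticodon neighbors charging a different amino acid
(stop-complements excluded; the neighbor relation is symmetric). Per genome
and degeneracy class (D = 2, 4, 6, plus pooled), ρ_t is the Pearson
correlation of (t_F, t_N) (Spearman by flag; the choice is logged in output
headers), with groups of n < 3 or zero variance flagged undefined. Panel
location tests are a two-sided Wilcoxon signed-rank of ρ_t against 0 and a
binomial sign test of positive counts against 1/2.

An important caveat the package surfaces rather than hides: even for fully
independent counts, the within-genome sample correlation between a species
and the *sum of its neighbors* has a negative centering bias of order
√(mean degree)/(n−1) (≈ −0.03 to −0.07 at ~30 present species), because the
focal value of one record reappears inside other records' sums. The
zero-against tests are therefore anti-conservative toward negative, which
is precisely why the randomization null matters: gene copies are
redistributed over a permitted-anticodon set (default: anticodons observed
anywhere in the panel, standing in for stereochemical constraints on which
anticodons can exist), uniformly or with amino acids drawn by usage weight
first, conserving each genome's total exactly; observed and null ρ_t
distributions are then compared per class with a two-sample KS test. Null
streams are derived deterministically from (seed, genome id via crc32,
replicate index).

The comparative layer scores, per genome and amino acid, the sign of the
R_c-vs-error-rate relationship across synonyms: the difference product for
D = 2, the Pearson (or Spearman) correlation sign for D ≥ 3 — the right
rule for higher boxes is genuinely open, so both are exposed. "Violation"
of the classical lowest-error-at-highest-R_c expectation is operationalized
as argmax-R_c ≠ argmin-ε_M (weakest reading); an "any synonym lower"
criterion is also implemented and the choice is logged. A sensitivity sweep
rescales d over two decades and shifts both wobble penalties by ±0.1 and
reports the fraction of amino acids with unchanged sign; on the bundled
E. coli pool that fraction is 1.0 at every grid point.

## Synthetic panels

The generator emulates bacterial tRNA complements: permitted anticodons
default to the 61 sense complements minus A34 starters (coarsely mimicking
their near-absence in bacteria), and the count marginal is a point mass at
zero (sparsity, default 0.35) plus a shifted negative binomial
(mean 2.2, shape 1.2) — many 1–2 copy species, occasional high-copy ones.
Neighbor correlation is induced through a Gaussian copula: a latent field
with correlation rho_target between distance-1 anticodon pairs (eigenvalue-
clipped and renormalized to the nearest valid correlation matrix when the
request exceeds what the anticodon graph admits — requests above ~0.3 are
shrunk, which is why recovered panel means saturate near 0.4) is mapped
through the count marginal's quantile function. Attained latent correlation
is logged. Marginals are calibrated by construction; recovered panel-level
ρ_t is ordered in rho_target and near (slightly below, per the centering
bias above) zero at rho_target = 0.

What the generator does not emulate: phylogenetic relatedness between
genomes (draws are i.i.d.), amino-acid-specific anticodon sparsity
patterns, genome-size/copy-number covariation, and real stereochemical
wobble constraints beyond the permitted set. Passing recovery tests
therefore demonstrate statistical correctness of the pipeline, not fidelity
of any particular bacterial panel.

## Problem sizes and numerical choices

Stochastic checks use 100 genomes per correlation-recovery panel, 100
replicate 50-genome panels for null sign-test behavior, 30 trials of
8-replicate nulls on a 15-genome panel for KS self-consistency, and 45
genomes across three correlation levels for the nonsense-sign exhaustive
check; property checks use 1e4 random rate profiles (normalization), 1e3
profile pairs (ordering condition) and 500 random schemes (kinetics oracle).
Calibration solves the harmonic mean in closed form (relative error at
machine precision, asserted to 1e-9). Ties in sign computations map to
"flat" and are excluded from binomial counts; undefined correlation groups
are dropped from panel tests with counts reported.

## Bundled data

`data/ecoli_k12_trna_gcn.tsv` is a reconstruction of the E. coli K-12 tRNA
gene complement (85 genes over 39 anticodons; selC excluded as a
stop-complement), compiled from the canonical K-12 gene set rather than
exported from a database; the file header lists the gene-family reasoning.
Counts for a specific strain/database version may differ by a few copies,
which leaves the structural results (empty near-cognate sets, two-fold sign
pattern) intact but can shift the exact violation count among the 4- and
6-fold boxes.

## Known limitations

GCN is a proxy for abundance (real-valued abundance tables are accepted
through the same I/O path); the drop-off rate is genome-independent;
non-cognate species are assumed never accepted; the model is bacterial —
eukaryotic wobble chemistry (inosine editing, expanded U34 reading) is out
of scope; and whole-transcript error aggregation and ribosome queueing are
deliberately not modeled.
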