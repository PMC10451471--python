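# Methods

## Model and scope

introgscan detects introgression between closely related species from
three genome-wide signals that are all derived from the multispecies
coalescent (MSC): an imbalance in the two discordant biallelic site
patterns of a rooted triplet (Patterson's D, with the Dp
introgression-proportion variant), an imbalance in the two discordant
gene-tree topologies of a rooted quartet (the Δ statistic), and an
imbalance in the two NNI-discordant resolutions of each species-tree
branch (concordance factors with a chi-square test). Under ILS alone
each of these pairs is exchangeable; directional excess of one member
indicates gene flow between the taxa it joins. The three statistics
share an orientation convention: a positive value means excess sharing
between P2 and P3 (or between the NNI pair joined by df1).

The package computes the statistics from standard inputs (VCF, newick,
FASTA); it does not infer trees, call variants, or fit networks.

## Site-pattern statistics (D, Dp)

Sites are polarized by the majority allele among outgroup calls; tied
outgroups and sites with an uncalled population are skipped and
counted. Pattern weights use products of derived-allele frequencies,
which with one diploid sample per species reduces to quarter-integer
weights and handles heterozygotes without phasing. Whether to weight
fractional heterozygote contributions or collapse to haploid calls is
a genuine free choice; frequency weighting was chosen because it is the
standard f-statistic estimator and loses no information.

The block jackknife deletes fixed, half-open windows in reference
coordinates (default 1 Mb), recomputes D without each block, and uses
SE² = ((n−1)/n)·Σⱼ(D₍₋ⱼ₎ − mean)² over the n blocks carrying nonzero
ABBA+BABA weight. Z = D/SE is referred to the standard normal. An
optional weighted variant (block weights proportional to informative
weight, Busing-style delete-mⱼ) is available behind a flag; the
unweighted form is the default because the simulated blocks are
homogeneous by construction. p-values print to 3 decimals with values
below 0.0005 shown as ".000".

Within a sister pair the P1/P2 orientation is chosen so D ≥ 0 (the
Dsuite BBAA convention); the species tree fixes only which taxon is P3.

## Gene-tree statistics (Δ, concordance factors)

Quartet topologies are classified by bipartitions, so rooting of the
input gene trees is irrelevant; trees missing a quartet taxon or with a
polytomy across the quartet are uninformative. The Δ bootstrap
resamples the four classification categories multinomially (equivalent
to resampling trees with replacement), recomputes Δ per
pseudoreplicate, and reports the bootstrap standard deviation as SE;
replicates with no discordant trees leave Δ undefined and are dropped
and counted rather than imputed. The bootstrap SD (not a percentile
interval) defines Z because it matches the delta-method closed form
sqrt((1−Δ²)/(n₁+n₂)) and reproduces published SEs at rounding
precision.

Branch classification for gCF uses the bipartition criterion: a
decisive gene tree (≥1 leaf from each of the four flanking subtrees
A, B, C, D) is concordant if it contains a split separating A∪B from
C∪D on the shared taxa, df1/df2 for the two NNI regroupings (df1 joins
A with C), and paraphyletic otherwise — including polytomies at the
relevant split, which is conservative for the chi-square test. The
chi-square test uses (n₁−n₂)²/(n₁+n₂) on 1 df without continuity
correction (counts are large in intended use; a Yates flag exists).

sCF is implemented in its parsimony form: per branch, 300 quartets are
sampled uniformly with replacement (one taxon per flanking subtree);
a column is decisive iff its four states are unambiguous nucleotides
with exactly two states split 2–2; per-quartet support fractions are
averaged over quartets with at least one decisive site. Likelihood-based
sCF variants give systematically different (typically higher) values;
sCF results here are therefore validated by their properties, not
against published likelihood-sCF numbers. Columns with three or more
states, or 3–1 splits, are not decisive — the strictest published
definition, flagged for users.

## Filters

All threshold comparisons are strict as stated (< and >): boundary
values pass. Genotypes lacking GQ or DP are masked (conservative).
SNV-to-indel proximity is measured to the indel's reference-affected
interval (a deletion at p with REF length L occupies [p, p+L−1]; an
insertion only its anchor), because anchor-only distance under-counts
proximity for long deletions; switching to anchor-only is a one-line
change. Removal reasons report the first failing metric in the
documented rule order, for determinism.

CDS alignments keep 1:1 column correspondence with the reference:
insertions are skipped, deleted bases become '-', heterozygous SNVs
become IUPAC ambiguity codes (treated as missing by the
informative-site counter), and missing genotypes keep the reference
base but are recorded in a sidecar N mask so they can be excluded in
sensitivity analyses. Alignments are emitted in reference orientation
regardless of gene strand; no codon model is applied downstream, so
frame is not affected. Locus spacing is a greedy left-to-right scan
per chromosome (keep a gene iff its start is ≥ 20 kb past the end of
the last kept gene), which is deterministic and maximal for the
left-to-right order.

## The simulator

`synthetic` draws independent gene trees under the MSC on an
ultrametric species tree with branch lengths in coalescent units
(2N generations) and constant population size per branch. Ancestry is
generated by msprime, parameterized (haploid lineages, population size
1) so one unit of msprime time equals one coalescent unit. An
introgression pulse (donor, recipient, time, γ) is an instantaneous
mass-migration event: each recipient lineage alive at the pulse time
jumps to the donor population with probability γ, the standard
admixture-pulse model.

Mutations follow infinite sites: Poisson(θ/2 × tree length) mutations
per locus, placed on branches proportionally to length, each creating
one biallelic site carried by the subtended leaves. Loci are tiled on
one synthetic chromosome with 20-kb gaps so genomic blocking and the
spacing filter operate on realistic coordinates. Defaults: 5-kb loci,
θ = 2 per locus (tens of segregating sites per locus, comparable to a
few kb of coding sequence in a diverse marine invertebrate clade), one
diploid sample per species.

What the simulator does **not** emulate: recombination within loci,
mutation-rate variation, sequencing error, gene-tree estimation error,
missing data, or reference bias. Passing calibration tests therefore
demonstrates the statistics behave correctly given correct genotypes
and gene trees; on real data, gene-tree error inflates all discordance
classes (visible as gCF below sCF), which these tests do not probe.

## Validation design and problem sizes

Study conditions for the simulation-based checks, chosen once:

* **Coalescent closed form** — 10,000 loci on a quartet tree with
  internal branch T = 1: discordance within 3 binomial SEs of
  (2/3)e⁻¹ ≈ 0.245, NNI chi-square nonsignificant.
* **Null calibration** — 500 replicates per statistic. For D: 3,000
  loci per replicate, θ = 2, jackknife blocks of 500 kb (20 loci per
  block, 150 blocks). The jackknife Z is an asymptotic quantity: with
  sparse blocks (a handful of loci each) its null distribution is
  visibly heavy-tailed, so block contents were sized to carry
  substantial pattern weight, mirroring the data-rich 1-Mb genome
  blocks of intended use. For Δ: 300 gene trees per replicate, 2,000
  bootstrap resamples (bootstrap-SE Monte-Carlo error ≪ the 5%
  rejection margin). Both rejection rates are required to fall in
  [3%, 7%].
* **Power** — γ = 0.2 pulse from P3 into P2 at t = 0.5, 5,000
  loci/trees, 25 replicates per statistic; detection requires
  Z > 1.96 with the positive sign that identifies the donor–recipient
  pair.
* **Filter bookkeeping** — fixtures with planted violations of every
  rule; removal sets must match the planted sets exactly.

All randomness is seeded; reruns are bit-identical. The acceptance
script (`scripts/acceptance.py`) recomputes the worked-example
statistics from their published genome-wide inputs through the same
code paths and takes its bootstrap seed from `--seed`.

## Numerical conventions and degenerate inputs

D, Dp, Δ, and the concordance factors return NaN when their
denominators are empty (no discordant weight, no decisive trees);
jackknife/bootstrap SEs of exactly zero yield infinite Z with p = 0
when the point estimate is nonzero and NaN otherwise. Fewer than two
contributing jackknife blocks leaves SE undefined. Outgroup ties at
exactly 0.5 are skipped rather than broken arbitrarily. The simulator
derives its msprime seed as (seed mod 2³¹−1)+1 and its mutation-layer
stream from an offset of the same seed, keeping the two layers
independent but jointly reproducible.

## Known limitations

* sCF is the parsimony form; values are not comparable to
  likelihood-based sCF implementations.
* The Δ bootstrap treats gene trees as exchangeable; it does not block
  by genomic position (adjacent loci 20 kb apart are nearly
  independent at the simulated scales).
* `run_dtrios` assumes one species per sample group as given by the
  species map and a fully resolved species tree.
* CDS alignment construction assumes deletions lie within a single CDS
  interval and does not realign around indels.
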