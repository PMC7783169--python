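# Methods

This note documents the models, conventions and numerical choices behind
`cifdyn`, in the order data flows through the package.

## Generative model (`synthetic_evolution`)

**Strain tree.** Pure-birth (Yule) trees conditioned on the number of tips:
the k-lineage epoch lasts Exp(k·birth_rate), including a final epoch with
all n lineages, so E[height] = Σ_{k=2..n} 1/(k·birth_rate). No extinction is
modeled: in the analyses the strain tree is an observed input, and the Yule
tree is the simplest stand-in with realistic branch-length structure.

**Gene-pair events.** A tree-wide Gillespie walk draws exponential waiting
times over all lineages alive in each inter-node epoch, so horizontal
transfer can copy an intact pair from any *contemporaneous* lineage. When no
intact donor exists anywhere, a founder pair is seeded from a fixed pool of
five divergent reference pairs, one per phylogenetic type (I–V). Per-pair
rates: deletion, cifB loss-of-function (`mu_b`), cifA loss-of-function
(`mu_a`), recombination proposal. Under `gating="strict"` the cifA rate is
zero while the partner cifB is intact — the model in which the
sperm-modification gene, selectively neutral in random mating, must die
first. `gating="independent"` removes the constraint (the host-suppression
alternative); with per-gene rates proportional to gene length the
singly-pseudogenized A:B ratio then approaches len_a:len_b, and the suite
verifies both regimes.

**Loss-of-function lesions** are point events at a uniform random codon
(excluding the start and terminal-stop codons): a premature stop or a 1–2 nt
indel, chosen uniformly. Only stop/indel kinds are generated;
mobile-element insertions and inversions are accepted in catalogs but never
simulated. A gene receives at most one *event* lesion (rates apply to intact
genes); pseudogenes degrade further only through the sequence layer.

**Recombination acceptance.** A proposed donor is accepted with probability
exp(−d/θ), θ = `recomb_scale`. Because the history is simulated before
sequences exist, d is an analytic proxy: 2·subst_rate·(t − t_MRCA) on the
pair genealogy for pairs sharing a founder, and a fixed `founder_divergence`
(default 0.75, the expected identity of independent random sequences) between
founder types. The proxy ignores homogenization by earlier recombination
events; at the low per-pair recombination rates used this second-order
effect is negligible, and the constructed property — acceptance mass
concentrated on closely related pairs, vanishing between types as θ→0 — is
what the detection stages are tested against. Breakpoints are placed on
codon boundaries so a chimera of two in-frame stop-free parents cannot gain
a chimeric stop codon.

**Sequences.** A two-parameter (Kimura-style) jump process with
transition/transversion bias κ = 2 and total per-site rate `subst_rate`;
substitutions are applied event-by-event so rejection rules can act:
on *intact* genes a substitution that would create an in-frame internal
stop, destroy the start codon, or destroy the terminal stop is rejected
(pseudogenes accept everything and additionally accrue 1–2 nt indels at
`indel_rate`). The expected proportion of differing sites is checked against
the matrix exponential of the generator; the rejection rules produce a
small, quantified deficit. The sequence layer replays the logged history in
global time order, so horizontal transfers copy the donor's sequence *at
transfer time* and tips carry the fully evolved sequences.

**Emission.** Each strain's pairs are laid out on one synthetic contig with
random 100 nt spacers and a 30 nt intergenic gap inside each pair; 20% of
pairs are placed on the minus strand. Contig spacer sequence derives from a
CRC of the contig name, so emission is reproducible without threading the
generator through IO. Defaults (30 strains, height ≈ 3, hgt 0.3, deletion
0.1, mu_b 0.25, mu_a 0.15, subst 0.05/site, genes 150/250 codons) are
illustrative — no gain/loss rate estimates exist to calibrate against — and
were chosen once to yield 0–7 pairs per strain with a realistic mixture of
intact and eroded pairs.

**What the simulator does not emulate:** within-host population dynamics and
selection coefficients, phage/mobile-element structure around the genes,
assembly artifacts (partial genes at contig ends are representable in the
data model but not generated), rate heterogeneity across sites, and
between-gene length variation within a role. Passing recovery tests
therefore demonstrates correctness of the analysis machinery under the
stated model, not robustness to every pathology of real assemblies.

## Homolog cataloging (`homolog_catalog`)

The scan is a six-frame translated local alignment (BLOSUM62, affine gaps
−11/−1) of each protein query against every contig, with iterative masking
to find multiple copies per frame. A raw-score threshold (default 60,
calibrated on shuffled-sequence nulls to sit far above the random-alignment
score for 150–250 aa queries) plays the role of an E-value cutoff; the
decisive acceptance rules are implemented exactly: hits must cover ≥ 40% of
the smallest query, except that short hits are rescued when they display
cifA–cifB synteny with a passing partner. When a hit passes in several
frames the highest-scoring frame wins. Hits are extended 5′ to the nearest
in-frame start codon (ATG; GTG/TTG behind a flag) and 3′ to the nearest
in-frame stop; running off the contig marks the gene `partial`. ORF
fragments of one role separated by ≤ 60 nt (a pseudogene split at an
internal stop) are re-merged into a single reannotated gene.

Disruption calling aligns the gene against an intact reference
*nucleotide* sequence (global, match 5 / mismatch −4, gaps −10/−0.5):
gap runs whose length is not a multiple of 3 are frameshifts, reported at
the first affected reference codon; stop codons in the gene's own reading
frame aligned inside the reference ORF are premature stops. Terminal gap
runs are truncation, not lesions; lesions in the final 10% of codons are
reported with position_fraction > 0.9 so downstream analyses can filter
them. Alignment gap placement is ambiguous within repeated context, so
frameshift positions are guaranteed only to ±1 codon; stop positions are
exact. Coinheritance is positional — same aligned codon, same kind, in more
than one homolog — with the phylogenetic collapse deferred to the
minimum-gain count.

Type assignment is nearest-reference by normalized edit distance on the
concatenated pair (cutoff 0.35 substitutions/site, configurable and
explicitly illustrative: the types are clades, not a fixed radius); beyond
the cutoff from every reference a pair falls in the divergent assemblage
(Type V).

## Phylogenetics (`phylo`)

Codon-aware alignment translates ORFs (internal stops masked as X), aligns
the proteins — exact affine-gap DP for two sequences, MAFFT for three or
more — and back-threads codons, so all gaps are codon multiples. The
conserved-block filter removes columns with occupancy < 0.5 and surviving
runs shorter than 30 columns (10 codons), returning a column-provenance
map. Distances: p, Jukes–Cantor, or Kimura two-parameter; saturated pairs
(non-positive log argument) are clamped to 3.0 substitutions/site and
flagged, keeping matrices finite for Mantel/NJ.

Trees are built by neighbor joining with a deterministic tie-break (lowest
index pair at equal Q), midpoint-rooted, with bootstrap support as the
percentage of column-resampled NJ replicates containing each bipartition.
NJ on corrected distances replaces maximum-likelihood search deliberately:
the downstream statistics consume distances and topologies, NJ recovers
additive trees exactly (verified on random instances), and the result is
fully deterministic. Midpoint rooting is a presentation choice; statistics
that depend on rooting are exposed on rooted trees only.

## Congruence (`congruence`)

Mantel is one-sided (positive association), Pearson on off-diagonal entries,
null by simultaneous row/column permutation, p = (b+1)/(m+1) — p is never 0,
so with 1,000 permutations the smallest reportable p is ≈ 0.001; a bound
like "p < 0.0001" requires more permutations under this convention. ParaFit
computes principal coordinates of each double-centered squared-distance
matrix (axes with eigenvalue < −10⁻⁸·λmax dropped; patristic matrices are
metric so the discarded mass is ordinarily nil), the global statistic as the
sum of squared entries of the fourth-corner cross-product through the
association matrix, a null permuting each parasite's host associations
independently, and per-link contributions by leave-one-link-out with their
own permutation p (flagged at α = 0.05). Individual link tests are
conservative; the global test carries the calibration guarantee.

## Recombination (`recombination`)

MaxChi reduces each triplet to match/mismatch vectors over its variable
sites and maximizes the 2×2 (match × side) χ² over all partition points
with a minimum flank of 10 variable sites. Significance comes from
permuting variable-site order and recomputing the maximum — the max over
partitions inside the permutation absorbs the partition multiplicity, so no
separate per-partition correction is applied. Scanning an alignment
Bonferroni-corrects across triplets, merges signals sharing a recombinant
with breakpoints within 3 windows, and designates as recombinant the
triplet member whose nearest neighbor switches across the breakpoint (the
nearer parent on the longer flank is "major"). Only this single method is
implemented; consensus-of-methods event counts from recombination-detection
suites are not comparable, and no attempt is made to match them. The
parental-distance test compares the mean distance between inferred parents
with a null drawing uniform random distinct pairs, one-sided (lower),
p = (b+1)/(m+1).

## Loss statistics (`loss_dynamics`)

The exact binomial and Fisher tests are computed in integer arithmetic over
a common denominator (2ⁿ and C(N, margin)), with minimum-likelihood
two-sidedness: sum every outcome whose probability does not exceed the
observed one. This makes the implementation bit-for-bit comparable with the
enumeration oracles in the suite. On the published 15/124 vs 27/97
pseudogene frequencies this convention yields p = 0.0053 (scipy agrees to
the last bit), not the 0.02 printed in the literature source of those
counts, whose software convention is unstated; the package reports its own
exact value. The R×2 exact test enumerates all tables with the observed
margins — feasible because the strain tables here have N ≈ 30.

The minimum-gain count treats each distinct lesion as a character gained
but never lost: the number of independent origins is the number of maximal
subtrees whose leaves all carry it. Identical lesions shared through
speciation or within-genome duplication are therefore counted once, exactly
as in Fig.-style tick-mark accounting; the count is verified against an
exhaustive minimum-cover oracle on every topology with ≤ 6 leaves. Events
whose maximal subtree is a single leaf are "terminal", giving the
terminal-branch fraction.

The per-site rate comparison takes the amino-acid site totals as explicit
inputs (the published rates' denominators are not printed anywhere, so they
cannot be hard-coded). The paralog-distance test permutes genome labels
across genes preserving per-genome counts, two-sided by doubling the
smaller tail; scope `intact_only` is the default, `intact_vs_pseudo`
additionally reports the descriptive intact–intact vs intact–pseudo means.
The dispersion test is the Cameron–Trivedi auxiliary OLS of
((y−μ̂)² − y) on g(μ̂) without intercept (g = μ or μ², selectable; with a
scalar μ̂ both give the same z), z = the regression t, two-sided normal p;
constant counts give a degenerate perfect fit whose sign (underdispersion)
is still reported.

CI-phenotype association: strains with unknown or conflicting phenotype are
discarded; pairs whose status is undeterminable (partial genes) are
ignored, and strains with only such pairs are discarded; "Present" means at
least one syntenic pair with no ORF-disrupting mutation. Both the 2×2
collapse (Present vs rest) Fisher p and the full R×2 exact p are reported.

## Pipeline and problem sizes

Per-stage sub-seeds are SHA-256 hashes of (global seed, stage name) mod
2³¹, so toggling one stage never shifts another's randomness; manifests
carry SHA-256 content hashes and identical (config, seed) runs are
byte-identical. The test suite and the acceptance script run the synthetic
pipeline at 8–20 strains with 99–999 permutations, and the calibration
suites use 200–400 replicates at reduced permutation counts — sizes chosen
to exercise every code path at well-resolved Monte-Carlo error.

## Known limitations

* Sequence-level recombination between pseudogenes of different lengths
  splices at clamped coordinates, which can blur the exact breakpoint.
* The divergence proxy for recombination acceptance ignores homogenization
  by prior transfers (see above).
* MaxChi alone detects fewer and different events than a multi-method
  consensus; the within-type fraction, not the event count, is the
  comparable statistic.
* ParaFit per-link significance is conservative on small systems.
* `evolve_sequences` requires the in-process event log; replaying a log
  deserialized from disk is not supported (catalog round-trips are).
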