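# Methods

## Scope and model

`codonuse` quantifies synonymous codon usage bias in sets of coding
sequences and compares it across genomes. The underlying model is the
classic two-force picture: directional mutation pressure shifts base
composition at all positions but is felt most freely at synonymous third
positions (GC₃), while translational selection skews synonymous choice
toward a genome-specific set of preferred codons. Every statistic in the
package is a projection of per-gene codon counts designed to separate those
forces.

## CDS selection

A gene enters the analysis only if it (1) contains more than 300 bases
(strict), (2) begins with an accepted start codon, (3) has a length
divisible by 3, and (4) contains no in-frame stop codon before the final
codon. Rules are checked in that fixed order and a failing gene is
attributed to the first violated rule, making the audit table
deterministic. A terminal stop codon is allowed and is *kept* in the codon
table, so stop-codon RSCU stays computable; stops are excluded again from
composition, CAI/CBI/FOP and clustering, where they would only add
amino-acid-level signal. Sequences with ambiguous bases (N or other IUPAC
codes) are dropped at read time: codon classification needs unambiguous
triplets.

The default accepted start set is `{ATG}`. Many GC-rich bacteria annotate
GTG/TTG starts; `--start-codons ATG,GTG,TTG` switches the convention, and
the filter report makes the consequences visible per genome.

## Index definitions and conventions

* **RSCU.** Per synonymous family, observed count divided by the
  equal-usage expectation; family sums always equal family size. The three
  stop codons form a family of size 3, so a stop's RSCU/3 is its share of
  all stop codons. Families absent from a gene are *undefined* (NaN), not
  zero.
* **ENC.** Wright-style estimator: per amino acid, homozygosity
  f = (nS − 1)/(n − 1) with S = Σ(nᵢ/n)², averaged within the degeneracy
  classes (9 two-fold amino acids, Ile alone as three-fold, 5 four-fold,
  3 six-fold; Met and Trp excluded), then
  ENC = 2 + 9/f̄₂ + 1/f̄₃ + 5/f̄₄ + 3/f̄₆. Amino acids with n < 2 are skipped
  (the n − 1 denominator); a missing three-fold mean falls back to
  (f̄₂ + f̄₄)/2, the estimator's source convention; any other missing class
  leaves the gene's ENC undefined. The estimator is *not* clipped at 61:
  for short genes f̄ₖ can drop below 1/k (counts (2, 2) give 1/3), so
  per-gene values above 61 — or infinity when a class mean is exactly 0 —
  are legitimate and are excluded from genome means as undefined-like
  (non-finite) values. The mutation-only expectation used for the ENC plot
  is ENC(s) = 2 + s + 29/(s² + (1 − s)²), s = GC₃.
* **CAI.** Geometric mean (computed in log space) of relative adaptiveness
  w = RSCU/RSCU_max over the gene's codons, excluding stops, ATG and TGG
  (no synonymous choice). The reference is self-referential: pooled usage
  of the genome's own selected genes. Codons unseen in the reference
  receive a 0.5 pseudo-count before the RSCU→w conversion, the standard
  guard against CAI collapsing to 0.
* **CBI / FOP.** Optimal ("superior") codons are those with genome-wide
  RSCU strictly above 1.6. CBI = (N_opt − N_ran)/(N_tot − N_ran), where
  N_ran is the expected optimal count under random synonymous choice; it
  is 0 at random usage, 1 at exclusive optimal usage, negative when
  optimal codons are avoided, and undefined when no codon passes the
  threshold (a genuinely unbiased genome). FOP defaults to the standard
  ratio N_opt/N_tot. A second mode, `rscu_weighted`, implements the
  alternative literal reading "count-weighted mean RSCU of superior
  codons"; that quantity necessarily exceeds 1.6 whenever defined, which is
  inconsistent with FOP means near 0.6 reported in comparative studies, so
  `ratio` is the default and the mode is flagged in output.
* **Composition and PR2.** Base fractions are tallied per codon position
  over sense codons (terminal stop excluded); GC₁₂ = (GC₁ + GC₂)/2,
  GC = (GC₁ + GC₂ + GC₃)/3. GC₃ₛ additionally excludes ATG and TGG and is
  reported alongside all-codon GC₃; the correlation matrix uses all-codon
  GC₃ for its GC₃ₛ column by default (`gc3s_column="gc3s"` switches).
  PR2 coordinates are G₃/(G₃+C₃) and A₃/(A₃+T₃); (0.5, 0.5) is the
  no-strand-bias point.

## Cohort statistics

Correlations are Pearson product-moment, computed across genes pooled over
all genomes (the per-gene scatter, not the 12 genome means, is what the
diagnostic plots show); `corr_level="genome"` switches to genome-mean
level. Missing values are handled pairwise-complete with per-pair n
reported. The neutrality statistic is the OLS regression of GC₁₂ on GC₃
(slope ≈ 1 ⇒ mutation pressure dominates; ≈ 0 ⇒ selection). For the
CBI–ENC comparison, ENC is first mapped affinely onto the CBI range
(E.ENC); since Pearson r is affine-invariant, the equalization changes
plotting, not the correlation — a property the tests pin to 1e−12. OLS
minimizes vertical residuals (ordinary, not orthogonal, regression). The
length–GC profile keeps proteins strictly shorter than 1500 aa and reports
means in 50-aa bins.

Clustering stacks each genome's pooled RSCU into a 59-dimensional vector
(64 codons minus 3 stops, ATG and TGG), takes pairwise Euclidean
distances, and joins them agglomeratively — single linkage by default,
matching the defaults of the pdist/dendrogram tooling this workflow
descends from; average/complete/ward are one flag away. The dendrogram is
serialized as Newick with branch lengths from merge heights. This is a
distance dendrogram over usage profiles, not an inferred phylogeny, and no
bootstrap support is attached by design.

## Synthetic data

The generator produces what the analysis consumes: framed CDS
(start + body + stop) with two independent dials on synonymous choice.
A *mutational tilt* t multiplies the weight of every G/C-ending codon by
e^t; t is solved by bisection (per genome; interpolated over a 33-point
grid when bias varies per gene) so the cohort's expected GC₃ matches a
target. A *selection bias* b multiplies one preferred codon per family by
e^b; the preferred codon defaults to the first C-ending (else G-ending)
family member, mimicking GC-rich optimal-codon sets, and can be overridden.
b = 0 with no tilt yields exactly uniform synonymous usage (verified by a
χ² test); b → ∞ collapses each family to one codon and drives ENC to 20.

Protein lengths are lognormal (median 260 aa, σ_log 0.45, clipped to
100–1499 aa), concentrating mass under 500 aa as real bacterial proteomes
do. Amino-acid composition is uniform over the 20 amino acids by default;
a GC-rich proteome profile (Ala/Gly/Pro/Arg-heavy) is provided and used by
the study-shaped cohort, which is what pushes GC₁₂ to ~0.58 and overall GC
to ~0.65 at GC₃ ≈ 0.79. Cohorts can plant violations of each selection
filter at requested rates via a single categorical draw per gene, with
ground truth recorded for filter testing; the study-shaped default plants
12% per rule, so roughly half the cohort survives filtering. Each genome
runs on its own RNG stream spawned from the cohort seed, so runs are
byte-reproducible.

What the generator does **not** emulate: real gene-content, operon
structure, amino-acid composition differences between genes, shared
phylogenetic signal between genomes, or selection that varies by codon
rather than by family-preferred codon. Passing tests therefore demonstrate
the correctness and calibration of the *estimators* under a controlled
two-force model, not biological claims about any particular organism.

## Numerical choices

* Undefined quantities are NaN throughout (never 0); infinities from the
  ENC estimator are excluded from means like NaN.
* CAI in log space; tests compare dual implementations at 1e−9 absolute.
* All thresholds strict: length > 300 nt, RSCU > 1.6 for superior codons,
  RSCU > 1.5 for the abundant-codon plot highlight, protein length < 1500.
* TSV floats printed at %.6g for deterministic, diff-able outputs.
* The acceptance script's cohort uses 12 genomes × 1200 genes (within the
  1000–2000 genes/genome range the pipeline is designed around), a size
  chosen so per-gene statistics are stable (≈7.5k selected genes) while a
  full from-scratch run stays fast; in the per-cohort qualitative test the
  "on/below the expected-ENC curve" band is two RMS residuals of the ENC
  estimator around the curve, i.e. a one-sided ≈95% band if the cloud is
  centred — an upward systematic shift of the whole cohort would fail it.

## Known limitations

* ENC has no background-composition correction (no ENC′ variant), and no
  codon-pair or dinucleotide statistics are computed.
* CAI's self-referential reference measures conformity to genome-wide
  usage, not expression-weighted adaptation; with a highly biased genome
  the reference and the measured genes are not independent.
* Filter counts on real annotations depend on the CDS enumeration of the
  input records and on the start-codon convention; both are surfaced
  (filter audit table, `--start-codons`) rather than hidden.
* GenBank CDS features with fuzzy locations are skipped with a warning
  rather than repaired.
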