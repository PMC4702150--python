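# Methods

## Scope and model

`sramap` operationalizes a transcript-anchored (genome-free) small-RNA
regulatory-map analysis for a four-organ plant design (root, stem, leaf,
flower; two replicates each). Its biological model is the canonical plant
miRNA pathway: DCL1 excises a miRNA/miRNA\* duplex with 2-nt 3′ overhangs
from a stem-loop precursor; AGO1, guided by the miRNA, slices targets
between guide nucleotides 10 and 11, leaving uncapped 5′ ends that
degradome sequencing observes; and long precursor stems can be processed
progressively into phased duplex ladders. Everything operates on transcript
coordinates (1-based inclusive), sense strand only by default, DNA alphabet
internally (T/U unified on input).

## Screens and their parameters

| parameter | default | units | role |
|---|---|---|---|
| `fold` | 5 | ratio | organ A vs B mean-RPKM enrichment (inclusive) |
| `alpha` | 0.05 | p | two-tailed pooled Student t-test cutoff |
| `floor` | 1 | RPKM | minimum mean in the high organ |
| `srna_rpm_min` | 10 | RPM | sRNA organ-specificity floor (≥ 1 replicate) |
| `catalog_min_rpm` | 5 | RPM | miRNA accumulation floor (organ mean of replicates) |
| `min_coverage` | 0.5 | fraction | paired positions in a candidate locus |
| `min_stem_pairs` | 15 | bp | minimum helix size for a stem-loop call |
| `max_interior` | 12 | nt | interior loop/bulge tolerated per helix step |
| `long_stem_pairs` | 40 | bp | stem size opened for phasing search |
| `phasing_tolerance` | 0 | nt | allowed head-to-tail slip in a chain |
| `degradome_fold` | 5 | ratio | site vs surrounding mean signature RPM |
| `degradome_top_k` | 12 | rank | abundance rank cutoff, ties share rank |

Statistical choices. With two replicates per organ the pooled-variance
Student test is used (Welch degrees of freedom degenerate at n = 2); when
the pooled SD is zero the statistic's limit is taken: p = 0 for unequal
means, p = 1 for equal means. No multiple-testing correction is applied —
the screen is a fixed rule set, not an inference procedure. When the
reference organ mean is zero the fold ratio is undefined; presence/absence
is treated as the strongest enrichment and the fold criterion reduces to
the floor. "Detected" on the sRNA exclusion side means raw count ≥ 1, with
no RPM threshold. All stated thresholds are inclusive.

Catalog naming is deterministic (descending total raw count, then
lexicographic sequence) so identical inputs always produce identical ids.
Matching is exact full-length identity; isomiR shifting and mismatches are
out of scope.

## Structure logic

Dot-bracket strings are stack-parsed into a symmetric partner table;
pseudoknots and non-`()` bracket alphabets are rejected, with the first
offending position reported. The stem-loop detector codifies what is often
a manual step: hairpins are seeded at innermost pairs and their helices
extended outward while each step's unpaired gap (both sides combined) stays
within `max_interior`; a locus qualifies when all its paired positions fall
in one arm of a helix with at least `min_stem_pairs` pairs.

The miRNA\* call uses the standard geometric consequence of 2-nt 3′
overhangs: star = `[partner(e−2), partner(s)+2]`. Because that formula is
self-consistent on nested structures, overhangs are *re-measured*
independently as the distance from each locus 3′ end to the outermost
position whose partner lies inside the other locus (`duplex_overhangs`).
On perfect stems the derived star measures (2, 2); shifted or bulged
constructions measure (1, 1), (3, 3) or fail to pair and are rejected. The
star-detected flag (raw count ≥ 1 in any library) is recorded but does not
reject a call — valid duplex geometry with an uncloned star is a weaker,
still reportable, precursor.

Phasing operationalizes "in phase" as exact head-to-tail adjacency (next
start = previous end + 1) on the arm carrying more mapped loci; the other
arm is reached only through duplex geometry, so no duplex is reported
twice. A `phasing_tolerance` of ±1 nt can be enabled because natural
registers slip; the default is strict. Phased chains are anchored ≥ 2 nt
from the stem base so that every partner locus (which extends 2 nt past its
pairing toward the 3′ side) stays inside the arm. No RPM floor is applied
to phased sRNAs: detection (count ≥ 1) suffices.

## Degradome logic

"Surrounding" in rule 1 averages over *distinct signatures* mapped to the
transcript outside the site, not per-nucleotide; a silent site never passes
rule 1, and an empty surrounding does not block a real site (5 × 0 = 0).
Rule 2 ranks the best site signature among all distinct signatures on the
transcript with ties sharing the better rank, so a site tied with the 12th
most abundant signature passes. Rule 3 accepts a tag 5′ end opposite guide
nucleotide 10 or 11. A pair is retained when all three rules hold in at
least one organ library; organ classification then reads the per-organ
verdicts (exactly one organ → organ-specific; vegetative organs only →
vegetative-specific; all → constitutive). Degradome RPM uses the raw tag
total by default (`rpm_basis="placed"` is available where only placed tags
are comparable across libraries).

The complementarity scorer is deliberately plumbing, not a reimplementation
of any published predictor: gapless antiparallel alignment, penalties
mismatch 1.0 and G:U wobble 0.5, doubled over guide positions 2–13, site
reported at score ≤ 4.0. Users with an external predictor can supply sites
as a TSV instead; validation is independent of how sites were proposed.

## Synthetic data: what it emulates and what it does not

The generator plants, per seed: 5 organ-high transcripts per organ at
8-fold with 5% replicate CV (and 1 per organ at 4.5-fold that the 5-fold
rule must exclude) among 200 background transcripts; 3 organ-specific
sRNAs per organ at 15 RPM; three constructed hairpins — one full duplex
with the miRNA\* cloned, one with the star absent from the libraries, one
70-bp long stem carrying a phased block of three duplexes; two target
transcripts with a perfect-complement site and a 100-RPM degradome spike
opposite guide nt 10 over 2-RPM background signatures, in the flower
libraries. Library totals are padded to 10⁶ (sRNA) and 5·10⁵ (degradome)
reads with a single 30/40-nt filler sequence so planted RPM values are
exact. Background sRNAs (300 sequences, 21–24 nt) appear in each library
with probability 0.9 and geometric counts (mean ≈ 2), and are rejected at
generation if they collide with planted sequences or map into a hairpin.
Structures are emitted by construction, never by folding, so structure
tests are hermetic.

Deliberately not modeled: sequencing error, adapters and quality scores;
isomiR heterogeneity; multi-locus miRNA families; folding ambiguity
(real RNAfold structures can disagree with the constructed ground truth);
expression correlation structure beyond lognormal replicate noise. Passing
tests therefore demonstrate the correctness of the screening logic under
the stated statistical conditions, not performance on real libraries,
where threshold choices and structure quality dominate.

Problem sizes in the test and acceptance runs (200 transcripts, 100 random
hairpins, 20 background seeds, phased k ∈ {2,3,4}) were chosen as the
smallest sizes at which every planted effect is comfortably identifiable
and every property is exercised across its boundary cases.

One statistical caveat: at 4.5-fold and 5% CV the observed fold of a
just-below-threshold transcript can cross 5 in a small fraction of seeds;
exclusion of the planted sub-threshold transcripts is guaranteed only in
distribution, not per seed.

## Numerical and design choices

* The pooled t-test is computed in closed form (`scipy.stats.t.sf`); tests
  cross-check it against `scipy.stats.ttest_ind(equal_var=True)`.
* RPKM column totals are taken over all rows of the supplied matrix; each
  perfect placement of a multi-mapping read counts once.
* Multiple placements of one miRNA on one transcript are screened
  independently; per-placement counting is used in the funnel counters.
* Renaming, table rows and JSON keys are sorted everywhere, which is what
  makes rerun summaries byte-identical.
* Degenerate inputs: empty libraries, zero column totals, missing lengths
  and out-of-range loci raise immediately with the offending entity named;
  a star interval leaving the transcript returns "no call" rather than an
  error, since it is a legitimate geometric outcome near transcript ends.

## Known limitations

* Sense-strand-only mapping (antisense behind a flag) assumes precursors
  are assembled in the orientation that carries their sRNAs.
* The stem-loop detector's helix walk is greedy outward from the innermost
  pair; highly branched structures with multi-loops are conservatively
  rejected rather than decomposed.
* Rule 2's "top 12" counts distinct signature sequences, one reading of an
  ambiguous convention (positions would be the alternative).
* The built-in scorer is not a substitute for dedicated target predictors;
  its threshold trades recall for scan speed on large catalogs.
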