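# Methods

This note documents the models, conventions and numerical choices behind
each stage of the toolkit, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Coordinates and formats

Internal coordinates are 0-based half-open everywhere. GFF3 I/O converts to
1-based closed at the boundary; BED/bedGraph output stays 0-based half-open;
interval queries (`genes_in_interval`) accept 1-based closed arguments, the
convention of genome browsers. All text output is UTF-8 with LF line
endings; FASTA is wrapped at 60 columns. These conventions are stated once
here to avoid off-by-one drift between stages.

## Assembly statistics

N50 is the length of the scaffold at which the cumulative length, in
descending order, first reaches half the assembly total; L50 is its rank
(ties in length are broken by input order, which affects only rank
reporting, never the N50 value). A run of ≥20 Ns counts as a contig break;
contigs are counted by splitting scaffolds on such runs and the mean break
length is reported. Lowercase bases are folded to uppercase; any character
outside ACGTN is rejected with its position.

## Marker placement and arm merging

Tags are placed at **perfect identity only** and retained only when the tag
or its reverse complement occurs exactly once genome-wide; multi-hit tags
are discarded entirely rather than assigned to a best hit, because in a
genome that is mostly repetitive any mismatch-tolerant or best-hit rule
inflates false anchors. Palindromic tags count their two strand readings as
two hits and are therefore rejected as ambiguous. The search uses a
polynomial rolling hash over each chromosome with direct string verification
of candidates, so hash collisions cannot create false placements.

Scaffolds are assigned to the linkage group contributing the plurality of
their placed markers; exact ties resolve to the lexicographically smallest
LG id and are flagged. Percentages are rounded half-up to one decimal,
matching conventional table formatting. The pooled mismatch rate
(Σ mismatches / Σ placements) and the mean of per-row percentages differ
slightly; both are reported, labeled `pooled` and `mean_of_rows`.

A merge plan orders the scaffolds of a shared LG by the midpoint of their cM
spans and orients each by the sign of the Spearman correlation between cM
and physical position; fewer than 3 placements give orientation `+` with a
`low_evidence` flag. Overlapping cM spans beyond a 1-cM tolerance are a
conflict, not a silent reorder. Merging joins parts with exactly 1000 Ns —
the scaffolder gap convention — and reverse-complements minus parts.

## Subgenome deconvolution

The A and D subgenomes of hexaploid oat are phylogenetically close, the C
subgenome distant. Placing one marker panel on an A-genome and a C-genome
reference therefore separates LGs into: C-derived (placements concentrated
on the C reference; called when `n_C ≥ c_ratio · n_A`, with `c_ratio = 2`
motivated by the observed ~2× placement asymmetry between the references),
and A/D-derived pairs that share a primary A-reference chromosome. Within a
pair, the LG with more perfect placements is called A — the closer subgenome
retains more exact 64-mers — and an optional prior-label file can override
this data-driven ordering. When the minority reference still holds ≥20% of
an LG's placements the label becomes a slash label (A/C, D/C), larger
segment first. Both thresholds are exposed because no field-standard numeric
cutoff exists for "substantial" secondary mapping.

Translocations are detected per LG in cM order: a maximal run of ≥5 markers
(configurable) agreeing on a foreign (reference, chromosome) against the
flanking modal label yields a call, with the breakpoint interval spanning
the last cM before the switch to the first cM inside the run. Markers
placing on both references are dropped as ambiguous. Because A- and
D-derived markers both resolve on the A reference, an A↔D exchange would
present as intragenomic; only exchanges involving C are labeled
intergenomic.

## Synteny orthology

The denominator of a partner fraction is the summed block length on the
query chromosome's side, with overlapping blocks merged per partner before
summation to avoid double counting; fractions over partners then sum to 1 by
construction. A partner is an ortholog iff its fraction strictly exceeds
0.5. Block-size correlation is the squared Pearson correlation of side
lengths; a zero-variance side returns 0 with a `degenerate` flag rather than
NaN.

## Ks estimation and the molecular clock

Synonymous divergence uses the Nei–Gojobori (1986) counting method: each
codon contributes fractional synonymous sites (changes producing stop codons
count as nonsynonymous, so S + N equals the nucleotide length);
multi-difference codons average their synonymous/nonsynonymous step counts
over all minimal substitution pathways, excluding pathways through stop
codons (if every pathway is blocked, the average falls back to all
pathways); and pS = Sd/S is corrected with the Jukes–Cantor transform
Ks = −(3/4)·ln(1 − (4/3)·pS), flagged saturated at pS ≥ 3/4. The pairwise
counting tables are precomputed once over all 64×64 codon pairs, which makes
the batch estimator a pair of table lookups per codon.

The distribution peak is the center of the fullest fixed-width histogram bin
(default 0.005), anchored at zero, ties to the smaller center — a
deterministic, seed-free choice in preference to kernel density estimates.
The clock is the strict two-lineage identity Ks = 2rT; calibration and
dating are exact inverses by construction. The eukaryote-wide alternative
rate 8.1×10⁻⁹ substitutions/site/year ships as the named constant
`CORE_EUKARYOTE_RATE`; it is an externally sourced literature value, not a
fitted quantity.

An ML codon-model estimator would be the classical alternative for Ks; the
NG86 counting estimator was chosen as the package's method because it is
deterministic, fast enough to run exhaustively in tests, and verifiable
against a brute-force pathway-enumeration oracle, which the test suite does
on thousands of short random alignments.

## SNP filtering, LD pruning, phylogeny

Site filters mirror an inbred (cleistogamous) panel: any missing call
removes a site; a heterozygote fraction **strictly greater** than 5% removes
it (excess heterozygosity indicates collapsed paralogs or spurious mapping);
minor allele frequency below 0.1 removes it, with heterozygotes counted as
half a dose. Removal is attributed to the first failing rule in the order
unplaced → missing → het → MAF, so the report's counts add up to the input.

LD pruning is a greedy left-to-right scan per chromosome: a site is dropped
when its dosage r² with any retained site within 500 kb upstream exceeds
0.1. Greedy windowed pruning is an order-dependent approximation to optimal
thinning, matching how such reductions are done in practice; the guarantee
it provides — no retained pair within a window above the threshold — is
asserted in tests.

Trees are neighbor-joining on pairwise p-distances over allele dosage
(het = 0.5), rooted on a designated outgroup. Bootstrap resamples site
indices with replacement (canonical by index, so accession order does not
change the resampled site sets) and reports, per internal node of the
reference tree, the percentage of replicates containing that clade. NJ on
zero-length-branch regions of the tree is tie-dependent; supports for such
arbitrary resolutions are correspondingly low and not order-stable, while
supported clades are.

## Repeat landscape

Tandem discovery seeds candidate periods from 21-mers recurring at a
distance within [min_len, max_len] on the same chromosome, then scans the
period-p self-match profile s[i] = s[i+p]: a segment qualifies when its
match density over a one-period window stays at or above 1 − 2·max_divergence
(0.6 at the default 20% divergence; random i.i.d. sequence self-matches at
~25%, so the separation is wide), with edges snapped to locally dense
positions. The monomer is extracted from an interior copy of the span —
edge slop can only rotate, never corrupt, an interior unit — and
canonicalized: primitive unit first, then the lexicographically minimal
rotation over both strands. Arrays sharing a canonical monomer are pooled
and ranked by total array bp. The top-ranked monomer is the centromere
candidate, following the empirical rule that the most common tandem repeat
in a plant genome is the centromeric satellite.

Density tracks count greedy non-overlapping occurrences (both strands,
Hamming distance ≤ 10% of the monomer length), assigned to the window of
their start, so tracks are additive and a base is never counted twice. The
centromere midpoint is the count-weighted centroid of the contiguous
non-zero run around the track maximum; arm ratio uses Levan-style cutoffs
(metacentric < 1.7 ≤ submetacentric < 3.0 ≤ sub-telocentric ≤ 7.0 <
telocentric), configurable since the morphology classes have no universal
numeric boundaries. Telomere-array runs are `terminal` when their midpoint
lies within 5% of a chromosome end — "distal" made quantitative — else
`interstitial`.

The SSR scanner reports maximal perfect runs of primitive di-, tri- and
tetranucleotide units at minimum copy numbers 6/5/5 (common practice for
microsatellite surveys); non-primitive units are skipped so each locus is
reported once at its true period.

## Synthetic data: what it emulates and what it does not

The generator produces, per seed, byte-identical artifacts. Defaults are
desk-scale: 3 chromosomes × 2 Mb at 44% GC (the GC of the real assemblies),
centromere fractions (0.5, 0.3, 0.15) cycled across chromosomes so all three
observed morphology classes appear, a 159-bp centromeric monomer × 400
copies and a 665-bp telomeric monomer × 30 copies per end (the monomer
lengths of the real satellites, at array sizes a desk machine can scan),
120 markers of 64 bp per LG, subgenome divergences A→D = 1% and A→C = 5%
(close vs distant, preserving the ~2× perfect-match asymmetry), a 100-cM map
with uniform recombination density suppressed 10-fold in the middle third
around the centromere (suppression factors of 5–200× are reported across
species; 10× is a representative choice), 2000 codon pairs of 300 codons
with a truncated-normal target-Ks distribution, and 12 accessions in two
clades plus an outgroup over 3000 infinite-sites mutations.

Ks pairs are evolved only at fourfold-degenerate third positions — every
substitution is guaranteed synonymous — with a per-pair substitution
probability scaled so the expected NG86 pS matches the pair's target Ks
after Jukes–Cantor inversion. The per-pair bookkeeping stores the realized
substitution count and the NG86 quantities recomputed from the counting
tables, so tests can assert exact agreement between generator and
estimator. The peak-recovery checks use longer alignments (1000–4000
codons) and up to 4000 pairs: the binomial noise of pS at S synonymous
sites must stay below the 0.005 histogram bin for the mode to be a sharp
estimator, which at Ks = 0.3 requires thousands of sites per pair. Problem
sizes in the acceptance script follow the same power reasoning.

Not emulated: read-level data (no FASTQ or sequencing-error model — the
generator's heterozygote/missing contamination is a site-wise Bernoulli
stand-in for genotyping noise, not a model of the real tag pipeline's error
process), structural variation other than the planted translocation,
satellite higher-order repeat structure, gene-density gradients, and
transposable elements. Passing tests therefore demonstrate that the
algorithms recover planted structure under the stated statistical
assumptions, not that real oat data are this clean; on real assemblies the
perfect-identity placement rate, for example, is far below the synthetic
~100%.

## Pipeline determinism

The pipeline fans a single global seed out to per-stage seeds by stable
hashing of stage names (BLAKE2, reduced below 2³¹), so adding a stage never
perturbs earlier stages' randomness. The manifest lists every output with a
SHA-256 checksum; two runs with the same config and seed produce identical
manifests. The pipeline's repeat stage defaults to 50-kb windows (rather
than the library's 1-Mb default) because desk-scale chromosomes are 2 Mb;
both are configurable.

## Known limitations

- Perfect-identity placement is deliberately brittle to reference error;
  real marker recovery rates depend on assembly quality.
- The A-vs-D call inside a homoeolog pair is a data-driven proxy (perfect
  placement counts); historical subgenome designations can be supplied as
  prior labels when available.
- NG86 underestimates Ks relative to ML codon models at high divergence;
  the saturation flag (pS ≥ 3/4) marks where the estimate is undefined.
- Greedy LD pruning and greedy occurrence counting are order-dependent
  approximations chosen for determinism.
- The tandem-array finder reports arrays, not higher-order repeat
  structure, and its copy counts at ≤1 period precision at array edges.
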