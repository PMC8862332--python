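# Methods

This note documents the models, parameter choices and numerical
behaviour of `mitemir`, in the spirit of a methods appendix: what each
stage assumes, which knobs matter, what the synthetic benchmark does and
does not demonstrate.

## Sequence identity and homology search

All alignments use one fixed scoring scheme: match +1, mismatch −1,
gap −2 (`Bio.Align.PairwiseAligner`). Identity is always *identical
columns / all alignment columns, gap columns included* — the strict
convention under which the 0.8 clustering threshold and the 80/80
annotation rule are interpreted. Between co-optimal global alignments of
two unrelated sequences the identity so defined is not unique; the
quantity is only meaningful (and only used) in the high-similarity
regime, and the test oracles restrict themselves to substitution-derived
pairs where the optimal alignment is the gapless diagonal.

Genome-scale search is exact-k-mer seeding (k = 11, diagonal band
tolerance 20) followed by optimal local alignment inside each candidate
window. At copy divergence ≤ 20 % and element length ≥ 50 nt a preserved
11-mer is essentially guaranteed, so at pipeline scale the accelerator
returns the same hits a full scan would; this is an implementation of
the filter semantics, not of any particular external search tool.

### Annotation filters

Copies are kept when the genomic span lies in [50, 1100] nt, identity
≥ 80 %, and the alignment covers ≥ 80 % of the element; two hits whose
start and end positions both differ by < 5 nt describe the same locus
and the higher-identity one wins (ties: lexicographically smaller
element id — the underlying procedure is silent here and determinism is
worth more than any particular choice).

### The 80/80 coverage denominator

For MITE-derivedness of a precursor window the coverage denominator is
the *shorter* of window and element. Precursor windows (60–900 nt) can
far exceed element lengths, in which case an element-side denominator is
the only satisfiable reading; both denominators are exposed
(`coverage_denominator="shorter" | "element"`).

## RNA folding

The validation ladder consumes pairing topology only, so folding is
deterministic base-pair maximization (Nussinov-style interval DP) with
A-U, G-C and G-U pairs and a minimum hairpin loop of 3 — not a
thermodynamic MFE model. Pure pair-count maximization is heavily
degenerate: typical hairpin windows admit dozens of co-optimal
structures, most with isolated pairs scattered through the flanks.
The objective is therefore lexicographic — pair count first, then the
number of stacked pairs ((i, j) with (i+1, j−1) also paired) — encoded
as `1000·pairs + stacks` in one integer DP. The pair count stays
maximal (verified against exhaustive enumeration for short sequences)
while ties resolve toward contiguous helices, as stacking energies would
dictate in a thermodynamic model. Traceback is deterministic: a position
is left unpaired when co-optimal, otherwise paired to the smallest
co-optimal partner, which recovers the outermost register of a clean
stem. An MFE backend could be substituted behind the same
`SecondaryStructure` contract.

## The validation ladder

Checks run in a fixed order and the first failure codes the cluster
(N1–N15; Y if everything passes). Parameters: `foldsize` 300 nt,
Dicer range 20–24 nt, strandedness bounds 20 %/80 %, ≤ 5 unpaired mature
bases, duplex limits 2 bulges / 3 bulged nt, precision threshold 50 %.
Conventions the ladder needs but the underlying procedure leaves
implicit:

* the candidate mature is always the cluster's major RNA (ties:
  lexicographically smallest sequence) — single-pass semantics; no
  second candidate is tried when the major RNA fails;
* the precursor window is the cluster span, extended symmetrically to a
  minimum of 60 nt with genomic flank;
* the star is the duplex partner of the mature with 2-nt 3' overhangs on
  both arms, computed from the first/last paired mature base outside its
  own overhang;
* a *bulge* is a maximal unpaired run strictly inside the duplex
  (flanked by paired bases) on either arm, overhangs excluded;
* "3' variants" (precision check) are reads sharing the mature's or
  star's 5' end with 3' ends within ±2 nt;
* "single stem" means every paired mature base has its partner on one
  side of the mature, with antiparallel (monotonically decreasing)
  partner order;
* the star counts as sequenced only when a read with the exact star
  sequence and 5' end is present.

## Target analysis

The expectation score penalizes, per miRNA position from the 5' end:
mismatch 1.0, G:U wobble 0.5, gap open 2.0 / extend 0.5, everything
multiplied by 1.5 inside the seed (positions 2–13); candidate sites
require expectation ≤ 5.0. All six constants live in `ScoringConfig`.
The predicted cleavage position is the transcript base paired to miRNA
position 10 (canonical slicing between 10 and 11), computed under the
gapless register. Transcript scanning is a vectorized gapless sweep over
all windows; windows near the cutoff are re-scored with the gapped
alignment and the better value kept.

Degradome categories follow the classical ranking: 0 unique maximum,
1 tied maximum, 2 above the median, 3 at or below it, 4 a single read;
positions without signal are dropped. The median is taken over
*positive* counts only — sparse degradome vectors would otherwise have
median 0 and categories 2/3 would collapse.

The permutation p-value shuffles the miRNA (composition-preserving,
seeded Fisher–Yates) `n_perm` times (default 1000); each shuffle records
its best gapless expectation over the transcript positions whose
category is at or below the observed one, and
p = (1 + #{best ≤ observed}) / (n_perm + 1). Using the gapless score on
both sides keeps observed and null exchangeable, which is what makes the
p-value uniform under a true null (verified by KS test). The category
definitions and this null are explicit, seeded re-specifications of
behaviour that degradome pipelines usually leave inside an external
tool; they are approximations, not bit-compatible re-implementations.
When several degradome libraries are supplied they are evaluated
per-library and the minimum p is reported.

Both evidence streams must agree on the exact (miRNA, transcript,
cleavage position) key; retained sites additionally need category ≤ 3,
p < 0.05 and expectation ≤ cutoff. Category-4 (single-read) sites are
carried through scoring but can never pass the merged filter. MITE
detection at the target lifts the cleavage position to genomic
coordinates through the exon structure and requires an 80/80 hit whose
span contains that exact location.

## Synthetic data: what it emulates, and what it does not

Defaults (one `SimConfig`): 150 kb genome on 2 chromosomes, 10 two-exon
plus-strand genes (5'UTR/CDS/intron/CDS/3'UTR), 6 MITE families, 14
generic MITE copies at 2 % divergence, 10 miRNA loci (40 % inside MITE
copies), mature lengths drawn from the observed size-class distribution
(21 nt dominant), 3 sRNA libraries of ~100 reads per locus plus 60
scattered background reads and 2 mixed-strand noise islands, 6 planted
cleavage targets, degradome background ~40 5'-ends per transcript with
20× spikes at slice sites. All randomness flows from the single seed;
a fixed seed reproduces byte-identical files.

Planting geometry. MITE consensus = TIR + core + revcomp(TIR), insertion
= TSD + copy + TSD. A miRNA-hosting family gets a TIR long enough to
carry the mature (≥ mature + 4; 26 nt default) and a total length of
120–185 nt so that the mature-to-star span stays inside one sRNA cluster
and under the folding window. The mature sits at TIR offset 2; the star
is the element's last `L` bases — the duplex-partner region with its
2-nt 3' overhang. Standalone (non-MITE) loci are
flank + mature + loop + revcomp(mature) + flank with non-self-pairing
A/C flanks and loop. Because any copy of a hosting family carries the
reverse complement of the mature near its 3' end, planting an exact
family copy in a 3' UTR *is* the target-site planting mechanism for
MITE-derived miRNAs; non-MITE miRNAs get the literal reverse complement
inserted into a sampled transcript region.

Two deliberate departures from naive planting keep read placement
unambiguous and make recovery failures attributable to the method under
test rather than to simulation artifacts:

* every planted stem carries exactly **one engineered mismatch**
  opposite the middle of the mature (real miRNA/miRNA* duplexes are
  imperfect; a perfect stem would make the two arms exact reverse
  complements, letting every mature read exact-map to the minus strand
  of its own precursor). One mismatch keeps the duplex valid (one 1-nt
  bulge per arm) and costs 1.5 at the planted target site — well under
  the cutoff;
* genomic copies of a hosting family that are *not* the production locus
  are forced to diverge inside the mature and star footprints, and
  background reads avoid a 400-nt exclusion zone around planted loci;
  compartments (introns, promoters) hosting a miRNA block take no other
  inserts. Without this, multi-mapping reads stretch cluster bounds and
  fold windows in ways real screens resolve with dedicated multi-mapping
  machinery that is out of scope here.

Consequently the benchmark demonstrates that the *method* recovers
cleanly planted signal (recall ≥ 90 %, zero validated noise) and rejects
noise; it does not demonstrate robustness to sequencing error, adapter
remnants, polyploid homeologs, overlapping loci, or heavy multi-mapping
— all absent from the generator by design.

## Numerical and formatting choices

* Coordinates are 1-based inclusive in every GFF-facing type; 0-based
  half-open slices are internal only.
* Percentages round half-up to one decimal, locale-independent
  (`decimal.Decimal`).
* RPM totals are multiplicity-weighted mapped-read counts, not distinct
  sequences.
* Cluster deduplication is exact on (major RNA, chrom, start, end) by
  contract; the pipeline passes `tolerance=5` so that interval-pass
  clusters, whose bounds are clipped at interval edges, collapse onto
  their de-novo twins.
* Degenerate inputs: empty genomes annotate to nothing; clusters without
  reads code N1; folding an empty sequence, clustering an empty element
  list, malformed intervals, zero library totals and out-of-transcript
  degradome positions raise `ValueError`.

## Known limitations

* The ladder evaluates only the major RNA per cluster; an abundant
  second read that would pass is never tried.
* Pair-count folding ignores thermodynamics; pathological windows can
  fold differently from an MFE model even with the stacking tie-break.
* Identity between distantly related sequences depends on the chosen
  co-optimal alignment and should not be over-interpreted below ~50 %.
* The de-novo and interval passes can both report a locus with bounds
  differing by more than the dedup tolerance, in which case it is
  counted twice in raw record lists (recovery metrics are
  overlap-based and unaffected).
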