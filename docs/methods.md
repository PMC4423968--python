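# Methods

This note documents the models, statistics and design decisions behind
pirnakit: a pipeline for characterizing Piwi-interacting RNAs (piRNAs) and
other small RNAs in testis small-RNA sequencing libraries, exercised
end-to-end on synthetic data with known ground truth.

## The analysis

piRNAs are ~24–32 nt germline small RNAs loaded onto Piwi-clade Argonaute
proteins. Three population-level fingerprints identify them in sequencing
data, and the pipeline computes all three:

1. **Primary piRNAs** are processed from long single-stranded precursor
   transcripts of genomic piRNA clusters and carry a strong 5'-uridine bias
   (1U). Their length distribution is roughly Gaussian with a mode near
   30 nt.
2. **Secondary piRNAs** arise in the ping-pong amplification loop: a
   piRNA-guided cleavage 10 nt from the guide's 5' end creates a responder
   piRNA on the opposite strand whose 5' end overlaps the guide's by
   exactly 10 nt, and which inherits an adenine at position 10 (10A)
   complementary to the guide's 1U.
3. **piRNA clusters** are the 10–100 kb genomic loci producing the
   precursors, detectable as regions of extreme mapped-read density, either
   mono- or bidirectionally transcribed.

The pipeline stages are: adapter clipping and 18–34 nt size selection;
collapsing to unique sequences with counts; sense-orientation exact
matching against labeled ncRNA reference sets (miRNA, tRNA, rRNA, snoRNA,
snRNA — precedence in that order) to remove structural-RNA fragments;
perfect-match genome mapping of the remaining putative piRNAs with all hits
reported; multimapper weighting; signature statistics; cluster detection
and characterization; gene-level target calling on spliced transcripts; a
cross-species homolog-overlap permutation test; and tRNA-fragment (tRF)
profiling.

## Statistics

**Multimapper weight.** Every sequence carries weight w = 1/h where h is
its total number of genomic hits; a hit's mass is count × w. Each sequenced
read therefore contributes total mass exactly 1, an invariant the tests
assert on every simulation. Transcript-level analyses reuse the genomic
weights by default (sequences without genomic hits fall back to reciprocal
transcript hit counts); reciprocal transcript-hit weighting is selectable.

**Ping-pong signature.** For opposite-strand hits on one reference with 5'
positions p (plus) and q (minus), the 5' overlap is o = q − p + 1. For
every o in 1..20 the histogram bin s(o) accumulates the product of the two
sides' weighted masses, summed over all 5'-position pairs. Product
weighting makes the histogram invariant to duplicating a multimapping
locus. The z-score is

    z = (s(10) − mean(background)) / sd(background)

with background = all bins except o = 10 and sd the sample (n−1) standard
deviation. A flat histogram scores z = 0; a spike over a constant
background has no finite z and the call falls back to the 2-fold rule. The
signature is called *evident* when s(10) is at least twice the next-highest
bin (boundary inclusive); a z threshold can additionally be required via a
flag but is off by default.

**Cluster scan.** A 1-kb window slides in 0.1-kb steps. A window qualifies
when (i) its weighted mass is at least `min_window_mass` (default 5 reads),
(ii) its density (mass/kb) is at least `density_factor` (default 10) times
the background density, (iii) at least 75% of its mass comes from 24–32 nt
reads, and (iv) at least 50% from reads with a 1U or 10A. The background
density is the **median** window mass per kb over the whole genome
(assembly-gap windows — N runs ≥ 100 bp — excluded). The median rather
than the mean is deliberate: cluster reads are so concentrated that they
dominate a genome-wide mean (in the default simulation ~90% of reads fall
in ~1.5% of the genome), which would make the threshold scale with the
very signal being detected; the median tracks the background the factor-
of-10 rule intends. Qualifying windows that overlap or abut within one
step merge; each merged region is then trimmed to the span of its actual
read support (the window grid otherwise pads a dense region by up to
window − step per side), and trimmed regions shorter than `min_size`
(default 10 kb) are discarded. Directionality is mono-X when ≥ 75% of a
cluster's weighted mass maps to strand X (boundary inclusive), else
bidirectional; bidirectional clusters get a strand-switch point maximizing
left/right strand consistency (ties leftmost), and the "main strand" at a
position is the dominant strand of that arm. These qualification
thresholds are package choices — the analysis they descend from delegated
them to a cluster-prediction tool whose full parameterization is not
public — so cluster counts on real data are approximate by design; all are
exposed in configuration.

**Gene targets.** One transcript per gene (longest spliced form, avoiding
isoform double counting). Coverage is rpm = weighted mass × 10⁶ / mapped
library size; genes with rpm ≥ 10 (inclusive) are tested for a ping-pong
signature in transcript coordinates (sense = matches the mRNA, antisense =
matches its reverse complement), and a target requires both the coverage
and an evident signature.

**Homolog-overlap test.** X = number of species-A targets with at least
one homolog among species-B targets (many-to-many homology collapsed on
the A side). Each Monte-Carlo draw samples |targets_A| and |targets_B|
genes uniformly without replacement from the two universes and recomputes
X; E(X) is the mean and p = (#{X ≥ X_obs} + 1)/(draws + 1), the add-one
estimator that can never return 0 and recovers the plain frequency as
draws → ∞. The universes are an explicit input (all expressed
protein-coding genes in the synthetic studies). The library default is 10⁶
draws; the test suite and acceptance script use 10⁵ draws, at which the
Monte-Carlo standard error is well below the tolerances checked (the
calibration test verifies E(X) and p against exact hypergeometric values
at 3 SE).

**tRFs.** Reads classified as tRNA are matched back to the (deduplicated)
tRNA set; a read matching several anticodon types splits its mass 1/n
across them; the start position is the leftmost 1-based match coordinate,
and starts ≤ 3 count as genuine 5' fragments (tolerating slight 5'
heterogeneity) versus interior-start degradation. Shares use weighted
counts by default; raw counts are selectable.

## The synthetic-data generator

`simulate.make_genome` / `simulate_reads` build, per seed (one global seed
drives per-component RNG streams, so components are independently
reproducible):

- 2 chromosomes × 2.5 Mb of uniform random background sequence;
- 3 planted clusters of 15–40 kb (one bidirectional with a central
  divergent switch point, the rest mono-directional), pairwise disjoint;
- 4 TE families (consensus lengths 160–400 bp), 40 copies/family inside
  clusters and 60 outside, each copy mutated by independent substitutions
  at a per-copy divergence drawn from 0–30% (no indels, so RepeatMasker-
  style divergence equals the substitution fraction), inserted sense to
  the local cluster main strand with per-family probability β (defaults
  0.8/0.7/0.6/0.5), minus-strand copies reverse-complemented. Extra-
  cluster copies keep out of clusters and a 2-kb flanking margin: an
  identical copy abutting a cluster would collect multimapped cluster-read
  mass and make the planted boundary ill-defined at 1-kb resolution;
- 12 genes (2–4 exons) outside clusters, every sixth a pseudogene, plus
  one single-exon 1.2-kb gene embedded antisense within each cluster;
- 8 tRNA genes (72 nt, named by the AminoAcid-Anticodon convention) and 5
  miRNA loci written into the genome; small rRNA/snoRNA/snRNA reference
  entries;
- 200,000 reads: 5% uniform degradation contaminants (80% genomic, 20%
  tRNA-interior), 5% 5'-tRNA halves with strongly skewed type abundances,
  2% miRNA reads, and the rest cluster-derived piRNAs with lengths
  round(N(30, 1.5)) clipped to [24, 33]. A fraction f/(1+f) of the piRNA
  reads (f = 0.3 by default) are ping-pong secondaries placed exactly 10 nt
  inside their guide's 5' end on the opposite strand. Because a
  secondary's position-10 base is the complement of its guide's 5' base,
  10A(secondaries) ≡ 1U(paired primaries); the generator therefore gives
  paired primaries P(5'T) = 0.7 (the 10A target) and unpaired primaries
  (0.8 − 0.7·s)/(1 − s) with s the paired fraction, so the overall primary
  1U is 0.8. 1U states are imposed by rejection sampling of read start
  positions, keeping every read a perfect genome match. Mono-cluster
  primaries are entirely on the main strand: antisense mass in a mono
  cluster arises only through ping-pong, which with f = 0.3 yields a main-
  strand fraction of ~0.77, above the 0.75 mono threshold — the
  directionality call is therefore informative, not guaranteed.

Every read carries a ground-truth record (class, origin locus, pairing),
and |reads| equals the sum of class counts.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing errors and quality scores, ligation
and PCR bias, adapter mismatches, indel/mismatch mapping, isoform
complexity, nested/fragmented TE copies, non-uniform background
composition, and chromatin or expression context. Recovery results on
synthetic data demonstrate the estimators' correctness and calibration
under the stated model, not performance on real libraries.

## Numerical and edge-case conventions

- Internal coordinates 0-based half-open everywhere; GTF and RepeatMasker
  converted on I/O (1-based inclusive; RepeatMasker "C" = minus strand).
- Adapter clipping is an exact match of the adapter's first 8 nt; reads
  containing N are discarded before collapsing (a perfect matcher cannot
  place them); 5' tags are removed as a fixed-length prefix strip.
- The exact-match index seeds on 12-mers and verifies every candidate by
  full string comparison, so results equal a naive all-positions scan
  (asserted against one in the tests). Reads are ≥ 18 nt, guaranteeing a
  seed. Palindromic sequences report one hit per locus and strand state.
- Feature partition assigns each hit by its 5' position with precedence
  TE > exon > intron > pseudogene (piRNA identity is defined by the 5'
  end, and the TE analysis removes TE-derived reads before gene-level
  shares); overlapping same-class features resolve to the leftmost.
- Weight conservation is exact to 1e-9 and checked as an invariant.
- Zero-variance ping-pong backgrounds: see above. Empty overlap histograms
  are flagged, not errors.
- The insertion-bias (β) recovery analysis pools TE copies across
  families configured at the same β: a per-family check at 100 copies
  would sit at only ~1.25 binomial SD of the ±0.05 band and fail by
  chance far too often to be informative.

## Problem sizes used in tests

The shared test simulation uses 2 × 0.6 Mb and 30,000 reads; the planted-
cluster recovery check runs 20 seeds at the full default scale (2 × 2.5 Mb,
200,000 reads); permutation calibration uses 10 configurations × 10⁵
draws; null/alternative ping-pong behavior uses hit-level simulations
(uniform placement with planted 10-nt offset pairs) at 10³–10⁴ pairs.
These sizes give the statistical resolution each check needs (binomial SE
≤ 0.5 of each tolerance) while keeping the suite fast.

## Known limitations

- The cluster caller is an equivalent-parameter re-implementation, not a
  clone of any published tool; absolute cluster counts on real data will
  differ from tools with probabilistic window models.
- Exact matching only: polymorphic or edited piRNAs are unmapped by
  design.
- ncRNA classification is exact substring matching in sense orientation;
  fragmentary matches shorter than the read are not recognized.
- The homolog-overlap p-value is Monte-Carlo, with resolution 1/(draws+1).
- Whether transcript-level normalization should divide by genomic or by
  transcript hit counts is ambiguous in the source analysis; genomic is
  the default, and both modes are exposed.
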