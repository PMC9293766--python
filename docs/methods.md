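# Methods

## The screen

The package identifies mRNAs undergoing stop codon readthrough (SCR) from
ribosome profiling data.  All analysis is performed in transcript (cDNA)
space with 0-based, half-open coordinates; spliced genome coordinates are
out of scope.

### Curation

For every transcript with annotated start and canonical stop codons we scan
codon-by-codon downstream of the stop for the first in-frame stop codon.
The region between the two stops (whole codons, excluding both stop
triplets) is the interstop codon region (ISR); the sequence after the
downstream stop is the rest-of-3′UTR.  Transcripts are rejected when:

* no downstream in-frame stop exists;
* the ISR or the rest-of-3′UTR is shorter than 45 nt (too little room for
  density and coverage statistics to mean anything);
* the ISR shares an exact sense-strand substring of more than 24 nt with
  the CDS of another gene's transcript, implemented as a k-mer (k = 25)
  index over all CDSs — reads from such an ISR could equally well come from
  that CDS.  CDSs of the same gene are excluded by default, because an
  isoform annotated with the extended ORF would otherwise veto its own
  sibling; a strict mode disables the exclusion;
* more than 10% of ISR bases are ambiguous (N).  Windows containing N never
  participate in k-mer matching.

Rejected transcripts stay in the output with their reasons recorded, so the
input is always fully accounted for.

### Read processing

Reads are adapter-truncated (leftmost exact occurrence of the adapter's
first 10 nt), trimmed by a fixed 3 nt at the 5′ end (these bases are
low-quality in the protocols this models), and dropped below 18 nt.  Reads
occurring exactly within any noncoding RNA (either strand) are removed.
Alignment to the curated transcriptome is exact-match only: a k-mer-seeded
(k = 18) search whose result set provably equals brute-force substring
scanning.  Because the screen discards any alignment with even one
mismatch, a general-purpose aligner would add capability that the contract
immediately throws away; the exact matcher makes the zero-mismatch rule
structural.  An import path for externally produced transcript-space SAM
(filtered by the NM tag) is provided.  Multi-mapping reads are counted on
every transcript they match (isoforms share 3′UTR signal); `n_loci` is
recorded so unique-only analyses remain possible.

Footprint lengths: the three most abundant aligned lengths are selected per
dataset (ties resolved toward the shorter length); all downstream
statistics use only these.

### Region assignment and statistics

A footprint is assigned by its 5′-end position alone:

* CDS window: `[cds_start − 12, stop − 22]`
* ISR window: `[stop − 12, downstream_stop − 22]`
* 3′UTR window: `[downstream_stop − 12, transcript end]`

(inclusive bounds; `stop` denotes the first nt of the codon).  The ~12 nt
offset reflects 80S footprint geometry: a read whose P-site decodes a
region's first codon has its 5′ end ~12 nt upstream.  The upper bounds stop
22 nt before the closing stop so that no footprint is ambiguous between
regions; the 9-position gaps are deliberate, and gap reads are reported as
unassigned rather than silently dropped.  Whether each bound is inclusive
is a documented choice (both inclusive here) and is config-overridable.

Densities divide read counts by the *biological* region lengths (CDS, ISR,
rest-of-3′UTR), not window lengths, which would distort short regions.
Coverage is the fraction of region nucleotides under at least one assigned
footprint, footprints clipped to the region.  Frames are
`(pos5 − cds_start) mod 3`.  Stop-spanning counts footprints covering all
three nt of the canonical stop, regardless of window assignment.

Dataset QC makes the "clear three-nucleotide periodicity" judgement
operational: a dataset passes when its best footprint length concentrates
≥ 0.55 (configurable) of CDS-assigned 5′ ends in one frame.

### The four levels

1. **Density** — ISR density ≤ CDS density (an ISR hotter than its own CDS
   is not readthrough) and ISR density ≥ 4× rest-3′UTR density.  A zero
   3′UTR density with a non-empty ISR counts as an infinite ratio.  Both
   comparisons are inclusive at the boundary ("at least 4-fold").
2. **Coverage** — ≥ 30 ISR reads; ISR coverage strictly > 0.5; rest-3′UTR
   coverage strictly < 0.25; ≥ 1 stop-spanning footprint.
3. **Periodicity** — reference distribution: per-frame mean and population
   SD of CDS frame-fraction vectors over all transcripts with ≥ 200 CDS
   reads (each transcript contributes one vector; a per-codon pooling mode
   is available behind a flag).  A candidate passes when its ISR vector
   *and* its CDS vector each lie within 2 SD of the reference mean in at
   least one frame (the CDS requirement can be relaxed by flag).  A frame
   with zero reference SD is satisfied only by exact equality.
4. **Annotation collision** — the ISR peptide (standard genetic code) is
   searched for an exact window of ≥ 8 aa in the proteome, via an 8-mer
   index; a hit eliminates the candidate.  This replaces a BLAST step: for
   the annotation-error question an exact-window criterion is the sharper
   tool, and an externally produced elimination list is accepted for users
   who prefer BLAST.  With no proteome the level passes with a prominent
   warning.

All four levels are evaluated for every transcript regardless of earlier
failures, so reports can show near-misses; the funnel applies them
cumulatively.  Across datasets, a transcript is called when it passes all
levels in ≥ K datasets (default K = 1: the union rule; the combination rule
is not forced by the data model, so it is a parameter).  A gene is positive
when any isoform is.

### Sequence features

Stop-codon usage of positives is compared with expectation from the stop
frequencies of all curated transcripts (`fold = observed/expected`, plus a
chi-square goodness-of-fit as a convenience).  The stop-context position
frequency matrix covers 6 nt either side of the stop triplet by default
(window width configurable; the triplet itself excluded unless requested);
information content is `2 − H` bits per position, with an optional Basharin
small-sample correction for parity with common logo software (off by
default; contexts are read qualitatively).

## The simulator

`SimSpec` states a world; everything is drawn from one seed
(`numpy.random.default_rng([seed, k])` per stage) and all outputs are
byte-identical under a fixed seed.

* **Structure** — 5′UTR 30–60 nt; CDS 300–1,800 nt; ISR 60–300 nt;
  rest-3′UTR 60–400 nt (CDS/ISR whole codons, interiors stop-free);
  stop usage TAA/TAG/TGA = 0.36/0.20/0.44, approximating dicot
  transcriptomes.
* **Footprints** — lengths 24/25/26 at 0.25/0.40/0.35; 5′ end at
  (decoded codon start − 12) plus a frame offset drawn from per-gene frame
  probabilities; raw reads carry 3 extra upstream transcript bases that the
  standard trim removes, plus the adapter when configured.
* **Frame bias** — per-gene frame probabilities are Dirichlet-distributed
  around (0.80, 0.15, 0.05) with concentration 200, i.e. an SD of ~0.03 on
  the dominant-frame fraction across genes.  This inter-gene dispersion is
  what the level-3 reference SD measures in real data; with no dispersion
  the reference SD collapses to sampling noise and the 2-SD test becomes
  vacuous or unstable.  The value was chosen by a design study balancing
  two properties the world must have simultaneously: genuine readthrough
  (same frames as the CDS) accepted, +1-rotated frameshift signal rejected.
  Optional ±1 nt jitter models imperfect digestion (off by default; the
  frame mixture already encodes imperfect phasing).
* **Readthrough** — a planted gene with efficiency *e* receives ISR reads
  at *e* times its local CDS per-codon rate, over the recoded stop codon
  (dwell weight 3 — recoding is slow, so ribosomes pile up there, which is
  also what makes stop-spanning footprints observable) and the ISR codons.
  Readthrough ribosomes terminate at the downstream stop; no footprint is
  emitted there and no double readthrough occurs.  Terminating ribosomes at
  the *canonical* stop contribute one decoded position to every gene's CDS
  process, so even non-readthrough genes show a small, low-coverage ISR
  window count — exactly the nonspecific signal levels 1–2 must reject.
* **Background and contamination** — 0.2% of a gene's reads are placed
  uniformly, frame-free, downstream of the canonical stop; 5% of all reads
  are windows of the ncRNA set (either strand), removed by the depletion
  step.
* **Decoys and collisions** — frameshift decoys receive ISR reads with
  frame probabilities rotated by +1; annotation-collision plants are
  readthrough-like genes whose 10-aa ISR-peptide window is spliced into an
  unrelated proteome entry; CDS-collision plants carry a codon-aligned
  27-nt copy of another gene's CDS in their ISR (sense codons, so the ISR
  geometry is unchanged).

### The benchmark world

`benchmark_spec(seed)`: 100 genes — 20 readthrough (efficiency uniform
0.1–0.8), 10 frameshift decoys, 5 annotation collisions, 65 negatives.
Signal-carrying genes use CDS 300–450 nt, ISR 240–300 nt, rest-3′UTR
350–400 nt, and their expression is raised until the expected ISR depth
reaches 250 reads, capped at 900 CDS reads per gene.  Two constraints force
this geometry, and they are worth stating because they are properties of
the published thresholds, not of this implementation:

* the 2-SD periodicity test needs enough ISR reads (≳100) for a
  frame-fraction vector to be measurable against a reference SD of ~0.03;
* 3′UTR background scales with a gene's total reads (it is a fixed
  fraction), so the <25% 3′UTR-coverage bound caps how deep any gene may
  be sequenced before its own background disqualifies it — with 25-nt
  footprints on a ~400-nt rest-3′UTR, roughly 5 background reads suffice.

Detection at efficiency 0.1 is therefore only possible for genes whose ISR
is long relative to their CDS; the benchmark plants positives in that
sensitive regime, which is the regime the screen targets.  Fixed
count/coverage thresholds make detectability depth- and geometry-dependent;
this is a real property of the method, and the benchmark does not pretend
otherwise.  One planted positive at the stated depths still misses
a coverage bound occasionally (the seed-1 run recovers 19/20 with zero
false positives).

### What a green test establishes (and what it does not)

The simulator emulates footprint geometry, frame dispersion, background
and contamination, but not: ligation/PCR sequence bias, nucleotide-specific
digestion ends, condition-specific readthrough, nonsense-mediated decay,
uneven codon-level dwell times (beyond the stop pause), or multi-condition
designs.  Parameter recovery therefore validates the screen's logic and
its thresholds' interplay — not performance on any particular real
library.  The published counts for *A. thaliana* depend on specific SRA
datasets and annotation releases and are not reproduced here.

## Numerical choices

* Population SD (n denominator) for the frame reference, matching the
  "reference distribution" reading of the procedure.
* `select_top_lengths` breaks count ties toward shorter lengths, making
  length selection deterministic.
* Zero reference SD in a frame → exact-equality criterion for that frame.
* Metagene windows are 62 nt, offsets −31…+30 around the first nt of the
  anchor codon; the periodicity score is the modal-frame fraction of all
  CDS-assigned 5′ ends of that length.
* Density denominators are region lengths; empty regions are a hard error
  (curation prevents them).
* Coverage masks are boolean per-nucleotide arrays; no smoothing.

## Known limitations

* Transcript space only; no spliced alignment, no paired-end reads.
* The exact matcher is memory-proportional to transcriptome size (one dict
  entry per 18-mer position); fine for desk-scale and plant-transcriptome
  work, but a disk-backed index would be needed far beyond that.
* The ncRNA filter is exact-substring; a contaminant read with a sequencing
  error survives it (as it would survive a zero-mismatch policy anywhere).
* Level 3 is undefined for ISRs with no reads in the selected lengths; such
  candidates fail it, which is the conservative direction.
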