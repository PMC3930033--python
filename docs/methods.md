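# Methods

## Overview

`genomescreen` detects cross-species and adapter contamination in
sequencing datasets by aligning a subsample of reads against a panel of
reference genomes and, separately, against a set of adapter/primer
sequences. The two screens use deliberately different alignment models:
species alignment is ungapped and end-to-end, because a trimmed 36-base
read either originates from a genome or it does not; adapter detection
is local with affine gaps, because only part of a read may be adapter
(3′ read-through when the insert is shorter than the read). The screen
cannot, by design, detect contamination from the *same* species as the
target — such reads are indistinguishable from signal at this level.

## Sampling and trimming

A fixed-size sample (default 100,000 reads) is drawn across all FASTQ
files of a dataset by single-pass reservoir sampling (Algorithm R) with
an explicit seed. Reservoir sampling was chosen over taking the first N
records because early records in a FASTQ are not representative (tile
and cycle effects); over evenly spaced subsets because it needs no
second pass or record count. Reads are trimmed to 36 bases from the 5′
end. Reads shorter than the trim length are kept at full length rather
than discarded, so short-insert libraries remain visible; their
alignment is end-to-end over their own length and the mismatch ceiling
is not rescaled (a deliberate simplification — short reads are a small
minority and rescaling would complicate the error-rate baseline).
Quality scores are validated (Phred+33, printable range), carried
through, and summarised as a per-dataset mean, but never gate alignment.

## Species alignment

Each genome is indexed by its exact k-mers (default k = 12, forward
strand only; windows containing N are skipped). A read aligns to a
genome if some end-to-end placement — of the read or its reverse
complement — has at most `max_mismatches` substitutions (default 2),
with N on either side always counting as a mismatch. Candidate
placements come from exact k-mer seeds taken at non-overlapping offsets
covering the read (0, k, 2k, …, plus the tail window). For the default
36/12/2 configuration the pigeonhole principle makes seeding exact: any
placement with ≤ 2 mismatches leaves at least one of the three seed
partitions mismatch-free. For non-default configurations where
`(trim_length // k) <= max_mismatches` the seed search is best-effort;
the oracle-equivalence tests pin the default configuration.

Collections (e.g. a pooled set of bacterial genomes) are indexed per
member genome but reported as one unit: per (read, unit) only the best
mismatch count over members is kept. Ties between placements are
irrelevant because no coordinate is reported.

## Ranking, assignment, and error rates

Units are ranked once by pre-assignment aligned-read counts (no
iterative re-ranking); ties break target-first, then lexicographically,
so rankings are deterministic. Every aligned read is assigned to the
single highest-ranked unit among those it aligns to. Consequently the
declared target absorbs homologous reads and a contaminant's assigned
count reflects reads mapping uniquely to it.

A unit's error rate is total mismatches over total aligned bases *of
its assigned reads*. Using assigned (not merely aligned) reads keeps a
contaminant's error rate from being diluted by homologous reads that
were assigned elsewhere. The rate is bounded by
`max_mismatches / trim_length` (≈ 0.056 by default); reads whose true
error count exceeds the ceiling fall out of the alignment entirely,
which biases the estimate slightly low at high substitution rates —
negligible at the ≤ 1% per-base rates the screen is meant for
(P(≥3 errors in 36 bases) ≈ 6 × 10⁻⁵ at 1%).

## Adapter screen

Adapter detection runs the Smith–Waterman local alignment with Gotoh's
three-state affine-gap recurrence, on the same trimmed reads as the
species screen (keeping runs comparable; read-through is visible within
36 bases whenever ≥ 16 adapter bases are present). Scoring defaults are
match +1, mismatch −1, gap open −2, gap extend −1; a hit requires score
≥ 16 and identity ≥ 0.9 over aligned columns. The score threshold is
calibrated by the alphabet, not by data: ≈ 16 matched bases are
essentially impossible by chance in a 36-mer against a fixed short
adapter (the clean-lane check measures ~0% false positives on 10,000
random reads). Both orientations of each adapter are screened; one hit
per read is kept (adapter contamination is a per-read boolean in the
report). Detection is deliberately independent of the species screen:
a read can count as both species-assigned and adapter-positive.

The production scan is a numpy-vectorised scoring pass (same
recurrence, advanced row-by-row over adapter positions with all reads
in parallel); spans and identities are recovered by re-running the
single-pair DP with traceback only on reads whose score clears the
threshold. The batch scorer is tested cell-for-cell against the
reference DP, and the reference DP against brute-force enumeration of
all affine-gap local alignments on short strings.

## Report

Each dataset is one stacked bar of assigned counts in descending order
plus a grey unmapped segment; colors are a pure function of role
(green target / orange control / red other / grey unmapped). Opacity is
`max(0.25, 1 − error_rate / (max_mismatches / trim_length))` — linear
in the mismatch rate with a floor so segments never vanish; only the
monotone direction (lower error ⇒ more opaque) is semantically
meaningful. Adapter counts overlap species counts and cannot be
stacked, so they are drawn as a thin mauve companion bar. Outputs are a
PNG chart, a TSV table with fixed column order (`dataset, unit, role,
aligned, assigned, pct_assigned, error_rate, adapter_count,
pct_adapter, unmapped`), and a self-contained HTML page; the TSV is
byte-deterministic for fixed input.

The control check compares the observed control-assigned fraction to a
per-dataset expectation with a ±50% relative band. A lane is
"low-yield" when the target fraction is below 0.5 (the package's
choice; the concept needs a threshold and 50% cleanly separates good
lanes from problem lanes in practice). Within band + low yield ⇒
sequencing-side issue; out of band + low yield ⇒ sample/quantification
issue; out of band + good yield ⇒ unexpected control level.

## Synthetic data

The generator emulates what the screen consumes: uniform random
genomes, a homolog pair sharing a copied span (to exercise rank-based
assignment), and lanes mixed from panel units at stated fractions with
per-base substitution noise and a fraction of reads built as
short-fragment + adapter suffix (≥ 16 adapter bases within the first
36). Defaults for study-condition lanes are 10,000 reads of 100 bases;
acceptance-scale genomes are 50 kb — large enough that a random 36-mer
never aligns by chance (collision probability ≈ 2 × 50,000 / 4³⁶ per
read), small enough to screen in seconds.

What the generator does *not* emulate: indels (the error model is
substitution-only, matching the ungapped aligner), position-dependent
quality or error profiles, duplicates, tiles/optical artifacts, and
real genome repeat structure. Passing tests therefore demonstrate the
screen's counting, ranking, and detection logic under its own model
assumptions, not robustness to platform-specific artifacts or to
repeat-rich genomes, where k-mer seeds would hit many placements and
runtime (not correctness) would suffer.

## Numerical and design choices

- Seeds: every stochastic component (sampling, simulation) takes an
  explicit integer seed; identical config + seed reproduces outputs
  byte-for-byte (tables; image encoding is not guaranteed
  byte-stable).
- Tie-breaks: ranking ties are target-first then lexicographic;
  equal-scoring alignment placements are interchangeable.
- Degenerate inputs: empty panels, empty FASTQ, malformed records
  (with record number), out-of-range quality characters, unknown units
  in role maps or recipes are all fatal with specific messages;
  non-alignment of a read is a normal outcome.
- Per-dataset isolation: one dataset's failure is recorded and the
  rest of the run completes, unless strict mode is set.
- Test problem sizes (20–50 kb genomes, 2,000–10,000-read lanes) were
  chosen so statistical checks have power at 3-standard-error
  tolerances while the whole suite stays fast.

## Known limitations

- Same-species contamination is undetectable by construction.
- Contaminants absent from the panel appear only as unmapped reads.
- Mismatch counts are defined by this package's ungapped contract; no
  claim is made of equivalence with any external aligner's policy.
- Collections report presence, not member-level attribution.
- The adapter screen detects but does not trim; identity/span values
  describe one optimal alignment among possibly several.
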