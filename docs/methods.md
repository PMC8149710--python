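# Methods

This note records the conventions, models, and defaults the package is
built on, the places where a genuine design choice had to be made, and
what the synthetic-data tests do and do not demonstrate.

## Coordinates and the region table

All intervals are stored 0-based half-open (the BED convention).
TSV/CSV input is assumed 0-based half-open as well; `one_based=True` on
`load_regions` decrements start coordinates for 1-based files, since
spreadsheet-exported tables come in both conventions and the file itself
cannot tell you which. BED and narrowPeak input are natively 0-based and
ignore the flag.

Rows receive stable integer ids 1..n in file order. Filtering and
tagging never reorder or remove rows; `clone_subset` is the only way to
materialise a renumbered table. Malformed rows (non-integer coordinate,
empty chromosome, `start >= end`) are dropped at load time with a
logged warning and a count in `table.meta["rejected_rows"]` — user
tables exported from spreadsheets are routinely dirty, and a single bad
line should not kill an import.

Metadata columns are typed on load: a column is numeric when at least
half of its non-empty cells parse as numbers (the remaining bad cells
become missing); a column whose non-empty cells are all `True`/`False`
is boolean; everything else is text. Missing values are a single
sentinel concept (NaN / NA), rendered as an empty field on export.
Numeric parsing goes through Python's correctly-rounded `float()` and
floats are written with `repr`, so a write → load → write cycle is
byte-identical.

Numeric range filters are closed intervals `[lo, hi]`, matching the
semantics of brushing a histogram bar range; rows with a missing value
in a filtered column never match, because an unvalued row cannot
satisfy a range. Tags are per-row string sets, serialized as a
comma-joined `tags` column (commas are therefore forbidden inside a
tag), and `load_regions` recognises that column on the way back in.

## Signal quantification

A bigWig track is a step function. "Area" is defined as the per-base
sum of that step function over the region (units: signal·bp), not a
trapezoid over interpolated values — the step-function sum is exactly
additive across adjacent regions and can be checked against a per-base
brute force, which the test suite does on randomized regions. `mean`
is `area / length`, and `max` is the largest step value overlapping the
region (with 0 contributed by uncovered bases). Bases with no data
count as signal 0 by default, because absent ChIP coverage is
biologically zero signal; `missing_as_zero=False` marks fully
data-free regions as missing instead for callers who want to
distinguish "no data" from "no signal". No normalisation (per-million
scaling or otherwise) is applied: tracks are quantified as stored.

## Nearest TSS and intersection

The distance convention is pinned so an oracle can be written down:
for a TSS at base `t` and region `[s, e)` with slop `k`, distance is 0
when `s − k ≤ t < e + k`, otherwise `s − t` when `t < s` and
`t − (e − 1)` when `t ≥ e`. A TSS at the first base past the region has
distance 1. Ties break to the smaller TSS position, then the
lexicographically smaller accession. Region strand is ignored — peaks
are unstranded — and only the TSS strand determines where the TSS sits
on its transcript (`txStart` for `+`, `txEnd − 1` for `−`).

Intersection uses half-open overlap (touching intervals do not
overlap). When importing metadata from a multiply-overlapping record,
the default `max_overlap` rule takes the record with the largest bp
overlap (ties to the smaller start), which is deterministic and favours
the dominant overlapping feature.

## GO simplification

The hierarchical level of a term is the length of the **shortest**
`is_a` path to its namespace root (root = 0). Shortest-path is cheap
and deterministic; because GO depth is often defined by the longest
path instead, that variant is available behind `method="longest"`.
Only `is_a` edges are traversed (the go-basic release is acyclic over
them); `part_of` and other relations are ignored, and obsolete terms
are skipped at parse time.

Collapse counts term frequency across the whole gene corpus supplied
to `collapse_scheme` — not within a single gene, where every term's
frequency after closure would be 1 and nothing could collapse, and not
across all of NCBI, which would make the result depend on data the
caller never provided. Frequency ties break to the lexicographically
smallest GO id so the scheme is independent of gene input order. The
first reportable level is 1 (children of the root), and at most five
levels can be joined onto a region table.

`gene2go`/`gene2refseq` ingestion is a plain two-file join on GeneID
using the NCBI tab layouts (comment lines starting with `#`), filtered
to one namespace (default molecular function) via the Category column,
with RNA accession versions stripped.

## Embedding

Default scaling is per-column z-scoring; raw ChIP areas span orders of
magnitude and an unscaled neighbour graph would be dominated by one
column. `log1p_zscore` (log(1+x), then z-score) is the right choice
for heavy-tailed signal areas and is what the class-recovery tests
use. Constant columns map to all zeros rather than dividing by zero.
Rows with any missing value in the chosen columns are excluded from
the fit and get missing coordinates on attach; used + excluded always
equals the table size.

Both algorithms run with fixed seeds and are deterministic for fixed
input. t-SNE perplexity and UMAP `n_neighbors` are clamped to valid
ranges for small n with a logged warning, since fixtures are small by
design. Fewer than 10 rows is an error — a neighbour graph on fewer
points is noise. t-SNE switches to the exact method above 3 output
dimensions (a Barnes-Hut limitation).

## Recipes

Thresholds are explicit parameters with documented defaults: q
threshold 10, ratio thresholds +1/−1 log₂ units, pseudocount 1.0 for
every ratio/fold-change, fold-change windows `(−∞, 0)` / `[0, ∞)`.
The pseudocount prevents missing-value cascades on zero-signal
regions. Recipes tag rather than drop rows, so the same table can be
re-filtered under different thresholds without reloading. The
differential-binding fold changes go through the same derived-column
code path as interactive column arithmetic — there is one
implementation of `l2fc`, asserted by test.

## The synthetic generator

The generator's defaults are the study conditions of the test suite:
two 1 Mb chromosomes, 400 regions (130 promoter, 130 enhancer, 120
noise, 20 blacklist — planned weak fraction 0.30), four marks
(H3K4me1, H3K4me3, H3K27ac, CTCF), 10 bp bins, background level 0.5,
peak widths uniform in 300–800 bp, regions ≥ 1 kb apart.

Peak heights are log-normal per class and mark. Promoters are
H3K4me3-dominated with high H3K27ac/CTCF and sit on a planted TSS;
enhancers are H3K4me1-dominated, CTCF-poor, and at least 2 kb from
every TSS (50 decoy TSSs are scattered in the gaps); noise regions sit
barely above background in every mark; blacklist regions get extreme
log-normal spikes in *all* tracks at once, the shared-artefact
phenotype that blacklists exist to catch. The ln-space height means
were chosen so the log₂ me1:me3 area ratio separates promoters and
enhancers by ≈ ±3.5 with standard deviation ≈ 0.5 — a realistic-looking
but resolvable separation — and the noise class was placed low enough
that its significance proxy stays clearly below the q = 10 threshold.

The signal kernel is a symmetric plateau-with-ramps step function
(central half at full height, linear quarter-width ramps) quantised to
the bin grid, so the planned area and max in the truth table are exact
closed forms of the emitted bins (up to bigWig float32 rounding). The
significance proxy is `4·log₂(1 + max_height/background) + N(0, 1)`,
clipped at 0 — a monotone function of enrichment with class-dependent
spread, standing in for a peak caller's −log₁₀ q without simulating
reads.

What the fixtures do **not** emulate: read-level sampling noise,
mappability and GC structure, fragment-length smearing, overlapping or
nested peaks, chromosome-scale covariates, and realistic TSS density.
Passing the recovery tests therefore shows the pipeline's logic is
correct and self-consistent on cleanly separable data; it does not
show that any particular threshold is right for a real experiment —
that is exactly the judgement the interactive workflow leaves to the
analyst.

Everything is driven by one `numpy` Generator seeded from the config,
and every emitted byte (bigWig included) is reproducible for a fixed
seed; the test suite checks checksums of a full replay.

## Problem sizes

The default test and acceptance runs use the 400-region fixture, 1,000
random regions × 3 tracks for the signal oracle, 10 random fixtures up
to 1,000 × 1,000 for the interval oracle, 20 random toy DAGs for the
GO oracle, and 5 generator seeds for parameter recovery — sizes at
which every oracle is exhaustive and the whole suite runs in well
under a minute plus one-time UMAP JIT compilation.

## Known limitations

* No BAM/pileup input and no binned-matrix (heatmap-style) export;
  quantification is strictly per supplied region.
* `intersect` has no strand-aware mode and no split-feature handling.
* GO support is deliberately minimal: no enrichment statistics, no
  evidence-code filtering, no relations beyond `is_a`.
* The CLI persists state as TSV between invocations; very wide tables
  pay a serialization cost each step.
* Visual outputs (browser snapshots, interactive charts) are out of
  scope; the package guarantees the columns such views would be drawn
  from, not the views themselves.
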