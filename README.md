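# regionkit

Headless, scriptable analysis of genomic region tables for ChIP-seq /
ATAC-seq work: peak quality control, per-region bigWig signal
quantification, enhancer/promoter classification, nearest-TSS and GO
annotation, interval intersection, and UMAP/t-SNE embedding — the
operations an interactive peak-exploration session is made of, exposed as
a Python library and a CLI so they can run in pipelines and be tested
against oracles.

## Who this is for

Anyone holding a table of genomic intervals (a BED file, MACS2
narrowPeak output, or any TSV/CSV whose first three columns are
`chrom start end`) plus coverage tracks in bigWig, who wants to:

* triage true/false-positive peaks by the −log₁₀ *q*-value distribution,
* classify open-chromatin elements by histone-mark ratios
  (log₂ H3K4me1:H3K4me3 — high for enhancers, low for promoters),
* compare conditions via per-region log₂ fold changes and flag
  blacklist artefacts,
* cluster regions by their signal profiles in a low-dimensional
  embedding,

without dropping rows: regions are *tagged* (`weak_peak`, `enhancer`,
…), filtered by predicates, and cloned into subsets, so every decision
stays reversible and exportable.

## The model in brief

* **Regions** are 0-based half-open intervals with typed metadata
  columns, per-row tag sets, and stable integer row ids.
* **Signal** is a genome-wide step function. For a region *R* = [s, e)
  and track *v*(x), the package reports
  `area = Σ_{x∈R} v(x)` (signal·bp), `max = max_{x∈R} v(x)`, and
  `mean = area / (e − s)`; uncovered bases count as 0. Area is additive
  across adjacent regions and checkable base by base.
* **Derived columns** come from a tiny arithmetic grammar over numeric
  columns, including `ratio(a,b,p) = (a+p)/(b+p)` and
  `l2fc(a,b,p) = log₂((a+p)/(b+p))` with pseudocount *p*.
* **Nearest TSS**: for a TSS at base *t* and region [s, e), distance is
  0 when `s ≤ t < e`, else `s − t` or `t − (e−1)`; ties go to the
  smaller position, then the lexicographically smaller accession.
* **GO simplification**: each gene's direct GO terms are expanded
  through the `is_a` hierarchy; at each hierarchical level (shortest
  path to the namespace root) candidates collapse to the corpus-most-
  frequent term, leaving one term per gene per level (up to 5 levels).
* **Embedding**: any numeric columns → (optionally z-scored) matrix →
  UMAP or t-SNE coordinates attached as `UMAP1..k` / `tSNE1..k`
  columns, deterministic under a fixed seed.

A seeded synthetic-data generator (`regionkit.simulate`) produces a
complete labelled genome — promoter/enhancer/noise/blacklist regions,
four bigWig tracks, TSSs, a toy GO corpus — with closed-form ground
truth, so every stage is tested against planted answers.

## Worked example

```python
import regionkit as rk
from regionkit import recipes

ds = rk.simulate_dataset(rk.FixtureConfig(seed=7), "fixture")
table = rk.load_regions(ds.regions_tsv)

for mark, path in ds.bigwig_paths.items():
    with rk.BigWigSignal(str(path)) as track:
        rk.quantify(track, table, prefix=mark)

tss = rk.load_tss(ds.tss_bed)
rk.annotate_nearest_tss(table, tss)

table, qc = recipes.peak_qc(table, threshold=10)
print(f"weak peaks: {qc.n_below}/{qc.n_total}  (fraction {qc.frac_below:.2f})")

table, cs = recipes.classify_elements(
    table, "H3K4me1_area", "H3K4me3_area",
    k27_col="H3K27ac_area", ctcf_col="CTCF_area")
for name, info in cs.classes.items():
    print(f"{name:>12}: n={info['count']:<4} TSS overlap={info['tss_overlap_fraction']:.2f} "
          f"mean CTCF area={info['mean_CTCF']:.0f}")
```

prints

```
weak peaks: 120/400  (fraction 0.30)
    enhancer: n=131  TSS overlap=0.00 mean CTCF area=1470
    promoter: n=134  TSS overlap=0.97 mean CTCF area=9595
unclassified: n=135  TSS overlap=0.00 mean CTCF area=8430
```

The generator planted 120 noise regions among 400, and the *q*-value
threshold of 10 recovers exactly that weak fraction (0.30). Regions
tagged `promoter` (low me1:me3 ratio) overlap planted TSSs almost
always and carry ~6× the CTCF signal of `enhancer`-tagged regions —
the expected phenotypes of the two element classes. The
`unclassified` tier is dominated by the noise and artefact regions
whose mark ratio is near zero.

The same pipeline from a shell:

```bash
regionkit simulate --out fixture --seed 7
regionkit signal --table fixture/regions.tsv --bigwig fixture/H3K4me1.bw \
         --prefix H3K4me1 --out step1.tsv
regionkit signal --table step1.tsv --bigwig fixture/H3K4me3.bw \
         --prefix H3K4me3 --out step2.tsv
regionkit annotate-tss --table step2.tsv --tss fixture/tss.bed --out step3.tsv
regionkit recipe classify --table step3.tsv \
         --me1 H3K4me1_area --me3 H3K4me3_area --out final.tsv
```

Every mutating subcommand writes a `<output>.manifest.json` with the
resolved parameters and input checksums, so a run can be replayed and
verified byte for byte.

## Layout

| module | purpose |
|---|---|
| `regionkit.regions` | region table, I/O, derived columns, filters, tags, clones, projects |
| `regionkit.expr` | safe arithmetic expression engine for derived columns |
| `regionkit.signal` | bigWig / in-memory step-function quantification |
| `regionkit.annotate` | nearest-TSS annotation, interval intersection |
| `regionkit.go` | OBO parsing, ancestor expansion, per-level collapse |
| `regionkit.embed` | feature matrices, UMAP/t-SNE, coordinate columns |
| `regionkit.recipes` | peak-QC, enhancer/promoter, differential-binding pipelines |
| `regionkit.simulate` | seeded synthetic genome + toy GO corpus with ground truth |
| `regionkit.cli` | `regionkit` command with per-operation subcommands |

See `docs/methods.md` for the underlying conventions, parameter
defaults, and known limitations.
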