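"""Seeded synthetic datasets with machine-readable ground truth.

The generator produces a complete, self-contained test genome: a small
chromosome set, four classes of labelled regions, one coverage track per
histone mark / factor, a TSS annotation, a blacklist, and a toy GO corpus.
It exists so that every analysis stage can be checked against planted
truth — the class of every region, the closed-form area/max of every
planted signal kernel, the identity of the nearest planted TSS.

Region classes and their signal profiles:

* ``promoter``  — placed at a planted TSS; high H3K4me3, low H3K4me1,
  high H3K27ac and CTCF.
* ``enhancer``  — distal to every TSS; high H3K4me1, low H3K4me3,
  moderate H3K27ac, low CTCF.
* ``noise``     — barely-above-background signal in every mark and a low
  significance proxy (the weak-peak class a q-value threshold removes).
* ``blacklist`` — extreme, shared signal spikes in every track, mimicking
  recurrent sequencing artefacts; also emitted as a blacklist BED.

Signal kernel: a symmetric step-function peak — a central plateau at the
drawn height with linear ramps on either side — added to a uniform
background and quantised to fixed-width bins.  Heights are log-normal per
class and mark.  Because the kernel is built directly from the emitted
bins, its planned area/max are exact (up to bigWig float32 rounding).

The significance proxy ``neg_log10_q`` is a monotone function of the
region's maximum planted height over background plus Gaussian noise, so a
q threshold of 10 separates the noise class from real classes with a wide
margin and the planned weak fraction equals ``n_noise / n_total``.

All outputs are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import StepSignal

__all__ = [
    "FixtureConfig",
    "FixtureDataset",
    "GoFixture",
    "simulate_dataset",
    "simulate_go_fixture",
    "CLASS_HEIGHTS",
]

MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "CTCF")

# ln-space (mu, sigma) of the plateau height above background, per class/mark
CLASS_HEIGHTS: dict[str, dict[str, tuple[float, float]]] = {
    "promoter": {
        "H3K4me1": (math.log(2.0), 0.35),
        "H3K4me3": (math.log(32.0), 0.35),
        "H3K27ac": (math.log(20.0), 0.5),
        "CTCF": (math.log(15.0), 0.5),
    },
    "enhancer": {
        "H3K4me1": (math.log(32.0), 0.35),
        "H3K4me3": (math.log(2.0), 0.35),
        "H3K27ac": (math.log(10.0), 0.6),
        "CTCF": (math.log(1.5), 0.6),
    },
    "noise": {m: (math.log(0.4), 0.3) for m in MARKS},
    "blacklist": {m: (math.log(150.0), 0.3) for m in MARKS},
}

Q_SCALE = 4.0  # q proxy = Q_SCALE * log2(1 + max_height/background) + N(0,1)


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic dataset."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    n_promoter: int = 130
    n_enhancer: int = 130
    n_noise: int = 120
    n_blacklist: int = 20
    bin_size: int = 10
    background: float = 0.5
    peak_width_range: tuple[int, int] = (300, 800)
    min_gap: int = 1000        # bp between placed regions
    n_decoy_tss: int = 50      # TSSs not attached to any generated region
    decoy_clearance: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_promoter, self.n_enhancer, self.n_noise, self.n_blacklist):
            if n < 0:
                raise ValueError("class counts must be >= 0")
        for size in self.chrom_sizes.values():
            if size % self.bin_size:
                raise ValueError("bin size must divide every chromosome size")

    @property
    def n_total(self) -> int:
        return self.n_promoter + self.n_enhancer + self.n_noise + self.n_blacklist

    @property
    def planned_weak_fraction(self) -> float:
        return self.n_noise / self.n_total if self.n_total else 0.0


@dataclass
class FixtureDataset:
    """Paths plus in-memory objects for one simulated dataset."""

    config: FixtureConfig
    out_dir: Path
    chrom_sizes_path: Path
    regions_tsv: Path
    regions_bed: Path
    bigwig_paths: dict[str, Path]
    tss_bed: Path
    tss_refseq_tsv: Path
    blacklist_bed: Path
    truth_tsv: Path
    tracks: dict[str, StepSignal]
    truth: pd.DataFrame


def _place_regions(cfg: FixtureConfig, rng: np.random.Generator) -> list[tuple[str, int, int, str]]:
    """Non-overlapping (chrom, start, end, class) placements on the bin grid."""
    labels = (
        ["promoter"] * cfg.n_promoter
        + ["enhancer"] * cfg.n_enhancer
        + ["noise"] * cfg.n_noise
        + ["blacklist"] * cfg.n_blacklist
    )
    order = rng.permutation(len(labels))
    chroms = sorted(cfg.chrom_sizes)
    weights = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[tuple[str, int, int, str]] = []
    max_tries = 200 * max(1, len(labels))
    tries = 0
    for idx in order:
        label = labels[idx]
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "could not place all regions without overlap; use a larger genome"
                )
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            lo_w, hi_w = cfg.peak_width_range
            width = int(rng.integers(lo_w // cfg.bin_size, hi_w // cfg.bin_size + 1)) * cfg.bin_size
            size = cfg.chrom_sizes[chrom]
            start = int(rng.integers(0, (size - width) // cfg.bin_size)) * cfg.bin_size
            end = start + width
            ok = all(
                end + cfg.min_gap <= s or start >= e + cfg.min_gap
                for s, e in placed[chrom]
            )
            if ok:
                placed[chrom].append((start, end))
                out.append((chrom, start, end, label))
                break
    out.sort(key=lambda r: (r[0], r[1]))
    return out


def _kernel_bins(width: int, bin_size: int, height: float) -> np.ndarray:
    """Plateau-with-ramps peak, evaluated per bin (bin-centre heights)."""
    nbins = width // bin_size
    x = (np.arange(nbins) + 0.5) / nbins  # bin centres in [0, 1]
    ramp = 0.25
    y = np.ones(nbins)
    left = x < ramp
    right = x > 1 - ramp
    y[left] = x[left] / ramp
    y[right] = (1 - x[right]) / ramp
    return height * y


def _rle(values: np.ndarray, bin_size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode per-bin values into step intervals."""
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change]) * bin_size
    ends = np.concatenate([change, [len(values)]]) * bin_size
    vals = values[np.concatenate([[0], change])]
    return starts.astype(np.int64), ends.astype(np.int64), vals


def _write_bigwig(path: Path, chrom_values: dict[str, np.ndarray], bin_size: int,
                  chrom_sizes: dict[str, int]) -> None:
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    header = [(c, chrom_sizes[c]) for c in sorted(chrom_sizes)]
    bw.addHeader(header)
    for chrom, _ in header:
        starts, ends, vals = _rle(chrom_values[chrom], bin_size)
        bw.addEntries(
            [chrom] * len(starts),
            [int(s) for s in starts],
            ends=[int(e) for e in ends],
            values=[float(v) for v in np.asarray(vals, dtype=np.float32)],
        )
    bw.close()


def _brute_force_nearest_tss(
    chrom: str, start: int, end: int, tss: list[tuple[str, int, str]]
) -> tuple[int | None, str | None]:
    """All-pairs nearest TSS under the pinned distance convention."""
    best: tuple[int, int, str] | None = None  # (distance, pos, refseq)
    for t_chrom, pos, refseq in tss:
        if t_chrom != chrom:
            continue
        if start <= pos < end:
            d = 0
        elif pos < start:
            d = start - pos
        else:
            d = pos - (end - 1)
        key = (d, pos, refseq)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[0], best[2]


def simulate_dataset(config: FixtureConfig | None = None, out_dir: str | Path = ".") -> FixtureDataset:
    """Emit a full synthetic dataset plus ground truth to ``out_dir``.

    Files written: ``chrom.sizes``, ``regions.tsv`` (with the q proxy),
    ``regions.bed``, one ``<mark>.bw`` per mark, ``tss.bed`` +
    ``tss_refseq.tsv``, ``blacklist.bed``, ``truth.tsv``.  The returned
    object also carries the in-memory step-function tracks and the truth
    table.
    """
    cfg = config or FixtureConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    regions = _place_regions(cfg, rng)
    nbins = {c: size // cfg.bin_size for c, size in cfg.chrom_sizes.items()}
    values = {
        mark: {c: np.full(nbins[c], cfg.background) for c in cfg.chrom_sizes}
        for mark in MARKS
    }

    truth_rows = []
    heights: list[dict[str, float]] = []
    for i, (chrom, start, end, label) in enumerate(regions, start=1):
        row_heights = {}
        for mark in MARKS:
            mu, sigma = CLASS_HEIGHTS[label][mark]
            h = float(rng.lognormal(mu, sigma))
            row_heights[mark] = h
            kernel = _kernel_bins(end - start, cfg.bin_size, h)
            b0 = start // cfg.bin_size
            values[mark][chrom][b0 : b0 + len(kernel)] += kernel
        heights.append(row_heights)

    # significance proxy from the strongest planted mark
    q_vals = []
    for i, (chrom, start, end, label) in enumerate(regions):
        peak_max = max(heights[i].values())
        q = Q_SCALE * math.log2(1 + peak_max / cfg.background) + float(rng.normal(0, 1))
        q_vals.append(max(0.0, q))

    # TSSs: one per promoter (inside the region), plus distal decoys
    tss: list[tuple[str, int, str, str, str]] = []  # chrom, pos, strand, refseq, gene
    tss_counter = 0
    promoter_tss: dict[int, tuple[int, str]] = {}
    for i, (chrom, start, end, label) in enumerate(regions, start=1):
        if label != "promoter":
            continue
        tss_counter += 1
        centre_bin = (start + end) // 2 // cfg.bin_size
        jitter = int(rng.integers(-5, 6))
        pos = int(
            np.clip(
                (centre_bin + jitter) * cfg.bin_size,
                start,
                end - 1,
            )
        )
        strand = "+" if rng.random() < 0.5 else "-"
        refseq = f"NM_{tss_counter:06d}"
        tss.append((chrom, pos, strand, refseq, f"GENE{tss_counter}"))
        promoter_tss[i] = (pos, refseq)

    chroms = sorted(cfg.chrom_sizes)
    weights = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    region_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, start, end, _ in regions:
        region_by_chrom[chrom].append((start, end))
    decoys = 0
    guard = 0
    while decoys < cfg.n_decoy_tss:
        guard += 1
        if guard > 200 * max(1, cfg.n_decoy_tss):
            break  # genome too crowded for more decoys; keep what we have
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = int(rng.integers(0, cfg.chrom_sizes[chrom]))
        clear = all(
            pos < s - cfg.decoy_clearance or pos >= e + cfg.decoy_clearance
            for s, e in region_by_chrom[chrom]
        )
        if clear:
            tss_counter += 1
            decoys += 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss.append((chrom, pos, strand, f"NM_{tss_counter:06d}", f"GENE{tss_counter}"))
    tss.sort(key=lambda t: (t[0], t[1], t[3]))

    tss_points = [(c, p, r) for c, p, _, r, _ in tss]
    for i, (chrom, start, end, label) in enumerate(regions, start=1):
        d, refseq = _brute_force_nearest_tss(chrom, start, end, tss_points)
        row = {
            "region_id": i,
            "chrom": chrom,
            "start": start,
            "end": end,
            "class": label,
            "neg_log10_q": q_vals[i - 1],
            "nearest_tss_refseq": refseq,
            "nearest_tss_distance": d,
            "blacklisted": label == "blacklist",
        }
        for mark in MARKS:
            h = heights[i - 1][mark]
            kernel = _kernel_bins(end - start, cfg.bin_size, h)
            row[f"{mark}_planned_area"] = float(
                np.sum((kernel + cfg.background).astype(np.float32)) * cfg.bin_size
            )
            row[f"{mark}_planned_max"] = float(
                np.float32(kernel.max() + cfg.background)
            )
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows).set_index("region_id")

    # ---- write files -----------------------------------------------------
    chrom_sizes_path = out_dir / "chrom.sizes"
    with open(chrom_sizes_path, "w") as fh:
        for c in chroms:
            fh.write(f"{c}\t{cfg.chrom_sizes[c]}\n")

    regions_tsv = out_dir / "regions.tsv"
    with open(regions_tsv, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tname\tneg_log10_q\n")
        for i, (chrom, start, end, label) in enumerate(regions, start=1):
            fh.write(f"{chrom}\t{start}\t{end}\t.\tregion_{i}\t{q_vals[i - 1]:.6f}\n")

    regions_bed = out_dir / "regions.bed"
    with open(regions_bed, "w") as fh:
        for i, (chrom, start, end, label) in enumerate(regions, start=1):
            fh.write(f"{chrom}\t{start}\t{end}\tregion_{i}\t0\t.\n")

    blacklist_bed = out_dir / "blacklist.bed"
    with open(blacklist_bed, "w") as fh:
        for chrom, start, end, label in regions:
            if label == "blacklist":
                fh.write(f"{chrom}\t{start}\t{end}\n")

    tss_bed = out_dir / "tss.bed"
    with open(tss_bed, "w") as fh:
        for chrom, pos, strand, refseq, gene in tss:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{refseq}\t0\t{strand}\n")

    tss_refseq_tsv = out_dir / "tss_refseq.tsv"
    with open(tss_refseq_tsv, "w") as fh:
        fh.write("chrom\ttxStart\ttxEnd\tstrand\tname\tname2\n")
        for chrom, pos, strand, refseq, gene in tss:
            if strand == "+":
                tx_start, tx_end = pos, min(pos + 1000, cfg.chrom_sizes[chrom])
            else:
                tx_start, tx_end = max(0, pos - 999), pos + 1
            fh.write(f"{chrom}\t{tx_start}\t{tx_end}\t{strand}\t{refseq}\t{gene}\n")

    truth_tsv = out_dir / "truth.tsv"
    truth.to_csv(truth_tsv, sep="\t")

    tracks: dict[str, StepSignal] = {}
    bigwig_paths: dict[str, Path] = {}
    for mark in MARKS:
        step_intervals = {}
        for c in chroms:
            binned = values[mark][c].astype(np.float32).astype(float)
            starts, ends, vals = _rle(binned, cfg.bin_size)
            step_intervals[c] = list(zip(starts.tolist(), ends.tolist(), vals.tolist()))
        tracks[mark] = StepSignal(step_intervals, chrom_sizes=dict(cfg.chrom_sizes))
        path = out_dir / f"{mark}.bw"
        _write_bigwig(path, {c: values[mark][c] for c in chroms}, cfg.bin_size, cfg.chrom_sizes)
        bigwig_paths[mark] = path

    return FixtureDataset(
        config=cfg,
        out_dir=out_dir,
        chrom_sizes_path=chrom_sizes_path,
        regions_tsv=regions_tsv,
        regions_bed=regions_bed,
        bigwig_paths=bigwig_paths,
        tss_bed=tss_bed,
        tss_refseq_tsv=tss_refseq_tsv,
        blacklist_bed=blacklist_bed,
        truth_tsv=truth_tsv,
        tracks=tracks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Toy GO corpus


@dataclass
class GoFixture:
    obo_path: Path
    gene2go_path: Path
    gene2refseq_path: Path
    expected_scheme: dict[str, dict[int, str]]  # refseq -> level -> term id
    direct: dict[str, set[str]]                 # refseq -> direct term ids
    terms: dict[str, list[str]]                 # term id -> parent ids
    levels: dict[str, int]
    namespace: str = "molecular_function"


def _oracle_levels(parents: dict[str, list[str]], root: str) -> dict[str, int]:
    """Shortest path to root, by naive memoised recursion."""
    memo: dict[str, int] = {root: 0}

    def level(t: str) -> int:
        if t not in memo:
            memo[t] = 1 + min(level(p) for p in parents[t])
        return memo[t]

    for t in parents:
        level(t)
    return memo


def _oracle_closure(term: str, parents: dict[str, list[str]]) -> set[str]:
    out = {term}
    for p in parents.get(term, []):
        out |= _oracle_closure(p, parents)
    return out


def _oracle_collapse(
    direct: dict[str, set[str]], parents: dict[str, list[str]], root: str, max_level: int
) -> dict[str, dict[int, str]]:
    """Brute-force expand + per-level most-frequent collapse (tie: min id)."""
    levels = _oracle_levels(parents, root)
    expanded = {
        g: set().union(*(_oracle_closure(t, parents) for t in ts)) if ts else set()
        for g, ts in direct.items()
    }
    freq: dict[str, int] = {}
    for ts in expanded.values():
        for t in ts:
            freq[t] = freq.get(t, 0) + 1
    scheme: dict[str, dict[int, str]] = {}
    for g, ts in expanded.items():
        per_level: dict[int, str] = {}
        for lvl in range(1, max_level + 1):
            cands = sorted(t for t in ts if levels[t] == lvl)
            if cands:
                best = max(cands, key=lambda t: freq[t])  # ties: first of sorted = min id
                best = min([t for t in cands if freq[t] == freq[best]])
                per_level[lvl] = best
        scheme[g] = per_level
    return scheme


def simulate_go_fixture(
    n_genes: int = 10,
    depth: int = 4,
    n_terms: int = 20,
    seed: int = 0,
    out_dir: str | Path = ".",
    max_level: int = 5,
) -> GoFixture:
    """Emit a toy OBO + gene2go + gene2refseq trio with a known collapse.

    A random DAG with one molecular_function root is grown term by term
    (each new term gets 1–2 parents among earlier terms, keeping depth
    bounded); each gene is directly annotated to 1–3 random non-root
    terms.  The expected simplified scheme is computed by an independent
    brute-force enumeration, not by the production collapse code.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root = "GO:0000001"
    parents: dict[str, list[str]] = {}
    terms = [root]
    for i in range(2, n_terms + 1):
        tid = f"GO:{i:07d}"
        n_parents = 1 + int(rng.random() < 0.4)
        ps = sorted(
            {terms[int(j)] for j in rng.choice(len(terms), size=n_parents, replace=True)}
        )
        parents[tid] = ps
        terms.append(tid)
    levels = _oracle_levels(parents, root)
    # enforce the requested depth bound by re-parenting overly deep terms
    for tid in terms[1:]:
        if levels[tid] > depth:
            shallow = [t for t in terms if t != tid and levels[t] < depth]
            parents[tid] = [min(shallow, key=lambda t: (levels[t], t))]
    levels = _oracle_levels(parents, root)

    non_root = terms[1:]
    direct: dict[str, set[str]] = {}
    gene_ids: dict[str, int] = {}
    for g in range(1, n_genes + 1):
        acc = f"NM_{g:06d}"
        gene_ids[acc] = 1000 + g
        k = int(rng.integers(1, 4))
        direct[acc] = {non_root[int(j)] for j in rng.choice(len(non_root), size=k, replace=True)}

    expected = _oracle_collapse(direct, parents, root, max_level)

    obo_path = out_dir / "toy.obo"
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n\n")
        for tid in terms:
            fh.write("[Term]\n")
            fh.write(f"id: {tid}\n")
            fh.write(f"name: term {tid[3:].lstrip('0') or '1'}\n")
            fh.write("namespace: molecular_function\n")
            for p in parents.get(tid, []):
                fh.write(f"is_a: {p} ! parent\n")
            fh.write("\n")
        # one obsolete stray term: parsers must skip it
        fh.write("[Term]\nid: GO:9999999\nname: obsolete stray\n")
        fh.write("namespace: molecular_function\nis_obsolete: true\n\n")

    gene2go_path = out_dir / "gene2go.tsv"
    with open(gene2go_path, "w") as fh:
        fh.write("#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory\n")
        for acc in sorted(direct):
            for t in sorted(direct[acc]):
                fh.write(f"9606\t{gene_ids[acc]}\t{t}\tIEA\t-\tterm\t-\tFunction\n")

    gene2refseq_path = out_dir / "gene2refseq.tsv"
    with open(gene2refseq_path, "w") as fh:
        fh.write(
            "#tax_id\tGeneID\tstatus\tRNA_nucleotide_accession.version\t"
            "RNA_nucleotide_gi\tprotein_accession.version\tprotein_gi\t"
            "genomic_nucleotide_accession.version\tgenomic_nucleotide_gi\t"
            "start_position_on_the_genomic_accession\t"
            "end_position_on_the_genomic_accession\torientation\tassembly\t"
            "mature_peptide_accession.version\tmature_peptide_gi\tSymbol\n"
        )
        for acc in sorted(direct):
            fields = ["9606", str(gene_ids[acc]), "VALIDATED", f"{acc}.1"] + ["-"] * 11 + [
                f"SYM{gene_ids[acc]}"
            ]
            fh.write("\t".join(fields) + "\n")

    return GoFixture(
        obo_path=obo_path,
        gene2go_path=gene2go_path,
        gene2refseq_path=gene2refseq_path,
        expected_scheme=expected,
        direct=direct,
        terms={t: parents.get(t, []) for t in terms},
        levels=levels,
    )
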