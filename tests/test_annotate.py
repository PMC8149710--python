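"""Nearest-TSS annotation and interval intersection against brute force."""

import numpy as np
import pandas as pd
import pytest

from regionkit import RegionTable, TssRecord, annotate_nearest_tss, intersect, load_tss


def make_table(rows):
    df = pd.DataFrame(
        [{"chrom": c, "start": s, "end": e} for c, s, e in rows],
        index=pd.RangeIndex(1, len(rows) + 1),
    )
    return RegionTable(df)


def brute_nearest(chrom, start, end, tss, slop=0):
    """All-pairs oracle under the pinned distance convention."""
    best = None
    for r in tss:
        if r.chrom != chrom:
            continue
        if start - slop <= r.pos < end + slop:
            d = 0
        elif r.pos < start:
            d = start - r.pos
        else:
            d = r.pos - (end - 1)
        key = (d, r.pos, r.refseq_id)
        if best is None or key < best:
            best = key
    return best  # (distance, pos, refseq) or None


# ------------------------------------------------------------------- load_tss


def test_load_tss_strand_rule(tmp_path):
    p = tmp_path / "tss.bed"
    p.write_text("chr1\t100\t200\tNM_1\t0\t+\nchr1\t100\t200\tNM_2\t0\t-\n")
    recs = load_tss(p, format="bed6")
    assert recs[0].pos == 100 and recs[0].refseq_id == "NM_1"
    assert recs[1].pos == 199 and recs[1].refseq_id == "NM_2"


def test_load_tss_requires_strand(tmp_path):
    p = tmp_path / "tss.bed"
    p.write_text("chr1\t100\t200\tNM_1\n")
    with pytest.raises(ValueError):
        load_tss(p, format="bed6")


def test_load_tss_refseq_tsv_sorted(tmp_path):
    p = tmp_path / "tss.tsv"
    p.write_text(
        "chrom\ttxStart\ttxEnd\tstrand\tname\tname2\n"
        "chr2\t500\t900\t-\tNM_9\tGENEB\n"
        "chr1\t300\t700\t+\tNM_5\tGENEA\n"
    )
    recs = load_tss(p, format="refseq_tsv")
    assert [(r.chrom, r.pos, r.gene_name) for r in recs] == [
        ("chr1", 300, "GENEA"), ("chr2", 899, "GENEB")
    ]


# ---------------------------------------------------------------- nearest TSS


def test_overlapping_tss_distance_zero():
    t = make_table([("chr1", 90, 110)])
    annotate_nearest_tss(t, [TssRecord("chr1", 100, "+", "NM_1", "G1")])
    assert t.df["tss_distance"].iloc[0] == 0
    assert bool(t.df["tss_overlap"].iloc[0]) is True


def test_gap_distance_convention():
    # TSS one base past the half-open end has distance 1
    t = make_table([("chr1", 0, 10), ("chr1", 0, 10)])
    annotate_nearest_tss(t, [TssRecord("chr1", 25, "+", "NM_1", "G1")])
    assert t.df["tss_distance"].iloc[0] == 25 - (10 - 1)
    t2 = make_table([("chr1", 0, 10)])
    annotate_nearest_tss(t2, [TssRecord("chr1", 10, "+", "NM_1", "G1")])
    assert t2.df["tss_distance"].iloc[0] == 1


def test_tie_breaks_smaller_pos_then_refseq():
    t = make_table([("chr1", 100, 111)])  # TSS at 90 and 120 both distance 10
    tss = [TssRecord("chr1", 120, "+", "NM_A", "G"), TssRecord("chr1", 90, "+", "NM_B", "G")]
    annotate_nearest_tss(t, tss)
    assert t.df["tss_refseq_id"].iloc[0] == "NM_B"
    t2 = make_table([("chr1", 50, 60)])  # equal positions: lexicographic id
    tss2 = [TssRecord("chr1", 55, "+", "NM_Z", "G"), TssRecord("chr1", 55, "+", "NM_A", "G")]
    annotate_nearest_tss(t2, tss2)
    assert t2.df["tss_refseq_id"].iloc[0] == "NM_A"


def test_chromosome_without_tss_gets_missing():
    t = make_table([("chr1", 0, 10), ("chrM", 0, 10)])
    annotate_nearest_tss(t, [TssRecord("chr1", 5, "+", "NM_1", "G1")])
    assert t.df["tss_distance"].iloc[1] is pd.NA
    assert t.df["tss_refseq_id"].iloc[1] is None


def test_no_tss_on_any_table_chromosome_errors():
    t = make_table([("chr9", 0, 10)])
    with pytest.raises(ValueError):
        annotate_nearest_tss(t, [TssRecord("chr1", 5, "+", "NM_1", "G1")])


def test_nearest_tss_matches_all_pairs_oracle():
    rng = np.random.default_rng(123)
    for trial in range(4):
        n, m = 300, 150
        rows, tss = [], []
        for i in range(n):
            chrom = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(0, 100_000))
            rows.append((chrom, s, s + int(rng.integers(1, 2000))))
        for j in range(m):
            tss.append(
                TssRecord(f"chr{rng.integers(1, 4)}", int(rng.integers(0, 100_000)),
                          "+" if rng.random() < 0.5 else "-", f"NM_{j:04d}", f"G{j}")
            )
        slop = int(rng.choice([0, 0, 100]))
        t = make_table(rows)
        annotate_nearest_tss(t, tss, slop=slop)
        for i, (chrom, s, e) in enumerate(rows):
            want = brute_nearest(chrom, s, e, tss, slop=slop)
            if want is None:
                assert t.df["tss_distance"].iloc[i] is pd.NA
            else:
                assert t.df["tss_distance"].iloc[i] == want[0]
                assert t.df["tss_refseq_id"].iloc[i] == want[2]


def test_slop_monotonicity():
    rng = np.random.default_rng(5)
    rows = [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 50_000, 100)]
    tss = [TssRecord("chr1", int(p), "+", f"NM_{i:03d}", "G")
           for i, p in enumerate(rng.integers(0, 50_000, 40))]
    d = {}
    ov = {}
    for slop in (0, 50, 500):
        t = make_table(rows)
        annotate_nearest_tss(t, tss, slop=slop)
        d[slop] = t.df["tss_distance"].to_numpy(dtype=float)
        ov[slop] = t.df["tss_overlap"].to_numpy(dtype=bool)
    assert np.all(d[50] <= d[0]) and np.all(d[500] <= d[50])
    assert not np.any(ov[0] & ~ov[50]) and not np.any(ov[50] & ~ov[500])


# ------------------------------------------------------------------ intersect


def test_flag_half_open_touching_is_not_overlap():
    t = make_table([("chr1", 0, 10), ("chr1", 10, 20)])
    intersect(t, [("chr1", 5, 15)], mode="flag", column="f")
    assert list(t.df["f"]) == [True, True]
    t2 = make_table([("chr1", 0, 10)])
    intersect(t2, [("chr1", 10, 20)], mode="flag", column="f")
    assert list(t2.df["f"]) == [False]


def test_count_mode():
    t = make_table([("chr1", 0, 100)])
    intersect(t, [("chr1", 0, 10), ("chr1", 20, 30), ("chr1", 200, 300)],
              mode="count", column="n")
    assert t.df["n"].iloc[0] == 2


def test_import_mode_max_overlap_rule():
    t = make_table([("chr1", 0, 100)])
    other = [
        ("chr1", 0, 30, {"lab": "small"}),
        ("chr1", 40, 100, {"lab": "big"}),
    ]
    intersect(t, other, mode="import", column="imp", import_columns=["lab"])
    assert t.df["imp_lab"].iloc[0] == "big"
    t2 = make_table([("chr1", 0, 100)])
    intersect(t2, other, mode="import", column="imp", import_columns=["lab"],
              multi_rule="first")
    assert t2.df["imp_lab"].iloc[0] == "small"


def test_import_requires_columns_and_flags_reject_them():
    t = make_table([("chr1", 0, 10)])
    with pytest.raises(ValueError):
        intersect(t, [("chr1", 0, 5)], mode="import")
    with pytest.raises(ValueError):
        intersect(t, [("chr1", 0, 5)], mode="flag", import_columns=["x"])
    with pytest.raises(KeyError):
        intersect(t, [("chr1", 0, 5)], mode="import", import_columns=["absent"])


def test_flag_matches_brute_force_on_fixture(fixture_ds):
    from regionkit import load_regions

    table = load_regions(fixture_ds.regions_tsv)
    blacklist = load_regions(fixture_ds.blacklist_bed, dialect="bed")
    intersect(table, blacklist, mode="flag", column="bl")
    bl_rows = [(r["chrom"], r["start"], r["end"]) for _, r in blacklist.df.iterrows()]
    for rid in table.row_ids:
        row = table.df.loc[rid]
        brute = any(
            c == row["chrom"] and max(row["start"], s) < min(row["end"], e)
            for c, s, e in bl_rows
        )
        assert bool(table.df["bl"].loc[rid]) == brute
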