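"""Region table core: I/O, column arithmetic, filters, tags, clones, projects."""

import json

import numpy as np
import pandas as pd
import pytest

from regionkit import (
    FilterPredicate,
    GenomicInterval,
    RegionTable,
    apply_filter,
    clone_subset,
    delete_column,
    derive_column,
    load_project,
    load_regions,
    save_project,
    summarize_column,
    tag_rows,
    write_bed,
    write_table,
)
from regionkit.expr import ExpressionError, evaluate
from regionkit.regions import ProjectSchemaError, Selection


# ---------------------------------------------------------------------- types


def test_interval_invariants():
    iv = GenomicInterval("chr1", 100, 200)
    assert len(iv) == 100 and iv.strand == "."
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 200, 100)
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -5, 10)


# -------------------------------------------------------------------- loading


def test_load_bed3(tmp_path):
    p = tmp_path / "r.bed"
    p.write_text("chr1\t100\t200\n")
    t = load_regions(p, dialect="bed")
    assert t.interval(1) == GenomicInterval("chr1", 100, 200)
    assert t.metadata_columns == []


def test_load_tsv_one_based(tmp_path):
    p = tmp_path / "r.tsv"
    p.write_text("chrom\tstart\tend\tscore\nchr1\t101\t200\t5.0\n")
    t = load_regions(p, dialect="tsv", one_based=True)
    assert t.interval(1) == GenomicInterval("chr1", 100, 200)
    assert t.numeric("score")[0] == 5.0


def test_load_rejects_malformed_rows(tmp_path):
    lines = [
        "chrom\tstart\tend\tv",
        "chr1\t0\t10\t1",
        "chr1\t50\t50\t2",      # empty interval
        "chr1\t10\t20\t3",
        "chr1\tx\t30\t4",       # non-integer start
        "chr2\t5\t25\t5",
        "\t5\t25\t6",           # empty chrom
    ]
    p = tmp_path / "r.tsv"
    p.write_text("\n".join(lines) + "\n")
    t = load_regions(p, dialect="tsv")
    assert len(t) == 3
    assert t.meta["rejected_rows"] == 3
    assert t.row_ids == [1, 2, 3]


def test_load_narrowpeak_exposes_q_column(tmp_path):
    p = tmp_path / "peaks.narrowPeak"
    p.write_text(
        "chr1\t0\t100\tpeak1\t0\t.\t4.5\t9.1\t7.3\t50\n"
        "chr1\t200\t350\tpeak2\t0\t.\t8.0\t20.0\t15.5\t80\n"
    )
    t = load_regions(p, dialect="narrowPeak")
    assert list(t.numeric("neg_log10_q")) == [7.3, 15.5]
    assert list(t.numeric("signalValue")) == [4.5, 8.0]
    assert list(t.numeric("summit_offset")) == [50, 80]


def test_numeric_column_with_bad_cell_becomes_missing(tmp_path):
    p = tmp_path / "r.tsv"
    p.write_text("chrom\tstart\tend\tv\nchr1\t0\t10\t1.5\nchr1\t20\t30\toops\nchr1\t40\t50\t2.5\n")
    t = load_regions(p)
    v = t.numeric("v")
    assert v[0] == 1.5 and np.isnan(v[1]) and v[2] == 2.5


# ------------------------------------------------------------------ round trip


def test_write_load_round_trip_preserves_everything(small_table, tmp_path):
    tag_rows(small_table, Selection(frozenset({1, 3})), "kept")
    derive_column(small_table, "r", "ratio(a, b, 1)")
    p = tmp_path / "t.tsv"
    write_table(small_table, p)
    back = load_regions(p)
    assert len(back) == len(small_table)
    for rid in small_table.row_ids:
        assert back.interval(rid) == small_table.interval(rid)
    np.testing.assert_allclose(back.numeric("r"), small_table.numeric("r"), rtol=1e-9)
    assert list(back.tags) == list(small_table.tags)


def test_write_load_write_is_byte_idempotent(analysed_table, tmp_path):
    p1 = tmp_path / "a.tsv"
    write_table(analysed_table, p1)
    t1 = load_regions(p1)
    p2 = tmp_path / "b.tsv"
    write_table(t1, p2)
    t2 = load_regions(p2)
    p3 = tmp_path / "c.tsv"
    write_table(t2, p3)
    assert p2.read_bytes() == p3.read_bytes()


def test_empty_table_writes_header_only(tmp_path):
    df = pd.DataFrame({"chrom": [], "start": [], "end": []})
    t = RegionTable(df)
    p = tmp_path / "e.tsv"
    write_table(t, p)
    assert p.read_text().count("\n") == 1


def test_tags_serialized_comma_joined(small_table, tmp_path):
    tag_rows(small_table, Selection(frozenset({1, 3})), "a")
    tag_rows(small_table, Selection(frozenset({3})), "b")
    p = tmp_path / "t.tsv"
    write_table(small_table, p)
    rows = p.read_text().splitlines()
    assert rows[1].split("\t")[-1] == "a"
    assert rows[2].split("\t")[-1] == ""
    assert rows[3].split("\t")[-1] == "a,b"


def test_write_bed_selection(small_table, tmp_path):
    p = tmp_path / "x.bed"
    write_bed(small_table, p, Selection(frozenset({1, 4})))
    lines = p.read_text().splitlines()
    assert lines == ["chr1\t0\t50\t1\t0\t+", "chr2\t50\t150\t4\t0\t+"]
    write_bed(small_table, p, Selection(frozenset()))
    assert p.read_text() == ""


# ------------------------------------------------------------ derived columns


@pytest.mark.parametrize(
    "expr,expected",
    [
        ("a/b", [4.0, 1.0, np.nan, 0.0, np.nan]),
        ("l2fc(a, a, 1)", [0.0, 0.0, 0.0, 0.0, np.nan]),
        ("ratio(a, b, 0)", [4.0, 1.0, np.nan, 0.0, np.nan]),
        ("-a + 2 * b", [-4.0, 1.0, -4.0, 10.0, np.nan]),
        ("log2(a)", [3.0, 0.0, 2.0, np.nan, np.nan]),
    ],
)
def test_derive_column_values(small_table, expr, expected):
    derive_column(small_table, "out", expr)
    np.testing.assert_allclose(small_table.numeric("out"), expected, rtol=1e-12)


def test_derive_errors_before_mutation(small_table):
    ncols = len(small_table.df.columns)
    with pytest.raises(ExpressionError):
        derive_column(small_table, "bad", "a + nope")
    with pytest.raises(ExpressionError):
        derive_column(small_table, "bad", "a +* b")
    with pytest.raises(ExpressionError):
        derive_column(small_table, "bad", "__import__('os').system('x')")
    assert len(small_table.df.columns) == ncols


def test_derive_matches_per_row_oracle():
    rng = np.random.default_rng(42)
    n = 1000
    a = rng.lognormal(1, 1, n)
    b = rng.lognormal(0.5, 1, n)
    df = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 10,
                       "end": np.arange(n) * 10 + 5, "a": a, "b": b},
                      index=pd.RangeIndex(1, n + 1))
    t = RegionTable(df)
    derive_column(t, "x", "l2fc(a, b, 1) - log10(a + b) / 3")
    got = t.numeric("x")
    for i in rng.choice(n, 50, replace=False):
        want = np.log2((a[i] + 1) / (b[i] + 1)) - np.log10(a[i] + b[i]) / 3
        assert got[i] == pytest.approx(want, rel=1e-12)


def test_delete_column_rules(small_table):
    delete_column(small_table, "a")
    assert not small_table.has_column("a")
    with pytest.raises(ValueError):
        delete_column(small_table, "start")
    with pytest.raises(KeyError):
        delete_column(small_table, "nope")
    # delete then re-derive under the same name is allowed
    derive_column(small_table, "b2", "b + 0")
    delete_column(small_table, "b2")
    derive_column(small_table, "b2", "b * 2")
    assert small_table.numeric("b2")[0] == 4.0


# ------------------------------------------------------------------ filtering


def test_empty_predicate_list_selects_all(small_table):
    assert apply_filter(small_table, []).row_ids == frozenset(small_table.row_ids)


def test_numeric_range_is_closed_and_skips_missing(small_table):
    sel = apply_filter(
        small_table, [FilterPredicate(kind="numeric_range", column="a", lo=1.0, hi=8.0)]
    )
    assert sel.row_ids == frozenset({1, 2, 3})  # 0.0 below lo; NaN excluded


def test_filter_matches_brute_force_on_fixture(analysed_table):
    q = analysed_table.numeric("neg_log10_q")
    sel = apply_filter(
        analysed_table,
        [FilterPredicate(kind="numeric_range", column="neg_log10_q", lo=0, hi=10)],
    )
    ids = np.asarray(analysed_table.df.index)
    brute = {int(i) for i, v in zip(ids, q) if np.isfinite(v) and 0 <= v <= 10}
    assert sel.row_ids == frozenset(brute)


def test_conjunction_is_monotone(analysed_table):
    p1 = FilterPredicate(kind="numeric_range", column="neg_log10_q", lo=5, hi=50)
    p2 = FilterPredicate(kind="numeric_range", column="H3K4me3_area", lo=0, hi=5000)
    s1, s2 = apply_filter(analysed_table, [p1]), apply_filter(analysed_table, [p2])
    s12 = apply_filter(analysed_table, [p1, p2])
    assert s12.row_ids <= s1.row_ids and s12.row_ids <= s2.row_ids
    assert len(s12) <= min(len(s1), len(s2))


def test_filter_never_mutates(small_table):
    before = small_table.df.copy()
    apply_filter(small_table, [FilterPredicate(kind="numeric_range", column="b", lo=0, hi=9)])
    pd.testing.assert_frame_equal(small_table.df, before)


# --------------------------------------------------------------------- tagging


def test_tagging_is_idempotent_and_round_trips(small_table):
    sel = Selection(frozenset({1, 2}))
    tag_rows(small_table, sel, "enhancer")
    tag_rows(small_table, sel, "enhancer")
    assert small_table.tags.loc[1] == {"enhancer"}
    got = apply_filter(
        small_table, [FilterPredicate(kind="tag_has_any", values=frozenset({"enhancer"}))]
    )
    assert got.row_ids == sel.row_ids


def test_disjoint_tags_stay_disjoint(small_table):
    tag_rows(small_table, Selection(frozenset({1, 2})), "strong")
    tag_rows(small_table, Selection(frozenset({4, 5})), "weak")
    assert not any({"strong", "weak"} <= t for t in small_table.tags)


def test_invalid_tags_rejected(small_table):
    with pytest.raises(ValueError):
        tag_rows(small_table, Selection(frozenset({1})), "")
    with pytest.raises(ValueError):
        tag_rows(small_table, Selection(frozenset({1})), "a,b")


# --------------------------------------------------------------------- cloning


def test_clone_is_independent(small_table):
    tag_rows(small_table, Selection(frozenset({2})), "x")
    clone = clone_subset(small_table)
    assert len(clone) == len(small_table)
    assert list(clone.tags.loc[2]) == ["x"]
    tag_rows(clone, Selection(frozenset({1})), "only_clone")
    derive_column(clone, "new", "a + 1")
    assert "only_clone" not in small_table.tags.loc[1]
    assert not small_table.has_column("new")


def test_clone_subset_renumbers(small_table):
    clone = clone_subset(small_table, Selection(frozenset({2, 4})))
    assert clone.row_ids == [1, 2]
    assert clone.interval(1) == small_table.interval(2)
    empty = clone_subset(small_table, Selection(frozenset()))
    assert len(empty) == 0 and empty.metadata_columns == small_table.metadata_columns


# ------------------------------------------------------------------ histograms


def test_histogram_constant_column():
    df = pd.DataFrame({"chrom": ["chr1"] * 4, "start": [0, 10, 20, 30],
                       "end": [5, 15, 25, 35], "v": [2.0] * 4},
                      index=pd.RangeIndex(1, 5))
    edges, counts = summarize_column(RegionTable(df), "v")
    assert list(counts) == [4]


def test_histogram_two_bins(small_table):
    derive_column(small_table, "v", "b + 0")
    edges, counts = summarize_column(small_table, "v", bins=5)
    assert counts.sum() == 5  # all non-missing values counted


def test_histogram_counts_conserved_over_selection(analysed_table):
    sel = apply_filter(
        analysed_table,
        [FilterPredicate(kind="numeric_range", column="neg_log10_q", lo=0, hi=15)],
    )
    edges, counts = summarize_column(analysed_table, "neg_log10_q", selection=sel)
    assert counts.sum() == len(sel)


def test_histogram_all_missing_is_empty():
    df = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5], "v": [np.nan]},
                      index=pd.RangeIndex(1, 2))
    edges, counts = summarize_column(RegionTable(df), "v")
    assert len(edges) == 0 and len(counts) == 0


# -------------------------------------------------------------------- projects


def test_project_round_trip(tmp_path):
    filters = {
        "weak": [FilterPredicate(kind="numeric_range", column="q", lo=0, hi=10)],
        "enh": [FilterPredicate(kind="tag_has_any", values=frozenset({"enhancer"}))],
    }
    p = tmp_path / "proj.json"
    save_project(p, "table.tsv", filters=filters,
                 derived_columns={"r": "l2fc(a, b, 1)"},
                 tag_vocabulary={"enhancer", "promoter"})
    doc = load_project(p)
    assert doc["filters"]["weak"][0].hi == 10
    assert doc["derived_columns"]["r"] == "l2fc(a, b, 1)"
    # save -> load -> save is byte identical
    p2 = tmp_path / "proj2.json"
    save_project(p2, doc["table_path"],
                 filters=doc["filters"], derived_columns=doc["derived_columns"],
                 tag_vocabulary=doc["tag_vocabulary"], embeddings=doc["embeddings"],
                 genome=doc["genome"])
    assert p.read_bytes() == p2.read_bytes()


def test_project_schema_errors(tmp_path):
    p = tmp_path / "bad.json"
    p.write_text('{"schema_version": 99}')
    with pytest.raises(ProjectSchemaError):
        load_project(p)
    p.write_text('{"schema_version": 1, "trunc')
    with pytest.raises(ProjectSchemaError):
        load_project(p)
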