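import numpy as np
import pandas as pd
import pytest

from regionkit import (
    BigWigSignal,
    FixtureConfig,
    RegionTable,
    annotate_nearest_tss,
    load_regions,
    load_tss,
    quantify,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def fixture_ds(tmp_path_factory):
    """One default synthetic dataset shared (read-only) across the session."""
    return simulate_dataset(FixtureConfig(seed=11), tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def _analysed_table(fixture_ds):
    """Regions with all four marks quantified and TSSs annotated (master copy)."""
    table = load_regions(fixture_ds.regions_tsv, dialect="tsv")
    for mark, path in fixture_ds.bigwig_paths.items():
        with BigWigSignal(str(path)) as track:
            quantify(track, table, prefix=mark)
    tss = load_tss(fixture_ds.tss_bed, format="bed6")
    annotate_nearest_tss(table, tss)
    return table


@pytest.fixture
def analysed_table(_analysed_table) -> RegionTable:
    """Mutable per-test copy of the analysed fixture table."""
    return _analysed_table.copy()


@pytest.fixture
def small_table() -> RegionTable:
    """A hand-built 5-row table with two numeric columns."""
    df = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
            "start": [0, 100, 250, 50, 500],
            "end": [50, 200, 300, 150, 700],
            "strand": ["+", "-", ".", "+", "."],
            "a": [8.0, 1.0, 4.0, 0.0, np.nan],
            "b": [2.0, 1.0, 0.0, 5.0, 3.0],
        },
        index=pd.RangeIndex(1, 6),
    )
    return RegionTable(df)
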