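from pathlib import Path

import pandas as pd
import pytest

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def toy_sites() -> pd.DataFrame:
    """30-row site table with hand-checkable NM/MQ/coverage boundary values.

    Composition: 16 rows pass every filter; 4 fail NM (= 7); 3 fail MQ
    (= 175 exactly, strict >); 4 fail coverage (19 < 20); 3 fall inside the
    exclusion interval chrX:[999, 1003).
    """
    return pd.read_csv(DATA_DIR / "toy_sites.tsv", sep="\t")


@pytest.fixture
def toy_exclusions() -> pd.DataFrame:
    from xbias.io import read_bed
    return read_bed(DATA_DIR / "toy_exclude.bed")


@pytest.fixture
def simple_annotation() -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": ["GENE1", "GENE2", "GENE3"],
        "chrom": ["chrX", "chrX", "chr1"],
        "start": [1000, 5000, 100],
        "end": [3000, 9000, 4000],
        "tss": [1000, 8999, 100],
        "strand": ["+", "-", "+"],
        "stratum": ["S1", "S5", "NA"],
    })
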