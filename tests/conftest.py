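import io

import pandas as pd
import pytest

from geotidy.fixtures import PATHOLOGIES, PathologySpec, generate_series
from geotidy.geo_io import parse_platform_table, parse_series_matrix
from geotidy.model import AnnotationTable

#: every pathology that can coexist in one fixture (missing_assay removes the
#: assay block that duplicate_gene_mapping needs)
ALL_COMPATIBLE = tuple(p for p in PATHOLOGIES if p != "missing_assay")


def parse_fixture(spec: PathologySpec):
    """Generate a fixture and parse it into a bundle with features attached."""
    series_text, platform_text, ledger = generate_series(spec)
    bundle = parse_series_matrix(io.StringIO(series_text))
    bundle.features = parse_platform_table(io.StringIO(platform_text))
    return bundle, ledger


@pytest.fixture
def rich_bundle():
    """Six-sample bundle exhibiting every compatible pathology."""
    spec = PathologySpec(n_samples=6, n_features=12,
                         pathologies=ALL_COMPATIBLE, seed=7)
    return parse_fixture(spec)


@pytest.fixture
def small_table():
    return AnnotationTable(
        pd.DataFrame(
            {
                "geo_accession": ["GSM1", "GSM2", "GSM3"],
                "title": ["s1", "s2", "s3"],
                "characteristics_ch1": ["sex: female", "sex: male", "sex: female"],
                "last_update_date": ["Mar 14 2019"] * 3,
            },
            dtype=object,
        ),
        id_column="geo_accession",
    )
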