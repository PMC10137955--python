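from pathlib import Path

import pandas as pd
import pytest

from mitolineage.fixture import load_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_data():
    return load_fixture()


@pytest.fixture(scope="session")
def table5_expected():
    return pd.read_csv(DATA_DIR / "table5_expected.tsv", sep="\t",
                       keep_default_na=False)


@pytest.fixture(scope="session")
def mother_offspring_table(fixture_data):
    from mitolineage.comparison import tabulate_mother_offspring

    return tabulate_mother_offspring(
        fixture_data.mother_offspring_pairs, fixture_data.haplotypes
    )


# The fourteen documented length-variant reporting cases: region, molecule
# read fractions, expected reported calls, expected LHP flag.
TABLE4_CASES = [
    ("302-315", {"A-7C-T-6C-G": 0.97, "A-7C-T-5C-G": 0.03},
     {"315.1C"}, False),
    ("302-315", {"A-8C-T-6C-G": 0.96, "A-7C-T-6C-G": 0.04},
     {"309.1C", "315.1C"}, False),
    ("302-315", {"A-8C-T-6C-G": 0.70, "A-7C-T-6C-G": 0.30},
     {"309.1c", "315.1C"}, True),
    ("302-315", {"A-9C-T-6C-G": 0.70, "A-8C-T-6C-G": 0.30},
     {"309.1C", "309.2c", "315.1C"}, True),
    ("955-966", {"A-12C-A": 0.75, "A-11C-A": 0.25},
     {"961C", "965.1C", "965.2c"}, True),
    ("955-966", {"A-12C-A": 0.60, "A-11C-A": 0.20, "A-10C-A": 0.20},
     {"961C", "965.1c", "965.2c"}, True),
    ("955-966",
     {"A-12C-A": 0.60, "A-11C-A": 0.15, "A-10C-A": 0.15, "A-5C-T-4C-A": 0.10},
     {"961c", "965.1c", "965.2c"}, True),
    ("955-966",
     {"A-13C-A": 0.55, "A-12C-A": 0.15, "A-11C-A": 0.15, "A-10C-A": 0.15},
     {"961C", "965.1c", "965.2c", "965.3c"}, True),
    ("12417-12426", {"C-9A-C": 0.70, "C-8A-C": 0.30},
     {"12425.1a"}, True),
    ("16180-16194", {"2A-13C-A": 0.80, "2A-12C-A": 0.20},
     {"16182C", "16183C", "16189C", "16193.1c"}, True),
    ("16180-16194", {"3A-12C-A": 0.80, "3A-11C-A": 0.20},
     {"16183C", "16189C", "16193.1c"}, True),
    ("249", {"DEL": 0.97, "ref": 0.03}, {"249DEL"}, False),
    ("514-524", {"C(AC)4": 0.8452, "C(AC)5": 0.1548},
     {"523a", "524c"}, True),
    ("8272-8280", {"DEL": 0.882, "ref": 0.118},
     {"8272DEL", "8273DEL", "8274DEL", "8275c", "8276c", "8277t",
      "8278c", "8279t", "8280a"}, True),
]
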