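import warnings

import pytest

import pvlabel as pv
from pvlabel.features import CaseIndex
from pvlabel.report_store import clean_reports
from pvlabel.simulate import PlantedPair, SimConfig

warnings.filterwarnings("ignore", message="The `probability` parameter")


@pytest.fixture(scope="session")
def gmap():
    return pv.load_grouping()


def small_config(seed=0, **overrides):
    """A fast 6-drug x 4-disease database with one planted pair."""
    base = dict(
        n_drugs=6,
        n_diseases=4,
        n_quarters=12,
        start_quarter="2016Q1",
        baseline_rate=0.8,
        planted_pairs=[
            PlantedPair("D000", "Interstitial lung disease", 8.0, 4, "2018Q2")
        ],
        missing_date_prob=0.15,
        duplicate_prob=0.05,
        pre_admin_onset_prob=0.02,
        otc_drug_fraction=0.2,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_db(gmap):
    return pv.generate_database(small_config(), gmap)


@pytest.fixture(scope="session")
def small_cases(small_db, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_db")
    pv.write_database(small_db, outdir)
    return pv.load_reports(outdir)


@pytest.fixture(scope="session")
def small_cleaned(small_cases):
    cleaned, _ = clean_reports(small_cases)
    return cleaned


@pytest.fixture(scope="session")
def small_index(small_cleaned, gmap):
    return CaseIndex(small_cleaned, gmap)
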