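import pytest

from famvar import datasets as ds
from famvar.cascade import run_cascade
from famvar.core.types import CohortCallset, Individual, Pedigree, VariantKey


@pytest.fixture(scope="session")
def study_pedigree():
    return ds.load_pedigree()


@pytest.fixture(scope="session")
def study_cohort():
    return ds.load_cohort()


@pytest.fixture(scope="session")
def study_annotations():
    return ds.load_annotations()


@pytest.fixture(scope="session")
def study_config():
    return ds.study_filter_config()


@pytest.fixture(scope="session")
def cascade_result(study_cohort, study_annotations, study_pedigree, study_config):
    return run_cascade(study_cohort, study_annotations, study_pedigree, study_config)


@pytest.fixture(scope="session")
def fragile_track():
    return ds.load_fragile_sites()


@pytest.fixture(scope="session")
def sister_callset():
    return ds.load_sister_callset()


@pytest.fixture(scope="session")
def pair_data():
    return ds.load_pair_callsets()


@pytest.fixture
def trio_pedigree():
    """Toy pedigree: father F, mother M, daughter D, plus unrelated sister S."""
    return Pedigree(
        [
            Individual("F", "male"),
            Individual("M", "female", affected=True),
            Individual("D", "female", father_id="F", mother_id="M", affected=True),
            Individual("S", "female", affected=True),
        ]
    )


def make_callset(samples, carriers):
    """Merged callset from {(chrom,pos,ref,alt): iterable-of-samples}."""
    return CohortCallset.from_merged(
        samples, {VariantKey.of(*k): set(v) for k, v in carriers.items()}
    )


@pytest.fixture
def make_merged_callset():
    return make_callset
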