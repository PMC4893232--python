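import pytest

from bloodmeal import tables


@pytest.fixture(scope="session")
def survey():
    """Record-level reconstruction of the packaged survey fixtures."""
    return tables.reconstruct_survey()


@pytest.fixture(scope="session")
def taxonomy():
    return tables.default_taxonomy()


@pytest.fixture()
def tiny_records_file(tmp_path):
    """A small well-formed records CSV on disk."""
    path = tmp_path / "records.csv"
    path.write_text(
        "specimen_id,mosquito_taxon,host_species,site_id,collection_date,trap_method,land_use\n"
        "m1,Aedes vexans,Capreolus capreolus,s1,2014-06-15,EVS,rural\n"
        "m2,Aedes vexans,Homo sapiens,s1,2014-07-01,EVS,rural\n"
        "m3,Culex torrentium,Turdus merula,s2,2014-08-20,gravid,urban\n"
    )
    return path
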