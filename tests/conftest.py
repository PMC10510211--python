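import pytest

from paretodock import ObjectivePair, worked_example_fixture


@pytest.fixture
def reference_opioids() -> list[ObjectivePair]:
    """The four reference opioids with printed mean score magnitudes."""
    return worked_example_fixture()


@pytest.fixture
def score_csv(tmp_path):
    """A small well-formed replicate score table on disk."""
    path = tmp_path / "scores.csv"
    path.write_text(
        "ligand_id,condition,replicate,score\n"
        "ligA,neutral,1,-9.0\n"
        "ligA,acidic,1,-9.4\n"
        "ligB,neutral,1,-8.5\n"
        "ligB,acidic,1,-8.5\n"
    )
    return path
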