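import pytest

from wcsim import fixtures


@pytest.fixture
def minimal_cell():
    model, manifest = fixtures.make_minimal_cell_model()
    return model, manifest


@pytest.fixture
def transcription_submodel():
    rnas = [
        fixtures.RnaSpec("RNA_1", 10, (3, 2, 2, 3), 2e-25),
        fixtures.RnaSpec("RNA_2", 8, (2, 2, 2, 2), 2e-21),
    ]
    return fixtures.make_transcription_submodel(rnas, n_rnap=10)
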