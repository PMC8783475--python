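import pytest

from strandcheck import build_index, make_transcriptome


@pytest.fixture(scope="session")
def toy_transcriptome():
    """Ten random transcripts, 500-2000 bp — small enough for brute force."""
    return make_transcriptome(10, (500, 2000), seed=42)


@pytest.fixture(scope="session")
def toy_index(toy_transcriptome):
    return build_index(toy_transcriptome)
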