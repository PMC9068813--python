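import pytest


@pytest.fixture
def chrom_sizes():
    return {"chr1": 1_000, "chr2": 1_000}
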