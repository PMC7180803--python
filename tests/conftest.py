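import pytest
from hypothesis import settings

from idrpatterns import ChainRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from idrpatterns.clustering import ClusterForest

BASE50 = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG"


@pytest.fixture
def base_sequence():
    return BASE50


@pytest.fixture
def single_chain_forest():
    """Forest factory: every chain alone in its own C100 = C75 cluster."""

    def _make(records):
        assignment = {rec.key: i for i, rec in enumerate(records)}
        return ClusterForest(
            levels=(100, 75),
            assignment={100: dict(assignment), 75: dict(assignment)},
        )

    return _make


def make_record(entry, seq, mask, chain="A", method="X-RAY DIFFRACTION", resolution=2.0):
    return ChainRecord(
        entry_id=entry,
        chain_id=chain,
        sequence=seq,
        disorder_mask=mask,
        method=method,
        resolution=resolution,
    )
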