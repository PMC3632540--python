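import numpy as np
import pytest
from hypothesis import settings

from methtrack import BinnedTrack, Genome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_genome() -> Genome:
    return Genome("toy", {"chr1": 1000, "chr2": 550})


def make_track(values, sample_id="s", bin_size=100, normalized=False, n_u=None):
    """Build a single-chromosome track from a plain list of bin values."""
    values = np.asarray(values, dtype=float)
    genome = Genome("toy", {"chr1": len(values) * bin_size})
    track = BinnedTrack(
        sample_id=sample_id,
        genome=genome,
        bin_size=bin_size,
        values={"chr1": values},
        total_unique_reads=float(values.sum() if n_u is None else n_u),
        normalized=normalized,
    )
    return track
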