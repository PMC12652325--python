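import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import occudelta as od

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_design():
    # large enough that cluster III holds ~15 genes and recovery is stable
    return od.SimulationDesign(n_genes=400, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """One generated dataset shared across tests (truth + tracks + counts)."""
    annotation, truth = od.generate_annotation(small_design)
    tracks, true_factors, samples = od.simulate_chip_experiment(annotation, truth, small_design)
    expression = od.simulate_rnaseq_counts(annotation, truth, small_design)
    return {
        "design": small_design,
        "annotation": annotation,
        "truth": truth,
        "tracks": tracks,
        "true_factors": true_factors,
        "samples": samples,
        "expression": expression,
    }


def make_track(chrom_sizes, intervals, sample_id="s", namespace="target", total_fragments=None):
    """Convenience: build a CoverageTrack from (chrom -> list of (start, end, value))."""
    data = {
        c: (
            np.array([iv[0] for iv in ivs]),
            np.array([iv[1] for iv in ivs]),
            np.array([iv[2] for iv in ivs], dtype=float),
        )
        for c, ivs in intervals.items()
    }
    return od.CoverageTrack.from_intervals(
        sample_id=sample_id,
        namespace=namespace,
        chrom_sizes=chrom_sizes,
        intervals=data,
        total_fragments=total_fragments,
    )


@pytest.fixture
def uniform_track():
    def _make(value, length=20000, chrom="chr1", namespace="target", **kw):
        return make_track({chrom: length}, {chrom: [(0, length, value)]}, namespace=namespace, **kw)

    return _make
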