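import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sipscreen.gradient import FractionRecord, GradientMeta, GradientSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_fraction(gid="g1", idx=1, density=1.812, copies=1e5, counts=None):
    return FractionRecord(
        gradient_id=gid,
        fraction_index=idx,
        density=density,
        copies=copies,
        counts=counts or {},
    )


@pytest.fixture
def toy_experiment():
    """Two hand-built gradients (13C + 12C) with one clearly enriched
    taxon, small enough to verify every number by hand."""

    def grad(gid, treatment, heavy_counts, light_counts):
        meta = GradientMeta(
            gradient_id=gid, treatment=treatment, prey="E_coli", timepoint="1d"
        )
        fractions = [
            make_fraction(gid, 1, 1.790, 10.0, {}),
            make_fraction(gid, 2, 1.812, 8e5, light_counts),
            make_fraction(gid, 3, 1.860, 2e5, heavy_counts),
        ]
        return GradientSet(meta, fractions)

    c13 = grad(
        "c13", "C13",
        heavy_counts={"pred": 600, "bystander": 200, "rare": 200},
        light_counts={"pred": 100, "bystander": 500, "rare": 400},
    )
    c12 = grad(
        "c12", "C12",
        heavy_counts={"pred": 100, "bystander": 500, "rare": 400},
        light_counts={"pred": 100, "bystander": 500, "rare": 400},
    )
    return [c13, c12]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230211)
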