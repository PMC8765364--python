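import pytest

from mangrove_nbudget.core_model import CoreSlice, SedimentCore
from mangrove_nbudget.synthetic_data import default_templates, generate_estuary


def make_slice(top=0.0, bottom=1.0, date=2000.0, bd=0.5, fn=0.01, cf=0.2,
               **kw):
    return CoreSlice(depth_top=top, depth_bottom=bottom, mid_date=date,
                     bulk_density=bd, n_fraction=fn, c_fraction=cf, **kw)


@pytest.fixture
def simple_core():
    """Three-slice core spanning both deposition windows."""
    return SedimentCore(
        core_id="c1",
        site_id="s1",
        slices=[
            make_slice(0, 10, 2000, bd=0.5, fn=0.01),
            make_slice(10, 20, 1980, bd=0.5, fn=0.01),
            make_slice(20, 30, 1950, bd=0.4, fn=0.008),
        ],
        sar_by_period={"recent": 3.0, "historic": 2.0},
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Two-site zero-noise bundle on a small mask (fast, deterministic)."""
    templates = default_templates()[:2]
    return generate_estuary(templates, cores_per_site=2, seed=11,
                            noise_scale=0.0, cell_size=200.0)


@pytest.fixture(scope="session")
def noisy_bundle():
    templates = default_templates()
    return generate_estuary(templates, cores_per_site=2, seed=13,
                            noise_scale=1.0, cell_size=200.0)
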