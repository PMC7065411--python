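import pytest

from cowbw import ModelSpec, default_config, packaged_model, simulate_herd


@pytest.fixture(scope="session")
def hgbghw():
    return packaged_model("hgbghw")


@pytest.fixture(scope="session")
def hgbg():
    return packaged_model("hgbg")


@pytest.fixture(scope="session")
def small_herd():
    """Default-condition herd, small enough for fast fits."""
    return simulate_herd(default_config("hgbghw", n_records=4000, seed=7))


@pytest.fixture(scope="session")
def noiseless_herd():
    """Noise-free herd with days at stage-class midpoints: the exactness limit."""
    cfg = default_config(
        "hgbghw", n_records=4000, seed=11,
        residual_sd=0.0, farm_sd=0.0, days_at_class_midpoints=True,
    )
    return simulate_herd(cfg)


@pytest.fixture(scope="session")
def eq2_spec():
    return ModelSpec(("HG", "BG", "HW"), genotype_specific=True)
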