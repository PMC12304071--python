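import pytest

from renalscale import RunConfig, make_subject


@pytest.fixture(scope="session")
def baseline_subject():
    return make_subject(20.0)


@pytest.fixture(scope="session")
def subjects():
    return {bmi: make_subject(bmi) for bmi in (20.0, 25.0, 30.0, 40.0, 50.0, 60.0)}


@pytest.fixture()
def small_config(tmp_path):
    """A reduced but structurally complete study configuration."""
    return RunConfig(
        bmi_categories=(20.0, 40.0),
        grid_axes={
            "fu": [0.05, 1.0],
            "kp": [1.0, 4.0],
            "clint_ats": [2.0, 500.0],
            "rta": [0.5, 1.0],
        },
        output_dir=str(tmp_path / "out"),
    )
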