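import pytest

from torsodose.phantom import PhantomSpec, generate_phantom, load_method_comparison_table


@pytest.fixture(scope="session")
def comparison_table():
    return load_method_comparison_table()


@pytest.fixture
def default_spec():
    return PhantomSpec()


@pytest.fixture
def phantom_study(tmp_path, default_spec):
    """One rendered study folder plus its spec and analytic ground truth."""
    folder = tmp_path / "study"
    gt = generate_phantom(default_spec, folder)
    return folder, default_spec, gt
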