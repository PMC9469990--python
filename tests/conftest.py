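import pytest

from tumoronly.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default synthetic cohort (2 tumors, 23 normals, 250 planted
    variants per tumor), generated once per session."""
    out = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(CohortConfig(), seed=20, out_dir=str(out))
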