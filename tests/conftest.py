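import numpy as np
import pytest

from pbsi.cohort import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    """Two groups, one site, small region counts — fast everywhere."""
    return CohortSpec(
        n_per_group=20,
        groups=("hc", "scz"),
        sites=("siteA",),
        n_ct_regions=16,
        n_sv_regions=8,
        within_group_dispersion={"hc": 0.2, "scz": 0.8},
        seed=7,
    )


@pytest.fixture
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture
def toy_csv(tmp_path):
    """3-subject table with 5 CT and 3 SV regions."""
    path = tmp_path / "toy.csv"
    header = ["subject_id", "group", "site", "sex", "age"]
    ct = [f"ct__r{i}" for i in range(5)]
    sv = [f"sv__v{i}" for i in range(3)]
    rows = [
        ["s1", "hc", "A", "F", "30", "2.1", "2.5", "2.3", "2.8", "2.0", "900", "1100", "1250"],
        ["s2", "hc", "A", "M", "41", "2.2", "2.4", "2.6", "2.7", "2.1", "950", "1050", "1300"],
        ["s3", "scz", "A", "F", "35", "2.0", "2.6", "2.2", "2.9", "1.9", "870", "1150", "1210"],
    ]
    lines = [",".join(header + ct + sv)] + [",".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
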