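import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disaccharide():
    """Default synthetic cellobiose-like model: torsion -77.2, gt, perpendicular."""
    from glycomech.synthetic import SyntheticDisaccharideSpec, build_disaccharide
    return build_disaccharide(SyntheticDisaccharideSpec())


@pytest.fixture(scope="session")
def beta14_link():
    from glycomech.mechanism import GlycosidicLinkage, LinkageType
    return GlycosidicLinkage(chain="A", donor_res_seq=1, acceptor_res_seq=2,
                             linkage_type=LinkageType.BETA_1_4)


@pytest.fixture(scope="session")
def fixture_pdb(tmp_path_factory):
    """Two-residue PDB fixture written by the synthetic builder."""
    from glycomech.synthetic import SyntheticDisaccharideSpec, build_disaccharide
    path = tmp_path_factory.mktemp("fixtures") / "disaccharide.pdb"
    st = build_disaccharide(SyntheticDisaccharideSpec(), path=path)
    return path, st


def random_rigid_transform(rng):
    """Uniform random rotation matrix + translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.normal(scale=5.0, size=3)
    return R, t
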