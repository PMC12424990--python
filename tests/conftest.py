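import numpy as np
import pytest

import slicepasef as sp


@pytest.fixture(scope="session")
def default_cloud():
    """The default synthetic cloud (50,000 ions, fixed seed)."""
    return sp.generate_synthetic_cloud(sp.CloudGenConfig(seed=0))


@pytest.fixture(scope="session")
def small_cloud():
    """A smaller cloud for design/simulation tests."""
    return sp.generate_synthetic_cloud(sp.CloudGenConfig(n_ions=8000, seed=5))


@pytest.fixture(scope="session")
def design_cfg():
    """Designer config over the benchmark precursor region, no survey scan."""
    return sp.DesignConfig(im_range=(0.75, 1.2), mz_range=(400.0, 1000.0),
                           ms1_per_subcycle=0)


@pytest.fixture(scope="session")
def one_f(small_cloud, design_cfg):
    return sp.design_1f(small_cloud, design_cfg)


@pytest.fixture(scope="session")
def reference_scheme():
    """8-frame dia-PASEF, 3 × 25 Th windows per frame, equal fills."""
    return sp.design_diapasef_reference((400.0, 1000.0), (0.75, 1.2), 25.0, 8, 3)


def fragments_of(cloud, prec):
    return [sp.FragmentIon(prec.id, float(r.mz), float(r.rel_intensity))
            for r in cloud.fragments_of(prec.id).itertuples(index=False)]


@pytest.fixture(scope="session")
def joint_subcloud(small_cloud, one_f, reference_scheme):
    """Precursors covered by both the 1F and the reference scheme, eluting
    inside a 24 s simulation window."""
    ions = small_cloud.ions
    d1 = sp.duty_cycle_many(one_f, ions["mz"].to_numpy(), ions["inv_k0"].to_numpy())
    dr = sp.duty_cycle_many(reference_scheme, ions["mz"].to_numpy(),
                            ions["inv_k0"].to_numpy())
    joint = ions[(d1 > 0) & (dr > 0)
                 & (ions["rt_apex_s"] > 28) & (ions["rt_apex_s"] < 36)]
    return small_cloud.subset(joint["id"].head(40).tolist())
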