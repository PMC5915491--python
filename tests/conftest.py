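import numpy as np
import pytest

from gstrw import (
    GstrwParams,
    SyntheticSpec,
    fuse_mirna_similarity,
    generate,
    loocv,
    permute_associations,
)


@pytest.fixture(scope="session")
def strong_fixture():
    """The strong-signal synthetic dataset used throughout the suite.

    60 miRNAs x 30 diseases, 3 aligned blocks, within-block similarity 0.7
    vs 0.1 between, association density 0.5 on matched blocks with 0.02
    noise, generator seed 1.
    """
    spec = SyntheticSpec()
    sm, sd, fam, a = generate(spec)
    sim = fuse_mirna_similarity(sm, fam)
    return {"spec": spec, "sm": sm, "sd": sd, "fam": fam, "a": a, "sim": sim}


@pytest.fixture(scope="session")
def fixture_loocv_aucs(strong_fixture):
    """LOOCV AUCs on the strong-signal fixture, computed once per session."""
    fx = strong_fixture
    return {
        "fused": loocv(fx["a"], fx["sim"], fx["sd"], GstrwParams()).auc,
        "mirna_only": loocv(fx["a"], fx["sim"], fx["sd"], GstrwParams(w=1.0)).auc,
        "disease_only": loocv(fx["a"], fx["sim"], fx["sd"], GstrwParams(w=0.0)).auc,
        "null": loocv(permute_associations(fx["a"], 2), fx["sim"], fx["sd"]).auc,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
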