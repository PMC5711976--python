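import numpy as np
import pytest

from seqshift import kernel, q3, synthetic

IDP_SEED = 11
FOLDED_SEED = 2
FOLDED_HALF_WINDOW = 4  # matches the preset's planted ramp length


@pytest.fixture(scope="session")
def idp_db():
    config = synthetic.idp_preset(IDP_SEED)
    entries, truth = synthetic.generate(config)
    return config, entries, truth


@pytest.fixture(scope="session")
def idp_model(idp_db):
    _, entries, _ = idp_db
    return kernel.train_kernel_model(entries)


@pytest.fixture(scope="session")
def folded_db():
    config = synthetic.folded_preset(FOLDED_SEED)
    entries, truth = synthetic.generate(config)
    return config, entries, truth


@pytest.fixture(scope="session")
def folded_split(folded_db):
    _, entries, _ = folded_db
    return entries[:48], entries[48:]


@pytest.fixture(scope="session")
def folded_models(folded_split):
    train, _ = folded_split
    models = q3.train_q3_kernels(train, exclude_boundary=FOLDED_HALF_WINDOW)
    profiles = q3.build_boundary_profiles(train, models["C"], half_window=FOLDED_HALF_WINDOW)
    return models, profiles


def corrupt_labels(labels: str, rate: float, rng: np.random.Generator) -> str:
    """Flip each Q3 label with the given probability to a different state."""
    out = []
    for c in labels:
        if rng.random() < rate:
            out.append(str(rng.choice([s for s in "HEC" if s != c])))
        else:
            out.append(c)
    return "".join(out)
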