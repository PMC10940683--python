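import numpy as np
import pytest

from dieanet.preprocessing import preprocess_dataset
from dieanet.synthetic import SynthSpec, synth_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mini_pipeline(tmp_path_factory):
    """A small synthetic dataset run through the full preprocessing stage.

    Smaller scans than the generator default keep the suite quick; grade
    structure, stain handling and fold assignment are identical.
    """
    root = tmp_path_factory.mktemp("mini")
    spec = SynthSpec(n_cases_per_grade=5, images_per_case=2,
                     image_size=(448, 512), seed=11)
    cases, metas = synth_dataset(spec, root / "images")
    manifest = preprocess_dataset(cases, root / "patches", seed=11)
    return {"root": root, "spec": spec, "cases": cases, "metas": metas,
            "manifest": manifest, "patch_dir": root / "patches"}


@pytest.fixture(scope="session")
def smoke_result(tmp_path_factory):
    """The full-scale pipeline smoke experiment (generator defaults,
    5 cases/grade, 2 scans/case, 5-fold CV of the tiny attention CNN)."""
    from dieanet.train import smoke_experiment
    work = tmp_path_factory.mktemp("smoke")
    return smoke_experiment(work, seed=1)
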