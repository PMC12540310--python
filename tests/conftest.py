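import numpy as np
import pytest

from maunet.synthetic_phantoms import PhantomConfig, generate_cohort
from maunet.training import RunConfig, load_cohort, train, evaluate_cases, mean_region_dice


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """Four small phantoms on disk plus their manifest."""
    out = tmp_path_factory.mktemp("phantoms")
    manifest = generate_cohort(4, PhantomConfig.tiny(), seed=41, out_dir=out)
    return manifest


@pytest.fixture(scope="session")
def smoke_training_results(tiny_cohort):
    """Three short tiny-preset training runs on the phantom cohort.

    Shared between the learnability acceptance check and the
    loss-decrease contract to avoid training twice.
    """
    cases = load_cohort(tiny_cohort, pad_to_standard=False)
    results = []
    for seed in (41, 42, 43):
        cfg = RunConfig.tiny(seed=seed, max_steps=300, val_fraction=0.0,
                             early_stopping_patience=10_000)
        res = train(cases, cfg)
        per_case = evaluate_cases(res.net, cases, cfg.eval_patches)
        results.append({
            "seed": seed,
            "log": res.log,
            "steps": res.steps,
            "train_dice": mean_region_dice(per_case),
        })
    return results
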