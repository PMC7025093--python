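import numpy as np
import pytest

from phenoscreen import classify, simulate
from phenoscreen.core_data import default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def fast_classifier_config():
    """Small-but-adequate training settings for separable synthetic classes."""
    return classify.ClassifierConfig(seed=7, n_inits=3, epochs=60)


@pytest.fixture(scope="session")
def small_screen(taxonomy):
    """One synthetic vacuole screen with 8 mutant strains of known penetrance."""
    cfg = simulate.GeneratorConfig(
        seed=11, marker="vacuole", n_features=12, cells_per_field_mean=15.0
    )
    cfg.strains = simulate.random_strains(
        8, 11, taxonomy.classes_of("vacuole"), cfg.wild_type_class
    )
    table, layouts, truth = simulate.generate_screen(cfg)
    return cfg, table, layouts, truth


@pytest.fixture(scope="session")
def trained_late_endosome_ensemble(fast_classifier_config):
    """A 4-class ensemble trained on well-separated synthetic cells."""
    gcfg = simulate.GeneratorConfig(seed=21, marker="late_endosome", n_features=10)
    ts, _ = simulate.generate_training_set(gcfg, 60)
    model = classify.train_final(ts, fast_classifier_config)
    return gcfg, ts, model
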