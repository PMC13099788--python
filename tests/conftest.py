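import numpy as np
import pandas as pd
import pytest

from alcomediome import exposure, synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SynthConfig(
        n_participants=400,
        n_species=120,
        n_assoc_taxa_pos=6,
        n_assoc_taxa_neg=6,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort = synth.generate_cohort(small_config)
    return exposure.classify_exposure_frame(cohort)


@pytest.fixture(scope="session")
def small_abundances(small_config, small_cohort):
    return synth.generate_abundances(small_cohort, small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_cohort, small_abundances):
    """Cohort + abundances + mediator + outcome + ground truth, analysis-ready."""
    mediator, med_model = synth.gaussian_mediator(small_cohort, small_config)
    cohort, truth = synth.generate_outcome(
        small_cohort, mediator, small_config, mediator_model=med_model
    )
    cohort = cohort.reset_index(drop=True)
    cohort["mediator"] = mediator
    return {
        "cohort": cohort,
        "matrix": small_abundances.matrix,
        "taxa_pos": list(small_abundances.taxa_pos),
        "taxa_neg": list(small_abundances.taxa_neg),
        "mediator_model": med_model,
        "truth": truth,
        "config": small_config,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def make_mediation_frame(n, cfg_kwargs=None, seed=0):
    """Analysis-ready frame with known mediator law and outcome truth."""
    kwargs = dict(n_participants=n, seed=seed)
    kwargs.update(cfg_kwargs or {})
    cfg = synth.SynthConfig(**kwargs)
    cohort = exposure.classify_exposure_frame(synth.generate_cohort(cfg))
    mediator, med_model = synth.gaussian_mediator(cohort, cfg)
    cohort, truth = synth.generate_outcome(cohort, mediator, cfg, mediator_model=med_model)
    cohort = cohort.reset_index(drop=True)
    cohort["mediator"] = mediator
    return cohort, truth, cfg
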