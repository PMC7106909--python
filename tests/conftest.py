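"""Shared fixtures: a small synthetic cohort bundle, generated once per session."""

import numpy as np
import pytest

from tvburden.synthetic import CallerModel, CohortConfig, generate_cohort, write_bundle


def small_config(seed: int = 11, **overrides) -> CohortConfig:
    """Desk-scale cohort: three cancer types, three callers, modest burdens."""
    kwargs = dict(
        n_patients_per_type={"melanoma": 10, "RCC": 6, "NSCLC": 6},
        tmb_lognormal={
            "melanoma": (np.log(300.0), 0.8),
            "RCC": (np.log(150.0), 0.6),
            "NSCLC": (np.log(200.0), 0.7),
        },
        caller_models=(
            CallerModel("muse", 0.90, 1.0),
            CallerModel("mutect", 0.95, 2.0),
            CallerModel("varscan2", 0.85, 1.5),
        ),
        coverage_mbp=(100.0, 15.0),
        jx_lognormal=(np.log(25.0), 0.3),
        rna_fraction=0.5,
        epitope_variants_cap=3,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def bundle():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, out)
    return out
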