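"""Shared fixtures: a deterministic desk-scale study area and cohort."""

import warnings

import numpy as np
import pytest

from lifedose import pipeline
from lifedose.dispersion import MetSummary, StabilityClass
from lifedose.synthetic import (CohortConfig, apply_missingness,
                                default_emission_series, default_met,
                                default_registration_series,
                                default_traffic_series, generate_cohort,
                                generate_network, generate_sites)

SEED = 20259


@pytest.fixture(scope="session")
def uniform_met():
    """Uniform 8-sector rose, one neutral stability class."""
    return MetSummary(stability_classes=(
        StabilityClass(1.0, sigma_y=(0.11, 0.91), sigma_z=(0.086, 0.85)),))


@pytest.fixture(scope="session")
def study():
    """A 2000-subject cohort on a mid-sized network, with ground truth,
    masked observables and the historical series."""
    cfg = CohortConfig(n_subjects=2000, n_sites=300, minor_spacing_km=1.2,
                       n_major_roads=5)
    met = default_met(1)
    network, centres = generate_network(cfg, SEED)
    sites = generate_sites(cfg, network, centres, met, SEED)
    cohort, truth = generate_cohort(cfg, SEED, sites=sites)
    masked = apply_missingness(cohort, SEED)
    return {
        "cfg": cfg, "network": network, "centres": centres, "sites": sites,
        "cohort": cohort, "truth": truth, "masked": masked, "met": met,
        "eps": default_emission_series(),
        "traffic": default_traffic_series(),
        "registrations": default_registration_series(),
    }


@pytest.fixture(scope="session")
def study_pipeline(study):
    """Place-method pipeline result (M=5) on the masked study cohort."""
    pcfg = pipeline.PipelineConfig(m_imputations=5,
                                   imputation_method="place")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run(study["masked"], study["eps"], study["traffic"],
                            study["registrations"], pcfg, seed=SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
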