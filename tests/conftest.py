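"""Shared fixtures: literature-parameter simulations and synthetic cohorts.

Heavy objects (cohorts, fine-grid simulations) are session-scoped so the
kinetics, baseline, GLM and acceptance tests reuse them.
"""

import numpy as np
import pytest

from fpetkit.baselines import BaselineSpec, detrend, _poly_design
from fpetkit.cohort import CohortSpec, generate_cohort
from fpetkit.glm import BlockDesign, select_sham_regressors
from fpetkit.kinetics import (InfusionSchedule, KineticParams, frame_tac,
                              make_aif, simulate_tac)

CI_FRAME = 16.0 / 60.0
BCI_FRAME = 0.5


@pytest.fixture(scope="session")
def lit_params():
    return KineticParams.literature()


@pytest.fixture(scope="session")
def ci_schedule():
    return InfusionSchedule("CI", duration=95.0)


@pytest.fixture(scope="session")
def bci_schedule():
    return InfusionSchedule("B+CI", duration=105.0, kbol=19.3, bolus_width=1.0)


@pytest.fixture(scope="session")
def ci_aif(ci_schedule):
    from fpetkit.cohort import DEFAULT_RESPONSE_CI
    return make_aif(ci_schedule, DEFAULT_RESPONSE_CI)


@pytest.fixture(scope="session")
def bci_aif(bci_schedule):
    from fpetkit.cohort import DEFAULT_RESPONSE_BCI
    return make_aif(bci_schedule, DEFAULT_RESPONSE_BCI)


@pytest.fixture(scope="session")
def ci_framed(ci_aif, lit_params):
    """Noise-free 95-min CI TAC at 16-s frames, literature kinetics."""
    return frame_tac(simulate_tac(ci_aif, lit_params), CI_FRAME, 95.0)


@pytest.fixture(scope="session")
def bci_framed(bci_aif, lit_params):
    """Noise-free 105-min B+CI TAC at 30-s frames, literature kinetics."""
    return frame_tac(simulate_tac(bci_aif, lit_params), BCI_FRAME, 105.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Small null CI cohort for fast pipeline checks."""
    return generate_cohort(CohortSpec(n_subjects=4, n_parcels=12, seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """The study-scale null CI cohort: 24 subjects, 100 parcels."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def sham_selection(null_cohort):
    """Sham regressors ranked against the cohort's P3MT mean residual."""
    fits = [detrend(tac, BaselineSpec("P3MT")) for tac in null_cohort.tacs]
    reference = np.mean([f.mean_residual() for f in fits], axis=0)
    frame_mid = null_cohort.frame_mid
    candidates = [BlockDesign(10.0, 10.0, float(r), 95.0) for r in range(20)]
    return select_sham_regressors(candidates, reference, frame_mid,
                                  orthogonalize_to=_poly_design(frame_mid))
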