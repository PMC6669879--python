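import pytest

from ceatk import TrialDesign, SimTruth, generate_trial, build_analysis_table


@pytest.fixture(scope="session")
def default_trial():
    """Default-sized synthetic trial (162:88, 30% MAR missingness)."""
    return generate_trial(TrialDesign(seed=11))


@pytest.fixture(scope="session")
def default_table(default_trial):
    return build_analysis_table(
        default_trial.participants,
        default_trial.attendance,
        therapist_params=default_trial.therapist_params,
    )


@pytest.fixture(scope="session")
def big_trial():
    """Large trial (n=5000) for Monte-Carlo checks of generator moments."""
    return generate_trial(
        TrialDesign(n_intervention=3250, n_control=1750, seed=5)
    )


@pytest.fixture(scope="session")
def small_complete_table():
    """Small trial without missingness for fast analysis-stage tests."""
    design = TrialDesign(
        n_intervention=60,
        n_control=30,
        seed=17,
        true_effects=SimTruth(missing_fraction=0.0),
    )
    trial = generate_trial(design)
    return build_analysis_table(
        trial.participants, trial.attendance, therapist_params=trial.therapist_params
    )
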