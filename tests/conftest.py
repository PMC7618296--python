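import pytest

from ovatriage.accuracy import AgeGroup, TestId, load_default_accuracy

TestId.__test__ = False  # enum, not a test case, despite the name
from ovatriage.decision_tree import standard_pathways
from ovatriage.economics import OutcomeLibrary
from ovatriage.synthetic_data import default_profile


@pytest.fixture(scope="session")
def profile():
    return default_profile(seed=0)


@pytest.fixture(scope="session")
def accuracy():
    return load_default_accuracy()


@pytest.fixture(scope="session")
def pathways():
    return standard_pathways()


@pytest.fixture(scope="session")
def ge50(profile):
    return profile.stratum(AgeGroup.GE50)


@pytest.fixture(scope="session")
def under50(profile):
    return profile.stratum(AgeGroup.UNDER50)


@pytest.fixture(scope="session")
def library_ge50(profile, ge50):
    return OutcomeLibrary.build(ge50, profile.markov_parameters())


@pytest.fixture(scope="session")
def library_under50(profile, under50):
    return OutcomeLibrary.build(under50, profile.markov_parameters())
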