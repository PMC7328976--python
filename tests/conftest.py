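import pytest

import metacred as mc


@pytest.fixture(scope="session")
def fixture_summaries():
    return mc.load_inpaper_fixture()


@pytest.fixture(scope="session")
def significant_summaries(fixture_summaries):
    return [s for s in fixture_summaries if s.significant]


@pytest.fixture
def worked_pair():
    """Two studies with log ORs (0, 0.6931) and equal SE 0.1."""
    return [
        mc.EffectEstimate(0.0, 0.1, "allele", "s1", 2001),
        mc.EffectEstimate(0.6931, 0.1, "allele", "s2", 2003),
    ]


def make_record(study_id="S1", year=2005, case=(25, 50, 25), ctrl=(25, 50, 25), **kw):
    defaults = dict(
        author=f"auth-{study_id}",
        cancer="prostate",
        variant="rs0000001",
        ethnicity="Caucasian",
        case_counts=case,
        control_counts=ctrl,
    )
    defaults.update(kw)
    return mc.StudyRecord(study_id=study_id, year=year, **defaults)


@pytest.fixture
def record_factory():
    return make_record
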