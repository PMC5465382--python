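import numpy as np
import pytest

from moodlatent import (
    CohortTemplate,
    StudyConfig,
    build_matrix,
    center_by_participant,
    generate_study,
)
from moodlatent.synthetic import mz_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mz_study(n_participants=20, duration_days=100, seed=0, **template_kwargs):
    """Small MZ-only synthetic study used across test modules."""
    cohort = CohortTemplate(
        name="BD", templates=(mz_template(**template_kwargs),)
    )
    return StudyConfig(
        cohorts=((cohort, n_participants),),
        duration_days=duration_days,
        seed=seed,
    )


@pytest.fixture
def mz_dataset():
    return generate_study(make_mz_study())


@pytest.fixture
def mz_centered(mz_dataset):
    return center_by_participant(build_matrix(mz_dataset, "MZ", "BD"))


def random_psd(rng, M):
    A = rng.standard_normal((M, M))
    return A @ A.T


@pytest.fixture
def toy_csv(tmp_path):
    """One complete MZ record plus two unrelated rows."""
    path = tmp_path / "toy.csv"
    rows = ["participant_id,cohort,date,questionnaire,item,value"]
    for item, value in zip(
        ("anxious", "elated", "sad", "angry", "irritable", "energetic"),
        (3, 4, 2, 1, 5, 6),
    ):
        rows.append(f"P1,BD,2014-01-01,MZ,{item},{value}")
    rows.append("P1,BD,2014-01-02,MZ,anxious,2")  # incomplete record
    rows.append("P2,HC,2014-01-01,GAD7,nervous,1")
    path.write_text("\n".join(rows) + "\n")
    return path
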