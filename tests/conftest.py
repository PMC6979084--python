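import numpy as np
import pytest

from eiphlca import CohortDesign, ExamRecord, LatentClassParams, default_study_params, generate_cohort


def exercised_record(horse_id: str, tbe_score: int, balf_rbc: float, occasion: int = 1) -> ExamRecord:
    return ExamRecord(
        horse_id=horse_id,
        group="exercised",
        modality="treadmill",
        occasion=occasion,
        tbe_score=tbe_score,
        balf_rbc=balf_rbc,
    )


def sedentary_record(horse_id: str, balf_rbc: float, occasion: int = 1) -> ExamRecord:
    return ExamRecord(
        horse_id=horse_id,
        group="sedentary",
        modality="none",
        occasion=occasion,
        tbe_score=None,
        balf_rbc=balf_rbc,
        latent_eiph=False,
    )


@pytest.fixture(scope="session")
def study_params() -> LatentClassParams:
    return default_study_params()


@pytest.fixture(scope="session")
def small_cohort(study_params):
    """Study-sized synthetic cohort: 102 exercised + 9x2 sedentary."""
    return generate_cohort(study_params, CohortDesign(102, 9, 2, seed=424242))


@pytest.fixture(scope="session")
def agreement_table_cohort():
    """102 exercised records engineered to reproduce the study's 2x2
    agreement cells at a 992 cells/uL cutoff: 59 TBE+/RBC+, 1 TBE+/RBC-,
    39 TBE-/RBC+, 3 TBE-/RBC-."""
    records = []
    k = 0
    for n_cell, score, rbc in [(59, 1, 2000.0), (1, 1, 500.0), (39, 0, 2000.0), (3, 0, 500.0)]:
        for _ in range(n_cell):
            k += 1
            records.append(exercised_record(f"tb{k:03d}", score, rbc))
    return records


def brute_spearman(x, y):
    """Independent oracle: Pearson correlation of average ranks, with ranks
    assigned by sorting (no scipy rank machinery)."""
    def avg_ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx = np.asarray(avg_ranks(x))
    ry = np.asarray(avg_ranks(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
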