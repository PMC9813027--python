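import numpy as np
import pytest
from hypothesis import settings

from mrmcroc import CaseTruth, RatingRecord, SimConfig, StudyDataset, generate_study

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


def make_rating(case_id, reader_id, mode, bi_rads, pom=None):
    from mrmcroc.datamodel import MODE_SESSION
    return RatingRecord(case_id=case_id, reader_id=reader_id, mode=mode,
                        session=MODE_SESSION[mode], bi_rads=bi_rads, pom=pom)


@pytest.fixture
def tiny_dataset():
    """4 patients / 8 breasts, 2 readers, 2 modes, handmade deterministic ratings."""
    truths = []
    specs = [
        ("P001", "left", "malignant", "dense", "mass", 19.0),
        ("P001", "right", "normal_negative", "dense", "none", None),
        ("P002", "left", "benign_biopsy", "non_dense", "calcification", 12.0),
        ("P002", "right", "malignant", "non_dense", "calcification", 25.0),
        ("P003", "left", "normal_negative", "dense", "none", None),
        ("P003", "right", "normal_negative", "dense", "none", None),
        ("P004", "left", "malignant", "non_dense", "mass", 30.0),
        ("P004", "right", "benign_biopsy", "non_dense", "mass", 10.0),
    ]
    for pid, side, truth, dens, ft, size in specs:
        cid = f"{pid}_{side[0].upper()}"
        truths.append(CaseTruth(case_id=cid, patient_id=pid, side=side,
                                truth=truth, density=dens, finding_type=ft,
                                lesion_size_mm=size))
    # reader x case BI-RADS (DM), AICAD_SM shifts malignant up one notch
    base = {
        "R1": [5, 1, 3, 4, 1, 2, 4, 2],
        "R2": [4, 2, 2, 3, 1, 1, 5, 3],
    }
    ratings = []
    for reader, scores in base.items():
        for t, b_dm in zip(truths, scores):
            b_sm = min(5, b_dm + 1) if t.truth == "malignant" else b_dm
            for mode, b in (("DM", b_dm), ("AICAD_SM", b_sm)):
                pom = 20 * b if b >= 3 else None
                ratings.append(make_rating(t.case_id, reader, mode, b, pom))
    return StudyDataset(truths=truths, ratings=ratings,
                        metadata={"provenance": "synthetic", "seed": None})


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down two-mode study used by bootstrap/metrics tests."""
    return SimConfig.with_composition(12, 12, 36, n_patients=30,
                                      modes=("DM", "AICAD_SM"), seed=11)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_study(small_cfg)


@pytest.fixture(scope="session")
def default_study():
    """Full-size reference study (388 breasts, 4 readers, 4 modes)."""
    return generate_study(seed=123)


def brute_force_auc(scores, labels):
    """Pair-counting oracle: (#{pos>neg} + 0.5 #{pos=neg}) / (n_pos n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
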