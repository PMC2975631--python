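import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neoseg import (ConfusionCounts, accuracy_report, confusion,
                    estimation_indices, icc, reliability_report, repeatability,
                    similarity_index, within_subject_sd)
from neoseg.metrics import DesignError
from neoseg.volumes_io import LabelMap
from neoseg.cohort_tables import (INTRA_RATER_RELIABILITY,
                                  INTER_RATER_RELIABILITY, WMSA_RELIABILITY)


def _maps(ref, auto):
    ref = np.asarray(ref, dtype=np.int16).reshape(-1, 1, 1)
    auto = np.asarray(auto, dtype=np.int16).reshape(-1, 1, 1)
    return (LabelMap(labels=ref, spacing=(1, 1, 1)),
            LabelMap(labels=auto, spacing=(1, 1, 1)))


def test_confusion_worked_example():
    # Ref has 4 class-1 voxels, Auto has 3, overlap 2
    ref, auto = _maps([1, 1, 1, 1, 0, 0], [1, 1, 0, 0, 1, 0])
    c = confusion(ref, auto, 1)
    assert (c.tp, c.fp, c.fn) == (2, 1, 2)
    assert c.ref_size == 4 and c.auto_size == 3


def test_confusion_identical_and_absent():
    ref, auto = _maps([1, 2, 0], [1, 2, 0])
    c = confusion(ref, auto, 1)
    assert c.fp == 0 and c.fn == 0
    c3 = confusion(ref, auto, 3)
    assert (c3.tp, c3.fp, c3.fn) == (0, 0, 0)


def test_similarity_index_examples():
    assert similarity_index(ConfusionCounts(5, 0, 0)) == 1.0
    assert similarity_index(ConfusionCounts(0, 3, 4)) == 0.0
    assert similarity_index(ConfusionCounts(2, 1, 2)) == pytest.approx(4 / 7)
    assert np.isnan(similarity_index(ConfusionCounts(0, 0, 0)))  # undefined


def test_estimation_indices_examples():
    assert estimation_indices(ConfusionCounts(5, 0, 0)) == (1.0, 0.0, 0.0)
    cei, oei, uei = estimation_indices(ConfusionCounts(2, 1, 2))
    assert (cei, oei, uei) == (0.5, 0.25, 0.5)
    assert all(np.isnan(v) for v in estimation_indices(ConfusionCounts(0, 7, 0)))


@settings(derandomize=True, max_examples=200)
@given(tp=st.integers(0, 1000), fp=st.integers(0, 1000), fn=st.integers(1, 1000))
def test_index_identities(tp, fp, fn):
    c = ConfusionCounts(tp, fp, fn)
    cei, oei, uei = estimation_indices(c)
    assert cei + uei == pytest.approx(1.0)
    # SI expressed through the reference-relative indices
    si = similarity_index(c)
    assert si == pytest.approx(2 * cei / (2 * cei + oei + uei))


def test_si_symmetric_estimation_indices_not():
    ref, auto = _maps([1, 1, 1, 0], [1, 0, 0, 0])
    a = confusion(ref, auto, 1)
    b = confusion(auto, ref, 1)
    assert similarity_index(a) == similarity_index(b)
    assert estimation_indices(a) != estimation_indices(b)


def test_confusion_against_bruteforce_enumeration():
    rng = np.random.default_rng(0)
    for _ in range(20):
        ref = rng.choice([0, 1, 2, 3], size=(16, 16, 4)).astype(np.int16)
        auto = rng.choice([0, 1, 2, 3], size=(16, 16, 4)).astype(np.int16)
        for code in (1, 2, 3):
            c = confusion(ref, auto, code)
            tp = fp = fn = 0
            for r, a in zip(ref.ravel(), auto.ravel()):
                if r == code and a == code:
                    tp += 1
                elif r != code and a == code:
                    fp += 1
                elif r == code and a != code:
                    fn += 1
            assert (c.tp, c.fp, c.fn) == (tp, fp, fn)


def _pairs_df(pairs, region=None):
    rows = []
    for i, (a, b) in enumerate(pairs):
        rows.append({"subject": i, "repeat": 1, "volume": a})
        rows.append({"subject": i, "repeat": 2, "volume": b})
    df = pd.DataFrame(rows)
    if region is not None:
        df["region"] = region
    return df


def test_within_subject_sd_worked_example():
    # pairs (100,104), (200,202): sqrt((16+4)/4) = sqrt(5)
    df = _pairs_df([(100, 104), (200, 202)])
    assert within_subject_sd(df) == pytest.approx(np.sqrt(5))


def test_within_subject_sd_properties():
    df = _pairs_df([(10, 10), (20, 20)])
    assert within_subject_sd(df) == 0.0
    df2 = _pairs_df([(100, 104), (200, 202)])
    df2_shift = df2.assign(volume=df2.volume + 1000)
    assert within_subject_sd(df2_shift) == pytest.approx(within_subject_sd(df2))
    with pytest.raises(DesignError):
        within_subject_sd(pd.DataFrame({"subject": [1], "volume": [5.0]}))


def test_within_subject_sd_equals_duplicate_formula():
    rng = np.random.default_rng(1)
    pairs = rng.normal(1000, 100, (12, 2))
    df = _pairs_df([tuple(p) for p in pairs])
    d = pairs[:, 0] - pairs[:, 1]
    assert within_subject_sd(df) == pytest.approx(
        np.sqrt((d ** 2).sum() / (2 * len(d))))


def test_repeatability_values():
    assert repeatability(20.8) == pytest.approx(57.6, abs=0.05)
    assert repeatability(42.7) == pytest.approx(118.3, abs=0.05)
    assert repeatability(0.0) == 0.0
    with pytest.raises(ValueError):
        repeatability(-1.0)


def test_icc_worked_example():
    df = _pairs_df([(10, 12), (20, 19), (30, 31)])
    res = icc(df, model="icc1")
    assert res.estimate == pytest.approx(0.990, abs=5e-4)


def test_icc_perfect_duplicates():
    df = _pairs_df([(10, 10), (20, 20), (30, 30)])
    res = icc(df, model="icc1")
    assert res.estimate == 1.0


def test_icc_matches_pingouin():
    import pingouin as pg
    rng = np.random.default_rng(2)
    subj_effect = rng.normal(1000, 300, 10)
    pairs = subj_effect[:, None] + rng.normal(0, 30, (10, 2))
    df = _pairs_df([tuple(p) for p in pairs])
    long = df.rename(columns={"repeat": "rater"})
    pgres = pg.intraclass_corr(data=long, targets="subject", raters="rater",
                               ratings="volume").set_index("Type")
    ours1 = icc(df, model="icc1")
    ours2 = icc(df, model="icc2", within_col="repeat")
    assert ours1.estimate == pytest.approx(float(pgres.loc["ICC(1,1)", "ICC"]),
                                           abs=1e-10)
    assert ours2.estimate == pytest.approx(float(pgres.loc["ICC(A,1)", "ICC"]),
                                           abs=1e-10)
    ci1 = pgres.loc["ICC(1,1)", "CI95"]  # pingouin rounds the CI to 2 dp
    assert round(ours1.ci_low, 2) == pytest.approx(ci1[0], abs=0.011)
    assert round(ours1.ci_high, 2) == pytest.approx(ci1[1], abs=0.011)


def test_oneway_icc_is_rater_agnostic():
    """Swapping which column a measurement sits in leaves ICC(1,1) unchanged."""
    rng = np.random.default_rng(3)
    pairs = rng.normal(500, 100, (10, 2))
    df = _pairs_df([tuple(p) for p in pairs])
    swapped = _pairs_df([(b, a) if i % 2 else (a, b)
                         for i, (a, b) in enumerate(pairs)])
    assert icc(swapped, model="icc1").estimate == pytest.approx(
        icc(df, model="icc1").estimate, abs=1e-12)


def test_icc_requires_balance():
    df = pd.DataFrame({"subject": [1, 1, 2, 2, 2],
                       "volume": [1.0, 2, 3, 4, 5]})
    with pytest.raises(DesignError):
        icc(df, model="icc1", within_col=None)


def test_reliability_report_columns_consistent():
    rng = np.random.default_rng(4)
    rows = []
    for region in ("thalamus", "caudate"):
        base = rng.normal(5000, 1000, 10)
        for i, b in enumerate(base):
            for rep in (1, 2):
                rows.append({"region": region, "subject": i, "repeat": rep,
                             "volume": b + rng.normal(0, 50)})
    rep = reliability_report(pd.DataFrame(rows))
    for _, row in rep.iterrows():
        assert row["repeatability_mm3"] == pytest.approx(
            round(2.77 * row["within_subject_sd_mm3"], 1))
        assert -1 <= row["icc"] <= 1


@pytest.mark.parametrize("table", [INTRA_RATER_RELIABILITY,
                                   INTER_RATER_RELIABILITY])
def test_cohort_tables_repeatability_consistent(table):
    """The published repeatability column is 2.77x the SD column (the table
    prints both to one decimal from unrounded SDs, so cells computed from the
    printed SDs can differ by up to ~0.2)."""
    for region, (sd, rep, *_rest) in table.items():
        assert repeatability(sd) == pytest.approx(rep, abs=0.2), region
    assert repeatability(WMSA_RELIABILITY["within_subject_sd"]) == pytest.approx(
        WMSA_RELIABILITY["repeatability"], abs=0.05)


def test_accuracy_report_identical_maps():
    rng = np.random.default_rng(5)
    lab = rng.choice([0, 1, 2, 3], size=(8, 8, 2)).astype(np.int16)
    lm = LabelMap(labels=lab, spacing=(1, 1, 1))
    rep = accuracy_report(lm, lm, [1, 2, 3])
    assert (rep["SI"] == 1.0).all()
    assert (rep["CEI"] == 1.0).all()
    assert (rep["OEI"] == 0.0).all()
    assert len(rep) == 3
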