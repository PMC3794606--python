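"""Fold induction, ratio classification, Fisher test and association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import oracles
from p53recode import (ContingencyTable2x2, TransactivationRecord,
                       classify_ratio, fisher_exact_two_sided, fold_induction,
                       signature_association)


def _record(activities, normalizers, background, bg_norm=1.0):
    return TransactivationRecord("re", "WT", tuple(activities),
                                 tuple(normalizers), background, bg_norm)


@pytest.mark.parametrize(
    "activities, normalizers, background, expected",
    [
        ((100, 100), (1, 1), 10, 10.0),
        ((10,), (1,), 10, 1.0),
        ((90, 110), (1, 1), 10, 10.0),
        ((200, 200), (2, 2), 50, 2.0),
    ],
)
def test_fold_induction(activities, normalizers, background, expected):
    assert fold_induction(_record(activities, normalizers, background)) == \
        pytest.approx(expected)


def test_fold_induction_scale_invariant(rng):
    acts = rng.uniform(50, 500, 4)
    base = fold_induction(_record(acts, np.ones(4), 25))
    scaled = fold_induction(_record(acts * 7.3, np.ones(4), 25 * 7.3))
    assert scaled == pytest.approx(base)


def test_fold_induction_errors():
    with pytest.raises(ValueError):
        _record((), (), 10)
    with pytest.raises(ValueError):
        fold_induction(_record((100,), (1,), 0))


@pytest.mark.parametrize(
    "mut, wt, ratio, klass",
    [
        (20, 10, 2.0, "enhanced"),
        (5, 10, 0.5, "reduced"),
        (15, 10, 1.5, "similar"),     # boundary maps to similar
        (6.7, 10, 0.67, "similar"),
        (10, 10, 1.0, "similar"),
    ],
)
def test_classify_ratio(mut, wt, ratio, klass):
    cls = classify_ratio(mut, wt)
    assert cls.ratio == pytest.approx(ratio)
    assert cls.klass == klass


def test_classify_ratio_partitions_positive_axis(rng):
    for r in np.concatenate([rng.uniform(0.01, 5, 200), [0.67, 1.5]]):
        cls = classify_ratio(r, 1.0)
        n_classes = sum([cls.ratio > 1.5, cls.ratio < 0.67,
                         0.67 <= cls.ratio <= 1.5])
        assert n_classes == 1
    with pytest.raises(ValueError):
        classify_ratio(-1, 1)


@pytest.mark.parametrize(
    "table, expected",
    [
        ([[28, 16], [5, 13]], 0.013),      # half-site worked example
        ([[1, 1], [1, 1]], 1.0),
        ([[2, 0], [0, 2]], 1 / 3),
    ],
)
def test_fisher_worked_examples(table, expected):
    assert fisher_exact_two_sided(table) == pytest.approx(expected, abs=5e-4)


def test_fisher_matches_rational_enumeration(rng):
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
        if a + b + c + d == 0:
            continue
        mine = fisher_exact_two_sided([[a, b], [c, d]])
        ref = oracles.fisher_enum(a, b, c, d)
        assert mine == pytest.approx(ref, rel=1e-7, abs=1e-12)


def test_fisher_matches_scipy(rng):
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
        if a + b + c + d == 0:
            continue
        mine = fisher_exact_two_sided([[a, b], [c, d]])
        ref = sps.fisher_exact([[a, b], [c, d]])[1]
        assert mine == pytest.approx(ref, rel=1e-6, abs=1e-12)


def test_fisher_symmetries(rng):
    """p is invariant under transpose and simultaneous row+column swap."""
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
        if a + b + c + d == 0:
            continue
        p = fisher_exact_two_sided([[a, b], [c, d]])
        assert fisher_exact_two_sided([[a, c], [b, d]]) == pytest.approx(p)
        assert fisher_exact_two_sided([[d, c], [b, a]]) == pytest.approx(p)


def test_fisher_rejects_all_zero():
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)


def _classified_frame(rng, n, p_feature=0.5, coupled=False):
    rows = []
    for i in range(n):
        klass = rng.choice(["enhanced", "reduced"])
        ww = []
        for _ in range(2):
            p = p_feature + (0.3 if coupled and klass == "enhanced" else 0.0)
            ww.append("TT" if rng.random() < p else "AT")
        rows.append({"name": f"re{i}", "ratio": float(rng.uniform(0.1, 3)),
                     "klass": klass, "ry_count": int(rng.integers(0, 5)),
                     "ww1": ww[0], "ww2": ww[1],
                     "ry_half1": bool(rng.integers(2)),
                     "ry_half2": bool(rng.integers(2))})
    return pd.DataFrame(rows)


def test_association_counts_half_sites(rng):
    """Denominators are 2 half-sites per RE, as in the 44-vs-18 layout."""
    df = _classified_frame(rng, 31)
    rep = signature_association(df)
    arr = rep.table.as_array()
    n_enh = (df["klass"] == "enhanced").sum()
    n_red = (df["klass"] == "reduced").sum()
    assert arr[0].sum() == 2 * n_enh
    assert arr[1].sum() == 2 * n_red
    assert 0 < rep.fisher_p <= 1


def test_association_detects_coupling(rng):
    df = _classified_frame(rng, 150, p_feature=0.3, coupled=True)
    rep = signature_association(df)
    assert rep.fisher_p < 0.01


def test_association_ry_feature(rng):
    df = _classified_frame(rng, 40)
    rep = signature_association(df, feature="ry")
    assert "RY" in rep.table.col_labels[0]
    assert 0 < rep.fisher_p <= 1


def test_association_empty_group_raises(rng):
    df = _classified_frame(rng, 20)
    df["klass"] = "enhanced"
    with pytest.raises(ValueError, match="reduced"):
        signature_association(df)


def test_fisher_null_p_values_are_valid(rng):
    """Type-I control: under independence, P(p <= 0.05) stays <= 0.05.

    The exact test is conservative (its p-values are stochastically larger
    than uniform, with an atom at p = 1), so validity rather than exact
    uniformity is the operative null guarantee.
    """
    hits = 0
    n_rep = 400
    for _ in range(n_rep):
        x = rng.binomial(1, 0.5, 60).sum()
        y = rng.binomial(1, 0.5, 60).sum()
        p = fisher_exact_two_sided([[int(x), 60 - int(x)],
                                    [int(y), 60 - int(y)]])
        hits += p <= 0.05
    # binomial 3-sigma headroom above the nominal level
    assert hits / n_rep <= 0.05 + 3 * (0.05 * 0.95 / n_rep) ** 0.5
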