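"""PERMANOVA, dispersion and variance-partition tests against classical
oracles and hand-computed cases."""

import numpy as np
import pandas as pd
import pytest

from phytodiv.multivariate import (
    _permutations,
    compact_letter_display,
    dispersion,
    pairwise_permanova,
    permanova,
    variance_partition,
)
from phytodiv.occurrence import DistanceMatrix


def euclid_dm(points, ids=None):
    pts = np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    d = d / max(d.max(), 1.0)  # keep in [0, 1]
    ids = ids or [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(sample_ids=ids, d=d)


def meta_for(ids, **cols):
    return pd.DataFrame(cols, index=ids)


def test_two_separated_groups_r2_one():
    """Duplicated identical points per group: all SS between groups."""
    d = np.ones((6, 6)) - np.eye(6)
    d[np.ix_(range(3), range(3))] = 0.0
    d[np.ix_(range(3, 6), range(3, 6))] = 0.0
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i}" for i in range(6)]
    dm = DistanceMatrix(sample_ids=ids, d=d)
    meta = meta_for(ids, group=["a"] * 3 + ["b"] * 3)
    tab = permanova(dm, meta, ["group"], n_permutations=99, seed=0)
    assert tab.term("group")["R2"] == pytest.approx(1.0, abs=1e-9)


def test_euclidean_anova_equivalence():
    """For Euclidean distances the PERMANOVA decomposition equals the
    classical one-way ANOVA sums of squares (computed independently)."""
    values = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 12.0])
    labels = ["a", "a", "a", "b", "b", "b"]
    pts = values / 12.0  # match the matrix normalization below
    d = np.abs(pts[:, None] - pts[None, :])
    ids = [f"s{i}" for i in range(6)]
    dm = DistanceMatrix(sample_ids=ids, d=d)
    tab = permanova(dm, meta_for(ids, group=labels), ["group"],
                    n_permutations=99, seed=1)
    grand = pts.mean()
    ss_total = ((pts - grand) ** 2).sum()
    ss_between = sum(3 * (pts[np.array(labels) == g].mean() - grand) ** 2
                     for g in ("a", "b"))
    ss_within = ss_total - ss_between
    assert tab.table.loc["Total", "SS"] == pytest.approx(ss_total, rel=1e-9)
    assert tab.term("group")["SS"] == pytest.approx(ss_between, rel=1e-9)
    assert tab.table.loc["Residual", "SS"] == pytest.approx(ss_within, rel=1e-9)
    f_classic = (ss_between / 1) / (ss_within / 4)
    assert tab.term("group")["F"] == pytest.approx(f_classic, rel=1e-9)


def test_pvalue_floor_and_bounds():
    rng = np.random.default_rng(0)
    pts = np.concatenate([rng.normal(0, 0.01, 12), rng.normal(1, 0.01, 12)])
    dm = euclid_dm(pts)
    meta = meta_for(dm.sample_ids, group=["a"] * 12 + ["b"] * 12)
    tab = permanova(dm, meta, ["group"], n_permutations=999, seed=5)
    p = tab.term("group")["p"]
    assert p == pytest.approx(1.0 / (999 + 1))
    assert p >= 1.0 / (999 + 1)


def test_strata_restricts_permutations():
    strata = np.array(["p1", "p1", "p2", "p2", "p3", "p3"])
    perms = _permutations(6, 200, np.random.default_rng(0), strata)
    for p in perms:
        assert (strata[p] == strata).all()  # never crosses a stratum


def test_sample_order_invariance():
    rng = np.random.default_rng(8)
    pts = rng.random(12)
    dm = euclid_dm(pts)
    organ = [["leaf", "seed"][i % 2] for i in range(12)]
    meta = meta_for(dm.sample_ids, group=organ)
    tab = permanova(dm, meta, ["group"], n_permutations=199, seed=2)
    order = rng.permutation(12)
    ids2 = [dm.sample_ids[i] for i in order]
    dm2 = dm.subset(ids2)
    tab2 = permanova(dm2, meta.loc[ids2], ["group"], n_permutations=199, seed=2)
    assert tab2.term("group")["F"] == pytest.approx(tab.term("group")["F"])
    assert tab2.term("group")["SS"] == pytest.approx(tab.term("group")["SS"])


def test_strata_same_as_term_rejected():
    dm = euclid_dm(np.arange(4) / 3)
    meta = meta_for(dm.sample_ids, group=["a", "a", "b", "b"])
    with pytest.raises(ValueError, match="strata"):
        permanova(dm, meta, ["group"], strata="group")


# ------------------------------------------------------------- pairwise

def test_pairwise_count_and_holm():
    rng = np.random.default_rng(1)
    pts = rng.random(16)
    dm = euclid_dm(pts)
    organ = ["leaf", "seed", "unripe_pulp", "ripe_pulp"] * 4
    meta = meta_for(dm.sample_ids, organ=organ)
    tables, summary = pairwise_permanova(dm, meta, "organ",
                                         n_permutations=99, seed=0)
    assert len(tables) == 6  # C(4, 2)
    assert (summary["p_adjusted"] >= summary["p_raw"] - 1e-12).all()


def test_holm_hand_computation():
    from statsmodels.stats.multitest import multipletests
    adj = multipletests([0.01, 0.02, 0.04], method="holm")[1]
    np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])


# ------------------------------------------------------------- dispersion

def test_dispersion_hand_distances():
    """group1 = {0, 2}, group2 = {0, 6} on a line: centroids 1 and 3."""
    pts = np.array([0.0, 2.0, 0.0, 6.0]) / 6.0
    dm = euclid_dm(pts)
    meta = meta_for(dm.sample_ids, group=["g1", "g1", "g2", "g2"])
    res = dispersion(dm, meta, "group", n_permutations=99, seed=0)
    assert res.group_means["g1"] == pytest.approx(1.0 / 6.0, abs=1e-9)
    assert res.group_means["g2"] == pytest.approx(3.0 / 6.0, abs=1e-9)


def test_dispersion_translation_invariance():
    rng = np.random.default_rng(5)
    pts = rng.random((10, 2))
    meta_groups = ["a"] * 5 + ["b"] * 5
    d1 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    shifted = np.hstack([pts, np.full((10, 1), 3.0)])  # constant new axis
    d2 = np.sqrt(((shifted[:, None] - shifted[None, :]) ** 2).sum(-1))
    scale = max(d1.max(), d2.max())
    ids = [f"s{i}" for i in range(10)]
    meta = meta_for(ids, group=meta_groups)
    r1 = dispersion(DistanceMatrix(ids, d1 / scale), meta, "group",
                    n_permutations=49, seed=0)
    r2 = dispersion(DistanceMatrix(ids, d2 / scale), meta, "group",
                    n_permutations=49, seed=0)
    np.testing.assert_allclose(r1.distances, r2.distances, atol=1e-9)


def test_dispersion_single_sample_group_errors():
    dm = euclid_dm(np.arange(3) / 2)
    meta = meta_for(dm.sample_ids, group=["a", "a", "b"])
    with pytest.raises(ValueError, match="single sample"):
        dispersion(dm, meta, "group")


# -------------------------------------------------------- compact letters

def test_letters_all_significant():
    groups = ["g1", "g2", "g3", "g4"]
    sig = {(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]}
    letters = compact_letter_display(groups, sig)
    assert len(set(letters.values())) == 4


def test_letters_none_significant():
    letters = compact_letter_display(["g1", "g2", "g3"], set())
    assert set(letters.values()) == {"a"}


def test_letters_chain_case():
    letters = compact_letter_display(["a", "b", "c"], {("a", "c")})
    assert letters == {"a": "a", "b": "ab", "c": "b"}


# --------------------------------------------------- variance partition

def test_species_explains_everything():
    d = np.ones((8, 8)) - np.eye(8)
    d[np.ix_(range(4), range(4))] = 0.0
    d[np.ix_(range(4, 8), range(4, 8))] = 0.0
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i}" for i in range(8)]
    dm = DistanceMatrix(ids, d)
    meta = meta_for(ids, species=["spA"] * 4 + ["spB"] * 4, organ=["leaf"] * 8)
    out = variance_partition(dm, meta, n_permutations=99, seed=0)
    assert out[0].eta2_species == pytest.approx(1.0, abs=1e-9)
    assert out[0].eta2_species + out[0].eta2_residual == pytest.approx(1.0)


def test_shuffled_labels_null_eta2():
    """Random labels: E[eta2] ~ (k-1)/(n-1)."""
    rng = np.random.default_rng(6)
    n, k = 24, 3
    vals = []
    for _ in range(60):
        pts = rng.random(n)
        dm = euclid_dm(pts)
        meta = meta_for(dm.sample_ids,
                        species=rng.permutation([f"sp{i % k}" for i in range(n)]),
                        organ=["leaf"] * n)
        out = variance_partition(dm, meta, n_permutations=9, seed=1)
        vals.append(out[0].eta2_species)
    assert np.mean(vals) == pytest.approx((k - 1) / (n - 1), abs=0.03)
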