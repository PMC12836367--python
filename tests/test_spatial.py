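import numpy as np
import pandas as pd
import pytest

import tmescope as tm
from tmescope.spatial import SpatialDataset, knn_mean, perinecrotic_split


def make_dataset(coords, necrotic, expr=None, weights=None):
    n = len(coords)
    ids = pd.Index([f"spot_{i:04d}" for i in range(n)], name="spot")
    spots = pd.DataFrame(coords, columns=["x", "y"], index=ids)
    if expr is None:
        expr = pd.DataFrame({"LIG": np.zeros(n), "REC": np.zeros(n)}, index=ids)
    else:
        expr = pd.DataFrame(expr, index=ids)
    if weights is None:
        weights = pd.DataFrame({"ct": np.ones(n)}, index=ids)
    else:
        weights = pd.DataFrame(weights, index=ids)
    weights = weights.div(weights.sum(axis=1), axis=0)
    return SpatialDataset(
        spots=spots,
        necrotic=pd.Series(np.asarray(necrotic, bool), index=ids),
        expression=expr,
        weights=weights,
    )


def test_distance_to_necrosis_basic_and_brute_force(rng):
    d = make_dataset([(0, 0), (3, 4), (1, 0)], [True, False, False])
    dist = tm.distance_to_necrosis(d)
    assert dist.iloc[0] == pytest.approx(5.0)  # 3-4-5 triangle
    assert dist.iloc[1] == pytest.approx(1.0)  # adjacent on the unit grid

    coords = rng.uniform(0, 30, size=(200, 2))
    nec = np.zeros(200, bool)
    nec[rng.choice(200, 12, replace=False)] = True
    big = make_dataset(coords, nec)
    dist = tm.distance_to_necrosis(big)
    for i, sid in enumerate(big.spots.index[~nec]):
        manual = min(
            np.hypot(*(coords[~nec][i] - nc)) for nc in coords[nec]
        )
        assert dist[sid] == pytest.approx(manual, abs=1e-10)

    with pytest.raises(ValueError, match="no necrotic"):
        tm.distance_to_necrosis(make_dataset([(0, 0), (1, 1)], [False, False]))


def test_stratify_equal_count_regions(rng):
    dist = pd.Series(rng.permutation(100).astype(float),
                     index=[f"spot_{i:04d}" for i in range(100)])
    strata = tm.stratify(dist, n_regions=10)
    sizes = strata.labels.value_counts()
    assert (sizes == 10).all()
    # region 1 holds the ten smallest distances
    assert set(dist[strata.labels.index[strata.labels == 1]]) == set(range(10))
    one = tm.stratify(dist, n_regions=1)
    assert (one.labels == 1).all()


def test_stratify_ties_match_sort_then_chunk_reference(rng):
    vals = rng.integers(0, 5, 40).astype(float)  # heavy ties
    ids = [f"spot_{i:04d}" for i in range(40)]
    dist = pd.Series(vals, index=ids)
    strata = tm.stratify(dist, n_regions=4)
    order = sorted(ids, key=lambda s: (dist[s], s))
    expected = {}
    for r, chunk in enumerate(np.array_split(order, 4)):
        for sid in chunk:
            expected[sid] = r + 1
    assert strata.labels.to_dict() == expected
    # strata partition the spots
    assert sorted(strata.labels.index) == sorted(ids)


def test_high_infiltration_profile_decay_and_constant():
    # 100 spots on a line, necrotic at x<0 side; weight decays with distance
    coords = [(float(i), 0.0) for i in range(-1, 99)]
    nec = [True] + [False] * 99
    w = np.exp(-np.arange(-1, 99) / 20.0)
    d = make_dataset(coords, nec, weights={"ct": w, "other": np.ones(100)})
    dist = tm.distance_to_necrosis(d)
    strata = tm.stratify(dist, n_regions=10)
    prof = tm.high_infiltration_profile(d, strata, "ct")
    vals = prof.loc[1:5].to_numpy()
    assert np.all(np.diff(vals) <= 0)
    assert vals[0] == 1.0
    assert np.allclose(prof.loc[6:].to_numpy(), 0.0)
    # constant weights: nothing is strictly above the median
    dc = make_dataset(coords, nec)
    assert (tm.high_infiltration_profile(dc, strata, "ct") == 0).all()


def test_smooth_expression_constant_impulse_and_variance(rng):
    coords = [(float(i % 10), float(i // 10)) for i in range(100)]
    const = make_dataset(coords, [True] + [False] * 99,
                         expr={"LIG": np.full(100, 3.3), "REC": np.zeros(100)})
    sm = tm.smooth_expression(const, k=6)
    assert np.allclose(sm["LIG"], 3.3)
    impulse = np.zeros(100)
    impulse[55] = 7.0
    di = make_dataset(coords, [True] + [False] * 99, expr={"LIG": impulse})
    assert tm.smooth_expression(di, k=6)["LIG"].iloc[55] == pytest.approx(7.0 / 7)
    noisy = rng.normal(size=100)
    dn = make_dataset(coords, [True] + [False] * 99, expr={"LIG": noisy})
    assert tm.smooth_expression(dn, k=6)["LIG"].var() < np.var(noisy)


def test_niche_ligand_mean_of_neighbors(rng):
    # star layout: 20 spots at distance 1 with ligand 2, one far spot
    coords = [(0.0, 0.0)] + [
        (np.cos(a), np.sin(a)) for a in np.linspace(0, 2 * np.pi, 20, endpoint=False)
    ] + [(50.0, 50.0)]
    lig = np.array([9.0] + [2.0] * 20 + [4.0])
    d = make_dataset(coords, [False] * 22, expr={"LIG": lig})
    niche = tm.niche_ligand(d, "LIG", k=20)
    assert niche.iloc[0] == pytest.approx(2.0)
    # k = n-1 gives the leave-one-out global mean
    loo = tm.niche_ligand(d, "LIG", k=21)
    manual = (lig.sum() - lig) / 21
    assert np.allclose(loo.to_numpy(), manual)
    with pytest.raises(ValueError, match="more than k"):
        tm.niche_ligand(d, "LIG", k=22)


def test_niche_matches_exhaustive_distance_sort(rng):
    coords = rng.uniform(0, 20, size=(60, 2))
    vals = rng.normal(size=60)
    got = knn_mean(coords, vals, k=7)
    for i in range(60):
        dist = np.hypot(*(coords - coords[i]).T)
        order = np.argsort(dist, kind="stable")
        nbrs = [j for j in order if j != i][:7]
        assert got[i] == pytest.approx(vals[nbrs].mean(), abs=1e-10)


def test_adjusted_r2_values(rng):
    x = np.arange(10, dtype=float)
    assert tm.adjusted_r2(2 * x + 1, x) == pytest.approx(1.0)
    # closed form for (0,0), (1,1), (2,1): R^2 = 0.75, adjusted = 0.5
    assert tm.adjusted_r2([0.0, 1.0, 1.0], [0.0, 1.0, 2.0]) == pytest.approx(0.5)
    assert np.isnan(tm.adjusted_r2([1.0, 2.0], [0.0, 1.0]))
    assert np.isnan(tm.adjusted_r2(rng.normal(size=5), np.ones(5)))
    big = rng.normal(size=(2, 2000))
    assert abs(tm.adjusted_r2(big[0], big[1])) < 0.05


def test_perinecrotic_split_takes_ceiling_half():
    coords = [(0.0, 0.0)] + [(float(i), 0.0) for i in range(1, 6)]  # 5 non-necrotic
    d = make_dataset(coords, [True] + [False] * 5)
    peri, distant = perinecrotic_split(d)
    assert len(peri) == 3 and len(distant) == 2
    assert set(peri) == {"spot_0001", "spot_0002", "spot_0003"}


def test_region_contrast_recovers_planted_perinecrotic_coupling():
    d = tm.simulate_spatial(tm.SpatialSimConfig(seed=5))
    r2_peri, r2_dist = tm.region_contrast(d, "LIG", "REC")
    assert r2_peri > 0.9 > r2_dist


def test_distance_outputs_invariant_to_rigid_motions(rng):
    coords = rng.uniform(0, 15, size=(80, 2))
    nec = np.zeros(80, bool)
    nec[:6] = True
    base = make_dataset(coords, nec)
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = make_dataset(coords @ rot.T + np.array([100.0, -40.0]), nec)
    d1 = tm.distance_to_necrosis(base)
    d2 = tm.distance_to_necrosis(moved)
    assert np.allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-9)
    s1 = tm.stratify(d1, 8).labels
    s2 = tm.stratify(d2, 8).labels
    assert (s1 == s2).all()
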