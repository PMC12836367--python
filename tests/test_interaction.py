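import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tmescope as tm
from tmescope.preprocess import PseudobulkTensor


def tensor_from_array(values: np.ndarray, samples, cell_types, population="myeloid"):
    """genes x (samples * cell_types) array -> single-population tensor."""
    n_genes = values.shape[0]
    cols = pd.MultiIndex.from_tuples(
        [(s, population, ct) for s in samples for ct in cell_types],
        names=["sample", "population", "cell_type"],
    )
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    return PseudobulkTensor(
        values=df, cell_counts=pd.Series(10, index=cols)
    )


def test_minmax_maps_span_to_unit_interval_and_constants_to_zero():
    vals = np.array([[2.0, 5.0, 8.0], [4.0, 4.0, 4.0]])
    t = tensor_from_array(vals, samples=["s1"], cell_types=["a", "b", "c"])
    norm = tm.minmax_normalize(t)
    assert np.allclose(norm.values.to_numpy()[0], [0.0, 0.5, 1.0])
    assert np.allclose(norm.values.to_numpy()[1], [0.0, 0.0, 0.0])


def test_minmax_matches_per_gene_loop(rng):
    vals = rng.uniform(0, 12, size=(8, 4 * 3))
    t = tensor_from_array(vals, samples=list("wxyz"), cell_types=["a", "b", "c"])
    norm = tm.minmax_normalize(t).values.to_numpy()
    for g in range(8):
        for si in range(4):
            block = vals[g, si * 3 : (si + 1) * 3]
            lo, hi = block.min(), block.max()
            expected = (block - lo) / (hi - lo) if hi > lo else np.zeros(3)
            assert np.allclose(norm[g, si * 3 : (si + 1) * 3], expected, atol=1e-12)


def test_minmax_requires_at_least_two_cell_types():
    t = tensor_from_array(np.ones((3, 1)), samples=["s1"], cell_types=["only"])
    with pytest.raises(ValueError, match="single cell type"):
        tm.minmax_normalize(t)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    a=st.floats(0.1, 50),
    b=st.floats(-20, 20),
    seed=st.integers(0, 10_000),
)
def test_minmax_invariant_under_affine_transforms(a, b, seed):
    """x -> a*x + b with a > 0 leaves the min-max output unchanged."""
    vals = np.random.default_rng(seed).uniform(0, 9, size=(5, 3))
    t1 = tensor_from_array(vals, ["s1"], ["a", "b", "c"])
    t2 = tensor_from_array(a * vals + b, ["s1"], ["a", "b", "c"])
    assert np.allclose(
        tm.minmax_normalize(t1).values.to_numpy(),
        tm.minmax_normalize(t2).values.to_numpy(),
        atol=1e-9,
    )


def test_interaction_score_is_the_product_of_normalized_factors():
    vals = np.array(
        [[0.0, 1.0, 2.0],   # g0: normalized [0, .5, 1]
         [1.0, 6.0, 11.0]]  # g1: normalized [0, .5, 1]
    )
    t = tm.minmax_normalize(tensor_from_array(vals, ["s1"], ["a", "b", "c"]))
    assert tm.interaction_score(t, "g0", "c", "g1", "c", "s1") == 1.0
    assert tm.interaction_score(t, "g0", "b", "g1", "b", "s1") == pytest.approx(0.25)
    # ligand at the minimum-expressing cell type kills the product
    assert tm.interaction_score(t, "g0", "a", "g1", "c", "s1") == 0.0
    with pytest.raises(KeyError):
        tm.interaction_score(t, "absent", "a", "g1", "c", "s1")


def exact_rank_sum_p(x, y):
    """Two-sided Wilcoxon p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(xi > yj for xi in x for yj in y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        g1 = pooled[list(comb)]
        g2 = np.delete(pooled, list(comb))
        us.append(sum(a > b for a in g1 for b in g2))
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lo, hi))


def test_group_difference_statistics():
    wt = pd.Series({f"w{i}": v for i, v in enumerate([0.9, 0.8, 0.7])})
    mut = pd.Series({f"m{i}": v for i, v in enumerate([0.1, 0.2, 0.3])})
    scores = pd.concat([wt, mut])
    groups = pd.Series({**{k: "WT" for k in wt.index}, **{k: "MUT" for k in mut.index}})
    es, p = tm.test_group_difference(scores, groups)
    assert es == pytest.approx(0.6)
    assert p == pytest.approx(exact_rank_sum_p(wt.to_numpy(), mut.to_numpy()))
    assert p == pytest.approx(0.1)
    # identical vectors: zero enrichment, p = 1 under the tie convention
    same = pd.Series(0.5, index=scores.index)
    es0, p0 = tm.test_group_difference(same, groups)
    assert es0 == 0.0 and p0 == 1.0


def test_group_label_swap_negates_enrichment_and_keeps_p(rng):
    scores = pd.Series(rng.uniform(0, 1, 12), index=[f"s{i}" for i in range(12)])
    groups = pd.Series(["WT"] * 6 + ["MUT"] * 6, index=scores.index)
    swapped = groups.map({"WT": "MUT", "MUT": "WT"})
    es1, p1 = tm.test_group_difference(scores, groups)
    es2, p2 = tm.test_group_difference(scores, swapped)
    assert es1 == pytest.approx(-es2)
    assert p1 == pytest.approx(p2)


def test_small_group_flagged_missing():
    scores = pd.Series([0.1, 0.4, 0.5], index=["a", "b", "c"])
    groups = pd.Series({"a": "WT", "b": "MUT", "c": "MUT"})
    with pytest.warns(UserWarning, match="<2 samples"):
        es, p = tm.test_group_difference(scores, groups)
    assert np.isnan(p) and es == pytest.approx(0.1 - 0.45)


def test_bh_adjust_examples():
    assert np.allclose(
        tm.bh_adjust([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
    )
    assert tm.bh_adjust([0.123]) == pytest.approx([0.123])
    assert np.allclose(tm.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


def test_cross_sample_correlation_definition(rng):
    samples = [f"s{i}" for i in range(8)]
    cols = pd.MultiIndex.from_tuples(
        [(s, "myeloid", ct) for s in samples for ct in ["a", "b"]],
        names=["sample", "population", "cell_type"],
    )
    vals = rng.uniform(0, 10, size=(4, len(cols)))
    # g0 in 'a' perfectly monotone with g1 in 'b'
    base = np.arange(8, dtype=float)
    for si, s in enumerate(samples):
        vals[0, 2 * si] = base[si]
        vals[1, 2 * si + 1] = base[si] ** 2 + 1
    vals[3, :] = 7.0  # constant gene
    t = PseudobulkTensor(
        values=pd.DataFrame(vals, index=["g0", "g1", "g2", "g3"], columns=cols),
        cell_counts=pd.Series(5, index=cols),
    )
    pairs = pd.DataFrame(
        {"ligand": ["g0", "g2", "g3"], "receptor": ["g1", "g1", "g1"]}
    )
    with pytest.warns(UserWarning, match="constant vector"):
        rho = tm.cross_sample_correlation(t, pairs, "a", "b")
    assert rho[("g0", "g1")] == pytest.approx(1.0)
    assert np.isnan(rho[("g3", "g1")])
    # definitional check: rank-transform then Pearson
    lig = vals[2, 0::2]
    rec = vals[1, 1::2]
    rl = pd.Series(lig).rank().to_numpy()
    rr = pd.Series(rec).rank().to_numpy()
    manual = np.corrcoef(rl, rr)[0, 1]
    assert rho[("g2", "g1")] == pytest.approx(manual, abs=1e-12)


def test_interaction_table_end_to_end(small_cohort):
    tensor = tm.pseudobulk(small_cohort)
    norm = tm.minmax_normalize(tensor)
    pairs = pd.DataFrame(
        {
            "ligand": ["G0001", "G0002", "MISSING"],
            "receptor": ["G0003", "G0004", "G0001"],
            "cell_a": ["myeloid_1", "myeloid_2", "myeloid_1"],
            "cell_b": ["tumor_1", "T_1", "tumor_1"],
        }
    )
    groups = (
        small_cohort.obs.drop_duplicates("sample").set_index("sample")["condition"]
    )
    with pytest.warns(UserWarning, match="skipping pair"):
        table = tm.build_interaction_table(norm, pairs, groups)
    assert len(table) == 2
    nis_cols = [c for c in table.columns if c.startswith("nis_")]
    nis = table[nis_cols].to_numpy()
    assert ((nis >= 0) & (nis <= 1) | np.isnan(nis)).all()
    assert table["enrichment_score"].between(-1, 1).all()
    assert ((table["fdr"] >= 0) & (table["fdr"] <= 1)).all()
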