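"""Expression calls, PO attribution, smoothing, two-tier clustering."""

import numpy as np
import pandas as pd
import pytest

from famscan import syndata
from famscan.atlas import (
    ExpressionAtlas,
    attribute_po,
    average_replicates,
    call_expression,
    collapse_redundant_conditions,
    dendrogram_newick,
    group_coexpressed,
    pearson_distance,
    smooth_background,
)


def _atlas(values: dict[str, list], kinds: dict[str, str], genes=None, po=None):
    df = pd.DataFrame(values, index=genes or [f"g{i}" for i in range(len(next(iter(values.values()))))])
    return ExpressionAtlas(df, {c: "p1" for c in df.columns}, kinds, po or {})


def test_replicate_mean():
    mat = pd.DataFrame({"s1": [6.0], "s2": [8.0], "s3": [10.0], "t1": [3.0]}, index=["g"])
    smap = pd.DataFrame(
        {"sample": ["s1", "s2", "s3", "t1"], "condition": ["c1", "c1", "c1", "c2"]}
    )
    out = average_replicates(mat, smap)
    assert out.loc["g", "c1"] == 8.0
    assert out.loc["g", "c2"] == 3.0  # single replicate unchanged


def test_replicate_means_match_groupby_oracle():
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(rng.normal(8, 2, size=(5, 12)), columns=[f"s{i}" for i in range(12)])
    smap = pd.DataFrame({"sample": mat.columns, "condition": [f"c{i % 4}" for i in range(12)]})
    out = average_replicates(mat, smap)
    for cond in out.columns:
        cols = [s for s, c in zip(smap["sample"], smap["condition"]) if c == cond]
        assert np.allclose(out[cond], mat[cols].to_numpy().mean(axis=1))


@pytest.mark.parametrize(
    "value,kind,call",
    [
        (8.1, "array", "expressed"),
        (8.0, "array", "detected"),  # 'higher than 8' is strict
        (5.0, "array", "detected"),
        (4.99, "array", "background"),
        (10, "count", "expressed"),  # 'at least 10' is inclusive
        (9, "count", "detected"),
        (1, "count", "detected"),
        (0, "count", "background"),
    ],
)
def test_call_thresholds(value, kind, call):
    atlas = _atlas({"c": [value]}, {"c": kind}, genes=["g"])
    calls, _ = call_expression(atlas)
    assert calls.loc["g", "c"] == call


def test_calls_partition_cells():
    rng = np.random.default_rng(1)
    atlas = _atlas(
        {"a": rng.uniform(0, 14, 20), "b": rng.integers(0, 40, 20)},
        {"a": "array", "b": "count"},
        genes=[f"g{i}" for i in range(20)],
    )
    calls, _ = call_expression(atlas)
    assert calls.isin(["background", "detected", "expressed"]).all().all()


def test_gene_status_vocabulary():
    atlas = _atlas(
        {"c1": [9.0, 6.0, 2.0], "c2": [2.0, 6.5, 1.0]},
        {"c1": "array", "c2": "array"},
        genes=["expressed_gene", "putative_gene", "silent_gene"],
    )
    _, status = call_expression(atlas)
    assert status["expressed_gene"] == "gene"
    assert status["putative_gene"] == "putative"
    assert status["silent_gene"] == "hypothetical"


def test_all_zero_counts_gene_is_hypothetical():
    atlas = _atlas({"c1": [0], "c2": [0]}, {"c1": "count", "c2": "count"}, genes=["g"])
    _, status = call_expression(atlas)
    assert status["g"] == "hypothetical"


def test_po_attribution_union_of_expressed_conditions():
    atlas = _atlas(
        {"leaf1": [9.0, 2.0], "leaf2": [8.5, 2.0], "seed1": [2.0, 2.0]},
        {"leaf1": "array", "leaf2": "array", "seed1": "array"},
        genes=["g1", "g2"],
        po={"leaf1": "PO:leaf", "leaf2": "PO:leaf", "seed1": "PO:seed"},
    )
    po = attribute_po(atlas)
    assert po["g1"] == {"PO:leaf"}
    assert po["g2"] == set()  # expressed nowhere


def test_po_matches_threshold_oracle_on_random_atlas():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(8)]
    conds = {f"c{j}": rng.uniform(0, 14, 8) for j in range(6)}
    po_map = {f"c{j}": f"PO:{j % 3}" for j in range(6)}
    atlas = _atlas(conds, {c: "array" for c in conds}, genes=genes, po=po_map)
    po = attribute_po(atlas)
    for i, g in enumerate(genes):
        oracle = {po_map[c] for c, vals in conds.items() if vals[i] > 8.0}
        assert po[g] == oracle


def test_smoothing_floor_and_idempotence():
    atlas = _atlas({"c": [3.2, 5.0, 7.0]}, {"c": "array"}, genes=["a", "b", "c"])
    sm = smooth_background(atlas)
    assert list(sm.values["c"]) == [5.0, 5.0, 7.0]
    assert atlas.values.loc["a", "c"] == 3.2  # original untouched
    again = smooth_background(sm)
    assert (again.values == sm.values).all().all()


def test_counts_enter_clustering_as_log2():
    atlas = _atlas({"c": [0, 63]}, {"c": "count"}, genes=["a", "b"])
    sm = smooth_background(atlas)
    assert sm.values.loc["a", "c"] == 5.0  # log2(1) floored to 5
    assert sm.values.loc["b", "c"] == 6.0  # log2(64)


# ---------------------------------------------------------------------------
# condition collapse


def _conditions_with_correlation(r, n=40, seed=0):
    """Two unit-variance condition profiles with Pearson correlation ~ r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    y -= y.dot(x) / x.dot(x) * x  # orthogonalize
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    z = r * x + np.sqrt(1 - r * r) * y
    return 8 + x, 8 + z


def test_identical_conditions_merge():
    prof = np.array([6.0, 9.0, 7.0, 8.0])
    atlas = _atlas(
        {"c1": prof, "c2": prof, "c3": prof[::-1]},
        {"c1": "array", "c2": "array", "c3": "array"},
        genes=[f"g{i}" for i in range(4)],
    )
    collapsed = collapse_redundant_conditions(atlas)
    assert collapsed.values.shape[1] == 2
    assert "c1|c2" in collapsed.values.columns


def test_collapse_boundary_strictness():
    """d = 0.04 (r = 0.96) merges; d = 0.06 (r = 0.94) does not."""
    for r, merged in ((0.96, True), (0.94, False)):
        a, b = _conditions_with_correlation(r)
        atlas = _atlas({"c1": a, "c2": b}, {"c1": "array", "c2": "array"}, genes=[f"g{i}" for i in range(len(a))])
        collapsed = collapse_redundant_conditions(atlas, 0.05)
        assert (collapsed.values.shape[1] == 1) is merged


def test_collapse_restricted_within_platform():
    prof = np.array([6.0, 9.0, 7.0, 8.0])
    atlas = ExpressionAtlas(
        pd.DataFrame({"c1": prof, "c2": prof}, index=[f"g{i}" for i in range(4)]),
        {"c1": "p1", "c2": "p2"},
        {"c1": "array", "c2": "array"},
    )
    collapsed = collapse_redundant_conditions(atlas)
    assert collapsed.values.shape[1] == 2  # identical but on different platforms


def test_collapse_matches_exhaustive_average_linkage_oracle():
    """On <= 10 conditions the collapsed partition equals a brute-force
    agglomerative clustering with the same metric and linkage."""
    rng = np.random.default_rng(3)
    n_genes, n_cond = 12, 8
    mat = rng.uniform(5, 12, size=(n_genes, n_cond))
    mat[:, 1] = mat[:, 0] + rng.normal(0, 0.01, n_genes)
    mat[:, 5] = mat[:, 4]
    conds = [f"c{j}" for j in range(n_cond)]
    atlas = _atlas(
        {c: mat[:, j] for j, c in enumerate(conds)},
        {c: "array" for c in conds},
        genes=[f"g{i}" for i in range(n_genes)],
    )
    collapsed = collapse_redundant_conditions(atlas, 0.05)

    # brute-force agglomerative average linkage on the full distance matrix
    d = pearson_distance(mat.T)
    clusters = [[j] for j in range(n_cond)]
    while True:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                link = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or link < best[0]:
                    best = (link, i, j)
        if best is None or best[0] >= 0.05:
            break
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    oracle = {frozenset(c) for c in clusters}
    got = set()
    for name in collapsed.values.columns:
        got.add(frozenset(conds.index(c) for c in name.split("|")))
    assert got == oracle


def test_zero_variance_condition_stays_singleton():
    atlas = _atlas(
        {"flat1": [5.0] * 4, "flat2": [5.0] * 4, "var": [5.0, 9.0, 6.0, 8.0]},
        {"flat1": "array", "flat2": "array", "var": "array"},
        genes=[f"g{i}" for i in range(4)],
    )
    collapsed = collapse_redundant_conditions(atlas)
    assert collapsed.values.shape[1] == 3


# ---------------------------------------------------------------------------
# gene grouping


def test_planted_triple_groups_at_zero_noise():
    rng = np.random.default_rng(4)
    prof = rng.uniform(5, 12, 10)
    other = rng.uniform(5, 12, 10)
    values = {f"c{j}": [prof[j], prof[j] + 1, prof[j] * 1.5, other[j]] for j in range(10)}
    atlas = _atlas(values, {f"c{j}": "array" for j in range(10)}, genes=["a", "b", "c", "x"])
    result = group_coexpressed(atlas, 0.15)
    assert frozenset({"a", "b", "c"}) in result.groups
    assert frozenset({"x"}) in result.groups


def test_independent_genes_mostly_singletons():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(10)]
    values = {f"c{j}": rng.uniform(5, 12, 10) for j in range(30)}
    atlas = _atlas(values, {f"c{j}": "array" for j in range(30)}, genes=genes)
    result = group_coexpressed(atlas, 0.15)
    assert sum(1 for g in result.groups if len(g) == 1) >= 9


def test_condition_order_permutation_invariance():
    expr = syndata.generate_expression(syndata.ExpressionConfig(seed=6, noise_sd=0.1))
    mat = expr.matrices["nimblegen"]
    sub = expr.sample_map[expr.sample_map["platform"] == "nimblegen"]
    avg = average_replicates(mat, sub)
    kinds = {c: "array" for c in avg.columns}
    plat = {c: "nimblegen" for c in avg.columns}
    a1 = ExpressionAtlas(avg, plat, kinds)
    perm = list(avg.columns)[::-1]
    a2 = ExpressionAtlas(avg[perm], plat, kinds)
    g1 = group_coexpressed(collapse_redundant_conditions(smooth_background(a1)))
    g2 = group_coexpressed(collapse_redundant_conditions(smooth_background(a2)))
    assert set(g1.groups) == set(g2.groups)


def test_truth_recovery_rand_index(small_genome):
    from sklearn.metrics import rand_score

    expr = syndata.generate_expression(syndata.ExpressionConfig(seed=7, noise_sd=0.0))
    kind = dict(expr.config.platforms)
    tabs, plat, kinds = [], {}, {}
    for pname, mat in expr.matrices.items():
        sub = expr.sample_map[expr.sample_map["platform"] == pname]
        avg = average_replicates(mat, sub)
        tabs.append(avg)
        plat.update({c: pname for c in avg.columns})
        kinds.update({c: kind[pname] for c in avg.columns})
    atlas = ExpressionAtlas(pd.concat(tabs, axis=1), plat, kinds)
    result = group_coexpressed(collapse_redundant_conditions(smooth_background(atlas)))
    truth_label = {g: i for i, grp in enumerate(expr.truth.coexpr_groups) for g in grp}
    pred = result.group_of()
    genes = result.gene_ids
    assert rand_score([truth_label[g] for g in genes], [pred[g] for g in genes]) == 1.0


def test_pearson_distance_axioms():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(6, 15))
    d = pearson_distance(x)
    assert np.allclose(np.diag(d), 0.0)
    assert (d >= 0).all() and (d <= 2).all()
    assert np.allclose(d, d.T)


def test_dendrogram_newick_contains_all_genes():
    rng = np.random.default_rng(9)
    atlas = _atlas(
        {f"c{j}": rng.uniform(5, 12, 5) for j in range(8)},
        {f"c{j}": "array" for j in range(8)},
        genes=[f"g{i}" for i in range(5)],
    )
    result = group_coexpressed(atlas)
    nwk = dendrogram_newick(result)
    assert nwk.endswith(";") and all(g in nwk for g in result.gene_ids)
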