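"""UPGMA clustering against a brute-force oracle, planted-structure
recovery, fold changes and group mean intensities."""

import numpy as np
import pandas as pd
import pytest

from confinetrack import (ProteinMatrix, group_fold_change,
                          group_mean_intensity, hierarchical_cluster,
                          simulate_protein_matrix)


def brute_force_upgma(X):
    """Naive UPGMA on rows of X: merge the closest pair of clusters under
    the average of all between-member Euclidean distances, smallest
    indices first on ties.  Returns [(leafset_a, leafset_b, height)]."""
    n = len(X)
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or avg < best[0] - 1e-12:
                    best = (avg, i, j)
        avg, i, j = best
        merges.append((clusters[i], clusters[j], avg))
        clusters = ([c for k, c in enumerate(clusters) if k not in (i, j)]
                    + [clusters[i] | clusters[j]])
    return merges


def linkage_to_leafsets(Z, n):
    """SciPy linkage matrix -> [(leafset_a, leafset_b, height)]."""
    sets = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, h, _) in enumerate(Z):
        sa, sb = sets[int(a)], sets[int(b)]
        out.append((sa, sb, h))
        sets[n + k] = sa | sb
    return out


def make_matrix(X, group_of=None):
    samples = [f"s{i}" for i in range(X.shape[0])]
    data = pd.DataFrame(X.T, columns=samples,
                        index=[f"P{j}" for j in range(X.shape[1])])
    groups = pd.Series({s: (group_of[i] if group_of else "g")
                        for i, s in enumerate(samples)})
    return ProteinMatrix(data=data, sample_groups=groups)


def test_planted_pairs_merge_first():
    rng = np.random.default_rng(10)
    base = rng.uniform(50, 100, size=8)
    X = np.stack([base, base + rng.normal(0, 0.1, 8),
                  base + 40, base + 40 + rng.normal(0, 0.1, 8)])
    dend = hierarchical_cluster(make_matrix(X))
    first_two = [frozenset(map(int, row[:2])) for row in dend.linkage[:2]]
    assert frozenset([0, 1]) in first_two and frozenset([2, 3]) in first_two


def test_duplicate_samples_merge_at_zero():
    X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
    dend = hierarchical_cluster(make_matrix(X))
    assert dend.linkage[0, 2] == 0.0
    assert set(dend.linkage[0, :2].astype(int)) == {0, 1}


@pytest.mark.parametrize("n_samples", [5, 6, 7])
def test_upgma_matches_brute_force(n_samples):
    rng = np.random.default_rng(n_samples)
    X = rng.uniform(1, 100, size=(n_samples, 10))
    dend = hierarchical_cluster(make_matrix(X))
    got = linkage_to_leafsets(dend.linkage, n_samples)
    expect = brute_force_upgma(X)
    for (ga, gb, gh), (ea, eb, eh) in zip(got, expect):
        assert {ga, gb} == {ea, eb}
        assert gh == pytest.approx(eh)


def test_merge_heights_monotone_nondecreasing():
    rng = np.random.default_rng(2)
    X = rng.lognormal(8, 1, size=(9, 30))
    dend = hierarchical_cluster(make_matrix(X))
    heights = dend.merge_heights()
    assert np.all(np.diff(heights) >= -1e-9)


def test_column_permutation_invariance():
    rng = np.random.default_rng(3)
    X = rng.uniform(1, 50, size=(6, 12))
    d1 = hierarchical_cluster(make_matrix(X))
    perm = [3, 0, 5, 1, 4, 2]
    d2 = hierarchical_cluster(make_matrix(X[perm]))
    s1 = {frozenset({frozenset(a), frozenset(b)}) for a, b, _ in
          linkage_to_leafsets(d1.linkage, 6)}
    inv = {v: k for k, v in enumerate(perm)}
    s2 = set()
    for a, b, _ in linkage_to_leafsets(d2.linkage, 6):
        s2.add(frozenset({frozenset(perm[i] for i in a),
                          frozenset(perm[i] for i in b)}))
    assert {frozenset({a, b}) for fs in s1 for a, b in [tuple(fs)]} \
        == {frozenset({a, b}) for fs in s2 for a, b in [tuple(fs)]}
    assert np.allclose(sorted(d1.merge_heights()), sorted(d2.merge_heights()))


def test_motility_subset_and_rejection():
    matrix = simulate_protein_matrix(n_proteins=60, n_motility=10, seed=1)
    dend = hierarchical_cluster(matrix, subset="motility")
    assert len(dend.labels) == 8
    empty = ProteinMatrix(data=matrix.data, sample_groups=matrix.sample_groups)
    with pytest.raises(ValueError, match="zero proteins"):
        hierarchical_cluster(empty, subset="motility")


def test_newick_well_formed():
    matrix = simulate_protein_matrix(n_proteins=50, n_motility=8, seed=2)
    nwk = hierarchical_cluster(matrix).to_newick()
    assert nwk.endswith(";")
    assert nwk.count("(") == nwk.count(")") == len(matrix.samples) - 1
    for s in matrix.samples:
        assert s in nwk


def test_fold_change_exact_and_identity():
    data = pd.DataFrame({"a1": [2.0, 5.0], "a2": [2.0, 5.0],
                         "b1": [1.0, 5.0], "b2": [1.0, 5.0]},
                        index=["arp", "other"])
    groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    pm = ProteinMatrix(data=data, sample_groups=groups)
    fc = group_fold_change(pm, ["arp", "other"], "A", "B")
    assert fc.loc["arp", "fold_change"] == 2.0
    assert fc.loc["other", "fold_change"] == 1.0


def test_fold_change_scale_covariance():
    matrix = simulate_protein_matrix(n_proteins=40, n_motility=6, seed=4)
    prots = matrix.data.index[:5]
    fc = group_fold_change(matrix, prots, "T-cHL", "cHL")["fold_change"]
    scaled = matrix.data.copy()
    cols = matrix.group_samples("T-cHL")
    scaled[cols] = scaled[cols] * 3.0
    pm2 = ProteinMatrix(data=scaled, sample_groups=matrix.sample_groups,
                        motility=matrix.motility)
    fc2 = group_fold_change(pm2, prots, "T-cHL", "cHL")["fold_change"]
    assert np.allclose(fc2, 3.0 * fc)


def test_planted_fold_change_recovered():
    """1.5-fold planted on flagged proteins, ±5% noise: ratios land in
    [1.4, 1.6] for at least 95% of flagged proteins."""
    matrix = simulate_protein_matrix(n_proteins=500, n_motility=80,
                                     fold=1.5, noise=0.05, seed=11)
    flagged = matrix.data.index[matrix.motility]
    fc = group_fold_change(matrix, flagged, "T-cHL", "cHL")["fold_change"]
    frac = np.mean((fc >= 1.4) & (fc <= 1.6))
    assert frac >= 0.95


def test_group_mean_intensity():
    data = pd.DataFrame({"a1": [100.0], "a2": [200.0], "b1": [400.0]},
                        index=["lmna"])
    groups = pd.Series({"a1": "A", "a2": "A", "b1": "B"})
    pm = ProteinMatrix(data=data, sample_groups=groups)
    means = group_mean_intensity(pm, "lmna")
    assert means["A"] == 150.0 and means["B"] == 400.0
    with pytest.raises(KeyError):
        group_mean_intensity(pm, "absent")


def test_planted_group_ranking_recovered():
    """A lamin-A-like protein planted lowest in one group keeps that
    ranking in the recovered group means."""
    rng = np.random.default_rng(9)
    cols, groups = {}, {}
    for g, level in (("ALK+ ALCL", 1.6e8), ("ALK- ALCL", 2.4e8),
                     ("cHL", 2.44e8), ("T-cHL", 2.6e8)):
        for r in range(2):
            name = f"{g}_{r}"
            cols[name] = [level * (1 + rng.uniform(-0.02, 0.02))]
            groups[name] = g
    pm = ProteinMatrix(data=pd.DataFrame(cols, index=["LMNA"]),
                       sample_groups=pd.Series(groups))
    means = group_mean_intensity(pm, "LMNA")
    assert means.idxmin() == "ALK+ ALCL"
    assert means.idxmax() == "T-cHL"


def test_matrix_validation():
    data = pd.DataFrame({"s1": [1.0, -2.0]}, index=["p1", "p2"])
    with pytest.raises(ValueError, match="strictly positive"):
        ProteinMatrix(data=data, sample_groups=pd.Series({"s1": "A"}))
    with pytest.raises(ValueError, match="without group"):
        ProteinMatrix(data=pd.DataFrame({"s1": [1.0]}, index=["p"]),
                      sample_groups=pd.Series(dtype=object))


def test_tsv_round_trip(tmp_path):
    matrix = simulate_protein_matrix(n_proteins=30, n_motility=5, seed=6)
    mx, ann = tmp_path / "m.tsv", tmp_path / "a.tsv"
    lst = tmp_path / "motility.txt"
    matrix.data.to_csv(mx, sep="\t")
    pd.DataFrame({"sample": matrix.samples,
                  "group": [matrix.sample_groups[s] for s in matrix.samples]}
                 ).to_csv(ann, sep="\t", index=False)
    lst.write_text("\n".join(matrix.data.index[matrix.motility]) + "\n")
    back = ProteinMatrix.from_tsv(mx, ann, lst)
    assert np.allclose(back.data.to_numpy(), matrix.data.to_numpy())
    assert (back.motility == matrix.motility).all()
    assert (back.sample_groups[back.samples] ==
            matrix.sample_groups[matrix.samples]).all()
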