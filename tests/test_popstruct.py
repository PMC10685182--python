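import numpy as np
import pandas as pd
import pytest

from strpop import popstruct, simulate
from strpop.io import AUTOSOMAL, GenotypeTable, LocusDef, Sample, StrpopError


def _bn_two_pop_table(n_loci, n_alleles, n_per_pop, F, seed):
    rng = np.random.default_rng(seed)
    panel = [LocusDef(f"L{i}", AUTOSOMAL) for i in range(n_loci)]
    anc = {
        f"L{i}": {
            str(8 + j): float(x)
            for j, x in enumerate(rng.dirichlet(np.ones(n_alleles)))
        }
        for i in range(n_loci)
    }
    model = simulate.PopulationModel(
        panel=panel,
        ancestral_freqs=anc,
        subpop_F={"a": F, "b": F},
        sex_counts={"a": (n_per_pop, 0), "b": (n_per_pop, 0)},
        seed=seed + 1,
    )
    return simulate.simulate_population(model)


class TestPairwiseFst:
    def test_null_populations_near_zero(self):
        table = _bn_two_pop_table(30, 8, 500, 0.0, seed=2)
        res = popstruct.pairwise_fst(table)
        assert abs(res.fst.loc["a", "b"]) < 0.005

    def test_fixed_difference_gives_one(self):
        panel = [LocusDef("L", AUTOSOMAL)]
        samples = [Sample(f"a{i}", "M", "a") for i in range(10)] + [
            Sample(f"b{i}", "M", "b") for i in range(10)
        ]
        calls = {(f"a{i}", "L"): ("8", "8") for i in range(10)}
        calls |= {(f"b{i}", "L"): ("9", "9") for i in range(10)}
        table = GenotypeTable(samples, calls, panel)
        res = popstruct.pairwise_fst(table)
        assert res.fst.loc["a", "b"] == pytest.approx(1.0)

    def test_balding_nichols_recovery(self):
        table = _bn_two_pop_table(50, 8, 200, 0.01, seed=4)
        res = popstruct.pairwise_fst(table)
        assert 0.005 <= res.fst.loc["a", "b"] <= 0.02

    def test_invariant_to_allele_relabeling(self):
        table = _bn_two_pop_table(5, 4, 50, 0.05, seed=6)
        relabel = {"8": "30", "9": "9.3", "10": "12", "11": "7"}
        calls = {
            k: tuple(relabel[a] for a in v) for k, v in table.calls.items()
        }
        table2 = GenotypeTable(list(table.samples), calls, list(table.panel))
        r1 = popstruct.pairwise_fst(table)
        r2 = popstruct.pairwise_fst(table2)
        assert r1.fst.loc["a", "b"] == pytest.approx(r2.fst.loc["a", "b"], abs=1e-12)

    def test_permutation_p_values(self):
        diverged = _bn_two_pop_table(20, 6, 100, 0.05, seed=8)
        res = popstruct.pairwise_fst(diverged, n_permutations=200, seed=1)
        assert res.p_values.loc["a", "b"] <= 0.01
        null = _bn_two_pop_table(5, 6, 50, 0.0, seed=9)
        res0 = popstruct.pairwise_fst(null, n_permutations=200, seed=1)
        assert res0.p_values.loc["a", "b"] > 0.01

    def test_tiny_population_rejected(self):
        panel = [LocusDef("L", AUTOSOMAL)]
        samples = [Sample("a1", "M", "a"), Sample("a2", "M", "a"), Sample("b1", "M", "b")]
        calls = {(s.sample_id, "L"): ("8", "9") for s in samples}
        table = GenotypeTable(samples, calls, panel)
        with pytest.raises(StrpopError, match="fewer than 2"):
            popstruct.pairwise_fst(table)

    def test_x_loci_use_pooled_haploid_coding(self):
        # X-only table: estimator still recovers strong differentiation
        from strpop.io import X

        panel = [LocusDef("DX", X)]
        samples = [Sample(f"a{i}", "M", "a") for i in range(20)] + [
            Sample(f"b{i}", "F", "b") for i in range(20)
        ]
        calls = {(f"a{i}", "DX"): ("8",) for i in range(20)}
        calls |= {(f"b{i}", "DX"): ("9", "9") for i in range(20)}
        table = GenotypeTable(samples, calls, panel)
        res = popstruct.pairwise_fst(table)
        assert res.fst.loc["a", "b"] == pytest.approx(1.0)


class TestPcoa:
    def test_equilateral_triangle(self):
        D = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = popstruct.pcoa(D)
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], abs=1e-9)
        C = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(C[i] - C[j]) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_points(self):
        D = pd.DataFrame(
            [[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        res = popstruct.pcoa(D)
        assert res.coordinates.shape[1] == 1  # a single positive axis
        x = res.coordinates.iloc[:, 0].to_numpy()
        assert abs(x[0] - x[2]) == pytest.approx(2.0, abs=1e-9)
        assert abs(x[0] - x[1]) == pytest.approx(1.0, abs=1e-9)
        assert abs(res.eigenvalues[1]) < 1e-9

    def test_reconstructs_embeddable_distances(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = popstruct.pcoa(D)
        C = res.coordinates.to_numpy()
        D2 = np.linalg.norm(C[:, None] - C[None, :], axis=-1)
        assert np.abs(D2 - D).max() < 1e-9

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = popstruct.pcoa(D)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        pos = ours.eigenvalues[ours.eigenvalues > 1e-9]
        ref = np.asarray(theirs.eigvals)[: len(pos)]
        assert np.allclose(pos, ref, atol=1e-8)
        # coordinates agree up to per-axis sign
        C_ref = np.asarray(theirs.samples)[:, : pos.size]
        C = ours.coordinates.to_numpy()
        for k in range(pos.size):
            assert np.allclose(C[:, k], C_ref[:, k], atol=1e-8) or np.allclose(
                C[:, k], -C_ref[:, k], atol=1e-8
            )

    def test_two_cluster_scenario_separates_on_axis_one(self):
        rng = np.random.default_rng(7)
        n = 6
        labels = [f"p{i}" for i in range(n)]
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < 3) == (j < 3)
                base = 0.001 if same else 0.05
                D[i, j] = D[j, i] = base * (1 + 0.1 * rng.random())
        res = popstruct.pcoa(pd.DataFrame(D, index=labels, columns=labels))
        x = res.coordinates.iloc[:, 0].to_numpy()
        g1, g2 = x[:3], x[3:]
        if g1.mean() > g2.mean():
            g1, g2 = g2, g1
        margin = g2.min() - g1.max()
        spread = max(np.ptp(g1), np.ptp(g2))
        assert margin > spread

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(StrpopError, match="symmetric"):
            popstruct.pcoa(D)


def test_ordered_distance_matrix_is_a_permutation():
    rng = np.random.default_rng(3)
    n = 5
    M = rng.random((n, n)) * 0.05
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    df = pd.DataFrame(D, index=list("abcde"), columns=list("abcde"))
    out = popstruct.ordered_distance_matrix(df)
    assert sorted(out.index) == sorted(df.index)
    a, b = out.index[0], out.index[1]
    assert out.loc[a, b] == df.loc[a, b]
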