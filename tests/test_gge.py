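"""GGE biplot: decomposition geometry and the four interpretive views."""

import numpy as np
import pytest

from geitools import GGEBiplot, gge_decompose


def _additive_plus_rank1(rng, g=4, e=6):
    u = rng.normal(size=g)
    v = rng.normal(size=e)
    v -= v.mean()
    return 10 + np.add.outer(u, np.zeros(e)) + np.outer(u * 0 + 1, v) \
        + np.outer(u, v * 0)


class TestDecompose:
    def test_rank1_centered_matrix_pc1_100(self, rng):
        # gene effects only: after tissue centering the matrix is rank 1
        alpha = np.array([4.0, 1.0, -2.0, -3.0])
        y = 10 + alpha[:, None] + rng.normal(size=6)[None, :]
        model = gge_decompose(y)
        assert model.pct_variance_[0] == pytest.approx(100.0)

    def test_genotype_svp_scales_gamma_by_lambda(self, rng):
        y = rng.normal(size=(4, 7)) * 3
        m = GGEBiplot(svp="genotype").fit(y)
        expect = m.full_gene_scores_[:, :2] * m.singular_values_[:2]
        assert np.allclose(m.gene_coords_, expect)

    def test_two_pc_reconstruction_error(self, rng):
        """Product of coordinate matrices reproduces the centered matrix up
        to the trailing singular values."""
        y = rng.normal(size=(5, 8)) * 4
        m = GGEBiplot(svp="symmetric").fit(y)
        approx = m.gene_coords_ @ m.tissue_coords_.T
        err = ((m.centered_ - approx) ** 2).sum()
        assert err == pytest.approx(
            float((m.singular_values_[2:] ** 2).sum()), rel=1e-9)

    def test_fixture_is_near_rank_two(self, ge_matrices):
        for m in ge_matrices.values():
            model = gge_decompose(m)
            assert model.pct_variance_[:2].sum() >= 95.0

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gge_decompose(np.ones((4, 5)))

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError, match="3 genes"):
            gge_decompose(rng.normal(size=(2, 5)))


class TestTissueRelationships:
    def test_duplicated_column_cosine_one(self, rng):
        y = rng.normal(size=(4, 5)) * 2
        y[:, 4] = y[:, 3]
        m = gge_decompose(y)
        cos, _, _ = m.tissue_relationships(full_rank=True)
        assert cos.iloc[3, 4] == pytest.approx(1.0)

    def test_fullrank_cosine_equals_correlation(self, rng):
        y = rng.normal(size=(5, 6)) * 3
        m = gge_decompose(y)
        cos, _, _ = m.tissue_relationships(full_rank=True)
        z = m.centered_
        for a in range(6):
            for b in range(a):
                corr = np.corrcoef(z[:, a], z[:, b])[0, 1]
                assert cos.iloc[a, b] == pytest.approx(corr, abs=1e-8)

    @pytest.mark.parametrize("cond,top2", [
        (5, ["Muscle", "Skin"]),
        (8, ["Spleen", "Kidney"]),
        (13, ["Muscle", "Skin"]),
    ])
    def test_fixture_discrimination(self, ge_matrices, cond, top2):
        _, _, order = gge_decompose(ge_matrices[cond]).tissue_relationships()
        assert order[:2] == top2

    def test_genotype_svp_rejected(self, rng):
        m = GGEBiplot(svp="genotype").fit(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError):
            m.tissue_relationships()


class TestWhichWonWhere:
    def test_fixture_single_region_low_temps(self, ge_matrices):
        for cond in (5, 8):
            part = gge_decompose(ge_matrices[cond]).which_won_where()
            assert set(part.winners.values()) == {"AFP1"}

    def test_fixture_muscle_region(self, ge_matrices):
        for cond in (13, 18):
            part = gge_decompose(ge_matrices[cond]).which_won_where()
            assert part.winners["Muscle"] == "YB-1"
        part13 = gge_decompose(ge_matrices[13]).which_won_where()
        rest = {t: w for t, w in part13.winners.items() if t != "Muscle"}
        assert set(rest.values()) == {"AFP1"}

    def test_dominant_gene_wins_everywhere(self, rng):
        y = 5 + rng.normal(size=(4, 6)) * 0.01
        y[2] += 50  # one gene dominates every tissue, no interaction
        part = gge_decompose(y).which_won_where()
        assert set(part.winners.values()) == {2}

    def test_winner_matches_rank2_argmax(self, rng, ge_matrices):
        """Sector winner == argmax of the rank-2 reconstructed centered
        expression, on random tables and on all fixture conditions."""
        models = [gge_decompose(rng.normal(size=(4, 7)) * 3)
                  for _ in range(10)]
        models += [gge_decompose(m) for m in ge_matrices.values()]
        for m in models:
            part = m.which_won_where()
            recon = m.gene_coords_ @ m.tissue_coords_.T
            for j, t in enumerate(m.tissues_):
                assert part.winners[t] == m.genes_[int(np.argmax(
                    recon[:, j]))]

    def test_every_tissue_assigned_once(self, ge_matrices):
        part = gge_decompose(ge_matrices[18]).which_won_where()
        assigned = [t for ts in part.regions.values() for t in ts]
        assert sorted(assigned) == sorted(part.winners)

    def test_collinear_genes_rejected(self):
        y = np.outer([1.0, 2.0, 3.0], [1.0, -1.0, 0.5, 2.0])
        with pytest.raises(ValueError, match="collinear"):
            gge_decompose(y).which_won_where()


class TestRankings:
    @pytest.mark.parametrize("cond,mean,stab", [
        (5, ["AFP1", "YB-1", "CIRP", "HMGB1"],
         ["AFP1", "CIRP", "HMGB1", "YB-1"]),
        (18, ["YB-1", "AFP1", "HMGB1", "CIRP"],
         ["CIRP", "HMGB1", "AFP1", "YB-1"]),
    ])
    def test_fixture_mean_and_stability(self, ge_matrices, cond, mean,
                                        stab):
        rank = gge_decompose(ge_matrices[cond]).mean_stability()
        assert rank.mean_order == mean
        assert rank.stability_order == stab

    @pytest.mark.parametrize("cond,order", [
        (5, ["AFP1", "YB-1", "CIRP", "HMGB1"]),
        (13, ["AFP1", "YB-1", "HMGB1", "CIRP"]),
        (18, ["YB-1", "AFP1", "HMGB1", "CIRP"]),
    ])
    def test_fixture_comprehensive(self, ge_matrices, cond, order):
        rank = gge_decompose(ge_matrices[cond]).ideal_gene_distance()
        assert rank.comprehensive_order == order

    def test_zero_interaction_all_stable(self, rng):
        alpha = np.array([5.0, 2.0, -1.0, -6.0])
        y = 20 + alpha[:, None] + rng.normal(size=7)[None, :]
        rank = gge_decompose(y).mean_stability()
        scale = max(abs(v) for v in rank.mean_scores.values())
        assert all(abs(s) < 1e-6 * scale
                   for s in rank.stability_scores.values())
        assert rank.mean_order == list(np.argsort(-alpha))

    def test_gene_at_ideal_point_ranks_first(self, rng):
        y = rng.normal(size=(4, 6)) * 2
        m = gge_decompose(y)
        rank = m.ideal_gene_distance()
        # move the best gene onto the ideal point and refit artificially
        ata = m._ata()
        radius = np.linalg.norm(m.gene_coords_[:, :2], axis=1).max()
        best = rank.comprehensive_order[0]
        i = m.genes_.index(best)
        m.gene_coords_[i, :2] = ata * radius
        rank2 = m.ideal_gene_distance()
        assert rank2.ideal_distances[best] == pytest.approx(0, abs=1e-9)
        assert rank2.comprehensive_order[0] == best

    def test_svp_invariance_of_inner_product_orderings(self, ge_matrices):
        """Sector winners and the mean-performance ordering derive from
        inner products, so they are unchanged by how the singular values
        are split between the two coordinate sets (the scores themselves
        change; perpendicular-distance orderings may too)."""
        for m in ge_matrices.values():
            a = gge_decompose(m, svp="symmetric")
            b = gge_decompose(m, svp="genotype")
            assert a.which_won_where().winners == \
                b.which_won_where().winners
            assert a.mean_stability().mean_order == \
                b.mean_stability().mean_order

    def test_environment_svp_rejected_for_rankings(self, rng):
        m = GGEBiplot(svp="environment").fit(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError):
            m.mean_stability()
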