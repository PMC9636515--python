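"""Gene cumulative contribution abundance and association statistics."""

import numpy as np
import pandas as pd
import pytest

import sigcca as sc
from sigcca.cca import CCAResult, GeneCountTensor, _weights


def _attrib(P, S, signames=None):
    P = np.asarray(P, dtype=float)
    S = np.asarray(S, dtype=float)
    Pm = sc.SignatureMatrix(P / P.sum(axis=0),
                            [f"cat{i}" for i in range(P.shape[0])],
                            signames or [f"S{k+1}" for k in range(P.shape[1])])
    Sm = sc.ExposureMatrix(S, list(Pm.col_labels),
                           [f"n{j+1}" for j in range(S.shape[1])])
    return sc.signature_attribution(Pm, Sm)


def _tensor(counts, categories=None):
    counts = np.asarray(counts)
    M, G, N = counts.shape
    return GeneCountTensor(counts,
                           categories or [f"cat{i}" for i in range(M)],
                           [f"g{j+1}" for j in range(G)],
                           [f"n{j+1}" for j in range(N)])


@pytest.fixture
def random_setup(rng):
    """Random K=3, M=8, G=5, N=6 attribution + tensor with positive phi."""
    P = rng.random((8, 3)) + 0.05
    S = rng.random((3, 6)) * 100 + 1
    counts = rng.integers(0, 4, size=(8, 5, 6))
    return _attrib(P, S), _tensor(counts)


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

class TestAttribution:
    def test_identity_P_hand_example(self):
        att = _attrib(np.eye(2), np.array([[3.0], [1.0]]))
        assert np.allclose(att.phi[:, 0], [3.0, 1.0])
        assert np.allclose(att.rho[:, 0, 0], [1.0, 0.0])  # category 1 <- sig 1
        assert np.allclose(att.rho[:, 1, 0], [0.0, 1.0])

    def test_single_signature_rho_is_one(self, rng):
        att = _attrib(rng.random((6, 1)) + 0.1, rng.random((1, 4)) + 0.1)
        assert np.allclose(att.rho[0][att.defined], 1.0)

    def test_rho_sums_to_one_where_defined(self, random_setup):
        att, _ = random_setup
        assert np.allclose(att.rho.sum(axis=0)[att.defined], 1.0)

    def test_rho_scale_invariant_in_exposures(self, rng):
        P = rng.random((8, 3)) + 0.05
        S = rng.random((3, 6)) + 0.05
        a = _attrib(P, S)
        b = _attrib(P, S * 37.0)
        assert np.allclose(a.rho, b.rho)

    def test_zero_phi_flagged(self):
        P = np.array([[1.0, 1.0], [0.0, 0.0]])  # category 2 unreachable
        att = _attrib(P, np.ones((2, 3)))
        assert not att.defined[1].any()
        assert np.all(att.rho[:, 1, :] == 0)


# ---------------------------------------------------------------------------
# Gene impact
# ---------------------------------------------------------------------------

class TestGeneImpact:
    def test_single_gene_carries_all(self):
        counts = np.zeros((2, 3, 1), dtype=int)
        counts[0, 1, 0] = 4
        imp = sc.gene_impact(_tensor(counts))
        assert imp.rho[0, :, 0].tolist() == [0.0, 1.0, 0.0]

    def test_three_to_one_ratio(self):
        counts = np.array([[[3], [1]]])  # M=1, G=2, N=1
        imp = sc.gene_impact(_tensor(counts))
        assert np.allclose(imp.rho[0, :, 0], [0.75, 0.25])

    def test_length_inverse_weighting(self):
        counts = np.array([[[2], [2]]])
        ann = sc.GeneAnnotation({"g1": 1000, "g2": 2000})
        imp = sc.gene_impact(_tensor(counts), ann)
        assert np.allclose(imp.rho_length[0, :, 0], [2 / 3, 1 / 3])

    def test_missing_length_for_mutated_gene_raises(self):
        counts = np.array([[[1], [1]]])
        with pytest.raises(KeyError, match="g2"):
            sc.gene_impact(_tensor(counts), sc.GeneAnnotation({"g1": 100}))

    def test_rho_sums_to_one_over_genes(self, random_setup):
        _, tensor = random_setup
        imp = sc.gene_impact(tensor)
        has_muts = tensor.counts.sum(axis=1) > 0
        assert np.allclose(imp.rho.sum(axis=1)[has_muts], 1.0)


# ---------------------------------------------------------------------------
# CCA identities
# ---------------------------------------------------------------------------

class TestComputeCCA:
    def test_count_weighted_theta_totals_one_per_sample(self, random_setup):
        att, tensor = random_setup
        res = sc.compute_cca(att, sc.gene_impact(tensor))
        totals = res.theta().sum(axis=(0, 1, 2))
        with_muts = tensor.per_sample_totals() > 0
        assert np.allclose(totals[with_muts], 1.0)

    def test_single_everything_alpha_is_one(self):
        att = _attrib(np.ones((3, 1)), np.array([[10.0]]))
        counts = np.zeros((3, 1, 1), dtype=int)
        counts[1, 0, 0] = 5
        res = sc.compute_cca(att, sc.gene_impact(_tensor(counts)))
        assert res.alpha.iloc[0, 0] == pytest.approx(1.0)

    def test_cca_of_single_mutation_gene_equals_its_rho(self, random_setup):
        att, tensor = random_setup
        counts = np.zeros_like(tensor.counts)
        counts[4, 2, 3] = 1  # exactly one mutation
        res = sc.compute_cca(att, sc.gene_impact(_tensor(counts)))
        assert np.allclose(res.cca[:, 2, 3], att.rho[:, 4, 3])

    def test_cca_sums_to_one_over_signatures(self, random_setup):
        att, tensor = random_setup
        res = sc.compute_cca(att, sc.gene_impact(tensor))
        mutated = tensor.counts.sum(axis=0) > 0
        assert np.allclose(res.cca.sum(axis=0)[mutated], 1.0)

    def test_alpha_additive_over_disjoint_sample_sets(self, rng):
        P = rng.random((8, 3)) + 0.05
        S = rng.random((3, 6)) * 50 + 1
        counts = rng.integers(0, 4, size=(8, 5, 6))
        att = _attrib(P, S)
        joint = sc.compute_cca(att, sc.gene_impact(_tensor(counts))).alpha
        parts = []
        for sl in (slice(0, 3), slice(3, 6)):
            att_p = _attrib(P, S[:, sl])
            t = GeneCountTensor(counts[:, :, sl],
                                [f"cat{i}" for i in range(8)],
                                [f"g{j+1}" for j in range(5)],
                                att_p.samples)
            parts.append(sc.compute_cca(att_p, sc.gene_impact(t)).alpha)
        assert np.allclose(joint.to_numpy(), (parts[0] + parts[1]).to_numpy())

    def test_eta_equals_alpha_for_equal_lengths(self, random_setup):
        att, tensor = random_setup
        ann = sc.GeneAnnotation({g: 5000 for g in tensor.genes})
        res = sc.compute_cca(att, sc.gene_impact(tensor, ann))
        assert np.allclose(res.eta.to_numpy(), res.alpha.to_numpy())

    def test_plain_weighting_sums_categories(self, random_setup):
        att, tensor = random_setup
        w = _weights(tensor, "plain")
        assert (w == 1).all()
        with pytest.raises(ValueError):
            _weights(tensor, "bogus")


class TestFlagLowCCA:
    def test_threshold_is_strict(self, random_setup):
        att, tensor = random_setup
        res = sc.compute_cca(att, sc.gene_impact(tensor))
        res.cca[0, 0, 0] = 0.06
        res.cca[1, 0, 0] = 0.0599
        flags = sc.flag_low_cca(res)
        assert not flags[0, 0, 0] and flags[1, 0, 0]

    def test_unmutated_gene_flagged(self, random_setup):
        att, tensor = random_setup
        counts = tensor.counts.copy()
        counts[:, 1, :] = 0
        res = sc.compute_cca(att, sc.gene_impact(_tensor(counts)))
        assert sc.flag_low_cca(res)[:, 1, :].all()


# ---------------------------------------------------------------------------
# Association battery
# ---------------------------------------------------------------------------

def _direct_cca(arr, signames=None):
    K, G, N = arr.shape
    signames = signames or [f"S{k+1}" for k in range(K)]
    genes = [f"g{j+1}" for j in range(G)]
    samples = [f"n{j+1}" for j in range(N)]
    return CCAResult(alpha=pd.DataFrame(arr.sum(axis=2), index=signames, columns=genes),
                     eta=None, cca=arr, signatures=signames, genes=genes,
                     samples=samples, weighting="count_weighted",
                     attribution=None, impact=None)


class TestAssociation:
    def test_permutation_floor_with_add_one_correction(self, rng):
        """An extreme planted difference reaches p = 1/(n_perm+1)."""
        K, G, N = 2, 3, 60
        arr = rng.random((K, G, N)) * 0.05
        mut = np.zeros((G, N), dtype=bool)
        mut[:, :20] = True
        arr[0, 0, :20] += 10.0  # unmissable effect for (g1, S1)
        tab = sc.associate_gene_signature(_direct_cca(arr), mut, n_perm=500, seed=0)
        row = tab[(tab.gene == "g1") & (tab.signature == "S1")].iloc[0]
        assert row["perm_p"] == pytest.approx(1 / 501)

    def test_q_values_match_manual_bh(self, rng):
        arr = rng.random((2, 6, 80))
        mut = rng.random((6, 80)) < 0.4
        tab = sc.associate_gene_signature(_direct_cca(arr), mut, n_perm=200, seed=1)
        for signame in ["S1", "S2"]:
            sub = tab[tab.signature == signame].sort_values("perm_p")
            p = sub["perm_p"].to_numpy()
            m = len(p)
            q_manual = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
            assert np.allclose(sub["q"].to_numpy(), q_manual)

    def test_fully_mutated_gene_flagged(self, rng):
        arr = rng.random((2, 2, 30))
        mut = np.zeros((2, 30), dtype=bool)
        mut[0] = True                       # no wild-type group
        mut[1, :10] = True
        tab = sc.associate_gene_signature(_direct_cca(arr), mut, n_perm=200, seed=2)
        assert tab[tab.gene == "g1"]["flagged"].all()
        assert not tab[tab.gene == "g2"]["flagged"].any()

    def test_min_mutated_fraction_filter(self, rng):
        arr = rng.random((2, 2, 100))
        mut = np.zeros((2, 100), dtype=bool)
        mut[0, :3] = True                   # 3% <= 5%: excluded
        mut[1, :30] = True
        tab = sc.associate_gene_signature(_direct_cca(arr), mut, n_perm=200, seed=3)
        assert set(tab.gene) == {"g2"}

    def test_planted_effect_attains_min_q(self, rng):
        """Background genes independent of status; the planted pair wins."""
        K, G, N = 3, 10, 120
        arr = rng.random((K, G, N))
        arr /= arr.sum(axis=0)
        mut = rng.random((G, N)) < 0.35
        boost = mut[4] & (np.arange(N) >= 0)
        arr[1, 4, boost] = 0.95             # gene g5 <- signature S2
        arr[0, 4, boost] = 0.03
        arr[2, 4, boost] = 0.02
        tab = sc.associate_gene_signature(_direct_cca(arr), mut, n_perm=999, seed=4)
        best = tab.sort_values(["q", "median_cca_diff"],
                               ascending=[True, False]).iloc[0]
        assert (best.gene, best.signature) == ("g5", "S2")


class TestFisher:
    def test_perfect_association(self):
        pres = np.array([[True] * 10 + [False] * 10])
        status = np.array([[True] * 10 + [False] * 10])
        tab = sc.fisher_presence_test(pres, status)
        row = tab.iloc[0]
        assert row["p"] < 0.001 and row["odds_ratio_infinite"]

    def test_independent_balanced_table(self):
        pres = np.array([[True, True, False, False] * 5])
        status = np.array([[True, False, True, False] * 5])
        assert sc.fisher_presence_test(pres, status).iloc[0]["p"] == pytest.approx(1.0)

    def test_swapping_rows_inverts_odds_ratio(self, rng):
        pres = rng.random((1, 40)) < 0.5
        status = (rng.random((1, 40)) < 0.5) | pres  # dependence, finite OR
        a = sc.fisher_presence_test(pres, status).iloc[0]
        b = sc.fisher_presence_test(~pres, status).iloc[0]
        if np.isfinite(a["odds_ratio"]) and a["odds_ratio"] > 0:
            assert b["odds_ratio"] == pytest.approx(1 / a["odds_ratio"])

    def test_degenerate_margin(self):
        pres = np.array([[True] * 10])
        status = np.array([[True] * 5 + [False] * 5])
        row = sc.fisher_presence_test(pres, status).iloc[0]
        assert row["degenerate"] and row["p"] == 1.0


# ---------------------------------------------------------------------------
# Gene tensor and image matrix
# ---------------------------------------------------------------------------

class TestGeneTensor:
    def test_counts_and_conservation(self, toy_genome):
        recs = [
            sc.MutationRecord("A", "chr1", 3, "C", "T", gene="GA", is_nonsilent=True),
            sc.MutationRecord("A", "chr1", 7, "T", "C", gene="GA", is_nonsilent=False),
            sc.MutationRecord("A", "chr1", 8, "G", "A", gene="GB", is_nonsilent=True),
            sc.MutationRecord("A", "chr1", 5, "A", "T", gene="ZZ", is_nonsilent=True),
        ]
        t = sc.build_gene_tensor(recs, toy_genome, "SBS96", ["GA", "GB"])
        assert t.counts.sum(axis=(0, 2)).tolist() == [2, 1]
        assert t.unassigned == 1
        assert t.per_sample_totals().tolist() == [3]

    def test_nonsilent_filter(self, toy_genome):
        recs = [
            sc.MutationRecord("A", "chr1", 3, "C", "T", gene="GA", is_nonsilent=True),
            sc.MutationRecord("A", "chr1", 7, "T", "C", gene="GA", is_nonsilent=False),
        ]
        t = sc.build_gene_tensor(recs, toy_genome, "SBS96", ["GA"], nonsilent_only=True)
        assert t.counts.sum() == 1

    def test_empty_gene_list_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            sc.build_gene_tensor([], toy_genome, "SBS96", [])


class TestImageMatrix:
    def _result(self, G, rng):
        arr = rng.random((2, G, 3))
        return _direct_cca(arr)

    def test_nine_genes_three_by_three(self, rng):
        res = self._result(9, rng)
        img = sc.image_matrix(res, "S1", "n1", gene_order=res.genes)
        assert img.shape == (3, 3)
        assert np.allclose(img.ravel(), res.cca[0, :, 0])

    def test_ten_genes_padded_four_by_four(self, rng):
        res = self._result(10, rng)
        img = sc.image_matrix(res, "S2", "n2", gene_order=res.genes)
        assert img.shape == (4, 4)
        assert (img.ravel()[10:] == 0).all()

    def test_explicit_order_respected(self, rng):
        res = self._result(4, rng)
        order = ["g3", "g1", "g4", "g2"]
        img = sc.image_matrix(res, "S1", "n1", gene_order=order)
        idx = [res.genes.index(g) for g in order]
        assert np.allclose(img.ravel(), res.cca[0, idx, 0])

    def test_hclust_order_is_deterministic_permutation(self, rng):
        res = self._result(12, rng)
        o1 = sc.hclust_gene_order(res)
        o2 = sc.hclust_gene_order(res)
        assert o1 == o2 and sorted(o1) == sorted(res.genes)
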