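import math
import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from intercov.dca import (CouplingModel, couplings_from_frequencies,
                          direct_information, frobenius_apc_score,
                          mfdca_fit, pair_index, plmdca_fit,
                          pseudolikelihood, reweight_sequences,
                          zero_sum_gauge)
from intercov.mi import apc_correct, mutual_information, weighted_frequencies
from intercov.synthetic import iid_column_msa

from conftest import make_msa, uniform_weights


def top_pairs(matrix, k):
    L = matrix.shape[0]
    iu = np.triu_indices(L, k=1)
    order = np.argsort(-matrix[iu])
    return set(zip(iu[0][order[:k]], iu[1][order[:k]]))


class TestReweightSequences:
    def test_all_identical(self):
        msa = make_msa(["ACDE"] * 4)
        w = reweight_sequences(msa)
        assert np.allclose(w.weights, 0.25)
        assert w.meff == pytest.approx(1.0)

    def test_all_distinct(self):
        msa = make_msa(["AAAA", "CCCC", "DDDD"])
        w = reweight_sequences(msa, theta=0.8)
        assert np.allclose(w.weights, 1.0)
        assert w.meff == pytest.approx(3.0)

    def test_near_duplicate_pair(self):
        # rows 0,1 are 90% identical; rows 2,3 unrelated to everything
        msa = make_msa(["AAAAAAAAAA", "AAAAAAAAAC",
                        "DDDDDDDDDD", "EEEEEEEEEE"])
        w = reweight_sequences(msa, theta=0.8)
        assert w.weights.tolist() == [0.5, 0.5, 1.0, 1.0]
        assert w.meff == pytest.approx(3.0)


class TestMeanFieldCouplings:
    def test_two_state_closed_form(self):
        # q=2, L=2: C is 2x2 over the single non-gauged state per site;
        # the coupling equals the hand-inverted off-diagonal element
        f1 = np.array([[0.6, 0.4], [0.3, 0.7]])
        f2 = np.empty((2, 2, 2, 2))
        joint = np.array([[0.25, 0.35], [0.05, 0.35]])   # marginals 0.6/0.3
        f2[0, :, 1, :] = joint
        f2[1, :, 0, :] = joint.T
        e = couplings_from_frequencies(f1, f2, q=2)
        v0 = 0.6 * 0.4
        v1 = 0.3 * 0.7
        c = joint[0, 0] - 0.6 * 0.3
        expected = c / (v0 * v1 - c * c)     # -inv([[v0,c],[c,v1]])[0,1]
        assert e[pair_index(0, 1, 2)][0, 0] == pytest.approx(expected,
                                                             abs=1e-12)

    def test_independent_columns_have_no_structure(self):
        paired = iid_column_msa(n=1000, L=6, q=8, seed=4)
        msa = paired.msa
        model = mfdca_fit(msa, reweight_sequences(msa))
        norms = [np.linalg.norm(model.couplings[k])
                 for k in range(len(model.couplings))]
        assert max(norms) < 10 * np.median(norms)

    def test_planted_pairs_have_largest_blocks(self, planted_potts):
        paired, planted = planted_potts
        msa = paired.msa
        model = mfdca_fit(msa, reweight_sequences(msa))
        L = msa.length
        norms = np.zeros((L, L))
        for i in range(L):
            for j in range(i + 1, L):
                norms[i, j] = np.linalg.norm(
                    model.couplings[pair_index(i, j, L)][:20, :20])
        assert len(top_pairs(norms, 10) & set(planted)) >= 8

    def test_singular_correlation_advises_pseudocount(self):
        msa = make_msa(["ACDE", "ACDE", "ACDE"])
        with pytest.raises(ValueError, match="pseudocount"):
            mfdca_fit(msa, uniform_weights(msa), pseudocount_fraction=0.0)


class TestDirectInformation:
    def _uniform_model(self, L, q, couplings):
        n_pairs = L * (L - 1) // 2
        e = np.zeros((n_pairs, q, q))
        for (i, j), block in couplings.items():
            e[pair_index(i, j, L)] = block
        f = np.full((L, q), 1.0 / q)
        return CouplingModel(q, np.zeros((L, q)), e, "zero-sum",
                             single_freqs=f)

    def test_zero_couplings_zero_di(self):
        model = self._uniform_model(3, 4, {})
        assert np.allclose(direct_information(model), 0.0, atol=1e-9)

    def test_two_state_symmetric_coupling_closed_form(self):
        J = 1.7
        block = np.array([[J, 0.0], [0.0, J]])
        model = self._uniform_model(2, 2, {(0, 1): block})
        di = direct_information(model)
        # P propto exp(J*[a==b]) with uniform marginals by symmetry
        Z = 2 * math.exp(J) + 2
        p_same = math.exp(J) / Z
        p_diff = 1 / Z
        expected = 2 * p_same * math.log(p_same / 0.25) + \
            2 * p_diff * math.log(p_diff / 0.25)
        assert di[0, 1] == pytest.approx(expected, abs=1e-6)

    def test_symmetric_on_random_models(self):
        rng = np.random.default_rng(8)
        L, q = 4, 5
        couplings = {(i, j): rng.normal(scale=0.3, size=(q, q))
                     for i in range(L) for j in range(i + 1, L)}
        model = self._uniform_model(L, q, couplings)
        f = rng.dirichlet(np.ones(q), size=L)
        di = direct_information(model, f)
        assert np.allclose(di, di.T, atol=1e-9)
        assert (di >= 0).all()


class TestPlmdca:
    def test_single_column_field_shrinkage(self):
        msa = make_msa(["A", "A", "A", "C"],
                       ids=["r0", "r1", "r2", "r3"])
        w = uniform_weights(msa)
        weak = plmdca_fit(msa, w, lam_h=0.01)
        strong = plmdca_fit(msa, w, lam_h=1.0)
        assert weak.couplings.shape[0] == 0
        assert np.linalg.norm(strong.fields) < np.linalg.norm(weak.fields)
        # fields rank states like their frequencies
        assert weak.fields[0, 0] > weak.fields[0, 1] > weak.fields[0, 2]

    def test_independent_columns_flat_norms(self):
        paired = iid_column_msa(n=1000, L=8, q=6, seed=9)
        msa = paired.msa
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = plmdca_fit(msa, reweight_sequences(msa))
        norms = [np.linalg.norm(model.couplings[k][:20, :20])
                 for k in range(len(model.couplings))]
        assert max(norms) / np.median(norms) < 3

    def test_gauge_invariance_of_pseudolikelihood(self):
        rng = np.random.default_rng(12)
        L, q = 4, 21
        msa = iid_column_msa(n=30, L=L, q=8, seed=13).msa
        w = uniform_weights(msa)
        n_pairs = L * (L - 1) // 2
        model = CouplingModel(
            q, rng.normal(size=(L, q)),
            rng.normal(scale=0.2, size=(n_pairs, q, q)), "raw")
        gauged = zero_sum_gauge(model)
        assert abs(pseudolikelihood(model, msa, w)
                   - pseudolikelihood(gauged, msa, w)) < 1e-6
        # and the gauge constraint holds: coupling rows/cols sum to zero
        assert np.allclose(gauged.couplings.sum(axis=1), 0.0, atol=1e-6)
        assert np.allclose(gauged.couplings.sum(axis=2), 0.0, atol=1e-6)


class TestFrobeniusApc:
    def test_zero_couplings_zero_scores(self):
        L, q = 4, 21
        model = CouplingModel(q, np.zeros((L, q)),
                              np.zeros((L * 3 // 2 * 2, q, q))[:6], "zero-sum")
        assert np.allclose(frobenius_apc_score(model), 0.0)

    def test_constant_norms_cancel(self):
        # couplings whose 20x20 blocks all have identical Frobenius norm
        L, q = 5, 21
        n_pairs = L * (L - 1) // 2
        e = np.zeros((n_pairs, q, q))
        block = np.zeros((q, q))
        block[0, 0], block[0, 1], block[1, 0], block[1, 1] = 1, -1, -1, 1
        for k in range(n_pairs):
            e[k] = block
        model = CouplingModel(q, np.zeros((L, q)), e, "zero-sum")
        assert np.allclose(frobenius_apc_score(model), 0.0, atol=1e-12)

    def test_matches_two_loop_oracle(self):
        rng = np.random.default_rng(21)
        L, q = 6, 21
        n_pairs = L * (L - 1) // 2
        e = rng.normal(size=(n_pairs, q, q))
        model = CouplingModel(q, np.zeros((L, q)), e, "raw")
        fapc = frobenius_apc_score(model)
        gauged = zero_sum_gauge(model)
        S = np.zeros((L, L))
        for i in range(L):
            for j in range(i + 1, L):
                block = gauged.couplings[pair_index(i, j, L)][:20, :20]
                S[i, j] = S[j, i] = math.sqrt(float((block ** 2).sum()))
        _, expected = apc_correct(S)
        assert np.allclose(fapc, expected, atol=1e-10)


class TestModelDump:
    def test_text_roundtrip(self, tmp_path):
        from intercov.dca import load_coupling_model, save_coupling_model
        rng = np.random.default_rng(5)
        L, q = 3, 4
        model = CouplingModel(q, rng.normal(size=(L, q)),
                              rng.normal(size=(3, q, q)), "zero-sum",
                              method="plmdca", converged=False)
        path = tmp_path / "model.txt"
        save_coupling_model(model, path)
        back = load_coupling_model(path)
        assert back.q == q and back.gauge == "zero-sum"
        assert back.method == "plmdca" and back.converged is False
        assert np.allclose(back.fields, model.fields)
        assert np.allclose(back.couplings, model.couplings)


class TestCrossMethod:
    def test_row_permutation_invariance(self):
        msa = iid_column_msa(n=60, L=5, q=6, seed=2).msa
        perm = np.random.default_rng(0).permutation(msa.n_records)
        from intercov.msa import Msa
        permuted = Msa([msa.records[k] for k in perm])
        di1 = direct_information(mfdca_fit(msa, reweight_sequences(msa)))
        di2 = direct_information(
            mfdca_fit(permuted, reweight_sequences(permuted)))
        assert np.allclose(di1, di2, atol=1e-8)

    def test_dca_scores_correlate_with_corrected_mi(self):
        # dense planted fixture: every cross-segment pair coupled, so the
        # rankings of all three methods carry comparable signal
        from intercov.synthetic import PlantedPottsSpec, sample_potts_msa
        L, split = 10, 5
        pairs = [(i, j) for i in range(split) for j in range(split, L)]
        spec = PlantedPottsSpec(L=L, q=4, n_sequences=1500,
                                segment_split=split, planted_pairs=pairs,
                                coupling_strength=1.5, seed=3)
        paired, _ = sample_potts_msa(spec)
        msa = paired.msa
        freqs = weighted_frequencies(msa, uniform_weights(msa), 0.05)
        _, mip = apc_correct(mutual_information(freqs))
        rw = reweight_sequences(msa)
        model = mfdca_fit(msa, rw)
        di = direct_information(model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fapc = frobenius_apc_score(plmdca_fit(msa, rw))
        iu = np.triu_indices(L, k=1)
        assert spearmanr(di[iu], mip[iu]).statistic > 0.5
        assert spearmanr(fapc[iu], mip[iu]).statistic > 0.5
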