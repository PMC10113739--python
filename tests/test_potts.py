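"""Mean-field DCA inference and Hamiltonian scoring against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lgl.msa_io import Alignment, one_hot_encode
from lgl.potts import (
    FrequencyTables,
    PottsError,
    PottsModel,
    compute_frequencies,
    coupling_norms,
    delta_hamiltonian,
    hamiltonian,
    infer_potts,
    zero_sum_fields,
)
from lgl.synthetic import (
    SyntheticFamilySpec,
    make_truth_potts,
    restricted_alphabet,
    sample_potts_family,
)


def _random_model(L, q, rng, coupling_scale=1.0):
    h = rng.normal(size=(L, q))
    e = rng.normal(scale=coupling_scale, size=(L, L, q, q))
    e = 0.5 * (e + e.transpose(1, 0, 3, 2))  # pair symmetry
    e[np.arange(L), np.arange(L)] = 0.0
    return PottsModel(h=h, e=e, alphabet=restricted_alphabet(q))


def _oracle_hamiltonian(idx, model):
    """Naive double-loop evaluation of H(S)."""
    H = 0.0
    L = model.L
    for i in range(L):
        H -= model.h[i, idx[i]]
        for j in range(i + 1, L):
            H -= model.e[i, j, idx[i], idx[j]]
    return H


class TestFrequencies:
    def test_matches_counting_oracle(self):
        seqs = ["ACD", "ACC", "AAD", "CCD"]
        aln = Alignment([f"s{i}" for i in range(4)], seqs)
        X = one_hot_encode(aln)
        fq = compute_frequencies(X, pseudocount=0.0, reweight_identity=None)
        # independent per-column / per-column-pair counting
        for i in range(3):
            for a, sym in enumerate(aln.alphabet.symbols):
                expected = sum(s[i] == sym for s in seqs) / 4
                assert fq.f_i[i, a] == pytest.approx(expected, abs=1e-12)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                for a, sa in enumerate("ACD"):
                    for b, sb in enumerate("ACD"):
                        expected = (
                            sum(s[i] == sa and s[j] == sb for s in seqs) / 4
                        )
                        ia, ib = aln.alphabet.index[sa], aln.alphabet.index[sb]
                        assert fq.f_ij[i, j, ia, ib] == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_identical_pair_is_one_hot(self):
        aln = Alignment(["a", "b"], ["ACD", "ACD"])
        fq = compute_frequencies(
            one_hot_encode(aln), pseudocount=0.0, reweight_identity=None
        )
        assert np.array_equal(fq.f_i, one_hot_encode(aln)[0])

    def test_full_pseudocount_is_uniform(self, family_onehot):
        fq = compute_frequencies(family_onehot, pseudocount=1.0, reweight_identity=None)
        assert np.allclose(fq.f_i, 1 / 23)

    def test_invariants(self, family_onehot):
        fq = compute_frequencies(family_onehot, pseudocount=0.5)
        assert np.allclose(fq.f_i.sum(axis=1), 1.0, atol=1e-9)
        L = fq.L
        marg = fq.f_ij.sum(axis=3)
        assert np.allclose(marg, np.broadcast_to(fq.f_i[:, None, :], marg.shape), atol=1e-9)
        assert ((fq.f_i >= 0) & (fq.f_i <= 1)).all()

    def test_reweighting_downweights_duplicates(self):
        # 3 identical sequences + 1 distinct: reweighted f_i moves toward 50/50
        aln = Alignment(list("abcd"), ["AAAA", "AAAA", "AAAA", "CCCC"])
        X = one_hot_encode(aln)
        plain = compute_frequencies(X, pseudocount=0.0, reweight_identity=None)
        rew = compute_frequencies(X, pseudocount=0.0, reweight_identity=0.8)
        ia = aln.alphabet.index["A"]
        assert plain.f_i[0, ia] == pytest.approx(0.75)
        assert rew.f_i[0, ia] == pytest.approx(0.5)
        assert rew.n_eff == pytest.approx(2.0)

    def test_single_sequence_rejected(self):
        aln = Alignment(["a"], ["ACD"])
        with pytest.raises(PottsError):
            compute_frequencies(one_hot_encode(aln))


class TestInference:
    def test_independent_columns_give_zero_couplings(self):
        # hand-built tables with exact factorization f_ij = f_i f_j
        rng = np.random.default_rng(5)
        L, q = 4, 3
        f_i = rng.dirichlet(np.ones(q), size=L)
        f_ij = f_i[:, None, :, None] * f_i[None, :, None, :]
        ii = np.arange(L)
        f_ij[ii, ii] = 0.0
        for a in range(q):
            f_ij[ii, ii, a, a] = f_i[:, a]
        fq = FrequencyTables(f_i, f_ij, n_eff=100.0, pseudocount=0.0, reweight_identity=None)
        model = infer_potts(fq)
        assert np.abs(model.e).max() < 1e-8

    def test_two_site_binary_closed_form(self):
        # L=2, q=2: the reduced correlation matrix is 2x2 and invertible by hand
        f_i = np.array([[0.6, 0.4], [0.3, 0.7]])
        c12 = 0.08  # connected correlation between state-0 occupancies
        f_ij = np.empty((2, 2, 2, 2))
        f11 = f_i[0, 0] * f_i[1, 0] + c12
        f_ij[0, 1] = np.array(
            [[f11, f_i[0, 0] - f11], [f_i[1, 0] - f11, 1 - f_i[0, 0] - f_i[1, 0] + f11]]
        )
        f_ij[1, 0] = f_ij[0, 1].T
        for i in range(2):
            f_ij[i, i] = np.diag(f_i[i])
        fq = FrequencyTables(f_i, f_ij, n_eff=50.0, pseudocount=0.0, reweight_identity=None)
        model = infer_potts(fq)
        # hand inversion of [[v1, c], [c, v2]]
        v1 = f_i[0, 0] * (1 - f_i[0, 0])
        v2 = f_i[1, 0] * (1 - f_i[1, 0])
        det = v1 * v2 - c12**2
        expected_e = c12 / det  # -( C^-1 )_{01} = -(-c/det) = c/det
        assert model.e[0, 1, 0, 0] == pytest.approx(expected_e, rel=1e-9)
        # symmetry and gauge zeros
        assert model.e[1, 0, 0, 0] == pytest.approx(expected_e, rel=1e-9)
        assert model.e[0, 1, 1, 0] == 0.0 and model.e[0, 1, 0, 1] == 0.0

    def test_inferred_marginals_match_frequencies(self, family_onehot):
        """Mean-field self-consistency: independent-site softmax of the
        fields plus coupling background reproduces f_i."""
        fq = compute_frequencies(family_onehot, pseudocount=0.3)
        model = infer_potts(fq)
        logits = model.h + np.einsum("ijab,jb->ia", model.e, fq.f_i)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        assert np.allclose(p, fq.f_i, atol=1e-8)

    def test_singular_correlation_reports_pseudocount(self):
        aln = Alignment(["a", "b"], ["AAAA", "AAAA"])
        fq = compute_frequencies(one_hot_encode(aln), pseudocount=0.0, reweight_identity=None)
        with pytest.raises(PottsError, match="pseudocount"):
            infer_potts(fq)

    def test_save_load_round_trip(self, potts_model, tmp_path):
        p = tmp_path / "potts.h5"
        potts_model.save(p)
        back = PottsModel.load(p)
        assert np.array_equal(back.h, potts_model.h)
        assert np.array_equal(back.e, potts_model.e)
        assert back.meta["pseudocount"] == potts_model.meta["pseudocount"]


class TestHamiltonian:
    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 11))
        q = int(rng.integers(2, 5))
        model = _random_model(L, q, rng)
        idx = rng.integers(0, q, size=(4, L))
        H = hamiltonian(idx, model)
        for k in range(4):
            assert H[k] == pytest.approx(_oracle_hamiltonian(idx[k], model), abs=1e-12)

    def test_zero_model_scores_zero(self):
        model = PottsModel(h=np.zeros((5, 23)), e=np.zeros((5, 5, 23, 23)))
        assert hamiltonian("ACDEF", model) == 0.0

    def test_batch_equals_individual(self, potts_model, family):
        aln, _ = family
        batch = hamiltonian(aln, potts_model)
        singles = np.array([hamiltonian(s, potts_model) for s in aln.seqs[:25]])
        assert np.allclose(batch[:25], singles, atol=1e-9)

    def test_string_and_index_agree(self, potts_model, family):
        aln, _ = family
        assert hamiltonian(aln.seqs[0], potts_model) == pytest.approx(
            hamiltonian(aln.indices()[:1], potts_model)[0], abs=1e-12
        )

    def test_gauge_shift_moves_H_but_not_dH(self, rng):
        model = _random_model(6, 4, rng)
        shifted = PottsModel(
            h=model.h.copy(), e=model.e.copy(), alphabet=model.alphabet
        )
        shifted.h[2] += 1.7  # constant shift at one site
        idx = rng.integers(0, 4, size=(10, 6))
        H0, H1 = hamiltonian(idx, model), hamiltonian(idx, shifted)
        assert np.allclose(H1 - H0, -1.7, atol=1e-12)
        ref = model.alphabet.decode(idx[0])
        d0 = delta_hamiltonian(idx, ref, model)
        d1 = delta_hamiltonian(idx, ref, shifted)
        assert np.allclose(d0, d1, atol=1e-12)


class TestDeltaHamiltonian:
    def test_self_difference_is_zero(self, potts_model, family):
        aln, _ = family
        assert delta_hamiltonian(aln.seqs[0], aln.seqs[0], potts_model) == 0.0

    def test_fields_only_single_substitution(self, rng):
        L, q = 8, 4
        model = PottsModel(
            h=rng.normal(size=(L, q)),
            e=np.zeros((L, L, q, q)),
            alphabet=restricted_alphabet(q),
        )
        ref_idx = rng.integers(0, q, size=L)
        ref = model.alphabet.decode(ref_idx)
        mut_idx = ref_idx.copy()
        i = 3
        mut_idx[i] = (ref_idx[i] + 1) % q
        mut = model.alphabet.decode(mut_idx)
        expected = model.h[i, ref_idx[i]] - model.h[i, mut_idx[i]]
        assert delta_hamiltonian(mut, ref, model) == pytest.approx(expected, abs=1e-12)

    def test_telescoping_identity(self, rng):
        model = _random_model(7, 3, rng)
        seqs = rng.integers(0, 3, size=(3, 7))
        ref = model.alphabet.decode(seqs[2])
        a, b = (model.alphabet.decode(s) for s in seqs[:2])
        lhs = delta_hamiltonian(a, ref, model) - delta_hamiltonian(b, ref, model)
        rhs = hamiltonian(a, model) - hamiltonian(b, model)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_length_mismatch(self, potts_model):
        with pytest.raises(PottsError):
            hamiltonian("ACD", potts_model)


class TestRecovery:
    """Ground-truth parameter and contact recovery on Gibbs-sampled families."""

    def test_field_recovery(self):
        spec = SyntheticFamilySpec(L=20, q=5, n=5000, field_scale=1.0, seed=11)
        truth = make_truth_potts(spec)
        fam = sample_potts_family(
            truth, 5000, burn_in=200, thin=3,
            rng=np.random.default_rng(12), n_chains=50,
        )
        fq = compute_frequencies(
            one_hot_encode(fam), pseudocount=0.01, reweight_identity=None
        )
        inferred = infer_potts(fq)
        r = stats.pearsonr(
            zero_sum_fields(truth).ravel(), zero_sum_fields(inferred).ravel()
        ).statistic
        assert r > 0.9

    def test_contact_recovery(self):
        rng = np.random.default_rng(7)
        pairs = set()
        while len(pairs) < 10:
            i, j = sorted(rng.choice(20, 2, replace=False).tolist())
            pairs.add((i, j))
        spec = SyntheticFamilySpec(
            L=20, q=5, n=5000, field_scale=0.5, coupling_scale=1.0,
            coupling_pairs=sorted(pairs), seed=13,
        )
        truth = make_truth_potts(spec)
        fam = sample_potts_family(
            truth, 5000, burn_in=200, thin=3,
            rng=np.random.default_rng(14), n_chains=50,
        )
        fq = compute_frequencies(
            one_hot_encode(fam), pseudocount=0.01, reweight_identity=None
        )
        inferred = infer_potts(fq)
        F = coupling_norms(inferred)
        iu = np.triu_indices(20, 1)
        order = np.argsort(-F[iu])
        top10 = {(iu[0][k], iu[1][k]) for k in order[:10]}
        assert len(top10 & pairs) >= 8
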