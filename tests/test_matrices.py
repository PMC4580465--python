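"""Rate-matrix construction across all model families."""

import numpy as np
import pytest

from seqevolve import (
    FrequencyVector,
    MechanisticCodonParameters,
    MutSelParameters,
    NucleotideParameters,
    build_alphabet,
    build_custom,
    build_empirical,
    build_gtr,
    build_mechanistic_codon,
    build_mutsel,
    jc69_matrix,
    load_empirical_data,
    scale_matrix,
)
from seqevolve.matrices import MatrixError, fixation_factor


def assert_valid_rate_matrix(rm):
    """Shared invariants: non-negative off-diagonals, zero row sums,
    stationarity of the stored frequencies, unit mean rate when scaled."""
    off = rm.Q.copy()
    np.fill_diagonal(off, 0)
    assert np.all(off >= 0)
    np.testing.assert_allclose(rm.Q.sum(axis=1), 0, atol=1e-10)
    np.testing.assert_allclose(rm.frequencies.values @ rm.Q, 0, atol=1e-8)
    if rm.scaled:
        assert abs(rm.mean_rate - 1) < 1e-8


def assert_detailed_balance(rm):
    pi = rm.frequencies.values
    flux = pi[:, None] * rm.Q
    np.testing.assert_allclose(flux, flux.T, atol=1e-8)


class TestGTRFamily:
    def test_jc69_scaled_off_diagonals(self):
        rm = jc69_matrix()
        off = rm.Q[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1 / 3, atol=1e-12)
        assert_valid_rate_matrix(rm)

    def test_hky_kappa_one_equals_equal_rate_gtr(self, nuc_alphabet):
        fv = FrequencyVector(nuc_alphabet, np.array([0.4, 0.3, 0.2, 0.1]))
        hky = build_gtr(NucleotideParameters.hky85(1.0, fv))
        gtr = build_gtr(NucleotideParameters.gtr([1] * 6, fv))
        np.testing.assert_allclose(hky.Q, gtr.Q, atol=1e-12)

    def test_transition_transversion_ratio(self, nuc_alphabet):
        fv = FrequencyVector.uniform(nuc_alphabet)
        rm = build_gtr(NucleotideParameters.hky85(3.25, fv))
        i = {s: k for k, s in enumerate(nuc_alphabet.states)}
        assert rm.Q[i["A"], i["G"]] / rm.Q[i["A"], i["C"]] == pytest.approx(3.25)
        assert rm.Q[i["C"], i["T"]] / rm.Q[i["C"], i["G"]] == pytest.approx(3.25)

    def test_tn93_equal_transitions_collapses_to_hky(self, nuc_alphabet):
        fv = FrequencyVector(nuc_alphabet, np.array([0.1, 0.2, 0.3, 0.4]))
        tn = build_gtr(NucleotideParameters.tn93(2.5, 2.5, fv))
        hky = build_gtr(NucleotideParameters.hky85(2.5, fv))
        np.testing.assert_allclose(tn.Q, hky.Q, atol=1e-12)

    def test_detailed_balance(self, nuc_alphabet):
        fv = FrequencyVector(nuc_alphabet, np.array([0.4, 0.3, 0.2, 0.1]))
        rm = build_gtr(NucleotideParameters.gtr([1, 2, 3, 4, 5, 6], fv))
        assert_valid_rate_matrix(rm)
        assert_detailed_balance(rm)

    def test_negative_exchangeability_rejected(self, nuc_alphabet):
        with pytest.raises(MatrixError, match="negative"):
            NucleotideParameters.gtr([1, -1, 1, 1, 1, 1], FrequencyVector.uniform(nuc_alphabet))


class TestEmpiricalModels:
    def test_wag_default_frequencies_stationary(self):
        rm = build_empirical("WAG")
        assert len(rm.alphabet) == 20
        assert_valid_rate_matrix(rm)
        assert_detailed_balance(rm)

    def test_uniform_frequencies_detailed_balance_exact(self, aa_alphabet):
        rm = build_empirical("WAG", FrequencyVector.uniform(aa_alphabet))
        np.testing.assert_allclose(rm.Q, rm.Q.T, atol=1e-12)

    @pytest.mark.parametrize("name", ["JTT", "LG", "DAYHOFF", "mtMAM", "mtREV24"])
    def test_all_bundled_models_load(self, name):
        assert_valid_rate_matrix(build_empirical(name))

    def test_unknown_model_name(self):
        with pytest.raises(MatrixError, match="unknown"):
            build_empirical("NOSUCH")

    def test_unbundled_model_clear_error(self):
        with pytest.raises(MatrixError, match="not.*bundled"):
            build_empirical("ECM_restricted")

    def test_synthetic_file_loader(self, tmp_path):
        # synthetic 3-state exchangeability file exercising the generic loader
        p = tmp_path / "toy.dat"
        p.write_text(
            "# state order: x y z\n"
            "2.0\n"
            "1.0 4.0\n"
            "\n"
            "0.5 0.25 0.25\n"
        )
        data = load_empirical_data(str(p), "toy")
        assert data.exchangeabilities[1, 0] == 2.0
        assert data.exchangeabilities[2, 1] == 4.0
        rm = build_empirical(data)
        assert_valid_rate_matrix(rm)

    def test_restricted_codon_model_keeps_multi_step_zeros(self, tmp_path, codon_alphabet):
        """A restricted empirical codon file (synthetic: single-nucleotide
        pairs only) must yield zero rates for multi-nucleotide changes."""
        states = codon_alphabet.states
        n = len(states)
        lines = [f"# state order: {' '.join(states)}"]
        for i in range(1, n):
            row = []
            for j in range(i):
                ndiff = sum(a != b for a, b in zip(states[i], states[j]))
                row.append("1.0" if ndiff == 1 else "0.0")
            lines.append(" ".join(row))
        lines.append("")
        lines.append(" ".join([f"{1/n:.10f}"] * n))
        p = tmp_path / "ecm_restricted_synthetic.dat"
        p.write_text("\n".join(lines) + "\n")
        rm = build_empirical(load_empirical_data(str(p), "ecm_restricted_synthetic"))
        i, j = codon_alphabet.index_of("AAA"), codon_alphabet.index_of("ACG")
        assert rm.Q[i, j] == 0.0

    def test_asymmetric_data_rejected(self, tmp_path):
        from seqevolve.matrices import EmpiricalModelData

        with pytest.raises(MatrixError, match="asymmetric"):
            EmpiricalModelData("bad", np.array([[0, 1.0], [2.0, 0]]),
                               FrequencyVector(build_alphabet("custom", ["a", "b"]),
                                               np.array([0.5, 0.5])))


class TestMechanisticCodon:
    def test_neutral_equals_mutation_matrix(self, uniform_codon_freqs):
        """alpha = beta, kappa = 1, uniform frequencies: selection cancels
        and Q is the neutral single-step mutation matrix up to scaling."""
        rm = build_mechanistic_codon(
            MechanisticCodonParameters("MG", 1.0, 1.0, uniform_codon_freqs)
        )
        alphabet = rm.alphabet
        for i, ci in enumerate(alphabet.states):
            for j, cj in enumerate(alphabet.states):
                if i == j:
                    continue
                ndiff = sum(a != b for a, b in zip(ci, cj))
                if ndiff > 1:
                    assert rm.Q[i, j] == 0
        off = rm.Q[rm.Q > 0]
        np.testing.assert_allclose(off, off[0], atol=1e-12)

    def test_beta_zero_kills_nonsynonymous_rates(self, uniform_codon_freqs, codon_alphabet):
        rm = build_mechanistic_codon(
            MechanisticCodonParameters("MG", 1.0, 0.0, uniform_codon_freqs)
        )
        i, j = codon_alphabet.index_of("AAA"), codon_alphabet.index_of("AAT")  # Lys -> Asn
        assert rm.Q[i, j] == 0
        i, j = codon_alphabet.index_of("AAA"), codon_alphabet.index_of("AAG")  # Lys -> Lys
        assert rm.Q[i, j] > 0

    def test_example_rate_ratio(self, uniform_codon_freqs, codon_alphabet):
        """omega = 0.75, kappa = 3.25: synonymous transition AAA->AAG over
        nonsynonymous transversion AAA->AAT is (1 * 3.25) / (0.75 * 1)."""
        rm = build_mechanistic_codon(
            MechanisticCodonParameters.from_omega(0.75, uniform_codon_freqs, kappa=3.25)
        )
        i = codon_alphabet.index_of("AAA")
        ratio = rm.Q[i, codon_alphabet.index_of("AAG")] / rm.Q[i, codon_alphabet.index_of("AAT")]
        assert ratio == pytest.approx(3.25 / 0.75)

    def test_gy_and_mg_coincide_for_uniform_frequencies(self, uniform_codon_freqs):
        gy = build_mechanistic_codon(
            MechanisticCodonParameters("GY", 1.0, 0.5, uniform_codon_freqs, kappa=2.0)
        )
        mg = build_mechanistic_codon(
            MechanisticCodonParameters("MG", 1.0, 0.5, uniform_codon_freqs, kappa=2.0)
        )
        np.testing.assert_allclose(gy.Q, mg.Q, atol=1e-10)

    def test_invalid_alpha(self, uniform_codon_freqs):
        with pytest.raises(MatrixError, match="alpha"):
            build_mechanistic_codon(
                MechanisticCodonParameters("MG", 0.0, 1.0, uniform_codon_freqs)
            )


class TestMutSel:
    def test_equal_fitnesses_neutral(self, nuc_alphabet):
        rm = build_mutsel(MutSelParameters(nuc_alphabet, np.zeros(4)))
        off = rm.Q[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, off[0], atol=1e-12)
        assert_valid_rate_matrix(rm)

    def test_stationary_distribution_is_softmax_of_fitness(self, nuc_alphabet):
        """With symmetric mutation, the stationary distribution is
        e^f / sum e^f; the builder's null-space solve must agree."""
        f = np.array([0.0, 1.0, -0.5, 0.3])
        rm = build_mutsel(MutSelParameters(nuc_alphabet, f))
        expected = np.exp(f) / np.exp(f).sum()
        np.testing.assert_allclose(rm.frequencies.values, expected, atol=1e-8)

    def test_flux_ratio_identity(self, nuc_alphabet):
        """Q_ij / Q_ji = (mu_ij / mu_ji) * e^(f_j - f_i)."""
        f = np.array([0.2, -0.7, 1.1, 0.0])
        mu = {("A", "C"): 1.0, ("C", "A"): 2.0, ("A", "G"): 1.5, ("G", "A"): 1.5,
              ("A", "T"): 0.5, ("T", "A"): 0.5, ("C", "G"): 1.0, ("G", "C"): 1.0,
              ("C", "T"): 3.0, ("T", "C"): 3.0, ("G", "T"): 1.0, ("T", "G"): 1.0}
        rm = build_mutsel(MutSelParameters(nuc_alphabet, f, mu=mu), scale=False)
        i, j = 0, 1  # A, C
        expected = (1.0 / 2.0) * np.exp(f[1] - f[0])
        assert rm.Q[i, j] / rm.Q[j, i] == pytest.approx(expected, rel=1e-10)

    def test_codon_mutsel_single_step_only(self, codon_alphabet):
        rng = np.random.default_rng(5)
        f = rng.normal(size=61) * 0.5
        rm = build_mutsel(MutSelParameters(codon_alphabet, f))
        i, j = codon_alphabet.index_of("AAA"), codon_alphabet.index_of("ACG")
        assert rm.Q[i, j] == 0
        assert_valid_rate_matrix(rm)

    def test_fixation_factor_continuity_at_zero(self):
        S = np.array([-1e-12, 0.0, 1e-12, 2.0, -2.0])
        F = fixation_factor(S)
        np.testing.assert_allclose(F[:3], 1.0)
        assert F[3] == pytest.approx(2 / (1 - np.exp(-2)))
        assert F[4] == pytest.approx(-2 / (1 - np.exp(2)))


class TestCustomMatrices:
    def test_mk_three_state_uniform_stationary(self):
        a = build_alphabet("custom", ["0", "1", "2"])
        rm = build_custom(np.ones((3, 3)), a)
        np.testing.assert_allclose(rm.frequencies.values, 1 / 3, atol=1e-10)

    def test_two_state_balance(self):
        a = build_alphabet("custom", ["u", "v"])
        rm = build_custom(np.array([[0, 1.0], [2.0, 0]]), a)
        np.testing.assert_allclose(rm.frequencies.values, [2 / 3, 1 / 3], atol=1e-10)

    def test_user_diagonal_ignored(self):
        a = build_alphabet("custom", ["u", "v"])
        rm = build_custom(np.array([[99.0, 1.0], [2.0, -77.0]]), a, scale=False)
        np.testing.assert_allclose(rm.Q.sum(axis=1), 0, atol=1e-12)

    def test_negative_off_diagonal_reports_indices(self):
        a = build_alphabet("custom", ["u", "v"])
        with pytest.raises(MatrixError, match=r"\(0,1\)"):
            build_custom(np.array([[0, -1.0], [2.0, 0]]), a)

    def test_reducible_matrix_warns(self):
        a = build_alphabet("custom", ["u", "v", "w"])
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = 1.0  # state w unreachable
        with pytest.warns(UserWarning, match="reducible"):
            build_custom(M, a, scale=False)


class TestScaling:
    def test_idempotent(self):
        rm = jc69_matrix()
        again = scale_matrix(rm)
        np.testing.assert_allclose(again.Q, rm.Q)

    def test_scale_invariance(self, nuc_alphabet):
        fv = FrequencyVector(nuc_alphabet, np.array([0.4, 0.3, 0.2, 0.1]))
        params = NucleotideParameters.gtr([1, 2, 3, 4, 5, 6], fv)
        a = build_gtr(params)
        b = build_gtr(NucleotideParameters.gtr([7, 14, 21, 28, 35, 42], fv))
        np.testing.assert_allclose(a.Q, b.Q, atol=1e-12)
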