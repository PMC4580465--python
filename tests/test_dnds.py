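"""Substitution counting, site opportunities, and mutation-selection dN/dS."""

import itertools

import numpy as np
import pytest

from seqevolve import (
    MutSelParameters,
    Partition,
    STANDARD_CODE,
    build_alphabet,
    build_mutsel,
    count_dnds,
    evolve,
    expected_dnds_from_mutsel,
    parse_newick,
    site_opportunities,
)
from seqevolve.dnds import CountingError, opportunity_arrays, pair_tables
from seqevolve.matrices import _mu_table, fixation_factor
from seqevolve.validation import mg94


def enumerate_opportunities(codon):
    """Independent brute-force oracle: loop over the 9 mutations, skip
    stops, classify by direct translation."""
    syn = tot = 0
    for pos, y in itertools.product(range(3), "ACGT"):
        if y == codon[pos]:
            continue
        nb = codon[:pos] + y + codon[pos + 1 :]
        if nb in ("TAA", "TAG", "TGA"):
            continue
        tot += 1
        if STANDARD_CODE.translate(nb) == STANDARD_CODE.translate(codon):
            syn += 1
    S = 3 * syn / tot
    return 3 - S, S


class TestSiteOpportunities:
    def test_phe_hand_count(self):
        N, S = site_opportunities("TTT")
        assert S == pytest.approx(1 / 3)
        assert N == pytest.approx(8 / 3)

    def test_met_has_no_synonymous_sites(self):
        _, S = site_opportunities("ATG")
        assert S == 0.0

    def test_partition_of_opportunity_all_codons(self, codon_alphabet):
        for codon in codon_alphabet.states:
            N, S = site_opportunities(codon)
            assert N + S == pytest.approx(3.0)

    def test_matches_bruteforce_enumeration(self, codon_alphabet):
        for codon in codon_alphabet.states:
            N, S = site_opportunities(codon)
            N2, S2 = enumerate_opportunities(codon)
            assert (N, S) == pytest.approx((N2, S2))

    def test_kappa_weighting_shifts_synonymous_share(self):
        """Transitions are enriched for synonymous changes, so kappa > 1
        raises S (e.g. TTT: the only synonymous neighbor TTC is a
        transition)."""
        _, S1 = site_opportunities("TTT")
        _, S2 = site_opportunities("TTT", mu=3.25)
        assert S2 > S1
        # TTT: one transition per position, only TTC synonymous:
        # S = 3*kappa / (3*kappa + 6)
        assert S2 == pytest.approx(3 * 3.25 / (3 * 3.25 + 6))

    def test_weighted_still_partitions(self, codon_alphabet):
        for codon in codon_alphabet.states[::7]:
            N, S = site_opportunities(codon, mu=2.5)
            assert N + S == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(CountingError, match="stop"):
            site_opportunities("TGA")


class TestPairTables:
    def test_single_synonymous_change(self, codon_alphabet):
        tab = pair_tables()
        i, j = codon_alphabet.index_of("AAA"), codon_alphabet.index_of("AAG")
        assert tab.syn[i, j] == 1.0 and tab.nonsyn[i, j] == 0.0

    def test_single_nonsynonymous_change(self, codon_alphabet):
        tab = pair_tables()
        i, j = codon_alphabet.index_of("TTT"), codon_alphabet.index_of("ATT")
        assert tab.syn[i, j] == 0.0 and tab.nonsyn[i, j] == 1.0

    def test_double_change_path_average(self, codon_alphabet):
        """AAA -> ACG: both orders give one synonymous plus one
        nonsynonymous step (hand enumeration)."""
        tab = pair_tables()
        i, j = codon_alphabet.index_of("AAA"), codon_alphabet.index_of("ACG")
        assert tab.syn[i, j] == pytest.approx(1.0)
        assert tab.nonsyn[i, j] == pytest.approx(1.0)

    def test_step_totals_match_ndiff_when_paths_exist(self, codon_alphabet):
        tab = pair_tables()
        total = tab.syn + tab.nonsyn
        counted = total > 0
        assert np.all(total[counted] == tab.ndiff[counted])

    def test_symmetric_total_change_count(self):
        tab = pair_tables()
        np.testing.assert_array_equal(tab.ndiff, tab.ndiff.T)


class TestCountDnds:
    def _two_site_alignment(self, parent_codons, child_codons):
        """Minimal one-branch alignment built directly from codon strings."""
        from seqevolve.evolve import PartitionResult, SimulatedAlignment
        alphabet = build_alphabet("codon")
        tree = parse_newick("(tip:0.1);")
        size = len(parent_codons)
        part = Partition(size=size, model="m")
        pr = PartitionResult(part, alphabet, np.zeros(size, dtype=np.int64),
                             ["m"] * size, np.ones(size))
        enc = lambda cs: np.array([alphabet.index_of(c) for c in cs], dtype=np.int64)
        node_names = {id(tree): "root", id(tree.children[0]): "tip"}
        return SimulatedAlignment(
            tree, [pr],
            {"root": [enc(parent_codons)], "tip": [enc(child_codons)]},
            ["tip"], ["root"], node_names,
        )

    def test_single_synonymous_change_gives_zero_omega(self):
        aln = self._two_site_alignment(["AAA"], ["AAG"])
        c = count_dnds(aln, scope="global")
        assert (c.n, c.s) == (0.0, 1.0)
        assert c.omega == 0.0

    def test_hand_classified_two_sites(self):
        # AAA->AAG synonymous; TTT->ATT nonsynonymous (Phe -> Ile)
        aln = self._two_site_alignment(["AAA", "TTT"], ["AAG", "ATT"])
        c = count_dnds(aln, scope="global")
        assert (c.n, c.s) == (1.0, 1.0)

    def test_omega_missing_when_no_synonymous_changes(self):
        aln = self._two_site_alignment(["AAA"], ["AAT"])
        c = count_dnds(aln, scope="global")
        assert np.isnan(c.omega)

    def test_missing_ancestors_instructive_error(self):
        tree = parse_newick("(a:0.05,b:0.05);")
        aln = evolve(tree, [Partition(size=10, model="m")], {"m": mg94(1.0)},
                     seed=1, keep_ancestors=False)
        with pytest.raises(CountingError, match="ancestors"):
            count_dnds(aln)

    def test_neutral_simulation_recovers_omega_one(self):
        tree = parse_newick("(a:0.1,b:0.1);")
        aln = evolve(tree, [Partition(size=40_000, model="m")], {"m": mg94(1.0)}, seed=6)
        c = count_dnds(aln, scope="global")
        assert c.omega_corrected == pytest.approx(1.0, abs=0.05)

    def test_scopes_consistent(self):
        tree = parse_newick("(a:0.1,b:0.1);")
        aln = evolve(tree, [Partition(size=5_000, model="m")], {"m": mg94(0.5)}, seed=3)
        g = count_dnds(aln, scope="global")
        b = count_dnds(aln, scope="per_branch")
        s = count_dnds(aln, scope="per_site")
        assert np.sum(b.n) == pytest.approx(g.n)
        assert np.sum(s.s) == pytest.approx(g.s)
        assert np.sum(s.N) == pytest.approx(g.N)

    def test_taxon_relabeling_invariance(self):
        tree1 = parse_newick("(a:0.1,b:0.1);")
        tree2 = parse_newick("(x:0.1,y:0.1);")
        m = {"m": mg94(0.5)}
        c1 = count_dnds(evolve(tree1, [Partition(size=3_000, model="m")], m, seed=9))
        c2 = count_dnds(evolve(tree2, [Partition(size=3_000, model="m")], m, seed=9))
        assert c1.omega == pytest.approx(c2.omega)


class TestExpectedDndsFromMutsel:
    def test_equal_fitnesses_neutral(self, codon_alphabet):
        params = MutSelParameters(codon_alphabet, np.zeros(61))
        assert expected_dnds_from_mutsel(params) == pytest.approx(1.0)

    def test_unequal_amino_acid_fitnesses_purifying(self):
        rng = np.random.default_rng(0)
        aas = sorted(set(STANDARD_CODE.table.values()))
        fit = dict(zip(aas, rng.normal(scale=1.0, size=20)))
        params = MutSelParameters.from_amino_acid_fitnesses(fit)
        assert expected_dnds_from_mutsel(params) < 1.0

    def test_two_amino_acid_toy_against_enumeration(self, codon_alphabet):
        """Lys (fitness 0) vs Asn (fitness -2): brute-force flux ratio over
        the enumerated single-step pairs must match the formula."""
        f = np.array([
            0.0 if STANDARD_CODE.translate(c) == "K"
            else (-2.0 if STANDARD_CODE.translate(c) == "N" else -60.0)
            for c in codon_alphabet.states
        ])
        params = MutSelParameters(codon_alphabet, f)
        got = expected_dnds_from_mutsel(params)

        # independent oracle: direct enumeration with softmax stationary
        pi = np.exp(f) / np.exp(f).sum()
        mu = _mu_table(None, None)
        num = den = 0.0
        for i, ci in enumerate(codon_alphabet.states):
            for j, cj in enumerate(codon_alphabet.states):
                diffs = [k for k in range(3) if ci[k] != cj[k]]
                if len(diffs) != 1:
                    continue
                if STANDARD_CODE.translate(ci) == STANDARD_CODE.translate(cj):
                    continue
                S = f[j] - f[i]
                flux0 = pi[i] * mu[(ci[diffs[0]], cj[diffs[0]])]
                num += flux0 * float(fixation_factor(S))
                den += flux0
        assert got == pytest.approx(num / den, rel=1e-9)

    def test_consistency_with_counted_simulation(self, codon_alphabet):
        """The analytic expectation must agree with counting on a long
        simulation under the same mutation-selection model."""
        rng = np.random.default_rng(4)
        aas = sorted(set(STANDARD_CODE.table.values()))
        fit = dict(zip(aas, 0.8 * rng.normal(size=20)))
        params = MutSelParameters.from_amino_acid_fitnesses(fit)
        expected = expected_dnds_from_mutsel(params)

        rm = build_mutsel(params)
        tree = parse_newick("(a:0.05,b:0.05);")
        aln = evolve(tree, [Partition(size=120_000, model="ms")], {"ms": rm}, seed=12)
        counted = count_dnds(aln, scope="global").omega_corrected
        assert counted == pytest.approx(expected, abs=0.05)

    def test_mutsel_tip_frequencies_match_softmax(self, nuc_alphabet):
        """Long-branch simulation under a nucleotide mutation-selection
        model reaches e^f / sum e^f."""
        f = np.array([0.5, 0.0, -0.5, 0.2])
        rm = build_mutsel(MutSelParameters(nuc_alphabet, f))
        tree = parse_newick("(a:30,b:30);")
        n = 50_000
        aln = evolve(tree, [Partition(size=n, model="ms")], {"ms": rm}, seed=13)
        pooled = np.concatenate([aln.states["a"][0], aln.states["b"][0]])
        freqs = np.bincount(pooled, minlength=4) / pooled.size
        expected = np.exp(f) / np.exp(f).sum()
        sigma = np.sqrt(expected * (1 - expected) / pooled.size)
        assert np.all(np.abs(freqs - expected) < 3 * sigma)
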