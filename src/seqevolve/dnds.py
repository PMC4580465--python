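"""Suzuki-Gojobori-style dN/dS counting on simulated trees, and expected
dN/dS under mutation-selection models.

Counting uses the simulator's true ancestral sequences, so every branch
provides parent -> child codon pairs at each site.  Observed changes are
classified as synonymous or nonsynonymous; codons differing at several
positions are resolved by averaging over all minimal single-step paths
through sense codons (paths through stop codons are discarded).  Mutational
opportunities per parent codon partition its 3 sites into synonymous (S)
and nonsynonymous (N) fractions, N + S = 3; mutations to stop codons are
excluded throughout.  Opportunities can be weighted by the simulation's own
mutational model (kappa / mu and target nucleotide frequencies), which is
required for counted dN/dS to match the simulated omega when the mutation
process is biased.

The observed ratio is omega_hat = (n/N) / (s/S); with s = 0 it is reported
as missing (NaN), not infinity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .alphabets import (
    AlphabetKind,
    GeneticCode,
    NUCLEOTIDES,
    STANDARD_CODE,
    build_alphabet,
    codon_diff_positions,
)
from .evolve import SimulatedAlignment
from .matrices import MutSelParameters, _mu_table, build_mutsel, fixation_factor


class CountingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# precomputed codon-pair tables


@dataclass(frozen=True)
class CodonPairTables:
    """Per ordered codon pair: number of differing positions and the
    path-averaged synonymous / nonsynonymous change counts."""

    states: tuple[str, ...]
    ndiff: np.ndarray  # int, 61x61
    syn: np.ndarray  # float, path-averaged synonymous steps
    nonsyn: np.ndarray  # float, path-averaged nonsynonymous steps


_TABLE_CACHE: dict[int, CodonPairTables] = {}


def _path_average(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """Average (syn, nonsyn) step counts over minimal single-step paths from
    c1 to c2 through sense codons, equally weighted; (0, 0) if every path
    crosses a stop codon."""
    positions = codon_diff_positions(c1, c2)
    syn_tot = nonsyn_tot = 0.0
    n_valid = 0
    for order in itertools.permutations(positions):
        current = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate(current) == code.translate(nxt):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_valid += 1
    if n_valid == 0:
        return 0.0, 0.0
    return syn_tot / n_valid, nonsyn_tot / n_valid


def pair_tables(code: GeneticCode = STANDARD_CODE) -> CodonPairTables:
    key = id(code)
    if key not in _TABLE_CACHE:
        states = tuple(sorted(code.table))
        n = len(states)
        ndiff = np.zeros((n, n), dtype=np.int64)
        syn = np.zeros((n, n))
        nonsyn = np.zeros((n, n))
        for i, ci in enumerate(states):
            for j, cj in enumerate(states):
                if i == j:
                    continue
                ndiff[i, j] = len(codon_diff_positions(ci, cj))
                syn[i, j], nonsyn[i, j] = _path_average(ci, cj, code)
        _TABLE_CACHE[key] = CodonPairTables(states, ndiff, syn, nonsyn)
    return _TABLE_CACHE[key]


# ---------------------------------------------------------------------------
# site opportunities


def _neighbor_weights(
    codon: str,
    code: GeneticCode,
    mu: Mapping[tuple[str, str], float] | None,
    target_freqs: np.ndarray | None,
) -> tuple[float, float]:
    """(synonymous, total) mutational flux over the non-stop single-
    nucleotide neighbors of ``codon``."""
    nuc_index = {x: i for i, x in enumerate(NUCLEOTIDES)}
    syn_w = tot_w = 0.0
    for pos in range(3):
        x = codon[pos]
        for y in NUCLEOTIDES:
            if y == x:
                continue
            neighbor = codon[:pos] + y + codon[pos + 1 :]
            if code.is_stop(neighbor):
                continue
            w = 1.0 if mu is None else mu[(x, y)]
            if target_freqs is not None:
                tf = np.asarray(target_freqs, dtype=float)
                w *= tf[pos, nuc_index[y]] if tf.ndim == 2 else tf[nuc_index[y]]
            tot_w += w
            if code.translate(codon) == code.translate(neighbor):
                syn_w += w
    return syn_w, tot_w


def site_opportunities(
    codon: str,
    code: GeneticCode = STANDARD_CODE,
    mu: Mapping[tuple[str, str], float] | float | None = None,
    target_freqs: np.ndarray | None = None,
) -> tuple[float, float]:
    """(N, S): nonsynonymous and synonymous site opportunities of a sense
    codon, N + S = 3.

    With no mutational model every non-stop single-nucleotide neighbor
    counts equally; passing ``mu`` (a kappa value or an ordered-pair rate
    table) and/or target nucleotide frequencies (length-4 global or 3x4
    position-specific) weights neighbors by mutational flux, S = 3 *
    syn_flux / total_flux.
    """
    if code.is_stop(codon):
        raise CountingError(f"stop codon {codon!r} has no site opportunities")
    if codon not in code.table:
        raise CountingError(f"{codon!r} is not a sense codon")
    mu_table = None
    if mu is not None:
        mu_table = _mu_table(mu, None) if isinstance(mu, (int, float)) else _mu_table(None, mu)
    syn_w, tot_w = _neighbor_weights(codon, code, mu_table, target_freqs)
    if tot_w == 0:
        raise CountingError(f"codon {codon!r} has no reachable neighbors")
    S = 3.0 * syn_w / tot_w
    return 3.0 - S, S


def opportunity_arrays(
    code: GeneticCode = STANDARD_CODE,
    mu: Mapping[tuple[str, str], float] | float | None = None,
    target_freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (N, S) over the codon alphabet in canonical order."""
    states = tuple(sorted(code.table))
    N = np.empty(len(states))
    S = np.empty(len(states))
    for i, c in enumerate(states):
        N[i], S[i] = site_opportunities(c, code, mu, target_freqs)
    return N, S


# ---------------------------------------------------------------------------
# counting over a simulated alignment


@dataclass(frozen=True)
class SubstitutionCounts:
    """Observed change counts and opportunities at some scope.

    ``n``/``s`` are nonsynonymous/synonymous change counts; ``N``/``S`` the
    accumulated opportunities of the parent codons (branch-site weighted).
    Scalars for global scope, arrays with ``labels`` otherwise.
    """

    scope: str
    n: np.ndarray | float
    s: np.ndarray | float
    N: np.ndarray | float
    S: np.ndarray | float
    labels: list | None = None

    @property
    def omega(self) -> np.ndarray | float:
        """(n/N) / (s/S); NaN where undefined (s = 0 or empty opportunity)."""
        n, s = np.asarray(self.n, dtype=float), np.asarray(self.s, dtype=float)
        N, S = np.asarray(self.N, dtype=float), np.asarray(self.S, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = (n / N) / (s / S)
        w = np.where((s > 0) & (N > 0) & (S > 0), w, np.nan)
        return float(w) if w.ndim == 0 else w

    @property
    def dn(self) -> np.ndarray | float:
        """Multiple-hit-corrected nonsynonymous rate per nonsynonymous site:
        -(3/4) ln(1 - 4 (n/N) / 3), the Jukes-Cantor-style correction of the
        Nei-Gojobori procedure."""
        return self._corrected(self.n, self.N)

    @property
    def ds(self) -> np.ndarray | float:
        """Multiple-hit-corrected synonymous rate per synonymous site."""
        return self._corrected(self.s, self.S)

    @property
    def omega_corrected(self) -> np.ndarray | float:
        """dn / ds with the multiple-hit correction applied to each rate.

        Endpoint counting misses back- and multiple substitutions within a
        branch, which depresses the faster class (usually synonymous) on
        long branches; the correction removes that saturation.  NaN where
        undefined.
        """
        dn, ds = np.asarray(self.dn, dtype=float), np.asarray(self.ds, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = dn / ds
        w = np.where(np.asarray(self.s, dtype=float) > 0, w, np.nan)
        return float(w) if w.ndim == 0 else w

    @staticmethod
    def _corrected(count, sites) -> np.ndarray | float:
        c = np.asarray(count, dtype=float)
        m = np.asarray(sites, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = c / m
            d = np.where(p < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(p, 0.749999) / 3.0), np.nan)
        d = np.where(m > 0, d, np.nan)
        return float(d) if d.ndim == 0 else d


def count_dnds(
    aln: SimulatedAlignment,
    code: GeneticCode = STANDARD_CODE,
    scope: str = "global",
    mu: Mapping[tuple[str, str], float] | float | None = None,
    target_freqs: np.ndarray | None = None,
) -> SubstitutionCounts:
    """Count synonymous/nonsynonymous changes over every branch of a
    simulated alignment that retained its ancestral sequences.

    scope: ``global`` (one ratio), ``per_site`` (arrays over codon sites),
    or ``per_branch`` (arrays labeled by child-node name).  ``mu`` /
    ``target_freqs`` weight the opportunities by the mutational model (pass
    the simulation's kappa to reproduce its omega under biased mutation).
    """
    if scope not in ("global", "per_site", "per_branch"):
        raise CountingError(f"unknown scope {scope!r}")
    if not aln.ancestor_names:
        raise CountingError(
            "no ancestral sequences in the alignment; simulate with "
            "keep_ancestors=True so branch-wise changes are observable"
        )
    codon_parts = [
        (k, pr) for k, pr in enumerate(aln.partitions)
        if pr.alphabet.kind is AlphabetKind.CODON
    ]
    if not codon_parts:
        raise CountingError("no codon partitions to count")
    tables = pair_tables(code)
    Nvec, Svec = opportunity_arrays(code, mu, target_freqs)
    n_sites = sum(pr.partition.size for _, pr in codon_parts)

    branches: list[tuple[str, str]] = []  # (parent name, child name)

    def collect(node) -> None:
        pname = aln.node_names[id(node)]
        for child in node.children:
            branches.append((pname, aln.node_names[id(child)]))
            collect(child)

    collect(aln.tree)

    if scope == "per_branch":
        labels = [c for _, c in branches]
        n = np.zeros(len(branches))
        s = np.zeros(len(branches))
        N = np.zeros(len(branches))
        S = np.zeros(len(branches))
        for b, (pname, cname) in enumerate(branches):
            for k, _pr in codon_parts:
                p, c = aln.states[pname][k], aln.states[cname][k]
                n[b] += tables.nonsyn[p, c].sum()
                s[b] += tables.syn[p, c].sum()
                N[b] += Nvec[p].sum()
                S[b] += Svec[p].sum()
        return SubstitutionCounts(scope, n, s, N, S, labels)

    if scope == "per_site":
        n = np.zeros(n_sites)
        s = np.zeros(n_sites)
        N = np.zeros(n_sites)
        S = np.zeros(n_sites)
        for pname, cname in branches:
            offset = 0
            for k, pr in codon_parts:
                size = pr.partition.size
                p, c = aln.states[pname][k], aln.states[cname][k]
                sl = slice(offset, offset + size)
                n[sl] += tables.nonsyn[p, c]
                s[sl] += tables.syn[p, c]
                N[sl] += Nvec[p]
                S[sl] += Svec[p]
                offset += size
        return SubstitutionCounts(scope, n, s, N, S, list(range(1, n_sites + 1)))

    n_tot = s_tot = N_tot = S_tot = 0.0
    for pname, cname in branches:
        for k, _pr in codon_parts:
            p, c = aln.states[pname][k], aln.states[cname][k]
            n_tot += float(tables.nonsyn[p, c].sum())
            s_tot += float(tables.syn[p, c].sum())
            N_tot += float(Nvec[p].sum())
            S_tot += float(Svec[p].sum())
    return SubstitutionCounts(scope, n_tot, s_tot, N_tot, S_tot)


# ---------------------------------------------------------------------------
# expected dN/dS from mutation-selection parameters


def expected_dnds_from_mutsel(
    params: MutSelParameters, code: GeneticCode = STANDARD_CODE
) -> float:
    """Expected dN/dS of a codon mutation-selection model.

    dN is the stationary nonsynonymous substitution flux relative to the
    neutral (mutation-only) nonsynonymous flux,

        dN = sum_NS pi_i mu_ij F(S_ij) / sum_NS pi_i mu_ij,

    and dS is the analogous ratio over synonymous pairs (identically 1 when
    fitnesses are amino-acid-level, since then S_ij = 0 within amino
    acids); both sums run over ordered single-nucleotide-step sense-codon
    pairs.  Returns NaN when the stationary distribution is degenerate.
    """
    if params.alphabet.kind is not AlphabetKind.CODON:
        raise CountingError("expected dN/dS requires codon mutation-selection parameters")
    rm = build_mutsel(params, scale=False)
    pi = rm.frequencies.values
    if np.max(pi) > 1.0 - 1e-9:
        return float("nan")
    alphabet = build_alphabet("codon")
    mu = _mu_table(params.kappa, params.mu)
    f = params.fitnesses
    num_n = den_n = num_s = den_s = 0.0
    for i, ci in enumerate(alphabet.states):
        for j, cj in enumerate(alphabet.states):
            if i == j or len(codon_diff_positions(ci, cj)) != 1:
                continue
            pos = codon_diff_positions(ci, cj)[0]
            flux0 = pi[i] * mu[(ci[pos], cj[pos])]
            flux = flux0 * float(fixation_factor(f[j] - f[i]))
            if code.translate(ci) == code.translate(cj):
                num_s += flux
                den_s += flux0
            else:
                num_n += flux
                den_n += flux0
    if den_n == 0 or den_s == 0 or num_s == 0:
        return float("nan")
    return (num_n / den_n) / (num_s / den_s)
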