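"""Instantaneous rate matrices Q for all supported model families.

Families
--------
* GTR and nested nucleotide models (HKY85, TN93, JC69) via exchangeabilities
  r_xy and stationary frequencies: Q_ij = r_ij * pi_j.
* Empirical amino-acid models (WAG, JTT, LG, DAYHOFF, mtMAM, mtREV24) loaded
  from plain-text exchangeability files, optionally with user frequencies
  ("+F" usage).
* Mechanistic codon models in GY style (target factor = codon frequency) and
  MG style (target factor = target-nucleotide frequency at the changed
  position), parameterized by synonymous/nonsynonymous rate factors alpha and
  beta (omega = beta/alpha) and a transition-transversion bias kappa or full
  mutational rates mu_xy.
* Halpern-Bruno mutation-selection models for nucleotides and codons:
  Q_ij = mu_ij * S_ij / (1 - exp(-S_ij)) with scaled selection coefficient
  S_ij = f_j - f_i.
* Fully custom matrices over any alphabet.

All matrices are scaled by default so the expected substitution rate at the
stationary distribution is 1 (branch lengths then mean expected substitutions
per site, or per codon site for codon models).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import scipy.linalg

from .alphabets import (
    Alphabet,
    AlphabetKind,
    GeneticCode,
    NUCLEOTIDES,
    STANDARD_CODE,
    build_alphabet,
    codon_diff_positions,
    is_transition,
)
from .frequencies import FrequencyVector

NUCLEOTIDE_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))

# PAML's conventional amino-acid order used by the empirical data files.
PAML_AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

EMPIRICAL_MODEL_FILES = {
    "WAG": "wag.dat",
    "JTT": "jtt.dat",
    "LG": "lg.dat",
    "DAYHOFF": "dayhoff.dat",
    "mtMAM": "mtmam.dat",
    "mtREV24": "mtrev24.dat",
}
# Named in the model catalogue but without bundled numeric data.
EMPIRICAL_MODELS_UNBUNDLED = ("AB", "ECM_restricted", "ECM_unrestricted")


class MatrixError(ValueError):
    pass


def _stationary_from_null_space(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution as the normalized left null vector of Q."""
    ns = scipy.linalg.null_space(Q.T, rcond=1e-10)
    if ns.shape[1] == 0:
        raise MatrixError("rate matrix has no stationary distribution")
    if ns.shape[1] > 1:
        warnings.warn(
            "rate matrix is reducible (stationary distribution not unique); "
            "using one arbitrary component",
            stacklevel=3,
        )
    v = np.abs(ns[:, 0])
    return v / v.sum()


@dataclass(frozen=True)
class RateMatrix:
    """A validated instantaneous rate matrix with its state ordering."""

    alphabet: Alphabet
    Q: np.ndarray
    frequencies: FrequencyVector
    scaled: bool
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "Q", Q)
        n = len(self.alphabet)
        if Q.shape != (n, n):
            raise MatrixError(f"Q shape {Q.shape} does not match alphabet size {n}")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            i, j = np.argwhere(off < 0)[0]
            raise MatrixError(f"negative off-diagonal rate at ({i},{j})")
        rows = Q.sum(axis=1)
        if np.max(np.abs(rows)) > 1e-10:
            raise MatrixError(f"row sums not zero (max |sum| = {np.max(np.abs(rows))})")
        if self.scaled and abs(self.mean_rate - 1.0) > 1e-8:
            raise MatrixError(f"scaled flag set but mean rate is {self.mean_rate}")

    @property
    def mean_rate(self) -> float:
        """Expected substitution rate at the stationary distribution."""
        return float(-np.dot(self.frequencies.values, np.diag(self.Q)))


def scale_matrix(rm: RateMatrix) -> RateMatrix:
    """Rescale so the mean rate at stationarity is exactly 1 (idempotent)."""
    m = rm.mean_rate
    if m <= 0:
        raise MatrixError("cannot scale: mean substitution rate is zero")
    return RateMatrix(rm.alphabet, rm.Q / m, rm.frequencies, True, dict(rm.provenance))


def _finish(alphabet, Q, fv, scale, provenance) -> RateMatrix:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rm = RateMatrix(alphabet, Q, fv, False, provenance)
    return scale_matrix(rm) if scale else rm


# ---------------------------------------------------------------------------
# nucleotide models


@dataclass(frozen=True)
class NucleotideParameters:
    """GTR exchangeabilities over the 6 unordered nucleotide pairs.

    Nested models are constraints: :meth:`hky85` sets transition
    exchangeabilities to kappa and transversions to 1; :meth:`tn93` allows
    two transition rates; :meth:`jc69` is all-equal rates and frequencies.
    """

    exchangeabilities: Mapping[tuple[str, str], float]
    frequencies: FrequencyVector

    def rate(self, x: str, y: str) -> float:
        key = (x, y) if (x, y) in self.exchangeabilities else (y, x)
        try:
            return float(self.exchangeabilities[key])
        except KeyError:
            raise MatrixError(f"no exchangeability for pair {x}-{y}") from None

    @classmethod
    def gtr(cls, rates: Mapping[tuple[str, str], float] | list[float],
            frequencies: FrequencyVector) -> "NucleotideParameters":
        if not isinstance(rates, Mapping):
            if len(rates) != 6:
                raise MatrixError("need 6 exchangeabilities (AC, AG, AT, CG, CT, GT)")
            rates = dict(zip(NUCLEOTIDE_PAIRS, rates))
        vals = [float(rates[(x, y)] if (x, y) in rates else rates[(y, x)])
                for x, y in NUCLEOTIDE_PAIRS]
        if any(v < 0 for v in vals):
            raise MatrixError("negative exchangeability")
        if all(v == 0 for v in vals):
            raise MatrixError("all exchangeabilities zero")
        return cls(dict(zip(NUCLEOTIDE_PAIRS, vals)), frequencies)

    @classmethod
    def hky85(cls, kappa: float, frequencies: FrequencyVector) -> "NucleotideParameters":
        if kappa <= 0:
            raise MatrixError("kappa must be positive")
        rates = {p: (kappa if is_transition(*p) else 1.0) for p in NUCLEOTIDE_PAIRS}
        return cls(rates, frequencies)

    @classmethod
    def tn93(cls, kappa_ag: float, kappa_ct: float,
             frequencies: FrequencyVector) -> "NucleotideParameters":
        rates = {p: 1.0 for p in NUCLEOTIDE_PAIRS}
        rates[("A", "G")] = float(kappa_ag)
        rates[("C", "T")] = float(kappa_ct)
        return cls(rates, frequencies)

    @classmethod
    def jc69(cls) -> "NucleotideParameters":
        fv = FrequencyVector.uniform(build_alphabet("nucleotide"))
        return cls({p: 1.0 for p in NUCLEOTIDE_PAIRS}, fv)


def build_gtr(params: NucleotideParameters, scale: bool = True) -> RateMatrix:
    """Q_ij = r_ij * pi_j for the GTR family (time-reversible by construction)."""
    alphabet = params.frequencies.alphabet
    if alphabet.kind is not AlphabetKind.NUCLEOTIDE:
        raise MatrixError("GTR family requires the nucleotide alphabet")
    pi = params.frequencies.values
    n = len(alphabet)
    Q = np.zeros((n, n))
    for i, x in enumerate(alphabet.states):
        for j, y in enumerate(alphabet.states):
            if i != j:
                Q[i, j] = params.rate(x, y) * pi[j]
    return _finish(alphabet, Q, params.frequencies, scale,
                   {"family": "GTR", "exchangeabilities": dict(params.exchangeabilities)})


def jc69_matrix() -> RateMatrix:
    return build_gtr(NucleotideParameters.jc69())


# ---------------------------------------------------------------------------
# empirical models


@dataclass(frozen=True)
class EmpiricalModelData:
    """Symmetric exchangeabilities s_ij plus default frequencies for a named
    empirical model, in the canonical alphabet order."""

    name: str
    exchangeabilities: np.ndarray
    default_frequencies: FrequencyVector

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        object.__setattr__(self, "exchangeabilities", s)
        if s.shape[0] != s.shape[1]:
            raise MatrixError("exchangeability matrix not square")
        if not np.allclose(s, s.T):
            raise MatrixError(f"{self.name}: exchangeability matrix is asymmetric")
        if np.any(s < 0):
            raise MatrixError(f"{self.name}: negative exchangeability")


def load_empirical_data(source: str, name: str | None = None) -> EmpiricalModelData:
    """Load a lower-triangle exchangeability file.

    Layout: optional '#' comment lines, one of which must declare
    '# state order: ...'; then n-1 lines of the strict lower triangle; then
    one line of n stationary frequencies.  Values are re-ordered into the
    canonical alphabet ordering.
    """
    if name is None:
        name = source
    if "/" not in source and not source.endswith(".dat"):
        # registered model name
        if source in EMPIRICAL_MODELS_UNBUNDLED:
            raise MatrixError(
                f"model {source!r} is recognized but its numeric data is not "
                "bundled; supply the exchangeability file yourself"
            )
        try:
            fname = EMPIRICAL_MODEL_FILES[source]
        except KeyError:
            raise MatrixError(
                f"unknown empirical model {source!r}; available: "
                f"{sorted(EMPIRICAL_MODEL_FILES)}"
            ) from None
        text = resources.files("seqevolve.data").joinpath(fname).read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    order: list[str] | None = None
    numbers: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("state order:"):
                order = body.split(":", 1)[1].split()
            continue
        numbers.append([float(tok) for tok in line.split()])
    if order is None:
        raise MatrixError(f"{name}: missing '# state order:' header")
    n = len(order)
    tri, freqs = numbers[:-1], numbers[-1]
    if len(tri) != n - 1 or any(len(row) != i + 1 for i, row in enumerate(tri)):
        raise MatrixError(f"{name}: lower triangle does not match {n} states")
    if len(freqs) != n:
        raise MatrixError(f"{name}: expected {n} frequencies, got {len(freqs)}")
    s_file = np.zeros((n, n))
    for i, row in enumerate(tri):
        for j, val in enumerate(row):
            s_file[i + 1, j] = s_file[j, i + 1] = val
    if n == 20:
        alphabet = build_alphabet("amino_acid")
    elif n == 61:
        alphabet = build_alphabet("codon")
    else:
        alphabet = build_alphabet("custom", list(order))
    perm = [order.index(s) for s in alphabet.states]
    s = s_file[np.ix_(perm, perm)]
    fv = FrequencyVector(alphabet, np.asarray(freqs)[perm] / np.sum(freqs))
    return EmpiricalModelData(name, s, fv)


def build_empirical(
    data: EmpiricalModelData | str,
    frequencies: FrequencyVector | None = None,
    scale: bool = True,
) -> RateMatrix:
    """Q_ij = s_ij * pi_j with the model's default or user-supplied ("+F")
    frequencies."""
    if isinstance(data, str):
        data = load_empirical_data(data)
    fv = frequencies if frequencies is not None else data.default_frequencies
    alphabet = fv.alphabet
    if len(alphabet) != data.exchangeabilities.shape[0]:
        raise MatrixError("frequency vector does not match model alphabet size")
    Q = data.exchangeabilities * fv.values[np.newaxis, :]
    return _finish(alphabet, Q, fv, scale, {"family": "empirical", "name": data.name})


# ---------------------------------------------------------------------------
# mechanistic codon models (GY / MG)


def _mu_table(kappa: float | None,
              mu: Mapping[tuple[str, str], float] | None) -> dict[tuple[str, str], float]:
    """Ordered nucleotide mutation rates from kappa or an explicit table.

    An explicit table may give 6 unordered or 12 ordered pairs; missing
    reverse directions inherit the forward rate.
    """
    if mu is not None:
        out = {}
        for x, y in itertools.permutations(NUCLEOTIDES, 2):
            if (x, y) in mu:
                out[(x, y)] = float(mu[(x, y)])
            elif (y, x) in mu:
                out[(x, y)] = float(mu[(y, x)])
            else:
                raise MatrixError(f"no mutation rate for {x}->{y}")
            if out[(x, y)] < 0:
                raise MatrixError(f"negative mutation rate for {x}->{y}")
        return out
    k = 1.0 if kappa is None else float(kappa)
    if k <= 0:
        raise MatrixError("kappa must be positive")
    return {
        (x, y): (k if is_transition(x, y) else 1.0)
        for x, y in itertools.permutations(NUCLEOTIDES, 2)
    }


@dataclass(frozen=True)
class MechanisticCodonParameters:
    """GY/MG codon model parameters.

    alpha scales synonymous rates (dS), beta nonsynonymous rates (dN);
    omega = beta/alpha.  Specifying omega alone means alpha = 1, beta =
    omega.  The mutational level is either a kappa bias (transitions kappa,
    transversions 1) or a full mu table.
    """

    style: str  # "GY" | "MG"
    alpha: float
    beta: float
    frequencies: FrequencyVector
    kappa: float | None = None
    mu: Mapping[tuple[str, str], float] | None = None
    code: GeneticCode = STANDARD_CODE
    mg_position_specific: bool = True

    @classmethod
    def from_omega(cls, omega: float, frequencies: FrequencyVector, *,
                   style: str = "MG", kappa: float | None = None,
                   mu=None, **kw) -> "MechanisticCodonParameters":
        return cls(style=style, alpha=1.0, beta=float(omega),
                   frequencies=frequencies, kappa=kappa, mu=mu, **kw)

    @property
    def omega(self) -> float:
        return self.beta / self.alpha


def position_nucleotide_frequencies(fv: FrequencyVector) -> np.ndarray:
    """3x4 matrix of observed nucleotide frequencies at each codon position
    (marginals of the codon frequency vector)."""
    out = np.zeros((3, 4))
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for i, codon in enumerate(fv.alphabet.states):
        for pos in range(3):
            out[pos, nuc_index[codon[pos]]] += fv.values[i]
    return out / out.sum(axis=1, keepdims=True)


def implied_target_frequencies(
    fv: FrequencyVector, position_specific: bool = True,
    tol: float = 1e-12, max_iter: int = 500,
) -> np.ndarray:
    """MG-style target nucleotide frequencies implied by a codon vector.

    Finds the (position-specific 3x4, or global length-4) nucleotide
    frequencies p whose product measure, restricted to sense codons and
    renormalized, best reproduces the codon frequencies — the stationary
    codon distribution of an MG-style model is exactly that restriction.
    Fitted by iterative proportional fitting on the positional marginals;
    for a uniform codon vector the result is uniform (1/4), because the
    uniform product restricted to the 61 sense codons is uniform.
    """
    nuc_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    codes = np.array([[nuc_index[c[k]] for k in range(3)] for c in fv.alphabet.states])
    target_marg = np.zeros((3, 4))
    for k in range(3):
        np.add.at(target_marg[k], codes[:, k], fv.values)
    p = target_marg.copy()  # start from the observed marginals
    for _ in range(max_iter):
        q = p[0, codes[:, 0]] * p[1, codes[:, 1]] * p[2, codes[:, 2]]
        q = q / q.sum()
        model_marg = np.zeros((3, 4))
        for k in range(3):
            np.add.at(model_marg[k], codes[:, k], q)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(model_marg > 0, target_marg / model_marg, 1.0)
        p = p * ratio
        p = p / p.sum(axis=1, keepdims=True)
        if np.max(np.abs(ratio - 1.0)) < tol:
            break
    if not position_specific:
        g = p.mean(axis=0)
        return g / g.sum()
    return p


def build_mechanistic_codon(params: MechanisticCodonParameters,
                            scale: bool = True) -> RateMatrix:
    """GY- or MG-style codon matrix.

    Single-nucleotide changes x->y at one position get rate
    (beta if nonsynonymous else alpha) * mu_xy * T, where T is the codon
    frequency pi_j (GY) or the target-nucleotide frequency at the changed
    position (MG; position-specific by default, global nucleotide
    frequencies as a fallback).  Multi-nucleotide changes have rate 0.
    """
    if params.alpha <= 0:
        raise MatrixError("alpha (dS factor) must be positive")
    if params.beta < 0:
        raise MatrixError("beta (dN factor) must be non-negative")
    style = params.style.upper()
    if style not in ("GY", "MG"):
        raise MatrixError(f"style must be GY or MG, not {params.style!r}")
    fv = params.frequencies
    alphabet = fv.alphabet
    if alphabet.kind is not AlphabetKind.CODON:
        raise MatrixError("mechanistic codon model requires the codon alphabet")
    mu = _mu_table(params.kappa, params.mu)
    code = params.code
    n = len(alphabet)
    Q = np.zeros((n, n))
    pos_freqs = implied_target_frequencies(fv, position_specific=True)
    global_nuc = implied_target_frequencies(fv, position_specific=False)
    nuc_index = {x: i for i, x in enumerate(NUCLEOTIDES)}
    aa = [code.translate(c) for c in alphabet.states]
    for i, ci in enumerate(alphabet.states):
        for j, cj in enumerate(alphabet.states):
            if i == j:
                continue
            diff = codon_diff_positions(ci, cj)
            if len(diff) != 1:
                continue
            pos = diff[0]
            x, y = ci[pos], cj[pos]
            sel = params.alpha if aa[i] == aa[j] else params.beta
            if style == "GY":
                target = fv.values[j]
            elif params.mg_position_specific:
                target = pos_freqs[pos, nuc_index[y]]
            else:
                target = global_nuc[nuc_index[y]]
            Q[i, j] = sel * mu[(x, y)] * target
    prov = {"family": f"{style}94-style", "alpha": params.alpha, "beta": params.beta,
            "omega": params.omega, "kappa": params.kappa}
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rm = RateMatrix(alphabet, Q, _mechanistic_stationary(alphabet, Q, fv), False, prov)
    return scale_matrix(rm) if scale else rm


def _mechanistic_stationary(alphabet, Q, fv) -> FrequencyVector:
    """Use the supplied codon frequencies when they are stationary for Q
    (GY always; MG with consistent frequencies), else solve numerically."""
    if np.max(np.abs(fv.values @ Q)) <= 1e-8 * max(1.0, np.max(np.abs(Q))):
        return fv
    return FrequencyVector(alphabet, _stationary_from_null_space(Q))


# ---------------------------------------------------------------------------
# mutation-selection (Halpern-Bruno) models


def fixation_factor(S: float | np.ndarray) -> np.ndarray:
    """Halpern-Bruno relative fixation rate S / (1 - exp(-S)).

    Continuous at S = 0 (limit 1); guarded for |S| < 1e-9.
    """
    arr = np.atleast_1d(np.asarray(S, dtype=float))
    out = np.ones_like(arr)
    nz = np.abs(arr) >= 1e-9
    with np.errstate(over="ignore"):
        out[nz] = arr[nz] / -np.expm1(-arr[nz])
    if not np.all(np.isfinite(out)):
        raise MatrixError("non-finite fixation factor")
    return out.reshape(np.shape(S))


@dataclass(frozen=True)
class MutSelParameters:
    """Halpern-Bruno parameters: per-state fitnesses f_i (or frequencies,
    from which f_i = ln pi_i) plus nucleotide mutation rates.

    For the codon alphabet, fitnesses may instead be given per amino acid
    and are expanded to all synonymous codons.
    """

    alphabet: Alphabet
    fitnesses: np.ndarray
    kappa: float | None = None
    mu: Mapping[tuple[str, str], float] | None = None
    code: GeneticCode = STANDARD_CODE

    def __post_init__(self) -> None:
        f = np.asarray(self.fitnesses, dtype=float)
        object.__setattr__(self, "fitnesses", f)
        if self.alphabet.kind not in (AlphabetKind.NUCLEOTIDE, AlphabetKind.CODON):
            raise MatrixError("mutation-selection models support nucleotide or codon alphabets")
        if f.shape != (len(self.alphabet),):
            raise MatrixError(f"need {len(self.alphabet)} fitnesses, got {f.shape}")
        if not np.all(np.isfinite(f)):
            raise MatrixError("fitnesses must be finite")

    @classmethod
    def from_frequencies(cls, fv: FrequencyVector, **kw) -> "MutSelParameters":
        if np.any(fv.values <= 0):
            raise MatrixError("frequencies must be strictly positive to take log-fitnesses")
        return cls(fv.alphabet, np.log(fv.values), **kw)

    @classmethod
    def from_amino_acid_fitnesses(cls, fitness_by_aa: Mapping[str, float],
                                  **kw) -> "MutSelParameters":
        alphabet = build_alphabet("codon")
        code = kw.get("code", STANDARD_CODE)
        f = np.array([fitness_by_aa[code.translate(c)] for c in alphabet.states])
        return cls(alphabet, f, **kw)


def build_mutsel(params: MutSelParameters, scale: bool = True) -> RateMatrix:
    """Q_ij = mu_ij * F(f_j - f_i), restricted to single-nucleotide
    neighbors for codons."""
    alphabet = params.alphabet
    mu = _mu_table(params.kappa, params.mu)
    n = len(alphabet)
    f = params.fitnesses
    Q = np.zeros((n, n))
    for i, si in enumerate(alphabet.states):
        for j, sj in enumerate(alphabet.states):
            if i == j:
                continue
            if alphabet.kind is AlphabetKind.CODON:
                diff = codon_diff_positions(si, sj)
                if len(diff) != 1:
                    continue
                pos = diff[0]
                pair = (si[pos], sj[pos])
            else:
                pair = (si, sj)
            Q[i, j] = mu[pair] * float(fixation_factor(f[j] - f[i]))
    np.fill_diagonal(Q, -Q.sum(axis=1))
    fv = FrequencyVector(alphabet, _stationary_from_null_space(Q))
    rm = RateMatrix(alphabet, Q, fv, False,
                    {"family": "mutsel", "kappa": params.kappa})
    return scale_matrix(rm) if scale else rm


# ---------------------------------------------------------------------------
# custom matrices


def build_custom(matrix: np.ndarray, alphabet: Alphabet,
                 scale: bool = True) -> RateMatrix:
    """Wrap a user matrix: off-diagonals must be non-negative; the diagonal
    is recomputed as the negative row sum regardless of input; the
    stationary distribution is solved numerically."""
    Q = np.array(matrix, dtype=float)
    n = len(alphabet)
    if Q.shape != (n, n):
        raise MatrixError(f"matrix shape {Q.shape} does not match alphabet size {n}")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        i, j = np.argwhere(off < 0)[0]
        raise MatrixError(f"negative off-diagonal rate at ({int(i)},{int(j)})")
    Q = off
    np.fill_diagonal(Q, -Q.sum(axis=1))
    fv = FrequencyVector(alphabet, _stationary_from_null_space(Q))
    rm = RateMatrix(alphabet, Q, fv, False, {"family": "custom"})
    return scale_matrix(rm) if scale else rm
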