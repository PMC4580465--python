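"""Sequence simulation along a fixed tree.

For each branch the substitution process is a continuous-time Markov chain:
the child state at each site is drawn from the row of P(t) = exp(Q * t * r)
selected by the parent state, where Q is the branch's (possibly flagged)
model, t the branch length, and r the site's rate factor.  Sites are
independent; the tree is traversed pre-order and sites are consumed
left-to-right from a single seeded random stream, so output is bit-identical
for identical inputs and independent of the transition-matrix cache.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .alphabets import Alphabet
from .matrices import RateMatrix
from .partitions import Partition, PartitionError, assign_site_categories
from .trees import TreeNode, resolve_branch_models


class EvolveError(ValueError):
    pass


def transition_probabilities(Q: RateMatrix, t: float, rate: float = 1.0) -> np.ndarray:
    """P(t) = exp(Q * t * rate), guarded: entries clipped to [0, 1] (tiny
    negative round-off zeroed) and rows renormalized to sum to 1."""
    if t < 0:
        raise EvolveError(f"negative branch length {t}")
    if rate < 0:
        raise EvolveError(f"negative rate factor {rate}")
    if t * rate == 0.0:
        return np.eye(len(Q.alphabet))
    P = scipy.linalg.expm(Q.Q * (t * rate))
    if not np.all(np.isfinite(P)):
        raise EvolveError("non-finite transition probabilities")
    P[(P < 0) & (P > -1e-12)] = 0.0
    if np.any(P < 0):
        raise EvolveError("negative transition probability beyond round-off")
    P /= P.sum(axis=1, keepdims=True)
    return P


def root_sequence(
    model: RateMatrix,
    size: int,
    seed: int | np.random.Generator,
    mrca: str | None = None,
) -> np.ndarray:
    """Root (MRCA) state indices: the given sequence verbatim, or i.i.d.
    draws from the model's stationary frequencies."""
    alphabet = model.alphabet
    if mrca is not None:
        states = _split_states(mrca, alphabet)
        if len(states) != size:
            raise EvolveError(
                f"MRCA has {len(states)} states but the partition has {size} sites"
            )
        return np.array([alphabet.index_of(s) for s in states], dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(size)
    cum = np.cumsum(model.frequencies.values)
    cum[-1] = 1.0
    return np.searchsorted(cum, u, side="right").astype(np.int64)


def _split_states(seq: str, alphabet: Alphabet) -> list[str]:
    w = alphabet.state_width
    if len(seq) % w:
        raise EvolveError(f"sequence length {len(seq)} not a multiple of state width {w}")
    return [seq[i : i + w] for i in range(0, len(seq), w)]


@dataclass
class PartitionResult:
    """Simulated states and per-site metadata for one partition."""

    partition: Partition
    alphabet: Alphabet
    site_categories: np.ndarray  # per-site category index
    site_models: list[str]  # per-site model name
    site_rates: np.ndarray  # per-site rate factor
    # sites grouped by shared (model, rate) so each branch needs one P per group
    site_groups: list[tuple[np.ndarray, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.site_groups:
            keys: dict[tuple[str, float], list[int]] = {}
            for k in range(self.partition.size):
                keys.setdefault((self.site_models[k], float(self.site_rates[k])), []).append(k)
            self.site_groups = [
                (np.asarray(idx, dtype=np.int64), m, r) for (m, r), idx in keys.items()
            ]


@dataclass
class SimulatedAlignment:
    """Tip (and optionally ancestral) sequences with per-site metadata.

    Sequences are stored as state-index arrays per partition; string views
    concatenate the partitions (codon states appear as nucleotide triplets).
    """

    tree: TreeNode
    partitions: list[PartitionResult]
    states: dict[str, list[np.ndarray]]  # node name -> per-partition indices
    tip_names: list[str]
    ancestor_names: list[str]
    node_names: dict[int, str] = field(default_factory=dict, repr=False)

    def sequence(self, name: str) -> str:
        try:
            arrays = self.states[name]
        except KeyError:
            raise EvolveError(f"no sequence for node {name!r}") from None
        return "".join(
            "".join(pr.alphabet.states[i] for i in arr)
            for pr, arr in zip(self.partitions, arrays)
        )

    @property
    def tip_sequences(self) -> dict[str, str]:
        return {n: self.sequence(n) for n in self.tip_names}

    @property
    def ancestor_sequences(self) -> dict[str, str]:
        return {n: self.sequence(n) for n in self.ancestor_names}

    def site_table(self) -> list[dict]:
        """One row per site (alphabet units): partition, category, model, rate."""
        rows = []
        site = 1
        for pr in self.partitions:
            pname = pr.partition.name or pr.partition.model
            for k in range(pr.partition.size):
                rows.append(
                    {
                        "site": site,
                        "partition": pname,
                        "category": int(pr.site_categories[k]),
                        "model": pr.site_models[k],
                        "rate": float(pr.site_rates[k]),
                    }
                )
                site += 1
        return rows


def _assign_node_names(tree: TreeNode) -> dict[int, str]:
    """Stable ids for unnamed internal nodes: 'root', then 'internal_k' in
    pre-order."""
    names: dict[int, str] = {}
    counter = 0
    for node in tree.preorder():
        if node.is_leaf:
            names[id(node)] = node.name  # type: ignore[assignment]
        elif node is tree:
            names[id(node)] = tree.name or "root"
        elif node.name:
            names[id(node)] = node.name
        else:
            counter += 1
            names[id(node)] = f"internal_{counter}"
    return names


class _PCache:
    def __init__(self, enabled: bool = True):
        self.enabled = enabled
        self._store: dict[tuple, np.ndarray] = {}

    def get(self, models: dict[str, RateMatrix], model_name: str, t: float,
            rate: float) -> np.ndarray:
        key = (model_name, float(t), float(rate))
        if self.enabled and key in self._store:
            return self._store[key]
        P = transition_probabilities(models[model_name], t, rate)
        if self.enabled:
            self._store[key] = P
        return P


def _sample_children(parent: np.ndarray, P: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of child states given parent states and one uniform
    per site (consumed in site order)."""
    child = np.empty_like(parent)
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    for s in np.unique(parent):
        idx = np.nonzero(parent == s)[0]
        child[idx] = np.searchsorted(cum[s], u[idx], side="right")
    return child


def evolve(
    tree: TreeNode,
    partitions: list[Partition],
    models: dict[str, RateMatrix],
    seed: int | np.random.Generator,
    keep_ancestors: bool = True,
    cache_transition_matrices: bool = True,
) -> SimulatedAlignment:
    """Simulate one alignment.

    Every model flag on the tree and every model referenced by a partition
    must appear in ``models``.  A branch's model is its flag (inherited down
    the tree) if any, else the site's category model (``custom_models``
    distributions), else the partition's root model; the site's rate factor
    multiplies the branch length.
    """
    tree.validate()
    if not partitions:
        raise EvolveError("no partitions given")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    node_names = _assign_node_names(tree)

    for node in tree.preorder():
        if node.model_flag and node.model_flag not in models:
            raise EvolveError(f"model flag {node.model_flag!r} is not a declared model")

    prs: list[PartitionResult] = []
    for part in partitions:
        if part.model not in models:
            raise EvolveError(f"partition model {part.model!r} is not declared")
        dist = part.site_distribution
        cats = assign_site_categories(part, rng)
        if dist.kind == "custom_models":
            names = dist.model_names
            for m in names:
                if m not in models:
                    raise EvolveError(f"site-category model {m!r} is not declared")
                if models[m].alphabet.states != models[part.model].alphabet.states:
                    raise PartitionError(
                        "all models in a partition must share one alphabet"
                    )
            site_models = [names[c] for c in cats]
            site_rates = np.ones(part.size)
        else:
            rates = dist.rates
            site_models = [part.model] * part.size
            site_rates = rates[cats]
        prs.append(
            PartitionResult(part, models[part.model].alphabet, cats, site_models, site_rates)
        )

    cache = _PCache(cache_transition_matrices)
    states: dict[str, list[np.ndarray]] = {}

    root_states: list[np.ndarray] = []
    for pr in prs:
        part = pr.partition
        if part.root_sequence is not None:
            arr = root_sequence(models[part.model], part.size, rng, part.root_sequence)
            for k, si in enumerate(arr):
                if models[pr.site_models[k]].frequencies.values[si] == 0:
                    import warnings

                    warnings.warn(
                        f"MRCA state {pr.alphabet.states[si]} at site {k + 1} has zero "
                        "stationary frequency under its model",
                        stacklevel=2,
                    )
                    break
        else:
            # draw each site from its own site-model's stationary frequencies
            u = rng.random(part.size)
            arr = np.empty(part.size, dtype=np.int64)
            for idx, m, _r in pr.site_groups:
                cum = np.cumsum(models[m].frequencies.values)
                cum[-1] = 1.0
                arr[idx] = np.searchsorted(cum, u[idx], side="right")
        root_states.append(arr)
    states[node_names[id(tree)]] = root_states

    def walk(node: TreeNode, parent_name: str, branch_models: dict[int, str]) -> None:
        for child in node.children:
            cname = node_names[id(child)]
            child_states: list[np.ndarray] = []
            for pr, parent_arr in zip(prs, states[parent_name]):
                flag_model = branch_models[id(child)]
                u = rng.random(pr.partition.size)
                child_arr = np.empty_like(parent_arr)
                for idx, site_model, r in pr.site_groups:
                    m = flag_model if flag_model is not None else site_model
                    P = cache.get(models, m, child.branch_length, r)
                    child_arr[idx] = _sample_children(parent_arr[idx], P, u[idx])
                child_states.append(child_arr)
            states[cname] = child_states
            walk(child, cname, branch_models)

    # branch flags: None means "no flag anywhere above" -> site/partition model
    flags = resolve_branch_models(tree, root_model="")
    branch_models = {k: (v if v else None) for k, v in flags.items()}
    walk(tree, node_names[id(tree)], branch_models)

    tip_names = [node_names[id(t)] for t in tree.tips()]
    ancestor_names = [
        node_names[id(n)] for n in tree.preorder() if not n.is_leaf
    ]
    if not keep_ancestors:
        for n in ancestor_names:
            states.pop(n, None)
        ancestor_names = []
    return SimulatedAlignment(tree, prs, states, tip_names, ancestor_names, node_names)
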