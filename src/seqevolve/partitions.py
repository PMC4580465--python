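"""Partitions and site-rate/site-model heterogeneity.

A simulation is organized in partitions: contiguous blocks of sites that
share a model configuration.  Within a partition, site-wise heterogeneity is
expressed as a :class:`SiteRateDistribution`, which is one of

* ``gamma`` — k equal-probability discrete-gamma rate categories
  (mean-of-bin discretization, overall mean rate exactly 1);
* ``gamma_inv`` — gamma plus an invariant (rate 0) class with probability
  p_inv, gamma rates rescaled by 1/(1-p_inv) to keep the overall mean 1;
* ``custom_rates`` — arbitrary (rate factor, probability) categories;
* ``custom_models`` — categories that name whole substitution models rather
  than rate factors, e.g. codon models differing only in dN/dS, which is how
  site-wise dN/dS variation is expressed.

Sites are assigned to categories either i.i.d. (stochastic mode, the
default) or tiled deterministically in blocks matching the proportions
exactly (used by the validation experiments, where exact per-category
counts matter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class SiteRateDistribution:
    """Discrete site-category distribution.

    ``categories`` pairs each category's rate factor (float) or model name
    (str, kind ``custom_models``) with its probability.
    """

    kind: str  # gamma | gamma_inv | custom_rates | custom_models
    categories: tuple[tuple[float | str, float], ...]
    shape: float | None = None
    p_inv: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "gamma_inv", "custom_rates", "custom_models"):
            raise PartitionError(f"unknown distribution kind {self.kind!r}")
        probs = np.array([p for _, p in self.categories], dtype=float)
        if np.any(probs < 0):
            raise PartitionError("negative category probability")
        if abs(probs.sum() - 1.0) > 1e-10:
            raise PartitionError(f"category probabilities sum to {probs.sum()}, not 1")
        if self.kind != "custom_models":
            rates = np.array([r for r, _ in self.categories], dtype=float)
            if np.any(rates < 0):
                raise PartitionError("negative rate factor")
            if self.kind in ("gamma", "gamma_inv"):
                mean = float(np.dot(rates, probs))
                if abs(mean - 1.0) > 1e-8:
                    raise PartitionError(f"gamma-family mean rate {mean}, expected 1")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.categories], dtype=float)

    @property
    def rates(self) -> np.ndarray:
        if self.kind == "custom_models":
            raise PartitionError("custom_models categories carry models, not rates")
        return np.array([r for r, _ in self.categories], dtype=float)

    @property
    def model_names(self) -> list[str]:
        if self.kind != "custom_models":
            raise PartitionError("only custom_models categories carry model names")
        return [m for m, _ in self.categories]

    @classmethod
    def single(cls) -> "SiteRateDistribution":
        """Degenerate single-category distribution (homogeneous sites)."""
        return cls("custom_rates", ((1.0, 1.0),))

    @classmethod
    def from_models(cls, names_probs: list[tuple[str, float]]) -> "SiteRateDistribution":
        return cls("custom_models", tuple((str(m), float(p)) for m, p in names_probs))


def gamma_categories(shape: float, k: int) -> SiteRateDistribution:
    """Discrete-gamma rates: k equal-probability bins of Gamma(shape,
    scale=1/shape); each category's rate is the mean of its bin, so the
    overall mean is exactly 1."""
    if shape <= 0:
        raise PartitionError("gamma shape must be positive")
    if k < 1:
        raise PartitionError("need at least one category")
    edges = stats.gamma.ppf(np.linspace(0.0, 1.0, k + 1), a=shape, scale=1.0 / shape)
    # E[X; bin] via the Gamma(shape+1) CDF identity, with mean(X) = 1
    upper_cdf = stats.gamma.cdf(edges, a=shape + 1.0, scale=1.0 / shape)
    rates = k * np.diff(upper_cdf)
    rates = rates / rates.mean()  # pin the category-weighted mean to exactly 1
    cats = tuple((float(r), 1.0 / k) for r in rates)
    return SiteRateDistribution("gamma", cats, shape=shape)


def gamma_inv_categories(shape: float, p_inv: float, k: int) -> SiteRateDistribution:
    """Gamma + invariant-sites distribution: an extra rate-0 category with
    probability p_inv; gamma rates scaled by 1/(1-p_inv) so the overall
    mean stays 1."""
    if not 0.0 <= p_inv < 1.0:
        raise PartitionError("p_inv must be in [0, 1)")
    base = gamma_categories(shape, k)
    if p_inv == 0.0:
        return base
    cats = [(0.0, p_inv)]
    for r, p in base.categories:
        cats.append((r / (1.0 - p_inv), p * (1.0 - p_inv)))
    return SiteRateDistribution("gamma_inv", tuple(cats), shape=shape, p_inv=p_inv)


@dataclass(frozen=True)
class Partition:
    """A block of sites evolving under a shared configuration.

    ``size`` counts sites in alphabet units (codon sites for codon models).
    ``model`` names the root model: it generates the root sequence and
    governs branches not covered by a site-category model or a branch flag.
    ``root_sequence`` optionally fixes the MRCA sequence instead of drawing
    it from the stationary distribution.
    """

    size: int
    model: str
    site_distribution: SiteRateDistribution = field(default_factory=SiteRateDistribution.single)
    root_sequence: str | None = None
    name: str | None = None
    category_mode: str = "stochastic"  # or "deterministic"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise PartitionError("partition size must be >= 1")
        if self.category_mode not in ("stochastic", "deterministic"):
            raise PartitionError(f"unknown category mode {self.category_mode!r}")


def assign_site_categories(
    partition: Partition,
    seed: int | np.random.Generator | None = None,
    mode: str | None = None,
) -> np.ndarray:
    """Per-site category indices for a partition.

    Deterministic mode tiles categories in fixed blocks matching the
    proportions exactly (requires size * probability integral for every
    category); stochastic mode draws i.i.d. categorical sites with the
    given seed.
    """
    mode = mode or partition.category_mode
    probs = partition.site_distribution.probabilities
    k = len(probs)
    if k == 1:
        return np.zeros(partition.size, dtype=np.int64)
    if mode == "deterministic":
        counts = probs * partition.size
        rounded = np.rint(counts)
        if np.max(np.abs(counts - rounded)) > 1e-9:
            raise PartitionError(
                f"proportions {probs.tolist()} not exactly representable over "
                f"{partition.size} sites; use stochastic assignment"
            )
        return np.repeat(np.arange(k, dtype=np.int64), rounded.astype(np.int64))
    if seed is None:
        raise PartitionError("stochastic assignment needs a seed")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(k, size=partition.size, p=probs).astype(np.int64)
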