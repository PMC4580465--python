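"""Parameter-recovery experiments.

Each experiment simulates data under known parameters and measures how well
the observed substitution process recovers them:

* ``rate_recovery`` — JC69 on two-taxon trees over a branch-length grid;
  the JC-corrected distance between the two tips, halved, estimates the
  per-branch substitution rate.
* ``dnds_recovery`` — MG-style codon models on two-taxon trees over a
  dN/dS grid; global counted omega-hat estimates omega.
* ``site_het`` — four equal-proportion omega categories tiled across 400
  codon sites on a balanced tree; per-site counted omega grouped by the
  true category.
* ``branch_het`` — a four-taxon tree with a distinct omega per branch via
  model flags (lowest omega on the internal branch); per-branch counted
  omega.

Every experiment returns a tidy summary DataFrame (one row per condition
with mean and standard deviation of the recovered parameter).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dnds import count_dnds
from .evolve import evolve
from .frequencies import FrequencyVector
from .matrices import (
    MechanisticCodonParameters,
    build_mechanistic_codon,
    jc69_matrix,
)
from .partitions import Partition, SiteRateDistribution
from .trees import balanced_tree, parse_newick

from .alphabets import build_alphabet

EXPERIMENTS = ("rate_recovery", "dnds_recovery", "site_het", "branch_het")

SITE_HET_OMEGAS = (0.2, 0.4, 0.6, 0.8)
BRANCH_HET_TERMINAL_OMEGAS = (0.4, 0.7, 1.0, 1.5)
BRANCH_HET_INTERNAL_OMEGA = 0.1


def mg94(omega: float, kappa: float = 1.0):
    """MG-style codon model with equal codon frequencies."""
    fv = FrequencyVector.uniform(build_alphabet("codon"))
    return build_mechanistic_codon(
        MechanisticCodonParameters.from_omega(omega, fv, style="MG", kappa=kappa)
    )


def jc_corrected_distance(seq_a: np.ndarray, seq_b: np.ndarray) -> float:
    """JC69 distance from the proportion of differing sites:
    d = -(3/4) ln(1 - 4p/3)."""
    p = float(np.mean(seq_a != seq_b))
    if p >= 0.75:
        return float("inf")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def rate_recovery(
    branch_lengths=(0.01, 0.05, 0.1, 0.3, 0.5),
    replicates: int = 50,
    sites: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """JC69 substitution-rate recovery on two-taxon trees."""
    rng = np.random.default_rng(seed)
    model = {"jc": jc69_matrix()}
    rows = []
    for b in branch_lengths:
        tree = parse_newick(f"(t1:{b},t2:{b});")
        part = [Partition(size=sites, model="jc")]
        estimates = []
        for _ in range(replicates):
            aln = evolve(tree, part, model, rng, keep_ancestors=False)
            d = jc_corrected_distance(
                aln.states["t1"][0], aln.states["t2"][0]
            )
            estimates.append(d / 2.0)  # path length 2b across two branches
        estimates = np.asarray(estimates)
        rows.append(
            {
                "branch_length": b,
                "mean_rate": estimates.mean(),
                "sd_rate": estimates.std(ddof=1) if replicates > 1 else 0.0,
                "replicates": replicates,
                "sites": sites,
            }
        )
    return pd.DataFrame(rows)


def dnds_recovery(
    omegas=(0.25, 0.5, 0.75, 1.0, 1.25, 1.5),
    kappa: float = 1.0,
    branch_length: float = 0.1,
    replicates: int = 50,
    sites: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Global counted dN/dS recovery under MG-style two-taxon simulations."""
    rng = np.random.default_rng(seed)
    rows = []
    for omega in omegas:
        models = {"m": mg94(omega, kappa)}
        tree = parse_newick(f"(t1:{branch_length},t2:{branch_length});")
        part = [Partition(size=sites, model="m")]
        estimates = []
        for _ in range(replicates):
            aln = evolve(tree, part, models, rng)
            counts = count_dnds(aln, scope="global", mu=kappa)
            estimates.append(counts.omega_corrected)
        estimates = np.asarray(estimates)
        rows.append(
            {
                "omega": omega,
                "kappa": kappa,
                "mean_omega": np.nanmean(estimates),
                "sd_omega": np.nanstd(estimates, ddof=1) if replicates > 1 else 0.0,
                "replicates": replicates,
                "sites": sites,
            }
        )
    return pd.DataFrame(rows)


def site_het(
    levels: int = 12,
    sites: int = 400,
    omegas=SITE_HET_OMEGAS,
    kappa: float = 1.0,
    branch_length: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Site-wise dN/dS heterogeneity on a balanced 2**levels-taxon tree.

    The omega categories are attached to sites as whole models (equal
    proportions, deterministic tiling) and recovered per site by counting;
    the summary groups sites by their true category.
    """
    rng = np.random.default_rng(seed)
    models = {f"w{i}": mg94(w, kappa) for i, w in enumerate(omegas)}
    dist = SiteRateDistribution.from_models(
        [(f"w{i}", 1.0 / len(omegas)) for i in range(len(omegas))]
    )
    part = Partition(
        size=sites, model="w0", site_distribution=dist, category_mode="deterministic"
    )
    tree = balanced_tree(levels, branch_length)
    aln = evolve(tree, [part], models, rng)
    counts = count_dnds(aln, scope="per_site", mu=kappa)
    omega_hat = counts.omega_corrected
    cats = aln.partitions[0].site_categories
    rows = []
    for i, w in enumerate(omegas):
        vals = omega_hat[cats == i]
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "category": i,
                "omega": w,
                "mean_omega": vals.mean(),
                "sd_omega": vals.std(ddof=1),
                "sites_counted": len(vals),
            }
        )
    return pd.DataFrame(rows)


def branch_het(
    terminal_omegas=BRANCH_HET_TERMINAL_OMEGAS,
    internal_omega: float = BRANCH_HET_INTERNAL_OMEGA,
    kappa: float = 1.0,
    branch_length: float = 0.15,
    replicates: int = 10,
    sites: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Branch-wise dN/dS heterogeneity on a four-taxon tree.

    Terminal branches carry distinct omegas via model flags; the internal
    branch carries the lowest omega.  Per-branch counted omega is averaged
    over replicates.
    """
    rng = np.random.default_rng(seed)
    wa, wb, wc, wd = terminal_omegas
    models = {
        "mA": mg94(wa, kappa),
        "mB": mg94(wb, kappa),
        "mC": mg94(wc, kappa),
        "mD": mg94(wd, kappa),
        "mI": mg94(internal_omega, kappa),
    }
    bl = branch_length
    tree = parse_newick(
        f"(A:{bl}#mA,B:{bl}#mB,(C:{bl}#mC,D:{bl}#mD)#mI:{bl});"
    )
    simulated = {"A": wa, "B": wb, "C": wc, "D": wd, "internal_1": internal_omega}
    part = [Partition(size=sites, model="mI")]
    per_branch: dict[str, list[float]] = {k: [] for k in simulated}
    for _ in range(replicates):
        aln = evolve(tree, part, models, rng)
        counts = count_dnds(aln, scope="per_branch", mu=kappa)
        for label, w in zip(counts.labels, np.atleast_1d(counts.omega_corrected)):
            per_branch[label].append(float(w))
    rows = []
    for label, w_true in simulated.items():
        vals = np.asarray(per_branch[label])
        rows.append(
            {
                "branch": label,
                "omega": w_true,
                "mean_omega": np.nanmean(vals),
                "sd_omega": np.nanstd(vals, ddof=1) if replicates > 1 else 0.0,
                "replicates": replicates,
                "sites": sites,
            }
        )
    return pd.DataFrame(rows)


_SMALL = {
    "rate_recovery": dict(branch_lengths=(0.05, 0.3), replicates=5, sites=5_000),
    "dnds_recovery": dict(omegas=(0.5, 1.0), replicates=3, sites=5_000),
    "site_het": dict(levels=7, sites=100),
    "branch_het": dict(replicates=2, sites=10_000),
}

_FULL = {
    "rate_recovery": dict(),
    "dnds_recovery": dict(omegas=(0.75,), kappa=3.25),
    "site_het": dict(),
    "branch_het": dict(),
}


def run_validation(experiment: str, scale: str | dict = "small", seed: int = 0) -> pd.DataFrame:
    """Run one named recovery experiment at a preset ('small' for quick
    checks, 'full' for the headline scales) or an explicit kwargs dict."""
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; choose from {EXPERIMENTS}")
    if isinstance(scale, dict):
        kwargs = dict(scale)
    elif scale == "small":
        kwargs = dict(_SMALL[experiment])
    elif scale == "full":
        kwargs = dict(_FULL[experiment])
    else:
        raise ValueError(f"scale must be 'small', 'full', or a dict, not {scale!r}")
    kwargs["seed"] = seed
    return globals()[experiment](**kwargs)
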