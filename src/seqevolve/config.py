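"""YAML/dict configuration for the command-line simulator.

A config declares named models and a list of partitions::

    models:
      codon_model:
        family: mg94          # jc69 | gtr | hky85 | tn93 | empirical |
                              # gy94 | mg94 | mutsel | custom
        omega: 0.75
        kappa: 3.25
        frequencies: equal    # equal | random | [..] | {A: 0.3, ...} |
                              # {file: aln.fasta, format: fasta, columns: [1,2]}
    partitions:
      - size: 100
        model: codon_model
        # optional: root_sequence, rates: {gamma: {shape: 0.5, categories: 4}}
        # or site_models: [{model: m1, prob: 0.5}, ...], mode: deterministic
"""

from __future__ import annotations

import numpy as np
import yaml

from .alphabets import build_alphabet
from .frequencies import (
    FrequencyVector,
    frequencies_from_file,
    random_frequencies,
)
from .matrices import (
    MechanisticCodonParameters,
    MutSelParameters,
    NucleotideParameters,
    RateMatrix,
    build_custom,
    build_empirical,
    build_gtr,
    build_mechanistic_codon,
    build_mutsel,
)
from .partitions import Partition, SiteRateDistribution, gamma_categories, gamma_inv_categories


class ConfigError(ValueError):
    pass


_FAMILY_ALPHABET = {
    "jc69": "nucleotide", "gtr": "nucleotide", "hky85": "nucleotide",
    "tn93": "nucleotide", "gy94": "codon", "mg94": "codon",
}


def _frequencies(spec, alphabet, rng) -> FrequencyVector:
    if spec is None or spec == "equal":
        return FrequencyVector.uniform(alphabet)
    if spec == "random":
        return random_frequencies(alphabet, rng)
    if isinstance(spec, list):
        return FrequencyVector(alphabet, np.asarray(spec, dtype=float))
    if isinstance(spec, dict) and "file" in spec:
        return frequencies_from_file(
            spec["file"], spec.get("format", "fasta"), alphabet,
            columns=spec.get("columns"),
            pseudocount=spec.get("pseudocount", 0.0),
        )
    if isinstance(spec, dict):
        return FrequencyVector.from_dict(alphabet, spec)
    raise ConfigError(f"cannot interpret frequency specification {spec!r}")


def build_model(spec: dict, rng) -> RateMatrix:
    if "family" not in spec:
        raise ConfigError("model specification needs a 'family'")
    family = str(spec["family"]).lower()
    if family == "jc69":
        return build_gtr(NucleotideParameters.jc69())
    if family in ("gtr", "hky85", "tn93"):
        fv = _frequencies(spec.get("frequencies"), build_alphabet("nucleotide"), rng)
        if family == "gtr":
            params = NucleotideParameters.gtr(spec["rates"], fv)
        elif family == "hky85":
            params = NucleotideParameters.hky85(spec["kappa"], fv)
        else:
            params = NucleotideParameters.tn93(spec["kappa_ag"], spec["kappa_ct"], fv)
        return build_gtr(params)
    if family in ("gy94", "mg94"):
        fv = _frequencies(spec.get("frequencies"), build_alphabet("codon"), rng)
        style = "GY" if family == "gy94" else "MG"
        kw = dict(style=style, kappa=spec.get("kappa"), frequencies=fv)
        if "omega" in spec:
            params = MechanisticCodonParameters(alpha=1.0, beta=float(spec["omega"]), **kw)
        else:
            params = MechanisticCodonParameters(
                alpha=float(spec.get("alpha", 1.0)), beta=float(spec.get("beta", 1.0)), **kw
            )
        return build_mechanistic_codon(params)
    if family == "empirical":
        name = spec.get("name") or spec.get("file")
        if name is None:
            raise ConfigError("empirical model needs 'name' (or 'file')")
        freqs = None
        if "frequencies" in spec:
            kind = "amino_acid" if spec.get("alphabet", "amino_acid") == "amino_acid" else "codon"
            freqs = _frequencies(spec["frequencies"], build_alphabet(kind), rng)
        return build_empirical(name, freqs)
    if family == "mutsel":
        alphabet = build_alphabet(spec.get("alphabet", "codon"))
        if "fitnesses" in spec:
            params = MutSelParameters(alphabet, np.asarray(spec["fitnesses"], dtype=float),
                                      kappa=spec.get("kappa"))
        elif "amino_acid_fitnesses" in spec:
            params = MutSelParameters.from_amino_acid_fitnesses(
                spec["amino_acid_fitnesses"], kappa=spec.get("kappa"))
        elif "frequencies" in spec:
            fv = _frequencies(spec["frequencies"], alphabet, rng)
            params = MutSelParameters.from_frequencies(fv, kappa=spec.get("kappa"))
        else:
            raise ConfigError("mutsel model needs fitnesses, amino_acid_fitnesses, or frequencies")
        return build_mutsel(params)
    if family == "custom":
        states = spec.get("states")
        if states is None:
            raise ConfigError("custom model needs 'states'")
        alphabet = build_alphabet("custom", [str(s) for s in states])
        return build_custom(np.asarray(spec["matrix"], dtype=float), alphabet)
    raise ConfigError(f"unknown model family {family!r}")


def build_partition(spec: dict) -> Partition:
    if "size" not in spec or "model" not in spec:
        raise ConfigError("each partition needs 'size' and 'model'")
    dist = SiteRateDistribution.single()
    if "rates" in spec:
        r = spec["rates"]
        if "gamma" in r:
            g = r["gamma"]
            if "p_inv" in g:
                dist = gamma_inv_categories(g["shape"], g["p_inv"], g.get("categories", 4))
            else:
                dist = gamma_categories(g["shape"], g.get("categories", 4))
        elif "categories" in r:
            dist = SiteRateDistribution(
                "custom_rates",
                tuple((float(c["rate"]), float(c["prob"])) for c in r["categories"]),
            )
        else:
            raise ConfigError("rates section needs 'gamma' or 'categories'")
    elif "site_models" in spec:
        dist = SiteRateDistribution.from_models(
            [(c["model"], float(c["prob"])) for c in spec["site_models"]]
        )
    return Partition(
        size=int(spec["size"]),
        model=str(spec["model"]),
        site_distribution=dist,
        root_sequence=spec.get("root_sequence"),
        name=spec.get("name"),
        category_mode=spec.get("mode", "stochastic"),
    )


def load_config(path: str, rng) -> tuple[dict[str, RateMatrix], list[Partition]]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "models" not in cfg or "partitions" not in cfg:
        raise ConfigError("config must contain 'models' and 'partitions' sections")
    models = {name: build_model(spec, rng) for name, spec in cfg["models"].items()}
    partitions = [build_partition(p) for p in cfg["partitions"]]
    return models, partitions
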