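"""Statistical calibration and recovery simulations.

These routines check, by simulation, that the preference and deformation
statistics behave as designed: the KLd quantity keeps its nominal χ² type-I
error under the null, planted compartment preferences are detected with the
expected power and direction, planted interface-only substitutions are
recovered in P_interf and ranked first by ΔP, and the Viterbi decoder agrees
with exhaustive path enumeration on small models.
"""

from __future__ import annotations

import itertools

import numpy as np

from .deformation import (PositionMap, delta_p, deformation_proportions,
                          transition_counts)
from .encoder import viterbi_encode
from .io import ResidueKey
from .model import CLASS_LETTERS, LETTERS
from .stats import CHI2_CRITICAL_95, kld, kld_quantities, zscore
from .synthetic import (PreferenceProfile, SubstitutionSpec, mutate_sequence,
                        sample_counts, toy_alphabet_model)

__all__ = [
    "kld_null_rejection_rate",
    "preference_recovery",
    "deformation_recovery",
    "viterbi_agreement",
]


def kld_null_rejection_rate(n_sl: int = 500, reps: int = 10_000,
                            class_freq=(0.25, 0.45, 0.30),
                            seed: int | None = None) -> float:
    """Fraction of null multinomial samples whose KLd quantity exceeds the
    χ²(2) 0.95 critical value (nominally 5%)."""
    rng = np.random.default_rng(seed)
    q = np.asarray(class_freq, dtype=float)
    counts = rng.multinomial(n_sl, q, size=reps)
    quantities = kld_quantities(counts, q)
    return float(np.mean(quantities > CHI2_CRITICAL_95))


def preference_recovery(n_sims: int = 100, n_per_letter: int = 2000,
                        planted_letter: str = "D",
                        planted_probs=(1 / 3, 4 / 9, 2 / 9),
                        seed: int | None = None) -> dict[str, float]:
    """Power to detect a planted 2:1 surface:core preference.

    One loop-letter receives the planted compartment distribution, the rest
    of its class stays uniform; returns the fraction of simulations where the
    KLd flags the letter significant and where Z_surface/core is positive.
    """
    rng = np.random.default_rng(seed)
    letters = CLASS_LETTERS["loop"]
    base = PreferenceProfile.uniform(letters=letters, n_per_letter=n_per_letter)
    profile = base.plant(planted_letter, planted_probs)
    n_sig = n_dir = 0
    for _ in range(n_sims):
        table = sample_counts(profile, seed=int(rng.integers(2 ** 31)))
        if kld(table, planted_letter).significant:
            n_sig += 1
        if zscore(table, planted_letter, "surface", "core").z > 0:
            n_dir += 1
    return {"significant": n_sig / n_sims, "direction": n_dir / n_sims}


def _identity_map(n: int) -> PositionMap:
    pairs = [(ResidueKey("U", i + 1), ResidueKey("B", i + 1)) for i in range(n)]
    return PositionMap(pairs=pairs)


def deformation_recovery(n_sims: int = 50, n_per_compartment: int = 2000,
                         planted=("a", {"A": 0.7, "V": 0.3}),
                         interface_rate: float = 0.38,
                         surface_rate: float = 0.05,
                         seed: int | None = None) -> float:
    """Recovery rate of a planted interface-enriched substitution pattern.

    Unbound letters are drawn uniformly; at the interface they deform at the
    published-scale rate with the planted substitution distribution for the
    planted letter, at the surface with a low uniform background.  A
    simulation counts as recovered when P_interf of the planted letter is
    within 3 multinomial standard errors of the planted probabilities *and*
    ΔP ranks the planted target first in that letter's row.
    """
    rng = np.random.default_rng(seed)
    letter, targets = planted
    top_target = max(targets, key=targets.get)
    # the planted pattern acts at the interface only; the surface sees an
    # unstructured (uniform-substitution) flexibility background
    spec_interface = SubstitutionSpec(rates={"interface": interface_rate},
                                      substitutions={letter: dict(targets)})
    spec_surface = SubstitutionSpec(rates={"surface": surface_rate})
    n_total = 2 * n_per_compartment
    pmap = _identity_map(n_total)
    keys_u = [k for k, _ in pmap.pairs]
    keys_b = [k for _, k in pmap.pairs]
    compartments_b = {k: ("interface" if i < n_per_compartment else "surface")
                      for i, k in enumerate(keys_b)}
    compartments_u = {keys_u[i]: compartments_b[keys_b[i]] for i in range(n_total)}
    n_ok = 0
    for _ in range(n_sims):
        sim_seed = int(rng.integers(2 ** 31))
        sub_rng = np.random.default_rng(sim_seed)
        letters_u = {k: LETTERS[sub_rng.integers(27)] for k in keys_u}
        step1 = mutate_sequence(letters_u, spec_interface, compartments_u,
                                seed=sim_seed + 1)
        letters_b_by_u = mutate_sequence(step1, spec_surface, compartments_u,
                                         seed=sim_seed + 2)
        letters_b = {keys_b[i]: letters_b_by_u[keys_u[i]] for i in range(n_total)}
        c = transition_counts(pmap, letters_u, letters_b, compartments_b)
        p_i = deformation_proportions(c["interface"])
        p_s = deformation_proportions(c["surface"])
        dp, _ = delta_p(p_i, p_s)
        if letter not in p_i.index:
            continue
        row = c["interface"].loc[letter]
        n_def = float(row.sum() - row[letter])
        within = all(
            abs(p_i.loc[letter, t] - p) <= 3 * np.sqrt(p * (1 - p) / n_def)
            for t, p in targets.items())
        ranked_first = dp.loc[letter].idxmax() == top_target
        if within and ranked_first:
            n_ok += 1
    return n_ok / n_sims


def _brute_force_path(descriptors: np.ndarray, model) -> list[str]:
    """Exhaustive maximization over all state paths (small models only)."""
    emis = model.log_emission(descriptors)
    n, k = emis.shape
    log_t = np.log(model.transition)
    log_i = np.log(model.initial)
    best, best_score = None, -np.inf
    for path in itertools.product(range(k), repeat=n):
        score = log_i[path[0]] + emis[0, path[0]]
        for t in range(1, n):
            score += log_t[path[t - 1], path[t]] + emis[t, path[t]]
        if score > best_score + 1e-12:
            best, best_score = path, score
    return [model.letters[s] for s in best]


def viterbi_agreement(n_models: int = 100, max_states: int = 5,
                      max_fragments: int = 6, seed: int | None = None) -> float:
    """Fraction of random toy models where Viterbi equals brute force."""
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_models):
        k = int(rng.integers(2, max_states + 1))
        n = int(rng.integers(2, max_fragments + 1))
        m = toy_alphabet_model(k, seed=int(rng.integers(2 ** 31)))
        x = rng.uniform(0, 6, size=(n, 4))
        if viterbi_encode(x, m) == _brute_force_path(x, m):
            n_ok += 1
    return n_ok / n_models
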