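"""Synthetic inputs for every pipeline stage.

Generators produce Cα-only traces with controlled secondary-structure shape
(straight/curved helices and strands, self-avoiding loops), two-chain
complexes with a genuine buried interface (pseudo-atom spheres for surface
areas), letter-count tables with planted compartment preferences, and paired
bound/unbound letter sequences with controlled substitution patterns.  Every
generator is deterministic given its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .io import AtomRecord, CaChain, ComplexStructure, ResidueKey, detect_breaks
from .model import LETTERS, SS_CLASS, AlphabetModel

__all__ = [
    "HelixSpec",
    "StrandSpec",
    "LoopSpec",
    "make_helix",
    "make_strand",
    "make_loop",
    "make_complex",
    "PreferenceProfile",
    "sample_counts",
    "SubstitutionSpec",
    "mutate_sequence",
    "toy_alphabet_model",
    "chain_from_coords",
]

# deterministic filler sequence for generated chains (all 20 amino acids)
_FILLER = "AVLIEKRDSTNQGMFWYHPC"


def _sequence(n: int, offset: int = 0) -> list[str]:
    return [_FILLER[(i + offset) % len(_FILLER)] for i in range(n)]


def chain_from_coords(coords: np.ndarray, chain_id: str = "A",
                      sequence: list[str] | None = None,
                      start_number: int = 1) -> CaChain:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    keys = [ResidueKey(chain_id, start_number + i) for i in range(n)]
    aa = sequence if sequence is not None else _sequence(n)
    chain = CaChain(chain_id, keys, list(aa), coords)
    chain.breaks = detect_breaks(chain)
    return chain


@dataclass
class HelixSpec:
    """An (optionally bent) α-helical Cα trace.

    Defaults are canonical α-helix values — radius 2.3 Å, rise 1.5 Å/residue,
    twist 100°/residue — which reproduce the d1 ≈ 5.43 / d2 ≈ 5.05 Å
    fingerprint of the straight-helix letter.  ``curvature`` bends the helix
    axis (degrees/residue); ``jitter`` adds Gaussian coordinate noise (Å).
    """

    n_residues: int = 12
    radius: float = 2.3
    rise: float = 1.5
    twist: float = 100.0
    curvature: float = 0.0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("a helix needs at least 4 residues")
        if self.curvature < 0:
            raise ValueError("curvature must be >= 0")

    def points(self) -> np.ndarray:
        return geometry.helix_points(self.n_residues, self.radius, self.rise,
                                     self.twist, self.curvature)


@dataclass
class StrandSpec:
    """An extended, pleated (optionally twisted/bent) strand trace."""

    n_residues: int = 6
    pleat: float = 0.9
    twist: float = 0.0
    curvature: float = 0.0
    step: float = 3.8
    jitter: float = 0.0

    def points(self) -> np.ndarray:
        return geometry.strand_points(self.n_residues, self.step, self.pleat,
                                      self.twist, self.curvature)


@dataclass
class LoopSpec:
    """A self-avoiding random Cα walk with protein-like step lengths."""

    n_residues: int = 8
    step: float = 3.8
    min_separation: float = 3.2     # Å between non-adjacent residues
    max_retries: int = 200

    def points(self, rng: np.random.Generator) -> np.ndarray:
        for _ in range(self.max_retries):
            pts = [np.zeros(3), np.array([self.step, 0.0, 0.0])]
            ok = True
            for _ in range(self.n_residues - 2):
                # random direction biased away from backtracking
                for _attempt in range(50):
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    cand = pts[-1] + self.step * v
                    prev_dir = pts[-1] - pts[-2]
                    prev_dir /= np.linalg.norm(prev_dir)
                    if np.dot(v, prev_dir) < -0.5:
                        continue  # implausible bond angle
                    d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)
                    if np.all(d >= self.min_separation):
                        pts.append(cand)
                        break
                else:
                    ok = False
                    break
            if ok and len(pts) == self.n_residues:
                return np.array(pts)
        raise RuntimeError("self-avoiding loop generation failed; relax the spec")


def _jitter(points: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma > 0:
        points = points + rng.normal(scale=sigma, size=points.shape)
    return points


def _validated(coords: np.ndarray, what: str) -> np.ndarray:
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if np.any(d < 2.5) or np.any(d > 4.5):
        raise ValueError(f"{what} parameters produce Cα steps outside [2.5, 4.5] Å")
    return coords


def make_helix(spec: HelixSpec, seed: int | None = None,
               chain_id: str = "A") -> CaChain:
    rng = np.random.default_rng(seed)
    pts = _validated(_jitter(spec.points(), spec.jitter, rng), "helix")
    return chain_from_coords(pts, chain_id=chain_id)


def make_strand(n: int = 6, pleat: float = 0.9, curvature: float = 0.0,
                seed: int | None = None, twist: float = 0.0,
                chain_id: str = "A", jitter: float = 0.0) -> CaChain:
    spec = StrandSpec(n_residues=n, pleat=pleat, twist=twist,
                      curvature=curvature, jitter=jitter)
    rng = np.random.default_rng(seed)
    pts = _validated(_jitter(spec.points(), spec.jitter, rng), "strand")
    return chain_from_coords(pts, chain_id=chain_id)


def make_loop(n: int = 8, seed: int | None = None,
              chain_id: str = "A") -> CaChain:
    rng = np.random.default_rng(seed)
    pts = LoopSpec(n_residues=n).points(rng)
    return chain_from_coords(pts, chain_id=chain_id)


def _pseudo_atoms(chain: CaChain) -> list[AtomRecord]:
    from .io import three_letter
    return [AtomRecord(chain_id=chain.chain_id, residue_number=k.residue_number,
                       insertion_code=k.insertion_code,
                       residue_name=three_letter(chain.aa[i]),
                       atom_name="CA", element="C", coord=chain.coords[i])
            for i, k in enumerate(chain.keys)]


def _build_chain(specs, rng: np.random.Generator, chain_id: str) -> CaChain:
    """Concatenate one or more segment specs into a single chain, each new
    segment continuing 3.8 Å beyond the previous end."""
    if not isinstance(specs, (list, tuple)):
        specs = [specs]
    pieces = []
    for spec in specs:
        if isinstance(spec, HelixSpec):
            pts = spec.points()
        elif isinstance(spec, StrandSpec):
            pts = spec.points()
        elif isinstance(spec, LoopSpec):
            pts = spec.points(rng)
        else:
            raise TypeError(f"unsupported chain spec {type(spec).__name__}")
        if pieces:
            prev = pieces[-1]
            direction = prev[-1] - prev[-2]
            direction /= np.linalg.norm(direction)
            pts = pts - pts[0] + prev[-1] + 3.8 * direction
        pieces.append(pts)
    coords = np.vstack(pieces)
    chain = chain_from_coords(coords, chain_id=chain_id)
    return chain


def make_complex(chain_a_specs, chain_b_specs, separation: float = 9.0,
                 seed: int | None = None) -> ComplexStructure:
    """A two-chain complex of Cα pseudo-atom chains.

    Chain B is a translate of its spec'd geometry ``separation`` Å away from
    chain A along +y; at close separations the facing residues genuinely lose
    accessibility, at large ones there is no interface.  Contacts closer than
    2 Å raise.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    a = _build_chain(chain_a_specs, rng, "A")
    b = _build_chain(chain_b_specs, rng, "B")
    b_coords = b.coords + np.array([0.0, separation, 0.0])
    b = CaChain("B", b.keys, b.aa, b_coords, breaks=b.breaks)
    d_min = np.min(np.linalg.norm(a.coords[:, None, :] - b.coords[None, :, :], axis=2))
    if d_min < 2.0:
        raise ValueError(f"chains clash (min contact {d_min:.2f} Å); increase separation")
    chains = {"A": a, "B": b}
    atoms = {cid: _pseudo_atoms(c) for cid, c in chains.items()}
    return ComplexStructure(chains=chains, atoms=atoms,
                            pair_of_interest=("A", "B"), name="synthetic_complex")


@dataclass
class PreferenceProfile:
    """Per-letter compartment probabilities and per-letter totals."""

    probs: dict[str, np.ndarray]        # letter -> 3-vector over (interface, surface, core)
    totals: dict[str, int]              # letter -> N_sl

    def __post_init__(self) -> None:
        for letter, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError(f"invalid probability vector for {letter!r}")
            self.probs[letter] = p

    @classmethod
    def uniform(cls, letters=LETTERS, n_per_letter: int = 500) -> "PreferenceProfile":
        p = np.full(3, 1.0 / 3.0)
        return cls({l: p.copy() for l in letters},
                   {l: n_per_letter for l in letters})

    def plant(self, letter: str, probs) -> "PreferenceProfile":
        new = dict(self.probs)
        new[letter] = np.asarray(probs, dtype=float)
        return PreferenceProfile(new, dict(self.totals))


def sample_counts(profile: PreferenceProfile, seed: int | None = None):
    """Multinomial letter-count table under a preference profile."""
    from .stats import COMPARTMENTS, CountTable
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = {}
    for letter in profile.probs:
        rows[letter] = dict(zip(COMPARTMENTS,
                                rng.multinomial(profile.totals[letter],
                                                profile.probs[letter])))
    return CountTable(pd.DataFrame.from_dict(rows, orient="index"))


@dataclass
class SubstitutionSpec:
    """Per-compartment deformation rates and per-letter substitution targets.

    ``rates`` maps compartment → probability that a letter deforms there;
    ``substitutions`` maps letter → {target letter: probability} (summing to
    1 over targets ≠ the letter).  Letters without an entry fall back to a
    uniform draw over the other 26 letters.
    """

    rates: dict[str, float]
    substitutions: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cp, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {cp!r} outside [0, 1]")
        for letter, dist in self.substitutions.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in dist.values()):
                raise ValueError(f"substitution distribution for {letter!r} must sum to 1")
            if letter in dist:
                raise ValueError("a letter cannot substitute to itself")

    def draw(self, letter: str, rng: np.random.Generator) -> str:
        dist = self.substitutions.get(letter)
        if dist is None:
            others = [l for l in LETTERS if l != letter]
            return others[rng.integers(len(others))]
        targets = list(dist)
        return targets[rng.choice(len(targets), p=np.array(list(dist.values())))]


def mutate_sequence(letters_unbound: dict, spec: SubstitutionSpec,
                    compartments: dict, seed: int | None = None) -> dict:
    """Bound-state letter map derived from the unbound one.

    Each position deforms with its compartment's rate; deformed letters are
    redrawn from the letter's substitution distribution.  Positions with no
    compartment (or a compartment without a rate) are left unchanged.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for key in letters_unbound:
        letter = letters_unbound[key]
        rate = spec.rates.get(compartments.get(key), 0.0)
        if rate > 0 and rng.random() < rate:
            out[key] = spec.draw(letter, rng)
        else:
            out[key] = letter
    return out


def toy_alphabet_model(k: int = 3, seed: int | None = None,
                       mean_spread: float = 6.0) -> AlphabetModel:
    """A small random-but-valid alphabet model for decoder tests.

    Up to 27 states named from the canonical letters, Dirichlet transition
    rows, and descriptor means kept at least 1 Å apart.
    """
    if not 1 <= k <= 27:
        raise ValueError("k must be in 1..27")
    rng = np.random.default_rng(seed)
    letters = tuple(LETTERS[:k])
    means = []
    while len(means) < k:
        cand = rng.uniform(0.0, mean_spread, size=4)
        if all(np.linalg.norm(cand - m) >= 1.0 for m in means):
            means.append(cand)
    covs = rng.uniform(0.3, 1.0, size=(k, 4))
    trans = rng.dirichlet(np.ones(k), size=k)
    init = rng.dirichlet(np.ones(k))
    classes = {l: SS_CLASS[l] for l in letters}
    return AlphabetModel(letters, np.array(means), covs, trans, init,
                         classes=classes)
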