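"""The 27-letter structural alphabet: letter definitions, secondary-structure
classes, and the Gaussian-emission hidden Markov model used for encoding.

The alphabet follows the HMM-SA convention: 27 one-character letters
``A..Z`` plus ``a``, each a prototype conformation of four consecutive Cα
atoms described by the descriptor vector (d1, d2, d3, P4).  Letters are
partitioned into five secondary-structure classes:

* helix          — ``a A V W``
* strand         — ``L M N T X``
* loop           — ``D E F G H I O P Q R S U Y``
* helix_border   — ``Z B C``
* strand_border  — ``J K``

A model is loaded from a JSON file (keys ``letters``, ``ss_class``,
``emission`` with ``mean``/``cov``, ``transition``, ``initial``) or built by
:func:`default_model`.

.. note::
   The default model shipped here is a *synthetic* prototype library: the
   descriptor means of the regular-structure letters are computed from
   idealized helix/strand parametric geometry and the loop/border means are
   plausible literals consistent with the published qualitative
   characterization (curved vs. straight, d1/d3/P4 ordering).  It is not the
   original fitted alphabet; with shared isotropic variance and uniform
   transitions the encoder reduces to nearest-prototype assignment.  For
   letter-exact reproduction of published encodings, supply the fitted
   emission and transition parameters as a JSON model file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import helix_points, strand_points

__all__ = [
    "LETTERS",
    "SS_CLASS",
    "CLASS_LETTERS",
    "SURFACE_LETTERS",
    "CORE_LETTERS",
    "NON_INTERFACE_LETTERS",
    "INTERFACE_LETTERS",
    "AlphabetModel",
    "default_model",
    "load_model",
    "ss_class",
]

#: Canonical letter order (ties in Viterbi break toward the earlier letter).
LETTERS: tuple[str, ...] = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZa")

_HELIX = tuple("aAVW")
_STRAND = tuple("LMNTX")
_LOOP = tuple("DEFGHIOPQRSUY")
_HELIX_BORDER = tuple("ZBC")
_STRAND_BORDER = tuple("JK")

SS_CLASS: dict[str, str] = {}
for _ls, _cls in [(_HELIX, "helix"), (_STRAND, "strand"), (_LOOP, "loop"),
                  (_HELIX_BORDER, "helix_border"), (_STRAND_BORDER, "strand_border")]:
    for _l in _ls:
        SS_CLASS[_l] = _cls

CLASS_LETTERS: dict[str, tuple[str, ...]] = {
    "helix": _HELIX,
    "strand": _STRAND,
    "loop": _LOOP,
    "helix_border": _HELIX_BORDER,
    "strand_border": _STRAND_BORDER,
    # umbrella class covering both border kinds
    "border": _HELIX_BORDER + _STRAND_BORDER,
}

# Letter groups by compartment preference (used by the deformation analysis):
# curved conformations prefer the surface, straight ones the core; a small set
# is avoided at (or preferred for) the interface.
SURFACE_LETTERS = frozenset("aVLPHYDUFBK")
CORE_LETTERS = frozenset("ATMNGROISEQZCJ")
NON_INTERFACE_LETTERS = frozenset("aND")
INTERFACE_LETTERS = frozenset("F")


def ss_class(letter: str, umbrella_border: bool = False) -> str:
    """Secondary-structure class of a letter.

    With ``umbrella_border=True`` both border kinds report ``"border"``.
    """
    try:
        cls = SS_CLASS[letter]
    except KeyError:
        raise ValueError(f"unknown structural letter {letter!r}") from None
    if umbrella_border and cls in ("helix_border", "strand_border"):
        return "border"
    return cls


def _window_descriptors(points: np.ndarray) -> np.ndarray:
    from .encoder import compute_descriptors  # local import: avoid cycle
    return np.array([compute_descriptors(points[i:i + 4])
                     for i in range(len(points) - 3)])


def _synthetic_prototype_means() -> np.ndarray:
    """27×4 descriptor means of the synthetic prototype library (Å).

    Regular-structure prototypes are computed from the parametric generators
    (so synthetic chains built with the same parameters encode to the
    intended letters); curved prototypes average the window cloud of a bent
    12-residue chain.  Loop and border prototypes are frozen literals
    consistent with the qualitative d1/d3/P4 characterization of the letter
    groups (surface loops: long d1, short d3, low/negative P4; core loops:
    short d1, positive P4, split by d3; borders intermediate).
    """
    w = _window_descriptors
    means: dict[str, list[float]] = {
        # helices: A straight canonical, a curved, V kinked, W wide;
        # 'a' is the bent-helix window most distant from the straight one
        "A": list(w(helix_points(4))[0]),
        "a": list(w(helix_points(12, curvature_deg=8.0))[3]),
        "V": list(w(helix_points(4, radius=2.4, rise=1.9, twist_deg=112.0))[0]),
        "W": list(w(helix_points(4, radius=2.5, rise=1.7, twist_deg=93.0))[0]),
        # strands: T/M straight (largest d2), N curved (in-plane window mean),
        # X twisted, L curved with the shortest d3 and negative P4
        "T": list(w(strand_points(4, pleat=0.7))[0]),
        "M": list(w(strand_points(4, pleat=1.0, twist_deg=-15.0))[0]),
        "N": list(w(strand_points(12, pleat=1.1, curvature_deg=14.0)).mean(axis=0)),
        "X": list(w(strand_points(4, pleat=0.9, twist_deg=20.0))[0]),
        "L": [6.60, 9.40, 6.10, -3.20],
        # surface loops: long d1, short d3, low/negative P4
        "P": [6.50, 6.80, 4.80, -0.80],
        "H": [6.40, 7.40, 5.10, -1.40],
        "Y": [6.20, 6.30, 4.60, -0.30],
        "U": [6.60, 7.90, 5.30, -2.00],
        # D (non-interface) and F (interface): the shortest d1 among loops
        "D": [4.70, 5.20, 4.90, -0.50],
        "F": [4.90, 6.00, 5.00, 0.20],
        # core loops, long d3 subgroup
        "I": [5.20, 7.20, 6.60, 2.20],
        "R": [5.00, 6.60, 6.90, 1.60],
        "S": [5.40, 7.60, 7.00, 2.60],
        "Q": [5.10, 5.90, 6.50, 1.20],
        # core loops, short d3 subgroup
        "G": [5.00, 5.60, 5.20, 1.00],
        "E": [5.30, 6.40, 5.40, 1.80],
        "O": [4.80, 4.90, 5.00, 0.60],
        # helix borders
        "Z": [5.70, 6.20, 5.70, 2.20],
        "B": [5.60, 6.70, 6.00, 1.20],
        "C": [5.90, 7.10, 5.80, 2.50],
        # strand borders
        "J": [6.30, 8.80, 6.40, 1.00],
        "K": [6.50, 8.40, 5.90, -1.00],
    }
    return np.array([means[l] for l in LETTERS], dtype=float)


@dataclass
class AlphabetModel:
    """Gaussian-emission HMM over the 27 structural letters.

    ``covariances`` is ``(27, 4)`` (diagonal, Å²) or ``(27, 4, 4)`` (full).
    """

    letters: tuple[str, ...]
    means: np.ndarray
    covariances: np.ndarray
    transition: np.ndarray
    initial: np.ndarray
    classes: dict[str, str] = field(default_factory=lambda: dict(SS_CLASS))

    def __post_init__(self) -> None:
        self.letters = tuple(self.letters)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.letters)

    def validate(self, tol: float = 1e-6) -> None:
        k = self.n_states
        if len(set(self.letters)) != k:
            raise ValueError("duplicate letters in model")
        if self.means.shape != (k, 4):
            raise ValueError("means must be (n_letters, 4)")
        if self.covariances.shape not in ((k, 4), (k, 4, 4)):
            raise ValueError("covariances must be diagonal (k,4) or full (k,4,4)")
        if self.covariances.ndim == 2:
            if np.any(self.covariances <= 0):
                raise ValueError("diagonal covariances must be positive")
        else:
            for c in self.covariances:
                if np.any(np.linalg.eigvalsh(c) <= 0):
                    raise ValueError("covariance matrices must be positive-definite")
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if np.any(self.transition < 0) or np.any(self.initial < 0):
            raise ValueError("negative probabilities")
        rows = self.transition.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > tol):
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > tol:
            raise ValueError("initial probabilities must sum to 1")
        if self.initial.shape != (k,):
            raise ValueError("initial vector shape mismatch")

    def log_emission(self, descriptors: np.ndarray) -> np.ndarray:
        """Log N(x | mean_s, cov_s) for each descriptor row and state → (n, k)."""
        x = np.atleast_2d(np.asarray(descriptors, dtype=float))
        n, k = x.shape[0], self.n_states
        out = np.empty((n, k))
        if self.covariances.ndim == 2:
            var = self.covariances  # (k, 4)
            for s in range(k):
                diff = x - self.means[s]
                out[:, s] = -0.5 * (np.sum(diff ** 2 / var[s], axis=1)
                                    + np.sum(np.log(2.0 * np.pi * var[s])))
        else:
            for s in range(k):
                cov = self.covariances[s]
                diff = x - self.means[s]
                sol = np.linalg.solve(cov, diff.T).T
                _, logdet = np.linalg.slogdet(cov)
                out[:, s] = -0.5 * (np.sum(diff * sol, axis=1)
                                    + logdet + 4 * np.log(2.0 * np.pi))
        return out

    def class_of(self, letter: str) -> str:
        return self.classes[letter]

    def to_json(self, path) -> None:
        payload = {
            "letters": list(self.letters),
            "ss_class": {l: self.classes[l] for l in self.letters},
            "emission": {
                "mean": self.means.tolist(),
                "cov": self.covariances.tolist(),
            },
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def default_model(variance: float = 0.5) -> AlphabetModel:
    """The synthetic default alphabet model (see module note).

    Shared isotropic descriptor variance (``variance`` Å², default 0.5) and
    uniform transition/initial probabilities: Viterbi decoding then reduces
    to per-fragment nearest-prototype assignment in descriptor space.
    """
    k = len(LETTERS)
    means = _synthetic_prototype_means()
    covs = np.full((k, 4), float(variance))
    trans = np.full((k, k), 1.0 / k)
    init = np.full(k, 1.0 / k)
    return AlphabetModel(LETTERS, means, covs, trans, init)


def load_model(path) -> AlphabetModel:
    """Load and validate an alphabet model from JSON."""
    with open(path) as fh:
        payload = json.load(fh)
    letters = tuple(payload["letters"])
    classes = dict(payload.get("ss_class") or SS_CLASS)
    return AlphabetModel(
        letters=letters,
        means=np.array(payload["emission"]["mean"], dtype=float),
        covariances=np.array(payload["emission"]["cov"], dtype=float),
        transition=np.array(payload["transition"], dtype=float),
        initial=np.array(payload["initial"], dtype=float),
        classes=classes,
    )
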