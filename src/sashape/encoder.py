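"""Structural-alphabet encoding of Cα traces.

A trace is cut into overlapping four-residue fragments (never spanning a
chain break); each fragment is summarized by four descriptors — the inter-Cα
distances d1 = |Cα1–Cα3|, d2 = |Cα1–Cα4|, d3 = |Cα2–Cα4| and the oriented
projection P4 of Cα4 onto the plane of the first three — and the descriptor
series is decoded into structural letters with the Viterbi algorithm under
the alphabet model's Gaussian emissions and transition probabilities.

The letter of the fragment covering residues r−2 … r+1 is attributed to
residue r, so an unbroken segment of n residues yields n−3 letters carried
by residues 3 … n−1 (1-based within the segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CaChain, ResidueKey

__all__ = [
    "Fragment",
    "StructuralSequence",
    "fragmentize",
    "compute_descriptors",
    "viterbi_encode",
    "assign_letters",
    "structural_identity",
]

#: Minimum triangle area (Å²) of Cα1-Cα2-Cα3 below which the fragment plane,
#: and hence P4, is undefined.
COLLINEARITY_AREA_TOL = 1e-6


@dataclass
class Fragment:
    start: ResidueKey                 # residue key of Cα1
    segment_index: int                # which unbroken segment of the chain
    position: int                     # 0-based fragment index within segment
    descriptors: np.ndarray | None    # (4,) or None if geometry is degenerate
    letter: str | None = None


@dataclass
class StructuralSequence:
    """Per-fragment letter string of one chain with the residue→letter map."""

    name: str
    chain: CaChain
    fragments: list[Fragment]
    residue_letter_map: dict[ResidueKey, str] = field(default_factory=dict)

    def body(self) -> str:
        """Letter string; unbroken segments joined by '-', '-' also marking
        fragments without a letter."""
        parts: dict[int, list[str]] = {}
        for frag in self.fragments:
            parts.setdefault(frag.segment_index, []).append(
                frag.letter if frag.letter is not None else "-")
        n_segments = len(self.chain.segments())
        return "-".join("".join(parts.get(i, [])) for i in range(n_segments))

    def letter_of(self, key: ResidueKey) -> str | None:
        return self.residue_letter_map.get(key)


def fragmentize(chain: CaChain) -> list[tuple[int, int, int]]:
    """Sliding four-residue windows as ``(segment_index, start, stop)`` index
    triples into ``chain.coords``; windows never span a break and segments
    shorter than four residues yield none."""
    windows = []
    for seg_i, (a, b) in enumerate(chain.segments()):
        for s in range(a, b - 3):
            windows.append((seg_i, s, s + 4))
    return windows


def compute_descriptors(window: np.ndarray) -> np.ndarray | None:
    """Descriptor vector (d1, d2, d3, P4) of a four-Cα window.

    P4 is the signed distance of Cα4 from the plane through Cα1..Cα3, the
    sign taken along n = (Cα2−Cα1) × (Cα3−Cα2); a right-handed α-helix gives
    P4 > 0.  Returns None when the first three points are collinear.
    """
    w = np.asarray(window, dtype=float)
    if w.shape != (4, 3):
        raise ValueError("window must contain exactly four Cα coordinates")
    c1, c2, c3, c4 = w
    d1 = float(np.linalg.norm(c3 - c1))
    d2 = float(np.linalg.norm(c4 - c1))
    d3 = float(np.linalg.norm(c4 - c2))
    normal = np.cross(c2 - c1, c3 - c2)
    area2 = np.linalg.norm(normal)        # twice the triangle area
    if area2 / 2.0 <= COLLINEARITY_AREA_TOL:
        return None
    p4 = float(np.dot(c4 - c1, normal / area2))
    return np.array([d1, d2, d3, p4])


def _viterbi_run(log_emis: np.ndarray, log_trans: np.ndarray,
                 log_init: np.ndarray) -> list[int]:
    """Maximum-probability state path; ties resolved toward the lower state
    index (canonical letter order)."""
    n, k = log_emis.shape
    delta = log_init + log_emis[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + log_trans          # (from, to)
        back[t] = np.argmax(cand, axis=0)          # argmax keeps first max
        delta = cand[back[t], np.arange(k)] + log_emis[t]
    path = [int(np.argmax(delta))]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t][path[-1]]))
    return path[::-1]


def viterbi_encode(descriptors, model) -> list[str | None]:
    """Decode a descriptor sequence into structural letters.

    ``descriptors`` is an iterable of 4-vectors or ``None`` entries; invalid
    (None) positions receive no letter and split the sequence into runs that
    are decoded independently (each restarting from the initial distribution).
    """
    model.validate(tol=1e-6)
    rows = [None if d is None else np.asarray(d, dtype=float) for d in descriptors]
    if not any(r is not None for r in rows):
        raise ValueError("no valid descriptors to decode")
    with np.errstate(divide="ignore"):
        log_trans = np.log(model.transition)
        log_init = np.log(model.initial)
    letters: list[str | None] = [None] * len(rows)
    run: list[int] = []
    for i in range(len(rows) + 1):
        if i < len(rows) and rows[i] is not None:
            run.append(i)
            continue
        if run:
            emis = model.log_emission(np.array([rows[j] for j in run]))
            states = _viterbi_run(emis, log_trans, log_init)
            for j, s in zip(run, states):
                letters[j] = model.letters[s]
            run = []
    return letters


def assign_letters(chain: CaChain, model, name: str = "") -> StructuralSequence:
    """Encode a chain and attribute each fragment's letter to its third residue."""
    windows = fragmentize(chain)
    fragments: list[Fragment] = []
    per_segment: dict[int, list[Fragment]] = {}
    for seg_i, s, e in windows:
        frag = Fragment(
            start=chain.keys[s],
            segment_index=seg_i,
            position=len(per_segment.setdefault(seg_i, [])),
            descriptors=compute_descriptors(chain.coords[s:e]),
        )
        frag._start_index = s  # internal: index into chain arrays
        per_segment[seg_i].append(frag)
        fragments.append(frag)
    for seg_frags in per_segment.values():
        descs = [f.descriptors for f in seg_frags]
        if not any(d is not None for d in descs):
            continue
        letters = viterbi_encode(descs, model)
        for frag, letter in zip(seg_frags, letters):
            frag.letter = letter
    seq = StructuralSequence(name=name or chain.chain_id, chain=chain,
                             fragments=fragments)
    for frag in fragments:
        if frag.letter is not None:
            seq.residue_letter_map[chain.keys[frag._start_index + 2]] = frag.letter
    return seq


def structural_identity(seq1: str, seq2: str) -> float:
    """Percent identity of two aligned letter strings over non-gap columns.

    Columns containing ``-`` on either side are excluded; raises if no
    comparable column remains.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    pairs = [(a, b) for a, b in zip(seq1, seq2) if a != "-" and b != "-"]
    if not pairs:
        raise ValueError("no comparable (non-gap) columns")
    matches = sum(a == b for a, b in pairs)
    return 100.0 * matches / len(pairs)
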