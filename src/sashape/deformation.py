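"""Bound/unbound comparison: letter transitions, deformation matrices and
exposure changes.

Matched bound/unbound chains are paired position-by-position through a
global amino-acid sequence alignment.  At every paired position carrying a
letter on both sides, the transition sl_unbound → sl_bound is counted in the
compartment of the *bound* state (interface is a bound-state notion).  From
the counts C we form, per compartment, the deformation-proportion matrix

    P(sl1, sl2) = C(sl1, sl2) / Σ_{sl2' ≠ sl1} C(sl1, sl2'),   sl2 ≠ sl1,

conditioning on deformed letters only, and the interface-minus-surface
difference ΔP = P_interf − P_surf, which isolates deformations induced by
the interaction from those due to intrinsic flexibility.

For deformed loop positions at the interface, the exposure difference
D = A_chain(unbound) − A_chain(bound, disjoint) is reported per
surface-/core-letter transition category (s/s, s/c, c/s, c/c); a negative D
means the deformation increased exposure to the protein exterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .geometry import superpose
from .io import CaChain, ResidueKey
from .model import (CORE_LETTERS, INTERFACE_LETTERS, LETTERS,
                    NON_INTERFACE_LETTERS, SURFACE_LETTERS, SS_CLASS)

__all__ = [
    "SURFACE_LETTERS",
    "CORE_LETTERS",
    "NON_INTERFACE_LETTERS",
    "INTERFACE_LETTERS",
    "PositionMap",
    "pair_chains",
    "transition_counts",
    "changed_fraction",
    "deformation_proportions",
    "delta_p",
    "exposure_difference",
    "straight_letter_shift",
    "kabsch_rmsd",
    "STRAIGHT_LETTERS",
]

#: Regular straight letters whose occurrence shift tracks the straightening
#: of secondary structures upon binding.
STRAIGHT_LETTERS = frozenset("ATM")

MIN_PAIRING_IDENTITY = 80.0  # percent, over aligned columns


@dataclass
class PositionMap:
    """One-to-one, order-preserving residue pairing between two chains."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    unaligned_unbound: list[ResidueKey] = field(default_factory=list)
    unaligned_bound: list[ResidueKey] = field(default_factory=list)
    identity: float = 100.0

    def __len__(self) -> int:
        return len(self.pairs)


def pair_chains(unbound: CaChain, bound: CaChain) -> PositionMap:
    """Pair residues of the unbound and bound chains.

    Global alignment of the amino-acid sequences (match +1, mismatch −1,
    gap −2); only aligned *identical* residues become pairs, mismatches are
    dropped with a warning.  Aligned-column identity below 80% raises — the
    chains are probably not the same protein.
    """
    if len(unbound) == 0 or len(bound) == 0:
        raise ValueError("cannot pair empty chains")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    s1, s2 = "".join(unbound.aa), "".join(bound.aa)
    alignment = aligner.align(s1, s2)[0]
    pairs, mismatched = [], 0
    aligned_cols = 0
    paired_u, paired_b = set(), set()
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            aligned_cols += 1
            if s1[i] == s2[j]:
                pairs.append((unbound.keys[i], bound.keys[j]))
                paired_u.add(i)
                paired_b.add(j)
            else:
                mismatched += 1
    if aligned_cols == 0:
        raise ValueError("no aligned columns between chains")
    identity = 100.0 * len(pairs) / aligned_cols
    if identity < MIN_PAIRING_IDENTITY:
        raise ValueError(
            f"aligned-column identity {identity:.1f}% < {MIN_PAIRING_IDENTITY}%: "
            "wrong chain pairing suspected")
    if mismatched:
        warnings.warn(f"{mismatched} mismatched aligned columns dropped from pairing")
    return PositionMap(
        pairs=pairs,
        unaligned_unbound=[unbound.keys[i] for i in range(len(unbound)) if i not in paired_u],
        unaligned_bound=[bound.keys[j] for j in range(len(bound)) if j not in paired_b],
        identity=identity,
    )


def _letter_map(seq) -> dict:
    return seq if isinstance(seq, dict) else seq.residue_letter_map


def _compartment_map(records) -> dict:
    if isinstance(records, dict):
        return records
    return {r.residue: r.compartment for r in records}


def transition_counts(position_map: PositionMap, seq_unbound, seq_bound,
                      compartments_bound,
                      letters: tuple[str, ...] = LETTERS) -> dict[str, pd.DataFrame]:
    """Per-compartment transition count matrices C(sl_unbound, sl_bound).

    Positions lacking a letter on either side, or whose bound-state
    compartment is undefined/missing, are skipped.
    """
    lu, lb = _letter_map(seq_unbound), _letter_map(seq_bound)
    cp_of = _compartment_map(compartments_bound)
    out = {cp: pd.DataFrame(0, index=list(letters), columns=list(letters))
           for cp in ("interface", "surface", "core")}
    for key_u, key_b in position_map.pairs:
        a, b = lu.get(key_u), lb.get(key_b)
        cp = cp_of.get(key_b)
        if a is None or b is None or cp not in out:
            continue
        out[cp].loc[a, b] += 1
    return out


def changed_fraction(c: pd.DataFrame) -> float:
    """Off-diagonal mass over total: the proportion of letters changed."""
    total = float(c.to_numpy().sum())
    if total == 0:
        raise ValueError("empty transition matrix")
    diag = float(np.trace(c.to_numpy()))
    return (total - diag) / total


def deformation_proportions(c: pd.DataFrame) -> pd.DataFrame:
    """P(sl1, sl2) over deformed letters only.

    Rows with zero deformations are absent; the diagonal is NaN (a letter
    staying itself is not a deformation).
    """
    mat = c.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative transition counts")
    off = mat.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    keep = row_sums > 0
    p = off[keep] / row_sums[keep, None]
    frame = pd.DataFrame(p, index=c.index[keep], columns=c.columns)
    for letter in frame.index:
        if letter in frame.columns:
            frame.loc[letter, letter] = np.nan
    return frame


def delta_p(p_interf: pd.DataFrame, p_surf: pd.DataFrame
            ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """ΔP = P_interf − P_surf, entrywise.

    Rows present in only one compartment use 0 for the missing one; the
    second return value lists those rows per side.
    """
    rows = sorted(set(p_interf.index) | set(p_surf.index))
    cols = sorted(set(p_interf.columns) | set(p_surf.columns))
    pi = p_interf.reindex(index=rows, columns=cols)
    ps = p_surf.reindex(index=rows, columns=cols)
    missing = {
        "surface_only": sorted(set(p_surf.index) - set(p_interf.index)),
        "interface_only": sorted(set(p_interf.index) - set(p_surf.index)),
    }
    delta = pi.fillna(0.0) - ps.fillna(0.0)
    for letter in delta.index:
        if letter in delta.columns:
            delta.loc[letter, letter] = np.nan
    return delta, missing


def _transition_category(sl1: str, sl2: str) -> str | None:
    def group(l: str) -> str | None:
        if l in SURFACE_LETTERS:
            return "s"
        if l in CORE_LETTERS:
            return "c"
        return None
    g1, g2 = group(sl1), group(sl2)
    if g1 is None or g2 is None:
        return None
    return f"{g1}/{g2}"


def exposure_difference(position_map: PositionMap, seq_unbound, seq_bound,
                        compartments_bound, a_chain_unbound: dict,
                        a_chain_bound: dict,
                        restrict_class: str = "loop"
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure differences D for deformed letters at the bound interface.

    D = A_chain(unbound) − A_chain(bound, disjoint), per position, for paired
    positions whose bound compartment is interface, whose letters differ and
    (by default) are both loop-letters.  Returns the per-position table and
    mean ± sd / median aggregates per surface/core transition category.
    """
    lu, lb = _letter_map(seq_unbound), _letter_map(seq_bound)
    cp_of = _compartment_map(compartments_bound)
    rows = []
    for key_u, key_b in position_map.pairs:
        sl1, sl2 = lu.get(key_u), lb.get(key_b)
        if sl1 is None or sl2 is None or sl1 == sl2:
            continue
        if cp_of.get(key_b) != "interface":
            continue
        if restrict_class and not (SS_CLASS.get(sl1) == restrict_class
                                   and SS_CLASS.get(sl2) == restrict_class):
            continue
        au, ab = a_chain_unbound.get(key_u), a_chain_bound.get(key_b)
        if au is None or ab is None:
            warnings.warn(f"position {key_u}/{key_b} missing accessibility; skipped")
            continue
        rows.append({"unbound": key_u, "bound": key_b, "sl1": sl1, "sl2": sl2,
                     "D": float(au) - float(ab),
                     "category": _transition_category(sl1, sl2)})
    positions = pd.DataFrame(rows, columns=["unbound", "bound", "sl1", "sl2",
                                            "D", "category"])
    if len(positions):
        grouped = positions.dropna(subset=["category"]).groupby("category")["D"]
        aggregates = grouped.agg(["mean", "std", "median", "count"])
    else:
        aggregates = pd.DataFrame(columns=["mean", "std", "median", "count"])
    return positions, aggregates


def straight_letter_shift(seq_unbound, seq_bound) -> int:
    """Occurrence difference of the straight letters [A, T, M]:
    count(bound) − count(unbound)."""
    def count(seq) -> int:
        letters = seq.values() if isinstance(seq, dict) else (
            seq.residue_letter_map.values() if hasattr(seq, "residue_letter_map")
            else seq)
        return sum(1 for l in letters if l in STRAIGHT_LETTERS)
    return count(seq_bound) - count(seq_unbound)


def kabsch_rmsd(coords1: np.ndarray, coords2: np.ndarray) -> float:
    """RMSD (Å) after least-squares rigid superposition of matched Cα sets."""
    a = np.asarray(coords1, dtype=float)
    b = np.asarray(coords2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 3:
        raise ValueError("need two equal sets of at least 3 matched points")
    rot, t = superpose(a, b)
    moved = a @ rot.T + t
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
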