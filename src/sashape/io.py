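"""Reading PDB coordinate files into Cα traces and writing result tables.

Structures are reduced to two parallel views: per-chain full-atom records
(used for surface-area calculations) and per-chain ordered Cα traces (used
for structural-alphabet encoding).  Residue identity follows author
numbering: ``(chain_id, residue_number, insertion_code)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "ResidueKey",
    "AtomRecord",
    "CaChain",
    "ComplexStructure",
    "read_pdb",
    "detect_breaks",
    "write_structural_fasta",
    "write_pdb",
    "CA_MIN_DIST",
    "CA_MAX_DIST",
]

#: Plausible range for a consecutive Cα–Cα distance (Å); steps outside this
#: window mark a chain break.
CA_MIN_DIST = 2.5
CA_MAX_DIST = 4.5

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Common non-standard residues mapped to their parent amino acid.  Kept for
#: backbone geometry; anything not listed here or in the standard 20 is
#: excluded from composition statistics but still traced if it has a Cα.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "M3L": "LYS", "KCX": "LYS", "LLP": "LYS",
}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author-numbering identity of a residue: chain, number, insertion code."""

    chain_id: str
    residue_number: int
    insertion_code: str = " "

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ic = self.insertion_code.strip()
        return f"{self.chain_id}:{self.residue_number}{ic}"


@dataclass
class AtomRecord:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = " "
    is_hetero: bool = False

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class CaChain:
    """Ordered Cα trace of one chain.

    ``breaks`` holds 0-based positions ``i`` such that the chain is
    discontinuous between residues ``i`` and ``i+1``.
    """

    chain_id: str
    keys: list[ResidueKey]
    aa: list[str]                     # one-letter codes, 'X' when unknown
    coords: np.ndarray                # (n, 3) Å
    breaks: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.keys) == 0:
            raise ValueError("CaChain requires at least one residue")
        if self.coords.shape != (len(self.keys), 3):
            raise ValueError("coordinate array shape mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite Cα coordinates")

    def __len__(self) -> int:
        return len(self.keys)

    def segments(self) -> list[tuple[int, int]]:
        """Contiguous runs ``[start, stop)`` delimited by chain breaks."""
        bounds = sorted(self.breaks)
        segs, start = [], 0
        for b in bounds:
            segs.append((start, b + 1))
            start = b + 1
        segs.append((start, len(self)))
        return [(a, b) for a, b in segs if b > a]


@dataclass
class ComplexStructure:
    """All chains of one PDB entry plus the two chains whose interface is studied."""

    chains: dict[str, CaChain]
    atoms: dict[str, list[AtomRecord]]
    pair_of_interest: tuple[str, str] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.pair_of_interest is not None:
            a, b = self.pair_of_interest
            if a == b:
                raise ValueError("pair of interest must be two distinct chains")
            for c in (a, b):
                if c not in self.chains:
                    raise ValueError(f"chain {c!r} not present in structure")

    def chain(self, chain_id: str) -> CaChain:
        return self.chains[chain_id]


_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def three_letter(aa: str) -> str:
    """Three-letter code of a one-letter amino acid ('UNK' when unknown)."""
    return _ONE_TO_THREE.get(aa.upper(), "UNK")


def one_letter(resname: str) -> str:
    """One-letter code; non-standard residues map to their parent, else 'X'."""
    resname = resname.upper()
    if resname in _THREE_TO_ONE:
        return _THREE_TO_ONE[resname]
    parent = NONSTANDARD_PARENT.get(resname)
    return _THREE_TO_ONE.get(parent, "X") if parent else "X"


def is_standard_or_parent(resname: str) -> bool:
    return resname.upper() in _THREE_TO_ONE or resname.upper() in NONSTANDARD_PARENT


def detect_breaks(coords: np.ndarray | CaChain) -> set[int]:
    """Positions ``i`` where the Cα(i)→Cα(i+1) step leaves [2.5, 4.5] Å.

    Distance governs: a jump in author numbering with a plausible step
    distance is *not* a break.
    """
    if isinstance(coords, CaChain):
        coords = coords.coords
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        return set()
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    bad = (d < CA_MIN_DIST) | (d > CA_MAX_DIST)
    return set(np.nonzero(bad)[0].tolist())


def _pick_altloc(atoms: Iterable) -> "object":
    """Highest-occupancy altloc; ties keep the first encountered."""
    best, best_occ = None, -np.inf
    for a in atoms:
        occ = a.get_occupancy()
        occ = 1.0 if occ is None else occ
        if occ > best_occ:
            best, best_occ = a, occ
    return best


def read_pdb(path, pair_of_interest: tuple[str, str] | None = None,
             model_index: int = 0, name: str = "") -> ComplexStructure:
    """Parse a PDB file into a :class:`ComplexStructure`.

    Altloc duplicates keep the highest-occupancy conformer (ties: first in
    file).  HETATM residues are excluded from the Cα trace but retained in
    the atom records (flagged) so they can optionally enter surface-area
    calculations.  Multi-model files use ``model_index`` only.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(name or "entry", path)
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no ATOM records")
    try:
        model = models[model_index]
    except IndexError:
        raise ValueError(f"{path}: model index {model_index} out of range") from None

    chains: dict[str, CaChain] = {}
    atoms: dict[str, list[AtomRecord]] = {}
    n_atoms = 0
    for chain in model:
        chain_id = chain.id
        recs: list[AtomRecord] = []
        keys, aas, coords = [], [], []
        for residue in chain:
            hetflag, resseq, icode = residue.id
            is_het = hetflag.strip() != "" and not is_standard_or_parent(residue.resname)
            for atom in residue:
                picked = _pick_altloc(atom) if atom.is_disordered() else atom
                occ = picked.get_occupancy()
                recs.append(AtomRecord(
                    chain_id=chain_id,
                    residue_number=resseq,
                    insertion_code=icode or " ",
                    residue_name=residue.resname,
                    atom_name=picked.get_name(),
                    element=(picked.element or "").strip() or picked.get_name()[:1],
                    coord=np.asarray(picked.coord, dtype=float),
                    occupancy=1.0 if occ is None else float(occ),
                    altloc=picked.get_altloc() or " ",
                    is_hetero=is_het,
                ))
                n_atoms += 1
            if is_het:
                continue
            if "CA" in residue:
                ca = residue["CA"]
                picked = _pick_altloc(ca) if ca.is_disordered() else ca
                keys.append(ResidueKey(chain_id, resseq, icode or " "))
                aas.append(one_letter(residue.resname))
                coords.append(np.asarray(picked.coord, dtype=float))
        if recs:
            atoms[chain_id] = recs
        if keys:
            trace = CaChain(chain_id, keys, aas, np.array(coords))
            trace.breaks = detect_breaks(trace)
            chains[chain_id] = trace
        elif recs and any(not r.is_hetero for r in recs):
            warnings.warn(f"{path}: chain {chain_id} has no Cα atoms; dropped from trace")
    if n_atoms == 0:
        raise ValueError(f"{path}: no ATOM records")
    return ComplexStructure(chains=chains, atoms=atoms,
                            pair_of_interest=pair_of_interest,
                            name=name or str(path))


def write_structural_fasta(sequences: Sequence, path) -> None:
    """Write structural sequences as FASTA-like records.

    Each record header is ``>name_chain``; the body is the letter string of
    each unbroken segment, segments joined by ``-`` (a position with no
    letter).  Segments shorter than four residues contribute an empty string.
    """
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.name}\n")
            fh.write(seq.body() + "\n")


def write_pdb(complex_structure: ComplexStructure, path) -> None:
    """Serialize atom records back to PDB format (fixed columns, 3 decimals)."""
    with open(path, "w") as fh:
        serial = 1
        for chain_id in complex_structure.atoms:
            for rec in complex_structure.atoms[chain_id]:
                tag = "HETATM" if rec.is_hetero else "ATOM  "
                name = rec.atom_name
                # PDB atom-name column convention: element right-justified in 14-15
                name_field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"{tag}{serial:5d} {name_field}{rec.altloc if rec.altloc.strip() else ' '}"
                    f"{rec.residue_name:>3s} {rec.chain_id}{rec.residue_number:4d}"
                    f"{rec.insertion_code if rec.insertion_code.strip() else ' '}   "
                    f"{rec.coord[0]:8.3f}{rec.coord[1]:8.3f}{rec.coord[2]:8.3f}"
                    f"{rec.occupancy:6.2f}{0.0:6.2f}          "
                    f"{rec.element:>2s}\n"
                )
                serial += 1
            fh.write("TER\n")
        fh.write("END\n")
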