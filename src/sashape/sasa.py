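"""Solvent accessibility and residue compartments.

Per-residue relative solvent accessibility is computed in three structural
contexts — the chain alone (A_chain), the two-chain complex forming the
interface of interest (A_interf) and the full entry with all chains
(A_complex) — each as a percentage of the residue's accessible area in an
extended ALA-X-ALA tripeptide.  Residues are then assigned to one of the
compartments

* interface — exposed (A_chain > 5%) and losing more than 1 point of
  accessibility when the partner chain is added (A_chain − A_interf > 1);
* surface   — exposed and unchanged in the full complex;
* core      — buried (A_chain < 5%) and unchanged in the full complex;
* undefined — anything else (excluded from downstream statistics).

"Unchanged" means |A_chain − A_complex| ≤ 0.05 percentage points: the
published rule states an exact 0% change, which is ill-defined in floating
point; the tolerance mirrors fixed-precision accessibility output.

Atomic areas use the Shrake–Rupley construction: each atom's sphere is
expanded by the probe radius (1.4 Å water) and sampled with a deterministic
golden-spiral point lattice; sample points inside any neighbour's expanded
sphere are occluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import nerf_place, superpose
from .io import AtomRecord, ComplexStructure, ResidueKey, one_letter

__all__ = [
    "RadiusSet",
    "AccessibilityRecord",
    "sphere_points",
    "shrake_rupley",
    "build_reference",
    "relative_accessibility",
    "accessibility_contexts",
    "assign_compartment",
    "PSEUDO_ATOM_RADIUS",
    "DEFAULT_PROBE",
    "DEFAULT_N_POINTS",
]

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
#: Radius of the single per-residue pseudo-atom used for Cα-only synthetic
#: structures (compartment logic depends on accessibility *changes*, so a
#: coarse sphere per residue suffices there).
PSEUDO_ATOM_RADIUS = 3.0

COMPARTMENTS = ("interface", "surface", "core")


@dataclass
class RadiusSet:
    """Van der Waals radii by element (NACCESS/Chothia-style values, Å)."""

    by_element: dict[str, float] = None
    default: float = 1.80

    def __post_init__(self) -> None:
        if self.by_element is None:
            self.by_element = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85,
                               "P": 1.90, "H": 1.00, "SE": 1.90}
        for r in list(self.by_element.values()) + [self.default]:
            if not 0.5 < r < 3.0:
                raise ValueError("van der Waals radii must lie in (0.5, 3.0) Å")

    def radius(self, element: str) -> float:
        return self.by_element.get(element.upper().strip(), self.default)

    def for_atoms(self, atoms: list[AtomRecord]) -> np.ndarray:
        return np.array([self.radius(a.element) for a in atoms])


@dataclass
class AccessibilityRecord:
    residue: ResidueKey
    aa: str
    a_chain: float
    a_interf: float
    a_complex: float
    compartment: str | None = None
    capped: bool = False
    has_reference: bool = True


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere lattice (golden spiral), deterministic."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible area (Å²)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    expanded = radii + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    r_max = expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        neigh = tree.query_ball_point(coords[i], expanded[i] + r_max)
        neigh = [j for j in neigh if j != i
                 and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]]
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        if neigh:
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            exposed = np.all(d2 >= (expanded[neigh] ** 2)[None, :], axis=1)
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed.mean()
    return areas


# --- extended ALA-X-ALA reference ------------------------------------------

_BB_GEOMETRY = {
    # bond (Å), angle (deg) for the repeating N-CA-C backbone; extended chain
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "phi": -139.0, "psi": 135.0, "omega": 180.0,
}

STANDARD_AA3 = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY",
                "HIS", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER",
                "THR", "TRP", "TYR", "VAL")


def _extended_backbone(n_res: int = 3) -> list[dict[str, np.ndarray]]:
    """Idealized extended (β-like) backbone frames: N, CA, C per residue."""
    g = _BB_GEOMETRY
    frames = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g["n_ca"], 0.0, 0.0])
    # orient C so that the N-CA-C angle is correct
    ang = np.radians(g["ang_n_ca_c"])
    c0 = ca0 + g["ca_c"] * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    frames.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = frames[-1]
        n = nerf_place(prev["N"], prev["CA"], prev["C"],
                       g["c_n"], g["ang_ca_c_n"], g["psi"])
        ca = nerf_place(prev["CA"], prev["C"], n,
                        g["n_ca"], g["ang_c_n_ca"], g["omega"])
        c = nerf_place(prev["C"], n, ca,
                       g["ca_c"], g["ang_n_ca_c"], g["phi"])
        frames.append({"N": n, "CA": ca, "C": c})
    return frames


def _template_heavy_atoms(resname: str):
    """Idealized residue template (heavy atoms, no OXT) from the chemical
    component dictionary bundled with biotite."""
    import biotite.structure.info as bsinfo

    res = bsinfo.residue(resname)
    keep = (res.element != "H") & (res.atom_name != "OXT")
    res = res[keep]
    return res.atom_name.tolist(), res.coord.astype(float), res.element.tolist()


def build_tripeptide(center_resname: str) -> tuple[list[str], np.ndarray, list[str], list[int]]:
    """Extended ALA-X-ALA heavy-atom model.

    Returns atom names, coordinates, elements and the residue index (0/1/2)
    of each atom; residue 1 is X.
    """
    frames = _extended_backbone(3)
    names_all, coords_all, elements_all, res_idx = [], [], [], []
    for i, resname in enumerate(["ALA", center_resname, "ALA"]):
        names, coords, elements = _template_heavy_atoms(resname)
        idx = {n: j for j, n in enumerate(names)}
        for bb in ("N", "CA", "C"):
            if bb not in idx:
                raise ValueError(f"template {resname} lacks backbone atom {bb}")
        mobile = coords[[idx["N"], idx["CA"], idx["C"]]]
        target = np.array([frames[i]["N"], frames[i]["CA"], frames[i]["C"]])
        rot, t = superpose(mobile, target)
        placed = coords @ rot.T + t
        names_all.extend(names)
        coords_all.append(placed)
        elements_all.extend(elements)
        res_idx.extend([i] * len(names))
    return names_all, np.vstack(coords_all), elements_all, res_idx


def build_reference(radii: RadiusSet | None = None, probe: float = DEFAULT_PROBE,
                    n_points: int = DEFAULT_N_POINTS) -> dict[str, float]:
    """Absolute accessible area (Å²) of residue X in extended ALA-X-ALA,
    for each of the 20 standard amino acids."""
    radii = radii or RadiusSet()
    reference = {}
    for resname in STANDARD_AA3:
        _, coords, elements, res_idx = build_tripeptide(resname)
        r = np.array([radii.radius(e) for e in elements])
        areas = shrake_rupley(coords, r, probe=probe, n_points=n_points)
        reference[resname] = float(areas[np.array(res_idx) == 1].sum())
    return reference


_ONE_TO_THREE = {one_letter(r): r for r in STANDARD_AA3}


def relative_accessibility(area: float, aa: str,
                           reference: dict[str, float]) -> tuple[float, bool]:
    """Percent of the extended-tripeptide reference; values over 100 are
    capped (flag returned).  ``aa`` may be a one- or three-letter code."""
    key = aa if len(aa) == 3 else _ONE_TO_THREE.get(aa, "")
    if key not in reference:
        raise KeyError(f"no reference accessibility for residue {aa!r}")
    pct = 100.0 * area / reference[key]
    if pct > 100.0:
        return 100.0, True
    return pct, False


def _residue_areas(atoms: list[AtomRecord], radii: RadiusSet, probe: float,
                   n_points: int, pseudo: bool) -> dict[ResidueKey, float]:
    coords = np.array([a.coord for a in atoms])
    if pseudo:
        r = np.full(len(atoms), PSEUDO_ATOM_RADIUS)
    else:
        r = radii.for_atoms(atoms)
    areas = shrake_rupley(coords, r, probe=probe, n_points=n_points)
    out: dict[ResidueKey, float] = {}
    for a, area in zip(atoms, areas):
        out[a.residue_key] = out.get(a.residue_key, 0.0) + float(area)
    return out


def _is_ca_only(atoms: list[AtomRecord]) -> bool:
    return all(a.atom_name == "CA" for a in atoms)


def accessibility_contexts(complex_structure: ComplexStructure, chain_id: str,
                           reference: dict[str, float] | None = None,
                           radii: RadiusSet | None = None,
                           probe: float = DEFAULT_PROBE,
                           n_points: int = DEFAULT_N_POINTS,
                           include_hetero: bool = False,
                           mode: str = "auto") -> list[AccessibilityRecord]:
    """A_chain / A_interf / A_complex for every residue of ``chain_id``.

    ``mode`` is ``"atomic"``, ``"pseudo"`` (one Cα sphere per residue) or
    ``"auto"`` (pseudo when the chain holds only Cα records).  In pseudo mode
    the reference area is the isolated pseudo-sphere surface.
    """
    if chain_id not in complex_structure.atoms:
        raise KeyError(f"chain {chain_id!r} not in structure")
    radii = radii or RadiusSet()

    def keep(a: AtomRecord) -> bool:
        return include_hetero or not a.is_hetero

    chain_atoms = [a for a in complex_structure.atoms[chain_id] if keep(a)]
    if not chain_atoms:
        raise ValueError(f"chain {chain_id!r} has no atoms for SASA")
    pseudo = (mode == "pseudo") or (mode == "auto" and _is_ca_only(chain_atoms))
    if mode not in ("auto", "atomic", "pseudo"):
        raise ValueError(f"unknown SASA mode {mode!r}")

    pair = complex_structure.pair_of_interest
    if pair is not None and chain_id in pair:
        partner = pair[0] if pair[1] == chain_id else pair[1]
        pair_ids = [chain_id, partner]
    else:
        pair_ids = [chain_id]
    all_ids = list(complex_structure.atoms)

    def atom_set(ids: list[str]) -> list[AtomRecord]:
        return [a for cid in ids for a in complex_structure.atoms[cid] if keep(a)]

    contexts = []
    for ids in ([chain_id], pair_ids, all_ids):
        contexts.append(_residue_areas(atom_set(ids), radii, probe, n_points, pseudo))

    if pseudo:
        iso = 4.0 * np.pi * (PSEUDO_ATOM_RADIUS + probe) ** 2
        ref = None
    else:
        ref = reference if reference is not None else build_reference(
            radii, probe=probe, n_points=n_points)

    trace = complex_structure.chains.get(chain_id)
    aa_of = {}
    if trace is not None:
        aa_of = dict(zip(trace.keys, trace.aa))
    records = []
    seen: set[ResidueKey] = set()
    for a in chain_atoms:
        key = a.residue_key
        if key in seen:
            continue
        seen.add(key)
        aa = aa_of.get(key, one_letter(a.residue_name))
        pcts, capped, has_ref = [], False, True
        for ctx in contexts:
            area = ctx.get(key, 0.0)
            if pseudo:
                pct = min(100.0 * area / iso, 100.0)
            else:
                try:
                    pct, c = relative_accessibility(area, a.residue_name, ref)
                    capped = capped or c
                except KeyError:
                    has_ref = False
                    pct = float("nan")
            pcts.append(pct)
        records.append(AccessibilityRecord(
            residue=key, aa=aa, a_chain=pcts[0], a_interf=pcts[1],
            a_complex=pcts[2], capped=capped, has_reference=has_ref))
    for rec in records:
        rec.compartment = assign_compartment(rec) if rec.has_reference else None
    return records


def assign_compartment(rec: AccessibilityRecord, burial_threshold: float = 5.0,
                       interface_delta: float = 1.0, tol: float = 0.05) -> str:
    """Compartment label from the three accessibility percentages.

    Strict inequalities on both sides of the burial threshold: a residue at
    exactly 5% fits neither the exposed nor the buried definition.
    """
    a_chain, a_interf, a_complex = rec.a_chain, rec.a_interf, rec.a_complex
    if a_chain > burial_threshold and a_chain - a_interf > interface_delta:
        return "interface"
    if a_chain > burial_threshold and abs(a_chain - a_complex) <= tol:
        return "surface"
    if a_chain < burial_threshold and abs(a_chain - a_complex) <= tol:
        return "core"
    return "undefined"
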