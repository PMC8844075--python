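"""Activation-geometry measurements between paired receptor states.

Quantifies the inactive→active transition of a receptor from two
superposable structures: per-residue Cα displacements (e.g. the outward
movement of the extracellular TM tips on agonist binding), helix-axis tilt
angles (e.g. the Gα α5 helix), χ1 rotamer changes, explicit distance-cutoff
contacts (polar, van der Waals, salt bridge, π–cation), minimum heavy-atom
distances, and peptide insertion depth below the pocket's upper boundary.

Polar contacts are distance-only (deposited models lack hydrogens, so no
donor–acceptor angle term is applied); this is a documented limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError, PairingError
from .membrane_frame import apply_transform, kabsch_superpose
from .structure_io import AtomRecord, Selector, Structure, TMAnnotation, select_atoms
from .tm_boundary import PocketBounds

__all__ = ["ContactCriteria", "ContactRecord", "StateComparison", "Chi1Result",
           "ca_displacements", "helix_axis", "tilt_angle", "chi1_rotamer",
           "detect_contacts", "min_distance", "insertion_depth", "dihedral_angle",
           "helix_tip_residue", "compare_states"]

_HEAVY = Selector.heavy()

# first side-chain heavy atom beyond CB, per residue type (χ1 gamma atom)
GAMMA_ATOM = {
    "SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1", "ILE": "CG1",
    "ALA": None, "GLY": None,
}
_DEFAULT_GAMMA = "CG"

_POLAR_ELEMENTS = {"N", "O", "S"}
_BASIC_SIDECHAIN = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
_ACIDIC_SIDECHAIN = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_CATION_ATOMS = {"ARG": {"CZ", "NH1", "NH2"}, "LYS": {"NZ"}}
_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


@dataclass(frozen=True)
class ContactCriteria:
    """Distance cutoffs (Å) defining each contact kind."""

    polar_cutoff: float = 3.5
    vdw_cutoff: float = 4.0
    salt_bridge_cutoff: float = 4.0
    pi_cation_cutoff: float = 6.0
    kinds: tuple = ("polar", "vdw", "salt_bridge", "pi_cation")


@dataclass(frozen=True)
class ContactRecord:
    """One qualifying atom pair (or cation–ring-centroid pair for π–cation)."""

    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    kind: str

    def as_row(self) -> tuple:
        a, b = self.atom_a, self.atom_b
        return (f"{a.chain_id}/{a.residue_name}{a.residue_number}{a.insertion_code}/{a.atom_name}",
                f"{b.chain_id}/{b.residue_name}{b.residue_number}{b.insertion_code}/{b.atom_name}",
                self.kind, round(self.distance, 3))


@dataclass(frozen=True)
class Chi1Result:
    chi1: float | None
    chi1_class: str  # gauche-, gauche+, trans, undefined


@dataclass
class StateComparison:
    """Bundle of per-residue and per-segment activation metrics for a pair."""

    displacements: dict = field(default_factory=dict)
    tilts: dict = field(default_factory=dict)
    rotamer_changes: dict = field(default_factory=dict)
    contacts_gained: list = field(default_factory=list)
    contacts_lost: list = field(default_factory=list)
    alignment_rmsd: float = 0.0


# ---------------------------------------------------------------------------
# displacements
# ---------------------------------------------------------------------------

def _ca_index(structure: Structure, selector: Selector | None) -> dict:
    sub = structure if selector is None else select_atoms(structure, selector)
    out = {}
    for a in sub:
        if a.atom_name == "CA" and not a.is_hydrogen:
            out.setdefault(a.residue_key, a)
    return out


def ca_displacements(a: Structure, b: Structure,
                     align_selector: Selector | None = None,
                     measure_selector: Selector | None = None
                     ) -> dict[tuple[str, int, str], float]:
    """Per-residue Cα distance after superposing *b* onto *a*.

    *b* is rigidly superposed onto *a* using the Cα atoms common to both and
    matching ``align_selector``; distances are then reported for every
    residue matching ``measure_selector`` present in both structures.
    """
    align_a = _ca_index(a, align_selector)
    align_b = _ca_index(b, align_selector)
    keys = [k for k in align_a if k in align_b]
    if len(keys) < 3:
        raise PairingError(f"only {len(keys)} common Cα atoms available for alignment")
    P = np.array([align_b[k].position for k in keys])
    Q = np.array([align_a[k].position for k in keys])
    transform, _ = kabsch_superpose(P, Q)

    meas_a = _ca_index(a, measure_selector)
    meas_b = _ca_index(b, measure_selector)
    out: dict[tuple[str, int, str], float] = {}
    for k in meas_a:
        if k in meas_b:
            moved = transform.apply(meas_b[k].position)
            out[k] = float(np.linalg.norm(moved - meas_a[k].position))
    if not out:
        raise PairingError("no common residues in the measurement selection")
    return out


# ---------------------------------------------------------------------------
# helix axes and tilts
# ---------------------------------------------------------------------------

def helix_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis and centroid of an ordered Cα trace (≥5 points).

    The axis is the largest-variance direction of the centered coordinates,
    its sign chosen to point from the first toward the last residue.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise InputError(f"coordinates must be (N,3), got {X.shape}")
    if X.shape[0] < 5:
        raise InputError(f"helix axis needs ≥5 Cα atoms, got {X.shape[0]}")
    centroid = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - centroid)
    axis = Vt[0]
    if axis @ (X[-1] - X[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), centroid


def tilt_angle(axis_a: np.ndarray, axis_b: np.ndarray) -> float:
    """Unsigned acute angle between two axis directions, degrees in [0, 90]."""
    a = np.asarray(axis_a, dtype=float)
    b = np.asarray(axis_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InputError("tilt angle undefined for a zero vector")
    cosang = np.clip(abs(float(a @ b) / (na * nb)), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# rotamers
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> float:
    """IUPAC torsion p0–p1–p2–p3, degrees in (−180, 180] (cis = 0)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    ang = np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w))
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def classify_chi1(chi1: float) -> str:
    """Nearest canonical well: trans 180°±60, gauche+ −60°±60, gauche− +60°±60."""
    c = (chi1 + 180.0) % 360.0 - 180.0
    if 0.0 <= c < 120.0:
        return "gauche-"
    if -120.0 <= c < 0.0:
        return "gauche+"
    return "trans"


def chi1_rotamer(residue_atoms) -> Chi1Result:
    """χ1 (N–CA–CB–γ) and its rotamer class for one residue's atoms.

    Gly/Ala have no χ1 → ``undefined``; missing atoms give ``undefined`` with
    a warning rather than an exception.
    """
    atoms = list(residue_atoms)
    if not atoms:
        raise InputError("empty residue")
    resname = atoms[0].residue_name
    gamma_name = GAMMA_ATOM.get(resname, _DEFAULT_GAMMA)
    if gamma_name is None:
        return Chi1Result(None, "undefined")
    pos = {a.atom_name: a.position for a in atoms if not a.is_hydrogen}
    needed = ("N", "CA", "CB", gamma_name)
    if any(n not in pos for n in needed):
        missing = [n for n in needed if n not in pos]
        warnings.warn(f"{resname} {atoms[0].residue_key}: missing {missing}; "
                      f"χ1 undefined", stacklevel=2)
        return Chi1Result(None, "undefined")
    chi1 = dihedral_angle(*(pos[n] for n in needed))
    return Chi1Result(chi1, classify_chi1(chi1))


# ---------------------------------------------------------------------------
# contacts and distances
# ---------------------------------------------------------------------------

def _heavy_atoms(structure: Structure) -> list[AtomRecord]:
    return [a for a in structure if not a.is_hydrogen]


def _pairwise(a_atoms, b_atoms):
    if not a_atoms or not b_atoms:
        return np.zeros((0, 0))
    A = np.array([a.position for a in a_atoms])
    B = np.array([b.position for b in b_atoms])
    return cdist(A, B)


def _charged_atoms(atoms, table):
    """Atoms named in *table* for their residue, plus C-terminal carboxylate.

    The carboxylate case (OXT present in the residue) only augments the
    acidic set: O and OXT of that residue become acceptors of salt bridges.
    """
    out = []
    if table is _ACIDIC_SIDECHAIN:
        with_oxt = {a.residue_key for a in atoms if a.atom_name == "OXT"}
    else:
        with_oxt = set()
    for a in atoms:
        names = table.get(a.residue_name, set())
        if a.atom_name in names:
            out.append(a)
        elif a.residue_key in with_oxt and a.atom_name in ("O", "OXT"):
            out.append(a)
    return out


def _polar_contacts(a_atoms, b_atoms, cutoff):
    ap = [a for a in a_atoms if a.element.upper() in _POLAR_ELEMENTS]
    bp = [b for b in b_atoms if b.element.upper() in _POLAR_ELEMENTS]
    D = _pairwise(ap, bp)
    return [ContactRecord(ap[i], bp[j], float(D[i, j]), "polar")
            for i, j in zip(*np.nonzero(D <= cutoff))]


def _vdw_contacts(a_atoms, b_atoms, cutoff):
    D = _pairwise(a_atoms, b_atoms)
    return [ContactRecord(a_atoms[i], b_atoms[j], float(D[i, j]), "vdw")
            for i, j in zip(*np.nonzero(D <= cutoff))]


def _salt_bridges(a_atoms, b_atoms, cutoff):
    out = []
    for basic_side, acidic_side, flip in (
            (a_atoms, b_atoms, False), (b_atoms, a_atoms, True)):
        basics = _charged_atoms(basic_side, _BASIC_SIDECHAIN)
        acids = _charged_atoms(acidic_side, _ACIDIC_SIDECHAIN)
        D = _pairwise(basics, acids)
        for i, j in zip(*np.nonzero(D <= cutoff)):
            a, b = (acids[j], basics[i]) if flip else (basics[i], acids[j])
            out.append(ContactRecord(a, b, float(D[i, j]), "salt_bridge"))
    return out


def _ring_centroids(atoms):
    """(representative CG-side atom, centroid) per aromatic ring present."""
    by_res: dict = {}
    for a in atoms:
        if a.residue_name in _RING_ATOMS:
            by_res.setdefault(a.residue_key, {})[a.atom_name] = a
    out = []
    for key, named in by_res.items():
        resname = next(iter(named.values())).residue_name
        ring_names = _RING_ATOMS[resname]
        if all(n in named for n in ring_names):
            centroid = np.mean([named[n].position for n in ring_names], axis=0)
            out.append((named[ring_names[0]], centroid))
    return out


def _pi_cation(a_atoms, b_atoms, cutoff):
    out = []
    for cation_side, ring_side, flip in (
            (a_atoms, b_atoms, False), (b_atoms, a_atoms, True)):
        cations = _charged_atoms(cation_side, _CATION_ATOMS)
        rings = _ring_centroids(ring_side)
        for c in cations:
            for rep, centroid in rings:
                d = float(np.linalg.norm(c.position - centroid))
                if d <= cutoff:
                    a, b = (rep, c) if flip else (c, rep)
                    out.append(ContactRecord(a, b, d, "pi_cation"))
    return out


def detect_contacts(group_a: Structure, group_b: Structure,
                    criteria: ContactCriteria = ContactCriteria()
                    ) -> list[ContactRecord]:
    """Distance-cutoff contacts between two heavy-atom groups.

    polar: N/O/S pairs ≤ polar_cutoff; vdw: any heavy pair ≤ vdw_cutoff;
    salt_bridge: Arg/Lys/His sidechain N vs Asp/Glu/C-terminal carboxylate O
    ≤ salt_bridge_cutoff; pi_cation: Arg/Lys cation atom within
    pi_cation_cutoff of a Phe/Tyr/Trp six-membered-ring centroid. Each
    qualifying pair is reported once per kind; order of *a*/*b* atoms in the
    record follows the argument order.
    """
    a_atoms = _heavy_atoms(group_a)
    b_atoms = _heavy_atoms(group_b)
    records: list[ContactRecord] = []
    if "polar" in criteria.kinds:
        records += _polar_contacts(a_atoms, b_atoms, criteria.polar_cutoff)
    if "vdw" in criteria.kinds:
        records += _vdw_contacts(a_atoms, b_atoms, criteria.vdw_cutoff)
    if "salt_bridge" in criteria.kinds:
        records += _salt_bridges(a_atoms, b_atoms, criteria.salt_bridge_cutoff)
    if "pi_cation" in criteria.kinds:
        records += _pi_cation(a_atoms, b_atoms, criteria.pi_cation_cutoff)
    records.sort(key=lambda r: (r.kind, r.atom_a.residue_key, r.atom_a.atom_name,
                                r.atom_b.residue_key, r.atom_b.atom_name))
    return records


def min_distance(group_a: Structure, group_b: Structure) -> float:
    """Minimum pairwise heavy-atom distance between the two groups, Å."""
    a_atoms = _heavy_atoms(group_a)
    b_atoms = _heavy_atoms(group_b)
    if not a_atoms or not b_atoms:
        raise InputError("min_distance requires two non-empty heavy-atom groups")
    return float(_pairwise(a_atoms, b_atoms).min())


def insertion_depth(peptide: Structure, bounds: PocketBounds) -> float:
    """Depth (Å) of the deepest peptide heavy atom below the pocket's upper
    boundary (the membrane's extracellular surface proxy); 0 if the peptide
    sits entirely above it."""
    atoms = _heavy_atoms(peptide)
    if not atoms:
        raise InputError("insertion depth requires a non-empty peptide selection")
    zmin = min(float(a.position[2]) for a in atoms)
    return max(0.0, bounds.z_upper - zmin)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def helix_tip_residue(structure: Structure, helix, tip: str = "extracellular"):
    """Residue key of the helix residue whose Cα is most extracellular
    (largest z; ``tip="intracellular"`` for smallest z)."""
    sel = Selector(chains=[helix.chain_id], residues=[(helix.start, helix.end)],
                   atom_names=["CA"])
    cas = [a for a in select_atoms(structure, sel) if not a.is_hydrogen]
    if not cas:
        raise PairingError(f"helix {helix.helix_id}: no Cα atoms")
    pick = max if tip == "extracellular" else min
    return pick(cas, key=lambda a: a.position[2]).residue_key


def compare_states(a: Structure, b: Structure, tm: TMAnnotation,
                   align_selector: Selector | None = None) -> StateComparison:
    """Full activation-geometry comparison of state *b* against state *a*.

    Aligns on common TM Cα atoms (or ``align_selector`` if given), then
    reports per-residue Cα displacements, per-helix axis tilts, and χ1
    rotamer changes for every residue with a defined χ1 in both states.
    """
    if align_selector is None:
        align_selector = tm.tm_selector()
    align_a = _ca_index(a, align_selector)
    align_b = _ca_index(b, align_selector)
    keys = [k for k in align_a if k in align_b]
    if len(keys) < 3:
        raise PairingError("too few common TM Cα atoms to align the state pair")
    P = np.array([align_b[k].position for k in keys])
    Q = np.array([align_a[k].position for k in keys])
    transform, rmsd = kabsch_superpose(P, Q)
    b_aligned = apply_transform(b, transform)

    comp = StateComparison(alignment_rmsd=rmsd)
    all_a = _ca_index(a, None)
    all_b = _ca_index(b_aligned, None)
    for k in all_a:
        if k in all_b:
            comp.displacements[k] = float(
                np.linalg.norm(all_a[k].position - all_b[k].position))

    for h in tm.tm_helices():
        sel = Selector(chains=[h.chain_id], residues=[(h.start, h.end)],
                       atom_names=["CA"])
        ca_a = select_atoms(a, sel).coords
        ca_b = select_atoms(b_aligned, sel).coords
        if len(ca_a) >= 5 and len(ca_b) >= 5:
            ax_a, _ = helix_axis(ca_a)
            ax_b, _ = helix_axis(ca_b)
            comp.tilts[h.helix_id] = tilt_angle(ax_a, ax_b)

    res_a = a.residues()
    res_b = b_aligned.residues()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in res_a:
            if k in res_b:
                ra = chi1_rotamer(res_a[k])
                rb = chi1_rotamer(res_b[k])
                if ra.chi1_class != "undefined" and rb.chi1_class != "undefined":
                    if ra.chi1_class != rb.chi1_class:
                        comp.rotamer_changes[k] = (ra.chi1, rb.chi1,
                                                   ra.chi1_class, rb.chi1_class)
    return comp
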