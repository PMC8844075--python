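"""Synthetic TM bundles with known ground-truth geometry.

Generates idealized seven-helix (or n-helix) transmembrane bundles — ideal
α-helical Cα traces with minimal backbone/sidechain pseudo-atoms, helices on
a circle with alternating chain direction, a designated toggle-switch
residue, matching annotation tables — plus perturbed copies with exactly
known per-helix displacements, tilts, and χ1 reassignments. Every quantity
the pipeline should recover (analytic prism volume, applied perturbations,
peptide depth) is recorded in a :class:`GroundTruth` computed independently
of the code under test.

These bundles emulate the architecture the cavity algorithm assumes, not
real protein packing: no loops, no Ramachandran validity, carbon pseudo-atom
sidechains. What they do pin down exactly is the geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError
from .structure_io import (AtomRecord, GenericNumberingMap, Structure,
                           TMAnnotation, TMHelix)

__all__ = ["BundleSpec", "GroundTruth", "Perturbation", "make_ideal_helix",
           "make_bundle", "make_peptide", "perturb_bundle", "shoelace_area",
           "place_atom"]

# textbook ideal alpha-helix constants
RISE_PER_RESIDUE = 1.5       # Å
TWIST_PER_RESIDUE = 100.0    # degrees
CA_RADIUS = 2.3              # Å


def shoelace_area(vertices: np.ndarray) -> float:
    """Unsigned polygon area (shoelace formula); analytic truth for tests."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d with |cd| = bond, ∠bcd = angle and torsion a–b–c–d given
    (natural extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(dihedral_deg)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


@dataclass(frozen=True)
class BundleSpec:
    """Parameters of a synthetic TM bundle; defaults emulate a class-A 7TM fold."""

    n_helices: int = 7
    bundle_radius: float = 12.0      # helix axes on this circle, Å
    helix_length: int = 30           # residues per helix
    rise: float = RISE_PER_RESIDUE
    twist: float = TWIST_PER_RESIDUE
    ca_radius: float = CA_RADIUS
    tilts: tuple = ()                # per-helix tilt, degrees (default all 0)
    toggle_helix: int = 6
    toggle_position: int = 22        # 0-based index within the toggle helix
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self):
        if self.n_helices < 3:
            raise InputError("a bundle needs at least 3 helices")
        for name in ("bundle_radius", "helix_length", "rise", "twist", "ca_radius"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if not (1 <= self.toggle_helix <= self.n_helices):
            raise InputError(f"toggle helix {self.toggle_helix} outside 1..{self.n_helices}")
        if not (0 <= self.toggle_position < self.helix_length):
            raise InputError("toggle position outside its helix")
        if self.tilts and len(self.tilts) != self.n_helices:
            raise InputError("tilts must list one angle per helix")
        # neighbouring helix axes must clear each other's Cα cylinders
        min_sep = 2 * self.bundle_radius * math.sin(math.pi / self.n_helices)
        if min_sep <= 2 * (self.ca_radius + 1.0):
            raise InputError(f"helices overlap: axis separation {min_sep:.1f} Å vs "
                             f"Cα cylinder diameter {2 * self.ca_radius:.1f} Å")

    @property
    def helix_span(self) -> float:
        return (self.helix_length - 1) * self.rise

    def helix_residue_range(self, helix_id: int) -> tuple[int, int]:
        start = (helix_id - 1) * 100 + 1
        return start, start + self.helix_length - 1


@dataclass(frozen=True)
class GroundTruth:
    """Generator bookkeeping, recomputable deterministically from the spec."""

    axis_polygon: np.ndarray          # (n_helices, 2) helix-axis (x, y)
    z_lower: float                    # toggle Cα z
    z_upper: float                    # max TM Cα z
    prism_volume: float | None        # shoelace(axis polygon) × height; None if tilted
    n_atoms: int
    n_residues: int
    applied_displacements: dict = field(default_factory=dict)
    applied_tilts: dict = field(default_factory=dict)
    applied_chi1: dict = field(default_factory=dict)
    peptide_depth: float | None = None


def make_ideal_helix(n_res: int, origin, direction, rise: float = RISE_PER_RESIDUE,
                     twist: float = TWIST_PER_RESIDUE, ca_radius: float = CA_RADIUS,
                     phase: float = 0.0, chain_id: str = "A", start_resnum: int = 1,
                     resnames=None, chi1: float = -60.0) -> list[AtomRecord]:
    """Ideal α-helix: Cα k at angle phase + k·twist and height k·rise around
    *direction* at *ca_radius*; each residue carries N, CA, C, CB and a γ
    pseudo-atom placed at torsion χ1, enough for rotamer and contact tests.
    """
    if n_res < 4:
        raise InputError(f"a helix needs at least 4 residues, got {n_res}")
    if rise <= 0 or ca_radius <= 0 or twist == 0:
        raise InputError("rise, twist and ca_radius must be non-zero/positive")
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)

    def ca_point(t: float) -> np.ndarray:
        ang = math.radians(phase + t * twist)
        return origin + d * (t * rise) + ca_radius * (math.cos(ang) * u + math.sin(ang) * v)

    atoms: list[AtomRecord] = []
    for k in range(n_res):
        resnum = start_resnum + k
        resname = resnames[k] if resnames else "LEU"
        ca = ca_point(k)
        n_at = ca_point(k - 0.35)
        c_at = ca_point(k + 0.35)
        axis_pt = origin + d * ((ca - origin) @ d)
        outward = ca - axis_pt
        outward /= np.linalg.norm(outward)
        cb = ca + 1.53 * outward
        gamma_names = {"SER": "OG", "THR": "OG1", "CYS": "SG",
                       "VAL": "CG1", "ILE": "CG1"}
        gname = gamma_names.get(resname, "CG")
        has_gamma = resname not in ("GLY", "ALA")
        common = dict(chain_id=chain_id, residue_number=resnum, insertion_code="",
                      residue_name=resname)
        atoms.append(AtomRecord(atom_name="N", element="N", position=n_at, **common))
        atoms.append(AtomRecord(atom_name="CA", element="C", position=ca, **common))
        atoms.append(AtomRecord(atom_name="C", element="C", position=c_at, **common))
        if resname != "GLY":
            atoms.append(AtomRecord(atom_name="CB", element="C", position=cb, **common))
        if has_gamma:
            cg = place_atom(n_at, ca, cb, 1.52, 111.0, chi1)
            elem = gname[0] if gname[0] in ("O", "S") else "C"
            atoms.append(AtomRecord(atom_name=gname, element=elem, position=cg, **common))
    return atoms


def make_bundle(spec: BundleSpec = BundleSpec()
                ) -> tuple[Structure, TMAnnotation, GenericNumberingMap, GroundTruth]:
    """Build the bundle, its annotation tables, and its ground truth.

    Helices sit at equal angles on a circle of ``bundle_radius``, alternating
    N→C direction (odd ids run intracellular→extracellular). The toggle
    residue (TRP, labelled "6.48"-equivalent) sits ``toggle_position``
    residues into the toggle helix; all helices get BW codes with position 50
    anchored two residues past the toggle index.
    """
    rng = np.random.default_rng(spec.seed)
    span = spec.helix_span
    atoms: list[AtomRecord] = []
    helices: list[TMHelix] = []
    bw_entries: list[tuple[str, int, str]] = []
    axis_xy = np.zeros((spec.n_helices, 2))
    tilts = spec.tilts if spec.tilts else (0.0,) * spec.n_helices
    center_idx = spec.toggle_position + 2  # BW position 50 at this index

    for h in range(1, spec.n_helices + 1):
        theta = 2 * math.pi * (h - 1) / spec.n_helices
        base = np.array([spec.bundle_radius * math.cos(theta),
                         spec.bundle_radius * math.sin(theta), 0.0])
        axis_xy[h - 1] = base[:2]
        up = (h % 2 == 1)
        d = np.array([0.0, 0.0, 1.0 if up else -1.0])
        mid = base + np.array([0.0, 0.0, span / 2])
        tilt = tilts[h - 1]
        if tilt:
            tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
            d = Rotation.from_rotvec(np.radians(tilt) * tangent).apply(d)
        origin = mid - d * (span / 2)
        start, end = spec.helix_residue_range(h)
        resnames = ["LEU"] * spec.helix_length
        if h == spec.toggle_helix:
            resnames[spec.toggle_position] = "TRP"
        phase = float(rng.uniform(0.0, 360.0))
        atoms += make_ideal_helix(spec.helix_length, origin, d, spec.rise, spec.twist,
                                  spec.ca_radius, phase=phase, chain_id=spec.chain_id,
                                  start_resnum=start, resnames=resnames)
        helices.append(TMHelix(h, spec.chain_id, start, end))
        for i in range(spec.helix_length):
            pp = 50 + (i - center_idx)
            if 1 <= pp <= 99:
                bw_entries.append((spec.chain_id, start + i, f"{h}.{pp}"))

    structure = Structure(atoms, f"synthetic-bundle-seed{spec.seed}")
    tm = TMAnnotation(helices)
    bw = GenericNumberingMap(bw_entries)

    toggle_resnum = spec.helix_residue_range(spec.toggle_helix)[0] + spec.toggle_position
    toggle_ca = structure.atom(spec.chain_id, toggle_resnum, "CA")
    z_lower = float(toggle_ca.position[2])
    ca_z = [a.position[2] for a in atoms if a.atom_name == "CA"]
    z_upper = float(max(ca_z))
    untilted = all(t == 0 for t in tilts)
    prism = shoelace_area(axis_xy) * (z_upper - z_lower) if untilted else None
    truth = GroundTruth(axis_polygon=axis_xy, z_lower=z_lower, z_upper=z_upper,
                        prism_volume=prism, n_atoms=len(atoms),
                        n_residues=spec.n_helices * spec.helix_length)
    return structure, tm, bw, truth


def make_peptide(n_res: int, start_point, direction, spacing: float = 3.5,
                 chain_id: str = "P", start_resnum: int = 1) -> list[AtomRecord]:
    """Extended pseudo-peptide: N/CA/C per residue along *direction*."""
    if n_res < 1:
        raise InputError("peptide needs at least one residue")
    p0 = np.asarray(start_point, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    atoms = []
    for k in range(n_res):
        ca = p0 + d * (k * spacing)
        common = dict(chain_id=chain_id, residue_number=start_resnum + k,
                      insertion_code="", residue_name="GLY")
        atoms.append(AtomRecord(atom_name="N", element="N", position=ca - d * 1.2, **common))
        atoms.append(AtomRecord(atom_name="CA", element="C", position=ca, **common))
        atoms.append(AtomRecord(atom_name="C", element="C", position=ca + d * 1.2, **common))
    return atoms


@dataclass(frozen=True)
class Perturbation:
    """Exactly known structural edits creating an 'active-like' state.

    displacements: helix_id → rigid 3-vector applied to every helix atom, Å;
    tilts: helix_id → rotation (degrees) about an axis perpendicular to the
    helix through its Cα centroid; chi1_set: residue number → new χ1.
    """

    displacements: dict = field(default_factory=dict)
    tilts: dict = field(default_factory=dict)
    chi1_set: dict = field(default_factory=dict)


def _helix_atom_indices(structure: Structure, tm: TMAnnotation, helix_id) -> list[int]:
    h = tm.helix(helix_id)
    return [i for i, a in enumerate(structure)
            if a.chain_id == h.chain_id and h.contains(a.residue_number)]


def perturb_bundle(structure: Structure, tm: TMAnnotation,
                   perturbation: Perturbation,
                   truth: GroundTruth | None = None
                   ) -> tuple[Structure, GroundTruth | None]:
    """Apply a :class:`Perturbation`; returns the new structure and, when a
    ground truth is supplied, an updated copy recording what was applied."""
    from .errors import AnnotationError
    for hid in list(perturbation.displacements) + list(perturbation.tilts):
        try:
            tm.helix(hid)
        except AnnotationError as exc:
            raise InputError(str(exc)) from None
    coords = structure.coords

    for hid, vec in perturbation.displacements.items():
        idx = _helix_atom_indices(structure, tm, hid)
        coords[idx] += np.asarray(vec, dtype=float)

    for hid, angle in perturbation.tilts.items():
        idx = _helix_atom_indices(structure, tm, hid)
        ca_idx = [i for i in idx if structure[i].atom_name == "CA"]
        ca = coords[ca_idx]
        centroid = ca.mean(axis=0)
        _, _, Vt = np.linalg.svd(ca - centroid)
        axis = Vt[0]
        perp = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(axis, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        rot = Rotation.from_rotvec(np.radians(angle) * perp)
        coords[idx] = rot.apply(coords[idx] - centroid) + centroid

    out = structure.with_coords(coords, label=structure.label + "-perturbed")

    if perturbation.chi1_set:
        from .state_compare import GAMMA_ATOM, _DEFAULT_GAMMA
        atoms = list(out.atoms)
        by_key: dict = {}
        for i, a in enumerate(atoms):
            by_key.setdefault(a.residue_key, {})[a.atom_name] = i
        for resnum, new_chi1 in perturbation.chi1_set.items():
            matches = [k for k in by_key if k[1] == resnum]
            if not matches:
                raise InputError(f"residue {resnum} not found for χ1 reassignment")
            for key in matches:
                named = by_key[key]
                resname = atoms[named["CA"]].residue_name
                gname = GAMMA_ATOM.get(resname, _DEFAULT_GAMMA)
                if gname is None or gname not in named:
                    raise InputError(f"residue {resnum} ({resname}) has no γ atom")
                n_p = atoms[named["N"]].position
                ca_p = atoms[named["CA"]].position
                cb_p = atoms[named["CB"]].position
                g_i = named[gname]
                bond = float(np.linalg.norm(atoms[g_i].position - cb_p))
                v1 = ca_p - cb_p
                v2 = atoms[g_i].position - cb_p
                angle = math.degrees(math.acos(
                    float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
                atoms[g_i] = atoms[g_i].moved_to(
                    place_atom(n_p, ca_p, cb_p, bond, angle, new_chi1))
        out = Structure(atoms, out.label)

    new_truth = None
    if truth is not None:
        new_truth = replace(
            truth,
            applied_displacements={k: np.asarray(v, dtype=float)
                                   for k, v in perturbation.displacements.items()},
            applied_tilts=dict(perturbation.tilts),
            applied_chi1=dict(perturbation.chi1_set),
        )
    return out, new_truth
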