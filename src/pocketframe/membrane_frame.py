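"""Membrane-frame placement by least-squares rigid superposition.

The cavity algorithm assumes the receptor sits in the OPM frame: z along the
membrane normal, extracellular side up. A receptor is placed there by Kabsch
superposition of its Cα trace onto a user-supplied, already membrane-aligned
reference — paired by (chain, residue number), restricted to TM-annotated
residues when an annotation is available, since loops differ between
activation states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InputError, PairingError
from .structure_io import Selector, Structure, TMAnnotation, select_atoms

__all__ = ["RigidTransform", "kabsch_superpose", "apply_transform", "align_to_reference"]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation R ∈ SO(3), translation t in Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InputError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise GeometryError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise GeometryError("rotation matrix determinant is not +1 (improper rotation)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying *other* first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[RigidTransform, float]:
    """Least-squares superposition of *mobile* onto *reference* (Kabsch).

    Both inputs are equal-length ordered (N, 3) Cα coordinate arrays, N ≥ 3
    and not all collinear. Returns the proper rigid transform minimizing the
    RMSD of the transformed mobile set to the reference, and that minimum
    RMSD in Å. If the optimal orthogonal matrix is a reflection, the sign of
    the smallest singular vector is flipped (proper rotation enforced).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or Q.shape != P.shape:
        raise InputError(f"coordinate lists must be matching (N,3) arrays, "
                         f"got {P.shape} and {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise InputError(f"need at least 3 paired points, got {n}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinear point sets leave a rotation about the line undetermined
    for name, X in (("mobile", Pc), ("reference", Qc)):
        if np.linalg.matrix_rank(X, tol=1e-8 * max(1.0, np.abs(X).max())) < 2:
            raise GeometryError(f"{name} points are collinear; superposition is rank-deficient")

    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def apply_transform(structure: Structure, transform: RigidTransform) -> Structure:
    """Return *structure* with every position mapped through *transform*."""
    return structure.with_coords(transform.apply(structure.coords))


def _ca_map(structure: Structure) -> dict:
    out = {}
    for a in select_atoms(structure, Selector.calpha()):
        out.setdefault(a.residue_key, a)
    return out


def align_to_reference(mobile: Structure, reference: Structure,
                       tm: TMAnnotation | None = None,
                       pairing: str = "tm") -> tuple[Structure, RigidTransform, float]:
    """Superpose *mobile* onto a membrane-aligned *reference* structure.

    Cα atoms are paired by (chain, residue number, insertion code);
    ``pairing="tm"`` restricts the pairing to TM-annotated residues when *tm*
    is given, ``pairing="all"`` uses every common Cα.
    """
    if pairing not in ("tm", "all"):
        raise InputError(f"pairing must be 'tm' or 'all', got {pairing!r}")
    mob = _ca_map(mobile)
    ref = _ca_map(reference)
    keys = [k for k in mob if k in ref]
    if pairing == "tm" and tm is not None:
        keys = [k for k in keys if tm.covers(mob[k])]
    if len(keys) < 3:
        raise PairingError(f"only {len(keys)} common Cα atoms between "
                           f"{mobile.label!r} and {reference.label!r}")
    P = np.array([mob[k].position for k in keys])
    Q = np.array([ref[k].position for k in keys])
    transform, rmsd = kabsch_superpose(P, Q)
    return apply_transform(mobile, transform), transform, rmsd
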