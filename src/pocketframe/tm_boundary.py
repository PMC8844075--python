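"""Cavity boundaries from TM-bundle geometry.

For a membrane-aligned receptor the binding cavity is bounded:

* laterally, at every discrete z level, by the closed polygon through the
  seven TM helix centers (center = mean Cα (x,y) within a z window, falling
  back to the nearest Cα when the window is empty — helices end);
* below, by the z of the toggle-switch Cα (generic number 6.48);
* above, by the z of the most extracellular TM Cα.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnnotationError, GeometryError
from .structure_io import (GenericNumberingMap, Selector, Structure, TMAnnotation,
                           TMHelix, select_atoms)

__all__ = ["PocketBounds", "SlabPolygonSet", "helix_center_at_z",
           "lateral_polygons", "pocket_z_bounds"]

#: default half-width of the z window used to average helix Cα positions, Å
DEFAULT_WINDOW = 2.0


@dataclass(frozen=True)
class PocketBounds:
    """Closed z interval [z_lower, z_upper] of the cavity, Å.

    Equal bounds describe a degenerate zero-height (empty) slab; inverted
    bounds are an error.
    """

    z_lower: float
    z_upper: float

    def __post_init__(self):
        if self.z_lower > self.z_upper:
            raise GeometryError(f"z_lower {self.z_lower:.2f} must not exceed "
                                f"z_upper {self.z_upper:.2f}")

    @property
    def height(self) -> float:
        return self.z_upper - self.z_lower


@dataclass(frozen=True)
class SlabPolygonSet:
    """Per-z-level lateral boundary rings, one vertex per TM helix.

    ``polygons`` has shape (n_levels, n_helices, 2); ``z_levels`` is strictly
    increasing with uniform spacing; ``helix_ids`` gives the vertex order.
    """

    z_levels: np.ndarray
    polygons: np.ndarray
    helix_ids: tuple

    def __post_init__(self):
        z = np.asarray(self.z_levels, dtype=float)
        polys = np.asarray(self.polygons, dtype=float)
        object.__setattr__(self, "z_levels", z)
        object.__setattr__(self, "polygons", polys)
        if polys.ndim != 3 or polys.shape[0] != z.size or polys.shape[2] != 2:
            raise GeometryError(f"polygon array shape {polys.shape} inconsistent "
                                f"with {z.size} z levels")
        if polys.shape[1] < 3:
            raise GeometryError("lateral boundary needs at least 3 helices")
        if z.size > 1:
            dz = np.diff(z)
            if np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-9):
                raise GeometryError("z levels must be strictly increasing and uniform")

    def polygon_at(self, z: float) -> np.ndarray:
        """Ring of the z level nearest to *z* (ties resolved to the lower level)."""
        i = int(np.argmin(np.abs(self.z_levels - z)))
        return self.polygons[i]

    def to_table(self):
        """Long-format rows (z, helix_id, x, y) for TSV export."""
        rows = []
        for z, ring in zip(self.z_levels, self.polygons):
            for hid, (x, y) in zip(self.helix_ids, ring):
                rows.append((float(z), hid, float(x), float(y)))
        return rows


def _helix_ca(structure: Structure, helix: TMHelix) -> tuple[np.ndarray, np.ndarray]:
    sel = Selector(chains=[helix.chain_id], residues=[(helix.start, helix.end)],
                   atom_names=["CA"], exclude_elements=["H", "D"])
    cas = select_atoms(structure, sel)
    if len(cas) == 0:
        raise AnnotationError(f"helix {helix.helix_id}: no Cα atoms in "
                              f"{helix.chain_id}[{helix.start},{helix.end}]")
    resnums = np.array([a.residue_number for a in cas])
    return cas.coords, resnums


def helix_center_at_z(structure: Structure, helix: TMHelix, z: float,
                      window: float = DEFAULT_WINDOW) -> np.ndarray:
    """(x, y) center of *helix* at height *z*.

    Mean (x, y) of the helix Cα atoms with |z_atom − z| ≤ window; if none,
    the (x, y) of the Cα nearest in z (lower residue number on a tie).
    """
    coords, resnums = _helix_ca(structure, helix)
    dz = np.abs(coords[:, 2] - z)
    in_window = dz <= window
    if np.any(in_window):
        return coords[in_window, :2].mean(axis=0)
    # nearest-point fallback, deterministic tie-break on residue number
    order = np.lexsort((resnums, dz))
    return coords[order[0], :2].copy()


def lateral_polygons(structure: Structure, tm: TMAnnotation, z_levels,
                     window: float = DEFAULT_WINDOW,
                     order: str = "index") -> SlabPolygonSet:
    """Lateral boundary rings at each z level.

    ``order="index"`` visits helices TM1→TM7 (the sequential arrangement of a
    GPCR bundle); ``order="angular"`` sorts them by the polar angle of their
    mean Cα (x, y), for bundles whose index order is not circular.
    """
    helices = tm.tm_helices()
    if len(helices) < 3:
        raise GeometryError(f"lateral boundary needs ≥3 TM helices, got {len(helices)}")
    if order == "angular":
        means = [_helix_ca(structure, h)[0][:, :2].mean(axis=0) for h in helices]
        centroid = np.mean(means, axis=0)
        angles = [np.arctan2(m[1] - centroid[1], m[0] - centroid[0]) for m in means]
        helices = [h for _, h in sorted(zip(angles, helices), key=lambda p: p[0])]
    elif order != "index":
        raise GeometryError(f"unknown helix order {order!r}")

    z_levels = np.atleast_1d(np.asarray(z_levels, dtype=float))
    polys = np.empty((z_levels.size, len(helices), 2))
    for i, z in enumerate(z_levels):
        for j, h in enumerate(helices):
            polys[i, j] = helix_center_at_z(structure, h, z, window)
    return SlabPolygonSet(z_levels, polys, tuple(h.helix_id for h in helices))


def pocket_z_bounds(structure: Structure, tm: TMAnnotation,
                    bw: GenericNumberingMap) -> PocketBounds:
    """Lower/upper cavity bounds: toggle-switch (6.48) Cα z and max TM Cα z."""
    chain, resnum = bw.resolve("6.48")
    try:
        toggle_ca = structure.atom(chain, resnum, "CA")
    except Exception as exc:
        raise AnnotationError(f"toggle residue {chain}/{resnum} (6.48) has no Cα "
                              f"in structure {structure.label!r}") from exc
    z_lower = float(toggle_ca.position[2])

    helices = tm.tm_helices()
    if not helices:
        raise AnnotationError("TM annotation carries no numbered helices")
    z_upper = -np.inf
    for h in helices:
        coords, _ = _helix_ca(structure, h)
        z_upper = max(z_upper, float(coords[:, 2].max()))
    if z_upper <= z_lower:
        raise GeometryError(f"toggle Cα z ({z_lower:.2f}) is at or above the most "
                            f"extracellular TM Cα z ({z_upper:.2f})")
    return PocketBounds(z_lower, z_upper)
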