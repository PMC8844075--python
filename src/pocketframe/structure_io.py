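"""Structure and annotation I/O.

Reads PDB / mmCIF coordinate files (via :mod:`gemmi`) into a small immutable
atom-record model, offers declarative atom selection, and loads the two
annotation tables the geometry pipeline needs:

* a TM table assigning inclusive residue ranges to the seven transmembrane
  helices (plus optional named extra segments such as the G-protein α5 helix);
* a generic-numbering table mapping ``(chain, residue)`` to a
  Ballesteros–Weinstein code ``"t.pp"``; code ``"6.48"`` locates the toggle
  switch tryptophan whose Cα z-coordinate bounds the cavity from below.

Conventions: coordinates in Å; z is the membrane normal with the
extracellular side at larger z (OPM); residue numbering is as deposited;
altlocs other than blank/"A" are dropped at parse time; hydrogens are kept
but flagged by element and excluded from geometry downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import AnnotationError, InputError

__all__ = [
    "AtomRecord",
    "Structure",
    "Selector",
    "TMHelix",
    "TMAnnotation",
    "GenericNumberingMap",
    "parse_structure",
    "select_atoms",
    "load_annotations",
    "write_pdb",
]

#: altloc identifiers retained at parse time (single-conformer policy)
_KEPT_ALTLOCS = ("", "A")


@dataclass(eq=False)
class AtomRecord:
    """One ATOM/HETATM row; identity is (chain, resnum, icode, atom name, altloc)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise InputError(f"atom position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise InputError(f"non-finite coordinates for atom {self.key}")
        if not self.element:
            raise InputError(f"empty element symbol for atom {self.key}")

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.atom_name, self.altloc)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def moved_to(self, position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))

    def __repr__(self) -> str:  # compact, grep-friendly
        x, y, z = self.position
        return (f"<{self.chain_id}/{self.residue_name}{self.residue_number}"
                f"{self.insertion_code}/{self.atom_name} ({x:.3f},{y:.3f},{z:.3f})>")


class Structure:
    """Ordered collection of :class:`AtomRecord` with a text label.

    Order is stable: parsing, selection and rigid transforms never reorder
    or fabricate atoms.
    """

    def __init__(self, atoms: Sequence[AtomRecord], label: str = ""):
        self.atoms: list[AtomRecord] = list(atoms)
        self.label = label

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    def __getitem__(self, i: int) -> AtomRecord:
        return self.atoms[i]

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of positions in Å (copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise InputError(f"coordinate array shape {coords.shape} does not match "
                             f"{len(self.atoms)} atoms")
        atoms = [a.moved_to(c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, self.label if label is None else label)

    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Atoms grouped by (chain, residue number, insertion code), order kept."""
        out: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def atom(self, chain_id: str, residue_number: int, atom_name: str,
             insertion_code: str = "") -> AtomRecord:
        for a in self.atoms:
            if (a.chain_id == chain_id and a.residue_number == residue_number
                    and a.insertion_code == insertion_code and a.atom_name == atom_name):
                return a
        raise InputError(f"atom {chain_id}/{residue_number}{insertion_code}/{atom_name} "
                         f"not found in structure {self.label!r}")

    def __repr__(self) -> str:
        return f"Structure({self.label!r}, {len(self.atoms)} atoms)"


@dataclass(frozen=True)
class Selector:
    """Declarative atom-selection criteria; all set fields must match.

    ``residues`` accepts residue numbers and/or inclusive ``(start, end)``
    tuples. ``hetero=None`` matches both ATOM and HETATM records.
    """

    chains: frozenset[str] | None = None
    exclude_chains: frozenset[str] | None = None
    residues: tuple = ()
    atom_names: frozenset[str] | None = None
    elements: frozenset[str] | None = None
    exclude_elements: frozenset[str] | None = None
    residue_names: frozenset[str] | None = None
    exclude_residue_names: frozenset[str] | None = None
    hetero: bool | None = None

    def __init__(self, chains=None, exclude_chains=None, residues=(), atom_names=None,
                 elements=None, exclude_elements=None, residue_names=None,
                 exclude_residue_names=None, hetero=None):
        def fs(x):
            return None if x is None else frozenset(x if not isinstance(x, str) else [x])
        object.__setattr__(self, "chains", fs(chains))
        object.__setattr__(self, "exclude_chains", fs(exclude_chains))
        object.__setattr__(self, "residues", tuple(residues))
        object.__setattr__(self, "atom_names", fs(atom_names))
        object.__setattr__(self, "elements",
                           None if elements is None else frozenset(e.upper() for e in fs(elements)))
        object.__setattr__(self, "exclude_elements",
                           None if exclude_elements is None
                           else frozenset(e.upper() for e in fs(exclude_elements)))
        object.__setattr__(self, "residue_names", fs(residue_names))
        object.__setattr__(self, "exclude_residue_names", fs(exclude_residue_names))
        object.__setattr__(self, "hetero", hetero)

    def _residue_ok(self, n: int) -> bool:
        if not self.residues:
            return True
        for item in self.residues:
            if isinstance(item, tuple):
                lo, hi = item
                if lo <= n <= hi:
                    return True
            elif n == item:
                return True
        return False

    def matches(self, atom: AtomRecord) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.exclude_chains is not None and atom.chain_id in self.exclude_chains:
            return False
        if not self._residue_ok(atom.residue_number):
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.elements is not None and atom.element.upper() not in self.elements:
            return False
        if self.exclude_elements is not None and atom.element.upper() in self.exclude_elements:
            return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if (self.exclude_residue_names is not None
                and atom.residue_name in self.exclude_residue_names):
            return False
        if self.hetero is not None and atom.is_hetero != self.hetero:
            return False
        return True

    @staticmethod
    def calpha() -> "Selector":
        return Selector(atom_names=["CA"], exclude_elements=["H", "D"])

    @staticmethod
    def heavy() -> "Selector":
        return Selector(exclude_elements=["H", "D"])


def select_atoms(structure: Structure, selector: Selector) -> Structure:
    """Atoms of *structure* satisfying *selector*, original order preserved."""
    return Structure([a for a in structure.atoms if selector.matches(a)],
                     structure.label)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TMHelix:
    """One helix annotation: inclusive residue range on a chain.

    ``helix_id`` is 1..7 for the TM bundle; extra segments (e.g. the Gα α5
    helix) use string ids.
    """

    helix_id: int | str
    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise AnnotationError(f"helix {self.helix_id}: end {self.end} < start {self.start}")
        if self.end - self.start + 1 < 4:
            raise AnnotationError(f"helix {self.helix_id}: fewer than 4 residues")

    def contains(self, residue_number: int) -> bool:
        return self.start <= residue_number <= self.end


class TMAnnotation:
    """Validated set of helix ranges; ranges must not overlap within a chain."""

    def __init__(self, helices: Iterable[TMHelix]):
        self.helices: list[TMHelix] = list(helices)
        by_chain: dict[str, list[TMHelix]] = {}
        for h in self.helices:
            by_chain.setdefault(h.chain_id, []).append(h)
        for chain, hs in by_chain.items():
            hs = sorted(hs, key=lambda h: h.start)
            for a, b in zip(hs, hs[1:]):
                if b.start <= a.end:
                    raise AnnotationError(
                        f"overlapping helix ranges on chain {chain}: "
                        f"{a.helix_id} [{a.start},{a.end}] and {b.helix_id} [{b.start},{b.end}]")
        ids = [h.helix_id for h in self.helices]
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate helix ids in TM annotation")

    def __iter__(self) -> Iterator[TMHelix]:
        return iter(self.helices)

    def __len__(self) -> int:
        return len(self.helices)

    def tm_helices(self) -> list[TMHelix]:
        """The numbered TM helices, sorted by id (extra named segments excluded)."""
        return sorted((h for h in self.helices if isinstance(h.helix_id, int)),
                      key=lambda h: h.helix_id)

    def helix(self, helix_id: int | str) -> TMHelix:
        for h in self.helices:
            if h.helix_id == helix_id:
                return h
        raise AnnotationError(f"helix {helix_id!r} not in annotation")

    def covers(self, atom: AtomRecord) -> bool:
        return any(h.chain_id == atom.chain_id and h.contains(atom.residue_number)
                   for h in self.helices)

    def tm_selector(self) -> Selector:
        """Selector matching residues of the numbered TM helices (any chain listed)."""
        ranges = tuple((h.start, h.end) for h in self.tm_helices())
        chains = {h.chain_id for h in self.tm_helices()}
        return Selector(chains=chains, residues=ranges)


class GenericNumberingMap:
    """Bijection between (chain, residue number) and BW codes ``"t.pp"``."""

    def __init__(self, entries: Iterable[tuple[str, int, str]]):
        self._by_residue: dict[tuple[str, int], str] = {}
        self._by_code: dict[str, tuple[str, int]] = {}
        for chain, resnum, code in entries:
            code = str(code)
            if (chain, resnum) in self._by_residue:
                raise AnnotationError(f"residue {chain}/{resnum} mapped to two BW codes")
            if code in self._by_code:
                raise AnnotationError(f"BW code {code} assigned to two residues")
            self._by_residue[(chain, resnum)] = code
            self._by_code[code] = (chain, resnum)

    def __len__(self) -> int:
        return len(self._by_code)

    def code_of(self, chain_id: str, residue_number: int) -> str | None:
        return self._by_residue.get((chain_id, residue_number))

    def resolve(self, code: str) -> tuple[str, int]:
        """(chain, residue number) carrying *code*; AnnotationError if absent."""
        try:
            return self._by_code[code]
        except KeyError:
            raise AnnotationError(f"BW code {code} not present in generic-numbering map") from None

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def items(self):
        return self._by_residue.items()


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _structure_from_gemmi(st: gemmi.Structure, label: str) -> Structure:
    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise InputError(f"{label}: no models in file")
    model = st[0]
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            het = res.het_flag == "H"
            for at in res:
                if at.altloc not in ("", "A", "\x00"):
                    continue
                elem = at.element.name if at.element.name else at.name[:1]
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=icode,
                    residue_name=res.name,
                    atom_name=at.name,
                    element=elem,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    altloc="" if at.altloc in ("\x00",) else at.altloc,
                    is_hetero=het,
                ))
    if not atoms:
        raise InputError(f"{label}: file contains zero atoms")
    return Structure(atoms, label)


def parse_structure(source, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file (path or text stream) into a :class:`Structure`.

    ``format`` is ``"pdb"`` or ``"mmcif"``; inferred from the file suffix when
    omitted. Only altlocs blank/"A" are kept; hydrogens are retained.
    """
    if hasattr(source, "read"):
        text = source.read()
        label = getattr(source, "name", "<stream>")
        if format is None:
            raise InputError("format must be given explicitly when parsing a stream")
    else:
        path = Path(source)
        if not path.is_file():
            raise InputError(f"structure file not found: {path}")
        text = path.read_text()
        label = path.name
        if format is None:
            suf = path.suffix.lower()
            format = "mmcif" if suf in (".cif", ".mmcif") else "pdb"
    format = format.lower()
    try:
        if format == "pdb":
            st = gemmi.read_pdb_string(text)
        elif format == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise InputError(f"unknown structure format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"{label}: unreadable {format} content: {exc}") from exc
    st.setup_entities()
    return _structure_from_gemmi(st, label)


def load_annotations(tm_table, bw_table) -> tuple[TMAnnotation, GenericNumberingMap]:
    """Load and cross-validate the TM-range and generic-numbering tables.

    Tab-separated with one header line; columns ``helix_id  chain  start  end``
    and ``chain  residue_number  bw_code``. If the map carries code "6.48" and
    the annotation carries helix 6 on the same chain, the toggle residue must
    lie inside the helix-6 range.
    """
    try:
        tm_df = pd.read_csv(tm_table, sep="\t", dtype=str)
        bw_df = pd.read_csv(bw_table, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read annotation table: {exc}") from exc
    for col in ("helix_id", "chain", "start", "end"):
        if col not in tm_df.columns:
            raise AnnotationError(f"TM table lacks column {col!r}")
    for col in ("chain", "residue_number", "bw_code"):
        if col not in bw_df.columns:
            raise AnnotationError(f"BW table lacks column {col!r}")

    helices = []
    for row in tm_df.itertuples(index=False):
        hid: int | str = row.helix_id
        try:
            hid = int(hid)
        except (TypeError, ValueError):
            pass
        try:
            helices.append(TMHelix(hid, str(row.chain), int(row.start), int(row.end)))
        except ValueError as exc:
            raise AnnotationError(f"bad TM table row {tuple(row)}: {exc}") from exc
    tm = TMAnnotation(helices)

    try:
        bw = GenericNumberingMap(
            (str(r.chain), int(r.residue_number), str(r.bw_code))
            for r in bw_df.itertuples(index=False))
    except ValueError as exc:
        raise AnnotationError(f"bad BW table row: {exc}") from exc

    if "6.48" in bw:
        chain, resnum = bw.resolve("6.48")
        try:
            h6 = tm.helix(6)
        except AnnotationError:
            h6 = None
        if h6 is not None and h6.chain_id == chain and not h6.contains(resnum):
            raise AnnotationError(
                f"toggle residue 6.48 ({chain}/{resnum}) lies outside the annotated "
                f"helix-6 range [{h6.start},{h6.end}]")
    return tm, bw


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial: int, a: AtomRecord) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    name = a.atom_name
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    x, y, z = a.position
    return (f"{record}{serial % 100000:5d} {name:<4s}{a.altloc or ' ':1s}"
            f"{a.residue_name:>3s} {a.chain_id[:1] or 'A':1s}"
            f"{a.residue_number % 10000:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{a.element[:2].upper():>2s}")


def write_pdb(structure: Structure, target) -> None:
    """Write *structure* as fixed-column PDB (one model, no CONECT).

    Used both for transformed receptor models and for retained-grid-point
    pseudo-atom dumps (HETATM, element "X").
    """
    lines = [_pdb_atom_line(i + 1, a) for i, a in enumerate(structure.atoms)]
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)


def grid_points_structure(points: np.ndarray, label: str = "cavity-grid") -> Structure:
    """Wrap retained grid points as pseudo-atoms for PDB export (element "X")."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    atoms = [AtomRecord(chain_id="X", residue_number=1, insertion_code="",
                        residue_name="GRD", atom_name="X", element="X",
                        position=p, is_hetero=True)
             for p in points]
    return Structure(atoms, label)
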