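"""Ligand container and I/O.

A :class:`Ligand` is a connected molecular graph carrying, per atom, an
element symbol, a fixed partial charge (in units of the elementary charge e)
and Cartesian coordinates (Å).  Partial charges are mandatory throughout the
toolkit: the dual-topology construction prunes the common core on per-atom
charge differences and averages core charges, so a ligand without charges is
rejected at read time rather than failing later.

Two input formats are supported:

* TRIPOS MOL2 with a populated charge column (parsed through MDAnalysis);
* a plain molecule table — a single TSV file with an ``atoms`` section
  (columns ``atom_id  element  x  y  z  charge``) and a ``bonds`` section
  (columns ``a1  a2``), atom ids being 1-based.  This is the format
  :func:`write_ligand` emits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .errors import LigandFormatError

__all__ = ["Atom", "Ligand", "read_ligand", "write_ligand"]

_TABLE_MAGIC = "# ties-kit molecule-table v1"


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, partial charge (e) and coordinates (Å)."""

    element: str
    charge: float
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Ligand:
    """Molecular graph with per-atom partial charges.

    Bonds are unordered index pairs into ``atoms``; the graph must be
    connected.  ``net_charge`` is derived from the atoms, never stored.
    """

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a ligand must contain at least one atom")
        n = len(self.atoms)
        norm: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a}, {b}) refers to a missing atom (n={n})")
            if a == b:
                raise ValueError(f"self-bond on atom {a}")
            pair = (min(a, b), max(a, b))
            if pair in seen:
                raise ValueError(f"duplicate bond {pair}")
            seen.add(pair)
            norm.append(pair)
        self.bonds = sorted(norm)
        if not nx.is_connected(self.graph()):
            raise ValueError(f"ligand {self.name!r} is not a connected graph")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def graph(self) -> "nx.Graph":
        """Molecular graph with node attributes ``element`` and ``charge``."""
        g = nx.Graph()
        for i, atom in enumerate(self.atoms):
            g.add_node(i, element=atom.element, charge=atom.charge)
        g.add_edges_from(self.bonds)
        return g

    def rings(self) -> list[frozenset[int]]:
        """Rings as a minimum cycle basis (smallest set of smallest rings)."""
        return [frozenset(c) for c in nx.minimum_cycle_basis(self.graph())]


# ---------------------------------------------------------------------------
# reading


def read_ligand(path: str | Path, format: str | None = None) -> Ligand:
    """Read a ligand, with mandatory partial charges.

    Parameters
    ----------
    path
        Input file.
    format
        ``"mol2"`` or ``"table"``; inferred from the file extension when
        omitted (``.mol2`` vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mol2" if path.suffix.lower() == ".mol2" else "table"
    if format == "mol2":
        return _read_mol2(path)
    if format == "table":
        return _read_table(path)
    raise ValueError(f"unknown ligand format {format!r}")


def _read_mol2(path: Path) -> Ligand:
    text = path.read_text()
    if "@<TRIPOS>MOLECULE" not in text:
        raise LigandFormatError(f"{path}: no @<TRIPOS>MOLECULE record — not a MOL2 file")
    # The charge-type line of the MOLECULE block is authoritative: a file
    # declaring NO_CHARGES cannot feed the charge-based core pruning.
    block = text.split("@<TRIPOS>MOLECULE", 1)[1].splitlines()
    meaningful = [ln.strip() for ln in block[1:] if ln.strip() and not ln.startswith("@")]
    if len(meaningful) >= 4 and meaningful[3].upper().startswith("NO_CHARGES"):
        raise LigandFormatError(
            f"{path}: charges required — MOL2 declares NO_CHARGES, but partial "
            "charges are mandatory for dual-topology construction"
        )
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format="MOL2")
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise LigandFormatError(f"{path}: unparseable MOL2 ({exc})") from exc
    if not hasattr(u.atoms, "charges"):
        raise LigandFormatError(f"{path}: charges required — no charge column found")
    try:
        elements = [str(e) for e in u.atoms.elements]
    except Exception:
        # fall back to the SYBYL type, e.g. "C.ar" -> "C"
        elements = [str(t).split(".")[0] for t in u.atoms.types]
    elements = [e.capitalize() for e in elements]
    atoms = [
        Atom(elements[i], float(u.atoms.charges[i]), *map(float, u.atoms.positions[i]))
        for i in range(len(u.atoms))
    ]
    bonds = [(int(b.atoms[0].ix), int(b.atoms[1].ix)) for b in u.bonds]
    name = str(getattr(u.atoms, "resnames", [path.stem])[0]) or path.stem
    return Ligand(name=name, atoms=atoms, bonds=bonds)


def _read_table(path: Path) -> Ligand:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _TABLE_MAGIC:
        raise LigandFormatError(
            f"{path}: line 1: expected header {_TABLE_MAGIC!r}"
        )
    name = path.stem
    section = None
    header: list[str] | None = None
    atoms: dict[int, Atom] = {}
    bonds: list[tuple[int, int]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("# name="):
            name = line.split("=", 1)[1].strip()
            continue
        if line.startswith("# section="):
            section = line.split("=", 1)[1].strip()
            header = None
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if header is None:
            header = cols
            if section == "atoms" and "charge" not in header:
                raise LigandFormatError(
                    f"{path}: line {lineno}: charges required — atoms section "
                    "has no 'charge' column"
                )
            continue
        if section == "atoms":
            try:
                rec = dict(zip(header, cols, strict=True))
                idx = int(rec["atom_id"])
                atoms[idx] = Atom(
                    rec["element"],
                    float(rec["charge"]),
                    float(rec["x"]),
                    float(rec["y"]),
                    float(rec["z"]),
                )
            except (ValueError, KeyError) as exc:
                raise LigandFormatError(
                    f"{path}: line {lineno}: bad atom record {line!r} ({exc})"
                ) from exc
        elif section == "bonds":
            try:
                a1, a2 = (int(c) for c in cols[:2])
            except ValueError as exc:
                raise LigandFormatError(
                    f"{path}: line {lineno}: bad bond record {line!r}"
                ) from exc
            bonds.append((a1, a2))
        else:
            raise LigandFormatError(
                f"{path}: line {lineno}: data outside any declared section"
            )
    if not atoms:
        raise LigandFormatError(f"{path}: no atoms section found")
    order = sorted(atoms)
    if order != list(range(1, len(order) + 1)):
        raise LigandFormatError(f"{path}: atom_id values must be 1..N, got {order}")
    try:
        return Ligand(
            name=name,
            atoms=[atoms[i] for i in order],
            bonds=[(a - 1, b - 1) for a, b in bonds],
        )
    except ValueError as exc:
        raise LigandFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# writing


def write_ligand(ligand: Ligand, path: str | Path) -> None:
    """Write a ligand as a molecule table (the TSV dialect read back by
    :func:`read_ligand`)."""
    path = Path(path)
    out: list[str] = [
        _TABLE_MAGIC,
        f"# name={ligand.name}",
        "# section=atoms",
        "atom_id\telement\tx\ty\tz\tcharge",
    ]
    for i, a in enumerate(ligand.atoms, start=1):
        out.append(f"{i}\t{a.element}\t{a.x!r}\t{a.y!r}\t{a.z!r}\t{a.charge!r}")
    out.append("# section=bonds")
    out.append("a1\ta2")
    for a, b in ligand.bonds:
        out.append(f"{a + 1}\t{b + 1}")
    path.write_text("\n".join(out) + "\n")


def from_arrays(
    name: str,
    elements: Sequence[str],
    charges: Sequence[float],
    coords: Iterable[Sequence[float]],
    bonds: Sequence[tuple[int, int]],
) -> Ligand:
    """Convenience constructor from parallel arrays."""
    atoms = [
        Atom(e, float(q), float(x), float(y), float(z))
        for e, q, (x, y, z) in zip(elements, charges, coords, strict=True)
    ]
    return Ligand(name=name, atoms=atoms, bonds=list(bonds))
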