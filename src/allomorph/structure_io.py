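"""Macromolecular structure I/O and residue-range atom selection.

Structures are held as a flat atom table (one row per atom) with author
residue numbering preserved, which is the numbering the βPGM literature
uses (cap T16–V87, core M1–D15 + S88–K221).  Reading and writing go
through :mod:`gemmi`; PDB v3.3 is the canonical write format and mmCIF is
supported read-only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ATOM_COLUMNS = [
    "chain_id", "residue_number", "residue_name", "atom_name",
    "element", "altloc", "occupancy", "het", "x", "y", "z",
]

#: Default βPGM domain boundaries (author numbering, inclusive).
BPGM_CAP_RANGES = ((16, 87),)
BPGM_CORE_RANGES = ((1, 15), (88, 221))


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with chain/residue/atom identity and position (Å)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    altloc: str
    occupancy: float
    position: tuple[float, float, float]
    het: bool = False

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class StructureModel:
    """Atomic model: an identifier plus a per-atom table.

    ``atoms`` columns: chain_id, residue_number, residue_name, atom_name,
    element, altloc, occupancy, het (bool), x, y, z (Å).
    """

    identifier: str
    atoms: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        if len(self.atoms) == 0:
            raise ValueError("empty model")
        key = self.atoms[["chain_id", "residue_number", "atom_name", "altloc"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate atom identity {tuple(dup)} in model "
                             f"{self.identifier!r}")

    @classmethod
    def from_records(cls, identifier: str,
                     records: Iterable[AtomRecord]) -> "StructureModel":
        rows = [
            (r.chain_id, r.residue_number, r.residue_name, r.atom_name,
             r.element, r.altloc, r.occupancy, r.het, *r.position)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
        return cls(identifier, df)

    def to_records(self) -> list[AtomRecord]:
        return [
            AtomRecord(row.chain_id, int(row.residue_number), row.residue_name,
                       row.atom_name, row.element, row.altloc,
                       float(row.occupancy), (row.x, row.y, row.z),
                       bool(row.het))
            for row in self.atoms.itertuples(index=False)
        ]

    @property
    def chain_ids(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain_id"]))

    def coordinates(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def with_coordinates(self, coords: np.ndarray,
                         identifier: str | None = None) -> "StructureModel":
        """Copy of the model with replaced coordinates (same atom order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = coords
        return StructureModel(identifier or self.identifier, atoms)


@dataclass(frozen=True)
class DomainDefinition:
    """Cap/core residue intervals (inclusive, author numbering).

    Defaults are the βPGM boundaries: cap T16–V87, core M1–D15 + S88–K221.
    """

    cap_ranges: tuple[tuple[int, int], ...] = BPGM_CAP_RANGES
    core_ranges: tuple[tuple[int, int], ...] = BPGM_CORE_RANGES

    def __post_init__(self) -> None:
        cap = self._numbers(self.cap_ranges)
        core = self._numbers(self.core_ranges)
        if cap & core:
            raise ValueError("cap and core residue ranges overlap")

    @staticmethod
    def _numbers(ranges: Sequence[tuple[int, int]]) -> set[int]:
        out: set[int] = set()
        for lo, hi in ranges:
            if hi < lo:
                raise ValueError(f"invalid interval {lo}-{hi}")
            out.update(range(lo, hi + 1))
        return out

    def residues(self, which: str) -> set[int]:
        if which == "cap":
            return self._numbers(self.cap_ranges)
        if which == "core":
            return self._numbers(self.core_ranges)
        raise ValueError(f"unknown domain {which!r} (expected 'cap' or 'core')")

    @classmethod
    def from_strings(cls, cap: str, core: str) -> "DomainDefinition":
        """Parse CLI-style range syntax, e.g. cap="16-87", core="1-15,88-221"."""
        return cls(parse_ranges(cap), parse_ranges(core))


def parse_ranges(text: str) -> tuple[tuple[int, int], ...]:
    """Parse "16-87" or "1-15,88-221" into inclusive interval tuples."""
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-", 1)
            out.append((int(lo), int(hi)))
        else:
            out.append((int(part), int(part)))
    if not out:
        raise ValueError(f"no residue ranges in {text!r}")
    return tuple(out)


def read_structure(path: str | Path, dialect: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``dialect`` is 'pdb' or 'mmcif'; if omitted it is inferred from the
    file extension.  Multi-model files yield the first model with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if dialect not in ("pdb", "mmcif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        fmt = gemmi.CoorFormat.Pdb if dialect == "pdb" else gemmi.CoorFormat.Mmcif
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {dialect}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"empty model in {path}")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} models present; using the first",
                      stacklevel=2)
    model = st[0]
    rows = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for atom in res:
                altloc = "" if atom.altloc in ("\0", "") else atom.altloc
                rows.append((chain.name, res.seqid.num, res.name, atom.name,
                             atom.element.name, altloc, float(atom.occ), het,
                             atom.pos.x, atom.pos.y, atom.pos.z))
    if not rows:
        raise ValueError(f"empty model in {path}")
    df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return StructureModel(path.stem if not st.name or st.name == "XXXX"
                          else st.name, df)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write PDB v3.3 fixed-column ATOM/HETATM records.

    Coordinates are emitted at PDB precision (3 decimal places).  Residue
    numbers above 9999 do not fit the fixed columns and raise an error.
    """
    path = Path(path)
    if (model.atoms["residue_number"] > 9999).any():
        raise ValueError("residue numbers > 9999 exceed PDB fixed columns")
    st = gemmi.Structure()
    st.name = model.identifier
    gm = gemmi.Model("1")
    for chain_id in model.chain_ids:
        chain = gemmi.Chain(chain_id)
        sub = model.atoms[model.atoms["chain_id"] == chain_id]
        for (resnum, resname, het), res_atoms in sub.groupby(
                ["residue_number", "residue_name", "het"], sort=False):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(int(resnum), " ")
            res.het_flag = "H" if het else "A"
            for row in res_atoms.itertuples(index=False):
                atom = gemmi.Atom()
                atom.name = row.atom_name
                atom.element = gemmi.Element(row.element)
                atom.pos = gemmi.Position(row.x, row.y, row.z)
                atom.occ = float(row.occupancy)
                atom.altloc = row.altloc if row.altloc else "\0"
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def _filtered_atoms(model: StructureModel, chain: str | None,
                    atom_filter: str, include_het: bool) -> pd.DataFrame:
    if atom_filter not in ("ca_only", "non_h", "all"):
        raise ValueError(f"unknown atom_filter {atom_filter!r}")
    atoms = model.atoms
    if chain is None:
        chain = model.chain_ids[0]
    if chain not in set(atoms["chain_id"]):
        raise ValueError(f"chain {chain!r} not present in {model.identifier!r}")
    atoms = atoms[atoms["chain_id"] == chain]
    # Altloc policy: keep blank or 'A' only; log when alternates are dropped.
    keep = atoms["altloc"].isin(["", "A"])
    if (~keep).any():
        logger.info("%s chain %s: dropping %d alternate-location atoms",
                    model.identifier, chain, int((~keep).sum()))
    atoms = atoms[keep]
    if not include_het:
        atoms = atoms[~atoms["het"]]
    if atom_filter == "ca_only":
        atoms = atoms[atoms["atom_name"] == "CA"]
    elif atom_filter == "non_h":
        atoms = atoms[~atoms["element"].isin(["H", "D"])]
    return atoms.sort_values(["residue_number", "atom_name"], kind="stable")


def select_domain_coords(
    model: StructureModel,
    domains: DomainDefinition,
    which: str,
    atom_filter: str = "ca_only",
    chain: str | None = None,
    include_het: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Coordinates and identities of atoms in the cap or core domain.

    Atoms are ordered by residue number then atom name.  Residues defined
    by the domain ranges but absent from the model are simply omitted; the
    returned identity table records what survived.
    """
    atoms = _filtered_atoms(model, chain, atom_filter, include_het)
    wanted = domains.residues(which)
    sel = atoms[atoms["residue_number"].isin(wanted)]
    if len(sel) < 3:
        raise ValueError(
            f"degenerate selection: {len(sel)} atoms for {which} domain of "
            f"{model.identifier!r}")
    coords = sel[["x", "y", "z"]].to_numpy(dtype=float)
    identity = sel[["chain_id", "residue_number", "residue_name",
                    "atom_name"]].reset_index(drop=True)
    return coords, identity


def pair_shared_atoms(
    a: StructureModel,
    b: StructureModel,
    atom_filter: str = "non_h",
    chain_a: str | None = None,
    chain_b: str | None = None,
    include_het: bool = False,
    residue_subset: set[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Pair atoms present in both models under (residue_number, atom_name).

    A residue number shared by both models but with differing residue names
    (a point mutant such as D10N or P146A) is excluded from the pairing and
    logged.  Returns equal-length coordinate arrays in matching order plus
    the paired identity table.
    """
    fa = _filtered_atoms(a, chain_a, atom_filter, include_het)
    fb = _filtered_atoms(b, chain_b, atom_filter, include_het)
    if residue_subset is not None:
        fa = fa[fa["residue_number"].isin(residue_subset)]
        fb = fb[fb["residue_number"].isin(residue_subset)]
    merged = fa.merge(fb, on=["residue_number", "atom_name"],
                      suffixes=("_a", "_b"))
    mismatch = merged["residue_name_a"] != merged["residue_name_b"]
    if mismatch.any():
        bad = sorted(merged.loc[mismatch, "residue_number"].unique())
        logger.info("excluding residues with mismatched names %s "
                    "(%s vs %s)", bad, a.identifier, b.identifier)
        merged = merged[~mismatch]
    merged = merged.sort_values(["residue_number", "atom_name"], kind="stable")
    if len(merged) < 3:
        raise ValueError(
            f"fewer than 3 shared atoms between {a.identifier!r} and "
            f"{b.identifier!r}")
    coords_a = merged[["x_a", "y_a", "z_a"]].to_numpy(dtype=float)
    coords_b = merged[["x_b", "y_b", "z_b"]].to_numpy(dtype=float)
    identity = merged[["residue_number", "residue_name_a",
                       "atom_name"]].rename(
        columns={"residue_name_a": "residue_name"}).reset_index(drop=True)
    return coords_a, coords_b, identity
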