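"""PDB parsing into a lightweight antigen model of chains, residues and heavy atoms.

The in-memory model keeps only what the pipeline consumes: heavy-atom coordinates,
residue identities and side-chain membership.  Parsing is delegated to gemmi; this
module applies the project conventions on top of it (single chain, first altloc,
MODEL 1 only, waters and non-amino-acid heteroatoms excluded, MSE/SEC mapped onto
their standard parents).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .chemistry import (
    BACKBONE_ATOMS,
    BONDI_RADII,
    DEFAULT_VDW_RADIUS,
    NONSTANDARD_MAP,
    THREE_TO_ONE,
)

#: (chain id, residue number, insertion code)
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_key: ResidueKey
    position: np.ndarray  # (3,) Angstrom
    vdw_radius: float
    is_heavy: bool
    is_side_chain: bool

    def distance(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.position - other.position))


@dataclass
class Residue:
    residue_key: ResidueKey
    amino_acid: str  # one-letter code
    atoms: list[Atom]
    sequence_index: int

    @property
    def number(self) -> int:
        return self.residue_key[1]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def ca_position(self) -> np.ndarray:
        ca = self.atom("CA")
        if ca is not None:
            return ca.position
        # degenerate fallback: centroid of heavy atoms
        return np.mean([a.position for a in self.heavy_atoms()], axis=0)


@dataclass
class Structure:
    pdb_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.residues)

    def __len__(self):
        return len(self.residues)

    def heavy_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms if a.is_heavy]

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.residue_key == key:
                return r
        raise KeyError(key)

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.residue_key: r for r in self.residues}


def _validate_coordinates(text: str) -> None:
    """Raise with a line number if an ATOM/HETATM record has unparseable coordinates."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ValueError(
                        f"malformed record at line {lineno}: bad coordinate field "
                        f"{line[lo:hi]!r}"
                    ) from None


def parse_pdb(
    text: str,
    chain_id: str,
    pdb_id: str = "",
    radius_table: dict[str, float] | None = None,
) -> Structure:
    """Parse one chain of a PDB-format string into a :class:`Structure`.

    Hydrogens are retained but flagged ``is_heavy=False``; waters and
    non-amino-acid HETATM records are excluded; only the first-listed altloc of
    each atom and only MODEL 1 are kept.  MSE is mapped to MET and SEC to CYS;
    other non-standard residues are dropped with a warning.

    Raises
    ------
    ValueError
        If the chain has no ATOM records ("chain not found") or a coordinate
        field cannot be parsed ("malformed record" with the line number).
    """
    _validate_coordinates(text)
    radii = dict(BONDI_RADII)
    if radius_table:
        radii.update({k.upper(): v for k, v in radius_table.items()})

    st = gemmi.read_pdb_string(text)
    st.remove_alternative_conformations()  # keeps the first-listed altloc
    if len(st) == 0:
        raise ValueError(f"chain not found: no ATOM records for chain {chain_id!r}")
    model = st[0]  # MODEL 1 only
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ValueError(f"chain not found: no ATOM records for chain {chain_id!r}")

    residues: list[Residue] = []
    serial = 0
    for res in chain:
        resname = res.name.upper()
        atom_renames: dict[str, str] = {}
        if resname in NONSTANDARD_MAP:
            resname, atom_renames = NONSTANDARD_MAP[resname]
        if resname not in THREE_TO_ONE:
            if resname not in ("HOH", "DOD"):
                warnings.warn(f"dropping non-standard residue {res.name} {res.seqid}")
            continue
        key: ResidueKey = (chain_id, res.seqid.num, res.seqid.icode.strip() or "")
        atoms: list[Atom] = []
        for at in res:
            serial += 1
            name = atom_renames.get(at.name, at.name)
            element = at.element.name.upper() if at.element else ""
            if not element:
                element = name[0].upper()
            is_heavy = element not in ("H", "D")
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_key=key,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
                    vdw_radius=radii.get(element, DEFAULT_VDW_RADIUS),
                    is_heavy=is_heavy,
                    is_side_chain=is_heavy and name not in BACKBONE_ATOMS,
                )
            )
        if not any(a.is_heavy for a in atoms):
            continue
        residues.append(
            Residue(
                residue_key=key,
                amino_acid=THREE_TO_ONE[resname],
                atoms=atoms,
                sequence_index=len(residues),
            )
        )
    if not residues:
        raise ValueError(f"chain not found: no ATOM records for chain {chain_id!r}")
    residues.sort(key=lambda r: (r.residue_key[1], r.residue_key[2]))
    for i, r in enumerate(residues):
        r.sequence_index = i
    return Structure(pdb_id=pdb_id, chain_id=chain_id, residues=residues)


def side_chain_atoms(residue: Residue) -> list[Atom]:
    """Heavy side-chain atoms of a residue; for glycine, [CA] is the surrogate.

    The residue surface rate averages over side-chain atoms, which would
    otherwise be undefined for glycine.
    """
    sc = [a for a in residue.atoms if a.is_side_chain]
    if sc:
        return sc
    ca = residue.atom("CA")
    return [ca] if ca is not None else []


def assign_vdw_radii(structure: Structure, radius_table: dict[str, float]) -> Structure:
    """Return a copy of the structure with van der Waals radii reassigned.

    Unknown elements receive the 1.7 A default.
    """
    table = {k.upper(): v for k, v in radius_table.items()}
    new_residues = []
    for res in structure.residues:
        atoms = [
            replace(a, vdw_radius=table.get(a.element, DEFAULT_VDW_RADIUS))
            for a in res.atoms
        ]
        new_residues.append(replace_atoms(res, atoms))
    return Structure(structure.pdb_id, structure.chain_id, new_residues)


def replace_atoms(residue: Residue, atoms: list[Atom]) -> Residue:
    return Residue(
        residue_key=residue.residue_key,
        amino_acid=residue.amino_acid,
        atoms=atoms,
        sequence_index=residue.sequence_index,
    )


def write_pdb(*structures: Structure) -> str:
    """Serialize structures (e.g. an antigen/pseudo-antibody pair) as PDB text."""
    from .chemistry import ONE_TO_THREE

    lines = []
    serial = 0
    for structure in structures:
        for res in structure.residues:
            resname = ONE_TO_THREE[res.amino_acid]
            chain, num, icode = res.residue_key
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.position
                lines.append(
                    f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} {chain:1s}"
                    f"{num:4d}{icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
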