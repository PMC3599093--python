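"""Knowledge-based heavy-atom contact potential and per-residue energy profiles.

Heavy atoms are typed by (residue, atom name) over the 20 standard residues —
167 types.  The pair energy is the negative log ratio of observed to expected
contact counts within a distance cutoff, with a pseudocount keeping every pair
finite:

    e(a, b) = -log10( (O(a,b) + c) / (E(a,b) + c) ),
    E(a,b)  = T * x_a * x_b * (2 - delta_ab),

where T is the total number of contacts and x_t the mole fraction of type t
among contacting atoms.  Higher energy means fewer contacts than expected,
i.e. a less favorable (more epitope-like) environment.  Residue energies sum
the pair energies over all contacts of the residue's heavy atoms with atoms at
sequence separation >= 2, and the profile is smoothed by averaging over
surface residues whose CA lies within an 8-A sphere (a sequence-window
variant is available).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import ONE_TO_THREE, RESIDUE_HEAVY_ATOMS
from .structure_io import Residue, ResidueKey, Structure

DEFAULT_CUTOFF = 5.0  # Angstrom
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_SEQ_SEP = 2
DEFAULT_LOCAL_RADIUS = 8.0  # Angstrom
DEFAULT_TOP_FRACTION = 0.2

#: canonical atom-type alphabet: "RES:NAME" for all heavy atoms of the 20 residues.
ATOM_TYPES: list[str] = [
    f"{res}:{name}"
    for res in sorted(RESIDUE_HEAVY_ATOMS)
    for name in RESIDUE_HEAVY_ATOMS[res]
]
ATOM_TYPE_INDEX: dict[str, int] = {t: i for i, t in enumerate(ATOM_TYPES)}
N_TYPES = len(ATOM_TYPES)  # 167


def atom_type_id(residue_aa: str, atom_name: str) -> int | None:
    """Type id for a heavy atom, or None for names outside the canonical set."""
    three = ONE_TO_THREE.get(residue_aa)
    if three is None:
        return None
    return ATOM_TYPE_INDEX.get(f"{three}:{atom_name}")


@dataclass
class ContactPotential:
    cutoff: float
    pseudocount: float
    energies: np.ndarray  # (N_TYPES, N_TYPES), symmetric
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP
    provenance: list[str] = field(default_factory=list)

    def energy(self, type_a: int, type_b: int) -> float:
        return float(self.energies[type_a, type_b])

    def to_json(self) -> str:
        return json.dumps(
            {
                "cutoff": self.cutoff,
                "pseudocount": self.pseudocount,
                "min_seq_sep": self.min_seq_sep,
                "atom_types": ATOM_TYPES,
                "energies": self.energies.tolist(),
                "provenance": self.provenance,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ContactPotential":
        d = json.loads(text)
        if d["atom_types"] != ATOM_TYPES:
            raise ValueError("atom-type alphabet mismatch")
        return cls(
            cutoff=d["cutoff"],
            pseudocount=d["pseudocount"],
            energies=np.asarray(d["energies"], dtype=float),
            min_seq_sep=d.get("min_seq_sep", DEFAULT_MIN_SEQ_SEP),
            provenance=list(d.get("provenance", [])),
        )


def _typed_heavy_atoms(structure: Structure):
    """(positions, type ids, sequence indices, residue keys) of typable heavy atoms."""
    pos, types, seq, keys = [], [], [], []
    for res in structure:
        for atom in res.heavy_atoms():
            t = atom_type_id(res.amino_acid, atom.name)
            if t is None:
                continue
            pos.append(atom.position)
            types.append(t)
            seq.append(res.sequence_index)
            keys.append(res.residue_key)
    return (np.asarray(pos, dtype=float).reshape(-1, 3), np.asarray(types),
            np.asarray(seq), keys)


def count_contacts(structures: list[Structure], cutoff: float = DEFAULT_CUTOFF,
                   min_seq_sep: int = DEFAULT_MIN_SEQ_SEP) -> np.ndarray:
    """Symmetric observed-contact matrix O over atom types.

    A contact is an unordered heavy-atom pair within ``cutoff`` whose residues
    are separated by at least ``min_seq_sep`` in sequence; O[a, b] counts each
    contact once (homo-type contacts on the diagonal).
    """
    observed = np.zeros((N_TYPES, N_TYPES), dtype=float)
    for st in structures:
        pos, types, seq, _ = _typed_heavy_atoms(st)
        if len(pos) < 2:
            continue
        tree = cKDTree(pos)
        for i, j in tree.query_pairs(cutoff):
            if abs(seq[i] - seq[j]) < min_seq_sep:
                continue
            a, b = types[i], types[j]
            observed[a, b] += 1
            if a != b:
                observed[b, a] += 1
    return observed


def potential_from_observed(observed: np.ndarray, cutoff: float,
                            pseudocount: float,
                            min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
                            provenance: list[str] | None = None) -> ContactPotential:
    """Turn an observed-contact matrix into energies via the observed/expected ratio."""
    upper = np.triu(observed)
    total = upper.sum()
    if total == 0:
        raise ValueError("training set too small: no contacts found")
    # each contact contributes its two atom instances
    instance_counts = observed.sum(axis=1) + np.diag(observed)
    x = instance_counts / (2.0 * total)
    expected = total * np.outer(x, x) * (2.0 - np.eye(N_TYPES))
    energies = -np.log10((observed + pseudocount) / (expected + pseudocount))
    return ContactPotential(
        cutoff=cutoff,
        pseudocount=pseudocount,
        energies=energies,
        min_seq_sep=min_seq_sep,
        provenance=provenance or [],
    )


def train_contact_potential(structures: list[Structure],
                            cutoff: float = DEFAULT_CUTOFF,
                            pseudocount: float = DEFAULT_PSEUDOCOUNT,
                            min_seq_sep: int = DEFAULT_MIN_SEQ_SEP) -> ContactPotential:
    """Estimate the contact potential from a corpus of structures."""
    if not structures:
        raise ValueError("training set too small: no structures")
    observed = count_contacts(structures, cutoff, min_seq_sep)
    return potential_from_observed(
        observed, cutoff, pseudocount, min_seq_sep,
        provenance=[st.pdb_id or f"structure-{i}" for i, st in enumerate(structures)],
    )


def residue_energy(residue: Residue, structure: Structure,
                   potential: ContactPotential) -> float:
    """Sum of pair energies over the residue's contacts with the rest of the chain."""
    pos, types, seq, keys = _typed_heavy_atoms(structure)
    own = np.array([k == residue.residue_key for k in keys])
    if not own.any() or len(pos) < 2:
        return 0.0
    tree = cKDTree(pos[~own])
    other_types = types[~own]
    other_seq = seq[~own]
    total = 0.0
    for p, t in zip(pos[own], types[own]):
        for j in tree.query_ball_point(p, potential.cutoff):
            if abs(int(other_seq[j]) - residue.sequence_index) < potential.min_seq_sep:
                continue
            total += potential.energy(t, other_types[j])
    return total


@dataclass
class EnergyProfile:
    per_residue: dict[ResidueKey, float]
    local_average: dict[ResidueKey, float]
    radius: float = DEFAULT_LOCAL_RADIUS
    mode: str = "spatial"  # "spatial" (CA sphere) or "window" (sequence)


def compute_energy_profile(structure: Structure, potential: ContactPotential,
                           surface: set[ResidueKey],
                           radius: float = DEFAULT_LOCAL_RADIUS,
                           mode: str = "spatial",
                           window: int = 8) -> EnergyProfile:
    """Per-residue energies on the surface set plus their local averages.

    ``mode='spatial'`` averages over surface residues whose CA lies within
    ``radius`` of this residue's CA (itself included); ``mode='window'``
    averages over surface residues within a sequence window of ``window``
    residues (half-width window//2).
    """
    pos_all, types_all, seq_all, keys_all = _typed_heavy_atoms(structure)
    tree = cKDTree(pos_all) if len(pos_all) else None
    energies: dict[ResidueKey, float] = {}
    surf_res = [r for r in structure if r.residue_key in surface]
    for res in surf_res:
        own = np.array([k == res.residue_key for k in keys_all])
        total = 0.0
        if tree is not None and own.any():
            for p, t in zip(pos_all[own], types_all[own]):
                for j in tree.query_ball_point(p, potential.cutoff):
                    if own[j]:
                        continue
                    if abs(int(seq_all[j]) - res.sequence_index) < potential.min_seq_sep:
                        continue
                    total += potential.energy(int(t), int(types_all[j]))
        energies[res.residue_key] = total

    local: dict[ResidueKey, float] = {}
    if surf_res:
        cas = np.array([r.ca_position() for r in surf_res])
        seqs = np.array([r.sequence_index for r in surf_res])
        evals = np.array([energies[r.residue_key] for r in surf_res])
        for i, res in enumerate(surf_res):
            if mode == "window":
                near = np.abs(seqs - seqs[i]) <= window // 2
            else:
                near = ((cas - cas[i]) ** 2).sum(axis=1) <= radius ** 2 + 1e-12
            local[res.residue_key] = float(evals[near].mean())
    return EnergyProfile(per_residue=energies, local_average=local,
                         radius=radius, mode=mode)


def rank_by_energy(profile: EnergyProfile, surface: set[ResidueKey],
                   top_fraction: float = DEFAULT_TOP_FRACTION) -> list[ResidueKey]:
    """Top fraction of surface residues by descending local-average energy.

    Ties break by higher single-residue energy, then lower residue number.
    """
    if not surface:
        raise ValueError("empty surface set")
    ordered = sorted(
        surface,
        key=lambda k: (-profile.local_average.get(k, 0.0),
                       -profile.per_residue.get(k, 0.0), k[1], k[2]),
    )
    n_keep = math.ceil(top_fraction * len(ordered))
    return ordered[:n_keep]


def export_energy_profile(profile: EnergyProfile, structure: Structure, path) -> None:
    """TSV export: chain, resnum, aa, energy, local_avg (surface residues only)."""
    aa = {r.residue_key: r.amino_acid for r in structure}
    lines = ["chain\tresnum\ticode\taa\tenergy\tlocal_avg"]
    for key in sorted(profile.per_residue, key=lambda k: (k[0], k[1], k[2])):
        chain, num, icode = key
        lines.append(
            f"{chain}\t{num}\t{icode}\t{aa.get(key, 'X')}\t"
            f"{profile.per_residue[key]:.6f}\t{profile.local_average[key]:.6f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
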