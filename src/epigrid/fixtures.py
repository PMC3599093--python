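"""Deterministic synthetic structures: toy antigens, planted epitope patches,
and pseudo-antibody complexes.

The generator emits compact self-avoiding pseudo-protein chains whose heavy
atoms use canonical residue/atom names, so every downstream stage (voxel
surface, contact typing, pair statistics, complex-based truth extraction)
runs on them unchanged.  Geometry is simplified — idealized backbone offsets
and side chains grown along a jittered outward ray, no rotamers — because the
pipeline depends only on heavy-atom coordinates, types and labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemistry import (
    AMINO_ACIDS,
    ONE_TO_THREE,
    SIDE_CHAIN_HEAVY_ATOMS,
    element_from_atom_name,
    BONDI_RADII,
    DEFAULT_VDW_RADIUS,
)
from .structure_io import Atom, Residue, ResidueKey, Structure

CA_STEP = 3.8  # Angstrom, consecutive CA distance
MIN_CA_DIST = 3.6  # Angstrom, self-avoidance
MAX_SIDE_CHAIN_ATOMS = 5


@dataclass
class FixtureSpec:
    n_residues: int = 40
    seed: int = 0
    patch_size: int = 6
    patch_pair_bias: tuple[tuple[str, str], float] = (("H", "Q"), 5.0)
    energy_bias: float = 1.0
    geometry: str = "compact-globule"
    alphabet: list[str] = field(default_factory=lambda: list(AMINO_ACIDS))

    def __post_init__(self):
        if self.patch_size >= self.n_residues:
            raise ValueError("patch_size must be smaller than n_residues")
        if self.patch_pair_bias[1] < 1:
            raise ValueError("enrichment factor must be >= 1")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _sample_ca_chain(n: int, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding CA trace confined to a ball sized for Rg ~ 3 n^(1/3)."""
    target_rg = 3.0 * n ** (1.0 / 3.0)
    r_max = target_rg / np.sqrt(3.0 / 5.0)  # uniform-ball radius giving that Rg
    for _ in range(50):  # chain restarts
        pts = [rng.normal(scale=0.5, size=3)]
        ok = True
        for _i in range(1, n):
            placed = False
            for _try in range(300):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                cand = pts[-1] + CA_STEP * d
                if np.linalg.norm(cand) > r_max:
                    continue
                arr = np.asarray(pts)
                if (((arr - cand) ** 2).sum(axis=1) < MIN_CA_DIST ** 2).any():
                    continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise RuntimeError(f"could not pack a {n}-residue chain (rng state exhausted)")


def _build_residue(key: ResidueKey, aa: str, ca: np.ndarray, centroid: np.ndarray,
                   seq_index: int, rng: np.random.Generator,
                   serial_start: int, outward_weight: float = 0.7) -> Residue:
    """Backbone at idealized offsets plus a side chain along a jittered outward ray."""
    rot = _random_rotation(rng)
    atoms: list[Atom] = []
    serial = serial_start

    def add(name: str, pos: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        element = element_from_atom_name(name)
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_key=key,
                position=np.asarray(pos, dtype=float),
                vdw_radius=BONDI_RADII.get(element, DEFAULT_VDW_RADIUS),
                is_heavy=True,
                is_side_chain=name not in ("N", "CA", "C", "O"),
            )
        )

    add("N", ca + rot @ np.array([-1.46, 0.0, 0.0]))
    add("CA", ca)
    add("C", ca + rot @ np.array([1.52, 0.0, 0.0]))
    add("O", ca + rot @ np.array([2.02, 1.06, 0.0]))

    outward = ca - centroid
    nrm = np.linalg.norm(outward)
    outward = outward / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
    direction = outward_weight * outward + rng.normal(scale=0.45, size=3)
    direction /= np.linalg.norm(direction)
    names = SIDE_CHAIN_HEAVY_ATOMS[ONE_TO_THREE[aa]][:MAX_SIDE_CHAIN_ATOMS]
    for k, name in enumerate(names, start=1):
        jitter = rng.normal(scale=0.30, size=3)
        add(name, ca + direction * 1.5 * k + jitter)

    return Residue(residue_key=key, amino_acid=aa, atoms=atoms,
                   sequence_index=seq_index)


def make_toy_antigen(spec: FixtureSpec) -> Structure:
    """Seeded compact pseudo-protein chain of ``n_residues`` residues, chain A."""
    if spec.n_residues < 10:
        raise ValueError("n_residues must be >= 10")
    rng = np.random.default_rng(spec.seed)
    cas = _sample_ca_chain(spec.n_residues, rng)
    centroid = cas.mean(axis=0)
    residues = []
    serial = 0
    for i, ca in enumerate(cas):
        aa = str(rng.choice(spec.alphabet))
        key: ResidueKey = ("A", i + 1, "")
        res = _build_residue(key, aa, ca, centroid, i, rng, serial)
        serial += len(res.atoms)
        residues.append(res)
    return Structure(pdb_id=f"FIX{spec.seed:04d}", chain_id="A", residues=residues)


def plant_epitope(structure: Structure, spec: FixtureSpec) -> tuple[Structure, set[ResidueKey]]:
    """Relabel a surface-exposed spatial patch to enrich the biased residue pair.

    The patch seeds at the most exposed residue and takes its nearest exposed
    neighbors.  With enrichment factor e, round(patch_size * min(1, e/10))
    patch residues alternate between the two biased amino acids along a
    nearest-neighbor ordering (maximizing their mutual contacts); the rest are
    redrawn from the alphabet.  Side chains of patch residues are rebuilt
    pointing outward so the patch stays exposed.
    """
    (aa1, aa2), enrich = spec.patch_pair_bias
    rng = np.random.default_rng(spec.seed + 1_000_003)
    cas = np.array([r.ca_position() for r in structure])
    centroid = cas.mean(axis=0)
    exposure = np.linalg.norm(cas - centroid, axis=1)
    exposed = exposure >= np.median(exposure)
    seed_i = int(np.argmax(exposure))
    cand = [i for i in range(len(structure)) if exposed[i] or i == seed_i]
    cand.sort(key=lambda i: float(np.linalg.norm(cas[i] - cas[seed_i])))
    patch_idx = cand[: spec.patch_size]
    if len(patch_idx) < spec.patch_size:
        raise RuntimeError("no sufficiently exposed patch")

    # nearest-neighbor ordering through the patch so biased residues adjoin
    ordering = [seed_i]
    remaining = [i for i in patch_idx if i != seed_i]
    while remaining:
        last = ordering[-1]
        nxt = min(remaining, key=lambda i: float(np.linalg.norm(cas[i] - cas[last])))
        ordering.append(nxt)
        remaining.remove(nxt)

    n_biased = int(round(spec.patch_size * min(1.0, enrich * 2.0 / 20.0)))
    biased = ordering[:n_biased]
    # two-color the biased residues to maximize aa1-aa2 adjacencies among
    # spatially close, sequence-separated pairs (the pairs that count both for
    # geometric pair statistics and for the contact potential)
    edges = {
        (i, j)
        for i in biased
        for j in biased
        if i < j
        and abs(structure.residues[i].sequence_index
                - structure.residues[j].sequence_index) >= 2
        and np.linalg.norm(cas[i] - cas[j]) <= 7.0
    }
    color: dict[int, str] = {}
    for i in biased:
        votes = {aa1: 0, aa2: 0}
        for j, c in color.items():
            if (min(i, j), max(i, j)) in edges:
                votes[aa2 if c == aa1 else aa1] += 1
        color[i] = aa1 if votes[aa1] >= votes[aa2] else aa2
    assignments: dict[int, str] = dict(color)
    for i in ordering[n_biased:]:
        assignments[i] = str(rng.choice(spec.alphabet))

    new_residues = list(structure.residues)
    serial = max(a.serial for r in structure for a in r.atoms)
    ce_keys: set[ResidueKey] = set()
    for i in ordering:
        old = structure.residues[i]
        res = _build_residue(old.residue_key, assignments[i], cas[i], centroid,
                             old.sequence_index, rng, serial, outward_weight=1.2)
        serial += len(res.atoms)
        new_residues[i] = res
        ce_keys.add(old.residue_key)
    return (
        Structure(structure.pdb_id, structure.chain_id, new_residues),
        ce_keys,
    )


def make_labeled_antigen(spec: FixtureSpec) -> tuple[Structure, set[ResidueKey]]:
    """Convenience: toy antigen with a planted, pair-enriched epitope patch."""
    return plant_epitope(make_toy_antigen(spec), spec)


def make_training_backgrounds(n_structures: int, seed: int,
                              bias_pair: tuple[str, str] = ("H", "Q"),
                              n_residues: int = 60) -> list[Structure]:
    """Reference corpus in which the biased pair types never co-occur.

    Half the structures omit one partner, half the other, so the trained
    potential observes zero contacts between the pair's atom types and assigns
    them high (unfavorable) energies — the energy enrichment planted patches
    rely on.
    """
    a, b = bias_pair
    out = []
    for i in range(n_structures):
        drop = a if i % 2 == 0 else b
        alphabet = [x for x in AMINO_ACIDS if x != drop]
        out.append(
            make_toy_antigen(
                FixtureSpec(n_residues=n_residues, seed=seed + 7919 * (i + 1),
                            alphabet=alphabet)
            )
        )
    return out


def make_complex(antigen: Structure, ce_set: set[ResidueKey],
                 seed: int) -> Structure:
    """Rigid pseudo-antibody atom cloud touching exactly the CE residues.

    Every CE residue gets >= 1 antibody atom within 3.5 A of a heavy atom;
    no antibody atom comes within 4 A of any non-CE residue.  The antibody is
    returned as chain B of one-atom glycine pseudo-residues.
    """
    if not ce_set:
        raise ValueError("CE set must be nonempty")
    rng = np.random.default_rng(seed)
    all_atoms = antigen.heavy_atoms()
    centroid = np.mean([a.position for a in all_atoms], axis=0)
    non_ce_pos = np.array(
        [a.position for a in all_atoms if a.residue_key not in ce_set]
    ).reshape(-1, 3)
    probes: list[np.ndarray] = []
    for res in antigen:
        if res.residue_key not in ce_set:
            continue
        atoms = sorted(res.heavy_atoms(),
                       key=lambda a: -np.linalg.norm(a.position - centroid))
        placed = False
        for atom in atoms:
            outward = atom.position - centroid
            outward /= np.linalg.norm(outward)
            for trial in range(60):
                d = outward if trial == 0 else outward + rng.normal(scale=0.3, size=3)
                d = d / np.linalg.norm(d)
                p = atom.position + 3.2 * d
                if np.linalg.norm(p - atom.position) > 3.5:
                    continue
                if len(non_ce_pos) and np.min(
                    ((non_ce_pos - p) ** 2).sum(axis=1)
                ) < 4.05 ** 2:
                    continue
                all_pos = np.array([a.position for a in all_atoms])
                if np.min(((all_pos - p) ** 2).sum(axis=1)) < 2.5 ** 2:
                    continue
                probes.append(p)
                placed = True
                break
            if placed:
                break
        if not placed:
            raise RuntimeError(
                f"pseudo-antibody placement infeasible for residue "
                f"{res.residue_key} (seed {seed})"
            )
    residues = []
    for i, p in enumerate(probes):
        key: ResidueKey = ("B", i + 1, "")
        residues.append(
            Residue(
                residue_key=key,
                amino_acid="G",
                atoms=[
                    Atom(serial=i + 1, name="CA", element="C", residue_key=key,
                         position=p, vdw_radius=BONDI_RADII["C"], is_heavy=True,
                         is_side_chain=False)
                ],
                sequence_index=i,
            )
        )
    return Structure(pdb_id=antigen.pdb_id, chain_id="B", residues=residues)
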