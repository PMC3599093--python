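"""Residue surface rates SR(r) aggregated from atomic surface rates AR(r).

Only side-chain heavy atoms enter the residue surface rate: side-chain exposure
is what governs antibody engagement.  A "surface atom" is a side-chain atom
with AR > 0; SR is the mean AR over those N atoms, and a residue with no
surface atoms is buried (SR = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .morphology import (
    DEFAULT_B1_RADIUS,
    DEFAULT_SPACING,
    atom_surface_rate,
    morphological_surface,
)
from .structure_io import Residue, ResidueKey, Structure, side_chain_atoms

DEFAULT_MIN_SR = 0.05


@dataclass
class SurfaceTable:
    """Per-atom AR and per-residue SR records for one antigen chain."""

    min_sr: float = DEFAULT_MIN_SR
    atom_rates: dict[int, float] = field(default_factory=dict)  # atom serial -> AR
    residue_sr: dict[ResidueKey, float] = field(default_factory=dict)
    residue_n_surface: dict[ResidueKey, int] = field(default_factory=dict)
    residue_aa: dict[ResidueKey, str] = field(default_factory=dict)

    def is_surface(self, key: ResidueKey) -> bool:
        return (
            self.residue_n_surface.get(key, 0) > 0
            and self.residue_sr.get(key, 0.0) >= self.min_sr
        )

    def surface_residues(self, min_sr: float | None = None) -> set[ResidueKey]:
        thr = self.min_sr if min_sr is None else min_sr
        return {
            k
            for k, sr in self.residue_sr.items()
            if self.residue_n_surface[k] > 0 and sr >= thr
        }


def residue_surface_rate(residue: Residue, atom_rates: dict[int, float]) -> tuple[float, int]:
    """SR = mean AR over the residue's side-chain atoms with AR > 0.

    Returns ``(SR, N)`` where N is the number of surface atoms; a fully buried
    side chain yields ``(0.0, 0)``.
    """
    rates = [atom_rates[a.serial] for a in side_chain_atoms(residue)
             if a.serial in atom_rates and atom_rates[a.serial] > 0.0]
    if not rates:
        return 0.0, 0
    return sum(rates) / len(rates), len(rates)


def compute_surface_table(
    structure: Structure,
    spacing: float = DEFAULT_SPACING,
    b1_radius: float = DEFAULT_B1_RADIUS,
    b2_radius: float | None = None,
    min_sr: float = DEFAULT_MIN_SR,
) -> SurfaceTable:
    """Run the morphological surface construction and aggregate AR into SR."""
    morph = morphological_surface(structure, spacing, b1_radius, b2_radius)
    table = SurfaceTable(min_sr=min_sr)
    for res in structure:
        for atom in side_chain_atoms(res):
            table.atom_rates[atom.serial] = atom_surface_rate(
                atom, morph.shell, morph.occupied
            )
        sr, n = residue_surface_rate(res, table.atom_rates)
        table.residue_sr[res.residue_key] = sr
        table.residue_n_surface[res.residue_key] = n
        table.residue_aa[res.residue_key] = res.amino_acid
    return table


def surface_residues(table: SurfaceTable, min_sr: float = DEFAULT_MIN_SR) -> set[ResidueKey]:
    """Residues whose SR meets the threshold (and that have >=1 surface atom)."""
    return table.surface_residues(min_sr)


def export_surface_table(table: SurfaceTable, path) -> None:
    """Write the look-up table as TSV, rows ordered deterministically by residue key."""
    lines = ["chain\tresnum\ticode\taa\tSR\tN\tis_surface"]
    for key in sorted(table.residue_sr, key=lambda k: (k[0], k[1], k[2])):
        chain, num, icode = key
        lines.append(
            f"{chain}\t{num}\t{icode}\t{table.residue_aa.get(key, 'X')}\t"
            f"{table.residue_sr[key]:.6f}\t{table.residue_n_surface[key]}\t"
            f"{int(table.is_surface(key))}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
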