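"""Geometrically related amino-acid pair (GAAP) statistics and the CE index.

Two surface residues form a geometric pair when their minimal heavy-atom
distance falls within a radius (2-6 A; default 4 A).  Pair occurrences are
tallied separately in epitope (both residues CE-labeled) and non-epitope
(both on the surface, at least one non-CE) sets; the CE index of a pair is
the min-max-normalized log10 ratio of its frequencies in the two sets, so
that values near 1 mark pairings over-represented at antibody-binding sites.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import AMINO_ACIDS
from .structure_io import ResidueKey, Structure

DEFAULT_PAIR_RADIUS = 4.0  # Angstrom, midpoint of the 2-6 A range
DEFAULT_PSEUDOCOUNT = 1.0

Pair = tuple[str, str]  # unordered, stored sorted


def pair_key(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def enumerate_pair_alphabet() -> list[Pair]:
    """All 210 unordered amino-acid pairs (190 hetero + 20 homo)."""
    pairs = [pair_key(a, b) for a, b in combinations(AMINO_ACIDS, 2)]
    pairs += [(a, a) for a in AMINO_ACIDS]
    return sorted(pairs)


def extract_geometric_pairs(structure: Structure, residue_set: set[ResidueKey],
                            radius: float = DEFAULT_PAIR_RADIUS) -> list[Pair]:
    """Multiset of amino-acid pairs for residue pairs in geometric contact.

    One pair instance per unordered residue pair (i != j), both in
    ``residue_set``, whose minimal heavy-atom distance is <= ``radius``.
    """
    residues = [r for r in structure if r.residue_key in residue_set]
    pos, owner = [], []
    for i, res in enumerate(residues):
        for atom in res.heavy_atoms():
            pos.append(atom.position)
            owner.append(i)
    if len(pos) < 2:
        return []
    pos = np.asarray(pos)
    owner = np.asarray(owner)
    tree = cKDTree(pos)
    contacting: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(radius):
        a, b = owner[i], owner[j]
        if a != b:
            contacting.add((min(a, b), max(a, b)))
    return [pair_key(residues[a].amino_acid, residues[b].amino_acid)
            for a, b in sorted(contacting)]


@dataclass
class GAAPCounts:
    radius: float
    n_plus: dict[Pair, int] = field(default_factory=dict)
    n_minus: dict[Pair, int] = field(default_factory=dict)

    @property
    def total_plus(self) -> int:
        return sum(self.n_plus.values())

    @property
    def total_minus(self) -> int:
        return sum(self.n_minus.values())


def tally_gaap(labeled_antigens: list[tuple[Structure, set[ResidueKey], set[ResidueKey]]],
               radius: float = DEFAULT_PAIR_RADIUS) -> GAAPCounts:
    """Accumulate pair counts over (structure, CE set, surface set) triples.

    Positives: geometric pairs with BOTH residues CE-labeled.  Negatives:
    surface pairs with at least one non-CE residue.  Pair instances are
    counted per occurrence across antigens.
    """
    if not labeled_antigens:
        raise ValueError("empty dataset")
    counts = GAAPCounts(radius=radius)
    for structure, ce_set, surface_set in labeled_antigens:
        if not ce_set <= surface_set:
            raise ValueError("CE set must be a subset of the surface set")
        for res_pair, aa_pair in _surface_pairs(structure, surface_set, radius):
            if res_pair[0] in ce_set and res_pair[1] in ce_set:
                counts.n_plus[aa_pair] = counts.n_plus.get(aa_pair, 0) + 1
            else:
                counts.n_minus[aa_pair] = counts.n_minus.get(aa_pair, 0) + 1
    return counts


def _surface_pairs(structure: Structure, surface_set: set[ResidueKey], radius: float):
    residues = [r for r in structure if r.residue_key in surface_set]
    pos, owner = [], []
    for i, res in enumerate(residues):
        for atom in res.heavy_atoms():
            pos.append(atom.position)
            owner.append(i)
    if len(pos) < 2:
        return
    tree = cKDTree(np.asarray(pos))
    owner = np.asarray(owner)
    contacting: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(radius):
        a, b = owner[i], owner[j]
        if a != b:
            contacting.add((min(a, b), max(a, b)))
    for a, b in sorted(contacting):
        yield ((residues[a].residue_key, residues[b].residue_key),
               pair_key(residues[a].amino_acid, residues[b].amino_acid))


@dataclass
class CEITable:
    radius: float
    pseudocount: float
    f_plus: dict[Pair, float]
    f_minus: dict[Pair, float]
    raw: dict[Pair, float]
    cei: dict[Pair, float]
    normalization: str = "min-max"

    def to_json(self) -> str:
        fmt = lambda d: {f"{a}{b}": v for (a, b), v in d.items()}
        return json.dumps(
            {
                "radius": self.radius,
                "pseudocount": self.pseudocount,
                "normalization": self.normalization,
                "f_plus": fmt(self.f_plus),
                "f_minus": fmt(self.f_minus),
                "raw": fmt(self.raw),
                "cei": fmt(self.cei),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CEITable":
        d = json.loads(text)
        parse = lambda m: {(k[0], k[1]): v for k, v in m.items()}
        return cls(
            radius=d["radius"], pseudocount=d["pseudocount"],
            f_plus=parse(d["f_plus"]), f_minus=parse(d["f_minus"]),
            raw=parse(d["raw"]), cei=parse(d["cei"]),
            normalization=d.get("normalization", "min-max"),
        )


def compute_cei(counts: GAAPCounts,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> CEITable:
    """CE index per pair: min-max-normalized log10 frequency ratio.

    ``f+-(p) = (N+-(p) + c) / (Total+- + 210 c)``; ``raw = log10(f+/f-)``;
    CEI rescales raw onto [0, 1].  A degenerate (constant-raw) table maps
    every pair to 0.5.
    """
    if counts.total_plus <= 0 or counts.total_minus <= 0:
        raise ValueError("degenerate totals: need pairs in both CE and non-CE sets")
    alphabet = enumerate_pair_alphabet()
    denom_plus = counts.total_plus + len(alphabet) * pseudocount
    denom_minus = counts.total_minus + len(alphabet) * pseudocount
    f_plus, f_minus, raw = {}, {}, {}
    for p in alphabet:
        np_, nm = counts.n_plus.get(p, 0), counts.n_minus.get(p, 0)
        if pseudocount == 0 and (np_ == 0 or nm == 0):
            # pairs unseen in either set carry no ratio information
            continue
        fp = (np_ + pseudocount) / denom_plus
        fm = (nm + pseudocount) / denom_minus
        f_plus[p], f_minus[p] = fp, fm
        raw[p] = math.log10(fp / fm)
    values = list(raw.values())
    lo, hi = min(values), max(values)
    if math.isclose(lo, hi):
        cei = {p: 0.5 for p in raw}
    else:
        cei = {p: (v - lo) / (hi - lo) for p, v in raw.items()}
    return CEITable(radius=counts.radius, pseudocount=pseudocount,
                    f_plus=f_plus, f_minus=f_minus, raw=raw, cei=cei)


def cluster_cei(cluster: set[ResidueKey], structure: Structure,
                table: CEITable, radius: float | None = None) -> float:
    """Average CEI over geometric pair instances internal to a candidate cluster."""
    r = table.radius if radius is None else radius
    pairs = extract_geometric_pairs(structure, set(cluster), r)
    if not pairs:
        return 0.0
    return sum(table.cei.get(p, 0.0) for p in pairs) / len(pairs)


def export_cei_table(counts: GAAPCounts, table: CEITable, path) -> None:
    """TSV export: one row per pair with counts, frequencies, raw and CEI."""
    lines = ["aa1\taa2\tN_plus\tN_minus\tf_plus\tf_minus\traw\tcei"]
    for p in enumerate_pair_alphabet():
        if p not in table.cei:
            continue
        lines.append(
            f"{p[0]}\t{p[1]}\t{counts.n_plus.get(p, 0)}\t{counts.n_minus.get(p, 0)}\t"
            f"{table.f_plus[p]:.6g}\t{table.f_minus[p]:.6g}\t"
            f"{table.raw[p]:.6f}\t{table.cei[p]:.6f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
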