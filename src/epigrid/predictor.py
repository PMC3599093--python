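"""Four-stage epitope prediction workflow.

1. Morphological surface extraction and residue surface rates.
2. Knowledge-based energy profile with local averaging.
3. Anchor selection (top-energy, mid-exposure, mutually exclusive) and
   10-A region growing into candidate clusters.
4. Weighted combination of normalized cluster energy and average CE index;
   the top-3 clusters are reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .energy import (
    DEFAULT_CUTOFF,
    DEFAULT_LOCAL_RADIUS,
    ContactPotential,
    EnergyProfile,
    compute_energy_profile,
    rank_by_energy,
)
from .gaap import CEITable, cluster_cei
from .morphology import DEFAULT_B1_RADIUS, DEFAULT_SPACING
from .structure_io import ResidueKey, Structure
from .surface import DEFAULT_MIN_SR, SurfaceTable, compute_surface_table


@dataclass
class PredictorConfig:
    # stage 1: surface
    spacing: float = DEFAULT_SPACING
    b1_radius: float = DEFAULT_B1_RADIUS
    b2_radius: float | None = None
    min_sr: float = DEFAULT_MIN_SR
    # stage 2: energy
    contact_cutoff: float = DEFAULT_CUTOFF
    local_radius: float = DEFAULT_LOCAL_RADIUS
    local_mode: str = "spatial"  # or "window"
    top_energy_fraction: float = 0.2
    # stage 3: anchors and growth
    sr_band: tuple[float, float] = (0.2, 0.5)
    # "percentile": the band is an interval of the surface-SR distribution
    # (the 20th-50th percentile); "value": a literal SR interval.  Percentile
    # is the default because grid surface rates concentrate near 1 for exposed
    # side chains, which empties a literal [0.2, 0.5] band.
    sr_band_mode: str = "percentile"
    anchor_min_separation: float = 12.0
    grow_radius: float = 10.0
    distance_ref: str = "ca"  # or "sidechain_centroid"
    # stage 4: ranking
    energy_weight: float = 0.8
    gaap_weight: float = 0.2
    pair_radius: float | None = None  # default: the CEI table's radius
    top_k: int = 3

    def __post_init__(self):
        if not math.isclose(self.energy_weight + self.gaap_weight, 1.0):
            raise ValueError("energy_weight + gaap_weight must equal 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class EpitopeCluster:
    anchor: ResidueKey
    members: set[ResidueKey]
    energy_score: float = 0.0
    cei_score: float = 0.0
    combined_score: float = 0.0
    rank: int = 0


@dataclass
class PredictionResult:
    clusters: list[EpitopeCluster]
    surface: set[ResidueKey]
    surface_table: SurfaceTable
    profile: EnergyProfile
    anchors: list[ResidueKey]
    config: PredictorConfig
    diagnostics: list[str] = field(default_factory=list)


def _ref_positions(structure: Structure, cfg: PredictorConfig) -> dict[ResidueKey, np.ndarray]:
    out = {}
    for res in structure:
        if cfg.distance_ref == "sidechain_centroid":
            from .structure_io import side_chain_atoms

            atoms = side_chain_atoms(res)
            out[res.residue_key] = np.mean([a.position for a in atoms], axis=0)
        else:
            out[res.residue_key] = res.ca_position()
    return out


def select_anchors(profile: EnergyProfile, table: SurfaceTable,
                   structure: Structure, cfg: PredictorConfig) -> list[ResidueKey]:
    """High-energy, mid-exposure, mutually exclusive anchor residues.

    Candidates are the top ``top_energy_fraction`` of surface residues by
    local-average energy whose SR lies in ``sr_band``; a greedy pass in
    descending energy order keeps a candidate iff it is at least
    ``anchor_min_separation`` from every kept anchor.
    """
    surface = table.surface_residues()
    if not surface:
        return []
    top = rank_by_energy(profile, surface, cfg.top_energy_fraction)
    if cfg.sr_band_mode == "percentile":
        srs = sorted(table.residue_sr[k] for k in surface)
        lo = float(np.quantile(srs, cfg.sr_band[0]))
        hi = float(np.quantile(srs, cfg.sr_band[1]))
    else:
        lo, hi = cfg.sr_band
    candidates = [k for k in top if lo <= table.residue_sr[k] <= hi]
    ref = _ref_positions(structure, cfg)
    anchors: list[ResidueKey] = []
    for k in candidates:  # already in descending-energy order
        if all(np.linalg.norm(ref[k] - ref[a]) >= cfg.anchor_min_separation
               for a in anchors):
            anchors.append(k)
    return anchors


def grow_cluster(anchor: ResidueKey, structure: Structure,
                 surface: set[ResidueKey], cfg: PredictorConfig) -> EpitopeCluster:
    """Single-sphere region growing: surface residues within grow_radius of the anchor."""
    ref = _ref_positions(structure, cfg)
    center = ref[anchor]
    members = {
        k for k in surface
        if np.linalg.norm(ref[k] - center) <= cfg.grow_radius
    }
    members.add(anchor)
    return EpitopeCluster(anchor=anchor, members=members)


def score_clusters(clusters: list[EpitopeCluster], structure: Structure,
                   profile: EnergyProfile, cei_table: CEITable,
                   cfg: PredictorConfig) -> list[EpitopeCluster]:
    """Attach energy, CEI and combined scores to each candidate cluster.

    The cluster energy score is the per-antigen min-max normalization of the
    mean local-average energy over members (a single cluster scores 1.0), so
    it combines with the CEI score on the same [0, 1] scale.
    """
    if not clusters:
        return []
    means = [
        float(np.mean([profile.local_average.get(k, 0.0) for k in c.members]))
        for c in clusters
    ]
    lo, hi = min(means), max(means)
    for c, m in zip(clusters, means):
        c.energy_score = 1.0 if math.isclose(lo, hi) else (m - lo) / (hi - lo)
        c.cei_score = cluster_cei(c.members, structure, cei_table,
                                  radius=cfg.pair_radius)
        c.combined_score = cfg.energy_weight * c.energy_score + cfg.gaap_weight * c.cei_score
    return clusters


def rank_clusters(clusters: list[EpitopeCluster], top_k: int) -> list[EpitopeCluster]:
    ordered = sorted(
        clusters,
        key=lambda c: (-c.combined_score, -c.energy_score, c.anchor[1], c.anchor[2]),
    )[:top_k]
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered


def predict(structure: Structure, potential: ContactPotential,
            cei_table: CEITable, cfg: PredictorConfig | None = None) -> PredictionResult:
    """Run the full four-stage workflow on one antigen chain."""
    cfg = cfg or PredictorConfig()
    table = compute_surface_table(structure, cfg.spacing, cfg.b1_radius,
                                  cfg.b2_radius, cfg.min_sr)
    surface = table.surface_residues()
    diagnostics: list[str] = []
    if not surface:
        return PredictionResult([], surface, table,
                                EnergyProfile({}, {}), [], cfg,
                                ["no surface residues detected"])
    profile = compute_energy_profile(structure, potential, surface,
                                     radius=cfg.local_radius, mode=cfg.local_mode)
    anchors = select_anchors(profile, table, structure, cfg)
    if not anchors:
        diagnostics.append("no anchor candidates survived the SR/energy filters")
    clusters = [grow_cluster(a, structure, surface, cfg) for a in anchors]
    clusters = score_clusters(clusters, structure, profile, cei_table, cfg)
    ranked = rank_clusters(clusters, cfg.top_k)
    return PredictionResult(ranked, surface, table, profile, anchors, cfg, diagnostics)


def prediction_to_json(result: PredictionResult) -> str:
    def key_str(k: ResidueKey) -> str:
        return f"{k[0]}:{k[1]}{k[2]}"

    return json.dumps(
        {
            "config": {k: v for k, v in asdict(result.config).items()},
            "n_surface_residues": len(result.surface),
            "anchors": [key_str(a) for a in result.anchors],
            "clusters": [
                {
                    "rank": c.rank,
                    "anchor": key_str(c.anchor),
                    "members": sorted(key_str(m) for m in c.members),
                    "energy_score": c.energy_score,
                    "cei_score": c.cei_score,
                    "combined_score": c.combined_score,
                }
                for c in result.clusters
            ],
            "diagnostics": result.diagnostics,
        },
        indent=2,
    )
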