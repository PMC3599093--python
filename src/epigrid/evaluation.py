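"""Ground-truth epitope extraction, confusion metrics, and cross-validation.

True conformational epitopes are read off antigen-antibody complexes by
distance: residues in direct antibody contact (tied residues, 4-A heavy-atom
cutoff) expanded by their 4-A neighbors, or, in the looser convention, all
antigen residues within 6 A of the antibody.  Predictions are scored over the
universe of antigen surface residues with SE/SP/PPV/ACC, taking the best of
the top-3 clusters, and the weighted-combination grid is assessed by seeded
10-fold cross-validation in which the CE-index table is retrained on each
training split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .gaap import DEFAULT_PAIR_RADIUS, compute_cei, tally_gaap
from .predictor import (
    EpitopeCluster,
    PredictorConfig,
    grow_cluster,
    rank_clusters,
    score_clusters,
    select_anchors,
)
from .energy import ContactPotential, compute_energy_profile
from .structure_io import ResidueKey, Structure
from .surface import compute_surface_table


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int


@dataclass
class MetricsRecord:
    SE: float
    SP: float
    PPV: float
    ACC: float
    degenerate: bool = False


def true_epitope_residues(antigen: Structure, antibody: Structure,
                          mode: str = "discotope",
                          contact_cutoff: float = 4.0,
                          expand_cutoff: float = 4.0,
                          loose_cutoff: float = 6.0) -> set[ResidueKey]:
    """Ground-truth epitope residues from an antigen-antibody complex.

    ``mode='discotope'``: antigen residues with any heavy atom within 4 A of
    the antibody (tied residues) plus antigen residues within 4 A of a tied
    residue.  ``mode='epitome'``: antigen residues with any heavy atom within
    6 A of the antibody.
    """
    ab_pos = np.array([a.position for a in antibody.heavy_atoms()])
    if len(ab_pos) == 0:
        return set()
    ab_tree = cKDTree(ab_pos)

    res_atoms = {
        r.residue_key: np.array([a.position for a in r.heavy_atoms()])
        for r in antigen
    }

    def residues_near(tree: cKDTree, cutoff: float) -> set[ResidueKey]:
        hits = set()
        for key, pos in res_atoms.items():
            d, _ = tree.query(pos, k=1)
            if np.min(d) <= cutoff:
                hits.add(key)
        return hits

    if mode == "epitome":
        return residues_near(ab_tree, loose_cutoff)
    if mode != "discotope":
        raise ValueError(f"unknown mode {mode!r}")
    tied = residues_near(ab_tree, contact_cutoff)
    if not tied:
        import warnings

        warnings.warn("no antigen-antibody contacts found; empty epitope")
        return set()
    tied_pos = np.concatenate([res_atoms[k] for k in tied])
    tied_tree = cKDTree(tied_pos)
    expanded = residues_near(tied_tree, expand_cutoff)
    return tied | expanded


def confusion(predicted: set[ResidueKey], truth: set[ResidueKey],
              universe: set[ResidueKey]) -> ConfusionCounts:
    """TP/FP/TN/FN over an explicit evaluation universe."""
    if not predicted <= universe or not truth <= universe:
        raise ValueError("predicted and truth sets must lie within the universe")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def metrics(cm: ConfusionCounts) -> MetricsRecord:
    """SE, SP, PPV, ACC from confusion counts; 0/0 ratios map to 0 (flagged)."""
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    se = ratio(cm.TP, cm.TP + cm.FN)
    sp = ratio(cm.TN, cm.TN + cm.FP)
    ppv = ratio(cm.TP, cm.TP + cm.FP)
    acc = ratio(cm.TP + cm.TN, cm.TP + cm.TN + cm.FN + cm.FP)
    return MetricsRecord(SE=se, SP=sp, PPV=ppv, ACC=acc, degenerate=degenerate)


def best_of_top_k(clusters: list[EpitopeCluster], truth: set[ResidueKey],
                  universe: set[ResidueKey], k: int = 3) -> MetricsRecord:
    """Metrics of the best (max SE, ties by ACC) of the first k clusters."""
    if not clusters:
        cm = ConfusionCounts(TP=0, FP=0, TN=len(universe - truth), FN=len(truth))
        return metrics(cm)
    best: MetricsRecord | None = None
    for c in clusters[:k]:
        m = metrics(confusion(c.members & universe, truth, universe))
        if best is None or (m.SE, m.ACC) > (best.SE, best.ACC):
            best = m
    return best


@dataclass
class LabeledAntigen:
    structure: Structure
    ce_residues: set[ResidueKey]


def _clusters_for(antigen: LabeledAntigen, potential: ContactPotential,
                  cei_table, cfg: PredictorConfig):
    """Weight-independent part of a prediction: surface, anchors, scored clusters."""
    table = compute_surface_table(antigen.structure, cfg.spacing, cfg.b1_radius,
                                  cfg.b2_radius, cfg.min_sr)
    surface = table.surface_residues()
    if not surface:
        return [], surface
    profile = compute_energy_profile(antigen.structure, potential, surface,
                                     radius=cfg.local_radius, mode=cfg.local_mode)
    anchors = select_anchors(profile, table, antigen.structure, cfg)
    clusters = [grow_cluster(a, antigen.structure, surface, cfg) for a in anchors]
    clusters = score_clusters(clusters, antigen.structure, profile, cei_table, cfg)
    return clusters, surface


DEFAULT_WEIGHT_GRID = [(round(w, 1), round(1 - w, 1)) for w in np.arange(0.0, 1.01, 0.1)]


def make_folds(n: int, k_folds: int, seed: int) -> list[list[int]]:
    """Seeded random partition of ``range(n)`` into ``k_folds`` balanced folds."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [[int(x) for x in order[i::k_folds]] for i in range(k_folds)]


def cross_validate(dataset: list[LabeledAntigen], potential: ContactPotential,
                   k_folds: int = 10,
                   weight_grid: list[tuple[float, float]] | None = None,
                   seed: int = 17,
                   cfg: PredictorConfig | None = None,
                   pair_radius: float = DEFAULT_PAIR_RADIUS) -> pd.DataFrame:
    """Seeded k-fold cross-validation over the weighted-combination grid.

    The CE-index table is retrained on each 9/10 training split; the contact
    potential is a fixed input (trained on a reference corpus).  Metrics are
    averaged per antigen across all validation folds, one row per weight pair.
    """
    if len(dataset) < k_folds:
        raise ValueError("fewer antigens than folds")
    weight_grid = weight_grid or DEFAULT_WEIGHT_GRID
    base_cfg = cfg or PredictorConfig()
    folds = make_folds(len(dataset), k_folds, seed)

    # surface tables are fold-independent; cache per antigen
    surf_cache = {
        i: compute_surface_table(a.structure, base_cfg.spacing, base_cfg.b1_radius,
                                 base_cfg.b2_radius, base_cfg.min_sr)
        for i, a in enumerate(dataset)
    }

    per_weight: dict[tuple[float, float], list[MetricsRecord]] = {
        w: [] for w in weight_grid
    }
    for fold in folds:
        train_idx = [i for i in range(len(dataset)) if i not in fold]
        labeled = [
            (
                dataset[i].structure,
                dataset[i].ce_residues & surf_cache[i].surface_residues(),
                surf_cache[i].surface_residues(),
            )
            for i in train_idx
        ]
        counts = tally_gaap(labeled, radius=pair_radius)
        cei_table = compute_cei(counts)
        for i in fold:
            antigen = dataset[i]
            clusters, surface = _clusters_for(antigen, potential, cei_table, base_cfg)
            truth = antigen.ce_residues & surface
            for w_eg, w_gaap in weight_grid:
                for c in clusters:
                    c.combined_score = w_eg * c.energy_score + w_gaap * c.cei_score
                ranked = rank_clusters(list(clusters), base_cfg.top_k)
                per_weight[(w_eg, w_gaap)].append(
                    best_of_top_k(ranked, truth, surface, k=base_cfg.top_k)
                )

    rows = []
    for (w_eg, w_gaap), records in per_weight.items():
        rows.append(
            {
                "w_EG": w_eg,
                "w_GAAP": w_gaap,
                "SE": float(np.mean([m.SE for m in records])),
                "SP": float(np.mean([m.SP for m in records])),
                "PPV": float(np.mean([m.PPV for m in records])),
                "ACC": float(np.mean([m.ACC for m in records])),
                "n_antigens": len(records),
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
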