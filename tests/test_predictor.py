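import dataclasses
import json

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from epigrid.energy import EnergyProfile, compute_energy_profile
from epigrid.fixtures import FixtureSpec, make_toy_antigen
from epigrid.predictor import (
    EpitopeCluster,
    PredictorConfig,
    grow_cluster,
    predict,
    prediction_to_json,
    rank_clusters,
    score_clusters,
    select_anchors,
)
from epigrid.surface import compute_surface_table


def _rigid_copy(st, seed=0):
    rot = Rotation.from_euler("xyz", [0.7, -0.4, 1.9]).as_matrix()
    shift = np.array([8.0, -2.0, 5.0])
    moved = []
    for r in st.residues:
        atoms = [dataclasses.replace(a, position=rot @ a.position + shift)
                 for a in r.atoms]
        moved.append(dataclasses.replace(r, atoms=atoms))
    return dataclasses.replace(st, residues=moved)


class TestConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PredictorConfig(energy_weight=0.8, gaap_weight=0.3)

    def test_top_k_positive(self):
        with pytest.raises(ValueError):
            PredictorConfig(top_k=0)

    @pytest.mark.parametrize("w", [0.0, 0.5, 1.0])
    def test_boundary_weights_accepted(self, w):
        cfg = PredictorConfig(energy_weight=w, gaap_weight=1.0 - w)
        assert cfg.energy_weight == w


class TestSelectAnchors:
    def _setup(self, seed=5, n=30):
        st = make_toy_antigen(FixtureSpec(n_residues=n, seed=seed))
        table = compute_surface_table(st)
        surf = table.surface_residues()
        return st, table, surf

    def _profile_from_values(self, keys, values):
        d = dict(zip(keys, values))
        return EnergyProfile(d, dict(d))

    def test_greedy_matches_bruteforce_oracle(self, potential):
        """Re-derive the anchor list with an independent straight-line pass."""
        st, table, surf = self._setup()
        prof = compute_energy_profile(st, potential, surf)
        cfg = PredictorConfig()
        anchors = select_anchors(prof, table, st, cfg)

        # oracle: sort surface by (-local energy, resnum), take top ceil(0.2n),
        # keep SR percentile band, then greedy min-separation
        import math

        ordered = sorted(
            surf,
            key=lambda k: (-prof.local_average[k], -prof.per_residue[k], k[1], k[2]),
        )
        top = ordered[: math.ceil(cfg.top_energy_fraction * len(surf))]
        srs = sorted(table.residue_sr[k] for k in surf)
        lo = float(np.quantile(srs, cfg.sr_band[0]))
        hi = float(np.quantile(srs, cfg.sr_band[1]))
        cands = [k for k in top if lo <= table.residue_sr[k] <= hi]
        cas = {r.residue_key: r.ca_position() for r in st}
        expected = []
        for k in cands:
            if all(np.linalg.norm(cas[k] - cas[a]) >= cfg.anchor_min_separation
                   for a in expected):
                expected.append(k)
        assert anchors == expected

    def test_anchors_mutually_separated(self, potential):
        st, table, surf = self._setup(seed=6, n=40)
        prof = compute_energy_profile(st, potential, surf)
        anchors = select_anchors(prof, table, st, PredictorConfig())
        cas = {r.residue_key: r.ca_position() for r in st}
        for i in range(len(anchors)):
            for j in range(i + 1, len(anchors)):
                assert np.linalg.norm(cas[anchors[i]] - cas[anchors[j]]) >= 12.0

    def test_value_mode_band_filters_literally(self):
        st, table, surf = self._setup()
        keys = sorted(surf)
        prof = self._profile_from_values(keys, range(len(keys)))
        cfg = PredictorConfig(sr_band=(0.0, 1.0), sr_band_mode="value",
                              top_energy_fraction=1.0,
                              anchor_min_separation=0.0)
        # full band + zero separation: every surface residue is an anchor
        anchors = select_anchors(prof, table, st, cfg)
        assert set(anchors) == surf

    def test_empty_band_no_anchors(self):
        st, table, surf = self._setup()
        keys = sorted(surf)
        prof = self._profile_from_values(keys, range(len(keys)))
        cfg = PredictorConfig(sr_band=(2.0, 3.0), sr_band_mode="value")
        assert select_anchors(prof, table, st, cfg) == []


class TestGrowCluster:
    def test_matches_distance_oracle(self, potential):
        st = make_toy_antigen(FixtureSpec(n_residues=30, seed=5))
        table = compute_surface_table(st)
        surf = table.surface_residues()
        cfg = PredictorConfig()
        anchor = sorted(surf)[0]
        cluster = grow_cluster(anchor, st, surf, cfg)
        cas = {r.residue_key: r.ca_position() for r in st}
        expected = {k for k in surf
                    if np.linalg.norm(cas[k] - cas[anchor]) <= cfg.grow_radius}
        expected.add(anchor)
        assert cluster.members == expected
        assert cluster.anchor == anchor

    def test_zero_radius_keeps_only_anchor(self):
        st = make_toy_antigen(FixtureSpec(n_residues=20, seed=2))
        surf = {r.residue_key for r in st}
        anchor = st.residues[0].residue_key
        cfg = PredictorConfig(grow_radius=0.0)
        assert grow_cluster(anchor, st, surf, cfg).members == {anchor}


class TestScoring:
    def _clusters(self, st, anchors, surf, cfg):
        return [grow_cluster(a, st, surf, cfg) for a in anchors]

    def test_minmax_normalization_hand_case(self, toy_antigen, cei_table):
        surf = {r.residue_key for r in toy_antigen}
        keys = sorted(surf)
        # synthetic profile: residue i has energy i
        prof = EnergyProfile(dict(zip(keys, map(float, range(len(keys))))),
                             dict(zip(keys, map(float, range(len(keys))))))
        cfg = PredictorConfig(grow_radius=0.0)
        clusters = self._clusters(toy_antigen, [keys[0], keys[4], keys[8]], surf, cfg)
        scored = score_clusters(clusters, toy_antigen, prof, cei_table, cfg)
        # cluster means are 0, 4, 8 -> normalized 0, 0.5, 1
        assert [c.energy_score for c in scored] == pytest.approx([0.0, 0.5, 1.0])
        for c in scored:
            assert c.combined_score == pytest.approx(
                0.8 * c.energy_score + 0.2 * c.cei_score
            )

    def test_single_cluster_energy_score_is_one(self, toy_antigen, cei_table):
        surf = {r.residue_key for r in toy_antigen}
        keys = sorted(surf)
        prof = EnergyProfile({k: 1.0 for k in keys}, {k: 1.0 for k in keys})
        cfg = PredictorConfig()
        scored = score_clusters(self._clusters(toy_antigen, [keys[0]], surf, cfg),
                                toy_antigen, prof, cei_table, cfg)
        assert scored[0].energy_score == 1.0

    @pytest.mark.parametrize("w_eg", [0.0, 1.0])
    def test_boundary_weight_reduces_to_single_term(self, toy_antigen, cei_table, w_eg):
        surf = {r.residue_key for r in toy_antigen}
        keys = sorted(surf)
        prof = EnergyProfile(dict(zip(keys, map(float, range(len(keys))))),
                             dict(zip(keys, map(float, range(len(keys))))))
        cfg = PredictorConfig(energy_weight=w_eg, gaap_weight=1.0 - w_eg)
        scored = score_clusters(self._clusters(toy_antigen, keys[:3], surf, cfg),
                                toy_antigen, prof, cei_table, cfg)
        for c in scored:
            expected = c.energy_score if w_eg == 1.0 else c.cei_score
            assert c.combined_score == pytest.approx(expected)

    def test_empty_input(self, toy_antigen, cei_table):
        assert score_clusters([], toy_antigen, EnergyProfile({}, {}), cei_table,
                              PredictorConfig()) == []


class TestRankClusters:
    def _c(self, combined, energy, resnum):
        return EpitopeCluster(anchor=("A", resnum, ""), members=set(),
                              energy_score=energy, combined_score=combined)

    def test_orders_by_combined_then_energy_then_resnum(self):
        cs = [self._c(0.5, 0.2, 3), self._c(0.9, 0.1, 2),
              self._c(0.5, 0.8, 1), self._c(0.5, 0.8, 4)]
        ranked = rank_clusters(cs, top_k=4)
        assert [c.anchor[1] for c in ranked] == [2, 1, 4, 3]
        assert [c.rank for c in ranked] == [1, 2, 3, 4]

    def test_truncates_to_top_k(self):
        cs = [self._c(v, v, i + 1) for i, v in enumerate([0.1, 0.9, 0.5, 0.7])]
        ranked = rank_clusters(cs, top_k=3)
        assert len(ranked) == 3
        assert ranked[0].combined_score == 0.9


class TestPredict:
    def test_end_to_end_invariants(self, potential, cei_table):
        st = make_toy_antigen(FixtureSpec(n_residues=40, seed=13))
        result = predict(st, potential, cei_table)
        assert len(result.clusters) <= 3
        for c in result.clusters:
            assert c.members <= result.surface
            assert c.anchor in c.members
            assert 0.0 <= c.energy_score <= 1.0
            assert 0.0 <= c.cei_score <= 1.0
            assert 0.0 <= c.combined_score <= 1.0
        assert [c.rank for c in result.clusters] == list(
            range(1, len(result.clusters) + 1)
        )

    def test_deterministic(self, potential, cei_table):
        st = make_toy_antigen(FixtureSpec(n_residues=35, seed=21))
        r1 = predict(st, potential, cei_table)
        r2 = predict(st, potential, cei_table)
        assert prediction_to_json(r1) == prediction_to_json(r2)

    def test_invariant_under_lattice_translation(self, potential, cei_table):
        """Shifting the antigen by a voxel-lattice multiple leaves the whole
        prediction unchanged (the grid origin snaps to the same lattice)."""
        st = make_toy_antigen(FixtureSpec(n_residues=35, seed=17))
        shift = np.array([7.0, -13.0, 4.0])  # integer multiples of 1 A spacing
        moved = []
        for r in st.residues:
            atoms = [dataclasses.replace(a, position=a.position + shift)
                     for a in r.atoms]
            moved.append(dataclasses.replace(r, atoms=atoms))
        st2 = dataclasses.replace(st, residues=moved)
        r1 = predict(st, potential, cei_table)
        r2 = predict(st2, potential, cei_table)
        assert r1.anchors == r2.anchors
        assert [c.anchor for c in r1.clusters] == [c.anchor for c in r2.clusters]
        assert [c.members for c in r1.clusters] == [c.members for c in r2.clusters]
        for c1, c2 in zip(r1.clusters, r2.clusters):
            assert c1.combined_score == pytest.approx(c2.combined_score, abs=1e-9)

    def test_grid_free_stages_invariant_under_rotation(self, potential, cei_table):
        """Given the same surface labels, anchor selection, growth and scoring
        depend only on pairwise distances, so an arbitrary rigid motion leaves
        them unchanged (the grid-based SR stage is only approximately
        rotation invariant and is held fixed here)."""
        st = make_toy_antigen(FixtureSpec(n_residues=35, seed=17))
        st2 = _rigid_copy(st)
        table = compute_surface_table(st)
        surf = table.surface_residues()
        prof1 = compute_energy_profile(st, potential, surf)
        prof2 = compute_energy_profile(st2, potential, surf)
        cfg = PredictorConfig()
        a1 = select_anchors(prof1, table, st, cfg)
        a2 = select_anchors(prof2, table, st2, cfg)
        assert a1 == a2
        c1 = score_clusters([grow_cluster(a, st, surf, cfg) for a in a1],
                            st, prof1, cei_table, cfg)
        c2 = score_clusters([grow_cluster(a, st2, surf, cfg) for a in a2],
                            st2, prof2, cei_table, cfg)
        for x, y in zip(c1, c2):
            assert x.members == y.members
            assert x.combined_score == pytest.approx(y.combined_score, abs=1e-9)

    def test_json_output_parses(self, potential, cei_table):
        st = make_toy_antigen(FixtureSpec(n_residues=30, seed=3))
        result = predict(st, potential, cei_table)
        doc = json.loads(prediction_to_json(result))
        assert doc["n_surface_residues"] == len(result.surface)
        assert len(doc["clusters"]) == len(result.clusters)
        assert doc["config"]["energy_weight"] == 0.8
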