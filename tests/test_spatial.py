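"""Spatial QC, vessel distances, PVN membership, neighborhoods, and nearest
phenotype distances — all checked against brute-force geometry."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from braintil import spatial
from braintil.spatial import SpatialScene


def make_scene(cells, vessels=None, window=(0, 0, 100, 100)):
    cells = pd.DataFrame(cells, columns=["x", "y", "diameter", "probability",
                                         "phenotype"])
    if vessels is None:
        vessels = pd.DataFrame({"cx": [50.0], "cy": [50.0], "r": [5.0]})
    return SpatialScene(cells, vessels, window)


def random_scene(rng, n=120, n_vessels=5, window=(0, 0, 200, 200)):
    phen = rng.choice(spatial.PHENOTYPES, size=n)
    cells = pd.DataFrame({
        "x": rng.uniform(window[0], window[2], n),
        "y": rng.uniform(window[1], window[3], n),
        "diameter": rng.uniform(5, 12, n),
        "probability": rng.uniform(0.7, 1.0, n),
        "phenotype": phen,
    })
    vessels = pd.DataFrame({
        "cx": rng.uniform(20, 180, n_vessels),
        "cy": rng.uniform(20, 180, n_vessels),
        "r": rng.uniform(3, 15, n_vessels),
    })
    return SpatialScene(cells, vessels, window)


class TestQc:
    @pytest.mark.parametrize("d,p,kept", [
        (13.0, 0.9, False),   # too large
        (12.5, 0.9, False),   # strict <
        (4.0, 0.9, False),    # strict >
        (8.0, 0.65, False),   # probability strict >
        (8.0, 0.9, True),
    ])
    def test_cell_filters(self, d, p, kept):
        scene = make_scene([(10, 10, d, p, "pTRT")])
        out = spatial.qc_cells_spatial(scene)
        assert (len(out.cells) == 1) is kept

    def test_scene_filter_boundary(self):
        rows29 = [(float(i), 1.0, 8.0, 0.9, "nonPTRT_CD8") for i in range(29)]
        assert not spatial.qc_scene(make_scene(rows29))
        rows30 = rows29 + [(50.0, 2.0, 8.0, 0.9, "pTRT")]
        assert spatial.qc_scene(make_scene(rows30))
        assert not spatial.qc_scene(make_scene([]))


class TestVesselDistance:
    def test_geometry(self):
        vessels = pd.DataFrame({"cx": [0.0], "cy": [0.0], "r": [5.0]})
        d = spatial.vessel_distance(np.array([[0.0, 18.0], [1.0, 1.0]]), vessels)
        assert np.isclose(d[0], 13.0)
        assert d[1] == 0.0  # inside the disc

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(100, 2))
        vessels = pd.DataFrame({"cx": rng.uniform(0, 100, 10),
                                "cy": rng.uniform(0, 100, 10),
                                "r": rng.uniform(1, 10, 10)})
        d = spatial.vessel_distance(pts, vessels)
        for i, (x, y) in enumerate(pts):
            best = min(
                max(0.0, np.hypot(x - vx, y - vy) - vr)
                for vx, vy, vr in vessels.itertuples(index=False)
            )
            assert np.isclose(d[i], best, rtol=1e-9)

    def test_no_vessels_raises(self):
        with pytest.raises(ValueError):
            spatial.vessel_distance(np.array([[0, 0]]),
                                    pd.DataFrame(columns=["cx", "cy", "r"]))


class TestPvnMembership:
    def test_boundaries(self):
        vessels = pd.DataFrame({"cx": [0.0], "cy": [0.0], "r": [5.0]})
        pts = np.array([[0, 18.0], [0, 25.0], [0, 20.0]])  # distances 13, 20, 15
        inside = spatial.pvn_membership(pts, vessels)
        assert inside.tolist() == [True, False, True]  # boundary inclusive


class TestNeighborhood:
    def test_counting(self):
        cells = [
            (50, 50, 8, 0.9, "pTRT"),
            (55, 50, 8, 0.9, "nonimmune"),
            (50, 58, 8, 0.9, "nonimmune"),
            (45, 45, 8, 0.9, "MG"),
            (90, 90, 8, 0.9, "MDM"),  # out of range
        ]
        res = spatial.neighborhood_composition(make_scene(cells))
        assert np.isclose(res.composition["nonimmune"], 2 / 3)
        assert np.isclose(res.composition["MG"], 1 / 3)

    def test_isolated_index_cell(self):
        cells = [(10, 10, 8, 0.9, "pTRT"), (90, 90, 8, 0.9, "MG")]
        res = spatial.neighborhood_composition(make_scene(cells))
        assert res.per_cell.iloc[0].sum() == 0
        assert res.composition.sum() == 0

    def test_no_index_cells_flagged(self):
        res = spatial.neighborhood_composition(
            make_scene([(10, 10, 8, 0.9, "MG")]))
        assert res.flagged_empty

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        scene = random_scene(rng)
        res = spatial.neighborhood_composition(scene, radius=20)
        cells = scene.cells.reset_index(drop=True)
        pts = cells[["x", "y"]].to_numpy()
        for i in res.per_cell.index:
            for ph in spatial.PHENOTYPES:
                expected = sum(
                    1 for j in range(len(cells))
                    if j != i and cells.loc[j, "phenotype"] == ph
                    and np.hypot(*(pts[j] - pts[i])) <= 20
                )
                assert res.per_cell.loc[i, ph] == expected


class TestFractionWithNeighbor:
    def test_counting(self):
        cells = [
            (10, 10, 8, 0.9, "nonPTRT_CD8"),  # MG at 15 um -> has neighbor
            (10, 25, 8, 0.9, "MG"),
            (80, 80, 8, 0.9, "pTRT"),         # nearest TAM ~91 um away
        ]
        frac = spatial.fraction_with_neighbor(make_scene(cells), radius=20.0)
        assert np.isclose(frac, 0.5)

    def test_no_targets(self):
        cells = [(10, 10, 8, 0.9, "pTRT")]
        assert spatial.fraction_with_neighbor(make_scene(cells)) == 0.0


class TestNearestPhenotype:
    def test_triangle(self):
        cells = [(0, 0, 8, 0.9, "pTRT"), (3, 4, 8, 0.9, "MG"), (10, 0, 8, 0.9, "MG")]
        out = spatial.nearest_phenotype_distance(make_scene(cells))
        assert np.isclose(out["distance"].iloc[0], 5.0)

    def test_coincident_cells(self):
        cells = [(5, 5, 8, 0.9, "nonPTRT_CD8"), (5, 5, 8, 0.9, "MG")]
        out = spatial.nearest_phenotype_distance(make_scene(cells))
        assert out["distance"].iloc[0] == 0.0

    def test_no_targets_flagged(self):
        out = spatial.nearest_phenotype_distance(
            make_scene([(5, 5, 8, 0.9, "pTRT")]))
        assert out.attrs["no_targets"]
        assert out["distance"].isna().all()

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        scene = random_scene(rng)
        out = spatial.nearest_phenotype_distance(scene, to_phenotypes=("MG", "MDM"))
        cells = scene.cells.reset_index(drop=True)
        tgt = cells[cells["phenotype"].isin(["MG", "MDM"])]
        for i, row in out.iterrows():
            expected = min(np.hypot(cells.loc[i, "x"] - t.x, cells.loc[i, "y"] - t.y)
                           for t in tgt.itertuples())
            assert np.isclose(row["distance"], expected, rtol=1e-9)


class TestInvariance:
    def test_translation_rotation(self):
        rng = np.random.default_rng(3)
        scene = random_scene(rng, n=60)
        d0 = spatial.vessel_distance(scene.cells[["x", "y"]].to_numpy(), scene.vessels)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        pts = scene.cells[["x", "y"]].to_numpy() @ R.T + [1000.0, -300.0]
        vc = scene.vessels[["cx", "cy"]].to_numpy() @ R.T + [1000.0, -300.0]
        vessels = pd.DataFrame({"cx": vc[:, 0], "cy": vc[:, 1],
                                "r": scene.vessels["r"]})
        d1 = spatial.vessel_distance(pts, vessels)
        assert np.allclose(d0, d1, atol=1e-9)


def test_pvn_enrichment_detectable_across_seeds():
    """Planted PVN enrichment raises the within-PVN pTRT fraction above a
    matched pvn_enrichment=1 control in >=95% of 20 seeds."""
    from conftest import small_config
    from braintil import simulate_cohort

    wins = 0
    for seed in range(20):
        def pooled_fraction(enr):
            cohort = simulate_cohort(small_config(
                n_patients=4, n_spatial_cells=1500, pvn_enrichment=enr,
                seed=seed))
            tot_in = tot = 0
            for scene in cohort.scenes:
                cells = scene.cells[scene.cells["phenotype"] == "pTRT"]
                if len(cells) == 0:
                    continue
                inside = spatial.pvn_membership(
                    cells[["x", "y"]].to_numpy(), scene.vessels)
                tot_in += inside.sum()
                tot += len(cells)
            return tot_in / tot
        if pooled_fraction(3.0) > pooled_fraction(1.0):
            wins += 1
    assert wins >= 19  # >= 95% of 20 seeds
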