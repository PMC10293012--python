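"""Spatial analysis of segmented multiplexed-IF cell tables.

A scene is one tissue section: segmented cells (centroid coordinates in um,
diameter, detection probability, phenotype call) plus the vasculature as a
union of discs. The perivascular niche (PVN) is the closed 15-um buffer
around vessel boundaries. Distances are centroid-based Euclidean; all
pairwise operations are exact (KD-tree accelerated where it matters, but
always equal to the brute-force pairwise answer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

PHENOTYPES = ("pTRT", "nonPTRT_CD8", "MG", "MDM", "other_immune", "nonimmune")
CD8_PHENOTYPES = ("pTRT", "nonPTRT_CD8")


@dataclass
class SpatialScene:
    """Segmented cells and vessel discs for one tissue section."""

    cells: pd.DataFrame  # x, y, diameter, probability, phenotype
    vessels: pd.DataFrame  # cx, cy, r
    window: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    scene_id: str = "scene"

    def __post_init__(self) -> None:
        if not self.vessels.empty and (self.vessels["r"] <= 0).any():
            raise ValueError("vessel radii must be positive")
        bad = ~self.cells["phenotype"].isin(PHENOTYPES)
        if bad.any():
            raise ValueError(
                f"unknown phenotypes: {sorted(self.cells.loc[bad, 'phenotype'].unique())}"
            )
        x0, y0, x1, y1 = self.window
        inside = (
            self.cells["x"].between(x0, x1) & self.cells["y"].between(y0, y1)
        )
        if not inside.all():
            raise ValueError("cells outside the window")


def qc_cells_spatial(
    scene: SpatialScene,
    d_min: float = 4.0,
    d_max: float = 12.5,
    p_min: float = 0.65,
) -> SpatialScene:
    """Keep cells with d_min < diameter < d_max and probability > p_min
    (all strict inequalities)."""
    c = scene.cells
    keep = (c["diameter"] > d_min) & (c["diameter"] < d_max) & (c["probability"] > p_min)
    return SpatialScene(c.loc[keep].copy(), scene.vessels, scene.window, scene.scene_id)


def qc_scene(scene: SpatialScene, min_cd8: int = 30) -> bool:
    """True (keep) iff the scene has at least min_cd8 CD8+ cells
    (pTRT + non-pTRT CD8)."""
    n_cd8 = int(scene.cells["phenotype"].isin(CD8_PHENOTYPES).sum())
    return n_cd8 >= min_cd8


def vessel_distance(points: np.ndarray, vessels: pd.DataFrame) -> np.ndarray:
    """Distance from each point to the nearest vessel boundary.

    min over discs of max(0, ||point - center|| - radius); points inside a
    disc are at distance 0. ``points`` is (n, 2).
    """
    if vessels.empty:
        raise ValueError("no vessels in scene")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    centers = vessels[["cx", "cy"]].to_numpy()
    radii = vessels["r"].to_numpy()
    d = np.sqrt(((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)) - radii[None, :]
    return np.maximum(d, 0.0).min(axis=1)


def pvn_membership(
    points: np.ndarray, vessels: pd.DataFrame, pvn_radius: float = 15.0
) -> np.ndarray:
    """True where the nearest vessel boundary is within pvn_radius
    (boundary inclusive: the PVN is the closed buffer)."""
    return vessel_distance(points, vessels) <= pvn_radius


def scene_pvn_summary(scene: SpatialScene, pvn_radius: float = 15.0) -> pd.DataFrame:
    """Per-phenotype counts inside/outside the PVN plus within-PVN fraction."""
    pts = scene.cells[["x", "y"]].to_numpy()
    inside = pvn_membership(pts, scene.vessels, pvn_radius)
    out = (
        scene.cells.assign(in_pvn=inside)
        .groupby("phenotype", observed=True)["in_pvn"]
        .agg(n_cells="size", n_in_pvn="sum")
    )
    out["pvn_fraction"] = out["n_in_pvn"] / out["n_cells"]
    return out


def pvn_area_fraction(
    scene: SpatialScene, pvn_radius: float = 15.0, resolution: int = 600
) -> float:
    """PVN share of the window area, by dense grid evaluation."""
    x0, y0, x1, y1 = scene.window
    xs = np.linspace(x0, x1, resolution)
    ys = np.linspace(y0, y1, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return float(pvn_membership(pts, scene.vessels, pvn_radius).mean())


@dataclass
class NeighborhoodResult:
    per_cell: pd.DataFrame  # index cell id -> neighbor counts per phenotype
    composition: pd.Series  # pooled phenotype fractions over all neighbors
    n_index_cells: int = 0
    flagged_empty: bool = field(default=False)


def neighborhood_composition(
    scene: SpatialScene, index_phenotype: str = "pTRT", radius: float = 20.0
) -> NeighborhoodResult:
    """Phenotype composition within ``radius`` um of each index cell.

    Center-to-center distances, the index cell itself excluded. The scene
    summary pools neighbor counts over all index cells; index cells with no
    neighbors contribute nothing to the pooled fractions.
    """
    cells = scene.cells.reset_index(drop=True)
    idx = cells.index[cells["phenotype"] == index_phenotype]
    if len(idx) == 0:
        empty = pd.DataFrame(columns=list(PHENOTYPES))
        return NeighborhoodResult(empty, pd.Series(dtype=float), 0, True)
    pts = cells[["x", "y"]].to_numpy()
    tree = cKDTree(pts)
    rows = []
    for i in idx:
        nb = [j for j in tree.query_ball_point(pts[i], radius) if j != i]
        counts = cells.loc[nb, "phenotype"].value_counts()
        rows.append(counts.reindex(PHENOTYPES, fill_value=0))
    per_cell = pd.DataFrame(rows, index=idx)
    pooled = per_cell.sum(axis=0)
    total = pooled.sum()
    comp = pooled / total if total > 0 else pooled.astype(float)
    return NeighborhoodResult(per_cell, comp, len(idx), False)


def fraction_with_neighbor(
    scene: SpatialScene,
    source_phenotypes=CD8_PHENOTYPES,
    target_phenotypes=("MG", "MDM"),
    radius: float = 20.0,
) -> float:
    """Fraction of source cells with at least one target cell within
    ``radius`` (the reverse neighborhood query, e.g. CD8 cells near a TAM)."""
    cells = scene.cells.reset_index(drop=True)
    src = cells.index[cells["phenotype"].isin(source_phenotypes)]
    tgt = cells.index[cells["phenotype"].isin(target_phenotypes)]
    if len(src) == 0:
        raise ValueError("no source cells")
    if len(tgt) == 0:
        return 0.0
    pts = cells[["x", "y"]].to_numpy()
    tree = cKDTree(pts[tgt])
    d, _ = tree.query(pts[src], k=1)
    return float((d <= radius).mean())


def nearest_phenotype_distance(
    scene: SpatialScene,
    from_phenotypes=CD8_PHENOTYPES,
    to_phenotypes=("MG",),
    stratify_by: str | None = "phenotype",
) -> pd.DataFrame:
    """Per-source-cell distance to the nearest target cell.

    Coincident distinct cells are at distance 0. Returns a table with the
    distance and the source stratum (e.g. pTRT vs non-pTRT CD8); when there
    are no target cells the distances are NaN and the table is flagged via
    an attribute ``attrs['no_targets']``.
    """
    cells = scene.cells.reset_index(drop=True)
    src = cells.index[cells["phenotype"].isin(from_phenotypes)]
    tgt = cells.index[cells["phenotype"].isin(to_phenotypes)]
    out = cells.loc[src, ["phenotype"]].copy()
    if len(tgt) == 0:
        out["distance"] = np.nan
        out.attrs["no_targets"] = True
        return out
    pts = cells[["x", "y"]].to_numpy()
    tree = cKDTree(pts[tgt])
    d, _ = tree.query(pts[src], k=1)
    out["distance"] = d
    out.attrs["no_targets"] = False
    return out
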