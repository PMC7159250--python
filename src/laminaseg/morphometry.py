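"""Thickness, shrinkage correction, masking, geodesic gradients and atlas
comparisons.

Total cortical thickness is the distance between corresponding pial and
white vertices; laminar thicknesses are the distances between adjacent
boundary surfaces, so they sum to the total exactly (the streamline
construction keeps each vertex column collinear). Postmortem geometry is
rescaled for fixation shrinkage before any thickness statistics.
Hierarchy position is quantified as geodesic distance along the cortical
mesh from a primary-area label, and thickness-versus-distance gradients
are summarized with Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .io_formats import Mesh
from .profiles import smooth_scalar_on_mesh, vertex_adjacency
from .reconstruction import SurfaceSet

LAYER_NAMES = ("I", "II", "III", "IV", "V", "VI")


class AnalysisError(ValueError):
    pass


@dataclass
class ShrinkageFactors:
    """Fixation shrinkage of the histological volume.

    volume_factor is the fresh-to-processed volume ratio (default 1.931);
    axis_factors are the linear x/y/z scales from affine registration to an
    age-matched MRI template (defaults 1.15, 1.22, 1.43). The isotropic
    linear factor is the cube root of the volume factor.
    """

    volume_factor: float = 1.931
    axis_factors: tuple[float, float, float] = (1.15, 1.22, 1.43)

    @property
    def isotropic_linear(self) -> float:
        return linear_factor_from_volume(self.volume_factor)


@dataclass
class ThicknessMap:
    total: np.ndarray    # (n,) mm
    laminar: np.ndarray  # (n, 6) mm, layers I..VI
    mask: np.ndarray     # (n,) bool, True = included

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=float)
        self.laminar = np.asarray(self.laminar, dtype=float)
        if self.mask is None:
            self.mask = np.ones(len(self.total), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class GradientResult:
    system: str
    r: float
    p: float
    n: int
    per_layer_r: np.ndarray  # (6,)
    per_layer_p: np.ndarray
    sliding_window: pd.DataFrame | None = None


def linear_factor_from_volume(volume_factor: float) -> float:
    """Isotropic 1D scale corresponding to a 3D volume shrinkage factor."""
    if volume_factor <= 0:
        raise AnalysisError("volume factor must be positive")
    return float(volume_factor ** (1.0 / 3.0))


def apply_shrinkage(geometry, factors: ShrinkageFactors,
                    mode: str = "per_axis"):
    """Scale mesh coordinates to compensate fixation shrinkage.

    ``mode='isotropic'`` multiplies all coordinates by the cube root of the
    volume factor; ``'per_axis'`` applies the x/y/z linear factors.
    Accepts a Mesh or a SurfaceSet.
    """
    if mode == "isotropic":
        scale = np.full(3, factors.isotropic_linear)
    elif mode == "per_axis":
        scale = np.asarray(factors.axis_factors, dtype=float)
    else:
        raise AnalysisError(f"unknown shrinkage mode {mode!r}")
    if isinstance(geometry, SurfaceSet):
        return SurfaceSet([Mesh(s.vertices * scale, s.triangles,
                                dict(s.per_vertex_scalars))
                           for s in geometry.surfaces])
    return Mesh(geometry.vertices * scale, geometry.triangles,
                dict(geometry.per_vertex_scalars))


# ---------------------------------------------------------------------------
# thickness


def thickness(ss: SurfaceSet) -> ThicknessMap:
    """Per-vertex total and laminar thickness from a nested SurfaceSet."""
    surfs = ss.surfaces
    total = np.linalg.norm(surfs[-1].vertices - surfs[0].vertices, axis=1)
    laminar = np.column_stack([
        np.linalg.norm(surfs[i + 1].vertices - surfs[i].vertices, axis=1)
        for i in range(len(surfs) - 1)])
    # crossing surfaces would show up as laminar sums exceeding the total
    if np.any(laminar.sum(axis=1) > total * (1 + 1e-6) + 1e-9):
        raise AnalysisError("surfaces cross: laminar thicknesses exceed total")
    return ThicknessMap(total, laminar, np.ones(len(total), dtype=bool))


def mask_vertices(tm: ThicknessMap, *label_masks: np.ndarray) -> ThicknessMap:
    """Exclude flagged vertices (True in any mask) from downstream stats."""
    mask = tm.mask.copy()
    for lm in label_masks:
        mask &= ~np.asarray(lm, dtype=bool)
    if not mask.any():
        raise AnalysisError("mask excludes every vertex")
    return ThicknessMap(tm.total.copy(), tm.laminar.copy(), mask)


# ---------------------------------------------------------------------------
# geodesic distance


def geodesic_distance(mesh: Mesh, source_label: np.ndarray) -> np.ndarray:
    """Multi-source Dijkstra distance (mm) along mesh edges; 0 inside the
    source label; inf for vertices disconnected from it."""
    source_label = np.asarray(source_label, dtype=bool)
    if not source_label.any():
        raise AnalysisError("empty source label")
    adj = vertex_adjacency(mesh).tolil()
    n = mesh.n_vertices
    # virtual source node connected by zero-weight edges to the label set
    big = sparse.lil_matrix((n + 1, n + 1))
    big[:n, :n] = adj
    src = np.nonzero(source_label)[0]
    # scipy dijkstra ignores explicit zeros; use a negligible epsilon
    big[n, src] = 1e-12
    dist = _dijkstra(big.tocsr(), directed=False, indices=n)
    d = dist[:n]
    d[source_label] = 0.0
    return d


def gradient_analysis(tm: ThicknessMap, distances: np.ndarray,
                      system_region: np.ndarray, system: str = "",
                      window_mm: float | None = None,
                      step_mm: float = 5.0) -> GradientResult:
    """Pearson correlation of (laminar) thickness with geodesic distance
    over the unmasked vertices of one system's region."""
    region = np.asarray(system_region, dtype=bool) & tm.mask
    region &= np.isfinite(distances)
    n = int(region.sum())
    if n < 10:
        raise AnalysisError(f"only {n} unmasked vertices in region")
    d = distances[region]
    if np.ptp(d) < 1e-12 or np.ptp(tm.total[region]) < 1e-12:
        raise AnalysisError("zero variance: correlation undefined")
    r, p = stats.pearsonr(d, tm.total[region])
    layer_r = np.empty(6)
    layer_p = np.empty(6)
    for i in range(6):
        vals = tm.laminar[region, i]
        if np.ptp(vals) < 1e-12:
            layer_r[i], layer_p[i] = np.nan, np.nan
        else:
            layer_r[i], layer_p[i] = stats.pearsonr(d, vals)
    sw = None
    if window_mm is not None:
        sw = sliding_window_laminar(tm, distances, window_mm, step_mm,
                                    region=region)
    return GradientResult(system, float(r), float(p), n, layer_r, layer_p, sw)


def sliding_window_laminar(tm: ThicknessMap, distances: np.ndarray,
                           window_mm: float, step_mm: float,
                           region: np.ndarray | None = None) -> pd.DataFrame:
    """Mean laminar (and total) thickness in sliding geodesic-distance
    windows [d, d + window). Empty windows are omitted."""
    if window_mm <= 0:
        raise AnalysisError("window_mm must be positive")
    sel = tm.mask & np.isfinite(distances)
    if region is not None:
        sel &= region
    d = distances[sel]
    lam = tm.laminar[sel]
    tot = tm.total[sel]
    rows = []
    start = 0.0
    while start < d.max() + 1e-9:
        inwin = (d >= start) & (d < start + window_mm)
        if inwin.any():
            row = {"distance_mm": start, "n": int(inwin.sum()),
                   "total": float(tot[inwin].mean())}
            for i, name in enumerate(LAYER_NAMES):
                row[f"layer_{name}"] = float(lam[inwin, i].mean())
            rows.append(row)
        start += step_mm
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# atlas tables


def weighted_pearson(x: np.ndarray, y: np.ndarray,
                     w: np.ndarray | None = None) -> float:
    """Area-weighted Pearson correlation via weighted moments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise AnalysisError("weights must be positive")
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum() / wsum
    vx = (w * (x - mx) ** 2).sum() / wsum
    vy = (w * (y - my) ** 2).sum() / wsum
    if vx <= 0 or vy <= 0:
        raise AnalysisError("zero variance: correlation undefined")
    return float(cov / np.sqrt(vx * vy))


def weighted_atlas_correlation(table: pd.DataFrame, source_a: str,
                               source_b: str, weight_col: str | None = None,
                               ) -> tuple[float, int]:
    """Correlation of two regional thickness columns, optionally weighted
    by regional surface area. Rows with missing values are dropped;
    returns (r, rows used)."""
    cols = [source_a, source_b] + ([weight_col] if weight_col else [])
    sub = table[cols].dropna()
    n = len(sub)
    if n < 3:
        raise AnalysisError("need at least 3 regions with both sources")
    w = sub[weight_col].to_numpy() if weight_col else None
    return weighted_pearson(sub[source_a].to_numpy(),
                            sub[source_b].to_numpy(), w), n


def surface_smooth_scalar(values: np.ndarray, mesh: Mesh,
                          fwhm_mm: float = 3.0,
                          mask: np.ndarray | None = None) -> np.ndarray:
    """Gaussian smoothing of a per-vertex scalar along the surface;
    masked vertices are excluded from kernel normalization."""
    return smooth_scalar_on_mesh(values, mesh, fwhm_mm, mask=mask)
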