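"""Synthetic laminar histology: labeled profiles and folded cortical phantoms.

The generator emulates the statistical structure of cell-body-stained
cortical profiles: eight depth classes (0 = supra-pial background/CSF,
1–6 = cortical layers I–VI, 7 = white matter) laid out with realistic
relative extents, per-layer staining contrast, within-layer texture noise,
a rostrocaudal (posterior→anterior) mean-intensity drift, per-profile
boundary jitter, a V1-like variant with an enlarged sublaminated layer IV,
and a small fraction of corrupted (failed) profiles. Every output carries
its ground truth, so the downstream classifier, surface reconstruction and
morphometry can be validated end to end without real histology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io_formats import GeometryError, Mesh, Volume3D
from .profiles import N_POINTS, IntensityProfile

# Mean class proportions of manually annotated cortical profiles
# (background/CSF, I, II, III, IV, V, VI, white matter).
DEFAULT_FRACTIONS = (0.146, 0.075, 0.056, 0.208, 0.055, 0.148, 0.178, 0.134)

# Staining darkness per class, arbitrary units in [0, 1]. Cell-dense layers
# (II, IV) are dark; layer I and white matter are pale; CSF nearly empty.
DEFAULT_INTENSITIES = (0.05, 0.25, 0.85, 0.50, 0.90, 0.55, 0.70, 0.20)

CLASS_NAMES = ("csf", "layer1", "layer2", "layer3", "layer4", "layer5",
               "layer6", "white")


class SpecError(ValueError):
    pass


@dataclass
class LayerSpec:
    """One depth class of the generative model."""

    class_id: int
    fraction: float
    mean_intensity: float
    texture_sd: float = 0.05
    # (relative offset in the layer, amplitude) Gaussian intensity bumps
    sublayer_pattern: list[tuple[float, float]] = field(default_factory=list)


def _default_layers(texture_sd: float = 0.05) -> list[LayerSpec]:
    return [LayerSpec(i, DEFAULT_FRACTIONS[i], DEFAULT_INTENSITIES[i], texture_sd)
            for i in range(8)]


def _v1_layers(texture_sd: float = 0.05) -> list[LayerSpec]:
    """V1-like variant: layer IV tripled and sublaminated (IVa/IVb/IVc),
    layer III thinned by the same amount."""
    layers = _default_layers(texture_sd)
    extra = DEFAULT_FRACTIONS[4] * 2.0
    layers[4] = replace(layers[4], fraction=DEFAULT_FRACTIONS[4] * 3.0,
                        sublayer_pattern=[(0.3, -0.35), (0.7, -0.35)])
    layers[3] = replace(layers[3], fraction=DEFAULT_FRACTIONS[3] - extra)
    return layers


@dataclass
class SyntheticCortexSpec:
    """Generative parameters; doubles as the ground truth description.

    staining_slope is the change in mean intensity per mm along the
    posterior→anterior (y) axis. boundary_jitter_sd is a per-profile
    Gaussian shift (mm) of each layer boundary, truncated to preserve
    ordering. extension_range_mm is the interval from which the padding
    beyond pial and white is drawn when extensions are randomized.
    """

    layer_specs: list[LayerSpec] = field(default_factory=_default_layers)
    area_variants: dict[str, list[LayerSpec]] = field(
        default_factory=lambda: {"V1": _v1_layers()})
    staining_slope: float = 0.0
    boundary_jitter_sd: float = 0.0
    extension_range_mm: tuple[float, float] = (0.25, 0.75)
    fail_rate: float = 0.005
    thickness_mm: float = 2.57
    smooth_sigma_points: float = 2.0
    anchor_extent_mm: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_specs) != 8:
            raise SpecError("need exactly 8 layer specs")
        total = sum(s.fraction for s in self.layer_specs)
        if abs(total - 1.0) > 1e-6:
            raise SpecError(f"class fractions sum to {total}, expected 1")
        if not 0 <= self.fail_rate <= 0.05:
            raise SpecError("fail_rate must be in [0, 0.05]")

    def layers_for(self, area: str) -> list[LayerSpec]:
        if area == "default":
            return self.layer_specs
        if area in self.area_variants:
            return self.area_variants[area]
        raise SpecError(f"unknown area variant: {area!r}")


@dataclass
class LabeledProfileSet:
    """Array-backed collection of labeled profiles.

    raw/smoothed: (n, 200) intensity channels; labels: (n, 200) int classes;
    anchors: (n, 3) world coordinates; spacing_mm: (n,); truth_depths_mm:
    (n, 7) boundary depths from the profile start (pial=0/1 … VI/white);
    failed: (n,) corruption flags.
    """

    raw: np.ndarray
    smoothed: np.ndarray
    labels: np.ndarray
    anchors: np.ndarray
    spacing_mm: np.ndarray
    truth_depths_mm: np.ndarray
    failed: np.ndarray

    def __len__(self) -> int:
        return len(self.raw)

    @property
    def x(self) -> np.ndarray:
        """(n, 2, 200) network input: raw + smoothed channels."""
        return np.stack([self.raw, self.smoothed], axis=1)

    def profile(self, i: int) -> IntensityProfile:
        return IntensityProfile(self.raw[i], self.smoothed[i],
                                float(self.spacing_mm[i]),
                                anchor=self.anchors[i], vertex_id=i)

    def subset(self, idx: np.ndarray) -> "LabeledProfileSet":
        return LabeledProfileSet(
            self.raw[idx], self.smoothed[idx], self.labels[idx],
            self.anchors[idx], self.spacing_mm[idx],
            self.truth_depths_mm[idx], self.failed[idx])


# ---------------------------------------------------------------------------


def _profile_layout(layers: list[LayerSpec], spec: SyntheticCortexSpec,
                    rng: np.random.Generator | None,
                    randomize_extension: bool) -> tuple[np.ndarray, float]:
    """Boundary depths (mm, 7 values) and total profile length (mm).

    By default extensions are proportional to the class fractions, so label
    proportions match them exactly. With randomized extensions, padding on
    each side is drawn from ``extension_range_mm`` (the cortical layers keep
    their relative extents).
    """
    f = np.array([s.fraction for s in layers])
    cortex_frac = 1.0 - f[0] - f[7]
    thick = spec.thickness_mm
    if randomize_extension:
        if rng is None:
            raise SpecError("randomized extensions need an RNG")
        ext_pial, ext_white = rng.uniform(*spec.extension_range_mm, size=2)
    else:
        ext_pial = f[0] / cortex_frac * thick
        ext_white = f[7] / cortex_frac * thick
    total = ext_pial + thick + ext_white
    layer_extents = f[1:7] / cortex_frac * thick
    bounds = ext_pial + np.concatenate([[0.0], np.cumsum(layer_extents)])
    return bounds, total  # 7 boundaries: pial, I/II, ..., VI/white


def generate_profile(spec: SyntheticCortexSpec, area: str = "default",
                     seed: int | None = None,
                     randomize_extension: bool = False,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[IntensityProfile, np.ndarray, np.ndarray]:
    """One labeled 200-point profile.

    Returns ``(profile, labels, boundary_depths_mm)`` where labels is the
    (200,) class sequence and boundary_depths_mm the 7 true boundary depths
    from the profile start.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
    layers = spec.layers_for(area)
    bounds, total = _profile_layout(layers, spec, rng, randomize_extension)
    if spec.boundary_jitter_sd > 0:
        jitter = rng.normal(0.0, spec.boundary_jitter_sd, size=7)
        bounds = np.clip(np.sort(bounds + jitter), 0.0, total)
    depths = np.linspace(0.0, total, N_POINTS)
    labels = np.searchsorted(bounds, depths, side="right").astype(np.int64)
    spacing = total / (N_POINTS - 1)

    means = np.array([s.mean_intensity for s in layers])
    sds = np.array([s.texture_sd for s in layers])
    raw = means[labels] + rng.normal(0.0, 1.0, N_POINTS) * sds[labels]
    # sublaminar intensity bumps (e.g. the pale band inside V1's layer IV)
    edges = np.concatenate([[0.0], bounds, [total]])
    for c, lay in enumerate(layers):
        if not lay.sublayer_pattern:
            continue
        lo, hi = edges[c], edges[c + 1]
        if hi - lo <= 0:
            continue
        u = (depths - lo) / (hi - lo)
        inside = (u >= 0) & (u <= 1) & (labels == c)
        for offset, amp in lay.sublayer_pattern:
            bump = amp * np.exp(-0.5 * ((u - offset) / 0.08) ** 2)
            raw = np.where(inside, raw + bump, raw)

    anchor = rng.uniform(0.0, spec.anchor_extent_mm, size=3)
    raw = raw + spec.staining_slope * (anchor[1] - spec.anchor_extent_mm / 2.0)
    smoothed = ndimage.gaussian_filter1d(raw, spec.smooth_sigma_points)
    prof = IntensityProfile(raw, smoothed, spacing, anchor=anchor)
    return prof, labels, bounds


def generate_training_set(spec: SyntheticCortexSpec, n_profiles: int,
                          seed: int | None = None, area: str = "default",
                          randomize_extension: bool = True,
                          ) -> LabeledProfileSet:
    """A pooled set of labeled profiles with randomized extensions.

    Pooled class proportions converge to the spec fractions (within 1%
    absolute for n ≥ 10,000); the staining slope appears as a linear trend
    of mean profile intensity against the anterior-posterior anchor
    coordinate.
    """
    if n_profiles < 1:
        raise SpecError("n_profiles must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    raw = np.empty((n_profiles, N_POINTS))
    smo = np.empty((n_profiles, N_POINTS))
    labels = np.empty((n_profiles, N_POINTS), dtype=np.int64)
    anchors = np.empty((n_profiles, 3))
    spacing = np.empty(n_profiles)
    truth = np.empty((n_profiles, 7))
    for i in range(n_profiles):
        p, lab, bounds = generate_profile(
            spec, area=area, rng=rng, randomize_extension=randomize_extension)
        raw[i], smo[i], labels[i] = p.raw, p.smoothed, lab
        anchors[i], spacing[i], truth[i] = p.anchor, p.spacing_mm, bounds
    return LabeledProfileSet(raw, smo, labels, anchors, spacing, truth,
                             np.zeros(n_profiles, dtype=bool))


def corrupt_profiles(pset: LabeledProfileSet, fail_rate: float,
                     seed: int = 0, mode: str = "constant") -> LabeledProfileSet:
    """Replace a deterministic count round(fail_rate·n) of profiles with
    corrupted values ('constant' flat traces or 'saturated' noise)."""
    if not 0 <= fail_rate <= 0.05:
        raise SpecError("fail_rate must be in [0, 0.05]")
    n = len(pset)
    k = int(round(fail_rate * n))
    out = LabeledProfileSet(pset.raw.copy(), pset.smoothed.copy(),
                            pset.labels.copy(), pset.anchors.copy(),
                            pset.spacing_mm.copy(), pset.truth_depths_mm.copy(),
                            pset.failed.copy())
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    if mode == "constant":
        vals = rng.uniform(0.0, 1.0, size=k)
        out.raw[idx] = vals[:, None]
        out.smoothed[idx] = vals[:, None]
    elif mode == "saturated":
        out.raw[idx] = rng.choice([0.0, 1.0], size=(k, N_POINTS))
        out.smoothed[idx] = out.raw[idx]
    else:
        raise SpecError(f"unknown corruption mode {mode!r}")
    out.failed[idx] = True
    return out


# ---------------------------------------------------------------------------
# folded cortical phantom


def generate_cortical_sheet(spec: SyntheticCortexSpec,
                            folding_amplitude_mm: float = 0.6,
                            grid_size: int = 64,
                            voxel_size_um: float = 100.0,
                            mesh_resolution: int = 20,
                            curvature_thinning: float = 0.0,
                            thickness_mm: float | None = None,
                            thickness_gradient: float = 0.0,
                            seed: int = 0,
                            ) -> tuple[Volume3D, Mesh, Mesh, Volume3D, np.ndarray]:
    """Voxelized sinusoidally folded laminar slab with paired meshes.

    Returns ``(intensity volume, pial mesh, white mesh, label volume,
    per-vertex truth thickness)``. The pial and white meshes share vertex
    order (1:1 correspondence); layer boundaries follow the spec's relative
    layer extents through the slab. With ``curvature_thinning`` > 0, the
    sheet is thinner where it dips toward the white side (sulcal fundi)
    and thicker on raised crowns. ``thickness_gradient`` (mm per mm)
    imposes a linear thickness trend along x, emulating a hierarchy
    gradient away from a primary area at the x = 0 edge.
    """
    if grid_size < 16:
        raise SpecError("grid_size must be >= 16")
    vox = voxel_size_um / 1000.0
    extent = grid_size * vox
    t0 = spec.thickness_mm if thickness_mm is None else thickness_mm
    a = folding_amplitude_mm
    wavelength = extent / 1.5
    margin = 0.7  # keep extended streamlines inside the volume
    z_mid = extent / 2.0
    t_max = (t0 * (1.0 + abs(curvature_thinning))
             + abs(thickness_gradient) * extent / 2.0)
    if z_mid - t_max / 2.0 - a - margin < 0:
        raise GeometryError(
            f"folding amplitude {a} mm too large for a {t0} mm slab in a "
            f"{extent:.1f} mm volume")
    slope = a * 2.0 * np.pi / wavelength
    if slope > 0.9:
        raise GeometryError("folding amplitude causes near-vertical sheet")

    def height(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return a * np.sin(2 * np.pi * x / wavelength) * np.sin(
            2 * np.pi * y / wavelength)

    def thickness_at(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        t = np.full(np.shape(x), t0, dtype=float)
        if a != 0 and curvature_thinning != 0:
            t = t * (1.0 - curvature_thinning * height(x, y) / a)
        t = t + thickness_gradient * (np.asarray(x) - extent / 2.0)
        if np.any(t <= 0.2):
            raise GeometryError("thickness gradient collapses the sheet")
        return t

    rng = np.random.default_rng(seed)
    layers = spec.layer_specs
    f = np.array([s.fraction for s in layers])
    cortex_frac = 1.0 - f[0] - f[7]
    rel = np.concatenate([[0.0], np.cumsum(f[1:7] / cortex_frac)])  # 0..1

    idx = (np.arange(grid_size) + 0.5) * vox
    xg, yg, zg = np.meshgrid(idx, idx, idx, indexing="ij")
    h = height(xg[:, :, 0], yg[:, :, 0])
    t = thickness_at(xg[:, :, 0], yg[:, :, 0])
    z_pial = (z_mid - t / 2.0 + h)[:, :, None]
    z_white = (z_mid + t / 2.0 + h)[:, :, None]
    depth_rel = (zg - z_pial) / (z_white - z_pial)
    label = np.searchsorted(rel[1:], np.clip(depth_rel, 0, 1),
                            side="right") + 1
    label = np.where(depth_rel < 0, 0, label)
    label = np.where(depth_rel >= 1, 7, label)
    means = np.array([s.mean_intensity for s in layers])
    sds = np.array([s.texture_sd for s in layers])
    intensity = means[label] + rng.normal(0, 1, label.shape) * sds[label]
    intensity += spec.staining_slope * (yg - extent / 2.0)
    vol = Volume3D(intensity, voxel_size_um)
    lab_vol = Volume3D(label.astype(np.int16), voxel_size_um)

    # paired meshes on an inner grid (margin keeps extensions in-volume)
    g = np.linspace(margin, extent - margin, mesh_resolution)
    mx, my = np.meshgrid(g, g, indexing="ij")
    mh = height(mx, my)
    mt = thickness_at(mx, my)
    pial_v = np.column_stack([mx.ravel(), my.ravel(),
                              (z_mid - mt / 2.0 + mh).ravel()])
    white_v = np.column_stack([mx.ravel(), my.ravel(),
                               (z_mid + mt / 2.0 + mh).ravel()])
    tris = []
    for i in range(mesh_resolution - 1):
        for j in range(mesh_resolution - 1):
            v00 = i * mesh_resolution + j
            v01, v10 = v00 + 1, v00 + mesh_resolution
            v11 = v10 + 1
            tris.extend([[v00, v10, v01], [v01, v10, v11]])
    tris = np.asarray(tris, dtype=np.int64)
    return (vol, Mesh(pial_v, tris), Mesh(white_v, tris), lab_vol,
            mt.ravel().copy())
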