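"""Synthetic phantom volumes with ground truth for labelled volume-EM.

Genetically encoded EM labels (miniSOG-driven DAB photo-oxidation followed
by osmium staining) render targeted structures at a distinct intensity range
against textured neuropil. The generators here emulate the two specimen
classes the segmentation procedures were designed for:

* a mitochondria phantom — randomly oriented solid ellipsoids at label
  intensity over textured background, plus sub-cutoff speckle (non-specific
  signal) and thin, high-intensity-variance membrane fragments (the
  structures a variance filter must reject);
* a neurite phantom — a soma plus branching tubular tree rendered at label
  intensity, with optional signal drop-off at branch points and large-calibre
  segments, "crossover" cells sharing the soma cluster, and a trachiole tube
  just below the label range.

All geometry is specified in physical nanometres and rasterised per-axis, so
the ~8x anisotropic SBEM voxels are handled uniformly. Every generator is a
pure function of (spec, parameters, rng seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume import IntensityRange, VolumeGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "ObjectInfo",
    "NeuriteTreeSpec",
    "PlacementError",
    "make_mitochondria_phantom",
    "make_neurite_phantom",
    "add_background_texture",
    "mito_sbem_spec",
    "neurite_sbem_spec",
    "fibsem_spec",
    "separability_report",
]

_MAX_PLACEMENT_ATTEMPTS = 1000


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an object of some class."""


# ---------------------------------------------------------------------------
# Specs and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of a synthetic labelled EM volume.

    Intensities are in working (bit-depth) units. The label distribution is
    a Gaussian truncated at ±2·label_sd, so the closed separating interval
    [label_mean − 2·label_sd, domain max] contains every labelled voxel by
    construction while background (mean + texture + Gaussian noise) stays
    far below it — the default contrast puts the separating bound 9 noise
    standard deviations above the background mean.
    """

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    bit_depth: int = 8
    background_mean: float = 100.0
    background_sd: float = 10.0
    label_mean: float = 200.0
    label_sd: float = 5.0
    membrane_intensity: float = 150.0
    texture_granularity_nm: float = 150.0
    texture_amplitude: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 extents >= 1; got {self.grid_shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive extents (nm); got {self.voxel_size}")
        if abs(self.label_mean - self.background_mean) < 4 * self.background_sd:
            raise ValueError(
                "label_mean must differ from background_mean by >= 4*background_sd "
                f"(got |{self.label_mean} - {self.background_mean}| < {4 * self.background_sd})"
            )

    @property
    def domain_max(self) -> float:
        return float(2**self.bit_depth - 1)

    def separating_range(self) -> IntensityRange:
        """The intensity interval that isolates labelled structures."""
        return IntensityRange(self.label_mean - 2 * self.label_sd, self.domain_max)


def mito_sbem_spec(grid_shape=(256, 256, 256), rng_seed=0, **kw) -> PhantomSpec:
    """Mitochondria-label preset at the binned SBEM working geometry.

    The acquisition voxel was 6.3 × 6.3 × 50 nm; segmentation ran on volumes
    binned 3×3 in-plane, i.e. 18.9 × 18.9 × 50 nm, which is the native
    resolution of this preset.
    """
    return PhantomSpec(grid_shape=grid_shape, voxel_size=(50.0, 18.9, 18.9), rng_seed=rng_seed, **kw)


def neurite_sbem_spec(grid_shape=(120, 256, 256), rng_seed=0, **kw) -> PhantomSpec:
    """Cytosol-label (projection neuron) preset: 10.5 × 10.5 × 25 nm voxels."""
    return PhantomSpec(grid_shape=grid_shape, voxel_size=(25.0, 10.5, 10.5), rng_seed=rng_seed, **kw)


def fibsem_spec(grid_shape=(192, 192, 192), rng_seed=0, **kw) -> PhantomSpec:
    """Near-isotropic FIBSEM preset: ~10 nm voxels."""
    return PhantomSpec(grid_shape=grid_shape, voxel_size=(10.0, 10.0, 10.0), rng_seed=rng_seed, **kw)


@dataclass
class ObjectInfo:
    """One ground-truth object: its class, id and generating parameters."""

    class_name: str
    object_id: int
    params: dict = field(default_factory=dict)


@dataclass
class PhantomTruth:
    """Ground truth for a phantom: per-class labelled masks plus a catalogue.

    ``class_labels[c]`` is an int32 array of the volume's shape with 0 =
    background and k >= 1 = object id within class ``c``; objects within a
    class are voxel-disjoint by construction.
    """

    shape: tuple[int, int, int]
    class_labels: dict[str, np.ndarray] = field(default_factory=dict)
    catalogue: list[ObjectInfo] = field(default_factory=list)
    #: accumulated index-units of geometry clipped at the grid boundary;
    #: 0 means nothing escaped the grid.
    clipped_voxel_count: int = 0

    def classes(self) -> list[str]:
        return list(self.class_labels)

    def mask(self, class_name: str) -> np.ndarray:
        return self.class_labels[class_name] > 0

    def object_mask(self, class_name: str, object_id: int) -> np.ndarray:
        return self.class_labels[class_name] == object_id

    def n_objects(self, class_name: str) -> int:
        return sum(1 for o in self.catalogue if o.class_name == class_name)

    def _new_class(self, class_name: str) -> np.ndarray:
        arr = np.zeros(self.shape, dtype=np.int32)
        self.class_labels[class_name] = arr
        return arr


# ---------------------------------------------------------------------------
# Geometry helpers (all in physical nm, rasterised per-axis)
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _bbox_slices(shape, center_nm, half_extent_nm, voxel_size):
    """Index slices covering a physical bounding box; also #voxels clipped off."""
    los, his, clipped = [], [], 0
    for ax in range(3):
        lo = int(math.floor((center_nm[ax] - half_extent_nm[ax]) / voxel_size[ax]))
        hi = int(math.ceil((center_nm[ax] + half_extent_nm[ax]) / voxel_size[ax])) + 1
        clo, chi = max(lo, 0), min(hi, shape[ax])
        if chi <= clo:
            return None, 0
        clipped = max(clipped, (clo - lo) + (hi - chi))
        los.append(clo)
        his.append(chi)
    sl = tuple(slice(lo, hi) for lo, hi in zip(los, his))
    return sl, clipped


def _voxel_centers(slices, voxel_size):
    """Physical (z, y, x) centre coordinates (nm) of voxels in a slice box."""
    axes = [
        (np.arange(s.start, s.stop) + 0.5) * voxel_size[i]
        for i, s in enumerate(slices)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _rasterize_ellipsoid(shape, voxel_size, center_nm, semi_axes_nm, rotation):
    sl, _ = _bbox_slices(shape, center_nm, [max(semi_axes_nm)] * 3, voxel_size)
    if sl is None:
        return None, None
    zz, yy, xx = _voxel_centers(sl, voxel_size)
    d = np.stack([zz - center_nm[0], yy - center_nm[1], xx - center_nm[2]], axis=-1)
    local = d @ rotation  # rotate into the ellipsoid frame
    q = (local / np.asarray(semi_axes_nm)) ** 2
    return sl, q.sum(axis=-1) <= 1.0


def _rasterize_capsule(shape, voxel_size, p0_nm, p1_nm, radius_nm):
    """Voxels within radius of the segment p0-p1 (a cylinder with round caps)."""
    p0 = np.asarray(p0_nm, dtype=float)
    p1 = np.asarray(p1_nm, dtype=float)
    lo = np.minimum(p0, p1) - radius_nm
    hi = np.maximum(p0, p1) + radius_nm
    center = (lo + hi) / 2
    half = (hi - lo) / 2
    sl, clipped = _bbox_slices(shape, center, half, voxel_size)
    if sl is None:
        return None, None, 0
    zz, yy, xx = _voxel_centers(sl, voxel_size)
    p = np.stack([zz, yy, xx], axis=-1)
    axis = p1 - p0
    seg_len2 = float(axis @ axis)
    if seg_len2 == 0:
        dist2 = ((p - p0) ** 2).sum(axis=-1)
    else:
        t = np.clip(((p - p0) @ axis) / seg_len2, 0.0, 1.0)
        nearest = p0 + t[..., None] * axis
        dist2 = ((p - nearest) ** 2).sum(axis=-1)
    return sl, dist2 <= radius_nm**2, clipped


def _rasterize_disk_slab(shape, voxel_size, center_nm, normal, radius_nm, thickness_nm):
    half = np.full(3, radius_nm + thickness_nm)
    sl, _ = _bbox_slices(shape, center_nm, half, voxel_size)
    if sl is None:
        return None, None
    zz, yy, xx = _voxel_centers(sl, voxel_size)
    d = np.stack([zz - center_nm[0], yy - center_nm[1], xx - center_nm[2]], axis=-1)
    axial = d @ normal
    radial2 = (d**2).sum(axis=-1) - axial**2
    return sl, (np.abs(axial) <= thickness_nm / 2) & (radial2 <= radius_nm**2)


_STRUCT26 = ndi.generate_binary_structure(3, 3)


class _Occupancy:
    """Tracks claimed voxels; enforces a >=1-voxel gap between objects.

    An accepted object is recorded with a one-voxel 26-dilation, so any later
    candidate that avoids the recorded set is guaranteed not to touch (even
    diagonally) any earlier object — thresholded objects then stay separate
    connected components.
    """

    def __init__(self, shape):
        self.taken = np.zeros(shape, dtype=bool)

    def conflicts(self, sl, local_mask) -> bool:
        return bool(np.any(self.taken[sl] & local_mask))

    def claim(self, sl, local_mask) -> None:
        ext = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(sl, self.taken.shape)
        )
        pad = np.zeros(tuple(e.stop - e.start for e in ext), dtype=bool)
        ins = tuple(
            slice(s.start - e.start, s.start - e.start + (s.stop - s.start))
            for s, e in zip(sl, ext)
        )
        pad[ins] = local_mask
        self.taken[ext] |= ndi.binary_dilation(pad, structure=_STRUCT26)


# ---------------------------------------------------------------------------
# Intensity painting
# ---------------------------------------------------------------------------

def _label_draw(rng, spec: PhantomSpec, n: int) -> np.ndarray:
    v = rng.normal(spec.label_mean, spec.label_sd, size=n)
    v = np.clip(v, spec.label_mean - 2 * spec.label_sd, spec.label_mean + 2 * spec.label_sd)
    return np.clip(np.rint(v), 0, spec.domain_max)


def _background_values(rng, spec: PhantomSpec) -> np.ndarray:
    """Textured neuropil background: mean + band-limited texture + noise."""
    vals = np.full(spec.grid_shape, spec.background_mean, dtype=np.float64)
    if spec.texture_amplitude > 0:
        sig = [spec.texture_granularity_nm / v for v in spec.voxel_size]
        tex = ndi.gaussian_filter(rng.normal(size=spec.grid_shape), sigma=sig)
        sd = tex.std()
        if sd > 0:
            vals += spec.texture_amplitude * tex / sd
    vals += rng.normal(0.0, spec.background_sd, size=spec.grid_shape)
    return np.clip(np.rint(vals), 0, spec.domain_max)


def _paint_neuropil_sheets(values, rng, spec: PhantomSpec, n_sheets: int) -> None:
    """Faint constant-intensity membrane sheets: sub-threshold distractors."""
    shape = spec.grid_shape
    extent = np.asarray(shape) * np.asarray(spec.voxel_size)
    for _ in range(n_sheets):
        center = rng.uniform(0.15, 0.85, size=3) * extent
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        out = _rasterize_disk_slab(
            shape, spec.voxel_size, center, normal,
            radius_nm=rng.uniform(300, 700), thickness_nm=25.0,
        )
        if out[0] is not None:
            sl, m = out
            values[sl][m] = spec.membrane_intensity


# ---------------------------------------------------------------------------
# Mitochondria phantom
# ---------------------------------------------------------------------------

def make_mitochondria_phantom(
    spec: PhantomSpec,
    n_objects: int = 50,
    semi_axis_range: tuple[float, float] = (100.0, 400.0),
    n_speckle: int = 200,
    n_membrane_fragments: int = 20,
    n_neuropil_sheets: int = 4,
    max_attempts: int = _MAX_PLACEMENT_ATTEMPTS,
) -> tuple[VolumeGrid, PhantomTruth]:
    """Generate a mitochondria-labelled phantom with ground truth.

    Parameters
    ----------
    n_objects : int
        Number of labelled mitochondria (randomly oriented solid ellipsoids
        at label intensity). Must be >= 1.
    semi_axis_range : (float, float)
        Uniform sampling interval for each ellipsoid semi-axis, in nm. The
        defaults give mitochondrial volumes spanning roughly the 0.004-0.3
        µm³ scale observed in labelled fly-brain specimens.
    n_speckle : int
        Connected blobs of < 10 voxels at label intensity — the non-specific
        background signal the minimum-size cutoff removes.
    n_membrane_fragments : int
        Thin sheets whose voxels alternate between background values and
        label-range values spanning the full label interval; their segmented
        voxel sets have high intensity variance, which is what the variance
        filter rejects.
    n_neuropil_sheets : int
        Faint sub-threshold membranes adding background structure.

    Returns
    -------
    (VolumeGrid, PhantomTruth)
        Truth classes: ``mitochondria``, ``speckle``, ``membrane_fragment``.
    """
    if n_objects < 1:
        raise ValueError(f"n_objects must be >= 1; got {n_objects}")
    if n_speckle < 0 or n_membrane_fragments < 0:
        raise ValueError("speckle/fragment counts must be >= 0")
    lo_ax, hi_ax = semi_axis_range
    if not 0 < lo_ax <= hi_ax:
        raise ValueError(f"invalid semi_axis_range {semi_axis_range}")

    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.grid_shape
    voxel_size = np.asarray(spec.voxel_size)
    extent = np.asarray(shape) * voxel_size

    values = _background_values(rng, spec)
    _paint_neuropil_sheets(values, rng, spec, n_neuropil_sheets)

    truth = PhantomTruth(shape=tuple(shape))
    occ = _Occupancy(shape)

    mito = truth._new_class("mitochondria")
    for oid in range(1, n_objects + 1):
        for attempt in range(max_attempts):
            axes = np.sort(rng.uniform(lo_ax, hi_ax, size=3))[::-1]
            margin = axes[0] + 2 * voxel_size
            if np.any(extent - 2 * margin <= 0):
                raise PlacementError("mitochondria: ellipsoid larger than the grid")
            center = rng.uniform(margin, extent - margin)
            rot = _random_rotation(rng)
            sl, m = _rasterize_ellipsoid(shape, spec.voxel_size, center, axes, rot)
            if sl is None or not m.any() or occ.conflicts(sl, m):
                continue
            occ.claim(sl, m)
            mito[sl][m] = oid
            values[sl][m] = _label_draw(rng, spec, int(m.sum()))
            truth.catalogue.append(
                ObjectInfo("mitochondria", oid, {
                    "center_nm": tuple(center),
                    "semi_axes_nm": tuple(axes),
                    "rotation": rot.tolist(),
                })
            )
            break
        else:
            raise PlacementError(f"mitochondria: could not place object {oid} after {max_attempts} attempts")

    spk = truth._new_class("speckle")
    for oid in range(1, n_speckle + 1):
        size = int(rng.integers(1, 10))  # strictly < 10 voxels
        voxels = _place_speckle(rng, shape, occ, size, max_attempts, "speckle")
        zz, yy, xx = zip(*voxels)
        spk[zz, yy, xx] = oid
        values[zz, yy, xx] = _label_draw(rng, spec, len(voxels))
        truth.catalogue.append(ObjectInfo("speckle", oid, {"n_voxels": size}))

    frag = truth._new_class("membrane_fragment")
    sep = spec.separating_range()
    for oid in range(1, n_membrane_fragments + 1):
        _place_membrane_fragment(rng, spec, values, occ, frag, oid, sep, truth, max_attempts)

    vol = VolumeGrid(
        values.astype(np.float32),
        voxel_size=spec.voxel_size,
        bit_depth=spec.bit_depth,
        provenance=[{"op": "make_mitochondria_phantom", "rng_seed": spec.rng_seed,
                     "n_objects": n_objects, "n_speckle": n_speckle,
                     "n_membrane_fragments": n_membrane_fragments}],
        name="phantom-mito",
    )
    return vol, truth


def _place_speckle(rng, shape, occ, size, max_attempts, class_name):
    """Grow a random-walk blob of `size` 6-connected voxels with a gap margin."""
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for _ in range(max_attempts):
        start = tuple(int(rng.integers(2, n - 2)) for n in shape)
        voxels = [start]
        chosen = {start}
        ok = True
        while len(voxels) < size:
            base = voxels[int(rng.integers(len(voxels)))]
            d = offsets[int(rng.integers(6))]
            cand = (base[0] + d[0], base[1] + d[1], base[2] + d[2])
            if any(c < 1 or c >= n - 1 for c, n in zip(cand, shape)):
                ok = False
                break
            if cand not in chosen:
                chosen.add(cand)
                voxels.append(cand)
        if not ok:
            continue
        zmin = [min(v[i] for v in voxels) for i in range(3)]
        zmax = [max(v[i] for v in voxels) + 1 for i in range(3)]
        sl = tuple(slice(a, b) for a, b in zip(zmin, zmax))
        local = np.zeros([b - a for a, b in zip(zmin, zmax)], dtype=bool)
        for v in voxels:
            local[v[0] - zmin[0], v[1] - zmin[1], v[2] - zmin[2]] = True
        if occ.conflicts(sl, local):
            continue
        occ.claim(sl, local)
        return voxels
    raise PlacementError(f"{class_name}: could not place object after {max_attempts} attempts")


def _place_membrane_fragment(rng, spec, values, occ, frag, oid, sep, truth, max_attempts):
    """A thin slab of alternating background / label-range voxels.

    The label-range voxels sit on the even (z+y+x) sublattice, which is
    26-connected inside the slab, and alternate between the separating
    range's lower bound and the domain maximum — so the thresholded fragment
    is one connected object whose intensity variance is far above any
    genuinely labelled (near-constant) structure.
    """
    shape = spec.grid_shape
    voxel_size = np.asarray(spec.voxel_size)
    extent = np.asarray(shape) * voxel_size
    min_inplane = min(spec.voxel_size[1], spec.voxel_size[2])
    thickness = 2.4 * min_inplane
    for _ in range(max_attempts):
        radius = rng.uniform(150.0, 280.0)
        margin = radius + thickness + 2 * voxel_size
        if np.any(extent - 2 * margin <= 0):
            raise PlacementError("membrane_fragment: fragment larger than the grid")
        center = rng.uniform(margin, extent - margin)
        phi = rng.uniform(0, 2 * np.pi)
        tilt = rng.uniform(-0.25, 0.25)  # normal mostly in-plane: slab spans fine axes
        normal = np.array([tilt, np.cos(phi), np.sin(phi)])
        normal /= np.linalg.norm(normal)
        sl, m = _rasterize_disk_slab(shape, spec.voxel_size, center, normal, radius, thickness)
        if sl is None or not m.any() or occ.conflicts(sl, m):
            continue
        zz, yy, xx = np.nonzero(m)
        gz, gy, gx = zz + sl[0].start, yy + sl[1].start, xx + sl[2].start
        even = (gz + gy + gx) % 2 == 0
        if even.sum() < 20:
            continue
        inrange = np.zeros(m.shape, dtype=bool)
        inrange[zz[even], yy[even], xx[even]] = True
        n_comp = ndi.label(inrange, structure=_STRUCT26)[1]
        if n_comp != 1:
            continue
        occ.claim(sl, m)
        frag[sl][m] = oid
        vals = np.where(gx % 2 == 0, sep.lo, spec.domain_max)
        bg = np.clip(np.rint(rng.normal(spec.background_mean, spec.background_sd, size=len(gz))),
                     0, spec.domain_max)
        values[gz, gy, gx] = np.where(even, vals, bg)
        truth.catalogue.append(
            ObjectInfo("membrane_fragment", oid, {
                "center_nm": tuple(center),
                "normal": tuple(normal),
                "radius_nm": float(radius),
                "thickness_nm": float(thickness),
            })
        )
        return
    raise PlacementError(f"membrane_fragment: could not place object after {max_attempts} attempts")


# ---------------------------------------------------------------------------
# Neurite phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuriteTreeSpec:
    """Branching parameters for the primary labelled cell.

    Lengths and radii are in nm; the tree is built in physical space and
    rasterised per-axis. ``calibre_threshold_nm`` marks segments as "large
    calibre" for the signal-drop-off model.
    """

    depth: int = 3
    n_children: int = 2
    branch_angle_deg: tuple[float, float] = (25.0, 55.0)
    segment_length_nm: tuple[float, float] = (600.0, 1000.0)
    root_radius_nm: float = 150.0
    taper: float = 0.75
    soma_radius_nm: float = 450.0
    calibre_threshold_nm: float = 220.0
    soma_center_frac: tuple[float, float, float] = (0.5, 0.5, 0.22)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 < self.taper <= 1:
            raise ValueError("taper must be in (0, 1]")


def _perturbed_direction(rng, direction, angle_deg_range):
    """Rotate `direction` by an angle in the given range about a random azimuth."""
    theta = math.radians(rng.uniform(*angle_deg_range))
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    phi = rng.uniform(0, 2 * np.pi)
    out = math.cos(theta) * d + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v)
    return out / np.linalg.norm(out)


def _build_tree(rng, tree: NeuriteTreeSpec, root_nm, initial_direction):
    """Return (segments, branch_nodes); segments = (p0, p1, radius, depth)."""
    segments, branch_nodes = [], []

    def grow(p0, direction, radius, level):
        if level > tree.depth:
            return
        length = rng.uniform(*tree.segment_length_nm)
        p1 = p0 + direction * length
        segments.append((p0.copy(), p1.copy(), radius, level))
        if level < tree.depth:
            branch_nodes.append((p1.copy(), radius))
            for _ in range(tree.n_children):
                child_dir = _perturbed_direction(rng, direction, tree.branch_angle_deg)
                grow(p1, child_dir, radius * tree.taper, level + 1)

    if tree.depth >= 1:
        grow(np.asarray(root_nm, dtype=float), np.asarray(initial_direction, dtype=float), tree.root_radius_nm, 1)
    return segments, branch_nodes


def _paint_cell(values, mask_arr, oid, rng, spec, cell_voxel_mask, dropoff_mult):
    """Paint a cell's voxels with (possibly dropped) label intensities."""
    zz, yy, xx = np.nonzero(cell_voxel_mask)
    draw = _label_draw(rng, spec, len(zz)).astype(np.float64)
    mult = dropoff_mult[zz, yy, xx]
    v = spec.background_mean + (draw - spec.background_mean) * mult
    values[zz, yy, xx] = np.clip(np.rint(v), 0, spec.domain_max)
    mask_arr[zz, yy, xx] = oid


def make_neurite_phantom(
    spec: PhantomSpec,
    tree: NeuriteTreeSpec | None = None,
    dropoff: float = 0.2,
    n_crossover_cells: int = 2,
    with_trachiole: bool = True,
    trachiole_offset: float = 2.0,
    contact_offset: float = 4.0,
    trachiole_radius_nm: float = 70.0,
    trachiole_length_nm: float = 900.0,
    n_neuropil_sheets: int = 4,
    max_attempts: int = _MAX_PLACEMENT_ATTEMPTS,
) -> tuple[VolumeGrid, PhantomTruth]:
    """Generate a cytosol-labelled neurite phantom with ground truth.

    The primary cell is a soma sphere plus a branching tubular tree at label
    intensity. ``dropoff`` is the fractional reduction of label contrast
    (above background) applied in spherical zones around branch points and
    along large-calibre segments, emulating uneven DAB labelling; at
    ``dropoff=0`` every cell voxel is drawn from the same label distribution.

    Crossover cells are independent labelled cells clustered around the
    primary soma, each connected to the primary tree by a short bridge
    rendered ``contact_offset`` intensity units below the separating range's
    lower bound — so tight ranges segment the cells separately while
    permissive ranges merge them. The trachiole is a tube abutting the
    primary trunk at a constant intensity ``trachiole_offset`` units below
    the separating bound; it is incorporated by a seeded trial series exactly
    when the lower bound steps past its intensity.

    Truth classes: ``cell`` (id 1 = primary, 2.. = crossovers),
    ``trachiole``, ``contact``.
    """
    if tree is None:
        tree = NeuriteTreeSpec()
    if not 0 <= dropoff < 1:
        raise ValueError("dropoff must be in [0, 1)")
    if n_crossover_cells < 0:
        raise ValueError("n_crossover_cells must be >= 0")

    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.grid_shape
    voxel_size = np.asarray(spec.voxel_size)
    extent = np.asarray(shape) * voxel_size
    sep = spec.separating_range()

    soma_center = np.asarray(tree.soma_center_frac) * extent
    if np.any(soma_center - tree.soma_radius_nm < 0) or np.any(soma_center + tree.soma_radius_nm > extent):
        raise ValueError("soma must be placed inside the grid")

    values = _background_values(rng, spec)
    _paint_neuropil_sheets(values, rng, spec, n_neuropil_sheets)

    truth = PhantomTruth(shape=tuple(shape))
    cells = truth._new_class("cell")

    # --- primary cell geometry -------------------------------------------
    initial_direction = np.array([0.0, 0.0, 1.0])  # grow along +x
    segments, branch_nodes = _build_tree(rng, tree, soma_center, initial_direction)

    primary = np.zeros(shape, dtype=bool)
    clipped = 0

    def add_sphere(mask, center, radius):
        nonlocal clipped
        sl, c = _bbox_slices(shape, center, [radius] * 3, spec.voxel_size)
        clipped += c
        if sl is None:
            return
        zz, yy, xx = _voxel_centers(sl, spec.voxel_size)
        d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        mask[sl] |= d2 <= radius**2

    def add_capsule(mask, p0, p1, radius):
        nonlocal clipped
        sl, m, c = _rasterize_capsule(shape, spec.voxel_size, p0, p1, radius)
        clipped += c
        if sl is not None:
            mask[sl] |= m

    add_sphere(primary, soma_center, tree.soma_radius_nm)
    for p0, p1, r, _level in segments:
        add_capsule(primary, p0, p1, r)

    # --- drop-off field ----------------------------------------------------
    dropoff_mult = np.ones(shape, dtype=np.float32)
    if dropoff > 0:
        zone = np.zeros(shape, dtype=bool)
        for node, r in branch_nodes:
            add_sphere(zone, node, 2.5 * r)
        for p0, p1, r, _level in segments:
            if r >= tree.calibre_threshold_nm:
                add_capsule(zone, p0, p1, r)
        dropoff_mult[zone] = 1.0 - dropoff

    _paint_cell(values, cells, 1, rng, spec, primary, dropoff_mult)
    truth.catalogue.append(
        ObjectInfo("cell", 1, {
            "role": "primary",
            "soma_center_nm": tuple(soma_center),
            "soma_radius_nm": tree.soma_radius_nm,
            "n_segments": len(segments),
            "n_branch_nodes": len(branch_nodes),
            "dropoff": dropoff,
        })
    )

    # --- crossover cells ---------------------------------------------------
    all_cells = primary.copy()
    contact = truth._new_class("contact")
    trunk = segments[0] if segments else None
    for i in range(n_crossover_cells):
        placed = False
        for _ in range(max_attempts):
            co_r = 0.75 * tree.soma_radius_nm
            phi = rng.uniform(0, 2 * np.pi)
            tilt = rng.uniform(-0.3, 0.3)
            d = np.array([tilt, np.cos(phi), np.sin(phi)])
            d /= np.linalg.norm(d)
            co_center = soma_center + d * (tree.soma_radius_nm + co_r) * rng.uniform(1.25, 1.6)
            if np.any(co_center - co_r < 0) or np.any(co_center + co_r > extent):
                continue
            co_mask = np.zeros(shape, dtype=bool)
            add_sphere(co_mask, co_center, co_r)
            trunk_dir = _perturbed_direction(rng, d, (0.0, 40.0))
            add_capsule(co_mask, co_center, co_center + trunk_dir * rng.uniform(500, 800), 120.0)
            if np.any(co_mask & ndi.binary_dilation(all_cells, structure=_STRUCT26)):
                continue
            oid = 2 + i
            _paint_cell(values, cells, oid, rng, spec, co_mask & ~all_cells, dropoff_mult)
            all_cells |= co_mask
            # bridge to the primary trunk (or soma for a degenerate tree)
            if trunk is not None:
                f = 0.3 + 0.5 * (i + 1) / (n_crossover_cells + 1)
                target = trunk[0] + f * (trunk[1] - trunk[0])
            else:
                target = soma_center
            bridge = np.zeros(shape, dtype=bool)
            add_capsule(bridge, co_center, target, 70.0)
            gap = bridge & ~all_cells & ~primary
            zz, yy, xx = np.nonzero(gap)
            contact_val = np.clip(round(sep.lo - contact_offset), 0, spec.domain_max)
            values[zz, yy, xx] = contact_val
            contact[zz, yy, xx] = i + 1
            truth.catalogue.append(
                ObjectInfo("contact", i + 1, {
                    "bridges_cell_id": 2 + i,
                    "intensity": float(contact_val),
                    "n_voxels": int(gap.sum()),
                })
            )
            truth.catalogue.append(
                ObjectInfo("cell", oid, {
                    "role": "crossover",
                    "soma_center_nm": tuple(co_center),
                    "soma_radius_nm": co_r,
                    "contact_intensity": float(contact_val),
                })
            )
            placed = True
            break
        if not placed:
            raise PlacementError(f"crossover cell {i + 1}: could not place after {max_attempts} attempts")

    # --- trachiole ---------------------------------------------------------
    tra = truth._new_class("trachiole")
    if with_trachiole:
        if trunk is None:
            raise ValueError("with_trachiole requires a tree of depth >= 1")
        p0, p1, r_trunk, _ = trunk
        q = p0 + 0.6 * (p1 - p0)
        axis = (p1 - p0) / np.linalg.norm(p1 - p0)
        n = _perturbed_direction(rng, axis, (88.0, 92.0))  # ~perpendicular
        start = q + n * (0.5 * r_trunk)  # overlaps the trunk: guaranteed contact
        end = start + n * trachiole_length_nm
        tmask = np.zeros(shape, dtype=bool)
        add_capsule(tmask, start, end, trachiole_radius_nm)
        tmask &= ~all_cells
        tmask &= contact == 0
        t_val = np.clip(round(sep.lo - trachiole_offset), 0, spec.domain_max)
        values[tmask] = t_val
        tra[tmask] = 1
        truth.catalogue.append(
            ObjectInfo("trachiole", 1, {
                "intensity": float(t_val),
                "radius_nm": trachiole_radius_nm,
                "length_nm": trachiole_length_nm,
            })
        )

    truth.clipped_voxel_count = int(clipped)
    vol = VolumeGrid(
        values.astype(np.float32),
        voxel_size=spec.voxel_size,
        bit_depth=spec.bit_depth,
        provenance=[{"op": "make_neurite_phantom", "rng_seed": spec.rng_seed,
                     "dropoff": dropoff, "n_crossover_cells": n_crossover_cells,
                     "with_trachiole": with_trachiole}],
        name="phantom-neurite",
    )
    return vol, truth


# ---------------------------------------------------------------------------
# Texture op and diagnostics
# ---------------------------------------------------------------------------

def add_background_texture(
    volume: VolumeGrid, granularity_nm: float, amplitude: float, rng_seed: int
) -> VolumeGrid:
    """Add band-limited (Gaussian-correlated) texture to a volume.

    White noise is low-pass filtered at the given physical granularity,
    rescaled to unit standard deviation, scaled by ``amplitude`` and added;
    the result is clipped to the bit-depth domain. ``amplitude=0`` is the
    identity.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return volume.evolve(volume.values.copy(), "add_background_texture",
                             granularity_nm=granularity_nm, amplitude=0.0, rng_seed=rng_seed)
    vs = volume.require_voxel_size()
    rng = np.random.default_rng(rng_seed)
    tex = ndi.gaussian_filter(rng.normal(size=volume.shape), sigma=[granularity_nm / v for v in vs])
    sd = tex.std()
    if sd > 0:
        tex /= sd
    out = np.clip(volume.values + amplitude * tex, 0, volume.domain_max).astype(np.float32)
    return volume.evolve(out, "add_background_texture",
                         granularity_nm=granularity_nm, amplitude=amplitude, rng_seed=rng_seed)


def separability_report(volume: VolumeGrid, truth: PhantomTruth, spec: PhantomSpec) -> dict:
    """Fractions of labelled / background voxels inside the separating range.

    Labelled voxels are those in any label-intensity truth class
    (mitochondria, speckle, cell); background is everything in no truth
    class at all.
    """
    sep = spec.separating_range()
    inr = sep.contains(volume.values)
    label_classes = [c for c in ("mitochondria", "speckle", "cell") if c in truth.class_labels]
    labelled = np.zeros(volume.shape, dtype=bool)
    for c in label_classes:
        labelled |= truth.mask(c)
    any_class = labelled.copy()
    for c in truth.classes():
        any_class |= truth.mask(c)
    background = ~any_class
    return {
        "label_fraction_in_range": float(inr[labelled].mean()) if labelled.any() else float("nan"),
        "background_fraction_in_range": float(inr[background].mean()) if background.any() else float("nan"),
        "range": (sep.lo, sep.hi),
    }
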