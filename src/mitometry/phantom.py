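"""Synthetic 2D/3D label-map phantoms with closed-form ground truth.

Every phantom is rasterized by pixel-center inclusion: an element is
foreground iff its center lies inside the analytic shape.  Pixel centers
sit at ``index * pitch``, so rendering is deterministic and platform
independent (integer grid test against an analytic inequality).

Contact phantoms place organelle boundaries so that the center-to-center
boundary gap equals the requested physical gap exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import Calibration, LabelMap
from .morpho3d import MoasParams, moas_rule


@dataclass
class GroundTruth:
    """Analytic values for whichever metrics the phantom determines."""

    area_um2: Optional[float] = None
    perimeter_um: Optional[float] = None
    feret_length_um: Optional[float] = None
    volume_um3: Optional[float] = None
    surface_area_um2: Optional[float] = None
    length_um: Optional[float] = None
    gap_nm: Optional[float] = None
    contact_length_um: Optional[float] = None
    contact_area_um2: Optional[float] = None
    cleft_volume_um3: Optional[float] = None
    cristae_count: Optional[int] = None
    pct_lamellar: Optional[float] = None
    junctions: Optional[int] = None
    moas: Optional[bool] = None
    tunnel_segments: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            k: v for k, v in dataclasses.asdict(self).items() if v is not None
        }


@dataclass
class PhantomSpec:
    kind: str
    params: dict = field(default_factory=dict)
    px_nm: float = 10.0
    px_z_nm: Optional[float] = None  # 3D kinds default to isotropic px_nm
    seed: int = 0
    jitter_amplitude_px: float = 0.0


NM = 1.0  # parameters are given in nm throughout

_KINDS_2D = {"disc", "ellipse", "rectangle", "apposed_pair_2d", "cristae_mix", "wrap_sheath"}
_KINDS_3D = {"sphere", "cylinder", "bent_tube", "beads_on_string", "apposed_slabs_3d"}


def _cal2d(px_nm: float) -> Calibration:
    return Calibration(px_x_nm=px_nm, px_y_nm=px_nm)


def _cal3d(px_nm: float, px_z_nm: Optional[float]) -> Calibration:
    return Calibration(px_x_nm=px_nm, px_y_nm=px_nm, px_z_nm=px_z_nm or px_nm)


def _grid2d(shape: tuple[int, int], px_nm: float) -> tuple[np.ndarray, np.ndarray]:
    y = np.arange(shape[0])[:, None] * px_nm
    x = np.arange(shape[1])[None, :] * px_nm
    return y, x


# ---------------------------------------------------------------------------
# 2D shapes


def render_disc(radius_nm: float, px_nm: float = 10.0, margin_px: int = 4):
    r_px = radius_nm / px_nm
    n = int(np.ceil(2 * r_px)) + 2 * margin_px + 1
    y, x = _grid2d((n, n), px_nm)
    c = (n // 2) * px_nm
    mask = (y - c) ** 2 + (x - c) ** 2 <= radius_nm**2
    gt = GroundTruth(
        area_um2=np.pi * (radius_nm / 1000.0) ** 2,
        perimeter_um=2 * np.pi * radius_nm / 1000.0,
        feret_length_um=2 * radius_nm / 1000.0,
    )
    lm = LabelMap(mask.astype(np.uint8), "mitochondrion", _cal2d(px_nm))
    return {"mito": lm}, gt


def render_ellipse(a_nm: float, b_nm: float, px_nm: float = 10.0, margin_px: int = 4):
    """Axis-aligned ellipse with semi-axes a (x) and b (y)."""
    ny = int(np.ceil(2 * b_nm / px_nm)) + 2 * margin_px + 1
    nx = int(np.ceil(2 * a_nm / px_nm)) + 2 * margin_px + 1
    y, x = _grid2d((ny, nx), px_nm)
    cy, cx = (ny // 2) * px_nm, (nx // 2) * px_nm
    mask = ((x - cx) / a_nm) ** 2 + ((y - cy) / b_nm) ** 2 <= 1.0
    # Ramanujan's second approximation for the perimeter
    h = ((a_nm - b_nm) / (a_nm + b_nm)) ** 2
    perim = np.pi * (a_nm + b_nm) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    gt = GroundTruth(
        area_um2=np.pi * a_nm * b_nm / 1e6,
        perimeter_um=perim / 1000.0,
        feret_length_um=2 * max(a_nm, b_nm) / 1000.0,
    )
    lm = LabelMap(mask.astype(np.uint8), "mitochondrion", _cal2d(px_nm))
    return {"mito": lm}, gt


def render_rectangle(w_nm: float, h_nm: float, px_nm: float = 10.0, margin_px: int = 4):
    """w x h axis-aligned rectangle rendered as an exact block of pixels."""
    w_px, h_px = int(round(w_nm / px_nm)), int(round(h_nm / px_nm))
    arr = np.zeros((h_px + 2 * margin_px, w_px + 2 * margin_px), dtype=np.uint8)
    arr[margin_px : margin_px + h_px, margin_px : margin_px + w_px] = 1
    w_nm, h_nm = w_px * px_nm, h_px * px_nm
    gt = GroundTruth(
        area_um2=w_nm * h_nm / 1e6,
        perimeter_um=2 * (w_nm + h_nm) / 1000.0,
        feret_length_um=float(np.hypot(w_nm, h_nm)) / 1000.0,
    )
    return {"mito": LabelMap(arr, "mitochondrion", _cal2d(px_nm))}, gt


def render_apposed_pair_2d(
    gap_nm: float,
    span_nm: float = 1000.0,
    thickness_nm: float = 100.0,
    px_nm: float = 10.0,
    margin_px: int = 8,
    overhang_px: int = 6,
):
    """A mitochondrial slab apposed by a thin parallel ER membrane.

    The ER is a one-pixel-thick line of length ``span_nm``; the
    mitochondrion extends ``overhang_px`` beyond it on both sides so every
    ER boundary pixel sits at exactly ``gap_nm`` (an integer number of
    pixels) from the mitochondrial boundary, center-to-center.
    """
    k = gap_nm / px_nm
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError("gap_nm must be a positive integer multiple of px_nm")
    k = int(round(k))
    span_px = int(round(span_nm / px_nm))
    t_px = max(1, int(round(thickness_nm / px_nm)))
    h = t_px + k + 2 + 2 * margin_px
    w = span_px + 2 * overhang_px + 2 * margin_px
    mito = np.zeros((h, w), dtype=np.uint8)
    er = np.zeros((h, w), dtype=np.uint8)
    m1 = margin_px + t_px - 1  # last mito row (its boundary)
    e0 = m1 + k  # ER row, centers k px from the mito boundary row
    mito[margin_px : m1 + 1, margin_px : margin_px + span_px + 2 * overhang_px] = 1
    er[e0, margin_px + overhang_px : margin_px + overhang_px + span_px] = 1
    cal = _cal2d(px_nm)
    gt = GroundTruth(
        gap_nm=k * px_nm,
        contact_length_um=(span_px - 1) * px_nm / 1000.0,  # polyline arc length
    )
    return {
        "mito": LabelMap(mito, "mitochondrion", cal),
        "er": LabelMap(er, "er", cal),
    }, gt


def render_wrap_sheath(
    mito_radius_nm: float = 400.0,
    gap_nm: float = 30.0,
    sheath_thickness_nm: float = 60.0,
    px_nm: float = 10.0,
    margin_px: int = 6,
):
    """A disc mitochondrion fully wrapped by an annular ER sheath."""
    outer = mito_radius_nm + gap_nm + sheath_thickness_nm
    n = int(np.ceil(2 * outer / px_nm)) + 2 * margin_px + 1
    y, x = _grid2d((n, n), px_nm)
    c = (n // 2) * px_nm
    rr = np.sqrt((y - c) ** 2 + (x - c) ** 2)
    mito = rr <= mito_radius_nm
    er = (rr >= mito_radius_nm + gap_nm) & (rr <= outer)
    cal = _cal2d(px_nm)
    gt = GroundTruth(gap_nm=gap_nm)
    return {
        "mito": LabelMap(mito.astype(np.uint8), "mitochondrion", cal),
        "er": LabelMap(er.astype(np.uint8), "er", cal),
    }, gt


def render_cristae_mix(
    n_lamellar: int = 3,
    n_tubular: int = 2,
    px_nm: float = 10.0,
    lamellar_size_px: tuple[int, int] = (40, 8),
    tubular_radius_px: int = 6,
):
    """One rectangular mitochondrion containing lamellar sheets
    (aspect >= 4 by construction) and tubular cross-sections (aspect 1)."""
    n_cristae = n_lamellar + n_tubular
    slot_w = max(lamellar_size_px[0], 2 * tubular_radius_px + 2) + 10
    w = n_cristae * slot_w + 20
    h = 80
    mito = np.zeros((h, w), dtype=np.uint8)
    mito[4 : h - 4, 4 : w - 4] = 1
    cristae = np.zeros_like(mito)
    cy = h // 2
    for i in range(n_cristae):
        cx = 10 + i * slot_w + slot_w // 2
        if i < n_lamellar:
            lw, lh = lamellar_size_px
            cristae[cy - lh // 2 : cy - lh // 2 + lh, cx - lw // 2 : cx - lw // 2 + lw] = 1
        else:
            yy, xx = np.ogrid[:h, :w]
            cristae |= (
                (yy - cy) ** 2 + (xx - cx) ** 2 <= tubular_radius_px**2
            ).astype(np.uint8)
    cal = _cal2d(px_nm)
    gt = GroundTruth(
        cristae_count=n_cristae,
        pct_lamellar=100.0 * n_lamellar / n_cristae if n_cristae else 0.0,
    )
    return {
        "mito": LabelMap(mito, "mitochondrion", cal),
        "cristae": LabelMap(cristae, "crista", cal),
    }, gt


# ---------------------------------------------------------------------------
# 3D shapes


def _grid3d(shape, spacing):
    z = np.arange(shape[0])[:, None, None] * spacing[0]
    y = np.arange(shape[1])[None, :, None] * spacing[1]
    x = np.arange(shape[2])[None, None, :] * spacing[2]
    return z, y, x


def render_sphere(
    radius_nm: float, px_nm: float = 10.0, px_z_nm: Optional[float] = None, margin_px: int = 3
):
    cal = _cal3d(px_nm, px_z_nm)
    sp = cal.spacing(3)
    shape = tuple(int(np.ceil(2 * radius_nm / s)) + 2 * margin_px + 1 for s in sp)
    z, y, x = _grid3d(shape, sp)
    c = [(n // 2) * s for n, s in zip(shape, sp)]
    mask = (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= radius_nm**2
    r_um = radius_nm / 1000.0
    gt = GroundTruth(
        volume_um3=4.0 / 3.0 * np.pi * r_um**3,
        surface_area_um2=4.0 * np.pi * r_um**2,
        feret_length_um=2 * r_um,
    )
    return {"mito": LabelMap(mask.astype(np.uint8), "mitochondrion", cal)}, gt


def render_cylinder(
    length_nm: float,
    radius_nm: float,
    px_nm: float = 10.0,
    px_z_nm: Optional[float] = None,
    margin_px: int = 4,
):
    """Straight capped tube along the x axis; length includes the caps."""
    cal = _cal3d(px_nm, px_z_nm)
    sp = cal.spacing(3)
    nz = int(np.ceil(2 * radius_nm / sp[0])) + 2 * margin_px + 1
    ny = int(np.ceil(2 * radius_nm / sp[1])) + 2 * margin_px + 1
    nx = int(np.ceil(length_nm / sp[2])) + 2 * margin_px + 1
    z, y, x = _grid3d((nz, ny, nx), sp)
    cz, cy = (nz // 2) * sp[0], (ny // 2) * sp[1]
    x0 = margin_px * sp[2]
    mask = (
        ((z - cz) ** 2 + (y - cy) ** 2 <= radius_nm**2)
        & (x >= x0)
        & (x <= x0 + length_nm)
    )
    gt = GroundTruth(
        length_um=length_nm / 1000.0,
        volume_um3=np.pi * (radius_nm / 1000.0) ** 2 * (length_nm / 1000.0),
        junctions=0,
        moas=False,
    )
    return {"mito": LabelMap(mask.astype(np.uint8), "mitochondrion", cal)}, gt


def render_bent_tube(
    arc_radius_nm: float,
    tube_radius_nm: float,
    px_nm: float = 10.0,
    margin_px: int = 4,
):
    """Quarter-torus tube: centerline is a 90° arc of radius R in the
    (y, x) plane; ground-truth length is (π/2)·R."""
    cal = _cal3d(px_nm, None)
    sp = cal.spacing(3)
    R, r = arc_radius_nm, tube_radius_nm
    nz = int(np.ceil(2 * r / sp[0])) + 2 * margin_px + 1
    nxy = int(np.ceil(R + r)) // int(sp[1]) + 2 * margin_px + 2
    z, y, x = _grid3d((nz, nxy, nxy), sp)
    cz = (nz // 2) * sp[0]
    oy = ox = margin_px * sp[1]
    yy, xx = y - oy, x - ox
    rho = np.sqrt(yy**2 + xx**2)
    in_quadrant = (yy >= 0) & (xx >= 0)
    dist_arc = np.sqrt((rho - R) ** 2 + (z - cz) ** 2)
    mask = in_quadrant & (dist_arc <= r)
    # cap the ends (quarter only, no end spheres) — endpoints on the axes
    gt = GroundTruth(length_um=(np.pi / 2) * R / 1000.0, junctions=0)
    return {"mito": LabelMap(mask.astype(np.uint8), "mitochondrion", cal)}, gt


def render_beads_on_string(
    n_bulbs: int = 3,
    bulb_radius_nm: float = 200.0,
    tunnel_radius_nm: float = 40.0,
    tunnel_length_nm: float = 500.0,
    px_nm: float = 10.0,
    moas_params: Optional[MoasParams] = None,
    margin_px: int = 4,
    seed: Optional[int] = None,
):
    """Bulb spheres joined by thin cylindrical tunnels along x.

    The ground-truth MOAS label is the analytic decision rule applied to
    the construction parameters, so detector runs can be scored against
    construction labels.  A ``seed`` applies a sub-voxel offset to the
    analytic geometry, varying the rasterization without changing any
    ground-truth value.
    """
    cal = _cal3d(px_nm, None)
    sp = cal.spacing(3)
    pitch = 2 * bulb_radius_nm + tunnel_length_nm
    total_x = 2 * bulb_radius_nm + (n_bulbs - 1) * pitch
    nz = ny = int(np.ceil(2 * bulb_radius_nm / px_nm)) + 2 * margin_px + 1
    nx = int(np.ceil(total_x / px_nm)) + 2 * margin_px + 1
    z, y, x = _grid3d((nz, ny, nx), sp)
    cz, cy = (nz // 2) * px_nm, (ny // 2) * px_nm
    dx = dy = dz = 0.0
    if seed is not None:
        rng = np.random.default_rng(seed)
        dz, dy, dx = rng.uniform(-0.45, 0.45, size=3) * px_nm
        cz, cy = cz + dz, cy + dy
    mask = np.zeros((nz, ny, nx), dtype=bool)
    centers = [
        margin_px * px_nm + bulb_radius_nm + i * pitch + dx for i in range(n_bulbs)
    ]
    for cx in centers:
        mask |= (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= bulb_radius_nm**2
    for cx0, cx1 in zip(centers[:-1], centers[1:]):
        mask |= (
            ((z - cz) ** 2 + (y - cy) ** 2 <= tunnel_radius_nm**2)
            & (x >= cx0)
            & (x <= cx1)
        )
    is_moas = moas_rule(
        bulb_radius_nm, tunnel_radius_nm, tunnel_length_nm, n_bulbs, moas_params
    )
    gt = GroundTruth(
        moas=is_moas,
        tunnel_segments=(n_bulbs - 1) if is_moas else 0,
        junctions=0,
        length_um=total_x / 1000.0,
    )
    return {"mito": LabelMap(mask.astype(np.uint8), "mitochondrion", cal)}, gt


def render_apposed_slabs_3d(
    gap_nm: float,
    side_nm: float = 1000.0,
    thickness_nm: float = 100.0,
    px_nm: float = 10.0,
    px_z_nm: Optional[float] = None,
    margin_px: int = 6,
    overhang_px: int = 6,
):
    """A mitochondrial slab apposed by a thin parallel ER sheet (normal z).

    The ER sheet is one voxel thick and the mitochondrion overhangs it
    laterally, so every ER surface voxel lies at exactly ``gap_nm`` (an
    integer number of slices) from the mitochondrial surface.
    """
    cal = _cal3d(px_nm, px_z_nm)
    sp = cal.spacing(3)
    k = gap_nm / sp[0]
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError("gap_nm must be a positive integer multiple of px_z_nm")
    k = int(round(k))
    side_px = int(round(side_nm / px_nm))
    t_px = max(1, int(round(thickness_nm / sp[0])))
    nz = t_px + k + 2 + 2 * margin_px
    ny = nx = side_px + 2 * overhang_px + 2 * margin_px
    mito = np.zeros((nz, ny, nx), dtype=np.uint8)
    er = np.zeros_like(mito)
    m1 = margin_px + t_px - 1
    e0 = m1 + k
    big = slice(margin_px, margin_px + side_px + 2 * overhang_px)
    small = slice(margin_px + overhang_px, margin_px + overhang_px + side_px)
    mito[margin_px : m1 + 1, big, big] = 1
    er[e0, small, small] = 1
    area_um2 = (side_px * px_nm / 1000.0) ** 2
    gt = GroundTruth(
        gap_nm=k * sp[0],
        contact_area_um2=area_um2,
        cleft_volume_um3=area_um2 * (k * sp[0] / 1000.0),
        contact_length_um=np.sqrt(2) * (side_px - 1) * px_nm / 1000.0,
    )
    return {
        "mito": LabelMap(mito, "mitochondrion", cal),
        "er": LabelMap(er, "er", cal),
    }, gt


# ---------------------------------------------------------------------------
# dispatch, jitter, file output

_RENDERERS = {
    "disc": render_disc,
    "ellipse": render_ellipse,
    "rectangle": render_rectangle,
    "sphere": render_sphere,
    "cylinder": render_cylinder,
    "bent_tube": render_bent_tube,
    "beads_on_string": render_beads_on_string,
    "apposed_pair_2d": render_apposed_pair_2d,
    "apposed_slabs_3d": render_apposed_slabs_3d,
    "cristae_mix": render_cristae_mix,
    "wrap_sheath": render_wrap_sheath,
}


def render(spec: PhantomSpec) -> tuple[dict[str, LabelMap], GroundTruth]:
    """Render a phantom spec to label map(s) plus analytic ground truth."""
    if spec.kind not in _RENDERERS:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")
    fn = _RENDERERS[spec.kind]
    kwargs = dict(spec.params)
    kwargs.setdefault("px_nm", spec.px_nm)
    if spec.kind in _KINDS_3D and spec.kind not in ("bent_tube", "beads_on_string"):
        kwargs.setdefault("px_z_nm", spec.px_z_nm)
    maps, gt = fn(**kwargs)
    if spec.jitter_amplitude_px > 0:
        maps = {
            name: jitter(lm, spec.jitter_amplitude_px, spec.seed + i)
            for i, (name, lm) in enumerate(maps.items())
        }
    return maps, gt


def _topology_signature(mask: np.ndarray) -> tuple[int, int]:
    struct = np.ones((3,) * mask.ndim, dtype=bool)
    _, n_fg = ndimage.label(mask, structure=struct)
    _, n_bg = ndimage.label(~mask, structure=ndimage.generate_binary_structure(mask.ndim, 1))
    return n_fg, n_bg


def jitter(
    map_: LabelMap, amplitude_px: float, seed: int, max_retries: int = 20
) -> LabelMap:
    """Randomly flip boundary elements to simulate segmentation noise.

    Each foreground boundary element and each background element adjacent
    to foreground flips independently with probability
    ``min(0.9, 0.25 * amplitude_px)``.  Object/hole topology is re-checked
    and broken samples are redrawn (up to ``max_retries``).
    """
    if amplitude_px < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude_px == 0:
        return map_
    p = min(0.9, 0.25 * amplitude_px)
    fg = map_.foreground()
    sig = _topology_signature(fg)
    struct = ndimage.generate_binary_structure(fg.ndim, 1)
    boundary = fg & ~ndimage.binary_erosion(fg, struct, border_value=0)
    halo = ndimage.binary_dilation(fg, struct) & ~fg
    struct_full = np.ones((3,) * fg.ndim, dtype=bool)
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        flips = (boundary | halo) & (rng.random(fg.shape) < p)
        new_fg = fg ^ flips
        # repair: drop added pixels detached from the object body
        body = new_fg & fg
        lab, n = ndimage.label(new_fg, structure=struct_full)
        keep = np.zeros(n + 1, dtype=bool)
        keep[np.unique(lab[body])] = True
        keep[0] = False
        new_fg = keep[lab]
        # repair: fill background pockets created by the flips (pockets
        # overlapping an original hole are legitimate and stay open)
        orig_holes = ndimage.binary_fill_holes(fg) & ~fg
        pockets = ndimage.binary_fill_holes(new_fg) & ~new_fg
        plab, np_ = ndimage.label(pockets, structure=struct)
        legit = np.zeros(np_ + 1, dtype=bool)
        legit[np.unique(plab[orig_holes & pockets])] = True
        legit[0] = True
        new_fg |= ~legit[plab]
        if _topology_signature(new_fg) == sig:
            labels = np.where(new_fg, np.maximum(map_.labels, 1), 0)
            # keep original ids where present; grown pixels inherit a neighbor id
            grown = new_fg & (map_.labels == 0)
            if grown.any():
                _, idx = ndimage.distance_transform_edt(
                    map_.labels == 0, return_indices=True
                )
                labels[grown] = map_.labels[tuple(ix[grown] for ix in idx)]
            return LabelMap(
                labels.astype(map_.labels.dtype), map_.organelle_class, map_.calibration
            )
    raise RuntimeError("jitter retry limit exceeded without preserving topology")


def write_phantom(
    spec: PhantomSpec, out_dir: str, fmt: str = "tif", hdf5_dataset: str = "labels"
) -> dict:
    """Render and write label files plus a ground-truth JSON; returns a
    manifest of written paths."""
    import os

    from .core import save_label_map

    os.makedirs(out_dir, exist_ok=True)
    maps, gt = render(spec)
    manifest = {"kind": spec.kind, "files": {}, "ground_truth": gt.to_dict()}
    for name, lm in maps.items():
        path = os.path.join(out_dir, f"{name}.{fmt}")
        save_label_map(lm, path, hdf5_dataset=hdf5_dataset)
        manifest["files"][name] = path
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
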