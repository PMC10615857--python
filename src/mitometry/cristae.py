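"""Cristae metrics inside each mitochondrion.

Cristae components are 8-connected components of the cristae label map,
assigned to the enclosing mitochondrion by majority pixel overlap and
clipped to its support before measuring.  "Volume density" is the
stereological areal fraction (sum of crista area over mitochondrion
profile area); "surface" is reported as total crista membrane length in
μm, with an optional section-thickness conversion.

Cristae scores (0–4, human-assigned) are validated and aggregated, never
computed: scoring is a subjective judgment by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .core import NM_PER_UM, LabelMap, LabelMapError
from .morpho2d import EIGHT_CONN_2D, _require_isotropic_2d, boundary_length_px

SCORE_MIN = 0
SCORE_MAX = 4
DEFAULT_LAMELLAR_MIN_ASPECT = 3.0

LAMELLAR = "lamellar"
TUBULAR = "tubular"


@dataclass
class CristaRecord:
    mito_id: int
    crista_id: int
    area_um2: float
    membrane_length_um: float
    aspect_ratio: float
    shape_class: str


@dataclass
class ScoreStats:
    n: int
    mean: Optional[float]
    median: Optional[float]
    note: str = "cristae scoring is a subjective judgment; scores are human input"


@dataclass
class CristaeSummary:
    mito_id: int
    cristae_count: int
    total_crista_area_um2: float
    volume_density: float
    surface_proxy_um: float
    pct_lamellar: float
    pct_tubular: float
    score_stats: Optional[ScoreStats] = None


@dataclass
class CristaeScore:
    mito_id: int
    score: int

    def __post_init__(self) -> None:
        if self.score not in range(SCORE_MIN, SCORE_MAX + 1):
            raise ValueError(
                f"cristae score for mito {self.mito_id} is {self.score}; "
                f"admissible range is {SCORE_MIN}..{SCORE_MAX}"
            )


def classify_crista(
    aspect_ratio: float, lamellar_min_aspect: float = DEFAULT_LAMELLAR_MIN_ASPECT
) -> str:
    """Lamellar iff the second-moment aspect ratio is >= the threshold."""
    return LAMELLAR if aspect_ratio >= lamellar_min_aspect else TUBULAR


def measure_cristae(
    mito_map: LabelMap,
    cristae_map: LabelMap,
    lamellar_min_aspect: float = DEFAULT_LAMELLAR_MIN_ASPECT,
) -> tuple[list[CristaRecord], list[CristaeSummary]]:
    """Measure cristae per mitochondrion in matched 2D label maps.

    Returns per-crista records and per-mitochondrion summaries.  Crista
    components with zero mitochondrial overlap are excluded and counted
    in the summary of mito_id 0 is NOT produced; they are simply dropped
    after being reported via a warning.
    """
    import warnings

    if mito_map.dims != 2 or cristae_map.dims != 2:
        raise LabelMapError("measure_cristae requires 2D label maps")
    if mito_map.shape != cristae_map.shape:
        raise LabelMapError(
            f"shape mismatch: mito {mito_map.shape} vs cristae {cristae_map.shape}"
        )
    if mito_map.calibration != cristae_map.calibration:
        raise LabelMapError("mito and cristae maps must share a calibration")

    px_nm = _require_isotropic_2d(mito_map)
    px_area_um2 = mito_map.calibration.pixel_area_nm2 / NM_PER_UM**2
    px_um = px_nm / NM_PER_UM

    comp, n_comp = ndimage.label(cristae_map.foreground(), structure=EIGHT_CONN_2D)
    mito_filled = {
        int(mid): ndimage.binary_fill_holes(mito_map.mask(int(mid)))
        for mid in mito_map.object_ids()
    }

    records: list[CristaRecord] = []
    per_mito: dict[int, list[CristaRecord]] = {int(m): [] for m in mito_filled}
    n_orphans = 0
    for cid in range(1, n_comp + 1):
        cmask = comp == cid
        # majority overlap against filled mitochondrion profiles
        best_mid, best_overlap = 0, 0
        for mid, mmask in mito_filled.items():
            ov = int(np.count_nonzero(cmask & mmask))
            if ov > best_overlap:
                best_mid, best_overlap = mid, ov
        if best_overlap == 0:
            n_orphans += 1
            continue
        clipped = cmask & mito_filled[best_mid]
        props = regionprops(clipped.astype(np.uint8))[0]
        minor = props.axis_minor_length
        aspect = float(props.axis_major_length / minor) if minor > 0 else float("inf")
        rec = CristaRecord(
            mito_id=best_mid,
            crista_id=cid,
            area_um2=int(clipped.sum()) * px_area_um2,
            membrane_length_um=boundary_length_px(clipped) * px_um,
            aspect_ratio=aspect,
            shape_class=classify_crista(aspect, lamellar_min_aspect),
        )
        records.append(rec)
        per_mito[best_mid].append(rec)

    if n_orphans:
        warnings.warn(
            f"{n_orphans} crista component(s) had no mitochondrial overlap "
            "and were excluded",
            stacklevel=2,
        )

    summaries = []
    for mid, recs in sorted(per_mito.items()):
        mito_area_um2 = int(mito_filled[mid].sum()) * px_area_um2
        total_area = sum(r.area_um2 for r in recs)
        n = len(recs)
        n_lam = sum(1 for r in recs if r.shape_class == LAMELLAR)
        summaries.append(
            CristaeSummary(
                mito_id=mid,
                cristae_count=n,
                total_crista_area_um2=total_area,
                volume_density=(total_area / mito_area_um2) if mito_area_um2 else 0.0,
                surface_proxy_um=sum(r.membrane_length_um for r in recs),
                pct_lamellar=100.0 * n_lam / n if n else 0.0,
                pct_tubular=100.0 * (n - n_lam) / n if n else 0.0,
            )
        )
    return records, summaries


def surface_proxy_to_area_um2(surface_proxy_um: float, section_thickness_nm: float) -> float:
    """Optional conversion of membrane length to an area via section thickness."""
    if section_thickness_nm <= 0:
        raise ValueError("section thickness must be positive")
    return surface_proxy_um * (section_thickness_nm / NM_PER_UM)


def validate_scores(scores: Iterable[CristaeScore]) -> ScoreStats:
    """Aggregate validated human cristae scores into mean/median/n."""
    vals = [s.score for s in scores]
    if not vals:
        return ScoreStats(n=0, mean=None, median=None)
    return ScoreStats(
        n=len(vals), mean=float(np.mean(vals)), median=float(np.median(vals))
    )


def scores_from_frame(df) -> list[CristaeScore]:
    """Build validated scores from a DataFrame with columns mito_id, score."""
    return [
        CristaeScore(mito_id=int(row.mito_id), score=int(row.score))
        for row in df.itertuples(index=False)
    ]
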