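"""Equal-volume parcellation of peritumoral edema into inner/middle/outer zones.

The enhancing tumor core seeds a Euclidean distance expansion: every edema
voxel is assigned its distance (mm, anisotropy-aware) to the nearest core
voxel.  Sorting the included edema voxels by that distance and cutting the
order into thirds yields three zones of equal volume — the inner zone (IZ)
hugging the core outline, the outer zone (OZ) at the edema boundary, and
the middle zone (MZ) between them.

Before parcellation, voxels that could be contaminated by partial-volume
effects are excluded: edema voxels within a configurable margin of the
core (face-connected dilation) and edema voxels face-adjacent to gray
matter.

Determinism: ties in distance are broken by flat voxel index after a
stable sort, and remainder voxels (N mod n_zones) are assigned
innermost-first, so the parcellation is invariant to traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateParcellationError

__all__ = ["ZoneParcellation", "ZONE_LABELS", "exclude_margins",
           "distance_from_core", "partition_equal_volume", "parcellate"]

ZONE_LABELS = {"IZ": 1, "MZ": 2, "OZ": 3}

# label codes of the synthetic label volumes (see phantom module)
LABEL_BACKGROUND, LABEL_CORE, LABEL_EDEMA, LABEL_GM, LABEL_WM = 0, 1, 2, 3, 4

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class ZoneParcellation:
    """Zone labels and distances for one lesion.

    ``zone_map``: 0 = background/excluded, 1 = IZ, 2 = MZ, 3 = OZ.
    ``distance``: mm to the nearest core voxel, NaN outside included edema.
    ``thresholds``: maximum distance inside each zone except the last
    (the zone band edges, mm).
    """

    zone_map: np.ndarray
    distance: np.ndarray
    thresholds: tuple[float, ...]
    zone_counts: dict[str, int]
    excluded: dict[str, int] = field(default_factory=dict)
    n_edema_total: int = 0

    @property
    def included(self) -> np.ndarray:
        return self.zone_map > 0

    def zone_mask(self, zone: str) -> np.ndarray:
        return self.zone_map == ZONE_LABELS[zone]

    def sidecar(self) -> dict:
        """JSON-serializable summary (thresholds, counts, exclusions)."""
        return {"thresholds_mm": list(self.thresholds),
                "zone_counts": dict(self.zone_counts),
                "excluded": dict(self.excluded),
                "n_edema_total": int(self.n_edema_total)}


def exclude_margins(core: np.ndarray, edema: np.ndarray,
                    gm: np.ndarray | None = None,
                    margin_vox: int = 1) -> tuple[np.ndarray, dict[str, int]]:
    """Included edema voxels after margin and gray-matter exclusions.

    Removes edema voxels within ``margin_vox`` face-connected dilation
    steps of the core, and edema voxels face-adjacent to gray matter.

    Returns the included boolean mask and a tally per exclusion reason.

    Raises
    ------
    DegenerateParcellationError
        If nothing remains.
    """
    core = np.asarray(core, bool)
    edema = np.asarray(edema, bool)
    if core.any() and edema.any() and (core & edema).any():
        raise ValueError("core and edema masks overlap")
    included = edema.copy()
    tallies = {"margin": 0, "gray-matter": 0}
    if margin_vox > 0:
        dilated = ndimage.binary_dilation(core, structure=_FACE_STRUCT,
                                          iterations=margin_vox)
        hit = included & dilated
        tallies["margin"] = int(hit.sum())
        included &= ~hit
    if gm is not None and np.asarray(gm, bool).any():
        near_gm = ndimage.binary_dilation(np.asarray(gm, bool), structure=_FACE_STRUCT)
        hit = included & near_gm
        tallies["gray-matter"] = int(hit.sum())
        included &= ~hit
    if not included.any():
        raise DegenerateParcellationError("all edema voxels excluded")
    return included, tallies


def distance_from_core(core: np.ndarray, included: np.ndarray,
                       spacing: tuple[float, float, float]) -> np.ndarray:
    """Euclidean distance (mm) from each included voxel to the nearest core voxel.

    Computed with a sampled exact Euclidean distance transform of the core
    complement, so anisotropic voxels are handled through ``spacing``.
    Returns NaN outside ``included``.
    """
    core = np.asarray(core, bool)
    if not core.any():
        raise ValueError("core mask is empty")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("voxel spacing must be positive")
    dist = ndimage.distance_transform_edt(~core, sampling=spacing)
    out = np.where(included, dist, np.nan)
    return out


def partition_equal_volume(distance: np.ndarray, included: np.ndarray,
                           n_zones: int = 3) -> ZoneParcellation:
    """Cut the included voxels into ``n_zones`` equal-count distance bands.

    Voxels are ordered by (distance, flat index) with a stable sort;
    the first ceil(N/n) go to the innermost zone and remainders are
    assigned innermost-first.
    """
    if n_zones < 2:
        raise ValueError("need at least 2 zones")
    included = np.asarray(included, bool)
    flat_idx = np.flatnonzero(included.ravel())
    d = distance.ravel()[flat_idx]
    n = flat_idx.size
    if n < n_zones:
        raise DegenerateParcellationError(
            f"{n} included voxels cannot form {n_zones} zones")

    order = np.argsort(d, kind="stable")     # ties keep flat-index order
    sizes = [n // n_zones + (1 if i < n % n_zones else 0) for i in range(n_zones)]

    zone_map = np.zeros(distance.shape, dtype=np.int8)
    thresholds = []
    pos = 0
    names = ["IZ", "MZ", "OZ"] if n_zones == 3 else [f"Z{i+1}" for i in range(n_zones)]
    counts = {}
    flat_zone = zone_map.ravel()
    for i, size in enumerate(sizes):
        sel = flat_idx[order[pos:pos + size]]
        flat_zone[sel] = i + 1
        counts[names[i]] = size
        if i < n_zones - 1:
            thresholds.append(float(d[order[pos + size - 1]]))
        pos += size

    return ZoneParcellation(zone_map=zone_map,
                            distance=np.where(included, distance, np.nan),
                            thresholds=tuple(thresholds),
                            zone_counts=counts,
                            n_edema_total=n)


def parcellate(core: np.ndarray, edema: np.ndarray,
               spacing: tuple[float, float, float],
               gm: np.ndarray | None = None,
               margin_vox: int = 1, n_zones: int = 3) -> ZoneParcellation:
    """exclude_margins -> distance_from_core -> partition_equal_volume."""
    included, tallies = exclude_margins(core, edema, gm=gm, margin_vox=margin_vox)
    dist = distance_from_core(core, included, spacing)
    parc = partition_equal_volume(dist, included, n_zones=n_zones)
    parc.excluded = tallies
    parc.n_edema_total = int(np.asarray(edema, bool).sum())
    return parc
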