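"""Per-subject, per-zone aggregation of parameter maps and zone gradients."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .zonation import ZoneParcellation

__all__ = ["METRICS", "SubjectZoneSummary", "summarize_zones", "gradients",
           "tidy_frame"]

METRICS = ("fa", "md", "d_ax_intra", "d_ax_extra", "v_intra", "v_csf")
ZONES = ("IZ", "MZ", "OZ")


@dataclass
class SubjectZoneSummary:
    """Zone-level scalars for one subject.

    ``values[metric][zone]`` is the chosen statistic over the zone's valid
    voxels.  ``edema_volume_ml`` counts included (post-exclusion) voxels;
    ``edema_volume_total_ml`` the full edema mask before exclusions.
    """

    subject_id: str
    group: str
    values: dict[str, dict[str, float]]
    zone_counts: dict[str, int]
    edema_volume_ml: float
    edema_volume_total_ml: float
    statistic: str = "mean"
    complete: bool = True
    invalid_voxels: dict[str, int] = field(default_factory=dict)


def summarize_zones(maps: dict[str, np.ndarray], parcellation: ZoneParcellation,
                    spacing: tuple[float, float, float],
                    subject_id: str = "subj", group: str = "",
                    statistic: str = "mean") -> SubjectZoneSummary:
    """Aggregate each metric map over each zone.

    NaN voxels (failed fits) are dropped from the aggregation and tallied;
    a zone left with no valid voxel for some metric marks the subject
    incomplete.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    agg = np.nanmean if statistic == "mean" else np.nanmedian
    for name, arr in maps.items():
        if arr.shape != parcellation.zone_map.shape:
            raise ValueError(f"map {name!r} does not share the parcellation grid")

    values: dict[str, dict[str, float]] = {}
    invalid: dict[str, int] = {}
    complete = True
    for name, arr in maps.items():
        values[name] = {}
        for zone in ZONES:
            vox = arr[parcellation.zone_mask(zone)]
            n_bad = int(np.isnan(vox).sum())
            invalid[f"{name}/{zone}"] = n_bad
            if vox.size - n_bad == 0:
                values[name][zone] = np.nan
                complete = False
            else:
                with np.errstate(invalid="ignore"):
                    values[name][zone] = float(agg(vox))

    voxel_ml = float(np.prod(spacing)) / 1000.0
    n_inc = int(parcellation.included.sum())
    return SubjectZoneSummary(
        subject_id=subject_id, group=group, values=values,
        zone_counts=dict(parcellation.zone_counts),
        edema_volume_ml=n_inc * voxel_ml,
        edema_volume_total_ml=parcellation.n_edema_total * voxel_ml,
        statistic=statistic, complete=complete, invalid_voxels=invalid)


def gradients(summary: SubjectZoneSummary) -> dict[str, dict[str, float]]:
    """Zone differences normalized to the inner zone: MZ-IZ and OZ-IZ per metric.

    Incomplete subjects propagate NaN for the affected metrics.
    """
    out = {}
    for metric, zones in summary.values.items():
        out[metric] = {"MZ-IZ": zones["MZ"] - zones["IZ"],
                       "OZ-IZ": zones["OZ"] - zones["IZ"]}
    return out


def tidy_frame(summaries: list[SubjectZoneSummary]) -> pd.DataFrame:
    """Long-format table: subject, group, metric, zone, value (+ volumes)."""
    rows = []
    for s in summaries:
        for metric, zones in s.values.items():
            for zone, v in zones.items():
                rows.append({"subject": s.subject_id, "group": s.group,
                             "metric": metric, "zone": zone, "value": v,
                             "edema_volume_ml": s.edema_volume_ml,
                             "complete": s.complete})
    return pd.DataFrame(rows)
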