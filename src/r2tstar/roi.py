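"""Region-wise aggregation: median R2t* per labeled region and
skull-normalized volumes.

Medians (rather than means) are used so that a handful of mislabeled or
artifact voxels at region boundaries cannot drag the regional value; the
fit quality mask is intersected before the median for the same reason.
Volumes, by contrast, count ALL labeled voxels — atrophy measurement must
not depend on fit quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ROILabelMap",
    "SkullScaling",
    "LIMBIC_REGIONS",
    "region_median",
    "normalized_volume",
    "summarize_subject",
]

#: The default region set: limbic-system cortical and subcortical regions,
#: each analyzed per hemisphere.
LIMBIC_REGIONS = (
    "hippocampus",
    "amygdala",
    "parahippocampal",
    "insula",
    "entorhinal",
    "lateral_orbitofrontal",
    "medial_orbitofrontal",
    "caudal_anterior_cingulate",
    "rostral_anterior_cingulate",
    "isthmus_cingulate",
    "posterior_cingulate",
)

HEMISPHERES = ("left", "right")


@dataclass
class ROILabelMap:
    """Integer label volume plus its lookup table.

    ``label_table`` columns: label_id, region_name, hemisphere (one of
    'left', 'right', 'none'); FreeSurfer-convention naming plugs in directly
    but any conforming table works.
    """

    labels: np.ndarray
    label_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        required = {"label_id", "region_name", "hemisphere"}
        if not required.issubset(self.label_table.columns):
            raise ValueError(f"label table needs columns {sorted(required)}")
        ids = self.label_table["label_id"]
        if ids.duplicated().any():
            raise ValueError("label_ids must be unique")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(ids)
        if missing:
            raise ValueError(f"labels present in volume but not in table: {sorted(missing)}")

    def lookup(self, region_name: str, hemisphere: str) -> int | None:
        t = self.label_table
        row = t[(t.region_name == region_name) & (t.hemisphere == hemisphere)]
        return int(row.label_id.iloc[0]) if len(row) else None


@dataclass(frozen=True)
class SkullScaling:
    """Volumetric normalization factor (dimensionless, > 0) that scales raw
    regional volume to skull-normalized volume (NV)."""

    scaling_factor: float

    def __post_init__(self) -> None:
        if self.scaling_factor <= 0:
            raise ValueError("scaling_factor must be > 0")


def region_median(
    value_map: np.ndarray,
    labels: ROILabelMap,
    label_id: int,
    quality_mask: np.ndarray | None = None,
) -> tuple[float, int]:
    """Median of ``value_map`` over voxels with ``label_id`` inside the
    quality mask; returns (median, n_voxels).  Empty selection yields
    (nan, 0) — a missing value, not an error."""
    value_map = np.asarray(value_map)
    if value_map.shape != labels.labels.shape:
        raise ValueError("value map and label volume shapes must match")
    sel = labels.labels == label_id
    if quality_mask is not None:
        if quality_mask.shape != sel.shape:
            raise ValueError("quality mask shape must match label volume")
        sel &= quality_mask
    n = int(sel.sum())
    if n == 0:
        return float("nan"), 0
    return float(np.median(value_map[sel])), n


def normalized_volume(n_voxels: int, voxel_volume: float, scaling: SkullScaling) -> float:
    """NV = n_voxels * voxel_volume * scaling_factor (mm^3)."""
    if n_voxels < 0 or voxel_volume < 0:
        raise ValueError("inputs must be non-negative")
    return n_voxels * voxel_volume * scaling.scaling_factor


def summarize_subject(
    r2t_star_map: np.ndarray,
    labels: ROILabelMap,
    scaling: SkullScaling,
    voxel_volume: float,
    subject_id: str,
    quality_mask: np.ndarray | None = None,
    region_set=None,
    hemispheres=HEMISPHERES,
) -> pd.DataFrame:
    """One row per (region, hemisphere): median R2t*, raw and normalized
    volume.  Regions absent from the label volume emit rows with missing
    markers (NaN) rather than failing the subject."""
    if region_set is None:
        region_set = LIMBIC_REGIONS
    rows = []
    for region in region_set:
        for hemi in hemispheres:
            label_id = labels.lookup(region, hemi)
            if label_id is None:
                rows.append(
                    dict(
                        subject_id=subject_id, region_name=region, hemisphere=hemi,
                        median_r2t_star=np.nan, n_voxels=0,
                        volume_mm3=np.nan, normalized_volume=np.nan,
                    )
                )
                continue
            med, _ = region_median(r2t_star_map, labels, label_id, quality_mask)
            n_all = int((labels.labels == label_id).sum())
            vol = n_all * voxel_volume
            rows.append(
                dict(
                    subject_id=subject_id, region_name=region, hemisphere=hemi,
                    median_r2t_star=med, n_voxels=n_all,
                    volume_mm3=vol if n_all else np.nan,
                    normalized_volume=(
                        normalized_volume(n_all, voxel_volume, scaling) if n_all else np.nan
                    ),
                )
            )
    return pd.DataFrame(rows)
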