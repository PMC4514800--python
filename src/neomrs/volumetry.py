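"""Region volumes and MRS-voxel tissue composition from a label map.

The voxel-composition computation is analytic: the MRS voxel and every atlas
cell are axis-aligned boxes, so per-cell overlap volumes factor into three
1-D interval overlaps, which are exact (no rasterization error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LabelMap, VoxelGeometry
from .errors import DomainError

#: Aggregate definitions mirroring the study's volume table: name -> labels.
DEFAULT_AGGREGATES = {
    "cortex": ("cingulate_cortex", "frontal_cortex", "medial_frontal_cortex",
               "parietal_cortex"),
    "basal_ganglia": ("striatum", "thalamus"),
}

#: Labels counted as "cortical tissue" in an MRS-voxel composition.
CORTEX_FRACTION_LABELS = DEFAULT_AGGREGATES["cortex"]


def voxel_volume(dims_mm) -> float:
    """Volume of an MRS voxel box in uL (1 mm^3 == 1 uL)."""
    dims = np.asarray(dims_mm, dtype=float)
    if np.any(dims <= 0):
        raise DomainError("voxel dimensions must be positive")
    return float(np.prod(dims))


def region_volumes(label_map: LabelMap, background_label=0,
                   csf_names=("csf",), aggregates=None) -> pd.Series:
    """Per-label volumes (mm^3): voxel count x voxel volume.

    Adds aggregate rows: ``brain`` is the sum of all non-background,
    non-CSF labels; further aggregates (default: cortex as the sum of its
    sub-regions, basal ganglia as striatum+thalamus) are configurable.
    Background is excluded throughout.
    """
    vv = label_map.voxel_volume_mm3
    ids, counts = np.unique(label_map.volume, return_counts=True)
    vols = {}
    for lid, cnt in zip(ids, counts):
        if lid == background_label:
            continue
        vols[label_map.label_names[int(lid)]] = float(cnt) * vv
    out = pd.Series(vols, dtype=float, name="volume_mm3")
    if len(out):
        brain = sum(v for k, v in vols.items() if k not in csf_names)
        agg = {"brain": brain}
        for name, members in (aggregates or DEFAULT_AGGREGATES).items():
            present = [m for m in members if m in vols]
            if present:
                agg[name] = sum(vols[m] for m in present)
        out = pd.concat([out, pd.Series(agg, dtype=float)])
        out.name = "volume_mm3"
    return out


@dataclass
class CompositionResult:
    """Tissue composition of one MRS voxel."""

    table: pd.DataFrame          # per label: overlap_mm3, fraction_pct
    total_volume_ul: float
    dominant_label: str
    clipped: bool = False

    def fraction(self, label_name) -> float:
        if label_name not in self.table.index:
            return 0.0
        return float(self.table.loc[label_name, "fraction_pct"])


def voxel_composition(voxel: VoxelGeometry,
                      label_map: LabelMap) -> CompositionResult:
    """Exact per-label overlap of an axis-aligned voxel with the label map.

    For each axis the overlap of the voxel interval with every atlas-cell
    interval is computed in closed form; the per-cell overlap volume is the
    outer product of the three 1-D overlaps, accumulated per label.
    Fractions are percentages of the voxel volume actually inside the map
    (a voxel partly outside is clipped with a warning; entirely outside is
    an error).
    """
    lo = voxel.lo_mm - label_map.origin_mm
    hi = voxel.hi_mm - label_map.origin_mm
    h = label_map.voxel_size_mm
    shape = np.array(label_map.volume.shape)
    extent = shape * h
    if np.any(hi <= 0) or np.any(lo >= extent):
        raise DomainError("MRS voxel lies entirely outside the label map")
    clipped = bool(np.any(lo < 0) or np.any(hi > extent))
    if clipped:
        warnings.warn("MRS voxel extends beyond the label map; clipping",
                      stacklevel=2)
    overlaps = []
    slices = []
    for ax in range(3):
        i0 = max(int(np.floor(lo[ax] / h[ax])), 0)
        i1 = min(int(np.ceil(hi[ax] / h[ax])), shape[ax])
        edges_lo = np.arange(i0, i1) * h[ax]
        edges_hi = edges_lo + h[ax]
        ov = np.minimum(edges_hi, hi[ax]) - np.maximum(edges_lo, lo[ax])
        overlaps.append(np.clip(ov, 0.0, None))
        slices.append(slice(i0, i1))
    w = overlaps[0][:, None, None] * overlaps[1][None, :, None] \
        * overlaps[2][None, None, :]
    sub = label_map.volume[slices[0], slices[1], slices[2]]
    acc = np.bincount(sub.ravel(), weights=w.ravel())
    total = float(acc.sum())
    if total <= 0:
        raise DomainError("MRS voxel has zero overlap with the label map")
    rows = {}
    for lid, vol in enumerate(acc):
        if vol > 0:
            rows[label_map.label_names[int(lid)]] = vol
    table = pd.DataFrame({"overlap_mm3": pd.Series(rows)})
    table["fraction_pct"] = table["overlap_mm3"] / total * 100.0
    table = table.sort_values("overlap_mm3", ascending=False)
    return CompositionResult(
        table=table, total_volume_ul=round(total, 10),
        dominant_label=table.index[0], clipped=clipped)


def aggregate_fraction(result: CompositionResult, labels) -> float:
    """Summed fraction (%) of a set of labels (e.g. the cortex sub-regions)."""
    return float(sum(result.fraction(name) for name in labels))
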