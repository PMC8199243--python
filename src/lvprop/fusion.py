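"""Fuse same-label superpixels into LV candidate regions.

After every superpixel has a dictionary label, the LV-labeled regions are
merged; each 8-connected component of the merged mask is one candidate
region.  At training time the candidate closest to the labeled LV center is
the "salient" region used to build the saliency anchor; at test time every
candidate proceeds to anchor generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .phantoms import mask_to_box
from .superpixels import SuperpixelPartition

__all__ = ["CandidateRegion", "fuse", "select_salient"]


@dataclass
class CandidateRegion:
    """One fused LV candidate: a single 8-connected binary component."""

    region_id: int
    mask: np.ndarray
    centroid: tuple[float, float]  # (row, col)
    bounding_box: tuple[int, int, int, int]  # (x1, y1, x2, y2) half-open
    area: int
    source_ids: list[int]


def fuse(
    partition: SuperpixelPartition,
    labels: np.ndarray,
    lv_class: int = 1,
    min_area: int = 20,
) -> list[CandidateRegion]:
    """Merge LV-labeled superpixels and split into connected candidates.

    ``labels`` holds one class label per superpixel (aligned with region
    ids).  The union of LV-labeled superpixels is decomposed into
    8-connected components; components smaller than ``min_area`` pixels are
    discarded as speckle (set ``min_area=0`` to keep everything).  Returns
    candidates sorted by descending area.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != partition.n_regions:
        raise ValueError("need exactly one label per superpixel region")
    lv_mask = np.isin(partition.label_map, np.flatnonzero(labels == lv_class))
    if not lv_mask.any():
        return []
    comps = cc_label(lv_mask, connectivity=2)
    out = []
    for cid in range(1, comps.max() + 1):
        m = comps == cid
        area = int(m.sum())
        if area < min_area:
            continue
        rows, cols = np.nonzero(m)
        out.append(
            CandidateRegion(
                region_id=cid - 1,
                mask=m,
                centroid=(float(rows.mean()), float(cols.mean())),
                bounding_box=mask_to_box(m),
                area=area,
                source_ids=sorted(np.unique(partition.label_map[m]).tolist()),
            )
        )
    out.sort(key=lambda r: (-r.area, r.region_id))
    return out


def select_salient(
    candidates: list[CandidateRegion],
    reference_center: tuple[float, float],
) -> CandidateRegion:
    """Candidate whose centroid is nearest the reference center (row, col).

    Ties on distance go to the larger area, then the lower region id.
    Raises ``ValueError`` on an empty candidate list.
    """
    if not candidates:
        raise ValueError("no candidate region available")
    ry, rx = reference_center

    def key(c: CandidateRegion):
        d = float(np.hypot(c.centroid[0] - ry, c.centroid[1] - rx))
        return (round(d, 9), -c.area, c.region_id)

    return min(candidates, key=key)
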