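"""Phase IV: condensing the registered, irregular z-stack into voxel slabs.

Slide numbers encode physical position (sections are l_s = 5 µm apart, with
gaps where slides were discarded), while the coarse-grained pixels are
l_r ~ 47.5 µm long.  The stack is therefore partitioned into ranges of one
voxel thickness — range z covers slide numbers s with

    z * l_r / l_s <= s < (z + 1) * l_r / l_s

— and each range is condensed into one *representative slide* by pooling the
nuclei of its substack and re-running the regional classification on the
pooled multiset.  Counts become the average cross-sectional nuclear count
(pooled total / number of source slides).  A range holding a single
surviving slide borrows the nearest surviving slide outside the range; an
empty range borrows the nearest survivors on each side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import RegionalSlide, RegionParams, grid_from_nuclei

__all__ = ["partition_ranges", "build_representative", "assemble_stack", "Volume"]


def partition_ranges(slide_numbers: list[int], l_r: float, l_s: float
                     ) -> list[tuple[int, tuple[int, ...]]]:
    """Substack (range) membership per representative-slide index z.

    Ties when borrowing the nearest outside slide break to the lower number.
    """
    if not slide_numbers:
        raise ValueError("empty stack")
    if not l_r > l_s > 0:
        raise ValueError("need l_r > l_s > 0")
    s = np.array(sorted(slide_numbers))
    q = l_r / l_s
    z_lo = int(np.floor(s.min() / q))
    z_hi = int(np.floor(s.max() / q))
    out = []
    for z in range(z_lo, z_hi + 1):
        lo, hi = z * q, (z + 1) * q
        members = [int(v) for v in s[(s >= lo) & (s < hi)]]
        if len(members) == 1:
            outside = s[(s < lo) | (s >= hi)]
            if len(outside):
                d = np.abs(outside - members[0])
                best = outside[np.lexsort((outside, d))][0]
                members.append(int(best))
        elif not members:
            below = s[s < lo]
            above = s[s >= hi]
            if len(below):
                members.append(int(below.max()))
            if len(above):
                members.append(int(above.min()))
        out.append((z, tuple(sorted(members))))
    return out


def build_representative(substack: list[RegionalSlide], z_index: int = 0,
                         params: RegionParams | None = None) -> RegionalSlide:
    """Pool nuclei across a substack and classify voxels like Phase II.

    The voxel count planes carry the average cross-sectional count: pooled
    nuclei divided by the number of source slides.
    """
    if not substack:
        raise ValueError("empty substack")
    n = len(substack)
    nuclei = pd.concat([s.nuclei for s in substack], ignore_index=True)
    planes = grid_from_nuclei(nuclei, substack[0].frame_shape, params, divisor=n)
    return RegionalSlide(nuclei=nuclei, slide_number=z_index,
                         pitch_um=substack[0].pitch_um,
                         source_slides=tuple(s.slide_number for s in substack),
                         **planes)


@dataclass
class Volume:
    """Voxel stack of representative slides (z = slab index).

    Plane arrays are (Z, H, W); ``nuclei`` keeps the per-slab pooled nuclear
    tables (for the homogeneity weighting, which needs individual angles).
    """

    category: np.ndarray
    theta: np.ndarray
    count: np.ndarray
    count_all: np.ndarray
    count_small: np.ndarray
    nuclei: list
    pitch_um: float
    z_indices: tuple
    sources: tuple

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.category.shape


def assemble_stack(stack: list[RegionalSlide], l_r: float | None = None,
                   l_s: float = 5.0, params: RegionParams | None = None,
                   crop: bool = True) -> Volume:
    """Partition a registered stack by slide number and build the volume.

    ``crop=True`` trims the padded frame to the joint content bounding box
    (plus one voxel) so downstream volume passes do not walk empty padding.
    """
    by_number = {s.slide_number: s for s in stack}
    l_r = l_r or stack[0].pitch_um
    ranges = partition_ranges(sorted(by_number), l_r, l_s)
    reps = [build_representative([by_number[m] for m in members], z, params)
            for z, members in ranges]
    cat = np.stack([r.category for r in reps])
    th = np.stack([r.theta for r in reps])
    cnt = np.stack([r.count for r in reps])
    call = np.stack([r.count_all for r in reps])
    csmall = np.stack([r.count_small for r in reps])
    nuclei = [r.nuclei for r in reps]
    if crop:
        zz, yy, xx = np.nonzero(cat)
        if len(zz):
            y0, y1 = int(yy.min()) - 1, int(yy.max()) + 2
            x0, x1 = int(xx.min()) - 1, int(xx.max()) + 2
            y0, x0 = max(y0, 0), max(x0, 0)
            cat = cat[:, y0:y1, x0:x1]
            th = th[:, y0:y1, x0:x1]
            cnt = cnt[:, y0:y1, x0:x1]
            call = call[:, y0:y1, x0:x1]
            csmall = csmall[:, y0:y1, x0:x1]
            nuclei = []
            for r in reps:
                t = r.nuclei.copy()
                t["x"] -= x0
                t["y"] -= y0
                nuclei.append(t)
    return Volume(category=cat, theta=th, count=cnt, count_all=call,
                  count_small=csmall, nuclei=nuclei,
                  pitch_um=stack[0].pitch_um,
                  z_indices=tuple(z for z, _ in ranges),
                  sources=tuple(m for _, m in ranges))
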