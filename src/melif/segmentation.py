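"""Liver masks: validation / ingestion of external masks and a classical
intensity-based segmenter adequate for synthetic phantoms.

Clinical-grade segmentation is deliberately out of scope: real studies
supply masks from dedicated tools, and :func:`segment_phantom` is only
guaranteed on images with clear bimodal liver/background contrast.
Whether supplied masks exclude vessels or lesions is the caller's concern;
masks are used exactly as given.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import ball, closing

from .errors import SegmentationError, ValidationError
from .image import Geometry, LiverMask, Volume, resample_array

__all__ = ["load_mask", "segment_phantom", "mask_volume_ml"]

logger = logging.getLogger(__name__)


def load_mask(
    path: str | Path,
    expected: Geometry | None = None,
    label_id: int | None = None,
) -> LiverMask:
    """Load a binary or label mask, optionally aligning it to a geometry.

    ``label_id`` selects one label from a multi-label image; otherwise any
    nonzero voxel is foreground.  If ``expected`` differs from the stored
    geometry the mask is nearest-neighbour resampled onto it.  An empty
    result raises :class:`ValidationError`; losing more than 5% of the mask
    to the target field of view logs a warning.
    """
    raw = Volume.load(path)
    fg = raw.data == label_id if label_id is not None else raw.data > 0.5
    n_src = int(fg.sum())
    if n_src == 0:
        raise ValidationError(f"mask {path} is empty")

    if expected is None or expected.matches(raw.geometry):
        return LiverMask(fg, expected or raw.geometry)

    res = resample_array(fg.astype(float), raw.geometry, expected, order=0) > 0.5
    n_tgt = int(res.sum())
    if n_tgt == 0:
        raise ValidationError(f"mask {path} lies entirely outside the target geometry")
    if n_tgt < 0.95 * n_src * raw.geometry.voxel_volume_mm3 / expected.voxel_volume_mm3:
        logger.warning(
            "mask %s: >5%% of its volume falls outside the target field of view", path
        )
    return LiverMask(res, expected)


def segment_phantom(image: Volume, closing_radius: int = 2) -> LiverMask:
    """Segment the liver from a phantom hepatobiliary-phase image.

    Otsu threshold -> largest connected component -> morphological closing
    -> hole filling.  Phantom-only: assumes bimodal liver/background
    contrast.
    """
    data = image.data
    if np.ptp(data) <= 0:
        raise SegmentationError("uniform image: no threshold separates foreground")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise SegmentationError("no foreground voxels above the Otsu threshold")

    lab = label(fg)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    fg = lab == int(np.argmax(counts))
    if closing_radius > 0:
        fg = closing(fg, ball(closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    return LiverMask(fg, image.geometry)


def mask_volume_ml(mask: LiverMask) -> float:
    """Mask volume in millilitres: voxel count x voxel volume (mm^3) / 1000."""
    return mask.n_voxels * mask.geometry.voxel_volume_mm3 / 1000.0
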