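"""Voxel-wise T1 mapping from multi-flip-angle SPGR series.

Uses the linearized DESPOT1 formulation: for each voxel, the SPGR signals
``S_i`` acquired at flip angles ``a_i`` satisfy

    S/sin(a) = E1 * S/tan(a) + M0' * (1 - E1),   E1 = exp(-TR/T1),

so an ordinary least-squares line through the points
``(S/tan(a), S/sin(a))`` yields E1 as the slope and the proton density
from the intercept.  An optional relative-B1 map scales the nominal flip
angles voxel-wise before the fit.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError
from .image import B1Map, Geometry, T1Map, VFASeries, Volume, resample_array

__all__ = ["fit_t1_vfa", "resample_to", "T1_MIN_MS", "T1_MAX_MS"]

T1_MIN_MS = 1.0
T1_MAX_MS = 5000.0


def fit_t1_vfa(series: VFASeries, b1: B1Map | None = None) -> tuple[T1Map, Volume]:
    """Fit a T1 map and proton-density map from a variable-flip-angle series.

    Parameters
    ----------
    series:
        SPGR magnitude volumes with their nominal flip angles and TR.
    b1:
        Optional relative flip-angle scale; must share the series geometry
        (resample first with :func:`resample_to` otherwise).

    Returns
    -------
    (T1Map, Volume)
        T1 in ms with a validity mask, and the estimated proton density.
        Voxels whose regression slope falls outside (0, 1), whose signals
        are all zero, or whose T1 leaves [1, 5000] ms are flagged invalid.
    """
    if b1 is not None and not b1.geometry.matches(series.geometry):
        raise GeometryError("B1 map geometry does not match the VFA series")

    angles_rad = np.deg2rad(np.asarray(series.flip_angles_deg, dtype=float))
    signals = series.volumes  # (n, *shape)
    n = len(angles_rad)

    if b1 is None:
        a_eff = np.broadcast_to(
            angles_rad[:, None, None, None], signals.shape
        )
    else:
        a_eff = angles_rad[:, None, None, None] * b1.data[None]

    with np.errstate(divide="ignore", invalid="ignore"):
        y = signals / np.sin(a_eff)
        x = signals / np.tan(a_eff)

    sx = x.sum(axis=0)
    sy = y.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    sxy = (x * y).sum(axis=0)
    denom = n * sxx - sx * sx

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n
        t1 = -series.tr_ms / np.log(slope)
        m0 = intercept / (1.0 - slope)

    nonzero = np.any(signals > 0, axis=0)
    valid = (
        nonzero
        & np.isfinite(slope)
        & (slope > 0.0)
        & (slope < 1.0)
        & np.isfinite(t1)
        & (t1 >= T1_MIN_MS)
        & (t1 <= T1_MAX_MS)
    )
    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid & np.isfinite(m0), m0, 0.0)
    return T1Map(t1, series.geometry, valid), Volume(m0, series.geometry)


def resample_to(map_, target: Geometry, interpolation: str = "linear"):
    """Resample a T1 or B1 map onto a target geometry.

    Values are interpolated (``linear`` or ``nearest``); validity masks, when
    present, are resampled nearest-neighbour and out-of-field voxels are
    marked invalid.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0

    if isinstance(map_, B1Map):
        data = resample_array(map_.data, map_.geometry, target, order=order, cval=1.0)
        return B1Map(np.clip(data, 1e-6, 2.0), target)

    # masked quantitative map (T1Map / RRMap)
    filled = np.where(map_.valid, map_.data, 0.0)
    data = resample_array(filled, map_.geometry, target, order=order, cval=0.0)
    valid = (
        resample_array(
            map_.valid.astype(float), map_.geometry, target, order=0, cval=0.0
        )
        > 0.5
    )
    inside = (
        resample_array(
            np.ones(map_.geometry.shape), map_.geometry, target, order=0, cval=0.0
        )
        > 0.5
    )
    valid &= inside
    data = np.where(valid, data, np.nan)
    return type(map_)(data, target, valid)
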