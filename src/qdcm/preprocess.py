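"""Separation of interleaved dual-excitation data into ASL and BOLD series.

BOLD contamination is removed from the TE1 (ASL-weighted) data by
surround subtraction — each volume is differenced against the mean of
its two temporal neighbours of opposite tag/control condition — and ASL
contamination is removed from the TE2 (BOLD-weighted) data by surround
averaging.  Both operators use single-neighbour differences at the
series ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .physio import ArterialTimeseries
from .signals import AcquisitionParams, asl_difference_signal

__all__ = [
    "DexiSeries",
    "surround_subtract",
    "surround_average",
    "bold_fraction",
    "initial_perfusion_and_gm_pv",
    "invert_asl_to_cbf",
]


@dataclass
class DexiSeries:
    """Interleaved tag/control dual-excitation dataset.

    Volumes along the last axis; ``tag_first`` records the interleave
    order of the acquisition.
    """

    te1_vols: np.ndarray  # (..., T)
    te2_vols: np.ndarray  # (..., T)
    m0_vol: np.ndarray  # (...)
    mask: np.ndarray  # (...), bool
    volume_times: np.ndarray  # (T,), s
    tag_first: bool = True

    def __post_init__(self) -> None:
        if self.te1_vols.shape != self.te2_vols.shape:
            raise ValueError("te1/te2 shapes must match")
        n = self.te1_vols.shape[-1]
        if n % 2:
            raise ValueError("number of volumes must be even")
        if self.volume_times.shape != (n,):
            raise ValueError("volume_times must have one entry per volume")
        if self.m0_vol.shape != self.te1_vols.shape[:-1]:
            raise ValueError("m0_vol shape must match the spatial grid")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.m0_vol.shape:
            raise ValueError("mask shape must match the spatial grid")
        if np.any(self.mask & (self.m0_vol <= 0)):
            raise ValueError("mask includes voxels without M0 support")


def _neighbour_mean(series: np.ndarray) -> np.ndarray:
    """Sliding mean of the two temporal neighbours; one-sided at the ends."""
    nb = np.empty_like(series, dtype=float)
    nb[..., 1:-1] = 0.5 * (series[..., :-2] + series[..., 2:])
    nb[..., 0] = series[..., 1]
    nb[..., -1] = series[..., -2]
    return nb


def surround_subtract(series: np.ndarray, tag_first: bool = True,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Per-volume tag/control difference with the BOLD component removed.

    For each volume the mean of its two opposite-condition neighbours is
    subtracted (sign-corrected per parity so perfusion gives a positive
    output); linear drifts cancel to first order.  If a mask is supplied
    and the mean difference inside it is negative, the interleave order
    flag is probably wrong and a warning is raised.
    """
    series = np.asarray(series, dtype=float)
    nb = _neighbour_mean(series)
    n = series.shape[-1]
    sign = np.ones(n)
    # control volumes: self - neighbours; tag volumes: neighbours - self
    sign[::2] = -1.0 if tag_first else 1.0
    sign[1::2] = 1.0 if tag_first else -1.0
    out = sign * (series - nb)
    if mask is not None and float(out[mask].mean()) < 0:
        warnings.warn(
            "mean ASL difference negative inside mask; check tag_first flag",
            stacklevel=2,
        )
    return out


def surround_average(series: np.ndarray) -> np.ndarray:
    """Mean of each volume with its neighbour pair: removes the alternating
    (ASL) component while preserving the slow (BOLD) component."""
    series = np.asarray(series, dtype=float)
    return 0.5 * (series + _neighbour_mean(series))


def bold_fraction(te2_vols: np.ndarray, baseline_mask: np.ndarray) -> np.ndarray:
    """Fractional BOLD series: surround-average, then normalise each voxel
    by its mean over baseline (air-breathing) volumes."""
    sa = surround_average(te2_vols)
    base = sa[..., np.asarray(baseline_mask, dtype=bool)].mean(axis=-1)
    return sa / base[..., None] - 1.0


def invert_asl_to_cbf(delta_s, m0, t1_blood: float,
                      acq: AcquisitionParams) -> np.ndarray:
    """Invert the single-PLD pCASL kinetic model for CBF (ml/100g/min)."""
    delta_s = np.asarray(delta_s, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    unit = asl_difference_signal(1.0, t1_blood, 1.0, acq)  # dS per unit CBF*M0
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = delta_s / (m0 * unit)
    return np.where(np.isfinite(cbf), cbf, 0.0)


def initial_perfusion_and_gm_pv(
    asl_mean: np.ndarray,
    m0_vol: np.ndarray,
    arterial: ArterialTimeseries,
    acq: AcquisitionParams,
    mask: np.ndarray | None = None,
    dc_scale: float = 0.15,
    n_top: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Initial CBF map, grey-matter partial volume and diffusivity prior.

    The baseline-period ASL mean is inverted through the kinetic model at
    the baseline blood T1.  The grey-matter partial-volume surrogate is
    the perfusion map normalised by the median of its ``n_top``
    highest-signal voxels (clipped to [0, 1]); the diffusivity prior is
    ``dc_scale`` (ml/100g/mmHg/min) times that partial volume.
    """
    asl_mean = np.asarray(asl_mean, dtype=float)
    if mask is None:
        mask = m0_vol > 0
    mask = np.asarray(mask, dtype=bool)
    cbf_init = invert_asl_to_cbf(asl_mean, m0_vol, arterial.t1_blood_0, acq)
    cbf_init = np.clip(cbf_init, 0.0, None) * mask
    vals = cbf_init[mask]
    if vals.size < n_top:
        n_use = max(1, int(round(0.1 * vals.size)))
        warnings.warn(
            f"fewer than {n_top} masked voxels; using top {n_use} instead",
            stacklevel=2,
        )
    else:
        n_use = n_top
    top = np.sort(vals)[-n_use:]
    ref = float(np.median(top))
    if ref <= 0:
        raise ValueError("no positive perfusion signal inside mask")
    gm_pv = np.clip(cbf_init / ref, 0.0, 1.0) * mask
    dc_prior = dc_scale * gm_pv
    return cbf_init, gm_pv, dc_prior
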