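"""Forward models for the dual-excitation ASL (TE1) and BOLD (TE2) signals.

The BOLD channel follows the simplified calibration model

    dS/S0 = TE * kappa * [dHb]0 * {1 - (CBF/CBF0)**theta * ([dHb]/[dHb]0)},

with the deoxyhaemoglobin ratio driven by flow and arterial-content
changes under the isometabolic assumption.  The ASL channel is the
simplified single-PLD pCASL kinetic model

    dS = 2*alpha*alpha_inv*CBF*T1b*M0*(1-exp(-tau/T1b))*exp(-PLD/T1b)
         / (6000*lambda),

with the arterial-blood T1 varying per volume (hyperoxia shortens it).
CBF is driven by PaCO2 through the cerebrovascular reactivity:
CBF(t) = CBF0*(1 + CVR/100 * dPaCO2(t)).

``compose_dexi`` assembles raw interleaved tag/control series from the
clean ASL-difference and BOLD-fraction timecourses; it is shared by the
digital phantom generator and by the fitter's prediction path, so both
see identical tag/control bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .oxygen import OxygenLookupTable, fick_cmro2
from .physio import ArterialTimeseries

__all__ = [
    "AcquisitionParams",
    "VoxelPhysioState",
    "ForwardSignals",
    "cbf_timecourse",
    "deoxyhemoglobin_baseline",
    "dhb_ratio",
    "bold_signal",
    "asl_difference_signal",
    "forward_model",
    "compose_dexi",
]

_CBF_FLOOR = 1.0  # ml/100g/min; vasodilatory clipping floor


@dataclass(frozen=True)
class AcquisitionParams:
    """Dual-excitation pCASL acquisition parameters and model constants."""

    te1: float = 10.0  # ms, ASL-weighted echo
    te2: float = 30.0  # ms, BOLD-weighted echo
    tr: float = 4.4  # effective TR, s
    tau: float = 1.5  # labelling duration, s
    pld: float = 1.5  # post-labelling delay, s
    alpha: float = 0.85  # inversion efficiency
    alpha_inv: float = 0.88  # background-suppression efficiency factor
    lambda_bp: float = 0.9  # brain/blood partition coefficient
    theta: float = 0.06  # hypercapnic venous flow-volume/diffusion exponent
    #: residual label weighting at the second excitation (label T2*
    #: decay over te2-te1 at 3T); scales the ASL bleed into TE2 data.
    asl_te2_scale: float = 0.67
    #: static TE2 signal relative to M0 (tissue T2* decay); cancels in
    #: the fractional BOLD normalisation.
    te2_static_scale: float = 0.7

    def __post_init__(self) -> None:
        for name in ("te1", "te2", "tr", "tau", "alpha", "alpha_inv",
                     "lambda_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.pld < 0:
            raise ValueError("pld must be non-negative")
        if not (0.0 <= self.theta <= 0.5):
            raise ValueError("theta must lie in [0, 0.5]")
        if not (0 < self.alpha <= 1 and 0 < self.alpha_inv <= 1):
            raise ValueError("efficiencies must lie in (0, 1]")


@dataclass(frozen=True)
class VoxelPhysioState:
    """Voxelwise physiological parameters (fitted or ground truth)."""

    cbf0: float  # ml/100g/min
    dc: float  # ml/100g/mmHg/min
    kappa: float  # BOLD calibration parameter, 1/ms per (g/ml)
    cvr: float  # % CBF change per mmHg CO2
    m0: float  # equilibrium magnetisation, arbitrary units
    oef0: float | None = None  # derived through the lookup table
    cmro2_0: float | None = None  # umol/100g/min, derived

    def __post_init__(self) -> None:
        if not (0.0 < self.cbf0 < 200.0):
            raise ValueError("cbf0 must lie in (0, 200) ml/100g/min")
        if self.kappa <= 0:
            raise ValueError("kappa must be strictly positive")
        if not (-1.0 < self.cvr < 10.0):
            raise ValueError("cvr must lie in (-1, 10) %/mmHg")
        if self.oef0 is not None and not (0.0 < self.oef0 < 1.0):
            raise ValueError("oef0 must lie in (0, 1)")


class ForwardSignals(NamedTuple):
    asl: np.ndarray  # tag/control difference, same units as M0
    bold: np.ndarray  # fractional dS/S0
    cbf: np.ndarray  # ml/100g/min per volume
    oef0: float


def cbf_timecourse(cbf0: float, cvr: float, delta_paco2) -> np.ndarray:
    """CBF(t) = CBF0 * (1 + CVR/100 * dPaCO2(t)), clipped at a small floor."""
    if cbf0 <= 0:
        raise ValueError("cbf0 must be strictly positive")
    cbf = cbf0 * (1.0 + cvr / 100.0 * np.asarray(delta_paco2, dtype=float))
    if np.any(cbf <= _CBF_FLOOR):
        warnings.warn("CBF(t) clipped at floor; CVR/dPaCO2 combination extreme",
                      stacklevel=2)
        cbf = np.clip(cbf, _CBF_FLOOR, None)
    return cbf


def deoxyhemoglobin_baseline(hb: float, oef0: float, sao2_0: float) -> float:
    """[dHb]0 = [Hb]*(1 - SvO2,0) with SvO2,0 = SaO2,0*(1 - OEF0)."""
    if not (0.0 < oef0 < 1.0) or not (0.0 < sao2_0 <= 1.0):
        raise ValueError("oef0 in (0,1) and sao2_0 in (0,1] required")
    return hb * (1.0 - sao2_0 * (1.0 - oef0))


def dhb_ratio(cbf, cbf0: float, cao2, cao2_0: float, hb: float, oef0: float,
              sao2_0: float, check: bool = True) -> np.ndarray:
    """Deoxyhaemoglobin ratio [dHb]/[dHb]0 under isometabolic modulation.

    [dHb]/[dHb]0 = CBF0/CBF
        - (1/[dHb]0) * { (CaO2 - (CBF0/CBF)*CaO2|0)/phi
                         + [Hb]*((CBF0/CBF) - 1) }

    Equals 1 at baseline; falls below 1 for hypercapnic washout (CBF up)
    and for hyperoxia (CaO2 up at constant flow).
    """
    phi = 1.34
    dhb0 = deoxyhemoglobin_baseline(hb, oef0, sao2_0)
    r = cbf0 / np.asarray(cbf, dtype=float)
    cao2 = np.asarray(cao2, dtype=float)
    ratio = r - ((cao2 - r * cao2_0) / phi + hb * (r - 1.0)) / dhb0
    if check and np.any(ratio <= 0):
        raise ValueError("non-positive [dHb] ratio: model-inconsistent inputs")
    return ratio


def bold_signal(kappa: float, te2: float, hb: float, oef0: float,
                sao2_0: float, dhb_ratio_t, cbf_ratio_t,
                theta: float = 0.06) -> np.ndarray:
    """Fractional BOLD change dS/S0 from the simplified calibration model."""
    dhb0 = deoxyhemoglobin_baseline(hb, oef0, sao2_0)
    dhb_ratio_t = np.asarray(dhb_ratio_t, dtype=float)
    cbf_ratio_t = np.asarray(cbf_ratio_t, dtype=float)
    return te2 * kappa * dhb0 * (1.0 - cbf_ratio_t**theta * dhb_ratio_t)


def asl_difference_signal(cbf, t1_blood, m0: float,
                          acq: AcquisitionParams) -> np.ndarray:
    """Tag/control difference of the simplified single-PLD pCASL model."""
    cbf = np.asarray(cbf, dtype=float)
    t1b = np.asarray(t1_blood, dtype=float)
    return (
        2.0 * acq.alpha * acq.alpha_inv * cbf * t1b * m0
        * (1.0 - np.exp(-acq.tau / t1b)) * np.exp(-acq.pld / t1b)
        / (6000.0 * acq.lambda_bp)
    )


def forward_model(
    state: VoxelPhysioState,
    arterial: ArterialTimeseries,
    table: OxygenLookupTable | None,
    acq: AcquisitionParams,
    cbf_override: np.ndarray | None = None,
) -> ForwardSignals:
    """Predict clean ASL-difference and fractional-BOLD timecourses.

    OEF0 is tied to (CBF0, Dc) through the lookup table unless the state
    carries an explicit ``oef0`` and ``table`` is None.  ``cbf_override``
    bypasses the CVR-driven flow timecourse (hook for externally measured
    CBF(t)).
    """
    if table is not None:
        # linear extrapolation beyond the table margins can leave (0, 1)
        oef0 = float(np.clip(table.interp(state.cbf0, state.dc),
                             1e-6, 1.0 - 1e-6))
    elif state.oef0 is not None:
        oef0 = state.oef0
    else:
        raise ValueError("need a lookup table or an explicit oef0")
    if cbf_override is not None:
        cbf = np.asarray(cbf_override, dtype=float)
    else:
        cbf = cbf_timecourse(state.cbf0, state.cvr, arterial.delta_paco2)
    # trial points during optimisation may wander into regions where the
    # deoxyhaemoglobin ratio goes non-positive; leave them unchecked so
    # the least-squares objective stays smooth there
    ratio = dhb_ratio(cbf, state.cbf0, arterial.cao2, arterial.cao2_0,
                      arterial.constants.hb, oef0, arterial.sao2_0,
                      check=False)
    bold = bold_signal(state.kappa, acq.te2, arterial.constants.hb, oef0,
                       arterial.sao2_0, ratio, cbf / state.cbf0, acq.theta)
    asl = asl_difference_signal(cbf, arterial.t1_blood, state.m0, acq)
    return ForwardSignals(asl=asl, bold=bold, cbf=cbf, oef0=oef0)


def compose_dexi(
    asl: np.ndarray,
    bold: np.ndarray,
    m0: float,
    acq: AcquisitionParams,
    tag_first: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Interleave clean signals into raw tag/control TE1/TE2 series.

    Control volumes carry +dS/2 and tag volumes -dS/2 about the static
    signal; the BOLD fraction scales with echo time (TE1/TE2 at the first
    echo) and a residual, T2*-attenuated label appears at TE2.
    """
    asl = np.asarray(asl, dtype=float)
    bold = np.asarray(bold, dtype=float)
    n = asl.size
    sign = np.ones(n)
    sign[::2] = -1.0 if tag_first else 1.0
    sign[1::2] = 1.0 if tag_first else -1.0
    te1 = m0 * (1.0 + bold * acq.te1 / acq.te2) + sign * asl / 2.0
    te2 = acq.te2_static_scale * m0 * (1.0 + bold) \
        + sign * acq.asl_te2_scale * asl / 2.0
    return te1, te2
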