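"""Task-evoked quantification: %BOLD, %CBF, task CMRO2, OEF and Dc.

Percentage signal changes come from a two-regressor (boxcar + constant)
least-squares fit of the block design.  Task CMRO2 inverts the
calibration model used at rest,

    CMRO2 = CMRO2,0 * (1 - dBOLD/(BOLD0*TE*kappa*[dHb]0))
                    * (CBF/CBF0)**(1-theta),

with kappa and [dHb]0 taken voxelwise from the resting fit.  Task OEF
follows from the Fick principle at the task CBF and arterial content,
and the task effective diffusivity from inverting the oxygen-exchange
lookup table at constant [Hb] and P50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oxygen import (
    OxygenLookupTable,
    flow_volume_exponent,
    invert_lookup_for_dc,
    ml_to_umol,
)
from .signals import AcquisitionParams, VoxelPhysioState, deoxyhemoglobin_baseline

__all__ = [
    "TaskResult",
    "block_percent_change",
    "task_cmro2",
    "task_oef_and_dc",
    "quantify_task",
]


@dataclass(frozen=True)
class TaskResult:
    pct_cbf: float  # % CBF change
    pct_bold: float  # % BOLD change
    pct_cmro2: float  # % CMRO2 change
    coupling_n: float  # CBF:CMRO2 coupling ratio (pct_cbf / pct_cmro2)
    pct_dc: float  # % effective-diffusivity change
    eta: float  # implied flow-volume coupling exponent
    oef_task: float
    dc_task: float
    cmro2_task: float


def block_percent_change(timeseries, design) -> float:
    """Percentage signal change of a block design.

    Fits ``y = c + a * boxcar`` by least squares and returns 100*a/c.
    Requires at least two ON blocks and a positive constant term.
    """
    y = np.asarray(timeseries, dtype=float)
    box = np.asarray(design, dtype=float)
    if box.shape != y.shape:
        raise ValueError("design must match the timeseries length")
    onsets = np.flatnonzero(np.diff(box, prepend=0.0) > 0)
    if onsets.size < 2:
        raise ValueError("need at least two ON blocks")
    X = np.column_stack([box, np.ones_like(box)])
    (a, c), *_ = np.linalg.lstsq(X, y, rcond=None)
    if c <= 0:
        raise ValueError("non-positive constant term; cannot form % change")
    return float(100.0 * a / c)


def task_cmro2(
    cmro2_0: float,
    dbold_over_s0: float,
    te: float,
    kappa: float,
    dhb0: float,
    cbf_ratio: float,
    theta: float = 0.06,
) -> float:
    """Task CMRO2 from the modified calibration model (see module docstring)."""
    if cmro2_0 <= 0 or kappa <= 0 or dhb0 <= 0 or cbf_ratio <= 0:
        raise ValueError("cmro2_0, kappa, dhb0 and cbf_ratio must be positive")
    bracket = 1.0 - dbold_over_s0 / (te * kappa * dhb0)
    if bracket <= 0:
        raise ValueError(
            "non-physical voxel: BOLD change exceeds the calibrated ceiling")
    return float(cmro2_0 * bracket * cbf_ratio ** (1.0 - theta))


def task_oef_and_dc(
    cmro2_task: float,
    cbf_task: float,
    cao2: float,
    table: OxygenLookupTable,
) -> tuple[float, float]:
    """Task OEF via the Fick principle and task Dc via lookup inversion."""
    if cmro2_task <= 0 or cbf_task <= 0 or cao2 <= 0:
        raise ValueError("inputs must be strictly positive")
    oef = cmro2_task / float(ml_to_umol(cbf_task * cao2))
    if oef >= 1.0:
        raise ValueError("non-physical OEF >= 1 during task")
    dc = invert_lookup_for_dc(oef, cbf_task, table)
    return float(oef), float(dc)


def quantify_task(
    rest: VoxelPhysioState,
    bold_series,
    cbf_series,
    design,
    arterial_sao2_0: float,
    cao2_0: float,
    hb: float,
    table: OxygenLookupTable,
    acq: AcquisitionParams | None = None,
) -> TaskResult:
    """Full task quantification for a voxel or ROI-mean timeseries.

    ``rest`` must carry the resting fit (oef0, cmro2_0, kappa); the BOLD
    series is fractional (dS/S0, so its constant term is 1 + drift) and
    the CBF series is in absolute units.  Arterial content is assumed at
    its resting value during visual-type stimulation.
    """
    acq = acq or AcquisitionParams()
    if rest.oef0 is None or rest.cmro2_0 is None:
        raise ValueError("rest state must include oef0 and cmro2_0")
    pct_bold = block_percent_change(1.0 + np.asarray(bold_series), design)
    pct_cbf = block_percent_change(cbf_series, design)
    cbf_ratio = 1.0 + pct_cbf / 100.0
    dhb0 = deoxyhemoglobin_baseline(hb, rest.oef0, arterial_sao2_0)
    cmro2 = task_cmro2(rest.cmro2_0, pct_bold / 100.0, acq.te2, rest.kappa,
                       dhb0, cbf_ratio, acq.theta)
    pct_cmro2 = 100.0 * (cmro2 / rest.cmro2_0 - 1.0)
    oef_task, dc_task = task_oef_and_dc(cmro2, rest.cbf0 * cbf_ratio, cao2_0,
                                        table)
    pct_dc = 100.0 * (dc_task / rest.dc - 1.0)
    coupling = pct_cbf / pct_cmro2 if pct_cmro2 != 0 else np.inf
    eta = flow_volume_exponent(cbf_ratio, dc_task / rest.dc)
    return TaskResult(
        pct_cbf=pct_cbf, pct_bold=pct_bold, pct_cmro2=pct_cmro2,
        coupling_n=coupling, pct_dc=pct_dc, eta=eta, oef_task=oef_task,
        dc_task=dc_task, cmro2_task=cmro2,
    )
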