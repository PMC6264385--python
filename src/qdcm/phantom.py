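"""Digital phantoms: synthetic gas protocols, ground-truth maps and noisy
dual-excitation datasets.

The default gas protocol emulates an 18-minute acquisition with two
hypercapnic and two hyperoxic blocks interleaved with medical air:
plateaus at PETCO2 41.6 mmHg (air) / 51.7 mmHg (hypercapnia) and PETO2
116 mmHg (air) / 325.2 mmHg (hyperoxia), with first-order (15 s)
wash-in/wash-out transitions.  Noise is additive white Gaussian per
channel, with the temporal SNR defined on the baseline TE2 signal and
the TE1 channel scaled by a configurable thermal-noise ratio.

The generator composes raw tag/control volumes through the same
``signals.compose_dexi`` path used by the fitter's prediction, so
phantom-based parameter recovery isolates estimation error rather than
model mismatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .oxygen import OxygenLookupTable, fick_cmro2
from .physio import ArterialTimeseries, BloodConstants, EndTidalTrace, derive_arterial
from .preprocess import DexiSeries, bold_fraction, surround_subtract
from .signals import (
    AcquisitionParams,
    VoxelPhysioState,
    asl_difference_signal,
    bold_signal,
    compose_dexi,
    deoxyhemoglobin_baseline,
    forward_model,
)

__all__ = [
    "GasBlock",
    "GasProtocol",
    "PhantomSpec",
    "make_protocol",
    "synthesize_dataset",
    "synthesize_voxel_bank",
    "synthesize_task_series",
    "draw_truth_states",
]


@dataclass(frozen=True)
class GasBlock:
    kind: str  # "air" | "hypercapnia" | "hyperoxia"
    duration: float  # s


@dataclass(frozen=True)
class GasProtocol:
    """Block schedule and plateau targets of the respiratory paradigm."""

    blocks: tuple[GasBlock, ...]
    co2_baseline: float = 41.6  # mmHg
    co2_step: float = 10.1  # hypercapnic rise, mmHg (to 51.7)
    o2_baseline: float = 116.0  # mmHg
    o2_target: float = 325.2  # hyperoxic plateau, mmHg
    transition_tau: float = 15.0  # gas wash-in time constant, s
    dt: float = 1.0  # trace sampling interval, s
    pad: float = 40.0  # trace extension before/after the scan, s

    def __post_init__(self) -> None:
        if any(b.duration <= 0 for b in self.blocks):
            raise ValueError("block durations must be positive")
        if any(b.kind not in ("air", "hypercapnia", "hyperoxia")
               for b in self.blocks):
            raise ValueError("unknown gas block kind")

    @property
    def total_duration(self) -> float:
        return float(sum(b.duration for b in self.blocks))

    @classmethod
    def default(cls, n_volumes: int = 244, tr: float = 4.4) -> "GasProtocol":
        """Two hypercapnia + two hyperoxia blocks filling ``n_volumes*tr``."""
        total = n_volumes * tr
        fixed = [
            GasBlock("air", 90.0), GasBlock("hypercapnia", 180.0),
            GasBlock("air", 90.0), GasBlock("hyperoxia", 180.0),
            GasBlock("air", 90.0), GasBlock("hypercapnia", 180.0),
            GasBlock("air", 90.0), GasBlock("hyperoxia", 120.0),
        ]
        tail = total - sum(b.duration for b in fixed)
        if tail <= 0:
            raise ValueError("protocol longer than the acquisition")
        return cls(blocks=tuple(fixed + [GasBlock("air", tail)]))

    @classmethod
    def flat(cls, n_volumes: int = 244, tr: float = 4.4) -> "GasProtocol":
        """Air-only protocol (no gas modulation)."""
        return cls(blocks=(GasBlock("air", n_volumes * tr),))


def make_protocol(protocol: GasProtocol) -> EndTidalTrace:
    """Synthesise the end-tidal trace for a gas protocol.

    Plateau targets switch at block boundaries and the measured gas
    relaxes toward the current target with the wash-in time constant.
    """
    t = np.arange(-protocol.pad, protocol.total_duration + protocol.pad,
                  protocol.dt)
    edges = np.cumsum([0.0] + [b.duration for b in protocol.blocks])
    co2_target = np.full(t.size, protocol.co2_baseline)
    o2_target = np.full(t.size, protocol.o2_baseline)
    for block, t0, t1 in zip(protocol.blocks, edges[:-1], edges[1:]):
        sel = (t >= t0) & (t < t1)
        if block.kind == "hypercapnia":
            co2_target[sel] = protocol.co2_baseline + protocol.co2_step
        elif block.kind == "hyperoxia":
            o2_target[sel] = protocol.o2_target
    decay = np.exp(-protocol.dt / protocol.transition_tau)
    co2 = np.empty_like(co2_target)
    o2 = np.empty_like(o2_target)
    co2[0], o2[0] = co2_target[0], o2_target[0]
    for i in range(1, t.size):
        co2[i] = co2_target[i] + (co2[i - 1] - co2_target[i]) * decay
        o2[i] = o2_target[i] + (o2[i - 1] - o2_target[i]) * decay
    return EndTidalTrace(time=t, petco2=co2, peto2=o2)


@dataclass(frozen=True)
class PhantomSpec:
    """Ground truth, protocol and noise description of a digital phantom."""

    shape: tuple[int, ...] = (8, 8, 3)
    cbf0: np.ndarray | float = 55.6
    dc: np.ndarray | float = 0.092
    kappa: np.ndarray | float = 0.06
    cvr: np.ndarray | float = 2.4
    m0: np.ndarray | float = 1000.0
    constants: BloodConstants = field(
        default_factory=lambda: BloodConstants(hb=0.143))
    protocol: GasProtocol = field(default_factory=GasProtocol.default)
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    tsnr: float = 200.0  # baseline TE2 temporal SNR (thermal noise only)
    noise_ratio: float = 1.0  # TE1/TE2 thermal noise ratio
    seed: int = 0
    tag_first: bool = True
    trace_lag: float = 0.0  # extra shift applied to the emitted trace, s

    def __post_init__(self) -> None:
        if self.tsnr <= 0:
            raise ValueError("tsnr must be strictly positive")

    def truth_map(self, name: str) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(getattr(self, name), dtype=float), self.shape
        ).copy()

    @property
    def n_volumes(self) -> int:
        return int(self.protocol.total_duration // self.acq.tr) // 2 * 2

    @property
    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.acq.tr


def _arterial_for(spec: PhantomSpec) -> tuple[EndTidalTrace, ArterialTimeseries]:
    trace = make_protocol(spec.protocol)
    arterial = derive_arterial(trace, spec.volume_times, spec.constants)
    return trace, arterial


def synthesize_dataset(
    spec: PhantomSpec, table: OxygenLookupTable
) -> tuple[DexiSeries, dict, EndTidalTrace, ArterialTimeseries]:
    """Generate a noisy interleaved DEXI dataset from ground-truth maps.

    Returns the dataset, a truth dictionary (including the lookup-derived
    OEF0 and Fick CMRO2,0 maps), the emitted end-tidal trace (shifted by
    ``spec.trace_lag``) and the generating arterial timeseries.
    """
    trace, arterial = _arterial_for(spec)
    rng = np.random.default_rng(spec.seed)
    n_vox = int(np.prod(spec.shape))
    n_t = spec.n_volumes
    maps = {k: spec.truth_map(k).ravel() for k in
            ("cbf0", "dc", "kappa", "cvr", "m0")}
    te1 = np.empty((n_vox, n_t))
    te2 = np.empty((n_vox, n_t))
    oef0 = np.empty(n_vox)
    for i in range(n_vox):
        state = VoxelPhysioState(
            cbf0=maps["cbf0"][i], dc=maps["dc"][i], kappa=maps["kappa"][i],
            cvr=maps["cvr"][i], m0=maps["m0"][i],
        )
        sig = forward_model(state, arterial, table, spec.acq)
        oef0[i] = sig.oef0
        te1[i], te2[i] = compose_dexi(sig.asl, sig.bold, state.m0, spec.acq,
                                      spec.tag_first)
    sigma2 = spec.acq.te2_static_scale * maps["m0"] / spec.tsnr
    sigma1 = spec.noise_ratio * sigma2
    te1 += sigma1[:, None] * rng.standard_normal(te1.shape)
    te2 += sigma2[:, None] * rng.standard_normal(te2.shape)
    truth = {k: v.reshape(spec.shape) for k, v in maps.items()}
    truth["oef0"] = oef0.reshape(spec.shape)
    truth["cmro2_0"] = fick_cmro2(truth["cbf0"], arterial.cao2_0, truth["oef0"])
    dexi = DexiSeries(
        te1_vols=te1.reshape(spec.shape + (n_t,)),
        te2_vols=te2.reshape(spec.shape + (n_t,)),
        m0_vol=spec.truth_map("m0"),
        mask=np.ones(spec.shape, dtype=bool),
        volume_times=spec.volume_times,
        tag_first=spec.tag_first,
    )
    return dexi, truth, trace.shifted(-spec.trace_lag), arterial


def draw_truth_states(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Sample voxel truths for a partial-volume-graded grey-matter mask.

    Voxels inside a 0.5-thresholded grey-matter mask span a continuum of
    grey-matter partial volume (pv), and perfusion, capillary density
    (hence effective diffusivity), venous blood volume (hence the BOLD
    calibration amplitude) and vascular reactivity all scale with it.
    The pv ~ U(0.3, 1) gradation with multiplicative jitter reproduces
    the group grey-matter means (CBF ~55.5 ml/100g/min, Dc ~0.092
    ml/100g/mmHg/min, CVR ~2.4 %/mmHg) at the mean pv of 0.65.
    """
    pv = rng.uniform(0.3, 1.0, n)
    jit = lambda s: 1.0 + s * rng.uniform(-1.0, 1.0, n)  # noqa: E731
    return {
        "cbf0": (10.0 + 70.0 * pv) * jit(0.05),
        "dc": 0.1415 * pv * jit(0.15),
        "kappa": 0.092 * pv * jit(0.15),
        "cvr": 3.7 * pv * jit(0.10),
        "m0": rng.uniform(800.0, 1200.0, n),
    }


def synthesize_voxel_bank(
    n_voxels: int,
    table: OxygenLookupTable,
    tsnr: float = 100.0,
    seed: int = 0,
    acq: AcquisitionParams | None = None,
    constants: BloodConstants | None = None,
    protocol: GasProtocol | None = None,
    truths: dict[str, np.ndarray] | None = None,
) -> dict:
    """Flat bank of preprocessed phantom voxels for recovery experiments.

    Returns observation arrays (surround-subtracted ASL and fractional
    BOLD, one row per voxel), the generating truths, and the shared
    arterial timeseries.
    """
    acq = acq or AcquisitionParams()
    constants = constants or BloodConstants(hb=0.143)
    rng = np.random.default_rng(seed)
    if truths is None:
        truths = draw_truth_states(n_voxels, rng)
    spec = PhantomSpec(
        shape=(n_voxels,), protocol=protocol or GasProtocol.default(),
        acq=acq, constants=constants, tsnr=tsnr,
        seed=int(rng.integers(2**31)), **truths,
    )
    dexi, truth, _, arterial = synthesize_dataset(spec, table)
    asl_obs = surround_subtract(dexi.te1_vols, dexi.tag_first)
    bold_obs = bold_fraction(dexi.te2_vols, arterial.baseline_mask)
    # perfusion-derived grey-matter partial volume and diffusivity prior,
    # exactly as the fitting pipeline computes them on real data
    from .preprocess import initial_perfusion_and_gm_pv

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small banks use a top-10% median
        _, gm_pv, dc_priors = initial_perfusion_and_gm_pv(
            asl_obs[..., arterial.baseline_mask].mean(axis=-1),
            dexi.m0_vol, arterial, acq, dexi.mask)
    return {
        "asl_obs": asl_obs, "bold_obs": bold_obs, "truth": truth,
        "arterial": arterial, "acq": acq, "m0": truth["m0"],
        "tag_first": dexi.tag_first, "gm_pv": gm_pv, "dc_priors": dc_priors,
    }


def synthesize_task_series(
    rest: VoxelPhysioState,
    design: np.ndarray,
    cbf_ratio: float,
    cmro2_ratio: float,
    arterial_baseline: ArterialTimeseries,
    table: OxygenLookupTable,
    acq: AcquisitionParams | None = None,
    tsnr: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Block-design task run: fractional BOLD and CBF timecourses.

    During ON blocks flow and metabolism rise by the given ratios; the
    task deoxyhaemoglobin follows from the Fick principle at constant
    arterial content, and the BOLD series from the calibration model.
    Returns (bold_frac, cbf) per volume, optionally with noise at the
    given BOLD tSNR (CBF noise scaled accordingly).
    """
    acq = acq or AcquisitionParams()
    design = np.asarray(design, dtype=bool)
    hb = arterial_baseline.constants.hb
    sao2_0 = arterial_baseline.sao2_0
    cao2_0 = arterial_baseline.cao2_0
    oef0 = float(table.interp(rest.cbf0, rest.dc))
    oef_task = oef0 * cmro2_ratio / cbf_ratio
    dhb0 = deoxyhemoglobin_baseline(hb, oef0, sao2_0)
    dhb_task = deoxyhemoglobin_baseline(hb, oef_task, sao2_0)
    ratio = np.where(design, dhb_task / dhb0, 1.0)
    f = np.where(design, cbf_ratio, 1.0)
    bold = bold_signal(rest.kappa, acq.te2, hb, oef0, sao2_0, ratio, f,
                       acq.theta)
    cbf = rest.cbf0 * f
    if tsnr is not None:
        rng = np.random.default_rng(seed)
        bold = bold + rng.standard_normal(bold.shape) / tsnr
        cbf = cbf + rest.cbf0 * rng.standard_normal(cbf.shape) * 5.0 / tsnr
    return bold, cbf
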