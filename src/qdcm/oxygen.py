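"""Capillary oxygen exchange: ODE model, OEF lookup table, oxygen arithmetic.

A single representative capillary exchanges oxygen with a well-stirred
tissue pool at mitochondrial tension Pm.  With plasma in Hill
equilibrium with haemoglobin-bound oxygen, the content along the
fractional capillary coordinate x in [0, 1] obeys

    dCt/dx = -(Dc / CBF) * (P(Ct) - Pm),
    P(Ct)  = P50 * (Ct / (phi*[Hb] - Ct))**(1/h),

where Dc = k*V is the effective oxygen diffusivity of the capillary
network (ml/100g/mmHg/min) and CBF is in ml/100g/min, so Dc/CBF has
units 1/mmHg.  The inlet content is a fixed fraction (0.95) of the
haemoglobin carrying capacity phi*[Hb]; the oxygen extraction fraction
is OEF = (Ct(0) - Ct(1)) / Ct(0).

Because Dc and CBF enter only through their ratio, a 2-D (CBF, Dc)
lookup table at fixed [Hb] and P50 can be solved in a single vectorised
ODE integration over the distinct Dc/CBF ratios.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator
from scipy.optimize import brentq

from .physio import MOLAR_VOLUME_O2_BODY, MOLAR_VOLUME_O2_STPD

__all__ = [
    "OxygenModelParams",
    "CapillaryProfile",
    "OxygenLookupTable",
    "hill_pressure",
    "solve_capillary_profile",
    "oef_from_profile",
    "build_lookup",
    "invert_lookup_for_dc",
    "ml_to_umol",
    "umol_to_ml",
    "fick_cmro2",
    "flow_volume_exponent",
]

_CT_FLOOR = 1e-12  # fractional-saturation floor; full-extraction regime


def hill_pressure(ct, hb: float, p50: float, h: float = 2.8, phi: float = 1.34):
    """Plasma O2 tension (mmHg) in Hill equilibrium with bound content ct.

    P = P50 * (ct / (phi*hb - ct))**(1/h); singular as ct -> phi*hb.
    """
    ct = np.asarray(ct, dtype=float)
    cap = phi * hb
    if np.any(ct >= cap):
        raise ValueError("ct must be strictly below the carrying capacity phi*hb")
    if np.any(ct < 0):
        raise ValueError("ct must be non-negative")
    p = p50 * (ct / (cap - ct)) ** (1.0 / h)
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class OxygenModelParams:
    """Parameters of the capillary oxygen-exchange model."""

    dc: float  # effective diffusivity, ml/100g/mmHg/min
    cbf: float  # ml/100g/min
    hb: float  # g/ml
    p50: float  # mmHg
    h: float = 2.8
    phi: float = 1.34
    inlet_fraction: float = 0.95  # Ct(0) as a fraction of phi*hb
    pm: float = 0.0  # mitochondrial O2 tension, mmHg

    def __post_init__(self) -> None:
        if self.dc < 0 or self.cbf <= 0 or self.hb <= 0 or self.p50 <= 0:
            raise ValueError("dc must be >= 0; cbf, hb, p50 strictly positive")
        if not (0.0 < self.inlet_fraction < 1.0):
            raise ValueError("inlet_fraction must lie in (0, 1)")
        if self.pm < 0:
            raise ValueError("pm must be non-negative")


@dataclass(frozen=True)
class CapillaryProfile:
    """Oxygen content/tension along the capillary, x in [0, 1]."""

    x: np.ndarray
    ct: np.ndarray  # ml O2 / ml blood (haemoglobin-bound)
    p: np.ndarray  # mmHg
    params: OxygenModelParams
    floored: bool = False  # content hit the numerical floor (OEF -> 1 regime)


def _power_rhs(v, gamma, h: float, pm_over_p50: float):
    """ODE right-hand side in the transformed variable v = u**((h-1)/h).

    With u = Ct/(phi*hb) and gamma = Dc*P50/(CBF*phi*hb) the raw
    saturation ODE du/dx = -gamma*((u/(1-u))**(1/h) - pm/p50) is
    non-Lipschitz at u -> 0 (content extinguishes at finite x for h > 1).
    In v-space,

        dv/dx = -gamma*(h-1)/h * [(1-u)**(-1/h) - (pm/p50)*u**(-1/h)],

    the pm = 0 right-hand side stays bounded through extinction, so an
    explicit adaptive integrator handles the complete-extraction regime
    without step-size collapse.
    """
    w = (h - 1.0) / h
    v = np.clip(v, 0.0, None)
    u = np.clip(v ** (1.0 / w), _CT_FLOOR, 1.0 - 1e-12)
    drive = (1.0 - u) ** (-1.0 / h)
    if pm_over_p50 > 0.0:
        drive = drive - pm_over_p50 * u ** (-1.0 / h)
    return -gamma * w * drive


def solve_capillary_profile(
    params: OxygenModelParams, n_points: int = 257, rtol: float = 1e-10
) -> CapillaryProfile:
    """Integrate the oxygen-loss ODE along the capillary.

    Uses an adaptive Runge-Kutta integrator with dense output; content is
    clipped at a small floor in the complete-extraction regime (flagged).
    """
    cap = params.phi * params.hb
    gamma = params.dc * params.p50 / (params.cbf * cap)
    pm_ratio = params.pm / params.p50
    w = (params.h - 1.0) / params.h
    v0 = params.inlet_fraction**w
    sol = solve_ivp(
        lambda x, v: _power_rhs(v, gamma, params.h, pm_ratio),
        (0.0, 1.0),
        [v0],
        method="RK45",
        rtol=rtol,
        atol=1e-13,
        dense_output=True,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"capillary ODE solver failed: {sol.message}")
    x = np.linspace(0.0, 1.0, n_points)
    u = np.clip(sol.sol(x)[0], 0.0, None) ** (1.0 / w)
    floored = bool(np.any(u <= 10 * _CT_FLOOR))
    if floored:
        warnings.warn(
            "capillary content reached the numerical floor (OEF -> 1 regime)",
            stacklevel=2,
        )
    u = np.clip(u, _CT_FLOOR, 1.0 - 1e-12)
    ct = u * cap
    p = params.p50 * (u / (1.0 - u)) ** (1.0 / params.h)
    return CapillaryProfile(x=x, ct=ct, p=p, params=params, floored=floored)


def oef_from_profile(profile: CapillaryProfile) -> float:
    """Oxygen extraction fraction (Ct(0) - Ct(1)) / Ct(0)."""
    return float((profile.ct[0] - profile.ct[-1]) / profile.ct[0])


def _batch_oef(
    gammas: np.ndarray,
    h: float,
    inlet_fraction: float,
    pm_over_p50: float,
    rtol: float = 1e-10,
) -> np.ndarray:
    """OEF for many Dc*P50/(CBF*phi*hb) ratios in one vector integration."""
    gammas = np.asarray(gammas, dtype=float)
    w = (h - 1.0) / h
    v0 = np.full(gammas.shape, inlet_fraction**w)
    sol = solve_ivp(
        lambda x, v: _power_rhs(v, gammas, h, pm_over_p50),
        (0.0, 1.0),
        v0,
        method="RK45",
        rtol=rtol,
        atol=1e-13,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"capillary ODE solver failed: {sol.message}")
    u1 = np.clip(np.clip(sol.y[:, -1], 0.0, None) ** (1.0 / w), _CT_FLOOR, None)
    return (inlet_fraction - u1) / inlet_fraction


@dataclass(frozen=True)
class OxygenLookupTable:
    """Gridded OEF(CBF, Dc) at fixed [Hb] and P50.

    OEF is strictly decreasing along the CBF axis and strictly increasing
    along the Dc axis.  Interpolation is (bi)linear in (log CBF, log Dc).
    """

    cbf_grid: np.ndarray  # ml/100g/min, strictly increasing
    dc_grid: np.ndarray  # ml/100g/mmHg/min, strictly increasing
    oef: np.ndarray  # (n_cbf, n_dc)
    hb: float
    p50: float
    h: float = 2.8
    phi: float = 1.34
    inlet_fraction: float = 0.95
    pm: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cbf_grid) <= 0) or np.any(np.diff(self.dc_grid) <= 0):
            raise ValueError("grids must be strictly increasing")
        if self.oef.shape != (self.cbf_grid.size, self.dc_grid.size):
            raise ValueError("oef shape does not match grids")
        if np.any((self.oef <= 0) | (self.oef >= 1)):
            raise ValueError("oef values must lie in (0, 1)")
        # Strict monotonicity holds away from complete extraction; in the
        # saturated corner (low CBF, high Dc) the capillary content hits
        # zero at finite x and OEF plateaus at ~1, producing genuine ties.
        d_cbf = np.diff(self.oef, axis=0)
        d_dc = np.diff(self.oef, axis=1)
        if np.any(d_cbf > 1e-10) or np.any(d_dc < -1e-10):
            raise ValueError("oef not monotone in (cbf, dc)")
        unsat = self.oef < 1.0 - 1e-6
        if np.any((d_cbf >= 0) & unsat[:-1, :] & unsat[1:, :]):
            raise ValueError("oef must strictly decrease along the cbf axis")
        if np.any((d_dc <= 0) & unsat[:, :-1] & unsat[:, 1:]):
            raise ValueError("oef must strictly increase along the dc axis")
        interp = RegularGridInterpolator(
            (np.log(self.cbf_grid), np.log(self.dc_grid)),
            self.oef,
            method="linear",
            bounds_error=False,
            fill_value=None,  # linear extrapolation at the margins
        )
        object.__setattr__(self, "_interp", interp)

    def interp(self, cbf, dc):
        """Bilinear OEF interpolation (log-axes); scalar or broadcast arrays."""
        cbf = np.asarray(cbf, dtype=float)
        dc = np.asarray(dc, dtype=float)
        pts = np.stack(np.broadcast_arrays(np.log(cbf), np.log(dc)), axis=-1)
        out = self._interp(pts)
        if cbf.ndim == 0 and dc.ndim == 0:
            return float(out.reshape(-1)[0])
        return out

    def resample(self, n_cbf: int = 512, n_dc: int = 512) -> "OxygenLookupTable":
        """Monotone (PCHIP) resampling onto a denser log-spaced grid.

        Mirrors resampling a coarse solver table to a high-resolution 2-D
        table so that cheap linear interpolation can be used during
        fitting; PCHIP preserves the monotonicity along both axes.
        """
        cbf_new = np.geomspace(self.cbf_grid[0], self.cbf_grid[-1], n_cbf)
        dc_new = np.geomspace(self.dc_grid[0], self.dc_grid[-1], n_dc)
        tmp = PchipInterpolator(np.log(self.dc_grid), self.oef, axis=1)(
            np.log(dc_new)
        )
        oef_new = PchipInterpolator(np.log(self.cbf_grid), tmp, axis=0)(
            np.log(cbf_new)
        )
        oef_new = np.clip(oef_new, 1e-9, 1 - 1e-9)
        return OxygenLookupTable(
            cbf_grid=cbf_new, dc_grid=dc_new, oef=oef_new, hb=self.hb,
            p50=self.p50, h=self.h, phi=self.phi,
            inlet_fraction=self.inlet_fraction, pm=self.pm,
            provenance=self.provenance,
        )

    # Serialisation ----------------------------------------------------
    def save(self, path) -> None:
        np.savez(
            path,
            cbf_grid=self.cbf_grid, dc_grid=self.dc_grid, oef=self.oef,
            meta=json.dumps({
                "hb": self.hb, "p50": self.p50, "h": self.h, "phi": self.phi,
                "inlet_fraction": self.inlet_fraction, "pm": self.pm,
                "provenance": self.provenance,
            }),
        )

    @classmethod
    def load(cls, path) -> "OxygenLookupTable":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(cbf_grid=z["cbf_grid"], dc_grid=z["dc_grid"],
                       oef=z["oef"], **meta)


DEFAULT_CBF_GRID = np.geomspace(5.0, 150.0, 96)
DEFAULT_DC_GRID = np.geomspace(0.005, 0.35, 96)


def build_lookup(
    cbf_grid=None,
    dc_grid=None,
    hb: float = 0.143,
    p50: float = 27.1,
    h: float = 2.8,
    phi: float = 1.34,
    inlet_fraction: float = 0.95,
    pm: float = 0.0,
    rtol: float = 1e-10,
) -> OxygenLookupTable:
    """Solve the exchange ODE over a (CBF, Dc) grid and tabulate OEF.

    The default grid spans grey/white matter and pathological margins:
    CBF in [5, 150] ml/100g/min and Dc in [0.005, 0.35] ml/100g/mmHg/min,
    96 log-spaced points each.
    """
    cbf_grid = np.asarray(DEFAULT_CBF_GRID if cbf_grid is None else cbf_grid,
                          dtype=float)
    dc_grid = np.asarray(DEFAULT_DC_GRID if dc_grid is None else dc_grid,
                         dtype=float)
    cap = phi * hb
    gammas = (dc_grid[None, :] * p50) / (cbf_grid[:, None] * cap)
    oef = _batch_oef(gammas.ravel(), h, inlet_fraction, pm / p50, rtol=rtol)
    oef = oef.reshape(gammas.shape)
    settings = {
        "cbf_grid": [float(cbf_grid[0]), float(cbf_grid[-1]), int(cbf_grid.size)],
        "dc_grid": [float(dc_grid[0]), float(dc_grid[-1]), int(dc_grid.size)],
        "hb": hb, "p50": p50, "h": h, "phi": phi,
        "inlet_fraction": inlet_fraction, "pm": pm, "rtol": rtol,
    }
    prov = hashlib.sha256(json.dumps(settings, sort_keys=True).encode()).hexdigest()
    try:
        return OxygenLookupTable(
            cbf_grid=cbf_grid, dc_grid=dc_grid, oef=oef, hb=hb, p50=p50, h=h,
            phi=phi, inlet_fraction=inlet_fraction, pm=pm, provenance=prov,
        )
    except ValueError as err:  # non-monotone table indicates solver failure
        raise RuntimeError(f"lookup construction failed: {err}") from err


def invert_lookup_for_dc(oef: float, cbf: float, table: OxygenLookupTable) -> float:
    """Dc from (OEF, CBF) by monotone root-finding along the table's Dc axis.

    OEF outside the achievable range at that CBF returns the boundary Dc
    with a warning.
    """
    lo, hi = float(table.dc_grid[0]), float(table.dc_grid[-1])
    f_lo = table.interp(cbf, lo) - oef
    f_hi = table.interp(cbf, hi) - oef
    if f_lo >= 0:
        if f_lo > 1e-12:
            warnings.warn("oef below table range; boundary dc returned",
                          stacklevel=2)
        return lo
    if f_hi <= 0:
        if f_hi < -1e-12:
            warnings.warn("oef above table range; boundary dc returned",
                          stacklevel=2)
        return hi
    return float(
        brentq(lambda d: table.interp(cbf, d) - oef, lo, hi, xtol=1e-12,
               rtol=1e-12)
    )


def ml_to_umol(value, molar_volume: float = MOLAR_VOLUME_O2_BODY):
    """Convert an O2 quantity from an ml basis to micromoles.

    The default molar volume (~25.45 ml/mmol) is the ideal-gas value at
    body temperature (310.15 K); pass ``molar_volume=22.414`` for STPD.
    """
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("value must be non-negative")
    out = value * 1000.0 / molar_volume
    return out if out.ndim else float(out)


def umol_to_ml(value, molar_volume: float = MOLAR_VOLUME_O2_BODY):
    value = np.asarray(value, dtype=float)
    out = value * molar_volume / 1000.0
    return out if out.ndim else float(out)


def fick_cmro2(cbf, cao2, oef, molar_volume: float = MOLAR_VOLUME_O2_BODY):
    """CMRO2 (umol/100g/min) by the Fick principle: CBF * CaO2 * OEF."""
    cbf = np.asarray(cbf, dtype=float)
    cao2 = np.asarray(cao2, dtype=float)
    oef = np.asarray(oef, dtype=float)
    if np.any(cbf < 0) or np.any(cao2 < 0) or np.any((oef < 0) | (oef >= 1)):
        raise ValueError("cbf, cao2 must be >= 0 and oef in [0, 1)")
    return ml_to_umol(cbf * cao2 * oef, molar_volume)


def flow_volume_exponent(flow_ratio: float, volume_ratio: float) -> float:
    """Coupling exponent eta in CBV/CBV0 = (CBF/CBF0)**eta.

    eta = ln(volume_ratio) / ln(flow_ratio); undefined at flow_ratio = 1.
    """
    if flow_ratio <= 0 or volume_ratio <= 0:
        raise ValueError("ratios must be strictly positive")
    if flow_ratio == 1.0:
        raise ValueError("flow_ratio = 1 leaves the exponent undefined")
    return float(np.log(volume_ratio) / np.log(flow_ratio))
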