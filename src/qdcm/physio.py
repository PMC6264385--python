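"""Arterial physiology derived from end-tidal gas recordings.

End-tidal partial pressures are taken as surrogates for arterial tensions
(PaO2 = PETO2, PaCO2 = PETCO2).  From these and a measured haemoglobin
concentration we derive, per MR volume: arterial oxygen saturation
(Severinghaus dissociation curve), arterial oxygen content, and the
longitudinal relaxation time of arterial blood.  Baseline pH and the
haemoglobin half-saturation pressure P50 are scalars computed from the
mean PaCO2 over air-breathing periods (Henderson-Hasselbalch followed by
a linear pH->P50 correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BloodConstants",
    "EndTidalTrace",
    "ArterialTimeseries",
    "AlignmentWarning",
    "severinghaus_sao2",
    "ph_from_paco2",
    "p50_from_ph",
    "cao2_from_state",
    "t1_blood_from_oxygenation",
    "find_baseline_volumes",
    "derive_arterial",
    "align_traces",
]

#: O2 molar volume at body temperature (310.15 K), ml/mmol, ideal gas.
MOLAR_VOLUME_O2_BODY = 22.414 * 310.15 / 273.15  # ~25.45
#: O2 molar volume at STPD, ml/mmol.
MOLAR_VOLUME_O2_STPD = 22.414


class AlignmentWarning(UserWarning):
    """Raised when trace/MR alignment looks unreliable."""


@dataclass(frozen=True)
class BloodConstants:
    """Haematological constants.

    hb is stored in g/ml (whole blood); typical adult values are
    0.12-0.17 g/ml (12-17 g/dl).  Use :meth:`from_gdl` when the value
    comes in the customary g/dl.
    """

    hb: float  # g/ml
    phi: float = 1.34  # ml O2 per g Hb
    h: float = 2.8  # Hill coefficient
    epsilon: float = 0.0031  # ml O2 / mmHg / dl plasma
    hco3: float = 24.0  # mmol/L
    molar_volume_o2: float = MOLAR_VOLUME_O2_BODY  # ml/mmol

    def __post_init__(self) -> None:
        for name in ("hb", "phi", "h", "epsilon", "hco3", "molar_volume_o2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.05 < self.hb < 0.25):
            raise ValueError(
                f"hb={self.hb} outside (0.05, 0.25) g/ml; "
                "a g/dl value must be divided by 100"
            )

    @classmethod
    def from_gdl(cls, hb_gdl: float, **kwargs) -> "BloodConstants":
        return cls(hb=hb_gdl / 100.0, **kwargs)


def severinghaus_sao2(pao2):
    """Arterial O2 saturation from O2 tension (mmHg), Severinghaus curve.

    S = (23400 / (P^3 + 150 P) + 1)^-1; monotone in P, ->1 as P->inf.
    """
    p = np.asarray(pao2, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pao2 must be strictly positive")
    s = 1.0 / (23400.0 / (p**3 + 150.0 * p) + 1.0)
    return s if s.ndim else float(s)


def severinghaus_pao2(sao2, lo: float = 1e-3, hi: float = 5000.0):
    """Numerical inverse of :func:`severinghaus_sao2` (bisection-safe brentq)."""
    from scipy.optimize import brentq

    def _inv(s: float) -> float:
        if not 0.0 < s < 1.0:
            raise ValueError("sao2 must be in (0, 1)")
        return brentq(lambda p: severinghaus_sao2(p) - s, lo, hi, xtol=1e-10)

    s = np.asarray(sao2, dtype=float)
    if s.ndim == 0:
        return _inv(float(s))
    return np.array([_inv(v) for v in s.ravel()]).reshape(s.shape)


def ph_from_paco2(paco2, hco3: float = 24.0):
    """Blood pH from CO2 tension via Henderson-Hasselbalch.

    pH = 6.1 + log10(HCO3- / (0.03 * PaCO2)), HCO3- in mmol/L.
    """
    p = np.asarray(paco2, dtype=float)
    if np.any(p <= 0):
        raise ValueError("paco2 must be strictly positive")
    ph = 6.1 + np.log10(hco3 / (0.03 * p))
    return ph if ph.ndim else float(ph)


def p50_from_ph(ph):
    """Haemoglobin half-saturation pressure (mmHg) from pH, linear correlation.

    P50 = 221.87 - 26.37 * pH.  Values outside pH (6.5, 8.0) are
    physiologically implausible and trigger a warning.
    """
    ph_arr = np.asarray(ph, dtype=float)
    if np.any((ph_arr <= 6.5) | (ph_arr >= 8.0)):
        warnings.warn("pH outside (6.5, 8.0); P50 extrapolated", stacklevel=2)
    p50 = 221.87 - 26.37 * ph_arr
    return p50 if p50.ndim else float(p50)


def cao2_from_state(pao2, sao2, hb: float, constants: BloodConstants | None = None):
    """Arterial O2 content (ml O2 / ml blood).

    CaO2 = phi*[Hb]*SaO2 + eps*PaO2 with the plasma solubility eps
    rescaled from its customary per-dl basis to per-ml.
    """
    c = constants or BloodConstants(hb=hb)
    if not (0.05 < hb < 0.25):
        raise ValueError(f"hb={hb} outside (0.05, 0.25) g/ml (unit mix-up?)")
    pao2 = np.asarray(pao2, dtype=float)
    sao2 = np.asarray(sao2, dtype=float)
    if np.any(pao2 < 0) or np.any(sao2 < 0) or np.any(sao2 > 1):
        raise ValueError("pao2 must be >= 0 and sao2 in [0, 1]")
    cao2 = c.phi * hb * sao2 + (c.epsilon / 100.0) * pao2
    return cao2 if cao2.ndim else float(cao2)


def t1_blood_from_oxygenation(pao2, sao2):
    """T1 of arterial blood (s) from oxygenation.

    R1 = 1.527e-4*PaO2 + 0.1713*(1-SaO2) + 0.5848 (1/s); hyperoxia
    (high PaO2) shortens T1, desaturation also shortens it.
    """
    pao2 = np.asarray(pao2, dtype=float)
    sao2 = np.asarray(sao2, dtype=float)
    r1 = 1.527e-4 * pao2 + 0.1713 * (1.0 - sao2) + 0.5848
    t1 = 1.0 / r1
    return t1 if t1.ndim else float(t1)


@dataclass(frozen=True)
class EndTidalTrace:
    """End-tidal CO2/O2 recordings on a common, strictly increasing time axis."""

    time: np.ndarray  # s since trace start
    petco2: np.ndarray  # mmHg
    peto2: np.ndarray  # mmHg

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        co2 = np.asarray(self.petco2, dtype=float)
        o2 = np.asarray(self.peto2, dtype=float)
        if not (t.shape == co2.shape == o2.shape) or t.ndim != 1 or t.size < 2:
            raise ValueError("time/petco2/peto2 must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(~np.isfinite(co2)) or np.any(~np.isfinite(o2)):
            raise ValueError("traces contain non-finite samples")
        if np.any((co2 <= 10) | (co2 >= 120)):
            raise ValueError("petco2 outside plausible (10, 120) mmHg range")
        if np.any((o2 <= 40) | (o2 >= 700)):
            raise ValueError("peto2 outside plausible (40, 700) mmHg range")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "petco2", co2)
        object.__setattr__(self, "peto2", o2)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    def sample(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolate (petco2, peto2) at times ``t`` (clamped ends)."""
        t = np.asarray(t, dtype=float)
        co2 = np.interp(t, self.time, self.petco2)
        o2 = np.interp(t, self.time, self.peto2)
        return co2, o2

    def shifted(self, lag_s: float) -> "EndTidalTrace":
        return replace(self, time=self.time - lag_s)

    @classmethod
    def from_file(cls, path, o2_path=None) -> "EndTidalTrace":
        """Read a trace from delimited text.

        Either one three-column file (time_s, petco2, peto2) or two
        two-column files (time_s, mmHg), CO2 first, O2 via ``o2_path``.
        """
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        if o2_path is None:
            if df.shape[1] < 3:
                raise ValueError("single-file trace needs 3 columns: time, co2, o2")
            a = df.iloc[:, :3].to_numpy(dtype=float)
            return cls(time=a[:, 0], petco2=a[:, 1], peto2=a[:, 2])
        df2 = pd.read_csv(o2_path, sep=None, engine="python", comment="#")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        co2 = df.iloc[:, 1].to_numpy(dtype=float)
        o2 = np.interp(t, df2.iloc[:, 0].to_numpy(dtype=float),
                       df2.iloc[:, 1].to_numpy(dtype=float))
        return cls(time=t, petco2=co2, peto2=o2)


@dataclass(frozen=True)
class ArterialTimeseries:
    """Per-volume arterial state plus scalar baseline quantities."""

    time: np.ndarray  # volume acquisition times, s
    pao2: np.ndarray  # mmHg
    paco2: np.ndarray  # mmHg
    sao2: np.ndarray  # fraction
    cao2: np.ndarray  # ml O2 / ml blood
    t1_blood: np.ndarray  # s
    baseline_mask: np.ndarray  # bool per volume (air breathing)
    ph: float
    p50: float  # mmHg
    constants: BloodConstants
    lag_s: float = 0.0  # applied trace shift, s

    def __post_init__(self) -> None:
        if np.any((self.sao2 <= 0) | (self.sao2 > 1)):
            raise ValueError("sao2 must lie in (0, 1]")
        if not (20.0 < self.p50 < 35.0):
            raise ValueError(f"p50={self.p50:.2f} mmHg outside (20, 35)")
        if np.any((self.t1_blood <= 1.0) | (self.t1_blood >= 2.2)):
            raise ValueError("t1_blood outside (1.0, 2.2) s")
        c = self.constants
        cap = c.phi * c.hb + (c.epsilon / 100.0) * self.pao2 + 1e-9
        if np.any(self.cao2 >= cap):
            raise ValueError("cao2 exceeds haemoglobin + dissolved capacity")

    # Baseline scalars -------------------------------------------------
    @property
    def pao2_0(self) -> float:
        return float(np.mean(self.pao2[self.baseline_mask]))

    @property
    def paco2_0(self) -> float:
        return float(np.mean(self.paco2[self.baseline_mask]))

    @property
    def sao2_0(self) -> float:
        return float(np.mean(self.sao2[self.baseline_mask]))

    @property
    def cao2_0(self) -> float:
        return float(np.mean(self.cao2[self.baseline_mask]))

    @property
    def t1_blood_0(self) -> float:
        return float(np.mean(self.t1_blood[self.baseline_mask]))

    @property
    def delta_paco2(self) -> np.ndarray:
        return self.paco2 - self.paco2_0

    def to_table(self) -> pd.DataFrame:
        """Per-volume arterial state as a table for audit export."""
        return pd.DataFrame(
            {
                "time_s": self.time,
                "pao2_mmHg": self.pao2,
                "paco2_mmHg": self.paco2,
                "sao2": self.sao2,
                "cao2_ml_per_ml": self.cao2,
                "t1_blood_s": self.t1_blood,
                "baseline": self.baseline_mask.astype(int),
            }
        )


def find_baseline_volumes(
    paco2: np.ndarray,
    pao2: np.ndarray,
    co2_tol: float = 1.0,
    o2_tol: float = 15.0,
    n_ref: int = 10,
) -> np.ndarray:
    """Boolean mask of air-breathing volumes.

    A volume counts as baseline when both gases sit near the scan-start
    median (first ``n_ref`` volumes): |dPETCO2| < 1 mmHg and
    |dPETO2| < 15 mmHg by default.
    """
    paco2 = np.asarray(paco2, dtype=float)
    pao2 = np.asarray(pao2, dtype=float)
    ref_co2 = np.median(paco2[:n_ref])
    ref_o2 = np.median(pao2[:n_ref])
    mask = (np.abs(paco2 - ref_co2) < co2_tol) & (np.abs(pao2 - ref_o2) < o2_tol)
    if not mask.any():  # pathological trace: fall back to first volumes
        warnings.warn("no baseline volumes found; using scan start", stacklevel=2)
        mask = np.zeros_like(mask)
        mask[:n_ref] = True
    return mask


def derive_arterial(
    trace: EndTidalTrace,
    volume_times: np.ndarray,
    constants: BloodConstants,
    baseline_mask: np.ndarray | None = None,
    lag_s: float = 0.0,
) -> ArterialTimeseries:
    """Resample an end-tidal trace at volume times and derive arterial state.

    pH and P50 are scalars from the mean PaCO2 over baseline volumes.
    """
    t = np.asarray(volume_times, dtype=float)
    paco2, pao2 = trace.sample(t + lag_s)
    if baseline_mask is None:
        baseline_mask = find_baseline_volumes(paco2, pao2)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    sao2 = severinghaus_sao2(pao2)
    cao2 = cao2_from_state(pao2, sao2, constants.hb, constants)
    t1b = t1_blood_from_oxygenation(pao2, sao2)
    ph = ph_from_paco2(float(np.mean(paco2[baseline_mask])), constants.hco3)
    p50 = p50_from_ph(ph)
    return ArterialTimeseries(
        time=t, pao2=pao2, paco2=paco2, sao2=sao2, cao2=cao2, t1_blood=t1b,
        baseline_mask=baseline_mask, ph=ph, p50=p50, constants=constants,
        lag_s=lag_s,
    )


def align_traces(
    trace: EndTidalTrace,
    asl_gm_mean: np.ndarray,
    tr: float,
    max_lag: float = 30.0,
    constants: BloodConstants | None = None,
    volume_times: np.ndarray | None = None,
    min_corr: float = 0.2,
) -> ArterialTimeseries:
    """Align an end-tidal trace to the MR timeseries and derive arterial state.

    The lag maximising the normalised cross-correlation between PaCO2 and
    the mean grey-matter ASL signal is searched on the trace's native
    sampling grid within +/- ``max_lag`` seconds; the trace (not the MR
    data) is then shifted by that lag.  A boundary lag or a weak peak
    correlation triggers :class:`AlignmentWarning`.
    """
    if constants is None:
        raise ValueError("constants (BloodConstants) are required")
    asl = np.asarray(asl_gm_mean, dtype=float)
    n_vol = asl.size
    if volume_times is None:
        volume_times = np.arange(n_vol) * tr
    lags = np.arange(-max_lag, max_lag + 0.5 * trace.dt, trace.dt)

    asl_c = asl - asl.mean()
    asl_norm = np.linalg.norm(asl_c)
    best_lag, best_r = 0.0, -np.inf
    for lag in lags:
        co2, _ = trace.sample(volume_times + lag)
        co2_c = co2 - co2.mean()
        denom = np.linalg.norm(co2_c) * asl_norm
        r = float(co2_c @ asl_c / denom) if denom > 0 else 0.0
        if r > best_r:
            best_r, best_lag = r, float(lag)

    if best_r < min_corr:
        warnings.warn(
            f"peak PaCO2/ASL correlation {best_r:.2f} < {min_corr}; "
            "lag estimate unreliable", AlignmentWarning, stacklevel=2,
        )
    if abs(abs(best_lag) - max_lag) < 0.5 * trace.dt:
        warnings.warn(
            f"best lag {best_lag:.1f}s at the search boundary; possible "
            "misalignment", AlignmentWarning, stacklevel=2,
        )
    return derive_arterial(trace, volume_times, constants, lag_s=best_lag)
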