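"""Forward MDME signal model and synthetic contrast weighting.

The steady-state magnitude signal of a saturation-recovery fast-spin-echo
acquisition, for a voxel with relaxation times T1, T2 and proton density PD,
measured at echo time TE after a saturation-to-acquisition delay TI within a
repetition time TR, is

    I = A * PD * exp(-TE/T2)
        * [1 - (1 - cos(B1*theta)) * exp(-TI/T1) - cos(B1*theta) * exp(-TR/T1)]
        / [1 - cos(B1*alpha) * cos(B1*theta) * exp(-TR/T1)]

where alpha is the excitation flip angle (90 deg here), theta the saturation
flip angle (120 deg), B1 the relative transmit field scaling both flips, and
A an overall intensity scale (coil sensitivity, receiver gain, voxel volume).
A and PD are algebraically inseparable and are handled downstream as the
single product M0 = A * PD.

For alpha = 90 deg and B1 = 1 the denominator is exactly 1, so the model
reduces to a pure saturation-recovery curve scaled by T2 decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueParams",
    "SignalSample",
    "SignalSet",
    "TISSUE_PRESETS",
    "tissue_presets",
    "mdme_signal",
    "mdme_signal_arrays",
    "signal_set",
    "synthesize_weighted_image",
]

_DENOM_TOL = 1e-12


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth relaxation parameters of one phantom vial.

    ``pd`` is proton density in arbitrary units; only the product with the
    scanner intensity scale is observable.
    """

    label: str
    t1_ms: float
    t2_ms: float
    pd: float = 1.0

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError(f"relaxation times must be positive (got T1={self.t1_ms}, T2={self.t2_ms})")
        if self.pd <= 0:
            raise ValueError(f"proton density must be positive (got {self.pd})")


#: Mean measured T1/T2 (ms) of the three brain-mimicking vials, per protocol
#: family.  The ETL-family row doubles as the package's canonical ground
#: truth.  Proton densities are package defaults at typical relative values
#: for agarose gels (GM, WM) and free water (CSF); the phantom study itself
#: reports no PD.
TISSUE_PRESETS: dict[str, tuple[TissueParams, TissueParams, TissueParams]] = {
    "ETL": (
        TissueParams("GM", 1100.0, 139.0, 0.80),
        TissueParams("WM", 571.0, 135.0, 0.65),
        TissueParams("CSF", 2543.0, 1790.0, 1.00),
    ),
    "Matrix": (
        TissueParams("GM", 1104.0, 141.0, 0.80),
        TissueParams("WM", 576.0, 138.0, 0.65),
        TissueParams("CSF", 2561.0, 1813.0, 1.00),
    ),
    "Phase": (
        TissueParams("GM", 1106.0, 141.0, 0.80),
        TissueParams("WM", 574.0, 135.0, 0.65),
        TissueParams("CSF", 2565.0, 1842.0, 1.00),
    ),
}


def tissue_presets(group: str = "ETL") -> tuple[TissueParams, TissueParams, TissueParams]:
    """The (GM, WM, CSF) vial presets for one protocol family's mean values."""
    try:
        return TISSUE_PRESETS[group]
    except KeyError:
        raise KeyError(f"no tissue preset group {group!r}; choose from {sorted(TISSUE_PRESETS)}")


@dataclass(frozen=True)
class SignalSample:
    """One modeled or measured magnitude intensity at given (TE, TI)."""

    te_ms: float
    ti_ms: float
    intensity: float


@dataclass(frozen=True)
class SignalSet:
    """The 8 intensities of one voxel: 2 echo times x 4 delay times.

    Samples are ordered (te1,ti1)..(te1,ti4), (te2,ti1)..(te2,ti4).
    """

    samples: tuple[SignalSample, ...]
    protocol_name: str = ""

    def __post_init__(self) -> None:
        if len(self.samples) != 8:
            raise ValueError(f"a SignalSet holds exactly 8 samples (got {len(self.samples)})")
        tes = sorted({s.te_ms for s in self.samples})
        tis = sorted({s.ti_ms for s in self.samples})
        if len(tes) != 2 or len(tis) != 4:
            raise ValueError("a SignalSet requires 2 distinct echo times and 4 distinct delay times")

    @property
    def intensities(self) -> np.ndarray:
        return np.array([s.intensity for s in self.samples], dtype=float)

    @property
    def te_ms(self) -> np.ndarray:
        return np.array([s.te_ms for s in self.samples], dtype=float)

    @property
    def ti_ms(self) -> np.ndarray:
        return np.array([s.ti_ms for s in self.samples], dtype=float)


def mdme_signal_arrays(t1_ms, t2_ms, m0, b1, te_ms, ti_ms, tr_ms,
                       alpha_deg: float = 90.0, theta_deg: float = 120.0) -> np.ndarray:
    """Vectorized forward model on raw parameter arrays (M0 = A*PD).

    All arguments broadcast; the single point of degree-to-radian conversion
    for the whole package lives here.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    t2 = np.asarray(t2_ms, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    cos_theta = np.cos(b1 * math.radians(theta_deg))
    cos_alpha = np.cos(b1 * math.radians(alpha_deg))
    with np.errstate(divide="ignore", invalid="ignore"):
        e_ti = np.exp(-np.asarray(ti_ms, dtype=float) / t1)
        e_tr = np.exp(-np.asarray(tr_ms, dtype=float) / t1)
        e_te = np.exp(-np.asarray(te_ms, dtype=float) / t2)
    numer = 1.0 - (1.0 - cos_theta) * e_ti - cos_theta * e_tr
    denom = 1.0 - cos_alpha * cos_theta * e_tr
    if np.any(np.abs(denom) < _DENOM_TOL):
        raise ZeroDivisionError("degenerate signal model: steady-state denominator is ~0")
    return np.asarray(m0, dtype=float) * e_te * numer / denom


def mdme_signal(tissue: TissueParams, scale: float, b1: float, te_ms: float, ti_ms: float,
                tr_ms: float, alpha_deg: float = 90.0, theta_deg: float = 120.0) -> float:
    """Forward signal intensity for one tissue at one (TE, TI, TR) point.

    ``scale`` is the overall intensity factor A; ``b1`` the relative transmit
    field in (0, 2].
    """
    if not (0 < b1 <= 2):
        raise ValueError(f"relative B1 must lie in (0, 2] (got {b1})")
    if te_ms <= 0 or ti_ms <= 0 or tr_ms <= ti_ms:
        raise ValueError("require TE > 0 and TR > TI > 0")
    return float(mdme_signal_arrays(tissue.t1_ms, tissue.t2_ms, scale * tissue.pd, b1,
                                    te_ms, ti_ms, tr_ms, alpha_deg, theta_deg))


def signal_set(tissue: TissueParams, protocol, scale: float = 1.0, b1: float = 1.0) -> SignalSet:
    """Noise-free 8-point signal set for a tissue under an acquisition protocol."""
    samples = []
    for te in (protocol.te1_ms, protocol.te2_ms):
        for ti in protocol.delay_times_ms:
            samples.append(SignalSample(te_ms=te, ti_ms=ti, intensity=mdme_signal(
                tissue, scale, b1, te, ti, protocol.tr_ms,
                protocol.flip_excitation_deg, protocol.flip_saturation_deg)))
    return SignalSet(samples=tuple(samples), protocol_name=protocol.name)


def synthesize_weighted_image(maps, te_syn_ms: float, tr_syn_ms: float) -> np.ndarray:
    """Synthesize a conventional spin-echo contrast image from fitted maps.

    Per voxel, S = M0 * (1 - exp(-TR_syn/T1)) * exp(-TE_syn/T2).  This is the
    package's own synthesis convention (standard spin-echo weighting); long
    TE_syn yields a fluid-bright T2-weighted appearance, short TE_syn with
    long TR_syn approaches the M0 map.  Voxels with non-finite or
    non-positive fitted values map to 0.
    """
    if te_syn_ms <= 0 or tr_syn_ms <= 0:
        raise ValueError("synthetic TE and TR must be positive")
    t1 = np.asarray(maps.t1_map, dtype=float)
    t2 = np.asarray(maps.t2_map, dtype=float)
    m0 = np.asarray(maps.m0_map, dtype=float)
    valid = np.isfinite(t1) & np.isfinite(t2) & np.isfinite(m0) & (t1 > 0) & (t2 > 0)
    out = np.zeros_like(t1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = m0 * (1.0 - np.exp(-tr_syn_ms / t1)) * np.exp(-te_syn_ms / t2)
    out[valid] = s[valid]
    return out
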