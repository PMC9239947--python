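"""Synthetic phantom generation and scanner-like acquisition simulation.

Emulates the bench setup of a scan-parameter repeatability experiment: three
cylindrical vials with brain-like relaxation times (GM, WM, CSF mimics) in a
square field of view, imaged by the MDME sequence.  Each simulated
acquisition produces the 8 magnitude images (2 echo times x 4 delay times)
of one slice, with Rician noise whose standard deviation scales with voxel
volume, receiver bandwidth and parallel-imaging acceleration.

The full study design — 3 protocol families x 4 protocols x ``n_repeats``
acquisitions — is replicated by :func:`replicate_study` with per-stack seeds
derived deterministically from one master seed, so an entire study is
reproducible end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .protocols import AcquisitionProtocol, ProtocolFamily, load_presets, voxel_volume_mm3
from .signal import TissueParams, mdme_signal_arrays, tissue_presets

__all__ = [
    "PhantomLayout",
    "PhantomMaps",
    "NoiseModel",
    "StudyDesign",
    "StackRecord",
    "DEFAULT_SCALE",
    "DEFAULT_SIGMA_REF",
    "default_layout",
    "default_noise_model",
    "build_phantom",
    "noise_sigma",
    "simulate_acquisition",
    "replicate_study",
]

#: Overall intensity scale A applied to all simulated acquisitions; with the
#: default proton densities (0.65-1.0) the brightest fully recovered signal
#: is ~500 intensity units.
DEFAULT_SCALE = 500.0

#: Noise standard deviation at the reference acquisition conditions (those
#: of preset ETL1).  Chosen by the calibration procedure in
#: scripts/calibrate_noise.py: ROI-mean repeatability of T1 in the GM vial
#: at ETL1 must sit in the sub-1% range while the fitted-parameter bias of
#: every vial stays small (~2%) at every protocol's noise level, so that
#: group comparisons reflect scan parameters rather than estimator bias;
#: see docs/methods.md.
DEFAULT_SIGMA_REF = 1.0


@dataclass(frozen=True)
class PhantomLayout:
    """Geometric description of the vials inside the field of view.

    ``vials`` is a sequence of ``(center_xy_mm, radius_mm, TissueParams)``
    with coordinates in mm relative to the FOV center.  ``image_size`` is
    the default raster grid (pixels per side) used when no explicit grid is
    requested.
    """

    fov_mm: float
    vials: tuple[tuple[tuple[float, float], float, TissueParams], ...]
    image_size: int = 288

    def validate(self) -> None:
        half = self.fov_mm / 2.0
        for (cx, cy), r, tissue in self.vials:
            if r <= 0:
                raise ValueError(f"vial {tissue.label!r} has non-positive radius {r}")
            if abs(cx) + r > half or abs(cy) + r > half:
                raise ValueError(f"vial {tissue.label!r} extends outside the FOV")
        for i in range(len(self.vials)):
            for j in range(i + 1, len(self.vials)):
                (c1, r1, t1), (c2, r2, t2) = self.vials[i], self.vials[j]
                dist = math.hypot(c1[0] - c2[0], c1[1] - c2[1])
                if dist < r1 + r2:
                    raise ValueError(f"vials {t1.label!r} and {t2.label!r} overlap")


def default_layout(group: str = "ETL", fov_mm: float = 240.0, vial_radius_mm: float = 27.0,
                   image_size: int = 288) -> PhantomLayout:
    """Three vials (GM, WM, CSF) centred on an equilateral triangle.

    The triangle's circumradius is 60 mm, so 27 mm vials stay well inside a
    240 mm FOV and comfortably contain the default 18.0 cm^2 analysis ROI
    (radius ~23.9 mm).
    """
    circum = fov_mm / 4.0
    tissues = tissue_presets(group)
    angles = (90.0, 210.0, 330.0)
    vials = tuple(
        ((circum * math.cos(math.radians(a)), circum * math.sin(math.radians(a))),
         vial_radius_mm, t)
        for a, t in zip(angles, tissues)
    )
    layout = PhantomLayout(fov_mm=fov_mm, vials=vials, image_size=image_size)
    layout.validate()
    return layout


@dataclass(frozen=True)
class PhantomMaps:
    """Rasterized ground truth: T1/T2/PD images plus integer vial labels."""

    t1_map: np.ndarray
    t2_map: np.ndarray
    pd_map: np.ndarray
    label_map: np.ndarray
    fov_mm: float
    tissues: tuple[TissueParams, ...]
    centers_mm: tuple[tuple[float, float], ...]

    @property
    def grid(self) -> int:
        return self.t1_map.shape[0]


def _pixel_centers_mm(fov_mm: float, grid: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinate images (x, y) in mm, origin at FOV center."""
    px = fov_mm / grid
    coords = (np.arange(grid) + 0.5) * px - fov_mm / 2.0
    x, y = np.meshgrid(coords, coords)
    return x, y


def build_phantom(layout: PhantomLayout, grid: int | None = None) -> PhantomMaps:
    """Rasterize a layout onto a square pixel grid.

    A pixel belongs to a vial iff its center lies within the vial's radius;
    background pixels carry label 0 and zero T1/T2/PD.
    """
    layout.validate()
    n = int(grid or layout.image_size)
    x, y = _pixel_centers_mm(layout.fov_mm, n)
    t1 = np.zeros((n, n))
    t2 = np.zeros((n, n))
    pd = np.zeros((n, n))
    labels = np.zeros((n, n), dtype=np.int16)
    tissues, centers = [], []
    for k, ((cx, cy), r, tissue) in enumerate(layout.vials, start=1):
        inside = (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2
        t1[inside] = tissue.t1_ms
        t2[inside] = tissue.t2_ms
        pd[inside] = tissue.pd
        labels[inside] = k
        tissues.append(tissue)
        centers.append((cx, cy))
    return PhantomMaps(t1, t2, pd, labels, layout.fov_mm, tuple(tissues), tuple(centers))


@dataclass(frozen=True)
class NoiseModel:
    """Magnitude-noise model with scanner-like scaling.

    sigma(p) = sigma_ref * (ref_voxel_volume / voxel_volume(p))
                         * sqrt(bandwidth / ref_bandwidth)
                         * sqrt(accel / ref_accel)

    i.e. smaller voxels, wider receiver bandwidth and higher parallel-imaging
    acceleration all raise the noise level, as on a real scanner (the
    acceleration term ignores g-factor spatial structure).  ``kind`` selects
    Rician magnitude noise (default), plain additive Gaussian, or none.
    """

    sigma_ref: float = DEFAULT_SIGMA_REF
    ref_voxel_volume_mm3: float = 240.0 / 288 * 240.0 / 224 * 4.0
    ref_bandwidth_khz: float = 25.0
    ref_accel: float = 3.0
    kind: str = "rician"

    def __post_init__(self) -> None:
        if self.kind not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma_ref < 0:
            raise ValueError("sigma_ref must be non-negative")
        if self.kind == "none" and self.sigma_ref != 0.0:
            object.__setattr__(self, "sigma_ref", 0.0)


def default_noise_model(sigma_ref: float = DEFAULT_SIGMA_REF, kind: str = "rician") -> NoiseModel:
    return NoiseModel(sigma_ref=sigma_ref, kind=kind)


def noise_sigma(nm: NoiseModel, p: AcquisitionProtocol) -> float:
    """Noise standard deviation for one protocol under a noise model."""
    vol = voxel_volume_mm3(p)
    return (nm.sigma_ref
            * (nm.ref_voxel_volume_mm3 / vol)
            * math.sqrt(p.bandwidth_khz / nm.ref_bandwidth_khz)
            * math.sqrt(p.accel_factor / nm.ref_accel))


def simulate_acquisition(truth: PhantomMaps, p: AcquisitionProtocol, nm: NoiseModel,
                         b1_field: float | np.ndarray = 1.0,
                         seed: int | np.random.SeedSequence | None = None,
                         scale: float = DEFAULT_SCALE) -> np.ndarray:
    """Simulate the 8 magnitude images of one MDME acquisition.

    Returns an array of shape ``(8, n, n)`` ordered (te1,ti1)..(te1,ti4),
    (te2,ti1)..(te2,ti4).  Background voxels (PD = 0) have zero signal plus
    noise.  Deterministic for a fixed seed.
    """
    n = truth.grid
    tes = np.repeat([p.te1_ms, p.te2_ms], 4)
    tis = np.tile(p.delay_times_ms, 2)
    b1 = np.broadcast_to(np.asarray(b1_field, dtype=float), (n, n))
    fg = truth.pd_map > 0
    stack = np.zeros((8, n, n))
    if fg.any():
        sig = mdme_signal_arrays(
            truth.t1_map[fg][None, :], truth.t2_map[fg][None, :],
            scale * truth.pd_map[fg][None, :], b1[fg][None, :],
            tes[:, None], tis[:, None], p.tr_ms,
            p.flip_excitation_deg, p.flip_saturation_deg)
        stack[:, fg] = sig
    sigma = noise_sigma(nm, p)
    # observations are magnitude images: the signed steady-state signal is
    # negative at short delays for long-T1 media and folds over in magnitude
    if nm.kind == "none" or sigma == 0.0:
        return np.abs(stack)
    rng = np.random.default_rng(seed)
    if nm.kind == "gaussian":
        return np.abs(stack) + rng.normal(0.0, sigma, stack.shape)
    # rician: magnitude of the complex signal (real part carries the sign)
    # with iid Gaussian noise in both channels
    re = stack + rng.normal(0.0, sigma, stack.shape)
    im = rng.normal(0.0, sigma, stack.shape)
    return np.hypot(re, im)


@dataclass(frozen=True)
class StudyDesign:
    """The repeatability study: all protocol families, repeated acquisitions."""

    families: tuple[ProtocolFamily, ...] = None
    n_repeats: int = 9
    seed: int = 0
    b1_field: float | np.ndarray = 1.0
    scale: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        if self.families is None:
            object.__setattr__(self, "families", tuple(load_presets()))
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class StackRecord:
    """One simulated acquisition with its provenance."""

    family: str
    protocol: AcquisitionProtocol
    repeat_index: int
    stack: np.ndarray
    seed_entropy: tuple[int, ...]


def replicate_study(design: StudyDesign, layout: PhantomLayout, nm: NoiseModel,
                    grid: int | None = None) -> tuple[PhantomMaps, list[StackRecord]]:
    """Simulate every (family, protocol, repeat) acquisition of a study.

    Per-stack random streams are spawned from the master seed and the
    (family, protocol, repeat) indices via ``numpy.random.SeedSequence``, so
    repeats differ from each other but the full collection is reproducible
    bit-for-bit from ``design.seed``.
    """
    truth = build_phantom(layout, grid)
    records: list[StackRecord] = []
    for fi, fam in enumerate(design.families):
        for pi, proto in enumerate(fam):
            for rep in range(design.n_repeats):
                entropy = (int(design.seed), fi, pi, rep)
                ss = np.random.SeedSequence(entropy)
                stack = simulate_acquisition(truth, proto, nm, design.b1_field,
                                             seed=ss, scale=design.scale)
                records.append(StackRecord(fam.family, proto, rep, stack, entropy))
    return truth, records
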