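"""ROI statistics and coefficient-of-variation repeatability analysis.

The repeatability of quantitative T1/T2 mapping under scan-parameter changes
is summarised by two coefficients of variation (CV = 100 * SD / mean):

* **intragroup CV** — over the repeated measurements at one protocol setting
  (one ROI mean per repeat);
* **intergroup CV** — over the per-protocol mean values within one parameter
  family (one mean per family member, 4 members per family).

Measurements are ROI means of the fitted T1 and T2 maps, taken in a circle
(default area 18.0 cm^2) centred in each vial.  Sample standard deviations
(n-1 denominator) are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROISpec",
    "Measurement",
    "RepeatabilityReport",
    "roi_mean",
    "cv_percent",
    "intragroup_cv",
    "intergroup_cv",
    "measure_vials",
    "summarize_study",
]

_QUANTITIES = ("T1", "T2")


@dataclass(frozen=True)
class ROISpec:
    """A circular region of interest, specified by center and area."""

    center_xy_mm: tuple[float, float]
    area_cm2: float = 18.0
    shape: str = "circle"

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise ValueError("ROI area must be positive")
        if self.shape != "circle":
            raise ValueError(f"unsupported ROI shape {self.shape!r}")

    @property
    def radius_mm(self) -> float:
        return math.sqrt(self.area_cm2 * 100.0 / math.pi)


@dataclass(frozen=True)
class Measurement:
    """One ROI-mean value with its full provenance."""

    family: str
    protocol: str
    repeat_index: int
    vial: str
    quantity: str  # "T1" or "T2"
    value_ms: float


def roi_mean(map_img: np.ndarray, roi: ROISpec, fov_mm: float) -> tuple[float, float, int]:
    """Mean, SD and pixel count of a map inside a circular ROI.

    A pixel contributes iff its center falls within the circle (no
    partial-area weighting).  Non-finite map values inside the circle are
    excluded from the statistics but counted in ``n_pixels``.
    """
    img = np.asarray(map_img, dtype=float)
    ny, nx = img.shape
    if ny != nx:
        raise ValueError("expected a square map grid")
    px = fov_mm / nx
    cx, cy = roi.center_xy_mm
    r = roi.radius_mm
    half = fov_mm / 2.0
    if abs(cx) + r > half or abs(cy) + r > half:
        raise ValueError("ROI extends outside the map grid")
    coords = (np.arange(nx) + 0.5) * px - half
    x, y = np.meshgrid(coords, coords)
    inside = (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2
    n_pixels = int(inside.sum())
    if n_pixels == 0:
        raise ValueError("ROI covers no pixel centers; grid too coarse for this ROI")
    vals = img[inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), float("nan"), n_pixels
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd, n_pixels


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation, percent: 100 * sample SD / mean."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean


def intragroup_cv(measurements: Iterable[Measurement]) -> float:
    """CV over the repeat values of one (family, protocol, vial, quantity) cell."""
    ms = list(measurements)
    keys = {(m.family, m.protocol, m.vial, m.quantity) for m in ms}
    if len(keys) != 1:
        raise ValueError(f"measurements span {len(keys)} cells; expected exactly one")
    reps = sorted(m.repeat_index for m in ms)
    if reps != list(range(len(reps))):
        raise ValueError(f"missing or duplicated repeats: got indices {reps}")
    return cv_percent([m.value_ms for m in ms])


def intergroup_cv(group_means: Sequence[float]) -> float:
    """CV over the 4 per-protocol mean values of one family."""
    if len(group_means) != 4:
        raise ValueError(f"intergroup CV needs exactly 4 member means, got {len(group_means)}")
    return cv_percent(group_means)


def measure_vials(maps, layout, roi_area_cm2: float = 18.0, *, family: str,
                  protocol: str, repeat_index: int) -> list[Measurement]:
    """ROI-measure T1 and T2 at every vial center of a phantom layout."""
    out = []
    fov = maps.fov_mm if maps.fov_mm is not None else layout.fov_mm
    for (center, _radius, tissue) in layout.vials:
        roi = ROISpec(center_xy_mm=center, area_cm2=roi_area_cm2)
        for quantity, img in (("T1", maps.t1_map), ("T2", maps.t2_map)):
            mean, _sd, _n = roi_mean(img, roi, fov)
            out.append(Measurement(family=family, protocol=protocol,
                                   repeat_index=repeat_index, vial=tissue.label,
                                   quantity=quantity, value_ms=mean))
    return out


@dataclass(frozen=True)
class RepeatabilityReport:
    """Study summary tables.

    ``group_means``: per (family, vial, quantity) mean and SD over all
    member-protocol repeats.  ``intragroup``: CV% per (family, protocol,
    vial, quantity).  ``intergroup``: CV% per (family, vial, quantity),
    computed from the 4 per-protocol means.
    """

    group_means: pd.DataFrame
    intragroup: pd.DataFrame
    intergroup: pd.DataFrame
    n_repeats: int

    def max_intergroup_cv(self) -> float:
        return float(self.intergroup["cv_percent"].max())

    def write_csv(self, out_dir) -> list[Path]:
        """Write report tables: one means table plus one CV table per family."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = [out_dir / "report_means.csv"]
        self.group_means.to_csv(paths[0], index=False)
        for fam, sub in self.intragroup.groupby("family", sort=False):
            path = out_dir / f"report_cv_{fam}.csv"
            inter = self.intergroup[self.intergroup["family"] == fam]
            block = pd.concat([sub, inter.assign(protocol="intergroup", repeat_n=np.nan)],
                              ignore_index=True)
            block.to_csv(path, index=False)
            paths.append(path)
        return paths


def summarize_study(measurements: Iterable[Measurement]) -> RepeatabilityReport:
    """Aggregate per-scan ROI measurements into the repeatability report.

    Requires the complete (family x protocol x repeat x vial x quantity)
    grid; incomplete input raises with an explicit list of missing cells.
    """
    df = pd.DataFrame([m.__dict__ for m in measurements])
    if df.empty:
        raise ValueError("no measurements given")
    _check_complete(df)
    n_repeats = df["repeat_index"].nunique()

    gm = (df.groupby(["family", "vial", "quantity"], sort=False)["value_ms"]
            .agg(mean_ms="mean", sd_ms=lambda v: np.std(v, ddof=1))
            .reset_index())

    intra = (df.groupby(["family", "protocol", "vial", "quantity"], sort=False)["value_ms"]
               .agg(cv_percent=cv_percent, repeat_n="size")
               .reset_index())

    proto_means = (df.groupby(["family", "protocol", "vial", "quantity"], sort=False)["value_ms"]
                     .mean().reset_index())
    inter = (proto_means.groupby(["family", "vial", "quantity"], sort=False)["value_ms"]
               .agg(cv_percent=intergroup_cv)
               .reset_index())

    return RepeatabilityReport(group_means=gm, intragroup=intra, intergroup=inter,
                               n_repeats=int(n_repeats))


def _check_complete(df: pd.DataFrame) -> None:
    families = list(dict.fromkeys(df["family"]))
    vials = list(dict.fromkeys(df["vial"]))
    repeats = sorted(df["repeat_index"].unique())
    missing = []
    for fam in families:
        protos = list(dict.fromkeys(df.loc[df["family"] == fam, "protocol"]))
        if len(protos) != 4:
            missing.append(f"family {fam}: expected 4 protocols, found {protos}")
        have = {(r.protocol, r.repeat_index, r.vial, r.quantity)
                for r in df[df["family"] == fam].itertuples()}
        for proto in protos:
            for rep in repeats:
                for vial in vials:
                    for q in _QUANTITIES:
                        if (proto, rep, vial, q) not in have:
                            missing.append(f"({fam}, {proto}, repeat {rep}, {vial}, {q})")
    if missing:
        raise ValueError("incomplete study grid; missing cells:\n  " + "\n  ".join(missing[:20]))
    counts = df.groupby(["family", "protocol", "vial", "quantity"], sort=False).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced repeats across cells")
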