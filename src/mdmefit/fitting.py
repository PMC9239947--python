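"""Voxelwise least-squares inversion of the MDME signal model.

Each voxel contributes 8 magnitude intensities (2 echo times x 4 saturation
delays) that are fitted jointly for four parameters: T1, T2, the intensity
product M0 = A*PD, and the relative transmit field B1.  The observed data
are magnitudes, so the predicted intensity is the absolute value of the
signed steady-state signal; with a 120 deg saturation pulse the early-delay
signal of long-T1 media crosses zero and the magnitude folds it back up.

The optimizer is a bounded damped Gauss-Newton (Levenberg-Marquardt) solve
with an analytic Jacobian, started from closed-form staged estimates: T2
from the two-echo log ratio at the longest delay, then T1 from a log-linear
fit of the recovery at the first echo, then M0 from the recovery-corrected
amplitude.  Because the magnitude operation folds negative signals, every
admissible fold hypothesis is solved as its own smooth problem and the best
explanation wins (with a parsimony margin against spurious folds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .protocols import AcquisitionProtocol
from .signal import SignalSet, mdme_signal_arrays

__all__ = [
    "FitOptions",
    "InitEstimates",
    "FitResult",
    "QuantMaps",
    "init_estimates",
    "fit_signal",
    "fit_maps",
    "DEFAULT_BOUNDS",
]

#: Parameter bounds (T1 ms, T2 ms, M0, B1) for the bounded solver.
DEFAULT_BOUNDS = {
    "t1_ms": (50.0, 10000.0),
    "t2_ms": (5.0, 5000.0),
    "m0": (1e-9, np.inf),
    "b1": (0.5, 1.5),
}


@dataclass(frozen=True)
class FitOptions:
    """Solver options for the per-voxel fit."""

    fix_b1: bool = False          # fix B1 = 1 instead of fitting it
    max_iter: int = 200
    step_tol: float = 1e-10       # step/objective/gradient tolerance of the solver
    noise_floor: float = 0.0      # intensities at/below this do not count as signal
    min_valid_samples: int = 6
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))


@dataclass(frozen=True)
class InitEstimates:
    """Staged starting values; ``fallback`` flags a degenerate initialization."""

    t1_ms: float
    t2_ms: float
    m0: float
    b1: float
    fallback: bool = False


@dataclass(frozen=True)
class FitResult:
    t1_ms: float
    t2_ms: float
    m0: float
    b1: float
    residual_norm: float
    converged: bool
    n_iter: int
    at_bounds: bool = False


@dataclass(frozen=True)
class QuantMaps:
    """Fitted parameter images on the acquisition grid.

    Voxels outside the fitted mask are NaN in all parameter maps and False
    in ``converged_mask``; non-converged fits keep their best-so-far values
    but are flagged.
    """

    t1_map: np.ndarray
    t2_map: np.ndarray
    m0_map: np.ndarray
    b1_map: np.ndarray
    residual_map: np.ndarray
    converged_mask: np.ndarray
    fov_mm: float | None = None

    @property
    def shape(self):
        return self.t1_map.shape


def _protocol_design(p: AcquisitionProtocol):
    te = np.repeat([p.te1_ms, p.te2_ms], 4)
    ti = np.tile(np.asarray(p.delay_times_ms, dtype=float), 2)
    return te, ti


def _fold_sign_patterns(y: np.ndarray):
    """Admissible sign patterns of the 8 magnitudes.

    The recovery factor's sign is shared by both echoes and can only be
    negative at the leading delays, so each hypothesis negates the first k
    delays of both echo rows; it is admissible if the un-folded first-echo
    series is non-decreasing.
    """
    y1 = y[:4]
    patterns = []
    for k in range(4):
        s1 = y1.copy()
        s1[:k] = -s1[:k]
        if np.all(np.diff(s1) >= 0):
            pat = np.ones(8)
            pat[:k] = -1.0
            pat[4:4 + k] = -1.0
            patterns.append(pat)
    return patterns


def _sign_candidates(y: np.ndarray):
    """Possible un-foldings of a magnitude saturation-recovery series.

    The signed recovery is strictly increasing in delay time, so only the
    leading samples can be sign-flipped.  Every flip count that leaves the
    series non-decreasing is a candidate; the caller picks the branch whose
    recovery fit explains the data best.
    """
    out = []
    for k in range(len(y)):
        cand = y.copy()
        cand[:k] = -cand[:k]
        if np.all(np.diff(cand) >= 0):
            out.append(cand)
    return out or [y]


def _t1_log_linear(ys: np.ndarray, tis: np.ndarray, tr: float, cos_theta: float,
                   t1_bounds) -> tuple[float, float, bool]:
    """Iterated plateau log-linear T1 estimate from one signed recovery.

    Signed model: C * (K - (1-cos_theta) exp(-ti/T1)), K = 1 - cos_theta
    exp(-TR/T1).  Estimates the amplitude C from the longest delay at a T1
    guess, regresses ln(C*K - y) on ti, and iterates.  Returns (t1, C, ok).
    """
    t1, c = 1000.0, float("nan")
    ok = False
    for _ in range(3):
        k = 1.0 - cos_theta * math.exp(-tr / t1)
        rec_last = k - (1.0 - cos_theta) * math.exp(-tis[-1] / t1)
        if rec_last <= 0 or ys[-1] <= 0:
            break
        c = ys[-1] / rec_last
        z = c * k - ys
        if np.any(z[:-1] <= 0):
            break
        slope = np.polyfit(tis[:-1], np.log(z[:-1]), 1)[0]
        if slope >= 0:
            break
        t1 = float(np.clip(-1.0 / slope, *t1_bounds))
        ok = True
    return t1, c, ok


def init_estimates(s: SignalSet, p: AcquisitionProtocol,
                   opts: FitOptions | None = None) -> InitEstimates:
    """Closed-form staged starting values for the nonlinear fit.

    T2 comes from the log ratio of the two echoes at the longest delay
    (exact for noise-free single-exponential decay); T1 from an iterated
    log-linear fit of the first-echo recovery; M0 from the longest-delay
    amplitude corrected for T2 decay and incomplete recovery at B1 = 1.
    Noise-degenerate inputs fall back to midpoint-of-bounds values and are
    flagged.
    """
    opts = opts or FitOptions()
    te1, te2 = sorted({v.te_ms for v in s.samples})
    return _init_core(np.abs(s.intensities), te1, te2,
                      np.asarray(p.delay_times_ms, dtype=float), p.tr_ms,
                      math.cos(math.radians(p.flip_saturation_deg)), opts.bounds)


def _init_core(y, te1, te2, tis, tr, cos_theta, b) -> InitEstimates:
    y1, y2 = y[:4], y[4:]               # first echo, second echo over delays
    mid = InitEstimates(
        t1_ms=0.5 * (b["t1_ms"][0] + b["t1_ms"][1]),
        t2_ms=0.5 * (b["t2_ms"][0] + b["t2_ms"][1]),
        m0=float(np.max(y)) or 1.0, b1=1.0, fallback=True)

    if y1[-1] <= 0 or y2[-1] <= 0:
        return mid
    ratio = y1[-1] / y2[-1]
    if ratio <= 1.0:                    # noise-dominated: no measurable decay
        return mid
    t2 = float(np.clip((te2 - te1) / math.log(ratio), *b["t2_ms"]))

    # T1 from the first-echo recovery.  Each admissible magnitude un-folding
    # gets its own iterated log-linear estimate; the branch whose predicted
    # magnitudes best match the observations wins.
    t1, ok = mid.t1_ms, False
    best_sse = np.inf
    for ys in _sign_candidates(y1.copy()):
        cand_t1, c, cand_ok = _t1_log_linear(ys, tis, tr, cos_theta, b["t1_ms"])
        if not cand_ok:
            continue
        k = 1.0 - cos_theta * math.exp(-tr / cand_t1)
        pred = np.abs(c * (k - (1.0 - cos_theta) * np.exp(-tis / cand_t1)))
        sse = float(np.sum((pred - y1) ** 2))
        if sse < best_sse:
            best_sse, t1, ok = sse, cand_t1, True

    k = 1.0 - cos_theta * math.exp(-tr / t1)
    rec_last = k - (1.0 - cos_theta) * math.exp(-tis[-1] / t1)
    if rec_last <= 0:
        return mid
    m0 = float(y1[-1] / (math.exp(-te1 / t2) * rec_last))
    if not (m0 > 0 and math.isfinite(m0)):
        return mid
    return InitEstimates(t1_ms=t1, t2_ms=t2, m0=m0, b1=1.0, fallback=not ok)


def _model_and_jac(x, te, ti, tr, alpha_rad, theta_rad, fix_b1):
    """Signed model values and Jacobian w.r.t. the active parameters."""
    if fix_b1:
        t1, t2, m0 = x
        b1 = 1.0
    else:
        t1, t2, m0, b1 = x
    ct = math.cos(b1 * theta_rad)
    ca = math.cos(b1 * alpha_rad)
    e2 = np.exp(-te / t2)
    et = np.exp(-ti / t1)
    er = math.exp(-tr / t1)
    numer = 1.0 - (1.0 - ct) * et - ct * er
    denom = 1.0 - ca * ct * er
    f = m0 * e2 * numer / denom

    det_dt1 = et * (ti / t1 ** 2)
    der_dt1 = er * (tr / t1 ** 2)
    dn_dt1 = -(1.0 - ct) * det_dt1 - ct * der_dt1
    dd_dt1 = -ca * ct * der_dt1
    df_dt1 = m0 * e2 * (dn_dt1 * denom - numer * dd_dt1) / denom ** 2
    df_dt2 = f * te / t2 ** 2
    df_dm0 = e2 * numer / denom
    if fix_b1:
        jac = np.column_stack([df_dt1, df_dt2, df_dm0])
    else:
        dct = -theta_rad * math.sin(b1 * theta_rad)
        dca = -alpha_rad * math.sin(b1 * alpha_rad)
        dn_db1 = dct * (et - er)
        dd_db1 = -(dca * ct + ca * dct) * er
        df_db1 = m0 * e2 * (dn_db1 * denom - numer * dd_db1) / denom ** 2
        jac = np.column_stack([df_dt1, df_dt2, df_dm0, df_db1])
    return f, jac


@dataclass
class _LMResult:
    x: np.ndarray
    sse: float
    nfev: int
    status: int  # 1 = step/gradient tolerance met, 0 = iteration limit


def _lm_bounded(resid_jac, x0, lo, hi, scales, max_iter=200, tol=1e-10):
    """Bounded Levenberg-Marquardt for tiny problems (4 parameters, 8 data).

    Damped Gauss-Newton steps on column-scaled Jacobians, projected onto the
    box constraints with an active-set reduction (coordinates pinned at a
    bound with an outward gradient are frozen for that step).  Built for
    throughput: a voxelwise map fit runs hundreds of thousands of these
    solves, each a handful of 4x4 linear systems.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    d = np.asarray(scales, dtype=float)
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    r, jac = resid_jac(x)
    sse = float(r @ r)
    nfev = 1
    lam = 1e-3
    status = 0
    for _ in range(max_iter):
        js = jac * d                      # derivative w.r.t. scaled parameters
        g = js.T @ r
        a = js.T @ js
        free = ~(((x <= lo) & (g > 0)) | ((x >= hi) & (g < 0)))
        if not free.any() or np.max(np.abs(g[free])) <= tol * max(1.0, sse):
            status = 1
            break
        accepted = False
        for _inner in range(30):
            af = a[np.ix_(free, free)].copy()
            diag = np.maximum(af.diagonal(), 1e-30)
            af[np.diag_indices_from(af)] = diag * (1.0 + lam)
            try:
                p_free = np.linalg.solve(af, -g[free])
            except np.linalg.LinAlgError:
                p_free = -g[free] / diag
            step = np.zeros_like(x)
            step[free] = p_free * d[free]
            x_new = np.clip(x + step, lo, hi)
            r_new, jac_new = resid_jac(x_new)
            nfev += 1
            sse_new = float(r_new @ r_new)
            if sse_new <= sse:
                rel_step = np.max(np.abs(x_new - x) / (np.abs(x) + d))
                small = (sse - sse_new) <= tol * max(sse, 1e-300)
                x, r, jac, sse = x_new, r_new, jac_new, sse_new
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                if rel_step < tol or small:
                    status = 1
                break
            lam = min(lam * 4.0, 1e10)
        if not accepted or status == 1:
            if not accepted:
                status = 1            # trust region collapsed: local optimum
            break
    return _LMResult(x=x, sse=sse, nfev=nfev, status=status)


#: Cached coarse-grid design tables keyed by protocol timing and bounds; the
#: model-shape tensor is voxel-independent, so the per-voxel scan reduces to
#: one matrix-vector product.
_GRID_CACHE: dict = {}


def _grid_table(te, ti, tr, alpha_rad, theta_rad, b, fix_b1, n_t1, n_t2, n_b1):
    key = (tuple(np.round(te, 9)), tuple(np.round(ti, 9)), round(float(tr), 9),
           round(alpha_rad, 12), round(theta_rad, 12),
           tuple(b["t1_ms"]), tuple(b["t2_ms"]), tuple(b["b1"]),
           bool(fix_b1), n_t1, n_t2, n_b1)
    tab = _GRID_CACHE.get(key)
    if tab is None:
        t1g = np.geomspace(b["t1_ms"][0], b["t1_ms"][1], n_t1)
        t2g = np.geomspace(b["t2_ms"][0], b["t2_ms"][1], n_t2)
        b1g = np.array([1.0]) if fix_b1 else np.linspace(b["b1"][0], b["b1"][1], n_b1)
        T1, T2, B1 = np.meshgrid(t1g, t2g, b1g, indexing="ij")
        shape = np.abs(mdme_signal_arrays(
            T1[..., None], T2[..., None], 1.0, B1[..., None], te, ti, tr,
            math.degrees(alpha_rad), math.degrees(theta_rad)))
        flat = np.ascontiguousarray(shape.reshape(-1, len(te)))
        s2 = np.maximum(np.einsum("ij,ij->i", flat, flat), 1e-300)
        tab = (t1g, t2g, b1g, flat, s2)
        if len(_GRID_CACHE) > 64:
            _GRID_CACHE.clear()
        _GRID_CACHE[key] = tab
    return tab


def _coarse_grid_starts(y, te, ti, tr, alpha_rad, theta_rad, b, fix_b1,
                        n_t1=24, n_t2=24, n_b1=11, max_starts=2):
    """Restart candidates from a coarse (T1, T2, B1) grid, closed-form M0.

    The magnitude model can hold several basins along the (T1, B1)
    trade-off, so the scan keeps the best (T1, T2, M0) point of each local
    minimum of the per-B1-slice SSE profile (up to ``max_starts``, best
    first) rather than the single global grid optimum.
    """
    t1g, t2g, b1g, flat, s2 = _grid_table(te, ti, tr, alpha_rad, theta_rad,
                                          b, fix_b1, n_t1, n_t2, n_b1)
    q = flat @ y
    m0 = np.maximum(q / s2, b["m0"][0])
    sse = float(y @ y) - 2.0 * m0 * q + m0 * m0 * s2
    sse = sse.reshape(n_t1, n_t2, len(b1g))
    m0 = m0.reshape(n_t1, n_t2, len(b1g))

    profile = sse.min(axis=(0, 1))                    # best SSE per B1 slice
    slices = [k for k in range(len(b1g))
              if (k == 0 or profile[k] <= profile[k - 1])
              and (k == len(b1g) - 1 or profile[k] <= profile[k + 1])]
    slices.sort(key=lambda k: profile[k])
    starts = []
    for k in slices[:max_starts]:
        i, j = np.unravel_index(np.argmin(sse[:, :, k]), sse[:, :, k].shape)
        starts.append(np.array([t1g[i], t2g[j], m0[i, j, k], b1g[k]]))
    return starts


def _fit_one(y, te, ti, tr, alpha_rad, theta_rad, x0, opts: FitOptions):
    """Bounded least-squares solve for one voxel's 8 magnitudes.

    Magnitude data fold the signed recovery at its zero crossing, which
    makes the naive |model| objective non-smooth and multimodal.  The solve
    therefore works sign-restored: every admissible fold hypothesis (which
    leading delays were negative before the magnitude operation) defines a
    smooth signed-model objective, and one bounded trust-region solve runs
    per hypothesis — started from the staged initialization, or from a
    coarse-grid candidate whose predicted signs match that hypothesis.  The
    solution with the lowest magnitude-domain objective wins.
    """
    b = opts.bounds
    if opts.fix_b1:
        lo = [b["t1_ms"][0], b["t2_ms"][0], b["m0"][0]]
        hi = [b["t1_ms"][1], b["t2_ms"][1], b["m0"][1]]
        x0 = x0[:3]
        scales = [1000.0, 100.0, max(x0[2], 1e-6)]
    else:
        lo = [b["t1_ms"][0], b["t2_ms"][0], b["m0"][0], b["b1"][0]]
        hi = [b["t1_ms"][1], b["t2_ms"][1], b["m0"][1], b["b1"][1]]
        scales = [1000.0, 100.0, max(x0[2], 1e-6), 0.1]
    hi_clip = np.minimum(hi, np.finfo(float).max)
    x0 = np.clip(x0, lo, hi_clip)

    def model_signs(x):
        f, _ = _model_and_jac(x, te, ti, tr, alpha_rad, theta_rad, opts.fix_b1)
        return np.where(f >= 0, 1.0, -1.0)

    def magnitude_sse(x):
        f, _ = _model_and_jac(x, te, ti, tr, alpha_rad, theta_rad, opts.fix_b1)
        return float(np.sum((np.abs(f) - y) ** 2))

    def solve_signed(x_start, signs):
        ys = signs * y

        def resid_jac(x):
            f, j = _model_and_jac(x, te, ti, tr, alpha_rad, theta_rad, opts.fix_b1)
            return f - ys, j

        return _lm_bounded(resid_jac, x_start, lo, hi, scales,
                           max_iter=opts.max_iter, tol=opts.step_tol)

    grid_starts = _coarse_grid_starts(y, te, ti, tr, alpha_rad, theta_rad,
                                      b, opts.fix_b1)
    starts = [x0] + [np.clip(g[:3] if opts.fix_b1 else g, lo, hi_clip)
                     for g in grid_starts]

    # one solve per sign hypothesis: every admissible fold of the data plus
    # every pattern implied by a start, each matched to the most suitable
    # start (one whose predicted signs agree, else the staged init)
    start_by_pattern: dict = {}
    for x_start in starts:
        start_by_pattern.setdefault(tuple(model_signs(x_start)), x_start)
    patterns = list(start_by_pattern)
    for pat in _fold_sign_patterns(y):
        if tuple(pat) not in patterns:
            patterns.append(tuple(pat))
    patterns = patterns[:4]

    solutions, n_iter = [], 0
    sse_floor = 1e-20 * float(np.sum(y ** 2))          # numerically perfect fit
    for pat in patterns:
        x_start = start_by_pattern.get(pat, x0)
        cand = solve_signed(x_start, np.array(pat))
        n_iter += cand.nfev
        n_flips = int(np.sum(np.array(pat)[:4] < 0))
        solutions.append((magnitude_sse(cand.x), n_flips, cand))
        if solutions[-1][0] <= sse_floor:              # cannot be beaten
            break

    # fold-parsimony selection: adopting an extra sign flip must buy a
    # noise-scale SSE improvement, otherwise marginal wrong-fold fits bias
    # the parameters (an F-test-like margin; lambda=4)
    n_par = 3 if opts.fix_b1 else 4
    sigma2 = min(s for s, _, _ in solutions) / max(y.size - n_par, 1)
    best_sse, _, sol = min(solutions,
                           key=lambda t: (t[0] + 9.0 * sigma2 * t[1], t[1]))

    x = sol.x
    if opts.fix_b1:
        t1, t2, m0 = x
        b1 = 1.0
    else:
        t1, t2, m0, b1 = x
    eps = 1e-9
    at_bounds = bool(np.any(np.isclose(x, lo, rtol=0, atol=eps)
                            | np.isclose(x, np.where(np.isfinite(hi), hi, np.nan), rtol=0, atol=eps)))
    return FitResult(
        t1_ms=float(t1), t2_ms=float(t2), m0=float(m0), b1=float(b1),
        residual_norm=float(np.sqrt(best_sse / y.size)),
        converged=bool(sol.status > 0), n_iter=int(n_iter), at_bounds=at_bounds)


def fit_signal(s: SignalSet, p: AcquisitionProtocol,
               opts: FitOptions | None = None) -> FitResult:
    """Fit T1, T2, M0 (and optionally B1) to one voxel's signal set.

    Deterministic for fixed inputs and options.  Signals with fewer than
    ``opts.min_valid_samples`` intensities above the noise floor are flagged
    as non-fits (``converged=False`` with NaN parameters).
    """
    opts = opts or FitOptions()
    y = np.abs(s.intensities)
    if int(np.sum(y > opts.noise_floor)) < opts.min_valid_samples:
        nan = float("nan")
        return FitResult(nan, nan, nan, nan, nan, converged=False, n_iter=0)
    te, ti = _protocol_design(p)
    init = init_estimates(s, p, opts)
    x0 = np.array([init.t1_ms, init.t2_ms, init.m0, init.b1])
    return _fit_one(y, te, ti, p.tr_ms,
                    math.radians(p.flip_excitation_deg),
                    math.radians(p.flip_saturation_deg), x0, opts)


def _auto_mask(stack: np.ndarray, threshold: float | None) -> np.ndarray:
    mean_img = np.mean(np.abs(stack), axis=0)
    if threshold is None:
        threshold = 0.25 * float(mean_img.max())
    return mean_img > threshold


def fit_maps(stack: np.ndarray, p: AcquisitionProtocol, opts: FitOptions | None = None,
             mask: np.ndarray | None = None, mask_threshold: float | None = None,
             fov_mm: float | None = None) -> QuantMaps:
    """Apply the voxelwise fit to an 8-image stack.

    ``stack`` has shape (8, ny, nx) with images ordered (te1,ti1)..(te1,ti4),
    (te2,ti1)..(te2,ti4).  Background voxels (below ``mask_threshold`` on the
    mean intensity image, 25% of its maximum by default) are excluded and
    left NaN.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != 8:
        raise ValueError(f"expected stack of shape (8, ny, nx), got {stack.shape}")
    opts = opts or FitOptions()
    if mask is None:
        mask = _auto_mask(stack, mask_threshold)
    elif mask.shape != stack.shape[1:]:
        raise ValueError("mask shape does not match image grid")

    ny, nx = stack.shape[1:]
    t1 = np.full((ny, nx), np.nan)
    t2 = np.full((ny, nx), np.nan)
    m0 = np.full((ny, nx), np.nan)
    b1 = np.full((ny, nx), np.nan)
    res = np.full((ny, nx), np.nan)
    conv = np.zeros((ny, nx), dtype=bool)

    te, ti = _protocol_design(p)
    alpha = math.radians(p.flip_excitation_deg)
    theta = math.radians(p.flip_saturation_deg)
    tes = sorted({p.te1_ms, p.te2_ms})
    tis = p.delay_times_ms

    tis_arr = np.asarray(tis, dtype=float)
    cos_theta = math.cos(theta)
    idx = np.argwhere(mask)
    for iy, ix in idx:
        y = np.abs(stack[:, iy, ix])
        if int(np.sum(y > opts.noise_floor)) < opts.min_valid_samples:
            continue
        init = _init_core(y, tes[0], tes[1], tis_arr, p.tr_ms, cos_theta, opts.bounds)
        x0 = np.array([init.t1_ms, init.t2_ms, init.m0, init.b1])
        r = _fit_one(y, te, ti, p.tr_ms, alpha, theta, x0, opts)
        t1[iy, ix] = r.t1_ms
        t2[iy, ix] = r.t2_ms
        m0[iy, ix] = r.m0
        b1[iy, ix] = r.b1
        res[iy, ix] = r.residual_norm
        conv[iy, ix] = r.converged
    return QuantMaps(t1, t2, m0, b1, res, conv, fov_mm=fov_mm)
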