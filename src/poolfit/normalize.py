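"""Two-channel intensities to normalized log2 ratios (M) and intensities (A).

The stage follows the classic two-color workflow: median local background
is subtracted per channel, negative values are floored at 1, each spot gets
M = log2(experimental/control) and A = 0.5*log2(experimental*control), and
the intensity-dependent dye bias is removed by subtracting a loess fit of
M on A.  The smoother is a tri-cube-weighted local *quadratic* regression
with bisquare robustness iterations: degree 2 is needed because spots in
the sparse intensity tails see strongly one-sided neighbor windows, where
a local line cannot follow the curvature of the bias and leaves residual
trend exactly on the spots most likely to matter.  The fit uses usable
in-pool spots only and is applied to every spot.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import NormalizationError, PoolfitError

FLOOR = 1.0


def subtract_background(fg, bg, floor: float = FLOOR):
    """Background-subtract one channel, flooring non-positive values at 1."""
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    return np.maximum(fg - bg, floor)


def compute_MA(exp_channel, ctl_channel):
    """M/A transform of floored channel pairs.

    M = log2(exp/ctl) measures relative abundance versus the day-1 control;
    A = 0.5*log2(exp*ctl) is the mean log2 spot intensity.
    """
    exp_channel = np.asarray(exp_channel, dtype=float)
    ctl_channel = np.asarray(ctl_channel, dtype=float)
    if np.any(exp_channel < FLOOR) or np.any(ctl_channel < FLOOR):
        raise PoolfitError("channels must be floored (>= 1) before the M/A transform")
    m = np.log2(exp_channel / ctl_channel)
    a = 0.5 * np.log2(exp_channel * ctl_channel)
    return m, a


def normalize_spots(scan: pd.DataFrame) -> pd.DataFrame:
    """Add floored channels, M, A and a usability flag to a scan table."""
    out = scan.copy()
    out["exp_ch"] = subtract_background(scan["fg_exp"], scan["bg_exp"])
    out["ctl_ch"] = subtract_background(scan["fg_ctl"], scan["bg_ctl"])
    m, a = compute_MA(out["exp_ch"], out["ctl_ch"])
    out["M"] = m
    out["A"] = a
    out["usable"] = out["flag"].astype(str) != "discarded"
    return out


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    iterations: int = 3,
    anchor_spacing: float = 0.003,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust loess curve of y on x, returned as an (anchor, value) pair.

    Tri-cube weights over the ``span`` fraction of nearest neighbors,
    degree-2 local fits, ``iterations`` bisquare robustness passes.  The
    curve is evaluated at anchor points thinned to ``anchor_spacing`` of
    the x range (isolated extreme points always get their own anchor,
    where smoother bias is largest) and is meant to be interpolated
    linearly between anchors, constant beyond them.
    """
    if len(x) != len(y) or len(x) < 4:
        raise PoolfitError("loess_fit needs >= 4 paired observations")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    k = max(int(np.ceil(span * n)), 4)
    x_range = xs[-1] - xs[0]
    if x_range == 0.0:
        return np.array([xs[0]]), np.array([np.mean(ys)])
    delta = anchor_spacing * x_range

    anchors = [0]
    for i in range(1, n):
        if xs[i] - xs[anchors[-1]] > delta:
            anchors.append(i)
    if anchors[-1] != n - 1:
        anchors.append(n - 1)
    anchors = np.asarray(anchors)

    robust = np.ones(n)
    fit_at_anchors = np.empty(len(anchors))
    for _ in range(iterations + 1):
        for ai, i in enumerate(anchors):
            lo = max(0, min(i - k // 2, n - k))
            hi = lo + k
            # slide the window to hold the k nearest neighbors of xs[i]
            while lo > 0 and xs[i] - xs[lo - 1] < xs[hi - 1] - xs[i]:
                lo -= 1
                hi -= 1
            wx = xs[lo:hi]
            wy = ys[lo:hi]
            d = np.abs(wx - xs[i])
            dmax = d.max()
            tric = (1.0 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
            w = tric * robust[lo:hi]
            if w.sum() <= 0:
                w = tric
            xc = wx - xs[i]
            if np.unique(wx).size >= 3:
                # weighted quadratic via normal equations; the intercept is
                # the fitted value at the (centered) anchor
                xc2 = xc * xc
                design = np.empty((3, 3))
                s0, s1, s2 = w.sum(), (w * xc).sum(), (w * xc2).sum()
                s3, s4 = (w * xc2 * xc).sum(), (w * xc2 * xc2).sum()
                design[:] = [[s0, s1, s2], [s1, s2, s3], [s2, s3, s4]]
                rhs = np.array([(w * wy).sum(), (w * xc * wy).sum(), (w * xc2 * wy).sum()])
                try:
                    fit_at_anchors[ai] = np.linalg.solve(design, rhs)[0]
                except np.linalg.LinAlgError:
                    fit_at_anchors[ai] = np.average(wy, weights=np.maximum(w, 1e-12))
            else:
                fit_at_anchors[ai] = np.average(wy, weights=np.maximum(w, 1e-12))
        resid = ys - np.interp(xs, xs[anchors], fit_at_anchors)
        scale = np.median(np.abs(resid))
        if scale <= 0.0:
            break
        robust = np.clip(1.0 - (resid / (6.0 * scale)) ** 2, 0.0, None) ** 2
    return xs[anchors], fit_at_anchors


def loess_normalize(
    spots: pd.DataFrame,
    in_pool: pd.Series | np.ndarray | None = None,
    span: float = 0.3,
    iterations: int = 3,
    min_spots: int = 50,
) -> pd.DataFrame:
    """Subtract a loess fit of M on A from every spot of one array.

    The smoother is fitted on usable spots of in-pool strains only (false
    barcodes sit at the noise floor and would drag the curve down), then
    evaluated at every spot's A, flat beyond the fitted range.  With fewer
    than ``min_spots`` usable spots the data pass through unchanged with a
    warning.
    """
    out = spots.copy()
    fit_mask = out["usable"].to_numpy(bool)
    if in_pool is not None:
        fit_mask = fit_mask & np.asarray(in_pool, dtype=bool)
    if not fit_mask.any():
        raise NormalizationError("no usable spots to normalize on this array")
    if fit_mask.sum() < min_spots:
        warnings.warn(
            f"only {int(fit_mask.sum())} usable spots; skipping loess normalization",
            stacklevel=2,
        )
        return out

    xa, ya = loess_fit(
        out.loc[fit_mask, "A"].to_numpy(float),
        out.loc[fit_mask, "M"].to_numpy(float),
        span=span,
        iterations=iterations,
    )
    trend = np.interp(out["A"].to_numpy(float), xa, ya)
    out["M"] = out["M"] - trend
    return out


def normalize_all(
    scans: dict[int, pd.DataFrame],
    key: pd.DataFrame | None = None,
    span: float = 0.3,
    iterations: int = 3,
) -> dict[int, pd.DataFrame]:
    """Run background subtraction, M/A and loess per array."""
    pool_ids = None
    if key is not None:
        pool_ids = set(key.loc[key["in_pool"], "strain_id"])
    out = {}
    for day, scan in scans.items():
        spots = normalize_spots(scan)
        in_pool = (
            spots["strain_id"].isin(pool_ids) if pool_ids is not None else None
        )
        out[day] = loess_normalize(spots, in_pool=in_pool, span=span, iterations=iterations)
    return out
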