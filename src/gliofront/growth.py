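"""Density-dependent growth-rate estimation from culture time lapse.

The in-vitro pipeline quantifies how the net per-cell proliferation rate of
cultured glioblastoma cells depends on their density, using area confluency
A (fraction of the field covered by cells) as the density proxy:

1. texture segmentation of each phase-contrast frame (cells are detected as
   regions of high local intensity standard deviation, thresholded
   globally per frame);
2. confluency series A_s(t) per microscopic field s;
3. windowed growth rates: a linear fit A_s(t) = b_s(T) t + const over each
   sliding window [T, T + DT] (default DT = 30 h — short enough for
   linearity, long enough to resolve slow coverage changes);
4. per-cell rates r = b_s(T) / A_s(T), pooled across fields and windows
   into confluency bins: r(A) = < b_s(T)/A_s(T) > over windows with
   A_s(T) ~ A;
5. a weighted fit of the quadratic Allee law
   r(A) = rho (A/K + beta)(1 - A/K) to the binned curve.

A rising-then-falling r(A) — in contrast to the monotonically decreasing
logistic law — is the in-vitro signature of a (weak) Allee effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, optimize

__all__ = [
    "ImageStack",
    "ConfluencySeries",
    "WindowRate",
    "GrowthRateCurve",
    "AlleeFit",
    "segment",
    "confluency_series",
    "window_rates",
    "rate_curve",
    "allee_fit",
    "read_confluency_tsv",
    "write_confluency_tsv",
]


@dataclass
class ImageStack:
    """Grayscale time-lapse frames of one microscopic field."""

    frames: np.ndarray           # (n_frames, h, w)
    times: np.ndarray            # hours
    pixel_size: float = 1.0      # length / pixel
    field_id: str = "field0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if len(self.times) != len(self.frames):
            raise ValueError("one time stamp per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ConfluencySeries:
    """Coverage fraction A(t) of one culture field."""

    series_id: str
    times: np.ndarray            # hours
    A: np.ndarray                # area fraction in [0, 1]
    seeding_density: float | None = None   # cells / mm^2 label

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.times.shape != self.A.shape:
            raise ValueError("times and A must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.A < 0) | (self.A > 1)):
            raise ValueError("coverage must lie in [0, 1]")


@dataclass(frozen=True)
class WindowRate:
    """Fitted coverage growth rate over one window [T, T + DT]."""

    series_id: str
    T: float
    DT: float
    b: float                     # slope, coverage / h
    A_at_T: float
    r2: float


@dataclass
class GrowthRateCurve:
    """Binned per-cell growth rate r(A) with uncertainties."""

    A_bins: np.ndarray           # bin centres
    r: np.ndarray                # mean of b/A(T) per bin (1/h)
    sem: np.ndarray              # standard error (NaN where n_eff < 2)
    n: np.ndarray                # windows per bin
    n_eff: np.ndarray            # effective (non-overlapping) windows
    bin_width: float = 0.025
    DT: float | None = None      # window length the rates came from

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"A_bin": self.A_bins, "r": self.r,
                             "sem": self.sem, "n": self.n,
                             "n_eff": self.n_eff})


def local_std(frame: np.ndarray, window_px: int = 9) -> np.ndarray:
    """Local standard deviation of intensity over a window_px^2 neighbourhood."""
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be an odd integer >= 3")
    f = np.asarray(frame, dtype=float)
    m = ndimage.uniform_filter(f, window_px, mode="reflect")
    m2 = ndimage.uniform_filter(f * f, window_px, mode="reflect")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def segment(frame: np.ndarray, window_px: int = 9,
            threshold: str | float = "otsu") -> np.ndarray:
    """Cell-occupied mask: local intensity standard deviation above a
    global per-frame threshold.

    Cells appear as textured (high local variance) regions on a smooth
    background, so the mask is shift-invariant under global intensity
    offsets. ``threshold="otsu"`` picks the threshold per frame from the
    local-std histogram; a float gives a fixed threshold.
    """
    f = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("frame contains non-finite values")
    s = local_std(f, window_px)
    if threshold == "otsu":
        from skimage.filters import threshold_otsu
        if np.ptp(s) == 0:
            warnings.warn("constant local-std image; returning empty mask",
                          stacklevel=2)
            return np.zeros_like(s, dtype=bool)
        thr = threshold_otsu(s)
    else:
        thr = float(threshold)
        if thr == 0 and np.ptp(s) == 0:
            warnings.warn("constant image with zero threshold: empty mask",
                          stacklevel=2)
    return s > thr


def confluency_series(stack: ImageStack, window_px: int = 9,
                      threshold: str | float = "otsu") -> ConfluencySeries:
    """Coverage fraction per frame from texture segmentation."""
    A = np.array([segment(fr, window_px, threshold).mean()
                  for fr in stack.frames])
    return ConfluencySeries(stack.field_id, stack.times.copy(), A)


def window_rates(series: ConfluencySeries, DT: float = 30.0,
                 stride: int = 1, min_samples: int = 4) -> list[WindowRate]:
    """Sliding-window linear fits of coverage versus time.

    A window starts at every ``stride``-th sample time T with
    T + DT <= t_end; the OLS slope b and the coverage at the window start
    are recorded. Windows with fewer than ``min_samples`` points are
    skipped.
    """
    if DT <= 0:
        raise ValueError("DT must be > 0")
    t, A = series.times, series.A
    if t[-1] - t[0] < DT:
        raise ValueError("series shorter than one window")
    # uniform sampling lets every window share one design matrix
    dt_all = np.diff(t)
    uniform = np.allclose(dt_all, dt_all[0], rtol=1e-6)
    out: list[WindowRate] = []
    if uniform:
        n_win = int(np.floor(DT / dt_all[0])) + 1
        if n_win < min_samples:
            warnings.warn(f"windows of {n_win} samples skipped "
                          f"(min {min_samples})", stacklevel=2)
            return out
        starts = np.arange(0, len(t) - n_win + 1, stride)
        tw = sliding_window_view(t, n_win)[starts]
        Aw = sliding_window_view(A, n_win)[starts]
        tc = tw - tw.mean(axis=1, keepdims=True)
        Ac = Aw - Aw.mean(axis=1, keepdims=True)
        denom = np.sum(tc * tc, axis=1)
        b = np.sum(tc * Ac, axis=1) / denom
        resid = Ac - b[:, None] * tc
        ss_tot = np.sum(Ac * Ac, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - np.sum(resid**2, axis=1) / ss_tot,
                          1.0)
        for k, i in enumerate(starts):
            out.append(WindowRate(series.series_id, float(t[i]), DT,
                                  float(b[k]), float(A[i]), float(r2[k])))
        return out
    # non-uniform sampling: per-window fits
    for i in range(0, len(t), stride):
        sel = (t >= t[i]) & (t <= t[i] + DT)
        if t[i] + DT > t[-1]:
            break
        if sel.sum() < min_samples:
            continue
        b, _ = np.polyfit(t[sel], A[sel], 1)
        resid = A[sel] - np.polyval(np.polyfit(t[sel], A[sel], 1), t[sel])
        ss = np.sum((A[sel] - A[sel].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss if ss > 0 else 1.0
        out.append(WindowRate(series.series_id, float(t[i]), DT, float(b),
                              float(A[i]), float(r2)))
    return out


def rate_curve(rates: list[WindowRate],
               A_bins: np.ndarray | float = 0.025,
               A_max: float = 0.5) -> GrowthRateCurve:
    """Pool per-cell rates r = b/A(T) into confluency bins.

    ``A_bins`` may be a bin width (default 2.5% coverage, from 0 to
    ``A_max``) or explicit bin edges. Because sliding windows overlap, the
    SEM uses an effective sample size: per series and bin, the number of
    non-overlapping windows the contributing window starts span.
    """
    if not rates:
        raise ValueError("no window rates supplied")
    if np.isscalar(A_bins):
        edges = np.arange(0.0, A_max + A_bins / 2, A_bins)
    else:
        edges = np.asarray(A_bins, dtype=float)
    width = float(np.min(np.diff(edges)))
    A0 = np.array([w.A_at_T for w in rates])
    rv = np.array([w.b / w.A_at_T for w in rates])
    sid = np.array([w.series_id for w in rates])
    T = np.array([w.T for w in rates])
    DT = np.array([w.DT for w in rates])
    which = np.digitize(A0, edges) - 1

    centres, rr, sem, nn, neff = [], [], [], [], []
    for k in range(len(edges) - 1):
        sel = which == k
        if not sel.any():
            continue
        vals = rv[sel]
        n = int(sel.sum())
        n_eff = 0
        for s in np.unique(sid[sel]):
            ss = sel & (sid == s)
            span = T[ss].max() - T[ss].min()
            n_eff += min(int(ss.sum()), int(np.floor(span / DT[ss][0])) + 1)
        centres.append(0.5 * (edges[k] + edges[k + 1]))
        rr.append(vals.mean())
        nn.append(n)
        neff.append(n_eff)
        sem.append(vals.std(ddof=1) / np.sqrt(n_eff) if n_eff >= 2 else np.nan)
    DTs = np.unique(DT)
    return GrowthRateCurve(np.array(centres), np.array(rr), np.array(sem),
                           np.array(nn), np.array(neff), bin_width=width,
                           DT=float(DTs[0]) if len(DTs) == 1 else None)


@dataclass
class AlleeFit:
    """Weighted fit of r(A) = rho (A/K + beta)(1 - A/K)."""

    rho: float
    K: float
    beta: float
    stderr: dict
    converged: bool
    ssr: float
    logistic_preferred: bool
    A_range: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)

    def predict(self, A):
        A = np.asarray(A, dtype=float)
        return self.rho * (A / self.K + self.beta) * (1.0 - A / self.K)


def _windowed_rate(rate_fn, A0: np.ndarray, DT: float,
                   n_steps: int = 24) -> np.ndarray:
    """Predicted windowed estimate b/A(T) for trajectories of dA/dt=A*r(A).

    The sliding-window OLS slope of a smooth trajectory equals its secant
    slope to third order, so the window estimator is modelled as
    (A(T+DT) - A(T)) / (DT * A(T)); fitting this forward model instead of
    the instantaneous law removes the window-start labelling bias
    (~ r * DT/2 leftward shift of the apparent rate curve).
    """
    A = np.array(A0, dtype=float)
    hstep = DT / n_steps
    for _ in range(n_steps):
        k1 = A * rate_fn(A)
        k2 = (A + 0.5 * hstep * k1) * rate_fn(A + 0.5 * hstep * k1)
        k3 = (A + 0.5 * hstep * k2) * rate_fn(A + 0.5 * hstep * k2)
        k4 = (A + hstep * k3) * rate_fn(A + hstep * k3)
        A = A + hstep / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return (A - np.asarray(A0)) / (DT * np.asarray(A0))


def _fit_quadratic(A, r, w, DT=None):
    def law(rho, K, beta):
        return lambda a: rho * (a / K + beta) * (1.0 - a / K)

    if DT is None:
        def f(A, rho, K, beta):
            return law(rho, K, beta)(A)
    else:
        def f(A, rho, K, beta):
            return _windowed_rate(law(rho, K, beta), A, DT)

    p0 = [max(r.max(), 1e-4) * 4, max(2.0 * A.max(), 0.5), 0.05]
    popt, pcov = optimize.curve_fit(
        f, A, r, p0=p0, sigma=w, absolute_sigma=False,
        bounds=([1e-8, A.max() * 1.001, -5.0], [np.inf, 10.0, 5.0]),
        maxfev=20000)
    resid = (r - f(A, *popt)) / w
    return popt, np.sqrt(np.diag(pcov)), float(np.sum(resid**2))


def _fit_logistic(A, r, w, DT=None):
    def law(rho, K):
        return lambda a: rho * (1.0 - a / K)

    if DT is None:
        def f(A, rho, K):
            return law(rho, K)(A)
    else:
        def f(A, rho, K):
            return _windowed_rate(law(rho, K), A, DT)

    popt, _ = optimize.curve_fit(f, A, r, p0=[max(r.max(), 1e-4), 1.0],
                                 sigma=w, absolute_sigma=False,
                                 bounds=([1e-8, A.max() * 1.001],
                                         [np.inf, 10.0]), maxfev=20000)
    resid = (r - f(A, *popt)) / w
    return float(np.sum(resid**2))


def allee_fit(curve: GrowthRateCurve) -> AlleeFit:
    """Fit the quadratic Allee law to a binned r(A) curve.

    Weighted least squares with per-bin SEM weights (bins with undefined
    SEM get the median weight). When the curve carries its window length
    DT, the fit forward-models the windowed estimator b/A(T) (see
    :func:`_windowed_rate`) rather than the instantaneous law. Also fits
    the nested logistic law and flags ``logistic_preferred`` when it has
    the lower AIC — the null model for monotonically decreasing data. The
    fit is only valid over the observed coverage range (``A_range``).
    """
    if len(curve.A_bins) < 4:
        raise ValueError("need >= 4 bins to fit the three-parameter law")
    A, r = curve.A_bins, curve.r
    w = curve.sem.copy()
    good = np.isfinite(w) & (w > 0)
    if good.any():
        w = np.where(good, w, np.median(w[good]))
    else:
        w = np.ones_like(r)
    try:
        (rho, K, beta), perr, ssr_q = _fit_quadratic(A, r, w, curve.DT)
        converged = True
    except RuntimeError as exc:
        return AlleeFit(np.nan, np.nan, np.nan, {}, False, np.nan, False,
                        (float(A.min()), float(A.max())),
                        {"error": str(exc)})
    try:
        ssr_l = _fit_logistic(A, r, w, curve.DT)
    except RuntimeError:
        ssr_l = np.inf
    n = len(A)
    aic_q = n * np.log(max(ssr_q, 1e-300) / n) + 2 * 3
    aic_l = n * np.log(max(ssr_l, 1e-300) / n) + 2 * 2
    return AlleeFit(
        rho=float(rho), K=float(K), beta=float(beta),
        stderr={"rho": float(perr[0]), "K": float(perr[1]),
                "beta": float(perr[2])},
        converged=converged, ssr=ssr_q,
        logistic_preferred=bool(aic_l < aic_q),
        A_range=(float(A.min()), float(A.max())),
        diagnostics={"ssr_logistic": float(ssr_l), "aic_quadratic": float(aic_q),
                     "aic_logistic": float(aic_l)})


# --------------------------------------------------------------------------
# TSV interchange


def read_confluency_tsv(path) -> list[ConfluencySeries]:
    """Read series from a TSV with columns: series, t_hours, coverage
    [, seeding_density]."""
    df = pd.read_csv(path, sep="\t")
    required = {"series", "t_hours", "coverage"}
    if not required.issubset(df.columns):
        raise ValueError(f"TSV must have columns {sorted(required)}")
    out = []
    for sid, g in df.groupby("series", sort=False):
        g = g.sort_values("t_hours")
        dens = (float(g["seeding_density"].iloc[0])
                if "seeding_density" in g else None)
        out.append(ConfluencySeries(str(sid), g["t_hours"].to_numpy(),
                                    g["coverage"].to_numpy(), dens))
    return out


def write_confluency_tsv(series: list[ConfluencySeries], path) -> None:
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "series": s.series_id, "t_hours": s.times, "coverage": s.A,
            "seeding_density": s.seeding_density}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
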