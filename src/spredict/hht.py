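"""Hilbert-Huang transform: empirical mode decomposition + analytic signal.

EMD sifts a series into intrinsic mode functions (IMFs), locally narrowband
components ordered from fast to slow, by repeatedly subtracting the mean of
cubic-spline envelopes through the local maxima and minima.  Each IMF is then
Hilbert-transformed to get instantaneous amplitude, wrapped phase and
instantaneous angular frequency.  The sifting inner loop is compiled with
numba; envelopes use a natural cubic spline with two extrema mirror-extended
at each end to tame boundary swings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from numba import njit
from scipy.signal import hilbert

from spredict.signal_io import Segment, ValidationError

SD_TOL = 0.25  # sifting stop: sum((d_prev-d_new)^2)/sum(d_prev^2) below this
MAX_SIFT = 100


class MonotonicSignalError(ValidationError):
    """Raised when a series has fewer than 2 maxima or 2 minima."""


@dataclass
class IMFDecomposition:
    imfs: List[np.ndarray]
    residual: np.ndarray
    sift_counts: List[int]

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class AnalyticSeries:
    amplitude: np.ndarray  # a(t) >= 0
    phase: np.ndarray      # wrapped, in (-pi, pi]
    frequency: np.ndarray  # d(phase)/dt on the unwrapped phase, rad/s


@njit(cache=True, fastmath=True)
def _extrema(x):
    """Indices and values of local maxima/minima; plateaus use the midpoint."""
    n = x.shape[0]
    max_idx = np.empty(n // 2 + 2, np.int64)
    min_idx = np.empty(n // 2 + 2, np.int64)
    nmax = 0
    nmin = 0
    s_prev = 0
    last_i = 0
    for i in range(n - 1):
        d = x[i + 1] - x[i]
        if d > 0.0:
            s = 1
        elif d < 0.0:
            s = -1
        else:
            continue
        if s_prev == 1 and s == -1:
            max_idx[nmax] = ((last_i + 1) + i) // 2
            nmax += 1
        elif s_prev == -1 and s == 1:
            min_idx[nmin] = ((last_i + 1) + i) // 2
            nmin += 1
        s_prev = s
        last_i = i
    return max_idx[:nmax], min_idx[:nmin]


@njit(cache=True, fastmath=True)
def _zero_crossings(x):
    c = 0
    prev = 0.0
    for i in range(x.shape[0]):
        v = x[i]
        if v != 0.0:
            if prev != 0.0 and ((v > 0.0) != (prev > 0.0)):
                c += 1
            prev = v
    return c


@njit(cache=True, fastmath=True)
def _mirror_knots(idx, vals, n):
    """Extend extrema by mirroring up to 2 of them about each boundary."""
    m = idx.shape[0]
    # left mirrors: positions -i for the first (up to 2) extrema with i > 0
    nleft = 0
    left_pos = np.empty(2, np.float64)
    left_val = np.empty(2, np.float64)
    for k in range(m):
        if idx[k] > 0 and nleft < 2:
            left_pos[nleft] = -float(idx[k])
            left_val[nleft] = vals[k]
            nleft += 1
        if nleft == 2:
            break
    nright = 0
    right_pos = np.empty(2, np.float64)
    right_val = np.empty(2, np.float64)
    for k in range(m - 1, -1, -1):
        if idx[k] < n - 1 and nright < 2:
            right_pos[nright] = 2.0 * (n - 1) - float(idx[k])
            right_val[nright] = vals[k]
            nright += 1
        if nright == 2:
            break
    total = nleft + m + nright
    xk = np.empty(total, np.float64)
    yk = np.empty(total, np.float64)
    p = 0
    for k in range(nleft - 1, -1, -1):  # most negative first
        xk[p] = left_pos[k]
        yk[p] = left_val[k]
        p += 1
    for k in range(m):
        xk[p] = float(idx[k])
        yk[p] = vals[k]
        p += 1
    for k in range(nright):
        xk[p] = right_pos[k]
        yk[p] = right_val[k]
        p += 1
    return xk, yk


@njit(cache=True, fastmath=True)
def _natural_spline_eval(xk, yk, nq):
    """Natural cubic spline through (xk, yk), evaluated at 0, 1, ..., nq-1."""
    m = xk.shape[0]
    out = np.empty(nq, np.float64)
    if m == 2:
        slope = (yk[1] - yk[0]) / (xk[1] - xk[0])
        for q in range(nq):
            out[q] = yk[0] + slope * (float(q) - xk[0])
        return out
    h = np.empty(m - 1, np.float64)
    for i in range(m - 1):
        h[i] = xk[i + 1] - xk[i]
    nint = m - 2
    diag = np.empty(nint, np.float64)
    sub = np.empty(nint, np.float64)
    sup = np.empty(nint, np.float64)
    rhs = np.empty(nint, np.float64)
    for i in range(1, m - 1):
        sub[i - 1] = h[i - 1]
        diag[i - 1] = 2.0 * (h[i - 1] + h[i])
        sup[i - 1] = h[i]
        rhs[i - 1] = 6.0 * (
            (yk[i + 1] - yk[i]) / h[i] - (yk[i] - yk[i - 1]) / h[i - 1]
        )
    for i in range(1, nint):  # Thomas forward sweep
        w = sub[i] / diag[i - 1]
        diag[i] -= w * sup[i - 1]
        rhs[i] -= w * rhs[i - 1]
    second = np.zeros(m, np.float64)
    second[m - 2] = rhs[nint - 1] / diag[nint - 1]
    for i in range(nint - 2, -1, -1):
        second[i + 1] = (rhs[i] - sup[i] * second[i + 2]) / diag[i]
    j = 0
    for q in range(nq):
        xq = float(q)
        while j < m - 2 and xq > xk[j + 1]:
            j += 1
        hj = xk[j + 1] - xk[j]
        a = (xk[j + 1] - xq) / hj
        b = (xq - xk[j]) / hj
        out[q] = (
            a * yk[j]
            + b * yk[j + 1]
            + ((a ** 3 - a) * second[j] + (b ** 3 - b) * second[j + 1]) * hj * hj / 6.0
        )
    return out


@njit(cache=True, fastmath=True)
def _envelope_mean_from_extrema(x, max_idx, min_idx):
    n = x.shape[0]
    xk_u, yk_u = _mirror_knots(max_idx, x[max_idx], n)
    xk_l, yk_l = _mirror_knots(min_idx, x[min_idx], n)
    upper = _natural_spline_eval(xk_u, yk_u, n)
    lower = _natural_spline_eval(xk_l, yk_l, n)
    return 0.5 * (upper + lower)


@njit(cache=True, fastmath=True)
def _mean_envelope(x):
    """Mean of upper/lower spline envelopes; flags if extrema are too few."""
    max_idx, min_idx = _extrema(x)
    nmax = max_idx.shape[0]
    nmin = min_idx.shape[0]
    if nmax < 2 or nmin < 2:
        return np.zeros(x.shape[0], np.float64), nmax, nmin
    return _envelope_mean_from_extrema(x, max_idx, min_idx), nmax, nmin


@njit(cache=True, fastmath=True)
def _sift(x, sd_tol, max_sift):
    """Sift one IMF out of x.  Returns (imf, n_sifts); n_sifts == 0 means
    x is monotonic-like and no IMF can be extracted.

    Stops once the current iterate both passed the SD convergence test on the
    last subtraction and satisfies the IMF criteria (balanced extrema counts,
    zero crossings within one of the extrema count), or at the sift cap."""
    d = x.copy()
    nsift = 0
    sd = np.inf
    for _ in range(max_sift + 1):
        max_idx, min_idx = _extrema(d)
        nmax = max_idx.shape[0]
        nmin = min_idx.shape[0]
        if nmax < 2 or nmin < 2:
            break
        if nsift > 0 and sd < sd_tol:
            zc = _zero_crossings(d)
            if abs(nmax - nmin) <= 1 and abs(zc - (nmax + nmin)) <= 1:
                break
        if nsift == max_sift:
            break
        m = _envelope_mean_from_extrema(d, max_idx, min_idx)
        den = 0.0
        num = 0.0
        for i in range(d.shape[0]):
            den += d[i] * d[i]
            num += m[i] * m[i]
        d = d - m
        nsift += 1
        if den == 0.0:
            break
        sd = num / den
    return d, nsift


def sift_once(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """One sifting step: detail = x minus the mean of the two envelopes."""
    x = np.ascontiguousarray(x, dtype=float)
    if x.shape[0] < 4:
        raise ValidationError("series too short to sift (need >= 4 samples)")
    if np.ptp(x) == 0:
        raise ValidationError("cannot sift a constant series")
    mean_env, nmax, nmin = _mean_envelope(x)
    if nmax < 2 or nmin < 2:
        raise MonotonicSignalError(
            f"monotonic-like series: {nmax} maxima, {nmin} minima"
        )
    return x - mean_env, mean_env


def emd(x: np.ndarray, max_imf: int = 10) -> IMFDecomposition:
    """Decompose x into at most max_imf IMFs plus a residual trend.

    The residual is defined by subtraction, so summing the IMFs and the
    residual reconstructs the input to machine precision.  A constant input
    yields zero IMFs with the input itself as residual.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("input series contains non-finite values")
    if x.shape[0] < 16:
        raise ValidationError("series too short for EMD (need >= 16 samples)")
    imfs: List[np.ndarray] = []
    counts: List[int] = []
    residual = x.copy()
    if np.ptp(x) > 0:
        for _ in range(max_imf):
            imf, nsift = _sift(residual, SD_TOL, MAX_SIFT)
            if nsift == 0:
                break
            imfs.append(imf)
            counts.append(nsift)
            residual = residual - imf
    return IMFDecomposition(imfs=imfs, residual=residual, sift_counts=counts)


def analytic(imf: np.ndarray, fs: float) -> AnalyticSeries:
    """Amplitude / wrapped phase / instantaneous frequency of one IMF."""
    imf = np.asarray(imf, dtype=float)
    if imf.shape[0] < 8:
        raise ValidationError("series too short for the analytic signal")
    z = hilbert(imf)
    amplitude = np.abs(z)
    phase = np.angle(z)  # four-quadrant, in (-pi, pi]
    frequency = np.gradient(np.unwrap(phase)) * fs
    return AnalyticSeries(amplitude=amplitude, phase=phase, frequency=frequency)


def window_phases(segment: Segment, max_imf: int = 3) -> np.ndarray:
    """Phase matrix of one window: (window_samples x d*max_imf).

    Per channel, EMD with at most ``max_imf`` IMFs followed by the Hilbert
    phase of each IMF; columns are channel-major (ch1/imf1, ch1/imf2, ...).
    Channels yielding fewer than ``max_imf`` IMFs (e.g. constant channels)
    are zero-padded in the missing columns.
    """
    data = segment.data
    if data.shape[1] < 2:
        raise ValidationError("window_phases needs at least 2 channels")
    n, d = data.shape
    out = np.zeros((n, d * max_imf))
    for ch in range(d):
        x = data[:, ch]
        if np.ptp(x) == 0:
            continue
        dec = emd(x, max_imf=max_imf)
        for k, imf in enumerate(dec.imfs[:max_imf]):
            out[:, ch * max_imf + k] = analytic(imf, segment.fs).phase
    return out
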