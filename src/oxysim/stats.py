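"""Spike-train and time-series statistics.

The measures used throughout the experiments: interspike-interval
histograms (5-ms bins), binned firing rates, the index of dispersion
(variance-to-mean of binned spike counts, the Fano factor: 1 for a
Poisson process at every bin width), coefficients of variation, and
exponential decay fits for response half-lives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .spiking import SpikeTrain
from .units import LN2

__all__ = [
    "isi_histogram",
    "binned_counts",
    "binned_rate",
    "index_of_dispersion",
    "coefficient_of_variation",
    "DecayFit",
    "fit_exponential_decay",
]


def isi_histogram(train: SpikeTrain, bin_ms: float = 5.0) -> pd.DataFrame:
    """Interspike-interval histogram in half-open ``[k*bin, (k+1)*bin)`` ms
    bins; counts sum to N-1 for N spikes."""
    if bin_ms <= 0:
        raise ValueError("bin width must be > 0")
    isis_ms = np.diff(train.times) * 1000.0
    if isis_ms.size == 0:
        return pd.DataFrame({"bin_start_ms": np.empty(0),
                             "count": np.empty(0, dtype=int)})
    n_bins = int(np.floor(isis_ms.max() / bin_ms)) + 1
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(isis_ms, bins=edges)
    return pd.DataFrame({"bin_start_ms": edges[:-1], "count": counts})


def binned_counts(train: SpikeTrain, width: float,
                  t0: float = 0.0, t1: Optional[float] = None) -> np.ndarray:
    """Spike counts per half-open bin anchored at ``t0``; a trailing
    partial bin is dropped."""
    if width <= 0:
        raise ValueError("bin width must be > 0")
    if t1 is None:
        t1 = train.duration
    n_bins = int(np.floor((t1 - t0) / width))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    edges = t0 + np.arange(n_bins + 1) * width
    counts, _ = np.histogram(train.times, bins=edges)
    return counts


def binned_rate(train: SpikeTrain, width: float = 1.0,
                t0: float = 0.0, t1: Optional[float] = None) -> np.ndarray:
    """Firing rate (spikes/s) per bin."""
    return binned_counts(train, width, t0, t1) / width


def index_of_dispersion(train: SpikeTrain,
                        widths: Sequence[float] = (0.5, 1.0, 2.0, 4.0, 8.0),
                        mode: str = "counts") -> pd.Series:
    """Variance-to-mean ratio of binned spike activity per bin width.

    ``mode="counts"`` (default) is the Fano factor of spike counts, whose
    Poisson baseline is 1 at every width.  ``mode="rate"`` divides the
    variance of the binned rate by its mean instead (equals Fano/width).
    Returns NaN for widths where the train has no spikes.
    """
    if mode not in ("counts", "rate"):
        raise ValueError("mode must be 'counts' or 'rate'")
    out = {}
    for w in widths:
        counts = binned_counts(train, w)
        m = counts.mean()
        if m == 0:
            out[w] = np.nan
            continue
        if mode == "rate":
            rate = counts / w
            out[w] = rate.var() / rate.mean()
        else:
            out[w] = counts.var() / m
    return pd.Series(out, name=f"index_of_dispersion_{mode}")


def coefficient_of_variation(series: np.ndarray) -> float:
    """SD/mean of a binned series; NaN when the mean is not positive."""
    series = np.asarray(series, dtype=float)
    m = series.mean()
    if not m > 0:
        return np.nan
    return float(series.std() / m)


@dataclass
class DecayFit:
    """Single-exponential decay fit ``baseline + A * 2**(-(t-t0)/half_life)``."""

    half_life_s: float
    amplitude: float
    baseline: float
    r_squared: float
    degenerate: bool = False


def fit_exponential_decay(times: np.ndarray, values: np.ndarray,
                          fit_start: float = 0.0,
                          baseline: float = 0.0) -> DecayFit:
    """Least-squares fit of a decaying exponential from ``fit_start``.

    The baseline is held fixed (pass the pre-stimulus mean); the half-life
    and amplitude are fitted.  A non-decaying or flat input returns a
    ``degenerate`` fit rather than raising.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = times >= fit_start
    t = times[mask] - fit_start
    y = values[mask] - baseline
    if t.size < 5:
        raise ValueError("need at least 5 points after fit_start")

    if y[0] <= 0 or np.ptp(y) == 0 or y[-5:].mean() >= y[:5].mean():
        return DecayFit(np.nan, float(y.mean()), baseline, 0.0,
                        degenerate=True)

    # log-linear prefit for the initial guess, on the positive part
    pos = y > 0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    lam0 = -LN2 / slope if slope < 0 else t[-1] / 2.0
    a0 = float(np.exp(intercept))

    def model(t, a, lam):
        return a * 2.0 ** (-t / lam)

    try:
        popt, _ = curve_fit(model, t, y, p0=[a0, lam0], maxfev=20000)
    except RuntimeError:
        return DecayFit(np.nan, a0, baseline, 0.0, degenerate=True)
    a, lam = popt
    if lam <= 0:
        return DecayFit(np.nan, float(a), baseline, 0.0, degenerate=True)
    resid = y - model(t, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return DecayFit(float(lam), float(a), baseline, r2)
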