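"""The 24 connectivity measures and the 48-pipeline suite.

Six measure families are computed between every channel pair of a
re-referenced epoch, inside non-overlapping 2-s windows and averaged over
windows (then over epochs):

* time domain — Pearson correlation (signed), squared Pearson, and
  cross-correlation (max of |normalized cross-correlation| over lags up to
  200 ms);
* spectral domain — magnitude-squared coherence and phase locking value
  (PLV), per canonical frequency band;
* amplitude domain — relative entropy (RE), the Kullback-Leibler divergence
  between the two signals' amplitude histograms, taken in the larger
  direction (RE is asymmetric).  Higher RE means *lower* functional
  connectivity.

Coherence, PLV and RE are evaluated over seven canonical bands (delta
0.5-4, theta 4-8, alpha 8-12, beta 12-30, gamma 30-80, ripple 80-250,
broadband 0.5-250 Hz), giving 3 + 3x7 = 24 measures and, with two montages,
48 pre-processing pipelines.

Coherence cannot be estimated from a single segment (it is identically 1),
so auto-/cross-spectra are averaged across all the epoch's 2-s windows and
the coherence ratio is formed afterwards.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .rereference import apply_reference
from .signals import EpochSet, Recording, bandpass_array

logger = logging.getLogger("connet")


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSpec:
    name: str
    low: float
    high: float


CANONICAL_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 80.0),
    "ripple": BandSpec("ripple", 80.0, 250.0),
    "broadband": BandSpec("broadband", 0.5, 250.0),
}

BAND_ORDER = tuple(CANONICAL_BANDS)

TIME_DOMAIN_MEASURES = ("pearson", "pearson_sq", "xcorr")
BANDED_MEASURES = ("coh", "plv", "re")
MEASURES = TIME_DOMAIN_MEASURES + BANDED_MEASURES


@dataclass(frozen=True)
class MeasureSpec:
    id: str
    banded: bool
    window_s: float = 2.0
    max_lag_ms: float = 200.0  # xcorr only
    re_bins: int = 10          # re only

    def __post_init__(self):
        if self.id not in MEASURES:
            raise ValueError(f"unknown measure {self.id!r}")
        if self.banded != (self.id in BANDED_MEASURES):
            raise ValueError(f"measure {self.id} banded flag inconsistent")


@dataclass(frozen=True)
class PipelineSpec:
    """One (re-reference, measure, band) combination."""

    scheme: str             # 'car' | 'bipolar'
    measure: str            # one of MEASURES
    band: str | None = None  # banded measures only

    def __post_init__(self):
        if (self.band is not None) != (self.measure in BANDED_MEASURES):
            raise ValueError(
                f"measure {self.measure} and band {self.band} are inconsistent")

    @property
    def label(self) -> str:
        return "-".join(filter(None, (self.scheme, self.measure, self.band)))


def enumerate_pipelines(schemes=("car", "bipolar")) -> list[PipelineSpec]:
    """The canonical pipeline enumeration: per scheme, 3 time-domain measures
    plus 3 banded measures x 7 bands = 24; 48 in total for two schemes."""
    out = []
    for scheme in schemes:
        for m in TIME_DOMAIN_MEASURES:
            out.append(PipelineSpec(scheme, m))
        for m in BANDED_MEASURES:
            for b in BAND_ORDER:
                out.append(PipelineSpec(scheme, m, b))
    return out


@dataclass
class ConnectivityNetwork:
    """Symmetric node x node edge-weight matrix (diagonal undefined -> NaN)."""

    nodes: list[str]
    W: np.ndarray
    spec: PipelineSpec | None = None
    n_windows_used: int = 0

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.nodes)
        if self.W.shape != (n, n):
            raise ValueError("W shape does not match node count")


class EstimatorError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Windowing
# --------------------------------------------------------------------------

def window_signal(rec: Recording | np.ndarray, fs: float | None = None,
                  window_s: float = 2.0) -> np.ndarray:
    """Cut an epoch into non-overlapping windows.

    Returns an array of shape (n_windows, n_channels, window_len); the
    trailing remainder shorter than one window is dropped.
    """
    if isinstance(rec, Recording):
        data, fs = rec.data, rec.fs
    else:
        data = np.asarray(rec)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    win = int(round(window_s * fs))
    n_win = data.shape[-1] // win
    if n_win < 1:
        raise EstimatorError(
            f"epoch of {data.shape[-1]} samples shorter than one "
            f"{window_s}-s window ({win} samples)")
    trimmed = data[:, :n_win * win]
    return np.moveaxis(trimmed.reshape(data.shape[0], n_win, win), 1, 0)


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _to_matrix(vals: np.ndarray, n: int) -> np.ndarray:
    W = np.full((n, n), np.nan)
    iu, ju = _pair_index(n)
    W[iu, ju] = vals
    W[ju, iu] = vals
    return W


# --------------------------------------------------------------------------
# Time-domain measures
# --------------------------------------------------------------------------

def _window_corr(windows: np.ndarray) -> np.ndarray:
    """Per-window Pearson correlation matrices, shape (n_win, C, C); windows
    with a zero-variance channel get NaN for that channel's pairs."""
    x = windows - windows.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1)
    denom = sd[:, :, None] * sd[:, None, :]
    cov = np.einsum("wct,wdt->wcd", x, x) / windows.shape[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    r[~np.isfinite(r)] = np.nan
    return r


def pearson_network(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed Pearson r and squared Pearson r^2 per pair, each computed per
    2-s window and averaged over windows. Returns (W_r, W_r2)."""
    r = _window_corr(windows)
    with np.errstate(invalid="ignore"):
        mean_r = np.nanmean(r, axis=0)
        mean_r2 = np.nanmean(r ** 2, axis=0)
    n = windows.shape[1]
    np.fill_diagonal(mean_r, np.nan)
    np.fill_diagonal(mean_r2, np.nan)
    return mean_r, mean_r2


def xcorr_network(windows: np.ndarray, fs: float,
                  max_lag_ms: float = 200.0) -> np.ndarray:
    """Maximum over lags |tau| <= max_lag of |normalized cross-correlation|.

    Per window the signals are demeaned; the lag-tau product sum is divided
    by the overlap length and by the product of full-window standard
    deviations, then the maximum absolute value over lags is taken and
    averaged across windows.  Values are clipped to [0, 1] (the overlap
    normalization can marginally exceed 1 for strongly nonstationary
    windows).
    """
    n_win, C, N = windows.shape
    L = int(round(max_lag_ms / 1000.0 * fs))
    if L >= N:
        raise EstimatorError("max lag must be shorter than the window")
    x = windows - windows.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1)
    nfft = int(2 ** np.ceil(np.log2(2 * N)))
    F = np.fft.rfft(x, n=nfft, axis=-1)
    lags = np.concatenate([np.arange(0, L + 1), np.arange(-L, 0)])
    overlap = N - np.abs(lags)
    best = np.empty((n_win, C, C))
    for w in range(n_win):  # one window at a time to bound memory
        # cross-covariance at lag tau: sum_t x_i[t] * x_j[t + tau]
        G = np.conj(F[w])[:, None, :] * F[w][None, :, :]
        cc = np.fft.irfft(G, n=nfft, axis=-1)[..., lags % nfft]
        denom = sd[w][:, None, None] * sd[w][None, :, None] * overlap
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = np.abs(cc) / denom
        bw = np.max(cc, axis=-1)
        bw[~np.isfinite(bw)] = np.nan
        best[w] = bw
    with np.errstate(invalid="ignore"):
        W = np.nanmean(best, axis=0)
    W = np.clip(W, 0.0, 1.0)
    W = (W + W.T) / 2.0  # kill rounding asymmetry of the two FFT directions
    np.fill_diagonal(W, np.nan)
    return W


# --------------------------------------------------------------------------
# Spectral measures
# --------------------------------------------------------------------------

def coherence_networks(windows: np.ndarray, fs: float,
                       bands: dict[str, BandSpec] = CANONICAL_BANDS,
                       squared: bool = True) -> dict[str, np.ndarray]:
    """Band-averaged (magnitude-squared) coherence for every band at once.

    Hann-tapered periodograms are computed per 2-s window; auto- and
    cross-spectra are averaged across all windows of the epoch before the
    coherence ratio |Sxy|^2 / (Sxx Syy) is formed per frequency bin and
    averaged over the bins inside each band.
    """
    n_win, C, N = windows.shape
    if n_win < 2:
        raise EstimatorError(
            "coherence needs >= 2 windows (a single segment gives coherence 1)")
    taper = scipy.signal.get_window("hann", N)
    X = np.fft.rfft(windows * taper, axis=-1)
    freqs = np.fft.rfftfreq(N, d=1.0 / fs)
    Sxx = np.mean(np.abs(X) ** 2, axis=0)                      # (C, F)
    Sxy = np.einsum("wcf,wdf->cdf", X, np.conj(X)) / n_win      # (C, C, F)
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.abs(Sxy) ** 2 / (Sxx[:, None, :] * Sxx[None, :, :])
    coh = msc if squared else np.sqrt(msc)
    out = {}
    for name, band in bands.items():
        sel = (freqs >= band.low) & (freqs <= min(band.high, fs / 2))
        if not sel.any():
            raise EstimatorError(f"band {name} has no frequency bins at fs={fs}")
        with np.errstate(invalid="ignore"):
            W = np.nanmean(coh[..., sel], axis=-1)
        np.fill_diagonal(W, np.nan)
        out[name] = W
    return out


def _band_edges(band: BandSpec, fs: float) -> tuple[float, float]:
    return band.low, band.high


def _plv_from_phasors(P: np.ndarray) -> np.ndarray:
    """PLV per pair from unit phasors, shape (n_win, C, N): per window
    |mean_t exp(i dphi)|, averaged across windows."""
    n_win, C, N = P.shape
    plv = np.abs(np.einsum("wct,wdt->wcd", P, np.conj(P))) / N
    W = plv.mean(axis=0)
    np.fill_diagonal(W, np.nan)
    return W


def _unit_phasors(analytic: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        P = analytic / np.abs(analytic)
    P[~np.isfinite(P)] = 0.0
    return P


def plv_network(filtered_windows: np.ndarray) -> np.ndarray:
    """Phase locking value from band-passed windows: the analytic phase is
    extracted per window and PLV = |mean_t exp(i dphi)|, averaged across
    windows."""
    analytic = scipy.signal.hilbert(filtered_windows, axis=-1)
    return _plv_from_phasors(_unit_phasors(analytic))


def plv_network_epoch(filtered_epoch: np.ndarray, fs: float,
                      window_s: float = 2.0) -> np.ndarray:
    """PLV with the analytic signal computed on the whole band-passed epoch
    (one Hilbert transform, no per-window edge transients), then windowed."""
    analytic = scipy.signal.hilbert(filtered_epoch, axis=-1)
    P = _unit_phasors(analytic)
    return _plv_from_phasors(window_signal(P, fs, window_s))


# --------------------------------------------------------------------------
# Relative entropy
# --------------------------------------------------------------------------

def _histogram_pairs(a: np.ndarray, b: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise histograms of a and b over each row pair's pooled min-max
    range. a, b: (P, N); returns counts (P, bins) for each."""
    P, N = a.shape
    lo = np.minimum(a.min(axis=1), b.min(axis=1))
    hi = np.maximum(a.max(axis=1), b.max(axis=1))
    span = hi - lo
    degenerate = span <= 0
    span = np.where(degenerate, 1.0, span)
    def counts(x):
        idx = np.floor((x - lo[:, None]) / span[:, None] * bins).astype(np.int64)
        np.clip(idx, 0, bins - 1, out=idx)
        idx += np.arange(P)[:, None] * bins
        return np.bincount(idx.ravel(), minlength=P * bins).reshape(P, bins).astype(float)
    return counts(a), counts(b)


def _kl(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return np.sum(p * np.log(p / q), axis=-1)


def relative_entropy_pairs(a: np.ndarray, b: np.ndarray, bins: int = 10) -> np.ndarray:
    """Symmetrized-by-max KL divergence between amplitude histograms, row-wise.

    Each row pair is histogrammed into ``bins`` equal-width bins spanning the
    pooled min-max of the pair; counts get add-one-half smoothing; the KL
    divergence is computed in both directions and the larger value returned.
    """
    ca, cb = _histogram_pairs(a, b, bins)
    pa = (ca + 0.5) / (ca + 0.5).sum(axis=1, keepdims=True)
    pb = (cb + 0.5) / (cb + 0.5).sum(axis=1, keepdims=True)
    return np.maximum(_kl(pa, pb), _kl(pb, pa))


def relative_entropy_network(filtered_windows: np.ndarray,
                             re_bins: int = 10) -> np.ndarray:
    """RE network from band-passed windows, averaged across windows."""
    if re_bins < 2:
        raise EstimatorError("re_bins must be >= 2")
    n_win, C, N = filtered_windows.shape
    iu, ju = _pair_index(C)
    vals = np.zeros((n_win, len(iu)))
    for w in range(n_win):
        vals[w] = relative_entropy_pairs(
            filtered_windows[w, iu], filtered_windows[w, ju], bins=re_bins)
    return _to_matrix(vals.mean(axis=0), C)


def transform_re(W: np.ndarray, mode: str) -> np.ndarray:
    """Positivity transforms for RE networks: 'abs' -> |w|;
    'inverse_one_plus' -> 1/(1+w) (a monotone-decreasing map, so higher RE,
    i.e. lower connectivity, maps to smaller values)."""
    if mode == "abs":
        return np.abs(W)
    if mode == "inverse_one_plus":
        return 1.0 / (1.0 + W)
    raise ValueError(f"unknown RE transform {mode!r}")


# --------------------------------------------------------------------------
# Suite
# --------------------------------------------------------------------------

def epoch_networks(rec: Recording, window_s: float = 2.0,
                   max_lag_ms: float = 200.0, re_bins: int = 10,
                   bands: dict[str, BandSpec] = CANONICAL_BANDS,
                   measures: tuple[str, ...] = MEASURES,
                   ) -> dict[tuple[str, str | None], np.ndarray]:
    """All requested measures for one re-referenced epoch.

    Returns a map (measure, band or None) -> matrix.  Band-passed windows are
    shared between PLV and RE so each band is filtered once.
    """
    windows = window_signal(rec, window_s=window_s)
    out: dict[tuple[str, str | None], np.ndarray] = {}
    if "pearson" in measures or "pearson_sq" in measures:
        r, r2 = pearson_network(windows)
        if "pearson" in measures:
            out[("pearson", None)] = r
        if "pearson_sq" in measures:
            out[("pearson_sq", None)] = r2
    if "xcorr" in measures:
        out[("xcorr", None)] = xcorr_network(windows, rec.fs, max_lag_ms)
    if "coh" in measures:
        for name, W in coherence_networks(windows, rec.fs, bands).items():
            out[("coh", name)] = W
    need_filtered = [m for m in ("plv", "re") if m in measures]
    if need_filtered:
        # band-pass the continuous epoch once per band (no per-window filter
        # transients, which dominate the low bands on 2-s chunks), then window
        win = int(round(window_s * rec.fs))
        n_win = rec.n_samples // win
        epoch = rec.data[:, :n_win * win]
        for name, band in bands.items():
            filt = bandpass_array(epoch, rec.fs, band.low, band.high,
                                  warn_clip=False)
            if "plv" in measures:
                out[("plv", name)] = plv_network_epoch(filt, rec.fs, window_s)
            if "re" in measures:
                out[("re", name)] = relative_entropy_network(
                    window_signal(filt, rec.fs, window_s), re_bins)
    return out


def run_pipeline_suite(es: EpochSet, schemes=("car", "bipolar"),
                       window_s: float = 2.0, max_lag_ms: float = 200.0,
                       re_bins: int = 10, max_skip: int = 1,
                       measures: tuple[str, ...] = MEASURES,
                       bands: dict[str, BandSpec] = CANONICAL_BANDS,
                       ) -> dict[PipelineSpec, ConnectivityNetwork]:
    """Run the full pre-processing suite on a cleaned EpochSet.

    Each epoch is re-referenced under every scheme, every measure (x band) is
    computed per epoch, and per-epoch matrices are averaged element-wise into
    one network per pipeline.  With both schemes and all measures/bands this
    yields exactly 48 networks.
    """
    results: dict[PipelineSpec, ConnectivityNetwork] = {}
    n_win_total = 0
    for scheme in schemes:
        derived = [apply_reference(ep, scheme, max_skip=max_skip)
                   for ep in es.epochs]
        nodes = derived[0].labels
        acc: dict[tuple[str, str | None], list[np.ndarray]] = {}
        for rec in derived:
            n_win_total = rec.n_samples // int(round(window_s * rec.fs))
            try:
                nets = epoch_networks(rec, window_s=window_s,
                                      max_lag_ms=max_lag_ms, re_bins=re_bins,
                                      bands=bands, measures=measures)
            except EstimatorError as exc:
                logger.error("pipeline %s epoch failed: %s", scheme, exc)
                raise
            for key, W in nets.items():
                acc.setdefault(key, []).append(W)
        for (measure, band), mats in acc.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN diag
                W = np.nanmean(np.stack(mats), axis=0)
            spec = PipelineSpec(scheme, measure, band)
            results[spec] = ConnectivityNetwork(
                nodes=list(nodes), W=W, spec=spec,
                n_windows_used=n_win_total * len(derived))
    return results
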