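"""Segmentation, per-axis statistical features, normalization and PCA.

Every channel of a segment is summarized by 26 features, in fixed order:

0. minimum                     6-15. autocorrelation at lags 5, 10, ..., 50
1. maximum                     16-20. five largest DFT peak magnitudes
2. mean                        21-25. the corresponding peak frequencies (Hz)
3. variance (population)
4. skewness
5. kurtosis (non-excess)

Autocorrelation is the biased sample estimate normalized by the lag-0 value
after mean removal, so it is dimensionless in [-1, 1]; a constant channel
yields 0 at every lag.  DFT peaks are local maxima of the one-sided magnitude
spectrum excluding the DC bin, selected greedily by magnitude under a minimum
pairwise bin separation; missing peaks are reported as (0, 0).

Feature vectors are min-max normalized to [0, 1] per subject, and reduced by
PCA (eigen-decomposition of the feature covariance, top-F eigenvectors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: autocorrelation lags, in samples
AUTOCORR_LAGS = tuple(range(5, 51, 5))
#: minimum separation between reported DFT peaks, in bins (= samples of the DFT)
PEAK_MIN_SEPARATION = 11
#: number of DFT peaks reported (magnitude + frequency each)
N_PEAKS = 5
#: features per channel
N_FEATURES = 6 + len(AUTOCORR_LAGS) + 2 * N_PEAKS
#: default PCA dimensionality
DEFAULT_N_COMPONENTS = 30


def segment_stream(stream: np.ndarray, window_s: float = 5.0,
                   rate: float = 25.0) -> np.ndarray:
    """Cut a (T,) or (T, C) stream into non-overlapping windows.

    Returns an (n_segments, W[, C]) array with W = rate * window_s; a trailing
    remainder shorter than one window is dropped.  A stream shorter than one
    window yields an empty array with a warning.
    """
    stream = np.asarray(stream, dtype=float)
    w = int(round(window_s * rate))
    n = stream.shape[0] // w
    if n == 0:
        warnings.warn("stream shorter than one window: no segments produced")
    return stream[: n * w].reshape((n, w) + stream.shape[1:])


def _dft_peaks(mag: np.ndarray, floor: float = 0.0) -> list[tuple[int, float]]:
    """Greedy local-maxima selection on a one-sided spectrum (DC removed).

    ``mag[i]`` is the magnitude at bin ``i + 1``.  Candidates must exceed the
    left neighbour and be >= the right one (plateaus resolve to their first
    bin); the ends need only beat their single neighbour.  Candidates are
    taken in descending magnitude, skipping any within PEAK_MIN_SEPARATION
    bins of an already selected peak.
    """
    m = mag
    n = m.shape[0]
    if n == 0:
        return []
    left = np.empty(n, dtype=bool)
    right = np.empty(n, dtype=bool)
    left[0], right[-1] = True, True
    left[1:] = m[1:] > m[:-1]
    right[:-1] = m[:-1] >= m[1:]
    cand = np.nonzero(left & right & (m > floor))[0]
    order = cand[np.argsort(-m[cand], kind="stable")]
    chosen: list[int] = []
    for i in order:
        if len(chosen) == N_PEAKS:
            break
        if all(abs(i - j) >= PEAK_MIN_SEPARATION for j in chosen):
            chosen.append(int(i))
    return [(i + 1, float(m[i])) for i in chosen]


def extract_axis_features(x: np.ndarray, rate: float = 25.0) -> np.ndarray:
    """26 statistical features of one channel (or a batch of channels).

    ``x`` is (N,) or (B, N) with N >= max autocorrelation lag + 1; returns
    (26,) or (B, 26).  Never produces NaN: moments and autocorrelations of a
    constant channel are defined as zero.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[1]
    if n <= max(AUTOCORR_LAGS):
        raise ValueError(f"need more than {max(AUTOCORR_LAGS)} samples per channel")

    out = np.empty((x.shape[0], N_FEATURES))
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    m2 = (xc ** 2).mean(axis=1)
    m3 = (xc ** 3).mean(axis=1)
    m4 = (xc ** 4).mean(axis=1)
    nonconst = m2 > 0.0
    out[:, 0] = x.min(axis=1)
    out[:, 1] = x.max(axis=1)
    out[:, 2] = mean
    out[:, 3] = m2
    out[:, 4] = np.where(nonconst, m3 / np.where(nonconst, m2, 1.0) ** 1.5, 0.0)
    out[:, 5] = np.where(nonconst, m4 / np.where(nonconst, m2, 1.0) ** 2, 0.0)

    den = (xc ** 2).sum(axis=1)
    safe_den = np.where(den > 0.0, den, 1.0)
    for j, k in enumerate(AUTOCORR_LAGS):
        num = (xc[:, :-k] * xc[:, k:]).sum(axis=1)
        out[:, 6 + j] = np.where(den > 0.0, num / safe_den, 0.0)

    spec = np.abs(np.fft.rfft(x, axis=1))[:, 1:]  # one-sided, DC excluded
    # round-off crumbs of an (almost) frequency-free channel are not peaks
    floors = 1e-12 * np.abs(x).sum(axis=1)
    for b in range(x.shape[0]):
        peaks = _dft_peaks(spec[b], floors[b])
        mags = [p[1] for p in peaks] + [0.0] * (N_PEAKS - len(peaks))
        freqs = [p[0] * rate / n for p in peaks] + [0.0] * (N_PEAKS - len(peaks))
        out[b, 16:16 + N_PEAKS] = mags
        out[b, 16 + N_PEAKS:] = freqs
    return out[0] if single else out


def feature_matrix(channels: np.ndarray, rate: float = 25.0) -> np.ndarray:
    """Stack per-channel features of (S, C, N) channel data into (S, C*26)."""
    channels = np.asarray(channels, dtype=float)
    S, C, _ = channels.shape
    out = np.empty((S, C * N_FEATURES))
    for c in range(C):
        out[:, c * N_FEATURES:(c + 1) * N_FEATURES] = \
            extract_axis_features(channels[:, c, :], rate)
    return out


def normalize_per_subject(X: np.ndarray, subjects: np.ndarray) -> np.ndarray:
    """Min-max scale each feature dimension to [0, 1] within each subject.

    Dimensions that are constant for a subject map to 0 for that subject.
    """
    X = np.asarray(X, dtype=float)
    subjects = np.asarray(subjects)
    out = np.empty_like(X)
    for s in np.unique(subjects):
        sl = subjects == s
        lo = X[sl].min(axis=0)
        span = X[sl].max(axis=0) - lo
        safe = np.where(span > 0.0, span, 1.0)
        out[sl] = np.where(span > 0.0, (X[sl] - lo) / safe, 0.0)
    return out


@dataclass
class PcaModel:
    """Mean, top-F eigenvectors and eigenvalues of the feature covariance."""

    mean: np.ndarray
    components: np.ndarray   # (D, F), orthonormal columns
    eigenvalues: np.ndarray  # (F,), descending

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def fit_pca(X: np.ndarray, n_components: int = DEFAULT_N_COMPONENTS) -> PcaModel:
    """Eigen-decomposition of the sample covariance, keeping the top-F axes.

    If the data rank is below ``n_components`` only the informative axes are
    kept, with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two vectors to fit PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    rank = int(np.sum(w > max(w[0], 0.0) * 1e-10))
    f = min(n_components, X.shape[1], max(rank, 1))
    if f < n_components:
        warnings.warn(f"feature rank {f} below requested {n_components} "
                      "components; keeping the informative ones")
    return PcaModel(mean, V[:, :f], np.maximum(w[:f], 0.0))


def apply_pca(model: PcaModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - model.mean) @ model.components
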