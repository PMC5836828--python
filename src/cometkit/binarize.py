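"""Binarization: gray-level histogram, first-valley and Otsu thresholds,
and connected-component labeling.

Comet-assay histograms always show their first peak at the background
intensity, with comet pixels spread over a long bright shoulder.  Otsu's
criterion places its threshold high inside that shoulder and misses faint
(typically apoptotic) comets; the first valley after the background peak
sits between the background and Otsu's threshold and behaves like an
adaptive threshold that keeps the faint objects.
"""

from __future__ import annotations

import numpy as np
from skimage import measure


class NoValleyError(ValueError):
    """Raised when the smoothed histogram has no valley after its first
    peak (monotone or unimodal histograms)."""


class DegenerateHistogramError(ValueError):
    """Raised when Otsu's criterion is identically zero (single-valued
    image)."""


def histogram(img: np.ndarray, bins: int = 256) -> np.ndarray:
    """Gray-level histogram with uniform bin edges over [0, 255].

    The final bin is closed on the right so intensity 255 is counted; the
    counts sum to the number of pixels.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    img = np.asarray(img, dtype=np.float64)
    counts, _ = np.histogram(img.ravel(), bins=bins, range=(0.0, 255.0))
    return counts.astype(np.int64)


def _moving_average(counts: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smooth window must be odd and positive, got {window}")
    if window == 1:
        return counts.astype(np.float64)
    half = window // 2
    padded = np.pad(counts.astype(np.float64), half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def first_valley_threshold(counts: np.ndarray, smooth_window: int = 5) -> int:
    """Bin index of the first valley of the smoothed histogram.

    The histogram counts are moving-average smoothed, the first local
    maximum is located, and the first strict local minimum after it is
    returned (leftmost index on plateaus).  Foreground is then defined as
    intensity strictly greater than the threshold.

    Raises
    ------
    NoValleyError
        If no valley exists (callers fall back to :func:`otsu_threshold`).
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty histogram")
    s = _moving_average(counts, smooth_window)
    n = s.size

    # first local maximum: first i whose following value drops
    peak = None
    i = 0
    while i < n - 1:
        if s[i + 1] < s[i]:
            peak = i
            break
        i += 1
    if peak is None:
        raise NoValleyError("histogram is non-decreasing; no valley")

    # first strict local minimum after the peak (leftmost of plateau)
    j = peak + 1
    while j < n - 1:
        if s[j] < s[j - 1]:
            # leftmost point of a potential valley plateau
            k = j
            while k < n - 1 and s[k + 1] == s[k]:
                k += 1
            if k < n - 1 and s[k + 1] > s[k]:
                return int(j)
            j = k + 1
        else:
            j += 1
    raise NoValleyError("no valley after the first peak")


def otsu_threshold(counts: np.ndarray) -> int:
    """Threshold maximizing the between-class variance w0*w1*(mu0-mu1)^2.

    Classes are {bin <= t} and {bin > t}; ties are broken by the smallest
    t.  Raises :class:`DegenerateHistogramError` when fewer than two bins
    are populated.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("histogram has < 2 populated bins")
    total = counts.sum()
    bins = np.arange(counts.size, dtype=np.float64)
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    m0 = np.cumsum(counts * bins)[:-1]
    m1 = (counts * bins).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(counts.size - 1)
    sigma_b[valid] = (w0[valid] / total) * (w1[valid] / total) * \
        (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest t)


def apply_threshold(img: np.ndarray, t: float) -> np.ndarray:
    """Binary foreground mask: pixels with intensity strictly above ``t``."""
    return (np.asarray(img, dtype=np.float64) > t).astype(np.int32)


def label_components(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected components 1..n, ordered by first
    raster-scan pixel (8-connectivity by default, per comet candidates)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = measure.label(np.asarray(binary) > 0, connectivity=1 if connectivity == 4 else 2)
    return relabel_raster_order(lab)


def relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber nonzero labels 1..n by the raster order of each label's
    first pixel; guarantees deterministic, contiguous labeling."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    seen: dict[int, int] = {}
    order: list[int] = []
    for v in flat:
        if v != 0 and v not in seen:
            seen[v] = len(order) + 1
            order.append(v)
    if not seen:
        return labels.astype(np.int32)
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    for old, new in seen.items():
        lut[old] = new
    return lut[labels]


def threshold_image(img: np.ndarray, method: str = "valley",
                    bins: int = 256, hist_smooth_window: int = 5) -> tuple[np.ndarray, float, str]:
    """Binarize with the requested method; the valley method falls back to
    Otsu when no valley exists.  Returns (binary mask, threshold, method
    actually used)."""
    counts = histogram(img, bins)
    bin_width = 255.0 / bins
    used = method
    if method == "valley":
        try:
            t_bin = first_valley_threshold(counts, hist_smooth_window)
        except NoValleyError:
            t_bin = otsu_threshold(counts)
            used = "otsu"
    elif method == "otsu":
        t_bin = otsu_threshold(counts)
    else:
        raise ValueError(f"unknown threshold method: {method!r}")
    # threshold in intensity units: upper edge of the threshold bin
    t = (t_bin + 1) * bin_width if bins != 256 else float(t_bin)
    return apply_threshold(img, t), t, used
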