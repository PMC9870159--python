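"""Per-pixel fluctuation statistics on remapped movies.

Once a movie is remapped to a rigid reference geometry, every pixel carries
a meaningful intensity time-series. This module implements the transforms
that turn those series into maps of hidden spatiotemporal organization:

* **local coherence** — for each pixel, the mean Pearson correlation over
  the 36 unordered pairs among the 9 time-series of its 3×3 neighborhood
  (optionally on superpixel block averages). High coherence marks spatially
  coupled fluctuations; defined only where the whole neighborhood lies
  inside the reference cell mask.
* **rolling Shannon entropy** — bits of variability of a pixel's intensity
  distribution inside a temporal window; a proxy for local turnover of
  structures.
* **Gini coefficient** — spatial heterogeneity of any per-pixel map over
  the cell footprint, 0 for a homogeneous signal, → 1 for signal
  concentrated in a single pixel.
* **distance-band cross-correlation** — lagged correlation between entropy
  and coherence map sequences, summarized in zones defined by distance from
  the cell edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import block_reduce

from .io import MovieStack
from .masking import CellMask, mask_gradient

__all__ = [
    "CoherenceMap",
    "EntropyMap",
    "local_coherence",
    "rolling_coherence",
    "rolling_entropy",
    "gini",
    "zone_bands",
    "entropy_coherence_xcorr",
]

N_NEIGHBORHOOD = 9
N_PAIRS = N_NEIGHBORHOOD * (N_NEIGHBORHOOD - 1) // 2  # 36 unordered pairs


@dataclass
class CoherenceMap:
    """Mean pairwise Pearson correlation per pixel; NaN where undefined."""

    values: np.ndarray
    window_length: int | str = "full"
    window_start: int = 0
    superpixel: int = 1


@dataclass
class EntropyMap:
    """Shannon entropies (bits) per pixel; NaN outside the mask."""

    values: np.ndarray
    n_bins: int
    window_length: int
    window_start: int = 0


def _mask_array(mask) -> np.ndarray:
    return mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)


def _frames(stack) -> np.ndarray:
    if isinstance(stack, MovieStack):
        return stack.frames.astype(np.float64)
    return np.asarray(stack, dtype=np.float64)


def local_coherence(stack, mask, superpixel: int = 1) -> CoherenceMap:
    """Local 3×3 time-series coherence of a (remapped) movie.

    For every admissible pixel the nine neighborhood time-series are
    pairwise Pearson-correlated (all 36 unordered pairs) and averaged.
    Pairs involving a zero-variance series are excluded from the mean; if
    fewer than two series have variance, the value is NaN. Admissible
    pixels are those whose full 3×3 neighborhood lies inside the cell mask
    of the reference frame. With ``superpixel > 1`` the movie and mask are
    first block-averaged (mask blocks must lie fully inside the cell).
    """
    frames = _frames(stack)
    m = _mask_array(mask)
    if frames.shape[0] < 3:
        raise ValueError("coherence needs at least 3 time points")
    if frames.shape[1:] != m.shape:
        raise ValueError("mask shape must match the frame shape")
    if superpixel < 1:
        raise ValueError("superpixel must be >= 1")
    if superpixel > 1:
        frames = block_reduce(frames, (1, superpixel, superpixel), np.mean)
        m = block_reduce(m, (superpixel, superpixel), np.min).astype(bool)

    T = frames.shape[0]
    mu = frames.mean(axis=0)
    sd = frames.std(axis=0, ddof=1)
    valid = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(valid[None], (frames - mu[None]) / np.where(valid, sd, 1.0)[None], 0.0)

    # Mean over unordered pairs via the neighborhood sum of z-scores:
    #   sum_{i,j} r_ij = ||sum_i z_i||^2 / (T-1),  r_ii = 1 for valid series.
    kernel = np.ones((1, 3, 3))
    zsum = ndimage.convolve(z, kernel, mode="constant", cval=0.0)
    s_total = (zsum**2).sum(axis=0) / (T - 1)
    k = ndimage.convolve(
        valid.astype(np.float64), np.ones((3, 3)), mode="constant", cval=0.0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_r = np.where(k >= 2, (s_total - k) / np.where(k >= 2, k * (k - 1), 1.0), np.nan)

    admissible = ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    values = np.where(admissible, mean_r, np.nan)
    return CoherenceMap(values=values, window_length="full", superpixel=superpixel)


def rolling_coherence(
    stack, mask, window: int = 25, step: int = 1, superpixel: int = 1
) -> list[CoherenceMap]:
    """Local coherence in sliding temporal windows (default 25 frames)."""
    frames = _frames(stack)
    if window < 3:
        raise ValueError("window must be >= 3")
    if window > frames.shape[0]:
        raise ValueError("window longer than the movie")
    maps = []
    for start in range(0, frames.shape[0] - window + 1, step):
        cm = local_coherence(frames[start : start + window], mask, superpixel=superpixel)
        cm.window_length = window
        cm.window_start = start
        maps.append(cm)
    return maps


def _window_entropy(block: np.ndarray, n_bins: int) -> np.ndarray:
    """Shannon entropy (bits) per pixel of one (window, rows, cols) block.

    Equal-width bins spanning each pixel's min–max range within the window;
    constant series fall in a single bin and get 0 bits.
    """
    w = block.shape[0]
    mn = block.min(axis=0)
    mx = block.max(axis=0)
    span = mx - mn
    flat = span <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.floor(
            (block - mn[None]) / np.where(flat, 1.0, span)[None] * n_bins
        ).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)
    idx[:, flat] = 0
    h = np.zeros(block.shape[1:], dtype=np.float64)
    for b in range(n_bins):
        p = (idx == b).sum(axis=0) / w
        with np.errstate(divide="ignore", invalid="ignore"):
            h -= np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return h


def rolling_entropy(
    stack, mask=None, window: int = 25, n_bins: int = 8, step: int = 1
) -> list[EntropyMap]:
    """Per-pixel Shannon entropy of intensity series in sliding windows.

    Each pixel's series within the window is histogrammed into ``n_bins``
    equal-width bins over its min–max range; H = −Σ p·log2 p (0·log 0 := 0).
    Values lie in [0, log2(n_bins)] bits; NaN outside the mask.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    frames = _frames(stack)
    if window > frames.shape[0]:
        raise ValueError("window longer than the movie")
    if window < n_bins:
        import logging

        logging.getLogger(__name__).warning(
            "entropy window (%d) shorter than n_bins (%d); histograms undersampled",
            window,
            n_bins,
        )
    m = _mask_array(mask) if mask is not None else None
    maps = []
    for start in range(0, frames.shape[0] - window + 1, step):
        h = _window_entropy(frames[start : start + window], n_bins)
        if m is not None:
            h = np.where(m, h, np.nan)
        maps.append(EntropyMap(values=h, n_bins=n_bins, window_length=window, window_start=start))
    return maps


def gini(values: np.ndarray) -> float:
    """Gini coefficient of a non-negative value vector.

    G = Σ_ij |v_i − v_j| / (2 n² v̄) ∈ [0, 1): 0 for a homogeneous signal,
    (n−1)/n when all mass sits in a single pixel.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero input: Gini undefined")
    n = v.size
    x = np.sort(v)
    i = np.arange(1, n + 1)
    # sorted-form identity of the pairwise-difference definition
    return float((2.0 * np.sum(i * x) / (n * total)) - (n + 1.0) / n)


def zone_bands(
    mask,
    bands: list[tuple[float, float]] = ((0.0, 1.2), (3.6, 6.0), (8.4, 12.0)),
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Label cell pixels by distance-from-edge bands (micrometers).

    Band k (1-based label k) holds pixels whose interior distance to the
    cell edge d satisfies inner ≤ d < outer. Pixels in no band are 0.
    Default bands correspond to the lamellipodium (0–1.2 μm), transverse
    arcs (3.6–6 μm) and perinuclear region (8.4–12 μm).
    """
    import logging

    m = _mask_array(mask)
    for i, (a, b) in enumerate(bands):
        if b <= a:
            raise ValueError(f"band {i}: outer must exceed inner")
        for j, (c, d) in enumerate(bands):
            if i < j and max(a, c) < min(b, d):
                raise ValueError("bands must not overlap")
    depth = np.maximum(mask_gradient(m).distance_map, 0.0) * pixel_size
    labels = np.zeros(m.shape, dtype=np.int32)
    for k, (inner, outer) in enumerate(bands, start=1):
        sel = m & (depth >= inner) & (depth < outer)
        if not sel.any():
            logging.getLogger(__name__).warning(
                "zone band %g-%g um is empty (cell too small?)", inner, outer
            )
        labels[sel] = k
    return labels


def _lagged_pearson(e: np.ndarray, c: np.ndarray, lag: int) -> np.ndarray:
    """Per-pixel Pearson r between e(t) and c(t+lag); NaN where undefined."""
    if lag >= 0:
        a, b = e[: e.shape[0] - lag], c[lag:]
    else:
        a, b = e[-lag:], c[: c.shape[0] + lag]
    n = a.shape[0]
    if n < 3:
        return np.full(e.shape[1:], np.nan)
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    num = (am * bm).sum(axis=0)
    den = np.sqrt((am**2).sum(axis=0) * (bm**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def entropy_coherence_xcorr(
    entropy_maps: list[EntropyMap],
    coherence_maps: list[CoherenceMap],
    zones: np.ndarray,
    max_lag: int = 5,
    mode: str = "per-pixel",
) -> dict[int, pd.DataFrame]:
    """Lagged cross-correlation of entropy vs coherence map sequences, per zone.

    The two map sequences must be time-aligned (same rolling windows). In
    ``"per-pixel"`` mode each pixel's entropy/coherence series pair is
    correlated at every lag in [−max_lag, max_lag] and zone curves are the
    mean ± sd over defined pixels; ``"zone-mean"`` correlates the
    zone-averaged series instead.

    Returns a mapping from zone label to a DataFrame with columns
    ``lag``, ``mean_r``, ``std_r``, ``n_pixels``.
    """
    if len(entropy_maps) != len(coherence_maps):
        raise ValueError("entropy and coherence sequences must be time-aligned")
    starts_e = [m.window_start for m in entropy_maps]
    starts_c = [m.window_start for m in coherence_maps]
    if starts_e != starts_c:
        raise ValueError("entropy and coherence windows are misaligned")
    if mode not in ("per-pixel", "zone-mean"):
        raise ValueError("mode must be 'per-pixel' or 'zone-mean'")
    e = np.stack([m.values for m in entropy_maps])
    c = np.stack([m.values for m in coherence_maps])
    lags = range(-max_lag, max_lag + 1)
    out: dict[int, pd.DataFrame] = {}
    for zone in np.unique(zones[zones > 0]):
        zsel = zones == zone
        rows = []
        if mode == "zone-mean":
            ez = np.array([np.nanmean(np.where(zsel, fr, np.nan)) for fr in e])
            cz = np.array([np.nanmean(np.where(zsel, fr, np.nan)) for fr in c])
            for lag in lags:
                r = _lagged_pearson(ez[:, None, None], cz[:, None, None], lag)[0, 0]
                rows.append(
                    {"lag": lag, "mean_r": float(r), "std_r": 0.0, "n_pixels": int(zsel.sum())}
                )
        else:
            defined = zsel & np.all(np.isfinite(e), axis=0) & np.all(np.isfinite(c), axis=0)
            for lag in lags:
                r = _lagged_pearson(e, c, lag)
                vals = r[defined]
                vals = vals[np.isfinite(vals)]
                rows.append(
                    {
                        "lag": lag,
                        "mean_r": float(np.mean(vals)) if vals.size else np.nan,
                        "std_r": float(np.std(vals)) if vals.size else np.nan,
                        "n_pixels": int(vals.size),
                    }
                )
        out[int(zone)] = pd.DataFrame(rows)
    return out
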