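"""Texture descriptors for OCT enface images.

Four descriptor families are extracted from each grayscale enface image:
an oriented Gabor filter bank, multi-scale local binary patterns (LBP),
local phase quantization (LPQ), and gray-level co-occurrence matrix (GLCM)
statistics.  Desmoplastic (fibrotic) tumor stroma produces oriented,
band-limited structure that these descriptors separate from the isotropic
speckle of healthy mucosa.

Gabor filter bank
-----------------
Filters are defined directly in the Fourier plane as Gaussian
annular sectors,

    G(f, theta) = exp(-(|f| - f_c)^2 / (2 sigma_r^2))
                  * exp(-d(theta, theta_c)^2 / (2 sigma_t^2)),    G(0) = 0,

with four centre frequencies one octave apart starting at 0.4 cycles/pixel,
sigma_r set so the half-power radial width spans one octave
(sigma_r ~= 0.3 f_c), six orientations (0..165 degrees in 33-degree steps)
and a 30-degree FWHM angular bandwidth (sigma_t = 30 / 2.355 degrees).
The filter is one-sided (analytic); the per-filter features are the mean and
standard deviation of the complex response magnitude.  Zeroing the DC bin
makes every filter exactly offset-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern
from sklearn.base import BaseEstimator, TransformerMixin

BLOCK_ORDER = ("gabor", "lbp", "lpq", "glcm")


@dataclass
class TextureConfig:
    """Descriptor parameters (defaults follow the published configuration)."""

    gabor_frequency: float = 0.4
    gabor_n_bands: int = 4
    gabor_octave: float = 1.0
    gabor_angular_bandwidth_deg: float = 30.0
    gabor_orientations_deg: tuple = (0.0, 33.0, 66.0, 99.0, 132.0, 165.0)
    lbp_radii: tuple = (1, 2, 3)
    lbp_neighbors: tuple = (8, 16, 24)
    lpq_winsize: int = 7
    glcm_distance: int = 5
    glcm_angles_deg: tuple = (0.0, 90.0, 180.0, 270.0)
    glcm_levels: int = 256
    glcm_props: tuple = (
        "contrast",
        "dissimilarity",
        "homogeneity",
        "energy",
        "correlation",
        "ASM",
    )


@dataclass
class TextureFeatureBlock:
    """One descriptor family's feature vector with per-entry names."""

    method: str
    vector: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"{self.method} features contain non-finite values")
        if len(self.names) != self.vector.size:
            raise ValueError("names must match the feature vector length")


def _check_image(image: np.ndarray, min_side: int = 1) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if min(img.shape) < min_side:
        raise ValueError(f"image side must be >= {min_side}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    return img


# ---------------------------------------------------------------------------
# Gabor


def gabor_frequency_mask(
    shape: tuple[int, int],
    frequency: float,
    orientation_deg: float,
    angular_bandwidth_deg: float = 30.0,
) -> np.ndarray:
    """Fourier-plane Gabor mask (one-sided Gaussian annular sector)."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    r = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    sigma_r = 0.3 * frequency
    sigma_t = np.deg2rad(angular_bandwidth_deg) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t0 = np.deg2rad(orientation_deg)
    dtheta = np.angle(np.exp(1j * (theta - t0)))
    mask = np.exp(-((r - frequency) ** 2) / (2 * sigma_r**2))
    mask *= np.exp(-(dtheta**2) / (2 * sigma_t**2))
    mask[0, 0] = 0.0  # exactly DC-free
    return mask


_GABOR_MASK_CACHE: dict = {}


def _cached_gabor_mask(shape, freq, theta, bw):
    key = (shape, round(freq, 9), round(theta, 6), round(bw, 6))
    if key not in _GABOR_MASK_CACHE:
        if len(_GABOR_MASK_CACHE) > 256:
            _GABOR_MASK_CACHE.clear()
        _GABOR_MASK_CACHE[key] = gabor_frequency_mask(shape, freq, theta, bw)
    return _GABOR_MASK_CACHE[key]


def gabor_features(image: np.ndarray, config: TextureConfig | None = None) -> TextureFeatureBlock:
    """Mean and sd of the response magnitude for each (band, orientation) filter."""
    config = config or TextureConfig()
    img = _check_image(image, min_side=4)
    F = np.fft.fft2(img)
    values, names = [], []
    for b in range(config.gabor_n_bands):
        freq = config.gabor_frequency / (2.0**config.gabor_octave) ** b
        for theta in config.gabor_orientations_deg:
            mask = _cached_gabor_mask(img.shape, freq, theta, config.gabor_angular_bandwidth_deg)
            mag = np.abs(np.fft.ifft2(F * mask))
            values += [mag.mean(), mag.std()]
            names += [
                f"gabor_f{freq:.4f}_t{int(theta):03d}_mean",
                f"gabor_f{freq:.4f}_t{int(theta):03d}_sd",
            ]
    return TextureFeatureBlock("gabor", np.array(values), names)


# ---------------------------------------------------------------------------
# LBP


def lbp_features(image: np.ndarray, config: TextureConfig | None = None) -> TextureFeatureBlock:
    """Multi-scale rotation-invariant uniform LBP histograms plus local variance.

    For each (radius, P) pair the normalized P+2-bin uniform-pattern histogram
    is concatenated with the mean of the local neighbourhood variance map
    (the "histograms and variances" pairing).
    """
    config = config or TextureConfig()
    img = _check_image(image)
    # quantize to integer gray levels first: LBP thresholds neighbour
    # differences, and float round-off in interpolated neighbours is noise
    img = quantize_gray_levels(img, config.glcm_levels).astype(int)
    values, names = [], []
    for radius, P in zip(config.lbp_radii, config.lbp_neighbors):
        if min(img.shape) < 2 * radius + 1:
            raise ValueError(f"image smaller than 2*radius+1 for radius {radius}")
        codes = local_binary_pattern(img, P, radius, method="uniform")
        hist, _ = np.histogram(codes, bins=np.arange(P + 3) - 0.5)
        hist = hist / hist.sum()
        var_map = local_binary_pattern(img, P, radius, method="var")
        var_summary = float(np.nanmean(np.nan_to_num(var_map, nan=0.0)))
        values += list(hist) + [var_summary]
        names += [f"lbp_r{radius}_p{P}_h{k}" for k in range(P + 2)]
        names += [f"lbp_r{radius}_p{P}_var"]
    return TextureFeatureBlock("lbp", np.array(values), names)


# ---------------------------------------------------------------------------
# LPQ


def lpq_codes(image: np.ndarray, winsize: int = 7) -> np.ndarray:
    """8-bit LPQ code image (valid region only).

    The short-time Fourier transform of each winsize x winsize neighbourhood
    (uniform window) is evaluated at the four lowest non-zero frequencies
    u1 = (a, 0), u2 = (0, a), u3 = (a, a), u4 = (a, -a) with a = 1/winsize,
    via  F(u, x) = sum_k f(x + k) exp(-2 pi i u . k).  The code packs the
    signs of [Re F1..F4, Im F1..F4] into a byte (bit j set iff g_j > 0).
    """
    img = _check_image(image, min_side=winsize)
    r = winsize // 2
    k = np.arange(-r, r + 1)
    a = 1.0 / winsize
    w0 = np.ones(winsize, dtype=complex)
    w1 = np.exp(-2j * np.pi * a * k)
    # separable kernels, index order (row, col) = (y, x)
    kernels = [
        np.outer(w0, w1),            # u = (a, 0): oscillation along x (columns)
        np.outer(w1, w0),            # u = (0, a): along y (rows)
        np.outer(w1, w1),            # u = (a, a)
        np.outer(w1, np.conj(w1)),   # u = (fy, fx) = (a, -a)
    ]
    responses = []
    for K in kernels:
        # correlation with the window: convolve with the doubly reversed kernel
        resp = fftconvolve(img.astype(complex), K[::-1, ::-1], mode="valid")
        responses.append(resp)
    g = np.concatenate(
        [np.real(responses[i])[None] for i in range(4)]
        + [np.imag(responses[i])[None] for i in range(4)],
        axis=0,
    )
    bits = (g > 1e-9).astype(np.uint8)  # small tolerance kills FFT round-off at 0
    codes = np.zeros(bits.shape[1:], dtype=np.uint8)
    for j in range(8):
        codes |= bits[j] << j
    return codes


def lpq_features(image: np.ndarray, config: TextureConfig | None = None) -> TextureFeatureBlock:
    """Normalized 256-bin histogram of LPQ codes."""
    config = config or TextureConfig()
    codes = lpq_codes(image, config.lpq_winsize)
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    hist /= hist.sum()
    names = [f"lpq_h{k}" for k in range(256)]
    return TextureFeatureBlock("lpq", hist, names)


# ---------------------------------------------------------------------------
# GLCM


def quantize_gray_levels(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Linear min-max rescale to integer gray levels 0..levels-1."""
    img = _check_image(image)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_features(image: np.ndarray, config: TextureConfig | None = None) -> TextureFeatureBlock:
    """Six co-occurrence properties per angle at the configured pixel offset.

    Each angle's matrix is kept separate (asymmetric, normalized); properties
    are ordered property-major, angle-minor.
    """
    config = config or TextureConfig()
    img = _check_image(image)
    if max(img.shape) <= config.glcm_distance:
        raise ValueError("image max dimension must exceed the GLCM distance")
    q = quantize_gray_levels(img, config.glcm_levels)
    glcm = graycomatrix(
        q,
        distances=[config.glcm_distance],
        angles=list(np.deg2rad(config.glcm_angles_deg)),
        levels=config.glcm_levels,
        symmetric=False,
        normed=True,
    )
    values, names = [], []
    for prop in config.glcm_props:
        vals = graycoprops(glcm, prop)[0]  # one distance -> (n_angles,)
        values += list(vals)
        names += [f"glcm_{prop}_a{int(a):03d}" for a in config.glcm_angles_deg]
    return TextureFeatureBlock("glcm", np.array(values), names)


# ---------------------------------------------------------------------------
# combined extraction


def extract_all(image: np.ndarray, config: TextureConfig | None = None) -> list[TextureFeatureBlock]:
    """The four descriptor blocks in fixed order (gabor, lbp, lpq, glcm)."""
    config = config or TextureConfig()
    return [
        gabor_features(image, config),
        lbp_features(image, config),
        lpq_features(image, config),
        glcm_features(image, config),
    ]


class TextureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping a stack of images to texture features.

    ``transform`` accepts a list of 2-D arrays (or objects with a ``pixels``
    attribute) and returns an (n_images, n_features) matrix.  After the first
    transform, ``block_slices_`` maps each block name to its column slice and
    ``feature_names_`` holds the per-column labels.
    """

    def __init__(self, config: TextureConfig | None = None):
        self.config = config

    def fit(self, images, y=None):
        return self

    def transform(self, images) -> np.ndarray:
        config = self.config or TextureConfig()
        rows = []
        for im in images:
            pix = getattr(im, "pixels", im)
            blocks = extract_all(pix, config)
            rows.append(np.concatenate([b.vector for b in blocks]))
            if not hasattr(self, "block_slices_"):
                self.block_slices_ = {}
                self.feature_names_ = []
                start = 0
                for b in blocks:
                    stop = start + b.vector.size
                    self.block_slices_[b.method] = slice(start, stop)
                    self.feature_names_ += b.names
                    start = stop
        return np.stack(rows)
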