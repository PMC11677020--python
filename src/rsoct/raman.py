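"""Raman spectral preprocessing chain.

Raw probe spectra carry autofluorescence background, the instrument's
intensity-response modulation, detector noise and cosmic-ray spikes.  The
chain applied here, in fixed order, is:

    spike removal -> wavenumber calibration -> intensity-response correction
    -> batch SVD denoising -> ALS baseline removal -> EMSC background removal
    -> area normalization -> Welch band selection

Each stage is available both as a plain function (operating on one spectrum
or one batch) and, where it is fit/transform shaped, as a scikit-learn style
transformer so the stages compose with sklearn pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solveh_banded
from scipy.stats import ttest_ind
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import HEALTHY, TUMOR, SpectrumRecord

PREPROCESS_STAGES = (
    "spikes",
    "calibration",
    "response",
    "svd",
    "als",
    "emsc",
    "normalize",
    "welch",
)


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    Defaults follow the published settings: SVD rank 30, ALS with
    lambda = 1e3, p = 1e-5 over 10 iterations, and Welch selection at
    alpha = 1e-10.
    """

    svd_rank: int = 30
    als_lambda: float = 1e3
    als_p: float = 1e-5
    als_iterations: int = 10
    welch_alpha: float = 1e-10
    spike_threshold: float = 8.0
    spike_max_width: int = 3
    emsc_poly_order: int = 2
    emsc_interferents: tuple = ()

    def __post_init__(self) -> None:
        if not 0 < self.als_p < 1:
            raise ValueError("als_p must be in (0, 1)")
        if self.svd_rank < 1:
            raise ValueError("svd_rank must be >= 1")
        if not 0 < self.welch_alpha < 1:
            raise ValueError("welch_alpha must be in (0, 1)")


@dataclass
class CalibrationModel:
    """Channel-to-wavenumber mapping plus optional intensity response.

    ``pixel_to_wavenumber`` is a degree-5 polynomial fitted to reference-peak
    positions (polystyrene in practice); ``response_correction`` is a strictly
    positive per-channel curve the spectra are divided by.
    """

    pixel_to_wavenumber: np.polynomial.Polynomial
    residuals: np.ndarray
    response_correction: np.ndarray | None = None

    def map_channels(self, channels: np.ndarray) -> np.ndarray:
        return self.pixel_to_wavenumber(np.asarray(channels, dtype=float))


@dataclass
class BandSelection:
    """Per-channel Welch p-values with the selected-channel mask and regions."""

    wavenumbers: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray
    regions: list[tuple[float, float]]
    alpha: float

    @property
    def n_regions(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# spike removal


def detect_spikes(
    intensities: np.ndarray, threshold: float = 8.0, max_width: int = 3
) -> np.ndarray:
    """Flag cosmic-spike channels from first-difference statistics.

    A spike is a 1..max_width channel excursion: a robust (median/MAD)
    z-score of the first differences crosses +threshold and then crosses
    -threshold within max_width channels.  Genuine Raman bands are far wider
    and never reverse slope that fast, so they are not flagged.
    """
    y = np.asarray(intensities, dtype=float)
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    scale = 1.4826 * mad
    if scale < 1e-12:
        scale = np.std(d) + 1e-12
    z = (d - np.median(d)) / scale
    flags = np.zeros(y.size, dtype=bool)
    up = np.flatnonzero(z > threshold)
    for i in up:
        for j in range(i + 1, min(i + max_width + 1, z.size)):
            if z[j] < -threshold:
                flags[i + 1 : j + 1] = True
                break
    return flags


def remove_cosmic_spikes(
    intensities: np.ndarray, threshold: float = 8.0, max_width: int = 3
) -> np.ndarray:
    """Replace flagged spike channels by linear interpolation of neighbours.

    All unflagged channels are returned bit-identical.
    """
    y = np.asarray(intensities, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    flags = detect_spikes(y, threshold, max_width)
    if not flags.any():
        return y.copy()
    if flags.all():
        raise ValueError("all channels flagged as spikes; degenerate input")
    out = y.copy()
    idx = np.arange(y.size)
    out[flags] = np.interp(idx[flags], idx[~flags], y[~flags])
    return out


# ---------------------------------------------------------------------------
# calibration


def calibrate_wavenumber(
    measured_channels: np.ndarray, reference_wavenumbers: np.ndarray, degree: int = 5
) -> CalibrationModel:
    """Fit the channel -> wavenumber polynomial from matched reference peaks.

    Requires at least degree + 2 matched pairs (one more than the fit needs,
    so a residual check is possible) and a strictly increasing mapping over
    the measured channel range.
    """
    ch = np.asarray(measured_channels, dtype=float)
    wn = np.asarray(reference_wavenumbers, dtype=float)
    if ch.size != wn.size:
        raise ValueError("measured and reference peak lists must have equal length")
    if ch.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} matched peak pairs, got {ch.size}")
    poly = np.polynomial.Polynomial.fit(ch, wn, deg=degree)
    grid = np.linspace(ch.min(), ch.max(), 2048)
    if not np.all(np.diff(poly(grid)) > 0):
        raise ValueError("fitted calibration is non-monotone over the used range")
    residuals = wn - poly(ch)
    return CalibrationModel(poly.convert(), residuals)


def correct_intensity_response(
    intensities: np.ndarray, response_correction: np.ndarray
) -> np.ndarray:
    """Divide out the instrument intensity-response curve, channel-wise."""
    y = np.asarray(intensities, dtype=float)
    r = np.asarray(response_correction, dtype=float)
    if r.shape != y.shape:
        raise ValueError("response curve length must match the spectrum")
    if np.any(r <= 0):
        raise ValueError("response curve must be strictly positive")
    return y / r


# ---------------------------------------------------------------------------
# denoising and background removal


def svd_denoise(spectra: np.ndarray, rank: int = 30) -> np.ndarray:
    """Best low-rank approximation of the (n_spectra, n_channels) batch.

    The effective rank is min(rank, n, m); a batch smaller than the requested
    rank is passed through unchanged (no error).
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 spectra")
    r = min(rank, *X.shape)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    return (U[:, :r] * s[:r]) @ Vt[:r]


_DTD_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _second_diff_penalty(m: int):
    """Diagonals of D2'D2 for the ALS smoothness penalty (cached per length)."""
    if m not in _DTD_CACHE:
        D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m))
        A = (D.T @ D).todia()
        offsets = {off: A.diagonal(off) for off in (0, 1, 2)}
        _DTD_CACHE[m] = (offsets[0], offsets[1], offsets[2])
    return _DTD_CACHE[m]


def als_baseline(
    intensities: np.ndarray,
    lam: float = 1e3,
    p: float = 1e-5,
    iterations: int = 10,
):
    """Asymmetric-least-squares baseline estimate.

    Minimizes sum_i w_i (y_i - z_i)^2 + lam * ||D2 z||^2 with asymmetric
    weights w_i = p where y_i > z_i and 1 - p otherwise, re-estimated for the
    stated number of iterations.  The tiny p pushes the smooth curve under the
    peaks, so z tracks the slowly varying autofluorescence background.

    Returns ``(baseline, corrected)`` with corrected = y - baseline.
    """
    y = np.asarray(intensities, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("input spectrum must be finite")
    m = y.size
    d0, d1, d2 = _second_diff_penalty(m)
    w = np.ones(m)
    z = y.copy()
    ab = np.zeros((3, m))
    for _ in range(iterations):
        ab[2] = lam * d0 + w
        ab[1, 1:] = lam * d1
        ab[0, 2:] = lam * d2
        z = solveh_banded(ab, w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z, y - z


def emsc_correct(
    intensities: np.ndarray,
    reference: np.ndarray,
    interferents: list[np.ndarray] | tuple = (),
    poly_order: int = 2,
):
    """Extended multiplicative signal correction against a reference spectrum.

    Models the spectrum as  y ~= b * reference + sum_k c_k * interferent_k +
    polynomial(poly_order)  by least squares and returns the corrected
    spectrum  (y - interferent part - polynomial) / b  together with the
    fitted coefficients ``{"b": b, "interferents": c, "poly": d}``.
    With an empty interferent library this reduces to multiplicative scatter
    correction with a polynomial background.
    """
    y = np.asarray(intensities, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != y.shape:
        raise ValueError("reference must be on the same axis as the spectrum")
    cols = [ref]
    for q in interferents:
        q = np.asarray(q, dtype=float)
        if q.shape != y.shape:
            raise ValueError("interferent spectra must be on the same axis")
        cols.append(q)
    t = np.linspace(-1.0, 1.0, y.size)
    poly_cols = [np.polynomial.chebyshev.Chebyshev.basis(k)(t) for k in range(poly_order + 1)]
    X = np.column_stack(cols + poly_cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    b = coef[0]
    if abs(b) < 1e-6:
        raise ValueError("EMSC reference coefficient ~ 0; non-invertible scaling")
    n_int = len(cols) - 1
    c = coef[1 : 1 + n_int]
    d = coef[1 + n_int :]
    background = X[:, 1 : 1 + n_int] @ c + X[:, 1 + n_int :] @ d
    corrected = (y - background) / b
    return corrected, {"b": float(b), "interferents": c, "poly": d}


def area_normalize(intensities: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    """Scale the spectrum so its trapezoidal integral over the axis is 1."""
    y = np.asarray(intensities, dtype=float)
    x = np.asarray(wavenumbers, dtype=float)
    area = np.trapezoid(y, x)
    if abs(area) < 1e-12 * max(np.abs(y).max(), 1.0) * (x[-1] - x[0]):
        raise ValueError("zero-area spectrum cannot be normalized")
    return y / area


# ---------------------------------------------------------------------------
# band selection


def welch_band_select(
    healthy_spectra: np.ndarray,
    tumor_spectra: np.ndarray,
    wavenumbers: np.ndarray,
    alpha: float = 1e-10,
) -> BandSelection:
    """Per-channel Welch (unequal-variance) t-test between the two classes.

    Channels with two-sided p < alpha form the selection mask; maximal
    contiguous runs of the mask are reported as (start, end) wavenumber
    regions (single-channel runs kept).
    """
    H = np.atleast_2d(np.asarray(healthy_spectra, dtype=float))
    T = np.atleast_2d(np.asarray(tumor_spectra, dtype=float))
    if H.shape[0] < 2 or T.shape[0] < 2:
        raise ValueError("need at least 2 spectra per class (variance undefined)")
    with np.errstate(divide="ignore", invalid="ignore"):
        result = ttest_ind(H, T, axis=0, equal_var=False)
    p = np.asarray(result.pvalue)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical channels
    mask = p < alpha
    x = np.asarray(wavenumbers, dtype=float)
    regions = _mask_regions(mask, x)
    return BandSelection(x, p, mask, regions, alpha)


def _mask_regions(mask: np.ndarray, wavenumbers: np.ndarray) -> list[tuple[float, float]]:
    regions = []
    in_run = False
    start = 0
    for i, m in enumerate(mask):
        if m and not in_run:
            in_run, start = True, i
        elif not m and in_run:
            regions.append((float(wavenumbers[start]), float(wavenumbers[i - 1])))
            in_run = False
    if in_run:
        regions.append((float(wavenumbers[start]), float(wavenumbers[-1])))
    return regions


def select_channels(spectra: np.ndarray, selection: BandSelection) -> np.ndarray:
    """Restrict a (n, m) spectra matrix to the selected channels."""
    return np.atleast_2d(np.asarray(spectra, dtype=float))[:, selection.mask]


# ---------------------------------------------------------------------------
# batch chain


def preprocess_batch(
    records: list[SpectrumRecord],
    calibration: CalibrationModel | None = None,
    config: PreprocessConfig | None = None,
    stages=None,
):
    """Run the full preprocessing chain on a batch of spectra.

    The stage order is fixed (``PREPROCESS_STAGES``); passing any other
    ``stages`` sequence is refused.  All records must share one wavenumber
    grid.  Returns ``(processed_records, BandSelection)`` with metadata
    intact; the Welch selection is computed on the whole batch.
    """
    config = config or PreprocessConfig()
    if stages is not None and tuple(stages) != PREPROCESS_STAGES:
        raise ValueError("the preprocessing stage order is fixed and cannot be changed")
    if not records:
        raise ValueError("empty batch")
    x = records[0].wavenumbers
    for r in records:
        if not np.array_equal(r.wavenumbers, x):
            raise ValueError("all records must share one channel grid")

    Y = np.stack([r.intensities for r in records])

    # 1. cosmic spike removal (per record)
    Y = np.stack(
        [
            remove_cosmic_spikes(row, config.spike_threshold, config.spike_max_width)
            for row in Y
        ]
    )

    # 2. wavenumber calibration + 3. intensity-response correction
    if calibration is not None:
        x = calibration.map_channels(np.arange(x.size))
        if not np.all(np.diff(x) > 0):
            raise ValueError("calibrated axis is non-monotone")
        if calibration.response_correction is not None:
            Y = np.stack(
                [correct_intensity_response(row, calibration.response_correction) for row in Y]
            )

    # 4. batch SVD denoising
    if Y.shape[0] >= 2:
        Y = svd_denoise(Y, config.svd_rank)

    # 5. ALS baseline removal
    Y = np.stack(
        [
            als_baseline(row, config.als_lambda, config.als_p, config.als_iterations)[1]
            for row in Y
        ]
    )

    # 6. EMSC against the batch mean, with optional known interferents
    reference = Y.mean(axis=0)
    Y = np.stack(
        [
            emsc_correct(row, reference, config.emsc_interferents, config.emsc_poly_order)[0]
            for row in Y
        ]
    )

    # 7. area normalization
    Y = np.stack([area_normalize(row, x) for row in Y])

    # 8. Welch band selection over the whole batch
    labels = np.array([r.label for r in records])
    selection = welch_band_select(
        Y[labels == HEALTHY], Y[labels == TUMOR], x, config.welch_alpha
    )

    processed = [
        replace(r, wavenumbers=x.copy(), intensities=Y[i]) for i, r in enumerate(records)
    ]
    return processed, selection


class RamanPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer wrapper around the batch preprocessing chain.

    Operates transductively on a whole batch (the published analysis
    preprocesses the entire dataset as a single batch before splitting);
    ``fit_transform`` runs the chain on a list of :class:`SpectrumRecord` and
    stores the resulting :class:`BandSelection` as ``band_selection_``.
    """

    def __init__(self, calibration=None, config: PreprocessConfig | None = None):
        self.calibration = calibration
        self.config = config

    def fit(self, records, y=None):
        self.fit_transform(records, y)
        return self

    def fit_transform(self, records, y=None):
        processed, selection = preprocess_batch(
            records, self.calibration, self.config or PreprocessConfig()
        )
        self.band_selection_ = selection
        self.processed_records_ = processed
        return processed

    def transform(self, records):
        warnings.warn(
            "RamanPreprocessor is transductive; transform() re-runs the batch chain",
            stacklevel=2,
        )
        processed, _ = preprocess_batch(
            records, self.calibration, self.config or PreprocessConfig()
        )
        return processed
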