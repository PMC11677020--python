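"""Synthetic cohort generator (subjects -> samples -> Raman/OCT records).

The generator emulates the statistical structure the downstream analysis
assumes rather than the physics of either instrument:

* Raman records are pseudo-Voigt peak mixtures at the twelve assigned colon
  bands, sitting on a smooth autofluorescence baseline, multiplied by a smooth
  instrument-response curve, with heteroscedastic (shot-like) noise and
  occasional 1-3 channel cosmic spikes.  Tumor-like and healthy-like tissue
  differ only through fixed per-band amplitude shifts scaled by
  ``rs_effect_size`` (in units of the channel-noise sd).
* OCT enface records are isotropic speckle for healthy-like tissue; tumor-like
  tissue adds an oriented band-limited fibrous (desmoplastic) component at a
  random dominant orientation, with amplitude scaled by ``oct_effect_size``.
* Tumor biopsies are heterogeneous: each tumor sample draws a tumor-area
  purity from ``tumor_purity_range`` and each of its records is tumor-like
  with that probability, so tumor-labelled cohorts contain healthy-like
  records, exactly the within-class variability that limits record-level
  classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .datatypes import (
    HEALTHY,
    TUMOR,
    CohortSpec,
    EnfaceImage,
    GroundTruth,
    SpectrumRecord,
)

# Band positions (cm^-1) with their colon-tissue assignments: proline /
# hydroxyproline / tyrosine (853), C-C proline (935), lipid C-C gauche (1078),
# Amide III (1265), CH2 twist (1302), CH2/CH3 deformation (1451), Amide I
# (1661), lipid CH2 sym. (2860), CH2 asym. (2890), CH3 sym. (2935),
# unsaturated =CH (3010), water OH / NH stretch (3210).
DEFAULT_PEAK_POSITIONS = (
    853.0, 935.0, 1078.0, 1265.0, 1302.0, 1451.0,
    1661.0, 2860.0, 2890.0, 2935.0, 3010.0, 3210.0,
)


@dataclass
class RamanGenParams:
    """Parameters of the Raman spectrum generator."""

    n_channels: int = 1024
    wn_min: float = 600.0
    wn_max: float = 3300.0
    peak_positions: tuple[float, ...] = DEFAULT_PEAK_POSITIONS
    healthy_amplitudes: tuple[float, ...] = (
        0.60, 0.50, 0.45, 0.55, 0.60, 0.70, 0.90, 0.80, 0.85, 1.00, 0.30, 0.40,
    )
    # Signed per-band class-shift weights (protein bands up, lipid bands down
    # in tumor; the broad water band is class-independent).
    tumor_shift_weights: tuple[float, ...] = (
        1.0, 0.8, -0.9, 0.7, -0.8, 0.6, 1.0, -1.0, -0.7, 1.2, -0.6, 0.0,
    )
    fwhm: tuple[float, ...] = (
        18.0, 16.0, 20.0, 24.0, 18.0, 22.0, 28.0, 25.0, 25.0, 30.0, 20.0, 30.0,
    )
    lorentz_fraction: float = 0.3
    # autofluorescence baseline: quadratic + broad Gaussian, jittered per record
    baseline_poly: tuple[float, float, float] = (2.0, -1.0, 0.5)
    baseline_gauss_amp: float = 1.5
    baseline_gauss_center: float = 1300.0
    baseline_gauss_sigma: float = 600.0
    baseline_jitter: float = 0.10
    noise_scale: float = 0.03
    spike_prob: float = 0.1
    spike_amp_range: tuple[float, float] = (20.0, 60.0)
    subject_sd: float = 0.08   # log-normal subject effect on peak amplitudes
    record_sd: float = 0.05    # log-normal record-to-record amplitude jitter

    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.wn_min, self.wn_max, self.n_channels)

    def response_curve(self) -> np.ndarray:
        """Smooth, strictly positive instrument intensity-response curve."""
        t = np.linspace(0.0, 1.0, self.n_channels)
        return 0.6 + 0.8 * np.exp(-((t - 0.4) ** 2) / (2 * 0.3**2))

    def interferent_spectra(self) -> list[np.ndarray]:
        """Known background constituents (holder material, room light)."""
        x = self.wavenumbers()
        holder = np.exp(-((x - 1100.0) ** 2) / (2 * 150.0**2))  # broad holder band
        room = 0.5 + 0.5 * np.cos(2 * np.pi * (x - x[0]) / (x[-1] - x[0]))
        return [holder, room]


@dataclass
class OCTGenParams:
    """Parameters of the OCT enface image generator."""

    side: int = 500
    pixel_size_um: float = 4.0
    speckle_corr_px: float = 2.0
    fiber_freq: float = 0.08        # cycles/pixel, centre of the fibrous band
    fiber_radial_bw: float = 0.03   # radial Gaussian width (cycles/pixel)
    fiber_angular_bw_deg: float = 12.0
    fiber_gain: float = 0.25        # fibrous amplitude per unit effect size
    subject_sd: float = 0.10        # log-normal subject effect on fiber gain

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("image side must be positive")

    @property
    def field_of_view_mm(self) -> float:
        return self.side * self.pixel_size_um / 1000.0


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, eta: float) -> np.ndarray:
    """Unit-height pseudo-Voigt line: eta * Lorentzian + (1 - eta) * Gaussian."""
    hwhm = fwhm / 2.0
    lor = hwhm**2 / ((x - center) ** 2 + hwhm**2)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gau = np.exp(-((x - center) ** 2) / (2.0 * sigma**2))
    return eta * lor + (1.0 - eta) * gau


def class_mean_signal(
    latent_class: str, params: RamanGenParams, effect_size: float
) -> np.ndarray:
    """Noiseless, baseline-free peak mixture for one latent class."""
    x = params.wavenumbers()
    amps = np.asarray(params.healthy_amplitudes, dtype=float).copy()
    if latent_class == TUMOR:
        shifts = np.asarray(params.tumor_shift_weights) * effect_size * params.noise_scale
        amps = amps + shifts
    y = np.zeros_like(x)
    for amp, pos, fw in zip(amps, params.peak_positions, params.fwhm):
        y += amp * pseudo_voigt(x, pos, fw, params.lorentz_fraction)
    return y


def generate_raman_spectrum(
    latent_class: str,
    params: RamanGenParams,
    rng: np.random.Generator,
    effect_size: float = 2.0,
    amp_scale: float = 1.0,
    noiseless: bool = False,
):
    """Draw one Raman record.

    Returns ``(wavenumbers, intensities, spike_channels)``.  ``amp_scale`` is
    a multiplicative subject/record random effect applied to all peak
    amplitudes.  With ``noiseless=True`` the baseline, response modulation,
    noise and spikes are all suppressed (pure peak mixture), which the tests
    use as a closed-form oracle.
    """
    x = params.wavenumbers()
    if not np.all(np.diff(x) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    signal = class_mean_signal(latent_class, params, effect_size) * amp_scale
    if noiseless:
        return x, signal, []

    record_jitter = float(np.exp(rng.normal(0.0, params.record_sd)))
    signal = signal * record_jitter

    t = (x - params.wn_min) / (params.wn_max - params.wn_min)
    c0, c1, c2 = params.baseline_poly
    jit = 1.0 + params.baseline_jitter * rng.normal(size=4)
    baseline = (
        c0 * jit[0]
        + c1 * jit[1] * t
        + c2 * jit[2] * t**2
        + params.baseline_gauss_amp
        * jit[3]
        * np.exp(
            -((x - params.baseline_gauss_center) ** 2)
            / (2 * params.baseline_gauss_sigma**2)
        )
    )
    response = params.response_curve()
    clean = (signal + baseline) * response
    sigma = params.noise_scale * np.sqrt(np.clip(clean, 0.0, None) + 0.5)
    y = clean + rng.normal(size=x.size) * sigma

    spike_channels: list[int] = []
    if rng.random() < params.spike_prob:
        width = int(rng.integers(1, 4))
        start = int(rng.integers(1, params.n_channels - width - 1))
        lo, hi = params.spike_amp_range
        amp = rng.uniform(lo, hi) * float(np.median(sigma))
        for k in range(width):
            y[start + k] += amp * rng.uniform(0.7, 1.0)
            spike_channels.append(start + k)
    return x, y, spike_channels


def generate_enface_image(
    latent_class: str,
    params: OCTGenParams,
    rng: np.random.Generator,
    effect_size: float = 2.0,
    gain_scale: float = 1.0,
    orientation_deg: float | None = None,
):
    """Draw one OCT enface image; returns ``(pixels, orientation_deg)``.

    Healthy-like tissue is isotropic speckle (squared magnitude of a smoothed
    complex Gaussian field).  Tumor-like tissue adds a band-limited oriented
    component: white noise filtered in the Fourier domain by a Gaussian
    annular-sector mask centred at ``fiber_freq`` cycles/pixel and at the
    requested wave-vector angle, so the dominant spectral energy of the image
    lies along ``orientation_deg``.  The image is min-max scaled to [0, 1].
    """
    if params.side <= 0:
        raise ValueError("image side must be positive")
    n = params.side
    # orientation is drawn for every record (regardless of class) so that the
    # effect_size == 0 null keeps the two classes on identical random streams
    if orientation_deg is None:
        orientation_deg = float(rng.uniform(0.0, 180.0))

    re = rng.normal(size=(n, n))
    im = rng.normal(size=(n, n))
    fld = gaussian_filter(re, params.speckle_corr_px) + 1j * gaussian_filter(
        im, params.speckle_corr_px
    )
    speckle = np.abs(fld) ** 2
    speckle /= speckle.mean()
    img = speckle

    if latent_class == TUMOR and effect_size > 0:
        noise = rng.normal(size=(n, n))
        fy = np.fft.fftfreq(n)[:, None]
        fx = np.fft.fftfreq(n)[None, :]
        r = np.hypot(fx, fy)
        theta = np.arctan2(fy, fx)
        t0 = np.deg2rad(orientation_deg)
        dtheta = np.angle(np.exp(1j * (theta - t0)))
        # pi-periodic: the mask must cover both +k and -k
        dtheta = np.minimum(np.abs(dtheta), np.pi - np.abs(dtheta))
        sig_t = np.deg2rad(params.fiber_angular_bw_deg)
        mask = np.exp(-((r - params.fiber_freq) ** 2) / (2 * params.fiber_radial_bw**2))
        mask *= np.exp(-(dtheta**2) / (2 * sig_t**2))
        fib = np.real(np.fft.ifft2(np.fft.fft2(noise) * mask))
        fib /= fib.std() + 1e-12
        img = img + effect_size * params.fiber_gain * gain_scale * speckle.std() * fib

    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        pixels = np.zeros_like(img)
    else:
        pixels = (img - lo) / (hi - lo)
    return pixels, orientation_deg


def _shifted_poisson(rng: np.random.Generator, mean: float) -> int:
    """Per-sample record count: 1 + Poisson(mean - 1), minimum 1."""
    lam = max(mean - 1.0, 0.0)
    return 1 + int(rng.poisson(lam))


def generate_cohort(
    spec: CohortSpec,
    raman_params: RamanGenParams | None = None,
    oct_params: OCTGenParams | None = None,
):
    """Generate a full hierarchical cohort.

    Returns ``(spectra, images, truth)`` where ``spectra`` is a list of
    :class:`SpectrumRecord`, ``images`` a list of :class:`EnfaceImage`, and
    ``truth`` a :class:`GroundTruth` with the latent per-record classes,
    per-sample purities and generator parameters.  Deterministic for a fixed
    ``spec.seed``.
    """
    raman_params = raman_params or RamanGenParams()
    oct_params = oct_params or OCTGenParams()
    rng = np.random.default_rng(spec.seed)

    subjects = [f"SU{i:03d}" for i in range(spec.n_subjects)]
    n_samples = spec.n_samples
    # every subject receives at least one sample; the rest go to random subjects
    owner = list(range(spec.n_subjects))
    owner += list(rng.integers(0, spec.n_subjects, size=n_samples - spec.n_subjects))
    rng.shuffle(owner)
    labels = [HEALTHY] * spec.n_healthy_samples + [TUMOR] * spec.n_tumor_samples
    rng.shuffle(labels)

    subj_amp = {s: float(np.exp(rng.normal(0.0, raman_params.subject_sd))) for s in subjects}
    subj_oct = {s: float(np.exp(rng.normal(0.0, oct_params.subject_sd))) for s in subjects}

    truth = GroundTruth(raman_params=raman_params, oct_params=oct_params)
    spectra: list[SpectrumRecord] = []
    images: list[EnfaceImage] = []
    lo, hi = spec.tumor_purity_range

    for si in range(n_samples):
        sample_id = f"SA{si:03d}"
        subject_id = subjects[owner[si]]
        label = labels[si]
        if label == TUMOR:
            purity = float(rng.uniform(max(lo, 1e-6), hi))
        else:
            purity = 0.0
        truth.sample_purity[sample_id] = purity

        n_rs = _shifted_poisson(rng, spec.mean_rs_records_per_sample)
        n_oct = _shifted_poisson(rng, spec.mean_oct_records_per_sample)

        for k in range(n_rs):
            record_id = f"{sample_id}-R{k:02d}"
            latent = TUMOR if (label == TUMOR and rng.random() < purity) else HEALTHY
            x, y, spikes = generate_raman_spectrum(
                latent,
                raman_params,
                rng,
                effect_size=spec.rs_effect_size,
                amp_scale=subj_amp[subject_id],
            )
            truth.record_latent[record_id] = latent
            if spikes:
                truth.spike_channels[record_id] = spikes
            spectra.append(
                SpectrumRecord(x, y, subject_id, sample_id, record_id, label)
            )

        for k in range(n_oct):
            record_id = f"{sample_id}-O{k:02d}"
            latent = TUMOR if (label == TUMOR and rng.random() < purity) else HEALTHY
            pix, orient = generate_enface_image(
                latent,
                oct_params,
                rng,
                effect_size=spec.oct_effect_size,
                gain_scale=subj_oct[subject_id],
            )
            truth.record_latent[record_id] = latent
            truth.fiber_orientation_deg[record_id] = orient
            images.append(
                EnfaceImage(
                    pix,
                    subject_id,
                    sample_id,
                    record_id,
                    label,
                    pixel_size_um=oct_params.pixel_size_um,
                    field_of_view_mm=oct_params.field_of_view_mm,
                )
            )

    return spectra, images, truth
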