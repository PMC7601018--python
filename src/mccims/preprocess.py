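"""Normalization, baseline correction, noise handling and denoising.

Every operator returns a new :class:`~mccims.io_formats.Measurement` with
the same axes, non-negative intensities, and the step appended to the
provenance list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from mccims._wavelet import wavedec_rows, waverec_rows
from mccims.errors import ValidationError
from mccims.io_formats import Measurement, ProvenanceStep

logger = logging.getLogger(__name__)

DEFAULT_NOISE_REGION_MAX_IRM = 0.4

__all__ = [
    "NoiseEstimate",
    "locate_rip",
    "normalize_intensities",
    "baseline_correct_rip",
    "estimate_noise",
    "subtract_noise",
    "denoise_wavelet",
    "filter_gaussian",
    "filter_median",
    "filter_savgol",
    "default_chain",
    "apply_chain",
]


@dataclass(frozen=True)
class NoiseEstimate:
    """Mean intensity of the metabolite-free low-IRM region."""

    level: float
    region_max_irm: float = DEFAULT_NOISE_REGION_MAX_IRM

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValidationError("noise level must be non-negative")


def locate_rip(m: Measurement, rip_irm: float | None = None) -> int:
    """IRM column index of the reactant ion peak.

    The RIP dominates every spectrum, so by default it is taken as the IRM
    column with the largest total intensity.  ``rip_irm`` overrides with an
    explicit coordinate (nearest column).
    """
    if m.irm_axis.size == 0:
        raise ValidationError("empty measurement")
    if rip_irm is not None:
        return int(np.argmin(np.abs(m.irm_axis - rip_irm)))
    col_sums = m.intensity.sum(axis=0)
    best = int(np.argmax(col_sums))
    if np.sum(col_sums == col_sums[best]) > 1:
        logger.warning(
            "%s: RIP column sum tie; using smallest index %d", m.sample_id, best
        )
    return best


def normalize_intensities(m: Measurement, rip_irm: float | None = None) -> Measurement:
    """Scale intensities to [0, 1] using the maximum intensity in the RIP."""
    rip_col = locate_rip(m, rip_irm)
    rip_max = float(m.intensity[:, rip_col].max())
    if rip_max <= 0:
        raise ValidationError("no RIP detectable: RIP column has no positive intensity")
    out = m.intensity / rip_max
    step = ProvenanceStep("normalize", {"rip_col": str(rip_col), "rip_max": repr(rip_max)})
    return m.with_intensity(out, step)


def baseline_correct_rip(m: Measurement, quantile: float = 0.25) -> Measurement:
    """Subtract each spectrum's 25% quantile intensity, clamped at zero.

    A spectrum is one RT row; the quantile uses linear interpolation.
    Counters the RIP tailing that raises the baseline of affected spectra.
    """
    q = np.quantile(m.intensity, quantile, axis=1, method="linear")
    out = np.clip(m.intensity - q[:, None], 0.0, None)
    step = ProvenanceStep("baseline_correct_rip", {"quantile": repr(quantile)})
    return m.with_intensity(out, step)


def estimate_noise(m: Measurement, region_max_irm: float = DEFAULT_NOISE_REGION_MAX_IRM) -> NoiseEstimate:
    """Average intensity over IRM columns below ``region_max_irm``.

    That region carries no metabolite peaks and is unaffected by the RIP.
    """
    mask = m.irm_axis < region_max_irm
    if not mask.any():
        raise ValidationError(
            f"no IRM columns below {region_max_irm}; set region_max_irm explicitly"
        )
    return NoiseEstimate(level=float(m.intensity[:, mask].mean()), region_max_irm=region_max_irm)


def subtract_noise(m: Measurement, noise: NoiseEstimate) -> Measurement:
    """Subtract the fixed noise level everywhere, clamped at zero."""
    out = np.clip(m.intensity - noise.level, 0.0, None)
    step = ProvenanceStep("subtract_noise", {"level": repr(noise.level)})
    return m.with_intensity(out, step)


def denoise_wavelet(m: Measurement, drop_levels: int = 2, wavelet_moments: int = 8) -> Measurement:
    """Per-spectrum Daubechies-8 wavelet denoising.

    Each RT row is decomposed, the finest ``drop_levels`` detail bands are
    zeroed, and the row reconstructed (clamped at zero).  ``drop_levels=0``
    is a perfect-reconstruction no-op up to machine precision.
    """
    if drop_levels < 0:
        raise ValidationError("drop_levels must be >= 0")
    approx, details, orig_len = wavedec_rows(m.intensity, n_moments=wavelet_moments)
    if drop_levels > len(details):
        raise ValidationError(
            f"drop_levels={drop_levels} exceeds decomposition depth {len(details)}"
        )
    for i in range(drop_levels):
        details[-(i + 1)] = np.zeros_like(details[-(i + 1)])
    out = waverec_rows(approx, details, orig_len, n_moments=wavelet_moments)
    out = np.clip(out, 0.0, None)
    step = ProvenanceStep(
        "denoise_wavelet",
        {"wavelet": f"db{wavelet_moments}", "drop_levels": str(drop_levels)},
    )
    return m.with_intensity(out, step)


def _check_odd(name: str, value: int) -> None:
    if value % 2 == 0:
        raise ValidationError(f"{name} must be odd, got {value}")


def filter_gaussian(m: Measurement, sigma_points: float = 1.0) -> Measurement:
    """2D Gaussian smoothing (sigma in grid points, nearest-edge extension)."""
    if sigma_points <= 0:
        raise ValidationError("sigma_points must be positive")
    out = ndimage.gaussian_filter(m.intensity, sigma=sigma_points, mode="nearest")
    out = np.clip(out, 0.0, None)
    step = ProvenanceStep("filter_gaussian", {"sigma": repr(sigma_points)})
    return m.with_intensity(out, step)


def filter_median(m: Measurement, size_points: int = 3) -> Measurement:
    """2D median filter (square window, nearest-edge extension)."""
    _check_odd("median size", size_points)
    if size_points > min(m.shape):
        raise ValidationError("median window larger than the measurement")
    out = ndimage.median_filter(m.intensity, size=size_points, mode="nearest")
    step = ProvenanceStep("filter_median", {"size": str(size_points)})
    return m.with_intensity(out, step)


def filter_savgol(m: Measurement, window_points: int = 9, polyorder: int = 2) -> Measurement:
    """Savitzky-Golay smoothing of each RT row (weighted local polynomial)."""
    _check_odd("savgol window", window_points)
    if window_points < polyorder + 2:
        raise ValidationError("savgol window must be >= polyorder + 2")
    if window_points > m.irm_axis.size:
        raise ValidationError("savgol window larger than the IRM axis")
    out = signal.savgol_filter(m.intensity, window_points, polyorder, axis=1, mode="nearest")
    out = np.clip(out, 0.0, None)
    step = ProvenanceStep(
        "filter_savgol", {"window": str(window_points), "polyorder": str(polyorder)}
    )
    return m.with_intensity(out, step)


def default_chain(
    m: Measurement,
    rip_irm: float | None = None,
    noise_region_max_irm: float = DEFAULT_NOISE_REGION_MAX_IRM,
    gaussian_sigma: float = 1.0,
) -> tuple[Measurement, NoiseEstimate]:
    """Automatic-mode preprocessing chain.

    normalize -> baseline-correct -> estimate noise -> subtract noise ->
    Gaussian smoothing.  Returns the processed measurement and the noise
    estimate (taken before subtraction) used by detection thresholds.
    """
    m1 = normalize_intensities(m, rip_irm=rip_irm)
    m2 = baseline_correct_rip(m1)
    noise = estimate_noise(m2, region_max_irm=noise_region_max_irm)
    m3 = subtract_noise(m2, noise)
    m4 = filter_gaussian(m3, sigma_points=gaussian_sigma)
    return m4, noise


def apply_chain(m: Measurement, params: dict | None) -> tuple[Measurement, NoiseEstimate]:
    """Replay a preprocessing configuration (used at prediction time).

    ``params["chain"]`` is either ``"default"`` (or absent) for
    :func:`default_chain`, or an explicit list of step dicts like
    ``{"step": "filter_median", "size_points": 3}``.  The returned noise
    estimate is the one taken just before noise subtraction (or at the end
    when the chain never subtracts noise) and feeds detection thresholds.
    """
    params = dict(params or {})
    chain = params.get("chain", "default")
    region = float(params.get("noise_region_max_irm", DEFAULT_NOISE_REGION_MAX_IRM))
    if chain == "default" or chain is None:
        return default_chain(
            m,
            rip_irm=params.get("rip_irm"),
            noise_region_max_irm=region,
            gaussian_sigma=float(params.get("gaussian_sigma", 1.0)),
        )
    noise: NoiseEstimate | None = None
    cur = m
    for spec in chain:
        spec = dict(spec)
        name = spec.pop("step")
        if name == "normalize":
            cur = normalize_intensities(cur, rip_irm=spec.get("rip_irm"))
        elif name == "baseline_correct_rip":
            cur = baseline_correct_rip(cur, quantile=float(spec.get("quantile", 0.25)))
        elif name == "subtract_noise":
            noise = estimate_noise(cur, region_max_irm=region)
            cur = subtract_noise(cur, noise)
        elif name == "denoise_wavelet":
            cur = denoise_wavelet(cur, drop_levels=int(spec.get("drop_levels", 2)))
        elif name == "filter_gaussian":
            cur = filter_gaussian(cur, sigma_points=float(spec.get("sigma_points", 1.0)))
        elif name == "filter_median":
            cur = filter_median(cur, size_points=int(spec.get("size_points", 3)))
        elif name == "filter_savgol":
            cur = filter_savgol(
                cur,
                window_points=int(spec.get("window_points", 9)),
                polyorder=int(spec.get("polyorder", 2)),
            )
        else:
            raise ValidationError(f"unknown preprocessing step {name!r}")
    if noise is None:
        noise = estimate_noise(cur, region_max_irm=region)
    return cur, noise
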