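"""2D peak detection on preprocessed measurements.

Four built-in methods (tophat filtering, the JIBB rising-signal heuristic,
a falling-water-level watershed, and rectangle extraction from layer
annotations) plus an optional subprocess hook for the external PEAX binary.
All methods are deterministic: identical input yields an identical peak
list ordered by (rt, irm).
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from mccims.errors import FormatError, PeaxUnavailableError, ValidationError
from mccims.io_formats import LayerAnnotation, Measurement
from mccims.preprocess import NoiseEstimate

logger = logging.getLogger(__name__)

METHODS = ("TOPHAT", "JIBB", "WATERSHED", "LAYER", "PEAX", "IMPORTED")

# 4-connectivity for connected components
_STRUCT4 = ndimage.generate_binary_structure(2, 1)

__all__ = [
    "Peak",
    "detect_tophat",
    "detect_jibb",
    "detect_watershed",
    "detect_layer",
    "run_peax",
    "parse_peax_output",
    "METHODS",
]


@dataclass(frozen=True)
class Peak:
    """A detected local maximum in one measurement."""

    sample_id: str
    rt: float
    irm: float
    intensity: float
    method: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValidationError(f"peak intensity must be positive, got {self.intensity}")
        if self.method not in METHODS:
            raise ValidationError(f"unknown detection method {self.method!r}")


def _peaks_from_label_maxima(
    m: Measurement, values: np.ndarray, labels: np.ndarray, n_regions: int, method: str
) -> list[Peak]:
    """One peak per labeled region, at the region's maximum of ``values``.

    Ties within a region break to the smallest (rt, irm) grid point.
    """
    peaks = []
    for region in range(1, n_regions + 1):
        mask = labels == region
        vmax = values[mask].max()
        cand = np.argwhere(mask & (values == vmax))
        i, j = min(map(tuple, cand))
        if m.intensity[i, j] <= 0:
            continue
        peaks.append(
            Peak(
                sample_id=m.sample_id,
                rt=float(m.rt_axis[i]),
                irm=float(m.irm_axis[j]),
                intensity=float(m.intensity[i, j]),
                method=method,
            )
        )
    peaks.sort(key=lambda p: (p.rt, p.irm))
    return peaks


def detect_tophat(
    m: Measurement,
    noise_threshold: float,
    window: tuple[int, int] = (5, 5),
) -> list[Peak]:
    """Tophat filtering followed by local-maximum extraction.

    Intensities below ``noise_threshold`` are zeroed; a morphological
    white-tophat with a rectangular ``window`` highlights high-intensity
    areas; overlapping above-zero windows merge into connected regions and
    each region contributes one peak at its maximum.
    """
    if noise_threshold < 0:
        raise ValidationError("noise_threshold must be >= 0")
    if any(w % 2 == 0 for w in window):
        raise ValidationError("tophat window dimensions must be odd")
    if window[0] > m.shape[0] or window[1] > m.shape[1]:
        raise ValidationError(f"window {window} larger than measurement {m.shape}")
    thresholded = np.where(m.intensity >= noise_threshold, m.intensity, 0.0)
    tophat = ndimage.white_tophat(thresholded, size=window)
    highlight = (tophat > 0) & (thresholded > 0)
    # each above-zero point spans one window; overlapping windows merge
    highlight = ndimage.binary_dilation(highlight, structure=np.ones(window, dtype=bool))
    highlight &= thresholded > 0
    labels, n_regions = ndimage.label(highlight, structure=_STRUCT4)
    return _peaks_from_label_maxima(m, thresholded, labels, n_regions, "TOPHAT")


def _rising_toward(x: np.ndarray, steps: int, axis: int) -> np.ndarray:
    """Cells whose ``steps`` predecessors along +axis rise toward them.

    The run must be non-decreasing and consist of positive signal: zero
    background does not count as consecutive rising signals, so an isolated
    width-1 spike never qualifies.
    """
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, -1)
    # d[i]: step (i -> i+1) non-decreasing and starting from actual signal
    d = (np.diff(x, axis=axis) >= 0) & (x[tuple(sl)] > 0)
    ok = np.zeros(x.shape, dtype=bool)
    n = x.shape[axis]
    if n <= steps:
        return ok
    # acc[i] = all of d[i .. i+steps-1]; then ok[i+steps] = acc[i]
    acc = np.ones_like(d, dtype=bool)
    for s in range(steps):
        sl_src = [slice(None)] * x.ndim
        sl_src[axis] = slice(s, d.shape[axis])
        sl_dst = [slice(None)] * x.ndim
        sl_dst[axis] = slice(0, d.shape[axis] - s)
        if s == 0:
            acc = d.copy()
        else:
            acc[tuple(sl_dst)] &= d[tuple(sl_src)]
    sl_ok = [slice(None)] * x.ndim
    sl_ok[axis] = slice(steps, n)
    sl_acc = [slice(None)] * x.ndim
    sl_acc[axis] = slice(0, n - steps)
    ok[tuple(sl_ok)] = acc[tuple(sl_acc)]
    return ok


def detect_jibb(
    m: Measurement,
    noise: NoiseEstimate,
    rise_steps: int = 5,
    factor: float = 1.5,
    min_threshold: float | None = None,
) -> list[Peak]:
    """Rising-signal peak detection.

    A grid point is a candidate iff its intensity is at least
    ``factor * noise.level`` and, in both the RT and the IRM direction,
    the ``rise_steps`` neighbors on each side are non-decreasing toward it
    (equivalently non-increasing moving away).  Adjacent candidates merge
    into one region; each region yields one peak at its maximum with ties
    broken to the smallest (rt, irm).
    """
    if rise_steps < 1:
        raise ValidationError("rise_steps must be >= 1")
    threshold = factor * noise.level
    if threshold <= 0:
        if min_threshold is None:
            raise ValidationError(
                "noise level is zero: supply an explicit min_threshold for JIBB"
            )
        threshold = min_threshold
    x = m.intensity
    rising = (
        _rising_toward(x, rise_steps, axis=0)
        & _rising_toward(x[::-1, :], rise_steps, axis=0)[::-1, :]
        & _rising_toward(x, rise_steps, axis=1)
        & _rising_toward(x[:, ::-1], rise_steps, axis=1)[:, ::-1]
    )
    candidates = rising & (x >= threshold)
    labels, n_regions = ndimage.label(candidates, structure=_STRUCT4)
    return _peaks_from_label_maxima(m, x, labels, n_regions, "JIBB")


def detect_watershed(
    m: Measurement,
    noise: NoiseEstimate,
    levels: int = 256,
) -> list[Peak]:
    """Falling-water-level watershed.

    The threshold sweeps linearly from the global maximum down to the noise
    level in ``levels`` steps.  At each step, connected components
    (4-connectivity) of super-threshold points that do not yet contain a
    labeled peak spawn one peak at the component maximum.
    """
    if levels < 2:
        raise ValidationError("levels must be >= 2")
    x = m.intensity
    top = float(x.max())
    if top <= noise.level:
        return []
    thresholds = np.linspace(top, noise.level, levels)
    peak_mask = np.zeros(x.shape, dtype=bool)
    found: list[tuple[int, int]] = []
    for t in thresholds:
        above = x > t if t > noise.level else x > noise.level
        labels, n_regions = ndimage.label(above, structure=_STRUCT4)
        if not n_regions:
            continue
        has_peak = np.zeros(n_regions + 1, dtype=bool)
        np.logical_or.at(has_peak, labels[peak_mask], True)
        for region in range(1, n_regions + 1):
            if has_peak[region]:
                continue
            mask = labels == region
            vmax = x[mask].max()
            cand = np.argwhere(mask & (x == vmax))
            i, j = min(map(tuple, cand))
            found.append((i, j))
            peak_mask[i, j] = True
    peaks = [
        Peak(
            sample_id=m.sample_id,
            rt=float(m.rt_axis[i]),
            irm=float(m.irm_axis[j]),
            intensity=float(x[i, j]),
            method="WATERSHED",
        )
        for i, j in found
        if x[i, j] > 0
    ]
    peaks.sort(key=lambda p: (p.rt, p.irm))
    return peaks


def detect_layer(m: Measurement, layer: LayerAnnotation) -> list[Peak]:
    """Extract one peak per annotation rectangle at the in-rectangle maximum.

    Rectangles with no positive signal yield no peak; rectangles fully
    outside the measurement domain are skipped with a warning.
    """
    peaks = []
    for region in layer:
        rt_lo, rt_hi = region.rt_center - region.rt_radius, region.rt_center + region.rt_radius
        irm_lo, irm_hi = region.irm_center - region.irm_radius, region.irm_center + region.irm_radius
        ri = np.where((m.rt_axis >= rt_lo) & (m.rt_axis <= rt_hi))[0]
        ci = np.where((m.irm_axis >= irm_lo) & (m.irm_axis <= irm_hi))[0]
        if ri.size == 0 or ci.size == 0:
            warnings.warn(f"layer region {region.name!r} outside measurement domain; skipped")
            continue
        sub = m.intensity[np.ix_(ri, ci)]
        vmax = sub.max()
        if vmax <= 0:
            continue
        cand = np.argwhere(sub == vmax)
        i, j = min(map(tuple, cand))
        peaks.append(
            Peak(
                sample_id=m.sample_id,
                rt=float(m.rt_axis[ri[i]]),
                irm=float(m.irm_axis[ci[j]]),
                intensity=float(vmax),
                method="LAYER",
                name=region.name,
            )
        )
    peaks.sort(key=lambda p: (p.rt, p.irm))
    return peaks


# ---------------------------------------------------------------------------
# optional external PEAX hook
# ---------------------------------------------------------------------------

def parse_peax_output(source, sample_id: str) -> list[Peak]:
    """Parse a PEAX result table (tab-separated, header with t/r/signal)."""
    import os

    if isinstance(source, (str, os.PathLike)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].rstrip().split("\t")
    aliases = {"t": "rt", "r": "irm", "signal": "intensity", "rt": "rt",
               "irm": "irm", "intensity": "intensity"}
    col_of: dict[str, int] = {}
    for i, name in enumerate(header):
        key = aliases.get(name.strip().lower())
        if key and key not in col_of:
            col_of[key] = i
    missing = {"rt", "irm", "intensity"} - set(col_of)
    if missing:
        raise FormatError(f"PEAX output missing columns: {sorted(missing)}", line=1)
    peaks = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.rstrip().split("\t")
        try:
            peaks.append(
                Peak(
                    sample_id=sample_id,
                    rt=float(cells[col_of["rt"]]),
                    irm=float(cells[col_of["irm"]]),
                    intensity=float(cells[col_of["intensity"]]),
                    method="PEAX",
                )
            )
        except (IndexError, ValueError) as exc:
            raise FormatError(f"malformed PEAX row: {exc}", line=lineno) from None
    peaks.sort(key=lambda p: (p.rt, p.irm))
    return peaks


def run_peax(m: Measurement, binary_path: str) -> list[Peak]:
    """Run the external PEAX binary on a measurement and parse its output.

    PEAX is academic-use-only and not bundled; a missing binary raises
    :class:`PeaxUnavailableError` so callers can continue with the
    built-in methods.
    """
    if not binary_path or shutil.which(binary_path) is None and not Path(binary_path).is_file():
        raise PeaxUnavailableError(
            f"PEAX binary not found at {binary_path!r}; PEAX is optional and "
            "external — continue with tophat/jibb/watershed/layer"
        )
    from mccims.io_formats import write_measurement

    with tempfile.TemporaryDirectory() as tmp:
        in_path = Path(tmp) / f"{m.sample_id}.csv"
        out_path = Path(tmp) / f"{m.sample_id}_peax.tsv"
        write_measurement(m, in_path)
        try:
            subprocess.run(
                [str(binary_path), str(in_path), str(out_path)],
                check=True, capture_output=True,
            )
        except (OSError, subprocess.CalledProcessError) as exc:
            raise PeaxUnavailableError(f"PEAX execution failed: {exc}") from exc
        return parse_peax_output(out_path, m.sample_id)


def detect_with_method(
    m: Measurement,
    noise: NoiseEstimate,
    detection: dict,
) -> list[Peak]:
    """Dispatch on a serialized detection config (pipeline + prediction).

    ``detection`` looks like ``{"method": "WATERSHED", "params": {...}}``;
    LAYER configs additionally carry their annotation rows under
    ``"layer"``.
    """
    method = detection["method"].upper()
    params = dict(detection.get("params") or {})
    if method == "TOPHAT":
        factor = float(params.get("noise_factor", 5.0))
        floor = float(params.get("min_threshold", 0.01))
        window = tuple(params.get("window", (5, 5)))
        return detect_tophat(m, noise_threshold=max(factor * noise.level, floor), window=window)
    if method == "JIBB":
        return detect_jibb(
            m,
            noise,
            rise_steps=int(params.get("rise_steps", 5)),
            factor=float(params.get("factor", 1.5)),
            min_threshold=float(params.get("min_threshold", 1e-3)),
        )
    if method == "WATERSHED":
        return detect_watershed(m, noise, levels=int(params.get("levels", 256)))
    if method == "LAYER":
        from mccims.io_formats import LayerRegion

        regions = [LayerRegion(**row) for row in detection.get("layer", [])]
        return detect_layer(m, LayerAnnotation(regions))
    if method == "PEAX":
        return run_peax(m, params.get("binary_path", "peax"))
    raise ValidationError(f"unknown detection method {method!r}")
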