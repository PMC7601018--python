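"""Synthetic MCC-IMS measurements with known ground truth.

Each spectrum is a reactant ion peak (an RT-constant Gaussian ridge in IRM
with an exponential tail toward higher IRM), plus class-conditional and
shared 2D Gaussian analyte peaks, plus clamped Gaussian noise.  Ground
truth lists every planted apex, so detection, alignment, scoring and the
end-to-end pipeline can be validated offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from mccims.errors import ValidationError
from mccims.io_formats import LabelTable, Measurement
from mccims.peak_detection import Peak

__all__ = ["PlantedPeak", "SynthSpec", "generate_measurement", "generate_dataset", "preset"]


@dataclass(frozen=True)
class PlantedPeak:
    rt_center: float
    irm_center: float
    rt_sigma: float
    irm_sigma: float
    height: float
    label: str | None = None  # None = shared between classes

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0 or self.irm_sigma <= 0:
            raise ValidationError("planted peak sigmas must be positive")


@dataclass(frozen=True)
class SynthSpec:
    rt_points: int = 120
    irm_points: int = 160
    rt_range: tuple[float, float] = (0.0, 60.0)
    irm_range: tuple[float, float] = (0.0, 1.59)
    rip_irm: float = 0.48
    rip_height: float = 10.0
    rip_sigma: float = 0.015
    tail_decay: float = 8.0  # per IRM unit, exponential
    tail_height: float = 0.5
    peaks: tuple[PlantedPeak, ...] = ()
    noise_sd: float = 0.05
    rt_jitter_sd: float = 0.0
    irm_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.irm_range
        if not (lo <= self.rip_irm <= hi):
            raise ValidationError("RIP position outside the IRM domain")
        for p in self.peaks:
            if not (0.0 <= p.rt_center <= 2000.0 and 0.0 <= p.irm_center <= 1.6):
                raise ValidationError("planted peak outside the grid domain")


def generate_measurement(
    spec: SynthSpec,
    label: str,
    sample_seed: int,
    sample_id: str | None = None,
) -> tuple[Measurement, list[Peak]]:
    """One synthetic measurement plus its ground-truth apex list.

    Peaks whose ``label`` is None or equals ``label`` are planted; position
    jitter (if configured) is drawn from ``sample_seed``, so identical
    (spec, seed) pairs give identical matrices.  Jitter is clipped at
    2.5 standard deviations and the jittered center snapped to the nearest
    axis grid point (the apex of a sampled Gaussian lies on the grid), so
    the ground-truth apex is always an exact matrix coordinate.
    """
    rng = np.random.default_rng(sample_seed)
    sid = sample_id or f"synth_{sample_seed}"
    rt = np.linspace(*spec.rt_range, spec.rt_points)
    irm = np.linspace(*spec.irm_range, spec.irm_points)
    intensity = np.zeros((rt.size, irm.size))

    # RIP ridge: constant along RT, Gaussian in IRM, exponential tailing
    rip = spec.rip_height * np.exp(-0.5 * ((irm - spec.rip_irm) / spec.rip_sigma) ** 2)
    tail = np.where(
        irm > spec.rip_irm,
        spec.tail_height * np.exp(-spec.tail_decay * (irm - spec.rip_irm)),
        0.0,
    )
    intensity += (rip + tail)[None, :]

    truth: list[Peak] = []
    for p in spec.peaks:
        if p.label is not None and p.label != label:
            continue
        rt_c, irm_c = p.rt_center, p.irm_center
        if spec.rt_jitter_sd:
            j = rng.normal(0.0, spec.rt_jitter_sd)
            rt_c += float(np.clip(j, -2.5 * spec.rt_jitter_sd, 2.5 * spec.rt_jitter_sd))
        if spec.irm_jitter_sd:
            j = rng.normal(0.0, spec.irm_jitter_sd)
            irm_c += float(np.clip(j, -2.5 * spec.irm_jitter_sd, 2.5 * spec.irm_jitter_sd))
        rt_c = float(rt[np.argmin(np.abs(rt - rt_c))])
        irm_c = float(irm[np.argmin(np.abs(irm - irm_c))])
        bump = p.height * np.exp(
            -0.5 * (((rt - rt_c)[:, None] / p.rt_sigma) ** 2
                    + ((irm - irm_c)[None, :] / p.irm_sigma) ** 2)
        )
        intensity += bump
        truth.append(
            Peak(sample_id=sid, rt=float(rt_c), irm=float(irm_c),
                 intensity=float(p.height), method="IMPORTED")
        )
    if spec.noise_sd > 0:
        intensity += rng.normal(0.0, spec.noise_sd, intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    m = Measurement(sample_id=sid, rt_axis=rt, irm_axis=irm, intensity=intensity, label=label)
    return m, truth


def generate_dataset(
    spec: SynthSpec,
    n_per_class: Mapping[str, int],
    seed: int,
) -> tuple[list[Measurement], LabelTable, list[Peak]]:
    """Generate a two-class dataset with deterministic per-sample seeds."""
    if len(n_per_class) != 2:
        raise ValidationError("need exactly two classes")
    master = np.random.default_rng(seed)
    sample_seeds = master.integers(0, 2**31 - 1, size=sum(n_per_class.values()))
    measurements: list[Measurement] = []
    entries: dict[str, str] = {}
    truth: list[Peak] = []
    i = 0
    for cls in sorted(n_per_class):
        for j in range(n_per_class[cls]):
            sid = f"{cls}_{j:03d}"
            m, t = generate_measurement(spec, cls, int(sample_seeds[i]), sample_id=sid)
            measurements.append(m)
            truth.extend(t)
            entries[sid] = cls
            i += 1
    return measurements, LabelTable(entries), truth


def preset(name: str, discriminative_height: float = 0.5, noise_sd: float = 0.05) -> tuple[SynthSpec, dict[str, int]]:
    """Named dataset designs for the CLI and tests.

    ``candy`` mirrors a 20/22 two-flavor design, ``copd`` a 93/35
    case-control design, ``minimal`` a fast 15/15 fixture.  Each plants one
    discriminative peak per class (about 10x the noise level after
    normalization) and one shared peak, with small position jitter.
    """
    peaks = {
        "candy": (
            PlantedPeak(28.7, 0.8125, 2.0, 0.03, discriminative_height, "citrus"),
            PlantedPeak(28.7, 1.0125, 2.0, 0.03, discriminative_height, "menthol"),
            PlantedPeak(45.0, 0.9125, 2.0, 0.03, 0.3 * discriminative_height, None),
        ),
        "copd": (
            PlantedPeak(18.5, 0.6125, 2.0, 0.03, discriminative_height, "copd"),
            PlantedPeak(35.0, 0.9625, 2.0, 0.03, discriminative_height, "control"),
            PlantedPeak(50.0, 1.1125, 2.0, 0.03, 0.3 * discriminative_height, None),
        ),
        "minimal": (
            PlantedPeak(28.7, 0.8125, 2.0, 0.03, discriminative_height, "case"),
            PlantedPeak(28.7, 1.0125, 2.0, 0.03, discriminative_height, "control"),
        ),
    }
    counts = {
        "candy": {"citrus": 20, "menthol": 22},
        "copd": {"copd": 93, "control": 35},
        "minimal": {"case": 15, "control": 15},
    }
    if name not in peaks:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(peaks)}")
    spec = SynthSpec(
        peaks=peaks[name],
        noise_sd=noise_sd,
        rt_jitter_sd=0.4,
        irm_jitter_sd=0.003,
    )
    return spec, counts[name]
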