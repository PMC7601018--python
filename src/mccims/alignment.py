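"""Peak alignment: map per-measurement peaks to shared peak ids.

Two routes produce a :class:`FeatureMatrix` from detected peaks:

* probe clustering on a fixed grid whose RT row heights grow geometrically
  (``H(0)=0, H(1)=3, H(q)=(2+srt)*H(q-1)``) while IRM columns have constant
  width ``w`` — deterministic and order-independent;
* DBSCAN on normalized peak positions, with clusters (and noise peaks)
  labeled through the same grid.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from mccims.errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from mccims.peak_detection import Peak

logger = logging.getLogger(__name__)

RT_MAX = 2000.0
IRM_MAX = 1.6

__all__ = [
    "GridSpec",
    "FeatureMatrix",
    "build_grid",
    "assign_cell",
    "decode_peak_id",
    "probe_cluster",
    "dbscan_align",
    "RT_MAX",
    "IRM_MAX",
]


@dataclass(frozen=True)
class GridSpec:
    """The probe-clustering grid.

    ``boundaries`` holds the RT row boundaries ``H(0)..H(Q)``; the last one
    is clipped at ``rt_max``.  ``n_cols = ceil(irm_max / w)`` IRM columns of
    constant width ``w``.  Cell ids run left to right (IRM) then bottom to
    top (RT): ``id = row * n_cols + col``.
    """

    w: float
    srt: float
    boundaries: tuple[float, ...]
    rt_max: float = RT_MAX
    irm_max: float = IRM_MAX

    @property
    def n_cols(self) -> int:
        return math.ceil(self.irm_max / self.w)

    @property
    def n_rows(self) -> int:
        return len(self.boundaries) - 1

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        rt_c = (self.boundaries[row] + self.boundaries[row + 1]) / 2.0
        irm_c = (col + 0.5) * self.w
        return rt_c, irm_c

    def to_dict(self) -> dict:
        return {
            "w": self.w,
            "srt": self.srt,
            "rt_max": self.rt_max,
            "irm_max": self.irm_max,
            "boundaries": list(self.boundaries),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(
            w=float(d["w"]),
            srt=float(d["srt"]),
            boundaries=tuple(float(b) for b in d["boundaries"]),
            rt_max=float(d.get("rt_max", RT_MAX)),
            irm_max=float(d.get("irm_max", IRM_MAX)),
        )


@dataclass
class FeatureMatrix:
    """Samples x aligned-peak-id intensity matrix (0 = peak absent)."""

    sample_ids: list[str]
    peak_ids: list[str]
    values: np.ndarray
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)
    alignment_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.peak_ids)):
            raise ValidationError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.peak_ids)} peaks"
            )
        if self.values.size and self.values.min() < 0:
            raise ValidationError("feature matrix contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, peak_id: str) -> np.ndarray:
        return self.values[:, self.peak_ids.index(peak_id)]

    def select_columns(self, peak_ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.peak_ids.index(p) for p in peak_ids]
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            peak_ids=list(peak_ids),
            values=self.values[:, idx].copy(),
            coords={p: self.coords.get(p, (float("nan"),) * 2) for p in peak_ids},
            alignment_params=dict(self.alignment_params),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureMatrix(
            sample_ids=list(sample_ids),
            peak_ids=list(self.peak_ids),
            values=self.values[idx, :].copy(),
            coords=dict(self.coords),
            alignment_params=dict(self.alignment_params),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.peak_ids)


# ---------------------------------------------------------------------------
# grid construction and cell assignment
# ---------------------------------------------------------------------------

def build_grid(w: float = 0.025, srt: float = 0.0, rt_max: float = RT_MAX,
               irm_max: float = IRM_MAX) -> GridSpec:
    """Build the probe-clustering grid.

    Row boundaries follow the recurrence ``H(0)=0, H(1)=3,
    H(q) = H(q-1) + (1+srt)*H(q-1)``; generation stops at the first value
    >= ``rt_max``, which is clipped to ``rt_max``.
    """
    if w <= 0:
        raise ValidationError("grid width w must be positive")
    if w > irm_max:
        raise ValidationError(f"grid width w={w} exceeds the IRM domain {irm_max}")
    if srt < 0:
        raise ValidationError("srt must be non-negative")
    boundaries = [0.0, 3.0]
    while boundaries[-1] < rt_max:
        nxt = boundaries[-1] + (1.0 + srt) * boundaries[-1]
        boundaries.append(min(nxt, rt_max))
    return GridSpec(w=w, srt=srt, boundaries=tuple(boundaries), rt_max=rt_max, irm_max=irm_max)


def _cell_indices(grid: GridSpec, rt: float, irm: float) -> tuple[int, int]:
    if not (0.0 <= rt <= grid.rt_max):
        raise ValidationError(f"rt={rt} outside grid domain [0, {grid.rt_max}]")
    if not (0.0 <= irm <= grid.irm_max):
        raise ValidationError(f"irm={irm} outside grid domain [0, {grid.irm_max}]")
    bounds = np.asarray(grid.boundaries)
    # rows half-open [H(q), H(q+1)); rt == rt_max clipped into last row
    row = int(np.searchsorted(bounds, rt, side="right")) - 1
    row = min(row, grid.n_rows - 1)
    col = min(int(irm / grid.w), grid.n_cols - 1)
    return row, col


def assign_cell(grid: GridSpec, rt: float, irm: float) -> str:
    """Grid cell id ("Peak_%04d") of a position; total on the domain."""
    row, col = _cell_indices(grid, rt, irm)
    return f"Peak_{row * grid.n_cols + col:04d}"


def decode_peak_id(peak_id: str, grid: GridSpec) -> tuple[int, int]:
    """Inverse of :func:`assign_cell`: id -> (row, col)."""
    if not peak_id.startswith("Peak_"):
        raise ValueError(f"not a grid peak id: {peak_id!r}")
    index = int(peak_id[5:])
    row, col = divmod(index, grid.n_cols)
    if row >= grid.n_rows:
        raise IndexError(f"{peak_id} outside grid with {grid.n_rows} rows")
    return row, col


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _build_feature_matrix(
    assignments: Iterable[tuple["Peak", str]],
    sample_ids: Sequence[str] | None,
    grid: GridSpec,
    params: dict,
) -> FeatureMatrix:
    """Aggregate (peak, cell-id) pairs: per (sample, cell) keep the max."""
    cell_values: dict[tuple[str, str], float] = {}
    seen_samples: set[str] = set()
    seen_ids: set[str] = set()
    for peak, pid in assignments:
        key = (peak.sample_id, pid)
        cell_values[key] = max(cell_values.get(key, 0.0), peak.intensity)
        seen_samples.add(peak.sample_id)
        seen_ids.add(pid)
    samples = sorted(seen_samples) if sample_ids is None else list(sample_ids)
    ids = sorted(seen_ids)
    values = np.zeros((len(samples), len(ids)))
    col_of = {p: j for j, p in enumerate(ids)}
    row_of = {s: i for i, s in enumerate(samples)}
    for (sid, pid), val in cell_values.items():
        if sid not in row_of:
            raise ValidationError(f"peak from unknown sample {sid!r}")
        values[row_of[sid], col_of[pid]] = val
    coords = {p: grid.cell_center(*decode_peak_id(p, grid)) for p in ids}
    return FeatureMatrix(
        sample_ids=samples, peak_ids=ids, values=values, coords=coords,
        alignment_params=params,
    )


def _clip_peak(grid: GridSpec, rt: float, irm: float) -> tuple[float, float]:
    return (min(max(rt, 0.0), grid.rt_max), min(max(irm, 0.0), grid.irm_max))


def probe_cluster(
    peaks: Sequence["Peak"],
    grid: GridSpec | None = None,
    sample_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Align peaks deterministically by grid-cell membership.

    Each peak maps to the cell containing its apex; per (sample, cell) the
    maximum intensity wins.  ``sample_ids`` fixes the row set (samples with
    no peaks get all-zero rows); by default rows are the sorted sample ids
    seen among the peaks.
    """
    grid = grid or build_grid()
    assignments = [
        (p, assign_cell(grid, *_clip_peak(grid, p.rt, p.irm))) for p in peaks
    ]
    params = {"method": "probe_clustering", "grid": grid.to_dict()}
    return _build_feature_matrix(assignments, sample_ids, grid, params)


def dbscan_align(
    peaks: Sequence["Peak"],
    eps: float = 0.01,
    min_samples: int = 2,
    grid: GridSpec | None = None,
    sample_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Align peaks by density clustering of their positions.

    Distances are Euclidean on ``(rt/rt_max, irm/irm_max)`` since the raw
    axes are incommensurate.  Each cluster is labeled by the grid cell of
    its mean position; noise peaks are labeled individually by their own
    position.  Two clusters landing in one cell are merged with a warning.
    """
    if eps <= 0:
        raise ValidationError("eps must be positive")
    if min_samples < 1:
        raise ValidationError("min_samples must be >= 1")
    grid = grid or build_grid()
    params = {
        "method": "dbscan",
        "eps": eps,
        "min_samples": min_samples,
        "grid": grid.to_dict(),
    }
    if not peaks:
        return FeatureMatrix(
            sample_ids=list(sample_ids or []), peak_ids=[],
            values=np.zeros((len(sample_ids or []), 0)),
            coords={}, alignment_params=params,
        )
    from sklearn.cluster import DBSCAN

    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].sample_id, peaks[i].rt, peaks[i].irm))
    pts = np.array([
        [peaks[i].rt / grid.rt_max, peaks[i].irm / grid.irm_max] for i in order
    ])
    cluster_labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts)

    assignments: list[tuple["Peak", str]] = []
    cluster_cells: dict[int, str] = {}
    for lab in sorted(set(cluster_labels)):
        if lab == -1:
            continue
        members = np.where(cluster_labels == lab)[0]
        mean_rt = float(np.mean([peaks[order[i]].rt for i in members]))
        mean_irm = float(np.mean([peaks[order[i]].irm for i in members]))
        cluster_cells[lab] = assign_cell(grid, *_clip_peak(grid, mean_rt, mean_irm))
    if len(set(cluster_cells.values())) < len(cluster_cells):
        warnings.warn("multiple DBSCAN clusters map to the same grid cell; merged")
    for pos, lab in zip(order, cluster_labels):
        p = peaks[pos]
        if lab == -1:
            pid = assign_cell(grid, *_clip_peak(grid, p.rt, p.irm))
        else:
            pid = cluster_cells[lab]
        assignments.append((p, pid))
    return _build_feature_matrix(assignments, sample_ids, grid, params)
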