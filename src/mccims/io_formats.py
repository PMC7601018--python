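"""Reading and writing of every on-disk artifact the pipeline touches.

All formats are plain UTF-8 CSV so that artifacts are diff-able and
round-trippable:

* Measurement matrix: cell (0,0) empty; row 0 holds the IRM axis (Vs/cm2);
  column 0 holds the RT axis (seconds); optional leading ``#step:`` comment
  lines record the provenance of applied preprocessing steps.
* Feature matrix: header ``sample_id,Peak_0000,...``; one row per sample;
  blank cells mean "peak absent" and read as 0.0.
* Labels: ``sample_id,label``.
* Layer annotation: ``name,rt_center,irm_center,rt_radius,irm_radius``.
* Peak list: ``sample_id,rt,irm,intensity,method``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from mccims.alignment import FeatureMatrix, GridSpec, build_grid, decode_peak_id
from mccims.errors import FormatError, ValidationError

__all__ = [
    "Measurement",
    "ProvenanceStep",
    "LabelTable",
    "LayerRegion",
    "LayerAnnotation",
    "read_measurement",
    "write_measurement",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_labels",
    "write_labels",
    "read_layer",
    "write_layer",
    "read_peaks",
    "write_peaks",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProvenanceStep:
    """One applied preprocessing step: its name and its parameters."""

    name: str
    params: dict[str, str] = field(default_factory=dict)

    def format(self) -> str:
        parts = [f"#step:{self.name}"]
        parts.extend(f"{k}={v}" for k, v in self.params.items())
        return " ".join(parts)

    @classmethod
    def parse(cls, line: str) -> "ProvenanceStep":
        body = line[len("#step:"):].strip()
        tokens = body.split()
        params = {}
        for tok in tokens[1:]:
            key, _, val = tok.partition("=")
            params[key] = val
        return cls(name=tokens[0], params=params)


@dataclass
class Measurement:
    """One sample's RT x IRM intensity matrix with axes and metadata.

    ``rt_axis`` is in seconds, ``irm_axis`` in Vs/cm2; both strictly
    increasing.  ``intensity`` has shape ``(len(rt_axis), len(irm_axis))``
    and is finite and non-negative.  ``provenance`` is the append-only list
    of preprocessing steps already applied; empty means raw.
    """

    sample_id: str
    rt_axis: np.ndarray
    irm_axis: np.ndarray
    intensity: np.ndarray
    label: str | None = None
    provenance: list[ProvenanceStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rt_axis = np.asarray(self.rt_axis, dtype=float)
        self.irm_axis = np.asarray(self.irm_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.rt_axis.ndim != 1 or self.irm_axis.ndim != 1:
            raise ValidationError("axes must be 1-D")
        if self.intensity.shape != (self.rt_axis.size, self.irm_axis.size):
            raise ValidationError(
                f"intensity shape {self.intensity.shape} does not match axes "
                f"({self.rt_axis.size}, {self.irm_axis.size})"
            )
        if self.rt_axis.size and np.any(np.diff(self.rt_axis) <= 0):
            raise ValidationError("rt axis not strictly increasing")
        if self.irm_axis.size and np.any(np.diff(self.irm_axis) <= 0):
            raise ValidationError("irm axis not strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensity contains non-finite values")
        if self.intensity.size and self.intensity.min() < 0:
            raise ValidationError("intensity contains negative values")

    def with_intensity(self, intensity: np.ndarray, step: ProvenanceStep) -> "Measurement":
        """New Measurement with replaced intensities and ``step`` appended."""
        return Measurement(
            sample_id=self.sample_id,
            rt_axis=self.rt_axis.copy(),
            irm_axis=self.irm_axis.copy(),
            intensity=np.asarray(intensity, dtype=float),
            label=self.label,
            provenance=[*self.provenance, step],
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class LabelTable:
    """Mapping sample_id -> class label."""

    entries: dict[str, str]

    def classes(self) -> list[str]:
        return sorted(set(self.entries.values()))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.entries.values():
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def require_binary(self) -> tuple[str, str]:
        """Return the (negative, positive) label pair or raise."""
        classes = self.classes()
        if len(classes) != 2:
            raise ValidationError(
                f"classification requires exactly 2 classes, found {len(classes)}: {classes}"
            )
        return classes[0], classes[1]

    def subset(self, sample_ids: Iterable[str]) -> "LabelTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.entries]
        if missing:
            raise ValidationError(f"samples without labels: {missing[:5]}")
        return LabelTable({s: self.entries[s] for s in ids})

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, sample_id: str) -> str:
        return self.entries[sample_id]


@dataclass(frozen=True)
class LayerRegion:
    name: str
    rt_center: float
    irm_center: float
    rt_radius: float
    irm_radius: float

    def __post_init__(self) -> None:
        if self.rt_radius <= 0 or self.irm_radius <= 0:
            raise ValidationError(f"layer region {self.name!r}: radii must be positive")


@dataclass
class LayerAnnotation:
    """Named rectangles in (RT, IRM) from which to read peak intensities."""

    regions: list[LayerRegion]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValidationError("layer region names must be unique")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def _open_read(source) -> tuple[IO[str], bool]:
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def _open_write(dest) -> tuple[IO[str], bool]:
    if isinstance(dest, (str, os.PathLike)):
        return open(dest, "w", encoding="utf-8", newline=""), True
    return dest, False


def _stem(source) -> str | None:
    if isinstance(source, (str, os.PathLike)):
        return Path(source).stem
    return getattr(source, "name", None) and Path(source.name).stem or None


# ---------------------------------------------------------------------------
# measurement matrix
# ---------------------------------------------------------------------------

def read_measurement(source, sample_id: str | None = None) -> Measurement:
    """Parse a measurement-matrix CSV (path or text stream).

    ``sample_id`` defaults to the filename stem when reading from a path.
    """
    fh, close = _open_read(source)
    try:
        provenance: list[ProvenanceStep] = []
        header: list[str] | None = None
        rt_values: list[float] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#step:"):
                    provenance.append(ProvenanceStep.parse(line))
                continue
            cells = line.split(",")
            if header is None:
                if cells[0].strip() != "":
                    raise FormatError("header cell (0,0) must be empty", lineno)
                header = cells[1:]
                continue
            if len(cells) != len(header) + 1:
                raise FormatError(
                    f"ragged row: expected {len(header) + 1} cells, got {len(cells)}",
                    lineno,
                )
            try:
                rt_values.append(float(cells[0]))
                rows.append([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise FormatError(f"non-numeric cell: {exc}", lineno) from None
        if header is None:
            raise FormatError("empty measurement file")
        try:
            irm_axis = np.array([float(c) for c in header], dtype=float)
        except ValueError as exc:
            raise FormatError(f"non-numeric IRM header: {exc}") from None
        sid = sample_id or _stem(source) or "measurement"
        try:
            return Measurement(
                sample_id=sid,
                rt_axis=np.array(rt_values),
                irm_axis=irm_axis,
                intensity=np.array(rows, dtype=float),
                provenance=provenance,
            )
        except ValidationError as exc:
            raise FormatError(str(exc)) from None
    finally:
        if close:
            fh.close()


def write_measurement(m: Measurement, dest) -> None:
    """Write ``m`` in the measurement-matrix dialect; re-readable bit-exact."""
    fh, close = _open_write(dest)
    try:
        for step in m.provenance:
            fh.write(step.format() + "\n")
        fh.write("," + ",".join(_fmt(v) for v in m.irm_axis) + "\n")
        for rt, row in zip(m.rt_axis, m.intensity):
            fh.write(_fmt(rt) + "," + ",".join(_fmt(v) for v in row) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def read_feature_matrix(source, grid: GridSpec | None = None) -> FeatureMatrix:
    """Read a feature-matrix CSV; blank cells become 0.0 (peak absent).

    Column ids of the form ``Peak_%04d`` are assigned cell-center
    coordinates under ``grid`` (default grid when omitted); other ids get
    NaN coordinates.  Samples are ordered by sample_id for determinism.
    """
    df = pd.read_csv(source, dtype={0: str})
    if df.columns[0] != "sample_id":
        raise FormatError("first column must be 'sample_id'")
    peak_cols = list(df.columns[1:])
    if len(set(peak_cols)) != len(peak_cols):
        raise FormatError("duplicate peak-id columns")
    if df["sample_id"].duplicated().any():
        dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise FormatError(f"duplicate sample ids: {dupes}")
    df = df.sort_values("sample_id", kind="stable").reset_index(drop=True)
    values = df[peak_cols].apply(pd.to_numeric, errors="raise").fillna(0.0).to_numpy(float)
    grid = grid or build_grid()
    coords: dict[str, tuple[float, float]] = {}
    for pid in peak_cols:
        try:
            coords[pid] = grid.cell_center(*decode_peak_id(pid, grid))
        except (ValueError, IndexError):
            coords[pid] = (float("nan"), float("nan"))
    return FeatureMatrix(
        sample_ids=df["sample_id"].tolist(),
        peak_ids=peak_cols,
        values=values,
        coords=coords,
        alignment_params={"source": "imported"},
    )


def write_feature_matrix(fm: FeatureMatrix, dest) -> None:
    fh, close = _open_write(dest)
    try:
        fh.write("sample_id," + ",".join(fm.peak_ids) + "\n")
        for sid, row in zip(fm.sample_ids, fm.values):
            fh.write(sid + "," + ",".join(_fmt(v) for v in row) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# labels / layer / peak list
# ---------------------------------------------------------------------------

def read_labels(source) -> LabelTable:
    df = pd.read_csv(source, dtype=str)
    expected = ["sample_id", "label"]
    if list(df.columns[:2]) != expected:
        raise FormatError(f"labels header must be {','.join(expected)}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in labels file")
    df = df.sort_values("sample_id", kind="stable")
    return LabelTable(dict(zip(df["sample_id"], df["label"])))


def write_labels(labels: LabelTable, dest) -> None:
    fh, close = _open_write(dest)
    try:
        fh.write("sample_id,label\n")
        for sid in sorted(labels.entries):
            fh.write(f"{sid},{labels.entries[sid]}\n")
    finally:
        if close:
            fh.close()


def read_layer(source) -> LayerAnnotation:
    df = pd.read_csv(source)
    expected = ["name", "rt_center", "irm_center", "rt_radius", "irm_radius"]
    if list(df.columns) != expected:
        raise FormatError(f"layer header must be {','.join(expected)}")
    regions = []
    for i, row in df.iterrows():
        try:
            regions.append(
                LayerRegion(
                    name=str(row["name"]),
                    rt_center=float(row["rt_center"]),
                    irm_center=float(row["irm_center"]),
                    rt_radius=float(row["rt_radius"]),
                    irm_radius=float(row["irm_radius"]),
                )
            )
        except ValidationError as exc:
            raise FormatError(str(exc), line=int(i) + 2) from None
    return LayerAnnotation(regions)


def write_layer(layer: LayerAnnotation, dest) -> None:
    fh, close = _open_write(dest)
    try:
        fh.write("name,rt_center,irm_center,rt_radius,irm_radius\n")
        for r in layer:
            fh.write(
                f"{r.name},{_fmt(r.rt_center)},{_fmt(r.irm_center)},"
                f"{_fmt(r.rt_radius)},{_fmt(r.irm_radius)}\n"
            )
    finally:
        if close:
            fh.close()


def read_peaks(source) -> list:
    from mccims.peak_detection import Peak

    df = pd.read_csv(source)
    expected = ["sample_id", "rt", "irm", "intensity", "method"]
    if list(df.columns[:5]) != expected:
        raise FormatError(f"peak list header must start with {','.join(expected)}")
    return [
        Peak(
            sample_id=str(r["sample_id"]),
            rt=float(r["rt"]),
            irm=float(r["irm"]),
            intensity=float(r["intensity"]),
            method=str(r["method"]),
            name=str(r["name"]) if "name" in df.columns and pd.notna(r.get("name")) else None,
        )
        for _, r in df.iterrows()
    ]


def write_peaks(peaks: Iterable, dest) -> None:
    fh, close = _open_write(dest)
    try:
        fh.write("sample_id,rt,irm,intensity,method\n")
        for p in peaks:
            fh.write(f"{p.sample_id},{_fmt(p.rt)},{_fmt(p.irm)},{_fmt(p.intensity)},{p.method}\n")
    finally:
        if close:
            fh.close()
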