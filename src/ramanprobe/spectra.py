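"""Spectrum containers and plain-text I/O.

A :class:`Spectrum` is the universal currency of the pipeline: a sampled Raman
trace on a strictly increasing shift axis (cm^-1) with per-sample metadata.
An :class:`ExposureStack` holds repeated short-exposure traces on a shared
axis, prior to co-addition. A :class:`Report` collects the per-spectrum summary
rows (mode, windowed mean, FWHM, sequestration call) emitted by the pipeline.

File dialects are deliberately minimal: two numeric columns separated by
whitespace (``xy_text``) or a comma (``csv``), with optional ``# key = value``
comment lines carrying metadata. This matches common spectrometer text exports.
Vendor binary formats (SPC, WDF) and JCAMP-DX are out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "ExposureStack",
    "Report",
    "ParseError",
    "AxisMismatchError",
    "read_spectrum",
    "write_spectrum",
    "read_stack",
    "write_stack",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]

#: Column order of a Report table.
REPORT_COLUMNS = [
    "sample_id",
    "probe",
    "mode_cm1",
    "mean_cm1",
    "fwhm_cm1",
    "label",
    "fraction",
]

_META_KEYS = ("sample_id", "probe", "sample_class", "normalized")


class ParseError(ValueError):
    """A spectrum file could not be parsed (names the offending line)."""


class AxisMismatchError(ValueError):
    """Two traces expected to share a shift axis do not."""


@dataclass
class Spectrum:
    """A single Raman trace.

    Parameters
    ----------
    shift : array-like
        Raman shift axis in cm^-1, strictly increasing.
    intensity : array-like
        Signal values (arbitrary counts, or dimensionless after
        normalization); same length as ``shift``.
    sample_id, probe, sample_class : str
        Metadata; ``sample_class`` is ``free_probe`` or ``probe_on_protein``
        when known.
    normalized : bool
        Set by :func:`ramanprobe.preprocess.normalize_peak` once the peak
        maximum has been scaled to 1.0.
    """

    shift: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    probe: str = ""
    sample_class: str = ""
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.shift.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("shift and intensity must be one-dimensional")
        if self.shift.size != self.intensity.size:
            raise ValueError(
                f"axis length {self.shift.size} != intensity length {self.intensity.size}"
            )
        if self.shift.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(self.shift)
        if np.any(d == 0):
            raise ValueError("duplicate Raman shift values on the axis")
        if np.any(d < 0):
            raise ValueError("shift axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.shift.size)

    def replace(self, **kwargs) -> "Spectrum":
        """Return a copy with the given fields replaced."""
        base = dict(
            shift=self.shift.copy(),
            intensity=self.intensity.copy(),
            sample_id=self.sample_id,
            probe=self.probe,
            sample_class=self.sample_class,
            normalized=self.normalized,
            meta=dict(self.meta),
        )
        base.update(kwargs)
        return Spectrum(**base)


@dataclass
class ExposureStack:
    """Repeated exposures on one shared shift axis, pre-co-addition."""

    shift: np.ndarray
    exposures: np.ndarray  # shape (n_exposures, n_points)
    exposure_time: float = 60.0  # seconds per acquisition
    sample_id: str = ""
    probe: str = ""
    sample_class: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.exposures = np.atleast_2d(np.asarray(self.exposures, dtype=float))
        if self.exposures.shape[0] < 1:
            raise ValueError("an exposure stack needs at least one exposure")
        if self.exposures.shape[1] != self.shift.size:
            raise ValueError(
                f"exposures have {self.exposures.shape[1]} points but the axis has {self.shift.size}"
            )
        if np.any(np.diff(self.shift) <= 0):
            raise ValueError("shift axis must be strictly increasing")

    @property
    def n_exposures(self) -> int:
        return int(self.exposures.shape[0])


def _parse_meta_comment(line: str, meta: dict) -> None:
    body = line.lstrip("#").strip()
    if "=" in body:
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()


def _split_row(line: str, dialect: str) -> list[str]:
    if dialect == "csv":
        return [tok.strip() for tok in line.split(",")]
    return line.split()


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            return "csv" if "," in line else "xy_text"
    return "xy_text"


def read_spectrum(path, dialect: str | None = None) -> Spectrum:
    """Read a two-column (shift, intensity) text file.

    ``dialect`` is ``"xy_text"`` (whitespace-separated), ``"csv"`` or ``None``
    to sniff. ``# key = value`` comment lines populate metadata. A descending
    axis is sorted ascending with a logged warning; duplicate axis values and
    non-numeric rows are errors.
    """
    path = Path(path)
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect not in ("xy_text", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")

    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_meta_comment(line, meta)
                continue
            tokens = _split_row(line, dialect)
            if len(tokens) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(tokens)}")
            try:
                xs.append(float(tokens[0]))
                ys.append(float(tokens[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from exc

    shift = np.asarray(xs)
    intensity = np.asarray(ys)
    if shift.size and np.unique(shift).size != shift.size:
        raise ParseError(f"{path}: duplicate Raman shift values")
    if shift.size >= 2 and np.any(np.diff(shift) < 0):
        logger.warning("%s: shift axis not ascending; sorting", path)
        order = np.argsort(shift)
        shift, intensity = shift[order], intensity[order]

    return Spectrum(
        shift=shift,
        intensity=intensity,
        sample_id=meta.pop("sample_id", path.stem),
        probe=meta.pop("probe", ""),
        sample_class=meta.pop("sample_class", ""),
        normalized=meta.pop("normalized", "false").lower() in ("true", "1"),
        meta=meta,
    )


def write_spectrum(spec: Spectrum, path, dialect: str = "xy_text") -> None:
    """Write a spectrum with ``# key = value`` metadata header lines."""
    if dialect not in ("xy_text", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else " "
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id = {spec.sample_id}\n")
        if spec.probe:
            fh.write(f"# probe = {spec.probe}\n")
        if spec.sample_class:
            fh.write(f"# sample_class = {spec.sample_class}\n")
        fh.write(f"# normalized = {str(spec.normalized).lower()}\n")
        for key, value in spec.meta.items():
            fh.write(f"# {key} = {value}\n")
        for x, y in zip(spec.shift, spec.intensity):
            fh.write(f"{x:.17g}{sep}{y:.17g}\n")


def read_stack(source, exposure_time: float = 60.0) -> ExposureStack:
    """Assemble an :class:`ExposureStack`.

    ``source`` is either a sequence of spectrum file paths sharing one axis
    (within 1e-9 per point) or a single multi-column file whose first column
    is the axis and remaining columns are exposures.
    """
    if isinstance(source, (str, Path)):
        return _read_stack_multicolumn(Path(source), exposure_time)

    paths = [Path(p) for p in source]
    if not paths:
        raise ValueError("no exposure files given")
    first = read_spectrum(paths[0])
    rows = [first.intensity]
    for p in paths[1:]:
        spec = read_spectrum(p)
        if spec.shift.size != first.shift.size or np.any(
            np.abs(spec.shift - first.shift) > 1e-9
        ):
            raise AxisMismatchError(f"{p}: shift axis differs from {paths[0]}")
        rows.append(spec.intensity)
    return ExposureStack(
        shift=first.shift,
        exposures=np.vstack(rows),
        exposure_time=exposure_time,
        sample_id=first.sample_id,
        probe=first.probe,
        sample_class=first.sample_class,
    )


def _read_stack_multicolumn(path: Path, exposure_time: float) -> ExposureStack:
    meta: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_meta_comment(line, meta)
                continue
            tokens = line.replace(",", " ").split()
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric row") from exc
    if not rows:
        raise ParseError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: ragged rows (column counts {sorted(widths)})")
    data = np.asarray(rows)
    if data.shape[1] < 2:
        raise ParseError(f"{path}: need at least axis + 1 exposure column")
    return ExposureStack(
        shift=data[:, 0],
        exposures=data[:, 1:].T,
        exposure_time=exposure_time,
        sample_id=meta.pop("sample_id", path.stem),
        probe=meta.pop("probe", ""),
        sample_class=meta.pop("sample_class", ""),
        meta=meta,
    )


def write_stack(stack: ExposureStack, path) -> None:
    """Write a stack as one multi-column file (axis, then one column/exposure)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id = {stack.sample_id}\n")
        if stack.probe:
            fh.write(f"# probe = {stack.probe}\n")
        if stack.sample_class:
            fh.write(f"# sample_class = {stack.sample_class}\n")
        for i, x in enumerate(stack.shift):
            cols = " ".join(f"{v:.17g}" for v in stack.exposures[:, i])
            fh.write(f"{x:.12g} {cols}\n")


@dataclass
class Report:
    """Per-sample summary table: one row per analyzed spectrum."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.rows, pd.DataFrame):
            self.rows = pd.DataFrame(list(self.rows), columns=REPORT_COLUMNS)
        missing = [c for c in REPORT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"report missing columns: {missing}")
        self.rows = self.rows[REPORT_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "Report":
        return cls(pd.DataFrame(list(records), columns=REPORT_COLUMNS))

    def __len__(self) -> int:
        return len(self.rows)


def write_report(report: Report, path, fmt: str = "csv") -> None:
    """Persist a report as CSV or JSON (records orientation)."""
    if len(report) == 0:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    if fmt == "csv":
        report.rows.to_csv(path, index=False)
    elif fmt == "json":
        records = report.rows.to_dict(orient="records")
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path, fmt: str | None = None) -> Report:
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix == ".json" else "csv"
    if fmt == "csv":
        return Report(pd.read_csv(path))
    records = json.loads(path.read_text())
    return Report(pd.DataFrame(records, columns=REPORT_COLUMNS))
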