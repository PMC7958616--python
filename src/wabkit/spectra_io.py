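"""Spectrum containers and I/O.

A :class:`Spectrum` is the universal carrier of the pipeline: a strictly
increasing wavenumber grid (cm-1), a same-length absorbance series
(dimensionless), and sample metadata. Spectra are read from two-column
delimited text or from a minimal JCAMP-DX-like single-block XYDATA table;
sample metadata travel in a sidecar manifest rather than in filenames.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from wabkit.errors import DataError, FormatError, RangeError, UsageError

#: Closed vocabulary of sugar identities ("none" = sugar-free control).
SUGARS = ("trehalose", "sucrose", "maltose", "lactose", "raffinose", "none")

#: Sentinel S/P ratio for protein-free (binary sugar-water) samples.
PROTEIN_FREE = math.inf


@dataclass(frozen=True)
class SampleMeta:
    """Identity and formulation labels attached to one measured spectrum.

    ``sp_ratio`` is the monosaccharide-units-per-protein molar ratio;
    protein-free samples use ``math.inf`` (spelled ``inf`` in manifests).
    """

    sample_id: str = ""
    sugar: str = "none"
    sp_ratio: float = PROTEIN_FREE
    replicate_index: int = 1

    def __post_init__(self):
        if self.sugar not in SUGARS:
            raise DataError(f"unknown sugar {self.sugar!r}; expected one of {SUGARS}")
        if not (self.sp_ratio > 0):  # also rejects nan
            raise DataError(f"sp_ratio must be > 0 or inf, got {self.sp_ratio}")
        if self.replicate_index < 1:
            raise DataError(f"replicate_index must be >= 1, got {self.replicate_index}")


@dataclass
class Spectrum:
    """Wavenumber grid + absorbance series + sample metadata."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise DataError("wavenumbers and absorbance must be 1-D")
        if len(self.wavenumbers) < 2:
            raise DataError("a spectrum needs at least 2 points")
        if len(self.wavenumbers) != len(self.absorbance):
            raise DataError(
                f"length mismatch: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.absorbance)} absorbance values"
            )
        dw = np.diff(self.wavenumbers)
        if np.any(dw <= 0):
            raise DataError("wavenumbers must be strictly increasing (no duplicates)")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise DataError("non-finite wavenumber values")
        if not np.all(np.isfinite(self.absorbance)):
            raise DataError("non-finite absorbance values")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavenumbers[0] <= lo and hi <= self.wavenumbers[-1]

    def with_absorbance(self, absorbance: np.ndarray) -> "Spectrum":
        """Same grid and metadata, new absorbance values."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(absorbance, float), self.meta)

    def interp(self, w) -> np.ndarray:
        """Linear interpolation of absorbance at ``w`` (must lie in the span)."""
        w = np.asarray(w, dtype=float)
        lo, hi = self.span
        if np.any(w < lo) or np.any(w > hi):
            raise RangeError(f"wavenumbers outside data span [{lo}, {hi}]")
        return np.interp(w, self.wavenumbers, self.absorbance)


# ---------------------------------------------------------------------------
# readers / writers


def _parse_two_column(text: str, path) -> tuple[np.ndarray, np.ndarray]:
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\t;]+|\s+", line)
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if lineno == 1:  # tolerate a single header line
                continue
            raise FormatError(f"{path}:{lineno}: non-numeric row {line!r}")
    if len(rows) < 2:
        raise FormatError(f"{path}: fewer than 2 data rows")
    arr = np.array(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


def _parse_jcamp(text: str, path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX-like reader: one ##XYDATA=(X++(Y..Y)) or (XY..XY) block."""
    lines = text.splitlines()
    header: dict[str, str] = {}
    data_start = None
    form = None
    for i, raw in enumerate(lines):
        line = raw.strip()
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            header[key] = val.strip()
            if key == "XYDATA":
                form = val.strip().upper().replace(" ", "")
                data_start = i + 1
                break
    if data_start is None:
        raise FormatError(f"{path}: no ##XYDATA block found")
    body = []
    for raw in lines[data_start:]:
        line = raw.strip()
        if line.startswith("##"):
            break
        if line:
            body.append(line)
    if not body:
        raise FormatError(f"{path}: empty XYDATA block")

    if form.startswith("(XY..XY)"):
        xs, ys = [], []
        for line in body:
            nums = [float(t) for t in re.split(r"[,\s;]+", line) if t]
            if len(nums) % 2:
                raise FormatError(f"{path}: odd token count in (XY..XY) line {line!r}")
            xs.extend(nums[0::2])
            ys.extend(nums[1::2])
        return np.asarray(xs), np.asarray(ys)

    if form.startswith("(X++(Y..Y))"):
        try:
            deltax = float(header["DELTAX"])
        except KeyError:
            try:
                firstx = float(header["FIRSTX"])
                lastx = float(header["LASTX"])
                npoints = int(float(header["NPOINTS"]))
                deltax = (lastx - firstx) / (npoints - 1)
            except KeyError:
                raise FormatError(f"{path}: (X++(Y..Y)) needs ##DELTAX or FIRSTX/LASTX/NPOINTS")
        xs, ys = [], []
        for line in body:
            nums = [float(t) for t in re.split(r"[,\s;]+", line) if t]
            if len(nums) < 2:
                raise FormatError(f"{path}: short (X++(Y..Y)) line {line!r}")
            x0 = nums[0]
            for j, y in enumerate(nums[1:]):
                xs.append(x0 + j * deltax)
                ys.append(y)
        return np.asarray(xs), np.asarray(ys)

    raise FormatError(f"{path}: unsupported XYDATA form {form!r}")


def read_spectrum(path, dialect: str = "csv2col", meta: SampleMeta | None = None) -> Spectrum:
    """Read a spectrum from disk.

    Parameters
    ----------
    path
        File location.
    dialect
        ``"csv2col"`` (two numeric columns, comma/tab/whitespace separated,
        optional single header line) or ``"jcamp"`` (single-block
        XYDATA-style table).
    meta
        Optional metadata to attach (manifests are the usual source).

    The returned spectrum is sorted by ascending wavenumber; duplicated
    wavenumbers are rejected as a :class:`~wabkit.errors.DataError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    text = path.read_text()
    if dialect == "csv2col":
        w, a = _parse_two_column(text, path)
    elif dialect == "jcamp":
        w, a = _parse_jcamp(text, path)
    else:
        raise UsageError(f"unknown dialect {dialect!r}; expected 'csv2col' or 'jcamp'")
    order = np.argsort(w, kind="stable")
    w, a = w[order], a[order]
    if np.any(np.diff(w) == 0):
        raise DataError(f"{path}: duplicated wavenumber values")
    return Spectrum(w, a, meta or SampleMeta())


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column CSV (full float precision)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("wavenumber_cm1,absorbance\n")
        for w, a in zip(spectrum.wavenumbers, spectrum.absorbance):
            fh.write(f"{float(w)!r},{float(a)!r}\n")


def resample(spectrum: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linear interpolation onto ``grid`` (no extrapolation); metadata kept."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.span
    if grid[0] < lo or grid[-1] > hi:
        raise RangeError(
            f"target grid [{grid[0]}, {grid[-1]}] extends outside data span [{lo}, {hi}]"
        )
    return Spectrum(grid, spectrum.interp(grid), spectrum.meta)


# ---------------------------------------------------------------------------
# manifests


MANIFEST_COLUMNS = ["sample_id", "sugar", "sp_ratio", "replicate", "path"]


def read_manifest(path) -> list[tuple[SampleMeta, Path]]:
    """Read a sidecar manifest (CSV/TSV: sample_id, sugar, sp_ratio, replicate, path).

    ``sp_ratio`` accepts ``inf`` for protein-free samples. Paths are resolved
    relative to the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such manifest: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    entries = []
    for _, row in df.iterrows():
        meta = SampleMeta(
            sample_id=str(row["sample_id"]),
            sugar=str(row["sugar"]),
            sp_ratio=float(row["sp_ratio"]),
            replicate_index=int(float(row["replicate"])),
        )
        entries.append((meta, path.parent / str(row["path"])))
    if not entries:
        raise DataError(f"{path}: empty manifest")
    return entries


def write_manifest(entries: Iterable[tuple[SampleMeta, str]], path) -> None:
    """Write a manifest; sp_ratio inf is spelled ``inf``."""
    rows = []
    for meta, spath in entries:
        rows.append(
            {
                "sample_id": meta.sample_id,
                "sugar": meta.sugar,
                "sp_ratio": "inf" if math.isinf(meta.sp_ratio) else repr(meta.sp_ratio),
                "replicate": meta.replicate_index,
                "path": str(spath),
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result tables


SUMMARY_COLUMNS = [
    "sample_id",
    "class",
    "mean_population",
    "sd_population",
    "mean_center",
    "sd_center",
    "n_replicates",
]


def write_decomposition_table(results, path) -> None:
    """Write replicate summaries as a delimited table.

    One row per (sample, sub-band class) with mean/SD population and
    mean/SD center, in a fixed column order. ``results`` is a non-empty
    sequence of :class:`wabkit.banddecomp.ReplicateSummary`.
    """
    results = list(results)
    if not results:
        raise UsageError("write_decomposition_table: empty results")
    rows = []
    for summary in results:
        for name, stats in summary.classes.items():
            rows.append(
                {
                    "sample_id": summary.sample_id,
                    "class": name,
                    "mean_population": repr(stats.mean_population),
                    "sd_population": repr(stats.sd_population),
                    "mean_center": "" if stats.mean_center is None else repr(stats.mean_center),
                    "sd_center": "" if stats.sd_center is None else repr(stats.sd_center),
                    "n_replicates": summary.n_replicates,
                }
            )
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False)


def read_decomposition_table(path) -> pd.DataFrame:
    """Read back a summary table written by :func:`write_decomposition_table`."""
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: summary table missing columns {missing}")
    return df
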