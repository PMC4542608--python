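"""Spectrum readers/writers and dataset assembly.

Supported on-disk forms: two-column CSV/TSV (header
``wavenumber_cm-1,intensity``; headerless numeric files accepted) and the
common AFFN JCAMP-DX layouts (``##XYDATA=(X++(Y..Y))`` and
``##XYPOINTS=(XY..XY)``). Spectra stored with a descending axis are
returned ascending with the fact recorded in ``Spectrum.meta``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import SpectralDataset, Spectrum

_DIALECTS = ("csv", "tsv", "jcampdx")


def _infer_dialect(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in (".jdx", ".dx", ".jcm"):
        return "jcampdx"
    if ext == ".tsv":
        return "tsv"
    return "csv"


def read_spectrum(path: str | Path, dialect: Optional[str] = None) -> Spectrum:
    """Read one two-column spectrum file.

    Returns a :class:`Spectrum` with a strictly ascending axis; files stored
    descending are reversed (``meta['axis_reversed']`` set). Non-numeric
    cells and NaN intensities raise with the offending line/channel.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "jcampdx":
        axis, intensity = _read_jcampdx(path)
    else:
        axis, intensity = _read_columns(path, sep="\t" if dialect == "tsv" else ",")

    if np.any(np.isnan(intensity)):
        bad = int(np.flatnonzero(np.isnan(intensity))[0])
        raise ValueError(f"{path.name}: NaN intensity at channel {bad}")

    meta = {"source": str(path)}
    diffs = np.diff(axis)
    if axis.size >= 2 and np.all(diffs < 0):
        axis, intensity = axis[::-1].copy(), intensity[::-1].copy()
        meta["axis_reversed"] = True
    elif axis.size >= 2 and not np.all(diffs > 0):
        raise ValueError(f"{path.name}: wavenumber axis is not monotonic")
    return Spectrum(axis, intensity, site_id=path.stem, meta=meta)


def _read_columns(path: Path, sep: str) -> tuple[np.ndarray, np.ndarray]:
    lines = path.read_text().splitlines()
    start = 0
    if lines and not _is_numeric_row(lines[0], sep):
        start = 1  # header row
    xs, ys = [], []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 2:
            raise ValueError(f"{path.name}: line {lineno}: expected two columns")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path.name}: line {lineno}: non-numeric value") from exc
    if not xs:
        raise ValueError(f"{path.name}: no data rows")
    return np.asarray(xs), np.asarray(ys)


def _is_numeric_row(line: str, sep: str) -> bool:
    parts = [p.strip() for p in line.split(sep)]
    if len(parts) < 2:
        return False
    try:
        float(parts[0]), float(parts[1])
        return True
    except ValueError:
        return False


_NUM = re.compile(r"[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")


def _read_jcampdx(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal AFFN JCAMP-DX reader (XYDATA and XYPOINTS forms)."""
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None
    for line in path.read_text().splitlines():
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                mode = "xydata"
                continue
            if key == "XYPOINTS":
                mode = "xypoints"
                continue
            if key == "END":
                mode = None
                continue
            fields[key] = value
            continue
        if mode is not None and line.strip():
            data_lines.append(line.strip())
    if not data_lines:
        raise ValueError(f"{path.name}: no XYDATA/XYPOINTS block found")
    xfac = float(fields.get("XFACTOR", 1.0))
    yfac = float(fields.get("YFACTOR", 1.0))
    if "FIRSTX" in fields and "LASTX" in fields and "NPOINTS" in fields and mode is None:
        pass
    nums_per_line = [[float(m) for m in _NUM.findall(ln)] for ln in data_lines]
    if "NPOINTS" in fields and "FIRSTX" in fields and "LASTX" in fields and any(
        len(row) > 2 for row in nums_per_line
    ):
        # X++(Y..Y): first number per line is an x checkpoint, rest are y
        n = int(float(fields["NPOINTS"]))
        ys: list[float] = []
        for row in nums_per_line:
            ys.extend(row[1:])
        if len(ys) != n:
            raise ValueError(f"{path.name}: NPOINTS={n} but {len(ys)} ordinates read")
        axis = np.linspace(float(fields["FIRSTX"]), float(fields["LASTX"]), n)
        return axis * xfac, np.asarray(ys) * yfac
    # XY..XY pairs
    flat = [v for row in nums_per_line for v in row]
    if len(flat) % 2:
        raise ValueError(f"{path.name}: odd number of values in XY point list")
    arr = np.asarray(flat).reshape(-1, 2)
    return arr[:, 0] * xfac, arr[:, 1] * yfac


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavenumber_cm-1": spectrum.wavenumbers, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t")
    required = {"file", "site_id"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return manifest


def assemble_dataset(
    spectra: Mapping[str, Spectrum] | Sequence[Spectrum],
    manifest: Optional[pd.DataFrame] = None,
) -> SpectralDataset:
    """Stack spectra onto the first spectrum's axis and join the manifest.

    Axes differing by less than half the channel step are linearly
    interpolated onto the common grid (flagged per spectrum in the
    metadata); larger discrepancies raise. When ``spectra`` is a mapping of
    file name to spectrum, metadata is joined from the manifest's ``file``
    column; otherwise each spectrum's own identifiers are used.
    """
    if isinstance(spectra, Mapping):
        if manifest is None:
            raise ValueError("a manifest is required when spectra are keyed by file")
        items = list(spectra.items())
    else:
        items = [(None, s) for s in spectra]
    if not items:
        raise ValueError("no spectra to assemble")

    by_file = None
    if manifest is not None:
        if manifest["file"].duplicated().any():
            raise ValueError("manifest contains duplicate file entries")
        by_file = manifest.set_index("file")

    axis = items[0][1].wavenumbers
    step = float(np.median(np.diff(axis))) if axis.size > 1 else 1.0
    rows, data = [], []
    for name, s in items:
        if s.wavenumbers.size == axis.size and np.array_equal(s.wavenumbers, axis):
            y, interpolated = s.intensities, False
        else:
            if s.wavenumbers.size != axis.size or np.max(
                np.abs(s.wavenumbers - axis)
            ) >= 0.5 * step:
                raise ValueError(
                    f"spectrum {name or s.site_id!r}: axis differs from the common "
                    f"grid by more than half a step"
                )
            y, interpolated = np.interp(axis, s.wavenumbers, s.intensities), True
        row = {
            "site_id": s.site_id,
            "specimen_id": s.specimen_id,
            "gross_label": s.gross_label,
            "interpolated": interpolated,
        }
        if by_file is not None:
            if name is None:
                raise ValueError("manifest given but spectra are not keyed by file")
            if name not in by_file.index:
                raise ValueError(f"no manifest row for file {name!r}")
            mrow = by_file.loc[name]
            for col in by_file.columns:
                row[col] = mrow[col]
        rows.append(row)
        data.append(y)
    return SpectralDataset(axis, np.asarray(data), pd.DataFrame(rows))


def load_dataset(manifest_path: str | Path, root: Optional[str | Path] = None) -> SpectralDataset:
    """Read every file listed in a manifest TSV and assemble the dataset."""
    manifest_path = Path(manifest_path)
    root = Path(root) if root is not None else manifest_path.parent
    manifest = read_manifest(manifest_path)
    spectra = {row["file"]: read_spectrum(root / row["file"]) for _, row in manifest.iterrows()}
    return assemble_dataset(spectra, manifest)
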