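"""Reflection, map and configuration file I/O.

Formats
-------
* hkl-text: whitespace-separated columns ``h k l F [phi] [centric] [eps]
  [measured]`` with ``#`` comment lines. Unmeasured amplitudes and absent
  phases are written as ``nan``. Round trips are exact on the decimal
  representation written.
* MTZ: read through gemmi using standard column labels (H K L, an
  amplitude column, optionally a phase column).
* CCP4/MRC maps: written through gemmi in mode 2 (float32), axis order XYZ.
* Run configuration and manifests: YAML key-value files.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .reciprocal import REFLECTION_COLUMNS, DensityMap, ReflectionSet, UnitCellGrid

__all__ = [
    "read_reflections",
    "write_reflections",
    "read_mtz",
    "write_map",
    "read_map",
    "read_config",
    "write_config",
    "RunManifest",
]

_HEADER = "# h k l F phi centric epsilon measured"


def write_reflections(path: str | Path, refl: ReflectionSet) -> None:
    """Write a reflection set in the plain-text hkl format."""
    path = Path(path)
    t = refl.table
    lines = [
        f"# cell {' '.join(f'{v:g}' for v in refl.cell.cell_lengths)} "
        f"{' '.join(f'{v:g}' for v in refl.cell.cell_angles)}",
        f"# grid {' '.join(str(v) for v in refl.cell.shape)} d_min {refl.cell.d_min:g}",
        f"# f000 {refl.f000:.8g}",
        _HEADER,
    ]
    for row in t.itertuples(index=False):
        lines.append(
            f"{row.h:5d} {row.k:5d} {row.l:5d} {row.F:15.8g} {row.phi:15.10g} "
            f"{int(row.centric):d} {row.epsilon:g} {int(row.is_measured):d}"
        )
    path.write_text("\n".join(lines) + "\n")


def _parse_header(lines: list[str]) -> tuple[UnitCellGrid | None, float]:
    cell = None
    f000 = 0.0
    lengths = angles = shape = d_min = None
    for ln in lines:
        parts = ln[1:].split()
        if not parts:
            continue
        if parts[0] == "cell" and len(parts) == 7:
            lengths = tuple(float(x) for x in parts[1:4])
            angles = tuple(float(x) for x in parts[4:7])
        elif parts[0] == "grid" and len(parts) >= 4:
            shape = tuple(int(x) for x in parts[1:4])
            if len(parts) >= 6 and parts[4] == "d_min":
                d_min = float(parts[5])
        elif parts[0] == "f000":
            f000 = float(parts[1])
    if lengths and shape and d_min:
        cell = UnitCellGrid(lengths, angles or (90.0, 90.0, 90.0), shape, d_min)
    return cell, f000


def read_reflections(path: str | Path, cell: UnitCellGrid | None = None) -> ReflectionSet:
    """Read a plain-text hkl file, with line-numbered diagnostics.

    The cell may be given in ``#``-header lines (as written by
    :func:`write_reflections`) or passed explicitly.
    """
    path = Path(path)
    header_lines = []
    rows = []
    seen: dict[tuple[int, int, int], int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            header_lines.append(s)
            continue
        parts = s.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: malformed line (need at least h k l F): {s!r}")
        try:
            h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
            F = float(parts[3])
            phi = float(parts[4]) if len(parts) > 4 else np.nan
            centric = bool(int(parts[5])) if len(parts) > 5 else False
            eps = float(parts[6]) if len(parts) > 6 else 1.0
            measured = bool(int(parts[7])) if len(parts) > 7 else np.isfinite(F)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed line: {s!r}") from exc
        if np.isfinite(F) and F < 0:
            raise ValueError(f"{path}:{lineno}: negative amplitude {F}")
        key = (h, k, l)
        if key in seen:
            raise ValueError(f"{path}:{lineno}: duplicate hkl {key} (first seen at line {seen[key]})")
        seen[key] = lineno
        rows.append((h, k, l, F, phi, centric, eps, measured))
    header_cell, f000 = _parse_header(header_lines)
    cell = cell or header_cell
    if cell is None:
        raise ValueError(f"{path}: no cell information in header and none supplied")
    df = pd.DataFrame(rows, columns=["h", "k", "l", "F", "phi", "centric", "epsilon", "is_measured"])
    df["d"] = cell.d_spacing(df[["h", "k", "l"]].to_numpy())
    return ReflectionSet(df[REFLECTION_COLUMNS], cell, f000=f000)


def read_mtz(
    path: str | Path,
    cell: UnitCellGrid | None = None,
    amplitude_label: str = "F",
    phase_label: str | None = "PHI",
    shape: tuple[int, int, int] | None = None,
) -> ReflectionSet:
    """Import reflections from an MTZ file via gemmi.

    Column labels default to H K L F PHI; the grid shape (needed for the
    Fourier mapping) is chosen Shannon-adequately from the data resolution
    when not supplied.
    """
    mtz = gemmi.read_mtz_file(str(path))
    labels = [c.label for c in mtz.columns]
    for required in ("H", "K", "L", amplitude_label):
        if required not in labels:
            raise ValueError(f"MTZ file lacks required column {required!r}")
    data = np.array(mtz, copy=True)
    col = {label: i for i, label in enumerate(labels)}
    hkl = data[:, [col["H"], col["K"], col["L"]]].astype(int)
    F = data[:, col[amplitude_label]]
    phi = np.deg2rad(data[:, col[phase_label]]) if phase_label and phase_label in labels else np.full(len(F), np.nan)
    eps = data[:, col["EPS"]] if "EPS" in labels else np.ones(len(F))
    d = mtz.make_d_array()
    d_min = float(np.nanmin(d))
    if cell is None:
        c = mtz.cell
        if shape is None:
            shape = tuple(int(2 * np.ceil(length / d_min / 2.0) * 2) for length in (c.a, c.b, c.c))
        cell = UnitCellGrid((c.a, c.b, c.c), (c.alpha, c.beta, c.gamma), shape, d_min * 0.999)
    df = pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "F": F,
            "phi": phi,
            "centric": False,
            "epsilon": eps,
            "d": d,
            "is_measured": np.isfinite(F),
        }
    )
    return ReflectionSet(df[REFLECTION_COLUMNS], cell)


def write_map(path: str | Path, dmap: DensityMap) -> None:
    """Write a density map in CCP4 format (mode 2, axis order XYZ)."""
    grid = gemmi.FloatGrid(np.asarray(dmap.values, dtype=np.float32))
    grid.unit_cell = dmap.cell.gemmi_cell
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    ccp4.write_ccp4_map(str(path))


def read_map(path: str | Path, d_min: float | None = None) -> DensityMap:
    """Read a CCP4/MRC map back into a DensityMap."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    ccp4.setup(float("nan"))
    grid = ccp4.grid
    values = np.array(grid, copy=True)
    c = grid.unit_cell
    if d_min is None:
        d_min = 2.0 * max(length / n for length, n in zip((c.a, c.b, c.c), values.shape))
    cell = UnitCellGrid((c.a, c.b, c.c), (c.alpha, c.beta, c.gamma), values.shape, d_min)
    return DensityMap(values.astype(float), cell)


def read_config(path: str | Path) -> dict:
    """Read a YAML run-configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a key-value mapping")
    return cfg


def write_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


@dataclass
class RunManifest:
    """Everything needed to re-run a replicate bit-identically."""

    config: dict
    seeds: list[int]
    outputs: dict[str, str] = field(default_factory=dict)
    software_version: str = ""
    started: float = field(default_factory=time.time)
    elapsed: float = 0.0

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
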