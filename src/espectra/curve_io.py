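"""Force-curve containers and plain-text I/O.

All in-memory quantities are SI (metres, newtons, pascals).  Unit conversion
happens only at the file boundary, driven by optional ``z_unit`` / ``F_unit``
header keys.  The canonical on-disk dialects are two numeric columns (z, F)
preceded by ``#``-prefixed metadata lines::

    # radius_m 8e-6
    # k_N_per_m 0.049
    # nu 0.5
    z,F
    0.0,1.2e-11
    ...

``csv2col`` uses a comma delimiter, ``tsv2col`` tab/whitespace.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import CurveFormatError, CurveParseError, MetadataError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for typing only
    from .bilayer import BilayerFit
    from .hertz import HertzPopulation
    from .spectra import MeanSpectrum

__all__ = [
    "AcquisitionMetadata",
    "ForceDistanceCurve",
    "ForceIndentationCurve",
    "read_curve",
    "write_curve",
    "write_results",
    "read_results",
    "DIALECTS",
]

DIALECTS = {"csv2col": ",", "tsv2col": None}  # None -> any whitespace

_Z_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}
_F_UNITS = {"N": 1.0, "mN": 1e-3, "uN": 1e-6, "µN": 1e-6, "nN": 1e-9, "pN": 1e-12}

_MIN_SAMPLES = 16


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Probe and cantilever parameters attached to every curve.

    Parameters
    ----------
    probe_radius : float
        Radius R of the spherical probe, in metres.
    spring_constant : float
        Cantilever spring constant k, in N/m.
    poisson_ratio : float
        Poisson's ratio of the sample; 0.5 (incompressible) by default,
        the standard assumption for living cells.
    approach_speed : float, optional
        Piezo approach speed in m/s (informational).
    label : str
        Free-text identifier.
    """

    probe_radius: float
    spring_constant: float
    poisson_ratio: float = 0.5
    approach_speed: float | None = None
    label: str = ""

    def __post_init__(self):
        if not (self.probe_radius > 0 and np.isfinite(self.probe_radius)):
            raise MetadataError(f"probe_radius must be positive, got {self.probe_radius!r}")
        if not (self.spring_constant > 0 and np.isfinite(self.spring_constant)):
            raise MetadataError(f"spring_constant must be positive, got {self.spring_constant!r}")
        if not (0.0 <= self.poisson_ratio <= 0.5 + 1e-12):
            raise MetadataError(f"poisson_ratio must lie in [0, 0.5], got {self.poisson_ratio!r}")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ForceDistanceCurve:
    """Raw approach curve: force F versus piezo displacement z (both SI)."""

    z: np.ndarray
    F: np.ndarray
    metadata: AcquisitionMetadata

    def __post_init__(self):
        z = _as_float_array(self.z, "z")
        F = _as_float_array(self.F, "F")
        if len(z) != len(F):
            raise ValidationError(f"z and F lengths differ: {len(z)} vs {len(F)}")
        if len(z) < _MIN_SAMPLES:
            raise ValidationError(f"curve needs at least {_MIN_SAMPLES} samples, got {len(z)}")
        # de-duplicate identical z, then require strict monotonicity
        keep = np.concatenate([[True], np.diff(z) > 0])
        if np.any(np.diff(z) < 0):
            raise ValidationError("z must be non-decreasing on the approach segment")
        object.__setattr__(self, "z", z[keep])
        object.__setattr__(self, "F", F[keep])
        if len(self.z) < _MIN_SAMPLES:
            raise ValidationError("fewer than the minimum samples remain after de-duplication")

    def __len__(self) -> int:
        return len(self.z)


@dataclass(frozen=True)
class ForceIndentationCurve:
    """Contact-corrected curve: force F versus indentation depth delta (SI)."""

    delta: np.ndarray
    F: np.ndarray
    contact_point_z: float
    metadata: AcquisitionMetadata

    def __post_init__(self):
        d = _as_float_array(self.delta, "delta")
        F = _as_float_array(self.F, "F")
        if len(d) != len(F):
            raise ValidationError(f"delta and F lengths differ: {len(d)} vs {len(F)}")
        if len(d) and d[0] < 0:
            raise ValidationError("delta must be non-negative")
        if np.any(np.diff(d) < 0):
            raise ValidationError("delta must be non-decreasing")
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "F", F)

    def __len__(self) -> int:
        return len(self.delta)


# ---------------------------------------------------------------------------
# reading

_HEADER_KEYS = {
    "radius_m": ("probe_radius", float),
    "k_N_per_m": ("spring_constant", float),
    "nu": ("poisson_ratio", float),
    "approach_speed_m_per_s": ("approach_speed", float),
    "label": ("label", str),
}


def _approach_segment(z: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep the forward (approach) part: increasing z up to the force maximum."""
    turn = int(np.argmax(z)) + 1  # end of the increasing-z leg
    z, F = z[:turn], F[:turn]
    stop = int(np.argmax(F)) + 1
    return z[:stop], F[:stop]


def read_curve(
    path: str | Path,
    dialect: str = "csv2col",
    metadata: AcquisitionMetadata | None = None,
) -> ForceDistanceCurve:
    """Read a two-column force–distance file in the canonical dialect.

    Metadata may come from ``#``-prefixed header lines (keys ``radius_m``,
    ``k_N_per_m``, ``nu``, optional ``z_unit``/``F_unit``, ``label``) or be
    supplied via the ``metadata`` argument, which takes precedence.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise CurveFormatError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    sep = DIALECTS[dialect]

    header: dict[str, str] = {}
    rows: list[tuple[int, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#").strip().split(None, 1)
                if len(parts) == 2:
                    header[parts[0]] = parts[1]
                continue
            rows.append((i, line))

    # optional single column-name line
    if rows:
        first = rows[0][1]
        tokens = first.split(sep) if sep else first.split()
        try:
            [float(t) for t in tokens if t != ""]
        except ValueError:
            rows = rows[1:]

    if not rows:
        raise CurveParseError(f"{path}: no data rows found")

    z_vals, F_vals = [], []
    for lineno, line in rows:
        tokens = [t for t in (line.split(sep) if sep else line.split()) if t != ""]
        if len(tokens) < 2:
            raise CurveFormatError(f"{path}:{lineno}: expected 2 columns, got {len(tokens)}")
        try:
            z_vals.append(float(tokens[0]))
            F_vals.append(float(tokens[1]))
        except ValueError as exc:
            raise CurveParseError(f"{path}:{lineno}: non-numeric row: {line!r}", row=lineno) from exc

    z = np.array(z_vals) * _unit_factor(header.get("z_unit", "m"), _Z_UNITS, "z_unit")
    F = np.array(F_vals) * _unit_factor(header.get("F_unit", "N"), _F_UNITS, "F_unit")
    z, F = _approach_segment(z, F)

    if metadata is None:
        kwargs: dict = {}
        for key, (attr, conv) in _HEADER_KEYS.items():
            if key in header:
                kwargs[attr] = conv(header[key])
        if "probe_radius" not in kwargs:
            raise MetadataError(f"{path}: missing 'radius_m' header and no metadata supplied")
        if "spring_constant" not in kwargs:
            raise MetadataError(f"{path}: missing 'k_N_per_m' header and no metadata supplied")
        metadata = AcquisitionMetadata(**kwargs)

    return ForceDistanceCurve(z=z, F=F, metadata=metadata)


def _unit_factor(name: str, table: dict[str, float], key: str) -> float:
    try:
        return table[name]
    except KeyError:
        raise CurveFormatError(f"unknown {key} {name!r}; expected one of {sorted(table)}") from None


# ---------------------------------------------------------------------------
# writing

def write_curve(curve: ForceDistanceCurve, path: str | Path, dialect: str = "csv2col") -> None:
    """Write a curve in the canonical dialect (SI units, full float precision)."""
    if dialect not in DIALECTS:
        raise CurveFormatError(f"unknown dialect {dialect!r}")
    sep = DIALECTS[dialect] or "\t"
    md = curve.metadata
    lines = [
        f"# radius_m {md.probe_radius!r}",
        f"# k_N_per_m {md.spring_constant!r}",
        f"# nu {md.poisson_ratio!r}",
    ]
    if md.approach_speed is not None:
        lines.append(f"# approach_speed_m_per_s {md.approach_speed!r}")
    if md.label:
        lines.append(f"# label {md.label}")
    lines.append(sep.join(["z", "F"]))
    for zi, Fi in zip(curve.z, curve.F):
        lines.append(f"{float(zi)!r}{sep}{float(Fi)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_results(
    fit,
    spectrum: "MeanSpectrum | None",
    path: str | Path,
    *,
    extra: dict | None = None,
) -> None:
    """Emit a JSON result record and, alongside it, a CSV of the mean spectrum.

    ``fit`` may be a :class:`~espectra.bilayer.BilayerFit`, a
    :class:`~espectra.hertz.HertzPopulation`, or a mapping of named blocks of
    either.  Floats are serialized via Python's shortest round-trip ``repr``
    (>= 9 significant digits), so a read-back reproduces them bit-exactly.
    The spectrum CSV lives next to the JSON file with suffix
    ``_spectrum.csv`` and columns (delta_m, E_mean_Pa, E_std_Pa, n).
    """
    from . import __version__

    path = Path(path)
    if spectrum is not None:
        n_arr = np.asarray(spectrum.n_curves_per_point)
        if n_arr.size == 0 or int(n_arr.max()) == 0:
            raise ValidationError("refusing to write a mean spectrum built from 0 curves")

    record: dict = {"software": "espectra", "version": __version__}
    if extra:
        record["config"] = extra
    record.update(_result_blocks(fit))
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")

    if spectrum is not None:
        csv_path = path.with_name(path.stem + "_spectrum.csv")
        pd.DataFrame(
            {
                "delta_m": np.asarray(spectrum.delta_grid),
                "E_mean_Pa": np.asarray(spectrum.E_mean),
                "E_std_Pa": np.asarray(spectrum.E_std),
                "n": np.asarray(spectrum.n_curves_per_point, dtype=int),
            }
        ).to_csv(csv_path, index=False)


def _result_blocks(fit) -> dict:
    if fit is None:
        return {}
    if isinstance(fit, dict):
        out = {}
        for name, block in fit.items():
            out.update({name: _serialize_obj(block)})
        return out
    # single object: pick a block name from its type
    name = type(fit).__name__
    block_key = {"BilayerFit": "bilayer", "HertzPopulation": "hertz"}.get(name, name.lower())
    return {block_key: _serialize_obj(fit)}


def _serialize_obj(obj):
    if obj is None or isinstance(obj, (int, float, str, bool)):
        return obj
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_serialize_obj(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _serialize_obj(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj):
        return {f.name: _serialize_obj(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise ValidationError(f"cannot serialize {type(obj).__name__} into a result record")


def read_results(path: str | Path) -> dict:
    """Read back a JSON result record written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
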