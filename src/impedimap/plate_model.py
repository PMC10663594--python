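"""Data model and container I/O for impedance-imaging plates.

A plate is a 96-well microelectrode-array culture plate; each well carries a
64x64 electrode grid at 25 um pitch.  A full scan of a well produces 27
parameter maps: three field configurations (vertical field VF, lateral field
LF, electrode-impedance field EF), each demodulated into four frequency
magnitudes, four phases and a DC component.

On disk a plate is an HDF5 file with one ``(27, 64, 64)`` dataset per well
per scan plus a JSON metadata sidecar (``<plate>.json``) describing the plate
map.  Grid indexing is row-major, 0-based, ``(row 0, col 0)`` at the top-left
of the well image.  Time is expressed in hours since cell seeding.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRID_SHAPE",
    "N_WELLS",
    "FIELDS",
    "FREQUENCIES_HZ",
    "MAP_KEYS",
    "WELL_IDS",
    "ElectrodeArray",
    "FieldConfig",
    "ParameterMapStack",
    "WellMask",
    "WellTimeSeries",
    "WellAnnotation",
    "PlateMetadata",
    "PlateFormatError",
    "PlateWriter",
    "read_plate",
    "write_plate",
    "export_timeseries",
    "read_platemap_csv",
    "well_id_to_rc",
    "rc_to_well_id",
]

# ---------------------------------------------------------------------------
# Fixed vocabulary
# ---------------------------------------------------------------------------

GRID_SHAPE = (64, 64)
N_WELLS = 96
PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12

FIELDS = ("VF", "LF", "EF")
FREQUENCIES_HZ = (250.0, 1000.0, 4000.0, 16000.0)

#: Per-field parameter names, in canonical storage order.
PARAMS = tuple(
    [f"mag@{int(f)}" for f in FREQUENCIES_HZ]
    + [f"phase@{int(f)}" for f in FREQUENCIES_HZ]
    + ["DC"]
)

#: Canonical (field, parameter) order of the 27 maps in a stack.
MAP_KEYS = tuple((fld, p) for fld in FIELDS for p in PARAMS)

WELL_IDS = tuple(f"{r}{c}" for r in PLATE_ROWS for c in range(1, PLATE_COLS + 1))

_WELL_RE = re.compile(r"^([A-H])(\d{1,2})$")


class PlateFormatError(ValueError):
    """Raised when a plate container or stack violates the format contract."""


def well_id_to_rc(well_id: str) -> tuple[int, int]:
    """Map a well ID like ``"B7"`` to 0-based ``(row, col)`` on the 8x12 plate."""
    m = _WELL_RE.match(well_id)
    if not m:
        raise ValueError(f"invalid well id {well_id!r}")
    col = int(m.group(2))
    if not 1 <= col <= PLATE_COLS:
        raise ValueError(f"well column out of range in {well_id!r}")
    return PLATE_ROWS.index(m.group(1)), col - 1


def rc_to_well_id(row: int, col: int) -> str:
    if not (0 <= row < len(PLATE_ROWS) and 0 <= col < PLATE_COLS):
        raise ValueError(f"plate position ({row}, {col}) out of range")
    return f"{PLATE_ROWS[row]}{col + 1}"


def map_key_str(key: tuple[str, str]) -> str:
    return f"{key[0]}:{key[1]}"


def parse_map_key(s: str) -> tuple[str, str]:
    fld, _, param = s.partition(":")
    key = (fld, param)
    if key not in MAP_KEYS:
        raise PlateFormatError(f"unknown map key {s!r}")
    return key


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeArray:
    """Geometry of the per-well electrode grid."""

    n_rows: int = 64
    n_cols: int = 64
    pitch_um: float = 25.0

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def electrode_area_cm2(self) -> float:
        """Effective unit area of one electrode (pitch squared), in cm^2."""
        return (self.pitch_um * 1e-4) ** 2


@dataclass(frozen=True)
class FieldConfig:
    """Stimulation settings for one field configuration.

    Amplitudes are scaled per frequency so the TIA output amplitudes are
    similar across tones; the defaults are the lateral-field values.
    """

    name: str = "LF"
    frequencies_hz: tuple[float, ...] = FREQUENCIES_HZ
    amplitudes_v: tuple[float, ...] = (0.2, 0.08, 0.04, 0.02)
    tia_gain_ohm: float = 1.8e7

    def __post_init__(self) -> None:
        if self.name not in FIELDS:
            raise ValueError(f"unknown field {self.name!r}; expected one of {FIELDS}")
        freqs = np.asarray(self.frequencies_hz, dtype=float)
        if len(freqs) != len(self.amplitudes_v):
            raise ValueError("frequencies and amplitudes must align")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(np.asarray(self.amplitudes_v) <= 0):
            raise ValueError("amplitudes must be positive")
        if self.tia_gain_ohm <= 0:
            raise ValueError("TIA gain must be positive")


#: Default stimulation amplitudes per field (V), lowest to highest frequency.
DEFAULT_AMPLITUDES_V: dict[str, tuple[float, ...]] = {
    "LF": (0.2, 0.08, 0.04, 0.02),
    "VF": (0.25, 0.1, 0.04, 0.025),
    "EF": (0.2, 0.08, 0.04, 0.02),  # shares the LF stimulation pattern
}


def default_field_config(name: str) -> FieldConfig:
    """The published stimulation settings for field ``name``."""
    return FieldConfig(name=name, amplitudes_v=DEFAULT_AMPLITUDES_V[name])


@dataclass
class ParameterMapStack:
    """The 27 labeled 64x64 parameter maps of one well at one scan time."""

    well_id: str
    scan_time_h: float
    maps: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key in MAP_KEYS:
            if key not in self.maps:
                raise PlateFormatError(
                    f"stack for well {self.well_id} is missing map {map_key_str(key)}"
                )
        extra = set(self.maps) - set(MAP_KEYS)
        if extra:
            raise PlateFormatError(f"unexpected map keys {sorted(extra)}")
        for key, arr in self.maps.items():
            if np.shape(arr) != GRID_SHAPE:
                raise PlateFormatError(
                    f"map {map_key_str(key)} of well {self.well_id} has shape "
                    f"{np.shape(arr)}, expected {GRID_SHAPE}"
                )

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        return self.maps[key]

    def to_array(self) -> np.ndarray:
        """Stack the maps into a ``(27, 64, 64)`` array in canonical key order."""
        return np.stack([np.asarray(self.maps[k]) for k in MAP_KEYS])

    @classmethod
    def from_array(
        cls, well_id: str, scan_time_h: float, arr: np.ndarray
    ) -> "ParameterMapStack":
        arr = np.asarray(arr)
        if arr.shape != (len(MAP_KEYS),) + GRID_SHAPE:
            raise PlateFormatError(
                f"expected array of shape {(len(MAP_KEYS),) + GRID_SHAPE}, got {arr.shape}"
            )
        return cls(well_id, scan_time_h, {k: arr[i] for i, k in enumerate(MAP_KEYS)})


@dataclass
class WellMask:
    """Cell and epoxy masks for one well, tied to their reference calibration."""

    cell_mask: np.ndarray
    epoxy_mask: np.ndarray
    reference_map: np.ndarray | None = None
    threshold_rel: float = 0.2

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.epoxy_mask = np.asarray(self.epoxy_mask, dtype=bool)
        if self.cell_mask.shape != self.epoxy_mask.shape:
            raise ValueError("cell and epoxy masks must share a shape")
        if np.any(self.cell_mask & self.epoxy_mask):
            raise ValueError("epoxy pixels can never be cell pixels")


@dataclass
class WellTimeSeries:
    """Per-well scalar traces sampled on the scan grid.

    ``values`` maps a parameter name (e.g. ``"confluence"``, ``"VF:mag@4000"``,
    ``"rms"``) to a 1-D array.  A trace shorter than ``times_h`` is aligned to
    the *end* of the time axis (the normalized-RMS trace needs a prior frame,
    so it starts ``lag`` scans late).
    """

    well_id: str
    times_h: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.times_h.ndim != 1:
            raise ValueError("times_h must be 1-D")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.ndim != 1 or len(v) > len(self.times_h):
                raise ValueError(f"trace {name!r} does not fit the time axis")
            self.values[name] = v

    def param_times(self, name: str) -> np.ndarray:
        """Time axis of one trace (end-aligned for lagged traces)."""
        n = len(self.values[name])
        return self.times_h[len(self.times_h) - n :]


@dataclass
class WellAnnotation:
    cell_type: str = ""
    density: float = 0.0
    compound: str = ""
    concentration_um: float = 0.0
    role: str = "test"
    exclusion_reason: str = ""

    ROLES = ("negative_control", "positive_control", "test", "excluded")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        if self.role == "excluded" and not self.exclusion_reason:
            raise ValueError("excluded wells must carry an exclusion reason")


@dataclass
class PlateMetadata:
    """Plate map: what was seeded and dosed in each of the 96 wells."""

    plate_id: str
    wells: dict[str, WellAnnotation] = field(default_factory=dict)
    compound_addition_time_h: float | None = None

    def __post_init__(self) -> None:
        for wid in self.wells:
            well_id_to_rc(wid)  # validates

    def excluded_wells(self) -> dict[str, str]:
        return {
            w: a.exclusion_reason for w, a in self.wells.items() if a.role == "excluded"
        }

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, a in self.wells.items() if a.role == role]

    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "compound_addition_time_h": self.compound_addition_time_h,
            "wells": {
                w: {
                    "cell_type": a.cell_type,
                    "density": a.density,
                    "compound": a.compound,
                    "concentration_um": a.concentration_um,
                    "role": a.role,
                    "exclusion_reason": a.exclusion_reason,
                }
                for w, a in self.wells.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlateMetadata":
        return cls(
            plate_id=d["plate_id"],
            compound_addition_time_h=d.get("compound_addition_time_h"),
            wells={w: WellAnnotation(**a) for w, a in d.get("wells", {}).items()},
        )


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------
#
# Layout of <plate>.h5:
#   /scans/s<k>/<well_id>     (27, 64, 64) dataset, attrs: time_h
#   /scans/s<k>               attrs: time_h
#   root attrs: map_keys (canonical "FIELD:param" order), format_version
# Metadata sidecar: <plate>.json (PlateMetadata.to_dict()).


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_plate(
    meta: PlateMetadata,
    scans: Sequence[Iterable[ParameterMapStack]],
    path: str | Path,
    *,
    overwrite: bool = False,
) -> Path:
    """Write a plate container (HDF5 + JSON sidecar).

    ``scans`` is a sequence of scans, each an iterable of stacks sharing one
    scan time.  Refuses to clobber an existing container unless ``overwrite``.
    """
    import h5py

    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = 1
        h5.attrs["map_keys"] = [map_key_str(k) for k in MAP_KEYS]
        grp = h5.create_group("scans")
        for k, scan in enumerate(scans):
            sg = grp.create_group(f"s{k:04d}")
            t = None
            for stack in scan:
                stack.validate()
                if t is None:
                    t = stack.scan_time_h
                    sg.attrs["time_h"] = t
                ds = sg.create_dataset(
                    stack.well_id, data=stack.to_array(), chunks=(1,) + GRID_SHAPE
                )
                ds.attrs["time_h"] = stack.scan_time_h
    _sidecar(path).write_text(json.dumps(meta.to_dict(), indent=1, sort_keys=True))
    return path


class PlateWriter:
    """Incremental plate-container writer (one well's scans at a time).

    Streams stacks straight to HDF5 so a full-scale plate never has to fit
    in memory; produces the same layout as :func:`write_plate`.

    >>> with PlateWriter(meta, path) as pw:
    ...     for well in wells:
    ...         for k, stack in enumerate(stacks_of(well)):
    ...             pw.add(k, stack)
    """

    def __init__(self, meta: PlateMetadata, path: str | Path, *, overwrite: bool = False):
        import h5py

        self.path = Path(path)
        if self.path.exists() and not overwrite:
            raise FileExistsError(f"{self.path} exists; pass overwrite=True")
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._h5 = h5py.File(self.path, "w")
        self._h5.attrs["format_version"] = 1
        self._h5.attrs["map_keys"] = [map_key_str(k) for k in MAP_KEYS]
        self._scans = self._h5.create_group("scans")
        _sidecar(self.path).write_text(
            json.dumps(meta.to_dict(), indent=1, sort_keys=True)
        )

    def add(self, scan_index: int, stack: ParameterMapStack) -> None:
        stack.validate()
        name = f"s{scan_index:04d}"
        sg = self._scans.require_group(name)
        if "time_h" not in sg.attrs:
            sg.attrs["time_h"] = stack.scan_time_h
        ds = sg.create_dataset(
            stack.well_id, data=stack.to_array(), chunks=(1,) + GRID_SHAPE
        )
        ds.attrs["time_h"] = stack.scan_time_h

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "PlateWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_plate(
    path: str | Path, wells: Sequence[str] | None = None
) -> tuple[PlateMetadata, list[list[ParameterMapStack]]]:
    """Read a plate container; scans are returned sorted by time.

    ``wells`` restricts reading to a subset of well IDs.
    """
    import h5py

    path = Path(path)
    meta = PlateMetadata.from_dict(json.loads(_sidecar(path).read_text()))
    scans: list[tuple[float, list[ParameterMapStack]]] = []
    with h5py.File(path, "r") as h5:
        stored = [parse_map_key(s) for s in h5.attrs["map_keys"]]
        if tuple(stored) != MAP_KEYS:
            raise PlateFormatError("container map-key vocabulary does not match")
        for name in sorted(h5["scans"]):
            sg = h5["scans"][name]
            stacks = []
            t = float(sg.attrs.get("time_h", np.nan))
            for wid in sorted(sg, key=well_id_to_rc):
                if wells is not None and wid not in wells:
                    continue
                ds = sg[wid]
                stacks.append(
                    ParameterMapStack.from_array(
                        wid, float(ds.attrs.get("time_h", t)), ds[()]
                    )
                )
            scans.append((t, stacks))
    scans.sort(key=lambda ts: ts[0])
    return meta, [s for _, s in scans]


def export_timeseries(
    series: Iterable[WellTimeSeries], path: str | Path
) -> Path:
    """Write well time series as a long-format CSV (well, parameter, time_h, value)."""
    rows: list[tuple[str, str, float, float]] = []
    vocab: set[frozenset] = set()
    series = list(series)
    for ts in series:
        vocab.add(frozenset(ts.values))
        for name, vals in ts.values.items():
            t = ts.param_times(name)
            rows.extend(zip([ts.well_id] * len(vals), [name] * len(vals), t, vals))
    if len(vocab) > 1:
        raise ValueError("inconsistent parameter sets across wells")
    df = pd.DataFrame(rows, columns=["well", "parameter", "time_h", "value"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_timeseries(path: str | Path) -> list[WellTimeSeries]:
    """Parse a long-format time-series CSV back into :class:`WellTimeSeries`."""
    df = pd.read_csv(path)
    out = []
    for wid, wdf in df.groupby("well", sort=True):
        times = np.array(sorted(wdf["time_h"].unique()))
        values = {}
        for name, pdf in wdf.groupby("parameter"):
            pdf = pdf.sort_values("time_h")
            values[name] = pdf["value"].to_numpy()
        out.append(WellTimeSeries(str(wid), times, values))
    return out


def read_platemap_csv(
    path: str | Path,
    plate_id: str = "plate",
    compound_addition_time_h: float | None = None,
) -> PlateMetadata:
    """Read a plate-map CSV with columns well,cell_type,density,compound,concentration_um,role."""
    df = pd.read_csv(path, dtype={"well": str}).fillna("")
    wells = {}
    for _, r in df.iterrows():
        wells[r["well"]] = WellAnnotation(
            cell_type=str(r.get("cell_type", "")),
            density=float(r.get("density") or 0.0),
            compound=str(r.get("compound", "")),
            concentration_um=float(r.get("concentration_um") or 0.0),
            role=str(r.get("role") or "test"),
            exclusion_reason=str(r.get("exclusion_reason", "")),
        )
    return PlateMetadata(plate_id, wells, compound_addition_time_h)
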