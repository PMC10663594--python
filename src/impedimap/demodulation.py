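"""Multi-tone stimulation, scan scheduling and FFT demodulation.

Each electrode is driven with the sum of four sine tones (250 Hz, 1 kHz,
4 kHz, 16 kHz) and the return current, converted to a voltage by a
transimpedance amplifier (TIA) with an 18 MOhm feedback resistor, is
demodulated by an FFT into four magnitudes, four phases and a DC component.
The acquisition window is one 4 ms period of the lowest tone so that every
tone lands exactly on an FFT bin and there is no spectral leakage.

Magnitudes are reported as peak sinusoid amplitudes (a pure ``A*sin`` tone
demodulates to magnitude ``A``); phases are sine-referenced and reported in
``(-pi, pi]``, with NaN where the bin magnitude is numerically zero.

Scan scheduling covers the 64x64 grid in steps of 16 simultaneously recorded
electrodes:

* vertical field (VF): a 16x16 block of electrodes is biased together and
  the 4x4 group at its center is recorded; the block slides in steps of 4 so
  that each of the 256 readout tiles sits at the center of a full 16x16 bias
  window (clamped inside the array near the edges);
* lateral field (LF) and electrode-impedance field (EF): 16 electrodes on a
  4x4 super-grid with 16-electrode stride are recorded per step, keeping
  simultaneously recorded electrodes at least 12 electrodes apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plate_model import (
    GRID_SHAPE,
    MAP_KEYS,
    ElectrodeArray,
    FieldConfig,
    ParameterMapStack,
)

__all__ = [
    "MIN_WINDOW_S",
    "DEFAULT_SAMPLE_RATE_HZ",
    "StimulusWaveform",
    "ScanStep",
    "ScanSchedule",
    "DemodResult",
    "build_stimulus",
    "demodulate_trace",
    "schedule_scan",
    "assemble_maps",
    "current_to_impedance",
]

#: One full period of the lowest tone (250 Hz).
MIN_WINDOW_S = 4e-3
#: Default synthetic sampling rate; >=60x the highest tone.
DEFAULT_SAMPLE_RATE_HZ = 1_000_000.0

VF_BLOCK = 16  # biased block edge (electrodes)
VF_READOUT = 4  # recorded center-group edge
LF_STRIDE = 16  # super-grid stride between simultaneously recorded electrodes
LF_MIN_SPACING = 12  # published lower bound on simultaneous-readout spacing


class InsufficientWindowError(ValueError):
    """Acquisition window shorter than one period of the lowest tone."""


class FrequencyResolutionError(ValueError):
    """A target tone does not land on an FFT bin of the given window."""


@dataclass(frozen=True)
class StimulusWaveform:
    """A sampled multi-tone stimulation waveform."""

    sample_rate_hz: float
    duration_s: float
    samples: np.ndarray
    frequencies_hz: tuple[float, ...]
    amplitudes_v: tuple[float, ...]


@dataclass(frozen=True)
class ScanStep:
    """One scheduling step: which electrodes are biased and which are recorded."""

    biased: frozenset[tuple[int, int]]
    recorded: frozenset[tuple[int, int]]


@dataclass(frozen=True)
class ScanSchedule:
    field: str
    steps: tuple[ScanStep, ...]

    def recorded_union(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for s in self.steps:
            out |= s.recorded
        return out


@dataclass(frozen=True)
class DemodResult:
    """Demodulation output for one electrode trace.

    ``magnitudes`` are peak amplitudes per tone; ``phases`` are
    sine-referenced in ``(-pi, pi]`` and NaN where the magnitude is zero.
    """

    frequencies_hz: tuple[float, ...]
    magnitudes: np.ndarray
    phases: np.ndarray
    dc: float

    def phase_defined(self) -> np.ndarray:
        return ~np.isnan(self.phases)


def build_stimulus(
    config: FieldConfig,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    duration_s: float = MIN_WINDOW_S,
    phases: tuple[float, ...] | None = None,
) -> StimulusWaveform:
    """Synthesize the four-tone stimulation waveform for one field config.

    The waveform is ``sum_f A_f * sin(2 pi f t + phi_f)`` sampled at
    ``sample_rate_hz`` over ``duration_s``; default phases are zero.
    """
    if duration_s < MIN_WINDOW_S - 1e-12:
        raise InsufficientWindowError(
            f"duration {duration_s} s is shorter than one 250 Hz period ({MIN_WINDOW_S} s)"
        )
    if sample_rate_hz < 2 * max(config.frequencies_hz):
        raise ValueError("sample rate below Nyquist for the highest tone")
    phi = np.zeros(len(config.frequencies_hz)) if phases is None else np.asarray(phases)
    n = int(round(sample_rate_hz * duration_s))
    t = np.arange(n) / sample_rate_hz
    samples = np.zeros(n)
    for f, a, p in zip(config.frequencies_hz, config.amplitudes_v, phi):
        samples += a * np.sin(2 * np.pi * f * t + p)
    return StimulusWaveform(
        sample_rate_hz=sample_rate_hz,
        duration_s=n / sample_rate_hz,
        samples=samples,
        frequencies_hz=tuple(config.frequencies_hz),
        amplitudes_v=tuple(config.amplitudes_v),
    )


def demodulate_trace(
    trace: np.ndarray,
    sample_rate_hz: float,
    frequencies_hz: tuple[float, ...] = (250.0, 1000.0, 4000.0, 16000.0),
    *,
    zero_tol: float = 1e-12,
) -> DemodResult:
    """Extract per-tone magnitude/phase and the DC component of one trace.

    The trace must span an integer number of periods of every target tone so
    that each tone is bin-aligned; otherwise a
    :class:`FrequencyResolutionError` is raised.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n == 0:
        raise ValueError("empty trace")
    spectrum = np.fft.rfft(trace)
    scale = np.max(np.abs(trace)) if n else 0.0
    mags = np.empty(len(frequencies_hz))
    phases = np.empty(len(frequencies_hz))
    for i, f in enumerate(frequencies_hz):
        k = f * n / sample_rate_hz
        ki = int(round(k))
        if abs(k - ki) > 1e-6 or ki <= 0 or ki > n // 2:
            raise FrequencyResolutionError(
                f"{f} Hz is not resolvable on a {n}-sample window at {sample_rate_hz} Hz"
            )
        coeff = spectrum[ki] * 2.0 / n
        mags[i] = np.abs(coeff)
        if mags[i] <= zero_tol * max(scale, 1.0):
            mags[i] = abs(mags[i])
            phases[i] = np.nan
        else:
            # rfft phase is cosine-referenced; shift by +pi/2 for sine reference
            ph = np.angle(coeff) + np.pi / 2
            phases[i] = (ph + np.pi) % (2 * np.pi) - np.pi
            if phases[i] == -np.pi:
                phases[i] = np.pi
    dc = float(spectrum[0].real / n)
    return DemodResult(tuple(frequencies_hz), mags, phases, dc)


# ---------------------------------------------------------------------------
# Scan scheduling
# ---------------------------------------------------------------------------


def _vf_schedule(array: ElectrodeArray) -> tuple[ScanStep, ...]:
    if array.n_rows % VF_READOUT or array.n_cols % VF_READOUT:
        raise ValueError("array dimensions must be divisible by the 4x4 readout group")
    if array.n_rows < VF_BLOCK or array.n_cols < VF_BLOCK:
        raise ValueError("array smaller than one 16x16 bias block")
    steps = []
    margin = (VF_BLOCK - VF_READOUT) // 2
    for r0 in range(0, array.n_rows, VF_READOUT):
        for c0 in range(0, array.n_cols, VF_READOUT):
            br = min(max(r0 - margin, 0), array.n_rows - VF_BLOCK)
            bc = min(max(c0 - margin, 0), array.n_cols - VF_BLOCK)
            biased = frozenset(
                (r, c)
                for r in range(br, br + VF_BLOCK)
                for c in range(bc, bc + VF_BLOCK)
            )
            recorded = frozenset(
                (r, c)
                for r in range(r0, r0 + VF_READOUT)
                for c in range(c0, c0 + VF_READOUT)
            )
            steps.append(ScanStep(biased=biased, recorded=recorded))
    return tuple(steps)


def _lf_schedule(array: ElectrodeArray, record_active: bool) -> tuple[ScanStep, ...]:
    if array.n_rows % LF_STRIDE or array.n_cols % LF_STRIDE:
        raise ValueError("array dimensions must be divisible by the 16-electrode stride")
    steps = []
    for r0 in range(LF_STRIDE):
        for c0 in range(LF_STRIDE):
            active = frozenset(
                (r, c)
                for r in range(r0, array.n_rows, LF_STRIDE)
                for c in range(c0, array.n_cols, LF_STRIDE)
            )
            if record_active:
                recorded = active  # EF measures current through the active electrode
            else:
                # LF reads the nearest-neighbor electrode of each active one;
                # coverage bookkeeping is kept on the active coordinates, the
                # cross-electrode transfer itself is supplied by the simulator.
                recorded = active
            steps.append(ScanStep(biased=active, recorded=recorded))
    return tuple(steps)


def schedule_scan(field: str, array: ElectrodeArray | None = None) -> ScanSchedule:
    """Build the step schedule covering every electrode exactly once.

    VF records the 4x4 center of a sliding 16x16 bias block; LF/EF record 16
    electrodes per step on a 16-stride super-grid (pairwise spacing 16 >= 12).
    """
    array = array or ElectrodeArray()
    if field == "VF":
        steps = _vf_schedule(array)
    elif field in ("LF", "EF"):
        steps = _lf_schedule(array, record_active=(field == "EF"))
    else:
        raise ValueError(f"unknown field {field!r}")
    return ScanSchedule(field=field, steps=steps)


def min_recorded_spacing(schedule: ScanSchedule) -> float:
    """Minimum pairwise Euclidean grid distance among electrodes recorded
    simultaneously in any step of the schedule."""
    best = np.inf
    for step in schedule.steps:
        pts = np.array(sorted(step.recorded), dtype=float)
        if len(pts) < 2:
            continue
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        iu = np.triu_indices(len(pts), k=1)
        best = min(best, float(np.sqrt(d2[iu].min())))
    return best


# ---------------------------------------------------------------------------
# Map assembly and impedance conversion
# ---------------------------------------------------------------------------


class MapCompletenessError(ValueError):
    """Raised when electrodes are missing from a demodulated field."""


def assemble_maps(
    results: dict[str, dict[tuple[int, int], DemodResult]],
    array: ElectrodeArray | None = None,
    *,
    well_id: str = "A1",
    scan_time_h: float = 0.0,
) -> ParameterMapStack:
    """Place per-electrode demodulation results into the 27-map stack.

    ``results`` maps field name -> {(row, col): DemodResult} with one entry
    per electrode per field.  Placement is by coordinate, so input order is
    irrelevant.
    """
    array = array or ElectrodeArray()
    shape = (array.n_rows, array.n_cols)
    if shape != GRID_SHAPE:
        raise ValueError("assemble_maps expects the 64x64 array")
    maps: dict[tuple[str, str], np.ndarray] = {}
    for fld, per_elec in results.items():
        missing = [
            (r, c)
            for r in range(array.n_rows)
            for c in range(array.n_cols)
            if (r, c) not in per_elec
        ]
        if missing:
            head = ", ".join(map(str, missing[:5]))
            raise MapCompletenessError(
                f"field {fld}: {len(missing)} electrodes missing (first: {head})"
            )
        some = next(iter(per_elec.values()))
        freqs = some.frequencies_hz
        mag = np.zeros((len(freqs),) + shape)
        ph = np.zeros((len(freqs),) + shape)
        dc = np.zeros(shape)
        for (r, c), res in per_elec.items():
            mag[:, r, c] = res.magnitudes
            ph[:, r, c] = res.phases
            dc[r, c] = res.dc
        for i, f in enumerate(freqs):
            maps[(fld, f"mag@{int(f)}")] = mag[i]
            maps[(fld, f"phase@{int(f)}")] = ph[i]
        maps[(fld, "DC")] = dc
    for key in MAP_KEYS:
        if key not in maps:
            raise MapCompletenessError(f"no results supplied for map {key}")
    return ParameterMapStack(well_id=well_id, scan_time_h=scan_time_h, maps=maps)


def current_to_impedance(
    tia_output_v: np.ndarray | float,
    stimulus_amplitude_v: float,
    tia_gain_ohm: float = 1.8e7,
) -> np.ndarray | float:
    """Convert a TIA output amplitude back to an impedance magnitude.

    ``I = V_out / R2`` and ``|Z| = V_stim / I = V_stim * R2 / V_out``.  A zero
    TIA output means no measurable current and maps to ``inf`` (open circuit)
    rather than raising.
    """
    if stimulus_amplitude_v <= 0 or tia_gain_ohm <= 0:
        raise ValueError("stimulus amplitude and TIA gain must be positive")
    v = np.asarray(tia_output_v, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.where(v > 0, stimulus_amplitude_v * tia_gain_ohm / np.where(v > 0, v, 1.0), np.inf)
    if np.isscalar(tia_output_v) or np.ndim(tia_output_v) == 0:
        return float(z)
    return z
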