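"""Synthetic plate generator with known ground truth.

Stands in for the instrument: every well carries a latent cell-biology state
(per-pixel occupancy and type, plus well-level barrier, attachment, flatness
and motility trajectories) that is rendered into the 27 parameter maps per
scan, optionally all the way down to raw per-electrode TIA traces.  Every
stochastic choice flows from one seed, so a dataset is exactly reproducible
and every downstream statistic can be checked against the latent truth.

The latent model, per well:

* occupancy grows by seeded neighborhood colonization whose expected pixel
  count follows coupled logistic growth (two populations share one carrying
  capacity, so a faster-growing co-culture partner takes the well over);
* barrier rises after a confluence threshold (tight-junction formation),
  attachment rises with a saturating time constant and can collapse after a
  water-transport peak, flatness spikes shortly after plating as suspended
  cells settle and spread, and motility sets the amplitude of frame-to-frame
  pixel jitter;
* doming events arrive as a Poisson process after the attachment peak and
  stamp transient disc depressions (~150 um across) on the attachment map;
* compound kernels multiply the latent drivers after an onset delay; DMSO is
  the identity kernel;
* maps are the per-pixel electrode baseline (drawn once per well) times the
  latent contrast, times multiplicative lognormal measurement noise.

Latent-to-map routing: barrier -> VF 250 Hz magnitude, attachment -> LF
16 kHz, flatness -> VF 16 kHz, cell-mask contrast -> VF 4 kHz; the remaining
maps carry plain occupancy contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .plate_model import (
    FIELDS,
    FREQUENCIES_HZ,
    GRID_SHAPE,
    MAP_KEYS,
    FieldConfig,
    ParameterMapStack,
    PlateMetadata,
    WellAnnotation,
    rc_to_well_id,
)

__all__ = [
    "CellTypeArchetype",
    "CompoundEffect",
    "SimulationConfig",
    "SimulatedWell",
    "ARCHETYPES",
    "COMPOUND_LIBRARY",
    "simulate_well",
    "simulate_coculture",
    "simulate_plate",
    "iter_simulated_wells",
    "simulate_raw_scan",
    "simulate_profiles",
    "default_screen_platemap",
]

N_PIXELS = GRID_SHAPE[0] * GRID_SHAPE[1]

#: Seeding density (cells/well) that corresponds to plating at full coverage.
CONFLUENT_DENSITY = 40_000.0


# ---------------------------------------------------------------------------
# Archetypes and compounds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellTypeArchetype:
    """Latent-parameter bundle describing one cell type's behavior.

    Rates are per hour, amplitudes are unitless map contrasts relative to the
    cell-free electrode baseline.
    """

    name: str
    growth_rate: float = 0.15
    motility_amplitude: float = 0.05
    barrier_onset_confluence: float = 0.9  # fraction of coverage
    barrier_rise_rate: float = 0.3
    barrier_amplitude: float = 0.0
    attachment_amplitude: float = 1.0
    attachment_rise_tau_h: float = 4.0
    water_transport_peak_h: float | None = None
    water_transport_decay: float = 0.15
    flatness_spike_amplitude: float = 0.8
    flatness_spike_tau_h: float = 2.0
    flatness_steady: float = 0.4
    doming_rate_per_h: float = 0.0
    dome_diameter_px: tuple[float, float] = (4.0, 8.0)
    dome_depth: float = 0.5
    suspension: bool = False

    def __post_init__(self) -> None:
        for f in ("growth_rate", "motility_amplitude", "barrier_rise_rate",
                  "barrier_amplitude", "attachment_amplitude", "doming_rate_per_h"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.suspension and (self.barrier_amplitude > 0 or self.attachment_amplitude > 0.2):
            raise ValueError("suspension cells form no barrier and barely attach")


#: Archetype presets loosely emulating well-characterized cell types.
ARCHETYPES: dict[str, CellTypeArchetype] = {
    # strong epithelial barrier former with water transport and doming
    "MDCK-like": CellTypeArchetype(
        name="MDCK-like",
        growth_rate=0.2,
        motility_amplitude=0.05,
        barrier_amplitude=2.0,
        barrier_onset_confluence=0.85,
        barrier_rise_rate=0.25,
        attachment_amplitude=1.5,
        water_transport_peak_h=30.0,
        water_transport_decay=0.12,
        doming_rate_per_h=0.5,
    ),
    # weakly adherent alveolar epithelial line, little barrier
    "A549-like": CellTypeArchetype(
        name="A549-like",
        growth_rate=0.12,
        motility_amplitude=0.12,
        barrier_amplitude=0.2,
        attachment_amplitude=1.0,
    ),
    # epithelial breast line, low motility
    "MCF7-like": CellTypeArchetype(
        name="MCF7-like",
        growth_rate=0.08,
        motility_amplitude=0.06,
        barrier_amplitude=0.8,
        attachment_amplitude=1.2,
    ),
    # mesenchymal breast line, high motility, faster growth, no barrier
    "MDA-MB-231-like": CellTypeArchetype(
        name="MDA-MB-231-like",
        growth_rate=0.14,
        motility_amplitude=0.3,
        barrier_amplitude=0.0,
        attachment_amplitude=0.8,
        flatness_steady=0.2,
    ),
    "suspension": CellTypeArchetype(
        name="suspension",
        growth_rate=0.1,
        motility_amplitude=0.15,
        barrier_amplitude=0.0,
        attachment_amplitude=0.1,
        flatness_spike_amplitude=0.0,
        flatness_steady=0.05,
        suspension=True,
    ),
}


@dataclass(frozen=True)
class CompoundEffect:
    """Multiplicative response kernels on the latent drivers.

    ``kernels`` maps a target in {barrier, attachment, flatness, motility,
    viability} to ``(direction, magnitude, rate_per_h)``; the latent driver is
    multiplied by ``1 + direction * magnitude * (1 - exp(-rate * dt))`` where
    ``dt`` is the time since compound addition plus onset delay.  DMSO keeps
    every kernel at identity.
    """

    name: str
    onset_delay_h: float = 0.0
    kernels: dict[str, tuple[int, float, float]] = field(default_factory=dict)

    def multiplier(self, target: str, t_h: np.ndarray | float, t_add_h: float) -> np.ndarray:
        t_h = np.asarray(t_h, dtype=float)
        if target not in self.kernels:
            return np.ones_like(t_h)
        direction, mag, rate = self.kernels[target]
        dt = np.clip(t_h - t_add_h - self.onset_delay_h, 0.0, None)
        m = 1.0 + direction * mag * (1.0 - np.exp(-rate * dt))
        return np.clip(m, 0.0, None)


#: DMSO vehicle plus five positive-control kernels with orthogonal signatures.
COMPOUND_LIBRARY: dict[str, CompoundEffect] = {
    "DMSO": CompoundEffect(name="DMSO"),
    # rapid, drastic loss of barrier, attachment and movement (kinase-inhibitor-like)
    "barrier-breaker": CompoundEffect(
        name="barrier-breaker",
        kernels={"barrier": (-1, 0.9, 1.0), "attachment": (-1, 0.6, 1.0),
                 "motility": (-1, 0.5, 1.0)},
    ),
    # cytotoxic: confluence loss with detachment (DNA-damage-like)
    "cytotoxic": CompoundEffect(
        name="cytotoxic",
        onset_delay_h=4.0,
        kernels={"viability": (-1, 0.7, 0.15), "attachment": (-1, 0.8, 0.2)},
    ),
    # cytoskeletal: flatter, static cells (microtubule-stabilizer-like)
    "cytoskeletal": CompoundEffect(
        name="cytoskeletal",
        kernels={"flatness": (1, 0.9, 0.5), "motility": (-1, 0.7, 0.5)},
    ),
    # motogenic: scattering, increased movement, mild barrier loss
    "motogenic": CompoundEffect(
        name="motogenic",
        kernels={"motility": (1, 1.5, 0.4), "barrier": (-1, 0.3, 0.3)},
    ),
    # growth arrest: stalls proliferation without detachment
    "growth-arrest": CompoundEffect(
        name="growth-arrest",
        onset_delay_h=2.0,
        kernels={"viability": (-1, 0.25, 0.08), "flatness": (-1, 0.4, 0.2),
                 "motility": (-1, 0.3, 0.2)},
    ),
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Global knobs of the synthetic plate.

    ``noise_sd`` is the per-pixel multiplicative lognormal measurement noise
    of every magnitude map; ``baseline_sd`` the electrode-to-electrode relief
    drawn once per well; ``trace_noise_v`` the additive noise of raw traces.
    ``noiseless()`` switches all three off (latent motility jitter is signal,
    not noise, and stays on).
    """

    seed: int = 0
    scan_interval_h: float = 0.25
    duration_h: float = 48.0
    noise_sd: float = 0.05
    baseline_sd: float = 0.1
    trace_noise_v: float = 0.0
    sample_rate_hz: float = 1_000_000.0
    window_s: float = 4e-3
    epoxy_center: tuple[int, int] | None = (3, 3)
    epoxy_radius_px: float = 3.0
    growth_substep_h: float = 0.05

    def noiseless(self) -> "SimulationConfig":
        return replace(self, noise_sd=0.0, baseline_sd=0.0, trace_noise_v=0.0)

    def scan_times(self) -> np.ndarray:
        n = int(np.floor(self.duration_h / self.scan_interval_h)) + 1
        return np.arange(n) * self.scan_interval_h


#: Per-map cell-free baseline level (arbitrary impedance-proportional units).
BASE_LEVELS: dict[tuple[str, str], float] = {}
for _fld in FIELDS:
    for _i, _f in enumerate(FREQUENCIES_HZ):
        BASE_LEVELS[(_fld, f"mag@{int(_f)}")] = 1.0 / (1.0 + 0.5 * _i)
        BASE_LEVELS[(_fld, f"phase@{int(_f)}")] = 0.4 / (1.0 + _i)
    BASE_LEVELS[(_fld, "DC")] = 0.02

#: Plain occupancy contrast of maps not driven by a dedicated latent.
GENERIC_OCCUPANCY_CONTRAST = 0.3
#: Occupancy contrast of the VF 4 kHz cell-mask source.
MASK_CONTRAST = 1.0


@dataclass
class SimulatedWell:
    """One simulated well: rendered stacks plus the latent ground truth."""

    well_id: str
    times_h: np.ndarray
    stacks: list[ParameterMapStack]
    reference: ParameterMapStack
    epoxy_mask: np.ndarray
    occupancy_fraction: dict[str, np.ndarray]  # per archetype, of non-epoxy pixels
    latents: dict[str, dict[str, np.ndarray]]  # archetype -> driver -> trace
    dome_log: list[dict]
    occupancy_maps: list[np.ndarray] | None = None

    @property
    def total_occupancy(self) -> np.ndarray:
        return np.sum(list(self.occupancy_fraction.values()), axis=0)


# ---------------------------------------------------------------------------
# Latent dynamics
# ---------------------------------------------------------------------------


def _epoxy_mask(cfg: SimulationConfig) -> np.ndarray:
    mask = np.zeros(GRID_SHAPE, dtype=bool)
    if cfg.epoxy_center is not None and cfg.epoxy_radius_px > 0:
        rr, cc = np.ogrid[: GRID_SHAPE[0], : GRID_SHAPE[1]]
        r0, c0 = cfg.epoxy_center
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= cfg.epoxy_radius_px**2
    return mask


def _coupled_logistic(
    rates: Sequence[float],
    init_fractions: Sequence[float],
    times_h: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Expected occupancy fractions of competing populations sharing one
    carrying capacity; Euler integration on a fine internal grid."""
    n = np.array(init_fractions, dtype=float)
    rates = np.asarray(rates, dtype=float)
    out = np.empty((len(times_h), len(n)))
    t = 0.0
    ti = 0
    t_end = float(times_h[-1])
    while ti < len(times_h):
        while ti < len(times_h) and times_h[ti] <= t + 1e-9:
            out[ti] = n
            ti += 1
        if ti >= len(times_h):
            break
        step = min(dt, t_end - t)
        if step <= 0:
            out[ti:] = n
            break
        total = n.sum()
        n = n + step * rates * n * max(1.0 - total, 0.0)
        t += step
    return out


def _latent_traces(
    arch: CellTypeArchetype,
    times_h: np.ndarray,
    confluence_fraction: np.ndarray,
    compound: CompoundEffect | None,
    t_compound_h: float | None,
) -> dict[str, np.ndarray]:
    """Well-level latent driver trajectories for one archetype."""
    t = np.asarray(times_h, dtype=float)

    def kernel(target: str) -> np.ndarray:
        if compound is None or t_compound_h is None:
            return np.ones_like(t)
        return compound.multiplier(target, t, t_compound_h)

    attach = arch.attachment_amplitude * (1.0 - np.exp(-t / arch.attachment_rise_tau_h))
    if arch.water_transport_peak_h is not None:
        decay = np.exp(
            -arch.water_transport_decay * np.clip(t - arch.water_transport_peak_h, 0, None)
        )
        attach = attach * decay
    attach = attach * kernel("attachment")

    barrier = np.zeros_like(t)
    if arch.barrier_amplitude > 0:
        above = confluence_fraction >= arch.barrier_onset_confluence
        if above.any():
            t_on = t[np.argmax(above)]
            rise = 1.0 - np.exp(-arch.barrier_rise_rate * np.clip(t - t_on, 0, None))
            barrier = arch.barrier_amplitude * np.where(t >= t_on, rise, 0.0)
    barrier = barrier * kernel("barrier")

    spike = arch.flatness_spike_amplitude * (t / arch.flatness_spike_tau_h) * np.exp(
        1.0 - t / arch.flatness_spike_tau_h
    )
    flat = (spike + arch.flatness_steady * (1.0 - np.exp(-t / 8.0))) * kernel("flatness")

    motility = arch.motility_amplitude * kernel("motility")

    return {
        "attachment": attach,
        "barrier": barrier,
        "flatness": flat,
        "motility": motility,
        "viability": kernel("viability"),
    }


def _colonize(
    occupied: np.ndarray,
    type_map: np.ndarray,
    type_idx: int,
    n_add: int,
    allowed: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Add ``n_add`` pixels of one type adjacent to its existing pixels."""
    struct = np.ones((3, 3), dtype=bool)
    while n_add > 0:
        own = type_map == type_idx
        if own.any():
            frontier = ndimage.binary_dilation(own, structure=struct) & ~occupied & allowed
        else:
            frontier = ~occupied & allowed
        coords = np.argwhere(frontier)
        if len(coords) == 0:
            coords = np.argwhere(~occupied & allowed)
            if len(coords) == 0:
                return
        take = min(n_add, len(coords))
        pick = coords[rng.choice(len(coords), size=take, replace=False)]
        occupied[pick[:, 0], pick[:, 1]] = True
        type_map[pick[:, 0], pick[:, 1]] = type_idx
        n_add -= take


def _render_stack(
    well_id: str,
    time_h: float,
    occupied: np.ndarray,
    type_map: np.ndarray,
    latents_now: list[dict[str, float]],
    relief: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
    dome_depression: np.ndarray | None,
) -> ParameterMapStack:
    """Render the 27 maps for one scan from the latent state."""
    # per-pixel latent contrast fields
    def latent_field(driver: str) -> np.ndarray:
        out = np.zeros(GRID_SHAPE)
        for i, lat in enumerate(latents_now):
            sel = occupied & (type_map == i)
            out[sel] = lat[driver]
        return out

    occ = occupied.astype(float)
    barrier = latent_field("barrier")
    attach = latent_field("attachment")
    flat = latent_field("flatness")
    # frame-to-frame motility jitter, per occupied pixel
    jitter = np.zeros(GRID_SHAPE)
    for i, lat in enumerate(latents_now):
        sel = occupied & (type_map == i)
        if lat["motility"] > 0 and sel.any():
            jitter[sel] = lat["motility"] * rng.standard_normal(int(sel.sum()))

    contrast: dict[tuple[str, str], np.ndarray] = {}
    for fld in FIELDS:
        for f in FREQUENCIES_HZ:
            contrast[(fld, f"mag@{int(f)}")] = GENERIC_OCCUPANCY_CONTRAST * occ
    contrast[("VF", "mag@250")] = 0.3 * occ + barrier
    contrast[("VF", "mag@1000")] = 0.4 * occ + 0.5 * barrier
    contrast[("VF", "mag@4000")] = MASK_CONTRAST * occ * (1.0 + jitter)
    contrast[("VF", "mag@16000")] = 0.3 * occ + flat
    lf_attach = (0.3 * occ + attach)
    if dome_depression is not None:
        lf_attach = lf_attach * dome_depression
    contrast[("LF", "mag@16000")] = lf_attach

    maps: dict[tuple[str, str], np.ndarray] = {}
    for key in MAP_KEYS:
        base = BASE_LEVELS[key]
        _, param = key
        if param.startswith("mag@"):
            m = base * relief * (1.0 + np.clip(contrast[key], -0.95, None))
            if noise_sd > 0:
                m = m * rng.lognormal(0.0, noise_sd, size=GRID_SHAPE)
            maps[key] = m
        elif param.startswith("phase@"):
            ph = base + 0.1 * occ
            if noise_sd > 0:
                ph = ph + 0.02 * rng.standard_normal(GRID_SHAPE)
            maps[key] = (ph + np.pi) % (2 * np.pi) - np.pi
        else:  # DC
            d = base * (1.0 + 0.5 * occ)
            if noise_sd > 0:
                d = d + 0.002 * rng.standard_normal(GRID_SHAPE)
            maps[key] = d
    return ParameterMapStack(well_id=well_id, scan_time_h=time_h, maps=maps)


def _reference_stack(
    well_id: str,
    relief: np.ndarray,
    epoxy: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
) -> ParameterMapStack:
    """Cell-free reference scan; epoxy pixels read far above baseline."""
    maps: dict[tuple[str, str], np.ndarray] = {}
    for key in MAP_KEYS:
        base = BASE_LEVELS[key]
        _, param = key
        if param.startswith("mag@"):
            m = base * relief.copy()
            m[epoxy] *= 3.0
            if noise_sd > 0:
                m = m * rng.lognormal(0.0, noise_sd, size=GRID_SHAPE)
            maps[key] = m
        elif param.startswith("phase@"):
            ph = np.full(GRID_SHAPE, base)
            if noise_sd > 0:
                ph = ph + 0.02 * rng.standard_normal(GRID_SHAPE)
            maps[key] = (ph + np.pi) % (2 * np.pi) - np.pi
        else:
            d = np.full(GRID_SHAPE, base)
            if noise_sd > 0:
                d = d + 0.002 * rng.standard_normal(GRID_SHAPE)
            maps[key] = d
    return ParameterMapStack(well_id=well_id, scan_time_h=-1.0, maps=maps)


# ---------------------------------------------------------------------------
# Well / plate simulation
# ---------------------------------------------------------------------------


def simulate_well(
    archetypes: CellTypeArchetype | Sequence[CellTypeArchetype],
    ratios: Sequence[float] | float = 1.0,
    cfg: SimulationConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    well_id: str = "A1",
    density: float = 15_000.0,
    compound: CompoundEffect | None = None,
    t_compound_h: float | None = None,
    scan_times_h: np.ndarray | None = None,
    keep_occupancy: bool = False,
) -> SimulatedWell:
    """Simulate one well end to end.

    ``ratios`` gives the seeding composition across ``archetypes`` and must
    sum to 1.  ``scan_times_h`` overrides the regular scan grid (the latent
    model is continuous in time).  Ground truth — per-type occupancy
    fractions, latent trajectories and the doming event log — is returned
    alongside the rendered stacks and the cell-free reference scan.
    """
    cfg = cfg or SimulationConfig()
    if isinstance(archetypes, CellTypeArchetype):
        archetypes = [archetypes]
    ratios = np.atleast_1d(np.asarray(ratios, dtype=float))
    if len(ratios) != len(archetypes):
        raise ValueError("one ratio per archetype required")
    if np.any(ratios < 0) or abs(ratios.sum() - 1.0) > 1e-9:
        raise ValueError("ratios must be non-negative and sum to 1")
    times = (
        np.asarray(scan_times_h, dtype=float)
        if scan_times_h is not None
        else cfg.scan_times()
    )
    if len(times) < 1:
        raise ValueError("duration must cover at least one scan")
    if np.any(np.diff(times) <= 0):
        raise ValueError("scan times must be strictly increasing")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    epoxy = _epoxy_mask(cfg)
    allowed = ~epoxy
    n_avail = int(allowed.sum())
    relief = (
        rng.lognormal(0.0, cfg.baseline_sd, size=GRID_SHAPE)
        if cfg.baseline_sd > 0
        else np.ones(GRID_SHAPE)
    )

    init_total = min(density / CONFLUENT_DENSITY, 1.0)
    init_fractions = init_total * ratios
    rates = [a.growth_rate for a in archetypes]
    expected = _coupled_logistic(rates, init_fractions, times, cfg.growth_substep_h)
    conf_expected = expected.sum(axis=1)

    latents = [
        _latent_traces(a, times, conf_expected, compound, t_compound_h)
        for a in archetypes
    ]
    # viability scales the realized pixel counts
    target_counts = np.empty_like(expected, dtype=int)
    for i in range(len(archetypes)):
        target_counts[:, i] = np.round(
            expected[:, i] * latents[i]["viability"] * n_avail
        ).astype(int)

    occupied = np.zeros(GRID_SHAPE, dtype=bool)
    type_map = np.full(GRID_SHAPE, -1, dtype=np.int8)

    # doming events (Poisson arrivals after the attachment peak)
    dome_log: list[dict] = []
    for i, arch in enumerate(archetypes):
        if arch.doming_rate_per_h <= 0 or arch.water_transport_peak_h is None:
            continue
        t0, t1 = arch.water_transport_peak_h, float(times[-1])
        if t1 <= t0:
            continue
        n_events = rng.poisson(arch.doming_rate_per_h * (t1 - t0))
        for _ in range(n_events):
            start = rng.uniform(t0, t1)
            dome_log.append(
                {
                    "archetype": arch.name,
                    "t_start_h": float(start),
                    "t_end_h": float(start + rng.uniform(1.0, 3.0)),
                    "center": (int(rng.integers(8, GRID_SHAPE[0] - 8)),
                               int(rng.integers(8, GRID_SHAPE[1] - 8))),
                    "diameter_px": float(rng.uniform(*arch.dome_diameter_px)),
                    "depth": arch.dome_depth,
                }
            )
    dome_log.sort(key=lambda d: d["t_start_h"])

    reference = _reference_stack(well_id, relief, epoxy, rng, cfg.noise_sd)

    stacks: list[ParameterMapStack] = []
    occ_frac = np.zeros((len(times), len(archetypes)))
    occ_maps: list[np.ndarray] = []
    for k, t in enumerate(times):
        for i in range(len(archetypes)):
            current = int((occupied & (type_map == i)).sum())
            delta = target_counts[k, i] - current
            if delta > 0:
                _colonize(occupied, type_map, i, delta, allowed, rng)
            elif delta < 0:
                coords = np.argwhere(occupied & (type_map == i))
                kill = coords[rng.choice(len(coords), size=min(-delta, len(coords)), replace=False)]
                occupied[kill[:, 0], kill[:, 1]] = False
                type_map[kill[:, 0], kill[:, 1]] = -1
            occ_frac[k, i] = (occupied & (type_map == i)).sum() / n_avail

        depression = None
        active = [d for d in dome_log if d["t_start_h"] <= t < d["t_end_h"]]
        if active:
            depression = np.ones(GRID_SHAPE)
            rr, cc = np.ogrid[: GRID_SHAPE[0], : GRID_SHAPE[1]]
            for d in active:
                r0, c0 = d["center"]
                disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= (d["diameter_px"] / 2.0) ** 2
                depression[disc] = 1.0 - d["depth"]

        latents_now = [
            {drv: float(tr[k]) for drv, tr in lat.items()} for lat in latents
        ]
        stacks.append(
            _render_stack(
                well_id, float(t), occupied, type_map, latents_now, relief,
                rng, cfg.noise_sd, depression,
            )
        )
        if keep_occupancy:
            occ_maps.append(occupied.copy())

    return SimulatedWell(
        well_id=well_id,
        times_h=times,
        stacks=stacks,
        reference=reference,
        epoxy_mask=epoxy,
        occupancy_fraction={a.name: occ_frac[:, i] for i, a in enumerate(archetypes)},
        latents={a.name: latents[i] for i, a in enumerate(archetypes)},
        dome_log=dome_log,
        occupancy_maps=occ_maps if keep_occupancy else None,
    )


def simulate_coculture(
    archetype_a: CellTypeArchetype,
    archetype_b: CellTypeArchetype,
    ratio: float,
    growth_advantage: float = 1.0,
    cfg: SimulationConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    **kwargs,
) -> SimulatedWell:
    """Two-population well; ``ratio`` is the seeded fraction of type B and
    ``growth_advantage`` multiplies type B's growth rate."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    b = replace(archetype_b, growth_rate=archetype_b.growth_rate * growth_advantage)
    if ratio == 0.0:
        return simulate_well(archetype_a, 1.0, cfg, seed, **kwargs)
    if ratio == 1.0:
        return simulate_well(b, 1.0, cfg, seed, **kwargs)
    return simulate_well([archetype_a, b], [1.0 - ratio, ratio], cfg, seed, **kwargs)


def default_screen_platemap(
    plate_id: str = "sim-plate",
    cell_type: str = "A549-like",
    density: float = 15_000.0,
    compound_addition_time_h: float = 24.0,
    n_dmso: int = 6,
    test_compounds: Sequence[str] = (),
) -> PlateMetadata:
    """96-well screen layout: edge columns 1 and 12 excluded, positive and
    negative controls on the interior, remaining interior wells dosed with
    ``test_compounds`` (cycled)."""
    positives = [n for n in COMPOUND_LIBRARY if n != "DMSO"]
    wells: dict[str, WellAnnotation] = {}
    interior = [
        rc_to_well_id(r, c) for r in range(8) for c in range(1, 11)
    ]
    edge = [rc_to_well_id(r, c) for r in range(8) for c in (0, 11)]
    for w in edge:
        wells[w] = WellAnnotation(
            cell_type=cell_type, density=density, role="excluded",
            exclusion_reason="edge well",
        )
    queue = list(positives) + ["DMSO"] * n_dmso
    tc = list(test_compounds)
    for i, w in enumerate(interior):
        if i < len(queue):
            name = queue[i]
            role = "negative_control" if name == "DMSO" else "positive_control"
        elif tc:
            name = tc[(i - len(queue)) % len(tc)]
            role = "test"
        else:
            name = "DMSO"
            role = "negative_control"
        wells[w] = WellAnnotation(
            cell_type=cell_type, density=density, compound=name,
            concentration_um=10.0 if name != "DMSO" else 0.0, role=role,
        )
    return PlateMetadata(plate_id, wells, compound_addition_time_h)


def iter_simulated_wells(
    meta: PlateMetadata,
    cfg: SimulationConfig | None = None,
    *,
    scan_times_h: np.ndarray | None = None,
    compounds: dict[str, CompoundEffect] | None = None,
    archetypes: dict[str, CellTypeArchetype] | None = None,
):
    """Yield one :class:`SimulatedWell` at a time for every annotated
    (non-excluded) well — the streaming form of :func:`simulate_plate`.

    Per-well seeds are spawned from ``cfg.seed`` keyed by the well's position
    in the sorted plate map, so results do not depend on iteration order.
    """
    cfg = cfg or SimulationConfig()
    compounds = compounds or COMPOUND_LIBRARY
    archetypes = archetypes or ARCHETYPES
    root = np.random.SeedSequence(cfg.seed)
    for idx, (wid, ann) in enumerate(sorted(meta.wells.items())):
        if ann.role == "excluded":
            continue
        arch_names = [n.strip() for n in ann.cell_type.split("+")] if ann.cell_type else ["A549-like"]
        archs = [archetypes[n] for n in arch_names]
        ratios = [1.0 / len(archs)] * len(archs)
        comp = compounds[ann.compound] if ann.compound else None
        ws = root.spawn(idx + 1)[0]
        yield simulate_well(
            archs,
            ratios,
            cfg,
            ws,
            well_id=wid,
            density=ann.density or 15_000.0,
            compound=comp,
            t_compound_h=meta.compound_addition_time_h if comp else None,
            scan_times_h=scan_times_h,
        )


def simulate_plate(
    meta: PlateMetadata,
    cfg: SimulationConfig | None = None,
    **kwargs,
) -> dict[str, SimulatedWell]:
    """Simulate every annotated (non-excluded) well of a plate in memory.

    Convenience wrapper over :func:`iter_simulated_wells`; for full-scale
    plates prefer the iterator with :class:`impedimap.plate_model.PlateWriter`
    so only one well is resident at a time.
    """
    return {sw.well_id: sw for sw in iter_simulated_wells(meta, cfg, **kwargs)}


# ---------------------------------------------------------------------------
# Raw-trace synthesis (inverse of demodulation)
# ---------------------------------------------------------------------------


def simulate_raw_scan(
    impedance_by_freq: dict[float, np.ndarray],
    config: FieldConfig,
    cfg: SimulationConfig | None = None,
    *,
    dc_v: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize per-electrode TIA output traces from ground-truth |Z|.

    For electrode ``e``: ``trace_e(t) = sum_f (A_f / |Z_f[e]|) * R2 *
    sin(2 pi f t) + DC + noise``.  Returns an array of shape
    ``(64, 64, n_samples)`` covering one 4 ms acquisition window.
    """
    cfg = cfg or SimulationConfig()
    n = int(round(cfg.sample_rate_hz * cfg.window_s))
    for f in config.frequencies_hz:
        if abs(f * n / cfg.sample_rate_hz - round(f * n / cfg.sample_rate_hz)) > 1e-6:
            raise ValueError(f"{f} Hz does not fit the {cfg.window_s} s window")
    t = np.arange(n) / cfg.sample_rate_hz
    traces = np.zeros(GRID_SHAPE + (n,), dtype=float)
    for f, a in zip(config.frequencies_hz, config.amplitudes_v):
        z = np.asarray(impedance_by_freq[f], dtype=float)
        if z.shape != GRID_SHAPE:
            raise ValueError("impedance maps must be 64x64")
        if np.any(z <= 0):
            raise ValueError("ground-truth impedance must be positive")
        amp = (a / z) * config.tia_gain_ohm  # TIA output amplitude per electrode
        traces += amp[..., None] * np.sin(2 * np.pi * f * t)[None, None, :]
    traces += dc_v
    if cfg.trace_noise_v > 0:
        rng = np.random.default_rng(seed)
        traces += cfg.trace_noise_v * rng.standard_normal(traces.shape)
    return traces


# ---------------------------------------------------------------------------
# Profile-level fast path (for large Monte-Carlo designs)
# ---------------------------------------------------------------------------


def simulate_profiles(
    compound_names: Sequence[str],
    seed: int = 0,
    *,
    t_compound_h: float = 24.0,
    n_timepoints: int = 16,
    noise_sd: float = 0.02,
    effect_scale: float = 1.0,
    compounds: dict[str, CompoundEffect] | None = None,
):
    """Generate normalized response profiles directly at the profile level.

    Skips map rendering: each well's trace per parameter is the compound
    kernel's multiplier on that parameter's latent target, times lognormal
    well-to-well noise.  This keeps thousand-replicate Monte-Carlo designs
    (e.g. null calibration of the DMSO gate) affordable while reusing the
    same compound kernels as the full simulator.
    """
    from .profiling import NormalizedProfile, log_time_grid

    compounds = compounds or COMPOUND_LIBRARY
    rng = np.random.default_rng(seed)
    grid = log_time_grid(t_compound_h, n_timepoints)
    param_targets = {
        "VF:mag@250": "barrier",
        "VF:mag@16000": "flatness",
        "LF:mag@16000": "attachment",
        "rms": "motility",
        "confluence": "viability",
    }
    out = []
    for i, name in enumerate(compound_names):
        comp = compounds[name]
        values = {}
        raw_values = {}
        for param, target in param_targets.items():
            m = comp.multiplier(target, grid, t_compound_h)
            m = 1.0 + effect_scale * (m - 1.0)
            noisy = m * rng.lognormal(0.0, noise_sd, size=len(grid))
            values[param] = noisy
            if param == "confluence":
                # raw percent trace behind the normalized one (60% at baseline)
                raw_values[param] = 60.0 * np.clip(noisy, 0.0, None)
        out.append(
            NormalizedProfile(
                compound=name,
                well_id=f"W{i:03d}",
                times_h=grid.copy(),
                values=values,
                raw_values=raw_values,
            )
        )
    return out
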