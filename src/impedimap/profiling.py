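"""Compound-response profiling.

Each treated well's parameter traces are normalized to their value one hour
before compound addition and resampled onto a shared grid of timepoints
logarithmically spaced over the 48 h after addition (log spacing resolves
both rapid binding effects and slow 48 h trends).  From these profiles the
module computes:

* **phenoactivity** — root-mean-square residual of a profile against the
  mean DMSO (vehicle) profile across all parameters and timepoints, gated at
  the DMSO mean + 2 sigma to call active compounds;
* **bio-basis** — 11 interpretable response metrics: eight signed
  area-under-curve excursions relative to DMSO (attachment up / detachment
  down, barrier strength up / barrier loss down, dynamicity up / staticity
  down, flatness up / cell height down), cell death, death rate, and the
  phenoactivity score;
* **functional indices** — seven per-cell-type characteristics (flatness,
  tissue barrier, cell-cell adhesion, attachment, growth rate, short/long
  term movement), min-max scaled to [0, 1] across the cell-type panel;
* **clustering / classification** — z-scored profile matrix, PCA to the top
  20 components, Ward agglomerative clustering, and a linear discriminant
  analysis classifier validated on a stratified 80/20 split (with a
  randomized-label control at chance precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .plate_model import WellTimeSeries

__all__ = [
    "PROFILE_PARAMS",
    "NormalizedProfile",
    "BioBasisVector",
    "FunctionalIndexSet",
    "ClusterModel",
    "BaselineError",
    "GridAlignmentError",
    "log_time_grid",
    "normalize_profile",
    "mean_profile",
    "phenoactivity",
    "dmso_gate",
    "biobasis",
    "functional_indices",
    "profile_matrix",
    "cluster_compounds",
    "train_classifier",
]

#: The 5 measurement parameters profiled per well: tissue barrier (VF 250 Hz),
#: cell flatness (VF 16 kHz), cell-substrate attachment (LF 16 kHz),
#: short-term movement (normalized RMS) and confluence.
PROFILE_PARAMS = ("VF:mag@250", "VF:mag@16000", "LF:mag@16000", "rms", "confluence")

DEFAULT_N_TIMEPOINTS = 16
PROFILE_WINDOW_H = 48.0

#: Which measurement parameter feeds which pair of signed-AUC bio-basis.
BIOBASIS_PARAM_MAP = {
    "LF:mag@16000": ("attachment_up", "detachment_down"),
    "VF:mag@250": ("barrier_strength_up", "barrier_loss_down"),
    "rms": ("dynamicity_up", "staticity_down"),
    "VF:mag@16000": ("flatness_up", "cell_height_down"),
}

BIOBASIS_NAMES = (
    "attachment_up",
    "detachment_down",
    "barrier_strength_up",
    "barrier_loss_down",
    "dynamicity_up",
    "staticity_down",
    "flatness_up",
    "cell_height_down",
    "cell_death",
    "death_rate",
    "phenoactivity",
)

FUNCTIONAL_INDEX_NAMES = (
    "flatness",
    "tissue_barrier",
    "cell_cell_adhesion",
    "attachment",
    "growth_rate",
    "short_term_movement",
    "long_term_movement",
)

#: Measurement parameter behind each steady-state functional index.
FUNCTIONAL_INDEX_PARAMS = {
    "flatness": "VF:mag@16000",
    "tissue_barrier": "VF:mag@250",
    "cell_cell_adhesion": "VF:mag@1000",
    "attachment": "LF:mag@16000",
    "short_term_movement": "rms",
    "long_term_movement": "rms_long",
}


class BaselineError(ValueError):
    """Raised when a well has no usable pre-compound baseline (the well is
    excluded with this reason)."""


class GridAlignmentError(ValueError):
    """Raised when profiles that must share a timepoint grid do not."""


@dataclass
class NormalizedProfile:
    """Baseline-normalized parameter traces on the shared log-spaced grid."""

    compound: str
    well_id: str
    times_h: np.ndarray
    values: dict[str, np.ndarray]
    baseline_time_h: float = float("nan")
    #: unnormalized resampled traces (e.g. raw confluence percent for the
    #: cell-death bio-basis)
    raw_values: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def params(self) -> tuple[str, ...]:
        return tuple(self.values)


@dataclass
class BioBasisVector:
    """The 11 bio-basis response metrics of one compound profile.

    AUC metrics are magnitudes (unit * h): "up" metrics integrate only the
    positive excursions of (compound - DMSO), "down" metrics only the
    negative excursions.  ``cell_death`` is the largest confluence decrease
    relative to DMSO (percentage points), ``death_rate`` the steepest
    confluence decline (%/h).
    """

    attachment_up: float = 0.0
    detachment_down: float = 0.0
    barrier_strength_up: float = 0.0
    barrier_loss_down: float = 0.0
    dynamicity_up: float = 0.0
    staticity_down: float = 0.0
    flatness_up: float = 0.0
    cell_height_down: float = 0.0
    cell_death: float = 0.0
    death_rate: float = 0.0
    phenoactivity: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BIOBASIS_NAMES])


@dataclass
class FunctionalIndexSet:
    """Per-cell-type functional indices, min-max scaled across the panel."""

    indices: dict[str, dict[str, float]]
    raw: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class ClusterModel:
    """Fitted profiling model: PCA basis, cluster labels, discriminant model
    and its held-out precision."""

    scaler: object
    pca: object
    cluster_labels: np.ndarray | None
    lda: object | None
    train_idx: np.ndarray | None
    test_idx: np.ndarray | None
    precision_macro: float | None
    precision_per_class: dict | None


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def log_time_grid(
    t_compound_h: float,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    window_h: float = PROFILE_WINDOW_H,
    first_offset_h: float = 0.25,
) -> np.ndarray:
    """Timepoints logarithmically spaced over ``(t_compound, t_compound + 48 h]``.

    The first point sits one scan interval after addition; the last point is
    exactly at +48 h.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if not 0 < first_offset_h < window_h:
        raise ValueError("first offset must lie inside the window")
    return t_compound_h + np.geomspace(first_offset_h, window_h, n_timepoints)


def _resample_nearest(times: np.ndarray, vals: np.ndarray, grid: np.ndarray) -> np.ndarray:
    idx = np.abs(times[None, :] - grid[:, None]).argmin(axis=1)
    return vals[idx]


def normalize_profile(
    series: WellTimeSeries,
    t_compound_h: float,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    params: tuple[str, ...] = PROFILE_PARAMS,
    *,
    window_h: float = PROFILE_WINDOW_H,
    first_offset_h: float = 0.25,
    compound: str = "",
    normalize_params: tuple[str, ...] | None = None,
) -> NormalizedProfile:
    """Normalize a well's traces to 1 h before compound addition and resample
    them (nearest scan) onto the shared log-spaced grid.

    Every parameter (confluence included) is divided by its baseline value;
    the unnormalized resampled traces are kept in ``raw_values`` because the
    cell-death bio-basis are defined on raw confluence percentage points.  A
    missing or non-positive baseline raises :class:`BaselineError` so the
    caller can exclude the well with a recorded reason.
    """
    t_baseline = t_compound_h - 1.0
    grid = log_time_grid(t_compound_h, n_timepoints, window_h, first_offset_h)
    scan_dt = float(np.median(np.diff(series.times_h)))
    if normalize_params is None:
        normalize_params = params
    values: dict[str, np.ndarray] = {}
    raw_values: dict[str, np.ndarray] = {}
    for p in params:
        if p not in series.values:
            raise KeyError(f"well {series.well_id} has no trace {p!r}")
        t = series.param_times(p)
        v = np.asarray(series.values[p], dtype=float)
        i0 = int(np.abs(t - t_baseline).argmin())
        if abs(t[i0] - t_baseline) > scan_dt / 2 + 1e-9:
            raise BaselineError(
                f"well {series.well_id}: no scan within half a scan interval of "
                f"t = {t_baseline} h for {p!r}"
            )
        resampled = _resample_nearest(t, v, grid)
        raw_values[p] = resampled.copy()
        if p in normalize_params:
            base = v[i0]
            if not np.isfinite(base) or base <= 0:
                raise BaselineError(
                    f"well {series.well_id}: non-positive baseline for {p!r}"
                )
            resampled = resampled / base
        values[p] = resampled
    return NormalizedProfile(
        compound=compound,
        well_id=series.well_id,
        times_h=grid,
        values=values,
        baseline_time_h=t_baseline,
        raw_values=raw_values,
    )


def _check_aligned(profiles: list[NormalizedProfile]) -> None:
    ref = profiles[0]
    for p in profiles[1:]:
        if p.params != ref.params or not np.allclose(p.times_h, ref.times_h):
            raise GridAlignmentError(
                f"profiles {ref.well_id} and {p.well_id} are not on the same grid"
            )


def mean_profile(profiles: list[NormalizedProfile]) -> NormalizedProfile:
    """Parameter-wise mean of profiles sharing a grid (e.g. the DMSO mean)."""
    if not profiles:
        raise ValueError("no profiles to average")
    _check_aligned(profiles)
    ref = profiles[0]
    values = {
        p: np.mean([pr.values[p] for pr in profiles], axis=0) for p in ref.params
    }
    return NormalizedProfile(
        compound="mean", well_id="", times_h=ref.times_h.copy(), values=values
    )


# ---------------------------------------------------------------------------
# Phenoactivity and DMSO gate
# ---------------------------------------------------------------------------


def phenoactivity(
    profile: NormalizedProfile,
    dmso_profiles: list[NormalizedProfile] | None = None,
    params: tuple[str, ...] | None = None,
    *,
    dmso_mean: NormalizedProfile | None = None,
) -> float:
    """Root-mean-square residual of a profile against the mean DMSO response.

    ``score = sqrt( sum_{p,t} (x_pt - dmso_mean_pt)^2 / (n_p * n_t) )``; zero
    iff the profile matches the DMSO mean exactly.  Pass ``dmso_mean`` to
    reuse a precomputed mean response instead of averaging
    ``dmso_profiles`` on every call.
    """
    if dmso_mean is not None:
        _check_aligned([profile, dmso_mean])
        dmso = dmso_mean
    else:
        if dmso_profiles is None or len(dmso_profiles) < 2:
            raise ValueError("need at least 2 DMSO profiles for a mean response")
        _check_aligned([profile] + list(dmso_profiles))
        dmso = mean_profile(dmso_profiles)
    params = params or profile.params
    sq = 0.0
    count = 0
    for p in params:
        resid = profile.values[p] - dmso.values[p]
        sq += float(np.sum(resid**2))
        count += resid.size
    return float(np.sqrt(sq / count))


def dmso_gate(
    scores: np.ndarray | dict[str, float], dmso_scores: np.ndarray
) -> np.ndarray | dict[str, bool]:
    """Call compounds active when their phenoactivity exceeds the DMSO
    mean + 2 sigma; the rest are 'no response'."""
    dmso_scores = np.asarray(dmso_scores, dtype=float)
    if dmso_scores.size < 3:
        raise ValueError("need at least 3 DMSO scores to estimate the gate")
    sd = float(np.std(dmso_scores, ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate DMSO score spread; gating at the mean", stacklevel=2)
    cutoff = float(np.mean(dmso_scores)) + 2.0 * sd
    if isinstance(scores, dict):
        return {k: bool(v > cutoff) for k, v in scores.items()}
    return np.asarray(scores, dtype=float) > cutoff


# ---------------------------------------------------------------------------
# Bio-basis
# ---------------------------------------------------------------------------


def _signed_aucs(t: np.ndarray, diff: np.ndarray) -> tuple[float, float]:
    """Positive-part and |negative-part| trapezoidal AUCs of a trace."""
    up = float(np.trapezoid(np.clip(diff, 0.0, None), t))
    down = float(-np.trapezoid(np.clip(diff, None, 0.0), t))
    return up, down


def biobasis(
    profile: NormalizedProfile,
    dmso_mean: NormalizedProfile,
    confluence_trace: np.ndarray | None = None,
    dmso_confluence: np.ndarray | None = None,
    *,
    phenoactivity_score: float = 0.0,
) -> BioBasisVector:
    """Compute the 11 bio-basis metrics of one compound profile.

    Confluence traces (raw percent, on the profile grid) default to the
    ``"confluence"`` entries of the profiles themselves.
    """
    _check_aligned([profile, dmso_mean])
    t = profile.times_h
    out: dict[str, float] = {}
    for param, (up_name, down_name) in BIOBASIS_PARAM_MAP.items():
        diff = profile.values[param] - dmso_mean.values[param]
        up, down = _signed_aucs(t, diff)
        out[up_name] = up
        out[down_name] = down
    def _conf(explicit, prof):
        if explicit is not None:
            return np.asarray(explicit, dtype=float)
        if "confluence" in prof.raw_values:
            return prof.raw_values["confluence"]
        return prof.values["confluence"]

    conf = _conf(confluence_trace, profile)
    dconf = _conf(dmso_confluence, dmso_mean)
    if conf.shape != t.shape or dconf.shape != t.shape:
        raise GridAlignmentError("confluence traces must be on the profile grid")
    out["cell_death"] = float(max(np.max(dconf - conf), 0.0))
    slopes = np.diff(conf) / np.diff(t)
    out["death_rate"] = float(max(-np.min(slopes), 0.0))
    out["phenoactivity"] = float(phenoactivity_score)
    return BioBasisVector(**out)


# ---------------------------------------------------------------------------
# Functional indices
# ---------------------------------------------------------------------------


def functional_indices(
    celltype_series: dict[str, WellTimeSeries],
    *,
    growth_window_h: tuple[float, float] = (0.0, 12.0),
    steady_window_h: tuple[float, float] = (36.0, 48.0),
) -> FunctionalIndexSet:
    """Seven functional indices per cell type, min-max scaled across the panel.

    Growth rate is the least-squares slope of confluence over the first 12 h;
    the six steady-state indices are the mean of their parameter over
    36-48 h.  Requires at least two cell types (otherwise min-max scaling is
    undefined) and traces spanning 48 h.
    """
    if len(celltype_series) < 2:
        raise ValueError("min-max scaling needs at least 2 cell types")
    raw: dict[str, dict[str, float]] = {}
    for ct, series in celltype_series.items():
        if series.times_h[-1] < steady_window_h[1] - 1e-9:
            raise ValueError(f"cell type {ct!r}: traces must span 48 h")
        vals: dict[str, float] = {}
        t = series.param_times("confluence")
        conf = series.values["confluence"]
        sel = (t >= growth_window_h[0]) & (t <= growth_window_h[1])
        slope = np.polyfit(t[sel], conf[sel], 1)[0]
        vals["growth_rate"] = float(slope)
        for name, param in FUNCTIONAL_INDEX_PARAMS.items():
            pt = series.param_times(param)
            pv = series.values[param]
            sel = (pt >= steady_window_h[0]) & (pt <= steady_window_h[1])
            vals[name] = float(np.nanmean(pv[sel]))
        raw[ct] = vals
    indices: dict[str, dict[str, float]] = {ct: {} for ct in raw}
    for name in FUNCTIONAL_INDEX_NAMES:
        vals = np.array([raw[ct][name] for ct in raw])
        lo, hi = float(vals.min()), float(vals.max())
        span = hi - lo if hi > lo else 1.0
        for ct in raw:
            indices[ct][name] = (raw[ct][name] - lo) / span
    return FunctionalIndexSet(indices=indices, raw=raw)


# ---------------------------------------------------------------------------
# Clustering and classification
# ---------------------------------------------------------------------------


def profile_matrix(profiles: list[NormalizedProfile]) -> np.ndarray:
    """Flatten profiles into an (n_wells, n_params * n_timepoints) matrix."""
    _check_aligned(profiles)
    return np.array(
        [np.concatenate([p.values[k] for k in p.params]) for p in profiles]
    )


def cluster_compounds(
    features: np.ndarray,
    n_components: int = 20,
    *,
    n_clusters: int | None = None,
    distance_threshold: float | None = None,
    linkage: str = "ward",
) -> tuple[np.ndarray, ClusterModel]:
    """Unbiased profile clustering: z-score, PCA to the top components, Ward
    agglomerative clustering on the scores.

    ``n_clusters`` or ``distance_threshold`` selects the cut; by default the
    dendrogram is cut inside the largest gap between consecutive merge
    distances (the natural cluster-count choice for well-separated data).
    """
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (wells x features)")
    if X.shape[0] < n_components:
        raise ValueError(
            f"{X.shape[0]} samples cannot support {n_components} PCA components"
        )
    scaler = StandardScaler()
    if np.allclose(X, X[0]):  # all profiles identical: one cluster
        scaler.fit(X)
        labels = np.zeros(X.shape[0], dtype=int)
        model = ClusterModel(
            scaler=scaler, pca=None, cluster_labels=labels, lda=None,
            train_idx=None, test_idx=None,
            precision_macro=None, precision_per_class=None,
        )
        return labels, model
    Xs = scaler.fit_transform(X)
    # constant features carry no information; z-score leaves them at 0
    Xs = np.nan_to_num(Xs, nan=0.0)
    pca = PCA(n_components=min(n_components, min(X.shape)), svd_solver="full")
    scores = pca.fit_transform(Xs)
    if n_clusters is None and distance_threshold is None:
        probe = AgglomerativeClustering(
            n_clusters=None, distance_threshold=0.0, linkage=linkage
        ).fit(scores)
        dists = np.sort(probe.distances_) if len(probe.distances_) else np.array([0.0])
        if dists[-1] == 0.0:  # all profiles identical: one cluster
            labels = np.zeros(X.shape[0], dtype=int)
            model = ClusterModel(
                scaler=scaler, pca=pca, cluster_labels=labels, lda=None,
                train_idx=None, test_idx=None,
                precision_macro=None, precision_per_class=None,
            )
            return labels, model
        gaps = np.diff(dists)
        i = int(np.argmax(gaps))
        distance_threshold = float((dists[i] + dists[i + 1]) / 2.0)
    agg = AgglomerativeClustering(
        n_clusters=n_clusters,
        distance_threshold=distance_threshold if n_clusters is None else None,
        linkage=linkage,
    )
    labels = agg.fit_predict(scores)
    model = ClusterModel(
        scaler=scaler,
        pca=pca,
        cluster_labels=labels,
        lda=None,
        train_idx=None,
        test_idx=None,
        precision_macro=None,
        precision_per_class=None,
    )
    return labels, model


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    split: float = 0.8,
    seed: int = 0,
    n_components: int | None = 20,
) -> ClusterModel:
    """Train the linear discriminant classifier on a stratified 80/20 split
    and report held-out macro-averaged precision.

    Features are z-scored and optionally PCA-reduced before LDA; every label
    must appear in the training split.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.decomposition import PCA
    from sklearn.metrics import precision_score
    from sklearn.model_selection import train_test_split
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("classification needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs >=2 members for a stratified split")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=split, random_state=seed, stratify=y
    )
    if len(np.unique(y[train_idx])) < len(classes):
        raise ValueError("a class is absent from the training split")
    scaler = StandardScaler()
    Xtr = np.nan_to_num(scaler.fit_transform(X[train_idx]), nan=0.0)
    Xte = np.nan_to_num(scaler.transform(X[test_idx]), nan=0.0)
    pca = None
    if n_components is not None and min(Xtr.shape) > 1:
        pca = PCA(n_components=min(n_components, min(Xtr.shape)), svd_solver="full")
        Xtr = pca.fit_transform(Xtr)
        Xte = pca.transform(Xte)
    lda = LinearDiscriminantAnalysis()
    lda.fit(Xtr, y[train_idx])
    pred = lda.predict(Xte)
    macro = float(precision_score(y[test_idx], pred, average="macro", zero_division=0))
    per_class = {
        str(c): float(p)
        for c, p in zip(
            classes,
            precision_score(
                y[test_idx], pred, average=None, labels=classes, zero_division=0
            ),
        )
    }
    return ClusterModel(
        scaler=scaler,
        pca=pca,
        cluster_labels=None,
        lda=lda,
        train_idx=train_idx,
        test_idx=test_idx,
        precision_macro=macro,
        precision_per_class=per_class,
    )
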