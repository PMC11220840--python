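"""Fitting model curves to SAXS data and scanning the threshold landscape.

Each dummy model is compared with the measured curve through

    I_exp(q) = a * I_model(q; c_w) + b,

where the scale ``a`` and constant background ``b`` come from a weighted
linear least-squares closed form and the hydration-shell contrast ``c_w`` is
optimized over a grid that always contains zero (the fit is free to switch
the shell off).  The goodness of fit is the reduced chi-square with three
fitted parameters; the scanned threshold is a model index, not a fitted
parameter, so it does not enter the degrees of freedom.

Scanning the threshold from high to low produces the chi-square landscape.
Near small volumes the landscape is intrinsically noisy (each density step
adds a surface-proportional batch of new voxels), so a centred moving
average smooths it before minima are located.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .map_io import DensityMap, density_levels
from .model_generation import (
    DummyModel,
    build_shells,
    estimate_mass,
    excise_model,
    hydrate,
    threshold_to_rms,
)
from .scattering import (
    FormFactorParams,
    LevelHistograms,
    ScatteringCurve,
    cross_histogram,
    pair_histogram,
    scan_histograms,
)
from .structure_io import SAXSData, write_model_pdb

__all__ = [
    "FitResult",
    "Landscape",
    "ScanConfig",
    "linear_fit",
    "fit_model",
    "scan_landscape",
    "moving_average",
    "find_local_minima",
    "report",
]


class RankDeficiencyError(ValueError):
    """Raised when the linear fit is degenerate (constant model curve)."""


@dataclasses.dataclass
class FitResult:
    """One model's fit: scale, background, water contrast and chi-square."""

    a: float
    b: float
    c_w: float
    chi2: float
    n_points: int
    n_params: int = 3
    threshold: float = float("nan")
    threshold_rms: float = float("nan")
    mass_kda: float = float("nan")

    @property
    def chi2_reduced(self) -> float:
        return self.chi2 / (self.n_points - self.n_params)


@dataclasses.dataclass
class Landscape:
    """Reduced chi-square and mass versus threshold, with smoothed minima.

    Levels where the model was empty are recorded as NaN and excluded from
    the minima.  ``best_index`` is the global minimum of the smoothed curve
    among the local minima; on ties the lower threshold (larger model) wins.
    """

    thresholds: np.ndarray
    chi2_reduced: np.ndarray
    chi2_smoothed: np.ndarray
    masses: np.ndarray
    minima: list[int]
    best_index: int
    fits: list[FitResult | None]
    window: int = 5

    @property
    def best_fit(self) -> FitResult:
        fit = self.fits[self.best_index]
        assert fit is not None
        return fit

    def chi2_window_average(self, index: int | None = None) -> float:
        """Mean raw reduced chi-square in the averaging window around a minimum."""
        i = self.best_index if index is None else index
        half = self.window // 2
        lo, hi = max(0, i - half), min(len(self.chi2_reduced), i + half + 1)
        values = self.chi2_reduced[lo:hi]
        return float(np.nanmean(values))


def linear_fit(I_model, data: SAXSData) -> tuple[float, float, float]:
    """Weighted least-squares fit ``I_exp ~ a I_model + b``; returns (a, b, chi2)."""
    m = np.asarray(I_model, dtype=np.float64)
    if m.shape != data.q.shape:
        raise ValueError("model curve and data have different lengths")
    a, b, chi2 = _linear_fit_many(m[None, :], data.intensity, data.sigma)
    return float(a[0]), float(b[0]), float(chi2[0])


def _linear_fit_many(M: np.ndarray, y: np.ndarray, sigma: np.ndarray):
    """Closed-form weighted fits of many model curves (rows of M) at once."""
    w = 1.0 / sigma**2
    sw = w.sum()
    swy = (w * y).sum()
    swm = M @ w
    swmy = M @ (w * y)
    swmm = (M * M) @ w
    denom = sw * swmm - swm**2
    scale = sw * np.mean(swmm) if np.any(swmm) else 1.0
    if np.any(np.abs(denom) <= 1e-14 * max(scale, 1e-300)):
        raise RankDeficiencyError("model curve is constant; a and b are degenerate")
    a = (sw * swmy - swm * swy) / denom
    b = (swy - a * swm) / sw
    resid = (y[None, :] - a[:, None] * M - b[:, None]) / sigma[None, :]
    chi2 = np.einsum("ij,ij->i", resid, resid)
    return a, b, chi2


def default_cw_grid(c_w_max: float = 5.0, c_w_step: float = 0.05) -> np.ndarray:
    return np.arange(0.0, c_w_max + c_w_step / 2, c_w_step)


def fit_model(
    curve: ScatteringCurve,
    data: SAXSData,
    c_w_grid: np.ndarray | None = None,
) -> FitResult:
    """Fit scale, background and hydration contrast for one model curve.

    ``I(q; c_w)`` is quadratic in ``c_w``, so a fine grid search (which must
    include 0) is cheap, robust and reproducible; for each grid value the
    (a, b) fit is the weighted closed form and the overall minimum chi-square
    wins.
    """
    if c_w_grid is None:
        c_w_grid = default_cw_grid()
    c_w_grid = np.asarray(c_w_grid, dtype=np.float64)
    if len(c_w_grid) == 0:
        raise ValueError("c_w grid is empty")
    M = (
        curve.I_pp[None, :]
        + c_w_grid[:, None] * curve.I_pw[None, :]
        + (c_w_grid**2)[:, None] * curve.I_ww[None, :]
    )
    a, b, chi2 = _linear_fit_many(M, data.intensity, data.sigma)
    k = int(np.argmin(chi2))
    return FitResult(
        a=float(a[k]),
        b=float(b[k]),
        c_w=float(c_w_grid[k]),
        chi2=float(chi2[k]),
        n_points=len(data),
    )


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average, truncated at the ends, NaN-aware.

    NaN entries (empty-model levels) are ignored inside the window; an entry
    that is itself NaN stays NaN.
    """
    values = np.asarray(values, dtype=np.float64)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return values.copy()
    half = window // 2
    out = np.full_like(values, np.nan)
    for i in range(len(values)):
        if np.isnan(values[i]):
            continue
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = np.nanmean(values[lo:hi])
    return out


def find_local_minima(values: np.ndarray) -> list[int]:
    """Indices of local minima, treating NaN as +inf; endpoints count.

    Plateaus are compared against the first differing neighbour on each side,
    and only the last index of a plateau (the lower threshold in a descending
    scan) is reported.
    """
    y = np.where(np.isnan(values), np.inf, np.asarray(values, dtype=np.float64))
    n = len(y)
    minima = []
    for i in range(n):
        if not np.isfinite(y[i]):
            continue
        left = i - 1
        while left >= 0 and y[left] == y[i]:
            left -= 1
        right = i + 1
        while right < n and y[right] == y[i]:
            right += 1
        if right < n and y[i] == y[right - 1] and right - 1 != i:
            continue  # interior of a plateau; its last index will report it
        ok_left = left < 0 or y[left] > y[i]
        ok_right = right >= n or y[right] > y[i]
        if ok_left and ok_right:
            minima.append(i)
    return minima


@dataclasses.dataclass
class ScanConfig:
    """Full configuration of a validation run (the reproducibility unit).

    Defaults encode the method's recommended operation: unity weights,
    hydration on, 100 equidistant threshold levels, stride 1, 0.1 A histogram
    bins with weighted centres, a 5-point moving-average window, and a
    c_w grid from 0 to 5 in steps of 0.05.  All randomness flows from the
    single ``seed``.
    """

    n_levels: int = 100
    weight_mode: str = "unity"
    stride: int = 1
    tmin: float | None = None
    tmax: float | None = None
    hydrate: bool = True
    shell_distance: float = 3.0
    water_density: float = 0.2
    min_water_spacing: float = 2.8
    bin_width: float = 0.1
    weighted_bins: bool = True
    form_factor_sigma: float = 1.0
    qmin: float | None = None
    qmax: float | None = None
    rebin: int | None = None
    c_w_max: float = 5.0
    c_w_step: float = 0.05
    window: int = 5
    seed: int = 0

    def c_w_grid(self) -> np.ndarray:
        return default_cw_grid(self.c_w_max, self.c_w_step)

    def form_factor(self) -> FormFactorParams:
        return FormFactorParams(self.form_factor_sigma)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _level_seeds(config: ScanConfig, n: int) -> list[int]:
    """Deterministic per-level hydration seeds derived from the run seed."""
    ss = np.random.SeedSequence(config.seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _prepare_data(data: SAXSData, config: ScanConfig) -> SAXSData:
    data = data.truncate(config.qmin, config.qmax)
    if config.rebin is not None:
        data = data.rebin(config.rebin)
    if len(data) <= 4:
        raise ValueError("too few SAXS points after truncation/rebinning")
    return data


def _hydrated_model(
    dmap: DensityMap, threshold: float, config: ScanConfig, level_seed: int
) -> DummyModel:
    model = excise_model(dmap, threshold, config.weight_mode, config.stride)
    if config.hydrate and not model.is_empty:
        model = hydrate(
            model,
            level_seed,
            shell_distance=config.shell_distance,
            target_density=config.water_density,
            min_water_spacing=config.min_water_spacing,
        )
    return model


def scan_landscape(
    dmap: DensityMap, data: SAXSData, config: ScanConfig | None = None
) -> Landscape:
    """Scan the threshold from high to low and fit every dummy model.

    The map-map (pp) pair histogram grows incrementally through the
    onion-shell cache; the hydration shell is regenerated per level (with a
    per-level seed spawned from the run seed) and its pw/ww components are
    computed fresh.  Levels whose model is empty are recorded as NaN.
    """
    config = config or ScanConfig()
    data = _prepare_data(data, config)
    levels = density_levels(dmap, config.n_levels, config.tmin, config.tmax)
    shells = build_shells(dmap, levels, config.weight_mode, config.stride)
    seeds = _level_seeds(config, len(levels))
    params = config.form_factor()
    c_w_grid = config.c_w_grid() if config.hydrate else np.array([0.0])

    waters_per_level: list[np.ndarray] = []
    cum_positions: list[np.ndarray] = []
    cum_weights: list[np.ndarray] = []
    for k in range(len(levels)):
        cum_positions.append(shells.shell_positions[k])
        cum_weights.append(shells.shell_weights[k])
        total = sum(len(p) for p in cum_positions)
        if config.hydrate and total > 0:
            model = DummyModel(
                threshold=float(levels[k]),
                positions=np.concatenate(cum_positions),
                weights=np.concatenate(cum_weights),
                waters=np.empty((0, 3)),
                stride=config.stride,
                voxel_size=shells.voxel_size,
                source_id=dmap.source_id,
            )
            model = hydrate(
                model,
                seeds[k],
                shell_distance=config.shell_distance,
                target_density=config.water_density,
                min_water_spacing=config.min_water_spacing,
            )
            waters_per_level.append(model.waters)
        else:
            waters_per_level.append(np.empty((0, 3)))

    level_hists = scan_histograms(
        shells, waters_per_level, config.bin_width, config.weighted_bins
    )

    chi2_reduced = np.full(len(levels), np.nan)
    masses = np.zeros(len(levels))
    fits: list[FitResult | None] = [None] * len(levels)
    for k, hists in enumerate(level_hists):
        if hists.pp.total_weight == 0:
            continue
        curve = ScatteringCurve.from_histograms(hists, data.q, params)
        fit = fit_model(curve, data, c_w_grid)
        fit.threshold = float(levels[k])
        fit.threshold_rms = threshold_to_rms(dmap, levels[k])
        model_stub = DummyModel(
            threshold=float(levels[k]),
            positions=np.empty((1, 3)),
            weights=np.ones(1),
            waters=np.empty((0, 3)),
        )
        fit.mass_kda = estimate_mass(model_stub, dmap)
        fits[k] = fit
        chi2_reduced[k] = fit.chi2_reduced
        masses[k] = fit.mass_kda

    if all(f is None for f in fits):
        raise ValueError("no threshold level produced a non-empty model")

    chi2_smoothed = moving_average(chi2_reduced, config.window)
    minima = find_local_minima(chi2_smoothed)
    if not minima:
        minima = [int(np.nanargmin(chi2_smoothed))]
    # ties: the later index (lower threshold, larger model) wins
    best_value = min(chi2_smoothed[i] for i in minima)
    best_index = max(i for i in minima if chi2_smoothed[i] == best_value)
    return Landscape(
        thresholds=levels,
        chi2_reduced=chi2_reduced,
        chi2_smoothed=chi2_smoothed,
        masses=masses,
        minima=minima,
        best_index=best_index,
        fits=fits,
        window=config.window,
    )


def _model_curve(
    dmap: DensityMap, data: SAXSData, config: ScanConfig, index: int,
    landscape: Landscape,
) -> tuple[DummyModel, np.ndarray]:
    """Rebuild the model and fitted intensity at one landscape level."""
    seeds = _level_seeds(config, len(landscape.thresholds))
    model = _hydrated_model(
        dmap, float(landscape.thresholds[index]), config, seeds[index]
    )
    fit = landscape.fits[index]
    assert fit is not None
    params = config.form_factor()
    ones = np.ones(len(model.waters))
    hists = LevelHistograms(
        pp=pair_histogram(
            model.positions, model.weights, config.bin_width, config.weighted_bins
        ),
        pw=cross_histogram(
            model.positions, model.weights, model.waters, ones,
            config.bin_width, config.weighted_bins,
        ),
        ww=pair_histogram(
            model.waters, ones, config.bin_width, config.weighted_bins
        ),
    )
    curve = ScatteringCurve.from_histograms(hists, data.q, params)
    return model, fit.a * curve.intensity(fit.c_w) + fit.b


def report(
    landscape: Landscape,
    dmap: DensityMap,
    data: SAXSData,
    config: ScanConfig,
    out_dir,
) -> dict:
    """Write the validation report files and return the summary dict.

    Emits the landscape table, the best-fit curve with residuals, the
    serialized configuration, a human-readable and a JSON summary (absolute
    and window-averaged chi-square, optimal threshold in map units and RMS
    units, mass), and one PDB dummy model per landscape minimum.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = _prepare_data(data, config)

    rows = np.column_stack(
        [
            landscape.thresholds,
            [threshold_to_rms(dmap, t) for t in landscape.thresholds],
            landscape.masses,
            landscape.chi2_reduced,
            landscape.chi2_smoothed,
        ]
    )
    np.savetxt(
        out_dir / "landscape.tsv",
        rows,
        delimiter="\t",
        header="threshold\tthreshold_rms\tmass_kda\tchi2_reduced\tchi2_smoothed",
        fmt="%.8g",
    )

    best = landscape.best_fit
    model, I_fit = _model_curve(dmap, data, config, landscape.best_index, landscape)
    residuals = (data.intensity - I_fit) / data.sigma
    np.savetxt(
        out_dir / "fit.tsv",
        np.column_stack([data.q, data.intensity, data.sigma, I_fit, residuals]),
        delimiter="\t",
        header="q\tI_exp\tsigma\tI_fit\tresidual",
        fmt="%.8g",
    )

    model_files = {}
    write_model_pdb(model, out_dir / "best_model.pdb")
    model_files[landscape.best_index] = "best_model.pdb"
    for rank, idx in enumerate(i for i in landscape.minima if i != landscape.best_index):
        fname = f"secondary_model_{rank + 1}.pdb"
        secondary, _ = _model_curve(dmap, data, config, idx, landscape)
        if not secondary.is_empty:
            write_model_pdb(secondary, out_dir / fname)
            model_files[idx] = fname

    summary = {
        "chi2_reduced_min": best.chi2_reduced,
        "chi2_reduced_avg": landscape.chi2_window_average(),
        "threshold": best.threshold,
        "threshold_rms": best.threshold_rms,
        "mass_kda": best.mass_kda,
        "a": best.a,
        "b": best.b,
        "c_w": best.c_w,
        "n_points": best.n_points,
        "n_minima": len(landscape.minima),
        "n_waters": int(len(model.waters)),
        "seed": config.seed,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    lines = [
        "EM-map validation against SAXS data",
        f"  data: {data.label} ({len(data)} points)",
        f"  map:  {dmap.source_id} {dmap.dims}",
        f"  best reduced chi2 (raw minimum): {best.chi2_reduced:.4g}",
        f"  window-averaged reduced chi2:    {summary['chi2_reduced_avg']:.4g}",
        f"  optimal threshold: {best.threshold:.6g} "
        f"({best.threshold_rms:.4g} x RMS)",
        f"  model mass: {best.mass_kda:.4g} kDa",
        f"  hydration contrast c_w: {best.c_w:.3g} "
        f"({len(model.waters)} dummy waters)",
        f"  minima found: {len(landscape.minima)}",
    ]
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
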