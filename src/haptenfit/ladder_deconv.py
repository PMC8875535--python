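"""Constrained Gaussian deconvolution of a conjugate ion ladder.

A peptide-carrier conjugate appears in a linear-MALDI spectrum as a series
of peaks: the carrier bearing n = 0, 1, 2, ... peptides, observed at a fixed
charge state z (doubly charged ions for a ~58 kDa carrier).  The expected
peak centers form an arithmetic ladder

    c(n) = (M0 + n * Delta + z * m_proton) / z,

so the whole series is fitted jointly as a sum of Gaussians whose centers
are pinned to the ladder up to a small common shift (absorbing residual
calibration error) and tiny per-peak jitter.  Pinning the centers is what
keeps the load assignment — and hence the hapten density — unambiguous.

Fit quality is summarised by the adjusted R-square of the cumulative fit,
the criterion used to accept a deconvolution (> 0.99 in practice).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError
from .spectra_io import MassSpectrum, PROTON_MASS


@dataclass
class ConjugateLadder:
    """Parametric description of the expected conjugate ion series.

    Parameters
    ----------
    M0 :
        Neutral mass (Da) of the load-0 species — carrier plus any
        activation/capping adducts.  Its residual uncertainty is absorbed
        by the fitted ``global_shift``; M0 itself is never fit freely.
    delta :
        Neutral mass increment per conjugated peptide (Da).
    z :
        Charge state of the fitted series (2 for the doubly charged ions
        a linear MALDI source mainly produces for large conjugates).
    n_min, n_max :
        Inclusive peptide-load range of the series.
    global_shift :
        Common m/z offset (Th) fitted to the whole series.
    """

    M0: float
    delta: float
    z: int = 2
    n_min: int = 0
    n_max: int = 12
    global_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise FitError(f"delta must be > 0, got {self.delta}")
        if self.z < 1:
            raise FitError(f"charge must be >= 1, got {self.z}")
        if self.n_min < 0 or self.n_max < self.n_min:
            raise FitError(f"invalid load range [{self.n_min}, {self.n_max}]")

    @property
    def spacing_mz(self) -> float:
        """m/z distance between consecutive ladder peaks: delta / z."""
        return self.delta / self.z

    def loads(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_max + 1)

    def centers(self) -> np.ndarray:
        """Predicted m/z centers (including the current global shift)."""
        n = self.loads()
        return (self.M0 + n * self.delta + self.z * PROTON_MASS) / self.z + (
            self.global_shift
        )


def predict_ladder(
    M0: float, delta: float, z: int, n_range: tuple[int, int]
) -> list[tuple[int, float]]:
    """Predicted (load, m/z center) pairs: c(n) = (M0 + n*delta + z*mp)/z."""
    ladder = ConjugateLadder(M0=M0, delta=delta, z=z, n_min=n_range[0], n_max=n_range[1])
    return list(zip(ladder.loads().tolist(), ladder.centers().tolist()))


@dataclass
class PeakFit:
    """One fitted conjugate species."""

    load: int
    center: float
    width: float
    amplitude: float

    @property
    def area(self) -> float:
        """Gaussian closed-form area: A * sigma * sqrt(2 pi)."""
        return self.amplitude * self.width * np.sqrt(2.0 * np.pi)


@dataclass
class DeconvolutionResult:
    """Fitted ladder peaks plus diagnostics of the cumulative fit."""

    peaks: list[PeakFit]
    adj_r2: float
    residual_rms: float
    ladder: ConjugateLadder
    fit_window: tuple[float, float]
    converged: bool = True
    n_params: int = 0

    def loads(self) -> list[int]:
        return [p.load for p in self.peaks]

    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks])

    def to_table(self) -> list[dict]:
        return [
            {
                "load": p.load,
                "center": p.center,
                "sigma": p.width,
                "amplitude": p.amplitude,
                "area": p.area,
            }
            for p in self.peaks
        ]


@dataclass
class FitConfig:
    """Options for :func:`fit_ladder`.

    The center constraints default to 20% of the peak spacing for the
    common shift and 5% for per-peak jitter — loose enough to absorb
    calibration error, tight enough to keep species assignment unique.
    """

    width_model: Literal["shared", "linear"] = "shared"
    shift_bound: float | None = None  # Th; default 0.2 * delta / z
    jitter_bound: float | None = None  # Th; default 0.05 * delta / z
    prune_threshold: float = 0.01  # fraction of max fitted amplitude
    sigma_init: float | None = None  # Th
    fit_window: tuple[float, float] | None = None
    max_restarts: int = 3
    seed: int = 0


def adjusted_r2(observed, fitted, n_params: int) -> float:
    """Adjusted coefficient of determination of a fit.

    ``1 - (1 - R^2) * (N - 1) / (N - n_params - 1)`` with
    ``R^2 = 1 - SS_res / SS_tot``.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    n = observed.size
    if fitted.size != n:
        raise FitError("observed and fitted arrays differ in length")
    if n <= n_params + 1:
        raise FitError(f"need more than n_params + 1 = {n_params + 1} points, got {n}")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise FitError("zero total variance: adjusted R^2 undefined")
    ss_res = float(np.sum((observed - fitted) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------


def _unpack(params: np.ndarray, k: int, width_model: str):
    shift = params[0]
    if width_model == "shared":
        widths = params[1:2]
        rest = params[2:]
    else:
        widths = params[1:3]
        rest = params[3:]
    jitter = rest[:k]
    amps = rest[k:]
    return shift, widths, jitter, amps


def _sigmas(widths: np.ndarray, centers: np.ndarray, width_model: str) -> np.ndarray:
    if width_model == "shared":
        return np.full_like(centers, widths[0])
    return widths[0] + widths[1] * (centers - centers.mean())


def _model(
    x: np.ndarray,
    params: np.ndarray,
    pred_centers: np.ndarray,
    width_model: str,
) -> np.ndarray:
    k = pred_centers.size
    shift, widths, jitter, amps = _unpack(params, k, width_model)
    centers = pred_centers + shift + jitter
    sigmas = _sigmas(widths, centers, width_model)
    y = np.zeros_like(x)
    for c, s, a in zip(centers, sigmas, amps):
        y += a * np.exp(-0.5 * ((x - c) / s) ** 2)
    return y


def _initial_amplitudes(
    x: np.ndarray, y: np.ndarray, centers: np.ndarray, half_window: float
) -> np.ndarray:
    amps = np.empty(centers.size)
    for i, c in enumerate(centers):
        sel = (x >= c - half_window) & (x <= c + half_window)
        amps[i] = y[sel].max() if np.any(sel) else 0.0
    return np.maximum(amps, 1e-12 * max(y.max(), 1.0))


def _estimate_sigma(x: np.ndarray, y: np.ndarray, spacing: float) -> float:
    """Crude width guess from the tallest peak's half-height span."""
    imax = int(np.argmax(y))
    half = y[imax] / 2.0
    left = imax
    while left > 0 and y[left] > half:
        left -= 1
    right = imax
    while right < y.size - 1 and y[right] > half:
        right += 1
    width = x[right] - x[left]
    if width <= 0 or width > spacing:
        return spacing / 6.0
    return max(width / 2.3548, (x[1] - x[0]))


def _fit_once(
    x: np.ndarray,
    y: np.ndarray,
    ladder: ConjugateLadder,
    config: FitConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, bool]:
    pred = ladder.centers() - ladder.global_shift  # raw ladder positions
    k = pred.size
    spacing = ladder.spacing_mz
    shift_bound = (
        config.shift_bound if config.shift_bound is not None else 0.2 * spacing
    )
    jitter_bound = (
        config.jitter_bound if config.jitter_bound is not None else 0.05 * spacing
    )
    sigma0 = config.sigma_init or _estimate_sigma(x, y, spacing)
    amps0 = _initial_amplitudes(x, y, pred, 0.25 * spacing)
    ymax = y.max()

    if config.width_model == "shared":
        w0 = np.array([sigma0])
        w_lo = np.array([max(sigma0 * 0.05, (x[1] - x[0]) * 0.5)])
        w_hi = np.array([min(sigma0 * 20.0, spacing)])
    else:
        span = max(x[-1] - x[0], 1.0)
        w0 = np.array([sigma0, 0.0])
        w_lo = np.array([max(sigma0 * 0.05, (x[1] - x[0]) * 0.5), -sigma0 / span])
        w_hi = np.array([min(sigma0 * 20.0, spacing), sigma0 / span])
    w0 = np.clip(w0, w_lo, w_hi)

    p0 = np.concatenate([[0.0], w0, np.zeros(k), amps0])
    lo = np.concatenate([[-shift_bound], w_lo, -jitter_bound * np.ones(k), np.zeros(k)])
    hi = np.concatenate(
        [[shift_bound], w_hi, jitter_bound * np.ones(k), 1.05 * ymax * np.ones(k)]
    )
    p0 = np.clip(p0, lo, hi)

    def residual(params):
        return _model(x, params, pred, config.width_model) - y

    best = None
    for attempt in range(config.max_restarts + 1):
        start = p0
        if attempt > 0:
            # perturb the initial guess within bounds (seeded, deterministic)
            jiggle = rng.uniform(0.8, 1.2, size=p0.size)
            start = np.clip(p0 * jiggle, lo, hi)
        sol = least_squares(residual, start, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            break
    if best is None:
        raise FitError("ladder fit failed to produce a solution")
    return best.x, p0.size, bool(best.success)


def fit_ladder(
    spectrum: MassSpectrum,
    ladder: ConjugateLadder,
    config: FitConfig | None = None,
) -> DeconvolutionResult:
    """Fit the conjugate ion ladder as a constrained sum of Gaussians.

    The spectrum is expected to be preprocessed (smoothed and
    baseline-subtracted).  Centers are pinned to the ladder prediction up to
    a bounded global shift plus bounded per-peak jitter; amplitudes are
    non-negative; widths are either one shared sigma or linear in m/z.
    Species whose fitted amplitude falls below ``prune_threshold`` times the
    maximum amplitude are removed (the load range is trimmed to the
    surviving contiguous span) and the model refit once.
    """
    config = config or FitConfig()
    if config.fit_window is not None:
        window = config.fit_window
    else:
        raw = ConjugateLadder(
            M0=ladder.M0, delta=ladder.delta, z=ladder.z,
            n_min=ladder.n_min, n_max=ladder.n_max,
        )
        c = raw.centers()
        margin = 0.6 * ladder.spacing_mz
        window = (c[0] - margin, c[-1] + margin)
    sel = (spectrum.mz >= window[0]) & (spectrum.mz <= window[1])
    x = spectrum.mz[sel]
    y = spectrum.intensity[sel]
    if x.size < 10:
        raise FitError(
            f"fit window {window} contains only {x.size} points"
        )
    if np.all(y == 0):
        raise FitError("all-zero spectrum in fit window")

    rng = np.random.default_rng(config.seed)
    current = dataclasses.replace(ladder, global_shift=0.0)
    # species whose predicted center falls outside the data carry no
    # information; drop them or their amplitudes are unidentifiable
    pred_all = current.centers()
    inside = (pred_all >= x[0]) & (pred_all <= x[-1])
    if not np.any(inside):
        raise FitError("no predicted ladder centers fall inside the data range")
    in_loads = current.loads()[inside]
    current = dataclasses.replace(
        current, n_min=int(in_loads.min()), n_max=int(in_loads.max())
    )
    params, n_params, converged = _fit_once(x, y, current, config, rng)

    # prune weak species (trim the load range to the surviving span), refit
    k = current.loads().size
    _, _, _, amps = _unpack(params, k, config.width_model)
    keep = amps >= config.prune_threshold * amps.max()
    if not np.all(keep):
        loads = current.loads()[keep]
        current = dataclasses.replace(
            current, n_min=int(loads.min()), n_max=int(loads.max())
        )
        params, n_params, converged = _fit_once(x, y, current, config, rng)

    k = current.loads().size
    shift, widths, jitter, amps = _unpack(params, k, config.width_model)
    pred = current.centers()  # global_shift == 0 here
    centers = pred + shift + jitter
    sigmas = _sigmas(widths, centers, config.width_model)
    fitted = _model(x, params, pred, config.width_model)

    peaks = [
        PeakFit(load=int(n), center=float(c), width=float(s), amplitude=float(a))
        for n, c, s, a in zip(current.loads(), centers, sigmas, amps)
    ]
    result_ladder = dataclasses.replace(current, global_shift=float(shift))
    adj = adjusted_r2(y, fitted, n_params)
    rms = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return DeconvolutionResult(
        peaks=peaks,
        adj_r2=adj,
        residual_rms=rms,
        ladder=result_ladder,
        fit_window=(float(window[0]), float(window[1])),
        converged=converged,
        n_params=n_params,
    )


def select_load_range(
    spectrum: MassSpectrum,
    ladder: ConjugateLadder,
    criterion: Literal["bic", "amplitude_threshold"] = "bic",
    config: FitConfig | None = None,
) -> tuple[int, int]:
    """Choose the contiguous load range actually present in the spectrum.

    ``ladder`` describes the candidate superset range.  With
    ``amplitude_threshold`` the superset is fitted once and the range is
    trimmed to species above the pruning threshold; with ``bic`` the
    trimmed range is then shrunk/grown at either end while the Bayesian
    information criterion of the refit improves.
    """
    config = config or FitConfig()
    base = fit_ladder(spectrum, ladder, config)
    loads = base.loads()
    if not loads:
        raise FitError("no species survive fitting; cannot select a range")
    lo, hi = min(loads), max(loads)
    if criterion == "amplitude_threshold":
        return lo, hi
    if criterion != "bic":
        raise FitError(f"unknown criterion {criterion!r}")

    # all candidate ranges are scored on one fixed window so that their
    # BIC values are comparable
    window = base.fit_window

    def bic_of(rng_pair: tuple[int, int]) -> float:
        # keep the pruning threshold: species below it vanish from the trial
        # model, so BIC cannot reward fitting noise pedestals with phantoms
        lad = dataclasses.replace(ladder, n_min=rng_pair[0], n_max=rng_pair[1])
        cfg = dataclasses.replace(config, fit_window=window)
        res = fit_ladder(spectrum, lad, cfg)
        sel = (spectrum.mz >= window[0]) & (spectrum.mz <= window[1])
        n = int(sel.sum())
        ss = res.residual_rms**2 * n
        return n * np.log(max(ss / n, 1e-300)) + res.n_params * np.log(n)

    best = (lo, hi)
    best_bic = bic_of(best)
    improved = True
    while improved:
        improved = False
        candidates = []
        blo, bhi = best
        if blo > ladder.n_min:
            candidates.append((blo - 1, bhi))
        if bhi < ladder.n_max:
            candidates.append((blo, bhi + 1))
        if blo < bhi:
            candidates.extend([(blo + 1, bhi), (blo, bhi - 1)])
        for cand in candidates:
            b = bic_of(cand)
            if b < best_bic - 1e-9:
                best, best_bic = cand, b
                improved = True
                break
    return best
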