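"""Synthetic linear-MALDI spectra of conjugate mixtures with known truth.

The simulator emulates what the instrument sees for a ~58 kDa carrier
bearing 0..n copies of a ~1.6-3.3 kDa peptide, observed mainly as doubly
charged ions: a ladder of Gaussian peaks on a smooth exponentially decaying
baseline with additive detector noise.  Species abundances come from an
analytic load model — by default a binomial over the ~20 activatable
carrier sites (independent site occupancy), the natural mechanistic
stand-in for conjugation at increasing peptide molar excess; a Poisson
model and explicit tables are also available.

Ground truth (species fractions, mean load, load SD, per-peak parameters)
is returned alongside every spectrum so each downstream stage can be tested
without instrument data.  Peak areas are rendered proportional to molar
fractions — the same quantitative assumption the hapten-density estimator
relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .conjugate_chem import ladder_spacing, mouse_iris_design, sbap_chemistry
from .errors import SimulationError
from .ladder_deconv import ConjugateLadder
from .spectra_io import MassSpectrum, write_spectrum

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

#: Average mass of the CRM197 carrier protein (Da).
CRM197_MASS = 58408.0


def _default_delta() -> float:
    return ladder_spacing(mouse_iris_design(1), sbap_chemistry())


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic conjugate spectrum.

    Defaults mirror the system the pipeline targets: CRM197 (~58.4 kDa)
    conjugated with a single-repeat IRIS peptide (Delta ~1835 Da including
    the SBAP remnant), observed as doubly charged ions at linear-MALDI
    resolution (peak FWHM 0.8% of m/z), on a decaying baseline with 1%
    additive Gaussian noise.
    """

    load_model: Literal["binomial", "poisson", "explicit"] = "binomial"
    n_sites: int = 20
    p: float = 0.1
    lam: float = 2.0
    explicit_species: Sequence[tuple[int, float]] | None = None
    carrier_mass: float = CRM197_MASS
    delta: float = field(default_factory=_default_delta)
    charge_states: Sequence[tuple[int, float]] = ((2, 1.0),)
    resolution: float = 0.008  # peak FWHM as a fraction of m/z
    baseline_amplitude: float = 0.2  # fraction of the tallest clean peak
    baseline_rate: float = 5e-4  # per Th
    noise_sd: float = 0.01  # fraction of the tallest clean peak
    grid: tuple[float, float, int] | None = None
    n_points: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.load_model == "binomial" and not (0.0 <= self.p <= 1.0):
            raise SimulationError(f"binomial p must be in [0, 1], got {self.p}")
        if self.load_model == "poisson" and self.lam < 0:
            raise SimulationError(f"poisson lambda must be >= 0, got {self.lam}")
        if self.load_model == "explicit" and not self.explicit_species:
            raise SimulationError("explicit load model needs explicit_species")
        if self.resolution <= 0:
            raise SimulationError("resolution must be > 0")
        if self.noise_sd < 0 or self.baseline_amplitude < 0:
            raise SimulationError("noise and baseline amplitudes must be >= 0")
        if self.grid is not None and self.grid[2] < 100:
            raise SimulationError("grid must have at least 100 points")


@dataclass
class SimulatedTruth:
    """Ground truth paired with a rendered spectrum."""

    species: list[tuple[int, float]]  # (load, molar fraction)
    true_hd: float
    true_sigma: float
    peak_params: list[dict] = field(default_factory=list)

    def loads(self) -> np.ndarray:
        return np.array([n for n, _ in self.species])

    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.species])


_TRUNCATION = 1e-6


def sample_loads(config: SimulationConfig) -> SimulatedTruth:
    """Analytic species fractions of the configured load distribution.

    Fractions come from the model's pmf (no Monte-Carlo), truncated to
    loads with fraction >= 1e-6 and renormalized; the true mean and SD are
    those of the truncated distribution.
    """
    if config.load_model == "binomial":
        loads = np.arange(config.n_sites + 1)
        fracs = stats.binom.pmf(loads, config.n_sites, config.p)
    elif config.load_model == "poisson":
        hi = int(stats.poisson.ppf(1.0 - 1e-9, config.lam)) + 1 if config.lam > 0 else 1
        loads = np.arange(hi + 1)
        fracs = stats.poisson.pmf(loads, config.lam)
    else:
        loads = np.array([n for n, _ in config.explicit_species])
        fracs = np.array([w for _, w in config.explicit_species], dtype=float)
        if np.any(fracs < 0) or fracs.sum() <= 0:
            raise SimulationError("explicit species weights must be >= 0, sum > 0")
        fracs = fracs / fracs.sum()
    keep = fracs >= _TRUNCATION
    loads, fracs = loads[keep], fracs[keep]
    fracs = fracs / fracs.sum()
    hd = float(np.sum(loads * fracs))
    sigma = float(np.sqrt(np.sum(fracs * (loads - hd) ** 2)))
    return SimulatedTruth(
        species=[(int(n), float(f)) for n, f in zip(loads, fracs)],
        true_hd=hd,
        true_sigma=sigma,
    )


def render_spectrum(truth: SimulatedTruth, config: SimulationConfig) -> MassSpectrum:
    """Render a spectrum from a load distribution.

    Each species contributes one Gaussian per charge state, centered at the
    ladder-predicted m/z, with sigma = resolution * center / 2.3548 and
    area proportional to (molar fraction x charge-state weight).  An
    exponential baseline and seeded additive Gaussian noise are added and
    the result clipped at zero.
    """
    loads = truth.loads()
    centers_by_charge = []
    for z, weight in config.charge_states:
        lad = ConjugateLadder(
            M0=config.carrier_mass,
            delta=config.delta,
            z=z,
            n_min=int(loads.min()),
            n_max=int(loads.max()),
        )
        all_centers = lad.centers()
        centers = all_centers[np.searchsorted(lad.loads(), loads)]
        centers_by_charge.append((z, weight, centers))

    fwhm_max = config.resolution * max(
        c.max() for _, _, c in centers_by_charge
    )
    if config.grid is None:
        lo = min(c.min() for _, _, c in centers_by_charge) - 6.0 * fwhm_max
        hi = max(c.max() for _, _, c in centers_by_charge) + 6.0 * fwhm_max
        n_points = config.n_points
    else:
        lo, hi, n_points = config.grid
        c_lo = min(c.min() for _, _, c in centers_by_charge)
        c_hi = max(c.max() for _, _, c in centers_by_charge)
        if lo > c_lo - 5.0 * fwhm_max or hi < c_hi + 5.0 * fwhm_max:
            raise SimulationError(
                "grid too narrow: must cover all predicted centers +/- 5 FWHM"
            )
    mz = np.linspace(lo, hi, int(n_points))

    clean = np.zeros_like(mz)
    peak_params = []
    fracs = truth.fractions()
    for z, weight, centers in centers_by_charge:
        sigmas = config.resolution * centers / FWHM_FACTOR
        areas = fracs * weight
        amps = areas / (sigmas * np.sqrt(2.0 * np.pi))
        for n, c, s, a in zip(loads, centers, sigmas, amps):
            clean += a * np.exp(-0.5 * ((mz - c) / s) ** 2)
            peak_params.append(
                {"load": int(n), "charge": int(z), "center": float(c),
                 "sigma": float(s), "amplitude": float(a)}
            )
    scale = clean.max()
    if scale <= 0:
        raise SimulationError("rendered spectrum has no signal")
    clean = clean / scale
    for p in peak_params:
        p["amplitude"] /= scale

    baseline = config.baseline_amplitude * np.exp(-config.baseline_rate * (mz - lo))
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, size=mz.size) if config.noise_sd > 0 else 0.0
    intensity = np.clip(clean + baseline + noise, 0.0, None)

    truth.peak_params = peak_params
    meta = {
        "simulated": True,
        "seed": config.seed,
        "charge_states": list(map(list, config.charge_states)),
        "resolution": config.resolution,
        "true_hd": truth.true_hd,
        "true_sigma": truth.true_sigma,
    }
    return MassSpectrum(mz=mz, intensity=intensity, meta=meta)


def simulate_spectrum(config: SimulationConfig) -> tuple[MassSpectrum, SimulatedTruth]:
    """Convenience: sample the load model and render in one call."""
    truth = sample_loads(config)
    return render_spectrum(truth, config), truth


def _config_record(config: SimulationConfig) -> dict:
    rec = asdict(config)
    rec["charge_states"] = list(map(list, config.charge_states))
    if rec["explicit_species"] is not None:
        rec["explicit_species"] = list(map(list, rec["explicit_species"]))
    return rec


def generate_batch(configs: Sequence[SimulationConfig], out_dir) -> list[dict]:
    """Write spectra (txt + mzML) and a JSON manifest pairing files to truth.

    Returns the manifest: one entry per config with the file names, seed,
    true HD/sigma, species table and the full configuration.  Re-running
    with identical configs reproduces byte-identical text fixtures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, config in enumerate(configs):
        spectrum, truth = simulate_spectrum(config)
        stem = f"sim_{i:03d}"
        txt_path = out_dir / f"{stem}.txt"
        mzml_path = out_dir / f"{stem}.mzML"
        write_spectrum(spectrum, txt_path, format="txt")
        write_spectrum(spectrum, mzml_path, format="mzml")
        manifest.append(
            {
                "file": txt_path.name,
                "format": "txt",
                "mzml_file": mzml_path.name,
                "seed": config.seed,
                "true_hd": truth.true_hd,
                "true_sigma": truth.true_sigma,
                "species": [
                    {"load": n, "fraction": f} for n, f in truth.species
                ],
                "config": _config_record(config),
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
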