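"""Hapten density and dispersity from a deconvolved conjugate ladder.

The average hapten density of a conjugate preparation is the peak-area
weighted mean peptide load across the fitted species:

    HD = sum(VUC_n * PL_n) / sum(VUC_n)

where VUC is the Gaussian area under the curve of species n and PL its
integer peptide load.  The matching dispersity is the area-weighted
(population-style) standard deviation of the load,

    sigma = sqrt( sum(VUC_n * (PL_n - HD)^2) / sum(VUC_n) ),

the conjugate analogue of a polymer's dispersity.  Both quantities are
invariant to rescaling all areas, so only relative species abundances
matter — the regime in which MALDI peak areas are quantitative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FitError
from .ladder_deconv import DeconvolutionResult


def _areas(abundances: Sequence[tuple[int, float]]) -> tuple[np.ndarray, np.ndarray]:
    if len(abundances) == 0:
        raise FitError("empty abundance table")
    loads = np.array([pl for pl, _ in abundances], dtype=float)
    areas = np.array([vuc for _, vuc in abundances], dtype=float)
    if np.any(areas < 0):
        raise FitError("negative peak area")
    total = areas.sum()
    if total <= 0:
        raise FitError("all peak areas are zero; HD undefined")
    return loads, areas


def compute_hd(abundances: Sequence[tuple[int, float]]) -> float:
    """Area-weighted mean peptide load: sum(VUC * PL) / sum(VUC)."""
    loads, areas = _areas(abundances)
    return float(np.sum(areas * loads) / areas.sum())


def compute_dispersity(abundances: Sequence[tuple[int, float]]) -> float:
    """Area-weighted population standard deviation of the peptide load."""
    loads, areas = _areas(abundances)
    hd = np.sum(areas * loads) / areas.sum()
    return float(np.sqrt(np.sum(areas * (loads - hd) ** 2) / areas.sum()))


@dataclass
class HaptenDensityReport:
    """HD, dispersity and per-species abundances for one conjugate sample."""

    hd: float
    sigma: float
    adj_r2: float
    abundances: list[tuple[int, float, float]]  # (load, area, fraction)
    sample_id: str = ""
    config_digest: str = ""

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "hd": self.hd,
            "sigma": self.sigma,
            "adj_r2": self.adj_r2,
            "species": [
                {"load": pl, "area": area, "fraction": frac}
                for pl, area, frac in self.abundances
            ],
            "config_digest": self.config_digest,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_tsv(self) -> str:
        lines = ["load\tarea\tfraction"]
        lines += [
            f"{pl}\t{area:.6g}\t{frac:.6g}" for pl, area, frac in self.abundances
        ]
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        return f"HD={self.hd:.3f} sigma={self.sigma:.3f} adjR2={self.adj_r2:.5f}"


def report(
    result: DeconvolutionResult,
    sample_id: str = "",
    config_digest: str = "",
) -> HaptenDensityReport:
    """Assemble the hapten-density report from a deconvolution result."""
    if not result.peaks:
        raise FitError("deconvolution result contains no peaks")
    table = [(p.load, p.area) for p in result.peaks]
    hd = compute_hd(table)
    sigma = compute_dispersity(table)
    total = sum(area for _, area in table)
    abundances = [(pl, area, area / total) for pl, area in table]
    return HaptenDensityReport(
        hd=hd,
        sigma=sigma,
        adj_r2=result.adj_r2,
        abundances=abundances,
        sample_id=sample_id,
        config_digest=config_digest,
    )
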