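"""End-to-end convenience: preprocess, fit and report in one call."""

from __future__ import annotations

import numpy as np

from .hapten_metrics import HaptenDensityReport, report
from .ladder_deconv import (
    ConjugateLadder,
    DeconvolutionResult,
    FitConfig,
    fit_ladder,
)
from .preprocess import PreprocessConfig, preprocess, snip_iterations_for_fwhm
from .spectra_io import MassSpectrum


def _peak_fwhm_points(spectrum: MassSpectrum) -> float:
    """Half-height width, in points, of the tallest feature in the spectrum."""
    y = spectrum.intensity
    imax = int(np.argmax(y))
    half = y[imax] / 2.0
    left = imax
    while left > 0 and y[left] > half:
        left -= 1
    right = imax
    while right < y.size - 1 and y[right] > half:
        right += 1
    return max(right - left, 3)


def default_preprocess_config(spectrum: MassSpectrum) -> PreprocessConfig:
    """Data-driven defaults: SNIP half-window scaled to the peak width."""
    fwhm_pts = _peak_fwhm_points(spectrum)
    iters = snip_iterations_for_fwhm(fwhm_pts)
    iters = min(iters, (len(spectrum) - 1) // 2 - 1)
    return PreprocessConfig(snip_iterations=max(iters, 1))


def estimate_hapten_density(
    spectrum: MassSpectrum,
    ladder: ConjugateLadder,
    pre_config: PreprocessConfig | None = None,
    fit_config: FitConfig | None = None,
    sample_id: str = "",
    config_digest: str = "",
) -> tuple[HaptenDensityReport, DeconvolutionResult]:
    """Smooth, subtract the SNIP baseline, fit the ladder and report HD."""
    pre_config = pre_config or default_preprocess_config(spectrum)
    cleaned = preprocess(spectrum, pre_config)
    result = fit_ladder(cleaned, ladder, fit_config)
    rep = report(result, sample_id=sample_id, config_digest=config_digest)
    return rep, result
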