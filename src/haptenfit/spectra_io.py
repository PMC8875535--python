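"""Spectrum I/O, m/z calibration and generic peak-shape utilities.

A :class:`MassSpectrum` is the currency of the whole pipeline: a pair of
aligned arrays (m/z in Thomson, intensity in arbitrary counts) plus free-form
acquisition metadata.  Spectra are read from and written to either mzML
(single-spectrum documents) or two-column delimited text, the formats lab
instruments commonly export.

Calibration is defined on the m/z axis: a low-degree polynomial mapping the
observed positions of known calibrant ions (e.g. multiply charged BSA ions
spanning ~13-66 kDa) onto their theoretical m/z.  All downstream arithmetic
needs only a corrected m/z axis, so no time-of-flight physics is modelled.
"""

from __future__ import annotations

import base64
import re
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from lxml import etree

from .errors import CalibrationError, PeakShapeError, SpectrumIOError

#: Mass of a proton in Da, used for charge adduction (average-mass regime).
PROTON_MASS = 1.007276


@dataclass
class MassSpectrum:
    """A single mass spectrum: aligned m/z and intensity arrays.

    Parameters
    ----------
    mz :
        m/z values in Thomson, strictly increasing, finite and positive.
    intensity :
        Non-negative intensities (arbitrary units), same length as ``mz``.
    meta :
        Free-form acquisition metadata (instrument, laser events, calibration
        status, preprocessing provenance ...).
    """

    mz: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumIOError("mz and intensity must be 1-D arrays")
        if self.mz.size == 0:
            raise SpectrumIOError("empty spectrum")
        if self.mz.size != self.intensity.size:
            raise SpectrumIOError(
                f"length mismatch: {self.mz.size} m/z values vs "
                f"{self.intensity.size} intensities"
            )
        if not np.all(np.isfinite(self.mz)) or np.any(self.mz <= 0):
            raise SpectrumIOError("m/z values must be finite and positive")
        if not np.all(np.diff(self.mz) > 0):
            raise SpectrumIOError("m/z axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumIOError("intensities must be finite")

    def __len__(self) -> int:
        return int(self.mz.size)

    def copy(self, **overrides) -> "MassSpectrum":
        """Return a deep copy, optionally replacing fields."""
        kw = {
            "mz": self.mz.copy(),
            "intensity": self.intensity.copy(),
            "meta": dict(self.meta),
        }
        kw.update(overrides)
        return MassSpectrum(**kw)


@dataclass
class CalibrationModel:
    """Polynomial m/z correction fitted to calibrant ions.

    ``coefficients`` are in :func:`numpy.polyval` order (highest degree
    first) and map observed m/z to corrected m/z.  ``residuals`` holds the
    per-calibrant error (corrected observed minus reference, in Th).
    """

    degree: int
    coefficients: np.ndarray
    residuals: np.ndarray

    def apply(self, mz: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(mz, dtype=float))


# ---------------------------------------------------------------------------
# Text format
# ---------------------------------------------------------------------------

_NUMBER_SPLIT = re.compile(r"[,;\s]+")


def _parse_txt(path: Path) -> tuple[np.ndarray, np.ndarray]:
    values: list[float] = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise SpectrumIOError(f"cannot read {path}: {exc}") from exc
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        # tolerate tuple-style exports like "(100,1.0),(200,2.0)"
        line = line.replace("(", " ").replace(")", " ")
        tokens = [t for t in _NUMBER_SPLIT.split(line) if t]
        try:
            row = [float(t) for t in tokens]
        except ValueError as exc:
            raise SpectrumIOError(
                f"{path}:{lineno}: non-numeric value in {raw!r}"
            ) from exc
        if len(row) % 2 != 0:
            raise SpectrumIOError(
                f"{path}:{lineno}: expected (m/z, intensity) pairs, got "
                f"{len(row)} values"
            )
        values.extend(row)
    if not values:
        raise SpectrumIOError(f"{path}: no data rows")
    arr = np.asarray(values, dtype=float).reshape(-1, 2)
    return arr[:, 0], arr[:, 1]


def _write_txt(spectrum: MassSpectrum, path: Path) -> None:
    lines = ["# m/z\tintensity"]
    lines.extend(
        f"{mz:.10g}\t{inten:.10g}"
        for mz, inten in zip(spectrum.mz, spectrum.intensity)
    )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# mzML format
# ---------------------------------------------------------------------------
# Single-spectrum mzML documents, written and parsed with lxml.  Reading
# understands 64/32-bit float arrays with zlib or no compression — the
# encodings profile-mode exporters emit.

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *values)
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "") -> None:
    etree.SubElement(
        parent,
        "cvParam",
        cvRef="MS",
        accession=accession,
        name=name,
        value=value,
    )


def _write_mzml(spectrum: MassSpectrum, path: Path) -> None:
    root = etree.Element(
        "mzML", xmlns=_MZML_NS, version="1.1.0", id=path.stem or "spectrum"
    )
    cvlist = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cvlist,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = etree.SubElement(root, "run", id="run1")
    slist = etree.SubElement(
        run, "spectrumList", count="1", defaultDataProcessingRef="dp1"
    )
    spec = etree.SubElement(
        slist,
        "spectrum",
        index="0",
        id="scan=1",
        defaultArrayLength=str(len(spectrum)),
    )
    _cv(spec, "MS:1000128", "profile spectrum")
    _cv(spec, "MS:1000511", "ms level", "1")
    bal = etree.SubElement(spec, "binaryDataArrayList", count="2")
    for accession, name, values in (
        ("MS:1000514", "m/z array", spectrum.mz),
        ("MS:1000515", "intensity array", spectrum.intensity),
    ):
        encoded = _encode_array(values)
        bda = etree.SubElement(
            bal, "binaryDataArray", encodedLength=str(len(encoded))
        )
        _cv(bda, "MS:1000523", "64-bit float")
        _cv(bda, "MS:1000574", "zlib compression")
        _cv(bda, accession, name)
        binary = etree.SubElement(bda, "binary")
        binary.text = encoded
    path.write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="utf-8", pretty_print=True)
    )


def _decode_array(bda) -> np.ndarray:
    accessions = {
        cv.get("accession") for cv in bda.iter(f"{{{_MZML_NS}}}cvParam")
    } | {cv.get("accession") for cv in bda.iter("cvParam")}
    dtype = "<f8" if "MS:1000523" in accessions else "<f4"
    binary = bda.find(f"{{{_MZML_NS}}}binary")
    if binary is None:
        binary = bda.find("binary")
    if binary is None or not (binary.text or "").strip():
        return np.array([], dtype=float)
    raw = base64.b64decode(binary.text.strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> tuple[np.ndarray, np.ndarray, dict]:
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SpectrumIOError(f"cannot parse mzML file {path}: {exc}") from exc
    root = tree.getroot()
    spectra = root.findall(f".//{{{_MZML_NS}}}spectrum") or root.findall(
        ".//spectrum"
    )
    if not spectra:
        raise SpectrumIOError(f"{path}: mzML file contains no spectra")
    spec = spectra[0]
    mz = intensity = None
    arrays = spec.findall(f".//{{{_MZML_NS}}}binaryDataArray") or spec.findall(
        ".//binaryDataArray"
    )
    for bda in arrays:
        accessions = {cv.get("accession") for cv in bda.iter() if cv.tag.endswith("cvParam")}
        if "MS:1000514" in accessions:
            mz = _decode_array(bda)
        elif "MS:1000515" in accessions:
            intensity = _decode_array(bda)
    if mz is None or intensity is None:
        raise SpectrumIOError(f"{path}: spectrum lacks m/z or intensity arrays")
    return mz, intensity, {"source_format": "mzml"}


# ---------------------------------------------------------------------------
# Public I/O API
# ---------------------------------------------------------------------------


def _detect_format(path: Path) -> str:
    if path.suffix.lower() == ".mzml":
        return "mzml"
    return "txt"


def read_spectrum(path, format: str = "auto") -> MassSpectrum:
    """Read a spectrum from mzML or two-column delimited text.

    The returned spectrum always satisfies the :class:`MassSpectrum`
    invariants: unsorted input is sorted by m/z, duplicate m/z values are
    merged by summing their intensities (conserving total ion count), and
    negative intensities are clipped to zero (recorded in ``meta``).
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumIOError(f"no such file: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "txt":
        mz, intensity = _parse_txt(path)
        meta = {"source_format": "txt"}
    elif fmt == "mzml":
        mz, intensity, meta = _read_mzml(path)
    else:
        raise SpectrumIOError(f"unknown format {format!r}")
    if mz.size == 0:
        raise SpectrumIOError(f"{path}: empty spectrum")

    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    if uniq.size != mz.size:
        summed = np.zeros(uniq.size)
        np.add.at(summed, inverse, intensity)
        mz, intensity = uniq, summed
        meta["merged_duplicate_mz"] = True
    if np.any(intensity < 0):
        intensity = np.clip(intensity, 0.0, None)
        meta["clipped_negative_intensity"] = True
    meta["source_path"] = str(path)
    return MassSpectrum(mz=mz, intensity=intensity, meta=meta)


def write_spectrum(spectrum: MassSpectrum, path, format: str = "auto") -> None:
    """Write a spectrum to mzML or two-column text (round-trip safe)."""
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    try:
        if fmt == "txt":
            _write_txt(spectrum, path)
        elif fmt == "mzml":
            _write_mzml(spectrum, path)
        else:
            raise SpectrumIOError(f"unknown format {format!r}")
    except OSError as exc:
        raise SpectrumIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def reference_mz(neutral_mass: float, charge: int) -> float:
    """Theoretical m/z of an ion: (M + z * m_proton) / z."""
    if charge < 1:
        raise CalibrationError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def calibrate(
    spectrum: MassSpectrum,
    observed_peaks: Sequence[float],
    reference_masses: Sequence[tuple[float, int]],
    degree: int = 1,
) -> tuple[MassSpectrum, CalibrationModel]:
    """Fit a polynomial m/z correction against calibrant ions and apply it.

    Parameters
    ----------
    observed_peaks :
        Observed m/z positions of the calibrant ions in this spectrum.
    reference_masses :
        Matching ``(neutral mass in Da, charge)`` pairs; reference m/z is
        computed as ``(M + z * 1.007276) / z``.
    degree :
        Polynomial degree, 1 (affine) or 2.

    Returns the corrected spectrum and the fitted :class:`CalibrationModel`.
    """
    if degree not in (1, 2):
        raise CalibrationError(f"degree must be 1 or 2, got {degree}")
    observed = np.asarray(observed_peaks, dtype=float)
    if observed.size != len(reference_masses):
        raise CalibrationError(
            f"{observed.size} observed peaks but {len(reference_masses)} references"
        )
    if observed.size < degree + 1:
        raise CalibrationError(
            f"need at least {degree + 1} calibrants for degree {degree}, "
            f"got {observed.size}"
        )
    if np.unique(observed).size != observed.size:
        raise CalibrationError("duplicate observed calibrant positions")
    ref = np.array([reference_mz(m, z) for m, z in reference_masses])

    coeffs = np.polyfit(observed, ref, degree)
    residuals = np.polyval(coeffs, observed) - ref
    corrected_mz = np.polyval(coeffs, spectrum.mz)
    if not np.all(np.diff(corrected_mz) > 0):
        raise CalibrationError(
            "calibration polynomial is not monotone over the spectrum range"
        )
    meta = dict(spectrum.meta)
    meta["calibrated"] = True
    meta["calibration_residual_rms"] = float(np.sqrt(np.mean(residuals**2)))
    out = MassSpectrum(
        mz=corrected_mz, intensity=spectrum.intensity.copy(), meta=meta
    )
    return out, CalibrationModel(degree=degree, coefficients=coeffs, residuals=residuals)


# ---------------------------------------------------------------------------
# Peak shape
# ---------------------------------------------------------------------------


def fwhm(x, y) -> float:
    """Full width at half maximum of a single peak, by linear interpolation.

    The half level is ``b + (max - b) / 2`` with ``b = min(y[0], y[-1])``
    (the lower baseline endpoint), so the same routine applies to SEC traces
    and to mass peaks.  For a Gaussian of width sigma the result approaches
    ``2 * sqrt(2 * ln 2) * sigma ~= 2.3548 sigma`` as the grid refines.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise PeakShapeError("x and y must be equal-length arrays of >= 3 points")
    imax = int(np.argmax(y))
    ymax = y[imax]
    if imax == 0 or imax == y.size - 1 or ymax <= y[0] or ymax <= y[-1]:
        raise PeakShapeError(
            "no interior maximum strictly above both endpoints (monotone curve?)"
        )
    baseline = min(y[0], y[-1])
    half = baseline + 0.5 * (ymax - baseline)

    def _cross(idx_range) -> float:
        prev = imax
        for i in idx_range:
            if y[i] <= half:
                # linear interpolation between i and the previous point
                x0, x1, y0, y1 = x[i], x[prev], y[i], y[prev]
                if y1 == y0:
                    return float(x0)
                return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
            prev = i
        raise PeakShapeError("curve does not descend to half maximum on one side")

    left = _cross(range(imax - 1, -1, -1))
    right = _cross(range(imax + 1, y.size))
    return right - left
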