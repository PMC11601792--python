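"""MS/MS spectra: peak lists, the fixed 1000-bin log-scaled vectorization,
and readers/writers for the MGF and MSP text formats.

The binning pipeline turns a peak list into the 1000-dimensional input of the
spectral encoder: peaks at or above 1000 Da are dropped, intensities are
rescaled so the tallest surviving peak is 999 (the NIST convention), peaks
falling in the same 1-Da bin are summed, and each non-empty bin value v is
mapped to (1/3)*log10(v). Bin sums below 1 are clamped to 1 before the log so
the vector stays non-negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

N_BINS = 1000
MAX_INTENSITY = 999.0


class EmptySpectrumError(ValueError):
    """Raised when no peaks survive the m/z filter."""


class SpectrumFormatError(ValueError):
    """Raised on malformed MGF/MSP records."""


@dataclass
class Spectrum:
    """A centroided MS/MS peak list with acquisition metadata.

    peaks is an (n, 2) array of (m/z in Da, intensity in arbitrary counts).
    molecule_id links the spectrum to its target molecule when known; query
    spectra leave it None.
    """

    peaks: np.ndarray
    precursor_mz: float | None = None
    adduct: str = "[M+H]+"
    molecule_id: str | None = None
    spectrum_id: str | None = None
    collision_energy: float | None = None

    def __post_init__(self):
        self.peaks = np.atleast_2d(np.asarray(self.peaks, dtype=np.float64))
        if self.peaks.size == 0 or self.peaks.shape[1] != 2:
            raise ValueError("spectrum needs >=1 (mz, intensity) peak")
        if np.any(self.peaks[:, 0] <= 0):
            raise ValueError("all m/z values must be > 0")
        if np.any(self.peaks[:, 1] < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclass
class BinnedSpectrum:
    """The encoder input: 1000 non-negative reals, bin n covering [n, n+1) Da."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"binned spectrum must have length {N_BINS}")
        if np.any(self.values < 0):
            raise ValueError("binned values must be >= 0")


def bin_spectrum(spec: Spectrum, normalize_first: bool = True) -> BinnedSpectrum:
    """Vectorize a spectrum into 1000 one-Dalton bins with a log10/3 transform.

    With normalize_first (default), raw intensities are rescaled to a maximum
    of 999 before same-bin summation, which makes the output invariant to
    uniform intensity rescaling; the alternative sums first and then rescales
    the bin maxima.
    """
    keep = spec.mz < N_BINS
    if not np.any(keep):
        raise EmptySpectrumError(
            f"empty spectrum after filtering: all peaks >= {N_BINS} Da"
        )
    mz = spec.mz[keep]
    inten = spec.intensity[keep].astype(np.float64)
    if inten.max() <= 0:
        raise EmptySpectrumError("all surviving peaks have zero intensity")

    if normalize_first:
        inten = inten * (MAX_INTENSITY / inten.max())
    bins = np.floor(mz).astype(np.intp)
    summed = np.zeros(N_BINS)
    np.add.at(summed, bins, inten)
    if not normalize_first:
        summed *= MAX_INTENSITY / summed.max()

    nz = summed > 0
    vals = np.zeros(N_BINS)
    # clamp sub-1 sums to 1 so the log-scaled vector stays non-negative
    vals[nz] = np.log10(np.maximum(summed[nz], 1.0)) / 3.0
    return BinnedSpectrum(values=vals)


# --- MGF -------------------------------------------------------------------

def read_mgf(path) -> list:
    """Read an MGF file (BEGIN IONS/END IONS blocks) into Spectrum records.

    Blocks without peaks are skipped with a warning rather than failing the
    whole file.
    """
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for i, rec in enumerate(reader):
                params = rec.get("params", {})
                mzs = np.asarray(rec.get("m/z array", []), dtype=np.float64)
                if mzs.size == 0:
                    logger.warning("skipping peakless MGF block %d in %s", i, path)
                    continue
                intens = np.asarray(rec["intensity array"], dtype=np.float64)
                pepmass = params.get("pepmass")
                precursor = float(pepmass[0]) if pepmass else None
                ce = params.get("collision_energy")
                out.append(
                    Spectrum(
                        peaks=np.column_stack([mzs, intens]),
                        precursor_mz=precursor,
                        adduct=str(params.get("adduct", "[M+H]+")),
                        molecule_id=params.get("molecule_id"),
                        spectrum_id=str(params.get("title", f"spectrum_{i}")),
                        collision_energy=float(ce) if ce is not None else None,
                    )
                )
    return out


def write_mgf(spectra: list, path) -> None:
    records = []
    for i, s in enumerate(spectra):
        params = {"title": s.spectrum_id or f"spectrum_{i}", "adduct": s.adduct}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.molecule_id is not None:
            params["molecule_id"] = s.molecule_id
        if s.collision_energy is not None:
            params["collision_energy"] = s.collision_energy
        records.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(records, str(path), file_mode="w")


# --- MSP -------------------------------------------------------------------
# NIST MSP is a simple line-based format; the reader enforces the Num Peaks
# header and reports line numbers on malformed records.

def read_msp(path) -> list:
    out = []
    headers: dict = {}
    peaks: list = []
    n_expected = None
    start_line = 1

    def flush(line_no):
        nonlocal headers, peaks, n_expected
        if not headers and not peaks:
            return
        if n_expected is None:
            raise SpectrumFormatError(
                f"{path}: record starting at line {start_line} missing 'Num Peaks'"
            )
        if len(peaks) != n_expected:
            raise SpectrumFormatError(
                f"{path}: line {line_no}: expected {n_expected} peaks, got {len(peaks)}"
            )
        if peaks:
            prec = headers.get("precursormz")
            ce = headers.get("collision_energy") or headers.get("collisionenergy")
            out.append(
                Spectrum(
                    peaks=np.asarray(peaks),
                    precursor_mz=float(prec) if prec else None,
                    adduct=headers.get("precursor_type", headers.get("adduct", "[M+H]+")),
                    molecule_id=headers.get("molecule_id"),
                    spectrum_id=headers.get("name", f"spectrum_{len(out)}"),
                    collision_energy=float(ce) if ce else None,
                )
            )
        else:
            logger.warning("skipping peakless MSP record at line %d in %s", start_line, path)
        headers, peaks, n_expected = {}, [], None

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush(line_no)
                start_line = line_no + 1
                continue
            if ":" in line and not line.split(":", 1)[0].replace(".", "").isdigit():
                key, val = line.split(":", 1)
                key = key.strip().lower().replace(" ", "_")
                val = val.strip()
                if key == "num_peaks":
                    try:
                        n_expected = int(val)
                    except ValueError as e:
                        raise SpectrumFormatError(
                            f"{path}: line {line_no}: bad Num Peaks value {val!r}"
                        ) from e
                else:
                    headers[key] = val
            else:
                parts = line.replace(",", " ").split()
                try:
                    mz, inten = float(parts[0]), float(parts[1])
                except (IndexError, ValueError) as e:
                    raise SpectrumFormatError(
                        f"{path}: line {line_no}: malformed peak line {line!r}"
                    ) from e
                peaks.append((mz, inten))  # extra annotation columns ignored
    flush(line_no if "line_no" in dir() else 1)
    return out


def write_msp(spectra: list, path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(spectra):
            fh.write(f"Name: {s.spectrum_id or f'spectrum_{i}'}\n")
            if s.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {s.precursor_mz:.5f}\n")
            fh.write(f"Precursor_type: {s.adduct}\n")
            if s.molecule_id is not None:
                fh.write(f"molecule_id: {s.molecule_id}\n")
            if s.collision_energy is not None:
                fh.write(f"Collision_energy: {s.collision_energy}\n")
            fh.write(f"Num Peaks: {len(s.peaks)}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.5f} {inten:.4f}\n")
            fh.write("\n")


def write_binned_matrix(binned: list, ids: list, path) -> None:
    """Dump binned vectors as a dense TSV (rows: spectra) for debugging."""
    with open(path, "w") as fh:
        fh.write("spectrum_id\t" + "\t".join(f"bin{i}" for i in range(N_BINS)) + "\n")
        for sid, b in zip(ids, binned):
            fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in b.values) + "\n")
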