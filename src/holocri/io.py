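"""File formats: TIFF for images/fields, CSV for curves and spectra.

Complex fields are stored as two-page float64 TIFFs (real, imaginary)
with acquisition metadata in the image description (JSON), so write/read
round trips are bit-exact.  CSV numeric precision is 17 significant
digits (float64 round-trippable).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidArgumentError
from .types import (ComplexFieldImage, ComplexIndex, CRISpectrum, Hologram,
                    ImageGrid, ScatteringCurve)

__all__ = [
    "write_field_tiff", "read_field_tiff",
    "write_hologram_tiff", "read_hologram_tiff",
    "write_curve_csv", "read_curve_csv",
    "write_cri_spectrum_csv", "read_cri_spectrum_csv",
]

_FMT = "%.17g"


def _grid_meta(grid: ImageGrid) -> dict:
    return {
        "n_pixels": grid.n_pixels,
        "pixel_pitch_um": grid.pixel_pitch_um,
        "numerical_aperture": grid.numerical_aperture,
    }


def _grid_from_meta(meta: dict) -> ImageGrid:
    return ImageGrid(int(meta["n_pixels"]), float(meta["pixel_pitch_um"]),
                     float(meta["numerical_aperture"]))


def write_field_tiff(field: ComplexFieldImage, path) -> None:
    meta = {"kind": "complex_field", "wavelength_nm": field.wavelength_nm,
            **_grid_meta(field.grid)}
    pages = np.stack([field.field.real, field.field.imag]).astype(np.float64)
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_field_tiff(path) -> ComplexFieldImage:
    with tifffile.TiffFile(path) as tif:
        meta = json.loads(tif.pages[0].description)
        pages = tif.asarray()
    if meta.get("kind") != "complex_field" or pages.shape[0] != 2:
        raise InvalidArgumentError(f"{path}: not a two-page complex-field TIFF")
    return ComplexFieldImage(pages[0] + 1j * pages[1], _grid_from_meta(meta),
                             float(meta["wavelength_nm"]))


def write_hologram_tiff(holo: Hologram, path) -> None:
    meta = {"kind": "hologram", "wavelength_nm": holo.wavelength_nm,
            "carrier": list(holo.carrier),
            "reference_amplitude": holo.reference_amplitude,
            **_grid_meta(holo.grid)}
    tifffile.imwrite(path, np.asarray(holo.intensity, np.float64),
                     description=json.dumps(meta))


def read_hologram_tiff(path) -> Hologram:
    with tifffile.TiffFile(path) as tif:
        meta = json.loads(tif.pages[0].description)
        arr = tif.asarray()
    if meta.get("kind") != "hologram":
        raise InvalidArgumentError(f"{path}: not a hologram TIFF")
    return Hologram(arr, tuple(meta["carrier"]), float(meta["reference_amplitude"]),
                    _grid_from_meta(meta), float(meta["wavelength_nm"]))


def write_curve_csv(curve: ScatteringCurve, path) -> None:
    cols = {"n_sin_theta": curve.axis, "intensity": curve.intensity}
    if curve.counts is not None:
        cols["counts"] = curve.counts
    if curve.bin_lo is not None:
        cols["bin_lo"] = curve.bin_lo
    df = pd.DataFrame(cols)
    if curve.bin_width is not None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# bin_width = {curve.bin_width!r}\n")
            df.to_csv(fh, index=False, float_format=_FMT)
    else:
        df.to_csv(path, index=False, float_format=_FMT)


def read_curve_csv(path) -> ScatteringCurve:
    path = Path(path)
    bin_width = None
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        try:
            bin_width = float(first.split("=")[1])
        except (IndexError, ValueError) as exc:
            raise InvalidArgumentError(
                f"{path}: malformed bin_width header line") from exc
    df = pd.read_csv(path, skiprows=skip)
    for col in ("n_sin_theta", "intensity"):
        if col not in df:
            raise InvalidArgumentError(f"{path}: missing column {col!r}")
    return ScatteringCurve(
        axis=df["n_sin_theta"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        counts=df["counts"].to_numpy() if "counts" in df else None,
        bin_width=bin_width,
        bin_lo=df["bin_lo"].to_numpy() if "bin_lo" in df else None,
    )


def write_cri_spectrum_csv(spectrum: CRISpectrum, path) -> None:
    df = pd.DataFrame({
        "wavelength_nm": spectrum.wavelengths_nm,
        "n": spectrum.n,
        "kappa": spectrum.kappa,
        "sd_n": spectrum.sd_n if spectrum.sd_n is not None
        else np.zeros(len(spectrum.indices)),
        "sd_kappa": spectrum.sd_kappa if spectrum.sd_kappa is not None
        else np.zeros(len(spectrum.indices)),
    })
    df.to_csv(path, index=False, float_format=_FMT)


def read_cri_spectrum_csv(path) -> CRISpectrum:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "n", "kappa"):
        if col not in df:
            raise InvalidArgumentError(f"{path}: missing column {col!r}")
    indices = tuple(ComplexIndex(float(r["n"]), max(float(r["kappa"]), 0.0))
                    for _, r in df.iterrows())
    return CRISpectrum(
        df["wavelength_nm"].to_numpy(), indices,
        df["sd_n"].to_numpy() if "sd_n" in df else None,
        df["sd_kappa"].to_numpy() if "sd_kappa" in df else None,
    )
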