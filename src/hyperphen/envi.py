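"""ENVI-style hypercube I/O and radiometric calibration.

Push-broom hyperspectral cameras emit raw digital numbers (DN) line by
line; this module stores such cubes in the ENVI interchange dialect
(ASCII ``.hdr`` header + flat binary) and converts DN to absolute
radiance using per-band gain/offset/dark-frame calibration profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "Unit",
    "Interleave",
    "HyperCube",
    "CalibrationProfile",
    "read_envi_cube",
    "write_envi_cube",
    "calibrate_to_radiance",
    "EnviFormatError",
]


class Unit(str, Enum):
    DN = "DN"
    RADIANCE = "radiance"
    REFLECTANCE = "reflectance"


class Interleave(str, Enum):
    BIL = "bil"  # band-interleaved-by-line: (lines, bands, samples)
    BIP = "bip"  # band-interleaved-by-pixel: (lines, samples, bands)
    BSQ = "bsq"  # band-sequential: (bands, lines, samples)


class EnviFormatError(ValueError):
    """Raised for malformed or inconsistent ENVI header/binary pairs."""


# ENVI "data type" codes for the dtypes this module writes/reads.
_ENVI_DTYPES = {
    1: np.dtype("uint8"),
    2: np.dtype("int16"),
    3: np.dtype("int32"),
    4: np.dtype("float32"),
    5: np.dtype("float64"),
    12: np.dtype("uint16"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """A 3-D spectral image: two spatial axes and one spectral axis.

    ``data`` is always held in-memory as (lines, samples, bands)
    regardless of the on-disk interleave.
    """

    data: np.ndarray  # (lines, samples, bands), non-negative
    wavelengths_nm: np.ndarray  # strictly increasing, length = bands
    unit: Unit = Unit.DN
    camera_id: str = ""
    interleave: Interleave = Interleave.BIL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.unit = Unit(self.unit)
        self.interleave = Interleave(self.interleave)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, samples, bands)")
        if self.wavelengths_nm.shape != (self.data.shape[2],):
            raise ValueError(
                f"wavelength vector length {self.wavelengths_nm.size} != "
                f"band count {self.data.shape[2]}"
            )
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    def pixel_matrix(self) -> np.ndarray:
        """Flatten to (lines*samples, bands) — the per-pixel spectra."""
        return self.data.reshape(-1, self.bands)


@dataclass
class CalibrationProfile:
    """Radiometric calibration: DN -> radiance.

    gain has units of radiance per DN per unit integration time; shapes
    are per-band ``(bands,)`` or per-band-per-sample ``(samples, bands)``
    (manufacturer profiles come in either shape).
    """

    gain: np.ndarray
    offset: np.ndarray | float = 0.0
    dark_frame: np.ndarray | float = 0.0
    integration_time: float = 1.0  # ms

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        self.dark_frame = np.asarray(self.dark_frame, dtype=float)
        if np.any(self.gain <= 0):
            raise ValueError("gain must be strictly positive everywhere")
        if self.integration_time <= 0:
            raise ValueError("integration_time must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationProfile":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            gain=np.asarray(d["gain"], dtype=float),
            offset=np.asarray(d.get("offset", 0.0), dtype=float),
            dark_frame=np.asarray(d.get("dark_frame", 0.0), dtype=float),
            integration_time=float(d.get("integration_time", 1.0)),
        )

    def to_json(self, path: str | Path) -> Path:
        d = {
            "gain": np.asarray(self.gain).tolist(),
            "offset": np.asarray(self.offset).tolist(),
            "dark_frame": np.asarray(self.dark_frame).tolist(),
            "integration_time": self.integration_time,
        }
        path = Path(path)
        path.write_text(json.dumps(d))
        return path


# ---------------------------------------------------------------------------
# ENVI header + flat binary I/O


def _format_header(cube: HyperCube, dtype: np.dtype) -> str:
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths_nm)
    lines = [
        "ENVI",
        f"samples = {cube.samples}",
        f"lines = {cube.lines}",
        f"bands = {cube.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[dtype]}",
        f"interleave = {cube.interleave.value}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"unit = {cube.unit.value}",
        f"camera id = {cube.camera_id}",
        "wavelength = { " + wl + " }",
    ]
    return "\n".join(lines) + "\n"


def _parse_header(text: str) -> dict:
    """Parse ENVI header key = value pairs; {}-values may span lines."""
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError("not an ENVI header (missing ENVI magic)")
    # join brace-delimited multi-line values
    body = text.split("ENVI", 1)[1]
    out: dict[str, str] = {}
    buf = ""
    key = None
    for raw in body.splitlines():
        line = raw.strip()
        if key is None:
            if "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            if val.startswith("{") and "}" not in val:
                buf = val
                continue
            out[key.lower()] = val
            key = None
        else:
            buf += " " + line
            if "}" in line:
                out[key.lower()] = buf
                key, buf = None, ""
    return out


def write_envi_cube(cube: HyperCube, header_path: str | Path) -> Path:
    """Write ``cube`` as ENVI header + flat binary next to it.

    Raw DN cubes are stored as unsigned 16-bit, everything else as
    32-bit floats; round trip is lossless at that precision.
    Returns the header path; the binary drops the ``.hdr`` suffix.
    """
    header_path = Path(header_path)
    if cube.unit is Unit.DN and np.issubdtype(cube.data.dtype, np.integer):
        dtype = np.dtype("uint16")
    else:
        dtype = np.dtype("float32")
    data = cube.data
    if cube.interleave is Interleave.BIL:
        disk = np.transpose(data, (0, 2, 1))  # lines, bands, samples
    elif cube.interleave is Interleave.BSQ:
        disk = np.transpose(data, (2, 0, 1))  # bands, lines, samples
    else:
        disk = data
    header_path.write_text(_format_header(cube, dtype))
    bin_path = header_path.with_suffix("") if header_path.suffix == ".hdr" else (
        header_path.parent / (header_path.name + ".img")
    )
    np.ascontiguousarray(disk).astype(dtype).tofile(bin_path)
    return header_path


def read_envi_cube(header_path: str | Path) -> HyperCube:
    """Read an ENVI header + flat binary pair written by this module
    (or any conforming writer carrying a wavelength list)."""
    header_path = Path(header_path)
    hdr = _parse_header(header_path.read_text())
    try:
        samples = int(hdr["samples"])
        lines = int(hdr["lines"])
        bands = int(hdr["bands"])
        dtype = _ENVI_DTYPES[int(hdr["data type"])]
        interleave = Interleave(hdr["interleave"].lower())
    except (KeyError, ValueError) as exc:
        raise EnviFormatError(f"missing/invalid header field: {exc}") from exc
    if "wavelength" not in hdr:
        raise EnviFormatError("header carries no wavelength list")
    wl_text = hdr["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array(
        [float(t) for t in wl_text.replace(",", " ").split()], dtype=float
    )
    if wavelengths.size != bands:
        raise EnviFormatError(
            f"header wavelength count {wavelengths.size} != bands {bands}"
        )
    bin_path = header_path.with_suffix("")
    if not bin_path.exists():
        alt = header_path.parent / (header_path.name + ".img")
        if alt.exists():
            bin_path = alt
        else:
            raise EnviFormatError(f"binary file for {header_path} not found")
    raw = np.fromfile(bin_path, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"binary holds {raw.size} values, header implies {expected}"
        )
    if interleave is Interleave.BIL:
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave is Interleave.BSQ:
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        data = raw.reshape(lines, samples, bands)
    unit = Unit(hdr.get("unit", "DN"))
    return HyperCube(
        data=np.ascontiguousarray(data),
        wavelengths_nm=wavelengths,
        unit=unit,
        camera_id=hdr.get("camera id", ""),
        interleave=interleave,
    )


# ---------------------------------------------------------------------------
# Radiometric calibration


def calibrate_to_radiance(
    raw: HyperCube, cal: CalibrationProfile
) -> HyperCube:
    """Convert a raw-DN cube to absolute radiance.

    L = (DN - dark_frame) * gain / integration_time + offset, clipped
    below at zero (a detector cannot report negative radiance).
    Wavelengths and spatial layout are unchanged.
    """
    if raw.unit is not Unit.DN:
        raise ValueError(f"cube unit is {raw.unit.value!r}, expected DN")
    dn = raw.data.astype(np.float64)
    # calibration arrays broadcast as (bands,) or (samples, bands)
    # against data of shape (lines, samples, bands)
    radiance = (dn - cal.dark_frame) * cal.gain / cal.integration_time
    radiance = radiance + cal.offset
    np.clip(radiance, 0.0, None, out=radiance)
    # float64 in memory; write_envi_cube stores calibrated cubes as float32
    return replace(raw, data=radiance, unit=Unit.RADIANCE)
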