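"""Containers and ASCII I/O for scattering curves and QENS spectra.

Curves are 3-column ASCII (q, I, sigma) with ``#`` comment/header lines;
header keys use the form ``# key: value``.  A ``# units:`` line records the
q unit.  Metadata needed to interpret the curve (slit smearing flag and the
vertical slit half-width) is carried in header keys and round-trips through
read/write.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SASCurve", "QENSSpectrum", "read_sas", "write_sas",
           "read_qens", "write_qens"]


@dataclass
class SASCurve:
    """One-dimensional scattering intensity vs momentum transfer.

    q is strictly increasing and positive (reciprocal ångström unless the
    ``units`` metadata says otherwise); ``sigma`` is the 1-sigma uncertainty
    on I.  ``smeared`` flags slit-smeared (Bonse-Hart) data; ``dq_v`` is the
    vertical slit half-width in the same reciprocal unit as q and is
    required when ``smeared`` is set.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    smeared: bool = False
    dq_v: float | None = None
    units: str = "1/A"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or len(self.q) == 0:
            raise ValueError("q must be a non-empty 1-d array")
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise ValueError("q, I, sigma must have equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("I must be finite")
        if self.smeared and self.dq_v is None:
            raise ValueError("smeared curves require dq_v")

    def __len__(self):
        return len(self.q)

    def copy_with(self, **kw):
        return replace(self, **kw)


@dataclass
class QENSSpectrum:
    """S(q, omega) at one scattering vector with its resolution spectrum.

    ``omega`` is the energy-transfer grid in µeV (strictly increasing,
    roughly symmetric about zero); ``resolution`` is a companion spectrum
    measured on a vanadium-like standard, tabulated on the same grid and
    normalized to unit area on it.
    """

    q: float
    omega: np.ndarray
    S: np.ndarray
    sigma: np.ndarray
    resolution: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be strictly increasing")
        if not (len(self.omega) == len(self.S) == len(self.sigma)):
            raise ValueError("omega, S, sigma must have equal length")
        if self.resolution is not None:
            self.resolution = np.asarray(self.resolution, dtype=float)
            if len(self.resolution) != len(self.omega):
                raise ValueError("resolution must share the omega grid")
            area = np.trapezoid(self.resolution, self.omega)
            if not area > 0:
                raise ValueError("resolution spectrum has non-positive area")
            if abs(area - 1.0) > 1e-6:
                self.resolution = self.resolution / area


_HEADER_RE = re.compile(r"#\s*([A-Za-z_][\w.]*)\s*[:=]\s*(.*\S)\s*$")

_BOOL = {"true": True, "false": False, "yes": True, "no": False}


def _parse_header_value(v: str):
    lv = v.strip().lower()
    if lv in _BOOL:
        return _BOOL[lv]
    try:
        return int(v)
    except ValueError:
        pass
    try:
        return float(v)
    except ValueError:
        return v.strip()


def _read_table(path_or_buf):
    """Parse `#`-headed ASCII with whitespace and/or comma delimiters."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
        name = "<buffer>"
    else:
        name = str(path_or_buf)
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    header, rows = {}, []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _HEADER_RE.match(line)
            if m:
                header[m.group(1)] = _parse_header_value(m.group(2))
            continue
        parts = re.split(r"[,\s]+", line)
        try:
            rows.append([float(p) for p in parts if p])
        except ValueError as exc:
            raise ValueError(f"{name}: malformed row at line {ln}: {raw!r}") from exc
    if not rows:
        raise ValueError(f"{name}: no data rows found (empty input)")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise ValueError(f"{name}: inconsistent column counts {sorted(ncols)}")
    return header, np.asarray(rows, dtype=float)


def read_sas(path, sigma_frac_if_missing=0.05):
    """Read a 3-column (q, I, sigma) ASCII curve.

    A missing sigma column is imputed as ``sigma_frac_if_missing * |I|``
    and flagged in ``meta['sigma_imputed']``.
    """
    header, arr = _read_table(path)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 numeric columns")
    q, I = arr[:, 0], arr[:, 1]
    imputed = arr.shape[1] < 3
    sigma = sigma_frac_if_missing * np.abs(I) if imputed else arr[:, 2]
    known = {"smeared", "dq_v", "units"}
    meta = {k: v for k, v in header.items() if k not in known}
    if imputed:
        meta["sigma_imputed"] = True
    return SASCurve(q=q, I=I, sigma=sigma,
                    smeared=bool(header.get("smeared", False)),
                    dq_v=header.get("dq_v"),
                    units=str(header.get("units", "1/A")),
                    meta=meta)


def write_sas(curve: SASCurve, path):
    with open(path, "w") as fh:
        fh.write(f"# units: {curve.units}\n")
        fh.write(f"# smeared: {str(curve.smeared).lower()}\n")
        if curve.dq_v is not None:
            fh.write(f"# dq_v: {curve.dq_v!r}\n")
        for k, v in curve.meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("# columns: q I sigma\n")
        for q, i, s in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{q:.12e} {i:.12e} {s:.12e}\n")


def read_qens(path, resolution=None):
    """Read one per-q QENS spectrum: columns (omega, S, sigma), `# q=` header."""
    header, arr = _read_table(path)
    if arr.shape[1] < 3:
        raise ValueError(f"{path}: need 3 numeric columns (omega, S, sigma)")
    if "q" not in header:
        raise ValueError(f"{path}: missing '# q = ...' header")
    meta = {k: v for k, v in header.items() if k not in {"q", "units"}}
    return QENSSpectrum(q=float(header["q"]), omega=arr[:, 0], S=arr[:, 1],
                        sigma=arr[:, 2], resolution=resolution, meta=meta)


def write_qens(spec: QENSSpectrum, path):
    with open(path, "w") as fh:
        fh.write(f"# q: {spec.q!r}\n")
        fh.write("# units: ueV\n")
        for k, v in spec.meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("# columns: omega S sigma\n")
        for w, s, e in zip(spec.omega, spec.S, spec.sigma):
            fh.write(f"{w:.10e} {s:.10e} {e:.10e}\n")
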