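"""Peak-height-ratio quantification of binary drug co-formulations from ATR-FTIR spectra.

This module implements, end to end, a univariate calibration workflow for the
simultaneous determination of two co-formulated active pharmaceutical
ingredients (APIs) — piperacillin (PIP) and tazobactam (TAZ) — from attenuated
total reflectance (ATR) infrared absorbance spectra of analyte films:

1.  **Spectra** — an ordered (wavenumber, absorbance) carrier with CSV and
    JCAMP-DX (subset) readers and linear resampling.
2.  **Ratio statistic** — baseline-anchored peak heights at 873 cm⁻¹ (TAZ
    marker) and 890 cm⁻¹ (PIP reference), with the single straight baseline
    anchored at 862 and 905 cm⁻¹, and the height ratio I(873)/I(890).
3.  **Calibration** — the closed-mixture transform x = 100/C_PIP linearizes
    the ratio for a binary mixture with closure C_PIP + C_TAZ = 100 % w/w;
    ordinary least squares gives y = b·x + a; inverse prediction, delta-method
    uncertainty, replicate RSD, and blank-based LOD/LOQ complete the
    statistics.
4.  **Synthetic data** — a seeded Beer–Lambert generator of pseudo-Voigt film
    spectra whose anchor-band amplitudes are derived algebraically from a
    target calibration line, with multiplicative film-deposition scatter,
    linear drift, and additive noise.
5.  **Pipeline** — manifest-driven ``calibrate`` / ``quantify`` / ``simulate``
    commands (thin CLI in :mod:`atrquant.__main__`).

All compositions are percent weight/weight (% w/w); wavenumbers are cm⁻¹;
absorbance is in absorbance units (a.u.).
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import math
import re
import warnings
from dataclasses import dataclass, field, asdict, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    # spectra
    "Spectrum", "RatioConfig", "PeakHeight", "PeakTable", "MarkerReport",
    "read_spectrum", "write_spectrum", "resample",
    "corrected_heights", "ratio_statistic", "match_reference_peaks",
    # calibration
    "StandardRecord", "CalibrationModel", "QuantResult", "BlankStats",
    "DetectionLimits", "ReplicateSummary",
    "composition_transform", "fit_calibration", "predict_ratio",
    "invert_to_composition", "replicate_summary", "propagate_uncertainty",
    "estimate_detection_limits",
    # synthetic data
    "Band", "GeneratorConfig", "default_band_tables",
    "derive_anchor_amplitudes", "pseudo_voigt",
    "synth_component_spectrum", "synth_mixture_replicates",
    "synth_blank_pip_films", "calibrate_additive_noise_sd",
    # pipeline
    "RunConfig", "Manifest", "read_manifest",
    "cmd_calibrate", "cmd_quantify", "cmd_simulate",
    "save_model", "load_model",
]

__version__ = "0.1.0"

logger = logging.getLogger("atrquant")

# --------------------------------------------------------------------------
# Configuration constants (package-wide defaults)
# --------------------------------------------------------------------------

#: Ratio-denominator floor below which the PIP reference peak is deemed absent.
DENOMINATOR_FLOOR = 1e-12

#: Characteristic mid-IR band positions (cm⁻¹) of the pure APIs, used both for
#: qualitative peak matching and as the synthetic generator's band inventory.
PIP_PEAK_POSITIONS = (728.0, 762.0, 850.0, 890.0, 1072.0, 1094.0,
                      1461.0, 1602.0, 1713.0, 1764.0)
TAZ_PEAK_POSITIONS = (1135.0, 1191.0, 1232.0, 1312.0, 1385.0, 1452.0, 1616.0)

#: Positions where TAZ admixture enhances the PIP-dominated spectrum
#: (intensity enhancement markers), 873 cm⁻¹ being the quantification band.
TAZ_MARKER_POSITIONS = (873.0, 945.0, 1023.0, 1081.0, 1135.0)

#: Published calibration-line parameters used as the generator's default
#: anchor target: ratio = SLOPE·(100/C_PIP) + INTERCEPT.
REFERENCE_SLOPE = 2.74
REFERENCE_INTERCEPT = -2.52

_UTC = timezone.utc


def _utcnow() -> str:
    return datetime.now(_UTC).isoformat(timespec="seconds")


# ==========================================================================
# Section 1 — Spectrum data model and file I/O
# ==========================================================================

@dataclass(frozen=True)
class Spectrum:
    """An infrared absorbance spectrum on a strictly increasing wavenumber grid.

    Parameters
    ----------
    wavenumbers : ndarray
        Strictly increasing grid in cm⁻¹ (descending input is normalized by
        the readers / constructor helper).
    absorbance : ndarray
        Absorbance values (a.u.), same length as ``wavenumbers``, all finite.
    meta : dict
        Free-form metadata (sample id, replicate index, role, resolution …).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise ValueError("wavenumbers and absorbance must be 1-D and equal length")
        if w.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if w[0] > w[-1]:  # normalize descending instrument exports
            w, a = w[::-1].copy(), a[::-1].copy()
        d = np.diff(w)
        if np.any(d <= 0):
            idx = int(np.argmax(d <= 0))
            raise ValueError(
                f"wavenumber grid not strictly increasing near index {idx} "
                f"(duplicate or unordered value {w[idx + 1]:g} cm-1)")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(a))):
            raise ValueError("non-finite values in spectrum")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavenumbers[0] <= lo and hi <= self.wavenumbers[-1]

    def interp(self, nu: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of absorbance at wavenumber(s) ``nu``."""
        return np.interp(nu, self.wavenumbers, self.absorbance)

    def scaled(self, g: float) -> "Spectrum":
        return Spectrum(self.wavenumbers, g * self.absorbance, dict(self.meta))


_NUMERIC_ROW = re.compile(r"^\s*[-+0-9.eEdD]")


def _parse_csv_xy(text: str, source: str) -> Spectrum:
    meta: dict = {"source": source, "dialect": "csv-xy"}
    xs: list[float] = []
    ys: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            # capture "# key: value" comments as metadata
            body = line.lstrip("#").strip()
            if ":" in body:
                k, _, v = body.partition(":")
                meta.setdefault(k.strip(), v.strip())
            continue
        parts = re.split(r"[,\t;]+|\s{1,}", line)
        parts = [p for p in parts if p]
        if len(parts) < 2:
            raise ValueError(f"{source}: line {lineno}: expected two columns, got {line!r}")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError:
            if not header_seen and not xs and not _NUMERIC_ROW.match(line):
                header_seen = True  # one optional header line
                continue
            raise ValueError(f"{source}: line {lineno}: non-numeric row {line!r}") from None
        xs.append(x)
        ys.append(y)
    if len(xs) < 2:
        raise ValueError(f"{source}: fewer than 2 numeric rows")
    w = np.array(xs)
    if len(np.unique(w)) != len(w):
        dup = w[np.isin(w, w[pd.Index(w).duplicated()])][0]
        row = int(np.where(w == dup)[0][1]) + 1
        raise ValueError(f"{source}: duplicate wavenumber {dup:g} at data row {row}")
    return Spectrum(w, np.array(ys), meta)


def _parse_jcamp_subset(text: str, source: str) -> Spectrum:
    """Minimal JCAMP-DX reader for uncompressed ``XYDATA=(X++(Y..Y))`` records.

    Supports AFFN (plain decimal) ordinates with the standard affine decoding
    ``x = FIRSTX + i*DELTAX`` (or XFACTOR-scaled abscissa), ``y = y_raw*YFACTOR``.
    Compressed forms (SQZ/DIF/DUP/PAC) and multi-block files are rejected.
    """
    meta: dict = {"source": source, "dialect": "jcamp-subset"}
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.split("$$")[0].strip()
            if label == "XYDATA":
                if value.replace(" ", "") != "(X++(Y..Y))":
                    raise ValueError(f"{source}: unsupported XYDATA form {value!r}")
                in_data = True
                continue
            if in_data and label in ("END", "ENDBLOCK"):
                in_data = False
            labels[label] = value
        elif in_data:
            if re.search(r"[A-DF-Za-df-z%@]", line.replace("E", "").replace("e", "")):
                raise ValueError(f"{source}: compressed JCAMP ordinates are not supported")
            data_lines.append(line)
    if not data_lines:
        raise ValueError(f"{source}: no XYDATA=(X++(Y..Y)) table found")
    yfactor = float(labels.get("YFACTOR", 1.0))
    xfactor = float(labels.get("XFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        vals = [float(v) for v in re.split(r"[,\s]+", line) if v]
        if len(vals) < 2:
            raise ValueError(f"{source}: short XYDATA line {line!r}")
        x0 = vals[0] * xfactor
        npts_before = len(ys)
        ys.extend(v * yfactor for v in vals[1:])
        xs.append((x0, npts_before))
    npoints = int(float(labels["NPOINTS"])) if "NPOINTS" in labels else len(ys)
    firstx = float(labels.get("FIRSTX", xs[0][0]))
    lastx = float(labels.get("LASTX", 0.0)) if "LASTX" in labels else None
    if "DELTAX" in labels:
        deltax = float(labels["DELTAX"])
    elif lastx is not None and npoints > 1:
        deltax = (lastx - firstx) / (npoints - 1)
    else:
        raise ValueError(f"{source}: cannot determine DELTAX")
    if len(ys) != npoints:
        raise ValueError(f"{source}: NPOINTS={npoints} but decoded {len(ys)} ordinates")
    w = firstx + deltax * np.arange(npoints)
    for title_key in ("TITLE", "SAMPLEID"):
        if title_key in labels:
            meta[title_key.lower()] = labels[title_key]
    return Spectrum(w, np.array(ys), meta)


def read_spectrum(path: str | Path, dialect: str = "csv-xy") -> Spectrum:
    """Read one spectrum file.

    Parameters
    ----------
    path : path
        Existing file with at least two parseable numeric rows.
    dialect : {"csv-xy", "jcamp-subset"}
        ``csv-xy``: two numeric columns (comma/tab/whitespace separated),
        optional single header line, ``#`` comment lines.
        ``jcamp-subset``: uncompressed JCAMP-DX ``XYDATA=(X++(Y..Y))``.

    Returns
    -------
    Spectrum
        With an ascending grid; descending input is reversed.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"spectrum file not found: {p}")
    text = p.read_text()
    if dialect == "csv-xy":
        return _parse_csv_xy(text, str(p))
    if dialect == "jcamp-subset":
        return _parse_jcamp_subset(text, str(p))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as csv-xy with metadata in ``# key: value`` comments.

    Round-trips bit-compatibly through :func:`read_spectrum` (repr-exact
    floats).
    """
    p = Path(path)
    buf = io.StringIO()
    for k, v in s.meta.items():
        if k in ("source", "dialect"):
            continue
        buf.write(f"# {k}: {v}\n")
    buf.write("wavenumber_cm-1,absorbance\n")
    for x, y in zip(s.wavenumbers, s.absorbance):
        buf.write(f"{float(x)!r},{float(y)!r}\n")
    p.write_text(buf.getvalue())


def resample(s: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Linearly interpolate ``s`` onto an increasing target grid.

    The target must lie within the spectrum's range; extrapolation is refused.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 1:
        raise ValueError("target grid must be a 1-D sequence")
    if g.size > 1 and np.any(np.diff(g) <= 0):
        raise ValueError("target grid must be strictly increasing")
    lo, hi = s.range
    if g[0] < lo or g[-1] > hi:
        raise ValueError(
            f"resample target [{g[0]:g}, {g[-1]:g}] outside spectrum range [{lo:g}, {hi:g}]")
    a = np.interp(g, s.wavenumbers, s.absorbance)
    if g.size == 1:  # Spectrum requires >= 2 points; not constructible
        raise ValueError("target grid must contain at least 2 points for a Spectrum")
    return Spectrum(g, a, dict(s.meta))


# ==========================================================================
# Section 2 — Anchored baseline, peak heights, ratio statistic
# ==========================================================================

@dataclass(frozen=True)
class RatioConfig:
    """Definition of the I(873)/I(890) peak-height-ratio statistic.

    A single straight baseline is anchored at ``baseline_left`` /
    ``baseline_right`` (862–905 cm⁻¹ by default, bracketing both peaks); each
    peak height is the maximum of the baseline-corrected absorbance within
    ``apex_halfwidth`` of its nominal position (the instrument resolution,
    4 cm⁻¹, by default).
    """

    numerator_position: float = 873.0
    denominator_position: float = 890.0
    baseline_left: float = 862.0
    baseline_right: float = 905.0
    apex_halfwidth: float = 4.0

    def __post_init__(self) -> None:
        if not (self.baseline_left < self.numerator_position
                < self.denominator_position < self.baseline_right):
            raise ValueError(
                "require baseline_left < numerator < denominator < baseline_right")
        if self.apex_halfwidth <= 0:
            raise ValueError("apex_halfwidth must be positive")
        if (self.numerator_position + self.apex_halfwidth
                >= self.denominator_position - self.apex_halfwidth):
            raise ValueError("numerator and denominator apex windows overlap")


@dataclass(frozen=True)
class PeakHeight:
    """Baseline-corrected height of one peak and the apex wavenumber used."""

    height: float
    apex: float
    detected: bool  # False when the whole corrected window is <= 0


def corrected_heights(
    s: Spectrum,
    cfg: RatioConfig = RatioConfig(),
    positions: Sequence[float] | None = None,
    mode: str = "apex",
) -> dict[float, PeakHeight]:
    """Baseline-anchored peak heights.

    The baseline B(ν) is the straight line through
    ``(baseline_left, A(baseline_left))`` and ``(baseline_right,
    A(baseline_right))``, the anchor absorbances being linearly interpolated
    from the bracketing grid points. For each target position the height is

    * ``mode="apex"`` (default): the maximum of A(ν) − B(ν) over grid points
      in the closed window ``position ± apex_halfwidth`` (robust to small band
      shifts; the apex position used is reported), or
    * ``mode="fixed"``: A(ν) − B(ν) interpolated exactly at the nominal
      position.

    A window whose corrected values are all ≤ 0 is reported with
    ``detected=False`` and a warning, not clipped.
    """
    if positions is None:
        positions = (cfg.numerator_position, cfg.denominator_position)
    if mode not in ("apex", "fixed"):
        raise ValueError(f"unknown height mode {mode!r}")
    if not s.covers(cfg.baseline_left, cfg.baseline_right):
        raise ValueError(
            f"spectrum range {s.range} does not cover baseline window "
            f"[{cfg.baseline_left:g}, {cfg.baseline_right:g}]")
    spacing = float(np.max(np.diff(s.wavenumbers)))
    if spacing > cfg.apex_halfwidth:
        raise ValueError(
            f"grid spacing {spacing:g} cm-1 exceeds apex_halfwidth "
            f"{cfg.apex_halfwidth:g} cm-1")
    xl, xr = cfg.baseline_left, cfg.baseline_right
    al = float(s.interp(xl))
    ar = float(s.interp(xr))
    slope = (ar - al) / (xr - xl)

    def baseline(nu: np.ndarray | float) -> np.ndarray | float:
        return al + slope * (np.asarray(nu) - xl)

    out: dict[float, PeakHeight] = {}
    for pos in positions:
        lo, hi = pos - cfg.apex_halfwidth, pos + cfg.apex_halfwidth
        if not s.covers(lo, hi):
            raise ValueError(f"spectrum does not cover search window [{lo:g}, {hi:g}]")
        if mode == "fixed":
            h = float(s.interp(pos) - baseline(pos))
            apex = float(pos)
        else:
            sel = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
            corr = s.absorbance[sel] - baseline(s.wavenumbers[sel])
            k = int(np.argmax(corr))
            h = float(corr[k])
            apex = float(s.wavenumbers[sel][k])
        detected = h > 0
        if not detected:
            warnings.warn(
                f"peak at {pos:g} cm-1 not detected (corrected height {h:.3g} <= 0)",
                stacklevel=2)
        out[float(pos)] = PeakHeight(h, apex, detected)
    return out


def ratio_statistic(
    heights: Mapping[float, PeakHeight],
    cfg: RatioConfig = RatioConfig(),
    floor: float = DENOMINATOR_FLOOR,
) -> float:
    """The peak-height ratio I(numerator)/I(denominator).

    Raises if the denominator (PIP reference) height is at or below ``floor``.
    """
    num = heights[cfg.numerator_position].height
    den = heights[cfg.denominator_position].height
    if den <= floor:
        raise ValueError(
            f"denominator peak absent: height {den:.3g} at "
            f"{cfg.denominator_position:g} cm-1 <= floor {floor:g}")
    return num / den


def spectrum_ratio(s: Spectrum, cfg: RatioConfig = RatioConfig(),
                   mode: str = "apex") -> float:
    """Convenience: corrected heights then ratio statistic for one spectrum."""
    return ratio_statistic(corrected_heights(s, cfg, mode=mode), cfg)


# ==========================================================================
# Section 3 — Qualitative peak matching (identification)
# ==========================================================================

@dataclass(frozen=True)
class PeakTable:
    """Reference peak positions per API for qualitative identification.

    ``entries`` are ``(api_label, position_cm-1, weight)`` rows; positions are
    matched to detected local maxima within ``match_tolerance`` cm⁻¹.
    """

    entries: tuple[tuple[str, float, float], ...] = tuple(
        [("PIP", p, 1.0) for p in PIP_PEAK_POSITIONS]
        + [("TAZ", p, 1.0) for p in TAZ_PEAK_POSITIONS]
    )
    match_tolerance: float = 4.0

    def __post_init__(self) -> None:
        for api, pos, _w in self.entries:
            if api not in ("PIP", "TAZ"):
                raise ValueError(f"unknown API label {api!r}")
            if pos <= 0:
                raise ValueError(f"non-positive peak position {pos!r}")
        if self.match_tolerance <= 0:
            raise ValueError("match_tolerance must be positive")

    def positions(self, api: str) -> list[float]:
        return [p for a, p, _ in self.entries if a == api]


@dataclass(frozen=True)
class MarkerReport:
    """Result of qualitative matching plus the TAZ-presence ratio test."""

    matched_positions: dict[str, list[float]]
    match_fraction: dict[str, float]
    taz_marker_ratio: float  # I(873)/I(890); NaN if the 890 peak is absent
    taz_flag: bool

    def to_json(self, **kw) -> str:
        d = asdict(self)
        d["taz_marker_ratio"] = (None if math.isnan(self.taz_marker_ratio)
                                 else self.taz_marker_ratio)
        return json.dumps(d, **kw)


def _noise_scale(a: np.ndarray) -> float:
    """Noise estimate: median absolute successive difference of absorbance."""
    return float(np.median(np.abs(np.diff(a))))


def match_reference_peaks(
    s: Spectrum,
    table: PeakTable = PeakTable(),
    cfg: RatioConfig = RatioConfig(),
    threshold: float = 0.27,
) -> MarkerReport:
    """Match detected local maxima to reference peak positions per API.

    Local maxima of the raw absorbance are accepted when their prominence is
    at least 3× a noise scale (median absolute successive difference); each
    reference position counts as matched when a detected maximum lies within
    ``table.match_tolerance``. The TAZ flag is raised when the I(873)/I(890)
    ratio statistic exceeds ``threshold`` (default 0.27: the pure-PIP ratio
    implied by the reference calibration line plus a blank-based margin, cf.
    :func:`estimate_detection_limits`).
    """
    from scipy.signal import find_peaks

    all_pos = [p for _a, p, _w in table.entries]
    lo, hi = min(all_pos), max(all_pos)
    if not s.covers(lo, hi):
        raise ValueError(
            f"spectrum range {s.range} too short for peak table span [{lo:g}, {hi:g}]")
    prom = 3.0 * _noise_scale(s.absorbance)
    peaks, _props = find_peaks(s.absorbance, prominence=max(prom, 1e-300))
    peak_nu = s.wavenumbers[peaks]
    matched: dict[str, list[float]] = {}
    frac: dict[str, float] = {}
    for api in ("PIP", "TAZ"):
        targets = table.positions(api)
        got = [t for t in targets
               if peak_nu.size and np.min(np.abs(peak_nu - t)) <= table.match_tolerance]
        matched[api] = got
        frac[api] = len(got) / len(targets) if targets else 0.0
    try:
        ratio = spectrum_ratio(s, cfg)
    except ValueError:
        ratio = float("nan")  # 890 reference absent: cannot assert TAZ presence
    flag = bool(ratio > threshold) if math.isfinite(ratio) else False
    return MarkerReport(matched, frac, ratio, flag)


# ==========================================================================
# Section 4 — Calibration statistics
# ==========================================================================

@dataclass(frozen=True)
class StandardRecord:
    """One calibration standard: known composition plus replicate ratios."""

    c_pip: float
    c_taz: float
    replicate_ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(self.c_pip + self.c_taz - 100.0) > 1e-9:
            raise ValueError(
                f"closure violated: c_pip + c_taz = {self.c_pip + self.c_taz!r} != 100")
        if not (0 < self.c_pip < 100):
            raise ValueError("standard c_pip must lie strictly inside (0, 100) % w/w")
        if len(self.replicate_ratios) < 1:
            raise ValueError("at least one replicate ratio required")
        object.__setattr__(self, "replicate_ratios",
                           tuple(float(r) for r in self.replicate_ratios))


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted calibration line ratio = b·(100/C_PIP) + a with OLS statistics.

    ``se_slope`` / ``se_intercept`` / ``residual_sd`` are NaN for an exact
    two-point fit (no residual degrees of freedom).
    """

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float
    residual_sd: float
    n_points: int
    fit_mode: str = "on_replicates"
    ratio_config: RatioConfig = RatioConfig()

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a calibration line needs at least 2 points")
        if math.isfinite(self.r_squared) and not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean / sd / RSD% / standard error of replicate ratio measurements."""

    mean: float
    sd: float        # NaN with n == 1
    rsd_pct: float   # NaN when undefined (n == 1, or mean == 0 with sd > 0)
    se: float        # sd / sqrt(n); NaN with n == 1
    n: int


@dataclass(frozen=True)
class BlankStats:
    """Ratio statistics of blank (pure-PIP film) measurements."""

    mean_ratio: float
    sd_ratio: float
    n_blanks: int

    def __post_init__(self) -> None:
        if self.n_blanks < 2:
            raise ValueError("blank sd requires n_blanks >= 2")
        if self.sd_ratio < 0:
            raise ValueError("sd_ratio must be >= 0")


@dataclass(frozen=True)
class DetectionLimits:
    """Blank-based detection and quantification limits for TAZ (% w/w)."""

    lod_taz: float
    loq_taz: float
    k_detect: float = 3.0
    loq_factor: float = 3.0
    method: str = "blank_k_sigma/factor"


@dataclass(frozen=True)
class QuantResult:
    """Recovered composition of one unknown sample with uncertainty.

    Closure holds exactly: ``c_pip_hat + c_taz_hat == 100`` and the standard
    deviations of the two contents are equal by construction.
    """

    sample_id: str
    c_pip_hat: float
    c_taz_hat: float
    sd: float            # common sd of both contents; NaN if undefined
    mean_ratio: float
    ratio_rsd_pct: float
    n_replicates: int
    warnings: tuple[str, ...] = ()


def composition_transform(c_pip: float) -> float:
    """Closed-mixture linearizing transform x = 100 / C_PIP (C_PIP in % w/w)."""
    if c_pip <= 0:
        raise ValueError(f"c_pip must be positive, got {c_pip!r}")
    if c_pip > 100:
        raise ValueError(f"c_pip exceeds 100 % w/w: {c_pip!r}")
    return 100.0 / c_pip


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, ...]:
    """Closed-form simple linear regression with standard errors.

    Returns (b, a, se_b, se_a, r2, s, n). For n == 2 the fit is exact and
    se/s are NaN.
    """
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("all x values identical: calibration design is degenerate")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    b = sxy / sxx
    a = ybar - b * xbar
    res = y - (a + b * x)
    ssres = float((res ** 2).sum())
    sstot = float(((y - ybar) ** 2).sum())
    r2 = 1.0 if sstot == 0.0 and ssres == 0.0 else 1.0 - ssres / sstot
    if n > 2:
        s2 = ssres / (n - 2)
        s = math.sqrt(s2)
        se_b = math.sqrt(s2 / sxx)
        se_a = s * math.sqrt(1.0 / n + xbar ** 2 / sxx)
    else:
        s = se_b = se_a = float("nan")
    return b, a, se_b, se_a, r2, s, n


def fit_calibration(
    standards: Sequence[StandardRecord],
    mode: str = "on_replicates",
    ratio_config: RatioConfig = RatioConfig(),
) -> CalibrationModel:
    """Ordinary least-squares calibration of ratio against x = 100/C_PIP.

    ``mode="on_means"`` regresses the per-standard mean replicate ratio on x
    (one point per standard, mirroring a printed calibration table);
    ``mode="on_replicates"`` uses every replicate film as a point. Standard
    errors follow the textbook formulas se_b = s/√Sxx and
    se_a = s·√(1/n + x̄²/Sxx) with s² = SSres/(n−2).

    Fewer than 3 distinct compositions is permitted (n = 2 gives an exact
    line) but the standard errors are then NaN and a warning is issued.
    """
    if mode not in ("on_means", "on_replicates"):
        raise ValueError(f"unknown fit mode {mode!r}")
    if not standards:
        raise ValueError("no calibration standards supplied")
    xs: list[float] = []
    ys: list[float] = []
    for rec in standards:
        x = composition_transform(rec.c_pip)
        if mode == "on_means":
            xs.append(x)
            ys.append(float(np.mean(rec.replicate_ratios)))
        else:
            for r in rec.replicate_ratios:
                xs.append(x)
                ys.append(r)
    x = np.asarray(xs)
    y = np.asarray(ys)
    n_distinct = len({round(v, 12) for v in xs})
    if n_distinct < 3:
        warnings.warn(
            f"only {n_distinct} distinct compositions: standard errors are "
            "undefined or unreliable", stacklevel=2)
    b, a, se_b, se_a, r2, s, n = _ols_line(x, y)
    return CalibrationModel(b, a, se_b, se_a, r2, s, n,
                            fit_mode=mode, ratio_config=ratio_config)


def predict_ratio(m: CalibrationModel, c_pip: float) -> float:
    """Forward prediction: expected I(873)/I(890) at composition ``c_pip``."""
    return m.slope * composition_transform(c_pip) + m.intercept


def invert_to_composition(
    m: CalibrationModel, mean_ratio: float
) -> tuple[float, float, list[str]]:
    """Inverse prediction with closure.

    Solves y = b·(100/C_PIP) + a for C_PIP = 100·b/(y − a) and sets
    C_TAZ = 100 − C_PIP. A ratio at or below the intercept has no positive
    solution and raises; a recovered C_PIP above 100 (ratio below the
    pure-PIP calibration point) is returned but flagged as extrapolation.

    Returns
    -------
    (c_pip, c_taz, warnings)
    """
    y = float(mean_ratio)
    if y <= m.intercept:
        raise ValueError(
            f"ratio {y:g} at or below calibration intercept {m.intercept:g}: "
            "no positive composition solution")
    c_pip = 100.0 * m.slope / (y - m.intercept)
    warns: list[str] = []
    if c_pip > 100.0:
        warns.append(
            f"extrapolation: recovered c_pip {c_pip:.2f} > 100 % w/w "
            "(ratio below the pure-PIP calibration point)")
    if not (0.0 < c_pip):
        raise ValueError(f"recovered c_pip {c_pip:g} outside (0, 100]")
    return c_pip, 100.0 - c_pip, warns


def replicate_summary(ratios: Sequence[float]) -> ReplicateSummary:
    """Mean, sample (n−1) sd, RSD% and standard error of replicate ratios."""
    r = np.asarray(ratios, dtype=float)
    if r.size < 1:
        raise ValueError("at least one replicate required")
    mean = float(r.mean())
    if r.size >= 2:
        sd = float(r.std(ddof=1))
        se = sd / math.sqrt(r.size)
        if mean == 0.0 and sd > 0.0:
            rsd = float("nan")
        else:
            rsd = 100.0 * sd / mean if mean != 0.0 else 0.0
    else:
        sd = se = rsd = float("nan")
    return ReplicateSummary(mean, sd, rsd, se, int(r.size))


def propagate_uncertainty(
    m: CalibrationModel,
    summary: ReplicateSummary,
    mode: str = "replicate",
) -> float:
    """First-order (delta-method) sd of the recovered C_PIP.

    With C(y) = 100·b/(y − a), the replicate-only mode propagates the standard
    error of the mean ratio through |dC/dy| = 100·b/(ȳ − a)²:

        sd(C_PIP) = 100·b/(ȳ − a)² · se(ȳ).

    ``mode="extended"`` additionally folds in the calibration parameter
    uncertainties to first order (independence assumed):

        var(C) = (dC/db)²·se_b² + (dC/da)²·se_a² + (dC/dy)²·se_ȳ²,
        dC/db = 100/(ȳ − a),  dC/da = +100·b/(ȳ − a)²,  dC/dy = −100·b/(ȳ − a)².

    By closure, sd(C_TAZ) = sd(C_PIP).
    """
    if mode not in ("replicate", "extended"):
        raise ValueError(f"unknown uncertainty mode {mode!r}")
    ybar = summary.mean
    if ybar <= m.intercept:
        raise ValueError("mean ratio at or below intercept: inversion undefined")
    d = ybar - m.intercept
    dcdy = 100.0 * m.slope / d ** 2
    var = (dcdy * summary.se) ** 2
    if mode == "extended":
        dcdb = 100.0 / d
        dcda = 100.0 * m.slope / d ** 2
        var += (dcdb * m.se_slope) ** 2 + (dcda * m.se_intercept) ** 2
    return math.sqrt(var)


def quantify_sample(
    m: CalibrationModel,
    ratios: Sequence[float],
    sample_id: str = "unknown",
    uncertainty_mode: str = "replicate",
    calibrated_taz_range: tuple[float, float] = (5.0, 50.0),
) -> QuantResult:
    """Full inverse prediction for one unknown: mean ratio → composition ± sd.

    Compositions outside the calibrated TAZ range are allowed but flagged
    with a range warning.
    """
    summ = replicate_summary(ratios)
    c_pip, c_taz, warns = invert_to_composition(m, summ.mean)
    if math.isfinite(summ.se):
        sd = propagate_uncertainty(m, summ, mode=uncertainty_mode)
    else:
        sd = float("nan")
        warns.append("single replicate: sd undefined")
    lo, hi = calibrated_taz_range
    if not (lo <= c_taz <= hi):
        warns.append(
            f"recovered TAZ content {c_taz:.2f} % w/w outside calibrated "
            f"range [{lo:g}, {hi:g}] % w/w")
    return QuantResult(sample_id, c_pip, c_taz, sd, summ.mean, summ.rsd_pct,
                       summ.n, tuple(warns))


def estimate_detection_limits(
    m: CalibrationModel,
    blanks: BlankStats,
    k_detect: float = 3.0,
    loq_factor: float = 3.0,
    loq_mode: str = "factor",
    k_quant: float = 10.0,
) -> DetectionLimits:
    """Blank-based LOD/LOQ for TAZ via the calibration line.

    The decision ratio is y_D = ȳ_b + k_detect·s_b; inverting it through the
    calibration line gives the smallest distinguishable TAZ content
    LOD = 100 − C_PIP(y_D). In factor mode (default) LOQ = loq_factor·LOD;
    in ratio mode LOQ is obtained by inverting y_Q = ȳ_b + k_quant·s_b.
    """
    if loq_mode not in ("factor", "ratio"):
        raise ValueError(f"unknown loq_mode {loq_mode!r}")
    y_d = blanks.mean_ratio + k_detect * blanks.sd_ratio
    c_pip_d, _c_taz, _w = invert_to_composition(m, y_d)
    lod = 100.0 - min(c_pip_d, 100.0)
    if loq_mode == "factor":
        loq = loq_factor * lod
        method = "blank_k_sigma/factor"
    else:
        y_q = blanks.mean_ratio + k_quant * blanks.sd_ratio
        c_pip_q, _, _ = invert_to_composition(m, y_q)
        loq = 100.0 - min(c_pip_q, 100.0)
        method = "blank_k_sigma/ratio"
    return DetectionLimits(lod, loq, k_detect, loq_factor, method)


# ==========================================================================
# Section 5 — Synthetic spectrum generator (Beer–Lambert film model)
# ==========================================================================

@dataclass(frozen=True)
class Band:
    """One pseudo-Voigt absorption band (unit-height at the center)."""

    center: float
    amplitude: float
    fwhm: float = 6.0
    eta: float = 0.7  # Lorentzian fraction

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be > 0")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")


def pseudo_voigt(nu: np.ndarray, center: float, fwhm: float,
                 eta: float = 0.7) -> np.ndarray:
    """Unit-height pseudo-Voigt profile η·L + (1−η)·G.

    L(ν) = 1/(1 + (2(ν−c)/fwhm)²) and G(ν) = exp(−4 ln2 ((ν−c)/fwhm)²), both
    unit height with the common full width at half maximum ``fwhm``.
    """
    t = (np.asarray(nu, dtype=float) - center) / fwhm
    lor = 1.0 / (1.0 + 4.0 * t * t)
    gau = np.exp(-4.0 * math.log(2.0) * t * t)
    return eta * lor + (1.0 - eta) * gau


def derive_anchor_amplitudes(b: float, a: float) -> tuple[float, float, float, float]:
    """Anchor-band amplitudes that make the generator reproduce a target line.

    Under Beer–Lambert mixing with closure, zero TAZ response at 890 cm⁻¹
    (T890 = 0) and the PIP 890 band as unit normalization (P890 = 1), the
    noiseless mixture ratio is

        y = (P873 − T873) + T873 · (100 / C_PIP),

    so matching y = b·x + a requires T873 = b and P873 = a + b (the pure-PIP
    ratio). Returns ``(P873, P890, T873, T890) = (a + b, 1, b, 0)``.
    """
    if b <= 0:
        raise ValueError("slope b must be positive")
    if a + b <= 0:
        raise ValueError(
            f"infeasible pure-PIP ratio a + b = {a + b:g} <= 0")
    return (a + b, 1.0, b, 0.0)


def default_band_tables(
    slope: float = REFERENCE_SLOPE,
    intercept: float = REFERENCE_INTERCEPT,
    fwhm: float = 6.0,
    eta: float = 0.7,
) -> dict[str, tuple[Band, ...]]:
    """Band inventories for the two pure APIs.

    Only the four anchor amplitudes (PIP/TAZ at 873 and 890 cm⁻¹) are
    calibrated — to the target calibration line via
    :func:`derive_anchor_amplitudes`. The remaining amplitudes are fixed
    plausible constants: the characteristic positions are tabulated for the
    real compounds but their relative intensities are not, so these spectra
    are structurally, not spectroscopically, faithful.
    """
    p873, p890, t873, t890 = derive_anchor_amplitudes(slope, intercept)
    pip_amp = {728.0: 0.45, 762.0: 0.35, 850.0: 0.40, 1072.0: 0.30,
               1094.0: 0.35, 1461.0: 0.50, 1602.0: 0.55, 1713.0: 0.70,
               1764.0: 0.60}
    taz_amp = {1135.0: 0.90, 1191.0: 0.60, 1232.0: 0.50, 1312.0: 0.45,
               1385.0: 0.55, 1452.0: 0.40, 1616.0: 0.65,
               # TAZ contributions at the enhancement-marker positions
               945.0: 0.50, 1023.0: 0.45, 1081.0: 0.55}
    pip = [Band(873.0, p873, fwhm, eta), Band(890.0, p890, fwhm, eta)]
    pip += [Band(c, amp, fwhm, eta) for c, amp in sorted(pip_amp.items())]
    taz = [Band(873.0, t873, fwhm, eta)]
    if t890 > 0:
        taz.append(Band(890.0, t890, fwhm, eta))
    taz += [Band(c, amp, fwhm, eta) for c, amp in sorted(taz_amp.items())]
    return {"PIP": tuple(sorted(pip, key=lambda b: b.center)),
            "TAZ": tuple(sorted(taz, key=lambda b: b.center))}


#: Additive noise sd (a.u.) calibrated once so that 3-replicate ratio RSD at
#: the 10:90 TAZ:PIP composition falls in the 2–4 % band typical of replicate
#: film depositions; see calibrate_additive_noise_sd().
DEFAULT_ADDITIVE_NOISE_SD = 0.012


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic film-spectrum generator settings.

    The replicate model is

        M(ν) = g·[C_PIP·R_PIP(ν) + C_TAZ·R_TAZ(ν)]/100 + d(ν) + ε(ν)

    with g ~ lognormal(0, σ_g) the film-deposition scale (non-uniform analyte
    deposition changes the effective optical path multiplicatively — the ratio
    statistic is designed to cancel it), d(ν) a gentle random straight
    baseline drift, and ε i.i.d. Gaussian noise.
    """

    band_tables: dict[str, tuple[Band, ...]] = field(
        default_factory=default_band_tables)
    grid_start: float = 600.0
    grid_stop: float = 4000.0
    grid_step: float = 1.0
    film_scale_sd: float = 0.2
    additive_noise_sd: float = DEFAULT_ADDITIVE_NOISE_SD
    drift_slope_range: float = 2e-5   # a.u. per cm⁻¹
    drift_offset_range: float = 0.01  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("film_scale_sd", "additive_noise_sd",
                     "drift_slope_range", "drift_offset_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.grid_step <= 0 or self.grid_stop <= self.grid_start:
            raise ValueError("invalid grid definition")
        if self.grid_start > 862.0 or self.grid_stop < 905.0:
            raise ValueError("grid must cover the 862-905 cm-1 baseline window")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    def noiseless(self) -> "GeneratorConfig":
        return replace(self, film_scale_sd=0.0, additive_noise_sd=0.0,
                       drift_slope_range=0.0, drift_offset_range=0.0)


def synth_component_spectrum(api: str, cfg: GeneratorConfig) -> Spectrum:
    """Noiseless pure-component reference spectrum R_api(ν) (per 100 % w/w)."""
    if api not in cfg.band_tables or not cfg.band_tables[api]:
        raise ValueError(f"no band table for API {api!r}")
    nu = cfg.grid
    a = np.zeros_like(nu)
    for band in cfg.band_tables[api]:
        a += band.amplitude * pseudo_voigt(nu, band.center, band.fwhm, band.eta)
    return Spectrum(nu, a, {"sample_id": f"pure_{api}", "role": "component",
                            "api": api})


def _replicate_rng(cfg: GeneratorConfig, c_pip: float, rep: int,
                   tag: int) -> np.random.Generator:
    # deterministic per (seed, composition, replicate, stream tag)
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, tag,
                                int(round(c_pip * 1000)), rep]))


def synth_mixture_replicates(
    c_pip: float,
    c_taz: float,
    n_reps: int,
    cfg: GeneratorConfig,
    sample_id: str | None = None,
    _tag: int = 1,
) -> list[Spectrum]:
    """Seeded replicate film spectra of a closed binary mixture.

    Each replicate draws its own film scale g ~ lognormal(0, σ_g), linear
    drift line, and additive Gaussian noise; replicates are seeded
    deterministically per (seed, composition, replicate index).
    """
    if abs(c_pip + c_taz - 100.0) > 1e-9:
        raise ValueError(f"closure violated: {c_pip} + {c_taz} != 100")
    if not (0.0 <= c_pip <= 100.0):
        raise ValueError("c_pip must lie in [0, 100] % w/w")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    r_pip = synth_component_spectrum("PIP", cfg).absorbance
    r_taz = synth_component_spectrum("TAZ", cfg).absorbance
    nu = cfg.grid
    clean = (c_pip * r_pip + c_taz * r_taz) / 100.0
    sid = sample_id or f"mix_{c_taz:g}_{c_pip:g}"
    out: list[Spectrum] = []
    for rep in range(n_reps):
        rng = _replicate_rng(cfg, c_pip, rep, _tag)
        g = float(rng.lognormal(0.0, cfg.film_scale_sd)) if cfg.film_scale_sd else 1.0
        d1 = rng.uniform(-cfg.drift_slope_range, cfg.drift_slope_range)
        d0 = rng.uniform(-cfg.drift_offset_range, cfg.drift_offset_range)
        eps = (rng.normal(0.0, cfg.additive_noise_sd, nu.size)
               if cfg.additive_noise_sd else 0.0)
        a = g * clean + d0 + d1 * (nu - nu[0]) + eps
        out.append(Spectrum(nu, a, {
            "sample_id": sid, "replicate": rep, "c_pip": c_pip, "c_taz": c_taz,
            "resolution_cm-1": cfg.grid_step}))
    return out


def synth_blank_pip_films(n: int, cfg: GeneratorConfig) -> list[Spectrum]:
    """Blank films: pure PIP (C_PIP = 100 % w/w) under the full noise model.

    Their ratio statistics define :class:`BlankStats` for the detection-limit
    estimate; at least 2 films are required for a defined blank sd.
    """
    if n < 2:
        raise ValueError("need n >= 2 blank films for a defined sd")
    return synth_mixture_replicates(100.0, 0.0, n, cfg, sample_id="blank_PIP",
                                    _tag=2)


def calibrate_additive_noise_sd(
    target_rsd_pct: float = 3.0,
    c_taz: float = 10.0,
    n_sets: int = 200,
    seed: int = 123,
) -> float:
    """One-off calibration of the default additive noise scale.

    Finds the additive noise sd for which the expected 3-replicate ratio RSD
    at the ``c_taz``:PIP composition equals ``target_rsd_pct`` (bisection on
    the mean RSD over ``n_sets`` seeded replicate triples). This reproduces
    the shipped :data:`DEFAULT_ADDITIVE_NOISE_SD`; it is not called at
    runtime.
    """
    rc = RatioConfig()

    def mean_rsd(sd: float) -> float:
        cfg = GeneratorConfig(additive_noise_sd=sd, seed=seed)
        vals = []
        for k in range(n_sets):
            reps = synth_mixture_replicates(100.0 - c_taz, c_taz, 3,
                                            replace(cfg, seed=seed + k))
            ratios = [spectrum_ratio(s, rc) for s in reps]
            vals.append(replicate_summary(ratios).rsd_pct)
        return float(np.mean(vals))

    lo, hi = 1e-4, 0.05
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        if mean_rsd(mid) < target_rsd_pct:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ==========================================================================
# Section 6 — Pipeline: manifest, run configuration, commands
# ==========================================================================

MANIFEST_COLUMNS = ("spectrum_path", "sample_id", "role", "c_pip", "c_taz",
                    "replicate_index")
_ROLES = ("standard", "blank", "unknown")


@dataclass
class Manifest:
    """Validated sample manifest: one row per spectrum file."""

    rows: pd.DataFrame
    base_dir: Path

    def paths(self) -> list[Path]:
        return [self.base_dir / p for p in self.rows["spectrum_path"]]


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate a delimited-text manifest.

    Columns: ``spectrum_path, sample_id, role, c_pip, c_taz,
    replicate_index``; roles are standard/blank/unknown. Standards must carry
    a closed composition (c_pip + c_taz = 100); unknowns must carry none.
    Paths are resolved relative to the manifest's directory.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"manifest not found: {p}")
    df = pd.read_csv(p, sep=None, engine="python", comment="#",
                     skip_blank_lines=True)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{p}: manifest missing columns {missing}")
    df = df.loc[:, list(MANIFEST_COLUMNS)].copy()
    bad_roles = sorted(set(df["role"]) - set(_ROLES))
    if bad_roles:
        raise ValueError(f"{p}: unknown roles {bad_roles}; expected {_ROLES}")
    for i, row in df.iterrows():
        has_comp = pd.notna(row["c_pip"]) and pd.notna(row["c_taz"])
        if row["role"] == "standard":
            if not has_comp:
                raise ValueError(f"{p}: standard row {i} lacks a composition")
            if abs(float(row["c_pip"]) + float(row["c_taz"]) - 100.0) > 1e-6:
                raise ValueError(f"{p}: standard row {i} violates closure")
        elif row["role"] == "unknown" and has_comp:
            raise ValueError(f"{p}: unknown row {i} must not carry a composition")
        fp = p.parent / str(row["spectrum_path"])
        if not fp.is_file():
            raise FileNotFoundError(f"{p}: row {i}: spectrum file missing: {fp}")
    return Manifest(df, p.parent)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings; defaults reproduce the reference method."""

    ratio: RatioConfig = RatioConfig()
    fit_mode: str = "on_replicates"
    height_mode: str = "apex"
    k_detect: float = 3.0
    loq_factor: float = 3.0
    loq_mode: str = "factor"
    uncertainty_mode: str = "replicate"
    calibrated_taz_range: tuple[float, float] = (5.0, 50.0)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.fit_mode not in ("on_means", "on_replicates"):
            raise ValueError(f"unknown fit_mode {self.fit_mode!r}")
        if self.height_mode not in ("apex", "fixed"):
            raise ValueError(f"unknown height_mode {self.height_mode!r}")
        if self.uncertainty_mode not in ("replicate", "extended"):
            raise ValueError(f"unknown uncertainty_mode {self.uncertainty_mode!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        ratio_keys = {"numerator_position", "denominator_position",
                      "baseline_left", "baseline_right", "apex_halfwidth"}
        ratio_kw = {k: raw.pop(k) for k in list(raw) if k in ratio_keys}
        if "ratio" in raw:
            ratio_kw.update(raw.pop("ratio") or {})
        if "calibrated_taz_range" in raw:
            raw["calibrated_taz_range"] = tuple(raw["calibrated_taz_range"])
        known = {"fit_mode", "height_mode", "k_detect", "loq_factor",
                 "loq_mode", "uncertainty_mode", "calibrated_taz_range",
                 "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(ratio=RatioConfig(**ratio_kw), **raw)


def _sha256_of(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _model_dict(m: CalibrationModel) -> dict:
    d = asdict(m)
    d["ratio_config"] = asdict(m.ratio_config)
    return d


def save_model(m: CalibrationModel, path: str | Path) -> None:
    """Serialize a CalibrationModel to JSON (full precision, reloadable)."""
    d = _model_dict(m)
    payload = {"model": d, "model_hash": _sha256_of(d),
               "package_version": __version__, "created": _utcnow()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_model(path: str | Path) -> CalibrationModel:
    payload = json.loads(Path(path).read_text())
    d = dict(payload["model"])
    d["ratio_config"] = RatioConfig(**d["ratio_config"])
    return CalibrationModel(**d)


def _ratios_by_sample(
    manifest: Manifest, role: str, cfg: RunConfig
) -> dict[str, dict]:
    """Per-sample replicate ratio lists for rows of the given role."""
    rows = manifest.rows[manifest.rows["role"] == role]
    out: dict[str, dict] = {}
    for _, row in rows.iterrows():
        s = read_spectrum(manifest.base_dir / str(row["spectrum_path"]))
        ratio = spectrum_ratio(s, cfg.ratio, mode=cfg.height_mode)
        entry = out.setdefault(str(row["sample_id"]), {
            "ratios": [], "c_pip": None, "c_taz": None})
        entry["ratios"].append(ratio)
        if pd.notna(row["c_pip"]):
            entry["c_pip"] = float(row["c_pip"])
            entry["c_taz"] = float(row["c_taz"])
    return out


def cmd_calibrate(manifest_path: str | Path, config: RunConfig,
                  out_dir: str | Path) -> CalibrationModel:
    """Fit the calibration line from the manifest's standard spectra.

    Reads every standard spectrum, computes per-replicate ratios, summarizes
    each standard (mean ratio, RSD%), fits the calibration model, and writes
    ``model.json`` plus ``standards_table.csv`` (mean ratio and RSD per
    composition) to ``out_dir``.
    """
    manifest = read_manifest(manifest_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = _ratios_by_sample(manifest, "standard", config)
    if len({(v["c_pip"], v["c_taz"]) for v in samples.values()}) < 3:
        raise ValueError(
            f"need >= 3 distinct standard compositions, got {len(samples)}")
    records = []
    table_rows = []
    for sid, v in sorted(samples.items(),
                         key=lambda kv: -kv[1]["c_taz"]):
        rec = StandardRecord(v["c_pip"], v["c_taz"], tuple(v["ratios"]))
        records.append(rec)
        summ = replicate_summary(rec.replicate_ratios)
        table_rows.append({
            "sample_id": sid,
            "mass_ratio_taz_pip": f"{v['c_taz']:g}:{v['c_pip']:g}",
            "mean_ratio": round(summ.mean, 4),
            "rsd_pct": round(summ.rsd_pct, 2) if math.isfinite(summ.rsd_pct) else "",
            "n_replicates": summ.n,
        })
    model = fit_calibration(records, mode=config.fit_mode,
                            ratio_config=config.ratio)
    save_model(model, out / "model.json")
    pd.DataFrame(table_rows).to_csv(out / "standards_table.csv", index=False)
    logger.info(
        "calibrate: config=%s model=%s version=%s | slope=%.4f intercept=%.4f R2=%.5f n=%d",
        _sha256_of(asdict(config)), _sha256_of(_model_dict(model)),
        __version__, model.slope, model.intercept, model.r_squared,
        model.n_points)
    return model


def cmd_quantify(manifest_path: str | Path, model_path: str | Path,
                 config: RunConfig, out_dir: str | Path) -> dict:
    """Quantify unknown samples (and blanks, if present) against a model.

    Writes ``quant_results.json`` plus a human-readable ``report.txt`` with
    compositions in % w/w at 2 decimals. Per-sample inversion failures are
    recorded and do not abort the batch; the returned dict carries
    ``results``, ``errors`` and optional ``blank_stats``/``detection_limits``.
    """
    manifest = read_manifest(manifest_path)
    model = load_model(model_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknowns = _ratios_by_sample(manifest, "unknown", config)
    results: list[QuantResult] = []
    errors: dict[str, str] = {}
    for sid, v in sorted(unknowns.items()):
        try:
            results.append(quantify_sample(
                model, v["ratios"], sample_id=sid,
                uncertainty_mode=config.uncertainty_mode,
                calibrated_taz_range=config.calibrated_taz_range))
        except ValueError as exc:
            errors[sid] = str(exc)
            logger.error("quantify: sample %s failed: %s", sid, exc)
    payload: dict = {
        "results": [asdict(r) for r in results],
        "errors": errors,
        "model_hash": _sha256_of(_model_dict(model)),
        "config_hash": _sha256_of(asdict(config)),
        "package_version": __version__,
    }
    blanks_rows = _ratios_by_sample(manifest, "blank", config)
    if blanks_rows:
        blank_ratios = [r for v in blanks_rows.values() for r in v["ratios"]]
        if len(blank_ratios) >= 2:
            summ = replicate_summary(blank_ratios)
            bs = BlankStats(summ.mean, summ.sd, summ.n)
            payload["blank_stats"] = asdict(bs)
            try:
                dl = estimate_detection_limits(
                    model, bs, k_detect=config.k_detect,
                    loq_factor=config.loq_factor, loq_mode=config.loq_mode)
                payload["detection_limits"] = asdict(dl)
            except ValueError as exc:
                errors["__detection_limits__"] = str(exc)
                logger.error("quantify: detection limits failed: %s", exc)
    (out / "quant_results.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    lines = [f"{'sample':<16}{'C_PIP %w/w':>12}{'C_TAZ %w/w':>12}"
             f"{'sd':>8}{'RSD%':>8}{'n':>4}"]
    for r in results:
        sd = f"{r.sd:.2f}" if math.isfinite(r.sd) else "n/a"
        rsd = f"{r.ratio_rsd_pct:.2f}" if math.isfinite(r.ratio_rsd_pct) else "n/a"
        lines.append(f"{r.sample_id:<16}{r.c_pip_hat:>12.2f}{r.c_taz_hat:>12.2f}"
                     f"{sd:>8}{rsd:>8}{r.n_replicates:>4}")
        for w in r.warnings:
            lines.append(f"  ! {w}")
    for sid, msg in errors.items():
        lines.append(f"{sid:<16}  ERROR: {msg}")
    if "detection_limits" in payload:
        dl = payload["detection_limits"]
        lines.append(f"TAZ LOD = {dl['lod_taz']:.3f} % w/w, "
                     f"LOQ = {dl['loq_taz']:.3f} % w/w "
                     f"(k={dl['k_detect']:g}, method {dl['method']})")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return payload


#: Standard TAZ:PIP compositions of the simulated calibration design (% w/w).
DEFAULT_STANDARD_TAZ = (50.0, 45.0, 25.0, 15.0, 10.0, 5.0)


def cmd_simulate(cfg: GeneratorConfig, out_dir: str | Path,
                 n_reps: int = 3, n_blanks: int = 20,
                 unknown_c_taz: float = 11.0,
                 standards_taz: Sequence[float] = DEFAULT_STANDARD_TAZ) -> Path:
    """Write a complete synthetic dataset: spectra, manifest, ground truth.

    Default design: six standards (TAZ 50…5 % w/w) × ``n_reps`` replicate
    films, ``n_blanks`` pure-PIP blank films, and one unknown at
    ``unknown_c_taz`` % w/w TAZ with ``n_reps`` replicates. Idempotent for a
    fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []

    def emit(spectra: Iterable[Spectrum], sid: str, role: str,
             c_pip: float | None, c_taz: float | None) -> None:
        for i, s in enumerate(spectra):
            fn = f"{sid}_rep{i}.csv"
            write_spectrum(s, out / fn)
            rows.append({
                "spectrum_path": fn, "sample_id": sid, "role": role,
                "c_pip": "" if c_pip is None else c_pip,
                "c_taz": "" if c_taz is None else c_taz,
                "replicate_index": i})

    truth: dict = {"generator": {
        "grid": [cfg.grid_start, cfg.grid_stop, cfg.grid_step],
        "film_scale_sd": cfg.film_scale_sd,
        "additive_noise_sd": cfg.additive_noise_sd,
        "drift_slope_range": cfg.drift_slope_range,
        "drift_offset_range": cfg.drift_offset_range,
        "seed": cfg.seed}, "samples": {}}
    for c_taz in standards_taz:
        c_pip = 100.0 - c_taz
        sid = f"std_{c_taz:g}_{c_pip:g}"
        emit(synth_mixture_replicates(c_pip, c_taz, n_reps, cfg, sample_id=sid),
             sid, "standard", c_pip, c_taz)
        truth["samples"][sid] = {"c_pip": c_pip, "c_taz": c_taz}
    emit(synth_blank_pip_films(n_blanks, cfg), "blank_PIP", "blank", None, None)
    truth["samples"]["blank_PIP"] = {"c_pip": 100.0, "c_taz": 0.0}
    c_taz_u = unknown_c_taz
    emit(synth_mixture_replicates(100.0 - c_taz_u, c_taz_u, n_reps, cfg,
                                  sample_id="unknown_A", _tag=3),
         "unknown_A", "unknown", None, None)
    truth["samples"]["unknown_A"] = {"c_pip": 100.0 - c_taz_u, "c_taz": c_taz_u}
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        out / "manifest.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n")
    logger.info("simulate: wrote %d spectra to %s (seed %d)",
                len(rows), out, cfg.seed)
    return out
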