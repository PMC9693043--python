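"""Spectral preprocessing: I/O, apodization/FT, calibration, binning, normalization.

Turns 1D proton spectra into the samples x features matrix that the
multivariate models consume.  The processing chain mirrors standard NMR
metabolomics practice: exponential line broadening on the FID, Fourier
transform, chemical-shift calibration against a reference resonance
(lactate doublet at 1.33 ppm for plasma, TSP singlet at 0.00 ppm for
urine), removal of the urea and residual-water windows, fixed-width
integral binning of the retained region, and optional dilution
normalization (total-area or probabilistic quotient).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

GROUPS = ("C", "H")
DAYS = ("D8", "D11", "D14", "D17", "D20")
FLUIDS = ("plasma", "urine")

#: spectrometer proton frequency in MHz; converts Hz linewidths to ppm
PROTON_FREQ_MHZ = 600.13

# region / spacing / exclusion defaults per fluid (ppm)
PLASMA_REGION = (0.5, 9.0)
PLASMA_SPACING = 0.002
PLASMA_EXCLUSIONS = ((5.5, 6.0), (4.54, 5.23))
URINE_REGION = (0.5, 9.5)
URINE_SPACING = 0.005
URINE_EXCLUSIONS = ((5.55, 6.00), (4.50, 5.10))

# calibration references: nominal ppm, search window, peak shape
PLASMA_REFERENCE = {"nominal": 1.33, "window": (1.2, 1.45), "shape": "doublet"}
URINE_REFERENCE = {"nominal": 0.00, "window": (-0.25, 0.25), "shape": "singlet"}

# line-broadening defaults (Hz) applied before FT
LINE_BROADENING_HZ = {"plasma": 1.0, "urine": 0.3}


class SpectrumError(ValueError):
    """Raised for malformed spectra, files or processing parameters."""


@dataclass
class SampleMeta:
    """Identity of one sample: animal/replicate, group, gestational day, fluid."""

    sample_id: str
    group: str
    day: str
    fluid: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SpectrumError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.day not in DAYS:
            raise SpectrumError(f"day must be one of {DAYS}, got {self.day!r}")
        if self.fluid not in FLUIDS:
            raise SpectrumError(f"fluid must be one of {FLUIDS}, got {self.fluid!r}")


@dataclass
class Spectrum1D:
    """A 1D spectrum on a strictly monotone ppm axis (stored descending)."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise SpectrumError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if np.all(d > 0):  # ascending input: flip to the NMR convention
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise SpectrumError("ppm axis must be strictly monotone")

    def __len__(self) -> int:
        return self.ppm.size


@dataclass
class Fid:
    """Complex time-domain signal with its acquisition parameters."""

    data: np.ndarray
    dwell_s: float
    sweep_hz: float
    freq_mhz: float = PROTON_FREQ_MHZ
    carrier_ppm: float = 4.7
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.size < 1024:
            raise SpectrumError("FID must have at least 1024 points")
        if self.dwell_s <= 0:
            raise SpectrumError("dwell time must be positive")


@dataclass(frozen=True)
class BinSpec:
    """Fixed-width integral binning over a region with excluded windows."""

    region: tuple[float, float]
    spacing: float
    exclusions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.region
        if not lo < hi:
            raise SpectrumError("region low must be below region high")
        if self.spacing <= 0:
            raise SpectrumError("bin spacing must be positive")
        for a, b in self.exclusions:
            if not (lo <= a < b <= hi):
                raise SpectrumError(f"exclusion ({a}, {b}) outside region {self.region}")

    @classmethod
    def for_fluid(cls, fluid: str, spacing: float | None = None) -> "BinSpec":
        if fluid == "plasma":
            return cls(PLASMA_REGION, spacing or PLASMA_SPACING, PLASMA_EXCLUSIONS)
        if fluid == "urine":
            return cls(URINE_REGION, spacing or URINE_SPACING, URINE_EXCLUSIONS)
        raise SpectrumError(f"unknown fluid {fluid!r}")


@dataclass
class FeatureRow:
    """One sample's feature vector (bin integrals or metabolite quantities)."""

    feature_ids: tuple[str, ...]
    values: np.ndarray
    meta: SampleMeta


@dataclass
class AssignmentMap:
    """Metabolite name -> ppm windows used to aggregate bins into quantities.

    ``fc_masked`` flags features (broad lipoprotein/lipid envelopes) whose
    fold changes are unreliable and reported masked downstream.
    """

    windows: dict[str, list[tuple[float, float]]]
    fc_masked: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, wins in self.windows.items():
            for lo, hi in wins:
                if not lo < hi:
                    raise SpectrumError(f"bad window ({lo}, {hi}) for {name}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssignmentMap":
        raw = yaml.safe_load(Path(path).read_text())
        wins = {m: [tuple(map(float, w)) for w in ws] for m, ws in raw["windows"].items()}
        return cls(windows=wins, fc_masked=set(raw.get("fc_masked", [])))

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "windows": {m: [list(w) for w in ws] for m, ws in self.windows.items()},
            "fc_masked": sorted(self.fc_masked),
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


class FeatureMatrix:
    """Samples x features table with sample metadata and provenance.

    ``values`` is a DataFrame indexed by sample id; feature ids are bin
    centers formatted to 6 decimals, or metabolite names after
    quantification.  Samples are kept in a canonical (group, day,
    sample_id) order and bin features in descending ppm order.
    """

    META_COLS = ("group", "day", "fluid")

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame,
                 provenance: Sequence[str] = ()) -> None:
        if values.isna().any().any():
            raise SpectrumError("feature matrix contains missing values")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise SpectrumError(f"duplicate feature id {dup!r}")
        if not values.index.equals(meta.index):
            raise SpectrumError("values and meta must share the sample index")
        self.values = values
        self.meta = meta
        self.provenance = list(provenance)

    # -- construction ------------------------------------------------
    @classmethod
    def from_rows(cls, rows: Iterable[FeatureRow]) -> "FeatureMatrix":
        rows = list(rows)
        if not rows:
            raise SpectrumError("no feature rows supplied")
        ref_ids = rows[0].feature_ids
        for r in rows[1:]:
            if r.feature_ids != ref_ids:
                bad = next(
                    (a for a, b in zip(r.feature_ids, ref_ids) if a != b),
                    f"length {len(r.feature_ids)} != {len(ref_ids)}",
                )
                raise SpectrumError(
                    f"ragged feature rows: sample {r.meta.sample_id!r} "
                    f"first mismatching feature {bad!r}")
        ids = [r.meta.sample_id for r in rows]
        if len(set(ids)) != len(ids):
            raise SpectrumError("duplicate sample ids")
        values = pd.DataFrame([r.values for r in rows], index=ids, columns=list(ref_ids))
        meta = pd.DataFrame(
            {"group": [r.meta.group for r in rows],
             "day": [r.meta.day for r in rows],
             "fluid": [r.meta.fluid for r in rows]},
            index=ids)
        order = sorted(
            range(len(rows)),
            key=lambda i: (rows[i].meta.group, DAYS.index(rows[i].meta.day),
                           rows[i].meta.sample_id))
        values = values.iloc[order]
        meta = meta.iloc[order]
        return cls(values, meta, provenance=["assembled"])

    # -- helpers -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, day: str | None = None, groups: Sequence[str] | None = None
               ) -> "FeatureMatrix":
        keep = pd.Series(True, index=self.meta.index)
        if day is not None:
            keep &= self.meta["day"] == day
        if groups is not None:
            keep &= self.meta["group"].isin(groups)
        return FeatureMatrix(self.values.loc[keep], self.meta.loc[keep],
                             self.provenance + [f"subset(day={day}, groups={groups})"])

    def class_vector(self) -> np.ndarray:
        """Group coding y in {-1 (C), +1 (H)}: positive = hypoxia."""
        return np.where(self.meta["group"].to_numpy() == "H", 1.0, -1.0)

    def bin_centers(self) -> np.ndarray:
        try:
            return np.array([float(c) for c in self.values.columns])
        except ValueError as exc:
            raise SpectrumError("feature ids are not bin centers") from exc

    # -- I/O ---------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta, self.values], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        meta = df[list(cls.META_COLS)]
        values = df.drop(columns=list(cls.META_COLS))
        return cls(values, meta, provenance=[f"read {path}"])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("sample_id", "group", "day", "fluid")


def write_spectrum_csv(spectrum: Spectrum1D, path: str | Path) -> None:
    """Two-column ppm,intensity CSV with metadata in '#' header lines."""
    m = spectrum.meta
    with open(path, "w") as fh:
        for key in _META_KEYS:
            fh.write(f"# {key}: {getattr(m, key)}\n")
        fh.write("ppm,intensity\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{x:.9f},{y:.12e}\n")


def read_spectrum_csv(path: str | Path) -> Spectrum1D:
    meta_kv: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*([\w-]+)\s*:\s*(.+)", line)
                if m:
                    meta_kv[m.group(1)] = m.group(2).strip()
                continue
            if line.lower().startswith("ppm"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumError(f"{path}: line {lineno}: expected 'ppm,intensity', got {line!r}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumError(f"{path}: line {lineno}: non-numeric value in {line!r}") from exc
    missing = [k for k in _META_KEYS if k not in meta_kv]
    if missing:
        raise SpectrumError(f"{path}: missing metadata keys {missing}")
    meta = SampleMeta(**{k: meta_kv[k] for k in _META_KEYS})
    return Spectrum1D(np.array(xs), np.array(ys), meta)


def write_spectrum_jcampdx(spectrum: Spectrum1D, path: str | Path) -> None:
    """Minimal JCAMP-DX writer: AFFN ``(X++(Y..Y))`` XYDATA, full precision."""
    m = spectrum.meta
    ppm = spectrum.ppm
    n = ppm.size
    lines = [
        f"##TITLE={m.sample_id}",
        "##JCAMP-DX=5.00",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##$SAMPLEID={m.sample_id}",
        f"##$GROUP={m.group}",
        f"##$DAY={m.day}",
        f"##$FLUID={m.fluid}",
        f"##NPOINTS={n}",
        f"##FIRSTX={ppm[0]:.12g}",
        f"##LASTX={ppm[-1]:.12g}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 4
    for i in range(0, n, per_line):
        ys = " ".join(f"{y:.12e}" for y in spectrum.intensity[i:i + per_line])
        lines.append(f"{ppm[i]:.9f} {ys}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_jcampdx(path: str | Path) -> Spectrum1D:
    labels: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            if line.startswith("##END"):
                in_data = False
                continue
            try:
                key, val = line[2:].split("=", 1)
            except ValueError as exc:
                raise SpectrumError(f"{path}: line {lineno}: malformed label {line!r}") from exc
            key = key.strip().upper()
            labels[key] = val.strip()
            if key == "XYDATA":
                in_data = True
            continue
        if in_data:
            parts = line.split()
            if len(parts) < 2:
                raise SpectrumError(f"{path}: line {lineno}: XYDATA line needs X and Y values")
            try:
                ys.extend(float(p) for p in parts[1:])
            except ValueError as exc:
                raise SpectrumError(f"{path}: line {lineno}: non-numeric XYDATA") from exc
    for req in ("NPOINTS", "FIRSTX", "LASTX"):
        if req not in labels:
            raise SpectrumError(f"{path}: missing ##{req}")
    n = int(labels["NPOINTS"])
    if len(ys) != n:
        raise SpectrumError(f"{path}: NPOINTS={n} but {len(ys)} Y values read")
    yfac = float(labels.get("YFACTOR", "1.0"))
    ppm = np.linspace(float(labels["FIRSTX"]), float(labels["LASTX"]), n)
    missing = [k for k in ("$SAMPLEID", "$GROUP", "$DAY", "$FLUID") if k not in labels]
    if missing:
        raise SpectrumError(f"{path}: missing metadata labels {missing}")
    meta = SampleMeta(sample_id=labels["$SAMPLEID"], group=labels["$GROUP"],
                      day=labels["$DAY"], fluid=labels["$FLUID"])
    return Spectrum1D(ppm, np.array(ys) * yfac, meta)


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum1D:
    """Dispatch on ``format`` or the file suffix (.csv / .jdx / .dx)."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "jcampdx" if suffix in (".jdx", ".dx", ".jcamp") else "csv"
    if format == "csv":
        return read_spectrum_csv(path)
    if format == "jcampdx":
        return read_spectrum_jcampdx(path)
    raise SpectrumError(f"unknown spectrum format {format!r}")


def write_spectrum(spectrum: Spectrum1D, path: str | Path, format: str | None = None) -> None:
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "jcampdx" if suffix in (".jdx", ".dx", ".jcamp") else "csv"
    if format == "csv":
        write_spectrum_csv(spectrum, path)
    elif format == "jcampdx":
        write_spectrum_jcampdx(spectrum, path)
    else:
        raise SpectrumError(f"unknown spectrum format {format!r}")


# ---------------------------------------------------------------------------
# processing
# ---------------------------------------------------------------------------

def apodize_transform(fid: Fid, line_broadening_hz: float) -> Spectrum1D:
    """Exponential apodization then FT; returns the real spectrum on a ppm axis.

    The FID is multiplied by exp(-pi * lb * t), which adds ``lb`` Hz to every
    Lorentzian full width at half maximum, then Fourier-transformed.
    """
    if line_broadening_hz < 0:
        raise SpectrumError("line broadening must be >= 0")
    t = np.arange(fid.data.size) * fid.dwell_s
    window = np.exp(-math.pi * line_broadening_hz * t)
    spec = np.fft.fftshift(np.fft.fft(fid.data * window))
    freq = np.fft.fftshift(np.fft.fftfreq(fid.data.size, d=fid.dwell_s))
    ppm = freq / fid.freq_mhz + fid.carrier_ppm
    meta = fid.meta or SampleMeta("fid", "C", "D8", "plasma")
    return Spectrum1D(ppm, spec.real, meta)


def _noise_scale(intensity: np.ndarray) -> float:
    """Robust noise scale: median absolute deviation of the full trace."""
    med = np.median(intensity)
    return float(np.median(np.abs(intensity - med))) + 1e-30


def detect_reference(spectrum: Spectrum1D, nominal: float,
                     window: tuple[float, float], shape: str = "singlet",
                     min_snr: float = 5.0) -> float:
    """Locate the calibration resonance inside ``window``; returns its ppm.

    Singlet: position of the smoothed maximum.  Doublet: midpoint of the two
    tallest local maxima (the lactate CH3 doublet in plasma).
    """
    lo, hi = min(window), max(window)
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if mask.sum() < 5:
        raise SpectrumError(f"search window ({lo}, {hi}) covers <5 points of the axis")
    x = spectrum.ppm[mask]
    y = spectrum.intensity[mask]
    smooth = uniform_filter1d(y, size=max(3, y.size // 200))
    floor = _noise_scale(spectrum.intensity)
    prominence = smooth.max() - float(np.median(spectrum.intensity))
    if prominence < min_snr * floor:
        raise SpectrumError(
            f"no peak above the noise floor in ({lo}, {hi}); widen the search window")
    if shape == "singlet":
        return float(x[int(np.argmax(smooth))])
    if shape == "doublet":
        idx, props = find_peaks(smooth, height=0.2 * smooth.max())
        if idx.size >= 2:
            top2 = idx[np.argsort(props["peak_heights"])[-2:]]
            return float(x[top2].mean())
        return float(x[int(np.argmax(smooth))])  # merged doublet: fall back to max
    raise SpectrumError(f"unknown reference shape {shape!r}")


def calibrate(spectrum: Spectrum1D, reference: Mapping | None = None,
              min_snr: float = 5.0) -> Spectrum1D:
    """Shift the ppm axis so the reference peak lands on its nominal position.

    Intensities are untouched; the applied shift accumulates in
    ``meta.extra['calibration_shift_ppm']``.
    """
    if reference is None:
        reference = PLASMA_REFERENCE if spectrum.meta.fluid == "plasma" else URINE_REFERENCE
    detected = detect_reference(spectrum, reference["nominal"], reference["window"],
                                reference.get("shape", "singlet"), min_snr=min_snr)
    shift = reference["nominal"] - detected
    extra = dict(spectrum.meta.extra)
    extra["calibration_shift_ppm"] = extra.get("calibration_shift_ppm", 0.0) + shift
    meta = replace(spectrum.meta, extra=extra)
    return Spectrum1D(spectrum.ppm + shift, spectrum.intensity.copy(), meta)


def bin_spectrum(spectrum: Spectrum1D, spec: BinSpec) -> FeatureRow:
    """Integrate fixed-width bins over the retained region.

    Bin value = trapezoidal integral of intensity over the bin; bin id = its
    center ppm (6 decimals).  Bins overlapping an exclusion window are
    dropped whole, keeping all retained bins equal width.
    """
    lo, hi = spec.region
    x = spectrum.ppm[::-1]  # ascending for integration
    y = spectrum.intensity[::-1]
    if lo < x[0] - 1e-12 or hi > x[-1] + 1e-12:
        raise SpectrumError(
            f"binning region ({lo}, {hi}) outside the spectrum axis ({x[0]:.3f}, {x[-1]:.3f})")
    n_bins = int(round((hi - lo) / spec.spacing))
    if abs(n_bins * spec.spacing - (hi - lo)) > 1e-6:
        n_bins = int(math.floor((hi - lo) / spec.spacing + 1e-9))
    edges = lo + spec.spacing * np.arange(n_bins + 1)
    cum = np.concatenate([[0.0], cumulative_trapezoid(y, x)])
    at_edges = np.interp(edges, x, cum)
    integrals = np.diff(at_edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    eps = 1e-9
    keep = np.ones(n_bins, dtype=bool)
    for a, b in spec.exclusions:
        keep &= ~((edges[:-1] < b - eps) & (edges[1:] > a + eps))
    centers = centers[keep][::-1]  # descending ppm feature order
    integrals = integrals[keep][::-1]
    ids = tuple(f"{c:.6f}" for c in centers)
    return FeatureRow(ids, integrals, spectrum.meta)


def assemble_matrix(rows: Iterable[FeatureRow]) -> FeatureMatrix:
    """Stack per-sample feature rows into a canonical FeatureMatrix."""
    return FeatureMatrix.from_rows(rows)


def normalize(matrix: FeatureMatrix, method: str = "none") -> FeatureMatrix:
    """Dilution normalization: ``none``, ``total_area`` or ``pqn``.

    total_area rescales every sample to the cohort-median total integral.
    pqn divides each sample by the median quotient of its features against
    the cohort-median spectrum (robust to a few genuinely changed features).
    """
    if method == "none":
        out = FeatureMatrix(matrix.values.copy(), matrix.meta.copy(),
                            matrix.provenance + ["normalize(none)"])
        return out
    X = matrix.values.to_numpy(dtype=float)
    if method == "total_area":
        sums = X.sum(axis=1)
        bad = np.nonzero(sums <= 0)[0]
        if bad.size:
            raise SpectrumError(
                f"non-positive total area for sample {matrix.values.index[bad[0]]!r}")
        target = np.median(sums)
        Xn = X * (target / sums)[:, None]
    elif method == "pqn":
        if X.shape[0] < 3:
            raise SpectrumError("pqn needs at least 3 samples")
        sums = X.sum(axis=1)
        bad = np.nonzero(sums <= 0)[0]
        if bad.size:
            raise SpectrumError(
                f"non-positive total area for sample {matrix.values.index[bad[0]]!r}")
        ref = np.median(X, axis=0)
        pos = ref > 0
        if not pos.any():
            raise SpectrumError("pqn reference spectrum is non-positive everywhere")
        quot = X[:, pos] / ref[pos]
        factors = np.median(quot, axis=1)
        Xn = X / factors[:, None]
    else:
        raise SpectrumError(f"unknown normalization method {method!r}")
    values = pd.DataFrame(Xn, index=matrix.values.index, columns=matrix.values.columns)
    return FeatureMatrix(values, matrix.meta.copy(),
                         matrix.provenance + [f"normalize({method})"])


def quantify_metabolites(matrix: FeatureMatrix, assignments: AssignmentMap) -> FeatureMatrix:
    """Aggregate bin integrals into named metabolite quantities.

    A metabolite's value is the sum of the retained bin integrals across all
    of its assignment windows.  A window that overlaps no retained bin is an
    error (it is either misconfigured or sits inside an exclusion).
    """
    centers = matrix.bin_centers()
    cols = {}
    for name, wins in assignments.windows.items():
        mask = np.zeros(centers.size, dtype=bool)
        for lo, hi in wins:
            hit = (centers >= lo) & (centers <= hi)
            if not hit.any():
                raise SpectrumError(
                    f"assignment window ({lo}, {hi}) for {name!r} overlaps no retained bin")
            mask |= hit
        cols[name] = matrix.values.to_numpy(dtype=float)[:, mask].sum(axis=1)
    values = pd.DataFrame(cols, index=matrix.values.index)
    out = FeatureMatrix(values, matrix.meta.copy(),
                        matrix.provenance + ["quantify_metabolites"])
    out.fc_masked = set(assignments.fc_masked)  # carried for the screen stage
    return out
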