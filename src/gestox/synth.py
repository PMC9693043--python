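"""Synthetic two-group NMR cohort generator with known ground truth.

Emulates a chronic-gestational-hypoxia rat study: two groups (C control,
H hypoxia) sampled on five gestational days (D8..D20), eight animals per
cell, plasma or urine.  Metabolite concentrations are log-normal around
fluid-specific base levels, with planted hypoxia effects expressed as
H/C fold changes on chosen (metabolite, day) cells.  Each sample is
rendered as a sum of Lorentzian multiplets on a uniform ppm grid, plus a
smooth baseline and white noise; urine samples additionally carry a
random dilution factor (which the internal TSP standard does not share,
so calibration and quotient normalization behave as they do on real
urine).  Everything is deterministic given a seed, and the planted truth
is returned alongside the spectra for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .spectra import (
    DAYS,
    FLUIDS,
    GROUPS,
    PROTON_FREQ_MHZ,
    SampleMeta,
    Spectrum1D,
    AssignmentMap,
    write_spectrum,
)


class SynthError(ValueError):
    """Raised for invalid simulator configuration."""


# ---------------------------------------------------------------------------
# peak library
# ---------------------------------------------------------------------------

#: multiplet patterns as (offset in units of J, relative weight)
MULTIPLETS = {
    "s": ((0.0, 1.0),),
    "d": ((-0.5, 0.5), (0.5, 0.5)),
    "t": ((-1.0, 0.25), (0.0, 0.5), (1.0, 0.25)),
    "q": ((-1.5, 0.125), (-0.5, 0.375), (0.5, 0.375), (1.5, 0.125)),
    "dd": ((-0.714, 0.25), (-0.286, 0.25), (0.286, 0.25), (0.714, 0.25)),
    "m": ((-2.0, 0.0625), (-1.0, 0.25), (0.0, 0.375), (1.0, 0.25), (2.0, 0.0625)),
}

#: scalar coupling used for multiplet splitting, Hz
J_COUPLING_HZ = 7.0


@dataclass(frozen=True)
class Peak:
    """One resonance: center (ppm), multiplicity, relative area, linewidth (Hz)."""

    center: float
    multiplicity: str = "s"
    rel_area: float = 1.0
    linewidth_hz: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.center <= 10.0:
            raise SynthError(f"peak center {self.center} outside 0-10 ppm")
        if self.rel_area <= 0:
            raise SynthError("relative area must be positive")
        if self.linewidth_hz <= 0:
            raise SynthError("linewidth must be positive")
        if self.multiplicity not in MULTIPLETS:
            raise SynthError(f"unknown multiplicity {self.multiplicity!r}")


@dataclass(frozen=True)
class MetaboliteEntry:
    name: str
    peaks: tuple[Peak, ...]


@dataclass
class MetabolitePeakLibrary:
    """Assignment vocabulary: metabolite -> resonances."""

    entries: tuple[MetaboliteEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise SynthError(f"duplicate metabolite name {dup!r}")
        self._index = {e.name: e for e in self.entries}

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> MetaboliteEntry:
        return self._index[name]

    def __len__(self) -> int:
        return len(self.entries)


def _lib(spec: Mapping[str, Sequence[tuple]]) -> MetabolitePeakLibrary:
    entries = tuple(
        MetaboliteEntry(name, tuple(Peak(*p) for p in peaks))
        for name, peaks in spec.items())
    return MetabolitePeakLibrary(entries)


# Chemical shifts are typical literature values for aqueous biofluids at
# pH ~7; multiplicities are simplified to fixed patterns.
_PLASMA_LIBRARY = {
    "3-Hydroxybutyrate": [(1.20, "d", 3.0), (2.31, "dd", 1.0), (4.13, "m", 1.0)],
    "Acetoacetate": [(2.27, "s", 3.0), (3.43, "s", 2.0)],
    "Acetate": [(1.92, "s", 3.0)],
    "Acetone": [(2.23, "s", 6.0)],
    "Benzoate": [(7.87, "d", 2.0), (7.55, "t", 1.0), (7.48, "t", 2.0)],
    "cis-Aconitate": [(3.11, "d", 2.0), (5.69, "s", 1.0)],
    "Choline": [(3.20, "s", 9.0), (3.52, "m", 2.0), (4.07, "m", 2.0)],
    "Citrate": [(2.54, "d", 2.0), (2.66, "d", 2.0)],
    "Creatine": [(3.03, "s", 3.0), (3.93, "s", 2.0)],
    "Cytidine": [(5.90, "d", 1.0), (7.84, "d", 1.0)],
    "Deoxyguanosine": [(6.28, "t", 1.0), (7.95, "s", 1.0)],
    "N,N-Dimethylglycine": [(2.92, "s", 6.0), (3.71, "s", 2.0)],
    "Ethanolamine": [(3.14, "t", 2.0), (3.82, "t", 2.0)],
    "Fumarate": [(6.52, "s", 2.0)],
    "Glutamine": [(2.13, "m", 2.0), (2.45, "m", 2.0), (3.77, "t", 1.0)],
    "Glycerol": [(3.56, "dd", 2.0), (3.65, "dd", 2.0), (3.78, "m", 1.0)],
    "Isobutyrate": [(1.06, "d", 6.0), (2.38, "m", 1.0)],
    "Isoleucine": [(0.93, "t", 3.0), (1.01, "d", 3.0), (1.97, "m", 1.0)],
    "Lipid": [(1.26, "s", 10.0, 18.0), (0.84, "s", 4.0, 18.0), (5.30, "s", 2.0, 18.0)],
    "VLDL": [(0.87, "s", 6.0, 12.0), (1.29, "s", 4.0, 12.0)],
    "LDL": [(0.82, "s", 6.0, 14.0), (1.24, "s", 4.0, 14.0)],
    "Lactate": [(1.33, "d", 3.0), (4.11, "q", 1.0)],
    "Leucine": [(0.95, "d", 3.0), (0.96, "d", 3.0), (1.70, "m", 3.0)],
    "Lysine": [(1.72, "m", 2.0), (1.90, "m", 2.0), (3.02, "t", 2.0)],
    "Methionine": [(2.13, "s", 3.0), (2.64, "t", 2.0)],
    "Phenylalanine": [(7.32, "d", 2.0), (7.37, "t", 1.0), (7.42, "m", 2.0)],
    "Sarcosine": [(2.73, "s", 3.0), (3.60, "s", 2.0)],
    "Serine": [(3.83, "dd", 1.0), (3.94, "dd", 2.0)],
    "Threonine": [(1.32, "d", 3.0), (3.58, "d", 1.0), (4.25, "m", 1.0)],
    "Valine": [(0.98, "d", 3.0), (1.03, "d", 3.0), (2.26, "m", 1.0)],
    # additional resonances routinely visible in plasma
    "Alanine": [(1.47, "d", 3.0)],
    "Glycine": [(3.55, "s", 2.0)],
    "Pyruvate": [(2.36, "s", 3.0)],
    "Formate": [(8.44, "s", 1.0)],
    "Tyrosine": [(6.89, "d", 2.0), (7.18, "d", 2.0)],
    "Betaine": [(3.25, "s", 9.0), (3.89, "s", 2.0)],
}

_URINE_LIBRARY = {
    "TSP": [(0.00, "s", 9.0)],
    "1-Methylhistidine": [(7.05, "s", 1.0), (7.77, "s", 1.0), (3.69, "s", 3.0)],
    "2-Hydroxybutyrate": [(0.89, "t", 3.0), (4.00, "dd", 1.0)],
    "3-Hydroxybutyrate": [(1.20, "d", 3.0), (2.31, "dd", 1.0), (4.13, "m", 1.0)],
    "Acetoacetate": [(2.27, "s", 3.0), (3.43, "s", 2.0)],
    "Acetone": [(2.23, "s", 6.0)],
    "Allantoin": [(5.39, "s", 1.0)],
    "Aminoadipate": [(1.65, "m", 4.0), (2.24, "t", 2.0), (3.74, "t", 1.0)],
    "Benzoate": [(7.87, "d", 2.0), (7.55, "t", 1.0), (7.48, "t", 2.0)],
    "Butyrate": [(0.90, "t", 3.0), (1.56, "m", 2.0), (2.16, "t", 2.0)],
    "cis-Aconitate": [(3.11, "d", 2.0), (5.69, "s", 1.0)],
    "Citrate": [(2.54, "d", 2.0), (2.66, "d", 2.0)],
    "Fumarate": [(6.52, "s", 2.0)],
    "Glycine": [(3.56, "s", 2.0)],
    "Hippurate": [(3.97, "d", 2.0), (7.54, "t", 2.0), (7.64, "t", 1.0), (7.83, "d", 2.0)],
    "Hydroxypyruvate": [(4.36, "s", 2.0)],
    "Lactate": [(1.33, "d", 3.0), (4.11, "q", 1.0)],
    "Malate": [(2.37, "dd", 1.0), (2.67, "dd", 1.0), (4.30, "dd", 1.0)],
    "Maleicate": [(6.26, "s", 2.0)],
    "N,N-Dimethylglycine": [(2.92, "s", 6.0), (3.71, "s", 2.0)],
    "N-Acetylaspartate": [(2.01, "s", 3.0), (2.48, "dd", 1.0), (2.68, "dd", 1.0)],
    "N-Acetylglutamate": [(2.04, "s", 3.0), (1.88, "m", 2.0), (2.22, "m", 2.0)],
    "ortho-Hydroxyphenylacetate": [(3.61, "s", 2.0), (6.93, "t", 2.0), (7.21, "t", 2.0)],
    "Phenylacetylglycine": [(3.67, "s", 2.0), (3.75, "d", 2.0), (7.36, "m", 5.0)],
    "Picolinate": [(7.50, "m", 1.0), (7.92, "t", 1.0), (8.05, "d", 1.0), (8.55, "d", 1.0)],
    "Succinate": [(2.41, "s", 4.0)],
    "Taurine": [(3.26, "t", 2.0), (3.42, "t", 2.0)],
    "Trigonelline": [(4.43, "s", 3.0), (8.08, "m", 1.0), (8.83, "m", 2.0), (9.12, "s", 1.0)],
    "Urocanate": [(6.40, "d", 1.0), (7.31, "d", 1.0), (7.86, "s", 1.0)],
    "alpha-Ketoglutarate": [(2.45, "t", 2.0), (3.01, "t", 2.0)],
    # common urine background signals
    "Creatinine": [(3.05, "s", 3.0), (4.06, "s", 2.0)],
    "Urea": [(5.78, "s", 2.0, 25.0)],
    "Formate": [(8.44, "s", 1.0)],
    "Dimethylamine": [(2.72, "s", 6.0)],
    "Alanine": [(1.47, "d", 3.0)],
    "Betaine": [(3.25, "s", 9.0), (3.89, "s", 2.0)],
}

#: metabolite names of the two published difference tables; alpha-Ketoglutarate
#: appears under its Greek-letter spelling there.
TABLE_NAME_ALIASES = {"alpha-Ketoglutarate": "α-Ketoglutarate"}


def build_default_library(fluid: str) -> MetabolitePeakLibrary:
    """Default peak library for a fluid (>=20 plasma / >=25 urine metabolites)."""
    if fluid == "plasma":
        return _lib(_PLASMA_LIBRARY)
    if fluid == "urine":
        return _lib(_URINE_LIBRARY)
    raise SynthError(f"unknown fluid {fluid!r}; expected one of {FLUIDS}")


def default_base_levels(library: MetabolitePeakLibrary) -> dict[str, float]:
    """Arbitrary-unit base concentrations; only fold changes are meaningful.

    Levels are staggered deterministically so spectra show realistic dynamic
    range rather than identical peak heights.
    """
    levels = {}
    for i, name in enumerate(library.names):
        levels[name] = 1.0 + 0.35 * ((i * 7) % 11)  # 1.0 .. 4.5 a.u., fixed pattern
    if "TSP" in levels:
        levels["TSP"] = 3.0
    if "Urea" in levels:
        levels["Urea"] = 12.0
    return levels


def default_assignment_map(library: MetabolitePeakLibrary,
                           fluid: str | None = None,
                           half_width: float = 0.02,
                           exclude_tsp: bool = True) -> AssignmentMap:
    """Windows of +/- ``half_width`` ppm around each library peak center.

    Windows falling inside the fluid's excluded urea/water regions (or
    outside its retained region) are dropped, so every remaining window
    overlaps retained bins.  Lipoprotein/lipid envelopes are flagged
    fold-change-masked, as their broad overlapping signals make ratio
    estimates unreliable.
    """
    from .spectra import BinSpec

    bin_spec = BinSpec.for_fluid(fluid) if fluid else None
    windows: dict[str, list[tuple[float, float]]] = {}
    for entry in library.entries:
        if exclude_tsp and entry.name == "TSP":
            continue
        if entry.name == "Urea":
            continue  # sits inside the excluded urea window by design
        wins = []
        for pk in entry.peaks:
            lo = round(pk.center - half_width, 4)
            hi = round(pk.center + half_width, 4)
            if bin_spec is not None:
                rlo, rhi = bin_spec.region
                if hi <= rlo or lo >= rhi:
                    continue
                if any(lo >= a - half_width and hi <= b + half_width
                       for a, b in bin_spec.exclusions):
                    continue
            wins.append((lo, hi))
        if not wins:
            continue
        windows[entry.name] = wins
    fc_masked = {n for n in ("Lipid", "VLDL", "LDL") if n in windows}
    return AssignmentMap(windows=windows, fc_masked=fc_masked)


# ---------------------------------------------------------------------------
# design / effects / truth
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Study layout and acquisition noise model for one fluid."""

    fluid: str = "plasma"
    groups: tuple[str, str] = GROUPS
    days: tuple[str, ...] = DAYS
    n_per_cell: int = 8
    ppm_range: tuple[float, float] = (-0.5, 9.5)
    points: int = 16384
    noise_sd: float = 0.5
    shift_jitter_sd: float = 0.002
    baseline_amplitude: float = 2.0
    dilution_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.fluid not in FLUIDS:
            raise SynthError(f"unknown fluid {self.fluid!r}")
        if self.n_per_cell < 2:
            raise SynthError("n_per_cell must be >= 2")
        if self.points < 1024:
            raise SynthError("points must be >= 1024")
        if not self.ppm_range[0] < self.ppm_range[1]:
            raise SynthError("ppm_range must be (low, high)")

    def ppm_axis(self) -> np.ndarray:
        lo, hi = self.ppm_range
        return np.linspace(hi, lo, self.points)  # descending, NMR convention


@dataclass(frozen=True)
class Effect:
    """A planted group difference: H/C fold change on one (metabolite, day)."""

    metabolite: str
    day: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise SynthError("fold change must be positive")
        if self.day not in DAYS:
            raise SynthError(f"unknown day {self.day!r}")


@dataclass
class EffectSpec:
    effects: tuple[Effect, ...] = ()

    def __post_init__(self) -> None:
        self.effects = tuple(self.effects)
        keys = [(e.metabolite, e.day) for e in self.effects]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise SynthError(f"duplicate effect for {dup}")

    def lookup(self, metabolite: str, day: str) -> float:
        for e in self.effects:
            if e.metabolite == metabolite and e.day == day:
                return e.fold_change
        return 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EffectSpec":
        raw = yaml.safe_load(Path(path).read_text()) or []
        return cls(tuple(Effect(e["metabolite"], e["day"], float(e["fold_change"]))
                         for e in raw))

    def to_yaml(self, path: str | Path) -> None:
        raw = [{"metabolite": e.metabolite, "day": e.day, "fold_change": e.fold_change}
               for e in self.effects]
        Path(path).write_text(yaml.safe_dump(raw))


@dataclass
class SyntheticTruth:
    """Planted effects plus the realized per-sample concentration table."""

    effects: EffectSpec
    concentrations: pd.DataFrame  # samples x metabolites, a.u.
    sample_meta: pd.DataFrame  # group, day, fluid per sample
    dilution: pd.Series | None = None  # urine only

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.sample_meta, self.concentrations], axis=1)
        if self.dilution is not None:
            out.insert(3, "dilution", self.dilution)
        out.index.name = "sample_id"
        out.to_csv(path)

    def to_feature_matrix(self):
        """Metabolite-level FeatureMatrix of the true concentrations."""
        from .spectra import FeatureMatrix

        return FeatureMatrix(self.concentrations.copy(), self.sample_meta.copy(),
                             provenance=["synthetic truth concentrations"])


def _sample_ids(design: CohortDesign) -> list[tuple[str, str, str]]:
    ids = []
    for group in design.groups:
        for day in design.days:
            for i in range(design.n_per_cell):
                ids.append((f"{group}_{day}_{i + 1:02d}", group, day))
    return ids


def sample_concentrations(design: CohortDesign, effects: EffectSpec,
                          base_levels: Mapping[str, float], seed: int,
                          sigma_log: float = 0.15) -> SyntheticTruth:
    """Draw log-normal concentrations with planted fold changes on H cells.

    concentration = base * FC(H, day) * exp(sigma_log * z); at sigma_log = 0
    every sample sits exactly at its (possibly scaled) base level.
    """
    for e in effects.effects:
        if e.metabolite not in base_levels:
            raise SynthError(f"effect references unknown metabolite {e.metabolite!r}")
    metabolites = list(base_levels)
    ids = _sample_ids(design)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = np.empty((len(ids), len(metabolites)))
    for r, (sid, group, day) in enumerate(ids):
        z = rng.standard_normal(len(metabolites))
        for c, met in enumerate(metabolites):
            level = base_levels[met]
            if group == "H":
                level *= effects.lookup(met, day)
            rows[r, c] = level * np.exp(sigma_log * z[c])
    conc = pd.DataFrame(rows, index=[i[0] for i in ids], columns=metabolites)
    meta = pd.DataFrame({"group": [i[1] for i in ids], "day": [i[2] for i in ids],
                         "fluid": design.fluid}, index=conc.index)
    return SyntheticTruth(effects=effects, concentrations=conc, sample_meta=meta)


def _lorentzian_sum(ppm: np.ndarray, lines: list[tuple[float, float, float]]) -> np.ndarray:
    """Sum of area-normalized Lorentzians: (center ppm, area, hwhm ppm)."""
    out = np.zeros_like(ppm)
    for center, area, hwhm in lines:
        out += area * (hwhm / np.pi) / ((ppm - center) ** 2 + hwhm ** 2)
    return out


def render_spectrum(concentrations: Mapping[str, float],
                    library: MetabolitePeakLibrary,
                    design: CohortDesign, seed: int,
                    meta: SampleMeta | None = None) -> Spectrum1D:
    """Render one spectrum: Lorentzian multiplets + smooth baseline + noise.

    Each peak integrates to concentration x relative area; a per-metabolite
    chemical-shift jitter (SD ``design.shift_jitter_sd`` ppm) moves all of a
    metabolite's resonances together.
    """
    for name in concentrations:
        if name not in library:
            raise SynthError(f"no library entry for metabolite {name!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ppm = design.ppm_axis()
    j_ppm = J_COUPLING_HZ / PROTON_FREQ_MHZ
    lines: list[tuple[float, float, float]] = []
    for name, conc in concentrations.items():
        jitter = rng.normal(0.0, design.shift_jitter_sd)
        if conc == 0:
            continue
        for pk in library[name].peaks:
            hwhm = (pk.linewidth_hz / PROTON_FREQ_MHZ) / 2.0
            for off, weight in MULTIPLETS[pk.multiplicity]:
                lines.append((pk.center + jitter + off * j_ppm,
                              conc * pk.rel_area * weight, hwhm))
    intensity = _lorentzian_sum(ppm, lines)
    if design.baseline_amplitude > 0:
        lo, hi = design.ppm_range
        u = (ppm - lo) / (hi - lo)
        ph1, ph2 = rng.uniform(0, 1, size=2)
        intensity += design.baseline_amplitude * (
            0.5 + 0.3 * np.sin(2 * np.pi * (u + ph1)) + 0.2 * np.sin(4 * np.pi * (u + ph2)))
    if design.noise_sd > 0:
        intensity += rng.normal(0.0, design.noise_sd, size=ppm.size)
    if meta is None:
        meta = SampleMeta("synthetic", "C", "D8", design.fluid)
    return Spectrum1D(ppm, intensity, meta)


def simulate_cohort(design: CohortDesign, effects: EffectSpec | None = None,
                    seed: int = 0, library: MetabolitePeakLibrary | None = None,
                    base_levels: Mapping[str, float] | None = None,
                    sigma_log: float = 0.15
                    ) -> tuple[list[Spectrum1D], SyntheticTruth]:
    """Simulate the full |groups| x |days| x n_per_cell cohort.

    For urine, each sample's metabolite signal is scaled by a log-normal
    dilution factor with CV ``design.dilution_cv``; the TSP internal
    standard is exempt (it is added to the measurement buffer at a fixed
    amount, which is also what makes it a usable reference).
    """
    effects = effects or EffectSpec()
    library = library or build_default_library(design.fluid)
    base_levels = dict(base_levels or default_base_levels(library))
    ss = np.random.SeedSequence(seed)
    conc_seed, dil_seed, *render_seeds = ss.generate_state(
        2 + len(design.groups) * len(design.days) * design.n_per_cell)
    truth = sample_concentrations(design, effects, base_levels, int(conc_seed),
                                  sigma_log=sigma_log)
    dilution = None
    if design.fluid == "urine" and design.dilution_cv > 0:
        sigma_d = float(np.sqrt(np.log1p(design.dilution_cv ** 2)))
        drng = np.random.default_rng(np.random.SeedSequence(int(dil_seed)))
        factors = np.exp(drng.normal(-sigma_d ** 2 / 2.0, sigma_d,
                                     size=truth.concentrations.shape[0]))
        dilution = pd.Series(factors, index=truth.concentrations.index, name="dilution")
        truth.dilution = dilution
    spectra: list[Spectrum1D] = []
    for i, sid in enumerate(truth.concentrations.index):
        conc = truth.concentrations.loc[sid].to_dict()
        if dilution is not None:
            d = float(dilution.loc[sid])
            conc = {m: (v if m == "TSP" else v * d) for m, v in conc.items()}
        meta = SampleMeta(sample_id=sid,
                          group=truth.sample_meta.loc[sid, "group"],
                          day=truth.sample_meta.loc[sid, "day"],
                          fluid=design.fluid)
        spectra.append(render_spectrum(conc, library, design,
                                       int(render_seeds[i]), meta=meta))
    return spectra, truth


def write_cohort(out_dir: str | Path, spectra: Sequence[Spectrum1D],
                 truth: SyntheticTruth, design: CohortDesign,
                 format: str = "csv") -> list[Path]:
    """Write spectra (+ truth table and design config) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = {"csv": ".csv", "jcampdx": ".jdx"}[format]
    written = []
    for sp in spectra:
        p = out_dir / f"{sp.meta.sample_id}{suffix}"
        write_spectrum(sp, p, format=format)
        written.append(p)
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path)
    written.append(truth_path)
    cfg_path = out_dir / "design.json"
    cfg_path.write_text(json.dumps({
        "fluid": design.fluid, "groups": design.groups, "days": design.days,
        "n_per_cell": design.n_per_cell, "ppm_range": design.ppm_range,
        "points": design.points, "noise_sd": design.noise_sd,
        "shift_jitter_sd": design.shift_jitter_sd,
        "baseline_amplitude": design.baseline_amplitude,
        "dilution_cv": design.dilution_cv,
        "effects": [{"metabolite": e.metabolite, "day": e.day,
                     "fold_change": e.fold_change} for e in truth.effects.effects],
    }, indent=2))
    written.append(cfg_path)
    return written
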