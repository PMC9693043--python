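"""Differential-metabolite screening, volcano datasets and masked reports.

A metabolite counts as significantly changed in a within-day C-vs-H
comparison when three conditions hold simultaneously:

* two-sided t-test p < alpha (default 0.05),
* |r| above a critical correlation-loading threshold (default the exact
  Pearson critical value at alpha for the comparison's degrees of
  freedom; the fixed 0.5 cut is one configuration of the same rule),
* VIP in the top decile of the comparison's VIP distribution.

Reports render r as "/" below a *display* threshold (default the
critical value at p = 0.05 with df = 7, which is 0.666), mirroring how
such screening tables are conventionally printed.
"""

from __future__ import annotations

import math
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import chemo
from .spectra import DAYS, FeatureMatrix


class ScreenError(ValueError):
    """Raised for invalid screening inputs."""


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def critical_r(alpha: float = 0.05, df: int = 7) -> float:
    """Critical Pearson |r| at two-sided level ``alpha`` with ``df`` degrees
    of freedom: t / sqrt(t^2 + df) with t the Student-t critical value.

    critical_r(0.05, 7) = 0.666 (3 d.p.); critical_r(0.05, 14) ~ 0.497,
    the usual "|r| > 0.5" rule for a pooled 8-vs-8 comparison.
    """
    if not 0.0 < alpha < 1.0:
        raise ScreenError("alpha must lie in (0, 1)")
    if df < 1:
        raise ScreenError("df must be >= 1")
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / math.sqrt(t * t + df))


def fold_change(values: np.ndarray, groups: Sequence[str]) -> float:
    """mean(H) / mean(C); NaN when either group mean is non-positive."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    h = values[groups == "H"]
    c = values[groups == "C"]
    if h.size == 0 or c.size == 0:
        raise ScreenError("fold change needs both groups non-empty")
    mh, mc = h.mean(), c.mean()
    if mh <= 0 or mc <= 0:
        return float("nan")
    return float(mh / mc)


def group_ttest(values: np.ndarray, groups: Sequence[str],
                variant: str = "welch") -> float:
    """Two-sided two-sample t-test p value (Welch by default)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    h = values[groups == "H"]
    c = values[groups == "C"]
    if h.size < 2 or c.size < 2:
        raise ScreenError("t-test needs at least 2 samples per group")
    if h.std() == 0 and c.std() == 0:
        return 1.0 if h.mean() == c.mean() else 0.0
    equal_var = {"welch": False, "student": True}.get(variant)
    if equal_var is None:
        raise ScreenError(f"unknown t-test variant {variant!r}")
    return float(stats.ttest_ind(h, c, equal_var=equal_var).pvalue)


# ---------------------------------------------------------------------------
# per-comparison screening
# ---------------------------------------------------------------------------

def comparison_label(day: str) -> str:
    """'D11' -> 'C11-H11', the conventional column label."""
    if day not in DAYS:
        raise ScreenError(f"unknown day {day!r}")
    n = day[1:]
    return f"C{n}-H{n}"


def screen_comparison(stats_df: pd.DataFrame, alpha: float = 0.05,
                      r_rule: float | tuple[float, int] | None = None,
                      vip_top: float = 0.10) -> pd.DataFrame:
    """Apply the three-way screen to aligned per-feature statistics.

    ``stats_df`` must carry columns r, p, vip, fold_change indexed by
    feature.  ``r_rule`` is either a fixed |r| threshold or an
    (alpha, df) pair passed to :func:`critical_r`.  The VIP cut is the
    (1 - vip_top) quantile of the comparison's VIPs (linear interpolation).
    Adds boolean ``significant`` plus the thresholds used.
    """
    required = {"r", "p", "vip", "fold_change"}
    missing = required - set(stats_df.columns)
    if missing:
        raise ScreenError(f"stats table missing columns {sorted(missing)}")
    if isinstance(r_rule, tuple):
        r_cut = critical_r(*r_rule)
    elif r_rule is None:
        r_cut = critical_r(alpha, 7)
    else:
        r_cut = float(r_rule)
    vip_cut = float(np.quantile(stats_df["vip"].to_numpy(dtype=float), 1.0 - vip_top))
    out = stats_df.copy()
    with np.errstate(invalid="ignore"):
        out["significant"] = ((out["p"] < alpha)
                              & (out["r"].abs() >= r_cut)
                              & (out["vip"] >= vip_cut)).fillna(False)
    out.attrs["alpha"] = alpha
    out.attrs["r_cut"] = r_cut
    out.attrs["vip_cut"] = vip_cut
    return out


@dataclass
class ComparisonResult:
    """Everything the screen produced for one within-day C-vs-H contrast."""

    day: str
    label: str
    stats: pd.DataFrame  # feature-indexed: r, p, vip, fold_change, fc_masked, significant
    model: chemo.OplsdaModel
    summary: dict


def compare_groups(matrix: FeatureMatrix, day: str, n_orth: int = 1,
                   alpha: float = 0.05,
                   r_rule: float | tuple[float, int] | None = None,
                   vip_top: float = 0.10, folds: int = 7, n_perm: int = 0,
                   seed: int = 0, ttest_variant: str = "welch") -> ComparisonResult:
    """Fit OPLS-DA for one day's C-vs-H contrast and run the screen.

    The multivariate statistics (r, VIP) come from the Pareto-scaled
    model; fold changes and t-tests are computed on the raw quantities.
    By default the |r| rule is the exact critical value for the pooled
    degrees of freedom (n_samples - 2) of this comparison.
    """
    sub = matrix.subset(day=day)
    if sub.n_samples < 4:
        raise ScreenError(f"comparison {day} has too few samples ({sub.n_samples})")
    y = sub.class_vector()
    scaled, _ = chemo.scale(sub, "pareto")
    X = scaled.values.to_numpy(dtype=float)
    try:
        model = chemo.fit_oplsda(X, y, n_orth=n_orth)
    except chemo.ChemoError:
        model = chemo.fit_oplsda(X, y, n_orth=0)
    r = chemo.correlation_loadings(model, X)
    vip = model.vip
    raw = sub.values
    groups = sub.meta["group"].to_numpy()
    fc_masked = getattr(matrix, "fc_masked", set())
    rows = {}
    for j, feat in enumerate(raw.columns):
        v = raw[feat].to_numpy(dtype=float)
        fc = float("nan") if feat in fc_masked else fold_change(v, groups)
        rows[feat] = {"r": r[j], "p": group_ttest(v, groups, ttest_variant),
                      "vip": vip[j], "fold_change": fc,
                      "fc_masked": feat in fc_masked}
    stats_df = pd.DataFrame.from_dict(rows, orient="index")
    stats_df.index.name = "feature"
    if r_rule is None:
        r_rule = (alpha, sub.n_samples - 2)
    stats_df = screen_comparison(stats_df, alpha=alpha, r_rule=r_rule, vip_top=vip_top)
    spec = chemo.FitSpec(method="oplsda", n_orth=model.n_orth)
    # stratified CV needs folds <= minority class size (folds >= n means LOO)
    n_min = int(min((groups == "C").sum(), (groups == "H").sum()))
    folds_eff = folds if folds >= len(y) else min(folds, n_min)
    model.q2 = chemo.cross_validate(spec, X, y, folds=folds_eff, seed=seed)
    extras = {"day": day, "n_samples": sub.n_samples, "q2": model.q2}
    if n_perm > 0:
        perm = chemo.permutation_test(spec, X, y, n_perm=n_perm, seed=seed,
                                      folds=folds_eff)
        anova = chemo.cv_anova(spec, X, y, folds=folds_eff, seed=seed)
        extras.update({"permutation_p_r2y": perm.p_r2y, "permutation_p_q2": perm.p_q2,
                       "cv_anova_f": anova.f_statistic, "cv_anova_p": anova.p_value})
    summary = chemo.model_summary(model, extras)
    return ComparisonResult(day=day, label=comparison_label(day),
                            stats=stats_df, model=model, summary=summary)


# ---------------------------------------------------------------------------
# volcano dataset
# ---------------------------------------------------------------------------

def build_volcano(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Four-dimensional volcano dataset: x = log2(FC), y = -log10(p),
    point size keyed by VIP, color keyed by |r|.

    Features with a masked fold change or undefined p are skipped.
    """
    keep = stats_df["fold_change"].notna() & stats_df["p"].notna() \
        & (stats_df["fold_change"] > 0) & (stats_df["p"] > 0)
    df = stats_df.loc[keep]
    out = pd.DataFrame({
        "feature": df.index,
        "log2_fold_change": np.log2(df["fold_change"].to_numpy(dtype=float)),
        "neglog10_p": -np.log10(df["p"].to_numpy(dtype=float)),
        "vip": df["vip"].to_numpy(dtype=float),
        "abs_r": df["r"].abs().to_numpy(dtype=float),
    }).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# masked report tables
# ---------------------------------------------------------------------------

#: default display threshold for printing r: critical value at p=0.05, df=7
DISPLAY_R_DF = 7

_NAME_VARIANTS = {
    "n,n-dimethylglycin": "n,n-dimethylglycine",
    "alpha-ketoglutarate": "α-ketoglutarate",
    "a-ketoglutarate": "α-ketoglutarate",
}


def normalize_name(name: str) -> str:
    """Canonical metabolite key: casefold, trim, unify spelling variants."""
    key = unicodedata.normalize("NFC", name).strip().casefold()
    key = " ".join(key.split())
    return _NAME_VARIANTS.get(key, key)


@dataclass
class ScreeningTable:
    """Metabolites x comparisons table of (r, fold change), NaN = masked."""

    r: pd.DataFrame  # metabolite x comparison label
    fc: pd.DataFrame
    display_r_threshold: float = field(default_factory=lambda: critical_r(0.05, DISPLAY_R_DF))

    def __post_init__(self) -> None:
        if not self.r.index.equals(self.fc.index) or not self.r.columns.equals(self.fc.columns):
            raise ScreenError("r and fold-change tables must be aligned")
        if self.r.index.duplicated().any():
            dup = self.r.index[self.r.index.duplicated()][0]
            raise ScreenError(f"duplicate metabolite row {dup!r}")

    @property
    def metabolites(self) -> list[str]:
        return list(self.r.index)

    @property
    def comparisons(self) -> list[str]:
        return list(self.r.columns)

    def significant_metabolites(self) -> list[str]:
        """Metabolites with at least one unmasked (displayed-r) comparison."""
        keep = self.r.notna().any(axis=1)
        return list(self.r.index[keep])

    def to_csv(self, path: str | Path) -> None:
        cols: dict[str, list[str]] = {}
        for label in self.comparisons:
            cols[f"r_{label}"] = [
                "/" if pd.isna(v) else f"{v:g}" for v in self.r[label]]
            cols[f"fc_{label}"] = [
                "/" if pd.isna(v) else f"{v:g}" for v in self.fc[label]]
        out = pd.DataFrame(cols, index=self.r.index)
        out.index.name = "metabolite"
        out.to_csv(path)

    def to_records(self) -> list[dict]:
        recs = []
        for met in self.metabolites:
            cells = {}
            for label in self.comparisons:
                rv, fv = self.r.loc[met, label], self.fc.loc[met, label]
                cells[label] = {"r": None if pd.isna(rv) else float(rv),
                                "fold_change": None if pd.isna(fv) else float(fv),
                                "direction": (None if pd.isna(fv)
                                              else ("up" if fv > 1 else "down" if fv < 1 else "flat"))}
            recs.append({"metabolite": met, "cells": cells})
        return recs


def build_report(comparisons: Mapping[str, pd.DataFrame],
                 display_r_threshold: float | None = None) -> ScreeningTable:
    """Assemble per-comparison screening stats into a masked report.

    ``comparisons`` maps comparison label -> stats table (as produced by
    :func:`compare_groups` / :func:`screen_comparison`).  r is displayed
    only where |r| reaches the display threshold; fold change is shown
    whenever it is computable.
    """
    if display_r_threshold is None:
        display_r_threshold = critical_r(0.05, DISPLAY_R_DF)
    labels = list(comparisons)
    features: list[str] = []
    for df in comparisons.values():
        for feat in df.index:
            if feat not in features:
                features.append(feat)
    r = pd.DataFrame(np.nan, index=features, columns=labels)
    fc = pd.DataFrame(np.nan, index=features, columns=labels)
    for label, df in comparisons.items():
        for feat in df.index:
            rv = df.loc[feat, "r"]
            if pd.notna(rv) and abs(rv) >= display_r_threshold:
                r.loc[feat, label] = rv
            fv = df.loc[feat, "fold_change"]
            if pd.notna(fv):
                fc.loc[feat, label] = fv
    return ScreeningTable(r=r, fc=fc, display_r_threshold=display_r_threshold)


def read_report_csv(path: str | Path) -> ScreeningTable:
    """Read a masked report CSV ("/" = masked cell) back into a table."""
    df = pd.read_csv(path, comment="#", index_col="metabolite", dtype=str)
    r_cols = [c for c in df.columns if c.startswith("r_")]
    fc_cols = [c for c in df.columns if c.startswith("fc_")]
    labels = [c[2:] for c in r_cols]
    if labels != [c[3:] for c in fc_cols]:
        raise ScreenError(f"{path}: r_*/fc_* columns do not pair up")

    def parse(col: pd.Series) -> pd.Series:
        return pd.to_numeric(col.where(col.str.strip() != "/"), errors="raise")

    r = pd.DataFrame({lab: parse(df[f"r_{lab}"]) for lab in labels})
    fc = pd.DataFrame({lab: parse(df[f"fc_{lab}"]) for lab in labels})
    return ScreeningTable(r=r, fc=fc)


def load_reference_report(fluid: str) -> ScreeningTable:
    """Packaged reference screening reports (plasma / urine)."""
    name = {"plasma": "table1_plasma.csv", "urine": "table2_urine.csv"}.get(fluid)
    if name is None:
        raise ScreenError(f"no reference report for fluid {fluid!r}")
    with resources.as_file(resources.files("gestox.data") / name) as p:
        return read_report_csv(p)


def summarize_counts(tables: Mapping[str, ScreeningTable]) -> dict:
    """Per-fluid significant-metabolite counts plus union and intersection.

    Names are normalized (case, spelling variants) before set algebra, so
    |union| = sum of per-fluid counts - |intersection| holds exactly.
    """
    per_fluid = {}
    sets: list[set[str]] = []
    for fluid, table in tables.items():
        names = {normalize_name(m) for m in table.significant_metabolites()}
        per_fluid[fluid] = len(names)
        sets.append(names)
    union: set[str] = set().union(*sets) if sets else set()
    inter = set.intersection(*sets) if sets else set()
    return {"per_fluid": per_fluid, "union": len(union),
            "intersection": len(inter),
            "union_names": sorted(union), "intersection_names": sorted(inter)}
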