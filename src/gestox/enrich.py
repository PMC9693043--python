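"""Metabolite-set over-representation analysis (hypergeometric ORA).

Given a hit list of differential metabolites and the background of all
quantified metabolites, each pathway's enrichment p value is the
upper-tail hypergeometric probability of drawing at least the observed
overlap, with Benjamini-Hochberg adjustment across the tested pathways.
Pathway membership comes from GMT files (one pathway per line:
id, description, member ids).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen import normalize_name


class EnrichError(ValueError):
    """Raised for invalid enrichment inputs."""


@dataclass
class PathwaySet:
    """pathway id -> (display name, member metabolite ids)."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (_, members) in self.pathways.items():
            if not members:
                raise EnrichError(f"pathway {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.pathways)

    def items(self):
        return self.pathways.items()


def read_pathways(path: str | Path, format: str = "gmt") -> PathwaySet:
    """Read a GMT file; duplicate members within a pathway are collapsed."""
    if format != "gmt":
        raise EnrichError(f"unknown pathway format {format!r}")
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            warnings.warn(f"{path}: line {lineno}: empty pathway skipped")
            continue
        pid, name = parts[0].strip(), parts[1].strip()
        if pid in pathways:
            raise EnrichError(f"{path}: duplicate pathway id {pid!r}")
        members = frozenset(normalize_name(m) for m in parts[2:] if m.strip())
        pathways[pid] = (name, members)
    return PathwaySet(pathways)


def write_pathways(pathways: PathwaySet, path: str | Path) -> None:
    lines = []
    for pid, (name, members) in pathways.items():
        lines.append("\t".join([pid, name, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_demo_pathways() -> PathwaySet:
    """Small curated demo pathway collection shipped with the package.

    Covers the six pathways most relevant to gestational-hypoxia
    metabolomics, with members drawn from the fluids' metabolite
    vocabulary.  It is a demo resource for testing and examples, not a
    KEGG export.
    """
    with resources.as_file(resources.files("gestox.data") / "demo_pathways.gmt") as p:
        return read_pathways(p)


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    overlap: int
    pathway_size: int  # background-restricted
    background_size: int
    hits_size: int
    p_value: float
    adjusted_p: float
    overlap_names: tuple[str, ...]


def ora(hits: Iterable[str], background: Iterable[str],
        pathways: PathwaySet) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``hits`` within ``background``.

    p = P(overlap >= observed) under random draws of |hits| metabolites
    from the background; BH adjustment across tested pathways.  Pathways
    with no background member are skipped.  Names are normalized before
    matching.
    """
    hit_set = {normalize_name(h) for h in hits}
    bg_set = {normalize_name(b) for b in background}
    stray = sorted(hit_set - bg_set)
    if stray:
        raise EnrichError(f"hits not contained in background: {stray}")
    if not hit_set:
        return []
    M, N = len(bg_set), len(hit_set)
    rows = []
    for pid, (name, members) in pathways.items():
        in_bg = members & bg_set
        if not in_bg:
            continue
        overlap = sorted(in_bg & hit_set)
        k, n = len(overlap), len(in_bg)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append((pid, name, k, n, p, tuple(overlap)))
    if not rows:
        return []
    ps = np.array([r[4] for r in rows])
    adj = stats.false_discovery_control(ps, method="bh")
    results = [
        EnrichmentResult(pathway_id=pid, name=name, overlap=k, pathway_size=n,
                         background_size=M, hits_size=N, p_value=p,
                         adjusted_p=float(a), overlap_names=names)
        for (pid, name, k, n, p, names), a in zip(rows, adj)]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of ORA results, ordered by raw p."""
    return pd.DataFrame([{
        "pathway_id": r.pathway_id, "name": r.name, "overlap": r.overlap,
        "pathway_size": r.pathway_size, "background_size": r.background_size,
        "hits_size": r.hits_size, "p_value": r.p_value,
        "adjusted_p": r.adjusted_p, "overlap_names": ";".join(r.overlap_names),
    } for r in results])
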