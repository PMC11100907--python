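"""Threshold gating and per-sample immune scoring.

The original imaging workflow phenotyped cells with density-based flow
cytometry tooling; that procedure is not reproducible from published
parameters, so this module gates with explicit per-marker intensity
thresholds supplied in a :class:`GatingConfig` (deterministic and
auditable), plus derived boolean phenotype expressions evaluated in
dependency order.  An automatic threshold picker based on the kernel
density of log intensity is available but never the default.

Scores implemented here:

* TIL fraction — CD3+ T cells plus CD20+ B cells as a percentage of all
  cells, counting CD3+CD20+ double positives once (set union, so the
  fraction can never exceed 100).
* TPS — PD-L1+ tumor cells / all tumor cells × 100.
* CPS — (PD-L1+ tumor cells + PD-L1+ immune cells) / all tumor cells × 100.
  CPS is deliberately not capped at 100: the defining formula has no cap,
  so a sample with few tumor cells and many PD-L1+ immune cells can exceed
  100 (the clinical-assay convention of capping is a separate choice).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, QCWarning, SchemaError, ValidationError
from .io_model import INTENSITY_PREFIX, CellTable

#: immune phenotypes whose union forms the CPS "immune cell" set
DEFAULT_CPS_IMMUNE = ("CD3", "CD20", "CD68")

#: named cell populations as boolean expressions over base phenotype flags.
#: These mirror the panel definitions used throughout the analysis.
POPULATION_DEFS: dict[str, str] = {
    "Tum": "Tum",
    "T": "CD3",
    "B": "CD20",
    "Mac": "CD68",
    "CD8T": "CD3 AND CD8",
    "CD8nT": "CD3 AND NOT CD8",
    "Treg": "CD3 AND Foxp3",
    "TIL": "CD3 OR CD20",
    "Myoep": "aSMA AND p63",
}

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_KEYWORDS = {"AND", "OR", "NOT", "and", "or", "not"}


def _expr_names(expr: str) -> set[str]:
    return {m.group(0) for m in _IDENT.finditer(expr) if m.group(0) not in _KEYWORDS}


def _eval_expr(expr: str, env: Mapping[str, np.ndarray]) -> np.ndarray:
    """Evaluate a boolean gate expression against named boolean arrays.

    Grammar: identifiers, AND/OR/NOT (case-insensitive keywords), and
    parentheses.  Trailing +/− on identifiers are accepted as positive /
    negated gates (``CD8-`` ≡ ``NOT CD8``).
    """
    expr = re.sub(r"([A-Za-z_][A-Za-z0-9_]*)\s*\+", r"\1", expr)
    expr = re.sub(r"([A-Za-z_][A-Za-z0-9_]*)\s*[-−]", r"(NOT \1)", expr)
    py = re.sub(r"\bAND\b", "and", expr)
    py = re.sub(r"\bOR\b", "or", py)
    py = re.sub(r"\bNOT\b", "not", py)
    py = py.replace(" and ", " & ").replace(" or ", " | ")
    py = re.sub(r"\bnot\s+", "~", py)
    names = _expr_names(expr)
    missing = sorted(n for n in names if n not in env)
    if missing:
        raise ConfigError(f"expression {expr!r} references undefined gate(s): {missing}")
    local = {n: env[n] for n in names}
    try:
        result = eval(py, {"__builtins__": {}}, local)  # noqa: S307 - restricted namespace
    except SyntaxError as e:
        raise ConfigError(f"cannot parse gate expression {expr!r}") from e
    return np.asarray(result, dtype=bool)


@dataclass
class GatingConfig:
    """Per-marker intensity cutoffs plus derived phenotype expressions.

    ``thresholds`` gates marker M positive when ``int_M > cutoff``
    (strictly).  ``derived_phenotypes`` maps new phenotype names to boolean
    expressions over already-defined gates; definitions may reference each
    other and are evaluated in topological order (cycles are an error).
    """

    thresholds: dict[str, float] = field(default_factory=dict)
    derived_phenotypes: dict[str, str] = field(default_factory=dict)

    def derived_order(self) -> list[str]:
        ts = TopologicalSorter()
        for name, expr in self.derived_phenotypes.items():
            deps = _expr_names(expr) & set(self.derived_phenotypes)
            ts.add(name, *deps)
        try:
            return list(ts.static_order())
        except CycleError as e:
            raise ConfigError(f"cyclic derived phenotype definitions: {e.args[1]}") from None


def auto_threshold(intensities: np.ndarray) -> float:
    """Threshold at the minimum between the two highest modes of the
    kernel density of log intensity.  Provided for exploration; explicit
    thresholds are the supported path."""
    from scipy.signal import argrelextrema
    from scipy.stats import gaussian_kde

    v = np.log(np.asarray(intensities, dtype=float) + 1e-9)
    grid = np.linspace(v.min(), v.max(), 512)
    dens = gaussian_kde(v)(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) < 2:
        return float(np.exp(np.median(v)))
    top2 = sorted(sorted(maxima, key=lambda i: dens[i])[-2:])
    valley = top2[0] + int(np.argmin(dens[top2[0]:top2[1] + 1]))
    return float(np.exp(grid[valley]))


def gate_phenotypes(cells: CellTable, config: GatingConfig) -> CellTable:
    """Set phenotype flags by threshold comparison, then derived rules.

    Cells already carrying a phenotype column listed in ``thresholds`` are
    re-gated only if the matching intensity column exists; otherwise the
    existing flags pass through unchanged.
    """
    df = cells.df.copy()
    for marker, cutoff in config.thresholds.items():
        col = INTENSITY_PREFIX + marker
        if col not in df.columns:
            if marker in df.columns and df[marker].dtype == bool:
                continue  # pre-gated upstream
            raise SchemaError(f"marker {marker!r} has no intensity column {col!r}")
        df[marker] = df[col].to_numpy(dtype=float) > cutoff
    env = {c: df[c].to_numpy() for c in df.columns if df[c].dtype == bool}
    for name in config.derived_order():
        env[name] = _eval_expr(config.derived_phenotypes[name], env)
        df[name] = env[name]
    return CellTable(df, validate=False)


def resolve_population(cells: CellTable, population: str) -> np.ndarray:
    """Boolean mask for a phenotype column or a named population alias."""
    if population in cells.df.columns and cells.df[population].dtype == bool:
        return cells.positive(population)
    if population in POPULATION_DEFS:
        env = {c: cells.df[c].to_numpy() for c in cells.phenotypes}
        return _eval_expr(POPULATION_DEFS[population], env)
    raise SchemaError(f"unknown phenotype or population {population!r}")


# ---------------------------------------------------------------------------
# scores


def til_fraction(cells: CellTable) -> float:
    """Percent of all cells that are CD3+ T cells or CD20+ B cells."""
    n = len(cells)
    if n == 0:
        warnings.warn("TIL fraction undefined on empty cell table", QCWarning)
        return float("nan")
    member = resolve_population(cells, "CD3") | resolve_population(cells, "CD20")
    return 100.0 * member.sum() / n


def tps(cells: CellTable, tumor: str = "Tum", pdl1: str = "PDL1") -> float:
    """PD-L1 tumor proportion score: PD-L1+ tumor / all tumor × 100."""
    tum = resolve_population(cells, tumor)
    n_tum = int(tum.sum())
    if n_tum == 0:
        warnings.warn("TPS undefined: no tumor cells", QCWarning)
        return float("nan")
    pos = resolve_population(cells, pdl1)
    return 100.0 * (tum & pos).sum() / n_tum


def cps(
    cells: CellTable,
    tumor: str = "Tum",
    pdl1: str = "PDL1",
    immune_phenotypes: Sequence[str] = DEFAULT_CPS_IMMUNE,
) -> float:
    """PD-L1 combined positive score; denominator is tumor cells only and
    the score is not capped at 100."""
    tum = resolve_population(cells, tumor)
    n_tum = int(tum.sum())
    if n_tum == 0:
        warnings.warn("CPS undefined: no tumor cells", QCWarning)
        return float("nan")
    pos = resolve_population(cells, pdl1)
    immune = np.zeros(len(cells), dtype=bool)
    for p in immune_phenotypes:
        immune |= resolve_population(cells, p)
    immune &= ~tum
    return 100.0 * ((tum & pos).sum() + (immune & pos).sum()) / n_tum


# ---------------------------------------------------------------------------
# per-sample summaries


@dataclass
class PopulationSummary:
    """Per-sample population fractions, densities, ratios and checkpoint scores.

    Fractions are percent of total cells; densities are cells/mm² within a
    region class; ratios are population-count ratios (NaN when the
    denominator count is zero).
    """

    sample_id: str
    fractions: dict[str, float]
    densities: dict[str, float]
    ratios: dict[str, float]
    tps: float
    cps: float
    til_pct: float
    qc_flags: set[str] = field(default_factory=set)

    def to_series(self) -> pd.Series:
        data: dict[str, float] = {}
        data.update({f"{k}.pct": v for k, v in self.fractions.items()})
        data.update(self.densities)
        data.update(self.ratios)
        data.update({"TPS": self.tps, "CPS": self.cps, "TIL": self.til_pct})
        return pd.Series(data, name=self.sample_id)


DEFAULT_RATIOS = {
    "Treg_T.ratio": ("Treg", "T"),
    "CD8T_T.ratio": ("CD8T", "T"),
    "B_T.ratio": ("B", "T"),
    "Mac_T.ratio": ("Mac", "T"),
}

DEFAULT_DENSITY_REGIONS = ("DCIS", "stroma")


def population_summary(
    cells: CellTable,
    regions: pd.DataFrame,
    config: GatingConfig | None = None,
    populations: Sequence[str] = ("Tum", "T", "CD8T", "CD8nT", "Treg", "B", "Mac"),
    ratios: Mapping[str, tuple[str, str]] = DEFAULT_RATIOS,
    density_regions: Sequence[str] = DEFAULT_DENSITY_REGIONS,
) -> PopulationSummary:
    """Summarise one sample's gated cell table.

    Densities divide the population count among cells whose ``region_class``
    matches by the summed area (mm²) of that class in the region table; a
    class with zero total area yields a missing density with a QC flag.
    """
    samples = cells.sample_ids
    if len(samples) != 1:
        raise ValidationError(f"population_summary expects one sample, got {samples}")
    sid = samples[0]
    if config is not None:
        cells = gate_phenotypes(cells, config)
    n = len(cells)
    qc: set[str] = set()

    fractions = {}
    for p in populations:
        mask = resolve_population(cells, p)
        fractions[p] = 100.0 * mask.sum() / n if n else float("nan")
    if n == 0:
        qc.add("empty_table")

    reg = regions[regions["sample"] == sid]
    class_area_mm2 = reg.groupby("region_class")["area"].sum() / 1e6
    densities = {}
    rc_col = cells.df["region_class"].to_numpy() if n else np.array([])
    for p in populations:
        mask = resolve_population(cells, p) if n else np.array([], dtype=bool)
        for rc in density_regions:
            key = f"{p}.density.{rc}"
            area = float(class_area_mm2.get(rc, 0.0))
            if area <= 0:
                densities[key] = float("nan")
                qc.add(f"no_area:{rc}")
                continue
            densities[key] = float((mask & (rc_col == rc)).sum()) / area

    ratio_vals = {}
    for name, (num, den) in ratios.items():
        if n == 0:
            ratio_vals[name] = float("nan")
            continue
        n_num = int(resolve_population(cells, num).sum())
        n_den = int(resolve_population(cells, den).sum())
        if n_den == 0:
            ratio_vals[name] = float("nan")
            qc.add(f"zero_denominator:{name}")
        else:
            ratio_vals[name] = n_num / n_den

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", QCWarning)
        t = tps(cells) if n else float("nan")
        c = cps(cells) if n else float("nan")
        til = til_fraction(cells)
    if np.isnan(t):
        qc.add("tps_undefined")
    if np.isnan(c):
        qc.add("cps_undefined")
    return PopulationSummary(
        sample_id=sid, fractions=fractions, densities=densities,
        ratios=ratio_vals, tps=t, cps=c, til_pct=til, qc_flags=qc,
    )
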