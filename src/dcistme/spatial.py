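"""Spatial point-pattern statistics for the DCIS microenvironment.

Implements the four spatial measures the analysis is built on:

* **Morisita–Horn colocalization** of two cell types counted over a
  tessellation of non-overlapping hexagons with 100 μm sides.  MH = 1 when
  the two types have proportional counts in every hexagon (colocalized),
  0 when no hexagon holds both types (segregated).
* **Cross nearest-neighbor distribution** G(r): the probability that a
  reference-type cell has at least one target-type cell within distance r,
  estimated as the raw empirical CDF of per-reference nearest-neighbor
  distances.  No edge correction is applied by default: at the 20 μm radii
  of interest on mm-scale fields the boundary bias is negligible and the
  uncorrected estimator is exactly reproducible; a border-exclusion option
  is available.
* **Spatial Proximity Score (SPS)**: the exact area under the G(r) step
  function on [0, 20] μm.  SPS is directional — sps(a→b) averages over
  a-cells, so it generally differs from sps(b→a).
* **Myoepithelial continuity**: the average nearest-neighbor distance among
  αSMA+/p63+ myoepithelial cells within DCIS regions, reverse-scored
  cohort-wide as (max over samples + 1) − value so that a high score means
  a tightly spaced (intact) myoepithelial layer.  NOTE: the reverse score
  depends on the cohort maximum, so scores are comparable only within one
  cohort.

When a cell is positive for both the reference and the target type
(overlapping definitions such as Treg ⊂ T cell), it never counts as its
own nearest neighbor; a distinct cell at the same location is a legal
neighbor at distance 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, QCWarning, ValidationError
from .io_model import CellTable
from .phenotyping import resolve_population

#: features computed from fewer reference or target cells than this carry a QC flag
MIN_CELLS_QC = 5

SPS_RADIUS = 20.0  # μm; roughly two lymphocyte diameters
HEX_SIDE = 100.0  # μm


def _as_mask(cells: CellTable, cell_type) -> np.ndarray:
    if isinstance(cell_type, str):
        return resolve_population(cells, cell_type)
    mask = np.asarray(cell_type, dtype=bool)
    if mask.shape != (len(cells),):
        raise ValidationError("boolean mask length does not match cell table")
    return mask


# ---------------------------------------------------------------------------
# hexagonal binning and Morisita-Horn


@dataclass
class HexCounts:
    """Per-hexagon counts of two cell types on a shared tessellation."""

    side: float
    origin: tuple[float, float]
    counts: dict[tuple[int, int], list[int]]

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.array([v[0] for v in self.counts.values()], dtype=float)
        b = np.array([v[1] for v in self.counts.values()], dtype=float)
        return a, b


def _axial_round(q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # cube rounding of fractional axial coordinates
    x, z = q, r
    y = -x - z
    rx, ry, rz = np.round(x), np.round(y), np.round(z)
    dx, dy, dz = np.abs(rx - x), np.abs(ry - y), np.abs(rz - z)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def hex_bin(cells: CellTable, type_a, type_b, side: float = HEX_SIDE) -> HexCounts:
    """Count two cell types over a pointy-top hexagonal tessellation.

    The tessellation is anchored at the bounding-box minimum of the union
    of both types, making the binning deterministic for a given pattern.
    Every cell falls in exactly one hexagon; totals are conserved.
    """
    if side <= 0:
        raise ConfigError(f"hex side must be > 0, got {side}")
    mask_a = _as_mask(cells, type_a)
    mask_b = _as_mask(cells, type_b)
    xy = cells.coords()
    both = mask_a | mask_b
    if not both.any():
        return HexCounts(side=side, origin=(0.0, 0.0), counts={})
    origin = xy[both].min(axis=0)
    counts: dict[tuple[int, int], list[int]] = {}
    for mask, slot in ((mask_a, 0), (mask_b, 1)):
        pts = xy[mask] - origin
        if len(pts) == 0:
            continue
        q = (np.sqrt(3.0) / 3.0 * pts[:, 0] - pts[:, 1] / 3.0) / side
        r = (2.0 / 3.0 * pts[:, 1]) / side
        qi, ri = _axial_round(q, r)
        for key in zip(qi.tolist(), ri.tolist()):
            counts.setdefault(key, [0, 0])[slot] += 1
    return HexCounts(side=side, origin=(float(origin[0]), float(origin[1])), counts=counts)


def morisita_horn(counts) -> float:
    """Morisita–Horn similarity of two count distributions over shared bins.

    Accepts a :class:`HexCounts` or a pair of count vectors.  Returns NaN
    with a QC warning when either type has zero total count.
    """
    if isinstance(counts, HexCounts):
        a, b = counts.arrays()
    else:
        a, b = (np.asarray(v, dtype=float) for v in counts)
        if a.shape != b.shape:
            raise ValidationError("count vectors must share the same bins")
    A, B = a.sum(), b.sum()
    if A == 0 or B == 0:
        warnings.warn("Morisita-Horn undefined: a type has zero cells", QCWarning)
        return float("nan")
    num = 2.0 * float(np.dot(a, b))
    den = ((a @ a) / A**2 + (b @ b) / B**2) * A * B
    return num / den


# ---------------------------------------------------------------------------
# cross nearest-neighbor distances, G(r), SPS


def _nearest_cross(xy: np.ndarray, ref_idx: np.ndarray, tgt_idx: np.ndarray) -> np.ndarray:
    """Distance from each ref cell to its nearest *distinct* target cell."""
    tgt_xy = xy[tgt_idx]
    tree = cKDTree(tgt_xy)
    k = min(2, len(tgt_idx))
    dist, pos = tree.query(xy[ref_idx], k=k)
    if k == 1:
        dist = dist[:, None]
        pos = pos[:, None]
    tgt_of = tgt_idx[pos]  # global row ids of the returned neighbors
    out = np.full(len(ref_idx), np.nan)
    first_is_self = tgt_of[:, 0] == ref_idx
    out[~first_is_self] = dist[~first_is_self, 0]
    if k == 2:
        out[first_is_self] = dist[first_is_self, 1]
    # refs whose only target is themselves stay NaN and are dropped
    return out[~np.isnan(out)]


def cross_nn_distances(
    cells: CellTable,
    ref_type,
    target_type,
    border_exclude: float | None = None,
) -> np.ndarray:
    """Per-reference-cell distance to the nearest distinct target cell.

    ``border_exclude`` optionally drops reference cells within that margin
    of the pattern's bounding box (minus-sampling border correction).
    """
    ref = _as_mask(cells, ref_type)
    tgt = _as_mask(cells, target_type)
    xy = cells.coords()
    ref_idx = np.flatnonzero(ref)
    tgt_idx = np.flatnonzero(tgt)
    if len(ref_idx) == 0 or len(tgt_idx) == 0:
        warnings.warn("cross_nn_distances undefined: empty reference or target set", QCWarning)
        return np.array([])
    if border_exclude is not None:
        lo = xy.min(axis=0) + border_exclude
        hi = xy.max(axis=0) - border_exclude
        keep = ((xy[ref_idx] >= lo) & (xy[ref_idx] <= hi)).all(axis=1)
        ref_idx = ref_idx[keep]
        if len(ref_idx) == 0:
            warnings.warn("border exclusion removed every reference cell", QCWarning)
            return np.array([])
    d = _nearest_cross(xy, ref_idx, tgt_idx)
    if len(d) == 0:
        warnings.warn("no distinct target cell for any reference cell", QCWarning)
    return d


@dataclass
class GFunctionCurve:
    """Empirical cross nearest-neighbor distribution as a step function."""

    jumps: np.ndarray  # sorted nearest-neighbor distances, μm
    n_ref: int
    ref_type: str = ""
    target_type: str = ""

    def __call__(self, r) -> np.ndarray:
        """G(r): fraction of reference cells with a target within r
        (right-continuous)."""
        return np.searchsorted(self.jumps, np.asarray(r, dtype=float), side="right") / self.n_ref


def g_curve(distances: np.ndarray, ref_type: str = "", target_type: str = "") -> GFunctionCurve:
    d = np.sort(np.asarray(distances, dtype=float))
    if len(d) == 0:
        raise ValidationError("cannot build a G curve from zero distances")
    if (d < 0).any():
        raise ValidationError("nearest-neighbor distances must be >= 0")
    return GFunctionCurve(jumps=d, n_ref=len(d), ref_type=ref_type, target_type=target_type)


def sps(curve: GFunctionCurve, r_max: float = SPS_RADIUS) -> float:
    """Spatial Proximity Score: exact area under G(r) on [0, r_max].

    Computed as the closed-form step-function area
    Σ_i max(0, r_max − d_i) / n, so the score lies in [0, r_max] and equals
    r_max when every reference cell sits on a target cell.
    """
    if r_max <= 0:
        raise ConfigError(f"r_max must be > 0, got {r_max}")
    return float(np.clip(r_max - curve.jumps, 0.0, None).sum() / curve.n_ref)


def sps_pair(cells: CellTable, ref_type, target_type, r_max: float = SPS_RADIUS) -> float:
    """Convenience: cross NN distances → G curve → SPS, NaN when undefined."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", QCWarning)
        d = cross_nn_distances(cells, ref_type, target_type)
    if len(d) == 0:
        warnings.warn("SPS undefined: empty reference or target set", QCWarning)
        return float("nan")
    return sps(g_curve(d), r_max=r_max)


def mh_pair(cells: CellTable, type_a, type_b, side: float = HEX_SIDE) -> float:
    """Convenience: hex binning → Morisita–Horn index."""
    return morisita_horn(hex_bin(cells, type_a, type_b, side=side))


# ---------------------------------------------------------------------------
# distance from epithelium


def distance_from_epithelium(cells: CellTable, marker: str) -> float:
    """Mean distance from marker+ cells to the nearest αSMA+p63+
    myoepithelial cell.

    For ``marker == "aSMA"`` the numerator population is αSMA+p63−
    (the co-positive myoepithelial cells themselves are excluded).
    """
    myoep = resolve_population(cells, "aSMA") & resolve_population(cells, "p63")
    num = _as_mask(cells, marker)
    if marker == "aSMA":
        num = num & ~resolve_population(cells, "p63")
    if num.sum() == 0 or myoep.sum() == 0:
        warnings.warn(f"{marker}_DistFromEpithelium undefined: empty set", QCWarning)
        return float("nan")
    xy = cells.coords()
    d = _nearest_cross(xy, np.flatnonzero(num), np.flatnonzero(myoep))
    if len(d) == 0:
        warnings.warn(f"{marker}_DistFromEpithelium undefined: no distinct myoepithelial cell", QCWarning)
        return float("nan")
    return float(d.mean())


# ---------------------------------------------------------------------------
# myoepithelial continuity


def myoep_continuity_raw(cells: CellTable, regions: pd.DataFrame) -> dict[str, float]:
    """Average nearest-neighbor distance among myoepithelial cells within
    DCIS regions, per sample.

    Distances never cross region boundaries; regions with fewer than two
    myoepithelial cells are excluded; the per-sample average weights every
    contributing cell equally (regions with more cells weigh more).
    """
    out: dict[str, float] = {}
    dcis_regions = regions[regions["region_class"] == "DCIS"]
    for sid in cells.sample_ids:
        sub = cells.for_sample(sid)
        myo = resolve_population(sub, "aSMA") & resolve_population(sub, "p63")
        rids = dcis_regions.loc[dcis_regions["sample"] == sid, "region_id"]
        nn_all: list[np.ndarray] = []
        for rid in rids:
            in_reg = myo & (sub.df["region_id"] == rid).to_numpy()
            pts = sub.coords(in_reg)
            if len(pts) < 2:
                continue
            tree = cKDTree(pts)
            d, _ = tree.query(pts, k=2)
            nn_all.append(d[:, 1])
        if nn_all:
            out[sid] = float(np.concatenate(nn_all).mean())
        else:
            warnings.warn(f"sample {sid}: <2 myoepithelial cells in every DCIS region", QCWarning)
            out[sid] = float("nan")
    return out


def myoep_continuity_score(raw: Mapping[str, float]) -> dict[str, float]:
    """Reverse-score raw distances: score = (cohort max + 1 μm) − raw.

    High score ⇔ short inter-cell distances ⇔ intact myoepithelial layer.
    Cohort-relative: the score depends on the cohort maximum, so values are
    only comparable within the cohort they were scored in.
    """
    vals = [v for v in raw.values() if not np.isnan(v)]
    if not vals:
        raise ValidationError("all raw continuity values are missing")
    top = max(vals) + 1.0
    return {k: (top - v if not np.isnan(v) else float("nan")) for k, v in raw.items()}


# ---------------------------------------------------------------------------
# batch feature computation


@dataclass
class SpatialFeature:
    """A named per-sample spatial feature with QC bookkeeping."""

    sample_id: str
    name: str
    value: float
    n_ref: int = 0
    n_target: int = 0
    qc: bool = False


def spatial_features(
    cells: CellTable,
    regions: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]],
    min_cells: int = MIN_CELLS_QC,
    include_continuity: bool = True,
) -> list[SpatialFeature]:
    """Compute a panel of spatial features for every sample.

    ``pairs`` lists (ref, target, metric) with metric in
    {"MHI", "SPS", "DistFromEpithelium"}; for DistFromEpithelium the target
    entry is ignored (always the αSMA+p63+ layer).  Feature names follow
    the ``<ref>_<target>.SPS`` / ``<a>_<b>.MHI`` /
    ``<marker>_DistFromEpithelium`` convention (SPS direction: ref first).
    Features from fewer than ``min_cells`` reference or target cells are
    reported with ``qc=True``, never suppressed.
    """
    feats: list[SpatialFeature] = []
    continuity_raw: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", QCWarning)
        for sid in cells.sample_ids:
            sub = cells.for_sample(sid)
            for ref, target, metric in pairs:
                n_ref = int(_as_mask(sub, ref).sum())
                if metric == "MHI":
                    n_tgt = int(_as_mask(sub, target).sum())
                    val = mh_pair(sub, ref, target)
                    name = f"{ref}_{target}.MHI"
                elif metric == "SPS":
                    n_tgt = int(_as_mask(sub, target).sum())
                    val = sps_pair(sub, ref, target)
                    name = f"{ref}_{target}.SPS"
                elif metric == "DistFromEpithelium":
                    myo = resolve_population(sub, "aSMA") & resolve_population(sub, "p63")
                    n_tgt = int(myo.sum())
                    val = distance_from_epithelium(sub, ref)
                    name = f"{ref}_DistFromEpithelium"
                else:
                    raise ConfigError(f"unknown spatial metric {metric!r}")
                feats.append(
                    SpatialFeature(
                        sample_id=sid, name=name, value=val,
                        n_ref=n_ref, n_target=n_tgt,
                        qc=(n_ref < min_cells or n_tgt < min_cells),
                    )
                )
        if include_continuity:
            continuity_raw = myoep_continuity_raw(cells, regions)
    if include_continuity and continuity_raw:
        if all(np.isnan(v) for v in continuity_raw.values()):
            for sid, v in continuity_raw.items():
                feats.append(SpatialFeature(sid, "MyoEpiContinuity", float("nan"), qc=True))
        else:
            scores = myoep_continuity_score(continuity_raw)
            for sid, v in scores.items():
                feats.append(
                    SpatialFeature(sid, "MyoEpiContinuity", v, qc=bool(np.isnan(v)))
                )
    return feats


def features_frame(feats: Sequence[SpatialFeature]) -> pd.DataFrame:
    """Pivot a feature list into a samples × features matrix (NaN missing)."""
    if not feats:
        return pd.DataFrame()
    df = pd.DataFrame(
        {"sample": [f.sample_id for f in feats],
         "name": [f.name for f in feats],
         "value": [f.value for f in feats]}
    )
    return df.pivot_table(index="sample", columns="name", values="value", aggfunc="first")
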