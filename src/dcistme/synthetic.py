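"""Synthetic tissue, cohort and feature-matrix generators.

The generators emulate the geometric and statistical structure the
downstream analysis assumes, so that every stage of the pipeline can be
exercised without access to clinical imaging data:

* circular ducts ringed by αSMA+/p63+ myoepithelial cells, with ring
  positions independently vacated at a controllable rate (the "gap
  fraction") to emulate scattered myoepithelial discontinuity,
* pancytokeratin+ tumor cells as a homogeneous Poisson process inside
  ducts,
* stromal immune populations (CD8+ T, CD8− T, Treg, B, macrophage) as
  Poisson processes in the stroma, optionally displaced radially toward
  the nearest duct boundary to emulate immune attraction to tumor,
* marker-intensity log-normal mixtures for threshold-gating tests,
* a cohort outcome model in which the recurrence hazard is exponential in
  z-scored spatial/immune features.

None of the geometric defaults are estimates of any real cohort; they are
chosen to be histologically plausible (duct radii of order 100 μm, cell
densities of order 10³–10⁴ cells/mm²).  The generators make no attempt to
simulate marker spillover, segmentation error or image noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_model import CellTable, ClinicalRecord, INTENSITY_PREFIX

#: immune population name → phenotype flags set true for that population
POPULATION_PHENOTYPES: dict[str, dict[str, bool]] = {
    "T": {"CD3": True},
    "CD8T": {"CD3": True, "CD8": True},
    "CD8nT": {"CD3": True, "CD8": False},
    "Treg": {"CD3": True, "Foxp3": True},
    "B": {"CD20": True},
    "Mac": {"CD68": True},
}

#: phenotype columns every simulated cell table carries
PHENOTYPE_COLUMNS = (
    "Tum", "CD3", "CD8", "CD20", "Foxp3", "CD68", "PDL1", "PD1", "aSMA", "p63",
)

#: markers for which intensity mixtures are emitted when requested
INTENSITY_MARKERS = ("Tum", "CD3", "CD8", "CD20", "Foxp3", "CD68", "PDL1")

_INTENSITY_MU_POS = 2.0  # log-scale mean for marker-positive cells
_INTENSITY_MU_NEG = 0.0  # log-scale mean for marker-negative cells
_INTENSITY_SIGMA = 0.4


@dataclass
class TissueConfig:
    """Geometry and composition of one simulated tissue field.

    Units: μm for lengths, cells/μm² for intensities (0.001 cells/μm² =
    1000 cells/mm²).  ``gap_fraction`` is the probability that each
    regularly spaced myoepithelial ring position is left vacant
    (independent thinning: scattered vacancies lengthen nearest-neighbor
    distances monotonically in the rate, which a single contiguous gap
    would not).  ``attraction_sigma`` (if set) displaces each stromal
    immune cell toward the nearest duct boundary by |N(0, σ)|, clipped at
    the boundary.
    """

    n_ducts: int = 3
    duct_radius: float = 120.0
    field_size: tuple[float, float] = (1500.0, 1500.0)
    myoep_spacing: float = 15.0
    gap_fraction: float = 0.0
    tumor_intensity: float = 0.004
    immune_intensities: Mapping[str, float] = field(
        default_factory=lambda: {
            "CD8T": 3e-4, "CD8nT": 4e-4, "Treg": 1e-4, "B": 2e-4, "Mac": 2e-4,
        }
    )
    attraction_sigma: float | None = None
    pdl1_tumor_prob: float = 0.1
    pdl1_immune_prob: float = 0.1
    pd1_t_prob: float = 0.2
    duct_region_class: str = "DCIS"
    emit_intensities: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.duct_radius <= 0:
            raise ConfigError("duct_radius must be > 0")
        if not (0.0 <= self.gap_fraction <= 1.0):
            raise ConfigError("gap_fraction must be in [0, 1]")
        for name in ("pdl1_tumor_prob", "pdl1_immune_prob", "pd1_t_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.n_ducts < 0 or self.myoep_spacing <= 0:
            raise ConfigError("n_ducts must be >= 0 and myoep_spacing > 0")
        unknown = set(self.immune_intensities) - set(POPULATION_PHENOTYPES)
        if unknown:
            raise ConfigError(f"unknown immune population(s): {sorted(unknown)}")


def _place_ducts(rng: np.random.Generator, cfg: TissueConfig) -> np.ndarray:
    """Rejection-sample non-overlapping duct centers fully inside the field."""
    w, h = cfg.field_size
    r = cfg.duct_radius
    if 2 * r > min(w, h):
        raise ConfigError("duct diameter exceeds the field")
    centers: list[np.ndarray] = []
    for _ in range(cfg.n_ducts):
        for attempt in range(1000):
            c = rng.uniform([r, r], [w - r, h - r])
            if all(np.linalg.norm(c - o) > 2 * r for o in centers):
                centers.append(c)
                break
        else:
            raise ConfigError(
                f"could not place {cfg.n_ducts} non-overlapping ducts in 1000 attempts"
            )
    return np.array(centers).reshape(-1, 2)


def _ring_points(
    rng: np.random.Generator, center: np.ndarray, cfg: TissueConfig
) -> np.ndarray:
    """Myoepithelial positions: a regularly spaced ring, independently
    thinned at rate ``gap_fraction``."""
    r = cfg.duct_radius
    n = int(round(2.0 * math.pi * r / cfg.myoep_spacing))
    if n == 0 or cfg.gap_fraction >= 1.0:
        return np.empty((0, 2))
    start = rng.uniform(0.0, 2.0 * math.pi)
    # full-circle spacing 2πr/n reproduces myoep_spacing up to rounding
    angles = start + 2.0 * math.pi * np.arange(n) / n
    kept = rng.uniform(size=n) >= cfg.gap_fraction
    angles = angles[kept]
    return center + r * np.stack([np.cos(angles), np.sin(angles)], axis=1)


def _poisson_in_disk(
    rng: np.random.Generator, center: np.ndarray, radius: float, intensity: float
) -> np.ndarray:
    n = rng.poisson(intensity * math.pi * radius**2)
    rad = radius * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return center + np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)


def _poisson_in_stroma(
    rng: np.random.Generator, cfg: TissueConfig, centers: np.ndarray, intensity: float
) -> np.ndarray:
    """Uniform points in the field outside every duct, Poisson-distributed."""
    w, h = cfg.field_size
    stroma_area = w * h - len(centers) * math.pi * cfg.duct_radius**2
    n = rng.poisson(intensity * max(stroma_area, 0.0))
    pts = np.empty((0, 2))
    while len(pts) < n:
        cand = rng.uniform([0.0, 0.0], [w, h], size=(max(n - len(pts), 16) * 2, 2))
        if len(centers):
            d = np.linalg.norm(cand[:, None, :] - centers[None, :, :], axis=2)
            cand = cand[(d > cfg.duct_radius).all(axis=1)]
        pts = np.vstack([pts, cand])
    return pts[:n]


def _attract(
    rng: np.random.Generator, pts: np.ndarray, centers: np.ndarray, cfg: TissueConfig
) -> np.ndarray:
    """Displace stromal points radially toward the nearest duct boundary."""
    if cfg.attraction_sigma is None or cfg.attraction_sigma == 0 or not len(centers) or not len(pts):
        return pts
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    c = centers[nearest]
    dist = d[np.arange(len(pts)), nearest]
    pull = np.abs(rng.normal(0.0, cfg.attraction_sigma, size=len(pts)))
    new_dist = np.maximum(cfg.duct_radius, dist - pull)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dist[:, None] > 0, (pts - c) / dist[:, None], 0.0)
    moved = c + unit * new_dist[:, None]
    # a displaced point may clip a second duct; push it back to that boundary
    if len(centers) > 1:
        d2 = np.linalg.norm(moved[:, None, :] - centers[None, :, :], axis=2)
        inside = d2 < cfg.duct_radius
        for i in np.flatnonzero(inside.any(axis=1)):
            j = int(d2[i].argmin())
            v = moved[i] - centers[j]
            norm = np.linalg.norm(v)
            if norm == 0:
                v, norm = np.array([1.0, 0.0]), 1.0
            moved[i] = centers[j] + v / norm * cfg.duct_radius
    return moved


def _blank_frame(n: int) -> dict:
    row: dict = {}
    for p in PHENOTYPE_COLUMNS:
        row[p] = np.zeros(n, dtype=bool)
    return row


def simulate_tissue(config: TissueConfig) -> tuple[CellTable, pd.DataFrame]:
    """Simulate one tissue field; returns (cell table, region table).

    Fully reproducible for a given ``config.seed``.  The region table
    carries one duct region per duct (class ``config.duct_region_class``,
    area πr²) plus one stroma region holding the remaining field area.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    centers = _place_ducts(rng, config)
    sid = "S0"

    frames: list[pd.DataFrame] = []
    regions: list[dict] = []

    for i, c in enumerate(centers):
        rid = f"duct{i}"
        regions.append(
            {"sample": sid, "region_id": rid, "region_class": config.duct_region_class,
             "area": math.pi * config.duct_radius**2}
        )
        ring = _ring_points(rng, c, config)
        if len(ring):
            cols = _blank_frame(len(ring))
            cols.update(
                {"sample": sid, "x": ring[:, 0], "y": ring[:, 1],
                 "compartment": "duct", "region_class": config.duct_region_class,
                 "region_id": rid}
            )
            cols["aSMA"] = np.ones(len(ring), dtype=bool)
            cols["p63"] = np.ones(len(ring), dtype=bool)
            frames.append(pd.DataFrame(cols))
        tum = _poisson_in_disk(rng, c, config.duct_radius, config.tumor_intensity)
        if len(tum):
            cols = _blank_frame(len(tum))
            cols.update(
                {"sample": sid, "x": tum[:, 0], "y": tum[:, 1],
                 "compartment": "duct", "region_class": config.duct_region_class,
                 "region_id": rid}
            )
            cols["Tum"] = np.ones(len(tum), dtype=bool)
            cols["PDL1"] = rng.uniform(size=len(tum)) < config.pdl1_tumor_prob
            frames.append(pd.DataFrame(cols))

    for pop, intensity in config.immune_intensities.items():
        pts = _poisson_in_stroma(rng, config, centers, intensity)
        pts = _attract(rng, pts, centers, config)
        if not len(pts):
            continue
        cols = _blank_frame(len(pts))
        cols.update(
            {"sample": sid, "x": pts[:, 0], "y": pts[:, 1],
             "compartment": "stroma", "region_class": "stroma", "region_id": None}
        )
        for flag, value in POPULATION_PHENOTYPES[pop].items():
            cols[flag] = np.full(len(pts), value)
        cols["PDL1"] = rng.uniform(size=len(pts)) < config.pdl1_immune_prob
        if POPULATION_PHENOTYPES[pop].get("CD3"):
            cols["PD1"] = rng.uniform(size=len(pts)) < config.pd1_t_prob
        frames.append(pd.DataFrame(cols))

    w, h = config.field_size
    stroma_area = w * h - len(centers) * math.pi * config.duct_radius**2
    if stroma_area > 0:
        regions.append(
            {"sample": sid, "region_id": "stroma_all", "region_class": "stroma",
             "area": stroma_area}
        )

    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(
            {"sample": pd.Series(dtype=str), "x": pd.Series(dtype=float),
             "y": pd.Series(dtype=float)}
        )
        for p in PHENOTYPE_COLUMNS:
            df[p] = pd.Series(dtype=bool)
    if config.emit_intensities and len(df):
        for m in INTENSITY_MARKERS:
            pos = df[m].to_numpy(dtype=bool)
            mu = np.where(pos, _INTENSITY_MU_POS, _INTENSITY_MU_NEG)
            df[INTENSITY_PREFIX + m] = np.exp(rng.normal(mu, _INTENSITY_SIGMA))
    table = CellTable(df, validate=bool(len(df)))
    region_table = pd.DataFrame(regions, columns=["sample", "region_id", "region_class", "area"])
    return table, region_table


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortConfig:
    """A cohort of tissue fields with an exponential recurrence model.

    ``tissue_ranges`` maps :class:`TissueConfig` field names to (low, high)
    uniform ranges sampled independently per sample; unlisted fields keep
    the ``tissue`` defaults.  The hazard for sample s is
    ``baseline_hazard * exp(Σ_f coef_f · z_f(s))`` with features z-scored
    across the cohort; event times are exponential, censored at
    ``censor_time``.
    """

    n_samples: int = 60
    tissue: TissueConfig = field(default_factory=TissueConfig)
    tissue_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    outcome_model: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.05
    censor_time: float = 10.0
    invasive_event_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.censor_time <= 0:
            raise ConfigError("censor_time must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        valid = set(TissueConfig.__dataclass_fields__)
        unknown = set(self.tissue_ranges) - valid
        if unknown:
            raise ConfigError(f"unknown tissue parameter(s) in ranges: {sorted(unknown)}")


_INT_TISSUE_FIELDS = {"n_ducts"}


def _feature_value(table: CellTable, regions: pd.DataFrame, name: str) -> float:
    """Compute a named outcome-model feature for one sample.

    Supported names: ``<ref>_<target>.SPS``, ``<a>_<b>.MHI``, ``TIL``,
    ``MyoEpiContinuityRaw`` (the cohort-relative reverse scoring of
    ``MyoEpiContinuity`` is applied by :func:`simulate_cohort`).
    """
    import warnings as _w

    from .errors import QCWarning
    from .phenotyping import til_fraction
    from .spatial import mh_pair, myoep_continuity_raw, sps_pair

    with _w.catch_warnings():
        _w.simplefilter("ignore", QCWarning)
        if name == "TIL":
            return til_fraction(table)
        if name in ("MyoEpiContinuityRaw", "MyoEpiContinuity"):
            raw = myoep_continuity_raw(table, regions)
            return next(iter(raw.values())) if raw else float("nan")
        if name.endswith(".SPS"):
            ref, target = name[:-4].split("_", 1)
            return sps_pair(table, ref, target)
        if name.endswith(".MHI"):
            a, b = name[:-4].split("_", 1)
            return mh_pair(table, a, b)
    raise ConfigError(f"outcome model references unknown feature {name!r}")


def _check_feature_names(names) -> None:
    for name in names:
        ok = (
            name in ("TIL", "MyoEpiContinuity", "MyoEpiContinuityRaw")
            or (name.endswith(".SPS") and "_" in name[:-4])
            or (name.endswith(".MHI") and "_" in name[:-4])
        )
        if not ok:
            raise ConfigError(f"outcome model references unknown feature {name!r}")


def simulate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, CellTable], pd.DataFrame, list[ClinicalRecord], dict]:
    """Simulate a cohort: tissues, regions, clinical outcomes, truth.

    Returns (cell tables by sample, combined region table, clinical
    records, true_params).  ``true_params`` holds the per-sample feature
    values, linear predictors and uncensored event times for
    parameter-recovery experiments.
    """
    config.validate()
    _check_feature_names(config.outcome_model)
    rng = np.random.default_rng(config.seed)

    tables: dict[str, CellTable] = {}
    region_frames: list[pd.DataFrame] = []
    feature_rows: list[dict[str, float]] = []
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]

    for sid in sample_ids:
        overrides: dict = {}
        for fname, (lo, hi) in config.tissue_ranges.items():
            v = rng.uniform(lo, hi)
            overrides[fname] = int(round(v)) if fname in _INT_TISSUE_FIELDS else v
        tissue_cfg = replace(
            config.tissue, seed=int(rng.integers(0, 2**31 - 1)), **overrides
        )
        table, regions = simulate_tissue(tissue_cfg)
        table.df["sample"] = sid
        regions["sample"] = sid
        tables[sid] = table
        region_frames.append(regions)
        feature_rows.append(
            {f: _feature_value(table, regions, f) for f in config.outcome_model}
        )

    all_regions = (
        pd.concat(region_frames, ignore_index=True)
        if region_frames
        else pd.DataFrame(columns=["sample", "region_id", "region_class", "area"])
    )
    features = pd.DataFrame(feature_rows, index=sample_ids)
    if "MyoEpiContinuity" in features.columns:
        from .spatial import myoep_continuity_score

        raw = features["MyoEpiContinuity"].to_dict()
        features["MyoEpiContinuity"] = pd.Series(myoep_continuity_score(raw))

    lp = np.zeros(config.n_samples)
    for fname, coef in config.outcome_model.items():
        v = features[fname].to_numpy(dtype=float)
        sd = np.nanstd(v)
        z = (v - np.nanmean(v)) / sd if sd > 0 else np.zeros_like(v)
        z = np.nan_to_num(z)
        lp += coef * z

    hazard = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    observed = t_event <= config.censor_time
    followup = np.minimum(t_event, config.censor_time)
    invasive = rng.uniform(size=config.n_samples) < config.invasive_event_prob

    records: list[ClinicalRecord] = []
    for i, sid in enumerate(sample_ids):
        event = "none"
        if observed[i]:
            event = "invasive" if invasive[i] else "DCIS"
        records.append(
            ClinicalRecord(
                sample_id=sid,
                age=float(np.clip(rng.normal(50.0, 8.0), 25.0, 85.0)),
                grade=int(rng.choice([1, 2, 3], p=[0.15, 0.35, 0.5])),
                hr="pos" if rng.uniform() < 0.7 else "neg",
                her2="pos" if rng.uniform() < 0.3 else "neg",
                comedo=bool(rng.uniform() < 0.5),
                palpable=bool(rng.uniform() < 0.4),
                path_mass=bool(rng.uniform() < 0.5),
                followup_time=float(followup[i]),
                event=event,
            )
        )

    true_params = {
        "features": features,
        "linear_predictor": pd.Series(lp, index=sample_ids),
        "event_time": pd.Series(t_event, index=sample_ids),
        "coefficients": dict(config.outcome_model),
        "baseline_hazard": config.baseline_hazard,
        "censor_time": config.censor_time,
    }
    return tables, all_regions, records, true_params


# ---------------------------------------------------------------------------
# planted feature matrices for clustering recovery


def simulate_planted_matrix(
    n_per_cluster: Sequence[int],
    n_features: int,
    separation: float,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian feature matrix with planted clusters.

    A random half of the features are informative: on those, cluster c has
    mean ``separation · c`` (unit noise SD), so adjacent clusters are
    separated by ``separation`` standard deviations.  Missing cells are
    inserted completely at random at ``missing_rate``.
    """
    if separation < 0:
        raise ConfigError("separation must be >= 0")
    if not (0.0 <= missing_rate < 1.0):
        raise ConfigError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.full(n, c) for c, n in enumerate(n_per_cluster)])
    n = len(labels)
    informative = rng.choice(n_features, size=max(n_features // 2, 1), replace=False)
    means = np.zeros((len(n_per_cluster), n_features))
    means[:, informative] = separation * np.arange(len(n_per_cluster))[:, None]
    X = rng.normal(means[labels], 1.0)
    if missing_rate > 0:
        X[rng.uniform(size=X.shape) < missing_rate] = np.nan
    df = pd.DataFrame(
        X,
        index=[f"S{i:03d}" for i in range(n)],
        columns=[f"F{j:02d}" for j in range(n_features)],
    )
    return df, labels
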