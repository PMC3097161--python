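"""Synthetic phenotype-microarray experiments with known ground truth.

No public raw kinetic dataset accompanies the standard two-strain PM
design, so this module generates one: logistic growth (or inhibition)
curves with additive Gaussian noise, laid out exactly like an instrument
run — by default 2 strains × 20 plates × 96 wells × 2 replicates, read
every 15 minutes over 72 hours (289 time points per curve).  The
generator can plant ground-truth effects for recovery testing: aberrant
replicates (time-reversed curves) for the outlier screen, distinct shape
families for clustering, and known test/parent summary ratios for the
fold-change comparison.  Everything is driven by a single seeded RNG, so
a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .io import write_kinetic_csv, write_phenotype_map
from .model import WELL_IDS, KineticCurve, RecordSet, WellRecord
from .curves import curve_summary

__all__ = [
    "GrowthModel",
    "ExperimentConfig",
    "ControlConfig",
    "TruthTable",
    "generate_experiment",
    "generate_negative_controls",
    "write_experiment",
]

#: Reserved phenotype label for negative-control wells.
NEGATIVE_CONTROL_PHENOTYPE = "negative_control"


@dataclass(frozen=True)
class GrowthModel:
    """Logistic kinetic model for one well.

    ``v(t) = baseline + A * sigma(direction * r * (t - t_m)) + noise``
    with ``sigma`` the logistic function; ``direction=+1`` is growth,
    ``-1`` inhibition (signal decaying from an initially reduced state),
    and ``A = 0`` a no-growth (flat) well.  Noise is additive Gaussian
    per time point, clipped so intensities stay non-negative.
    """

    baseline: float  # intensity units
    amplitude: float  # intensity units (A)
    rate: float  # per minute (r)
    midpoint: float  # minutes (t_m)
    noise_sd: float  # intensity units
    direction: int = 1

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("baseline, amplitude and noise_sd must be >= 0")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 (growth) or -1 (inhibition)")

    def noiseless(self, times: np.ndarray) -> np.ndarray:
        from scipy.special import expit  # overflow-safe logistic

        z = self.direction * self.rate * (np.asarray(times, dtype=float) - self.midpoint)
        return self.baseline + self.amplitude * expit(z)

    def sample(self, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        v = self.noiseless(times)
        if self.noise_sd > 0:
            v = v + rng.normal(0.0, self.noise_sd, size=v.shape)
        return np.clip(v, 0.0, None)

    @property
    def shape(self) -> str:
        if self.amplitude == 0:
            return "flat"
        return "growth" if self.direction == 1 else "inhibition"


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of a synthetic PM experiment.

    Defaults mirror the standard bacterial panel: two strains (parent
    first), 20 plates of 96 wells, two replicates, one reading per well
    every 15 minutes for 72 hours.  Kinetic parameters are drawn per
    (plate, well) — the same substrate behaves the same for both strains
    unless a fold change is planted — from the stated uniform ranges.
    """

    strains: tuple[str, ...] = ("WT", "MUT")
    n_plates: int = 20
    wells_per_plate: int = 96
    replicates: int = 2
    cycle_min: float = 15.0
    duration_min: float = 72 * 60.0
    project: str = "SYN"
    species: str = "Bacillus sp."
    temperature: float = 37.0
    baseline: float = 20.0
    amplitude_range: tuple[float, float] = (120.0, 280.0)
    rate_range: tuple[float, float] = (0.005, 0.02)
    midpoint_range: tuple[float, float] = (600.0, 2400.0)
    noise_sd: float = 2.0  # ~1% of a typical amplitude
    growth_fraction: float = 0.7
    inhibition_fraction: float = 0.0
    n_outliers: int = 0
    #: (plate, well) -> planted test/parent summary ratio (applied to
    #: every non-parent strain; the whole noiseless curve is scaled).
    planted_ratios: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = []
        if len(self.strains) < 1 or len(set(self.strains)) != len(self.strains):
            bad.append("strains")
        if self.n_plates < 1:
            bad.append("n_plates")
        if not 1 <= self.wells_per_plate <= 96:
            bad.append("wells_per_plate")
        if self.replicates < 1:
            bad.append("replicates")
        if self.cycle_min <= 0 or self.duration_min < self.cycle_min:
            bad.append("cycle_min/duration_min")
        if self.noise_sd < 0 or self.baseline < 0:
            bad.append("noise_sd/baseline")
        if not 0 <= self.growth_fraction <= 1 or not 0 <= self.inhibition_fraction <= 1:
            bad.append("growth_fraction/inhibition_fraction")
        if self.growth_fraction + self.inhibition_fraction > 1:
            bad.append("growth_fraction+inhibition_fraction")
        if self.n_outliers < 0:
            bad.append("n_outliers")
        if any(r <= 0 or not np.isfinite(r) for r in self.planted_ratios.values()):
            bad.append("planted_ratios")
        if bad:
            raise ValueError(f"invalid experiment config value(s): {bad}")

    @property
    def times(self) -> np.ndarray:
        n = int(self.duration_min // self.cycle_min) + 1
        return np.arange(n) * self.cycle_min

    @property
    def plates(self) -> tuple[str, ...]:
        return tuple(f"PM{i:02d}" for i in range(1, self.n_plates + 1))

    @property
    def wells(self) -> tuple[str, ...]:
        return WELL_IDS[: self.wells_per_plate]

    @property
    def parent_strain(self) -> str:
        return self.strains[0]

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "strains" in raw:
            raw["strains"] = tuple(raw["strains"])
        for key in ("amplitude_range", "rate_range", "midpoint_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "planted_ratios" in raw:
            raw["planted_ratios"] = {
                (str(p), str(w)): float(r)
                for (p, w, r) in (
                    entry if isinstance(entry, (list, tuple)) else entry.split(":")
                    for entry in raw["planted_ratios"]
                )
            }
        return cls(**raw)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a generated experiment.

    ``models`` holds the per-(plate, well) kinetic parameters shared by
    all strains; ``cluster_labels`` the shape family of each well;
    ``outliers`` the (strain, plate, well, replicate) slots whose curve
    was replaced with a time-reversed one; ``planted_ratios`` the true
    test/parent summary ratios.
    """

    seed: int
    models: dict[tuple[str, str], GrowthModel]
    cluster_labels: dict[tuple[str, str], str]
    outliers: frozenset[tuple[str, str, str, int]]
    planted_ratios: dict[tuple[str, str], float]

    def to_table(self) -> tuple[list, list[str]]:
        columns = [
            "plate",
            "well",
            "shape",
            "baseline",
            "amplitude",
            "rate",
            "midpoint",
            "noise_sd",
            "planted_ratio",
        ]
        rows = []
        for (plate, well), m in self.models.items():
            rows.append(
                [
                    plate,
                    well,
                    m.shape,
                    m.baseline,
                    m.amplitude,
                    m.rate,
                    m.midpoint,
                    m.noise_sd,
                    self.planted_ratios.get((plate, well), 1.0),
                ]
            )
        return rows, columns


def _draw_model(cfg: ExperimentConfig, rng: np.random.Generator) -> GrowthModel:
    u = rng.random()
    if u < cfg.growth_fraction:
        direction, amp = 1, float(rng.uniform(*cfg.amplitude_range))
    elif u < cfg.growth_fraction + cfg.inhibition_fraction:
        direction, amp = -1, float(rng.uniform(*cfg.amplitude_range))
    else:
        direction, amp = 1, 0.0
    return GrowthModel(
        baseline=cfg.baseline,
        amplitude=amp,
        rate=float(rng.uniform(*cfg.rate_range)),
        midpoint=float(rng.uniform(*cfg.midpoint_range)),
        noise_sd=cfg.noise_sd,
        direction=direction,
    )


def generate_experiment(
    config: Optional[ExperimentConfig] = None, seed: int = 0
) -> tuple[RecordSet, TruthTable]:
    """Generate a seeded synthetic experiment and its ground truth.

    Records are emitted in (strain, plate, replicate, well) order — one
    plate-run per (strain, plate, replicate), matching the one-file-per-
    run export convention.  Planted outlier slots are drawn among growth
    wells only (reversing a flat curve changes nothing).
    """
    cfg = config or ExperimentConfig()
    rng = np.random.default_rng(seed)
    times = cfg.times

    models: dict[tuple[str, str], GrowthModel] = {}
    for plate in cfg.plates:
        for well in cfg.wells:
            models[(plate, well)] = _draw_model(cfg, rng)

    # choose planted-outlier slots among growth wells
    growth_slots = [
        (strain, plate, well, rep)
        for strain in cfg.strains
        for plate in cfg.plates
        for well in cfg.wells
        for rep in range(1, cfg.replicates + 1)
        if models[(plate, well)].shape == "growth"
    ]
    if cfg.n_outliers > len(growth_slots):
        raise ValueError(
            f"n_outliers={cfg.n_outliers} exceeds the {len(growth_slots)} "
            "growth-well replicate slots"
        )
    outliers: frozenset = frozenset()
    if cfg.n_outliers:
        idx = rng.choice(len(growth_slots), size=cfg.n_outliers, replace=False)
        outliers = frozenset(growth_slots[int(i)] for i in idx)

    planted = {k: float(v) for k, v in cfg.planted_ratios.items()}
    records = []
    for strain in cfg.strains:
        is_parent = strain == cfg.parent_strain
        for plate in cfg.plates:
            for rep in range(1, cfg.replicates + 1):
                for well in cfg.wells:
                    m = models[(plate, well)]
                    base = m.noiseless(times)
                    if not is_parent and (plate, well) in planted:
                        base = base * planted[(plate, well)]
                    if (strain, plate, well, rep) in outliers:
                        base = base[::-1].copy()
                    vals = base
                    if m.noise_sd > 0:
                        vals = vals + rng.normal(0.0, m.noise_sd, size=vals.shape)
                    vals = np.clip(vals, 0.0, None)
                    records.append(
                        WellRecord(
                            project=cfg.project,
                            species=cfg.species,
                            strain=strain,
                            phenotype=f"{plate}_{well}",
                            plate=plate,
                            well=well,
                            replicate=rep,
                            temperature=cfg.temperature,
                            curve=KineticCurve(times, vals),
                        )
                    )
    truth = TruthTable(
        seed=seed,
        models=models,
        cluster_labels={k: m.shape for k, m in models.items()},
        outliers=outliers,
        planted_ratios=planted,
    )
    return RecordSet(records), truth


@dataclass(frozen=True)
class ControlConfig:
    """Design of a synthetic negative-control set (flat noisy wells)."""

    count: int = 96
    baseline: float = 20.0
    noise_sd: float = 2.0
    cycle_min: float = 15.0
    duration_min: float = 72 * 60.0
    project: str = "SYN"
    species: str = "Bacillus sp."
    strain: str = "control"
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("control count must be >= 1")
        if self.baseline < 0 or self.noise_sd < 0:
            raise ValueError("baseline and noise_sd must be >= 0")
        if self.cycle_min <= 0 or self.duration_min < self.cycle_min:
            raise ValueError("invalid cycle_min/duration_min")


def generate_negative_controls(
    config: Optional[ControlConfig] = None, seed: int = 0
) -> RecordSet:
    """Flat noisy control wells carrying the reserved phenotype label.

    Wells cycle A01..H12 on plates NC01, NC02, ... as the count grows.
    """
    cfg = config or ControlConfig()
    rng = np.random.default_rng(seed)
    n = int(cfg.duration_min // cfg.cycle_min) + 1
    times = np.arange(n) * cfg.cycle_min
    records = []
    for i in range(cfg.count):
        plate = f"NC{i // 96 + 1:02d}"
        well = WELL_IDS[i % 96]
        vals = np.full(n, cfg.baseline)
        if cfg.noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.noise_sd, size=n)
        records.append(
            WellRecord(
                project=cfg.project,
                species=cfg.species,
                strain=cfg.strain,
                phenotype=NEGATIVE_CONTROL_PHENOTYPE,
                plate=plate,
                well=well,
                replicate=1,
                temperature=cfg.temperature,
                curve=KineticCurve(times, np.clip(vals, 0.0, None)),
            )
        )
    return RecordSet(records)


def write_experiment(
    rs: RecordSet,
    outdir: Union[str, Path],
    truth: Optional[TruthTable] = None,
) -> list[Path]:
    """Write an experiment as per-run kinetic CSVs plus sidecar files.

    One file per (strain, plate, replicate), named
    ``<strain>_<plate>_rep<replicate>.csv``; a ``phenotype_map.csv``
    covering every (plate, well); and, when truth is given, a
    ``truth_table.csv``.  Returns the kinetic file paths.
    """
    from .io import write_report_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runs: dict[tuple, list[WellRecord]] = {}
    phen_map: dict[tuple[str, str], str] = {}
    for rec in rs:
        runs.setdefault((rec.strain, rec.plate, rec.replicate), []).append(rec)
        phen_map.setdefault((rec.plate, rec.well), rec.phenotype)
    paths = []
    for (strain, plate, rep), members in runs.items():
        path = outdir / f"{strain}_{plate}_rep{rep}.csv"
        write_kinetic_csv(RecordSet(members), path)
        paths.append(path)
    write_phenotype_map(phen_map, outdir / "phenotype_map.csv")
    if truth is not None:
        rows, columns = truth.to_table()
        write_report_table(rows, columns, outdir / "truth_table.csv")
    return paths
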