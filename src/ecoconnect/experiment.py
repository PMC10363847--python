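"""Factorial experiment grids, seeding, and pipeline orchestration.

Two grids mirror the study design:

* the **biophysical grid** — 6 flow years x 6 release weeks x 2 swimming
  behaviors x 3 pelagic larval durations = 216 particle-tracking runs, each
  yielding one connectivity matrix;
* the **eco-genetic grid** — {6 matrix years + pooled} x {6 individual weeks
  + 3 week sets} x 3 model durations x 3 PLDs x 4 local population sizes x
  2 swimming behaviors = 4536 parameter combinations, each replicated 100
  times (453,600 runs) at full scale.

Child seeds are derived from a root seed and each cell's coordinates through
SHA-256, so every (parameter set, replicate) draws from an independent,
collision-free stream and reruns are bit-reproducible.

:func:`run_experiment` executes the whole chain at desk scale: synthesize a
domain and candidate flow scenarios, track particles into connectivity
matrices, generate a pseudo-empirical genotype panel under a designated
truth matrix, run the eco-genetic model for every candidate x replicate, and
score each run's predictive F_ST against the panel.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ecoconnect import (
    eco_genetic,
    fit_evaluation,
    particle_tracking,
    popgen,
    synthetic_domain,
)

logger = logging.getLogger(__name__)

MATRIX_YEARS = ("2014", "2015", "2016", "2017", "2018", "2019")
POOLED_YEARS = "2014-2019"
RELEASE_WEEKS = ("May(4)", "Jun(1)", "Jun(2)", "Jun(3)", "Jun(4)", "Jul(1)")
WEEK_SETS = {
    "set1": RELEASE_WEEKS[:3],  # early spawning window
    "set2": RELEASE_WEEKS[3:],  # late spawning window
    "set3": RELEASE_WEEKS,  # full window
}
MODEL_YEARS = (50, 100, 200)
PLD_DAYS = (30, 40, 50)
W_SWIM = (0.0, 0.0003)
LOCAL_N = (600, 800, 1000, 1200)
N_REPLICATES = 100


@dataclass(frozen=True)
class BiophysicalGridSpec:
    """Axes of the particle-tracking factorial (full factorial product)."""

    years: tuple = MATRIX_YEARS
    release_weeks: tuple = RELEASE_WEEKS
    w_swim: tuple = W_SWIM
    pld_days: tuple = PLD_DAYS


@dataclass(frozen=True)
class EcoGeneticGridSpec:
    """Axes of the eco-genetic factorial.

    ``matrix_year`` options are the individual years plus the pooled label;
    ``matrix_week`` options are the individual weeks plus the three week
    sets (set1 = early, set2 = late, set3 = all weeks), under which one
    matrix is redrawn each model year.
    """

    matrix_years: tuple = MATRIX_YEARS + (POOLED_YEARS,)
    matrix_weeks: tuple = RELEASE_WEEKS + tuple(WEEK_SETS)
    model_years: tuple = MODEL_YEARS
    pld_days: tuple = PLD_DAYS
    local_n: tuple = LOCAL_N
    w_swim: tuple = W_SWIM
    replicates: int = N_REPLICATES


@dataclass(frozen=True)
class ParameterSet:
    """One cell of the eco-genetic factorial grid (plus replicate index)."""

    model_years: int
    matrix_year: str
    matrix_week: str
    pld: int
    w_swim: float
    local_n: int
    replicate: int = 0

    @property
    def cell_id(self) -> str:
        return (
            f"y{self.matrix_year}_w{self.matrix_week}_pld{self.pld}"
            f"_sw{self.w_swim:g}_N{self.local_n}_my{self.model_years}"
        )

    def derive_seed(self, root_seed: int) -> int:
        """Collision-free child seed for this cell and replicate."""
        return derive_seed(root_seed, self.cell_id, self.replicate)


def derive_seed(root_seed: int, label: str, replicate: int = 0) -> int:
    """Hash (root seed, label, replicate) into a 63-bit integer seed.

    63 bits keep the full-scale grid (453,600 replicate runs) collision-free
    with overwhelming probability while remaining a plain non-negative int64.
    """
    digest = hashlib.sha256(
        f"{root_seed}|{label}|{replicate}".encode()
    ).digest()
    return int.from_bytes(digest[:8], "big") & 0x7FFFFFFFFFFFFFFF


def enumerate_biophysical_grid(
    spec: Optional[BiophysicalGridSpec] = None,
) -> list[dict]:
    """All tracking configurations: full Cartesian product, stable order."""
    spec = spec or BiophysicalGridSpec()
    grid = []
    for year, week, w_swim, pld in itertools.product(
        spec.years, spec.release_weeks, spec.w_swim, spec.pld_days
    ):
        grid.append(
            {
                "id": f"y{year}_w{week}_sw{w_swim:g}_pld{pld}",
                "year": year,
                "release_week": week,
                "w_swim": w_swim,
                "pld_days": pld,
            }
        )
    return grid


def enumerate_ecogenetic_grid(
    spec: Optional[EcoGeneticGridSpec] = None,
) -> list[ParameterSet]:
    """All unique eco-genetic parameter combinations (pre-replication)."""
    spec = spec or EcoGeneticGridSpec()
    return [
        ParameterSet(
            model_years=my,
            matrix_year=year,
            matrix_week=week,
            pld=pld,
            w_swim=sw,
            local_n=n,
        )
        for year, week, my, pld, n, sw in itertools.product(
            spec.matrix_years,
            spec.matrix_weeks,
            spec.model_years,
            spec.pld_days,
            spec.local_n,
            spec.w_swim,
        )
    ]


def total_runs(spec: Optional[EcoGeneticGridSpec] = None) -> int:
    """Unique combinations times replicates."""
    spec = spec or EcoGeneticGridSpec()
    return len(enumerate_ecogenetic_grid(spec)) * spec.replicates


def select_matrices(
    params: ParameterSet,
    matrices: dict[tuple[str, str], particle_tracking.ConnectivityMatrix],
) -> list[particle_tracking.ConnectivityMatrix]:
    """Resolve a parameter set's (year, week) choice into a matrix set.

    An individual week under an individual year names a single matrix; a week
    set and/or the pooled year option yields the list of matrices the model
    redraws from (uniformly, with replacement) each model year.
    """
    years = MATRIX_YEARS if params.matrix_year == POOLED_YEARS else (params.matrix_year,)
    weeks = WEEK_SETS.get(params.matrix_week, (params.matrix_week,))
    chosen = []
    for y, w in itertools.product(years, weeks):
        if (y, w) not in matrices:
            raise KeyError(f"no connectivity matrix for year={y}, week={w}")
        chosen.append(matrices[(y, w)])
    return chosen


# ---------------------------------------------------------------------------
# desk-scale end-to-end experiment
# ---------------------------------------------------------------------------

DEFAULT_SCENARIO_SPEEDS = (0.0, 0.03, 0.06, 0.10, 0.15, 0.22)


@dataclass
class ExperimentConfig:
    """Desk-scale configuration of the full pipeline.

    Candidate circulation scenarios span retentive (zero alongshore speed)
    to dispersive (strong alongshore jet); the pseudo-empirical panel is
    generated under the ``truth_scenario``-th candidate's matrix.
    """

    n_regions: int = 20
    local_n: int = 250
    n_loci: int = 100
    model_years: int = 60
    replicates: int = 5
    pld_days: float = 10.0
    particles_per_site: int = 50
    w_swim: float = 0.0
    scenario_speeds: Sequence[float] = DEFAULT_SCENARIO_SPEEDS
    gyre_strength: float = 0.03
    noise_amplitude: float = 0.03
    truth_scenario: int = -1  # index into scenario_speeds; default most dispersive
    n_per_site: int = 40
    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class ExperimentResult:
    """Outputs of one desk-scale experiment."""

    grid: pd.DataFrame  # replicate-averaged rows, one per scenario
    runs: pd.DataFrame  # per-replicate FitResult rows
    ranking: pd.DataFrame  # scenarios by mean gof, with connectivity
    truth_label: str
    empirical_fst: popgen.FstMatrix
    matrices: dict[str, particle_tracking.ConnectivityMatrix] = field(
        default_factory=dict
    )


def build_scenario_matrices(
    cfg: ExperimentConfig,
) -> tuple[dict[str, particle_tracking.ConnectivityMatrix], pd.Series]:
    """Track particles under each candidate scenario; return matrices
    and per-scenario mean connectivity."""
    partition = synthetic_domain.build_region_partition(cfg.n_regions)
    sites = synthetic_domain.make_release_sites(
        partition, particles_per_site=cfg.particles_per_site
    )
    matrices: dict[str, particle_tracking.ConnectivityMatrix] = {}
    connectivity = {}
    for k, speed in enumerate(cfg.scenario_speeds):
        label = f"S{k}_v{speed:g}"
        flow = synthetic_domain.make_flow_field(
            alongshore_speed=speed,
            gyre_strength=cfg.gyre_strength,
            noise_amplitude=cfg.noise_amplitude,
            seed=derive_seed(cfg.seed, f"flow_{label}"),
        )
        tracking = particle_tracking.TrackingConfig(
            duration_days=cfg.pld_days,
            w_swim=cfg.w_swim,
            seed=derive_seed(cfg.seed, f"track_{label}"),
        )
        particles = particle_tracking.advect(flow, sites, tracking)
        matrix = particle_tracking.build_connectivity(
            particles,
            partition,
            meta={
                "id": label,
                "alongshore_speed": speed,
                "pld_days": cfg.pld_days,
                "w_swim": cfg.w_swim,
                "seed": tracking.seed,
            },
        )
        matrices[label] = matrix
        summary = particle_tracking.summarize_connectivity(matrix)
        connectivity[label] = summary.mean_connectivity
    return matrices, pd.Series(connectivity, name="mean_connectivity")


def run_experiment(
    cfg: ExperimentConfig,
    resume: bool = True,
) -> ExperimentResult:
    """Execute the desk-scale pipeline end to end.

    Deterministic given ``cfg.seed``.  When ``cfg.out_dir`` is set, each
    (scenario, replicate) fit row is persisted as a small CSV and completed
    cells are skipped on rerun (resumability); matrices and the panel VCF are
    written alongside.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    cells_dir = None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        cells_dir = out_dir / "cells"
        cells_dir.mkdir(exist_ok=True)

    matrices, connectivity = build_scenario_matrices(cfg)
    labels = list(matrices)
    truth_label = labels[cfg.truth_scenario]
    if out_dir:
        for label, m in matrices.items():
            particle_tracking.write_matrix(m, out_dir / f"matrix_{label}.csv")

    panel = synthetic_domain.generate_pseudo_empirical(
        matrices[truth_label],
        n_per_site=cfg.n_per_site,
        n_loci=cfg.n_loci,
        seed=derive_seed(cfg.seed, "pseudo_empirical"),
        local_n=cfg.local_n,
        model_years=cfg.model_years,
        vcf_path=(out_dir / "pseudo_empirical.vcf") if out_dir else None,
    )
    empirical_fst = popgen.pairwise_fst(panel.to_genotype_table())

    rows = []
    for label in labels:
        for rep in range(cfg.replicates):
            cell_path = (
                cells_dir / f"{label}_rep{rep}.csv" if cells_dir else None
            )
            if resume and cell_path is not None and cell_path.exists():
                rows.append(pd.read_csv(cell_path).iloc[0].to_dict())
                continue
            seed = derive_seed(cfg.seed, f"abm_{label}", rep)
            demography = eco_genetic.DemographyConfig(
                n_loci=cfg.n_loci, model_years=cfg.model_years, seed=seed
            )
            result = eco_genetic.run_simulation(
                matrices[label], demography, local_n=cfg.local_n
            )
            fit = fit_evaluation.compare_fst(result.fst, empirical_fst)
            row = {
                "scenario": label,
                "alongshore_speed": matrices[label].meta["alongshore_speed"],
                "replicate": rep,
                "seed": seed,
                **{f: getattr(fit, f) for f in fit_evaluation.FIT_FIELDS},
                "n_pairs": fit.n_pairs,
            }
            rows.append(row)
            if cell_path is not None:
                pd.DataFrame([row]).to_csv(cell_path, index=False)
            logger.info("scenario %s replicate %d: gof=%.3f", label, rep, row["gof"])

    runs = pd.DataFrame(rows)
    grid = fit_evaluation.aggregate_replicates(
        runs, ["scenario", "alongshore_speed"]
    )
    ranking = fit_evaluation.rank_candidates(
        runs, "scenario", connectivity=connectivity
    )
    if out_dir:
        runs.to_csv(out_dir / "runs.csv", index=False)
        grid.to_csv(out_dir / "grid.csv", index=False)
        ranking.to_csv(out_dir / "ranking.csv")
        empirical_fst.write(out_dir / "empirical_fst.csv")
        with open(out_dir / "experiment.json", "w") as fh:
            json.dump(
                {
                    "truth_scenario": truth_label,
                    "rho_connectivity": ranking.attrs.get("rho_connectivity"),
                },
                fh,
                indent=1,
            )
    return ExperimentResult(
        grid=grid,
        runs=runs,
        ranking=ranking,
        truth_label=truth_label,
        empirical_fst=empirical_fst,
        matrices=matrices,
    )
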