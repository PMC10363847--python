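"""Lagrangian particle tracking and dispersal connectivity matrices.

Particles released in the nearshore band are advected through a
:class:`~ecoconnect.synthetic_domain.FlowField` with an Euler-Maruyama
horizontal step (advection plus ``sqrt(2 K_h dt)`` Gaussian noise per axis)
and a Visser (1997) diffusivity-gradient-corrected vertical random walk with
an optional deterministic upward swimming velocity.  All boundaries are
reflective (closed basin).

End positions are binned by region to form the connectivity matrix
``P[i, f] = N_if / N_i``: the probability that a particle released in region
``i`` finishes in region ``f``.  Row sums equal 1 exactly when every particle
of the row remains inside the partitioned domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ecoconnect.synthetic_domain import FlowField, RegionPartition, ReleaseSite

#: safety factor applied to the Visser time-step criterion dt << 1/|K_v''|
_VISSER_SAFETY = 0.5


@dataclass(frozen=True)
class TrackingConfig:
    """Numerical settings for one particle-tracking run.

    ``duration_days`` is the pelagic larval duration (PLD): larvae drift for
    this long before the end-of-run positions are scored.  ``w_swim`` is a
    deterministic upward swimming velocity (m/s; positive moves particles
    toward the surface).
    """

    dt: float = 360.0  # s
    duration_days: float = 30.0
    k_h: float = 5.6  # horizontal diffusivity, m^2/s
    w_swim: float = 0.0  # upward swimming velocity, m/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration_days <= 0:
            raise ValueError("dt and duration_days must be positive")
        if self.k_h < 0 or self.w_swim < 0:
            raise ValueError("k_h and w_swim must be non-negative")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_days * 86400.0 / self.dt))


@dataclass
class ParticleEnsemble:
    """Final states of a tracked particle cohort (struct-of-arrays)."""

    origin_region: np.ndarray  # int, fixed at release
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    in_domain: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.origin_region)


def _check_visser_stability(flow: FlowField, dt: float) -> None:
    """Reject time steps too coarse for the vertical diffusivity profile.

    The Visser random walk is unbiased only when ``dt`` is small against the
    curvature timescale of K_v; we require dt <= 0.5 / max|d2K_v/dz2|,
    estimating the second derivative numerically over the water column.
    """
    z = np.linspace(0.0, flow.geometry.max_depth, 2001)
    dz = z[1] - z[0]
    kpp = np.gradient(flow.k_v_gradient(z), dz)
    limit = _VISSER_SAFETY / max(np.abs(kpp).max(), 1e-300)
    if dt > limit:
        raise ValueError(
            f"dt={dt:.0f}s violates the Visser stability criterion for this "
            f"K_v profile (max |K_v''| = {np.abs(kpp).max():.3e} 1/s "
            f"=> dt must be <= {limit:.0f}s)"
        )


def _reflect(values: np.ndarray, lower, upper) -> np.ndarray:
    """Reflect positions into [lower, upper] (single fold per boundary)."""
    values = np.where(values < lower, 2.0 * lower - values, values)
    values = np.where(values > upper, 2.0 * upper - values, values)
    return np.clip(values, lower, upper)


def advect(
    flow: FlowField,
    sites: Sequence[ReleaseSite],
    cfg: TrackingConfig,
) -> ParticleEnsemble:
    """Track all particles of all release sites through the flow field.

    Particles start at their site's horizontal position, uniformly
    distributed through the local water column.  Each step applies Euler
    advection with horizontal diffusion, then the Visser vertical random walk
    evaluated at ``z + 0.5 K_v'(z) dt``, then the upward swimming velocity,
    with reflection at the surface, the local bottom and the shoreline.
    """
    if not sites:
        raise ValueError("at least one release site is required")
    g = flow.geometry
    if not all(bool(g.contains(s.x, s.y)) for s in sites):
        raise ValueError("all release sites must lie inside the domain")
    _check_visser_stability(flow, cfg.dt)

    rng = np.random.default_rng(cfg.seed)
    x = np.concatenate([np.full(s.n_particles, s.x) for s in sites])
    y = np.concatenate([np.full(s.n_particles, s.y) for s in sites])
    origin = np.concatenate(
        [np.full(s.n_particles, s.region, dtype=int) for s in sites]
    )
    depth0 = np.concatenate([np.full(s.n_particles, s.depth) for s in sites])
    z = rng.uniform(0.0, depth0)

    n = len(x)
    sigma_h = np.sqrt(2.0 * cfg.k_h * cfg.dt)
    for step in range(cfg.n_steps):
        t = step * cfg.dt
        u, v = flow.velocity(x, y, z, t)
        x = x + u * cfg.dt + sigma_h * rng.standard_normal(n)
        y = y + v * cfg.dt + sigma_h * rng.standard_normal(n)
        x = _reflect(x, 0.0, g.lx)
        y = _reflect(y, 0.0, g.ly)
        # Visser vertical random walk: drift by K_v'(z) dt, diffuse with K_v
        # evaluated at the offset depth, then deterministic upward swimming.
        kp = flow.k_v_gradient(z)
        k_mid = flow.k_v(z + 0.5 * kp * cfg.dt)
        z = (
            z
            + kp * cfg.dt
            + rng.standard_normal(n) * np.sqrt(2.0 * k_mid * cfg.dt)
            - cfg.w_swim * cfg.dt
        )
        z = _reflect(z, 0.0, np.maximum(g.depth(x, y), 0.1))
        if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()):
            raise FloatingPointError(f"non-finite particle position at step {step}")

    return ParticleEnsemble(
        origin_region=origin,
        x=x,
        y=y,
        z=z,
        in_domain=np.asarray(g.contains(x, y), dtype=bool),
    )


@dataclass
class ConnectivityMatrix:
    """Origin -> destination dispersal probabilities with provenance metadata.

    ``P[i, f]`` is the fraction of particles released in region ``i + 1``
    finishing in region ``f + 1`` (0-based array over 1-based region labels).
    Rows of regions that released no particles are flagged invalid in
    ``row_valid`` rather than silently zero-filled.
    """

    P: np.ndarray
    meta: dict = field(default_factory=dict)
    row_valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {self.P.shape}")
        if (self.P < 0).any() or (self.P > 1.0 + 1e-9).any():
            raise ValueError("connectivity entries must lie in [0, 1]")
        sums = self.P.sum(axis=1)
        if (sums > 1.0 + 1e-9).any():
            raise ValueError(
                f"row sums must not exceed 1 (max {sums.max():.6f})"
            )
        if self.row_valid is None:
            self.row_valid = np.ones(self.P.shape[0], dtype=bool)
        else:
            self.row_valid = np.asarray(self.row_valid, dtype=bool)

    @property
    def n_regions(self) -> int:
        return self.P.shape[0]

    def retention(self) -> np.ndarray:
        """Diagonal: probability of finishing in the natal region."""
        return np.diag(self.P)


def build_connectivity(
    particles: ParticleEnsemble,
    partition: RegionPartition,
    meta: Optional[dict] = None,
) -> ConnectivityMatrix:
    """Bin particle end positions into ``P[i, f] = N_if / N_i``.

    ``N_i`` counts all particles released in region ``i`` (including those
    finishing outside the partitioned domain, which are assigned to no
    destination, so such rows sum to less than 1).  Regions that released no
    particles are flagged invalid.
    """
    n = partition.n_regions
    final_region = np.where(
        particles.in_domain, partition.assign(particles.x, particles.y), 0
    )
    counts = np.zeros((n, n))
    released = np.zeros(n)
    for i in range(1, n + 1):
        rows = particles.origin_region == i
        released[i - 1] = rows.sum()
        if released[i - 1] == 0:
            continue
        dest = final_region[rows]
        dest = dest[dest > 0]
        np.add.at(counts[i - 1], dest - 1, 1.0)
    valid = released > 0
    P = np.zeros((n, n))
    P[valid] = counts[valid] / released[valid, None]
    full_meta = dict(meta or {})
    full_meta.setdefault("n_particles_per_region", released.astype(int).tolist())
    return ConnectivityMatrix(P, full_meta, row_valid=valid)


@dataclass(frozen=True)
class ConnectivitySummary:
    """Row-averaged dispersal metrics of one connectivity matrix.

    ``mean_connectivity`` is the mean, over origin regions, of the number of
    destination regions that received at least one particle from that origin;
    ``mean_retention`` is the mean diagonal entry.  ``mean_current_strength``
    is the domain-time-averaged horizontal speed of the driving flow (m/s),
    present only when the flow is supplied.
    """

    mean_connectivity: float
    mean_retention: float
    mean_current_strength: Optional[float] = None


def summarize_connectivity(
    matrix: ConnectivityMatrix, flow: Optional[FlowField] = None
) -> ConnectivitySummary:
    """Compute :class:`ConnectivitySummary` over the matrix's valid rows."""
    valid = matrix.row_valid
    if not valid.any():
        raise ValueError("connectivity matrix has no valid rows")
    P = matrix.P[valid]
    return ConnectivitySummary(
        mean_connectivity=float((P > 0).sum(axis=1).mean()),
        mean_retention=float(np.diag(matrix.P)[valid].mean()),
        mean_current_strength=(
            flow.mean_current_strength() if flow is not None else None
        ),
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Write a matrix as labeled CSV plus a JSON metadata sidecar."""
    path = Path(path)
    n = matrix.n_regions
    labels = [str(i + 1) for i in range(n)]
    pd.DataFrame(matrix.P, index=labels, columns=labels).to_csv(
        path, index_label="origin", float_format="%.17g"
    )
    sidecar = dict(matrix.meta)
    sidecar["row_valid"] = matrix.row_valid.astype(int).tolist()
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    """Read a CSV connectivity matrix (and its sidecar metadata, if present).

    Rejects non-square tables, negative entries and rows summing above 1.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    P = df.to_numpy(dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"matrix in {path} is not square: shape {P.shape}")
    meta: dict = {}
    row_valid = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        rv = meta.pop("row_valid", None)
        if rv is not None:
            row_valid = np.asarray(rv, dtype=bool)
    return ConnectivityMatrix(P, meta, row_valid=row_valid)


def uniform_matrix(n: int, meta: Optional[dict] = None) -> ConnectivityMatrix:
    """Panmictic reference: every destination equally likely (entries 1/n)."""
    return ConnectivityMatrix(np.full((n, n), 1.0 / n), dict(meta or {"id": "uniform"}))


def identity_matrix(n: int, meta: Optional[dict] = None) -> ConnectivityMatrix:
    """Fully retentive reference: every particle stays home."""
    return ConnectivityMatrix(np.eye(n), dict(meta or {"id": "identity"}))


def island_matrix(n: int, m: float, meta: Optional[dict] = None) -> ConnectivityMatrix:
    """Symmetric island model: retention 1 - m, migrants m split evenly."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("migration rate m must lie in [0, 1]")
    P = np.full((n, n), m / (n - 1))
    np.fill_diagonal(P, 1.0 - m)
    return ConnectivityMatrix(P, dict(meta or {"id": f"island_m{m}"}))
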