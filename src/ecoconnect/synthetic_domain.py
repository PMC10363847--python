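"""Stylized lake domain: region partition, circulation, and genotype panels.

The domain is a closed rectangular basin (default 150 km x 500 km, echoing a
long, narrow temperate lake) with depth increasing linearly away from shore.
It stands in for hydrodynamic-model output so the dispersal -> gene flow
pipeline can run end to end on synthesized inputs:

* :func:`build_region_partition` splits the basin into ``n_regions``
  shoreline-anchored polygons (every interior point maps to the region owning
  the nearest stretch of shoreline);
* :func:`make_flow_field` builds a parametric 3-D circulation from three
  motifs observed in large stratified lakes -- a nearshore alongshore jet,
  stationary gyres derived from a stream function (hence divergence-free),
  and temporally correlated (Ornstein-Uhlenbeck) velocity noise -- over a
  two-layer vertical diffusivity profile;
* :func:`make_release_sites` places larval release points along the
  shallow (< 10 m by default) nearshore band;
* :func:`generate_pseudo_empirical` runs the eco-genetic model under a
  designated "truth" connectivity matrix and samples genotypes per site,
  emulating a field RAD-Seq panel of known provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

DEFAULT_LX = 150_000.0  # basin width (m), east-west
DEFAULT_LY = 500_000.0  # basin length (m), north-south
DEFAULT_MAX_DEPTH = 100.0  # m, at the basin centerline
DEFAULT_EPILIMNION_DEPTH = 10.0  # m
K_V_EPILIMNION = 1.0e-3  # m^2/s, well-mixed surface layer
K_V_DEEP = 1.0e-5  # m^2/s, quiescent below the thermocline
K_V_TRANSITION_WIDTH = 3.0  # m, smoothness of the two-layer transition


@dataclass(frozen=True)
class BasinGeometry:
    """Closed rectangular basin with depth increasing linearly from shore."""

    lx: float = DEFAULT_LX
    ly: float = DEFAULT_LY
    max_depth: float = DEFAULT_MAX_DEPTH

    @property
    def perimeter(self) -> float:
        return 2.0 * (self.lx + self.ly)

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.lx) & (y >= 0) & (y <= self.ly)

    def shore_distance(self, x, y):
        """Distance (m) to the nearest shoreline; 0 outside the basin."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = np.minimum.reduce([x, self.lx - x, y, self.ly - y])
        return np.where(self.contains(x, y), d, 0.0)

    def depth(self, x, y):
        """Bathymetric depth (m); linear ramp from shore to ``max_depth``."""
        d = self.shore_distance(x, y)
        ramp = self.max_depth / (min(self.lx, self.ly) / 2.0)
        return np.minimum(d * ramp, self.max_depth)

    def perimeter_arclength(self, x, y):
        """Arclength (m) of the shoreline point nearest each (x, y).

        The perimeter is traversed counterclockwise from the southwest corner:
        south edge, east edge, north edge, west edge.  Interior points project
        onto their nearest edge; ties break toward the earlier edge.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dists = np.stack([y, self.lx - x, self.ly - y, x])  # S, E, N, W
        edge = np.argmin(dists, axis=0)
        s = np.choose(
            edge,
            [
                x,
                self.lx + y,
                self.lx + self.ly + (self.lx - x),
                2.0 * self.lx + self.ly + (self.ly - y),
            ],
        )
        return np.mod(s, self.perimeter)


@dataclass
class RegionPartition:
    """Partition of the basin into shoreline-anchored regions.

    Region ``k`` (1-based) owns the interior points whose nearest shoreline
    point falls on the k-th of ``n_regions`` equal perimeter arcs.  Region
    indices 1..n_regions are contiguous; points outside the basin map to 0.
    """

    n_regions: int
    geometry: BasinGeometry = field(default_factory=BasinGeometry)
    bay_regions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be at least 2")

    def assign(self, x, y) -> np.ndarray:
        """Region index (1..n_regions) per point; 0 for points outside."""
        s = self.geometry.perimeter_arclength(x, y)
        arc = self.geometry.perimeter / self.n_regions
        idx = np.minimum(np.floor(s / arc).astype(int), self.n_regions - 1) + 1
        return np.where(self.geometry.contains(x, y), idx, 0)

    @property
    def topology(self) -> dict[int, list[int]]:
        """Ring adjacency of the shoreline arcs."""
        n = self.n_regions
        return {k: [(k - 2) % n + 1, k % n + 1] for k in range(1, n + 1)}

    def region_arc_centers(self) -> np.ndarray:
        """(n_regions, 2) shoreline coordinates of each region's arc midpoint."""
        arc = self.geometry.perimeter / self.n_regions
        s_mid = (np.arange(self.n_regions) + 0.5) * arc
        return np.stack([self._point_at_arclength(s) for s in s_mid])

    def _point_at_arclength(self, s: float) -> np.ndarray:
        g = self.geometry
        s = s % g.perimeter
        if s < g.lx:
            return np.array([s, 0.0])
        s -= g.lx
        if s < g.ly:
            return np.array([g.lx, s])
        s -= g.ly
        if s < g.lx:
            return np.array([g.lx - s, g.ly])
        s -= g.lx
        return np.array([0.0, g.ly - s])

    def export_grid(self, path: str | Path, resolution: int = 50) -> None:
        """Write a delimited (x, y, depth, region) table on a regular grid."""
        g = self.geometry
        xs = np.linspace(0, g.lx, resolution)
        ys = np.linspace(0, g.ly, resolution)
        xx, yy = np.meshgrid(xs, ys)
        rows = np.column_stack(
            [
                xx.ravel(),
                yy.ravel(),
                g.depth(xx.ravel(), yy.ravel()),
                self.assign(xx.ravel(), yy.ravel()),
            ]
        )
        np.savetxt(
            path,
            rows,
            delimiter=",",
            header="x_m,y_m,depth_m,region",
            comments="",
            fmt=["%.1f", "%.1f", "%.3f", "%d"],
        )


def build_region_partition(
    n_regions: int = 40,
    geometry: Optional[BasinGeometry] = None,
    n_bay_regions: int = 0,
) -> RegionPartition:
    """Partition the basin into ``n_regions`` roughly equal shoreline regions.

    With ``n_bay_regions > 0``, the final ``n_bay_regions`` indices are
    designated an "appendage basin" subset (used by genotype-panel scenarios
    to emulate a semi-isolated embayment); geometrically they remain ordinary
    shoreline arcs.
    """
    if n_regions < 2:
        raise ValueError(f"n_regions must be >= 2, got {n_regions}")
    if not 0 <= n_bay_regions < n_regions:
        raise ValueError("n_bay_regions must lie in [0, n_regions)")
    bay = tuple(range(n_regions - n_bay_regions + 1, n_regions + 1))
    return RegionPartition(n_regions, geometry or BasinGeometry(), bay)


def vertical_diffusivity(z, epilimnion_depth: float = DEFAULT_EPILIMNION_DEPTH):
    """Two-layer K_v(z) (m^2/s): high in the epilimnion, low beneath.

    ``z`` is depth in metres (0 at the surface, increasing downward); the
    layers blend through a tanh transition at ``epilimnion_depth``.
    """
    z = np.asarray(z, dtype=float)
    frac = 0.5 * (1.0 - np.tanh((z - epilimnion_depth) / K_V_TRANSITION_WIDTH))
    return K_V_DEEP + (K_V_EPILIMNION - K_V_DEEP) * frac


def vertical_diffusivity_gradient(z, epilimnion_depth: float = DEFAULT_EPILIMNION_DEPTH):
    """Analytic dK_v/dz (m/s) matching :func:`vertical_diffusivity`."""
    z = np.asarray(z, dtype=float)
    sech2 = 1.0 / np.cosh((z - epilimnion_depth) / K_V_TRANSITION_WIDTH) ** 2
    return -(K_V_EPILIMNION - K_V_DEEP) * sech2 / (2.0 * K_V_TRANSITION_WIDTH)


@dataclass
class FlowField:
    """Parametric 3-D circulation over the basin.

    Horizontal velocity superposes (i) an alongshore jet of peak speed
    ``alongshore_speed`` flowing counterclockwise in a nearshore band,
    (ii) one cyclonic and one anticyclonic Gaussian gyre of peak speed
    ``gyre_strength`` (stream-function derived, so divergence-free), and
    (iii) a spatially uniform Ornstein-Uhlenbeck velocity noise of stationary
    standard deviation ``noise_amplitude`` and decorrelation time
    ``noise_tau`` (default 2 days).  Velocities are attenuated with depth and
    vanish outside the basin.  Identical scenario + seed yields bitwise
    identical velocities at any (x, y, z, t).
    """

    alongshore_speed: float = 0.05  # m/s, peak jet speed
    gyre_strength: float = 0.05  # m/s, peak gyre speed scale
    noise_amplitude: float = 0.0  # m/s, stationary SD of OU noise
    epilimnion_depth: float = DEFAULT_EPILIMNION_DEPTH
    seed: int = 0
    geometry: BasinGeometry = field(default_factory=BasinGeometry)
    jet_band_width: float = 20_000.0  # m, e-folding width of the jet
    k_v_scale: float = 1.0  # multiplier on the K_v profile (0 disables mixing)
    noise_tau: float = 2.0 * 86400.0  # s, OU decorrelation time
    noise_horizon: float = 90.0 * 86400.0  # s, precomputed noise extent
    _noise_dt: float = field(default=3600.0, repr=False)
    _noise_path: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if min(self.alongshore_speed, self.gyre_strength, self.noise_amplitude) < 0:
            raise ValueError("flow scenario speeds must be non-negative")
        n = int(self.noise_horizon / self._noise_dt) + 2
        rng = np.random.default_rng(self.seed)
        path = np.empty((n, 2))
        rho = np.exp(-self._noise_dt / self.noise_tau)
        path[0] = rng.standard_normal(2)
        innovations = rng.standard_normal((n - 1, 2)) * np.sqrt(1.0 - rho**2)
        for k in range(1, n):
            path[k] = rho * path[k - 1] + innovations[k - 1]
        self._noise_path = self.noise_amplitude * path

    # -- gyre layout: cyclonic in the southern half, anticyclonic in the north
    def _gyres(self):
        g = self.geometry
        sigma = min(g.lx, g.ly) / 4.0
        return [
            (g.lx / 2.0, g.ly / 4.0, +1.0, sigma),
            (g.lx / 2.0, 3.0 * g.ly / 4.0, -1.0, sigma),
        ]

    def _noise_at(self, t):
        t = np.clip(np.asarray(t, dtype=float), 0.0, self.noise_horizon)
        k = np.minimum((t / self._noise_dt).astype(int), len(self._noise_path) - 2)
        frac = t / self._noise_dt - k
        return (
            self._noise_path[k] * (1.0 - frac)[..., None]
            + self._noise_path[k + 1] * frac[..., None]
        )

    def velocity(self, x, y, z, t):
        """Horizontal velocity (u, v) in m/s at depth z (m) and time t (s)."""
        g = self.geometry
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        u = np.zeros(np.broadcast(x, y).shape)
        v = np.zeros_like(u)

        if self.alongshore_speed > 0:
            d = g.shore_distance(x, y)
            mag = self.alongshore_speed * np.exp(-d / self.jet_band_width)
            # counterclockwise tangent of the nearest edge (S, E, N, W)
            edge = np.argmin(np.stack([y, g.lx - x, g.ly - y, x]), axis=0)
            tx = np.choose(edge, [1.0, 0.0, -1.0, 0.0])
            ty = np.choose(edge, [0.0, 1.0, 0.0, -1.0])
            u = u + mag * tx
            v = v + mag * ty

        if self.gyre_strength > 0:
            for cx, cy, sign, sigma in self._gyres():
                dx = x - cx
                dy = y - cy
                env = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
                u = u + self.gyre_strength * sign * (dy / sigma) * env
                v = v - self.gyre_strength * sign * (dx / sigma) * env

        if self.noise_amplitude > 0:
            noise = self._noise_at(t)
            u = u + noise[..., 0]
            v = v + noise[..., 1]

        # mild attenuation below the epilimnion; zero outside the basin
        atten = np.exp(-np.maximum(z, 0.0) / (3.0 * self.epilimnion_depth))
        inside = g.contains(x, y)
        return u * atten * inside, v * atten * inside

    def k_v(self, z):
        return self.k_v_scale * vertical_diffusivity(z, self.epilimnion_depth)

    def k_v_gradient(self, z):
        return self.k_v_scale * vertical_diffusivity_gradient(z, self.epilimnion_depth)

    def mean_current_strength(self, t_samples=None, resolution: int = 20) -> float:
        """Domain- and time-averaged horizontal speed (m/s) at mid-epilimnion."""
        g = self.geometry
        if t_samples is None:
            t_samples = np.linspace(0.0, 30.0 * 86400.0, 16)
        xs = np.linspace(0, g.lx, resolution + 2)[1:-1]
        ys = np.linspace(0, g.ly, resolution + 2)[1:-1]
        xx, yy = np.meshgrid(xs, ys)
        z = np.full_like(xx, self.epilimnion_depth / 2.0)
        speeds = []
        for t in np.atleast_1d(t_samples):
            u, v = self.velocity(xx, yy, z, np.full_like(xx, float(t)))
            speeds.append(np.hypot(u, v).mean())
        return float(np.mean(speeds))


def make_flow_field(
    alongshore_speed: float = 0.05,
    gyre_strength: float = 0.05,
    noise_amplitude: float = 0.0,
    epilimnion_depth: float = DEFAULT_EPILIMNION_DEPTH,
    seed: int = 0,
    geometry: Optional[BasinGeometry] = None,
) -> FlowField:
    """Build a :class:`FlowField` for one circulation scenario.

    High ``alongshore_speed`` gives dispersive transport along the shoreline;
    near-zero speeds give retentive conditions dominated by local diffusion.
    """
    return FlowField(
        alongshore_speed=alongshore_speed,
        gyre_strength=gyre_strength,
        noise_amplitude=noise_amplitude,
        epilimnion_depth=epilimnion_depth,
        seed=seed,
        geometry=geometry or BasinGeometry(),
    )


@dataclass(frozen=True)
class ReleaseSite:
    """A larval release point in the shallow nearshore band."""

    x: float
    y: float
    depth: float  # local water-column depth (m)
    region: int
    n_particles: int = 100


def make_release_sites(
    partition: RegionPartition,
    depth_threshold: float = 10.0,
    particles_per_site: int = 100,
    spacing: Optional[float] = None,
) -> list[ReleaseSite]:
    """Place release sites along shoreline where depth < ``depth_threshold``.

    Candidate nodes sit on a ring following the shoreline at half the
    threshold's isobath distance, spaced ``spacing`` metres apart (default:
    one third of a region arc, guaranteeing every region at least two sites).
    """
    if depth_threshold <= 0:
        raise ValueError("depth_threshold must be positive")
    g = partition.geometry
    ramp = g.max_depth / (min(g.lx, g.ly) / 2.0)
    offset = 0.5 * depth_threshold / ramp  # shore distance with depth = thr/2
    if spacing is None:
        spacing = g.perimeter / (3 * partition.n_regions)
    n_nodes = max(int(g.perimeter // spacing), 1)
    sites = []
    for k in range(n_nodes):
        s = (k + 0.5) * g.perimeter / n_nodes
        px, py = partition._point_at_arclength(s)
        # step inward from the shoreline, perpendicular to the nearest edge
        x, y = px, py
        if px < 1e-9:
            x = offset
        elif abs(px - g.lx) < 1e-9:
            x = g.lx - offset
        if py < 1e-9:
            y = offset
        elif abs(py - g.ly) < 1e-9:
            y = g.ly - offset
        depth = float(g.depth(x, y))
        if depth >= depth_threshold:
            continue
        region = int(partition.assign(x, y))
        sites.append(ReleaseSite(float(x), float(y), depth, region, particles_per_site))
    if not sites:
        raise ValueError(
            "no release sites found: depth_threshold too small for this "
            "bathymetry/spacing"
        )
    return sites


@dataclass
class PseudoEmpiricalPanel:
    """A synthetic field-sampling panel of known dispersal provenance.

    Genotypes are sampled from an eco-genetic simulation driven by a
    designated "truth" connectivity matrix, so downstream fit evaluation can
    be validated against a known answer.
    """

    genotypes: np.ndarray  # (individuals, loci) dosage
    site_labels: np.ndarray
    locus_ids: list[str]
    truth_matrix_id: str
    n_per_site: int

    def to_genotype_table(self):
        from ecoconnect.popgen import GenotypeTable

        return GenotypeTable(self.genotypes, self.site_labels, self.locus_ids)


def generate_pseudo_empirical(
    truth_matrix,
    n_per_site: int = 40,
    n_loci: int = 100,
    seed: int = 0,
    local_n: int = 250,
    model_years: int = 60,
    vcf_path: str | Path | None = None,
    demography=None,
) -> PseudoEmpiricalPanel:
    """Run the eco-genetic model under ``truth_matrix`` and sample a panel.

    The model runs ``model_years`` years (enough for differentiation to
    reflect the dispersal regime at desk scale), then ``n_per_site``
    individuals are sampled per local population.  When a population holds
    fewer individuals, all of them are sampled and a warning is emitted.
    Optionally writes the panel as a GT-only VCF with site labels encoded in
    sample IDs (``SITE_<region>_<nnn>``).
    """
    import warnings

    from ecoconnect import eco_genetic, popgen

    n_pops = truth_matrix.P.shape[0]
    cfg = demography or eco_genetic.DemographyConfig(
        n_loci=n_loci, model_years=model_years, seed=seed
    )
    result = eco_genetic.run_simulation(truth_matrix, cfg, local_n=local_n)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA11]))
    dosages = []
    labels = []
    for k, pop in enumerate(result.metapopulation.populations):
        size = pop.size
        take = min(n_per_site, size)
        if take < n_per_site:
            warnings.warn(
                f"population {k + 1} holds {size} < n_per_site={n_per_site}; "
                "sampling all",
                stacklevel=2,
            )
        idx = rng.choice(size, size=take, replace=False)
        dosages.append(pop.genotypes[idx].sum(axis=2))
        labels.extend([f"SITE_{k + 1}"] * take)
    panel = PseudoEmpiricalPanel(
        genotypes=np.concatenate(dosages).astype(np.int8),
        site_labels=np.asarray(labels, dtype=object),
        locus_ids=[f"L{j + 1:04d}" for j in range(cfg.n_loci)],
        truth_matrix_id=str(truth_matrix.meta.get("id", "truth")),
        n_per_site=n_per_site,
    )
    if vcf_path is not None:
        popgen.write_vcf(panel.to_genotype_table(), vcf_path)
    return panel
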