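"""Condensed-history CSDA Monte Carlo transport with per-region tallies.

Charged particles (protons, α) travel in straight lines and lose energy
continuously at the stopping-power rate (no multiple Coulomb scattering or
nuclear elastic interactions — paths here are shorter than 30 µm).  Steps are
limited to a 1% fractional energy loss and to the exact distance to the next
region boundary, so every deposit is attributed to a single region.  Particles
are killed at a 1 keV cutoff with the residual deposited locally.

Histories are processed in vectorized arrays, grouped into independent
batches; batch b of a run with seed s draws from ``default_rng([s, b])`` so
results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physics
from .errors import InvalidArgumentError
from .geometry import CellModel, DegraderStack, transported_energy

_CUTOFF_MEV = 1e-3
_NUDGE_UM = 1e-7     # push across a boundary after a geometric step
_UM_TO_CM = 1e-4


@dataclass
class ParticleState:
    """One Monte Carlo history's state."""

    species: physics.Species
    position: np.ndarray          # µm
    direction: np.ndarray         # unit vector
    kinetic_energy: float         # MeV
    alive: bool = True
    statistical_weight: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-12:
            raise InvalidArgumentError("direction must be unit-norm (1e-12)")
        if self.kinetic_energy < 0:
            raise InvalidArgumentError("kinetic_energy must be >= 0")
        if self.statistical_weight < 0:
            raise InvalidArgumentError("statistical_weight must be >= 0")


@dataclass(frozen=True)
class BeamSpec:
    """Mono-directional proton beam along +z.

    ``field_type``:
      * ``"point"`` — pencil beam on the cell axis;
      * ``"square"`` — positions uniform over a ``field_side_um`` square
        (the experimental raster spot is 70 × 70 µm²);
      * ``"broad"`` — uniform square just covering the cell (side = cell
        diameter), the shoot-through uniform-irradiation idealization.
    """

    energy_mev: float = 2.0
    field_type: str = "square"
    field_side_um: float = 70.0
    flux_per_s: float = 2e7
    duration_s: float = 10.0
    energy_sigma_kev: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_mev <= 0:
            raise InvalidArgumentError("beam energy must be positive")
        if self.flux_per_s * self.duration_s <= 0:
            raise InvalidArgumentError("total fluence must be positive")
        if self.field_type not in ("point", "square", "broad"):
            raise InvalidArgumentError(f"unknown field type {self.field_type!r}")

    @property
    def total_protons(self) -> float:
        return self.flux_per_s * self.duration_s

    def field_area_um2(self, cell: CellModel | None = None) -> float:
        if self.field_type == "point":
            return 0.0
        if self.field_type == "square":
            return self.field_side_um ** 2
        if cell is None:
            raise InvalidArgumentError("broad field needs a cell model")
        return (2.0 * cell.cell_radius) ** 2


# --- geometry adapters ------------------------------------------------------

class CellGeometry:
    """Transport view of a :class:`CellModel`: concentric spherical regions."""

    def __init__(self, cell: CellModel):
        self.cell = cell
        self.boundaries = cell.boundaries
        self.labels = cell.region_labels
        self.masses_g = cell.region_masses_g
        self.densities = cell.region_densities
        materials = [physics.WATER] * len(self.labels)
        if cell.boron_solid:
            materials[0] = physics.BORON
        self.materials = materials

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def region_index(self, pos: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(pos, axis=1)
        return np.searchsorted(self.boundaries, r - 1e-9, side="left")

    def distance_to_boundary(self, pos, dirs, ridx) -> np.ndarray:
        """Distance to the nearest region boundary along the flight direction."""
        b = np.einsum("ij,ij->i", pos, dirs)
        r2 = np.einsum("ij,ij->i", pos, pos)
        dist = np.full(len(pos), np.inf)
        outer_r = self.boundaries[np.minimum(ridx, self.n_regions - 1)]
        # outer sphere: particle is inside it, the +sqrt root is ahead
        disc = b * b - (r2 - outer_r ** 2)
        disc = np.maximum(disc, 0.0)
        dist = -b + np.sqrt(disc)
        # inner sphere (if any): the -sqrt root if positive
        has_inner = ridx > 0
        if np.any(has_inner):
            inner_r = self.boundaries[np.maximum(ridx - 1, 0)]
            disc_i = b * b - (r2 - inner_r ** 2)
            hit = has_inner & (disc_i > 0)
            t_in = -b[hit] - np.sqrt(disc_i[hit])
            d_hit = dist[hit]
            d_hit = np.where(t_in > 1e-9, np.minimum(d_hit, t_in), d_hit)
            dist[hit] = d_hit
        return np.maximum(dist, 0.0)

    def entry_distance(self, pos, dirs) -> np.ndarray:
        """Distance for an exterior particle to reach the cell; inf on a miss."""
        b = np.einsum("ij,ij->i", pos, dirs)
        r2 = np.einsum("ij,ij->i", pos, pos)
        disc = b * b - (r2 - self.boundaries[-1] ** 2)
        t = np.where(disc > 0, -b - np.sqrt(np.maximum(disc, 0.0)), np.inf)
        return np.where(t > 0, t, np.inf)


class SlabGeometry:
    """Single homogeneous slab normal to z, used for transport validation."""

    def __init__(self, thickness_um: float, area_um2: float,
                 material: physics.StoppingModel = physics.WATER):
        if thickness_um <= 0 or area_um2 <= 0:
            raise InvalidArgumentError("slab dimensions must be positive")
        self.thickness_um = thickness_um
        self.labels = ["slab"]
        self.materials = [material]
        self.densities = np.array([material.density])
        self.masses_g = np.array(
            [thickness_um * area_um2 * material.density * 1e-12])

    @property
    def n_regions(self) -> int:
        return 1

    def region_index(self, pos):
        z = pos[:, 2]
        inside = (z >= 0.0) & (z <= self.thickness_um)
        return np.where(inside, 0, 1)

    def distance_to_boundary(self, pos, dirs, ridx):
        dz = dirs[:, 2]
        z = pos[:, 2]
        with np.errstate(divide="ignore"):
            t_fwd = np.where(dz > 0, (self.thickness_um - z) / dz, np.inf)
            t_bwd = np.where(dz < 0, -z / dz, np.inf)
        return np.maximum(np.minimum(t_fwd, t_bwd), 0.0)

    def entry_distance(self, pos, dirs):
        z, dz = pos[:, 2], dirs[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where((z < 0) & (dz > 0), -z / dz,
                         np.where((z > self.thickness_um) & (dz < 0),
                                  (self.thickness_um - z) / dz, np.inf))
        return np.where(t > 0, t, np.inf)


# --- tallies ----------------------------------------------------------------

@dataclass
class TallySet:
    """Per-region energy deposits with batch statistics and dose conversion.

    ``energy_mev[b, r]`` is batch b's independent estimate of the physical
    energy (MeV, weight-scaled) deposited in region r.
    """

    region_labels: list[str]
    energy_mev: np.ndarray           # (batches, regions)
    masses_g: np.ndarray
    escaped_mev: np.ndarray = field(default=None)  # (batches,)

    @property
    def batches(self) -> int:
        return self.energy_mev.shape[0]

    def mean_energy(self) -> np.ndarray:
        return self.energy_mev.mean(axis=0)

    def mean_dose_gy(self) -> np.ndarray:
        if np.any(self.masses_g <= 0):
            bad = self.region_labels[int(np.argmin(self.masses_g))]
            raise ZeroDivisionError(f"region {bad!r} has zero mass")
        return np.array([dose_from_energy(e, m) for e, m in
                         zip(self.mean_energy(), self.masses_g)])

    def rel_err(self) -> np.ndarray:
        """Relative standard error of the mean over batches."""
        mean = self.mean_energy()
        sem = self.energy_mev.std(axis=0, ddof=1) / math.sqrt(self.batches)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(mean > 0, sem / np.maximum(mean, 1e-300), 0.0)
        return out

    def dose(self, label: str) -> float:
        return float(self.mean_dose_gy()[self.region_labels.index(label)])

    def dose_err(self, label: str) -> float:
        i = self.region_labels.index(label)
        return float(self.mean_dose_gy()[i] * self.rel_err()[i])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region": self.region_labels,
            "energy_MeV": self.mean_energy(),
            "mean_dose_Gy": self.mean_dose_gy(),
            "rel_err": self.rel_err(),
        })


def dose_from_energy(energy_mev: float, mass_g: float) -> float:
    """Absorbed dose in Gy from energy (MeV) deposited in a mass (g)."""
    if mass_g <= 0:
        raise InvalidArgumentError("mass must be positive")
    return energy_mev * physics.MEV_TO_J / (mass_g * 1e-3)


def sample_isotropic(rng: np.random.Generator, n: int | None = None):
    """Directions uniform on the unit sphere (Marsaglia cosθ/φ sampling)."""
    m = 1 if n is None else n
    cos_t = rng.uniform(-1.0, 1.0, m)
    phi = rng.uniform(0.0, 2.0 * math.pi, m)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    d = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return d[0] if n is None else d


# --- stepping ---------------------------------------------------------------

def _transport_batch(geometry, species: physics.Species, pos, dirs, energy,
                     weight, rng: np.random.Generator | None = None,
                     straggling: bool = False,
                     max_frac_loss: float = 0.01,
                     max_iter: int = 200000):
    """Transport one batch of histories to completion.

    Returns (deposit per region [weighted MeV], escaped weighted MeV).
    """
    n_regions = geometry.n_regions
    deposits = np.zeros(n_regions)
    escaped = 0.0
    pos = np.array(pos, dtype=float)
    dirs = np.array(dirs, dtype=float)
    energy = np.array(energy, dtype=float)
    weight = np.array(weight, dtype=float)
    tables = [physics.get_range_table(species.name, m)
              for m in geometry.materials]
    alive = energy > _CUTOFF_MEV
    escaped += float(np.sum(weight[~alive] * energy[~alive]))

    for _ in range(max_iter):
        if not np.any(alive):
            break
        idx = np.flatnonzero(alive)
        p, d, e, w = pos[idx], dirs[idx], energy[idx], weight[idx]
        ridx = geometry.region_index(p)

        outside = ridx >= n_regions
        if np.any(outside):
            t_in = geometry.entry_distance(p[outside], d[outside])
            miss = ~np.isfinite(t_in)
            out_ids = idx[outside]
            escaped += float(np.sum(w[outside][miss] * e[outside][miss]))
            alive[out_ids[miss]] = False
            enter = ~miss
            pos[out_ids[enter]] = (p[outside][enter]
                                   + (t_in[enter, None] + _NUDGE_UM)
                                   * d[outside][enter])
            continue

        # geometric limit and energy limit per history, grouped by material
        s_geo = geometry.distance_to_boundary(p, d, ridx)
        rho = geometry.densities[ridx]
        rng_now = np.empty(len(idx))
        rng_after_frac = np.empty(len(idx))
        for mat_id in np.unique(ridx):
            sel = ridx == mat_id
            tbl = tables[mat_id]
            rng_now[sel] = tbl.range_of(e[sel])
            rng_after_frac[sel] = tbl.range_of(e[sel] * (1.0 - max_frac_loss))
        s_energy = (rng_now - rng_after_frac) / rho / _UM_TO_CM
        geometric = s_geo <= s_energy
        s = np.where(geometric, s_geo + _NUDGE_UM, s_energy)

        # energy after the step via range inversion
        new_range = rng_now - rho * s * _UM_TO_CM
        e_new = np.empty(len(idx))
        for mat_id in np.unique(ridx):
            sel = ridx == mat_id
            e_new[sel] = tables[mat_id].energy_at(np.maximum(new_range[sel], 0.0))
        e_new = np.minimum(e_new, e)
        de = e - e_new
        if straggling and rng is not None:
            sig = np.array([physics.bohr_straggling_sigma(
                species, geometry.materials[m], x)
                for m, x in zip(ridx, rho * s * _UM_TO_CM)])
            de = np.clip(de + rng.normal(0.0, 1.0, len(idx)) * sig, 0.0, e)
            e_new = e - de

        np.add.at(deposits, ridx, w * de)
        pos[idx] = p + s[:, None] * d
        stopped = e_new <= _CUTOFF_MEV
        if np.any(stopped):
            np.add.at(deposits, ridx[stopped], w[stopped] * e_new[stopped])
            alive[idx[stopped]] = False
            e_new = np.where(stopped, 0.0, e_new)
        energy[idx] = e_new
    else:
        raise RuntimeError("transport failed to terminate (internal error)")
    return deposits, escaped


def step(state: ParticleState, max_frac_loss: float, geometry):
    """Advance one history by a single condensed-history step.

    Returns ``(state, (region_label, deposit_MeV))``; the deposit is the
    unweighted energy lost in the step's region (straggling off).
    """
    if not state.alive:
        raise InvalidArgumentError("state is not alive")
    if not 0.0 < max_frac_loss <= 0.05:
        raise InvalidArgumentError("max_fractional_loss must be in (0, 0.05]")
    geo = geometry if not isinstance(geometry, CellModel) else CellGeometry(geometry)
    p = state.position[None, :]
    d = state.direction[None, :]
    ridx = geo.region_index(p)
    if ridx[0] >= geo.n_regions:
        t = geo.entry_distance(p, d)[0]
        if not np.isfinite(t):
            state.alive = False
            return state, ("exterior", 0.0)
        state.position = state.position + (t + _NUDGE_UM) * state.direction
        return state, ("exterior", 0.0)
    tbl = physics.get_range_table(state.species.name, geo.materials[ridx[0]])
    rho = geo.densities[ridx[0]]
    s_geo = geo.distance_to_boundary(p, d, ridx)[0]
    r_now = float(tbl.range_of(state.kinetic_energy))
    r_frac = float(tbl.range_of(state.kinetic_energy * (1 - max_frac_loss)))
    s_energy = (r_now - r_frac) / rho / _UM_TO_CM
    s = s_geo + _NUDGE_UM if s_geo <= s_energy else s_energy
    e_new = float(tbl.energy_at(max(r_now - rho * s * _UM_TO_CM, 0.0)))
    e_new = min(e_new, state.kinetic_energy)
    deposit = state.kinetic_energy - e_new
    state.position = state.position + s * state.direction
    if e_new <= _CUTOFF_MEV:
        deposit += e_new
        e_new = 0.0
        state.alive = False
    state.kinetic_energy = e_new
    return state, (geo.labels[ridx[0]], deposit)


def _sample_beam_positions(beam: BeamSpec, geometry, n: int,
                           rng: np.random.Generator,
                           stratify_radius_um: float | None = None,
                           stratify_fraction: float = 0.5):
    """Start positions and weights for a parallel +z beam.

    With stratification, a fraction of histories is forced into the inner
    disk of radius ``stratify_radius_um`` with area-proportional weights —
    an unbiased variance-reduction for the tiny nanoshell target.
    """
    cell_r = getattr(getattr(geometry, "cell", None), "cell_radius", None)
    if beam.field_type == "point":
        xy = np.zeros((n, 2))
        weights = np.full(n, beam.total_protons / n)
    else:
        side = (beam.field_side_um if beam.field_type == "square"
                else 2.0 * cell_r)
        area = side * side
        if stratify_radius_um is None:
            xy = rng.uniform(-side / 2.0, side / 2.0, (n, 2))
            weights = np.full(n, beam.total_protons / n)
        else:
            r0 = stratify_radius_um
            a_in = math.pi * r0 * r0
            if a_in >= area:
                raise InvalidArgumentError("stratify radius exceeds the field")
            n_in = max(int(round(n * stratify_fraction)), 1)
            n_out = n - n_in
            # inner disk, uniform by area
            u = rng.uniform(0.0, 1.0, n_in)
            phi = rng.uniform(0.0, 2 * math.pi, n_in)
            r_in = r0 * np.sqrt(u)
            xy_in = np.column_stack([r_in * np.cos(phi), r_in * np.sin(phi)])
            # outer: rejection-sample the square minus the disk
            xy_out = np.empty((0, 2))
            while len(xy_out) < n_out:
                cand = rng.uniform(-side / 2, side / 2,
                                   (max(2 * (n_out - len(xy_out)), 16), 2))
                keep = np.einsum("ij,ij->i", cand, cand) > r0 * r0
                xy_out = np.vstack([xy_out, cand[keep]])
            xy_out = xy_out[:n_out]
            xy = np.vstack([xy_in, xy_out])
            weights = np.concatenate([
                np.full(n_in, beam.total_protons * (a_in / area) / n_in),
                np.full(n_out, beam.total_protons * (1 - a_in / area)
                        / max(n_out, 1)),
            ])
    z0 = -(cell_r + 5.0) if cell_r is not None else -5.0
    pos = np.column_stack([xy, np.full(n, z0)])
    dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
    return pos, dirs, weights


def run(beam: BeamSpec, geometry, n_histories: int, batches: int,
        seed: int, straggling: bool = False,
        degrader: DegraderStack | None = None,
        stratify_radius_um: float | None = None,
        stratify_fraction: float = 0.5) -> TallySet:
    """Transport a proton beam and tally per-region doses.

    ``degrader`` (optional) degrades the nominal beam energy by CSDA and adds
    Bohr straggling to the entrance spectrum; straggling inside the cell is
    controlled by ``straggling`` (default off).
    """
    if isinstance(geometry, CellModel):
        geometry = CellGeometry(geometry)
    if n_histories < batches or batches < 2:
        raise InvalidArgumentError("need n_histories >= batches >= 2")
    e_mean = beam.energy_mev
    strag_sigma = beam.energy_sigma_kev * 1e-3
    if degrader is not None:
        e_mean = transported_energy(beam.energy_mev, degrader)
        strag_sigma = math.hypot(strag_sigma, physics.bohr_straggling_sigma(
            physics.PROTON, physics.WATER, degrader.path_gcm2()))

    per_batch = n_histories // batches
    energy_tally = np.zeros((batches, geometry.n_regions))
    escaped_tally = np.zeros(batches)
    for b in range(batches):
        rng = np.random.default_rng([seed, b])
        pos, dirs, w = _sample_beam_positions(
            beam, geometry, per_batch, rng, stratify_radius_um,
            stratify_fraction)
        if strag_sigma > 0:
            e0 = np.maximum(rng.normal(e_mean, strag_sigma, per_batch), 2e-3)
        else:
            e0 = np.full(per_batch, e_mean)
        # each batch is scaled to the full physical fluence independently
        dep, esc = _transport_batch(geometry, physics.PROTON, pos, dirs, e0,
                                    w, rng, straggling)
        energy_tally[b] = dep
        escaped_tally[b] = esc
    return TallySet(list(geometry.labels), energy_tally,
                    np.asarray(geometry.masses_g, dtype=float), escaped_tally)


def run_alpha_source(cell: CellModel, n_histories: int, batches: int,
                     seed: int, alpha_energy_mev: float = 3.0,
                     total_weight: float = 1.0,
                     straggling: bool = False) -> TallySet:
    """Isotropic mono-energetic α source uniform in the boron sphere.

    ``total_weight`` is the physical number of α particles the tally is
    scaled to (per batch), e.g. the expected fusion α count.
    """
    geometry = CellGeometry(cell)
    if n_histories < batches or batches < 2:
        raise InvalidArgumentError("need n_histories >= batches >= 2")
    per_batch = n_histories // batches
    energy_tally = np.zeros((batches, geometry.n_regions))
    escaped_tally = np.zeros(batches)
    r_b = cell.boron_sphere_radius
    for b in range(batches):
        rng = np.random.default_rng([seed, b])
        u = rng.uniform(0.0, 1.0, per_batch)
        radius = r_b * np.cbrt(u)
        dirs0 = sample_isotropic(rng, per_batch)   # position direction
        pos = radius[:, None] * dirs0
        dirs = sample_isotropic(rng, per_batch)
        e0 = np.full(per_batch, alpha_energy_mev)
        w = np.full(per_batch, total_weight / per_batch)
        dep, esc = _transport_batch(geometry, physics.ALPHA, pos, dirs, e0,
                                    w, rng, straggling)
        energy_tally[b] = dep
        escaped_tally[b] = esc
    return TallySet(list(geometry.labels), energy_tally,
                    np.asarray(geometry.masses_g, dtype=float), escaped_tally)
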