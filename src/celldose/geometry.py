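"""MIRD cell geometry, degrader stack and ray utilities.

The cell is the standard concentric-sphere idealization used in cellular
dosimetry: a spherical nucleus (default radius 5 µm) inside a spherical cell
(default radius 12.5 µm), with a ¹¹B inclusion (default radius 1.5 µm) at the
nucleus center wrapped in a contiguous stack of nanometric water shells
(default 10 shells × 10 nm) for nanodosimetric scoring.

Coordinates are Cartesian µm, the beam travels along +z and the cell is
centered at the origin.  Points falling exactly on a spherical boundary
(within 1e-9 µm) belong to the inner region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import physics
from .errors import InvalidArgumentError, NoSolutionError

_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class CellModel:
    """Concentric-sphere cell with boron inclusion and nanoshell stack."""

    nucleus_radius: float = 5.0        # µm
    cell_radius: float = 12.5          # µm
    boron_sphere_radius: float = 1.5   # µm, centered at the nucleus center
    shell_count: int = 10
    shell_thickness_nm: float = 10.0
    boron_solid: bool = False          # solid boron (2.37 g/cm³) vs water-equivalent

    def __post_init__(self) -> None:
        if self.boron_sphere_radius <= 0:
            raise InvalidArgumentError("boron_sphere_radius must be positive")
        if self.shell_count < 0 or self.shell_thickness_nm < 0:
            raise InvalidArgumentError("shell stack parameters must be >= 0")
        if self.shell_stack_outer_radius > self.nucleus_radius:
            raise InvalidArgumentError(
                "boron sphere plus shells must fit inside the nucleus")
        if self.nucleus_radius >= self.cell_radius:
            raise InvalidArgumentError(
                "nucleus_radius must be smaller than cell_radius")

    @property
    def shell_stack_outer_radius(self) -> float:
        return (self.boron_sphere_radius
                + self.shell_count * self.shell_thickness_nm * 1e-3)

    @property
    def boundaries(self) -> np.ndarray:
        """Outer radii of every region, innermost first (µm)."""
        shells = (self.boron_sphere_radius
                  + np.arange(1, self.shell_count + 1)
                  * self.shell_thickness_nm * 1e-3)
        return np.concatenate([[self.boron_sphere_radius], shells,
                               [self.nucleus_radius, self.cell_radius]])

    @property
    def region_labels(self) -> list[str]:
        return (["boron_sphere"]
                + [f"shell_{k}" for k in range(1, self.shell_count + 1)]
                + ["nucleus", "cytoplasm"])

    @property
    def region_densities(self) -> np.ndarray:
        """g/cm³ per region; everything is water except an optionally solid inclusion."""
        rho = np.ones(len(self.region_labels))
        if self.boron_solid:
            rho[0] = physics.BORON.density
        return rho

    @property
    def region_volumes_um3(self) -> np.ndarray:
        b = self.boundaries
        v = 4.0 / 3.0 * math.pi * b ** 3
        return np.diff(np.concatenate([[0.0], v]))

    @property
    def region_masses_g(self) -> np.ndarray:
        # 1 µm³ of unit-density material is 1e-12 g
        return self.region_volumes_um3 * self.region_densities * 1e-12

    def region_table(self) -> pd.DataFrame:
        b = self.boundaries
        return pd.DataFrame({
            "label": self.region_labels,
            "r_inner_um": np.concatenate([[0.0], b[:-1]]),
            "r_outer_um": b,
            "volume_um3": self.region_volumes_um3,
            "mass_g": self.region_masses_g,
        })


def locate(point, cell: CellModel) -> str:
    """Region label containing a point; boundary ties go to the inner region."""
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise InvalidArgumentError("point coordinates must be finite")
    r = float(np.linalg.norm(p))
    idx = int(np.searchsorted(cell.boundaries, r - _BOUNDARY_TOL, side="left"))
    if idx >= len(cell.region_labels):
        return "exterior"
    return cell.region_labels[idx]


def _sphere_crossings(pos: np.ndarray, direction: np.ndarray,
                      radius: float) -> list[float]:
    # positive ray parameters where |pos + t*dir| == radius
    b = float(np.dot(pos, direction))
    c = float(np.dot(pos, pos)) - radius * radius
    disc = b * b - c
    if disc <= 0.0:
        return []
    sq = math.sqrt(disc)
    return [t for t in (-b - sq, -b + sq) if t > _BOUNDARY_TOL]


def ray_trace(position, direction, cell: CellModel) -> list[tuple[str, float]]:
    """Ordered (region, path length µm) segments of a ray through the cell.

    Segment boundaries are exact sphere intersections; segments outside the
    cell are omitted, so a ray that misses returns an empty list.
    """
    pos = np.asarray(position, dtype=float)
    d = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(d))
    if norm == 0.0:
        raise InvalidArgumentError("direction must be a non-zero vector")
    if abs(norm - 1.0) > 1e-9:
        raise InvalidArgumentError("direction must be unit-norm")
    ts = sorted({t for radius in cell.boundaries
                 for t in _sphere_crossings(pos, d, radius)})
    if np.linalg.norm(pos) < cell.cell_radius - _BOUNDARY_TOL:
        ts = [0.0] + ts
    segments: list[tuple[str, float]] = []
    for t0, t1 in zip(ts[:-1], ts[1:]):
        if t1 - t0 <= _BOUNDARY_TOL:
            continue
        # probe off-center: the exact midpoint of a tangent chord lies on the
        # osculating sphere and would be mis-assigned to the inner region
        probe = pos + (t0 + 0.37 * (t1 - t0)) * d
        label = locate(probe, cell)
        if label != "exterior":
            segments.append((label, t1 - t0))
    return segments


# --- degrader stack --------------------------------------------------------

@dataclass(frozen=True)
class DegraderSlab:
    material: str                 # "air" or "mylar"
    thickness_um: float | None    # None marks the free slab solved by tune_degrader

    def __post_init__(self) -> None:
        if self.material not in physics.MATERIALS:
            raise InvalidArgumentError(f"unknown material {self.material!r}")
        if self.thickness_um is not None and self.thickness_um <= 0:
            raise InvalidArgumentError("thickness must be positive")


@dataclass(frozen=True)
class DegraderStack:
    """Ordered attenuator slabs (beam direction) upstream of the cell."""

    slabs: tuple[DegraderSlab, ...]
    exit_gap_um: float = 0.0

    def path_gcm2(self) -> float:
        """Total mass thickness, requiring all slabs to be resolved."""
        total = 0.0
        for s in self.slabs:
            if s.thickness_um is None:
                raise InvalidArgumentError("stack contains an unsolved slab")
            total += (physics.MATERIALS[s.material].density
                      * s.thickness_um * physics.CM_PER_UM)
        return total


def transported_energy(beam_energy_mev: float, stack: DegraderStack) -> float:
    """Mean proton energy after the stack by CSDA range subtraction.

    Gaussian energy straggling is symmetric about the mean, so the
    transported mean equals the deterministic CSDA value.
    """
    table = physics.get_range_table("proton", physics.WATER)
    e = beam_energy_mev
    for slab in stack.slabs:
        model = physics.MATERIALS[slab.material]
        tbl = physics.get_range_table("proton", model)
        r = float(tbl.range_of(e)) - (model.density * slab.thickness_um
                                      * physics.CM_PER_UM)
        if r <= float(tbl.range_of(1e-3)):
            return 0.0
        e = float(tbl.energy_at(r))
    return e


def tune_degrader(beam_energy_mev: float, target_energy_kev: float,
                  stack_template: DegraderStack,
                  tolerance_kev: float = 1.0) -> DegraderStack:
    """Solve the free slab thickness so the transported mean energy hits target.

    Exactly one slab in the template must have ``thickness_um=None``; its
    thickness is found by bisection (Brent), ≤ 60 iterations.  Raises
    :class:`NoSolutionError`, naming the bracketing energies, when the fixed
    slabs alone already degrade the beam past the target.
    """
    target_mev = target_energy_kev * 1e-3
    if target_mev >= beam_energy_mev:
        raise InvalidArgumentError("target must be below the beam energy")
    free = [i for i, s in enumerate(stack_template.slabs)
            if s.thickness_um is None]
    if len(free) != 1:
        raise InvalidArgumentError("template must have exactly one free slab")
    idx = free[0]
    material = physics.MATERIALS[stack_template.slabs[idx].material]

    def with_thickness(t_um: float) -> DegraderStack:
        slabs = list(stack_template.slabs)
        slabs[idx] = replace(slabs[idx], thickness_um=max(t_um, 1e-12))
        return DegraderStack(tuple(slabs), stack_template.exit_gap_um)

    def exit_energy(t_um: float) -> float:
        return transported_energy(beam_energy_mev, with_thickness(t_um))

    e_zero = exit_energy(0.0)
    if e_zero < target_mev:
        raise NoSolutionError(
            f"target {target_energy_kev} keV unreachable: fixed slabs alone "
            f"degrade the beam to {e_zero * 1e3:.1f} keV")
    # free-slab thickness that would stop the beam entirely
    tbl = physics.get_range_table("proton", material)
    t_max_um = (float(tbl.range_of(beam_energy_mev))
                / material.density / physics.CM_PER_UM)
    t_solution = brentq(lambda t: exit_energy(t) - target_mev,
                        0.0, t_max_um, xtol=1e-3, maxiter=60)
    solved = with_thickness(float(t_solution))
    achieved = transported_energy(beam_energy_mev, solved)
    if abs(achieved - target_mev) * 1e3 > 10.0:
        raise NoSolutionError(
            f"bisection stalled at {achieved * 1e3:.1f} keV "
            f"(target {target_energy_kev} keV)")
    return solved
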