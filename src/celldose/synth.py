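"""Synthetic assay data with known ground truth.

Every generator is deterministic under a fixed seed and returns the data
together with the ground-truth parameters used, so analyzer round trips can
be checked exactly (noise → 0) and statistically (noise on).  Noise families:
lognormal for concentrations and fluorescence (positive, multiplicative
measurement error), Poisson for colony counts, Gaussian for pixel maps.
Defaults are the study's printed magnitudes (IC50 ~83.5/103 µM, compartment
iron levels 150–430 µg/g, 7.5 mg B/kg injected dose) so demonstration output
looks like the real assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioanalysis import STOICHIOMETRIC_B_FE_MASS_RATIO, four_pl
from .errors import InvalidArgumentError


def _lognormal_about(rng, mean, cv, size):
    """Lognormal samples with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean, dtype=float)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    mu = math.log(mean) - 0.5 * sigma * sigma
    return rng.lognormal(mu, sigma, size)


def gen_icpms_uptake(true_b_ng: float = 150.0, compartment_split: float = 0.4,
                     cv: float = 0.10, n: int = 6, seed: int = 0):
    """ICP-MS style B/Fe uptake records with the compound's 18:1 stoichiometry.

    ``compartment_split`` is the fraction of internalized compound in the
    nucleus.  Fe amounts follow B through the fixed B:Fe mass ratio with
    independent lognormal noise.

    Returns ``(records DataFrame, truth dict)``.
    """
    if cv < 0:
        raise InvalidArgumentError("cv must be >= 0")
    if not 0.0 <= compartment_split <= 1.0:
        raise InvalidArgumentError("compartment_split must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for compartment, frac in (("nucleus", compartment_split),
                              ("cytoplasm", 1.0 - compartment_split)):
        b_true = true_b_ng * frac
        fe_true = b_true / STOICHIOMETRIC_B_FE_MASS_RATIO
        b_vals = _lognormal_about(rng, b_true, cv, n) if b_true > 0 else np.zeros(n)
        fe_vals = (_lognormal_about(rng, fe_true, cv, n)
                   if fe_true > 0 else np.zeros(n))
        for i in range(n):
            rows.append(("B", compartment, b_vals[i], "treated", i))
            rows.append(("Fe", compartment, fe_vals[i], "treated", i))
    records = pd.DataFrame(rows, columns=[
        "element", "compartment", "amount_ng_per_1e6_cells", "group",
        "replicate"])
    truth = {"true_b_ng": true_b_ng, "compartment_split": compartment_split,
             "b_fe_mass_ratio": STOICHIOMETRIC_B_FE_MASS_RATIO, "cv": cv}
    return records, truth


def gen_elemental_map(cell_radius_px: int = 40, nucleus_radius_px: int = 16,
                      cyto_level: float = 250.0, nucleus_level: float = 430.0,
                      noise_sd: float = 0.0, seed: int = 0):
    """Disk-in-disk 2-D elemental map (µg/g dry weight) with masks.

    Emulates a micro-beam elemental image of a single cell with nuclear
    enrichment of the tracked element.  Returns ``(image, masks, truth)``
    where masks has boolean ``cytoplasm`` and ``nucleus`` arrays.
    """
    if nucleus_radius_px >= cell_radius_px:
        raise InvalidArgumentError("nucleus must be smaller than the cell")
    if cyto_level <= 0 or nucleus_level <= 0:
        raise InvalidArgumentError("levels must be positive")
    rng = np.random.default_rng(seed)
    n = 2 * cell_radius_px + 1
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = (xx - cell_radius_px) ** 2 + (yy - cell_radius_px) ** 2
    nucleus = r2 <= nucleus_radius_px ** 2
    cytoplasm = (r2 <= cell_radius_px ** 2) & ~nucleus
    image = np.zeros((n, n))
    image[cytoplasm] = cyto_level
    image[nucleus] = nucleus_level
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, image.shape) * (
            cytoplasm | nucleus)
    truth = {"cyto_level": cyto_level, "nucleus_level": nucleus_level,
             "noise_sd": noise_sd}
    return image, {"cytoplasm": cytoplasm, "nucleus": nucleus}, truth


def gen_dose_response(ic50: float = 83.5, slope: float = 1.5,
                      top: float = 1.0, bottom: float = 0.05,
                      cv: float = 0.08, concentrations=None,
                      n: int = 4, seed: int = 0):
    """Viability plate table from a 4PL curve with multiplicative noise."""
    if ic50 <= 0 or cv < 0:
        raise InvalidArgumentError("ic50 must be positive and cv >= 0")
    if concentrations is None:
        concentrations = np.geomspace(ic50 / 30.0, ic50 * 30.0, 8)
    concentrations = np.asarray(concentrations, dtype=float)
    if not (concentrations.min() < ic50 < concentrations.max()):
        raise InvalidArgumentError("concentrations must span the IC50")
    rng = np.random.default_rng(seed)
    rows = []
    for c in concentrations:
        mean = four_pl(c, bottom, top, ic50, slope)
        vals = _lognormal_about(rng, mean, cv, n)
        for i, v in enumerate(vals):
            rows.append((c, v, i))
    table = pd.DataFrame(rows, columns=["concentration_um", "viability",
                                        "replicate"])
    truth = {"ic50": ic50, "slope": slope, "top": top, "bottom": bottom,
             "cv": cv}
    return table, truth


def gen_colony_counts(sf_true: float, seeded: int = 150,
                      pe_control: float = 0.5, wells: int = 3, seed: int = 0):
    """Poisson colony counts per well for a true survival fraction."""
    if not 0.0 <= sf_true:
        raise InvalidArgumentError("sf_true must be >= 0")
    if seeded <= 0 or not 0 < pe_control <= 1:
        raise InvalidArgumentError("invalid seeding parameters")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(seeded * pe_control * sf_true, wells)
    truth = {"sf_true": sf_true, "seeded": seeded, "pe_control": pe_control}
    return counts, truth


DEFAULT_ORGAN_PARAMS = {
    # organ: (%ID/g extrapolated to t=0, clearance rate 1/h);
    # tumor clears slower than liver/lung (retention up to 4 h)
    "tumor": (2.5, 0.05),
    "liver": (8.0, 0.40),
    "lung": (4.0, 0.45),
    "kidney": (6.0, 0.30),
    "spleen": (3.0, 0.30),
    "blood": (5.0, 0.50),
    "muscle": (1.0, 0.30),
    "brain": (0.3, 0.30),
}


def gen_biodistribution(dose_mg_b_per_kg: float = 7.5, organ_params=None,
                        times_h=(1.0, 4.0), n_mice: int = 4,
                        cv: float = 0.15, seed: int = 0):
    """%ID/g biodistribution table with mono-exponential organ clearance."""
    organ_params = organ_params or DEFAULT_ORGAN_PARAMS
    times_h = np.asarray(times_h, dtype=float)
    if np.any(times_h <= 0):
        raise InvalidArgumentError("times must be positive")
    for organ, (a0, lam) in organ_params.items():
        if a0 <= 0 or lam < 0:
            raise InvalidArgumentError(f"invalid parameters for {organ!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for organ, (a0, lam) in organ_params.items():
        for t in times_h:
            mean = a0 * math.exp(-lam * t)
            vals = _lognormal_about(rng, mean, cv, n_mice)
            for mouse, v in enumerate(vals):
                rows.append((organ, t, mouse, v))
    table = pd.DataFrame(rows, columns=["organ", "time_h", "mouse",
                                        "pct_id_per_g"])
    truth = {"dose_mg_b_per_kg": dose_mg_b_per_kg,
             "organ_params": dict(organ_params), "cv": cv}
    return table, truth


def gen_ros_kinetics(baseline: float = 100.0, slope_per_hour: float = 2.0,
                     horizon_h: float = 48.0, step_h: float = 2.0,
                     cv: float = 0.05, n: int = 4, seed: int = 0):
    """Fluorescence kinetics: linear ROS growth plus multiplicative noise."""
    if baseline <= 0 or cv < 0:
        raise InvalidArgumentError("baseline must be positive and cv >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, horizon_h + 0.5 * step_h, step_h)
    rows = []
    for t in times:
        mean = baseline + slope_per_hour * t
        vals = _lognormal_about(rng, mean, cv, n)
        for i, v in enumerate(vals):
            rows.append((t, v, i))
    table = pd.DataFrame(rows, columns=["time_h", "value", "replicate"])
    truth = {"baseline": baseline, "slope_per_hour": slope_per_hour, "cv": cv}
    return table, truth
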