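"""Particle populations and the generators that produce them.

The study design rests on number-weighted size distributions: a series of
near-spherical metal cores with constant relative spread, the same cores
after grafting a polymer shell of thickness ``L`` (hydrodynamic diameter
``d_core + 2 L``), and polyplex cores whose median size is set by an
equilibrium-grafting-density growth mechanism.  All distributions are
log-normal, parameterized by median and log-standard-deviation; for a
log-normal the relative standard deviation is ``sqrt(exp(sigma_log**2)-1)``,
so a target relative SD maps to ``sigma_log = sqrt(log(1 + rel_sd**2))``.

Every stochastic generator requires an explicit integer seed; unseeded calls
raise rather than silently drawing from global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import chemistry

__all__ = [
    "ParticlePopulation",
    "FunctionalizedPopulation",
    "Formulation",
    "TitrationSeries",
    "gen_core_population",
    "functionalize",
    "gen_polyplex_cores",
    "gen_titration",
    "default_polydispersity_schedule",
    "GOLD_SERIES_NOMINAL_NM",
]

#: nominal core diameters (nm) of the 11-member reference gold series
GOLD_SERIES_NOMINAL_NM = (5, 10, 30, 40, 50, 60, 80, 100, 150, 200, 250)


def _require_seed(seed) -> int:
    if seed is None:
        raise ValueError("stochastic generators require an explicit integer seed")
    return int(seed)


@dataclass
class ParticlePopulation:
    """A number-weighted sample of core diameters (nm)."""

    diameters: np.ndarray
    label: str = ""
    generative: dict | None = None

    def __post_init__(self):
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.diameters.ndim != 1 or self.diameters.size < 1:
            raise ValueError("diameters must be a nonempty 1-D array")
        if not np.all(self.diameters > 0):
            raise ValueError("all diameters must be positive")
        if self.generative is not None and "n" in self.generative:
            if int(self.generative["n"]) != self.diameters.size:
                raise ValueError("generative n does not match sample size")

    @property
    def n(self) -> int:
        return int(self.diameters.size)

    @property
    def median_nm(self) -> float:
        return float(np.median(self.diameters))

    @property
    def rel_sd(self) -> float:
        return float(np.std(self.diameters) / np.mean(self.diameters))


@dataclass
class FunctionalizedPopulation:
    """Cores carrying a uniform shell: hydrodynamic diameter = core + 2 L."""

    core: ParticlePopulation
    shell_thickness_nm: float
    hydrodynamic_diameters: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.shell_thickness_nm < 0:
            raise ValueError("shell thickness must be >= 0")
        expected = self.core.diameters + 2.0 * self.shell_thickness_nm
        if self.hydrodynamic_diameters is None:
            self.hydrodynamic_diameters = expected
        else:
            self.hydrodynamic_diameters = np.asarray(self.hydrodynamic_diameters, float)
            if not np.array_equal(self.hydrodynamic_diameters, expected):
                raise ValueError("hydrodynamic diameters must equal core + 2*L exactly")


@dataclass
class Formulation:
    """Composition of a polyplex formulation."""

    np_ratio: float
    pei_pp_ratio: float
    conjugation_pct: float
    nucleic_acid: Mapping = field(
        default_factory=lambda: {"name": "oligo", "mw_g_per_mol": 12850.0, "shape_factor": 1.2}
    )

    def __post_init__(self):
        if self.np_ratio <= 0:
            raise ValueError("np_ratio must be > 0")
        if self.pei_pp_ratio <= 0:
            raise ValueError("pei_pp_ratio must be > 0")
        if not (0 < self.conjugation_pct <= 100):
            raise ValueError("conjugation_pct must be in (0, 100]")


@dataclass
class TitrationSeries:
    """Sequential-addition series: cumulative polymer added, its partitioning
    between particle uptake and supernatant, and the resulting shell thickness."""

    step_added: np.ndarray
    uptake: np.ndarray
    supernatant: np.ndarray
    shell_thickness_nm: np.ndarray
    gold: dict

    def __post_init__(self):
        for name in ("step_added", "uptake", "supernatant", "shell_thickness_nm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        # "exact" at machine precision: a few ulps of slack for round-tripping
        if not np.allclose(self.uptake + self.supernatant, self.step_added,
                           rtol=1e-12, atol=0.0):
            raise ValueError("mass balance violated: uptake + supernatant != added")
        if np.any(np.diff(self.uptake) < 0):
            raise ValueError("uptake must be non-decreasing")


def gen_core_population(median_nm: float, rel_sd: float, n: int, seed: int,
                        label: str = "") -> ParticlePopulation:
    """Draw ``n`` log-normal core diameters with the given median and target
    relative standard deviation.

    ``rel_sd = 0`` degenerates to a monodisperse population.  Seeded draws are
    bit-reproducible.
    """
    if median_nm <= 0:
        raise ValueError("median_nm must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= rel_sd < 1):
        raise ValueError("rel_sd must be in [0, 1)")
    seed = _require_seed(seed)
    sigma_log = math.sqrt(math.log1p(rel_sd ** 2))
    if sigma_log == 0.0:
        d = np.full(n, float(median_nm))
    else:
        rng = np.random.default_rng(seed)
        d = median_nm * np.exp(sigma_log * rng.standard_normal(n))
    return ParticlePopulation(
        d, label=label,
        generative={"median_nm": median_nm, "sigma_log": sigma_log, "n": n, "seed": seed},
    )


def functionalize(pop: ParticlePopulation, shell_thickness_nm: float) -> FunctionalizedPopulation:
    """Add a uniform shell of thickness ``L``: hydrodynamic diameter = core + 2 L.

    Deterministic given the core population; preserves the distribution width.
    """
    if shell_thickness_nm < 0:
        raise ValueError("shell thickness must be >= 0")
    return FunctionalizedPopulation(core=pop, shell_thickness_nm=float(shell_thickness_nm))


def default_polydispersity_schedule(pei_pp_ratio: float, base: float = 0.08,
                                    amplitude: float = 0.17, center_ratio: float = 10.0,
                                    width_log: float = 0.8) -> float:
    """Default sigma_log vs PEI/(R)PP blend ratio: a Gaussian bump in log-ratio.

    The trend — distributions widening toward mid blend ratios and narrowing
    again for the largest cores — is reported qualitatively only, so this
    functional form is a declared stand-in (flagged as an assumption in run
    configs).  Defaults put sigma_log ~ 0.25 at 10:1 and ~ 0.10 at 50:1.
    """
    x = math.log(pei_pp_ratio) - math.log(center_ratio)
    return base + amplitude * math.exp(-x * x / (2.0 * width_log ** 2))


def gen_polyplex_cores(formulation: Formulation, model: Mapping, n: int, seed: int,
                       polydispersity_schedule: Callable[[float], float] | None = None,
                       label: str = "") -> ParticlePopulation:
    """Generate polyplex core diameters under the equilibrium-grafting-density
    growth model.

    Cores grow until the PEG chains carried by the conjugated polycation just
    tile the total core surface at the equilibrium density ``D*``; with fixed
    total core volume the median diameter is ``6 V_tot D* / P_total``.

    ``model`` keys: ``equilibrium_density_per_nm2``, ``total_core_volume_nm3``,
    ``total_peg_count``.
    """
    dstar = float(model["equilibrium_density_per_nm2"])
    vtot = float(model["total_core_volume_nm3"])
    ptot = float(model["total_peg_count"])
    if dstar <= 0 or vtot <= 0:
        raise ValueError("model parameters must be > 0")
    if ptot <= 0:
        raise ValueError("total_peg_count must be > 0: no shell-limited growth possible")
    seed = _require_seed(seed)
    median = chemistry.equilibrium_core_diameter(vtot, ptot, dstar)
    if polydispersity_schedule is None:
        polydispersity_schedule = default_polydispersity_schedule
    sigma_log = float(polydispersity_schedule(formulation.pei_pp_ratio))
    rel_sd = math.sqrt(math.expm1(sigma_log ** 2))
    return gen_core_population(median, rel_sd, n, seed, label=label)


def gen_titration(step_added: Sequence[float], capacity_molecules: float,
                  gold_spec: Mapping, brush_params: Mapping,
                  softness: float = 0.0) -> TitrationSeries:
    """Simulate sequential polymer addition to a fixed particle stock.

    With ``softness = 0`` uptake is hard-saturating, ``min(added, capacity)``:
    every molecule is taken up until the shell is complete, after which all
    excess stays in the supernatant.  With ``softness > 0`` uptake follows the
    smooth ``capacity * (1 - exp(-added / (softness * capacity)))``.  The mass
    balance ``uptake + supernatant == added`` is exact by construction.

    ``gold_spec`` keys: ``core_diameter_nm``, ``particle_concentration_per_uL``,
    ``volume_uL``.  ``brush_params`` keys: ``n_monomers``, ``monomer_nm``.
    """
    added = np.asarray(step_added, dtype=float)
    if added.ndim != 1 or added.size < 1 or np.any(np.diff(added) <= 0):
        raise ValueError("step_added must be strictly increasing")
    if capacity_molecules <= 0:
        raise ValueError("capacity must be > 0")
    if softness > 0:
        uptake = capacity_molecules * (-np.expm1(-added / (softness * capacity_molecules)))
    else:
        uptake = np.minimum(added, capacity_molecules)
    supernatant = added - uptake
    d = float(gold_spec["core_diameter_nm"])
    count = float(gold_spec["particle_concentration_per_uL"]) * float(gold_spec["volume_uL"])
    density = np.array([chemistry.grafting_density(u, d, count) if u > 0 else 0.0
                        for u in uptake])
    thickness = np.array([
        chemistry.brush_thickness(brush_params["n_monomers"], brush_params["monomer_nm"], dd)
        if dd > 0 else 0.0
        for dd in density
    ])
    return TitrationSeries(added, uptake, supernatant, thickness,
                           gold=dict(gold_spec))
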