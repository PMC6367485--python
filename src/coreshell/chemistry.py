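"""Polymer-shell chemistry: brush scaling, grafting density, titration
analysis, payload per particle and the equilibrium-growth consequences.

The shell is a grafted polymer brush.  For a chain of ``N`` monomers of size
``a`` (nm) at grafting density ``D`` (chains/nm²) the brush height is

    L = N * a**(5/3) * D**(1/3)

which for the 5-kDa PEG used here (N = 114, a = 0.35 nm) predicts ~15.7 nm at
the 0.5 chains/nm² plateau — consistent with the measured 17 nm shell.

Core growth of polyplexes is limited by an equilibrium grafting density D*:
condensation stops once the conjugated PEG just covers the total core
surface.  At fixed total core volume V_tot (set by the amount of nucleic
acid) the monodisperse-sphere identity A_tot = 6 V_tot / d = P_total / D*
gives d = 6 V_tot D* / P_total, so the total surface area — and hence the
payload partitioning — scales with the number of conjugated PEG chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import units

__all__ = [
    "BrushModel",
    "PayloadParams",
    "brush_thickness",
    "brush_density",
    "monomer_count",
    "grafting_density",
    "analyze_titration",
    "dna_mass_fraction",
    "payload_count",
    "equilibrium_core_diameter",
    "surface_area_ratio",
    "peg_per_pei",
    "DEFAULT_AMINES_PER_PEI",
]

#: protonatable amines on a 25-kDa branched PEI at ~43 g/mol per nitrogen,
#: under the all-amines reading of "percentage of PEI amines conjugated"
DEFAULT_AMINES_PER_PEI = 581


@dataclass
class BrushModel:
    """Grafted-brush description of the PEG shell."""

    n_monomers: float
    monomer_nm: float
    density_per_nm2: float | None = None
    thickness_nm: float | None = None

    def __post_init__(self):
        if self.n_monomers <= 0 or self.monomer_nm <= 0:
            raise ValueError("N and a must be > 0")
        if self.density_per_nm2 is not None and self.thickness_nm is None:
            self.thickness_nm = brush_thickness(self.n_monomers, self.monomer_nm,
                                                self.density_per_nm2)
        elif self.thickness_nm is not None and self.density_per_nm2 is None:
            self.density_per_nm2 = brush_density(self.thickness_nm, self.n_monomers,
                                                 self.monomer_nm)


@dataclass
class PayloadParams:
    """Assumptions for converting a core diameter into payload molecules.

    ``core_density_ug_per_uL`` defaults to 1370 (protein-compressibility
    estimate); ``na_mw_g_per_mol`` defaults to the 21-bp oligo (12850 g/mol);
    ``dna_mass_fraction`` is the mass fraction of the core that is nucleic
    acid, in (0, 1].
    """

    core_density_ug_per_uL: float = 1370.0
    na_mw_g_per_mol: float = 12850.0
    dna_mass_fraction: float = 1.0

    def __post_init__(self):
        if self.core_density_ug_per_uL <= 0 or self.na_mw_g_per_mol <= 0:
            raise ValueError("density and MW must be > 0")
        if not (0 < self.dna_mass_fraction <= 1):
            raise ValueError("dna_mass_fraction must be in (0, 1]")


def brush_thickness(n_monomers: float, monomer_nm: float, density_per_nm2: float) -> float:
    """Brush height L = N a^(5/3) D^(1/3) (nm)."""
    if n_monomers <= 0 or monomer_nm <= 0:
        raise ValueError("N and a must be > 0")
    if density_per_nm2 < 0:
        raise ValueError("density must be >= 0")
    return n_monomers * monomer_nm ** (5.0 / 3.0) * density_per_nm2 ** (1.0 / 3.0)


def brush_density(thickness_nm: float, n_monomers: float, monomer_nm: float) -> float:
    """Invert the brush law: D = (L / (N a^(5/3)))**3 (chains/nm²)."""
    if n_monomers <= 0 or monomer_nm <= 0:
        raise ValueError("N and a must be > 0")
    if thickness_nm < 0:
        raise ValueError("thickness must be >= 0")
    return (thickness_nm / (n_monomers * monomer_nm ** (5.0 / 3.0))) ** 3


def monomer_count(mw_polymer: float, mw_repeat: float = units.PEG_REPEAT_G_PER_MOL) -> int:
    """Number of repeat units in a polymer of the given molar mass (rounded)."""
    if mw_polymer <= 0 or mw_repeat <= 0:
        raise ValueError("molar masses must be > 0")
    return int(round(mw_polymer / mw_repeat))


def grafting_density(peg_molecules_taken_up: float, core_diameter_nm: float,
                     particle_count: float) -> float:
    """Chains per nm² from total uptake, sphere surface area and particle count."""
    if core_diameter_nm <= 0 or particle_count <= 0:
        raise ValueError("diameter and particle count must be > 0")
    if peg_molecules_taken_up < 0:
        raise ValueError("uptake must be >= 0")
    area = math.pi * core_diameter_nm ** 2
    return peg_molecules_taken_up / (particle_count * area)


def analyze_titration(series, brush_params=None, increment_fraction: float = 0.01) -> dict:
    """Locate the uptake plateau of a sequential-addition series.

    The saturation step is the first step at which the uptake increment falls
    below ``increment_fraction`` of the added increment.  The plateau grafting
    density follows from the uptake at that step and the particle stock; the
    plateau thickness from the brush law.  If no plateau is reached the result
    is censored (``saturated = False``) rather than an error.
    """
    added, uptake = series.step_added, series.uptake
    d = float(series.gold["core_diameter_nm"])
    count = (float(series.gold["particle_concentration_per_uL"])
             * float(series.gold["volume_uL"]))
    du = np.diff(uptake)
    da = np.diff(added)
    below = np.nonzero(du < increment_fraction * da)[0]
    if below.size == 0:
        return {"saturated": False, "saturation_step": None,
                "plateau_density": None, "plateau_thickness": None}
    step = int(below[0] + 1)
    density = grafting_density(uptake[step], d, count)
    if brush_params is not None:
        thickness = brush_thickness(brush_params["n_monomers"],
                                    brush_params["monomer_nm"], density)
    else:
        thickness = float(series.shell_thickness_nm[step])
    return {"saturated": True, "saturation_step": step,
            "plateau_density": density, "plateau_thickness": thickness}


def dna_mass_fraction(np_ratio: float,
                      mw_per_phosphate: float = units.MW_PER_PHOSPHATE_G_PER_MOL,
                      mw_per_nitrogen: float = units.MW_PER_NITROGEN_G_PER_MOL) -> float:
    """Mass fraction of nucleic acid in a core formed at molar ratio N/P.

    Per phosphate the core carries ``np_ratio`` PEI nitrogens, so
    f = MW_P / (MW_P + np_ratio * MW_N).  Tends to 1 as N/P -> 0.
    """
    if np_ratio <= 0:
        raise ValueError("np_ratio must be > 0")
    return mw_per_phosphate / (mw_per_phosphate + np_ratio * mw_per_nitrogen)


def payload_count(core_diameter_nm: float, params: PayloadParams) -> float:
    """Number of nucleic-acid molecules inside one core of the given diameter.

    count = (pi/6) d³ [nm³] * rho [g/nm³] * f / MW [g/mol] * N_A.
    """
    if core_diameter_nm <= 0:
        raise ValueError("diameter must be > 0")
    volume_nm3 = math.pi / 6.0 * core_diameter_nm ** 3
    rho_g_per_nm3 = units.ug_per_ul_to_g_per_nm3(params.core_density_ug_per_uL)
    mass_na_g = volume_nm3 * rho_g_per_nm3 * params.dna_mass_fraction
    return mass_na_g / params.na_mw_g_per_mol * units.AVOGADRO_PER_MOL


def equilibrium_core_diameter(total_core_volume_nm3: float, total_peg_count: float,
                              equilibrium_density_per_nm2: float) -> float:
    """Median core diameter under equilibrium-grafting-density-limited growth.

    Monodisperse spheres of diameter d have A_tot = 6 V_tot / d; growth stops
    when A_tot = P_total / D*, hence d = 6 V_tot D* / P_total.
    """
    if total_core_volume_nm3 <= 0 or total_peg_count <= 0 or equilibrium_density_per_nm2 <= 0:
        raise ValueError("all growth-model inputs must be > 0")
    return 6.0 * total_core_volume_nm3 * equilibrium_density_per_nm2 / total_peg_count


def surface_area_ratio(conjugation_pct_1: float, conjugation_pct_2: float) -> float:
    """Ratio of total core surface areas for two conjugation degrees.

    At fixed total core volume and fixed polymer/nucleic-acid amounts the
    total surface area is proportional to the total PEG count, itself
    proportional to the degree of conjugation, so A1/A2 = c1/c2 — equal to
    the inverse ratio of the equilibrium core diameters.
    """
    for c in (conjugation_pct_1, conjugation_pct_2):
        if not (0 < c <= 100):
            raise ValueError("conjugation degrees must be in (0, 100]")
    return conjugation_pct_1 / conjugation_pct_2


def peg_per_pei(conjugation_pct: float, amines_per_pei: int = DEFAULT_AMINES_PER_PEI) -> float:
    """PEG chains per PEI macromolecule at the given conjugation degree (%)."""
    if not (0 < conjugation_pct <= 100):
        raise ValueError("conjugation_pct must be in (0, 100]")
    if amines_per_pei <= 0:
        raise ValueError("amines_per_pei must be > 0")
    return conjugation_pct / 100.0 * amines_per_pei
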