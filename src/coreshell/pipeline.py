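"""End-to-end synthetic study: simulate every raw observable, then run the
full analysis chain (AFM image analysis -> DLS inversion -> core-shell
inference -> shell chemistry) through the declared CSV interfaces only.

`simulate_study` writes a fixture directory; `analyze_study` consumes one
(fixture or real data with the same schemas) and emits the shell estimate,
chemistry table, exclusion list and a human-readable report with the
uncertainty budget.  Both are deterministic given the configured seed.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import afm as afm_mod
from . import chemistry, dls, io, populations, topography
from .config import ASSUMPTIONS, RunConfig, config_hash
from .inference import (ShellThicknessModel, build_series_pair,
                        combine_uncertainty, predicted_gap, screen_rows)

__all__ = ["simulate_study", "analyze_study", "member_seed"]

DEFAULT_TAUS_S = np.logspace(-7, -1, 200)


def member_seed(seed: int, index: int) -> int:
    """Deterministic per-member child seed below 2**31."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % 2 ** 31)


def _member_pixel_nm(nominal: float, cap_nm: float) -> float:
    # finer pixels for small particles, capped at the configured spacing
    return float(np.clip(nominal / 25.0, 0.5, cap_nm))


def _member_threshold(nominal: float, noise_sd: float) -> float:
    return max(0.4 * nominal, 5.0 * noise_sd if noise_sd > 0 else 0.5)


def _field_nm_for(pop, margin_nm: float = 5.0, packing: float = 0.22) -> float:
    area = float(np.sum(np.pi * (pop.diameters / 2.0 + margin_nm) ** 2))
    return max(math.sqrt(area / packing), 6.0 * (pop.diameters.max() + 2 * margin_nm))


def simulate_study(config: RunConfig, outdir, force: bool = False) -> Path:
    """Generate the full synthetic study into ``outdir``.

    Writes populations.csv, series_manifest.csv, per-member topographs with
    ground truth, per-member correlograms of the functionalized particles,
    and a default titration series.  Byte-identical across runs at a fixed
    config and seed.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    (outdir / "topographs").mkdir(parents=True, exist_ok=True)
    (outdir / "correlograms").mkdir(exist_ok=True)

    syn = config.synthetic
    dls_cfg = dls.DLSConfig(**config.dls.model_dump())
    pop_rows, manifest_rows = [], []
    for i, nominal in enumerate(syn.nominal_series_nm):
        label = f"{nominal:g}nm"
        seed_i = member_seed(config.seed, i)
        pop = populations.gen_core_population(nominal, syn.rel_sd,
                                              syn.particles_per_member, seed_i,
                                              label=label)
        pop_rows.append(pd.DataFrame({"label": label, "diameter_nm": pop.diameters}))
        manifest_rows.append({"label": label, "nominal_nm": nominal,
                              "n": syn.particles_per_member, "rel_sd": syn.rel_sd,
                              "seed": seed_i})
        pixel = _member_pixel_nm(nominal, config.afm.pixel_nm)
        field = _field_nm_for(pop)
        topo, truth = topography.gen_afm_topograph(
            pop, pixel, field, tilt_nm_per_px=syn.tilt_nm_per_px,
            noise_sd_nm=syn.noise_sd_nm, shape_aspect=1.0, seed=seed_i + 1)
        topography.write_topograph(topo, outdir / "topographs" / f"{label}.txt")
        truth.to_csv(outdir / "topographs" / f"{label}_truth.csv", index=False)

        func = populations.functionalize(pop, syn.shell_thickness_nm)
        corr = dls.simulate_g2(func, dls_cfg, DEFAULT_TAUS_S, noise_sd=1e-4,
                               seed=seed_i + 2)
        pd.DataFrame({"tau_s": corr.taus_s, "g2": corr.g2}).to_csv(
            outdir / "correlograms" / f"{label}.csv", index=False)

    pd.concat(pop_rows, ignore_index=True).to_csv(outdir / "populations.csv", index=False)
    pd.DataFrame(manifest_rows).to_csv(outdir / "series_manifest.csv", index=False)

    chem = config.chemistry
    n_mono = chemistry.monomer_count(chem.peg_mw_g_per_mol)
    gold_spec = {"core_diameter_nm": 100.0,
                 "particle_concentration_per_uL": 5.6e6, "volume_uL": 100.0}
    count = gold_spec["particle_concentration_per_uL"] * gold_spec["volume_uL"]
    capacity = (chem.equilibrium_density_per_nm2 * math.pi
                * gold_spec["core_diameter_nm"] ** 2 * count)
    added = capacity * np.linspace(0.2, 2.0, 10)
    series = populations.gen_titration(added, capacity, gold_spec,
                                       {"n_monomers": n_mono, "monomer_nm": chem.monomer_nm})
    pd.DataFrame({"step_added": series.step_added, "uptake": series.uptake,
                  "supernatant": series.supernatant,
                  "shell_thickness_nm": series.shell_thickness_nm}).to_csv(
        outdir / "titration.csv", index=False)
    return outdir


def _flatten_two_pass(topo, noise_sd_guess: float):
    """Rough flatten, mask everything well above the background, re-flatten."""
    rough = afm_mod.flatten_first_order(topo)
    scale = max(noise_sd_guess, 1e-3)
    mask = rough.heights > 3.0 * scale
    mask = ndimage.binary_dilation(mask, iterations=3)
    if (~mask).sum() < 0.05 * mask.size:  # nearly everything masked: keep rough
        return rough
    return afm_mod.flatten_first_order(topo, exclusion_mask=mask)


def analyze_member_topograph(topo, min_height_nm: float, config: RunConfig,
                             noise_sd_guess: float = 0.5):
    """Flatten, detect and measure one topograph; return the measurement
    table plus the log-normal fit of shape-corrected diameters."""
    flat = _flatten_two_pass(topo, noise_sd_guess)
    meas = afm_mod.measure_all(flat, min_height_nm, config.afm.min_area_px,
                               config.afm.max_eccentricity)
    ok = meas[~meas["excluded"].astype(bool)]
    if config.afm.shape_factor is not None:
        f = config.afm.shape_factor
    else:
        try:
            f, _ = afm_mod.shape_correction_factor(ok)
        except ValueError:
            f = 1.0
    corrected = f * ok["height_nm"].to_numpy(float)
    fit = afm_mod.fit_lognormal(corrected)
    return meas, fit, f


def analyze_study(config: RunConfig, fixture_dir, outdir, dry_run: bool = False) -> dict:
    """Run the full analysis chain on a fixture directory.

    With ``dry_run`` only the CSV schemas are validated and nothing is
    written.  Returns a dict with the key results.
    """
    fixture_dir, outdir = Path(fixture_dir), Path(outdir)
    diagnostics = []
    for name, schema in (("populations.csv", "populations"),
                         ("series_manifest.csv", "series_manifest"),
                         ("titration.csv", "titration")):
        ok, diags = io.validate_csv(fixture_dir / name, schema)
        diagnostics.extend(diags)
    manifest = pd.read_csv(fixture_dir / "series_manifest.csv")
    for label in manifest["label"]:
        ok, diags = io.validate_csv(fixture_dir / "correlograms" / f"{label}.csv",
                                    "correlogram")
        diagnostics.extend(diags)
    if diagnostics:
        raise ValueError("schema validation failed:\n" + "\n".join(diagnostics))
    if dry_run:
        return {"validated": True}

    outdir.mkdir(parents=True, exist_ok=True)
    dls_cfg = dls.DLSConfig(**config.dls.model_dump())
    syn = config.synthetic

    afm_rows, dls_rows, meas_tables = [], [], []
    for _, row in manifest.iterrows():
        label, nominal = row["label"], float(row["nominal_nm"])
        topo = topography.read_topograph(fixture_dir / "topographs" / f"{label}.txt")
        thr = _member_threshold(nominal, syn.noise_sd_nm)
        meas, fit, f = analyze_member_topograph(topo, thr, config,
                                                noise_sd_guess=syn.noise_sd_nm)
        meas.insert(0, "label", label)
        meas_tables.append(meas)
        afm_rows.append({"label": label, "d_afm_nm": fit.mode_nm,
                         "median_nm": fit.median_nm, "sigma_log_afm": fit.sigma_log,
                         "mode_nm": fit.mode_nm, "n": fit.n, "shape_factor": f,
                         "gap_nm": predicted_gap(fit.median_nm, fit.sigma_log)})
        cdf = pd.read_csv(fixture_dir / "correlograms" / f"{label}.csv")
        corr = dls.Correlogram(cdf["tau_s"].to_numpy(), cdf["g2"].to_numpy(), dls_cfg)
        cum = dls.cumulant_analysis(corr)
        dls_rows.append({"label": label, "d_dls_nm": cum.z_average_nm,
                         "z_average_nm": cum.z_average_nm, "pdi": cum.pdi})

    afm_fits = pd.DataFrame(afm_rows)
    dls_results = pd.DataFrame(dls_rows)
    pd.concat(meas_tables, ignore_index=True).to_csv(outdir / "measurements.csv", index=False)
    afm_fits.to_csv(outdir / "fits.csv", index=False)
    dls_results.to_csv(outdir / "dls_results.csv", index=False)

    pair = build_series_pair(afm_fits, dls_results)
    pair = screen_rows(pair, config.inference.min_core_nm, config.inference.max_sigma_log)
    results = ShellThicknessModel(pair).fit()
    pair.data.to_csv(outdir / "series_pair.csv", index=False)
    pd.DataFrame([{"thickness_nm": results.thickness_nm, "se_nm": results.se_nm,
                   "n_used": results.n_used}]).to_csv(outdir / "shell_estimate.csv",
                                                      index=False)
    pd.DataFrame(results.excluded, columns=["label", "reason"]).to_csv(
        outdir / "exclusions.csv", index=False)

    k = config.inference.coverage_k
    stat_pct = (100.0 * results.se_nm / abs(results.thickness_nm)
                if results.thickness_nm else 0.0)
    budget = combine_uncertainty(
        [{"name": "AFM height (standard)", "u_pct": config.inference.u_afm_pct / 2.0},
         {"name": "DLS z-average (standard)", "u_pct": config.inference.u_dls_pct / 2.0},
         {"name": "trendline repeatability", "u_pct": stat_pct}], k=k)

    chem = config.chemistry
    n_mono = chemistry.monomer_count(chem.peg_mw_g_per_mol)
    dstar = chem.equilibrium_density_per_nm2
    l_pred = chemistry.brush_thickness(n_mono, chem.monomer_nm, dstar)
    f_mass = chemistry.dna_mass_fraction(chem.np_ratio)
    params = chemistry.PayloadParams(chem.core_density_ug_per_uL,
                                     chem.na_mw_g_per_mol, f_mass)
    titr = pd.read_csv(fixture_dir / "titration.csv")
    series = populations.TitrationSeries(
        titr["step_added"], titr["uptake"], titr["supernatant"],
        titr["shell_thickness_nm"],
        gold={"core_diameter_nm": 100.0, "particle_concentration_per_uL": 5.6e6,
              "volume_uL": 100.0})
    plateau = chemistry.analyze_titration(
        series, {"n_monomers": n_mono, "monomer_nm": chem.monomer_nm})
    area_ratio = chemistry.surface_area_ratio(7.0, 10.0)
    ref = afm_fits.loc[afm_fits["label"] == "100nm", "d_afm_nm"]
    payload_100 = (chemistry.payload_count(float(ref.iloc[0]), params)
                   if not ref.empty else float("nan"))
    chem_rows = [
        ("peg_monomer_count", n_mono),
        ("brush_thickness_nm_at_equilibrium_density", l_pred),
        ("plateau_grafting_density_per_nm2", plateau["plateau_density"]),
        ("plateau_shell_thickness_nm", plateau["plateau_thickness"]),
        ("dna_mass_fraction", f_mass),
        ("payload_oligos_100nm_core", payload_100),
        ("surface_area_ratio_7_vs_10_pct", area_ratio),
    ]
    pd.DataFrame(chem_rows, columns=["quantity", "value"]).to_csv(
        outdir / "chemistry.csv", index=False)

    report = _render_report(config, results, budget, chem_rows, len(manifest))
    (outdir / "report.txt").write_text(report)
    return {"shell": results, "budget": budget, "chemistry": dict(chem_rows),
            "pair": pair, "report": report}


def _render_report(config, results, budget, chem_rows, n_members) -> str:
    lines = [
        "Core-shell nanoparticle study report",
        "=" * 40,
        f"seed: {config.seed}   config hash: {config_hash(config)}",
        f"series members analyzed: {n_members}",
        "",
        results.summary(),
        "",
        budget.summary(),
        f"expanded thickness interval ({budget.confidence_label}): "
        f"{results.thickness_nm:.2f} nm ± {budget.expanded_pct / 100 * abs(results.thickness_nm):.2f} nm",
        "",
        "Shell chemistry",
    ]
    for name, value in chem_rows:
        if value is None:
            shown = "censored"
        elif isinstance(value, float):
            shown = f"{value:.6g}"
        else:
            shown = str(value)
        lines.append(f"  {name:<42s} {shown}")
    lines.append("")
    lines.append("Declared assumptions (defaults standing in for unstated choices):")
    for key, text in ASSUMPTIONS.items():
        lines.append(f"  assumption: true  [{key}] {text}")
    return "\n".join(lines) + "\n"
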