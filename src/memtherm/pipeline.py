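"""Config-driven pipeline tying the stages together.

A single YAML config selects stages and carries every stage parameter.
Each artifact written records a provenance header (config hash, seed,
package version) sufficient to re-run the producing command.

Config layout (all keys optional unless a stage needs them)::

    seed: 1
    outdir: out/
    simulate:
      series:
        noise_sd: 0.02
    dsc:
      input: thermogram.csv          # or simulate: {...}
      main_window: [37.0, 45.0]
      pre_window: [31.0, 36.5]
      baseline_windows: [[30.0, 36.0], [44.0, 48.0]]
    esr:
      basis_strategy: supplied       # or endpoints
    vanthoff:
      degree: auto                   # or 1 | 2 | 3
      kp: 1.0
      exclusion_threshold: 0.02
      boot: 1000
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from . import io as mio
from .esr import build_population_series
from .synthetic import (default_series_spec, generate_nitroxide_spectrum,
                        generate_two_state_thermogram,
                        default_thermogram_spec)
from .vanthoff import (bootstrap_uncertainty, fit_vant_hoff,
                       ln_equilibrium_constant, select_degree,
                       thermodynamic_curves)
from .dsc import analyze_thermogram, subtract_baseline

log = logging.getLogger("memtherm")

__all__ = ["run_pipeline", "config_hash"]


def config_hash(config: dict) -> str:
    """Stable short hash of the canonical JSON form of the config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: dict, seed: int) -> dict:
    return {"config_hash": config_hash(config), "seed": seed,
            "memtherm_version": __version__}


def run_pipeline(config: dict, outdir=None) -> dict:
    """Execute the configured stages; returns a dict of artifact paths.

    Stages: ``simulate`` (synthetic series and/or thermogram),
    ``dsc`` (baseline + transition analysis), ``esr`` (population series
    from spectra), ``vanthoff`` (fit, curves, special temperatures,
    bootstrap bands).  Any stage error propagates as an exception after
    removing partially written artifacts is *not* attempted; callers get
    a nonzero exit through the CLI wrapper instead.
    """
    outdir = Path(outdir or config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    prov = _provenance(config, seed)
    artifacts: dict[str, str] = {}
    spectra = None
    populations = None
    bases = None

    sim = config.get("simulate", {})
    if "thermogram" in sim:
        tspec = default_thermogram_spec(
            noise_sd=float(sim["thermogram"].get("noise_sd", 0.0)),
            seed=seed)
        tg = generate_two_state_thermogram(tspec)
        p = outdir / "thermogram.csv"
        mio.write_thermogram(p, _with_prov(tg, prov))
        artifacts["thermogram"] = str(p)
        log.info("simulated thermogram -> %s", p)
    if "series" in sim:
        sspec = default_series_spec(
            noise_sd=float(sim["series"].get("noise_sd", 0.0)), seed=seed)
        from .synthetic import generate_two_component_series
        spectra, truth = generate_two_component_series(sspec)
        bases = (
            generate_nitroxide_spectrum(sspec.ordered_model,
                                        sspec.field_grid),
            generate_nitroxide_spectrum(sspec.disordered_model,
                                        sspec.field_grid),
        )
        sdir = outdir / "spectra"
        sdir.mkdir(exist_ok=True)
        for i, s in enumerate(spectra):
            sp = sdir / f"spectrum_{i:03d}.csv"
            s.metadata.update(prov)
            mio.write_spectrum(sp, s)
        artifacts["spectra"] = str(sdir)
        p = outdir / "populations_truth.csv"
        mio.write_populations(p, truth, metadata=prov)
        artifacts["populations_truth"] = str(p)
        log.info("simulated %d spectra -> %s", len(spectra), sdir)

    if "dsc" in config:
        c = config["dsc"]
        if "input" in c:
            tg = mio.read_xy_table(c["input"], "thermogram")
        elif "thermogram" in artifacts:
            tg = mio.read_xy_table(artifacts["thermogram"], "thermogram")
        else:
            raise ValueError("dsc stage needs an input thermogram")
        if "buffer" in c or "baseline_windows" in c:
            buffer = (mio.read_xy_table(c["buffer"], "thermogram")
                      if "buffer" in c else None)
            windows = c.get("baseline_windows")
            tg = subtract_baseline(tg, buffer=buffer, windows=windows,
                                   degree=int(c.get("baseline_degree", 1)))
        res = analyze_thermogram(tg, tuple(c["main_window"]),
                                 tuple(c["pre_window"])
                                 if c.get("pre_window") else None)
        p = outdir / "dsc_result.csv"
        with p.open("w", encoding="utf-8") as fh:
            for k, v in prov.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("dHcal_kcal_mol,Tm_C,dTm_half_C,Tp_C,dS_cal_mol_K,"
                     "dHvH_kcal_mol,CUS\n")
            fh.write(",".join("" if v is None else repr(float(v)) for v in
                              (res.dHcal, res.Tm_C, res.dTm_half_C, res.Tp_C,
                               res.dS_at_Tm, res.dHvH, res.CUS)) + "\n")
        artifacts["dsc_result"] = str(p)
        log.info("dsc analysis -> %s", p)

    if "esr" in config:
        c = config["esr"]
        if spectra is None:
            sdir = Path(c["input"])
            spectra = [mio.read_xy_table(f, "spectrum")
                       for f in sorted(sdir.glob("*.csv"))]
        strategy = c.get("basis_strategy", "supplied" if bases else
                         "endpoints")
        populations = build_population_series(
            spectra, basis_strategy=strategy,
            bases=bases if strategy == "supplied" else None,
            allow_shift=bool(c.get("allow_shift", False)))
        p = outdir / "populations.csv"
        mio.write_populations(p, populations, metadata=prov)
        artifacts["populations"] = str(p)
        log.info("population series (%d T) -> %s",
                 populations.temperature_K.size, p)

    if "vanthoff" in config:
        c = config["vanthoff"]
        if populations is None:
            populations = mio.read_xy_table(c["populations"], "populations")
        kp = float(c.get("kp", 1.0))
        thr = float(c.get("exclusion_threshold", 0.02))
        table = ln_equilibrium_constant(populations, Kp=kp,
                                        exclusion_threshold=thr)
        degree = c.get("degree", "auto")
        if degree == "auto":
            degree = select_degree(table)
            log.info("degree=auto resolved to %d", degree)
        model = fit_vant_hoff(table, int(degree))
        model.Kp = kp
        p = outdir / "vanthoff_model.json"
        mio.write_model_json(p, model, metadata=prov)
        artifacts["model"] = str(p)
        grid = np.linspace(model.T_range[0], model.T_range[1],
                           int(c.get("grid_points", 201)))
        curves = thermodynamic_curves(model, grid)
        pc = outdir / "curves.csv"
        mio.write_curves(pc, curves, metadata=prov)
        artifacts["curves"] = str(pc)
        ps = outdir / "special_temperatures.csv"
        mio.write_special_temperatures(ps, curves, metadata=prov)
        artifacts["special_temperatures"] = str(ps)
        n_boot = int(c.get("boot", 0))
        if n_boot:
            bands = bootstrap_uncertainty(table, model, n_boot=n_boot,
                                          seed=seed, T_grid=grid)
            pb = outdir / "curve_bands.csv"
            with pb.open("w", encoding="utf-8") as fh:
                for k, v in prov.items():
                    fh.write(f"# {k}: {v}\n")
                fh.write("T_K," + ",".join(
                    f"{k}_{e}" for k in ("dG", "dH", "dS", "dC")
                    for e in ("lo", "hi")) + "\n")
                for i, t in enumerate(grid):
                    row = [t]
                    for k in ("dG", "dH", "dS", "dC"):
                        row += [bands.bands[k][0][i], bands.bands[k][1][i]]
                    fh.write(",".join(repr(float(v)) for v in row) + "\n")
            artifacts["curve_bands"] = str(pb)
        log.info("van't Hoff stage done (degree %d)", model.degree)

    return artifacts


def _with_prov(tg, prov):
    tg.metadata.update(prov)
    return tg
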