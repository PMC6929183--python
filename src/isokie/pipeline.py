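"""End-to-end demo pipeline: toy reaction → KIEs → bulk ε → batch → Rayleigh.

The demo mirrors the comparative logic of a combined modelling/measurement
isotope study: predict position-specific KIEs two ways (semiclassical
Bigeleisen and path-integral mass perturbation), assemble bulk enrichment
factors from a primary effect plus assumed secondary positions, simulate the
batch-degradation experiment those KIEs imply, and recover ε by Rayleigh
regression — then put the three ε routes side by side.  A WHAM stage
reconstructs the proton-transfer free-energy profile from synthetic umbrella
windows along the way.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict

import numpy as np

from .bigeleisen import semiclassical_kie, write_kie_table
from .config import RunConfig
from .fractionation import (
    PositionKIE,
    EnrichmentResult,
    hybrid_bulk,
    infer_secondary_average,
    write_bulk_table,
)
from .pifep import PISettings, pi_kie_from_frequency_sets
from .rayleigh import rayleigh_fit, write_fit_report
from .synthetic import (
    BatchExperimentParams,
    ElementKIESpec,
    ProfileSpec,
    make_toy_reaction,
    sample_umbrella_windows,
    simulate_batch_experiment,
)
from .thermo import ThermoSettings
from .vibrations import IsotopeSubstitution, frequencies_from_hessian, isotopolog_frequency_sets
from .wham import barrier_height, wham

log = logging.getLogger("isokie.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
                raise StageError(name, str(exc)) from exc
            log.info("stage %-12s done in %.2f s", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("toy")
def _build_reaction(config: RunConfig):
    return make_toy_reaction(config.toy)


@_stage("semiclassical")
def _semiclassical_kies(reactant, ts, th: ThermoSettings) -> Dict[str, PositionKIE]:
    out = {}
    for element in ("H", "C", "Cl"):
        if element not in reactant.labels:
            continue
        idx = reactant.labels.index(element)
        sub = IsotopeSubstitution(idx, element)
        r_l, r_h = isotopolog_frequency_sets(reactant, sub)
        t_l, t_h = isotopolog_frequency_sets(ts, sub)
        out[element] = semiclassical_kie(
            r_l, r_h, t_l, t_h, th, position=f"{element}{idx}", element=element
        )
    return out


@_stage("pi")
def _pi_primary_h(reactant, ts, config: RunConfig, seed: int) -> PositionKIE:
    idx = reactant.labels.index("H")
    sub = IsotopeSubstitution(idx, "H")
    r_l, r_h = isotopolog_frequency_sets(reactant, sub)
    t_l, t_h = isotopolog_frequency_sets(ts, sub)
    settings = PISettings(
        beads=config.pi.beads,
        temperature=config.temperature,
        n_classical=config.pi.n_classical,
        pi_steps_per_config=config.pi.pi_steps_per_config,
        seed=seed,
    )
    return pi_kie_from_frequency_sets(
        r_l, r_h, t_l, t_h, settings, position=f"H{idx}", element="H",
        include_classical_factor=True,
    )


@_stage("bulk")
def _bulk_routes(primaries: dict, config: RunConfig):
    routes = {}
    for route, prims in primaries.items():
        per_element = {}
        for element, primary in prims.items():
            pos = config.positions.get(element)
            if pos is None:
                continue
            n = pos["n"]
            secondaries = [
                PositionKIE(
                    position=f"{element}sec{i}", element=element,
                    value=pos["secondary_kie"], provenance="assumed",
                )
                for i in range(n - 1)
            ]
            bulk, enr = hybrid_bulk(primary, secondaries, strict_provenance=False)
            per_element[element] = (primary, bulk, enr)
        routes[route] = per_element
    return routes


@_stage("batch")
def _batch_and_fit(route_pi: dict, config: RunConfig, seed: int):
    elements = {
        el: ElementKIESpec(
            primary=primary.value,
            secondary=config.positions[el]["secondary_kie"],
            n=config.positions[el]["n"],
        )
        for el, (primary, _, _) in route_pi.items()
    }
    params = BatchExperimentParams(
        k_light_per_s=config.batch.k_light_per_s,
        elements=elements,
        times_h=tuple(config.batch.times_h),
        c0=config.batch.c0,
        conc_noise_rel=config.batch.conc_noise_rel,
        delta_noise_permil=config.batch.delta_noise_permil,
        seed=seed,
    )
    ds = simulate_batch_experiment(params)
    fits = {
        el: rayleigh_fit(ds, el, through_origin=config.batch.fit_through_origin)
        for el in ds.elements
    }
    return ds, fits


@_stage("wham")
def _pmf(config: RunConfig, seed: int):
    u = config.umbrella
    profile = ProfileSpec(
        form=u.profile_form, params=dict(u.profile_params),
        temperature=config.temperature,
    )
    centers = np.linspace(u.z_min, u.z_max, u.n_windows)
    windows = sample_umbrella_windows(
        profile, centers, bias_k=u.bias_k, n_per_window=u.n_per_window, seed=seed
    )
    prof = wham(windows, profile.thermo)
    barrier = barrier_height(prof, u.reactant_range)
    return windows, prof, barrier


def run_demo(config: RunConfig, write: bool = True) -> dict:
    """Execute the full demo and return (and optionally write) the report.

    All randomness derives from ``config.seed`` through a seed sequence, so a
    fixed configuration reproduces the report byte-identically.
    """
    th = ThermoSettings(temperature=config.temperature)
    ss = np.random.SeedSequence(config.seed)
    seed_pi, seed_batch, seed_umbrella = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)
    )

    reactant, ts = _build_reaction(config)
    fr = frequencies_from_hessian(reactant)
    fts = frequencies_from_hessian(ts)

    semi = _semiclassical_kies(reactant, ts, th)
    pi_h = _pi_primary_h(reactant, ts, config, seed_pi)

    primaries = {
        "semiclassical": semi,
        "pi": {**semi, "H": pi_h},
    }
    routes = _bulk_routes(primaries, config)
    ds, fits = _batch_and_fit(routes["pi"], config, seed_batch)
    windows, prof, barrier = _pmf(config, seed_umbrella)

    elements_report = {}
    for element in routes["pi"]:
        p_semi, b_semi, e_semi = routes["semiclassical"][element]
        p_pi, b_pi, e_pi = routes["pi"][element]
        fit = fits[element]
        n = config.positions[element]["n"]
        elements_report[element] = {
            "n_positions": n,
            "secondary_kie_assumed": config.positions[element]["secondary_kie"],
            "semiclassical": {
                "primary_kie": p_semi.value,
                "kie_av": b_semi.kie_av,
                "epsilon_permil": e_semi.epsilon_permil,
            },
            "pi": {
                "primary_kie": p_pi.value,
                "primary_kie_se": p_pi.se,
                "kie_av": b_pi.kie_av,
                "epsilon_permil": e_pi.epsilon_permil,
                "epsilon_se_permil": 1000.0 * p_pi.se / n,
            },
            "rayleigh": {
                "epsilon_permil": fit.epsilon_permil,
                "se_permil": fit.se_permil,
                "ci95_permil": list(fit.ci95_permil),
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
            },
        }

    h_fit = fits.get("H")
    diagnostics = {}
    if h_fit is not None and "H" in routes["pi"]:
        s_bar, inverse = infer_secondary_average(
            EnrichmentResult(element="H", epsilon_permil=h_fit.epsilon_permil),
            routes["pi"]["H"][0].value,
            config.positions["H"]["n"],
        )
        diagnostics = {
            "H_implied_secondary_kie": s_bar,
            "H_secondary_inverse": bool(inverse),
        }

    report = {
        "meta": {
            "package": "isokie",
            "seed": config.seed,
            "temperature_K": config.temperature,
            "pi_beads": config.pi.beads,
        },
        "toy": {
            "labels": list(config.toy.labels),
            "reactant_wavenumbers_cm": [float(v) for v in fr.real],
            "ts_wavenumbers_cm": [float(v) for v in fts.real],
            "ts_imaginary_cm": fts.imaginary,
        },
        "elements": elements_report,
        "pmf": {
            "barrier_kcal_mol": barrier,
            "true_barrier_kcal_mol": config.umbrella.profile_params.get("barrier"),
            "n_iter": prof.n_iter,
            "converged": prof.converged,
            "n_windows": config.umbrella.n_windows,
        },
        "diagnostics": diagnostics,
    }

    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        write_kie_table(out / "position_kies.csv",
                        [routes["pi"][el][0] for el in sorted(routes["pi"])])
        write_bulk_table(
            out / "bulk.csv",
            [(routes["pi"][el][1], routes["pi"][el][2]) for el in sorted(routes["pi"])],
        )
        ds.to_csv(out / "batch.csv")
        write_fit_report(out / "rayleigh_fits.csv", [fits[el] for el in sorted(fits)])
        prof.to_tsv(out / "pmf.tsv")
        log.info("demo outputs written to %s", out)
    return report
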