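"""Named scenario sweeps over adhesion size, distribution, rates and lifetime.

Each preset is a list of labelled configurations run with ≥3 replicates and
summarized as mean ± SD steady-state pYAP ratios.  Desk-scale budgets default
to 10⁶ events per run (the ``full`` flag raises this to 10⁷); runs at the
fast diffusion rate get proportionally more events so that comparable
simulated time is covered.

Presets
-------
size-number     one small (3×3), nine small, one large (9×9) adhesion, D=0.8
confinement     nine small adhesions confined to r ∈ {1, 0.25, 0.09}
equal-area      N ∈ {1, 2, 4, 9} adhesions of (near-)equal total area at
                D ∈ {0.8, 19}; N=2 and N=4 use 5×8 and 4×5 rectangles (the
                closest integer-site realizations of half/quarter area), and
                the realized area is recorded in the output
binding-rates   Rb ∈ {10, 50} × Ru_YAP ∈ {0.1, 0.2} for both sizes
binding-sweep   Rb ∈ {5 … 100} for both sizes, with a Hill fit per size
turnover        lifetime ∈ {none, 60, 135} × Ru_pYAP ∈ {0.001 … 0.2} ×
                Rdeph ∈ {0.035, 0.56} for nine small adhesions
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .adhesions import average_pairwise_distance
from .config import SimulationConfig
from .engine import ReplicateResult, run_replicates
from .observables import fit_hill

logger = logging.getLogger("yapkmc")

DESK_STEPS = 1_000_000
FULL_STEPS = 10_000_000

#: footprint (width, height) used in the equal-total-area sweep
EQUAL_AREA_FOOTPRINTS = {1: (9, 9), 2: (5, 8), 4: (4, 5), 9: (3, 3)}

Scenario = Tuple[str, SimulationConfig]


def _steps_for(config: SimulationConfig, base_steps: int) -> int:
    # fast-diffusion runs spend most events on hops; scale the budget so the
    # simulated time stays comparable across D
    return base_steps * 8 if config.D > 5 else base_steps


def _sized(base: SimulationConfig, n: int, w: int, h: int,
           **kw) -> SimulationConfig:
    return base.replace(n_adhesions=n, adhesion_width=w, adhesion_height=h,
                        **kw)


def preset_size_number(base: SimulationConfig) -> List[Scenario]:
    return [
        ("one_small", _sized(base, 1, 3, 3)),
        ("nine_small", _sized(base, 9, 3, 3)),
        ("one_large", _sized(base, 1, 9, 9)),
    ]


def preset_confinement(base: SimulationConfig) -> List[Scenario]:
    out = [("r_1.00", _sized(base, 9, 3, 3, r=1.0, clump_policy="spaced"))]
    for r in (0.25, 0.09):
        out.append((f"r_{r:.2f}",
                    _sized(base, 9, 3, 3, r=r,
                           clump_policy="clumping_allowed")))
    return out


def preset_equal_area(base: SimulationConfig) -> List[Scenario]:
    out = []
    for D in (0.8, 19.0):
        for n, (w, h) in EQUAL_AREA_FOOTPRINTS.items():
            out.append((f"N{n}_D{D:g}", _sized(base, n, w, h, D=D)))
    return out


def preset_binding_rates(base: SimulationConfig) -> List[Scenario]:
    out = []
    for label, (n, w, h) in (("one_large", (1, 9, 9)),
                             ("nine_small", (9, 3, 3))):
        for rb in (10.0, 50.0):
            for ru in (0.1, 0.2):
                out.append((f"{label}_Rb{rb:g}_Ru{ru:g}",
                            _sized(base, n, w, h, Rb=rb, Ru_YAP=ru)))
    return out


BINDING_SWEEP_RB = (5.0, 10.0, 20.0, 50.0, 100.0)


def preset_binding_sweep(base: SimulationConfig) -> List[Scenario]:
    out = []
    for label, (n, w, h) in (("one_large", (1, 9, 9)),
                             ("nine_small", (9, 3, 3))):
        for rb in BINDING_SWEEP_RB:
            out.append((f"{label}_Rb{rb:g}", _sized(base, n, w, h, Rb=rb)))
    return out


TURNOVER_RU_PYAP = (0.001, 0.01, 0.1, 0.2)


def preset_turnover(base: SimulationConfig) -> List[Scenario]:
    out = []
    for rdeph in (0.035, 0.56):
        for lifetime in (None, 60.0, 135.0):
            for ru in TURNOVER_RU_PYAP:
                lab = "none" if lifetime is None else f"{lifetime:g}"
                out.append((
                    f"life_{lab}_RuP{ru:g}_Rdeph{rdeph:g}",
                    _sized(base, 9, 3, 3, lifetime=lifetime, Ru_pYAP=ru,
                           Rdeph=rdeph)))
    return out


PRESETS = {
    "size-number": preset_size_number,
    "confinement": preset_confinement,
    "equal-area": preset_equal_area,
    "binding-rates": preset_binding_rates,
    "binding-sweep": preset_binding_sweep,
    "turnover": preset_turnover,
}


def _scenario_row(label: str, cfg: SimulationConfig,
                  rep: ReplicateResult) -> dict:
    layout = rep.results[0].state.layout
    return {
        "scenario": label,
        "n_adhesions": cfg.n_adhesions,
        "adhesion_width": cfg.adhesion_width,
        "adhesion_height": cfg.adhesion_height,
        "D": cfg.D, "Rb": cfg.Rb, "Ru_YAP": cfg.Ru_YAP,
        "Ru_pYAP": cfg.Ru_pYAP, "Rdeph": cfg.Rdeph, "r": cfg.r,
        "lifetime": cfg.lifetime if cfg.lifetime is not None else "none",
        "steps": cfg.steps,
        "seed": cfg.seed,
        "replicates": len(rep.results),
        "realized_area_um2": rep.results[0].realized_adhesion_area,
        "avg_pairwise_distance_um": average_pairwise_distance(layout),
        "ratio_mean": rep.mean, "ratio_sd": rep.sd,
        "ratio_inside_mean": rep.inside_mean,
        "ratio_inside_sd": rep.inside_sd,
        "ratio_outside_mean": rep.outside_mean,
        "ratio_outside_sd": rep.outside_sd,
    }


def run_preset(name: str, out_dir, base: Optional[SimulationConfig] = None,
               seed: int = 0, full: bool = False,
               steps: Optional[int] = None, replicates: int = 3,
               write_series: bool = True) -> Dict:
    """Run every scenario of a preset and write sweep CSV + JSON summary.

    Deterministic under a fixed ``seed``: replicate i of every scenario uses
    seed + i plus fresh random adhesion positions.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from "
                       f"{', '.join(sorted(PRESETS))}")
    base = SimulationConfig() if base is None else base
    base_steps = steps if steps is not None else (
        FULL_STEPS if full else DESK_STEPS)
    out_dir = Path(out_dir) / name
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "series").mkdir(exist_ok=True)

    rows = []
    summaries = {}
    for label, cfg in PRESETS[name](base):
        cfg = cfg.replace(seed=seed, replicates=replicates,
                          steps=_steps_for(cfg, base_steps))
        logger.info("preset %s / %s: %d steps x %d replicates",
                    name, label, cfg.steps, replicates)
        rep = run_replicates(cfg)
        rows.append(_scenario_row(label, cfg, rep))
        summaries[label] = {
            "config": cfg.to_dict(),
            "ratio_mean": rep.mean, "ratio_sd": rep.sd,
            "ratio_replicates": rep.ss_means.tolist(),
            "counters": [r.counters for r in rep.results],
            "n_turnovers": [r.n_turnovers for r in rep.results],
        }
        if write_series:
            for r in rep.results:
                fn = out_dir / "series" / f"{label}_seed{r.seed}.csv"
                r.series.to_dataframe().to_csv(fn, index=False)

    table = pd.DataFrame(rows)
    summary: Dict = {"preset": name, "seed": seed,
                     "steps_base": base_steps, "scenarios": summaries}

    if name == "binding-sweep":
        fits = {}
        for size in ("one_large", "nine_small"):
            sub = table[table.scenario.str.startswith(size)]
            fit = fit_hill(sub.Rb.values, sub.ratio_mean.values)
            fits[size] = {"k1": fit.k1, "k2": fit.k2,
                          "residual_ss": fit.residual_ss}
        summary["hill_fits"] = fits

    table.to_csv(out_dir / "sweep.csv", index=False)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
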