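"""Report generation: run the full pipeline on a model and write tables.

Monetary values are carried at full precision internally; rendered tables
round costs to 2 decimals and QALYs to 2 decimals.  Report files are a pure
function of (configuration, seed) — no timestamps or environment state.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .config import config_hash
from .model import DecisionModel
from .sensitivity import ceac, ceac_frame, quadrant_summary, run_psa, tornado, tornado_frame

DISPLAY_DECIMALS = 2


def base_case_frame(model: DecisionModel) -> pd.DataFrame:
    """Table-style base-case comparison: strategy, cost, dCost, QALY, dQALY, NMB."""
    outs = model.outcomes()
    cmp_ = model.base_case()
    rows = []
    for strat in (model.intervention, model.reference):
        out = outs[strat]
        is_int = strat == model.intervention
        rows.append(
            {
                "strategy": strat,
                "cost": round(out.expected_cost, DISPLAY_DECIMALS),
                "delta_cost": round(cmp_.delta_cost, DISPLAY_DECIMALS) if is_int else None,
                "qaly": round(out.expected_qaly, DISPLAY_DECIMALS),
                "delta_qaly": round(cmp_.delta_qaly, DISPLAY_DECIMALS) if is_int else None,
                "nmb": round(
                    cmp_.nmb_intervention if is_int else cmp_.nmb_reference,
                    DISPLAY_DECIMALS,
                ),
            }
        )
    return pd.DataFrame(rows)


def run_report(
    model: DecisionModel,
    seed: int,
    n_psa: Optional[int] = None,
    outdir: Optional[Path] = None,
    plots: bool = False,
) -> dict:
    """Base case + tornado + PSA + CEAC; returns the summary and optionally
    writes base_case.csv, tornado.csv, psa_draws.csv, ceac.csv,
    psa_summary.json and metadata.json into ``outdir``."""
    n = n_psa if n_psa is not None else model.n_psa

    comparison = model.base_case()
    base_frame = base_case_frame(model)
    entries = tornado(model, model.dsa_fraction)
    psa = run_psa(model, n=n, seed=seed)
    quadrants = quadrant_summary(psa)
    grid = model.default_wtp_grid()
    curve = ceac(psa, grid)

    summary = {
        "base_case": {
            "verdict": comparison.icer_status,
            "delta_cost": comparison.delta_cost,
            "delta_qaly": comparison.delta_qaly,
            "delta_qaly_rounded": round(comparison.delta_qaly, DISPLAY_DECIMALS),
            "icer": comparison.icer_value,
            "nmb": {
                model.intervention: comparison.nmb_intervention,
                model.reference: comparison.nmb_reference,
            },
            "inmb": comparison.inmb,
        },
        "psa": {
            "n": n,
            "seed": seed,
            "quadrants": {
                "gain_save": quadrants.gain_save,
                "gain_cost": quadrants.gain_cost,
                "loss_save": quadrants.loss_save,
                "loss_cost": quadrants.loss_cost,
            },
            "proportion_cost_saving": quadrants.gain_save + quadrants.loss_save,
            "proportion_cost_effective_at_wtp": quadrants.cost_effective,
            "mean_inmb": float(psa.inmb.mean()),
            "mean_delta_cost": float(psa.delta_cost.mean()),
            "mean_delta_qaly": float(psa.delta_qaly.mean()),
            "clamp_counts": psa.clamp_counts,
        },
        "metadata": run_metadata(model, seed, n),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        base_frame.to_csv(outdir / "base_case.csv", index=False)
        tornado_frame(entries).to_csv(outdir / "tornado.csv", index=False)
        psa.table().to_csv(outdir / "psa_draws.csv", index=False)
        ceac_frame(curve).to_csv(outdir / "ceac.csv", index=False)
        (outdir / "psa_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        (outdir / "metadata.json").write_text(
            json.dumps(summary["metadata"], indent=2) + "\n"
        )
        if plots:
            from . import plots as _plots

            _plots.ce_plane(psa, outdir / "ce_plane.png")
            _plots.tornado_plot(entries, outdir / "tornado.png")
            _plots.ceac_plot(curve, model.wtp, outdir / "ceac.png")
    return summary


def run_metadata(model: DecisionModel, seed: int, n: int) -> dict:
    """Everything needed to reproduce a run: config hash, seed, n, versions."""
    import numpy

    return {
        "model": model.name,
        "config_sha256": config_hash(model),
        "seed": seed,
        "n_psa": n,
        "wtp": model.wtp,
        "horizon": model.horizon,
        "parameterization": "method of moments",
        "qaly_scale": "utility scale over the model horizon (no annualization)",
        "versions": {"qalytree": __version__, "numpy": numpy.__version__},
    }
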