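"""Stage-wise pipeline chaining the full workflow on synthetic inputs.

Stages, in dependency order::

    generate -> mass -> monod-fit -> yield -> balance -> batch-sim

``generate`` writes synthetic tracks, phase images and batch series to the
output directory; each later stage reads its predecessors' artifacts from
there, and a JSON run report records parameters, seeds and per-stage row
counts.  Stage lists must form a prefix of the dependency order (``mass``
alone is fine; ``yield`` without the earlier stages is an error).
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from picophys import qpi, synthetic, kinetics, stoichiometry, batch
from picophys.config import RunConfig

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("generate", "mass", "monod-fit", "yield", "balance", "batch-sim")

log = logging.getLogger("picophys")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _info(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stage prefix; returns the JSON-able run report.

    Raises
    ------
    ValueError
        If the stage list is not a prefix of the dependency order, or an
        upstream artifact a stage needs is missing.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    if tuple(stages) != STAGES[:len(stages)]:
        missing = [s for s in STAGES[:len(stages)] if s not in stages]
        raise ValueError(
            f"stages must form a prefix of {STAGES}; missing {missing}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {},
                    "config": {k: v for k, v in cfg.__dict__.items()}}

    def need(name: str) -> Path:
        p = out / name
        if not p.exists():
            raise ValueError(f"missing upstream output {name}; "
                             "run the earlier stages first")
        return p

    for stage in stages:
        if stage == "generate":
            gen = synthetic.GeneratorConfig(seed=cfg.seed,
                                            frame_interval=cfg.frame_interval_mm_min)
            tracks = synthetic.simulate_mother_machine_tracks(gen)
            tracks.to_csv(out / "tracks.csv", index=False)
            rng = np.random.default_rng(cfg.seed + 1)
            cells = [synthetic.CellSpec(
                length=float(rng.uniform(2.0, 4.0)),
                width=float(rng.uniform(0.8, 1.0)),
                density=float(rng.uniform(0.13, 0.28)),
                refraction_increment=cfg.refraction_increment_cell,
                position=(float(rng.uniform(3, 8.5)), float(rng.uniform(3, 8.5))),
                orientation=float(rng.uniform(0, np.pi)))
                for _ in range(3)]
            img = synthetic.render_phase_image(cells, cfg.pixel_size_um,
                                               (256, 256), noise_sd=0.002,
                                               rng=rng)
            qpi.write_phase_tiff(img, out / "phase.tif")
            series = synthetic.simulate_picoliter_batch(
                s0_mass=1.0 * cfg.reactor_volume_pL,
                reactor_volume=cfg.reactor_volume_pL,
                chamber_height=cfg.chamber_height_um,
                dt=cfg.frame_interval_plb_min, seed=cfg.seed + 2)
            series.to_csv(out / "batch_series.csv", index=False)
            report["stages"]["generate"] = {
                "tracks_rows": len(tracks), "batch_rows": len(series)}
            _info(stage, f"wrote {len(tracks)} track rows")
        elif stage == "mass":
            img = qpi.read_phase_tiff(need("phase.tif"))
            records = qpi.measure_cells(img)
            frame = qpi.records_to_frame(records)
            frame.to_csv(out / "mass.csv", index=False)
            report["stages"]["mass"] = {"cells": len(frame)}
            _info(stage, f"measured {len(frame)} cells")
        elif stage == "monod-fit":
            tracks = pd.read_csv(need("tracks.csv"))
            model = kinetics.MonodModel.from_dataframe(
                tracks, cfg.frame_interval_mm_min)
            res = model.fit()
            res.to_frame().to_csv(out / "monod_fit.csv", index=False)
            (out / "monod_fit.json").write_text(
                res.to_frame().to_json(orient="records", indent=2))
            report["stages"]["monod-fit"] = {
                "mu_max_per_h": res.mean.mu_max, "ks_ug_per_L": res.mean.ks_ug_L,
                "r2": res.mean.fit_r2}
            _info(stage, f"mu_max={res.mean.mu_max:.3f} /h, "
                         f"KS={res.mean.ks_ug_L:.0f} ug/L")
        elif stage == "yield":
            need("mass.csv")
            series = pd.read_csv(need("batch_series.csv"))
            density = float(pd.read_csv(out / "mass.csv")["density_pg_um3"].mean())
            geom = stoichiometry.ReactorGeometry(
                cfg.chamber_width_um, cfg.chamber_length_um,
                cfg.chamber_height_um, cfg.reactor_volume_pL)
            s0 = stoichiometry.initial_substrate_mass(1.0, geom)
            recs = stoichiometry.yields_from_batch_series(
                {0: series}, {0: s0}, density, geom)
            stoichiometry.yield_records_to_frame(recs).to_csv(
                out / "yields.csv", index=False)
            report["stages"]["yield"] = {"chambers": len(recs),
                                         "y_xs": recs[0].y_xs}
            _info(stage, f"Y_X,S={recs[0].y_xs:.3f} g/g")
        elif stage == "balance":
            fit = pd.read_csv(need("monod_fit.csv"))
            yields = pd.read_csv(need("yields.csv"))
            mu_max = float(fit.loc[fit["variant"] == "mean", "mu_max_per_h"].iloc[0])
            ks = float(fit.loc[fit["variant"] == "mean", "ks_g_per_L"].iloc[0])
            mu = kinetics.monod_mu(1.0, kinetics.MonodParams(mu_max, ks))
            y_xs = float(yields["y_xs"].iloc[0])
            stoich = stoichiometry.close_stoichiometry(
                mu, y_xs, cfg.m_x_cmol, cfg.m_s_cmol)
            (out / "stoichiometry.json").write_text(stoich.to_json())
            report["stages"]["balance"] = json.loads(stoich.to_json())
            _info(stage, f"Y_P,S={stoich.y_ps:.3f} Cmol/Cmol")
        elif stage == "batch-sim":
            fit = pd.read_csv(need("monod_fit.csv"))
            stoich_d = json.loads(need("stoichiometry.json").read_text())
            tracks = pd.read_csv(need("tracks.csv"))
            mu_max = float(fit.loc[fit["variant"] == "mean", "mu_max_per_h"].iloc[0])
            dist = kinetics.ks_distribution(
                kinetics.tracks_from_frame(tracks), mu_max,
                cfg.frame_interval_mm_min)
            model = batch.BatchModel(
                kinetics.MonodParams(mu_max, dist.mean),
                stoichiometry.StoichiometrySet(**stoich_d))
            trajs = model.simulate_ensemble(
                dist, batch.BatchState(x=1e-4, s=1.0), t_end=20.0,
                n_members=50, seed=cfg.seed + 3)
            pd.concat([tr.to_frame() for tr in trajs]).to_csv(
                out / "ensemble.csv", index=False)
            batch.phenotype_space_summary(trajs).to_csv(
                out / "envelopes.csv", index=False)
            (out / "model_spec.json").write_text(model.spec_json())
            report["stages"]["batch-sim"] = {"members": len(trajs)}
            _info(stage, f"simulated {len(trajs)} phenotypes")
    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
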