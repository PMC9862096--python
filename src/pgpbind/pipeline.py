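"""End-to-end analysis pipeline: partition fit -> cycle closure -> dose-response scan.

Orders the stages the way the study is read: partition titrations give the
whole-membrane coefficient, the volume-weighted closure splits it into
bilayer and protein parts, the local-concentration bookkeeping qualifies the
assay conditions, and the dose-response scan re-analyses ATPase or IAAP data
in terms of the intrinsic microscopic constant for each candidate site count.
All outputs embed the configuration hash and seed, and a Markdown report ties
the pieces together.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as pio
from .binding import build_binding_model
from .config import AnalysisConfig
from .fitting import FitResult, ModelSpec, ScanResult, profile_confidence, scan_site_count
from .partition import PartitionCoefficientSet, check_aggregation, close_cycle, distribute_dilute
from .speciation import solve_speciation
from .titration import PartitionFit, fit_partition_titration

log = logging.getLogger("pgpbind")


@dataclass
class ReportBundle:
    """Paths and in-memory results produced by :func:`run_pipeline`."""

    out_dir: Path
    partition_fit: Optional[PartitionFit]
    kp_set: Optional[PartitionCoefficientSet]
    scan: Optional[ScanResult]
    best_fit: Optional[FitResult]
    report_path: Path


def run_pipeline(config: AnalysisConfig, out_dir: str | Path, seed: int = 0) -> ReportBundle:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = pio.config_hash(config)
    prep = config.preparation.build()
    amph = config.amphiphile.build()
    scenario = config.assay.partition_scenario
    sections: list[str] = [
        "# pgpbind analysis report",
        f"- amphiphile: {amph.id}",
        f"- config hash: `{chash}`",
        f"- seed: {seed}",
    ]

    # --- stage 1: partition titration -> whole-membrane KP -----------------
    partition_fit = None
    kp_set = None
    if config.titration_csv:
        data = pio.read_titration_csv(config.titration_csv, amphiphile_id=amph.id)
        log.info("stage=fit-partition input=%s hash=%s", config.titration_csv, chash)
        partition_fit = fit_partition_titration(data, prep, scenario=scenario)
        fit_doc = {
            "log_kp": partition_fit.log_kp,
            "f_water": partition_fit.f_water,
            "f_membrane": partition_fit.f_membrane,
            "ci75": list(partition_fit.ci75),
            "residual_norm": partition_fit.residual_norm,
            "scenario": partition_fit.scenario,
            "provenance": {"config_hash": chash, "seed": seed},
        }
        (out / "partition_fit.json").write_text(json.dumps(fit_doc, indent=2) + "\n")
        sections += [
            "## Partition titration",
            f"- Log10 KP(W->M) = {partition_fit.log_kp:.3f} "
            f"(75% CI {partition_fit.ci75[0]:.3f} .. {partition_fit.ci75[1]:.3f})",
            f"- amplitudes F_W = {partition_fit.f_water:.1f}, F_M = {partition_fit.f_membrane:.1f}",
        ]
        kp_w_m = partition_fit.kp
    else:
        kp_w_m = None

    # --- stage 2: thermodynamic-cycle closure ------------------------------
    if kp_w_m is not None:
        kp_set = close_cycle(kp_w_m, config.assay.kp_w_lb, prep, scenario)
        row = pd.DataFrame(
            [
                {
                    "amphiphile": amph.id,
                    "scenario": scenario,
                    "kp_w_m": kp_set.kp_w_m,
                    "kp_w_lb": kp_set.kp_w_lb,
                    "kp_w_p": kp_set.kp_w_p,
                    "kp_lb_p": kp_set.kp_lb_p,
                }
            ]
        )
        row.to_csv(out / "partition_coefficients.csv", index=False)
        dist = distribute_dilute(kp_set, prep, total_ligand=50e-6)
        agg = check_aggregation(amph, dist.conc_water)
        sections += [
            "## Partition coefficients (cycle closure)",
            "```\n" + row.to_string(index=False) + "\n```",
            "## Local-concentration bookkeeping (50 uM total)",
            f"- fraction in water / bilayer / protein: "
            f"{dist.frac_water:.3f} / {dist.frac_bilayer:.3f} / {dist.frac_protein:.3f}",
            f"- PL:ligand mole ratio in the bilayer: {dist.pl_to_ligand:.1f}",
            f"- aqueous concentration {dist.conc_water * 1e6:.2f} uM; "
            f"aggregation flag: {agg.flag} (margin {agg.margin if agg.margin is None else round(agg.margin, 2)})",
        ]

    # --- stage 3: speciation sweep -----------------------------------------
    vf = prep.volume_fractions()
    model = build_binding_model(config.fit.n_max, 5e-6)
    sweep_l = np.linspace(0.0, 50e-6, 26)
    rows = []
    for lt in sweep_l:
        st = solve_speciation(lt, prep.pgp_conc, config.assay.kp_w_lb, vf.v_lb, model)
        rows.append(
            {
                "l_total_uM": lt * 1e6,
                "l_water_uM": st.l_water * 1e6,
                "l_bilayer_uM": st.l_bilayer * 1e6,
                "bound_uM": st.bound_ligand * 1e6,
                "mean_occupancy": st.mean_occupancy,
            }
        )
    pd.DataFrame(rows).to_csv(out / "speciation_sweep.csv", index=False)
    log.info("stage=speciate points=%d hash=%s", len(rows), chash)

    # --- stage 4: dose-response scan ---------------------------------------
    scan = None
    best = None
    if config.dose_response_csv:
        points = pio.read_dose_response_csv(config.dose_response_csv)
        spec = ModelSpec(
            kind=config.assay.kind,
            n_sites=config.fit.n_min,
            p_total=prep.pgp_conc,
            kp_w_lb=config.assay.kp_w_lb,
            v_lb=vf.v_lb,
            assay=config.assay.build_iaap() if config.assay.kind == "iaap" else None,
            pgp_molar_volume=prep.pgp_molar_volume,
        )
        log.info(
            "stage=scan-n kind=%s n=%d..%d hash=%s",
            config.assay.kind, config.fit.n_min, config.fit.n_max, chash,
        )
        scan = scan_site_count(points, spec, n_max=config.fit.n_max, weighted=config.fit.weighted)
        pio.write_scan_csv(out / "site_count_scan.csv", scan)
        best_n = scan.best_n()
        best = scan.fits[best_n - 1]
        from dataclasses import replace

        profile_confidence(points, replace(spec, n_sites=best_n), best, "log10_kd",
                           level=config.fit.ci_level, weighted=config.fit.weighted)
        pio.write_fit_json(out / "best_fit.json", best, config=config, seed=seed)
        sections += [
            f"## Dose-response scan ({config.assay.kind})",
            "```\n"
            + scan.table.assign(kd_uM=scan.table.kd * 1e6)[
                ["n", "chi2", "kd_uM", "kp_beta1", "success"]
            ].to_string(index=False)
            + "\n```",
            f"- best n = {best_n}, Kd = {best.kd * 1e6:.2f} uM, chi2 = {best.chi2:.4g}",
            f"- Log10 Kd 75% profile CI: {best.ci75['log10_kd'][0]:.3f} .. {best.ci75['log10_kd'][1]:.3f}",
        ]

    report_path = out / "report.md"
    report_path.write_text("\n\n".join(sections) + "\n")
    return ReportBundle(
        out_dir=out,
        partition_fit=partition_fit,
        kp_set=kp_set,
        scan=scan,
        best_fit=best,
        report_path=report_path,
    )
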