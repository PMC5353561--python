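"""End-to-end pipeline: simulate -> deg -> response -> aberrancy -> trends -> report.

A single YAML config drives all stages::

    seed: 1
    analysis:        # PipelineConfig fields (thresholds, test variants)
      fc_threshold: 1.2
      alpha: 0.05
    synth:           # SynthConfig fields (generator settings)
      n_genes: 800

All randomness flows from the top-level seed through per-stage derived
streams.  Every stage writes TSV outputs into the run directory; the run
manifest records the config echo, the seed, per-stage row counts and a
sha256 digest of every output file, so a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import deg_calling, evolution_trends, set_response, synthetic_data, tu_aberrancy
from ._utils import sha256_file
from .data_model import (
    DEGTable,
    PipelineConfig,
    read_contrasts,
    read_expression_study,
    read_gene_sets,
    read_network,
    write_deg_table,
)

logger = logging.getLogger("regustress")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def load_run_config(path: str | Path) -> tuple[int, PipelineConfig, synthetic_data.SynthConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"seed", "analysis", "synth"}
    if unknown:
        raise PipelineError(f"invalid config key {sorted(unknown)[0]!r}")
    seed = int(raw.get("seed", 0))
    analysis = PipelineConfig(**(raw.get("analysis") or {}), seed=seed)
    synth = synthetic_data.SynthConfig(**(raw.get("synth") or {}), seed=seed)
    return seed, analysis, synth


def _params(analysis: PipelineConfig) -> deg_calling.DEGParams:
    return deg_calling.DEGParams(
        fc_threshold=analysis.fc_threshold,
        alpha=analysis.alpha,
        ea_min_mean_rel_diff=analysis.ea_min_mean_rel_diff,
        detection_threshold=analysis.detection_threshold,
        rank_test=analysis.rank_test,
    )


def run_pipeline(config_path: str | Path, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed, analysis, synth = load_run_config(config_path)
    params = _params(analysis)
    counts: dict[str, int] = {}
    warnings_log: list[str] = []

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        network, sets, nea, ea = synthetic_data.generate_all(synth, seed=seed)
        fixtures = outdir / "fixtures"
        synthetic_data.write_fixtures(fixtures, synth, network, sets, nea, ea, seed=seed)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    logger.info("stage %s: fixtures written to %s", stage, fixtures)

    # --- deg (reads the written fixtures back through the public readers) --
    stage = "deg"
    try:
        nea_study = read_expression_study(
            fixtures / "nea_matrix.tsv", fixtures / "nea_metadata.tsv"
        )
        contrasts = read_contrasts(fixtures / "contrasts.tsv")
        ea_study = read_expression_study(
            fixtures / "ea_matrix.tsv", fixtures / "ea_metadata.tsv"
        )
        all_sets = read_gene_sets(
            fixtures / "gene_sets.gmt", fixtures / "gene_set_directions.tsv"
        )
        network = read_network(fixtures / "network.tsv")
    except Exception as exc:
        raise PipelineError(
            f"stage {stage!r} failed reading fixtures in {fixtures}: {exc}"
        ) from exc
    nea_deg = DEGTable.concat(
        [deg_calling.call_deg_nea(nea_study, c, params) for c in contrasts]
    )
    write_deg_table(nea_deg, outdir / "deg_nea.tsv")
    counts["deg_nea"] = len(nea_deg)

    meta = ea_study.metadata
    timepoints = sorted(
        int(t) for t in meta.loc[meta["condition"] == "evolved", "time_h"].dropna().unique() if t > 0
    )
    ea_tables = []
    for t in timepoints:
        evolved = list(meta[(meta["condition"] == "evolved") & (meta["time_h"] == t)].index)
        ea_tables.append(
            deg_calling.call_deg_ea(
                ea_study, "parent", evolved, params, contrast_name=f"ea_h{t}"
            )
        )
    ea_deg = DEGTable.concat(ea_tables)
    write_deg_table(ea_deg, outdir / "deg_ea.tsv")
    counts["deg_ea"] = len(ea_deg)

    # --- response ---------------------------------------------------------
    stage = "response"
    try:
        profile = set_response.set_deg_proportions(nea_deg, all_sets)
        profile.to_csv(outdir / "response_profile.tsv", sep="\t", index=False)
        counts["response_profile"] = len(profile)
        ethanol = {c.name: c.ethanol_pct for c in contrasts}
        corr_rows = []
        for s in all_sets:
            levels = set_response.set_response_level(
                nea_study, nea_deg, s.genes, "prop_up_minus_down"
            )
            levels = levels.reindex([c.name for c in contrasts])
            cov = [ethanol[c] for c in levels.index]
            if levels.notna().sum() >= 3:
                res = set_response.correlate_with_covariate(
                    levels.to_numpy(), cov, method=analysis.correlation_method
                )
                corr_rows.append(
                    {
                        "set": s.name,
                        "covariate": "ethanol_pct",
                        "method": res.method,
                        "n": res.n,
                        "r": res.r,
                        "defined": res.defined,
                    }
                )
        pd.DataFrame(corr_rows).to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        counts["correlations"] = len(corr_rows)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- aberrancy --------------------------------------------------------
    stage = "aberrancy"
    try:
        per_tf, per_tu = tu_aberrancy.aberrancy_report(
            network, nea_deg, rule=analysis.tu_rule
        )
        per_tf.to_csv(outdir / "aberrancy_tf.tsv", sep="\t", index=False)
        per_tu.to_csv(outdir / "aberrancy_tu.tsv", sep="\t", index=False)
        counts["aberrancy_tf"] = len(per_tf)
        counts["aberrancy_tu"] = len(per_tu)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- trends -----------------------------------------------------------
    stage = "trends"
    try:
        trends = evolution_trends.build_trend_table(
            ea_study,
            "parent",
            detection_threshold=analysis.detection_threshold,
            tie_tolerance=analysis.tie_tolerance,
        )
        trends.to_csv(outdir / "trends.tsv", sep="\t", index=False)
        counts["trends"] = len(trends)
        tallies = evolution_trends.trend_tallies(trends)
        tallies.to_csv(outdir / "trend_tallies.tsv", sep="\t", index=False)
        conc = evolution_trends.concordance_with_annotation(trends, all_sets, deg=ea_deg)
        tol = all_sets["tolerance"] if "tolerance" in all_sets.sets else None
        if tol is not None:
            prof = evolution_trends.stepwise_pathway_profile(trends, tol.genes)
            prof.rename_axis("time_h").rename("mean_lfc").to_frame().to_csv(
                outdir / "pathway_profile.tsv", sep="\t"
            )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- report -----------------------------------------------------------
    stage = "report"
    summary = {
        "seed": seed,
        "config": {
            "analysis": dataclasses.asdict(analysis),
            "synth": dataclasses.asdict(synth),
        },
        "row_counts": counts,
        "concordance_pct": None if not conc.defined else round(conc.percent, 4),
        "concordance_n": conc.n,
        "concordance_per_strain": {k: round(v, 4) for k, v in conc.per_strain.items()},
        "warnings": warnings_log,
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    build_report(outdir)

    manifest = dict(summary)
    manifest["digests"] = {
        str(p.relative_to(outdir)): sha256_file(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def build_report(outdir: str | Path) -> list[Path]:
    """Derive summary report tables from the stage TSVs alone.

    Every number in a report table is recomputable from the stage outputs;
    percentages use the shared half-away-from-zero convention.
    """
    from ._utils import pct_display

    outdir = Path(outdir)
    written: list[Path] = []

    profile_path = outdir / "response_profile.tsv"
    if not profile_path.exists():
        raise PipelineError("stage 'report' failed: missing response_profile.tsv")
    profile = pd.read_csv(profile_path, sep="\t")
    heat = profile[profile["defined"]].assign(
        pct_deg=lambda d: [
            pct_display((u + dn) / n) for u, dn, n in
            zip(d["n_up"], d["n_down"], d["n_in_set_expressed"])
        ]
    )[["set", "contrast", "pct_up", "pct_down", "pct_deg"]]
    path = outdir / "report_set_response.tsv"
    heat.to_csv(path, sep="\t", index=False)
    written.append(path)

    tf_path = outdir / "aberrancy_tf.tsv"
    if tf_path.exists():
        per_tf = pd.read_csv(tf_path, sep="\t")
        path = outdir / "report_aberrancy.tsv"
        per_tf[
            ["tf", "contrast", "n_sole_regulator_tus", "n_scored", "n_aberrant",
             "percent_aberrant"]
        ].to_csv(path, sep="\t", index=False)
        written.append(path)
    else:
        logger.warning("report: aberrancy stage output missing; section omitted")

    tallies_path = outdir / "trend_tallies.tsv"
    if tallies_path.exists():
        tallies = pd.read_csv(tallies_path, sep="\t")
        path = outdir / "report_trends.tsv"
        tallies.to_csv(path, sep="\t", index=False)
        written.append(path)
    else:
        logger.warning("report: trends stage output missing; section omitted")
    return written
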