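"""End-to-end orchestration: config validation, staged runs, figures.

A run executes simulate -> screen -> dose -> biomarker -> splicing ->
iralu with all randomness flowing from named per-stage seeds, writes each
stage's outputs under a run directory, and aggregates the headline
numbers (hit list, AAC table, top pathways, passing-event counts by type,
IR-Alu fractions) into a JSON report.  Rerunning with the same config and
seeds reproduces every numeric field exactly.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import biomarker as bm
from . import drug_response as dr
from . import ir_alu
from . import splicing as sp
from . import synth
from .errors import ConfigError
from .io import write_tsv, write_gmt
from .models import Interval

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_all", "make_figures"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with study defaults."""

    out_dir: str = "vm_run"
    # per-stage seeds
    seed_genome: int = 11
    seed_screen: int = 12
    seed_dose: int = 13
    seed_expression: int = 14
    seed_junctions: int = 15
    seed_gsea: int = 16
    seed_diff: int = 17
    # screen
    n_compounds: int = 36
    n_lines: int = 15
    n_planted_hits: int = 6
    inhibition_threshold: float = 0.5
    line_fraction: float = 1.0 / 3.0
    # dose-response
    n_dose_lines: int = 17
    dose_noise_sd: float = 0.02
    # expression / GSEA
    n_genes: int = 1000
    signature_size: int = 50
    signature_strength: float = 0.8
    n_decoy_sets: int = 20
    weight_p: float = 1.0
    n_perm: int = 1000
    # splicing
    coverage: int = 200
    replicates: int = 3
    retained_fraction: float = 0.6
    dpsi_cut: float = 0.2
    mv_cut: float = 0.05
    min_reads: float = 10
    n_draws: int = 10000
    # genome / IR-Alu
    n_transcripts: int = 40
    ir_pair_fraction: float = 0.62
    alu_per_intron: float = 0.5
    max_gap: int = 5000
    min_alu_len: int = 100

    _RANGES = {
        "inhibition_threshold": (0.0, 1.0), "line_fraction": (0.0, 1.0),
        "dpsi_cut": (0.0, 1.0), "mv_cut": (0.0, 1.0),
        "ir_pair_fraction": (0.0, 1.0), "signature_strength": (0.0, 1.0),
        "retained_fraction": (0.0, 1.0), "alu_per_intron": (0.0, 10.0),
        "weight_p": (0.0, 2.0),
    }


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; defaults fill missing keys.

    Unknown keys are rejected with a nearest-valid-key suggestion; every
    problem found is reported at once in a single :class:`ConfigError`.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    if overrides:
        raw.update(overrides)
    valid = {f for f in RunConfig.__dataclass_fields__ if not f.startswith("_")}
    problems = []
    for key in raw:
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            problems.append(f"unknown key {key!r}{suffix}")
    cfg_kwargs = {k: v for k, v in raw.items() if k in valid}
    cfg = RunConfig(**cfg_kwargs)
    for key, (lo, hi) in RunConfig._RANGES.items():
        v = getattr(cfg, key)
        if not (lo <= v <= hi):
            problems.append(f"{key}={v} outside [{lo}, {hi}]")
    for key in ("n_compounds", "n_lines", "n_genes", "n_transcripts",
                "n_perm", "n_draws", "coverage", "replicates"):
        if getattr(cfg, key) < 1:
            problems.append(f"{key} must be >= 1")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    logger.info("resolved config: %s", asdict(cfg))
    return cfg


# ------------------------------------------------------------ stages

def _stage_dir(root: Path, name: str) -> Path:
    d = root / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_all(config: RunConfig) -> dict:
    """Execute all stages on synthetic inputs; return the run report."""
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": asdict(config),
                    "warnings": [], "stages": {}}
    stage = "simulate"
    try:
        # ---- simulate ------------------------------------------------
        sim_dir = _stage_dir(root, "simulate")
        bundle = synth.gen_genome(config.seed_genome,
                                  n_transcripts=config.n_transcripts,
                                  alu_per_intron=config.alu_per_intron,
                                  ir_pair_fraction=config.ir_pair_fraction)
        bundle.write(sim_dir)
        raw_screen, dmso, planted_hits = synth.gen_screen(
            config.seed_screen, n_compounds=config.n_compounds,
            n_lines=config.n_lines,
            planted_hits=[f"CPD{i + 1:03d}" for i in range(config.n_planted_hits)])
        write_tsv(raw_screen, sim_dir / "screen_raw.tsv")
        write_tsv(dmso, sim_dir / "screen_dmso.tsv")
        report["stages"]["simulate"] = {
            "n_transcripts": config.n_transcripts,
            "n_planted_ir_alu_introns": len(bundle.truth.planted_ir_alu_introns),
            "planted_hits": planted_hits,
        }

        # ---- screen --------------------------------------------------
        stage = "screen"
        scr_dir = _stage_dir(root, "screen")
        screen = dr.normalize_screen(raw_screen, dmso)
        hits = dr.call_hits(screen, config.inhibition_threshold,
                            config.line_fraction)
        write_tsv(screen.normalized, scr_dir / "normalized.tsv")
        write_tsv(screen.log2, scr_dir / "log2.tsv")
        hit_list = sorted(hits.index[hits["hit"]])
        (scr_dir / "hits.json").write_text(json.dumps(
            {"hits": hit_list,
             "rule": {"inhibition_threshold": config.inhibition_threshold,
                      "line_fraction": config.line_fraction}}, indent=2))
        report["stages"]["screen"] = {"n_compounds": int(len(hits)),
                                      "hits": hit_list}

        # ---- dose-response ------------------------------------------
        stage = "dose"
        dose_dir = _stage_dir(root, "dose")
        rng = np.random.default_rng(config.seed_dose)
        lines = [f"DLINE{j + 1:02d}" for j in range(config.n_dose_lines)]
        rows = []
        truth_hill = {}
        for j, line in enumerate(lines):
            ec50 = float(10 ** rng.uniform(np.log10(0.08), np.log10(5.0)))
            slope = float(rng.uniform(0.8, 2.5))
            e_inf = float(rng.uniform(0.0, 0.6))
            truth_hill[line] = (ec50, slope, e_inf)
            table = synth.gen_dose_response(config.seed_dose + 1 + j,
                                            (ec50, slope, e_inf),
                                            noise_sd=config.dose_noise_sd)
            curve = dr.DoseResponseCurve(table["dose_uM"].to_numpy(),
                                         table["viability"].to_numpy())
            fit = dr.fit_hill(curve)
            rows.append({"line": line, "aac": dr.compute_aac(curve),
                         "ec50": fit.ec50, "hill_slope": fit.hill_slope,
                         "e_inf": fit.e_inf,
                         "ic50": fit.ic50 if fit.ic50 is not None else np.nan,
                         "ic50_censored": fit.ic50_censored})
        sens_tab = pd.DataFrame(rows).set_index("line")
        write_tsv(sens_tab, dose_dir / "sensitivity.tsv")
        profile = dr.SensitivityProfile(aac=sens_tab["aac"],
                                        ic50=sens_tab["ic50"])
        report["stages"]["dose"] = {
            "n_lines": len(lines),
            "aac_range": [float(sens_tab["aac"].min()),
                          float(sens_tab["aac"].max())],
            "n_ic50_censored": int(sens_tab["ic50_censored"].sum()),
        }

        # ---- biomarker ----------------------------------------------
        stage = "biomarker"
        bio_dir = _stage_dir(root, "biomarker")
        signature = [f"ISG{i:03d}" for i in range(config.signature_size)]
        expr = synth.gen_expression(config.seed_expression, config.n_genes,
                                    profile.aac, signature,
                                    strength=config.signature_strength)
        write_tsv(expr, sim_dir / "expression.tsv")
        ranked = bm.correlate_sensitivity(expr, profile, metric="aac")
        decoy_rng = np.random.default_rng(config.seed_expression + 1)
        sets = {"PLANTED_ISG_SIGNATURE": signature}
        for d in range(config.n_decoy_sets):
            sets[f"DECOY_{d:02d}"] = decoy_rng.choice(
                expr.index.to_numpy(), size=len(signature),
                replace=False).tolist()
        write_gmt(sets, sim_dir / "gene_sets.gmt")
        gsea = bm.gsea_preranked(ranked, sets, weight_p=config.weight_p,
                                 n_perm=config.n_perm, seed=config.seed_gsea)
        top = bm.top_pathways(gsea, k=9)
        write_tsv(ranked.table, bio_dir / "ranked_genes.tsv")
        write_tsv(gsea.table, bio_dir / "gsea.tsv")
        write_tsv(top, bio_dir / "top_pathways.tsv")
        # sensitive vs resistant group summary (median AAC split)
        labels = pd.Series(np.where(profile.aac >= profile.aac.median(),
                                    "sensitive", "resistant"),
                           index=profile.aac.index)
        diff = bm.group_differential(expr, labels)
        write_tsv(diff, bio_dir / "group_differential.tsv")
        report["stages"]["biomarker"] = {
            "top_pathways": list(top.index),
            "planted_signature_rank": int(
                list(top.index).index("PLANTED_ISG_SIGNATURE") + 1
                if "PLANTED_ISG_SIGNATURE" in top.index else -1),
            "n_genes_fdr05": int((diff["fdr"] < 0.05).sum()),
            "metric": ranked.metadata["metric"],
        }

        # ---- splicing -----------------------------------------------
        stage = "splicing"
        spl_dir = _stage_dir(root, "splicing")
        events = synth.events_from_genome(bundle,
                                          retained_fraction=config.retained_fraction,
                                          seed=config.seed_junctions)
        counts = synth.gen_junction_counts(config.seed_junctions, events,
                                           coverage=config.coverage,
                                           replicates=config.replicates)
        write_tsv(counts, sim_dir / "junction_counts.tsv", index=False)
        diff_rows = analyze_junction_table(
            counts, bundle, n_draws=config.n_draws, seed=config.seed_diff,
            dpsi_cut=config.dpsi_cut, mv_cut=config.mv_cut,
            min_reads=config.min_reads)
        write_tsv(diff_rows, spl_dir / "diff_splice.tsv", index=False)
        summary = sp.summarize_events(diff_rows)
        (spl_dir / "summary.json").write_text(json.dumps(
            {k: v for k, v in summary.items() if k != "retained_introns"},
            indent=2))
        report["stages"]["splicing"] = {
            "n_events": int(len(diff_rows)),
            "n_events_passing": summary["n_events_passing"],
            "n_genes_passing": summary["n_genes_passing"],
            "counts_by_type": summary["counts_by_type"],
            "orf_labels": diff_rows[diff_rows["passes"]]["orf_label"]
            .value_counts().to_dict(),
        }

        # ---- iralu ---------------------------------------------------
        stage = "iralu"
        ir_dir = _stage_dir(root, "iralu")
        passing = summary["retained_introns"]
        not_passing = [d for d in bundle.retained_introns
                       if d["intron_id"] not in {p["event_id"] for p in passing}]
        rep_a = ir_alu.iralu_summary(
            [dict(p, transcript_id=p.get("transcript_id")) for p in passing],
            bundle.repeats, bundle.transcripts,
            max_gap=config.max_gap, min_len=config.min_alu_len)
        rep_b = ir_alu.iralu_summary(
            not_passing, bundle.repeats, bundle.transcripts,
            max_gap=config.max_gap, min_len=config.min_alu_len)
        comparison = ir_alu.compare_conditions(rep_a, rep_b)
        (ir_dir / "iralu_report.json").write_text(json.dumps(
            {"retained_passing": _strip(rep_a), "retained_not_passing": _strip(rep_b),
             "comparison": comparison}, indent=2))
        report["stages"]["iralu"] = {
            "n_retained_introns": rep_a["n_introns"],
            "n_with_iralu": rep_a["n_introns_with_iralu"],
            "fraction_with_iralu": rep_a["fraction_with_iralu"],
            "fraction_bidirectional": rep_a["fraction_bidirectional"],
            "category_counts": rep_a["category_counts"],
        }
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        report["failed_stage"] = stage
        (root / "report.json").write_text(json.dumps(report, indent=2,
                                                     default=str))
        raise

    (root / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (root / "report.txt").write_text(_render_text(report))
    return report


def _strip(rep: dict) -> dict:
    return {k: v for k, v in rep.items() if k != "per_intron"}


def analyze_junction_table(counts: pd.DataFrame, bundle: synth.GenomeBundle | None,
                           n_draws: int = 10000, seed: int = 0,
                           dpsi_cut: float = 0.2, mv_cut: float = 0.05,
                           min_reads: float = 10) -> pd.DataFrame:
    """Differential splicing + classification over a junction-count table.

    One seeded generator drives all events in row order, so results are
    reproducible for the table as a whole.
    """
    ctrl_cols = sorted(c[:-4] for c in counts.columns if c.startswith("ctrl") and c.endswith("_inc"))
    trt_cols = sorted(c[:-4] for c in counts.columns if c.startswith("trt") and c.endswith("_inc"))
    tx_by_id = {t.transcript_id: t for t in (bundle.transcripts if bundle else [])}
    seq = next(iter(bundle.sequences.values())) if bundle else None
    rng = np.random.default_rng(seed)
    rows = []
    for row in counts.itertuples():
        control = [(getattr(row, f"{s}_inc"), getattr(row, f"{s}_exc"))
                   for s in ctrl_cols]
        treated = [(getattr(row, f"{s}_inc"), getattr(row, f"{s}_exc"))
                   for s in trt_cols]
        res = sp.diff_splice(control, treated,
                             n_inc_junc=int(row.n_inc_junc),
                             n_exc_junc=int(row.n_exc_junc),
                             n_draws=n_draws, rng=rng, dpsi_cut=dpsi_cut,
                             mv_cut=mv_cut, min_reads=min_reads)
        orf_label = None
        tx = tx_by_id.get(row.transcript_id)
        if tx is not None and seq is not None and tx.has_cds:
            ev = sp.SpliceEvent(event_id=row.event_id, gene_id=row.gene_id,
                                transcript_id=row.transcript_id,
                                chrom=row.chrom, strand=row.strand,
                                segment=Interval(int(row.start), int(row.end)),
                                event_type=row.event_type)
            orf_label = sp.classify_orf_impact(ev, tx, seq).label
        rows.append({"event_id": row.event_id, "gene_id": row.gene_id,
                     "transcript_id": row.transcript_id,
                     "event_type": row.event_type, "chrom": row.chrom,
                     "strand": row.strand, "start": int(row.start),
                     "end": int(row.end), "dpsi_point": res.dpsi_point,
                     "mv95": res.mv95, "passes": res.passes,
                     "coverage_ok": res.coverage_ok,
                     "psi_control": res.psi_control,
                     "psi_treated": res.psi_treated,
                     "orf_label": orf_label})
    return pd.DataFrame(rows)


def _render_text(report: dict) -> str:
    lines = [f"vmtools run report (v{report['version']})", ""]
    for name, section in report["stages"].items():
        lines.append(f"[{name}]")
        for k, v in section.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    return "\n".join(lines)


# ------------------------------------------------------------- figures

def make_figures(run_dir: str | Path) -> list[Path]:
    """Deterministic plots + companion plot-data tables for a finished run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    report = json.loads((run_dir / "report.json").read_text())
    fig_dir = _stage_dir(run_dir, "figures")
    made = []

    def _bar(name: str, data: dict, title: str, ylabel: str):
        keys = sorted(data)
        vals = [data[k] for k in keys]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.bar(keys, vals, color="#4477aa")
        ax.set_title(title)
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        p = fig_dir / f"{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        pd.DataFrame({"category": keys, "count": vals}).to_csv(
            fig_dir / f"{name}.tsv", sep="\t", index=False)
        made.append(p)

    spl = report["stages"].get("splicing")
    if spl:
        _bar("event_type_counts", spl["counts_by_type"],
             "Passing splicing events by type", "events")
    else:
        logger.warning("no splicing section; event-type figure skipped")
    ira = report["stages"].get("iralu")
    if ira:
        _bar("pair_categories", ira["category_counts"],
             "IR-Alu pair vs retained-intron categories", "pair tests")
    else:
        logger.warning("no iralu section; pair-category figure skipped")

    diff_path = run_dir / "biomarker" / "group_differential.tsv"
    if diff_path.exists():
        diff = pd.read_csv(diff_path, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.scatter(diff["log2_fc"], -np.log10(diff["p_value"]), s=6,
                   c=np.where(diff["fdr"] < 0.05, "#cc3311", "#888888"))
        ax.set_xlabel("log2 fold change (sensitive - resistant)")
        ax.set_ylabel("-log10 p")
        ax.set_title("Group differential expression")
        fig.tight_layout()
        p = fig_dir / "volcano.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        diff.sort_index().to_csv(fig_dir / "volcano.tsv", sep="\t")
        made.append(p)

    sens_path = run_dir / "dose" / "sensitivity.tsv"
    if sens_path.exists():
        sens = pd.read_csv(sens_path, sep="\t", index_col=0).sort_values("aac")
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.bar(sens.index, sens["aac"], color="#228833")
        ax.set_ylabel("AAC")
        ax.set_title("Dose-response sensitivity (area above curve)")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        p = fig_dir / "aac.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        sens.to_csv(fig_dir / "aac.tsv", sep="\t")
        made.append(p)
    return made
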