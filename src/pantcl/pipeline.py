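"""End-to-end orchestration: simulate → collapse → panel DE → signature → TSP
→ stratify → TME → enrichment → IHC, from a single YAML-able configuration.

Every stage writes plain-text outputs into the run directory and contributes
a manifest entry (parameters, seed, summary counts, sha256 of outputs); reruns
with an identical configuration reproduce identical files. Stage seeds are
derived from the master seed by fixed offsets so stages can be toggled without
reshuffling the others.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enrichment_mod
from . import ihc as ihc_mod
from . import io, preprocess, signature, simulate, stratify, tme, tsp
from .class_comparison import MODE_KORN, DECriteria, permutation_test

logger = logging.getLogger("pantcl")

STAGES = (
    "simulate",
    "collapse",
    "panel_filter",
    "de",
    "signature",
    "tsp",
    "stratify",
    "tme",
    "enrich",
    "ihc",
)

#: Patient-level lymphoid-positivity marginals used for the default IHC
#: emulation (subtype, marker) -> (n positive, n patients).
DEFAULT_IHC_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("AITL", "BCL10"): (7, 8),
    ("AITL", "CAV1"): (5, 8),
    ("AITL", "GILZ"): (8, 8),
    ("AITL", "CD90"): (6, 8),
    ("ALCL", "BCL10"): (13, 14),
    ("ALCL", "CAV1"): (6, 14),
    ("ALCL", "GILZ"): (13, 14),
    ("ALCL", "CD90"): (5, 14),
    ("PTCL-NOS", "BCL10"): (39, 43),
    ("PTCL-NOS", "CAV1"): (25, 43),
    ("PTCL-NOS", "GILZ"): (40, 43),
    ("PTCL-NOS", "CD90"): (18, 43),
}


@dataclass
class PipelineConfig:
    outdir: str = "pantcl_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    tme_criteria: dict = field(default_factory=dict)
    min_support: int = 3
    tsp_scheme: str = "LOOCV"
    stratify_gene: str = "CAV1"
    panel_set: str = "TCELL_COMPARTMENT"
    corr_p_cutoff: float = 0.01
    corr_r_cutoff: float = 0.22
    enrich_alpha: float = 0.05
    ihc_counts: dict = field(default_factory=lambda: dict(DEFAULT_IHC_COUNTS))
    ihc_cores_per_patient: int = 2
    stages: dict[str, bool] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "ihc_counts" in raw:
            raw["ihc_counts"] = {
                (s, m): tuple(v) for (s, m), v in
                ((tuple(k.split("/")), v) for k, v in raw["ihc_counts"].items())
            }
        return cls(**raw)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    outputs: dict[str, Path] = {}

    def record(stage: str, status: str, files: dict[str, Path] | None = None, **summary):
        entry = {"status": status, "summary": summary}
        if files:
            entry["files"] = {k: str(p) for k, p in files.items()}
            entry["sha256"] = {k: _sha256(p) for k, p in files.items()}
            outputs.update(files)
        manifest["stages"][stage] = entry
        logger.info("stage %-12s %s %s", stage, status, summary or "")

    state: dict = {}
    try:
        # --- simulate -----------------------------------------------------
        if config.enabled("simulate"):
            sim_cfg = simulate.SimulationConfig(**{"seed": config.seed, **config.simulate})
            dataset = simulate.simulate_dataset(sim_cfg)
            files = simulate.write_dataset(dataset, outdir)
            state["dataset"] = dataset
            record(
                "simulate", "complete", files,
                n_probes=dataset.expression.shape[0],
                n_samples=dataset.expression.shape[1],
            )
        else:
            record("simulate", "skipped")

        # --- collapse -----------------------------------------------------
        if config.enabled("collapse") and "dataset" in state:
            dataset = state["dataset"]
            collapsed = preprocess.collapse_probes(dataset.expression, dataset.probe_map)
            path = outdir / "gene_expression.tsv"
            io.write_expression(collapsed.matrix, path, index_label="gene_symbol")
            state["gene_matrix"] = collapsed.matrix
            record("collapse", "complete", {"gene_expression": path},
                   n_genes=collapsed.matrix.shape[0])
        else:
            record("collapse", "skipped")

        # --- panel filter -------------------------------------------------
        if config.enabled("panel_filter") and "gene_matrix" in state:
            panel = state["dataset"].gene_sets[config.panel_set]
            panel_matrix = preprocess.filter_to_panel(state["gene_matrix"], panel)
            path = outdir / "panel_expression.tsv"
            io.write_expression(panel_matrix, path, index_label="gene_symbol")
            state["panel_matrix"] = panel_matrix
            record("panel_filter", "complete", {"panel_expression": path},
                   n_genes=panel_matrix.shape[0])
        else:
            record("panel_filter", "skipped")

        # --- per-subtype DE -------------------------------------------------
        if config.enabled("de") and "panel_matrix" in state:
            annotations = state["dataset"].annotations
            criteria = DECriteria(**config.de)
            per_subtype = {}
            files = {}
            healthy = annotations.index[annotations["class"] == io.CLASS_HEALTHY]
            for i, subtype in enumerate(sorted(set(annotations["subtype"]) - {"CD4", "CD8"})):
                cols = annotations.index[annotations["subtype"] == subtype]
                sub = state["panel_matrix"][list(healthy) + list(cols)]
                labels = annotations.loc[sub.columns, "class"]
                de = permutation_test(
                    sub, labels, criteria=criteria,
                    seed=config.seed + 1000 + i, reference=io.CLASS_HEALTHY,
                )
                per_subtype[subtype] = de
                path = outdir / f"de_{subtype.replace('-', '')}.tsv"
                de.table.to_csv(path, sep="\t", index_label="gene")
                files[f"de_{subtype}"] = path
            state["per_subtype_de"] = per_subtype
            record("de", "complete", files,
                   n_significant={s: int(r.table["significant"].sum())
                                  for s, r in per_subtype.items()})
        else:
            record("de", "skipped")

        # --- signature ------------------------------------------------------
        if config.enabled("signature") and "per_subtype_de" in state:
            sig = signature.intersect_signatures(state["per_subtype_de"], config.min_support)
            path = outdir / "signature.tsv"
            sig.relaxed.to_csv(path, sep="\t")
            gmt_path = outdir / "signature_pan.gmt"
            sets = {}
            if sig.pan_up:
                sets["PAN_UP"] = sig.pan_up
            if sig.pan_down:
                sets["PAN_DOWN"] = sig.pan_down
            if sets:
                io.write_gmt(sets, gmt_path)
            state["signature"] = sig
            record("signature", "complete",
                   {"signature": path, **({"signature_pan": gmt_path} if sets else {})},
                   pan_up=len(sig.pan_up), pan_down=len(sig.pan_down),
                   relaxed=len(sig.relaxed))
        else:
            record("signature", "skipped")

        # --- TSP -----------------------------------------------------------
        if config.enabled("tsp") and "signature" in state:
            sig = state["signature"]
            candidates = sig.pan_up + sig.pan_down
            if len(candidates) < 2:
                candidates = sig.relaxed_genes
            annotations = state["dataset"].annotations
            labels = annotations.loc[state["gene_matrix"].columns, "class"]
            ev = tsp.evaluate(state["gene_matrix"], labels, candidates, scheme=config.tsp_scheme)
            model = tsp.fit_tsp(state["gene_matrix"], labels, candidates)
            path = outdir / "tsp_report.json"
            io.write_json(
                {
                    "pair": [model.gene_i, model.gene_j],
                    "delta": model.delta,
                    "p_hat": model.p_hat,
                    "scheme": ev.scheme,
                    "sensitivity": ev.sensitivity,
                    "specificity": ev.specificity,
                    "confusion": {"tp": ev.tp, "fn": ev.fn, "tn": ev.tn, "fp": ev.fp},
                },
                path,
            )
            state["tsp_eval"] = ev
            record("tsp", "complete", {"tsp_report": path},
                   sensitivity=round(ev.sensitivity, 4), specificity=round(ev.specificity, 4))
        else:
            record("tsp", "skipped")

        # --- stratify --------------------------------------------------------
        if config.enabled("stratify") and "gene_matrix" in state:
            strat = stratify.stratify_cohort(
                state["gene_matrix"], state["dataset"].annotations, gene=config.stratify_gene
            )
            path = outdir / "stratification.tsv"
            strat.labels.to_frame().to_csv(path, sep="\t", index_label="sample_id")
            spath = outdir / "stratification_summary.tsv"
            strat.per_subtype.to_csv(spath, sep="\t")
            state["stratification"] = strat
            record("stratify", "complete",
                   {"stratification": path, "stratification_summary": spath},
                   threshold=round(strat.threshold, 4),
                   pooled_high_pct=strat.pooled_pct)
        else:
            record("stratify", "skipped")

        # --- TME --------------------------------------------------------------
        if config.enabled("tme") and "stratification" in state:
            strat = state["stratification"]
            corr = tme.correlation_filter(
                state["gene_matrix"], config.stratify_gene,
                samples=strat.labels.index.tolist(),
                p_cutoff=config.corr_p_cutoff, r_cutoff=config.corr_r_cutoff,
            )
            criteria = DECriteria(**{"mode": MODE_KORN, **config.tme_criteria})
            result = tme.tme_de(
                state["gene_matrix"], strat, corr, criteria=criteria, seed=config.seed + 2000
            )
            cpath = outdir / "correlation_filter.tsv"
            corr.table.to_csv(cpath, sep="\t", index_label="gene")
            dpath = outdir / "tme_de.tsv"
            result.de.table.to_csv(dpath, sep="\t", index_label="gene")
            state["tme"] = result
            record("tme", "complete", {"correlation_filter": cpath, "tme_de": dpath},
                   n_filtered=result.n_tested, n_de=result.n_de,
                   fraction_up=round(result.fraction_up, 4) if result.n_de else None)
        else:
            record("tme", "skipped")

        # --- enrichment --------------------------------------------------------
        if config.enabled("enrich"):
            if "tme" not in state:
                raise RuntimeError("enrichment requires the TME stage output")
            result = state["tme"]
            categories = {
                k: v for k, v in state["dataset"].gene_sets.items()
                if k != config.panel_set
            }
            universe = result.de.table.index.tolist()
            sig_table = result.de.table[result.de.table["significant"]]
            up_genes = sig_table.index[sig_table["fold_change"] > 1.0].tolist()
            files = {}
            if up_genes:
                over = enrichment_mod.overrepresentation(
                    up_genes, universe, categories, alpha=config.enrich_alpha
                )
                opath = outdir / "enrichment_overrep.tsv"
                over.table.to_csv(opath, sep="\t")
                files["enrichment_overrep"] = opath
            rank = enrichment_mod.rank_enrichment(
                sig_table["fold_change"], categories, alpha=config.enrich_alpha
            ) if len(sig_table) else None
            if rank is not None and len(rank.table):
                rpath = outdir / "enrichment_rank.tsv"
                rank.table.to_csv(rpath, sep="\t")
                files["enrichment_rank"] = rpath
            record("enrich", "complete", files,
                   n_up_genes=len(up_genes),
                   n_categories=len(categories))
        else:
            record("enrich", "skipped")

        # --- IHC -----------------------------------------------------------------
        if config.enabled("ihc"):
            counts = {tuple(k) if not isinstance(k, tuple) else k: tuple(v)
                      for k, v in config.ihc_counts.items()}
            calls = simulate.simulate_ihc_table(
                counts, seed=config.seed + 3000,
                cores_per_patient=config.ihc_cores_per_patient,
            )
            cpath = outdir / "ihc_calls.tsv"
            calls.to_csv(cpath, sep="\t", index=False)
            summary = ihc_mod.summarize_staining(calls)
            spath = outdir / "ihc_summary.tsv"
            summary.per_subtype.to_csv(spath, sep="\t")
            ppath = outdir / "ihc_pooled.tsv"
            summary.pooled.to_csv(ppath, sep="\t")
            record("ihc", "complete",
                   {"ihc_calls": cpath, "ihc_summary": spath, "ihc_pooled": ppath},
                   n_markers=len(summary.pooled))
        else:
            record("ihc", "skipped")

    except Exception as exc:
        failed = next((s for s in STAGES if s not in manifest["stages"]), "unknown")
        record(failed, "failed", error=str(exc))
        manifest["status"] = "incomplete"
        io.write_json(_manifest_jsonable(manifest), outdir / "manifest.json")
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest["status"] = "complete"
    io.write_json(_manifest_jsonable(manifest), outdir / "manifest.json")
    return manifest


def _manifest_jsonable(manifest: dict) -> dict:
    def conv(obj):
        if isinstance(obj, dict):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (pd.Timestamp, Path)):
            return str(obj)
        return obj

    return conv(manifest)
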