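"""End-to-end pipeline: files in, metric tables out, deterministically.

Stages: input preparation (or simulation), tRNA normalization + DE,
codon-usage matrices, CSC, tAI, CAI, SDR, PCA/k-means clustering, report.
Every threshold defaults to the study value (|log2FC| >= 0.5 and q <= 0.1
for tRNA DE; CSC class boundaries +/-0.01; delta-tAI report cutoff 0.2;
codon-set enrichment 2%; top/bottom selection fraction 10%). A run is fully
determined by its config + seed; the manifest records a config hash so
reruns can be audited.

All tabular outputs are UTF-8 TSV with '.' decimals and '#'-prefixed
metadata lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clustering, codon_core, optimality, synthetic, trna_quant

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class PipelineConfig:
    """Paths, thresholds and mode flags for one pipeline run."""

    # inputs; all may be filled in by simulation
    cds_fasta: str | None = None
    trna_table: str | None = None
    counts: str | None = None
    design: str | None = None
    half_lives: str | None = None
    expression: str | None = None
    reference_genes: str | None = None
    wobble_rules: str | None = None  # None -> packaged default rule set
    conditions: tuple[str, str] = ("neuroblast", "neuron")

    # simulation
    simulate: bool = False
    seed: int = 0
    simulate_params: dict = field(default_factory=dict)

    # thresholds (study defaults)
    fc_threshold: float = 0.5
    q_threshold: float = 0.1
    csc_threshold: float = 0.01
    delta_tai_threshold: float = 0.2
    enrichment_threshold: float = 0.02
    selection_fraction: float = 0.10

    # mode flags
    log_half_life: bool = False
    tai_zero_policy: str = "strict"
    demand_rescale: bool = True
    isoacceptor_agg: str = "mean"
    pca_scale: bool = False
    kmeans_restarts: int = 25
    k_min: int = 2
    k_max: int = 10
    k_override: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, metadata: dict | None = None, index=True) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index=index)


def _load_half_lives(path, conditions) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"gene_id", "condition", "half_life"}
    if not need <= set(df.columns):
        raise ValueError(f"half-life table needs columns {sorted(need)}")
    wide = df.pivot(index="gene_id", columns="condition", values="half_life")
    missing = set(conditions) - set(wide.columns)
    if missing:
        raise ValueError(f"half-life table missing condition(s) {sorted(missing)}")
    return wide[list(conditions)]


def _load_expression(path, conditions) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"gene_id", "condition", "expression"}
    if not need <= set(df.columns):
        raise ValueError(f"expression table needs columns {sorted(need)}")
    wide = df.pivot(index="gene_id", columns="condition", values="expression")
    missing = set(conditions) - set(wide.columns)
    if missing:
        raise ValueError(f"expression table missing condition(s) {sorted(missing)}")
    return wide[list(conditions)]


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run all stages; returns the output directory.

    Identical config + seed produces byte-identical outputs. Stage failures
    abort with the failing stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conditions = tuple(config.conditions)
    stages_done: list[str] = []

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            ds = synthetic.generate_dataset(
                seed=config.seed, conditions=conditions, **config.simulate_params
            )
            indir = outdir / "inputs"
            paths = synthetic.write_dataset(ds, indir)
            config.cds_fasta = paths["cds_fasta"]
            config.trna_table = paths["trna_table"]
            config.counts = paths["counts"]
            config.design = paths["design"]
            config.half_lives = paths["half_lives"]
            config.expression = paths["expression"]
            config.reference_genes = paths["reference_genes"]
        for name in ("cds_fasta", "trna_table", "counts", "design"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input '{name}' missing: {p}")
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    stages_done.append(stage)

    # ---- stage: trna ---------------------------------------------------
    stage = "trna"
    try:
        genes = trna_quant.read_trna_table(config.trna_table)
        groups = trna_quant.collapse_isodecoders(genes)
        features = trna_quant.features_from_groups(groups)
        counts, design = trna_quant.read_counts(config.counts, config.design)
        unknown = set(counts.index) - set(features.index)
        if unknown:
            raise ValueError(f"count features not in collapsed reference: {sorted(unknown)[:5]}")
        table = trna_quant.AbundanceTable(
            values=counts, design=design, features=features.loc[counts.index]
        )
        norm = trna_quant.tmm_normalize(table)
        de = trna_quant.differential_expression(
            norm,
            condition_a=conditions[0],
            condition_b=conditions[1],
            fc_threshold=config.fc_threshold,
            q_threshold=config.q_threshold,
        )
        iso = trna_quant.isoacceptor_abundance(norm, agg=config.isoacceptor_agg)

        tmm_out = norm.values.copy().sort_index()
        tmm_out.index.name = "feature_id"
        _write_tsv(
            tmm_out,
            outdir / "trna_tmm.tsv",
            {"normalization": "TMM", "factors": dict(norm.norm_factors.round(6))},
        )
        _write_tsv(
            de.sort_index(),
            outdir / "trna_de.tsv",
            {
                "method": de.attrs["method"],
                "fc_threshold": config.fc_threshold,
                "q_threshold": config.q_threshold,
                "orientation": de.attrs["orientation"],
            },
        )
        _write_tsv(iso.sort_index(), outdir / "isoacceptor_abundance.tsv", {"agg": config.isoacceptor_agg})
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    stages_done.append(stage)

    # ---- stage: usage --------------------------------------------------
    stage = "usage"
    try:
        cds_list, rejected = codon_core.read_cds_fasta(config.cds_fasta)
        if not cds_list:
            raise ValueError("no valid CDS records")
        cds_list = sorted(cds_list, key=lambda c: c.gene_id)
        count_mat = codon_core.count_matrix(cds_list)
        rel = codon_core.rel_freq_matrix(count_mat)
        aa_norm = codon_core.aa_norm_matrix(count_mat)
        cds_by_id = {c.gene_id: c for c in cds_list}
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    stages_done.append(stage)

    # ---- stage: csc ----------------------------------------------------
    stage = "csc"
    try:
        if config.half_lives is None or not Path(config.half_lives).exists():
            raise FileNotFoundError(f"half-life table missing: {config.half_lives}")
        half = _load_half_lives(config.half_lives, conditions)
        csc = {}
        for cond in conditions:
            csc[cond] = optimality.compute_csc(
                rel, half[cond].dropna(), log_half_life=config.log_half_life
            )
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    stages_done.append(stage)

    # ---- stage: tai ----------------------------------------------------
    stage = "tai"
    try:
        rules = (
            optimality.WobbleRuleSet.from_tsv(config.wobble_rules)
            if config.wobble_rules
            else optimality.WobbleRuleSet.default()
        )
        iso_means = trna_quant.isoacceptor_abundance(norm, agg=config.isoacceptor_agg)
        raw_w, tai, tai_gene = {}, {}, {}
        for cond in conditions:
            raw_w[cond] = optimality.compute_tai_weights(iso_means[cond], rules)
            tai[cond] = optimality.normalize_tai(raw_w[cond], zero_policy=config.tai_zero_policy)
            tai_gene[cond] = optimality.tai_gene_bulk(count_mat, tai[cond])
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    stages_done.append(stage)

    # ---- stage: cai ----------------------------------------------------
    stage = "cai"
    try:
        if config.reference_genes:
            ref_ids = [
                line.strip()
                for line in Path(config.reference_genes).read_text().splitlines()
                if line.strip()
            ]
            ref_cds = [cds_by_id[g] for g in ref_ids if g in cds_by_id]
            if not ref_cds:
                raise ValueError("no reference gene ids match the CDS set")
        else:
            # fall back: top 5% of genes by mean expression as the
            # highly-expressed reference (ribosomal-protein stand-in)
            if config.expression is None or not Path(config.expression).exists():
                raise FileNotFoundError("neither reference_genes nor expression available")
            expr_tmp = _load_expression(config.expression, conditions)
            top = optimality.rank_select(expr_tmp.mean(axis=1), top_fraction=0.05)
            ref_cds = [cds_by_id[g] for g in top if g in cds_by_id]
        cai_w = optimality.compute_cai_weights(ref_cds)
        cai_scores = optimality.cai_bulk(count_mat, cai_w)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    stages_done.append(stage)

    # ---- stage: sdr ----------------------------------------------------
    stage = "sdr"
    try:
        if config.expression is None or not Path(config.expression).exists():
            raise FileNotFoundError(f"expression table missing: {config.expression}")
        expr = _load_expression(config.expression, conditions)
        demand, sdr_c, sdr = {}, {}, {}
        for cond in conditions:
            demand[cond] = optimality.codon_demand(
                expr[cond].dropna(), rel, rescale=config.demand_rescale
            )
            sdr_c[cond] = optimality.sdr_codon(tai[cond], demand[cond])
            sdr[cond] = optimality.sdr_gene_bulk(count_mat, sdr_c[cond])
        dsdr = optimality.delta_sdr(sdr[conditions[1]], sdr[conditions[0]]).rename("delta_sdr")
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    stages_done.append(stage)

    # ---- stage: cluster ------------------------------------------------
    stage = "cluster"
    try:
        pca = clustering.pca_codon_usage(aa_norm, scale=config.pca_scale)
        n_pc = min(5, pca.scores.shape[1])
        clusters = clustering.kmeans_elbow(
            pca.scores.iloc[:, :n_pc],
            k_range=range(config.k_min, config.k_max + 1),
            n_restarts=config.kmeans_restarts,
            seed=config.seed,
            k_override=config.k_override,
        )
        gene_summary = pd.DataFrame(
            {
                "cai": cai_scores,
                "delta_sdr": dsdr,
                "cluster": clusters.labels,
                "PC1": pca.scores["PC1"],
                "PC2": pca.scores["PC2"] if "PC2" in pca.scores else np.nan,
            }
        )
        corr = clustering.correlate_delta_sdr_cai(gene_summary)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e
    stages_done.append(stage)

    # ---- stage: report -------------------------------------------------
    stage = "report"
    try:
        codon_rows = []
        for cond in conditions:
            df = pd.DataFrame(
                {
                    "condition": cond,
                    "csc": csc[cond],
                    "optimality_class": optimality.classify_optimality(csc[cond]),
                    "raw_tai_weight": raw_w[cond],
                    "tai": tai[cond],
                    "demand": demand[cond],
                    "sdr_c": sdr_c[cond],
                }
            )
            df.index.name = "codon"
            codon_rows.append(df.reset_index())
        codon_metrics = pd.concat(codon_rows).sort_values(["codon", "condition"])
        _write_tsv(
            codon_metrics,
            outdir / "codon_metrics.tsv",
            {
                "csc_threshold": config.csc_threshold,
                "tai_zero_policy": config.tai_zero_policy,
                "demand_rescale": config.demand_rescale,
            },
            index=False,
        )

        gene_rows = []
        for cond in conditions:
            df = pd.DataFrame(
                {
                    "condition": cond,
                    "half_life": half[cond].reindex(count_mat.index),
                    "mrna_abundance": expr[cond].reindex(count_mat.index),
                    "tai_gene": tai_gene[cond],
                    "sdr": sdr[cond],
                }
            )
            df.index.name = "gene_id"
            gene_rows.append(df.reset_index())
        gene_metrics = pd.concat(gene_rows).sort_values(["gene_id", "condition"])
        _write_tsv(gene_metrics, outdir / "gene_metrics.tsv", {}, index=False)

        gene_summary = gene_summary.sort_index()
        gene_summary.index.name = "gene_id"
        _write_tsv(
            gene_summary,
            outdir / "gene_summary.tsv",
            {"chosen_k": clusters.chosen_k, "selection_fraction": config.selection_fraction},
        )

        dtai = optimality.delta_tai_report(
            tai[conditions[0]], tai[conditions[1]],
            threshold=config.delta_tai_threshold, labels=conditions,
        )
        _write_tsv(dtai, outdir / "delta_tai.tsv", {"threshold": config.delta_tai_threshold})

        comparisons = {}
        for cond in conditions:
            res = optimality.tai_csc_comparison(tai[cond], csc[cond])
            comparisons[cond] = asdict(res)

        summary = {
            "conditions": list(conditions),
            "n_genes": int(count_mat.shape[0]),
            "n_isodecoders": int(norm.values.shape[0]),
            "n_isoacceptors": int(iso.shape[0]),
            "n_de_flagged": int(de["flagged"].sum()),
            "n_optimal_codons": {
                c: int((optimality.classify_optimality(csc[c]) == "optimal").sum())
                for c in conditions
            },
            "n_tai_1_codons": {
                c: int((tai[c] >= 1.0 - 1e-12).sum()) for c in conditions
            },
            "chosen_k": int(clusters.chosen_k),
            "inertia_curve": {str(k): v for k, v in clusters.inertia_curve.items()},
            "pca_explained_variance_fraction": [
                float(v) for v in pca.explained_variance_fraction[:5]
            ],
            "pearson_delta_sdr_cai": {"r": corr.r, "p": corr.p_value, "n": corr.n},
            "delta_sdr": {
                "min": float(dsdr.min()),
                "median": float(dsdr.median()),
                "max": float(dsdr.max()),
            },
            "tai_csc_comparison": comparisons,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)

        manifest = {
            "package": "codonadapt",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "stages": stages_done + [stage],
            "outputs": sorted(p.name for p in outdir.glob("*.tsv")) + ["summary.json"],
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    return outdir


def build_report(run_dir) -> dict:
    """Summarize an existing run directory into a single JSON-able dict."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json under {run_dir}")
    with open(summary_path) as fh:
        summary = json.load(fh)
    return {
        "n_optimal_codons": summary["n_optimal_codons"],
        "chosen_k": summary["chosen_k"],
        "pearson_delta_sdr_cai": summary["pearson_delta_sdr_cai"],
        "n_de_flagged": summary["n_de_flagged"],
        "delta_sdr": summary["delta_sdr"],
    }
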