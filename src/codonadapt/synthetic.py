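"""Synthetic two-condition datasets with known ground truth.

Every generator emulates the statistical structure the analysis assumes in
real progenitor/neuron data, at the scale of the study system it stands in
for:

* a cytosolic tRNA panel of 84 isodecoders over 44 anticodon groups with
  lognormal baseline abundances spanning several orders of magnitude, a
  small set of differentially expressed isodecoders, and overdispersed
  (negative-binomial) replicate counts;
* a CDS library with planted codon-bias clusters: amino-acid composition is
  shared across clusters, only synonymous codon choice differs, so cluster
  structure lives entirely in the 59-dimensional normalized usage space;
* half-lives generated log-linearly from optimal-codon content
  (``half_life = exp(b0 + b1 * optimal_fraction + eps)``), the simplest
  monotone model consistent with a correlation-based stabilization
  coefficient;
* lognormal mRNA abundances, with optional per-cluster condition boosts so
  codon demand (and hence supply-demand ratios) can differ by condition.

All generators are deterministic given a seed; the truth object is enough
to score recovery for every pipeline output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_core import CodingSequence, count_matrix, rel_freq_matrix, write_cds_fasta
from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    MULTI_CODON_FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
    reverse_complement,
)
from .trna_quant import AbundanceTable, TRNAGene, collapse_isodecoders, features_from_groups

AA1_TO_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

# Typical eukaryotic amino-acid composition (shared across all clusters so
# that only synonymous usage separates them).
DEFAULT_AA_FREQS = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.053, "C": 0.018, "Q": 0.040,
    "E": 0.062, "G": 0.063, "H": 0.023, "I": 0.046, "L": 0.093, "K": 0.058,
    "M": 0.023, "F": 0.037, "P": 0.053, "S": 0.072, "T": 0.057, "W": 0.011,
    "Y": 0.030, "V": 0.064,
}

DEFAULT_CONDITIONS = ("neuroblast", "neuron")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators, serializable to JSON."""

    trna: dict = field(default_factory=dict)
    cds: dict = field(default_factory=dict)
    half_life: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    optimal_codons: dict = field(default_factory=dict)
    reference_genes: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# tRNA panel
# ---------------------------------------------------------------------------


def default_anticodon_panel() -> list[tuple[str, str]]:
    """44 (amino_acid_3letter, anticodon) pairs covering all 61 sense codons.

    Construction mirrors eukaryotic repertoires: one G34 anticodon per
    NNT/NNC codon box (reading NNC Watson-Crick and NNT through G:U
    wobble), one U34 anticodon per sense NNA codon (also reading NNG
    through U:G wobble), and one C34 anticodon per sense NNG codon; the
    redundant C34 anticodon of the Arg-CGG box is omitted, leaving CGG to
    wobble decoding, which brings the panel to 44 groups.
    """
    panel: list[tuple[str, str]] = []
    bases = "ACGT"
    for b1 in bases:
        for b2 in bases:
            prefix = b1 + b2
            for third in ("C", "A", "G"):
                codon = prefix + third
                if codon in STOP_CODONS:
                    continue
                anticodon = reverse_complement(codon)
                if anticodon == "CCG":  # Arg-CGG read via U:G wobble instead
                    continue
                panel.append((AA1_TO_AA3[CODON_TO_AA[codon]], anticodon))
    return panel


def _random_trna_body(rng: np.random.Generator, anticodon: str, length: int = 73) -> str:
    body = "".join(rng.choice(list("ACGT"), size=length))
    return body[:33] + anticodon + body[36:]


def generate_trna_panel(
    n_anticodon_groups: int = 44,
    n_isodecoders: int = 84,
    n_de: int = 10,
    de_log2fc: float = 1.0,
    n_replicates: int = 3,
    cv: float = 0.10,
    seed: int = 0,
    conditions: tuple[str, str] = DEFAULT_CONDITIONS,
    log10_mean: float = 4.5,
    log10_sd: float = 1.1,
    depth_sd: float = 0.25,
    n_mito: int = 2,
) -> tuple[list[TRNAGene], AbundanceTable, SyntheticTruth]:
    """Synthetic tRNA gene set plus raw replicate counts and truth.

    Baseline isodecoder abundances are lognormal (log10 sd ~1.1, so the
    panel spans >= 4 orders of magnitude); ``n_de`` cytosolic isodecoders
    are shifted by ``de_log2fc`` log2 units in the first condition
    (alternating sign so both directions occur); replicate counts are
    negative-binomial at coefficient of variation ``cv``, with per-sample
    lognormal depth factors so normalization has real work to do.
    """
    if n_isodecoders < n_anticodon_groups:
        raise ValueError("need at least one isodecoder per anticodon group")
    if n_de > n_isodecoders:
        raise ValueError("n_de exceeds isodecoder count")
    if cv <= 0 or n_replicates < 1:
        raise ValueError("cv must be > 0 and n_replicates >= 1")
    panel = default_anticodon_panel()
    if n_anticodon_groups > len(panel):
        raise ValueError(f"at most {len(panel)} anticodon groups available")
    panel = panel[:n_anticodon_groups]
    rng = np.random.default_rng(seed)

    # distribute isodecoders round-robin so multiplicity is deterministic
    per_group = [1] * n_anticodon_groups
    for i in range(n_isodecoders - n_anticodon_groups):
        per_group[i % n_anticodon_groups] += 1

    genes: list[TRNAGene] = []
    seen_seqs: set[str] = set()
    iso_index = 0
    for (aa, anticodon), n_iso in zip(panel, per_group):
        for j in range(n_iso):
            seq = _random_trna_body(rng, anticodon)
            while seq in seen_seqs:
                seq = _random_trna_body(rng, anticodon)
            seen_seqs.add(seq)
            # every 5th isodecoder is encoded by two indistinguishable genes
            n_copies = 2 if iso_index % 5 == 4 else 1
            for copy in range(n_copies):
                genes.append(
                    TRNAGene(
                        gene_name=f"tRNA:{aa}-{anticodon.replace('T', 'U')}-{j + 1}-{copy + 1}",
                        amino_acid=aa,
                        anticodon=anticodon,
                        mature_sequence=seq,
                        genome="cytosolic",
                    )
                )
            iso_index += 1
    for m in range(n_mito):
        aa, anticodon = panel[m % len(panel)]
        seq = _random_trna_body(rng, anticodon, length=70)
        while seq in seen_seqs:
            seq = _random_trna_body(rng, anticodon, length=70)
        seen_seqs.add(seq)
        genes.append(
            TRNAGene(
                gene_name=f"mt:tRNA:{aa}-{anticodon.replace('T', 'U')}-{m + 1}",
                amino_acid=aa,
                anticodon=anticodon,
                mature_sequence=seq,
                genome="mitochondrial",
            )
        )

    groups = collapse_isodecoders(genes)
    features = features_from_groups(groups)
    group_ids = [g.group_id for g in groups]
    cyto_ids = [g.group_id for g in groups if g.genome == "cytosolic"]

    base = 10.0 ** rng.normal(log10_mean, log10_sd, size=len(groups))
    base_means = pd.Series(base, index=group_ids)

    de_ids = list(rng.choice(cyto_ids, size=n_de, replace=False)) if n_de else []
    true_log2fc = pd.Series(0.0, index=group_ids)
    for i, gid in enumerate(de_ids):
        true_log2fc[gid] = de_log2fc * (1 if i % 2 == 0 else -1)

    cond_a, cond_b = conditions
    true_means = pd.DataFrame({cond_b: base_means})
    true_means[cond_a] = base_means * 2.0 ** true_log2fc
    true_means = true_means[[cond_a, cond_b]]

    samples, cols = [], {}
    r_disp = 1.0 / cv**2
    for cond in conditions:
        for rep in range(n_replicates):
            sample = f"{cond}_rep{rep + 1}"
            samples.append((sample, cond))
            depth = rng.lognormal(0.0, depth_sd)
            mu = true_means[cond].to_numpy() * depth
            p = r_disp / (r_disp + mu)
            cols[sample] = rng.negative_binomial(r_disp, p)
    counts = pd.DataFrame(cols, index=group_ids)
    design = pd.DataFrame(
        {"condition": [c for _, c in samples]}, index=[s for s, _ in samples]
    )
    design.index.name = "sample"

    table = AbundanceTable(values=counts, design=design, features=features)
    truth = SyntheticTruth(
        trna={
            "de_features": de_ids,
            "true_log2fc": true_log2fc.to_dict(),
            "true_means": {c: true_means[c].to_dict() for c in conditions},
            "de_log2fc": de_log2fc,
            "cv": cv,
            "conditions": list(conditions),
        }
    )
    return genes, table, truth


def true_isoacceptor_means(table_truth: SyntheticTruth, features: pd.DataFrame) -> pd.DataFrame:
    """Anticodon x condition means of the *true* (noise-free) abundances."""
    means = pd.DataFrame(table_truth.trna["true_means"])
    cyto = features[features["genome"] == "cytosolic"]
    means = means.loc[cyto.index]
    return means.groupby(cyto["anticodon"]).mean()


# ---------------------------------------------------------------------------
# CDS library
# ---------------------------------------------------------------------------


def default_cluster_spec(
    n_clusters: int = 5, bias: float = 0.7, spec_seed: int = 987654321
) -> dict[int, dict]:
    """Per-cluster synonymous preference vectors.

    Within each multi-codon family, each cluster concentrates probability
    ``bias`` on one preferred codon (drawn by a fixed internal RNG, so the
    spec itself is a constant of the generator) and spreads the remainder
    uniformly. Preferred codons necessarily coincide between some clusters
    in 2-codon families, but across the 18 families every cluster pair
    differs in many coordinates, keeping the planted clusters well
    separated in normalized usage space.
    """
    rng = np.random.default_rng(spec_seed)
    spec: dict[int, dict] = {}
    for j in range(n_clusters):
        prefs: dict[str, dict[str, float]] = {}
        for aa, codons in sorted(MULTI_CODON_FAMILIES.items()):
            k = len(codons)
            p = np.full(k, (1.0 - bias) / (k - 1))
            p[rng.integers(k)] = bias
            prefs[aa] = dict(zip(codons, p))
        spec[j] = prefs
    return spec


def _validate_cluster_spec(spec: dict) -> None:
    for cluster, prefs in spec.items():
        for aa, pmap in prefs.items():
            if set(pmap) != set(MULTI_CODON_FAMILIES[aa]):
                raise ValueError(f"cluster {cluster}: preference keys != family {aa}")
            total = sum(pmap.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cluster {cluster}, family {aa}: preferences sum to {total}")


def generate_cds_library(
    n_genes: int = 2000,
    mean_length: int = 350,
    length_sigma: float = 0.25,
    min_length: int = 80,
    n_clusters: int = 5,
    cluster_spec: dict | None = None,
    bias: float = 0.7,
    aa_freqs: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[CodingSequence], SyntheticTruth]:
    """CDS library with planted synonymous-usage clusters.

    Lengths (in codons) are lognormal around ``mean_length``; every gene
    starts with ATG; amino acids are drawn from a composition shared across
    clusters; codons within multi-codon families follow the cluster's
    preference vector. No stop codons are ever emitted internally.
    """
    if cluster_spec is None:
        cluster_spec = default_cluster_spec(n_clusters, bias=bias)
    _validate_cluster_spec(cluster_spec)
    clusters = sorted(cluster_spec)
    aa_freqs = aa_freqs or DEFAULT_AA_FREQS
    aas = sorted(aa_freqs)
    pvec = np.array([aa_freqs[a] for a in aas], dtype=float)
    pvec = pvec / pvec.sum()
    rng = np.random.default_rng(seed)

    labels = rng.choice(len(clusters), size=n_genes)
    lengths = np.maximum(
        min_length, rng.lognormal(np.log(mean_length), length_sigma, n_genes).astype(int)
    )
    total = int(lengths.sum())
    gene_of_pos = np.repeat(np.arange(n_genes), lengths)
    starts = np.zeros(n_genes, dtype=int)
    starts[1:] = np.cumsum(lengths)[:-1]

    aa_idx = rng.choice(len(aas), size=total, p=pvec)
    aa_idx[starts] = aas.index("M")  # every CDS begins with Met

    codon_strings = np.array(SENSE_CODONS)
    sense_index = {c: i for i, c in enumerate(SENSE_CODONS)}
    codon_idx = np.empty(total, dtype=np.int64)
    cluster_of_pos = np.asarray(labels)[gene_of_pos]
    for ai, aa in enumerate(aas):
        codons = AA_TO_CODONS[aa]
        aa_mask = aa_idx == ai
        if len(codons) == 1:
            codon_idx[aa_mask] = sense_index[codons[0]]
            continue
        fam_idx = np.array([sense_index[c] for c in codons])
        for cj, cluster in enumerate(clusters):
            mask = aa_mask & (cluster_of_pos == cj)
            n = int(mask.sum())
            if n == 0:
                continue
            prefs = cluster_spec[cluster][aa]
            p = np.array([prefs[c] for c in codons], dtype=float)
            codon_idx[mask] = fam_idx[rng.choice(len(codons), size=n, p=p)]

    pos_codons = codon_strings[codon_idx]
    cds_list: list[CodingSequence] = []
    width = len(str(n_genes - 1)) if n_genes > 1 else 1
    for g in range(n_genes):
        seq = "".join(pos_codons[starts[g] : starts[g] + lengths[g]])
        cds_list.append(
            CodingSequence(gene_id=f"gene{g:0{width}d}", sequence=seq, n_codons=int(lengths[g]))
        )
    truth = SyntheticTruth(
        cds={
            "cluster_labels": {c.gene_id: int(l) for c, l in zip(cds_list, labels)},
            "n_clusters": len(clusters),
            "bias": bias,
        }
    )
    return cds_list, truth


# ---------------------------------------------------------------------------
# Half-lives and expression
# ---------------------------------------------------------------------------


def generate_half_lives(
    cds_or_relfreq,
    optimal_codons,
    beta0: float = float(np.log(30.0)),
    beta1: float = 1.5,
    sigma: float = 0.3,
    seed: int = 0,
) -> tuple[pd.Series, SyntheticTruth]:
    """Half-lives log-linear in optimal-codon fraction.

    ``half_life_g = exp(beta0 + beta1 * f_g + eps)`` where ``f_g`` is the
    summed relative frequency over the planted optimal codon set and
    ``eps ~ N(0, sigma^2)``. beta0 sets the typical half-life scale
    (default e^ln(30) = 30 time units, i.e. minutes for a fly mRNA).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    optimal = sorted(set(optimal_codons))
    unknown = set(optimal) - set(SENSE_CODONS)
    if unknown:
        raise ValueError(f"not sense codons: {sorted(unknown)}")
    if isinstance(cds_or_relfreq, pd.DataFrame):
        rel = cds_or_relfreq
    else:
        rel = rel_freq_matrix(count_matrix(cds_or_relfreq))
    frac = rel[optimal].sum(axis=1)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=len(frac)) if sigma > 0 else np.zeros(len(frac))
    hl = np.exp(beta0 + beta1 * frac.to_numpy() + eps)
    truth = SyntheticTruth(
        half_life={
            "beta0": beta0,
            "beta1": beta1,
            "sigma": sigma,
            "optimal_codons": optimal,
        }
    )
    return pd.Series(hl, index=rel.index, name="half_life"), truth


def generate_expression(
    gene_ids,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    log_mean: float = float(np.log(50.0)),
    log_sd: float = 1.0,
    cluster_labels: pd.Series | None = None,
    cluster_boost: dict[str, dict[int, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Lognormal mRNA abundances per condition.

    A shared lognormal baseline per gene, optionally multiplied by a
    per-cluster, per-condition boost factor (``cluster_boost[condition]
    [cluster] = factor``) so demand can shift between conditions.
    """
    gene_ids = list(gene_ids)
    rng = np.random.default_rng(seed)
    base = rng.lognormal(log_mean, log_sd, size=len(gene_ids))
    out = pd.DataFrame({c: base.copy() for c in conditions}, index=gene_ids)
    boost_applied: dict[str, dict[int, float]] = {}
    if cluster_boost:
        if cluster_labels is None:
            raise ValueError("cluster_boost needs cluster_labels")
        lab = cluster_labels.reindex(gene_ids)
        for cond, boosts in cluster_boost.items():
            boost_applied[cond] = {int(k): float(v) for k, v in boosts.items()}
            for cl, factor in boosts.items():
                out.loc[lab == int(cl), cond] *= float(factor)
    truth = SyntheticTruth(
        expression={
            "log_mean": log_mean,
            "log_sd": log_sd,
            "cluster_boost": boost_applied,
        }
    )
    return out, truth


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    trna_genes: list[TRNAGene]
    counts: AbundanceTable
    cds: list[CodingSequence]
    half_lives: pd.DataFrame  # genes x conditions
    expression: pd.DataFrame  # genes x conditions
    reference_genes: list[str]
    truth: SyntheticTruth
    conditions: tuple[str, str] = DEFAULT_CONDITIONS


def generate_dataset(
    seed: int = 0,
    n_genes: int = 2000,
    n_clusters: int = 5,
    n_isodecoders: int = 84,
    n_anticodon_groups: int = 44,
    n_de: int = 10,
    de_log2fc: float = 1.0,
    n_replicates: int = 3,
    cv: float = 0.10,
    beta1: float = 1.5,
    sigma: float = 0.3,
    boost_factor: float = 4.0,
    n_reference: int = 150,
    conditions: tuple[str, str] = DEFAULT_CONDITIONS,
) -> SyntheticDataset:
    """A complete, internally consistent two-condition dataset.

    The condition-specific optimal codon sets driving half-lives are the
    family-maximal tAI codons computed from the *true* tRNA abundances, so
    stabilization signal agrees with the planted supply. The CAI reference
    set is drawn from cluster 0 (the stand-in for highly expressed
    proliferation transcripts), and cluster 0 expression is boosted in the
    second condition so its codons are in higher demand there -- planting a
    negative CAI vs delta-SDR association.
    """
    from .optimality import WobbleRuleSet, compute_tai_weights, normalize_tai

    ss = np.random.SeedSequence(seed)
    s_trna, s_cds, s_hl, s_expr = [int(x % 2**31) for x in ss.generate_state(4)]

    genes, counts, trna_truth = generate_trna_panel(
        n_anticodon_groups=n_anticodon_groups,
        n_isodecoders=n_isodecoders,
        n_de=n_de,
        de_log2fc=de_log2fc,
        n_replicates=n_replicates,
        cv=cv,
        seed=s_trna,
        conditions=conditions,
    )
    cds, cds_truth = generate_cds_library(n_genes=n_genes, n_clusters=n_clusters, seed=s_cds)

    rules = WobbleRuleSet.default()
    iso_true = true_isoacceptor_means(trna_truth, counts.features)
    optimal: dict[str, list[str]] = {}
    for cond in conditions:
        tai = normalize_tai(compute_tai_weights(iso_true[cond], rules))
        fam_codons = [c for fam in MULTI_CODON_FAMILIES.values() for c in fam]
        optimal[cond] = sorted(c for c in fam_codons if tai[c] >= 1.0 - 1e-12)

    rel = rel_freq_matrix(count_matrix(cds))
    half = {}
    hl_truth = None
    for i, cond in enumerate(conditions):
        series, hl_truth = generate_half_lives(
            rel, optimal[cond], beta1=beta1, sigma=sigma, seed=s_hl + i
        )
        half[cond] = series
    half_df = pd.DataFrame(half)

    labels = pd.Series(cds_truth.cds["cluster_labels"])
    expr, expr_truth = generate_expression(
        [c.gene_id for c in cds],
        conditions=conditions,
        cluster_labels=labels,
        cluster_boost={conditions[1]: {0: boost_factor}},
        seed=s_expr,
    )
    reference = sorted(labels.index[labels == 0])[:n_reference]

    truth = SyntheticTruth(
        trna=trna_truth.trna,
        cds=cds_truth.cds,
        half_life=hl_truth.half_life if hl_truth else {},
        expression=expr_truth.expression,
        optimal_codons=optimal,
        reference_genes=list(reference),
    )
    return SyntheticDataset(
        trna_genes=genes,
        counts=counts,
        cds=cds,
        half_lives=half_df,
        expression=expr,
        reference_genes=list(reference),
        truth=truth,
        conditions=conditions,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write a dataset in the exact file formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cds_fasta": outdir / "cds.fasta",
        "trna_table": outdir / "trna_genes.tsv",
        "counts": outdir / "trna_counts.tsv",
        "design": outdir / "design.tsv",
        "half_lives": outdir / "half_lives.tsv",
        "expression": outdir / "expression.tsv",
        "reference_genes": outdir / "cai_reference_genes.txt",
        "truth": outdir / "truth.json",
    }
    write_cds_fasta(ds.cds, paths["cds_fasta"])
    pd.DataFrame(
        {
            "gene_name": [g.gene_name for g in ds.trna_genes],
            "amino_acid": [g.amino_acid for g in ds.trna_genes],
            "anticodon": [g.anticodon for g in ds.trna_genes],
            "genome": [g.genome for g in ds.trna_genes],
            "sequence": [g.mature_sequence for g in ds.trna_genes],
        }
    ).to_csv(paths["trna_table"], sep="\t", index=False)
    counts = ds.counts.values.copy()
    counts.index.name = "feature_id"
    counts.to_csv(paths["counts"], sep="\t")
    ds.counts.design.to_csv(paths["design"], sep="\t")
    half_long = ds.half_lives.stack().rename("half_life").reset_index()
    half_long.columns = ["gene_id", "condition", "half_life"]
    half_long.to_csv(paths["half_lives"], sep="\t", index=False, float_format="%.10g")
    expr_long = ds.expression.stack().rename("expression").reset_index()
    expr_long.columns = ["gene_id", "condition", "expression"]
    expr_long.to_csv(paths["expression"], sep="\t", index=False, float_format="%.10g")
    Path(paths["reference_genes"]).write_text("\n".join(ds.reference_genes) + "\n")
    ds.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
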