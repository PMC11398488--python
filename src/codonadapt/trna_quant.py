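"""tRNA reference collapsing, TMM normalization, isoacceptor aggregation, DE.

The quantification model follows hydrolysis-based tRNA sequencing practice:
tRNA genes whose mature sequences (with the post-transcriptional 3' CCA
appended) are identical are collapsed into a single *isodecoder group*, the
unit at which reads can actually be assigned. Isodecoder counts are
normalized between samples with the trimmed mean of M-values (TMM,
Robinson & Oshlack 2010). All isodecoders sharing an anticodon form an
*isoacceptor* (anticodon group) whose abundance is the arithmetic mean of
its member isodecoders' condition-mean normalized values.

Differential expression uses a variance-moderated t-test on log2 values
with Benjamini-Hochberg correction. This is an explicit stand-in for the
nonparametric Bayesian method used on real hydro-tRNAseq data; results
carry a ``method=welch_bh_standin`` tag so the two are never confused.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DE_METHOD_TAG = "welch_bh_standin"


@dataclass(frozen=True)
class TRNAGene:
    """One tRNA gene: name, decoded amino acid, anticodon, mature sequence."""

    gene_name: str
    amino_acid: str  # 3-letter code or "SeC"
    anticodon: str  # 3-mer, stored uppercase DNA
    mature_sequence: str
    genome: str = "cytosolic"  # cytosolic | mitochondrial

    def __post_init__(self):
        ac = self.anticodon.upper().replace("U", "T")
        object.__setattr__(self, "anticodon", ac)
        if len(ac) != 3:
            raise ValueError(f"{self.gene_name}: anticodon must be a 3-mer, got {ac!r}")
        object.__setattr__(self, "mature_sequence", self.mature_sequence.upper().replace("U", "T"))
        if self.genome not in ("cytosolic", "mitochondrial"):
            raise ValueError(f"{self.gene_name}: genome must be cytosolic|mitochondrial")


@dataclass(frozen=True)
class IsodecoderGroup:
    """Genes with identical mature sequence; the countable tRNA unit."""

    group_id: str
    member_gene_names: tuple[str, ...]
    amino_acid: str
    anticodon: str
    collapsed_sequence: str
    genome: str = "cytosolic"


def _rna(anticodon: str) -> str:
    return anticodon.replace("T", "U")


def collapse_isodecoders(genes: list[TRNAGene]) -> list[IsodecoderGroup]:
    """Collapse genes with identical mature sequences into isodecoder groups.

    A CCA is appended to any mature sequence lacking it before comparison.
    Group ids follow the ``Aa-ANT-i`` convention with an ``-X`` suffix when
    more than one gene encodes the isodecoder. Identical sequences annotated
    with different anticodons are an annotation inconsistency and raise.
    """
    by_seq: dict[str, list[TRNAGene]] = {}
    order: list[str] = []
    for g in genes:
        seq = g.mature_sequence
        if not seq.endswith("CCA"):
            seq = seq + "CCA"
        if seq not in by_seq:
            by_seq[seq] = []
            order.append(seq)
        by_seq[seq].append(g)

    groups: list[IsodecoderGroup] = []
    counter: dict[tuple[str, str], int] = {}
    for seq in order:
        members = by_seq[seq]
        anticodons = {m.anticodon for m in members}
        if len(anticodons) > 1:
            names = ", ".join(m.gene_name for m in members)
            raise ValueError(f"identical mature sequence with conflicting anticodons: {names}")
        aas = {m.amino_acid for m in members}
        if len(aas) > 1:
            names = ", ".join(m.gene_name for m in members)
            raise ValueError(f"identical mature sequence with conflicting amino acids: {names}")
        genomes = {m.genome for m in members}
        if len(genomes) > 1:
            raise ValueError("identical mature sequence in both genomes")
        aa, ac = members[0].amino_acid, members[0].anticodon
        key = (aa, ac)
        counter[key] = counter.get(key, 0) + 1
        gid = f"{aa}-{_rna(ac)}-{counter[key]}"
        if len(members) > 1:
            gid += "-X"
        groups.append(
            IsodecoderGroup(
                group_id=gid,
                member_gene_names=tuple(m.gene_name for m in members),
                amino_acid=aa,
                anticodon=ac,
                collapsed_sequence=seq,
                genome=members[0].genome,
            )
        )
    return groups


@dataclass
class AbundanceTable:
    """Isodecoder (or isoacceptor) abundances across samples.

    ``values``: features x samples; ``design``: per-sample condition labels
    (index = sample id, column ``condition``); ``features``: optional
    per-feature metadata (``anticodon``, ``amino_acid``, ``genome``).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    features: pd.DataFrame | None = None
    normalized: bool = False
    norm_factors: pd.Series | None = None

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        self.design = self.design.loc[list(self.values.columns)]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])

    def condition_means(self) -> pd.DataFrame:
        """Features x conditions matrix of within-condition mean values."""
        cols = {c: self.values[self.samples_for(c)].mean(axis=1) for c in self.conditions}
        return pd.DataFrame(cols)

    def subset_genome(self, genome: str) -> "AbundanceTable":
        if self.features is None:
            raise ValueError("no feature metadata to subset on")
        keep = self.features.index[self.features["genome"] == genome]
        keep = [f for f in self.values.index if f in set(keep)]
        return replace(self, values=self.values.loc[keep], features=self.features.loc[keep])


def features_from_groups(groups: list[IsodecoderGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "anticodon": [g.anticodon for g in groups],
            "amino_acid": [g.amino_acid for g in groups],
            "genome": [g.genome for g in groups],
        },
        index=[g.group_id for g in groups],
    )


# ---------------------------------------------------------------------------
# TMM normalization (Robinson & Oshlack 2010)
# ---------------------------------------------------------------------------


def _quantile_factor(counts: np.ndarray, lib_sizes: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts, p, axis=0) / lib_sizes


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 scaling factor of one sample against the reference sample.

    Doubly trimmed (on M and on A ranks), inverse-variance-weighted mean of
    the M-values over features observed in both samples.
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    y, r = obs[keep], ref[keep]
    if y.size == 0:
        return 0.0
    log_r = np.log2((y / n_obs) / (r / n_ref))  # M values
    abs_e = 0.5 * (np.log2(y / n_obs) + np.log2(r / n_ref))  # A values
    v = (n_obs - y) / (n_obs * y) + (n_ref - r) / (n_ref * r)  # delta-method variance

    if np.max(np.abs(log_r)) < 1e-6:
        return 0.0

    n = log_r.size
    lo_l = math.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep2 = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep2.any():
        return 0.0
    f = np.sum(log_r[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(
    counts: pd.DataFrame,
    ref_column: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean 1).

    The reference sample, unless given, is the one whose 75th-percentile
    count fraction is closest to the mean across samples.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = list(counts.columns[lib == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    if ref_column is None:
        f75 = _quantile_factor(mat, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_column)
    ref = mat[:, ref_idx]
    logf = np.array(
        [_tmm_pair_factor(mat[:, k], ref, trim_m, trim_a) for k in range(mat.shape[1])]
    )
    factors = 2.0**logf
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def tmm_normalize(
    table: AbundanceTable,
    ref_column: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> AbundanceTable:
    """TMM-normalize raw counts.

    Normalized value = count / (library size x TMM factor) x geometric mean
    library size, so values stay on a count-like scale and pure sequencing
    depth differences cancel exactly.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    factors = tmm_factors(table.values, ref_column=ref_column, trim_m=trim_m, trim_a=trim_a)
    lib = table.values.sum(axis=0)
    scale = np.exp(np.mean(np.log(lib.to_numpy(dtype=float))))
    eff = lib * factors
    norm = table.values / eff * scale
    return replace(table, values=norm, normalized=True, norm_factors=factors)


# ---------------------------------------------------------------------------
# Isoacceptor aggregation and differential expression
# ---------------------------------------------------------------------------


def isoacceptor_abundance(
    table: AbundanceTable,
    cytosolic_only: bool = True,
    agg: str = "mean",
) -> pd.DataFrame:
    """Anticodon-group x condition abundances.

    For each anticodon group and condition, the arithmetic mean (default; a
    "sum" mode exists) over member isodecoders of their condition-mean
    normalized values. Anticodons with no measured isodecoders are simply
    absent from the output.
    """
    if table.features is None:
        raise ValueError("feature metadata with anticodons required")
    if agg not in ("mean", "sum"):
        raise ValueError("agg must be 'mean' or 'sum'")
    tab = table.subset_genome("cytosolic") if cytosolic_only else table
    means = tab.condition_means()
    anticodons = tab.features.loc[means.index, "anticodon"]
    grouped = means.groupby(anticodons)
    out = grouped.mean() if agg == "mean" else grouped.sum()
    out.index.name = "anticodon"
    return out


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    feature_id: str
    log2_fold_change: float
    q_value: float
    flagged: bool


def differential_expression(
    table: AbundanceTable,
    condition_a: str | None = None,
    condition_b: str | None = None,
    fc_threshold: float = 0.5,
    q_threshold: float = 0.1,
    pseudocount: float = 0.5,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Two-condition differential expression with threshold flagging.

    log2FC = log2(mean(condition_a) / mean(condition_b)) on normalized
    values (a/b defaults to the first/second condition in the design, i.e.
    neuroblast/neuron orientation for the default panel). q-values come from
    a t-test on log2(value + pseudocount) with Benjamini-Hochberg
    correction -- a stand-in for count-model-based testing, and tagged as
    such in ``DataFrame.attrs['method']``. A feature is flagged iff
    |log2FC| >= ``fc_threshold`` and q <= ``q_threshold``. A zero condition
    mean yields an infinite log2FC sentinel.

    With ``prior_df`` > 0 (default 4), per-feature variances are shrunk
    toward the panel-wide median with that many prior degrees of freedom
    before testing (empirical-Bayes moderation; log-scale variances are
    near-homoscedastic for count data with a shared coefficient of
    variation, so pooling information across the panel is appropriate and
    is what makes a 3-replicate design usable). ``prior_df=0`` gives plain
    Welch's t.
    """
    conds = table.conditions
    if condition_a is None or condition_b is None:
        if len(conds) != 2:
            raise ValueError("specify condition_a/condition_b for >2 conditions")
        condition_a, condition_b = conds[0], conds[1]
    a = table.values[table.samples_for(condition_a)]
    b = table.values[table.samples_for(condition_b)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >=2 replicates per condition")

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_a / mean_b)
    log2fc = log2fc.fillna(0.0)  # 0/0 -> no change; +/-inf sentinels kept

    la = np.log2(a.to_numpy(dtype=float) + pseudocount)
    lb = np.log2(b.to_numpy(dtype=float) + pseudocount)
    if prior_df and prior_df > 0:
        n1, n2 = la.shape[1], lb.shape[1]
        d_g = n1 + n2 - 2
        s2 = ((n1 - 1) * la.var(axis=1, ddof=1) + (n2 - 1) * lb.var(axis=1, ddof=1)) / d_g
        s2_post = (prior_df * np.median(s2) + d_g * s2) / (prior_df + d_g)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (la.mean(axis=1) - lb.mean(axis=1)) / np.sqrt(s2_post * (1 / n1 + 1 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), d_g + prior_df)
    else:
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]

    flagged = (np.abs(log2fc.to_numpy()) >= fc_threshold) & (q <= q_threshold)
    out = pd.DataFrame(
        {
            "feature_id": table.values.index,
            "log2_fold_change": log2fc.to_numpy(),
            "p_value": p,
            "q_value": q,
            "flagged": flagged,
        }
    ).set_index("feature_id")
    out.attrs["method"] = DE_METHOD_TAG
    out.attrs["variance_moderation_prior_df"] = float(prior_df or 0.0)
    out.attrs["fc_threshold"] = fc_threshold
    out.attrs["q_threshold"] = q_threshold
    out.attrs["orientation"] = f"{condition_a}/{condition_b}"
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_trna_table(path) -> list[TRNAGene]:
    """Read a tRNA gene TSV: gene_name, amino_acid, anticodon, genome, sequence."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_name", "amino_acid", "anticodon", "genome", "sequence"}
    if not required <= set(df.columns):
        raise ValueError(f"tRNA table needs columns {sorted(required)}")
    return [
        TRNAGene(
            gene_name=r.gene_name,
            amino_acid=r.amino_acid,
            anticodon=r.anticodon,
            mature_sequence=r.sequence,
            genome=r.genome,
        )
        for r in df.itertuples()
    ]


def read_counts(counts_path, design_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a counts TSV (feature_id + sample columns) and a design TSV."""
    counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    design = pd.read_csv(design_path, sep="\t", comment="#", index_col=0)
    if "condition" not in design.columns:
        raise ValueError("design TSV needs a 'condition' column")
    return counts, design
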