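"""Per-codon and per-gene optimality / translation-efficiency metrics.

The metrics implemented here:

* **CSC** (codon stabilization coefficient): for each sense codon, the
  Pearson correlation across genes between the codon's relative frequency
  in a CDS and the mRNA half-life. Positive CSC = stabilizing codon.
* **tAI** from measured tRNA abundance: per codon, the wobble-weighted sum
  ``w_c = sum_j (1 - s_cj) * abundance_j`` over decoding anticodons j,
  normalized within each synonymous family by the family maximum so the
  best-decoded codon of every family has tAI exactly 1.0. ``tAI_gene`` is
  the geometric mean over the CDS.
* **CAI** (Sharp & Li): relative synonymous weights from a pooled reference
  set of highly expressed genes; gene score is the geometric mean of the
  weights over the CDS, excluding Met/Trp/stops.
* **SDR** (supply-demand ratio): per codon, tAI divided by the
  expression-weighted transcriptome codon frequency (demand); per gene, the
  geometric mean of SDR_c over the CDS. ``delta_sdr`` compares conditions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import CodingSequence, count_matrix
from .genetic_code import (
    CODON_TO_AA,
    MULTI_CODON_FAMILIES,
    SENSE_CODONS,
    SINGLE_CODON_AAS,
    AA_TO_CODONS,
)

logger = logging.getLogger(__name__)

CSC_OPTIMAL_THRESHOLD = 0.01  # |CSC| boundary between neutral and optimal/non-optimal


# ---------------------------------------------------------------------------
# Wobble rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WobbleRule:
    codon: str
    anticodon: str
    s: float  # selective constraint in [0, 1]; 0 for Watson-Crick


class WobbleRuleSet:
    """Codon <-> anticodon decoding pairs with selective constraints.

    The default rule set uses the canonical eukaryotic constraints of the
    tAI literature (G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68, Watson-Crick
    0), shipped as an editable TSV; the prokaryotic lysidine rule is
    excluded and ATG is treated as Watson-Crick-only.
    """

    def __init__(self, rules: Iterable[WobbleRule]):
        self.rules = list(rules)
        for r in self.rules:
            if not (0.0 <= r.s <= 1.0):
                raise ValueError(f"selective constraint out of [0,1]: {r}")
        self.by_codon: dict[str, list[WobbleRule]] = {c: [] for c in SENSE_CODONS}
        for r in self.rules:
            if r.codon not in self.by_codon:
                raise ValueError(f"rule for non-sense codon {r.codon}")
            self.by_codon[r.codon].append(r)

    @classmethod
    def from_tsv(cls, path) -> "WobbleRuleSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            WobbleRule(r.codon, str(r.anticodon).upper().replace("U", "T"), float(r.s))
            for r in df.itertuples()
        )

    @classmethod
    def default(cls) -> "WobbleRuleSet":
        with resources.as_file(
            resources.files("codonadapt").joinpath("data/wobble_rules.tsv")
        ) as p:
            return cls.from_tsv(p)

    def anticodons(self) -> list[str]:
        return sorted({r.anticodon for r in self.rules})


# ---------------------------------------------------------------------------
# CSC
# ---------------------------------------------------------------------------


def compute_csc(
    rel_freq: pd.DataFrame,
    half_lives: pd.Series,
    log_half_life: bool = False,
    min_genes: int = 3,
) -> pd.Series:
    """Codon stabilization coefficients.

    For each of the 61 sense codons, the Pearson correlation across genes
    between the codon's relative frequency and the (optionally log-scale)
    half-life. Codons whose frequency has zero variance across genes get
    NaN (undefined CSC). Genes are matched by id between the two inputs.
    """
    genes = rel_freq.index.intersection(half_lives.index)
    if len(genes) < min_genes:
        raise ValueError(f"need >= {min_genes} genes with both usage and half-life")
    x = rel_freq.loc[genes].to_numpy(dtype=float)
    y = half_lives.loc[genes].to_numpy(dtype=float)
    if log_half_life:
        y = np.log(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = np.nan
    if sy == 0:
        r[:] = np.nan
    return pd.Series(r, index=rel_freq.columns, name="csc")


def classify_optimality(csc) -> pd.Series | str:
    """Three-way codon class at +/-0.01: optimal (CSC >= 0.01), neutral
    (-0.01 < CSC < 0.01), non-optimal (CSC <= -0.01); NaN -> undefined."""

    def one(v: float) -> str:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return "undefined"
        if v >= CSC_OPTIMAL_THRESHOLD:
            return "optimal"
        if v <= -CSC_OPTIMAL_THRESHOLD:
            return "non-optimal"
        return "neutral"

    if isinstance(csc, pd.Series):
        return csc.map(one)
    return one(csc)


# ---------------------------------------------------------------------------
# tAI
# ---------------------------------------------------------------------------


def compute_tai_weights(
    abundance: pd.Series | Mapping[str, float],
    rules: WobbleRuleSet | None = None,
) -> pd.Series:
    """Raw tAI weights from measured anticodon abundances.

    ``weight_c = sum over decoding anticodons j of (1 - s_cj) * abundance_j``.
    ``abundance`` is keyed by anticodon (DNA alphabet); anticodons referenced
    by a rule but absent from the table contribute 0 and are logged once.
    """
    rules = rules or WobbleRuleSet.default()
    ab = pd.Series(abundance, dtype=float)
    ab.index = [str(a).upper().replace("U", "T") for a in ab.index]
    if (ab < 0).any():
        raise ValueError("negative abundance")
    missing = sorted({r.anticodon for r in rules.rules} - set(ab.index))
    if missing:
        logger.info("anticodons absent from abundance table contribute 0: %s", missing)
    weights = {}
    for codon in SENSE_CODONS:
        w = 0.0
        for r in rules.by_codon[codon]:
            w += (1.0 - r.s) * float(ab.get(r.anticodon, 0.0))
        weights[codon] = w
    out = pd.Series(weights, name="raw_tai_weight")
    if (out == 0).all():
        raise ValueError("all tAI weights are zero (empty abundance table?)")
    return out


def normalize_tai(weights: pd.Series, zero_policy: str = "strict") -> pd.Series:
    """Within-family normalization: tAI_c = weight_c / max synonymous weight.

    Every family's maximum tAI is exactly 1.0. A family whose weights are
    all zero is an error. With ``zero_policy="lenient"``, individual
    zero-weight codons are replaced by the geometric mean of the nonzero
    weights in their family before normalizing; with "strict" (default)
    they propagate as tAI 0 and are rejected later by ``tai_gene``.
    """
    if zero_policy not in ("strict", "lenient"):
        raise ValueError("zero_policy must be 'strict' or 'lenient'")
    w = weights.astype(float).copy()
    out = pd.Series(np.nan, index=w.index, name="tai")
    for aa, codons in AA_TO_CODONS.items():
        fam = w[list(codons)]
        if (fam <= 0).all():
            raise ValueError(f"all-zero tAI weights for family {aa}")
        if zero_policy == "lenient" and (fam == 0).any():
            gm = np.exp(np.mean(np.log(fam[fam > 0])))
            fam = fam.replace(0.0, gm)
        out[list(codons)] = fam / fam.max()
    return out


def tai_gene(cds: CodingSequence, tai: pd.Series, zero_policy: str = "strict") -> float:
    """Geometric mean of per-codon tAI over the L sense codons of a CDS.

    Computed in the log domain for numerical stability. A codon with tAI 0
    raises (naming the codon) under the strict policy and is skipped under
    the lenient policy.
    """
    vals = tai[list(cds.codons())].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(f"{cds.gene_id}: undefined tAI for a codon in the CDS")
    zero = vals <= 0
    if zero.any():
        if zero_policy == "strict":
            bad = sorted({c for c, z in zip(cds.codons(), zero) if z})
            raise ValueError(f"{cds.gene_id}: zero tAI for codon(s) {bad}")
        vals = vals[~zero]
        if vals.size == 0:
            raise ValueError(f"{cds.gene_id}: no codons with positive tAI")
    return float(np.exp(np.mean(np.log(vals))))


# ---------------------------------------------------------------------------
# CAI (Sharp & Li)
# ---------------------------------------------------------------------------


def compute_cai_weights(
    reference: Sequence[CodingSequence],
    zero_count: float = 0.5,
) -> pd.Series:
    """Sharp-Li relative adaptiveness weights from a reference gene set.

    Codon counts are pooled over the reference; within each synonymous
    family ``w_c = count_c / max family count``. Codons unobserved in the
    reference receive a pseudo-count floor (default 0.5) before dividing,
    so no weight is exactly zero. Single-codon families get w = 1.
    """
    if len(reference) == 0:
        raise ValueError("empty reference set")
    pooled = count_matrix(reference).sum(axis=0).astype(float)
    w = pd.Series(1.0, index=list(SENSE_CODONS), name="cai_weight")
    for codons in MULTI_CODON_FAMILIES.values():
        fam = pooled[list(codons)].copy()
        fam[fam == 0] = zero_count
        w[list(codons)] = fam / fam.max()
    return w


def cai(cds: CodingSequence, weights: pd.Series) -> float:
    """Geometric-mean CAI of a CDS, excluding Met, Trp and stop codons."""
    codons = [c for c in cds.codons() if CODON_TO_AA[c] not in SINGLE_CODON_AAS]
    if not codons:
        raise ValueError(f"{cds.gene_id}: no informative codons for CAI")
    vals = weights[codons].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("CAI weights must be positive")
    return float(np.exp(np.mean(np.log(vals))))


# ---------------------------------------------------------------------------
# Supply-demand ratio
# ---------------------------------------------------------------------------


def codon_demand(
    expression: pd.Series,
    rel_freq: pd.DataFrame,
    rescale: bool = True,
) -> pd.Series:
    """Expression-weighted transcriptome codon frequency (tRNA demand).

    ``demand_c = sum over genes g of expression_g * rel_freq[g, c]``,
    rescaled to sum to 1 across codons (default) so SDR magnitudes are
    comparable between conditions with different total expression.
    """
    genes = rel_freq.index.intersection(expression.index)
    if len(genes) == 0:
        raise ValueError("expression and usage cover disjoint gene sets")
    e = expression.loc[genes].to_numpy(dtype=float)
    if (e < 0).any():
        raise ValueError("negative expression")
    d = rel_freq.loc[genes].mul(e, axis=0).sum(axis=0)
    if rescale:
        total = d.sum()
        if total <= 0:
            raise ValueError("zero total demand")
        d = d / total
    d.name = "demand"
    return d


def sdr_codon(tai: pd.Series, demand: pd.Series) -> pd.Series:
    """Per-codon supply-demand ratio tAI_c / demand_c (NaN where demand 0)."""
    d = demand.reindex(tai.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = tai / d
    out[d <= 0] = np.nan
    out.name = "sdr_c"
    return out


def sdr_gene(cds: CodingSequence, sdr_c: pd.Series) -> float:
    """Geometric mean of SDR_c over the codons of a CDS (log domain)."""
    vals = sdr_c[list(cds.codons())].to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals <= 0).any():
        bad = sorted({c for c, v in zip(cds.codons(), vals) if not v > 0})
        raise ValueError(f"{cds.gene_id}: zero/undefined demand for codon(s) {bad}")
    return float(np.exp(np.mean(np.log(vals))))


def delta_sdr(sdr_after: float | pd.Series, sdr_before: float | pd.Series):
    """SDR difference, post-differentiation minus progenitor (neuron - neuroblast)."""
    return sdr_after - sdr_before


# ---------------------------------------------------------------------------
# Bulk per-gene geometric means (log-domain, vectorized over a count matrix)
# ---------------------------------------------------------------------------


def gene_geometric_mean(
    counts: pd.DataFrame,
    values: pd.Series,
    include: Sequence[str] | None = None,
) -> pd.Series:
    """Per-gene geometric mean of per-codon ``values``, weighted by counts.

    ``exp( (counts @ log(values)) / L )`` restricted to the ``include``
    codon columns (default: all 61). Genes with no included codons, or any
    used codon with a non-positive value, raise.
    """
    cols = list(include) if include is not None else list(counts.columns)
    sub = counts[cols]
    vals = values[cols].to_numpy(dtype=float)
    used = sub.to_numpy().sum(axis=0) > 0
    if np.any(used & ~(vals > 0)):
        bad = [c for c, u, v in zip(cols, used, vals) if u and not v > 0]
        raise ValueError(f"non-positive metric for used codon(s) {bad}")
    L = sub.sum(axis=1).to_numpy(dtype=float)
    if (L == 0).any():
        bad = list(sub.index[L == 0])
        raise ValueError(f"gene(s) with no scored codons: {bad[:5]}")
    with np.errstate(divide="ignore"):
        logv = np.where(vals > 0, np.log(vals), 0.0)
    out = np.exp(sub.to_numpy(dtype=float) @ logv / L)
    return pd.Series(out, index=counts.index)


def tai_gene_bulk(counts: pd.DataFrame, tai: pd.Series) -> pd.Series:
    """tAI_gene for every row of a genes x 61 count matrix."""
    return gene_geometric_mean(counts, tai).rename("tai_gene")


def cai_bulk(counts: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """CAI for every gene, excluding Met/Trp (and stops, never counted)."""
    from .genetic_code import AA_NORM_CODONS

    return gene_geometric_mean(counts, weights, include=list(AA_NORM_CODONS)).rename("cai")


def sdr_gene_bulk(counts: pd.DataFrame, sdr_c: pd.Series) -> pd.Series:
    """Gene-level supply-demand ratio for every row of a count matrix."""
    if sdr_c.isna().any():
        used = counts.to_numpy().sum(axis=0) > 0
        bad = [c for c, u in zip(counts.columns, used) if u and np.isnan(sdr_c[c])]
        if bad:
            raise ValueError(f"undefined SDR_c for used codon(s) {bad}")
        sdr_c = sdr_c.fillna(1.0)  # unused codons, value irrelevant
    return gene_geometric_mean(counts, sdr_c).rename("sdr")


# ---------------------------------------------------------------------------
# Selection helpers and group comparisons
# ---------------------------------------------------------------------------


def enrichment_filter(
    rel_freq: pd.DataFrame,
    codon_set: Iterable[str],
    threshold: float = 0.02,
) -> list[str]:
    """Genes whose summed relative frequency over ``codon_set`` >= threshold."""
    codons = list(codon_set)
    if not codons:
        raise ValueError("empty codon set")
    unknown = set(codons) - set(rel_freq.columns)
    if unknown:
        raise ValueError(f"codons not in usage matrix: {sorted(unknown)}")
    total = rel_freq[codons].sum(axis=1)
    return list(total.index[total >= threshold])


def rank_select(
    metric: pd.Series,
    top_fraction: float | None = None,
    bottom_fraction: float | None = None,
) -> list[str]:
    """Deterministic top/bottom-fraction selection by a per-gene metric.

    Exactly one of the fractions must be given, in (0, 1]. Sorting is
    stable, with ties broken lexicographically by gene id; a tie spanning
    the cut emits a warning.
    """
    if (top_fraction is None) == (bottom_fraction is None):
        raise ValueError("give exactly one of top_fraction / bottom_fraction")
    frac = top_fraction if top_fraction is not None else bottom_fraction
    if not (0 < frac <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if metric.isna().any():
        raise ValueError("metric undefined (NaN) for some genes")
    n_sel = max(1, int(len(metric) * frac))
    df = pd.DataFrame({"metric": metric, "gene_id": metric.index.astype(str)})
    ascending = top_fraction is None
    df = df.sort_values(["metric", "gene_id"], ascending=[ascending, True], kind="stable")
    if len(df) > n_sel and df["metric"].iloc[n_sel - 1] == df["metric"].iloc[n_sel]:
        warnings.warn("tie at the selection boundary; broken by gene_id", stacklevel=2)
    return list(df["gene_id"].iloc[:n_sel])


@dataclass(frozen=True)
class GroupComparisonResult:
    """Effect size and Welch test between stabilizing and destabilizing codons."""

    cohens_d: float
    welch_t: float
    p_value: float
    n_stabilizing: int
    n_destabilizing: int


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-standard-deviation Cohen's d, sign = mean(x) - mean(y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs >= 2 values")
    sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def tai_csc_comparison(tai: pd.Series, csc: pd.Series) -> GroupComparisonResult:
    """Compare tAI of stabilizing (CSC > 0) vs destabilizing (CSC < 0) codons.

    Effect size is pooled-SD Cohen's d (positive when stabilizing codons
    have higher tAI); significance is Welch's t-test.
    """
    common = tai.index.intersection(csc.dropna().index)
    stab = tai[common[csc[common] > 0]].to_numpy(dtype=float)
    destab = tai[common[csc[common] < 0]].to_numpy(dtype=float)
    if stab.size < 2 or destab.size < 2:
        raise ValueError("need >= 2 codons per CSC group")
    t, p = stats.ttest_ind(stab, destab, equal_var=False)
    return GroupComparisonResult(
        cohens_d=cohens_d(stab, destab),
        welch_t=float(t),
        p_value=float(p),
        n_stabilizing=int(stab.size),
        n_destabilizing=int(destab.size),
    )


def delta_tai_report(
    tai_a: pd.Series,
    tai_b: pd.Series,
    threshold: float = 0.2,
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Codons whose between-condition tAI difference is |delta| >= threshold."""
    df = pd.DataFrame({f"tai_{labels[0]}": tai_a, f"tai_{labels[1]}": tai_b})
    df["delta_tai"] = df.iloc[:, 0] - df.iloc[:, 1]
    out = df[df["delta_tai"].abs() >= threshold].copy()
    out.index.name = "codon"
    return out
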