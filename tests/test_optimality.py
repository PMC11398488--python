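"""CSC, tAI, CAI, SDR, selection helpers and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonadapt import codon_core, optimality
from codonadapt.codon_core import parse_cds
from codonadapt.genetic_code import AA_TO_CODONS, MULTI_CODON_FAMILIES, SENSE_CODONS
from codonadapt.optimality import (
    WobbleRuleSet,
    cai,
    cai_bulk,
    classify_optimality,
    codon_demand,
    cohens_d,
    compute_cai_weights,
    compute_csc,
    compute_tai_weights,
    delta_sdr,
    delta_tai_report,
    enrichment_filter,
    normalize_tai,
    rank_select,
    sdr_codon,
    sdr_gene,
    sdr_gene_bulk,
    tai_csc_comparison,
    tai_gene,
    tai_gene_bulk,
)


class TestWobbleRules:
    def test_every_sense_codon_has_a_decoder(self, rules):
        assert all(len(rules.by_codon[c]) >= 1 for c in SENSE_CODONS)

    def test_watson_crick_pairs_have_zero_constraint(self, rules):
        from codonadapt.genetic_code import anticodon_for

        for codon in SENSE_CODONS:
            wc = [r for r in rules.by_codon[codon] if r.anticodon == anticodon_for(codon)]
            assert len(wc) == 1 and wc[0].s == 0.0

    def test_sole_decoder_weight(self, rules):
        w = compute_tai_weights({"TTT": 100.0}, rules)
        assert w["AAA"] == pytest.approx(100.0)

    def test_wobble_plus_watson_crick_weight(self, rules):
        """AAG read by TTT (U:G, s=0.68) at 100 and CTT (WC) at 50 -> 82."""
        w = compute_tai_weights({"TTT": 100.0, "CTT": 50.0}, rules)
        assert w["AAG"] == pytest.approx(0.32 * 100 + 50)

    def test_all_zero_abundance_raises(self, rules):
        with pytest.raises(ValueError, match="zero"):
            compute_tai_weights({"TTT": 0.0}, rules)

    def test_constraint_out_of_range_rejected(self):
        from codonadapt.optimality import WobbleRule

        with pytest.raises(ValueError):
            WobbleRuleSet([WobbleRule("AAA", "TTT", 1.5)])


class TestNormalizeTai:
    def test_lys_example(self):
        w = pd.Series(0.0, index=list(SENSE_CODONS))
        for fam in AA_TO_CODONS.values():
            w[list(fam)] = 10.0
        w["AAA"], w["AAG"] = 100.0, 82.0
        tai = normalize_tai(w)
        assert tai["AAA"] == 1.0
        assert tai["AAG"] == pytest.approx(0.82)

    def test_single_codon_family_is_one(self, rules, small_panel):
        _, table, truth = small_panel
        from codonadapt.synthetic import true_isoacceptor_means

        iso = true_isoacceptor_means(truth, table.features)
        tai = normalize_tai(compute_tai_weights(iso["neuron"], rules))
        assert tai["ATG"] == 1.0
        assert tai["TGG"] == 1.0

    def test_family_max_is_exactly_one(self, rules, small_panel):
        _, table, truth = small_panel
        from codonadapt.synthetic import true_isoacceptor_means

        iso = true_isoacceptor_means(truth, table.features)
        tai = normalize_tai(compute_tai_weights(iso["neuroblast"], rules))
        for fam in AA_TO_CODONS.values():
            assert tai[list(fam)].max() == 1.0

    def test_scale_invariance(self, rules, small_panel):
        _, table, truth = small_panel
        from codonadapt.synthetic import true_isoacceptor_means

        iso = true_isoacceptor_means(truth, table.features)["neuron"]
        t1 = normalize_tai(compute_tai_weights(iso, rules))
        t2 = normalize_tai(compute_tai_weights(iso * 2.0, rules))
        assert np.allclose(t1, t2)

    def test_all_zero_family_raises(self):
        w = pd.Series(1.0, index=list(SENSE_CODONS))
        w[list(AA_TO_CODONS["K"])] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            normalize_tai(w)

    def test_lenient_substitutes_family_geometric_mean(self):
        w = pd.Series(1.0, index=list(SENSE_CODONS))
        fam = list(AA_TO_CODONS["L"])  # 6 codons
        w[fam] = [4.0, 1.0, 0.0, 1.0, 1.0, 1.0]
        tai = normalize_tai(w, zero_policy="lenient")
        gm = np.exp(np.mean(np.log([4.0, 1.0, 1.0, 1.0, 1.0])))
        assert tai[fam[2]] == pytest.approx(gm / 4.0)


class TestTaiGene:
    def test_two_codon_geometric_mean(self):
        tai = pd.Series(1.0, index=list(SENSE_CODONS))
        tai["AAA"], tai["ATG"] = 0.25, 1.0
        cds = parse_cds(("g", "ATGAAA"))
        assert tai_gene(cds, tai) == pytest.approx(0.5)

    def test_all_optimal_cds_scores_one(self):
        tai = pd.Series(1.0, index=list(SENSE_CODONS))
        assert tai_gene(parse_cds(("g", "ATGAAAGGC")), tai) == 1.0

    def test_matches_log_domain_oracle(self, small_library, rules):
        cds_list, _ = small_library
        rng = np.random.default_rng(3)
        tai = pd.Series(rng.uniform(0.05, 1.0, len(SENSE_CODONS)), index=list(SENSE_CODONS))
        for cds in cds_list[:20]:
            vals = tai[list(cds.codons())].to_numpy()
            oracle = float(np.exp(np.sum(np.log(vals)) / cds.n_codons))
            assert tai_gene(cds, tai) == pytest.approx(oracle, abs=1e-12)

    def test_product_and_log_forms_agree(self):
        rng = np.random.default_rng(5)
        tai = pd.Series(rng.uniform(0.2, 1.0, len(SENSE_CODONS)), index=list(SENSE_CODONS))
        cds = parse_cds(("g", "".join(rng.choice(SENSE_CODONS, 50))))
        product_form = float(np.prod(tai[list(cds.codons())].to_numpy()) ** (1 / cds.n_codons))
        assert tai_gene(cds, tai) == pytest.approx(product_form, abs=1e-10)

    def test_zero_tai_strict_names_codon(self):
        tai = pd.Series(1.0, index=list(SENSE_CODONS))
        tai["AAA"] = 0.0
        with pytest.raises(ValueError, match="AAA"):
            tai_gene(parse_cds(("g", "ATGAAA")), tai)

    def test_bulk_matches_scalar(self, small_library):
        cds_list, _ = small_library
        rng = np.random.default_rng(9)
        tai = pd.Series(rng.uniform(0.1, 1.0, len(SENSE_CODONS)), index=list(SENSE_CODONS))
        counts = codon_core.count_matrix(cds_list[:15])
        bulk = tai_gene_bulk(counts, tai)
        for cds in cds_list[:15]:
            assert bulk[cds.gene_id] == pytest.approx(tai_gene(cds, tai), rel=1e-12)


class TestCSC:
    def test_matches_pearson_oracle_on_fixture(self):
        """5-gene fixture: CSC equals a hand-coded Pearson formula to 1e-12."""
        rng = np.random.default_rng(17)
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(5, 61)),
            index=[f"g{i}" for i in range(5)],
            columns=list(SENSE_CODONS),
        )
        rel = codon_core.rel_freq_matrix(counts)
        hl = pd.Series([10.0, 25.0, 12.0, 40.0, 33.0], index=rel.index)
        csc = compute_csc(rel, hl)
        for codon in SENSE_CODONS:
            x, y = rel[codon].to_numpy(), hl.to_numpy()
            sx = np.sqrt(np.sum((x - x.mean()) ** 2))
            sy = np.sqrt(np.sum((y - y.mean()) ** 2))
            if sx == 0:
                assert np.isnan(csc[codon])
            else:
                oracle = np.sum((x - x.mean()) * (y - y.mean())) / (sx * sy)
                assert csc[codon] == pytest.approx(oracle, abs=1e-12)

    def test_constant_half_life_is_all_undefined(self, small_library):
        cds_list, _ = small_library
        rel = codon_core.rel_freq_matrix(codon_core.count_matrix(cds_list[:10]))
        hl = pd.Series(5.0, index=rel.index)
        assert compute_csc(rel, hl).isna().all()

    def test_planted_optimal_codons_get_higher_csc(self):
        """Half-lives increasing in optimal-codon content push CSC up for
        the planted set (2,000 genes, fixed seed)."""
        from codonadapt import synthetic

        cds_list, _ = synthetic.generate_cds_library(n_genes=2000, seed=42)
        rel = codon_core.rel_freq_matrix(codon_core.count_matrix(cds_list))
        optimal = sorted(fam[0] for fam in MULTI_CODON_FAMILIES.values())
        hl, _ = synthetic.generate_half_lives(rel, optimal, seed=43)
        csc = compute_csc(rel, hl)
        other = [c for fam in MULTI_CODON_FAMILIES.values() for c in fam[1:]]
        assert csc[optimal].mean() > csc[other].mean()

    def test_too_few_genes_raise(self):
        rel = pd.DataFrame(np.ones((2, 61)) / 61, columns=list(SENSE_CODONS))
        with pytest.raises(ValueError):
            compute_csc(rel, pd.Series([1.0, 2.0], index=rel.index))

    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.02, "optimal"),
            (0.01, "optimal"),
            (0.005, "neutral"),
            (-0.005, "neutral"),
            (-0.01, "non-optimal"),
            (-0.5, "non-optimal"),
            (float("nan"), "undefined"),
        ],
    )
    def test_classification_boundaries(self, value, expected):
        assert classify_optimality(value) == expected


class TestCAI:
    def test_weights_from_pooled_counts(self):
        ref = [parse_cds(("r", "AAA" * 90 + "AAG" * 10))]
        w = compute_cai_weights(ref)
        assert w["AAA"] == 1.0
        assert w["AAG"] == pytest.approx(1 / 9)

    def test_uniform_reference_gives_unit_weights(self):
        ref = [parse_cds(("r", "".join(SENSE_CODONS)))]
        w = compute_cai_weights(ref)
        assert np.allclose(w, 1.0)

    def test_cai_geometric_mean_example(self):
        ref = [parse_cds(("r", "AAA" * 90 + "AAG" * 10))]
        w = compute_cai_weights(ref)
        value = cai(parse_cds(("g", "AAAAAG")), w)
        assert value == pytest.approx(np.sqrt(1 / 9), abs=1e-12)

    def test_family_maximal_cds_scores_one(self, small_library):
        cds_list, _ = small_library
        w = compute_cai_weights(cds_list[:50])
        best = "".join(
            fam[int(np.argmax(w[list(fam)].to_numpy()))]
            for fam in MULTI_CODON_FAMILIES.values()
        )
        assert cai(parse_cds(("g", best)), w) == pytest.approx(1.0)

    def test_met_trp_only_cds_raises(self, small_library):
        w = compute_cai_weights(small_library[0][:10])
        with pytest.raises(ValueError, match="informative"):
            cai(parse_cds(("g", "ATGTGG")), w)

    def test_reference_genes_outscore_random_genes(self):
        """Reference-style genes score higher CAI than random-codon genes."""
        from codonadapt import synthetic

        spec = synthetic.default_cluster_spec(n_clusters=1, bias=0.8)
        biased, _ = synthetic.generate_cds_library(
            n_genes=60, n_clusters=1, cluster_spec=spec, seed=5
        )
        rng = np.random.default_rng(6)
        from conftest import random_cds_strings

        random_genes = [
            parse_cds((f"r{i}", s))
            for i, s in enumerate(random_cds_strings(rng, 60, min_len=100, max_len=300))
        ]
        w = compute_cai_weights(biased[:30])
        mean_ref = np.mean([cai(c, w) for c in biased[30:]])
        mean_rand = np.mean([cai(c, w) for c in random_genes])
        assert mean_ref > mean_rand

    def test_bulk_matches_scalar(self, small_library):
        cds_list, _ = small_library
        w = compute_cai_weights(cds_list[:30])
        counts = codon_core.count_matrix(cds_list[:10])
        bulk = cai_bulk(counts, w)
        for cds in cds_list[:10]:
            assert bulk[cds.gene_id] == pytest.approx(cai(cds, w), rel=1e-12)


class TestSDR:
    def _rel(self, rows: dict) -> pd.DataFrame:
        df = pd.DataFrame(0.0, index=list(rows), columns=list(SENSE_CODONS))
        for g, freqs in rows.items():
            for codon, f in freqs.items():
                df.loc[g, codon] = f
        return df

    def test_demand_formula(self):
        rel = self._rel({"g1": {"CTC": 0.5, "AAA": 0.5}, "g2": {"CTC": 0.25, "AAA": 0.75}})
        expr = pd.Series({"g1": 10.0, "g2": 30.0})
        raw = codon_demand(expr, rel, rescale=False)
        assert raw["CTC"] == pytest.approx(10 * 0.5 + 30 * 0.25)

    def test_all_expression_on_one_gene(self):
        rel = self._rel({"g1": {"CTC": 0.3, "AAA": 0.7}, "g2": {"GGT": 1.0}})
        expr = pd.Series({"g1": 5.0, "g2": 0.0})
        d = codon_demand(expr, rel)
        assert d["CTC"] == pytest.approx(0.3)
        assert d["AAA"] == pytest.approx(0.7)

    def test_demand_scale_invariance(self, small_library):
        cds_list, _ = small_library
        rel = codon_core.rel_freq_matrix(codon_core.count_matrix(cds_list))
        rng = np.random.default_rng(2)
        expr = pd.Series(rng.lognormal(3, 1, len(rel)), index=rel.index)
        assert np.allclose(codon_demand(expr, rel), codon_demand(expr * 10, rel))

    def test_disjoint_gene_sets_raise(self):
        rel = self._rel({"g1": {"AAA": 1.0}})
        with pytest.raises(ValueError, match="disjoint"):
            codon_demand(pd.Series({"other": 1.0}), rel)

    def test_sdr_codon_division(self):
        tai = pd.Series(1.0, index=list(SENSE_CODONS))
        demand = pd.Series(0.02, index=list(SENSE_CODONS))
        assert sdr_codon(tai, demand)["AAA"] == pytest.approx(50.0)

    def test_identical_conditions_give_zero_delta(self, small_library):
        cds_list, _ = small_library
        counts = codon_core.count_matrix(cds_list)
        rel = codon_core.rel_freq_matrix(counts)
        rng = np.random.default_rng(4)
        tai = pd.Series(rng.uniform(0.2, 1.0, 61), index=list(SENSE_CODONS))
        expr = pd.Series(rng.lognormal(3, 1, len(rel)), index=rel.index)
        sdr_c = sdr_codon(tai, codon_demand(expr, rel))
        sdr = sdr_gene_bulk(counts, sdr_c)
        assert np.allclose(delta_sdr(sdr, sdr), 0.0)

    def test_gene_sdr_matches_scalar(self, small_library):
        cds_list, _ = small_library
        counts = codon_core.count_matrix(cds_list)
        rel = codon_core.rel_freq_matrix(counts)
        rng = np.random.default_rng(8)
        tai = pd.Series(rng.uniform(0.2, 1.0, 61), index=list(SENSE_CODONS))
        expr = pd.Series(rng.lognormal(3, 1, len(rel)), index=rel.index)
        sdr_c = sdr_codon(tai, codon_demand(expr, rel))
        bulk = sdr_gene_bulk(counts, sdr_c)
        for cds in cds_list[:10]:
            assert bulk[cds.gene_id] == pytest.approx(sdr_gene(cds, sdr_c), rel=1e-12)

    def test_zero_demand_for_used_codon_raises(self):
        tai = pd.Series(1.0, index=list(SENSE_CODONS))
        demand = pd.Series(0.02, index=list(SENSE_CODONS))
        demand["AAA"] = 0.0
        sdr_c = sdr_codon(tai, demand)
        with pytest.raises(ValueError, match="AAA"):
            sdr_gene(parse_cds(("g", "ATGAAA")), sdr_c)


class TestSelection:
    def test_enrichment_threshold(self, rules):
        seq_in = "CTC" * 2 + "AAA" * 98
        seq_out = "CTC" * 1 + "AAA" * 99
        rel = codon_core.rel_freq_matrix(
            codon_core.count_matrix(
                [parse_cds(("in", seq_in)), parse_cds(("out", seq_out))]
            )
        )
        hits = enrichment_filter(rel, {"CTC"}, threshold=0.02)
        assert hits == ["in"]
        assert set(enrichment_filter(rel, {"CTC"}, threshold=0.0)) == {"in", "out"}

    def test_empty_codon_set_raises(self, small_library):
        rel = codon_core.rel_freq_matrix(codon_core.count_matrix(small_library[0][:5]))
        with pytest.raises(ValueError, match="empty"):
            enrichment_filter(rel, [], 0.02)

    def test_top_fraction_size_and_content(self):
        metric = pd.Series(np.arange(100, dtype=float), index=[f"g{i:03d}" for i in range(100)])
        top = rank_select(metric, top_fraction=0.10)
        assert len(top) == 10
        assert set(top) == {f"g{i:03d}" for i in range(90, 100)}
        bottom = rank_select(metric, bottom_fraction=0.10)
        assert set(bottom) == {f"g{i:03d}" for i in range(10)}

    def test_all_equal_warns_and_breaks_ties_by_id(self):
        metric = pd.Series(1.0, index=[f"g{i:02d}" for i in range(20)])
        with pytest.warns(UserWarning, match="tie"):
            sel = rank_select(metric, top_fraction=0.5)
        assert sel == sorted(metric.index)[:10]

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.5])
    def test_bad_fraction_raises(self, frac):
        metric = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            rank_select(metric, top_fraction=frac)


class TestGroupComparison:
    def test_cohens_d_of_unit_shift(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(1, 1, 20000), rng.normal(0, 1, 20000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.05)

    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res_d = cohens_d(x, x.copy())
        assert res_d == 0.0
        t, p = stats.ttest_ind(x, x.copy(), equal_var=False)
        assert p == pytest.approx(1.0)

    def test_comparison_orientation_and_errors(self):
        tai = pd.Series(
            [0.9, 0.8, 0.95, 0.2, 0.3, 0.25], index=["c1", "c2", "c3", "c4", "c5", "c6"]
        )
        csc = pd.Series([0.1, 0.2, 0.15, -0.1, -0.2, -0.15], index=tai.index)
        res = tai_csc_comparison(tai, csc)
        assert res.cohens_d > 0
        assert res.n_stabilizing == res.n_destabilizing == 3
        with pytest.raises(ValueError):
            tai_csc_comparison(tai[:3], csc[:3])  # no destabilizing group

    def test_delta_tai_threshold(self):
        a = pd.Series({"AAA": 1.0, "AAG": 0.50, "GGT": 0.9})
        b = pd.Series({"AAA": 1.0, "AAG": 0.69, "GGT": 0.6})
        out = delta_tai_report(a, b, threshold=0.2)
        assert "GGT" in out.index  # |0.3| >= 0.2
        assert "AAG" not in out.index  # |0.19| excluded
        assert "AAA" not in out.index
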