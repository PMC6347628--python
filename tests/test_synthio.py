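"""Tests for the synthetic-data generators and their ground truth."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from millet_evol import degen4dtv
from millet_evol.synthio import (
    DOMAIN_VOCABULARY,
    ExpressionSimConfig,
    RILSimConfig,
    SubstitutionParams,
    WGDCohortSpec,
    beta_for_target_4dtv,
    expected_4dtv,
    simulate_codon_pairs,
    simulate_domain_table,
    simulate_expression_families,
    simulate_ril_population,
    simulate_wgd_genome,
)
from millet_evol.famexpr import entropy_table
from millet_evol.rilfilter import expected_genotype_proportions


def k2p_transversion_probability_matrix_oracle(
    alpha: float, beta: float, t: float
) -> float:
    """Expected transversion-difference proportion via a numerical
    matrix exponential of the full 4x4 two-parameter rate matrix —
    independent of the closed form used by the package."""
    bases = "ACGT"
    purine = {b: b in "AG" for b in bases}
    q = np.zeros((4, 4))
    for i, bi in enumerate(bases):
        for j, bj in enumerate(bases):
            if i == j:
                continue
            q[i, j] = alpha if purine[bi] == purine[bj] else beta
        q[i, i] = -q[i].sum()
    p = expm(q * t)  # per-lineage over time t
    total = 0.0
    for anc in range(4):
        for x in range(4):
            for y in range(4):
                if purine[bases[x]] != purine[bases[y]]:
                    total += 0.25 * p[anc, x] * p[anc, y]
    return total


class TestSubstitutionModel:
    def test_closed_form_agrees_with_matrix_exponential(self):
        for alpha, beta, t in [(0.003, 0.0015, 18), (0.01, 0.002, 5.8), (0.0, 0.005, 70)]:
            params = SubstitutionParams(alpha, beta, t)
            oracle = k2p_transversion_probability_matrix_oracle(alpha, beta, t)
            assert expected_4dtv(params) == pytest.approx(oracle, abs=1e-12)

    def test_beta_inversion_round_trip(self):
        beta = beta_for_target_4dtv(0.032, 5.8)
        assert expected_4dtv(SubstitutionParams(0.0, beta, 5.8)) == pytest.approx(0.032)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionParams(-0.1, 0.001, 1.0)


class TestCodonPairSimulator:
    def test_zero_time_gives_identical_pairs(self):
        sim = simulate_codon_pairs(
            SubstitutionParams(0.003, 0.0015, 0.0), 20, 50, seed=1
        )
        for pair in sim.pairs:
            assert pair.seq_a == pair.seq_b
        assert (sim.truth["n_transversions"] == 0).all()

    def test_saturation_limit(self):
        # beta*t = 100: transversion proportion saturates at 1/2
        sim = simulate_codon_pairs(
            SubstitutionParams(0.0, 1.0, 100.0), 200, 100, seed=2,
            fourfold_only=True,
        )
        values = sim.truth["n_transversions"] / sim.truth["n_4d_sites"]
        assert values.mean() == pytest.approx(0.5, abs=0.01)

    def test_mean_4dtv_matches_k2p_closed_form(self):
        params = SubstitutionParams(0.003, 0.0015, 18.0)
        sim = simulate_codon_pairs(params, 500, 500, seed=3, fourfold_only=True)
        values = (sim.truth["n_transversions"] / sim.truth["n_4d_sites"]).to_numpy()
        se = values.std(ddof=1) / math.sqrt(values.size)
        expected = expected_4dtv(params)
        assert expected == pytest.approx(0.0977, abs=0.001)  # sanity on the constant
        assert abs(values.mean() - expected) < 3 * se

    def test_truth_counts_match_compute_4dtv(self):
        sim = simulate_codon_pairs(
            SubstitutionParams(0.003, 0.002, 30.0), 30, 80, seed=4
        )
        for pair, row in zip(sim.pairs, sim.truth.itertuples(index=False)):
            result = degen4dtv.compute_4dtv(pair)
            assert result.n_4d_sites == row.n_4d_sites
            assert result.n_transversions == row.n_transversions

    def test_seed_reproducibility(self):
        a = simulate_codon_pairs(SubstitutionParams(0.003, 0.0015, 10), 10, 30, seed=9)
        b = simulate_codon_pairs(SubstitutionParams(0.003, 0.0015, 10), 10, 30, seed=9)
        assert [(p.seq_a, p.seq_b) for p in a.pairs] == \
            [(p.seq_a, p.seq_b) for p in b.pairs]

    def test_no_stop_codons_in_ancestral_frame(self):
        sim = simulate_codon_pairs(SubstitutionParams(0.01, 0.01, 50), 20, 100, seed=5)
        stops = {"TAA", "TAG", "TGA"}
        for pair in sim.pairs:
            codons_a = {pair.seq_a[i:i + 3] for i in range(0, len(pair.seq_a), 3)}
            codons_b = {pair.seq_b[i:i + 3] for i in range(0, len(pair.seq_b), 3)}
            assert not (codons_a & stops) and not (codons_b & stops)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_pairs(SubstitutionParams(0.1, 0.1, 1), 0, 10, seed=0)
        with pytest.raises(ValueError):
            simulate_codon_pairs(SubstitutionParams(0.1, 0.1, 1), 5, 0, seed=0)


class TestWGDGenome:
    @staticmethod
    def _params():
        return {
            "wgd": SubstitutionParams(0.003, beta_for_target_4dtv(0.032, 5.8), 5.8),
            "ortholog": SubstitutionParams(
                0.003, beta_for_target_4dtv(0.081, 18.0), 18.0),
            "background": SubstitutionParams(
                0.003, beta_for_target_4dtv(0.38, 70.0), 70.0),
        }

    def test_tandem_triplets_share_homeolog_at_adjacent_ranks(self):
        spec = WGDCohortSpec(
            n_pairs_wgd=10, n_pairs_ortholog=0, n_pairs_background=0,
            n_tandem_triplets=2, seq_len_codons=30, seed=11,
        )
        sim = simulate_wgd_genome(spec, self._params())
        shared = sim.pair_table.groupby("gene_b").size()
        groups = shared[shared >= 2]
        assert len(groups) == 2
        pos = sim.positions.set_index("gene")
        for homeolog in groups.index:
            partners = sim.pair_table.loc[
                sim.pair_table["gene_b"] == homeolog, "gene_a"
            ]
            ranks = sorted(pos.loc[partners, "rank"])
            assert ranks == list(range(ranks[0], ranks[0] + len(ranks)))

    def test_empty_cohort_absent(self):
        spec = WGDCohortSpec(
            n_pairs_wgd=8, n_pairs_ortholog=0, n_pairs_background=8,
            seq_len_codons=20, seed=1,
        )
        sim = simulate_wgd_genome(spec, self._params())
        assert "ortholog" not in set(sim.pair_table["cohort_label"])

    def test_anchor_blocks_meet_minimum_size(self):
        spec = WGDCohortSpec(
            n_pairs_wgd=23, n_pairs_ortholog=7, n_pairs_background=5,
            seq_len_codons=20, seed=2,
        )
        sim = simulate_wgd_genome(spec, self._params())
        assert (sim.anchors.groupby("block_id").size() >= 5).all()
        assert len(sim.anchors) == len(sim.pair_table)

    def test_single_params_applied_to_all_cohorts(self):
        spec = WGDCohortSpec(
            n_pairs_wgd=5, n_pairs_ortholog=5, n_pairs_background=5,
            seq_len_codons=20, seed=3,
        )
        sim = simulate_wgd_genome(spec, SubstitutionParams(0.003, 0.0015, 1.0))
        assert set(sim.pair_table["cohort_label"]) == {
            "wgd", "ortholog", "background"
        }

    def test_write_round_trip(self, tmp_path):
        spec = WGDCohortSpec(
            n_pairs_wgd=6, n_pairs_ortholog=0, n_pairs_background=6,
            n_tandem_triplets=1, seq_len_codons=20, seed=4,
        )
        sim = simulate_wgd_genome(spec, self._params())
        sim.write(tmp_path)
        from Bio import SeqIO

        seqs = {r.id: str(r.seq) for r in SeqIO.parse(tmp_path / "sequences.fasta", "fasta")}
        assert seqs == sim.sequences
        pairs = pd.read_csv(tmp_path / "pairs.tsv", sep="\t")
        assert len(pairs) == len(sim.pair_table)


class TestRILSimulator:
    def test_f2_marginals(self):
        cfg = RILSimConfig(n_lines=5000, n_markers=10, generation=2, seed=1)
        pop = simulate_ril_population(cfg)
        freqs = [(pop.genotypes == g).mean() for g in (0, 1, 2)]
        assert freqs == pytest.approx([0.25, 0.5, 0.25], abs=0.02)

    def test_f6_heterozygote_fraction(self):
        # 31:2:31 expectation: pooled het fraction ~ 2/64
        cfg = RILSimConfig(n_lines=132, n_markers=2000, generation=6, seed=2)
        pop = simulate_ril_population(cfg)
        n = pop.genotypes.size
        p = 2 / 64
        se = math.sqrt(p * (1 - p) / n)
        assert abs((pop.genotypes == 1).mean() - p) < 3 * se

    def test_all_missing(self):
        cfg = RILSimConfig(n_lines=10, n_markers=20, missing_rate=1.0, seed=3)
        pop = simulate_ril_population(cfg)
        assert (pop.genotypes == -1).all()

    def test_marginals_survive_linkage(self):
        cfg = RILSimConfig(
            n_lines=2000, n_markers=200, generation=6, linkage=0.1, seed=4
        )
        pop = simulate_ril_population(cfg)
        exp = expected_genotype_proportions(6)
        freqs = [(pop.genotypes == g).mean() for g in (0, 1, 2)]
        assert freqs == pytest.approx(list(exp.proportions), abs=0.01)
        # and adjacent markers really are correlated
        same = (pop.genotypes[1:] == pop.genotypes[:-1]).mean()
        assert same > 0.85

    def test_null_marginals_chi2_calibration(self):
        # pooled genotype counts fit the F_g expectation across seeds
        from millet_evol.rilfilter import segregation_chi2

        exp = expected_genotype_proportions(6)
        failures = 0
        for seed in range(20):
            cfg = RILSimConfig(n_lines=132, n_markers=500, generation=6, seed=seed)
            pop = simulate_ril_population(cfg)
            counts = [(pop.genotypes == g).sum() for g in (0, 1, 2)]
            _, p = segregation_chi2(
                np.array([counts[0]]), np.array([counts[1]]),
                np.array([counts[2]]), exp,
            )
            if p[0] <= 0.001:
                failures += 1
        assert failures <= 1

    def test_distortion_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            RILSimConfig(distortion_proportions=(0.5, 0.2, 0.2))

    def test_vcf_round_trip_with_parents(self, tmp_path):
        from cyvcf2 import VCF

        cfg = RILSimConfig(n_lines=20, n_markers=30, missing_rate=0.1, seed=5)
        pop = simulate_ril_population(cfg)
        path = tmp_path / "ril.vcf"
        pop.write_vcf(path, include_parents=True)
        vcf = VCF(str(path))
        assert vcf.samples[:2] == ["P1", "P2"]
        records = list(vcf)
        assert len(records) == 30
        assert all(v.QUAL == 999.0 for v in records)

    def test_seed_reproducibility(self, tmp_path):
        cfg = RILSimConfig(n_lines=12, n_markers=40, missing_rate=0.2,
                           error_rate=0.05, seed=6)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        simulate_ril_population(cfg).write_vcf(p1)
        simulate_ril_population(cfg).write_vcf(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestExpressionSimulator:
    def test_high_concentration_is_near_uniform(self):
        cfg = ExpressionSimConfig(
            family_sizes={1: 200}, n_tissues=8, specificity=1e6, seed=1
        )
        expr, _ = simulate_expression_families(cfg)
        ent = entropy_table(expr)
        assert ent["H"].mean() == pytest.approx(3.0, abs=0.01)

    def test_lower_specificity_means_lower_entropy(self):
        means = {}
        for spec in (0.1, 10.0):
            cfg = ExpressionSimConfig(
                family_sizes={1: 200}, n_tissues=8, specificity=spec, seed=2
            )
            expr, _ = simulate_expression_families(cfg)
            means[spec] = entropy_table(expr)["H"].mean()
        assert means[0.1] < means[10.0]

    def test_family_size_classes_respected(self):
        cfg = ExpressionSimConfig(family_sizes={1: 50}, n_tissues=4, seed=3)
        expr, families = simulate_expression_families(cfg)
        assert families["family_id"].nunique() == 50
        assert (families.groupby("family_id").size() == 1).all()
        assert len(expr) == 50

    def test_reproducibility(self):
        cfg = ExpressionSimConfig(seed=4)
        e1, f1 = simulate_expression_families(cfg)
        e2, f2 = simulate_expression_families(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(f1, f2)


class TestDomainTable:
    def test_architectures_realized_in_order(self):
        table = simulate_domain_table([(("MATH", "BTB", "BACK"), 3)], seed=1)
        assert table["protein"].nunique() == 3
        for _, sub in table.groupby("protein"):
            assert list(sub.sort_values("start")["domain"]) == ["MATH", "BTB", "BACK"]

    def test_empty_spec_gives_empty_table_with_header(self):
        table = simulate_domain_table([], seed=1)
        assert len(table) == 0
        assert list(table.columns) == [
            "protein", "species", "domain", "start", "end", "evalue"
        ]

    def test_evalues_below_cutoff(self):
        table = simulate_domain_table([(("BTB",), 50)], seed=2, evalue_cutoff=1e-5)
        assert (table["evalue"] < 1e-5).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="WD40"):
            simulate_domain_table([(("BTB", "WD40"), 1)], seed=1)

    def test_vocabulary_is_shared_with_classifier(self):
        assert "BTB" in DOMAIN_VOCABULARY and "F5_F8" in DOMAIN_VOCABULARY
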