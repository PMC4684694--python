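"""The cohort simulator: seed contracts, base composition, planted signals."""

import numpy as np
import pytest
from scipy import stats

from polarix.protein_consequence import GENETIC_CODE, SYNONYMOUS_FAMILY, cds_codons
from polarix.synthetic_data import (
    draw_optimal_codons,
    simulate_expression,
    simulate_gene_annotations,
    simulate_snps,
    simulate_transcriptome,
)


class TestTranscriptome:
    def test_cds_structure(self):
        txs = simulate_transcriptome(5, mean_cds_codons=10, seed=0)
        for tx in txs.values():
            codons = cds_codons(tx)
            assert codons[0] == "ATG"
            assert GENETIC_CODE[codons[-1]] == "*"
            assert all(GENETIC_CODE[c] != "*" for c in codons[:-1])
            assert (tx.cds[1] - tx.cds[0]) % 3 == 0
            assert 1 <= len(tx.exon_ends) <= 4

    def test_gc_concentration(self):
        txs = simulate_transcriptome(120, mean_cds_codons=200, gc=0.5, seed=1)
        bases = "".join(tx.seq for tx in txs.values())
        assert len(bases) > 1e5
        gc = sum(b in "GC" for b in bases) / len(bases)
        assert 0.49 < gc < 0.51

    def test_gc_parameter_respected(self):
        txs = simulate_transcriptome(40, mean_cds_codons=200, gc=0.7, seed=2)
        bases = "".join(tx.seq for tx in txs.values())
        gc = sum(b in "GC" for b in bases) / len(bases)
        assert 0.68 < gc < 0.72

    def test_seed_contract(self):
        a = simulate_transcriptome(10, seed=5)
        b = simulate_transcriptome(10, seed=5)
        assert all(a[k].seq == b[k].seq for k in a)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_transcriptome(0)
        with pytest.raises(ValueError):
            simulate_transcriptome(1, gc=1.5)


class TestExpression:
    def test_zero_bias_is_uniform_within_family(self):
        txs = simulate_transcriptome(150, mean_cds_codons=150, seed=3)
        optimal = draw_optimal_codons(3)
        _, rewritten = simulate_expression(txs, optimal, bias_strength=0.0, seed=4)
        # pooled usage of the designated codon should match 1/family-size
        for aa in ("L", "A", "G"):
            fam = SYNONYMOUS_FAMILY[aa]
            counts = {c: 0 for c in fam}
            for tx in rewritten.values():
                for c in cds_codons(tx):
                    if c in counts:
                        counts[c] += 1
            total = sum(counts.values())
            frac = counts[optimal[aa]] / total
            se = np.sqrt((1 / len(fam)) * (1 - 1 / len(fam)) / total)
            assert frac == pytest.approx(1 / len(fam), abs=5 * se)

    def test_bias_separates_expression_quintiles(self):
        txs = simulate_transcriptome(500, mean_cds_codons=150, seed=5)
        optimal = draw_optimal_codons(5)
        expr, rewritten = simulate_expression(txs, optimal, bias_strength=2.0, seed=6)
        gm = np.exp(np.log(expr + 1).mean(axis=1)).sort_values()
        lo, hi = list(gm.index[:100]), list(gm.index[-100:])
        by_gene = {tx.gene_id: tx for tx in rewritten.values()}

        def optimal_fraction(genes):
            used = opportunities = 0
            for g in genes:
                for c in cds_codons(by_gene[g]):
                    aa = GENETIC_CODE[c]
                    if aa != "*" and len(SYNONYMOUS_FAMILY[aa]) > 1:
                        opportunities += 1
                        used += c == optimal[aa]
            return used / opportunities

        assert optimal_fraction(hi) > optimal_fraction(lo)

    def test_seed_contract_and_protein_preserved(self):
        txs = simulate_transcriptome(20, seed=7)
        optimal = draw_optimal_codons(7)
        e1, r1 = simulate_expression(txs, optimal, seed=8)
        e2, r2 = simulate_expression(txs, optimal, seed=8)
        assert e1.equals(e2)
        assert all(r1[k].seq == r2[k].seq for k in r1)
        # synonymous rewriting must not change the protein
        for k in txs:
            assert [GENETIC_CODE[c] for c in cds_codons(txs[k])] == [
                GENETIC_CODE[c] for c in cds_codons(r1[k])
            ]

    def test_negative_bias_rejected(self):
        txs = simulate_transcriptome(5, seed=9)
        with pytest.raises(ValueError):
            simulate_expression(txs, draw_optimal_codons(9), bias_strength=-1)


class TestSNPs:
    def test_independence_when_s_zero(self, small_transcriptome):
        records, _, truth = simulate_snps(
            small_transcriptome, 20000, daf_params=(0.25, 0.0), seed=10
        )
        daf = np.array([r.alt_freq for r in records])
        x = np.array([truth.effect_by_snp[r.snp_id] for r in records])
        rho, _ = stats.spearmanr(daf, x)
        assert abs(rho) < 0.02

    def test_planted_negative_coupling(self, small_transcriptome):
        records, _, truth = simulate_snps(
            small_transcriptome, 20000, daf_params=(0.25, 2.0), seed=11
        )
        daf = np.array([r.alt_freq for r in records])
        x = np.array([truth.effect_by_snp[r.snp_id] for r in records])
        rho, p = stats.spearmanr(daf, x)
        assert rho < 0 and p < 1e-6

    def test_alt_is_derived_and_ref_ancestral(self, small_transcriptome):
        records, _, _ = simulate_snps(small_transcriptome, 500, seed=12)
        for r in records:
            assert r.ancestral == r.ref
            assert r.alts[0] != r.ref
            tx = small_transcriptome[r.chrom_or_tx_id]
            assert tx.seq[r.pos - 1] == r.ref

    def test_transition_fraction(self, small_transcriptome):
        records, _, _ = simulate_snps(small_transcriptome, 30000, seed=13)
        ts = {"AG", "GA", "CT", "TC"}
        frac = np.mean([(r.ref + r.alts[0]) in ts for r in records])
        assert frac == pytest.approx(2 / 3, abs=0.01)

    def test_corner_labels(self, small_transcriptome):
        records, ann, truth = simulate_snps(
            small_transcriptome, 5000, corner_fraction=0.02, seed=14
        )
        labels = truth.corner_labels
        n_corner = sum(v != "none" for v in labels.values())
        assert n_corner == int(0.02 * 5000)
        age = ann.set_index("snp_id")["age_ky"]
        daf = {r.snp_id: r.alt_freq for r in records}
        for sid, lab in labels.items():
            if lab == "quick":
                assert age[sid] < 300 and daf[sid] > 0.8
            elif lab == "slow":
                assert age[sid] > 700 and daf[sid] < 0.2
        # and the null case
        _, _, truth0 = simulate_snps(small_transcriptome, 500, corner_fraction=0.0, seed=15)
        assert set(truth0.corner_labels.values()) == {"none"}

    def test_score_tracks_daf(self, small_transcriptome):
        records, ann, truth = simulate_snps(small_transcriptome, 5000, seed=16)
        daf = np.array([r.alt_freq for r in records])
        rho, p = stats.spearmanr(daf, ann["cons_score"])
        assert rho < -0.3 and p < 1e-10

    def test_seed_contract(self, small_transcriptome):
        a = simulate_snps(small_transcriptome, 200, seed=17)
        b = simulate_snps(small_transcriptome, 200, seed=17)
        assert [r.snp_id for r in a[0]] == [r.snp_id for r in b[0]]
        assert a[1].equals(b[1])
        assert a[2].effect_by_snp == b[2].effect_by_snp


class TestGeneAnnotations:
    def test_penalty_off_is_null(self, small_transcriptome):
        table, mult = simulate_gene_annotations(small_transcriptome, seed=18, penalty=1.0)
        assert set(mult.values()) == {1.0}
        assert (table["omega_mouse"] > 0).all()

    def test_penalty_lowers_daf_of_flagged_genes(self, small_transcriptome):
        table, mult = simulate_gene_annotations(small_transcriptome, seed=19, penalty=2.0)
        records, _, _ = simulate_snps(
            small_transcriptome, 20000, seed=20, gene_s_multiplier=mult
        )
        flagged = {g for g, m in mult.items() if m > 1}
        by_gene = {t.tx_id: t.gene_id for t in small_transcriptome.values()}
        daf = np.array([r.alt_freq for r in records])
        is_flagged = np.array([by_gene[r.chrom_or_tx_id] in flagged for r in records])
        stat, p = stats.mannwhitneyu(daf[is_flagged], daf[~is_flagged])
        assert p < 0.01
        assert np.median(daf[is_flagged]) < np.median(daf[~is_flagged])

    def test_seed_contract(self, small_transcriptome):
        a = simulate_gene_annotations(small_transcriptome, seed=21)
        b = simulate_gene_annotations(small_transcriptome, seed=21)
        assert a[0].equals(b[0]) and a[1] == b[1]
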