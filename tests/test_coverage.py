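"""Coverage stamping, metagene matrices, travelling ratio, normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from bipair import (AnalysisConfig, CoverageTrack, MetageneLayout,
                    RefpointLayout, metagene_refpoint, metagene_scaled,
                    normalize_polii, pausing_index, select_unchanged_genes,
                    tss_anchors)

from conftest import make_gene

CHROMS = {"chr1": 100_000}


def frag(chrom, start, end, strand="+"):
    return {"chrom": chrom, "start": start, "end": end, "strand": strand}


class TestFragmentsToCoverage:
    def test_single_read_extension(self):
        frags = pd.DataFrame([frag("chr1", 100, 150)])
        t = CoverageTrack.from_fragments(frags, CHROMS, extend=150)
        assert t.window_sum("chr1", 100, 250) == 150
        assert t.window_sum("chr1", 0, 100) == 0
        assert t.window_sum("chr1", 250, 300) == 0

    def test_minus_strand_extends_upstream(self):
        frags = pd.DataFrame([frag("chr1", 500, 550, "-")])
        t = CoverageTrack.from_fragments(frags, CHROMS, extend=150)
        assert t.window_sum("chr1", 400, 550) == 150
        assert t.data["chr1"][399] == 0

    def test_additivity(self):
        frags = pd.DataFrame([frag("chr1", 100, 150)] * 2)
        t = CoverageTrack.from_fragments(frags, CHROMS)
        assert (t.data["chr1"][100:150] == 2).all()

    def test_matches_per_read_stamping_oracle_and_conserves_mass(self):
        rng = np.random.default_rng(8)
        starts = rng.integers(0, 90_000, 500)
        lens = rng.integers(20, 200, 500)
        frags = pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + lens,
            "strand": np.where(rng.random(500) < 0.5, "+", "-")})
        t = CoverageTrack.from_fragments(frags, CHROMS)
        oracle = np.zeros(100_000)
        for s, e in zip(frags.start, frags.end):
            oracle[s:e] += 1
        assert np.array_equal(t.data["chr1"], oracle)
        assert t.total() == lens.sum()

    def test_strand_selection(self):
        frags = pd.DataFrame([frag("chr1", 0, 10, "+"),
                              frag("chr1", 0, 10, "-")])
        t = CoverageTrack.from_fragments(frags, CHROMS, strand="+")
        assert t.total() == 10

    def test_clipping_at_chromosome_end(self):
        frags = pd.DataFrame([frag("chr1", 99_990, 100_050)])
        t = CoverageTrack.from_fragments(frags, CHROMS)
        assert t.total() == 10

    def test_bedgraph_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        starts = rng.integers(0, 9_000, 50)
        frags = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + 80, "strand": "+"})
        t = CoverageTrack.from_fragments(frags, {"chr1": 10_000}, strand="+")
        path = tmp_path / "x.bedgraph"
        t.to_bedgraph(str(path))
        back = CoverageTrack.from_bedgraph(str(path), {"chr1": 10_000})
        assert np.array_equal(t.data["chr1"], back.data["chr1"])
        assert back.strand == "+"


class TestMetageneScaled:
    def test_constant_track_gives_constant_matrix(self):
        t = CoverageTrack(CHROMS)
        t.data["chr1"][:] = 7.0
        genes = [make_gene("a", "chr1", "+", 5000, 9000),
                 make_gene("b", "chr1", "-", 20_000, 26_000)]
        m = metagene_scaled(t, genes)
        assert m.shape == (2, 350)
        assert np.allclose(m.to_numpy(), 7.0)

    def test_identity_when_body_is_already_target_length(self):
        layout = MetageneLayout()
        rng = np.random.default_rng(1)
        t = CoverageTrack(CHROMS)
        t.data["chr1"] = rng.random(100_000)
        g = make_gene("g", "chr1", "+", 10_000, 12_000)  # body exactly 500
        m = metagene_scaled(t, [g])
        direct = t.window("chr1", 9_000, 12_500)
        expected = direct.reshape(-1, layout.bin).mean(axis=1)
        assert np.allclose(m.to_numpy()[0], expected)

    def test_triangular_profile_matches_interpolation_oracle(self):
        layout = MetageneLayout()
        t = CoverageTrack(CHROMS)
        g = make_gene("g", "chr1", "+", 10_000, 18_000)
        body_lo, body_hi = 11_000, 17_500
        ramp = np.linspace(0.0, 100.0, body_hi - body_lo)
        t.data["chr1"][body_lo:body_hi] = ramp
        m = metagene_scaled(t, [g]).to_numpy()[0]
        # body occupies bins [200, 250); oracle = dense linear resampling
        oracle = np.interp(np.linspace(0, 1, layout.body),
                           np.linspace(0, 1, len(ramp)), ramp)
        oracle_bins = oracle.reshape(-1, layout.bin).mean(axis=1)
        body = m[200:250]
        assert np.abs(body - oracle_bins).max() < (100.0 / len(ramp)) * layout.bin

    def test_minus_strand_orientation(self):
        t = CoverageTrack(CHROMS)
        g = make_gene("g", "chr1", "-", 20_000, 26_000)
        t.data["chr1"][25_990:26_000] = 5.0  # at the TSS of the minus gene
        m = metagene_scaled(t, [g]).to_numpy()[0]
        tss_bin = 100  # first bin after the upstream flank
        assert m[tss_bin] == 5.0
        assert m[:tss_bin].sum() == 0

    def test_linearity(self):
        rng = np.random.default_rng(2)
        t1, t2 = CoverageTrack(CHROMS), CoverageTrack(CHROMS)
        t1.data["chr1"] = rng.random(100_000)
        t2.data["chr1"] = rng.random(100_000)
        combo = CoverageTrack(CHROMS)
        combo.data["chr1"] = 3.0 * t1.data["chr1"] + t2.data["chr1"]
        genes = [make_gene("g", "chr1", "+", 10_000, 16_000)]
        m = metagene_scaled(combo, genes).to_numpy()
        m12 = (3.0 * metagene_scaled(t1, genes).to_numpy()
               + metagene_scaled(t2, genes).to_numpy())
        assert np.allclose(m, m12)

    def test_short_genes_dropped(self):
        t = CoverageTrack(CHROMS)
        m = metagene_scaled(t, [make_gene("s", "chr1", "+", 0, 1200)])
        assert len(m) == 0


class TestMetageneRefpoint:
    def test_delta_signal_lands_in_central_bin(self):
        t = CoverageTrack(CHROMS)
        t.data["chr1"][5_000] = 1.0
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [5_000],
                                "strand": ["+"], "name": ["a"]})
        m = metagene_refpoint(t, anchors, RefpointLayout(b=500, a=500, bin=1))
        row = m.to_numpy()[0]
        assert row[500] == 1.0 and row.sum() == 1.0

    def test_minus_anchor_mirrors_plus(self):
        t = CoverageTrack(CHROMS)
        t.data["chr1"][4_000:4_100] = 2.0  # asymmetric: left of pos 5000
        plus = pd.DataFrame({"chrom": ["chr1"], "pos": [5_000],
                             "strand": ["+"], "name": ["p"]})
        minus = pd.DataFrame({"chrom": ["chr1"], "pos": [5_000],
                              "strand": ["-"], "name": ["m"]})
        layout = RefpointLayout(b=1500, a=1500, bin=1)
        mp = metagene_refpoint(t, plus, layout).to_numpy()[0]
        mm = metagene_refpoint(t, minus, layout).to_numpy()[0]
        assert np.array_equal(mm, mp[::-1])

    def test_off_chromosome_zero_padded(self):
        t = CoverageTrack(CHROMS)
        t.data["chr1"][:] = 1.0
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                                "strand": ["+"], "name": ["a"]})
        m = metagene_refpoint(t, anchors, RefpointLayout(b=500, a=500, bin=1))
        row = m.to_numpy()[0]
        assert row[:400].sum() == 0 and (row[400:] == 1).all()

    def test_matches_direct_slicing_oracle(self):
        rng = np.random.default_rng(4)
        t = CoverageTrack(CHROMS)
        t.data["chr1"] = rng.random(100_000)
        pos = rng.integers(2_000, 90_000, 20)
        anchors = pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+",
                                "name": [f"a{i}" for i in range(20)]})
        m = metagene_refpoint(t, anchors, RefpointLayout(b=500, a=500, bin=1))
        for i, p in enumerate(pos):
            assert np.array_equal(m.to_numpy()[i], t.data["chr1"][p - 500:p + 500])


class TestPausingIndex:
    def test_uniform_coverage_closed_form(self):
        """Uniform density: TR = window / (length - window)."""
        t = CoverageTrack(CHROMS)
        t.data["chr1"][:] = 4.0
        g = make_gene("g", "chr1", "+", 1000, 3750)  # length 2750
        tr = pausing_index(t, [g]).travelling_ratio.iloc[0]
        assert tr == pytest.approx(250 / 2500)

    def test_minus_strand_promoter_at_span_end(self):
        t = CoverageTrack(CHROMS)
        g = make_gene("g", "chr1", "-", 1000, 4000)
        t.data["chr1"][3750:4000] = 1.0  # promoter-proximal on minus strand
        t.data["chr1"][1000:3750] = 0.5
        row = pausing_index(t, [g]).iloc[0]
        assert row.promoter_count == 250
        assert row.body_count == 0.5 * 2750

    def test_all_signal_in_promoter_flagged_infinite(self):
        t = CoverageTrack(CHROMS)
        g = make_gene("g", "chr1", "+", 1000, 4000)
        t.data["chr1"][1000:1250] = 2.0
        row = pausing_index(t, [g]).iloc[0]
        assert np.isinf(row.travelling_ratio) and row.body_zero

    def test_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(6)
        t = CoverageTrack(CHROMS)
        t.data["chr1"] = rng.random(100_000)
        g = make_gene("g", "chr1", "+", 1000, 9000)
        tr1 = pausing_index(t, [g]).travelling_ratio.iloc[0]
        t.data["chr1"] *= 17.0
        tr2 = pausing_index(t, [g]).travelling_ratio.iloc[0]
        assert tr1 == pytest.approx(tr2)

    def test_short_gene_excluded(self):
        t = CoverageTrack(CHROMS)
        assert len(pausing_index(t, [make_gene("s", "chr1", "+", 0, 200)])) == 0

    def test_planted_tr_recovered(self, sim_study):
        """Generator truth: recovered TR tracks the planted TR."""
        genes, truth = sim_study["genes"], sim_study["truth"]
        cov = sim_study["control"]["coverage"]
        parts = [pausing_index(cov[s], [g for g in genes if g.strand == s])
                 for s in ("+", "-")]
        tab = pd.concat(parts).merge(truth, on="gene_id")
        ok = tab[np.isfinite(tab.travelling_ratio) & (tab.true_expression > 50)]
        rho = spearmanr(ok.travelling_ratio, ok.true_TR).statistic
        assert rho > 0.95


def peaked_track(genes, scale=1.0, offset=0.0, seed=0):
    """Pol II-like track: promoter peak + gene-body plateau + noise."""
    rng = np.random.default_rng(seed)
    t = CoverageTrack(CHROMS)
    t.data["chr1"] = rng.random(100_000) * 0.1 + 1.0
    for g in genes:
        t.data["chr1"][g.start:g.start + 300] += 8.0
        t.data["chr1"][g.start:g.end] += 1.0
    t.data["chr1"] = t.data["chr1"] * scale + offset
    return t


class TestNormalizePolii:
    @pytest.fixture
    def ref_genes(self):
        return [make_gene(f"g{i}", "chr1", "+", 2000 + i * 6000,
                          2000 + i * 6000 + 2500) for i in range(12)]

    def test_self_normalization_tss_mean_is_one(self, ref_genes):
        m = metagene_scaled(peaked_track(ref_genes), ref_genes)
        n = normalize_polii(m, [g.gene_id for g in ref_genes])
        layout = m.attrs["layout"]
        tss = layout.upstream // layout.bin
        k = 1000 // layout.bin
        assert n.iloc[:, tss - k:tss + k].to_numpy().mean() == \
               pytest.approx(1.0, abs=1e-9)

    def test_shift_and_scale_invariance(self, ref_genes):
        ids = [g.gene_id for g in ref_genes]
        n1 = normalize_polii(metagene_scaled(peaked_track(ref_genes),
                                             ref_genes), ids)
        n2 = normalize_polii(metagene_scaled(
            peaked_track(ref_genes, scale=3.5, offset=2.0), ref_genes), ids)
        assert np.abs(n1.to_numpy() - n2.to_numpy()).max() < 1e-9

    def test_idempotent_reapplication(self, ref_genes):
        ids = [g.gene_id for g in ref_genes]
        n = normalize_polii(metagene_scaled(peaked_track(ref_genes),
                                            ref_genes), ids)
        n2 = normalize_polii(n, ids)
        assert n2.attrs["normalization"]["beta"] == pytest.approx(0.0, abs=1e-12)
        assert n2.attrs["normalization"]["mu"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(n.to_numpy(), n2.to_numpy())

    def test_too_few_reference_genes_raises(self, ref_genes):
        m = metagene_scaled(peaked_track(ref_genes), ref_genes)
        with pytest.raises(ValueError, match=">= 10"):
            normalize_polii(m, [g.gene_id for g in ref_genes[:5]])


class TestSelectUnchangedGenes:
    def _de(self, fc, padj, expr=None):
        n = len(fc)
        return pd.DataFrame({
            "gene_id": [f"g{i:03d}" for i in range(n)],
            "mean_expression": expr if expr is not None else [10.0] * n,
            "log2FC": fc, "padj": padj})

    def test_all_null_ties_broken_by_gene_id(self):
        de = self._de([0.0] * 10, [1.0] * 10)
        assert select_unchanged_genes(de, 3) == ["g000", "g001", "g002"]

    def test_changed_gene_excluded(self):
        de = self._de([0.0, 2.0, 0.0], [1.0, 1e-9, 1.0])
        assert "g001" not in select_unchanged_genes(de, 3)

    def test_ranked_by_expression(self):
        de = self._de([0.0] * 4, [1.0] * 4, expr=[1.0, 50.0, 10.0, 5.0])
        assert select_unchanged_genes(de, 2) == ["g001", "g002"]

    def test_selection_hits_true_nulls(self, sim_study):
        """On simulated DE the selection stays inside the planted nulls."""
        truth = sim_study["truth"].set_index("gene_id")
        chosen = select_unchanged_genes(sim_study["de"], 50)
        true_fc = truth.loc[chosen, "true_log2FC"]
        assert (true_fc == 0.0).mean() >= 0.99
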