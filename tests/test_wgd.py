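"""Block classification, multiplicity, Ks peaks, dating and karyotype painting."""

import numpy as np
import pytest

from wgdkit import (Calibration, InsufficientDataError, chain_anchors, classify_blocks,
                    date_event, detect_ks_peaks, estimate_ks, infer_multiplicity,
                    paint_karyotype)
from wgdkit.io import GeneModel, Genome
from wgdkit.simulate import (WGDScenario, ancestral_gene_map, evolve_cds_pair,
                             simulate_wgd_genome)
from wgdkit.synteny import SyntenyBlock
from wgdkit.wgd import KsEstimate, KsPeak, block_ks_distribution


def _ref_genome(n=40, chrom="r1"):
    return Genome("ref", [GeneModel(f"r{i}", chrom, i * 100 + 1, i * 100 + 50)
                          for i in range(n)])


def _block(bid, ranks, ref_start=0, chrom_b="f1"):
    pairs = [(f"r{ref_start + i}", f"f{bid}_{i}", r) for i, r in enumerate(ranks)]
    return SyntenyBlock(bid, "ref", "r1", "focal", chrom_b, pairs, "same")


class TestClassifyBlocks:
    def test_isolated_majority_rank_one_is_orthologous(self):
        ref = _ref_genome()
        blocks = classify_blocks([_block("a", [1, 1, 1, 2, 1])], ref)
        assert blocks[0].block_class == "orthologous"

    def test_isolated_majority_secondary_is_outparalogous(self):
        ref = _ref_genome()
        blocks = classify_blocks([_block("a", [2, 2, 3, 2])], ref)
        assert blocks[0].block_class == "outparalogous"

    def test_competing_blocks_split_by_mean_rank(self):
        """Two homeolog copies sharing rank 1/2 both read orthologous; the
        older outparalog block over the same span does not."""
        ref = _ref_genome()
        b1 = _block("a", [1, 2, 1, 2, 1, 2], chrom_b="f1")
        b2 = _block("b", [2, 1, 2, 1, 2, 1], chrom_b="f2")
        b3 = _block("c", [3, 4, 3, 4, 3, 4], chrom_b="f3")
        labeled = classify_blocks([b1, b2, b3], ref)
        assert [b.block_class for b in labeled] == \
            ["orthologous", "orthologous", "outparalogous"]

    def test_missing_ranks_rejected(self):
        ref = _ref_genome()
        bad = SyntenyBlock("x", "ref", "r1", "focal", "f1", [("r0", "f0", None)], "same")
        with pytest.raises(ValueError, match="rank"):
            classify_blocks([bad], ref)


class TestMultiplicity:
    def test_single_best_matched_region_gives_modal_one(self):
        ref = _ref_genome()
        labeled = classify_blocks([_block("a", [1] * 20)], ref)
        rep = infer_multiplicity(labeled, ref, min_region_pairs=5)
        assert rep.modal_multiplicity == 1
        assert rep.inferred_extra_wgd_count == 0

    def test_fragmented_region_not_double_counted(self):
        """Two collinear fragments of one region on the same focal chromosome
        merge across a fractionation gap."""
        ref = _ref_genome()
        b1 = _block("a", [1] * 8, ref_start=0, chrom_b="f1")
        b2 = _block("b", [1] * 8, ref_start=20, chrom_b="f1")
        labeled = classify_blocks([b1, b2], ref)
        rep = infer_multiplicity(labeled, ref, min_region_pairs=5)
        assert rep.per_chromosome["r1"] == 1

    def test_one_extra_wgd_recovered_from_simulation(self, lossless_sim, lossless_hits):
        _, focal, reference, _ = lossless_sim
        blocks = chain_anchors(lossless_hits, reference, focal)
        labeled = classify_blocks(blocks, reference)
        rep = infer_multiplicity(labeled, reference, min_region_pairs=10)
        assert rep.modal_multiplicity == 2
        assert rep.inferred_extra_wgd_count == 1

    def test_two_stacked_wgds_give_modal_four(self):
        from wgdkit import find_homologs

        sc = WGDScenario(n_chromosomes=2, genes_per_chromosome=50, retention_prob=1.0,
                         extra_specific_wgds=1, seed=21)
        focal, reference, _ = simulate_wgd_genome(sc)
        hits = find_homologs(reference.proteins, focal.proteins)
        labeled = classify_blocks(chain_anchors(hits, reference, focal), reference)
        rep = infer_multiplicity(labeled, reference, min_region_pairs=10)
        assert rep.modal_multiplicity == 4
        assert rep.inferred_extra_wgd_count == 2

    def test_no_orthologous_blocks_rejected(self):
        ref = _ref_genome()
        labeled = classify_blocks([_block("a", [2, 2, 2, 2, 2, 2])], ref)
        with pytest.raises(InsufficientDataError):
            infer_multiplicity(labeled, ref)


class TestBlockKs:
    def _est(self, ga, gb, ks, saturated=False):
        return (ga, gb), KsEstimate(ga, gb, 0.1, ks, 100, 50, 1, 1,
                                    saturated_ks=saturated)

    def test_block_mean_is_arithmetic_mean(self):
        b = _block("a", [1, 1, 1])
        ests = dict([self._est("r0", "fa_0", 0.1), self._est("r1", "fa_1", 0.2),
                     self._est("r2", "fa_2", 0.3)])
        means, kept = block_ks_distribution([b], ests)
        assert means.tolist() == [pytest.approx(0.2)]
        assert kept[0].mean_ks == pytest.approx(0.2)

    def test_blocks_below_min_pairs_excluded(self):
        b = _block("a", [1, 1])
        ests = dict([self._est("r0", "fa_0", 0.1), self._est("r1", "fa_1", 0.2)])
        means, kept = block_ks_distribution([b], ests, min_pairs_for_mean=3)
        assert means.size == 0 and kept == []

    def test_all_saturated_warns_and_empties(self, caplog):
        b = _block("a", [1, 1, 1])
        ests = dict([self._est("r0", "fa_0", np.inf, True),
                     self._est("r1", "fa_1", np.inf, True),
                     self._est("r2", "fa_2", np.inf, True)])
        with caplog.at_level("WARNING"):
            means, _ = block_ks_distribution([b], ests)
        assert means.size == 0
        assert "saturated" in caplog.text


class TestKsPeaks:
    def test_single_event_mode_recovered(self, rng):
        means = []
        for _ in range(120):
            ks = [estimate_ks(*evolve_cds_pair(200, 0.5, seed=rng)[:2]).ks
                  for _ in range(4)]
            means.append(np.mean(ks))
        peaks = detect_ks_peaks(np.array(means))
        main = max(peaks, key=lambda p: p.weight)
        assert main.mode == pytest.approx(0.5, abs=0.05)

    def test_two_events_recovered_with_low_bias(self, rng):
        means = np.concatenate([
            np.exp(rng.normal(np.log(0.15), 0.10, size=250)),
            np.exp(rng.normal(np.log(0.50), 0.08, size=250))])
        peaks = detect_ks_peaks(means)
        assert peaks[0].n_components_selected == 2
        assert peaks[0].mode == pytest.approx(0.15, abs=0.03)
        assert peaks[-1].mode == pytest.approx(0.50, abs=0.05)
        for p in peaks:
            assert abs(p.mode - (0.15 if p is peaks[0] else 0.50)) < p.component_sd
            assert not p.kde_flag

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_ks_peaks(np.full(10, 0.3))

    def test_degenerate_identical_values(self):
        peaks = detect_ks_peaks(np.full(60, 0.4))
        assert len(peaks) == 1
        assert peaks[0].mode == pytest.approx(0.4, abs=0.01)


class TestDating:
    def test_calibration_identity(self):
        assert date_event(KsPeak(0.6, 1.0, 0.1, 1)) == pytest.approx(96.0)

    def test_proportional_scaling(self):
        cal = Calibration(0.6, 96.0)
        assert date_event(0.3, cal) == pytest.approx(48.0)
        assert date_event(0.15, cal) == pytest.approx(24.0)

    def test_linearity(self, rng):
        cal = Calibration(0.6, 96.0)
        for ks in rng.uniform(0.05, 1.0, size=10):
            assert date_event(2 * ks, cal) == pytest.approx(2 * date_event(ks, cal))

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            Calibration(0.0, 96.0)


class TestPainting:
    def _genome(self, labels_by_chrom):
        genes, amap = [], {}
        for chrom, labels in labels_by_chrom.items():
            for i, lab in enumerate(labels):
                gid = f"{chrom}_g{i}"
                genes.append(GeneModel(gid, chrom, i * 100 + 1, i * 100 + 50))
                if lab is not None:
                    amap[gid] = lab
        return Genome("t", genes), amap

    def test_uniform_chromosome_single_segment(self):
        genome, amap = self._genome({"c1": ["A"] * 30})
        painting = paint_karyotype(genome, amap)
        assert painting.labels_on("c1") == ["A"]
        assert painting.fusion_flags["c1"] is False

    def test_fusion_of_two_ancestral_chromosomes_flagged(self):
        genome, amap = self._genome({"c1": ["A"] * 25 + ["B"] * 25})
        painting = paint_karyotype(genome, amap)
        assert painting.labels_on("c1") == ["A", "B"]
        assert painting.fusion_flags["c1"] is True

    def test_sporadic_mislabels_absorbed(self):
        labels = ["A"] * 14 + ["B"] + ["A"] * 15
        genome, amap = self._genome({"c1": labels})
        painting = paint_karyotype(genome, amap)
        assert painting.labels_on("c1") == ["A"]

    def test_unmapped_chromosome_labelled_unassigned(self):
        genome, amap = self._genome({"c1": [None] * 20})
        painting = paint_karyotype(genome, amap)
        assert painting.labels_on("c1") == ["unassigned"]

    def test_planted_fusion_count_recovered_exactly(self):
        sc = WGDScenario(n_chromosomes=5, genes_per_chromosome=60, n_fusions=3,
                         retention_prob=0.9, with_sequences=False, seed=13)
        focal, _, truth = simulate_wgd_genome(sc)
        painting = paint_karyotype(focal, ancestral_gene_map(truth))
        assert painting.n_fused_chromosomes == 3
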