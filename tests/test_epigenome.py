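import numpy as np
import pytest

from anchorfill.epigenome import (
    chip_cluster_enrichment,
    methylation_frequency,
    summarize_regions,
)
from anchorfill.seqio import GenomicInterval


class TestMethylationFrequency:
    def test_site_frequency(self):
        calls = [("c", 10, f"r{i}", i < 5) for i in range(10)]
        sites = methylation_frequency(calls)
        assert len(sites) == 1
        assert sites[0].frequency == 0.5
        assert sites[0].total_reads == 10

    def test_duplicate_calls_keep_first(self, caplog):
        calls = [("c", 10, "r1", True), ("c", 10, "r1", False), ("c", 10, "r2", False)]
        with caplog.at_level("WARNING", logger="anchorfill"):
            sites = methylation_frequency(calls)
        assert sites[0].methylated_reads == 1 and sites[0].total_reads == 2
        assert "duplicate" in caplog.text

    def test_empty_input(self):
        assert methylation_frequency([]) == []

    def test_hypomethylated_block_recovered(self, default_bundle):
        # the simulator plants a high-frequency satellite block over a
        # lower background; check both planted levels are recovered
        sites = methylation_frequency(default_bundle.methylation_calls)
        region = default_bundle.satellite_region
        inside = [s.frequency for s in sites if region.start <= s.position < region.end]
        outside = [s.frequency for s in sites if not region.start <= s.position < region.end]
        cfg = default_bundle.config
        assert np.mean(inside) == pytest.approx(cfg.methylation_block, abs=0.05)
        assert np.mean(outside) == pytest.approx(cfg.methylation_background, abs=0.05)


class TestSummarizeRegions:
    def _sites(self, freqs, start=0):
        return methylation_frequency(
            [
                ("c", start + i, f"r{i}_{j}", j < round(f * 10))
                for i, f in enumerate(freqs)
                for j in range(10)
            ]
        )

    def test_mean_and_fraction_above(self):
        sites = self._sites([0.9, 0.7])
        [summary] = summarize_regions(sites, [GenomicInterval("c", 0, 10, ".", "r1")])
        assert summary.mean_frequency == pytest.approx(0.8)
        assert summary.fraction_sites_above_threshold == pytest.approx(0.5)

    def test_boundary_is_strict_inequality(self):
        sites = self._sites([0.8, 0.8, 0.8])
        [summary] = summarize_regions(sites, [GenomicInterval("c", 0, 10, ".", "r1")])
        assert summary.fraction_sites_above_threshold == 0.0

    def test_empty_region_flagged(self):
        sites = self._sites([0.5])
        [summary] = summarize_regions(sites, [GenomicInterval("c", 100, 200, ".", "r1")])
        assert summary.site_count == 0 and summary.flagged
        assert summary.mean_frequency is None

    def test_centromere_vs_pericentromere_ordering(self, default_bundle):
        b = default_bundle
        sites = methylation_frequency(b.methylation_calls)
        regions = [
            GenomicInterval("chrSim", b.satellite_region.start, b.satellite_region.end, ".", "cen"),
            GenomicInterval("chrSim", 2100, b.satellite_region.start, ".", "peri"),
        ]
        cen, peri = summarize_regions(sites, regions)
        assert cen.mean_frequency > peri.mean_frequency
        assert cen.fraction_sites_above_threshold > peri.fraction_sites_above_threshold


class TestChipEnrichment:
    def _uniform_reads(self, rng, n, length=10_000):
        return [
            GenomicInterval("c", s, s + 100)
            for s in rng.integers(0, length - 100, size=n).tolist()
        ]

    def _clusters(self):
        return [
            GenomicInterval("c", i * 2_000, i * 2_000 + 1_000, ".", str(i + 1))
            for i in range(4)
        ]

    def test_uniform_samples_ratio_near_one(self, rng):
        t = self._uniform_reads(rng, 20_000)
        c = self._uniform_reads(rng, 20_000)
        for s in chip_cluster_enrichment(t, c, self._clusters()):
            assert s.enrichment_ratio == pytest.approx(1.0, abs=0.15)

    def test_planted_cluster3_preference_recovered(self, chip_bundle):
        b = chip_bundle
        summaries = chip_cluster_enrichment(
            b.chip_treatment, b.chip_control, b.cluster_blocks
        )
        by_id = {s.region_id: s.enrichment_ratio for s in summaries}
        assert by_id["3"] == pytest.approx(3.0, rel=0.15)
        assert all(by_id[k] < by_id["3"] for k in "124")

    def test_scale_invariance(self, rng):
        t = self._uniform_reads(rng, 5_000)
        c = self._uniform_reads(rng, 5_000)
        regions = self._clusters()
        base = chip_cluster_enrichment(t, c, regions)
        tripled = chip_cluster_enrichment(t * 3, c * 3, regions)
        for a, b in zip(base, tripled):
            assert b.enrichment_ratio == pytest.approx(a.enrichment_ratio, rel=0.01)

    def test_count_conservation(self, rng):
        t = self._uniform_reads(rng, 3_000)
        c = self._uniform_reads(rng, 3_000)
        regions = self._clusters()
        summaries = chip_cluster_enrichment(t, c, regions)
        in_any = sum(
            1
            for r in t
            if any(
                reg.start <= (r.start + r.end) // 2 < reg.end for reg in regions
            )
        )
        assert sum(s.chip_treatment_count for s in summaries) == in_any

    def test_empty_region_uses_pseudocount(self, rng):
        t = self._uniform_reads(rng, 1_000, length=2_000)
        c = self._uniform_reads(rng, 1_000, length=2_000)
        regions = [
            GenomicInterval("c", 0, 2_000, ".", "hit"),
            GenomicInterval("c", 100_000, 101_000, ".", "empty"),
        ]
        summaries = {s.region_id: s for s in chip_cluster_enrichment(t, c, regions)}
        assert summaries["empty"].flagged
        assert summaries["empty"].enrichment_ratio == pytest.approx(1.0)

    def test_zero_reads_error(self):
        with pytest.raises(ValueError):
            chip_cluster_enrichment([], [GenomicInterval("c", 0, 10)], self._clusters())
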