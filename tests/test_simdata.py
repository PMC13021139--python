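"""Simulator invariants: determinism, alignment consistency, planted
distributions."""

import numpy as np
import pytest

from flare.cnvtf import GenomeBins, bin_reads, correct_gc
from flare.fragprofile import size_class_profile
from flare.ionmodel import Strand, parse_alignment_records
from flare.simdata import (LengthMixture, SimConfig, plant_markers,
                           simulate_cohort, simulate_pon, simulate_reference,
                           simulate_sample)


def small_config(**kw):
    defaults = dict(seed=5, n_chromosomes=2, chrom_length=600_000,
                    bin_width=100_000, depth=2000, n_markers=10)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestReference:
    def test_deterministic(self, tmp_path):
        config = small_config()
        fastas = []
        for rep in range(2):
            ref, _ = simulate_reference(config)
            p = tmp_path / f"r{rep}.fa"
            ref.write(p)
            fastas.append(p.read_bytes())
        assert fastas[0] == fastas[1]

    def test_chromosome_count(self):
        ref, _ = simulate_reference(small_config(n_chromosomes=3))
        assert len(ref.chromosomes()) == 3

    def test_gc_targets_realized(self):
        config = small_config(chrom_length=1_000_000, gc_range=(0.6, 0.6))
        ref, targets = simulate_reference(config)
        bins = GenomeBins.from_reference(ref, config.bin_width)
        assert np.all(np.abs(bins.frame["gc"].to_numpy() - 0.6) <= 0.02)

    def test_too_small_chromosome_rejected(self):
        with pytest.raises(ValueError):
            simulate_reference(small_config(chrom_length=10))


class TestSample:
    def test_sam_deterministic(self, tmp_path):
        config = small_config()
        outs = []
        for rep in range(2):
            rng = np.random.default_rng(config.seed)
            ref, _ = simulate_reference(config, rng)
            markers = plant_markers(config, ref)
            bins = GenomeBins.from_reference(ref, config.bin_width)
            p = tmp_path / f"s{rep}.sam"
            simulate_sample(config, ref, bins, 0.2, markers, "S", p, rng)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_parses_cleanly_and_alignment_consistent(self, small_sim):
        """Every simulated read parses without modification errors and its
        stored sequence equals the reference substring (exhaustive)."""
        from flare.endmotif import ReferenceAccessor

        ref = ReferenceAccessor(small_sim["fasta"])
        records = list(parse_alignment_records(small_sim["sam"]))
        assert len(records) == small_sim["config"].depth
        assert all(r.meth_calls is not None for r in records)
        for r in records:
            assert r.query_sequence == ref.fetch(r.chrom, r.ref_start,
                                                 r.ref_end)

    def test_mm_ml_round_trip(self, small_sim):
        """Parsed methylation probabilities are the 1/256 bin midpoints and
        agree with pysam's decoder on every read."""
        import pysam

        records = list(parse_alignment_records(small_sim["sam"]))
        n_with = 0
        with pysam.AlignmentFile(str(small_sim["sam"])) as fh:
            for rec, seg in zip(records, fh.fetch(until_eof=True)):
                if not rec.meth_calls:
                    continue
                n_with += 1
                ours = sorted((c.read_offset,
                               int(round(c.probability * 256 - 0.5)))
                              for c in rec.meth_calls)
                theirs = sorted((pos, qual)
                                for v in seg.modified_bases.values()
                                for pos, qual in v)
                assert ours == theirs
        assert n_with > 0

    def test_reverse_read_call_is_crick_cpg(self, small_sim):
        """Reverse-strand calls sit on the G of a CpG (the C of the
        opposite strand)."""
        from flare.endmotif import ReferenceAccessor

        ref = ReferenceAccessor(small_sim["fasta"])
        seen = 0
        for r in parse_alignment_records(small_sim["sam"]):
            if not r.meth_calls:
                continue
            for c in r.meth_calls:
                duplex = ref.fetch(r.chrom, c.genomic_pos - 1,
                                   c.genomic_pos + 2)
                if r.strand is Strand.REVERSE:
                    assert duplex[:2] == "CG"
                else:
                    assert duplex[1:] == "CG"
                seen += 1
        assert seen > 10

    def test_planted_length_mixture_recovered(self, tmp_path):
        """Size-class proportions at n=20,000 match the lognormal mixture's
        class masses within 0.02."""
        mixture = LengthMixture(weights=(0.3, 0.5, 0.2))
        config = small_config(depth=20_000, tumor_fraction=0.0,
                              normal_length_mixture=mixture)
        rng = np.random.default_rng(9)
        ref, _ = simulate_reference(config, rng)
        markers = plant_markers(config, ref)
        bins = GenomeBins.from_reference(ref, config.bin_width)
        p = tmp_path / "s.sam"
        simulate_sample(config, ref, bins, 0.0, markers, "S", p, rng)
        lengths = [r.query_length for r in parse_alignment_records(p)]
        prof = size_class_profile(lengths)
        for got, want in zip(prof.proportions, mixture.class_masses()):
            assert abs(got - want) <= 0.02

    def test_cnv_depth_profile_planted(self, tmp_path):
        """A c=3 gain at tumor fraction 0.5 raises that bin's expected
        depth by (2n+(1-n)c)/2 = 1.25."""
        config = small_config(depth=30_000, chrom_length=1_000_000,
                              n_chromosomes=1,
                              cnv_segments=[("chr1", 0, 500_000, 3)])
        rng = np.random.default_rng(13)
        ref, _ = simulate_reference(config, rng)
        markers = plant_markers(config, ref)
        bins = GenomeBins.from_reference(ref, config.bin_width)
        p = tmp_path / "s.sam"
        simulate_sample(config, ref, bins, 0.5, markers, "S", p, rng)
        counts, _ = bin_reads(parse_alignment_records(p), bins)
        gained = counts[:5].mean()
        neutral = counts[5:].mean()
        assert gained / neutral == pytest.approx(1.25, abs=0.08)


class TestPon:
    def test_flat_within_bound(self):
        config = small_config(depth=200_000, chrom_length=4_000_000)
        ref, _ = simulate_reference(config)
        bins = GenomeBins.from_reference(ref, config.bin_width)
        pon = simulate_pon(config, bins, n_normals=10)
        vals = pon["median_corrected_count"].to_numpy()
        assert np.ptp(vals) / vals.mean() <= 0.05

    def test_deterministic(self):
        config = small_config()
        ref, _ = simulate_reference(config)
        bins = GenomeBins.from_reference(ref, config.bin_width)
        a = simulate_pon(config, bins)
        b = simulate_pon(config, bins)
        assert a.equals(b)

    def test_single_normal_equals_its_corrected_counts(self):
        config = small_config()
        ref, _ = simulate_reference(config)
        bins = GenomeBins.from_reference(ref, config.bin_width)
        rng = np.random.default_rng(3)
        pon = simulate_pon(config, bins, n_normals=1,
                           rng=np.random.default_rng(3))
        w = np.ones(len(bins)) / len(bins)
        counts = rng.multinomial(config.depth, w).astype(float)
        corr, _ = correct_gc(counts, bins.frame["gc"].to_numpy())
        np.testing.assert_allclose(
            pon["median_corrected_count"].to_numpy(),
            np.nan_to_num(corr))


class TestCohort:
    def test_structure_and_manifest(self, tmp_path):
        config = small_config(depth=500)
        thetas = [(0.1, 0.05)] * 6
        paths = simulate_cohort(config, thetas, tmp_path / "cohort")
        import pandas as pd
        manifest = pd.read_csv(paths["manifest"], sep="\t")
        assert len(manifest) == 12
        assert set(manifest["condition"]) == {"C1D1", "C5D1"}
        for p in manifest["path"]:
            assert (tmp_path / "cohort" / p).exists()

    def test_empty_grid(self, tmp_path):
        config = small_config(depth=500)
        paths = simulate_cohort(config, [], tmp_path / "empty")
        import pandas as pd
        assert len(pd.read_csv(paths["manifest"], sep="\t")) == 0
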