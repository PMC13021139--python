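"""Marker methylation summaries and beta-mixture tumor fraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import betabinom

from flare.ionmodel import MethylationCall
from flare.methtf import (MarkerRegion, ReadMethylationSummary,
                          estimate_tumor_fraction, export_cftools_table,
                          read_class_likelihood, read_marker_bed,
                          summarize_marker_methylation, train_marker_betas,
                          write_marker_bed)
from tests.test_ionmodel import make_fragment


def make_markers(n, alpha_t=8.0, beta_t=2.0, alpha_n=2.0, beta_n=8.0,
                 chrom="chr1", length=300, spacing=1000):
    return [MarkerRegion(f"M{i}", chrom, i * spacing, i * spacing + length,
                         alpha_t, beta_t, alpha_n, beta_n)
            for i in range(n)]


def simulate_summaries(theta, n_reads, markers, seed, y_range=(5, 15)):
    """Beta-binomial reads from the tumor/normal mixture at fraction theta."""
    rng = np.random.default_rng(seed)
    out = []
    for j in range(n_reads):
        m = markers[rng.integers(len(markers))]
        if rng.random() < theta:
            level = rng.beta(m.alpha_t, m.beta_t)
        else:
            level = rng.beta(m.alpha_n, m.beta_n)
        y = int(rng.integers(*y_range))
        x = int(rng.binomial(y, level))
        out.append(ReadMethylationSummary(f"r{j}", m.marker_id, x, y, 0.0))
    return out


class TestSummaries:
    def record_with_calls(self, probs, start=100, chrom="chr1"):
        calls = [MethylationCall(i, start + i, "m", p)
                 for i, p in enumerate(probs)]
        return make_fragment(chrom=chrom, ref_start=start,
                             ref_end=start + len(probs), meth_calls=calls)

    def test_all_above_threshold(self):
        markers = [MarkerRegion("M0", "chr1", 0, 1000, 8, 2, 2, 8)]
        rec = self.record_with_calls([0.9, 0.8, 0.7])
        summaries, table = summarize_marker_methylation([rec], markers)
        assert summaries[0].x == 3 and summaries[0].y == 3
        assert table.loc[0, "mean_methylation"] == 1.0

    def test_threshold_rule(self):
        markers = [MarkerRegion("M0", "chr1", 0, 1000, 8, 2, 2, 8)]
        rec = self.record_with_calls([0.9, 0.2, 0.2])
        summaries, _ = summarize_marker_methylation([rec], markers)
        assert (summaries[0].x, summaries[0].y) == (1, 3)

    def test_read_outside_markers_excluded(self):
        markers = [MarkerRegion("M0", "chr1", 5000, 6000, 8, 2, 2, 8)]
        rec = self.record_with_calls([0.9, 0.9])
        summaries, _ = summarize_marker_methylation([rec], markers)
        assert summaries == []

    def test_non_autosome_excluded(self):
        markers = [MarkerRegion("M0", "chrX", 0, 1000, 8, 2, 2, 8)]
        rec = self.record_with_calls([0.9], chrom="chrX")
        summaries, _ = summarize_marker_methylation([rec], markers)
        assert summaries == []
        summaries, _ = summarize_marker_methylation(
            [rec], markers, autosomes_only=False)
        assert len(summaries) == 1

    def test_undecodable_tags_excluded(self):
        markers = [MarkerRegion("M0", "chr1", 0, 1000, 8, 2, 2, 8)]
        rec = make_fragment(meth_calls=None)
        summaries, _ = summarize_marker_methylation([rec], markers)
        assert summaries == []

    def test_overlapping_markers_rejected_at_load(self, tmp_path):
        p = tmp_path / "markers.bed"
        p.write_text("chr1\t0\t1000\tA\nchr1\t500\t1500\tB\n")
        with pytest.raises(ValueError):
            read_marker_bed(p)

    def test_bed_round_trip(self, tmp_path):
        markers = make_markers(3)
        p = tmp_path / "m.bed"
        write_marker_bed(markers, p)
        assert read_marker_bed(p) == markers


class TestTrainBetas:
    def test_method_of_moments_example(self):
        # m=0.5, v=0.05 -> s=4, (alpha, beta) = (2, 2)
        rng = np.random.default_rng(0)
        rows = []
        for cls in ("tumor", "normal"):
            # construct fractions with exact mean 0.5, variance 0.05
            vals = np.array([0.5 - np.sqrt(0.05), 0.5, 0.5 + np.sqrt(0.05)])
            vals = 0.5 + (vals - 0.5) * np.sqrt(0.05 / vals.var(ddof=1))
            for i, v in enumerate(vals):
                rows.append({"sample": f"{cls}{i}", "class": cls,
                             "marker_id": "M0", "fraction": v})
        params = train_marker_betas(pd.DataFrame(rows))
        at, bt, an, bn = params["M0"]
        assert (at, bt) == pytest.approx((2.0, 2.0), rel=1e-6)

    def test_variance_floor_preserves_mean(self):
        rows = [{"sample": f"s{i}", "class": cls, "marker_id": "M0",
                 "fraction": 0.5}
                for cls in ("tumor", "normal") for i in range(3)]
        params = train_marker_betas(pd.DataFrame(rows))
        at, bt, an, bn = params["M0"]
        assert at / (at + bt) == pytest.approx(0.5)
        assert at > 100  # floored variance -> concentrated beta

    def test_boundary_fractions_clamped(self):
        rows = [{"sample": f"s{i}", "class": cls, "marker_id": "M0",
                 "fraction": 0.0}
                for cls in ("tumor", "normal") for i in range(3)]
        params = train_marker_betas(pd.DataFrame(rows))
        at, bt, _, _ = params["M0"]
        assert at > 0 and bt > 0
        assert at / (at + bt) == pytest.approx(0.01)

    def test_missing_class_dropped(self):
        rows = [{"sample": f"s{i}", "class": "tumor", "marker_id": "M0",
                 "fraction": 0.5} for i in range(3)]
        assert train_marker_betas(pd.DataFrame(rows)) == {}


class TestLikelihoodKernel:
    def test_empty_read(self):
        assert read_class_likelihood(0, 0, 2.0, 3.0) == pytest.approx(1.0)

    def test_closed_forms(self):
        # B(2,1)/B(1,1) = 0.5 ; B(4,2)/B(2,2) = (1/20)/(1/6) = 0.3
        assert read_class_likelihood(1, 1, 1.0, 1.0) == pytest.approx(0.5)
        assert read_class_likelihood(2, 2, 2.0, 2.0) == pytest.approx(0.3)

    def test_symmetry_lattice(self):
        """L(x, y, a, b) == L(y-x, y, b, a) over a small lattice."""
        for y in range(7):
            for x in range(y + 1):
                for a, b in ((1, 1), (2, 5), (0.5, 3)):
                    assert read_class_likelihood(x, y, a, b) == pytest.approx(
                        read_class_likelihood(y - x, y, b, a), rel=1e-12)


class TestEstimateTumorFraction:
    def test_uninformative_ties_to_zero(self):
        markers = make_markers(1, 2, 2, 2, 2)  # identical classes
        s = [ReadMethylationSummary("r", "M0", 2, 4, 0.5)]
        est = estimate_tumor_fraction(s, markers)
        assert est.theta_hat == 0.0
        assert est.uninformative

    def test_pure_normal_reads(self):
        markers = make_markers(50)
        s = simulate_summaries(0.0, 5000, markers, seed=1)
        est = estimate_tumor_fraction(s, markers)
        assert est.theta_hat <= 0.02

    def test_planted_theta_recovered(self):
        markers = make_markers(50)
        s = simulate_summaries(0.2, 10_000, markers, seed=2)
        est = estimate_tumor_fraction(s, markers)
        assert abs(est.theta_hat - 0.2) <= 0.02

    def test_curve_maximum_is_theta_hat(self):
        markers = make_markers(20)
        s = simulate_summaries(0.1, 2000, markers, seed=3)
        est = estimate_tumor_fraction(s, markers)
        assert est.grid[np.argmax(est.curve)] == est.theta_hat
        assert 0.0 <= est.theta_hat <= 1.0

    def test_lambda_zero_matches_bruteforce_betabinom(self):
        """With lam=0 the estimate equals an independent grid maximizer of
        the unweighted beta-binomial mixture likelihood (within one step)."""
        markers = make_markers(30)
        s = simulate_summaries(0.15, 3000, markers, seed=4)
        est = estimate_tumor_fraction(s, markers, lam=0.0)
        mmap = {m.marker_id: m for m in markers}
        grid = np.arange(0, 1.0001, 5e-4)
        ll = np.zeros(len(grid))
        for r in s:
            m = mmap[r.marker_id]
            pt = betabinom.pmf(r.x, r.y, m.alpha_t, m.beta_t)
            pn = betabinom.pmf(r.x, r.y, m.alpha_n, m.beta_n)
            ll += np.log(grid * pt + (1 - grid) * pn)
        theta_brute = grid[np.argmax(ll)]
        assert abs(est.theta_hat - theta_brute) <= 5e-4 + 1e-12

    def test_monotone_information(self):
        """Widening tumor/normal separation does not worsen recovery on
        average over seeds."""
        errs = {}
        for sep, (at, bt) in {"narrow": (4, 6), "wide": (9, 1)}.items():
            e = []
            for seed in range(10):
                markers = make_markers(20, alpha_t=at, beta_t=bt)
                s = simulate_summaries(0.2, 1500, markers, seed=seed)
                est = estimate_tumor_fraction(s, markers)
                e.append(abs(est.theta_hat - 0.2))
            errs[sep] = np.mean(e)
        assert errs["wide"] <= errs["narrow"] + 1e-9

    def test_no_summaries_rejected(self):
        with pytest.raises(ValueError):
            estimate_tumor_fraction([], make_markers(1))


class TestExport:
    def test_deterministic_bytes(self, tmp_path):
        table = pd.DataFrame({
            "marker_id": ["M0", "M1"], "chrom": ["chr1", "chr1"],
            "start": [0, 1000], "end": [300, 1300],
            "n_calls": [10, 20], "mean_methylation": [0.5, 0.25]})
        outs = []
        for rep in range(2):
            mp = tmp_path / f"means{rep}.tsv"
            tp = tmp_path / f"theta{rep}.tsv"
            export_cftools_table({"s1": table, "s2": table},
                                 {"s1": 0.3, "s2": 0.1}, mp, tp)
            outs.append(mp.read_bytes() + tp.read_bytes())
        assert outs[0] == outs[1]
        theta = pd.read_csv(tmp_path / "theta0.tsv", sep="\t")
        assert theta.loc[0, "normal_fraction"] == pytest.approx(0.7)

    def test_empty_markers_header_only(self, tmp_path):
        mp = tmp_path / "m.tsv"
        tp = tmp_path / "t.tsv"
        export_cftools_table({}, {}, mp, tp)
        assert mp.read_text().strip() == "marker_id\tchrom\tstart\tend"
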