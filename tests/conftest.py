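"""Shared fixtures: toy SAM records and a small simulated sample."""

from __future__ import annotations

import numpy as np
import pytest

from flare.cnvtf import GenomeBins
from flare.simdata import (SimConfig, plant_markers, simulate_reference,
                           simulate_sample)

TOY_SAM = """\
@HD\tVN:1.6\tSO:unknown
@SQ\tSN:chr1\tLN:100000
pass1\t0\tchr1\t100\t60\t100M\t*\t0\t0\t{seq100}\t*
pass2\t16\tchr1\t300\t20\t100M\t*\t0\t0\t{seq100}\t*
pass3\t0\tchr1\t500\t35\t100M\t*\t0\t0\t{seq100}\t*
pass4\t16\tchr1\t700\t60\t100M\t*\t0\t0\t{seq100}\t*
sec1\t256\tchr1\t900\t60\t100M\t*\t0\t0\t*\t*
sec2\t272\tchr1\t1100\t60\t100M\t*\t0\t0\t*\t*
supp1\t2048\tchr1\t1300\t60\t100M\t*\t0\t0\t{seq100}\t*
unmap1\t4\t*\t0\t0\t*\t*\t0\t0\t{seq100}\t*
lowq1\t0\tchr1\t1500\t19\t100M\t*\t0\t0\t{seq100}\t*
lowq2\t16\tchr1\t1700\t19\t100M\t*\t0\t0\t{seq100}\t*
"""


@pytest.fixture()
def toy_sam_path(tmp_path):
    """10 records: 4 retainable (one at the mapq=20 boundary), 2 secondary,
    1 supplementary, 1 unmapped, 2 below mapq 20."""
    seq = ("ACGT" * 25)
    path = tmp_path / "toy.sam"
    path.write_text(TOY_SAM.format(seq100=seq))
    return path


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One simulated sample on a small genome, with its reference written
    to disk (shared across tests; treat as read-only)."""
    out = tmp_path_factory.mktemp("smallsim")
    config = SimConfig(seed=11, n_chromosomes=2, chrom_length=1_000_000,
                       bin_width=100_000, depth=5000, n_markers=20,
                       tumor_fraction=0.3)
    rng = np.random.default_rng(config.seed)
    ref, _ = simulate_reference(config, rng)
    markers = plant_markers(config, ref)
    bins = GenomeBins.from_reference(ref, config.bin_width)
    sam_path = out / "sample.sam"
    simulate_sample(config, ref, bins, config.tumor_fraction, markers,
                    "S1", sam_path, rng)
    ref_path = out / "ref.fa"
    ref.write(ref_path)
    return {"config": config, "ref": ref, "markers": markers, "bins": bins,
            "sam": sam_path, "fasta": ref_path}


def matched_min_cosine(H_est: np.ndarray, H_true: np.ndarray) -> float:
    """Minimum cosine similarity between estimated and planted profile rows
    after optimal (Hungarian) matching on cosine distance."""
    from scipy.optimize import linear_sum_assignment

    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    C = np.array([[1.0 - cos(hi, hj) for hj in H_true] for hi in H_est])
    ri, cj = linear_sum_assignment(C)
    return min(1.0 - C[i, j] for i, j in zip(ri, cj))
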