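"""Synthetic cfDNA cohort generation.

Emulates the statistical structure of a nanopore cfDNA experiment at desk
scale: a random reference genome with per-bin GC, aligned error-free reads
whose lengths follow a mono-/di-nucleosomal + tumor-short lognormal mixture,
per-class 5' end-motif cleavage biases (planted by locally rewriting the
reference so read and reference stay consistent on both strands), per-bin
read depth reflecting a planted copy-number profile at a planted tumor
fraction, CpG-rich methylation markers with per-class beta-distributed
methylation encoded as MM/ML tags, and a panel of normals.  All outputs are
pure functions of (config, seed).
"""

from __future__ import annotations

import array
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats as sps

from .cnvtf import GenomeBins, correct_gc
from .endmotif import MOTIFS
from .ionmodel import Strand, revcomp
from .methtf import MarkerRegion, _MarkerIndex, write_marker_bed

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class LengthMixture:
    """Lognormal fragment-length mixture (weights over components)."""

    weights: tuple[float, ...]
    medians: tuple[float, ...] = (145.0, 167.0, 320.0)
    sigmas: tuple[float, ...] = (0.08, 0.10, 0.12)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")

    def sample(self, rng: np.random.Generator, size: int,
               lo: int, hi: int) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=size, p=self.weights)
        mu = np.log(np.asarray(self.medians))[comp]
        sigma = np.asarray(self.sigmas)[comp]
        lengths = np.rint(rng.lognormal(mu, sigma)).astype(int)
        return np.clip(lengths, lo, hi)

    def class_masses(self) -> tuple[float, float, float]:
        """Expected (short, intermediate, long) probabilities under the
        continuous mixture (boundaries 150 / 300 bp)."""
        p_short = p_long = 0.0
        for w, m, s in zip(self.weights, self.medians, self.sigmas):
            dist = sps.lognorm(s, scale=m)
            p_short += w * dist.cdf(149.5)
            p_long += w * dist.sf(300.5)
        return p_short, 1.0 - p_short - p_long, p_long


def canonical_motif_profiles() -> dict[str, np.ndarray]:
    """Planted 256-motif end-cleavage profiles.

    'tumor' mimics apoptotic CAD/DFFB cleavage (A- and G-end enriched);
    'normal' retains a DNASE1L3-like C-end component (CCCA and CC-starts).
    """
    tumor = np.ones(len(MOTIFS))
    normal = np.ones(len(MOTIFS))
    for j, motif in enumerate(MOTIFS):
        if motif[0] == "A":
            tumor[j] += 5.0
        if motif[0] == "G":
            tumor[j] += 4.0
        if motif[0] == "C":
            normal[j] += 3.0
        if motif.startswith("CC"):
            normal[j] += 4.0
    normal[MOTIFS.index("CCCA")] += 30.0
    return {"tumor": tumor / tumor.sum(), "normal": normal / normal.sum()}


def planted_fragmentation_profiles() -> np.ndarray:
    """Three nuclease-like latent end-motif profiles (3 x 256): A-end
    enriched (apoptotic CAD/DFFB-like), G-end enriched, and C-end /
    CCCA-enriched (DNASE1L3-like)."""
    rows = []
    for base, boost in (("A", 6.0), ("G", 6.0), ("C", 4.0)):
        h = np.ones(len(MOTIFS))
        for j, motif in enumerate(MOTIFS):
            if motif[0] == base:
                h[j] += boost
            if base == "C" and motif.startswith("CC"):
                h[j] += 3.0
        if base == "C":
            h[MOTIFS.index("CCCA")] += 25.0
        rows.append(h / h.sum())
    return np.vstack(rows)


def simulate_motif_cohort(
    n_samples: int = 20,
    noise: float = 0.01,
    seed: int = 0,
    dominance: float = 0.85,
    profiles: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Motif matrix from planted latent profiles plus uniform noise.

    Samples carry one dominant profile (weight ``dominance``) with the
    remainder split evenly — the clustered structure NMF consensus
    stability assumes.  ``noise`` is the total width of a zero-mean uniform
    perturbation per entry (clipped at 0 to keep the matrix non-negative).
    Returns (V, W_true, H_true).
    """
    rng = np.random.default_rng(seed)
    H = planted_fragmentation_profiles() if profiles is None else profiles
    k = H.shape[0]
    W = np.full((n_samples, k), (1.0 - dominance) / (k - 1))
    for i in range(n_samples):
        W[i, i % k] = dominance
    W *= rng.uniform(0.9, 1.1, size=(n_samples, 1))
    V = W @ H + rng.uniform(-noise / 2, noise / 2, size=(n_samples, H.shape[1]))
    return np.maximum(V, 0.0), W, H


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a shallow nanopore cfDNA run scaled to desk size: two
    4 Mb autosomes at 100 kb bins, 20,000 reads per sample, fragment-length
    mixtures with a 167 bp mononucleosomal peak and tumor-short enrichment,
    and 50 well-separated methylation markers (tumor Beta(8,2) vs normal
    Beta(2,8)).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 4_000_000
    bin_width: int = 100_000
    gc_range: tuple[float, float] = (0.35, 0.55)
    depth: int = 20_000
    tumor_fraction: float = 0.1
    cnv_segments: Optional[list[tuple[str, int, int, int]]] = None
    normal_length_mixture: LengthMixture = field(
        default_factory=lambda: LengthMixture(weights=(0.10, 0.62, 0.28)))
    tumor_length_mixture: LengthMixture = field(
        default_factory=lambda: LengthMixture(weights=(0.45, 0.35, 0.20)))
    motif_profiles: dict[str, np.ndarray] = field(
        default_factory=canonical_motif_profiles)
    n_markers: int = 50
    marker_length: int = 300
    marker_cpg_spacing: int = 15
    marker_betas: tuple[tuple[float, float], tuple[float, float]] = ((8.0, 2.0),
                                                                    (2.0, 8.0))
    mapq: int = 60
    min_length: int = 20
    max_length: int = 1000
    strand_prob: float = 0.5
    gc_bias: Optional[Sequence[float]] = None
    meth_byte_range: tuple[int, int] = (180, 256)
    unmeth_byte_range: tuple[int, int] = (0, 76)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


class SimReference:
    """In-memory mutable reference genome (duck-types the FASTA accessor)."""

    def __init__(self, seqs: dict[str, np.ndarray]):
        self.seqs = seqs  # chrom -> |S1 array

    def chromosomes(self) -> list[str]:
        return list(self.seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.seqs[chrom][start:end].tobytes().decode()

    def write(self, path, line_width: int = 70) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for chrom, seq in self.seqs.items():
                fh.write(f">{chrom}\n")
                raw = seq.tobytes().decode()
                for i in range(0, len(raw), line_width):
                    fh.write(raw[i:i + line_width] + "\n")
        pysam.faidx(str(path))

    def sam_header(self) -> dict:
        return {"HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": c, "LN": self.length(c)}
                       for c in self.chromosomes()]}


def simulate_reference(
    config: SimConfig, rng: Optional[np.random.Generator] = None,
) -> tuple[SimReference, np.ndarray]:
    """Random genome with per-bin GC targets drawn from ``gc_range``.

    Returns (reference, per-bin GC targets in bin order).
    """
    if config.chrom_length < config.bin_width:
        raise ValueError("chrom_length < bin_width")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    seqs: dict[str, np.ndarray] = {}
    gc_targets = []
    n_bins_per_chrom = config.chrom_length // config.bin_width
    usable = n_bins_per_chrom * config.bin_width
    for chrom in config.chrom_names():
        parts = []
        for _ in range(n_bins_per_chrom):
            gc = rng.uniform(*config.gc_range)
            gc_targets.append(gc)
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            parts.append(_BASES[rng.choice(4, size=config.bin_width, p=p)])
        tail = config.chrom_length - usable
        if tail:
            parts.append(_BASES[rng.integers(0, 4, size=tail)])
        seqs[chrom] = np.concatenate(parts)
    return SimReference(seqs), np.asarray(gc_targets)


def plant_markers(
    config: SimConfig, ref: SimReference,
) -> list[MarkerRegion]:
    """Evenly spaced CpG-rich marker intervals (CG planted every
    ``marker_cpg_spacing`` bp), round-robin across chromosomes."""
    (a_t, b_t), (a_n, b_n) = config.marker_betas
    chroms = ref.chromosomes()
    per_chrom = int(np.ceil(config.n_markers / len(chroms)))
    markers: list[MarkerRegion] = []
    i = 0
    for chrom in chroms:
        clen = ref.length(chrom)
        span = clen - 20_000
        step = span // per_chrom
        for k in range(per_chrom):
            if i >= config.n_markers:
                break
            start = 10_000 + k * step
            end = start + config.marker_length
            seq = ref.seqs[chrom]
            for pos in range(start, end - 1, config.marker_cpg_spacing):
                seq[pos] = b"C"
                seq[pos + 1] = b"G"
            markers.append(MarkerRegion(
                marker_id=f"M{i:04d}", chrom=chrom, start=start, end=end,
                alpha_t=a_t, beta_t=b_t, alpha_n=a_n, beta_n=b_n))
            i += 1
    markers.sort(key=lambda m: (m.chrom, m.start))
    return markers


def default_cnv_segments(config: SimConfig,
                         gain_frac: float = 0.2,
                         loss_frac: float = 0.1) -> list[tuple[str, int, int, int]]:
    """A planted profile: one gained (c=3) and one lost (c=1) block sized as
    fractions of the genome, placed on the first chromosome(s)."""
    total = config.n_chromosomes * config.chrom_length
    gain_len = int(total * gain_frac)
    loss_len = int(total * loss_frac)
    chrom1 = config.chrom_names()[0]
    segs = [(chrom1, 0, min(gain_len, config.chrom_length), 3)]
    chrom_l = config.chrom_names()[-1]
    segs.append((chrom_l, config.chrom_length - loss_len,
                 config.chrom_length, 1))
    return segs


def states_per_bin(config: SimConfig, bins: GenomeBins,
                   segments: Optional[list[tuple[str, int, int, int]]] = None,
                   ) -> np.ndarray:
    segs = segments if segments is not None else (config.cnv_segments or [])
    states = np.full(len(bins), 2, dtype=int)
    df = bins.frame
    for chrom, start, end, c in segs:
        sel = ((df["chrom"] == chrom) & (df["start"] >= start)
               & (df["end"] <= end))
        states[sel.to_numpy()] = c
    return states


def _gc_weight(config: SimConfig, gc: np.ndarray) -> np.ndarray:
    if config.gc_bias is None:
        return np.ones_like(gc)
    return np.maximum(np.polyval(list(config.gc_bias), gc), 0.05)


@dataclass
class FragmentDraw:
    """All fragments of one sample, pre-SAM."""

    chrom: list[str]
    start: np.ndarray
    length: np.ndarray
    reverse: np.ndarray     # bool
    is_tumor: np.ndarray    # bool
    motif_idx: np.ndarray   # index into MOTIFS


def draw_fragments(
    config: SimConfig,
    ref: SimReference,
    bins: GenomeBins,
    theta: float,
    rng: np.random.Generator,
    cnv_states: Optional[np.ndarray] = None,
) -> FragmentDraw:
    """Draw read class, position, length, strand and end motif.

    Tumor-class reads are placed with per-bin intensity proportional to the
    planted copy state (c/2), normal-class reads uniformly; both are
    modulated by the optional GC bias, so the aggregate per-bin intensity is
    proportional to 2n + (1-n)c.
    """
    df = bins.frame
    n_bins = len(df)
    gc = df["gc"].to_numpy()
    base_w = _gc_weight(config, gc)
    if cnv_states is None:
        cnv_states = states_per_bin(config, bins)
    w_normal = base_w / base_w.sum()
    w_t = base_w * (cnv_states / 2.0)
    w_tumor = w_t / w_t.sum()

    n = config.depth
    is_tumor = rng.random(n) < theta
    bin_idx = np.empty(n, dtype=int)
    n_t = int(is_tumor.sum())
    bin_idx[is_tumor] = rng.choice(n_bins, size=n_t, p=w_tumor)
    bin_idx[~is_tumor] = rng.choice(n_bins, size=n - n_t, p=w_normal)

    lengths = np.empty(n, dtype=int)
    lengths[is_tumor] = config.tumor_length_mixture.sample(
        rng, n_t, config.min_length, config.max_length)
    lengths[~is_tumor] = config.normal_length_mixture.sample(
        rng, n - n_t, config.min_length, config.max_length)

    offset = rng.integers(0, config.bin_width, size=n)
    chrom = df["chrom"].to_numpy()[bin_idx]
    start = df["start"].to_numpy()[bin_idx] + offset
    # clamp fragments that would overrun the chromosome end
    for c in np.unique(chrom):
        clen = ref.length(str(c))
        sel = chrom == c
        start[sel] = np.minimum(start[sel], clen - lengths[sel])
    start = np.maximum(start, 0)

    reverse = rng.random(n) < config.strand_prob
    motif_idx = np.empty(n, dtype=int)
    profiles = config.motif_profiles
    motif_idx[is_tumor] = rng.choice(len(MOTIFS), size=n_t,
                                     p=profiles["tumor"])
    motif_idx[~is_tumor] = rng.choice(len(MOTIFS), size=n - n_t,
                                      p=profiles["normal"])
    return FragmentDraw(chrom=[str(c) for c in chrom], start=start,
                        length=lengths, reverse=reverse, is_tumor=is_tumor,
                        motif_idx=motif_idx)


def draw_strand_paired_fragments(
    config: SimConfig,
    ref: SimReference,
    bins: GenomeBins,
    n_per_strand: int,
    rng: np.random.Generator,
    profile: str = "normal",
) -> FragmentDraw:
    """Each planted end-motif draw is emitted twice — once as a forward and
    once as a reverse record — so the two strand-derived motif frequency
    vectors estimate the same multiset and their total-variation distance
    isolates the extraction path (read-derived vs reference-derived),
    not sampling noise."""
    df = bins.frame
    n_bins = len(df)
    motif_idx = rng.choice(len(MOTIFS), size=n_per_strand,
                           p=config.motif_profiles[profile])
    out = {"chrom": [], "start": [], "length": [], "reverse": []}
    for rev in (False, True):
        bin_idx = rng.integers(0, n_bins, size=n_per_strand)
        lengths = config.normal_length_mixture.sample(
            rng, n_per_strand, config.min_length, config.max_length)
        offset = rng.integers(0, config.bin_width, size=n_per_strand)
        chrom = df["chrom"].to_numpy()[bin_idx]
        start = df["start"].to_numpy()[bin_idx] + offset
        for c in np.unique(chrom):
            clen = ref.length(str(c))
            sel = chrom == c
            start[sel] = np.minimum(start[sel], clen - lengths[sel])
        out["chrom"].extend(str(c) for c in chrom)
        out["start"].append(start)
        out["length"].append(lengths)
        out["reverse"].append(np.full(n_per_strand, rev))
    return FragmentDraw(
        chrom=out["chrom"],
        start=np.concatenate(out["start"]),
        length=np.concatenate(out["length"]),
        reverse=np.concatenate(out["reverse"]),
        is_tumor=np.zeros(2 * n_per_strand, dtype=bool),
        motif_idx=np.tile(motif_idx, 2),
    )


def apply_motif_rewrites(ref: SimReference, draw: FragmentDraw) -> None:
    """Write each fragment's planted 5' 4-mer into the reference: at
    [start, start+4) for forward fragments, revcomp at [end-4, end) for
    reverse fragments (the fragment's 5' end is the reference-rightmost
    base there)."""
    for j in range(len(draw.start)):
        motif = MOTIFS[draw.motif_idx[j]]
        seq = ref.seqs[draw.chrom[j]]
        s, ln = int(draw.start[j]), int(draw.length[j])
        if draw.reverse[j]:
            target = np.frombuffer(revcomp(motif).encode(), dtype="S1")
            seq[s + ln - 4:s + ln] = target
        else:
            seq[s:s + 4] = np.frombuffer(motif.encode(), dtype="S1")


def _encode_mm_ml(
    stored_seq: str,
    reverse: bool,
    call_offsets: list[int],
    ml_bytes: list[int],
) -> tuple[str, list[int]]:
    """Build MM ('C+m?') and ML over calls given as stored-sequence offsets
    (paired with ml_bytes); handles the orientation flip for reverse reads."""
    length = len(stored_seq)
    original = revcomp(stored_seq) if reverse else stored_seq
    if reverse:
        pairs = sorted(((length - 1 - off, b)
                        for off, b in zip(call_offsets, ml_bytes)))
    else:
        pairs = sorted(zip(call_offsets, ml_bytes))
    c_positions = [i for i, b in enumerate(original) if b == "C"]
    c_rank = {pos: r for r, pos in enumerate(c_positions)}
    deltas = []
    prev_rank = -1
    ml_out = []
    for off, byte in pairs:
        rank = c_rank[off]
        deltas.append(rank - prev_rank - 1)
        prev_rank = rank
        ml_out.append(byte)
    mm = "C+m?," + ",".join(str(d) for d in deltas) + ";"
    return mm, ml_out


def emit_sam(
    config: SimConfig,
    ref: SimReference,
    draw: FragmentDraw,
    markers: Sequence[MarkerRegion],
    sample_id: str,
    path,
    rng: np.random.Generator,
) -> None:
    """Write the drawn fragments as a coordinate-sorted SAM file with MM/ML
    methylation at marker CpGs (per read and marker, a methylation level is
    drawn from the class beta distribution)."""
    index = _MarkerIndex(markers)
    (a_t, b_t), (a_n, b_n) = config.marker_betas
    order = np.lexsort((draw.start,
                        np.array([ref.chromosomes().index(c)
                                  for c in draw.chrom])))
    header = pysam.AlignmentHeader.from_dict(ref.sam_header())
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rank, j in enumerate(order):
            chrom = draw.chrom[j]
            s = int(draw.start[j])
            ln = int(draw.length[j])
            seq = ref.fetch(chrom, s, s + ln)
            a = pysam.AlignedSegment(header)
            a.query_name = f"{sample_id}_r{rank:06d}"
            a.reference_name = chrom
            a.reference_start = s
            a.mapping_quality = config.mapq
            a.cigarstring = f"{ln}M"
            a.flag = 16 if draw.reverse[j] else 0
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * ln)

            call_offsets: list[int] = []
            ml_bytes: list[int] = []
            level_by_marker: dict[str, float] = {}
            for i in range(ln - 1):
                if seq[i] != "C" or seq[i + 1] != "G":
                    continue
                if draw.reverse[j]:
                    off, gpos = i + 1, s + i + 1
                else:
                    off, gpos = i, s + i
                if off >= ln:
                    continue
                marker = index.find(chrom, gpos)
                if marker is None:
                    continue
                if marker.marker_id not in level_by_marker:
                    if draw.is_tumor[j]:
                        level = rng.beta(a_t, b_t)
                    else:
                        level = rng.beta(a_n, b_n)
                    level_by_marker[marker.marker_id] = level
                level = level_by_marker[marker.marker_id]
                if rng.random() < level:
                    byte = int(rng.integers(*config.meth_byte_range))
                else:
                    byte = int(rng.integers(*config.unmeth_byte_range))
                call_offsets.append(off)
                ml_bytes.append(byte)
            if call_offsets:
                mm, ml = _encode_mm_ml(seq, bool(draw.reverse[j]),
                                       call_offsets, ml_bytes)
                a.set_tag("MM", mm)
                a.set_tag("ML", array.array("B", ml))
            out.write(a)


def simulate_sample(
    config: SimConfig,
    ref: SimReference,
    bins: GenomeBins,
    theta: float,
    markers: Sequence[MarkerRegion],
    sample_id: str,
    path,
    rng: np.random.Generator,
    cnv_states: Optional[np.ndarray] = None,
) -> dict:
    """draw -> rewrite -> emit for one sample.  Mutates ``ref`` (write the
    FASTA only after the last sample has been simulated)."""
    draw = draw_fragments(config, ref, bins, theta, rng, cnv_states)
    apply_motif_rewrites(ref, draw)
    emit_sam(config, ref, draw, markers, sample_id, path, rng)
    return {
        "sample": sample_id,
        "theta": theta,
        "n_reads": int(len(draw.start)),
        "n_tumor_reads": int(draw.is_tumor.sum()),
    }


def simulate_pon(
    config: SimConfig,
    bins: GenomeBins,
    n_normals: int = 10,
    rng: Optional[np.random.Generator] = None,
    depth: Optional[int] = None,
) -> pd.DataFrame:
    """Per-bin median GC-corrected coverage over simulated normal samples."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    depth = config.depth if depth is None else depth
    gc = bins.frame["gc"].to_numpy()
    w = _gc_weight(config, gc)
    w = w / w.sum()
    corrected = np.zeros((n_normals, len(bins)))
    for i in range(n_normals):
        counts = rng.multinomial(depth, w).astype(float)
        corr, _ = correct_gc(counts, gc)
        corrected[i] = corr
    with np.errstate(all="ignore"):
        med = np.nanmedian(corrected, axis=0)
    out = bins.frame[["chrom", "start", "end"]].copy()
    out["median_corrected_count"] = np.nan_to_num(med)
    return out


def simulate_cohort(
    config: SimConfig,
    subject_thetas: Sequence[tuple[float, float]],
    out_dir,
    conditions: tuple[str, str] = ("C1D1", "C5D1"),
) -> dict:
    """Paired two-timepoint cohort: per-subject (theta_baseline,
    theta_on_treatment).  Writes reference.fa(+.fai), bins.tsv, markers.bed,
    pon.tsv, per-sample SAMs, manifest.tsv and truth.json; returns the path
    map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    ref, _ = simulate_reference(config, rng)
    markers = plant_markers(config, ref)
    bins = GenomeBins.from_reference(ref, config.bin_width)
    segments = (config.cnv_segments if config.cnv_segments is not None
                else default_cnv_segments(config))
    cnv_states = states_per_bin(config, bins, segments)

    # two-phase: draw (and rewrite) every sample's fragments before emitting
    # any SAM, so every stored sequence matches the final reference
    draws = []
    manifest_rows = []
    truths = []
    for si, (th_a, th_b) in enumerate(subject_thetas):
        subject = f"P{si + 1}"
        for cond, theta in zip(conditions, (th_a, th_b)):
            sample_id = f"{subject}_{cond}"
            draw = draw_fragments(config, ref, bins, theta, rng, cnv_states)
            apply_motif_rewrites(ref, draw)
            draws.append((sample_id, draw))
            sam_path = out_dir / f"{sample_id}.sam"
            manifest_rows.append({"sample": sample_id, "subject": subject,
                                  "condition": cond,
                                  "path": sam_path.name})
            truths.append({"sample": sample_id, "subject": subject,
                           "condition": cond, "theta": theta})
    for (sample_id, draw), row in zip(draws, manifest_rows):
        emit_sam(config, ref, draw, markers, sample_id,
                 out_dir / row["path"], rng)

    ref_path = out_dir / "reference.fa"
    ref.write(ref_path)
    bins = GenomeBins.from_reference(ref, config.bin_width)
    bins.to_tsv(out_dir / "bins.tsv")
    write_marker_bed(markers, out_dir / "markers.bed")
    pon = simulate_pon(config, bins, rng=np.random.default_rng(config.seed + 1))
    pon.to_csv(out_dir / "pon.tsv", sep="\t", index=False)
    manifest = pd.DataFrame(manifest_rows,
                            columns=["sample", "subject", "condition", "path"])
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)

    truth = {
        "seed": config.seed,
        "samples": truths,
        "cnv_segments": [list(s) for s in segments],
        "marker_betas": [list(config.marker_betas[0]),
                         list(config.marker_betas[1])],
        "depth": config.depth,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    return {
        "dir": str(out_dir),
        "reference": str(ref_path),
        "bins": str(out_dir / "bins.tsv"),
        "markers": str(out_dir / "markers.bed"),
        "pon": str(out_dir / "pon.tsv"),
        "manifest": str(out_dir / "manifest.tsv"),
        "truth": str(out_dir / "truth.json"),
    }
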