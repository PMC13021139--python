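"""End-to-end pipeline orchestration.

Per sample: filter -> length summary / size classes -> end motifs ->
methylation tumor fraction; CNV/tumor-fraction HMM on all fragments and on
each size-class stream (identical configuration).  Cohort level: motif
matrix + NMF profiles, paired Wilcoxon tests (short-class vs all-fragment
tumor fraction; per-profile contributions across conditions; end-base
composition across conditions) and the Spearman comparison of CNV-based vs
methylation-based tumor fractions.  The report JSON is deterministic
(timestamp-free) for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cnvtf, endmotif, fragprofile, methtf, motifnmf, stats
from .ionmodel import FilterPolicy, filter_alignments, parse_alignment_records

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    input_dir: str                    # cohort directory (manifest.tsv etc.)
    out_dir: str
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    nmf_k: int = 3
    nmf_runs: int = 100
    nmf_seed: int = 17
    lam: float = 0.5
    call_threshold: float = 0.5
    conditions: tuple[str, str] = ("C1D1", "C5D1")
    cnv_kwargs: dict = field(default_factory=dict)

    def policy_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self.filter_policy),
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def _cnv_summary(sol: Optional[cnvtf.CNVSolution]) -> Optional[dict]:
    if sol is None:
        return None
    return {
        "tumor_fraction": sol.tumor_fraction,
        "n_hat": sol.n_hat,
        "ploidy": sol.phi_hat,
        "log_likelihood": sol.log_likelihood,
        "data_log_likelihood": sol.data_log_likelihood,
        "sigma": sol.sigma,
        "chosen_restart": sol.chosen_restart,
        "restart_log_likelihoods": sol.restart_log_likelihoods,
        "n_segments": int(len(sol.segments)),
        "converged": sol.converged,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on the cohort under ``config.input_dir``; write the
    report directory and return the report dict.  Stage failures are
    recorded and re-raised as PipelineError after partial results are
    preserved."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
    bins = cnvtf.GenomeBins.from_tsv(in_dir / "bins.tsv")
    pon = pd.read_csv(in_dir / "pon.tsv", sep="\t")[
        "median_corrected_count"].to_numpy(float)
    markers = methtf.read_marker_bed(in_dir / "markers.bed")
    reference = endmotif.ReferenceAccessor(in_dir / "reference.fa")
    policy_hash = config.policy_hash()

    per_sample: dict[str, dict] = {}
    motif_counts: dict[str, dict] = {}
    marker_tables: dict[str, pd.DataFrame] = {}
    failures: list[str] = []

    for row in manifest.itertuples():
        sid = row.sample
        try:
            records = list(parse_alignment_records(in_dir / row.path))
            kept, freport = filter_alignments(records, config.filter_policy)
            lengths = [r.query_length for r in kept]
            lsum = fragprofile.length_summary(lengths)
            sprof = fragprofile.size_class_profile(lengths)
            counts, n_used = endmotif.count_end_motifs(kept, reference)
            motif_counts[sid] = counts

            summaries, marker_table = methtf.summarize_marker_methylation(
                kept, markers, call_threshold=config.call_threshold)
            marker_tables[sid] = marker_table
            if summaries:
                est = methtf.estimate_tumor_fraction(summaries, markers,
                                                     lam=config.lam)
                theta_meth = est.theta_hat
            else:
                theta_meth = None

            streams = fragprofile.split_by_size_class(kept)
            cnv_results: dict[str, Optional[cnvtf.CNVSolution]] = {}
            sol_all, table = cnvtf.run_cnv(kept, bins, pon,
                                           **config.cnv_kwargs)
            cnv_results["all"] = sol_all
            table.to_csv(out_dir / f"{sid}.cnv_bins.tsv", sep="\t",
                         index=False)
            for cls in fragprofile.CLASS_NAMES:
                try:
                    sol_cls, _ = cnvtf.run_cnv(streams[cls], bins, pon,
                                               **config.cnv_kwargs)
                except ValueError as exc:
                    log.warning("sample %s class %s CNV skipped: %s",
                                sid, cls, exc)
                    sol_cls = None
                cnv_results[cls] = sol_cls

            per_sample[sid] = {
                "subject": row.subject,
                "condition": row.condition,
                "filter_policy_hash": policy_hash,
                "filter_report": freport.as_dict(),
                "length_summary": {
                    "n_reads": lsum.n_reads, "mean": lsum.mean,
                    "median": lsum.median, "n50": lsum.n50},
                "size_class": {
                    "counts": [sprof.n_short, sprof.n_intermediate,
                               sprof.n_long],
                    "proportions": list(sprof.proportions)},
                "n_motif_reads": n_used,
                "theta_methylation": theta_meth,
                "cnv": {k: _cnv_summary(v) for k, v in cnv_results.items()},
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation
            log.error("sample %s failed: %s", sid, exc)
            failures.append(f"{sid}: {exc}")

    report: dict = {"samples": per_sample, "policy_hash": policy_hash,
                    "config": {
                        "nmf_k": config.nmf_k, "nmf_runs": config.nmf_runs,
                        "nmf_seed": config.nmf_seed, "lambda": config.lam}}

    # --- cohort level -----------------------------------------------------
    matrix = endmotif.build_motif_matrix(motif_counts)
    matrix.to_tsv(out_dir / "motif_matrix.tsv")
    composition = endmotif.end_base_composition(matrix)
    composition.to_csv(out_dir / "end_composition.tsv", sep="\t",
                       index_label="sample")

    nmf = motifnmf.nmf_factorize(matrix, k=config.nmf_k,
                                 n_runs=config.nmf_runs,
                                 seed=config.nmf_seed)
    pd.DataFrame(nmf.W, index=matrix.sample_ids).to_csv(
        out_dir / "W.tsv", sep="\t", index_label="sample")
    pd.DataFrame(nmf.H, columns=list(endmotif.MOTIFS)).to_csv(
        out_dir / "H.tsv", sep="\t", index_label="profile")
    top = motifnmf.top_profile_motifs(nmf.H)
    report["nmf"] = {"k": nmf.k, "objective": nmf.objective,
                     "cophenetic": nmf.cophenetic,
                     "best_run_seed": nmf.best_run_seed,
                     "top_motifs": top}

    pairing = {r.sample: (r.condition, r.subject)
               for r in manifest.itertuples()}
    tests: dict = {}
    try:
        prof_tests = motifnmf.compare_profile_contributions(
            nmf.W, matrix.sample_ids, pairing, config.conditions)
        tests["profile_contributions"] = prof_tests.to_dict("records")
    except ValueError as exc:
        tests["profile_contributions"] = str(exc)

    tf_all, tf_short, samples_order = [], [], []
    theta_cnv, theta_meth = [], []
    for sid, res in per_sample.items():
        samples_order.append(sid)
        cnv_all = res["cnv"].get("all")
        cnv_short = res["cnv"].get("short")
        if cnv_all is not None and cnv_short is not None:
            tf_all.append(cnv_all["tumor_fraction"])
            tf_short.append(cnv_short["tumor_fraction"])
        if cnv_all is not None and res["theta_methylation"] is not None:
            theta_cnv.append(cnv_all["tumor_fraction"])
            theta_meth.append(res["theta_methylation"])
    try:
        r = stats.wilcoxon_signed_rank(list(zip(tf_short, tf_all)))
        tests["short_vs_all_tumor_fraction"] = {
            "statistic": r.statistic, "p_value": r.p_value,
            "method": r.method, "n": r.n_used}
    except ValueError as exc:
        tests["short_vs_all_tumor_fraction"] = str(exc)

    comp_tests = {}
    cond_a, cond_b = config.conditions
    in_a = [s for s in matrix.sample_ids if pairing.get(s, ("",))[0] == cond_a]
    in_b = [s for s in matrix.sample_ids if pairing.get(s, ("",))[0] == cond_b]
    for base in endmotif.BASES:
        try:
            r = stats.wilcoxon_rank_sum(
                composition.loc[in_a, base].to_numpy(),
                composition.loc[in_b, base].to_numpy())
            comp_tests[base] = {"statistic": r.statistic,
                                "p_value": r.p_value, "method": r.method}
        except ValueError as exc:
            comp_tests[base] = str(exc)
    tests["end_composition_by_condition"] = comp_tests

    try:
        c = stats.spearman_correlation(theta_cnv, theta_meth)
        tests["cnv_vs_methylation_tf"] = {
            "rho": c.rho, "ci_low": c.ci_low, "ci_high": c.ci_high,
            "p_value": c.p_value, "n": c.n}
    except ValueError as exc:
        tests["cnv_vs_methylation_tf"] = str(exc)
    report["tests"] = tests

    theta_by_sample = {sid: per_sample[sid]["theta_methylation"] or 0.0
                       for sid in per_sample}
    methtf.export_cftools_table(marker_tables, theta_by_sample,
                                out_dir / "marker_means.tsv",
                                out_dir / "tumor_fractions_methylation.tsv")

    report = _jsonable(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _write_report_md(report, out_dir / "report.md")
    reference.close()

    if failures:
        raise PipelineError("; ".join(failures))
    return report


def _write_report_md(report: dict, path) -> None:
    lines = ["# FLARE cohort report", ""]
    lines.append("| sample | condition | reads kept | median len | "
                 "tf (CNV) | tf (meth) |")
    lines.append("|---|---|---|---|---|---|")
    for sid, res in sorted(report["samples"].items()):
        cnv = res["cnv"].get("all") or {}
        tf_cnv = cnv.get("tumor_fraction")
        lines.append(
            f"| {sid} | {res['condition']} "
            f"| {res['filter_report']['retained']} "
            f"| {res['length_summary']['median']} "
            f"| {tf_cnv if tf_cnv is None else round(tf_cnv, 4)} "
            f"| {res['theta_methylation']} |")
    lines.append("")
    nmf = report.get("nmf", {})
    lines.append(f"NMF: k={nmf.get('k')}, cophenetic="
                 f"{round(nmf.get('cophenetic', float('nan')), 4)}")
    for p, motifs in enumerate(nmf.get("top_motifs", [])):
        lines.append(f"- profile {p} top motifs: {', '.join(motifs[:5])}")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
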