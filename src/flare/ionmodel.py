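"""Aligned-record model, filtering, and base-modification (MM/ML) parsing.

Long-read cfDNA alignments arrive as SAM/BAM records whose auxiliary MM/ML
tags carry per-base modification calls (typically 5mC) made by the
basecaller.  This module turns each record into an :class:`AlignedFragment`
with strand-aware clip bookkeeping and decoded methylation calls, and applies
the standard cfDNA retention policy: primary, mapped records with mapping
quality >= 20 and a fragment-length cut.

Coordinates are 0-based half-open throughout; 1-based conventions exist only
inside the SAM/BED codecs (pysam handles them).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_AUTOSOME_RE = re.compile(r"^(chr)?\d+$")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_autosome(chrom: Optional[str]) -> bool:
    return chrom is not None and _AUTOSOME_RE.match(chrom) is not None


class Strand(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


class MalformedModificationError(ValueError):
    """MM/ML tag structure is inconsistent with the read sequence."""


@dataclass(frozen=True)
class MethylationCall:
    """One decoded base-modification call.

    ``read_offset`` indexes the *stored* (alignment-orientation) query
    sequence.  ``genomic_pos`` is the 0-based reference coordinate, or None
    when the base is soft-clipped / inserted.  ``probability`` is the bin
    midpoint (ml + 0.5) / 256 of the 8-bit ML likelihood.
    """

    read_offset: int
    genomic_pos: Optional[int]
    mod_code: str
    probability: float


@dataclass
class AlignedFragment:
    """One alignment record reduced to the fields the pipeline consumes."""

    read_id: str
    chrom: Optional[str]
    ref_start: int
    ref_end: int
    strand: Strand
    mapq: int
    query_length: int
    query_sequence: str
    clip_5prime: int
    clip_3prime: int
    is_primary: bool
    is_supplementary: bool
    is_mapped: bool
    # None means the record carried MM/ML tags that could not be decoded
    # (excluded from methylation analyses); [] means no tags present.
    meth_calls: Optional[list[MethylationCall]] = field(default_factory=list)
    raw: object = field(default=None, repr=False, compare=False)


@dataclass
class FilterPolicy:
    """Retention policy for cfDNA alignments.

    ``length_filter_mode``: "max" retains query_length <= max_fragment_length
    (the default, consistent with cfDNA fragment-size biology); "min" retains
    query_length > max_fragment_length.
    """

    min_mapq: int = 20
    max_fragment_length: int = 700
    length_filter_mode: str = "max"
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_unmapped: bool = True
    autosomes_only_for_methylation: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.max_fragment_length <= 0:
            raise ValueError("max_fragment_length must be > 0")
        if self.length_filter_mode not in ("max", "min"):
            raise ValueError("length_filter_mode must be 'max' or 'min'")


@dataclass
class FilterReport:
    """Per-reason drop counts; reasons are checked in a fixed order
    (mapped -> primary -> supplementary -> mapq -> length), so each record
    is counted once."""

    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0
    low_mapq: int = 0
    length: int = 0
    retained: int = 0

    @property
    def total(self) -> int:
        return (self.unmapped + self.secondary + self.supplementary
                + self.low_mapq + self.length + self.retained)

    def as_dict(self) -> dict:
        return {
            "unmapped": self.unmapped,
            "secondary": self.secondary,
            "supplementary": self.supplementary,
            "low_mapq": self.low_mapq,
            "length": self.length,
            "retained": self.retained,
        }


_MM_ENTRY_RE = re.compile(r"^([ACGTUN])([-+])((?:[a-z]+)|(?:\d+))([.?]?)$")


def parse_base_modifications(
    query_sequence: str,
    mm_tag: str,
    ml_values: Sequence[int],
    strand: Strand,
    aligned_pairs: Mapping[int, int],
    include_implicit: bool = False,
) -> list[MethylationCall]:
    """Decode SAM MM/ML base-modification tags into MethylationCall objects.

    The MM tag is defined over the read in its *original* (basecalled)
    orientation; for reverse-strand alignments the stored sequence is the
    reverse complement of that, so skip counts are consumed over
    revcomp(query_sequence) and offsets mapped back to stored coordinates.

    ``include_implicit``: for implicit-skip entries (no '?'), also emit the
    unlisted target bases as probability-0 calls.  Off by default.
    """
    if not mm_tag:
        return []
    if query_sequence is None:
        raise MalformedModificationError("MM tag present but no sequence")

    stored = query_sequence.upper()
    length = len(stored)
    original = revcomp(stored) if strand is Strand.REVERSE else stored

    calls: list[MethylationCall] = []
    ml_idx = 0
    for entry in mm_tag.split(";"):
        if not entry:
            continue
        head, *deltas_s = entry.split(",")
        m = _MM_ENTRY_RE.match(head)
        if m is None:
            raise MalformedModificationError(f"unparsable MM entry {head!r}")
        base, mod_strand, codes, flag = m.groups()
        if mod_strand == "-":
            raise MalformedModificationError(
                "opposite-strand modification entries are unsupported")
        code_list = [codes] if codes.isdigit() else list(codes)
        try:
            deltas = [int(d) for d in deltas_s]
        except ValueError as exc:
            raise MalformedModificationError(f"bad skip count in {entry!r}") from exc

        if base == "N":
            occurrences = list(range(len(original)))
        else:
            occurrences = [i for i, b in enumerate(original) if b == base]

        pos = -1  # index into occurrences of the previous listed base
        listed: list[int] = []
        for delta in deltas:
            pos += delta + 1
            if pos >= len(occurrences):
                raise MalformedModificationError(
                    f"MM entry {head!r} references more {base} bases than the "
                    f"read contains")
            listed.append(pos)

        n_needed = len(deltas) * len(code_list)
        if ml_idx + n_needed > len(ml_values):
            raise MalformedModificationError("ML array shorter than MM entries")

        listed_set = set(listed)
        for occ_rank in listed:
            orig_off = occurrences[occ_rank]
            for code in code_list:
                prob = (ml_values[ml_idx] + 0.5) / 256.0
                ml_idx += 1
                stored_off = (length - 1 - orig_off
                              if strand is Strand.REVERSE else orig_off)
                calls.append(MethylationCall(
                    read_offset=stored_off,
                    genomic_pos=aligned_pairs.get(stored_off),
                    mod_code=code,
                    probability=prob,
                ))
        if include_implicit and flag != "?":
            for occ_rank, orig_off in enumerate(occurrences):
                if occ_rank in listed_set:
                    continue
                stored_off = (length - 1 - orig_off
                              if strand is Strand.REVERSE else orig_off)
                for code in code_list:
                    calls.append(MethylationCall(
                        read_offset=stored_off,
                        genomic_pos=aligned_pairs.get(stored_off),
                        mod_code=code,
                        probability=0.0,
                    ))

    if ml_idx != len(ml_values):
        raise MalformedModificationError(
            f"ML array has {len(ml_values)} values, MM consumed {ml_idx}")
    calls.sort(key=lambda c: c.read_offset)
    return calls


def _clips(segment: pysam.AlignedSegment) -> tuple[int, int]:
    """(leading, trailing) soft+hard clip lengths from the CIGAR."""
    ct = segment.cigartuples
    if not ct:
        return 0, 0
    lead = trail = 0
    for op, ln in ct:
        if op in (4, 5):
            lead += ln
        else:
            break
    for op, ln in reversed(ct):
        if op in (4, 5):
            trail += ln
        else:
            break
    return lead, trail


def fragment_from_segment(
    segment: pysam.AlignedSegment,
    keep_raw: bool = True,
) -> AlignedFragment:
    """Convert one pysam AlignedSegment into an AlignedFragment."""
    strand = Strand.REVERSE if segment.is_reverse else Strand.FORWARD
    lead, trail = _clips(segment)
    if strand is Strand.REVERSE:
        clip5, clip3 = trail, lead
    else:
        clip5, clip3 = lead, trail

    seq = segment.query_sequence or ""
    qlen = segment.infer_read_length()  # includes hard-clipped bases
    if qlen is None:
        qlen = len(seq)

    meth: Optional[list[MethylationCall]] = []
    mm = None
    for tag in ("MM", "Mm"):
        if segment.has_tag(tag):
            mm = segment.get_tag(tag)
            break
    if mm:
        ml: Sequence[int] = ()
        for tag in ("ML", "Ml"):
            if segment.has_tag(tag):
                ml = list(segment.get_tag(tag))
                break
        pairs = {}
        if not segment.is_unmapped:
            pairs = {q: r for q, r in
                     segment.get_aligned_pairs(matches_only=True)}
        try:
            meth = parse_base_modifications(seq, mm, ml, strand, pairs)
        except MalformedModificationError as exc:
            log.warning("read %s: %s; methylation calls dropped",
                        segment.query_name, exc)
            meth = None

    return AlignedFragment(
        read_id=segment.query_name,
        chrom=segment.reference_name,
        ref_start=segment.reference_start if not segment.is_unmapped else 0,
        ref_end=segment.reference_end if segment.reference_end is not None else 0,
        strand=strand,
        mapq=segment.mapping_quality,
        query_length=qlen,
        query_sequence=seq,
        clip_5prime=clip5,
        clip_3prime=clip3,
        is_primary=not segment.is_secondary,
        is_supplementary=segment.is_supplementary,
        is_mapped=not segment.is_unmapped,
        meth_calls=meth,
        raw=segment if keep_raw else None,
    )


def parse_alignment_records(path, keep_raw: bool = True) -> Iterator[AlignedFragment]:
    """Stream AlignedFragments from a SAM (or BAM) file in input order."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for segment in fh.fetch(until_eof=True):
            yield fragment_from_segment(segment, keep_raw=keep_raw)


def filter_alignments(
    records: Iterable[AlignedFragment],
    policy: FilterPolicy,
) -> tuple[list[AlignedFragment], FilterReport]:
    """Apply the retention policy; drop reasons partition the input."""
    report = FilterReport()
    kept: list[AlignedFragment] = []
    for rec in records:
        if policy.drop_unmapped and not rec.is_mapped:
            report.unmapped += 1
            continue
        if policy.drop_secondary and not rec.is_primary:
            report.secondary += 1
            continue
        if policy.drop_supplementary and rec.is_supplementary:
            report.supplementary += 1
            continue
        if rec.mapq < policy.min_mapq:
            report.low_mapq += 1
            continue
        if policy.length_filter_mode == "max":
            if rec.query_length > policy.max_fragment_length:
                report.length += 1
                continue
        else:
            if rec.query_length <= policy.max_fragment_length:
                report.length += 1
                continue
        report.retained += 1
        kept.append(rec)
    log.info("filter: %s", report.as_dict())
    return kept, report


def write_sam(records: Sequence[AlignedFragment], path, header) -> None:
    """Write records (which must carry their raw pysam segments) as SAM."""
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            if rec.raw is None:
                raise ValueError(f"record {rec.read_id} has no raw segment")
            out.write(rec.raw)
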