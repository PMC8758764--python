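"""Split-read genotyping of a known insertion breakpoint.

A large insertion absent from the reference leaves a characteristic
footprint in short-read alignments: reads from the insertion-bearing (G)
haplotype that cross an insertion junction cannot align end to end and
are soft-clipped, with the clip boundary at the breakpoint, while reads
from the reference (d) haplotype span the breakpoint contiguously.  The
genotype at the locus is called from the ratio of split
(insertion-supporting) reads to total classifiable reads at the
breakpoint:

* ratio < 0.1, or at most 2 split reads          -> dd
* ratio > 0.9, or at most 2 non-split reads      -> GG
* otherwise                                      -> Gd

Reads flagged unmapped or duplicate are excluded, as are reads that
neither carry a clip boundary within ``clip_window`` (default 5 bp) of
the breakpoint nor overlap it by at least ``min_overlap`` (default 5)
aligned bases on both sides — short random overlaps cannot distinguish
the two alleles.  When both homozygote conditions fire at once (possible
only at very low read counts), or no classifiable reads exist, the
sample is left as an explicit no-call rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pysam

logger = logging.getLogger(__name__)

#: alignment operations that consume reference bases
_REF_CONSUMING = frozenset("MDN=X")
_CLIP_OPS = frozenset("SH")
_KNOWN_OPS = frozenset("MIDNSHP=X")

_PYSAM_OPS = "MIDNSHP=XB"

SPLIT = "split"
REFERENCE = "reference"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class AlignedReadRecord:
    """One alignment: flags, 1-based start, and parsed operation list."""

    name: str
    unmapped: bool
    duplicate: bool
    ref_start: int
    operations: tuple[tuple[str, int], ...]

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignedReadRecord":
        ops: tuple[tuple[str, int], ...] = ()
        if aln.cigartuples:
            ops = tuple((_PYSAM_OPS[op], length) for op, length in aln.cigartuples)
        return cls(
            name=aln.query_name or "",
            unmapped=aln.is_unmapped,
            duplicate=aln.is_duplicate,
            ref_start=(aln.reference_start + 1) if not aln.is_unmapped else 0,
            operations=ops,
        )

    def aligned_span(self) -> tuple[int, int]:
        """1-based inclusive reference interval consumed by the alignment."""
        length = sum(n for op, n in self.operations if op in _REF_CONSUMING)
        return self.ref_start, self.ref_start + length - 1


@dataclass(frozen=True)
class BreakpointEvidence:
    """Per-sample split-read evidence at the breakpoint."""

    sample_id: str
    n_total: int
    n_split: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_split < 0:
            raise ValueError("read counts must be non-negative")
        if self.n_split > self.n_total:
            raise ValueError("n_split cannot exceed n_total")

    @property
    def ratio(self) -> float | None:
        """Split-read fraction; None (undefined) when no reads classify."""
        if self.n_total == 0:
            return None
        return self.n_split / self.n_total


@dataclass(frozen=True)
class SVGenotype:
    call: str  # one of dd / Gd / GG / no-call
    evidence: BreakpointEvidence


def classify_read(
    read: AlignedReadRecord,
    breakpoint: int,
    clip_window: int = 5,
    min_overlap: int = 5,
) -> str:
    """Classify one read as split / reference / excluded at a breakpoint.

    A read supports the insertion (split) when a clip boundary — the
    reference coordinate where soft- or hard-clipping begins or ends —
    falls within ``clip_window`` of the breakpoint.  It supports the
    reference allele when its aligned span covers at least
    ``min_overlap`` bases on each side of the breakpoint without such a
    clip.  Everything else (unmapped, duplicate, too-short overlap,
    malformed operation string) is excluded.
    """
    if read.unmapped or read.duplicate:
        return EXCLUDED
    if not read.operations:
        logger.warning("read %s has no alignment operations; excluded", read.name)
        return EXCLUDED
    if any(op not in _KNOWN_OPS for op, _ in read.operations):
        bad = [op for op, _ in read.operations if op not in _KNOWN_OPS]
        logger.warning("read %s has unknown operations %s; excluded", read.name, bad)
        return EXCLUDED
    interior = [op for op, _ in read.operations[1:-1]]
    if any(op in _CLIP_OPS for op in interior):
        logger.warning("read %s has internal clipping; excluded", read.name)
        return EXCLUDED

    start, end = read.aligned_span()
    boundaries = []
    if read.operations[0][0] in _CLIP_OPS:
        boundaries.append(start)       # clipping ends where alignment begins
    if read.operations[-1][0] in _CLIP_OPS:
        boundaries.append(end)         # clipping begins after the last aligned base
    if any(abs(b - breakpoint) <= clip_window for b in boundaries):
        return SPLIT

    left = breakpoint - start + 1      # aligned bases at positions <= breakpoint
    right = end - breakpoint           # aligned bases at positions > breakpoint
    if left >= min_overlap and right >= min_overlap:
        return REFERENCE
    return EXCLUDED


def call_genotype(
    evidence: BreakpointEvidence,
    min_ratio: float = 0.1,
    max_ratio: float = 0.9,
    abs_count: int = 2,
) -> SVGenotype:
    """Call dd / Gd / GG / no-call from split-read evidence.

    dd requires ratio < ``min_ratio`` or n_split <= ``abs_count``; GG
    requires ratio > ``max_ratio`` or (n_total - n_split) <=
    ``abs_count``; anything between is Gd.  If both homozygote
    conditions hold simultaneously, or there are no classifiable reads,
    the evidence cannot discriminate and a no-call is returned.
    """
    if evidence.n_total == 0:
        return SVGenotype("no-call", evidence)
    ratio = evidence.ratio
    dd_cond = (ratio < min_ratio) or (evidence.n_split <= abs_count)
    gg_cond = (ratio > max_ratio) or (evidence.n_total - evidence.n_split <= abs_count)
    if dd_cond and gg_cond:
        return SVGenotype("no-call", evidence)
    if dd_cond:
        return SVGenotype("dd", evidence)
    if gg_cond:
        return SVGenotype("GG", evidence)
    return SVGenotype("Gd", evidence)


def collect_evidence(
    reads,
    sample_id: str,
    breakpoint: int,
    clip_window: int = 5,
    min_overlap: int = 5,
) -> BreakpointEvidence:
    """Count split and classifiable reads for one sample.

    ``reads`` may be a SAM/BAM path or any iterable of alignment
    records (:class:`AlignedReadRecord`, pysam segments, or simulated
    reads).
    """
    n_split = 0
    n_total = 0
    for read in _iter_records(reads):
        category = classify_read(read, breakpoint, clip_window, min_overlap)
        if category == EXCLUDED:
            continue
        n_total += 1
        if category == SPLIT:
            n_split += 1
    return BreakpointEvidence(sample_id=sample_id, n_total=n_total, n_split=n_split)


def _iter_records(source) -> Iterable[AlignedReadRecord]:
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with pysam.AlignmentFile(str(source), check_sq=False) as af:
            for aln in af:
                yield AlignedReadRecord.from_pysam(aln)
        return
    for item in source:
        if isinstance(item, AlignedReadRecord):
            yield item
        elif isinstance(item, pysam.AlignedSegment):
            yield AlignedReadRecord.from_pysam(item)
        else:  # simulate.SimRead or compatible
            yield AlignedReadRecord(
                name=item.name,
                unmapped=item.unmapped,
                duplicate=item.duplicate,
                ref_start=item.pos,
                operations=tuple(item.cigar),
            )


def genotype_cohort(
    alignments: Mapping[str, object],
    breakpoint: int,
    *,
    clip_window: int = 5,
    min_overlap: int = 5,
    min_ratio: float = 0.1,
    max_ratio: float = 0.9,
    abs_count: int = 2,
) -> dict[str, SVGenotype]:
    """Genotype every sample in a cohort at a known breakpoint.

    ``alignments`` maps sample id to a SAM/BAM path or an iterable of
    alignment records.  Samples with no reads at the locus are no-calls.
    """
    calls: dict[str, SVGenotype] = {}
    for sample_id, source in alignments.items():
        evidence = collect_evidence(
            _iter_records(source), sample_id, breakpoint, clip_window, min_overlap
        )
        genotype = call_genotype(evidence, min_ratio, max_ratio, abs_count)
        if genotype.call == "no-call":
            logger.info(
                "sample %s: no-call (split=%d total=%d)",
                sample_id, evidence.n_split, evidence.n_total,
            )
        calls[sample_id] = genotype
    return calls


_GT_CODES = {"dd": (0, 0), "Gd": (0, 1), "GG": (1, 1), "no-call": (None, None)}
GENOTYPE_DOSAGE = {"dd": 0.0, "Gd": 1.0, "GG": 2.0}


def write_sv_vcf(
    calls: Mapping[str, SVGenotype],
    path,
    *,
    contig: str,
    contig_length: int,
    breakpoint: int,
    sv_length: int | None = None,
    variant_id: str = "gold_SV",
    ref_base: str = "N",
) -> None:
    """Emit the cohort genotypes as one symbolic-insertion VCF record.

    Per-sample FORMAT fields carry the evidence: GT plus SR (split
    reads) and TR (total classifiable reads).  No-calls are missing
    genotypes.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_meta("INFO", items=[("ID", "SVTYPE"), ("Number", "1"),
                                   ("Type", "String"), ("Description", "Structural variant type")])
    header.add_meta("INFO", items=[("ID", "SVLEN"), ("Number", "1"),
                                   ("Type", "Integer"), ("Description", "Insertion length")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "SR"), ("Number", "1"),
                                     ("Type", "Integer"), ("Description", "Split (insertion-supporting) reads")])
    header.add_meta("FORMAT", items=[("ID", "TR"), ("Number", "1"),
                                     ("Type", "Integer"), ("Description", "Total classifiable reads")])
    samples = list(calls)
    header.add_samples(samples)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        rec = vf.new_record(
            contig=contig,
            start=breakpoint - 1,
            stop=breakpoint,
            alleles=(ref_base, "<INS>"),
            id=variant_id,
        )
        rec.info["SVTYPE"] = "INS"
        if sv_length is not None:
            rec.info["SVLEN"] = sv_length
        for sample_id in samples:
            genotype = calls[sample_id]
            rec.samples[sample_id]["GT"] = _GT_CODES[genotype.call]
            rec.samples[sample_id]["SR"] = genotype.evidence.n_split
            rec.samples[sample_id]["TR"] = genotype.evidence.n_total
        vf.write(rec)


def read_sv_vcf(path) -> dict[str, str]:
    """Read back the genotype calls written by :func:`write_sv_vcf`."""
    inverse = {value: key for key, value in _GT_CODES.items()}
    with pysam.VariantFile(str(path)) as vf:
        rec = next(iter(vf))
        out = {}
        for sample_id, sample in rec.samples.items():
            gt = sample["GT"]
            gt = tuple(gt) if gt is not None else (None, None)
            out[sample_id] = inverse.get(gt, "no-call")
        return out


def evidence_table(calls: Mapping[str, SVGenotype]) -> "pd.DataFrame":
    """Tabulate per-sample evidence and calls (TSV-ready)."""
    import pandas as pd

    rows = []
    for sample_id, genotype in calls.items():
        ev = genotype.evidence
        rows.append(
            {
                "id": sample_id,
                "n_split": ev.n_split,
                "n_total": ev.n_total,
                "ratio": float("nan") if ev.ratio is None else ev.ratio,
                "called_genotype": genotype.call,
            }
        )
    return pd.DataFrame(rows)
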