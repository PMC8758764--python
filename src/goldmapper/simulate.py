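"""Synthetic data generation for the gold-locus pipeline.

This module builds every input the downstream analysis consumes, with the
statistical structure the method assumes, so the whole pipeline can be
exercised end to end without external data:

* a *locus model* — a reference ("d") haplotype and an alternate ("G")
  haplotype that carries a transposon-style inverted-repeat insertion
  (two arms in head-to-head orientation separated by a short loop, the
  second arm differing from the reverse complement of the first by a
  small number of single-base deletions);
* a *diploid cohort* drawn under Hardy-Weinberg equilibrium at a chosen
  G-allele frequency, with a dominant phenotype model: carriers are gold
  unless sampled before their ontogenetic color transition (a
  dosage-dependent probability, higher for heterozygotes), and
  non-carriers are dark except for a rare phenocopy;
* independent background marker genotypes (for kinship and scan testing)
  with per-marker minor-allele frequencies drawn from a range and
  marker-wise missingness;
* short-read alignments around the insertion breakpoint, where
  G-haplotype reads that cross an insertion junction appear soft-clipped
  at the breakpoint — the split-read evidence the genotyper counts.

Alignments are emulated analytically rather than produced by a real
aligner: the mapping of every alternate-haplotype read onto the
reference is known exactly from its sampled coordinates, which makes the
soft-clip evidence exact and removes any external-tool dependence.
Reads falling wholly inside the insertion are emitted unmapped-flagged
(the transposon-derived insert would multi-map in practice, and such
reads carry no breakpoint signal either way).

All interfaces use 1-based inclusive coordinates (SAM/VCF convention).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

GENOTYPES = ("dd", "Gd", "GG")
PHENOTYPES = ("dark", "gold")

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case preserved)."""
    return seq.translate(_RC_TABLE)[::-1]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. ACGT sequence of the given length."""
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# Locus model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusModel:
    """A two-haplotype locus: reference (d) and insertion-bearing (G).

    The alternate haplotype is the reference with
    ``arm + loop + arm2`` inserted immediately after ``breakpoint``
    (1-based).  ``arm2`` is the reverse complement of ``arm`` carrying
    ``arm_edit_count`` single-base deletions, so the insertion is an
    inverted repeat with a ``len(arm)`` stem and a ``len(loop)`` loop.
    """

    ref_sequence: str
    arm_sequence: str
    loop_sequence: str
    arm2_sequence: str
    arm_edit_count: int
    breakpoint: int
    contig: str = "chr11"

    @property
    def insertion_sequence(self) -> str:
        return self.arm_sequence + self.loop_sequence + self.arm2_sequence

    @property
    def insertion_length(self) -> int:
        return len(self.insertion_sequence)

    @property
    def alt_sequence(self) -> str:
        bp = self.breakpoint
        return self.ref_sequence[:bp] + self.insertion_sequence + self.ref_sequence[bp:]

    def haplotypes(self, genotype: str) -> tuple[str, str]:
        """The two haplotype sequences of a diploid genotype."""
        if genotype == "dd":
            return (self.ref_sequence, self.ref_sequence)
        if genotype == "Gd":
            return (self.alt_sequence, self.ref_sequence)
        if genotype == "GG":
            alt = self.alt_sequence
            return (alt, alt)
        raise ValueError(f"unknown genotype {genotype!r}")


def build_locus(
    ref_length: int,
    arm_length: int,
    loop_length: int,
    arm_edit_count: int,
    breakpoint: int,
    seed: int,
    contig: str = "chr11",
) -> LocusModel:
    """Construct a random locus with an inverted-repeat insertion.

    Parameters mirror the geometry being emulated: an ``arm_length`` stem
    duplicated in inverted orientation around a ``loop_length`` spacer,
    the two copies differing by ``arm_edit_count`` single-base deletions
    applied to the second copy.  The deletions are placed away from the
    arm ends (margin 10 bp) and the loop is resampled so that its outer
    bases do not themselves base-pair, keeping the stated stem/loop
    geometry identical to the maximal inverted repeat of the insertion.

    Raises
    ------
    ValueError
        If the breakpoint is not strictly inside the reference sequence
        or the edit count exceeds what the arm can absorb.
    """
    if ref_length < 2:
        raise ValueError("ref_length must be at least 2")
    if not (1 <= breakpoint <= ref_length - 1):
        raise ValueError(
            f"breakpoint {breakpoint} is not strictly inside the "
            f"reference sequence (1..{ref_length - 1})"
        )
    if arm_length < 0 or loop_length < 0:
        raise ValueError("arm and loop lengths must be non-negative")
    if arm_edit_count < 0:
        raise ValueError("arm_edit_count must be non-negative")
    if arm_edit_count > 0 and arm_length < arm_edit_count + 20:
        raise ValueError("arm too short for the requested edit count")

    rng = np.random.default_rng(seed)
    ref = random_sequence(rng, ref_length)
    arm = random_sequence(rng, arm_length)

    loop = random_sequence(rng, loop_length)
    if loop_length >= 1:
        # Outer loop bases must not extend the stem by chance pairing.
        while loop[0] == revcomp(loop[-1]):
            loop = random_sequence(rng, loop_length)

    arm2 = revcomp(arm)
    if arm_edit_count > 0:
        margin = 10
        positions = rng.choice(
            np.arange(margin, arm_length - margin),
            size=arm_edit_count,
            replace=False,
        )
        kept = np.ones(len(arm2), dtype=bool)
        kept[positions] = False
        arm2 = "".join(np.array(list(arm2))[kept])

    # Left-normalize the representation: if the insertion's last base
    # equals the reference base at the breakpoint, the same alternate
    # haplotype could be written with the insertion one base further
    # left, making the stated breakpoint ambiguous.  Nudge that
    # reference base so the stated coordinate is the left-aligned one.
    insertion = arm + loop + arm2
    if insertion and insertion[-1] == ref[breakpoint - 1]:
        replacement = next(b for b in "ACGT" if b != insertion[-1])
        ref = ref[: breakpoint - 1] + replacement + ref[breakpoint:]

    return LocusModel(
        ref_sequence=ref,
        arm_sequence=arm,
        loop_sequence=loop,
        arm2_sequence=arm2,
        arm_edit_count=arm_edit_count,
        breakpoint=breakpoint,
        contig=contig,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Population and phenotype-model parameters for a simulated cohort.

    The phenotype model is Mendelian dominance with incomplete
    penetrance at sampling time: a carrier (Gd or GG) is dark only if it
    has not yet gone through the dark-to-gold transition
    (``p_untransformed_het`` / ``p_untransformed_hom``; the transition
    is dosage-dependent, so the heterozygote probability must be at
    least the homozygote one), and a dd individual is gold only as a
    rare phenocopy (``phenocopy_rate``).

    Defaults emulate a mapping panel enriched for the rare gold morph
    (roughly one third gold), not a wild population sample.
    """

    n_individuals: int = 300
    g_allele_freq: float = 0.2
    p_untransformed_het: float = 0.08
    p_untransformed_hom: float = 0.01
    phenocopy_rate: float = 0.005
    n_background_markers: int = 500
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "g_allele_freq": self.g_allele_freq,
            "p_untransformed_het": self.p_untransformed_het,
            "p_untransformed_hom": self.p_untransformed_hom,
            "phenocopy_rate": self.phenocopy_rate,
            "missing_rate": self.missing_rate,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.p_untransformed_hom > self.p_untransformed_het:
            raise ValueError(
                "p_untransformed_hom must not exceed p_untransformed_het "
                "(the color transition is dosage-dependent)"
            )
        lo, hi = self.background_maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("background_maf_range must satisfy 0 <= lo <= hi <= 0.5")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.n_background_markers < 0:
            raise ValueError("n_background_markers must be non-negative")


@dataclass
class SimulatedCohort:
    """Cohort truth table plus background marker genotypes.

    ``cohort`` has one row per individual (id, population,
    true_genotype, phenotype).  ``dosages`` is a variants x samples
    table of alternate-allele dosages in {0, 1, 2} with NaN for missing
    calls; ``variants`` carries chrom/pos per marker.
    """

    cohort: pd.DataFrame
    dosages: pd.DataFrame
    variants: pd.DataFrame


def simulate_cohort(config: CohortConfig, locus: LocusModel) -> SimulatedCohort:
    """Draw a diploid cohort under Hardy-Weinberg and the dominance model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    g = config.g_allele_freq

    geno_probs = np.array([(1 - g) ** 2, 2 * g * (1 - g), g * g])
    genotype_idx = rng.choice(3, size=n, p=geno_probs)
    genotypes = np.array(GENOTYPES)[genotype_idx]

    u = rng.random(n)
    p_dark = np.select(
        [genotype_idx == 0, genotype_idx == 1, genotype_idx == 2],
        [1.0 - config.phenocopy_rate,
         config.p_untransformed_het,
         config.p_untransformed_hom],
    )
    phenotypes = np.where(u < p_dark, "dark", "gold")

    ids = [f"S{i:04d}" for i in range(n)]
    cohort = pd.DataFrame(
        {
            "id": ids,
            "population": "sim",
            "true_genotype": genotypes,
            "phenotype": phenotypes,
        }
    )

    m = config.n_background_markers
    lo, hi = config.background_maf_range
    mafs = rng.uniform(lo, hi, size=m)
    dosage = rng.binomial(2, mafs[:, None], size=(m, n)).astype(float)
    if config.missing_rate > 0:
        dosage[rng.random((m, n)) < config.missing_rate] = np.nan

    positions = np.sort(rng.choice(np.arange(1, 40_000_000), size=m, replace=False))
    variant_ids = [f"M{i:05d}" for i in range(m)]
    variants = pd.DataFrame(
        {"chrom": locus.contig, "pos": positions}, index=variant_ids
    )
    dosages = pd.DataFrame(dosage, index=variant_ids, columns=ids)

    return SimulatedCohort(cohort=cohort, dosages=dosages, variants=variants)


def write_cohort_table(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "population", "true_genotype", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table {path} is missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimConfig:
    """Short-read simulation parameters (single-end, uniform sampling)."""

    coverage: float = 40.0
    read_length: int = 100
    substitution_rate: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 10:
            raise ValueError("read_length must be at least 10")
        for name in ("substitution_rate", "duplicate_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SimRead:
    """One simulated alignment record (SAM semantics, 1-based pos)."""

    name: str
    unmapped: bool
    duplicate: bool
    pos: int                      # 1-based leftmost aligned reference base; 0 if unmapped
    cigar: tuple[tuple[str, int], ...]
    sequence: str

    @property
    def flag(self) -> int:
        return (0x4 if self.unmapped else 0) | (0x400 if self.duplicate else 0)


def _place_alt_read(start: int, read_length: int, bp: int, ins_len: int):
    """Map a read sampled at 1-based ``start`` on the alternate haplotype
    onto the reference.  Returns (pos, cigar, unmapped)."""
    s, e = start, start + read_length - 1
    if e <= bp:
        return s, (("M", read_length),), False
    if s >= bp + ins_len + 1:
        return s - ins_len, (("M", read_length),), False
    if s >= bp + 1 and e <= bp + ins_len:
        return 0, (), True
    if s <= bp:
        # crosses the left junction: aligned prefix ends exactly at bp
        m = bp - s + 1
        return s, (("M", m), ("S", read_length - m)), False
    # crosses the right junction: aligned suffix starts at bp + 1
    clip = bp + ins_len - s + 1
    return bp + 1, (("S", clip), ("M", read_length - clip)), False


def simulate_reads(
    genotype: str,
    locus: LocusModel,
    config: ReadSimConfig,
    *,
    seed: int | None = None,
    sample_id: str = "sample",
) -> list[SimRead]:
    """Simulate aligned reads for one diploid individual.

    Each haplotype is sampled uniformly at half the target coverage.
    Reference-haplotype reads align end to end; alternate-haplotype
    reads crossing an insertion junction are soft-clipped with the clip
    boundary at the breakpoint, and reads wholly inside the insertion
    are unmapped-flagged.  Substitution errors are injected into the
    read sequence only, after placement, so clipping never moves.
    """
    if config.read_length > len(locus.ref_sequence):
        raise ValueError("read_length exceeds the reference locus length")

    # separate placement and noise streams: error injection can never
    # move read coordinates or clip boundaries
    placement_ss, noise_ss = np.random.SeedSequence(
        config.seed if seed is None else seed
    ).spawn(2)
    rng = np.random.default_rng(placement_ss)
    noise_rng = np.random.default_rng(noise_ss)
    bp = locus.breakpoint
    ins_len = locus.insertion_length
    rl = config.read_length
    reads: list[SimRead] = []

    for hap_idx, hap in enumerate(locus.haplotypes(genotype)):
        n_reads = rng.poisson(config.coverage / 2.0 * len(hap) / rl)
        starts = rng.integers(1, len(hap) - rl + 2, size=n_reads)
        is_alt = len(hap) != len(locus.ref_sequence)
        for i, s in enumerate(starts):
            s = int(s)
            if is_alt:
                pos, cigar, unmapped = _place_alt_read(s, rl, bp, ins_len)
            else:
                pos, cigar, unmapped = s, (("M", rl),), False
            seq = hap[s - 1 : s - 1 + rl]
            if config.substitution_rate > 0:
                hits = np.nonzero(noise_rng.random(rl) < config.substitution_rate)[0]
                if hits.size:
                    chars = list(seq)
                    for j in hits:
                        alternatives = [b for b in "ACGT" if b != chars[j]]
                        chars[j] = alternatives[noise_rng.integers(0, 3)]
                    seq = "".join(chars)
            duplicate = bool(noise_rng.random() < config.duplicate_rate)
            reads.append(
                SimRead(
                    name=f"{sample_id}.{hap_idx}.{i}",
                    unmapped=unmapped,
                    duplicate=duplicate,
                    pos=pos,
                    cigar=cigar,
                    sequence=seq,
                )
            )
    return reads


_CIGAR_CODES = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5}


def sam_header(locus: LocusModel) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": locus.contig, "LN": len(locus.ref_sequence)}],
        }
    )


def write_sam(reads: list[SimRead], locus: LocusModel, path) -> None:
    """Write simulated reads as a coordinate-sorted SAM file with header."""
    header = sam_header(locus)
    ordered = sorted(reads, key=lambda r: (r.unmapped, r.pos, r.name))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in ordered:
            aln = pysam.AlignedSegment(header)
            aln.query_name = read.name
            aln.flag = read.flag
            aln.query_sequence = read.sequence
            if read.unmapped:
                aln.reference_id = -1
                aln.reference_start = -1
                aln.mapping_quality = 0
            else:
                aln.reference_id = 0
                aln.reference_start = read.pos - 1
                aln.mapping_quality = 60
                aln.cigartuples = [(_CIGAR_CODES[op], ln) for op, ln in read.cigar]
            out.write(aln)


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA, normalizing sequences to uppercase (N preserved)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
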