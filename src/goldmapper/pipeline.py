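"""Pipeline configuration, orchestration, and file-format validation.

One :class:`PipelineConfig` holds every stage's parameters with the
published analysis values as defaults where such values exist (genotyper
thresholds 0.1 / 0.9 with the absolute-count override of 2, clip window
+/-5 bp, minimum overlap 5 bp, MAF >= 0.05, missingness <= 20%) and
serializes losslessly to JSON or YAML.

:func:`run_pipeline` executes simulate -> genotype -> associate ->
concordance (plus, optionally, insertion discovery and inverted-repeat
characterization on the simulated haplotypes) and writes a manifest
recording the configuration hash, the derived per-stage seeds, package
version, and a SHA-256 digest of every output file.  A single global
seed is expanded into per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn`` in a fixed stage order
(locus, cohort, reads), with per-sample read seeds spawned from the
reads child in cohort order, so any stage can be re-run in isolation
and identical configurations yield byte-identical outputs.

Logging goes to stderr with stage-tagged lines; machine-readable
outputs are never mixed into the log stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import concordance as concord_mod
from . import genotyper as geno_mod
from . import svstruct as sv_mod
from .simulate import (
    CohortConfig,
    LocusModel,
    ReadSimConfig,
    build_locus,
    read_fasta,
    simulate_cohort,
    simulate_reads,
    write_cohort_table,
    write_fasta,
    write_sam,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusParams:
    ref_length: int = 10_000
    arm_length: int = 4_100
    loop_length: int = 50
    arm_edit_count: int = 2
    breakpoint: int = 5_000
    contig: str = "chr11"


@dataclass(frozen=True)
class GenotyperParams:
    clip_window: int = 5
    min_overlap: int = 5
    min_ratio: float = 0.1
    max_ratio: float = 0.9
    abs_count: int = 2


@dataclass(frozen=True)
class AssocParams:
    maf_min: float = 0.05
    max_missing: float = 0.20
    no_kinship: bool = False


@dataclass(frozen=True)
class SvParams:
    anchor_k: int = 31
    word_size: int = 15
    min_stem: int = 500
    band_width: int = 16


@dataclass(frozen=True)
class PipelineConfig:
    locus: LocusParams = field(default_factory=LocusParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    reads: ReadSimConfig = field(default_factory=ReadSimConfig)
    genotyper: GenotyperParams = field(default_factory=GenotyperParams)
    association: AssocParams = field(default_factory=AssocParams)
    svstruct: SvParams = field(default_factory=SvParams)
    seed: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        cohort = dict(data.get("cohort", {}))
        if "background_maf_range" in cohort:
            cohort["background_maf_range"] = tuple(cohort["background_maf_range"])
        return cls(
            locus=LocusParams(**data.get("locus", {})),
            cohort=CohortConfig(**cohort),
            reads=ReadSimConfig(**data.get("reads", {})),
            genotyper=GenotyperParams(**data.get("genotyper", {})),
            association=AssocParams(**data.get("association", {})),
            svstruct=SvParams(**data.get("svstruct", {})),
            seed=int(data.get("seed", 1)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Expand the global seed into per-stage seeds (fixed order)."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("locus", "cohort", "reads")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            digest.update(block)
    return digest.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir,
    *,
    include_svstruct: bool = True,
    keep_alignments: bool = True,
) -> dict:
    """Run simulate -> genotype -> associate -> concordance (+ svstruct).

    Returns the manifest (also written to ``outdir/manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_seeds = derive_stage_seeds(config.seed)
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "version": _package_version(),
        "stages": {},
    }

    def register(stage: str, *paths: Path) -> None:
        entry = manifest["stages"].setdefault(stage, {"outputs": {}})
        for path in paths:
            entry["outputs"][str(path.relative_to(outdir))] = _sha256(path)

    try:
        # ------------------------------------------------------ simulate
        logger.info("[simulate] building locus and cohort")
        locus = build_locus(
            config.locus.ref_length, config.locus.arm_length,
            config.locus.loop_length, config.locus.arm_edit_count,
            config.locus.breakpoint, seed=stage_seeds["locus"],
            contig=config.locus.contig,
        )
        ref_fa = outdir / "reference.fa"
        alt_fa = outdir / "alternate.fa"
        write_fasta({f"{locus.contig}_d": locus.ref_sequence}, ref_fa)
        write_fasta({f"{locus.contig}_G": locus.alt_sequence}, alt_fa)

        cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seeds["cohort"])
        sim = simulate_cohort(cohort_cfg, locus)
        truth_tsv = outdir / "cohort_truth.tsv"
        write_cohort_table(sim.cohort, truth_tsv)
        markers = assoc_mod.GenotypeMatrix(dosages=sim.dosages, variants=sim.variants)
        markers_vcf = outdir / "markers.vcf"
        markers.to_vcf(markers_vcf)
        register("simulate", ref_fa, alt_fa, truth_tsv, markers_vcf)

        logger.info("[simulate] writing per-sample alignments")
        aln_dir = outdir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        read_seeds = np.random.SeedSequence(stage_seeds["reads"]).spawn(
            len(sim.cohort)
        )
        sam_paths: dict[str, Path] = {}
        for (_, row), child in zip(sim.cohort.iterrows(), read_seeds):
            sample_seed = int(child.generate_state(1)[0] % (2**31))
            reads = simulate_reads(
                row["true_genotype"], locus, config.reads,
                seed=sample_seed, sample_id=row["id"],
            )
            path = aln_dir / f"{row['id']}.sam"
            write_sam(reads, locus, path)
            sam_paths[row["id"]] = path
        if keep_alignments:
            register("simulate", *sam_paths.values())

        # ------------------------------------------------------ genotype
        logger.info("[genotype] split-read genotyping at breakpoint %d",
                    locus.breakpoint)
        gp = config.genotyper
        calls = geno_mod.genotype_cohort(
            sam_paths, locus.breakpoint,
            clip_window=gp.clip_window, min_overlap=gp.min_overlap,
            min_ratio=gp.min_ratio, max_ratio=gp.max_ratio,
            abs_count=gp.abs_count,
        )
        sv_vcf = outdir / "sv_genotypes.vcf"
        geno_mod.write_sv_vcf(
            calls, sv_vcf, contig=locus.contig,
            contig_length=len(locus.ref_sequence),
            breakpoint=locus.breakpoint, sv_length=locus.insertion_length,
        )
        evidence_tsv = outdir / "sv_evidence.tsv"
        geno_mod.evidence_table(calls).to_csv(evidence_tsv, sep="\t", index=False)
        register("genotype", sv_vcf, evidence_tsv)

        # ------------------------------------------------------ associate
        logger.info("[assoc] mixed-model scan over %d markers + SV",
                    markers.n_variants)
        sv_dosage = pd.Series(
            {s: geno_mod.GENOTYPE_DOSAGE.get(calls[s].call, np.nan)
             for s in sim.cohort["id"]},
            name="gold_SV",
        )
        sv_freq = sv_dosage.mean(skipna=True) / 2.0
        sv_maf = min(sv_freq, 1.0 - sv_freq) if np.isfinite(sv_freq) else 0.0
        include_sv = sv_maf >= config.association.maf_min
        if not include_sv:
            logger.info("[assoc] SV excluded from the scan: MAF %.4f below %.2f "
                        "(monomorphic or near-monomorphic)", sv_maf,
                        config.association.maf_min)
            full = markers
        else:
            dosages = pd.concat([markers.dosages, sv_dosage.to_frame().T])
            variants = pd.concat([
                markers.variants,
                pd.DataFrame({"chrom": [locus.contig],
                              "pos": [locus.breakpoint]}, index=["gold_SV"]),
            ])
            full = assoc_mod.GenotypeMatrix(dosages=dosages, variants=variants)
        phenotype = sim.cohort.set_index("id")["phenotype"].map(
            {"dark": 0.0, "gold": 1.0}
        )
        scan = assoc_mod.gwas_scan(
            full, phenotype,
            maf_min=config.association.maf_min,
            max_missing=config.association.max_missing,
            no_kinship=config.association.no_kinship,
        )
        scan_tsv = outdir / "association.tsv"
        assoc_mod.write_scan_tsv(scan, scan_tsv)
        register("assoc", scan_tsv)

        # ------------------------------------------------------ concordance
        logger.info("[concord] genotype-phenotype concordance")
        merged = sim.cohort.assign(
            called_genotype=[calls[s].call for s in sim.cohort["id"]]
        )
        table = concord_mod.crosstab(merged)
        conflicts = concord_mod.conflict_rates(table)
        concord_json = outdir / "concordance.json"
        with open(concord_json, "w") as fh:
            json.dump(
                {"table": {g: {p: int(table.counts.at[g, p])
                               for p in concord_mod.PHENOTYPE_LEVELS}
                           for g in concord_mod.GENOTYPE_LEVELS},
                 "n_no_call": table.n_no_call,
                 "conflicts": conflicts.to_dict()},
                fh, indent=2,
            )
        register("concord", concord_json)

        # ------------------------------------------------------ svstruct
        if include_svstruct:
            logger.info("[svstruct] insertion discovery and repeat geometry")
            ins_calls = sv_mod.call_insertion(
                locus.ref_sequence, locus.alt_sequence,
                anchor_k=config.svstruct.anchor_k,
            )
            ir = None
            if ins_calls:
                ir = sv_mod.find_inverted_repeat(
                    ins_calls[0].inserted_sequence,
                    min_stem=config.svstruct.min_stem,
                    band_width=config.svstruct.band_width,
                    word_size=config.svstruct.word_size,
                )
                dotplot = sv_mod.self_dotplot(
                    ins_calls[0].inserted_sequence,
                    word_size=config.svstruct.word_size,
                )
                dotplot_tsv = outdir / "dotplot.tsv"
                dotplot.to_tsv(dotplot_tsv)
                register("svstruct", dotplot_tsv)
            sv_json = outdir / "svstruct.json"
            with open(sv_json, "w") as fh:
                json.dump(
                    {"insertions": [
                        {"breakpoint": c.breakpoint, "length": c.length}
                        for c in ins_calls
                    ],
                     "inverted_repeat": None if ir is None else ir.to_dict()},
                    fh, indent=2,
                )
            register("svstruct", sv_json)
            if ir is not None:
                bed = outdir / "arms.bed"
                with open(bed, "w") as fh:
                    fh.write(f"insertion\t{ir.arm1[0] - 1}\t{ir.arm1[1]}\tarm1\n")
                    fh.write(f"insertion\t{ir.arm2[0] - 1}\t{ir.arm2[1]}\tarm2\n")
                register("svstruct", bed)
    except Exception:
        logger.exception("pipeline aborted; partial outputs preserved in %s", outdir)
        raise

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("goldmapper")
    except Exception:
        return "unknown"


# ---------------------------------------------------------------------------
# Format validation / round-trip checks
# ---------------------------------------------------------------------------

def _validate_fasta(path: Path) -> int:
    records = read_fasta(path)
    if not records:
        raise ValueError("no FASTA records found")
    for name, seq in records.items():
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"record {name}: unexpected characters {sorted(bad)}")
    return len(records)


def _validate_sam(path: Path) -> int:
    import pysam

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@"):
                continue
            if len(line.rstrip("\n").split("\t")) < 11:
                raise ValueError(f"line {lineno}: truncated SAM record")
    n = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for _ in af:
            n += 1
    return n


def _validate_vcf(path: Path) -> int:
    import pysam

    n = 0
    with pysam.VariantFile(str(path)) as vf:
        for _ in vf:
            n += 1
    return n


def _validate_tsv(path: Path) -> int:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("fewer than two tab-separated columns")
    return len(df)


_VALIDATORS = {
    ".fa": _validate_fasta, ".fasta": _validate_fasta,
    ".sam": _validate_sam,
    ".vcf": _validate_vcf,
    ".tsv": _validate_tsv,
}


def io_roundtrips(files) -> dict:
    """Validate that pipeline files parse cleanly; report per file.

    ``files`` is an iterable of paths; the format is inferred from the
    suffix (.fa/.fasta, .sam, .vcf, .tsv).  Each entry of the returned
    report carries ``ok``, a record count, and a positioned error
    message on failure.
    """
    report: dict[str, dict] = {}
    for item in files:
        path = Path(item)
        validator = _VALIDATORS.get(path.suffix.lower())
        entry: dict = {"ok": False, "n_records": None, "error": None}
        if validator is None:
            entry["error"] = f"unsupported format {path.suffix!r}"
        else:
            try:
                entry["n_records"] = validator(path)
                entry["ok"] = True
            except Exception as exc:  # noqa: BLE001 - reported, not swallowed
                entry["error"] = f"{path.name}: {exc}"
        report[str(path)] = entry
    return report
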