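"""Genotype-phenotype concordance accounting for a dominant locus.

Under strict dominance every G-allele carrier (Gd or GG) should be gold
and every dd individual dark.  In practice two kinds of conflicts occur
and are worth counting separately:

* dark carriers — genetically gold individuals sampled before their
  ontogenetic color transition (the transition is dosage-dependent, so
  these are expected to be mostly heterozygotes);
* gold dd individuals — phenocopies.

This module cross-tabulates called genotypes against phenotypes,
reports both conflict percentages (rounded half-even to one decimal, as
printed), and provides the small coordinate arithmetic used to relate
the insertion breakpoint to association-peak positions (signed
distances in kb).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import pandas as pd

GENOTYPE_LEVELS = ("dd", "Gd", "GG")
PHENOTYPE_LEVELS = ("dark", "gold")
NO_CALL = "no-call"


@dataclass(frozen=True)
class ConcordanceTable:
    """3x2 genotype-by-phenotype counts, with no-calls tallied aside."""

    counts: pd.DataFrame          # index dd/Gd/GG, columns dark/gold
    n_no_call: int = 0

    @property
    def phenotype_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def genotype_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_json(self, path) -> None:
        payload = {
            "counts": {g: {p: int(self.counts.at[g, p]) for p in PHENOTYPE_LEVELS}
                       for g in GENOTYPE_LEVELS},
            "n_no_call": int(self.n_no_call),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="genotype")


@dataclass(frozen=True)
class ConflictReport:
    """Counts and percentages of genotype-phenotype conflicts.

    Percentages are 100 * count / phenotype-total rounded half-even to
    one decimal; they are None (undefined) when the phenotype total is
    zero rather than being reported as 0.
    """

    n_dark_with_G: int
    dark_total: int
    pct_dark_with_G: float | None
    n_gold_dd: int
    gold_total: int
    pct_gold_dd: float | None

    def to_dict(self) -> dict:
        return {
            "n_dark_with_G": self.n_dark_with_G,
            "dark_total": self.dark_total,
            "pct_dark_with_G": self.pct_dark_with_G,
            "n_gold_dd": self.n_gold_dd,
            "gold_total": self.gold_total,
            "pct_gold_dd": self.pct_gold_dd,
        }


def crosstab(
    cohort: pd.DataFrame,
    genotype_col: str = "called_genotype",
    phenotype_col: str = "phenotype",
) -> ConcordanceTable:
    """Cross-tabulate one genotype and one phenotype per individual.

    No-calls are excluded from the 3x2 table but their count is kept.
    Unknown genotype or phenotype labels are rejected.
    """
    genotypes = cohort[genotype_col]
    phenotypes = cohort[phenotype_col]
    bad_geno = set(genotypes) - set(GENOTYPE_LEVELS) - {NO_CALL}
    if bad_geno:
        raise ValueError(f"unknown genotype labels: {sorted(bad_geno)}")
    bad_pheno = set(phenotypes) - set(PHENOTYPE_LEVELS)
    if bad_pheno:
        raise ValueError(f"unknown phenotype labels: {sorted(bad_pheno)}")

    called = cohort[genotypes != NO_CALL]
    table = pd.crosstab(called[genotype_col], called[phenotype_col])
    table = table.reindex(index=GENOTYPE_LEVELS, columns=PHENOTYPE_LEVELS,
                          fill_value=0).astype(int)
    return ConcordanceTable(counts=table, n_no_call=int((genotypes == NO_CALL).sum()))


def _pct(count: int, total: int) -> float | None:
    if total == 0:
        return None
    return round(100.0 * count / total, 1)


def conflict_rates(table: ConcordanceTable) -> ConflictReport:
    """Dark carriers and gold phenocopies, as counts and percentages."""
    dark_total = int(table.counts["dark"].sum())
    gold_total = int(table.counts["gold"].sum())
    n_dark_with_G = int(table.counts.at["Gd", "dark"] + table.counts.at["GG", "dark"])
    n_gold_dd = int(table.counts.at["dd", "gold"])
    return ConflictReport(
        n_dark_with_G=n_dark_with_G,
        dark_total=dark_total,
        pct_dark_with_G=_pct(n_dark_with_G, dark_total),
        n_gold_dd=n_gold_dd,
        gold_total=gold_total,
        pct_gold_dd=_pct(n_gold_dd, gold_total),
    )


_COORD_RE = re.compile(r"^(?:(?P<chrom>[^:]+):)?(?P<pos>[\d,]+)$")


def parse_coordinate(coordinate) -> tuple[str | None, int]:
    """Parse "chrom:1,234,567", "1234567" or an int into (chrom, pos)."""
    if isinstance(coordinate, int):
        return None, coordinate
    match = _COORD_RE.match(str(coordinate).strip())
    if not match:
        raise ValueError(f"cannot parse coordinate {coordinate!r}")
    return match.group("chrom"), int(match.group("pos").replace(",", ""))


def peak_distance(coordinate_a, coordinate_b) -> float:
    """Signed distance from a to b in kb, rounded half-even to 1 decimal.

    Accepts 1-based integer positions or "chrom:pos" strings (commas
    allowed); if both carry a chromosome it must match.
    """
    chrom_a, pos_a = parse_coordinate(coordinate_a)
    chrom_b, pos_b = parse_coordinate(coordinate_b)
    if chrom_a is not None and chrom_b is not None and chrom_a != chrom_b:
        raise ValueError(
            f"coordinates on different chromosomes: {chrom_a} vs {chrom_b}"
        )
    return round((pos_b - pos_a) / 1000.0, 1)
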