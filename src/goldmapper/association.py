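"""Single-variant linear mixed model association with a kinship random effect.

The model for a phenotype vector y (binary morphs coded 0/1 and treated
as quantitative, the standard practice for case/control mixed-model
scans) is

    y = W a + x b + u + e,   u ~ N(0, s2 * lambda * K),   e ~ N(0, s2 * I)

where W holds covariates (an intercept by default), x is the tested
variant's dosage, K is the centered kinship matrix over samples, and
lambda is the ratio of genetic to residual variance.  Writing K = U D U'
and rotating by U' diagonalizes the covariance, so for any lambda the
maximum-likelihood fit reduces to weighted least squares with weights
1 / (lambda * d_i + 1); lambda itself is profiled out by a log-spaced
grid search followed by bounded scalar refinement.  Each variant is
tested with a likelihood-ratio statistic 2 (logL_alt - logL_null)
against the null model that omits the variant, with p-values from a
chi-square distribution with one degree of freedom.  Full maximum
likelihood (not REML) is used throughout so the nested models are
directly comparable.

Marker hygiene before scanning: variants with minor allele frequency
below 0.05 (computed on non-missing calls) or more than 20% missing
genotypes are dropped; no Hardy-Weinberg filter is applied.  Missing
dosages are mean-imputed per variant before both kinship estimation and
testing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
_TINY_VARIANCE = 1e-300
#: smallest positive double, reported when a p-value underflows
MIN_POSITIVE_P = 5e-324

_LAMBDA_GRID = 10.0 ** np.linspace(-5.0, 5.0, 41)


@dataclass
class GenotypeMatrix:
    """Dosage matrix (variants x samples, NaN = missing) with positions."""

    dosages: pd.DataFrame
    variants: pd.DataFrame  # index = variant id, columns chrom, pos

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.variants.index):
            raise ValueError("dosage rows and variant table must share an index")
        values = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(values, initial=0) < 0 or np.nanmax(values, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def samples(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    def allele_freq(self) -> pd.Series:
        return self.dosages.mean(axis=1, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        freq = self.allele_freq()
        return np.minimum(freq, 1.0 - freq)

    def missingness(self) -> pd.Series:
        return self.dosages.isna().mean(axis=1)

    def imputed(self) -> np.ndarray:
        """Dosages with per-variant mean imputation (variants x samples)."""
        values = self.dosages.to_numpy(dtype=float).copy()
        means = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=1)
        means = np.nan_to_num(means)
        rows, cols = np.nonzero(np.isnan(values))
        values[rows, cols] = means[rows]
        return values

    def to_tsv(self, path) -> None:
        out = self.variants.join(self.dosages)
        out.to_csv(path, sep="\t", index_label="variant", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="variant")
        variants = df[["chrom", "pos"]]
        dosages = df.drop(columns=["chrom", "pos"]).astype(float)
        return cls(dosages=dosages, variants=variants)

    def to_vcf(self, path, contig_lengths: dict[str, int] | None = None) -> None:
        write_genotype_vcf(self, path, contig_lengths=contig_lengths)

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        return read_genotype_vcf(path)


def write_genotype_vcf(matrix: GenotypeMatrix, path,
                       contig_lengths: dict[str, int] | None = None) -> None:
    """Write hard-call dosages as a GT-only VCF (NaN becomes ./.)."""
    import pysam

    header = pysam.VariantHeader()
    contigs = matrix.variants["chrom"].unique()
    for contig in contigs:
        length = None if contig_lengths is None else contig_lengths.get(contig)
        if length is None:
            length = int(matrix.variants.loc[matrix.variants["chrom"] == contig, "pos"].max()) + 1
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    header.add_samples(matrix.samples)
    gt_codes = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for variant_id, row in matrix.variants.iterrows():
            rec = vf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                stop=int(row["pos"]), alleles=("A", "G"), id=str(variant_id),
            )
            for sample in matrix.samples:
                value = matrix.dosages.at[variant_id, sample]
                rec.samples[sample]["GT"] = (None, None) if pd.isna(value) else gt_codes[float(value)]
            vf.write(rec)


def read_genotype_vcf(path) -> GenotypeMatrix:
    import pysam

    ids, chroms, positions, rows = [], [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            chroms.append(rec.chrom)
            positions.append(rec.pos)
            row = []
            for sample in samples:
                gt = rec.samples[sample]["GT"]
                if gt is None or any(allele is None for allele in gt):
                    row.append(np.nan)
                else:
                    row.append(float(sum(gt)))
            rows.append(row)
    dosages = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
    variants = pd.DataFrame({"chrom": chroms, "pos": positions}, index=ids)
    return GenotypeMatrix(dosages=dosages, variants=variants)


# ---------------------------------------------------------------------------
# Filters and kinship
# ---------------------------------------------------------------------------

def filter_variants(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.20,
) -> GenotypeMatrix:
    """Drop variants with MAF < ``maf_min`` or missingness > ``max_missing``."""
    keep = (matrix.maf() >= maf_min) & (matrix.missingness() <= max_missing)
    if not keep.any():
        logger.warning("all %d variants removed by MAF/missingness filters",
                       matrix.n_variants)
    return GenotypeMatrix(
        dosages=matrix.dosages.loc[keep],
        variants=matrix.variants.loc[keep],
    )


def compute_kinship(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Centered kinship: K = (1/p) * sum_k outer(x_k - mean_k) over p variants.

    Missing dosages are mean-imputed per variant (so they contribute
    zero after centering).  Returns a symmetric samples x samples frame.
    """
    if matrix.n_samples < 2:
        raise ValueError("kinship requires at least two samples")
    if matrix.n_variants < 1:
        raise ValueError("kinship requires at least one variant")
    X = matrix.imputed()
    Xc = X - X.mean(axis=1, keepdims=True)
    K = (Xc.T @ Xc) / matrix.n_variants
    K = (K + K.T) / 2.0
    return pd.DataFrame(K, index=matrix.samples, columns=matrix.samples)


def eigendecompose_kinship(K: np.ndarray, tolerance: float = 1e-8):
    """Eigendecomposition of K with tiny negative eigenvalues clamped."""
    K = np.asarray(K, dtype=float)
    d, U = np.linalg.eigh(K)
    if d.min() < -tolerance * max(1.0, abs(d.max())):
        raise ValueError("kinship matrix has substantially negative eigenvalues")
    return np.maximum(d, 0.0), U


# ---------------------------------------------------------------------------
# Mixed-model likelihood machinery
# ---------------------------------------------------------------------------

def _ml_loglik(lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profile ML log-likelihood at variance ratio ``lam`` (rotated data)."""
    n = yt.shape[0]
    v = lam * d + 1.0
    w = 1.0 / v
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    b = Xw.T @ yt
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return -np.inf, np.full(Xt.shape[1], np.nan)
    rss = float(yt @ (w * yt) - b @ beta)
    s2 = max(rss / n, _TINY_VARIANCE)
    ll = -0.5 * (n * (_LOG2PI + 1.0) + n * math.log(s2) + np.log(v).sum())
    return ll, beta


def _optimize_lambda(d: np.ndarray, yt: np.ndarray, Xt: np.ndarray,
                     tol: float = 1e-8):
    """Grid search over lambda then bounded refinement on log10(lambda)."""
    lls = np.array([_ml_loglik(lam, d, yt, Xt)[0] for lam in _LAMBDA_GRID])
    best = int(np.argmax(lls))
    lo = math.log10(_LAMBDA_GRID[max(best - 1, 0)])
    hi = math.log10(_LAMBDA_GRID[min(best + 1, len(_LAMBDA_GRID) - 1)])

    def negated(log_lam: float) -> float:
        return -_ml_loglik(10.0 ** log_lam, d, yt, Xt)[0]

    res = optimize.minimize_scalar(negated, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    lam = 10.0 ** float(res.x)
    ll, beta = _ml_loglik(lam, d, yt, Xt)
    if lls[best] > ll:  # grid point beat the refinement (flat likelihood edge)
        lam = float(_LAMBDA_GRID[best])
        ll, beta = _ml_loglik(lam, d, yt, Xt)
    return lam, ll, beta


@dataclass
class AssociationResult:
    """Per-variant mixed-model test result."""

    variant: str
    beta: float
    lam: float
    lrt: float
    p_value: float
    minus_log10_p: float
    underflow: bool = False
    untestable: bool = False


def _finalize_p(lrt: float) -> tuple[float, float, bool]:
    p = float(stats.chi2.sf(lrt, df=1))
    if p <= 0.0:
        return MIN_POSITIVE_P, -math.log10(MIN_POSITIVE_P), True
    return p, -math.log10(p), False


def lmm_lrt(
    phenotype,
    dosage,
    kinship=None,
    covariates=None,
    *,
    eigen=None,
    variant_id: str = "variant",
) -> AssociationResult:
    """Likelihood-ratio mixed-model test of one variant.

    ``kinship`` may be omitted when ``eigen`` (a precomputed
    ``(d, U)`` pair from :func:`eigendecompose_kinship`) is given.
    Missing dosages must already be imputed.  A constant dosage vector
    is flagged untestable.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(dosage, dtype=float)
    if y.shape != x.shape:
        raise ValueError("phenotype and dosage must have the same length")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise ValueError("phenotype and dosage must be finite (impute first)")
    n = y.shape[0]
    if eigen is None:
        if kinship is None:
            raise ValueError("provide a kinship matrix or its eigendecomposition")
        eigen = eigendecompose_kinship(np.asarray(kinship, dtype=float))
    d, U = eigen

    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    if np.ptp(x) == 0.0:
        return AssociationResult(variant_id, math.nan, math.nan, math.nan,
                                 math.nan, math.nan, untestable=True)

    yt = U.T @ y
    Wt = U.T @ W
    xt = U.T @ x

    _, ll_null, _ = _optimize_lambda(d, yt, Wt)
    Xt = np.column_stack([Wt, xt])
    lam, ll_alt, beta = _optimize_lambda(d, yt, Xt)
    if not np.isfinite(ll_alt) or (not np.isfinite(ll_null) and not np.isfinite(ll_alt)):
        raise FloatingPointError(
            f"non-finite likelihood for {variant_id}: null={ll_null} alt={ll_alt}"
        )
    lrt = max(2.0 * (ll_alt - ll_null), 0.0)
    p, mlog10p, underflow = _finalize_p(lrt)
    return AssociationResult(variant_id, float(beta[-1]), lam, lrt, p, mlog10p,
                             underflow=underflow)


def _grid_scan_2col(d, yt, ct, X):
    """Vectorized lambda-grid profile likelihood for intercept + one
    variant, across all variants at once.

    ``ct`` is the rotated intercept column, ``X`` the rotated dosage
    matrix (n x V).  Returns per-variant best grid log-likelihood and
    its grid index.
    """
    n, n_var = X.shape
    best_ll = np.full(n_var, -np.inf)
    best_idx = np.zeros(n_var, dtype=int)
    y2 = yt * yt
    for gi, lam in enumerate(_LAMBDA_GRID):
        v = lam * d + 1.0
        w = 1.0 / v
        logdet = np.log(v).sum()
        a = float(np.sum(w * ct * ct))
        dy = float(np.sum(w * ct * yt))
        f = float(np.sum(w * y2))
        wX = X * w[:, None]
        b = ct @ wX                 # sum w c x per variant
        cc = np.einsum("ij,ij->j", X, wX)
        e = yt @ wX
        det = a * cc - b * b
        with np.errstate(divide="ignore", invalid="ignore"):
            beta0 = (cc * dy - b * e) / det
            beta1 = (a * e - b * dy) / det
            rss = f - dy * beta0 - e * beta1
        rss = np.where((det <= 0) | ~np.isfinite(rss), np.nan, np.maximum(rss, _TINY_VARIANCE * n))
        with np.errstate(invalid="ignore"):
            ll = -0.5 * (n * (_LOG2PI + 1.0) + n * np.log(rss / n) + logdet)
        improved = np.nan_to_num(ll, nan=-np.inf) > best_ll
        best_ll[improved] = ll[improved]
        best_idx[improved] = gi
    return best_ll, best_idx


def gwas_scan(
    matrix: GenotypeMatrix,
    phenotype: pd.Series,
    kinship: pd.DataFrame | None = None,
    *,
    maf_min: float = 0.05,
    max_missing: float = 0.20,
    no_kinship: bool = False,
    refine: bool = True,
) -> pd.DataFrame:
    """Scan every retained variant against the phenotype.

    Applies the MAF/missingness filters, computes the centered kinship
    from the retained markers unless one is supplied (or ``no_kinship``
    substitutes the identity), and runs the LRT per variant.  Returns a
    position-ordered table with chrom, pos, beta, lambda, lrt, p_value
    and minus_log10_p.
    """
    filtered = filter_variants(matrix, maf_min=maf_min, max_missing=max_missing)
    if filtered.n_variants == 0:
        return pd.DataFrame(columns=["variant", "chrom", "pos", "beta", "lam",
                                     "lrt", "p_value", "minus_log10_p"])
    samples = filtered.samples
    y = phenotype.loc[samples].to_numpy(dtype=float)
    n = len(samples)

    if no_kinship:
        K = np.eye(n)
    elif kinship is None:
        K = compute_kinship(filtered).to_numpy()
    else:
        K = kinship.loc[samples, samples].to_numpy(dtype=float)
    d, U = eigendecompose_kinship(K)

    X = filtered.imputed()                     # variants x samples
    yt = U.T @ y
    ct = U.T @ np.ones(n)
    Xt = U.T @ X.T                             # n x V, rotated dosages

    _, ll_null, _ = _optimize_lambda(d, yt, ct[:, None])

    grid_ll, grid_idx = _grid_scan_2col(d, yt, ct, Xt)

    rows = []
    for vi, variant_id in enumerate(filtered.dosages.index):
        xt = Xt[:, vi]
        if np.ptp(X[vi]) == 0.0:
            rows.append((variant_id, math.nan, math.nan, math.nan,
                         math.nan, math.nan, False, True))
            continue
        design = np.column_stack([ct, xt])
        if refine:
            gi = grid_idx[vi]
            lo = math.log10(_LAMBDA_GRID[max(gi - 1, 0)])
            hi = math.log10(_LAMBDA_GRID[min(gi + 1, len(_LAMBDA_GRID) - 1)])
            res = optimize.minimize_scalar(
                lambda ll_: -_ml_loglik(10.0 ** ll_, d, yt, design)[0],
                bounds=(lo, hi), method="bounded", options={"xatol": 1e-8},
            )
            lam = 10.0 ** float(res.x)
            ll_alt, beta = _ml_loglik(lam, d, yt, design)
            if grid_ll[vi] > ll_alt:
                lam = float(_LAMBDA_GRID[grid_idx[vi]])
                ll_alt, beta = _ml_loglik(lam, d, yt, design)
        else:
            lam = float(_LAMBDA_GRID[grid_idx[vi]])
            ll_alt, beta = _ml_loglik(lam, d, yt, design)
        lrt = max(2.0 * (ll_alt - ll_null), 0.0)
        p, mlog10p, underflow = _finalize_p(lrt)
        rows.append((variant_id, float(beta[-1]), lam, lrt, p, mlog10p,
                     underflow, False))

    results = pd.DataFrame(
        rows,
        columns=["variant", "beta", "lam", "lrt", "p_value", "minus_log10_p",
                 "underflow", "untestable"],
    ).set_index("variant")
    results = filtered.variants.join(results)
    results = results.sort_values(["chrom", "pos"], kind="mergesort")
    return results.reset_index(names="variant")


def write_scan_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
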