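"""GRAMMAR two-step association: polygenic adjustment, then per-SNP regression.

Step one fits a single polygenic model (genomic or pedigree relationship
matrix) by REML and removes the fixed part and the polygenic BLUP from
the phenotype.  Step two regresses the residuals on each SNP's allele
count by ordinary least squares, with a two-sided t test on n-2 degrees
of freedom.  The residual structure makes the test slightly conservative
(the classic GRAMMAR deflation); an optional genomic-control rescaling is
provided but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, t as t_dist

from .io_formats import GenotypeMatrix, MarkerMap
from .kinship import RelationshipMatrix
from .varcomp import VarCompModel, fit_reml

logger = logging.getLogger(__name__)

__all__ = ["AssocResult", "grammar_adjust", "grammar_assoc"]


@dataclass
class AssocResult:
    """Per-SNP effect, SE, t statistic and p-value; monomorphic SNPs flagged."""

    table: pd.DataFrame   # snp_id, beta, se, stat, p, minus_log10_p, estimable

    def write_tsv(self, path, mmap: MarkerMap | None = None) -> None:
        out = self.table
        if mmap is not None:
            ann = pd.DataFrame({"snp_id": mmap.snp_id,
                                "chromosome": mmap.chromosome,
                                "bp": mmap.position_bp})
            out = ann.merge(out, on="snp_id", how="right")
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def grammar_adjust(y, G: RelationshipMatrix | np.ndarray, tol: float = 1e-6,
                   max_iter: int = 200) -> np.ndarray:
    """Residuals after removing the intercept and the polygenic BLUP.

    residuals = y - X b_hat - g_hat at the REML estimates of the single
    polygenic model.  Since the fitted parts satisfy y - X b_hat =
    g_hat + e_hat with e_hat = sigma2_e * P y, the adjusted phenotype is
    exactly the residual BLUP; when the polygenic variance is estimated at
    zero this reduces to mean-centred y.
    """
    y = np.asarray(y, dtype=float).ravel()
    fit = fit_reml(VarCompModel(y, [("polygenic", G)]), tol=tol, max_iter=max_iter)
    return fit.sigma2_e * fit._Py


def grammar_assoc(residuals, genotypes: GenotypeMatrix,
                  genomic_control: bool = False) -> AssocResult:
    """OLS of residuals on each SNP's allele count (additive model).

    Missing genotypes are mean-imputed per SNP.  Monomorphic SNPs are
    returned flagged not-estimable with no p-value.  With
    ``genomic_control`` the chi-square statistics are deflated by their
    observed median over the expected median.
    """
    e = np.asarray(residuals, dtype=float).ravel()
    n = e.size
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if not np.all(np.isfinite(e)):
        raise ValueError("residuals must be finite")
    M = genotypes.codes.astype(float, copy=True)
    if M.shape[0] != n:
        raise ValueError("residuals do not match genotype rows")
    colmean = np.nanmean(M, axis=0)
    nan_mask = np.isnan(M)
    if nan_mask.any():
        M[nan_mask] = np.take(colmean, np.nonzero(nan_mask)[1])
    Xc = M - M.mean(axis=0)
    sxx = np.sum(Xc * Xc, axis=0)
    estimable = sxx > 0
    ec = e - e.mean()
    sxy = Xc.T @ ec
    syy = float(ec @ ec)
    beta = np.full(M.shape[1], np.nan)
    se = np.full(M.shape[1], np.nan)
    stat = np.full(M.shape[1], np.nan)
    p = np.full(M.shape[1], np.nan)
    ok = estimable
    beta[ok] = sxy[ok] / sxx[ok]
    rss = syy - beta[ok] ** 2 * sxx[ok]
    rss = np.clip(rss, 0.0, None)
    df = n - 2
    se[ok] = np.sqrt(rss / df / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        stat[ok] = np.where(se[ok] > 0, beta[ok] / se[ok], 0.0)
    p[ok] = 2.0 * t_dist.sf(np.abs(stat[ok]), df)
    p[ok] = np.minimum(p[ok], 1.0)
    if genomic_control:
        x2 = stat[ok] ** 2
        lam = np.median(x2) / chi2.ppf(0.5, 1)
        if lam > 1:
            logger.info("genomic control: lambda = %.3f", lam)
            x2 = x2 / lam
            p[ok] = chi2.sf(x2, 1)
            stat[ok] = np.sign(stat[ok]) * np.sqrt(x2)
    with np.errstate(divide="ignore"):
        mlp = -np.log10(p)
    table = pd.DataFrame({"snp_id": genotypes.snp_ids, "beta": beta, "se": se,
                          "stat": stat, "p": p, "minus_log10_p": mlp,
                          "estimable": estimable})
    return AssocResult(table)
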