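"""Characterization of significant regions.

Two analyses follow the scan: (i) pleiotropy screening, correlating the
regional estimated breeding values (BLUPs of the window component) of a
shared region between two traits; and (ii) a joint variance partition in
which every called QTL region enters one model simultaneously with the
whole-genome background, so the summed regional heritabilities and the
proportion of genetic variance they explain are estimated free of
double-counting between overlapping single-region fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix, MarkerMap
from .kinship import RelationshipMatrix, compute_grm
from .scan import Window
from .varcomp import VarCompFit, VarCompModel, blup_effects, fit_reml

logger = logging.getLogger(__name__)

__all__ = ["PleiotropyRecord", "JointPartition",
           "regional_ebv_correlation", "joint_fit", "variance_explained"]


@dataclass
class PleiotropyRecord:
    region: Window
    trait_pair: tuple
    correlation: float
    estimable: bool = True


@dataclass
class JointPartition:
    """All called regions fitted at once alongside the genomic background."""

    regions: list
    h2_reg: np.ndarray          # per region, under the joint model
    h2_background: float
    sum_h2_reg: float
    proportion_explained: float  # of total genetic variance, in [0,1]
    loglik: float
    converged: bool


def regional_ebv_correlation(fit_a: VarCompFit, fit_b: VarCompFit,
                             region: Window, component: str = "region",
                             trait_pair=("a", "b")) -> PleiotropyRecord:
    """Pearson correlation between two traits' regional EBVs for one region.

    Both fits must carry the same regional component (same GRM, same
    individuals).  If either regional variance sits at the boundary the
    EBVs are identically zero and the record is flagged not estimable.
    """
    for fit in (fit_a, fit_b):
        if component not in fit.component_names:
            raise KeyError(f"fit lacks component {component!r}")
    floor_a = 1e-7 * fit_a.total_variance
    floor_b = 1e-7 * fit_b.total_variance
    if fit_a.sigma2_of(component) <= floor_a or fit_b.sigma2_of(component) <= floor_b:
        return PleiotropyRecord(region, tuple(trait_pair), np.nan, estimable=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        u_a = blup_effects(fit_a, component).values
        u_b = blup_effects(fit_b, component).values
    if u_a.size != u_b.size:
        raise ValueError("fits cover different individual sets")
    r = float(np.corrcoef(u_a, u_b)[0, 1])
    return PleiotropyRecord(region, tuple(trait_pair), r, estimable=True)


def joint_fit(genotypes: GenotypeMatrix, mmap: MarkerMap, y,
              regions: list[Window],
              background: RelationshipMatrix | None = None,
              tol: float = 1e-6, max_iter: int = 200) -> JointPartition:
    """One REML fit with K regional components plus background plus residual.

    ``regions`` would normally be the peak windows of the QTL calls (one
    component per call, avoiding collinear overlapping windows).
    """
    if not regions:
        raise ValueError("need at least one region")
    spans = {(r.chromosome, r.snp_start, r.snp_end) for r in regions}
    if len(spans) != len(regions):
        raise ValueError("regions must be pairwise distinct")
    y = np.asarray(y, dtype=float).ravel()
    if background is None:
        background = compute_grm(genotypes)
    comps = []
    for k, win in enumerate(regions):
        Q = compute_grm(genotypes, snp_subset=np.array(win.columns))
        comps.append((f"region_{k + 1}", Q.values))
    comps.append(("background", background.values))
    fit = fit_reml(VarCompModel(y, comps, ids=genotypes.individual_ids),
                   tol=tol, max_iter=max_iter)
    if not fit.converged:
        logger.warning("joint fit did not converge; partition is partial")
    h2_reg = np.array([fit.h2[f"region_{k + 1}"] for k in range(len(regions))])
    h2_bg = fit.h2["background"]
    total, prop = variance_explained(h2_reg, h2_bg, as_percent=False)
    return JointPartition(list(regions), h2_reg, float(h2_bg), float(total),
                          float(prop), fit.loglik, fit.converged)


def variance_explained(regional_h2, remaining_h2: float, as_percent: bool = True):
    """Sum of regional heritabilities and their share of total genetic variance.

    proportion = sum(h2_reg) / (sum(h2_reg) + remaining background h2).
    With ``as_percent`` the proportion is returned as a percentage rounded
    to the nearest integer (the reporting convention); otherwise as a
    fraction.  Scale-free: rescaling all inputs leaves it unchanged.
    """
    h2 = np.asarray(regional_h2, dtype=float).ravel()
    if np.any(h2 < 0) or remaining_h2 < 0:
        raise ValueError("heritabilities must be non-negative")
    total = float(h2.sum())
    if total == 0 and remaining_h2 == 0:
        raise ValueError("all inputs zero: proportion undefined")
    prop = total / (total + remaining_h2)
    if as_percent:
        return total, int(round(100.0 * prop))
    return total, prop
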