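"""Single-marker genome scan for parent-of-origin effects.

The workflow: filter markers on minor allele frequency, estimate the
effective number of independent tests from inter-marker LD, set a
Šidák-corrected per-test threshold, then for every marker fit the nested
ladder of models

    null:      no marker term
    additive:  + I_a b1
    dominance: + I_a b1 + I_d b2
    full:      + I_a b1 + I_d b2 + I_i b3
    (optional) + I_a b1 + I_i b3          # dominance omitted

and test each added term by a likelihood-ratio test against its
predecessor.  Markers significant for imprinting form "box 1", markers
significant for additivity only form "box 2"; highly correlated
significant markers (r^2 above a pruning threshold) are collapsed to one
representative per LD cluster, and the retained markers feed the marked
(SNP-attributed) variance and heritability report:

    sigma2_SNP (no imprinting)   = sum_box2 2 p q alpha^2
    sigma2_SNP (with imprinting) = above + sum_box1 2 p q (alpha^2 + i^2)
    h2 = (sigma2_SNP + sigma2_u) / (sigma2_SNP + sigma2_u + sigma2_c + sigma2_e)

For a box-1 marker the direction of imprinting follows from the signs of
the estimated substitution and imprinting effects: the parental
substitution effects are ``alpha -/+ i`` (maternal/paternal), and the
silenced side is the one with the smaller absolute substitution effect, so
equal signs of ``alpha`` and ``i`` suggest maternal, opposite signs
paternal imprinting (the call flips if the heterozygote coding convention
is flipped).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import mixed_model as mm
from .data import Dataset

__all__ = [
    "ScanConfig",
    "VarianceReport",
    "maf_filter",
    "haplotype_correlation",
    "effective_tests",
    "sidak_threshold",
    "scan",
    "prune_clusters",
    "assign_box",
    "classify_direction",
    "marked_variance",
    "heritability_report",
    "percent_decrease",
    "reestimate_marked_variance",
    "build_report",
]

logger = logging.getLogger(__name__)

BOX_IMPRINTED = "box1_imprinted"
BOX_ADDITIVE = "box2_additive"


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds and model options of one scan run."""

    maf_threshold: float = 0.05
    alpha: float = 0.05
    r2_threshold: float = 0.99
    use_model9: bool = False      # test imprinting without the dominance term
    paper_mode: bool = False      # difference REML instead of ML criteria
    meff_method: str = "liji"     # or "bonferroni"
    collect_records: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in (0, 1]")
        if self.meff_method not in ("liji", "bonferroni"):
            raise ValueError("meff_method must be 'liji' or 'bonferroni'")


@dataclass
class VarianceReport:
    """Marked variance, averaged variance components and heritabilities."""

    snp_box2: float = 0.0            # Mendelian part (additive markers)
    snp_box1: float = 0.0            # imprinted markers, alpha^2 + i^2 part
    snp_box1_mendelian: float = 0.0  # alpha^2 share of box 1
    snp_box1_imprinting: float = 0.0  # i^2 share of box 1
    varcomps_imp: dict = field(default_factory=dict)
    varcomps_add: dict = field(default_factory=dict)
    h2_with: float = np.nan
    h2_without: float = np.nan

    @property
    def snp_without(self) -> float:
        return self.snp_box2

    @property
    def snp_with(self) -> float:
        return self.snp_box2 + self.snp_box1


# ----------------------------------------------------------------------
# marker filtering, LD, multiple testing
# ----------------------------------------------------------------------

def maf_filter(data: Dataset, threshold: float = 0.05) -> np.ndarray:
    """Indices of markers with minor allele frequency >= threshold.

    The rule is "remove MAF strictly less than the threshold", so a marker
    exactly at the threshold is retained.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    p = np.asarray(data.allele_frequency())
    maf = np.minimum(p, 1.0 - p)
    keep = np.flatnonzero(maf >= threshold)
    logger.info("MAF filter (< %.3g): %d of %d markers kept",
                threshold, keep.size, data.n_markers)
    return keep


def haplotype_correlation(data: Dataset, marker_idx=None) -> np.ndarray:
    """Pairwise haplotypic Pearson correlation between markers.

    Computed over the 2n stacked parental haplotypes; markers that are
    monomorphic in the sample get zero correlation with everything.
    """
    hap = data.haplotype_matrix(marker_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(hap, rowvar=False)
    r = np.atleast_2d(r)
    bad = ~np.isfinite(r)
    r[bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def effective_tests(corr_matrices) -> float:
    """Eigenvalue-based effective number of independent tests (Li-Ji).

    For each correlation block with eigenvalues ``lam`` the contribution is
    ``sum(1[lam >= 1] + (lam - floor(lam)))``; blocks (one per chromosome)
    are summed.  Uncorrelated markers give the block size, a perfectly
    correlated block gives 1.
    """
    total = 0.0
    for R in corr_matrices:
        R = np.atleast_2d(np.asarray(R, dtype=float))
        if R.shape[0] != R.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(np.diag(R), 1.0, atol=1e-6):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(R) > 1.0 + 1e-8):
            raise ValueError("correlation entries must lie in [-1, 1]")
        lam = np.linalg.eigvalsh((R + R.T) / 2.0)
        if lam.min() < -1e-6:
            raise ValueError(
                f"correlation matrix not PSD (min eigenvalue {lam.min():.3g})"
            )
        lam = np.clip(lam, 0.0, None)
        total += float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))
    return total


def sidak_threshold(genomewide_alpha: float, m_eff: float) -> float:
    """Per-test p-value threshold 1 - (1 - alpha)^(1/M_eff)."""
    if not 0.0 < genomewide_alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    return 1.0 - (1.0 - genomewide_alpha) ** (1.0 / m_eff)


# ----------------------------------------------------------------------
# the scan itself
# ----------------------------------------------------------------------

def _dataset_meff(data: Dataset, marker_idx, method: str) -> float:
    if method == "bonferroni":
        return float(len(marker_idx))
    chroms = data.markers["chrom"].to_numpy()[marker_idx]
    blocks = []
    for ch in pd.unique(chroms):
        sel = np.asarray(marker_idx)[chroms == ch]
        blocks.append(haplotype_correlation(data, sel))
    return effective_tests(blocks)


def scan(data: Dataset, config: ScanConfig = ScanConfig(),
         marker_idx=None) -> tuple[pd.DataFrame, dict]:
    """Run the per-marker LRT cascade over the (MAF-filtered) markers.

    Returns a result table (one row per scanned marker) and an info dict
    with the effective test count, the Šidák threshold, per-model averaged
    variance components and stage counts.  Markers whose dominance or
    imprinting codes are inestimable are carried through with flags but
    never enter a significance box.
    """
    if marker_idx is None:
        marker_idx = maf_filter(data, config.maf_threshold)
    marker_idx = np.asarray(marker_idx)
    if marker_idx.size == 0:
        raise ValueError("no markers to scan (all removed by the MAF filter?)")

    m_eff = _dataset_meff(data, marker_idx, config.meff_method)
    threshold = sidak_threshold(config.alpha, m_eff)

    base = mm.ModelSpec.for_data(data)
    null_fit = mm.fit(data, spec=base)
    # warm-start the per-marker variance searches at the null-model ratios
    s2e0 = null_fit.varcomps["sigma2_e"]
    start = [null_fit.varcomps[k] / s2e0
             for k in ("sigma2_u", "sigma2_c") if k in null_fit.varcomps]
    start = np.asarray(start) if len(start) == 2 else None

    imp_terms = ((mm.ADDITIVE, mm.IMPRINTING) if config.use_model9
                 else (mm.ADDITIVE, mm.DOMINANCE, mm.IMPRINTING))

    rows = []
    records = []
    vc_imp_acc: list[dict] = []
    vc_add_acc: list[dict] = []
    for j in marker_idx:
        kw = {"start_gammas": start, "compute_varcomp_sd": False}
        f_add = mm.fit(data, j, base.with_terms(mm.ADDITIVE), **kw)
        f_dom = mm.fit(data, j, base.with_terms(mm.ADDITIVE, mm.DOMINANCE), **kw)
        f_full = mm.fit(data, j, base.with_terms(*imp_terms), **kw)
        if config.use_model9:
            lrt_imp = mm.lrt(f_full, f_add, paper_mode=config.paper_mode)
        else:
            lrt_imp = mm.lrt(f_full, f_dom, paper_mode=config.paper_mode)
        lrt_add = mm.lrt(f_add, null_fit, paper_mode=config.paper_mode)
        lrt_dom = mm.lrt(f_dom, f_add, paper_mode=config.paper_mode)

        est = f_full.beta
        ses = f_full.se
        inest = set(f_add.inestimable) | set(f_dom.inestimable) | set(
            f_full.inestimable)
        p_add = lrt_add.pvalue if mm.ADDITIVE not in inest else np.nan
        p_dom = lrt_dom.pvalue if mm.DOMINANCE not in inest else np.nan
        p_imp = lrt_imp.pvalue if mm.IMPRINTING not in inest else np.nan
        sig_add = bool(p_add < threshold) if np.isfinite(p_add) else False
        sig_dom = bool(p_dom < threshold) if np.isfinite(p_dom) else False
        sig_imp = bool(p_imp < threshold) if np.isfinite(p_imp) else False
        box = assign_box(sig_add, sig_dom, sig_imp)
        rows.append(
            {
                "marker": data.markers["marker"].iloc[j],
                "chrom": data.markers["chrom"].iloc[j],
                "pos": data.markers["pos"].iloc[j],
                "index": int(j),
                "p_hat": data.allele_frequency(int(j)),
                "alpha_hat": est.get(mm.ADDITIVE, np.nan),
                "alpha_se": ses.get(mm.ADDITIVE, np.nan),
                "d_hat": f_dom.beta.get(mm.DOMINANCE, np.nan),
                "d_se": f_dom.se.get(mm.DOMINANCE, np.nan),
                "d_hat_full": est.get(mm.DOMINANCE, np.nan),
                "i_hat": est.get(mm.IMPRINTING, np.nan),
                "i_se": ses.get(mm.IMPRINTING, np.nan),
                "p_additive": p_add,
                "p_dominance": p_dom,
                "p_imprinting": p_imp,
                "sig_additive": sig_add,
                "sig_dominance": sig_dom,
                "sig_imprinting": sig_imp,
                "inestimable": ",".join(sorted(inest)),
                "box": box,
                "converged": f_full.converged and f_add.converged,
            }
        )
        vc_imp_acc.append(f_full.varcomps)
        vc_add_acc.append(f_add.varcomps)
        if config.collect_records:
            records.extend(r.to_record() for r in (f_add, f_dom, f_full))

    results = pd.DataFrame(rows)
    results["direction"] = [
        classify_direction(r.alpha_hat, r.i_hat) if r.box == BOX_IMPRINTED
        else "n/a"
        for r in results.itertuples()
    ]
    info = {
        "n_markers_scanned": int(marker_idx.size),
        "m_eff": m_eff,
        "threshold": threshold,
        "alpha": config.alpha,
        "n_box1": int((results["box"] == BOX_IMPRINTED).sum()),
        "n_box2": int((results["box"] == BOX_ADDITIVE).sum()),
        "varcomps_imp": _mean_varcomps(vc_imp_acc),
        "varcomps_add": _mean_varcomps(vc_add_acc),
        "null_loglik_reml": null_fit.loglik_reml,
    }
    if config.collect_records:
        info["records"] = records
    return results, info


def _mean_varcomps(acc: list[dict]) -> dict:
    keys = sorted({k for d in acc for k in d})
    return {k: float(np.mean([d[k] for d in acc if k in d])) for k in keys}


def assign_box(sig_additive: bool, sig_dominance: bool, sig_imprinting: bool) -> str:
    """Partition rule of the workflow's significance boxes.

    Box 1 holds every imprinting-significant marker; box 2 holds markers
    that are additively significant but not in box 1.  Markers significant
    only for dominance are reported but enter no box (marked variance is
    computed from boxes 1 and 2 only), so the boxes partition the
    significant-for-additivity-or-imprinting markers.
    """
    if sig_imprinting:
        return BOX_IMPRINTED
    if sig_additive:
        return BOX_ADDITIVE
    return "none"


def classify_direction(alpha_hat: float, i_hat: float) -> str:
    """Call the imprinting direction from the signs of alpha-hat and i-hat.

    Same sign -> maternal imprinting (the maternal substitution effect
    ``alpha - i`` is attenuated); opposite signs -> paternal.  A zero or
    missing estimate yields "n/a" with a warning.
    """
    if (not np.isfinite(alpha_hat) or not np.isfinite(i_hat)
            or alpha_hat == 0.0 or i_hat == 0.0):
        warnings.warn("imprinting direction undefined for a zero/missing estimate",
                      stacklevel=2)
        return "n/a"
    return "maternal" if np.sign(alpha_hat) == np.sign(i_hat) else "paternal"


# ----------------------------------------------------------------------
# LD pruning of significant markers
# ----------------------------------------------------------------------

def prune_clusters(results: pd.DataFrame, data: Dataset,
                   r2_threshold: float = 0.99) -> pd.DataFrame:
    """Collapse LD clusters of co-significant markers to one representative.

    Within each significance box, markers are grouped into connected
    components of the graph with an edge whenever pairwise haplotypic
    ``r^2`` exceeds the threshold (transitive chaining allowed).  The
    representative is the marker with the smallest relevant p-value
    (imprinting p for box 1, additive p for box 2), ties broken by genomic
    position.  Adds ``cluster`` and ``retained`` columns.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0, 1]")
    out = results.copy()
    out["cluster"] = ""
    out["retained"] = False
    for box, pcol in ((BOX_IMPRINTED, "p_imprinting"), (BOX_ADDITIVE, "p_additive")):
        sel = out.index[out["box"] == box]
        if len(sel) == 0:
            continue
        idx = out.loc[sel, "index"].to_numpy()
        r2 = haplotype_correlation(data, idx) ** 2
        adj = csr_matrix(r2 > r2_threshold)
        n_comp, labels = connected_components(adj, directed=False)
        for comp in range(n_comp):
            members = sel[labels == comp]
            sub = out.loc[members]
            best = sub.sort_values([pcol, "pos"], kind="stable").index[0]
            out.loc[members, "cluster"] = f"{box}_c{comp}"
            out.loc[best, "retained"] = True
    logger.info("LD pruning (r2 > %.3g): %d of %d significant markers retained",
                r2_threshold, int(out["retained"].sum()),
                int((out["box"] != "none").sum()))
    return out


# ----------------------------------------------------------------------
# marked variance and heritability
# ----------------------------------------------------------------------

def _locus_variance(p, alpha, i=None):
    v = 2.0 * p * (1.0 - p) * alpha**2
    if i is not None and np.isfinite(i):
        v += 2.0 * p * (1.0 - p) * i**2
    return v


def marked_variance(results: pd.DataFrame) -> VarianceReport:
    """Marked (SNP-attributed) variance from retained significant markers.

    Assumes linkage equilibrium between the retained markers, so per-locus
    contributions add: ``2 p q alpha^2`` for box-2 markers and
    ``2 p q (alpha^2 + i^2)`` for box-1 markers.
    """
    if "retained" not in results.columns:
        raise ValueError("results not pruned yet: run prune_clusters first")
    kept = results[results["retained"]]
    rep = VarianceReport()
    box2 = kept[kept["box"] == BOX_ADDITIVE]
    box1 = kept[kept["box"] == BOX_IMPRINTED]
    if len(box2) == 0 and len(box1) == 0:
        warnings.warn("no retained significant markers; marked variance is zero",
                      stacklevel=2)
    rep.snp_box2 = float(sum(
        _locus_variance(r.p_hat, r.alpha_hat) for r in box2.itertuples()
    ))
    rep.snp_box1_mendelian = float(sum(
        _locus_variance(r.p_hat, r.alpha_hat) for r in box1.itertuples()
    ))
    rep.snp_box1_imprinting = float(sum(
        _locus_variance(r.p_hat, r.i_hat) for r in box1.itertuples()
    ))
    rep.snp_box1 = rep.snp_box1_mendelian + rep.snp_box1_imprinting
    return rep


def heritability_report(sigma2_snp: float, sigma2_u: float,
                        sigma2_c: float, sigma2_e: float) -> float:
    """Combined bottom-up + top-down heritability.

    ``(sigma2_SNP + sigma2_u) / (sigma2_SNP + sigma2_u + sigma2_c +
    sigma2_e)``: marked variance plus the pedigree (infinitesimal) additive
    variance over the total phenotypic variance.
    """
    for name, v in (("sigma2_snp", sigma2_snp), ("sigma2_u", sigma2_u),
                    ("sigma2_c", sigma2_c), ("sigma2_e", sigma2_e)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    denom = sigma2_snp + sigma2_u + sigma2_c + sigma2_e
    if denom <= 0:
        raise ZeroDivisionError("total variance is zero; heritability undefined")
    return (sigma2_snp + sigma2_u) / denom


def percent_decrease(v_correct: float, v_wrong: float) -> float:
    """Percent decrease from the correct-model to the wrong-model variance."""
    if v_correct <= 0:
        raise ValueError("correct-model variance must be positive")
    return 100.0 * (v_correct - v_wrong) / v_correct


def reestimate_marked_variance(data: Dataset, results: pd.DataFrame,
                               box: str, terms: tuple[str, ...]) -> float:
    """Re-estimate the marked variance of one box's retained markers under
    a different (possibly deliberately wrong) marker model.

    Fitting imprinted markers with an additive-only model drops their
    ``2 p q i^2`` share and typically collapses the estimate; fitting
    additive markers with the imprinting model changes it only marginally.
    """
    base = mm.ModelSpec.for_data(data)
    kept = results[(results["retained"]) & (results["box"] == box)]
    total = 0.0
    with_imp = mm.IMPRINTING in terms
    for r in kept.itertuples():
        f = mm.fit(data, int(r.index), base.with_terms(*terms))
        alpha = f.beta.get(mm.ADDITIVE, np.nan)
        i_hat = f.beta.get(mm.IMPRINTING, np.nan) if with_imp else None
        total += _locus_variance(r.p_hat, alpha, i_hat)
    return float(total)


def build_report(results: pd.DataFrame, info: dict) -> dict:
    """Assemble the scan-level variance/heritability report dict."""
    rep = marked_variance(results)
    rep.varcomps_imp = info.get("varcomps_imp", {})
    rep.varcomps_add = info.get("varcomps_add", {})
    vi, va = rep.varcomps_imp, rep.varcomps_add
    rep.h2_with = heritability_report(
        rep.snp_with, vi.get("sigma2_u", 0.0), vi.get("sigma2_c", 0.0),
        vi["sigma2_e"],
    ) if vi else np.nan
    rep.h2_without = heritability_report(
        rep.snp_without, va.get("sigma2_u", 0.0), va.get("sigma2_c", 0.0),
        va["sigma2_e"],
    ) if va else np.nan
    return {
        "m_eff": info["m_eff"],
        "threshold": info["threshold"],
        "alpha": info["alpha"],
        "n_markers_scanned": info["n_markers_scanned"],
        "n_box1": info["n_box1"],
        "n_box2": info["n_box2"],
        "n_retained": int(results["retained"].sum()),
        "snp_variance_without_imprinting": rep.snp_without,
        "snp_variance_with_imprinting": rep.snp_with,
        "snp_variance_box1": rep.snp_box1,
        "snp_variance_box1_imprinting_part": rep.snp_box1_imprinting,
        "varcomps_imp": rep.varcomps_imp,
        "varcomps_add": rep.varcomps_add,
        "h2_with_imprinting": rep.h2_with,
        "h2_without_imprinting": rep.h2_without,
    }
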