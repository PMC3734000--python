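"""Imputation-accuracy statistics: allelic concordance, frequency baseline,
MAF-adjusted accuracy, dosage correlation, HPD intervals and stratification.

The central statistic is the proportion of correctly imputed alleles

    IA = 1 - sum_i sum_j |g_ij - ghat_ij| / (2 * sum_i N_i)

where g_ij is the observed allelic dosage of SNP i in individual j, ghat_ij
the posterior expected dosage, and N_i the number of called genotypes at
SNP i.  It decomposes exactly into the N_i-weighted mean of SNP-wise
accuracies IA_i. and the M_j-weighted mean of animal-wise accuracies IA_.j.

Raw concordance is biased upward at low MAF (frequency-only guessing already
gets the major allele right), so two MAF-robust companions are provided: the
frequency baseline IA_Freq (expected accuracy of assigning a random genotype
drawn from the reference panel) with the adjustment
IA_MAF = (IA - IA_Freq) / (1 - IA_Freq), and the squared correlation between
observed and imputed dosage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    MISSING,
    GenotypeMatrix,
    HaplotypePanel,
    MarkerMap,
    PosteriorGenotypeSet,
    compute_maf,
    genotype_frequencies,
)


@dataclass
class IAResult:
    """Overall concordance plus its SNP-wise and animal-wise decompositions."""

    overall: float
    by_snp: np.ndarray
    by_animal: np.ndarray
    n_by_snp: np.ndarray  # N_i over evaluated markers
    m_by_animal: np.ndarray  # M_j over evaluated markers
    evaluated_markers: np.ndarray


def _imputed_dosage(imputed, mode: str) -> np.ndarray:
    if isinstance(imputed, PosteriorGenotypeSet):
        if mode == "dosage":
            return imputed.dosage_expected
        return imputed.hard_calls().dosage.astype(float)
    if isinstance(imputed, GenotypeMatrix):
        return imputed.dosage.astype(float)
    return np.asarray(imputed, dtype=float)


def ia_overall(
    truth: GenotypeMatrix,
    imputed: PosteriorGenotypeSet | GenotypeMatrix | np.ndarray,
    evaluate_at: np.ndarray | None = None,
    mode: str = "dosage",
) -> IAResult:
    """Proportion of correctly imputed alleles with both decompositions.

    Evaluation is restricted to the markers in ``evaluate_at`` (those masked
    before imputation) and to entries with non-missing truth.  ``mode`` is
    "dosage" (compare against posterior expected dosage, the default) or
    "hard" (compare against the most likely genotype).
    """
    ghat = _imputed_dosage(imputed, mode)
    if ghat.shape != truth.dosage.shape:
        raise ValueError("truth and imputed shapes differ")
    cols = np.arange(truth.n_markers) if evaluate_at is None else np.asarray(evaluate_at, dtype=np.intp)
    g = truth.dosage[:, cols].astype(float)
    e = np.abs(g - ghat[:, cols])
    called = truth.dosage[:, cols] != MISSING
    e = np.where(called, e, 0.0)
    n_by_snp = called.sum(axis=0)
    m_by_animal = called.sum(axis=1)
    total = n_by_snp.sum()
    if total == 0:
        raise ValueError("no evaluable entries (no called truth at the evaluated markers)")
    overall = 1.0 - e.sum() / (2.0 * total)
    with np.errstate(invalid="ignore", divide="ignore"):
        by_snp = np.where(n_by_snp > 0, 1.0 - e.sum(axis=0) / (2.0 * n_by_snp), np.nan)
        by_animal = np.where(m_by_animal > 0, 1.0 - e.sum(axis=1) / (2.0 * m_by_animal), np.nan)
    return IAResult(float(overall), by_snp, by_animal, n_by_snp, m_by_animal, cols)


def ia_freq(
    reference: HaplotypePanel,
    imputed: PosteriorGenotypeSet,
    evaluate_at: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    per_snp: bool = True,
):
    """Expected accuracy of frequency-only imputation, per SNP.

    IA_Freq,i = p(AA)_ref p(AA)_val + p(AB)_ref p(AB)_val + p(BB)_ref p(BB)_val
    with reference frequencies observed in the reference haplotypes and
    predicted frequencies taken as per-SNP means of the posterior triples.
    With ``per_snp=False`` the SNP-wise values are combined into the
    weighted mean (weights default to equal).
    """
    cols = (
        np.arange(imputed.n_markers)
        if evaluate_at is None
        else np.asarray(evaluate_at, dtype=np.intp)
    )
    ref_freq = genotype_frequencies(reference)[cols]
    val_freq = imputed.probs[:, cols, :].mean(axis=0)
    vals = (ref_freq * val_freq).sum(axis=1)
    if per_snp:
        return vals
    w = np.ones(len(cols)) if weights is None else np.asarray(weights, dtype=float)
    return weighted_mean(vals, w)


def ia_maf(ia: float | np.ndarray, ia_freq_val: float | np.ndarray):
    """MAF-adjusted accuracy (IA - IA_Freq) / (1 - IA_Freq).

    Zero means no gain over frequency guessing; negative values mean the
    imputer underperformed it.  Undefined (NaN) where IA_Freq = 1.
    """
    ia = np.asarray(ia, dtype=float)
    f = np.asarray(ia_freq_val, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.isclose(f, 1.0), np.nan, (ia - f) / (1.0 - f))
    return float(out) if out.ndim == 0 else out


def dosage_r2(truth_col: np.ndarray, imputed_col: np.ndarray) -> float:
    """Squared Pearson correlation of observed vs imputed dosage.

    Missing truth entries are excluded; NaN when fewer than two pairs remain
    or the truth is constant among the evaluated individuals.
    """
    t = np.asarray(truth_col, dtype=float)
    x = np.asarray(imputed_col, dtype=float)
    ok = t != MISSING
    t, x = t[ok], x[ok]
    if len(t) < 2 or np.ptp(t) == 0 or np.ptp(x) == 0:
        return float("nan")
    r, _ = stats.pearsonr(t, x)
    return float(r * r)


def dosage_r2_by_snp(
    truth: GenotypeMatrix,
    imputed: PosteriorGenotypeSet | np.ndarray,
    evaluate_at: np.ndarray | None = None,
) -> np.ndarray:
    """SNP-wise squared dosage correlation over the evaluated markers."""
    ghat = _imputed_dosage(imputed, "dosage")
    cols = (
        np.arange(truth.n_markers)
        if evaluate_at is None
        else np.asarray(evaluate_at, dtype=np.intp)
    )
    return np.array([dosage_r2(truth.dosage[:, c], ghat[:, c]) for c in cols])


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted mean excluding flagged (NaN) values together with their weights."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    ok = np.isfinite(v) & (w > 0)
    if not ok.any() or w[ok].sum() == 0:
        raise ValueError("no usable entries for the weighted mean")
    return float(np.sum(v[ok] * w[ok]) / np.sum(w[ok]))


def hpd_interval(values: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Empirical shortest interval containing at least ``mass`` of the values.

    Among all contiguous windows of ceil(mass * n) sorted values the one of
    minimal width wins; ties go to the lower start.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("hpd_interval needs at least one finite value")
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    k = min(math.ceil(mass * len(v)), len(v))
    widths = v[k - 1 :] - v[: len(v) - k + 1]
    start = int(np.argmin(widths))
    return float(v[start]), float(v[start + k - 1])


def stratify(
    markers: MarkerMap,
    values: dict,
    weights: np.ndarray,
    by: str = "maf",
    maf: np.ndarray | None = None,
    maf_bin_width: float = 0.05,
    position_strata: dict | None = None,
) -> pd.DataFrame:
    """Per-stratum N_i-weighted means of SNP-wise accuracy statistics.

    ``values`` maps column names to per-SNP vectors (NaN entries excluded
    with their weights).  ``by`` is "maf" (bins of width ``maf_bin_width``)
    or "scaled_position" (default strata: the 5% chromosomal extremes on
    either side, the central 10%, and the remainder).  Empty strata are
    reported with count 0 and no value.
    """
    w = np.asarray(weights, dtype=float)
    if by == "maf":
        if maf is None:
            raise ValueError("stratifying by MAF requires a maf vector")
        edges = np.arange(0.0, 0.5 + maf_bin_width, maf_bin_width)
        labels = [f"[{edges[i]:.2f},{edges[i+1]:.2f})" for i in range(len(edges) - 1)]
        which = np.clip(np.digitize(maf, edges) - 1, 0, len(labels) - 1)
        strata = {lab: which == i for i, lab in enumerate(labels)}
    elif by == "scaled_position":
        sp = markers.scaled_position()
        if position_strata is None:
            strata = {
                "extremes": (sp <= 0.05) | (sp >= 0.95),
                "center": (sp >= 0.45) & (sp <= 0.55),
            }
            strata["other"] = ~(strata["extremes"] | strata["center"])
        else:
            strata = position_strata
    else:
        raise ValueError(f"unknown stratification {by!r}")

    rows = []
    for lab, sel in strata.items():
        row = {"stratum": lab, "n_snp": int(np.sum(sel))}
        for name, vec in values.items():
            v = np.asarray(vec, dtype=float)[sel]
            ww = w[sel]
            ok = np.isfinite(v) & (ww > 0)
            row[name] = float(np.sum(v[ok] * ww[ok]) / np.sum(ww[ok])) if ok.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def loess_curve(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    span: float = 0.3,
    grid: np.ndarray | None = None,
    degree: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted polynomial regression with tricube distance weights.

    Observation weights multiply the tricube kernel.  Windows whose local
    design is degenerate (all x equal) fall back to the weighted mean.
    Returns (grid, fitted values).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if weights is not None:
        wobs = np.asarray(weights, dtype=float)
        ok &= np.isfinite(wobs) & (wobs > 0)
        wobs = wobs[ok]
    x, y = x[ok], y[ok]
    if weights is None:
        wobs = np.ones(len(x))
    n = len(x)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1 or 2")
    k = max(degree + 2, math.ceil(span * n))
    if n < k:
        raise ValueError("not enough points for the requested span")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), min(100, n))
    grid = np.asarray(grid, dtype=float)

    fitted = np.empty(len(grid))
    for gi, g in enumerate(grid):
        d = np.abs(x - g)
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        tri = np.ones(k) if h == 0 else np.clip(1 - (d[idx] / h) ** 3, 0, 1) ** 3
        w = tri * wobs[idx]
        if w.sum() == 0:
            w = wobs[idx]
        xi, yi = x[idx], y[idx]
        if degree == 0 or np.ptp(xi) == 0:
            fitted[gi] = np.sum(w * yi) / np.sum(w)
            continue
        design = np.vander(xi - g, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], yi * sw, rcond=None)
        fitted[gi] = coef[0]
    return grid, fitted


@dataclass
class AccuracyReport:
    """Bundle of every accuracy statistic for one imputation run."""

    ia_overall: float
    ia_by_snp: np.ndarray
    ia_by_animal: np.ndarray
    ia_freq_by_snp: np.ndarray
    ia_maf_overall: float
    ia_maf_by_snp: np.ndarray
    r2_by_snp: np.ndarray
    r2_overall: float
    weights_by_snp: np.ndarray
    weights_by_animal: np.ndarray
    hpd_snp: tuple[float, float]
    hpd_animal: tuple[float, float]
    strata_maf: pd.DataFrame
    strata_position: pd.DataFrame
    evaluated_markers: np.ndarray


def accuracy_report(
    truth: GenotypeMatrix,
    imputed: PosteriorGenotypeSet,
    reference: HaplotypePanel,
    evaluate_at: np.ndarray | None = None,
    mode: str = "dosage",
    maf_source: str = "reference",
    hpd_mass: float = 0.95,
) -> AccuracyReport:
    """Compute the full accuracy battery for one masked-imputation run.

    MAF strata are indexed by the reference-panel MAF by default
    (``maf_source`` may be "truth" to use the testing panel instead).
    """
    ia = ia_overall(truth, imputed, evaluate_at, mode=mode)
    cols = ia.evaluated_markers
    freq_snp = ia_freq(reference, imputed, cols)
    ia_freq_overall = weighted_mean(freq_snp, ia.n_by_snp)
    adj_overall = ia_maf(ia.overall, ia_freq_overall)
    adj_snp = ia_maf(ia.by_snp, freq_snp)
    r2_snp = dosage_r2_by_snp(truth, imputed, cols)
    r2_all = weighted_mean(r2_snp, ia.n_by_snp) if np.isfinite(r2_snp).any() else float("nan")
    maf_vec = compute_maf(reference if maf_source == "reference" else truth)[cols]
    sub_map = truth.markers.subset(cols)
    per_snp_values = {"ia": ia.by_snp, "ia_maf": adj_snp, "r2": r2_snp}
    return AccuracyReport(
        ia_overall=ia.overall,
        ia_by_snp=ia.by_snp,
        ia_by_animal=ia.by_animal,
        ia_freq_by_snp=freq_snp,
        ia_maf_overall=adj_overall,
        ia_maf_by_snp=adj_snp,
        r2_by_snp=r2_snp,
        r2_overall=r2_all,
        weights_by_snp=ia.n_by_snp,
        weights_by_animal=ia.m_by_animal,
        hpd_snp=hpd_interval(ia.by_snp[np.isfinite(ia.by_snp)], hpd_mass),
        hpd_animal=hpd_interval(ia.by_animal[np.isfinite(ia.by_animal)], hpd_mass),
        strata_maf=stratify(sub_map, per_snp_values, ia.n_by_snp, by="maf", maf=maf_vec),
        strata_position=stratify(sub_map, per_snp_values, ia.n_by_snp, by="scaled_position"),
        evaluated_markers=cols,
    )
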