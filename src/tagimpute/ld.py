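"""Pairwise linkage disequilibrium (r-squared) from phased haplotypes.

r-squared is computed from haplotype counts as D^2 normalized by the product
of allele-frequency variances, equivalently the squared Pearson correlation of
the two binary allele columns.  Monomorphic markers have undefined LD and are
flagged NaN; cross-chromosome pairs are defined as 0 for tag-selection
coverage, since statistical selection runs per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import HaplotypePanel, MarkerMap


@dataclass
class LDMatrix:
    """Symmetric matrix of r-squared per marker pair.

    ``values[i, j]`` is NaN when either marker is monomorphic; pairs beyond
    the distance window (or across chromosomes) are stored as 0, which for
    coverage purposes means "not in LD".  ``segregating`` flags markers with
    defined LD.
    """

    values: np.ndarray
    markers: MarkerMap
    segregating: np.ndarray
    max_distance_bp: int | None = None

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]


def pairwise_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """r^2 between markers i and j: (p_AB - p_A p_B)^2 / (p_A q_A p_B q_B).

    Returns NaN when either marker is monomorphic in the panel.
    """
    x = panel.alleles[:, i].astype(float)
    y = panel.alleles[:, j].astype(float)
    pa, pb = x.mean(), y.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0.0 or vb == 0.0:
        return float("nan")
    d = (x * y).mean() - pa * pb
    return float(d * d / (va * vb))


def ld_matrix(panel: HaplotypePanel, max_distance_bp: int | None = None) -> LDMatrix:
    """All pairwise r^2 within a distance window on the same chromosome.

    Pairs farther apart than ``max_distance_bp`` (or on different
    chromosomes) are set to 0.  The diagonal is 1 for segregating markers and
    NaN for monomorphic ones.
    """
    h = panel.alleles.astype(np.float64)
    m = panel.n_markers
    freq = h.mean(axis=0)
    var = freq * (1 - freq)
    segregating = var > 0

    centered = h - freq
    cov = centered.T @ centered / h.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.outer(var, var)
        r2 = np.where(denom > 0, cov * cov / denom, np.nan)
    r2[~segregating, :] = np.nan
    r2[:, ~segregating] = np.nan

    pos = panel.markers.position_bp
    chrom = panel.markers.chromosome
    same_chrom = chrom[:, None] == chrom[None, :]
    out_of_window = ~same_chrom
    if max_distance_bp is not None:
        dist = np.abs(pos[:, None] - pos[None, :])
        out_of_window |= dist > max_distance_bp
    np.fill_diagonal(out_of_window, False)
    r2[out_of_window] = 0.0
    np.fill_diagonal(r2, np.where(segregating, 1.0, np.nan))
    return LDMatrix(r2, panel.markers, segregating, max_distance_bp)


def mean_r2_at_distance(
    panel: HaplotypePanel,
    target_bp: float,
    tolerance_bp: float,
) -> float:
    """Mean r^2 over segregating pairs whose separation is target +- tolerance."""
    ld = ld_matrix(panel)
    pos = panel.markers.position_bp.astype(float)
    dist = np.abs(pos[:, None] - pos[None, :])
    sel = (np.abs(dist - target_bp) <= tolerance_bp) & np.isfinite(ld.values)
    sel &= np.triu(np.ones_like(sel), k=1).astype(bool)
    if not sel.any():
        return float("nan")
    return float(ld.values[sel].mean())


def ld_decay_profile(
    panel: HaplotypePanel, bin_edges_bp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean r^2 per distance bin; returns (bin centers, mean r^2)."""
    ld = ld_matrix(panel)
    pos = panel.markers.position_bp.astype(float)
    iu = np.triu_indices(panel.n_markers, k=1)
    dist = np.abs(pos[iu[0]] - pos[iu[1]])
    vals = ld.values[iu]
    ok = np.isfinite(vals)
    dist, vals = dist[ok], vals[ok]
    centers = 0.5 * (bin_edges_bp[:-1] + bin_edges_bp[1:])
    means = np.full(len(centers), np.nan)
    which = np.digitize(dist, bin_edges_bp) - 1
    for b in range(len(centers)):
        sel = which == b
        if sel.any():
            means[b] = vals[sel].mean()
    return centers, means


def export_ld_tsv(ld: LDMatrix, path: str, min_r2: float = 0.0) -> None:
    """Write defined pairs (i < j) as a 3-column TSV: id_i, id_j, r2."""
    ids = ld.markers.marker_id
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tr2\n")
        iu = np.triu_indices(ld.n_markers, k=1)
        for i, j in zip(*iu):
            v = ld.values[i, j]
            if np.isfinite(v) and v >= min_r2:
                fh.write(f"{ids[i]}\t{ids[j]}\t{v:.10g}\n")
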