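"""TagSNP selection: even spacing, LD set cover, predictive forward search,
and MAF-weighted spacing with end-window densification.

Four selectors share the :class:`SelectionResult` return type.  Tie-breaking
is deterministic everywhere: coverage or score ties go to the marker with the
higher MAF (when MAF is available) and then the lower physical position, so
re-running a selection reproduces the tag list exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .datamodel import (
    GenotypeMatrix,
    HaplotypePanel,
    MarkerMap,
    TagSNPSet,
    compute_maf,
    mask_to_tagsnp,
)
from .ld import LDMatrix, ld_matrix


@dataclass
class SelectionResult:
    tags: TagSNPSet
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tags)


# ---------------------------------------------------------------------------
# 1. Even spacing on physical position
# ---------------------------------------------------------------------------

def select_even_spacing(
    markers: MarkerMap,
    k_per_chromosome: int,
    chromosome_length: dict | None = None,
) -> SelectionResult:
    """Partition each chromosome into k equal segments; tag the SNP nearest
    each segment center.

    Empty segments yield no tag, so the realized set can be smaller than k
    per chromosome.  Chromosome length defaults to the largest marker
    position; ``chromosome_length`` overrides it per chromosome.  Ties in
    center distance go to the lower position.
    """
    if k_per_chromosome < 1:
        raise ValueError("k_per_chromosome must be at least 1")
    chosen: list[int] = []
    per_segment: dict = {}
    for c in markers.chromosomes():
        idx = np.flatnonzero(markers.chromosome == c)
        pos = markers.position_bp[idx].astype(float)
        length = float(
            (chromosome_length or {}).get(c, pos.max())
        )
        seg_len = length / k_per_chromosome
        seg = np.minimum((pos / seg_len).astype(int), k_per_chromosome - 1)
        hits = 0
        for s in range(k_per_chromosome):
            in_seg = np.flatnonzero(seg == s)
            if in_seg.size == 0:
                continue
            center = (s + 0.5) * seg_len
            d = np.abs(pos[in_seg] - center)
            best = in_seg[np.lexsort((pos[in_seg], d))[0]]
            chosen.append(int(idx[best]))
            hits += 1
        per_segment[c] = hits
    tags = TagSNPSet(
        np.array(chosen, dtype=np.intp),
        method="even",
        params={"k_per_chromosome": k_per_chromosome},
        markers=markers,
    )
    return SelectionResult(tags, {"segments_hit": per_segment})


# ---------------------------------------------------------------------------
# 2. Statistical selection: greedy LD set cover at threshold rt2
# ---------------------------------------------------------------------------

def select_statistical(
    ld: LDMatrix,
    rt2: float,
    maf: np.ndarray | None = None,
) -> SelectionResult:
    """Greedy set cover on the LD graph at threshold rt2.

    After selection, every segregating SNP is either a tag or in LD
    r^2 >= rt2 with at least one tag (the covering property holds exactly).
    At each step the SNP covering the most still-uncovered SNP is added;
    coverage-count ties break toward higher MAF, then lower position.
    Monomorphic markers are excluded from the coverage universe; an undefined
    r^2 between two segregating markers is an error.
    """
    if not 0 < rt2 < 1:
        raise ValueError("rt2 must lie in (0, 1)")
    seg = ld.segregating
    vals = ld.values
    bad = ~np.isfinite(vals[np.ix_(seg, seg)])
    if bad.any():
        raise ValueError("LD matrix has undefined entries between segregating markers")

    m = ld.n_markers
    pos = ld.markers.position_bp.astype(float)
    maf_key = np.zeros(m) if maf is None else np.asarray(maf, dtype=float)
    with np.errstate(invalid="ignore"):
        cover = (vals >= rt2) & seg[None, :] & seg[:, None]
    np.fill_diagonal(cover, seg)

    uncovered = seg.copy()
    chosen: list[int] = []
    while uncovered.any():
        gain = (cover & uncovered[None, :]).sum(axis=1)
        gain[~seg] = 0
        best_gain = gain.max()
        cand = np.flatnonzero(gain == best_gain)
        # higher MAF first, then lower position
        cand = cand[np.lexsort((pos[cand], -maf_key[cand]))]
        pick = int(cand[0])
        chosen.append(pick)
        uncovered &= ~cover[pick]

    chosen_arr = np.array(sorted(chosen), dtype=np.intp)
    covered_by_tag = cover[chosen_arr].any(axis=0)
    non_tags = seg.copy()
    non_tags[chosen_arr] = False
    coverage = float(covered_by_tag[non_tags].mean()) if non_tags.any() else 1.0
    tags = TagSNPSet(chosen_arr, method="statistical", params={"rt2": rt2}, markers=ld.markers)
    diag = {
        "coverage": coverage,
        "n_segregating": int(seg.sum()),
        "mean_tag_maf": float(np.mean(maf_key[chosen_arr])) if maf is not None else None,
    }
    return SelectionResult(tags, diag)


# ---------------------------------------------------------------------------
# 3. Predictive forward search
# ---------------------------------------------------------------------------

def select_predictive(
    panel: HaplotypePanel,
    k_max: int,
    train_size: int,
    imputer: Callable[[GenotypeMatrix, HaplotypePanel], object],
    accuracy_fn: Callable[[GenotypeMatrix, object, np.ndarray], float],
    seed: int = 0,
    target_accuracy: float | None = None,
    evaluate: str = "masked",
    tie_tolerance: float = 1e-12,
) -> SelectionResult:
    """Forward search for tagSNP by direct imputation accuracy.

    The panel's diploid individuals are split at random into a training set
    (``train_size`` individuals, genotypes only) and reference haplotypes.
    Each step masks the training set down to the current tags plus one
    candidate, imputes from the reference, and adds the candidate with the
    highest mean accuracy; the search stops at ``k_max`` tags or when
    ``target_accuracy`` is reached.  ``evaluate`` is "masked" (score over all
    currently masked SNP) or "all" (every SNP).  Accuracy ties within
    ``tie_tolerance`` break toward higher MAF, then lower position.
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    if panel.n_haplotypes % 2:
        raise ValueError("panel must contain whole diploid individuals")
    n_ind = panel.n_haplotypes // 2
    if n_ind < train_size + 1:
        raise ValueError("panel too small for the requested training split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_ind)
    train_ind = perm[:train_size]
    ref_ind = perm[train_size:]
    hap_rows = lambda ind: np.concatenate([[2 * i, 2 * i + 1] for i in ind])
    reference = panel.subset_haplotypes(hap_rows(ref_ind))
    truth = panel.subset_haplotypes(hap_rows(train_ind)).to_genotypes()

    m = panel.n_markers
    maf = compute_maf(panel)
    pos = panel.markers.position_bp.astype(float)
    if m == 1:
        tags = TagSNPSet(np.array([0], dtype=np.intp), "predictive", {"k_max": k_max}, panel.markers)
        return SelectionResult(tags, {"trace": [(0, 1.0)], "seed": seed})

    chosen: list[int] = []
    trace: list[tuple[int, float]] = []
    while len(chosen) < min(k_max, m):
        candidates = [i for i in range(m) if i not in chosen]
        scores = np.full(m, -np.inf)
        for cand in candidates:
            tag_idx = np.array(sorted(chosen + [cand]), dtype=np.intp)
            masked = mask_to_tagsnp(truth, TagSNPSet(tag_idx, "predictive", markers=panel.markers))
            try:
                posterior = imputer(masked, reference)
            except Exception as exc:  # propagate with candidate context
                raise RuntimeError(f"imputer failed for candidate SNP {cand}") from exc
            if evaluate == "masked":
                eval_at = np.setdiff1d(np.arange(m), tag_idx)
                if eval_at.size == 0:
                    eval_at = np.arange(m)
            else:
                eval_at = np.arange(m)
            scores[cand] = accuracy_fn(truth, posterior, eval_at)
        best = scores.max()
        tied = np.flatnonzero(scores >= best - tie_tolerance)
        tied = tied[np.lexsort((pos[tied], -maf[tied]))]
        pick = int(tied[0])
        chosen.append(pick)
        trace.append((pick, float(scores[pick])))
        if target_accuracy is not None and scores[pick] >= target_accuracy:
            break
    tags = TagSNPSet(
        np.array(chosen, dtype=np.intp),
        method="predictive",
        params={"k_max": k_max, "train_size": train_size, "seed": seed},
        markers=panel.markers,
    )
    return SelectionResult(tags, {"trace": trace, "seed": seed})


# ---------------------------------------------------------------------------
# 4. Weighted spacing (MAF-scored greedy with densified chromosome ends)
# ---------------------------------------------------------------------------

def select_weighted_spacing(
    markers: MarkerMap,
    maf_tables: dict,
    weights: dict,
    end_window_bp: int,
    end_density_multiplier: float,
    k_per_chromosome: int,
    spacing_weight: float = 1.0,
) -> SelectionResult:
    """Greedy MAF-and-spacing score with doubled (or other) end-window density.

    This reconstructs the style of commercial low-density panel design: each
    candidate scores sum_pop w_pop * MAF_pop(i) plus a spacing term
    ``spacing_weight * min(d / target_spacing, 1)`` where d is the distance to
    the nearest already-selected tag.  The target spacing is divided by
    ``end_density_multiplier`` within ``end_window_bp`` of either chromosome
    end, so end windows receive proportionally more tags.  Deterministic;
    score ties break toward lower position.
    """
    if end_window_bp < 0:
        raise ValueError("end_window_bp must be non-negative")
    if any(w < 0 for w in weights.values()):
        raise ValueError("population weights must be non-negative")
    for pop, w in weights.items():
        if w > 0 and pop not in maf_tables:
            raise ValueError(f"no MAF table for weighted population {pop!r}")

    m = markers.n_markers
    maf_score = np.zeros(m)
    for pop, w in weights.items():
        if w > 0:
            maf_score += w * np.asarray(maf_tables[pop], dtype=float)

    chosen: list[int] = []
    for c in markers.chromosomes():
        idx = np.flatnonzero(markers.chromosome == c)
        pos = markers.position_bp[idx].astype(float)
        lo, hi = pos.min(), pos.max()
        length = hi - lo if hi > lo else 1.0
        in_end = (pos - lo <= end_window_bp) | (hi - pos <= end_window_bp)
        w_end = min(end_window_bp, length / 2)
        base_spacing = (length + 2 * w_end * (end_density_multiplier - 1)) / k_per_chromosome
        # discretization correction: greedy steps land on the next marker at or
        # beyond the target, overshooting by ~half the marker spacing on average
        if len(pos) > 1:
            base_spacing = max(base_spacing - 0.5 * np.median(np.diff(np.sort(pos))), 1.0)
        target = np.where(in_end, base_spacing / end_density_multiplier, base_spacing)
        target = np.maximum(target, 1.0)

        selected: list[int] = []
        nearest = np.full(len(idx), np.inf)
        for _ in range(min(k_per_chromosome, len(idx))):
            spacing_term = spacing_weight * np.minimum(nearest / target, 1.0)
            score = maf_score[idx] + spacing_term
            score[selected] = -np.inf
            best = score.max()
            cand = np.flatnonzero(score == best)
            pick = int(cand[np.argsort(pos[cand])[0]])
            selected.append(pick)
            nearest = np.minimum(nearest, np.abs(pos - pos[pick]))
        chosen.extend(int(idx[s]) for s in selected)

    tags = TagSNPSet(
        np.array(chosen, dtype=np.intp),
        method="weighted_spacing",
        params={
            "end_window_bp": end_window_bp,
            "end_density_multiplier": end_density_multiplier,
            "k_per_chromosome": k_per_chromosome,
            "spacing_weight": spacing_weight,
        },
        markers=markers,
    )
    return SelectionResult(tags, {"mean_tag_maf": float(maf_score[tags.marker_indices].mean())})


# ---------------------------------------------------------------------------
# Convenience
# ---------------------------------------------------------------------------

def statistical_tags_for_panel(
    panel: HaplotypePanel, rt2: float, max_distance_bp: int | None = None
) -> SelectionResult:
    """LD set cover computed directly from a phased panel."""
    return select_statistical(ld_matrix(panel, max_distance_bp), rt2, maf=compute_maf(panel))
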