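"""End-to-end imputation experiments on simulated populations.

Three experiment families, each replicated over independent Wright-Fisher
populations with per-replicate seeds recorded in every output row:

* tag density -- imputation accuracy as a function of the number of tagSNP
  and the selection method (even spacing vs LD set cover at matched counts);
* panel size / composition -- accuracy as a function of the number of
  reference haplotypes, for randomly sampled, oldest-individual, trio-derived
  and combined panels;
* stratified report -- SNP-wise accuracy against scaled chromosomal position
  (end-window deficit, with and without doubled end density) and against MAF.

The default geometry is deliberately scaled down (one chromosome, 200
markers over 20 Mb, small test sets) so that a full replicated run completes
in minutes on a single core; all qualitative contrasts of interest survive
the scaling because they depend only on relative LD structure.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    GenotypeMatrix,
    HaplotypePanel,
    TagSNPSet,
    compute_maf,
    mask_to_tagsnp,
)
from .hmm import HMMParams, impute, phase_trio, phase_unrelated, resolve_scaffold
from .metrics import accuracy_report
from .select import select_even_spacing, select_weighted_spacing, statistical_tags_for_panel
from .simulate import SimulationConfig, sample_trios, sample_unrelated, simulate_population


def _default_simulation() -> SimulationConfig:
    # chip-like density: 300 markers over 15 Mb = 50 kb spacing
    return SimulationConfig(n_markers=300, chromosome_length_bp=15_000_000)


def _default_phasing() -> HMMParams:
    # scaled-down phasing schedule for replicated experiments
    return HMMParams(n_iterations=5, n_samples_per_iteration=4, max_reference_haplotypes=32)


@dataclass
class ExperimentConfig:
    """Shared configuration of the replicated experiment families."""

    simulation: SimulationConfig = field(default_factory=_default_simulation)
    hmm: HMMParams = field(default_factory=HMMParams)
    phasing: HMMParams = field(default_factory=_default_phasing)
    replicates: int = 20
    n_test: int = 20
    reference_haplotypes: int = 64
    rt2_values: tuple = (0.2, 0.3, 0.45)
    panel_sizes_random: tuple = (16, 32, 64, 128)
    trio_panel_sizes: tuple = (128,)
    cost_equivalent_factor: float = 1.5
    panel_sizes_strat: tuple = (32, 128)
    n_tags_strat: int = 16
    end_window_fraction: float = 0.05
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")


def _log(config: ExperimentConfig, msg: str) -> None:
    if config.verbose:
        print(f"[tagimpute {time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def _replicate_population(config: ExperimentConfig, rep: int, keep_generations: int = 1):
    sim = replace(
        config.simulation,
        seed=(config.seed * 10_007 + rep) % (2**31 - 1),
        keep_last_generations=keep_generations,
    )
    return simulate_population(sim), sim.seed


def _split_test(panel: HaplotypePanel, n_test: int, seed: int):
    """Split simulated individuals into a test set and a reference pool."""
    rng = np.random.default_rng(seed)
    n_ind = panel.n_haplotypes // 2
    generation = np.asarray(
        panel.metadata.get("generation", np.zeros(panel.n_haplotypes))
    )[0::2]
    last = generation.max()
    candidates = np.flatnonzero(generation == last)
    test_ind = rng.choice(candidates, size=n_test, replace=False)
    pool_ind = np.setdiff1d(np.arange(n_ind), test_ind)
    rows = lambda ind: np.concatenate([[2 * i, 2 * i + 1] for i in ind])
    test_panel = panel.subset_haplotypes(rows(test_ind))
    truth = test_panel.to_genotypes()
    pool = panel.subset_haplotypes(rows(pool_ind))
    return truth, pool


def _score(truth, posterior, reference, tags):
    eval_at = np.setdiff1d(np.arange(truth.n_markers), tags.marker_indices)
    return accuracy_report(truth, posterior, reference, eval_at)


# ---------------------------------------------------------------------------
# Experiment 1: tagSNP density and selection method
# ---------------------------------------------------------------------------

def run_tag_density_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Accuracy vs number of tagSNP for even-spacing and LD set cover.

    Statistical tag counts are set by the configured rt2 thresholds; the
    even-spacing selector is then run at the matched target count so the two
    methods are compared at (approximately) equal density.
    """
    rows = []
    for rep in range(config.replicates):
        panel, sim_seed = _replicate_population(config, rep)
        truth, pool = _split_test(panel, config.n_test, sim_seed + 1)
        rng = np.random.default_rng(sim_seed + 2)
        ref_rows = rng.choice(pool.n_haplotypes, config.reference_haplotypes, replace=False)
        reference = pool.subset_haplotypes(ref_rows)
        _log(config, f"tag-density rep {rep}: {panel.n_markers} markers")
        for rt2 in config.rt2_values:
            stat = statistical_tags_for_panel(reference, rt2)
            selections = {
                "statistical": stat,
                "even": select_even_spacing(truth.markers, max(len(stat), 1)),
            }
            for method, sel in selections.items():
                masked = mask_to_tagsnp(truth, sel.tags)
                posterior = impute(masked, reference, config.hmm)
                rep_report = _score(truth, posterior, reference, sel.tags)
                rows.append(
                    {
                        "replicate": rep,
                        "seed": sim_seed,
                        "method": method,
                        "rt2": rt2,
                        "n_tags": len(sel),
                        "ia": rep_report.ia_overall,
                        "ia_maf": rep_report.ia_maf_overall,
                        "r2": rep_report.r2_overall,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment 2: reference panel size and composition
# ---------------------------------------------------------------------------

def build_trio_reference(trios, phasing: HMMParams, seed: int = 0) -> HaplotypePanel:
    """Phase sampled trios by Mendelian rules and resolve leftover ambiguity.

    Triple-heterozygous sites are first filled at random to obtain a
    complete scaffold, then each parent is re-decoded against the scaffold of
    the other parents with the haploid copying chain.
    """
    rng = np.random.default_rng(seed)
    n_trios = trios.sires.n_individuals
    markers = trios.sires.markers
    m = markers.n_markers
    pairs, genos = [], []
    for t in range(n_trios):
        res = phase_trio(
            trios.sires.dosage[t], trios.dams.dosage[t], trios.offspring.dosage[t]
        )
        pairs.extend([res.sire_haplotypes, res.dam_haplotypes])
        genos.extend([trios.sires.dosage[t], trios.dams.dosage[t]])

    filled = []
    for pair, g in zip(pairs, genos):
        f = pair.copy()
        amb = f[0] == MISSING
        flip = rng.integers(0, 2, size=m).astype(np.int8)
        het = amb & (g == 1)
        f[0, het] = flip[het]
        f[1, het] = 1 - flip[het]
        hom = amb & ((g == 0) | (g == 2))
        f[0, hom] = (g[hom] == 2).astype(np.int8)
        f[1, hom] = f[0, hom]
        rest = f[0] == MISSING
        f[:, rest] = rng.integers(0, 2, size=(2, int(rest.sum()))).astype(np.int8)
        filled.append(f)

    out = np.empty((2 * len(pairs), m), dtype=np.int8)
    for i, (pair, g) in enumerate(zip(pairs, genos)):
        others = np.vstack([filled[j] for j in range(len(filled)) if j != i])
        scaffold = HaplotypePanel(others, markers)
        resolved = resolve_scaffold(pair, g, scaffold, phasing)
        out[2 * i] = resolved[0]
        out[2 * i + 1] = resolved[1]
    return HaplotypePanel(out, markers, provenance="trio")


def _phase_pool_individuals(
    pool: HaplotypePanel,
    individuals: np.ndarray,
    phasing: HMMParams,
    seed: int,
    seed_panel: HaplotypePanel | None = None,
) -> HaplotypePanel:
    rows = np.concatenate([[2 * i, 2 * i + 1] for i in individuals])
    genotypes = pool.subset_haplotypes(rows).to_genotypes()
    params = replace(phasing, seed=seed % (2**31 - 1))
    return phase_unrelated(genotypes, seed_panel=seed_panel, params=params)


def run_panel_size_experiment(
    config: ExperimentConfig,
    compositions: tuple = ("random", "trio"),
) -> pd.DataFrame:
    """Accuracy vs reference panel size for the requested compositions.

    Three retained generations give the study's cohort structure: trio
    parents come from the oldest cohort (emulating a panel genotyped in an
    earlier study), while the supplementary pool and the test set are drawn
    from the two recent cohorts.  The random panel individuals are phased
    once, jointly, with the iterative HMM and sliced into nested panels;
    trio panels come from Mendelian phasing; combined panels add randomly
    sampled individuals, phased against the trio haplotypes, on top of them;
    "oldest" panels take the earliest-generation pool individuals.
    """
    rows = []
    for rep in range(config.replicates):
        panel, sim_seed = _replicate_population(config, rep, keep_generations=3)
        truth, pool = _split_test(panel, config.n_test, sim_seed + 1)
        rng = np.random.default_rng(sim_seed + 3)
        generation = np.asarray(
            pool.metadata.get("generation", np.zeros(pool.n_haplotypes))
        )[0::2]
        trio_source = np.flatnonzero(generation == generation.min())
        supplement = np.flatnonzero(generation > generation.min())

        sizes_random = sorted(config.panel_sizes_random)
        if "trio" in compositions and config.trio_panel_sizes:
            cost_eq = int(config.cost_equivalent_factor * max(config.trio_panel_sizes))
            if cost_eq not in sizes_random:
                sizes_random.append(cost_eq)
        max_ind = max(s // 2 for s in sizes_random)
        if max_ind > len(supplement):
            raise ValueError("supplementary pool too small for the requested sizes")
        nested = rng.choice(supplement, size=max_ind, replace=False)

        def record(composition, size, report):
            rows.append(
                {
                    "replicate": rep,
                    "seed": sim_seed,
                    "composition": composition,
                    "n_haplotypes": size,
                    "ia": report.ia_overall,
                    "ia_maf": report.ia_maf_overall,
                    "r2": report.r2_overall,
                }
            )

        tags = select_even_spacing(truth.markers, config.n_tags_strat).tags
        masked = mask_to_tagsnp(truth, tags)

        def evaluate(reference):
            posterior = impute(masked, reference, config.hmm)
            return _score(truth, posterior, reference, tags)

        phased_all = None
        if "random" in compositions or "combined" in compositions:
            phased_all = _phase_pool_individuals(
                pool, nested, config.phasing, sim_seed + 11
            )
            _log(config, f"panel rep {rep}: phased {max_ind} pool individuals")
        if "random" in compositions:
            for size in sizes_random:
                record("random", size, evaluate(phased_all.subset_haplotypes(np.arange(size))))
        if "oldest" in compositions:
            oldest = supplement[np.argsort(generation[supplement], kind="stable")]
            size = max(config.panel_sizes_random)
            ref = _phase_pool_individuals(
                pool, oldest[: size // 2], config.phasing, sim_seed + 17
            )
            record("oldest", size, evaluate(ref))
        trio_panel = None
        if "trio" in compositions or "combined" in compositions:
            trio_pool = pool.subset_haplotypes(
                np.concatenate([[2 * i, 2 * i + 1] for i in trio_source])
            )
            for size in config.trio_panel_sizes:
                trios = sample_trios(trio_pool, size // 4, seed=sim_seed + 23)
                trio_panel = build_trio_reference(trios, config.phasing, sim_seed + 29)
                _log(config, f"panel rep {rep}: trio {size}")
                if "trio" in compositions:
                    record("trio", size, evaluate(trio_panel))
        if "combined" in compositions and trio_panel is not None:
            extra = max(config.panel_sizes_random) // 2
            supp_panel = _phase_pool_individuals(
                pool, nested[:extra], config.phasing, sim_seed + 31, seed_panel=trio_panel
            )
            combined = HaplotypePanel(
                np.vstack([trio_panel.alleles, supp_panel.alleles]),
                truth.markers,
                provenance="combined",
            )
            record("combined", combined.n_haplotypes, evaluate(combined))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment 3: stratified accuracy (position and MAF)
# ---------------------------------------------------------------------------

def run_stratified_report(config: ExperimentConfig) -> pd.DataFrame:
    """Per-stratum accuracy vs scaled position and MAF across panel sizes.

    For every panel size the test set is imputed from evenly spaced tags and
    from an equal-count MAF-weighted set with doubled density inside the 5%
    end windows; rows carry the end/center contrast and the low-MAF (< 0.1)
    vs rest contrast.
    """
    rows = []
    for rep in range(config.replicates):
        panel, sim_seed = _replicate_population(config, rep)
        truth, pool = _split_test(panel, config.n_test, sim_seed + 1)
        rng = np.random.default_rng(sim_seed + 5)
        length = float(truth.markers.position_bp.max())
        end_bp = int(config.end_window_fraction * length)
        maf_pool = compute_maf(pool)
        for size in config.panel_sizes_strat:
            ref_rows = rng.choice(pool.n_haplotypes, size, replace=False)
            reference = pool.subset_haplotypes(ref_rows)
            schemes = {
                "even": select_even_spacing(truth.markers, config.n_tags_strat),
                "end_doubled": select_weighted_spacing(
                    truth.markers,
                    {"pop": maf_pool},
                    {"pop": 0.05},
                    end_window_bp=end_bp,
                    end_density_multiplier=2.0,
                    k_per_chromosome=config.n_tags_strat,
                ),
            }
            for scheme, sel in schemes.items():
                masked = mask_to_tagsnp(truth, sel.tags)
                posterior = impute(masked, reference, config.hmm)
                report = _score(truth, posterior, reference, sel.tags)
                pos_tab = report.strata_position.set_index("stratum")
                maf_ref = compute_maf(reference)[report.evaluated_markers]
                low = maf_ref < 0.1
                w = report.weights_by_snp.astype(float)

                def wmean(vec, sel_mask):
                    v = np.asarray(vec, dtype=float)
                    ok = sel_mask & np.isfinite(v) & (w > 0)
                    return float(np.sum(v[ok] * w[ok]) / np.sum(w[ok])) if ok.any() else np.nan

                rows.append(
                    {
                        "replicate": rep,
                        "seed": sim_seed,
                        "panel_size": size,
                        "scheme": scheme,
                        "n_tags": len(sel),
                        "ia": report.ia_overall,
                        "ia_end": pos_tab.loc["extremes", "ia"],
                        "ia_center": pos_tab.loc["center", "ia"],
                        "r2_low_maf": wmean(report.r2_by_snp, low),
                        "r2_high_maf": wmean(report.r2_by_snp, ~low),
                        "ia_maf_low": wmean(report.ia_maf_by_snp, low),
                        "ia_maf_high": wmean(report.ia_maf_by_snp, ~low),
                    }
                )
        _log(config, f"stratified rep {rep} done")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trend summaries (shared by tests and the acceptance script)
# ---------------------------------------------------------------------------

def paired_trend(df: pd.DataFrame, group: str, value: str, order: list) -> pd.DataFrame:
    """Mean and Monte-Carlo standard error of ``value`` per level of ``group``."""
    out = (
        df.groupby(group)[value]
        .agg(["mean", "sem", "count"])
        .reindex(order)
        .reset_index()
    )
    return out


def paired_difference(
    df: pd.DataFrame, key: str, a: str, b: str, value: str, on: str = "replicate"
) -> tuple[float, float]:
    """Mean and standard error of the per-replicate difference value(a) - value(b)."""
    pa = df[df[key] == a].groupby(on)[value].mean()
    pb = df[df[key] == b].groupby(on)[value].mean()
    diff = (pa - pb).dropna()
    if len(diff) == 0:
        return float("nan"), float("nan")
    se = float(diff.std(ddof=1) / np.sqrt(len(diff))) if len(diff) > 1 else float("nan")
    return float(diff.mean()), se
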