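"""LD-based genotype imputation and phasing with a diploid Li-Stephens HMM.

The imputer models each test individual's two haplotypes as imperfect mosaics
of the reference haplotypes.  The hidden state at marker m is an ordered pair
(k, l) of reference haplotypes (H^2 states); each chain switches templates
between adjacent markers with probability

    theta_m = 1 - exp(-4 * Ne * c * d_m / H)

where d_m is the inter-marker distance in bp, c the per-bp recombination
rate, Ne the effective-size scale and H the panel size.  The observed dosage
is emitted from the state's implied dosage with an independent per-allele
error epsilon; missing observations emit uniformly, so posteriors at untyped
markers interpolate smoothly between flanking tagSNP.  Forward-backward gives
exact per-marker posterior genotype probabilities; no sampling is involved in
imputation, which is therefore deterministic.

Phasing of unrelated individuals uses the classic iterative scheme: condition
each individual on the current haplotypes of all others, draw a few sampled
state-path decodings per round, and keep the most probable.  Trio phasing
applies the rules of Mendelian inheritance first and resolves the remaining
(triple-heterozygous) sites against a reference scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    MISSING,
    GenotypeMatrix,
    HaplotypePanel,
    PosteriorGenotypeSet,
)


@dataclass
class HMMParams:
    """Tunable parameters of the haplotype-copying model.

    ``error_rate`` is the per-allele emission error (array-genotyping scale,
    default 1e-3); ``ne_scale`` the effective population size entering the
    switch probability (default 113); ``recombination_rate`` the per-bp rate
    used to convert physical distance into expected crossovers.  The phasing
    loop runs ``n_iterations`` rounds drawing ``n_samples_per_iteration``
    haplotype-pair samples per individual.  ``max_reference_haplotypes``
    caps the conditioning panel during phasing (a random subsample is used
    when the panel is larger), which bounds the H^2 state space.
    """

    error_rate: float = 1e-3
    ne_scale: float = 113.0
    recombination_rate: float = 1e-8
    n_iterations: int = 10
    n_samples_per_iteration: int = 4
    max_reference_haplotypes: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must lie in (0, 0.5)")
        if self.ne_scale <= 0:
            raise ValueError("ne_scale must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")


def emission_table(eps: float) -> np.ndarray:
    """P(observed dosage | state dosage), rows = state dosage 0/1/2.

    Each observed allele equals the copied allele with probability 1 - eps.
    """
    return np.array(
        [
            [(1 - eps) ** 2, 2 * eps * (1 - eps), eps**2],
            [eps * (1 - eps), (1 - eps) ** 2 + eps**2, eps * (1 - eps)],
            [eps**2, 2 * eps * (1 - eps), (1 - eps) ** 2],
        ]
    )


def switch_probabilities(
    positions_bp: np.ndarray, n_haplotypes: int, params: HMMParams
) -> np.ndarray:
    """Per-interval template-switch probability theta_m (length M - 1)."""
    d = np.diff(positions_bp.astype(float))
    rho = 4.0 * params.ne_scale * params.recombination_rate * d / n_haplotypes
    return 1.0 - np.exp(-rho)


def _apply_transition(mat: np.ndarray, theta: float) -> np.ndarray:
    """Apply the factorized pair transition T (x) T along the last two axes."""
    h = mat.shape[-1]
    a, b = 1.0 - theta, theta / h
    mat = a * mat + b * mat.sum(axis=-2, keepdims=True)
    mat = a * mat + b * mat.sum(axis=-1, keepdims=True)
    return mat


def _emissions(g_col: np.ndarray, dosage_hh: np.ndarray, etab: np.ndarray) -> np.ndarray:
    """Emission probabilities for a batch of individuals at one marker.

    ``g_col`` is (N,) observed dosage (MISSING allowed), ``dosage_hh`` the
    (H, H) state-implied dosage.  Returns (N, H, H).
    """
    obs_prob = np.vstack([np.ones(3), etab.T])  # rows indexed by obs + 1
    return obs_prob[g_col + 1][:, dosage_hh]


def _fb_genotype_posteriors(
    g: np.ndarray,
    ref: np.ndarray,
    theta: np.ndarray,
    etab: np.ndarray,
) -> np.ndarray:
    """Exact forward-backward over the diploid state pair for one chromosome.

    ``g`` is (N, M) observed dosage, ``ref`` is (H, M).  Returns (N, M, 3)
    posterior probabilities of the state-implied dosage class, which is the
    posterior genotype distribution.
    """
    n, m = g.shape
    h = ref.shape[0]
    dosages = [ref[:, j][:, None] + ref[:, j][None, :] for j in range(m)]
    onehot = [np.eye(3)[d.ravel()] for d in dosages]

    # forward pass (scaled), alphas stored per marker
    alphas = np.empty((m, n, h, h))
    alpha = np.full((n, h, h), 1.0 / (h * h)) * _emissions(g[:, 0], dosages[0], etab)
    alpha /= alpha.sum(axis=(1, 2), keepdims=True)
    alphas[0] = alpha
    for j in range(1, m):
        alpha = _apply_transition(alpha, theta[j - 1])
        alpha *= _emissions(g[:, j], dosages[j], etab)
        alpha /= alpha.sum(axis=(1, 2), keepdims=True)
        alphas[j] = alpha

    # backward pass, combining into dosage-class posteriors on the fly
    post = np.empty((n, m, 3))
    beta = np.ones((n, h, h))
    for j in range(m - 1, -1, -1):
        ab = alphas[j] * beta
        ab /= ab.sum(axis=(1, 2), keepdims=True)
        post[:, j, :] = ab.reshape(n, -1) @ onehot[j]
        if j > 0:
            beta = _apply_transition(
                beta * _emissions(g[:, j], dosages[j], etab), theta[j - 1]
            )
            beta /= beta.sum(axis=(1, 2), keepdims=True)
    return post


def impute(
    genotypes_masked: GenotypeMatrix,
    reference: HaplotypePanel,
    params: HMMParams | None = None,
    batch_size: int | None = None,
) -> PosteriorGenotypeSet:
    """Impute every marker of every individual from a phased reference panel.

    Runs the exact diploid forward-backward per chromosome and returns
    posterior genotype triples plus expected B-allele dosage at all markers,
    typed and masked alike.  Deterministic given its inputs.
    """
    params = params or HMMParams()
    mk, rk = genotypes_masked.markers, reference.markers
    if mk.n_markers != rk.n_markers or not np.array_equal(mk.position_bp, rk.position_bp):
        raise ValueError("genotypes and reference must share one marker map")
    if reference.n_haplotypes < 2:
        raise ValueError("reference panel must contain at least 2 haplotypes")

    h = reference.n_haplotypes
    etab = emission_table(params.error_rate)
    n = genotypes_masked.n_individuals
    probs = np.empty((n, mk.n_markers, 3))
    if batch_size is None:
        # keep stored forward variables near ~3e7 doubles
        per_ind = max(mk.n_markers * h * h, 1)
        batch_size = max(1, int(3e7 // per_ind))
    for c in mk.chromosomes():
        cols = np.flatnonzero(mk.chromosome == c)
        theta = switch_probabilities(mk.position_bp[cols], h, params)
        ref = reference.alleles[:, cols]
        for lo in range(0, n, batch_size):
            sl = slice(lo, min(lo + batch_size, n))
            g = genotypes_masked.dosage[sl][:, cols]
            probs[sl][:, cols, :] = _fb_genotype_posteriors(g, ref, theta, etab)
    # guard tiny negative round-off and renormalize
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=2, keepdims=True)
    return PosteriorGenotypeSet(probs, mk, list(genotypes_masked.individual_ids))


# ---------------------------------------------------------------------------
# Sampling decodings (used by the phasing loop)
# ---------------------------------------------------------------------------

def _forward_pass(
    g: np.ndarray,
    ref: np.ndarray,
    theta: np.ndarray,
    etab: np.ndarray,
) -> np.ndarray:
    """Scaled forward variables (M, H, H) for one individual, one chromosome."""
    m = len(g)
    h = ref.shape[0]
    obs_prob = np.vstack([np.ones(3), etab.T])
    dos = ref.T[:, :, None] + ref.T[:, None, :]  # (M, H, H) state dosages
    emis = obs_prob[g + 1][np.arange(m)[:, None, None], dos]
    alphas = np.empty((m, h, h))
    alpha = np.full((h, h), 1.0 / (h * h)) * emis[0]
    alpha /= alpha.sum()
    alphas[0] = alpha
    for j in range(1, m):
        alpha = _apply_transition(alpha[None], theta[j - 1])[0]
        alpha *= emis[j]
        alpha /= alpha.sum()
        alphas[j] = alpha
    return alphas


def _draw_paths(
    alphas: np.ndarray,
    theta: np.ndarray,
    rng: np.random.Generator,
    n_samples: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backward-sample ``n_samples`` state paths from stored forward variables.

    Returns (k paths, l paths, posterior log-probabilities), each with the
    sample index first.  The log-probabilities share the evidence constant of
    the individual, so they rank the sampled decodings by joint probability.
    """
    m, h, _ = alphas.shape
    s = n_samples
    ks = np.empty((s, m), dtype=np.intp)
    ls = np.empty((s, m), dtype=np.intp)
    flat = alphas[m - 1].ravel()
    cs = np.cumsum(flat)
    picks = np.searchsorted(cs, rng.random(s) * cs[-1])
    ks[:, m - 1], ls[:, m - 1] = np.divmod(picks, h)
    logp = np.log(flat[picks] / cs[-1])
    rows = np.arange(s)
    for j in range(m - 2, -1, -1):
        a, b = 1.0 - theta[j], theta[j] / h
        tk = np.full((s, h), b)
        tk[rows, ks[:, j + 1]] += a
        tl = np.full((s, h), b)
        tl[rows, ls[:, j + 1]] += a
        w = alphas[j][None, :, :] * tk[:, :, None] * tl[:, None, :]
        flat = w.reshape(s, -1)
        cs = np.cumsum(flat, axis=1)
        tot = cs[:, -1]
        picks = np.array(
            [np.searchsorted(cs[i], rng.random() * tot[i]) for i in range(s)]
        )
        picks = np.minimum(picks, h * h - 1)
        ks[:, j], ls[:, j] = np.divmod(picks, h)
        logp += np.log(flat[rows, picks] / tot)
    return ks, ls, logp


def phase_unrelated(
    genotypes: GenotypeMatrix,
    seed_panel: HaplotypePanel | None = None,
    params: HMMParams | None = None,
) -> HaplotypePanel:
    """Iteratively phase a set of unrelated individuals.

    Phase is initialized randomly consistent with each genotype; each round
    re-decodes every individual against the current haplotypes of all others
    (plus an optional fixed ``seed_panel``), drawing
    ``n_samples_per_iteration`` sampled decodings and keeping the most
    probable.  The output haplotype pair of every individual sums to its
    genotype at all called markers.  Deterministic given ``params.seed``.
    """
    params = params or HMMParams()
    if genotypes.n_individuals < 2 and seed_panel is None:
        raise ValueError("need at least 2 individuals or a seed panel")
    if seed_panel is not None and not np.array_equal(
        seed_panel.markers.position_bp, genotypes.markers.position_bp
    ):
        raise ValueError("seed panel must share the genotype marker map")

    rng = np.random.default_rng(params.seed)
    n, m = genotypes.n_individuals, genotypes.n_markers
    g = genotypes.dosage
    called = g != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(
            called.sum(axis=0) > 0,
            np.where(called, g, 0).sum(axis=0) / (2.0 * np.maximum(called.sum(axis=0), 1)),
            0.5,
        )

    haps = np.empty((2 * n, m), dtype=np.int8)
    for j in range(n):
        hom = g[j] != 1
        base = np.where(g[j] == 2, 1, 0).astype(np.int8)
        miss = ~called[j]
        base[miss] = 0
        flip = rng.integers(0, 2, size=m).astype(np.int8)
        h0 = np.where(hom, base, flip)
        h1 = np.where(hom, base, 1 - flip)
        fill0 = (rng.random(m) < freq).astype(np.int8)
        fill1 = (rng.random(m) < freq).astype(np.int8)
        h0 = np.where(miss, fill0, h0)
        h1 = np.where(miss, fill1, h1)
        haps[2 * j], haps[2 * j + 1] = h0, h1

    etab = emission_table(params.error_rate)
    mk = genotypes.markers
    chrom_cols = [np.flatnonzero(mk.chromosome == c) for c in mk.chromosomes()]
    seed_alleles = seed_panel.alleles if seed_panel is not None else None

    for _ in range(params.n_iterations):
        for j in range(n):
            others = np.concatenate(
                [haps[: 2 * j], haps[2 * j + 2 :]]
                + ([seed_alleles] if seed_alleles is not None else [])
            )
            if (
                params.max_reference_haplotypes is not None
                and others.shape[0] > params.max_reference_haplotypes
            ):
                # condition on the most similar haplotypes (surrogate relatives):
                # count hard conflicts of each candidate against the genotype's
                # homozygous sites
                hom0 = (g[j] == 0) & called[j]
                hom2 = (g[j] == 2) & called[j]
                conflicts = (others[:, hom0] == 1).sum(axis=1) + (
                    others[:, hom2] == 0
                ).sum(axis=1)
                rows = np.argsort(conflicts, kind="stable")[
                    : params.max_reference_haplotypes
                ]
                others = others[rows]
            h = others.shape[0]
            for cols in chrom_cols:
                theta = switch_probabilities(mk.position_bp[cols], h, params)
                ref = others[:, cols]
                gj = g[j][cols]
                alphas = _forward_pass(gj, ref, theta, etab)
                kss, lss, scores = _draw_paths(
                    alphas, theta, rng, params.n_samples_per_iteration
                )
                best = int(np.argmax(scores))
                ks, ls = kss[best], lss[best]
                a0 = ref[ks, np.arange(len(cols))]
                a1 = ref[ls, np.arange(len(cols))]
                het = gj == 1
                hom = (gj == 0) | (gj == 2)
                new0 = np.where(gj == 2, 1, 0).astype(np.int8)
                new1 = new0.copy()
                informative = a0 != a1
                orient = np.where(informative, a0, rng.integers(0, 2, size=len(cols))).astype(np.int8)
                new0 = np.where(het, orient, new0)
                new1 = np.where(het, 1 - orient, new1)
                miss = gj == MISSING
                new0 = np.where(miss, a0, new0)
                new1 = np.where(miss, a1, new1)
                new0 = np.where(hom, np.where(gj == 2, 1, 0), new0).astype(np.int8)
                new1 = np.where(hom, np.where(gj == 2, 1, 0), new1).astype(np.int8)
                haps[2 * j][cols] = new0
                haps[2 * j + 1][cols] = new1

    labels = [f"{sid}_h{k}" for sid in genotypes.individual_ids for k in (0, 1)]
    return HaplotypePanel(haps, mk, labels, provenance="random")


# ---------------------------------------------------------------------------
# Trio phasing by Mendelian inheritance
# ---------------------------------------------------------------------------

@dataclass
class TrioPhaseResult:
    """Four parental haplotypes (transmitted first), ambiguity and error masks.

    Haplotype entries are -1 where the phase could not be resolved (triple
    heterozygotes, missing data or Mendelian inconsistencies).
    """

    sire_haplotypes: np.ndarray  # (2, M): transmitted, untransmitted
    dam_haplotypes: np.ndarray
    sire_ambiguous: np.ndarray
    dam_ambiguous: np.ndarray
    mendel_error: np.ndarray
    n_errors: int


def phase_trio(
    sire: np.ndarray,
    dam: np.ndarray,
    offspring: np.ndarray,
    max_error_fraction: float = 0.05,
) -> TrioPhaseResult:
    """Resolve parental phase wherever Mendelian rules determine transmission.

    At each marker the transmitted allele of a parent is determined whenever
    the offspring genotype together with the other parent pins it down (any
    member homozygous, or the offspring homozygous).  Markers where all three
    members are heterozygous stay ambiguous.  Mendelian inconsistencies are
    flagged and set missing; a trio whose inconsistency fraction exceeds
    ``max_error_fraction`` is rejected.
    """
    s = np.asarray(sire, dtype=np.int8)
    d = np.asarray(dam, dtype=np.int8)
    o = np.asarray(offspring, dtype=np.int8)
    m = len(s)
    all_called = (s != MISSING) & (d != MISSING) & (o != MISSING)

    # contribution bounds: min transmitted allele, max transmitted allele
    smin, smax = (s == 2).astype(np.int8), (s != 0).astype(np.int8)
    dmin, dmax = (d == 2).astype(np.int8), (d != 0).astype(np.int8)
    error = all_called & ((o < smin + dmin) | (o > smax + dmax))
    ok = all_called & ~error

    # transmitted alleles where determined
    t_s = np.full(m, MISSING, dtype=np.int8)
    t_d = np.full(m, MISSING, dtype=np.int8)
    s_hom, d_hom = s != 1, d != 1
    t_s[ok & s_hom] = (s[ok & s_hom] == 2).astype(np.int8)
    t_d[ok & d_hom] = (d[ok & d_hom] == 2).astype(np.int8)
    # het parent: transmitted allele = o - other side's transmission when that
    # is known, else pinned down by a homozygous offspring
    known_d = t_d != MISSING
    case1 = ok & ~s_hom & known_d
    t_s[case1] = np.clip(o[case1] - t_d[case1], 0, 1)
    case2 = ok & ~s_hom & ~known_d & (o != 1)
    t_s[case2] = (o[case2] == 2).astype(np.int8)
    known_s = t_s != MISSING
    case3 = ok & ~d_hom & known_s
    t_d[case3] = np.clip(o[case3] - t_s[case3], 0, 1)
    case4 = ok & ~d_hom & ~known_s & (o != 1)
    t_d[case4] = (o[case4] == 2).astype(np.int8)

    # parent genotypes called but trio info absent (not inconsistent):
    # homozygous parents still phase trivially
    solo_s = (s != MISSING) & ~all_called & (s != 1)
    t_s[solo_s] = (s[solo_s] == 2).astype(np.int8)
    solo_d = (d != MISSING) & ~all_called & (d != 1)
    t_d[solo_d] = (d[solo_d] == 2).astype(np.int8)

    def pair(parent: np.ndarray, trans: np.ndarray) -> np.ndarray:
        out = np.full((2, m), MISSING, dtype=np.int8)
        known = trans != MISSING
        out[0, known] = trans[known]
        out[1, known] = np.where(
            parent[known] == 1, 1 - trans[known], trans[known]
        )
        return out

    sire_h = pair(s, t_s)
    dam_h = pair(d, t_d)
    sire_amb = (s == 1) & (t_s == MISSING) & ~error
    dam_amb = (d == 1) & (t_d == MISSING) & ~error
    n_err = int(error.sum())
    n_called = int(all_called.sum())
    if n_called and n_err / n_called > max_error_fraction:
        raise ValueError(
            f"trio rejected: {n_err} Mendelian inconsistencies in {n_called} "
            f"fully-called markers"
        )
    return TrioPhaseResult(sire_h, dam_h, sire_amb, dam_amb, error, n_err)


# ---------------------------------------------------------------------------
# Haploid chain utilities (scaffold refinement, switch-error scoring)
# ---------------------------------------------------------------------------

def haploid_allele_posterior(
    obs_hap: np.ndarray,
    reference: HaplotypePanel,
    params: HMMParams | None = None,
) -> np.ndarray:
    """Posterior P(allele = 1) along one haploid Li-Stephens chain.

    ``obs_hap`` is a single haplotype with -1 at unobserved positions; the
    chain copies from ``reference`` with the usual switch and error model.
    Used to resolve ambiguous sites of a Mendelian scaffold.
    """
    params = params or HMMParams()
    ref = reference.alleles
    h, m = ref.shape
    eps = params.error_rate
    theta = switch_probabilities(reference.markers.position_bp, h, params)

    def emis(j: int) -> np.ndarray:
        if obs_hap[j] == MISSING:
            return np.ones(h)
        return np.where(ref[:, j] == obs_hap[j], 1 - eps, eps)

    alphas = np.empty((m, h))
    alpha = np.full(h, 1.0 / h) * emis(0)
    alpha /= alpha.sum()
    alphas[0] = alpha
    for j in range(1, m):
        a, b = 1.0 - theta[j - 1], theta[j - 1] / h
        alpha = a * alpha + b * alpha.sum()
        alpha *= emis(j)
        alpha /= alpha.sum()
        alphas[j] = alpha
    beta = np.ones(h)
    out = np.empty(m)
    for j in range(m - 1, -1, -1):
        post = alphas[j] * beta
        post /= post.sum()
        out[j] = post @ (ref[:, j] == 1)
        if j > 0:
            a, b = 1.0 - theta[j - 1], theta[j - 1] / h
            v = beta * emis(j)
            beta = a * v + b * v.sum()
            beta /= beta.sum()
    return out


def resolve_scaffold(
    hap_pair: np.ndarray,
    genotype: np.ndarray,
    reference: HaplotypePanel,
    params: HMMParams | None = None,
) -> np.ndarray:
    """Fill the unresolved sites of a partially phased haplotype pair.

    Ambiguous heterozygote orientations are decided by comparing the haploid
    chain posteriors of the two scaffold haplotypes against the reference;
    missing-genotype sites take each chain's own posterior call.
    """
    pair = np.asarray(hap_pair, dtype=np.int8).copy()
    g = np.asarray(genotype, dtype=np.int8)
    unresolved = pair[0] == MISSING
    if not unresolved.any():
        return pair
    p0 = haploid_allele_posterior(pair[0], reference, params)
    p1 = haploid_allele_posterior(pair[1], reference, params)
    het = unresolved & (g == 1)
    # orientation (1, 0) iff chain 0 favors allele 1 more strongly than chain 1
    take10 = p0 * (1 - p1) >= (1 - p0) * p1
    pair[0, het] = np.where(take10[het], 1, 0)
    pair[1, het] = 1 - pair[0, het]
    hom = unresolved & ((g == 0) | (g == 2))
    pair[0, hom] = (g[hom] == 2).astype(np.int8)
    pair[1, hom] = pair[0, hom]
    miss = unresolved & (g == MISSING)
    pair[0, miss] = (p0[miss] > 0.5).astype(np.int8)
    pair[1, miss] = (p1[miss] > 0.5).astype(np.int8)
    return pair


def switch_error_rate(est_pair: np.ndarray, true_pair: np.ndarray) -> float:
    """Fraction of adjacent heterozygote pairs with inconsistent orientation.

    Invariant to which haplotype of a pair is listed first.  Returns NaN if
    fewer than two heterozygous sites are comparable.
    """
    est = np.asarray(est_pair)
    tru = np.asarray(true_pair)
    het = (est[0] != est[1]) & (tru[0] != tru[1])
    idx = np.flatnonzero(het)
    if len(idx) < 2:
        return float("nan")
    orient = (est[0, idx] == tru[0, idx]).astype(int)
    switches = int(np.abs(np.diff(orient)).sum())
    return switches / (len(idx) - 1)
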