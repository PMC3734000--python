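"""Independent naive-loop oracles used to validate the vectorized library code.

Everything here is deliberately written as plain Python loops over explicit
definitions, so that agreement with the package is a genuine cross-check and
not a reimplementation of the same numpy expressions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Accuracy metrics
# ---------------------------------------------------------------------------

def ia_naive(truth: np.ndarray, ghat: np.ndarray) -> float:
    """Proportion of correctly imputed alleles, plain double loop."""
    num = 0.0
    n_total = 0
    n_ind, n_snp = truth.shape
    for i in range(n_snp):
        for j in range(n_ind):
            if truth[j, i] == MISSING:
                continue
            num += abs(truth[j, i] - ghat[j, i])
            n_total += 1
    return 1.0 - num / (2.0 * n_total)


def ia_by_snp_naive(truth: np.ndarray, ghat: np.ndarray) -> list:
    out = []
    n_ind, n_snp = truth.shape
    for i in range(n_snp):
        num, n = 0.0, 0
        for j in range(n_ind):
            if truth[j, i] == MISSING:
                continue
            num += abs(truth[j, i] - ghat[j, i])
            n += 1
        out.append(float("nan") if n == 0 else 1.0 - num / (2.0 * n))
    return out


def ia_freq_naive(ref_triples: np.ndarray, val_triples: np.ndarray) -> list:
    """Per-SNP dot products of reference and predicted genotype frequencies."""
    out = []
    for i in range(ref_triples.shape[0]):
        s = 0.0
        for g in range(3):
            s += ref_triples[i, g] * val_triples[i, g]
        out.append(s)
    return out


def ia_maf_naive(ia: float, ia_freq: float) -> float:
    return (ia - ia_freq) / (1.0 - ia_freq)


def pearson_r2_naive(x: list, y: list) -> float:
    """Textbook Pearson correlation squared."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return float("nan")
    return (sxy / math.sqrt(sxx * syy)) ** 2


def weighted_mean_naive(values: list, weights: list) -> float:
    num = den = 0.0
    for v, w in zip(values, weights):
        if math.isnan(v):
            continue
        num += v * w
        den += w
    return num / den


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def r2_contingency_naive(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """r^2 from an explicit 2x2 haplotype contingency table."""
    n = len(col_i)
    n11 = sum(1 for a, b in zip(col_i, col_j) if a == 1 and b == 1)
    p_ab = n11 / n
    p_a = sum(col_i) / n
    p_b = sum(col_j) / n
    if p_a in (0, 1) or p_b in (0, 1):
        return float("nan")
    d = p_ab - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


# ---------------------------------------------------------------------------
# Set cover
# ---------------------------------------------------------------------------

def minimal_cover_bruteforce(cover_sets: list) -> int:
    """Size of a minimal cover by exhaustive subset enumeration (<= ~12 SNP)."""
    m = len(cover_sets)
    universe = set(range(m))
    for size in range(1, m + 1):
        for combo in itertools.combinations(range(m), size):
            covered = set()
            for c in combo:
                covered |= cover_sets[c]
            if covered >= universe:
                return size
    return m


# ---------------------------------------------------------------------------
# Diploid HMM: exhaustive path enumeration
# ---------------------------------------------------------------------------

def hmm_posteriors_enumeration(
    g: np.ndarray,
    ref: np.ndarray,
    theta: np.ndarray,
    eps: float,
) -> np.ndarray:
    """Posterior dosage-class probabilities by brute force over all state paths.

    Enumerates every sequence of ordered haplotype pairs, accumulating the
    joint probability of path and observations, then marginalizes.  Feasible
    for (H^2)^M up to a few million paths.
    """
    h, m = ref.shape
    s = h * h
    # per-marker emission vector over states and the state dosage
    dos = np.empty((m, s), dtype=int)
    emis = np.empty((m, s))
    for j in range(m):
        for k in range(h):
            for l in range(h):
                d = ref[k, j] + ref[l, j]
                dos[j, k * h + l] = d
                if g[j] == MISSING:
                    emis[j, k * h + l] = 1.0
                else:
                    emis[j, k * h + l] = _emit_prob(g[j], d, eps)
    # pairwise haploid transition values
    def t_hap(a: int, b: int, th: float) -> float:
        return (1.0 - th) + th / h if a == b else th / h

    trans = []
    for j in range(m - 1):
        tm = np.empty((s, s))
        for prev in range(s):
            pk, pl = divmod(prev, h)
            for nxt in range(s):
                nk, nl = divmod(nxt, h)
                tm[prev, nxt] = t_hap(pk, nk, theta[j]) * t_hap(pl, nl, theta[j])
        trans.append(tm)

    # enumerate all paths, keeping the probability of each full prefix
    probs = (np.full(s, 1.0 / s) * emis[0]).astype(float)  # shape s^1
    for j in range(1, m):
        last = np.arange(len(probs)) % s  # final state digit of each prefix
        expanded = probs[:, None] * trans[j - 1][last, :] * emis[j][None, :]
        probs = expanded.ravel()
    total = probs.sum()
    post = np.zeros((m, 3))
    n_paths = len(probs)
    idx = np.arange(n_paths)
    for j in range(m):
        digit = (idx // (s ** (m - 1 - j))) % s
        for d in range(3):
            sel = dos[j][digit] == d
            post[j, d] = probs[sel].sum() / total
    return post


def _emit_prob(obs: int, d: int, eps: float) -> float:
    """P(observed dosage | state dosage) with independent per-allele error."""
    table = {
        0: [(1 - eps) ** 2, 2 * eps * (1 - eps), eps**2],
        1: [eps * (1 - eps), (1 - eps) ** 2 + eps**2, eps * (1 - eps)],
        2: [eps**2, 2 * eps * (1 - eps), (1 - eps) ** 2],
    }
    return table[d][obs]


# ---------------------------------------------------------------------------
# HPD
# ---------------------------------------------------------------------------

def hpd_naive(values: list, mass: float) -> tuple:
    v = sorted(values)
    n = len(v)
    k = math.ceil(mass * n)
    best = None
    for start in range(n - k + 1):
        width = v[start + k - 1] - v[start]
        if best is None or width < best[0]:
            best = (width, v[start], v[start + k - 1])
    return best[1], best[2]
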