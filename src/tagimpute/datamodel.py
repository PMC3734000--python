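"""Core domain containers for haplotype panels, genotype matrices and tagSNP sets.

Conventions used throughout the package:

* Physical positions are 1-based base pairs (as in VCF); all in-memory column
  indices are 0-based, half-open.
* Allele B is the counted allele: a genotype dosage is the number of copies
  of allele B (0, 1 or 2).  The A/B assignment comes from input order
  (REF = A, ALT = B), *not* from frequency, so the minor allele frequency is
  always computed, never assumed.
* Missing genotypes are encoded by the sentinel :data:`MISSING` (= -1), which
  is distinct from every valid dosage.  Arithmetic never silently treats a
  missing entry as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype dosage.  Stored in int8 matrices.
MISSING: int = -1


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every marker (or every animal)."""


@dataclass(frozen=True)
class MarkerMap:
    """Per-SNP map: identifier, chromosome, 1-based physical position, alleles.

    Positions must be strictly increasing within each chromosome, marker ids
    unique, and the two allele labels distinct at every marker.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        mid = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        aa = np.asarray(self.allele_a, dtype=object)
        ab = np.asarray(self.allele_b, dtype=object)
        n = len(mid)
        if not (len(chrom) == len(pos) == len(aa) == len(ab) == n):
            raise ValueError("MarkerMap fields must have equal length")
        if len(set(mid)) != n:
            raise ValueError("marker_id values must be unique")
        if np.any(aa == ab):
            raise ValueError("allele_a must differ from allele_b at every marker")
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)
        object.__setattr__(self, "allele_a", aa)
        object.__setattr__(self, "allele_b", ab)

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        return list(pd.unique(self.chromosome))

    def subset(self, indices: Sequence[int]) -> "MarkerMap":
        idx = np.asarray(indices, dtype=np.intp)
        return MarkerMap(
            self.marker_id[idx],
            self.chromosome[idx],
            self.position_bp[idx],
            self.allele_a[idx],
            self.allele_b[idx],
        )

    def scaled_position(self) -> np.ndarray:
        """Per-chromosome scaled location (pos - min) / (max - min), in [0, 1].

        A chromosome with a single marker maps to 0.5.
        """
        out = np.empty(self.n_markers, dtype=float)
        for c in self.chromosomes():
            m = self.chromosome == c
            p = self.position_bp[m].astype(float)
            span = p.max() - p.min()
            out[m] = 0.5 if span == 0 else (p - p.min()) / span
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
            }
        )

    @staticmethod
    def from_positions(
        positions: Iterable[int],
        chromosome: str = "1",
        prefix: str = "snp",
    ) -> "MarkerMap":
        """Convenience constructor for a single-chromosome map with A/B alleles."""
        pos = np.asarray(list(positions), dtype=np.int64)
        n = len(pos)
        return MarkerMap(
            np.array([f"{prefix}{i}" for i in range(n)], dtype=object),
            np.array([chromosome] * n, dtype=object),
            pos,
            np.array(["A"] * n, dtype=object),
            np.array(["B"] * n, dtype=object),
        )


@dataclass
class HaplotypePanel:
    """Phased haplotype x marker matrix with entries in {0, 1}.

    Reference panels are fully phased: no missing entries are allowed.  Rows
    come in consecutive pairs (2j, 2j+1) when the haplotypes belong to diploid
    individuals.
    """

    alleles: np.ndarray
    markers: MarkerMap
    haplotype_labels: list = field(default_factory=list)
    provenance: str = "simulated"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.int8))
        if a.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype x marker matrix")
        if a.shape[1] != self.markers.n_markers:
            raise ValueError("alleles column count must match the marker map")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0 or 1 (no missing entries)")
        if not self.haplotype_labels:
            self.haplotype_labels = [f"hap{i}" for i in range(a.shape[0])]
        if len(self.haplotype_labels) != a.shape[0]:
            raise ValueError("haplotype_labels length must match row count")
        self.alleles = a

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def subset_markers(self, indices: Sequence[int]) -> "HaplotypePanel":
        idx = np.asarray(indices, dtype=np.intp)
        return HaplotypePanel(
            self.alleles[:, idx],
            self.markers.subset(idx),
            list(self.haplotype_labels),
            self.provenance,
            dict(self.metadata),
        )

    def subset_haplotypes(self, indices: Sequence[int]) -> "HaplotypePanel":
        idx = np.asarray(indices, dtype=np.intp)
        meta = dict(self.metadata)
        if "generation" in meta:
            meta["generation"] = np.asarray(meta["generation"])[idx]
        return HaplotypePanel(
            self.alleles[idx],
            self.markers,
            [self.haplotype_labels[i] for i in idx],
            self.provenance,
            meta,
        )

    def to_genotypes(self, individual_ids: Sequence[str] | None = None) -> "GenotypeMatrix":
        """Collapse consecutive haplotype pairs into unphased diploid dosages."""
        if self.n_haplotypes % 2:
            raise ValueError("panel must have an even number of haplotypes")
        dosage = (self.alleles[0::2] + self.alleles[1::2]).astype(np.int8)
        n = dosage.shape[0]
        ids = list(individual_ids) if individual_ids is not None else [f"ind{i}" for i in range(n)]
        return GenotypeMatrix(dosage, self.markers, ids)


@dataclass
class GenotypeMatrix:
    """Unphased dosage matrix: individuals x markers, entries in {0, 1, 2, MISSING}."""

    dosage: np.ndarray
    markers: MarkerMap
    individual_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.ascontiguousarray(np.asarray(self.dosage, dtype=np.int8))
        if d.ndim != 2:
            raise ValueError("dosage must be a 2-D individual x marker matrix")
        if d.shape[1] != self.markers.n_markers:
            raise ValueError("dosage column count must match the marker map")
        if not np.isin(d, (0, 1, 2, MISSING)).all():
            raise ValueError("dosage entries must be 0, 1, 2 or MISSING")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(d.shape[0])]
        if len(self.individual_ids) != d.shape[0]:
            raise ValueError("individual_ids length must match row count")
        self.dosage = d

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of called (non-missing) entries."""
        return self.dosage != MISSING

    def calls_per_snp(self) -> np.ndarray:
        """N_i: number of individuals with a called genotype at each SNP."""
        return self.called().sum(axis=0)

    def calls_per_individual(self) -> np.ndarray:
        """M_j: number of called markers for each individual."""
        return self.called().sum(axis=1)

    def subset(
        self,
        individuals: Sequence[int] | None = None,
        markers: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        ii = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals, dtype=np.intp)
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers, dtype=np.intp)
        return GenotypeMatrix(
            self.dosage[np.ix_(ii, mi)],
            self.markers.subset(mi),
            [self.individual_ids[i] for i in ii],
        )


@dataclass
class PosteriorGenotypeSet:
    """Imputer output: per-genotype posterior triples and expected B-allele dosage.

    ``probs[n, m]`` holds (P(AA), P(AB), P(BB)); the expected dosage is their
    mean 0*P(AA) + 1*P(AB) + 2*P(BB), always within [0, 2].
    """

    probs: np.ndarray
    markers: MarkerMap
    individual_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("probs must have shape (individuals, markers, 3)")
        if p.shape[1] != self.markers.n_markers:
            raise ValueError("probs marker dimension must match the marker map")
        if np.any(p < -1e-12):
            raise ValueError("posterior probabilities must be non-negative")
        if np.max(np.abs(p.sum(axis=2) - 1.0)) > 1e-9:
            raise ValueError("posterior triples must sum to 1 within 1e-9")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(p.shape[0])]
        self.probs = p

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def n_markers(self) -> int:
        return self.probs.shape[1]

    @property
    def dosage_expected(self) -> np.ndarray:
        """Posterior expected allelic dosage of the B allele."""
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]

    def hard_calls(self) -> GenotypeMatrix:
        """Most likely genotype per entry (argmax of the posterior triple)."""
        return GenotypeMatrix(
            np.argmax(self.probs, axis=2).astype(np.int8),
            self.markers,
            list(self.individual_ids),
        )


@dataclass
class TagSNPSet:
    """A selected set of tagSNP: column indices into a marker map plus provenance."""

    marker_indices: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    markers: MarkerMap | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.marker_indices, dtype=np.intp)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("tag indices must be unique")
        if self.markers is not None:
            if idx.size and (idx.min() < 0 or idx.max() >= self.markers.n_markers):
                raise ValueError("tag index out of range for the marker map")
            # sort by (chromosome appearance order, position)
            order = np.lexsort(
                (
                    self.markers.position_bp[idx],
                    pd.Categorical(
                        self.markers.chromosome[idx],
                        categories=self.markers.chromosomes(),
                    ).codes,
                )
            )
            idx = idx[order]
        else:
            idx = np.sort(idx)
        self.marker_indices = idx

    def __len__(self) -> int:
        return len(self.marker_indices)


# ---------------------------------------------------------------------------
# Frequency machinery shared by every stage
# ---------------------------------------------------------------------------

def compute_maf(obj: HaplotypePanel | GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency in [0, 0.5], over called entries only.

    A marker with no called entry is flagged NaN.
    """
    if isinstance(obj, HaplotypePanel):
        freq_b = obj.alleles.mean(axis=0)
    elif isinstance(obj, GenotypeMatrix):
        called = obj.called()
        n = called.sum(axis=0)
        b = np.where(called, obj.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_b = np.where(n > 0, b / (2.0 * n), np.nan)
    else:
        raise TypeError(f"unsupported type {type(obj).__name__}")
    return np.minimum(freq_b, 1.0 - freq_b)


def genotype_frequencies(
    obj: HaplotypePanel | GenotypeMatrix | PosteriorGenotypeSet,
    per_snp: bool = True,
) -> np.ndarray:
    """Observed (or predicted) genotype frequency triples (p(AA), p(AB), p(BB)).

    For a :class:`HaplotypePanel` consecutive haplotype pairs form diploid
    genotypes; for a :class:`PosteriorGenotypeSet` the predicted frequencies
    are the per-SNP means of the posterior triples.  With ``per_snp=False``
    the per-SNP triples are averaged (equal weight per SNP).
    """
    if isinstance(obj, PosteriorGenotypeSet):
        trip = obj.probs.mean(axis=0)
    else:
        if isinstance(obj, HaplotypePanel):
            gm = obj.to_genotypes()
        else:
            gm = obj
        called = gm.called()
        n = called.sum(axis=0).astype(float)
        trip = np.empty((gm.n_markers, 3))
        for g in (0, 1, 2):
            with np.errstate(invalid="ignore", divide="ignore"):
                trip[:, g] = np.where(n > 0, ((gm.dosage == g) & called).sum(axis=0) / n, np.nan)
    return trip if per_snp else np.nanmean(trip, axis=0)


# ---------------------------------------------------------------------------
# QC and masking
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_individuals_in: int
    n_markers_in: int
    n_individuals_dropped_call_rate: int
    n_markers_dropped_maf: int
    n_markers_dropped_call_rate: int
    kept_individuals: np.ndarray
    kept_markers: np.ndarray


def apply_qc(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_snp_min: float = 0.9,
    call_rate_animal_min: float = 0.9,
) -> tuple[GenotypeMatrix, QCReport]:
    """Standard chip QC: animal call-rate filter first, then per-SNP filters.

    Keeps animals with call rate strictly above ``call_rate_animal_min``, then
    keeps SNP with MAF strictly above ``maf_min`` and call rate strictly above
    ``call_rate_snp_min`` (a zero threshold disables the corresponding rule).
    """
    for t in (maf_min, call_rate_snp_min, call_rate_animal_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    n, m = genotypes.n_individuals, genotypes.n_markers
    cr_animal = genotypes.calls_per_individual() / max(m, 1)
    keep_ind = cr_animal > call_rate_animal_min if call_rate_animal_min > 0 else np.ones(n, bool)
    sub = genotypes.subset(individuals=np.flatnonzero(keep_ind))
    if sub.n_individuals == 0:
        raise EmptyResultError("all animals removed by the call-rate filter")

    cr_snp = sub.calls_per_snp() / max(sub.n_individuals, 1)
    maf = compute_maf(sub)
    fail_cr = cr_snp <= call_rate_snp_min if call_rate_snp_min > 0 else np.zeros(m, bool)
    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf > maf_min) if maf_min > 0 else np.isnan(maf)
    keep_snp = ~(fail_cr | fail_maf)
    out = sub.subset(markers=np.flatnonzero(keep_snp))
    report = QCReport(
        n_individuals_in=n,
        n_markers_in=m,
        n_individuals_dropped_call_rate=int((~keep_ind).sum()),
        n_markers_dropped_maf=int(fail_maf.sum()),
        n_markers_dropped_call_rate=int(fail_cr.sum()),
        kept_individuals=np.flatnonzero(keep_ind),
        kept_markers=np.flatnonzero(keep_snp),
    )
    if out.n_markers == 0:
        raise EmptyResultError("all markers removed by QC")
    return out, report


def mask_to_tagsnp(genotypes: GenotypeMatrix, tags: TagSNPSet) -> GenotypeMatrix:
    """Set every non-tag column entirely to missing; tag columns are untouched.

    This is the masking step of an imputation experiment: the test set keeps
    only its tagSNP genotypes and everything else must be recovered by the
    imputer.  Masking is idempotent.
    """
    idx = tags.marker_indices
    if idx.size == 0:
        raise ValueError("empty tagSNP set: nothing to condition imputation on")
    if idx.min() < 0 or idx.max() >= genotypes.n_markers:
        raise ValueError("tag index out of range for this genotype matrix")
    out = genotypes.dosage.copy()
    mask = np.ones(genotypes.n_markers, dtype=bool)
    mask[idx] = False
    out[:, mask] = MISSING
    return GenotypeMatrix(out, genotypes.markers, list(genotypes.individual_ids))
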