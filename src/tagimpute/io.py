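"""Readers and writers for VCF 4.2, PLINK-style .map files and TSV matrices.

Phased objects are written with the ``|`` genotype separator, unphased with
``/``.  Only biallelic SNP records are accepted; ``./.`` maps to the missing
sentinel.  The secondary TSV matrix format has a header row of marker ids and
one labelled row per haplotype or individual, with missing genotypes written
as ``NA``.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .datamodel import (
    MISSING,
    GenotypeMatrix,
    HaplotypePanel,
    MarkerMap,
    PosteriorGenotypeSet,
)


def read_vcf(path: str, phased_required: bool = False) -> HaplotypePanel | GenotypeMatrix:
    """Read a biallelic-SNP VCF into a haplotype panel or genotype matrix.

    A file in which every genotype is phased yields a
    :class:`HaplotypePanel` with two haplotypes per sample; otherwise a
    :class:`GenotypeMatrix` is returned with ``./.`` mapped to missing.
    Multiallelic records are rejected.
    """
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        mid, chrom, pos, aa, ab = [], [], [], [], []
        gts: list[list[tuple]] = []
        all_phased = True
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multiallelic or ALT-less record at {rec.chrom}:{rec.pos} "
                    f"(id={rec.id}) is not supported"
                )
            mid.append(rec.id if rec.id else f"{rec.chrom}_{rec.pos}")
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            aa.append(rec.ref)
            ab.append(rec.alts[0])
            row = []
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                phased = bool(call.phased)
                if gt is None or all(a is None for a in gt):
                    gt = (None, None)
                    phased = False
                if not phased:
                    all_phased = False
                    if phased_required and gt != (None, None):
                        raise ValueError(
                            f"unphased genotype for sample {s} at {rec.chrom}:{rec.pos} "
                            "but phased input was required"
                        )
                row.append(gt)
            gts.append(row)

    markers = MarkerMap(
        np.array(mid, dtype=object),
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(aa, dtype=object),
        np.array(ab, dtype=object),
    )
    m, n = len(mid), len(samples)
    if all_phased and n > 0 and m > 0:
        alleles = np.empty((2 * n, m), dtype=np.int8)
        for i in range(m):
            for j, gt in enumerate(gts[i]):
                if gt[0] is None or gt[1] is None:
                    raise ValueError("phased panels may not contain missing genotypes")
                alleles[2 * j, i] = gt[0]
                alleles[2 * j + 1, i] = gt[1]
        labels = [f"{s}_h{k}" for s in samples for k in (0, 1)]
        return HaplotypePanel(alleles, markers, labels, provenance="random")
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    for i in range(m):
        for j, gt in enumerate(gts[i]):
            if gt[0] is not None and gt[1] is not None:
                dosage[j, i] = gt[0] + gt[1]
    return GenotypeMatrix(dosage, markers, list(samples))


def _vcf_header(markers: MarkerMap, sample_ids: Sequence[str], posterior: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in markers.chromosomes():
        length = int(markers.position_bp[markers.chromosome == c].max()) + 1
        header.contigs.add(str(c), length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    if posterior:
        header.formats.add("GP", 3, "Float", "Posterior genotype probabilities (AA, AB, BB)")
        header.formats.add("DS", 1, "Float", "Posterior expected dosage of the B allele")
    for s in sample_ids:
        header.add_sample(str(s))
    return header


def write_vcf(obj: HaplotypePanel | GenotypeMatrix | PosteriorGenotypeSet, path: str) -> None:
    """Write a domain object as uncompressed VCF 4.2, one record per marker.

    Haplotype panels use phased ``|`` genotypes; genotype matrices use ``/``
    with missing entries as ``./.``.  Posterior sets are written with GT
    (most likely genotype), GP (posterior triple) and DS (expected dosage).
    """
    markers = obj.markers
    if isinstance(obj, HaplotypePanel):
        if obj.n_haplotypes % 2:
            raise ValueError("panel must pair haplotypes into diploid samples for VCF output")
        sample_ids = [f"sample{i}" for i in range(obj.n_haplotypes // 2)]
        header = _vcf_header(markers, sample_ids, posterior=False)
    elif isinstance(obj, PosteriorGenotypeSet):
        sample_ids = [str(s) for s in obj.individual_ids]
        header = _vcf_header(markers, sample_ids, posterior=True)
    else:
        sample_ids = [str(s) for s in obj.individual_ids]
        header = _vcf_header(markers, sample_ids, posterior=False)

    hard = obj.hard_calls().dosage if isinstance(obj, PosteriorGenotypeSet) else None
    with pysam.VariantFile(path, "w", header=header) as out:
        for i in range(markers.n_markers):
            rec = out.new_record(
                contig=str(markers.chromosome[i]),
                start=int(markers.position_bp[i]) - 1,
                stop=int(markers.position_bp[i]),
                alleles=(str(markers.allele_a[i]), str(markers.allele_b[i])),
                id=str(markers.marker_id[i]),
            )
            for j, s in enumerate(sample_ids):
                if isinstance(obj, HaplotypePanel):
                    rec.samples[s]["GT"] = (int(obj.alleles[2 * j, i]), int(obj.alleles[2 * j + 1, i]))
                    rec.samples[s].phased = True
                elif isinstance(obj, PosteriorGenotypeSet):
                    d = int(hard[j, i])
                    rec.samples[s]["GT"] = (0, 0) if d == 0 else ((0, 1) if d == 1 else (1, 1))
                    rec.samples[s]["GP"] = tuple(float(x) for x in obj.probs[j, i])
                    rec.samples[s]["DS"] = float(obj.dosage_expected[j, i])
                else:
                    d = int(obj.dosage[j, i])
                    if d == MISSING:
                        rec.samples[s]["GT"] = (None, None)
                    else:
                        rec.samples[s]["GT"] = (0, 0) if d == 0 else ((0, 1) if d == 1 else (1, 1))
                    rec.samples[s].phased = False
            out.write(rec)


def read_map(path: str) -> MarkerMap:
    """Read a PLINK-style .map file (chrom, id, cM ignored, bp position).

    Allele labels are not part of the format and default to A/B.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position_bp"],
        dtype={"chromosome": str, "marker_id": str},
    )
    n = len(df)
    return MarkerMap(
        df["marker_id"].to_numpy(dtype=object),
        df["chromosome"].to_numpy(dtype=object),
        df["position_bp"].to_numpy(dtype=np.int64),
        np.array(["A"] * n, dtype=object),
        np.array(["B"] * n, dtype=object),
    )


def write_matrix_tsv(obj: HaplotypePanel | GenotypeMatrix, path: str) -> None:
    """Write the secondary TSV matrix format (marker-id header, labelled rows)."""
    if isinstance(obj, HaplotypePanel):
        data = obj.alleles.astype(object)
        index = list(obj.haplotype_labels)
    else:
        data = obj.dosage.astype(object)
        data[obj.dosage == MISSING] = "NA"
        index = list(obj.individual_ids)
    df = pd.DataFrame(data, index=index, columns=list(obj.markers.marker_id))
    df.to_csv(path, sep="\t", index_label="row_id")


def read_matrix_tsv(path: str, markers: MarkerMap, phased: bool) -> HaplotypePanel | GenotypeMatrix:
    """Read the TSV matrix format back against a known marker map."""
    df = pd.read_csv(path, sep="\t", index_col="row_id", na_values=["NA"])
    if list(df.columns) != list(markers.marker_id):
        raise ValueError("TSV marker columns do not match the marker map")
    if phased:
        return HaplotypePanel(df.to_numpy(dtype=np.int8), markers, [str(i) for i in df.index])
    arr = df.to_numpy(dtype=float)
    dosage = np.where(np.isnan(arr), MISSING, arr).astype(np.int8)
    return GenotypeMatrix(dosage, markers, [str(i) for i in df.index])


def write_tag_list(tags, markers: MarkerMap, path: str) -> None:
    """Write one marker id per line with a header comment recording method/params."""
    with open(path, "w") as fh:
        params = " ".join(f"{k}={v}" for k, v in sorted(tags.params.items()))
        fh.write(f"# method={tags.method} {params}\n")
        for i in tags.marker_indices:
            fh.write(f"{markers.marker_id[i]}\n")


def _ensure_parent(path: str) -> None:
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)
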