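"""VCF input/output and the read-count Dataset container.

Only allele depths (the AD FORMAT field) drive the model; GT in the input is
ignored.  Missing AD entries are encoded as (0, 0) — absence of reads is the
model's native missing state.  Multiallelic records are dropped (counted in a
log line), mirroring the automatic biallelic filter of typical GBS pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = ["Dataset", "read_vcf", "write_vcf", "filter_overrepresented_reads"]


@dataclass
class Dataset:
    """Markers x samples allele read counts with marker metadata and roles.

    ``reads`` has shape ``(M, N_samples, 2)`` (ref, alt); ``founder_mask`` is a
    boolean per sample.  Positions are 1-based bp as in VCF and strictly
    increasing within each chromosome.
    """

    marker_ids: list[str]
    chrom: np.ndarray  # (M,) str
    pos: np.ndarray  # (M,) int
    ref_allele: list[str]
    alt_allele: list[str]
    reads: np.ndarray  # (M, N, 2) int
    samples: list[str]
    founder_mask: np.ndarray  # (N,) bool

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.reads = np.asarray(self.reads, dtype=np.int64)
        self.founder_mask = np.asarray(self.founder_mask, dtype=bool)
        if self.reads.shape != (len(self.pos), len(self.samples), 2):
            raise ValueError("reads must have shape (M, N_samples, 2)")
        if (self.reads < 0).any():
            raise ValueError("read counts must be nonnegative")
        if self.n_founders < 2:
            raise ValueError("at least 2 founder samples are required")
        if self.n_offspring < 1:
            raise ValueError("at least 1 offspring sample is required")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    @property
    def n_founders(self) -> int:
        return int(self.founder_mask.sum())

    @property
    def n_offspring(self) -> int:
        return int((~self.founder_mask).sum())

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    @property
    def founder_reads(self) -> np.ndarray:
        return self.reads[:, self.founder_mask, :]

    @property
    def offspring_reads(self) -> np.ndarray:
        return self.reads[:, ~self.founder_mask, :]

    def subset_markers(self, index: np.ndarray) -> "Dataset":
        return replace(
            self,
            marker_ids=[self.marker_ids[i] for i in np.flatnonzero(np.asarray(index))]
            if np.asarray(index).dtype == bool
            else [self.marker_ids[i] for i in index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref_allele=[self.ref_allele[i] for i in np.flatnonzero(index)]
            if np.asarray(index).dtype == bool
            else [self.ref_allele[i] for i in index],
            alt_allele=[self.alt_allele[i] for i in np.flatnonzero(index)]
            if np.asarray(index).dtype == bool
            else [self.alt_allele[i] for i in index],
            reads=self.reads[index],
        )


def read_vcf(path: str, founder_names: list[str]) -> Dataset:
    """Load a VCF with per-sample allele depths into a Dataset.

    Multiallelic records are excluded; records lacking AD for a sample yield
    reads (0, 0).  ``founder_names`` must be a subset of the VCF samples.
    """
    vcf = VCF(str(path))
    if "ID=AD" not in vcf.raw_header:
        raise ValueError("VCF lacks an AD FORMAT definition")
    samples = list(vcf.samples)
    missing = [f for f in founder_names if f not in samples]
    if missing:
        raise ValueError(f"founder names absent from VCF header: {missing}")
    founder_mask = np.array([s in set(founder_names) for s in samples])

    ids, chroms, pos, refs, alts, reads = [], [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ad = var.format("AD")
        if ad is None:
            cell = np.zeros((len(samples), 2), dtype=np.int64)
        else:
            cell = np.asarray(ad, dtype=np.int64)[:, :2]
            cell = np.clip(cell, 0, None)  # cyvcf2 encodes '.' as negatives
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        reads.append(cell)
    if n_multi:
        logger.info("dropped %d multiallelic records", n_multi)
    if not pos:
        raise ValueError("no biallelic records in VCF")
    return Dataset(
        marker_ids=ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos),
        ref_allele=refs,
        alt_allele=alts,
        reads=np.stack(reads),
        samples=samples,
        founder_mask=founder_mask,
    )


def filter_overrepresented_reads(
    ds: Dataset, quantile: float = 0.90, zero_both: bool = True
) -> Dataset:
    """Zero out genotype calls supported by overrepresented reads.

    For each sample and each allele, the threshold is the given quantile
    (linear-interpolation, numpy's default "type 7") of that sample's counts
    for that allele across markers, zeros included.  Any call where either
    allele's count exceeds its threshold has both counts set to 0 (reads that
    abundant usually come from paralogous or repetitive sequence, so the whole
    call is suspect; set ``zero_both=False`` to zero only the offending
    allele).
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must lie in (0, 1]")
    thresholds = np.quantile(ds.reads, quantile, axis=0)  # (N, 2)
    exceeds = ds.reads > thresholds[None, :, :]
    reads = ds.reads.copy()
    if zero_both:
        reads[exceeds.any(axis=2)] = 0
    else:
        reads[exceeds] = 0
    return replace(ds, reads=reads)


def write_vcf(ds: Dataset, result, path: str) -> None:
    """Write corrected genotypes as a VCF with GT, AD and GPP FORMAT fields.

    GPP holds the posterior probability of the called genotype.  Founders get
    their estimated genotype classes; offspring get called genotypes with
    ``./.`` for masked (sub-threshold) calls.  Original AD values are kept.
    """
    geno = _genotype_matrix(ds, result)
    prob = _probability_matrix(ds, result)
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.3\n")
        for c in ds.chromosomes:
            out.write(f"##contig=<ID={c}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">\n'
        )
        out.write(
            '##FORMAT=<ID=GPP,Number=1,Type=Float,Description='
            '"Posterior probability of the called genotype">\n'
        )
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples)
            + "\n"
        )
        for m in range(ds.n_markers):
            fields = [
                str(ds.chrom[m]),
                str(ds.pos[m]),
                ds.marker_ids[m],
                ds.ref_allele[m],
                ds.alt_allele[m],
                ".",
                ".",
                ".",
                "GT:AD:GPP",
            ]
            for n in range(len(ds.samples)):
                ad = f"{ds.reads[m, n, 0]},{ds.reads[m, n, 1]}"
                gpp = "." if np.isnan(prob[m, n]) else f"{prob[m, n]:.4f}"
                fields.append(f"{gt_code[int(geno[m, n])]}:{ad}:{gpp}")
            out.write("\t".join(fields) + "\n")


def _genotype_matrix(ds: Dataset, result) -> np.ndarray:
    geno = np.full((ds.n_markers, len(ds.samples)), -1, dtype=np.int64)
    if result is None:
        return geno
    f_idx = np.flatnonzero(ds.founder_mask)
    o_idx = np.flatnonzero(~ds.founder_mask)
    if result.founder_genotypes.shape[:2] != (ds.n_markers, len(f_idx)):
        raise ValueError("result founder dimensions do not match dataset")
    if result.genotypes.shape != (ds.n_markers, len(o_idx)):
        raise ValueError("result offspring dimensions do not match dataset")
    geno[:, f_idx] = result.founder_genotypes.sum(axis=2)
    geno[:, o_idx] = result.genotypes
    return geno


def _probability_matrix(ds: Dataset, result) -> np.ndarray:
    prob = np.full((ds.n_markers, len(ds.samples)), np.nan)
    if result is None:
        return prob
    prob[:, np.flatnonzero(ds.founder_mask)] = 1.0
    prob[:, np.flatnonzero(~ds.founder_mask)] = result.marginal
    return prob
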