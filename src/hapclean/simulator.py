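"""Crossing-population and read-count simulation.

Three scenarios are supported, matching common mapping-population designs:

* ``homoP2_F2`` — biparental F2 from two inbred founders (selfed F1);
* ``hetP2_F1`` — F1 from a direct cross of two outbred (heterozygous) founders;
* ``homoP8_RIL`` — 8-way recombinant inbred lines: a three-round pairwise
  funnel of eight inbred founders followed by selfing to F6.

Meioses place a Poisson number of crossovers (mean = map length in Morgans)
uniformly on the genetic map, without interference.  Read counts are generated
per allele copy: each copy of the reference allele yields
``Poisson(depth * (1 - w_m))`` reads and each alternative copy
``Poisson(depth * w_m)``, so a read at a heterozygous cell is alternative with
probability ``w_m`` and amplification bias also skews homozygote depths, the
mechanism that makes the bias estimable from homozygote read totals.  At
unbiased markers (w=0.5) every cell's total is Poisson(depth).  Mismapping
flips each homozygote read to the opposite allele with the marker's rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_vcf import Dataset, write_vcf
from .scheme import MatingDesign

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_reads", "simulate", "write_simulation"]


@dataclass
class SimConfig:
    """Simulation settings; defaults follow the bundled study conditions.

    620 evenly spaced markers on a 50-Mb chromosome of 2 Morgans, founders at
    5x depth; 30% of markers are error-prone with true bias w ~ Beta(0.3, 0.3)
    (heavy tails near 0 and 1) and 10% are mismapping-prone with rates drawn
    uniformly from [0.05, 0.3].  Set ``bias_fraction = mismap_fraction = 0``
    for error-free data.
    """

    scenario: str = "homoP2_F2"
    n_offspring: int = 100
    n_markers: int = 620
    chrom_length_bp: int = 50_000_000
    chrom_length_morgan: float = 2.0
    offspring_depth: float = 3.0
    founder_depth: float = 5.0
    nonzero: bool = True  # founders guaranteed >= 1 read per marker
    bias_fraction: float = 0.3
    bias_beta: tuple[float, float] = (0.3, 0.3)
    mismap_fraction: float = 0.1
    mismap_range: tuple[float, float] = (0.05, 0.3)
    seed: int | None = None

    def design(self) -> MatingDesign:
        return MatingDesign.from_scenario(self.scenario)


@dataclass
class SimTruth:
    """Ground truth: phased ancestry, genotypes and the error parameters used."""

    pos: np.ndarray  # (M,) bp
    anc_alleles: np.ndarray  # (M, K) allele on each ancestral chromosome
    founder_genotypes: np.ndarray  # (M, N_f, 2)
    ancestry: np.ndarray  # (M, N_o, 2) ancestral-chromosome ids
    genotypes: np.ndarray  # (M, N_o) in {0,1,2}
    w: np.ndarray  # (M,) true allele read bias
    e_ref: np.ndarray
    e_alt: np.ndarray
    crossovers: list = field(default_factory=list)  # Morgan positions per offspring


def _meiosis(pair: np.ndarray, marker_morgan: np.ndarray, length: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a chromosome pair ``(2, M)``; returns (gamete, breakpoints)."""
    n_co = rng.poisson(length)
    breaks = np.sort(rng.uniform(0.0, length, n_co))
    start = rng.integers(2)
    which = (start + np.searchsorted(breaks, marker_morgan)) % 2
    return pair[which, np.arange(pair.shape[1])], breaks


def _founder_alleles(cfg: SimConfig, rng) -> np.ndarray:
    """Allele carried by each ancestral chromosome at each marker: (M, K)."""
    m = cfg.n_markers
    if cfg.scenario == "homoP2_F2":
        return np.tile(np.array([0, 1]), (m, 1))
    if cfg.scenario == "hetP2_F1":
        k = 4
    elif cfg.scenario == "homoP8_RIL":
        k = 8
    else:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    alleles = rng.integers(0, 2, size=(m, k))
    # every marker must segregate: resample monomorphic rows
    while True:
        mono = (alleles.sum(axis=1) == 0) | (alleles.sum(axis=1) == k)
        if not mono.any():
            break
        alleles[mono] = rng.integers(0, 2, size=(int(mono.sum()), k))
    return alleles


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Simulate founder alleles and offspring ancestry mosaics for a scenario."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    design = cfg.design()
    m, n = cfg.n_markers, cfg.n_offspring
    spacing = cfg.chrom_length_bp // m
    pos = spacing * np.arange(1, m + 1)
    marker_morgan = pos / cfg.chrom_length_bp * cfg.chrom_length_morgan
    length = cfg.chrom_length_morgan
    anc = _founder_alleles(cfg, rng)
    k = anc.shape[1]

    ancestry = np.empty((m, n, 2), dtype=np.int64)
    crossovers: list[np.ndarray] = []

    def gamete(pair):
        g, br = _meiosis(pair, marker_morgan, length, rng)
        return g, br

    if cfg.scenario == "homoP2_F2":
        f1 = np.stack([np.zeros(m, dtype=np.int64), np.ones(m, dtype=np.int64)])
        for i in range(n):
            g1, b1 = gamete(f1)
            g2, b2 = gamete(f1)
            ancestry[:, i, 0], ancestry[:, i, 1] = g1, g2
            crossovers.append(np.concatenate([b1, b2]))
    elif cfg.scenario == "hetP2_F1":
        p1 = np.stack([np.full(m, 0), np.full(m, 1)])
        p2 = np.stack([np.full(m, 2), np.full(m, 3)])
        for i in range(n):
            g1, b1 = gamete(p1)
            g2, b2 = gamete(p2)
            ancestry[:, i, 0], ancestry[:, i, 1] = g1, g2
            crossovers.append(np.concatenate([b1, b2]))
    elif cfg.scenario == "homoP8_RIL":
        const = [np.full(m, j, dtype=np.int64) for j in range(8)]
        for i in range(n):
            ind12 = np.stack([const[0], const[1]])
            ind34 = np.stack([const[2], const[3]])
            ind56 = np.stack([const[4], const[5]])
            ind78 = np.stack([const[6], const[7]])
            ind1234 = np.stack([gamete(ind12)[0], gamete(ind34)[0]])
            ind5678 = np.stack([gamete(ind56)[0], gamete(ind78)[0]])
            ind = np.stack([gamete(ind1234)[0], gamete(ind5678)[0]])
            for _ in range(5):  # selfing F1 -> F6
                ind = np.stack([gamete(ind)[0], gamete(ind)[0]])
            ancestry[:, i, 0], ancestry[:, i, 1] = ind[0], ind[1]
            crossovers.append(np.zeros(0))
    else:  # pragma: no cover
        raise ValueError(cfg.scenario)

    rows = np.arange(m)
    genotypes = anc[rows[:, None], ancestry[:, :, 0]] + anc[rows[:, None], ancestry[:, :, 1]]
    if design.inbred:
        founder_genotypes = np.stack([anc[:, : design.n_founders]] * 2, axis=2)
    else:
        founder_genotypes = anc.reshape(m, design.n_founders, 2)

    n_err = rng.binomial(m, cfg.bias_fraction)
    w = np.full(m, 0.5)
    err_idx = rng.choice(m, size=n_err, replace=False)
    w[err_idx] = rng.beta(*cfg.bias_beta, size=n_err)
    e_ref = np.zeros(m)
    e_alt = np.zeros(m)
    n_mis = rng.binomial(m, cfg.mismap_fraction)
    mis_idx = rng.choice(m, size=n_mis, replace=False)
    lo, hi = cfg.mismap_range
    e_ref[mis_idx] = rng.uniform(lo, hi, size=n_mis)
    e_alt[mis_idx] = rng.uniform(lo, hi, size=n_mis)

    return SimTruth(
        pos=pos,
        anc_alleles=anc,
        founder_genotypes=founder_genotypes,
        ancestry=ancestry,
        genotypes=genotypes,
        w=w,
        e_ref=e_ref,
        e_alt=e_alt,
        crossovers=crossovers,
    )


def _reads_for(
    genotypes: np.ndarray,
    depth: float,
    w: np.ndarray,
    e_ref: np.ndarray,
    e_alt: np.ndarray,
    rng,
    guarantee_one: bool = False,
) -> np.ndarray:
    """Per-copy Poisson read counts for a genotype matrix ``(M, N)``."""
    m, n = genotypes.shape
    lam_ref = depth * (1.0 - w)[:, None]
    lam_alt = depth * w[:, None]
    extra = max(depth - 1.0, 0.0) if guarantee_one else depth
    scale = extra / depth if depth > 0 else 0.0
    ref_copies = 2 - genotypes
    alt_copies = genotypes
    ref_reads = rng.poisson(ref_copies * lam_ref * scale if guarantee_one else ref_copies * lam_ref)
    alt_reads = rng.poisson(alt_copies * lam_alt * scale if guarantee_one else alt_copies * lam_alt)
    if guarantee_one:
        # one guaranteed read of a true allele per cell
        p_alt = np.where(
            genotypes == 1, np.broadcast_to(w[:, None], (m, n)), (genotypes == 2).astype(float)
        )
        extra_alt = rng.random((m, n)) < p_alt
        alt_reads = alt_reads + extra_alt
        ref_reads = ref_reads + (~extra_alt)
    # mismapping flips homozygote reads to the opposite allele
    hom_ref = genotypes == 0
    flips = rng.binomial(ref_reads, np.broadcast_to(e_ref[:, None], (m, n)))
    ref_reads = np.where(hom_ref, ref_reads - flips, ref_reads)
    alt_reads = np.where(hom_ref, alt_reads + flips, alt_reads)
    hom_alt = genotypes == 2
    flips = rng.binomial(alt_reads, np.broadcast_to(e_alt[:, None], (m, n)))
    alt_reads = np.where(hom_alt, alt_reads - flips, alt_reads)
    ref_reads = np.where(hom_alt, ref_reads + flips, ref_reads)
    return np.stack([ref_reads, alt_reads], axis=2)


def simulate_reads(truth: SimTruth, cfg: SimConfig, rng: np.random.Generator | None = None) -> Dataset:
    """Generate the read-count Dataset (founders first, then offspring)."""
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1) if rng is None else rng
    design = cfg.design()
    founder_cls = truth.founder_genotypes.sum(axis=2)
    f_reads = _reads_for(
        founder_cls, cfg.founder_depth, truth.w, truth.e_ref, truth.e_alt, rng,
        guarantee_one=cfg.nonzero,
    )
    o_reads = _reads_for(
        truth.genotypes, cfg.offspring_depth, truth.w, truth.e_ref, truth.e_alt, rng
    )
    reads = np.concatenate([f_reads, o_reads], axis=1)
    n_f = design.n_founders
    samples = [f"P{j + 1}" for j in range(n_f)] + [
        f"S{i + 1:04d}" for i in range(cfg.n_offspring)
    ]
    m = cfg.n_markers
    return Dataset(
        marker_ids=[f"M{i + 1:05d}" for i in range(m)],
        chrom=np.array(["chr1"] * m, dtype=object),
        pos=truth.pos,
        ref_allele=["A"] * m,
        alt_allele=["C"] * m,
        reads=reads,
        samples=samples,
        founder_mask=np.array([True] * n_f + [False] * cfg.n_offspring),
    )


def simulate(cfg: SimConfig, rng: np.random.Generator | None = None) -> tuple[SimTruth, Dataset]:
    """Convenience wrapper: genotypes then reads from one RNG stream."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    truth = simulate_genotypes(cfg, rng)
    ds = simulate_reads(truth, cfg, rng)
    return truth, ds


def write_simulation(truth: SimTruth, ds: Dataset, outdir: str, cfg: SimConfig | None = None) -> None:
    """Write the simulated VCF plus tabular truth files (TSV) and the config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(ds, None, str(out / "simulated.vcf"))
    offspring = [s for s, f in zip(ds.samples, ds.founder_mask) if not f]
    founders = [s for s, f in zip(ds.samples, ds.founder_mask) if f]
    pd.DataFrame(truth.genotypes, index=ds.marker_ids, columns=offspring).to_csv(
        out / "truth_genotypes.tsv", sep="\t"
    )
    hap = truth.ancestry.reshape(truth.ancestry.shape[0], -1)
    cols = [f"{s}_h{a + 1}" for s in offspring for a in (0, 1)]
    pd.DataFrame(hap, index=ds.marker_ids, columns=cols).to_csv(
        out / "truth_haplotypes.tsv", sep="\t"
    )
    pd.DataFrame(
        truth.founder_genotypes.sum(axis=2), index=ds.marker_ids, columns=founders
    ).to_csv(out / "truth_founder_genotypes.tsv", sep="\t")
    pd.DataFrame(
        {"w": truth.w, "e_ref": truth.e_ref, "e_alt": truth.e_alt}, index=ds.marker_ids
    ).to_csv(out / "truth_params.tsv", sep="\t")
    if cfg is not None:
        (out / "sim_config.json").write_text(json.dumps(asdict(cfg), indent=2))
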