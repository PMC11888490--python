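"""Synthetic phased duo/trio generator with known de novo ground truth.

The generator produces exactly the statistical structure the duo classifier
relies on: biallelic sites with population allele frequencies drawn from a
U-shaped Beta density, four parental haplotypes, child haplotypes formed by
recombination of each parent's pair, injected de novo alleles at
family-monomorphic positions on the transmitted paternal or maternal
haplotype, read-backed-phasing emulation (phase-set fragmentation with an
arbitrary per-fragment orientation and optional switch errors), per-genotype
error/GQ/DP models, and sorted multi-sample VCF output (GT:GQ:DP:PS) for
the trio and both masked duos plus a truth table.

It deliberately does not emulate reads, a reference genome, or realistic
mutation-rate heterogeneity — positions are abstract coordinates on one
synthetic contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SimulationParams",
    "TruthRecord",
    "SimulatedFamily",
    "simulate_family",
    "simulate_block_pair",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the phased-family generator.

    Defaults emulate one 5 Mb contig at roughly one variant site per 100 bp,
    ~33x depth, multi-hundred-kb phase sets (300 kb mean fragments, so joint
    proband-parent blocks average about half that), and a 4:1
    paternal:maternal de novo ratio (20 vs 5 events). Error rates default to
    zero; noisy regimes opt in explicitly.

    The symmetric Beta(2, 2) allele-frequency default is calibrated to the
    classifier's operating point: it makes two non-IBD haplotypes differ at
    ~0.4 of sites, so even a minimum-span (10 kb, ~100-site) block carries
    enough informative differences to clear the default Hamming
    dissimilarity threshold of 40. A more U-shaped density would leave
    marginally-sized blocks systematically unclassifiable.
    """

    seed: int = 0
    n_sites: int = 50_000
    region_length: int = 5_000_000
    contig: str = "chr1"
    af_beta_a: float = 2.0
    af_beta_b: float = 2.0
    recomb_rate: float = 1e-8  # crossovers per bp per transmission
    n_de_novo_paternal: int = 20
    n_de_novo_maternal: int = 5
    phase_block_mean_length: float = 300_000.0
    switch_error_rate: float = 0.0  # per phased het
    genotype_error_rate: float = 0.0  # per genotype call
    indel_fraction: float = 0.05
    gq_correct_mean: float = 60.0
    gq_correct_sd: float = 7.0
    gq_error_mean: float = 20.0
    gq_error_sd: float = 8.0
    dp_mean: float = 33.0
    unrelated: bool = False

    def __post_init__(self) -> None:
        for name in ("recomb_rate", "switch_error_rate", "genotype_error_rate", "indel_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_sites", "region_length", "n_de_novo_paternal", "n_de_novo_maternal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sites > self.region_length:
            raise ValueError("n_sites cannot exceed region_length (unique positions)")


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    pos: int
    alt: str
    origin: str  # "paternal" | "maternal"
    is_de_novo: bool
    transmitted_haplotype: int  # 1 or 2: which haplotype of that parent the child received


@dataclass
class SimulatedFamily:
    """Generator output: file paths, truth table and internal truth arrays."""

    params: SimulationParams
    positions: np.ndarray
    truth: pd.DataFrame
    trio_vcf: Optional[Path]
    father_duo_vcf: Optional[Path]
    mother_duo_vcf: Optional[Path]
    truth_tsv: Optional[Path]
    proband_id: str = "proband"
    father_id: str = "father"
    mother_id: str = "mother"
    # true (pre-error, pre-switch) haplotypes: sample -> (2, n_sites) int8
    true_haplotypes: dict = field(default_factory=dict)
    # which parental haplotype (0/1) each child haplotype copies at each site
    pat_source: Optional[np.ndarray] = None
    mat_source: Optional[np.ndarray] = None
    # sample -> boolean array of genotype-error sites
    error_mask: dict = field(default_factory=dict)

    @property
    def de_novo_positions(self) -> set[tuple[str, int]]:
        return {
            (row.chrom, int(row.pos))
            for row in self.truth.itertuples()
            if row.is_de_novo
        }


def _gamete(rng: np.random.Generator, haps: np.ndarray, positions: np.ndarray,
            recomb_rate: float, region_length: int) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete; returns (alleles, source-haplotype per site)."""
    n_x = rng.poisson(recomb_rate * region_length)
    xpos = np.sort(rng.uniform(0, region_length, size=n_x))
    start = int(rng.integers(2))
    source = (start + np.searchsorted(xpos, positions)) % 2
    return haps[source, np.arange(len(positions))], source


def _fragment_breaks(rng: np.random.Generator, mean_len: float, region_length: int) -> np.ndarray:
    """Interior phase-fragment breakpoints from an exponential renewal process."""
    breaks = []
    x = 0.0
    while True:
        x += rng.exponential(mean_len)
        if x >= region_length:
            break
        breaks.append(x)
    return np.asarray(breaks)


def _alleles(rng: np.random.Generator, n: int, indel_fraction: float) -> tuple[list, list]:
    ref_base = rng.choice(_BASES, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    base_idx = np.searchsorted(_BASES, ref_base)
    alt_base = _BASES[(base_idx + alt_shift) % 4]
    is_indel = rng.random(n) < indel_fraction
    is_insertion = rng.random(n) < 0.5
    extra = rng.choice(_BASES, size=n)
    refs, alts = [], []
    for i in range(n):
        if not is_indel[i]:
            refs.append(str(ref_base[i]))
            alts.append(str(alt_base[i]))
        elif is_insertion[i]:
            refs.append(str(ref_base[i]))
            alts.append(str(ref_base[i]) + str(extra[i]))
        else:
            refs.append(str(ref_base[i]) + str(extra[i]))
            alts.append(str(ref_base[i]))
    return refs, alts


def _phase_sample(
    rng: np.random.Generator,
    genotypes: np.ndarray,  # (2, n) emitted allele pair, order = true haplotype order
    positions: np.ndarray,
    breaks: np.ndarray,
    switch_error_rate: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Emulate read-backed phasing output for one sample.

    Heterozygous calls become phased with the PS of their fragment (PS = the
    position of the fragment's first site, the usual phaser convention); the
    allele order within each fragment starts at a random orientation and may
    flip at each het with probability ``switch_error_rate`` (a switch
    error affects the remainder of the fragment). Homozygous calls stay
    unphased. Returns (emitted genotype pairs, phased mask, PS values).
    """
    n = genotypes.shape[1]
    frag = np.searchsorted(breaks, positions)
    het = genotypes[0] != genotypes[1]
    out = genotypes.copy()
    phased = het.copy()
    ps = np.zeros(n, dtype=np.int64)
    for f in np.unique(frag):
        in_frag = frag == f
        idx = np.nonzero(in_frag)[0]
        ps[idx] = positions[idx[0]]
        flip = bool(rng.integers(2))
        for i in idx:
            if not het[i]:
                continue
            if switch_error_rate > 0.0 and rng.random() < switch_error_rate:
                flip = not flip
            if flip:
                out[0, i], out[1, i] = genotypes[1, i], genotypes[0, i]
    return out, phased, ps


def _gq_dp(rng, n, err, params) -> tuple[np.ndarray, np.ndarray]:
    gq = rng.normal(params.gq_correct_mean, params.gq_correct_sd, size=n)
    gq_err = rng.normal(params.gq_error_mean, params.gq_error_sd, size=n)
    gq = np.where(err, gq_err, gq)
    gq = np.clip(np.rint(gq), 2, 99).astype(int)
    dp = rng.poisson(params.dp_mean, size=n).astype(int)
    return gq, dp


def _write_vcf(path, contig, region_length, positions, refs, alts, samples, calls) -> None:
    """``calls``: sample -> (genotype (2,n), phased mask, ps, gq, dp)."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={region_length + 1}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Conditional genotype quality (PHRED)">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set identifier">')
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(len(positions)):
            rec = out.new_record(
                contig=contig, start=int(positions[i]) - 1, alleles=(refs[i], alts[i])
            )
            for s in samples:
                gt, phased, ps, gq, dp = calls[s]
                sm = rec.samples[s]
                sm["GT"] = (int(gt[0, i]), int(gt[1, i]))
                sm.phased = bool(phased[i])
                sm["GQ"] = int(gq[i])
                sm["DP"] = int(dp[i])
                if phased[i]:
                    sm["PS"] = int(ps[i])
            out.write(rec)


def simulate_family(params: SimulationParams, out_dir) -> SimulatedFamily:
    """Generate a phased trio plus both masked duos (or an unrelated pair).

    Byte-identical output for identical parameters (including the seed).
    De novo alleles are injected at family-monomorphic positions, one per
    joint phase fragment at most (real de novo events essentially never
    co-occur within a single phase block, and the classifier deliberately
    discards clustered calls). With ``unrelated=True`` two independent
    diploids are emitted as a two-sample duo VCF — the negative control in
    which no haplotype pair is identical by descent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    n = params.n_sites
    positions = np.sort(rng.choice(params.region_length, size=n, replace=False)) + 1
    af = rng.beta(params.af_beta_a, params.af_beta_b, size=n)
    refs, alts = _alleles(rng, n, params.indel_fraction)

    if params.unrelated:
        return _simulate_unrelated(params, out_dir, rng, positions, af, refs, alts)

    father = (rng.random((2, n)) < af).astype(np.int8)
    mother = (rng.random((2, n)) < af).astype(np.int8)
    child_h1, pat_source = _gamete(rng, father, positions, params.recomb_rate, params.region_length)
    child_h2, mat_source = _gamete(rng, mother, positions, params.recomb_rate, params.region_length)
    child = np.vstack([child_h1, child_h2]).astype(np.int8)

    # Phase fragmentation is drawn before de novo placement so injected
    # events can be spread across distinct haplotype blocks in BOTH duos
    # (real de novo events essentially never co-occur within one block; two
    # in one block would trip the clustered-call filter by design). Joint
    # blocks of a duo are delimited by the union of that duo's two samples'
    # fragment breaks, so placement works on those block ids; if a random
    # fragmentation leaves too few distinct blocks, it is redrawn.
    monomorphic = (father.sum(axis=0) + mother.sum(axis=0)) == 0
    n_dn = params.n_de_novo_paternal + params.n_de_novo_maternal
    mono_idx = np.nonzero(monomorphic)[0]
    breaks = None
    dn_sites: list[int] = []
    for _attempt in range(50):
        breaks = {
            name: _fragment_breaks(rng, params.phase_block_mean_length, params.region_length)
            for name in ("proband", "father", "mother")
        }
        fa_block = np.searchsorted(
            np.sort(np.concatenate([breaks["proband"], breaks["father"]])), positions
        )
        mo_block = np.searchsorted(
            np.sort(np.concatenate([breaks["proband"], breaks["mother"]])), positions
        )
        dn_sites = []
        used_fa: set[int] = set()
        used_mo: set[int] = set()
        for i in rng.permutation(mono_idx):
            if len(dn_sites) == n_dn:
                break
            if int(fa_block[i]) in used_fa or int(mo_block[i]) in used_mo:
                continue
            dn_sites.append(int(i))
            used_fa.add(int(fa_block[i]))
            used_mo.add(int(mo_block[i]))
            if len(dn_sites) == n_dn:
                break
        if len(dn_sites) == n_dn:
            break
    if len(dn_sites) != n_dn:
        raise ValueError(
            f"cannot place {n_dn} de novo variants in distinct haplotype blocks: "
            f"only {len(dn_sites)} blocks with family-monomorphic positions available"
        )
    # greedy picks hit large blocks first (they hold more sites); shuffle
    # before the paternal/maternal split so origin is independent of block size
    dn_sites = [int(i) for i in rng.permutation(dn_sites)] if dn_sites else dn_sites
    truth_rows = []
    for k, i in enumerate(dn_sites):
        paternal = k < params.n_de_novo_paternal
        if paternal:
            child[0, i] = 1
            hap = int(pat_source[i]) + 1
        else:
            child[1, i] = 1
            hap = int(mat_source[i]) + 1
        truth_rows.append(
            TruthRecord(
                chrom=params.contig,
                pos=int(positions[i]),
                alt=alts[i],
                origin="paternal" if paternal else "maternal",
                is_de_novo=True,
                transmitted_haplotype=hap,
            )
        )
    truth = pd.DataFrame([t.__dict__ for t in truth_rows],
                         columns=["chrom", "pos", "alt", "origin", "is_de_novo",
                                  "transmitted_haplotype"])

    true_haps = {"proband": child.copy(), "father": father, "mother": mother}
    calls = {}
    error_mask = {}
    for name in ("proband", "father", "mother"):
        haps = true_haps[name]
        emitted = haps.copy()
        err = rng.random(n) < params.genotype_error_rate
        which = rng.integers(2, size=n)
        flip_idx = np.nonzero(err)[0]
        emitted[which[flip_idx], flip_idx] = 1 - emitted[which[flip_idx], flip_idx]
        gt, phased, ps = _phase_sample(rng, emitted, positions, breaks[name],
                                       params.switch_error_rate)
        gq, dp = _gq_dp(rng, n, err, params)
        calls[name] = (gt, phased, ps, gq, dp)
        error_mask[name] = err

    trio_vcf = out_dir / "trio.vcf"
    father_duo = out_dir / "father_duo.vcf"
    mother_duo = out_dir / "mother_duo.vcf"
    truth_tsv = out_dir / "truth.tsv"
    _write_vcf(trio_vcf, params.contig, params.region_length, positions, refs, alts,
               ["proband", "father", "mother"], calls)
    _write_vcf(father_duo, params.contig, params.region_length, positions, refs, alts,
               ["proband", "father"], calls)
    _write_vcf(mother_duo, params.contig, params.region_length, positions, refs, alts,
               ["proband", "mother"], calls)
    truth.to_csv(truth_tsv, sep="\t", index=False)

    return SimulatedFamily(
        params=params,
        positions=positions,
        truth=truth,
        trio_vcf=trio_vcf,
        father_duo_vcf=father_duo,
        mother_duo_vcf=mother_duo,
        truth_tsv=truth_tsv,
        true_haplotypes=true_haps,
        pat_source=pat_source,
        mat_source=mat_source,
        error_mask=error_mask,
    )


def _simulate_unrelated(params, out_dir, rng, positions, af, refs, alts) -> SimulatedFamily:
    n = params.n_sites
    a = (rng.random((2, n)) < af).astype(np.int8)
    b = (rng.random((2, n)) < af).astype(np.int8)
    breaks = {
        "proband": _fragment_breaks(rng, params.phase_block_mean_length, params.region_length),
        "father": _fragment_breaks(rng, params.phase_block_mean_length, params.region_length),
    }
    calls = {}
    error_mask = {}
    for name, haps in (("proband", a), ("father", b)):
        emitted = haps.copy()
        err = rng.random(n) < params.genotype_error_rate
        which = rng.integers(2, size=n)
        flip_idx = np.nonzero(err)[0]
        emitted[which[flip_idx], flip_idx] = 1 - emitted[which[flip_idx], flip_idx]
        gt, phased, ps = _phase_sample(rng, emitted, positions, breaks[name],
                                       params.switch_error_rate)
        gq, dp = _gq_dp(rng, n, err, params)
        calls[name] = (gt, phased, ps, gq, dp)
        error_mask[name] = err
    duo = out_dir / "unrelated_duo.vcf"
    _write_vcf(duo, params.contig, params.region_length, positions, refs, alts,
               ["proband", "father"], calls)
    truth = pd.DataFrame(columns=["chrom", "pos", "alt", "origin", "is_de_novo",
                                  "transmitted_haplotype"])
    return SimulatedFamily(
        params=params,
        positions=positions,
        truth=truth,
        trio_vcf=None,
        father_duo_vcf=duo,
        mother_duo_vcf=None,
        truth_tsv=None,
        true_haplotypes={"proband": a, "father": b},
        error_mask=error_mask,
    )


def simulate_block_pair(
    n_informative: int, ibd: bool, mismatch_rate: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unit-level fixture: four binary haplotype vectors of one block.

    Returns (proband hap1, proband hap2, parent hap1, parent hap2). With
    ``ibd=True`` proband hap1 is an exact copy of parent hap1 (distance 0
    by construction); otherwise every pair differs at roughly
    ``mismatch_rate * n_informative`` positions.
    """
    if n_informative < 1:
        raise ValueError("n_informative must be >= 1")
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 2, size=n_informative, dtype=np.int8)
    vecs = [
        base ^ (rng.random(n_informative) < mismatch_rate / 2).astype(np.int8)
        for _ in range(4)
    ]
    pro1, pro2, par1, par2 = vecs
    if ibd:
        pro1 = par1.copy()
    return pro1, pro2, par1, par2
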