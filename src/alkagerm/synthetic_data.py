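"""Synthetic rice diversity-panel generator with planted genetic effects.

Emulates the study design the pipeline targets: two differentiated
subpopulations (Xian/indica and Geng/japonica) of fully inbred accessions,
clustered biallelic SNPs with block-structured linkage disequilibrium,
single-exon gene models whose coding sequences contain SNPs, and a 7-day
germination assay under control and alkali-stress conditions in which planted
causal coding variants shift a latent alkali-tolerance value.

Model sketch
------------
*Genotypes.*  Ancestral allele frequencies are Uniform(0.05, 0.95); each
subpopulation's frequencies are drawn from the Balding-Nichols distribution
with differentiation parameter ``fst``.  Per subpopulation a small pool of
founder haplotypes is drawn from those frequencies; each accession copies
founder haplotypes in blocks of ``ld_block_len`` bp, re-drawing its founder
at a block boundary with probability ``block_switch``.  Accessions are fully
inbred (dosages 0/2 before missingness).

*Gene models.*  SNP positions are clustered (short within-cluster gaps,
long between-cluster gaps), and genes are placed over SNP clusters so that
their single-exon CDS contains the cluster.  The emitted reference sequence
matches every SNP's REF allele, starts each CDS with ATG, ends with a stop,
and has no internal stops; each planted causal SNP is placed in a codon where
REF -> ALT changes the encoded amino acid (verified by translation).

*Phenotypes.*  Latent tolerance L_i = subpopulation shift + sum of planted
effects x (dosage/2) + Gaussian noise, standardized across accessions.  Each
viable seed's germination day is a rounded log-normal draw with mean day
``mu_control`` under control and ``mu_control + delta - gamma * L_i``
(floored at 1) under stress; days beyond day 7 count as non-germinated.
Root/shoot lengths are constant (plus noise) under control and linear in
L_i under stress.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .germination_traits import N_DAYS, GerminationCounts
from .io_formats import (
    MISSING,
    GeneModel,
    VariantTable,
    write_annotations,
    write_fasta,
    write_gff3,
    write_metadata,
    write_phenotype_table,
    write_vcf,
)

_NT = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CausalGene:
    """A planted effect: the ``snp_index``-th CDS SNP of the ``gene_index``-th
    gene shifts latent tolerance by ``effect`` (in roughly SD units) per
    founder alt allele."""

    gene_index: int
    snp_index: int
    effect: float


@dataclass
class SimConfig:
    """All knobs of the generator; one config fully determines the dataset."""

    # population
    n_accessions: int = 400
    subpop_fractions: dict = field(
        default_factory=lambda: {"Xian": 0.65, "Geng": 0.35}
    )
    n_chromosomes: int = 12
    n_snps: int = 20_000
    fst: float = 0.3
    n_founders: int = 16
    ld_block_len: int = 150_000
    block_switch: float = 0.9
    missing_rate: float = 0.02
    # SNP spacing (clustered): short gaps within gene-sized clusters,
    # long gaps between them
    short_gap_mean: float = 60.0
    long_gap_mean: float = 4_000.0
    long_gap_prob: float = 0.25
    # gene models
    n_genes: int = 40
    max_cds_span: int = 2_000
    utr_pad: int = 100
    causal_genes: list[CausalGene] = field(
        default_factory=lambda: [CausalGene(0, 0, 1.0)]
    )
    causal_min_maf: float = 0.15
    # latent tolerance
    subpop_shift: dict = field(
        default_factory=lambda: {"Xian": 0.5, "Geng": -0.5}
    )
    latent_noise_sd: float = 1.0
    # germination-day model (days)
    mu_control: float = 3.7
    delta: float = 1.5
    gamma: float = 1.0
    day_sd: float = 0.25  # log-scale dispersion
    viability: float = 0.95
    n_seeds: int = 20
    n_replicates: int = 3
    # length model (cm)
    root_control_mean: float = 6.9
    shoot_control_mean: float = 5.3
    root_stress_base: float = 1.6
    root_stress_slope: float = 0.6
    shoot_stress_base: float = 3.9
    shoot_stress_slope: float = 0.8
    length_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0,1), got {self.fst}")
        total = sum(self.subpop_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subpop fractions must sum to 1, got {total}")
        for cg in self.causal_genes:
            if not np.isfinite(cg.effect):
                raise ValueError("causal effect sizes must be finite")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if not 0.0 < self.viability <= 1.0:
            raise ValueError("viability must be in (0,1]")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    subpopulation: dict[str, str]
    latent: dict[str, float]
    causal_snps: list[dict]
    #: per causal gene: accession -> "tolerant" | "other" | "missing"
    gene_haplotypes: dict[str, dict[str, str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "subpopulation": self.subpopulation,
                "latent": self.latent,
                "causal_snps": self.causal_snps,
                "gene_haplotypes": self.gene_haplotypes,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SimDataset:
    config: SimConfig
    variants: VariantTable
    metadata: pd.DataFrame
    genes: list[GeneModel]
    reference: dict[str, str]
    counts: list[GerminationCounts]
    annotations: pd.DataFrame
    truth: SimTruth


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _subpop_counts(cfg: SimConfig) -> dict[str, int]:
    # largest-remainder apportionment, deterministic
    items = sorted(cfg.subpop_fractions.items())
    raw = {k: cfg.n_accessions * f for k, f in items}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = cfg.n_accessions - sum(counts.values())
    for k, _ in sorted(raw.items(), key=lambda kv: -(kv[1] - np.floor(kv[1])))[:short]:
        counts[k] += 1
    return counts


def simulate_population(cfg: SimConfig) -> tuple[VariantTable, pd.DataFrame]:
    """Genotypes and accession metadata under the Balding-Nichols +
    founder-block-copying model."""
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root.spawn(3)[0])

    counts = _subpop_counts(cfg)
    acc_ids, subpops = [], []
    i = 0
    for name in sorted(counts):
        for _ in range(counts[name]):
            acc_ids.append(f"ACC{i + 1:04d}")
            subpops.append(name)
            i += 1
    metadata = pd.DataFrame({"accession_id": acc_ids, "subpopulation": subpops})
    sub_index = {name: np.flatnonzero(np.array(subpops) == name) for name in counts}

    per_chrom = [cfg.n_snps // cfg.n_chromosomes] * cfg.n_chromosomes
    per_chrom[0] += cfg.n_snps - sum(per_chrom)

    frames, dosage_blocks = [], []
    for c in range(cfg.n_chromosomes):
        m = per_chrom[c]
        chrom = str(c + 1)
        # clustered positions
        is_long = rng.random(m) < cfg.long_gap_prob
        gaps = np.where(
            is_long,
            rng.exponential(cfg.long_gap_mean, m) + 200.0,
            rng.exponential(cfg.short_gap_mean, m) + 1.0,
        ).astype(np.int64)
        pos0 = np.cumsum(gaps) + 100
        pos0 = np.unique(pos0)
        while len(pos0) < m:  # rare collision after rounding
            extra = pos0[-1] + np.cumsum(
                rng.exponential(cfg.short_gap_mean, m - len(pos0)).astype(np.int64) + 1
            )
            pos0 = np.unique(np.concatenate([pos0, extra]))
        pos0 = pos0[:m]

        p_anc = rng.uniform(0.05, 0.95, m)
        a = p_anc * (1.0 - cfg.fst) / cfg.fst
        b = (1.0 - p_anc) * (1.0 - cfg.fst) / cfg.fst

        blocks = pos0 // cfg.ld_block_len
        _, block_idx = np.unique(blocks, return_inverse=True)
        n_blocks = block_idx.max() + 1

        dos = np.empty((m, cfg.n_accessions), dtype=np.int8)
        for name, acc_idx in sub_index.items():
            n_sub = len(acc_idx)
            if n_sub == 0:
                continue
            p_sub = rng.beta(a, b)
            founders = (rng.random((cfg.n_founders, m)) < p_sub).astype(np.int8)
            f = np.empty((n_sub, n_blocks), dtype=np.int64)
            f[:, 0] = rng.integers(cfg.n_founders, size=n_sub)
            fresh = rng.integers(cfg.n_founders, size=(n_sub, n_blocks))
            switch = rng.random((n_sub, n_blocks)) < cfg.block_switch
            for bix in range(1, n_blocks):
                f[:, bix] = np.where(switch[:, bix], fresh[:, bix], f[:, bix - 1])
            hap = founders[f[:, block_idx], np.arange(m)[None, :]]
            dos[:, acc_idx] = (2 * hap).T

        if cfg.missing_rate > 0:
            miss = rng.random((m, cfg.n_accessions)) < cfg.missing_rate
            dos[miss] = MISSING

        ref_i = rng.integers(0, 4, m)
        alt_i = (ref_i + rng.integers(1, 4, m)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"rs{chrom}_{p + 1}" for p in pos0],
                    "chrom": chrom,
                    "pos0": pos0,
                    "ref": _NT[ref_i].astype("U1"),
                    "alt": _NT[alt_i].astype("U1"),
                }
            )
        )
        dosage_blocks.append(dos)

    snps = pd.concat(frames, ignore_index=True)
    variants = VariantTable(snps, np.vstack(dosage_blocks), acc_ids)
    return variants, metadata


# ---------------------------------------------------------------------------
# gene models + reference
# ---------------------------------------------------------------------------

def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


class CausalPlacementError(RuntimeError):
    """Raised when a causal SNP cannot be made non-synonymous."""


def _candidate_runs(pos: np.ndarray, max_span: int) -> list[tuple[int, int]]:
    """Maximal runs [i, j] of consecutive SNPs with pos[j]-pos[i] <= max_span."""
    runs, j = [], 0
    for i in range(len(pos)):
        j = max(j, i)
        while j + 1 < len(pos) and pos[j + 1] - pos[i] <= max_span:
            j += 1
        if not runs or runs[-1][1] < j:
            runs.append((i, j))
    return runs


def _fix_orf(
    transcript: np.ndarray,
    fixed: np.ndarray,
    gene_id: str,
) -> None:
    """Force ATG start, stop end, no internal stops; only free bases change."""
    n = len(transcript)
    for off, base in zip((0, 1, 2), "ATG"):
        if fixed[off]:
            raise CausalPlacementError(f"SNP inside the start codon of {gene_id}")
        transcript[off] = base
    for off, base in zip((n - 3, n - 2, n - 1), "TAA"):
        if fixed[off]:
            raise CausalPlacementError(f"SNP inside the stop codon of {gene_id}")
        transcript[off] = base
    for c in range(1, n // 3 - 1):
        codon = "".join(transcript[3 * c : 3 * c + 3])
        if _translate(codon) != "*":
            continue
        free = [k for k in range(3) if not fixed[3 * c + k]]
        if not free:
            raise CausalPlacementError(
                f"unbreakable internal stop codon in {gene_id}"
            )
        transcript[3 * c + free[0]] = "C"  # no stop codon contains C
        assert _translate("".join(transcript[3 * c : 3 * c + 3])) != "*"


def _force_nonsynonymous(
    transcript: np.ndarray,
    fixed: np.ndarray,
    cds_off: int,
    alt_base: str,
    gene_id: str,
) -> None:
    """Re-choose free bases of the causal codon so REF->ALT changes the AA."""
    c = cds_off // 3
    k = cds_off % 3
    idx = [3 * c, 3 * c + 1, 3 * c + 2]
    free = [j for j in range(3) if not fixed[idx[j]] and j != k]
    from itertools import product

    for combo in product("ACGT", repeat=len(free)):
        trial = [transcript[i] for i in idx]
        for j, basepos in enumerate(free):
            trial[basepos] = combo[j]
        ref_codon = "".join(trial)
        alt = list(trial)
        alt[k] = alt_base
        alt_codon = "".join(alt)
        if _translate(ref_codon) != "*" and _translate(ref_codon) != _translate(alt_codon):
            for j, basepos in enumerate(free):
                transcript[idx[basepos]] = combo[j]
            return
    raise CausalPlacementError(
        f"cannot place causal SNP non-synonymously in {gene_id} "
        f"(codon offset {k}, alt {alt_base})"
    )


def simulate_gene_models(
    cfg: SimConfig, variants: VariantTable
) -> tuple[list[GeneModel], dict[str, str], list[dict]]:
    """Place genes over SNP clusters and build a consistent reference.

    Returns (gene models, reference sequences, causal placements); each
    causal placement records gene_id, snp_id, effect and favorable allele.
    """
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root.spawn(3)[1])
    # causal SNPs must segregate within every major subpopulation, so the
    # planted signal is identifiable under structure correction
    counts = _subpop_counts(cfg)
    starts = np.cumsum([0] + [counts[k] for k in sorted(counts)])
    sub_slices = [slice(a, b) for a, b in zip(starts, starts[1:]) if b > a]
    d = variants.dosages.astype(float)
    d[variants.dosages == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        sub_freq = np.stack([np.nanmean(d[:, s], axis=1) / 2 for s in sub_slices])
    sub_maf = np.nanmin(np.minimum(sub_freq, 1 - sub_freq), axis=0)
    maf = sub_maf

    # collect candidate SNP runs per chromosome (global SNP indices)
    chrom_of = variants.snps["chrom"].to_numpy()
    pos_of = variants.snps["pos0"].to_numpy()
    runs = []
    for chrom in dict.fromkeys(chrom_of):
        idx = np.flatnonzero(chrom_of == chrom)
        for i, j in _candidate_runs(pos_of[idx], cfg.max_cds_span - 60):
            runs.append((chrom, idx[i], idx[j]))
    order = rng.permutation(len(runs))

    causal_by_gene = {cg.gene_index: cg for cg in cfg.causal_genes}
    if len(causal_by_gene) != len(cfg.causal_genes):
        raise ValueError("at most one causal SNP per gene is supported")
    if causal_by_gene and max(causal_by_gene) >= cfg.n_genes:
        raise ValueError("causal gene_index beyond n_genes")

    min_edge_gap = 8  # bp clearance to the nearest SNP outside the CDS

    def trimmed(run):
        """Shrink a run until its boundary SNPs have clearance outside."""
        chrom, i, j = run
        while (
            i <= j and i > 0 and chrom_of[i - 1] == chrom
            and pos_of[i] - pos_of[i - 1] < min_edge_gap
        ):
            i += 1
        while (
            i <= j and j + 1 < len(pos_of) and chrom_of[j + 1] == chrom
            and pos_of[j + 1] - pos_of[j] < min_edge_gap
        ):
            j -= 1
        return (chrom, i, j) if i <= j else None

    def run_ok(run, need_snps, need_maf_at):
        _, i, j = run
        if j - i + 1 < need_snps:
            return False
        if need_maf_at is not None and maf[i + need_maf_at] < cfg.causal_min_maf:
            return False
        return not any(i <= b and a <= j for a, b in taken)

    chosen: list[tuple[str, int, int] | None] = [None] * cfg.n_genes
    taken: list[tuple[int, int]] = []  # global SNP-index ranges already used
    # place causal genes first (they have the strictest requirements)
    gene_order = sorted(causal_by_gene) + [
        g for g in range(cfg.n_genes) if g not in causal_by_gene
    ]
    for g in gene_order:
        cg = causal_by_gene.get(g)
        need = (cg.snp_index + 1, cg.snp_index) if cg else (1, None)
        for oi in order:
            run = trimmed(runs[oi])
            if run is None:
                continue
            if run_ok(run, *need):
                chosen[g] = run
                taken.append(run[1:])
                break
        if chosen[g] is None:
            raise RuntimeError(
                f"could not place gene {g}: no free SNP cluster satisfies "
                "its requirements (adjust n_genes/causal config)"
            )

    # reference scaffold: random sequence, REF base at every SNP
    reference: dict[str, np.ndarray] = {}
    for chrom in dict.fromkeys(chrom_of):
        idx = np.flatnonzero(chrom_of == chrom)
        length = int(pos_of[idx].max()) + 1_000
        seq = _NT[rng.integers(0, 4, length)]
        seq[pos_of[idx]] = variants.snps["ref"].to_numpy()[idx].astype("S1")
        reference[chrom] = seq

    genes: list[GeneModel] = []
    causal_placements: list[dict] = []
    for g in range(cfg.n_genes):
        chrom, i0, i1 = chosen[g]
        gpos = pos_of[i0 : i1 + 1]
        strand = "+" if rng.random() < 0.5 else "-"
        cg = causal_by_gene.get(g)

        pad = 15  # keeps SNPs out of the first/last codon
        start = int(gpos[0]) - pad
        end = int(gpos[-1]) + pad + 1  # half-open
        # keep neighbouring SNPs out of the CDS (with room for frame shifts)
        if i0 > 0 and chrom_of[i0 - 1] == chrom:
            start = max(start, int(pos_of[i0 - 1]) + 4)
        if i1 + 1 < len(pos_of) and chrom_of[i1 + 1] == chrom:
            end = min(end, int(pos_of[i1 + 1]) - 3)
        start = max(start, 0)
        # frame: put the causal SNP at codon position 1 (transcript offset % 3 == 0)
        if cg is not None:
            cpos = int(pos_of[i0 + cg.snp_index])
            if strand == "+":
                start -= (start - cpos) % 3  # transcript offset of cpos ≡ 0 (mod 3)
            else:
                end += (cpos + 1 - end) % 3
        # pad length to a multiple of 3
        rem = (end - start) % 3
        if rem:
            if strand == "+":
                end += 3 - rem
            else:
                start -= 3 - rem
        seq = reference[chrom]
        gene_id = f"LOC_Os{int(chrom):02d}g{10_000 + 10 * g:05d}"

        transcript = seq[start:end].astype("U1")
        if strand == "-":
            transcript = np.array(list(_revcomp(seq[start:end].tobytes().decode())), dtype="U1")
        # transcript offsets of the gene's SNPs (their base is pinned to REF)
        fixed = np.zeros(len(transcript), dtype=bool)
        offs = []
        for gi in range(i0, i1 + 1):
            p = int(pos_of[gi])
            off = p - start if strand == "+" else (end - 1 - p)
            fixed[off] = True
            offs.append(off)
        _fix_orf(transcript, fixed, gene_id)
        if cg is not None:
            alt = variants.snps["alt"].iloc[i0 + cg.snp_index]
            ref = variants.snps["ref"].iloc[i0 + cg.snp_index]
            alt_t = _revcomp(alt) if strand == "-" else alt
            _force_nonsynonymous(
                transcript, fixed, offs[cg.snp_index], alt_t, gene_id
            )
            causal_placements.append(
                {
                    "gene_id": gene_id,
                    "snp_id": variants.snps["snp_id"].iloc[i0 + cg.snp_index],
                    "snp_index": int(i0 + cg.snp_index),
                    "effect": cg.effect,
                    # genomic-scale allele, matching VCF / haplotype keys
                    "favorable_allele": alt if cg.effect > 0 else ref,
                }
            )
        # write transcript back to the genome
        genomic = transcript
        if strand == "-":
            genomic = np.array(list(_revcomp("".join(transcript))), dtype="U1")
        seq[start:end] = genomic.astype("S1")

        span = (max(0, start - cfg.utr_pad), end + cfg.utr_pad)
        genes.append(
            GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                      span=span, cds_segments=[(start, end)])
        )

    ref_str = {c: s.tobytes().decode() for c, s in reference.items()}
    genes.sort(key=lambda g: (int(g.chrom), g.span[0]))
    # re-key causal placements after sort is unnecessary: ids are stable
    return genes, ref_str, causal_placements


# ---------------------------------------------------------------------------
# latent tolerance + germination
# ---------------------------------------------------------------------------

def compute_latent_tolerance(
    cfg: SimConfig,
    variants: VariantTable,
    metadata: pd.DataFrame,
    causal_placements: list[dict],
) -> SimTruth:
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root.spawn(3)[2])
    acc = metadata["accession_id"].tolist()
    sub = metadata["subpopulation"].tolist()
    shift = np.array([cfg.subpop_shift.get(s, 0.0) for s in sub])

    raw = shift + rng.normal(0.0, cfg.latent_noise_sd, len(acc))
    gene_haps: dict[str, dict[str, str]] = {}
    for cp in causal_placements:
        d = variants.dosages[cp["snp_index"]].astype(float)
        obs = d != MISSING
        x = np.where(obs, d / 2.0, np.nanmean(np.where(obs, d, np.nan)) / 2.0)
        eff = cp["effect"]
        alt_is_fav = eff > 0
        raw = raw + eff * x
        labels = {}
        for k, a in enumerate(acc):
            if not obs[k]:
                labels[a] = "missing"
            else:
                carrier = (d[k] == 2) if alt_is_fav else (d[k] == 0)
                labels[a] = "tolerant" if carrier else "other"
        gene_haps[cp["gene_id"]] = labels

    latent = (raw - raw.mean()) / raw.std()
    return SimTruth(
        subpopulation=dict(zip(acc, sub)),
        latent={a: float(v) for a, v in zip(acc, latent)},
        causal_snps=[
            {k: v for k, v in cp.items() if k != "snp_index"}
            for cp in causal_placements
        ],
        gene_haplotypes=gene_haps,
    )


def simulate_germination(cfg: SimConfig, truth: SimTruth) -> list[GerminationCounts]:
    """Daily germination counts and end-point lengths for every accession."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    out: list[GerminationCounts] = []
    for a in truth.subpopulation:
        L = truth.latent[a]
        for cond in ("control", "stress"):
            if cond == "control":
                mu = cfg.mu_control
            else:
                mu = max(1.0, cfg.mu_control + cfg.delta - cfg.gamma * L)
            for rep in range(1, cfg.n_replicates + 1):
                viable = rng.random(cfg.n_seeds) < cfg.viability
                days = np.round(
                    np.exp(rng.normal(np.log(mu), cfg.day_sd, cfg.n_seeds))
                ).astype(int)
                days = np.clip(days, 1, None)
                counts = np.zeros(N_DAYS, dtype=int)
                for d in days[viable]:
                    if d <= N_DAYS:
                        counts[d - 1] += 1
                if cond == "control":
                    rl = cfg.root_control_mean + rng.normal(0, cfg.length_noise_sd)
                    sl = cfg.shoot_control_mean + rng.normal(0, cfg.length_noise_sd)
                else:
                    rl = (cfg.root_stress_base + cfg.root_stress_slope * L
                          + rng.normal(0, cfg.length_noise_sd))
                    sl = (cfg.shoot_stress_base + cfg.shoot_stress_slope * L
                          + rng.normal(0, cfg.length_noise_sd))
                out.append(
                    GerminationCounts(
                        accession_id=a, condition=cond, replicate=rep,
                        n0=cfg.n_seeds, new_counts=counts,
                        root_length_cm=max(0.05, float(rl)),
                        shoot_length_cm=max(0.05, float(sl)),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def _make_annotations(
    cfg: SimConfig, genes: list[GeneModel], causal_ids: set[str]
) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    rows = []
    for g in genes:
        causal = g.gene_id in causal_ids
        stress = causal or rng.random() < 0.1
        text = (
            "abiotic stress response protein" if stress
            else "expressed protein, function unknown"
        )
        rows.append({"gene_id": g.gene_id, "functional_annotation": text,
                     "stress_related": stress})
    return pd.DataFrame(rows)


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Generate the complete synthetic study: genotypes, gene models,
    reference, phenotypes, metadata, annotations and truth."""
    variants, metadata = simulate_population(cfg)
    genes, reference, causal = simulate_gene_models(cfg, variants)
    truth = compute_latent_tolerance(cfg, variants, metadata, causal)
    counts = simulate_germination(cfg, truth)
    annotations = _make_annotations(cfg, genes, {c["gene_id"] for c in causal})
    return SimDataset(
        config=cfg, variants=variants, metadata=metadata, genes=genes,
        reference=reference, counts=counts, annotations=annotations,
        truth=truth,
    )


def write_dataset(ds: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset directory (VCF, GFF3, FASTA, TSVs, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "gff3": outdir / "genes.gff3",
        "fasta": outdir / "reference.fasta",
        "phenotypes": outdir / "phenotypes.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(ds.variants, paths["vcf"])
    write_gff3(ds.genes, paths["gff3"])
    write_fasta(ds.reference, paths["fasta"])
    write_phenotype_table(ds.counts, paths["phenotypes"])
    write_metadata(ds.metadata, paths["metadata"])
    write_annotations(ds.annotations, paths["annotations"])
    paths["truth"].write_text(ds.truth.to_json())
    return paths
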