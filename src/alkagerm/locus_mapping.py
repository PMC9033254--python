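"""From significant SNPs to loci, candidate genes and local LD blocks.

A locus is a greedy cluster of significant SNPs: repeatedly take the
unassigned SNP with the lowest p-value as lead and absorb every unassigned
significant SNP within 150 kb on either side on the same chromosome, so a
locus never spans more than 300 kb.  Loci from different traits and panels
are unified when their lead SNPs lie within the same window.

Candidate genes are the union of three criteria: (1) a significant SNP in a
gene annotated as abiotic-stress related, (2) a gene harbouring SNPs
significantly associated with more than three distinct traits, (3) per trait,
the gene of the most significant SNP provided p < 0.05 / N_eff.  A SNP in an
intergenic region is assigned to the next gene in ascending genomic
coordinates.

Local LD is summarized by composite haplotype-frequency D' and r^2 (inbred
accessions: one haplotype per genotype), and blocks are called with a
Gabriel-style confidence-interval rule on D'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GeneModel, VariantTable

logger = logging.getLogger(__name__)

LOCUS_HALF_WINDOW = 150_000  # bp on either side of the lead SNP


# ---------------------------------------------------------------------------
# locus clustering
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    locus_id: str
    chrom: str
    lead_snp: str
    lead_pos: int  # 1-based
    lead_p: float
    member_snps: list[str]
    span: tuple[int, int]  # 1-based inclusive over members
    associations: list[tuple[str, str]] = field(default_factory=list)  # (trait, panel)

    @property
    def n_traits(self) -> int:
        return len({t for t, _ in self.associations})


def cluster_loci(
    significant: pd.DataFrame,
    trait: str = "",
    panel: str = "",
    half_window: int = LOCUS_HALF_WINDOW,
) -> list[Locus]:
    """Greedy lead-SNP clustering of already-thresholded association rows.

    ``significant`` needs columns snp_id, chrom, pos, p.  Loci are labelled
    in order of discovery (decreasing significance of their leads).
    """
    df = significant.reset_index(drop=True)
    unassigned = np.ones(len(df), dtype=bool)
    out: list[Locus] = []
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    pvals = df["p"].to_numpy(dtype=float)
    while unassigned.any():
        cand = np.flatnonzero(unassigned)
        lead = cand[np.argmin(pvals[cand])]
        near = unassigned & (chrom == chrom[lead]) & (np.abs(pos - pos[lead]) <= half_window)
        members = np.flatnonzero(near)
        unassigned[members] = False
        out.append(
            Locus(
                locus_id=f"L{len(out) + 1:03d}",
                chrom=str(chrom[lead]),
                lead_snp=str(df.loc[lead, "snp_id"]),
                lead_pos=int(pos[lead]),
                lead_p=float(pvals[lead]),
                member_snps=df.loc[members, "snp_id"].tolist(),
                span=(int(pos[members].min()), int(pos[members].max())),
                associations=[(trait, panel)] if trait or panel else [],
            )
        )
    return out


def merge_across_traits(
    loci_by_run: dict[tuple[str, str], list[Locus]],
    half_window: int = LOCUS_HALF_WINDOW,
) -> pd.DataFrame:
    """Unify per-trait/panel loci whose lead SNPs lie within ``half_window``.

    Keys of ``loci_by_run`` are (trait, panel).  Returns a table with one row
    per unified locus: locus_id, chrom, lead SNP of the most significant
    member locus, members' lead SNPs, associations and their count.
    """
    entries = []
    for (trait, panel), loci in loci_by_run.items():
        for lc in loci:
            entries.append((lc.chrom, lc.lead_pos, lc.lead_p, lc.lead_snp, trait, panel))
    entries.sort(key=lambda e: e[2])  # by p, most significant first

    groups: list[list[tuple]] = []
    for e in entries:
        for grp in groups:
            head = grp[0]
            if e[0] == head[0] and abs(e[1] - head[1]) <= half_window:
                grp.append(e)
                break
        else:
            groups.append([e])

    groups.sort(key=lambda g: (int(g[0][0]) if str(g[0][0]).isdigit() else 10**9,
                               str(g[0][0]), g[0][1]))
    rows = []
    for i, grp in enumerate(groups):
        head = grp[0]
        assoc = sorted({(t, pnl) for *_x, t, pnl in grp})
        rows.append(
            {
                "locus_id": f"locus_{i + 1}",
                "chrom": head[0],
                "lead_snp": head[3],
                "lead_pos": head[1],
                "lead_p": head[2],
                "all_lead_snps": ",".join(sorted({g[3] for g in grp})),
                "associations": ";".join(f"{t}|{pnl}" for t, pnl in assoc),
                "n_associations": len(assoc),
                "n_traits": len({t for t, _ in assoc}),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SNP -> gene assignment
# ---------------------------------------------------------------------------

def annotate_snp_gene(
    chrom: str, pos0: int, genes: list[GeneModel]
) -> GeneModel | None:
    """Assign a SNP to its gene, or the next gene downstream in ascending
    genomic coordinates when intergenic; None past the last gene (logged)."""
    on_chrom = sorted(
        (g for g in genes if g.chrom == chrom), key=lambda g: g.span[0]
    )
    for g in on_chrom:
        if g.contains(pos0):
            return g
    following = [g for g in on_chrom if g.span[0] > pos0]
    if following:
        return following[0]
    logger.info("SNP %s:%d beyond the last gene on its chromosome", chrom, pos0 + 1)
    return None


# ---------------------------------------------------------------------------
# candidate-gene selection
# ---------------------------------------------------------------------------

@dataclass
class CandidateGene:
    gene_id: str
    criteria: set[int]
    best_snp: str
    best_p: float
    traits: set[str] = field(default_factory=set)
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("criterion set must be non-empty")


def select_candidate_genes(
    significant: pd.DataFrame,
    genes: list[GeneModel],
    annotations: pd.DataFrame | None,
    n_effective: int,
    min_traits_criterion2: int = 4,
) -> list[CandidateGene]:
    """Union of the three shortlisting criteria, with provenance.

    ``significant`` holds thresholded association rows across traits/panels
    (columns snp_id, chrom, pos, p, trait).  Criterion 2 requires a gene's
    significant SNPs to cover at least ``min_traits_criterion2`` distinct
    traits (default: strictly more than three).  Criterion 3 takes, per
    trait, the gene of the minimum-p SNP provided p < 0.05/N_eff.
    """
    ann_map: dict[str, tuple[str, bool]] = {}
    if annotations is not None:
        ann_map = {
            r.gene_id: (r.functional_annotation, bool(r.stress_related))
            for r in annotations.itertuples(index=False)
        }
    else:
        logger.warning("no annotation table: criterion 1 disabled")

    df = significant.reset_index(drop=True)
    assigned = [
        annotate_snp_gene(str(r.chrom), int(r.pos) - 1, genes)
        for r in df.itertuples(index=False)
    ]
    df = df.assign(gene_id=[g.gene_id if g else None for g in assigned])
    df = df[df["gene_id"].notna()]

    per_gene: dict[str, CandidateGene] = {}

    def add(gene_id: str, crit: int, snp: str, p: float, trait: str) -> None:
        cg = per_gene.get(gene_id)
        if cg is None:
            ann = ann_map.get(gene_id, ("", False))[0]
            per_gene[gene_id] = CandidateGene(
                gene_id=gene_id, criteria={crit}, best_snp=snp, best_p=p,
                traits={trait}, annotation=ann,
            )
        else:
            cg.criteria.add(crit)
            cg.traits.add(trait)
            if p < cg.best_p:
                cg.best_p, cg.best_snp = p, snp

    # criterion 1: significant SNP in a stress-annotated gene
    if annotations is not None:
        for r in df.itertuples(index=False):
            if ann_map.get(r.gene_id, ("", False))[1]:
                add(r.gene_id, 1, r.snp_id, float(r.p), str(r.trait))

    # criterion 2: gene significant for >= min_traits_criterion2 distinct traits
    trait_counts = df.groupby("gene_id")["trait"].nunique()
    for gene_id, k in trait_counts.items():
        if k >= min_traits_criterion2:
            sub = df[df["gene_id"] == gene_id]
            best = sub.loc[sub["p"].idxmin()]
            add(str(gene_id), 2, str(best["snp_id"]), float(best["p"]), str(best["trait"]))

    # criterion 3: per trait, the gene of the top SNP if p < 0.05/N_eff
    strict = 0.05 / n_effective
    for trait, sub in df.groupby("trait"):
        best = sub.loc[sub["p"].idxmin()]
        if float(best["p"]) < strict:
            add(str(best["gene_id"]), 3, str(best["snp_id"]), float(best["p"]), str(trait))

    return sorted(per_gene.values(), key=lambda c: c.best_p)


def overlap_percentage(n_overlapping: int, n_total: int) -> float:
    """Percentage of loci overlapping a reference set, 1-decimal rounded."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_overlapping / n_total, 1)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_statistics(variants: VariantTable) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise r^2 and |D'| from inbred genotypes (haplotype = dosage/2).

    Monomorphic SNPs yield NaN rows/columns.  Pairwise-complete observations.
    """
    if variants.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    m = variants.n_snps
    r2 = np.full((m, m), np.nan)
    dp = np.full((m, m), np.nan)
    hap = variants.dosages.astype(float) / 2.0
    hap[variants.dosages == MISSING] = np.nan
    hap[variants.dosages == 1] = np.nan  # heterozygous: ambiguous haplotype
    for i in range(m):
        r2[i, i] = dp[i, i] = 1.0
        for j in range(i + 1, m):
            ok = ~(np.isnan(hap[i]) | np.isnan(hap[j]))
            if ok.sum() < 2:
                continue
            a, b = hap[i, ok], hap[j, ok]
            pa, pb = a.mean(), b.mean()
            if pa in (0.0, 1.0) or pb in (0.0, 1.0):
                continue
            pab = (a * b).mean()
            d = pab - pa * pb
            r2[i, j] = r2[j, i] = d * d / (pa * (1 - pa) * pb * (1 - pb))
            dmax = min(pa * (1 - pb), (1 - pa) * pb) if d > 0 else min(pa * pb, (1 - pa) * (1 - pb))
            dp[i, j] = dp[j, i] = 1.0 if dmax == 0 else abs(d) / dmax
    return r2, dp


def _dprime_ci(
    n11: int, n12: int, n21: int, n22: int, grid: int = 101
) -> tuple[float, float]:
    """Likelihood-based 90% confidence bounds on |D'| from haplotype counts,
    the Haploview convention: profile the multinomial likelihood over |D'|
    with allele frequencies fixed at their sample values."""
    n = n11 + n12 + n21 + n22
    pa = (n11 + n12) / n
    pb = (n11 + n21) / n
    d = n11 / n - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
        sign = 1.0
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
        sign = -1.0
    if dmax <= 0:
        return 0.0, 1.0
    dps = np.linspace(0.0, 1.0, grid)
    eps = 1e-12
    ll = np.empty(grid)
    for k, dp in enumerate(dps):
        dd = sign * dp * dmax
        p11 = pa * pb + dd
        p12 = pa * (1 - pb) - dd
        p21 = (1 - pa) * pb - dd
        p22 = (1 - pa) * (1 - pb) + dd
        ps = np.clip([p11, p12, p21, p22], eps, None)
        ll[k] = n11 * np.log(ps[0]) + n12 * np.log(ps[1]) + n21 * np.log(ps[2]) + n22 * np.log(ps[3])
    lk = np.exp(ll - ll.max())
    cdf = np.cumsum(lk) / lk.sum()
    low = float(dps[np.searchsorted(cdf, 0.05)])
    high = float(dps[min(np.searchsorted(cdf, 0.95), grid - 1)])
    return low, high


@dataclass
class LDBlock:
    chrom: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    n_snps: int
    snp_ids: list[str] = field(default_factory=list)


def detect_ld_block(
    variants: VariantTable,
    anchor_pos: int,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    min_strong_fraction: float = 0.95,
    max_snps: int = 120,
) -> LDBlock:
    """Gabriel-style D' confidence-interval block containing the anchor SNP.

    ``anchor_pos`` is 1-based.  A pair is in strong LD when its |D'| CI is
    within [strong_low, strong_high+]; it shows strong recombination when the
    CI upper bound is below ``recomb_high``.  A candidate block [i, j] is
    accepted when its endpoint pair is strong and at least
    ``min_strong_fraction`` of its informative pairs are strong.  Falls back
    to a degenerate single-SNP block.
    """
    pos1 = variants.pos1
    anchor_idx = int(np.argmin(np.abs(pos1 - anchor_pos)))
    chrom = str(variants.snps["chrom"].iloc[anchor_idx])
    # restrict to a window of SNPs around the anchor to bound the pair count
    lo = max(0, anchor_idx - max_snps // 2)
    hi = min(variants.n_snps, anchor_idx + max_snps // 2 + 1)
    sel = np.arange(lo, hi)
    sel = sel[variants.snps["chrom"].to_numpy()[sel] == chrom]
    sub = variants.take_snps(sel)
    a_local = int(np.argmin(np.abs(sub.pos1 - anchor_pos)))

    hap = sub.dosages.astype(float) / 2.0
    hap[(sub.dosages == MISSING) | (sub.dosages == 1)] = np.nan
    m = sub.n_snps

    ci = {}
    def bounds(i: int, j: int):
        if (i, j) not in ci:
            ok = ~(np.isnan(hap[i]) | np.isnan(hap[j]))
            a, b = hap[i, ok], hap[j, ok]
            if len(a) < 2 or a.std() == 0 or b.std() == 0:
                ci[(i, j)] = None
            else:
                n11 = int(((a == 1) & (b == 1)).sum())
                n12 = int(((a == 1) & (b == 0)).sum())
                n21 = int(((a == 0) & (b == 1)).sum())
                n22 = int(((a == 0) & (b == 0)).sum())
                ci[(i, j)] = _dprime_ci(n11, n12, n21, n22)
        return ci[(i, j)]

    def classify(i: int, j: int) -> str:
        b = bounds(i, j)
        if b is None:
            return "uninformative"
        low, high = b
        if low >= strong_low and high >= strong_high:
            return "strong"
        if high < recomb_high:
            return "recomb"
        return "uninformative"

    best = None
    # examine candidate spans containing the anchor, longest first
    spans = [
        (i, j)
        for i in range(0, a_local + 1)
        for j in range(a_local, m)
        if j > i
    ]
    spans.sort(key=lambda s: (s[1] - s[0]), reverse=True)
    for i, j in spans:
        if best is not None and (j - i) < (best[1] - best[0]):
            break
        if classify(i, j) != "strong":
            continue
        n_strong = n_inform = 0
        for x in range(i, j + 1):
            for y in range(x + 1, j + 1):
                c = classify(x, y)
                if c == "strong":
                    n_strong += 1
                    n_inform += 1
                elif c == "recomb":
                    n_inform += 1
        if n_inform > 0 and n_strong / n_inform >= min_strong_fraction:
            best = (i, j)
            break
    if best is None:
        best = (a_local, a_local)
    i, j = best
    return LDBlock(
        chrom=chrom,
        start=int(sub.pos1[i]),
        end=int(sub.pos1[j]),
        n_snps=j - i + 1,
        snp_ids=sub.snps["snp_id"].iloc[i : j + 1].tolist(),
    )
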