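"""Gene-CDS-haplotype analysis and favorable-haplotype pyramiding.

A gene's haplotype is the vector of alleles its accession carries at the
gene's *non-synonymous* coding SNPs (synonymous sites are ignored, so
accessions differing only at synonymous SNPs merge into one haplotype).
Accessions heterozygous or missing at any defining SNP are excluded from
that gene's assignment — the panels this targets are inbred, so losses are
small.  Haplotypes carried by at least ``min_size`` accessions (default 10)
enter phenotypic comparisons; smaller ones are pooled as rare.

Haplotype phenotypes are compared by one-way ANOVA with Duncan's multiple
range test: ordered means p steps apart are compared against the critical
range q(alpha_p, p, df) * sqrt(MSE / n_h), with the step-down protection
level alpha_p = 1 - (1-alpha)^(p-1), exact studentized-range quantiles and
the harmonic mean group size n_h.  Pyramiding groups accessions by their
favorable(+)/inferior(-) haplotype pattern across several genes and compares
group means with Fisher's LSD letters.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .io_formats import MISSING, GeneModel, VariantTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# CDS SNP classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CdsSnpEffect:
    snp_id: str
    gene_id: str
    cds_offset: int           # 0-based offset in transcript orientation
    codon_index: int          # 0-based codon number
    codon_position: int       # 1, 2 or 3
    ref_aa: str
    alt_aa: str
    effect: str               # synonymous | missense | nonsense | start_loss

    @property
    def is_synonymous(self) -> bool:
        return self.effect == "synonymous"


def _cds_sequence(gene: GeneModel, reference: Mapping[str, str]) -> str:
    chrom_seq = reference[gene.chrom]
    parts = []
    for s, e in gene.cds_segments:  # already transcript-ordered
        seg = chrom_seq[s:e]
        if gene.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        parts.append(seg)
    return "".join(parts)


def classify_cds_snps(
    gene: GeneModel,
    reference: Mapping[str, str],
    variants: VariantTable,
) -> list[CdsSnpEffect]:
    """Codon-aware effect classification of the SNPs inside a gene's CDS.

    Strand-aware: on the minus strand alleles are complemented and offsets
    follow transcript orientation.  Raises if the reference base disagrees
    with a SNP's REF allele.
    """
    cds = _cds_sequence(gene, reference)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length of {gene.gene_id} not divisible by 3")
    out: list[CdsSnpEffect] = []
    snps = variants.snps
    on_chrom = snps.index[snps["chrom"] == gene.chrom]
    for i in on_chrom:
        pos0 = int(snps.at[i, "pos0"])
        off = gene.cds_offset(pos0)
        if off is None:
            continue
        ref = str(snps.at[i, "ref"])
        alt = str(snps.at[i, "alt"])
        genomic_base = reference[gene.chrom][pos0]
        if genomic_base != ref:
            raise ValueError(
                f"reference base {genomic_base!r} != VCF REF {ref!r} "
                f"for SNP {snps.at[i, 'snp_id']}"
            )
        t_ref, t_alt = ref, alt
        if gene.strand == "-":
            t_ref = str(Seq(ref).reverse_complement())
            t_alt = str(Seq(alt).reverse_complement())
        ci = off // 3
        cp = off % 3
        codon = cds[3 * ci : 3 * ci + 3]
        assert codon[cp] == t_ref
        alt_codon = codon[:cp] + t_alt + codon[cp + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            effect = "synonymous"
        elif ci == 0 and codon == "ATG":
            effect = "start_loss"
        elif alt_aa == "*":
            effect = "nonsense"
        else:
            effect = "missense"
        out.append(
            CdsSnpEffect(
                snp_id=str(snps.at[i, "snp_id"]), gene_id=gene.gene_id,
                cds_offset=off, codon_index=ci, codon_position=cp + 1,
                ref_aa=ref_aa, alt_aa=alt_aa, effect=effect,
            )
        )
    out.sort(key=lambda e: e.cds_offset)
    return out


# ---------------------------------------------------------------------------
# haplotype construction
# ---------------------------------------------------------------------------

@dataclass
class CdsHaplotype:
    gene_id: str
    label: str                      # Hap1, Hap2, ... or "rare"
    defining_snps: list[str]
    alleles: tuple[str, ...]        # allele per defining SNP
    members: list[str]

    @property
    def n(self) -> int:
        return len(self.members)


def build_haplotypes(
    gene: GeneModel,
    effects: Sequence[CdsSnpEffect],
    variants: VariantTable,
    min_size: int = 10,
) -> tuple[list[CdsHaplotype], list[str]]:
    """Group accessions by their alleles at the gene's non-synonymous CDS SNPs.

    Returns (haplotypes, excluded accession ids).  Haplotypes with at least
    ``min_size`` members are labelled Hap1, Hap2, ... by descending size;
    the rest are pooled under the label "rare".  Accessions heterozygous or
    missing at any defining SNP are excluded (count logged).
    """
    defining = [e for e in effects if not e.is_synonymous]
    if not defining:
        logger.info("gene %s has no non-synonymous CDS SNP", gene.gene_id)
        return [], []
    ids = [e.snp_id for e in defining]
    rows = np.vstack([variants.dosage_of(s) for s in ids])
    snp_meta = variants.snps.set_index("snp_id").loc[ids]

    assignments: dict[tuple[str, ...], list[str]] = {}
    excluded: list[str] = []
    for k, acc in enumerate(variants.samples):
        dos = rows[:, k]
        if ((dos == MISSING) | (dos == 1)).any():
            excluded.append(acc)
            continue
        key = tuple(
            str(snp_meta["alt"].iloc[j]) if dos[j] == 2 else str(snp_meta["ref"].iloc[j])
            for j in range(len(ids))
        )
        assignments.setdefault(key, []).append(acc)
    if excluded:
        logger.info(
            "gene %s: %d accession(s) excluded (het/missing at defining SNPs)",
            gene.gene_id, len(excluded),
        )

    ordered = sorted(assignments.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    haps: list[CdsHaplotype] = []
    rare_members: list[str] = []
    rank = 0
    for key, members in ordered:
        if len(members) >= min_size:
            rank += 1
            haps.append(
                CdsHaplotype(
                    gene_id=gene.gene_id, label=f"Hap{rank}",
                    defining_snps=ids, alleles=key, members=members,
                )
            )
        else:
            rare_members.extend(members)
    if rare_members:
        haps.append(
            CdsHaplotype(
                gene_id=gene.gene_id, label="rare", defining_snps=ids,
                alleles=(), members=sorted(rare_members),
            )
        )
    return haps, excluded


def haplotype_subpop_frequencies(
    haps: Sequence[CdsHaplotype], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Haplotype x subpopulation member counts and within-subpop proportions."""
    sub = metadata.set_index("accession_id")["subpopulation"]
    rows = []
    for h in haps:
        counts = sub.reindex(h.members).value_counts()
        for pop, cnt in counts.items():
            rows.append({"haplotype": h.label, "subpopulation": pop, "count": int(cnt)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    totals = df.groupby("subpopulation")["count"].transform("sum")
    df["proportion"] = df["count"] / totals
    return df


# ---------------------------------------------------------------------------
# multiple-comparison letter displays
# ---------------------------------------------------------------------------

def letters_from_significance(
    labels: Sequence[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    ``labels`` must be ordered (by descending mean); ``significant`` holds
    unordered pairs declared different.  Groups sharing a letter are never a
    significant pair.
    """
    sig = {frozenset(p) for p in significant}
    columns: list[set[str]] = [set(labels)]
    for a, b in itertools.combinations(labels, 2):
        if frozenset((a, b)) not in sig:
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb: drop columns contained in another
        columns = [
            c for c in columns
            if c and not any(c < other for other in columns if other is not c)
        ]
    # deduplicate and order columns by the best-ranked member
    uniq: list[set[str]] = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    rank = {lab: i for i, lab in enumerate(labels)}
    uniq.sort(key=lambda c: min(rank[x] for x in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, col in enumerate(uniq):
        for lab in labels:
            if lab in col:
                out[lab] += alphabet[i % len(alphabet)]
    assert all(out.values()), "letter display left a group empty"
    return out


@dataclass
class DuncanResult:
    """Duncan multiple-range comparison of group means."""

    means: dict[str, float]
    ns: dict[str, int]
    letters: dict[str, str]
    anova_f: float
    anova_p: float
    alpha: float
    mse: float
    df_error: int
    critical_ranges: dict[int, float]  # span p -> least significant range


def _anova_mse(groups: Mapping[str, np.ndarray]) -> tuple[float, int, float, float]:
    vals = list(groups.values())
    all_v = np.concatenate(vals)
    n, k = len(all_v), len(vals)
    df_err = n - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in vals)
    mse = sse / df_err if df_err > 0 else 0.0
    grand = all_v.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in vals)
    if df_err > 0 and mse > 0:
        f = (ssb / (k - 1)) / mse
        p = float(stats.f.sf(f, k - 1, df_err))
    else:
        f, p = math.inf if ssb > 0 else 0.0, 0.0 if ssb > 0 else 1.0
    return mse, df_err, float(f), p


def duncan_mrt(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> DuncanResult:
    """Duncan's multiple range test with a compact letter display.

    Groups are ordered by descending mean; the critical range for means p
    steps apart uses the studentized-range quantile at the protected level
    alpha_p = 1-(1-alpha)^(p-1) and the harmonic mean group size.  With zero
    residual variance, groups with unequal means are all declared different.
    """
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrs) < 2 or any(len(v) < 2 for v in arrs.values()):
        raise ValueError("need >=2 groups with >=2 observations each")
    mse, df_err, f, p_anova = _anova_mse(arrs)
    means = {k: float(v.mean()) for k, v in arrs.items()}
    order = sorted(means, key=lambda k: -means[k])
    k = len(order)
    n_h = k / sum(1.0 / len(arrs[g]) for g in order)  # harmonic mean size

    ranges: dict[int, float] = {}
    for span in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_p, span, df_err)
        ranges[span] = float(q * math.sqrt(mse / n_h))

    significant: set[tuple[str, str]] = set()
    for i in range(k):
        for j in range(i + 1, k):
            span = j - i + 1
            diff = means[order[i]] - means[order[j]]
            if mse == 0:
                if diff > 0:
                    significant.add((order[i], order[j]))
                continue
            if diff > ranges[span]:
                significant.add((order[i], order[j]))
    # step-down protection: a difference inside a homogeneous (non-significant)
    # wider range is not declared significant
    for i in range(k):
        for j in range(i + 1, k):
            if (order[i], order[j]) in significant:
                continue
            for x in range(i, j + 1):
                for y in range(x + 1, j + 1):
                    significant.discard((order[x], order[y]))

    letters = letters_from_significance(order, significant)
    return DuncanResult(
        means=means, ns={g: len(arrs[g]) for g in order}, letters=letters,
        anova_f=f, anova_p=p_anova, alpha=alpha, mse=mse, df_error=df_err,
        critical_ranges=ranges,
    )


# ---------------------------------------------------------------------------
# favorable haplotypes and pyramiding
# ---------------------------------------------------------------------------

def favorable_haplotype(
    haps: Sequence[CdsHaplotype], trait_values: Mapping[str, float]
) -> str:
    """Label of the retained haplotype with the highest mean trait value
    (the ratio trait most sensitive to stress, RGE, by convention).

    Ties break toward larger membership, then the lower haplotype index.
    """
    scored = []
    for h in haps:
        if h.label == "rare":
            continue
        vals = [trait_values[a] for a in h.members
                if a in trait_values and not math.isnan(trait_values[a])]
        if vals:
            scored.append((float(np.mean(vals)), h.n, -int(h.label[3:]), h.label))
    if len(scored) < 2:
        raise ValueError("need >=2 retained haplotypes with trait data")
    scored.sort(reverse=True)
    return scored[0][3]


@dataclass
class HaplotypeCombination:
    pattern: str                 # e.g. "++-" across the gene list
    members: list[str]
    mean_trait: float
    n_favorable: int
    letter: str = ""

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class CombinationResult:
    genes: list[str]
    groups: list[HaplotypeCombination]   # ordered by descending mean
    anova_f: float
    anova_p: float
    spearman_rho: float                  # favorable count vs group mean
    dropped_small: int


def combine_haplotypes(
    haps_by_gene: Mapping[str, Sequence[CdsHaplotype]],
    favorable_by_gene: Mapping[str, str],
    trait_values: Mapping[str, float],
    min_group: int = 15,
    alpha: float = 0.05,
) -> CombinationResult:
    """Pyramiding analysis over the favorable/inferior haplotype patterns.

    Accessions are grouped by their "+"/"-" flag per gene (favorable means
    carrying that gene's favorable haplotype); accessions missing any gene's
    assignment are excluded.  Groups smaller than ``min_group`` are dropped.
    Group means are compared by one-way ANOVA with Fisher's-LSD letters at
    ``alpha`` (pooled MSE), and the rank correlation between the number of
    favorable haplotypes and the group mean is reported.
    """
    genes = sorted(haps_by_gene)
    assign: dict[str, dict[str, str]] = {}
    for g in genes:
        m = {}
        for h in haps_by_gene[g]:
            if h.label == "rare":
                continue
            for acc in h.members:
                m[acc] = h.label
        assign[g] = m

    patterns: dict[str, list[str]] = {}
    for acc in set.intersection(*(set(assign[g]) for g in genes)):
        if acc not in trait_values or math.isnan(trait_values[acc]):
            continue
        pat = "".join(
            "+" if assign[g][acc] == favorable_by_gene[g] else "-" for g in genes
        )
        patterns.setdefault(pat, []).append(acc)

    kept = {p: m for p, m in patterns.items() if len(m) >= min_group}
    dropped = len(patterns) - len(kept)
    groups = [
        HaplotypeCombination(
            pattern=p, members=sorted(m),
            mean_trait=float(np.mean([trait_values[a] for a in m])),
            n_favorable=p.count("+"),
        )
        for p, m in kept.items()
    ]
    groups.sort(key=lambda g: -g.mean_trait)

    if len(groups) < 2:
        return CombinationResult(
            genes=genes, groups=groups, anova_f=math.nan, anova_p=math.nan,
            spearman_rho=math.nan, dropped_small=dropped,
        )

    arrs = {
        g.pattern: np.array([trait_values[a] for a in g.members]) for g in groups
    }
    mse, df_err, f, p_anova = _anova_mse(arrs)
    order = [g.pattern for g in groups]
    significant: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(order, 2):
        na, nb = len(arrs[a]), len(arrs[b])
        se = math.sqrt(mse * (1.0 / na + 1.0 / nb))
        if se == 0:
            if arrs[a].mean() != arrs[b].mean():
                significant.add((a, b))
            continue
        t = (arrs[a].mean() - arrs[b].mean()) / se
        if 2.0 * stats.t.sf(abs(t), df_err) < alpha:
            significant.add((a, b))
    letters = letters_from_significance(order, significant)
    for g in groups:
        g.letter = letters[g.pattern]

    rho = stats.spearmanr(
        [g.n_favorable for g in groups], [g.mean_trait for g in groups]
    ).statistic
    return CombinationResult(
        genes=genes, groups=groups, anova_f=f, anova_p=p_anova,
        spearman_rho=float(rho), dropped_small=dropped,
    )


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def expression_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per condition; ddCt = dCt_treated -
    dCt_control; fold change = 2^-ddCt.
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
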