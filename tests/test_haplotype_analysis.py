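"""CDS SNP effects, haplotype construction, Duncan letters, pyramiding."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from scipy import stats

from alkagerm import haplotype_analysis as ha
from alkagerm.io_formats import MISSING, GeneModel
from tests.conftest import make_variant_table


def gene_with_cds(seq, chrom="1", strand="+", offset=100):
    """Place ``seq`` (a CDS in transcript orientation) on the genome."""
    genomic = seq if strand == "+" else str(Seq(seq).reverse_complement())
    reference = {chrom: "A" * offset + genomic + "T" * 50}
    gene = GeneModel(
        gene_id="gX", chrom=chrom, strand=strand,
        span=(offset - 10, offset + len(seq) + 10),
        cds_segments=[(offset, offset + len(seq))],
    )
    return gene, reference


def snp_table(entries, chrom="1"):
    """entries: list of (pos0, ref, alt); one haploid sample, all-ref."""
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(entries))],
            "chrom": chrom,
            "pos0": [e[0] for e in entries],
            "ref": [e[1] for e in entries],
            "alt": [e[2] for e in entries],
        }
    )
    d = np.zeros((len(entries), 1), dtype=np.int8)
    return make_variant_table(d, chrom=chrom).__class__(snps, d, ["S001"])


class TestClassifyCdsSnps:
    def test_plus_strand_examples(self):
        # codons: ATG GGA AAA TAA; third-position GGA->GGG synonymous,
        # second-position AAA->AGA missense
        gene, ref = gene_with_cds("ATGGGAAAATAA")
        vt = snp_table([(105, "A", "G"), (107, "A", "G")])
        effects = ha.classify_cds_snps(gene, ref, vt)
        by_id = {e.snp_id: e for e in effects}
        assert by_id["s0"].effect == "synonymous"
        assert (by_id["s0"].ref_aa, by_id["s0"].alt_aa) == ("G", "G")
        assert by_id["s1"].effect == "missense"
        assert (by_id["s1"].ref_aa, by_id["s1"].alt_aa) == ("K", "R")

    def test_minus_strand_glu_to_lys(self):
        # transcript codons ATG GAA TAA; genomic C->T at the G of GAA
        # (transcript G->A, codon position 1): GAA (E) -> AAA (K)
        gene, ref = gene_with_cds("ATGGAATAA", strand="-")
        # transcript offset 3 -> genomic position offset+len-1-3
        pos0 = 100 + 9 - 1 - 3
        assert ref["1"][pos0] == "C"
        vt = snp_table([(pos0, "C", "T")])
        (eff,) = ha.classify_cds_snps(gene, ref, vt)
        assert eff.effect == "missense"
        assert (eff.ref_aa, eff.alt_aa) == ("E", "K")
        assert eff.codon_position == 1
        # brute force: translate the fully mutated CDS
        mutated = ref["1"][:pos0] + "T" + ref["1"][pos0 + 1:]
        cds_mut = str(Seq(mutated[100:109]).reverse_complement())
        assert str(Seq(cds_mut).translate()) == "MK*"

    def test_nonsense_and_reference_mismatch(self):
        gene, ref = gene_with_cds("ATGTACAAATAA")
        vt = snp_table([(104, "A", "G")])  # TAC -> TGC missense
        (eff,) = ha.classify_cds_snps(gene, ref, vt)
        assert eff.effect == "missense"
        bad = snp_table([(104, "C", "G")])
        with pytest.raises(ValueError, match="s0"):
            ha.classify_cds_snps(gene, ref, bad)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_mutations_match_whole_cds_translation(self, strand):
        """Codon-level classification vs brute-force full-CDS translation."""
        rng = np.random.default_rng(0 if strand == "+" else 1)
        hits = 0
        while hits < 60:
            n_codons = int(rng.integers(4, 30))
            interior = "".join(rng.choice(list("ACGT"), 3 * (n_codons - 2)))
            cds = "ATG" + interior + "TAA"
            prot = str(Seq(cds).translate())
            if "*" in prot[:-1] or not prot.endswith("*"):
                continue
            off = int(rng.integers(3, len(cds) - 3))
            t_ref = cds[off]
            t_alt = str(rng.choice([b for b in "ACGT" if b != t_ref]))
            gene, ref = gene_with_cds(cds, strand=strand)
            if strand == "+":
                pos0 = 100 + off
                g_ref, g_alt = t_ref, t_alt
            else:
                pos0 = 100 + len(cds) - 1 - off
                g_ref = str(Seq(t_ref).reverse_complement())
                g_alt = str(Seq(t_alt).reverse_complement())
            vt = snp_table([(pos0, g_ref, g_alt)])
            (eff,) = ha.classify_cds_snps(gene, ref, vt)
            mut_cds = cds[:off] + t_alt + cds[off + 1:]
            mut_prot = str(Seq(mut_cds).translate())
            assert (eff.effect == "synonymous") == (prot == mut_prot)
            assert eff.ref_aa == prot[off // 3]
            assert eff.alt_aa == mut_prot[off // 3]
            hits += 1


class TestBuildHaplotypes:
    def _panel(self, patterns):
        """patterns: list of (dosage pair, count) over 2 defining SNPs."""
        cols = []
        for (d1, d2), k in patterns:
            cols += [[d1, d2]] * k
        d = np.array(cols, dtype=np.int8).T
        gene, ref = gene_with_cds("ATGAAAAAATAA")
        vt = snp_table([(104, "A", "G"), (107, "A", "C")])
        vt = vt.__class__(vt.snps, np.array(d), [f"S{i:03d}" for i in range(d.shape[1])])
        effects = ha.classify_cds_snps(gene, ref, vt)
        assert all(not e.is_synonymous for e in effects)
        return gene, effects, vt

    def test_hand_counted_grouping(self):
        gene, effects, vt = self._panel([((0, 0), 15), ((2, 2), 12), ((0, 2), 3)])
        haps, excluded = ha.build_haplotypes(gene, effects, vt, min_size=10)
        by_label = {h.label: h for h in haps}
        assert by_label["Hap1"].n == 15 and by_label["Hap1"].alleles == ("A", "A")
        assert by_label["Hap2"].n == 12 and by_label["Hap2"].alleles == ("G", "C")
        assert by_label["rare"].n == 3
        assert excluded == []

    def test_het_and_missing_excluded(self):
        gene, effects, vt = self._panel([((0, 0), 12), ((1, 0), 1), ((2, 2), 12)])
        vt.dosages[0, 0] = MISSING
        haps, excluded = ha.build_haplotypes(gene, effects, vt, min_size=10)
        assert len(excluded) == 2
        assert sum(h.n for h in haps) + len(excluded) == vt.n_samples

    def test_synonymous_only_variation_merges(self):
        gene, ref = gene_with_cds("ATGGGAGGATAA")
        vt = snp_table([(105, "A", "G"), (108, "A", "G")])  # both 3rd-position Gly
        d = np.array([[0, 2, 0], [0, 0, 2]], dtype=np.int8)
        vt = vt.__class__(vt.snps, d, ["a", "b", "c"])
        effects = ha.classify_cds_snps(gene, ref, vt)
        assert all(e.is_synonymous for e in effects)
        haps, _ = ha.build_haplotypes(gene, effects, vt)
        assert haps == []  # no defining SNPs at all

    def test_partition_property(self, small_dataset):
        cp = small_dataset.truth.causal_snps[0]
        gene = next(g for g in small_dataset.genes if g.gene_id == cp["gene_id"])
        effects = ha.classify_cds_snps(gene, small_dataset.reference, small_dataset.variants)
        haps, excluded = ha.build_haplotypes(gene, effects, small_dataset.variants)
        all_members = [a for h in haps for a in h.members]
        assert len(all_members) == len(set(all_members))
        assert len(all_members) + len(excluded) == small_dataset.variants.n_samples


# ---------------------------------------------------------------------------
# Duncan oracle: an independent re-derivation of the letter display
# ---------------------------------------------------------------------------

def duncan_oracle_letters(groups, alpha=0.05):
    """Brute-force Duncan grouping: enumerate every contiguous segment of the
    ordered means, mark it homogeneous when its range is below the critical
    range for its span (step-down: contained pairs are then never separated),
    and emit one letter per maximal homogeneous segment."""
    arrs = {k: np.asarray(v, float) for k, v in groups.items()}
    means = {k: v.mean() for k, v in arrs.items()}
    order = sorted(means, key=lambda k: -means[k])
    k = len(order)
    n = sum(len(v) for v in arrs.values())
    mse = sum(((v - v.mean()) ** 2).sum() for v in arrs.values()) / (n - k)
    n_h = k / sum(1 / len(arrs[g]) for g in order)

    def crit(span):
        a_p = 1 - (1 - alpha) ** (span - 1)
        return stats.studentized_range.ppf(1 - a_p, span, n - k) * math.sqrt(mse / n_h)

    homog = set()
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[order[i]] - means[order[j]]
            if (mse == 0 and diff == 0) or (mse > 0 and diff <= crit(j - i + 1)):
                homog.add((i, j))
    # step-down closure: segments inside a homogeneous segment are homogeneous
    changed = True
    while changed:
        changed = False
        for (i, j) in list(homog):
            for x in range(i, j + 1):
                for y in range(x + 1, j + 1):
                    if (x, y) not in homog:
                        homog.add((x, y))
                        changed = True
    # maximal homogeneous segments (single groups count when uncovered)
    segments = []
    for i in range(k):
        best = i
        for j in range(i + 1, k):
            if all((x, y) in homog for x in range(i, j + 1) for y in range(x + 1, j + 1)):
                best = j
        segments.append((i, best))
    maximal = [s for s in segments
               if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in segments)]
    letters = {g: "" for g in order}
    for idx, (i, j) in enumerate(sorted(set(maximal))):
        for g in order[i : j + 1]:
            letters[g] += "abcdefghijklmnopqrstuvwxyz"[idx]
    return letters


def assert_same_grouping(lhs, rhs):
    """Letter strings are display labels; compare the induced partitions of
    'shares a letter' pairs instead of the raw strings."""
    keys = sorted(lhs)
    assert keys == sorted(rhs)
    for a, b in itertools.combinations(keys, 2):
        shares_l = bool(set(lhs[a]) & set(lhs[b]))
        shares_r = bool(set(rhs[a]) & set(rhs[b]))
        assert shares_l == shares_r, (a, b, lhs, rhs)


class TestDuncanMrt:
    def test_identical_groups_share_one_letter(self):
        g = {f"H{i}": [1.0, 1.1, 0.9, 1.0] for i in range(3)}
        res = ha.duncan_mrt(g)
        assert set(res.letters.values()) == {"a"}
        assert res.anova_p > 0.9

    def test_well_separated_means_all_distinct(self):
        rng = np.random.default_rng(0)
        g = {
            "A": rng.normal(0, 1, 10),
            "B": rng.normal(10, 1, 10),
            "C": rng.normal(20, 1, 10),
        }
        res = ha.duncan_mrt(g)
        assert sorted(res.letters.values()) == ["a", "b", "c"]
        assert res.letters[max(res.means, key=res.means.get)] == "a"

    @pytest.mark.parametrize("seed,k,sep", [(1, 3, 0.8), (2, 4, 0.5), (3, 5, 1.2), (4, 4, 0.0)])
    def test_matches_independent_oracle(self, seed, k, sep):
        rng = np.random.default_rng(seed)
        groups = {
            f"H{i}": rng.normal(sep * i, 1.0, int(rng.integers(8, 20)))
            for i in range(k)
        }
        res = ha.duncan_mrt(groups)
        assert_same_grouping(res.letters, duncan_oracle_letters(groups))

    def test_letter_separation_respects_critical_range(self):
        rng = np.random.default_rng(9)
        groups = {f"H{i}": rng.normal(0.4 * i, 1.0, 12) for i in range(5)}
        res = ha.duncan_mrt(groups)
        order = sorted(res.means, key=lambda g: -res.means[g])
        for i, a in enumerate(order):
            for j in range(i + 1, len(order)):
                b = order[j]
                if not set(res.letters[a]) & set(res.letters[b]):
                    span = j - i + 1
                    assert res.means[a] - res.means[b] > res.critical_ranges[span]

    def test_zero_variance_unequal_means(self):
        res = ha.duncan_mrt({"A": [1.0, 1.0], "B": [2.0, 2.0]})
        assert not set(res.letters["A"]) & set(res.letters["B"])


class TestFavorable:
    def _hap(self, label, members):
        return ha.CdsHaplotype("g", label, ["s0"], ("A",), members)

    def test_highest_mean_wins(self):
        haps = [self._hap("Hap1", ["a", "b"]), self._hap("Hap2", ["c", "d"])]
        vals = {"a": 0.3, "b": 0.3, "c": 0.18, "d": 0.18}
        assert ha.favorable_haplotype(haps, vals) == "Hap1"

    def test_tie_breaks_to_larger_n_then_label(self):
        haps = [
            self._hap("Hap1", ["a", "b"]),
            self._hap("Hap2", ["c", "d", "e"]),
        ]
        vals = dict.fromkeys("abcde", 0.5)
        assert ha.favorable_haplotype(haps, vals) == "Hap2"
        haps2 = [self._hap("Hap1", ["a", "b"]), self._hap("Hap2", ["c", "d"])]
        assert ha.favorable_haplotype(haps2, vals) == "Hap1"

    def test_subpop_frequencies_sum_to_one(self):
        md = pd.DataFrame({
            "accession_id": list("abcdef"),
            "subpopulation": ["Xian"] * 3 + ["Geng"] * 3,
        })
        haps = [self._hap("Hap1", ["a", "b", "d"]), self._hap("rare", ["c", "e", "f"])]
        freq = ha.haplotype_subpop_frequencies(haps, md)
        sums = freq.groupby("subpopulation")["proportion"].sum()
        assert np.allclose(sums, 1.0)
        xian_hap1 = freq.query("haplotype=='Hap1' and subpopulation=='Xian'")
        assert float(xian_hap1["proportion"].iloc[0]) == pytest.approx(2 / 3)


class TestCombineHaplotypes:
    def _setup(self, counts, rng):
        """counts: dict pattern -> n; builds 2-gene haplotypes + trait."""
        haps = {"g1": {}, "g2": {}}
        trait = {}
        members = {p: [] for p in counts}
        i = 0
        for pat, n in counts.items():
            for _ in range(n):
                acc = f"a{i}"; i += 1
                members[pat].append(acc)
                trait[acc] = pat.count("+") * 0.1 + rng.normal(0, 0.02)
        def hap(gene, label, accs):
            return ha.CdsHaplotype(gene, label, ["s"], (label,), accs)
        g1_fav = [a for p, m in members.items() for a in m if p[0] == "+"]
        g1_inf = [a for p, m in members.items() for a in m if p[0] == "-"]
        g2_fav = [a for p, m in members.items() for a in m if p[1] == "+"]
        g2_inf = [a for p, m in members.items() for a in m if p[1] == "-"]
        haps_by_gene = {
            "g1": [hap("g1", "Hap1", g1_fav), hap("g1", "Hap2", g1_inf)],
            "g2": [hap("g2", "Hap1", g2_fav), hap("g2", "Hap2", g2_inf)],
        }
        fav = {"g1": "Hap1", "g2": "Hap1"}
        return haps_by_gene, fav, trait

    def test_small_groups_dropped_strictly(self):
        rng = np.random.default_rng(0)
        haps, fav, trait = self._setup({"++": 20, "+-": 14, "--": 25}, rng)
        res = ha.combine_haplotypes(haps, fav, trait, min_group=15)
        assert {g.pattern for g in res.groups} == {"++", "--"}
        assert res.dropped_small == 1

    def test_single_pattern_reports_without_test(self):
        rng = np.random.default_rng(1)
        haps, fav, trait = self._setup({"++": 30}, rng)
        res = ha.combine_haplotypes(haps, fav, trait)
        assert len(res.groups) == 1
        assert math.isnan(res.anova_f)

    def test_additive_architecture_monotone(self):
        rng = np.random.default_rng(2)
        haps, fav, trait = self._setup(
            {"++": 25, "+-": 25, "-+": 25, "--": 25}, rng
        )
        res = ha.combine_haplotypes(haps, fav, trait)
        assert res.spearman_rho > 0
        assert res.groups[0].pattern == "++"
        # LSD letters separate the extremes with this tight within-group sd
        assert not set(res.groups[0].letter) & set(res.groups[-1].letter)


@pytest.mark.parametrize(
    "ct,expected",
    [
        ((7.0, 2.0, 6.0, 3.0), 0.25),  # dCt 5 vs 3 -> fold 2^-2
        ((5.0, 2.0, 6.0, 3.0), 1.0),
        ((4.0, 2.0, 6.0, 3.0), 2.0),
    ],
)
def test_expression_fold_change(ct, expected):
    assert ha.expression_fold_change(*ct) == pytest.approx(expected)
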