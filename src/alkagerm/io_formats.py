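"""Readers and writers for the formats the pipeline touches.

Coordinate convention: VCF and GFF3 are 1-based (GFF3 end-inclusive) on disk;
everything in memory is 0-based half-open.  The conversion happens here and
only here — ``to_internal`` / ``to_gff3`` are the two boundary functions.

Genotypes are biallelic-SNP dosages (alt-allele counts 0/1/2) for inbred
diversity panels; multi-allelic records and indels are skipped, not split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .germination_traits import N_DAYS, CONDITIONS, GerminationCounts

logger = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel
NUCLEOTIDES = frozenset("ACGT")
SUBPOPULATIONS = ("Xian", "Geng", "Aus", "Basmati", "admix")


def to_internal(start1: int, end1_inclusive: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start1 - 1, end1_inclusive


def to_gff3(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Biallelic SNP dosage matrix with per-SNP metadata.

    ``snps``: DataFrame with columns snp_id, chrom, pos0, ref, alt (pos0 is
    the 0-based position).  ``dosages``: int8 array of shape
    (n_snps, n_samples), alt-allele counts with -1 for missing.
    """

    snps: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.snps), len(self.samples)):
            raise ValueError("dosage matrix shape does not match snps/samples")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")
        self._validate_sorted()

    def _validate_sorted(self) -> None:
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos0"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def pos1(self) -> np.ndarray:
        """1-based positions (I/O scale)."""
        return self.snps["pos0"].to_numpy() + 1

    def missing_fraction(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP over non-missing calls."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=1) / 2.0
        return np.minimum(p, 1.0 - p)

    def take_snps(self, index: np.ndarray | Sequence[int]) -> "VariantTable":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            self.snps.iloc[idx].reset_index(drop=True),
            self.dosages[idx],
            list(self.samples),
        )

    def take_samples(self, ids: Sequence[str]) -> "VariantTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"sample id(s) not present: {missing}")
        idx = [pos[s] for s in ids]
        return VariantTable(self.snps.copy(), self.dosages[:, idx], list(ids))

    def dosage_of(self, snp_id: str) -> np.ndarray:
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return self.dosages[idx[0]]

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.samples == other.samples
            and self.snps.reset_index(drop=True).equals(other.snps.reset_index(drop=True))
            and np.array_equal(self.dosages, other.dosages)
        )


def read_vcf(path: str | Path, sample_subset: Sequence[str] | None = None) -> VariantTable:
    """Load biallelic SNP records from a VCF 4.x file with GT fields.

    Multi-allelic records and indels are skipped (the skip count is logged);
    half-calls and non-diploid genotypes become missing.
    """
    vcf = VCF(str(path))
    if sample_subset is not None:
        known = set(vcf.samples)
        absent = [s for s in sample_subset if s not in known]
        if absent:
            raise KeyError(f"sample id(s) not present in {path}: {absent}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    ids, chroms, pos0s, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or rec.REF not in NUCLEOTIDES
            or rec.ALT[0] not in NUCLEOTIDES
        ):
            n_skipped += 1
            continue
        dos = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is phasing flag
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                continue
            dos[i] = alleles[0] + alleles[1]
        snp_id = rec.ID if rec.ID else f"rs{rec.CHROM}_{rec.POS}"
        ids.append(snp_id)
        chroms.append(rec.CHROM)
        pos0s.append(rec.POS - 1)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(dos)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP record(s)", n_skipped)

    snps = pd.DataFrame(
        {"snp_id": ids, "chrom": chroms, "pos0": pos0s, "ref": refs, "alt": alts}
    )
    dosages = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    table = VariantTable(snps, dosages, samples)
    if sample_subset is not None and list(sample_subset) != samples:
        table = table.take_samples(list(sample_subset))  # keep requested order
    table.n_skipped = n_skipped  # type: ignore[attr-defined]
    return table


_GT_OF_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a minimal VCF 4.2 file (GT only) from a VariantTable."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(table.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i, row in enumerate(table.snps.itertuples(index=False)):
            gts = "\t".join(_GT_OF_DOSAGE[int(d)] for d in table.dosages[i])
            fh.write(
                f"{row.chrom}\t{row.pos0 + 1}\t{row.snp_id}\t{row.ref}\t"
                f"{row.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with the CDS of its representative (first) mRNA.

    ``cds_segments`` are 0-based half-open genomic intervals ordered 5'->3'
    in transcript orientation (genomically descending on the minus strand).
    ``span`` is the 0-based half-open genomic gene span.
    """

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length of gene {self.gene_id!r} ({self.cds_length}) "
                "is not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def contains(self, pos0: int) -> bool:
        return self.span[0] <= pos0 < self.span[1]

    def cds_offset(self, pos0: int) -> int | None:
        """Transcript-orientation CDS offset of a genomic position, else None."""
        off = 0
        for s, e in self.cds_segments:
            if s <= pos0 < e:
                return off + (pos0 - s if self.strand == "+" else e - 1 - pos0)
            off += e - s
        return None


def _gff3_attributes(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.rstrip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (gene/mRNA/CDS) from a GFF3 file.

    One model per gene, using its first mRNA (file order).  CDS phase is
    ignored; the summed CDS length must be divisible by 3.
    """
    genes: dict[str, dict] = {}
    mrna_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = parts
            start0, end0 = to_internal(int(start1), int(end1))
            a = _gff3_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError(f"gene feature without ID: {line!r}")
                genes[gid] = {
                    "chrom": chrom, "strand": strand,
                    "span": (start0, end0), "mrna": None, "cds": [],
                }
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if parent in genes and genes[parent]["mrna"] is None:
                    genes[parent]["mrna"] = mid
                    mrna_gene[mid] = parent
            elif ftype == "CDS":
                parent = a.get("Parent")
                gid = mrna_gene.get(parent, parent if parent in genes else None)
                if gid is not None and genes[gid]["mrna"] in (parent, None):
                    genes[gid]["cds"].append((start0, end0))

    models = []
    for gid, g in genes.items():
        segs = sorted(g["cds"])
        for (s1, e1), (s2, _e2) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS segments in gene {gid!r}")
        if g["strand"] == "-":
            segs = segs[::-1]
        models.append(
            GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"],
                      span=g["span"], cds_segments=segs)
        )
    return models


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = to_gff3(*g.span)
            fh.write(
                f"{g.chrom}\talkagerm\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mid = g.gene_id + ".1"
            fh.write(
                f"{g.chrom}\talkagerm\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.gene_id}\n"
            )
            for s0, e0 in sorted(g.cds_segments):
                cs1, ce1 = to_gff3(s0, e0)
                fh.write(
                    f"{g.chrom}\talkagerm\tCDS\t{cs1}\t{ce1}\t.\t{g.strand}\t0\t"
                    f"ID={mid}.cds;Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = [
    "accession_id", "condition", "replicate", "day", "new_germinated",
    "total_seeds", "root_length_cm", "shoot_length_cm",
]


def read_phenotype_table(path: str | Path) -> list[GerminationCounts]:
    """Load a long-format germination TSV into GerminationCounts records.

    Expected columns: accession_id, condition (control/stress), replicate,
    day (1..7), new_germinated, total_seeds, and optional root_length_cm /
    shoot_length_cm (the first non-missing value per assay is used).  Days
    without a row contribute zero new germinations.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = PHENOTYPE_COLUMNS[:6]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype table missing column(s): {missing_cols}")

    dup = df.duplicated(subset=["accession_id", "condition", "replicate", "day"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["accession_id", "condition", "replicate", "day"]]
        raise ValueError(
            "duplicate phenotype row for (accession, condition, replicate, day) = "
            f"({key['accession_id']}, {key['condition']}, "
            f"{int(key['replicate'])}, {int(key['day'])})"
        )
    if not df["day"].between(1, N_DAYS).all():
        raise ValueError(f"day values must be in 1..{N_DAYS}")

    out = []
    for (acc, cond, rep), grp in df.groupby(
        ["accession_id", "condition", "replicate"], sort=True
    ):
        counts = np.zeros(N_DAYS, dtype=int)
        counts[grp["day"].to_numpy(dtype=int) - 1] = grp["new_germinated"].to_numpy(dtype=int)
        n0 = int(grp["total_seeds"].iloc[0])
        if grp["total_seeds"].nunique() != 1:
            raise ValueError(
                f"inconsistent total_seeds for ({acc}, {cond}, replicate {rep})"
            )

        def _first(col: str) -> float | None:
            if col not in grp.columns:
                return None
            vals = grp[col].dropna()
            return float(vals.iloc[0]) if len(vals) else None

        out.append(
            GerminationCounts(
                accession_id=str(acc), condition=str(cond), replicate=int(rep),
                n0=n0, new_counts=counts,
                root_length_cm=_first("root_length_cm"),
                shoot_length_cm=_first("shoot_length_cm"),
            )
        )
    return out


def write_phenotype_table(counts: Iterable[GerminationCounts], path: str | Path) -> None:
    rows = []
    for gc in counts:
        for day in range(1, N_DAYS + 1):
            rows.append({
                "accession_id": gc.accession_id, "condition": gc.condition,
                "replicate": gc.replicate, "day": day,
                "new_germinated": int(gc.new_counts[day - 1]),
                "total_seeds": gc.n0,
                "root_length_cm": gc.root_length_cm if day == 1 else None,
                "shoot_length_cm": gc.shoot_length_cm if day == 1 else None,
            })
    pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# metadata / annotation tables
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Accession metadata TSV: accession_id, subpopulation (closed vocabulary)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("accession_id", "subpopulation"):
        if col not in df.columns:
            raise ValueError(f"metadata table missing column {col!r}")
    if df["accession_id"].duplicated().any():
        dups = df.loc[df["accession_id"].duplicated(), "accession_id"].tolist()
        raise ValueError(f"duplicate accession id(s): {dups}")
    bad = set(df["subpopulation"]) - set(SUBPOPULATIONS)
    if bad:
        raise ValueError(
            f"unknown subpopulation label(s) {sorted(bad)}; "
            f"expected one of {SUBPOPULATIONS}"
        )
    return df[["accession_id", "subpopulation"]]


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df[["accession_id", "subpopulation"]].to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, functional_annotation, stress_related."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene_id", "functional_annotation", "stress_related"):
        if col not in df.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene id(s) in annotation table")
    df["stress_related"] = df["stress_related"].astype(bool)
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
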