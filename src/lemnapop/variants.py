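"""VCF input/output and site-level filtering.

The central container is :class:`VariantTable`, a dense sites x samples view of
biallelic SNP calls with per-sample allele depths (AD), total depth (DP) and
site quality, plus an optional sub-genome tag per contig (used for hybrid
references that concatenate the two parental genomes).

Genotype calls are diploid-model calls (0/0, 0/1, 1/1, missing) even for
triploid samples — this mirrors standard variant-caller output, where a
triploid site with allele dosage 1/3 is emitted as a 0/1 heterozygote.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: integer encoding of diploid genotype calls: alt-allele count, -1 = missing
GT_MISSING = -1

_CONTIG_RE = re.compile(r"##contig=<(.+)>")


@dataclass
class VariantTable:
    """Dense biallelic SNP matrix over a fixed sample set.

    Attributes
    ----------
    samples : list of str
    contig, pos, ref, alt, qual : per-site arrays (pos is 1-based)
    gt : (n_sites, n_samples) int8, alt-allele count 0/1/2 or -1 for missing
    ad_ref, ad_alt, dp : (n_sites, n_samples) int32 read-depth matrices
    contig_subgenome : contig name -> sub-genome tag (e.g. "M", "T")
    contig_lengths : contig name -> length (bp), for VCF headers
    """

    samples: list[str]
    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray
    contig_subgenome: dict[str, str] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_sites, n_samples = self.gt.shape
        if len(self.samples) != n_samples:
            raise ValueError("sample list does not match genotype matrix width")
        for name in ("contig", "pos", "ref", "alt", "qual"):
            if len(getattr(self, name)) != n_sites:
                raise ValueError(f"per-site array {name!r} has wrong length")
        if np.any(self.ad_ref < 0) or np.any(self.ad_alt < 0):
            raise ValueError("allele depths must be nonnegative")
        # positions strictly increasing within each contig
        for ctg in dict.fromkeys(self.contig.tolist()):
            p = self.pos[self.contig == ctg]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {ctg}")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    @property
    def site_subgenome(self) -> np.ndarray:
        """Sub-genome tag per site ('' where the contig is untagged)."""
        return np.asarray([self.contig_subgenome.get(c, "") for c in self.contig])

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask)
        return replace(
            self,
            contig=self.contig[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qual=self.qual[mask],
            gt=self.gt[mask],
            ad_ref=self.ad_ref[mask],
            ad_alt=self.ad_alt[mask],
            dp=self.dp[mask],
        )


@dataclass
class FilterReport:
    """Per-rule site rejection counts from :func:`filter_variants`."""

    n_input: int
    n_kept: int
    n_fail_qual: int
    n_fail_coverage: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_fail_qual": self.n_fail_qual,
            "n_fail_coverage": self.n_fail_coverage,
        }


def read_vcf(path: str) -> VariantTable:
    """Read a VCF 4.x file with GT (and optionally AD/DP) into a VariantTable.

    Multi-allelic records and non-SNP records (indels, MNPs) are skipped and
    counted in the log. Sub-genome tags are read from ``SUBGENOME=`` keys on
    ``##contig`` header lines when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")

    contig_subgenome: dict[str, str] = {}
    contig_lengths: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        m = _CONTIG_RE.match(line)
        if not m:
            continue
        fields = dict(kv.split("=", 1) for kv in m.group(1).split(",") if "=" in kv)
        cid = fields.get("ID")
        if cid is None:
            continue
        if "length" in fields:
            contig_lengths[cid] = int(fields["length"])
        if "SUBGENOME" in fields:
            contig_subgenome[cid] = fields["SUBGENOME"]

    contigs, pos, ref, alt, qual = [], [], [], [], []
    gt_rows, adr_rows, ada_rows, dp_rows = [], [], [], []
    n_skipped = 0
    n = len(samples)
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        contigs.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(v.QUAL if v.QUAL is not None else math.nan)

        row = np.full(n, GT_MISSING, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                row[i] = a + b
        gt_rows.append(row)

        ad = v.format("AD")
        if ad is not None:
            ad = np.maximum(np.asarray(ad, dtype=np.int64), 0)
            adr_rows.append(ad[:, 0].astype(np.int32))
            ada_rows.append(ad[:, 1].astype(np.int32))
        else:
            adr_rows.append(np.zeros(n, dtype=np.int32))
            ada_rows.append(np.zeros(n, dtype=np.int32))
        dpv = v.format("DP")
        if dpv is not None:
            dp_rows.append(np.maximum(np.asarray(dpv, dtype=np.int64), 0).ravel().astype(np.int32))
        else:
            dp_rows.append((adr_rows[-1] + ada_rows[-1]).astype(np.int32))
    vcf.close()

    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)

    n_sites = len(contigs)
    return VariantTable(
        samples=samples,
        contig=np.asarray(contigs, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        qual=np.asarray(qual, dtype=float),
        gt=np.asarray(gt_rows, dtype=np.int8).reshape(n_sites, n),
        ad_ref=np.asarray(adr_rows, dtype=np.int32).reshape(n_sites, n),
        ad_alt=np.asarray(ada_rows, dtype=np.int32).reshape(n_sites, n),
        dp=np.asarray(dp_rows, dtype=np.int32).reshape(n_sites, n),
        contig_subgenome=contig_subgenome,
        contig_lengths=contig_lengths,
    )


def write_vcf(table: VariantTable, path: str) -> None:
    """Write a VariantTable as VCF 4.2 with GT:AD:DP and SUBGENOME contig tags."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", GT_MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lemnapop\n")
        for ctg in dict.fromkeys(table.contig.tolist()):
            length = table.contig_lengths.get(ctg, int(table.pos[table.contig == ctg].max()) + 1000)
            sub = table.contig_subgenome.get(ctg)
            if sub is not None:
                fh.write(f"##contig=<ID={ctg},length={length},SUBGENOME={sub}>\n")
            else:
                fh.write(f"##contig=<ID={ctg},length={length}>\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            cols = [
                str(table.contig[i]),
                str(int(table.pos[i])),
                ".",
                str(table.ref[i]),
                str(table.alt[i]),
                f"{table.qual[i]:g}",
                "PASS",
                ".",
                "GT:AD:DP",
            ]
            for j in range(table.n_samples):
                cols.append(
                    f"{gt_str[int(table.gt[i, j])]}:"
                    f"{int(table.ad_ref[i, j])},{int(table.ad_alt[i, j])}:{int(table.dp[i, j])}"
                )
            fh.write("\t".join(cols) + "\n")


def filter_variants(
    table: VariantTable,
    qual_min: float = 20.0,
    dp_min: int = 10,
    dp_max: int = 1000,
    completeness: float = 0.8,
    coverage_from: str = "dp",
) -> tuple[VariantTable, FilterReport]:
    """Apply site-quality and per-sample coverage filters.

    A site is kept when QUAL >= ``qual_min`` (inclusive) and the number of
    samples with ``dp_min <= coverage <= dp_max`` (inclusive bounds) is at
    least ``ceil(completeness * n_samples)``. Coverage is read from DP by
    default; ``coverage_from='ad'`` falls back to the AD sum for callers that
    do not emit DP.
    """
    if not 0 < completeness <= 1:
        raise ValueError("completeness must be in (0, 1]")
    if coverage_from == "dp":
        cov = table.dp
    elif coverage_from == "ad":
        cov = table.ad_ref.astype(np.int64) + table.ad_alt
    else:
        raise ValueError("coverage_from must be 'dp' or 'ad'")

    qual_ok = table.qual >= qual_min
    need = math.ceil(completeness * table.n_samples)
    in_range = (cov >= dp_min) & (cov <= dp_max)
    cov_ok = in_range.sum(axis=1) >= need

    keep = qual_ok & cov_ok
    report = FilterReport(
        n_input=table.n_sites,
        n_kept=int(keep.sum()),
        n_fail_qual=int((~qual_ok).sum()),
        n_fail_coverage=int((~cov_ok).sum()),
    )
    return table.subset_sites(keep), report
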