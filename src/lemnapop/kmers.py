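"""Reference-free sample similarity from canonical k-mer presence/absence.

Stands in for external k-mer kinship pipelines: sequences are decomposed
into canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement, k odd, default 31), noise k-mers are removed with a per-sample
count threshold, and kinship between two samples is the fraction of
polymorphic k-mers (present in >=2 and <= n-1 samples) whose presence state
agrees. The exact estimator of dedicated k-mer GWAS pipelines is not
reproduced; this is a deliberately simple, documented replacement that
supports comparing reference-free with alignment-based distances.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class KmerProfile:
    """Canonical k-mers of one sample retained above a count threshold."""

    sample: str
    k: int
    kmers: frozenset[str]


def count_canonical_kmers(
    sequences, k: int = 31, min_count: int = 2, sample: str = "sample"
) -> KmerProfile:
    """Count canonical k-mers over a collection of A/C/G/T/N strings.

    k must be odd (even k makes a k-mer its own reverse complement possible,
    so canonicalization would be ambiguous). k-mers containing N are skipped;
    k-mers seen fewer than ``min_count`` times are dropped as likely
    sequencing-error artifacts.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd for unambiguous canonical k-mers")
    counts: dict[str, int] = {}
    for seq in sequences:
        s = str(seq).upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            kmer = _canonical(kmer)
            counts[kmer] = counts.get(kmer, 0) + 1
    kept = frozenset(km for km, c in counts.items() if c >= min_count)
    return KmerProfile(sample=sample, k=k, kmers=kept)


def read_sequences(path: str):
    """Yield sequences from a FASTA/FASTQ file, optionally gzipped."""
    from Bio import SeqIO

    p = Path(path)
    stem = p.name.removesuffix(".gz")
    fmt = "fastq" if stem.endswith(("fastq", "fq")) else "fasta"
    opener = gzip.open if p.name.endswith(".gz") else open
    with opener(p, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq)


def kmer_kinship(profiles: list[KmerProfile]) -> tuple[np.ndarray, list[str]]:
    """Presence/absence agreement kinship over polymorphic k-mers.

    k-mers present in fewer than 2 or more than n-1 samples carry no
    between-sample information (monomorphic) and are removed; kinship(i, j)
    is then the fraction of remaining k-mers with identical presence state
    in i and j. Diagonal is 1.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    n = len(profiles)
    universe = sorted(set().union(*(p.kmers for p in profiles)))
    presence = np.zeros((len(universe), n), dtype=bool)
    for j, p in enumerate(profiles):
        presence[:, j] = [km in p.kmers for km in universe]
    counts = presence.sum(axis=1)
    keep = (counts >= 2) & (counts <= n - 1)
    if not keep.any():
        raise ValueError("no k-mer passes the polymorphism filter")
    pres = presence[keep].astype(float)
    m = pres.shape[0]
    both = pres.T @ pres
    neither = (1 - pres).T @ (1 - pres)
    kinship = (both + neither) / m
    return kinship, [p.sample for p in profiles]
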