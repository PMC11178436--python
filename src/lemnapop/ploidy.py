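"""Allele-balance spectra, hybrid-dosage classification, sub-genome coverage.

At a heterozygous site the fraction of reads carrying the alternative allele
estimates the allele dosage: 1/2 in a diploid, 1/3 in a triploid with one
divergent copy (M/M/T when the alternative allele comes from the T parent),
2/3 with two divergent copies (M/T/T). A per-sample histogram of alt-read
fractions over heterozygous calls therefore separates diploids from triploid
hybrids by its modal position, and mean coverage per sub-genome of a combined
parental reference separates pure-species samples (near-zero coverage on the
other sub-genome) from hybrids (coverage ratio ~ copy-number ratio, 2:1 for
M/M/T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .distance import DistanceMatrix, pairwise_allele_distance

MIN_INFORMATIVE_SITES = 200


class DosageClass(Enum):
    DIPLOID_HET = "diploid_het"       # mode ~ 1/2
    TRIPLOID_MMT = "triploid_MMT"     # mode ~ 1/3
    TRIPLOID_MTT = "triploid_MTT"     # mode ~ 2/3
    UNINFORMATIVE = "uninformative"
    AMBIGUOUS = "ambiguous"


# mode windows: midway between adjacent theoretical modes, with extra
# allowance below 1/3 and above 2/3 because observed ratios run slightly low
WINDOWS = {
    DosageClass.TRIPLOID_MMT: (0.28, 0.41),   # [low, high)
    DosageClass.DIPLOID_HET: (0.45, 0.55),    # [low, high]
    DosageClass.TRIPLOID_MTT: (0.59, 0.72),   # (low, high]
}
AMBIGUITY_MASS_FRACTION = 0.10


@dataclass
class AlleleRatioSpectrum:
    """Histogram of alt-read fractions at heterozygous calls of one sample."""

    sample: str
    bin_centers: np.ndarray   # 0.005, 0.015, ..., 0.995
    counts: np.ndarray
    n_sites: int
    mode: float               # center of maximum smoothed bin
    mode_height: float

    def window_mass(self, lo: float, hi: float, lo_open: bool = False, hi_open: bool = False) -> int:
        sel = (self.bin_centers > lo if lo_open else self.bin_centers >= lo) & (
            self.bin_centers < hi if hi_open else self.bin_centers <= hi
        )
        return int(self.counts[sel].sum())


def allele_ratio_spectrum(
    table, sample: str, min_depth: int = 20, bin_width: float = 0.01
) -> AlleleRatioSpectrum:
    """Alt-read-fraction histogram over a sample's 0/1 calls.

    Only heterozygous calls with AD depth >= ``min_depth`` enter (at lower
    depth the 1/3 and 1/2 binomial modes overlap badly). The mode is the
    center of the maximum bin after a 3-bin moving-average smoothing.
    """
    j = table.sample_index(sample)
    het = table.gt[:, j] == 1
    depth = table.ad_ref[:, j].astype(np.int64) + table.ad_alt[:, j]
    use = het & (depth >= min_depth)
    n_used = int(use.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = table.ad_alt[use, j] / depth[use]

    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(r, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    if n_used == 0:
        return AlleleRatioSpectrum(sample, centers, counts, 0, float("nan"), 0.0)
    # the alt-read fraction takes discrete values k/depth, so single bins can
    # be artificially fat or thin depending on where those atoms fall; a
    # 3-bin moving average locates the peak neighborhood robustly, and the
    # maximum raw bin within that neighborhood is reported as the mode
    # (the smoothed argmax alone can be pulled a bin sideways by atom
    # placement asymmetries at depths near 1/bin_width)
    smoothed = np.convolve(counts, np.ones(3) / 3, mode="same")
    j = int(np.argmax(smoothed))
    lo = max(j - 1, 0)
    imax = lo + int(np.argmax(counts[lo : j + 2]))
    if n_used < MIN_INFORMATIVE_SITES:
        warnings.warn(
            f"{sample}: only {n_used} usable heterozygous sites "
            f"(< {MIN_INFORMATIVE_SITES}); spectrum is uninformative",
            stacklevel=2,
        )
    return AlleleRatioSpectrum(
        sample, centers, counts, n_used, float(centers[imax]), float(smoothed[imax])
    )


@dataclass
class DosageCall:
    sample: str
    dosage_class: DosageClass
    confidence: float   # fraction of het sites inside the winning window


def classify_hybrid_dosage(spectrum: AlleleRatioSpectrum) -> DosageCall:
    """Classify a spectrum as diploid-het, M/M/T, M/T/T or ambiguous.

    The mode must fall inside one of three disjoint windows around the
    theoretical dosages 1/3, 1/2 and 2/3; when the two heaviest windows are
    within 10% mass of each other, or the mode lies outside every window,
    the call is AMBIGUOUS. Fewer than 200 usable sites -> UNINFORMATIVE.
    """
    if spectrum.n_sites < MIN_INFORMATIVE_SITES:
        return DosageCall(spectrum.sample, DosageClass.UNINFORMATIVE, 0.0)

    masses = {
        DosageClass.TRIPLOID_MMT: spectrum.window_mass(0.28, 0.41, hi_open=True),
        DosageClass.DIPLOID_HET: spectrum.window_mass(0.45, 0.55),
        DosageClass.TRIPLOID_MTT: spectrum.window_mass(0.59, 0.72, lo_open=True),
    }
    winner = None
    m = spectrum.mode
    if 0.28 <= m < 0.41:
        winner = DosageClass.TRIPLOID_MMT
    elif 0.45 <= m <= 0.55:
        winner = DosageClass.DIPLOID_HET
    elif 0.59 < m <= 0.72:
        winner = DosageClass.TRIPLOID_MTT
    if winner is None:
        return DosageCall(spectrum.sample, DosageClass.AMBIGUOUS, 0.0)

    ranked = sorted(masses.values(), reverse=True)
    if len(ranked) > 1 and ranked[0] > 0:
        if (ranked[0] - ranked[1]) <= AMBIGUITY_MASS_FRACTION * ranked[0]:
            return DosageCall(spectrum.sample, DosageClass.AMBIGUOUS, 0.0)
    confidence = masses[winner] / spectrum.n_sites
    return DosageCall(spectrum.sample, winner, confidence)


@dataclass
class SubgenomeCoverageSummary:
    sample: str
    mean_depth: dict[str, float]       # sub-genome tag -> mean DP
    ratio: float                        # primary:secondary, NaN when undefined
    t_nonzero_fraction: float           # fraction of secondary sites with DP > 0
    species_call: str                   # pure_M | MMT | MT | MTT | flagged


def subgenome_coverage(
    table, sample: str, primary: str = "M", secondary: str = "T",
    pure_threshold: float = 0.05,
) -> SubgenomeCoverageSummary:
    """Mean read depth per sub-genome and the copy-number-style ratio.

    A sample whose fraction of covered secondary-sub-genome sites is below
    ``pure_threshold`` is called pure primary species; otherwise the
    primary:secondary mean-depth ratio maps to a dosage configuration
    (ratio ~2 -> M/M/T, ~1 -> M/T, ~0.5 -> M/T/T); anything else is flagged.
    """
    j = table.sample_index(sample)
    sub = table.site_subgenome
    means = {}
    for tag in (primary, secondary):
        sel = sub == tag
        if sel.sum() == 0:
            raise ValueError(f"no sites tagged with sub-genome {tag!r}")
        means[tag] = float(table.dp[sel, j].mean())
    t_sel = sub == secondary
    t_nonzero = float((table.dp[t_sel, j] > 0).mean())

    if means[secondary] <= 1e-9:
        ratio = float("nan")
    else:
        ratio = means[primary] / means[secondary]

    if t_nonzero < pure_threshold:
        call = "pure_M"
    elif 1.5 <= ratio <= 2.5:
        call = "MMT"
    elif 0.75 <= ratio <= 1.33:
        call = "MT"
    elif 0.4 <= ratio <= 0.67:
        call = "MTT"
    else:
        call = "flagged"
    return SubgenomeCoverageSummary(sample, means, ratio, t_nonzero, call)


def subgenome_distance_correlation(
    table,
    min_sites: int = 50,
    nperm: int = 9999,
    seed: int | None = None,
    samples: list[str] | None = None,
) -> dict[str, object]:
    """Distances per sub-genome partition and Mantel r between partitions.

    Splits the SNPs by the sub-genome tag of their contig, recomputes the
    pairwise allele-sharing distance within each partition (those with at
    least ``min_sites`` SNPs), and returns the pairwise Mantel correlation
    between partition distance matrices. When divergence accrues after
    hybridization, both sub-genomes mirror the same clonal structure and r
    approaches 1.
    """
    from .structure import mantel_test

    sub = table.site_subgenome
    tags = [t for t in dict.fromkeys(sub.tolist()) if t]
    matrices: dict[str, DistanceMatrix] = {}
    skipped: list[str] = []
    for tag in tags:
        sel = sub == tag
        if sel.sum() < min_sites:
            warnings.warn(f"sub-genome {tag!r} has < {min_sites} SNPs; skipped", stacklevel=2)
            skipped.append(tag)
            continue
        part = table.subset_sites(sel)
        if samples is not None:
            keep = [part.samples.index(s) for s in samples]
            part = _subset_samples(part, keep)
        matrices[tag] = pairwise_allele_distance(part)
    if len(matrices) < 2:
        raise ValueError("need at least two sub-genome partitions with enough SNPs")

    mantel = {}
    tags_kept = list(matrices)
    for a in range(len(tags_kept)):
        for b in range(a + 1, len(tags_kept)):
            res = mantel_test(matrices[tags_kept[a]], matrices[tags_kept[b]],
                              nperm=nperm, seed=seed)
            mantel[f"{tags_kept[a]}~{tags_kept[b]}"] = res
    return {"distances": matrices, "mantel": mantel, "skipped": skipped}


def _subset_samples(table, indices: list[int]):
    from dataclasses import replace

    return replace(
        table,
        samples=[table.samples[i] for i in indices],
        gt=table.gt[:, indices],
        ad_ref=table.ad_ref[:, indices],
        ad_alt=table.ad_alt[:, indices],
        dp=table.dp[:, indices],
    )
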