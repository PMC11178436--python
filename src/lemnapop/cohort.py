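"""Synthetic cohorts of clonal duckweed populations.

Generates cohorts with the statistical structure the downstream analyses
assume: clonal within-pond populations with drifted, spatially correlated
allele frequencies (Balding–Nichols drift plus a distance-dependent gradient
for isolation by distance), diploid samples of one species plus triploid
hybrids that carry two copies of one parental sub-genome (M) and one of the
other (T), binomial read sampling at each true allele dosage, and
diploid-model genotype calls in which intermediate dosages surface as 0/1
heterozygotes.

Two read-mapping modes are emulated, matching the two alignment strategies
used for such hybrids:

``minor_ref``
    all haplotypes of a sample pile up on the M (single-species) reference,
    so a triploid M/M/T site fixed between the parents shows alt-read
    fraction 1/3;
``combined_ref``
    each haplotype maps to its own sub-genome of a concatenated M+T
    reference, so an M/M/T hybrid shows a 2:1 M:T coverage ratio and pure-M
    diploids show near-zero T coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import GT_MISSING, VariantTable, write_vcf

# diploid-caller emulation constants: alt fraction <= T_LOW -> 0/0,
# >= T_HIGH -> 1/1, else 0/1; below MIN_CALL_DEPTH no call is made.
CALL_T_LOW = 0.15
CALL_T_HIGH = 0.85
MIN_CALL_DEPTH = 4

#: fraction of a diploid's depth that leaks onto the wrong sub-genome
#: (kept tiny, as mapping-quality filters discard nearly all cross-mapping)
CROSS_MAPPING_RATE = 0.0005

_KM_PER_DEG = 111.195  # 2*pi*6371/360

_PLOIDY_COPIES = {"MM": (2, 0), "MMT": (2, 1), "MT": (1, 1), "MTT": (1, 2)}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults mirror a ~200 km survey
    of small ponds with mostly clonal within-pond populations."""

    n_pops_sp1: int = 8
    n_pops_sp2: int = 4
    samples_per_pop: int | list[int] = 4
    n_sites: int = 4000
    fixed_diff_fraction: float = 0.1
    fst_drift: float = 0.2
    clone_mutation_rate: float = 1e-3
    region_extent_km: float = 200.0
    ibd_strength: float = 1.0
    mean_depth: float = 60.0
    error_rate: float = 0.001
    missing_rate: float = 0.02
    seed: int = 0
    sp2_ploidy: str = "MMT"
    mapping: str = "minor_ref"

    def __post_init__(self) -> None:
        for name in ("fixed_diff_fraction", "fst_drift", "clone_mutation_rate",
                     "error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_pops_sp1 + self.n_pops_sp2, self.n_sites) < 1:
            raise ValueError("counts must be >= 1")
        if self.mean_depth <= 0 or self.region_extent_km <= 0:
            raise ValueError("mean_depth and region_extent_km must be > 0")
        if self.sp2_ploidy not in _PLOIDY_COPIES:
            raise ValueError(f"sp2_ploidy must be one of {sorted(_PLOIDY_COPIES)}")
        if self.mapping not in ("minor_ref", "combined_ref"):
            raise ValueError("mapping must be 'minor_ref' or 'combined_ref'")

    @property
    def n_pops(self) -> int:
        return self.n_pops_sp1 + self.n_pops_sp2

    def pop_sizes(self) -> list[int]:
        if isinstance(self.samples_per_pop, int):
            return [self.samples_per_pop] * self.n_pops
        sizes = list(self.samples_per_pop)
        if len(sizes) != self.n_pops:
            raise ValueError("samples_per_pop list must have one entry per population")
        return sizes


@dataclass
class Founders:
    """Per-population founder allele frequencies and founder haplotypes."""

    p_anc: np.ndarray                 # (n_sites,) ancestral alt freq, M lineage
    pop_freq: np.ndarray              # (n_pops, n_sites) drifted M-lineage freqs
    t_anc: np.ndarray                 # (n_sites,) ancestral alt freq, T lineage
    t_pop_freq: np.ndarray            # (n_pops_sp2, n_sites) drifted T-lineage freqs
    is_fixed_diff: np.ndarray         # (n_sites,) bool, fixed between M and T
    founder_m_haps: np.ndarray        # (n_pops, n_sites, 2) int8
    founder_t_hap: np.ndarray         # (n_pops_sp2, n_sites) int8 (unused rows = 0)


@dataclass
class TrueState:
    """Hidden truth of a simulated cohort, for parameter-recovery tests."""

    spec: CohortSpec
    samples: pd.DataFrame             # sample, species, ploidy, population, clone_id, lat, lon
    founders: Founders
    haplotypes: np.ndarray            # (n_sites, n_samples, 3) int8; -1 = absent copy
    dosage: np.ndarray                # (n_sites, n_samples) true alt-dosage fraction
    n_copies: np.ndarray              # (n_samples,) haplotype count per sample

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample"].tolist()


def place_populations(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Uniform-random pond coordinates inside the survey bounding box."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lat0, lon0 = 47.0, 8.0
    half_lat = spec.region_extent_km / 2 / _KM_PER_DEG
    half_lon = spec.region_extent_km / 2 / (_KM_PER_DEG * math.cos(math.radians(lat0)))
    n = spec.n_pops
    lat = lat0 + rng.uniform(-half_lat, half_lat, size=n)
    lon = lon0 + rng.uniform(-half_lon, half_lon, size=n)
    names = [f"LM{i + 1:02d}" for i in range(spec.n_pops_sp1)]
    names += [f"LJ{i + 1:02d}" for i in range(spec.n_pops_sp2)]
    species = ["minor"] * spec.n_pops_sp1 + ["japonica"] * spec.n_pops_sp2
    return pd.DataFrame({"population": names, "species": species, "lat": lat, "lon": lon})


def _balding_nichols(p_local: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Beta-distributed drifted frequencies around local ancestral freqs."""
    if fst == 0:
        return p_local.copy()
    scale = (1 - fst) / fst
    a = np.clip(p_local * scale, 1e-6, None)
    b = np.clip((1 - p_local) * scale, 1e-6, None)
    return rng.beta(a, b)


def simulate_founders(
    spec: CohortSpec, coords: pd.DataFrame, rng: np.random.Generator | None = None
) -> Founders:
    """Draw ancestral and per-population allele frequencies and pond founders.

    Ancestral alt frequencies are uniform on [0.05, 0.95]. Isolation by
    distance enters as a per-site random planar gradient added on the logit
    scale, scaled by ``ibd_strength``, before Balding–Nichols drift; with
    ``fst_drift == 0`` the drift (and the gradient) degenerate and every
    population returns the ancestral frequency exactly.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    n_sites, n_pops = spec.n_sites, spec.n_pops

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    t_anc = rng.uniform(0.05, 0.95, size=n_sites)
    is_fixed = rng.random(n_sites) < spec.fixed_diff_fraction

    # normalized pond coordinates in [-1, 1]^2
    lat, lon = coords["lat"].to_numpy(), coords["lon"].to_numpy()
    x = np.zeros((n_pops, 2))
    for k, v in enumerate((lat, lon)):
        span = v.max() - v.min()
        x[:, k] = 0.0 if span == 0 else 2 * (v - v.min()) / span - 1

    grad = rng.normal(size=(2, n_sites))  # per-site gradient direction/magnitude

    if spec.fst_drift == 0:
        pop_freq = np.tile(p_anc, (n_pops, 1))
    else:
        shift = spec.ibd_strength * (x @ grad)  # (n_pops, n_sites)
        logit = np.log(p_anc / (1 - p_anc))[None, :] + shift
        p_local = 1 / (1 + np.exp(-logit))
        pop_freq = np.vstack(
            [_balding_nichols(p_local[i], spec.fst_drift, rng) for i in range(n_pops)]
        )

    n_sp2 = spec.n_pops_sp2
    if spec.fst_drift == 0:
        t_pop_freq = np.tile(t_anc, (max(n_sp2, 1), 1))[:n_sp2]
    else:
        t_pop_freq = np.vstack(
            [_balding_nichols(t_anc, spec.fst_drift, rng) for _ in range(n_sp2)]
        ) if n_sp2 else np.zeros((0, n_sites))

    # fixed differences: M lineage fixed ref, T lineage fixed alt
    pop_freq[:, is_fixed] = 0.0
    if n_sp2:
        t_pop_freq[:, is_fixed] = 1.0

    founder_m = (rng.random((n_pops, n_sites, 2)) < pop_freq[:, :, None]).astype(np.int8)
    founder_t = (
        (rng.random((n_sp2, n_sites)) < t_pop_freq).astype(np.int8)
        if n_sp2
        else np.zeros((0, n_sites), dtype=np.int8)
    )
    return Founders(p_anc, pop_freq, t_anc, t_pop_freq, is_fixed, founder_m, founder_t)


def simulate_samples(
    spec: CohortSpec, founders: Founders, coords: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> TrueState:
    """Expand pond founders into clone-mate samples with somatic mutations.

    Species-1 samples are diploid on the M genome; species-2 samples carry
    two M haplotypes and one T haplotype (M/M/T) by default. Every sample
    copies its pond founder and then differs at each site independently with
    probability ``clone_mutation_rate`` (one random haplotype flipped).
    """
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    if coords is None:
        coords = place_populations(spec)
    sizes = spec.pop_sizes()
    n_sites = spec.n_sites
    m_sp2, t_sp2 = _PLOIDY_COPIES[spec.sp2_ploidy]

    rows = []
    haps = []
    for ip in range(spec.n_pops):
        pop = coords.iloc[ip]
        is_sp2 = ip >= spec.n_pops_sp1
        n_m, n_t = (m_sp2, t_sp2) if is_sp2 else (2, 0)
        founder = np.full((n_sites, 3), -1, dtype=np.int8)
        founder[:, :n_m] = founders.founder_m_haps[ip, :, :n_m]
        if n_t:
            it = ip - spec.n_pops_sp1
            founder[:, n_m : n_m + n_t] = founders.founder_t_hap[it][:, None]
        for js in range(sizes[ip]):
            h = founder.copy()
            if spec.clone_mutation_rate > 0:
                hit = rng.random(n_sites) < spec.clone_mutation_rate
                which = rng.integers(0, n_m + n_t, size=n_sites)
                idx = np.flatnonzero(hit)
                h[idx, which[idx]] = 1 - h[idx, which[idx]]
            haps.append(h)
            rows.append(
                {
                    "sample": f"{pop['population']}_s{js + 1}",
                    "species": pop["species"],
                    "ploidy": spec.sp2_ploidy if is_sp2 else "MM",
                    "population": pop["population"],
                    "clone_id": f"{pop['population']}_clone",
                    "lat": pop["lat"],
                    "lon": pop["lon"],
                }
            )
    samples = pd.DataFrame(rows)
    haplotypes = np.stack(haps, axis=1)  # (n_sites, n_samples, 3)
    n_copies = np.asarray([(h[0] >= 0).sum() for h in haps], dtype=np.int64)
    alt_count = np.where(haplotypes >= 0, haplotypes, 0).sum(axis=2)
    dosage = alt_count / n_copies[None, :]
    return TrueState(spec, samples, founders, haplotypes, dosage, n_copies)


def _call_genotypes(depth: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Diploid-caller emulation on alt-read fractions."""
    gt = np.full(depth.shape, GT_MISSING, dtype=np.int8)
    ok = depth >= MIN_CALL_DEPTH
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    gt[ok & (af <= CALL_T_LOW)] = 0
    gt[ok & (af >= CALL_T_HIGH)] = 2
    gt[ok & (af > CALL_T_LOW) & (af < CALL_T_HIGH)] = 1
    return gt


def simulate_reads_and_calls(
    spec: CohortSpec, truth: TrueState, rng: np.random.Generator | None = None
) -> VariantTable:
    """Sample read depths and alt reads per site/sample and emit diploid calls.

    Depth is Poisson with a per-sample sequencing effort of ``mean_depth``
    reads per locus regardless of ploidy; alt reads are binomial at
    ``dosage*(1-e) + (1-dosage)*e``. In ``combined_ref`` mapping, each
    haplotype contributes only to its own sub-genome's contig, so triploid
    M/M/T samples show 2:1 M:T coverage and diploids nearly zero T coverage.
    """
    rng = np.random.default_rng(spec.seed + 3) if rng is None else rng
    n_sites = spec.n_sites
    n_samples = len(truth.samples)
    bases = np.array(list("ACGT"))

    if spec.mapping == "minor_ref":
        lam = np.full((n_sites, n_samples), spec.mean_depth)
        dosage = truth.dosage
        contigs = np.asarray(["M_1"] * n_sites, dtype=object)
        pos = np.arange(1, n_sites + 1) * 100
        contig_sub = {"M_1": "M"}
    else:
        # split sites half/half between the two sub-genome contigs
        n_m = n_sites - n_sites // 2
        contigs = np.asarray(["M_1"] * n_m + ["T_1"] * (n_sites - n_m), dtype=object)
        pos = np.concatenate(
            [np.arange(1, n_m + 1) * 100, np.arange(1, n_sites - n_m + 1) * 100]
        )
        contig_sub = {"M_1": "M", "T_1": "T"}
        per_copy = spec.mean_depth / truth.n_copies  # (n_samples,)
        m_copies = (truth.haplotypes[:, :, :2] >= 0).sum(axis=2)
        t_copies = (truth.haplotypes[:, :, 2:] >= 0).sum(axis=2)
        is_t_site = contigs == "T_1"
        lam = np.where(
            is_t_site[:, None],
            np.where(t_copies > 0, per_copy[None, :] * t_copies,
                     spec.mean_depth * CROSS_MAPPING_RATE),
            per_copy[None, :] * m_copies,
        )
        # dosage restricted to the haplotypes mapping to each contig
        m_alt = np.where(truth.haplotypes[:, :, :2] >= 0, truth.haplotypes[:, :, :2], 0).sum(axis=2)
        t_alt = np.where(truth.haplotypes[:, :, 2:] >= 0, truth.haplotypes[:, :, 2:], 0).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            dosage = np.where(
                is_t_site[:, None],
                np.where(t_copies > 0, t_alt / np.maximum(t_copies, 1), 0.0),
                m_alt / np.maximum(m_copies, 1),
            )

    depth = rng.poisson(lam).astype(np.int32)
    p_alt = dosage * (1 - spec.error_rate) + (1 - dosage) * spec.error_rate
    alt = rng.binomial(depth, p_alt).astype(np.int32)
    ad_ref = depth - alt

    gt = _call_genotypes(depth, alt)
    if spec.missing_rate > 0:
        gt[rng.random(gt.shape) < spec.missing_rate] = GT_MISSING
    ad_ref[depth == 0] = 0
    alt[depth == 0] = 0

    qual = np.minimum(99.0, np.round(3.0 * depth.mean(axis=1), 1))
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref = bases[ref_idx]
    alt_base = bases[alt_idx]
    return VariantTable(
        samples=truth.sample_ids,
        contig=contigs,
        pos=pos.astype(np.int64),
        ref=ref.astype(object),
        alt=alt_base.astype(object),
        qual=qual,
        gt=gt,
        ad_ref=ad_ref,
        ad_alt=alt,
        dp=depth,
        contig_subgenome=contig_sub,
        contig_lengths={c: int(pos[contigs == c].max()) + 1000 for c in contig_sub},
    )


def simulate_cohort(spec: CohortSpec) -> tuple[VariantTable, TrueState]:
    """Run the full generator: placement -> founders -> samples -> reads."""
    rng = np.random.default_rng(spec.seed)
    coords = place_populations(spec, rng)
    founders = simulate_founders(spec, coords, rng)
    truth = simulate_samples(spec, founders, coords, rng)
    table = simulate_reads_and_calls(spec, truth, rng)
    return table, truth


def write_cohort(table: VariantTable, truth: TrueState, prefix: str) -> dict[str, str]:
    """Write VCF + metadata TSV + truth TSV; returns the paths written."""
    paths = {
        "vcf": f"{prefix}.vcf",
        "metadata": f"{prefix}.metadata.tsv",
        "truth": f"{prefix}.truth.tsv",
    }
    write_vcf(table, paths["vcf"])
    meta = truth.samples[["sample", "population", "lat", "lon"]]
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    truth.samples.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# single-sample helpers for allele-balance and coverage experiments
# ---------------------------------------------------------------------------

_DOSAGE_BY_KIND = {"diploid_het": 0.5, "MMT": 1 / 3, "MTT": 2 / 3}


def single_sample_table(
    kind: str,
    n_sites: int = 10_000,
    mean_depth: float = 60.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> VariantTable:
    """One-sample table in minor_ref mapping where every site is informative.

    ``kind`` selects the true alt dosage at every site: ``diploid_het`` (1/2),
    ``MMT`` (1/3, two reference-parent copies and one alternative) or ``MTT``
    (2/3). Used for allele-ratio spectrum experiments.
    """
    if kind not in _DOSAGE_BY_KIND:
        raise ValueError(f"kind must be one of {sorted(_DOSAGE_BY_KIND)}")
    rng = np.random.default_rng(seed)
    d = _DOSAGE_BY_KIND[kind]
    depth = rng.poisson(mean_depth, size=n_sites).astype(np.int32)
    p_alt = d * (1 - error_rate) + (1 - d) * error_rate
    alt = rng.binomial(depth, p_alt).astype(np.int32)
    gt = _call_genotypes(depth[:, None], alt[:, None])
    return VariantTable(
        samples=["S1"],
        contig=np.asarray(["M_1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1) * 100,
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(["T"] * n_sites, dtype=object),
        qual=np.minimum(99.0, 3.0 * depth.astype(float)),
        gt=gt,
        ad_ref=(depth - alt)[:, None],
        ad_alt=alt[:, None],
        dp=depth[:, None],
        contig_subgenome={"M_1": "M"},
        contig_lengths={"M_1": (n_sites + 10) * 100},
    )


def single_sample_subgenome_table(
    composition: str = "MMT",
    n_sites_per_subgenome: int = 10_000,
    mean_depth: float = 60.0,
    seed: int = 0,
) -> VariantTable:
    """One-sample table in combined_ref mapping for coverage-ratio experiments.

    Reads originate uniformly from the sample's haplotypes and land on the
    sub-genome of their haplotype of origin, so expected per-site depth is
    proportional to copy number: an M/M/T sample shows a 2:1 M:T ratio, a
    pure diploid (``MM``) only residual cross-mapping depth on T.
    """
    m, t = _PLOIDY_COPIES[composition]
    rng = np.random.default_rng(seed)
    n = n_sites_per_subgenome
    per_copy = mean_depth / (m + t)
    lam_m = per_copy * m
    lam_t = per_copy * t if t > 0 else mean_depth * CROSS_MAPPING_RATE
    depth = np.concatenate(
        [rng.poisson(lam_m, size=n), rng.poisson(lam_t, size=n)]
    ).astype(np.int32)[:, None]
    gt = np.where(depth >= MIN_CALL_DEPTH, 0, GT_MISSING).astype(np.int8)
    return VariantTable(
        samples=["S1"],
        contig=np.asarray(["M_1"] * n + ["T_1"] * n, dtype=object),
        pos=np.concatenate([np.arange(1, n + 1) * 100] * 2),
        ref=np.asarray(["A"] * 2 * n, dtype=object),
        alt=np.asarray(["T"] * 2 * n, dtype=object),
        qual=np.minimum(99.0, 3.0 * depth[:, 0].astype(float)),
        gt=gt,
        ad_ref=depth.copy(),
        ad_alt=np.zeros_like(depth),
        dp=depth,
        contig_subgenome={"M_1": "M", "T_1": "T"},
        contig_lengths={"M_1": (n + 10) * 100, "T_1": (n + 10) * 100},
    )


def haplotype_sequences(
    truth: TrueState,
    table: VariantTable,
    spacing: int = 40,
    copies: int = 2,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Per-sample haplotype sequences for the reference-free k-mer path.

    Builds a random background genome with one variant per ``spacing`` bp and
    substitutes each sample's haplotype alleles; each haplotype string is
    emitted ``copies`` times (emulating read coverage, so genuine variant
    k-mers survive a min-count filter while singletons would not).
    """
    rng = np.random.default_rng(seed)
    n_sites = truth.dosage.shape[0]
    length = n_sites * spacing + spacing
    background = rng.integers(0, 4, size=length)
    var_pos = np.arange(n_sites) * spacing + spacing // 2
    bases = "ACGT"
    base_idx = {b: i for i, b in enumerate(bases)}
    out: dict[str, list[str]] = {}
    for j, sample in enumerate(truth.sample_ids):
        seqs = []
        for h in range(3):
            alleles = truth.haplotypes[:, j, h]
            if alleles[0] < 0:
                continue
            seq = background.copy()
            ref_idx = np.asarray([base_idx[b] for b in table.ref[:n_sites]])
            alt_idx = np.asarray([base_idx[b] for b in table.alt[:n_sites]])
            seq[var_pos] = np.where(alleles == 1, alt_idx, ref_idx)
            s = "".join(bases[i] for i in seq)
            seqs.extend([s] * copies)
        out[sample] = seqs
    return out
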