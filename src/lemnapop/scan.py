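"""Per-SNP assignment-marker scan.

Each SNP is tested for association between its genotype factor and a
two-group sample partition (typically the two species) with a quasibinomial
logistic model: the binary response is group membership, the predictor the
genotype call under three codings — the full three-level factor (0/0, 0/1,
1/1) and two dominant/recessive collapses (factor A: 0/0 vs rest; factor B:
1/1 vs rest). Effect size is the percent of null deviance explained (%-DEV);
significance is an F test of the deviance reduction scaled by the Pearson
dispersion, with Benjamini-Hochberg FDR control across sites. A marker is
significant when FDR < 0.05 and %-DEV >= 80 (both configurable).

For a single categorical predictor the logistic maximum likelihood has a
closed form — the fitted probability in each genotype level is the group
proportion within that level — which is the fixed point IRLS converges to;
the closed form is used directly so perfectly separated sites (every level
pure, residual deviance 0) are handled exactly rather than by a failed
iterative fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

_EPS_DEV = 1e-8  # deviance / dispersion floor at perfect separation


class CodingScheme(Enum):
    THREE_LEVEL = "three_level"
    FACTOR_A = "factor_A"   # 0/0 vs {0/1, 1/1}
    FACTOR_B = "factor_B"   # 1/1 vs {0/1, 0/0}


def _encode(gt: np.ndarray, coding: CodingScheme) -> np.ndarray:
    if coding is CodingScheme.THREE_LEVEL:
        return gt
    if coding is CodingScheme.FACTOR_A:
        return (gt >= 1).astype(np.int8)
    return (gt == 2).astype(np.int8)


def _binom_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


@dataclass
class GlmFit:
    pct_dev: float
    f_stat: float
    p_value: float
    separated: bool
    df_model: int
    df_resid: int


def fit_snp_glm(group_labels: np.ndarray, genotype_factor: np.ndarray) -> GlmFit:
    """Quasibinomial logistic fit of group membership on a genotype factor.

    Returns %-deviance explained, the F statistic
    ``((D_null - D_res)/df_model) / dispersion`` with the Pearson dispersion
    of the fitted model, its p-value, and a perfect-separation flag. At
    separation (residual deviance ~ 0) %-DEV is reported as 100 and the p
    value is computed with deviance and dispersion floored at 1e-8.
    """
    y = np.asarray(group_labels)
    x = np.asarray(genotype_factor)
    levels, inv = np.unique(x, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("genotype factor has a single observed level")
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError("need exactly two groups among non-missing samples")
    yb = (y == groups[1]).astype(float)
    n = len(yb)

    mu_level = np.array([yb[inv == k].mean() for k in range(len(levels))])
    mu = mu_level[inv]
    d_res = _binom_deviance(yb, mu)
    d_null = _binom_deviance(yb, np.full(n, yb.mean()))
    if d_null <= 0:
        raise ValueError("null deviance is zero: one group is empty")

    df_model = len(levels) - 1
    df_resid = n - len(levels)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
    pearson = float(np.sum((yb - mu_c) ** 2 / (mu_c * (1 - mu_c))))
    dispersion = pearson / df_resid

    separated = d_res < _EPS_DEV
    pct_dev = 100.0 if separated else 100.0 * (d_null - d_res) / d_null
    f_stat = ((d_null - max(d_res, _EPS_DEV)) / df_model) / max(dispersion, _EPS_DEV)
    p = float(stats.f.sf(f_stat, df_model, df_resid))
    return GlmFit(pct_dev, f_stat, p, separated, df_model, df_resid)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR with monotonicity enforcement.

    NaN p-values propagate as NaN and are excluded from the ranking.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(ranked, 1.0)
    out[ok] = fdr
    return out


@dataclass
class SNPAssociation:
    contig: str
    pos: int
    best_coding: CodingScheme
    pct_dev: float
    f_stat: float
    p_value: float
    fdr: float
    significant: bool
    diff_class: str     # hom_vs_hom | hom_vs_het | other
    separated: bool


@dataclass
class ScanSummary:
    n_scanned: int
    n_skipped: int
    n_significant: int
    fraction_significant: float
    diff_class_counts: dict[str, int]


_CODING_PRIORITY = [CodingScheme.FACTOR_A, CodingScheme.FACTOR_B, CodingScheme.THREE_LEVEL]


def _difference_class(gt: np.ndarray, yb: np.ndarray) -> str:
    """Classify a marker by the majority genotype in each group."""
    majors = []
    for g in (0, 1):
        sub = gt[yb == g]
        vals, counts = np.unique(sub, return_counts=True)
        majors.append(int(vals[np.argmax(counts)]))
    a, b = majors
    if a == b:
        return "other"
    if {a, b} == {0, 2}:
        return "hom_vs_hom"
    if 1 in (a, b):
        return "hom_vs_het"
    return "other"


def scan_assignment_markers(
    table,
    groups: dict[str, str] | pd.Series,
    fdr_thresh: float = 0.05,
    dev_thresh: float = 80.0,
    min_per_group: int = 3,
) -> tuple[list[SNPAssociation], ScanSummary]:
    """Scan every site of a (filtered) VariantTable for assignment markers.

    ``groups`` maps every sample to one of exactly two labels. Per site all
    three codings are fitted on non-missing samples and the coding with the
    highest %-DEV is kept (ties favor the two-level factors A then B); the
    selected coding's p enters one Benjamini-Hochberg correction across all
    scanned sites. Sites with fewer than ``min_per_group`` called samples in
    either group, or a single observed genotype level, are skipped.
    """
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    labels = np.asarray([groups[s] for s in table.samples])
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two group labels, got {list(uniq)}")
    for u in uniq:
        if (labels == u).sum() == 0:
            raise ValueError(f"group {u!r} has no samples")

    results: list[SNPAssociation] = []
    fits = []
    n_skipped = 0
    for i in range(table.n_sites):
        gt_row = table.gt[i]
        called = gt_row >= 0
        gt = gt_row[called].astype(np.int8)
        y = labels[called]
        if min((y == uniq[0]).sum(), (y == uniq[1]).sum()) < min_per_group:
            n_skipped += 1
            continue
        if len(np.unique(gt)) < 2:
            n_skipped += 1
            continue
        yb = (y == uniq[1]).astype(int)
        res = best_coding_fit(gt, y)
        if res is None:
            n_skipped += 1
            continue
        best_coding, best = res
        fits.append((i, best_coding, best, _difference_class(gt, yb)))

    fdrs = bh_fdr([f.p_value for _, _, f, _ in fits])
    counts = {"hom_vs_hom": 0, "hom_vs_het": 0, "other": 0}
    n_sig = 0
    for (i, coding, fit, diff), fdr in zip(fits, fdrs):
        sig = bool(fdr < fdr_thresh and fit.pct_dev >= dev_thresh)
        if sig:
            n_sig += 1
            counts[diff] += 1
        results.append(
            SNPAssociation(
                contig=str(table.contig[i]),
                pos=int(table.pos[i]),
                best_coding=coding,
                pct_dev=fit.pct_dev,
                f_stat=fit.f_stat,
                p_value=fit.p_value,
                fdr=float(fdr),
                significant=sig,
                diff_class=diff,
                separated=fit.separated,
            )
        )
    n_scanned = len(results)
    summary = ScanSummary(
        n_scanned=n_scanned,
        n_skipped=n_skipped,
        n_significant=n_sig,
        fraction_significant=n_sig / n_scanned if n_scanned else 0.0,
        diff_class_counts=counts,
    )
    return results, summary


def best_coding_fit(gt: np.ndarray, labels: np.ndarray) -> tuple[CodingScheme, GlmFit] | None:
    """Fit all three codings on called genotypes and return the best by %-DEV
    (ties favor factor A, then B, then the three-level factor)."""
    best = None
    best_coding = None
    for coding in _CODING_PRIORITY:
        enc = _encode(gt, coding)
        if len(np.unique(enc)) < 2:
            continue
        fit = fit_snp_glm(labels, enc)
        if best is None or fit.pct_dev > best.pct_dev + 1e-12:
            best, best_coding = fit, coding
    if best is None:
        return None
    return best_coding, best


def null_calibration_pit(
    genotypes: np.ndarray, labels: np.ndarray, seed: int | None = None
) -> np.ndarray:
    """Probability-integral transform of best-coding p-values against their
    exact label-permutation null.

    The F-test p at small n is discrete (its null support is a finite set of
    contingency tables), so its raw distribution cannot be continuous-uniform;
    the standard uniformity check for discrete p-values maps each observed p
    through its exact null CDF with randomization within atoms:
    ``u = F(p-) + V * P(p)`` with V ~ U(0,1). Under the null (genotypes
    independent of labels) the returned u are exactly Uniform(0,1).

    The exact permutation null per site is enumerated via the sufficient
    statistic: with genotype level sizes (n_1..n_L) and n1 group-1 samples,
    the per-level group-1 counts follow a multivariate hypergeometric law,
    and the best-coding p depends on the labels only through those counts.

    Parameters
    ----------
    genotypes : (n_sites, n_samples) int matrix of calls (no missing)
    labels : binary group label per sample
    """
    from math import comb

    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    n1 = int((y == uniq[1]).sum())
    n = len(y)

    def _enumerate(level_sizes: tuple[int, ...], level_values: tuple[int, ...]):
        """(p_value, weight) atoms over group-1 allocations across levels."""
        total = comb(n, n1)
        atoms: dict[float, float] = {}

        def rec(idx: int, remaining: int, ks: list[int]):
            if idx == len(level_sizes) - 1:
                if remaining > level_sizes[idx]:
                    return
                ks = ks + [remaining]
                w = 1.0
                for sz, k in zip(level_sizes, ks):
                    w *= comb(sz, k)
                w /= total
                gt_rep = np.repeat(level_values, level_sizes).astype(np.int8)
                y_rep = np.concatenate(
                    [[1] * k + [0] * (sz - k) for sz, k in zip(level_sizes, ks)]
                )
                res = best_coding_fit(gt_rep, y_rep) if len(set(y_rep)) == 2 else None
                p = res[1].p_value if res is not None else 1.0
                atoms[p] = atoms.get(p, 0.0) + w
                return
            for k in range(0, min(level_sizes[idx], remaining) + 1):
                rec(idx + 1, remaining - k, ks + [k])

        rec(0, n1, [])
        ps = np.array(sorted(atoms))
        ws = np.array([atoms[p] for p in ps])
        return ps, ws

    cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    out = np.empty(genotypes.shape[0])
    yb = (y == uniq[1]).astype(int)
    for i, gt in enumerate(genotypes):
        gt = np.asarray(gt, dtype=np.int8)
        vals, sizes = np.unique(gt, return_counts=True)
        key = (tuple(vals.tolist()), tuple(sizes.tolist()))
        if key not in cache:
            cache[key] = _enumerate(tuple(sizes.tolist()), tuple(vals.tolist()))
        ps, ws = cache[key]
        res = best_coding_fit(gt, yb)
        p_obs = res[1].p_value if res is not None else 1.0
        below = ps < p_obs - 1e-10
        at = np.abs(ps - p_obs) < 1e-10
        f_lo = float(ws[below].sum())
        mass = float(ws[at].sum())
        out[i] = f_lo + rng.random() * max(mass, 0.0)
    return np.clip(out, 0.0, 1.0)


def scan_to_frame(results: list[SNPAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [r.contig for r in results],
            "pos": [r.pos for r in results],
            "best_coding": [r.best_coding.value for r in results],
            "pct_dev": [r.pct_dev for r in results],
            "F": [r.f_stat for r in results],
            "p": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
            "diff_class": [r.diff_class for r in results],
            "separated": [r.separated for r in results],
        }
    )
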