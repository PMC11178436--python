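"""End-to-end pipeline: simulate/load -> filter -> distances -> cluster ->
species split -> assignment scan -> ploidy & coverage -> structure stats.

Produces a machine-readable JSON report with every threshold echoed, per-file
checksums, per-stage timing, and the seed, so a run is reproducible and each
stage re-runnable from its intermediate files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .distance import DistanceMatrix, cluster_samples, pairwise_allele_distance
from .ploidy import allele_ratio_spectrum, classify_hybrid_dosage, subgenome_coverage
from .scan import scan_assignment_markers, scan_to_frame
from .structure import dispersion_test, ibd_test, within_between_summary
from .variants import filter_variants, read_vcf

_KNOWN_KEYS = {
    "vcf", "metadata", "subgenome_map", "cohort_seed", "simulate",
    "qual_min", "dp_min", "dp_max", "completeness",
    "fdr", "dev", "cluster_height", "linkage", "nperm", "seed",
    "exclude_samples", "out_dir",
}


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the standard thresholds."""

    vcf: str | None = None
    metadata: str | None = None
    simulate: bool = False
    cohort_spec: cohort_mod.CohortSpec | None = None
    qual_min: float = 20.0
    dp_min: int = 10
    dp_max: int = 1000
    completeness: float = 0.8
    fdr: float = 0.05
    dev: float = 80.0
    cluster_height: float = 0.05
    linkage: str = "average"
    nperm: int = 999
    seed: int = 0
    exclude_samples: list[str] = field(default_factory=list)
    out_dir: str = "lemnapop_run"

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Parse a plain-text key=value config file; unknown keys rejected."""
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in _KNOWN_KEYS:
                raise ValueError(f"unknown config key {key!r}")
            if key == "exclude_samples":
                kwargs[key] = [s for s in val.split(",") if s]
            elif key == "simulate":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key in ("qual_min", "completeness", "fdr", "dev", "cluster_height"):
                kwargs[key] = float(val)
            elif key in ("dp_min", "dp_max", "nperm", "seed", "cohort_seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = val
        cohort_seed = kwargs.pop("cohort_seed", None)
        cfg = cls(**kwargs)
        if cfg.simulate:
            cfg.cohort_spec = cohort_mod.CohortSpec(
                seed=cohort_seed if cohort_seed is not None else cfg.seed
            )
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; any stage failure aborts with its name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {
            k: v
            for k, v in asdict(config).items()
            if k != "cohort_spec"
        },
        "stages": {},
        "files": {},
    }
    if config.cohort_spec is not None:
        report["config"]["cohort_spec"] = asdict(config.cohort_spec)

    stage = "setup"
    try:
        # ---- simulate or load -------------------------------------------
        stage = "input"
        t0 = time.perf_counter()
        if config.simulate or config.cohort_spec is not None:
            spec = config.cohort_spec or cohort_mod.CohortSpec(seed=config.seed)
            table, truth = cohort_mod.simulate_cohort(spec)
            paths = cohort_mod.write_cohort(table, truth, str(out / "cohort"))
            metadata = truth.samples[["sample", "population", "lat", "lon"]].copy()
            for p in paths.values():
                report["files"][Path(p).name] = _sha256(Path(p))
        else:
            if config.vcf is None:
                raise ValueError("config needs either simulate=true or a vcf path")
            table = read_vcf(config.vcf)
            metadata = (
                pd.read_csv(config.metadata, sep="\t") if config.metadata else None
            )
        if config.exclude_samples:
            keep = [i for i, s in enumerate(table.samples) if s not in config.exclude_samples]
            from .ploidy import _subset_samples

            table = _subset_samples(table, keep)
            if metadata is not None:
                metadata = metadata[~metadata["sample"].isin(config.exclude_samples)]
        report["stages"]["input"] = {
            "n_sites": table.n_sites,
            "n_samples": table.n_samples,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # ---- filter ------------------------------------------------------
        stage = "filter"
        t0 = time.perf_counter()
        table, frep = filter_variants(
            table,
            qual_min=config.qual_min,
            dp_min=config.dp_min,
            dp_max=config.dp_max,
            completeness=config.completeness,
        )
        report["stages"]["filter"] = {**frep.as_dict(), "seconds": round(time.perf_counter() - t0, 3)}

        # ---- distances + clustering -------------------------------------
        stage = "distance"
        t0 = time.perf_counter()
        dm = pairwise_allele_distance(table)
        dm.to_tsv(str(out / "distance.tsv"))
        report["files"]["distance.tsv"] = _sha256(out / "distance.tsv")
        newick, groups = cluster_samples(dm, linkage=config.linkage, height=config.cluster_height)
        (out / "tree.nwk").write_text(newick + "\n")
        report["files"]["tree.nwk"] = _sha256(out / "tree.nwk")
        report["stages"]["distance"] = {
            "n_groups": len(set(groups.values())),
            "groups": groups,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # ---- species split ----------------------------------------------
        stage = "species_split"
        t0 = time.perf_counter()
        tags = set(table.contig_subgenome.values())
        species: dict[str, str] = {}
        if {"M", "T"} <= tags:
            rule = "subgenome_coverage"
            for s in table.samples:
                cov = subgenome_coverage(table, s)
                species[s] = "minor" if cov.species_call == "pure_M" else "japonica"
        else:
            # allele-balance dosage separates diploids from triploid hybrids;
            # fall back to a two-way tree cut only when spectra are uninformative
            from .ploidy import DosageClass, classify_hybrid_dosage

            dosage_calls = {
                s: classify_hybrid_dosage(allele_ratio_spectrum(table, s)).dosage_class
                for s in table.samples
            }
            informative = {
                DosageClass.DIPLOID_HET,
                DosageClass.TRIPLOID_MMT,
                DosageClass.TRIPLOID_MTT,
            }
            if all(c in informative for c in dosage_calls.values()):
                rule = "allele_balance_dosage"
                species = {
                    s: ("minor" if c is DosageClass.DIPLOID_HET else "japonica")
                    for s, c in dosage_calls.items()
                }
            else:
                rule = "two_way_clustering"
                from scipy.cluster import hierarchy

                z = hierarchy.linkage(dm.condensed(), method=config.linkage)
                flat = hierarchy.fcluster(z, t=2, criterion="maxclust")
                for s, gidx in zip(dm.ids, flat):
                    species[s] = f"cluster{gidx}"
        report["stages"]["species_split"] = {
            "rule": rule,
            "species": species,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # ---- assignment scan --------------------------------------------
        stage = "scan"
        t0 = time.perf_counter()
        if len(set(species.values())) == 2:
            results, summary = scan_assignment_markers(
                table, species, fdr_thresh=config.fdr, dev_thresh=config.dev
            )
            scan_to_frame(results).to_csv(out / "scan.tsv", sep="\t", index=False)
            report["files"]["scan.tsv"] = _sha256(out / "scan.tsv")
            report["stages"]["scan"] = {
                "n_scanned": summary.n_scanned,
                "n_significant": summary.n_significant,
                "fraction_significant": summary.fraction_significant,
                "diff_class_counts": summary.diff_class_counts,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        else:
            report["stages"]["scan"] = {"skipped": "species split did not yield two groups"}

        # ---- ploidy ------------------------------------------------------
        stage = "ploidy"
        t0 = time.perf_counter()
        calls = {}
        for s in table.samples:
            spec_r = allele_ratio_spectrum(table, s)
            call = classify_hybrid_dosage(spec_r)
            calls[s] = {
                "class": call.dosage_class.value,
                "confidence": round(call.confidence, 4),
                "mode": None if np.isnan(spec_r.mode) else round(spec_r.mode, 4),
                "n_het_sites": spec_r.n_sites,
            }
        report["stages"]["ploidy"] = {"calls": calls, "seconds": round(time.perf_counter() - t0, 3)}

        # ---- structure ---------------------------------------------------
        stage = "structure"
        t0 = time.perf_counter()
        pop_of = None
        if metadata is not None and "population" in metadata.columns:
            pop_of = dict(zip(metadata["sample"].astype(str), metadata["population"]))
        struct: dict = {}
        if pop_of is not None:
            wb = within_between_summary(dm, {s: pop_of[s] for s in dm.ids})
            struct["within_between"] = {
                "mean_within": wb.mean_within,
                "mean_between": wb.mean_between,
                "n_within_pairs": wb.n_within_pairs,
                "n_between_pairs": wb.n_between_pairs,
            }
            sizes = pd.Series([pop_of[s] for s in dm.ids]).value_counts()
            if (sizes >= 2).sum() >= 2:
                big = set(sizes[sizes >= 2].index)
                keep_ids = [s for s in dm.ids if pop_of[s] in big]
                sub = dm.reorder(keep_ids)
                disp = dispersion_test(
                    sub, {s: pop_of[s] for s in keep_ids}, nperm=config.nperm, seed=config.seed
                )
                struct["dispersion"] = {"F": disp.f_stat, "p": disp.p_value, "nperm": disp.nperm}
        if metadata is not None and {"lat", "lon"} <= set(metadata.columns):
            meta = metadata.set_index(metadata["sample"].astype(str)).loc[dm.ids].reset_index(drop=True)
            ibd = ibd_test(dm, meta, nperm=config.nperm, seed=config.seed)
            struct["ibd"] = {
                "mantel_r": ibd.mantel.r,
                "mantel_p": ibd.mantel.p_value,
                "anova_F": ibd.anova_f,
                "anova_p": ibd.anova_p,
                "pearson_r": ibd.pearson_r,
            }
        else:
            struct["ibd"] = {"skipped": "no sample coordinates in metadata"}
        struct["seconds"] = round(time.perf_counter() - t0, 3)
        report["stages"]["structure"] = struct
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report
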