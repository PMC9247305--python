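"""End-to-end pipeline: simulate -> QC -> link -> LD/phase -> structure -> tables.

Every stage reads only prior-stage outputs and writes plain TSV/CSV, so all
reported numbers are recomputable from the emitted files.  One seed governs
the whole run; stage-level seeds are derived from it deterministically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from caprilink.genotypes import GenotypeMatrix, write_ped_map
from caprilink.ld import ld_decay, phase_consistency
from caprilink.pedigree import (
    Pedigree,
    link_pedigrees,
    pedigree_inbreeding,
    tabulate_connectedness,
    validate_pedigree,
)
from caprilink.qc import deduplicate, ld_prune, merge_datasets, qc_filter
from caprilink.simulate import PopulationSpec, SimulatedDataset, simulate_dataset
from caprilink.structure import (
    admixture_em,
    choose_k,
    genomic_inbreeding,
    grm,
    inbreeding_comparison,
    pca,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML losslessly."""

    simulation: PopulationSpec = field(default_factory=PopulationSpec)
    maf_min: float = 0.01
    snp_cr_min: float = 0.90
    sample_cr_min: float = 0.90
    prune_window: int = 50
    prune_step: int = 5
    prune_vif: float = 2.0
    fuzzy_threshold: float = 90.0
    ld_max_dist: int = 1_000_000
    ld_bins: int = 50
    admixture_k_min: int = 2
    admixture_k_max: int = 4
    admixture_cv_folds: int = 3
    admixture_max_iter: int = 300
    admixture_tol: float = 1e-2
    pca_components: int = 10
    seed: int = 0
    out_dir: str = "caprilink_run"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "simulation" in d:
            d["simulation"] = PopulationSpec.from_dict(d["simulation"])
        return cls(**d)

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        for name in ("snp_cr_min", "sample_cr_min"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.admixture_k_min > self.admixture_k_max:
            raise ValueError("admixture k grid is empty")


def summarize_counts(
    pedigrees: dict[str, Pedigree],
    genotypes: dict[str, GenotypeMatrix],
) -> pd.DataFrame:
    """Pedigree and genotype counts per country x breed with marginal totals."""
    breeds = sorted({i[:3] for p in pedigrees.values() for i in p.ids if len(i) == 23})
    rows = []
    for country, ped in sorted(pedigrees.items()):
        row = {"country": country}
        ped_breeds = ped.ids.str[:3]
        gm = genotypes.get(country)
        g_breeds = gm.samples["id"].str[:3] if gm is not None else pd.Series(dtype=str)
        for b in breeds:
            row[f"{b}_pedigree"] = int((ped_breeds == b).sum())
            row[f"{b}_genotypes"] = int((g_breeds == b).sum())
        row["total_pedigree"] = sum(row[f"{b}_pedigree"] for b in breeds)
        row["total_genotypes"] = sum(row[f"{b}_genotypes"] for b in breeds)
        rows.append(row)
    out = pd.DataFrame(rows)
    total = {"country": "Total"}
    for col in out.columns[1:]:
        total[col] = int(out[col].sum())
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def run_pipeline(config: RunConfig, dataset: SimulatedDataset | None = None) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of in-memory results; files land under ``config.out_dir``:
    count summary, connectedness tables, inbreeding comparison, LD-decay and
    phase-consistency TSVs, PCA coordinates, admixture Q matrices with the
    cross-validation error table, and a machine-readable run manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "thresholds": {
        "maf_min": config.maf_min,
        "snp_cr_min": config.snp_cr_min,
        "sample_cr_min": config.sample_cr_min,
        "prune_vif": config.prune_vif,
        "fuzzy_threshold": config.fuzzy_threshold,
    }}
    results: dict = {}

    def stage(name):
        t0 = time.time()

        def done():
            manifest["stages"][name] = round(time.time() - t0, 3)

        return done

    # --- simulate ---------------------------------------------------------
    end = stage("simulate")
    if dataset is None:
        spec = config.simulation
        spec.seed = config.seed
        dataset = simulate_dataset(spec)
    for country, ped in dataset.pedigrees.items():
        ped.write_csv(out / f"pedigree_{country}.csv")
    for country, gm in dataset.genotypes.items():
        write_ped_map(gm, out / f"genotypes_{country}")
    dataset.truth_matches.to_csv(out / "truth_matches.tsv", sep="\t", index=False)
    end()

    # --- pedigree validation ---------------------------------------------
    end = stage("validate")
    pedigrees = {}
    for country, ped in dataset.pedigrees.items():
        clean, rep = validate_pedigree(ped)
        pedigrees[country] = clean
        manifest.setdefault("validation", {})[country] = rep.total_actions
    end()

    # --- genotype QC ------------------------------------------------------
    end = stage("qc")
    qc_sets = {}
    for country, gm in dataset.genotypes.items():
        dd, rep = deduplicate(gm)
        filtered, rep = qc_filter(
            dd,
            maf_min=config.maf_min,
            snp_cr_min=config.snp_cr_min,
            sample_cr_min=config.sample_cr_min,
            report=rep,
        )
        qc_sets[country] = filtered
        rep.to_frame().to_csv(out / f"qc_{country}.tsv", sep="\t", index=False)
    merged, merge_rep = merge_datasets(
        list(qc_sets.values()),
        maf_min=config.maf_min,
        snp_cr_min=config.snp_cr_min,
        sample_cr_min=config.sample_cr_min,
    )
    merge_rep.to_frame().to_csv(out / "qc_merged.tsv", sep="\t", index=False)
    results["merged"] = merged
    end()

    # --- counts (Table-1 shape) ------------------------------------------
    counts = summarize_counts(pedigrees, qc_sets)
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    results["counts"] = counts

    # --- linkage + connectedness -----------------------------------------
    end = stage("link")
    matches = {}
    countries = list(pedigrees)
    for src in countries:
        for tgt in countries:
            if src != tgt:
                matches[(src, tgt)] = link_pedigrees(
                    pedigrees[src], pedigrees[tgt], config.fuzzy_threshold
                )
    match_rows = [
        {
            "source": src,
            "target": tgt,
            "target_id": m.target_id,
            "source_id": m.source_id or "",
            "method": m.method,
            "score": m.score,
            "status": m.status,
        }
        for (src, tgt), ml in matches.items()
        for m in ml
    ]
    pd.DataFrame(match_rows).to_csv(out / "matches.tsv", sep="\t", index=False)
    genotyped_ids = {c: set(gm.samples["id"]) for c, gm in qc_sets.items()}
    report = tabulate_connectedness(pedigrees, genotyped_ids, matches, countries)
    report.pairwise.to_csv(out / "connectedness_pairwise.tsv", sep="\t")
    report.foreign_sires.to_csv(out / "foreign_sires.tsv", sep="\t")
    report.foreign_dams.to_csv(out / "foreign_dams.tsv", sep="\t")
    report.shared_genotyped.to_csv(out / "shared_genotyped.tsv", sep="\t", index=False)
    results["connectedness"] = report
    results["matches"] = matches
    end()

    # --- pedigree inbreeding ---------------------------------------------
    end = stage("inbreeding_ped")
    f_ped = []
    for country, ped in pedigrees.items():
        f = pedigree_inbreeding(ped)
        f["country"] = country
        f_ped.append(f)
    f_ped = pd.concat(f_ped, ignore_index=True).drop_duplicates("id")
    f_ped.to_csv(out / "inbreeding_pedigree.tsv", sep="\t", index=False)
    results["f_ped"] = f_ped
    end()

    # --- pruning + genomic inbreeding ------------------------------------
    end = stage("inbreeding_gen")
    kept = ld_prune(
        merged, config.prune_window, config.prune_step, config.prune_vif
    )
    pruned = merged.take_snps(kept)
    f_gen = genomic_inbreeding(pruned)
    f_gen.to_csv(out / "inbreeding_genomic.tsv", sep="\t", index=False)
    sample_meta = merged.samples[["id", "breed", "country"]]
    comparison = inbreeding_comparison(f_ped, f_gen, sample_meta)
    comparison.to_csv(out / "inbreeding_comparison.tsv", sep="\t", index=False)
    results["f_gen"] = f_gen
    results["inbreeding_comparison"] = comparison
    results["pruned"] = pruned
    end()

    # --- LD decay + phase consistency ------------------------------------
    end = stage("ld")
    decay_tables = {}
    for country, gm in qc_sets.items():
        curve = ld_decay(gm, config.ld_max_dist, config.ld_bins)
        curve.to_csv(out / f"ld_decay_{country}.tsv", sep="\t", index=False)
        decay_tables[country] = curve
    results["ld_decay"] = decay_tables
    phase_tables = {}
    clist = list(qc_sets)
    for i, a in enumerate(clist):
        for b in clist[i + 1 :]:
            prof = phase_consistency(qc_sets[a], qc_sets[b], max_dist=config.ld_max_dist)
            prof.to_csv(out / f"phase_consistency_{a}_{b}.tsv", sep="\t", index=False)
            phase_tables[(a, b)] = prof
    results["phase_consistency"] = phase_tables
    end()

    # --- PCA --------------------------------------------------------------
    end = stage("pca")
    g = grm(pruned)
    pc = pca(g, config.pca_components)
    coords = pc.coords.merge(sample_meta, on="id", how="left")
    coords.to_csv(out / "pca_coordinates.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(pc.variance_pct))],
         "variance_pct": pc.variance_pct}
    ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
    results["pca"] = pc
    end()

    # --- admixture --------------------------------------------------------
    end = stage("admixture")
    k_grid = list(range(config.admixture_k_min, config.admixture_k_max + 1))
    cv_table, best_k = choose_k(
        pruned,
        k_grid,
        cv_folds=config.admixture_cv_folds,
        seed=config.seed,
        max_iter=config.admixture_max_iter,
        tol=config.admixture_tol,
    )
    cv_table.to_csv(out / "admixture_cv.tsv", sep="\t", index=False)
    fit = admixture_em(
        pruned,
        best_k,
        seed=config.seed,
        max_iter=config.admixture_max_iter,
        tol=config.admixture_tol,
    )
    qdf = pd.DataFrame(fit.q, columns=[f"q{c+1}" for c in range(best_k)])
    qdf.insert(0, "id", pruned.samples["id"])
    qdf.to_csv(out / f"admixture_q_k{best_k}.tsv", sep="\t", index=False)
    results["admixture"] = fit
    results["cv_table"] = cv_table
    results["best_k"] = best_k
    end()

    manifest["best_k"] = best_k
    manifest["n_merged_samples"] = merged.n_samples
    manifest["n_merged_snps"] = merged.n_snps
    manifest["n_pruned_snps"] = pruned.n_snps
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
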