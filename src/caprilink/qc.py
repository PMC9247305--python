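"""Genotype quality control, dataset merging, and LD-based pruning.

The filter chain mirrors routine SNP-chip practice: drop duplicated samples
keeping the copy with the higher call rate, drop low-call-rate samples,
then low-call-rate SNPs, then rare SNPs.  Thresholds use strict inequality,
so a marker at exactly the MAF boundary is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from caprilink.genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class EmptyDatasetError(ValueError):
    """All samples or SNPs removed; carries the responsible QC stage."""

    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"QC stage {stage!r} removed all remaining data")


@dataclass
class QCReport:
    """Per-stage removal counts; removed + retained = input at every stage."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, kind: str, n_in: int, n_removed: int) -> None:
        self.stages.append(
            {
                "stage": stage,
                "kind": kind,
                "n_input": n_in,
                "n_removed": n_removed,
                "n_retained": n_in - n_removed,
            }
        )

    def removed(self, stage: str) -> int:
        return sum(s["n_removed"] for s in self.stages if s["stage"] == stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def deduplicate(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, QCReport]:
    """Keep one sample per canonical ID, preferring the higher call rate.

    Ties are broken by first occurrence (and logged).
    """
    report = QCReport()
    ids = gm.samples["id"].to_numpy()
    cr = gm.sample_call_rate()
    keep = np.ones(gm.n_samples, dtype=bool)
    for uid in pd.unique(ids):
        pos = np.flatnonzero(ids == uid)
        if len(pos) == 1:
            continue
        best = pos[np.argmax(cr[pos])]
        if np.sum(cr[pos] == cr[best]) > 1:
            best = pos[np.flatnonzero(cr[pos] == cr[best])[0]]
            logger.info("duplicate tie for %s broken by first occurrence", uid)
        for p in pos:
            if p != best:
                keep[p] = False
    report.record("deduplicate", "samples", gm.n_samples, int((~keep).sum()))
    return gm.take_samples(np.flatnonzero(keep)), report


def qc_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    snp_cr_min: float = 0.90,
    sample_cr_min: float = 0.90,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove low-call-rate samples, then low-call-rate SNPs, then rare SNPs.

    All thresholds use strict ``<`` comparisons, so boundary values are
    kept.  SNP call rate and MAF are computed on the samples remaining
    after sample removal.
    """
    if report is None:
        report = QCReport()

    cr = gm.sample_call_rate()
    keep_s = cr >= sample_cr_min
    report.record("sample_call_rate", "samples", gm.n_samples, int((~keep_s).sum()))
    gm = gm.take_samples(np.flatnonzero(keep_s))
    if gm.n_samples == 0:
        raise EmptyDatasetError("sample_call_rate")

    scr = gm.snp_call_rate()
    keep_cr = scr >= snp_cr_min
    report.record("snp_call_rate", "snps", gm.n_snps, int((~keep_cr).sum()))
    gm = gm.take_snps(np.flatnonzero(keep_cr))
    if gm.n_snps == 0:
        raise EmptyDatasetError("snp_call_rate")

    maf = gm.maf()
    keep_maf = maf >= maf_min
    report.record("maf", "snps", gm.n_snps, int((~keep_maf).sum()))
    gm = gm.take_snps(np.flatnonzero(keep_maf))
    if gm.n_snps == 0:
        raise EmptyDatasetError("maf")

    return gm, report


def merge_datasets(
    datasets: list[GenotypeMatrix],
    run_qc: bool = True,
    **qc_kwargs,
) -> tuple[GenotypeMatrix, QCReport]:
    """Merge per-country genotype matrices on the shared SNP set.

    The SNP set is the intersection of the input maps (matched by SNP name).
    Where a dataset codes a SNP with swapped allele labels relative to the
    first dataset, calls are recoded (2 - g); a SNP whose labels cannot be
    reconciled at all is dropped and logged.  Samples are concatenated and,
    by default, the QC filter chain is re-applied to the merged matrix.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    report = QCReport()
    ref = datasets[0]
    common = set(ref.variants["snp"])
    for gm in datasets[1:]:
        common &= set(gm.variants["snp"])
    if not common:
        raise EmptyDatasetError("merge_intersection")
    ref_keep = ref.variants["snp"].isin(common).to_numpy()
    order = ref.variants.loc[ref_keep, "snp"].tolist()
    ref_var = ref.variants.set_index("snp")

    dropped: set[str] = set()
    aligned_calls = []
    aligned_phase = []
    have_phase = all(gm.phase is not None for gm in datasets)
    for gm in datasets:
        var = gm.variants.set_index("snp")
        sub = var.loc[order]
        flip = np.zeros(len(order), dtype=bool)
        for k, snp in enumerate(order):
            a1, a2 = sub["a1"].iloc[k], sub["a2"].iloc[k]
            r1, r2 = ref_var.loc[snp, "a1"], ref_var.loc[snp, "a2"]
            if (a1, a2) == (r1, r2):
                continue
            if (a1, a2) == (r2, r1):
                flip[k] = True
            else:
                dropped.add(snp)
        col_of = {s: k for k, s in enumerate(gm.variants["snp"])}
        pos = np.array([col_of[s] for s in order])
        calls = gm.calls[:, pos].astype(np.int8)
        fl = np.flatnonzero(flip)
        sub_fl = calls[:, fl]
        sub_fl = np.where(sub_fl == MISSING, MISSING, 2 - sub_fl)
        calls[:, fl] = sub_fl
        aligned_calls.append(calls)
        if have_phase:
            ph = gm.phase[:, :, pos].astype(np.int8)
            ph[:, :, fl] = 1 - ph[:, :, fl]
            aligned_phase.append(ph)

    keep = np.array([s not in dropped for s in order])
    if dropped:
        logger.warning("dropped %d SNPs with irreconcilable alleles", len(dropped))
    report.record("merge_alleles", "snps", len(order), len(dropped))
    calls = np.vstack(aligned_calls)[:, keep]
    variants = ref_var.loc[order].reset_index().loc[keep].reset_index(drop=True)
    samples = pd.concat([gm.samples for gm in datasets], ignore_index=True)
    phase = np.vstack(aligned_phase)[:, :, keep] if have_phase else None
    merged = GenotypeMatrix(calls=calls, variants=variants, samples=samples, phase=phase)
    if run_qc:
        merged, report = qc_filter(merged, report=report, **qc_kwargs)
    return merged, report


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step: int = 5,
    vif_max: float = 2.0,
) -> np.ndarray:
    """Sliding-window variance-inflation-factor pruning.

    Within each window of ``window_snps`` SNPs (advancing by ``step``,
    clipped at chromosome ends) the SNP with the highest VIF — the diagonal
    of the inverse genotype correlation matrix — is removed until all
    remaining VIFs are at most ``vif_max``.  A SNP in perfect LD with
    another has infinite VIF and is always removed.  Returns the sorted
    array of retained SNP indices; the procedure is deterministic.
    """
    m = gm.n_snps
    removed = np.zeros(m, dtype=bool)
    calls = gm.calls.astype(float)
    calls[gm.calls == MISSING] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    inds = np.where(np.isnan(calls), col_mean, calls)
    sd = inds.std(axis=0)
    chroms = gm.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(cidx):
            win = cidx[start : start + window_snps]
            active = [j for j in win if not removed[j] and sd[j] > 0]
            while len(active) > 1:
                X = inds[:, active]
                C = np.corrcoef(X, rowvar=False)
                # perfect LD makes C singular; drop the later member of the
                # most correlated pair first
                iu = np.triu_indices(len(active), k=1)
                if np.any(np.abs(C[iu]) > 1 - 1e-10):
                    k = np.argmax(np.abs(C[iu]))
                    j = max(iu[0][k], iu[1][k])
                    removed[active[j]] = True
                    active.pop(j)
                    continue
                try:
                    vif = np.diag(np.linalg.inv(C))
                except np.linalg.LinAlgError:
                    vif = np.diag(np.linalg.pinv(C))
                worst = int(np.argmax(vif))
                if vif[worst] > vif_max:
                    removed[active[worst]] = True
                    active.pop(worst)
                else:
                    break
            if start + window_snps >= len(cidx):
                break
            start += step
    retained = np.flatnonzero(~removed & (sd > 0))
    mono = np.flatnonzero(~removed & (sd == 0))
    if len(mono):
        logger.info("%d monomorphic SNPs excluded from pruned set", len(mono))
    return retained
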