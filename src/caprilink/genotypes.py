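"""Diploid SNP genotype container and PED/MAP text I/O.

Calls are stored individual x SNP as counts of the reference allele
(0, 1, 2) with -1 for missing.  The marker map holds chromosome, 1-based
physical position and the two allele labels per SNP; sample metadata holds
the canonical ID, breed, country and birth year.  Phased haplotypes, when
known (e.g. from simulation), ride along as an (n, 2, m) array and serve as
ground truth for phase-dependent statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

MAP_COLUMNS = ["chrom", "snp", "bp", "a1", "a2"]
SAMPLE_COLUMNS = ["id", "breed", "country", "birth_year"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs diploid calls plus marker map and sample metadata."""

    calls: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D individuals x SNPs array")
        n, m = self.calls.shape
        if len(self.variants) != m:
            raise ValueError("marker map length does not match call matrix")
        if len(self.samples) != n:
            raise ValueError("sample table length does not match call matrix")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=np.int8)
            if self.phase.shape != (n, 2, m):
                raise ValueError("phase must have shape (n, 2, m)")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per individual."""
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        if self.n_samples == 0:
            return np.ones(self.n_snps)
        return (self.calls != MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Reference-allele frequency per SNP, missing calls excluded."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        tot = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, tot / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            calls=self.calls[idx],
            samples=self.samples.iloc[idx],
            phase=None if self.phase is None else self.phase[idx],
        )

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            calls=self.calls[:, idx],
            variants=self.variants.iloc[idx],
            phase=None if self.phase is None else self.phase[:, :, idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            calls=self.calls.copy(),
            variants=self.variants.copy(),
            samples=self.samples.copy(),
            phase=None if self.phase is None else self.phase.copy(),
        )


def write_ped_map(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write PED/MAP text files (``<prefix>.ped`` and ``<prefix>.map``).

    The PED line prefix is family (country), individual ID, sire 0, dam 0,
    sex code, phenotype placeholder -9, followed by two allele labels per
    SNP; ``0 0`` encodes a missing call.
    """
    prefix = Path(prefix)
    mp = gm.variants
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in mp.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{int(row['bp'])}\n")
    a1 = mp["a1"].to_numpy()
    a2 = mp["a2"].to_numpy()
    sex_code = gm.samples["id"].astype(str).str[6].map({"M": "1", "F": "2"}).fillna("0")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(gm.n_samples):
            row = gm.samples.iloc[i]
            g = gm.calls[i]
            alleles = np.empty((gm.n_snps, 2), dtype=object)
            alleles[g == 2] = np.stack([a1, a1], axis=1)[g == 2]
            alleles[g == 1] = np.stack([a1, a2], axis=1)[g == 1]
            alleles[g == 0] = np.stack([a2, a2], axis=1)[g == 0]
            alleles[g == MISSING] = ["0", "0"]
            fields = [
                str(row.get("country", "0")),
                str(row["id"]),
                "0",
                "0",
                sex_code.iloc[i],
                "-9",
            ] + [a for pair in alleles for a in pair]
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Read PED/MAP text files written by :func:`write_ped_map`.

    Allele labels are taken from the data: the first allele observed at a
    SNP becomes ``a1`` (reference) unless both labels are seen, in which
    case the lexicographically smaller label is the reference.
    """
    prefix = Path(prefix)
    mp = pd.read_csv(
        prefix.with_suffix(".map"),
        sep="\t",
        header=None,
        names=["chrom", "snp", "cm", "bp"],
        dtype={"chrom": str, "snp": str},
    )
    m = len(mp)
    ids, countries, sexes = [], [], []
    rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError("malformed PED line")
            countries.append(parts[0])
            ids.append(parts[1])
            sexes.append({"1": "M", "2": "F"}.get(parts[4], "U"))
            rows.append(np.array(parts[6:], dtype=object).reshape(m, 2))
    alleles = np.stack(rows) if rows else np.empty((0, m, 2), dtype=object)
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    calls = np.full((len(rows), m), MISSING, dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        seen = sorted({a for a in col.ravel() if a != "0"})
        if not seen:
            a1[j], a2[j] = "A", "B"
            continue
        if len(seen) == 1:
            a1[j] = seen[0]
            a2[j] = "B" if seen[0] != "B" else "A"
        else:
            a1[j], a2[j] = seen[0], seen[1]
        obs = (col != "0").all(axis=1)
        calls[obs, j] = (col[obs] == a1[j]).sum(axis=1)
    variants = pd.DataFrame(
        {"chrom": mp["chrom"], "snp": mp["snp"], "bp": mp["bp"], "a1": a1, "a2": a2}
    )
    breeds = [i[:3] if len(i) == 23 else "" for i in ids]
    samples = pd.DataFrame(
        {
            "id": ids,
            "breed": breeds,
            "country": countries,
            "birth_year": pd.NA,
        }
    )
    samples["sex"] = sexes
    return GenotypeMatrix(calls=calls, variants=variants, samples=samples)
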