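"""Synthetic multi-country goat populations: pedigrees and phased genotypes.

The generator produces the statistical structure the downstream analyses
assume, without any external data:

* population divergence by a two-level Balding-Nichols model (ancestral ->
  breed -> country within breed), so PCA and admixture have real structure
  to recover;
* founder haplotypes as mosaics of a finite pool of ancestral templates,
  switching template between adjacent SNPs with probability
  ``1 - exp(-rate * distance)``, which yields linkage disequilibrium that
  decays with physical distance;
* gene dropping down discrete-generation pedigrees with Haldane
  recombination, so pedigree-based and genomic inbreeding are comparable;
* unidirectional live-animal export flows (France as the main exporter),
  with exported sires re-registered in the importing pedigree under clean,
  truncated, typo-bearing or alias identifiers, and a truth table recording
  every correspondence;
* per-country genotyping windows over birth years, emulating national
  genotyping campaigns that started in different years.

Everything is driven by a single integer seed; identical spec and seed give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from caprilink.genotypes import MISSING, GenotypeMatrix
from caprilink.ids import birth_code, standardize_id
from caprilink.pedigree import Pedigree


@dataclass
class IDCorruption:
    """Rates of identifier damage applied to imported-animal registrations."""

    truncation: float = 0.10  # keep only trailing digits of the foreign ID
    typo: float = 0.05  # substitute one digit
    alias: float = 0.30  # re-register locally, true ID kept as alias
    truncate_to: int = 5  # digits kept under truncation

    def validate(self) -> None:
        for name in ("truncation", "typo", "alias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} rate must be in [0, 1], got {v}")
        if self.truncation + self.typo + self.alias > 1.0:
            raise ValueError("corruption rates must sum to at most 1")


@dataclass
class PopulationSpec:
    """Parameters of the synthetic multi-country study design.

    Defaults emulate a two-breed, four-country design with France as the
    dominant exporter, moderate country-level divergence (strongest for the
    transatlantic population), and staggered per-country genotyping
    campaigns.
    """

    breeds: list[str] = field(default_factory=lambda: ["ALP", "SAA"])
    countries: list[str] = field(default_factory=lambda: ["CAN", "FRA", "ITA", "CHE"])
    n_founders: int = 60  # per breed x country population
    n_generations: int = 5
    offspring_per_mating: int = 2
    fst: dict = field(
        default_factory=lambda: {"CAN": 0.15, "FRA": 0.05, "ITA": 0.06, "CHE": 0.10}
    )
    fst_breed: float = 0.08  # breed-level divergence from the common ancestor
    export_rate: dict = field(
        default_factory=lambda: {
            ("FRA", "ITA"): 0.20,
            ("FRA", "CHE"): 0.08,
            ("FRA", "CAN"): 0.05,
            ("CHE", "ITA"): 0.05,
        }
    )
    export_dams: bool = False  # live-animal flow is sire-dominated
    n_ancestral_haplotypes: int = 20
    n_snps: int = 250  # per chromosome
    n_chromosomes: int = 2
    chrom_length_bp: int = 2_500_000
    mosaic_switch_rate: float = 2e-6  # per bp
    recomb_rate: float = 1e-8  # Morgans per bp (1 cM/Mb)
    id_corruption: IDCorruption = field(default_factory=IDCorruption)
    genotyping_windows: dict = field(
        default_factory=lambda: {
            "FRA": (1993, 2020),
            "CHE": (1996, 2020),
            "CAN": (1996, 2020),
            "ITA": (1999, 2020),
        }
    )
    missing_rate: float = 0.02
    female_fraction: float = 0.8  # offspring sex ratio, matching dairy herds
    base_year: int = 1990
    generation_interval: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for c, f in self.fst.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"fst for {c} must be in (0, 1), got {f}")
        if not 0.0 < self.fst_breed < 1.0:
            raise ValueError("fst_breed must be in (0, 1)")
        for (a, b), r in self.export_rate.items():
            if a == b:
                continue  # diagonal ignored
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"export rate {a}->{b} must be in [0, 1]")
        for name in (
            "n_founders",
            "n_generations",
            "offspring_per_mating",
            "n_ancestral_haplotypes",
            "n_snps",
            "n_chromosomes",
            "chrom_length_bp",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        self.id_corruption.validate()

    @property
    def populations(self) -> list[tuple[str, str]]:
        return [(b, c) for b in self.breeds for c in self.countries]

    @property
    def n_total_snps(self) -> int:
        return self.n_snps * self.n_chromosomes

    def marker_map(self) -> pd.DataFrame:
        rows = []
        spacing = self.chrom_length_bp / self.n_snps
        for chrom in range(1, self.n_chromosomes + 1):
            for j in range(self.n_snps):
                rows.append(
                    {
                        "chrom": str(chrom),
                        "snp": f"c{chrom}_s{j}",
                        "bp": int((j + 1) * spacing),
                        "a1": "A",
                        "a2": "B",
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["export_rate"] = {f"{a}>{b}": r for (a, b), r in self.export_rate.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        d = dict(d)
        if "export_rate" in d:
            d["export_rate"] = {
                tuple(k.split(">")): v for k, v in d["export_rate"].items()
            }
        if "id_corruption" in d and isinstance(d["id_corruption"], dict):
            d["id_corruption"] = IDCorruption(**d["id_corruption"])
        d["genotyping_windows"] = {
            k: tuple(v) for k, v in d.get("genotyping_windows", {}).items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# Allele frequencies and founder haplotypes
# ---------------------------------------------------------------------------


def balding_nichols(p_anc: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Draw descendant-population frequencies around ancestral ones.

    Frequencies follow Beta(p (1-F)/F, (1-p)(1-F)/F), whose mean is p and
    variance p (1-p) F; the draw is clipped to [0.01, 0.99] to keep every
    SNP segregating.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError(f"fst must be in (0, 1), got {fst}")
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 0.01, 0.99)


def draw_population_frequencies(
    spec: PopulationSpec,
) -> tuple[dict[tuple[str, str], np.ndarray], np.ndarray]:
    """Per-(breed, country) allele frequencies under the two-level model.

    A common ancestral frequency (uniform on [0.05, 0.95]) diverges first
    into breed-level frequencies (F = fst_breed), then into country-level
    frequencies within each breed (F = fst[country]).  Returns the
    population frequencies and the ancestral vector.
    """
    m = spec.n_total_snps
    rng = np.random.default_rng([spec.seed, 1])
    p_anc = rng.uniform(0.05, 0.95, size=m)
    freqs: dict[tuple[str, str], np.ndarray] = {}
    for bi, breed in enumerate(spec.breeds):
        breed_rng = np.random.default_rng([spec.seed, 2, bi])
        p_breed = balding_nichols(p_anc, spec.fst_breed, breed_rng)
        for ci, country in enumerate(spec.countries):
            pop_rng = np.random.default_rng([spec.seed, 3, bi, ci])
            freqs[(breed, country)] = balding_nichols(
                p_breed, spec.fst[country], pop_rng
            )
    return freqs, p_anc


def simulate_founder_haplotypes(
    spec: PopulationSpec,
    pop_freqs: dict[tuple[str, str], np.ndarray],
) -> dict[tuple[str, str], np.ndarray]:
    """Phased founder haplotypes as mosaics of ancestral templates.

    Each population gets ``n_ancestral_haplotypes`` templates drawn
    site-independently from its frequencies.  A founder haplotype copies
    one template and, between adjacent SNPs at distance d, switches to a
    uniformly chosen template with probability ``1 - exp(-rate * d)``.
    Shared template stretches between founders create LD that decays with
    distance.  Returns (2 * n_founders, m) arrays per population.
    """
    mp = spec.marker_map()
    bp = mp["bp"].to_numpy()
    chrom = mp["chrom"].to_numpy()
    m = len(mp)
    gaps = np.diff(bp).astype(float)
    new_chrom = chrom[1:] != chrom[:-1]
    p_switch = 1.0 - np.exp(-spec.mosaic_switch_rate * gaps)
    p_switch[new_chrom] = 1.0  # chromosomes are independent

    out: dict[tuple[str, str], np.ndarray] = {}
    for pi, (pop, freq) in enumerate(sorted(pop_freqs.items())):
        rng = np.random.default_rng([spec.seed, 4, pi])
        templates = (rng.random((spec.n_ancestral_haplotypes, m)) < freq).astype(
            np.int8
        )
        h = 2 * spec.n_founders
        tidx = rng.integers(0, spec.n_ancestral_haplotypes, size=h)
        haps = np.empty((h, m), dtype=np.int8)
        haps[:, 0] = templates[tidx, 0]
        for j in range(1, m):
            switch = rng.random(h) < p_switch[j - 1]
            if switch.any():
                tidx = np.where(
                    switch,
                    rng.integers(0, spec.n_ancestral_haplotypes, size=h),
                    tidx,
                )
            haps[:, j] = templates[tidx, j]
        out[pop] = haps
    return out


# ---------------------------------------------------------------------------
# Pedigree simulation with export flows
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes plus the ground truth behind it."""

    spec: PopulationSpec
    pedigrees: dict  # country -> Pedigree (native + imported records)
    genotypes: dict  # country -> GenotypeMatrix (phased)
    global_pedigree: pd.DataFrame  # one row per animal, native IDs
    truth_matches: pd.DataFrame  # stored_id <-> true_id per importing country
    truth_ancestry: pd.DataFrame  # per genotyped animal, founder-population fractions
    pop_freqs: dict  # (breed, country) -> founder allele frequencies
    ancestral_freqs: np.ndarray


def _corrupt_registration(
    true_id: str,
    importing_country: str,
    alloc_local,
    source_digits: set[str],
    corruption: IDCorruption,
    rng: np.random.Generator,
) -> tuple[str, str, str]:
    """Stored ID, alias, and corruption kind for an imported animal's record.

    Truncation keeps the birth-country letters and only the trailing digits
    of the local number.  A typo substitutes one significant digit, retried
    so the damaged number never coincides with a real source-country number
    (such a collision would be unresolvable for any linkage method).
    """
    breed, sex, core = true_id[:3], true_id[6], true_id[7:]
    letters = "".join(c for c in core if c.isalpha())[:2]
    digits = core[core.index(letters) + 2 :] if letters in core else ""
    u = rng.random()
    if u < corruption.truncation and len(digits) > corruption.truncate_to:
        kept = digits[-corruption.truncate_to :]
        new_core = (letters + kept).rjust(16, "0")
        return breed + importing_country + sex + new_core, "", "truncation"
    if u < corruption.truncation + corruption.typo:
        sig = [k for k, c in enumerate(digits) if c != "0"] or list(range(len(digits)))
        for _ in range(25):
            pos = int(rng.choice(sig))
            new = str((int(digits[pos]) + int(rng.integers(1, 10))) % 10)
            new_digits = digits[:pos] + new + digits[pos + 1 :]
            if new_digits not in source_digits:
                break
        new_core = (letters + new_digits).rjust(16, "0")
        return breed + importing_country + sex + new_core, "", "typo"
    if u < corruption.truncation + corruption.typo + corruption.alias:
        local_id = standardize_id(
            str(alloc_local()),
            breed,
            importing_country,
            sex,
            birth_code(importing_country),
        )
        return str(local_id), true_id, "alias"
    return breed + importing_country + sex + core, "", "none"


def simulate_pedigree(
    spec: PopulationSpec,
) -> tuple[dict[str, Pedigree], pd.DataFrame, pd.DataFrame]:
    """Discrete-generation pedigrees with unidirectional export flows.

    Matings happen within country; with probability ``export_rate[A, B]`` a
    mating in country B uses a sire from country A (same breed), whose
    record is then re-registered in B's pedigree — clean, truncated, with a
    typo, or under a local alias, at the configured corruption rates.
    Returns per-country pedigrees, the global one-record-per-animal
    pedigree, and the truth match table covering every imported
    registration.
    """
    rng = np.random.default_rng([spec.seed, 5])
    # sparse local numbering: random strides keep single-digit typos from
    # landing on another real animal's number
    counters = {c: [1_000_000] for c in spec.countries}
    digits_used: dict[str, set[str]] = {c: set() for c in spec.countries}

    def alloc_local(country: str) -> int:
        counters[country][0] += int(rng.integers(100, 150))
        digits_used[country].add(str(counters[country][0]))
        return counters[country][0]

    global_rows: list[dict] = []
    native_rows: dict[str, list[dict]] = {c: [] for c in spec.countries}
    foreign_rows: dict[str, list[dict]] = {c: [] for c in spec.countries}
    truth_rows: list[dict] = []
    # (breed, country) -> generation -> lists of (id, sex)
    pools: dict[tuple[str, str], dict[int, list[tuple[str, str]]]] = {}
    imported_seen: dict[str, set[str]] = {c: set() for c in spec.countries}

    def new_animal(breed, country, sex, year, sire, dam, generation):
        cid = str(
            standardize_id(
                str(alloc_local(country)), breed, country, sex, birth_code(country)
            )
        )
        rec = {
            "id": cid,
            "sire": sire,
            "dam": dam,
            "sex": sex,
            "birth_year": year,
            "breed": breed,
            "country": country,
            "alias1": "",
            "alias2": "",
            "alias3": "",
            "generation": generation,
        }
        global_rows.append(rec)
        native_rows[country].append({k: v for k, v in rec.items() if k != "generation"})
        return cid

    for pop in spec.populations:
        breed, country = pop
        pools[pop] = {0: []}
        for i in range(spec.n_founders):
            sex = "F" if rng.random() < spec.female_fraction else "M"
            if i < 4:  # guarantee a handful of each sex among founders
                sex = "M" if i % 2 else "F"
            cid = new_animal(breed, country, sex, spec.base_year, "", "", 0)
            pools[pop][0].append((cid, sex))

    sire_origin_of: dict[str, str] = {}  # native country of every animal

    for rec in global_rows:
        sire_origin_of[rec["id"]] = rec["country"]

    for gen in range(1, spec.n_generations + 1):
        year = spec.base_year + gen * spec.generation_interval
        for pop in spec.populations:
            breed, country = pop
            prev = pools[pop][gen - 1]
            dams = [a for a in prev if a[1] == "F"]
            local_sires = [a for a in prev if a[1] == "M"]
            pools[pop][gen] = []
            n_matings = max(1, spec.n_founders // spec.offspring_per_mating)
            exporters = [
                (a, r) for (a, b), r in spec.export_rate.items() if b == country and a != country
            ]
            for _ in range(n_matings):
                dam_id = dams[int(rng.integers(len(dams)))][0] if dams else ""
                sire_id = ""
                for src, rate in exporters:
                    if rng.random() < rate:
                        src_pool = [
                            a for a in pools[(breed, src)][gen - 1] if a[1] == "M"
                        ]
                        if src_pool:
                            sire_id = src_pool[int(rng.integers(len(src_pool)))][0]
                            break
                if not sire_id and local_sires:
                    sire_id = local_sires[int(rng.integers(len(local_sires)))][0]

                sire_stored = sire_id
                if sire_id and sire_origin_of.get(sire_id) != country:
                    # register the imported sire locally (once)
                    if sire_id not in imported_seen[country]:
                        imported_seen[country].add(sire_id)
                        src_country = sire_origin_of[sire_id]
                        stored, alias, kind = _corrupt_registration(
                            sire_id,
                            country,
                            lambda c=country: alloc_local(c),
                            digits_used[src_country],
                            spec.id_corruption,
                            rng,
                        )
                        src_rec = next(
                            r for r in global_rows if r["id"] == sire_id
                        )
                        foreign_rows[country].append(
                            {
                                "id": stored,
                                "sire": "",
                                "dam": "",
                                "sex": "M",
                                "birth_year": src_rec["birth_year"],
                                "breed": breed,
                                "country": country,
                                "alias1": alias,
                                "alias2": "",
                                "alias3": "",
                            }
                        )
                        truth_rows.append(
                            {
                                "importing_country": country,
                                "stored_id": stored,
                                "true_id": sire_id,
                                "corruption": kind,
                            }
                        )
                    stored = next(
                        t["stored_id"]
                        for t in truth_rows
                        if t["true_id"] == sire_id and t["importing_country"] == country
                    )
                    sire_stored = stored

                for _ in range(spec.offspring_per_mating):
                    sex = "F" if rng.random() < spec.female_fraction else "M"
                    cid = new_animal(
                        breed, country, sex, year, sire_id, dam_id, gen
                    )
                    sire_origin_of[cid] = country
                    pools[pop][gen].append((cid, sex))
                    # the national file stores the (possibly corrupted)
                    # local registration of an imported sire
                    native_rows[country][-1]["sire"] = sire_stored

    pedigrees = {
        c: Pedigree(
            df=pd.DataFrame(foreign_rows[c] + native_rows[c]), country=c
        )
        for c in spec.countries
    }
    global_ped = pd.DataFrame(global_rows)
    truth = pd.DataFrame(
        truth_rows, columns=["importing_country", "stored_id", "true_id", "corruption"]
    )
    return pedigrees, global_ped, truth


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


def _gamete(
    haps: np.ndarray,
    bp: np.ndarray,
    chrom_starts: list[int],
    chrom_len: int,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombined haplotype under the Haldane model.

    Crossover count per chromosome is Poisson with mean rate x length;
    positions are uniform.  The transmitted allele at a SNP comes from the
    parental haplotype selected by the parity of crossovers before it.
    """
    out = np.empty(haps.shape[1], dtype=np.int8)
    for k, start in enumerate(chrom_starts):
        stop = chrom_starts[k + 1] if k + 1 < len(chrom_starts) else haps.shape[1]
        pos = bp[start:stop]
        n_x = rng.poisson(recomb_rate * chrom_len)
        first = rng.integers(2)
        if n_x == 0:
            out[start:stop] = haps[first, start:stop]
            continue
        xpos = np.sort(rng.uniform(0, chrom_len, size=n_x))
        n_before = np.searchsorted(xpos, pos)
        which = (first + n_before) % 2
        seg = haps[:, start:stop]
        out[start:stop] = seg[which, np.arange(stop - start)]
    return out


def gene_drop(
    spec: PopulationSpec,
    global_ped: pd.DataFrame,
    founder_haps: dict[tuple[str, str], np.ndarray],
) -> dict[str, np.ndarray]:
    """Drop founder haplotypes through the pedigree with recombination.

    Founders take consecutive haplotype pairs from their population's pool;
    every non-founder receives one recombined gamete per parent.  Phase is
    retained.  Returns id -> (2, m) haplotype array.
    """
    mp = spec.marker_map()
    bp = mp["bp"].to_numpy()
    chrom = mp["chrom"].to_numpy()
    chrom_starts = [0] + list(np.flatnonzero(chrom[1:] != chrom[:-1]) + 1)
    rng = np.random.default_rng([spec.seed, 6])

    df = global_ped.sort_values("generation", kind="stable")
    haps: dict[str, np.ndarray] = {}
    founder_cursor: dict[tuple[str, str], int] = {p: 0 for p in founder_haps}
    for _, rec in df.iterrows():
        pop = (rec["breed"], rec["country"])
        if not rec["sire"] and not rec["dam"]:
            cur = founder_cursor[pop]
            pool = founder_haps[pop]
            if 2 * cur + 1 >= len(pool):
                raise ValueError("founder haplotype pool exhausted")
            haps[rec["id"]] = pool[2 * cur : 2 * cur + 2].copy()
            founder_cursor[pop] = cur + 1
            continue
        gametes = []
        for parent in (rec["sire"], rec["dam"]):
            if parent and parent in haps:
                gametes.append(
                    _gamete(
                        haps[parent],
                        bp,
                        chrom_starts,
                        spec.chrom_length_bp,
                        spec.recomb_rate,
                        rng,
                    )
                )
            else:
                # unknown parent side: an independent draw from the founder pool
                pool = founder_haps[pop]
                j = int(rng.integers(len(pool)))
                gametes.append(pool[j].copy())
        haps[rec["id"]] = np.stack(gametes)
    return haps


def mendelian_violations(
    global_ped: pd.DataFrame, haps: dict[str, np.ndarray]
) -> int:
    """Count loci where an offspring genotype is impossible given its parents."""
    bad = 0
    for _, rec in global_ped.iterrows():
        if not rec["sire"] or not rec["dam"]:
            continue
        if rec["sire"] not in haps or rec["dam"] not in haps:
            continue
        g = haps[rec["id"]].sum(axis=0)
        gs = haps[rec["sire"]].sum(axis=0)
        gd = haps[rec["dam"]].sum(axis=0)
        lo = np.where(gs == 2, 1, 0) + np.where(gd == 2, 1, 0)
        hi = np.where(gs == 0, 0, 1) + np.where(gd == 0, 0, 1)
        bad += int(np.sum((g < lo) | (g > hi)))
    return bad


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _truth_ancestry(global_ped: pd.DataFrame, populations: list) -> pd.DataFrame:
    """Founder-population fractions per animal (founders one-hot, then averaged)."""
    pop_index = {p: i for i, p in enumerate(populations)}
    k = len(populations)
    vec: dict[str, np.ndarray] = {}
    for _, rec in global_ped.sort_values("generation", kind="stable").iterrows():
        if not rec["sire"] and not rec["dam"]:
            v = np.zeros(k)
            v[pop_index[(rec["breed"], rec["country"])]] = 1.0
            vec[rec["id"]] = v
        else:
            parts = []
            for parent in (rec["sire"], rec["dam"]):
                if parent and parent in vec:
                    parts.append(vec[parent])
                else:
                    v = np.zeros(k)
                    v[pop_index[(rec["breed"], rec["country"])]] = 1.0
                    parts.append(v)
            vec[rec["id"]] = 0.5 * (parts[0] + parts[1])
    cols = [f"{b}_{c}" for b, c in populations]
    out = pd.DataFrame.from_dict(vec, orient="index", columns=cols)
    out.index.name = "id"
    return out.reset_index()


def simulate_dataset(spec: PopulationSpec) -> SimulatedDataset:
    """Run the full generator: frequencies, founders, pedigree, gene drop, QC-ready files.

    Animals are genotyped in their native country when their birth year
    falls inside that country's genotyping window; calls are masked
    missing i.i.d. at ``missing_rate`` while the phased truth is retained.
    """
    pop_freqs, p_anc = draw_population_frequencies(spec)
    founders = simulate_founder_haplotypes(spec, pop_freqs)
    pedigrees, global_ped, truth_matches = simulate_pedigree(spec)
    haps = gene_drop(spec, global_ped, founders)
    mp = spec.marker_map()
    rng = np.random.default_rng([spec.seed, 7])

    genotypes: dict[str, GenotypeMatrix] = {}
    for country in spec.countries:
        lo, hi = spec.genotyping_windows.get(country, (-np.inf, np.inf))
        sub = global_ped[
            (global_ped["country"] == country)
            & (global_ped["birth_year"] >= lo)
            & (global_ped["birth_year"] <= hi)
        ]
        if not len(sub):
            continue
        phase = np.stack([haps[i] for i in sub["id"]])
        calls = phase.sum(axis=1).astype(np.int8)
        mask = rng.random(calls.shape) < spec.missing_rate
        calls[mask] = MISSING
        samples = sub[["id", "breed", "country", "birth_year"]].reset_index(drop=True)
        samples = samples.assign(sex=sub["sex"].to_numpy())
        genotypes[country] = GenotypeMatrix(
            calls=calls, variants=mp.copy(), samples=samples, phase=phase
        )

    ancestry = _truth_ancestry(global_ped, spec.populations)
    return SimulatedDataset(
        spec=spec,
        pedigrees=pedigrees,
        genotypes=genotypes,
        global_pedigree=global_ped,
        truth_matches=truth_matches,
        truth_ancestry=ancestry,
        pop_freqs=pop_freqs,
        ancestral_freqs=p_anc,
    )


# ---------------------------------------------------------------------------
# Stand-alone panels and estimators used for calibration checks
# ---------------------------------------------------------------------------


def simulate_admixture_panel(
    n_per_pop: int,
    n_snps: int,
    fst: float,
    k: int,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """K well-separated Balding-Nichols populations in Hardy-Weinberg.

    Genotypes are binomial draws from each population's frequencies; the
    returned truth matrix is the one-hot ancestry of each individual.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    calls = np.empty((n_per_pop * k, n_snps), dtype=np.int8)
    truth = np.zeros((n_per_pop * k, k))
    for c in range(k):
        p = balding_nichols(p_anc, fst, rng)
        block = slice(c * n_per_pop, (c + 1) * n_per_pop)
        calls[block] = rng.binomial(2, p, size=(n_per_pop, n_snps)).astype(np.int8)
        truth[block, c] = 1.0
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "snp": [f"s{j}" for j in range(n_snps)],
            "bp": np.arange(1, n_snps + 1) * 1000,
            "a1": "A",
            "a2": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "id": [f"IND{i:05d}" for i in range(n_per_pop * k)],
            "breed": ["POP" for _ in range(n_per_pop * k)],
            "country": [f"P{i // n_per_pop}" for i in range(n_per_pop * k)],
            "birth_year": 2000,
        }
    )
    return GenotypeMatrix(calls=calls, variants=variants, samples=samples), truth


def drift_split_panel(
    n_individuals: int = 50,
    n_clusters: int = 100,
    cluster_spacing: int = 10_000,
    pair_offset: int = 800,
    n_generations: int = 30,
    n_templates: int = 10,
    switch_rate: float = 2e-6,
    recomb_rate: float = 1e-7,
    seed: int = 0,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Two populations drifting apart from one shared founder pool.

    SNPs come in tight pairs (``pair_offset`` apart) planted on a grid of
    ``cluster_spacing``, so every distance class from sub-kb to ~1 Mb is
    populated.  Both populations start from the same mosaic founder
    haplotypes and then random-mate separately with Haldane recombination;
    long-range gametic phase decorrelates between them faster than
    short-range phase, while allele labels stay shared.
    """
    rng = np.random.default_rng(seed)
    bp = np.sort(
        np.concatenate(
            [
                (np.arange(1, n_clusters + 1)) * cluster_spacing,
                (np.arange(1, n_clusters + 1)) * cluster_spacing + pair_offset,
            ]
        )
    )
    m = len(bp)
    chrom_len = int(bp[-1] + cluster_spacing)
    freq = rng.uniform(0.1, 0.9, size=m)
    templates = (rng.random((n_templates, m)) < freq).astype(np.int8)
    gaps = np.diff(bp).astype(float)
    p_switch = 1.0 - np.exp(-switch_rate * gaps)
    h = 2 * n_individuals
    tidx = rng.integers(0, n_templates, size=h)
    founders = np.empty((h, m), dtype=np.int8)
    founders[:, 0] = templates[tidx, 0]
    for j in range(1, m):
        switch = rng.random(h) < p_switch[j - 1]
        if switch.any():
            tidx = np.where(switch, rng.integers(0, n_templates, size=h), tidx)
        founders[:, j] = templates[tidx, j]

    def drift(pop_seed: int) -> np.ndarray:
        prng = np.random.default_rng([seed, pop_seed])
        haps = founders.reshape(n_individuals, 2, m).copy()
        for _ in range(n_generations):
            new = np.empty_like(haps)
            for i in range(n_individuals):
                pa, pb = prng.choice(n_individuals, size=2, replace=False)
                for slot, parent in enumerate((pa, pb)):
                    new[i, slot] = _gamete(
                        haps[parent], bp, [0], chrom_len, recomb_rate, prng
                    )
            haps = new
        return haps

    variants = pd.DataFrame(
        {
            "chrom": "1",
            "snp": [f"s{j}" for j in range(m)],
            "bp": bp,
            "a1": "A",
            "a2": "B",
        }
    )

    def to_gm(haps: np.ndarray, label: str) -> GenotypeMatrix:
        samples = pd.DataFrame(
            {
                "id": [f"{label}{i:04d}" for i in range(n_individuals)],
                "breed": label,
                "country": label,
                "birth_year": 2000,
            }
        )
        return GenotypeMatrix(
            calls=haps.sum(axis=1).astype(np.int8),
            variants=variants.copy(),
            samples=samples,
            phase=haps,
        )

    return to_gm(drift(101), "A"), to_gm(drift(202), "B")


def hudson_fst(h1: np.ndarray, h2: np.ndarray) -> float:
    """Hudson's FST estimator (ratio of averages) from two haplotype samples."""
    n1, n2 = h1.shape[0], h2.shape[0]
    p1 = h1.mean(axis=0)
    p2 = h2.mean(axis=0)
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())
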