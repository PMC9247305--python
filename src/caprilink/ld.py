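"""Pairwise linkage disequilibrium and cross-population gametic-phase consistency.

For two loci with allele frequencies p_A, p_B and haplotype frequency p_AB,

    D  = p_AB - p_A p_B
    r2 = D^2 / (p_A (1 - p_A) p_B (1 - p_B))

and the signed root ``sign(D) * sqrt(r2)`` carries the phase information.
The consistency of the gametic phase between two populations is the Pearson
correlation of these signed roots over shared SNP pairs, computed within
distance classes.  Haplotype frequencies come from direct counting when
phase is known, otherwise from the standard two-locus EM over the
double-heterozygote ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from caprilink.genotypes import MISSING, GenotypeMatrix

#: Distance classes (kb) used for the phase-consistency profile.
PHASE_CLASSES_KB = [
    (0, 1),
    (1, 10),
    (10, 20),
    (20, 40),
    (40, 60),
    (60, 100),
    (100, 200),
    (200, 500),
    (500, 1000),
]


@dataclass
class LocusPairStats:
    snp_i: str
    snp_j: str
    distance_bp: int
    p_a: float
    p_b: float
    p_ab: float
    d: float
    r2: float
    signed_r: float


class MonomorphicError(ValueError):
    """LD is undefined when either locus is monomorphic in the sample."""


def haplotype_freq(
    g1: np.ndarray,
    g2: np.ndarray,
    phase1: np.ndarray | None = None,
    phase2: np.ndarray | None = None,
    use_phase: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> float:
    """Frequency of the haplotype carrying the reference allele at both loci.

    With phased haplotypes (``phase1``/``phase2`` of shape (n, 2)) and
    ``use_phase``, p_AB is counted directly.  Otherwise it is the ML
    estimate from unphased genotypes: all two-locus genotype classes are
    phase-unambiguous except the double heterozygote, whose AB/ab vs Ab/aB
    split is resolved by EM starting from linkage equilibrium.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        raise MonomorphicError("fewer than two individuals with calls at both loci")
    if use_phase and phase1 is not None and phase2 is not None:
        h1 = phase1[ok].ravel()
        h2 = phase2[ok].ravel()
        return float(np.mean((h1 == 1) & (h2 == 1)))

    g1 = g1[ok].astype(np.int64)
    g2 = g2[ok].astype(np.int64)
    n = len(g1)
    p_a = g1.mean() / 2.0
    p_b = g2.mean() / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicError("monomorphic locus")

    # unambiguous AB haplotype counts per genotype class
    n_ab_known = np.zeros((3, 3))
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((g1 == i) & (g2 == j))
    # genotype (i alleles A at locus 1, j alleles B at locus 2)
    known = {
        (2, 2): 2, (2, 1): 1, (2, 0): 0,
        (1, 2): 1, (1, 0): 0,
        (0, 2): 0, (0, 1): 0, (0, 0): 0,
    }
    base_ab = sum(counts[i, j] * k for (i, j), k in known.items())
    n_dh = counts[1, 1]

    p_ab = p_a * p_b  # start at linkage equilibrium (D0 = 0)
    for _ in range(max_iter):
        p_Ab = max(p_a - p_ab, 0.0)
        p_aB = max(p_b - p_ab, 0.0)
        p_abq = max(1.0 - p_a - p_b + p_ab, 0.0)
        denom = p_ab * p_abq + p_Ab * p_aB
        frac = p_ab * p_abq / denom if denom > 0 else 0.5
        new = (base_ab + n_dh * frac) / (2.0 * n)
        if abs(new - p_ab) < tol:
            p_ab = new
            break
        p_ab = new
    return float(p_ab)


def ld_pair(
    gm: GenotypeMatrix,
    i: int,
    j: int,
    use_phase: bool = True,
) -> LocusPairStats:
    """LD statistics for the SNP pair (i, j); loci must share a chromosome."""
    vi = gm.variants.iloc[i]
    vj = gm.variants.iloc[j]
    if vi["chrom"] != vj["chrom"]:
        raise ValueError("LD is computed within chromosomes only")
    g1, g2 = gm.calls[:, i], gm.calls[:, j]
    ok = (g1 != MISSING) & (g2 != MISSING)
    p_a = g1[ok].mean() / 2.0
    p_b = g2[ok].mean() / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicError("monomorphic locus in analyzed sample")
    ph1 = gm.phase[:, :, i] if gm.phase is not None else None
    ph2 = gm.phase[:, :, j] if gm.phase is not None else None
    if use_phase and ph1 is not None:
        h1 = ph1[ok].ravel()
        h2 = ph2[ok].ravel()
        p_a = float(np.mean(h1 == 1))
        p_b = float(np.mean(h2 == 1))
        if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
            raise MonomorphicError("monomorphic locus in analyzed sample")
        p_ab = float(np.mean((h1 == 1) & (h2 == 1)))
    else:
        p_ab = haplotype_freq(g1, g2, use_phase=False)
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    r2 = min(r2, 1.0)
    signed_r = float(np.sign(d) * np.sqrt(r2))
    return LocusPairStats(
        snp_i=str(vi["snp"]),
        snp_j=str(vj["snp"]),
        distance_bp=int(abs(vi["bp"] - vj["bp"])),
        p_a=float(p_a),
        p_b=float(p_b),
        p_ab=float(p_ab),
        d=float(d),
        r2=float(r2),
        signed_r=signed_r,
    )


def _pair_table(
    gm: GenotypeMatrix,
    max_dist: int,
    use_phase: bool,
) -> pd.DataFrame:
    """All within-chromosome SNP pairs up to max_dist with r2 and signed r.

    Vectorized over haplotypes when phase is available; falls back to
    per-pair EM otherwise.  Monomorphic pairs are excluded and counted in
    the ``n_skipped`` attribute.
    """
    rows = []
    skipped = 0
    chroms = gm.variants["chrom"].to_numpy()
    bps = gm.variants["bp"].to_numpy()
    phased = use_phase and gm.phase is not None
    if phased:
        H = gm.phase.reshape(gm.n_samples * 2, gm.n_snps).astype(float)
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        cb = bps[cidx]
        for a_pos, a in enumerate(cidx):
            for b in cidx[a_pos + 1 :]:
                dist = abs(int(bps[b]) - int(bps[a]))
                if dist == 0 or dist > max_dist:
                    if dist > max_dist:
                        break
                    continue
                if phased:
                    h1, h2 = H[:, a], H[:, b]
                    p1, p2 = h1.mean(), h2.mean()
                    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
                        skipped += 1
                        continue
                    pab = np.mean(h1 * h2)
                    d = pab - p1 * p2
                    r2 = d * d / (p1 * (1 - p1) * p2 * (1 - p2))
                else:
                    try:
                        st = ld_pair(gm, a, b, use_phase=False)
                    except MonomorphicError:
                        skipped += 1
                        continue
                    d, r2 = st.d, st.r2
                r2 = min(r2, 1.0)
                rows.append(
                    {
                        "i": a,
                        "j": b,
                        "distance_bp": dist,
                        "d": d,
                        "r2": r2,
                        "signed_r": np.sign(d) * np.sqrt(r2),
                    }
                )
    out = pd.DataFrame(rows, columns=["i", "j", "distance_bp", "d", "r2", "signed_r"])
    out.attrs["n_skipped"] = skipped
    return out


def ld_decay(
    gm: GenotypeMatrix,
    max_dist: int = 1_000_000,
    n_bins: int = 50,
    use_phase: bool = True,
) -> pd.DataFrame:
    """Mean r2 in distance classes of ``max_dist / n_bins`` (default 20 kb).

    All within-chromosome pairs with distance in (0, max_dist] are used.
    Each class is labeled by the median pair distance realized inside it;
    empty classes keep the interval midpoint and a zero pair count.
    Columns: bin_low_bp, bin_high_bp, label_bp, mean_r2, n_pairs.
    """
    pairs = _pair_table(gm, max_dist, use_phase)
    width = max_dist / n_bins
    edges = np.arange(0, max_dist + width, width)
    rows = []
    if len(pairs):
        binned = np.digitize(pairs["distance_bp"], edges[1:], right=True)
    for k in range(n_bins):
        lo, hi = edges[k], edges[k + 1]
        sel = pairs[binned == k] if len(pairs) else pairs
        if len(sel):
            rows.append(
                {
                    "bin_low_bp": lo,
                    "bin_high_bp": hi,
                    "label_bp": float(np.median(sel["distance_bp"])),
                    "mean_r2": float(sel["r2"].mean()),
                    "n_pairs": len(sel),
                }
            )
        else:
            rows.append(
                {
                    "bin_low_bp": lo,
                    "bin_high_bp": hi,
                    "label_bp": (lo + hi) / 2.0,
                    "mean_r2": np.nan,
                    "n_pairs": 0,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = pairs.attrs.get("n_skipped", 0)
    return out


def harmonize_alleles(
    a: GenotypeMatrix, b: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Orient both matrices to a shared reference allele per SNP.

    Without a common orientation the sign of D is meaningless across
    datasets.  SNPs are matched by name; where B's labels are swapped
    relative to A, B's calls (and phase) are flipped.  Both matrices are
    restricted to the shared SNP set, in A's order.
    """
    common = [s for s in a.variants["snp"] if s in set(b.variants["snp"])]
    amap = {s: k for k, s in enumerate(a.variants["snp"])}
    bmap = {s: k for k, s in enumerate(b.variants["snp"])}
    ai = np.array([amap[s] for s in common])
    bi = np.array([bmap[s] for s in common])
    a2 = a.take_snps(ai)
    b2 = b.take_snps(bi)
    flip = (
        (b2.variants["a1"].to_numpy() == a2.variants["a2"].to_numpy())
        & (b2.variants["a2"].to_numpy() == a2.variants["a1"].to_numpy())
    )
    fl = np.flatnonzero(flip)
    if len(fl):
        calls = b2.calls.copy()
        sub = calls[:, fl]
        calls[:, fl] = np.where(sub == MISSING, MISSING, 2 - sub)
        b2.calls = calls
        b2.variants = b2.variants.copy()
        b2.variants.loc[flip, ["a1", "a2"]] = b2.variants.loc[
            flip, ["a2", "a1"]
        ].to_numpy()
        if b2.phase is not None:
            ph = b2.phase.copy()
            ph[:, :, fl] = 1 - ph[:, :, fl]
            b2.phase = ph
    return a2, b2


def phase_consistency(
    pop_a: GenotypeMatrix,
    pop_b: GenotypeMatrix,
    classes_kb: list[tuple[float, float]] | None = None,
    max_dist: int = 1_000_000,
    use_phase: bool = True,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Correlation of signed LD roots between two populations by distance class.

    Allele orientation is harmonized first; only SNP pairs polymorphic in
    both populations enter.  Classes with fewer than ``min_pairs`` shared
    pairs get a NaN correlation and are flagged.  Columns: class_low_kb,
    class_high_kb, correlation, n_pairs.
    """
    if classes_kb is None:
        classes_kb = PHASE_CLASSES_KB
    a, b = harmonize_alleles(pop_a, pop_b)
    ta = _pair_table(a, max_dist, use_phase)
    tb = _pair_table(b, max_dist, use_phase)
    merged = ta.merge(tb, on=["i", "j", "distance_bp"], suffixes=("_a", "_b"))
    rows = []
    for lo, hi in classes_kb:
        sel = merged[
            (merged["distance_bp"] > lo * 1000) & (merged["distance_bp"] <= hi * 1000)
        ]
        if len(sel) >= min_pairs:
            x = sel["signed_r_a"].to_numpy()
            y = sel["signed_r_b"].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                corr = np.nan
            else:
                corr = float(np.corrcoef(x, y)[0, 1])
        else:
            corr = np.nan
        rows.append(
            {
                "class_low_kb": lo,
                "class_high_kb": hi,
                "correlation": corr,
                "n_pairs": len(sel),
            }
        )
    return pd.DataFrame(rows)
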