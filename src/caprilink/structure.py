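"""Genomic relationships, PCA, genomic inbreeding, and admixture.

The genomic relationship matrix follows VanRaden's first method:
``G = Z Z' / (2 * sum_j p_j (1 - p_j))`` with ``Z`` the call matrix centered
at twice the sample allele frequencies.  PCA is the eigendecomposition of
G.  Genomic inbreeding is the excess-homozygosity estimator computed on an
LD-pruned marker set.  Admixture fits the standard model in which each
genotype is a binomial draw from an individual-specific allele frequency
mixing k ancestral frequencies, maximized by EM; the number of clusters is
chosen by entry-wise cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from caprilink.genotypes import MISSING, GenotypeMatrix

FREQ_CLIP = (0.01, 0.99)


def _imputed_dosages(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Float dosage matrix with missing imputed to 2p, and the frequencies."""
    calls = gm.calls.astype(float)
    calls[gm.calls == MISSING] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0
    calls = np.where(np.isnan(calls), 2.0 * p, calls)
    return calls, p


@dataclass
class GRM:
    """Symmetric genomic relationship matrix plus the centering frequencies."""

    matrix: np.ndarray
    freqs: np.ndarray
    ids: list[str]


def grm(gm: GenotypeMatrix) -> GRM:
    """VanRaden method-1 genomic relationship matrix.

    Frequencies come from the analyzed sample itself; monomorphic SNPs
    contribute nothing to either Z or the scaling and are excluded.
    """
    dos, p = _imputed_dosages(gm)
    poly = (p > 0) & (p < 1)
    dos, p = dos[:, poly], p[poly]
    if dos.shape[1] == 0:
        raise ValueError("no polymorphic SNPs for GRM")
    z = dos - 2.0 * p
    scale = 2.0 * np.sum(p * (1.0 - p))
    g = z @ z.T / scale
    return GRM(matrix=g, freqs=p, ids=gm.samples["id"].tolist())


@dataclass
class PCAResult:
    coords: pd.DataFrame  # id + PC1..PCn
    variance_pct: np.ndarray  # per retained component
    eigenvalues: np.ndarray  # all eigenvalues, descending


def pca(g: GRM, n_components: int = 10) -> PCAResult:
    """Eigendecomposition of the GRM.

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalues; the variance percentage of a component is its eigenvalue
    over the trace.  Sign convention: the largest-magnitude loading of each
    component is positive, making coordinates reproducible across runs.
    """
    m = g.matrix
    if not np.all(np.isfinite(m)):
        raise ValueError("GRM contains non-finite entries")
    vals, vecs = np.linalg.eigh(m)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_components = min(n_components, len(vals))
    trace = vals.sum()
    pct = 100.0 * vals[:n_components] / trace
    coords = np.empty((m.shape[0], n_components))
    for k in range(n_components):
        v = vecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, k] = v * np.sqrt(max(vals[k], 0.0))
    df = pd.DataFrame(coords, columns=[f"PC{k + 1}" for k in range(n_components)])
    df.insert(0, "id", g.ids)
    return PCAResult(coords=df, variance_pct=pct, eigenvalues=vals)


def genomic_inbreeding(
    gm: GenotypeMatrix,
    min_snps: int = 100,
) -> pd.DataFrame:
    """Excess-homozygosity inbreeding on a pruned marker set.

    For animal i with L non-missing SNPs, expected homozygous count under
    Hardy-Weinberg is ``E = sum_j (1 - 2 p_j (1 - p_j))`` over those SNPs
    (plug-in sample frequencies) and ``F = (O - E) / (L - E)`` with O the
    observed homozygous count.  Animals with fewer than ``min_snps``
    non-missing SNPs are flagged low-confidence.  Returns columns
    id, F_het, n_snps, low_confidence.
    """
    calls = gm.calls
    obs_mask = calls != MISSING
    p = gm.allele_freq()
    het_exp = 2.0 * p * (1.0 - p)
    hom_exp_site = 1.0 - het_exp
    hom_obs = ((calls == 0) | (calls == 2)) & obs_mask
    o = hom_obs.sum(axis=1).astype(float)
    l = obs_mask.sum(axis=1).astype(float)
    e = (obs_mask * hom_exp_site).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(l - e > 0, (o - e) / (l - e), np.nan)
    return pd.DataFrame(
        {
            "id": gm.samples["id"],
            "F_het": f,
            "n_snps": l.astype(int),
            "low_confidence": l < min_snps,
        }
    )


def grm_inbreeding(g: GRM) -> pd.DataFrame:
    """Secondary genomic inbreeding estimate: GRM diagonal minus one."""
    return pd.DataFrame({"id": g.ids, "F_grm": np.diag(g.matrix) - 1.0})


def inbreeding_comparison(
    f_ped: pd.DataFrame,
    f_gen: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Per (breed, country) means of pedigree and genomic F with differences.

    Shapes the classic side-by-side inbreeding table: mean and SD of each
    estimator over the genotyped animals of every breed-country group, plus
    the genomic-minus-pedigree difference of means.
    """
    merged = (
        samples[["id", "breed", "country"]]
        .merge(f_ped[["id", "F"]].rename(columns={"F": "F_ped"}), on="id", how="inner")
        .merge(f_gen[["id", "F_het"]], on="id", how="inner")
    )
    out = (
        merged.groupby(["breed", "country"])
        .agg(
            F_ped_mean=("F_ped", "mean"),
            F_ped_sd=("F_ped", "std"),
            F_gen_mean=("F_het", "mean"),
            F_gen_sd=("F_het", "std"),
            n=("id", "count"),
        )
        .reset_index()
    )
    out["difference"] = out["F_gen_mean"] - out["F_ped_mean"]
    return out


# ---------------------------------------------------------------------------
# Admixture
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureFit:
    k: int
    q: np.ndarray  # n x k ancestry proportions, rows sum to 1
    p_anc: np.ndarray  # k x m ancestral allele frequencies
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _admixture_loglik(g: np.ndarray, obs: np.ndarray, q: np.ndarray, f: np.ndarray) -> float:
    theta = np.clip(q @ f, 1e-12, 1 - 1e-12)
    ll = np.where(obs, g * np.log(theta) + (2.0 - g) * np.log(1.0 - theta), 0.0)
    return float(ll.sum())


def admixture_em(
    gm: GenotypeMatrix,
    k: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> AdmixtureFit:
    """EM fit of the k-cluster admixture model.

    Each of an individual's 2m allele draws is binomial with success
    probability ``theta_ij = sum_c q_ic f_cj``.  Q starts at a symmetric
    Dirichlet(1) draw, ancestral frequencies at the sample frequencies with
    seed-driven perturbation; both are updated by the exact EM step, which
    never decreases the log-likelihood.  Missing entries are skipped in the
    likelihood and the updates.  Frequencies are clipped to [0.01, 0.99]
    and Q rows renormalized every iteration.
    """
    n, m = gm.calls.shape
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    obs = gm.calls != MISSING
    g = np.where(obs, gm.calls, 0).astype(float)
    rng = np.random.default_rng(seed)

    p_hat = np.clip(gm.allele_freq(), *FREQ_CLIP)
    if k == 1:
        q = np.ones((n, 1))
        f = p_hat[None, :].copy()
        return AdmixtureFit(k=1, q=q, p_anc=f, loglik_trace=[_admixture_loglik(g, obs, q, f)])

    q = rng.dirichlet(np.ones(k), size=n)
    f = np.clip(
        p_hat[None, :] + rng.normal(0.0, 0.1, size=(k, m)), *FREQ_CLIP
    )

    trace: list[float] = []
    for _ in range(max_iter):
        theta = np.clip(q @ f, 1e-12, 1 - 1e-12)
        # per-entry weights for expected ancestry-c allele counts
        a_ref = g / theta
        a_alt = (2.0 - g) / (1.0 - theta)
        a_ref = np.where(obs, a_ref, 0.0)
        a_alt = np.where(obs, a_alt, 0.0)
        new_q = np.empty_like(q)
        new_f = np.empty_like(f)
        for c in range(k):
            e_ref = q[:, c : c + 1] * f[c] * a_ref  # n x m expected counts
            e_alt = q[:, c : c + 1] * (1.0 - f[c]) * a_alt
            new_q[:, c] = (e_ref + e_alt).sum(axis=1)
            ref_sum = e_ref.sum(axis=0)
            alt_sum = e_alt.sum(axis=0)
            with np.errstate(invalid="ignore"):
                new_f[c] = np.where(
                    ref_sum + alt_sum > 0, ref_sum / (ref_sum + alt_sum), f[c]
                )
        denom = 2.0 * obs.sum(axis=1, keepdims=True).astype(float)
        q = new_q / np.where(denom > 0, denom, 1.0)
        q = q / q.sum(axis=1, keepdims=True)
        f = np.clip(new_f, *FREQ_CLIP)
        ll = _admixture_loglik(g, obs, q, f)
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
    return AdmixtureFit(k=k, q=q, p_anc=f, loglik_trace=trace)


def choose_k(
    gm: GenotypeMatrix,
    k_grid: range | list[int] = range(2, 9),
    cv_folds: int = 5,
    seed: int = 0,
    holdout_frac: float = 0.10,
    **em_kwargs,
) -> tuple[pd.DataFrame, int]:
    """Select the number of ancestral clusters by entry-wise cross-validation.

    Per fold, a random ``holdout_frac`` of non-missing genotype entries is
    masked, the model is fitted on the rest, and held-out entries are
    scored by binomial deviance against the fitted ``2 theta``.  The
    reported cv_error is the mean deviance per held-out entry over folds;
    the selected k minimizes it (ties to the smallest k).  Grid values
    exceeding the sample count are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    n, m = gm.calls.shape
    obs_idx = np.argwhere(gm.calls != MISSING)
    rows = []
    k_grid = [k for k in k_grid if k <= n]
    fold_masks = []
    for _ in range(cv_folds):
        take = rng.random(len(obs_idx)) < holdout_frac
        fold_masks.append(obs_idx[take])
    for k in k_grid:
        errs = []
        for fold, held in enumerate(fold_masks):
            masked = gm.copy()
            masked.calls[held[:, 0], held[:, 1]] = MISSING
            fit = admixture_em(masked, k, seed=seed + 1000 * fold + k, **em_kwargs)
            theta = np.clip(fit.q @ fit.p_anc, 1e-9, 1 - 1e-9)
            gobs = gm.calls[held[:, 0], held[:, 1]].astype(float)
            th = theta[held[:, 0], held[:, 1]]
            dev = -2.0 * (gobs * np.log(th) + (2.0 - gobs) * np.log(1.0 - th))
            errs.append(float(np.mean(dev)))
        rows.append({"k": k, "cv_error": float(np.mean(errs))})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["cv_error"].idxmin(), "k"])
    return table, best


def align_q_to_truth(q: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Permute ancestry columns to best match a truth matrix (greedy on overlap)."""
    k = q.shape[1]
    cost = truth.T @ q  # k_true x k overlap
    perm = [-1] * k
    used_rows, used_cols = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(-cost, axis=None), cost.shape))[0]
    for r, c in order:
        if r not in used_rows and c not in used_cols:
            perm[r] = c
            used_rows.add(r)
            used_cols.add(c)
    return q[:, perm]
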