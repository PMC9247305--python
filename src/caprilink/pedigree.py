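"""Pedigree validation, cross-country record linkage, connectedness, inbreeding.

National pedigree files are linked through the standardized 23-character ID
(:mod:`caprilink.ids`).  Because the registration-country letters differ
between the exporting and the importing pedigree for the same animal, all
matching operates on the (breed, sex, core) key, where the core embeds the
birth country and local number.

Linkage runs in four tiers of decreasing confidence: exact key match, alias
match, unique trailing-digit (suffix) match for truncated registrations, and
fuzzy (normalized Levenshtein) match.  Fuzzy hits are never auto-accepted:
they are flagged for review, mirroring manual verification practice.
"""

from __future__ import annotations

import heapq
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from caprilink.ids import CanonicalID, birth_code

logger = logging.getLogger(__name__)

UNKNOWN = ""

PEDIGREE_COLUMNS = [
    "id",
    "sire",
    "dam",
    "sex",
    "birth_year",
    "breed",
    "country",
    "alias1",
    "alias2",
    "alias3",
]

#: Shortest digit suffix allowed to support a suffix match; shorter suffixes
#: collide too often in large pedigrees.
MIN_SUFFIX_LEN = 5


def _core_of(id_string: str) -> str:
    return id_string[7:] if len(id_string) == 23 else id_string


def _key_of(id_string: str) -> str:
    """Matching key: breed + sex + core (registration country dropped)."""
    if len(id_string) == 23:
        return id_string[:3] + id_string[6] + id_string[7:]
    return id_string


def _birth_code_of(id_string: str) -> str | None:
    try:
        return CanonicalID.from_string(id_string).birth_country
    except Exception:
        return None


_TAIL_RE = re.compile(r"[A-Z]{2}(\d+)$")


def _digits_of(id_string: str) -> str:
    """Local digit string after the birth-country letters, zeros preserved.

    Leading zeros inside the local number are meaningful for suffix
    matching of truncated registrations, so they are not stripped.
    """
    core = _core_of(id_string)
    m = _TAIL_RE.search(core)
    if m:
        return m.group(1)
    return "".join(c for c in core if c.isdigit()).lstrip("0")


@dataclass
class Pedigree:
    """A national pedigree: one record per animal, parents by canonical ID."""

    df: pd.DataFrame
    country: str

    def __post_init__(self) -> None:
        for col in PEDIGREE_COLUMNS:
            if col not in self.df.columns:
                self.df[col] = UNKNOWN if col.startswith("alias") else pd.NA
        self.df = self.df[PEDIGREE_COLUMNS].reset_index(drop=True)
        for col in ("id", "sire", "dam", "alias1", "alias2", "alias3"):
            self.df[col] = self.df[col].fillna(UNKNOWN).astype(str).replace("0", UNKNOWN)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Series:
        return self.df["id"]

    def aliases_of(self, row: pd.Series) -> list[str]:
        return [a for a in (row["alias1"], row["alias2"], row["alias3"]) if a]

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, country: str | None = None) -> "Pedigree":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if country is None:
            country = df["country"].iloc[0] if len(df) else "UNK"
        return cls(df=df, country=country)


@dataclass
class ValidationReport:
    """Counts of corrective actions taken while cleaning a pedigree."""

    phantom_parents_added: int = 0
    duplicates_collapsed: int = 0
    cycles_broken: int = 0
    conflicts: list[str] = field(default_factory=list)

    @property
    def total_actions(self) -> int:
        return self.phantom_parents_added + self.duplicates_collapsed + self.cycles_broken


def validate_pedigree(ped: Pedigree) -> tuple[Pedigree, ValidationReport]:
    """Clean a pedigree so every parent is registered and the graph is acyclic.

    Parents referenced but absent are added as founder records with sex
    inferred from their role (sire -> M, dam -> F).  Duplicate IDs collapse
    to the first occurrence (field conflicts logged).  Parent-offspring
    cycles are broken by unlinking the offending parent link.
    """
    report = ValidationReport()
    df = ped.df.copy()

    dup = df["id"].duplicated()
    if dup.any():
        for rid in df.loc[dup, "id"].unique():
            rows = df[df["id"] == rid]
            if rows.nunique().gt(1).any():
                report.conflicts.append(f"duplicate id {rid} with conflicting fields")
        report.duplicates_collapsed = int(dup.sum())
        df = df[~dup].reset_index(drop=True)

    known = set(df["id"])
    phantoms = []
    for role, sex in (("sire", "M"), ("dam", "F")):
        for pid in df[role].unique():
            if pid and pid not in known:
                phantoms.append(
                    {
                        "id": pid,
                        "sire": UNKNOWN,
                        "dam": UNKNOWN,
                        "sex": sex,
                        "birth_year": pd.NA,
                        "breed": pid[:3] if len(pid) == 23 else UNKNOWN,
                        "country": ped.country,
                        "alias1": UNKNOWN,
                        "alias2": UNKNOWN,
                        "alias3": UNKNOWN,
                    }
                )
                known.add(pid)
    if phantoms:
        report.phantom_parents_added = len(phantoms)
        df = pd.concat([pd.DataFrame(phantoms), df], ignore_index=True)

    g = nx.DiGraph()
    g.add_nodes_from(df["id"])
    for _, row in df.iterrows():
        for role in ("sire", "dam"):
            if row[role]:
                g.add_edge(row[role], row["id"], role=role)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        parent, child, *_ = cycle[0]
        role = g.edges[parent, child]["role"]
        df.loc[df["id"] == child, role] = UNKNOWN
        g.remove_edge(parent, child)
        report.cycles_broken += 1
        logger.warning("cycle broken: unlinked %s of %s", role, child)

    return Pedigree(df=df, country=ped.country), report


# ---------------------------------------------------------------------------
# Record linkage
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    """Outcome of looking up one foreign animal in its native pedigree."""

    target_id: str
    source_id: str | None
    method: str  # exact | alias | suffix | fuzzy | none
    score: float  # similarity in [0, 100]
    status: str  # accepted | review | unmatched


def similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity on a 0-100 scale."""
    if not a and not b:
        return 100.0
    dist = edlib.align(a, b)["editDistance"]
    return 100.0 * (1.0 - dist / max(len(a), len(b)))


def link_pedigrees(
    source: Pedigree,
    target: Pedigree,
    fuzzy_threshold: float = 90.0,
) -> list[MatchResult]:
    """Find source-country animals registered in ``target`` back in ``source``.

    Foreign animals in the target pedigree are those whose core carries the
    source country's birth code (directly or through an alias).  Matching
    tiers: exact key, alias, unique digit suffix, fuzzy core similarity.
    Fuzzy candidates scoring at or above ``fuzzy_threshold`` are flagged
    ``review``; below, ``unmatched``.  Each source ID is consumed at most
    once per tier.
    """
    src_birth = birth_code(source.country)

    source_keys: dict[str, str] = {}
    alias_keys: dict[str, str] = {}
    for _, row in source.df.iterrows():
        source_keys.setdefault(_key_of(row["id"]), row["id"])
        for a in (row["alias1"], row["alias2"], row["alias3"]):
            if a:
                alias_keys.setdefault(_key_of(a), row["id"])

    src_digit_index: dict[str, list[str]] = {}
    for sid in source.ids:
        src_digit_index.setdefault(_digits_of(sid), []).append(sid)
    all_src_digits = list(src_digit_index)

    fuzzy_pool = [
        sid for sid in source.ids if _birth_code_of(sid) == src_birth
    ]
    fuzzy_cores = [_core_of(sid) for sid in fuzzy_pool]

    used: dict[str, set[str]] = {t: set() for t in ("exact", "alias", "suffix", "fuzzy")}
    results: list[MatchResult] = []

    for _, row in target.df.iterrows():
        tid = row["id"]
        candidates = [tid] + target.aliases_of(row)
        if not any(_birth_code_of(c) == src_birth for c in candidates):
            continue

        match: MatchResult | None = None

        for cand in candidates:
            sid = source_keys.get(_key_of(cand))
            if sid is not None and sid not in used["exact"]:
                used["exact"].add(sid)
                method = "exact" if cand == tid else "alias"
                match = MatchResult(tid, sid, method, 100.0, "accepted")
                break
        if match is None:
            for cand in candidates:
                sid = alias_keys.get(_key_of(cand))
                if sid is not None and sid not in used["alias"]:
                    used["alias"].add(sid)
                    match = MatchResult(tid, sid, "alias", 100.0, "accepted")
                    break
        if match is None:
            tdig = _digits_of(tid)
            if len(tdig) >= MIN_SUFFIX_LEN:
                hits = [
                    sid
                    for d in all_src_digits
                    if d.endswith(tdig)
                    for sid in src_digit_index[d]
                    if sid not in used["suffix"]
                ]
                if len(hits) == 1:
                    used["suffix"].add(hits[0])
                    match = MatchResult(tid, hits[0], "suffix", 100.0, "accepted")
        if match is None and fuzzy_pool:
            tcore = _core_of(tid)
            best_sid, best_score = None, -1.0
            for sid, score_core in zip(fuzzy_pool, fuzzy_cores):
                if sid in used["fuzzy"]:
                    continue
                s = similarity(tcore, score_core)
                if s > best_score:
                    best_sid, best_score = sid, s
            if best_sid is not None and best_score >= fuzzy_threshold:
                used["fuzzy"].add(best_sid)
                match = MatchResult(tid, best_sid, "fuzzy", best_score, "review")
        if match is None:
            match = MatchResult(tid, None, "none", 0.0, "unmatched")
        results.append(match)

    return results


# ---------------------------------------------------------------------------
# Connectedness accounting
# ---------------------------------------------------------------------------


def _pair_label(a: str, b: str, order: list[str]) -> str:
    ia, ib = order.index(a), order.index(b)
    return f"{a}-{b}" if ia < ib else f"{b}-{a}"


@dataclass
class ConnectednessReport:
    """Pairwise found/missing counts, foreign-parent counts, shared genotypes.

    ``pairwise`` is indexed by (status, origin country, breed) with one
    column per country pair and an ``All`` margin column; ``foreign_sires``
    and ``foreign_dams`` count progeny of foreign parents per importing
    country, breed and offspring sex; ``shared_genotyped`` counts genotyped
    animals present in at least two national pedigrees, per native pedigree.
    """

    pairwise: pd.DataFrame
    foreign_sires: pd.DataFrame
    foreign_dams: pd.DataFrame
    shared_genotyped: pd.DataFrame

    @property
    def grand_total(self) -> int:
        cols = [c for c in self.pairwise.columns if c != "All"]
        return int(self.pairwise[cols].to_numpy().sum())

    @staticmethod
    def add_margins(cells: pd.DataFrame) -> pd.DataFrame:
        """Append the ``All`` column and bottom ``All`` row of a count table."""
        out = cells.copy()
        out["All"] = out.sum(axis=1)
        out.loc[("All", "", ""), :] = out.sum(axis=0)
        return out


def pairwise_connectedness(
    matches: dict[tuple[str, str], list[MatchResult]],
    pedigrees: dict[str, Pedigree],
    country_order: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate found/missing-in-local-pedigree counts per pair x origin x breed.

    ``found`` counts accepted matches; ``review`` and ``unmatched`` results
    count as missing, preserving the convention that unverified fuzzy hits
    are not treated as recovered pedigree links.
    """
    if country_order is None:
        country_order = sorted(pedigrees)
    breeds = sorted(
        {i[:3] for p in pedigrees.values() for i in p.ids if len(i) == 23}
    )
    pairs = []
    for i, a in enumerate(country_order):
        for b in country_order[i + 1 :]:
            pairs.append(f"{a}-{b}")
    index = pd.MultiIndex.from_tuples(
        [
            (status, origin, breed)
            for status in ("found", "missing")
            for origin in country_order
            for breed in breeds
        ],
        names=["status", "origin", "breed"],
    )
    table = pd.DataFrame(0, index=index, columns=pairs)
    for (src, tgt), mlist in matches.items():
        col = _pair_label(src, tgt, country_order)
        for m in mlist:
            breed = m.target_id[:3] if len(m.target_id) == 23 else breeds[0]
            status = "found" if m.status == "accepted" else "missing"
            table.loc[(status, src, breed), col] += 1
    table = table[(table.sum(axis=1) > 0) | (table.index.get_level_values(0) == "")]
    return table


def foreign_parent_counts(
    pedigrees: dict[str, Pedigree],
    origin_country: str,
    pedigree_sizes: dict[tuple[str, str], int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count progeny of foreign sires/dams from ``origin_country`` per pedigree.

    A parent is foreign when the birth-country code inside its core differs
    from the registering country's code and equals the origin country's.
    Direct progeny only are counted.  Returns (sire table, dam table)
    indexed by importing country with (breed, offspring sex) count columns,
    plus percentage columns when ``pedigree_sizes`` (keyed by
    (country, breed)) is given.
    """
    origin_code = birth_code(origin_country)
    sire_rows, dam_rows = {}, {}
    for country, ped in pedigrees.items():
        if country == origin_country:
            continue
        local_code = birth_code(country)
        df = ped.df
        breeds = df["id"].str[:3]
        sexes = df["sex"].astype(str)
        for role, store in (("sire", sire_rows), ("dam", dam_rows)):
            codes = df[role].map(lambda s: _birth_code_of(s) if s else None)
            mask = (codes == origin_code) & (codes != local_code)
            counts = (
                pd.DataFrame({"breed": breeds[mask], "sex": sexes[mask]})
                .value_counts()
                .unstack(fill_value=0)
            )
            store[country] = counts
    def _assemble(rows: dict) -> pd.DataFrame:
        if not rows:
            return pd.DataFrame()
        out = pd.concat(rows, axis=0).unstack(level=1).fillna(0).astype(int)
        out.columns = [f"{b}_{s}" for b, s in out.columns]
        out["total"] = out.sum(axis=1)
        if pedigree_sizes:
            for col in list(out.columns):
                if col == "total":
                    denom = out.index.map(
                        lambda c: sum(
                            v for (cc, _), v in pedigree_sizes.items() if cc == c
                        )
                    )
                else:
                    b = col.split("_")[0]
                    denom = out.index.map(lambda c, b=b: pedigree_sizes.get((c, b), 0))
                with np.errstate(divide="ignore", invalid="ignore"):
                    out[f"{col}_pct"] = np.where(
                        np.asarray(denom) > 0, 100.0 * out[col] / np.asarray(denom), 0.0
                    )
        return out

    return _assemble(sire_rows), _assemble(dam_rows)


def shared_genotyped_counts(
    pedigrees: dict[str, Pedigree],
    genotyped_ids: dict[str, set[str]],
    matches: dict[tuple[str, str], list[MatchResult]],
    pedigree_sizes: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Genotyped animals recorded in >= 2 national pedigrees, per native pedigree.

    Presence in a second pedigree is established either by an identical
    matching key or through an accepted linkage match.
    """
    presence: dict[str, set[str]] = {}
    for country, ped in pedigrees.items():
        for rid in ped.ids:
            presence.setdefault(_key_of(rid), set()).add(country)
    for (src, tgt), mlist in matches.items():
        for m in mlist:
            if m.status == "accepted" and m.source_id:
                presence.setdefault(_key_of(m.source_id), set()).update((src, tgt))
                presence.setdefault(_key_of(m.target_id), set()).update((src, tgt))

    rows = []
    for country, ids in genotyped_ids.items():
        by_breed: dict[str, int] = {}
        for gid in ids:
            if len(presence.get(_key_of(gid), ())) >= 2:
                breed = gid[:3] if len(gid) == 23 else "UNK"
                by_breed[breed] = by_breed.get(breed, 0) + 1
        for breed, n in sorted(by_breed.items()):
            row = {"native_pedigree": country, "breed": breed, "n_shared": n}
            if pedigree_sizes:
                denom = pedigree_sizes.get((country, breed), 0)
                row["pct_native_pedigree"] = 100.0 * n / denom if denom else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def tabulate_connectedness(
    pedigrees: dict[str, Pedigree],
    genotyped_ids: dict[str, set[str]],
    matches: dict[tuple[str, str], list[MatchResult]],
    country_order: list[str] | None = None,
) -> ConnectednessReport:
    """Assemble the full connectedness report from completed pairwise linkage."""
    sizes: dict[tuple[str, str], int] = {}
    for country, ped in pedigrees.items():
        for breed, n in ped.ids.str[:3].value_counts().items():
            sizes[(country, breed)] = int(n)
    pairwise = pairwise_connectedness(matches, pedigrees, country_order)
    pairwise = ConnectednessReport.add_margins(pairwise)
    origins = sorted({src for src, _ in matches}) or list(pedigrees)
    sire_tables, dam_tables = [], []
    for origin in origins:
        s, d = foreign_parent_counts(pedigrees, origin, sizes)
        if len(s):
            s.insert(0, "origin", origin)
            sire_tables.append(s)
        if len(d):
            d.insert(0, "origin", origin)
            dam_tables.append(d)
    shared = shared_genotyped_counts(pedigrees, genotyped_ids, matches, sizes)
    return ConnectednessReport(
        pairwise=pairwise,
        foreign_sires=pd.concat(sire_tables) if sire_tables else pd.DataFrame(),
        foreign_dams=pd.concat(dam_tables) if dam_tables else pd.DataFrame(),
        shared_genotyped=shared,
    )


# ---------------------------------------------------------------------------
# Pedigree inbreeding (Meuwissen & Luo)
# ---------------------------------------------------------------------------


def _topological_order(df: pd.DataFrame) -> list[int]:
    idx = {rid: i for i, rid in enumerate(df["id"])}
    g = nx.DiGraph()
    g.add_nodes_from(range(len(df)))
    for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
        for p in (s, d):
            if p in idx:
                g.add_edge(idx[p], i)
    try:
        return list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise ValueError("pedigree contains a cycle; validate it first") from exc


def pedigree_inbreeding(ped: Pedigree) -> pd.DataFrame:
    """Inbreeding coefficients by the Meuwissen & Luo recursion.

    For each animal the algorithm walks its ancestor list accumulating
    L-coefficients; the diagonal of the numerator relationship matrix is
    ``sum_j L_j^2 d_j`` with ``d_j`` the within-family segregation variance,
    and F is that diagonal minus one.  Unknown parents are treated as
    unrelated non-inbred founders, so unknown ancestry contributes nothing.
    Runs in O(n x ancestors) time and is order-independent.

    Returns a DataFrame with columns ``id`` and ``F``.
    """
    df = ped.df
    n = len(df)
    idx = {rid: i for i, rid in enumerate(df["id"])}
    sire = np.array([idx.get(s, -1) for s in df["sire"]], dtype=np.int64)
    dam = np.array([idx.get(d, -1) for d in df["dam"]], dtype=np.int64)

    order = _topological_order(df)
    rank = np.empty(n, dtype=np.int64)
    for r, i in enumerate(order):
        rank[i] = r

    F = np.zeros(n)
    D = np.ones(n)  # within-family segregation variance
    for i in order:
        fs = F[sire[i]] if sire[i] >= 0 else -1.0
        fd = F[dam[i]] if dam[i] >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if sire[i] < 0 and dam[i] < 0:
            F[i] = 0.0  # founder: A_ii = D_i = 1
            continue
        # Walk the ancestor list youngest-first; every contribution to an
        # ancestor j arrives from its descendants (all of higher rank),
        # so L[j] is complete when j is popped.
        L: dict[int, float] = {i: 1.0}
        pq = [-rank[i]]
        a_ii = 0.0
        while pq:
            r = -heapq.heappop(pq)
            j = order[r]
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            a_ii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in L:
                        L[p] = 0.0
                        heapq.heappush(pq, -rank[p])
                    L[p] += 0.5 * lj
        F[i] = a_ii - 1.0
    return pd.DataFrame({"id": df["id"], "F": F})


def inbreeding_summary(
    inbreeding: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Mean and standard deviation of F per (breed, country) for given animals.

    ``samples`` needs columns ``id``, ``breed``, ``country`` (typically the
    genotyped subset); animals absent from ``inbreeding`` are skipped.
    """
    merged = samples.merge(inbreeding, on="id", how="inner")
    return (
        merged.groupby(["breed", "country"])["F"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
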