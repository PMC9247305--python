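import numpy as np
import pandas as pd
import pytest

from caprilink.ids import standardize_id
from caprilink.pedigree import (
    Pedigree,
    link_pedigrees,
    pairwise_connectedness,
    pedigree_inbreeding,
    similarity,
    tabulate_connectedness,
    validate_pedigree,
)
from caprilink.simulate import PopulationSpec, simulate_dataset


def ped_from_rows(rows, country="FRA"):
    return Pedigree(df=pd.DataFrame(rows), country=country)


def cid(raw, breed="ALP", country="FRA", sex="M", birth="FR"):
    return str(standardize_id(raw, breed, country, sex, birth))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


class TestValidation:
    def test_phantom_parent_added_as_founder(self):
        ped = ped_from_rows(
            [dict(id="B", sire="X", dam="", sex="F", birth_year=2000)]
        )
        clean, rep = validate_pedigree(ped)
        assert rep.phantom_parents_added == 1
        row = clean.df[clean.df["id"] == "X"].iloc[0]
        assert row["sex"] == "M" and row["sire"] == "" and row["dam"] == ""

    def test_consistent_pedigree_untouched(self):
        ped = ped_from_rows(
            [
                dict(id="A", sire="", dam="", sex="M"),
                dict(id="B", sire="A", dam="", sex="F"),
            ]
        )
        clean, rep = validate_pedigree(ped)
        assert rep.total_actions == 0
        assert len(clean) == 2

    def test_self_ancestor_cycle_broken(self):
        ped = ped_from_rows([dict(id="A", sire="A", dam="", sex="M")])
        clean, rep = validate_pedigree(ped)
        assert rep.cycles_broken == 1
        assert clean.df.iloc[0]["sire"] == ""

    def test_duplicates_collapsed(self):
        ped = ped_from_rows(
            [
                dict(id="A", sire="", dam="", sex="M", birth_year=2000),
                dict(id="A", sire="", dam="", sex="M", birth_year=2001),
            ]
        )
        clean, rep = validate_pedigree(ped)
        assert rep.duplicates_collapsed == 1
        assert len(clean) == 1


# ---------------------------------------------------------------------------
# linkage tiers
# ---------------------------------------------------------------------------


class TestLinkage:
    def make_source(self):
        rows = [
            dict(id=cid("5248383"), sire="", dam="", sex="M"),
            dict(id=cid("7111222"), sire="", dam="", sex="M"),
            dict(
                id=cid("9000001"),
                sire="",
                dam="",
                sex="M",
                alias1=cid("8123123", country="FRA"),
            ),
        ]
        return ped_from_rows(rows, "FRA")

    def test_exact_match_across_registration_country(self):
        src = self.make_source()
        tgt = ped_from_rows(
            [dict(id=cid("5248383", country="CHE"), sire="", dam="", sex="M")], "CHE"
        )
        (m,) = link_pedigrees(src, tgt)
        assert (m.method, m.status) == ("exact", "accepted")
        assert m.source_id == cid("5248383")

    def test_alias_match(self):
        src = self.make_source()
        tgt = ped_from_rows(
            [dict(id=cid("8123123", country="CHE"), sire="", dam="", sex="M")], "CHE"
        )
        (m,) = link_pedigrees(src, tgt)
        assert (m.method, m.status) == ("alias", "accepted")
        assert m.source_id == cid("9000001")

    def test_suffix_match_on_truncated_id(self):
        src = self.make_source()
        # Swiss registration kept only the last 5 digits of 5248383
        tgt = ped_from_rows(
            [dict(id="ALPCHEM" + ("FR" + "48383").rjust(16, "0"), sire="", dam="", sex="M")],
            "CHE",
        )
        (m,) = link_pedigrees(src, tgt)
        assert (m.method, m.status) == ("suffix", "accepted")
        assert m.source_id == cid("5248383")

    def test_suffix_tie_not_matched(self):
        rows = [
            dict(id=cid("5248383"), sire="", dam="", sex="M"),
            dict(id=cid("9948383"), sire="", dam="", sex="M"),
        ]
        src = ped_from_rows(rows, "FRA")
        tgt = ped_from_rows(
            [dict(id="ALPCHEM" + ("FR" + "48383").rjust(16, "0"), sire="", dam="", sex="M")],
            "CHE",
        )
        (m,) = link_pedigrees(src, tgt)
        assert m.method in ("fuzzy", "none")
        assert m.status != "accepted"

    def test_typo_goes_to_fuzzy_review(self):
        src = self.make_source()
        typo = cid("5248388", country="CHE")  # one substituted digit
        tgt = ped_from_rows([dict(id=typo, sire="", dam="", sex="M")], "CHE")
        (m,) = link_pedigrees(src, tgt, fuzzy_threshold=90)
        assert m.method == "fuzzy"
        assert m.status == "review"  # never auto-accepted
        assert m.score >= 90
        assert m.source_id == cid("5248383")

    def test_one_char_core_typo_scores_above_90(self):
        a = "0000000FR5248383"
        b = "0000000FR5248388"
        assert similarity(a, b) == pytest.approx(100 * 15 / 16)

    def test_empty_source_all_unmatched(self):
        src = ped_from_rows([], "FRA")
        tgt = ped_from_rows(
            [dict(id=cid("5248383", country="CHE"), sire="", dam="", sex="M")], "CHE"
        )
        (m,) = link_pedigrees(src, tgt)
        assert m.status == "unmatched"

    def test_self_linkage_all_exact(self, validated_pedigrees):
        fra = validated_pedigrees["FRA"]
        ita_copy = Pedigree(df=fra.df.copy(), country="ITA")
        res = link_pedigrees(fra, ita_copy)
        assert len(res) == len(fra)
        assert all(m.method == "exact" and m.status == "accepted" for m in res)


class TestLinkageRecall:
    def test_recall_and_precision_on_truth(self, default_dataset, validated_pedigrees, default_matches):
        """With truncation 0.1 / typo 0.05, the tiers recover >= 95% of true
        matches and never auto-accept a wrong one."""
        pred = {}
        for (s, t), ml in default_matches.items():
            for m in ml:
                pred[(t, m.target_id)] = m
        truth = default_dataset.truth_matches
        assert len(truth) > 30
        correct = 0
        for _, row in truth.iterrows():
            m = pred.get((row["importing_country"], row["stored_id"]))
            assert m is not None, "foreign record not examined"
            if m.status == "accepted":
                assert m.source_id == row["true_id"], "false accepted match"
            if m.source_id == row["true_id"]:
                correct += 1
        assert correct / len(truth) >= 0.95


# ---------------------------------------------------------------------------
# connectedness
# ---------------------------------------------------------------------------


class TestConnectedness:
    def test_no_exports_all_cells_zero(self):
        spec = PopulationSpec(
            seed=2,
            export_rate={},
            n_founders=12,
            n_generations=2,
            n_snps=20,
            n_chromosomes=1,
        )
        ds = simulate_dataset(spec)
        matches = {}
        for s in ds.pedigrees:
            for t in ds.pedigrees:
                if s != t:
                    matches[(s, t)] = link_pedigrees(ds.pedigrees[s], ds.pedigrees[t])
        table = pairwise_connectedness(matches, ds.pedigrees)
        assert table.to_numpy().sum() == 0

    def test_unilateral_flow_structure(self):
        """Exports FRA -> {ITA, CHE, CAN} only: every nonzero origin is FRA."""
        spec = PopulationSpec(
            seed=3,
            export_rate={("FRA", "ITA"): 0.3, ("FRA", "CHE"): 0.2, ("FRA", "CAN"): 0.2},
            n_founders=24,
            n_generations=3,
            n_snps=20,
            n_chromosomes=1,
        )
        ds = simulate_dataset(spec)
        assert set(ds.truth_matches["importing_country"]) <= {"ITA", "CHE", "CAN"}
        matches = {
            (s, t): link_pedigrees(ds.pedigrees[s], ds.pedigrees[t])
            for s in ds.pedigrees
            for t in ds.pedigrees
            if s != t
        }
        table = pairwise_connectedness(matches, ds.pedigrees)
        nonzero = table[table.sum(axis=1) > 0]
        assert len(nonzero) > 0
        assert set(nonzero.index.get_level_values("origin")) == {"FRA"}

    def test_conservation_found_plus_missing(self, default_dataset, validated_pedigrees, default_matches):
        table = pairwise_connectedness(default_matches, validated_pedigrees)
        total_results = sum(len(ml) for ml in default_matches.values())
        assert int(table.to_numpy().sum()) == total_results

    def test_report_grand_total_equals_cell_sum(self, default_dataset, validated_pedigrees, default_matches):
        geno = {
            c: set(g.samples["id"]) for c, g in default_dataset.genotypes.items()
        }
        rep = tabulate_connectedness(validated_pedigrees, geno, default_matches)
        cells = rep.pairwise.drop(columns="All").drop(index=("All", "", ""))
        assert rep.pairwise.loc[("All", "", "")].drop("All").sum() == cells.to_numpy().sum()
        assert rep.grand_total == 2 * cells.to_numpy().sum()  # margins row included


# ---------------------------------------------------------------------------
# pedigree inbreeding
# ---------------------------------------------------------------------------


def tabular_a_diagonal(df):
    """Brute-force numerator relationship matrix by the tabular recursion."""
    ids = list(df["id"])
    idx = {r: i for i, r in enumerate(ids)}
    n = len(ids)
    sire = [idx.get(s, -1) for s in df["sire"]]
    dam = [idx.get(d, -1) for d in df["dam"]]
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return np.diag(A) - 1.0


class TestInbreeding:
    def test_founders_zero(self):
        ped = ped_from_rows(
            [dict(id=f"F{i}", sire="", dam="", sex="M") for i in range(5)]
        )
        f = pedigree_inbreeding(ped)
        assert (f["F"] == 0).all()

    def test_full_sib_offspring_quarter(self):
        ped = ped_from_rows(
            [
                dict(id="A", sire="", dam="", sex="M"),
                dict(id="B", sire="", dam="", sex="F"),
                dict(id="C", sire="A", dam="B", sex="M"),
                dict(id="D", sire="A", dam="B", sex="F"),
                dict(id="X", sire="C", dam="D", sex="F"),
            ]
        )
        f = pedigree_inbreeding(ped).set_index("id")["F"]
        assert f["X"] == pytest.approx(0.25, abs=1e-15)
        assert f[["A", "B", "C", "D"]].eq(0).all()

    def test_matches_tabular_relationship_matrix(self):
        """200-animal random pedigree: F equals diag(A) - 1 to 1e-12."""
        rng = np.random.default_rng(42)
        rows = []
        for i in range(200):
            if i < 20:
                s = d = ""
            else:
                s = f"a{rng.integers(0, i)}"
                d = f"a{rng.integers(0, i)}"
                if s == d:
                    d = ""
            rows.append(dict(id=f"a{i}", sire=s, dam=d, sex="M"))
        ped = ped_from_rows(rows)
        f = pedigree_inbreeding(ped)["F"].to_numpy()
        oracle = tabular_a_diagonal(ped.df)
        assert np.max(np.abs(f - oracle)) < 1e-12
        assert ((f >= 0) & (f <= 1)).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        rows = [
            dict(id="A", sire="", dam="", sex="M"),
            dict(id="B", sire="", dam="", sex="F"),
            dict(id="C", sire="A", dam="B", sex="M"),
            dict(id="D", sire="A", dam="B", sex="F"),
            dict(id="X", sire="C", dam="D", sex="F"),
        ]
        base = pedigree_inbreeding(ped_from_rows(rows)).set_index("id")["F"]
        for _ in range(5):
            perm = [rows[i] for i in rng.permutation(len(rows))]
            f = pedigree_inbreeding(ped_from_rows(perm)).set_index("id")["F"]
            pd.testing.assert_series_equal(f.sort_index(), base.sort_index())

    def test_cycle_raises(self):
        ped = ped_from_rows(
            [
                dict(id="A", sire="B", dam="", sex="M"),
                dict(id="B", sire="A", dam="", sex="M"),
            ]
        )
        with pytest.raises(ValueError, match="cycle"):
            pedigree_inbreeding(ped)
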