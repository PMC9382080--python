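"""PTM consolidation, enrichment tables, mutation filters and pLDDT maps."""

import numpy as np
import pandas as pd
import pytest

from ambiclass.context import (
    class_context_summary,
    consolidate_ptms,
    filter_mutation_proteins,
    mutation_enrichment,
    plddt_feature_histogram,
    ptm_enrichment,
)


def _ptm_rows(rows):
    return pd.DataFrame(rows, columns=["protein_id", "position", "ptm_type", "source"])


class TestConsolidatePtms:
    def test_two_database_site_kept(self):
        raw = _ptm_rows([("P1", 10, "phosphorylation", "scop3p"),
                         ("P1", 10, "phosphorylation", "dbptm")])
        sites = consolidate_ptms(raw)
        assert len(sites) == 1
        assert sites.iloc[0]["ptm_type"] == "phosphorylation"
        assert sites.iloc[0]["evidence"] == frozenset({"scop3p", "dbptm"})

    def test_single_evidence_dropped(self):
        raw = _ptm_rows([("P1", 3, "acetylation", "psp")])
        assert consolidate_ptms(raw).empty

    def test_two_surviving_types_become_multiple(self):
        raw = _ptm_rows([
            ("P1", 7, "phosphorylation", "scop3p"),
            ("P1", 7, "phosphorylation", "dbptm"),
            ("P1", 7, "acetylation", "psp"),
            ("P1", 7, "acetylation", "swissprot"),
        ])
        sites = consolidate_ptms(raw)
        assert len(sites) == 1 and sites.iloc[0]["ptm_type"] == "multiple"
        assert len(sites.iloc[0]["evidence"]) == 4

    def test_single_evidence_type_cannot_contribute_to_multiple(self):
        raw = _ptm_rows([
            ("P1", 7, "phosphorylation", "scop3p"),
            ("P1", 7, "phosphorylation", "dbptm"),
            ("P1", 7, "acetylation", "psp"),  # one database only
        ])
        sites = consolidate_ptms(raw)
        assert sites.iloc[0]["ptm_type"] == "phosphorylation"

    def test_position_beyond_sequence_dropped(self):
        raw = _ptm_rows([("P1", 99, "phosphorylation", "scop3p"),
                         ("P1", 99, "phosphorylation", "dbptm")])
        sites = consolidate_ptms(raw, sequence_lengths={"P1": 50})
        assert sites.empty

    def test_monotone_in_evidence(self):
        """Adding a source database never removes a previously kept site."""
        base = _ptm_rows([("P1", 1, "phosphorylation", "scop3p"),
                          ("P1", 1, "phosphorylation", "dbptm"),
                          ("P2", 5, "acetylation", "psp")])
        extra = pd.concat(
            [base, _ptm_rows([("P2", 5, "acetylation", "swissprot")])],
            ignore_index=True,
        )
        before = set(map(tuple, consolidate_ptms(base)[["protein_id", "position"]].values))
        after = set(map(tuple, consolidate_ptms(extra)[["protein_id", "position"]].values))
        assert before <= after


class TestPtmEnrichment:
    def test_no_sites_zero_table(self):
        table = ptm_enrichment(
            pd.DataFrame(columns=["protein_id", "position", "ptm_type", "evidence"]),
            {},
            {"order": 10, "ambiguous": 5, "disorder": 2},
        )
        assert (table.counts.to_numpy() == 0).all()

    def test_fractions_are_count_over_class_total(self):
        sites = pd.DataFrame(
            {
                "protein_id": ["P1"] * 3,
                "position": [1, 2, 11],
                "ptm_type": ["phosphorylation"] * 3,
                "evidence": [frozenset({"a", "b"})] * 3,
            }
        )
        class_map = {("P1", 1): "order", ("P1", 2): "order", ("P1", 11): "ambiguous"}
        table = ptm_enrichment(sites, class_map, {"order": 10, "ambiguous": 5, "disorder": 4})
        assert table.counts.loc["order", "phosphorylation"] == 2
        assert table.fractions.loc["order", "phosphorylation"] == pytest.approx(0.2)
        assert table.fractions.loc["ambiguous", "phosphorylation"] == pytest.approx(0.2)

    def test_count_conservation_with_unassigned(self):
        sites = pd.DataFrame(
            {
                "protein_id": ["P1", "P1", "P2"],
                "position": [1, 2, 3],
                "ptm_type": ["acetylation"] * 3,
                "evidence": [frozenset({"a", "b"})] * 3,
            }
        )
        class_map = {("P1", 1): "order"}
        table = ptm_enrichment(sites, class_map, {"order": 10, "ambiguous": 1, "disorder": 1})
        assert int(table.counts.to_numpy().sum()) + table.unassigned == len(sites)


class TestFilterMutationProteins:
    def _muts(self, rows):
        return pd.DataFrame(
            rows, columns=["protein_id", "position", "ref", "alt", "pathogenicity", "origin"]
        )

    def test_protein_with_both_kept(self):
        muts = self._muts([("P1", 1, "A", "V", "deleterious", "somatic"),
                           ("P1", 2, "G", "R", "benign", "germline")])
        filtered, summary = filter_mutation_proteins(muts)
        assert len(filtered) == 2
        assert summary == {"n_proteins": 1, "n_mutations": 2,
                           "n_deleterious": 1, "n_benign": 1}

    def test_one_sided_protein_removed(self):
        muts = self._muts([("P1", 1, "A", "V", "deleterious", "somatic"),
                           ("P1", 2, "G", "R", "deleterious", "somatic")])
        filtered, summary = filter_mutation_proteins(muts)
        assert filtered.empty and summary["n_proteins"] == 0

    def test_empty_input(self):
        filtered, summary = filter_mutation_proteins(self._muts([]))
        assert filtered.empty and summary["n_mutations"] == 0


class TestMutationEnrichment:
    def _muts(self):
        rows = []
        for i in range(10):
            rows.append(("P1", i + 1, "A", "V", "deleterious", "somatic"))
        for i in range(2):
            rows.append(("P2", i + 1, "A", "V", "deleterious", "germline"))
        return pd.DataFrame(
            rows, columns=["protein_id", "position", "ref", "alt", "pathogenicity", "origin"]
        )

    def test_pathogenicity_normalization(self):
        muts = self._muts()
        class_map = {("P1", i + 1): "order" for i in range(10)}
        class_map.update({("P2", i + 1): "disorder" for i in range(2)})
        table = mutation_enrichment(
            muts, class_map, {"order": 100, "ambiguous": 10, "disorder": 50}
        )
        assert table.fractions.loc["order", "deleterious"] == pytest.approx(0.10)
        assert table.fractions.loc["disorder", "deleterious"] == pytest.approx(0.04)
        assert (table.counts.loc["ambiguous"] == 0).all()

    def test_origin_ratio_normalization(self):
        muts = self._muts()  # 10 somatic, 2 germline -> ratio 5
        class_map = {("P1", i + 1): "order" for i in range(10)}
        class_map.update({("P2", i + 1): "order" for i in range(2)})
        table = mutation_enrichment(
            muts, class_map, {"order": 100, "ambiguous": 10, "disorder": 10}, mode="origin"
        )
        assert table.extra_normalization["somatic"] == pytest.approx(5.0)
        # 10/100 divided by the global somatic/germline ratio of 5
        assert table.fractions.loc["order", "somatic"] == pytest.approx(0.02)
        assert table.fractions.loc["order", "germline"] == pytest.approx(0.02)

    def test_equal_global_counts_make_ratio_a_noop(self):
        rows = [("P1", 1, "A", "V", "deleterious", "somatic"),
                ("P1", 2, "A", "V", "deleterious", "germline")]
        muts = pd.DataFrame(
            rows, columns=["protein_id", "position", "ref", "alt", "pathogenicity", "origin"]
        )
        class_map = {("P1", 1): "order", ("P1", 2): "order"}
        table = mutation_enrichment(muts, class_map, {"order": 10, "ambiguous": 1,
                                                      "disorder": 1}, mode="origin")
        assert table.fractions.loc["order", "somatic"] == pytest.approx(
            table.fractions.loc["order", "germline"]
        )

    def test_zero_class_total_flagged_nan(self):
        muts = self._muts()
        table = mutation_enrichment(muts, {}, {"order": 0, "ambiguous": 1, "disorder": 1})
        assert np.isnan(table.fractions.loc["order"]).all()


class TestPlddtHistogram:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["plddt", "backbone", "ss3"])

    def test_empty_input_zero_grids(self):
        grids = plddt_feature_histogram(self._records([]))
        assert all(grid.total == 0 for grid in grids.values())

    def test_single_residue_single_cell(self):
        grids = plddt_feature_histogram(self._records([(90.0, 0.85, "helix")]))
        assert grids["helix"].total == 1
        assert np.count_nonzero(grids["helix"].counts) == 1
        assert grids["strand"].total == 0

    def test_totals_partition_by_ss(self):
        rng = np.random.default_rng(0)
        rows = [
            (rng.uniform(0, 100), rng.uniform(0, 1.2), rng.choice(["helix", "strand", "coil"]))
            for _ in range(300)
        ]
        grids = plddt_feature_histogram(self._records(rows))
        assert sum(g.total for g in grids.values()) == 300

    def test_out_of_range_plddt_rejected_rows(self):
        grids = plddt_feature_histogram(
            self._records([(150.0, 0.5, "coil"), (50.0, 0.5, "coil")])
        )
        assert grids["coil"].total == 1


class TestClassContextSummary:
    def test_quantiles_monotone(self):
        rng = np.random.default_rng(1)
        records = pd.DataFrame(
            {
                "label": rng.choice(["order", "disorder"], size=200),
                "plddt": rng.uniform(0, 100, size=200),
            }
        )
        summary = class_context_summary(records)
        for entry in summary.values():
            q = entry["plddt"]
            assert q["q25"] <= q["q50"] <= q["q75"]

    def test_class_separation_recovered(self):
        rng = np.random.default_rng(2)
        records = pd.DataFrame(
            {
                "label": ["order"] * 100 + ["disorder"] * 100,
                "plddt": np.concatenate(
                    [rng.normal(90, 5, 100), rng.normal(40, 5, 100)]
                ),
            }
        )
        summary = class_context_summary(records)
        assert summary["order"]["plddt"]["q50"] > summary["disorder"]["plddt"]["q50"]

    def test_single_class_equals_global(self):
        records = pd.DataFrame({"label": ["order"] * 50, "plddt": np.arange(50.0)})
        summary = class_context_summary(records)
        assert summary["order"]["plddt"]["n"] == 50
        assert summary["order"]["plddt"]["q50"] == pytest.approx(np.median(np.arange(50.0)))
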