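import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from terminome.peptidome import (
    PeptideRecord,
    QuantTable,
    aggregate_protein_areas,
    count_significant,
    filter_peptides,
    fold_change_frame,
    fold_changes,
    load_published_fold_changes,
    normalize_runs,
    render_peptide_map,
)


def rec(seq="ACDEF", prot="P1", group="G1", rep=1, area=1.0, conf=1.0, shared=False):
    return PeptideRecord(seq, prot, group, rep, area, conf, shared)


class TestPeptideRecord:
    def test_rejects_bad_sequence(self):
        with pytest.raises(ValueError):
            rec(seq="ACXDE")

    def test_rejects_negative_area(self):
        with pytest.raises(ValueError):
            rec(area=-1.0)

    def test_rejects_bad_confidence(self):
        with pytest.raises(ValueError):
            rec(conf=1.5)


class TestFilterPeptides:
    def test_confidence_boundary_inclusive(self):
        table = QuantTable.from_records([rec(conf=0.79), rec(conf=0.80), rec(conf=0.99)])
        out = filter_peptides(table, 0.80)
        assert sorted(out.frame["confidence"]) == [0.80, 0.99]

    def test_shared_removed_despite_high_confidence(self):
        table = QuantTable.from_records([rec(conf=0.99, shared=True), rec(conf=0.85)])
        out = filter_peptides(table)
        assert len(out) == 1
        assert not out.frame["shared"].any()

    def test_empty_table_identity(self):
        table = QuantTable(pd.DataFrame(columns=QuantTable.from_records([rec()]).frame.columns))
        assert len(filter_peptides(table)) == 0

    def test_input_untouched(self):
        table = QuantTable.from_records([rec(conf=0.5), rec(conf=0.9)])
        filter_peptides(table)
        assert len(table) == 2


class TestNormalizeRuns:
    def test_simple_scaling(self):
        table = QuantTable.from_records(
            [rec(seq=s, area=a) for s, a in [("AAAAK", 2.0), ("CCCCK", 3.0), ("DDDDK", 5.0)]]
        )
        out = normalize_runs(table)
        assert sorted(out.frame["area"]) == pytest.approx([0.2, 0.3, 0.5])

    def test_idempotent(self):
        table = QuantTable.from_records([rec(seq="AAAAK", area=3.0), rec(seq="CCCCK", area=7.0)])
        once = normalize_runs(table)
        twice = normalize_runs(once)
        assert np.allclose(once.frame["area"], twice.frame["area"], atol=1e-12)

    def test_runs_independent(self):
        table = QuantTable.from_records(
            [
                rec(seq="AAAAK", rep=1, area=1.0),
                rec(seq="CCCCK", rep=1, area=1.0),
                rec(seq="AAAAK", rep=2, area=3.0),
                rec(seq="CCCCK", rep=2, area=1.0),
            ]
        )
        out = normalize_runs(table).frame
        run1 = out[out["replicate"] == 1]["area"].tolist()
        run2 = sorted(out[out["replicate"] == 2]["area"].tolist())
        assert run1 == pytest.approx([0.5, 0.5])
        assert run2 == pytest.approx([0.25, 0.75])

    def test_zero_run_errors_with_run_name(self):
        table = QuantTable.from_records([rec(area=0.0, group="Gz", rep=2)])
        with pytest.raises(ValueError, match="Gz"):
            normalize_runs(table)

    def test_run_sums_equal_one(self):
        rng = np.random.default_rng(0)
        records = [
            rec(seq="AAAAK", group=g, rep=r, area=float(rng.uniform(0.1, 5)))
            for g in ("G1", "G2")
            for r in (1, 2, 3)
        ]
        out = normalize_runs(QuantTable.from_records(records)).frame
        sums = out.groupby(["group", "replicate"])["area"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_preserves_within_run_ratios(self):
        table = QuantTable.from_records(
            [rec(seq="AAAAK", area=2.0), rec(seq="CCCCK", area=6.0)]
        )
        out = normalize_runs(table).frame
        a = out.set_index("peptide_seq")["area"]
        assert a["CCCCK"] / a["AAAAK"] == pytest.approx(3.0)


class TestAggregateProteinAreas:
    def test_peptides_sum_within_protein(self):
        table = QuantTable.from_records(
            [rec(seq="AAAAK", area=0.1), rec(seq="CCCCK", area=0.2)]
        )
        (p,) = aggregate_protein_areas(table)
        assert p.area_by_group["G1"] == pytest.approx(0.3)

    def test_absent_group_is_zero(self):
        table = QuantTable.from_records(
            [rec(prot="P1", group="G1"), rec(prot="P2", group="G2")]
        )
        areas = {p.protein_id: p.area_by_group for p in aggregate_protein_areas(table)}
        assert areas["P1"]["G2"] == 0.0
        assert areas["P2"]["G1"] == 0.0

    def test_replicate_mean(self):
        table = QuantTable.from_records(
            [rec(rep=1, area=0.1), rec(rep=2, area=0.2), rec(rep=3, area=0.3)]
        )
        (p,) = aggregate_protein_areas(table)
        assert p.area_by_group["G1"] == pytest.approx(0.2)


class TestFoldChanges:
    def _protein(self, areas):
        from terminome.peptidome import ProteinFoldChange

        return ProteinFoldChange(protein_id="P1", area_by_group=areas)

    def test_ratio(self):
        out = fold_changes([self._protein({"Decap": 0.0025, "AirEx1": 0.02988})], "Decap")
        fc = out[0].fold_change_by_group["AirEx1"]
        assert fc == pytest.approx(11.952)
        assert out[0].significant_by_group["AirEx1"]

    def test_identity_ratio_not_significant(self):
        out = fold_changes([self._protein({"Decap": 0.3, "G": 0.3})], "Decap")
        assert out[0].fold_change_by_group["G"] == pytest.approx(1.0)
        assert not out[0].significant_by_group["G"]

    def test_zero_reference_undefined(self):
        out = fold_changes([self._protein({"Decap": 0.0, "G": 0.5})], "Decap")
        assert out[0].fold_change_by_group["G"] is None
        assert not out[0].significant_by_group["G"]
        frame = fold_change_frame(out)
        assert count_significant(frame, 2.0)["G"] == 0

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            fold_changes([self._protein({"G": 0.5})], "Decap")

    def test_scale_invariance_to_global_rescaling(self):
        records = [
            rec(seq="AAAAK", group=g, rep=r, area=a)
            for (g, r, a) in [("Decap", 1, 2.0), ("T", 1, 5.0)]
        ] + [
            rec(seq="CCCCK", group=g, rep=r, area=a)
            for (g, r, a) in [("Decap", 1, 1.0), ("T", 1, 3.0)]
        ]

        def pipeline(scale):
            scaled = [
                PeptideRecord(r.peptide_seq, r.protein_id, r.group, r.replicate,
                              r.area * scale, r.confidence, r.shared)
                for r in records
            ]
            t = normalize_runs(QuantTable.from_records(scaled))
            return fold_changes(aggregate_protein_areas(t), "Decap")[0].fold_change_by_group["T"]

        assert pipeline(1.0) == pytest.approx(pipeline(137.5))


class TestCountSignificant:
    def test_published_matrix_first_column(self):
        frame = load_published_fold_changes()
        counts = count_significant(frame, 2.0)
        assert counts["AirEx1"] == 19

    def test_all_ones_zero(self):
        frame = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
        assert count_significant(frame, 2.0) == {"a": 0, "b": 0, "c": 0}

    def test_boundary_strict(self):
        frame = pd.DataFrame({"g": [2.0]})
        assert count_significant(frame, 2.0)["g"] == 0

    @given(st.floats(0.1, 30.0), st.floats(0.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_in_threshold(self, t1, delta):
        frame = load_published_fold_changes()
        c1 = count_significant(frame, t1)
        c2 = count_significant(frame, t1 + delta)
        for g in c1:
            assert c2[g] <= c1[g]


class TestPublishedFixture:
    def test_shape_and_columns(self):
        frame = load_published_fold_changes()
        assert list(frame.columns) == ["AirEx1", "AirEx5", "AirEx10"]
        assert len(frame) == 135
        assert frame.notna().all().all()


class TestRenderPeptideMap:
    def test_single_high_confidence_peptide(self):
        protein = "MKLVTAGWQH"
        report = render_peptide_map(protein, [rec(seq="LVTA", conf=0.96)])
        tier_line = report.splitlines()[1].split()[-1]
        assert tier_line == "..1111...."
        assert "coverage: 4/10" in report

    def test_overlap_best_tier_wins(self):
        protein = "MKLVTAGWQH"
        peps = [rec(seq="LVTAGW", conf=0.40), rec(seq="VTAG", conf=0.97)]
        report = render_peptide_map(protein, peps)
        tier_line = report.splitlines()[1].split()[-1]
        assert tier_line == "..311113.."

    def test_middle_tier(self):
        report = render_peptide_map("MKLVT", [rec(seq="KLV", conf=0.6)])
        assert report.splitlines()[1].split()[-1] == ".222."

    def test_no_peptides_all_uncovered(self):
        report = render_peptide_map("MKLVT", [])
        assert report.splitlines()[1].split()[-1] == "....."
        assert "coverage: 0/5" in report

    def test_unmapped_skipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            report = render_peptide_map("MKLVT", [rec(seq="WWWW", conf=0.99)])
        assert "does not map" in caplog.text
        assert "coverage: 0/5" in report


class TestQuantTableIO:
    def test_tsv_round_trip(self, tmp_path):
        table = QuantTable.from_records(
            [rec(conf=0.9), rec(seq="CCCCK", shared=True, area=2.5)]
        )
        path = tmp_path / "quant.tsv"
        table.to_tsv(path)
        back = QuantTable.read_tsv(path)
        pd.testing.assert_frame_equal(table.frame, back.frame)
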