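import math

import numpy as np
import pytest

from phenoclass import curation
from phenoclass.curation import (SchemaError, annotate_pactivity, curate,
                                 filter_mw, filter_protocol, filter_standard,
                                 protocol_overlap, read_activity_table,
                                 resolve_duplicates, to_pactivity)

from conftest import entries_from_pactivities, make_entry, make_record

CSV_HEADER = ("compound_id,smiles,assay_id,document_id,cell_line,assay_type,"
              "incubation_h,standard_type,standard_relation,standard_value,"
              "standard_units\n")


def _row(cid="C1", value="10000"):
    return (f"{cid},CCO,A1,D1,PC-3,MTT,72,IC50,=,{value},nM\n")


class TestReadActivityTable:
    def test_well_formed_rows_parse_one_to_one(self, tmp_path):
        p = tmp_path / "raw.csv"
        p.write_text(CSV_HEADER + _row("C1") + _row("C2") + _row("C3"))
        records = read_activity_table(p)
        assert len(records) == 3
        assert records[0].cell_line == "PC3"          # alias normalised
        assert records[0].standard_value == 10000.0

    def test_unparseable_numeric_row_dropped_and_counted(self, tmp_path):
        p = tmp_path / "raw.csv"
        p.write_text(CSV_HEADER + _row("C1") + _row("C2", value="n/a"))
        records = read_activity_table(p)
        assert [r.compound_id for r in records] == ["C1"]
        assert read_activity_table.last_drop_count == 1

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "raw.csv"
        p.write_text(CSV_HEADER)
        assert read_activity_table(p) == []

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "raw.csv"
        p.write_text("compound_id,smiles\nC1,CCO\n")
        with pytest.raises(SchemaError, match="standard_value"):
            read_activity_table(p)


class TestProtocolAndStandardFilters:
    def test_protocol_rule(self):
        recs = [make_record(assay_type="MTT", incubation_h=72),
                make_record(assay_type="SRB", incubation_h=48),
                make_record(assay_type="MTT", incubation_h=24)]
        assert filter_protocol(recs) == recs[:2]

    def test_all_records_fail_protocol(self):
        recs = [make_record(assay_type="SRB", incubation_h=24)] * 3
        assert filter_protocol(recs) == []

    def test_mixed_list_counts(self):
        # 4 of 10 qualify: MTT/SRB at 48/72 h only
        recs = ([make_record(assay_type="MTT", incubation_h=72),
                 make_record(assay_type="SRB", incubation_h=48),
                 make_record(assay_type="MTT", incubation_h=48),
                 make_record(assay_type="SRB", incubation_h=72)]
                + [make_record(assay_type="MTT", incubation_h=24)] * 3
                + [make_record(assay_type="XTT", incubation_h=72)] * 3)
        assert len(filter_protocol(recs)) == 4

    @pytest.mark.parametrize("kw,kept", [
        (dict(standard_relation=">"), False),
        (dict(standard_type="IC50"), True),
        (dict(standard_type="GI50"), True),
        (dict(standard_type="EC50"), False),
        (dict(standard_units="ug.mL-1"), False),
    ])
    def test_standard_rule(self, kw, kept):
        assert bool(filter_standard([make_record(**kw)])) is kept

    def test_filters_idempotent_and_commute(self):
        recs = [make_record(assay_type=a, incubation_h=h, standard_type=t,
                            standard_relation=rel)
                for a in ("MTT", "SRB", "XTT") for h in (24, 48, 72)
                for t in ("IC50", "EC50") for rel in ("=", ">")]
        once = filter_protocol(recs)
        assert filter_protocol(once) == once
        assert filter_standard(filter_protocol(recs)) == \
            filter_protocol(filter_standard(recs))


class TestToPactivity:
    @pytest.mark.parametrize("nM,expected", [
        (10000.0, 5.0), (1.0, 9.0), (6990.0, 9 - math.log10(6990)),
    ])
    def test_known_conversions(self, nM, expected):
        assert to_pactivity(nM) == pytest.approx(expected, abs=1e-9)

    def test_hand_value(self):
        assert to_pactivity(6990.0) == pytest.approx(5.1555, abs=5e-5)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            to_pactivity(bad)

    def test_strictly_decreasing_and_log_shift(self, rng):
        v = np.sort(rng.uniform(0.1, 1e7, size=50))
        p = [to_pactivity(x) for x in v]
        assert all(a > b for a, b in zip(p, p[1:]))
        # converting x µM expressed in nM: pActivity + log10(x) is constant
        for x in (0.5, 2.0, 10.0):
            assert to_pactivity(1000.0 * x) + math.log10(x) == pytest.approx(6.0)


class TestResolveDuplicates:
    def _records(self, pvals, cid="C1"):
        return annotate_pactivity(
            [make_record(compound_id=cid, standard_value=10 ** (9 - p))
             for p in pvals])

    def test_narrow_group_averages(self):
        entries = resolve_duplicates(self._records([5.2, 5.8]))
        assert len(entries) == 1
        assert entries[0].pactivity == pytest.approx(5.5)
        assert entries[0].n_source_records == 2

    def test_wide_group_discarded(self):
        assert resolve_duplicates(self._records([4.0, 5.5])) == []

    def test_range_exactly_one_is_kept(self):
        entries = resolve_duplicates(self._records([5.0, 5.5, 6.0]))
        assert len(entries) == 1
        assert entries[0].pactivity == pytest.approx(5.5)

    def test_consensus_within_group_range(self, rng):
        records = []
        for i in range(30):
            pvals = rng.uniform(4, 7) + rng.uniform(0, 1.5, size=rng.integers(1, 4))
            records += self._records(pvals, cid=f"C{i}")
        by_id = {}
        for r in records:
            by_id.setdefault(r.compound_id, []).append(r.pactivity)
        entries = resolve_duplicates(records)
        assert len(entries) <= len(by_id)
        for e in entries:
            grp = by_id[e.compound_id]
            assert min(grp) <= e.pactivity <= max(grp)


class TestFilterMw:
    def test_inclusive_bounds(self):
        kept = filter_mw([make_entry(compound_id="a", mw=350.0),
                          make_entry(compound_id="b", mw=601.0),
                          make_entry(compound_id="c", mw=100.0),
                          make_entry(compound_id="d", mw=600.0)])
        assert [e.compound_id for e in kept] == ["a", "c", "d"]

    def test_benzene_below_range(self):
        # C6H6 = 6*12.011 + 6*1.008 = 78.11 Da
        assert filter_mw([make_entry(smiles="c1ccccc1", mw=None)]) == []

    def test_unparseable_smiles_dropped(self):
        assert filter_mw([make_entry(smiles="not_a_smiles")]) == []


class TestProtocolOverlap:
    def _rec(self, cid, assay, h, p):
        return make_record(compound_id=cid, assay_type=assay, incubation_h=h,
                           standard_value=10 ** (9 - p))

    def test_disjoint_protocols(self):
        recs = annotate_pactivity(
            [self._rec("A", "MTT", 72, 5.0), self._rec("B", "SRB", 48, 6.0)])
        rep = protocol_overlap(recs)
        i = rep.protocols.index(("MTT", 72))
        j = rep.protocols.index(("SRB", 48))
        assert rep.counts[i, j] == 0 and np.isnan(rep.pearson[i, j])
        assert rep.counts[i, i] == 1 and rep.pearson[i, i] == 1.0

    def test_identical_values_give_r_one(self):
        recs = []
        for k in range(5):
            recs += [self._rec(f"C{k}", "MTT", 72, 5.0 + 0.3 * k),
                     self._rec(f"C{k}", "SRB", 48, 5.0 + 0.3 * k)]
        rep = protocol_overlap(annotate_pactivity(recs))
        i = rep.protocols.index(("MTT", 72))
        j = rep.protocols.index(("SRB", 48))
        assert rep.counts[i, j] == 5
        assert rep.pearson[i, j] == pytest.approx(1.0)
        np.testing.assert_array_equal(rep.counts, rep.counts.T)

    def test_matches_textbook_pearson(self):
        x = [5.0, 5.5, 6.2, 4.8]
        y = [5.1, 5.9, 6.0, 4.5]
        recs = []
        for k, (a, b) in enumerate(zip(x, y)):
            recs += [self._rec(f"C{k}", "MTT", 72, a),
                     self._rec(f"C{k}", "SRB", 48, b)]
        rep = protocol_overlap(annotate_pactivity(recs))
        i = rep.protocols.index(("MTT", 72))
        j = rep.protocols.index(("SRB", 48))
        xm, ym = np.mean(x), np.mean(y)
        r_hand = (sum((a - xm) * (b - ym) for a, b in zip(x, y))
                  / math.sqrt(sum((a - xm) ** 2 for a in x)
                              * sum((b - ym) ** 2 for b in y)))
        assert rep.pearson[i, j] == pytest.approx(r_hand, abs=1e-12)


def test_full_curation_pipeline_order():
    """End-to-end: bad protocol/relation rows drop, duplicates collapse, MW holds."""
    records = [
        make_record(compound_id="keep", standard_value=10 ** (9 - 5.2)),
        make_record(compound_id="keep", standard_value=10 ** (9 - 5.8)),
        make_record(compound_id="wide", standard_value=10 ** (9 - 4.0)),
        make_record(compound_id="wide", standard_value=10 ** (9 - 5.5)),
        make_record(compound_id="rel", standard_relation=">"),
        make_record(compound_id="proto", incubation_h=24),
        make_record(compound_id="small", smiles="c1ccccc1"),
    ]
    entries = curate(records)
    assert [e.compound_id for e in entries] == ["keep"]
    assert entries[0].pactivity == pytest.approx(5.5)
    assert 100 <= entries[0].mw <= 600
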