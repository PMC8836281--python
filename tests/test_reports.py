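"""Report I/O, acceptance filtering and protein roll-up."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oleopep.peptide import Peptide
from oleopep.reports import (
    FilterPolicy,
    PeptideRecord,
    SchemaError,
    apply_filters,
    compute_alc,
    neg10lgP_from_p,
    read_report,
    records_to_frame,
    rollup_proteins,
    write_report,
)


def make_record(seq="CCYSVY", flavour="db", **kw):
    base = dict(peptide=Peptide(seq), observed_mz=400.0, z=2, sample_id="s1")
    if flavour == "db":
        base["neg10lgP"] = 35.0
    else:
        base["alc_percent"] = 95.0
    base.update(kw)
    return PeptideRecord(**base)


class TestRecordInvariants:
    def test_exactly_one_score(self):
        with pytest.raises(ValueError):
            PeptideRecord(peptide=Peptide("AG"), observed_mz=100.0, z=2)
        with pytest.raises(ValueError):
            PeptideRecord(peptide=Peptide("AG"), observed_mz=100.0, z=2,
                          neg10lgP=30.0, alc_percent=90.0)

    def test_confidence_length_checked(self):
        with pytest.raises(ValueError):
            make_record(flavour="denovo", local_confidence=(90.0, 91.0))


class TestReadWrite:
    def test_bundled_db_report(self, db_records):
        assert len(db_records) == 19
        by_seq = {r.bare_sequence: r for r in db_records}
        assert by_seq["VVLQDTSNNVNQLD"].area == pytest.approx(3.44e5)
        assert by_seq["VVLQDTSNNVNQLDDIPRRFFLA"].area is None  # printed as ND
        assert by_seq["LLLGAGCM"].peptide.modifications == {7: 15.99}
        assert by_seq["CPANGFY"].neg10lgP == pytest.approx(29.54)

    def test_bundled_denovo_report(self, denovo_records):
        assert len(denovo_records) == 8
        first = denovo_records[0]
        assert first.bare_sequence == "CCYSVY"
        assert first.local_confidence == (92, 97, 99, 93, 92, 98)
        assert first.flavour == "denovo"

    def test_round_trip(self, tmp_path, db_records, denovo_records):
        for flavour, records in (("db", db_records), ("denovo", denovo_records)):
            out = tmp_path / f"{flavour}.tsv"
            write_report(records, out)
            again = read_report(out, flavour=flavour)
            assert again == records

    def test_missing_column_schema_error(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("peptide,m/z\nAG,100.0\n")
        with pytest.raises(SchemaError, match="neg10lgP"):
            read_report(f, flavour="db")

    def test_header_only_file(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("peptide,-10lgP,m/z,z\n")
        assert read_report(f, flavour="db") == []

    def test_confidence_mismatch_is_row_error(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("peptide\tlocal_confidence\tm/z\tz\nCCYSVY\t90 91\t369.1\t2\n")
        with pytest.raises(ValueError, match="local confidence"):
            read_report(f, flavour="denovo")


class TestAlc:
    @pytest.mark.parametrize(
        "conf, printed",
        [
            ([92, 97, 99, 93, 92, 98], 95),
            ([89, 91, 97, 91, 92, 85], 91),
            ([100, 100], 100),
        ],
    )
    def test_reference_values_half_up(self, conf, printed):
        assert compute_alc(conf, rounding="half_up").rounded == printed

    def test_floor_default(self):
        res = compute_alc([92, 98, 98, 98, 90, 93])  # mean 94.83
        assert res.rounded == 94
        assert res.mean == pytest.approx(94.8333, abs=1e-4)

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=25))
    def test_mean_between_min_and_max(self, conf):
        res = compute_alc(conf)
        assert min(conf) - 1e-9 <= res.mean <= max(conf) + 1e-9

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            compute_alc([])


class TestScoreFromP:
    @pytest.mark.parametrize("p, score", [(0.01, 20.0), (0.001, 30.0), (1.0, 0.0)])
    def test_reference_points(self, p, score):
        assert neg10lgP_from_p(p) == pytest.approx(score)

    @pytest.mark.parametrize("p", [0.0, -1.0, 1.5])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            neg10lgP_from_p(p)


class TestFilters:
    def test_replicated_high_scoring_kept(self):
        recs = [make_record(sample_id="s1"), make_record(sample_id="s2")]
        assert apply_filters(recs) == recs

    def test_single_sample_dropped_unless_min_samples_1(self):
        recs = [make_record(neg10lgP=95.0)]
        assert apply_filters(recs) == []
        assert apply_filters(recs, FilterPolicy(min_samples=1)) == recs

    def test_charge_one_rejected(self):
        recs = [make_record(sample_id=s, z=1) for s in ("s1", "s2")]
        assert apply_filters(recs) == []

    def test_score_threshold_per_flavour(self):
        low_db = [make_record(neg10lgP=29.9, sample_id=s) for s in ("s1", "s2")]
        assert apply_filters(low_db) == []
        low_dn = [make_record(flavour="denovo", alc_percent=89.9, sample_id=s)
                  for s in ("s1", "s2")]
        assert apply_filters(low_dn) == []

    def test_modification_stripping_pools_evidence(self):
        recs = [
            PeptideRecord(peptide=Peptide("LLLGAGCM", {7: 15.99}), observed_mz=397.2,
                          z=2, sample_id="s1", neg10lgP=34.5),
            PeptideRecord(peptide=Peptide("LLLGAGCM"), observed_mz=389.2,
                          z=2, sample_id="s2", neg10lgP=40.0),
        ]
        assert len(apply_filters(recs)) == 2
        strict = FilterPolicy(strip_modifications=False)
        assert apply_filters(recs, strict) == []

    def test_mixed_flavours_usage_error(self):
        with pytest.raises(ValueError):
            apply_filters([make_record(), make_record(flavour="denovo")])

    def test_order_preserved(self):
        recs = [make_record(sample_id=s, observed_mz=mz)
                for s, mz in (("s1", 400.0), ("s2", 401.0), ("s1", 402.0))]
        assert apply_filters(recs) == recs

    @given(
        st.lists(
            st.tuples(st.floats(20, 100), st.integers(1, 3), st.integers(1, 3)),
            max_size=30,
        ),
        st.floats(20, 60),
        st.integers(1, 3),
    )
    def test_monotonicity(self, rows, threshold, min_charge):
        recs = [
            make_record(neg10lgP=score, z=z, sample_id=f"s{s}")
            for score, z, s in rows
        ]
        lenient = FilterPolicy(min_neg10lgP=30, min_samples=1, min_charge=1)
        stricter = FilterPolicy(
            min_neg10lgP=max(30, threshold), min_samples=2, min_charge=min_charge
        )
        assert len(apply_filters(recs, stricter)) <= len(apply_filters(recs, lenient))


class TestRollup:
    def test_reference_protein_areas(self, db_records):
        rollups = {r.accession: r for r in rollup_proteins(db_records)}
        legumin = rollups["OE9A032471P1"]
        assert legumin.n_supporting == 6
        assert legumin.total_area == pytest.approx(2.82e6, rel=1e-3)
        apyrase = rollups["OE9A001718P2"]
        assert apyrase.n_supporting == 2
        assert apyrase.total_area == pytest.approx(4.543e5, rel=1e-3)

    def test_nd_area_counts_as_zero_not_nan(self, db_records):
        legumin = {r.accession: r for r in rollup_proteins(db_records)}[
            "OE9A032471P1"
        ]
        assert not math.isnan(legumin.total_area)

    def test_single_supporting_peptide(self):
        rec = make_record(area=123.0, accessions=("P1",))
        (rollup,) = rollup_proteins([rec])
        assert rollup.total_area == 123.0
        assert rollup.protein_neg10lgP == rec.neg10lgP

    def test_multi_accession_contributes_to_each(self):
        rec = make_record(area=10.0, accessions=("P1", "P2"))
        rollups = rollup_proteins([rec])
        assert {r.accession for r in rollups} == {"P1", "P2"}
        assert all(r.total_area == 10.0 for r in rollups)

    @given(st.permutations(list(range(6))))
    def test_permutation_invariant(self, db_records, order):
        legumin_records = [r for r in db_records if "OE9A032471P1" in r.accessions]
        shuffled = [legumin_records[i] for i in order]
        (a,) = [r for r in rollup_proteins(shuffled) if r.accession == "OE9A032471P1"]
        (b,) = [r for r in rollup_proteins(legumin_records)
                if r.accession == "OE9A032471P1"]
        assert a.total_area == b.total_area

    def test_coverage_when_positions_supplied(self):
        recs = [make_record(seq="AAAA", accessions=("P1",)),
                make_record(seq="GGGG", accessions=("P1",), sample_id="s2")]
        rollup, = rollup_proteins(
            recs,
            protein_lengths={"P1": 20},
            peptide_positions={("P1", "AAAA"): (0, 4), ("P1", "GGGG"): (2, 6)},
        )
        assert rollup.coverage_percent == pytest.approx(30.0)  # residues 0..5

    def test_coverage_absent_without_positions(self, db_records):
        rollups = rollup_proteins(db_records)
        assert all(r.coverage_percent is None for r in rollups)
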