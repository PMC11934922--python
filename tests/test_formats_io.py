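import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probefold.formats_io import (
    SENTINEL,
    ClassScheme,
    ReactivityProfile,
    SamplesTable,
    SecondaryStructure,
    parse_dotbracket,
    read_dotbracket,
    read_msa_fasta,
    read_reactivity_tsv,
    read_samples_table,
    write_color_annotation,
    write_dotbracket,
    write_msa_fasta,
    write_reactivity_tsv,
)


class TestReactivityTSV:
    def test_identity_read(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("1\t0.2\n2\t1.5\n3\t-0.1\n")
        profile = read_reactivity_tsv(path)
        assert profile.length == 3
        assert profile.values.tolist() == [0.2, 1.5, -0.1]

    def test_missing_positions_filled_with_sentinel(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("1\t0.2\n3\t0.4\n")
        profile = read_reactivity_tsv(path)
        assert profile.length == 3
        assert profile.value(2) == SENTINEL

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("1\t0.2\n2\tabc\n")
        with pytest.raises(ValueError, match="line 2"):
            read_reactivity_tsv(path)

    def test_duplicate_position_rejected(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("1\t0.2\n1\t0.3\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_reactivity_tsv(path)

    def test_comment_lines_skipped(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("# header\n1\t0.5\n")
        assert read_reactivity_tsv(path).value(1) == 0.5

    @given(
        values=st.lists(
            st.one_of(
                st.floats(-5, 50, allow_nan=False).map(lambda v: round(v, 4)),
                st.just(SENTINEL),
            ),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_write_read_round_trip(self, values, tmp_path_factory):
        path = tmp_path_factory.mktemp("io") / "p.tsv"
        profile = ReactivityProfile("x", "c", "r", np.array(values))
        write_reactivity_tsv(profile, path)
        back = read_reactivity_tsv(path, rna_id="x", condition_id="c", replicate_id="r")
        assert np.allclose(back.values, profile.values, rtol=1e-5, atol=1e-9)


class TestDotBracket:
    def test_matched_brackets(self):
        assert parse_dotbracket("((...))").pairs == {(1, 7), (2, 6)}

    def test_open_chain(self):
        assert parse_dotbracket(".......").pairs == frozenset()

    def test_unbalanced_reports_first_offending_index(self):
        with pytest.raises(ValueError, match="index 4"):
            parse_dotbracket("(.))")
        with pytest.raises(ValueError, match="index 1"):
            parse_dotbracket("(..")

    def test_invalid_character(self):
        with pytest.raises(ValueError, match="index 2"):
            parse_dotbracket(".x.")

    def test_round_trip(self):
        text = "..(((....)))..((...))."
        assert parse_dotbracket(text).to_dotbracket() == text

    def test_file_round_trip(self, tmp_path):
        structure = parse_dotbracket("((((...))))", sequence="GGCGAAACGCC")
        path = tmp_path / "s.dbn"
        write_dotbracket(structure, path, name="hp")
        back = read_dotbracket(path)
        assert back.pairs == structure.pairs
        assert back.sequence == structure.sequence

    def test_crossing_pairs_rejected(self):
        with pytest.raises(ValueError, match="crossing"):
            SecondaryStructure(10, {(1, 6), (3, 9)})

    def test_shared_endpoint_rejected(self):
        with pytest.raises(ValueError, match="more than one pair"):
            SecondaryStructure(10, {(1, 6), (6, 10)})


class TestClassScheme:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.39, "low"),
            (SENTINEL, "undefined"),
            (0.7, "medium"),   # closed upper boundary
            (0.4, "medium"),   # closed lower boundary
            (0.71, "high"),
            (0.0, "low"),
        ],
    )
    def test_boundaries(self, value, expected):
        assert ClassScheme().classify(value) == expected

    @given(st.floats(allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_total_function(self, value):
        assert ClassScheme().classify(value) in {"undefined", "low", "medium", "high"}

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            ClassScheme(reactivity_medium=0.8, reactivity_high=0.7)


class TestColorAnnotation:
    def test_contents_and_classes(self, tmp_path):
        path = tmp_path / "colors.tsv"
        write_color_annotation([0.39, SENTINEL, 0.7, 0.9], ClassScheme(), path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        classes = [l.split("\t")[2] for l in lines]
        assert classes == ["low", "undefined", "medium", "high"]

    def test_length_mismatch(self, tmp_path):
        with pytest.raises(ValueError, match="length"):
            write_color_annotation([0.1, 0.2], ClassScheme(), tmp_path / "c.tsv", length=3)


class TestSamplesTable:
    def _frame(self, **overrides):
        base = {
            "rna_id": ["R1", "R1"],
            "probe": ["1M7", "1M7"],
            "condition": ["apo", "apo"],
            "replicate": ["1", "2"],
            "primer_start": [1, 1],
            "primer_end": [50, 50],
            "file_path": ["a.tsv", "b.tsv"],
            "discarded": ["false", "true"],
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_discarded_rows_excluded(self):
        table = SamplesTable(self._frame())
        active = table.active()
        assert len(active) == 1
        assert active.iloc[0]["replicate"] == "1"

    def test_duplicate_key_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SamplesTable(self._frame(replicate=["1", "1"]))

    def test_round_trip(self, tmp_path):
        from probefold.formats_io import write_samples_table

        table = SamplesTable(self._frame())
        path = tmp_path / "samples.tsv"
        write_samples_table(table, path)
        back = read_samples_table(path)
        assert back.frame["discarded"].tolist() == [False, True]


class TestFasta:
    def test_msa_round_trip(self, tmp_path):
        rows = [("ref", "GGCA-ACC"), ("seq1", "GACA-ACC")]
        path = tmp_path / "msa.fa"
        write_msa_fasta(rows, path)
        assert read_msa_fasta(path) == rows

    def test_unequal_rows_rejected(self, tmp_path):
        path = tmp_path / "msa.fa"
        path.write_text(">a\nGGG\n>b\nGG\n")
        with pytest.raises(ValueError, match="unequal"):
            read_msa_fasta(path)
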