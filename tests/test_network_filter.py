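"""Signed-interaction loading, the extra-protein filter, and the
synthetic network generator."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from triosc.network_filter import (
    FormatError,
    InteractionRecord,
    filter_candidates,
    generate_synthetic_network,
    load_interactions,
    write_interactions,
)


def brute_force_candidates(records, ulk1="ULK1", ampk="AMPK"):
    """Independent oracle: exhaustive scan over all protein pairs."""
    proteins = sorted({r.source for r in records} | {r.target for r in records})
    out = []
    for p in proteins:
        if p in (ulk1, ampk):
            continue
        first = any(r.source == ulk1 and r.target == p and r.sign == "stimulation"
                    for r in records)
        second = any(r.source == p and r.target == ampk and r.sign == "stimulation"
                     for r in records)
        if first and second:
            out.append(p)
    return out


class TestLoadInteractions:
    def test_header_only_file_gives_empty_list(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("source\ttarget\tsign\tlayer\n")
        records, errors = load_interactions(f)
        assert records == [] and errors == []

    def test_sign_case_folded(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("source\ttarget\tsign\tlayer\nULK1\tX\tStimulation\tCore\n")
        records, _ = load_interactions(f)
        assert records[0].sign == "stimulation"
        assert records[0].layer == "core"

    def test_missing_column_named_in_error(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("source\ttarget\tsign\nA\tB\tstimulation\n")
        with pytest.raises(FormatError, match="layer"):
            load_interactions(f)

    def test_malformed_rows_collected_not_fatal(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("source\ttarget\tsign\tlayer\n"
                     "ULK1\tX\tstimulation\tcore\n"
                     "ULK1\tY\tbogus\tcore\n")
        records, errors = load_interactions(f)
        assert len(records) == 1 and len(errors) == 1

    @pytest.mark.parametrize("suffix", [".tsv", ".csv"])
    def test_round_trip_lossless(self, tmp_path, suffix):
        records, _ = generate_synthetic_network(n_proteins=20, n_planted=4,
                                                n_decoys=50, seed=9)
        f = tmp_path / ("t" + suffix)
        write_interactions(records, f)
        back, errors = load_interactions(f)
        assert errors == []
        assert back == records


class TestFilterCandidates:
    def test_empty_input_empty_report(self):
        assert filter_candidates([]).candidates == []

    def test_sign_criterion_excludes_inhibition(self):
        records = [
            InteractionRecord("ULK1", "X", "stimulation", "core"),
            InteractionRecord("X", "AMPK", "stimulation", "direct"),
            InteractionRecord("ULK1", "Y", "stimulation", "core"),
            InteractionRecord("Y", "AMPK", "inhibition", "core"),
        ]
        assert filter_candidates(records).candidates == ["X"]

    def test_unknown_sign_never_qualifies(self):
        records = [
            InteractionRecord("ULK1", "X", "unknown", "core"),
            InteractionRecord("X", "AMPK", "stimulation", "core"),
        ]
        assert filter_candidates(records).candidates == []

    def test_anchors_excluded_from_candidacy(self):
        records = [
            InteractionRecord("ULK1", "AMPK", "stimulation", "core"),
            InteractionRecord("AMPK", "AMPK", "stimulation", "core"),
        ]
        assert filter_candidates(records).candidates == []

    def test_planted_candidates_recovered_exactly(self):
        records, truth = generate_synthetic_network(n_proteins=80, n_planted=8,
                                                    n_decoys=500, seed=21)
        report = filter_candidates(records)
        assert report.candidates == sorted(truth)
        assert report.candidates == brute_force_candidates(records)

    def test_alias_symbols(self):
        records = [
            InteractionRecord("ULK2", "X", "stimulation", "core"),
            InteractionRecord("X", "PRKAA1", "stimulation", "core"),
        ]
        report = filter_candidates(records, ulk1_symbol="ULK2",
                                   ampk_symbol="PRKAA1")
        assert report.candidates == ["X"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 99))
    def test_pure_set_operation(self, seed, shuffle_seed):
        """Shuffling or duplicating rows never changes the candidate set."""
        records, _ = generate_synthetic_network(n_proteins=15, n_planted=3,
                                                n_decoys=40, seed=seed % 1000)
        base = filter_candidates(records).candidates
        shuffled = list(records)
        random.Random(shuffle_seed).shuffle(shuffled)
        assert filter_candidates(shuffled + shuffled[:7]).candidates == base


class TestGenerator:
    def test_zero_planted_filter_empty(self):
        records, truth = generate_synthetic_network(n_planted=0, seed=4)
        assert truth == set()
        assert filter_candidates(records).candidates == []

    def test_deterministic_given_seed(self):
        a, ta = generate_synthetic_network(seed=77)
        b, tb = generate_synthetic_network(seed=77)
        assert a == b and ta == tb

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_network(n_proteins=3, n_planted=5)
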