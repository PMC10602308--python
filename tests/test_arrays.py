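"""Probe/relation/lead table I/O: parsing, validation and round trips."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosphowalk.arrays import (
    KAM_1325,
    AntibodyProbe,
    KSRelation,
    ProbeMeasurement,
    is_valid_site,
    lead_table,
    read_ks_relations,
    read_probe_table,
    write_lead_table,
    write_probe_table,
)
from phosphowalk.errors import FormatError, TableValidationError

from conftest import chain


PROBE_HEADER = (
    "probe_id\ttarget\tsite\ttreated_signal\ttreated_error\tcontrol_signal\tcontrol_error\n"
)


def write_probe_text(path, rows):
    path.write_text(PROBE_HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))


class TestProbeTable:
    def test_reads_rows_in_file_order(self, tmp_path):
        p = tmp_path / "probes.tsv"
        write_probe_text(
            p,
            [
                ("a", "AKT", "S473", 1500, 10, 1000, 10),
                ("b", "SRC", "pan", 2000, 20, 2000, 20),
                ("c", "CDK1", "Y15", 900, 5, 1100, 5),
            ],
        )
        ms = read_probe_table(p, KAM_1325)
        assert [m.probe.probe_id for m in ms] == ["a", "b", "c"]
        assert ms[0].treated_signal == 1500
        assert ms[1].probe.is_pan
        assert all(m.cfc_percent is None for m in ms)

    def test_invalid_site_residue_rejected(self, tmp_path):
        p = tmp_path / "probes.tsv"
        write_probe_text(p, [("a", "AKT", "X99", 1500, 10, 1000, 10)])
        with pytest.raises(TableValidationError, match="X99"):
            read_probe_table(p, KAM_1325)

    def test_duplicate_probe_id_rejected_with_row(self, tmp_path):
        p = tmp_path / "probes.tsv"
        write_probe_text(
            p,
            [("a", "AKT", "S473", 1500, 10, 1000, 10), ("a", "SRC", "Y419", 1, 1, 1, 1)],
        )
        with pytest.raises(TableValidationError, match="row 2"):
            read_probe_table(p, KAM_1325)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "probes.tsv"
        p.write_text("probe_id\ttarget\tsite\ttreated_signal\n" "a\tAKT\tS473\t1\n")
        with pytest.raises(FormatError, match="control_signal"):
            read_probe_table(p, KAM_1325)

    def test_negative_signal_rejected(self, tmp_path):
        p = tmp_path / "probes.tsv"
        write_probe_text(p, [("a", "AKT", "S473", -5, 10, 1000, 10)])
        with pytest.raises(TableValidationError, match="row 1"):
            read_probe_table(p, KAM_1325)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(42)
        ms = [
            ProbeMeasurement(
                AntibodyProbe(f"p{i:02d}", f"G{i:03d}", "pan" if i % 5 == 0 else f"S{i + 1}"),
                float(np.round(rng.uniform(0, 5000), 3)),
                float(np.round(rng.uniform(0, 300), 3)),
                float(np.round(rng.uniform(1, 5000), 3)),
                float(np.round(rng.uniform(0, 300), 3)),
            )
            for i in range(20)
        ]
        path = tmp_path / "round.tsv"
        write_probe_table(ms, path)
        back = read_probe_table(path, KAM_1325)
        assert len(back) == 20
        for a, b in zip(ms, back):
            assert a.probe.probe_id == b.probe.probe_id
            assert a.probe.site == b.probe.site
            assert a.treated_signal == pytest.approx(b.treated_signal)
            assert a.control_error == pytest.approx(b.control_error)

    def test_alias_canonicalisation(self, tmp_path):
        p = tmp_path / "probes.tsv"
        write_probe_text(p, [("a", "bcl2", "S75", 1500, 10, 1000, 10)])
        ms = read_probe_table(p, KAM_1325, aliases={"BCL2": "BAD"})
        assert ms[0].probe.target_symbol == "BAD"


class TestRelationTable:
    def test_four_column_parse(self, tmp_path):
        p = tmp_path / "rel.tsv"
        p.write_text(
            "kinase\tsubstrate\tsite\teffect\n"
            "PDK1\tAKT\tS473\tactivation\n"
            "AKT\tBAD\tS75\tinhibition\n"
            "X\tY\tS1\tunknown\n"
        )
        rels = read_ks_relations(p)
        assert rels[0] == KSRelation("PDK1", "AKT", "S473", "activation")
        assert rels[1].effect == "inhibition"
        assert rels[2].effect == "unknown"

    def test_sif_like_three_column_parse(self, tmp_path):
        p = tmp_path / "rel.tsv"
        p.write_text("kinase\teffect\tsubstrate\nSRC\tactivation\tAKT@Y326\n")
        (rel,) = read_ks_relations(p)
        assert rel == KSRelation("SRC", "AKT", "Y326", "activation")

    def test_header_only_gives_empty(self, tmp_path):
        p = tmp_path / "rel.tsv"
        p.write_text("kinase\tsubstrate\tsite\teffect\n")
        assert read_ks_relations(p) == []

    def test_unknown_effect_token_rejected(self, tmp_path):
        p = tmp_path / "rel.tsv"
        p.write_text("kinase\tsubstrate\tsite\teffect\nA\tB\tS1\tboosts\n")
        with pytest.raises(FormatError, match="boosts"):
            read_ks_relations(p)

    def test_duplicate_relation_rejected(self, tmp_path):
        p = tmp_path / "rel.tsv"
        p.write_text(
            "kinase\tsubstrate\tsite\teffect\nA\tB\tS1\tactivation\nA\tB\tS1\tinhibition\n"
        )
        with pytest.raises(TableValidationError, match="duplicate"):
            read_ks_relations(p)


class TestLeadTable:
    def test_shared_site_counted_once_per_chain(self, tmp_path):
        c1 = chain(
            [("PDK1", "AKT", "S473", "activation"), ("AKT", "EZR", "T567", "activation")],
            [25.0, 15.0],
        )
        c2 = chain(
            [("MAPK14", "AKT", "S473", "activation"), ("AKT", "BAD", "S75", "inhibition")],
            [25.0, 15.0],
        )
        frame = lead_table([c1, c2])
        akt = frame[(frame.target == "AKT") & (frame.site == "S473")]
        assert len(akt) == 1
        assert int(akt.n_chains.iloc[0]) == 2

    def test_empty_chain_set_writes_header_only(self, tmp_path):
        path = tmp_path / "leads.tsv"
        write_lead_table([], path)
        assert path.read_text().strip() == "target\tsite\tdirection\tcfc_percent\tn_chains"

    def test_unmeasured_edges_do_not_become_leads(self):
        c = chain(
            [("A", "B", "S1", "activation"), ("B", "C", "S2", "activation")],
            [25.0, None],
        )
        frame = lead_table([c])
        assert list(frame.target) == ["B"]


class TestSiteGrammar:
    @given(
        residue=st.sampled_from("STY"),
        position=st.integers(min_value=1, max_value=99999),
    )
    @settings(max_examples=50, derandomize=True)
    def test_valid_sites_accepted(self, residue, position):
        assert is_valid_site(f"{residue}{position}")

    @pytest.mark.parametrize(
        "bad", ["X99", "S0", "S-3", "s473", "pan2", "", "S", "473", "SS12", "S1.5"]
    )
    def test_invalid_sites_rejected(self, bad):
        assert not is_valid_site(bad)

    def test_pan_sentinel_accepted(self):
        assert is_valid_site("pan")
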