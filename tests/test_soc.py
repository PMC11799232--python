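"""PT -> SOC mapping, signal aggregation by organ class, SOC-level ROR."""

from __future__ import annotations

import pytest

from pvsignal.contingency import build_contingency
from pvsignal.soc import SocMap, SocMapError, load_soc_map, soc_aggregate, soc_level_ror
from pvsignal.stats import signal_stats

from conftest import make_record


def write_map(tmp_path, text, name="map.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLoadSocMap:
    def test_three_row_file(self, tmp_path):
        path = write_map(tmp_path, "pt,soc\nptA,Eye disorders\nptB,Cardiac disorders\nptC,Investigations\n")
        soc_map = load_soc_map(path)
        assert len(soc_map) == 3
        assert soc_map.soc_of("PTA") == "Eye disorders"  # case-insensitive

    def test_duplicate_identical_rows_collapsed(self, tmp_path):
        path = write_map(tmp_path, "pt,soc\nptA,Eye disorders\nptA,Eye disorders\n")
        assert len(load_soc_map(path)) == 1

    def test_conflicting_duplicate_is_fatal_citing_lines(self, tmp_path):
        path = write_map(tmp_path, "pt,soc\nptA,Eye disorders\nptA,Cardiac disorders\n")
        with pytest.raises(SocMapError, match=r"line 2.*line 3"):
            load_soc_map(path)

    def test_non_primary_rows_ignored(self, tmp_path):
        path = write_map(
            tmp_path,
            "pt,soc,is_primary\nptA,Eye disorders,true\nptA,Investigations,false\n",
        )
        soc_map = load_soc_map(path)
        assert soc_map.soc_of("ptA") == "Eye disorders"

    def test_unknown_soc_label_warns_or_raises(self, tmp_path, caplog):
        path = write_map(tmp_path, "pt,soc\nptA,Imaginary disorders\n")
        with caplog.at_level("WARNING", logger="pvsignal"):
            load_soc_map(path)
        assert any("27 MedDRA" in m for m in caplog.messages)
        with pytest.raises(SocMapError):
            load_soc_map(path, strict_socs=True)


def _signal(drug, pt):
    # strongly associated small table: a=5, b=5, c=5, d=500
    from pvsignal.contingency import ContingencyTable

    return signal_stats(ContingencyTable(drug=drug, event=pt, a=5, b=5, c=5, d=500))


class TestSocAggregate:
    MAP = SocMap(entries={"pt1": "Eye disorders", "pt2": "Eye disorders",
                          "pt3": "Cardiac disorders", "pt4": "Cardiac disorders"})

    def test_even_split(self):
        signals = [_signal("d", p) for p in ("pt1", "pt2", "pt3", "pt4")]
        dist = soc_aggregate(signals, self.MAP)
        assert dist.soc_counts == {"Eye disorders": 2, "Cardiac disorders": 2}
        assert dist.soc_percent["Eye disorders"] == pytest.approx(50.0)

    def test_unmapped_bucket_with_warning(self, caplog):
        signals = [_signal("d", p) for p in ("pt1", "pt2", "pt3", "mystery pt")]
        with caplog.at_level("WARNING", logger="pvsignal"):
            dist = soc_aggregate(signals, self.MAP)
        assert dist.soc_counts["Unmapped"] == 1
        assert dist.soc_percent["Unmapped"] == pytest.approx(25.0)
        assert any("mystery pt" in m for m in caplog.messages)

    def test_counts_sum_to_signal_count_and_percent_to_100(self):
        signals = [_signal("d", p) for p in ("pt1", "pt2", "pt3", "pt4", "zzz")]
        dist = soc_aggregate(signals, self.MAP)
        assert dist.total_signals == 5
        assert sum(dist.soc_percent.values()) == pytest.approx(100.0, abs=0.05)

    def test_invariant_under_permutation(self):
        signals = [_signal("d", p) for p in ("pt1", "pt3", "pt2", "pt4")]
        assert soc_aggregate(signals, self.MAP) == soc_aggregate(signals[::-1], self.MAP)

    def test_empty_signal_set(self):
        dist = soc_aggregate([], self.MAP)
        assert dist.total_signals == 0
        assert dist.soc_percent == {}

    def test_mixed_drugs_rejected(self):
        with pytest.raises(ValueError):
            soc_aggregate([_signal("d1", "pt1"), _signal("d2", "pt2")], self.MAP)


class TestSocLevelRor:
    MAP = SocMap(entries={"pt1": "Eye disorders", "pt2": "Eye disorders",
                          "pt3": "Cardiac disorders"})

    def _records(self):
        recs = []
        for i in range(4):
            recs.append(make_record(f"a{i}", drug="drugx", role="PS", pt="pt1"))
        recs.append(make_record("a4", drug="drugx", role="PS", pt="pt2"))
        # one case carrying BOTH member PTs (union must count it once)
        recs.append(make_record("a5", drug="drugx", role="PS", pt="pt1"))
        recs.append(make_record("a5", drug="drugx", role="PS", pt="pt2"))
        recs.append(make_record("a6", drug="drugx", role="PS", pt="pt3"))
        for i in range(6):
            recs.append(make_record(f"b{i}", drug="drugz", role="PS", pt="pt3"))
        recs.append(make_record("b6", drug="drugz", role="PS", pt="pt1"))
        return recs

    def test_single_pt_soc_reduces_to_pt_level(self):
        recs = self._records()
        soc_stats = soc_level_ror(recs, "drugz", "Cardiac disorders", self.MAP)
        pt_stats = signal_stats(build_contingency(recs, "drugz", "pt3"))
        assert soc_stats.a == pt_stats.a
        assert soc_stats.ror == pt_stats.ror

    def test_union_counting_for_multi_pt_soc(self):
        recs = self._records()
        soc_stats = soc_level_ror(recs, "drugx", "Eye disorders", self.MAP)
        a1 = build_contingency(recs, "drugx", "pt1").a
        a2 = build_contingency(recs, "drugx", "pt2").a
        # brute-force union over cases
        union = {r.case_id for r in recs if r.drug_name == "drugx" and r.role == "PS"
                 and any(x.pt in ("pt1", "pt2") and x.case_id == r.case_id for x in recs)}
        assert soc_stats.a == len(union) == 6
        assert soc_stats.a <= a1 + a2  # union bound (strict here: case a5 overlaps)
        assert soc_stats.a < a1 + a2

    def test_unknown_soc_is_an_error(self):
        with pytest.raises(KeyError):
            soc_level_ror(self._records(), "drugx", "Hepatobiliary disorders", self.MAP)

    def test_drug_without_reports_propagates_contingency_error(self):
        with pytest.raises(ValueError):
            soc_level_ror([], "drugx", "Eye disorders", self.MAP)
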