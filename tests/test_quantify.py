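"""Read parsing, UMI deduplication, abundance and false-positive estimates."""

import math
import random

import numpy as np
import pandas as pd
import pytest

from mipfit import io as mio
from mipfit import simulate as sim
from mipfit.quantify import (
    ALT,
    OTHER,
    REF,
    CaptureEvent,
    FprEstimate,
    ReadLayout,
    dedup_umis,
    detection_limit,
    estimate_fpr,
    library_qc,
    parse_reads,
    probe_abundance,
    strain_abundance,
)


@pytest.fixture(scope="module")
def panel_df(toy_panels):
    return mio.panel_frame_for_quantify(toy_panels)


def _read_for(probe, call, umi="AAAACCCC"):
    gap = list(probe.gap_fill_seq)
    if call == ALT:
        gap[probe.snv_offset] = probe.target.alt_allele
    elif call == OTHER:
        candidates = set("ACGT") - {probe.target.ref_allele, probe.target.alt_allele}
        gap[probe.snv_offset] = sorted(candidates)[0]
    return (f"r:{umi}", probe.ext_arm_seq + "".join(gap) + probe.lig_arm_seq)


class TestParseReads:
    def test_alt_read_assigned_with_umi(self, toy_panels, panel_df):
        probe = toy_panels["S001"].probes[0]
        events, stats = parse_reads([_read_for(probe, ALT, "ACGTACGT")], panel_df)
        assert events == [CaptureEvent(probe.probe_id, "ACGTACGT", ALT)]
        assert stats["assigned"] == 1

    @pytest.mark.parametrize("call", [REF, OTHER])
    def test_ref_and_other_calls(self, toy_panels, panel_df, call):
        probe = toy_panels["S002"].probes[1]
        events, _ = parse_reads([_read_for(probe, call)], panel_df)
        assert events[0].allele_call == call

    def test_mutated_arms_unassigned(self, toy_panels, panel_df):
        probe = toy_panels["S001"].probes[0]
        name, seq = _read_for(probe, ALT)
        bad = "AAAA" + seq[4:-4] + "TTTT"  # both arms broken beyond tolerance
        events, stats = parse_reads([(name, bad)], panel_df)
        assert events == [] and stats["unassigned"] == 1

    def test_one_mismatch_tolerated_when_configured(self, toy_panels, panel_df):
        probe = toy_panels["S001"].probes[0]
        name, seq = _read_for(probe, ALT)
        flip = "A" if seq[0] != "A" else "C"
        mutated = flip + seq[1:]
        assert parse_reads([(name, mutated)], panel_df)[0] == []
        events, _ = parse_reads([(name, mutated)], panel_df,
                                ReadLayout(arm_match_max_mismatch=1))
        assert len(events) == 1

    def test_ambiguous_read_dropped(self, toy_panels, panel_df):
        # duplicate a probe row under a second id: its reads match both
        probe = toy_panels["S001"].probes[0]
        dup = panel_df[panel_df.probe_id == probe.probe_id].assign(probe_id="dup")
        both = pd.concat([panel_df, dup], ignore_index=True)
        events, stats = parse_reads([_read_for(probe, ALT)], both)
        assert events == [] and stats["ambiguous"] == 1

    def test_truncated_read_dropped(self, toy_panels, panel_df):
        probe = toy_panels["S001"].probes[0]
        name, seq = _read_for(probe, ALT)
        events, stats = parse_reads([(name, seq[:30])], panel_df)
        assert events == [] and stats["truncated"] == 1

    def test_inline_umi_layout(self, toy_panels, panel_df):
        probe = toy_panels["S001"].probes[0]
        _, seq = _read_for(probe, ALT)
        layout = ReadLayout(umi_len=6, umi_source="inline")
        events, _ = parse_reads([("r1", seq + "GGGTTT")], panel_df, layout)
        assert events[0].umi == "GGGTTT"

    def test_fastq_file_input(self, toy_panels, panel_df, tmp_path):
        probe = toy_panels["S001"].probes[0]
        name, seq = _read_for(probe, ALT, "ACACACAC")
        fq = tmp_path / "reads.fastq"
        fq.write_text(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
        events, _ = parse_reads(fq, panel_df)
        assert events == [CaptureEvent(probe.probe_id, "ACACACAC", ALT)]


class TestDedupUmis:
    def test_duplicate_umi_collapses(self):
        events = [CaptureEvent("P", "u1", ALT), CaptureEvent("P", "u1", ALT),
                  CaptureEvent("P", "u2", REF)]
        row = dedup_umis(events).iloc[0]
        assert (row.alt_umis, row.ref_umis, row.total_umis) == (1, 1, 2)

    def test_conflicting_umi_tie_discarded(self):
        events = [CaptureEvent("P", "u1", ALT), CaptureEvent("P", "u1", REF)]
        row = dedup_umis(events).iloc[0]
        assert (row.alt_umis, row.ref_umis, row.total_umis, row.discarded_ties) == (0, 0, 0, 1)

    def test_conflicting_umi_majority_wins(self):
        events = [CaptureEvent("P", "u1", ALT)] * 2 + [CaptureEvent("P", "u1", REF)]
        row = dedup_umis(events).iloc[0]
        assert (row.alt_umis, row.ref_umis) == (1, 0)

    def test_all_distinct_umis_counted(self):
        events = [CaptureEvent("P", f"u{i}", ALT) for i in range(1000)]
        assert dedup_umis(events).iloc[0].alt_umis == 1000

    def test_invariant_under_read_order(self):
        rng = random.Random(42)
        events = ([CaptureEvent("P", f"u{i}", ALT) for i in range(30)]
                  + [CaptureEvent("P", f"u{i}", REF) for i in range(10, 50)]
                  + [CaptureEvent("Q", f"u{i}", OTHER) for i in range(5)])
        base = dedup_umis(events)
        for _ in range(5):
            rng.shuffle(events)
            pd.testing.assert_frame_equal(dedup_umis(events), base)

    def test_conservation(self):
        rng = random.Random(0)
        events = [CaptureEvent(f"P{rng.randrange(3)}", f"u{rng.randrange(40)}",
                               rng.choice([ALT, REF, OTHER])) for _ in range(300)]
        df = dedup_umis(events)
        assert (df.alt_umis + df.ref_umis + df.other_umis == df.total_umis).all()


class TestProbeAbundance:
    @pytest.mark.parametrize("alt,ref,expected",
                             [(2, 98, 0.02), (0, 500, 0.0), (5, 0, 1.0)])
    def test_fraction(self, alt, ref, expected):
        assert probe_abundance(alt, ref) == pytest.approx(expected)

    def test_no_diagnostic_events_is_nan(self):
        assert math.isnan(probe_abundance(0, 0))


def _counts(lib, totals):
    return pd.DataFrame(
        [(lib, f"P{i}", 0, t, 0, t, 0) for i, t in enumerate(totals)],
        columns=["library_id", "probe_id", "alt_umis", "ref_umis", "other_umis",
                 "total_umis", "discarded_ties"])


class TestLibraryQc:
    def test_single_library_threshold(self):
        # mean 787.5, threshold 157.5: only the 150-UMI probe falls below
        retained, flags = library_qc(_counts("L1", [1000, 900, 1100, 150]))
        assert retained == {"P0", "P1", "P2"}
        assert flags.loc["P3", "L1"]

    def test_flagged_in_one_of_three_libraries_retained(self):
        counts = pd.concat([_counts("L1", [1000, 900, 1100, 150]),
                            _counts("L2", [1000, 900, 1100, 950]),
                            _counts("L3", [1000, 900, 1100, 1050])],
                           ignore_index=True)
        retained, flags = library_qc(counts)
        assert retained == {"P0", "P1", "P2", "P3"}
        assert flags.loc["P3"].sum() == 1

    def test_equal_depth_keeps_all(self):
        retained, _ = library_qc(_counts("L1", [500] * 6))
        assert len(retained) == 6

    def test_consistently_low_probe_removed(self):
        counts = pd.concat([_counts("L1", [1000, 900, 1100, 10]),
                            _counts("L2", [1000, 900, 1100, 20])],
                           ignore_index=True)
        retained, _ = library_qc(counts)
        assert retained == {"P0", "P1", "P2"}


class TestStrainAbundance:
    def _table(self, fracs, lib="L1"):
        rows = []
        for i, f in enumerate(fracs):
            alt = int(round(f * 1000))
            rows.append((lib, f"P{i}", alt, 1000 - alt, 0, 1000, 0))
        return pd.DataFrame(rows, columns=["library_id", "probe_id", "alt_umis",
                                           "ref_umis", "other_umis", "total_umis",
                                           "discarded_ties"])

    def test_equal_probes_zero_sd(self):
        df = strain_abundance(self._table([0.02] * 4), {f"P{i}": "s" for i in range(4)})
        row = df.iloc[0]
        assert row.mean_abundance == pytest.approx(0.02)
        assert row.sd_abundance == 0

    def test_sample_sd_by_hand(self):
        df = strain_abundance(self._table([0.01, 0.02, 0.03, 0.04]),
                              {f"P{i}": "s" for i in range(4)})
        row = df.iloc[0]
        assert row.mean_abundance == pytest.approx(0.025)
        assert row.sd_abundance == pytest.approx(0.012909944, abs=1e-6)

    def test_single_probe_sd_zero_with_flag(self):
        df = strain_abundance(self._table([0.3]), {"P0": "s"})
        row = df.iloc[0]
        assert (row.mean_abundance, row.sd_abundance) == (pytest.approx(0.3), 0.0)
        assert not row.sd_defined

    def test_strain_with_no_usable_probe_missing(self):
        table = self._table([0.02])
        table.loc[0, ["alt_umis", "ref_umis", "total_umis"]] = 0
        df = strain_abundance(table, {"P0": "s"})
        assert df.empty

    def test_qc_filter_respected(self):
        df = strain_abundance(self._table([0.1, 0.5]),
                              {"P0": "s", "P1": "s"}, retained={"P0"})
        assert df.iloc[0].mean_abundance == pytest.approx(0.1)
        assert df.iloc[0].n_probes_used == 1

    def test_mean_bounded_by_probe_range(self):
        rng = np.random.default_rng(9)
        fracs = rng.uniform(0, 1, size=6)
        df = strain_abundance(self._table(list(fracs)),
                              {f"P{i}": "s" for i in range(6)})
        assert fracs.min() <= df.iloc[0].mean_abundance <= fracs.max()


class TestFpr:
    def _table(self, alt_list, total=5000, lib="L1"):
        rows = [(lib, f"A{i}", a, total - a, 0, total, 0)
                for i, a in enumerate(alt_list)]
        return pd.DataFrame(rows, columns=["library_id", "probe_id", "alt_umis",
                                           "ref_umis", "other_umis", "total_umis",
                                           "discarded_ties"])

    def test_pooled_rate(self):
        counts = self._table([1, 2, 0, 0])  # 3 false ALT among 20,000 events
        est = estimate_fpr(counts, {f"A{i}": "absent" for i in range(4)},
                           {"L1": {"absent"}})
        assert est.per_event_rate == pytest.approx(1.5e-4)
        assert est.n_events == 20_000

    def test_zero_false_events(self):
        est = estimate_fpr(self._table([0, 0]), {"A0": "x", "A1": "x"}, {"L1": {"x"}})
        assert est.per_event_rate == 0.0

    def test_no_absent_strains_errors(self):
        with pytest.raises(ValueError, match="absent"):
            estimate_fpr(self._table([1]), {"A0": "x"}, {})

    def test_present_strain_probes_excluded(self):
        counts = pd.concat([self._table([5]),
                            self._table([500], lib="L1").assign(probe_id="B0")],
                           ignore_index=True)
        est = estimate_fpr(counts, {"A0": "absent", "B0": "present"}, {"L1": {"absent"}})
        assert est.n_events == 5000

    def test_recovers_injected_rate(self, toy_panels):
        # simulation oracle: an absent strain's ALT events are all miscalls
        cfg = sim.SimConfig(strains=[sim.SimStrain("S001", 1.0, 0)],
                            probe_depth_mean=50_000, probe_efficiency_sigma=0.0,
                            per_event_fpr=1.3e-4, rng_seed=5)
        counts = sim.simulate_counts({"S001": 0.0}, {"S001": toy_panels["S001"]},
                                     cfg, library_id="L1")
        p2s = {p.probe_id: "S001" for p in toy_panels["S001"].probes}
        est = estimate_fpr(counts, p2s, {"L1": {"S001"}})
        n = counts.total_umis.sum()
        ci = 1.96 * math.sqrt(1.3e-4 * (1 - 1.3e-4) / n)
        assert abs(est.per_event_rate - 1.3e-4) < ci


class TestDetectionLimit:
    def test_published_style_values(self):
        est = FprEstimate(1.25e-4, 1.29e-4, 1.38e-4, k_sd=5)
        assert detection_limit(est) == pytest.approx(8.19e-4)

    def test_degenerate_zero(self):
        assert detection_limit(FprEstimate(0, 0, 0)) == 0

    def test_arithmetic(self):
        assert detection_limit(FprEstimate(1e-4, 1e-4, 2e-4)) == pytest.approx(1.1e-3)
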