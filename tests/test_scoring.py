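"""Fragment enumeration, interaction scores, signature tables."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from protopep import (
    build_screen_dataset,
    build_signature_table,
    composition_trend,
    displacement_analysis,
    enumerate_fragments,
    enumerate_library,
    layout_array,
    preset_paperlike,
    score_fragments,
    simulate_screen,
)
from protopep.simulate import PlantedEffect, SimConfig


def brute_force_scores(spots, channel, k_min, k_max, min_support=3):
    """Independent oracle: double loop over peptides and fragments."""
    signals: dict[str, list[float]] = {}
    sel = spots[spots["channel"] == channel]
    for peptide, group in sel.groupby("peptide"):
        values = list(group["intensity"])
        for frag in enumerate_fragments(peptide, k_min, min(k_max, len(peptide))):
            signals.setdefault(frag, []).extend(values)
    out = {}
    for frag, vals in signals.items():
        if len(vals) < min_support:
            continue
        sd = statistics.stdev(vals)
        if sd == 0:
            continue
        out[frag] = (len(vals), statistics.fmean(vals), sd, statistics.fmean(vals) / sd)
    return out


class TestEnumerateFragments:
    def test_aecd_reference_set(self):
        assert enumerate_fragments("AECD", 1, 4) == {
            "A", "E", "C", "D", "AE", "EC", "CD", "AEC", "ECD", "AECD",
        }

    def test_duplicates_collapse_and_sub_ranges(self):
        assert enumerate_fragments("PPP", 1, 3) == {"P", "PP", "PPP"}
        assert enumerate_fragments("AECD", 3, 3) == {"AEC", "ECD"}

    @pytest.mark.parametrize("k_min, k_max", [(0, 3), (3, 2), (2, 9)])
    def test_invalid_ranges(self, k_min, k_max):
        with pytest.raises(ValueError, match="invalid k range"):
            enumerate_fragments("AECD", k_min, k_max)

    @given(st.text(alphabet="GPAR", min_size=1, max_size=10))
    def test_fragment_count_bound(self, seq):
        n = len(enumerate_fragments(seq, 1, len(seq)))
        L = len(seq)
        assert n <= L * (L + 1) // 2


class TestScoreFragments:
    def test_mean_sd_ratio_arithmetic(self):
        lib = enumerate_library(("A", "E"), 2, "toy", copies=1)
        design = layout_array([lib], seed=0)
        spots = design.spots
        intensity = {"AA": 10.0, "AE": 20.0, "EA": 30.0, "EE": 5.0}
        table = pd.DataFrame(
            {
                "spot_id": spots["spot_id"],
                "channel": "C12",
                "intensity": spots["peptide"].map(intensity),
            }
        )
        ds = build_screen_dataset(design, table)
        scores, _ = score_fragments(ds, "C12", k_min=1, k_max=1, min_support=3)
        a_row = scores[scores["fragment"] == "A"].iloc[0]
        # 'A' occurs in AA, AE, EA -> signals {10, 20, 30}
        assert a_row["support"] == 3
        assert a_row["mean"] == 20.0
        assert a_row["sd"] == pytest.approx(10.0)
        assert a_row["R"] == pytest.approx(2.0)

    def test_constant_signals_are_gated_not_infinite(self, small_gc_screen):
        import dataclasses

        constant = dataclasses.replace(small_gc_screen)
        constant.spots = small_gc_screen.spots.assign(intensity=5.0)
        scores, gated = score_fragments(constant, "C12")
        assert scores.empty
        assert (gated["reason"] == "sd == 0").any()
        assert np.isfinite(scores["R"]).all()

    def test_low_support_gated(self, small_gc_screen):
        scores, gated = score_fragments(small_gc_screen, "C12", min_support=3)
        # full 4-mer fragments have exactly 2 replicate signals
        assert set(gated.loc[gated["reason"] == "support < 3", "length"]) == {4}
        assert (scores["support"] >= 3).all()

    def test_matches_brute_force_oracle(self, small_gc_screen):
        scores, _ = score_fragments(small_gc_screen, "C12", k_min=3, min_support=3)
        oracle = brute_force_scores(small_gc_screen.spots, "C12", 3, 4)
        assert set(scores["fragment"]) == set(oracle)
        for row in scores.itertuples():
            n, mean, sd, r = oracle[row.fragment]
            assert row.support == n
            assert row.mean == pytest.approx(mean, abs=1e-9)
            assert row.sd == pytest.approx(sd, abs=1e-9)
            assert row.R == pytest.approx(r, abs=1e-9)

    def test_scale_invariance_and_offset_sensitivity(self, small_gc_screen):
        import dataclasses

        scores, _ = score_fragments(small_gc_screen, "C12")
        scaled = dataclasses.replace(
            small_gc_screen, spots=small_gc_screen.spots.assign(
                intensity=small_gc_screen.spots["intensity"] * 7.3
            )
        )
        scores_scaled, _ = score_fragments(scaled, "C12")
        merged = scores.merge(scores_scaled, on="fragment", suffixes=("", "_s"))
        np.testing.assert_allclose(merged["R"], merged["R_s"], rtol=1e-12)

        offset = dataclasses.replace(
            small_gc_screen, spots=small_gc_screen.spots.assign(
                intensity=small_gc_screen.spots["intensity"] + 50.0
            )
        )
        scores_off, _ = score_fragments(offset, "C12")
        merged = scores.merge(scores_off, on="fragment", suffixes=("", "_o"))
        assert not np.allclose(merged["R"], merged["R_o"], rtol=1e-6)

    def test_errors(self, small_gc_screen):
        with pytest.raises(ValueError, match="channel"):
            score_fragments(small_gc_screen, "A12")
        with pytest.raises(ValueError, match="library"):
            score_fragments(small_gc_screen, "C12", library_id="nope")


class TestSignatureTable:
    @pytest.fixture
    def scores(self):
        return pd.DataFrame(
            {
                "fragment": ["PPP", "GAR", "PPPA", "GARP", "PPPAG"],
                "length": [3, 3, 4, 4, 5],
                "support": [10] * 5,
                "mean": [10.0] * 5,
                "sd": [2.0, 5.0, 1.0, 4.0, 1.0],
                "R": [5.0, 2.0, 10.0, 2.5, 10.0],
            }
        )

    def test_cumulative_columns(self, scores):
        table = build_signature_table(scores, top_n=3)
        assert table.lengths == [3, 4, 5]
        assert [table.label(n) for n in table.lengths] == ["3mer", "3-4mer", "3-5mer"]
        assert list(table.columns[3]["fragment"]) == ["PPP", "GAR"]
        # column 4: PPPA (R=10) > PPP (5) > GARP (2.5)
        assert list(table.columns[4]["fragment"]) == ["PPPA", "PPP", "GARP"]
        # column 5: tie R=10 broken longer-first
        assert list(table.columns[5]["fragment"]) == ["PPPAG", "PPPA", "PPP"]

    def test_equal_r_same_length_breaks_lexicographically(self):
        scores = pd.DataFrame(
            {
                "fragment": ["GGG", "AAA"],
                "length": [3, 3],
                "support": [5, 5],
                "mean": [4.0, 4.0],
                "sd": [2.0, 2.0],
                "R": [2.0, 2.0],
            }
        )
        table = build_signature_table(scores, top_n=2)
        assert list(table.columns[3]["fragment"]) == ["AAA", "GGG"]

    def test_displacement_report(self, scores):
        table = build_signature_table(scores, top_n=2)
        report = displacement_analysis(table)
        first = report.iloc[0]
        assert first["displaced"] == ["GAR"]  # pushed out by PPPA
        assert "PPP" in first["retained"]
        # the overall top fragment is never displaced
        tops = [list(table.columns[n]["fragment"]) for n in table.lengths]
        assert all("PPPA" in t for t in tops[1:])

    def test_super_fragments_displace_planted_motif(self):
        """With per-occurrence effects, longer runs of the planted motif bind
        more, so super-fragments push the bare motif down the ranking."""
        lib = enumerate_library(("G", "P", "A", "R"), 5, "GC-dominant", copies=3)
        design = layout_array([lib], seed=4)
        config = SimConfig(
            design=design,
            baselines={"C12": 100.0},
            effects=[PlantedEffect("PP", "C12", 2.0, mode="per_occurrence")],
            sigma=0.1,
            seed=4,
        )
        ds = build_screen_dataset(design, simulate_screen(config))
        scores, _ = score_fragments(ds, "C12", k_min=3)
        table = build_signature_table(scores, top_n=len(scores))
        col3 = list(table.columns[3]["fragment"])
        col5 = list(table.columns[5]["fragment"])
        rank3 = col3.index("PPP")
        rank5 = col5.index("PPP")
        assert rank5 > rank3  # pushed down by entering longer fragments
        # the fragments that outrank PPP include its own super-fragments
        super_above = [f for f in col5[:rank5] if len(f) > 3 and "PPP" in f]
        assert super_above, "no super-fragment of the motif displaced it"

    def test_composition_trend_counts(self):
        scores = pd.DataFrame(
            {
                "fragment": ["FYF", "FY" + "F"],
                "length": [3, 3],
                "support": [5, 5],
                "mean": [4.0, 4.0],
                "sd": [1.0, 2.0],
                "R": [4.0, 2.0],
            }
        )
        scores = pd.DataFrame(
            {
                "fragment": ["FYF", "FYK", "KNKN"],
                "length": [3, 3, 4],
                "support": [5, 5, 5],
                "mean": [4.0] * 3,
                "sd": [1.0, 2.0, 4.0],
                "R": [4.0, 2.0, 1.0],
            }
        )
        table = build_signature_table(scores, top_n=2)
        trend = composition_trend(table, {"F", "Y"})
        assert list(trend["mean_residue_count"]) == [2.5, 2.5]
        zeros = composition_trend(table, set())
        assert (zeros["mean_residue_count"] == 0).all()

    def test_fy_content_grows_with_signature_length(self):
        """Planted saturating F/Y effects make longer top signatures richer
        in F and Y (trend assessed on adequately supported fragments)."""
        config = preset_paperlike("AU", seed=0, channels=["A12"])
        ds = build_screen_dataset(config.design, simulate_screen(config))
        scores, _ = score_fragments(
            ds, "A12", library_id="AU-dominant", min_support=30
        )
        table = build_signature_table(scores, top_n=25)
        trend = composition_trend(table, {"F", "Y"})
        counts = list(trend["mean_residue_count"])
        assert len(counts) >= 2
        assert all(c >= counts[0] for c in counts[1:])
        assert counts[-1] > counts[0]
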