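"""Activity indices: GM, hemolysis normalization, MHC, TI'."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heliamp.activity import (
    ActivitySummary,
    Bound,
    HemolysisCurve,
    MICTable,
    geometric_mean_mic,
    hemolysis_percent,
    mhc,
    pseudo_therapeutic_index,
    summarize_activity,
)


class TestGeometricMean:
    def test_identical_values(self):
        assert geometric_mean_mic([2, 2, 2, 2]) == pytest.approx(2.0)

    def test_w10_gram_positive(self):
        value = geometric_mean_mic([1, 1, 1, 2])
        assert value == pytest.approx(2 ** 0.25)
        assert round(value, 1) == 1.2

    def test_w8_gram_negative(self):
        value = geometric_mean_mic([4, 4, 4, 4, 8])
        assert round(value, 1) == 4.6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_mic([])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_mic([2, 0])

    def test_bound_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_mic([2, Bound(128)])

    @given(
        st.lists(st.floats(0.1, 1000), min_size=1, max_size=12),
        st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance_and_bounds(self, mics, k):
        gm = geometric_mean_mic(mics)
        assert min(mics) <= gm * (1 + 1e-9)
        assert gm <= max(mics) * (1 + 1e-9)
        assert geometric_mean_mic([k * m for m in mics]) == pytest.approx(
            k * gm, rel=1e-9
        )

    def test_log2_domain_exact_on_powers_of_two(self):
        assert geometric_mean_mic([2, 8]) == 4.0
        assert geometric_mean_mic([1, 4, 16, 64]) == 8.0


class TestHemolysisPercent:
    def test_full_lysis(self):
        assert hemolysis_percent(1.05, 0.05, 1.05) == pytest.approx(100.0)

    def test_blank(self):
        assert hemolysis_percent(0.05, 0.05, 1.05) == pytest.approx(0.0)

    def test_half(self):
        assert hemolysis_percent(0.55, 0.05, 1.05) == pytest.approx(50.0)

    def test_degenerate_control(self):
        with pytest.raises(ValueError):
            hemolysis_percent(0.5, 1.0, 1.0)


def curve(points, pid="X"):
    concentrations = sorted(points)
    return HemolysisCurve(
        peptide_id=pid,
        concentrations=concentrations,
        hemolysis_percent=[points[c] for c in concentrations],
    )


class TestMHC:
    def test_never_exceeds(self):
        series = [2.0**i for i in range(8)]
        quiet = HemolysisCurve("q", series, [0.0] * 8)
        result = mhc(quiet)
        assert isinstance(result, Bound)
        assert result.limit == 128
        assert str(result) == ">128"

    def test_first_strict_exceedance(self):
        assert mhc(curve({16: 4.9, 32: 5.1, 64: 40})) == 32

    def test_first_point_exceeds(self):
        assert mhc(curve({1: 6, 2: 80})) == 1

    def test_exactly_threshold_not_counted(self):
        assert isinstance(mhc(curve({8: 5.0})), Bound)

    def test_monotone_in_threshold(self):
        c = curve({1: 1, 2: 3, 4: 6, 8: 12, 16: 30, 32: 70, 64: 95, 128: 99})
        previous = 0.0
        for threshold in (0.5, 2, 5, 10, 25, 60, 90):
            value = mhc(c, threshold)
            numeric = value.limit if isinstance(value, Bound) else value
            assert numeric >= previous
            previous = numeric

    def test_empty_curve(self):
        with pytest.raises(ValueError):
            mhc(HemolysisCurve("e", [], []))


class TestTIPrime:
    def test_w7_gram_positive(self):
        gm = geometric_mean_mic([2, 2, 2, 4])
        ratio, bound = pseudo_therapeutic_index(128, gm)
        assert not bound
        assert round(ratio, 1) == 53.8

    def test_w2_gram_positive(self):
        ratio, _ = pseudo_therapeutic_index(16, geometric_mean_mic([2, 2, 2, 4]))
        assert round(ratio, 1) == 6.7

    def test_uses_unrounded_gm(self):
        # dividing by the rounded GM would give 128/2.4 = 53.3, not 53.8
        assert round(128 / 2.4, 1) != 53.8

    def test_mhc_equals_gm(self):
        assert pseudo_therapeutic_index(2.0, 2.0) == (1.0, False)

    def test_bounded_mhc_gives_lower_bound(self):
        ratio, bound = pseudo_therapeutic_index(Bound(128), 2.0)
        assert bound and ratio == 64.0

    def test_nonpositive_gm(self):
        with pytest.raises(ValueError):
            pseudo_therapeutic_index(128, 0.0)


def tiny_table(values):
    peptides = sorted({p for p, _ in values})
    strains = sorted({s for _, s in values})
    gram = ["positive" if s.startswith("GP") else "negative" for s in strains]
    return MICTable(
        peptide_ids=peptides, strain_ids=strains, gram_labels=gram, mic=dict(values)
    )


class TestSummarize:
    def test_single_cell(self):
        table = MICTable(
            peptide_ids=["P"], strain_ids=["GP1"], gram_labels=["positive"],
            mic={("P", "GP1"): 2.0},
        )
        [summary] = summarize_activity(table, mhc_values={"P": 2.0})
        assert summary.gm_gram_positive == 2.0
        assert summary.ti_prime_positive == 1.0

    def test_three_peptide_spreadsheet_oracle(self):
        cells = {
            ("A", "GP1"): 2.0, ("A", "GP2"): 4.0, ("A", "GN1"): 8.0,
            ("B", "GP1"): 1.0, ("B", "GP2"): 1.0, ("B", "GN1"): 2.0,
            ("C", "GP1"): 16.0, ("C", "GP2"): 4.0, ("C", "GN1"): 4.0,
        }
        table = tiny_table(cells)
        summaries = {s.peptide_id: s for s in summarize_activity(
            table, mhc_values={"A": 64.0, "B": 8.0, "C": Bound(128.0)}
        )}
        # hand-computed: GM+ = sqrt(2*4), sqrt(1), sqrt(64); GM- single values
        assert summaries["A"].gm_gram_positive == pytest.approx(math.sqrt(8))
        assert summaries["A"].gm_gram_negative == pytest.approx(8.0)
        assert summaries["A"].gm_all == pytest.approx((2 * 4 * 8) ** (1 / 3))
        assert summaries["A"].ti_prime_all == pytest.approx(64 / 4.0)
        assert summaries["B"].gm_all == pytest.approx((1 * 1 * 2) ** (1 / 3))
        assert summaries["C"].ti_is_lower_bound
        assert summaries["C"].ti_prime_positive == pytest.approx(128 / 8.0)

    def test_other_strains_never_enter(self, mic_table, mhc_panel):
        # doubling every MRSA ("other") MIC must not change any summary
        doubled = MICTable(
            peptide_ids=mic_table.peptide_ids,
            strain_ids=mic_table.strain_ids,
            gram_labels=mic_table.gram_labels,
            mic={
                key: (v * 2 if mic_table.gram_labels[
                    mic_table.strain_ids.index(key[1])] == "other" else v)
                for key, v in mic_table.mic.items()
            },
        )
        original = summarize_activity(mic_table, mhc_values=mhc_panel)
        altered = summarize_activity(doubled, mhc_values=mhc_panel)
        for a, b in zip(original, altered):
            assert a == b

    def test_unknown_peptide_ids_listed(self, mic_table):
        with pytest.raises(ValueError, match="W99"):
            summarize_activity(mic_table, mhc_values={"W99": 8.0})

    def test_mhc_derived_from_curves(self):
        table = MICTable(
            peptide_ids=["P"], strain_ids=["GP1"], gram_labels=["positive"],
            mic={("P", "GP1"): 2.0},
        )
        c = HemolysisCurve("P", [1, 2, 4, 8], [0, 1, 7, 50])
        [summary] = summarize_activity(table, curves=[c])
        assert summary.mhc == 4
        assert summary.ti_prime_positive == pytest.approx(2.0)


class TestTableValidation:
    def test_missing_cell(self):
        with pytest.raises(ValueError, match="missing MIC cell"):
            MICTable(
                peptide_ids=["A", "B"], strain_ids=["GP1"], gram_labels=["positive"],
                mic={("A", "GP1"): 2.0},
            )

    def test_bad_gram_label(self):
        with pytest.raises(ValueError):
            MICTable(
                peptide_ids=["A"], strain_ids=["GP1"], gram_labels=["gram+"],
                mic={("A", "GP1"): 2.0},
            )

    def test_curve_must_ascend(self):
        with pytest.raises(ValueError):
            HemolysisCurve("X", [4, 2], [1, 2])

    def test_bound_parse(self):
        assert Bound.parse("> 128").limit == 128.0
        with pytest.raises(ValueError):
            Bound.parse("128")
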