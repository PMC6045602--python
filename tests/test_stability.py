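"""Stability-landscape statistics: notation, binning, KDE, Spearman correlation."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resistograph.stability import (
    AMINO_ACIDS,
    DensityCurve,
    MutationKey,
    StabilityRecord,
    average_replicates,
    classify_stability,
    correlate_sasa_stability,
    find_peaks,
    kde_density,
    landscape_summary,
    load_resistance_table,
    parse_mutation_notation,
    read_stability_table,
    spearman_rho,
)
from resistograph.structio import ResidueSASA


class TestMutationNotation:
    def test_single_site(self):
        key = parse_mutation_notation("L1196M")
        assert key.sites == (("L", 1196, "M"),)
        assert key.notation == "L1196M"
        assert not key.is_multi_site

    def test_multi_site_order_preserved(self):
        key = parse_mutation_notation("E1210K/S1206C")
        assert key.sites == (("E", 1210, "K"), ("S", 1206, "C"))
        assert key.is_multi_site

    @pytest.mark.parametrize("bad", ["L1196", "1196M", "L1196Z/", "B12C", "L0M", "", "L-5M"])
    def test_malformed_notation_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_mutation_notation(bad)

    def test_case_normalized(self):
        assert parse_mutation_notation("l1196m").notation == "L1196M"

    def test_synonymous_control_allowed(self):
        assert parse_mutation_notation("L1196L").is_synonymous

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(AMINO_ACIDS),
                st.integers(min_value=1, max_value=9999),
                st.sampled_from(AMINO_ACIDS),
            ),
            min_size=1,
            max_size=3,
        )
    )
    def test_notation_round_trips(self, sites):
        key = MutationKey(sites=tuple(sites))
        assert parse_mutation_notation(key.notation) == key


class TestAverageReplicates:
    def test_identical_replicates(self):
        assert average_replicates([1.0, 1.0, 1.0]) == (1.0, 0.0)

    def test_two_values_sample_vs_population_std(self):
        # brute force: mean 1.5; sample var (2*1.5^2)/1 = 4.5; population var 2.25
        mean, std = average_replicates([0.0, 3.0])
        assert mean == 1.5 and std == pytest.approx(math.sqrt(4.5))
        _, std0 = average_replicates([0.0, 3.0], ddof=0)
        assert std0 == pytest.approx(1.5)

    def test_single_replicate_degenerate(self):
        assert average_replicates([2.5]) == (2.5, 0.0)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])
        with pytest.raises(ValueError):
            average_replicates([1.0, float("nan")])


class TestClassifyStability:
    @pytest.mark.parametrize(
        "value,category",
        [
            (3.07, "highly_destabilizing"),
            (0.0, "neutral"),
            (-1.19, "stabilizing"),
            (11.06, "highly_destabilizing"),
            (-2.0, "highly_stabilizing"),
            (0.7, "slightly_destabilizing"),
            (-0.7, "slightly_stabilizing"),
            (1.2, "destabilizing"),
            # boundaries closed toward zero
            (0.46, "neutral"),
            (-0.46, "neutral"),
            (0.92, "slightly_destabilizing"),
            (-0.92, "slightly_stabilizing"),
            (1.84, "destabilizing"),
            (-1.84, "stabilizing"),
        ],
    )
    def test_bins(self, value, category):
        assert classify_stability(value) == category

    def test_nonfinite_rejected(self):
        for bad in (float("nan"), float("inf")):
            with pytest.raises(ValueError):
                classify_stability(bad)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_every_finite_value_gets_exactly_one_category(self, x):
        assert classify_stability(x) in {
            "highly_stabilizing",
            "stabilizing",
            "slightly_stabilizing",
            "neutral",
            "slightly_destabilizing",
            "destabilizing",
            "highly_destabilizing",
        }


def _records(values, provenance="all_possible"):
    out = []
    for i, v in enumerate(values):
        key = parse_mutation_notation(f"A{i + 1}G")
        out.append(
            StabilityRecord(
                mutation=key, ddg_fold=v, category=classify_stability(v), provenance=provenance
            )
        )
    return out


class TestLandscapeSummary:
    def test_resistance_table_has_four_stabilizing_rows(self):
        df = load_resistance_table()
        assert len(df) == 22
        recs = [
            StabilityRecord(
                mutation=parse_mutation_notation(m),
                ddg_fold=v,
                category=classify_stability(v),
            )
            for m, v in zip(df["mutation"], df["ddg_fold"])
        ]
        summary = landscape_summary(recs)
        assert summary["n_stabilizing_any"] == 4

    def test_single_neutral_record(self):
        summary = landscape_summary(_records([0.0]))
        assert summary["n_moderate"] == 1
        assert summary["per_category"]["destabilizing"] == 0

    def test_counts_match_direct_enumeration(self, rng):
        values = rng.normal(1.0, 2.0, size=100)
        summary = landscape_summary(_records(values))
        assert summary["n_highly_destabilizing"] == int((values > 1.84).sum())
        assert summary["n_highly_stabilizing"] == int((values < -1.84).sum())
        assert summary["n_moderate"] == int(((values >= -1.84) & (values <= 1.84)).sum())
        assert sum(summary["per_category"].values()) == summary["n_total"] == 100
        assert sum(summary["fractions"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            landscape_summary([])


class TestKDE:
    def test_symmetric_two_point_curve(self):
        curve = kde_density([-1.0, 1.0], bandwidth=0.5)
        mirrored = np.interp(-curve.grid[::-1], curve.grid, curve.density)
        assert np.allclose(curve.density[::-1], mirrored, atol=1e-9)
        assert curve.integral() == pytest.approx(1.0, abs=1e-3)

    def test_standard_normal_mode_near_zero(self, rng):
        sample = rng.standard_normal(10_000)
        curve = kde_density(sample)
        mode = find_peaks(curve)[0][0]
        assert abs(mode) < 0.1

    def test_density_nonnegative_and_normalized(self, rng):
        curve = kde_density(rng.exponential(2.0, size=500))
        assert np.all(curve.density >= 0)
        assert curve.integral() == pytest.approx(1.0, abs=1e-3)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            kde_density([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            kde_density([1.0])


class TestFindPeaks:
    def test_unimodal_curve_single_peak(self):
        grid = np.linspace(-4, 4, 512)
        curve = DensityCurve(grid=grid, density=np.exp(-0.5 * grid**2), bandwidth=1.0)
        assert len(find_peaks(curve)) == 1

    def test_well_separated_mixture_two_peaks_near_means(self):
        grid = np.linspace(-3, 7, 1024)
        dens = 0.5 * np.exp(-0.5 * grid**2) + 0.5 * np.exp(-0.5 * (grid - 3.12) ** 2)
        curve = DensityCurve(grid=grid, density=dens, bandwidth=1.0)
        peaks = find_peaks(curve)
        assert len(peaks) == 2
        locs = sorted(p[0] for p in peaks)
        assert abs(locs[0] - 0.0) < 0.2 and abs(locs[1] - 3.12) < 0.2

    def test_flat_curve_no_peaks(self):
        grid = np.linspace(0, 1, 100)
        curve = DensityCurve(grid=grid, density=np.ones_like(grid), bandwidth=1.0)
        assert find_peaks(curve) == []

    def test_prominence_filter_drops_tail_blip(self):
        grid = np.linspace(-5, 10, 2048)
        dens = np.exp(-0.5 * grid**2) + 1e-3 * np.exp(-0.5 * (grid - 8) ** 2 / 0.04)
        curve = DensityCurve(grid=grid, density=dens, bandwidth=1.0)
        assert len(find_peaks(curve)) == 2
        assert len(find_peaks(curve, min_prominence=0.05)) == 1


class TestSpearman:
    def test_perfect_anticorrelation(self, rng):
        x = rng.uniform(size=20)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_tie_handling_matches_rank_then_pearson_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]

        def mean_ranks(v):
            v = np.asarray(v)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), dtype=float)
            i = 0
            sorted_v = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sorted_v[j] == sorted_v[i]:
                    j += 1
                ranks[order[i:j]] = (i + j - 1) / 2 + 1
                i = j
            return ranks

        rx, ry = mean_ranks(x), mean_ranks(y)
        oracle = float(
            ((rx - rx.mean()) * (ry - ry.mean())).sum()
            / math.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
        )
        assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=1000))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, y**3) == pytest.approx(base, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [3, 4])
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [3, 4, 5])


class TestCorrelateSASA:
    def _sasa(self, mapping):
        return [
            ResidueSASA(chain_id="A", residue_number=k, residue_name="ALA", sasa=v, exposure_class="intermediate")
            for k, v in mapping.items()
        ]

    def test_mutations_on_one_residue_share_its_sasa(self):
        recs = _records([1.0, 2.0, 3.0])  # residues 1..3
        recs += [
            StabilityRecord(mutation=parse_mutation_notation("A1C"), ddg_fold=0.5, category="neutral")
        ]
        rho, table = correlate_sasa_stability(recs, self._sasa({1: 30.0, 2: 10.0, 3: 5.0}))
        shared = table[table["residue_number"] == 1]["sasa"]
        assert len(shared) == 2 and set(shared) == {30.0}

    def test_multi_site_mutations_excluded(self):
        recs = _records([1.0, 2.0, 3.0])
        recs.append(
            StabilityRecord(
                mutation=parse_mutation_notation("A1C/G2D"), ddg_fold=9.9, category="highly_destabilizing"
            )
        )
        _, table = correlate_sasa_stability(recs, self._sasa({1: 30.0, 2: 10.0, 3: 5.0}))
        assert "A1C/G2D" not in set(table["mutation"])

    def test_missing_residue_listed_in_error(self):
        recs = _records([1.0, 2.0, 3.0])
        with pytest.raises(KeyError, match="3"):
            correlate_sasa_stability(recs, self._sasa({1: 30.0, 2: 10.0}))

    def test_planted_negative_trend_recovered(self):
        # deterministic monotone trend: high SASA -> low ddG
        sasa_values = {i: float(i) for i in range(1, 41)}
        recs = _records([10.0 - 0.2 * i for i in range(1, 41)])
        rho, _ = correlate_sasa_stability(recs, self._sasa(sasa_values))
        assert rho == pytest.approx(-1.0)


class TestReadStabilityTable:
    def test_replicate_columns_averaged(self):
        buf = io.StringIO("mutation\tddg_run1\tddg_run2\tddg_run3\nL1196M\t-0.1\t-0.2\t-0.18\n")
        (rec,) = read_stability_table(buf)
        assert rec.ddg_fold == pytest.approx(-0.16)
        assert rec.category == "neutral"

    def test_precomputed_column_with_sd(self):
        buf = io.StringIO("mutation\tddg_fold\tsd\nI1171T\t3.07\t0.026\n")
        (rec,) = read_stability_table(buf)
        assert rec.ddg_fold == 3.07 and rec.std == 0.026
        assert rec.category == "highly_destabilizing"

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            read_stability_table(io.StringIO("mutation\nL1196M\n"))
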