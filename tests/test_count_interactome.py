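"""Count filters, bait normalization, delta classification and roll-up."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_count_matrix
from coipquant.count_interactome import (
    CountMatrix,
    bait_normalize,
    category_rollup,
    classify_delta,
    delta_ratio,
    interactome_deltas,
    min_count_filter,
    per_animal_ratios,
    stratum_totals,
)
from coipquant.errors import InvalidInputError, SchemaError, UndefinedRatioError


class TestValidation:
    def test_negative_counts_rejected(self, simple_matrix):
        counts = simple_matrix.counts.copy()
        counts.iloc[0, 0] = -1
        with pytest.raises(InvalidInputError):
            CountMatrix(counts, simple_matrix.meta, simple_matrix.bait)

    def test_missing_bait_rejected(self, simple_matrix):
        with pytest.raises(SchemaError):
            CountMatrix(simple_matrix.counts, simple_matrix.meta, "NotThere")

    def test_bad_hemisphere_label(self, simple_matrix):
        meta = simple_matrix.meta.copy()
        meta.loc[meta.index[0], "hemisphere"] = "left"
        with pytest.raises(SchemaError):
            CountMatrix(simple_matrix.counts, meta, simple_matrix.bait)


class TestMinCountFilter:
    def _matrix_with_total(self, total):
        # spread `total` counts over the 24 samples: 2 per sample on the
        # first `total // 2` samples
        per_sample = [0] * 6
        strata = {}
        remaining = total
        for frac in ("S2", "S3"):
            for hemi in ("intact", "lesion"):
                vals = []
                for _ in range(6):
                    take = min(2, remaining)
                    vals.append(take)
                    remaining -= take
                strata[(frac, hemi)] = vals
        return make_count_matrix(
            {
                "Bait": {(f, h): 100 for f in ("S2", "S3") for h in ("intact", "lesion")},
                "Edge": strata,
            }
        )

    def test_boundary_at_minimum(self):
        kept = min_count_filter(self._matrix_with_total(48))
        assert "Edge" in kept.proteins
        dropped = min_count_filter(self._matrix_with_total(47))
        assert "Edge" not in dropped.proteins

    def test_all_zero_removed(self):
        m = self._matrix_with_total(0)
        assert "Edge" not in min_count_filter(m).proteins

    def test_idempotent(self, simple_matrix):
        once = min_count_filter(simple_matrix, min_total=10)
        twice = min_count_filter(once, min_total=10)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_bait_always_retained(self, simple_matrix):
        kept = min_count_filter(simple_matrix, min_total=10**9)
        assert simple_matrix.bait in kept.proteins


class TestBaitNormalize:
    def test_zero_bait_stratum_rejected(self):
        m = make_count_matrix(
            {
                "Bait": {("S2", "intact"): [200, 0, 0, 0, 0, 0]},
                "Prey": {("S2", "intact"): [16, 0, 0, 0, 0, 0]},
            }
        )
        with pytest.raises(UndefinedRatioError):
            bait_normalize(m)  # other strata have zero bait

    def test_normalized_values(self, simple_matrix):
        norm = bait_normalize(simple_matrix)
        # bait 100/rep -> 600 per stratum; prey 10/rep -> 60
        assert norm.loc["PreyDown", ("S2", "intact")] == pytest.approx(0.1)
        assert norm.loc["Bait"].to_numpy() == pytest.approx(np.ones(4))

    def test_stratum_scale_invariance(self, simple_matrix):
        scaled_counts = simple_matrix.counts.copy()
        s2_lesion = simple_matrix.samples_in("S2", "lesion")
        scaled_counts[s2_lesion] = scaled_counts[s2_lesion] * 3
        scaled = CountMatrix(scaled_counts, simple_matrix.meta, simple_matrix.bait)
        pd.testing.assert_frame_equal(
            bait_normalize(scaled), bait_normalize(simple_matrix)
        )


class TestDeltaRatio:
    def test_arithmetic(self, simple_matrix):
        norm = bait_normalize(simple_matrix)
        assert delta_ratio(norm, "PreyDown", "S3") == pytest.approx(0.8)
        assert delta_ratio(norm, "PreyDown", "S2") == pytest.approx(1.0)
        assert delta_ratio(norm, "Bait", "S3") == pytest.approx(1.0)

    def test_hemisphere_swap_inverts(self, simple_matrix):
        meta = simple_matrix.meta.copy()
        meta["hemisphere"] = meta["hemisphere"].map(
            {"intact": "lesion", "lesion": "intact"}
        )
        swapped = CountMatrix(simple_matrix.counts, meta, simple_matrix.bait)
        r = delta_ratio(bait_normalize(simple_matrix), "PreyDown", "S3")
        r_swapped = delta_ratio(bait_normalize(swapped), "PreyDown", "S3")
        assert r_swapped == pytest.approx(1.0 / r)

    def test_zero_intact_raises(self):
        m = make_count_matrix(
            {
                "Bait": {(f, h): 100 for f in ("S2", "S3") for h in ("intact", "lesion")},
                "Prey": {("S3", "lesion"): 10},
            }
        )
        with pytest.raises(UndefinedRatioError):
            delta_ratio(bait_normalize(m), "Prey", "S3")


class TestClassify:
    @pytest.mark.parametrize(
        "ratio,totals,expected",
        [
            (0.80, (60, 10), "decreased"),
            (1.30, (30, 20), "filtered_out"),
            (1.00, (100, 100), "unchanged"),
            (1.18, (60, 60), "increased"),  # inclusive threshold
            (0.82, (60, 60), "decreased"),  # inclusive threshold
            (1.17, (60, 60), "unchanged"),
            (0.83, (60, 60), "unchanged"),
            (2.00, (50, 0), "increased"),  # 50 in one fraction suffices
        ],
    )
    def test_rules(self, ratio, totals, expected):
        assert classify_delta(ratio, totals) == expected


class TestDeltasTable:
    def test_conservation_and_bait_unity(self, simple_matrix):
        deltas = interactome_deltas(simple_matrix)
        assert len(deltas) == 2 * len(simple_matrix.proteins)
        assert set(deltas["classification"]) <= {
            "increased",
            "decreased",
            "unchanged",
            "filtered_out",
        }
        bait = deltas[deltas["protein"] == "Bait"]
        assert (bait["ratio"] == 1.0).all()

    def test_zero_intact_reported_not_dropped(self):
        m = make_count_matrix(
            {
                "Bait": {(f, h): 100 for f in ("S2", "S3") for h in ("intact", "lesion")},
                "NewPrey": {("S3", "lesion"): 10},  # 60 total, only in lesion
            }
        )
        deltas = interactome_deltas(m)
        row = deltas[(deltas["protein"] == "NewPrey") & (deltas["fraction"] == "S3")].iloc[0]
        assert not row["ratio_defined"]
        assert np.isnan(row["ratio"])
        assert row["classification"] == "increased"

    def test_integer_stratum_scaling_keeps_classifications(self, simple_matrix):
        deltas = interactome_deltas(simple_matrix)
        scaled_counts = simple_matrix.counts.copy()
        cols = simple_matrix.samples_in("S3", "lesion")
        scaled_counts[cols] = scaled_counts[cols] * 2
        # scaling one stratum changes ratios; scaling *all* strata equally
        # must not change anything
        all_scaled = CountMatrix(
            simple_matrix.counts * 5, simple_matrix.meta, simple_matrix.bait
        )
        deltas_scaled = interactome_deltas(all_scaled)
        assert list(deltas["classification"]) == list(deltas_scaled["classification"])
        np.testing.assert_allclose(deltas["ratio"], deltas_scaled["ratio"])


class TestPerAnimalRatios:
    def test_paired_ratios(self, simple_matrix):
        ratios = per_animal_ratios(simple_matrix)
        s3 = ratios[(ratios["protein"] == "PreyDown") & (ratios["fraction"] == "S3")]
        assert len(s3) == 6
        np.testing.assert_allclose(s3["ratio"], 0.8)


class TestRollup:
    def test_empty(self):
        report = category_rollup(pd.DataFrame(columns=["protein", "fraction", "classification"]))
        assert report.empty

    def test_single_protein(self):
        deltas = pd.DataFrame(
            [{"protein": "Myo5a", "fraction": "S3", "classification": "increased"}]
        )
        report = category_rollup(deltas, {"Myo5a": "myosin"})
        row = report.iloc[0]
        assert (row["fraction"], row["classification"], row["category"], row["n"]) == (
            "S3",
            "increased",
            "myosin",
            1,
        )

    def test_partition_totals(self, simple_matrix):
        deltas = interactome_deltas(simple_matrix)
        report = category_rollup(deltas, {"PreyDown": "cytoskeletal"})
        assert report["n"].sum() == len(deltas)
        # uncategorized proteins land in "other"
        assert "other" in set(report["category"])
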