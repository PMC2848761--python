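"""Cross-platform candidate integration, enrichment, and qRT-PCR folds."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedqtl.integrate import (
    candidate_table,
    candidates_to_frame,
    comparative_ct,
    fisher_enrichment,
    normalize_coordinates,
)
from seedqtl.region import Region

REGION = Region(chromosome="Gm20", start=1_000, end=9_000)


def _coords(rows):
    return pd.DataFrame(rows, columns=["feature", "chromosome", "start", "end"])


class TestNormalizeCoordinates:
    def test_reversed_interval_is_oriented(self):
        out = normalize_coordinates(_coords([("f", "Gm20", 500, 100)]))
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (100, 500)

    def test_oriented_interval_is_unchanged_and_input_not_mutated(self):
        df = _coords([("f", "Gm20", 100, 500)])
        out = normalize_coordinates(df)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (100, 500)
        df2 = _coords([("f", "Gm20", 500, 100)])
        normalize_coordinates(df2)
        assert df2.loc[0, "start"] == 500


class TestCandidateTable:
    def _de(self, features, direction="LoPro"):
        return pd.DataFrame({"feature": features, "direction": direction})

    def test_overlapping_features_merge_with_both_evidence(self):
        coords = _coords(
            [("ps1", "Gm20", 2_000, 2_500), ("g1", "Gm20", 2_400, 3_000)]
        )
        cands = candidate_table(self._de(["ps1"]), self._de(["g1"]), coords, REGION)
        assert len(cands) == 1
        c = cands[0]
        assert c.members == ("g1", "ps1")
        assert c.evidence == "both"
        assert (c.start, c.end) == (2_000, 3_000)
        assert c.direction == "LoPro"

    def test_disjoint_features_stay_separate(self):
        coords = _coords(
            [("ps1", "Gm20", 2_000, 2_500), ("g1", "Gm20", 2_501, 3_000)]
        )
        cands = candidate_table(self._de(["ps1"]), self._de(["g1"]), coords, REGION)
        assert len(cands) == 2
        assert {c.evidence for c in cands} == {"microarray", "htts"}

    def test_single_linkage_chain(self):
        # a-b overlap and b-c overlap but a-c do not: one cluster of three
        coords = _coords(
            [
                ("a", "Gm20", 2_000, 2_400),
                ("b", "Gm20", 2_300, 2_800),
                ("c", "Gm20", 2_700, 3_200),
            ]
        )
        cands = candidate_table(self._de(["a", "b", "c"]), None, coords, REGION)
        assert len(cands) == 1
        assert cands[0].members == ("a", "b", "c")

    def test_out_of_region_features_are_dropped(self):
        coords = _coords(
            [("inside", "Gm20", 2_000, 2_100), ("outside", "Gm20", 20_000, 20_100),
             ("otherchrom", "Gm02", 2_000, 2_100)]
        )
        cands = candidate_table(
            self._de(["inside", "outside", "otherchrom"]), None, coords, REGION
        )
        assert [c.members for c in cands] == [("inside",)]

    def test_direction_tie_is_mixed(self):
        coords = _coords(
            [("a", "Gm20", 2_000, 2_500), ("b", "Gm20", 2_400, 3_000)]
        )
        de = pd.DataFrame({"feature": ["a", "b"], "direction": ["LoPro", "HiPro"]})
        cands = candidate_table(de, None, coords, REGION)
        assert cands[0].direction == "mixed"

    def test_missing_coordinates_is_an_error(self):
        with pytest.raises(ValueError, match="orphan"):
            candidate_table(self._de(["orphan"]), None, _coords([]), REGION)

    def test_empty_input_gives_empty_list(self):
        assert candidate_table(None, None, _coords([]), REGION) == []

    def test_input_order_invariance(self):
        coords = _coords(
            [("a", "Gm20", 2_000, 2_400), ("b", "Gm20", 2_300, 2_800),
             ("c", "Gm20", 5_000, 5_400)]
        )
        base = None
        for perm in itertools.permutations(["a", "b", "c"]):
            cands = candidate_table(self._de(list(perm)), None, coords, REGION)
            frame = candidates_to_frame(cands)
            if base is None:
                base = frame
            else:
                pd.testing.assert_frame_equal(frame, base)

    def test_frame_round_trip_columns(self):
        coords = _coords([("a", "Gm20", 2_000, 2_400)])
        frame = candidates_to_frame(
            candidate_table(self._de(["a"]), None, coords, REGION)
        )
        assert list(frame.columns) == [
            "chromosome", "start", "end", "members", "direction", "evidence",
        ]
        assert frame.loc[0, "evidence"] == "microarray"


class TestFisherEnrichment:
    def _map(self):
        rows = []
        for g in range(40):
            rows.append({"category": "metabolism", "gene": f"g{g}"})
        for g in range(10):
            rows.append({"category": "storage", "gene": f"g{g}"})
        return pd.DataFrame(rows)

    def test_enriched_category_found_and_bonferroni_applied(self):
        universe = {f"g{i}" for i in range(40)}
        de = {f"g{i}" for i in range(8)}  # 8/10 of "storage" is DE
        res = fisher_enrichment(
            de, universe, self._map(), n_categories_total=50, report_all=True
        ).set_index("category")
        a, b, c, d = 8, 2, 0, 30
        expected_p = stats.fisher_exact([[a, b], [c, d]])[1]
        assert res.loc["storage", "p"] == pytest.approx(expected_p)
        assert res.loc["storage", "p_adjusted"] == pytest.approx(
            min(1.0, expected_p * 50)
        )
        assert bool(res.loc["storage", "reported"]) is True
        # "metabolism" contains the whole universe: no enrichment possible
        assert bool(res.loc["metabolism", "reported"]) is False

    def test_under_represented_category_is_not_reported(self):
        universe = {f"g{i}" for i in range(40)}
        de = {f"g{i}" for i in range(10, 30)}  # avoids "storage" entirely
        res = fisher_enrichment(
            de, universe, self._map(), n_categories_total=2, report_all=True
        ).set_index("category")
        assert bool(res.loc["storage", "over_represented"]) is False
        assert bool(res.loc["storage", "reported"]) is False

    def test_default_reporting_filters(self):
        universe = {f"g{i}" for i in range(40)}
        de = {f"g{i}" for i in range(8)}
        res = fisher_enrichment(de, universe, self._map(), n_categories_total=2)
        assert list(res["category"]) == ["storage"]

    def test_de_not_subset_of_universe_is_an_error(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment({"x"}, {"y"}, self._map(), n_categories_total=2)

    def test_too_small_category_total_is_an_error(self):
        universe = {f"g{i}" for i in range(40)}
        with pytest.raises(ValueError, match="n_categories_total"):
            fisher_enrichment({"g1"}, universe, self._map(), n_categories_total=1)

    def test_matches_hypergeometric_enumeration(self):
        """Fisher two-tail p equals a direct enumeration over all tables with
        the same margins (sum of probabilities ≤ the observed one)."""
        rng = np.random.default_rng(13)
        for _ in range(15):
            a, b, c, d = (int(v) for v in rng.integers(0, 25, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n, K, N = a + b + c + d, a + b, a + c
            probs = [
                stats.hypergeom.pmf(x, n, K, N)
                for x in range(max(0, K + N - n), min(K, N) + 1)
            ]
            obs = stats.hypergeom.pmf(a, n, K, N)
            expected = sum(p for p in probs if p <= obs * (1 + 1e-9))
            got = stats.fisher_exact([[a, b], [c, d]])[1]
            assert got == pytest.approx(min(1.0, expected), rel=1e-9)


class TestComparativeCt:
    def _records(self, lo_dct, hi_dct, ref=15.0):
        rows = []
        for g, dcts in (("LoPro", lo_dct), ("HiPro", hi_dct)):
            for dct in dcts:
                rows.append(
                    {"genotype": g, "target_ct": ref + dct, "reference_ct": ref}
                )
        return pd.DataFrame(rows)

    def test_one_cycle_earlier_is_twofold(self):
        # LoPro target crosses one cycle earlier than HiPro: 2-fold higher
        fold, sd = comparative_ct(self._records([4.0], [5.0]), "LoPro", "HiPro")
        assert fold == pytest.approx(2.0)
        assert sd == 0.0

    def test_equal_groups_give_unit_fold(self):
        fold, _ = comparative_ct(
            self._records([4.0, 4.0], [4.0, 4.0]), "LoPro", "HiPro"
        )
        assert fold == pytest.approx(1.0)

    def test_sd_over_replicate_folds(self):
        records = self._records([3.0, 5.0], [4.0])
        fold, sd = comparative_ct(records, "LoPro", "HiPro")
        # per-replicate folds 2^1 and 2^-1 around the HiPro mean
        assert fold == pytest.approx(1.0)
        assert sd == pytest.approx(np.std([2.0, 0.5], ddof=1))

    def test_direction_inverts_when_groups_swap(self):
        records = self._records([4.0], [6.0])
        fa, _ = comparative_ct(records, "LoPro", "HiPro")
        fb, _ = comparative_ct(records, "HiPro", "LoPro")
        assert fa == pytest.approx(4.0)
        assert fa * fb == pytest.approx(1.0)

    def test_missing_reference_is_an_error(self):
        records = self._records([4.0], [5.0])
        records.loc[0, "reference_ct"] = math.nan
        with pytest.raises(ValueError, match="reference"):
            comparative_ct(records, "LoPro", "HiPro")

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="LoPro"):
            comparative_ct(self._records([], [5.0]), "LoPro", "HiPro")
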