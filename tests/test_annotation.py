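import math

import numpy as np
import pandas as pd
import pytest

from napsri import examples
from napsri.annotation import MatchParams, match_mz, match_mz_ri, relative_error
from napsri.chem import formula_adduct_mz


class TestRelativeError:
    @pytest.mark.parametrize(
        "reference,observed,expected",
        [
            (474, 472, 0.4),  # tryptophan RI, system 1
            (475, 472, 0.6),  # tryptophan RI, system 2
            (2.71, 5.03, 46.0),  # tryptophan RT, system 1
            (12.31, 9.69, 27.0),  # riboflavin RT, system 2
            (595, 586, 1.5),  # riboflavin RI, system 2
            (633, 634, 0.2),  # N-acetylphenylalanine RI, system 1
            (561, 513, 9.4),  # salicylic acid RI, system 1
            (6.85, 6.51, 5.2),  # 4-hydroxybenzoic acid RT, system 2
            (100, 100, 0.0),
        ],
    )
    def test_observed_denominator_with_printed_rounding(self, reference, observed, expected):
        assert relative_error(reference, observed) == expected

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            relative_error(100, 0)


class TestMatchMz:
    def test_empty_library_no_hits(self):
        feats = examples.isomer_feature()
        hits = match_mz(feats, pd.DataFrame(columns=["compound_id", "adduct", "mz"]))
        assert hits.empty

    def test_isomers_all_hit_on_mz_alone(self):
        hits = match_mz(examples.isomer_feature(), examples.isomer_library(1))
        assert len(hits) == 3
        assert set(hits["compound_id"]) == {
            "4-Hydroxybenzoic acid",
            "3-Hydroxybenzoic acid",
            "Salicylic acid",
        }

    def test_boundary_inclusive_and_symmetric(self):
        lib = pd.DataFrame(
            {"compound_id": ["x"], "adduct": ["[M+H]+"], "mz": [200.0], "polarity": ["pos"]}
        )
        feats = pd.DataFrame(
            {
                "feature_id": ["plus", "minus", "out"],
                "mz": [200.005, 199.995, 200.0051],
                "polarity": ["pos"] * 3,
            }
        )
        hits = match_mz(feats, lib, MatchParams(mz_tol=0.005))
        assert set(hits["feature_id"]) == {"plus", "minus"}

    def test_formula_based_candidate_mz(self):
        lib = examples.isomer_library(1).drop(columns=[])
        expected = formula_adduct_mz("C7H6O3", "[M+H]+")
        hits = match_mz(examples.isomer_feature(), lib)
        assert hits["library_mz"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_entry_without_mz_or_formula_rejected(self):
        lib = pd.DataFrame({"compound_id": ["x"], "adduct": ["[M+H]+"], "polarity": ["pos"]})
        with pytest.raises(ValueError, match="x"):
            match_mz(examples.isomer_feature(), lib)

    def test_ppm_and_da_are_exclusive(self):
        with pytest.raises(ValueError):
            MatchParams(mz_tol=0.005, mz_tol_ppm=5.0)
        params = MatchParams(mz_tol=None, mz_tol_ppm=10.0)
        assert params.mz_window(500.0) == pytest.approx(0.005)


class TestMatchMzRi:
    def test_ri_filter_resolves_isomers(self):
        hits = match_mz_ri(examples.isomer_feature(), examples.isomer_library(1))
        assert len(hits) == 1
        assert hits["compound_id"].iloc[0] == "4-Hydroxybenzoic acid"

    def test_infinite_ri_tol_equals_mz_only(self):
        params = MatchParams(ri_tol=math.inf)
        feats, lib = examples.isomer_feature(), examples.isomer_library(1)
        assert len(match_mz_ri(feats, lib, params)) == len(match_mz(feats, lib, params))

    def test_delta_ri_48_excluded_at_tol_10(self):
        hits = match_mz(examples.isomer_feature(), examples.isomer_library(1))
        assert hits["delta_ri"].abs().max() == pytest.approx(48.0)
        kept = match_mz_ri(examples.isomer_feature(), examples.isomer_library(1))
        assert kept["delta_ri"].abs().max() <= 10.0

    def test_subset_of_mz_hits(self):
        feats, lib = examples.case_study_features(), examples.isomer_library(2)
        all_hits = match_mz(feats, lib)
        ri_hits = match_mz_ri(feats, lib)
        key = ["feature_id", "compound_id", "adduct"]
        all_keys = set(map(tuple, all_hits[key].itertuples(index=False)))
        ri_keys = set(map(tuple, ri_hits[key].itertuples(index=False)))
        assert ri_keys <= all_keys

    def test_shrinking_tolerance_never_adds_hits(self):
        feats, lib = examples.case_study_features(), examples.isomer_library(1)
        wide = match_mz_ri(feats, lib, MatchParams(mz_tol=0.01, ri_tol=60))
        narrow = match_mz_ri(feats, lib, MatchParams(mz_tol=0.005, ri_tol=10))
        assert len(narrow) <= len(wide)

    def test_features_without_ri_skipped(self, caplog):
        feats = examples.isomer_feature().drop(columns=["ri"])
        hits = match_mz_ri(feats, examples.isomer_library(1))
        assert hits.empty


class TestGroundTruthRecovery:
    def test_ri_filter_raises_precision_keeps_truth(self):
        """With RI noise below ri_tol/2, the RI filter removes false isobaric
        candidates but never the true identity."""
        rng = np.random.default_rng(11)
        n = 30
        true_ri = rng.uniform(400, 1800, n)
        mz = np.round(rng.uniform(100, 800, n), 4)
        lib = pd.DataFrame(
            {
                "compound_id": [f"T{i}" for i in range(n)],
                "adduct": ["[M+H]+"] * n,
                "polarity": ["pos"] * n,
                "mz": mz,
                "mean_ri": true_ri,
            }
        )
        # decoys: same m/z (isomers), RI shifted well beyond tolerance
        decoys = lib.copy()
        decoys["compound_id"] = [f"D{i}" for i in range(n)]
        decoys["mean_ri"] = true_ri + 80.0
        lib_all = pd.concat([lib, decoys], ignore_index=True)
        feats = pd.DataFrame(
            {
                "feature_id": [f"F{i}" for i in range(n)],
                "mz": mz + rng.uniform(-0.002, 0.002, n),
                "ri": true_ri + rng.uniform(-4.0, 4.0, n),  # < ri_tol/2
                "polarity": ["pos"] * n,
            }
        )
        mz_hits = match_mz(feats, lib_all)
        ri_hits = match_mz_ri(feats, lib_all)
        prec_mz = (mz_hits["compound_id"].str.startswith("T")).mean()
        prec_ri = (ri_hits["compound_id"].str.startswith("T")).mean()
        assert prec_ri > prec_mz
        assert set(ri_hits["feature_id"]) == set(feats["feature_id"])  # truth retained
        assert ri_hits["compound_id"].str.startswith("T").all()
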