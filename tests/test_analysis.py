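"""Series extraction, WUE-correlation classification, storage diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camtransit import (
    classify_series,
    classify_trajectory,
    enzyme_phase_profile,
    extract_series,
    storage_report,
)
from camtransit.analysis import (
    AnalysisError,
    LABELS,
    carbon_balance,
    classification_matrix,
    classify_reaction,
)
from camtransit.synthetic import CARBON_NUMBERS, PHLOEM_AA_FRACTION


def pearson_oracle(x, y):
    """Plain-arithmetic Pearson r, independent of the implementation path."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestClassifySeries:
    def test_proportional_series_is_strong_up(self):
        wue = [1, 2, 3, 4, 5]
        label, r = classify_series([2 * w for w in wue], wue)
        assert label == "strong_up"
        assert r == pytest.approx(1.0)

    def test_constant_series_unclassified(self):
        label, r = classify_series([3.3] * 5, [1, 2, 3, 4, 5])
        assert label == "unclassified"
        assert r is None

    def test_sign_crossing_is_direction_flip(self):
        label, r = classify_series([-1.0, -0.2, 0.4, 1.0], [1, 2, 3, 4])
        assert label == "direction_flip"

    def test_solver_noise_does_not_flip(self):
        label, _ = classify_series([-1e-12, 0.5, 1.0, 2.0], [1, 2, 3, 4])
        assert label != "direction_flip"

    def test_hand_computed_example(self):
        """The mixed-monotone series correlates at r ~ 0.94 (> 0.9)."""
        values = [1, 2, 1.5, 3, 4, 3.5, 5]
        wue = [1, 2, 3, 4, 5, 6, 7]
        expected = pearson_oracle(values, wue)
        assert expected == pytest.approx(0.9408, abs=5e-4)
        label, r = classify_series(values, wue)
        assert label == "strong_up"
        assert r == pytest.approx(expected, rel=1e-12)

    def test_moderate_band(self):
        # descending series engineered between the 0.8 and 0.9 thresholds
        values = [5.0, 4.0, 4.4, 3.0, 3.4, 1.0, 2.0]
        wue = [1, 2, 3, 4, 5, 6, 7]
        r = pearson_oracle(values, wue)
        assert -0.9 < r < -0.8
        label, got = classify_series(values, wue)
        assert label == "moderate_down"

    def test_length_mismatch_rejected(self):
        with pytest.raises(AnalysisError, match="length"):
            classify_series([1, 2, 3], [1, 2])

    def test_too_short_rejected(self):
        with pytest.raises(AnalysisError):
            classify_series([1, 2], [1, 2])

    def test_spearman_flag(self):
        # convex but monotone: Spearman saturates at 1
        values = [1, 2, 4, 8, 16]
        label, r = classify_series(values, [1, 2, 3, 4, 5], method="spearman")
        assert label == "strong_up"
        assert r == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-50, max_value=50),
    )
    def test_invariant_to_positive_affine_wue_rescaling(self, a, b):
        values = [1.0, 2.0, 1.5, 3.0, 4.0, 3.5, 5.0]
        wue = np.array([1.0, 2, 3, 4, 5, 6, 7])
        base = classify_series(values, wue)
        scaled = classify_series(values, a * wue + b)
        assert base[0] == scaled[0]
        assert scaled[1] == pytest.approx(base[1], rel=1e-9)


class TestTrajectoryClassification:
    def test_extract_series_length_and_order(self, results):
        s = extract_series(results.trajectory, "PEPC", "MC", 5)
        assert len(s.values) == len(results.trajectory.points)
        wue = results.trajectory.wue_values
        assert wue == sorted(wue)  # increasing-WUE order

    def test_extract_series_bad_phase(self, results):
        with pytest.raises(AnalysisError):
            extract_series(results.trajectory, "PEPC", "MC", 7)

    def test_extract_series_unknown_reaction(self, results):
        with pytest.raises(KeyError):
            extract_series(results.trajectory, "NOT_A_REACTION", "MC", 1)

    def test_classify_reaction_wraps_series(self, results):
        s = extract_series(results.trajectory, "PEPC", "GC", 5)
        c = classify_reaction(s, results.trajectory.wue_values)
        assert c.reaction_id == "PEPC" and c.phase == 5 and c.cell_type == "GC"
        assert c.label in LABELS

    def test_every_triple_gets_exactly_one_label(self, results):
        table = results.classification
        n_base = len(results.combined.base.reactions)
        assert len(table) == n_base * 2 * 6
        assert not table.duplicated(["reaction_id", "cell", "phase"]).any()
        assert set(table["label"]) <= set(LABELS)
        assert table["label"].value_counts().sum() == len(table)

    def test_classification_matrix_shape(self, results):
        mat = classification_matrix(results.classification)
        assert mat.shape[1] == 12  # 2 cells x 6 phases


class TestProfilesAndStorage:
    def test_empty_derived_sum_is_zero(self, results):
        prof = enzyme_phase_profile(
            results.cam, results.combined, [], derived_sums={"nothing": []}
        )
        assert (prof["nothing_GC"] == 0).all()
        assert (prof["nothing_MC"] == 0).all()

    def test_derived_sum_is_elementwise_addition(self, results):
        prof = enzyme_phase_profile(
            results.cam,
            results.combined,
            ["ME", "PEPCK"],
            derived_sums={"decarb": ["ME", "PEPCK"]},
        )
        for cell in ("GC", "MC"):
            np.testing.assert_allclose(
                prof[f"decarb_{cell}"], prof[f"ME_{cell}"] + prof[f"PEPCK_{cell}"]
            )

    def test_unknown_enzyme_id_rejected(self, results):
        with pytest.raises(AnalysisError):
            enzyme_phase_profile(results.cam, results.combined, ["NOPE"])

    def test_cam_endpoint_temporal_separation(self, results):
        """Carboxylation sits in the night phases, decarboxylation in the
        morning, at the CAM endpoint."""
        prof = enzyme_phase_profile(
            results.cam,
            results.combined,
            ["PEPC"],
            derived_sums={"decarb": ["ME", "PEPCK"]},
        )
        pepc = prof["PEPC_MC"]
        assert pepc.loc[5] + pepc.loc[6] > 10 * (pepc.loc[2] + pepc.loc[3])
        decarb = prof["decarb_MC"]
        assert decarb.loc[1] + decarb.loc[2] > 10 * (
            decarb.loc[4] + decarb.loc[5] + decarb.loc[6]
        )

    def test_storage_report_c3_row(self, results):
        st = results.storage.table
        assert st["night_co2"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert st["night_co2_share"].iloc[-1] > 0.9

    def test_storage_report_k_fluxes_nonnegative(self, results):
        assert (results.storage.k_uptake_by_phase.values >= -1e-12).all()
        assert (results.storage.k_release_by_phase.values >= -1e-12).all()

    def test_malate_store_grows_toward_cam(self, results):
        st = results.storage.table
        for col in ("malate_P6_to_P1_GC", "malate_P6_to_P1_MC"):
            assert st[col].iloc[-1] > st[col].iloc[0] + 1e-6

    def test_carbon_closure(self, results):
        """Duration-weighted CO2 intake equals phloem carbon export: the
        storage pools close over the cycle and respiration is recaptured,
        so sucrose + amino-acid carbon is the only exit."""
        carbons = dict(CARBON_NUMBERS)
        expected_per_unit = (
            CARBON_NUMBERS["suc"] + PHLOEM_AA_FRACTION * CARBON_NUMBERS["aa"]
        )
        for pt in results.trajectory.points:
            co2_in, phloem_c = carbon_balance(
                results.combined, pt.solution.fluxes, carbons
            )
            assert phloem_c == pytest.approx(
                pt.solution.phloem_total * expected_per_unit, rel=1e-9
            )
            assert co2_in == pytest.approx(phloem_c, rel=1e-6)

    def test_storage_report_runs_from_raw_trajectory(self, results):
        rep = storage_report(results.trajectory)
        assert len(rep.table) == len(results.trajectory.points)

    def test_classify_trajectory_subset(self, results):
        table = classify_trajectory(results.trajectory, reaction_ids=["PEPC"])
        assert set(table["reaction_id"]) == {"PEPC"}
        assert len(table) == 12
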