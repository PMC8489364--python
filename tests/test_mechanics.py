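"""Elastance derivation, best-PEEP selection, hysteresis, imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qctpeep import (
    MechanicsRecord,
    best_peep,
    classify_injury,
    derive_mechanics,
    generate_physiology_table,
    hysteresis,
    impute_missing,
)
from qctpeep.io import load_reference_medians


class TestDeriveMechanics:
    def test_two_point_elastances(self):
        rec = derive_mechanics(
            MechanicsRecord(p_aw_insp=30, p_aw_exp=10, p_es_insp=20, p_es_exp=10, v_t=0.5)
        )
        assert rec.e_rs == pytest.approx(40.0)
        assert rec.e_w == pytest.approx(20.0)
        assert rec.e_l == pytest.approx(20.0)
        assert rec.p_l_insp == pytest.approx(10.0)

    def test_pf_ratio(self):
        rec = derive_mechanics(
            MechanicsRecord(
                p_aw_insp=30, p_aw_exp=10, p_es_insp=20, p_es_exp=10, v_t=0.5,
                pao2=90.0, fio2=0.6,
            )
        )
        assert rec.pf_ratio == pytest.approx(150.0)

    def test_rigid_chest_wall_degenerate(self):
        rec = derive_mechanics(
            MechanicsRecord(p_aw_insp=28, p_aw_exp=8, p_es_insp=12, p_es_exp=12, v_t=0.4)
        )
        assert rec.e_w == 0.0
        assert rec.e_l == rec.e_rs

    def test_partition_identity_holds(self, rng):
        for _ in range(20):
            p = rng.uniform(5, 45, size=4)
            rec = derive_mechanics(
                MechanicsRecord(
                    p_aw_insp=p[0], p_aw_exp=p[1], p_es_insp=p[2], p_es_exp=p[3],
                    v_t=float(rng.uniform(0.2, 0.8)),
                )
            )
            assert rec.e_rs == pytest.approx(rec.e_w + rec.e_l, abs=1e-12)

    @pytest.mark.parametrize("bad", [{"v_t": 0.0}, {"v_t": -0.5}, {"fio2": 0.0}, {"fio2": 1.2}])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(p_aw_insp=30, p_aw_exp=10, p_es_insp=20, p_es_exp=10, v_t=0.5,
                      pao2=100.0, fio2=0.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            derive_mechanics(MechanicsRecord(**kwargs))


class TestClassifyInjury:
    @pytest.mark.parametrize(
        "pf,injured", [(299.9, True), (300.0, False), (153.0, True), (542.0, False)]
    )
    def test_strict_threshold(self, pf, injured):
        assert classify_injury(pf) is injured

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_injury(-1.0)


def table_from(values_per_peep, endpoint="elastance_rs", condition="healthy"):
    rows = [
        {
            "subject": "median",
            "condition": condition,
            "phase": "descending",
            "peep_cmH2O": float(p),
            "endpoint": endpoint,
            "value": float(v),
        }
        for p, v in values_per_peep.items()
    ]
    return pd.DataFrame(rows)


class TestBestPeep:
    def test_lowest_elastance_healthy_medians(self):
        table = table_from({5: 103, 12: 94, 17: 85, 22: 81, 27: 92})
        res = best_peep(table, "elastance_rs", "lowest")
        assert res.peep_cmH2O == 22.0
        assert res.value == 81.0
        assert not res.tie

    def test_highest_pf_injured_medians(self):
        table = table_from({5: 175, 12: 235, 17: 244, 22: 285, 27: 243},
                           endpoint="pf_ratio", condition="injured")
        res = best_peep(table, "pf_ratio", "highest", condition="injured")
        assert res.peep_cmH2O == 22.0

    def test_all_equal_ties_to_lowest_peep(self):
        table = table_from({5: 7, 12: 7, 17: 7, 22: 7, 27: 7})
        res = best_peep(table, "elastance_rs", "lowest")
        assert res.peep_cmH2O == 5.0
        assert res.tie

    def test_missing_cell_raises_naming_it(self):
        table = table_from({5: 103, 12: 94, 22: 81, 27: 92})
        table = pd.concat(
            [table, table_from({17: np.nan})], ignore_index=True
        )
        with pytest.raises(ValueError, match="PEEP 17"):
            best_peep(table, "elastance_rs", "lowest")

    def test_mixed_conditions_require_filter(self):
        both = pd.concat(
            [table_from({5: 1, 12: 2}), table_from({5: 3, 12: 4}, condition="injured")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="condition"):
            best_peep(both, "elastance_rs", "lowest")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_invariant_under_monotone_transforms(self, shift, scale):
        base = {5: 103.0, 12: 94.0, 17: 85.0, 22: 81.0, 27: 92.0}
        transformed = {p: scale * v + shift for p, v in base.items()}
        r1 = best_peep(table_from(base), "elastance_rs", "lowest")
        r2 = best_peep(table_from(transformed), "elastance_rs", "lowest")
        assert r1.peep_cmH2O == r2.peep_cmH2O

    def test_packaged_medians_load_and_select(self):
        table = load_reference_medians()
        res = best_peep(table, "elastance_rs", "lowest", condition="healthy")
        assert res.peep_cmH2O == 22.0


class TestHysteresis:
    MEDIANS = {"pf_ratio": {5.0: 500.0, 12.0: 510.0}}

    def test_identical_phases_zero_delta(self):
        table = generate_physiology_table(
            self.MEDIANS, n_subjects=3, noise_cv=0.0, seed=0,
            phases=("ascending", "descending"),
        )
        res = hysteresis(table)
        assert np.allclose(res.deltas["delta"], 0.0)
        assert res.skipped == ()

    def test_sign_convention(self):
        table = pd.DataFrame(
            [
                dict(subject="s1", condition="healthy", phase="ascending",
                     peep_cmH2O=5.0, endpoint="pf_ratio", value=100.0),
                dict(subject="s1", condition="healthy", phase="descending",
                     peep_cmH2O=5.0, endpoint="pf_ratio", value=90.0),
            ]
        )
        res = hysteresis(table)
        assert res.deltas["delta"].iloc[0] == pytest.approx(-10.0)

    def test_known_offset_recovered(self):
        table = generate_physiology_table(
            self.MEDIANS, n_subjects=5, noise_cv=0.0, seed=3,
            phases=("ascending", "descending"), phase_offset=4.5,
        )
        res = hysteresis(table)
        assert np.allclose(res.summary["median"], 4.5)

    def test_single_phase_cell_skipped_and_reported(self):
        table = generate_physiology_table(
            self.MEDIANS, n_subjects=2, noise_cv=0.0, seed=0,
            phases=("ascending", "descending"),
        )
        drop = (
            (table.subject == "s1")
            & (table.phase == "ascending")
            & (table.peep_cmH2O == 5.0)
            & (table.endpoint == "pf_ratio")
        )
        table = table[~drop]
        res = hysteresis(table)
        assert ("s1", "healthy", "pf_ratio", 5.0) in res.skipped
        assert len(res.deltas) == 3


class TestImputation:
    @staticmethod
    def three_subject_table(blank=None):
        # s3 is exactly 10% above the mean of s1 and s2 everywhere
        peeps = [5.0, 12.0, 17.0]
        base = {5.0: 100.0, 12.0: 90.0, 17.0: 80.0}
        rows = []
        for subject, factor in (("s1", 0.9), ("s2", 1.1), ("s3", 1.1)):
            for p in peeps:
                mean_others = base[p]  # s1 and s2 average to base by construction
                value = base[p] * factor if subject != "s3" else 1.1 * mean_others
                rows.append(
                    dict(subject=subject, condition="healthy", phase="descending",
                         peep_cmH2O=p, endpoint="elastance_rs", value=value)
                )
        df = pd.DataFrame(rows)
        if blank is not None:
            hit = (df.subject == blank[0]) & (df.peep_cmH2O == blank[1])
            df.loc[hit, "value"] = np.nan
        return df

    def test_biased_subject_imputed_at_its_bias(self):
        """s3 runs 10% above the others; its blanked cell = 1.1 x others' mean."""
        df = self.three_subject_table(blank=("s3", 12.0))
        out, report = impute_missing(df)
        assert report == []
        got = out[(out.subject == "s3") & (out.peep_cmH2O == 12.0)]["value"].iloc[0]
        assert got == pytest.approx(1.1 * 90.0)

    def test_hand_computed_brute_force_oracle(self):
        # irregular 3-subject table, one blank; oracle applied by hand:
        # others' means at observed cells j' of s3: (10+14)/2=12, (30+34)/2=32
        # ratios: 18/12 = 1.5, 40/32 = 1.25  ->  r_s3 = 1.375
        # others' mean at the blank: (20+24)/2 = 22  ->  imputed = 30.25
        rows = []
        values = {
            ("s1", 5.0): 10.0, ("s1", 12.0): 20.0, ("s1", 17.0): 30.0,
            ("s2", 5.0): 14.0, ("s2", 12.0): 24.0, ("s2", 17.0): 34.0,
            ("s3", 5.0): 18.0, ("s3", 12.0): np.nan, ("s3", 17.0): 40.0,
        }
        for (s, p), v in values.items():
            rows.append(dict(subject=s, condition="healthy", phase="descending",
                             peep_cmH2O=p, endpoint="e", value=v))
        out, report = impute_missing(pd.DataFrame(rows))
        assert report == []
        got = out[(out.subject == "s3") & (out.peep_cmH2O == 12.0)]["value"].iloc[0]
        assert got == pytest.approx(30.25)

    def test_noop_on_complete_table(self):
        df = self.three_subject_table()
        out, report = impute_missing(df)
        assert report == []
        pd.testing.assert_frame_equal(out, df)

    def test_scale_equivariance(self):
        df = self.three_subject_table(blank=("s3", 12.0))
        out1, _ = impute_missing(df)
        scaled = df.copy()
        scaled["value"] = scaled["value"] * 3.0
        out2, _ = impute_missing(scaled)
        v1 = out1[(out1.subject == "s3") & (out1.peep_cmH2O == 12.0)]["value"].iloc[0]
        v2 = out2[(out2.subject == "s3") & (out2.peep_cmH2O == 12.0)]["value"].iloc[0]
        assert v2 == pytest.approx(3.0 * v1)

    def test_unimputable_cell_reported(self):
        # every subject missing at PEEP 12: no "others" observed there
        df = self.three_subject_table()
        df.loc[df.peep_cmH2O == 12.0, "value"] = np.nan
        out, report = impute_missing(df)
        assert len(report) == 3
        assert out["value"].isna().sum() == 3

    def test_imputation_feeds_best_peep(self):
        df = self.three_subject_table(blank=("s3", 12.0))
        out, _ = impute_missing(df)
        res = best_peep(out, "elastance_rs", "lowest")
        assert res.peep_cmH2O == 17.0
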