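"""Synthetic cohort generator: structure, names, effects, censoring."""

import io

import numpy as np
import pytest

from evohdtree.io import filter_by_presence, make_comparison, impute_half_lod, write_matrix
from evohdtree.simulate import (
    SimConfig,
    default_effects,
    make_rank_pair_dataset,
    make_threshold_dataset,
    p180_feature_names,
    simulate,
)


class TestFeatureNames:
    def test_default_panel_shape(self):
        df = p180_feature_names()
        assert len(df) == 188
        assert not df["metabolite"].duplicated().any()
        assert df["compound_class"].value_counts()["PC"] == 76

    def test_name_conventions(self):
        names = set(p180_feature_names()["metabolite"])
        assert {"Taurine", "Glutamate", "SM C24:1", "lysoPC a C18:0", "C2"} <= names
        assert any(n.startswith("PC aa C") for n in names)
        assert any(n.startswith("PC ae C") for n in names)


@pytest.fixture(scope="module")
def cohort():
    return simulate(SimConfig(seed=42))


class TestDefaultCohort:
    def test_shapes_and_groups(self, cohort):
        m, _ = cohort
        assert m.values.shape == (235, 188)
        counts = m.group.value_counts().to_dict()
        assert counts == {"GI": 3, "GII": 15, "GIII": 10, "GIV": 66, "MT": 70, "Con": 71}
        assert m.batch.nunique() == 3

    def test_concentrations_positive(self, cohort):
        m, _ = cohort
        vals = m.values.to_numpy()
        assert np.nanmin(vals) > 0

    def test_lod_censoring_is_consistent(self, cohort):
        m, _ = cohort
        # every recorded value is at or above its batch LOD
        for b in m.batch.unique():
            sub = m.values[(m.batch == b).to_numpy()]
            lods = m.lod[b].to_numpy()
            observed = sub.to_numpy()
            ok = np.isnan(observed) | (observed >= lods[None, :])
            assert ok.all()

    def test_well_detected_censoring_near_lod_quantile(self, cohort):
        m, truth = cohort
        low = set(truth.low_detect_metabolites)
        cols = [c for c in m.metabolite_names if c not in low]
        frac = m.values[cols].isna().to_numpy().mean()
        assert abs(frac - 0.05) < 0.03

    def test_presence_filter_has_work_to_do(self, cohort):
        m, _ = cohort
        kept = filter_by_presence(m).n_metabolites
        assert 140 <= kept < 188

    def test_planted_univariate_shift_visible(self, cohort):
        m, truth = cohort
        full = impute_half_lod(filter_by_presence(m, 1e-9))
        logv = np.log(full.values)
        for met, grp, shift in truth.univariate_markers:
            delta = (
                logv.loc[(full.group == grp).to_numpy(), met].mean()
                - logv.loc[(full.group == "Con").to_numpy(), met].mean()
            )
            if grp == "Con":
                continue
            assert np.sign(delta) == np.sign(shift)

    def test_planted_rank_reversal_flips_majority_ordering(self, cohort):
        m, truth = cohort
        full = impute_half_lod(filter_by_presence(m, 1e-9))
        for a, b, grp in truth.bivariate_pairs:
            in_grp = (full.group == grp).to_numpy()
            in_con = (full.group == "Con").to_numpy()
            frac_grp = (full.values.loc[in_grp, a] > full.values.loc[in_grp, b]).mean()
            frac_con = (full.values.loc[in_con, a] > full.values.loc[in_con, b]).mean()
            assert frac_con > 0.5 > frac_grp  # ordering flips in the target group


class TestDeterminismAndValidation:
    def test_byte_identical_csv(self):
        cfg = SimConfig(group_sizes={"GIV": 10, "Con": 10}, seed=5)
        outs = []
        for _ in range(2):
            m, _ = simulate(cfg)
            buf, lod_buf = io.StringIO(), io.StringIO()
            write_matrix(m, buf, lod_buf)
            outs.append((buf.getvalue(), lod_buf.getvalue()))
        assert outs[0] == outs[1]

    def test_different_seed_differs(self):
        m1, _ = simulate(SimConfig(group_sizes={"GIV": 5, "Con": 5}, seed=1))
        m2, _ = simulate(SimConfig(group_sizes={"GIV": 5, "Con": 5}, seed=2))
        assert not m1.values.equals(m2.values)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown groups"):
            SimConfig(group_sizes={"XX": 5}).validate()

    def test_unknown_effect_rejected(self):
        cfg = SimConfig(
            group_sizes={"GIV": 5, "Con": 5},
            univariate_effects=[("NotAMetabolite", "GIV", 1.0)],
        )
        with pytest.raises(ValueError, match="unknown"):
            simulate(cfg)

    def test_default_effects_respect_available_groups(self):
        names = p180_feature_names()["metabolite"].tolist()
        uni, bi = default_effects(names, groups={"GIV", "Con"})
        assert all(g == "GIV" for _, g, _ in uni)
        assert all(g == "GIV" for _, _, g in bi)

    def test_quantile_bounds_validated(self):
        with pytest.raises(ValueError):
            SimConfig(lod_quantile=1.0).validate()


class TestPlantedConstructions:
    def test_threshold_dataset_separates_exactly(self):
        d = make_threshold_dataset(threshold=5.0, seed=3)
        left = d.values[:, 0] <= 5.0
        assert (d.y[left] == 0).all() and (d.y[~left] == 1).all()

    def test_rank_pair_dataset_orders_by_class(self):
        d = make_rank_pair_dataset(pair=(0, 1), seed=4)
        gt = d.values[:, 0] > d.values[:, 1]
        assert (gt == (d.y == 1)).all()

    def test_rank_pair_marginals_overlap(self):
        # neither feature alone should separate the classes
        d = make_rank_pair_dataset(seed=5)
        for j in (0, 1):
            pos, neg = d.values[d.y == 1, j], d.values[d.y == 0, j]
            assert pos.min() < neg.max() and neg.min() < pos.max()


def test_small_cohort_supports_comparison(small_cohort):
    m, _ = small_cohort
    d = make_comparison(impute_half_lod(filter_by_presence(m)), ["GIV"], ["Con"])
    assert d.n_samples == 30
    assert d.y.sum() == 15
    assert d.n_features > 100
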