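"""RM-ASCA+ decomposition: effect matrices, PCA contracts, recovery."""

import numpy as np
import pandas as pd
import pytest

from rmasca import (
    GroupFactor,
    RMASCA,
    build_design_matrix,
    center_and_scale,
    combine_effect_matrices,
    construct_effect_matrix,
    pca_on_effect,
    run_rm_asca,
)
from rmasca.asca import EffectMatrix, parse_combination
from rmasca.design import cell_grid
from rmasca.lmm import RandomInterceptModel
from rmasca.simulate import SimulationConfig, VariableEffects, simulate_cohort

from conftest import make_noiseless


class TestCenterAndScale:
    def test_means_removed_exactly(self):
        x = np.random.default_rng(0).normal(size=(30, 4)) + [10, -5, 0.1, 3]
        z, means, scales = center_and_scale(x)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)

    def test_standardized_input_scales_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(500, 3))
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        _, _, scales = center_and_scale(x)
        assert np.allclose(scales, 1.0, atol=1e-12)

    def test_round_trip_inverse(self):
        x = np.random.default_rng(2).normal(size=(20, 5)) * 7 + 3
        z, means, scales = center_and_scale(x)
        assert np.allclose(z * scales + means, x, atol=1e-12)

    def test_zero_variance_column_named(self):
        x = np.ones((10, 2))
        x[:, 1] = np.arange(10)
        with pytest.raises(ValueError, match="flat_var"):
            center_and_scale(x, names=["flat_var", "ok"])


def _fit_pieces(registry, group_names, **kwargs):
    cfg, ds = make_noiseless(registry, group_names, **kwargs)
    factor = GroupFactor("group", group_names, coding="reference", reference_level=group_names[0])
    design = build_design_matrix(ds.frame, factor)
    model = RandomInterceptModel(design.X, ds.frame["patient_id"], design.columns)
    fits = {n: model.fit(ds.frame[n].to_numpy(), variable=n) for n in registry.names}
    return cfg, ds, factor, design, fits


class TestEffectMatrices:
    def test_additivity_of_single_effects(self, met_registry):
        cfg, ds, factor, design, fits = _fit_pieces(met_registry, ("Gr1", "Gr2"))
        names = met_registry.names
        singles = [
            construct_effect_matrix(fits, design, (e,), names)
            for e in ("time", "group", "time:group")
        ]
        combo = construct_effect_matrix(fits, design, ("time", "group", "time:group"), names)
        summed = combine_effect_matrices(singles)
        assert np.allclose(summed.values, combo.values, atol=1e-12)
        assert summed.effects == ("time", "group", "time:group")

    def test_reference_group_rows_zero_for_group_and_interaction(self, met_registry):
        cfg, ds, factor, design, fits = _fit_pieces(met_registry, ("Gr1", "Gr2"))
        em = construct_effect_matrix(fits, design, ("group", "time:group"), met_registry.names)
        ref_rows = em.cells["level"] == "Gr1"
        assert np.allclose(em.values[ref_rows.to_numpy()], 0.0, atol=1e-12)

    def test_zero_matrix_is_additive_identity(self, met_registry):
        cfg, ds, factor, design, fits = _fit_pieces(met_registry, ("Gr1", "Gr2"))
        em = construct_effect_matrix(fits, design, ("time",), met_registry.names)
        zero = EffectMatrix(
            effects=(), cells=em.cells.copy(), values=np.zeros_like(em.values),
            variables=em.variables, weights=em.weights.copy(),
        )
        combined = em + zero
        assert np.allclose(combined.values, em.values)
        assert combined.effects == ("time",)

    def test_grid_mismatch_rejected(self, met_registry):
        cfg, ds, factor, design, fits = _fit_pieces(met_registry, ("Gr1", "Gr2"))
        em = construct_effect_matrix(fits, design, ("time",), met_registry.names)
        other = EffectMatrix(
            effects=(), cells=em.cells.iloc[:5].reset_index(drop=True),
            values=em.values[:5], variables=em.variables, weights=em.weights[:5],
        )
        with pytest.raises(ValueError):
            combine_effect_matrices([em, other])

    def test_missing_fits_rejected(self, met_registry):
        cfg, ds, factor, design, fits = _fit_pieces(met_registry, ("Gr1", "Gr2"))
        del fits["glutamine"]
        with pytest.raises(ValueError, match="glutamine"):
            construct_effect_matrix(fits, design, ("time",), met_registry.names)


class TestPCA:
    def _rank1_effect(self, n_cells=10, n_vars=26, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.normal(size=n_cells)
        c = rng.normal(size=n_vars)
        cells = pd.DataFrame({"visit": ["T1"] * n_cells, "level": [str(i) for i in range(n_cells)]})
        return EffectMatrix(
            effects=("time",), cells=cells, values=np.outer(t, c),
            variables=[f"v{i}" for i in range(n_vars)], weights=np.ones(n_cells),
        )

    def test_rank1_explained_variance_is_one(self):
        sl = pca_on_effect(self._rank1_effect(), n_components=2)
        assert sl.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_truncated_svd_oracle(self):
        em = self._rank1_effect(seed=3)
        em.values = em.values + np.random.default_rng(4).normal(size=em.values.shape)
        sl = pca_on_effect(em, n_components=3)
        # Independent oracle: rank-k reconstruction from scipy's SVD of the
        # weighted matrix must match scores @ loadings reconstruction.
        from scipy.linalg import svd as scipy_svd

        w = em.weights / em.weights.sum()
        U, s, Vt = scipy_svd(np.sqrt(w)[:, None] * em.values, full_matrices=False)
        k = 3
        oracle = (U[:, :k] * s[:k]) @ Vt[:k]
        mine = np.sqrt(w)[:, None] * (sl.scores @ sl.loadings)
        assert np.linalg.norm(mine - oracle) < 1e-8

    def test_loadings_unit_norm_and_orthogonal(self):
        em = self._rank1_effect(seed=5)
        em.values = em.values + np.random.default_rng(6).normal(size=em.values.shape)
        sl = pca_on_effect(em, n_components=3)
        gram = sl.loadings @ sl.loadings.T
        assert np.allclose(gram, np.eye(3), atol=1e-10)

    def test_sign_convention_largest_loading_positive(self):
        sl = pca_on_effect(self._rank1_effect(seed=7), n_components=1)
        i = np.argmax(np.abs(sl.loadings[0]))
        assert sl.loadings[0, i] > 0

    def test_scores_are_projection_of_effect_matrix(self):
        em = self._rank1_effect(seed=8)
        em.values = em.values + np.random.default_rng(9).normal(size=em.values.shape)
        sl = pca_on_effect(em, n_components=2)
        assert np.allclose(sl.scores, em.values @ sl.loadings.T, atol=1e-10)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_on_effect(self._rank1_effect(n_cells=3), n_components=10)

    def test_explained_variance_invariant_to_variable_order(self):
        em = self._rank1_effect(seed=10)
        em.values = em.values + np.random.default_rng(11).normal(size=em.values.shape)
        sl = pca_on_effect(em, n_components=2)
        perm = np.random.default_rng(12).permutation(em.values.shape[1])
        em2 = EffectMatrix(
            effects=em.effects, cells=em.cells.copy(), values=em.values[:, perm],
            variables=[em.variables[i] for i in perm], weights=em.weights.copy(),
        )
        sl2 = pca_on_effect(em2, n_components=2)
        assert np.allclose(sl.explained_variance_ratio, sl2.explained_variance_ratio, atol=1e-10)


class TestCombinationParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("time", ("time",)),
            ("group + time*group", ("group", "time:group")),
            ("time + group + time:group", ("time", "group", "time:group")),
        ],
    )
    def test_parse(self, text, expected):
        assert parse_combination(text) == expected

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            parse_combination("time + batch")


class TestPipeline:
    def test_shared_time_trend_recovered(self, met_registry):
        """Noiseless planted shared time trend: PC1 trajectories identical
        across groups and PC1 loadings aligned with the planted direction."""
        rng = np.random.default_rng(42)
        direction = rng.normal(size=26)
        lib = {}
        for k, name in enumerate(met_registry.names):
            eff = VariableEffects.zeros(3)
            eff.time = direction[k] * np.array([0.25, 0.5, 0.75, 1.0])
            lib[name] = eff
        cfg, ds = make_noiseless(
            met_registry, ("Gr1", "Gr2", "Gr3"), n_patients=9, effect_library=lib
        )
        factor = GroupFactor("group", ("Gr1", "Gr2", "Gr3"), coding="sum")
        res = run_rm_asca(ds, factor, combination="time", scale=False)
        scores = res.scores.pivot(index="visit", columns="level", values="PC1")
        assert np.allclose(scores.std(axis=1), 0.0, atol=1e-10)
        cos = np.abs(res.scores_loadings.loadings[0] @ direction) / np.linalg.norm(direction)
        assert cos > 0.99

    def test_survivor_reference_flat_line(self, met_registry):
        cfg = SimulationConfig(registry=met_registry, n_patients=40, group_names=("survivor", "non-survivor"), seed=2)
        ds = simulate_cohort(cfg)
        factor = GroupFactor(
            "group", ("survivor", "non-survivor"),
            coding="reference", reference_level="survivor",
        )
        res = run_rm_asca(ds, factor, combination="group + time:group")
        ref = res.scores[res.scores["level"] == "survivor"]
        assert np.allclose(ref[["PC1", "PC2"]].to_numpy(), 0.0, atol=1e-12)

    def test_null_group_effects_give_zero_scores(self, met_registry):
        cfg, ds = make_noiseless(met_registry, ("Gr1", "Gr2"), n_patients=8, effect_library={})
        factor = GroupFactor("group", ("Gr1", "Gr2"), coding="reference", reference_level="Gr1")
        res = run_rm_asca(ds, factor, combination="group + time:group", scale=False)
        assert np.allclose(res.scores_loadings.scores, 0.0, atol=1e-10)

    def test_decomposition_completeness_noiseless_balanced(self, met_registry):
        """Observations minus the fitted intercept equal the summed time,
        group and interaction effect rows of their design cell."""
        lib = {}
        rng = np.random.default_rng(5)
        for name in met_registry.names:
            eff = VariableEffects.zeros(2)
            eff.time = rng.normal(size=4)
            eff.group = rng.normal(size=2)
            eff.interaction = rng.normal(size=(4, 2))
            lib[name] = eff
        cfg, ds = make_noiseless(met_registry, ("Gr1", "Gr2"), n_patients=8, effect_library=lib)
        factor = GroupFactor("group", ("Gr1", "Gr2"), coding="sum")
        res = run_rm_asca(ds, factor, "time + group + time:group", scale=False)
        intercepts = np.array([res.fits[n].beta[0] for n in met_registry.names])
        em = res.effect_matrix
        cell_lookup = {
            (v, l): i for i, (v, l) in enumerate(zip(em.cells["visit"], em.cells["level"]))
        }
        centered = ds.values - res.column_means - intercepts
        for i, row in ds.frame.iterrows():
            cell = cell_lookup[(row["visit"], row["group"])]
            assert np.allclose(centered[i], em.values[cell], atol=1e-8)

    def test_summary_mentions_effects_and_variance(self, small_cohort, five_group_factor):
        res = run_rm_asca(small_cohort, five_group_factor)
        text = res.summary()
        assert "time + group + time:group" in text
        assert "PC1" in text and "%" in text
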