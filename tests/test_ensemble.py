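"""Ensemble orchestration: grid completeness, replication-cell isolation,
determinism, and summary/variance-decomposition behavior."""

import pytest

from mtoboot import EnsembleConfig, run_coefficient_ensemble, run_specification_ensemble
from mtoboot.effects import ARM_CONTRASTS, EffectEstimate
from mtoboot.ensemble import (
    EnsembleCell,
    cells_to_frame,
    run_cell,
    summarize_ensemble,
)
from mtoboot.model import ConfigurationError, ModelSpec


@pytest.fixture(scope="module")
def tiny_ens_config():
    return EnsembleConfig(
        n_coef_draws=2,
        pr_seeds=[123, 1234567],
        mi_seeds=[524230, 524232],
        m_imputations=2,
    )


@pytest.fixture(scope="module")
def coef_cells(cohort, fitted_model, tiny_ens_config):
    return run_coefficient_ensemble(cohort, fitted_model, tiny_ens_config)


class TestCoefficientEnsemble:
    def test_grid_completeness(self, coef_cells, tiny_ens_config):
        assert len(coef_cells) == 2 * 2 * 2
        coords = {(c.index, c.pr_seed, c.mi_seed) for c in coef_cells}
        assert len(coords) == len(coef_cells)

    def test_exactly_one_replication_cell(self, coef_cells):
        flagged = [c for c in coef_cells if c.is_replication_cell]
        assert len(flagged) == 1
        assert flagged[0].index == 1
        assert (flagged[0].pr_seed, flagged[0].mi_seed) == (1234567, 524232)

    def test_single_cell_grid_is_the_replication_cell(self, cohort, fitted_model):
        config = EnsembleConfig(
            n_coef_draws=1, pr_seeds=[1234567], mi_seeds=[524232], m_imputations=2
        )
        cells = run_coefficient_ensemble(cohort, fitted_model, config)
        assert len(cells) == 1 and cells[0].is_replication_cell and cells[0].ok

    def test_rerun_is_cell_for_cell_identical(self, cohort, fitted_model,
                                              tiny_ens_config, coef_cells):
        again = run_coefficient_ensemble(cohort, fitted_model, tiny_ens_config)
        for a, b in zip(coef_cells, again):
            for contrast in ARM_CONTRASTS:
                assert a.estimates[contrast].log_or == b.estimates[contrast].log_or
                assert a.estimates[contrast].se == b.estimates[contrast].se

    def test_no_cross_cell_rng_leakage(self, cohort, fitted_model, coef_cells):
        """The replication cell is bit-identical standalone vs in-grid."""
        in_grid = next(c for c in coef_cells if c.is_replication_cell)
        standalone = run_cell(
            cohort, fitted_model, pr_seed=1234567, mi_seed=524232, m=2
        )
        for contrast in ARM_CONTRASTS:
            assert standalone[contrast].log_or == in_grid.estimates[contrast].log_or
            assert standalone[contrast].se == in_grid.estimates[contrast].se

    def test_estimation_failure_is_cell_local(self, cohort, fitted_model,
                                              tiny_ens_config):
        broken = cohort[cohort["arm"] != "traditional"].reset_index(drop=True)
        cells = run_coefficient_ensemble(broken, fitted_model, tiny_ens_config)
        assert len(cells) == 8  # grid complete, failures flagged not fatal
        assert all(not c.ok and "traditional" in c.error for c in cells)
        with pytest.raises(ValueError, match="no successful cells"):
            summarize_ensemble(cells)


class TestSpecificationEnsemble:
    def test_restricted_spec_grid_cardinality(self, training_sample, cohort):
        config = EnsembleConfig(
            mode="specification_grid",
            pr_seeds=[1234567],
            mi_seeds=[524230, 524232],
            m_imputations=2,
        )
        specs = [ModelSpec.from_label("a1r1s99"), ModelSpec.from_label("a0r0s40")]
        cells = run_specification_ensemble(training_sample, cohort, config, specs=specs)
        assert len(cells) == 2 * 1 * 2
        flagged = [c for c in cells if c.is_replication_cell]
        assert len(flagged) == 1 and flagged[0].index == "a1r1s99"
        # age-capped cells record the capped training subset in provenance
        for cell in cells:
            if cell.index == "a0r0s40":
                assert cell.provenance["training_max_age"] <= 40


class TestSummaries:
    def _constant_cells(self, log_or=0.5, se=0.1):
        cells = []
        for idx in (1, 2):
            for pr in (123, 1234):
                for mi in (524230, 524231):
                    est = {
                        c: EffectEstimate(c, log_or, se, m_used=2)
                        for c in ARM_CONTRASTS
                    }
                    cells.append(EnsembleCell(idx, pr, mi, estimates=est))
        return cells

    def test_constant_cells_have_zero_components_and_binary_fraction(self):
        summary = summarize_ensemble(self._constant_cells())
        for contrast in ARM_CONTRASTS:
            comp = summary["contrasts"][contrast]["log_or_variance_components"]
            for key in ("index", "pr_seed", "mi_seed", "residual", "total"):
                assert comp[key] == pytest.approx(0.0, abs=1e-15)
            assert summary["contrasts"][contrast]["fraction_ci_above_1"] in (0.0, 1.0)

    def test_pr_seed_only_variation_is_fully_attributed(self):
        """Constructed decomposition oracle: when log-OR depends only on
        pr_seed, all non-residual variance lands on the pr_seed factor."""
        cells = self._constant_cells()
        for cell in cells:
            value = 1.0 if cell.pr_seed == 123 else -1.0
            cell.estimates = {
                c: EffectEstimate(c, value, 0.1, m_used=2) for c in ARM_CONTRASTS
            }
        summary = summarize_ensemble(cells)
        comp = summary["contrasts"]["low_poverty_vs_control"]["log_or_variance_components"]
        assert comp["total"] == pytest.approx(1.0)
        assert comp["pr_seed"] == pytest.approx(1.0)
        assert comp["index"] == pytest.approx(0.0, abs=1e-15)
        assert comp["mi_seed"] == pytest.approx(0.0, abs=1e-15)
        assert comp["residual"] == pytest.approx(0.0, abs=1e-12)

    def test_summary_is_permutation_invariant(self, coef_cells):
        forward = summarize_ensemble(coef_cells)
        backward = summarize_ensemble(list(reversed(coef_cells)))
        assert forward == backward

    def test_cells_frame_shape(self, coef_cells):
        frame = cells_to_frame(coef_cells)
        assert len(frame) == len(coef_cells) * len(ARM_CONTRASTS)
        assert frame["is_replication_cell"].sum() == len(ARM_CONTRASTS)


class TestConfigValidation:
    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ConfigurationError, match="pr_seeds"):
            EnsembleConfig(pr_seeds=[1, 1])
        with pytest.raises(ConfigurationError, match="mi_seeds"):
            EnsembleConfig(mi_seeds=[5, 5])

    def test_default_seed_grids_match_the_reanalysis(self):
        config = EnsembleConfig()
        assert config.pr_seeds == [123, 1234, 12345, 123456, 1234567]
        assert config.mi_seeds == list(range(524230, 524240))
        assert config.n_coef_draws == 10
        assert config.m_imputations == 20


def test_plot_writes_vector_graphic(coef_cells, tmp_path):
    from mtoboot.ensemble import plot_ensemble

    out = tmp_path / "panel.svg"
    plot_ensemble(coef_cells, out)
    text = out.read_text()
    assert text.lstrip().startswith("<?xml") and "svg" in text[:300]
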