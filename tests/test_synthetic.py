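import numpy as np
import pandas as pd
import pytest

from mirtemporal.io import ExpressionMatrix
from mirtemporal.synthetic import (
    CohortConfig,
    PlantedCoR,
    TemporalTemplate,
    coupling_slope_for_r,
    default_templates,
    generate_cohort,
    generate_mirna_counts,
    generate_mrna_matrix,
    generate_target_map,
    mirna_group_assignment,
    mirna_group_sets,
)


def flat_templates(n: int = 9) -> tuple[TemporalTemplate, ...]:
    return tuple(
        TemporalTemplate(f"flat{i}", lambda t: np.zeros_like(t), amplitude=0.0)
        for i in range(n)
    )


class TestCohort:
    def test_study_layout(self):
        cfg = CohortConfig(seed=1)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 143
        assert (cohort.data["diagnosis"] == "case").sum() == 34
        ages = cohort.controls().data["age_years"]
        assert ages.min() < 0 < ages.max()  # fetal through adult coverage
        assert ages.max() <= 73.3

    def test_determinism(self):
        cfg = CohortConfig(seed=5)
        a = generate_cohort(cfg).data
        b = generate_cohort(cfg).data
        pd.testing.assert_frame_equal(a, b)

    def test_control_only_cohort_has_no_doses(self):
        cfg = CohortConfig(n_case=0, seed=2)
        cohort = generate_cohort(cfg)
        assert len(cohort) == cfg.n_control
        assert cohort.data["cpze_lifetime"].isna().all()

    def test_case_doses_populated(self):
        cohort = generate_cohort(CohortConfig(seed=3))
        cases = cohort.cases().data
        assert cases["cpze_lifetime"].notna().all()
        assert cases["cpze_daily"].notna().all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="age range"):
            CohortConfig(age_range_years=(5.0, 5.0))
        with pytest.raises(ValueError, match="n_case"):
            CohortConfig(n_case=-1)
        with pytest.raises(ValueError, match="does not exist"):
            CohortConfig(planted_de=(("miR-nope", 2.0),))
        with pytest.raises(ValueError, match="n_groups"):
            CohortConfig(n_groups=5)


class TestMirnaCounts:
    def test_determinism_and_dtype(self):
        cfg = CohortConfig(n_control=30, n_case=10, n_mirna=45, seed=7)
        cohort = generate_cohort(cfg)
        a = generate_mirna_counts(cohort, cfg)
        b = generate_mirna_counts(cohort, cfg)
        assert np.array_equal(a.values, b.values)
        assert a.values.dtype == np.int64
        assert (a.values >= 0).all()

    def test_flat_templates_give_flat_expected_profiles(self):
        cfg = CohortConfig(
            n_control=100, n_case=0, n_mirna=18, templates=flat_templates(),
            batch_effect_sd=0.0, seed=11,
        )
        cohort = generate_cohort(cfg)
        counts = generate_mirna_counts(cohort, cfg)
        cpm = counts.values * 1e6 / counts.values.sum(axis=0, keepdims=True)
        ages = cohort.data["age_years"].to_numpy()
        young, old = ages < 1.0, ages > 18.0
        ratio = np.log2(cpm[:, young].mean(axis=1) / cpm[:, old].mean(axis=1))
        assert np.abs(ratio).max() < 0.25  # no age trend beyond NB noise

    def test_planted_fold_change_recovered(self):
        """Monte-Carlo mean of the empirical case/control CPM log-ratio of a
        planted miRNA sits within +/- 0.3 of the planted value (flat
        templates, so age structure does not confound the arm contrast)."""
        ratios = []
        for rep in range(200):
            cfg = CohortConfig(
                n_control=40, n_case=40, n_mirna=45,
                templates=flat_templates(),
                planted_de=(("miR-0001", 2.0),), seed=1000 + rep,
            )
            cohort = generate_cohort(cfg)
            counts = generate_mirna_counts(cohort, cfg)
            cpm = counts.values * 1e6 / counts.values.sum(axis=0, keepdims=True)
            is_case = (cohort.data["diagnosis"] == "case").to_numpy()
            ratios.append(
                np.log2(cpm[0, is_case].mean() / cpm[0, ~is_case].mean())
            )
        assert abs(np.mean(ratios) - 2.0) < 0.3

    def test_group_shift_moves_group_up(self):
        cfg = CohortConfig(n_control=60, n_case=40, n_mirna=90,
                           group_shift=((8, 1.0),), seed=21)
        cohort = generate_cohort(cfg)
        counts = generate_mirna_counts(cohort, cfg)
        cpm = counts.values * 1e6 / counts.values.sum(axis=0, keepdims=True)
        is_case = (cohort.data["diagnosis"] == "case").to_numpy()
        lr = np.log2(cpm[:, is_case].mean(axis=1) / cpm[:, ~is_case].mean(axis=1))
        g8 = mirna_group_assignment(cfg) == 8
        assert (lr[g8] > 0).mean() > 0.5  # majority of the shifted group up

    def test_mismatched_cohort_rejected(self):
        cfg = CohortConfig(n_control=30, n_case=10, seed=1)
        cohort = generate_cohort(CohortConfig(n_control=20, n_case=5, seed=1))
        with pytest.raises(ValueError, match="cohort size"):
            generate_mirna_counts(cohort, cfg)


class TestMrnaMatrix:
    def _log_cpm(self, counts: ExpressionMatrix) -> ExpressionMatrix:
        cpm = counts.values * 1e6 / counts.values.sum(axis=0, keepdims=True)
        return ExpressionMatrix(
            counts.feature_ids, counts.sample_ids, np.log2(cpm + 1.0), "log_cpm"
        )

    def test_tight_negative_coupling_limit(self):
        cfg = CohortConfig(
            n_control=60, n_case=0, n_mirna=45, n_mrna=60,
            coupling=(("miR-0001", "GENE0001", -1.0),), mrna_noise_sd=1e-4, seed=4,
        )
        cohort = generate_cohort(cfg)
        mlog = self._log_cpm(generate_mirna_counts(cohort, cfg))
        mrna = generate_mrna_matrix(cohort, cfg, mirna_log_cpm=mlog)
        r = np.corrcoef(mlog.values[0], mrna.values[0])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-3)

    def test_no_coupling_gives_near_zero_correlations(self):
        cfg = CohortConfig(n_control=80, n_case=0, n_mirna=27, n_mrna=60, seed=8)
        cohort = generate_cohort(cfg)
        mlog = self._log_cpm(generate_mirna_counts(cohort, cfg))
        mrna = generate_mrna_matrix(cohort, cfg)
        r = np.corrcoef(np.vstack([mlog.values, mrna.values]))[:27, 27:]
        assert np.abs(r).mean() < 0.15
        assert (np.abs(r) > 0.49).mean() < 0.01

    def test_calibrated_slope_hits_target_r(self):
        """Slope from coupling_slope_for_r recovers r ~ -0.71 at n=109."""
        rs = []
        for rep in range(30):
            cfg = CohortConfig(
                n_control=109, n_case=0, n_mirna=45, n_mrna=50, seed=300 + rep,
            )
            cohort = generate_cohort(cfg)
            mlog = self._log_cpm(generate_mirna_counts(cohort, cfg))
            sd_x = mlog.values[0].std(ddof=1)
            slope = coupling_slope_for_r(-0.71, sd_x, cfg.mrna_noise_sd)
            cfg2 = cfg.with_(coupling=(("miR-0001", "GENE0001", slope),))
            mrna = generate_mrna_matrix(cohort, cfg2, mirna_log_cpm=mlog)
            rs.append(np.corrcoef(mlog.values[0], mrna.values[0])[0, 1])
        assert np.mean(rs) == pytest.approx(-0.71, abs=0.05)

    def test_unknown_coupling_ids_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            CohortConfig(coupling=(("miR-0001", "NOPE", -1.0),))


class TestTargetMap:
    def test_planted_cor_genes_have_multiple_group_mirnas(self):
        pc = PlantedCoR(group=6, genes=("GENE0001", "GENE0002"), n_mirnas=3)
        cfg = CohortConfig(n_mirna=90, n_mrna=120, planted_cor=pc, seed=13)
        tm = generate_target_map(cfg)
        group6 = set(mirna_group_sets(cfg)["Group6"])
        for gene in pc.genes:
            rec = tm.records[tm.records["gene_id"] == gene]
            assert rec["mirna_id"].isin(group6).sum() >= 2

    def test_degenerate_empty_map_rejected(self):
        cfg = CohortConfig(n_mirna=9, n_mrna=5, target_density=0.0, seed=1)
        with pytest.raises(ValueError, match="degenerate"):
            generate_target_map(cfg)

    def test_too_many_planted_genes_rejected(self):
        genes = tuple(f"GENE{i + 1:04d}" for i in range(10))
        with pytest.raises(ValueError, match="exceeds n_mrna"):
            CohortConfig(n_mrna=5, planted_cor=PlantedCoR(group=1, genes=genes))

    def test_determinism(self):
        cfg = CohortConfig(n_mirna=45, n_mrna=60, seed=2)
        a, b = generate_target_map(cfg), generate_target_map(cfg)
        pd.testing.assert_frame_equal(a.records, b.records)


def test_yaml_config_round_trip(tmp_path):
    cfg = CohortConfig(
        n_control=30, n_case=10, n_mirna=45, n_mrna=60,
        planted_de=(("miR-0001", 2.0),), group_shift=((8, 1.0),),
        planted_cor=PlantedCoR(group=6, genes=("GENE0001",)),
        seed=42,
    )
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = CohortConfig.from_yaml(path)
    assert back.n_control == cfg.n_control
    assert back.planted_de == cfg.planted_de
    assert back.group_shift == cfg.group_shift
    assert back.planted_cor == cfg.planted_cor
    assert back.seed == cfg.seed
    # same seed, same cohort
    pd.testing.assert_frame_equal(generate_cohort(cfg).data, generate_cohort(back).data)


def test_default_templates_are_nine_and_bounded():
    templates = default_templates()
    assert len(templates) == 9
    t = np.linspace(6.8, 14.8, 200)
    for tpl in templates:
        vals = tpl.mean_log_expression(t)
        assert np.all(np.isfinite(vals))
        assert np.abs(vals).max() <= 2.0 * abs(tpl.amplitude)
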