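"""Synthetic cohort generator: determinism, schema conformance, effect recovery."""

import json

import numpy as np
import pytest

from ratconnectome.functional import partial_correlation_matrix, read_nuisance, read_time_series
from ratconnectome.metrics import strengths, summarize
from ratconnectome.regions import load_region_table, structural_nodes
from ratconnectome.stats import read_subjects
from ratconnectome.structural import build_structural_connectome, read_streamlines
from ratconnectome.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_time_series,
    make_synthetic_region_table,
    plant_regional_effect,
    random_sparse_precision,
)


SMALL = dict(n_per_group=3, n_regions_structural=15, n_regions_functional=10, T=100)


class TestConfig:
    def test_defaults_match_study_conditions(self):
        cfg = CohortConfig()
        assert cfg.n_per_group == 9
        assert (cfg.n_regions_structural, cfg.n_regions_functional) == (76, 54)
        assert (cfg.T, cfg.tr_seconds) == (600, 2.0)
        assert (cfg.age_mean_control, cfg.age_sd_control) == (151.11, 12.06)
        assert (cfg.age_mean_transgenic, cfg.age_sd_transgenic) == (181.0, 32.6)

    def test_infeasible_coupling_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            CohortConfig(behavior_coupling=1.0)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(edge_density=0.0)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = CohortConfig(seed=5, **SMALL)
        d1 = generate_cohort(cfg).write(tmp_path / "a")
        d2 = generate_cohort(CohortConfig(seed=5, **SMALL)).write(tmp_path / "b")
        for p1 in sorted(d1.rglob("*")):
            if p1.is_file():
                p2 = d2 / p1.relative_to(d1)
                assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(seed=1, **SMALL))
        b = generate_cohort(CohortConfig(seed=2, **SMALL))
        assert a.streamlines["ctl01"] != b.streamlines["ctl01"]


class TestSchemaConformance:
    def test_all_outputs_parse_through_readers(self, tmp_path, small_cohort):
        out = small_cohort.write(tmp_path / "cohort")
        table = load_region_table(out / "regions.tsv")
        nodes = structural_nodes(table)
        subjects = read_subjects(out / "subjects.csv")
        assert len(subjects) == 2 * small_cohort.config.n_per_group
        for s in subjects:
            records = read_streamlines(out / "streamlines" / f"{s.subject_id}.tsv", nodes)
            assert records  # builders accept them
            build_structural_connectome(records, table, "fd_weighted")
            ts = read_time_series(out / "timeseries" / f"{s.subject_id}.tsv")
            assert ts.n_regions == small_cohort.config.n_regions_functional
            nuis = read_nuisance(out / "timeseries" / f"{s.subject_id}_nuisance.tsv")
            assert nuis.regressors.shape[0] == ts.n_samples
        manifest = json.loads((out / "manifest.json").read_text())
        assert "planted_effects" in manifest

    def test_full_size_uses_packaged_table(self):
        cfg = CohortConfig(seed=0, modalities=("structural",), behavior_coupling=0.0)
        ds = generate_cohort(cfg)
        assert ds.region_table.n_structural == 76
        assert ds.region_table.n_functional == 54


class TestPlantedEffects:
    def test_fa_effect_lowers_transgenic_fa_weights(self, small_cohort):
        by_group = {"control": [], "transgenic": []}
        for s in small_cohort.subjects:
            conn = build_structural_connectome(
                small_cohort.streamlines[s.subject_id], small_cohort.region_table, "fa_weighted"
            )
            by_group[s.group].append(strengths(conn.weights).mean())
        assert np.mean(by_group["control"]) > np.mean(by_group["transgenic"])

    def test_ages_reproduce_group_models(self):
        cfg = CohortConfig(
            n_per_group=500,
            n_regions_structural=6,
            n_regions_functional=4,
            modalities=(),
            behavior_coupling=0.0,
            seed=3,
        )
        ds = generate_cohort(cfg)
        ages = {"control": [], "transgenic": []}
        for s in ds.subjects:
            ages[s.group].append(s.age_days)
        # within ~3 standard errors of the configured group means
        assert abs(np.mean(ages["control"]) - 151.11) < 3 * 12.06 / np.sqrt(500)
        assert abs(np.mean(ages["transgenic"]) - 181.0) < 3 * 32.6 / np.sqrt(500)

    def test_behavior_coupling_recovered(self):
        from scipy.stats import spearmanr

        cfg = CohortConfig(
            seed=8,
            n_per_group=40,
            n_regions_structural=15,
            n_regions_functional=10,
            modalities=("structural",),
            behavior_coupling=-0.85,
        )
        ds = generate_cohort(cfg)
        vals, outcome = [], []
        for s in ds.subjects:
            conn = build_structural_connectome(
                ds.streamlines[s.subject_id], ds.region_table, "fd_weighted"
            )
            _, glob = summarize(conn)
            vals.append(glob.avg_strength)
            outcome.append(s.behavior["training_sessions_total"])
        r = spearmanr(vals, outcome).statistic
        assert r < -0.6  # negative coupling planted at -0.85

    def test_regional_plant_shifts_only_incident_edges(self, small_cohort):
        region = small_cohort.region_table.frame.iloc[0]["region_name"]
        planted = plant_regional_effect(small_cohort, region, "fa", -0.5)
        nodes = structural_nodes(small_cohort.region_table)
        rid = [n.node_id for n in nodes if n.region_name == region][0]
        for s in small_cohort.subjects:
            before = build_structural_connectome(
                small_cohort.streamlines[s.subject_id], small_cohort.region_table, "fa_weighted"
            ).weights
            after = build_structural_connectome(
                planted.streamlines[s.subject_id], small_cohort.region_table, "fa_weighted"
            ).weights
            diff = ~np.isclose(before, after)
            if s.group == "control":
                assert not diff.any()
            else:
                changed = np.argwhere(diff)
                assert len(changed)
                assert all(rid in pair for pair in changed)

    def test_zero_delta_changes_only_manifest(self, small_cohort):
        region = small_cohort.region_table.frame.iloc[0]["region_name"]
        planted = plant_regional_effect(small_cohort, region, "fa", 0.0)
        assert planted.streamlines == small_cohort.streamlines
        assert planted.manifest["planted_effects"]["regional_effects"] == [[region, "fa", 0.0]]

    def test_plants_on_distinct_regions_commute(self, small_cohort):
        names = list(small_cohort.region_table.frame["region_name"][:2])
        ab = plant_regional_effect(
            plant_regional_effect(small_cohort, names[0], "fa", -0.2), names[1], "fa", -0.3
        )
        ba = plant_regional_effect(
            plant_regional_effect(small_cohort, names[1], "fa", -0.3), names[0], "fa", -0.2
        )
        for sid in ab.streamlines:
            fa_ab = [s.mean_fa for s in ab.streamlines[sid]]
            fa_ba = [s.mean_fa for s in ba.streamlines[sid]]
            np.testing.assert_allclose(fa_ab, fa_ba, rtol=1e-14)  # multiplication commutes up to rounding

    def test_unknown_region_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown region"):
            plant_regional_effect(small_cohort, "Nonexistent", "fa", -0.1)


class TestTimeSeriesGenerator:
    def test_identity_precision_near_zero_partials(self):
        ts = generate_time_series(np.eye(8), T=5000, seed=1, band_hz=None)
        pcorr = partial_correlation_matrix(ts)
        off = pcorr[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_planted_partial_correlation_recovered(self):
        p = np.eye(5)
        p[0, 1] = p[1, 0] = -0.6  # precision entry -> partial correlation +0.6
        ts = generate_time_series(p, T=5000, seed=2)
        pcorr = partial_correlation_matrix(ts)
        assert pcorr[0, 1] == pytest.approx(0.6, abs=0.1)

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            generate_time_series(np.eye(3), T=2, seed=0)

    def test_non_positive_definite_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            generate_time_series(bad, T=100, seed=0)

    def test_random_precision_is_spd(self, rng):
        for n in (5, 20, 54):
            P = random_sparse_precision(n, seed=int(rng.integers(1000)))
            assert np.linalg.eigvalsh(P).min() > 0


class TestSyntheticRegionTable:
    def test_sizes_and_validity(self):
        table = make_synthetic_region_table(20, 12)
        assert table.n_structural == 20
        assert table.n_functional == 12
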