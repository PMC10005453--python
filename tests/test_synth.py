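"""Unit tests for the synthetic study-bundle generator."""

import numpy as np
import pytest

from netpharm.admet import screen_compounds
from netpharm.synth import StudyConfig, generate_dose_response, generate_study
from netpharm.io import write_bundle


class TestConfigValidation:
    def test_defaults_valid(self):
        StudyConfig()

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_compounds": 0}, "n_compounds"),
            ({"frac_fail_qed": 1.5}, "frac_fail_qed"),
            ({"n_planted_key_compounds": 200, "n_compounds": 100}, "n_planted_key_compounds"),
            ({"n_disease_genes": 500, "n_genes": 400}, "n_disease_genes"),
            ({"pathway_size_range": (50, 10)}, "pathway_size_range"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            StudyConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = StudyConfig(seed=7)
        b1, t1 = generate_study(cfg)
        b2, t2 = generate_study(cfg)
        p1 = write_bundle(b1, tmp_path / "a", t1)
        p2 = write_bundle(b2, tmp_path / "b", t2)
        assert p1.keys() == p2.keys()
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_differs(self, tmp_path):
        b1, _ = generate_study(StudyConfig(seed=1))
        b2, _ = generate_study(StudyConfig(seed=2))
        assert not b1.compounds.equals(b2.compounds)


class TestBundleStructure:
    def test_sizes_match_config(self, default_bundle):
        bundle, _ = default_bundle
        cfg = StudyConfig()
        assert len(bundle.compounds) == cfg.n_compounds
        assert bundle.compounds["herbs"].str.split(";").explode().nunique() <= cfg.n_herbs
        assert len(bundle.disease_genes) == cfg.n_disease_genes
        assert len(bundle.pathways) == cfg.n_pathways

    def test_study_design_sizes(self):
        bundle, _ = generate_study(StudyConfig(n_compounds=119, n_herbs=9, seed=3))
        assert len(bundle.compounds) == 119
        herbs = set(bundle.compounds["herbs"].str.split(";").explode())
        assert len(herbs) == 9

    def test_symbols_within_universe(self, default_bundle):
        bundle, _ = default_bundle
        universe = {f"G{i + 1:04d}" for i in range(StudyConfig().n_genes)}
        assert set(bundle.compound_targets["gene_symbol"]) <= universe
        assert set(bundle.disease_genes["gene_symbol"]) <= universe
        assert set(bundle.ppi_edges["protein1"]) | set(bundle.ppi_edges["protein2"]) <= universe
        assert bundle.pathways.all_genes <= universe

    def test_no_ppi_self_loops_and_handshake(self, default_bundle):
        bundle, _ = default_bundle
        e = bundle.ppi_edges
        assert (e["protein1"] != e["protein2"]).all()
        deg = {}
        for u, v in zip(e["protein1"], e["protein2"]):
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        assert sum(deg.values()) == 2 * len(e)

    def test_planted_hubs_top_the_degree_distribution(self):
        bundle, truth = generate_study(
            StudyConfig(n_planted_hub_targets=3, n_genes=200, n_disease_genes=150, seed=1)
        )
        deg = {}
        for u, v in zip(bundle.ppi_edges["protein1"], bundle.ppi_edges["protein2"]):
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        top3 = sorted(deg, key=lambda s: -deg[s])[:3]
        assert set(top3) == set(truth.planted_hub_target_symbols)

    def test_planted_pathway_contains_hubs(self, default_bundle):
        bundle, truth = default_bundle
        planted = next(s for s in bundle.pathways if s.pathway_id == truth.planted_enriched_pathway_id)
        hubs = set(truth.planted_hub_target_symbols)
        assert len(hubs & set(planted.genes)) >= 0.5 * len(hubs)

    def test_planted_compounds_pass_screen(self, default_bundle):
        bundle, truth = default_bundle
        verdicts = screen_compounds(bundle.compounds).set_index("compound_id")
        assert verdicts.loc[truth.planted_key_compound_ids, "is_eac"].all()

    def test_fail_fractions_respected(self):
        cfg = StudyConfig(
            n_compounds=100, frac_fail_qed=0.2, frac_fail_veber=0.1,
            n_planted_key_compounds=0, seed=4,
        )
        bundle, _ = generate_study(cfg)
        verdicts = screen_compounds(bundle.compounds)
        assert int(verdicts["is_eac"].sum()) == 70
        assert int((~verdicts["veber_ok"]).sum()) == 10

    def test_ground_truth_ids_exist(self, default_bundle):
        bundle, truth = default_bundle
        assert set(truth.planted_key_compound_ids) <= set(bundle.compounds["compound_id"])
        assert set(truth.planted_hub_target_symbols) <= set(bundle.disease_genes["gene_symbol"])
        assert truth.planted_enriched_pathway_id in {s.pathway_id for s in bundle.pathways}
        assert all(v > 0 for v in truth.true_ic50_per_compound.values())


class TestDoseResponseGenerator:
    def test_zero_noise_midpoint(self):
        s = generate_dose_response((0.0, 83.0, 27.32, 1.5), [27.32], n_reps=4, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(s.responses, 41.5)

    def test_zero_noise_matches_closed_form(self):
        conc = np.geomspace(1, 100, 6)
        s = generate_dose_response((5.0, 90.0, 20.0, 1.2), conc, n_reps=2, noise_sd=0.0, seed=0)
        want = 5.0 + (90.0 - 5.0) / (1 + (np.repeat(conc, 2) / 20.0) ** 1.2)
        np.testing.assert_allclose(s.responses, want)

    def test_noise_sd_calibrated(self):
        """Per-concentration sample SD of 4 replicates at sigma = 2 lies in
        [0.5, 5] for >= 95% of grid points, aggregated over many seeds."""
        conc = np.geomspace(1, 100, 7)
        inside = total = 0
        for seed in range(200):
            s = generate_dose_response((0.0, 83.0, 27.32, 1.5), conc, n_reps=4, noise_sd=2.0, seed=seed)
            for c in conc:
                sd = s.responses[s.concentrations == c].std(ddof=1)
                inside += 0.5 <= sd <= 5.0
                total += 1
        assert inside / total >= 0.95

    def test_truncation_to_percent_range(self):
        s = generate_dose_response((0.0, 100.0, 10.0, 1.0), [0.01, 1e4], n_reps=50, noise_sd=10.0, seed=1)
        assert s.responses.min() >= 0.0
        assert s.responses.max() <= 100.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"params": (0, 80, -1.0, 1), "concentrations": [1.0]},
            {"params": (0, 80, 10.0, 1), "concentrations": [0.0]},
            {"params": (0, 80, 10.0, 1), "concentrations": [1.0], "n_reps": 0},
            {"params": (0, 80, 10.0, 1), "concentrations": [1.0], "noise_sd": -1.0},
        ],
    )
    def test_domain_errors(self, kwargs):
        kw = {"n_reps": 4, "noise_sd": 0.0, "seed": 0, **kwargs}
        with pytest.raises(ValueError):
            generate_dose_response(kw.pop("params"), kw.pop("concentrations"), **kw)
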