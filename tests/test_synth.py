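"""Generator determinism, distributional correctness, and planted structure."""

import numpy as np
import pytest
from scipy import stats

from longnet.io import DataError
from longnet.netstats import interconnectivity, permutation_null
from longnet.screen import classify_thrashing
from longnet.synth import (
    GOMPERTZ_SCALE,
    GOMPERTZ_SHAPE,
    WorldConfig,
    gen_annotations,
    gen_interactome,
    gen_lifespans,
    gen_orthology,
    gen_thrashing,
    gen_world,
    gompertz_survival,
    plant_core_module,
    sample_gompertz,
    write_world,
)

SMALL = WorldConfig(n_nodes=300, core_size=20, foreign_partner_sample=100,
                    n_effect_long=4, n_effect_short=3, n_animals=40)


class TestGenInteractome:
    def test_deterministic(self):
        a = gen_interactome(100, "erdos_renyi", seed=1, p=0.05)
        b = gen_interactome(100, "erdos_renyi", seed=1, p=0.05)
        assert a.edge_set() == b.edge_set()

    def test_scale_free_has_hubs(self):
        inter = gen_interactome(200, "scale_free", seed=7, m=2)
        degrees = [inter.degree(n) for n in inter.nodes]
        assert max(degrees) > 3 * np.mean(degrees)

    def test_too_small(self):
        with pytest.raises(DataError):
            gen_interactome(5)

    def test_unknown_model(self):
        with pytest.raises(DataError):
            gen_interactome(50, "smallworld")


class TestPlantCoreModule:
    def test_boost_one_is_identity(self):
        inter = gen_interactome(100, seed=2)
        planted, core = plant_core_module(inter, 10, density_boost=1, seed=3)
        assert planted.edge_set() == inter.edge_set()
        assert len(core) == 10

    def test_module_is_detectable(self):
        inter = gen_interactome(200, seed=3, m=2)
        planted, core = plant_core_module(inter, 20, density_boost=4, seed=3)
        null = permutation_null(planted, core, n_permutations=199, seed=5)
        assert null.p_value < 0.05

    def test_module_too_large(self):
        inter = gen_interactome(50, seed=1)
        with pytest.raises(DataError):
            plant_core_module(inter, 50, 2, seed=0)

    def test_density_above_one(self):
        inter = gen_interactome(12, "erdos_renyi", seed=1, p=0.5)
        with pytest.raises(DataError):
            plant_core_module(inter, 5, density_boost=10, seed=0)


class TestGenAnnotations:
    def test_extremes(self):
        inter = gen_interactome(50, seed=4)
        assert not any(gen_annotations(inter, 0.0, seed=1).values())
        assert all(gen_annotations(inter, 1.0, seed=1).values())

    def test_core_enrichment(self):
        inter = gen_interactome(600, seed=5)
        core = frozenset(sorted(inter.nodes)[:60])
        labels = gen_annotations(inter, 0.2, core_essential_enrichment=5, seed=6,
                                 core=core)
        core_rate = np.mean([labels[g] for g in core])
        bg_rate = np.mean([labels[g] for g in inter.nodes - core])
        assert core_rate == 1.0
        assert bg_rate == pytest.approx(0.2, abs=0.05)


class TestGenOrthology:
    def test_full_coverage_bijection(self):
        omap = gen_orthology(["a", "b", "c"], coverage=1.0, paralog_rate=0.0, seed=1)
        assert omap.forward() == {"a": {"h_a"}, "b": {"h_b"}, "c": {"h_c"}}

    def test_zero_coverage(self):
        assert len(gen_orthology(["a", "b"], coverage=0.0, seed=1)) == 0

    def test_coverage_rate(self):
        genes = [f"g{i}" for i in range(1000)]
        omap = gen_orthology(genes, coverage=0.8, paralog_rate=0.0, seed=2)
        assert len(omap.forward()) / 1000 == pytest.approx(0.8, abs=0.04)


class TestGenLifespans:
    def test_deterministic(self):
        a = gen_lifespans({"g": 1.2}, n_animals=20, seed=9)
        b = gen_lifespans({"g": 1.2}, n_animals=20, seed=9)
        assert a["g"] == b["g"]

    def test_all_censored_breaks_km(self):
        from longnet.screen import km_estimate

        data = gen_lifespans({"g": 1.0}, n_animals=20, censor_rate=1.0, seed=1)
        with pytest.raises(DataError):
            km_estimate(data["g"])

    def test_gompertz_distribution(self):
        rng = np.random.default_rng(12)
        sample = sample_gompertz(5000, GOMPERTZ_SHAPE, GOMPERTZ_SCALE, rng)
        res = stats.kstest(sample, lambda t: 1 - gompertz_survival(t))
        assert res.pvalue > 0.01

    def test_invalid_parameters(self):
        with pytest.raises(DataError):
            gen_lifespans({"g": 1.0}, gompertz_shape=-1, seed=0)


class TestGenThrashing:
    def test_no_effect_mostly_none(self):
        records = gen_thrashing({f"g{i}": 1.0 for i in range(40)}, seed=3)
        calls = [classify_thrashing(r) for r in records.values()]
        assert calls.count("none") >= 30

    def test_zero_scored_hits_classifier_error_path(self):
        (rec,) = gen_thrashing({"g": 1.0}, n_scored=0, seed=1).values()
        with pytest.raises(DataError):
            classify_thrashing(rec)


class TestGenWorld:
    def test_world_files_reload(self, tmp_path):
        import longnet.io as lio

        world = gen_world(SMALL, seed=7)
        paths = write_world(world, tmp_path)
        edges = lio.load_edge_list(paths["edges.tsv"])
        assert len(edges) == world.interactome.n_edges
        core = lio.load_gene_set(paths["core.tsv"], species="worm")
        assert core.genes == world.true_core
        surv = lio.load_survival_csv(paths["survival.csv"])
        assert "control" in surv
        thr = lio.load_thrashing_csv(paths["thrashing.csv"])
        assert set(thr) == set(world.thrashing)

    def test_byte_identical_regeneration(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_world(gen_world(SMALL, seed=7), d1)
        write_world(gen_world(SMALL, seed=7), d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_oversized_core_rejected(self):
        with pytest.raises(DataError):
            gen_world(WorldConfig(n_nodes=50, core_size=50), seed=1)

    def test_planted_effects_are_screened_genes(self, default_world):
        w = default_world
        eff = w.effect_genes_long | w.effect_genes_short
        assert eff <= w.candidates.candidates
        assert w.true_core <= w.interactome.nodes
        inter = interconnectivity(w.interactome, w.true_core)
        assert inter.fraction > 0.5  # the planted module is tightly knit
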