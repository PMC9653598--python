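import numpy as np
import pytest

import anchorsig as a
from anchorsig.errors import ValidationError


class TestSimulationSpec:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_per_group": 1}, "n_per_group"),
            ({"module_penetrance": 1.5}, "module_penetrance"),
            ({"background_de_fraction": -0.1}, "background_de_fraction"),
            ({"module_genes": ("GPR19",)}, "module_genes"),
            ({"module_genes": ("X", "x")}, "module_genes"),
            ({"n_genes": 2, "module_genes": ("A", "B", "C")}, "n_genes"),
        ],
    )
    def test_invalid_spec_names_the_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            a.SimulationSpec(**kwargs)

    def test_gene_universe_puts_anchor_first(self):
        spec = a.SimulationSpec(n_genes=10, module_genes=("MA", "MB"))
        assert spec.genes[0] == "GPR19"
        assert set(spec.genes[1:3]) == {"MA", "MB"}
        assert len(spec.genes) == 10


class TestGenerateDataset:
    def test_same_seed_is_bitwise_identical(self):
        spec = a.SimulationSpec(n_genes=50, module_genes=("MA",), seed=7,
                                n_datasets=2)
        d1 = a.generate_dataset(spec, 0)
        d2 = a.generate_dataset(spec, 0)
        assert (d1.values.to_numpy() == d2.values.to_numpy()).all()
        d3 = a.generate_dataset(spec, 1)
        assert not (d1.values.to_numpy() == d3.values.to_numpy()).all()

    def test_null_model_has_zero_expected_difference(self):
        spec = a.SimulationSpec(n_genes=400, module_genes=(), effect_size=0.0,
                                background_de_fraction=0.0, seed=3, n_datasets=1)
        ds = a.generate_dataset(spec, 0)
        diff = (ds.values[ds.case_samples].mean(axis=1)
                - ds.values[ds.control_samples].mean(axis=1))
        # mean difference over genes ~ N(0, noise_sd * sqrt(2/n) / sqrt(G))
        assert abs(diff.mean()) < 4 * 1.0 * np.sqrt(2 / 10) / np.sqrt(400)

    def test_noiseless_limit_gives_exact_anchor_shift(self):
        spec = a.SimulationSpec(n_genes=20, module_genes=("MA",), noise_sd=0.0,
                                effect_size=2.0, background_de_fraction=0.0,
                                n_datasets=1)
        ds = a.generate_dataset(spec, 0)
        diff = (ds.values[ds.case_samples].mean(axis=1)
                - ds.values[ds.control_samples].mean(axis=1))
        assert diff["GPR19"] == pytest.approx(2.0, abs=1e-9)
        assert diff["MA"] == pytest.approx(2.0, abs=1e-9)
        assert (diff.drop(["GPR19", "MA"]) == 0).all()

    def test_zero_penetrance_leaves_module_unshifted(self):
        spec = a.SimulationSpec(n_genes=20, module_genes=("MA", "MB"),
                                noise_sd=0.0, effect_size=2.0,
                                module_penetrance=0.0,
                                background_de_fraction=0.0, n_datasets=1)
        ds = a.generate_dataset(spec, 0)
        diff = (ds.values[ds.case_samples].mean(axis=1)
                - ds.values[ds.control_samples].mean(axis=1))
        assert diff["MA"] == 0 and diff["MB"] == 0
        assert diff["GPR19"] == 2.0  # anchor always carries the shift

    def test_index_out_of_range_rejected(self):
        spec = a.SimulationSpec(n_genes=20, module_genes=(), n_datasets=2)
        with pytest.raises(ValidationError, match="index"):
            a.generate_dataset(spec, 2)


class TestGenerateGmt:
    UNIVERSE = [f"G{i:03d}" for i in range(60)]

    def test_zero_random_sets_leaves_only_planted(self):
        coll = a.generate_gmt(self.UNIVERSE, 0, (5, 10), self.UNIVERSE[:4], seed=1)
        assert list(coll.sets) == ["PLANTED"]
        assert coll.sets["PLANTED"] == frozenset(self.UNIVERSE[:4])

    def test_fixed_size_range_gives_fixed_sizes(self):
        coll = a.generate_gmt(self.UNIVERSE, 8, (5, 5), self.UNIVERSE[:4], seed=1)
        assert all(len(coll.sets[f"RS{i + 1:04d}"]) == 5 for i in range(8))

    def test_same_seed_identical(self):
        c1 = a.generate_gmt(self.UNIVERSE, 5, (5, 10), self.UNIVERSE[:4], seed=9)
        c2 = a.generate_gmt(self.UNIVERSE, 5, (5, 10), self.UNIVERSE[:4], seed=9)
        assert c1.sets == c2.sets

    def test_planted_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="planted"):
            a.generate_gmt(self.UNIVERSE, 3, (5, 10), ["NOT_THERE"], seed=1)


class TestGenerateReferenceSet:
    UNIVERSE = [f"G{i:04d}" for i in range(500)]
    POOL = [f"G{i:04d}" for i in range(80)]

    def test_zero_excess_is_uniform_subset(self):
        ref = a.generate_reference_set(self.UNIVERSE, 50, self.POOL, 0.0, seed=2)
        assert len(ref) == 50 and ref <= set(self.UNIVERSE)

    def test_full_excess_recovers_pool(self):
        ref = a.generate_reference_set(self.UNIVERSE, 80, self.POOL, 1.0, seed=2)
        assert ref == set(self.POOL)

    def test_planted_pool_membership_is_deterministic(self):
        # size 227 at 10% excess plants exactly round(22.7) = 23 pool members
        ref = a.generate_reference_set(self.UNIVERSE, 227, self.POOL, 0.1, seed=5)
        assert len(ref) == 227
        assert len(ref & set(self.POOL)) == 23

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValidationError):
            a.generate_reference_set(self.UNIVERSE, 501, self.POOL, 0.0, seed=1)
        with pytest.raises(ValidationError):
            a.generate_reference_set(self.UNIVERSE, 100, self.POOL[:5], 0.5, seed=1)


class TestGeneratePpi:
    def test_disjoint_cliques_have_exact_edge_count(self):
        g = a.generate_ppi(20, [4, 4, 4, 4], 0.0, seed=1)
        assert len(g.edges) == 4 * 6  # 4 * C(4,2)

    def test_background_one_gives_complete_graph(self):
        g = a.generate_ppi(10, [], 1.0, seed=1)
        assert len(g.edges) == 45

    def test_same_seed_identical_edge_set(self):
        g1 = a.generate_ppi(30, [5], 0.1, seed=3)
        g2 = a.generate_ppi(30, [5], 0.1, seed=3)
        assert g1.edges == g2.edges

    def test_cliques_exceeding_nodes_rejected(self):
        with pytest.raises(ValidationError, match="clique_sizes"):
            a.generate_ppi(5, [4, 4], 0.0, seed=1)

    def test_cliques_planted_on_named_nodes(self):
        names = [f"X{i}" for i in range(6)]
        g = a.generate_ppi(6, [3], 0.0, seed=1, nodes=names)
        assert g.edges == {("X0", "X1"), ("X0", "X2"), ("X1", "X2")}
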