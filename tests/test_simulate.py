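"""Generator contract: planted anchors, calibration, determinism, fidelity."""

import numpy as np
import pytest

from feadh.alignio import EUKARYOTE_GROUPS, global_align
from feadh.registry import ANCHORS, registry_by_id
from feadh.simulate import (
    GeneratorConfig,
    default_taxon_weights,
    make_gdh_decoys,
    make_reference,
    make_seed_sets,
    make_subfamily_ancestors,
    mean_inter_ancestor_identity,
    sample_sequences,
    simulate_family,
)


class TestReference:
    def test_length_and_planted_anchors(self):
        ref = make_reference(0)
        seq = ref.residues
        assert len(seq) == 467
        assert seq[80] == "D"  # coenzyme determinant
        assert seq[137:141] == "GGGS"
        tetrad = tuple(seq[p - 1] for p in (242, 246, 330, 357))
        assert tetrad == ("D", "H", "H", "H")
        assert seq[333] == "Y"  # catalytic position

    def test_reference_deterministic_per_seed(self):
        assert make_reference(3).residues == make_reference(3).residues
        assert make_reference(3).residues != make_reference(4).residues


class TestAncestors:
    def test_hot_ancestor_keeps_inserts_others_lose_them(self, dataset):
        assert len(dataset.ancestors["cd08190"]) == 467
        for cdd, anc in dataset.ancestors.items():
            if cdd != "cd08190":
                assert len(anc) == 467 - 19 - 13

    def test_subfamily_profiles_planted(self, dataset):
        from feadh.annotate import annotate

        lpo = annotate(dataset.ancestors["cd08176"], dataset.reference)
        assert lpo.res81 == "D" and lpo.coenzyme_call == "NAD"
        mar = annotate(dataset.ancestors["cd08177"], dataset.reference)
        assert mar.res81 == "T"
        assert mar.tetrad[0] == "N"
        assert mar.metal_call == "metal_independent_likely"

    def test_calibration_close_to_target(self, dataset, small_config):
        measured = mean_inter_ancestor_identity(dataset.ancestors)
        assert abs(measured - small_config.inter_identity) <= 5.0

    def test_subset_of_subfamilies(self, registry):
        config = GeneratorConfig(seed=2, subfamilies=("cd08176", "cd08177", "cd08190"))
        ancestors = make_subfamily_ancestors(registry, config)
        assert set(ancestors) == {"cd08176", "cd08177", "cd08190"}


class TestSampling:
    def test_byte_identical_reruns(self, registry, small_config):
        a = simulate_family(small_config, registry)
        b = simulate_family(small_config, registry)
        assert [r.residues for r in a.records] == [r.residues for r in b.records]
        assert [r.id for r in a.records] == [r.id for r in b.records]
        assert a.truths == b.truths

    def test_zero_intra_divergence_reproduces_ancestor(self, registry):
        config = GeneratorConfig(
            seed=5, n_per_subfamily=3, intra_identity=100.0,
            subfamilies=("cd08176", "cd08190"),
        )
        ancestors = make_subfamily_ancestors(registry, config)
        records, _ = sample_sequences(ancestors, config, registry)
        for rec in records:
            cdd = "cd08176" if rec.id.startswith("LPO") else "cd08190"
            assert rec.residues == ancestors[cdd].residues

    def test_intra_identity_near_target(self, dataset, small_config):
        hot = [r for r in dataset.records if r.id.startswith("HOT_")]
        pairs = [(hot[i], hot[j]) for i in range(len(hot)) for j in range(i + 1, len(hot))]
        idents = [
            global_align(a.residues, b.residues).percent_identity for a, b in pairs
        ]
        assert abs(float(np.mean(idents)) - small_config.intra_identity) <= 5.0

    def test_taxon_groups_respect_registry_flags(self, dataset, registry):
        by_id = registry_by_id(registry)
        for rec, truth in zip(dataset.records, dataset.truths):
            d = by_id[truth.true_subfamily]
            if rec.taxon_group == "archaea":
                assert d.in_archaea
            elif rec.taxon_group == "bacteria":
                assert d.in_bacteria
            elif rec.taxon_group in EUKARYOTE_GROUPS:
                assert d.in_eukarya

    def test_forced_animal_weight_for_hot(self, registry):
        config = GeneratorConfig(
            seed=9, n_per_subfamily=6, subfamilies=("cd08190",),
            taxon_sampling={"cd08190": {"animal": 1.0}},
        )
        ancestors = make_subfamily_ancestors(registry, config)
        records, truths = sample_sequences(ancestors, config, registry)
        assert all(r.taxon_group == "animal" for r in records)
        assert all(t.taxon_group == "animal" for t in truths)

    def test_conflicting_taxon_weight_rejected(self, registry):
        # PDD (cd08180) is bacteria-only; an animal weight conflicts
        config = GeneratorConfig(
            seed=9, n_per_subfamily=2, subfamilies=("cd08180",),
            taxon_sampling={"cd08180": {"animal": 1.0}},
        )
        ancestors = make_subfamily_ancestors(registry, config)
        with pytest.raises(ValueError, match="conflicts with registry flags"):
            sample_sequences(ancestors, config, registry)

    def test_truth_rows_one_per_record(self, dataset):
        assert len(dataset.truths) == len(dataset.records)
        assert [t.seq_id for t in dataset.truths] == [r.id for r in dataset.records]

    def test_default_weights_derive_from_lineages(self, registry):
        by_id = registry_by_id(registry)
        weights = default_taxon_weights(by_id["cd08190"])  # HOT
        assert set(weights) == {"bacteria", "archaea", "animal", "fungi", "other_eukaryote"}
        weights = default_taxon_weights(by_id["cd08180"])  # PDD, bacteria only
        assert set(weights) == {"bacteria"}


class TestDecoysAndSeeds:
    def test_decoy_tetrad_keeps_only_his357(self):
        decoys, truths = make_gdh_decoys(4, seed=0)
        ref = make_reference(0)
        from feadh.annotate import annotate

        for rec, truth in zip(decoys, truths):
            assert truth.true_subfamily == "gdh_decoy"
            ann = annotate(rec, ref)
            assert ann.gdh_like
            _, h246, h330, h357 = ann.tetrad
            assert h357 == "H" and h246 != "H" and h330 != "H"

    def test_zero_decoys(self):
        records, truths = make_gdh_decoys(0, seed=0)
        assert records == [] and truths == []

    def test_seed_sets_disjoint_from_samples(self, dataset, seed_sets, small_config):
        sample_seqs = {r.residues for r in dataset.records}
        for seeds in seed_sets.values():
            assert len(seeds) == 3
            for seed in seeds:
                assert seed.residues not in sample_seqs
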