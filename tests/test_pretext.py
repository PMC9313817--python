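"""Permutation-set selection, jigsaw samples, and the four pretext trainers."""
import itertools

import numpy as np
import pytest
from scipy import stats

from muscleseg import (
    PhantomParams,
    build_permutation_set,
    generate_phantom,
    make_jigsaw_sample,
    to_model_input,
    train_autoencoder,
    train_classification_proxy,
    train_jigsaw,
    train_segmentation_proxy,
    wall_mask,
    window_level,
)
from muscleseg.nn import NetConfig
from muscleseg.pretext import _tile, reassemble

TINY = NetConfig(width=4)


def brute_force_greedy(n: int, count: int):
    """Independent re-implementation of greedy max-mean-Hamming selection."""
    perms = list(itertools.permutations(range(n)))
    identity = tuple(range(n))

    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))

    # lexicographically first among maximal distances from the identity:
    best_d = max(ham(p, identity) for p in perms)
    start = min(p for p in perms if ham(p, identity) == best_d)
    chosen = [start]
    remaining = [p for p in perms if p != start]
    while len(chosen) < count:
        best_sum = max(sum(ham(p, c) for c in chosen) for p in remaining)
        pick = min(
            p for p in remaining if sum(ham(p, c) for c in chosen) == best_sum
        )
        chosen.append(pick)
        remaining.remove(pick)
    return chosen


class TestPermutationSet:
    def test_default_set_is_50_distinct_bijections(self):
        pset = build_permutation_set((3, 3), 50, seed=0)
        assert len(pset) == 50
        assert len(set(pset.permutations)) == 50
        for p in pset.permutations:
            assert sorted(p) == list(range(9))

    def test_single_permutation(self):
        assert len(build_permutation_set((3, 3), 1, seed=0)) == 1

    def test_matches_exhaustive_greedy_on_2x2(self):
        pset = build_permutation_set((2, 2), 10, seed=0)
        assert pset.permutations == brute_force_greedy(4, 10)

    def test_full_2x2_enumeration(self):
        pset = build_permutation_set((2, 2), 24, seed=0)
        assert sorted(pset.permutations) == sorted(itertools.permutations(range(4)))

    def test_selection_trace_recorded(self):
        pset = build_permutation_set((2, 2), 5, seed=0)
        assert len(pset.selection_trace) == 5
        assert pset.selection_trace[1]["mean_hamming"] > 0

    def test_count_bounds(self):
        with pytest.raises(ValueError):
            build_permutation_set((2, 2), 0, seed=0)
        with pytest.raises(ValueError):
            build_permutation_set((2, 2), 25, seed=0)


class TestJigsawSamples:
    def test_round_trip_restores_tiling(self, small_inputs):
        pset = build_permutation_set((3, 3), 20, seed=0)
        for seed in range(5):
            s = make_jigsaw_sample(small_inputs[0], pset, seed=seed)
            assert np.array_equal(
                reassemble(s, pset), _tile(small_inputs[0].channels, (3, 3))
            )

    def test_identity_permutation_keeps_reading_order(self, small_inputs):
        from muscleseg.pretext import PermutationSet

        pset = PermutationSet(permutations=[tuple(range(9))])
        s = make_jigsaw_sample(small_inputs[0], pset, seed=0)
        assert s.label == 0
        assert np.array_equal(s.patches, _tile(small_inputs[0].channels, (3, 3)))

    def test_label_frequencies_uniform(self, small_inputs):
        pset = build_permutation_set((3, 3), 10, seed=0)
        labels = [
            make_jigsaw_sample(small_inputs[0], pset, seed=i).label for i in range(1000)
        ]
        counts = np.bincount(labels, minlength=10)
        assert stats.chisquare(counts).pvalue > 0.01


@pytest.fixture(scope="module")
def trainer_cohort():
    params = PhantomParams(cohort_size=30, image_side=48, spacing_mm=8.0)
    cohort = generate_phantom(params, seed=77)
    inputs = [to_model_input(window_level(ct), provenance=ct.slice_id) for ct, _, _ in cohort]
    return cohort, inputs


class TestTrainers:
    def test_jigsaw_toy_two_permutations_separable(self, trainer_cohort):
        _, inputs = trainer_cohort
        pset = build_permutation_set((3, 3), 2, seed=0)
        res = train_jigsaw(inputs, pset, TINY, seed=0, epochs=20)
        assert res.final_metric > 0.9
        assert res.loss_history[-1] < res.loss_history[0]

    def test_jigsaw_deterministic(self, trainer_cohort):
        _, inputs = trainer_cohort
        pset = build_permutation_set((3, 3), 2, seed=0)
        a = train_jigsaw(inputs[:10], pset, TINY, seed=5, epochs=3)
        b = train_jigsaw(inputs[:10], pset, TINY, seed=5, epochs=3)
        assert all(np.array_equal(a.weights.entries[k], b.weights.entries[k])
                   for k in a.weights.entries)

    def test_jigsaw_needs_two_classes(self, trainer_cohort):
        from muscleseg.pretext import PermutationSet

        _, inputs = trainer_cohort
        with pytest.raises(ValueError):
            train_jigsaw(inputs, PermutationSet(permutations=[tuple(range(9))]), TINY, 0)

    def test_autoencoder_beats_variance_baseline(self, trainer_cohort):
        _, inputs = trainer_cohort
        res = train_autoencoder(inputs, TINY, seed=0, epochs=15)
        x = np.stack([inp.channels for inp in inputs])
        baseline = float(
            np.mean([(c - c.mean()) ** 2 for c in x.reshape(len(x), -1)])
        )
        assert res.final_metric < baseline
        assert res.loss_history[-1] < res.loss_history[0]
        assert set(res.weights.entries) == {
            k for k in res.weights.entries if k.startswith("encoder.")
        }

    def test_classification_learns_and_rejects_single_class(self, trainer_cohort):
        cohort, inputs = trainer_cohort
        # separable toy labels: bright vs dark muscle compartment
        labels = [int(ct.pixels[m.bool()].mean() > 45.0) for ct, m, _ in cohort]
        res = train_classification_proxy(inputs, labels, TINY, seed=0, epochs=25)
        assert res.loss_history[-1] < res.loss_history[0]
        assert res.final_metric > 0.7
        with pytest.raises(ValueError):
            train_classification_proxy(inputs, [0] * len(inputs), TINY, seed=0)

    def test_segmentation_proxy_full_topology_and_overlap_guard(self, trainer_cohort):
        cohort, inputs = trainer_cohort
        aux = [(inp, wall_mask(ct, mu)) for inp, (ct, mu, _) in zip(inputs, cohort)]
        res = train_segmentation_proxy(aux, TINY, seed=0, epochs=10)
        assert res.loss_history[-1] < res.loss_history[0]
        prefixes = {k.split(".")[0] for k in res.weights.entries}
        assert prefixes == {"encoder", "decoder", "head"}
        with pytest.raises(ValueError, match="overlap"):
            train_segmentation_proxy(
                aux, TINY, seed=0, epochs=1,
                target_ids={inp.provenance for inp, _ in aux},
            )

    def test_encoder_names_cover_target_encoder(self, trainer_cohort):
        # transferability contract: every pretext emits the target's encoder names
        from muscleseg.nn import SegmentationNet

        _, inputs = trainer_cohort
        target_enc = {
            k for k in SegmentationNet(TINY, 0).named_parameters() if k.startswith("encoder.")
        }
        res = train_autoencoder(inputs[:8], TINY, seed=0, epochs=2)
        assert target_enc <= set(res.weights.entries)
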