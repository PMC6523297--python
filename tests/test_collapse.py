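"""Collapse, master-ID and TPM-conversion behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isokit.collapse import (
    assign_master_ids,
    collapse_to_longest,
    counts_to_tpm,
    fpkm_to_tpm,
)
from isokit.models import TranscriptModel, chain_key


def tx(exons, tid, strand="+"):
    return TranscriptModel(tid, "g", "chr1", strand, tuple(exons))


def random_collapse_group(rng, base_pos):
    """Transcripts sharing an intron chain but differing in terminal ends."""
    n_exons = int(rng.integers(2, 6))
    pos, exons = base_pos, []
    for _ in range(n_exons):
        pos += int(rng.integers(50, 200))
        ln = int(rng.integers(100, 300))
        exons.append((pos, pos + ln))
        pos += ln
    members = []
    for j in range(int(rng.integers(1, 5))):
        jitter5 = int(rng.integers(0, 40))
        jitter3 = int(rng.integers(0, 40))
        e = list(exons)
        e[0] = (e[0][0] + jitter5, e[0][1])
        e[-1] = (e[-1][0], e[-1][1] - jitter3)
        members.append(tuple(e))
    return members


class TestCollapse:
    def test_shared_intron_chain_merges_keeping_longest(self):
        a = tx([(100, 200), (300, 400)], "a")
        b = tx([(130, 200), (300, 400)], "b")  # 30 nt shorter 5' end
        recs = collapse_to_longest([a, b], [1, 1])
        assert len(recs) == 1
        assert recs[0].model.transcript_id == "a"
        assert recs[0].read_count == 2

    def test_different_intron_chains_stay_separate(self):
        a = tx([(100, 200), (300, 400)], "a")
        b = tx([(100, 200), (320, 400)], "b")
        assert len(collapse_to_longest([a, b], [1, 1])) == 2

    def test_monoexonic_reciprocal_overlap_threshold(self):
        a = tx([(0, 1000)], "a")
        b = tx([(10, 1000)], "b")  # 99% reciprocal overlap
        c = tx([(600, 1600)], "c")  # 40%
        recs = collapse_to_longest([a, b, c], [1, 1, 1])
        assert len(recs) == 2

    def test_idempotence_and_count_conservation(self):
        rng = np.random.default_rng(42)
        txs, counts = [], []
        base = 0
        for g in range(100):
            for j, exons in enumerate(random_collapse_group(rng, base)):
                txs.append(tx(exons, f"t{g}.{j}"))
                counts.append(int(rng.integers(1, 20)))
            base += 5000
        once = collapse_to_longest(txs, counts)
        assert sum(r.read_count for r in once) == sum(counts)
        twice = collapse_to_longest([r.model for r in once], [r.read_count for r in once])
        assert [(r.model.exons, r.read_count) for r in twice] == [
            (r.model.exons, r.read_count) for r in once
        ]

    def test_empty_input(self):
        assert collapse_to_longest([], []) == []


class TestMasterIds:
    def test_same_chain_shares_id_across_samples(self):
        s1 = collapse_to_longest([tx([(0, 100), (200, 300)], "a")], [1], "T")
        s2 = collapse_to_longest([tx([(10, 100), (200, 280)], "b")], [1], "N")
        assign_master_ids([s1, s2])
        assert s1[0].master_id == s2[0].master_id

    def test_distinct_chains_get_distinct_ids(self):
        s = collapse_to_longest(
            [tx([(0, 100), (200, 300)], "a"), tx([(0, 100), (210, 300)], "b")], [1, 1]
        )
        registry = assign_master_ids([s])
        assert len(set(registry.values())) == 2

    def test_registry_size_matches_brute_force_chain_count(self):
        rng = np.random.default_rng(9)
        samples = []
        all_models = []
        for sid in "TN":
            txs, counts = [], []
            base = 0
            for g in range(30):
                for j, exons in enumerate(random_collapse_group(rng, base)):
                    txs.append(tx(exons, f"{sid}{g}.{j}"))
                    counts.append(1)
                base += 4000
            recs = collapse_to_longest(txs, counts, sid)
            samples.append(recs)
            all_models.extend(r.model for r in recs)
        registry = assign_master_ids(samples)
        assert len(registry) == len({chain_key(m) for m in all_models})
        assert len(set(registry.values())) == len(registry)  # injective


class TestTpm:
    def test_fpkm_worked_example(self):
        np.testing.assert_allclose(fpkm_to_tpm([10, 30, 60]), [1e5, 3e5, 6e5])

    def test_single_element_gets_everything(self):
        np.testing.assert_allclose(fpkm_to_tpm([1]), [1e6])
        np.testing.assert_allclose(counts_to_tpm([7]), [1e6])

    def test_counts_worked_example(self):
        np.testing.assert_allclose(counts_to_tpm([2, 3, 5]), [2e5, 3e5, 5e5])

    @pytest.mark.parametrize("converter", [fpkm_to_tpm, counts_to_tpm])
    def test_sum_conserved_on_random_vectors(self, converter):
        rng = np.random.default_rng(3)
        for _ in range(50):
            v = rng.uniform(0.01, 1000, size=int(rng.integers(1, 200)))
            if converter is counts_to_tpm:
                v = np.ceil(v)
            assert abs(converter(v).sum() - 1e6) <= 1e6 * 1e-6

    @pytest.mark.parametrize("converter", [fpkm_to_tpm, counts_to_tpm])
    def test_all_zero_vector_rejected(self, converter):
        with pytest.raises(ValueError):
            converter([0, 0, 0])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e6), min_size=1, max_size=100),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_fpkm_conversion_is_scale_invariant(self, fpkm, factor):
        scaled = fpkm_to_tpm([v * factor for v in fpkm])
        np.testing.assert_allclose(scaled, fpkm_to_tpm(fpkm), rtol=1e-9)
        assert abs(scaled.sum() - 1e6) <= 1.0

    def test_length_normalization_switch(self):
        with_len = counts_to_tpm([10, 10], lengths=[1000, 2000], length_normalize=True)
        assert with_len[0] > with_len[1]
        np.testing.assert_allclose(with_len.sum(), 1e6)
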