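"""Block enumeration via divergence-array LCP intervals and right-maximality."""

import numpy as np
import pytest

from hapblocks.blocks import (
    AvailableBlock,
    build_rightmax_index,
    enumerate_available_blocks,
    find_blocks,
    is_right_maximal,
    lcp_from_divergence,
)
from hapblocks.matrix import HaplotypeMatrix
from hapblocks.oracle import brute_force_blocks
from hapblocks.pbwt import extend, initial_state

from conftest import block_key, random_matrices


def states_of(matrix):
    state = initial_state(matrix.k, matrix.alphabet)
    out = []
    for c in range(1, matrix.n + 1):
        state = extend(state, matrix.column(c))
        out.append(state)
    return out


@pytest.fixture
def fixture_states(fixture_matrix):
    return states_of(fixture_matrix)


class TestLcpFromDivergence:
    def test_formula_on_fixture(self):
        assert lcp_from_divergence([3, 1, 2], 2).tolist() == [0, 2, 1]

    @pytest.mark.parametrize("l", [0, 1, 5, 40])
    def test_head_is_zero(self, l):
        # d[1] = l + 1 always maps to LCP[1] = 0
        assert lcp_from_divergence([l + 1], l).tolist() == [0]

    def test_identical_rows(self):
        assert lcp_from_divergence([4, 1], 3).tolist() == [0, 3]


class TestEnumerateAvailableBlocks:
    def test_fixture_column_two(self, fixture_states):
        assert set(enumerate_available_blocks(fixture_states[1])) == {
            AvailableBlock(i=1, j=2, x=1, y=2),
            AvailableBlock(i=2, j=2, x=1, y=3),
        }

    def test_fixture_column_one(self, fixture_states):
        assert set(enumerate_available_blocks(fixture_states[0])) == {
            AvailableBlock(i=1, j=1, x=1, y=2)
        }

    def test_single_row_empty(self):
        state = extend(initial_state(1), [0])
        assert enumerate_available_blocks(state) == []

    def test_definition_two_holds(self):
        # emitted quadruples satisfy the three divergence conditions
        for m in random_matrices(40, seed=7):
            for state in states_of(m):
                d, j = state.d, state.l
                for b in enumerate_available_blocks(state):
                    assert all(d[r - 1] <= b.i for r in range(b.x + 1, b.y + 1))
                    assert any(d[r - 1] == b.i for r in range(b.x + 1, b.y + 1))
                    assert b.x == 1 or d[b.x - 1] > b.i
                    assert b.y == state.k or d[b.y] > b.i

    def test_at_most_k_minus_one(self):
        for m in random_matrices(40, seed=8):
            for state in states_of(m):
                assert len(enumerate_available_blocks(state)) <= m.k - 1


class TestRightMaximality:
    def test_fixture_index_all_changes(self, fixture_states):
        idx = build_rightmax_index(fixture_states[1], [0, 1, 0])
        assert idx.prefix_sums.tolist() == [1, 2, 3]
        assert is_right_maximal(AvailableBlock(1, 2, 1, 2), idx, n=3)

    def test_constant_next_column_blocks_nothing(self):
        state = extend(extend(initial_state(3), [0, 0, 1]), [1, 1, 1])
        idx = build_rightmax_index(state, [1, 1, 1])
        assert idx.prefix_sums.tolist() == [1, 1, 1]
        for b in enumerate_available_blocks(state):
            assert not is_right_maximal(b, idx, n=5)

    def test_final_column_trivially_maximal(self):
        assert is_right_maximal(AvailableBlock(1, 3, 1, 2), None, n=3)

    def test_missing_index_rejected(self):
        with pytest.raises(ValueError):
            is_right_maximal(AvailableBlock(1, 2, 1, 2), None, n=3)

    def test_two_rows_disagreeing(self):
        state = extend(initial_state(2), [0, 0])
        idx = build_rightmax_index(state, [0, 1])
        assert idx.prefix_sums.tolist() == [1, 2]


class TestFindBlocks:
    def test_worked_example(self, fixture_matrix):
        assert block_key(find_blocks(fixture_matrix)) == {
            ((1, 2), 1, 2),
            ((1, 2, 3), 2, 2),
            ((1, 3), 2, 3),
        }

    def test_worked_example_size_filter(self, fixture_matrix):
        # the 1-column, 3-row block has size 3 and is filtered out
        assert block_key(find_blocks(fixture_matrix, min_size=4)) == {
            ((1, 2), 1, 2),
            ((1, 3), 2, 3),
        }

    def test_duplicate_rows_single_block(self):
        m = HaplotypeMatrix.from_strings(["00", "00"])
        blocks = list(find_blocks(m))
        assert block_key(blocks) == {((1, 2), 1, 2)}
        assert blocks[0].size == 4

    def test_emission_order(self):
        for m in random_matrices(20, seed=21):
            order = [(b.j, b.x) for b in find_blocks(m)]
            assert order == sorted(order)

    def test_compact_mode_matches_expanded(self, fixture_matrix):
        compact = list(find_blocks(fixture_matrix, expand_rows=False))
        expanded = list(find_blocks(fixture_matrix, expand_rows=True))
        assert [(b.i, b.j, b.x, b.y) for b in compact] == [
            (b.i, b.j, b.x, b.y) for b in expanded
        ]
        assert all(b.rows is None for b in compact)
        assert [b.size for b in compact] == [b.size for b in expanded]

    def test_min_size_monotonicity(self):
        for m in random_matrices(15, seed=5, k_max=8, n_max=20):
            all_blocks = block_key(find_blocks(m, min_size=1))
            for ms in (2, 4, 8):
                assert block_key(find_blocks(m, min_size=ms)) <= all_blocks

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            list(find_blocks(HaplotypeMatrix(np.zeros((1, 3), dtype=int))))

    def test_bad_min_size_rejected(self, fixture_matrix):
        with pytest.raises(ValueError):
            list(find_blocks(fixture_matrix, min_size=0))

    def test_matches_oracle_with_size_filter(self):
        for m in random_matrices(25, seed=77, k_max=8, n_max=25):
            for ms in (1, 3, 6):
                assert block_key(find_blocks(m, min_size=ms)) == block_key(
                    brute_force_blocks(m, min_size=ms)
                )

    def test_lemma_one_ranges_are_contiguous(self):
        # every oracle block maps under a_j^-1 to a contiguous colex range
        # that available-block enumeration emits
        for m in random_matrices(25, seed=31, k_max=8, n_max=20):
            states = states_of(m)
            for rows, i, j in block_key(brute_force_blocks(m)):
                state = states[j - 1]
                positions = sorted(int(state.a_inv[r - 1]) for r in rows)
                assert positions == list(range(positions[0], positions[-1] + 1))
                assert AvailableBlock(i, j, positions[0], positions[-1]) in set(
                    enumerate_available_blocks(state)
                )
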