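"""sDTW engines: oracle correctness, engine equivalence, fixed-point semantics.

Expected values come from independent brute-force evaluators defined here
(pure-Python full-matrix recurrences and word-width-masked integer
arithmetic), never from the engines under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import squigmap as sm
from squigmap.sdtw import sdtw_fixed_sequential


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_sdtw(x, y):
    """Pure-Python full-matrix sDTW: (score, end, last_row)."""
    M, N = len(x), len(y)
    INF = float("inf")
    g = [[0.0] * (N + 1)] + [[INF] * (N + 1) for _ in range(M)]
    for i in range(1, M + 1):
        g[i][0] = INF
    for j in range(N + 1):
        g[0][j] = 0.0
    for i in range(1, M + 1):
        for j in range(1, N + 1):
            g[i][j] = abs(x[i - 1] - y[j - 1]) + min(
                g[i - 1][j], g[i - 1][j - 1], g[i][j - 1]
            )
    last = g[M][1:]
    score = min(last)
    return score, last.index(score), last


def wrap_word(v, bits=16):
    """Interpret an integer in bits-wide two's complement (mask oracle)."""
    span = 1 << bits
    half = 1 << (bits - 1)
    return (v + half) % span - half


def sat_word(v, bits=16):
    half = 1 << (bits - 1)
    return max(-half, min(half - 1, v))


def brute_sdtw_fixed(x, y, bits=16, wrap=True):
    """Pure-Python fixed-point sDTW matching the documented word semantics."""
    clamp = (lambda v: wrap_word(v, bits)) if wrap else (lambda v: sat_word(v, bits))
    hi = (1 << (bits - 1)) - 1
    M, N = len(x), len(y)
    g = [[0] * (N + 1) for _ in range(M + 1)]
    for i in range(1, M + 1):
        g[i][0] = hi
    for i in range(1, M + 1):
        for j in range(1, N + 1):
            d = clamp(x[i - 1] - y[j - 1])
            if d < 0:
                d = clamp(-d)
            m = min(g[i - 1][j], g[i - 1][j - 1], g[i][j - 1])
            g[i][j] = hi if m == hi else clamp(d + m)
    last = g[M][1:]
    score = min(last)
    return score, last.index(score)


# ---------------------------------------------------------------------------
# float engines
# ---------------------------------------------------------------------------

class TestWorkedExamples:
    def test_exact_subsequence_zero_cost(self):
        for fn in (sm.sdtw_oracle, sm.sdtw_linear):
            r = fn([1, 2], [0, 1, 2, 3])
            assert r.score == 0.0
            assert r.end == 2

    def test_oracle_backtracking_on_exact_subsequence(self):
        r = sm.sdtw_oracle([1, 2], [0, 1, 2, 3])
        assert r.start == 1
        assert r.path == [(0, 1), (1, 2)]

    def test_two_by_four_example(self):
        # last row is [4, 2, 2, 2]: score 2, smallest index wins
        for fn in (sm.sdtw_oracle, sm.sdtw_linear):
            r = fn([1, 3], [0, 2, 4, 2])
            assert r.score == 2.0
            assert r.end == 1

    def test_single_sample_closed_form(self):
        y = [5.0, 2.0, 9.0, 2.0]
        r = sm.sdtw_linear([3.0], y)
        assert r.score == 1.0
        assert r.end == 1  # first argmin on ties

    def test_self_alignment_is_zero(self):
        x = np.random.default_rng(0).normal(size=32)
        r = sm.sdtw_linear(x, x)
        assert r.score == 0.0
        assert r.end == 31

    @pytest.mark.parametrize("x,y", [([], [1.0]), ([1.0], []), ([1, 2, 3], [1, 2])])
    def test_size_errors(self, x, y):
        for fn in (sm.sdtw_oracle, sm.sdtw_linear):
            with pytest.raises(sm.SizeError):
                fn(x, y)


class TestOracleProperties:
    def test_path_is_monotone_with_unit_steps(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=40)
        r = sm.sdtw_oracle(x, y)
        assert r.path[0][0] == 0
        assert r.path[-1] == (11, r.end)
        assert r.start == r.path[0][1] <= r.end
        for (i0, j0), (i1, j1) in zip(r.path[:-1], r.path[1:]):
            assert (i1 - i0, j1 - j0) in {(1, 0), (1, 1), (0, 1)}

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(1, 16))
        N = int(rng.integers(M, 48))
        x = rng.normal(size=M)
        y = rng.normal(size=N)
        score, end, _ = brute_sdtw(list(x), list(y))
        for fn in (sm.sdtw_oracle, sm.sdtw_linear):
            r = fn(x, y)
            assert r.score == score  # identical double-precision arithmetic
            assert r.end == end

    def test_score_nonnegative_and_zero_iff_subsequence(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=60)
        x = y[20:30].copy()
        assert sm.sdtw_linear(x, y).score == 0.0
        x2 = x + 0.25
        assert sm.sdtw_linear(x2, y).score > 0.0

    def test_shift_invariance_of_end(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=16)
        y = rng.normal(size=120)
        base = sm.sdtw_linear(x, y)
        prefix = np.full(37, 50.0)  # values far outside the query range
        shifted = sm.sdtw_linear(x, np.concatenate([prefix, y]))
        assert shifted.end == base.end + 37
        assert shifted.score == base.score


# ---------------------------------------------------------------------------
# fixed-point engines
# ---------------------------------------------------------------------------

class TestManhattan:
    def test_trivial(self):
        assert sm.manhattan(3, 5) == 2
        assert sm.manhattan(7.5, 7.5) == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=-32768, max_value=32767),
        st.integers(min_value=-32768, max_value=32767),
        st.booleans(),
    )
    def test_fixed_point_matches_mask_oracle(self, a, b, wrap):
        policy = "wraparound" if wrap else "saturate"
        fp = sm.FixedPointConfig(overflow_policy=policy)
        d = wrap_word(a - b) if wrap else sat_word(a - b)
        if d < 0:
            d = wrap_word(-d) if wrap else sat_word(-d)
        assert sm.manhattan(a, b, fp) == d

    def test_negating_min_word_wraps(self):
        fp = sm.FixedPointConfig(overflow_policy="wraparound")
        assert sm.manhattan(-32768, 0, fp) == -32768  # two's-complement abs


class TestFixedEngines:
    @pytest.mark.parametrize("policy", ["wraparound", "saturate"])
    def test_wavefront_matches_sequential_and_bruteforce(self, policy):
        fp = sm.FixedPointConfig(overflow_policy=policy)
        rng = np.random.default_rng(8)
        for _ in range(30):
            M = int(rng.integers(1, 12))
            N = int(rng.integers(M, 40))
            # wide values so accumulations overflow regularly
            x = rng.integers(-30000, 30001, size=M)
            y = rng.integers(-30000, 30001, size=N)
            seq = sdtw_fixed_sequential(x, y, fp)
            wav = sm.sdtw_wavefront_fixed(x, y, fp)
            bscore, bend = brute_sdtw_fixed(
                list(x), list(y), wrap=(policy == "wraparound")
            )
            assert (wav.score, wav.end) == (seq.score, seq.end) == (bscore, bend)

    def test_step_count_formula(self):
        fp = sm.FixedPointConfig()
        r = sm.sdtw_wavefront_fixed([1, 2, 3], [0, 1, 2, 3, 4], fp)
        assert r.steps == 3 + 5 - 1

    def test_toy_example_scales_with_factor(self):
        fp = sm.FixedPointConfig()
        s = fp.scale
        r = sm.sdtw_wavefront_fixed(
            np.array([1, 3]) * s, np.array([0, 2, 4, 2]) * s, fp
        )
        assert r.score == 2 * s
        assert r.end == 1

    def test_out_of_range_inputs_rejected(self):
        fp = sm.FixedPointConfig()
        with pytest.raises(sm.SizeError):
            sm.sdtw_wavefront_fixed([40000], [1, 2], fp)

    def test_quantization_error_bound_vs_float(self):
        """With scale 32 and no overflow, (score/scale, end) tracks the
        float engine within the accumulated rounding budget."""
        fp = sm.FixedPointConfig()
        rng = np.random.default_rng(9)
        for _ in range(10):
            M, N = 20, 200
            y = rng.uniform(-3, 3, size=N)
            start = int(rng.integers(0, N - M))
            x = y[start:start + M] + rng.normal(0, 0.05, size=M)
            x = np.clip(x, -4, 4)
            fl = sm.sdtw_linear(x, y)
            xq = sm.quantize(x, fp)
            yq = sm.quantize(y, fp)
            fx = sm.sdtw_wavefront_fixed(xq, yq, fp)
            assert fx.end == fl.end
            assert abs(fx.score / fp.scale - fl.score) <= 2 * M * (0.5 / fp.scale) * 2


class TestBestAndSecond:
    def test_worked_example(self):
        best, second = sm.best_and_second(np.array([4.0, 2.0, 2.0, 2.0]), 0)
        assert best == (1, 2.0)
        assert second == (2, 2.0)

    def test_single_element_no_second(self):
        best, second = sm.best_and_second(np.array([3.0]), 2)
        assert best == (0, 3.0)
        assert second is None

    def test_pair_stream_input(self):
        best, second = sm.best_and_second([(10, 5.0), (20, 1.0), (30, 2.0)], 5)
        assert best == (20, 1.0)
        assert second == (30, 2.0)

    def test_empty_stream(self):
        with pytest.raises(sm.SizeError):
            sm.best_and_second(np.array([]), 1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=0, max_value=20))
    def test_matches_double_scan(self, seed, window):
        vals = np.random.default_rng(seed).integers(0, 50, size=40).astype(float)
        best, second = sm.best_and_second(vals, window)
        bi = min(range(40), key=lambda i: (vals[i], i))
        assert best == (bi, vals[bi])
        cands = [i for i in range(40) if abs(i - bi) > window]
        if not cands:
            assert second is None
        else:
            si = min(cands, key=lambda i: (vals[i], i))
            assert second == (si, vals[si])


class TestRunEngine:
    def test_dispatch_names(self, fp_default):
        x, y = np.array([1.0, 2.0]), np.array([0.0, 1.0, 2.0, 3.0])
        xq, yq = sm.quantize(x, fp_default), sm.quantize(y, fp_default)
        for engine in sm.ENGINES:
            r = sm.run_engine(engine, x, y, x_quant=xq, y_quant=yq, fp=fp_default)
            assert r.engine == engine
        with pytest.raises(sm.ConfigError):
            sm.run_engine("fpga", x, y)

    def test_wavefront_requires_quantized(self):
        with pytest.raises(sm.ConfigError):
            sm.run_engine("wavefront", np.array([1.0]), np.array([1.0, 2.0]))
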