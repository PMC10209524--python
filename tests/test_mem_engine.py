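import pytest

from memfind.genome_io import SEPARATOR, genome_from_sequences
from memfind.mem_engine import (
    ConfigMismatchError,
    DiagonalCache,
    MatchTriple,
    chars_match,
    containment_skip,
    extend_seed,
    scan_query,
)
from memfind.params import Params, select_params
from memfind.seed_index import build_index
from memfind.synthetic import fixture_pair, generate_genome, oracle_mems


def _distinct_mems(R, Q, p, containment=True, idx=None):
    idx = idx or build_index(R, p)
    got = set()
    scan_query(R, Q, idx, p, got.add, containment=containment)
    return got


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("A", "A", True),
        ("C", "C", True),
        ("N", "N", False),
        ("A", "C", False),
        ("a", "a", False),  # text is uppercased before matching
        (chr(SEPARATOR), chr(SEPARATOR), False),
    ],
)
def test_chars_match_semantics(a, b, expected):
    assert chars_match(a, b) is expected


def test_extend_identical_strings():
    g = genome_from_sequences([("s", "ACGTACGTAC")])
    t = extend_seed(g, g, 0, 0, K=4, L=5)
    assert t == MatchTriple(0, 0, 10)


def test_extend_flanked_by_mismatches():
    R = genome_from_sequences([("r", "TTACGTAA")])
    Q = genome_from_sequences([("q", "GGACGTCC")])
    assert extend_seed(R, Q, 2, 2, K=4, L=4) == MatchTriple(2, 2, 4)
    assert extend_seed(R, Q, 2, 2, K=4, L=5) is None


def test_extension_stops_at_separators_and_ns():
    R = genome_from_sequences([("r1", "ACGT"), ("r2", "ACGT")])  # ACGT>ACGT
    t = extend_seed(R, R, 5, 5, K=4, L=1)
    assert t == MatchTriple(5, 5, 4)  # never crosses the separator
    Q = genome_from_sequences([("q", "ACGTNACGT")])
    t = extend_seed(Q, Q, 0, 0, K=4, L=1)
    assert t == MatchTriple(0, 0, 4)  # N breaks the run


def test_reported_triples_are_maximal(mutated_pair):
    R, Q = mutated_pair
    p = select_params(50)
    for t in _distinct_mems(R, Q, p):
        assert R.text[t.r_start : t.r_start + t.length] == Q.text[
            t.q_start : t.q_start + t.length
        ]
        assert all(c in b"ACGT" for c in R.text[t.r_start : t.r_start + t.length])
        before_ok = t.r_start == 0 or t.q_start == 0 or not chars_match(
            R.text[t.r_start - 1], Q.text[t.q_start - 1]
        )
        re_, qe = t.r_start + t.length, t.q_start + t.length
        after_ok = (
            re_ >= R.total_length
            or qe >= Q.total_length
            or not chars_match(R.text[re_], Q.text[qe])
        )
        assert before_ok and after_ok


def test_containment_skip_geometry():
    cache = DiagonalCache()
    assert containment_skip(cache, 40, 40, 36) is False
    cache.record(0, 0, 100)
    assert containment_skip(cache, 40, 40, 36) is True  # 40>=0 and 76<=100
    assert containment_skip(cache, 150, 40, 36) is False  # diagonal 110
    assert containment_skip(cache, 70, 70, 36) is False  # 106 > 100


def test_identical_genomes_full_length_mem():
    R = generate_genome(1, [1000], seed=33)
    p = select_params(50)
    got = _distinct_mems(R, R, p)
    assert got == oracle_mems(R, R, 50)
    assert MatchTriple(0, 0, 1000) in got


def test_query_without_nucleotides_yields_nothing():
    R = generate_genome(1, [500], seed=2)
    Q = genome_from_sequences([("q", "N" * 300)])
    p = select_params(50)
    assert _distinct_mems(R, Q, p) == set()


def test_containment_filter_is_lossless(mutated_pair):
    R, Q = mutated_pair
    p = select_params(50)
    idx = build_index(R, p)
    on = _distinct_mems(R, Q, p, containment=True, idx=idx)
    off = _distinct_mems(R, Q, p, containment=False, idx=idx)
    assert on == off


def test_params_mismatch_rejected():
    R = generate_genome(1, [500], seed=2)
    idx = build_index(R, select_params(50))
    with pytest.raises(ConfigMismatchError):
        scan_query(R, R, idx, select_params(200), lambda t: None)


@pytest.mark.parametrize("L", [37, 50, 80, 132, 200])
def test_completeness_and_soundness_against_oracle(mutated_pair, L):
    """Distinct engine output equals the brute-force oracle set exactly,
    end to end through the coprime-sampling guarantee."""
    R, Q = mutated_pair
    p = select_params(L)
    assert _distinct_mems(R, Q, p) == oracle_mems(R, Q, L)


def test_completeness_with_ambiguity_runs():
    R, Q = fixture_pair(seed=5, lengths=[4000, 2000], divergence=0.01,
                        n_run_rate=0.001)
    p = select_params(50)
    assert _distinct_mems(R, Q, p) == oracle_mems(R, Q, 50)


def test_probe_partitioning_covers_all_seeds(mutated_pair):
    """Splitting probes across workers never loses or invents MEMs."""
    import numpy as np

    R, Q = mutated_pair
    p = select_params(50)
    idx = build_index(R, p)
    probes = np.arange(0, Q.total_length - p.K + 1, p.k2, dtype=np.int64)
    whole = _distinct_mems(R, Q, p, idx=idx)
    for n_chunks in (2, 4):
        got = set()
        for chunk in np.array_split(probes, n_chunks):
            scan_query(R, Q, idx, p, got.add, probe_positions=chunk)
        assert got == whole
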