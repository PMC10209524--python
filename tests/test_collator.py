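import io
import random

import pytest

from memfind.collator import (
    Collator,
    CollatorConfig,
    OutputRecord,
    merge_spills,
    pack_key,
    sort_block,
    to_output_record,
    write_output,
    read_spill,
)
from memfind.mem_engine import MatchTriple
from memfind.predecessor_map import PredecessorMap
from memfind.genome_io import SeqRecord


def _random_triples(n, seed, coord_max=10**6):
    rnd = random.Random(seed)
    return [
        MatchTriple(rnd.randrange(coord_max), rnd.randrange(coord_max), rnd.randrange(50, 500))
        for _ in range(n)
    ]


def test_pack_key_order_isomorphism_examples():
    t1 = MatchTriple(r_start=5, q_start=3, length=50)
    t2 = MatchTriple(r_start=2, q_start=4, length=50)
    assert pack_key(t1) < pack_key(t2)  # qStart dominates
    t3 = MatchTriple(r_start=9, q_start=3, length=50)
    assert pack_key(t1) < pack_key(t3)  # rStart breaks ties


def test_pack_key_matches_pair_comparator_on_random_triples():
    triples = _random_triples(10_000, seed=1)
    by_key = sorted(triples, key=pack_key)
    by_pair = sorted(triples, key=lambda t: (t.q_start, t.r_start))
    assert [(t.q_start, t.r_start) for t in by_key] == [
        (t.q_start, t.r_start) for t in by_pair
    ]


def test_pack_key_overflow():
    with pytest.raises(OverflowError):
        pack_key(MatchTriple(1 << 40, 0, 50))


def test_sort_block_small_uses_comparison_and_sorts():
    cfg = CollatorConfig()
    triples = _random_triples(10, seed=2)
    out = sort_block(triples, cfg)
    assert out == sorted(triples, key=pack_key)


def test_radix_path_equals_comparison_path():
    cfg = CollatorConfig()
    triples = _random_triples(5000, seed=3)
    assert len(triples) > cfg.sort_threshold
    assert sort_block(triples, cfg) == sorted(triples, key=pack_key)


def test_sort_block_idempotent_on_sorted_input():
    cfg = CollatorConfig()
    triples = sorted(_random_triples(3000, seed=4), key=pack_key)
    assert sort_block(list(triples), cfg) == triples


def test_collator_config_validation(tmp_path):
    with pytest.raises(ValueError):
        CollatorConfig(match_block=6)
    with pytest.raises(ValueError):
        CollatorConfig(match_block=10)  # not divisible by 4


def test_block_dump_spills_three_quarters(tmp_path):
    cfg = CollatorConfig(match_block=8)
    c = Collator(cfg, tmp_path)
    c.begin_sequence("s")
    triples = sorted(_random_triples(8, seed=5), key=pack_key)
    for t in triples:
        c.push(t)
    # block filled once: 6 spilled, 2 retained
    assert c.blocks_dumped == 1
    assert len(c._buf) == 2
    path = c.end_sequence()
    assert list(read_spill(path)) == triples


def test_duplicates_collapse_to_single_record(tmp_path):
    cfg = CollatorConfig(match_block=8)
    c = Collator(cfg, tmp_path)
    c.begin_sequence("s")
    t = MatchTriple(10, 20, 55)
    for _ in range(5):
        c.push(t)
    path = c.end_sequence()
    assert list(read_spill(path)) == [t]
    assert c.rescues == 0


def test_rescue_recovers_adversarial_stream(tmp_path):
    """An early-keyed match arriving after a full-block dump forces the
    rescue path; output still equals a full in-memory sort."""
    cfg = CollatorConfig(match_block=8)
    c = Collator(cfg, tmp_path)
    c.begin_sequence("s")
    late = [MatchTriple(i, 1000 + i, 60) for i in range(10)]
    early = MatchTriple(0, 1, 60)
    for t in late:
        c.push(t)
    c.push(early)
    path = c.end_sequence()
    assert c.rescues == 1
    expected = sorted(set(late + [early]), key=pack_key)
    assert list(read_spill(path)) == expected


def test_no_rescue_on_orderly_stream(tmp_path):
    cfg = CollatorConfig(match_block=8)
    c = Collator(cfg, tmp_path)
    c.begin_sequence("s")
    for t in sorted(_random_triples(40, seed=6), key=pack_key):
        c.push(t)
    c.end_sequence()
    assert c.rescues == 0


@pytest.mark.parametrize("match_block", [8, 64, 1 << 21])
def test_spill_stream_equals_full_sort_for_any_block_size(tmp_path, match_block):
    triples = _random_triples(500, seed=7, coord_max=2000)  # forces duplicates
    cfg = CollatorConfig(match_block=match_block)
    c = Collator(cfg, tmp_path / str(match_block))
    (tmp_path / str(match_block)).mkdir()
    c.begin_sequence("s")
    for t in triples:
        c.push(t)
    path = c.end_sequence()
    expected = sorted(set(triples), key=pack_key)
    assert list(read_spill(path)) == expected


def test_merge_spills_equals_single_full_sort(tmp_path):
    all_triples = []
    paths = []
    for i in range(3):
        triples = sorted(set(_random_triples(200, seed=10 + i, coord_max=3000)), key=pack_key)
        all_triples.extend(triples)
        cfg = CollatorConfig(match_block=64)
        c = Collator(cfg, tmp_path)
        c.begin_sequence(f"f{i}")
        for t in triples:
            c.push(t)
        paths.append(c.end_sequence())
    merged = list(merge_spills(paths))
    assert merged == sorted(set(all_triples), key=pack_key)


def test_to_output_record_worked_example(chr_records):
    records, total = chr_records
    m = PredecessorMap.from_records(records, total, step=3)
    q_rec = SeqRecord("q1", 0, 30)
    t = MatchTriple(r_start=14, q_start=6, length=120)
    rec = to_output_record(t, m, q_rec)
    assert rec == OutputRecord("chr4", 2, 7, 120)  # 14 - 13 + 1 = 2
    t2 = MatchTriple(r_start=13, q_start=0, length=40)
    assert to_output_record(t2, m, q_rec).ref_pos == 1


def test_write_output_golden_format():
    q1 = SeqRecord("q1", 0, 500)
    q2 = SeqRecord("q2", 501, 100)
    groups = [
        (q1, [OutputRecord("chr4", 2, 7, 120)]),
        (q2, []),  # header still emitted for empty sequences
    ]
    sink = io.StringIO()
    n = write_output(groups, sink)
    assert n == 1
    assert sink.getvalue() == "> q1\n chr4\t2\t7\t120\n> q2\n"
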