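"""End-to-end MEM finding: index, scan, collate, convert, write.

The query's sampled probe positions are partitioned into contiguous
worker chunks; each worker scans its chunk with a private containment
cache and its own collator (one spill file per query sequence touched).
Because the containment filter is lossless and the collator deduplicates,
the final output is byte-identical for any worker count, any match-block
size, either mode, and with the filter on or off — worker count and
memory knobs are resource dials, never result dials.
"""

from __future__ import annotations

import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .collator import (
    Collator,
    CollatorConfig,
    merge_spills,
    to_output_record,
    write_output,
)
from .genome_io import Genome, load_fasta
from .mem_engine import scan_query
from .params import DEFAULT, MEMORY_FRUGAL, Params, select_params
from .predecessor_map import PredecessorMap
from .seed_index import build_index

__all__ = ["RunConfig", "run", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Memory-frugal match-block default (quarter of the default block).
_MF_MATCH_BLOCK = 1 << 19


@dataclass
class RunConfig:
    """One command-line invocation's worth of settings."""

    ref_path: str
    query_path: str
    out_path: str
    L: int
    mode: str = DEFAULT
    workers: int = 1
    temp_dir: str | None = None
    keep_temp: bool = False
    seed_length: int | None = None
    match_block: int | None = None
    bucket_bits: int | None = None
    containment: bool = True
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


def run_pipeline(
    R: Genome,
    Q: Genome,
    params: Params,
    sink,
    *,
    workers: int = 1,
    match_block: int | None = None,
    bucket_bits: int | None = None,
    containment: bool = True,
    temp_dir: str | None = None,
    keep_temp: bool = False,
) -> dict:
    """Find all MEMs of length >= params.L and write them to ``sink``.

    Returns a summary dict (sequences read, seeds probed, candidates
    verified, MEMs written, rescues, blocks dumped).
    """
    if match_block is None:
        match_block = _MF_MATCH_BLOCK if params.mode == MEMORY_FRUGAL else 1 << 21
    idx = build_index(R, params, bucket_bits)
    r_map = PredecessorMap.for_genome(R)

    K, k2 = params.K, params.k2
    nq = Q.total_length
    if nq >= K:
        probes = np.arange(0, nq - K + 1, k2, dtype=np.int64)
    else:
        probes = np.empty(0, dtype=np.int64)
    chunks = np.array_split(probes, workers)

    own_tmp = temp_dir is None
    spill_dir = Path(tempfile.mkdtemp(prefix="memfind_")) if own_tmp else Path(temp_dir)
    spill_dir.mkdir(parents=True, exist_ok=True)

    stats: dict = {"seeds_probed": 0, "candidates_verified": 0}
    cfg = CollatorConfig(match_block=match_block, temp_dir=spill_dir, workers=workers)
    spills: dict[int, list[Path]] = {ri: [] for ri in range(len(Q.records))}
    rescues = 0
    blocks_dumped = 0
    try:
        for w, chunk in enumerate(chunks):
            if len(chunk) == 0:
                continue
            collator = Collator(cfg, spill_dir)
            for ri, rec in enumerate(Q.records):
                sel = chunk[(chunk >= rec.start) & (chunk + K <= rec.end)]
                if len(sel) == 0:
                    continue
                # Fresh containment cache per (worker, query sequence).
                collator.begin_sequence(f"w{w}_r{ri}")
                scan_query(
                    R,
                    Q,
                    idx,
                    params,
                    collator.push,
                    probe_positions=sel,
                    containment=containment,
                    stats=stats,
                )
                spills[ri].append(collator.end_sequence())
            rescues += collator.rescues
            blocks_dumped += collator.blocks_dumped

        def groups():
            for ri, rec in enumerate(Q.records):
                yield rec, (
                    to_output_record(t, r_map, rec) for t in merge_spills(spills[ri])
                )

        mems_written = write_output(groups(), sink)
    finally:
        if not keep_temp:
            if own_tmp:
                shutil.rmtree(spill_dir, ignore_errors=True)
            else:
                for paths in spills.values():
                    for pth in paths:
                        pth.unlink(missing_ok=True)

    return {
        "ref_sequences": len(R.records),
        "query_sequences": len(Q.records),
        "sampled_index_positions": idx.n_positions,
        "seeds_probed": stats["seeds_probed"],
        "candidates_verified": stats["candidates_verified"],
        "mems_written": mems_written,
        "rescues": rescues,
        "blocks_dumped": blocks_dumped,
    }


def run(cfg: RunConfig) -> dict:
    """Load inputs, select parameters, run the pipeline, write the output."""
    R = load_fasta(cfg.ref_path)
    Q = load_fasta(cfg.query_path)
    params = select_params(cfg.L, cfg.mode, seed_length=cfg.seed_length)
    logger.info(
        "parameters: L=%d K=%d k1=%d k2=%d mode=%s",
        params.L,
        params.K,
        params.k1,
        params.k2,
        params.mode,
    )
    with open(cfg.out_path, "w") as sink:
        summary = run_pipeline(
            R,
            Q,
            params,
            sink,
            workers=cfg.workers,
            match_block=cfg.match_block,
            bucket_bits=cfg.bucket_bits,
            containment=cfg.containment,
            temp_dir=cfg.temp_dir,
            keep_temp=cfg.keep_temp,
        )
    logger.info("summary: %s", summary)
    return summary
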