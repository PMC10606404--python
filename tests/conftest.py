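"""Shared fixtures: one pipeline run per scenario, reused across tests.

The standard scenario is 2 chromosomes x 100 kb with six planted 1 kb
markers, three of them excised with 2 kb margins, error-free reads at
depth 20 and all built-in toy adapters, fixed seed.
"""

from __future__ import annotations

import numpy as np
import pytest

from contigrecall import fill_assembly, make_fixture, merge_contig_sets
from contigrecall.io_formats import AlignmentRecord

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def haploid_fixture():
    return make_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def haploid_result(haploid_fixture):
    fx = haploid_fixture
    return fill_assembly(
        fx.chrom_assembly, merge_contig_sets(fx.contig_sets), fx.reads, fx.catalog
    )


@pytest.fixture(scope="session")
def partial_fixture():
    return make_fixture(seed=FIXTURE_SEED, remove_support=True)


@pytest.fixture(scope="session")
def partial_result(partial_fixture):
    fx = partial_fixture
    return fill_assembly(
        fx.chrom_assembly, merge_contig_sets(fx.contig_sets), fx.reads, fx.catalog
    )


@pytest.fixture(scope="session")
def diploid_fixture():
    return make_fixture(seed=FIXTURE_SEED, diploid=True)


@pytest.fixture(scope="session")
def diploid_result(diploid_fixture):
    fx = diploid_fixture
    return fill_assembly(
        fx.chrom_assembly, merge_contig_sets(fx.contig_sets), fx.reads, fx.catalog
    )


def deletion_position_on_degraded(truth, deletion):
    """Excision point of a deletion in degraded-chromosome coordinates."""
    shift = sum(
        d.end - d.start
        for d in truth.deletions
        if d.chrom_id == deletion.chrom_id and d.start < deletion.start
    )
    return deletion.start - shift


def random_alignments(
    rng: np.random.Generator,
    n: int,
    query_ids: list[str],
    target_ids: list[str],
    target_len: int = 10_000,
    query_len: int = 2_000,
    with_tags: bool = False,
) -> list[AlignmentRecord]:
    """Arbitrary valid alignment records for brute-force comparisons."""
    records = []
    for _ in range(n):
        q_start = int(rng.integers(0, query_len - 1))
        q_end = int(rng.integers(q_start + 1, query_len + 1))
        t_start = int(rng.integers(0, target_len - 1))
        t_end = int(rng.integers(t_start + 1, target_len + 1))
        block = max(q_end - q_start, t_end - t_start)
        tags = {}
        if with_tags and rng.random() < 0.7:
            tags["tp"] = "P" if rng.random() < 0.7 else "S"
        records.append(
            AlignmentRecord(
                query_id=str(rng.choice(query_ids)),
                query_len=query_len,
                query_start=q_start,
                query_end=q_end,
                strand="+" if rng.random() < 0.5 else "-",
                target_id=str(rng.choice(target_ids)),
                target_len=target_len,
                target_start=t_start,
                target_end=t_end,
                residue_matches=int(rng.integers(1, block + 1)),
                block_len=block,
                mapq=int(rng.integers(0, 61)),
                tags=tags,
            )
        )
    return records
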