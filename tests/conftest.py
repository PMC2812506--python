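"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results by the most direct method
available (full-frame translation and string splitting, generic maximum
bipartite matching, quadratic scans) so they share no code with the
implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from sixframe.simulate import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic dataset (2 x 50 kb, 10 genes, 5 novel ORFs,
    3 pseudogenes), generated once per session with a fixed seed."""
    return generate_fixture(FixtureConfig(), seed=1)


@pytest.fixture(scope="session")
def pipeline_result(default_fixture):
    from sixframe.workflow import run_pipeline

    return run_pipeline(default_fixture, validate=True, seed=1)


# ------------------------------------------------------------- oracles

def brute_force_six_frame(
    seq: str, min_len: int = 6, require_kr: bool = True
) -> set[tuple]:
    """Independent six-frame enumerator: translate each full frame with
    Biopython, split on stop symbols, recover coordinates by arithmetic.

    Returns a set of (strand, frame, genomic_start, genomic_end, aa_seq).
    Only unambiguous sequences are supported (ambiguity handling is the
    implementation's own extension point).
    """
    n = len(seq)
    out = set()
    for strand in (1, -1):
        reading = seq if strand == 1 else str(Seq(seq).reverse_complement())
        for frame in (1, 2, 3):
            sub = reading[frame - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            aa = str(Seq(sub).translate())
            pos = 0
            for chunk in aa.split("*"):
                if len(chunk) >= min_len and (
                    not require_kr or "K" in chunk or "R" in chunk
                ):
                    s0 = (frame - 1) + 3 * pos  # 0-based on reading strand
                    e0 = s0 + 3 * len(chunk) - 1
                    if strand == 1:
                        g = (s0 + 1, e0 + 1)
                    else:
                        g = (n - e0, n - s0)
                    out.add((strand, frame, g[0], g[1], chunk))
                pos += len(chunk) + 1
    return out


def brute_force_matching(a, b, tol: float) -> int:
    """Maximum bipartite matching size via networkx Hopcroft-Karp."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from((("a", i) for i in range(len(a))))
    g.add_nodes_from((("b", j) for j in range(len(b))))
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if abs(x - y) <= tol:
                g.add_edge(("a", i), ("b", j))
    match = nx.bipartite.maximum_matching(
        g, top_nodes=[("a", i) for i in range(len(a))]
    )
    return len(match) // 2


def brute_force_digest(aa_seq: str, missed: int) -> set[str]:
    """Fully tryptic products by direct boundary enumeration."""
    sites = [
        i + 1
        for i in range(len(aa_seq) - 1)
        if aa_seq[i] in "KR" and aa_seq[i + 1] != "P"
    ]
    bounds = [0] + sites + [len(aa_seq)]
    out = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, len(bounds)):
            if j - i - 1 <= missed:
                out.add(aa_seq[bounds[i] : bounds[j]])
    return out


def rand_spectrum(rng: np.random.Generator, n_peaks: int, spectrum_id: str = "S"):
    from sixframe.search import Spectrum

    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=500.0,
        precursor_charge=2,
        mz=rng.uniform(100, 1500, size=n_peaks),
        intensity=rng.exponential(10, size=n_peaks) + 1,
    )
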