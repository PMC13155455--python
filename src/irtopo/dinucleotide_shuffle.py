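"""Dinucleotide-preserving sequence shuffling (Altschul–Erickson Euler walk).

A shuffled sequence has exactly the same multiset of overlapping dinucleotides
as the input — hence identical mononucleotide counts, GC content, and fixed
first/last residues. The construction views the sequence as an Euler path in
the doublet multigraph: one "last exit" edge per vertex is drawn uniformly and
accepted only if those edges form an arborescence into the final residue
(rejection sampling); remaining out-edges are permuted uniformly and the walk
is read off. ``N`` participates as a fifth symbol, so N-containing doublets
are preserved too.

Genomes are shuffled in independent non-overlapping chunks (default 1,000 bp);
doublets straddling a chunk boundary are not preserved, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeSequence


@dataclass(frozen=True)
class ShuffleParams:
    chunk_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chunk_bp < 2:
            raise ValueError("chunk_bp must be >= 2")


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


def shuffle_chunk(seq: str, rng: np.random.Generator) -> str:
    """One Euler-walk shuffle of ``seq``; returns ``seq`` unchanged if len < 2."""
    n = len(seq)
    if n < 2:
        return seq
    out_edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        out_edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(set(seq))
    if len(vertices) == 1:
        return seq

    # draw per-vertex last-exit edges until they form an arborescence into `last`
    while True:
        last_edge: dict[str, str] = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            succ = out_edges.get(v)
            if not succ:
                ok = False
                break
            last_edge[v] = succ[rng.integers(len(succ))]
        if not ok:
            # a non-terminal vertex with no out-edges cannot occur for a real
            # sequence (Euler path exists); defensive fallback
            raise ValueError("doublet graph has no Euler path")
        for v in vertices:
            if v == last:
                continue
            cur, hops = v, 0
            while cur != last and hops <= len(vertices):
                cur = last_edge.get(cur, last)
                hops += 1
            if cur != last:
                ok = False
                break
        if ok:
            break

    # permute the remaining out-edges per vertex; append the last-exit edge
    ordered: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(out_edges.get(v, []))
        if v in last_edge:
            edges.remove(last_edge[v])
        perm = rng.permutation(len(edges))
        edges = [edges[k] for k in perm]
        if v in last_edge:
            edges.append(last_edge[v])
        ordered[v] = edges

    ptr = {v: 0 for v in vertices}
    walk = [first]
    cur = first
    for _ in range(n - 1):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def shuffle_genome(genome: GenomeSequence, params: ShuffleParams) -> GenomeSequence:
    """Concatenation of independently shuffled chunk_bp blocks (one seeded stream).

    The final partial block (< chunk_bp) is shuffled as its own segment.
    """
    rng = np.random.default_rng(params.seed)
    seq = genome.residues
    chunks = []
    for off in range(0, len(seq), params.chunk_bp):
        chunks.append(shuffle_chunk(seq[off : off + params.chunk_bp], rng))
    return GenomeSequence(genome.seq_id, "".join(chunks), genome.topology)
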