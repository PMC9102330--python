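"""k-let-preserving random sequence shuffling (null model).

Random shuffling that preserves the exact multiset of k-lets (k = 2:
dinucleotides) destroys the positional and periodic structure of
dinucleotide occurrences while keeping sequence composition intact, which
is precisely the null model needed when asking whether a mapped nucleosome
position reflects sequence patterns rather than composition.

The algorithm is the Altschul-Erickson Euler-path doublet shuffle,
generalized to k-lets: (k-1)-mers are vertices of a multigraph whose edges
are the sequence's k-lets; a random "last-exit" edge is drawn per vertex
and accepted when the last edges form an arborescence into the final
vertex, after which the remaining edges are permuted and the Euler path is
walked.  The first and last (k-1)-mers of the sequence are preserved, and
every output has exactly the input's k-let counts.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .seqio import SequenceBatch

__all__ = ["klet_shuffle", "shuffle_batch"]

_MAX_ARBORESCENCE_TRIES = 100_000


def klet_shuffle(
    seq: str,
    k: int = 2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Shuffle ``seq`` preserving the exact multiset of its k-lets.

    A seed (or an explicit generator) is mandatory: shuffles are part of a
    null-model contract and must be reproducible.
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for reproducible shuffling")
        rng = np.random.default_rng(seed)
    n = len(seq)
    if k < 1 or k > n:
        raise ValueError(f"k must satisfy 1 <= k <= len(seq); got k={k}, len={n}")
    if k == 1:
        return "".join(np.array(list(seq))[rng.permutation(n)])
    if n == k:
        return seq

    # Multigraph on (k-1)-mers; the sequence is an Euler path through it.
    verts = [seq[i : i + k - 1] for i in range(n - k + 2)]
    s_first, s_last = verts[0], verts[-1]
    out: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(verts, verts[1:]):
        out[a].append(b)

    # Draw per-vertex last-exit edges until they form an in-tree to s_last.
    last_edge: dict[str, str] = {}
    for _ in range(_MAX_ARBORESCENCE_TRIES):
        last_edge = {
            v: targets[rng.integers(len(targets))]
            for v, targets in out.items()
            if v != s_last
        }
        ok = True
        for v in last_edge:
            cur, hops = v, 0
            while cur != s_last and hops <= len(last_edge):
                cur = last_edge.get(cur, cur)
                hops += 1
            if cur != s_last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - arborescence acceptance is near-certain for DNA
        raise RuntimeError("failed to sample an arborescence")

    adj: dict[str, list[str]] = {}
    for v, targets in out.items():
        rest = list(targets)
        if v != s_last:
            rest.remove(last_edge[v])
        rest = [rest[i] for i in rng.permutation(len(rest))]
        if v != s_last:
            rest.append(last_edge[v])
        adj[v] = rest

    ptr: dict[str, int] = defaultdict(int)
    chars = [s_first]
    cur = s_first
    for _ in range(n - k + 1):
        nxt = adj[cur][ptr[cur]]
        ptr[cur] += 1
        chars.append(nxt[-1])
        cur = nxt
    return "".join(chars)


def shuffle_batch(batch: SequenceBatch, k: int = 2, seed: int = 0) -> SequenceBatch:
    """Per-record k-let shuffle with per-record derived sub-seeds.

    Record ids gain a ``_shuf`` suffix; two calls with the same seed give
    byte-identical output.
    """
    children = np.random.SeedSequence(seed).spawn(len(batch))
    records = [
        (name + "_shuf", klet_shuffle(seq, k=k, rng=np.random.default_rng(child)))
        for (name, seq), child in zip(batch.records, children)
    ]
    return SequenceBatch(records, alignment=batch.alignment)
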