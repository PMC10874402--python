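"""Light-weight local alignment by exact k-mer seeding and diagonal chaining.

Desk-scale sequences only (insertions of a few kb against consensus
libraries or synthetic genomes of ~10^5 bp).  Seeds are exact k-mer matches
grouped by diagonal; runs of consecutive seeds on one diagonal become
high-scoring pairs (HSPs).  Percent identity of a candidate segment is
computed with edlib's global edit distance.  An external aligner can stand
in for larger problems; nothing downstream depends on more than the HSP
tuple shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

DEFAULT_K = 15

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Hsp:
    """An exact diagonal run: query [qstart, qend) matches target [tstart, tend)."""

    qstart: int
    qend: int
    tstart: int
    tend: int

    @property
    def length(self) -> int:
        return self.qend - self.qstart


def kmer_index(seq: str, k: int = DEFAULT_K) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def chain_hsps(
    query: str,
    target: str | None = None,
    k: int = DEFAULT_K,
    target_index: dict[str, list[int]] | None = None,
    max_gap: int = 0,
) -> list[Hsp]:
    """All maximal exact diagonal runs between query and target.

    ``max_gap`` merges runs on the same diagonal separated by at most that
    many unmatched query positions (mismatches on the diagonal).
    """
    if target_index is None:
        target_index = kmer_index(target, k)
    by_diag: dict[int, list[int]] = {}
    for q in range(len(query) - k + 1):
        for t in target_index.get(query[q : q + k], ()):
            by_diag.setdefault(t - q, []).append(q)
    hsps = []
    for diag, qs in by_diag.items():
        qs.sort()
        run_start = prev = qs[0]
        for q in qs[1:]:
            if q - prev <= k + max_gap:
                prev = q
            else:
                hsps.append(Hsp(run_start, prev + k, run_start + diag, prev + k + diag))
                run_start = prev = q
        hsps.append(Hsp(run_start, prev + k, run_start + diag, prev + k + diag))
    return hsps


def identity_pct(a: str, b: str) -> float:
    """Percent identity from edlib global edit distance (0 when either empty)."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 100.0 * (1.0 - dist / max(len(a), len(b)))


def best_chain(hsps: Sequence[Hsp], max_locus_gap: int = 2000) -> list[Hsp]:
    """Greedy co-linear chain: seed from the longest HSP and absorb HSPs that
    are query/target co-linear with it within ``max_locus_gap`` bp."""
    if not hsps:
        return []
    ordered = sorted(hsps, key=lambda h: h.length, reverse=True)
    chain = [ordered[0]]
    for h in ordered[1:]:
        ok = True
        for c in chain:
            same_order = (h.qstart >= c.qend and h.tstart >= c.tend - max_locus_gap) or (
                h.qend <= c.qstart and h.tend <= c.tstart + max_locus_gap
            )
            near = (
                abs(h.tstart - c.tend) <= max_locus_gap
                or abs(c.tstart - h.tend) <= max_locus_gap
                or (h.tstart < c.tend and c.tstart < h.tend)
            )
            if not (same_order and near):
                ok = False
                break
        if ok:
            chain.append(h)
    chain.sort(key=lambda h: h.qstart)
    return chain
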