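"""Independent brute-force oracle for overlap resolution.

Enumerates all subsets of hits and returns the unique subset S that is
a fixpoint of the pairwise rule cascade: a hit h belongs to S iff no
member of S that beats h in the cascade order overlaps h over more than
half of h's own length. This encodes the rule that an ignored hit plays
no further role (only surviving hits can veto), without ever running
the greedy path it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

from genecontext.annotation import DomainHit, ModelKind


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1)


def _beats(a: DomainHit, ia: int, b: DomainHit, ib: int) -> bool:
    """True iff hit a takes priority over b in the printed cascade.

    Higher score wins; at equal score the greater length normalized by
    the profile HMM length wins (1e-9 tolerance); then the longer raw
    hit; then accession, then input position (documented tie-breaks).
    """
    if a.score != b.score:
        return a.score > b.score
    na, nb = a.hit_length / a.model_len, b.hit_length / b.model_len
    if not math.isclose(na, nb, rel_tol=0.0, abs_tol=1e-9):
        return na > nb
    if a.hit_length != b.hit_length:
        return a.hit_length > b.hit_length
    if a.model_acc != b.model_acc:
        return a.model_acc < b.model_acc
    return ia < ib


def brute_force_resolve(
    hits: Sequence[DomainHit], max_overlap_frac: float = 0.5
) -> list[DomainHit]:
    """Resolve by exhaustive subset search (n <= ~12)."""
    n = len(hits)
    solutions = []
    for mask in itertools.product([False, True], repeat=n):
        ok = True
        for i in range(n):
            vetoed = any(
                mask[j]
                and j != i
                and _beats(hits[j], j, hits[i], i)
                and _overlap(hits[j], hits[i])
                > max_overlap_frac * hits[i].hit_length
                for j in range(n)
            )
            # fixpoint: i is in iff it is not vetoed by an accepted hit
            if mask[i] == vetoed:
                ok = False
                break
        if ok:
            solutions.append([hits[i] for i in range(n) if mask[i]])
    assert len(solutions) == 1, f"expected unique fixpoint, got {len(solutions)}"
    return sorted(
        solutions[0], key=lambda h: (h.ali_from, h.ali_to, h.model_acc)
    )


def random_instance(rng, max_hits: int = 8) -> list[DomainHit]:
    """A random overlapping-hit instance with deliberate score ties."""
    n = int(rng.integers(1, max_hits + 1))
    hits = []
    for i in range(n):
        start = int(rng.integers(1, 150))
        length = int(rng.integers(10, 120))
        hits.append(
            DomainHit(
                protein_id="P1",
                model_acc=f"COG{int(rng.integers(0, 5)):04d}",
                model_kind=ModelKind.COG,
                model_len=int(rng.integers(40, 300)),
                ali_from=start,
                ali_to=start + length - 1,
                score=float(rng.choice([26.0, 30.0, 30.0, 47.5, 60.0, 60.0, 110.0])),
                evalue=1e-6,
            )
        )
    return hits
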