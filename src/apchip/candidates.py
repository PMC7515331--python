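"""Cluster-subset construction and candidate filtering.

Every l-mer of the first h = t - q + 1 sequences is a *reference*.  Around
each reference the cluster subset gathers all l-mers of the *other*
sequences within Hamming radius k; since any two instances of one motif are
within 2d of each other, a reference that is itself an instance captures
each remaining instance with probability pk_motif(k) (all of them at
k = 2d).

Two thresholds prune the h*(n-l+1) subsets before clustering: a sequence
supports the reference when it contributes at least
max(1, ceil(p_occf * (n_i - l + 1))) members (its own expected degenerate
occurrence count), and a subset survives when at least q sequences —
counting the reference's own — support it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Iterator, Literal

import numpy as np

from .dataset import LMerOccurrence, SequenceDataset
from .probability import MotifProblem, occurrence_frequency

__all__ = [
    "ClusterSubset",
    "hamming",
    "build_cluster_subset",
    "enumerate_references",
    "occurrence_threshold",
    "filter_candidates",
]

_COMP = str.maketrans("ACGT", "TGCA")


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class ClusterSubset:
    """A reference l-mer plus the members gathered within radius k."""

    reference: LMerOccurrence
    members: list[LMerOccurrence]
    hits_per_sequence: dict[int, int] = field(default_factory=dict)
    supported_sequences: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.members)


def build_cluster_subset(
    reference: LMerOccurrence,
    dataset: SequenceDataset,
    k: int,
    both_strands: bool = False,
    max_per_sequence: int | None = None,
) -> ClusterSubset:
    """Gather all l-mers within Hamming distance k of the reference.

    Scans every offset of every sequence except the reference's own; the
    reference itself is always a member.  With ``both_strands`` the
    reverse-complement of each window is also tested (the member then stores
    the reverse-complemented text).  ``max_per_sequence`` optionally keeps
    only the closest few members per sequence (ties by offset), a ZOOPS-style
    reduction for very weak instances whose neighborhoods otherwise explode.
    """
    l = len(reference.text)
    from .dataset import encode

    ref_codes = encode(reference.text)
    members = [reference]
    hits: dict[int, int] = {}
    for i in range(dataset.t):
        if i == reference.seq_index:
            continue
        win, valid = dataset.windows(i, l)
        if win.shape[0] == 0:
            continue
        dist = (win != ref_codes).sum(axis=1)
        dist = np.where(valid, dist, l + 1)
        texts_rc: dict[int, str] = {}
        if both_strands:
            rc_dist = (win[:, ::-1] != (3 - ref_codes)).sum(axis=1)
            rc_dist = np.where(valid, rc_dist, l + 1)
            use_rc = rc_dist < dist
            for j in np.flatnonzero(use_rc):
                texts_rc[int(j)] = dataset.sequences[i][j : j + l].translate(_COMP)[::-1]
            dist = np.minimum(dist, rc_dist)
        sel = np.flatnonzero(dist <= k)
        if max_per_sequence is not None and sel.size > max_per_sequence:
            order = np.lexsort((sel, dist[sel]))
            sel = np.sort(sel[order[:max_per_sequence]])
        hits[i] = int(sel.size)
        seq = dataset.sequences[i]
        for j in sel:
            j = int(j)
            text = texts_rc.get(j, seq[j : j + l])
            members.append(LMerOccurrence(i, j, text))
    return ClusterSubset(reference=reference, members=members, hits_per_sequence=hits)


def enumerate_references(
    dataset: SequenceDataset, l: int, q: int, dedup: bool = True
) -> Iterator[LMerOccurrence]:
    """Yield reference l-mers from the first h = t - q + 1 sequences.

    Under ZOOPS at least one of the first h sequences carries an instance,
    so some reference is a true instance.  Occurrences are yielded in
    (sequence, offset) order; with ``dedup`` an l-mer text already seen is
    skipped, since it would rebuild an identical subset.
    """
    if not (1 <= q <= dataset.t):
        raise ValueError(f"need 1 <= q <= t, got q={q}, t={dataset.t}")
    h = dataset.t - q + 1
    seen: set[str] = set()
    for i in range(h):
        for occ in dataset.iter_lmers(i, l):
            if dedup:
                if occ.text in seen:
                    continue
                seen.add(occ.text)
            yield occ


def occurrence_threshold(
    problem: MotifProblem,
    n_positions: int,
    p_mut: float | None = None,
    mode: Literal["neighborhood", "literal"] = "neighborhood",
) -> int:
    """Per-sequence hit threshold p_occf * (n - l + 1), floored at one hit."""
    p_occf = occurrence_frequency(problem.l, problem.d, p_mut, mode)
    return max(1, ceil(p_occf * n_positions))


def filter_candidates(
    subset: ClusterSubset,
    problem: MotifProblem,
    occ_threshold: int | None = None,
    dataset: SequenceDataset | None = None,
) -> bool:
    """Decide whether a cluster subset is a candidate for clustering.

    A sequence (other than the reference's own, which always supports
    itself) supports the reference when its hit count reaches the occurrence
    threshold; the subset is a candidate when at least q sequences support
    it.  Fills ``subset.supported_sequences`` as a side effect.  With a
    ``dataset`` of unequal-length sequences the threshold is evaluated
    per sequence with that sequence's own length.
    """
    if occ_threshold is not None and occ_threshold < 1:
        raise ValueError("occ_threshold must be >= 1")
    l = problem.l
    supported = {subset.reference.seq_index}
    for i, count in subset.hits_per_sequence.items():
        if occ_threshold is not None:
            thr = occ_threshold
        else:
            n_i = dataset.length_of(i) if dataset is not None else problem.n
            thr = occurrence_threshold(problem, n_i - l + 1)
        if count >= thr:
            supported.add(i)
    subset.supported_sequences = supported
    return len(supported) >= problem.q
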