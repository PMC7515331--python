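"""Affinity propagation with cannot-link constraints for l-mer clustering.

Similarity between two l-mers is the negative Hamming distance, weighted by
a band factor rho (R1 on distances in (0, k], R2 on (k, 2k]) and struck to
a large negative *forbidden* sentinel for pairs drawn from the same
sequence — the cannot-link constraint that enforces the ZOOPS model (at
most one instance per sequence per cluster).  The published form writes the
forbidden branches as +inf factors inside a negative similarity; encoding
them as a finite sentinel at least 1e6 times the largest finite magnitude
keeps the message arithmetic finite while guaranteeing the pair never
co-clusters through an argmax.

Message passing is the standard responsibility/availability recursion with
damping; no randomness is injected, ties break toward the lowest point
index, so identical inputs give identical assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import ClusterSubset
from .dataset import LMerOccurrence, encode

__all__ = [
    "SimilarityMatrix",
    "APState",
    "adapted_similarity",
    "build_similarity",
    "run_ap",
    "extract_clusters",
]

_SENTINEL_FACTOR = 1e6


@dataclass
class SimilarityMatrix:
    """Pairwise adapted similarities for an ordered point set."""

    points: list[LMerOccurrence]
    s: np.ndarray  # (m, m) float, diagonal = preference
    forbidden: np.ndarray  # (m, m) bool, True for same-sequence pairs
    preference: float
    sentinel: float


def _rho(dist: int, k: int, R1: float, R2: float) -> float | None:
    """Distance-band weight; None marks the forbidden (2k, 4k] band."""
    if dist <= 0:
        return 0.0
    if dist <= k:
        return R1
    if dist <= 2 * k:
        return R2
    return None


def adapted_similarity(
    x: LMerOccurrence,
    y: LMerOccurrence,
    k: int,
    R1: float = 2.0,
    R2: float = 1.0,
    sentinel: float = -1e9,
) -> float:
    """Similarity -rho * d_H(x, y), or the forbidden sentinel.

    Same-sequence pairs and pairs beyond distance 2k get the sentinel;
    identical cross-sequence texts score 0 (the best possible).
    """
    if len(x.text) != len(y.text):
        raise ValueError("l-mer length mismatch")
    if x.seq_index == y.seq_index:
        return sentinel
    from .candidates import hamming

    dist = hamming(x.text, y.text)
    rho = _rho(dist, k, R1, R2)
    if rho is None:
        return sentinel
    return -rho * dist


def build_similarity(
    subset: ClusterSubset | list[LMerOccurrence],
    k: int,
    R1: float = 2.0,
    R2: float = 1.0,
    preference: float | str | None = None,
) -> SimilarityMatrix:
    """Vectorized similarity matrix over a cluster subset's members.

    ``preference`` sets the shared diagonal: a number is used as-is,
    ``"median"`` (the default) takes the median of the finite off-diagonal
    similarities (moderate cluster granularity) and ``"min"`` their minimum
    (fewer, larger clusters).
    """
    points = subset.members if isinstance(subset, ClusterSubset) else list(subset)
    m = len(points)
    codes = np.stack([encode(p.text) for p in points])
    seq_idx = np.array([p.seq_index for p in points])
    dist = (codes[:, None, :] != codes[None, :, :]).sum(axis=2).astype(float)

    rho = np.zeros_like(dist)
    rho[(dist > 0) & (dist <= k)] = R1
    rho[(dist > k) & (dist <= 2 * k)] = R2
    s = -rho * dist

    forbidden = (seq_idx[:, None] == seq_idx[None, :]) | (dist > 2 * k)
    np.fill_diagonal(forbidden, False)

    off = ~np.eye(m, dtype=bool) & ~forbidden
    finite = s[off]
    max_mag = float(np.abs(finite).max()) if finite.size else 1.0
    sentinel = -_SENTINEL_FACTOR * max(1.0, max_mag)
    s[forbidden] = sentinel
    if preference is None or preference == "median":
        preference = float(np.median(finite)) if finite.size else 0.0
    elif preference == "min":
        preference = float(finite.min()) if finite.size else 0.0
    elif isinstance(preference, str):
        raise ValueError(f"unknown preference mode {preference!r}")
    # deterministic symmetry breaking: perfectly symmetric inputs otherwise
    # leave every r+a diagonal at exactly zero and no exemplar emerges;
    # a tiny preference tilt decreasing with index breaks such ties toward
    # the lowest point index without injecting randomness
    tilt = 1e-8 * max(1.0, abs(float(preference)), max_mag)
    diag = float(preference) + tilt * (np.arange(m, 0, -1) / m)
    s[np.arange(m), np.arange(m)] = diag
    return SimilarityMatrix(points, s, forbidden, preference, sentinel)


@dataclass
class APState:
    """Message matrices and the exemplar assignment they induce."""

    r: np.ndarray
    a: np.ndarray
    iteration: int
    converged: bool
    exemplars: np.ndarray  # indices of exemplar points
    exemplar_of: np.ndarray  # for each point, index of its exemplar
    points: list[LMerOccurrence] = field(default_factory=list)
    forbidden: np.ndarray | None = None


def run_ap(
    sim: SimilarityMatrix,
    damping: float = 0.9,
    max_iter: int = 1000,
    stable_iters: int = 50,
) -> APState:
    """Run damped synchronous affinity propagation to convergence.

    Terminates when the exemplar decision vector is unchanged for
    ``stable_iters`` consecutive iterations, or at ``max_iter`` (returning
    the current assignment, flagged non-converged).  After the exemplar set
    is fixed, every non-exemplar point is assigned to the admissible
    exemplar of highest similarity; a point whose every exemplar is
    forbidden becomes its own singleton exemplar, preserving the
    cannot-link guarantee.
    """
    if not (0.5 <= damping < 1.0):
        raise ValueError(f"damping must be in [0.5, 1), got {damping}")
    s = sim.s
    m = s.shape[0]
    if m == 0:
        raise ValueError("need at least one point")
    if m == 1:
        return APState(
            r=np.zeros((1, 1)), a=np.zeros((1, 1)), iteration=0, converged=True,
            exemplars=np.array([0]), exemplar_of=np.array([0]),
            points=sim.points, forbidden=sim.forbidden,
        )

    r = np.zeros((m, m))
    a = np.zeros((m, m))
    idx = np.arange(m)
    last_decision = None
    stable = 0
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        # responsibilities: r(i,k) = s(i,k) - max_{k' != k} (a + s)(i,k')
        as_ = a + s
        first = as_.argmax(axis=1)
        max1 = as_[idx, first]
        as_[idx, first] = -np.inf
        max2 = as_.max(axis=1)
        as_[idx, first] = max1
        r_new = s - max1[:, None]
        r_new[idx, first] = s[idx, first] - max2
        r = damping * r + (1.0 - damping) * r_new

        # availabilities
        rp = np.maximum(r, 0.0)
        np.fill_diagonal(rp, r.diagonal())
        col = rp.sum(axis=0)
        a_new = np.minimum(0.0, col[None, :] - rp)
        # a(k,k) = sum_{i' != k} max(0, r(i',k)); col already holds r(k,k) + that sum
        np.fill_diagonal(a_new, col - r.diagonal())
        a = damping * a + (1.0 - damping) * a_new

        decision = (r.diagonal() + a.diagonal()) > 0
        if not decision.any():
            # no exemplar has emerged yet; the messages are still in
            # transient regime, so the stability window must not start
            last_decision = None
            stable = 0
            continue
        if last_decision is not None and np.array_equal(decision, last_decision):
            stable += 1
            if stable >= stable_iters:
                converged = True
                break
        else:
            stable = 0
        last_decision = decision

    exemplars = np.flatnonzero(r.diagonal() + a.diagonal() > 0)
    if exemplars.size == 0:
        # degenerate: fall back to the best r+a diagonal
        exemplars = np.array([int((r.diagonal() + a.diagonal()).argmax())])

    # final assignment: best admissible exemplar by similarity
    exemplar_of = np.empty(m, dtype=int)
    s_to_ex = s[:, exemplars]
    if sim.forbidden is not None:
        s_to_ex = np.where(sim.forbidden[:, exemplars], -np.inf, s_to_ex)
    extra: list[int] = []
    exemplar_set = set(int(e) for e in exemplars)
    for i in range(m):
        if i in exemplar_set:
            exemplar_of[i] = i
            continue
        best = s_to_ex[i]
        j = int(best.argmax())
        if not np.isfinite(best[j]) or best[j] <= sim.sentinel:
            extra.append(i)  # cannot join any exemplar without a violation
            exemplar_of[i] = i
        else:
            exemplar_of[i] = int(exemplars[j])

    # cannot-link repair: the sentinel blocks point-exemplar pairs, but two
    # same-sequence points may still pick the same cross-sequence exemplar;
    # keep the closer one (ties: lowest index), spill the rest to singletons.
    seq_idx = np.array([p.seq_index for p in sim.points])
    for e in list(exemplar_set):
        member_idx = np.flatnonzero(exemplar_of == e)
        by_seq: dict[int, list[int]] = {}
        for i in member_idx:
            by_seq.setdefault(int(seq_idx[i]), []).append(int(i))
        for _, group in by_seq.items():
            if len(group) <= 1:
                continue
            keep = max(group, key=lambda i: (s[i, e], -i))
            for i in group:
                if i != keep:
                    exemplar_of[i] = i
                    extra.append(i)
    if extra:
        exemplars = np.unique(np.concatenate([exemplars, extra]))
    return APState(
        r=r, a=a, iteration=it, converged=converged,
        exemplars=exemplars, exemplar_of=exemplar_of,
        points=sim.points, forbidden=sim.forbidden,
    )


def extract_clusters(state: APState) -> list[ClusterSubset]:
    """One cluster per exemplar; members sorted by (seq_index, offset).

    The partition property holds by construction: every point is assigned
    to exactly one exemplar.  Raises if a cluster would contain two l-mers
    from the same sequence (the cannot-link constraint).
    """
    clusters = []
    for e in state.exemplars:
        member_idx = np.flatnonzero(state.exemplar_of == e)
        points = [state.points[i] for i in member_idx]
        points.sort(key=lambda p: (p.seq_index, p.offset))
        seqs = [p.seq_index for p in points]
        if len(set(seqs)) != len(seqs):
            raise RuntimeError("cannot-link violation: two same-sequence l-mers in a cluster")
        clusters.append(ClusterSubset(reference=state.points[e], members=points))
    return clusters
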