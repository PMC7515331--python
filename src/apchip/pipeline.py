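"""End-to-end motif discovery: thresholds -> subsets -> filter -> AP -> rank.

The per-run radius k is support-aware.  The candidate filter demands that
at least q sequences each contribute a subset member, and a reference that
is a true instance captures another sequence's instance with probability
pk_motif(k); the expected support (t-1) * pk_motif(k) + 1 therefore has to
reach q, i.e. pk_motif(k) >= (q-1)/(t-1).  The pipeline raises the
pk_motif floor to that ratio (so q = t forces k = 2d, where capture is
certain), unless the user overrides k outright.

For each candidate subset, affinity propagation partitions the members and
the cluster containing the reference l-mer is taken as the refined cluster
of that candidate; clusters that pass the ZOOPS size window are summarised
as PWMs and ranked by information content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .ap import build_similarity, extract_clusters, run_ap
from .candidates import (
    ClusterSubset,
    build_cluster_subset,
    enumerate_references,
    filter_candidates,
    occurrence_threshold,
)
from .dataset import SequenceDataset
from .probability import MotifProblem, choose_k, motif_pair_prob
from .refine import (
    MotifModel,
    SizeVerdict,
    greedy_trim,
    information_content,
    rank_and_report,
    validate_size,
)

__all__ = ["AlgorithmConfig", "PipelineDiagnostics", "find_motifs", "pipeline_k"]

log = logging.getLogger("apchip")


@dataclass(frozen=True)
class AlgorithmConfig:
    """Resolved parameter set for one pipeline run.

    Exactly one of ``q`` / ``alpha`` must be given.  ``k`` and
    ``occ_threshold`` override the probabilistic defaults when set.
    """

    l: int
    d: int
    q: int | None = None
    alpha: float | None = None
    k: int | None = None
    p_mut: float | None = None  # defaults to d/l downstream
    occ_threshold: int | None = None
    occf_mode: Literal["neighborhood", "literal"] = "neighborhood"
    pkmotif_floor: float = 0.7
    support_aware_k: bool = True
    R1: float = 2.0
    R2: float = 1.0
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    ap_stable_iters: int = 50
    ap_preference: float | str | None = None  # None/"median", "min", or a number
    cluster_scope: Literal["reference", "all"] = "reference"
    pseudocount: float = 1.0
    uniform_background: bool = False
    both_strands: bool = False
    max_per_sequence: int | None = None
    max_ap_points: int = 4000
    top_n: int = 5
    sim_mode: Literal["lcs", "overlap"] = "lcs"
    polish_rounds: int = 4
    polish_max_dist: int | None = None  # None: d (instances lie within d of the motif)
    min_support: int | None = None  # None: q — a reported motif must solve the (l,d,q) problem

    def problem(self, t: int, n: int) -> MotifProblem:
        if (self.q is None) == (self.alpha is None):
            raise ValueError("give exactly one of q or alpha")
        if self.q is not None:
            return MotifProblem(l=self.l, d=self.d, t=t, n=n, q=self.q)
        return MotifProblem(l=self.l, d=self.d, t=t, n=n, alpha_ratio=self.alpha)


@dataclass
class PipelineDiagnostics:
    """Stage counts recorded during a run."""

    k: int = 0
    occ_threshold_nominal: int = 0
    n_references: int = 0
    n_candidates: int = 0
    n_clusters: int = 0
    n_valid: int = 0
    n_trimmed: int = 0
    max_ic: float = float("nan")
    ap_nonconverged: int = 0


def pipeline_k(config: AlgorithmConfig, problem: MotifProblem) -> int:
    """Radius used by a run: override, or support-aware probabilistic choice."""
    if config.k is not None:
        if not (problem.d < config.k <= 2 * problem.d):
            raise ValueError(
                f"k={config.k} outside (d, 2d] = ({problem.d}, {2 * problem.d}]"
            )
        return config.k
    floor = config.pkmotif_floor
    if config.support_aware_k and problem.t > 1:
        floor = max(floor, (problem.q - 1) / (problem.t - 1))
    floor = min(floor, 1.0)
    if floor >= 1.0:
        return 2 * problem.d
    return choose_k(problem.l, problem.d, floor)


def _majority_consensus(members: list) -> str:
    arr = np.stack([np.frombuffer(p.text.encode(), dtype=np.uint8) for p in members])
    out = []
    for j in range(arr.shape[1]):
        vals, counts = np.unique(arr[:, j], return_counts=True)
        out.append(chr(vals[counts.argmax()]))
    return "".join(out)


def consensus_polish(
    cluster: ClusterSubset,
    subset: ClusterSubset,
    rounds: int,
    max_dist: int,
) -> ClusterSubset:
    """Re-anchor a cluster on its own consensus.

    AP anchors membership on a single exemplar l-mer, so a true instance
    loses its slot whenever a background l-mer happens to sit closer to the
    exemplar.  Re-selecting, per sequence, the subset member closest to the
    column-majority consensus of the current members (and keeping only
    members within ``max_dist`` of it — instances lie within d of the
    motif) removes that single-anchor noise.  Iteration stops when the
    consensus is stable or after ``rounds`` re-anchorings.
    """
    from .candidates import hamming

    pool: dict[int, list] = {}
    for p in subset.members:
        pool.setdefault(p.seq_index, []).append(p)
    members = list(cluster.members)
    cons = _majority_consensus(members)
    for _ in range(rounds):
        members = [
            min(candidates, key=lambda p: (hamming(p.text, cons), p.offset))
            for _, candidates in sorted(pool.items())
        ]
        new_cons = _majority_consensus(members)
        if new_cons == cons:
            break
        cons = new_cons
    # an instance lies within max_dist of the motif; drop members that do not
    members = [p for p in members if hamming(p.text, cons) <= max_dist]
    members.sort(key=lambda p: (p.seq_index, p.offset))
    return ClusterSubset(reference=cluster.reference, members=members or list(cluster.members))


def _background(dataset: SequenceDataset, uniform: bool) -> np.ndarray:
    if uniform:
        return np.full(4, 0.25)
    counts = np.zeros(4)
    for i in range(dataset.t):
        codes = dataset.codes(i)
        for w in range(4):
            counts[w] += int((codes == w).sum())
    if counts.sum() == 0:
        return np.full(4, 0.25)
    counts = np.maximum(counts, 1.0)  # keep strictly positive
    return counts / counts.sum()


def find_motifs(
    dataset: SequenceDataset,
    config: AlgorithmConfig,
    diagnostics: PipelineDiagnostics | None = None,
) -> list[MotifModel]:
    """Run the full discovery pipeline and return the ranked motif models.

    Returns an empty list (with a logged diagnosis) when no candidate
    survives filtering or no cluster passes the size window.
    """
    diag = diagnostics if diagnostics is not None else PipelineDiagnostics()
    t = dataset.t
    n_max = max(dataset.length_of(i) for i in range(t))
    problem = config.problem(t, n_max)
    k = pipeline_k(config, problem)
    diag.k = k
    diag.occ_threshold_nominal = (
        config.occ_threshold
        if config.occ_threshold is not None
        else occurrence_threshold(problem, n_max - config.l + 1, config.p_mut, config.occf_mode)
    )
    log.info(
        "pipeline: l=%d d=%d t=%d q=%d k=%d (pk_motif=%.4f) occ_threshold=%d",
        config.l, config.d, t, problem.q, k,
        motif_pair_prob(config.l, config.d, k), diag.occ_threshold_nominal,
    )

    bg = _background(dataset, config.uniform_background)
    models: list[MotifModel] = []
    for reference in enumerate_references(dataset, config.l, problem.q):
        diag.n_references += 1
        subset = build_cluster_subset(
            reference, dataset, k,
            both_strands=config.both_strands,
            max_per_sequence=config.max_per_sequence,
        )
        if config.occ_threshold is not None:
            ok = filter_candidates(subset, problem, occ_threshold=config.occ_threshold)
        else:
            ok = filter_candidates(subset, problem, dataset=dataset)
        if not ok:
            continue
        diag.n_candidates += 1
        members = subset.members
        if len(members) > config.max_ap_points:
            log.info(
                "subset of %d members at %s capped to %d closest",
                len(members), reference, config.max_ap_points,
            )
            from .dataset import encode

            ref_codes = encode(reference.text)
            codes = np.stack([encode(p.text) for p in members])
            dists = (codes != ref_codes).sum(axis=1)
            order = sorted(range(len(members)), key=lambda i: (dists[i], i))
            members = [members[i] for i in order[: config.max_ap_points]]
            subset = ClusterSubset(reference=reference, members=members)
        sim = build_similarity(
            subset, k, R1=config.R1, R2=config.R2, preference=config.ap_preference
        )
        state = run_ap(
            sim,
            damping=config.ap_damping,
            max_iter=config.ap_max_iter,
            stable_iters=config.ap_stable_iters,
        )
        if not state.converged:
            diag.ap_nonconverged += 1
        clusters = extract_clusters(state)
        if config.cluster_scope == "reference":
            ref_pos = subset.members.index(reference)
            ref_exemplar = state.exemplar_of[ref_pos]
            clusters = [
                c for c, e in zip(clusters, state.exemplars) if e == ref_exemplar
            ]
        diag.n_clusters += len(clusters)
        for cluster in clusters:
            if config.polish_rounds > 0:
                max_dist = (
                    config.polish_max_dist if config.polish_max_dist is not None else config.d
                )
                cluster = consensus_polish(cluster, subset, config.polish_rounds, max_dist)
            verdict = validate_size(cluster, t, problem.q)
            if verdict is SizeVerdict.INVALID:
                continue
            if verdict is SizeVerdict.OVERSIZED:
                cluster = greedy_trim(cluster, cluster.reference, t, config.sim_mode)
                diag.n_trimmed += 1
            min_support = config.min_support if config.min_support is not None else problem.q
            if len(cluster.members) < min_support:
                continue
            diag.n_valid += 1
            models.append(information_content(cluster, bg, config.pseudocount))

    ranked = rank_and_report(models, config.top_n)
    if ranked:
        diag.max_ic = ranked[0].ic
    else:
        log.warning(
            "no motif found: %d references, %d candidates, %d valid clusters; "
            "consider lowering occ_threshold or q",
            diag.n_references, diag.n_candidates, diag.n_valid,
        )
    log.info(
        "stages: references=%d candidates=%d clusters=%d valid=%d trimmed=%d max_ic=%.2f",
        diag.n_references, diag.n_candidates, diag.n_clusters,
        diag.n_valid, diag.n_trimmed, diag.max_ic,
    )
    return ranked
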