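"""Planted-motif dataset simulation and nucleotide-level scoring.

The generator emulates the standard planted (l, d) benchmark protocol:
t i.i.d. uniform-background sequences of length n, a uniform random motif
of length l, and q instances — each obtained by redrawing d designated
positions of the motif uniformly over the four bases, so the realised
mutation count is Binomial(d, 3/4) — planted at uniform random offsets in
q distinct randomly chosen sequences (ZOOPS: at most one instance per
sequence).

Prediction accuracy is the nucleotide-level performance coefficient
nPC = |K ∩ P| / |K ∪ P|, the Jaccard overlap between the base positions
covered by the planted instances (K) and by the predicted occurrences (P).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .dataset import LMerOccurrence, SequenceDataset
from .probability import MotifProblem

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import AlgorithmConfig
    from .refine import MotifModel

__all__ = ["PlantedTruth", "NPCScore", "simulate_dataset", "npc", "run_trials", "TrialResult"]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated dataset."""

    motif: str
    placements: dict[int, tuple[int, str, int]]  # seq_index -> (offset, instance, d_H to motif)
    params: MotifProblem
    seed: int

    def positions(self) -> set[tuple[int, int]]:
        """All (sequence, base position) pairs covered by planted instances."""
        l = len(self.motif)
        return {
            (i, pos)
            for i, (off, _, _) in self.placements.items()
            for pos in range(off, off + l)
        }


def simulate_dataset(
    problem: MotifProblem,
    seed: int,
    mutation_model: str = "designated",
) -> tuple[SequenceDataset, PlantedTruth]:
    """Generate a planted (l, d) dataset; fully reproducible from the seed.

    ``mutation_model="designated"`` redraws exactly d designated positions
    uniformly over the four bases (mutation count Binomial(d, 3/4), the
    distribution the probability calculus assumes).  ``"uniform"`` instead
    draws each instance uniformly from the full Hamming ball of radius d
    around the motif — a sensitivity-analysis alternative.
    """
    l, d, t, n, q = problem.l, problem.d, problem.t, problem.n, problem.q
    rng = np.random.default_rng(seed)
    seqs = rng.integers(0, 4, size=(t, n), dtype=np.uint8)
    motif = rng.integers(0, 4, size=l, dtype=np.uint8)
    chosen = np.sort(rng.choice(t, size=q, replace=False))
    placements: dict[int, tuple[int, str, int]] = {}
    for i in chosen:
        inst = motif.copy()
        if d > 0:
            if mutation_model == "designated":
                pos = rng.choice(l, size=d, replace=False)
                inst[pos] = rng.integers(0, 4, size=d, dtype=np.uint8)
            elif mutation_model == "uniform":
                # rejection-free: pick mutation count by Hamming-ball shell mass
                from math import comb

                shell = np.array([comb(l, i) * 3**i for i in range(d + 1)], dtype=float)
                count = rng.choice(d + 1, p=shell / shell.sum())
                pos = rng.choice(l, size=count, replace=False)
                for p in pos:
                    inst[p] = (inst[p] + rng.integers(1, 4)) % 4
            else:
                raise ValueError(f"unknown mutation model {mutation_model!r}")
        offset = int(rng.integers(0, n - l + 1))
        seqs[i, offset : offset + l] = inst
        dist = int((inst != motif).sum())
        placements[int(i)] = (offset, "".join(_BASES[c] for c in inst), dist)
    strings = ["".join(_BASES[c] for c in row) for row in seqs]
    dataset = SequenceDataset(strings)
    truth = PlantedTruth(
        motif="".join(_BASES[c] for c in motif),
        placements=placements,
        params=problem,
        seed=seed,
    )
    return dataset, truth


@dataclass(frozen=True)
class NPCScore:
    value: float
    true_positions: frozenset[tuple[int, int]]
    predicted_positions: frozenset[tuple[int, int]]


def npc(truth: PlantedTruth, predicted: "MotifModel | list[LMerOccurrence]") -> NPCScore:
    """Jaccard overlap of true vs predicted motif base positions.

    1 on identical coverage, 0 on disjoint coverage (and 0 when both sets
    are empty, by convention).
    """
    occurrences = predicted if isinstance(predicted, list) else predicted.occurrences
    k_set = truth.positions()
    p_set = {(o.seq_index, pos) for o in occurrences for pos in range(o.offset, o.end)}
    union = k_set | p_set
    value = len(k_set & p_set) / len(union) if union else 0.0
    return NPCScore(value, frozenset(k_set), frozenset(p_set))


@dataclass
class TrialResult:
    seed: int
    npc: float
    consensus: str | None
    motif: str
    found: bool


def run_trials(
    problem: MotifProblem,
    n_trials: int = 5,
    master_seed: int = 0,
    config: "AlgorithmConfig | None" = None,
    seeds: list[int] | None = None,
) -> tuple[float, list[TrialResult]]:
    """Run the full pipeline on fresh simulated datasets and average nPC.

    One master seed spawns per-trial child seeds (all recorded for replay);
    a trial whose pipeline returns no motif scores 0.
    """
    from .pipeline import AlgorithmConfig, find_motifs

    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if seeds is None:
        rng = np.random.default_rng(master_seed)
        seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_trials)]
    if config is None:
        config = AlgorithmConfig(l=problem.l, d=problem.d, q=problem.q)
    results: list[TrialResult] = []
    for seed in seeds:
        dataset, truth = simulate_dataset(problem, seed)
        models = find_motifs(dataset, config)
        if models:
            top = models[0]
            score = npc(truth, top).value
            results.append(TrialResult(seed, score, top.consensus, truth.motif, True))
        else:
            results.append(TrialResult(seed, 0.0, None, truth.motif, False))
    mean = float(np.mean([r.npc for r in results]))
    return mean, results
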