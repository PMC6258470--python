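"""Decoy-set evaluation: Enrichment Score, native identification, correlation.

The Enrichment Score of a decoy set measures the overlap between the decile
of best (lowest) scores and the decile of lowest RMSDs:

    ES = |E_top10% ∩ R_top10%| / (0.1 * 0.1 * N_decoys)

ES = 10 for a perfect ranking, 1 in expectation for scores unrelated to
RMSD (hypergeometric), and < 1 for an anti-correlated scoring function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sp_stats

from .errors import EvaluationError


@dataclass(frozen=True)
class DecoyRecord:
    decoy_id: str
    rmsd_to_native: float  # Å
    global_score: float
    is_native: bool = False

    def __post_init__(self) -> None:
        if self.rmsd_to_native < 0:
            raise EvaluationError(f"decoy {self.decoy_id!r}: negative RMSD")


@dataclass
class DecoySet:
    target_id: str
    records: list[DecoyRecord] = field(default_factory=list)

    @property
    def includes_native(self) -> bool:
        return any(r.is_native for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ESResult:
    es: float
    k: int  # top-decile size
    intersection_size: int


def enrichment_score(decoys: DecoySet) -> ESResult:
    """Top-decile overlap between score ranking and RMSD ranking.

    ``k = floor(0.1 N)`` records are taken from each ranking; ties at the
    decile boundary are broken by decoy_id so the result is deterministic.
    """
    n = len(decoys)
    if n < 10:
        raise EvaluationError(f"need at least 10 decoys for ES, got {n}")
    k = int(np.floor(0.1 * n))
    by_score = sorted(decoys.records, key=lambda r: (r.global_score, r.decoy_id))
    by_rmsd = sorted(decoys.records, key=lambda r: (r.rmsd_to_native, r.decoy_id))
    top_e = {r.decoy_id for r in by_score[:k]}
    top_r = {r.decoy_id for r in by_rmsd[:k]}
    intersection = len(top_e & top_r)
    return ESResult(es=100.0 * intersection / n, k=k,  # == |E∩R| / (0.1·0.1·N)
                    intersection_size=intersection)


def count_native_identified(
    decoy_sets: list[DecoySet],
) -> tuple[int, int, list[dict]]:
    """How many targets give their native structure the strictly lowest score.

    A tie between the native and the best decoy counts as *not* identified
    and is flagged in the per-target detail.
    """
    identified = 0
    detail = []
    for dset in decoy_sets:
        natives = [r for r in dset.records if r.is_native]
        if not natives:
            raise EvaluationError(f"decoy set {dset.target_id!r} has no native record")
        native = natives[0]
        others = [r.global_score for r in dset.records if not r.is_native]
        best_other = min(others) if others else float("inf")
        is_identified = native.global_score < best_other
        tie = native.global_score == best_other
        if is_identified:
            identified += 1
        detail.append({
            "target_id": dset.target_id,
            "native_score": native.global_score,
            "best_decoy_score": best_other,
            "identified": is_identified,
            "tie": tie,
        })
    return identified, len(decoy_sets), detail


def label_prediction_correlation(pairs) -> float:
    """Pearson correlation between actual and predicted unfitness scores."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise EvaluationError("need at least 3 (actual, predicted) pairs")
    actual, predicted = arr[:, 0], arr[:, 1]
    if np.ptp(actual) == 0 or np.ptp(predicted) == 0:
        raise EvaluationError("zero variance in actual or predicted scores")
    return float(_sp_stats.pearsonr(actual, predicted).statistic)
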