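"""Scoring a screen run against simulator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

from .classify import ScaffoldCall
from .containers import TruthSet
from .scan import LgtCandidate


@dataclass
class RecoveryStats:
    """Implant recovery: a truth implant counts as recovered when any
    candidate on its scaffold overlaps it by at least one bp; a candidate
    with no truth overlap is spurious."""

    n_implants: int
    n_recovered: int
    n_candidates: int
    n_spurious: int

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_implants if self.n_implants else 1.0


def score_candidates(candidates: list[LgtCandidate],
                     truth: TruthSet) -> RecoveryStats:
    recovered = 0
    for t in truth.implants:
        if any(c.scaffold == t.scaffold and c.start < t.end and t.start < c.end
               for c in candidates):
            recovered += 1
    spurious = 0
    for c in candidates:
        if not any(t.scaffold == c.scaffold and c.start < t.end
                   and t.start < c.end for t in truth.implants):
            spurious += 1
    return RecoveryStats(n_implants=len(truth.implants),
                         n_recovered=recovered,
                         n_candidates=len(candidates), n_spurious=spurious)


@dataclass
class ContaminantStats:
    recall: float      # contaminants called bacterial / contaminants
    precision: float   # contaminants among bacterial calls / bacterial calls
    n_true: int
    n_called: int


def score_contaminants(calls: list[ScaffoldCall],
                       truth: TruthSet) -> ContaminantStats:
    true_set = {c.scaffold for c in truth.contaminants}
    called = {c.scaffold for c in calls if c.call == "bacterial"}
    tp = len(true_set & called)
    recall = tp / len(true_set) if true_set else 1.0
    precision = tp / len(called) if called else 1.0
    return ContaminantStats(recall=recall, precision=precision,
                            n_true=len(true_set), n_called=len(called))
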