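"""Percent-spliced-in (PSI), testability filters and differential calls.

PSI for a cassette-class event is

    PSI = 100 * (1/2)(C1A + AC2) / [ (1/2)(C1A + AC2) + C1C2 ]

where C1A and AC2 are reads across the two junctions adjacent to the
alternative exon and C1C2 reads across the skipping junction.  The half
weight reflects that each inclusion molecule is sampled at two junctions
while each skipping molecule is sampled at one.  Alternative-site events
use the same form with sums over all detected donor/acceptor combinations;
mutually exclusive events halve both sides (each form has two junctions).

Differential calls between a wild-type and a mutant sample use a 2-sided
Fisher exact test on the unhalved inclusion/exclusion read sums, requiring
p < 0.05 and |dPSI| >= 15 percentage points by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .event_catalog import ASEvent
from .formats_io import JunctionCountTable

HALVED_EXCLUSION_TYPES = {"mutually_exclusive"}
ADJACENT_BALANCE_TYPES = {"cassette", "mutually_exclusive"}


@dataclass
class PsiRecord:
    event_id: str
    sample_id: str
    psi: Optional[float]          # percent, None when no support
    inclusion_support: int        # unhalved summed inclusion reads
    exclusion_support: int


@dataclass
class DifferentialCall:
    event_id: str
    psi_wt: Optional[float]
    psi_mut: Optional[float]
    delta_psi: Optional[float]
    p_value: Optional[float]
    called: bool
    direction: Optional[str]      # increased_inclusion / increased_skipping
    testable: bool
    exclusion_reason: Optional[str] = None


def _support(event: ASEvent, counts: JunctionCountTable) -> Tuple[int, int]:
    inc = sum(counts.get(k) for _, k in event.inclusion_junctions)
    exc = sum(counts.get(k) for _, k in event.exclusion_junctions)
    return inc, exc


def compute_psi(event: ASEvent, counts: JunctionCountTable) -> PsiRecord:
    """PSI of one event in one sample; missing junctions count zero."""
    inc, exc = _support(event, counts)
    if inc == 0 and exc == 0:
        return PsiRecord(event.event_id, counts.sample_id, None, 0, 0)
    inc_w = inc / 2.0
    exc_w = exc / 2.0 if event.type in HALVED_EXCLUSION_TYPES else float(exc)
    psi = 100.0 * inc_w / (inc_w + exc_w)
    return PsiRecord(event.event_id, counts.sample_id, psi, inc, exc)


def filter_testable(event: ASEvent,
                    wt_counts: JunctionCountTable,
                    mut_counts: JunctionCountTable,
                    min_reads: int = 10,
                    max_adjacent_ratio: float = 30.0,
                    ) -> Tuple[bool, Optional[str]]:
    """Apply the read-support and adjacent-junction-balance filters.

    An event is testable when both samples have >= ``min_reads`` combined
    reads over the two splice forms and, for cassette and mutually
    exclusive events, the two adjacent inclusion junctions differ by no
    more than ``max_adjacent_ratio``-fold in either sample (a strictly
    greater ratio fails; one junction at zero with the other nonzero
    counts as infinite imbalance).
    """
    for counts in (wt_counts, mut_counts):
        inc, exc = _support(event, counts)
        if inc + exc < min_reads:
            return False, "min_reads"
    if event.type in ADJACENT_BALANCE_TYPES:
        adj = [k for r, k in event.inclusion_junctions]
        for counts in (wt_counts, mut_counts):
            a, b = (counts.get(adj[0]), counts.get(adj[1]))
            lo, hi = min(a, b), max(a, b)
            if hi == 0:
                continue  # no inclusion reads at all: balance undefined
            if lo == 0 or hi / lo > max_adjacent_ratio:
                return False, "adjacent_imbalance"
    return True, None


def call_differential(event: ASEvent,
                      wt_counts: JunctionCountTable,
                      mut_counts: JunctionCountTable,
                      alpha: float = 0.05,
                      min_delta: float = 15.0,
                      check_testable: bool = True,
                      ) -> DifferentialCall:
    """Fisher-test one event between wild-type and mutant samples."""
    if check_testable:
        ok, reason = filter_testable(event, wt_counts, mut_counts)
        if not ok:
            raise ValueError(
                f"event {event.event_id} is not testable ({reason}); "
                "run filter_testable first")
    rec_wt = compute_psi(event, wt_counts)
    rec_mut = compute_psi(event, mut_counts)
    table = [
        [rec_wt.inclusion_support, rec_wt.exclusion_support],
        [rec_mut.inclusion_support, rec_mut.exclusion_support],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    delta = None
    direction = None
    called = False
    if rec_wt.psi is not None and rec_mut.psi is not None:
        delta = rec_mut.psi - rec_wt.psi
        direction = ("increased_inclusion" if delta > 0
                     else "increased_skipping" if delta < 0 else None)
        called = bool(p < alpha and abs(delta) >= min_delta)
    return DifferentialCall(
        event.event_id, rec_wt.psi, rec_mut.psi, delta, float(p),
        called, direction if called or delta else direction, True)


def call_all(events: Sequence[ASEvent],
             wt_counts: JunctionCountTable,
             mut_counts: JunctionCountTable,
             alpha: float = 0.05,
             min_delta: float = 15.0,
             fdr: bool = False,
             ) -> List[DifferentialCall]:
    """Filter and test every event; untestable events carry their reason.

    ``fdr=True`` additionally applies Benjamini-Hochberg across testable
    events and requires the adjusted p to clear ``alpha``.
    """
    calls: List[DifferentialCall] = []
    for ev in events:
        ok, reason = filter_testable(ev, wt_counts, mut_counts)
        if not ok:
            rw, rm = compute_psi(ev, wt_counts), compute_psi(ev, mut_counts)
            delta = (rm.psi - rw.psi
                     if rw.psi is not None and rm.psi is not None else None)
            calls.append(DifferentialCall(
                ev.event_id, rw.psi, rm.psi, delta, None, False, None,
                False, reason))
        else:
            calls.append(call_differential(
                ev, wt_counts, mut_counts, alpha, min_delta,
                check_testable=False))
    if fdr:
        tested = [c for c in calls if c.testable and c.p_value is not None]
        if tested:
            padj = stats.false_discovery_control(
                [c.p_value for c in tested], method="bh")
            for c, q in zip(tested, padj):
                c.called = bool(c.called and q < alpha)
    return calls


def overlap_enrichment(calls_a: set, calls_b: set, background: set
                       ) -> Tuple[float, float]:
    """Fold and one-tailed hypergeometric p for overlap of two call sets
    drawn from a common background of testable events."""
    if not background:
        raise ValueError("empty background set")
    if not (calls_a <= background and calls_b <= background):
        raise ValueError("call sets must be subsets of the background")
    n = len(background)
    obs = len(calls_a & calls_b)
    expected = len(calls_a) * len(calls_b) / n
    fold = obs / expected if expected > 0 else float("nan")
    p = float(stats.hypergeom.sf(obs - 1, n, len(calls_a), len(calls_b)))
    return fold, p


def psi_correlation(records_a: Sequence[PsiRecord],
                    records_b: Sequence[PsiRecord]) -> float:
    """Pearson correlation of PSI over events with defined PSI in both."""
    pa = {r.event_id: r.psi for r in records_a if r.psi is not None}
    pb = {r.event_id: r.psi for r in records_b if r.psi is not None}
    shared = sorted(set(pa) & set(pb))
    if len(shared) < 3:
        raise ValueError(
            f"need >=3 shared events with defined PSI, got {len(shared)}")
    x = np.array([pa[e] for e in shared])
    y = np.array([pb[e] for e in shared])
    return float(stats.pearsonr(x, y).statistic)


def calls_to_table(events: Sequence[ASEvent],
                   calls: Sequence[DifferentialCall]) -> pd.DataFrame:
    etype = {e.event_id: e.type for e in events}
    rows = []
    for c in calls:
        rows.append({
            "event_id": c.event_id,
            "type": etype.get(c.event_id, "."),
            "psi_wt": c.psi_wt,
            "psi_mut": c.psi_mut,
            "delta_psi": c.delta_psi,
            "p_value": c.p_value,
            "called": c.called,
            "direction": c.direction,
            "testable": c.testable,
            "exclusion_reason": c.exclusion_reason,
        })
    return pd.DataFrame(rows)
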