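"""Motif enrichment, positional bias, co-occurrence, and composition /
functional-term controls.

Enrichment of a binding motif among differentially spliced events is
measured against PSI-matched control sets drawn from the alternatively
spliced background (wild-type PSI binned in 5-point bins, 100 random sets
by default).  Co-occurrence of two motifs over one event set uses a
multiplicative expectation N*(n_a/N)*(n_b/N) and a cumulative
hypergeometric p-value for the observed overlap.  A dinucleotide
Mann-Whitney comparison and an intron-length-matched functional-term
enrichment serve as composition controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .motif_conservation import INTRON_LABELS, MotifHit, SpliceRegion

PSI_BIN_WIDTH = 5.0

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass
class EnrichmentResult:
    motif: str
    n_cases: int
    cases_with_motif: int
    case_proportion: float
    control_proportion: float   # mean over control sets
    p_value: float
    conserved_only: bool
    region_policy: str          # "introns" or "introns+alt_exon"
    direction: str              # all / increased_inclusion / increased_skipping
    n_randomizations: int


@dataclass
class CooccurrenceResult:
    motif_a: str
    motif_b: str
    n_events: int
    n_a: int
    n_b: int
    observed: int
    expected: float
    p_value: float

    def __post_init__(self) -> None:
        if self.observed > min(self.n_a, self.n_b):
            raise ValueError("observed overlap exceeds a margin")


def psi_bin(psi: float, width: float = PSI_BIN_WIDTH) -> int:
    return int(min(psi, 100.0 - 1e-9) // width)


def sample_matched_controls(case_psi: Mapping[str, float],
                            background_psi: Mapping[str, float],
                            n: int = 100,
                            seed: int = 0,
                            rng: Optional[np.random.Generator] = None,
                            ) -> List[List[str]]:
    """Draw ``n`` control event sets matching the cases' PSI histogram.

    PSI is binned in 5-percentage-point bins; each control set draws,
    without replacement within the set, the same per-bin counts from the
    background (events not in the case set).  When a bin is empty in the
    background the nearest non-empty bin substitutes.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    bg = {e: p for e, p in background_psi.items() if e not in case_psi}
    if len(bg) < len(case_psi):
        raise ValueError(
            f"background ({len(bg)}) smaller than case set ({len(case_psi)})")
    bins_bg: Dict[int, List[str]] = {}
    for e, p in sorted(bg.items()):
        bins_bg.setdefault(psi_bin(p), []).append(e)
    need: Dict[int, int] = {}
    for e, p in case_psi.items():
        b = psi_bin(p)
        need[b] = need.get(b, 0) + 1
    sets: List[List[str]] = []
    for _ in range(n):
        chosen: List[str] = []
        taken: Set[str] = set()
        for b, k in sorted(need.items()):
            pool = [e for e in bins_bg.get(b, []) if e not in taken]
            if len(pool) < k:
                # nearest non-empty bins top up the shortfall
                for dist in range(1, 22):
                    for bb in (b - dist, b + dist):
                        extra = [e for e in bins_bg.get(bb, [])
                                 if e not in taken and e not in pool]
                        pool.extend(extra)
                        if len(pool) >= k:
                            break
                    if len(pool) >= k:
                        break
            if len(pool) < k:
                raise ValueError(f"cannot fill PSI bin {b}: background "
                                 "exhausted")
            pick = rng.choice(len(pool), size=k, replace=False)
            for i in pick:
                chosen.append(pool[i])
                taken.add(pool[i])
        sets.append(chosen)
    return sets


def events_with_motif(hits: Iterable[MotifHit], motif: str,
                      region_policy: str = "introns",
                      conserved_only: bool = True) -> Set[str]:
    """Events having >=1 qualifying occurrence of a motif.

    ``region_policy`` is "introns" (flanking introns only) or
    "introns+alt_exon" (additionally the alternative exon, as used for
    MEC-8 sites).
    """
    labels = set(INTRON_LABELS)
    if region_policy == "introns+alt_exon":
        labels.add("alt_exon")
    elif region_policy != "introns":
        raise ValueError(f"unknown region policy {region_policy!r}")
    out = set()
    for h in hits:
        if h.motif != motif or h.region_label not in labels:
            continue
        if conserved_only and not h.conserved:
            continue
        out.add(h.event_id)
    return out


def motif_enrichment(case_events: Sequence[str],
                     case_psi: Mapping[str, float],
                     background_psi: Mapping[str, float],
                     hits: Sequence[MotifHit],
                     motif: str,
                     region_policy: str = "introns",
                     conserved_only: bool = True,
                     direction: str = "all",
                     direction_of: Optional[Mapping[str, str]] = None,
                     n: int = 100,
                     seed: int = 0,
                     control_mode: str = "averaged",
                     ) -> EnrichmentResult:
    """Test enrichment of a motif among differentially spliced events.

    The case proportion is compared against PSI-matched control sets with
    a one-sided Fisher exact test (enrichment direction).  In "averaged"
    mode (default) the control cell counts are the rounded means over the
    ``n`` control sets; "pooled" mode sums all sets.
    """
    cases = list(case_events)
    if direction != "all":
        if direction_of is None:
            raise ValueError("direction split requires direction_of map")
        cases = [e for e in cases if direction_of.get(e) == direction]
    if not cases:
        raise ValueError("empty case set")
    flagged = events_with_motif(hits, motif, region_policy, conserved_only)
    case_with = sum(1 for e in cases if e in flagged)
    control_sets = sample_matched_controls(
        {e: case_psi[e] for e in cases}, background_psi, n=n, seed=seed)
    ctrl_props = [np.mean([e in flagged for e in cs]) for cs in control_sets]
    k = len(cases)
    if control_mode == "averaged":
        ctrl_with = int(round(float(np.mean(
            [sum(e in flagged for e in cs) for cs in control_sets]))))
        table = [[case_with, k - case_with], [ctrl_with, k - ctrl_with]]
    elif control_mode == "pooled":
        ctrl_with = sum(sum(e in flagged for e in cs) for cs in control_sets)
        table = [[case_with, k - case_with],
                 [ctrl_with, n * k - ctrl_with]]
    else:
        raise ValueError(f"unknown control mode {control_mode!r}")
    _, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(
        motif, k, case_with, case_with / k, float(np.mean(ctrl_props)),
        float(p), conserved_only, region_policy, direction, n)


def positional_bias(hits: Sequence[MotifHit], motif: str
                    ) -> Dict[str, float]:
    """Among events with >=1 conserved hit of the motif anywhere, the
    proportion with a conserved hit per region class."""
    classes = {
        "alt_exon": {"alt_exon"},
        "flanking_introns": set(INTRON_LABELS),
        "constitutive_exons": {"constitutive_up", "constitutive_down"},
    }
    conserved = [h for h in hits if h.motif == motif and h.conserved]
    events = {h.event_id for h in conserved}
    if not events:
        return {}
    out = {}
    for cls, labels in classes.items():
        with_cls = {h.event_id for h in conserved if h.region_label in labels}
        out[cls] = len(with_cls) / len(events)
    return out


def cooccurrence(event_ids: Sequence[str],
                 hits: Sequence[MotifHit],
                 motif_a: str, motif_b: str,
                 conserved_only: bool = True) -> CooccurrenceResult:
    """Co-occurrence of two motifs in flanking introns over an event set.

    expected = N*(n_a/N)*(n_b/N); p = P(X >= observed) for
    X ~ Hypergeom(N, n_a, n_b).  Presence/absence: multiple instances in
    one event count once.
    """
    ids = set(event_ids)
    if not ids:
        raise ValueError("empty event set")
    set_a = events_with_motif(hits, motif_a, "introns", conserved_only) & ids
    set_b = events_with_motif(hits, motif_b, "introns", conserved_only) & ids
    return cooccurrence_from_sets(len(ids), set_a, set_b, motif_a, motif_b)


def cooccurrence_from_sets(n_events: int, set_a: Set[str], set_b: Set[str],
                           motif_a: str = "a", motif_b: str = "b"
                           ) -> CooccurrenceResult:
    if n_events == 0:
        raise ValueError("empty event set")
    n_a, n_b = len(set_a), len(set_b)
    obs = len(set_a & set_b)
    expected = n_events * (n_a / n_events) * (n_b / n_events)
    p = float(stats.hypergeom.sf(obs - 1, n_events, n_a, n_b))
    return CooccurrenceResult(motif_a, motif_b, n_events, n_a, n_b, obs,
                              expected, p)


def dinucleotide_frequencies(seq: str) -> Optional[Dict[str, float]]:
    """Overlapping dinucleotide frequencies (denominator len-1)."""
    if len(seq) < 2:
        return None
    total = len(seq) - 1
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(total):
        d = seq[i:i + 2]
        if d in counts:
            counts[d] += 1
    return {d: c / total for d, c in counts.items()}


def dinucleotide_comparison(regions_a: Sequence[SpliceRegion],
                            regions_b: Sequence[SpliceRegion]
                            ) -> pd.DataFrame:
    """Per-dinucleotide Mann-Whitney comparison of two region sets.

    Returns a 16-row table with mean frequencies, fold difference of
    means, and the two-sided U-test p-value.
    """
    if not regions_a or not regions_b:
        raise ValueError("both region sets must be non-empty")
    fa = [f for r in regions_a
          if (f := dinucleotide_frequencies(r.sequence)) is not None]
    fb = [f for r in regions_b
          if (f := dinucleotide_frequencies(r.sequence)) is not None]
    rows = []
    for d in DINUCLEOTIDES:
        xa = np.array([f[d] for f in fa])
        xb = np.array([f[d] for f in fb])
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            u, p = len(xa) * len(xb) / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        ma, mb = float(xa.mean()), float(xb.mean())
        fold = ma / mb if mb > 0 else np.inf if ma > 0 else 1.0
        rows.append({"dinucleotide": d.replace("T", "U"), "mean_a": ma,
                     "mean_b": mb, "fold": fold, "u_statistic": float(u),
                     "p_value": float(p)})
    return pd.DataFrame(rows)


def _length_bins(lengths: Mapping[str, float], n_bins: int = 10
                 ) -> Dict[str, int]:
    vals = np.array(sorted(lengths.values()))
    qs = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
    qs[-1] = np.inf
    return {g: int(np.searchsorted(qs, l, side="right") - 1)
            for g, l in lengths.items()}


def term_enrichment_length_matched(term_map: Mapping[str, Set[str]],
                                   flagged: Set[str],
                                   intron_lengths: Mapping[str, float],
                                   n: int = 1000,
                                   seed: int = 0,
                                   min_term_genes: int = 3,
                                   n_bins: int = 10) -> pd.DataFrame:
    """Per-term proportion of genes with co-occurring motifs versus
    intron-length-matched random gene sets.

    ``term_map`` maps gene -> set of terms; ``flagged`` is the set of
    genes carrying co-occurring motifs; controls are drawn from non-term
    genes matched on total intron length (quantile bins).  Also reports a
    plain hypergeometric enrichment p over the gene universe.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(intron_lengths)
    bins = _length_bins(intron_lengths, n_bins)
    terms: Dict[str, Set[str]] = {}
    for g, ts in term_map.items():
        if g not in intron_lengths:
            continue
        for t in ts:
            terms.setdefault(t, set()).add(g)
    rows = []
    flagged_in_universe = flagged & set(universe)
    for term in sorted(terms):
        genes = sorted(terms[term])
        if len(genes) < min_term_genes:
            rows.append({"term": term, "n_genes": len(genes),
                         "proportion": np.nan, "control_proportion": np.nan,
                         "hypergeom_p": np.nan, "note": "too_few_genes"})
            continue
        prop = np.mean([g in flagged for g in genes])
        pool = [g for g in universe if term not in term_map.get(g, ())]
        pool_by_bin: Dict[int, List[str]] = {}
        for g in pool:
            pool_by_bin.setdefault(bins[g], []).append(g)
        need: Dict[int, int] = {}
        for g in genes:
            need[bins[g]] = need.get(bins[g], 0) + 1
        ctrl_props = []
        for _ in range(n):
            chosen = []
            for b, k in sorted(need.items()):
                cand = pool_by_bin.get(b, [])
                for dist in range(1, n_bins + 1):
                    if len(cand) >= k:
                        break
                    cand = cand + pool_by_bin.get(b - dist, []) \
                        + pool_by_bin.get(b + dist, [])
                idx = rng.choice(len(cand), size=min(k, len(cand)),
                                 replace=False)
                chosen.extend(cand[i] for i in idx)
            ctrl_props.append(np.mean([g in flagged for g in chosen]))
        k_term_flagged = sum(1 for g in genes if g in flagged_in_universe)
        hg_p = float(stats.hypergeom.sf(
            k_term_flagged - 1, len(universe), len(flagged_in_universe),
            len(genes)))
        rows.append({"term": term, "n_genes": len(genes),
                     "proportion": float(prop),
                     "control_proportion": float(np.mean(ctrl_props)),
                     "hypergeom_p": hg_p, "note": None})
    return pd.DataFrame(rows)


def developmental_overlap(genes_with_cooccurrence: Set[str],
                          developmental_genes: Set[str],
                          universe: Set[str]) -> Tuple[int, float]:
    """One-sided hypergeometric overlap with an external gene set."""
    a = genes_with_cooccurrence & universe
    b = developmental_genes & universe
    obs = len(a & b)
    p = float(stats.hypergeom.sf(obs - 1, len(universe), len(a), len(b)))
    return obs, p
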