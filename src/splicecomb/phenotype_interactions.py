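"""Fitness-based genetic-interaction scoring from RNAi plate tables.

Worm populations grown in multiwell plates are counted per (strain, RNAi,
technical replicate) in each independent experiment.  Relative fitness of
an RNAi condition within a strain is the population mean normalised to the
non-targeting control (GFP) condition of the same strain.  The expected
fitness of a mutant strain under an RNAi knockdown follows a
multiplicative model (relative fitness of the RNAi in wild type x relative
fitness of the untreated mutant); the interaction score is the observed
fitness relative to this expectation, so 1 means no interaction and 0 a
maximal aggravating interaction.  Pairs with a mean score below 0.7 across
experiments are screen hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

CONTROL_RNAI = "GFP"
REFERENCE_STRAIN = "WT"

PLATE_COLUMNS = ["strain", "rnai", "experiment", "replicate", "population"]


@dataclass
class FitnessPlate:
    """Well table of one or more experiments (long format)."""

    wells: pd.DataFrame
    control_rnai: str = CONTROL_RNAI
    reference_strain: str = REFERENCE_STRAIN

    def __post_init__(self) -> None:
        missing = set(PLATE_COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate table missing column(s) "
                             f"{sorted(missing)}")
        if (self.wells["population"] < 0).any():
            raise ValueError("negative population count")
        for strain, grp in self.wells.groupby("strain"):
            if not (grp["rnai"] == self.control_rnai).any():
                raise ValueError(
                    f"strain {strain} has no {self.control_rnai} control "
                    "wells")

    @classmethod
    def read(cls, path: str, **kw) -> "FitnessPlate":
        return cls(pd.read_csv(path, sep="\t", comment="#"), **kw)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            self.wells.to_csv(fh, sep="\t", index=False)

    def mean_population(self, strain: str, rnai: str,
                        experiment: Optional[object] = None
                        ) -> Optional[float]:
        """Mean population over technical replicates."""
        df = self.wells
        m = (df["strain"] == strain) & (df["rnai"] == rnai)
        if experiment is not None:
            m &= df["experiment"] == experiment
        sub = df.loc[m, "population"]
        return float(sub.mean()) if len(sub) else None

    def experiments(self) -> List[object]:
        return sorted(self.wells["experiment"].unique())


@dataclass
class InteractionResult:
    mutant: str
    rnai: str
    score: float                  # mean across experiments; >= 0
    log_ratio: float              # ln(score)
    p_value: Optional[float]
    n_experiments: int
    per_experiment: List[float] = field(default_factory=list)


def relative_fitness(plate: FitnessPlate,
                     experiment: Optional[object] = None
                     ) -> Dict[Tuple[str, str], float]:
    """Within-strain relative fitness w(strain, rnai) = mean population of
    the RNAi condition / mean population of the control RNAi."""
    out: Dict[Tuple[str, str], float] = {}
    df = plate.wells
    if experiment is not None:
        df = df[df["experiment"] == experiment]
    for (strain, rnai), grp in df.groupby(["strain", "rnai"]):
        ctrl = plate.mean_population(strain, plate.control_rnai, experiment)
        if not ctrl:
            raise ValueError(
                f"strain {strain}: zero or missing control mean")
        out[(strain, rnai)] = float(grp["population"].mean()) / ctrl
    return out


def _experiment_score(plate: FitnessPlate, mutant: str, rnai: str,
                      experiment: object) -> Optional[float]:
    """actual/expected for one experiment; None if a condition is absent.

    expected = w(WT, rnai) * m where m = mean(mut, ctrl)/mean(WT, ctrl);
    actual = mean(mut, rnai)/mean(WT, ctrl); the WT-control denominator
    cancels so the score equals w(mut, rnai)/w(WT, rnai).
    """
    wt, ctrl = plate.reference_strain, plate.control_rnai
    vals = {
        (s, r): plate.mean_population(s, r, experiment)
        for s in (wt, mutant) for r in (ctrl, rnai)
    }
    if any(v is None or v == 0 for v in vals.values()):
        return None
    w_wt = vals[(wt, rnai)] / vals[(wt, ctrl)]
    w_mut = vals[(mutant, rnai)] / vals[(mutant, ctrl)]
    return w_mut / w_wt


def interaction_score(plate: FitnessPlate, mutant: str, rnai: str
                      ) -> InteractionResult:
    """Interaction score across experiments with a t-test significance.

    The two-sided Welch t-test compares per-experiment log scores of the
    target RNAi against those of the control RNAi (which are identically
    zero by construction, making this equivalent to a one-sample test of
    the log score against 0).
    """
    scores, ctrl_scores = [], []
    for exp in plate.experiments():
        s = _experiment_score(plate, mutant, rnai, exp)
        if s is None:
            continue
        scores.append(s)
        c = _experiment_score(plate, mutant, plate.control_rnai, exp)
        ctrl_scores.append(c if c is not None else 1.0)
    if not scores:
        raise ValueError(
            f"no usable experiments for ({mutant}, {rnai})")
    mean_score = float(np.mean(scores))
    p = None
    if len(scores) >= 2:
        logs = np.log(scores)
        ctrl_logs = np.log(ctrl_scores)
        if np.allclose(logs.var(), 0) and np.allclose(ctrl_logs.var(), 0):
            p = 1.0 if np.allclose(logs.mean(), ctrl_logs.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(logs, ctrl_logs,
                                      equal_var=False).pvalue)
    return InteractionResult(mutant, rnai, mean_score,
                             math.log(mean_score) if mean_score > 0
                             else -math.inf,
                             p, len(scores), scores)


def screen_summary(results: Sequence[InteractionResult],
                   threshold: float = 0.7,
                   strain_classes: Optional[Mapping[str, str]] = None,
                   ) -> pd.DataFrame:
    """Per-pair mean scores and hit calls (mean score strictly < threshold).

    ``strain_classes`` maps strain -> class label so sister alleles of one
    gene (e.g. two different mutants of the same factor) average into a
    single pair score.
    """
    rows = []
    keyed: Dict[Tuple[str, str], List[InteractionResult]] = {}
    for r in results:
        cls = (strain_classes or {}).get(r.mutant, r.mutant)
        keyed.setdefault((cls, r.rnai), []).append(r)
    for (mutant_cls, rnai), rs in sorted(keyed.items()):
        score = float(np.mean([r.score for r in rs]))
        pvals = [r.p_value for r in rs if r.p_value is not None]
        rows.append({
            "mutant": mutant_cls,
            "rnai": rnai,
            "score": score,
            "hit": score < threshold,
            "min_p": min(pvals) if pvals else np.nan,
            "n_strains": len(rs),
            "n_experiments": sum(r.n_experiments for r in rs),
        })
    df = pd.DataFrame(rows).sort_values("score").reset_index(drop=True)
    return df


def size_summaries(wells: pd.DataFrame) -> pd.DataFrame:
    """Pass-through per-condition means of worm-size metrics (TOF/EXT)."""
    metrics = [c for c in ("tof", "ext") if c in wells.columns]
    if not metrics:
        return pd.DataFrame()
    return (wells.groupby(["strain", "rnai"])[metrics].mean()
            .reset_index())
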