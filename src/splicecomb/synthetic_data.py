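"""Synthetic study generator with a complete truth table.

Generates, from one seed, everything the pipeline consumes: a genome with
gene models (a fraction of genes carrying a cassette exon), per-sample
junction count tables with binomial sampling around true PSI values,
multi-species alignment blocks with motifs planted at controlled
conservation, spacing and ordering, and fitness plates with controlled
epistasis.  Every planted signal is recorded in a truth table so each
downstream stage can be checked against ground truth.

Junction sampling model: each junction is an independent read-out of the
isoform mixture at sequencing depth D, so for true inclusion level p the
two adjacent junctions draw C1A, AC2 ~ Binomial(D, p) and the skipping
junction C1C2 ~ Binomial(D, 1-p).  Under this model the half-weighted PSI
estimator is consistent (each inclusion molecule is seen at two junctions,
each skipping molecule at one).

Species divergence uses per-base substitutions and species-side deletions
only (no insertions relative to the reference), which keeps the reference
row of every alignment block gap-free and the planted coordinates exact.
Planted motif neighbourhoods are scrubbed of chance matches — in the
reference before planting and in each non-carrier species afterwards — so
the planted conservation level, spacing and order are recovered exactly
by construction, not merely in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import formats_io
from .event_catalog import ASEvent, build_catalog
from .formats_io import (ELEGANS_GROUP, AlignmentBlock, AlignmentSet, Gene,
                         GeneModelSet, JunctionCountTable, JunctionKey,
                         Transcript, reverse_complement)
from .motif_conservation import (MotifPattern, event_regions, find_matches,
                                 parse_motif)
from .phenotype_interactions import FitnessPlate

BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class MotifPlant:
    """One motif planted in a fixed region of selected events."""

    name: str
    pattern: str
    region: str = "downstream_intron_5p"
    conservation_species: int = 3   # other species carrying the motif
    jitter: int = 5                 # max |column shift| in carriers, <= 25


@dataclass
class MotifPairPlant:
    """A pair of motifs planted with controlled spacing and order."""

    first: MotifPlant
    second: MotifPlant
    spacing: int = 30               # nt between end of first, start of second
    order: str = "ab"               # "ab": first upstream (sense)
    spacing_conserved: bool = True  # carriers keep spacing within 20%


@dataclass
class FitnessConfig:
    baseline: float = 300.0
    strain_effects: Dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "mutA": 0.8})
    rnai_effects: Dict[str, float] = field(
        default_factory=lambda: {"GFP": 1.0, "sf2": 0.7})
    epistasis: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: {("mutA", "sf2"): 0.5})
    noise_sd: float = 0.1
    replicates: int = 8
    experiments: int = 4


@dataclass
class SimConfig:
    """Study conditions for one synthetic run."""

    n_genes: int = 60
    exons_per_gene: Tuple[int, int] = (4, 7)
    exon_length: Tuple[int, int] = (100, 220)
    intron_log_mean: float = math.log(500.0)
    intron_log_sd: float = 0.35
    intron_min: int = 320
    intergenic: int = 200
    cassette_fraction: float = 0.5
    wt_sample: str = "N2"
    mutant_samples: Tuple[str, ...] = ("sf1",)
    differential_fraction: float = 0.5
    delta_psi: float = 40.0
    depth: int = 100
    n_species: int = 5
    species: Tuple[str, ...] = ELEGANS_GROUP
    substitution_rate: float = 0.10
    deletion_rate: float = 0.02
    deletion_mean_len: float = 2.0
    pair_plants: Tuple[MotifPairPlant, ...] = (
        MotifPairPlant(MotifPlant("FOX1", "GCAUG"),
                       MotifPlant("MEC8", "GCACA")),
    )
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for p, label in ((self.cassette_fraction, "cassette_fraction"),
                         (self.differential_fraction,
                          "differential_fraction"),
                         (self.substitution_rate, "substitution_rate"),
                         (self.deletion_rate, "deletion_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {p}")
        if not 0.0 <= self.delta_psi <= 100.0:
            raise ValueError("delta_psi must be in [0, 100]")
        for pp in self.pair_plants:
            for mp in (pp.first, pp.second):
                if mp.conservation_species > self.n_species - 1:
                    raise ValueError(
                        f"plant {mp.name}: conservation_species "
                        f"{mp.conservation_species} exceeds n_species-1")
                if mp.jitter > 25:
                    raise ValueError(f"plant {mp.name}: jitter > 25")


@dataclass
class TruthTable:
    """Ground truth for every planted signal of one study."""

    psi: pd.DataFrame       # event_id, sample_id, true_psi, differential, delta
    motifs: pd.DataFrame    # event_id, motif, region, genomic_start, ...
    pairs: pd.DataFrame     # event_id, motifs, region, spacing, order, ...
    fitness: pd.DataFrame   # strain, rnai, epistasis


@dataclass
class StudyBundle:
    config: SimConfig
    genome: Dict[str, str]
    models: GeneModelSet
    events: List[ASEvent]
    counts: Dict[str, JunctionCountTable]
    alignments: AlignmentSet
    plate: FitnessPlate
    truth: TruthTable


# ---------------------------------------------------------------------------
# low-level samplers


def simulate_junction_counts(psi: float, depth: int,
                             rng: np.random.Generator
                             ) -> Tuple[int, int, int]:
    """Sample (C1A, AC2, C1C2) read counts for true PSI (percent)."""
    if not 0.0 <= psi <= 100.0:
        raise ValueError("psi must be in [0, 100]")
    p = psi / 100.0
    c1a = int(rng.binomial(depth, p))
    ac2 = int(rng.binomial(depth, p))
    c1c2 = int(rng.binomial(depth, 1.0 - p))
    return c1a, ac2, c1c2


def simulate_motif_presence(n_events: int, p_a: float, p_b: float,
                            cooccur_factor: float,
                            rng: np.random.Generator
                            ) -> Tuple[Set[str], Set[str]]:
    """Presence/absence of two motifs over events with a controlled joint.

    P(both) = cooccur_factor * p_a * p_b; marginals are preserved, so the
    factor must satisfy P(both) <= min(p_a, p_b) and the complement cell
    must stay non-negative.  factor=1 plants independently.
    """
    p11 = cooccur_factor * p_a * p_b
    p10, p01 = p_a - p11, p_b - p11
    p00 = 1.0 - p11 - p10 - p01
    if min(p11, p10, p01, p00) < -1e-12:
        raise ValueError(
            f"infeasible joint: factor {cooccur_factor} with marginals "
            f"{p_a}, {p_b}")
    cells = rng.choice(4, size=n_events,
                       p=np.clip([p11, p10, p01, p00], 0, None) /
                       sum(max(x, 0.0) for x in (p11, p10, p01, p00)))
    set_a = {f"ev{i}" for i in range(n_events) if cells[i] in (0, 1)}
    set_b = {f"ev{i}" for i in range(n_events) if cells[i] in (0, 2)}
    return set_a, set_b


def simulate_fitness_plate(config: FitnessConfig,
                           rng: np.random.Generator) -> FitnessPlate:
    """Multiplicative population model with log-normal well noise.

    population(strain, rnai, rep) = baseline * strain_effect * rnai_effect
    * epistasis(strain, rnai) * lognormal noise; epistasis defaults to 1
    (and is forced to 1 for the reference strain and the control RNAi).
    """
    if config.baseline <= 0:
        raise ValueError("baseline must be positive")
    if config.replicates < 2:
        raise ValueError("need >=2 technical replicates")
    rows = []
    for exp in range(1, config.experiments + 1):
        for strain, se in sorted(config.strain_effects.items()):
            for rnai, re_ in sorted(config.rnai_effects.items()):
                epi = 1.0
                if strain != "WT" and rnai != "GFP":
                    epi = config.epistasis.get((strain, rnai), 1.0)
                for rep in range(1, config.replicates + 1):
                    noise = (math.exp(rng.normal(0.0, config.noise_sd))
                             if config.noise_sd > 0 else 1.0)
                    rows.append({
                        "strain": strain, "rnai": rnai, "experiment": exp,
                        "replicate": rep,
                        "population": config.baseline * se * re_ * epi
                        * noise,
                    })
    return FitnessPlate(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# motif planting helpers


def _disallowed_index(pattern: MotifPattern) -> int:
    """A pattern position with a proper subset of bases (breakable)."""
    for i, s in enumerate(pattern.positions):
        if len(s) < 4:
            return i
    raise ValueError(f"pattern {pattern.name} matches everything")


def _break_base(pattern: MotifPattern, idx: int, current: str) -> str:
    for b in BASES:
        if b not in pattern.positions[idx] and b != current:
            return b
    raise AssertionError("unreachable: no breaking base")


def _sense_matches(chars: Sequence[str], strand: str,
                   pattern: MotifPattern) -> List[List[int]]:
    """Matches in a (possibly gapped) char row, scanned on the sense
    strand; each match is its list of columns in sense order."""
    cols = [i for i, c in enumerate(chars) if c != "-"]
    seq = "".join(c for c in chars if c != "-")
    if strand == "-":
        seq = reverse_complement(seq)
        cols = cols[::-1]
    return [cols[i:i + pattern.length]
            for i in find_matches(pattern, seq)]


def _ablate_match(chars: List[str], match_cols: List[int],
                  pattern: MotifPattern, strand: str) -> None:
    idx = _disallowed_index(pattern)
    col = match_cols[idx]
    sense_base = _break_base(pattern, idx, "")
    chars[col] = (sense_base if strand == "+"
                  else reverse_complement(sense_base))


@dataclass
class _PlantedHit:
    event_id: str
    motif: str
    pattern: MotifPattern
    region: str
    genomic_start: int          # genomic coordinate of footprint start
    length: int
    strand: str
    conservation_species: int
    carriers: Tuple[str, ...]
    shifts: Dict[str, int]      # genomic column shift per carrier
    pair_id: Optional[int] = None


# ---------------------------------------------------------------------------
# study generation


def _make_gene(gene_idx: int, offset: int, cassette: bool, strand: str,
               cfg: SimConfig, rng: np.random.Generator
               ) -> Tuple[Gene, int, Optional[int]]:
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exons = []
    pos = offset
    for k in range(n_ex):
        elen = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        exons.append((pos, pos + elen))
        pos += elen
        if k < n_ex - 1:
            ilen = max(cfg.intron_min, int(round(
                rng.lognormal(cfg.intron_log_mean, cfg.intron_log_sd))))
            pos += ilen
    gid = f"g{gene_idx:04d}"
    transcripts = [Transcript(f"{gid}.t1", list(exons))]
    cassette_exon = None
    if cassette and n_ex >= 3:
        cassette_exon = int(rng.integers(1, n_ex - 1))
        skipped = [e for i, e in enumerate(exons) if i != cassette_exon]
        transcripts.append(Transcript(f"{gid}.t2", skipped))
    gene = Gene(gid, "chrI", strand, transcripts)
    return gene, pos, cassette_exon


def simulate_study(config: SimConfig) -> StudyBundle:
    """Generate a full synthetic study; deterministic for a fixed seed."""
    ss = np.random.SeedSequence(config.seed)
    keys = ("genes", "genome", "psi", "counts", "alignment", "fitness",
            "plant")
    rngs = {k: np.random.default_rng(s)
            for k, s in zip(keys, ss.spawn(len(keys)))}

    # --- gene models -------------------------------------------------------
    genes: List[Gene] = []
    offset = cfg_gap = config.intergenic
    rng_g = rngs["genes"]
    n_cassette = int(round(config.cassette_fraction * config.n_genes))
    for i in range(config.n_genes):
        cassette = i < n_cassette
        strand = "+" if rng_g.random() < 0.5 else "-"
        gene, end, _ = _make_gene(i, offset, cassette, strand, config, rng_g)
        genes.append(gene)
        offset = end + cfg_gap
    models = GeneModelSet(genes)
    genome_len = offset + cfg_gap
    chrom = list(rngs["genome"].choice(list(BASES), size=genome_len))

    events = build_catalog(models)
    cassette_events = [e for e in events if e.type == "cassette"]

    # --- true PSI per sample ----------------------------------------------
    rng_psi = rngs["psi"]
    n_diff = int(round(config.differential_fraction * len(cassette_events)))
    psi_rows = []
    truth_psi: Dict[str, Dict[str, float]] = {}
    for j, ev in enumerate(cassette_events):
        differential = j < n_diff
        if differential:
            wt = float(rng_psi.uniform(20, 60))
            up = rng_psi.random() < 0.5
            mut = wt + config.delta_psi if up else max(
                0.0, wt - config.delta_psi)
            if mut > 100.0:
                mut = wt - config.delta_psi
        else:
            wt = float(rng_psi.uniform(5, 95))
            mut = wt
        truth_psi[ev.event_id] = {config.wt_sample: wt}
        psi_rows.append({"event_id": ev.event_id,
                         "sample_id": config.wt_sample, "true_psi": wt,
                         "differential": differential,
                         "delta": 0.0})
        for ms in config.mutant_samples:
            truth_psi[ev.event_id][ms] = mut
            psi_rows.append({"event_id": ev.event_id, "sample_id": ms,
                             "true_psi": mut, "differential": differential,
                             "delta": mut - wt})
    diff_events = [ev for j, ev in enumerate(cassette_events) if j < n_diff]

    # --- motif planting in the reference genome ---------------------------
    rng_plant = rngs["plant"]
    other_species = [sp for sp in config.species[:config.n_species]
                     if sp != config.species[0]]
    planted: List[_PlantedHit] = []
    pair_rows = []
    motif_rows = []
    genome = {"chrI": "".join(chrom)}
    for pair_id, ev in enumerate(diff_events):
        for pp in config.pair_plants:
            pat1 = parse_motif(pp.first.pattern, pp.first.name)
            pat2 = parse_motif(pp.second.pattern, pp.second.name)
            regions = {r.label: r for r in
                       event_regions(ev, genome, window=300)}
            region = regions.get(pp.first.region)
            if region is None:
                raise ValueError(
                    f"gene {ev.gene_id}: region {pp.first.region} absent")
            rlen = region.interval[1] - region.interval[0]
            margin = 30  # keep plants clear of region edges for jitter room
            need = pat1.length + pp.spacing + pat2.length + 2 * margin
            if need > rlen:
                raise ValueError(
                    f"gene {ev.gene_id}: planted spacing {pp.spacing} does "
                    f"not fit region {pp.first.region} of length {rlen}")
            base = margin + int(rng_plant.integers(0, rlen - need + 1))
            if pp.order == "ab":      # first motif upstream in sense
                o1 = base
                o2 = base + pat1.length + pp.spacing
            elif pp.order == "ba":
                o2 = base
                o1 = base + pat2.length + pp.spacing
            else:
                raise ValueError(f"unknown order {pp.order!r}")
            # sense offsets -> genomic coordinates
            def g_of(off: int, length: int) -> int:
                if region.strand == "+":
                    return region.interval[0] + off
                return region.interval[1] - off - length
            # write concrete instances into the genome
            for pat, off in ((pat1, o1), (pat2, o2)):
                gstart = g_of(off, pat.length)
                concrete = "".join(
                    sorted(s)[int(rng_plant.integers(0, len(s)))]
                    for s in pat.positions)
                if region.strand == "-":
                    concrete = reverse_complement(concrete)
                chrom[gstart:gstart + pat.length] = list(concrete)
            genome = {"chrI": "".join(chrom)}
            # carriers shared by the pair; per-carrier genomic shift
            k = pp.first.conservation_species
            order_idx = rng_plant.permutation(len(other_species))
            carriers = tuple(other_species[i] for i in order_idx[:k])
            jit = pp.first.jitter
            shifts = {sp: int(rng_plant.integers(-jit, jit + 1))
                      for sp in carriers}
            shift2 = dict(shifts)
            if not pp.spacing_conserved:
                bump = int(math.ceil(0.2 * pp.spacing)) + 3
                shift2 = {sp: d + bump for sp, d in shifts.items()}
            for pat, off, sh in ((pat1, o1, shifts), (pat2, o2, shift2)):
                gstart = g_of(off, pat.length)
                planted.append(_PlantedHit(
                    ev.event_id, pat.name, pat, pp.first.region, gstart,
                    pat.length, ev.strand, k, carriers, sh, pair_id))
                motif_rows.append({
                    "event_id": ev.event_id, "motif": pat.name,
                    "region": pp.first.region, "genomic_start": gstart,
                    "length": pat.length,
                    "conservation_species": k,
                    "conserved": k >= 2})
            pair_rows.append({
                "event_id": ev.event_id, "motif_a": pat1.name,
                "motif_b": pat2.name, "region": pp.first.region,
                "spacing": pp.spacing, "order": pp.order,
                "spacing_conserved": pp.spacing_conserved
                and pp.first.conservation_species >= 2,
                "conservation_species": k})

    # scrub chance matches of every planted pattern across each planted
    # event's span so planted signals are the only qualifying ones
    patterns = []
    for pp in config.pair_plants:
        patterns.append(parse_motif(pp.first.pattern, pp.first.name))
        patterns.append(parse_motif(pp.second.pattern, pp.second.name))
    protect: Set[int] = set()
    for h in planted:
        protect.update(range(h.genomic_start, h.genomic_start + h.length))
    for ev in diff_events:
        span = (ev.flank_up[0], ev.flank_down[1])
        _scrub_span(chrom, span, ev.strand, patterns, protect)
    genome = {"chrI": "".join(chrom)}

    # --- junction counts ---------------------------------------------------
    rng_c = rngs["counts"]
    samples = [config.wt_sample] + list(config.mutant_samples)
    counts: Dict[str, JunctionCountTable] = {
        s: JunctionCountTable(s, {}) for s in samples}
    event_keys: Set[Tuple[str, int, int]] = set()
    for ev in cassette_events:
        for _, key in ev.inclusion_junctions + ev.exclusion_junctions:
            event_keys.add((key.seq_id, key.donor_pos, key.acceptor_pos))
    for ev in cassette_events:
        inc = ev.inclusion_junctions
        exc = ev.exclusion_junctions
        for s in samples:
            p = truth_psi[ev.event_id][s]
            c1a, ac2, c1c2 = simulate_junction_counts(p, config.depth, rng_c)
            table = counts[s].counts
            table[inc[0][1]] = table.get(inc[0][1], 0) + c1a
            table[inc[1][1]] = table.get(inc[1][1], 0) + ac2
            table[exc[0][1]] = table.get(exc[0][1], 0) + c1c2
    for gene in genes:
        for t in gene.transcripts:
            for d, a in t.introns():
                if (gene.seq_id, d, a) in event_keys:
                    continue
                key = JunctionKey(gene.seq_id, d, a, gene.strand)
                for s in samples:
                    if key not in counts[s].counts:
                        counts[s].counts[key] = int(
                            rng_c.poisson(config.depth))

    # --- alignments --------------------------------------------------------
    rng_a = rngs["alignment"]
    blocks = []
    hits_by_event: Dict[str, List[_PlantedHit]] = {}
    for h in planted:
        hits_by_event.setdefault(h.event_id, []).append(h)
    for ev in diff_events:
        span = (ev.flank_up[0], ev.flank_down[1])
        blocks.append(_simulate_block(
            genome["chrI"], span, ev.strand, config, other_species,
            hits_by_event.get(ev.event_id, []), rng_a))
    alignments = AlignmentSet(config.species[0], blocks)

    # --- fitness -----------------------------------------------------------
    plate = simulate_fitness_plate(config.fitness, rngs["fitness"])
    fit_rows = []
    for strain in sorted(config.fitness.strain_effects):
        for rnai in sorted(config.fitness.rnai_effects):
            epi = 1.0
            if strain != "WT" and rnai != "GFP":
                epi = config.fitness.epistasis.get((strain, rnai), 1.0)
            fit_rows.append({"strain": strain, "rnai": rnai,
                             "epistasis": epi})

    truth = TruthTable(
        psi=pd.DataFrame(psi_rows),
        motifs=pd.DataFrame(motif_rows),
        pairs=pd.DataFrame(pair_rows),
        fitness=pd.DataFrame(fit_rows),
    )
    return StudyBundle(config, genome, models, events, counts, alignments,
                       plate, truth)


def _scrub_span(chrom: List[str], span: Tuple[int, int], strand: str,
                patterns: Sequence[MotifPattern],
                protect: Set[int]) -> None:
    """Ablate chance matches of the patterns inside a genomic span,
    leaving protected (planted) footprints untouched."""
    s, e = max(span[0], 0), min(span[1], len(chrom))
    for _ in range(10):
        dirty = False
        seg = chrom[s:e]
        for pat in patterns:
            for match_cols in _sense_matches(seg, strand, pat):
                g_cols = [s + c for c in match_cols]
                if any(g in protect for g in g_cols):
                    continue
                idx = _disallowed_index(pat)
                base = _break_base(pat, idx, "")
                chrom[g_cols[idx]] = (base if strand == "+"
                                      else reverse_complement(base))
                dirty = True
        if not dirty:
            break


def simulate_alignment_block(reference: str, ref_start: int, strand: str,
                             config: SimConfig,
                             planted_hits: Sequence[_PlantedHit],
                             rng: np.random.Generator) -> AlignmentBlock:
    """One alignment block over an explicit reference sequence.

    ``planted_hits`` use genomic coordinates consistent with
    ``ref_start``; each hit's carriers get an exact (jittered) copy of
    the motif and every other species has all nearby matches ablated.
    """
    species = [sp for sp in config.species[:config.n_species]
               if sp != config.species[0]]
    return _simulate_block(reference, (0, len(reference)), strand, config,
                           species, planted_hits, rng,
                           ref_start_override=ref_start)


def _simulate_block(chrom: str, span: Tuple[int, int], strand: str,
                    config: SimConfig, other_species: Sequence[str],
                    planted_hits: Sequence[_PlantedHit],
                    rng: np.random.Generator,
                    ref_start_override: Optional[int] = None
                    ) -> AlignmentBlock:
    s, e = span
    ref = chrom[s:e]
    width = len(ref)
    ref_start = ref_start_override if ref_start_override is not None else s
    origin = ref_start  # hits' genomic coordinates are origin-based

    # mutation-free zones: planted footprints with jitter slack, plus the
    # span between paired motifs so species spacing stays controllable
    frozen = np.zeros(width, dtype=bool)
    by_pair: Dict[Optional[int], List[_PlantedHit]] = {}
    for h in planted_hits:
        by_pair.setdefault(h.pair_id, []).append(h)
        lo = max(0, h.genomic_start - origin - 26)
        hi = min(width, h.genomic_start - origin + h.length + 26)
        frozen[lo:hi] = True
    for pid, hs in by_pair.items():
        if pid is None or len(hs) < 2:
            continue
        lo = min(h.genomic_start for h in hs) - origin - 26
        hi = max(h.genomic_start + h.length for h in hs) - origin + 26
        frozen[max(0, lo):min(width, hi)] = True

    rows: Dict[str, str] = {config.species[0]: ref}
    for sp in other_species:
        chars = list(ref)
        sub_mask = rng.random(width) < config.substitution_rate
        for i in np.flatnonzero(sub_mask):
            if frozen[i]:
                continue
            alts = [b for b in BASES if b != chars[i]]
            chars[i] = alts[int(rng.integers(0, 3))]
        i = 0
        geo_p = 1.0 / config.deletion_mean_len
        while i < width:
            if not frozen[i] and rng.random() < config.deletion_rate:
                dlen = int(rng.geometric(geo_p))
                j = i
                while j < min(i + dlen, width) and not frozen[j]:
                    chars[j] = "-"
                    j += 1
                i = j + 1
            else:
                i += 1
        _enforce_plants(chars, planted_hits, sp, origin, width, ref)
        rows[sp] = "".join(chars)
    return AlignmentBlock(config.species[0], "chrI", ref_start, rows)


def _enforce_plants(chars: List[str], planted_hits: Sequence[_PlantedHit],
                    sp: str, origin: int, width: int, ref: str) -> None:
    """Make one species row match the planted truth exactly: carriers get
    the (jitter-shifted) motif copy; every other match of a planted
    pattern anywhere in the block is ablated."""
    targets: Dict[int, Set[int]] = {}  # hit index -> target column set
    all_target_cols: Set[int] = set()
    for hi_idx, h in enumerate(planted_hits):
        if sp not in h.carriers:
            continue
        c0 = h.genomic_start - origin
        t0 = min(max(c0 + h.shifts[sp], 0), width - h.length)
        footprint = list(ref[c0:c0 + h.length])
        chars[t0:t0 + h.length] = footprint
        cols = set(range(t0, t0 + h.length))
        targets[hi_idx] = cols
        all_target_cols |= cols
    for hi_idx, h in enumerate(planted_hits):
        expected = targets.get(hi_idx)
        for _ in range(6):
            matches = _sense_matches(chars, h.strand, h.pattern)
            bad = [mc for mc in matches
                   if expected is None or set(mc) != expected]
            if expected is not None and not any(
                    set(mc) == expected for mc in matches):
                # carrier copy damaged by an ablation pass: restore it
                t0 = min(expected)
                chars[t0:t0 + h.length] = list(
                    ref[h.genomic_start - origin:
                        h.genomic_start - origin + h.length])
                continue
            if not bad:
                break
            progressed = False
            for mc in bad:
                # break the match at a position outside planted targets
                for idx in range(h.pattern.length):
                    col = mc[idx]
                    if col in all_target_cols:
                        continue
                    if len(h.pattern.positions[idx]) == 4:
                        continue
                    base = _break_base(h.pattern, idx, "")
                    chars[col] = (base if h.strand == "+"
                                  else reverse_complement(base))
                    progressed = True
                    break
            if not progressed:
                break


# ---------------------------------------------------------------------------
# serialisation


def write_study(bundle: StudyBundle, outdir: str) -> Dict[str, str]:
    """Write the study bundle to a directory; returns name -> path."""
    import os

    os.makedirs(outdir, exist_ok=True)
    cfg = bundle.config
    seed_line = f"seed={cfg.seed}"
    paths = {}

    p = os.path.join(outdir, "genome.fa")
    formats_io.write_genome(bundle.genome, p)
    paths["genome"] = p

    p = os.path.join(outdir, "annotation.gff3")
    formats_io.write_gene_models(bundle.models, p, header_comments=[
        f"!{seed_line}"])
    paths["annotation"] = p

    for sample, table in sorted(bundle.counts.items()):
        p = os.path.join(outdir, f"junctions_{sample}.tsv")
        formats_io.write_junction_counts(table, p,
                                         header_comments=[seed_line])
        paths[f"junctions_{sample}"] = p

    p = os.path.join(outdir, "alignments.maf")
    formats_io.write_alignments(
        bundle.alignments, p,
        seq_sizes={name: len(seq) for name, seq in bundle.genome.items()},
        header_comments=[seed_line])
    paths["alignments"] = p

    p = os.path.join(outdir, "fitness.tsv")
    with open(p, "w") as fh:
        fh.write(f"# {seed_line}\n")
        bundle.plate.wells.to_csv(fh, sep="\t", index=False)
    paths["fitness"] = p

    header = [seed_line, f"config={asdict(cfg)!r}"]
    for name in ("psi", "motifs", "pairs", "fitness"):
        p = os.path.join(outdir, f"truth_{name}.tsv")
        formats_io.write_table(getattr(bundle.truth, name), p,
                               header_comments=header)
        paths[f"truth_{name}"] = p
    return paths
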