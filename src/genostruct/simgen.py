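"""Synthetic four-species genome evolver with a planted-event truth ledger.

An ancestral genome (chromosome sequences, gene models, tRNA clusters,
satellite arrays, a pericentromeric heterochromatin compartment) is evolved
along the fixed four-taxon-plus-outgroup phylogeny.  Structural events —
TE insertions of three classes, inversions, tandem and dispersed
duplications, satellite expansions/contractions, tRNA cluster mutations,
intronic indels — are drawn per branch from Poisson(rate x branch Myr x
genome Mb) and applied sequentially; Jukes-Cantor substitutions are applied
last on each branch, never within +/-5 bp of a planted breakpoint so that
breakpoints remain recoverable downstream.

Every planted event is recorded in a :class:`~genostruct.models.TruthTable`
together with its lifted coordinates in each descendant taxon, so that
recovery by the analysis modules can be scored exactly.

Determinism: every (branch, event-type) pair draws from its own named
random substream derived from the configured seed, so changing one rate
does not perturb unrelated draws, and a fixed (config, seed) reproduces
outputs byte-identically.
"""

from __future__ import annotations

import copy as _copy
import json
import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import io as gio
from .models import Gene, PlantedEvent, Repeat, TruthTable, TRNAGene
from .phylo import Phylogeny

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)

EVENT_TYPES = (
    "te_dna",
    "te_ltr",
    "te_nonltr",
    "inversion",
    "tandem_dup",
    "dispersed_dup",
    "satellite_change",
    "trna_dup",
    "trna_del",
    "trna_anticodon",
    "intron_indel",
)

_TE_CLASS_OF = {"te_dna": "DNA", "te_ltr": "LTR", "te_nonltr": "non-LTR"}

TE_FAMILIES = {
    "DNA": ("INE-1", "hobo", "pogo", "S-element"),
    "LTR": ("roo", "copia", "gypsy", "blood"),
    "non-LTR": ("jockey", "Doc", "F-element", "I-element"),
}
# consensus lengths per class; individual copies are 5'-truncated draws
_CONSENSUS_LEN = {"DNA": 2500, "LTR": 9000, "non-LTR": 6500}

_STD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp_str(s: str) -> str:
    return "".join(_RC[b] for b in reversed(s))


#: anticodon (DNA) -> one-letter amino acid, sense codons only
ANTICODON_TO_AA: dict[str, str] = {
    _revcomp_str(codon): aa for codon, aa in _STD_TABLE.forward_table.items()
}
AA_TO_ANTICODONS: dict[str, tuple[str, ...]] = {}
for _ac in sorted(ANTICODON_TO_AA):
    AA_TO_ANTICODONS.setdefault(ANTICODON_TO_AA[_ac], ())
    AA_TO_ANTICODONS[ANTICODON_TO_AA[_ac]] += (_ac,)


class PlacementError(RuntimeError):
    """Requested feature density cannot be placed on the sequence."""


@dataclass
class SimConfig:
    """Evolution-scenario parameters.

    Rates are events per Mb per Myr, drawn per branch; ``branch_rates``
    overrides the flat defaults on named branches (the stem is given a
    DNA-transposon-heavy TE mixture and the root edge a non-LTR-heavy one,
    mirroring the class composition contrast between younger and older
    fixed TE content in the mel-complex genomes).
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr2": 2_500_000, "chrX": 2_500_000}
    )
    het_fraction: float = 0.5  # terminal pericentromeric segment at chromosome start
    # --- ancestral content
    n_genes: int = 150
    exons_per_gene: int = 5
    exon_len_range: tuple[int, int] = (120, 400)
    intron_len_range: tuple[int, int] = (80, 1200)
    n_trnas: int = 80
    n_trna_clusters: int = 16
    trna_len: int = 72
    trna_spacing_range: tuple[int, int] = (120, 400)
    n_satellites: int = 14
    n_satellite_families: int = 5
    satellite_monomer_len: int = 150
    satellite_copies_range: tuple[int, int] = (5, 40)
    n_ancestral_tes: int = 60
    # element-count mixture; with the class length medians below this yields
    # roughly 30/18/52 DNA/LTR/non-LTR base-pair shares (old shared content)
    ancestral_te_mixture: dict[str, float] = field(
        default_factory=lambda: {"DNA": 0.70, "LTR": 0.03, "non-LTR": 0.27}
    )
    # --- per-branch event rates (events / Mb / Myr)
    rates: dict[str, float] = field(
        default_factory=lambda: {
            # terminal-branch TE class rates give LTR-dominated bp shares
            # (~52/34/14 LTR/non-LTR/DNA), the species-specific pattern
            "te_dna": 2.2,
            "te_ltr": 0.65,
            "te_nonltr": 1.15,
            "inversion": 0.5,
            "tandem_dup": 1.6,
            "dispersed_dup": 0.3,
            "satellite_change": 0.4,
            "trna_dup": 0.05,
            "trna_del": 0.05,
            "trna_anticodon": 0.08,
            "intron_indel": 2.0,
        }
    )
    branch_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # young fixed stem content is DNA-transposon-dominated in bp
            # (~70% DNA bp despite short elements, the INE-1-like burst)
            "stem": {"te_dna": 5.1, "te_ltr": 0.10, "te_nonltr": 0.20},
            # old shared content (root edge) is non-LTR-dominated in bp
            "root": {"te_dna": 2.1, "te_ltr": 0.10, "te_nonltr": 0.78},
        }
    )
    substitution_rate: float = 0.005  # substitutions / bp / Myr (Jukes-Cantor)
    het_eu_multiplier: float = 20.0  # rearrangement placement weight, het vs eu
    # --- event geometry
    te_len_median: dict[str, float] = field(
        default_factory=lambda: {"DNA": 320.0, "LTR": 4000.0, "non-LTR": 1500.0}
    )
    te_len_sigma: dict[str, float] = field(
        default_factory=lambda: {"DNA": 0.6, "LTR": 0.5, "non-LTR": 0.7}
    )
    te_het_fraction: float = 0.3  # fraction of TE insertions landing in het
    te_exonic_fraction: dict[str, float] = field(
        default_factory=lambda: {"root": 0.5, "stem": 0.15}
    )  # default 0.1 on other branches
    te_exonic_default: float = 0.1
    inversion_len_range: tuple[int, int] = (5_000, 40_000)
    tandem_len_median: float = 1500.0
    tandem_len_sigma: float = 0.6
    tandem_len_range: tuple[int, int] = (300, 8000)
    dispersed_len_range: tuple[int, int] = (500, 5000)
    satellite_delta_range: tuple[int, int] = (2, 15)  # monomer copies added/removed
    intron_indel_len_median: float = 40.0
    intron_indel_len_sigma: float = 1.0
    intron_indel_ins_prob: float = 0.5
    intron_te_prob: float = 0.15  # intronic insertions that are TE fragments
    isoacceptor_prob: float = 0.25  # anticodon shifts preserving the isotype
    max_attempts: int = 60

    def validate(self) -> None:
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("event rates must be >= 0")
        for over in self.branch_rates.values():
            if any(v < 0 for v in over.values()):
                raise ValueError("event rates must be >= 0")
        if self.substitution_rate < 0:
            raise ValueError("substitution rate must be >= 0")
        if not 0.0 <= self.het_fraction < 1.0:
            raise ValueError("het_fraction must be in [0, 1)")
        unknown = set(self.rates) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")

    def rate(self, branch: str, etype: str) -> float:
        return self.branch_rates.get(branch, {}).get(etype, self.rates.get(etype, 0.0))

    def genome_mb(self) -> float:
        return sum(self.chrom_lengths.values()) / 1e6


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


@dataclass
class GenomeState:
    """A genome plus annotations; the ancestor and every evolved taxon."""

    seqs: dict[str, np.ndarray]
    genes: list[Gene]
    trnas: list[TRNAGene]
    repeats: list[Repeat]
    het_end: dict[str, int]  # heterochromatin occupies [0, het_end) per chromosome
    tracked: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def copy(self) -> "GenomeState":
        return GenomeState(
            seqs={c: s.copy() for c, s in self.seqs.items()},
            genes=[g.copy() for g in self.genes],
            trnas=[t.copy() for t in self.trnas],
            repeats=[r.copy() for r in self.repeats],
            het_end=dict(self.het_end),
            tracked=dict(self.tracked),
        )

    def sequences(self) -> dict[str, str]:
        return {c: _decode(s) for c, s in self.seqs.items()}

    def compartments(self) -> dict[str, list[tuple[int, int, str]]]:
        out = {}
        for chrom, arr in self.seqs.items():
            h = self.het_end[chrom]
            parts = []
            if h > 0:
                parts.append((0, h, "het"))
            if h < len(arr):
                parts.append((h, len(arr), "eu"))
            out[chrom] = parts
        return out

    # ------------------------------------------------------------ liftover

    def _occupied(self, chrom: str, pad: int = 10) -> list[tuple[int, int]]:
        iv = []
        for g in self.genes:
            if g.chrom == chrom:
                s, e = g.span
                iv.append((s - pad, e + pad))
        for t in self.trnas:
            if t.chrom == chrom:
                iv.append((t.start - pad, t.end + pad))
        for r in self.repeats:
            if r.chrom == chrom:
                iv.append((r.start - pad, r.end + pad))
        for c, s, e in self.tracked.values():
            if c == chrom:
                iv.append((s - pad, e + pad))
        iv.sort()
        merged: list[tuple[int, int]] = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def free_positions(self, chrom: str, lo: int, hi: int) -> list[tuple[int, int]]:
        """Feature-free sub-intervals of [lo, hi)."""
        gaps = []
        cursor = lo
        for s, e in self._occupied(chrom):
            if e <= lo:
                continue
            if s >= hi:
                break
            if s > cursor:
                gaps.append((cursor, min(s, hi)))
            cursor = max(cursor, e)
        if cursor < hi:
            gaps.append((cursor, hi))
        return [(s, e) for s, e in gaps if e > s]

    def insert(self, chrom: str, pos: int, payload: np.ndarray) -> None:
        """Insert sequence at pos; shift/grow features per the half-open rules."""
        L = len(payload)
        self.seqs[chrom] = np.concatenate(
            [self.seqs[chrom][:pos], payload, self.seqs[chrom][pos:]]
        )

        def iv(s: int, e: int) -> tuple[int, int]:
            if pos <= s:
                return s + L, e + L
            if pos < e:
                return s, e + L
            return s, e

        for g in self.genes:
            if g.chrom == chrom:
                g.exons = [iv(*x) for x in g.exons]
                g.cds = iv(*g.cds)
        for t in self.trnas:
            if t.chrom == chrom:
                t.start, t.end = iv(t.start, t.end)
        for r in self.repeats:
            if r.chrom == chrom:
                r.start, r.end = iv(r.start, r.end)
        for eid, (c, s, e) in list(self.tracked.items()):
            if c == chrom:
                self.tracked[eid] = (c, *iv(s, e))
        if pos < self.het_end[chrom]:
            self.het_end[chrom] += L

    def delete(self, chrom: str, ds: int, de: int) -> None:
        self.seqs[chrom] = np.concatenate([self.seqs[chrom][:ds], self.seqs[chrom][de:]])

        def pt(p: int) -> int:
            return p - max(0, min(p, de) - ds)

        for g in self.genes:
            if g.chrom == chrom:
                g.exons = [(pt(s), pt(e)) for s, e in g.exons]
                g.cds = (pt(g.cds[0]), pt(g.cds[1]))
        self.trnas = [
            t
            for t in self.trnas
            if not (t.chrom == chrom and pt(t.end) - pt(t.start) <= 0)
        ]
        for t in self.trnas:
            if t.chrom == chrom:
                t.start, t.end = pt(t.start), pt(t.end)
        kept = []
        for r in self.repeats:
            if r.chrom == chrom:
                r.start, r.end = pt(r.start), pt(r.end)
                if r.end - r.start <= 0:
                    continue
            kept.append(r)
        self.repeats = kept
        for eid, (c, s, e) in list(self.tracked.items()):
            if c == chrom:
                ns, ne = pt(s), pt(e)
                if ne - ns <= 0:
                    del self.tracked[eid]
                else:
                    self.tracked[eid] = (c, ns, ne)
        self.het_end[chrom] = pt(self.het_end[chrom])

    def features_partially_overlapping(self, chrom: str, a: int, b: int) -> bool:
        """True if any feature straddles either breakpoint of [a, b)."""

        def straddles(s: int, e: int) -> bool:
            return (s < a < e) or (s < b < e)

        for g in self.genes:
            if g.chrom == chrom and straddles(*g.span):
                return True
        for t in self.trnas:
            if t.chrom == chrom and straddles(t.start, t.end):
                return True
        for r in self.repeats:
            if r.chrom == chrom and straddles(r.start, r.end):
                return True
        for c, s, e in self.tracked.values():
            if c == chrom and straddles(s, e):
                return True
        return False

    def invert(self, chrom: str, a: int, b: int) -> None:
        """Invert [a, b); features must not straddle the breakpoints."""
        seg = self.seqs[chrom][a:b]
        self.seqs[chrom][a:b] = _COMP[seg[::-1]]

        def iv(s: int, e: int) -> tuple[int, int]:
            if a <= s and e <= b:
                return a + b - e, a + b - s
            return s, e

        flip = {"+": "-", "-": "+", ".": "."}
        for g in self.genes:
            if g.chrom == chrom and a <= g.span[0] and g.span[1] <= b:
                g.exons = sorted(iv(*x) for x in g.exons)
                g.cds = iv(*g.cds)
                g.strand = flip[g.strand]
        for t in self.trnas:
            if t.chrom == chrom and a <= t.start and t.end <= b:
                t.start, t.end = iv(t.start, t.end)
                t.strand = flip[t.strand]
        for r in self.repeats:
            if r.chrom == chrom and a <= r.start and r.end <= b:
                r.start, r.end = iv(r.start, r.end)
                r.strand = flip[r.strand]
        for eid, (c, s, e) in list(self.tracked.items()):
            if c == chrom and a <= s and e <= b:
                self.tracked[eid] = (c, *iv(s, e))


# ---------------------------------------------------------------- ancestor


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


@dataclass
class _Library:
    """Per-run sequence libraries shared by all branches (seed-derived)."""

    te_consensus: dict[str, np.ndarray]  # family -> sequence
    te_class: dict[str, str]
    sat_monomers: dict[str, np.ndarray]


def _build_library(config: SimConfig) -> _Library:
    rng = _substream(config.seed, 101)
    te_cons, te_cls = {}, {}
    for klass, families in TE_FAMILIES.items():
        for fam in families:
            te_cons[fam] = rng.integers(0, 4, size=_CONSENSUS_LEN[klass], dtype=np.uint8)
            te_cls[fam] = klass
    sats = {
        f"Sat{i+1}": rng.integers(0, 4, size=config.satellite_monomer_len, dtype=np.uint8)
        for i in range(config.n_satellite_families)
    }
    return _Library(te_cons, te_cls, sats)


def simulate_ancestor(config: SimConfig) -> GenomeState:
    """Build the ancestral genome: sequence, genes, tRNA clusters, satellites."""
    config.validate()
    lib = _build_library(config)
    rng = _substream(config.seed, 102)
    seqs = {
        chrom: rng.integers(0, 4, size=L, dtype=np.uint8)
        for chrom, L in config.chrom_lengths.items()
    }
    het_end = {c: int(L * config.het_fraction) for c, L in config.chrom_lengths.items()}
    state = GenomeState(seqs=seqs, genes=[], trnas=[], repeats=[], het_end=het_end)
    chroms = list(config.chrom_lengths)

    # satellite arrays in heterochromatin (exact tandem monomer copies)
    for i in range(config.n_satellites):
        fam = f"Sat{rng.integers(config.n_satellite_families) + 1}"
        copies = int(rng.integers(*config.satellite_copies_range))
        payload = np.tile(lib.sat_monomers[fam], copies)
        pos = _sample_free(state, rng, chroms, "het", len(payload), config.max_attempts)
        if pos is None:
            raise PlacementError("cannot place satellite array; genome too dense")
        chrom, p = pos
        state.seqs[chrom][p : p + len(payload)] = payload
        state.repeats.append(
            Repeat(chrom, p, p + len(payload), "+", fam, "satellite", f"anc_sat{i:03d}")
        )

    # protein-coding genes in euchromatin
    for i in range(config.n_genes):
        placed = False
        for _ in range(config.max_attempts):
            exon_lens = rng.integers(*config.exon_len_range, size=config.exons_per_gene)
            intron_lens = rng.integers(
                *config.intron_len_range, size=max(config.exons_per_gene - 1, 0)
            )
            span = int(exon_lens.sum() + intron_lens.sum())
            pos = _sample_free(state, rng, chroms, "eu", span, 1)
            if pos is None:
                continue
            chrom, p = pos
            exons = []
            cursor = p
            for j, xl in enumerate(exon_lens):
                exons.append((cursor, cursor + int(xl)))
                if j < len(intron_lens):
                    cursor += int(xl) + int(intron_lens[j])
                else:
                    cursor += int(xl)
            cds = (exons[0][0] + int(exon_lens[0] // 2), exons[-1][1] - int(exon_lens[-1] // 2))
            strand = "+" if rng.random() < 0.5 else "-"
            state.genes.append(Gene(f"g{i:04d}", chrom, strand, exons, cds))
            placed = True
            break
        if not placed:
            raise PlacementError("cannot place gene; requested density too high")

    # tRNA clusters in euchromatin
    if config.n_trna_clusters > 0 and config.n_trnas > 0:
        per = [config.n_trnas // config.n_trna_clusters] * config.n_trna_clusters
        for j in range(config.n_trnas % config.n_trna_clusters):
            per[j] += 1
        counter = 0
        aas = sorted(AA_TO_ANTICODONS)
        for ci, n_in_cluster in enumerate(per):
            if n_in_cluster == 0:
                continue
            spacing = rng.integers(*config.trna_spacing_range, size=n_in_cluster)
            span = int(n_in_cluster * config.trna_len + spacing.sum())
            pos = _sample_free(state, rng, chroms, "eu", span, config.max_attempts)
            if pos is None:
                raise PlacementError("cannot place tRNA cluster")
            chrom, p = pos
            cursor = p
            for gpos in range(n_in_cluster):
                aa = aas[rng.integers(len(aas))]
                ac = AA_TO_ANTICODONS[aa][rng.integers(len(AA_TO_ANTICODONS[aa]))]
                gene_seq = rng.integers(0, 4, size=config.trna_len, dtype=np.uint8)
                gene_seq[33:36] = _encode(ac)
                state.seqs[chrom][cursor : cursor + config.trna_len] = gene_seq
                strand = "+" if rng.random() < 0.5 else "-"
                state.trnas.append(
                    TRNAGene(
                        f"t{counter:04d}",
                        chrom,
                        cursor,
                        cursor + config.trna_len,
                        strand,
                        aa,
                        ac,
                        pseudo=False,
                        cluster=f"cl{ci:02d}",
                    )
                )
                counter += 1
                cursor += config.trna_len + int(spacing[gpos])

    # ancestral TE copies (shared, pre-divergence content)
    classes = sorted(config.ancestral_te_mixture)
    weights = np.array([config.ancestral_te_mixture[c] for c in classes])
    weights = weights / weights.sum()
    for i in range(config.n_ancestral_tes):
        klass = classes[rng.choice(len(classes), p=weights)]
        fams = TE_FAMILIES[klass]
        fam = fams[rng.integers(len(fams))]
        L = _lognormal_len(
            rng, config.te_len_median[klass], config.te_len_sigma[klass], 80,
            _CONSENSUS_LEN[klass],
        )
        compartment = "het" if rng.random() < config.te_het_fraction else "eu"
        pos = _sample_free(state, rng, chroms, compartment, L, config.max_attempts)
        if pos is None:
            logger.warning("skipping ancestral TE %d: no room", i)
            continue
        chrom, p = pos
        state.seqs[chrom][p : p + L] = lib.te_consensus[fam][-L:]
        strand = "+" if rng.random() < 0.5 else "-"
        state.repeats.append(Repeat(chrom, p, p + L, strand, fam, klass, f"anc_te{i:03d}"))

    return state


def _lognormal_len(rng, median: float, sigma: float, lo: int, hi: int) -> int:
    return int(np.clip(rng.lognormal(math.log(median), sigma), lo, hi))


def _sample_free(
    state: GenomeState,
    rng: np.random.Generator,
    chroms: list[str],
    compartment: str,
    length: int,
    attempts: int,
) -> tuple[str, int] | None:
    """Uniformly sample a start so [start, start+length) is feature-free."""
    for _ in range(attempts):
        chrom = chroms[rng.integers(len(chroms))]
        L = len(state.seqs[chrom])
        h = state.het_end[chrom]
        lo, hi = (0, h) if compartment == "het" else (h, L)
        gaps = [
            (s, e - length)
            for s, e in state.free_positions(chrom, lo, hi)
            if e - s >= length
        ]
        if not gaps:
            continue
        sizes = np.array([e - s + 1 for s, e in gaps], dtype=float)
        g = int(rng.choice(len(gaps), p=sizes / sizes.sum()))
        s, e = gaps[g]
        return chrom, int(rng.integers(s, e + 1))
    return None


# ---------------------------------------------------------------- evolution


class _Evolver:
    def __init__(self, config: SimConfig, phylogeny: Phylogeny):
        self.cfg = config
        self.phy = phylogeny
        self.lib = _build_library(config)
        self.events: list[PlantedEvent] = []
        self.counter = 0
        self.branch_order = list(phylogeny.branches)
        self.mb = config.genome_mb()

    def _rng(self, branch: str, key: str) -> np.random.Generator:
        bi = self.branch_order.index(branch) if branch in self.branch_order else 99
        ki = EVENT_TYPES.index(key) if key in EVENT_TYPES else {"order": 90, "subs": 91}[key]
        return _substream(self.cfg.seed, 200, bi, ki)

    def _next_id(self) -> str:
        self.counter += 1
        return f"E{self.counter:04d}"

    def evolve_branch(self, state: GenomeState, branch: str) -> None:
        cfg = self.cfg
        dur = self.phy.durations[branch]
        taxa = tuple(sorted(self.phy.descendants(branch)))
        plan: list[str] = []
        rngs = {}
        for etype in EVENT_TYPES:
            rngs[etype] = self._rng(branch, etype)
            lam = cfg.rate(branch, etype) * dur * self.mb
            n = int(rngs[etype].poisson(lam)) if lam > 0 else 0
            plan.extend([etype] * n)
        self._rng(branch, "order").shuffle(plan)
        for etype in plan:
            rng = rngs[etype]
            eid = self._next_id()
            try:
                ev = self._apply_event(state, rng, branch, taxa, etype, eid)
            except PlacementError as exc:
                logger.warning("skipped %s on %s: %s", etype, branch, exc)
                self.counter -= 1
                continue
            if ev is not None:
                self.events.append(ev)
            else:
                self.counter -= 1
        self._substitute(state, branch, dur)

    # ------------------------------------------------------ event handlers

    def _apply_event(self, state, rng, branch, taxa, etype, eid) -> PlantedEvent | None:
        if etype in _TE_CLASS_OF:
            return self._te_insert(state, rng, branch, taxa, etype, eid)
        handler = {
            "inversion": self._inversion,
            "tandem_dup": self._tandem_dup,
            "dispersed_dup": self._dispersed_dup,
            "satellite_change": self._satellite_change,
            "trna_dup": self._trna_dup,
            "trna_del": self._trna_del,
            "trna_anticodon": self._trna_anticodon,
            "intron_indel": self._intron_indel,
        }[etype]
        return handler(state, rng, branch, taxa, eid)

    def _te_insert(self, state, rng, branch, taxa, etype, eid):
        cfg = self.cfg
        klass = _TE_CLASS_OF[etype]
        fams = TE_FAMILIES[klass]
        fam = fams[rng.integers(len(fams))]
        L = _lognormal_len(
            rng, cfg.te_len_median[klass], cfg.te_len_sigma[klass], 80, _CONSENSUS_LEN[klass]
        )
        exonic_p = cfg.te_exonic_fraction.get(branch, cfg.te_exonic_default)
        exonic = rng.random() < exonic_p
        chroms = list(state.seqs)
        if exonic:
            pos = self._sample_exonic_site(state, rng)
            if pos is None:
                exonic = False
        if not exonic:
            compartment = "het" if rng.random() < cfg.te_het_fraction else "eu"
            got = _sample_free(state, rng, chroms, compartment, 1, cfg.max_attempts)
            if got is None:
                raise PlacementError("no TE insertion site")
            pos = got
        chrom, p = pos
        state.insert(chrom, p, self.lib.te_consensus[fam][-L:])
        strand = "+" if rng.random() < 0.5 else "-"
        state.repeats.append(Repeat(chrom, p, p + L, strand, fam, klass, eid, source_event=eid))
        state.tracked[eid] = (chrom, p, p + L)
        return PlantedEvent(
            eid, "te_insertion", branch, taxa, chrom, p, p + L,
            {"class": klass, "family": fam, "length": L, "exonic": bool(exonic)},
        )

    def _sample_exonic_site(self, state, rng):
        genes = [g for g in state.genes]
        if not genes:
            return None
        g = genes[rng.integers(len(genes))]
        xs, xe = g.exons[rng.integers(len(g.exons))]
        if xe - xs < 10:
            return None
        return g.chrom, int(rng.integers(xs + 3, xe - 3))

    def _pick_compartment(self, state, rng) -> tuple[str, int, int]:
        """Choose (chrom, lo, hi) weighted by het:eu multiplier for rearrangements."""
        opts, weights = [], []
        for chrom, arr in state.seqs.items():
            h = state.het_end[chrom]
            if h > 0:
                opts.append((chrom, 0, h))
                weights.append(h * self.cfg.het_eu_multiplier)
            if h < len(arr):
                opts.append((chrom, h, len(arr)))
                weights.append(len(arr) - h)
        w = np.array(weights, dtype=float)
        return opts[int(rng.choice(len(opts), p=w / w.sum()))]

    def _inversion(self, state, rng, branch, taxa, eid):
        cfg = self.cfg
        for _ in range(cfg.max_attempts):
            chrom, lo, hi = self._pick_compartment(state, rng)
            span = hi - lo
            if span < 4 * cfg.inversion_len_range[0]:
                continue
            L = int(rng.integers(cfg.inversion_len_range[0], min(cfg.inversion_len_range[1], span // 2)))
            a = int(rng.integers(lo, hi - L))
            b = a + L
            free_a = any(s <= a < e for s, e in state.free_positions(chrom, lo, hi))
            free_b = any(s <= b < e for s, e in state.free_positions(chrom, lo, hi))
            if not (free_a and free_b):
                continue
            if state.features_partially_overlapping(chrom, a, b):
                continue
            compartment = "het" if b <= state.het_end[chrom] else "eu"
            state.invert(chrom, a, b)
            state.tracked[eid] = (chrom, a, b)
            return PlantedEvent(
                eid, "inversion", branch, taxa, chrom, a, b,
                {"length": L, "compartment": compartment},
            )
        raise PlacementError("no inversion site")

    def _dup_source(self, state, rng, lo_len, hi_len, median=None, sigma=None):
        cfg = self.cfg
        for _ in range(cfg.max_attempts):
            if median is not None:
                L = _lognormal_len(rng, median, sigma, lo_len, hi_len)
            else:
                L = int(rng.integers(lo_len, hi_len))
            compartment = "het" if rng.random() < 0.15 else "eu"
            chroms = list(state.seqs)
            chrom = chroms[rng.integers(len(chroms))]
            h = state.het_end[chrom]
            lo, hi = (0, h) if compartment == "het" else (h, len(state.seqs[chrom]))
            if hi - lo < 3 * L:
                continue
            a = int(rng.integers(lo, hi - L))
            b = a + L
            if state.features_partially_overlapping(chrom, a, b):
                continue
            return chrom, a, b
        raise PlacementError("no duplication source")

    def _tandem_dup(self, state, rng, branch, taxa, eid):
        cfg = self.cfg
        chrom, a, b = self._dup_source(
            state, rng, *cfg.tandem_len_range, median=cfg.tandem_len_median,
            sigma=cfg.tandem_len_sigma,
        )
        payload = state.seqs[chrom][a:b].copy()
        state.insert(chrom, b, payload)
        state.tracked[eid] = (chrom, b, b + len(payload))
        return PlantedEvent(
            eid, "tandem_dup", branch, taxa, chrom, b, b + len(payload),
            {"src_start": a, "src_end": b, "length": len(payload), "copies": 2},
        )

    def _dispersed_dup(self, state, rng, branch, taxa, eid):
        cfg = self.cfg
        chrom, a, b = self._dup_source(state, rng, *cfg.dispersed_len_range)
        payload = state.seqs[chrom][a:b].copy()
        got = _sample_free(state, rng, list(state.seqs), "eu", 1, cfg.max_attempts)
        if got is None:
            raise PlacementError("no dispersed target site")
        tchrom, tpos = got
        if tchrom == chrom and abs(tpos - b) < 20_000:
            raise PlacementError("dispersed target too close to source")
        state.insert(tchrom, tpos, payload)
        state.tracked[eid] = (tchrom, tpos, tpos + len(payload))
        return PlantedEvent(
            eid, "dispersed_dup", branch, taxa, tchrom, tpos, tpos + len(payload),
            {"src_chrom": chrom, "src_start": a, "src_end": b, "length": len(payload),
             "copies": 2},
        )

    def _satellite_change(self, state, rng, branch, taxa, eid):
        sats = [r for r in state.repeats if r.klass == "satellite"]
        if not sats:
            raise PlacementError("no satellite arrays")
        arr = sats[rng.integers(len(sats))]
        mono = self.lib.sat_monomers.get(arr.family)
        if mono is None:
            raise PlacementError("unknown satellite family")
        m = len(mono)
        delta = int(rng.integers(*self.cfg.satellite_delta_range))
        expand = rng.random() < 0.5
        if not expand and arr.length < (delta + 2) * m:
            expand = True
        if expand:
            pos = arr.start + m  # inside the array so the annotation grows
            state.insert(arr.chrom, pos, np.tile(mono, delta))
            kind = "expansion"
            s, e = pos, pos + delta * m
        else:
            s, e = arr.start + m, arr.start + (delta + 1) * m
            state.delete(arr.chrom, s, e)
            kind = "contraction"
        state.tracked[eid] = (arr.chrom, arr.start, arr.end)
        return PlantedEvent(
            eid, "satellite_change", branch, taxa, arr.chrom, s, e,
            {"family": arr.family, "kind": kind, "delta_copies": delta},
        )

    def _trna_dup(self, state, rng, branch, taxa, eid):
        if not state.trnas:
            raise PlacementError("no tRNAs")
        t = state.trnas[rng.integers(len(state.trnas))]
        payload = state.seqs[t.chrom][t.start : t.end].copy()
        gap = int(rng.integers(40, 120))
        spacer = rng.integers(0, 4, size=gap, dtype=np.uint8)
        pos = t.end
        state.insert(t.chrom, pos, np.concatenate([spacer, payload]))
        new = t.copy()
        new.gene_id = f"{t.gene_id}.{eid}"
        new.start, new.end = pos + gap, pos + gap + (t.end - t.start)
        # the template's own interval was shifted only if it lay right of pos
        state.trnas.append(new)
        state.tracked[eid] = (t.chrom, new.start, new.end)
        return PlantedEvent(
            eid, "trna_change", branch, taxa, t.chrom, new.start, new.end,
            {"kind": "duplication", "template": t.gene_id, "gene": new.gene_id,
             "cluster": t.cluster},
        )

    def _trna_del(self, state, rng, branch, taxa, eid):
        if not state.trnas:
            raise PlacementError("no tRNAs")
        t = state.trnas[rng.integers(len(state.trnas))]
        chrom, s, e = t.chrom, t.start, t.end
        gid, cluster = t.gene_id, t.cluster
        state.delete(chrom, s, e)
        return PlantedEvent(
            eid, "trna_change", branch, taxa, chrom, s, s,
            {"kind": "deletion", "gene": gid, "cluster": cluster},
        )

    def _trna_anticodon(self, state, rng, branch, taxa, eid):
        candidates = [t for t in state.trnas if not t.pseudo]
        if not candidates:
            raise PlacementError("no tRNAs")
        t = candidates[rng.integers(len(candidates))]
        iso = rng.random() < self.cfg.isoacceptor_prob
        old_iso, old_ac = t.isotype, t.anticodon
        if iso:
            others = [a for a in AA_TO_ANTICODONS[t.isotype] if a != t.anticodon]
            if not others:
                iso = False
        if iso:
            new_ac = others[rng.integers(len(others))]
            new_iso = t.isotype
        else:
            aas = [a for a in sorted(AA_TO_ANTICODONS) if a != t.isotype]
            new_iso = aas[rng.integers(len(aas))]
            acs = AA_TO_ANTICODONS[new_iso]
            new_ac = acs[rng.integers(len(acs))]
        t.isotype, t.anticodon = new_iso, new_ac
        state.seqs[t.chrom][t.start + 33 : t.start + 36] = _encode(new_ac)
        state.tracked[eid] = (t.chrom, t.start, t.end)
        return PlantedEvent(
            eid, "trna_change", branch, taxa, t.chrom, t.start, t.end,
            {"kind": "anticodon", "gene": t.gene_id, "cluster": t.cluster,
             "old_isotype": old_iso, "old_anticodon": old_ac,
             "new_isotype": new_iso, "new_anticodon": new_ac,
             "shift_kind": "isoacceptor" if new_iso == old_iso else "alloacceptor"},
        )

    def _intron_indel(self, state, rng, branch, taxa, eid):
        cfg = self.cfg
        margin = 10
        genes = [g for g in state.genes if len(g.exons) > 1]
        if not genes:
            raise PlacementError("no introns")
        for _ in range(cfg.max_attempts):
            g = genes[rng.integers(len(genes))]
            introns = g.introns
            idx = int(rng.integers(len(introns)))
            s, e = introns[idx]
            if e - s < 3 * margin:
                continue
            insert = rng.random() < cfg.intron_indel_ins_prob
            L = _lognormal_len(rng, cfg.intron_indel_len_median, cfg.intron_indel_len_sigma,
                               3, 5000)
            if insert:
                pos = int(rng.integers(s + margin, e - margin))
                is_te = rng.random() < cfg.intron_te_prob
                if is_te:
                    klass = ("DNA", "LTR", "non-LTR")[rng.integers(3)]
                    fams = TE_FAMILIES[klass]
                    fam = fams[rng.integers(len(fams))]
                    L = max(L, 80)
                    payload = self.lib.te_consensus[fam][-L:]
                else:
                    payload = rng.integers(0, 4, size=L, dtype=np.uint8)
                state.insert(g.chrom, pos, payload)
                if is_te:
                    state.repeats.append(
                        Repeat(g.chrom, pos, pos + L, "+", fam, klass, eid, source_event=eid)
                    )
                state.tracked[eid] = (g.chrom, pos, pos + L)
                payload = {"kind": "insertion", "gene": g.gene_id, "intron_index": idx,
                           "length": int(L), "te": bool(is_te)}
                if is_te:
                    payload["class"] = klass
                    payload["family"] = fam
                return PlantedEvent(
                    eid, "intron_indel", branch, taxa, g.chrom, pos, pos + L, payload
                )
            # deletion bounded to keep the intron open
            L = min(L, e - s - 2 * margin)
            if L < 1:
                continue
            ds = int(rng.integers(s + margin, e - margin - L + 1))
            state.delete(g.chrom, ds, ds + L)
            return PlantedEvent(
                eid, "intron_indel", branch, taxa, g.chrom, ds, ds,
                {"kind": "deletion", "gene": g.gene_id, "intron_index": idx,
                 "length": int(L), "te": False},
            )
        raise PlacementError("no intron indel site")

    # ------------------------------------------------------ substitutions

    def _substitute(self, state: GenomeState, branch: str, dur: float) -> None:
        mu = self.cfg.substitution_rate
        if mu <= 0:
            return
        p = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * mu * dur))
        rng = self._rng(branch, "subs")
        protected: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in state.tracked.values():
            protected.setdefault(c, []).extend([(s - 5, s + 6), (e - 5, e + 6)])
        for chrom, arr in state.seqs.items():
            hits = np.nonzero(rng.random(len(arr)) < p)[0]
            if chrom in protected and len(hits):
                mask = np.ones(len(arr), dtype=bool)
                for s, e in protected[chrom]:
                    mask[max(s, 0) : max(e, 0)] = False
                hits = hits[mask[hits]]
            if len(hits):
                arr[hits] = (arr[hits] + rng.integers(1, 4, size=len(hits))) % 4


def evolve_tree(
    ancestor: GenomeState, phylogeny: Phylogeny, config: SimConfig
) -> tuple[dict[str, GenomeState], TruthTable]:
    """Evolve the ancestor along the tree; return per-taxon genomes + truth."""
    config.validate()
    ev = _Evolver(config, phylogeny)

    out: dict[str, GenomeState] = {}
    # outgroup: substitutions only, along its own (long) terminal branch
    og = ancestor.copy()
    og_dur = phylogeny.durations.get(phylogeny.outgroup, 6.0)
    ev._substitute(og, phylogeny.outgroup, og_dur)
    out[phylogeny.outgroup] = og

    mel_anc = ancestor.copy()
    ev.evolve_branch(mel_anc, "root")

    ref = mel_anc.copy()
    ev.evolve_branch(ref, phylogeny.reference)
    out[phylogeny.reference] = ref

    sim_anc = mel_anc.copy()
    ev.evolve_branch(sim_anc, "stem")

    for taxon in phylogeny.ingroup:
        st = sim_anc.copy()
        ev.evolve_branch(st, taxon)
        out[taxon] = st

    coords = {
        taxon: {eid: iv for eid, iv in state.tracked.items()}
        for taxon, state in out.items()
    }
    return out, TruthTable(events=ev.events, coords=coords)


# ---------------------------------------------------------------- output


def write_outputs(
    genomes: dict[str, GenomeState], truth: TruthTable, outdir: str | os.PathLike
) -> None:
    """Emit per-taxon FASTA/GFF3/BED plus the truth ledger TSVs."""
    os.makedirs(outdir, exist_ok=True)
    for taxon, state in genomes.items():
        gio.write_fasta(state.sequences(), os.path.join(outdir, f"{taxon}.fasta"))
        gio.write_gff3(state.genes, state.trnas, os.path.join(outdir, f"{taxon}.gff3"))
        gio.write_bed(
            gio.repeats_to_bed(state.repeats), os.path.join(outdir, f"{taxon}.repeats.bed")
        )
        comp_rows = [
            (chrom, s, e, label, 0, "+")
            for chrom, parts in state.compartments().items()
            for s, e, label in parts
        ]
        gio.write_bed(
            pd.DataFrame(comp_rows, columns=gio.BED_COLUMNS),
            os.path.join(outdir, f"{taxon}.compartments.bed"),
        )
        trna_rows = [
            (taxon, t.chrom, t.start, t.end, t.strand, t.isotype, t.anticodon,
             t.pseudo, t.cluster, t.gene_id)
            for t in state.trnas
        ]
        gio.write_tsv(
            pd.DataFrame(
                trna_rows,
                columns=["taxon", "chrom", "start", "end", "strand", "isotype",
                         "anticodon", "pseudo", "cluster", "gene_id"],
            ),
            os.path.join(outdir, f"{taxon}.trna.tsv"),
        )
    rows = [
        (e.event_id, e.etype, e.branch, ",".join(e.taxa), e.chrom, e.start, e.end,
         json.dumps(e.payload, sort_keys=True))
        for e in truth.events
    ]
    gio.write_tsv(
        pd.DataFrame(
            rows, columns=["event_id", "type", "branch", "taxon_list", "chrom",
                           "start", "end", "payload"]
        ),
        os.path.join(outdir, "truth.tsv"),
    )
    crows = [
        (taxon, eid, c, s, e)
        for taxon, m in truth.coords.items()
        for eid, (c, s, e) in sorted(m.items())
    ]
    gio.write_tsv(
        pd.DataFrame(crows, columns=["taxon", "event_id", "chrom", "start", "end"]),
        os.path.join(outdir, "truth_coords.tsv"),
    )
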