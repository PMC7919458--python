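"""End-to-end orchestration on simulated genomes, plus truth-ledger scoring.

These functions wire the simulator's outputs through the analysis modules
the way the comparative study is organized: all pairwise alignments use the
reference taxon's genome as the coordinate frame (except the TE-sharing
analysis, which is anchored on a focal ingroup taxon), inversion and
duplication calls are clustered across taxa and Dollo-polarized with the
outgroup, and every ``score_*`` function measures recovery of planted
events against the truth ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import dupes, introns, repeats, trna
from .models import TE_CLASSES, TruthTable, reciprocal_overlap
from .phylo import Phylogeny
from .rearrange import (
    RearrangementCall,
    blocks_to_permutation,
    call_inversions,
    classify_compartment,
    inversion_presence,
)
from .phylo import dollo_assign
from .simgen import GenomeState, SimConfig, evolve_tree, simulate_ancestor
from .synteny import AlignmentMap


@dataclass
class SimBundle:
    config: SimConfig
    phylogeny: Phylogeny
    ancestor: GenomeState
    genomes: dict[str, GenomeState]
    truth: TruthTable
    sequences: dict[str, dict[str, str]] = field(default_factory=dict)

    def seqs(self, taxon: str) -> dict[str, str]:
        if taxon not in self.sequences:
            self.sequences[taxon] = self.genomes[taxon].sequences()
        return self.sequences[taxon]


def simulate(config: SimConfig, phylogeny: Phylogeny | None = None) -> SimBundle:
    phy = phylogeny or Phylogeny()
    ancestor = simulate_ancestor(config)
    genomes, truth = evolve_tree(ancestor, phy, config)
    return SimBundle(config, phy, ancestor, genomes, truth)


def anticodon_shift_scenario(seed: int) -> SimBundle:
    """A tRNA-focused replicate: dense clusters, anticodon shifts the only
    cluster mutations, no structural noise.  Used to accumulate enough
    unambiguous shift events for stable accuracy estimates."""
    cfg = SimConfig(
        seed=seed,
        chrom_lengths={"chr2": 400_000},
        het_fraction=0.2,
        n_genes=10,
        n_trnas=40,
        n_trna_clusters=10,
        n_satellites=0,
        n_ancestral_tes=0,
        rates={"trna_anticodon": 1.2},
        branch_rates={},
    )
    return simulate(cfg)


def intron_effect_scenario(seed: int, n_genes: int = 150) -> SimBundle:
    """Insertion-only intron indels planted on the reference branch: the
    planted mean length shift is recoverable exactly from the truth ledger."""
    cfg = SimConfig(
        seed=seed,
        chrom_lengths={"chr2": 1_500_000},
        het_fraction=0.2,
        n_genes=n_genes,
        n_trnas=0,
        n_trna_clusters=0,
        n_satellites=0,
        n_ancestral_tes=0,
        rates={},
        branch_rates={"mel": {"intron_indel": 40.0}},
        intron_indel_ins_prob=1.0,
        intron_indel_len_median=500.0,
        intron_indel_len_sigma=0.1,
        intron_te_prob=0.3,
    )
    return simulate(cfg)


def reference_maps(
    bundle: SimBundle, k: int = 21, max_gap: int = 20_000, min_block: int = 1_000
) -> dict[str, AlignmentMap]:
    """reference-taxon -> taxon alignment maps for ingroup trio + outgroup."""
    phy = bundle.phylogeny
    ref = bundle.seqs(phy.reference)
    out = {}
    for taxon in (*phy.ingroup, phy.outgroup):
        out[taxon] = AlignmentMap.build(
            ref, bundle.seqs(taxon), k=k, max_gap=max_gap, min_block=min_block,
            ref_name=phy.reference, qry_name=taxon,
        )
    return out


def focal_maps(
    bundle: SimBundle, focal: str, k: int = 21, max_gap: int = 20_000,
    min_block: int = 1_000,
) -> dict[str, AlignmentMap]:
    """focal-taxon -> partner maps for the TE sharing analysis."""
    phy = bundle.phylogeny
    partners = [t for t in phy.ingroup if t != focal] + [phy.reference]
    return {
        t: AlignmentMap.build(
            bundle.seqs(focal), bundle.seqs(t), k=k, max_gap=max_gap,
            min_block=min_block, ref_name=focal, qry_name=t,
        )
        for t in partners
    }


# ------------------------------------------------------------- inversions

@dataclass
class InversionCluster:
    chrom: str
    start: int  # reference-taxon coordinates (union over member calls)
    end: int
    taxa_called: tuple[str, ...]
    member_intervals: list[tuple[int, int]] = field(default_factory=list)
    branch: str | None = None
    compartment: str | None = None


def inversion_analysis(
    bundle: SimBundle, maps: dict[str, AlignmentMap], min_reciprocal: float = 0.5
) -> list[InversionCluster]:
    """Per-taxon inversion calls, clustered in reference coordinates and
    Dollo-polarized; compartment from the reference taxon's annotation."""
    phy = bundle.phylogeny
    clusters: list[InversionCluster] = []
    for taxon, amap in maps.items():
        perm = blocks_to_permutation(amap)
        for call in call_inversions(perm):
            hit = None
            for cl in clusters:
                if cl.chrom == call.chrom and reciprocal_overlap(
                    (cl.start, cl.end), (call.start, call.end)
                ) >= min_reciprocal:
                    hit = cl
                    break
            if hit is None:
                clusters.append(
                    InversionCluster(
                        call.chrom, call.start, call.end, (taxon,),
                        member_intervals=[(call.start, call.end)],
                    )
                )
            else:
                hit.start = min(hit.start, call.start)
                hit.end = max(hit.end, call.end)
                hit.member_intervals.append((call.start, call.end))
                if taxon not in hit.taxa_called:
                    hit.taxa_called = (*hit.taxa_called, taxon)
    ref_comp = bundle.genomes[phy.reference].compartments()
    for cl in clusters:
        call = RearrangementCall("inversion", cl.chrom, cl.start, cl.end)
        states = inversion_presence(call, maps, phy.reference)
        cl.branch = dollo_assign(states, phy)
        cl.compartment = classify_compartment(call, ref_comp)
    return clusters


def score_inversions(
    clusters: list[InversionCluster],
    bundle: SimBundle,
    maps: dict[str, AlignmentMap],
    breakpoint_tol: int,
    min_reciprocal: float = 0.5,
) -> dict:
    """Recall / branch accuracy / breakpoint error vs planted inversions.

    Each planted inversion is located in reference coordinates (directly
    for events the reference carries; via back-projection from a carrier
    taxon otherwise).  Events whose reference-frame footprints overlap
    another planted inversion are ambiguous and excluded from the branch
    accuracy denominator.
    """
    phy = bundle.phylogeny
    ref = phy.reference
    targets = []  # (event, chrom, start, end) in reference coordinates
    for ev in bundle.truth.by_type("inversion"):
        if ref in ev.taxa:
            iv = bundle.truth.coords[ref].get(ev.event_id)
            if iv:
                targets.append((ev, *iv))
            continue
        carrier = next((t for t in ev.taxa if t in maps), None)
        if carrier is None:
            continue
        iv = bundle.truth.coords[carrier].get(ev.event_id)
        if not iv:
            continue
        chrom, s, e = iv
        images = maps[carrier].invert().project_interval(chrom, s, e)
        covered = sum(im["covered_ref"] for im in images)
        if covered < 0.5 * (e - s):
            continue
        qs = min(im["qry_start"] for im in images)
        qe = max(im["qry_end"] for im in images)
        targets.append((ev, images[0]["qry_chrom"], qs, qe))

    # ambiguity: overlapping planted inversions cannot be scored separately
    unambiguous = []
    for i, (ev, chrom, s, e) in enumerate(targets):
        clash = any(
            j != i and c2 == chrom and min(e, e2) > max(s, s2)
            for j, (_, c2, s2, e2) in enumerate(targets)
        )
        if not clash:
            unambiguous.append((ev, chrom, s, e))

    recovered = 0
    branch_ok = 0
    bp_errors = []
    for ev, chrom, s, e in unambiguous:
        match = None
        for cl in clusters:
            if cl.chrom == chrom and reciprocal_overlap(
                (cl.start, cl.end), (s, e)
            ) >= min_reciprocal:
                match = cl
                break
        if match is None:
            continue
        recovered += 1
        err = min(
            max(abs(cs - s), abs(ce - e))
            for cs, ce in (match.member_intervals or [(match.start, match.end)])
        )
        bp_errors.append(err)
        if match.branch == ev.branch:
            branch_ok += 1
    n = len(unambiguous)
    return {
        "n_planted": len(targets),
        "n_unambiguous": n,
        "recall": recovered / n if n else float("nan"),
        "branch_accuracy": branch_ok / recovered if recovered else float("nan"),
        "max_breakpoint_error": max(bp_errors) if bp_errors else 0,
        "breakpoint_within_tol": (
            sum(1 for x in bp_errors if x <= breakpoint_tol) / len(bp_errors)
            if bp_errors
            else float("nan")
        ),
    }


# ------------------------------------------------------------- repeats

def te_branch_analysis(bundle: SimBundle, focal: str | None = None, **map_kw) -> dict:
    """Fig-4-style sharing analysis anchored on a focal ingroup taxon."""
    phy = bundle.phylogeny
    focal = focal or phy.ingroup[1]
    fmaps = focal_maps(bundle, focal, **map_kw)
    sisters = tuple(t for t in phy.ingroup if t != focal)
    focal_state = bundle.genomes[focal]
    focal_reps = repeats.repeats_frame(focal_state.repeats)
    focal_reps = focal_reps[focal_reps["klass"].isin(TE_CLASSES)]
    focal_reps = repeats.euchromatic_subset(focal_reps, focal_state.compartments())
    # containment is evaluated per species pair (each pair has its own map);
    # an element outside the reference pair's blocks can still be stem-shared
    shared_with: dict[str, set] = {}
    for partner, amap in fmaps.items():
        contained = repeats.contained_repeats(focal_reps, amap, side="ref")
        partner_state = bundle.genomes[partner]
        partner_reps = repeats.repeats_frame(partner_state.repeats)
        partner_reps = partner_reps[partner_reps["klass"].isin(TE_CLASSES)]
        shared = repeats.shared_repeat_content(contained, partner_reps, amap)
        shared_with[partner] = set(shared["a_id"])
    assignment = repeats.assign_branches(
        focal_reps, shared_with, sisters, phy.reference
    )
    composition = repeats.composition_summary(assignment, focal_reps)
    exonic = repeats.exonic_overlap(focal_reps, assignment, focal_state.genes)
    return {
        "focal": focal,
        "elements": focal_reps,
        "assignment": assignment,
        "composition": composition,
        "exonic": exonic,
        "shared_with": shared_with,
    }


def planted_class_mixture(
    bundle: SimBundle, branch: str, focal: str | None = None, eu_only: bool = True
) -> dict[str, float]:
    """bp proportions by TE class among TEs planted on a branch (truth side).

    With ``eu_only`` (matching the sharing analysis' euchromatic scope) only
    events whose footprint midpoint is euchromatic in the focal taxon count.
    """
    focal = focal or bundle.phylogeny.ingroup[1]
    comp = bundle.genomes[focal].compartments()
    bp = {k: 0.0 for k in TE_CLASSES}
    for ev in bundle.truth.events:
        if ev.branch != branch:
            continue
        if ev.etype == "te_insertion":
            klass = ev.payload["class"]
        elif ev.etype == "intron_indel" and ev.payload.get("te"):
            klass = ev.payload["class"]
        else:
            continue
        iv = bundle.truth.coords.get(focal, {}).get(ev.event_id)
        if iv is None:
            continue
        chrom, s, e = iv
        if eu_only:
            mid = (s + e) // 2
            label = next(
                (lab for cs, ce, lab in comp.get(chrom, []) if cs <= mid < ce), None
            )
            if label != "eu":
                continue
        bp[klass] += e - s
    total = sum(bp.values())
    return {k: v / total if total else 0.0 for k, v in bp.items()}


def score_te_mixture(analysis: dict, bundle: SimBundle, category: str = "stem") -> dict:
    """Max |recovered - planted| class proportion (percentage points)."""
    recovered = repeats.class_proportions(analysis["composition"], category)
    planted = planted_class_mixture(bundle, category, focal=analysis["focal"])
    diffs = {k: abs(recovered[k] - planted[k]) for k in TE_CLASSES}
    return {
        "recovered": recovered,
        "planted": planted,
        "max_abs_diff": max(diffs.values()) if diffs else float("nan"),
    }


# ------------------------------------------------------------- duplications

def duplication_analysis(
    bundle: SimBundle, maps: dict[str, AlignmentMap], **detect_kw
) -> dict:
    """Detect per-taxon duplications vs the reference state and polarize."""
    phy = bundle.phylogeny
    ref_state = bundle.genomes[phy.reference]
    ref_reps = repeats.repeats_frame(ref_state.repeats)
    calls_by_taxon = {}
    for taxon in (*phy.ingroup, phy.outgroup):
        qry_reps = repeats.repeats_frame(bundle.genomes[taxon].repeats)
        calls_by_taxon[taxon] = dupes.detect_duplications(
            maps[taxon],
            bundle.seqs(phy.reference),
            bundle.seqs(taxon),
            taxon=taxon,
            ref_repeats=ref_reps,
            qry_repeats=qry_reps,
            **detect_kw,
        )
    outgroup_calls = calls_by_taxon.pop(phy.outgroup)
    polar = dupes.polarize_duplications(calls_by_taxon, outgroup_calls, phy)
    for calls in calls_by_taxon.values():
        for c in calls:
            dupes.classify_overlap(c, ref_state.genes)
    return {"calls_by_taxon": calls_by_taxon, "outgroup_calls": outgroup_calls,
            "polarization": polar}


def score_tandem_recall(
    analysis: dict, bundle: SimBundle, min_len: int = 1_000, breakpoint_tol: int = 20_021
) -> dict:
    """Recall of planted tandem duplications >= min_len, per carrying taxon."""
    phy = bundle.phylogeny
    n_target = 0
    n_hit = 0
    bp_errors = []
    for ev in bundle.truth.by_type("tandem_dup"):
        if ev.payload["length"] < min_len or phy.reference in ev.taxa:
            continue
        carriers = [t for t in ev.taxa if t in analysis["calls_by_taxon"]]
        for taxon in carriers:
            iv = bundle.truth.coords[taxon].get(ev.event_id)
            if not iv:
                continue
            chrom, s, e = iv
            n_target += 1
            best = None
            for call in analysis["calls_by_taxon"][taxon]:
                for qchrom, qs, qe in call.qry_copies:
                    if qchrom != chrom:
                        continue
                    ov = min(qe, e) - max(qs, s)
                    if ov >= 0.5 * (e - s):
                        err = max(abs(qs - s), abs(qe - e))
                        if best is None or err < best:
                            best = err
            if best is not None:
                n_hit += 1
                bp_errors.append(best)
    return {
        "n_targets": n_target,
        "recall": n_hit / n_target if n_target else float("nan"),
        "max_breakpoint_error": max(bp_errors) if bp_errors else 0,
        "breakpoint_within_tol": (
            sum(1 for x in bp_errors if x <= breakpoint_tol) / len(bp_errors)
            if bp_errors
            else float("nan")
        ),
    }


# ------------------------------------------------------------- tRNA

def trna_frame(bundle: SimBundle) -> pd.DataFrame:
    rows = []
    for taxon, state in bundle.genomes.items():
        for t in state.trnas:
            rows.append(
                (taxon, t.chrom, t.start, t.end, t.strand, t.isotype, t.anticodon,
                 t.pseudo, t.cluster, t.gene_id)
            )
    return pd.DataFrame(rows, columns=trna.TRNA_COLUMNS)


def trna_analysis(bundle: SimBundle, maps: dict | None = None) -> dict:
    df = trna_frame(bundle)
    phy = bundle.phylogeny
    chroms = sorted(df["chrom"].unique())
    columns = []
    for chrom in chroms:
        columns.extend(trna.call_orthology(df, phy, chrom, maps=maps))
    return {"frame": df, "columns": columns, "summary": trna.orthology_summary(columns)}


def score_anticodon_shifts(analysis: dict, bundle: SimBundle) -> dict:
    """Kind + branch accuracy for planted anticodon shifts.

    Unambiguous = the shift's tRNA cluster was hit by exactly one tRNA
    event across the whole tree; multiple events in one cluster (a gain
    next to a shift, say) can make the positional alignment itself
    ambiguous, which no caller could resolve from the end state.
    """
    df = analysis["frame"]
    hits_per_cluster: dict[str, int] = {}
    shift_events = []
    for ev in bundle.truth.by_type("trna_change"):
        cluster = ev.payload.get("cluster", "")
        hits_per_cluster[cluster] = hits_per_cluster.get(cluster, 0) + 1
        if ev.payload.get("kind") == "anticodon":
            shift_events.append(ev)
    unamb = [
        ev for ev in shift_events if hits_per_cluster[ev.payload.get("cluster", "")] == 1
    ]
    n_ok_kind = 0
    n_ok_branch = 0
    n_found = 0
    for ev in unamb:
        gene = ev.payload["gene"]
        col = None
        for c in analysis["columns"]:
            for taxon, i in c.members.items():
                if i is not None and df.loc[i, "gene_id"] == gene and taxon in ev.taxa:
                    col = c
                    break
            if col:
                break
        if col is None or col.shift is None:
            continue
        n_found += 1
        if col.shift.kind == ev.payload["shift_kind"]:
            n_ok_kind += 1
        if col.shift.branch == ev.branch:
            n_ok_branch += 1
    n = len(unamb)
    return {
        "n_planted": len(shift_events),
        "n_unambiguous": n,
        "n_recovered": n_found,
        "recall": n_found / n if n else float("nan"),
        "kind_accuracy": n_ok_kind / n_found if n_found else float("nan"),
        "branch_accuracy": n_ok_branch / n_found if n_found else float("nan"),
    }


# ------------------------------------------------------------- introns

def intron_analysis(bundle: SimBundle) -> dict:
    phy = bundle.phylogeny
    taxa = [*phy.ingroup, phy.reference, phy.outgroup]
    genes_by_taxon = {
        t: {g.gene_id: g for g in bundle.genomes[t].genes} for t in taxa
    }
    conserved = introns.match_conserved_introns(genes_by_taxon, phy.reference)
    repeats_by_taxon = {
        t: repeats.repeats_frame(bundle.genomes[t].repeats) for t in taxa
    }
    introns.classify_introns(conserved, repeats_by_taxon)
    table = introns.comparison_table(conserved, phy.reference, list(phy.ingroup))
    return {"conserved": conserved, "table": table}


def planted_intron_shift(bundle: SimBundle, branch: str, conserved) -> float:
    """Truth mean length change (bp per conserved intron) planted on a branch."""
    keyset = {(ci.gene_id, ci.intron_index) for ci in conserved}
    total = 0.0
    for ev in bundle.truth.events:
        if ev.etype != "intron_indel" or ev.branch != branch:
            continue
        key = (ev.payload["gene"], ev.payload["intron_index"])
        if key not in keyset:
            continue
        sign = 1 if ev.payload["kind"] == "insertion" else -1
        total += sign * ev.payload["length"]
    return total / len(keyset) if keyset else float("nan")
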