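"""Readers and writers for FASTA, GFF3, BED, PAF and TSV.

Internal coordinates are 0-based half-open; GFF3 is written 1-based closed
per the standard, BED stays 0-based half-open.  The BED dialect used for
repeats carries the family in the name column and the repeat class in a
seventh column.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Gene, Repeat, TRNAGene

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def gff_to_internal(start_1based: int) -> int:
    """GFF3 1-based start -> internal 0-based (ends are already half-open-compatible)."""
    return start_1based - 1


def internal_to_gff(start_0based: int) -> int:
    return start_0based + 1


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: Iterable[Gene], trnas: Iterable[TRNAGene], path: str | os.PathLike) -> None:
    """Emit gene/mRNA/exon/CDS features plus tRNA genes with isotype attributes."""
    lines = ["##gff-version 3"]
    for g in genes:
        s, e = g.span
        gid = g.gene_id
        lines.append(_gff_line(g.chrom, "gene", s, e, g.strand, f"ID={gid}"))
        lines.append(_gff_line(g.chrom, "mRNA", s, e, g.strand, f"ID={gid}.t1;Parent={gid}"))
        for i, (xs, xe) in enumerate(g.exons, 1):
            lines.append(
                _gff_line(g.chrom, "exon", xs, xe, g.strand, f"ID={gid}.e{i};Parent={gid}.t1")
            )
        cs, ce = g.cds
        lines.append(_gff_line(g.chrom, "CDS", cs, ce, g.strand, f"ID={gid}.cds;Parent={gid}.t1"))
    for t in trnas:
        attrs = (
            f"ID={t.gene_id};isotype={t.isotype};anticodon={t.anticodon};"
            f"pseudo={'true' if t.pseudo else 'false'};cluster={t.cluster}"
        )
        lines.append(_gff_line(t.chrom, "tRNA", t.start, t.end, t.strand, attrs))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _gff_line(chrom: str, ftype: str, start: int, end: int, strand: str, attrs: str) -> str:
    return "\t".join(
        [chrom, "genostruct", ftype, str(internal_to_gff(start)), str(end), ".", strand, ".", attrs]
    )


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | os.PathLike) -> tuple[list[Gene], list[TRNAGene]]:
    """Read the gene/tRNA dialect written by :func:`write_gff3`."""
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, tuple[int, int]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene id -> (chrom, strand)
    order: list[str] = []
    trnas: list[TRNAGene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, s1, e1, _, strand, _, attr_field = fields
            start, end = gff_to_internal(int(s1)), int(e1)
            attrs = _parse_attrs(attr_field)
            if ftype == "gene":
                meta[attrs["ID"]] = (chrom, strand)
                order.append(attrs["ID"])
            elif ftype == "exon":
                gid = attrs["Parent"].rsplit(".t1", 1)[0]
                exons.setdefault(gid, []).append((start, end))
            elif ftype == "CDS":
                gid = attrs["Parent"].rsplit(".t1", 1)[0]
                cds[gid] = (start, end)
            elif ftype == "tRNA":
                trnas.append(
                    TRNAGene(
                        gene_id=attrs["ID"],
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        isotype=attrs.get("isotype", "X"),
                        anticodon=attrs.get("anticodon", "NNN"),
                        pseudo=attrs.get("pseudo", "false") == "true",
                        cluster=attrs.get("cluster", ""),
                    )
                )
    genes = []
    for gid in order:
        chrom, strand = meta[gid]
        genes.append(Gene(gid, chrom, strand, sorted(exons[gid]), cds[gid]))
    return genes, trnas


# ---------------------------------------------------------------- BED

def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in BED_COLUMNS]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike, extra_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    names = BED_COLUMNS + list(extra_columns)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def repeats_to_bed(repeats: Iterable[Repeat]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.start, r.end, r.family, 0, r.strand, r.klass, r.repeat_id)
        for r in repeats
    ]
    return pd.DataFrame(rows, columns=BED_COLUMNS + ["klass", "repeat_id"])


def bed_to_repeats(df: pd.DataFrame) -> list[Repeat]:
    return [
        Repeat(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            family=row["name"],
            klass=row.get("klass", "DNA"),
            repeat_id=str(row.get("repeat_id", i)),
        )
        for i, row in df.iterrows()
    ]


# ---------------------------------------------------------------- PAF / TSV

def write_paf(amap, path: str | os.PathLike) -> None:
    """Blocks as PAF records (residue matches approximated by anchored bp)."""
    lines = []
    for b in amap.blocks:
        lines.append(
            "\t".join(
                str(v)
                for v in [
                    amap.qry_name + "." + b.qry_chrom,
                    amap.qry_lengths[b.qry_chrom],
                    b.qry_start,
                    b.qry_end,
                    "+" if b.orient > 0 else "-",
                    amap.ref_name + "." + b.ref_chrom,
                    amap.ref_lengths[b.ref_chrom],
                    b.ref_start,
                    b.ref_end,
                    b.anchored_bp,
                    max(b.ref_end - b.ref_start, b.qry_end - b.qry_start),
                    60,
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
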