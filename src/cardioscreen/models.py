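"""Gene models and genomic file I/O.

Coordinates are 0-based half-open everywhere inside the package; GTF import
and export translate to/from the 1-based inclusive convention at the
boundary.  A :class:`GeneModel` holds the transcript structures (exon and
CDS intervals) that guide design and ChIP scoring operate on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

Interval = tuple[int, int]


class ModelError(ValueError):
    """Raised when a gene model violates its structural invariants."""


@dataclass(frozen=True)
class Transcript:
    """One transcript isoform: sorted exon intervals and the CDS within them."""

    transcript_id: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts on a strand of a chromosome.

    Invariants (checked by :meth:`validate`): exons within a transcript are
    sorted and non-overlapping; every CDS interval lies within an exon; each
    transcript's total CDS length is positive and divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    @property
    def span(self) -> Interval:
        """First transcription start to last transcription end, all isoforms."""
        starts = [t.exons[0][0] for t in self.transcripts]
        ends = [t.exons[-1][1] for t in self.transcripts]
        return (min(starts), max(ends))

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.transcripts:
            raise ModelError(f"{self.gene_id}: no transcripts")
        for t in self.transcripts:
            if not t.exons:
                raise ModelError(f"{t.transcript_id}: no exons")
            prev_end = -1
            for s, e in t.exons:
                if e <= s:
                    raise ModelError(f"{t.transcript_id}: empty exon {s}-{e}")
                if s < prev_end:
                    raise ModelError(
                        f"{t.transcript_id}: exons unsorted or overlapping"
                    )
                prev_end = e
            for cs, ce in t.cds:
                if not any(s <= cs and ce <= e for s, e in t.exons):
                    raise ModelError(
                        f"{t.transcript_id}: CDS {cs}-{ce} outside exons"
                    )
            if t.cds_length <= 0:
                raise ModelError(f"{t.transcript_id}: zero CDS")
            if t.cds_length % 3 != 0:
                raise ModelError(
                    f"{t.transcript_id}: CDS length {t.cds_length} not a multiple of 3"
                )


def _intersect_two(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def constitutive_exons(gene: GeneModel) -> list[Interval]:
    """Genomic bases present in every transcript's exon set, as maximal intervals.

    A guide targeting these intervals disrupts every annotated isoform.
    """
    if not gene.transcripts:
        raise ModelError(f"{gene.gene_id}: no transcripts")
    common: list[Interval] = list(gene.transcripts[0].exons)
    for t in gene.transcripts[1:]:
        common = _intersect_two(common, t.exons)
        if not common:
            return []
    # merge adjacent pieces into maximal intervals
    merged: list[Interval] = []
    for s, e in common:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def gene_lengths(genes: Iterable[GeneModel]) -> pd.Series:
    """Span length per gene (first TSS to last TSE across isoforms), in bp."""
    return pd.Series({g.gene_id: g.length for g in genes}, name="gene_length")


# ---------------------------------------------------------------------------
# FASTA / GTF I/O


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_gtf(path: str | Path, genes: Iterable[GeneModel], source: str = "cardioscreen") -> None:
    """Emit gene/transcript/exon/CDS features, 1-based inclusive coordinates."""

    def line(chrom, feat, s, e, strand, attrs):
        attr = " ".join(f'{k} "{v}";' for k, v in attrs)
        return f"{chrom}\t{source}\t{feat}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attr}\n"

    with open(path, "w") as fh:
        for g in genes:
            gs, ge = g.span
            fh.write(line(g.chrom, "gene", gs, ge, g.strand, [("gene_id", g.gene_id)]))
            for t in g.transcripts:
                ts, te = t.exons[0][0], t.exons[-1][1]
                attrs = [("gene_id", g.gene_id), ("transcript_id", t.transcript_id)]
                fh.write(line(g.chrom, "transcript", ts, te, g.strand, attrs))
                for s, e in t.exons:
                    fh.write(line(g.chrom, "exon", s, e, g.strand, attrs))
                for s, e in t.cds:
                    fh.write(line(g.chrom, "CDS", s, e, g.strand, attrs))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF into GeneModels (via gffutils, in-memory database)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gfeat in db.features_of_type("gene"):
        gene_id = gfeat.attributes["gene_id"][0]
        transcripts = []
        for tfeat in db.children(gfeat, featuretype="transcript", order_by="start"):
            tid = tfeat.attributes["transcript_id"][0]
            exons = tuple(
                sorted(
                    (f.start - 1, f.end)
                    for f in db.children(tfeat, featuretype="exon")
                )
            )
            cds = tuple(
                sorted(
                    (f.start - 1, f.end)
                    for f in db.children(tfeat, featuretype="CDS")
                )
            )
            transcripts.append(Transcript(tid, exons, cds))
        if not transcripts:
            warnings.warn(f"gene {gene_id} has no transcripts; skipped")
            continue
        genes.append(GeneModel(gene_id, gfeat.seqid, gfeat.strand, tuple(transcripts)))
    return genes
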