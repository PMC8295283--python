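"""Pooled sgRNA library design.

Implements the screen's library-design pipeline for SpCas9 (NGG PAM, blunt
cut 3 bp 5' of the PAM): candidate-site discovery within exonic CDS,
constitutive-exon and CDS-position filters, off-target mismatch profiling
(0/1/2 mismatches genome-wide), microhomology-mediated out-of-frame
scoring, a five-tier fallback selection cascade, and construction of 80-nt
synthesis oligos with SapI cloning cassettes.

The five selection rules, applied in order until six guides are found:

  tier 1: constitutive exon, CDS 5-50%,  mismatch profile (1,0,0), OOF > 60
  tier 2: constitutive exon, CDS 5-80%,  profile (1,N,N),          OOF > 60
  tier 3: any exon,          CDS 5-80%,  profile (1,N,N),          OOF > 60
  tier 4: any exon,          CDS 5-80%,  profile (N,N,N),          OOF > 60
  tier 5: any exon,          any CDS,    profile (N,N,N),          any OOF

where the "1" in a profile is the on-target site itself and N leaves the
count unconstrained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, constitutive_exons

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SPACER_LEN = 20
#: SapI recognition sequence (cuts 1 nt downstream, 3-nt 5' overhang).
SAPI_SITE = "GCTCTTC"
SAPI_SITE_RC = "GAAGAGC"

# Fixed oligo scaffold pieces.  Layout (5'->3'):
#   LEFT_PAD  GCTCTTC  N  ACC  [G]spacer  AAC  N  GAAGAGC  RIGHT_PAD
# SapI digestion releases ACC+[G]spacer on the top strand with defined
# 3-nt overhangs for seamless ligation into the expression vector.
_LEFT_PAD = "TATCTTGTGGAAAGGACGA"
_RIGHT_PAD = "CGGTGTTTCGTCCTTTCCA"
_LEFT_SPACER_N = "A"
_RIGHT_SPACER_N = "A"
OVERHANG_LEFT = "ACC"
OVERHANG_RIGHT = "AAC"
OLIGO_LEN = 80


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class DesignError(ValueError):
    pass


@dataclass
class GuideSite:
    """A candidate protospacer with its scoring annotations.

    ``cut_pos`` is the forward-strand coordinate of the blunt-cut boundary
    (between protospacer positions 17 and 18, i.e. 3 bp 5' of the PAM); the
    cut falls between genomic bases ``cut_pos - 1`` and ``cut_pos``.
    """

    gene_id: str
    spacer: str
    pam: str
    chrom: str
    strand: str
    start: int  # protospacer interval, forward strand, 0-based half-open
    end: int
    cut_pos: int
    cds_percent: Optional[float] = None
    constitutive: bool = False
    mm_counts: Optional[tuple[int, int, int]] = None
    oof_score: Optional[float] = None
    oof_no_microhomology: bool = False


@dataclass(frozen=True)
class SelectionRule:
    tier: int
    require_constitutive: bool
    cds_min: Optional[float]
    cds_max: Optional[float]
    mm_profile: tuple[Optional[int], Optional[int], Optional[int]]
    oof_min: Optional[float]

    def admits(self, site: GuideSite) -> bool:
        if self.require_constitutive and not site.constitutive:
            return False
        if self.cds_min is not None:
            if site.cds_percent is None:
                return False
            if not (self.cds_min <= site.cds_percent <= self.cds_max):
                return False
        if site.mm_counts is not None:
            for want, have in zip(self.mm_profile, site.mm_counts):
                if want is not None and have != want:
                    return False
        if self.oof_min is not None:
            if site.oof_score is None or not (site.oof_score > self.oof_min):
                return False
        return True


DEFAULT_RULES: tuple[SelectionRule, ...] = (
    SelectionRule(1, True, 5.0, 50.0, (1, 0, 0), 60.0),
    SelectionRule(2, True, 5.0, 80.0, (1, None, None), 60.0),
    SelectionRule(3, False, 5.0, 80.0, (1, None, None), 60.0),
    SelectionRule(4, False, 5.0, 80.0, (None, None, None), 60.0),
    SelectionRule(5, False, None, None, (None, None, None), None),
)


@dataclass
class GuideRecord:
    site: GuideSite
    tier: int
    oligo: str

    @property
    def guide_id(self) -> str:
        return f"{self.site.gene_id}_g{self.site.cut_pos}_{self.site.strand}"


@dataclass
class ControlGuide:
    guide_id: str
    spacer: str
    oligo: str


@dataclass
class GuideLibrary:
    """A designed library: targeting guides plus non-targeting controls."""

    guides: list[GuideRecord]
    controls: list[ControlGuide]
    genes_targeted: int
    undesignable: list[str] = field(default_factory=list)
    tier_counts: dict[int, int] = field(default_factory=dict)

    def spacer_map(self) -> dict[str, str]:
        """spacer -> guide id, raising on duplicate spacers."""
        out: dict[str, str] = {}
        for gid, spacer in self.iter_spacers():
            if spacer in out:
                raise DesignError(f"duplicate spacer {spacer} ({out[spacer]}, {gid})")
            out[spacer] = gid
        return out

    def iter_spacers(self):
        for rec in self.guides:
            yield rec.guide_id, rec.site.spacer
        for ctl in self.controls:
            yield ctl.guide_id, ctl.spacer

    def guide_ids(self) -> list[str]:
        return [gid for gid, _ in self.iter_spacers()]

    def gene_map(self) -> pd.Series:
        """guide id -> gene id; controls map to NA (non-targeting)."""
        m = {rec.guide_id: rec.site.gene_id for rec in self.guides}
        m.update({ctl.guide_id: None for ctl in self.controls})
        return pd.Series(m, dtype=object)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.guides:
            s = rec.site
            rows.append(
                dict(
                    guide_id=rec.guide_id,
                    gene_id=s.gene_id,
                    spacer=s.spacer,
                    chrom=s.chrom,
                    start=s.start,
                    end=s.end,
                    strand=s.strand,
                    tier=rec.tier,
                    n0=s.mm_counts[0] if s.mm_counts else pd.NA,
                    n1=s.mm_counts[1] if s.mm_counts else pd.NA,
                    n2=s.mm_counts[2] if s.mm_counts else pd.NA,
                    oof_score=s.oof_score,
                    cds_percent=s.cds_percent,
                    oligo=rec.oligo,
                )
            )
        for ctl in self.controls:
            rows.append(
                dict(
                    guide_id=ctl.guide_id,
                    gene_id="",
                    spacer=ctl.spacer,
                    chrom="",
                    start=-1,
                    end=-1,
                    strand=".",
                    tier=0,
                    n0=0,
                    n1=0,
                    n2=0,
                    oof_score=pd.NA,
                    cds_percent=pd.NA,
                    oligo=ctl.oligo,
                )
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GuideLibrary":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        guides, controls = [], []
        for _, r in df.iterrows():
            if r["tier"] == 0 or not isinstance(r["gene_id"], str) or r["gene_id"] == "":
                controls.append(ControlGuide(r["guide_id"], r["spacer"], r["oligo"]))
            else:
                site = GuideSite(
                    gene_id=r["gene_id"],
                    spacer=r["spacer"],
                    pam="NGG",
                    chrom=r["chrom"],
                    strand=r["strand"],
                    start=int(r["start"]),
                    end=int(r["end"]),
                    cut_pos=int(r["start"]) + 17 if r["strand"] == "+" else int(r["start"]) + 3,
                    cds_percent=float(r["cds_percent"]) if pd.notna(r["cds_percent"]) else None,
                    mm_counts=(int(r["n0"]), int(r["n1"]), int(r["n2"]))
                    if pd.notna(r["n0"])
                    else None,
                    oof_score=float(r["oof_score"]) if pd.notna(r["oof_score"]) else None,
                )
                guides.append(GuideRecord(site, int(r["tier"]), r["oligo"]))
        n_genes = len({g.site.gene_id for g in guides})
        return cls(guides, controls, n_genes)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.guides:
                s = rec.site
                fh.write(
                    f"{s.chrom}\t{s.start}\t{s.end}\t{rec.guide_id}\t{rec.tier}\t{s.strand}\n"
                )


# ---------------------------------------------------------------------------
# Candidate-site discovery


def _cds_union(gene: GeneModel) -> list[tuple[int, int]]:
    ivals = sorted(iv for t in gene.transcripts for iv in t.cds)
    merged: list[tuple[int, int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def find_candidate_sites(gene: GeneModel, genome: Mapping[str, str]) -> list[GuideSite]:
    """All NGG protospacers, either strand, whose cut lies in the gene's exonic CDS."""
    seq = genome[gene.chrom].upper()
    cds = _cds_union(gene)
    if not cds:
        log.warning("gene %s has no CDS; no candidate sites", gene.gene_id)
        return []
    const = constitutive_exons(gene)

    def in_cds(cut: int) -> bool:
        return any(s < cut < e for s, e in cds)

    def in_const(cut: int) -> bool:
        return any(s < cut < e for s, e in const)

    gs, ge = gene.span
    lo, hi = max(0, gs - 30), min(len(seq), ge + 30)
    sites: list[GuideSite] = []
    for p in range(lo, hi - 23 + 1):
        # forward: protospacer [p, p+20), PAM [p+20, p+23) == NGG
        if seq[p + 21] == "G" and seq[p + 22] == "G":
            cut = p + 17
            spacer = seq[p : p + 20]
            if in_cds(cut) and set(spacer) <= set("ACGT"):
                sites.append(
                    GuideSite(
                        gene.gene_id,
                        spacer,
                        seq[p + 20 : p + 23],
                        gene.chrom,
                        "+",
                        p,
                        p + 20,
                        cut,
                        cds_percent=cds_percent(cut, gene),
                        constitutive=in_const(cut),
                    )
                )
        # reverse: PAM CCN at [p, p+3), protospacer [p+3, p+23) (revcomp)
        if seq[p] == "C" and seq[p + 1] == "C":
            cut = p + 6
            spacer = revcomp(seq[p + 3 : p + 23])
            if in_cds(cut) and set(spacer) <= set("ACGT"):
                sites.append(
                    GuideSite(
                        gene.gene_id,
                        spacer,
                        revcomp(seq[p : p + 3]),
                        gene.chrom,
                        "-",
                        p + 3,
                        p + 23,
                        cut,
                        cds_percent=cds_percent(cut, gene),
                        constitutive=in_const(cut),
                    )
                )
    return sites


def cds_percent(cut_pos: int, gene: GeneModel) -> Optional[float]:
    """Cut position within the coding sequence, percent of total CDS length.

    Computed on the longest-CDS transcript whose CDS contains the cut
    boundary; coding bases 5' of the cut are counted in translation order
    (reverse-strand genes translate right to left).  Returns None when the
    cut lies in no transcript's CDS.
    """
    best: Optional = None
    for t in gene.transcripts:
        if any(s <= cut_pos <= e for s, e in t.cds):
            if best is None or t.cds_length > best.cds_length:
                best = t
    if best is None:
        return None
    if gene.strand == "+":
        before = sum(max(0, min(e, cut_pos) - s) for s, e in best.cds)
    else:
        before = sum(max(0, e - max(s, cut_pos)) for s, e in best.cds)
    return 100.0 * before / best.cds_length


# ---------------------------------------------------------------------------
# Off-target counting

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class OffTargetIndex:
    """All NGG-adjacent protospacers of a genome, as a mismatch-countable matrix.

    Genomic N bases never match any spacer base (conservative).
    """

    def __init__(self, genome: Mapping[str, str]):
        mats = []
        for seq in genome.values():
            code = _encode(seq)
            if len(code) < 23:
                continue
            win = np.lib.stride_tricks.sliding_window_view(code, 23)
            fwd = win[(win[:, 21] == 2) & (win[:, 22] == 2)][:, :20]
            rev_rows = win[(win[:, 0] == 1) & (win[:, 1] == 1)][:, 3:23]
            # reverse-complement: reverse column order, complement codes (3 - x),
            # leaving N (4) as a never-matching sentinel
            rev = rev_rows[:, ::-1]
            rev = np.where(rev == 4, 4, 3 - rev).astype(np.uint8)
            if len(fwd):
                mats.append(fwd)
            if len(rev):
                mats.append(rev)
        self._mat = (
            np.vstack(mats) if mats else np.empty((0, 20), dtype=np.uint8)
        )

    def count(self, spacer: str, max_mm: int = 2) -> tuple[int, ...]:
        if len(spacer) != SPACER_LEN:
            raise DesignError(f"spacer length {len(spacer)} != {SPACER_LEN}")
        if set(spacer.upper()) - set("ACGT"):
            raise DesignError(f"spacer contains non-ACGT base: {spacer}")
        sp = _encode(spacer)
        if len(self._mat) == 0:
            return tuple([0] * (max_mm + 1))
        mm = (self._mat != sp).sum(axis=1)
        return tuple(int((mm == k).sum()) for k in range(max_mm + 1))


def count_offtargets(
    spacer: str, genome: Mapping[str, str], max_mm: int = 2
) -> tuple[int, ...]:
    """Counts of genomic NGG sites matching ``spacer`` with 0..max_mm mismatches.

    Convenience wrapper; building an :class:`OffTargetIndex` once is much
    faster when profiling many spacers against the same genome.
    """
    return OffTargetIndex(genome).count(spacer, max_mm=max_mm)


# ---------------------------------------------------------------------------
# Microhomology out-of-frame score

_LENGTH_WEIGHT = 20.0


@dataclass(frozen=True)
class MicrohomologyScore:
    score: float  # out-of-frame score, 0..100
    n_patterns: int  # deduplicated microhomology deletion patterns found

    @property
    def no_microhomology(self) -> bool:
        return self.n_patterns == 0


def out_of_frame_score(window: str, cut: Optional[int] = None) -> MicrohomologyScore:
    """Microhomology-associated out-of-frame score of a cut-site context.

    Flanking microhomologies (>= 2 nt repeats straddling the cut) each imply
    a deletion of length ``j - i``; a pattern scores
    ``100 / exp(len/20) * (#AT + 2*#GC)`` and patterns wholly contained in a
    longer pattern with the same implied deletion are dropped.  The score is
    100 x (sum of scores of deletions with length % 3 != 0) / (sum of all
    scores); 0 with a flag when no microhomology exists.
    """
    window = window.upper()
    if len(window) < 4:
        raise DesignError("microhomology window shorter than 4 nt")
    if cut is None:
        if len(window) % 2 != 0:
            raise DesignError("window length must be even when cut is implicit")
        cut = len(window) // 2
    if not (2 <= cut <= len(window) - 2):
        raise DesignError("cut must leave >= 2 nt on each side")
    L = len(window)
    entries: list[tuple[int, int, int, int, int, float]] = []
    for k in range(cut - 1, 1, -1):  # longest first
        for j in range(cut, L - k + 1):
            for i in range(0, cut - k + 1):
                if window[i : i + k] == window[j : j + k]:
                    dlen = j - i
                    gc = sum(1 for b in window[i : i + k] if b in "GC")
                    at = k - gc
                    s = 100.0 / math.exp(dlen / _LENGTH_WEIGHT) * (at + 2 * gc)
                    entries.append((i, i + k, j, j + k, dlen, s))
    sum_if = sum_oof = 0.0
    n = 0
    for idx, (i1, i2, j1, j2, dlen, s) in enumerate(entries):
        dup = False
        for I1, I2, J1, J2, _, _ in entries[:idx]:
            if (
                i1 >= I1
                and i2 <= I2
                and j1 >= J1
                and j2 <= J2
                and (i1 - I1) == (j1 - J1)
                and (i2 - I2) == (j2 - J2)
            ):
                dup = True
                break
        if dup:
            continue
        n += 1
        if dlen % 3 == 0:
            sum_if += s
        else:
            sum_oof += s
    total = sum_if + sum_oof
    if total == 0:
        return MicrohomologyScore(0.0, 0)
    return MicrohomologyScore(100.0 * sum_oof / total, n)


def annotate_oof(
    site: GuideSite, genome: Mapping[str, str], flank: int = 30
) -> None:
    """Score ``site`` in place using a +/- ``flank`` nt window around the cut.

    Windows are truncated (and flagged via ``oof_no_microhomology`` when the
    truncation leaves nothing scoreable) at contig edges.
    """
    seq = genome[site.chrom]
    lo = max(0, site.cut_pos - flank)
    hi = min(len(seq), site.cut_pos + flank)
    res = out_of_frame_score(seq[lo:hi], cut=site.cut_pos - lo)
    site.oof_score = res.score
    site.oof_no_microhomology = res.no_microhomology


# ---------------------------------------------------------------------------
# Selection cascade and oligos


def select_guides(
    candidates: Sequence[GuideSite],
    rules: Sequence[SelectionRule] = DEFAULT_RULES,
    k: int = 6,
) -> list[tuple[GuideSite, int]]:
    """Apply the tier cascade: fill up to ``k`` guides at the lowest tier possible.

    Within a tier, candidates are ranked by out-of-frame score (descending),
    then CDS percent (ascending; 5'-biased cuts preferred), then genomic
    coordinate — a deterministic tie-break.  No spacer is selected twice.
    """
    chosen: list[tuple[GuideSite, int]] = []
    used_spacers: set[str] = set()

    def order_key(s: GuideSite):
        return (
            -(s.oof_score if s.oof_score is not None else -1.0),
            s.cds_percent if s.cds_percent is not None else 101.0,
            s.chrom,
            s.cut_pos,
            s.strand,
        )

    for rule in rules:
        if len(chosen) >= k:
            break
        pool = [
            s
            for s in candidates
            if s.spacer not in used_spacers and rule.admits(s)
        ]
        pool.sort(key=order_key)
        for s in pool:
            if len(chosen) >= k:
                break
            if s.spacer in used_spacers:
                continue
            chosen.append((s, rule.tier))
            used_spacers.add(s.spacer)
    return chosen


def build_oligo(spacer: str) -> str:
    """80-nt synthesis oligo embedding the (possibly G-extended) spacer.

    A 5' G is prepended when the spacer does not already start with G, for
    efficient transcription from the U6 promoter.  The insert is flanked by
    SapI cassettes so that digestion releases it with defined overhangs; the
    right PCR-handle padding absorbs the 1-nt length difference.
    """
    if len(spacer) != SPACER_LEN:
        raise DesignError(f"spacer length {len(spacer)} != {SPACER_LEN}")
    core = spacer if spacer.startswith("G") else "G" + spacer
    if SAPI_SITE in core or SAPI_SITE_RC in core:
        raise DesignError(f"spacer {spacer} contains a SapI site (would self-cleave)")
    body = (
        _LEFT_PAD
        + SAPI_SITE
        + _LEFT_SPACER_N
        + OVERHANG_LEFT
        + core
        + OVERHANG_RIGHT
        + _RIGHT_SPACER_N
        + SAPI_SITE_RC
    )
    pad = OLIGO_LEN - len(body)
    oligo = body + _RIGHT_PAD[:pad]
    assert len(oligo) == OLIGO_LEN
    if oligo.count(SAPI_SITE) + oligo.count(SAPI_SITE_RC) != 2:
        raise DesignError(f"oligo for {spacer} forms an extra SapI site")
    return oligo


def digest_oligo(oligo: str) -> str:
    """Simulate SapI digestion; top strand of the released insert.

    SapI cleaves the top strand 1 nt 3' of its recognition site; the
    released fragment runs from there to the top-strand cut of the
    bottom-strand site, i.e. left overhang + (G-extended) spacer.
    """
    li = oligo.index(SAPI_SITE)
    ri = oligo.index(SAPI_SITE_RC, li + len(SAPI_SITE))
    return oligo[li + 8 : ri - 4]


# ---------------------------------------------------------------------------
# Whole-library design


def targeted_gene_count(*gene_lists: Iterable[str]) -> int:
    """Total genes targeted given candidate-category gene lists (union)."""
    all_ids: set[str] = set()
    for lst in gene_lists:
        all_ids.update(lst)
    return len(all_ids)


def nontargeting_controls(
    index: OffTargetIndex,
    n: int = 7,
    rng: Optional[np.random.Generator] = None,
) -> list[str]:
    """Random 20-mers verified to have zero 0/1/2-mismatch NGG sites."""
    rng = rng if rng is not None else np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        spacer = "".join(rng.choice(bases, size=SPACER_LEN))
        if SAPI_SITE in "G" + spacer or SAPI_SITE_RC in "G" + spacer:
            continue
        if spacer in out:
            continue
        if index.count(spacer) == (0, 0, 0):
            out.append(spacer)
    return out


def design_library(
    genemodels: Sequence[GeneModel],
    genome: Mapping[str, str],
    controls: int = 7,
    k: int = 6,
    rules: Sequence[SelectionRule] = DEFAULT_RULES,
    seed: int = 0,
) -> GuideLibrary:
    """Design ``k`` guides per gene plus verified non-targeting controls."""
    index = OffTargetIndex(genome)
    guides: list[GuideRecord] = []
    undesignable: list[str] = []
    tier_counts: dict[int, int] = {}
    used_spacers: set[str] = set()
    for gene in genemodels:
        sites = find_candidate_sites(gene, genome)
        usable: list[GuideSite] = []
        for s in sites:
            if s.spacer in used_spacers:
                continue
            core = s.spacer if s.spacer.startswith("G") else "G" + s.spacer
            if SAPI_SITE in core or SAPI_SITE_RC in core:
                continue  # would self-cleave during cloning
            s.mm_counts = index.count(s.spacer)
            annotate_oof(s, genome)
            usable.append(s)
        picked = select_guides(usable, rules=rules, k=k)
        if not picked:
            undesignable.append(gene.gene_id)
            continue
        for site, tier in picked:
            guides.append(GuideRecord(site, tier, build_oligo(site.spacer)))
            used_spacers.add(site.spacer)
            tier_counts[tier] = tier_counts.get(tier, 0) + 1
    rng = np.random.default_rng(seed)
    ctl_spacers = nontargeting_controls(index, n=controls, rng=rng)
    ctls = [
        ControlGuide(f"nt_{i + 1}", sp, build_oligo(sp))
        for i, sp in enumerate(ctl_spacers)
    ]
    n_targeted = len({rec.site.gene_id for rec in guides})
    return GuideLibrary(guides, ctls, n_targeted, undesignable, tier_counts)
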