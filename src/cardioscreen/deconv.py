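"""Screen read deconvolution and sample quality control.

Raw screen reads are trimmed to the 20-bp variable region between the 5'
vector adapter and the gRNA scaffold, assigned to library spacers by exact
dictionary match (equivalent to alignment-based interval counting for
uniquely designed spacers), and assembled into a guide x sample count
table.  Samples are then screened by three criteria: enrichment of the
spiked positive-control guides, Pearson clustering with their own role
group, and library coverage.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import GuideLibrary
from .screenstats import size_factors

#: 5' anchor: the 3' end of the U6/vector sequence preceding the spacer.
ADAPTER5 = "CTTGTGGAAAGGACGAAACACCG"[-14:]
#: 3' anchor: the start of the invariant gRNA scaffold.
SCAFFOLD3 = "GTTTTAGAGCTAGAAATAGCAAG"[:14]


class FastqError(ValueError):
    pass


@dataclass
class TrimReport:
    total: int = 0
    n_spacers: int = 0
    discarded: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return dict(total=self.total, n_spacers=self.n_spacers, **self.discarded)


def _open_maybe_gz(path: str | Path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(handle: IO[str]) -> Iterator[tuple[str, str]]:
    idx = 0
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        if not header.startswith("@") or not plus.startswith("+") or not qual:
            raise FastqError(f"malformed FASTQ record at index {idx}")
        seq = seq.strip()
        if len(qual.strip()) != len(seq):
            raise FastqError(f"malformed FASTQ record at index {idx}")
        yield header[1:].strip(), seq
        idx += 1


def _approx_find(seq: str, pattern: str, start: int = 0, max_mm: int = 1) -> int:
    """First index >= start where pattern matches with <= max_mm mismatches."""
    m = len(pattern)
    for i in range(start, len(seq) - m + 1):
        mm = 0
        for a, b in zip(pattern, seq[i : i + m]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return i
    return -1


def trim_reads(
    source: str | Path | IO[str] | Iterable[tuple[str, str]],
    adapter5: str = ADAPTER5,
    scaffold3: str = SCAFFOLD3,
    max_mm: int = 1,
) -> tuple[list[str], TrimReport]:
    """Extract the variable spacer region from each read.

    A read yields a spacer iff ``adapter5`` occurs (<= ``max_mm``
    mismatches) and is followed by >= 20 nt preceding a ``scaffold3`` match
    (<= ``max_mm`` mismatches); everything else is tallied with a reason.
    """
    if isinstance(source, (str, Path)):
        handle = _open_maybe_gz(source)
        records: Iterable[tuple[str, str]] = _iter_fastq(handle)
    elif hasattr(source, "readline"):
        records = _iter_fastq(source)  # type: ignore[arg-type]
    else:
        records = source
    report = TrimReport()
    spacers: list[str] = []
    for _name, seq in records:
        report.total += 1
        seq = seq.upper()
        i = _approx_find(seq, adapter5, 0, max_mm)
        if i == -1:
            report.discarded["no adapter"] += 1
            continue
        var_start = i + len(adapter5)
        j = _approx_find(seq, scaffold3, var_start + 20, max_mm)
        if j == -1:
            report.discarded["no scaffold"] += 1
            continue
        spacers.append(seq[var_start:j])
        report.n_spacers += 1
    return spacers, report


def count_guides(
    spacers: Iterable[str], library: GuideLibrary
) -> tuple[pd.Series, int]:
    """Exact-match assignment of trimmed spacers to library guides.

    Matches the 20-mer as designed; a 21-mer beginning with the prepended G
    matches on its trailing 20 bases.  Returns (counts indexed by guide id,
    number of unassigned spacers); assigned + unassigned = len(spacers).
    """
    smap = library.spacer_map()  # raises on duplicate library spacers
    counts: Counter = Counter()
    unassigned = 0
    for s in spacers:
        gid = smap.get(s)
        if gid is None and len(s) == 21 and s.startswith("G"):
            gid = smap.get(s[1:])
        if gid is None:
            unassigned += 1
        else:
            counts[gid] += 1
    col = pd.Series(0, index=library.guide_ids(), dtype=int)
    for gid, c in counts.items():
        col[gid] = c
    return col, unassigned


@dataclass
class GuideCountTable:
    """Integer guide x sample counts with sample roles ('input'/'sorted')."""

    counts: pd.DataFrame
    roles: dict[str, str]
    unassigned: dict[str, int] = field(default_factory=dict)
    pools: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.roles)
        if missing:
            raise ValueError(f"samples without a role: {sorted(missing)}")

    def samples(self, role: Optional[str] = None) -> list[str]:
        return [
            s for s in self.counts.columns if role is None or self.roles[s] == role
        ]

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "guide_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, roles: Mapping[str, str]) -> "GuideCountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, dict(roles))


@dataclass
class QCThresholds:
    control_log2_enrichment: float = 1.0
    coverage: float = 0.5
    clustering_margin: float = 0.0


def sample_qc(
    table: GuideCountTable,
    positive_guides: Sequence[str],
    thresholds: QCThresholds = QCThresholds(),
) -> pd.DataFrame:
    """Three-criterion sample QC.

    * control enrichment (sorted samples only): log2 ratio of the summed
      normalized abundance of the spiked positive-control guides versus the
      mean over input samples; must reach the threshold.
    * clustering: on log1p median-of-ratios-normalized counts, the sample's
      mean Pearson r with its own role group must exceed its mean r with
      the other role group by more than the margin.
    * coverage: fraction of library guides with >= 1 read.

    Returns a per-sample frame with the three metrics, ``pass`` and a
    semicolon-joined ``reasons`` column (non-empty iff the sample fails).
    """
    counts = table.counts
    for role in ("input", "sorted"):
        if len(table.samples(role)) < 2:
            raise ValueError(f"need >= 2 samples with role {role!r}")
    # degenerate (all-zero) samples cannot support a median-of-ratios factor;
    # give them a unit factor and let the coverage criterion flag them
    live = counts.columns[counts.sum() > 0]
    sf = pd.Series(1.0, index=counts.columns)
    sf[live] = size_factors(counts[live])
    norm = counts / sf
    logn = np.log1p(norm)
    corr = logn.corr(method="pearson")

    pos = [g for g in positive_guides if g in counts.index]
    input_samples = table.samples("input")
    pos_abund = norm.loc[pos].sum(axis=0) + 0.5
    input_ref = pos_abund[input_samples].mean()

    rows = []
    for s in counts.columns:
        role = table.roles[s]
        own = [x for x in table.samples(role) if x != s]
        other = table.samples("sorted" if role == "input" else "input")
        margin = (
            float(corr.loc[s, own].mean() - corr.loc[s, other].mean())
            if own
            else np.nan
        )
        coverage = float((counts[s] > 0).mean())
        if role == "sorted":
            ctl = float(np.log2(pos_abund[s] / input_ref))
        else:
            ctl = np.nan
        reasons = []
        if role == "sorted" and ctl < thresholds.control_log2_enrichment:
            reasons.append("control_enrichment")
        if np.isnan(margin):
            reasons.append("clustering_undefined")
        elif margin <= thresholds.clustering_margin:
            reasons.append("clustering")
        if coverage < thresholds.coverage:
            reasons.append("coverage")
        fail = [r for r in reasons if r != "clustering_undefined"]
        rows.append(
            dict(
                sample=s,
                role=role,
                control_enrichment=ctl,
                clustering_margin=margin,
                coverage=coverage,
                **{"pass": not fail},
                reasons=";".join(fail),
            )
        )
    return pd.DataFrame(rows).set_index("sample")


def qc_to_json(qc: pd.DataFrame, path) -> None:
    payload = qc.reset_index().to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
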