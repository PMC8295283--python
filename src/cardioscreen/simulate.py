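"""Synthetic genomes, screens and multi-omics count tables with ground truth.

Everything downstream of this module can run on its outputs alone.  The
generator emulates the study's structure: a gene-dense genome with
multi-isoform genes (so constitutive-exon logic is exercised), a pooled
screen with negative-binomial guide counts for input versus sorted
samples, gene-level enrichment effects with per-guide efficacy noise,
spiked positive-control guides and non-targeting negatives, stage-resolved
ChIP gene-body counts with a dynamic subset, and RNA counts whose
maturational change is correlated with the H2Bub1 change by a configured
coupling (the analogue of the observed r = 0.39).

One root seed spawns an independent child stream per artifact (genome,
library, screen, reads, chip, rna), so adding an artifact never perturbs
the others and a fixed seed determines every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .deconv import ADAPTER5, SCAFFOLD3, GuideCountTable
from .design import (
    ControlGuide,
    GuideLibrary,
    GuideRecord,
    GuideSite,
    SAPI_SITE,
    SAPI_SITE_RC,
    build_oligo,
)
from .models import GeneModel, Transcript

_STREAMS = {"genome": 0, "library": 1, "screen": 2, "reads": 3, "chip": 4, "rna": 5}

SPIKE_GENE = "spike_gata4_gata6"


class ConfigError(ValueError):
    pass


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Child RNG stream for one artifact, derived from the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    )


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment.

    Defaults mirror the screen scale used throughout the test suite: 500
    targeted genes with 6 guides each plus 7 non-targeting controls, 50 hit
    genes at log2FC 3 with per-guide efficacy noise (sd 0.5), NB dispersion
    0.1, and one million reads per sample.  The H2Bub1/RNA coupling default
    of 0.4 is the simulation analogue of the observed between-stage
    correlation.
    """

    seed: int = 0
    genome_length: int = 2_000_000
    n_genes: int = 500
    transcripts_per_gene: tuple[int, int] = (1, 3)
    n_hit_genes: int = 50
    hit_log2fc: float = 3.0
    guide_effect_sd: float = 0.5
    nb_dispersion: float = 0.1
    sequencing_depth: float = 1_000_000.0
    frac_dynamic_chip: float = 0.3
    chip_rna_coupling: float = 0.4
    ko_effect_rule: str = "oppose_maturation"
    # secondary knobs
    guides_per_gene: int = 6
    n_controls: int = 7
    spike_log2fc: float = 5.0
    n_spike_guides: int = 4
    # replicate-level dispersions for the multi-omics assays; ChIP and RNA
    # biological replicates correlate far better than screen samples do
    chip_dispersion: float = 0.02
    rna_dispersion: float = 0.05
    exons_per_gene: tuple[int, int] = (3, 6)

    def __post_init__(self):
        if self.n_hit_genes > self.n_genes:
            raise ConfigError("n_hit_genes > n_genes")
        if not 0.0 <= self.frac_dynamic_chip <= 1.0:
            raise ConfigError("frac_dynamic_chip outside [0, 1]")
        if abs(self.chip_rna_coupling) > 1.0:
            raise ConfigError("|chip_rna_coupling| > 1")
        if min(self.nb_dispersion, self.chip_dispersion, self.rna_dispersion) < 0:
            raise ConfigError("negative NB dispersion")
        if self.sequencing_depth <= 0:
            raise ConfigError("non-positive sequencing depth")
        if self.ko_effect_rule not in ("oppose_maturation", "none"):
            raise ConfigError(f"unknown ko_effect_rule {self.ko_effect_rule!r}")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}: {v}\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        import ast

        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition(":")
                v = v.strip()
                try:
                    kwargs[k.strip()] = ast.literal_eval(v)
                except (ValueError, SyntaxError):
                    kwargs[k.strip()] = v  # bare string (e.g. the KO rule)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted effects behind a simulated screen."""

    hit_genes: set[str]
    guide_log2fc: dict[str, float]
    spike_gene: Optional[str] = None

    def gene_truth(self) -> pd.Series:
        return pd.Series(self.guide_log2fc)


@dataclass
class MultiomicsTruth:
    delta_h2bub: pd.Series
    delta_rna: pd.Series
    ko_log2fc: pd.Series
    h2bub_p1: pd.Series
    dynamic_genes: set[str]
    ko_de_genes: dict[str, int]  # gene -> sign of the planted KO effect


# ---------------------------------------------------------------------------
# Genome generation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, dispersion alpha) with var = mu + alpha*mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def gen_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus non-overlapping gene models on alternating strands.

    Exons are fully coding with lengths divisible by 3, so every exon
    subset yields a valid CDS; multi-isoform genes drop one internal
    cassette exon per extra transcript.  At least one gene per run carries
    a cassette isoform whenever the configured transcript range allows it,
    so constitutive-exon logic is always exercised.  Intergenic spacing is
    at least 1 kb.
    """
    rng = stream_rng(config.seed, "genome")
    chrom = "chrS"
    genes: list[GeneModel] = []
    tx_lo, tx_hi = config.transcripts_per_gene
    ex_lo, ex_hi = config.exons_per_gene
    pos = int(rng.integers(1000, 2000))
    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_tx = int(rng.integers(tx_lo, tx_hi + 1))
        force_cassette = gi == 0 and tx_hi >= 2
        if force_cassette:
            n_tx = max(n_tx, 2)
        n_ex = int(rng.integers(ex_lo, ex_hi + 1))
        if n_tx > 1:
            n_ex = max(n_ex, 3)  # need an internal exon to drop
        ex_lens = 3 * rng.integers(30, 100, size=n_ex)
        intron_lens = rng.integers(80, 300, size=max(n_ex - 1, 0))
        exons = []
        p = pos
        for i, el in enumerate(ex_lens):
            exons.append((p, p + int(el)))
            p += int(el)
            if i < n_ex - 1:
                p += int(intron_lens[i])
        full = tuple(exons)
        transcripts = [Transcript(f"{gene_id}_t1", full, full)]
        internal = list(range(1, n_ex - 1))
        drop_order = rng.permutation(internal)
        for ti in range(1, n_tx):
            if ti - 1 >= len(drop_order):
                break
            drop = int(drop_order[ti - 1])
            sub = tuple(iv for k, iv in enumerate(exons) if k != drop)
            transcripts.append(Transcript(f"{gene_id}_t{ti + 1}", sub, sub))
        gene = GeneModel(gene_id, chrom, strand, tuple(transcripts))
        gene.validate()
        genes.append(gene)
        pos = p + int(rng.integers(1000, 2000))
    if pos > config.genome_length:
        raise ConfigError(
            f"genome_length {config.genome_length} too short for "
            f"{config.n_genes} genes (need >= {pos})"
        )
    seq = "".join(rng.choice(list("ACGT"), size=config.genome_length))
    return {chrom: seq}, genes


# ---------------------------------------------------------------------------
# Screen simulation


def synthetic_library(config: SimConfig) -> GuideLibrary:
    """A screen-shaped library with invented spacers (no genome design).

    Used for statistical simulations where only the guide-to-gene structure
    matters; spacers are distinct random 20-mers.  Includes the spiked
    positive-control gene and the non-targeting controls.
    """
    rng = stream_rng(config.seed, "library")
    bases = np.array(list("ACGT"))
    seen: set[str] = set()

    def fresh_spacer() -> str:
        while True:
            sp = "".join(rng.choice(bases, size=20))
            if sp in seen:
                continue
            if SAPI_SITE in "G" + sp or SAPI_SITE_RC in "G" + sp:
                continue
            seen.add(sp)
            return sp

    guides: list[GuideRecord] = []

    def add_gene(gene_id: str, n_guides: int):
        for i in range(n_guides):
            sp = fresh_spacer()
            site = GuideSite(
                gene_id=gene_id,
                spacer=sp,
                pam="NGG",
                chrom="synthetic",
                strand="+",
                start=i * 30,
                end=i * 30 + 20,
                cut_pos=i * 30 + 17,
                cds_percent=float(rng.uniform(5, 50)),
                constitutive=True,
                mm_counts=(1, 0, 0),
                oof_score=float(rng.uniform(60, 95)),
            )
            guides.append(GuideRecord(site, 1, build_oligo(sp)))

    for gi in range(config.n_genes):
        add_gene(f"g{gi + 1:04d}", config.guides_per_gene)
    add_gene(SPIKE_GENE, config.n_spike_guides)
    controls = []
    for i in range(config.n_controls):
        sp = fresh_spacer()
        controls.append(ControlGuide(f"nt_{i + 1}", sp, build_oligo(sp)))
    return GuideLibrary(
        guides, controls, config.n_genes + 1, tier_counts={1: len(guides)}
    )


def screen_truth(library: GuideLibrary, config: SimConfig) -> GroundTruth:
    """Plant hit genes and per-guide true log2 fold changes."""
    rng = stream_rng(config.seed, "screen")
    regular = sorted(
        {r.site.gene_id for r in library.guides if r.site.gene_id != SPIKE_GENE}
    )
    hits = set(
        rng.choice(regular, size=min(config.n_hit_genes, len(regular)), replace=False)
    )
    guide_lfc: dict[str, float] = {}
    for rec in library.guides:
        gene = rec.site.gene_id
        if gene == SPIKE_GENE:
            lfc = config.spike_log2fc + rng.normal(0, 0.2)
        elif gene in hits:
            lfc = config.hit_log2fc + rng.normal(0, config.guide_effect_sd)
        else:
            lfc = 0.0
        guide_lfc[rec.guide_id] = float(lfc)
    for ctl in library.controls:
        guide_lfc[ctl.guide_id] = 0.0
    spike = SPIKE_GENE if any(
        r.site.gene_id == SPIKE_GENE for r in library.guides
    ) else None
    return GroundTruth(hits, guide_lfc, spike)


def sim_screen_counts(
    library: GuideLibrary,
    truth: GroundTruth,
    config: SimConfig,
    n_input: int = 15,
    n_sorted: int = 15,
) -> GuideCountTable:
    """NB guide counts for input and sorted samples with planted effects.

    Guide representation varies log-normally around the even pool; sorted
    sample means scale guide representation by 2^(true log2fc), so
    non-targeting and non-hit guides keep equal expected representation in
    both roles.
    """
    if n_input < 2 or n_sorted < 2:
        raise ConfigError("need >= 2 samples per role")
    rng = stream_rng(config.seed, "screen")
    rng = np.random.default_rng(rng.integers(2**31))  # decouple from truth draws
    gids = library.guide_ids()
    lfc = np.array([truth.guide_log2fc[g] for g in gids])
    rel = np.exp(rng.normal(0, 0.5, size=len(gids)))
    rel = rel / rel.sum()
    mean_in = config.sequencing_depth * rel
    mean_sort = mean_in * np.power(2.0, lfc)
    cols = {}
    for j in range(n_input):
        cols[f"input_{j + 1:02d}"] = _nb_draw(rng, mean_in, config.nb_dispersion)
    for j in range(n_sorted):
        cols[f"sorted_{j + 1:02d}"] = _nb_draw(rng, mean_sort, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(gids, name="guide_id"))
    roles = {s: ("input" if s.startswith("input") else "sorted") for s in counts}
    return GuideCountTable(counts, roles)


def sim_screen_fastq(
    library: GuideLibrary,
    config: SimConfig,
    n_reads: int = 1000,
    corrupt_frac: float = 0.0,
) -> tuple[list[tuple[str, str]], pd.Series]:
    """Screen reads as (name, sequence) records plus the true guide tally.

    Valid reads are adapter + (G-extended) spacer + scaffold + random tail;
    a ``corrupt_frac`` fraction lose their scaffold and must be discarded
    by trimming.
    """
    rng = stream_rng(config.seed, "reads")
    gids = library.guide_ids()
    spacers = dict(library.iter_spacers())
    picks = rng.choice(len(gids), size=n_reads)
    n_corrupt = int(round(corrupt_frac * n_reads))
    corrupt = np.zeros(n_reads, dtype=bool)
    if n_corrupt:
        corrupt[rng.choice(n_reads, size=n_corrupt, replace=False)] = True
    bases = np.array(list("ACGT"))
    reads = []
    tally = pd.Series(0, index=pd.Index(gids, name="guide_id"), dtype=int)
    for ri in range(n_reads):
        gid = gids[picks[ri]]
        sp = spacers[gid]
        var = sp if sp.startswith("G") else "G" + sp
        tail = "".join(rng.choice(bases, size=10))
        if corrupt[ri]:
            seq = ADAPTER5 + var + "".join(rng.choice(bases, size=len(SCAFFOLD3))) + tail
        else:
            seq = ADAPTER5 + var + SCAFFOLD3 + tail
            tally[gid] += 1
        reads.append((f"read_{ri}", seq))
    return reads, tally


def write_fastq(path, reads: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Multi-omics simulation


@dataclass
class MultiomicsTables:
    h2bub_counts: pd.DataFrame  # gene-body counts: stage reps + stage inputs
    h2bub_stages: dict  # stage -> (chip cols, input col)
    k4_tss: pd.DataFrame  # per-TSS max window coverage + gene_id
    k4_design: tuple  # (chip cols, input col)
    k4_library_sizes: dict
    k36_counts: pd.DataFrame
    k36_cols: list
    k36_library_sizes: dict
    rna_p1: pd.DataFrame
    rna_p28: pd.DataFrame
    rna_ctrl: pd.DataFrame
    rna_ko: pd.DataFrame
    gene_lengths: pd.Series
    truth: MultiomicsTruth


def _gene_lengths_from(genemodels, config: SimConfig, rng) -> pd.Series:
    if genemodels is None:
        n = config.n_genes
        lengths = rng.integers(1_000, 20_000, size=n)
        return pd.Series(
            lengths.astype(float), index=[f"g{i + 1:04d}" for i in range(n)]
        )
    if isinstance(genemodels, pd.Series):
        return genemodels.astype(float)
    return pd.Series({g.gene_id: float(g.length) for g in genemodels})


def sim_multiomics(
    genemodels: Optional[Sequence[GeneModel] | pd.Series],
    config: SimConfig,
    n_chip_reps: int = 2,
    n_rna_reps: int = 3,
    n_ko_reps: int = 5,
) -> MultiomicsTables:
    """Stage-resolved ChIP and RNA count tables with coupled ground truth.

    Per gene, (delta_H2Bub1, delta_RNA) is a bivariate-Gaussian draw with
    correlation ``chip_rna_coupling``; the neonatal H2Bub1 level is
    log-normal and the adult level adds the delta (floored at a small
    positive occupancy).  Under ``ko_effect_rule='oppose_maturation'`` the
    knockout log2FC opposes the maturational RNA change plus noise, so
    genes gaining expression during maturation are preferentially
    KO-downregulated (planting the quadrant enrichment).  Replicates are
    independent NB draws around the gene-level means.
    """
    rng_chip = stream_rng(config.seed, "chip")
    rng_rna = stream_rng(config.seed, "rna")
    lengths = _gene_lengths_from(genemodels, config, rng_chip)
    genes = lengths.index
    n = len(genes)
    if n == 0:
        raise ConfigError("no genes to simulate")

    rho = config.chip_rna_coupling
    sd_h, sd_r = 0.6, 1.5
    cov = np.array([[sd_h**2, rho * sd_h * sd_r], [rho * sd_h * sd_r, sd_r**2]])
    draws = rng_chip.multivariate_normal([0.0, 0.0], cov, size=n)
    delta_h_raw, delta_r = draws[:, 0], draws[:, 1]

    base_h = np.exp(rng_chip.normal(0.0, 0.5, size=n))  # neonatal H2Bub1 level
    level_p1 = base_h
    level_p28 = np.maximum(base_h + delta_h_raw, 0.02)
    delta_h = level_p28 - level_p1  # realized truth after the occupancy floor

    if config.ko_effect_rule == "oppose_maturation":
        ko_lfc = -0.8 * delta_r + rng_rna.normal(0.0, 0.5, size=n)
    else:
        ko_lfc = rng_rna.normal(0.0, 0.6, size=n)

    dyn_cut = np.quantile(np.abs(delta_h), 1.0 - config.frac_dynamic_chip)
    dynamic = set(genes[np.abs(delta_h) >= dyn_cut])

    # --- H2Bub1 gene-body counts -------------------------------------------
    bg = 0.2  # nonspecific background level, input-subtracted downstream
    len_kb = lengths.to_numpy() / 1e3
    target_total = 1e7  # mapped gene-body reads per ChIP library

    def chip_cols(level, tag, rng):
        mean_gene = (level + bg) * len_kb
        scale = target_total / mean_gene.sum()
        cols = {}
        for r in range(n_chip_reps):
            s = np.exp(rng.normal(0, 0.15))
            cols[f"{tag}_rep{r + 1}"] = _nb_draw(
                rng, s * scale * mean_gene, config.chip_dispersion
            )
        s = np.exp(rng.normal(0, 0.15))
        cols[f"{tag}_input"] = _nb_draw(
            rng, s * scale * bg * len_kb, config.chip_dispersion
        )
        return cols

    h2b = {}
    h2b.update(chip_cols(level_p1, "P1", rng_chip))
    h2b.update(chip_cols(level_p28, "P28", rng_chip))
    h2bub_counts = pd.DataFrame(h2b, index=genes)
    h2bub_stages = {
        "P1": ([f"P1_rep{r + 1}" for r in range(n_chip_reps)], "P1_input"),
        "P28": ([f"P28_rep{r + 1}" for r in range(n_chip_reps)], "P28_input"),
    }

    # --- H3K4me3 per-TSS max window coverage -------------------------------
    k4_lib = 2e7
    # log-normal promoter coverage calibrated so ~20% of genes clear the
    # 500-RPKM floor after RPKM conversion (score = cov * 1e9 / libsize)
    # and subtraction of the flat input background (0.5 cov)
    k4_input_cov = 0.5
    cov_thresh = 500.0 * k4_lib / 1e9 + k4_input_cov
    mu = np.log(cov_thresh) - 0.8416 * 1.0
    tss_rows = []
    tss_level = []
    for gi, g in enumerate(genes):
        n_tss = int(rng_chip.integers(1, 3))
        lead = np.exp(rng_chip.normal(mu, 1.0))
        for ti in range(n_tss):
            level = lead if ti == 0 else lead * rng_chip.uniform(0.1, 0.6)
            tss_rows.append((f"{g}_tss{ti + 1}", g))
            tss_level.append(level)
    tss_level = np.array(tss_level)
    k4 = pd.DataFrame(tss_rows, columns=["tss_id", "gene_id"]).set_index("tss_id")
    k4_sizes = {}
    for r in range(n_chip_reps):
        col = f"k4_rep{r + 1}"
        k4[col] = _nb_draw(rng_chip, tss_level, config.chip_dispersion)
        k4_sizes[col] = k4_lib
    k4["k4_input"] = _nb_draw(
        rng_chip, np.full(len(k4), k4_input_cov), config.chip_dispersion
    )
    k4_sizes["k4_input"] = k4_lib
    k4_design = ([f"k4_rep{r + 1}" for r in range(n_chip_reps)], "k4_input")

    # --- H3K36me3 gene-body counts -----------------------------------------
    k36_lib = 2e7
    k36_level = np.exp(rng_chip.normal(2.0, 1.0, size=n))  # RPKM-scale
    k36 = pd.DataFrame(index=genes)
    k36_sizes = {}
    for r in range(n_chip_reps):
        col = f"k36_rep{r + 1}"
        mean = k36_level * lengths.to_numpy() * k36_lib / 1e9
        k36[col] = _nb_draw(rng_chip, mean, config.chip_dispersion)
        k36_sizes[col] = k36_lib
    k36_cols = list(k36.columns)

    # --- RNA counts ---------------------------------------------------------
    rna_depth = 5e6
    base_expr = np.exp(rng_rna.normal(0.0, 1.0, size=n))
    q = base_expr / base_expr.sum()
    mean_p1 = rna_depth * q
    mean_p28 = mean_p1 * np.power(2.0, delta_r)
    mean_ko = mean_p28 * np.power(2.0, ko_lfc)

    def rna_table(mean, tag, reps, rng):
        return pd.DataFrame(
            {
                f"{tag}_{r + 1}": _nb_draw(rng, mean, config.rna_dispersion)
                for r in range(reps)
            },
            index=genes,
        )

    rna_p1 = rna_table(mean_p1, "P1", n_rna_reps, rng_rna)
    rna_p28 = rna_table(mean_p28, "P28", n_rna_reps, rng_rna)
    rna_ctrl = rna_table(mean_p28, "ctrl", n_ko_reps, rng_rna)
    rna_ko = rna_table(mean_ko, "ko", n_ko_reps, rng_rna)

    truth = MultiomicsTruth(
        delta_h2bub=pd.Series(delta_h, index=genes),
        delta_rna=pd.Series(delta_r, index=genes),
        ko_log2fc=pd.Series(ko_lfc, index=genes),
        h2bub_p1=pd.Series(level_p1, index=genes),
        dynamic_genes=dynamic,
        ko_de_genes={
            g: int(np.sign(l)) for g, l in zip(genes, ko_lfc) if abs(l) > 1.0
        },
    )
    return MultiomicsTables(
        h2bub_counts=h2bub_counts,
        h2bub_stages=h2bub_stages,
        k4_tss=k4,
        k4_design=k4_design,
        k4_library_sizes=k4_sizes,
        k36_counts=k36,
        k36_cols=k36_cols,
        k36_library_sizes=k36_sizes,
        rna_p1=rna_p1,
        rna_p28=rna_p28,
        rna_ctrl=rna_ctrl,
        rna_ko=rna_ko,
        gene_lengths=lengths,
        truth=truth,
    )
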