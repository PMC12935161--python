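"""Synthetic genomes, annotations, counts and feature tables with ground truth.

The generator emulates the shape of a long-read isoform study: multi-isoform
gene loci sharing a coding core with alternative first/last exons (so
isoforms differ in TSS and UTRs but share the planted ORF), codon-biased
coding sequence embedded in random background, lognormal gene expression,
negative-binomial noise on per-sample gene totals and Dirichlet-multinomial
allocation of reads to isoforms.  Planted effects — per-transcript log2 fold
changes and per-gene usage shifts — are recorded in truth tables so that
power, type-I error and FDR of the statistical stages can be measured
exactly.  Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import IsokitError
from .diffexpr import CountMatrix, SampleDesign
from .genemodels import GeneModel, GenomicInterval, Transcript, project_interval

__all__ = [
    "SimulationConfig",
    "simulate_annotation",
    "simulate_counts",
    "toy_models",
    "training_sets",
    "make_toy_locus",
    "write_fasta",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset."""

    seed: int = 0
    n_genes: int = 50
    isoforms_per_gene: tuple[int, int] = (2, 4)
    exons_per_isoform: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (80, 400)
    intron_length: tuple[int, int] = (200, 2000)
    utr_exon_length: tuple[int, int] = (60, 300)
    n_samples_per_group: int = 10
    depth: int = 50_000
    nb_dispersion: float = 0.1
    dm_precision: float = 50.0
    frac_de: float = 0.1
    log2fc: float = 2.0
    frac_diu: float = 0.1
    usage_shift: float = 0.3
    frac_novel: float = 0.2
    frac_noncoding_genes: float = 0.25
    group_labels: tuple[str, str] = ("control", "case")

    def __post_init__(self) -> None:
        for frac in (self.frac_de, self.frac_diu, self.frac_novel,
                     self.frac_noncoding_genes):
            if not 0.0 <= frac <= 1.0:
                raise IsokitError("fractions must lie in [0, 1]")
        for positive in (self.n_genes, self.n_samples_per_group, self.depth):
            if positive <= 0:
                raise IsokitError("counts must be positive")
        if self.exons_per_isoform[0] < 3:
            raise IsokitError("isoforms need >= 3 exons (two UTR exons + coding core)")


_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_ALL_CODONS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _ALL_CODONS if c not in _STOPS]
# one "preferred" codon per amino-acid family: gives coding sequence the
# periodic hexamer bias that real CDS has over random DNA
_PREFERRED = {"GCC", "CGG", "AAC", "GAC", "TGC", "GAG", "CAG", "GGC", "CAC",
              "ATC", "CTG", "AAG", "ATG", "TTC", "CCC", "AGC", "ACC", "TGG",
              "TAC", "GTG"}
_CODON_W = np.array([4.0 if c in _PREFERRED else 1.0 for c in _SENSE_CODONS])
_CODON_P = _CODON_W / _CODON_W.sum()


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _coding_seq(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + biased sense codons + stop: the planted ORF (length 3*n_codons+6)."""
    idx = rng.choice(len(_SENSE_CODONS), size=n_codons, p=_CODON_P)
    body = "".join(_SENSE_CODONS[i] for i in idx)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# annotation + genome
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig
                        ) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Random gene loci with planted ORFs.

    Each gene has a shared block of core (coding) exons flanked by two
    alternative first exons and two alternative last exons; isoforms pick one
    of each, so they share the ORF but differ in TSS and UTR content.  A
    configurable fraction of genes is noncoding (no planted ORF) and a
    fraction of coding transcripts is emitted without CDS records (the
    "novel" set).  Returns (genome, models, truth) where the truth table
    records the planted ORF per transcript in transcript coordinates.
    """
    rng = np.random.default_rng(config.seed)
    genome: dict[str, list[str]] = {}
    models: list[GeneModel] = []
    truth_rows: list[dict] = []

    genes_per_chrom = 10
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        chrom = f"chr{g // genes_per_chrom + 1}"
        parts = genome.setdefault(chrom, [])
        offset = sum(len(p) for p in parts)
        strand = "+" if rng.random() < 0.5 else "-"
        noncoding = rng.random() < config.frac_noncoding_genes

        n_ex = int(rng.integers(config.exons_per_isoform[0],
                                config.exons_per_isoform[1] + 1))
        n_core = max(1, n_ex - 2)
        core_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1,
                                 size=n_core)
        # guarantee room for a >= 150 nt ORF plus pads inside the core block
        while core_lens.sum() < 240:
            core_lens = core_lens + 60
        utr_lens = rng.integers(config.utr_exon_length[0],
                                config.utr_exon_length[1] + 1, size=4)
        exon_lens = [utr_lens[0], utr_lens[1], *core_lens.tolist(),
                     utr_lens[2], utr_lens[3]]
        introns = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                               size=len(exon_lens) - 1)

        # genomic layout, left to right
        pos = offset + 500
        exon_iv: list[GenomicInterval] = []
        for i, length in enumerate(exon_lens):
            exon_iv.append(GenomicInterval(chrom, pos, pos + int(length), strand))
            pos += int(length) + (int(introns[i]) if i < len(introns) else 0)
        locus_end = pos + 500

        # core spliced sequence with the planted ORF (transcript orientation)
        core_total = int(core_lens.sum())
        if noncoding:
            core_seq = _random_seq(rng, core_total)
            orf_info = None
        else:
            pad5 = int(rng.integers(12, 49))
            n_codons = (core_total - pad5 - 12) // 3 - 2
            orf = _coding_seq(rng, n_codons)
            pad3 = core_total - pad5 - len(orf)
            core_seq = _random_seq(rng, pad5) + orf + _random_seq(rng, pad3)
            orf_info = (pad5, pad5 + len(orf))  # within the core block

        # chromosome segment: random background, exon sequence written on top
        seg = list(_random_seq(rng, locus_end - offset))
        core_slots = exon_iv[2:2 + n_core]
        tx_order_core = core_slots if strand == "+" else list(reversed(core_slots))
        cursor = 0
        for iv in tx_order_core:
            piece = core_seq[cursor:cursor + len(iv)]
            cursor += len(iv)
            if strand == "-":
                piece = _revcomp(piece)
            seg[iv.start - offset:iv.end - offset] = list(piece)
        parts.append("".join(seg))

        # isoforms: one alternative first exon + core + one alternative last
        up, down = exon_iv[:2], exon_iv[-2:]
        five = up if strand == "+" else down
        three = down if strand == "+" else up
        combos = [(a, b) for a in (0, 1) for b in (0, 1)]
        k = int(rng.integers(config.isoforms_per_gene[0],
                             min(config.isoforms_per_gene[1], 4) + 1))
        chosen = [combos[i] for i in rng.choice(4, size=k, replace=False)]

        txs: list[Transcript] = []
        for t, (a, b) in enumerate(sorted(chosen)):
            tid = f"{gene_id}.T{t + 1}"
            exons = sorted([five[a], *core_slots, three[b]], key=lambda e: e.start)
            novel = (not noncoding) and rng.random() < config.frac_novel
            attrs = {"biotype": "lncRNA" if noncoding else "protein_coding"}
            if novel:
                attrs["novel"] = "True"
            tx = Transcript(tid, gene_id, exons=list(exons),
                            gene_name=gene_id, attributes=attrs)
            t_start = t_end = frame = None
            if orf_info is not None:
                utr5 = len(five[a])
                t_start, t_end = utr5 + orf_info[0], utr5 + orf_info[1]
                frame = t_start % 3
                if not novel:
                    tx = replace(tx, cds=project_interval(tx, t_start, t_end - 3))
            txs.append(tx)
            truth_rows.append({
                "transcript_id": tid, "gene_id": gene_id, "strand": strand,
                "coding": not noncoding, "novel": novel,
                "orf_t_start": t_start, "orf_t_end": t_end, "frame": frame,
                "spliced_length": tx.spliced_length,
            })
        models.append(GeneModel(gene_id, txs))

    return ({c: "".join(p) for c, p in genome.items()}, models,
            pd.DataFrame(truth_rows))


def toy_models(n_genes: int, isoforms_per_gene: int = 3) -> list[GeneModel]:
    """Minimal single-exon gene models for count-only simulations."""
    models = []
    for g in range(n_genes):
        gid = f"G{g + 1:04d}"
        txs = [
            Transcript(f"{gid}.T{t + 1}", gid,
                       exons=[GenomicInterval("chr1", 1000 * g + 200 * t,
                                              1000 * g + 200 * t + 100, "+")])
            for t in range(isoforms_per_gene)
        ]
        models.append(GeneModel(gid, txs))
    return models


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(models: list[GeneModel], config: SimulationConfig
                    ) -> tuple[CountMatrix, SampleDesign, dict[str, pd.DataFrame]]:
    """Two-group count matrix with planted DE and DIU effects.

    Per sample, each gene's total is negative-binomial around a lognormal
    gene mean (scaled by a mild lognormal library-size factor), then
    allocated to isoforms by a Dirichlet-multinomial draw with group-specific
    proportions.  DIU genes shift ``usage_shift`` of usage from their major
    to their minor isoform in the case group; DE transcripts (planted only in
    non-DIU genes so each effect is cleanly attributable) have their case
    proportion scaled by 2**log2fc with the gene total rescaled so other
    isoforms keep their expectation.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_samples_per_group
    ctrl_label, case_label = config.group_labels
    sample_ids = [f"{ctrl_label}_{i + 1}" for i in range(n)] + \
                 [f"{case_label}_{i + 1}" for i in range(n)]
    group_of = {s: (ctrl_label if i < n else case_label)
                for i, s in enumerate(sample_ids)}

    genes = [(gm.gene_id, [t.transcript_id for t in gm.transcripts])
             for gm in models]
    weights = rng.lognormal(0.0, 1.0, size=len(genes))
    gene_mean = config.depth * weights / weights.sum()

    multi = [i for i, (_, tids) in enumerate(genes) if len(tids) >= 2]
    n_diu = int(round(config.frac_diu * len(multi)))
    diu_idx = set(rng.choice(multi, size=n_diu, replace=False).tolist()) \
        if n_diu else set()

    base_props = {}
    case_props = {}
    diu_rows = []
    for i, (gid, tids) in enumerate(genes):
        k = len(tids)
        p = rng.dirichlet(np.full(k, 2.0))
        p = np.maximum(p, 0.02)
        p = p / p.sum()
        q = p.copy()
        if i in diu_idx:
            hi, lo = int(np.argmax(p)), int(np.argmin(p))
            shift = min(config.usage_shift, float(p[hi]) - 0.02)
            q[hi] -= shift
            q[lo] += shift
            diu_rows.append({"gene_id": gid, "shift": shift,
                             "tx_down": tids[hi], "tx_up": tids[lo]})
        base_props[gid], case_props[gid] = p, q

    # plant DE transcripts in non-DIU genes only
    eligible = [(i, j) for i, (_, tids) in enumerate(genes)
                if i not in diu_idx for j in range(len(tids))]
    n_de = int(round(config.frac_de * sum(len(t) for _, t in genes)))
    de_rows = []
    de_pick = (rng.choice(len(eligible), size=min(n_de, len(eligible)),
                          replace=False).tolist() if n_de else [])
    gene_case_scale = np.ones(len(genes))
    for flat in de_pick:
        i, j = eligible[flat]
        gid, tids = genes[i]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        fold = 2.0 ** (sign * config.log2fc)
        q = case_props[gid].copy()
        scale = q[j] * (fold - 1.0) + 1.0
        q[j] *= fold
        case_props[gid] = q / q.sum()
        gene_case_scale[i] *= scale
        de_rows.append({"transcript_id": tids[j], "gene_id": gid,
                        "log2fc": sign * config.log2fc})

    lib_factor = rng.lognormal(0.0, 0.1, size=2 * n)
    tid_all = [t for _, tids in genes for t in tids]
    counts = np.zeros((len(tid_all), 2 * n), dtype=np.int64)
    row_of = {t: r for r, t in enumerate(tid_all)}
    r_nb = 1.0 / config.nb_dispersion
    for i, (gid, tids) in enumerate(genes):
        for s in range(2 * n):
            is_case = s >= n
            mean = gene_mean[i] * lib_factor[s] * (gene_case_scale[i] if is_case else 1.0)
            total = rng.negative_binomial(r_nb, r_nb / (r_nb + mean))
            if total == 0:
                continue
            p = case_props[gid] if is_case else base_props[gid]
            if len(tids) == 1:
                counts[row_of[tids[0]], s] = total
            else:
                dirichlet_p = rng.dirichlet(config.dm_precision * p)
                alloc = rng.multinomial(total, dirichlet_p)
                for j, t in enumerate(tids):
                    counts[row_of[t], s] = alloc[j]

    cm = CountMatrix(tid_all, sample_ids, counts)
    design = SampleDesign(group_of, control=ctrl_label, case=case_label)
    truth = {
        "de": pd.DataFrame(de_rows, columns=["transcript_id", "gene_id", "log2fc"]),
        "diu": pd.DataFrame(diu_rows, columns=["gene_id", "shift", "tx_down", "tx_up"]),
    }
    return cm, design, truth


# ---------------------------------------------------------------------------
# classifier training material
# ---------------------------------------------------------------------------

def training_sets(genome: dict[str, str], models: list[GeneModel],
                  truth: pd.DataFrame, holdout_novel: bool = True
                  ) -> tuple[list[str], list[str]]:
    """(coding, noncoding) sequence sets for the coding-potential model.

    Coding examples are the planted ORFs of annotated (non-novel) coding
    transcripts; noncoding examples are the spliced sequences of noncoding
    transcripts.  Novel transcripts are excluded so they stay a clean test
    set for frame recovery.
    """
    from .orf import spliced_sequence

    info = truth.set_index("transcript_id")
    coding, noncoding = [], []
    for gm in models:
        for tx in gm.transcripts:
            row = info.loc[tx.transcript_id]
            seq = spliced_sequence(tx, genome)
            if row["coding"] and not row["novel"]:
                coding.append(seq[int(row["orf_t_start"]):int(row["orf_t_end"])])
            elif not row["coding"]:
                noncoding.append(seq)
            elif not holdout_novel:
                noncoding.append(seq)
    return coding, noncoding


# ---------------------------------------------------------------------------
# the documented worked example
# ---------------------------------------------------------------------------

def make_toy_locus() -> dict:
    """A fixed 4-isoform locus with hand-written coordinates and counts.

    The scenario mirrors a compensatory usage switch: gene-level expression
    drops in the case group, three isoforms go down, but one gains usage at
    the expense of the dominant isoform.  Returned dict holds the gene model,
    counts, design, feature tables and the hand-computed expected values used
    in documentation and golden tests.
    """
    chrom, strand = "chrT", "+"
    exon_grid = [(100, 300), (5400, 5600), (10500, 10800), (15800, 16100),
                 (20000, 20400)]
    ex = [GenomicInterval(chrom, s, e, strand) for s, e in exon_grid]

    def tx(tid, exons, cds):
        return Transcript(tid, "TOY1", exons=exons, cds=cds, gene_name="TOY1",
                          attributes={"biotype": "protein_coding"})

    t1 = tx("TOY1.T1", [ex[0], ex[1], ex[2], ex[3], ex[4]],
            [GenomicInterval(chrom, 5450, 5600, strand),
             GenomicInterval(chrom, 10500, 10800, strand),
             GenomicInterval(chrom, 15800, 16100, strand),
             GenomicInterval(chrom, 20000, 20150, strand)])
    t2 = tx("TOY1.T2", [ex[0], ex[2], ex[3], ex[4]],
            [GenomicInterval(chrom, 10550, 10800, strand),
             GenomicInterval(chrom, 15800, 16100, strand),
             GenomicInterval(chrom, 20000, 20100, strand)])
    t3 = tx("TOY1.T3", [ex[1], ex[2], ex[3]],
            [GenomicInterval(chrom, 5450, 5600, strand),
             GenomicInterval(chrom, 10500, 10800, strand),
             GenomicInterval(chrom, 15800, 15950, strand)])
    t4 = tx("TOY1.T4", [ex[0], ex[1], ex[3], ex[4]],
            [GenomicInterval(chrom, 5450, 5600, strand),
             GenomicInterval(chrom, 15800, 16100, strand),
             GenomicInterval(chrom, 20000, 20050, strand)])
    model = GeneModel("TOY1", [t1, t2, t3, t4])

    # counts: 4 control + 4 case samples; T1 dominant in control, T2 takes
    # over in case while the gene total halves.  Within each sample the
    # composition is exactly proportional so usage arithmetic is exact:
    # control usage (0.50, 0.10, 0.25, 0.15), case (120, 200, 60, 40)/420.
    sample_ids = [f"control_{i}" for i in range(1, 5)] + \
                 [f"case_{i}" for i in range(1, 5)]
    base_ctrl = np.array([500, 100, 250, 150])
    base_case = np.array([120, 200, 60, 40])
    scale = [1.0, 1.1, 0.9, 1.0]
    counts = np.stack(
        [np.round(base_ctrl * s).astype(int) for s in scale]
        + [np.round(base_case * s).astype(int) for s in scale], axis=1)
    # constant background transcripts anchor library size and TMM, so fold
    # changes of the locus reflect absolute expression changes
    ballast_counts = np.tile(
        np.array([2000, 3000, 1500, 2500, 1000, 4000])[:, None], (1, 8))
    ballast_models = []
    for b in range(6):
        btx = Transcript(f"TOYB{b + 1}.T1", f"TOYB{b + 1}",
                         exons=[GenomicInterval("chrB", 1000 * b,
                                                1000 * b + 500, "+")])
        ballast_models.append(GeneModel(f"TOYB{b + 1}", [btx]))
    tids = [t.transcript_id for t in model.transcripts] + \
           [m.transcripts[0].transcript_id for m in ballast_models]
    cm = CountMatrix(tids, sample_ids, np.vstack([counts, ballast_counts]))
    design = SampleDesign({s: ("control" if s.startswith("control") else "case")
                           for s in sample_ids}, control="control", case="case")

    from .features import NonPositionalFeature, PositionalFeature
    positional = [
        PositionalFeature("TOY1.T1", "domain", "protein_aa", 10, 80, "PF_TOY1"),
        PositionalFeature("TOY1.T1", "domain", "protein_aa", 150, 220, "PF_TOY2"),
        PositionalFeature("TOY1.T2", "domain", "protein_aa", 40, 110, "PF_TOY1"),
        PositionalFeature("TOY1.T3", "signal_peptide", "protein_aa", 1, 20, "SP"),
    ]
    non_positional = [
        NonPositionalFeature("TOY1.T1", "uorf", "binary", True),
        NonPositionalFeature("TOY1.T2", "uorf", "binary", False),
        NonPositionalFeature("TOY1.T3", "uorf", "binary", False),
        NonPositionalFeature("TOY1.T4", "uorf", "binary", True),
        NonPositionalFeature("TOY1.T1", "biotype", "categorical", "coding"),
        NonPositionalFeature("TOY1.T2", "biotype", "categorical", "coding"),
        NonPositionalFeature("TOY1.T3", "biotype", "categorical", "NMD"),
        NonPositionalFeature("TOY1.T4", "biotype", "categorical", "coding"),
        NonPositionalFeature("TOY1.T1", "expression", "continuous", 310.0),
        NonPositionalFeature("TOY1.T2", "expression", "continuous", 150.0),
        NonPositionalFeature("TOY1.T3", "expression", "continuous", 155.0),
        NonPositionalFeature("TOY1.T4", "expression", "continuous", 95.0),
    ]

    expected_delta = {
        "TOY1.T1": 120 / 420 - 0.5,
        "TOY1.T2": 200 / 420 - 0.1,
        "TOY1.T3": 60 / 420 - 0.25,
        "TOY1.T4": 40 / 420 - 0.15,
    }
    return {
        "model": model, "models": [model, *ballast_models],
        "counts": cm, "design": design,
        "positional": positional, "non_positional": non_positional,
        "expected_delta_usage": expected_delta,
        "expected_de_sign": {"TOY1.T1": -1, "TOY1.T2": +1, "TOY1.T3": -1,
                             "TOY1.T4": -1},
    }


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
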