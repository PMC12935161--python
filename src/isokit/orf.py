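"""ORF prediction and coding-potential scoring for CDS-less transcripts.

Novel transcripts from long-read assembly usually arrive without CDS records.
This module enumerates ATG-initiated open reading frames per transcript,
scores each candidate with the classical coding-potential feature family
(ORF length, ORF coverage, Fickett TESTCODE statistic, in-frame hexamer
log-odds) combined by a logistic model, selects the most likely frame, and
writes the winning ORF back into the gene model as CDS intervals.  It also
derives two downstream attributes used in figures: uORF presence and
predicted nonsense-mediated decay (NMD) status via the 50-nt rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from Bio.Seq import Seq

from .errors import CoordinateError, IsokitError, ValidationError
from .genemodels import GeneModel, Transcript, project_interval

__all__ = [
    "OrfCandidate",
    "CodingScore",
    "HexamerTable",
    "CodingModel",
    "load_genome",
    "spliced_sequence",
    "enumerate_orfs",
    "fickett_score",
    "train_hexamer_table",
    "hexamer_score",
    "fit_coding_model",
    "score_orf",
    "select_orf",
    "annotate_cds",
    "detect_uorf",
    "predict_nmd",
    "annotate_models",
]

STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# sequence access
# ---------------------------------------------------------------------------

def load_genome(path) -> dict[str, str]:
    """Load a genome FASTA into an uppercase chrom -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def spliced_sequence(tx: Transcript, genome) -> str:
    """Spliced transcript sequence, 5'->3' (reverse-complemented on -)."""
    if tx.chrom not in genome:
        raise KeyError(f"chromosome {tx.chrom!r} absent from genome")
    chrom_seq = genome[tx.chrom]
    parts = [str(chrom_seq[e.start:e.end]).upper() for e in tx.exons]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


# ---------------------------------------------------------------------------
# ORF enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfCandidate:
    """An ATG-initiated reading frame: [t_start, t_end) in transcript space.

    ``t_end`` is the end of the stop codon when ``has_stop``; otherwise the
    transcript end (3'-incomplete ORF).
    """

    frame: int
    t_start: int
    t_end: int
    has_stop: bool

    def __post_init__(self) -> None:
        if self.has_stop and (self.t_end - self.t_start) % 3 != 0:
            raise ValidationError("complete ORF length must be a codon multiple")

    @property
    def length_nt(self) -> int:
        return self.t_end - self.t_start


def enumerate_orfs(seq: str, min_len_nt: int = 75) -> list[OrfCandidate]:
    """All ATG-initiated ORFs of length >= ``min_len_nt`` across 3 frames.

    Per frame, each in-frame stop yields at most one candidate anchored at the
    5'-most ATG since the previous stop; a trailing ATG run with no stop
    yields a 3'-incomplete candidate ending at the transcript end.
    """
    seq = seq.upper()
    out: list[OrfCandidate] = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in STOPS:
                if i + 3 - start >= min_len_nt:
                    out.append(OrfCandidate(frame, start, i + 3, True))
                start = None
        if start is not None and n - start >= min_len_nt:
            out.append(OrfCandidate(frame, start, n, False))
    return sorted(out, key=lambda o: (o.t_start, o.t_end))


# ---------------------------------------------------------------------------
# Fickett TESTCODE statistic
# ---------------------------------------------------------------------------
# Probability and weight lookup tables from Fickett (1982), Nucleic Acids
# Res. 10:5303 — the classic TESTCODE discriminator between coding and
# noncoding DNA based on base periodicity (position) and composition
# (content).  Thresholds are scanned in descending order; the first row whose
# threshold the observed value reaches supplies the probability.

_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, para: list[float], probs: list[float]) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence (length >= 6)."""
    seq = seq.upper()
    if len(seq) < 6:
        raise IsokitError("Fickett statistic requires length >= 6")
    counts = np.zeros((4, 3), dtype=float)  # base x (position mod 3)
    for i, b in enumerate(seq):
        j = _BASE_IDX.get(b)
        if j is not None:
            counts[j, i % 3] += 1
    score = 0.0
    for b in _BASES:
        row = counts[_BASE_IDX[b]]
        position_value = row.max() / (row.min() + 1.0)
        content_value = row.sum() / len(seq)
        score += _lookup(position_value, _POSITION_PARA, _POSITION_PROB[b]) * _POSITION_WEIGHT[b]
        score += _lookup(content_value, _CONTENT_PARA, _CONTENT_PROB[b]) * _CONTENT_WEIGHT[b]
    return score


# ---------------------------------------------------------------------------
# hexamer usage model
# ---------------------------------------------------------------------------

def _hexamer_index(hexamer: str) -> int | None:
    idx = 0
    for b in hexamer:
        j = _BASE_IDX.get(b)
        if j is None:
            return None  # hexamers containing N are skipped
        idx = idx * 4 + j
    return idx


@dataclass
class HexamerTable:
    """In-frame hexamer frequencies for coding vs noncoding sequences."""

    coding_freq: np.ndarray   # shape (4096,), sums to 1
    noncoding_freq: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.coding_freq, self.noncoding_freq):
            if arr.shape != (4096,) or not np.all(arr > 0):
                raise ValidationError("hexamer frequencies must be positive, length 4096")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValidationError("hexamer frequencies must sum to 1")

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log(self.coding_freq / self.noncoding_freq)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hexamer\tcoding_freq\tnoncoding_freq\n")
            for i in range(4096):
                h = "".join(_BASES[(i >> (2 * k)) & 3] for k in range(5, -1, -1))
                fh.write(f"{h}\t{self.coding_freq[i]:.10e}\t{self.noncoding_freq[i]:.10e}\n")

    @classmethod
    def from_tsv(cls, path) -> "HexamerTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        c = np.zeros(4096)
        n = np.zeros(4096)
        for h, cf, nf in zip(df["hexamer"], df["coding_freq"], df["noncoding_freq"]):
            c[_hexamer_index(h)] = cf
            n[_hexamer_index(h)] = nf
        return cls(c / c.sum(), n / n.sum())


def _count_hexamers(seqs, step: int) -> np.ndarray:
    counts = np.zeros(4096, dtype=float)
    for seq in seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - 5, step):
            idx = _hexamer_index(seq[i:i + 6])
            if idx is not None:
                counts[idx] += 1
    return counts


def train_hexamer_table(coding_seqs, noncoding_seqs, pseudocount: float = 1.0) -> HexamerTable:
    """Hexamer table: in-frame (step 3) for coding, all frames for noncoding."""
    if not coding_seqs or not noncoding_seqs:
        raise IsokitError("both sequence classes must be non-empty")
    c = _count_hexamers(coding_seqs, step=3) + pseudocount
    n = _count_hexamers(noncoding_seqs, step=1) + pseudocount
    return HexamerTable(c / c.sum(), n / n.sum())


def hexamer_score(seq: str, table: HexamerTable) -> float:
    """Mean in-frame hexamer log-odds log(coding/noncoding) along ``seq``."""
    seq = seq.upper()
    if len(seq) < 6:
        raise IsokitError("hexamer score requires length >= 6")
    lr = table.log_ratio
    total, count = 0.0, 0
    for i in range(0, len(seq) - 5, 3):
        idx = _hexamer_index(seq[i:i + 6])
        if idx is not None:
            total += lr[idx]
            count += 1
    return total / count if count else 0.0


# ---------------------------------------------------------------------------
# logistic coding-potential model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingScore:
    orf_length: int
    orf_coverage: float
    fickett: float
    hexamer: float
    probability: float = float("nan")

    def features(self) -> np.ndarray:
        return np.array(
            [math.log(self.orf_length), self.orf_coverage, self.fickett, self.hexamer]
        )


@dataclass
class CodingModel:
    """Logistic combiner over (log ORF length, coverage, Fickett, hexamer)."""

    coef: np.ndarray        # shape (4,)
    intercept: float
    ridge_fallback: bool = False

    def probability(self, score: CodingScore) -> float:
        z = float(self.coef @ score.features() + self.intercept)
        return 1.0 / (1.0 + math.exp(-z))

    def to_tsv(self, path) -> None:
        names = ["log_orf_length", "orf_coverage", "fickett", "hexamer"]
        with open(path, "w") as fh:
            fh.write("term\tcoefficient\n")
            fh.write(f"intercept\t{self.intercept:.10e}\n")
            for name, c in zip(names, self.coef):
                fh.write(f"{name}\t{c:.10e}\n")
            fh.write(f"ridge_fallback\t{int(self.ridge_fallback)}\n")

    @classmethod
    def from_tsv(cls, path) -> "CodingModel":
        import pandas as pd

        df = pd.read_csv(path, sep="\t").set_index("term")["coefficient"]
        names = ["log_orf_length", "orf_coverage", "fickett", "hexamer"]
        return cls(
            coef=np.array([float(df[n]) for n in names]),
            intercept=float(df["intercept"]),
            ridge_fallback=bool(int(df.get("ridge_fallback", 0))),
        )


def fit_coding_model(scores: list[CodingScore], labels) -> CodingModel:
    """Maximum-likelihood logistic fit; falls back to ridge on separation."""
    from sklearn.linear_model import LogisticRegression

    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise IsokitError("both coding and noncoding labels are required")
    X = np.vstack([s.features() for s in scores])

    clf = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-10)
    clf.fit(X, y)
    # perfect training classification means the classes are linearly
    # separable, so the unpenalized MLE does not exist: refit with ridge
    if np.all(clf.predict(X) == y):
        clf = LogisticRegression(C=1.0, max_iter=2000, tol=1e-10)
        clf.fit(X, y)
        return CodingModel(clf.coef_[0].copy(), float(clf.intercept_[0]), True)
    return CodingModel(clf.coef_[0].copy(), float(clf.intercept_[0]), False)


def score_orf(seq: str, cand: OrfCandidate, table: HexamerTable,
              model: CodingModel | None = None) -> CodingScore:
    """Coding-potential features (and probability, if a model is given)."""
    orf_seq = seq[cand.t_start:cand.t_end]
    score = CodingScore(
        orf_length=cand.length_nt,
        orf_coverage=cand.length_nt / len(seq),
        fickett=fickett_score(orf_seq),
        hexamer=hexamer_score(orf_seq, table),
    )
    if model is not None:
        score = replace(score, probability=model.probability(score))
    return score


def select_orf(scored: list[tuple[OrfCandidate, CodingScore]],
               threshold: float = 0.5) -> tuple[OrfCandidate, CodingScore] | None:
    """Candidate with the highest coding probability, if it clears threshold.

    Ties break toward the longer ORF, then the 5'-most start.
    """
    if not scored:
        return None
    best = max(scored, key=lambda cs: (cs[1].probability, cs[0].length_nt, -cs[0].t_start))
    if best[1].probability < threshold:
        return None
    return best


# ---------------------------------------------------------------------------
# writing ORFs back into the model, uORF and NMD attributes
# ---------------------------------------------------------------------------

def annotate_cds(tx: Transcript, orf: OrfCandidate) -> Transcript:
    """Return a copy of ``tx`` with the ORF written as CDS intervals.

    The stop codon is excluded from CDS records (GENCODE convention);
    3'-incomplete ORFs are written in full and flagged ``cds_incomplete``.
    Refuses to overwrite reference CDS annotation.
    """
    if tx.cds:
        raise IsokitError(f"{tx.transcript_id} already has CDS annotation")
    cds_end = orf.t_end - 3 if orf.has_stop else orf.t_end
    if not 0 <= orf.t_start < cds_end <= tx.spliced_length:
        raise CoordinateError(f"ORF [{orf.t_start}, {orf.t_end}) outside transcript")
    intervals = project_interval(tx, orf.t_start, cds_end)
    attrs = dict(tx.attributes)
    attrs["orf_source"] = "predicted"
    if not orf.has_stop:
        attrs["cds_incomplete"] = "True"
    return replace(tx, cds=intervals, attributes=attrs)


def _cds_t_range(tx: Transcript) -> tuple[int, int]:
    if not tx.cds:
        raise CoordinateError(f"{tx.transcript_id} has no CDS")
    return tx.cds_transcript_range()


def detect_uorf(tx: Transcript, genome) -> bool:
    """True iff the 5' UTR holds a complete ATG-initiated mini-ORF (>= 9 nt).

    The upstream ORF must terminate at or before the main CDS start, i.e. lie
    fully within the 5' UTR.
    """
    cds_start, _ = _cds_t_range(tx)
    utr = spliced_sequence(tx, genome)[:cds_start]
    for cand in enumerate_orfs(utr, min_len_nt=9):
        if cand.has_stop:
            return True
    return False


def predict_nmd(tx: Transcript) -> bool:
    """Predicted NMD susceptibility by the 50-nt rule.

    True iff the stop codon starts more than 50 nt upstream of the last
    exon-exon junction in transcript coordinates; single-exon transcripts are
    never NMD candidates.
    """
    _, cds_end = _cds_t_range(tx)
    if len(tx.exons) < 2:
        return False
    last_exon = tx.exons[0] if tx.strand == "-" else tx.exons[-1]
    last_junction = tx.spliced_length - len(last_exon)
    return last_junction - cds_end > 50


def annotate_models(models: list[GeneModel], genome, table: HexamerTable,
                    model: CodingModel, min_len_nt: int = 75,
                    threshold: float = 0.5) -> tuple[list[GeneModel], list[dict]]:
    """Predict and write CDS for every CDS-less transcript in ``models``.

    Returns the augmented models plus a per-transcript report of the decision
    (selected ORF coordinates and probability, or the reason none was kept).
    """
    report: list[dict] = []
    out_models: list[GeneModel] = []
    for gm in models:
        new_txs = []
        for tx in gm.transcripts:
            if tx.cds:
                new_txs.append(tx)
                continue
            seq = spliced_sequence(tx, genome)
            cands = enumerate_orfs(seq, min_len_nt=min_len_nt)
            scored = [(c, score_orf(seq, c, table, model)) for c in cands]
            best = select_orf(scored, threshold=threshold)
            if best is None:
                report.append({"transcript_id": tx.transcript_id, "status": "noncoding",
                               "n_candidates": len(cands)})
                new_txs.append(tx)
            else:
                cand, score = best
                new_txs.append(annotate_cds(tx, cand))
                report.append({"transcript_id": tx.transcript_id, "status": "annotated",
                               "t_start": cand.t_start, "t_end": cand.t_end,
                               "frame": cand.frame, "probability": score.probability,
                               "n_candidates": len(cands)})
        out_models.append(GeneModel(gm.gene_id, new_txs))
    return out_models, report
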