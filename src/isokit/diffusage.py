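"""Differential isoform usage (DIU) within genes.

Counts over a gene's isoforms are modelled as Dirichlet-multinomial (DM):
a multinomial over k isoforms whose per-sample proportions are themselves
Dirichlet-distributed with concentration ``precision * proportions``, which
captures the between-sample overdispersion of usage typical of real data.
A gene-level likelihood-ratio test compares group-specific proportion
vectors (shared precision) against shared proportions; per-transcript tests
collapse the gene to "this isoform vs the rest" (beta-binomial, 1 df).
Multiplicity is controlled stage-wise: Benjamini-Hochberg screening on gene
p-values, then within screened genes a Holm-Sidak confirmation of transcript
p-values at a significance level scaled by the screening pass rate, so that
the overall false discovery rate is controlled at the target level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import IsokitError, SchemaError, ValidationError
from .diffexpr import CountMatrix, SampleDesign, bh_adjust
from .genemodels import GeneModel

__all__ = [
    "UsageTable",
    "DMFit",
    "DIUResult",
    "build_usage_tables",
    "dm_loglik",
    "fit_dm",
    "gene_lrt",
    "transcript_test",
    "stagewise_correct",
    "delta_usage",
    "run_diu",
    "load_diu_table",
    "write_diu_table",
]


@dataclass
class UsageTable:
    """Counts over one gene's isoforms across samples (samples x k)."""

    gene_id: str
    transcript_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_samples, k)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.transcript_ids) < 2:
            raise ValidationError(f"{self.gene_id}: usage needs >= 2 transcripts")
        if self.counts.shape != (len(self.sample_ids), len(self.transcript_ids)):
            raise ValidationError(f"{self.gene_id}: counts shape mismatch")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def usable(self) -> np.ndarray:
        """Samples with a positive gene total (others are dropped from fits)."""
        return self.totals > 0

    def proportions(self) -> np.ndarray:
        """Per-sample usage proportions; NaN rows for zero-total samples."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / self.totals[:, None]


@dataclass
class DMFit:
    proportions: np.ndarray
    precision: float
    loglik: float

    def __post_init__(self) -> None:
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValidationError("DM proportions must lie on the simplex")
        if not np.isfinite(self.precision) or self.precision <= 0:
            raise ValidationError("DM precision must be positive and finite")


@dataclass
class DIUResult:
    """One transcript's row of the DIU output (gene-level fields repeated)."""

    gene_id: str
    transcript_id: str
    usage_control: float
    usage_case: float
    delta_usage: float
    gene_p: float
    gene_q: float
    tx_p: float
    tx_p_adjusted: float
    confirmed: bool


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_usage_tables(counts: CountMatrix, models: list[GeneModel],
                       min_gene_count: int = 10
                       ) -> tuple[list[UsageTable], list[tuple[str, str]]]:
    """Per-gene usage tables for genes with >= 2 expressed isoforms.

    Genes whose total count falls below ``min_gene_count`` in more than half
    the samples are excluded; the second return value reports every excluded
    gene with its reason.
    """
    tx2gene = {t.transcript_id: gm.gene_id for gm in models for t in gm.transcripts}
    unknown = [t for t in counts.transcript_ids if t not in tx2gene]
    if unknown:
        raise IsokitError(f"transcripts absent from the annotation: {unknown[:10]}")
    by_gene: dict[str, list[int]] = {}
    for i, t in enumerate(counts.transcript_ids):
        by_gene.setdefault(tx2gene[t], []).append(i)

    tables: list[UsageTable] = []
    excluded: list[tuple[str, str]] = []
    for gene_id in sorted(by_gene):
        rows = by_gene[gene_id]
        sub = counts.counts[rows].T.astype(float)  # samples x k
        expressed = sub.sum(axis=0) > 0
        if expressed.sum() < 2:
            excluded.append((gene_id, "fewer_than_2_expressed_transcripts"))
            continue
        sub = sub[:, expressed]
        tids = [counts.transcript_ids[rows[j]] for j in np.where(expressed)[0]]
        totals = sub.sum(axis=1)
        if np.sum(totals < min_gene_count) > len(totals) / 2:
            excluded.append((gene_id, "low_gene_count"))
            continue
        tables.append(UsageTable(gene_id, tids, list(counts.sample_ids), sub))
    return tables, excluded


# ---------------------------------------------------------------------------
# Dirichlet-multinomial likelihood and fits
# ---------------------------------------------------------------------------

def dm_loglik(counts: np.ndarray, proportions: np.ndarray, precision: float) -> float:
    """Sum over samples of the log Dirichlet-multinomial pmf."""
    y = np.asarray(counts, dtype=float)
    n = y.sum(axis=1)
    alpha = precision * np.asarray(proportions, dtype=float)
    ll = (special.gammaln(n + 1.0) - special.gammaln(y + 1.0).sum(axis=1)
          + special.gammaln(precision) - special.gammaln(n + precision)
          + (special.gammaln(y + alpha[None, :])
             - special.gammaln(alpha)[None, :]).sum(axis=1))
    return float(ll.sum())


_Z_BOUND = 30.0
_LOG_PREC_BOUNDS = (np.log(1e-3), np.log(1e7))


def _softmax_full(z: np.ndarray) -> np.ndarray:
    u = np.concatenate([z, [0.0]])
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


def _dm_negloglik_grad(y: np.ndarray, z: np.ndarray, t: float):
    """Negative DM log-likelihood and its gradient in (z, t = log precision)."""
    p = _softmax_full(z)
    s = np.exp(t)
    alpha = s * p
    n = y.sum(axis=1)
    ll = (special.gammaln(n + 1.0) - special.gammaln(y + 1.0).sum(axis=1)
          + special.gammaln(s) - special.gammaln(n + s)
          + (special.gammaln(y + alpha[None, :])
             - special.gammaln(alpha)[None, :]).sum(axis=1)).sum()
    g_alpha = (special.digamma(y + alpha[None, :])
               - special.digamma(alpha)[None, :]).sum(axis=0)
    d_s = (special.digamma(s) - special.digamma(n + s)).sum() + g_alpha @ p
    gbar = g_alpha @ p
    d_u = s * p * (g_alpha - gbar)
    grad = np.concatenate([d_u[:-1], [s * d_s]])
    return -ll, -grad


def _pooled_start(y: np.ndarray) -> np.ndarray:
    pooled = y.sum(axis=0) + 0.5
    p0 = pooled / pooled.sum()
    z0 = np.log(p0[:-1]) - np.log(p0[-1])
    return np.clip(z0, -_Z_BOUND, _Z_BOUND)


def fit_dm(counts: np.ndarray) -> DMFit:
    """Maximum-likelihood DM fit over k >= 2 categories.

    Deterministic: starts from pooled proportions and precision 10, optimized
    by bounded quasi-Newton (L-BFGS-B, tolerance 1e-8) on logit-transformed
    proportions and log precision.  Zero-total samples are dropped.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise IsokitError("DM fit needs a samples x k matrix with k >= 2")
    y = y[y.sum(axis=1) > 0]
    if len(y) == 0:
        raise IsokitError("no sample has a positive total")
    k = y.shape[1]
    x0 = np.concatenate([_pooled_start(y), [np.log(10.0)]])
    bounds = [(-_Z_BOUND, _Z_BOUND)] * (k - 1) + [_LOG_PREC_BOUNDS]

    def objective(x):
        return _dm_negloglik_grad(y, x[:-1], x[-1])

    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                            bounds=bounds, options={"ftol": 1e-8, "gtol": 1e-8,
                                                    "maxiter": 500})
    p = _softmax_full(res.x[:-1])
    s = float(np.exp(res.x[-1]))
    return DMFit(p, s, -float(res.fun))


def _fit_dm_two_groups(y_ctrl: np.ndarray, y_case: np.ndarray) -> float:
    """Max log-likelihood of group-specific proportions with shared precision."""
    k = y_ctrl.shape[1]
    z0 = _pooled_start(np.vstack([y_ctrl, y_case]))
    x0 = np.concatenate([z0, z0, [np.log(10.0)]])
    bounds = [(-_Z_BOUND, _Z_BOUND)] * (2 * (k - 1)) + [_LOG_PREC_BOUNDS]

    def objective(x):
        z1, z2, t = x[:k - 1], x[k - 1:2 * (k - 1)], x[-1]
        f1, g1 = _dm_negloglik_grad(y_ctrl, z1, t)
        f2, g2 = _dm_negloglik_grad(y_case, z2, t)
        grad = np.concatenate([g1[:-1], g2[:-1], [g1[-1] + g2[-1]]])
        return f1 + f2, grad

    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                            bounds=bounds, options={"ftol": 1e-8, "gtol": 1e-8,
                                                    "maxiter": 500})
    return -float(res.fun)


def _group_counts(table: UsageTable, design: SampleDesign):
    usable = table.usable
    ctrl = design.mask(table.sample_ids, design.control) & usable
    case = design.mask(table.sample_ids, design.case) & usable
    return table.counts[ctrl], table.counts[case]


def gene_lrt(table: UsageTable, design: SampleDesign) -> float:
    """Gene-level DM likelihood-ratio p-value (chi-square, k - 1 df)."""
    y_ctrl, y_case = _group_counts(table, design)
    if len(y_ctrl) < 2 or len(y_case) < 2:
        raise IsokitError(
            f"{table.gene_id}: need >= 2 usable samples per group"
        )
    ll_null = fit_dm(np.vstack([y_ctrl, y_case])).loglik
    ll_full = _fit_dm_two_groups(y_ctrl, y_case)
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    df = len(table.transcript_ids) - 1
    return float(stats.chi2.sf(stat, df))


def transcript_test(table: UsageTable, design: SampleDesign,
                    transcript_id: str) -> float:
    """Per-transcript usage p-value: one-vs-rest beta-binomial LRT (1 df)."""
    j = table.transcript_ids.index(transcript_id)
    collapsed = np.stack([table.counts[:, j],
                          table.counts.sum(axis=1) - table.counts[:, j]], axis=1)
    two_col = UsageTable(table.gene_id, [transcript_id, "__rest__"],
                         table.sample_ids, collapsed)
    y_ctrl, y_case = _group_counts(two_col, design)
    if len(y_ctrl) < 2 or len(y_case) < 2:
        raise IsokitError(f"{table.gene_id}: need >= 2 usable samples per group")
    ll_null = fit_dm(np.vstack([y_ctrl, y_case])).loglik
    ll_full = _fit_dm_two_groups(y_ctrl, y_case)
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    return float(stats.chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# stage-wise correction and effect size
# ---------------------------------------------------------------------------

def _holm_sidak(p: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        val = 1.0 - (1.0 - p[i]) ** (m - rank)
        running = max(running, val)
        adj[i] = min(running, 1.0)
    return adj


def stagewise_correct(gene_ps: dict[str, float],
                      tx_ps: dict[str, dict[str, float]],
                      alpha: float = 0.05):
    """Two-stage FDR control: gene screening, then in-gene confirmation.

    Screening applies BH to the gene p-values at ``alpha``.  Within each
    screened gene the transcript p-values are Holm-Sidak adjusted and tested
    against the level ``alpha * n_screened / n_genes``; transcripts of
    unscreened genes are never confirmed.  Reported transcript adjusted
    p-values are rescaled to the overall ``alpha`` scale (adjusted * n_genes
    / n_screened, capped at 1) so that confirmed <=> tx_p_adjusted <= alpha.
    """
    for g in tx_ps:
        if g not in gene_ps:
            raise IsokitError(f"transcript p-values for unknown gene {g!r}")
    genes = sorted(gene_ps)
    gene_q = dict(zip(genes, bh_adjust([gene_ps[g] for g in genes])))
    screened = {g for g in genes if gene_q[g] <= alpha}
    scale = len(genes) / len(screened) if screened else float("inf")

    tx_adj: dict[str, dict[str, float]] = {}
    confirmed: dict[str, dict[str, bool]] = {}
    for g in genes:
        tmap = tx_ps.get(g, {})
        tids = sorted(tmap)
        if not tids:
            tx_adj[g], confirmed[g] = {}, {}
            continue
        adj = _holm_sidak(np.array([tmap[t] for t in tids]))
        if g in screened:
            rescaled = np.minimum(adj * scale, 1.0)
            conf = rescaled <= alpha
        else:
            rescaled = np.ones_like(adj)
            conf = np.zeros(len(adj), dtype=bool)
        tx_adj[g] = dict(zip(tids, rescaled.tolist()))
        confirmed[g] = dict(zip(tids, conf.tolist()))
    return gene_q, screened, tx_adj, confirmed


def delta_usage(table: UsageTable, design: SampleDesign) -> dict[str, float]:
    """Case-minus-control difference in mean per-sample usage proportions."""
    props = table.proportions()
    out: dict[str, float] = {}
    ctrl = design.mask(table.sample_ids, design.control) & table.usable
    case = design.mask(table.sample_ids, design.case) & table.usable
    if not ctrl.any() or not case.any():
        raise IsokitError(f"{table.gene_id}: a group has no usable sample")
    mean_ctrl = props[ctrl].mean(axis=0)
    mean_case = props[case].mean(axis=0)
    for j, t in enumerate(table.transcript_ids):
        out[t] = float(mean_case[j] - mean_ctrl[j])
    return out


def group_mean_usage(table: UsageTable, design: SampleDesign, group: str) -> np.ndarray:
    mask = design.mask(table.sample_ids, group) & table.usable
    if not mask.any():
        raise IsokitError(f"{table.gene_id}: group {group!r} has no usable sample")
    return table.proportions()[mask].mean(axis=0)


def run_diu(counts: CountMatrix, models: list[GeneModel], design: SampleDesign,
            alpha: float = 0.05, min_gene_count: int = 10
            ) -> tuple[list[DIUResult], list[tuple[str, str]]]:
    """Full DIU pipeline: usage tables -> LRTs -> stage-wise correction."""
    tables, excluded = build_usage_tables(counts, models, min_gene_count)
    gene_ps: dict[str, float] = {}
    tx_ps: dict[str, dict[str, float]] = {}
    kept: list[UsageTable] = []
    for table in tables:
        try:
            gene_ps[table.gene_id] = gene_lrt(table, design)
        except IsokitError as exc:
            excluded.append((table.gene_id, f"skipped: {exc}"))
            continue
        tx_ps[table.gene_id] = {
            t: transcript_test(table, design, t) for t in table.transcript_ids
        }
        kept.append(table)

    gene_q, screened, tx_adj, confirmed = stagewise_correct(gene_ps, tx_ps, alpha)
    results: list[DIUResult] = []
    for table in kept:
        g = table.gene_id
        u_ctrl = group_mean_usage(table, design, design.control)
        u_case = group_mean_usage(table, design, design.case)
        for j, t in enumerate(table.transcript_ids):
            results.append(DIUResult(
                gene_id=g, transcript_id=t,
                usage_control=float(u_ctrl[j]), usage_case=float(u_case[j]),
                delta_usage=float(u_case[j] - u_ctrl[j]),
                gene_p=gene_ps[g], gene_q=float(gene_q[g]),
                tx_p=tx_ps[g][t], tx_p_adjusted=float(tx_adj[g][t]),
                confirmed=bool(confirmed[g][t]),
            ))
    return results, excluded


DIU_COLUMNS = ["gene_id", "transcript_id", "usage_control", "usage_case",
               "delta_usage", "gene_p", "gene_q", "tx_p", "tx_p_adjusted",
               "confirmed"]


def write_diu_table(results: list[DIUResult], path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in DIU_COLUMNS} for r in results])
    if df.empty:
        df = pd.DataFrame(columns=DIU_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def load_diu_table(path) -> list[DIUResult]:
    """Read a (possibly externally produced) DIU table; validates the schema."""
    df = pd.read_csv(path, sep="\t")
    for col in DIU_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"DIU table is missing required column {col!r}")
    out = []
    for i, row in df.iterrows():
        if abs(float(row["delta_usage"])) > 1.0 + 1e-9:
            raise ValidationError(f"row {i}: |delta_usage| > 1")
        out.append(DIUResult(*[row[c] for c in DIU_COLUMNS]))
    return out
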