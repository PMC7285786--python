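"""Two-group differential expression with empirical-Bayes variance moderation.

The model is the standard microarray moderated t-test: per gene a two-group
mean contrast on log2 intensities, a pooled residual variance ``s^2`` on
``d = n1 + n2 - 2`` degrees of freedom, and shrinkage of the gene-wise
variances toward a common prior,

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

where the prior ``(d0, s0^2)`` is estimated by matching the first two moments
of ``log s^2`` across genes against a scaled-F marginal (Smyth 2004).  The
moderated t is the mean contrast divided by ``s_tilde * sqrt(1/n1 + 1/n2)``
on ``d0 + d`` degrees of freedom; with ``d0 = 0`` it reduces exactly to the
ordinary pooled-variance two-sample t-test.

The surface is a small statsmodels-style pair: :class:`TwoGroupDE` is built
from an :class:`~sigcollapse.io_formats.ExpressionMatrix` and ``fit()``
returns a :class:`DEResults` carrying the per-gene table, the estimated
prior, and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, FormatError

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["log2FC", "t", "p", "p_adj", "direction"]


# ---------------------------------------------------------------------------
# Transcript -> gene collapse
# ---------------------------------------------------------------------------


def collapse_transcripts(transcript_matrix: ExpressionMatrix,
                         annotation: Mapping[str, Sequence[str] | str],
                         crosshyb_min: int = 2) -> ExpressionMatrix:
    """Collapse a transcript-level matrix to gene level.

    Transcripts annotated to ``crosshyb_min`` or more distinct genes are
    discarded as cross-hybridizing; among the transcripts of one gene, the
    one with the highest mean expression across all samples (the most
    detectable) is kept.

    Parameters
    ----------
    annotation : mapping
        Transcript id -> gene symbol or list of gene symbols; must cover
        every transcript in the matrix.
    crosshyb_min : int
        Minimum number of distinct annotated genes at which a transcript is
        treated as cross-hybridizing (default 2).
    """
    missing = sorted(set(transcript_matrix.genes) - set(annotation))
    if missing:
        raise FormatError(f"transcripts missing from annotation: {missing[:10]}")

    means = transcript_matrix.values.mean(axis=1)
    best: dict[str, tuple[float, str]] = {}
    for transcript in transcript_matrix.genes:
        genes = annotation[transcript]
        if isinstance(genes, str):
            genes = [genes]
        genes = sorted(set(genes))
        if len(genes) >= crosshyb_min:
            logger.debug("dropping cross-hybridizing transcript %s -> %s", transcript, genes)
            continue
        gene = genes[0]
        score = (means[transcript], transcript)
        if gene not in best or score > best[gene]:
            best[gene] = score
    if not best:
        raise FormatError("no transcripts left after cross-hybridization filtering")

    rows = {gene: transcript_matrix.values.loc[t] for gene, (_, t) in best.items()}
    collapsed = pd.DataFrame(rows).T
    collapsed.columns = transcript_matrix.samples
    return ExpressionMatrix(collapsed, transcript_matrix.group, transcript_matrix.timepoint)


# ---------------------------------------------------------------------------
# Empirical-Bayes prior estimation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on the trigamma function; monotone and fast.
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0^2`` by matching the
    mean and variance of ``log s^2`` across genes (scaled-F moments).

    Returns ``(inf, exp(mean))`` when the observed spread of ``log s^2`` is no
    larger than expected from chi-square sampling alone (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need at least two positive gene variances to estimate the prior")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    ebar = float(e.mean())
    evar = float(e.var(ddof=1))
    target = evar - float(special.polygamma(1, d / 2.0))
    if target <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(target)
    s02 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


@dataclass
class DEResults:
    """Fitted differential-expression results.

    Attributes
    ----------
    table : pandas.DataFrame
        Per-gene ``log2FC`` (case mean - control mean), moderated ``t``,
        two-sided ``p``, Benjamini-Hochberg ``p_adj`` and ``direction``.
    prior_df, prior_var : float
        Estimated empirical-Bayes prior ``(d0, s0^2)``; ``(0, nan)`` when
        moderation is off.
    residual_df : int
        Per-gene residual degrees of freedom ``n1 + n2 - 2``.
    """

    table: pd.DataFrame
    prior_df: float
    prior_var: float
    residual_df: int
    n_case: int
    n_control: int

    def select_degs(self, lfc_threshold: float = 0.5, alpha: float = 0.05) -> pd.DataFrame:
        return select_degs(self.table, lfc_threshold=lfc_threshold, alpha=alpha)

    def summary(self, top: int = 10) -> str:
        lines = [
            "Two-group differential expression (moderated t)",
            f"  genes: {len(self.table)}   case/control: {self.n_case}/{self.n_control}",
            f"  residual df: {self.residual_df}   prior df (d0): {self.prior_df:.4g}"
            f"   prior variance (s0^2): {self.prior_var:.4g}",
            f"  genes with p_adj < 0.05: {int((self.table['p_adj'] < 0.05).sum())}",
            "",
            self.table.sort_values("p").head(top).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class TwoGroupDE:
    """Moderated two-group differential-expression model.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log2 expression with case/control labels, at least two samples per
        group.
    prior_df_mode : {"moments", "off"}
        ``"moments"`` estimates the empirical-Bayes prior by the method of
        moments on ``log s^2``; ``"off"`` sets ``d0 = 0`` (ordinary t-test).
    """

    def __init__(self, matrix: ExpressionMatrix, prior_df_mode: str = "moments"):
        if prior_df_mode not in ("moments", "off"):
            raise ValueError(f"unknown prior_df_mode {prior_df_mode!r}")
        self.matrix = matrix
        self.prior_df_mode = prior_df_mode

    def fit(self) -> DEResults:
        m = self.matrix
        case = m.values[m.case_samples].to_numpy()
        ctrl = m.values[m.control_samples].to_numpy()
        n1, n2 = case.shape[1], ctrl.shape[1]
        d = n1 + n2 - 2

        lfc = case.mean(axis=1) - ctrl.mean(axis=1)
        ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
            + ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s2 = ss / d
        scale = np.sqrt(1.0 / n1 + 1.0 / n2)

        if self.prior_df_mode == "moments":
            d0, s02 = estimate_variance_prior(s2, d)
            if np.isinf(d0):
                s2_post = np.full_like(s2, s02)
                df_total = np.inf
            else:
                s2_post = (d0 * s02 + d * s2) / (d0 + d)
                df_total = d0 + d
        else:
            d0, s02 = 0.0, float("nan")
            s2_post = s2.copy()
            df_total = float(d)

        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / (np.sqrt(s2_post) * scale)
        zero_var = s2_post == 0
        if zero_var.any():
            logger.warning("%d genes with zero variance in both groups; "
                           "p set to 0 (log2FC != 0) or 1", int(zero_var.sum()))
            with np.errstate(invalid="ignore"):
                t[zero_var] = np.where(lfc[zero_var] != 0,
                                       np.sign(lfc[zero_var]) * np.inf, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p[zero_var] = np.where(lfc[zero_var] != 0, 0.0, 1.0)

        table = pd.DataFrame({
            "log2FC": lfc,
            "t": t,
            "p": p,
            "p_adj": benjamini_hochberg(p),
            "direction": np.where(lfc > 0, "up", "down"),
        }, index=m.values.index)
        table.index.name = "gene"
        return DEResults(table=table, prior_df=d0, prior_var=s02,
                         residual_df=d, n_case=n1, n_control=n2)


def differential_expression(m: ExpressionMatrix, prior_df_mode: str = "moments") -> pd.DataFrame:
    """Functional shorthand for ``TwoGroupDE(m, prior_df_mode).fit().table``."""
    return TwoGroupDE(m, prior_df_mode=prior_df_mode).fit().table


# ---------------------------------------------------------------------------
# Multiple testing and DEG selection
# ---------------------------------------------------------------------------


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(table: pd.DataFrame, lfc_threshold: float = 0.5,
                alpha: float = 0.05, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Select differentially expressed genes.

    Keeps genes with ``|log2FC| > lfc_threshold`` and ``p < alpha`` (both
    strict), and flags ``fdr_passing`` genes with ``p_adj < fdr_alpha`` —
    those are strong enough to stand as individual signatures.
    """
    if lfc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    kept = table[(table["log2FC"].abs() > lfc_threshold) & (table["p"] < alpha)].copy()
    kept["fdr_passing"] = kept["p_adj"] < fdr_alpha
    return kept


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
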