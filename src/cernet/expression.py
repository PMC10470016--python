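"""Normalisation, filtering, differential expression and qPCR arithmetic.

TPM and FPKM views of a count matrix, the FPKM >= 1 expression filter, a
Welch-t two-group differential-expression caller with the |log2FC| > 1 and
p < 0.001 decision rule, sample-level diagnostics (pairwise correlation and
PCA), DE summary counting, and relative qPCR quantification by 2^-ddCt.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import DEResult, ExpressionMatrix

#: decision thresholds for calling a transcript differentially expressed
LFC_THRESHOLD = 1.0
P_THRESHOLD = 0.001
#: pseudo-count added to FPKM group means before the fold-change log
PSEUDOCOUNT = 1.0


def compute_tpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Transcripts-per-million: length-normalised rates scaled to 1e6/sample."""
    rate = matrix.counts.div(matrix.lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0].index.tolist()
    if zero:
        warnings.warn(f"all-zero sample column(s) {zero}: TPM undefined there")
        colsum = colsum.replace(0, np.nan)
    return rate.div(colsum, axis=1) * 1e6


def compute_fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    FPKM_ij = count_ij * 1e9 / (length_i * library_size_j).
    """
    libsize = matrix.counts.sum(axis=0)
    zero = libsize[libsize == 0].index.tolist()
    if zero:
        warnings.warn(f"zero library size in sample(s) {zero}: FPKM undefined there")
        libsize = libsize.replace(0, np.nan)
    return matrix.counts.mul(1e9).div(matrix.lengths, axis=0).div(libsize, axis=1)


def filter_low_expression(fpkm: pd.DataFrame, threshold: float = 1.0) -> list[str]:
    """Ids of transcripts with FPKM >= threshold in at least one sample
    (transcripts below threshold in every sample are filtered out)."""
    keep = (fpkm >= threshold).any(axis=1)
    return fpkm.index[keep].tolist()


def classify_direction(log2fc: float, p: float,
                       lfc_threshold: float = LFC_THRESHOLD,
                       p_threshold: float = P_THRESHOLD) -> str:
    """DE direction label: up iff log2FC > 1 and p < 0.001 (strict), down
    iff log2FC < -1 and p < 0.001, else ns."""
    if p < p_threshold and log2fc > lfc_threshold:
        return "up"
    if p < p_threshold and log2fc < -lfc_threshold:
        return "down"
    return "ns"


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str = "A",
    group_c: str = "C",
    known_flags: dict[str, bool] | None = None,
    apply_expression_filter: bool = True,
    bh_correct: bool = False,
) -> list[DEResult]:
    """Two-group DE call on FPKM.

    log2FC = log2((mean_A + c) / (mean_C + c)) with pseudo-count c = 1 on
    group-mean FPKM; p from a Welch two-sample t-test on log2(FPKM + 1).
    Direction is "up" iff log2FC > 1 and p < 0.001, "down" iff
    log2FC < -1 and p < 0.001, else "ns".  Transcripts with zero
    within-group variance in both groups get p = 1 with a warning.
    ``bh_correct`` applies Benjamini-Hochberg before thresholding.
    """
    a_samples = matrix.samples_in(group_a)
    c_samples = matrix.samples_in(group_c)
    if len(a_samples) < 2 or len(c_samples) < 2:
        raise ValueError("differential expression needs >= 2 samples per group")

    fpkm = compute_fpkm(matrix)
    if apply_expression_filter:
        fpkm = fpkm.loc[filter_low_expression(fpkm)]
    log_expr = np.log2(fpkm + 1.0)

    a = log_expr[a_samples].to_numpy()
    c = log_expr[c_samples].to_numpy()
    mean_a = fpkm[a_samples].mean(axis=1).to_numpy()
    mean_c = fpkm[c_samples].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_a + PSEUDOCOUNT) / (mean_c + PSEUDOCOUNT))

    degenerate = (a.var(axis=1) == 0) & (c.var(axis=1) == 0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} transcript(s) with zero variance "
                      "in both groups: p set to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, c, axis=1, equal_var=False)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        p = multipletests(p, method="fdr_bh")[1]

    known_flags = known_flags or {}
    return [
        DEResult(tid, float(log2fc[i]), float(p[i]),
                 classify_direction(float(log2fc[i]), float(p[i])),
                 known=known_flags.get(tid, True))
        for i, tid in enumerate(fpkm.index)
    ]


def sample_diagnostics(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise sample Pearson r on log2(FPKM+1), and PCA sample scores.

    Returns (correlation matrix, PCA coordinate table with per-component
    explained-variance shares in the attrs dict).
    """
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 samples for diagnostics")
    log_expr = np.log2(compute_fpkm(matrix) + 1.0)
    const = log_expr.std(axis=0) == 0
    if const.any():
        warnings.warn(f"constant sample(s) {log_expr.columns[const].tolist()}: "
                      "correlation undefined")
    corr = log_expr.corr(method="pearson")

    x = log_expr.T.to_numpy()                      # samples x transcripts
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    k = min(len(matrix.samples), 5)
    pca = pd.DataFrame(scores[:, :k], index=log_expr.columns,
                       columns=[f"PC{i+1}" for i in range(k)])
    var = s ** 2
    pca.attrs["explained_variance_ratio"] = (var / var.sum())[:k].tolist()
    return corr, pca


def summarize_de(
    results: list[DEResult],
    biotypes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Up/down/total counts per class, split by known/novel.

    Rows are RNA classes (from ``biotypes``; "all" when absent); columns
    ``up, down, total, known_up, novel_up, known_down, novel_down``, with
    total = up + down and each known+novel split summing to its column.
    """
    rows: dict[str, dict[str, int]] = {}
    for r in results:
        if r.direction == "ns":
            continue
        cls = (biotypes or {}).get(r.transcript_id, "all")
        row = rows.setdefault(cls, {c: 0 for c in (
            "up", "down", "total", "known_up", "novel_up", "known_down", "novel_down")})
        row[r.direction] += 1
        row["total"] += 1
        row[f"{'known' if r.known else 'novel'}_{r.direction}"] += 1
    if not rows:
        rows["all"] = {c: 0 for c in (
            "up", "down", "total", "known_up", "novel_up", "known_down", "novel_down")}
    return pd.DataFrame(rows).T


def ddct(
    ct: pd.DataFrame,
    reference_gene: str,
    groups: dict[str, str],
    control_group: str = "C",
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct`` is genes x samples of Ct values.  Per sample,
    dCt = Ct_target - Ct_reference; ddCt subtracts the mean dCt of the
    control-group samples; the result is 2^-ddCt (reference gene row
    excluded from the output).
    """
    if reference_gene not in ct.index:
        raise ValueError(f"reference gene {reference_gene!r} not in Ct table")
    if ct.loc[reference_gene].isna().any():
        raise ValueError("missing reference Ct in some sample")
    control_samples = [s for s in ct.columns if groups.get(s) == control_group]
    if not control_samples:
        raise ValueError(f"no samples in control group {control_group!r}")
    dct = ct.sub(ct.loc[reference_gene], axis=1)
    ddct_tab = dct.sub(dct[control_samples].mean(axis=1), axis=0)
    rel = 2.0 ** (-ddct_tab)
    return rel.drop(index=reference_gene)
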