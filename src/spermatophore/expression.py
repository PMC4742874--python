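"""FPKM quantification, replicate pooling, fold ratios and proportion tests.

Counts are unique reads per gene per library; normalised expression is

    FPKM = count * 1e9 / (gene_length_bp * total_mapped_reads)

Replicate libraries are pooled into groups by arithmetic mean FPKM,
with unique-read totals summed alongside.  Differential expression
between two groups is assessed on read *proportions* (gene count over
total mapped reads) with a pooled two-sample Z-test, optionally
inflated by a Pearson overdispersion factor estimated from the
within-group replicate proportions; p-values are corrected with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_fpkm",
    "pool_groups",
    "fold_ratio",
    "fold_ratio_table",
    "proportion_test",
    "proportion_test_table",
    "bh_fdr",
    "TestResult",
]

META_COLUMNS = ["label", "sex", "tissue", "condition", "total_mapped_reads"]


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """FPKM matrix (genes x libraries) from unique-read counts.

    ``meta`` must be indexed by library label (or carry a ``label``
    column) and provide ``total_mapped_reads`` for every counted
    library; ``gene_lengths`` is exonic length in base pairs indexed by
    gene id.
    """
    if "label" in meta.columns:
        meta = meta.set_index("label")
    missing = [lib for lib in counts.columns if lib not in meta.index]
    if missing:
        raise ValueError(f"libraries without metadata: {missing}")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths does not cover every counted gene")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")
    totals = meta.loc[counts.columns, "total_mapped_reads"].astype(float)
    if (totals < 1).any():
        raise ValueError("total_mapped_reads must be >= 1")
    fpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return fpkm


def pool_groups(
    fpkm: pd.DataFrame,
    counts: pd.DataFrame,
    grouping: Mapping[str, str],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pool libraries into named groups.

    Returns ``(group_mean_fpkm, group_read_totals)``: the arithmetic
    mean FPKM over each group's libraries and the summed unique-read
    counts.  Every key of ``grouping`` must be a counted library; a
    group with no libraries is a configuration error (cannot arise from
    a mapping, but an empty mapping is rejected).
    """
    if not grouping:
        raise ValueError("grouping is empty")
    unknown = [lib for lib in grouping if lib not in fpkm.columns]
    if unknown:
        raise ValueError(f"grouping names unknown libraries: {unknown}")
    groups: dict[str, list[str]] = {}
    for lib, grp in grouping.items():
        groups.setdefault(grp, []).append(lib)
    mean_fpkm = pd.DataFrame(
        {grp: fpkm[libs].mean(axis=1) for grp, libs in groups.items()}
    )
    read_totals = pd.DataFrame(
        {grp: counts[libs].sum(axis=1) for grp, libs in groups.items()}
    )
    return mean_fpkm, read_totals


def fold_ratio(numerator_mean: float, denominator_mean: float) -> Tuple[float, bool]:
    """Fold-change ratio between two pooled means.

    Returns ``(ratio, defined)``.  A zero denominator (with or without
    a non-zero numerator) makes the ratio undefined — such genes are
    excluded from ratio-based classification rather than coerced to
    infinity.
    """
    if denominator_mean == 0:
        return (float("nan"), False)
    return (numerator_mean / denominator_mean, True)


def fold_ratio_table(
    mean_fpkm: pd.DataFrame, numerator_group: str, denominator_group: str
) -> pd.DataFrame:
    """Vectorised :func:`fold_ratio` over all genes.

    Returns a DataFrame with columns ``ratio`` (NaN when undefined) and
    ``defined``.
    """
    num = mean_fpkm[numerator_group].to_numpy(float)
    den = mean_fpkm[denominator_group].to_numpy(float)
    defined = den != 0
    ratio = np.full(len(num), np.nan)
    ratio[defined] = num[defined] / den[defined]
    return pd.DataFrame({"ratio": ratio, "defined": defined}, index=mean_fpkm.index)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group proportion test for one gene."""

    statistic: float
    pvalue: float
    dispersion: float
    method: str


def _pearson_dispersion(
    xs: Sequence[np.ndarray], ns: Sequence[np.ndarray]
) -> float:
    """Pearson dispersion of replicate proportions, pooled over groups.

    For each group with aggregate proportion p, the statistic sums
    (x_i - n_i p)^2 / (n_i p (1 - p)) over its libraries; dividing by
    the residual degrees of freedom (libraries - groups) gives the
    inflation factor, floored at 1.  With one library per group there
    are no residual degrees of freedom and the factor is 1.
    """
    chi2 = 0.0
    df = 0
    for x, n in zip(xs, ns):
        x = np.asarray(x, float)
        n = np.asarray(n, float)
        p = x.sum() / n.sum()
        if 0.0 < p < 1.0:
            chi2 += float(((x - n * p) ** 2 / (n * p * (1.0 - p))).sum())
        df += len(x) - 1
    if df <= 0:
        return 1.0
    return max(1.0, chi2 / df)


def proportion_test(
    x_a: Sequence[int],
    n_a: Sequence[int],
    x_b: Sequence[int],
    n_b: Sequence[int],
    method: str = "ztest",
) -> TestResult:
    """Two-sample test of read proportions between library groups.

    ``x_*`` are the gene's unique-read counts per library, ``n_*`` the
    libraries' total mapped reads.  Counts are aggregated within each
    group (x = sum x_i, n = sum n_i) and compared with the pooled
    two-proportion Z statistic; ``method="overdispersed"`` divides the
    statistic by the square root of the Pearson replicate-dispersion
    factor (floored at 1), widening the test when replicate libraries
    vary more than binomial sampling allows.
    """
    if method not in ("ztest", "overdispersed"):
        raise ValueError(f"unknown method {method!r}")
    x_a = np.asarray(x_a, float)
    n_a = np.asarray(n_a, float)
    x_b = np.asarray(x_b, float)
    n_b = np.asarray(n_b, float)
    if len(x_a) == 0 or len(x_b) == 0:
        raise ValueError("each group needs at least one library")
    na, nb = n_a.sum(), n_b.sum()
    if na <= 0 or nb <= 0:
        raise ValueError("library totals must be positive")
    pa, pb = x_a.sum() / na, x_b.sum() / nb
    pooled = (x_a.sum() + x_b.sum()) / (na + nb)
    var = pooled * (1.0 - pooled) * (1.0 / na + 1.0 / nb)
    phi = 1.0
    if method == "overdispersed":
        phi = _pearson_dispersion([x_a, x_b], [n_a, n_b])
        var *= phi
    if var == 0.0:
        return TestResult(0.0, 1.0, phi, method)
    z = (pa - pb) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), phi, method)


def proportion_test_table(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    method: str = "ztest",
    fdr: bool = True,
) -> pd.DataFrame:
    """Vectorised proportion test over every gene.

    ``group_a``/``group_b`` are library labels.  Returns a DataFrame
    with ``statistic, pvalue, dispersion`` and, when ``fdr``,
    ``qvalue`` (Benjamini-Hochberg).
    """
    if "label" in meta.columns:
        meta = meta.set_index("label")
    xa = counts[list(group_a)].to_numpy(float)
    xb = counts[list(group_b)].to_numpy(float)
    na_i = meta.loc[list(group_a), "total_mapped_reads"].to_numpy(float)
    nb_i = meta.loc[list(group_b), "total_mapped_reads"].to_numpy(float)
    na, nb = na_i.sum(), nb_i.sum()
    pa = xa.sum(axis=1) / na
    pb = xb.sum(axis=1) / nb
    pooled = (xa.sum(axis=1) + xb.sum(axis=1)) / (na + nb)
    var = pooled * (1.0 - pooled) * (1.0 / na + 1.0 / nb)
    phi = np.ones(len(counts))
    if method == "overdispersed":
        df = (len(group_a) - 1) + (len(group_b) - 1)
        if df > 0:
            chi2 = np.zeros(len(counts))
            for x, n_i, n in ((xa, na_i, na), (xb, nb_i, nb)):
                p = x.sum(axis=1) / n
                ok = (p > 0) & (p < 1)
                denom = np.outer(p, n_i)
                with np.errstate(divide="ignore", invalid="ignore"):
                    contrib = ((x - denom) ** 2 / (denom * (1.0 - p)[:, None])).sum(axis=1)
                chi2[ok] += contrib[ok]
            phi = np.maximum(1.0, chi2 / df)
        var = var * phi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (pa - pb) / np.sqrt(var), 0.0)
    p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    out = pd.DataFrame(
        {"statistic": z, "pvalue": p, "dispersion": phi}, index=counts.index
    )
    if fdr:
        out["qvalue"] = bh_fdr(out["pvalue"].to_numpy())
    return out


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
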