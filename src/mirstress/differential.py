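"""Negative-binomial Wald differential-accumulation testing.

A deliberately compact NB testing engine in the DESeq2 mould: library size
factors by median-of-ratios, per-row method-of-moments dispersion (variance
mu + alpha*mu^2) with a small floor, a Wald test on the log2 fold change
with a delta-method standard error, and Benjamini-Hochberg adjustment.
Simplifications relative to the full DESeq2 machinery (no empirical-Bayes
dispersion shrinkage, no independent filtering, no outlier refitting) are
documented in the methods note.

Classification follows the study's rule: a miRNA is called up (down) iff
log2FC >= 0.6 (<= -0.6) AND the adjusted p-value is <= 0.05, both
boundaries inclusive; everything else is "unchanged". The restoration
summary cross-tabulates drought calls against rehydration calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
LOG2FC_PSEUDOCOUNT = 0.5

CALLS = ("up", "down", "unchanged")


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one positive real per library.

    The pseudo-reference is the per-row geometric mean over libraries,
    computed on rows with all counts positive; each library's factor is
    the median of its counts over the reference.
    """
    counts = matrix.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no row has positive counts in every library; "
            "median-of-ratios needs at least one (consider a pseudo-reference fallback)"
        )
    pos = counts[all_positive]
    log_geo_mean = np.log(pos).mean(axis=1)
    ratios = np.log(pos) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def _normalized(matrix: pd.DataFrame, factors: pd.Series) -> np.ndarray:
    return matrix.to_numpy(dtype=float) / factors.to_numpy(dtype=float)[None, :]


def _moment_dispersion(q_a: np.ndarray, q_b: np.ndarray) -> np.ndarray:
    """Per-row method-of-moments dispersion from normalized counts.

    Pools the within-condition sample variances (Bessel-corrected) so the
    planted condition effect does not inflate the estimate, then solves
    var = mu + alpha*mu^2 for alpha at the grand mean.

    With only a handful of replicates the per-row estimate is noisy and
    roughly half the rows underestimate their dispersion, which makes a
    naive per-row Wald test anti-conservative. Instead of full
    empirical-Bayes shrinkage, each row's estimate is floored at the
    median of the per-row estimates across all rows (and at
    DISPERSION_FLOOR): rows may exceed the typical dispersion but not
    undercut it.
    """
    n_a, n_b = q_a.shape[1], q_b.shape[1]
    var_a = q_a.var(axis=1, ddof=1)
    var_b = q_b.var(axis=1, ddof=1)
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    mu = np.concatenate([q_a, q_b], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled - mu) / np.square(mu)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, np.median(alpha))


def nb_wald(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    contrast: tuple[str, str],
    fc_threshold: float = 0.6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """NB Wald test for one contrast ``(treated, control)``.

    Returns a DataFrame indexed by row name with columns base_mean,
    log2fc, se, p, padj and call. log2fc is log2 of the ratio of
    normalized condition means (pseudo-count 0.5); the Wald statistic is
    log2fc/se with the delta-method NB standard error; p-values are
    two-sided normal and BH-adjusted over all tested rows.
    """
    treated, control = contrast
    libs_t = sample_sheet.loc[sample_sheet["condition"] == treated, "library_id"].tolist()
    libs_c = sample_sheet.loc[sample_sheet["condition"] == control, "library_id"].tolist()
    for cond, libs in ((treated, libs_t), (control, libs_c)):
        if not libs:
            raise ValueError(f"condition {cond!r} absent from sample sheet")
        if len(libs) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
    factors = size_factors(matrix)
    q = _normalized(matrix, factors)
    cols = list(matrix.columns)
    idx_t = [cols.index(c) for c in libs_t]
    idx_c = [cols.index(c) for c in libs_c]
    q_t, q_c = q[:, idx_t], q[:, idx_c]
    s_t = factors.loc[libs_t].to_numpy()
    s_c = factors.loc[libs_c].to_numpy()

    mu_t = q_t.mean(axis=1)
    mu_c = q_c.mean(axis=1)
    disp = _moment_dispersion(q_t, q_c)

    log2fc = np.log2(mu_t + LOG2FC_PSEUDOCOUNT) - np.log2(mu_c + LOG2FC_PSEUDOCOUNT)

    # Var of a normalized count with group mean mu: mu/s_j + alpha*mu^2
    # (NB variance of the raw count divided by s_j^2); the group mean of
    # n such counts has the variance below.
    var_mean_t = (mu_t[:, None] / s_t[None, :] + disp[:, None] * mu_t[:, None] ** 2).sum(axis=1) / len(idx_t) ** 2
    var_mean_c = (mu_c[:, None] / s_c[None, :] + disp[:, None] * mu_c[:, None] ** 2).sum(axis=1) / len(idx_c) ** 2
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_mean_t / np.square(mu_t + LOG2FC_PSEUDOCOUNT)
        + var_mean_c / np.square(mu_c + LOG2FC_PSEUDOCOUNT)
    ) / ln2
    se = np.maximum(se, 1e-12)
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1] if len(p) else p

    result = pd.DataFrame(
        {
            "base_mean": q.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
        },
        index=matrix.index,
    )
    result["call"] = classify(result, fc_threshold=fc_threshold, alpha=alpha)
    return result


def classify(
    results: pd.DataFrame,
    fc_threshold: float = 0.6,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.Series:
    """Three-way call per row: up / down / unchanged.

    up iff log2fc >= fc_threshold and p(adj) <= alpha; down iff
    log2fc <= -fc_threshold and p(adj) <= alpha; both boundaries
    inclusive. ``use_adjusted`` selects padj (default) or raw p.
    """
    if fc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    pcol = "padj" if use_adjusted else "p"
    significant = results[pcol] <= alpha
    call = pd.Series("unchanged", index=results.index, name="call")
    call[significant & (results["log2fc"] >= fc_threshold)] = "up"
    call[significant & (results["log2fc"] <= -fc_threshold)] = "down"
    return call


def classify_fixture(
    fixture: pd.DataFrame, contrast: str, fc_threshold: float = 0.6
) -> pd.Series:
    """Calls for the packaged printed table, which carries significance
    star classes rather than p-values: any star class counts as
    significant.
    """
    fc = fixture[f"log2fc_{contrast}"]
    significant = fixture[f"p_class_{contrast}"] != "ns"
    call = pd.Series("unchanged", index=fixture.index, name="call")
    call[significant & (fc >= fc_threshold)] = "up"
    call[significant & (fc <= -fc_threshold)] = "down"
    call.index = fixture["mirna_name"]
    return call


@dataclass(frozen=True)
class RestorationSummary:
    """Cross-tabulation of drought calls vs rehydration calls.

    "Restored" miRNAs changed under drought but are back to unchanged
    after rehydration; "common" miRNAs carry the same non-unchanged call
    in both treatments.
    """

    n_up_drought: int
    n_down_drought: int
    n_unchanged_drought: int
    n_up_rehyd: int
    n_down_rehyd: int
    n_unchanged_rehyd: int
    n_common_up: int
    n_common_down: int
    n_common_unchanged: int
    n_restored_up: int
    n_restored_down: int

    @property
    def n_restored(self) -> int:
        return self.n_restored_up + self.n_restored_down

    def to_frame(self) -> pd.DataFrame:
        """Summary in the study's three-row layout (up/down/unchanged)."""
        return pd.DataFrame(
            {
                "up": [self.n_up_drought, self.n_up_rehyd, self.n_common_up],
                "down": [self.n_down_drought, self.n_down_rehyd, self.n_common_down],
                "unchanged": [
                    self.n_unchanged_drought,
                    self.n_unchanged_rehyd,
                    self.n_common_unchanged,
                ],
            },
            index=["drought", "rehydration", "common"],
        )


def restoration_summary(
    drought_calls: Mapping[str, str] | pd.Series,
    rehydration_calls: Mapping[str, str] | pd.Series,
) -> RestorationSummary:
    """Tabulate call agreement between the two treatments.

    Both call sets must cover exactly the same miRNA names.
    """
    d = pd.Series(drought_calls)
    r = pd.Series(rehydration_calls)
    if set(d.index) != set(r.index):
        raise ValueError("drought and rehydration calls cover different miRNA sets")
    r = r.loc[d.index]
    return RestorationSummary(
        n_up_drought=int((d == "up").sum()),
        n_down_drought=int((d == "down").sum()),
        n_unchanged_drought=int((d == "unchanged").sum()),
        n_up_rehyd=int((r == "up").sum()),
        n_down_rehyd=int((r == "down").sum()),
        n_unchanged_rehyd=int((r == "unchanged").sum()),
        n_common_up=int(((d == "up") & (r == "up")).sum()),
        n_common_down=int(((d == "down") & (r == "down")).sum()),
        n_common_unchanged=int(((d == "unchanged") & (r == "unchanged")).sum()),
        n_restored_up=int(((d == "up") & (r == "unchanged")).sum()),
        n_restored_down=int(((d == "down") & (r == "unchanged")).sum()),
    )


def primirna_crosstab(
    pri_calls: Mapping[str, str],
    mirna_calls: Mapping[str, str],
    order: Sequence[str] = ("up", "down", "const"),
) -> pd.DataFrame:
    """3x3 cross-tab of pri-miRNA calls vs mature miRNA calls.

    Counts names in the intersection of the two call sets; pairs outside
    the intersection are dropped (their number is recorded in the
    DataFrame attrs as ``n_dropped``). Cell (i, j) = number of names with
    pri call i and mature call j.
    """
    common = sorted(set(pri_calls) & set(mirna_calls))
    dropped = len(set(pri_calls) | set(mirna_calls)) - len(common)
    table = pd.DataFrame(0, index=list(order), columns=list(order), dtype=int)
    for name in common:
        table.loc[pri_calls[name], mirna_calls[name]] += 1
    table.attrs["n_dropped"] = dropped
    table.index.name = "pri_mirna"
    table.columns.name = "mirna"
    return table
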