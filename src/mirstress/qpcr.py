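"""Relative quantification (2^-ddCt) and miRNA/target anticorrelation.

qPCR cycle thresholds are normalized to a single reference gene per run
(delta Ct), contrasted between conditions (delta-delta Ct), and converted
to fold changes as 2^-ddCt. Fold changes below 1 are reported with the
signed convention -1/FC, so magnitudes are symmetric around +/-1.
Significance is a two-tailed two-sample t-test on the replicate delta-Ct
values. A target is negatively correlated with its cognate miRNA when the
miRNA call and the significant target fold change point in opposite
directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

CT_COLUMNS = ("gene", "library_id", "ct", "is_reference")


@dataclass(frozen=True)
class FoldChange:
    gene: str
    contrast: tuple[str, str]  # (treated, control)
    fc_raw: float  # > 0
    fc_signed: float  # |fc_signed| >= 1
    p: float


def read_ct_table(path) -> pd.DataFrame:
    """Load a Ct TSV (gene, library_id, ct, is_reference) and validate it."""
    df = pd.read_csv(path, sep="\t")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    df = df.copy()
    df["is_reference"] = df["is_reference"].astype(bool)
    refs = df.loc[df["is_reference"], "gene"].unique()
    if len(refs) != 1:
        raise ValueError(f"exactly one reference gene required, found {sorted(refs)}")
    return df


def ddct_fold_change(
    ct: pd.DataFrame,
    gene: str,
    contrast: tuple[str, str],
    sample_sheet: pd.DataFrame,
) -> FoldChange:
    """2^-ddCt fold change of ``gene`` for ``(treated, control)``.

    Per library: dCt = Ct(gene) - Ct(reference); ddCt is the difference
    of condition means of dCt; fc_raw = 2^-ddCt. The p-value is a
    two-tailed two-sample t-test on the replicate dCt values of the two
    conditions.
    """
    ct = validate_ct_table(ct)
    reference = ct.loc[ct["is_reference"], "gene"].iloc[0]
    if gene == reference:
        raise ValueError("cannot quantify the reference gene against itself")
    cond = sample_sheet.set_index("library_id")["condition"]

    def delta_ct(condition: str) -> pd.Series:
        libs = cond.index[cond == condition]
        g = ct[(ct["gene"] == gene) & ct["library_id"].isin(libs)].set_index("library_id")["ct"]
        r = ct[(ct["gene"] == reference) & ct["library_id"].isin(libs)].set_index("library_id")["ct"]
        if len(g) < 2 or len(r) < 2:
            raise ValueError(
                f"need >=2 replicates of {gene} and {reference} in condition {condition!r}"
            )
        return (g - r).dropna()

    treated, control = contrast
    dct_t, dct_c = delta_ct(treated), delta_ct(control)
    ddct = dct_t.mean() - dct_c.mean()
    fc_raw = 2.0 ** (-ddct)
    if dct_t.std(ddof=1) == 0 and dct_c.std(ddof=1) == 0:
        p = 1.0 if ddct == 0 else 0.0  # degenerate noise-free input
    else:
        p = float(stats.ttest_ind(dct_t, dct_c).pvalue)
    return FoldChange(gene, (treated, control), float(fc_raw), signed_fc(fc_raw), p)


def signed_fc(fc_raw: float) -> float:
    """Signed fold-change convention: FC >= 1 unchanged, FC in (0, 1)
    recalculated as -1/FC. |result| is always >= 1."""
    if fc_raw <= 0:
        raise ValueError("fold change must be positive")
    return fc_raw if fc_raw >= 1.0 else -1.0 / fc_raw


def fold_increase(treated: float, control: float) -> int:
    """Ratio treated/control rounded to the nearest integer (half away
    from zero) — the convention of printed n-fold statements."""
    if control <= 0:
        raise ValueError("control value must be positive")
    ratio = treated / control
    return int(math.floor(ratio + 0.5)) if ratio >= 0 else -int(math.floor(-ratio + 0.5))


def correlation_class(
    mirna_call: str,
    target: FoldChange,
    alpha: float = 0.05,
) -> str:
    """Anticorrelation call between a miRNA and its target mRNA.

    ``negatively_correlated`` iff the miRNA is up and the target fold
    change is significantly negative, or the miRNA is down and the target
    fold change is significantly above 1; else ``not_correlated``.
    """
    if mirna_call not in ("up", "down", "unchanged"):
        raise ValueError(f"unknown miRNA call: {mirna_call!r}")
    significant = target.p <= alpha
    if mirna_call == "up" and target.fc_signed < 0 and significant:
        return "negatively_correlated"
    if mirna_call == "down" and target.fc_signed > 1 and significant:
        return "negatively_correlated"
    return "not_correlated"
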