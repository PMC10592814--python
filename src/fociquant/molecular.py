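"""Tabular molecular quantification: qPCR fold changes, blot intensities,
peptide abundance ratios, and group comparison of fold changes.

The qPCR chain is the classic relative-quantification scheme with assumed
amplification efficiency 2: per sample, dCt = Ct(target) - Ct(reference
gene); per gene, ddCt = dCt - mean(dCt over baseline-condition samples);
fold change = 2**(-ddCt).  Subtracting the arithmetic mean baseline dCt is
equivalent to dividing each fold by the *geometric* mean of baseline folds,
so with noise the baseline condition's arithmetic-mean fold can exceed 1;
this is a property of the convention, not an error.

Blot quantification divides each band/lane volume by its loading-control
volume and expresses it relative to the mean normalized volume of the
reference condition.  Peptide quantification reports the ratio of mean
treated to mean untreated abundance.  Group comparison runs one- or
two-factor analysis of variance on the fold-change scale followed by
Tukey HSD all-pairs comparisons.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .model import CtTable, FoldChangeTable, IntensityTable

__all__ = [
    "ddct_fold_change",
    "relative_intensity",
    "abundance_ratio",
    "compare_groups",
]


def ddct_fold_change(table: CtTable, average_technical_replicates: bool = False) -> FoldChangeTable:
    """Relative gene expression by the 2^-ddCt method.

    Parameters
    ----------
    table
        Ct measurements with a designated reference gene and baseline
        condition.
    average_technical_replicates
        When True, replicate Ct values of the same (condition, gene) are
        averaged per replicate group before the chain is applied.

    Returns
    -------
    FoldChangeTable
        Per-sample dCt, ddCt and fold change, plus per (condition, gene)
        mean and sample s.d. of the fold changes.
    """
    frame = table.frame
    if average_technical_replicates:
        frame = (frame.groupby(["condition", "replicate", "gene"], as_index=False)
                 .agg(ct=("ct", "mean"))
                 .assign(sample_id=lambda d: d["condition"].str.cat(
                     d["replicate"].astype(str), sep="/")))

    ref = (frame[frame["gene"] == table.reference_gene]
           .set_index("sample_id")["ct"])
    targets = frame[frame["gene"] != table.reference_gene].copy()
    if targets.empty:
        raise ValueError("Ct table contains only the reference gene")
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[targets["sample_id"]].to_numpy()

    baseline = targets[targets["condition"] == table.baseline_condition]
    missing = sorted(set(targets["gene"]) - set(baseline["gene"]))
    if missing:
        raise ValueError(
            f"baseline condition {table.baseline_condition!r} has no samples "
            f"for genes {missing}"
        )
    baseline_mean = baseline.groupby("gene")["dct"].mean()
    targets["ddct"] = targets["dct"] - baseline_mean.loc[targets["gene"]].to_numpy()
    targets["fold_change"] = 2.0 ** (-targets["ddct"])

    per_sample = targets[["sample_id", "condition", "replicate", "gene",
                          "ct", "dct", "ddct", "fold_change"]].reset_index(drop=True)
    per_condition = (per_sample.groupby(["condition", "gene"], as_index=False)
                     .agg(n=("fold_change", "size"),
                          fold_change_mean=("fold_change", "mean"),
                          fold_change_sd=("fold_change", lambda s: s.std(ddof=1))))
    return FoldChangeTable(per_sample=per_sample, per_condition=per_condition,
                           baseline_condition=table.baseline_condition)


def relative_intensity(table: IntensityTable) -> FoldChangeTable:
    """Loading-control-normalized band intensities relative to a reference condition.

    ``normalized = target / loading_control``; ``relative = normalized /
    mean(normalized over the reference condition)``, so the reference
    condition's mean relative value is exactly 1.
    """
    frame = table.frame.copy()
    frame["normalized"] = frame["target_band_volume"] / frame["loading_control_volume"]
    reference = frame.loc[frame["condition"] == table.reference_condition, "normalized"]
    ref_mean = float(reference.mean())
    if ref_mean == 0:
        raise ValueError("reference condition has zero mean normalized intensity")
    frame["fold_change"] = frame["normalized"] / ref_mean
    per_sample = frame[["lane_id", "condition", "normalized", "fold_change"]].reset_index(drop=True)
    per_condition = (per_sample.groupby("condition", as_index=False)
                     .agg(n=("fold_change", "size"),
                          fold_change_mean=("fold_change", "mean"),
                          fold_change_sd=("fold_change", lambda s: s.std(ddof=1))))
    return FoldChangeTable(per_sample=per_sample, per_condition=per_condition,
                           baseline_condition=table.reference_condition)


def abundance_ratio(treated: Sequence[float], untreated: Sequence[float]) -> float:
    """Mean treated abundance over mean untreated abundance."""
    treated = np.asarray(treated, dtype=np.float64)
    untreated = np.asarray(untreated, dtype=np.float64)
    if treated.size == 0 or untreated.size == 0:
        raise ValueError("both abundance lists must be non-empty")
    denom = float(untreated.mean())
    if denom <= 0:
        raise ValueError("untreated mean abundance must be positive")
    return float(treated.mean()) / denom


def compare_groups(
    folds: FoldChangeTable,
    factors: Sequence[str],
    value_column: str = "fold_change",
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """ANOVA on fold changes followed by Tukey HSD all-pairs comparisons.

    Parameters
    ----------
    folds
        Fold-change table; the analysis runs on ``per_sample[value_column]``.
    factors
        One or two column names of ``per_sample`` defining the design
        (e.g. ``["condition"]`` or ``["condition", "gene"]``).  Two factors
        give a two-way ANOVA with interaction.

    Returns
    -------
    dict with ``"anova"`` (factor F statistics and p-values) and ``"tukey"``
    (all pairwise group comparisons with family-wise adjusted p-values).
    """
    if not 1 <= len(factors) <= 2:
        raise ValueError("factors must name one or two design columns")
    data = folds.per_sample.copy()
    for factor in factors:
        if factor not in data.columns:
            raise ValueError(f"factor column {factor!r} not in fold-change table")
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 levels")
    cells = data.groupby(list(factors)).size()
    if len(factors) == 2:
        full = data[factors[0]].nunique() * data[factors[1]].nunique()
        if len(cells) < full:
            raise ValueError("design has empty factor-level combinations")
    if (cells < 2).any():
        raise ValueError("every design cell needs at least 2 replicates")

    data = data.rename(columns={value_column: "_y"})
    if len(factors) == 1:
        formula = f"_y ~ C({factors[0]})"
    else:
        formula = f"_y ~ C({factors[0]}) * C({factors[1]})"
    model = ols(formula, data=data).fit()
    anova = anova_lm(model, typ=2).reset_index().rename(columns={"index": "term"})

    group = data[list(factors)].astype(str).agg(":".join, axis=1)
    if np.allclose(data["_y"].to_numpy(), data["_y"].iloc[0]):
        # degenerate zero-variance data: every comparison is a non-difference
        pairs = sorted(group.unique())
        rows = [{"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0,
                 "lower": 0.0, "upper": 0.0, "reject": False}
                for i, a in enumerate(pairs) for b in pairs[i + 1:]]
        tukey = pd.DataFrame(rows)
    else:
        result = pairwise_tukeyhsd(data["_y"].to_numpy(), group.to_numpy(), alpha=alpha)
        tukey = pd.DataFrame(result.summary().data[1:],
                             columns=[c.replace("-", "_") for c in result.summary().data[0]])
        tukey = tukey.rename(columns={"p_adj": "p_adj", "p-adj": "p_adj"})
    return {"anova": anova, "tukey": tukey}
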