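"""Community-aggregated decay traits from metagenomic gene-family counts.

Decay-gene counts are compositional: sequencing depth is arbitrary per
sample. Each family count is therefore expressed as an additive log-ratio
against the geometric mean of near-single-copy orthologue counts (a proxy for
the number of fungal genomes sequenced), optionally rescaled by the
standardized number of colonized root tips to fold community biomass back in.
Family-level and morpho-trait contrasts above vs below a threshold on the
mineralization gradient use one-way ANOVA with Bonferroni correction across
families.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dendro import DataError
from .synthetic import EXPLORATION_TYPES

__all__ = [
    "alr_standardize",
    "scale_by_roottips",
    "threshold_contrast_genes",
    "threshold_contrast_traits",
]


def alr_standardize(
    counts: pd.DataFrame, single_copy: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Additive log-ratio of gene-family counts against single-copy genes.

    alr_{s,g} = ln((c_{s,g} + p) / geometric-mean_k(s_{s,k} + p)); the
    geometric mean runs over every single-copy column. Invariant to
    multiplying all of a sample's counts by a constant in the p -> 0 limit.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    sc = single_copy.reindex(counts.index)
    if sc.isna().any().any():
        missing = sorted(set(counts.index) - set(single_copy.index))
        raise DataError(f"single-copy counts missing for samples {missing}")
    zero_rows = (sc.sum(axis=1) == 0)
    if zero_rows.any():
        raise DataError(
            f"all-zero single-copy row(s): {list(sc.index[zero_rows])}"
        )
    log_gm = np.log(sc.to_numpy(float) + pseudocount).mean(axis=1)
    vals = np.log(counts.to_numpy(float) + pseudocount) - log_gm[:, None]
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def scale_by_roottips(
    alr_values: pd.DataFrame, root_tips: pd.Series, mode: str = "mean-ratio"
) -> pd.DataFrame:
    """Rescale alr values by the standardized colonized-root-tip count.

    mode="mean-ratio" (default) divides tips by their across-sample mean, so
    equal tip counts leave the values untouched and the sign of the alr is
    preserved. mode="zscore" uses the across-sample z-score; it can flip
    signs for below-average samples and is provided for completeness.
    """
    tips = root_tips.reindex(alr_values.index)
    if tips.isna().any():
        raise DataError(
            f"missing root-tip counts for {list(alr_values.index[tips.isna()])}"
        )
    if (tips < 0).any():
        raise DataError("negative root-tip counts")
    if mode == "mean-ratio":
        factor = tips / tips.mean()
    elif mode == "zscore":
        factor = (tips - tips.mean()) / tips.std(ddof=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return alr_values.mul(factor, axis=0)


def _anova_two_group(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-way two-group ANOVA F and p with a degenerate-variance guard."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(a, b)
    if not np.isfinite(f):  # zero within-group variance etc.
        return 0.0, 1.0
    return float(f), float(p)


def threshold_contrast_genes(
    scaled_values: pd.DataFrame,
    nminer_per_sample: pd.Series,
    threshold: float,
) -> pd.DataFrame:
    """Per-family above/below-threshold ANOVA with Bonferroni correction.

    Returns one row per gene family (F, raw p, Bonferroni-adjusted p, group
    means, enrichment direction) plus a ``total`` row contrasting the
    per-sample sum of scaled values across all families.
    """
    m = nminer_per_sample.reindex(scaled_values.index)
    if m.isna().any():
        raise DataError(
            f"missing mineralization for {list(scaled_values.index[m.isna()])}"
        )
    below = (m < threshold).to_numpy()
    n_below, n_above = int(below.sum()), int((~below).sum())
    if n_below < 2 or n_above < 2:
        raise DataError(
            f"each group needs >= 2 samples (below={n_below}, above={n_above})"
        )
    rows = []
    vals = scaled_values.to_numpy(float)
    for k, fam in enumerate(scaled_values.columns):
        f, p = _anova_two_group(vals[below, k], vals[~below, k])
        mb, ma = float(vals[below, k].mean()), float(vals[~below, k].mean())
        rows.append(
            {
                "family": fam, "f_stat": f, "p_raw": p,
                "mean_below": mb, "mean_above": ma,
                "enriched_below": mb > ma,
                "n_below": n_below, "n_above": n_above,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = multipletests(out["p_raw"], method="bonferroni")[1]

    total = scaled_values.sum(axis=1).to_numpy()
    f_t, p_t = _anova_two_group(total[below], total[~below])
    total_row = pd.DataFrame(
        [
            {
                "family": "total", "f_stat": f_t, "p_raw": p_t,
                "mean_below": float(total[below].mean()),
                "mean_above": float(total[~below].mean()),
                "enriched_below": total[below].mean() > total[~below].mean(),
                "n_below": n_below, "n_above": n_above,
                "p_bonferroni": p_t,  # single pre-specified contrast
            }
        ]
    )
    return pd.concat([out, total_row], ignore_index=True)


def threshold_contrast_traits(
    trait_table: pd.DataFrame,
    abundance: pd.DataFrame,
    nminer_per_sample: pd.Series,
    threshold: float,
    *,
    coverage_warn: float = 0.9,
) -> pd.DataFrame:
    """Above/below-threshold contrasts of hyphal morpho-trait abundance.

    ``trait_table`` maps genus -> exploration_type / rhizomorphs;
    ``abundance`` is sample x genus relative sequence abundance. For
    rhizomorph presence and each exploration type the per-sample summed
    relative abundance is contrasted across the threshold with a one-way
    ANOVA. If assigned genera cover less than ``coverage_warn`` of total
    abundance a warning is emitted and results are still returned.
    """
    bad = set(trait_table["exploration_type"]) - set(EXPLORATION_TYPES)
    if bad:
        raise DataError(f"unknown exploration type(s): {sorted(bad)}")
    m = nminer_per_sample.reindex(abundance.index)
    if m.isna().any():
        raise DataError("missing mineralization for some samples")
    below = (m < threshold).to_numpy()
    if below.sum() < 2 or (~below).sum() < 2:
        raise DataError("each group needs >= 2 samples")

    assigned = [g for g in abundance.columns if g in set(trait_table["genus"])]
    coverage = float(
        abundance[assigned].sum(axis=1).sum() / abundance.sum(axis=1).sum()
    )
    if coverage < coverage_warn:
        warnings.warn(
            f"trait assignments cover only {coverage:.1%} of sequence abundance",
            stacklevel=2,
        )
    traits_i = trait_table.set_index("genus")
    groups = {"rhizomorphs": [g for g in assigned if traits_i.loc[g, "rhizomorphs"]]}
    for et in EXPLORATION_TYPES:
        groups[f"exploration_{et}"] = [
            g for g in assigned if traits_i.loc[g, "exploration_type"] == et
        ]
    rows = []
    for name, genera in groups.items():
        summed = (
            abundance[genera].sum(axis=1).to_numpy()
            if genera
            else np.zeros(len(abundance))
        )
        f, p = _anova_two_group(summed[below], summed[~below])
        rows.append(
            {
                "trait": name,
                "f_stat": f,
                "p_raw": p,
                "mean_below": float(summed[below].mean()),
                "mean_above": float(summed[~below].mean()),
                "enriched_below": summed[below].mean() > summed[~below].mean(),
                "n_genera": len(genera),
                "coverage": coverage,
            }
        )
    return pd.DataFrame(rows)
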