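"""Gene-level comparative statistics.

All operations act on per-gene (sense_avg, antisense_avg) frames indexed by
gene id (one frame per sample), are pure functions of their inputs, and use
strict inequalities throughout, matching the conventional "less than 1" /
"more than 0.5" / ">1" / ">2" phrasings of the cutoffs they implement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnalysisConfig:
    """Cutoffs for the gene-group selections, in log2 normalized units.

    ``new_antisense_ratio`` is a linear ratio taken directly on the stored
    antisense values (6 h / vegetative); vegetative values at or below zero
    (possible on the background-anchored log scale) are floored at
    ``ratio_floor`` before dividing.
    """

    sense_max: float = 1.0
    antisense_min: float = 0.5
    antisense_call_threshold: float = 1.0
    differential_delta: float = 1.0
    new_antisense_ratio: float = 2.0
    ratio_floor: float = 0.05


@dataclass
class EnrichmentResult:
    k: int  # hits in selection
    n: int  # selection size
    K: int  # hits in universe
    N: int  # universe size
    p_value: float
    log10_p: float

    def __post_init__(self):
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError("inconsistent enrichment counts")


def _complete(df: pd.DataFrame) -> pd.DataFrame:
    return df.dropna(subset=["sense_avg", "antisense_avg"])


def select_high_antisense_low_sense(
    table: pd.DataFrame, cfg: AnalysisConfig | None = None
) -> pd.Index:
    """Genes with sense_avg < sense_max and antisense_avg > antisense_min
    (both strict) in the given sample; missing-flagged genes are excluded."""
    cfg = cfg or AnalysisConfig()
    t = _complete(table)
    mask = (t["sense_avg"] < cfg.sense_max) & (t["antisense_avg"] > cfg.antisense_min)
    return t.index[mask]


def differential_sense(
    table_a: pd.DataFrame, table_b: pd.DataFrame, delta: float = 1.0
) -> pd.Index:
    """Genes with sense_avg(A) - sense_avg(B) > delta (strict)."""
    common = table_a.index.intersection(table_b.index)
    if len(common) < len(table_a.index) or len(common) < len(table_b.index):
        warnings.warn(
            "gene universes differ; differential computed on the intersection"
        )
    diff = table_a.loc[common, "sense_avg"] - table_b.loc[common, "sense_avg"]
    diff = diff.dropna()
    return diff.index[diff > delta]


def select_new_antisense(
    table_veg: pd.DataFrame,
    table_6h: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    exclude: pd.Index | None = None,
) -> pd.Index:
    """Genes whose antisense rises more than ``new_antisense_ratio``-fold
    from vegetative growth to 6 h of meiosis (ratio of stored values).

    ``exclude`` optionally removes a gene set (e.g. annotated meiotic genes)
    before the cutoff, for selections restricted to new antisense RNAs over
    non-meiotic genes.
    """
    cfg = cfg or AnalysisConfig()
    common = table_veg.index.intersection(table_6h.index)
    a0 = table_veg.loc[common, "antisense_avg"]
    a1 = table_6h.loc[common, "antisense_avg"]
    ok = a0.notna() & a1.notna()
    a0 = a0[ok].clip(lower=cfg.ratio_floor)
    ratio = a1[ok] / a0
    selected = ratio.index[ratio > cfg.new_antisense_ratio]
    if exclude is not None:
        selected = selected.difference(exclude)
    return selected


def delta_correlation(
    table_t0: pd.DataFrame,
    table_t1: pd.DataFrame,
    genes: pd.Index | None = None,
) -> float:
    """Pearson r between per-gene sense and antisense changes t0 -> t1."""
    common = table_t0.index.intersection(table_t1.index)
    if genes is not None:
        common = common.intersection(genes)
    ds = (table_t1.loc[common, "sense_avg"] - table_t0.loc[common, "sense_avg"]).dropna()
    da = (
        table_t1.loc[common, "antisense_avg"] - table_t0.loc[common, "antisense_avg"]
    ).dropna()
    paired = ds.index.intersection(da.index)
    if len(paired) < 3:
        raise ValueError(f"need >= 3 complete gene pairs, got {len(paired)}")
    x = ds.loc[paired].to_numpy()
    y = da.loc[paired].to_numpy()
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("delta correlation undefined: zero variance in deltas")
    return float(stats.pearsonr(x, y).statistic)


def meiotic_induction_status(
    table_veg: pd.DataFrame,
    table_4h: pd.DataFrame,
    table_6h: pd.DataFrame,
    genes: pd.Index | None = None,
) -> pd.Series:
    """Per-gene flag: sense expression increased at either meiotic time point
    (strictly positive delta vs vegetative, no magnitude threshold)."""
    if genes is None:
        genes = table_veg.index
    genes = pd.Index(genes).intersection(table_4h.index).intersection(table_6h.index)
    d4 = table_4h.loc[genes, "sense_avg"] - table_veg.loc[genes, "sense_avg"]
    d6 = table_6h.loc[genes, "sense_avg"] - table_veg.loc[genes, "sense_avg"]
    return ((d4 > 0) | (d6 > 0)).rename("induced")


def hypergeometric_enrichment(
    selection, annotated, universe
) -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= k), computed in log space.

    ``selection`` and ``annotated`` must be subsets of ``universe``.
    """
    universe = set(universe)
    selection = set(selection)
    annotated = set(annotated)
    if not universe:
        raise ValueError("empty universe")
    if not selection <= universe or not annotated <= universe:
        raise ValueError("selection and annotated must be subsets of the universe")
    N, K, n = len(universe), len(annotated), len(selection)
    k = len(selection & annotated)
    log_p = stats.hypergeom.logsf(k - 1, N, K, n)
    p = float(np.exp(log_p))
    return EnrichmentResult(
        k=k, n=n, K=K, N=N, p_value=min(p, 1.0), log10_p=float(log_p / np.log(10))
    )


def benjamini_hochberg(p_values: pd.Series) -> pd.Series:
    """Optional FDR adjustment for users testing many gene sets (off by
    default everywhere in this package)."""
    p = p_values.to_numpy(dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0, 1)
    return pd.Series(out, index=p_values.index, name="q_value")
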