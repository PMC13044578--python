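"""Dark-vs-light expression-bias statistics.

Applies the study's significance rules to three kinds of evidence —
bulk RNA-seq differential expression tables (|log2FC| > 0.5 and adjusted
p < 0.05, both strict), proteomic intensity matrices (per-time-point
Welch t test, |log2 fold change| > 0.5 and p < 0.05), and single-cell
fold-change tables (FC > 2.0, strict) — maps gene ids across dataset
versions by reciprocal best hit with a >60% coverage requirement, and
computes, per condition or cell type, the proportion of dark and of
light genes significant there out of each group's genes significant
anywhere, plus the bias Delta = prop_dark - prop_light.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEG_LFC_CUTOFF = 0.5
DEG_PADJ_CUTOFF = 0.05
CELLTYPE_FC_CUTOFF = 2.0
POVERA_MIN_COUNT = 10
POVERA_MIN_FRAC = 0.1
RBH_MIN_COV = 0.6

GRANULARITIES = ("broadcell", "cell", "metacell")


def filter_low_expression(
    counts: pd.DataFrame,
    min_count: float = POVERA_MIN_COUNT,
    min_frac: float = POVERA_MIN_FRAC,
) -> pd.Index:
    """pOverA-style filter: keep genes with count > min_count in > min_frac
    of samples (both strict).  ``counts`` is genes x samples."""
    if counts.shape[1] == 0:
        raise ValueError("count matrix has zero samples")
    frac = (counts > min_count).sum(axis=1) / counts.shape[1]
    return counts.index[frac > min_frac]


def call_degs(
    results: pd.DataFrame,
    lfc_cutoff: float = DEG_LFC_CUTOFF,
    padj_cutoff: float = DEG_PADJ_CUTOFF,
) -> pd.DataFrame:
    """Significant gene x comparison pairs from a DE result table.

    Expects columns gene, comparison, log2_fc, p_adj.  Rows with missing
    p_adj (independent-filtering NAs) are skipped with a warning.
    """
    required = {"gene", "comparison", "log2_fc", "p_adj"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    na = results["p_adj"].isna() | results["log2_fc"].isna()
    if na.any():
        logger.warning("skipping %d DE rows with missing statistics", int(na.sum()))
    ok = results[~na]
    sig = ok[(ok["log2_fc"].abs() > lfc_cutoff) & (ok["p_adj"] < padj_cutoff)]
    return sig[["gene", "comparison"]].reset_index(drop=True)


def welch_t(control: np.ndarray, treatment: np.ndarray) -> float:
    """Welch two-sample t-test p-value with the degenerate-variance rule:
    zero variance in both arms gives p=1 for equal means, p=0 otherwise."""
    control = np.asarray(control, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    if control.std(ddof=1) == 0.0 and treatment.std(ddof=1) == 0.0:
        return 1.0 if control.mean() == treatment.mean() else 0.0
    return float(stats.ttest_ind(treatment, control, equal_var=False).pvalue)


def is_differential(fc: float, p: float,
                    fc_cutoff: float = DEG_LFC_CUTOFF,
                    p_cutoff: float = DEG_PADJ_CUTOFF) -> bool:
    """Strict differential-accumulation rule: |FC| > 0.5 and p < 0.05."""
    return bool(np.isfinite(fc) and abs(fc) > fc_cutoff and p < p_cutoff)


def call_differential_proteins(
    intensities: pd.DataFrame,
    design: pd.DataFrame,
    fc_cutoff: float = DEG_LFC_CUTOFF,
    p_cutoff: float = DEG_PADJ_CUTOFF,
) -> pd.DataFrame:
    """Per-protein per-time-point Welch test on normalized intensities.

    ``intensities`` is proteins x samples; ``design`` has columns sample,
    arm ("control"/"treatment"), time_point.  FC is the log2 ratio of arm
    means.  Returns all tested rows with a ``significant`` flag
    (|FC| > 0.5 and p < 0.05, both strict).
    """
    required = {"sample", "arm", "time_point"}
    if required - set(design.columns):
        raise ValueError("design table needs sample, arm, time_point columns")
    rows = []
    for tp, sub in design.groupby("time_point"):
        ctrl = sub.loc[sub["arm"] == "control", "sample"].tolist()
        trt = sub.loc[sub["arm"] == "treatment", "sample"].tolist()
        if len(ctrl) < 2 or len(trt) < 2:
            raise ValueError(f"time point {tp!r} needs >= 2 replicates per arm")
        c = intensities[ctrl].to_numpy(dtype=float)
        t = intensities[trt].to_numpy(dtype=float)
        for i, protein in enumerate(intensities.index):
            mc, mt = c[i].mean(), t[i].mean()
            fc = np.log2(mt / mc) if mc > 0 and mt > 0 else np.nan
            p = welch_t(c[i], t[i])
            rows.append(
                {
                    "protein": protein,
                    "time_point": tp,
                    "fc": fc,
                    "p_value": p,
                    "significant": is_differential(fc, p, fc_cutoff, p_cutoff),
                }
            )
    return pd.DataFrame(rows)


def call_celltype_expression(
    fcs: pd.DataFrame, fc_cutoff: float = CELLTYPE_FC_CUTOFF
) -> pd.DataFrame:
    """Significant gene x cell-type pairs (FC strictly above the cutoff).

    Expects columns gene, granularity, cell_type, fc; granularities are
    analyzed independently, so the granularity column is carried through.
    """
    required = {"gene", "granularity", "cell_type", "fc"}
    if required - set(fcs.columns):
        raise ValueError(f"cell-type table missing columns {sorted(required - set(fcs.columns))}")
    bad_gran = set(fcs["granularity"]) - set(GRANULARITIES)
    if bad_gran:
        raise ValueError(f"unknown granularity levels {sorted(bad_gran)}")
    if (fcs["fc"] < 0).any():
        raise ValueError("cell-type fold changes must be non-negative")
    sig = fcs[fcs["fc"] > fc_cutoff]
    return sig[["gene", "granularity", "cell_type"]].reset_index(drop=True)


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Unique best hit per query by bitscore; queries with ties dropped."""
    best_score = hits.groupby("query")["bitscore"].transform("max")
    best = hits[hits["bitscore"] == best_score]
    tie_counts = best.groupby("query")["subject"].nunique()
    tied = tie_counts[tie_counts > 1].index
    if len(tied):
        logger.warning("dropping %d queries with tied best hits", len(tied))
        best = best[~best["query"].isin(tied)]
    return best.drop_duplicates("query")


def _coverage_ok(row, min_cov: float, mode: str) -> bool:
    q_cov = (row["qend"] - row["qstart"] + 1) / row["qlen"]
    s_cov = (row["send"] - row["sstart"] + 1) / row["slen"]
    if mode == "or":
        return q_cov > min_cov or s_cov > min_cov
    if mode == "and":
        return q_cov > min_cov and s_cov > min_cov
    raise ValueError(f"unknown coverage mode {mode!r}")


def map_ids_rbh(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    min_cov: float = RBH_MIN_COV,
    coverage_mode: str = "or",
) -> dict[str, str]:
    """Reciprocal-best-hit id map between two dataset versions.

    Hit tables need columns query, subject, bitscore, qstart, qend, qlen,
    sstart, send, slen (1-based inclusive).  A pair (a, b) is mapped iff b
    is a's unique best hit A->B, a is b's unique best hit B->A, and the
    forward hit's query or subject coverage exceeds ``min_cov`` (strict;
    "or" per the either-side reading, configurable to "and").  The result
    is an injective partial map a -> b.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    back = dict(zip(best_ba["query"], best_ba["subject"]))
    mapping: dict[str, str] = {}
    for _, row in best_ab.iterrows():
        a, b = row["query"], row["subject"]
        if back.get(b) != a:
            continue
        if not _coverage_ok(row, min_cov, coverage_mode):
            continue
        mapping[a] = b
    return mapping


@dataclass(frozen=True)
class ProportionRow:
    group: str
    unit: str
    n_sig_in_unit: int
    denominator: int
    proportion: float


def proportion_bias(
    sig: pd.DataFrame,
    group_of: Mapping[str, str],
    unit_col: str = "unit",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-unit dark/light proportions and the bias Delta per unit.

    ``sig`` holds one row per significant (gene, unit) pair with columns
    gene and ``unit_col``.  Each group's denominator is its number of
    genes significant in >= 1 unit, so a gene significant in k units
    counts k times in numerators but once in the denominator.  Returns the
    long proportion table and Delta(unit) = prop_dark - prop_light
    (NaN where a group's denominator is zero).
    """
    if sig.empty:
        raise ValueError("no significant calls supplied")
    sig = sig.copy()
    try:
        sig["group"] = [group_of[g] for g in sig["gene"]]
    except KeyError as exc:
        raise KeyError(f"significant gene without a dark/light group: {exc}") from None
    denominators = {
        grp: sub["gene"].nunique() for grp, sub in sig.groupby("group")
    }
    rows: list[ProportionRow] = []
    units = sorted(sig[unit_col].unique())
    for grp in ("dark", "light"):
        denom = denominators.get(grp, 0)
        for unit in units:
            n = sig[(sig["group"] == grp) & (sig[unit_col] == unit)]["gene"].nunique()
            prop = n / denom if denom else np.nan
            rows.append(ProportionRow(grp, unit, n, denom, prop))
    table = pd.DataFrame([r.__dict__ for r in rows])
    wide = table.pivot(index="unit", columns="group", values="proportion")
    delta = wide.get("dark", pd.Series(np.nan, index=wide.index)) - wide.get(
        "light", pd.Series(np.nan, index=wide.index)
    )
    delta.name = "delta"
    return table, delta


def two_proportion_test(
    n_dark_sig: int, n_dark: int, n_light_sig: int, n_light: int
) -> float:
    """Optional two-proportion z-test (extension; the headline statistic is
    the descriptive proportion table)."""
    p_pool = (n_dark_sig + n_light_sig) / (n_dark + n_light)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n_dark + 1 / n_light))
    if se == 0:
        return 1.0
    z = (n_dark_sig / n_dark - n_light_sig / n_light) / se
    return float(2 * stats.norm.sf(abs(z)))
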