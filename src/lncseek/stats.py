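"""Expression normalization, differential expression, enrichment, and qPCR arithmetic.

The differential-expression test is deliberately transparent: a two-sided
Welch t-test on log2(FPKM + pseudocount) per transcript, Benjamini-Hochberg
adjusted across all tested transcripts, with calls requiring both
|log2 fold change| >= 1 (i.e. at least 2-fold) and q < 0.05.  Fold changes
are castrated-over-intact (case over control).

qPCR quantities follow standard relative quantification: 2^-ddCt, and primer
efficiency E = 10^(-1/slope) - 1 from the slope of Ct against log10 template
dilution (slope -1/log10(2) ~ -3.3219 means perfect doubling, E = 1).
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "normalize_fpkm",
    "de_test",
    "bh_adjust",
    "enrich_targets",
    "delta_delta_ct",
    "primer_efficiency",
    "concordance",
]


def normalize_fpkm(
    counts: pd.DataFrame,
    lengths: Union[pd.Series, Mapping[str, float]],
    library_sizes: Optional[Union[pd.Series, Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """FPKM(t, s) = count(t, s) * 1e9 / (length(t) * library_size(s)).

    ``library_sizes`` defaults to the per-sample column sums.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise InputError(f"missing transcript lengths for {missing}")
    if (lengths <= 0).any():
        raise InputError("transcript lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise InputError("library sizes must be positive for every sample")
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving on the input index."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    expr: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression on an FPKM matrix.

    Returns a DataFrame indexed like ``expr`` with columns ``mean_case``,
    ``mean_control``, ``log2fc`` (case over control, pseudocounted), ``pvalue``
    (Welch t on log2(FPKM + pseudocount)), ``qvalue`` (BH), and ``call`` in
    {"up", "down", "ns"}.  A transcript with zero variance and equal means in
    both groups gets p = 1 by convention.
    """
    case_samples = list(case_samples)
    control_samples = list(control_samples)
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise InputError("need at least 2 samples per group")
    missing = (set(case_samples) | set(control_samples)) - set(expr.columns)
    if missing:
        raise KeyError(f"unknown sample ids {sorted(missing)}")
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")

    case = expr[case_samples].to_numpy(dtype=float)
    ctrl = expr[control_samples].to_numpy(dtype=float)
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_case + pseudocount) - np.log2(mean_ctrl + pseudocount)

    lcase = np.log2(case + pseudocount)
    lctrl = np.log2(ctrl + pseudocount)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(lcase, lctrl, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    var0 = (lcase.var(axis=1) == 0) & (lctrl.var(axis=1) == 0)
    equal = np.isclose(lcase.mean(axis=1), lctrl.mean(axis=1))
    p[var0 & equal] = 1.0
    p[var0 & ~equal] = 0.0
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)

    q = bh_adjust(p)
    call = np.full(len(p), "ns", dtype=object)
    call[(q < q_threshold) & (log2fc >= lfc_threshold)] = "up"
    call[(q < q_threshold) & (log2fc <= -lfc_threshold)] = "down"

    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2fc": log2fc,
            "pvalue": p,
            "qvalue": q,
            "call": call,
        },
        index=expr.index,
    )


def enrich_targets(
    target_genes: Set[str],
    pathway_sets: Mapping[str, Set[str]],
    universe: Set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each pathway in a target gene set.

    p = P(X >= k) with population N = |universe|, successes K = |pathway ∩
    universe|, draws n = |targets|, overlap k; BH across pathways.
    """
    universe = set(universe)
    if not universe:
        raise InputError("enrichment universe is empty")
    target_genes = set(target_genes)
    stray = target_genes - universe
    if stray:
        raise InputError(
            f"target genes outside the universe: {sorted(stray)[:5]}"
        )
    names, ks, Ks, ps = [], [], [], []
    n = len(target_genes)
    N = len(universe)
    for name in sorted(pathway_sets):
        pset = set(pathway_sets[name]) & universe
        k = len(target_genes & pset)
        K = len(pset)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        names.append(name)
        ks.append(k)
        Ks.append(K)
        ps.append(min(1.0, p))
    q = bh_adjust(ps) if ps else np.array([])
    return pd.DataFrame(
        {"pathway": names, "overlap": ks, "pathway_size": Ks, "pvalue": ps,
         "qvalue": q}
    ).set_index("pathway")


def _mean(x) -> float:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise InputError("Ct values must be finite and non-empty")
    return float(arr.mean())


def delta_delta_ct(ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl) -> float:
    """Relative expression 2^-ddCt; replicate Ct values are averaged first.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    ddct = (_mean(ct_target_case) - _mean(ct_ref_case)) - (
        _mean(ct_target_ctrl) - _mean(ct_ref_ctrl)
    )
    return float(2.0 ** (-ddct))


def primer_efficiency(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope: E = 10^(-1/slope) - 1."""
    if not np.isfinite(slope) or slope >= 0:
        raise InputError("standard-curve slope must be negative")
    return float(10.0 ** (-1.0 / slope) - 1.0)


def concordance(log2fc_qpcr: Sequence[float], log2fc_rnaseq: Sequence[float]) -> float:
    """Pearson correlation between qPCR and RNA-seq log2 fold changes."""
    x = np.asarray(log2fc_qpcr, dtype=float)
    y = np.asarray(log2fc_rnaseq, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("need two equal-length vectors of at least 3 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("fold-change vectors must be finite")
    if x.std() == 0 or y.std() == 0:
        raise InputError("correlation undefined: zero variance")
    return float(sps.pearsonr(x, y)[0])
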