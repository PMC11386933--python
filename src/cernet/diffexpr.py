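"""Differential expression: normalization, testing, and class-specific gating.

Abundances are normalized (CPM or DESeq-style median-of-ratios), fold
changes computed on a pseudocounted log2 scale, significance assessed with
Welch's t on log2(normalized + c), and BH-FDR applied within each RNA class.
The gates are class specific: |FC| > 2 for circRNAs, |FC| > 1.5 for miRNAs
and mRNAs, with alpha 0.05 applied to the raw p-value by default (the
printed result tables report raw p; an FDR gate is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, NormalizationError
from .io_formats import CountMatrix

PSEUDOCOUNT = 0.5

DEFAULT_MIN_ABS_FC = {"circRNA": 2.0, "miRNA": 1.5, "mRNA": 1.5}


@dataclass
class DEThresholds:
    """Fold-change and significance gates, per RNA class."""

    min_abs_fc: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIN_ABS_FC))
    alpha: float = 0.05
    alpha_applies_to: str = "pvalue"  # or "fdr"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must lie in (0, 1)")
        for cls, fc in self.min_abs_fc.items():
            if fc <= 1:
                raise DomainError(f"min_abs_fc[{cls!r}] must exceed 1")
        if self.alpha_applies_to not in ("pvalue", "fdr"):
            raise DomainError("alpha_applies_to must be 'pvalue' or 'fdr'")

    def fc_for(self, rna_class: str) -> float:
        return self.min_abs_fc.get(rna_class, 1.5)


def normalize(matrix: CountMatrix, method: str = "cpm") -> np.ndarray:
    """Return normalized abundances (features x samples).

    ``cpm`` scales each sample column to one million; ``median_ratio`` uses
    DESeq-style size factors (per-sample median of count / geometric row
    mean, rows containing any zero excluded from the median).
    """
    counts = matrix.counts.astype(float)
    if method == "cpm":
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            bad = matrix.sample_ids[int(np.argmax(totals == 0))]
            raise NormalizationError(f"sample {bad!r} has zero total count")
        return counts / totals * 1e6
    if method == "median_ratio":
        nonzero = np.all(counts > 0, axis=1)
        if not np.any(nonzero):
            raise NormalizationError("no feature free of zeros; cannot compute size factors")
        sub = counts[nonzero]
        log_geo_mean = np.mean(np.log(sub), axis=1)
        size_factors = np.exp(np.median(np.log(sub) - log_geo_mean[:, None], axis=0))
        if np.any(size_factors == 0):
            bad = matrix.sample_ids[int(np.argmax(size_factors == 0))]
            raise NormalizationError(f"sample {bad!r} has zero size factor")
        return counts / size_factors
    raise ValueError(f"unknown normalization method {method!r}")


def size_factors(matrix: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors (exposed for inspection/testing)."""
    counts = matrix.counts.astype(float)
    nonzero = np.all(counts > 0, axis=1)
    sub = counts[nonzero]
    log_geo_mean = np.mean(np.log(sub), axis=1)
    return np.exp(np.median(np.log(sub) - log_geo_mean[:, None], axis=0))


def test_de(
    matrix: CountMatrix,
    thresholds: DEThresholds | None = None,
    method: str = "cpm",
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-feature fold change, Welch p, BH-FDR and regulation call.

    Returns a DataFrame with columns id, rna_class, mean_control,
    mean_treated, log2fc, pvalue, fdr, regulation (UP/DOWN/NS). log2fc is
    log2((mean_treated + c) / (mean_control + c)) on normalized abundances.
    """
    thresholds = thresholds or DEThresholds()
    norm = normalize(matrix, method=method)
    ctrl_idx = [i for i, s in enumerate(matrix.sample_ids) if matrix.group_of[s] == "control"]
    trt_idx = [i for i, s in enumerate(matrix.sample_ids) if matrix.group_of[s] == "treated"]
    if len(ctrl_idx) < 2 or len(trt_idx) < 2:
        raise DomainError("need >= 2 samples per group")

    log_norm = np.log2(norm + pseudocount)
    mean_ctrl = norm[:, ctrl_idx].mean(axis=1)
    mean_trt = norm[:, trt_idx].mean(axis=1)
    log2fc = np.log2(mean_trt + pseudocount) - np.log2(mean_ctrl + pseudocount)

    t_res = stats.ttest_ind(
        log_norm[:, trt_idx], log_norm[:, ctrl_idx], axis=1, equal_var=False
    )
    pvalues = np.asarray(t_res.pvalue, dtype=float)
    # zero variance in both groups: equal means -> p = 1, unequal -> p -> 0
    flat = np.isnan(pvalues)
    if np.any(flat):
        same = np.isclose(
            log_norm[:, trt_idx].mean(axis=1), log_norm[:, ctrl_idx].mean(axis=1)
        )
        pvalues[flat & same] = 1.0
        pvalues[flat & ~same] = np.finfo(float).tiny
    pvalues = np.clip(pvalues, np.finfo(float).tiny, 1.0)
    fdr = bh_adjust(pvalues)

    df = pd.DataFrame(
        {
            "id": matrix.feature_ids,
            "rna_class": matrix.rna_class,
            "mean_control": mean_ctrl,
            "mean_treated": mean_trt,
            "log2fc": log2fc,
            "pvalue": pvalues,
            "fdr": fdr,
        }
    )
    df["regulation"] = _regulation_calls(df, matrix.rna_class, thresholds)
    return df


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _regulation_calls(df: pd.DataFrame, rna_class: str, thr: DEThresholds) -> list[str]:
    cut = np.log2(thr.fc_for(rna_class))
    sig_col = df["pvalue"] if thr.alpha_applies_to == "pvalue" else df["fdr"]
    calls = []
    for fc, sig in zip(df["log2fc"], sig_col):
        if abs(fc) >= cut and sig < thr.alpha:
            calls.append("UP" if fc > 0 else "DOWN")
        else:
            calls.append("NS")
    return calls


def gate(records: pd.DataFrame, thresholds: DEThresholds, rna_class: str | None = None) -> pd.DataFrame:
    """Keep records passing |log2fc| >= log2(min_abs_fc) and alpha; set regulation.

    Accepts either computed DE tables or the packaged fixture tables (which
    carry log2fc and pvalue directly). Idempotent and order independent.
    """
    cls = rna_class or (records["rna_class"].iloc[0] if "rna_class" in records else "mRNA")
    cut = np.log2(thresholds.fc_for(cls))
    if thresholds.alpha_applies_to == "fdr" and "fdr" in records:
        sig = records["fdr"]
    else:
        sig = records["pvalue"]
    keep = (records["log2fc"].abs() >= cut) & (sig < thresholds.alpha)
    out = records.loc[keep].copy()
    out["regulation"] = np.where(out["log2fc"] > 0, "UP", "DOWN")
    return out


def classify_regulation(log2fc: float) -> str:
    """Sign rule for the Regulation column; exactly zero is undefined."""
    if log2fc > 0:
        return "UP"
    if log2fc < 0:
        return "DOWN"
    raise DomainError("log2fc is exactly 0: regulation direction undefined")
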