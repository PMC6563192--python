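"""FPKM quantification, replicate-consistency filtering and DE calling.

Expression of genes and LTR elements is normalised as FPKM,

    fpkm = count * 1e9 / (feature_len * library_size),

with the library size defaulting to the column sum of counts.  Per-group
mean FPKMs give the reported fold change

    log2fc = log2(max(mean_infected, floor) / max(mean_control, floor))

with a 0.001 floor guarding zero means.  Features are called differentially
expressed (status up/down) when |log2fc| > 1, Benjamini-Hochberg FDR < 0.05
and the replicates are consistent: in a 2-vs-2 design both infected FPKMs
must lie on the same side of both control FPKMs.

P-values come from a two-group negative-binomial exact test on
library-size-normalised counts (conditioning on the total, double-tail sum
of outcome probabilities no more likely than the observed split), with a
single common dispersion estimated across features by method of moments.
With two replicates per group, per-feature dispersion is not estimable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

DEFAULT_FLOOR = 0.001
DEFAULT_LFC = 1.0
DEFAULT_FDR = 0.05
DISPERSION_FLOOR = 1e-4


@dataclass(frozen=True)
class Design:
    """Sample-to-group assignment for a control vs infected comparison."""
    control: tuple[str, ...]
    infected: tuple[str, ...]

    def __post_init__(self):
        if not self.control or not self.infected:
            raise ValueError("both groups need at least one sample")
        if set(self.control) & set(self.infected):
            raise ValueError("a sample cannot be in both groups")

    @property
    def samples(self) -> list[str]:
        return list(self.control) + list(self.infected)


def compute_fpkm(counts: pd.DataFrame,
                 feature_lens: Mapping[str, int] | pd.Series,
                 library_sizes: Mapping[str, float] | pd.Series | None = None) -> pd.DataFrame:
    """FPKM per feature (rows) and sample (columns)."""
    lens = pd.Series(feature_lens).reindex(counts.index)
    if lens.isna().any():
        missing = list(lens.index[lens.isna()])
        raise ValueError(f"no length for features {missing[:5]}")
    if (lens <= 0).any():
        raise ValueError("feature lengths must be > 0")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_sizes).reindex(counts.columns).astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    return counts.astype(float).mul(1e9).div(lib, axis=1).div(lens, axis=0)


def group_means_and_log2fc(fpkm_row: pd.Series, design: Design,
                           floor: float = DEFAULT_FLOOR) -> tuple[float, float, float]:
    """(control mean, infected mean, floored log2 fold change)."""
    ck = float(fpkm_row[list(design.control)].mean())
    npv = float(fpkm_row[list(design.infected)].mean())
    return ck, npv, log2fc_from_means(ck, npv, floor)


def log2fc_from_means(ck_mean: float, npv_mean: float,
                      floor: float = DEFAULT_FLOOR) -> float:
    if ck_mean < 0 or npv_mean < 0:
        raise ValueError("mean FPKMs must be non-negative")
    return float(np.log2(max(npv_mean, floor) / max(ck_mean, floor)))


def consistency_filter(fpkm_row: pd.Series, design: Design) -> bool:
    """True iff infected replicates all lie on one side of all controls.

    A feature with all four values equal is trivially consistent.
    """
    ck = fpkm_row[list(design.control)].to_numpy(float)
    npv = fpkm_row[list(design.infected)].to_numpy(float)
    if np.isnan(ck).any() or np.isnan(npv).any():
        raise ValueError("missing replicate value")
    if (ck == ck[0]).all() and (npv == ck[0]).all():
        return True
    return bool(npv.min() > ck.max() or npv.max() < ck.min())


def estimate_common_dispersion(norm_counts: pd.DataFrame, design: Design,
                               floor: float = DISPERSION_FLOOR) -> float:
    """Method-of-moments NB dispersion pooled across features and groups.

    Solves E[s^2] = mu + phi * mu^2 per feature/group and pools by summing
    numerators and denominators, floored at `floor`.
    """
    num = 0.0
    den = 0.0
    for group in (design.control, design.infected):
        if len(group) < 2:
            continue
        block = norm_counts[list(group)].to_numpy(float)
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        keep = m > 0
        num += float((v[keep] - m[keep]).sum())
        den += float((m[keep] ** 2).sum())
    if den == 0:
        return floor
    return max(floor, num / den)


def nb_exact_test(sum_a: int, sum_b: int, n_rep_a: int, n_rep_b: int,
                  dispersion: float) -> float:
    """Exact double-tail NB test of two group sums with equal library sizes.

    Conditions on the total T = sum_a + sum_b; each group sum is modelled as
    NB with mean proportional to its replicate number and size n_rep/phi.
    The p-value is the probability mass of all splits no more likely than
    the observed one, normalised over all splits of T.
    """
    total = int(sum_a) + int(sum_b)
    if total == 0:
        return 1.0
    phi = max(dispersion, DISPERSION_FLOOR)
    a = np.arange(total + 1)
    r_a = n_rep_a / phi
    r_b = n_rep_b / phi
    mu_a = total * n_rep_a / (n_rep_a + n_rep_b)
    mu_b = total - mu_a
    lp = (nbinom.logpmf(a, r_a, r_a / (r_a + mu_a))
          + nbinom.logpmf(total - a, r_b, r_b / (r_b + mu_b)))
    obs = lp[int(sum_a)]
    keep = lp <= obs + 1e-10
    return float(np.exp(logsumexp(lp[keep]) - logsumexp(lp)))


def call_de(counts: pd.DataFrame,
            feature_lens: Mapping[str, int] | pd.Series,
            design: Design,
            library_sizes: Mapping[str, float] | None = None,
            lfc_threshold: float = DEFAULT_LFC,
            fdr_threshold: float = DEFAULT_FDR,
            floor: float = DEFAULT_FLOOR,
            apply_consistency: bool = True) -> pd.DataFrame:
    """Differential-expression table for a two-group count matrix.

    Features with zero counts in every sample are excluded before testing
    and before FDR correction.  Returns a DataFrame indexed by feature id
    with columns ck_mean_fpkm, npv_mean_fpkm, log2fc, pvalue, fdr, status
    (up/down/ns) and consistent.
    """
    counts = counts[design.samples]
    counts = counts.loc[counts.sum(axis=1) > 0]
    if counts.empty:
        return pd.DataFrame(columns=["ck_mean_fpkm", "npv_mean_fpkm", "log2fc",
                                     "pvalue", "fdr", "status", "consistent"])
    fpkm = compute_fpkm(counts, feature_lens, library_sizes)

    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_sizes).reindex(counts.columns).astype(float)
    ref = float(np.exp(np.log(lib).mean()))
    norm = counts.astype(float).mul(ref / lib, axis=1)
    phi = estimate_common_dispersion(norm, design)

    sum_ck = norm[list(design.control)].sum(axis=1).round().astype(int)
    sum_npv = norm[list(design.infected)].sum(axis=1).round().astype(int)
    n_ck, n_npv = len(design.control), len(design.infected)
    pvals = np.array([
        nb_exact_test(a, b, n_ck, n_npv, phi)
        for a, b in zip(sum_ck.to_numpy(), sum_npv.to_numpy())
    ])
    if len(pvals) > 1:
        fdr = multipletests(pvals, method="fdr_bh")[1]
    else:
        fdr = pvals.copy()

    ck_mean = fpkm[list(design.control)].mean(axis=1)
    npv_mean = fpkm[list(design.infected)].mean(axis=1)
    lfc = np.log2(np.maximum(npv_mean, floor) / np.maximum(ck_mean, floor))
    consistent = fpkm.apply(consistency_filter, axis=1, design=design)

    out = pd.DataFrame({
        "ck_mean_fpkm": ck_mean,
        "npv_mean_fpkm": npv_mean,
        "log2fc": lfc,
        "pvalue": pvals,
        "fdr": fdr,
        "consistent": consistent,
    })
    passes = (np.abs(out["log2fc"]) > lfc_threshold) & (out["fdr"] < fdr_threshold)
    if apply_consistency:
        passes &= out["consistent"]
    out["status"] = np.where(~passes, "ns", np.where(out["log2fc"] > 0, "up", "down"))
    out.index.name = "feature_id"
    return out[["ck_mean_fpkm", "npv_mean_fpkm", "log2fc", "pvalue", "fdr",
                "status", "consistent"]]


def call_status(log2fc: float, fdr: float, consistent: bool = True,
                lfc_threshold: float = DEFAULT_LFC,
                fdr_threshold: float = DEFAULT_FDR) -> str:
    """up/down/ns decision for one feature from precomputed statistics."""
    if abs(log2fc) > lfc_threshold and fdr < fdr_threshold and consistent:
        return "up" if log2fc > 0 else "down"
    return "ns"
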