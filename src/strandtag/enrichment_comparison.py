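"""Transcriptome-composition comparison between library-preparation methods.

Covers technical-replicate collapsing, zero-replaced log2 counts, pairwise
r^2 and principal-component projection, TMM normalization factors, logCPM /
log fold-change with one-group-only flags, and GO-term Fisher enrichment
with Benjamini-Hochberg correction per GO domain.

Formal significance testing of per-feature differences (negative-binomial
dispersion modelling) is deliberately out of scope: this module computes
normalization, effect sizes and flags only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SampleDesign:
    """sample id -> (method, biological unit, technical replicate group)."""

    samples: dict[str, tuple[str, str, str]]

    def method(self, sample: str) -> str:
        return self.samples[sample][0]

    def replicate_group(self, sample: str) -> str:
        return self.samples[sample][2]

    def by_method(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, (m, _, _) in self.samples.items():
            out.setdefault(m, []).append(s)
        return out


# ---------------------------------------------------------------------------
# matrix preparation


def collapse_technical_replicates(
    matrix: pd.DataFrame, design: SampleDesign
) -> tuple[pd.DataFrame, SampleDesign]:
    """Arithmetic mean of counts within each technical replicate group.

    The collapsed column keeps the group name; a group spanning two methods
    is an error.
    """
    groups: dict[str, list[str]] = {}
    for sample in matrix.columns:
        groups.setdefault(design.replicate_group(sample), []).append(sample)
    cols = {}
    new_design: dict[str, tuple[str, str, str]] = {}
    for group, members in groups.items():
        methods = {design.method(m) for m in members}
        if len(methods) > 1:
            raise ValueError(f"replicate group {group!r} spans methods {methods}")
        cols[group] = matrix[members].mean(axis=1)
        method, unit, _ = design.samples[members[0]]
        new_design[group] = (method, unit, group)
    return pd.DataFrame(cols), SampleDesign(new_design)


def filter_all_zero(matrix: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop features with zero counts in every sample; report how many."""
    keep = (matrix != 0).any(axis=1)
    return matrix.loc[keep], int((~keep).sum())


def log2_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 of counts after replacing zeros with ones."""
    if (matrix < 0).any().any():
        raise ValueError("counts must be non-negative")
    return np.log2(matrix.mask(matrix == 0, 1))


def correlation_and_projection(
    log_matrix: pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r^2 between samples and sample coordinates on the
    first principal axes of the feature-centered log matrix.

    A constant sample column yields NaN correlations (undefined marker).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(log_matrix.to_numpy().T)
    r2 = pd.DataFrame(r**2, index=log_matrix.columns, columns=log_matrix.columns)
    np.fill_diagonal(r2.values, 1.0)

    centered = log_matrix.sub(log_matrix.mean(axis=1), axis=0).to_numpy()
    # samples are observations: SVD of the (samples x features) matrix
    u, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    k = min(n_components, len(s))
    coords = pd.DataFrame(
        u[:, :k] * s[:k],
        index=log_matrix.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return r2, coords


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float
) -> float:
    """Doubly trimmed, inverse-variance-weighted mean of M values for one
    sample against the reference; returns the normalization factor."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic binomial variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.abs(m).max() < 1e-6:  # all ratios equal: factor exactly 1
        return 1.0
    n = m.size
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0**f)


def tmm_factors(
    matrix: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the one whose upper-quartile/library-size ratio
    is closest to the mean of those ratios across samples.
    """
    counts = matrix.to_numpy(dtype=float)
    lib_sizes = counts.sum(axis=0)
    if (lib_sizes == 0).any():
        raise ValueError("sample with all-zero counts")
    f75 = np.array(
        [np.quantile(counts[:, j], 0.75) / lib_sizes[j] for j in range(counts.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(counts[:, j], counts[:, ref_idx], trim_m, trim_a)
            for j in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# logFC / logCPM


@dataclass
class DGEResult:
    table: pd.DataFrame  # index features; logFC, logCPM, one_group_only, group means

    @property
    def one_group_only(self) -> pd.Series:
        return self.table["one_group_only"]


def logfc_logcpm(
    matrix: pd.DataFrame,
    factors: pd.Series,
    design: SampleDesign,
    group_a: str = "ribozero",
    group_b: str = "polyA",
    prior_count: float = 0.5,
) -> DGEResult:
    """Per-feature logCPM (prior 0.5, effective library size + 1) and logFC
    of group mean normalized abundances (group_a / group_b orientation).

    Features with a zero mean in either group are flagged one-group-only and
    have logFC undefined (NaN).
    """
    by_method = design.by_method()
    for g in (group_a, group_b):
        if g not in by_method:
            raise ValueError(f"design lacks samples of method {g!r}")
    eff = matrix.sum(axis=0) * factors[matrix.columns]
    cpm = np.log2((matrix + prior_count).div(eff + 1.0, axis=1) * 1e6)
    logcpm = cpm.mean(axis=1)
    norm = matrix.div(eff, axis=1)  # normalized abundance per sample
    mean_a = norm[by_method[group_a]].mean(axis=1)
    mean_b = norm[by_method[group_b]].mean(axis=1)
    one_group = (mean_a == 0) | (mean_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logfc = np.log2(mean_a / mean_b)
    logfc[one_group] = np.nan
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "logCPM": logcpm,
            "one_group_only": one_group,
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
        }
    )
    return DGEResult(table)


# ---------------------------------------------------------------------------
# GO enrichment


def go_fisher(
    selected: Iterable[str],
    term_map: Mapping[str, set[str]],
    background: Iterable[str],
    domain_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Two-sided Fisher's exact test per GO term with BH correction.

    The 2x2 table contrasts the selected gene set against the rest of the
    background.  When ``domain_of`` maps terms to GO domains, BH adjustment
    is applied within each domain separately; otherwise across all terms.
    Terms never seen in the background are skipped.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        raise ValueError("selected set must be contained in the background")
    rest = background - selected
    term_genes: dict[str, set[str]] = {}
    for gene in background:
        for term in term_map.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        a = len(genes & selected)
        b = len(selected) - a
        c = len(genes & rest)
        d = len(rest) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        expected = len(genes) * len(selected) / len(background)
        rows.append(
            {
                "term": term,
                "domain": (domain_of or {}).get(term, "all"),
                "in_set_with_term": a,
                "in_set_total": len(selected),
                "background_with_term": len(genes),
                "background_total": len(background),
                "direction": "over" if a > expected else "under",
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["adjusted_p"] = []
        return df
    adj = np.full(len(df), np.nan)
    for _, idx in df.groupby("domain").groups.items():
        adj[df.index.get_indexer(idx)] = multipletests(
            df.loc[idx, "p_value"], method="fdr_bh"
        )[1]
    df["adjusted_p"] = adj
    return df
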