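"""Primed vs lineage-specific chromatin accessibility scoring.

Enhancer priming — peaks already open in stem cells that later support
lineage-specific gene activation — is disentangled from de-novo
lineage-specific accessibility in four steps:

1. link peaks to genes by correlating metacell-level accessibility with
   expression (Pearson r >= 0.1, empirical permutation p <= 0.1);
2. restrict to peaks more accessible in the lineage of interest (an external
   differential-accessibility peak list, or the naive log2 fold-change
   screen provided here as plumbing);
3. classify each linked, lineage-relevant peak as *primed* if it is open in
   the reference (stem-cell) population under a Poisson openness test, else
   *lineage-specific*;
4. summarise per gene and cell as a correlation-weighted average of the
   class's peak accessibilities.

An in-silico ChIP score combining motif strength with expression-to-
accessibility correlation is provided for ranking TF targets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import poisson

__all__ = [
    "tfidf_normalize",
    "gene_peak_correlation",
    "peak_openness",
    "lineage_relevant_peaks",
    "classify_peaks",
    "accessibility_scores",
    "insilico_chip",
    "read_peaks_bed",
    "write_peaks_bed",
]


def tfidf_normalize(counts) -> np.ndarray | pd.DataFrame:
    """TF-IDF normalisation of a cells-by-peaks count matrix.

    Term frequency is the count divided by the cell's total; the inverse
    document frequency is the smoothed ``log(1 + N_cells / (1 + n_cells
    with the peak open))``, up-weighting peaks accessible in few cells.
    """
    df = counts if isinstance(counts, pd.DataFrame) else None
    X = np.asarray(counts, dtype=float)
    if np.any(X < 0):
        raise ValueError("counts must be nonnegative")
    totals = X.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("matrix contains all-zero cells")
    tf = X / totals
    n_cells = X.shape[0]
    df_count = (X > 0).sum(axis=0)
    idf = np.log(1.0 + n_cells / (1.0 + df_count))
    out = tf * idf
    if df is not None:
        return pd.DataFrame(out, index=df.index, columns=df.columns)
    return out


def gene_peak_correlation(
    expression,
    accessibility,
    pairs,
    *,
    n_permutations: int = 999,
    seed: int = 0,
    min_correlation: float = 0.1,
    max_pvalue: float = 0.1,
) -> pd.DataFrame:
    """Correlate gene expression with candidate peak accessibility across
    metacells, with an empirical permutation null.

    ``pairs`` is an iterable of ``(gene, peak)`` labels (e.g. peaks within a
    genomic window around each gene).  For each pair the Pearson correlation
    is computed across metacells; the empirical p-value permutes the
    metacell labels within the gene ``n_permutations`` times and counts
    permuted correlations at least as extreme in absolute value.  Pairs with
    ``corr >= min_correlation`` and ``p <= max_pvalue`` are marked ``linked``.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    expr = expression if isinstance(expression, pd.DataFrame) else pd.DataFrame(expression)
    acc = accessibility if isinstance(accessibility, pd.DataFrame) else pd.DataFrame(accessibility)
    if expr.shape[0] != acc.shape[0]:
        raise ValueError("expression and accessibility must share the metacell set")
    rng = np.random.default_rng(seed)
    n = expr.shape[0]
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])

    rows = []
    gene_cache: dict = {}
    for gene, peak in pairs:
        e = expr[gene].to_numpy(dtype=float)
        a = acc[peak].to_numpy(dtype=float)
        if np.std(e) == 0 or np.std(a) == 0:
            raise ValueError(f"constant vector for pair ({gene}, {peak})")
        r = float(np.corrcoef(e, a)[0, 1])
        if gene not in gene_cache:
            ec = (e - e.mean()) / (e.std() * np.sqrt(n))
            gene_cache[gene] = ec[perms]  # (B, n) permuted standardized expr
        ac = (a - a.mean()) / (a.std() * np.sqrt(n))
        r_perm = gene_cache[gene] @ ac
        p = float((1 + np.sum(np.abs(r_perm) >= abs(r))) / (n_permutations + 1))
        rows.append((gene, peak, r, p, r >= min_correlation and p <= max_pvalue))
    return pd.DataFrame(rows, columns=["gene", "peak", "corr", "p", "linked"])


def peak_openness(
    counts,
    num_peaks: int | None = None,
    *,
    bp_per_peak: int = 5000,
    alpha: float = 1e-2,
) -> np.ndarray:
    """Poisson openness call per peak for one cell type.

    The background rate is ``lambda = total fragments / effective genome
    length`` with the effective length ``num_peaks * 5000`` bp-equivalents.
    A peak with ``n`` fragments is open iff ``P(X > n) < alpha`` for
    ``X ~ Poisson(lambda)``.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if np.any(c < 0):
        raise ValueError("fragment counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("zero total fragments")
    if num_peaks is None:
        num_peaks = c.size
    lam = total / (num_peaks * bp_per_peak)  # effective genome length = num_peaks * 5000
    return poisson.sf(c, lam) < alpha


def lineage_relevant_peaks(
    accessibility,
    lineage_groups: dict,
    lineage: str,
    other_lineages,
    reference: str,
    *,
    min_lfc_vs_other: float = 0.0,
    min_lfc_vs_reference: float = 0.25,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Naive mean-log2-fold-change screen for lineage-relevant peaks.

    Plumbing in place of a full differential-accessibility test (an
    externally computed peak list may be supplied instead): a peak is
    retained if its mean metacell accessibility in the target lineage has
    ``log2FC > min_lfc_vs_other`` against at least one alternative lineage,
    and ubiquitously open peaks are removed by additionally requiring
    ``log2FC >= min_lfc_vs_reference`` against the reference (stem-cell)
    population.  Returns a boolean mask over peaks.
    """
    acc = accessibility if isinstance(accessibility, pd.DataFrame) else pd.DataFrame(accessibility)

    def group_mean(name):
        idx = lineage_groups[name]
        return acc.iloc[idx].to_numpy(dtype=float).mean(axis=0)

    target = group_mean(lineage)
    keep = np.zeros(acc.shape[1], dtype=bool)
    for other in other_lineages:
        lfc = np.log2(target + pseudocount) - np.log2(group_mean(other) + pseudocount)
        keep |= lfc > min_lfc_vs_other
    ref_lfc = np.log2(target + pseudocount) - np.log2(group_mean(reference) + pseudocount)
    keep &= ref_lfc >= min_lfc_vs_reference
    return keep


def classify_peaks(
    links: pd.DataFrame,
    lineage_relevant,
    reference_open,
    peak_ids=None,
) -> pd.DataFrame:
    """Assign ``primed`` / ``lineage_specific`` / ``excluded`` classes.

    A linked, lineage-relevant peak is *primed* if it is open in the
    reference (stem-cell) population and *lineage-specific* if it is not;
    everything else is excluded.

    ``lineage_relevant`` and ``reference_open`` are boolean arrays over the
    peak universe (ordered as ``peak_ids``, defaulting to the sorted unique
    peaks of ``links``).
    """
    if peak_ids is None:
        peak_ids = np.asarray(sorted(links["peak"].unique()))
    peak_ids = np.asarray(peak_ids)
    relevant = dict(zip(peak_ids, np.asarray(lineage_relevant, dtype=bool)))
    is_open = dict(zip(peak_ids, np.asarray(reference_open, dtype=bool)))
    out = links.copy()
    classes = []
    for _, row in out.iterrows():
        p = row["peak"]
        if not row.get("linked", True) or not relevant.get(p, False):
            classes.append("excluded")
        elif is_open.get(p, False):
            classes.append("primed")
        else:
            classes.append("lineage_specific")
    out["class"] = classes
    return out


def accessibility_scores(
    accessibility,
    links: pd.DataFrame,
    gene,
    peak_class: str,
) -> np.ndarray | None:
    """Per-cell primed or lineage-specific score for one gene.

    The score is the correlation-weighted average of the accessibilities of
    the gene's peaks of the requested class:
    ``s_ig = sum_p a_ip c_gp / sum_p c_gp``.  Returns ``None`` (logged) when
    the gene has no peak of that class.
    """
    acc = accessibility if isinstance(accessibility, pd.DataFrame) else pd.DataFrame(accessibility)
    sel = links[(links["gene"] == gene) & (links["class"] == peak_class)]
    if sel.empty:
        warnings.warn(f"gene {gene!r} has no {peak_class} peak; score undefined",
                      stacklevel=2)
        return None
    weights = sel["corr"].to_numpy(dtype=float)
    A = acc[sel["peak"].tolist()].to_numpy(dtype=float)
    return (A @ weights) / weights.sum()


def insilico_chip(
    correlations,
    motif_scores,
    max_accessibility,
    *,
    min_score: float = 0.15,
) -> np.ndarray | pd.DataFrame:
    """In-silico ChIP TF-binding scores on a peaks-by-TFs grid.

    ``x_ij = rho_ij * minmax_i(s_ij / max_i s_ij * max_a_i)`` where
    ``rho_ij`` is the expression-accessibility correlation, ``s_ij`` the
    motif score and ``max_a_i`` the peak's maximum accessibility over cell
    types; the minmax spans the TF's peaks.  Magnitudes below ``min_score``
    are set to exactly 0; the sign distinguishes activating (positive) from
    repressive (negative) predicted binding.
    """
    df = correlations if isinstance(correlations, pd.DataFrame) else None
    rho = np.atleast_2d(np.asarray(correlations, dtype=float))
    s = np.atleast_2d(np.asarray(motif_scores, dtype=float))
    a = np.asarray(max_accessibility, dtype=float).ravel()
    if rho.shape != s.shape or a.shape[0] != rho.shape[0]:
        raise ValueError("correlations, motif scores and accessibility disagree in shape")
    x = np.zeros_like(rho)
    for j in range(rho.shape[1]):
        smax = s[:, j].max()
        if smax <= 0:
            warnings.warn(f"TF column {j} has no positive motif score", stacklevel=2)
            continue
        scaled = s[:, j] / smax * a
        rng = scaled.max() - scaled.min()
        if rng == 0:
            warnings.warn(
                f"TF column {j} has a degenerate minmax (single value); scores set to 0",
                stacklevel=2,
            )
            continue
        mm = (scaled - scaled.min()) / rng
        x[:, j] = rho[:, j] * mm
    x[np.abs(x) < min_score] = 0.0
    if df is not None:
        return pd.DataFrame(x, index=df.index, columns=df.columns)
    return x


def read_peaks_bed(path: str) -> pd.DataFrame:
    """Read peak intervals from BED (0-based half-open) into a table with
    columns chrom/start/end and ``chrom:start-end`` peak ids."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"empty/negative interval in BED: {line!r}")
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["peak"] = [f"{c}:{s}-{e}" for c, s, e in rows]
    return df


def write_peaks_bed(peak_ids, path: str) -> None:
    """Write ``chrom:start-end`` peak ids as a BED file (0-based half-open)."""
    with open(path, "w") as fh:
        for pid in peak_ids:
            chrom, span = str(pid).rsplit(":", 1)
            start, end = span.split("-")
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\n")
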