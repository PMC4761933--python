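"""Expression preprocessing, differential selection and set statistics.

Covers probe filtering and gene collapsing of two-class expression cohorts,
differential gene selection (Welch t-test with Benjamini-Hochberg FDR),
differential protein selection (fold change + peptide support), the
direction-concordance Fisher test between the two platforms, and a
hypergeometric enrichment statistic for annotated gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Log-scale intensities, genes (or probes) x samples, with class labels."""

    values: pd.DataFrame  # index: gene/probe symbols, columns: sample IDs
    labels: pd.Series  # index: sample IDs, values: class tags

    def __post_init__(self):
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"samples missing phenotype labels: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def class_split(self) -> tuple[np.ndarray, np.ndarray]:
        """Value blocks of the two classes (sorted label order)."""
        cls = self.classes
        if len(cls) != 2:
            raise ValueError(f"expected exactly 2 classes, got {cls}")
        a = self.values.loc[:, self.labels == cls[0]].to_numpy(dtype=float)
        b = self.values.loc[:, self.labels == cls[1]].to_numpy(dtype=float)
        return a, b


def reference_normalize(values: pd.DataFrame, reference: str | None = None,
                        method: str = "median") -> pd.DataFrame:
    """Normalize each array against a reference array.

    ``median`` (default) shifts every column so its median matches the
    reference column's median (log-scale intensities, hence additive).
    ``quantile`` maps every column onto the mean quantile profile.
    """
    if method == "quantile":
        ranked = values.rank(method="first").astype(int) - 1
        mean_quantiles = np.sort(values.to_numpy(), axis=0).mean(axis=1)
        out = values.copy()
        for c in values.columns:
            out[c] = mean_quantiles[ranked[c].to_numpy()]
        return out
    if method != "median":
        raise ValueError(f"unknown normalization method {method!r}")
    ref = reference if reference is not None else values.columns[0]
    target = values[ref].median()
    return values - values.median(axis=0) + target


def filter_and_collapse(
    values: pd.DataFrame,
    probe_to_gene: pd.Series,
    labels: pd.Series,
    max_missing: float = 0.2,
    reference: str | None = None,
    normalization: str = "median",
    collapse: str = "mean",
) -> ExpressionMatrix:
    """Filter probes by missingness, normalize, and collapse probes to genes.

    Probes with a missing fraction strictly greater than ``max_missing`` are
    dropped; remaining missing entries are imputed at the probe mean.  Each
    array is then normalized against the reference array and multiple probes
    of one gene are collapsed to a single row (mean on the log scale, or the
    probe with maximal mean intensity when ``collapse="max"``).
    """
    probe_to_gene = probe_to_gene.reindex(values.index).dropna().map(str.upper)
    if probe_to_gene.empty:
        raise ValueError("gene map missing for all probes")
    values = values.loc[probe_to_gene.index]

    missing_frac = values.isna().mean(axis=1)
    keep = missing_frac <= max_missing
    values, probe_to_gene = values[keep], probe_to_gene[keep]
    if values.empty:
        raise ValueError("all probes removed by the missingness filter")
    values = values.apply(lambda row: row.fillna(row.mean()), axis=1)

    values = reference_normalize(values, reference=reference, method=normalization)

    if collapse == "mean":
        collapsed = values.groupby(probe_to_gene).mean()
    elif collapse == "max":
        intensity = values.mean(axis=1)
        best = intensity.groupby(probe_to_gene).idxmax()
        collapsed = values.loc[best]
        collapsed.index = best.index
    else:
        raise ValueError(f"unknown collapse rule {collapse!r}")
    collapsed.index.name = "gene"
    return ExpressionMatrix(values=collapsed.sort_index(), labels=labels)


def select_degs(m: ExpressionMatrix, p_cut: float = 1e-4, q_cut: float = 1e-4) -> pd.DataFrame:
    """Differentially expressed genes by Welch two-sample t-test + BH FDR.

    Direction is the sign of (second class mean - first class mean) in
    sorted label order, i.e. "up" means higher in the lexicographically
    later class (tumor vs normal under the usual tags).  Genes with zero
    variance in both classes get p = 1 rather than NaN, keeping totals
    deterministic.

    Returns a gene-indexed table with columns t, p, q, direction, selected.
    """
    a, b = m.class_split()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    diff = b.mean(axis=1) - a.mean(axis=1)
    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "direction": np.where(diff >= 0, "up", "down"),
            "selected": (p < p_cut) & (q < q_cut),
        },
        index=pd.Index(m.genes, name="gene"),
    )
    return out


def select_deps(
    table: pd.DataFrame,
    fold_threshold: float = 1.5,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Differentially expressed proteins by fold change and peptide support.

    ``table`` is protein-indexed with columns ``fold`` (tumor/normal mean
    ratio, linear scale) and ``peptides`` (unique-peptide count).  A protein
    is selected when it has at least ``min_peptides`` unique peptides and a
    fold change at or beyond ``fold_threshold`` in either direction
    (fold >= t, or fold <= 1/t).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    fold = table["fold"].to_numpy(dtype=float)
    if np.any(fold <= 0):
        raise ValueError("fold changes must be positive ratios")
    peptides = table["peptides"].to_numpy(dtype=int)
    up = fold >= fold_threshold
    down = fold <= 1.0 / fold_threshold
    out = table.copy()
    out["direction"] = np.where(up, "up", np.where(down, "down", "flat"))
    out["selected"] = (peptides >= min_peptides) & (up | down)
    return out


def direction_concordance(deps: pd.DataFrame, degs: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate protein vs gene regulation direction on the overlap.

    Both inputs are the selected subsets (or full tables; only rows with
    ``selected`` are used when the column is present).  Returns the 2x2
    table (protein direction x gene direction) and the two-sided Fisher
    exact p-value.  Raises on an empty overlap.
    """
    dep_sel = deps[deps["selected"]] if "selected" in deps else deps
    deg_sel = degs[degs["selected"]] if "selected" in degs else degs
    common = dep_sel.index.intersection(deg_sel.index)
    if common.empty:
        raise ValueError("no overlapping molecules between DEPs and DEGs")
    tab = pd.crosstab(
        dep_sel.loc[common, "direction"], deg_sel.loc[common, "direction"]
    ).reindex(index=["up", "down"], columns=["up", "down"], fill_value=0)
    tab.index.name, tab.columns.name = "protein", "gene"
    _, p = stats.fisher_exact(tab.to_numpy(), alternative="two-sided")
    return tab, float(p)


def hypergeometric_enrichment(
    query: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
    p_cut: float = 1e-4,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set in annotated terms.

    For each term with gene set G (intersected with the universe), the
    p-value is P[X >= |query & G|] for X hypergeometric with population
    |universe|, |G| successes and |query| draws.  BH adjustment across
    terms; ``significant`` flags adjusted p < ``p_cut``.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & set(universe)
    if not query <= set(universe):
        raise ValueError("query must be a subset of the universe")
    rows = []
    for term, genes in annotation.items():
        g = set(genes) & set(universe)
        k = len(query & g)
        p = stats.hypergeom.sf(k - 1, len(universe), len(g), len(query)) if g else 1.0
        rows.append((term, len(g), k, float(p)))
    df = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"]).set_index("term")
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    df["significant"] = df["p_adj"] < p_cut
    return df.sort_values(["p", "term"])
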