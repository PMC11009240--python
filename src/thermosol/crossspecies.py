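"""Cross-species aggregation: orthologs, protein classes, regulons, TPM.

Per-protein pSup tables and per-gene fold-change tables from different
species are joined through consumed ortholog maps, summarized by functional
class (chaperones, glycolytic enzymes, ribosomal proteins, superaggregators,
...), correlated across species x condition, and aggregated into regulon-
level responses whose cross-species rank correlation quantifies regulatory
conservation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "join_orthologs",
    "class_summary",
    "condition_correlation_matrix",
    "tuning_curve",
    "compute_tpm",
    "regulon_summary",
]


def join_orthologs(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    ortho_map: pd.DataFrame,
    key: str = "protein_id",
    one_to_many: str = "drop",
    suffixes: tuple[str, str] = ("_a", "_b"),
) -> pd.DataFrame:
    """Inner-join two per-species tables on an ortholog map.

    ``ortho_map`` has columns ``id_a`` and ``id_b``.  One-to-many ortholog
    relationships are dropped by default (preventing double counting in
    downstream correlations) or expanded with ``one_to_many="expand"``.
    Never fabricates pairs absent from the map.
    """
    for col in ("id_a", "id_b"):
        if col not in ortho_map.columns:
            raise ValueError(f"ortholog map missing column {col!r}")
    pairs = ortho_map[["id_a", "id_b"]].drop_duplicates()
    if one_to_many == "drop":
        counts_a = pairs["id_a"].value_counts()
        counts_b = pairs["id_b"].value_counts()
        keep = pairs["id_a"].map(counts_a).eq(1) & pairs["id_b"].map(counts_b).eq(1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            warnings.warn(f"dropped {n_dropped} one-to-many ortholog pairs")
        pairs = pairs[keep]
    elif one_to_many != "expand":
        raise ValueError("one_to_many must be 'drop' or 'expand'")

    merged = (
        pairs.merge(table_a.add_suffix(suffixes[0]), left_on="id_a",
                    right_on=key + suffixes[0])
        .merge(table_b.add_suffix(suffixes[1]), left_on="id_b",
               right_on=key + suffixes[1])
    )
    if merged.empty:
        raise ValueError("ortholog join produced no rows")
    return merged.reset_index(drop=True)


def class_summary(
    psups: pd.DataFrame,
    classes: dict | pd.Series,
    value: str = "psup",
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Mean +/- standard error of pSup per protein class.

    ``classes`` maps protein id -> class label.  Singleton classes get a
    missing SE; classes absent from the data are omitted with a warning.
    Extra grouping columns (condition, species) go in ``by``.
    """
    cls = pd.Series(classes) if isinstance(classes, dict) else classes
    df = psups.copy()
    df["protein_class"] = df["protein_id"].map(cls)
    df = df.dropna(subset=["protein_class", value])
    if df.empty:
        raise ValueError("no proteins with class labels and pSup values")
    missing = set(cls.unique()) - set(df["protein_class"].unique())
    if missing:
        warnings.warn(f"classes absent from data: {sorted(missing)}")
    keys = ["protein_class"] + (by or [])
    out = (
        df.groupby(keys)[value]
        .agg(
            mean="mean",
            se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
            n="size",
        )
        .reset_index()
    )
    return out


def condition_correlation_matrix(vectors: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Symmetric squared-Pearson (R^2) matrix across (species, condition) vectors.

    ``vectors`` has one column per species x condition cell, indexed by
    shared class labels (default, matching class-level summaries) or by
    ortholog-joined protein ids.  Every pairwise cell needs at least
    ``min_shared`` jointly non-missing entries and non-zero variance.
    """
    cols = list(vectors.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pair = vectors[[a, b]].dropna()
            if len(pair) < min_shared:
                raise ValueError(
                    f"only {len(pair)} shared entries between {a!r} and {b!r}"
                )
            x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(
                    f"zero-variance vector in pair ({a!r}, {b!r}); "
                    "correlation undefined"
                )
            r = np.corrcoef(x, y)[0, 1]
            out.iloc[i, j] = out.iloc[j, i] = r**2
    return out


def tuning_curve(
    psups: pd.DataFrame,
    classes: dict | pd.Series,
    focus: list[str],
    temperature: str = "temperature_c",
) -> pd.DataFrame:
    """Per-species, per-temperature class means for selected classes.

    Produces the table behind a pSup-versus-temperature tuning plot, e.g.
    contrasting non-condensing glycolytic proteins with strongly condensing
    superaggregators across species.
    """
    if temperature not in psups.columns:
        raise ValueError(f"missing temperature column {temperature!r}")
    by = [temperature] + (["species"] if "species" in psups.columns else [])
    summary = class_summary(psups, classes, by=by)
    present = set(summary["protein_class"])
    absent = [c for c in focus if c not in present]
    if absent:
        raise ValueError(f"focus classes missing from data: {absent}")
    return summary[summary["protein_class"].isin(focus)].reset_index(drop=True)


def compute_tpm(counts, lengths) -> np.ndarray:
    """Transcripts-per-million from per-gene counts and effective lengths.

    ``rate_i = counts_i / length_i``; ``TPM_i = 1e6 * rate_i / sum(rate)``.
    TPMs sum to 1e6 by construction.
    """
    counts = np.asarray(counts, float)
    lengths = np.asarray(lengths, float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have matching shapes")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("all counts zero; TPM normalization undefined")
    return 1e6 * rate / total


def regulon_summary(
    foldchanges: pd.DataFrame,
    regulon_map: dict | pd.Series | None = None,
    min_genes: int = 3,
    agg_columns: tuple[str, str] = ("gene", "log2fc"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regulon-level fold-change medians per species, plus cross-species rho.

    ``foldchanges`` is a long table with columns ``gene``, ``species``,
    ``log2fc`` and optionally ``regulator`` (else supplied via
    ``regulon_map``).  Regulons below ``min_genes`` genes are omitted with
    a warning.  Returns ``(per-regulon summary, pairwise Spearman rho of
    regulon medians across species)``; an undefined correlation (fewer than
    two regulons, or zero variance) is reported as NaN with a warning.
    """
    gene_col, fc_col = agg_columns
    df = foldchanges.copy()
    if "regulator" not in df.columns:
        if regulon_map is None:
            raise ValueError("need a 'regulator' column or a regulon_map")
        reg = pd.Series(regulon_map) if isinstance(regulon_map, dict) else regulon_map
        df["regulator"] = df[gene_col].map(reg)
        unmapped = df["regulator"].isna()
        if unmapped.any():
            raise ValueError(
                f"{int(unmapped.sum())} genes absent from the regulon map"
            )
    sizes = df.groupby(["species", "regulator"])[gene_col].size()
    small = sizes[sizes < min_genes]
    if not small.empty:
        warnings.warn(
            f"omitting {len(small)} regulon cells below the {min_genes}-gene floor"
        )
        df = df.set_index(["species", "regulator"]).drop(small.index).reset_index()

    summary = (
        df.groupby(["species", "regulator"])[fc_col]
        .agg(median="median", mean="mean", n="size")
        .reset_index()
    )
    medians = summary.pivot(index="regulator", columns="species", values="median")
    species = list(medians.columns)
    rho = pd.DataFrame(np.eye(len(species)), index=species, columns=species)
    for i, a in enumerate(species):
        for j in range(i + 1, len(species)):
            b = species[j]
            pair = medians[[a, b]].dropna()
            if len(pair) < 2 or pair[a].nunique() == 1 or pair[b].nunique() == 1:
                warnings.warn(f"Spearman rho undefined for ({a}, {b})")
                val = np.nan
            else:
                val = stats.spearmanr(pair[a], pair[b]).statistic
            rho.iloc[i, j] = rho.iloc[j, i] = val
    return summary, rho
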