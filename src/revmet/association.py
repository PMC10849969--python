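"""Phenotype association over repository search results.

Joins spectral matches against ReDU-style sample metadata and aggregates
them into the summaries used to read off where compounds occur: boolean
presence/absence matrices, per-phenotype detection proportions, log10 match
counts, binary-Jaccard ordination of sample compositions, and pairwise
two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment on
relative-abundance tables (CD vs non-IBD adjusted separately from UC vs
non-IBD, i.e. one BH family per group pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .matching import SpectralMatch, matches_to_frame

__all__ = [
    "load_metadata",
    "normalize_phenotype",
    "build_presence_matrix",
    "phenotype_proportions",
    "log_match_counts",
    "jaccard_matrix",
    "pcoa",
    "OrdinationResult",
    "AssociationResult",
    "pairwise_wilcoxon_bh",
]

#: Map of free-text phenotype labels to the controlled vocabulary used in
#: figures; unmapped labels pass through verbatim.
PHENOTYPE_SYNONYMS: dict[str, str] = {
    "healthy": "no disease",
    "normal": "no disease",
    "control": "no disease",
    "no_disease": "no disease",
    "none": "no disease",
    "non-ibd": "nonIBD",
    "non ibd": "nonIBD",
    "nonibd": "nonIBD",
    "crohn's disease": "CD",
    "crohns disease": "CD",
    "crohn disease": "CD",
    "ulcerative colitis": "UC",
    "inflammatory bowel disease": "IBD",
}

#: ReDU column headers accepted for the canonical metadata fields.
_REDU_COLUMNS = {
    "filename": "source_file",
    "SampleType": "sample_type",
    "UBERONBodyPartName": "body_site",
    "DiseaseCommon": "phenotype",
    "NCBITaxonomy": "organism",
    "MassiveID": "dataset_id",
}


def normalize_phenotype(label: str) -> str:
    return PHENOTYPE_SYNONYMS.get(str(label).strip().lower(), str(label).strip())


def load_metadata(path: str, missing_token: str = "missing") -> pd.DataFrame:
    """Read a sample-metadata table, accepting ReDU-like headers.

    Returns a frame indexed by ``source_file`` with normalized phenotype
    labels; empty controlled-vocabulary cells become ``missing_token``.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    df = df.rename(columns={k: v for k, v in _REDU_COLUMNS.items() if k in df.columns})
    if "source_file" not in df.columns:
        raise ValueError(f"metadata {path} lacks a source_file/filename column")
    if df["source_file"].duplicated().any():
        dupes = df.loc[df["source_file"].duplicated(), "source_file"].tolist()
        raise ValueError(f"duplicate source_file entries: {dupes}")
    for col in ("organism", "sample_type", "phenotype", "dataset_id"):
        if col not in df.columns:
            df[col] = missing_token
        df[col] = df[col].fillna(missing_token).replace("", missing_token)
    df["phenotype"] = df["phenotype"].map(normalize_phenotype)
    return df.set_index("source_file", drop=False)


def _as_frame(matches) -> pd.DataFrame:
    if isinstance(matches, pd.DataFrame):
        return matches
    return matches_to_frame(matches)


def build_presence_matrix(
    matches: Sequence[SpectralMatch] | pd.DataFrame,
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Boolean compound x sample detection matrix from criteria-passing matches.

    Cell (c, s) is True iff at least one match of compound c occurred in
    sample s. Matches whose source file is absent from the metadata are
    returned in an orphan report rather than silently dropped.
    """
    df = _as_frame(matches)
    samples = list(metadata.index)
    known = set(samples)
    orphans = sorted(set(df.loc[~df["source_file"].isin(known), "source_file"]))
    df = df[df["source_file"].isin(known)]
    compounds = sorted(df["query_id"].unique())
    matrix = pd.DataFrame(False, index=compounds, columns=samples)
    for cid, sf in zip(df["query_id"], df["source_file"]):
        matrix.at[cid, sf] = True
    return matrix, orphans


def phenotype_proportions(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    group_by: str = "phenotype",
) -> pd.DataFrame:
    """Per-(compound, phenotype) detection proportions.

    Groups with zero samples are excluded (nothing to divide by).
    """
    labels = metadata.loc[matrix.columns, group_by]
    rows = []
    for label, cols in labels.groupby(labels):
        sub = matrix[cols.index]
        n = sub.shape[1]
        if n == 0:
            continue
        detected = sub.sum(axis=1)
        for cid in matrix.index:
            rows.append({
                "compound_id": cid, group_by: label,
                "n_samples": n, "n_detected": int(detected[cid]),
                "proportion": detected[cid] / n,
            })
    return pd.DataFrame(rows)


def log_match_counts(
    matches: Sequence[SpectralMatch] | pd.DataFrame,
    metadata: pd.DataFrame,
    category: str = "sample_type",
) -> pd.DataFrame:
    """log10 spectral-match counts per (compound, metadata category).

    Cells with zero matches are simply absent from the long-format result
    rather than carrying -inf.
    """
    df = _as_frame(matches)
    df = df[df["source_file"].isin(metadata.index)].copy()
    df[category] = metadata.loc[df["source_file"], category].to_numpy()
    counts = (df.groupby(["query_id", category], observed=True)
                .size().rename("n_matches").reset_index()
                .rename(columns={"query_id": "compound_id"}))
    counts["log10_matches"] = np.log10(counts["n_matches"])
    return counts


def jaccard_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise binary Jaccard distances between sample columns.

    Samples in which no compound was detected are dropped first (Jaccard is
    undefined for two empty sets) and reported in the returned census.
    """
    occupied = matrix.columns[matrix.any(axis=0)]
    dropped = [c for c in matrix.columns if c not in set(occupied)]
    sub = matrix[occupied]
    if sub.shape[1] < 2:
        raise ValueError("need >= 2 non-empty samples for a distance matrix")
    dm = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(sub.T.to_numpy(dtype=bool), metric="jaccard"))
    return pd.DataFrame(dm, index=occupied, columns=occupied), dropped


@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling (PCoA) output."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only
    negative_eigenvalues: np.ndarray


def pcoa(dist: pd.DataFrame | np.ndarray, k: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis by classical scaling.

    Double-centers -0.5 * D^2, eigendecomposes, and scales eigenvectors by
    the square roots of the positive eigenvalues. Axes for negative
    eigenvalues (non-Euclidean distances) are omitted but the eigenvalues
    are reported.
    """
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = scipy.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # eigenvalues that are zero up to symmetric-eigensolver noise are dropped
    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    negative = eigvals < -tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    if k is not None:
        coords = coords[:, :k]
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    frame = pd.DataFrame(
        coords,
        index=labels if labels is not None else range(n),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(frame, eigvals, prop, eigvals[negative])


@dataclass(frozen=True)
class AssociationResult:
    compound_id: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    q_value: float
    direction: int  # sign of median(a) - median(b)
    n_a: int
    n_b: int
    tie_flag: bool = False


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray, exact_max_n: int = 25
                       ) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small untied samples, normal approximation with
    tie correction otherwise; all-tied data reports p = 1 with a tie flag.
    """
    pooled = np.concatenate([a, b])
    tied = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, True
    if not tied and max(len(a), len(b)) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), min(float(res.pvalue), 1.0), tied


def pairwise_wilcoxon_bh(
    abundance: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    pairs: Iterable[tuple[str, str]],
    exact_max_n: int = 25,
) -> list[AssociationResult]:
    """Per-compound pairwise Wilcoxon tests with BH adjustment per pair.

    ``abundance`` has compounds as rows and samples as columns; ``groups``
    maps sample id to group label. Each group pair forms its own BH family
    across compounds.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    results: list[AssociationResult] = []
    for ga, gb in pairs:
        cols_a = [c for c in abundance.columns if groups.get(c) == ga]
        cols_b = [c for c in abundance.columns if groups.get(c) == gb]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValueError(f"pair ({ga}, {gb}) needs >= 2 samples per group")
        family: list[AssociationResult] = []
        pvals = []
        for cid in abundance.index:
            a = abundance.loc[cid, cols_a].to_numpy(dtype=float)
            b = abundance.loc[cid, cols_b].to_numpy(dtype=float)
            stat, p, tied = _wilcoxon_rank_sum(a, b, exact_max_n)
            family.append(AssociationResult(
                compound_id=str(cid), group_a=ga, group_b=gb,
                statistic=stat, p_value=p, q_value=np.nan,
                direction=int(np.sign(np.median(a) - np.median(b))),
                n_a=len(a), n_b=len(b), tie_flag=tied,
            ))
            pvals.append(p)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for res, q in zip(family, qvals):
            results.append(AssociationResult(
                res.compound_id, res.group_a, res.group_b, res.statistic,
                res.p_value, float(min(q, 1.0)), res.direction,
                res.n_a, res.n_b, res.tie_flag,
            ))
    return results


def association_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
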