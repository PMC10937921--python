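"""Paired pre-/on-treatment expression data: loading, filtering, normalization.

The analysis operates on per-patient *expression changes*: for every patient
with samples at both timepoints, the on-treatment minus pre-treatment
difference of (log-scale) normalized values, with each gene subsequently
divided by its cross-patient standard deviation (no mean centering, so the
sign of the change is preserved).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIMEPOINTS = ("pre", "on")
RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")


class AlignmentError(ValueError):
    """Gene or sample identifiers disagree between input tables."""


@dataclass
class ExpressionStudy:
    """Gene x sample raw counts and normalized (log-like) expression values.

    ``samples`` is indexed by sample id and carries ``patient_id`` and
    ``timepoint`` (``pre`` or ``on``) columns. Both matrices share the same
    genes (rows) and samples (columns); each patient contributes at most one
    sample per timepoint.
    """

    raw_counts: pd.DataFrame
    norm_values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.raw_counts.shape != self.norm_values.shape:
            raise AlignmentError(
                f"raw_counts {self.raw_counts.shape} and norm_values "
                f"{self.norm_values.shape} differ in shape"
            )
        if list(self.raw_counts.index) != list(self.norm_values.index):
            raise AlignmentError("gene order differs between counts and normalized values")
        if list(self.raw_counts.columns) != list(self.norm_values.columns):
            raise AlignmentError("sample order differs between counts and normalized values")
        if self.raw_counts.index.duplicated().any():
            dups = self.raw_counts.index[self.raw_counts.index.duplicated()].tolist()
            raise AlignmentError(f"duplicate gene ids: {dups}")
        missing = [s for s in self.raw_counts.columns if s not in self.samples.index]
        if missing:
            raise AlignmentError(f"samples missing from metadata: {missing}")
        bad_tp = set(self.samples["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoint labels: {sorted(bad_tp)}")
        meta = self.samples.loc[list(self.raw_counts.columns)]
        if meta.duplicated(subset=["patient_id", "timepoint"]).any():
            dup = meta[meta.duplicated(subset=["patient_id", "timepoint"], keep=False)]
            raise ValueError(
                "patients with more than one sample per timepoint: "
                f"{sorted(set(dup['patient_id']))}"
            )
        if (self.raw_counts.to_numpy() < 0).any():
            raise ValueError("raw counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.raw_counts.index)

    @property
    def n_genes(self) -> int:
        return self.raw_counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.raw_counts.shape[1]

    def matched_patients(self) -> list[str]:
        """Patients with a sample at both timepoints, in metadata order."""
        meta = self.samples.loc[list(self.raw_counts.columns)]
        by_patient = meta.groupby("patient_id", sort=False)["timepoint"].agg(set)
        return [p for p, tps in by_patient.items() if {"pre", "on"} <= tps]


@dataclass
class DifferenceMatrix:
    """Per-patient on-minus-pre expression changes (gene x patient).

    ``scaled`` records whether gene rows have been divided by their
    cross-patient standard deviation.
    """

    values: pd.DataFrame
    scaled: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_expression(counts_path, norm_path, sample_meta_path) -> ExpressionStudy:
    """Read raw counts, normalized values and sample metadata TSVs.

    The matrices have genes as rows (first column = gene id) and a header of
    sample ids; the metadata table has columns ``sample_id``, ``patient_id``,
    ``timepoint``. Gene sets must agree exactly between the two matrices.
    """
    counts = _read_matrix(counts_path)
    norm = _read_matrix(norm_path)
    meta = pd.read_csv(sample_meta_path, sep="\t", dtype=str).set_index("sample_id")

    only_counts = set(counts.index) - set(norm.index)
    only_norm = set(norm.index) - set(counts.index)
    if only_counts or only_norm:
        raise AlignmentError(
            f"gene sets differ: {sorted(only_counts)} only in counts, "
            f"{sorted(only_norm)} only in normalized values"
        )
    norm = norm.loc[counts.index]
    if set(counts.columns) != set(norm.columns):
        raise AlignmentError(
            "sample sets differ between counts and normalized values: "
            f"{sorted(set(counts.columns) ^ set(norm.columns))}"
        )
    norm = norm[counts.columns]
    return ExpressionStudy(raw_counts=counts, norm_values=norm, samples=meta)


def read_counts_table(path) -> pd.DataFrame:
    """Permissive reader for series-supplementary-style count tables.

    Accepts comma- or tab-separated files whose first column is the gene
    identifier; useful for public repository exports that do not follow the
    package's own TSV convention. Not used by the standard pipeline readers.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_clinical(path) -> pd.DataFrame:
    """Read the patient clinical table (patient_id, response, os_time, os_event).

    One row per patient; survival time must be nonnegative and the event
    indicator binary. Units of ``os_time`` are taken as given.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    df = df.set_index("patient_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate patient_id rows in clinical table")
    bad = set(df["response"]) - set(RESPONSE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown response categories: {sorted(bad)}")
    if (df["os_time"].astype(float) < 0).any():
        raise ValueError("os_time must be nonnegative")
    if not set(df["os_event"].astype(int)) <= {0, 1}:
        raise ValueError("os_event must be 0/1")
    df["os_time"] = df["os_time"].astype(float)
    df["os_event"] = df["os_event"].astype(int)
    return df


def filter_low_expression(
    study: ExpressionStudy, min_count: int = 10, frac_threshold: float = 0.90
) -> ExpressionStudy:
    """Drop genes with fewer than ``min_count`` raw counts in more than
    ``frac_threshold`` of samples.

    "More than" is strict: a gene low in exactly 90% of samples is retained
    at the default threshold. Idempotent; survivor order is preserved.
    """
    counts = study.raw_counts.to_numpy()
    frac_low = (counts < min_count).mean(axis=1)
    keep = frac_low <= frac_threshold
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("low-expression filter dropped %d of %d genes", n_dropped, len(keep))
    return ExpressionStudy(
        raw_counts=study.raw_counts.loc[keep],
        norm_values=study.norm_values.loc[keep],
        samples=study.samples,
    )


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Quantile-normalize the normalized-value columns across samples.

    Every sample column is mapped onto the common reference distribution
    (the mean of per-rank values over samples), preserving within-column
    ranks. Ties within a column receive the mean of the reference values
    spanned by the tied ranks.
    """
    X = study.norm_values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return study
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranked = reference.copy()
        # mean-tie rule: tied values share the mean reference over their rank span
        sorted_vals = col[order]
        i = 0
        while i < n_genes:
            k = i
            while k + 1 < n_genes and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            if k > i:
                ranked[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = ranked
    norm = pd.DataFrame(out, index=study.norm_values.index, columns=study.norm_values.columns)
    return ExpressionStudy(raw_counts=study.raw_counts, norm_values=norm, samples=study.samples)


def map_gene_ids(study: ExpressionStudy, mapping: pd.DataFrame) -> ExpressionStudy:
    """Rename genes via a two-column (source_id, symbol) mapping table.

    Genes without a mapping are dropped (count logged). When several source
    ids map to one symbol, the row with the highest mean raw count is kept.
    """
    if mapping.shape[1] < 2 or len(mapping) == 0:
        raise ValueError("mapping table must be nonempty with two columns (source_id, symbol)")
    lut = dict(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    mapped = [lut.get(g) for g in study.gene_ids]
    keep = [m is not None for m in mapped]
    n_unmapped = keep.count(False)
    if n_unmapped:
        logger.warning("map_gene_ids: dropping %d unmapped genes", n_unmapped)
    counts = study.raw_counts.loc[keep].copy()
    norm = study.norm_values.loc[keep].copy()
    symbols = [m for m in mapped if m is not None]
    counts.index = norm.index = pd.Index(symbols, name=study.raw_counts.index.name)

    if counts.index.duplicated().any():
        mean_counts = counts.mean(axis=1).to_numpy()
        best: dict[str, int] = {}
        for i, sym in enumerate(counts.index):
            if sym not in best or mean_counts[i] > mean_counts[best[sym]]:
                best[sym] = i
        rows = sorted(best.values())
        logger.warning(
            "map_gene_ids: %d duplicate symbols resolved by highest mean raw count",
            len(counts) - len(rows),
        )
        counts = counts.iloc[rows]
        norm = norm.iloc[rows]
    return ExpressionStudy(raw_counts=counts, norm_values=norm, samples=study.samples)


def paired_difference(study: ExpressionStudy) -> DifferenceMatrix:
    """On-treatment minus pre-treatment normalized expression per matched patient.

    Patients lacking either timepoint are excluded; at least one matched
    patient is required.
    """
    meta = study.samples.loc[list(study.norm_values.columns)]
    patients = study.matched_patients()
    if not patients:
        raise ValueError("no patients with both pre and on samples")
    cols = {}
    for p in patients:
        rows = meta[meta["patient_id"] == p]
        pre = rows.index[rows["timepoint"] == "pre"][0]
        on = rows.index[rows["timepoint"] == "on"][0]
        cols[p] = study.norm_values[on] - study.norm_values[pre]
    values = pd.DataFrame(cols, index=study.norm_values.index)
    return DifferenceMatrix(values=values, scaled=False)


def scale_differences(diff: DifferenceMatrix, ddof: int = 1) -> DifferenceMatrix:
    """Divide each gene row by its standard deviation across patients.

    The mean is deliberately *not* subtracted, so positive and negative
    expression changes keep their sign. Sample standard deviation (n-1
    denominator) is used. Genes with zero variance are set to zero with a
    warning rather than dropped, keeping the gene set aligned with the
    network construction downstream.
    """
    if diff.scaled:
        raise ValueError("difference matrix is already scaled")
    X = diff.values.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=ddof)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"scale_differences: {int(zero.sum())} zero-variance genes set to 0"
        )
    sd_safe = np.where(zero, 1.0, sd)
    out = X / sd_safe[:, None]
    out[zero, :] = 0.0
    values = pd.DataFrame(out, index=diff.values.index, columns=diff.values.columns)
    return DifferenceMatrix(values=values, scaled=True)
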