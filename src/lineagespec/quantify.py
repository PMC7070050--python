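"""Count containers, FPKM normalization and expressed-gene calling.

The pipeline starts from a gene-level count matrix with per-gene transcript
lengths and a sample sheet mapping samples to cell types and replicates.
Expression throughout the package is reported as FPKM (fragments per kilobase
of transcript per million mapped fragments):

    FPKM(g, s) = count(g, s) * 1e9 / (length(g) * total_count(s))

Size factors for the differential-expression test use the median-of-ratios
estimator (ratio of each sample to the per-gene geometric mean, computed over
genes with no zero count), rescaled to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "compute_fpkm",
    "size_factors",
    "expressed_genes",
    "read_counts",
    "read_sample_sheet",
]


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus gene lengths and sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id with one column per sample_id;
        non-negative integers.
    lengths
        Series of transcript lengths (nt) indexed by gene_id, all > 0.
    samples
        DataFrame indexed by sample_id with columns ``cell_type`` and
        ``replicate``, aligned with ``counts.columns``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene_ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample_ids in count matrix")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.counts.index[self.lengths.isna()][:5].tolist()
            raise ValueError(f"genes missing lengths: {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.samples = self.samples.reindex(self.counts.columns)
        if self.samples.isna().any().any():
            raise ValueError("sample sheet does not cover all count columns")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, cell_type: str) -> list[str]:
        """Sample ids belonging to one cell type, in sheet order."""
        hit = self.samples.index[self.samples["cell_type"] == cell_type]
        if len(hit) == 0:
            raise KeyError(f"unknown cell type: {cell_type!r}")
        return list(hit)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[sample_ids].copy(),
            lengths=self.lengths.copy(),
            samples=self.samples.loc[sample_ids].copy(),
        )


@dataclass
class ExpressionMatrix:
    """FPKM per (gene, sample) with the sample sheet carried along."""

    fpkm: pd.DataFrame
    samples: pd.DataFrame
    provenance: str = "fpkm"
    _mean_cache: dict = field(default_factory=dict, repr=False)

    def group_means(self, cell_types: list[str] | None = None) -> pd.DataFrame:
        """Mean FPKM per cell type (columns ordered as requested)."""
        if cell_types is None:
            cell_types = list(dict.fromkeys(self.samples["cell_type"]))
        key = tuple(cell_types)
        if key not in self._mean_cache:
            cols = {}
            for ct in cell_types:
                ids = self.samples.index[self.samples["cell_type"] == ct]
                if len(ids) == 0:
                    raise KeyError(f"unknown cell type: {ct!r}")
                cols[ct] = self.fpkm[list(ids)].mean(axis=1)
            self._mean_cache[key] = pd.DataFrame(cols)
        return self._mean_cache[key]


def compute_fpkm(cm: CountMatrix) -> ExpressionMatrix:
    """FPKM = count * 1e9 / (length * per-sample total count).

    Raises ``ValueError`` naming the sample if any sample has zero total.
    """
    totals = cm.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero)}")
    fpkm = cm.counts * 1e9
    fpkm = fpkm.div(totals, axis=1).div(cm.lengths, axis=0)
    return ExpressionMatrix(fpkm=fpkm, samples=cm.samples.copy())


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with strictly positive counts in every sample enter the
    per-gene geometric mean (the zero-safe convention).
    """
    counts = cm.counts.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "filter to expressed genes before computing size factors"
        )
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=cm.sample_ids, name="size_factor")
    logc = np.log(counts[allpos])
    loggeo = logc.mean(axis=1, keepdims=True)
    logratios = logc - loggeo
    logsf = np.median(logratios, axis=0)
    logsf = logsf - logsf.mean()  # geometric mean 1
    return pd.Series(np.exp(logsf), index=cm.sample_ids, name="size_factor")


def expressed_genes(
    em: ExpressionMatrix,
    group: str,
    threshold: float = 1.0,
    strict: bool = False,
) -> set[str]:
    """Genes whose mean FPKM over the group's replicates reaches the cutoff.

    ``strict=True`` requires mean FPKM > threshold, otherwise >= threshold.
    The detected-gene convention in this study is FPKM > 1 for whole
    transcriptomes but FPKM >= 1 for TF and isoform subsets, hence the flag.
    """
    ids = em.samples.index[em.samples["cell_type"] == group]
    if len(ids) == 0:
        raise KeyError(f"unknown cell type: {group!r}")
    means = em.fpkm[list(ids)].mean(axis=1)
    keep = means > threshold if strict else means >= threshold
    keep &= means > 0  # an all-zero gene is never "expressed"
    return set(means.index[keep])


# ---------------------------------------------------------------------------
# TSV interchange


def read_counts(counts_tsv, samples_tsv) -> CountMatrix:
    """Read a counts TSV (gene_id, length, one column per sample) plus a
    sample sheet TSV (sample_id, cell_type, replicate)."""
    tab = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    if "length" not in tab.columns:
        raise ValueError("counts TSV must have a 'length' column")
    lengths = tab["length"]
    counts = tab.drop(columns=["length"])
    samples = read_sample_sheet(samples_tsv)
    return CountMatrix(counts=counts, lengths=lengths, samples=samples)


def read_sample_sheet(samples_tsv) -> pd.DataFrame:
    sheet = pd.read_csv(samples_tsv, sep="\t", index_col=0)
    need = {"cell_type", "replicate"}
    if not need.issubset(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(need)}")
    return sheet


def write_counts(cm: CountMatrix, counts_tsv, samples_tsv) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.lengths)
    out.to_csv(counts_tsv, sep="\t", index_label="gene_id")
    cm.samples.to_csv(samples_tsv, sep="\t", index_label="sample_id")
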