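"""Shared tabular containers and TSV I/O helpers.

All pipeline stages exchange participant-by-feature tables. The canonical
on-disk form is tab-delimited text with a header row and the sample
identifier in the first column.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

INDEX_LABEL = "participant_id"


@dataclass
class FeatureMatrix:
    """A numeric sample-by-feature table with optional metadata.

    Parameters
    ----------
    values
        DataFrame with samples as rows and features as columns.
    feature_meta
        Per-feature annotations indexed by feature id (taxonomic lineage,
        exclusion flags, metabolite annotation, planted ground truth ...).
    sample_meta
        Per-sample annotations indexed by sample id (``qc`` flag,
        ``injection_order``, batch ...).
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, ids) -> "FeatureMatrix":
        sm = self.sample_meta.loc[ids] if self.sample_meta is not None else None
        return FeatureMatrix(self.values.loc[ids], self.feature_meta, sm)

    def subset_features(self, ids) -> "FeatureMatrix":
        fm = self.feature_meta.loc[ids] if self.feature_meta is not None else None
        return FeatureMatrix(self.values[list(ids)], fm, self.sample_meta)

    def study_samples(self) -> "FeatureMatrix":
        """Drop QC injections (rows flagged ``qc`` in sample_meta)."""
        if self.sample_meta is None or "qc" not in self.sample_meta.columns:
            return self
        keep = self.sample_meta.index[~self.sample_meta["qc"].astype(bool)]
        return self.subset_samples(keep)

    def write_tsv(self, path: str | Path, *, meta_suffix: bool = True) -> None:
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label=INDEX_LABEL)
        if meta_suffix:
            if self.feature_meta is not None:
                self.feature_meta.to_csv(
                    path.with_suffix(".features.tsv"), sep="\t", index_label="feature_id"
                )
            if self.sample_meta is not None:
                self.sample_meta.to_csv(
                    path.with_suffix(".samples.tsv"), sep="\t", index_label=INDEX_LABEL
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col=0)
        feature_meta = sample_meta = None
        fpath = path.with_suffix(".features.tsv")
        spath = path.with_suffix(".samples.tsv")
        if fpath.exists():
            feature_meta = pd.read_csv(fpath, sep="\t", index_col=0)
        if spath.exists():
            sample_meta = pd.read_csv(spath, sep="\t", index_col=0)
        return cls(values, feature_meta, sample_meta)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = INDEX_LABEL) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
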