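"""Amplicon count-table container and TSV I/O.

An :class:`AsvTable` bundles a samples x ASVs integer count matrix with
per-sample metadata (fraction FL/PA/sediment, water layer, region,
station) and per-ASV taxonomy strings.  Tables on disk follow the common
amplicon convention: counts as a TSV with ASVs in rows and samples in
columns, metadata and taxonomy as separate TSVs keyed by sample / ASV id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_METADATA = ("fraction", "layer")


@dataclass
class AsvTable:
    counts: pd.DataFrame                    # samples x ASVs, integers
    sample_metadata: pd.DataFrame           # indexed by sample id
    taxonomy: pd.DataFrame | None = None    # indexed by ASV id

    def __post_init__(self) -> None:
        c = self.counts
        if not c.index.is_unique or not c.columns.is_unique:
            raise ValueError("sample and ASV ids must be unique")
        arr = c.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        missing = set(c.index) - set(self.sample_metadata.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        for col in REQUIRED_METADATA:
            if col not in self.sample_metadata.columns:
                raise ValueError(f"sample metadata must contain '{col}'")
        self.sample_metadata = self.sample_metadata.loc[c.index]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, mask) -> "AsvTable":
        """New table restricted to samples selected by a boolean mask or
        an index list (ASV universe is kept intact)."""
        counts = self.counts.loc[mask]
        return AsvTable(counts, self.sample_metadata.loc[counts.index],
                        self.taxonomy)

    def subset_asvs(self, asv_ids) -> "AsvTable":
        counts = self.counts.loc[:, asv_ids]
        tax = self.taxonomy.loc[counts.columns] if self.taxonomy is not None \
            else None
        return AsvTable(counts, self.sample_metadata, tax)

    def select(self, **criteria) -> "AsvTable":
        """Subset samples by metadata equality, e.g.
        ``table.select(fraction="FL", layer="surface")``."""
        mask = pd.Series(True, index=self.counts.index)
        for key, value in criteria.items():
            col = self.sample_metadata[key]
            if isinstance(value, (list, tuple, set)):
                mask &= col.isin(list(value))
            else:
                mask &= col == value
        return self.subset_samples(mask)

    def totals(self) -> pd.Series:
        """Library size (total reads) per sample."""
        return self.counts.sum(axis=1)

    # ---------------------------------------------------------------- I/O

    def write(self, prefix: str | Path) -> None:
        """Write ``<prefix>.counts.tsv`` (ASVs x samples),
        ``<prefix>.metadata.tsv`` and, if present,
        ``<prefix>.taxonomy.tsv``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.counts.T.to_csv(f"{prefix}.counts.tsv", sep="\t",
                             index_label="asv")
        self.sample_metadata.to_csv(f"{prefix}.metadata.tsv", sep="\t",
                                    index_label="sample")
        if self.taxonomy is not None:
            self.taxonomy.to_csv(f"{prefix}.taxonomy.tsv", sep="\t",
                                 index_label="asv")

    @classmethod
    def read(cls, prefix: str | Path) -> "AsvTable":
        prefix = Path(prefix)
        counts = pd.read_csv(f"{prefix}.counts.tsv", sep="\t",
                             index_col="asv").T
        counts.index.name = "sample"
        counts.columns.name = None
        meta = pd.read_csv(f"{prefix}.metadata.tsv", sep="\t",
                           index_col="sample")
        tax_path = Path(f"{prefix}.taxonomy.tsv")
        tax = pd.read_csv(tax_path, sep="\t", index_col="asv") \
            if tax_path.exists() else None
        return cls(counts.astype(int), meta, tax)
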