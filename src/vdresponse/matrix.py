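"""Gene-by-sample expression container bound to sample metadata.

The matrix holds log2-scale intensities (genes in rows, samples in
columns) together with a per-sample metadata table describing the study
design: which subject the sample came from, whether it is the baseline or
follow-up visit, the daily vitamin D3 dose arm, and the subject's baseline
vitamin D status class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VISITS = ("baseline", "followup")
STATUSES = ("deficient", "insufficient_sufficient")

REQUIRED_META = ("subject", "visit", "dose", "status")


@dataclass
class ExpressionMatrix:
    """Log2 expression values with aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    meta
        DataFrame indexed by sample id with at least the columns
        ``subject``, ``visit`` (baseline/followup), ``dose`` (IU/day)
        and ``status`` (deficient / insufficient_sufficient).
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {sorted(set(dups))}")
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        lacking = [c for c in REQUIRED_META if c not in self.meta.columns]
        if lacking:
            raise ValueError(f"metadata missing required columns: {lacking}")
        bad_visit = set(self.meta["visit"]) - set(VISITS)
        if bad_visit:
            raise ValueError(f"unknown visit labels: {sorted(bad_visit)}")
        self.meta = self.meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_ids_for(self, **criteria) -> list[str]:
        """Sample ids whose metadata matches all keyword criteria."""
        mask = np.ones(len(self.meta), dtype=bool)
        for key, val in criteria.items():
            mask &= (self.meta[key] == val).to_numpy()
        return list(self.meta.index[mask])

    def paired_columns(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Return (subjects, baseline values, followup values).

        Columns are aligned subject-by-subject; raises if any subject
        lacks one of the two visits.
        """
        subjects = sorted(self.meta["subject"].unique())
        base_cols, follow_cols = [], []
        for subj in subjects:
            rows = self.meta[self.meta["subject"] == subj]
            for visit, store in (("baseline", base_cols), ("followup", follow_cols)):
                hit = rows.index[rows["visit"] == visit]
                if len(hit) != 1:
                    raise ValueError(
                        f"subject {subj!r} does not have exactly one "
                        f"{visit} sample"
                    )
                store.append(hit[0])
        base = self.values[base_cols].to_numpy(dtype=float)
        follow = self.values[follow_cols].to_numpy(dtype=float)
        return subjects, base, follow

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.meta.copy())
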