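"""In-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotypes import beta_to_m

ANNOT_COLUMNS = ["chr", "pos", "gene", "gene_region"]


@dataclass
class MethylationMatrix:
    """Beta-value matrix (sites x samples) with per-site genomic annotation.

    ``beta`` is a DataFrame indexed by site id with one column per sample id;
    ``annotation`` is indexed by the same site ids with columns
    chr / pos (1-based, build b37) / gene / gene_region.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annotation is None:
            self.annotation = pd.DataFrame(
                {"chr": "", "pos": 0, "gene": "", "gene_region": ""},
                index=self.beta.index,
            )
        if not self.beta.index.is_unique:
            raise ValueError("site ids must be unique")
        if not self.beta.index.equals(self.annotation.index):
            raise ValueError("annotation index must match beta site ids")
        vals = self.beta.to_numpy()
        if np.any((vals <= 0.0) | (vals >= 1.0)) or np.any(~np.isfinite(vals)):
            raise ValueError("beta-values must lie strictly in (0, 1)")

    @property
    def site_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_sites(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def m_values(self) -> pd.DataFrame:
        """Base-2 logit transform of the beta matrix."""
        return pd.DataFrame(
            beta_to_m(self.beta.to_numpy()),
            index=self.beta.index,
            columns=self.beta.columns,
        )

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.beta.loc[:, list(sample_ids)], self.annotation)

    def subset_sites(self, site_ids) -> "MethylationMatrix":
        ids = list(site_ids)
        return MethylationMatrix(self.beta.loc[ids], self.annotation.loc[ids])
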