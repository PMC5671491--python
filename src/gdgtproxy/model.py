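"""Regression screen of lipid variables against MG-II gene enrichment.

The core statistical object of the package: for each (variable, lipid
pool) cell, an ordinary least-squares regression of the per-sample lipid
variable on the [MG-II 16S]/[Archaea 16S] qPCR copy ratio across the
water-column (SPM) samples.  A significant positive slope for a
ring-bearing variable (RI_2, %GDGT-1..4) is the evidence that MG-II
Euryarchaeota contribute cyclopentane-ring GDGTs to the pool.

Follows the Model/Results idiom: build a :class:`RingEnrichmentModel`
from a :class:`~gdgtproxy.dataset.Dataset`, call :meth:`fit`, and read the
:class:`RingEnrichmentResults` matrices or its :meth:`summary` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import POOLS, Dataset
from .stats import RegressionResult, gene_ratio, ols_regression, resolve_variable

__all__ = ["RingEnrichmentModel", "RingEnrichmentResults", "regression_screen"]

DEFAULT_Y_VARIABLES = ("ri2",)


class RingEnrichmentModel:
    """OLS screen of lipid variables on the MG-II/archaea gene ratio.

    Parameters
    ----------
    dataset
        Samples; only SPM records with both qPCR abundances enter the fit
        (sediments carry no gene data).
    y_variables
        Variable accessor names (see :mod:`gdgtproxy.stats`) regressed on
        the gene ratio, one matrix row each.
    pools
        Lipid pools screened, one matrix column pair each.
    min_pairs
        Minimum complete (x, y) pairs for a cell to be computed.
    """

    def __init__(
        self,
        dataset: Dataset,
        y_variables=DEFAULT_Y_VARIABLES,
        pools=POOLS,
        min_pairs: int = 3,
    ):
        self.dataset = dataset
        self.y_variables = tuple(y_variables)
        self.pools = tuple(pools)
        self.min_pairs = int(min_pairs)
        self.records = [
            r for r in dataset if r.is_spm and not math.isnan(gene_ratio(r))
        ]
        self.ratios = np.array([gene_ratio(r) for r in self.records])

    @classmethod
    def from_dataset(cls, dataset: Dataset, **kwargs) -> "RingEnrichmentModel":
        return cls(dataset, **kwargs)

    def exog(self) -> np.ndarray:
        """Gene ratios of the records entering the fit."""
        return self.ratios.copy()

    def endog(self, variable: str, pool: str) -> np.ndarray:
        """y-values (NaN where undefined) aligned with :meth:`exog`."""
        return np.array(
            [resolve_variable(r, variable, pool) for r in self.records]
        )

    def fit(self) -> "RingEnrichmentResults":
        cells: dict[tuple[str, str], RegressionResult | None] = {}
        for var in self.y_variables:
            for pool in self.pools:
                y = self.endog(var, pool)
                ok = ~(np.isnan(self.ratios) | np.isnan(y))
                if ok.sum() < self.min_pairs:
                    cells[(var, pool)] = None
                    continue
                try:
                    cells[(var, pool)] = ols_regression(self.ratios[ok], y[ok])
                except ValueError:
                    cells[(var, pool)] = None
        return RingEnrichmentResults(self, cells)


@dataclass
class RingEnrichmentResults:
    """Fitted regression screen: one OLS fit per (variable, pool) cell."""

    model: RingEnrichmentModel
    cells: dict

    def _matrix(self, attr: str) -> pd.DataFrame:
        data = {
            pool: [
                getattr(self.cells[(v, pool)], attr) if self.cells[(v, pool)] else math.nan
                for v in self.model.y_variables
            ]
            for pool in self.model.pools
        }
        return pd.DataFrame(data, index=list(self.model.y_variables))

    @property
    def rsquared(self) -> pd.DataFrame:
        return self._matrix("r_squared")

    @property
    def pvalues(self) -> pd.DataFrame:
        return self._matrix("p_value")

    @property
    def slopes(self) -> pd.DataFrame:
        return self._matrix("slope")

    @property
    def nobs(self) -> pd.DataFrame:
        return self._matrix("n")

    def __getitem__(self, key: tuple[str, str]) -> RegressionResult | None:
        return self.cells[key]

    def to_frame(self, digits: int = 2) -> pd.DataFrame:
        """Wide table: rows = variables, column pairs = (R², P) per pool.

        Values rounded to ``digits`` decimals, matching the conventional
        presentation (a p of 0.004 prints as 0.00); full precision remains
        available on the matrices.  Not-computable cells are NaN.
        """
        cols: dict[str, list[float]] = {}
        for pool in self.model.pools:
            r2s, ps = [], []
            for v in self.model.y_variables:
                cell = self.cells[(v, pool)]
                r2s.append(round(cell.r_squared, digits) if cell else math.nan)
                ps.append(round(cell.p_value, digits) if cell else math.nan)
            cols[f"{pool}_R2"] = r2s
            cols[f"{pool}_P"] = ps
        return pd.DataFrame(cols, index=list(self.model.y_variables))

    def summary(self) -> str:
        """Human-readable report of the fitted screen."""
        lines = [
            "Ring-enrichment regression screen",
            "  x: [MG-II 16S]/[Archaea 16S] gene copy ratio",
            f"  samples with gene data: {len(self.model.records)}",
            "",
            self.to_frame().to_string(float_format=lambda v: f"{v:.2f}"),
            "",
            "n per cell:",
            self.nobs.to_string(),
        ]
        return "\n".join(lines)

    def to_tsv(self, path, digits: int = 2) -> None:
        frame = self.to_frame(digits=digits)
        frame.to_csv(path, sep="\t", index_label="variable", float_format=f"%.{digits}f")


def regression_screen(
    ds: Dataset,
    y_variables=DEFAULT_Y_VARIABLES,
    pools=POOLS,
) -> RingEnrichmentResults:
    """Functional wrapper: fit :class:`RingEnrichmentModel` in one call."""
    return RingEnrichmentModel(ds, y_variables=y_variables, pools=pools).fit()
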