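"""Core in-memory containers shared by all analysis stages.

The substrate of every stage is an :class:`ExpressionMatrix` — a gene x
sample table of nonnegative abundances carrying an explicit unit tag so
that unit transitions (FPKM -> TPM -> log-TPM) are type-checked rather
than implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Unit", "ExpressionMatrix", "GeneSet"]


class Unit(str, Enum):
    """Expression unit tag; transitions happen only via preprocessing ops."""

    FPKM = "FPKM"
    COUNTS = "COUNTS"
    TPM = "TPM"
    LOG_TPM = "LOG_TPM"


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with named axes and a unit tag.

    Parameters
    ----------
    data
        DataFrame with genes as the index and samples as columns. Gene
        labels may contain duplicates on input (e.g. raw cBioPortal
        downloads); :func:`coexkit.preprocess.dedupe_gene_names` makes
        them unique.
    unit
        One of :class:`Unit`. Values must be nonnegative unless the unit
        is ``LOG_TPM``.
    """

    data: pd.DataFrame
    unit: Unit

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (genes x samples)")
        if not self.data.columns.is_unique:
            raise ValueError("sample labels must be unique")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if self.unit is not Unit.LOG_TPM and values.size and values.min() < 0:
            raise ValueError(f"negative values are not allowed for unit {self.unit.value}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, unit: Unit | None = None) -> "ExpressionMatrix":
        """Return a new matrix with replaced values and (optionally) unit."""
        return ExpressionMatrix(data=data, unit=self.unit if unit is None else unit)

    def require_unit(self, *units: Unit) -> None:
        if self.unit not in units:
            wanted = ", ".join(u.value for u in units)
            raise ValueError(f"expected unit in {{{wanted}}}, got {self.unit.value}")


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene identifiers (e.g. a basal or luminal signature)."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __init__(self, name: str, members: Iterable[str], description: str = "") -> None:
        members = tuple(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        if len(set(members)) != len(members):
            seen: set[str] = set()
            dups = sorted({m for m in members if m in seen or seen.add(m)})
            raise ValueError(f"gene set {name!r} has duplicate members: {dups}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "description", description)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def present_in(self, genes: Sequence[str]) -> list[str]:
        """Members found among ``genes``, preserving member order."""
        universe = set(genes)
        return [m for m in self.members if m in universe]
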