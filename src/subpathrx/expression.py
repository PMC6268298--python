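"""Case/control expression matrix container and its TSV formats."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

log = logging.getLogger(__name__)

GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of normalized log-intensity values.

    Parameters
    ----------
    values
        DataFrame with unique gene (or probe) identifiers as the index and
        unique sample identifiers as the columns.
    groups
        Mapping sample_id -> "case" | "control" covering every column.
        May be empty for matrices that carry no case/control design (for
        example the perturbation reference profiles, where the pairing lives
        in the instance table instead).
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers in expression matrix")
        if self.groups:
            missing = set(self.values.columns) - set(self.groups)
            if missing:
                raise ValueError(f"samples without a group label: {sorted(missing)}")
            bad = {g for g in self.groups.values() if g not in GROUPS}
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]

    # ---------------------------------------------------------------- I/O

    def to_tsv(self, matrix_path: str | Path, groups_path: str | Path | None = None) -> None:
        """Write the matrix (and optionally the sample-group file) as TSV."""
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        if groups_path is not None:
            pd.DataFrame(
                {"sample_id": list(self.values.columns),
                 "group": [self.groups[s] for s in self.values.columns]}
            ).to_csv(groups_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path,
                 groups_path: str | Path | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        groups: dict[str, str] = {}
        if groups_path is not None:
            gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
            groups = dict(zip(gdf["sample_id"], gdf["group"]))
        return cls(values=values, groups=groups)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            values=self.values[sample_ids],
            groups={s: self.groups[s] for s in sample_ids if s in self.groups},
        )


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe_id -> gene_id TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError("probe map must have columns probe_id and gene_id")
    return dict(zip(df["probe_id"], df["gene_id"]))
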