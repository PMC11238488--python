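"""Binary solution containers and their TSV round-trip.

Each enumerated condition-specific model is a binary activity pattern over
the reactions of the GSMN (1 = the reaction carries flux at or above the
activation threshold in that optimum). A condition's enumeration output is
a solutions x reactions 0/1 matrix stored as a tab-separated file with the
reaction ids as header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["BinarySolution", "SolutionSet", "read_solution_matrix", "write_solution_matrix"]


@dataclass(frozen=True)
class BinarySolution:
    """One optimal activity pattern with its consensus score."""

    activities: tuple[int, ...]
    objective_score: int

    def as_dict(self, reactions: list[str]) -> dict[str, int]:
        return dict(zip(reactions, self.activities))


@dataclass
class SolutionSet:
    """An ordered, duplicate-free set of equally optimal activity patterns."""

    reactions: list[str]
    matrix: np.ndarray  # (n_solutions, n_reactions) of {0,1}
    condition: str = ""
    scores: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 and self.matrix.size == 0:
            self.matrix = self.matrix.reshape(0, len(self.reactions))
        if self.matrix.shape[1] != len(self.reactions):
            raise ValueError("matrix width does not match the reaction list")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("solution matrix cells must be 0 or 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def __iter__(self):
        for row in self.matrix:
            yield tuple(int(x) for x in row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.reactions)

    @staticmethod
    def from_rows(
        reactions: list[str],
        rows: list[tuple[int, ...]],
        condition: str = "",
        scores: list[int] | None = None,
    ) -> "SolutionSet":
        """Build from rows, dropping duplicates while keeping first-seen order."""
        seen: dict[tuple[int, ...], int] = {}
        kept_scores: list[int] = []
        for i, row in enumerate(rows):
            if row not in seen:
                seen[row] = i
                if scores is not None:
                    kept_scores.append(scores[i])
        mat = np.array(list(seen), dtype=np.int8).reshape(len(seen), len(reactions))
        return SolutionSet(reactions, mat, condition=condition, scores=kept_scores)

    def union(self, other: "SolutionSet", condition: str | None = None) -> "SolutionSet":
        if self.reactions != other.reactions:
            raise ValueError("cannot merge solution sets over different reaction lists")
        rows = list(self) + list(other)
        return SolutionSet.from_rows(self.reactions, rows, condition=condition or self.condition)


def write_solution_matrix(solutions: SolutionSet, path: str | Path) -> None:
    """Write a solutions x reactions TSV (header = reaction ids)."""
    solutions.to_frame().to_csv(path, sep="\t", index=False)


def read_solution_matrix(path: str | Path, condition: str = "") -> SolutionSet:
    """Read a solutions x reactions TSV written by :func:`write_solution_matrix`.

    Any cell outside {0, 1} raises a ValueError naming the row and column.
    """
    df = pd.read_csv(path, sep="\t")
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary cell {values[i, j]!r} at row {i}, column {df.columns[j]!r} in {path}"
        )
    return SolutionSet(list(df.columns), values.astype(np.int8), condition=condition)
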