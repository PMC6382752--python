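"""Sample-by-class composition tables with per-sample environment labels.

The central data structure is :class:`CompositionTable`: an ``n x K`` matrix
of non-negative abundances or proportions, one row per sample, one column
per class (e.g. resistance-gene drug classes or bacterial phyla), together
with an environment/treatment label for every sample.

Tables can be read from CSV/TSV files in two dialects (samples as rows or
samples as columns), with the environment label supplied either as a column
of the data file or as a separate two-column metadata file.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompositionTable",
    "read_table",
    "normalize",
    "write_table",
    "write_result",
]

_ROW_SUM_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class CompositionTable:
    """Samples x classes composition matrix with environment metadata.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, one per row of ``values``.
    class_names : sequence of str
        Unique class labels, one per column of ``values`` (K entries).
    environments : sequence of str
        Environment/treatment label per sample; m distinct values define
        the groups.
    values : ndarray of shape (n_samples, K)
        Non-negative abundances or proportions.
    is_normalized : bool
        True when every row sums to 1 (within 1e-9).
    """

    sample_ids: tuple[str, ...]
    class_names: tuple[str, ...]
    environments: tuple[str, ...]
    values: np.ndarray
    is_normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "class_names", tuple(str(c) for c in self.class_names))
        object.__setattr__(
            self, "environments", tuple(str(e).strip() for e in self.environments)
        )
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        object.__setattr__(self, "values", values)
        n, k = values.shape
        if n == 0 or k == 0:
            raise ValueError("empty table: need at least one sample and one class")
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows of data"
            )
        if len(self.class_names) != k:
            raise ValueError(
                f"{len(self.class_names)} class names for {k} columns of data"
            )
        if len(self.environments) != n:
            raise ValueError(
                f"{len(self.environments)} environment labels for {n} samples"
            )
        for name, seq in (("sample", self.sample_ids), ("class", self.class_names)):
            dupes = [x for x, c in Counter(seq).items() if c > 1]
            if dupes:
                raise ValueError(f"duplicate {name} names: {dupes}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"class {self.class_names[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[i, j]} at sample {self.sample_ids[i]!r}, "
                f"class {self.class_names[j]!r}"
            )
        if self.is_normalized:
            sums = values.sum(axis=1)
            bad = np.argwhere(np.abs(sums - 1.0) > _ROW_SUM_TOL)
            if bad.size:
                i = bad[0, 0]
                raise ValueError(
                    f"row for sample {self.sample_ids[i]!r} sums to {sums[i]}, "
                    "but table is flagged as normalized"
                )

    # -- geometry -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        """K, the number of classes."""
        return self.values.shape[1]

    @property
    def env_labels(self) -> tuple[str, ...]:
        """Distinct environment labels in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.environments:
            seen.setdefault(e)
        return tuple(seen)

    @property
    def n_environments(self) -> int:
        """m, the number of environments."""
        return len(self.env_labels)

    @property
    def group_sizes(self) -> dict[str, int]:
        """Mapping environment label -> n_i."""
        return dict(Counter(self.environments))

    def group_values(self, env: str) -> np.ndarray:
        """Rows of ``values`` belonging to environment ``env``."""
        mask = np.array([e == env for e in self.environments])
        if not mask.any():
            raise KeyError(f"unknown environment {env!r}")
        return self.values[mask]

    def with_environments(self, environments: Sequence[str]) -> "CompositionTable":
        """Same data under a different label vector (used by permutation tests)."""
        return dataclasses.replace(self, environments=tuple(environments))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.class_names)
        )
        df.index.name = "sample_id"
        df.insert(0, "environment", list(self.environments))
        return df


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_table(
    path: str | Path,
    dialect: str = "samples-as-rows",
    env_column: str = "environment",
    env_file: str | Path | None = None,
    delimiter: str | None = None,
) -> CompositionTable:
    """Read a composition table from a CSV/TSV file.

    Parameters
    ----------
    path : path
        Data file. First column holds sample ids (or class names when
        ``dialect="samples-as-columns"``).
    dialect : {"samples-as-rows", "samples-as-columns"}
        Orientation of the data matrix.
    env_column : str
        Name of the environment column inside the data file (ignored when
        ``env_file`` is given).
    env_file : path, optional
        Two-column metadata file (sample_id, environment); overrides
        ``env_column``.
    delimiter : str, optional
        Field delimiter; by default inferred from the extension
        (``.tsv`` -> tab, otherwise comma).

    Returns
    -------
    CompositionTable
        Un-normalized table preserving the input class order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in {"samples-as-rows", "samples-as-columns"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"empty table in {path}")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if dialect == "samples-as-columns":
        df = df.T

    environments: list[str]
    if env_file is not None:
        meta = pd.read_csv(Path(env_file), sep=_detect_delimiter(Path(env_file), delimiter))
        if meta.shape[1] < 2:
            raise ValueError("metadata file needs two columns: sample_id, environment")
        env_map = {
            str(s).strip(): str(e).strip()
            for s, e in zip(meta.iloc[:, 0], meta.iloc[:, 1])
        }
        missing = [s for s in df.index if s not in env_map]
        if missing:
            raise ValueError(f"no environment label for sample(s) {missing}")
        environments = [env_map[s] for s in df.index]
    else:
        if env_column not in df.columns:
            raise ValueError(
                f"environment column {env_column!r} not found in {path} "
                f"(columns: {list(df.columns)})"
            )
        env_series = df.pop(env_column)
        if env_series.isna().any():
            sample = df.index[env_series.isna()][0]
            raise ValueError(f"missing environment label for sample {sample!r}")
        environments = [str(e).strip() for e in env_series]

    if df.shape[1] == 0:
        raise ValueError(f"no class columns left in {path}")

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df.iloc[:, j]):
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {raw!r} at sample {df.index[i]!r}, "
                    f"class {col!r}"
                ) from None
            values[i, j] = v

    return CompositionTable(
        sample_ids=tuple(df.index),
        class_names=tuple(df.columns),
        environments=tuple(environments),
        values=values,
        is_normalized=False,
    )


def normalize(table: CompositionTable) -> CompositionTable:
    """Divide every row by its sum so the table lives on the simplex.

    Idempotent; raises on an all-zero row (proportions undefined).
    """
    sums = table.values.sum(axis=1)
    zero = np.argwhere(sums <= 0)
    if zero.size:
        i = zero[0, 0]
        raise ValueError(
            f"sample {table.sample_ids[i]!r} has zero total abundance; "
            "proportions are undefined"
        )
    return dataclasses.replace(
        table, values=table.values / sums[:, None], is_normalized=True
    )


def write_table(table: CompositionTable, path: str | Path, delimiter: str | None = None) -> None:
    """Write a table as CSV/TSV in the samples-as-rows dialect.

    ``read_table(write_table(t))`` is the identity on values, names and
    labels (up to float formatting at 17 significant digits).
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    df = table.to_dataframe()
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_result(result, path: str | Path, format: str = "json") -> None:
    """Serialize a result object (LRT, GOF or power) to ``path``.

    ``format="json"`` writes the machine-readable record produced by the
    result's ``to_dict``; ``format="text"`` writes the human-readable
    ``summary``. Numeric fields round-trip at full precision in JSON.
    """
    path = Path(path)
    if format == "json":
        payload = result.to_dict()
        payload["schema_version"] = 1
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "text":
        path.write_text(result.summary() + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
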