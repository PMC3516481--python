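"""File formats, run configuration, partitioning and reproducibility helpers.

Genotypes are delimited text (TSV by default): header row of marker ids,
first column of line ids, cells in ``{0, 1, NA}`` (dominant binary marker
calls).  Phenotypes are long-format TSV with columns
``line_id, env, trait, value``.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "CVPartition",
    "RunConfig",
    "GenotypeFormatError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "impute_and_prepare",
    "make_partitions",
    "derive_stream_seed",
]


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates the 0/1/NA cell contract."""


@dataclass
class GenotypeMatrix:
    """An ``n x p`` binary (dominant) marker matrix.

    Parameters
    ----------
    line_ids
        Unique identifiers of the ``n`` lines (rows).
    marker_ids
        Unique identifiers of the ``p`` markers (columns).
    X
        Float array of shape ``(n, p)``; entries are 0, 1, ``nan`` for
        missing calls, or imputed values in ``[0, 1]`` after
        :func:`impute_and_prepare`.
    q
        Length-``p`` allele-frequency vector, set after imputation
        (column mean of the imputed column); ``None`` beforehand.
    """

    line_ids: list[str]
    marker_ids: list[str]
    X: np.ndarray
    q: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.line_ids = [str(s) for s in self.line_ids]
        self.marker_ids = [str(s) for s in self.marker_ids]
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"dims(X)={self.X.shape} do not match "
                f"({len(self.line_ids)} line ids, {len(self.marker_ids)} marker ids)"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if self.q is not None:
            self.q = np.asarray(self.q, dtype=float)
            if self.q.shape != (len(self.marker_ids),):
                raise ValueError("q must have one entry per marker")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def is_imputed(self) -> bool:
        return not np.isnan(self.X).any()

    def subset_lines(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            [self.line_ids[i] for i in idx], list(self.marker_ids), self.X[idx], self.q
        )


@dataclass
class PhenotypeTable:
    """Long-format phenotype records ``(line_id, env, trait, value)``."""

    data: pd.DataFrame

    COLUMNS = ("line_id", "env", "trait", "value")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["line_id"] = df["line_id"].astype(str)
        df["env"] = df["env"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)
        if not np.isfinite(df["value"].to_numpy()).all():
            raise ValueError("phenotype values must be finite")
        if df.duplicated(subset=["line_id", "env", "trait"]).any():
            raise ValueError("(line_id, env, trait) must be unique")
        self.data = df.reset_index(drop=True)

    def envs(self, trait: str | None = None) -> list[str]:
        df = self.data if trait is None else self.data[self.data["trait"] == trait]
        return sorted(df["env"].unique())

    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def select(self, trait: str, env: str) -> pd.DataFrame:
        """Records for one trait/environment, one row per line."""
        sel = self.data[(self.data["trait"] == trait) & (self.data["env"] == env)]
        if sel.empty:
            raise ValueError(f"no phenotypes for trait={trait!r}, env={env!r}")
        return sel.reset_index(drop=True)

    def check_lines(self, G: GenotypeMatrix) -> None:
        known = set(G.line_ids)
        unknown = sorted(set(self.data["line_id"]) - known)
        if unknown:
            raise ValueError(f"phenotype line ids absent from genotypes: {unknown[:10]}")


@dataclass(frozen=True)
class CVPartition:
    """One random train/validation split (indices into the line axis)."""

    partition_index: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_idx", np.asarray(self.train_idx, dtype=int))
        object.__setattr__(self, "test_idx", np.asarray(self.test_idx, dtype=int))
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test overlap")


@dataclass
class RunConfig:
    """Resolved configuration of a benchmarking run.

    Everything a run needs to be reproduced bit-for-bit: model list, MCMC
    settings, partitioning scheme and the master seed.  ``model_options``
    holds per-model hyperparameter blocks keyed by model name.
    """

    models: list[str] = field(default_factory=lambda: ["brr"])
    n_iter: int = 35_000
    burn_in: int = 5_000
    thin: int = 1
    n_partitions: int = 50
    validation_fraction: float = 0.10
    seed: int = 0
    model_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if not (0.0 < self.validation_fraction <= 0.5):
            raise ValueError("validation_fraction must be in (0, 0.5]")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


# ---------------------------------------------------------------------------
# genotype / phenotype files
# ---------------------------------------------------------------------------

_NA_STRINGS = {"NA", "NaN", "nan", ""}


def read_genotypes(path: str | Path, delimiter: str = "\t") -> GenotypeMatrix:
    """Read a delimited genotype file into a :class:`GenotypeMatrix`.

    First row holds marker ids, first column line ids; cells must be
    ``0``, ``1`` or ``NA``.  Missing calls are preserved as ``nan``.

    Raises
    ------
    GenotypeFormatError
        For any cell outside ``{0, 1, NA}``, naming the offending
        line and marker.
    ValueError
        For duplicate line or marker ids.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    line_ids = [str(i) for i in df.index]
    marker_ids = [str(c) for c in df.columns]
    X = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell in _NA_STRINGS:
                X[i, j] = np.nan
            elif cell in ("0", "0.0"):
                X[i, j] = 0.0
            elif cell in ("1", "1.0"):
                X[i, j] = 1.0
            else:
                raise GenotypeFormatError(
                    f"non-binary genotype {cell!r} at line {line_ids[i]!r}, "
                    f"marker {marker_ids[j]!r}"
                )
    return GenotypeMatrix(line_ids, marker_ids, X)


def write_genotypes(G: GenotypeMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a genotype matrix as delimited text (``NA`` for missing)."""

    def fmt(v: float) -> str:
        if np.isnan(v):
            return "NA"
        if v in (0.0, 1.0):
            return str(int(v))
        return repr(v)

    with open(path, "w") as fh:
        fh.write("line_id" + delimiter + delimiter.join(G.marker_ids) + "\n")
        for i, lid in enumerate(G.line_ids):
            cells = delimiter.join(fmt(v) for v in G.X[i])
            fh.write(lid + delimiter + cells + "\n")


def read_phenotypes(path: str | Path, delimiter: str = "\t") -> PhenotypeTable:
    df = pd.read_csv(path, sep=delimiter)
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path, delimiter: str = "\t") -> None:
    table.data.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# imputation & preparation
# ---------------------------------------------------------------------------

def impute_and_prepare(G: GenotypeMatrix) -> GenotypeMatrix:
    """Mean-impute missing calls, compute allele frequencies, drop monomorphic markers.

    Missing entries in each marker column are replaced by the column mean of
    the observed binary calls (a value in ``[0, 1]``); ``q_j`` is then the
    column mean of the imputed column.  Markers with ``q_j`` equal to 0 or 1
    carry no information and are removed (logged).

    Raises
    ------
    ValueError
        If a marker column is entirely missing.
    """
    X = G.X.copy()
    n_obs = (~np.isnan(X)).sum(axis=0)
    if (n_obs == 0).any():
        bad = [G.marker_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"markers with no observed calls: {bad[:10]}")
    col_mean = np.nanmean(X, axis=0)
    missing = np.isnan(X)
    if missing.any():
        X[missing] = np.broadcast_to(col_mean, X.shape)[missing]
    q = X.mean(axis=0)
    keep = (q > 0.0) & (q < 1.0)
    if not keep.all():
        dropped = [G.marker_ids[j] for j in np.flatnonzero(~keep)]
        logger.info("removing %d monomorphic markers: %s%s", len(dropped),
                    dropped[:5], "..." if len(dropped) > 5 else "")
    marker_ids = [m for m, k in zip(G.marker_ids, keep) if k]
    return GenotypeMatrix(list(G.line_ids), marker_ids, X[:, keep], q[keep])


# ---------------------------------------------------------------------------
# partitioning & seeds
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def make_partitions(
    n: int,
    n_partitions: int = 50,
    validation_fraction: float = 0.10,
    seed: int = 0,
) -> list[CVPartition]:
    """Generate independent uniform-random train/validation splits.

    The validation-set size is ``round(validation_fraction * n)`` with ties
    rounded half away from zero (306 lines at 10% gives 31).  The same
    partition list is intended to be reused across all models being
    compared, enabling paired testing.
    """
    if n < 10:
        raise ValueError("need n >= 10 lines to partition")
    if not (0.0 < validation_fraction <= 0.5):
        raise ValueError("validation_fraction must be in (0, 0.5]")
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    n_test = _round_half_away(validation_fraction * n)
    n_test = max(n_test, 1)
    rng = np.random.default_rng(seed)
    out = []
    for k in range(1, n_partitions + 1):
        perm = rng.permutation(n)
        out.append(
            CVPartition(
                partition_index=k,
                train_idx=np.sort(perm[n_test:]),
                test_idx=np.sort(perm[:n_test]),
                seed=seed,
            )
        )
    return out


def derive_stream_seed(master_seed: int, partition_index: int, model: str) -> int:
    """Deterministic 32-bit seed for the ``(master, partition, model)`` stream.

    Derived through :class:`numpy.random.SeedSequence` so that models can be
    run in any order (or independently) and still see identical per-partition
    randomness.
    """
    tag = zlib.crc32(model.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, int(partition_index), tag])
    return int(ss.generate_state(1)[0])
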