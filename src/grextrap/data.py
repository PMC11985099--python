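"""Data containers: simulation logs for scalar and grid-valued output.

A :class:`SimulationLog` is the dataset the model is fitted to: n distinct
fidelity vectors x_i in (0, inf)^d with simulator outputs f(x_i) and optional
costs c(x_i).  The CSV layout is ``x1,...,xd,f[,cost]`` with one row per
simulation.

A :class:`GridLog` holds function-valued output sampled on a full Cartesian
grid of n1 fidelities times n2 output indices (times t, or extra model
parameters theta); the long CSV layout is ``x1,...,xd,t,f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GridIncompleteError

__all__ = ["SimulationLog", "GridLog"]


@dataclass
class SimulationLog:
    X: np.ndarray
    y: np.ndarray
    costs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        y = np.asarray(self.y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if X.shape[0] < 1:
            raise ValueError("at least one simulation is required")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite entries in simulation log")
        if np.any(np.all(X == 0.0, axis=1)):
            raise ValueError("simulation log contains the origin x = 0")
        if np.any(X < 0):
            raise ValueError("discretization parameters must be positive")
        seen = {tuple(row) for row in X}
        if len(seen) != X.shape[0]:
            raise ValueError("design points must be pairwise distinct")
        self.X = X
        self.y = y
        if self.costs is not None:
            c = np.asarray(self.costs, dtype=float).ravel()
            if c.shape[0] != X.shape[0]:
                raise ValueError("costs length must match the number of rows")
            if np.any(c <= 0):
                raise ValueError("costs must be positive")
            self.costs = c

    @property
    def n(self):
        return self.X.shape[0]

    @property
    def d(self):
        return self.X.shape[1]

    @classmethod
    def from_dataframe(cls, df, meta=None):
        xcols = [c for c in df.columns if c.startswith("x")]
        if not xcols or "f" not in df.columns:
            raise ValueError("expected columns x1,...,xd and f")
        costs = df["cost"].to_numpy() if "cost" in df.columns else None
        return cls(df[xcols].to_numpy(), df["f"].to_numpy(), costs, meta or {})

    @classmethod
    def from_csv(cls, path, meta=None):
        return cls.from_dataframe(pd.read_csv(path), meta)

    def to_dataframe(self):
        df = pd.DataFrame(self.X, columns=[f"x{i + 1}" for i in range(self.d)])
        df["f"] = self.y
        if self.costs is not None:
            df["cost"] = self.costs
        return df

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class GridLog:
    """Output f(x_i, t_j) on a full n1 x n2 Cartesian grid."""

    X: np.ndarray
    T: np.ndarray
    Y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        T = np.asarray(self.T, dtype=float).ravel()
        Y = np.asarray(self.Y, dtype=float)
        if Y.shape != (X.shape[0], T.shape[0]):
            raise GridIncompleteError(
                f"Y has shape {Y.shape}, expected ({X.shape[0]}, {T.shape[0]}); "
                "multi-output fitting requires a complete Cartesian grid"
            )
        if not np.all(np.isfinite(Y)):
            raise ValueError("non-finite outputs in grid log")
        if len({tuple(r) for r in X}) != X.shape[0]:
            raise ValueError("fidelity points must be distinct")
        if len(set(T.tolist())) != T.shape[0]:
            raise ValueError("output-index values must be distinct")
        if np.any(np.all(X == 0.0, axis=1)):
            raise ValueError("grid log contains the origin x = 0")
        self.X, self.T, self.Y = X, T, Y

    @property
    def n1(self):
        return self.X.shape[0]

    @property
    def n2(self):
        return self.T.shape[0]

    @property
    def d(self):
        return self.X.shape[1]

    @classmethod
    def from_long_dataframe(cls, df, meta=None):
        xcols = [c for c in df.columns if c.startswith("x")]
        if not xcols or "t" not in df.columns or "f" not in df.columns:
            raise ValueError("expected columns x1,...,xd, t and f")
        xs = df[xcols].drop_duplicates().to_numpy()
        ts = np.sort(df["t"].unique())
        n1, n2 = xs.shape[0], ts.shape[0]
        if len(df) != n1 * n2:
            raise GridIncompleteError(
                f"{len(df)} rows cannot form a complete {n1} x {n2} grid"
            )
        Y = np.full((n1, n2), np.nan)
        xindex = {tuple(r): i for i, r in enumerate(xs)}
        tindex = {t: j for j, t in enumerate(ts)}
        for _, row in df.iterrows():
            i = xindex[tuple(row[c] for c in xcols)]
            j = tindex[row["t"]]
            if not np.isnan(Y[i, j]):
                raise ValueError("duplicate grid cell in long-format data")
            Y[i, j] = row["f"]
        if np.any(np.isnan(Y)):
            raise GridIncompleteError("missing cells in the Cartesian grid")
        return cls(xs, ts, Y, meta or {})

    @classmethod
    def from_long_csv(cls, path, meta=None):
        return cls.from_long_dataframe(pd.read_csv(path), meta)

    def to_long_dataframe(self):
        rows = []
        for i in range(self.n1):
            for j in range(self.n2):
                rows.append(
                    dict(
                        **{f"x{k + 1}": self.X[i, k] for k in range(self.d)},
                        t=self.T[j],
                        f=self.Y[i, j],
                    )
                )
        return pd.DataFrame(rows)
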