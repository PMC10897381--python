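"""From-scratch Gaussian-copula synthesizer for daily activity tables.

The model couples arbitrary per-column marginals through a latent correlated
multivariate normal: each column is mapped through its (smoothed empirical)
CDF and the standard-normal quantile function, the correlation matrix of the
resulting normal scores is estimated, and sampling inverts the chain —
draw latent multivariate-normal vectors with the learned correlation, apply
the standard-normal CDF, then each marginal's inverse CDF.

Marginals default to smoothed empirical CDFs: linear interpolation between
order statistics at plotting positions (i − 0.5)/n, with tails clamped to
the observed minimum/maximum.  This keeps sampled values inside the training
support (common parametric copula toolkits can emit out-of-range values such
as negative step counts; that behavior is deliberately not reproduced).
Discrete columns are fitted with jittered ranks and sampled with rounding;
the label column can instead be snapped to the nearest observed value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = ["EmpiricalMarginal", "CopulaModel", "fit_copula", "sample_copula"]

_PSD_EPS = 1e-8


@dataclass(frozen=True)
class EmpiricalMarginal:
    """Smoothed empirical marginal: order statistics at (i − 0.5)/n positions."""

    values: np.ndarray      # sorted training values
    positions: np.ndarray   # plotting positions in (0, 1)
    integer: bool = False   # round on sampling

    @classmethod
    def fit(cls, x: np.ndarray, integer: bool) -> "EmpiricalMarginal":
        v = np.sort(np.asarray(x, dtype=float))
        n = len(v)
        p = (np.arange(1, n + 1) - 0.5) / n
        return cls(values=v, positions=p, integer=integer)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """Non-decreasing map onto (0, 1); clamped to the outermost positions."""
        return np.interp(x, self.values, self.positions)

    def inverse_cdf(self, u: np.ndarray, snap: bool = False) -> np.ndarray:
        """Quantile function; ``snap`` picks the nearest observed value."""
        if snap:
            idx = np.clip(np.searchsorted(self.positions, u), 0, len(self.values) - 1)
            left = np.clip(idx - 1, 0, None)
            use_left = np.abs(self.positions[left] - u) < np.abs(self.positions[idx] - u)
            return self.values[np.where(use_left, left, idx)]
        out = np.interp(u, self.positions, self.values)
        return np.round(out) if self.integer else out


@dataclass
class CopulaModel:
    """Fitted marginals plus the latent-normal correlation matrix."""

    marginals: dict[str, EmpiricalMarginal]
    correlation: np.ndarray
    columns: list[str]
    n_fit: int
    seed: int | None = None
    snap_columns: tuple[str, ...] = ()
    psd_repaired: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "columns": self.columns,
            "n_fit": self.n_fit,
            "seed": self.seed,
            "snap_columns": list(self.snap_columns),
            "psd_repaired": self.psd_repaired,
            "correlation": self.correlation.tolist(),
            "marginals": {
                c: {
                    "values": m.values.tolist(),
                    "positions": m.positions.tolist(),
                    "integer": m.integer,
                }
                for c, m in self.marginals.items()
            },
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CopulaModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            marginals={
                c: EmpiricalMarginal(
                    values=np.asarray(m["values"]),
                    positions=np.asarray(m["positions"]),
                    integer=m["integer"],
                )
                for c, m in d["marginals"].items()
            },
            correlation=np.asarray(d["correlation"]),
            columns=d["columns"],
            n_fit=d["n_fit"],
            seed=d["seed"],
            snap_columns=tuple(d["snap_columns"]),
            psd_repaired=d["psd_repaired"],
        )


def _nearest_psd(corr: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= -_PSD_EPS:
        return corr, False
    w = np.clip(w, _PSD_EPS, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, True


def fit_copula(
    table: pd.DataFrame,
    integer_columns: tuple[str, ...] = ("Steps", "Active"),
    snap_columns: tuple[str, ...] = (),
    seed: int | None = None,
) -> CopulaModel:
    """Fit marginals and the latent correlation of a numeric daily table.

    ``integer_columns`` are rounded on sampling; ``snap_columns`` (typically
    ``("Active",)`` to treat the label as discrete) are snapped to the
    nearest observed value instead of interpolated.  Discrete columns use
    jittered ranks so their normal scores are not degenerate.  A constant
    column cannot be mapped through a CDF and raises.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows to fit a copula")
    if table.isna().any().any():
        raise ValueError("table contains missing values; impute first")
    rng = np.random.default_rng(seed)
    columns = list(table.columns)
    marginals: dict[str, EmpiricalMarginal] = {}
    z = np.empty((len(table), len(columns)))
    for j, col in enumerate(columns):
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"column {col!r} is constant; its CDF is degenerate")
        integer = col in integer_columns
        marginals[col] = EmpiricalMarginal.fit(x, integer=integer)
        has_ties = len(np.unique(x)) < len(x)
        if has_ties:
            # jittered ranks break ties at random within each tie group
            u = (rankdata(x, method="ordinal") - rng.uniform(size=len(x))) / len(x)
        else:
            u = (rankdata(x) - 0.5) / len(x)
        z[:, j] = stats.norm.ppf(u)
    corr = np.corrcoef(z, rowvar=False)
    corr, repaired = _nearest_psd(corr)
    return CopulaModel(
        marginals=marginals,
        correlation=corr,
        columns=columns,
        n_fit=len(table),
        seed=seed,
        snap_columns=snap_columns,
        psd_repaired=repaired,
    )


def sample_copula(model: CopulaModel, n: int, seed: int | None = None) -> pd.DataFrame:
    """Draw ``n`` synthetic rows from a fitted copula (seeded, deterministic)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    d = len(model.columns)
    chol = np.linalg.cholesky(model.correlation + _PSD_EPS * np.eye(d))
    latent = rng.standard_normal((n, d)) @ chol.T
    u = stats.norm.cdf(latent)
    out = {}
    for j, col in enumerate(model.columns):
        m = model.marginals[col]
        x = m.inverse_cdf(u[:, j], snap=col in model.snap_columns)
        out[col] = x.astype(int) if m.integer else x
    return pd.DataFrame(out, columns=model.columns)
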