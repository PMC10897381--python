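"""Real-versus-synthetic table comparison statistics.

Four complementary channels:

* **Q–Q ordinary least squares** — per feature, the sorted synthetic sample
  is regressed on the sorted real sample (quantile-matched when sizes
  differ); a perfect synthesizer gives slope 1, intercept 0, R² 1.  The
  report carries R², adjusted R² = 1 − (1 − R²)(N − 1)/(N − p − 1),
  residual standard error √(RSS/df) and the variance-ratio F statistic
  (larger sample variance over smaller).
* **Moment distances** — per-feature differences of log₁₀|mean| and
  log₁₀|sd|.
* **Curve distances** — maximum discrepancy between normalized cumulative
  sums over sorted values, and the Kolmogorov–Smirnov ECDF distance.
* **Classifier-based similarity** — a fixed panel of seeded classifiers is
  trained once on real and once on synthetic data, both evaluated on a
  held-out real test split; reported as F1 pairs plus the Jaccard
  similarity J(A,B) = |A∩B|/|A∪B| of the two correctly-classified index
  sets.  A synthetic table whose labels collapsed to one class is reported
  as incompatible rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .classifier import FEATURES, TrainingConfig, _predict, train_mlp

__all__ = [
    "OlsReport",
    "ComparisonReport",
    "jaccard_similarity",
    "rmse_mae",
    "ols_compare",
    "feature_comparisons",
    "classifier_f1_jaccard",
]


@dataclass
class OlsReport:
    per_feature: dict[str, dict[str, float]]
    pooled: dict[str, float]
    skipped: list[str] = field(default_factory=list)


@dataclass
class ComparisonReport:
    log_mean_diff: dict[str, float]
    log_sd_diff: dict[str, float]
    cumsum_max_discrepancy: dict[str, float]
    ks_distance: dict[str, float]
    undefined: list[str] = field(default_factory=list)


def jaccard_similarity(a: set, b: set) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets count as identical (1)."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def rmse_mae(actual, predicted) -> tuple[float, float]:
    """Root-mean-square error and mean absolute error of paired series."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("actual and predicted must have equal length")
    if y.size == 0:
        raise ValueError("need at least one observation")
    resid = y - yhat
    return float(np.sqrt(np.mean(resid**2))), float(np.mean(np.abs(resid)))


def _quantile_match(x: np.ndarray, n: int) -> np.ndarray:
    """Sorted sample interpolated onto n quantile positions."""
    return np.quantile(np.sort(x), (np.arange(1, n + 1) - 0.5) / n)


def _qq_fit(real: np.ndarray, synth: np.ndarray) -> dict[str, float]:
    n = len(real)
    y = _quantile_match(synth, n) if len(synth) != n else np.sort(synth)
    x = np.sort(real)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    p = 1  # one regressor in the quantile-quantile design
    df = n - p - 1
    rss = float(np.sum(model.resid**2))
    s_real, s_synth = np.var(real, ddof=1), np.var(synth, ddof=1)
    f_value = max(s_real, s_synth) / min(s_real, s_synth)
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r2": float(model.rsquared),
        "adj_r2": 1.0 - (1.0 - float(model.rsquared)) * (n - 1) / (n - p - 1),
        "rse": float(np.sqrt(rss / df)) if df > 0 else float("nan"),
        "df": df,
        "f_value": float(f_value),
        "n": n,
    }


def ols_compare(real: pd.DataFrame, synthetic: pd.DataFrame) -> OlsReport:
    """Per-feature and pooled Q–Q OLS of the synthetic table on the real one.

    Row counts may differ (the synthetic sample is quantile-matched onto the
    real one's size).  Constant features cannot be regressed and are listed
    in ``skipped``.
    """
    common = [c for c in real.columns if c in synthetic.columns]
    if not common:
        raise ValueError("no shared columns to compare")
    per_feature: dict[str, dict[str, float]] = {}
    skipped: list[str] = []
    xs, ys = [], []
    for col in common:
        r = real[col].to_numpy(dtype=float)
        s = synthetic[col].to_numpy(dtype=float)
        if np.ptp(r) == 0 or np.ptp(s) == 0:
            skipped.append(col)
            continue
        per_feature[col] = _qq_fit(r, s)
        xs.append(np.sort(r))
        ys.append(_quantile_match(s, len(r)))
    if not per_feature:
        raise ValueError("all shared columns are constant")
    pooled = _pooled_fit(np.concatenate(xs), np.concatenate(ys), p=len(per_feature))
    return OlsReport(per_feature=per_feature, pooled=pooled, skipped=skipped)


def _pooled_fit(x: np.ndarray, y: np.ndarray, p: int) -> dict[str, float]:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(x)
    df = n - p - 1
    rss = float(np.sum(model.resid**2))
    return {
        "r2": float(model.rsquared),
        "adj_r2": 1.0 - (1.0 - float(model.rsquared)) * (n - 1) / df,
        "rse": float(np.sqrt(rss / df)),
        "df": df,
        "n": n,
        "p": p,
    }


def feature_comparisons(real: pd.DataFrame, synthetic: pd.DataFrame) -> ComparisonReport:
    """Log-moment, cumulative-sum and KS distances per shared feature."""
    common = [c for c in real.columns if c in synthetic.columns]
    if not common:
        raise ValueError("no shared columns to compare")
    report = ComparisonReport({}, {}, {}, {})
    for col in common:
        r = real[col].to_numpy(dtype=float)
        s = synthetic[col].to_numpy(dtype=float)
        for stat_name, fr, fs, target in (
            ("mean", np.mean(r), np.mean(s), report.log_mean_diff),
            ("sd", np.std(r, ddof=1), np.std(s, ddof=1), report.log_sd_diff),
        ):
            if fr == 0 or fs == 0:
                report.undefined.append(f"{col} log-{stat_name} (zero {stat_name})")
                target[col] = float("nan")
            else:
                target[col] = abs(float(np.log10(abs(fr)) - np.log10(abs(fs))))
        report.cumsum_max_discrepancy[col] = _cumsum_discrepancy(r, s)
        report.ks_distance[col] = float(stats.ks_2samp(r, s).statistic)
    return report


def _cumsum_discrepancy(r: np.ndarray, s: np.ndarray) -> float:
    """Max gap between normalized cumulative sums over sorted values."""
    n = max(len(r), len(s))
    rq = _quantile_match(r, n)
    sq = _quantile_match(s, n)

    def norm_cumsum(x: np.ndarray) -> np.ndarray:
        c = np.cumsum(x - x.min())
        total = c[-1]
        return c / total if total > 0 else c

    return float(np.max(np.abs(norm_cumsum(rq) - norm_cumsum(sq))))


def _default_panel(seed: int) -> dict[str, object]:
    return {
        "logistic": LogisticRegression(max_iter=2000, random_state=seed),
        "tree": DecisionTreeClassifier(max_depth=5, random_state=seed),
        "forest": RandomForestClassifier(n_estimators=50, random_state=seed),
        "mlp": "package-mlp",  # the in-package activity-level MLP
    }


def classifier_f1_jaccard(
    real: pd.DataFrame,
    synthetic: pd.DataFrame,
    seed: int = 0,
    test_size: float = 0.25,
    mlp_config: TrainingConfig | None = None,
) -> dict:
    """Train a fixed classifier panel on real vs synthetic; compare on real test data.

    Returns per-classifier macro-F1 pairs and the Jaccard similarity of the
    two correctly-classified test index sets.  When the synthetic labels
    have collapsed to a single class the comparison is not meaningful and
    ``{"compatible": False}`` is returned instead.
    """
    if synthetic["Active"].nunique() < 2:
        return {"compatible": False, "reason": "synthetic labels contain a single class"}
    y = real["Active"].to_numpy(dtype=int)
    tr, te = train_test_split(
        np.arange(len(real)), test_size=test_size, random_state=seed, stratify=y
    )
    x_te = real.iloc[te][FEATURES].to_numpy(dtype=float)
    y_te = y[te]
    out: dict = {"compatible": True, "panel": {}}
    for name, clf in _default_panel(seed).items():
        correct: dict[str, set] = {}
        f1s: dict[str, float] = {}
        for source, table in (("real", real.iloc[tr]), ("synthetic", synthetic)):
            x_tr = table[FEATURES].to_numpy(dtype=float)
            y_tr = table["Active"].to_numpy(dtype=int)
            if name == "mlp":
                cfg = mlp_config or TrainingConfig(seed=seed)
                net, scaling, _ = train_mlp(x_tr, y_tr, config=cfg, seed=seed)
                pred = _predict(net, scaling, x_te)
            else:
                scaler = StandardScaler().fit(x_tr)
                clf.fit(scaler.transform(x_tr), y_tr)
                pred = clf.predict(scaler.transform(x_te))
            f1s[source] = float(f1_score(y_te, pred, average="macro", zero_division=0))
            correct[source] = set(np.flatnonzero(pred == y_te))
        out["panel"][name] = {
            "f1_real": f1s["real"],
            "f1_synthetic": f1s["synthetic"],
            "jaccard": jaccard_similarity(correct["real"], correct["synthetic"]),
        }
    return out
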