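"""Quantitative evaluation of latent representations.

Reconstruction quality is measured with SSIM and PSNR. Disentanglement is
scored against PCA-orthogonalized ground-truth factors via

* DCI — Disentanglement (each latent predicts few factors), Completeness
  (each factor is predicted by few latents) and Informativeness (factors are
  predictable from the latents at all), derived from a latent-by-factor
  importance matrix fitted with a tree ensemble or lasso;
* MIG — per factor, the gap in mutual information between the two most
  informative latents, normalized by the factor entropy, estimated by
  quantile binning.

Point estimates are stabilized by averaging over independent resampling
iterations, and robustness is probed by comparing reports computed
separately from left- and right-eye images of the same subjects.

LPIPS is not computed (it requires pretrained perceptual-network weights);
the report schema carries an explicit "not computed" marker instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = [
    "ssim",
    "psnr",
    "factor_pca",
    "ImportanceMatrix",
    "importance_matrix",
    "DCIScores",
    "dci_scores",
    "group_disentanglement",
    "mig",
    "EvalReport",
    "resample_evaluate",
    "interocular_consistency",
]


def ssim(x: np.ndarray, y: np.ndarray, window: int = 7, k1: float = 0.01, k2: float = 0.03) -> float:
    """Gaussian-weighted local SSIM, mean over pixels and channels; inputs in [0, 1]."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if window > min(x.shape[0], x.shape[1]):
        raise ValueError(f"window {window} larger than image {x.shape[:2]}")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    kwargs = dict(
        win_size=window,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        data_range=1.0,
        K1=k1,
        K2=k2,
    )
    if x.ndim == 3:
        kwargs["channel_axis"] = -1
    return float(structural_similarity(x, y, **kwargs))


def psnr(x: np.ndarray, y: np.ndarray, max_val: float = 1.0) -> float:
    """10 log10(max_val^2 / MSE) in dB; +inf when the images are identical."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float(np.inf)
    return float(10.0 * np.log10(max_val**2 / mse))


def factor_pca(
    factors: pd.DataFrame, variance_target: float = 0.95, standardize: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orthogonal factor scores: standardize, drop constants, PCA, retain the
    smallest number of components reaching ``variance_target`` variance.

    Returns (scores, loadings); scores have mutually zero sample correlation.
    ``standardize=False`` keeps the factors' native scales, which makes the
    principal directions identifiable when the factors have distinct
    variances (after standardization a spherical spectrum leaves them
    determined only up to rotation).
    """
    from sklearn.decomposition import PCA

    numeric = factors.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2 or len(numeric) < 3:
        raise ValueError("factor PCA needs >= 2 numeric factors and >= 3 samples")
    sd = numeric.std(axis=0, ddof=0)
    constant = sd <= 0
    if constant.any():
        warnings.warn(f"dropping constant factor columns: {list(sd.index[constant])}")
        numeric = numeric.loc[:, ~constant]
        sd = sd[~constant]
    z = (numeric - numeric.mean(axis=0)) / sd if standardize else numeric - numeric.mean(axis=0)
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_keep = min(n_keep, scores.shape[1])
    cols = [f"PC{i + 1}" for i in range(n_keep)]
    score_df = pd.DataFrame(scores[:, :n_keep], index=factors.index, columns=cols)
    loadings = pd.DataFrame(pca.components_[:n_keep].T, index=numeric.columns, columns=cols)
    return score_df, loadings


@dataclass
class ImportanceMatrix:
    """Nonnegative latent-by-factor importances plus held-out prediction errors."""

    R: np.ndarray  # (n_latents, n_factors), >= 0
    latent_names: list[str]
    factor_names: list[str]
    estimator: str
    prediction_error: np.ndarray  # per factor, normalized to [0, 1]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.latent_names, columns=self.factor_names)


def importance_matrix(
    latents: pd.DataFrame,
    targets: pd.DataFrame,
    estimator: str = "tree_ensemble",
    seed: int = 0,
    n_estimators: int = 40,
) -> ImportanceMatrix:
    """Fit one regressor per factor on a train half; importances fill R[:, k].

    Informativeness error per factor is the held-out MSE normalized by the
    factor variance, clipped to [0, 1].
    """
    if len(latents) != len(targets):
        raise ValueError("latents and targets must have aligned rows")
    if len(latents) < 50:
        raise ValueError("importance estimation needs >= 50 samples")
    X = np.asarray(latents, dtype=np.float64)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    half = len(X) // 2
    tr, te = order[:half], order[half:]

    n_latents = X.shape[1]
    factor_names = list(targets.columns)
    R = np.zeros((n_latents, len(factor_names)))
    errors = np.zeros(len(factor_names))
    for k, name in enumerate(factor_names):
        y = np.asarray(targets[name], dtype=np.float64)
        try:
            if estimator == "tree_ensemble":
                from sklearn.ensemble import GradientBoostingRegressor

                model = GradientBoostingRegressor(
                    n_estimators=n_estimators, max_depth=3, random_state=seed
                )
                model.fit(X[tr], y[tr])
                imp = model.feature_importances_
            elif estimator == "lasso":
                from sklearn.linear_model import Lasso
                from sklearn.preprocessing import StandardScaler

                scaler = StandardScaler().fit(X[tr])
                model = Lasso(alpha=0.02, max_iter=5000)
                model.fit(scaler.transform(X[tr]), (y[tr] - y[tr].mean()) / (y[tr].std() + 1e-12))
                imp = np.abs(model.coef_)
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - estimator failure path
            raise RuntimeError(f"importance estimator failed for factor {name!r}: {exc}") from exc
        R[:, k] = np.maximum(imp, 0.0)
        if estimator == "lasso":
            pred = model.predict(scaler.transform(X[te])) * (y[tr].std() + 1e-12) + y[tr].mean()
        else:
            pred = model.predict(X[te])
        var = y[te].var()
        errors[k] = float(np.clip(np.mean((pred - y[te]) ** 2) / var, 0.0, 1.0)) if var > 0 else 1.0
    return ImportanceMatrix(
        R=R,
        latent_names=list(latents.columns),
        factor_names=factor_names,
        estimator=estimator,
        prediction_error=errors,
    )


@dataclass
class DCIScores:
    disentanglement: float
    completeness: float
    informativeness: float
    per_latent: np.ndarray
    per_factor: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {
            "D": self.disentanglement,
            "C": self.completeness,
            "I": self.informativeness,
        }


def _entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) along the last axis of a normalized array."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=-1)


def dci_scores(R) -> DCIScores:
    """DCI from an importance matrix: entropy-based exclusivity row- and column-wise."""
    if isinstance(R, ImportanceMatrix):
        imp, errors = R.R, R.prediction_error
    else:
        imp, errors = np.asarray(R, dtype=np.float64), None
    if imp.ndim != 2 or (imp < 0).any():
        raise ValueError("importance matrix must be 2-D and nonnegative")
    total = imp.sum()
    if total <= 0:
        raise ValueError("importance matrix is all-zero; DCI undefined")
    n_latents, n_factors = imp.shape

    row_sums = imp.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P_rows = np.where(row_sums[:, None] > 0, imp / row_sums[:, None], 0.0)
    if n_factors > 1:
        D_j = 1.0 - _entropy(P_rows) / np.log(n_factors)
    else:
        D_j = np.ones(n_latents)
    D_j = np.where(row_sums > 0, D_j, 0.0)
    rho = row_sums / total
    D = float((rho * D_j).sum())

    col_sums = imp.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        P_cols = np.where(col_sums[None, :] > 0, imp / col_sums[None, :], 0.0)
    if n_latents > 1:
        C_k = 1.0 - _entropy(P_cols.T) / np.log(n_latents)
    else:
        C_k = np.ones(n_factors)
    C_k = np.where(col_sums > 0, C_k, 0.0)
    w = col_sums / total
    C = float((w * C_k).sum())

    informativeness = float(1.0 - np.mean(errors)) if errors is not None else float("nan")
    return DCIScores(
        disentanglement=D,
        completeness=C,
        informativeness=informativeness,
        per_latent=D_j,
        per_factor=C_k,
    )


def group_disentanglement(imp: ImportanceMatrix, group_of: Mapping[str, str] | None = None) -> dict[str, float]:
    """Row-mass-weighted mean per-latent disentanglement within latent groups.

    Latents are grouped by ``group_of`` (default: the stream prefix before
    ``_z`` in the latent name). For a concatenated multi-stream latent matrix
    this yields each stream's dedicated-block disentanglement on a shared set
    of factor targets, directly comparable with a monolithic model's overall
    score on the same targets.
    """
    scores = dci_scores(imp)
    rho = imp.R.sum(axis=1) / imp.R.sum()
    groups: dict[str, list[int]] = {}
    for j, name in enumerate(imp.latent_names):
        g = group_of[name] if group_of is not None else str(name).rsplit("_z", 1)[0]
        groups.setdefault(g, []).append(j)
    out = {}
    for g, idx in groups.items():
        w = rho[idx]
        out[g] = float((w * scores.per_latent[idx]).sum() / w.sum()) if w.sum() > 0 else 0.0
    return out


def _quantile_bin(values: np.ndarray, bins: int) -> np.ndarray:
    """Quantile-bin a 1-D array; ties collapse bins (categorical behaviour)."""
    edges = np.unique(np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(values, edges)


def _mi_from_codes(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two integer code vectors."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (px * py)), 0.0)
    return float(terms.sum())


def mig(latents, factors, bins: int = 20) -> float:
    """Mutual Information Gap: mean over factors of the normalized MI gap
    between the two most informative latents; clipped to [0, 1]."""
    L = np.asarray(latents, dtype=np.float64)
    F = np.asarray(factors, dtype=np.float64)
    if len(L) != len(F):
        raise ValueError("latents and factors must have aligned rows")
    if len(L) < bins * 5:
        raise ValueError(f"MIG with {bins} bins needs >= {bins * 5} samples")
    if L.ndim == 1:
        L = L[:, None]
    if F.ndim == 1:
        F = F[:, None]
    latent_codes = [_quantile_bin(L[:, j], bins) for j in range(L.shape[1])]
    gaps = []
    for k in range(F.shape[1]):
        vk = _quantile_bin(F[:, k], bins)
        p = np.bincount(vk).astype(float)
        p = p[p > 0] / p.sum()
        h = float(-(p * np.log(p)).sum())
        if h <= 0:
            warnings.warn(f"factor column {k} is degenerate (single bin); excluded from MIG")
            continue
        mis = sorted((_mi_from_codes(zj, vk) for zj in latent_codes), reverse=True)
        top2 = mis[1] if len(mis) > 1 else 0.0
        gaps.append((mis[0] - top2) / h)
    if not gaps:
        raise ValueError("no non-degenerate factors for MIG")
    return float(np.clip(np.mean(gaps), 0.0, 1.0))


@dataclass
class EvalReport:
    """Mean and sd of each metric over resampling iterations."""

    metrics: dict[str, tuple[float, float]]
    iterations: int
    n: int
    with_replacement: bool = False
    lpips: str = "not computed"

    def mean(self, name: str) -> float:
        return self.metrics[name][0]

    def sd(self, name: str) -> float:
        return self.metrics[name][1]

    def to_dict(self) -> dict:
        return {
            "metrics": {k: {"mean": m, "sd": s} for k, (m, s) in self.metrics.items()},
            "iterations": self.iterations,
            "n": self.n,
            "with_replacement": self.with_replacement,
            "lpips": self.lpips,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(
            [{"metric": k, "mean": m, "sd": s} for k, (m, s) in sorted(self.metrics.items())]
        )
        frame.to_csv(path, index=False)


def resample_evaluate(
    latents: pd.DataFrame,
    factor_scores: pd.DataFrame,
    recon_pairs: tuple[np.ndarray, np.ndarray] | None = None,
    iters: int = 10,
    n: int = 1000,
    seed: int = 0,
    estimator: str = "tree_ensemble",
    bins: int = 20,
) -> EvalReport:
    """Average SSIM/PSNR/DCI/MIG over ``iters`` subsamples of size ``n``.

    Subsampling is without replacement when the population allows it,
    otherwise with replacement (flagged in the report). Per-sample SSIM/PSNR
    are computed once on the population and then averaged per subsample.
    """
    pop = len(latents)
    if pop != len(factor_scores):
        raise ValueError("latents and factor scores must have aligned rows")
    replace = pop < n
    rng = np.random.default_rng(seed)

    ssim_per, psnr_per = None, None
    if recon_pairs is not None:
        x, xhat = recon_pairs
        if len(x) != pop or len(xhat) != pop:
            raise ValueError("reconstruction pairs must align with the latent rows")
        ssim_per = np.array(
            [ssim(np.moveaxis(a, 0, -1), np.moveaxis(b, 0, -1)) for a, b in zip(x, xhat)]
        )
        psnr_per = np.array([psnr(a, b) for a, b in zip(x, xhat)])

    rows = []
    for _ in range(iters):
        # sorted indices: iterations drawing the same multiset of samples
        # produce identical metrics regardless of draw order
        idx = np.sort(rng.choice(pop, size=n, replace=replace))
        sub_lat = latents.iloc[idx]
        sub_fac = factor_scores.iloc[idx]
        imp = importance_matrix(sub_lat, sub_fac, estimator=estimator, seed=seed)
        dci = dci_scores(imp)
        rec = {
            "D": dci.disentanglement,
            "C": dci.completeness,
            "I": dci.informativeness,
            "MIG": mig(sub_lat, sub_fac, bins=bins),
        }
        if ssim_per is not None:
            finite = np.isfinite(psnr_per[idx])
            rec["SSIM"] = float(ssim_per[idx].mean())
            rec["PSNR"] = float(psnr_per[idx][finite].mean()) if finite.any() else float("inf")
        rows.append(rec)
    frame = pd.DataFrame(rows)
    metrics = {c: (float(frame[c].mean()), float(frame[c].std(ddof=0))) for c in frame.columns}
    return EvalReport(metrics=metrics, iterations=iters, n=n, with_replacement=replace)


def interocular_consistency(
    left: EvalReport, right: EvalReport, tolerance: float = 0.1
) -> pd.DataFrame:
    """Absolute left-right differences per metric with a pass/fail column."""
    if set(left.metrics) != set(right.metrics):
        raise ValueError(
            f"metric sets differ: {sorted(set(left.metrics) ^ set(right.metrics))}"
        )
    rows = []
    for name in sorted(left.metrics):
        delta = abs(left.mean(name) - right.mean(name))
        rows.append(
            {
                "metric": name,
                "left": left.mean(name),
                "right": right.mean(name),
                "abs_diff": delta,
                "within_tolerance": bool(delta <= tolerance),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
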