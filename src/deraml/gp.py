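"""Gaussian-process specificity models with multiple kernel learning.

One GP regressor is fitted per substrate on wild-type-relative activities.
The covariance is a convex combination of candidate contact-graph kernels,

    K_tilde = tau^2 * sum_m w_m K_m + sigma^2 * I,   w on the simplex,

and the simplex weights w, signal variance tau^2 and noise variance
sigma^2 are chosen by maximizing the exact log marginal likelihood

    L = -1/2 y^T K_tilde^-1 y - 1/2 log|K_tilde| - n/2 log(2 pi)

with exponentiated-gradient ascent on w and gradient ascent on the log
variances, under a shared backtracking line search (every accepted step
increases L, so the objective trace is monotone). The multiplicative
weight updates drive uninformative kernels towards zero, so kernel
selection is emergent rather than imposed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import pearsonr

from .kernels import KernelBank, KernelMatrix
from .variants import Variant

NOISE_FLOOR = 1e-6
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameter-optimization settings for the MKL GP."""

    n_starts: int = 5
    max_iter: int = 500
    rel_tol: float = 1e-8
    noise_floor: float = NOISE_FLOOR
    fixed_noise: float | None = None      # pin sigma^2 (e.g. at the floor)
    fixed_signal: float | None = None     # pin tau^2
    fixed_weights: Sequence[float] | None = None
    target_transform: str = "none"        # "none" | "log1p"
    seed: int = 0


@dataclass
class TrainedSpecificityModel:
    """A fitted per-substrate GP with learned simplex kernel weights."""

    substrate: str
    kernel_names: tuple[str, ...]
    kernel_weights: np.ndarray
    signal_variance: float
    noise_variance: float
    mean: float
    dual_coefficients: np.ndarray          # alpha = K_tilde^-1 (y - mean)
    training_index: tuple[str, ...]
    target_transform: str = "none"
    log_marginal_likelihood: float = float("nan")
    objective_trace: tuple[float, ...] = ()
    _chol: tuple[np.ndarray, bool] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.kernel_weights, dtype=float)
        if np.any(w < -1e-9) or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("kernel weights must lie on the simplex")
        if self.noise_variance <= 0:
            raise ValueError("noise variance must be positive")
        if len(self.dual_coefficients) != len(self.training_index):
            raise ValueError("dual coefficient length must equal training size")

    # -- serialization (weights and hyperparameters; the Cholesky factor is
    #    rebuilt from the Gram matrices on load) ---------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "substrate": self.substrate,
            "kernel_names": list(self.kernel_names),
            "kernel_weights": [float(w) for w in self.kernel_weights],
            "signal_variance": self.signal_variance,
            "noise_variance": self.noise_variance,
            "mean": self.mean,
            "dual_coefficients": [float(a) for a in self.dual_coefficients],
            "training_index": list(self.training_index),
            "target_transform": self.target_transform,
            "log_marginal_likelihood": self.log_marginal_likelihood,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "TrainedSpecificityModel":
        if isinstance(text_or_path, Path):
            text = text_or_path.read_text()
        else:
            text = text_or_path
        p = json.loads(text)
        return cls(
            substrate=p["substrate"],
            kernel_names=tuple(p["kernel_names"]),
            kernel_weights=np.array(p["kernel_weights"]),
            signal_variance=p["signal_variance"],
            noise_variance=p["noise_variance"],
            mean=p["mean"],
            dual_coefficients=np.array(p["dual_coefficients"]),
            training_index=tuple(p["training_index"]),
            target_transform=p["target_transform"],
            log_marginal_likelihood=p["log_marginal_likelihood"],
        )

    def attach_training_kernels(self, kernel_values: Sequence[np.ndarray]) -> None:
        """Rebuild the training Cholesky factor after deserialization."""
        Kw = _weighted_sum(kernel_values, self.kernel_weights)
        n = Kw.shape[0]
        Kt = self.signal_variance * Kw + self.noise_variance * np.eye(n)
        self._chol = cho_factor(Kt, lower=True)


def _weighted_sum(mats: Sequence[np.ndarray], w: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mats[0])
    for wi, K in zip(w, mats):
        if wi != 0.0:
            out += wi * K
    return out


def _transform(y: np.ndarray, kind: str) -> np.ndarray:
    if kind == "none":
        return y
    if kind == "log1p":
        return np.log1p(y)
    raise ValueError(f"unknown target transform {kind!r}")


def _inverse_transform(y: np.ndarray, kind: str) -> np.ndarray:
    return y if kind == "none" else np.expm1(y)


def _log_marginal(Ks, w, tau2, sig2, yc):
    n = len(yc)
    Kt = tau2 * _weighted_sum(Ks, w) + sig2 * np.eye(n)
    try:
        chol = cho_factor(Kt, lower=True)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "training covariance is singular at the noise floor; raise the "
            "noise floor or remove duplicate variants"
        ) from err
    alpha = cho_solve(chol, yc)
    lml = -0.5 * float(yc @ alpha) - float(np.log(np.diag(chol[0])).sum()) - 0.5 * n * _LOG_2PI
    return lml, chol, alpha


def _optimize_single_start(Ks, yc, w0, tau2_0, sig2_0, cfg: FitConfig):
    """Backtracking exponentiated-/log-gradient ascent from one start."""
    w = np.asarray(w0, dtype=float).copy()
    tau2, sig2 = float(tau2_0), float(sig2_0)
    fit_w = cfg.fixed_weights is None and len(Ks) > 1
    fit_sig = cfg.fixed_noise is None
    fit_tau = cfg.fixed_signal is None
    n = len(yc)
    eye = np.eye(n)

    lml, chol, alpha = _log_marginal(Ks, w, tau2, sig2, yc)
    trace = [lml]
    step = 0.1
    for _ in range(cfg.max_iter):
        Kinv = cho_solve(chol, eye)
        G = 0.5 * (np.outer(alpha, alpha) - Kinv)
        grad_w = np.array([tau2 * np.sum(G * K) for K in Ks]) if fit_w else None
        Kw = _weighted_sum(Ks, w)
        grad_lt = tau2 * float(np.sum(G * Kw)) if fit_tau else 0.0
        grad_ls = sig2 * float(np.trace(G)) if fit_sig else 0.0

        improved = False
        for _bt in range(40):
            if fit_w:
                # exponentiated gradient keeps w on the simplex
                z = np.clip(step * grad_w, -50.0, 50.0)
                w_new = w * np.exp(z - z.max())
                w_new /= w_new.sum()
            else:
                w_new = w
            tau2_new = tau2 * np.exp(np.clip(step * grad_lt, -5.0, 5.0)) if fit_tau else tau2
            sig2_new = sig2 * np.exp(np.clip(step * grad_ls, -5.0, 5.0)) if fit_sig else sig2
            sig2_new = max(sig2_new, cfg.noise_floor)
            try:
                lml_new, chol_new, alpha_new = _log_marginal(Ks, w_new, tau2_new, sig2_new, yc)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if lml_new >= lml:
                improved = lml_new > lml
                converged = abs(lml_new - lml) <= cfg.rel_tol * max(1.0, abs(lml))
                w, tau2, sig2 = w_new, tau2_new, sig2_new
                lml, chol, alpha = lml_new, chol_new, alpha_new
                trace.append(lml)
                step = min(step * 1.3, 10.0)
                break
            step *= 0.5
        else:
            converged = True
        if converged or not improved:
            break
    return w, tau2, sig2, lml, chol, alpha, trace


def fit_mkl_gp(
    records: pd.DataFrame | np.ndarray,
    grams: Sequence[KernelMatrix],
    config: FitConfig = FitConfig(),
    substrate: str = "",
) -> TrainedSpecificityModel:
    """Fit one per-substrate GP with learned simplex kernel weights.

    ``records`` is either a DataFrame with ``variant`` and
    ``relative_activity`` columns for a single substrate (replicates are
    averaged per variant) or an array of targets already aligned with the
    Gram index. All Gram matrices must be square and share one variant
    index covering every record.
    """
    if not grams:
        raise ValueError("at least one Gram matrix is required")
    index = grams[0].row_index
    for g in grams:
        if not g.is_square or g.row_index != index:
            raise ValueError("Gram matrices must be square and share one variant index")

    if isinstance(records, pd.DataFrame):
        if "substrate" in records.columns:
            labels = set(records["substrate"].unique())
            if len(labels) > 1:
                raise ValueError(f"records span several substrates: {sorted(labels)}")
            substrate = substrate or next(iter(labels))
        per_variant = records.groupby("variant")["relative_activity"].mean()
        missing = [v for v in index if v not in per_variant.index]
        if missing:
            raise ValueError(f"no activity record for indexed variants: {missing[:5]}")
        y = per_variant.reindex(list(index)).to_numpy(dtype=float)
    else:
        y = np.asarray(records, dtype=float)
        if y.shape != (len(index),):
            raise ValueError("target vector must align with the Gram index")

    n = len(y)
    if n < 3:
        raise ValueError("at least 3 training variants are required")

    yt = _transform(y, config.target_transform)
    mean = float(yt.mean())
    yc = yt - mean
    Ks = [g.values for g in grams]
    m = len(Ks)

    var_y = max(float(yc.var()), 1e-4)
    rng = np.random.default_rng(config.seed)

    if config.fixed_weights is not None:
        w_fixed = np.asarray(config.fixed_weights, dtype=float)
        if w_fixed.shape != (m,) or np.any(w_fixed < -1e-12) or abs(w_fixed.sum() - 1) > 1e-9:
            raise ValueError("fixed_weights must be a simplex vector over the kernels")

    starts: list[tuple[np.ndarray, float, float]] = []
    n_starts = max(1, config.n_starts)
    for s in range(n_starts):
        if config.fixed_weights is not None:
            w0 = np.asarray(config.fixed_weights, dtype=float)
        elif s == 0:
            w0 = np.full(m, 1.0 / m)
        else:
            w0 = rng.dirichlet(np.ones(m))
        tau2_0 = config.fixed_signal if config.fixed_signal is not None else var_y
        if config.fixed_noise is not None:
            sig2_0 = max(config.fixed_noise, config.noise_floor)
        else:
            sig2_0 = var_y * (0.1 if s % 2 == 0 else 0.01)
            sig2_0 = max(sig2_0, config.noise_floor)
        starts.append((w0, tau2_0, sig2_0))

    best = None
    for w0, tau2_0, sig2_0 in starts:
        result = _optimize_single_start(Ks, yc, w0, tau2_0, sig2_0, config)
        if best is None or result[3] > best[3]:
            best = result
    w, tau2, sig2, lml, chol, alpha, trace = best  # type: ignore[misc]

    model = TrainedSpecificityModel(
        substrate=substrate,
        kernel_names=tuple(g.name for g in grams),
        kernel_weights=w,
        signal_variance=tau2,
        noise_variance=sig2,
        mean=mean,
        dual_coefficients=alpha,
        training_index=index,
        target_transform=config.target_transform,
        log_marginal_likelihood=lml,
        objective_trace=tuple(trace),
    )
    model._chol = chol
    return model


def predict(
    model: TrainedSpecificityModel,
    variants: Sequence[Variant],
    bank: KernelBank,
    weight_cutoff: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """GP posterior mean and variance for new variants.

    Kernels whose learned weight is below ``weight_cutoff`` are skipped
    when computing cross-Gram matrices. Predictive variances are the
    latent-function variances (no observation noise), clipped at zero if
    rounding drives them negative.
    """
    if model._chol is None:
        raise RuntimeError(
            "model has no training Cholesky factor; call attach_training_kernels "
            "with the training Gram matrices after deserialization"
        )
    if not set(model.kernel_names).issubset(bank.names):
        missing = set(model.kernel_names) - set(bank.names)
        raise KeyError(f"kernel bank lacks substitution models: {sorted(missing)}")
    train = [Variant.parse(s) for s in model.training_index]
    active = [n for n, w in zip(model.kernel_names, model.kernel_weights) if w > weight_cutoff]
    cross = bank.cross_matrices(variants, train, only=active)
    Kx = np.zeros((len(variants), len(train)))
    for n_, w_ in zip(model.kernel_names, model.kernel_weights):
        if n_ in cross:
            Kx += w_ * cross[n_]
    kstar = model.signal_variance * Kx
    mean_t = model.mean + kstar @ model.dual_coefficients
    solved = cho_solve(model._chol, kstar.T)
    # normalized kernels have unit diagonal, so k(x*, x*) = tau^2 exactly
    var = model.signal_variance - np.einsum("ij,ji->i", kstar, solved)
    if np.any(var < -1e-8):
        warnings.warn("negative predictive variance clipped to zero", stacklevel=2)
    var = np.clip(var, 0.0, None)
    return _inverse_transform(mean_t, model.target_transform), var


@dataclass(frozen=True)
class CVReport:
    """Held-out cross-validation summary, per substrate."""

    correlations: dict[str, float | None]   # None = undefined (constant targets)
    fold_assignments: dict[str, int]        # variant -> fold
    n_folds: int
    seed: int
    predictions: pd.DataFrame | None = None

    def correlation(self, substrate: str) -> float | None:
        return self.correlations[substrate]


def cross_validate(
    records: pd.DataFrame,
    bank: KernelBank,
    n_folds: int = 10,
    seed: int = 0,
    config: FitConfig = FitConfig(),
) -> CVReport:
    """Variant-level k-fold CV of the full MKL + GP pipeline.

    Folds partition *variants* (not individual records), the kernel
    weights and hyperparameters are re-learned on every training split,
    and the held-out Pearson correlation is reported per substrate.
    Substrates whose held-out targets are constant get correlation None.
    """
    if n_folds < 2:
        raise ValueError("at least 2 folds are required")
    variants = sorted(records["variant"].unique())
    if len(variants) < n_folds:
        raise ValueError("more folds than variants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(variants))
    folds = {variants[i]: int(f % n_folds) for f, i in enumerate(order)}

    vobjs = [Variant.parse(v) for v in variants]
    grams_full = bank.gram_matrices(vobjs)
    name_to_pos = {v: i for i, v in enumerate(variants)}

    rows = []
    for substrate, sub in records.groupby("substrate"):
        per_variant = sub.groupby("variant")["relative_activity"].mean()
        y_all = per_variant.reindex(variants).to_numpy(dtype=float)
        if np.any(np.isnan(y_all)):
            raise ValueError(f"substrate {substrate} lacks records for some variants")
        for fold in range(n_folds):
            test_idx = np.array([name_to_pos[v] for v in variants if folds[v] == fold])
            train_idx = np.array([name_to_pos[v] for v in variants if folds[v] != fold])
            sub_grams = [
                KernelMatrix(
                    row_index=tuple(variants[i] for i in train_idx),
                    col_index=tuple(variants[i] for i in train_idx),
                    values=g.values[np.ix_(train_idx, train_idx)],
                    name=g.name,
                )
                for g in grams_full
            ]
            model = fit_mkl_gp(y_all[train_idx], sub_grams, config, substrate=str(substrate))
            Kx = _weighted_sum(
                [g.values[np.ix_(test_idx, train_idx)] for g in grams_full],
                model.kernel_weights,
            )
            kstar = model.signal_variance * Kx
            pred_t = model.mean + kstar @ model.dual_coefficients
            pred = _inverse_transform(pred_t, model.target_transform)
            for i, p in zip(test_idx, pred):
                rows.append({"substrate": substrate, "variant": variants[i],
                             "fold": fold, "observed": y_all[i], "predicted": float(p)})

    preds = pd.DataFrame(rows)
    correlations: dict[str, float | None] = {}
    for substrate, sub in preds.groupby("substrate"):
        obs, est = sub["observed"].to_numpy(), sub["predicted"].to_numpy()
        if np.std(obs) == 0.0 or np.std(est) == 0.0:
            correlations[str(substrate)] = None
        else:
            correlations[str(substrate)] = float(pearsonr(obs, est)[0])
    return CVReport(correlations=correlations, fold_assignments=folds,
                    n_folds=n_folds, seed=seed, predictions=preds)
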