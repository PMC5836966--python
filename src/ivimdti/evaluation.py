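"""Error metrics and the sensitivity / convergence simulation experiments.

The experiments quantify how each estimator degrades as the initialization is
moved away from the truth by a common ratio X_init (initial f and the initial
mean diffusivities of both tensors are all X_init times their target values),
as iteration count grows, and — for the two-step method — as the cut-off
b-value changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators, phantom, tensors
from .estimators import FitResult, SolverOptions
from .params import ParamVector
from .phantom import Config1Spec
from .scheme import AcquisitionScheme

__all__ = [
    "percentage_error",
    "voxel_error_metrics",
    "sensitivity_sweep",
    "convergence_trace",
    "cutoff_scan",
    "SweepResult",
    "METRICS",
]

METRICS = (
    "residual",
    "f_pct_error",
    "angle_dstar_deg",
    "angle_d_deg",
    "md_dstar_pct_error",
    "fa_dstar_pct_error",
    "md_d_pct_error",
    "fa_d_pct_error",
)

METHODS = ("tsm", "osm", "osm-dgn1", "osm-dgn2")


def percentage_error(estimate, target) -> np.ndarray | float:
    """Absolute relative error in percent, 100·|est - target|/|target|."""
    est = np.asarray(estimate, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if np.any(tgt == 0):
        raise ValueError("percentage error undefined for zero target")
    out = 100.0 * np.abs(est - tgt) / np.abs(tgt)
    return float(out) if out.ndim == 0 else out


@dataclass
class SweepResult:
    """Mean/std of each error metric per (X_init ratio, method)."""

    ratios: np.ndarray
    methods: List[str]
    table: pd.DataFrame  # columns: ratio, method, metric, mean, std

    def mean(self, method: str, metric: str) -> np.ndarray:
        sub = self.table[
            (self.table["method"] == method) & (self.table["metric"] == metric)
        ].sort_values("ratio")
        return sub["mean"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, metric: str, ax=None):
        """Mean +/- std of one error metric against the X_init ratio."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for method in self.methods:
            sub = self.table[
                (self.table["method"] == method) & (self.table["metric"] == metric)
            ].sort_values("ratio")
            m, s = sub["mean"].to_numpy(), sub["std"].to_numpy()
            ax.plot(sub["ratio"], m, label=method)
            ax.fill_between(sub["ratio"], m - s, m + s, alpha=0.2)
        ax.set_xlabel("X_init ratio")
        ax.set_ylabel(metric)
        ax.legend()
        return ax


def _truth_measures(truth: ParamVector) -> Dict[str, float | np.ndarray]:
    dstar = truth.d_star
    d = truth.d
    return {
        "f": truth.f,
        "md_dstar": tensors.mean_diffusivity(dstar),
        "fa_dstar": tensors.fractional_anisotropy(dstar),
        "dir_dstar": tensors.principal_direction(dstar),
        "md_d": tensors.mean_diffusivity(d),
        "fa_d": tensors.fractional_anisotropy(d),
        "dir_d": tensors.principal_direction(d),
    }


def voxel_error_metrics(fit: FitResult, truth: ParamVector) -> Dict[str, float]:
    """The eight per-voxel error measures against a known ground truth."""
    tm = _truth_measures(truth)
    dstar = fit.params.d_star
    d = fit.params.d
    return {
        "residual": fit.residual,
        "f_pct_error": percentage_error(fit.params.f, tm["f"]),
        "angle_dstar_deg": tensors.angle_error(
            tensors.principal_direction(dstar), tm["dir_dstar"]
        ),
        "angle_d_deg": tensors.angle_error(
            tensors.principal_direction(d), tm["dir_d"]
        ),
        "md_dstar_pct_error": percentage_error(
            tensors.mean_diffusivity(dstar), tm["md_dstar"]
        ),
        "fa_dstar_pct_error": percentage_error(
            tensors.fractional_anisotropy(dstar), tm["fa_dstar"]
        ),
        "md_d_pct_error": percentage_error(tensors.mean_diffusivity(d), tm["md_d"]),
        "fa_d_pct_error": percentage_error(
            tensors.fractional_anisotropy(d), tm["fa_d"]
        ),
    }


def _fit_one(
    method: str,
    y: np.ndarray,
    scheme: AcquisitionScheme,
    x0: ParamVector,
    s0_meas: float,
    b0_replicates: np.ndarray,
    opts: Optional[SolverOptions],
    b_cutoff: float,
) -> FitResult:
    if method == "tsm":
        return estimators.tsm_fit(y, scheme, s0_meas, b_cutoff, x0, opts)
    if method == "osm":
        return estimators.osm_fit(y, scheme, x0, opts)
    if method == "osm-dgn1":
        return estimators.dgn_fit(y, scheme, x0, opts, prior=None)
    if method == "osm-dgn2":
        prior = estimators.build_prior(b0_replicates)
        return estimators.dgn_fit(y, scheme, x0, opts, prior=prior)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _initialization(
    truth_measures: Dict, s0_meas: float, ratio: float
) -> ParamVector:
    return estimators.initialize_params(
        s0_meas,
        estimators.f_init_from_ratio(truth_measures["f"], ratio),
        ratio * truth_measures["md_dstar"],
        ratio * truth_measures["md_d"],
    )


def sensitivity_sweep(
    spec: Config1Spec,
    scheme: AcquisitionScheme,
    methods: Sequence[str] = METHODS,
    ratios: Sequence[float] = (0.2, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5),
    n_realizations: Optional[int] = None,
    seed: Optional[int] = None,
    opts: Optional[SolverOptions] = None,
    b_cutoff: float = 500.0,
) -> SweepResult:
    """Initialization-sensitivity experiment.

    For every ratio in the X_init grid each method is fitted to every noisy
    realization starting from the isotropic initialization implied by that
    ratio, and the mean/std of the eight error metrics are aggregated.
    The default grid endpoints (0.2, 3.5) match the study sweep.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; expected one of {METHODS}")
    ratios = np.asarray(sorted(ratios), dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("X_init ratios must be positive")
    if n_realizations is not None:
        spec = Config1Spec(**{**spec.__dict__, "n_realizations": n_realizations})
    reals, truth = phantom.synthesize_voxel(spec, scheme, seed=seed)
    tm = _truth_measures(truth)
    b0_mask = scheme.b0_mask

    rows = []
    for ratio in ratios:
        per_metric: Dict[str, Dict[str, List[float]]] = {
            m: {k: [] for k in METRICS} for m in methods
        }
        for y in reals:
            b0_reps = y[b0_mask]
            s0_meas = float(b0_reps.mean())
            x0 = _initialization(tm, s0_meas, ratio)
            for method in methods:
                fit = _fit_one(
                    method, y, scheme, x0, s0_meas, b0_reps, opts, b_cutoff
                )
                errs = voxel_error_metrics(fit, truth)
                for k in METRICS:
                    per_metric[method][k].append(errs[k])
        for method in methods:
            for k in METRICS:
                vals = np.asarray(per_metric[method][k])
                rows.append(
                    {
                        "ratio": ratio,
                        "method": method,
                        "metric": k,
                        "mean": vals.mean(),
                        "std": vals.std(ddof=1) if vals.size > 1 else 0.0,
                    }
                )
    return SweepResult(
        ratios=ratios, methods=list(methods), table=pd.DataFrame(rows)
    )


def convergence_trace(
    spec: Config1Spec,
    scheme: AcquisitionScheme,
    methods: Sequence[str] = ("osm", "osm-dgn1", "osm-dgn2"),
    x_init_ratio: float = 2.5,
    n_realizations: Optional[int] = None,
    seed: Optional[int] = None,
    opts: Optional[SolverOptions] = None,
) -> pd.DataFrame:
    """Per-iteration mean/std of S0, f, U1, V1 for each method.

    Iterate 0 is the isotropic initialization.  Realizations that stop early
    are padded with their final iterate so the aggregate is over a common
    length (at most max_iterations + 1).
    """
    if n_realizations is not None:
        spec = Config1Spec(**{**spec.__dict__, "n_realizations": n_realizations})
    reals, truth = phantom.synthesize_voxel(spec, scheme, seed=seed)
    tm = _truth_measures(truth)
    b0_mask = scheme.b0_mask
    opts = opts or SolverOptions()
    n_iter = opts.max_iterations + 1
    tracked = {"s0": 0, "f": 1, "u1": 2, "v1": 8}

    rows = []
    for method in methods:
        traces = np.empty((len(reals), n_iter, 14))
        for i, y in enumerate(reals):
            b0_reps = y[b0_mask]
            s0_meas = float(b0_reps.mean())
            x0 = _initialization(tm, s0_meas, x_init_ratio)
            fit = _fit_one(method, y, scheme, x0, s0_meas, b0_reps, opts, 500.0)
            xt = fit.x_trace
            if xt.shape[0] < n_iter:  # pad with the final iterate
                pad = np.repeat(xt[-1:], n_iter - xt.shape[0], axis=0)
                xt = np.vstack([xt, pad])
            traces[i] = xt[:n_iter]
        for name, idx in tracked.items():
            for it in range(n_iter):
                vals = traces[:, it, idx]
                rows.append(
                    {
                        "method": method,
                        "parameter": name,
                        "iteration": it,
                        "mean": vals.mean(),
                        "std": vals.std(ddof=1) if vals.size > 1 else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def cutoff_scan(
    spec: Config1Spec,
    scheme: AcquisitionScheme,
    cutoffs: Sequence[float] = (150.0, 250.0, 350.0, 450.0, 550.0, 650.0, 750.0, 850.0),
    n_realizations: Optional[int] = None,
    seed: Optional[int] = None,
    opts: Optional[SolverOptions] = None,
    x_init_ratio: float = 1.0,
) -> pd.DataFrame:
    """Mean two-step-method residual as a function of the cut-off b-value."""
    if n_realizations is not None:
        spec = Config1Spec(**{**spec.__dict__, "n_realizations": n_realizations})
    reals, truth = phantom.synthesize_voxel(spec, scheme, seed=seed)
    tm = _truth_measures(truth)
    b0_mask = scheme.b0_mask
    rows = []
    for cutoff in cutoffs:
        if np.count_nonzero(scheme.bvals >= cutoff) < 7:
            raise ValueError(f"cutoff {cutoff} leaves fewer than 7 measurements")
        resids = []
        for y in reals:
            b0_reps = y[b0_mask]
            s0_meas = float(b0_reps.mean())
            x0 = _initialization(tm, s0_meas, x_init_ratio)
            fit = estimators.tsm_fit(y, scheme, s0_meas, cutoff, x0, opts)
            resids.append(fit.residual)
        resids = np.asarray(resids)
        rows.append(
            {
                "b_cutoff": cutoff,
                "mean_residual": resids.mean(),
                "std_residual": resids.std(ddof=1) if resids.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def compare_methods_ttest(
    errors_a: np.ndarray, errors_b: np.ndarray
) -> Dict[str, float]:
    """Two-sample t-test on per-realization errors of two methods."""
    t, p = stats.ttest_ind(np.asarray(errors_a), np.asarray(errors_b))
    return {"t": float(t), "p": float(p)}
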