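"""1:1 binding-isotherm fitting for titration data.

The model is the exact ligand-depletion ("quadratic") 1:1 mass-action
isotherm.  With labeled target at total concentration T, titrant (ligand)
at total concentration L and dissociation constant K_D, the bound
fraction of target is

    f(L) = ((L + T + K_D) - sqrt((L + T + K_D)^2 - 4 L T)) / (2 T)

and the measured response (for MicroScale Thermophoresis, the normalized
fluorescence Fnorm in ‰) is modelled as

    response(L) = R_free + (R_bound - R_free) * f(L).

The depletion form is required whenever T is not negligible relative to
K_D (typical for MST, where the labeled target sits at tens of nM while
the titrant spans µM); in the T ≪ K_D limit it reduces to the simple
hyperbola L / (L + K_D), which is also available as an explicit model
choice.

All concentrations are handled internally in molar units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "BindingError",
    "TitrationDataset",
    "TitrationFit",
    "bound_fraction",
    "fit_kd",
    "read_titration_csv",
    "write_fit_json",
    "plot_fit",
]

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


class BindingError(ValueError):
    """Raised for invalid concentrations or unusable datasets."""


@dataclass(frozen=True)
class TitrationDataset:
    """A (pooled) titration series: ligand concentration vs response.

    ``target_conc`` is the constant molar concentration of the labeled
    target; ``ligand_conc`` and ``response`` are parallel arrays;
    ``replicate_id`` optionally labels independent dilution series that
    are pooled into one fit.
    """

    target_conc: float
    ligand_conc: np.ndarray
    response: np.ndarray
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        lig = np.asarray(self.ligand_conc, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "ligand_conc", lig)
        object.__setattr__(self, "response", resp)
        if self.target_conc <= 0:
            raise BindingError(f"target concentration must be positive, got {self.target_conc}")
        if lig.shape != resp.shape or lig.ndim != 1:
            raise BindingError("ligand_conc and response must be 1-D arrays of equal length")
        if np.any(lig <= 0):
            raise BindingError("ligand concentrations must be strictly positive")
        if len(lig) < 6:
            raise BindingError(f"need at least 6 titration points, got {len(lig)}")

    @property
    def n_points(self) -> int:
        return len(self.ligand_conc)

    def span_decades(self) -> float:
        return float(np.log10(self.ligand_conc.max() / self.ligand_conc.min()))


@dataclass(frozen=True)
class TitrationFit:
    """Fitted K_D with baseline/amplitude and diagnostics."""

    kd: float  # molar
    response_free: float
    response_bound: float
    kd_stderr: float  # molar; inf when the curvature is singular
    rss: float
    converged: bool
    n_points: int = 0
    model: str = "depletion"
    message: str = ""

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise BindingError(f"fitted kd must be positive, got {self.kd}")
        if self.converged and not np.isfinite(self.kd_stderr):
            raise BindingError("a converged fit must carry a finite stderr")


def bound_fraction(
    kd: float,
    target_conc: float,
    ligand_conc: float | np.ndarray,
) -> float | np.ndarray:
    """Bound fraction of the target under the 1:1 depletion model.

    Exact mass-action solution; clamped to [0, 1] against round-off.
    Scalar in, scalar out; array in, array out.
    """
    L = np.asarray(ligand_conc, dtype=float)
    scalar = L.ndim == 0
    if kd <= 0 or target_conc <= 0 or np.any(L <= 0):
        raise BindingError("kd, target_conc and ligand_conc must all be positive")
    s = L + target_conc + kd
    disc = s * s - 4.0 * L * target_conc
    f = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * target_conc)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if scalar else f


def _hyperbola_fraction(kd: float, ligand_conc: np.ndarray) -> np.ndarray:
    return ligand_conc / (ligand_conc + kd)


def _model_response(params: np.ndarray, data: TitrationDataset, model: str) -> np.ndarray:
    log_kd, r_free, r_bound = params
    kd = 10.0 ** log_kd
    if model == "depletion":
        f = bound_fraction(kd, data.target_conc, data.ligand_conc)
    else:
        f = _hyperbola_fraction(kd, data.ligand_conc)
    return r_free + (r_bound - r_free) * f


def fit_kd(data: TitrationDataset, model: str = "depletion") -> TitrationFit:
    """Least-squares fit of the 1:1 isotherm to a titration dataset.

    K_D is fitted on a log scale (bounded positive by construction);
    baseline and saturated responses start from the responses at the
    lowest/highest ligand concentrations and the K_D search starts at
    the mid-transition ligand concentration.  The standard error of K_D
    comes from the local curvature (Gauss-Newton covariance) at the
    optimum.  Non-convergence and degenerate (flat) data are flagged on
    the returned fit rather than raised.
    """
    if model not in ("depletion", "hyperbola"):
        raise BindingError(f"unknown binding model {model!r}")
    if data.span_decades() < 2.0:
        warnings.warn(
            f"ligand series spans only {data.span_decades():.2f} decades; "
            "K_D may be poorly constrained",
            stacklevel=2,
        )
    order = np.argsort(data.ligand_conc)
    lig_sorted = data.ligand_conc[order]
    resp_sorted = data.response[order]
    r_free0 = float(np.mean(resp_sorted[:2]))
    r_bound0 = float(np.mean(resp_sorted[-2:]))
    midpoint = 0.5 * (r_free0 + r_bound0)
    kd0 = float(lig_sorted[np.argmin(np.abs(resp_sorted - midpoint))])
    kd0 = min(max(kd0, lig_sorted[0]), lig_sorted[-1])

    x0 = np.array([np.log10(kd0), r_free0, r_bound0])
    lo_kd = np.log10(lig_sorted[0]) - 4.0
    hi_kd = np.log10(lig_sorted[-1]) + 4.0

    def residuals(p: np.ndarray) -> np.ndarray:
        return _model_response(p, data, model) - data.response

    try:
        res = least_squares(
            residuals,
            x0,
            bounds=([lo_kd, -np.inf, -np.inf], [hi_kd, np.inf, np.inf]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except Exception as exc:  # defensive: report, never raise, per contract
        return TitrationFit(
            kd=kd0, response_free=r_free0, response_bound=r_bound0,
            kd_stderr=float("inf"), rss=float("inf"), converged=False,
            n_points=data.n_points, model=model, message=f"optimizer failure: {exc}",
        )

    log_kd, r_free, r_bound = res.x
    kd = float(10.0 ** log_kd)
    rss = float(np.sum(res.fun**2))

    # covariance from J^T J at the optimum; propagate log10(kd) -> kd
    kd_stderr = float("inf")
    n, p = data.n_points, 3
    if res.success and n > p:
        JTJ = res.jac.T @ res.jac
        sigma2 = rss / (n - p)
        try:
            cov = np.linalg.inv(JTJ) * sigma2
            var_log_kd = cov[0, 0]
            if var_log_kd >= 0:
                kd_stderr = float(np.sqrt(var_log_kd) * np.log(10.0) * kd)
        except np.linalg.LinAlgError:
            pass

    amplitude = abs(r_bound - r_free)
    resid_scale = np.sqrt(rss / max(n - p, 1))
    degenerate = amplitude < max(3.0 * resid_scale, 1e-12) or not np.isfinite(kd_stderr)
    converged = bool(res.success) and not degenerate
    return TitrationFit(
        kd=kd,
        response_free=float(r_free),
        response_bound=float(r_bound),
        kd_stderr=kd_stderr if converged else float("inf"),
        rss=rss,
        converged=converged,
        n_points=n,
        model=model,
        message=res.message if res.success else f"not converged: {res.message}",
    )


# ---------------------------------------------------------------------------
# I/O


def read_titration_csv(
    path: str | Path,
    target_conc: float,
    unit: str | None = None,
) -> TitrationDataset:
    """Read a titration table from CSV.

    Expected columns: ``ligand_conc``, ``response`` and optionally
    ``series``.  The ligand-concentration unit may be declared in the
    column header as a bracketed suffix (``ligand_conc[uM]``) or passed
    explicitly; default is molar.  ``target_conc`` is always molar.
    Multiple series are pooled; per-series fits can be made by filtering
    beforehand.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    lig_col = None
    for c in df.columns:
        if c == "ligand_conc" or c.startswith("ligand_conc["):
            lig_col = c
            break
    if lig_col is None or "response" not in df.columns:
        raise BindingError(f"{path}: need columns 'ligand_conc[...]' and 'response', got {list(df.columns)}")
    scale = 1.0
    if "[" in lig_col:
        declared = lig_col.split("[", 1)[1].rstrip("]")
        if declared not in _UNIT_SCALE:
            raise BindingError(f"unknown concentration unit {declared!r}")
        scale = _UNIT_SCALE[declared]
    if unit is not None:
        if unit not in _UNIT_SCALE:
            raise BindingError(f"unknown concentration unit {unit!r}")
        scale = _UNIT_SCALE[unit]
    series = df["series"].to_numpy() if "series" in df.columns else None
    return TitrationDataset(
        target_conc=target_conc,
        ligand_conc=df[lig_col].to_numpy(dtype=float) * scale,
        response=df["response"].to_numpy(dtype=float),
        replicate_id=series,
    )


def write_fit_json(fit: TitrationFit, path: str | Path) -> None:
    payload = {
        "kd_molar": fit.kd,
        "kd_stderr_molar": fit.kd_stderr if np.isfinite(fit.kd_stderr) else None,
        "response_free": fit.response_free,
        "response_bound": fit.response_bound,
        "rss": fit.rss,
        "converged": fit.converged,
        "n_points": fit.n_points,
        "model": fit.model,
        "message": fit.message,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def plot_fit(data: TitrationDataset, fit: TitrationFit, path: str | Path) -> None:
    """Plot data points and the fitted isotherm on a log-x axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.logspace(
        np.log10(data.ligand_conc.min()), np.log10(data.ligand_conc.max()), 200
    )
    if fit.model == "depletion":
        f = bound_fraction(fit.kd, data.target_conc, grid)
    else:
        f = _hyperbola_fraction(fit.kd, grid)
    curve = fit.response_free + (fit.response_bound - fit.response_free) * f

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.semilogx(data.ligand_conc, data.response, "o", label="data")
    ax.semilogx(grid, curve, "-", label=f"fit, K_D = {fit.kd:.3g} M")
    ax.set_xlabel("ligand concentration (M)")
    ax.set_ylabel("response")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
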