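"""Ligand-depletion fluorescence binding analysis.

A fluorescently labelled receptor at total concentration R_T (here ~16 nM
of labelled HPt protein) is titrated with ligand (a receiver domain) to
total concentrations L_T comparable with Kd, so free ligand cannot be
approximated by total ligand. The complex concentration is the physical
root of the mass-action quadratic:

    [RL] = ((R_T + L_T + Kd) - sqrt((R_T + L_T + Kd)^2 - 4 R_T L_T)) / 2

Each raw series (titrant and buffer-only) is normalised to its own
pre-titration intensity F0 and the buffer series subtracted,

    delta_i = (F/F0)_titrant,i - (F/F0)_buffer,i ,

which removes dilution and drift. The model fitted to delta(L_T) is
A·[RL]/R_T with amplitude A the fractional fluorescence change of the
fully bound receptor; Kd is estimated on a log scale by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


@dataclass
class Titration:
    """One raw titration series: total ligand vs fluorescence intensity.

    ``baseline_intensity`` (F0) is the intensity of the receptor alone,
    before any addition.
    """

    receptor_total: float  # molar
    ligand_total: np.ndarray  # molar, strictly increasing
    intensity: np.ndarray  # arbitrary units
    baseline_intensity: float

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ligand_total.shape != self.intensity.shape:
            raise ValueError("ligand_total and intensity must have equal length")
        if np.any(self.ligand_total < 0):
            raise ValueError("ligand_total must be non-negative")
        if np.any(np.diff(self.ligand_total) <= 0):
            raise ValueError("ligand_total must be strictly increasing")
        if not self.baseline_intensity > 0:
            raise ValueError("baseline intensity F0 must be positive")

    @property
    def n_points(self) -> int:
        return self.ligand_total.size


@dataclass
class NormalizedTitration:
    """Buffer-subtracted normalised response delta vs total ligand."""

    receptor_total: float
    ligand_total: np.ndarray
    delta: np.ndarray


@dataclass
class BindingParams:
    Kd: float  # molar, > 0
    amplitude: float  # signed, dimensionless

    def __post_init__(self) -> None:
        if not self.Kd > 0:
            raise ValueError("Kd must be positive")


@dataclass
class FitResult:
    params: BindingParams
    std_errors: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = False
    n_points: int = 0
    message: str = ""


def complex_concentration(R_T, L_T, Kd):
    """Complex concentration [RL] from the ligand-depletion quadratic.

    Uses the product form 2·R_T·L_T / (b + sqrt(b² − 4·R_T·L_T)) with
    b = R_T + L_T + Kd, which is numerically stable when the discriminant
    nearly cancels (tight binding). Accepts scalars or arrays.
    """
    R_T = np.asarray(R_T, dtype=float)
    L_T = np.asarray(L_T, dtype=float)
    if np.any(R_T < 0) or np.any(L_T < 0):
        raise ValueError("concentrations must be non-negative")
    if not Kd > 0:
        raise ValueError("Kd must be positive")
    b = R_T + L_T + Kd
    disc = b * b - 4.0 * R_T * L_T
    rl = 2.0 * R_T * L_T / (b + np.sqrt(np.maximum(disc, 0.0)))
    out = np.minimum(rl, np.minimum(R_T, L_T))
    return out if out.ndim else float(out)


def predict_response(params: BindingParams, R_T: float, L_T) -> np.ndarray:
    """Model response delta = A·[RL]/R_T; saturates at A as L_T → ∞."""
    if R_T <= 0:
        raise ValueError("receptor_total must be positive")
    rl = complex_concentration(R_T, L_T, params.Kd)
    return params.amplitude * rl / R_T


def normalize_titration(
    ligand_series: Titration, buffer_series: Titration
) -> NormalizedTitration:
    """F/F0 normalisation of each series and point-wise buffer subtraction.

    The two series must share the same addition schedule length; L_T is
    taken from the ligand series.
    """
    if ligand_series.n_points != buffer_series.n_points:
        raise ValueError(
            f"series length mismatch: ligand {ligand_series.n_points} vs "
            f"buffer {buffer_series.n_points}"
        )
    delta = (
        ligand_series.intensity / ligand_series.baseline_intensity
        - buffer_series.intensity / buffer_series.baseline_intensity
    )
    return NormalizedTitration(
        ligand_series.receptor_total, ligand_series.ligand_total.copy(), delta
    )


class DegenerateDataError(ValueError):
    """The response carries no usable binding signal (all deltas equal)."""


_KD_BOUNDS = (1e-12, 1e-2)  # molar


def fit_binding(data: NormalizedTitration, with_drift: bool = False,
                weights=None) -> FitResult:
    """Least-squares fit of (Kd, amplitude) to a normalised titration.

    Kd is parameterised as log(Kd) internally and bounded to
    [1 pM, 10 mM]. Initial guesses: Kd0 = L_T at the half-maximal observed
    delta, A0 = the observed delta of largest magnitude. Standard errors
    come from the Jacobian at the optimum (delta method for Kd).
    ``with_drift`` adds a nuisance slope linear in L_T.
    """
    L = np.asarray(data.ligand_total, dtype=float)
    y = np.asarray(data.delta, dtype=float)
    if L.size < 4:
        raise ValueError("need at least 4 titration points to fit")
    if np.ptp(y) == 0.0:
        raise DegenerateDataError("all deltas equal; no binding signal to fit")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))
    R_T = data.receptor_total

    a0 = y[np.argmax(np.abs(y))]
    half = a0 / 2.0
    idx = int(np.argmin(np.abs(y - half)))
    kd0 = float(np.clip(L[idx] if L[idx] > 0 else np.median(L), *_KD_BOUNDS))
    if np.sum(y > half) == 0 or np.sum(y < half) == 0:
        warnings.warn(
            "titration does not bracket the response midpoint; "
            "Kd may be poorly determined",
            stacklevel=2,
        )

    def residuals(theta):
        kd = np.exp(theta[0])
        pred = theta[1] * complex_concentration(R_T, L, kd) / R_T
        if with_drift:
            pred = pred + theta[2] * L
        return w * (pred - y)

    theta0 = [np.log(kd0), a0] + ([0.0] if with_drift else [])
    lo = [np.log(_KD_BOUNDS[0]), -np.inf] + ([-np.inf] if with_drift else [])
    hi = [np.log(_KD_BOUNDS[1]), np.inf] + ([np.inf] if with_drift else [])
    sol = optimize.least_squares(
        residuals, theta0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
    )

    kd = float(np.exp(sol.x[0]))
    amp = float(sol.x[1])
    rss = float(np.sum(sol.fun**2))
    n, p = y.size, sol.x.size
    std = {}
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * (rss / max(n - p, 1))
        se = np.sqrt(np.diag(cov))
        std = {"Kd": kd * float(se[0]), "amplitude": float(se[1])}
        if with_drift:
            std["drift"] = float(se[2])
    except np.linalg.LinAlgError:
        pass

    result = FitResult(
        params=BindingParams(kd, amp),
        std_errors=std,
        rss=rss,
        converged=bool(sol.success and np.isfinite([kd, amp]).all()),
        n_points=int(n),
        message=sol.message,
    )
    if with_drift:
        result.std_errors.setdefault("drift", float("nan"))
        result.drift = float(sol.x[2])  # type: ignore[attr-defined]
    return result


def replicate_kd_summary(fits: list[FitResult]) -> tuple[float, float]:
    """Mean and sample SD of Kd over replicate titrations.

    This is the convention for reporting a dissociation constant from
    replicate titrations: fit each curve separately, then take the mean
    and standard deviation of the per-replicate estimates.
    """
    kds = np.array([f.params.Kd for f in fits if f.converged])
    if kds.size == 0:
        raise ValueError("no converged fits to summarise")
    sd = float(kds.std(ddof=1)) if kds.size > 1 else float("nan")
    return float(kds.mean()), sd
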