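"""The three-term linear rescoring model.

Docking scores alone correlate only weakly with measured PARP-1 inhibition.
Rescoring with residue-group energy sums does better: the binding free
energy is modelled as

    ΔG = c1·E_ele + c2·E_nonele + c3·E_other + c0

where the three features are the summed per-residue interaction energies of
the electrostatic, non-electrostatic and remaining pocket-residue groups
(kcal/mol) and the coefficients are calibrated by ordinary least squares
against experimental affinities derived from IC50 measurements via
ΔG = −RT·ln(1/IC50).

The API follows the Model/Results convention: build an
:class:`AffinityModel` from an :class:`~parpscreen.energy.EnergyPanel` (or a
DataFrame), call :meth:`AffinityModel.fit` and work with the returned
:class:`AffinityResults` (coefficients, standard errors, R², ``summary()``,
``predict()``, JSON round-trip, a fit plot).  ``AffinityResults.from_coefficients``
wraps an externally calibrated model — e.g. the published PARP-1 model
(0.067, 0.104, 0.457, −3.615) — in the same interface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .energy import EnergyPanel, GroupEnergyFeatures
from .errors import DomainError, FitError, InputError, ActivitySpreadError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE",
    "ic50_to_dg",
    "IC50Record",
    "consolidate_ic50",
    "r_squared",
    "AffinityModel",
    "AffinityResults",
    "fit_mlr",
    "published_parp1_model",
]

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 1.9872e-3
#: Default absolute temperature (K) for IC50 → ΔG conversion.
STANDARD_TEMPERATURE = 298.15

FEATURE_NAMES = ("e_ele", "e_nonele", "e_other")


def ic50_to_dg(ic50: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Convert an IC50 (molar) to a binding free energy, ΔG = −RT·ln(1/IC50).

    Negative (favourable) for sub-molar IC50; the usual caveat applies that
    IC50 stands in for Ki, so this is an operational affinity scale.
    """
    if ic50 <= 0:
        raise DomainError(f"ic50 must be positive, got {ic50}")
    if temperature <= 0:
        raise DomainError(f"temperature must be positive, got {temperature}")
    return -GAS_CONSTANT_KCAL * temperature * math.log(1.0 / ic50)


@dataclass
class IC50Record:
    """Replicate IC50 measurements (molar) for one complex."""

    complex_id: str
    ic50_values: list[float]
    temperature: float = STANDARD_TEMPERATURE

    def __post_init__(self) -> None:
        if not self.ic50_values:
            raise InputError(f"{self.complex_id}: no IC50 values")
        if any(v <= 0 for v in self.ic50_values):
            raise DomainError(f"{self.complex_id}: IC50 values must be positive")


def consolidate_ic50(record: IC50Record, max_fold_spread: float = 10.0) -> float:
    """Average replicate IC50s and convert to ΔG, rejecting inconsistent sets.

    Replicates are usable only when they agree to within ``max_fold_spread``
    (the same order of magnitude, by default 10-fold).  Averaging is
    arithmetic in concentration space; disagreement raises
    :class:`~parpscreen.errors.ActivitySpreadError`.
    """
    values = record.ic50_values
    spread = max(values) / min(values)
    if spread > max_fold_spread:
        raise ActivitySpreadError(
            f"{record.complex_id}: IC50 replicates span {spread:.1f}-fold "
            f"(> {max_fold_spread:g}-fold); activities are not at the same level"
        )
    return ic50_to_dg(sum(values) / len(values), record.temperature)


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 − SSres/SStot.

    May be negative for predictions worse than the observed mean; no capping
    is applied here.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise InputError("observed and predicted must be equal-length 1-d, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("observed values are constant; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


class AffinityModel:
    """Three-term linear affinity model bound to a panel of complexes.

    Parameters
    ----------
    panel : EnergyPanel
        Feature rows; only rows carrying ``experimental_dg`` enter the fit
        (at least 5 are required — four parameters plus one).
    """

    def __init__(self, panel: EnergyPanel):
        self.panel = panel
        self._labeled = panel.labeled()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "AffinityModel":
        return cls(EnergyPanel.from_dataframe(df, provenance=provenance))

    @property
    def exog_names(self) -> tuple[str, ...]:
        return FEATURE_NAMES + ("intercept",)

    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        rows = self._labeled.rows
        X = np.array([[r.e_ele, r.e_nonele, r.e_other] for r in rows])
        y = np.array([r.experimental_dg for r in rows])
        return X, y

    def fit(self) -> "AffinityResults":
        """Ordinary least squares with intercept on the labeled rows."""
        n = len(self._labeled)
        if n < 5:
            raise InputError(
                f"need at least 5 complexes with experimental affinities, have {n}"
            )
        X, y = self._design()
        # diagnose degeneracy before delegating, so the error names a column
        for j, name in enumerate(FEATURE_NAMES):
            if np.ptp(X[:, j]) == 0:
                raise FitError(f"feature {name!r} is constant; design is rank-deficient")
        for j in range(3):
            for k in range(j + 1, 3):
                if np.allclose(X[:, j], X[:, k]):
                    raise FitError(
                        f"features {FEATURE_NAMES[j]!r} and {FEATURE_NAMES[k]!r} "
                        "are identical; design is rank-deficient"
                    )
        design = sm.add_constant(X, prepend=False)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise FitError("design matrix is rank-deficient")
        ols = sm.OLS(y, design).fit()
        params = pd.Series(ols.params, index=self.exog_names)
        bse = pd.Series(ols.bse, index=self.exog_names)
        return AffinityResults(
            params=params,
            bse=bse,
            r_squared=float(ols.rsquared),
            n_fit=n,
            model=self,
            provenance=self.panel.provenance or "fit",
        )


@dataclass
class AffinityResults:
    """Fitted (or externally supplied) coefficients with diagnostics."""

    params: pd.Series
    bse: pd.Series | None = None
    r_squared: float | None = None
    n_fit: int | None = None
    model: AffinityModel | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.params.to_numpy(dtype=float))):
            raise InputError("model coefficients must be finite")
        if self.r_squared is not None and not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise InputError("stored r_squared must lie in [0, 1]")

    # -- coefficient accessors ------------------------------------------------
    @property
    def c1(self) -> float:
        return float(self.params["e_ele"])

    @property
    def c2(self) -> float:
        return float(self.params["e_nonele"])

    @property
    def c3(self) -> float:
        return float(self.params["e_other"])

    @property
    def c0(self) -> float:
        return float(self.params["intercept"])

    @classmethod
    def from_coefficients(
        cls,
        c1: float,
        c2: float,
        c3: float,
        c0: float,
        r_squared: float | None = None,
        n_fit: int | None = None,
        provenance: str = "coefficients",
    ) -> "AffinityResults":
        params = pd.Series([c1, c2, c3, c0], index=FEATURE_NAMES + ("intercept",))
        return cls(params=params, r_squared=r_squared, n_fit=n_fit, provenance=provenance)

    # -- prediction -----------------------------------------------------------
    def predict(self, features) -> float | np.ndarray:
        """Predicted ΔG (kcal/mol) for features.

        Accepts a :class:`GroupEnergyFeatures`, a (e_ele, e_nonele, e_other)
        triple, an :class:`EnergyPanel`, or a DataFrame with the three
        feature columns; returns a scalar for a single row.
        """
        if isinstance(features, GroupEnergyFeatures):
            vec = features.vector
            return float(vec @ [self.c1, self.c2, self.c3] + self.c0)
        if isinstance(features, EnergyPanel):
            features = features.to_dataframe()
        if isinstance(features, pd.DataFrame):
            X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
            return X @ [self.c1, self.c2, self.c3] + self.c0
        vec = np.asarray(features, dtype=float)
        if vec.shape == (3,):
            return float(vec @ [self.c1, self.c2, self.c3] + self.c0)
        if vec.ndim == 2 and vec.shape[1] == 3:
            return vec @ [self.c1, self.c2, self.c3] + self.c0
        raise InputError(f"cannot interpret features with shape {vec.shape}")

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Three-term linear affinity model (kcal/mol)",
            "=" * 46,
            f"{'term':<12}{'coef':>10}{'std err':>12}",
        ]
        for name in self.params.index:
            se = "" if self.bse is None else f"{self.bse[name]:>12.4f}"
            lines.append(f"{name:<12}{self.params[name]:>10.4f}{se}")
        lines.append("-" * 46)
        if self.r_squared is not None:
            lines.append(f"R-squared: {self.r_squared:.4f}")
        if self.n_fit is not None:
            lines.append(f"N (fit):   {self.n_fit}")
        if self.provenance:
            lines.append(f"source:    {self.provenance}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "c1": self.c1,
            "c2": self.c2,
            "c3": self.c3,
            "c0": self.c0,
            "r_squared": self.r_squared,
            "n_fit": self.n_fit,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AffinityResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls.from_coefficients(
            data["c1"],
            data["c2"],
            data["c3"],
            data["c0"],
            r_squared=data.get("r_squared"),
            n_fit=data.get("n_fit"),
            provenance=data.get("provenance", "json"),
        )

    def plot_fit(self, ax=None):
        """Observed vs predicted scatter for the fitting rows."""
        if self.model is None:
            raise InputError("plot_fit requires results produced by AffinityModel.fit")
        import matplotlib.pyplot as plt

        X, y = self.model._design()
        pred = self.predict(X)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(y, pred)
        lo, hi = min(y.min(), pred.min()), max(y.max(), pred.max())
        ax.plot([lo, hi], [lo, hi], ls="--", c="grey")
        ax.set_xlabel("experimental ΔG (kcal/mol)")
        ax.set_ylabel("predicted ΔG (kcal/mol)")
        ax.set_title(f"linear rescoring fit (R² = {self.r_squared:.2f})")
        return ax


def fit_mlr(panel: EnergyPanel) -> AffinityResults:
    """Convenience wrapper: ``AffinityModel(panel).fit()``."""
    return AffinityModel(panel).fit()


def published_parp1_model() -> AffinityResults:
    """The published PARP-1 rescoring model, as reported with its fit R².

    Coefficients (0.067, 0.104, 0.457) on (E_ele, E_nonele, E_other) with
    intercept −3.615 kcal/mol, calibrated on 15 complexes.
    """
    return AffinityResults.from_coefficients(
        0.067, 0.104, 0.457, -3.615, r_squared=0.84, n_fit=15, provenance="published PARP-1 model"
    )
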