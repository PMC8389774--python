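"""Binding-entropy estimators from finite interaction-energy samples.

Three estimators of the entropic contribution −TΔS (kJ/mol) to an
end-state (MM/GBSA-style) binding free energy:

* interaction entropy (IE): the mean-centered exponential average
  −TΔS = RT·ln⟨exp[(ΔE − ⟨ΔE⟩)/RT]⟩,
* the second-order cumulant approximation (C2): σ²/(2RT) with σ the
  population standard deviation of the energies,
* a cutoff-truncated IE that discards frames deviating more than k·σ
  from the mean before exponential averaging.

They are written as scikit-learn estimators (``fit`` on a 1-d energy
sample, results in trailing-underscore attributes) so they compose with
sklearn tooling; module-level functions wrap them for one-call use on
:class:`~entroconv.series.EnergySeries` objects.

The exponential average is evaluated in the log domain (log-sum-exp with
a shift by the maximum centered energy), so it cannot overflow even for
energy fluctuations of hundreds of kJ/mol, where the raw Boltzmann
factor exceeds double-precision range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .constants import DEFAULT_TEMPERATURE, rt
from .series import EnergySeries

__all__ = [
    "EntropyEstimate",
    "InteractionEntropy",
    "CumulantEntropy",
    "TruncatedInteractionEntropy",
    "ie_entropy",
    "c2_entropy",
    "truncated_ie_entropy",
]


@dataclass(frozen=True)
class EntropyEstimate:
    """A −TΔS estimate (kJ/mol) with provenance.

    Attributes
    ----------
    minus_T_delta_S : float
        The entropy contribution −TΔS in kJ/mol.
    method : str
        One of ``"IE"``, ``"C2"``, ``"IE_truncated"``.
    n_samples : int
        Number of energies that entered the average.
    sigma_hat : float
        Population standard deviation of the (full) energy sample, kJ/mol.
    std_error : float, optional
        Standard error over batches when computed by block averaging.
    """

    minus_T_delta_S: float
    method: str
    n_samples: int
    sigma_hat: float
    std_error: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.sigma_hat < 0:
            raise ValueError("sigma_hat must be >= 0")


def _as_energy_array(X, min_len: int = 2) -> np.ndarray:
    x = np.asarray(X, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"need at least {min_len} energies, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("energies must be finite")
    return x


def _resolve(X, temperature: float):
    """Accept either an EnergySeries or a raw array of energies."""
    if isinstance(X, EnergySeries):
        return X.values, X.temperature
    return np.asarray(X, dtype=float).ravel(), temperature


def _ie_log_average(centered: np.ndarray, rt_val: float) -> float:
    # log⟨exp(x/RT)⟩ via log-sum-exp; the implicit shift by max(x/RT)
    # keeps every intermediate within double range.
    return float(logsumexp(centered / rt_val) - np.log(centered.size))


class _EntropyBase(BaseEstimator):
    """Shared fit plumbing for the −TΔS estimators."""

    method: str = ""

    def __init__(self, temperature: float = DEFAULT_TEMPERATURE):
        self.temperature = temperature

    def _validate(self, X):
        values, temperature = _resolve(X, self.temperature)
        values = _as_energy_array(values)
        rt_val = rt(temperature)
        return values, temperature, rt_val

    def fit(self, X, y=None):
        values, temperature, rt_val = self._validate(X)
        self.temperature_ = temperature
        self.sigma_ = float(np.std(values))  # population (denominator N)
        self.n_samples_ = int(values.size)
        self._fit(values, rt_val)
        return self

    def _fit(self, values: np.ndarray, rt_val: float) -> None:  # pragma: no cover
        raise NotImplementedError

    def estimate(self, X=None) -> EntropyEstimate:
        """Return the fitted result as an :class:`EntropyEstimate`."""
        if X is not None:
            self.fit(X)
        return EntropyEstimate(
            minus_T_delta_S=self.minus_T_delta_S_,
            method=self.method,
            n_samples=self.n_samples_,
            sigma_hat=self.sigma_,
        )


class InteractionEntropy(_EntropyBase):
    """Interaction-entropy (IE) estimator: centered exponential average.

    −TΔS_IE = RT·ln⟨exp[(ΔE − ⟨ΔE⟩)/RT]⟩ over the sample. Non-negative
    by Jensen's inequality, and equal to σ²/(2RT) in the limit of an
    infinite Gaussian sample.

    Parameters
    ----------
    temperature : float, default 300.0
        Used only when ``fit`` receives a bare array; an
        :class:`~entroconv.series.EnergySeries` carries its own T.

    Attributes
    ----------
    minus_T_delta_S_ : float
        The IE entropy in kJ/mol.
    sigma_ : float
        Population standard deviation of the sample (kJ/mol).
    n_samples_ : int
    temperature_ : float
    """

    method = "IE"

    def _fit(self, values: np.ndarray, rt_val: float) -> None:
        centered = values - values.mean()
        log_avg = _ie_log_average(centered, rt_val)
        # Jensen guarantees >= 0; clamp the odd -1e-17 from rounding.
        self.minus_T_delta_S_ = max(rt_val * log_avg, 0.0)


class CumulantEntropy(_EntropyBase):
    """Second-order cumulant (C2) estimator: −TΔS_C2 = σ²/(2RT).

    Exact for Gaussian energy fluctuations, where the cumulant expansion
    of the exponential average truncates at second order. σ is the
    population standard deviation of the sample, which makes the value
    invariant under duplication of every frame.
    """

    method = "C2"

    def _fit(self, values: np.ndarray, rt_val: float) -> None:
        self.minus_T_delta_S_ = self.sigma_**2 / (2.0 * rt_val)


class TruncatedInteractionEntropy(_EntropyBase):
    """IE with a one-pass k·σ cutoff on the energy fluctuations.

    Recomputes the exponential average using only frames with
    |ΔE − mean| ≤ k·σ, where mean and σ come from the *full* sample
    (no iterative re-estimation), then re-centers on the mean of the
    surviving frames. Discarding the far tail stabilises the average but
    biases it low — the bias grows rapidly with σ (see
    :func:`entroconv.gaussian_lab.truncation_bias`).

    Parameters
    ----------
    cutoff_sigma : float, default 3.0
        The cutoff multiple k (dimensionless), k > 0.

    Attributes
    ----------
    n_samples_ : int
        Number of *surviving* frames after the cutoff.
    n_discarded_ : int
        Frames removed by the cutoff.
    """

    method = "IE_truncated"

    def __init__(self, cutoff_sigma: float = 3.0, temperature: float = DEFAULT_TEMPERATURE):
        super().__init__(temperature=temperature)
        self.cutoff_sigma = cutoff_sigma

    def _fit(self, values: np.ndarray, rt_val: float) -> None:
        if self.cutoff_sigma <= 0:
            raise ValueError(f"cutoff_sigma must be > 0, got {self.cutoff_sigma}")
        mean, sigma = values.mean(), self.sigma_
        keep = np.abs(values - mean) <= self.cutoff_sigma * sigma
        survivors = values[keep]
        if survivors.size == 0:
            raise ValueError("cutoff removed every frame")
        self.n_discarded_ = int(values.size - survivors.size)
        self.n_samples_ = int(survivors.size)
        centered = survivors - survivors.mean()
        self.minus_T_delta_S_ = max(rt_val * _ie_log_average(centered, rt_val), 0.0)


def ie_entropy(series: EnergySeries) -> EntropyEstimate:
    """Interaction entropy −TΔS_IE (kJ/mol) of an energy series."""
    return InteractionEntropy().estimate(series)


def c2_entropy(series: EnergySeries) -> EntropyEstimate:
    """Second-order cumulant entropy −TΔS_C2 = σ²/(2RT) (kJ/mol)."""
    return CumulantEntropy().estimate(series)


def truncated_ie_entropy(series: EnergySeries, k: float = 3.0) -> EntropyEstimate:
    """IE entropy with frames beyond k·σ of the mean discarded first."""
    return TruncatedInteractionEntropy(cutoff_sigma=k).estimate(series)
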