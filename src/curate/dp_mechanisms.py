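"""Noise mechanisms and privacy-budget accounting.

Composition convention: releases inside one order (or one optimizer
iteration batch) share a budget and are composed with the advanced
composition theorem; heterogeneous entries across orders/iterations are
summed (basic composition).  The ledger is append-only and enforces the
total (ε, δ) caps at spend time — a release that would overshoot is
rejected before any noise is drawn.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = [
    "PrivacyParams",
    "LedgerEntry",
    "AccountantLedger",
    "BudgetExceededError",
    "laplace_perturb",
    "analytic_gaussian_sigma",
    "classical_gaussian_sigma",
    "advanced_composition",
    "ledger_spend",
    "empirical_privacy_loss",
]


class BudgetExceededError(RuntimeError):
    """A proposed spend would push the ledger past its total budget."""


@dataclass(frozen=True)
class PrivacyParams:
    """Total privacy budget and the failure-probability knobs.

    delta_test
        per-test (or per-iteration) DP failure probability δ.
    delta_prime
        slack δ′ of the advanced composition theorem; the default 1e-12
        follows the δ′ <= n^-1.5 safety rule at n = 10^5.
    delta_total
        cap on the cumulative failure probability of a whole run.
    """

    eps_total: float
    delta_test: float = 1e-15
    delta_prime: float = 1e-12
    delta_total: float = 1e-6

    def __post_init__(self) -> None:
        if self.eps_total <= 0:
            raise ValueError("eps_total must be positive")
        if not (0 < self.delta_prime <= 1):
            raise ValueError("delta_prime must be in (0, 1]")
        if self.delta_test <= 0 or self.delta_total <= 0:
            raise ValueError("delta parameters must be positive")


@dataclass
class LedgerEntry:
    label: str
    t: int
    eps_each: float
    delta_each: float
    eps_composed: float
    delta_composed: float
    extras: dict = field(default_factory=dict)


class AccountantLedger:
    """Append-only record of privacy spends with running totals."""

    def __init__(self, params: PrivacyParams, seed: int | None = None) -> None:
        self.params = params
        self.seed = seed
        self.entries: list[LedgerEntry] = []
        self.flags: list[str] = []

    @property
    def spent_eps(self) -> float:
        return sum(e.eps_composed for e in self.entries)

    @property
    def spent_delta(self) -> float:
        return sum(e.delta_composed for e in self.entries)

    @property
    def remaining_eps(self) -> float:
        return self.params.eps_total - self.spent_eps

    def flag(self, message: str) -> None:
        self.flags.append(message)

    def _append(self, entry: LedgerEntry) -> None:
        if self.spent_eps + entry.eps_composed > self.params.eps_total + 1e-9:
            raise BudgetExceededError(
                f"spend {entry.eps_composed:.6g} exceeds remaining budget "
                f"{self.remaining_eps:.6g}"
            )
        if self.spent_delta + entry.delta_composed > self.params.delta_total + 1e-15:
            raise BudgetExceededError("cumulative delta budget exceeded")
        self.entries.append(entry)

    def spend(
        self,
        label: str,
        t: int,
        eps_each: float,
        delta_each: float | None = None,
        strict: bool = False,
        **extras,
    ) -> LedgerEntry:
        """Charge ``t`` same-budget releases, composed with the advanced
        composition theorem."""
        if delta_each is None:
            delta_each = self.params.delta_test
        eps_c, delta_c = advanced_composition(
            t, eps_each, delta_each, self.params.delta_prime, strict=strict
        )
        entry = LedgerEntry(label, t, eps_each, delta_each, eps_c, delta_c, extras)
        self._append(entry)
        return entry

    def spend_raw(
        self, label: str, eps: float, delta: float | None = None, **extras
    ) -> LedgerEntry:
        """Charge a single (ε, δ)-DP release at face value (basic
        composition with the rest of the ledger)."""
        if delta is None:
            delta = self.params.delta_test
        entry = LedgerEntry(label, 1, eps, delta, eps, delta, extras)
        self._append(entry)
        return entry

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "params": asdict(self.params),
            "flags": list(self.flags),
            "entries": [asdict(e) for e in self.entries],
            "spent_eps": self.spent_eps,
            "spent_delta": self.spent_delta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "AccountantLedger":
        ledger = cls(PrivacyParams(**payload["params"]), seed=payload.get("seed"))
        ledger.flags = list(payload.get("flags", []))
        for e in payload["entries"]:
            ledger.entries.append(LedgerEntry(**e))
        return ledger

    @classmethod
    def from_json(cls, path) -> "AccountantLedger":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def summary_table(self) -> str:
        lines = [
            f"{'label':<18}{'t':>6}{'eps_each':>12}{'eps_comp':>12}{'delta_comp':>12}"
        ]
        for e in self.entries:
            lines.append(
                f"{e.label:<18}{e.t:>6}{e.eps_each:>12.4g}"
                f"{e.eps_composed:>12.4g}{e.delta_composed:>12.4g}"
            )
        lines.append(
            f"{'TOTAL':<18}{'':>6}{'':>12}{self.spent_eps:>12.4g}"
            f"{self.spent_delta:>12.4g}  /  eps_total={self.params.eps_total:g}"
        )
        return "\n".join(lines)


def laplace_perturb(
    value: float, delta1: float, eps: float, rng: np.random.Generator
) -> float:
    """Laplace mechanism: ``value + Lap(Δ1/ε)``.

    Zero sensitivity returns the value unchanged (and draws nothing, so
    deterministic pipelines stay replayable).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if delta1 < 0:
        raise ValueError("sensitivity must be nonnegative")
    if delta1 == 0:
        return float(value)
    return float(value + rng.laplace(0.0, delta1 / eps))


def classical_gaussian_sigma(delta2: float, eps: float, delta: float) -> float:
    """Textbook Gaussian-mechanism calibration ``Δ2 sqrt(2 ln(1.25/δ))/ε``
    (valid for ε <= 1); used as a comparator for the analytic calibration."""
    return delta2 * math.sqrt(2.0 * math.log(1.25 / delta)) / eps


def _gaussian_dp_residual(sigma: float, delta2: float, eps: float) -> float:
    """Left-hand side of the analytic Gaussian-mechanism condition:
    Φ(Δ2/2σ − εσ/Δ2) − e^ε Φ(−Δ2/2σ − εσ/Δ2)."""
    u = delta2 / (2.0 * sigma) - eps * sigma / delta2
    v = -delta2 / (2.0 * sigma) - eps * sigma / delta2
    # exp(eps) * Phi(v) computed in log-space to avoid overflow for large eps
    return float(stats.norm.cdf(u) - math.exp(eps + stats.norm.logcdf(v)))


def analytic_gaussian_sigma(
    delta2: float, eps: float, delta: float, rtol: float = 1e-10
) -> float:
    """Smallest σ making the Gaussian mechanism (ε, δ)-DP.

    Solves the exact mechanism condition
    ``Φ(Δ2/2σ − εσ/Δ2) − e^ε Φ(−Δ2/2σ − εσ/Δ2) <= δ`` by bisection on σ
    (the left-hand side is decreasing in σ).  Never worse than the
    classical ``sqrt(2 ln(1.25/δ))`` calibration where that one applies.
    """
    if delta2 <= 0 or eps <= 0:
        raise ValueError("delta2 and eps must be positive")
    if not (0 < delta < 1):
        raise ValueError("delta must be in (0, 1)")
    hi = delta2 * max(1.0, math.sqrt(2.0 * math.log(1.25 / delta)) / eps)
    while _gaussian_dp_residual(hi, delta2, eps) > delta:
        hi *= 2.0
    lo = hi
    while _gaussian_dp_residual(lo, delta2, eps) <= delta:
        lo /= 2.0
        if lo < 1e-300:
            break
    # invariant: residual(lo) > delta >= residual(hi)
    while (hi - lo) / hi > rtol:
        mid = 0.5 * (lo + hi)
        if _gaussian_dp_residual(mid, delta2, eps) <= delta:
            hi = mid
        else:
            lo = mid
    return hi


def advanced_composition(
    t: int,
    eps_each: float,
    delta_each: float,
    delta_prime: float,
    strict: bool = False,
) -> tuple[float, float]:
    """Leakage of ``t`` adaptive (ε, δ)-DP releases under advanced
    composition.

    Default form: ``ε_comp = t ε² + ε sqrt(2 t ln(1/δ′))`` and
    ``δ_comp = δ′ + t δ`` (the simplified accounting used by the adaptive
    budget optimizer).  ``strict=True`` switches the first term to the
    textbook ``t ε (e^ε − 1)``.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t == 0:
        return 0.0, 0.0
    if eps_each <= 0 or delta_each <= 0 or delta_prime <= 0:
        raise ValueError("eps, delta, delta_prime must be positive")
    tail = eps_each * math.sqrt(2.0 * t * math.log(1.0 / delta_prime))
    if strict:
        eps_c = t * eps_each * (math.exp(eps_each) - 1.0) + tail
    else:
        eps_c = t * eps_each**2 + tail
    return eps_c, delta_prime + t * delta_each


def ledger_spend(
    ledger: AccountantLedger,
    label: str,
    t: int,
    eps_each: float,
    delta_each: float | None = None,
    **extras,
) -> AccountantLedger:
    """Functional wrapper over :meth:`AccountantLedger.spend`."""
    ledger.spend(label, t, eps_each, delta_each, **extras)
    return ledger


def empirical_privacy_loss(
    eps: float,
    n: int = 4,
    n_draws: int = 10**6,
    seed: int = 0,
    n_bins: int = 40,
    min_count: int = 2000,
) -> tuple[float, float]:
    """Histogram-ratio audit of the Laplace release of a binary mean.

    Releases ``mean(x) + Lap(Δ1/ε)`` with ``Δ1 = 1/n`` on an n-row binary
    toy domain and its worst-case neighbour (one flipped row).  Returns
    ``(max_ratio, max_se)`` where ``max_ratio`` is the largest estimated
    probability ratio across bins with at least ``min_count`` draws on both
    sides and ``max_se`` its Monte-Carlo standard error.  A valid mechanism
    keeps ``max_ratio`` at or below ``exp(eps)`` up to that error.
    """
    rng = np.random.default_rng(seed)
    delta1 = 1.0 / n
    x = np.zeros(n)
    x_neighbor = x.copy()
    x_neighbor[0] = 1.0
    scale = delta1 / eps
    a = x.mean() + rng.laplace(0.0, scale, size=n_draws)
    b = x_neighbor.mean() + rng.laplace(0.0, scale, size=n_draws)
    lo, hi = np.quantile(np.concatenate([a, b]), [0.001, 0.999])
    bins = np.linspace(lo, hi, n_bins + 1)
    ca, _ = np.histogram(a, bins=bins)
    cb, _ = np.histogram(b, bins=bins)
    mask = (ca >= min_count) & (cb >= min_count)
    ratios = np.maximum(ca[mask] / cb[mask], cb[mask] / ca[mask])
    i = int(np.argmax(ratios))
    r = float(ratios[i])
    se = r * math.sqrt(1.0 / ca[mask][i] + 1.0 / cb[mask][i])
    return r, se
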