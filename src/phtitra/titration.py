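"""λ-dynamics titration analysis.

Constant-pH MD engines propagate, for every titratable site *i*, a continuous
titration coordinate ``λ_i`` (1 = deprotonated, 0 = protonated) and — for
carboxylates and histidine, which have two titratable sites — a tautomer
interconversion coordinate ``χ_i``.  This module turns per-frame ``(λ, χ)``
records into protonation-state counts, deprotonated fractions ``S_i``, and a
generalized Henderson–Hasselbalch (Hill) fit

    S(pH) = 1 / (1 + 10^{n (pKa - pH)})

whose midpoint is the residue's pKa and whose slope parameter ``n`` is the
Hill coefficient.  Frames with a mixed tautomer (χ strictly inside the purity
band) or an intermediate λ are physically ambiguous and are discarded from the
counts, never silently folded into either state.

The fitting surface follows the Model/Results convention:
``TitrationModel(ph, fraction).fit()`` returns a :class:`TitrationResults`
carrying the point estimates, their asymptotic standard errors, residual
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationRecord",
    "StateCutoffs",
    "ProtonationCounts",
    "TitrationPoint",
    "ChargeSet",
    "ReferencePKaTable",
    "PhRangeFlag",
    "TitrationModel",
    "TitrationResults",
    "classify_state",
    "classify_states",
    "count_states",
    "deprotonated_fraction",
    "cumulative_fraction_series",
    "interpolate_charges",
    "hill_curve",
    "titration_points",
    "fit_titration_curve",
    "pka_shift",
    "UndefinedFractionError",
]

logger = logging.getLogger(__name__)

DEPROTONATED = "deprotonated"
PROTONATED = "protonated"
DISCARDED = "discarded"

# integer codes used by the vectorised classifier
_CODE_DEPROT = 1
_CODE_PROT = 0
_CODE_DISCARD = -1


class UndefinedFractionError(ValueError):
    """All frames at a pH were discarded; S_i has an empty denominator."""


class TitrationRecord(NamedTuple):
    """One per-frame observation of a titratable site.

    ``chi_value`` is ``None`` for residues with a single titratable site
    (e.g. lysine), in which case the tautomer-purity condition is vacuous.
    """

    frame_index: int
    residue_id: str
    lambda_value: float
    chi_value: float | None = None


@dataclass(frozen=True)
class StateCutoffs:
    """λ / χ cut-offs defining pure protonation states.

    A frame is deprotonated when λ ≥ ``deprot_lambda_min``, protonated when
    λ ≤ ``prot_lambda_max``; in both cases χ (when present) must lie outside
    the open mixed band (``chi_pure_low``, ``chi_pure_high``).  Everything
    else is discarded.
    """

    deprot_lambda_min: float = 0.8
    prot_lambda_max: float = 0.2
    chi_pure_low: float = 0.2
    chi_pure_high: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.prot_lambda_max < self.deprot_lambda_min <= 1.0):
            raise ValueError(
                "require 0 <= prot_lambda_max < deprot_lambda_min <= 1, got "
                f"({self.prot_lambda_max}, {self.deprot_lambda_min})"
            )
        if not (0.0 <= self.chi_pure_low < self.chi_pure_high <= 1.0):
            raise ValueError(
                "require 0 <= chi_pure_low < chi_pure_high <= 1, got "
                f"({self.chi_pure_low}, {self.chi_pure_high})"
            )


@dataclass(frozen=True)
class ProtonationCounts:
    """Tally of pure/discarded frames for one residue at one pH."""

    residue_id: str
    n_deprot: int
    n_prot: int
    n_discarded: int

    def __post_init__(self) -> None:
        for name in ("n_deprot", "n_prot", "n_discarded"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_deprot + self.n_prot + self.n_discarded

    @property
    def n_pure(self) -> int:
        return self.n_deprot + self.n_prot


@dataclass(frozen=True)
class TitrationPoint:
    """Deprotonated fraction S_i of one residue at one pH."""

    ph: float
    fraction_deprot: float
    counts: ProtonationCounts | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_deprot <= 1.0):
            raise ValueError("fraction_deprot must lie in [0, 1]")


@dataclass(frozen=True)
class ChargeSet:
    """Per-atom partial charges of a titratable group in its two end states."""

    atom_names: tuple[str, ...]
    q_prot: tuple[float, ...]
    q_deprot: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.atom_names) == len(self.q_prot) == len(self.q_deprot)):
            raise ValueError(
                "atom_names, q_prot and q_deprot must have equal length"
            )


class PhRangeFlag(str, enum.Enum):
    IN_RANGE = "in_range"
    BELOW_GRID = "below_grid"
    ABOVE_GRID = "above_grid"


# --------------------------------------------------------------------------
# state classification and counting
# --------------------------------------------------------------------------

def _check_unit_interval(value: float, name: str, context: str) -> None:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name}={value!r} outside [0, 1] for {context}")


def classify_state(
    record: TitrationRecord, cutoffs: StateCutoffs = StateCutoffs()
) -> str:
    """Classify a single (λ, χ) record as deprotonated / protonated / discarded."""
    context = f"residue {record.residue_id!r}, frame {record.frame_index}"
    _check_unit_interval(record.lambda_value, "lambda", context)
    chi = record.chi_value
    if chi is not None and not (isinstance(chi, float) and math.isnan(chi)):
        _check_unit_interval(chi, "chi", context)
        chi_pure = chi < cutoffs.chi_pure_low or chi > cutoffs.chi_pure_high
    else:
        chi_pure = True
    if chi_pure and record.lambda_value >= cutoffs.deprot_lambda_min:
        return DEPROTONATED
    if chi_pure and record.lambda_value <= cutoffs.prot_lambda_max:
        return PROTONATED
    return DISCARDED


def classify_states(
    lambda_values: np.ndarray,
    chi_values: np.ndarray | None = None,
    cutoffs: StateCutoffs = StateCutoffs(),
) -> np.ndarray:
    """Vectorised classifier; NaN χ means 'no tautomer coordinate'.

    Returns an int array with 1 = deprotonated, 0 = protonated, -1 = discarded.
    """
    lam = np.asarray(lambda_values, dtype=float)
    if np.any((lam < 0.0) | (lam > 1.0)) or np.any(np.isnan(lam)):
        bad = np.flatnonzero((lam < 0.0) | (lam > 1.0) | np.isnan(lam))
        raise ValueError(
            f"lambda values outside [0, 1] at positions {bad[:5].tolist()}"
        )
    if chi_values is None:
        chi_pure = np.ones(lam.shape, dtype=bool)
    else:
        chi = np.asarray(chi_values, dtype=float)
        present = ~np.isnan(chi)
        if np.any((chi[present] < 0.0) | (chi[present] > 1.0)):
            raise ValueError("chi values outside [0, 1]")
        chi_pure = ~present | (chi < cutoffs.chi_pure_low) | (chi > cutoffs.chi_pure_high)
    out = np.full(lam.shape, _CODE_DISCARD, dtype=int)
    out[chi_pure & (lam >= cutoffs.deprot_lambda_min)] = _CODE_DEPROT
    out[chi_pure & (lam <= cutoffs.prot_lambda_max)] = _CODE_PROT
    return out


def _records_to_arrays(
    records: pd.DataFrame | Iterable[TitrationRecord],
) -> tuple[str, np.ndarray, np.ndarray, np.ndarray]:
    """Normalise a record series to (residue_id, frames, lambdas, chis)."""
    if isinstance(records, pd.DataFrame):
        df = records
        if df.empty:
            raise ValueError("empty titration record series")
        residues = df["residue_id"].unique()
        if len(residues) != 1:
            raise ValueError(
                f"records must belong to a single residue, got {sorted(residues)}"
            )
        chi = (
            df["chi"].to_numpy(dtype=float)
            if "chi" in df.columns
            else np.full(len(df), np.nan)
        )
        return (
            str(residues[0]),
            df["frame"].to_numpy(dtype=int),
            df["lambda"].to_numpy(dtype=float),
            chi,
        )
    recs = list(records)
    if not recs:
        raise ValueError("empty titration record series")
    residues = {r.residue_id for r in recs}
    if len(residues) != 1:
        raise ValueError(
            f"records must belong to a single residue, got {sorted(residues)}"
        )
    frames = np.array([r.frame_index for r in recs], dtype=int)
    lam = np.array([r.lambda_value for r in recs], dtype=float)
    chi = np.array(
        [np.nan if r.chi_value is None else r.chi_value for r in recs], dtype=float
    )
    return recs[0].residue_id, frames, lam, chi


def count_states(
    records: pd.DataFrame | Iterable[TitrationRecord],
    cutoffs: StateCutoffs = StateCutoffs(),
) -> ProtonationCounts:
    """Tally pure deprotonated / protonated / discarded frames for one residue."""
    residue_id, _frames, lam, chi = _records_to_arrays(records)
    codes = classify_states(lam, chi, cutoffs)
    return ProtonationCounts(
        residue_id=residue_id,
        n_deprot=int(np.sum(codes == _CODE_DEPROT)),
        n_prot=int(np.sum(codes == _CODE_PROT)),
        n_discarded=int(np.sum(codes == _CODE_DISCARD)),
    )


def deprotonated_fraction(counts: ProtonationCounts) -> float:
    """S_i = N_deprot / (N_deprot + N_prot); discarded frames excluded."""
    if counts.n_pure == 0:
        raise UndefinedFractionError(
            f"residue {counts.residue_id!r}: no pure protonation states "
            f"({counts.n_discarded} frames discarded)"
        )
    return counts.n_deprot / counts.n_pure


def cumulative_fraction_series(
    records: pd.DataFrame | Iterable[TitrationRecord],
    cutoffs: StateCutoffs = StateCutoffs(),
) -> pd.DataFrame:
    """Running deprotonated fraction S_i over the frame series.

    Convergence diagnostic: element k is the fraction computed over records
    0..k.  Prefixes with no pure state yet have ``defined == False`` and a NaN
    fraction; they are flagged, never interpolated.
    """
    residue_id, frames, lam, chi = _records_to_arrays(records)
    order = np.argsort(frames, kind="stable")
    frames, lam, chi = frames[order], lam[order], chi[order]
    codes = classify_states(lam, chi, cutoffs)
    cum_deprot = np.cumsum(codes == _CODE_DEPROT)
    cum_pure = np.cumsum(codes != _CODE_DISCARD)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(cum_pure > 0, cum_deprot / np.maximum(cum_pure, 1), np.nan)
    return pd.DataFrame(
        {
            "frame": frames,
            "residue_id": residue_id,
            "n_pure": cum_pure,
            "fraction_deprot": frac,
            "defined": cum_pure > 0,
        }
    )


def interpolate_charges(lambda_value: float, charges: ChargeSet) -> np.ndarray:
    """Per-atom charge q_α(λ) = λ q_α^deprot + (1 − λ) q_α^prot."""
    if not (0.0 <= lambda_value <= 1.0):
        raise ValueError(f"lambda={lambda_value} outside [0, 1]")
    qd = np.asarray(charges.q_deprot, dtype=float)
    qp = np.asarray(charges.q_prot, dtype=float)
    return lambda_value * qd + (1.0 - lambda_value) * qp


# --------------------------------------------------------------------------
# Henderson–Hasselbalch / Hill fitting
# --------------------------------------------------------------------------

def hill_curve(ph: np.ndarray | float, pka: float, hill_n: float) -> np.ndarray | float:
    """Generalized Henderson–Hasselbalch curve S(pH) = 1/(1 + 10^{n(pKa − pH)})."""
    return 1.0 / (1.0 + 10.0 ** (hill_n * (pka - np.asarray(ph, dtype=float))))


def titration_points(
    records_by_ph: Mapping[float, pd.DataFrame | Iterable[TitrationRecord]],
    cutoffs: StateCutoffs = StateCutoffs(),
) -> list[TitrationPoint]:
    """Deprotonated fraction per pH; pH values with no pure state are dropped
    with a warning (their S_i is undefined)."""
    points: list[TitrationPoint] = []
    for ph in sorted(records_by_ph):
        counts = count_states(records_by_ph[ph], cutoffs)
        try:
            frac = deprotonated_fraction(counts)
        except UndefinedFractionError:
            logger.warning(
                "pH %.2f dropped for residue %s: all %d frames discarded",
                ph,
                counts.residue_id,
                counts.n_total,
            )
            continue
        points.append(TitrationPoint(ph=float(ph), fraction_deprot=frac, counts=counts))
    return points


@dataclass
class TitrationResults:
    """Fitted Hill/Henderson–Hasselbalch titration curve for one residue.

    ``pka`` is the pH of the curve midpoint (S = 0.5 by construction of the
    model); ``hill_n`` the Hill coefficient.  When every observed fraction is
    saturated (> 0.95 everywhere or < 0.05 everywhere) the midpoint lies
    outside the simulated pH grid: ``pka`` is then only a one-sided bound
    (grid edge), ``converged`` is False and ``ph_range_flag`` says which side.
    """

    residue_id: str
    pka: float
    hill_n: float
    residual_norm: float
    converged: bool
    ph_range_flag: PhRangeFlag
    pka_stderr: float = math.nan
    hill_stderr: float = math.nan
    n_points: int = 0
    ph: np.ndarray = field(default_factory=lambda: np.array([]))
    fraction: np.ndarray = field(default_factory=lambda: np.array([]))
    weights: np.ndarray | None = None

    def predict(self, ph: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the fitted curve at the given pH value(s)."""
        return hill_curve(ph, self.pka, self.hill_n)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self.predict(self.ph))

    @property
    def resid(self) -> np.ndarray:
        return self.fraction - self.fittedvalues

    def summary(self) -> str:
        lines = [
            "Titration curve fit (generalized Henderson-Hasselbalch)",
            "=" * 56,
            f"residue:        {self.residue_id}",
            f"n pH points:    {self.n_points}",
            f"converged:      {self.converged}",
            f"pH range flag:  {self.ph_range_flag.value}",
            f"pKa:            {self.pka:.4f}  (se {self.pka_stderr:.4f})",
            f"Hill n:         {self.hill_n:.4f}  (se {self.hill_stderr:.4f})",
            f"residual norm:  {self.residual_norm:.6g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Plot observed fractions and the fitted curve (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        ax.plot(self.ph, self.fraction, "o", label="observed $S_i$")
        if self.ph.size:
            grid = np.linspace(float(np.min(self.ph)), float(np.max(self.ph)), n_grid)
            ax.plot(grid, self.predict(grid), "-", label="fit")
            if self.converged:
                ax.axvline(self.pka, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("pH")
        ax.set_ylabel("deprotonated fraction $S_i$")
        ax.set_title(self.residue_id)
        ax.legend()
        return ax


class TitrationModel:
    """Generalized Henderson–Hasselbalch model for one residue's S_i(pH) data.

    Parameters
    ----------
    ph, fraction : array-like
        Observed pH grid and deprotonated fractions.
    weights : array-like, optional
        Per-point weights (e.g. pure-state counts).  Used only when
        ``fit(weighted=True)``.
    residue_id : str
        Label carried into the results.
    """

    def __init__(self, ph, fraction, weights=None, residue_id: str = "residue"):
        self.ph = np.asarray(ph, dtype=float)
        self.fraction = np.asarray(fraction, dtype=float)
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.residue_id = residue_id
        if self.ph.shape != self.fraction.shape:
            raise ValueError("ph and fraction must have the same shape")
        if self.ph.size < 3:
            raise ValueError("need at least 3 titration points to fit 2 parameters")
        if np.unique(self.ph).size < 2:
            raise ValueError("need at least 2 distinct pH values")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def from_points(
        cls, points: Sequence[TitrationPoint], residue_id: str | None = None
    ) -> "TitrationModel":
        if residue_id is None:
            ids = {p.counts.residue_id for p in points if p.counts is not None}
            residue_id = ids.pop() if len(ids) == 1 else "residue"
        weights = [
            p.counts.n_pure if p.counts is not None else 1.0 for p in points
        ]
        return cls(
            ph=[p.ph for p in points],
            fraction=[p.fraction_deprot for p in points],
            weights=weights,
            residue_id=residue_id,
        )

    @classmethod
    def from_records(
        cls,
        records_by_ph: Mapping[float, pd.DataFrame | Iterable[TitrationRecord]],
        cutoffs: StateCutoffs = StateCutoffs(),
        residue_id: str | None = None,
    ) -> "TitrationModel":
        return cls.from_points(titration_points(records_by_ph, cutoffs), residue_id)

    def fit(
        self,
        weighted: bool = False,
        pka_bounds: tuple[float, float] = (-10.0, 24.0),
        hill_bounds: tuple[float, float] = (1e-3, 10.0),
    ) -> TitrationResults:
        """Bounded nonlinear least squares on (pKa, n).

        Initialisation: pKa at the pH of the point nearest S = 0.5 (grid
        midpoint if all points are saturated), n = 1.  Fully saturated data
        yield a one-sided bound, not a point estimate.
        """
        ph, frac = self.ph, self.fraction
        w = np.ones_like(frac)
        if weighted:
            if self.weights is None:
                raise ValueError("weighted fit requested but no weights supplied")
            w = np.sqrt(self.weights / np.mean(self.weights))

        if np.all(frac > 0.95):
            # deprotonated over the whole grid: midpoint below the grid
            return self._saturated_result(PhRangeFlag.BELOW_GRID, float(np.min(ph)))
        if np.all(frac < 0.05):
            return self._saturated_result(PhRangeFlag.ABOVE_GRID, float(np.max(ph)))

        x0_pka = float(ph[np.argmin(np.abs(frac - 0.5))])
        x0 = np.array([np.clip(x0_pka, *pka_bounds), 1.0])

        def residuals(theta):
            return w * (hill_curve(ph, theta[0], theta[1]) - frac)

        sol = least_squares(
            residuals,
            x0,
            bounds=([pka_bounds[0], hill_bounds[0]], [pka_bounds[1], hill_bounds[1]]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        pka_hat, n_hat = float(sol.x[0]), float(sol.x[1])
        resid_norm = float(np.linalg.norm(sol.fun))
        pka_se, n_se = self._stderr(sol)
        return TitrationResults(
            residue_id=self.residue_id,
            pka=pka_hat,
            hill_n=n_hat,
            residual_norm=resid_norm,
            converged=bool(sol.success),
            ph_range_flag=PhRangeFlag.IN_RANGE,
            pka_stderr=pka_se,
            hill_stderr=n_se,
            n_points=int(ph.size),
            ph=ph.copy(),
            fraction=frac.copy(),
            weights=None if self.weights is None else self.weights.copy(),
        )

    def _saturated_result(
        self, flag: PhRangeFlag, bound: float
    ) -> TitrationResults:
        return TitrationResults(
            residue_id=self.residue_id,
            pka=bound,
            hill_n=math.nan,
            residual_norm=math.nan,
            converged=False,
            ph_range_flag=flag,
            n_points=int(self.ph.size),
            ph=self.ph.copy(),
            fraction=self.fraction.copy(),
        )

    @staticmethod
    def _stderr(sol) -> tuple[float, float]:
        m, k = sol.fun.size, 2
        if m <= k:
            return math.nan, math.nan
        dof = m - k
        s2 = 2.0 * sol.cost / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        except np.linalg.LinAlgError:
            return math.nan, math.nan
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        return float(se[0]), float(se[1])


# spec-level alias: a "TitrationFit" is the results object
TitrationFit = TitrationResults


def fit_titration_curve(
    points: Sequence[TitrationPoint],
    residue_id: str | None = None,
    weighted: bool = False,
) -> TitrationResults:
    """Fit the Hill/Henderson–Hasselbalch curve to per-pH fractions."""
    return TitrationModel.from_points(points, residue_id).fit(weighted=weighted)


# --------------------------------------------------------------------------
# reference pKa table and shifts
# --------------------------------------------------------------------------

_RESTYPE_SYNONYMS = {
    "ASH": "ASP",
    "GLH": "GLU",
    "HSD": "HIS",
    "HSE": "HIS",
    "HSP": "HIS",
    "HID": "HIS",
    "HIE": "HIS",
    "HIP": "HIS",
}


def residue_type(residue_id: str) -> str:
    """'ASP16' -> 'ASP'; CHARMM tautomer names are folded to PDB types."""
    letters = "".join(ch for ch in residue_id if ch.isalpha()).upper()
    return _RESTYPE_SYNONYMS.get(letters, letters)


@dataclass(frozen=True)
class ReferencePKaTable:
    """Model-pentapeptide reference pKa values per residue type.

    The defaults are editable placeholders for the standard model-compound
    set; load site-specific values from YAML for production analyses.
    """

    values: Mapping[str, float]

    @classmethod
    def default(cls) -> "ReferencePKaTable":
        return cls(values={"ASP": 4.0, "GLU": 4.4, "HIS": 6.5})

    @classmethod
    def from_yaml(cls, path) -> "ReferencePKaTable":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"reference pKa file {path} must map residue type -> pKa")
        return cls(values={str(k).upper(): float(v) for k, v in raw.items()})

    def get(self, residue_id: str) -> float:
        rtype = residue_type(residue_id)
        try:
            return float(self.values[rtype])
        except KeyError:
            raise KeyError(
                f"no reference pKa for residue type {rtype!r} (from {residue_id!r}); "
                f"known types: {sorted(self.values)}"
            ) from None


def pka_shift(fit: TitrationResults, reference: ReferencePKaTable) -> float:
    """ΔpKa = fitted pKa − reference pKa of the residue type.

    Positive when the environment raises the pKa (stabilised protonated
    form), negative when it lowers it (e.g. a salt bridge stabilising the
    carboxylate).
    """
    if not fit.converged:
        raise ValueError(
            f"fit for {fit.residue_id!r} did not converge "
            f"(flag {fit.ph_range_flag.value}); ΔpKa undefined"
        )
    return fit.pka - reference.get(fit.residue_id)
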