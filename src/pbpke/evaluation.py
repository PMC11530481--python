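"""Model evaluation: volatility screen, R^2 statistics, model comparison tables.

The screen classifies a chemical as volatile when its experimental mass
balance (percentage recovery of the applied dose across all measured
compartments, excluding the atmosphere) falls below a threshold — the
shortfall is attributed to evaporation.  Predicted "mass loss" for
atmosphere comparisons is 100 - recovery on the observed side and the
evaporated (atmosphere) percentage on the predicted side.

R^2 is reported in two conventions because the literature rarely states
which it uses: the squared Pearson correlation (scale/offset invariant,
the default) and the coefficient of determination about the identity line,
1 - SS_res/SS_tot with residuals taken against y = x (penalizes bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedStatisticError

__all__ = [
    "MassBalanceRecord",
    "ScreenResult",
    "volatility_screen",
    "r_squared",
    "compare_models",
    "observed_mass_loss",
]

#: Compartment columns expected in prediction/observation tables.
COMPARTMENT_COLUMNS = ["atmosphere", "vehicle", "sc", "ve", "dermis", "rf"]


@dataclass(frozen=True)
class MassBalanceRecord:
    """Experimental mass balance of one chemical, in % of applied dose.

    ``recovery`` is the sum of the recovered compartments (atmosphere/mass
    loss excluded).  Standard deviations are optional, keyed by compartment.
    """

    chemical: str
    recovery: float | None = None
    vehicle: float | None = None
    sc: float | None = None
    ve: float | None = None
    dermis: float | None = None
    rf: float | None = None
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("recovery", "vehicle", "sc", "ve", "dermis", "rf"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ConfigurationError(
                    f"{self.chemical}: {name} must be >= 0 %, got {v}"
                )

    @property
    def mass_loss(self) -> float | None:
        """Observed evaporative loss, % of dose: 100 - recovery."""
        return None if self.recovery is None else 100.0 - self.recovery


@dataclass
class ScreenResult:
    volatile: list[MassBalanceRecord]
    non_volatile: list[MassBalanceRecord]
    flagged: list[MassBalanceRecord]     # missing recovery; excluded


def volatility_screen(
    records: list[MassBalanceRecord], threshold: float = 90.0
) -> ScreenResult:
    """Partition records into volatile (recovery < threshold) / non-volatile.

    Records without a recovery value are flagged and excluded with a
    warning.  Input order is preserved within each partition.
    """
    volatile, non_volatile, flagged = [], [], []
    for rec in records:
        if rec.recovery is None:
            flagged.append(rec)
        elif rec.recovery < threshold:
            volatile.append(rec)
        else:
            non_volatile.append(rec)
    if flagged:
        warnings.warn(
            f"{len(flagged)} record(s) missing recovery excluded from the "
            f"volatility screen: {[r.chemical for r in flagged]}",
            stacklevel=2,
        )
    return ScreenResult(volatile, non_volatile, flagged)


def r_squared(predicted, observed, method: str = "pearson") -> float:
    """Coefficient of determination between predictions and observations.

    ``pearson`` (default): squared Pearson correlation — invariant to any
    affine rescaling of either vector.  ``identity``: 1 - SS_res/SS_tot
    with residuals measured against the identity line, so a biased but
    perfectly correlated prediction scores below 1 (and can go negative).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError(f"predicted/observed must be equal-length 1-D, got {p.shape}, {o.shape}")
    if p.size < 3:
        raise ValueError(f"need at least 3 points, got {p.size}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(o))):
        raise ValueError("non-finite values in input")

    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if method == "pearson":
        var_p = float(np.sum((p - p.mean()) ** 2))
        if var_p == 0.0 or ss_tot == 0.0:
            raise UndefinedStatisticError("zero variance: Pearson R^2 undefined")
        cov = float(np.sum((p - p.mean()) * (o - o.mean())))
        return cov**2 / (var_p * ss_tot)
    if method == "identity":
        if ss_tot == 0.0:
            raise UndefinedStatisticError("zero variance in observations")
        return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot
    raise ValueError(f"unknown method {method!r}; expected 'pearson' or 'identity'")


def observed_mass_loss(records: list[MassBalanceRecord]) -> pd.DataFrame:
    """Observed atmosphere table (chemical, mass_loss %), skipping missing recoveries."""
    rows = [
        (r.chemical, r.mass_loss) for r in records if r.recovery is not None
    ]
    return pd.DataFrame(rows, columns=["chemical", "mass_loss"])


def _check_panel(frames: dict[str, pd.DataFrame]) -> list[str]:
    sets = {name: set(df["chemical"]) for name, df in frames.items()}
    ref = sets["observations"]
    problems = []
    for name, s in sets.items():
        missing = ref - s
        extra = s - ref
        if missing:
            problems.append(f"{name} missing {sorted(missing)}")
        if extra:
            problems.append(f"{name} has extra {sorted(extra)}")
    if problems:
        raise ConfigurationError("panel mismatch: " + "; ".join(problems))
    return sorted(ref)


def compare_models(
    results_pbpk: pd.DataFrame,
    results_pbpke: pd.DataFrame,
    observations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-compartment R^2 of each model against observations.

    Inputs are tables with a ``chemical`` column plus compartment percentage
    columns (``atmosphere, vehicle, sc, ve, dermis, rf``; a missing
    ``dermal_delivery`` is derived as ve + dermis + rf).  The atmosphere row
    is reported only for the evaporation model — the no-evaporation model
    predicts no mass loss, so the statistic is undefined there.

    Returns a table with rows per compartment and columns
    ``r2_pbpk, r2_pbpke, r2_pbpk_identity, r2_pbpke_identity, n``.
    """
    frames = {
        "pbpk": results_pbpk.copy(),
        "pbpke": results_pbpke.copy(),
        "observations": observations.copy(),
    }
    for name, df in frames.items():
        if "chemical" not in df.columns:
            raise ConfigurationError(f"{name} table lacks a 'chemical' column")
        if "dermal_delivery" not in df.columns and {"ve", "dermis", "rf"} <= set(df.columns):
            df["dermal_delivery"] = df["ve"] + df["dermis"] + df["rf"]
        frames[name] = df.set_index("chemical")
    panel = _check_panel({k: v.reset_index() for k, v in frames.items()})

    compartments = COMPARTMENT_COLUMNS + ["dermal_delivery"]
    rows = []
    for comp in compartments:
        obs_has = comp in frames["observations"].columns
        entry = {"compartment": comp, "n": np.nan,
                 "r2_pbpk": np.nan, "r2_pbpke": np.nan,
                 "r2_pbpk_identity": np.nan, "r2_pbpke_identity": np.nan}
        if obs_has:
            obs = frames["observations"].loc[panel, comp].astype(float)
            mask = obs.notna()
            entry["n"] = int(mask.sum())
            for model in ("pbpk", "pbpke"):
                if comp == "atmosphere" and model == "pbpk":
                    continue    # no evaporation pathway: undefined
                if comp not in frames[model].columns:
                    continue
                pred = frames[model].loc[panel, comp].astype(float)[mask]
                try:
                    entry[f"r2_{model}"] = r_squared(pred.values, obs[mask].values)
                    entry[f"r2_{model}_identity"] = r_squared(
                        pred.values, obs[mask].values, method="identity"
                    )
                except UndefinedStatisticError:
                    pass
        rows.append(entry)
    return pd.DataFrame(rows).set_index("compartment")
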