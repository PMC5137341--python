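"""Stem-diameter and above-ground-biomass allometry.

Two models form the statistical core of the pipeline:

* the DBH model ``DBH = eps * H^rho * (1 + theta * CA)`` predicting stem
  diameter (cm) from crown height H (m) and crown area CA (m2), fitted by
  nonlinear median quantile regression (tau = 0.5), which is less sensitive
  to the strong heteroscedasticity of diameter-height data than least
  squares;
* the AGB model ``AGB = alpha * WD^beta * (DBH - d0)^gamma * H^delta``
  giving tree biomass (kg) from DBH (cm), height (m) and species wood
  density WD (g/cm3).

Carbon per tree is biomass times a carbon fraction (0.5 for conifers, 0.48
for angiosperms by default).

The packaged DBH coefficient table (``data/dbh_coefficients_alpine.csv``)
holds fits for an Alpine conifer stand; the packaged AGB table is a
clearly-labelled synthetic placeholder (regional stem-volume tables are not
redistributable) meant to be replaced by the user's own species table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

CARBON_FRACTION = {"conifer": 0.5, "angiosperm": 0.48}


@dataclass
class DbhCoefficients:
    """Per-species-group coefficients of the DBH model (one row per group)."""

    table: pd.DataFrame  # columns: species, epsilon, rho, theta[, se_*, rmse_cm, n]

    def __post_init__(self) -> None:
        required = {"species", "epsilon", "rho", "theta"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DBH coefficient table missing {sorted(missing)}")
        if (self.table["epsilon"] <= 0).any() or (self.table["rho"] <= 0).any():
            raise ValueError("epsilon and rho must be positive")

    def row(self, species: str | None) -> pd.Series:
        t = self.table.set_index("species")
        if species is not None and species in t.index:
            return t.loc[species]
        if "All" in t.index:
            return t.loc["All"]
        raise KeyError(f"no coefficients for species {species!r} and no 'All' row")

    @classmethod
    def from_csv(cls, path) -> "DbhCoefficients":
        return cls(pd.read_csv(path))

    @classmethod
    def packaged_alpine(cls) -> "DbhCoefficients":
        with resources.files("canopycarbon.data").joinpath(
                "dbh_coefficients_alpine.csv").open() as fh:
            return cls(pd.read_csv(fh))


@dataclass
class AgbCoefficients:
    """Per-species AGB coefficients, wood densities and carbon fractions."""

    table: pd.DataFrame  # species, alpha, beta, gamma, delta, d0, wd, carbon_fraction, group

    def __post_init__(self) -> None:
        required = {"species", "alpha", "beta", "gamma", "delta", "d0", "wd",
                    "carbon_fraction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"AGB coefficient table missing {sorted(missing)}")
        t = self.table
        if (t["wd"] <= 0).any() or (t["gamma"] <= 0).any():
            raise ValueError("wood density and gamma must be positive")
        if ((t["carbon_fraction"] <= 0) | (t["carbon_fraction"] >= 1)).any():
            raise ValueError("carbon_fraction must be in (0, 1)")

    def row(self, species: str | None) -> pd.Series:
        t = self.table.set_index("species")
        if species is not None and species in t.index:
            return t.loc[species]
        if "All" in t.index:
            return t.loc["All"]
        raise KeyError(f"no AGB coefficients for species {species!r}")

    @classmethod
    def from_csv(cls, path) -> "AgbCoefficients":
        return cls(pd.read_csv(path))

    @classmethod
    def packaged_synthetic(cls) -> "AgbCoefficients":
        """Synthetic placeholder table; replace with a regional species table."""
        with resources.files("canopycarbon.data").joinpath(
                "agb_coefficients_synthetic.csv").open() as fh:
            return cls(pd.read_csv(fh))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def dbh_model(h_m, ca_m2, epsilon: float, rho: float, theta: float):
    """DBH (cm) = epsilon * H^rho * (1 + theta * CA)."""
    return epsilon * np.power(h_m, rho) * (1.0 + theta * np.asarray(ca_m2))


def predict_dbh(h_m: float, ca_m2: float, coeffs: DbhCoefficients,
                species: str | None = None) -> float:
    """Predict stem diameter (cm) from crown height and crown area."""
    if np.any(np.asarray(h_m) <= 0):
        raise ValueError("height must be positive")
    if np.any(np.asarray(ca_m2) < 0):
        raise ValueError("crown area must be non-negative")
    row = coeffs.row(species)
    return float(dbh_model(h_m, ca_m2, row["epsilon"], row["rho"], row["theta"]))


def agb_tree(dbh_cm: float, h_m: float, coeffs: AgbCoefficients,
             species: str | None = None) -> float:
    """AGB (kg) = alpha * WD^beta * (DBH - d0)^gamma * H^delta.

    Stems at or below the allometry offset d0 get AGB 0 with a warning.
    """
    if h_m <= 0:
        raise ValueError("height must be positive")
    row = coeffs.row(species)
    if dbh_cm <= row["d0"]:
        logger.warning("DBH %.1f cm <= d0 %.1f cm; AGB set to 0", dbh_cm, row["d0"])
        return 0.0
    return float(row["alpha"] * row["wd"] ** row["beta"]
                 * (dbh_cm - row["d0"]) ** row["gamma"] * h_m ** row["delta"])


def carbon_tree(agb_kg: float, group: str = "conifer",
                fractions: dict[str, float] | None = None) -> float:
    """Carbon (kg) = AGB * carbon fraction of the species group."""
    if agb_kg < 0:
        raise ValueError("AGB must be non-negative")
    fractions = fractions or CARBON_FRACTION
    if group not in fractions:
        raise KeyError(f"unknown species group {group!r}; expected one of "
                       f"{sorted(fractions)}")
    return agb_kg * fractions[group]


# ---------------------------------------------------------------------------
# quantile-regression fitting of the DBH model
# ---------------------------------------------------------------------------


def _pinball(resid: np.ndarray, tau: float) -> np.ndarray:
    return np.where(resid >= 0, tau * resid, (tau - 1.0) * resid)


def _smoothed_loss(params: np.ndarray, h, ca, dbh, tau: float, eps: float) -> float:
    log_eps, rho, theta = params
    pred = dbh_model(h, ca, np.exp(log_eps), rho, theta)
    r = dbh - pred
    # smooth |.|-type approximation of the pinball loss
    smooth_abs = np.sqrt(r * r + eps * eps) - eps
    return float(np.sum(0.5 * smooth_abs + (tau - 0.5) * r))


def _fit_once(h, ca, dbh, tau: float) -> tuple[np.ndarray, float]:
    """Multi-start smoothed optimization followed by exact-loss polishing."""
    starts = []
    # data-driven starts from log-linear regression at several theta guesses
    for theta0 in (0.0, 0.005, 0.02, 0.05):
        with np.errstate(divide="ignore", invalid="ignore"):
            yy = np.log(dbh) - np.log1p(theta0 * ca)
        A = np.column_stack([np.ones_like(h), np.log(h)])
        beta, *_ = np.linalg.lstsq(A, yy, rcond=None)
        starts.append((beta[0], beta[1], theta0))
    for eps0, rho0 in ((np.log(1.0), 1.0), (np.log(5.0), 0.5)):
        starts.append((eps0, rho0, 0.01))
        starts.append((eps0, rho0, 0.0))

    best = None
    for s in starts:
        params = np.asarray(s, dtype=float)
        for eps in (1.0, 0.1, 0.01):
            res = optimize.minimize(
                _smoothed_loss, params, args=(h, ca, dbh, tau, eps),
                method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
            params = res.x
        exact = float(np.sum(_pinball(
            dbh - dbh_model(h, ca, np.exp(params[0]), params[1], params[2]), tau)))
        if best is None or exact < best[1]:
            best = (params, exact)
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError("DBH model fit failed to converge from all starts")
    return best


def fit_dbh_model(h_m, ca_m2, dbh_cm, tau: float = 0.5, n_boot: int = 200,
                  seed: int = 0, species=None, n_min: int = 100) -> DbhCoefficients:
    """Fit the DBH model by nonlinear quantile regression.

    Minimizes the tau-pinball loss of ``DBH - eps*H^rho*(1+theta*CA)`` with
    a smoothed multi-start optimizer (smoothing parameter annealed toward
    the exact loss).  Returns a coefficient table with a pooled ``All`` row
    and species-specific rows for groups with at least ``n_min`` samples,
    each with bootstrap standard errors (``n_boot`` resamples, seeded) and
    the fit RMSE in cm.  Set ``n_boot=0`` to skip the bootstrap.
    """
    h = np.asarray(h_m, dtype=float)
    ca = np.asarray(ca_m2, dtype=float)
    dbh = np.asarray(dbh_cm, dtype=float)
    if h.size < 10:
        raise ValueError("need at least 10 (H, CA, DBH) triples")
    if (h <= 0).any() or (ca < 0).any() or (dbh <= 0).any():
        raise ValueError("H, DBH must be positive and CA non-negative")

    groups: dict[str, np.ndarray] = {"All": np.arange(h.size)}
    if species is not None:
        sp = np.asarray(species)
        for s in np.unique(sp):
            idx = np.flatnonzero(sp == s)
            if idx.size >= n_min:
                groups[str(s)] = idx

    rng = np.random.default_rng(seed)
    rows = []
    for name, idx in groups.items():
        params, _ = _fit_once(h[idx], ca[idx], dbh[idx], tau)
        eps_hat, rho_hat, theta_hat = np.exp(params[0]), params[1], params[2]
        pred = dbh_model(h[idx], ca[idx], eps_hat, rho_hat, theta_hat)
        rmse = float(np.sqrt(np.mean((dbh[idx] - pred) ** 2)))
        ses = (np.nan, np.nan, np.nan)
        if n_boot > 0:
            boots = np.empty((n_boot, 3))
            for b in range(n_boot):
                bi = rng.integers(0, idx.size, idx.size)
                p, _ = _fit_once(h[idx][bi], ca[idx][bi], dbh[idx][bi], tau)
                boots[b] = (np.exp(p[0]), p[1], p[2])
            ses = tuple(boots.std(axis=0, ddof=1))
        rows.append({"species": name, "epsilon": eps_hat, "rho": rho_hat,
                     "theta": theta_hat, "se_epsilon": ses[0], "se_rho": ses[1],
                     "se_theta": ses[2], "rmse_cm": rmse, "n": int(idx.size)})
    return DbhCoefficients(pd.DataFrame(rows))
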