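"""Computational Arrhenius analysis of replicate activation barriers.

Replicate activation free energies dG(T) collected over a temperature
grid are averaged per temperature and regressed as dG/T against 1/T:
the slope is the activation enthalpy dH (kcal/mol) and the negative
intercept the activation entropy dS (in entropy units, cal/(mol K)).
Parameter uncertainties come from a nonparametric bootstrap over
replicates within each temperature.  Free energies convert to TST
rates via k = kappa * (kB T / h) * exp(-dG / RT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import KB_OVER_H, R_GAS

#: default grid: eight evenly spaced temperatures spanning 275-310 K
DEFAULT_TEMPERATURES = np.linspace(275.0, 310.0, 8)


class ArrheniusError(ValueError):
    """Invalid barrier table or unfittable temperature grid."""


def make_barrier_table(records) -> pd.DataFrame:
    """Normalise records into a (temperature, replicate, barrier) table."""
    df = pd.DataFrame(records, columns=["temperature", "replicate", "barrier"]) \
        if not isinstance(records, pd.DataFrame) else records.copy()
    missing = {"temperature", "replicate", "barrier"} - set(df.columns)
    if missing:
        raise ArrheniusError(f"barrier table lacks columns: {sorted(missing)}")
    if df.empty:
        raise ArrheniusError("barrier table is empty")
    dup = df.duplicated(subset=["temperature", "replicate"])
    if dup.any():
        raise ArrheniusError("replicate ids must be unique within a temperature")
    return df


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Per-temperature mean, SEM (= sd/sqrt(n), NaN for n = 1) and n."""
    table = make_barrier_table(table)
    grouped = table.groupby("temperature")["barrier"]
    out = grouped.agg(mean="mean", n="count")
    sd = grouped.std(ddof=1)  # NaN when n == 1: SEM undefined, not 0
    out["sem"] = sd / np.sqrt(out["n"])
    return out.reset_index()[["temperature", "mean", "sem", "n"]]


def _ols_dh_ds(temps: np.ndarray, means: np.ndarray):
    """OLS of dG/T on 1/T -> (dH kcal/mol, dS e.u.)."""
    x = 1.0 / temps
    y = means / temps
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(-intercept * 1000.0)


@dataclass
class ArrheniusFit:
    """Activation parameters from a computational Arrhenius plot.

    ``dH`` in kcal/mol, ``dS`` in e.u. = cal/(mol K); the fitted line is
    ``dG(T) = dH - T * dS / 1000`` at every temperature.
    """

    dH: float
    dS: float
    dH_se: float
    dS_se: float
    per_temperature: pd.DataFrame
    n_bootstrap: int
    reference_temperature: float = 300.0

    def predict_dG(self, temperature) -> float:
        return self.dH - np.asarray(temperature) * self.dS / 1000.0

    def tds(self, temperature: float | None = None) -> float:
        t = self.reference_temperature if temperature is None else temperature
        return t * self.dS / 1000.0

    def summary(self) -> pd.DataFrame:
        """One-row activation-parameter table at the reference temperature,
        mirroring the conventional dG / dH / TdS column order."""
        t = self.reference_temperature
        return pd.DataFrame([{
            "T_ref": t, "dG": float(self.predict_dG(t)), "dH": self.dH,
            "TdS": self.tds(), "dH_se": self.dH_se, "dS_se": self.dS_se,
        }])


def fit(table: pd.DataFrame, n_bootstrap: int = 2000, seed: int = 0,
        reference_temperature: float = 300.0) -> ArrheniusFit:
    """Fit dH and dS from a replicate barrier table.

    Per-temperature means feed an unweighted OLS of dG/T on 1/T; the
    standard errors are the spread of refits over ``n_bootstrap``
    resamples of the replicates within each temperature (seeded).
    """
    agg = aggregate(table)
    temps = agg["temperature"].to_numpy(dtype=float)
    if temps.size < 2:
        raise ArrheniusError("need at least two distinct temperatures to fit")
    dh, ds = _ols_dh_ds(temps, agg["mean"].to_numpy())

    dh_se = ds_se = np.nan
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        table = make_barrier_table(table)
        groups = [table.loc[table["temperature"] == t, "barrier"].to_numpy()
                  for t in temps]
        boot_means = np.empty((n_bootstrap, temps.size))
        for j, vals in enumerate(groups):
            idx = rng.integers(0, vals.size, size=(n_bootstrap, vals.size))
            m = vals[idx].mean(axis=1)
            if vals.size > 1:
                # finite-sample correction: resampled means scatter with the
                # ddof=0 variance; rescale deviations to the unbiased estimate
                c = np.sqrt(vals.size / (vals.size - 1.0))
                m = vals.mean() + (m - vals.mean()) * c
            boot_means[:, j] = m
        x = 1.0 / temps
        y = boot_means / temps
        xc = x - x.mean()
        slopes = (y @ xc) / (xc @ xc)
        intercepts = y.mean(axis=1) - slopes * x.mean()
        dh_se = float(np.std(slopes, ddof=1))
        ds_se = float(np.std(intercepts * 1000.0, ddof=1))

    return ArrheniusFit(dH=dh, dS=ds, dH_se=dh_se, dS_se=ds_se,
                        per_temperature=agg, n_bootstrap=int(n_bootstrap),
                        reference_temperature=float(reference_temperature))


def gibbs(dH: float, TdS: float) -> float:
    """dG = dH - TdS with the entropic term supplied as T * dS (kcal/mol)."""
    if not (np.isfinite(dH) and np.isfinite(TdS)):
        raise ArrheniusError("gibbs requires finite inputs")
    return float(dH - TdS)


def tst_rate(dG: float, temperature: float, kappa: float = 1.0) -> float:
    """Transition-state-theory rate kappa * (kB T / h) * exp(-dG/RT), 1/s.

    kappa is the transmission coefficient (default 1)."""
    if temperature <= 0:
        raise ArrheniusError("temperature must be positive")
    if not 0.0 < kappa <= 1.0:
        raise ArrheniusError("kappa must lie in (0, 1]")
    return float(kappa * KB_OVER_H * temperature
                 * np.exp(-dG / (R_GAS * temperature)))


def fold_change(dG_a: float, dG_b: float, temperature: float = 300.0,
                rounded: bool = False):
    """Rate ratio k_a / k_b = exp((dG_b - dG_a) / RT) of two barriers.

    Satisfies fold(a, b) = 1 / fold(b, a).  With ``rounded`` the value
    is reported to the nearest integer, the convention used for
    headline k_cat comparisons."""
    if temperature <= 0:
        raise ArrheniusError("temperature must be positive")
    ratio = float(np.exp((dG_b - dG_a) / (R_GAS * temperature)))
    return round(ratio) if rounded else ratio
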