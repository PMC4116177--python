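"""Binding- and stability-assay analytics.

Three pieces of mathematics validate a receptor redesign:

* **Fluorescence polarization.**  ``P = (F∥ − F⊥)/(F∥ + F⊥)`` from the two
  polarized emission intensities of a tracer; displacement of the tracer by
  a competitor lowers P.  (Note: the signal measured this way is often
  called *anisotropy* elsewhere; the formula implemented is exactly the
  ratio above, and we call it polarization throughout.)

* **One-site competition fit.**  P against competitor concentration is fit
  in log10-concentration space with a logistic,
  ``y = min + (max − min) / (1 + 10^(hill · (log10 x − logIC50)))``.
  In three-parameter mode the hill slope is fixed at 1; in four-parameter
  mode it is free.

* **Two-state thermal melt fit.**  CD signal at 222 nm against temperature
  with a Boltzmann sigmoid,
  ``y(T) = unfolded + (folded − unfolded) / (1 + exp((T − Tm)/width))``,
  whose midpoint is the melting temperature Tm.

Fold-change reports compare IC50 values between receptor variants per
ligand, classifying a difference as real only when the ±1·SE intervals do
not overlap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "AnisotropyReading",
    "CompetitionCurve",
    "CompetitionFit",
    "MeltCurve",
    "MeltFit",
    "AffinityTable",
    "FoldChangeEntry",
    "polarization",
    "competition_model",
    "fit_competition",
    "melt_model",
    "fit_melt",
    "fold_change",
    "load_published_affinities",
    "read_plate_table",
    "read_melt_table",
]

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class AnisotropyReading:
    """A pair of polarized fluorescence intensities (arbitrary units)."""

    f_parallel: float
    f_perpendicular: float

    def __post_init__(self) -> None:
        if self.f_parallel < 0 or self.f_perpendicular < 0:
            raise ValueError("fluorescence intensities must be ≥ 0")
        if self.f_parallel == 0 and self.f_perpendicular == 0:
            raise ValueError("both intensities are zero")


def polarization(reading: AnisotropyReading | tuple[float, float]) -> float:
    """P = (F∥ − F⊥) / (F∥ + F⊥), dimensionless in [−1, 1]."""
    if not isinstance(reading, AnisotropyReading):
        reading = AnisotropyReading(*reading)
    return (reading.f_parallel - reading.f_perpendicular) / (
        reading.f_parallel + reading.f_perpendicular
    )


@dataclass
class CompetitionCurve:
    """Measured polarization vs competitor concentration for one pair."""

    concentrations: np.ndarray  # mol/L, strictly positive
    polarizations: np.ndarray
    ligand: str = ""
    receptor: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.polarizations = np.asarray(self.polarizations, dtype=float)
        if self.concentrations.shape != self.polarizations.shape:
            raise ValueError("concentration and polarization arrays differ in shape")
        if len(self.concentrations) < 5:
            raise ValueError("competition fitting needs ≥ 5 points")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")


@dataclass
class CompetitionFit:
    """Fitted one-site competition parameters (concentrations in mol/L)."""

    min: float
    max: float
    log_ic50: float
    hill: float
    standard_errors: dict[str, float]
    rss: float
    converged: bool
    mode: str = "three_param"
    n_points: int = 0

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50


def competition_model(
    log10_x: np.ndarray, lo: float, hi: float, log_ic50: float, hill: float = 1.0
) -> np.ndarray:
    return lo + (hi - lo) / (1.0 + 10.0 ** (hill * (log10_x - log_ic50)))


def fit_competition(
    curve: CompetitionCurve,
    mode: Literal["three_param", "four_param"] = "three_param",
) -> CompetitionFit:
    """Least-squares one-site competition fit in log10-concentration space.

    Non-convergence is reported through the ``converged`` flag, never as an
    exception.  Parameter standard errors come from the covariance of the
    fit (NaN when the covariance is singular).
    """
    if mode not in ("three_param", "four_param"):
        raise ValueError(f"unknown mode {mode!r}")
    n_params = 3 if mode == "three_param" else 4
    x = np.log10(curve.concentrations)
    y = curve.polarizations
    if len(y) < n_params + 1:
        raise ValueError(f"{mode} fit needs ≥ {n_params + 1} points")

    lo0, hi0 = float(np.min(y)), float(np.max(y))
    half = (lo0 + hi0) / 2.0
    order = np.argsort(x)
    log_ic50_0 = float(np.interp(half, y[order][::-1], x[order][::-1]))
    if not np.isfinite(log_ic50_0):
        log_ic50_0 = float(np.median(x))

    names = ["min", "max", "log_ic50"] + (["hill"] if n_params == 4 else [])
    if n_params == 3:
        f = lambda lx, lo, hi, lic: competition_model(lx, lo, hi, lic, 1.0)
        p0 = [lo0, hi0, log_ic50_0]
    else:
        f = competition_model
        p0 = [lo0, hi0, log_ic50_0, 1.0]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # covariance failures surface via `converged`
            popt, pcov = curve_fit(f, x, y, p0=p0, maxfev=20000)
        resid = y - f(x, *popt)
        rss = float(resid @ resid)
        with np.errstate(invalid="ignore"):
            ses = np.sqrt(np.diag(pcov))
        converged = bool(np.all(np.isfinite(popt)) and popt[1] > popt[0])
    except RuntimeError:
        popt = np.full(n_params, np.nan)
        ses = np.full(n_params, np.nan)
        rss = math.nan
        converged = False

    return CompetitionFit(
        min=float(popt[0]),
        max=float(popt[1]),
        log_ic50=float(popt[2]),
        hill=float(popt[3]) if n_params == 4 else 1.0,
        standard_errors=dict(zip(names, (float(s) for s in ses))),
        rss=rss,
        converged=converged,
        mode=mode,
        n_points=len(y),
    )


@dataclass
class MeltCurve:
    """CD-at-222-nm signal vs temperature for one receptor."""

    temperatures: np.ndarray  # °C, strictly increasing
    signals: np.ndarray
    receptor: str = ""
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.temperatures.shape != self.signals.shape:
            raise ValueError("temperature and signal arrays differ in shape")
        if len(self.temperatures) < 8:
            raise ValueError("melt fitting needs ≥ 8 points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any((self.temperatures < 0) | (self.temperatures > 120)):
            raise ValueError("temperatures outside [0, 120] °C")


@dataclass
class MeltFit:
    """Fitted two-state (Boltzmann sigmoid) unfolding parameters."""

    tm: float
    slope_width: float
    folded_baseline: float
    unfolded_baseline: float
    standard_errors: dict[str, float]
    rss: float
    converged: bool


def melt_model(
    t: np.ndarray, tm: float, width: float, folded: float, unfolded: float
) -> np.ndarray:
    return unfolded + (folded - unfolded) / (1.0 + np.exp((t - tm) / width))


def fit_melt(curve: MeltCurve) -> MeltFit:
    """Least-squares Boltzmann melt fit; midpoint Tm with its standard error.

    A successful fit places Tm inside the measured temperature range and has
    a positive transition width; anything else is flagged unconverged.
    """
    t = curve.temperatures
    y = curve.signals
    folded0 = float(np.mean(y[: max(3, len(y) // 10)]))
    unfolded0 = float(np.mean(y[-max(3, len(y) // 10):]))
    half = (folded0 + unfolded0) / 2.0
    crossing = np.nonzero(np.diff(np.sign(y - half)))[0]
    tm0 = float(t[crossing[0]]) if crossing.size else float(np.median(t))
    p0 = [tm0, 2.0, folded0, unfolded0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(melt_model, t, y, p0=p0, maxfev=20000)
        resid = y - melt_model(t, *popt)
        rss = float(resid @ resid)
        with np.errstate(invalid="ignore"):
            ses = np.sqrt(np.diag(pcov))
        tm, width = float(popt[0]), float(popt[1])
        converged = bool(
            np.all(np.isfinite(popt)) and width > 0 and t[0] <= tm <= t[-1]
        )
    except RuntimeError:
        popt = np.full(4, np.nan)
        ses = np.full(4, np.nan)
        rss = math.nan
        converged = False
    return MeltFit(
        tm=float(popt[0]),
        slope_width=float(popt[1]),
        folded_baseline=float(popt[2]),
        unfolded_baseline=float(popt[3]),
        standard_errors=dict(
            zip(["tm", "slope_width", "folded", "unfolded"], (float(s) for s in ses))
        ),
        rss=rss,
        converged=converged,
    )


# --- affinity table and fold change ----------------------------------------


@dataclass
class AffinityTable:
    """(receptor, ligand) → (IC50 value, standard error, unit)."""

    entries: dict[tuple[str, str], tuple[float, float, str]] = field(default_factory=dict)

    def add(self, receptor: str, ligand: str, ic50: float, se: float, unit: str) -> None:
        if ic50 <= 0 or se <= 0:
            raise ValueError("IC50 and SE must be positive")
        if unit not in _UNIT_SCALE:
            raise ValueError(f"unresolvable unit {unit!r}")
        self.entries[(receptor, ligand)] = (ic50, se, unit)

    def in_molar(self, receptor: str, ligand: str) -> tuple[float, float]:
        ic50, se, unit = self.entries[(receptor, ligand)]
        s = _UNIT_SCALE[unit]
        return ic50 * s, se * s

    def ligands_of(self, receptor: str) -> list[str]:
        return sorted(l for r, l in self.entries if r == receptor)

    def receptors(self) -> list[str]:
        return sorted({r for r, _ in self.entries})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AffinityTable":
        table = cls()
        for _, row in df.iterrows():
            table.add(row["receptor"], row["ligand"], float(row["ic50"]),
                      float(row["se"]), str(row["unit"]))
        return table


@dataclass(frozen=True)
class FoldChangeEntry:
    """IC50 ratio of a variant receptor over a reference for one ligand."""

    ligand: str
    reference_receptor: str
    variant_receptor: str
    fold: float  # IC50_variant / IC50_reference; < 1 = tighter binding
    direction: Literal["improved", "worsened", "ns"]


def fold_change(
    table: AffinityTable, reference_receptor: str, variant_receptor: str
) -> list[FoldChangeEntry]:
    """Per-ligand IC50 ratios (variant / reference) with a ±1·SE interval call.

    ``improved`` means the variant's interval lies entirely below the
    reference's (tighter binding), ``worsened`` entirely above, ``ns``
    otherwise.  Units are normalized to mol/L before division.
    """
    shared = sorted(
        set(table.ligands_of(reference_receptor)) & set(table.ligands_of(variant_receptor))
    )
    if not shared:
        raise ValueError(
            f"{reference_receptor!r} and {variant_receptor!r} share no ligands"
        )
    out = []
    for ligand in shared:
        ref, ref_se = table.in_molar(reference_receptor, ligand)
        var, var_se = table.in_molar(variant_receptor, ligand)
        if variant_receptor == reference_receptor:
            direction: str = "ns"
        elif var + var_se < ref - ref_se:
            direction = "improved"
        elif var - var_se > ref + ref_se:
            direction = "worsened"
        else:
            direction = "ns"
        out.append(
            FoldChangeEntry(
                ligand=ligand,
                reference_receptor=reference_receptor,
                variant_receptor=variant_receptor,
                fold=var / ref,
                direction=direction,  # type: ignore[arg-type]
            )
        )
    return out


def load_published_affinities() -> AffinityTable:
    """Reported competitive-binding IC50 values (±SE) for wt and mutant ERα LBD.

    Six EDC ligands × three receptors, from the published four-replicate
    competitive fluorescence-polarization assay; inputs for fold-change
    analysis, not recomputable quantities.
    """
    text = resources.files("erdesign").joinpath("data/published_ic50.tsv").read_text()
    df = pd.read_csv(pd.io.common.StringIO(text), sep="\t", comment="#")
    return AffinityTable.from_frame(df)


# --- plate-table input ------------------------------------------------------


def read_plate_table(source) -> list[CompetitionCurve]:
    """Read a delimited plate table into competition curves.

    Expected columns: ``receptor, ligand, concentration, unit`` plus either
    ``F_parallel, F_perpendicular`` (polarization computed here) or a
    pre-computed ``P`` column.  Zero-concentration control wells are
    excluded from the curves (log of zero is undefined); they remain in the
    returned frame for inspection via the ``controls`` attribute.
    """
    df = pd.read_csv(source, sep=None, engine="python")
    required = {"receptor", "ligand", "concentration", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table lacks columns {sorted(missing)}")
    if "P" not in df.columns:
        if not {"F_parallel", "F_perpendicular"} <= set(df.columns):
            raise ValueError("plate table needs either P or F_parallel/F_perpendicular")
        df["P"] = [
            polarization((fp, fq))
            for fp, fq in zip(df["F_parallel"], df["F_perpendicular"])
        ]
    df["conc_molar"] = [
        float(c) * _UNIT_SCALE[str(u)] for c, u in zip(df["concentration"], df["unit"])
    ]
    curves = []
    controls = df[df["conc_molar"] == 0.0]
    df = df[df["conc_molar"] > 0.0]
    for (receptor, ligand), grp in df.groupby(["receptor", "ligand"], sort=True):
        grp = grp.sort_values("conc_molar")
        curves.append(
            CompetitionCurve(
                concentrations=grp["conc_molar"].to_numpy(),
                polarizations=grp["P"].to_numpy(),
                ligand=str(ligand),
                receptor=str(receptor),
            )
        )
    for c in curves:
        c.controls = controls  # type: ignore[attr-defined]
    return curves


def read_melt_table(source, receptor: str = "") -> MeltCurve:
    """Read a (temperature, signal) table into a :class:`MeltCurve`."""
    df = pd.read_csv(source, sep=None, engine="python")
    if not {"temperature", "signal"} <= set(df.columns):
        raise ValueError("melt table needs columns temperature, signal")
    df = df.sort_values("temperature")
    return MeltCurve(
        temperatures=df["temperature"].to_numpy(),
        signals=df["signal"].to_numpy(),
        receptor=receptor,
    )
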