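"""Thermodynamic 1:1 binding models and their fits.

Three related descriptions of single-site binding are implemented:

* :func:`bound_fraction` — the exact mass-balance ("quadratic") solution
  for the fraction of ligand bound at given totals and dissociation
  constant ``K_D``;
* :func:`wiseman_heats` — the heat-per-injection isotherm of an ITC
  titration with per-injection overflow dilution bookkeeping;
* :func:`anisotropy_model` — fluorescence anisotropy of a labelled probe
  as a population-weighted average of free and bound values.

Fits follow the Model -> fit() -> Results pattern: :class:`ITCModel` and
:class:`AnisotropyModel` are constructed from data and produce
:class:`ITCResults` / :class:`AnisotropyResults` carrying estimates,
standard errors and diagnostics.  ``K_D`` is optimised on a log10 scale
for stability and reported in linear uM.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd


class BindingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# closed-form models
# ---------------------------------------------------------------------------

def bound_fraction(l_total, p_total, kd):
    """Fraction of ligand bound at totals ``l_total``, ``p_total`` (uM).

    Exact single-site mass balance: with complex concentration C,
    ``C = ((K+L+P) - sqrt((K+L+P)^2 - 4 L P)) / 2`` and FB = C / L.
    At L -> 0 the limit ``P / (P + K)`` is used.  All arguments may be
    arrays (broadcast).
    """
    l_total = np.asarray(l_total, dtype=float)
    p_total = np.asarray(p_total, dtype=float)
    if np.any(l_total < 0) or np.any(p_total < 0) or kd <= 0:
        raise BindingError("concentrations must be >= 0 and K_D > 0")
    s = kd + l_total + p_total
    disc = np.maximum(s * s - 4.0 * l_total * p_total, 0.0)
    complex_conc = 0.5 * (s - np.sqrt(disc))
    with np.errstate(divide="ignore", invalid="ignore"):
        fb = np.where(l_total > 0, complex_conc / np.where(l_total > 0, l_total, 1.0),
                      p_total / (p_total + kd))
    out = np.clip(fb, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ITCSchedule:
    """Injection schedule of a fixed-volume (overflow) ITC cell."""

    cell_volume_uL: float = 164.0
    cell_conc_uM: float = 15.0       # binding-site macromolecule, as loaded
    syringe_conc_uM: float = 150.0
    injection_volume_uL: float = 2.0
    n_injections: int = 25
    temperature_C: float = 37.0

    def __post_init__(self):
        if min(self.cell_volume_uL, self.cell_conc_uM, self.syringe_conc_uM,
               self.injection_volume_uL) <= 0:
            raise BindingError("schedule quantities must be positive")
        if self.n_injections < 2:
            raise BindingError("need at least 2 injections")

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell concentrations (uM) of macromolecule and titrant after each
        injection, using the overflow convention: every injection of volume v
        dilutes existing contents by ``(1 - v/V0)`` and adds syringe material
        at ``c_syr * v / V0``."""
        d = 1.0 - self.injection_volume_uL / self.cell_volume_uL
        add = self.syringe_conc_uM * self.injection_volume_uL / self.cell_volume_uL
        m = np.empty(self.n_injections)
        x = np.empty(self.n_injections)
        m_cur, x_cur = self.cell_conc_uM, 0.0
        for i in range(self.n_injections):
            m_cur *= d
            x_cur = x_cur * d + add
            m[i], x[i] = m_cur, x_cur
        return m, x

    def molar_ratio(self) -> np.ndarray:
        m, x = self.totals()
        return x / m


def wiseman_heats(
    schedule: ITCSchedule,
    kd_uM: float,
    n: float,
    dh_kcal_mol: float,
    dilution_offset_uJ: float = 0.0,
) -> np.ndarray:
    """Predicted heats (uJ) per injection for a 1:1 isotherm.

    The cell heat content after injection i is ``Q(i) = dH * V0 * C(i)``
    where C is the complex concentration from the mass-balance quadratic
    with site concentration ``n * M_t(i)``.  The observed heat is the
    difference corrected for the complex carried out in the displaced
    volume: ``q_i = Q(i) - Q(i-1) * (1 - v/V0) + offset``.
    """
    if kd_uM <= 0 or n <= 0:
        raise BindingError("K_D and stoichiometry must be positive")
    m, x = schedule.totals()
    sites = n * m
    s = kd_uM + x + sites
    complex_conc = 0.5 * (s - np.sqrt(np.maximum(s * s - 4.0 * x * sites, 0.0)))
    # uM * uL = pmol; kcal/mol = 4184 J/mol -> pmol * kcal/mol = 4.184e-3 uJ
    q_cell = dh_kcal_mol * 4.184e-3 * complex_conc * schedule.cell_volume_uL
    d = 1.0 - schedule.injection_volume_uL / schedule.cell_volume_uL
    prev = np.concatenate([[0.0], q_cell[:-1]])
    return q_cell - prev * d + dilution_offset_uJ


def anisotropy_model(p_total, l_total, kd_uM, r_free, r_bound):
    """Anisotropy of the labelled species (total ``l_total``) at titrant
    totals ``p_total``: ``r = r_free + (r_bound - r_free) * FB``."""
    fb = bound_fraction(l_total, p_total, kd_uM)
    return r_free + (r_bound - r_free) * fb


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class ITCThermogram:
    schedule: ITCSchedule
    heats_uJ: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.heats_uJ = np.asarray(self.heats_uJ, dtype=float)
        if len(self.heats_uJ) != self.schedule.n_injections:
            raise BindingError("number of heats must equal number of injections")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection": np.arange(1, len(self.heats_uJ) + 1),
                "molar_ratio": self.schedule.molar_ratio(),
                "heat_uJ": self.heats_uJ,
            }
        )


@dataclass
class AnisotropySeries:
    probe_conc_uM: float
    titrant_conc_uM: np.ndarray
    anisotropy: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.titrant_conc_uM = np.asarray(self.titrant_conc_uM, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if len(self.titrant_conc_uM) != len(self.anisotropy):
            raise BindingError("concentration and anisotropy lists differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"titrant_uM": self.titrant_conc_uM, "anisotropy": self.anisotropy}
        )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class BindingFitResultBase:
    kd_uM: float
    kd_se: float
    rss: float
    success: bool
    flags: list[str]
    params: lmfit.Parameters

    @property
    def flagged(self) -> bool:
        return bool(self.flags)


@dataclass
class ITCResults(BindingFitResultBase):
    n: float = float("nan")
    n_se: float = float("nan")
    dh_kcal_mol: float = float("nan")
    dh_se: float = float("nan")
    dilution_offset_uJ: float = 0.0
    c_value: float = float("nan")
    model: "ITCModel | None" = None

    def summary(self) -> str:
        lines = [
            "ITC 1:1 binding fit",
            "-" * 46,
            f"K_D            {self.kd_uM:10.3g} +/- {self.kd_se:.2g} uM",
            f"stoichiometry  {self.n:10.3g} +/- {self.n_se:.2g}",
            f"dH             {self.dh_kcal_mol:10.3g} +/- {self.dh_se:.2g} kcal/mol",
            f"offset         {self.dilution_offset_uJ:10.3g} uJ",
            f"c value        {self.c_value:10.3g}",
            f"RSS            {self.rss:10.4g} uJ^2",
            f"converged      {self.success}",
        ]
        if self.flags:
            lines.append("flags          " + "; ".join(self.flags))
        return "\n".join(lines)


@dataclass
class AnisotropyResults(BindingFitResultBase):
    r_free: float = float("nan")
    r_free_se: float = float("nan")
    r_bound: float = float("nan")
    r_bound_se: float = float("nan")
    model: "AnisotropyModel | None" = None

    def summary(self) -> str:
        lines = [
            "Fluorescence anisotropy 1:1 binding fit",
            "-" * 46,
            f"K_D        {self.kd_uM:10.4g} +/- {self.kd_se:.3g} uM",
            f"r_free     {self.r_free:10.4g} +/- {self.r_free_se:.2g}",
            f"r_bound    {self.r_bound:10.4g} +/- {self.r_bound_se:.2g}",
            f"RSS        {self.rss:10.4g}",
            f"converged  {self.success}",
        ]
        if self.flags:
            lines.append("flags      " + "; ".join(self.flags))
        return "\n".join(lines)


def _kd_and_se(result: lmfit.minimizer.MinimizerResult) -> tuple[float, float]:
    p = result.params["log_kd"]
    kd = 10.0 ** p.value
    se = kd * np.log(10.0) * p.stderr if p.stderr is not None else float("nan")
    return kd, se


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class ITCModel:
    """Nonlinear least-squares fit of a Wiseman 1:1 isotherm.

    Parameters are (log10 K_D, n, dH, dilution offset).  The first
    injection is excluded from the residual by default (its effective
    volume is commonly compromised by diffusion from the syringe tip).
    """

    def __init__(
        self,
        thermogram: ITCThermogram,
        exclude_first: bool = True,
        fix_n: float | None = None,
        fit_offset: bool = True,
    ):
        if thermogram.schedule.n_injections < 5:
            raise BindingError("need >= 5 injections spanning the transition")
        self.thermogram = thermogram
        self.exclude_first = exclude_first
        self.fix_n = fix_n
        self.fit_offset = fit_offset

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        pred = wiseman_heats(
            self.thermogram.schedule,
            10.0 ** params["log_kd"].value,
            params["n"].value,
            params["dh"].value,
            params["offset"].value,
        )
        res = pred - self.thermogram.heats_uJ
        return res[1:] if self.exclude_first else res

    def _start_params(self) -> lmfit.Parameters:
        heats = self.thermogram.heats_uJ
        sched = self.thermogram.schedule
        dh0 = np.sum(heats) / (
            sched.cell_conc_uM * sched.cell_volume_uL * 4.184e-3
        )
        params = lmfit.Parameters()
        params.add("log_kd", value=0.0, min=-4.0, max=4.0)
        params.add("n", value=self.fix_n if self.fix_n is not None else 1.0,
                   min=0.05, max=10.0, vary=self.fix_n is None)
        params.add("dh", value=dh0 if abs(dh0) > 1e-6 else -1.0)
        params.add("offset", value=0.0, vary=self.fit_offset)
        return params

    def fit(self) -> ITCResults:
        out = lmfit.minimize(self._residual, self._start_params(), method="leastsq")
        kd, kd_se = _kd_and_se(out)
        sched = self.thermogram.schedule
        c_value = out.params["n"].value * sched.cell_conc_uM / kd
        flags = []
        if not out.success:
            flags.append("non-convergence")
        if not (0.5 <= c_value <= 5000.0):
            flags.append(f"c value {c_value:.3g} outside reliably fittable range")
        return ITCResults(
            kd_uM=kd,
            kd_se=kd_se,
            rss=float(np.sum(out.residual**2)),
            success=bool(out.success),
            flags=flags,
            params=out.params,
            n=out.params["n"].value,
            n_se=out.params["n"].stderr or float("nan"),
            dh_kcal_mol=out.params["dh"].value,
            dh_se=out.params["dh"].stderr or float("nan"),
            dilution_offset_uJ=out.params["offset"].value,
            c_value=c_value,
            model=self,
        )


class AnisotropyModel:
    """Nonlinear least-squares fit of a quadratic 1:1 anisotropy isotherm."""

    def __init__(self, series: AnisotropySeries):
        if len(series.titrant_conc_uM) < 5:
            raise BindingError("need >= 5 titrant concentrations")
        if not np.any(series.titrant_conc_uM == 0):
            raise BindingError("series must include a zero-titrant point")
        self.series = series

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        pred = anisotropy_model(
            self.series.titrant_conc_uM,
            self.series.probe_conc_uM,
            10.0 ** params["log_kd"].value,
            params["r_free"].value,
            params["r_bound"].value,
        )
        return pred - self.series.anisotropy

    def fit(self) -> AnisotropyResults:
        r = self.series.anisotropy
        params = lmfit.Parameters()
        params.add("log_kd", value=1.0, min=-4.0, max=5.0)
        params.add("r_free", value=float(r[np.argmin(self.series.titrant_conc_uM)]))
        params.add("r_bound", value=float(r[np.argmax(self.series.titrant_conc_uM)]))
        out = lmfit.minimize(self._residual, params, method="leastsq")
        kd, kd_se = _kd_and_se(out)
        flags = []
        if not out.success:
            flags.append("non-convergence")
        delta = out.params["r_bound"].value - out.params["r_free"].value
        resid_sd = float(np.std(out.residual)) if len(out.residual) else 0.0
        if abs(delta) < max(3.0 * resid_sd, 1e-6) or np.ptp(r) < 1e-9:
            flags.append("unidentifiable: r_bound ~ r_free (no signal change)")
        return AnisotropyResults(
            kd_uM=kd,
            kd_se=kd_se,
            rss=float(np.sum(out.residual**2)),
            success=bool(out.success),
            flags=flags,
            params=out.params,
            r_free=out.params["r_free"].value,
            r_free_se=out.params["r_free"].stderr or float("nan"),
            r_bound=out.params["r_bound"].value,
            r_bound_se=out.params["r_bound"].stderr or float("nan"),
            model=self,
        )


def write_thermogram(thermogram: ITCThermogram, path) -> None:
    s = thermogram.schedule
    header = (
        f"# cell_volume_uL={s.cell_volume_uL} cell_conc_uM={s.cell_conc_uM} "
        f"syringe_conc_uM={s.syringe_conc_uM} "
        f"injection_volume_uL={s.injection_volume_uL} "
        f"temperature_C={s.temperature_C}\n"
    )
    body = thermogram.to_frame().to_csv(index=False, float_format="%.6g")
    with open(path, "w") as fh:
        fh.write(header + body)


def read_thermogram(path) -> ITCThermogram:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise BindingError("thermogram file lacks a schedule header line")
        kv = dict(tok.split("=") for tok in first[1:].split())
        df = pd.read_csv(fh)
    schedule = ITCSchedule(
        cell_volume_uL=float(kv["cell_volume_uL"]),
        cell_conc_uM=float(kv["cell_conc_uM"]),
        syringe_conc_uM=float(kv["syringe_conc_uM"]),
        injection_volume_uL=float(kv["injection_volume_uL"]),
        n_injections=len(df),
        temperature_C=float(kv.get("temperature_C", 25.0)),
    )
    return ITCThermogram(schedule, df["heat_uJ"].to_numpy())


def write_anisotropy(series: AnisotropySeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# probe_conc_uM={series.probe_conc_uM}\n")
        fh.write(series.to_frame().to_csv(index=False, float_format="%.6g"))


def read_anisotropy(path) -> AnisotropySeries:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise BindingError("anisotropy file lacks a probe header line")
        probe = float(first.split("=")[1])
        df = pd.read_csv(fh)
    return AnisotropySeries(probe, df["titrant_uM"].to_numpy(),
                            df["anisotropy"].to_numpy())


def fit_itc(thermogram: ITCThermogram, fix_n: float | None = None,
            exclude_first: bool = True) -> ITCResults:
    return ITCModel(thermogram, exclude_first=exclude_first, fix_n=fix_n).fit()


def fit_anisotropy(series: AnisotropySeries) -> AnisotropyResults:
    return AnisotropyModel(series).fit()
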