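"""Chemical-shift-perturbation (CSP) titration analysis.

CSPs combine amide 1H and 15N shift changes as
``CSP = sqrt(dH^2 + (alpha * dN)^2)`` with the conventional 15N weight
``alpha = 0.154``.  Position uncertainties are the linewidth divided by
the signal-to-noise ratio, propagated to the CSP by first-order error
propagation.  Significance uses the mean-plus-one-standard-deviation
threshold; contiguous significant stretches of at least ``min_len``
residues mark candidate interaction sites.  A fast-exchange global fit
recovers K_D from the full titration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .binding import bound_fraction
from .peaks import PeakList

ALPHA_N = 0.154


class CSPError(ValueError):
    pass


def compute_csp(delta_h, delta_n, alpha: float = ALPHA_N):
    """Weighted combined shift change in ppm (array-friendly)."""
    if alpha <= 0:
        raise CSPError("alpha must be positive")
    dh = np.asarray(delta_h, dtype=float)
    dn = np.asarray(delta_n, dtype=float)
    out = np.sqrt(dh**2 + (alpha * dn) ** 2)
    return float(out) if out.ndim == 0 else out


def csp_uncertainty(
    linewidth_h: float,
    linewidth_n: float,
    snr: float,
    delta_h: float,
    delta_n: float,
    alpha: float = ALPHA_N,
) -> float:
    """First-order propagated CSP uncertainty.

    Position errors are sigma = linewidth / SNR per dimension;
    sigma_CSP = sqrt((dH*s_H)^2 + (alpha^2*dN*s_N)^2) / CSP, with the
    zero-CSP limit sqrt(s_H^2 + (alpha*s_N)^2).
    """
    if snr <= 0:
        raise CSPError("SNR must be positive")
    s_h = linewidth_h / snr
    s_n = linewidth_n / snr
    csp = compute_csp(delta_h, delta_n, alpha)
    if csp == 0.0:
        return float(np.sqrt(s_h**2 + (alpha * s_n) ** 2))
    return float(
        np.sqrt((delta_h * s_h) ** 2 + (alpha**2 * delta_n * s_n) ** 2) / csp
    )


@dataclass
class CSPProfile:
    """Per-residue CSP between a free and a ligand-bound spectrum."""

    df: pd.DataFrame  # residue, delta_h, delta_n, csp, sigma, broadened
    condition: dict = field(default_factory=dict)
    alpha: float = ALPHA_N

    def measurable(self) -> pd.DataFrame:
        return self.df[~self.df["broadened"]]


def profile_from_peaklists(
    free: PeakList,
    bound: PeakList,
    snr: float = 100.0,
    alpha: float = ALPHA_N,
) -> CSPProfile:
    """CSP of every NH peak present in the free list.

    Peaks are paired by assignment label; coordinates are (1H, 15N).
    Residues whose peak vanished in the bound spectrum are marked
    exchange-broadened and excluded from threshold statistics.
    """
    bound_by = bound.by_label()
    rows = []
    for label, pf in sorted(free.by_label().items()):
        assignment = pf.assignment
        if assignment is None:
            continue
        res = assignment[0]
        pb = bound_by.get(label)
        if pb is None or pb.intensity <= 0:
            rows.append((res, np.nan, np.nan, np.nan, np.nan, True))
            continue
        dh = abs(pb.position[0] - pf.position[0])
        dn = abs(pb.position[1] - pf.position[1])
        csp = compute_csp(dh, dn, alpha)
        lw_h, lw_n = pf.linewidth if pf.linewidth else (0.02, 0.15)
        sigma = csp_uncertainty(lw_h, lw_n, snr, dh, dn, alpha)
        rows.append((res, dh, dn, csp, sigma, False))
    df = pd.DataFrame(
        rows, columns=["residue", "delta_h", "delta_n", "csp", "sigma", "broadened"]
    ).sort_values("residue").reset_index(drop=True)
    cond = dict(bound.condition)
    return CSPProfile(df, condition=cond, alpha=alpha)


@dataclass
class SignificanceResult:
    threshold: float                      # ppm; mean + 1 sd of measurable CSPs
    flags: dict[int, bool]
    stretches: list[tuple[int, int]]      # inclusive residue ranges


def find_stretches(flagged: list[int], min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of consecutive residue numbers of length >= min_len."""
    if min_len < 1:
        raise CSPError("min_len must be >= 1")
    out = []
    run: list[int] = []
    for r in sorted(flagged) + [None]:
        if run and (r is None or r != run[-1] + 1):
            if len(run) >= min_len:
                out.append((run[0], run[-1]))
            run = []
        if r is not None:
            run.append(r)
    return out


def significance(profile: CSPProfile, min_len: int = 3) -> SignificanceResult:
    """Mean-plus-one-sd threshold over measurable residues; strict excess.

    Exchange-broadened residues are excluded from the statistics; the
    sample standard deviation (ddof=1) is used.
    """
    meas = profile.measurable()
    if len(meas) < 2:
        raise CSPError("need >= 2 residues with measurable CSP")
    csp = meas["csp"].to_numpy()
    threshold = float(csp.mean() + csp.std(ddof=1))
    flags = {
        int(r): bool(c > threshold)
        for r, c in zip(meas["residue"], csp)
    }
    stretches = find_stretches([r for r, f in flags.items() if f], min_len)
    return SignificanceResult(threshold, flags, stretches)


@dataclass
class CSPTitrationResults:
    kd_uM: float
    kd_se: float
    ddmax: dict[int, float]               # fitted per-residue CSP amplitude
    ddmax_se: dict[int, float]
    rss: float
    success: bool
    flags: list[str]

    @property
    def flagged(self) -> bool:
        return bool(self.flags)

    def summary(self) -> str:
        lines = [
            "Fast-exchange CSP titration fit (shared K_D)",
            "-" * 46,
            f"K_D        {self.kd_uM:10.4g} +/- {self.kd_se:.3g} uM",
            f"residues   {len(self.ddmax)}",
            f"RSS        {self.rss:10.4g}",
            f"converged  {self.success}",
        ]
        if self.flags:
            lines.append("flags      " + "; ".join(self.flags))
        return "\n".join(lines)


class CSPTitrationModel:
    """Global fast-exchange fit: CSP_r(L) = ddmax_r * FB_protein(L).

    FB_protein is the exact quadratic bound fraction of the observed
    protein at total ligand L and fixed protein concentration; K_D is
    shared across residues, one amplitude per residue.
    """

    def __init__(
        self,
        ligand_concs_uM: list[float],
        csp_by_residue: dict[int, np.ndarray],
        protein_conc_uM: float,
    ):
        concs = np.asarray(ligand_concs_uM, dtype=float)
        if len(concs) < 3 or concs[0] != 0:
            raise CSPError("need >= 3 ligand concentrations starting at 0")
        self.concs = concs
        self.protein_conc_uM = protein_conc_uM
        self.residues = sorted(csp_by_residue)
        self.y = np.vstack([np.asarray(csp_by_residue[r], float)
                            for r in self.residues])
        if self.y.shape[1] != len(concs):
            raise CSPError("CSP series length must match concentrations")

    def _fb(self, kd: float) -> np.ndarray:
        return np.array(
            [bound_fraction(self.protein_conc_uM, c, kd) for c in self.concs]
        )

    def fit(self) -> CSPTitrationResults:
        span = float(self.y.max() - self.y.min())
        if span < 1e-9:
            return CSPTitrationResults(
                float("nan"), float("nan"), {}, {}, 0.0, False,
                ["unidentifiable: flat CSPs (ddmax ~ 0)"],
            )
        params = lmfit.Parameters()
        params.add("log_kd", value=np.log10(max(self.concs.max() / 4, 1e-3)),
                   min=-4, max=6)
        for r in self.residues:
            params.add(f"ddmax_{r}", value=float(self.y[self.residues.index(r)].max()))

        def residual(p):
            fb = self._fb(10.0 ** p["log_kd"].value)
            pred = np.vstack(
                [p[f"ddmax_{r}"].value * fb for r in self.residues]
            )
            return (pred - self.y).ravel()

        out = lmfit.minimize(residual, params, method="leastsq")
        kd = 10.0 ** out.params["log_kd"].value
        se = out.params["log_kd"].stderr
        kd_se = kd * np.log(10.0) * se if se is not None else float("nan")
        flags = [] if out.success else ["non-convergence"]
        return CSPTitrationResults(
            kd_uM=kd,
            kd_se=kd_se,
            ddmax={r: out.params[f"ddmax_{r}"].value for r in self.residues},
            ddmax_se={
                r: out.params[f"ddmax_{r}"].stderr or float("nan")
                for r in self.residues
            },
            rss=float(np.sum(out.residual**2)),
            success=bool(out.success),
            flags=flags,
        )


def fit_titration_kd(
    peaklists: list[PeakList],
    ligand_concs_uM: list[float],
    protein_conc_uM: float,
    residues: list[int] | None = None,
    alpha: float = ALPHA_N,
) -> CSPTitrationResults:
    """Global K_D fit from an ordered series of NH peak lists.

    CSPs at each titration point are computed against the first (zero
    ligand) list; ``residues`` restricts the fit (default: the residues
    with the largest endpoint CSPs, top quartile, to keep the fit on
    residues that actually move).
    """
    free = peaklists[0]
    series: dict[int, list[float]] = {}
    for pl in peaklists:
        prof = profile_from_peaklists(free, pl, alpha=alpha)
        for r, c in zip(prof.df["residue"], prof.df["csp"]):
            series.setdefault(int(r), []).append(float(c))
    complete = {r: np.array(v) for r, v in series.items()
                if len(v) == len(peaklists) and np.isfinite(v).all()}
    if residues is None:
        endpoints = sorted(complete, key=lambda r: complete[r][-1], reverse=True)
        residues = endpoints[: max(3, len(endpoints) // 4)]
    chosen = {r: complete[r] for r in residues if r in complete}
    model = CSPTitrationModel(ligand_concs_uM, chosen, protein_conc_uM)
    return model.fit()


def salt_series(
    profiles: dict[float, CSPProfile],
    min_len: int = 3,
) -> dict:
    """Trend analysis of CSP profiles across ionic strengths.

    Reports per-salt max and mean CSP, a Kendall-tau monotonicity test of
    max CSP against salt, and an "abolished" flag when no residue at the
    highest salt exceeds the significance threshold established at the
    lowest (reference) salt.  A self-referential per-condition threshold
    would rescale with a screening decay and never report abolition, so
    the reference-condition threshold is the meaningful yardstick.
    """
    if len(profiles) < 2:
        raise CSPError("need >= 2 salt conditions")
    salts = sorted(profiles)
    per_salt = []
    for s in salts:
        meas = profiles[s].measurable()
        per_salt.append(
            {"salt_mM": s,
             "max_csp": float(meas["csp"].max()),
             "mean_csp": float(meas["csp"].mean())}
        )
    maxes = [d["max_csp"] for d in per_salt]
    tau, pvalue = kendalltau(salts, maxes)
    try:
        threshold = significance(profiles[salts[0]], min_len=min_len).threshold
    except CSPError:
        threshold = float("inf")
    top_csp = profiles[salts[-1]].measurable()["csp"]
    abolished = not bool((top_csp > threshold).any())
    monotonic_decrease = bool(tau < 0)
    return {
        "per_salt": per_salt,
        "reference_threshold": threshold,
        "kendall_tau": float(tau) if tau == tau else 0.0,
        "kendall_p": float(pvalue) if pvalue == pvalue else 1.0,
        "monotonic_decrease": monotonic_decrease,
        "abolished_at_mM": salts[-1] if abolished else None,
    }
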