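"""Relative lifespan from competitive-aging fluorescence assays.

An RFP-labeled mutant is aged in co-culture with a CFP-labeled wild-type
reference; at each aging day T_i an aliquot is regrown and OD plus both
fluorescence channels are read every couple of hours (t_j).  After
background subtraction, the signal ratio y = ln(RFP/CFP) of well w is fit
per plate to the linear model

    y = A_w + S_w * T_i + G_w * t_j + C_{T_i,t_j}

where A_w is the initial log viable-cell ratio, S_w the survival of the
mutant relative to the reference per aging day, G_w the outgrowth-rate
difference per hour, and C a plate-level systematic offset shared by all
wells at each sampling point (sum-to-zero for identifiability).  WT/WT
competition wells anchor the fit with S = G = 0 enforced by omitting their
slope columns.  Relative lifespan is L_w = 1 + S_w.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: required columns of the long-format measurement table
MEASUREMENT_COLUMNS = [
    "plate",
    "well",
    "strain",
    "is_wt_wt",
    "aging_day",
    "outgrowth_hour",
    "od",
    "rfp",
    "cfp",
]

REF_STRAINS = {"WT_RFP": "ref_rfp", "WT_CFP": "ref_cfp"}


@dataclass
class WellAssignment:
    well: str
    strain: str
    plate: str
    kind: str  # mutant | wt_wt | ref_rfp | ref_cfp


@dataclass
class CompetitionDesign:
    """Plate layout: competition wells plus single-color reference wells."""

    wells: dict[str, WellAssignment]

    def __post_init__(self) -> None:
        for plate in self.plates:
            kinds = [w.kind for w in self.wells.values() if w.plate == plate]
            if "wt_wt" not in kinds:
                raise ValueError(f"plate {plate!r} has no WT/WT competition well")
            for ref in ("ref_rfp", "ref_cfp"):
                if ref not in kinds:
                    raise ValueError(f"plate {plate!r} has no {ref} reference well")

    @property
    def plates(self) -> list[str]:
        return sorted({w.plate for w in self.wells.values()})

    def wells_of(self, plate: str, kinds) -> list[str]:
        return sorted(
            w for w, a in self.wells.items() if a.plate == plate and a.kind in kinds
        )


def design_from_frame(df: pd.DataFrame) -> CompetitionDesign:
    """Infer the plate design from the measurement table.

    Wells whose strain is ``WT_RFP``/``WT_CFP`` are single-color background
    references; wells flagged ``is_wt_wt`` are WT/WT competitions.
    """
    wells = {}
    for (plate, well), grp in df.groupby(["plate", "well"]):
        strain = str(grp["strain"].iloc[0])
        if strain in REF_STRAINS:
            kind = REF_STRAINS[strain]
        elif bool(grp["is_wt_wt"].iloc[0]):
            kind = "wt_wt"
        else:
            kind = "mutant"
        wells[str(well)] = WellAssignment(well=str(well), strain=strain, plate=str(plate), kind=kind)
    return CompetitionDesign(wells=wells)


def load_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["well"] = df["well"].astype(str)
    df["plate"] = df["plate"].astype(str)
    return df


def subtract_background(
    measurements: pd.DataFrame,
    design: CompetitionDesign,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Subtract per-plate, per-timepoint background from both channels.

    The RFP background at a sampling point is the mean RFP signal of the
    CFP-only reference wells (which contain no RFP cells), and vice versa.
    Corrected signals are floored at a small positive value before the log;
    a sampling point without a reference reading falls back to the nearest
    timepoint with a warning.
    """
    df = measurements.copy()
    corrected = {"rfp": df["rfp"].astype(float).copy(), "cfp": df["cfp"].astype(float).copy()}
    opposite_ref = {"rfp": "ref_cfp", "cfp": "ref_rfp"}
    for plate in design.plates:
        on_plate = df["plate"] == plate
        for channel in ("rfp", "cfp"):
            ref_wells = design.wells_of(plate, {opposite_ref[channel]})
            ref_rows = on_plate & df["well"].isin(ref_wells)
            bg = (
                df.loc[ref_rows]
                .groupby(["aging_day", "outgrowth_hour"])[channel]
                .mean()
            )
            if bg.empty:
                raise ValueError(
                    f"plate {plate!r}: no {opposite_ref[channel]} reference readings"
                )
            points = df.loc[on_plate, ["aging_day", "outgrowth_hour"]].drop_duplicates()
            bg_points = np.array(list(bg.index))
            for day, hour in points.itertuples(index=False):
                if (day, hour) in bg.index:
                    value = bg.loc[(day, hour)]
                else:
                    d2 = (bg_points[:, 0] - day) ** 2 + (bg_points[:, 1] - hour) ** 2
                    nearest = tuple(bg_points[int(np.argmin(d2))])
                    value = bg.loc[nearest]
                    warnings.warn(
                        f"plate {plate}: no {channel} background at (T={day}, t={hour}); "
                        f"using nearest timepoint {nearest}"
                    )
                rows = on_plate & (df["aging_day"] == day) & (df["outgrowth_hour"] == hour)
                corrected[channel].loc[rows] -= value
    n_clipped = 0
    for channel in ("rfp", "cfp"):
        clipped = corrected[channel] < floor
        n_clipped += int(clipped.sum())
        corrected[channel] = corrected[channel].clip(lower=floor)
        df[channel] = corrected[channel]
    if n_clipped:
        log.info("background subtraction clipped %d signals at floor %g", n_clipped, floor)
    return df


@dataclass
class SurvivalEstimate:
    """Fitted per-well parameters; L = 1 + S exactly."""

    well: str
    strain: str
    plate: str
    A: float
    S: float
    G: float
    L: float
    se_A: float
    se_S: float
    se_G: float
    is_wt_wt: bool = False


@dataclass
class SurvivalFit:
    """All per-well estimates plus per-plate systematic effects."""

    estimates: list[SurvivalEstimate]
    plate_effects: dict[str, dict[tuple[float, float], float]] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(default_factory=dict)
    df_resid: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well": [e.well for e in self.estimates],
                "strain": [e.strain for e in self.estimates],
                "plate": [e.plate for e in self.estimates],
                "A": [e.A for e in self.estimates],
                "S": [e.S for e in self.estimates],
                "G": [e.G for e in self.estimates],
                "L": [e.L for e in self.estimates],
                "se_S": [e.se_S for e in self.estimates],
            }
        )


def relative_lifespan(s: float) -> float:
    """Relative lifespan L = 1 + S (neutral S = 0 gives L = 1)."""
    if not np.isfinite(s):
        raise ValueError("survival slope must be finite")
    return 1.0 + s


def fit_survival_model(
    observations: pd.DataFrame,
    design: CompetitionDesign,
    od_min: float = 0.05,
    od_max: float = 1.0,
) -> SurvivalFit:
    """One joint least-squares fit per plate of the competitive-aging model.

    Only outgrowth readings with OD inside [od_min, od_max] (detection floor
    to saturation ceiling) enter the fit.  Design columns: one intercept A_w
    per well; S_w (aging day) and G_w (outgrowth hour) slopes for every
    competition well except WT/WT wells, whose columns are omitted to
    enforce S = G = 0; and one shared effect-coded C column per sampling
    point (sum-to-zero).  Standard errors come from the usual OLS covariance.
    """
    fit = SurvivalFit(estimates=[])
    for plate in design.plates:
        fit_wells = design.wells_of(plate, {"mutant", "wt_wt"})
        sub = observations[
            (observations["plate"] == plate)
            & observations["well"].isin(fit_wells)
            & (observations["od"] >= od_min)
            & (observations["od"] <= od_max)
        ].copy()
        n_window_dropped = int(
            (observations["plate"] == plate).sum()
            - len(sub)
        )
        log.info("plate %s: %d rows outside the OD window or non-fit wells", plate, n_window_dropped)
        days = np.sort(sub["aging_day"].unique())
        hours = np.sort(sub["outgrowth_hour"].unique())
        if len(days) < 2 or len(hours) < 2:
            raise ValueError(
                f"plate {plate!r}: need >= 2 aging days and >= 2 outgrowth times"
            )
        points = sorted(
            set(zip(sub["aging_day"].astype(float), sub["outgrowth_hour"].astype(float)))
        )
        wells = sorted(sub["well"].unique())
        slope_wells = [w for w in wells if design.wells[w].kind != "wt_wt"]
        col_names = (
            [f"A[{w}]" for w in wells]
            + [f"S[{w}]" for w in slope_wells]
            + [f"G[{w}]" for w in slope_wells]
            + [f"C[{p}]" for p in points[:-1]]
        )
        widx = {w: i for i, w in enumerate(wells)}
        sidx = {w: i for i, w in enumerate(slope_wells)}
        pidx = {p: i for i, p in enumerate(points)}
        n_obs = len(sub)
        ncols = len(col_names)
        X = np.zeros((n_obs, ncols))
        y = np.log(sub["rfp"].to_numpy(dtype=float) / sub["cfp"].to_numpy(dtype=float))
        n_wells = len(wells)
        n_slope = len(slope_wells)
        for r, row in enumerate(sub.itertuples(index=False)):
            w = row.well
            T, t = float(row.aging_day), float(row.outgrowth_hour)
            X[r, widx[w]] = 1.0
            if w in sidx:
                X[r, n_wells + sidx[w]] = T
                X[r, n_wells + n_slope + sidx[w]] = t
            k = pidx[(T, t)]
            if k < len(points) - 1:
                X[r, n_wells + 2 * n_slope + k] = 1.0
            else:
                X[r, n_wells + 2 * n_slope :] = -1.0
        rank = np.linalg.matrix_rank(X)
        if rank < ncols:
            _, _, vt = np.linalg.svd(X)
            culprit = vt[rank:]
            involved = sorted(
                {col_names[j] for vec in culprit for j in np.flatnonzero(np.abs(vec) > 1e-8)}
            )
            raise ValueError(
                f"plate {plate!r}: rank-deficient design; unidentifiable terms: {involved}"
            )
        beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n_obs - ncols
        sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        c_free = beta[n_wells + 2 * n_slope :]
        c_effects = dict(zip(points[:-1], c_free))
        c_effects[points[-1]] = -float(c_free.sum())
        fit.plate_effects[plate] = {p: float(c_effects[p]) for p in points}
        fit.residual_sd[plate] = float(np.sqrt(sigma2))
        fit.df_resid[plate] = dof
        for w in wells:
            a = float(beta[widx[w]])
            se_a = float(se[widx[w]])
            if w in sidx:
                s = float(beta[n_wells + sidx[w]])
                g = float(beta[n_wells + n_slope + sidx[w]])
                se_s = float(se[n_wells + sidx[w]])
                se_g = float(se[n_wells + n_slope + sidx[w]])
            else:
                s = g = se_s = se_g = 0.0
            fit.estimates.append(
                SurvivalEstimate(
                    well=w,
                    strain=design.wells[w].strain,
                    plate=plate,
                    A=a,
                    S=s,
                    G=g,
                    L=relative_lifespan(s),
                    se_A=se_a,
                    se_S=se_s,
                    se_G=se_g,
                    is_wt_wt=design.wells[w].kind == "wt_wt",
                )
            )
    return fit


def survival_confidence_interval(
    estimate: SurvivalEstimate, df_resid: int, level: float = 0.95
) -> tuple[float, float]:
    """t-interval for the survival slope S of one well."""
    tq = stats.t.ppf(0.5 + level / 2, df=df_resid)
    return estimate.S - tq * estimate.se_S, estimate.S + tq * estimate.se_S
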