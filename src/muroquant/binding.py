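"""Bocillin-FL binding assay quantification.

Bocillin-FL is a fluorescent penicillin that covalently labels active
penicillin-binding proteins; competition with unlabelled beta-lactams reads
out their affinity as a loss (or, allosterically, a gain) of band
fluorescence on a gel. This module normalises lane intensities to the
zero-concentration control per replicate, classifies the dose response
(inhibition / weak / enhancement), interpolates an IC50, and checks the
protein-amount linearity of the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

ResponseClass = Literal["inhibition", "weak", "enhancement"]


@dataclass
class TitrationResult:
    """Relative Bocillin-FL binding vs antibiotic concentration."""

    antibiotic: str
    concentrations: np.ndarray  # ascending, includes 0 (control)
    mean_relative: np.ndarray  # 1.0 at concentration 0 by construction
    sd: np.ndarray
    n_replicates: int
    single_replicate: bool = False
    response_class: ResponseClass | None = None
    ic50: float | None = None

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration": self.concentrations,
                "mean_relative": self.mean_relative,
                "sd": self.sd,
            }
        )


def relative_binding(lanes: pd.DataFrame, antibiotic: str | None = None) -> TitrationResult:
    """Normalise lane intensities to each replicate's zero-concentration control.

    ``lanes`` needs columns concentration, intensity, replicate (and
    antibiotic when several are present). Per concentration the mean and the
    n-1 standard deviation across replicates are reported; with a single
    replicate the sd is 0 and flagged.
    """
    df = lanes.copy()
    if antibiotic is not None:
        df = df[df["antibiotic"] == antibiotic]
    elif "antibiotic" in df.columns:
        names = df["antibiotic"].unique()
        if len(names) > 1:
            raise ValueError(f"multiple antibiotics present ({list(names)}); pick one")
        antibiotic = str(names[0]) if len(names) else "unknown"
    else:
        antibiotic = "unknown"
    if df.empty:
        raise ValueError(f"no lanes for antibiotic {antibiotic!r}")
    if "replicate" not in df.columns:
        df = df.assign(replicate=1)
    rel_rows = []
    for rep, sub in df.groupby("replicate"):
        controls = sub[sub["concentration"] == 0]
        if len(controls) != 1:
            raise ValueError(
                f"replicate {rep}: need exactly one zero-concentration control, "
                f"found {len(controls)}"
            )
        control = float(controls["intensity"].iloc[0])
        if control <= 0:
            raise ValueError(f"replicate {rep}: control intensity must be positive")
        rel_rows.append(
            pd.DataFrame(
                {
                    "concentration": sub["concentration"].to_numpy(dtype=float),
                    "relative": sub["intensity"].to_numpy(dtype=float) / control,
                }
            )
        )
    rel = pd.concat(rel_rows, ignore_index=True)
    grouped = rel.groupby("concentration")["relative"]
    concs = np.array(sorted(grouped.groups))
    means = grouped.mean().loc[concs].to_numpy()
    counts = grouped.count().loc[concs].to_numpy()
    sds = grouped.std(ddof=1).loc[concs].to_numpy()
    single = bool(np.any(counts < 2))
    sds = np.nan_to_num(sds, nan=0.0)
    return TitrationResult(
        antibiotic=antibiotic,
        concentrations=concs,
        mean_relative=means,
        sd=sds,
        n_replicates=int(counts.max()),
        single_replicate=single,
    )


def classify_response(
    result: TitrationResult,
    inhibition_threshold: float = 0.5,
    enhancement_threshold: float = 1.2,
) -> ResponseClass:
    """Enhancement if the top concentration reaches the enhancement threshold,
    inhibition if any mean drops to the inhibition threshold, else weak."""
    nz = result.concentrations > 0
    if nz.sum() < 2:
        raise ValueError("need at least 2 nonzero concentrations to classify")
    means = result.mean_relative[nz]
    if means[-1] >= enhancement_threshold:
        return "enhancement"
    if np.any(means <= inhibition_threshold):
        return "inhibition"
    return "weak"


def ic50_interpolate(result: TitrationResult) -> float | None:
    """Smallest concentration where the mean relative binding crosses 0.5.

    Located by linear interpolation on log10 concentration between the
    bracketing measured points; ``None`` when the curve never crosses. If the
    lowest nonzero concentration is already at or below 0.5, that
    concentration is returned (no log bracket exists to its left).
    """
    nz = result.concentrations > 0
    concs = result.concentrations[nz]
    means = result.mean_relative[nz]
    for i in range(len(concs)):
        if means[i] <= 0.5:
            if i == 0:
                return float(concs[0])
            c0, c1 = np.log10(concs[i - 1]), np.log10(concs[i])
            r0, r1 = means[i - 1], means[i]
            frac = (r0 - 0.5) / (r0 - r1)
            return float(10.0 ** (c0 + frac * (c1 - c0)))
    return None


def titrate(
    lanes: pd.DataFrame,
    inhibition_threshold: float = 0.5,
    enhancement_threshold: float = 1.2,
) -> dict[str, TitrationResult]:
    """Per-antibiotic titration: relative curve, response class, IC50."""
    if "antibiotic" in lanes.columns:
        names = list(pd.unique(lanes["antibiotic"]))
    else:
        names = [None]
    results: dict[str, TitrationResult] = {}
    for name in names:
        res = relative_binding(lanes, antibiotic=name)
        res.response_class = classify_response(
            res, inhibition_threshold, enhancement_threshold
        )
        res.ic50 = ic50_interpolate(res)
        results[res.antibiotic] = res
    return results


def linearity_check(
    points: Sequence[tuple[float, float]] | np.ndarray,
) -> tuple[float, float, float]:
    """OLS of band intensity on protein amount: (slope, intercept, pearson_r)."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (amount, intensity) pairs")
    if len(arr) < 3:
        raise ValueError("need at least 3 points")
    if np.var(arr[:, 0]) == 0:
        raise ValueError("zero variance in protein amount")
    fit = linregress(arr[:, 0], arr[:, 1])
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
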