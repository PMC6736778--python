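"""Statistics for the four-way host-microbe-drug-nutrient screen.

A nutrient plate screen crosses ~340 nutrients with drug treatment
(metformin) and reads out (i) bacterial growth curves, summarized as the
log2 area under the OD curve, and (ii) per-worm reporter fluorescence,
summarized as the 90th percentile (Q90) of the log2 intensity
distribution — a robust proxy for maximal expression given the reporter's
wide, non-normal intensity spread.

Per nutrient, a two-factor linear model with interaction is fitted on
log2 responses across the 2x2 cells {nutrient absent/present} x
{drug absent/present}; the drug-only and untreated baseline cells are
shared across nutrients per the plate design.  Interaction p-values are
Benjamini-Hochberg adjusted across nutrients; a significant positive
interaction means the nutrient suppresses the drug effect (antagonistic
call), a significant negative one amplifies it (synergistic).

Hit sets are tested for metabolite-class enrichment with the upper-tail
hypergeometric test, again under BH control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import benjamini_hochberg

__all__ = [
    "GrowthCurve",
    "WormIntensitySet",
    "growth_auc",
    "q90_intensity",
    "fit_interactions",
    "enrich",
    "associate_prediction",
]


@dataclass
class GrowthCurve:
    well_id: str
    nutrient_id: str
    metformin_mM: float
    replicate: int
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray     # optical density, >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.metformin_mM < 0:
            raise ValueError("negative drug dose")
        if self.times.shape != self.od.shape:
            raise ValueError(f"{self.well_id}: times and od lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.well_id}: times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError(f"{self.well_id}: negative OD values")


@dataclass
class WormIntensitySet:
    well_id: str
    nutrient_id: str
    metformin_mM: float
    intensities: np.ndarray  # per-worm fluorescence, > 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size < 1:
            raise ValueError(f"{self.well_id}: need at least one worm")
        if np.any(self.intensities <= 0):
            raise ValueError(f"{self.well_id}: non-positive intensities")


def growth_auc(curve: GrowthCurve) -> float:
    """log2 of the trapezoidal area under the OD curve (log2(OD*h)).

    Requires a positive integral: apply any OD floor upstream.
    """
    if curve.times.size < 2:
        raise ValueError(f"{curve.well_id}: need >= 2 time points")
    auc = float(np.trapezoid(curve.od, curve.times))
    if auc <= 0:
        raise ValueError(f"{curve.well_id}: non-positive AUC ({auc})")
    return float(np.log2(auc))


def q90_intensity(values: Iterable[float]) -> float:
    """90th percentile of log2-transformed per-worm intensities.

    Uses the linear-interpolation quantile between order statistics.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.size == 0:
        raise ValueError("empty intensity vector")
    if np.any(arr <= 0):
        raise ValueError("intensities must be positive for the log2 transform")
    return float(np.quantile(np.log2(arr), 0.9))


def fit_interactions(
    design: pd.DataFrame,
    response_col: str = "response",
    nutrient_col: str = "nutrient_id",
    drug_col: str = "drug",
    baseline: str = "none",
    fdr_threshold: float = 0.05,
    pool_variance: bool = True,
) -> pd.DataFrame:
    """Per-nutrient two-factor linear models with interaction.

    ``design`` is long-format: one row per well with the (log2) response,
    the nutrient id (``baseline`` marking no-nutrient wells) and a boolean
    drug column.  For each nutrient the model

        y = b0 + b1*nutrient + b2*drug + b3*nutrient:drug

    is fitted by OLS on that nutrient's wells plus the shared baseline
    wells.  Returns one row per nutrient with estimates, standard errors,
    raw and BH-adjusted interaction p-values, and the interaction call
    (``antagonistic`` for significant positive, ``synergistic`` for
    significant negative, else ``neutral``).  Nutrients missing one of
    the four cells are skipped.

    With ``pool_variance`` (the default) the residual variance is pooled
    across all nutrient models before computing standard errors — the
    wells of one plate share a single measurement process, and the few
    residual degrees of freedom per nutrient (4 cells x few replicates)
    make the per-nutrient variance estimate the limiting noise source.
    Set it to False for fully independent per-nutrient fits.
    """
    groups = {
        str(name): (grp[response_col].to_numpy(dtype=float),
                    grp[drug_col].to_numpy(dtype=bool))
        for name, grp in design.groupby(nutrient_col, sort=True)
    }
    if baseline not in groups:
        raise ValueError(f"no baseline ({baseline!r}) wells in the design")
    y_base, d_base = groups.pop(baseline)
    rows = []
    skipped = []
    for nutrient, (y_nut, d_nut) in groups.items():
        cells = {
            (False, False): np.sum(~d_base),
            (False, True): np.sum(d_base),
            (True, False): np.sum(~d_nut),
            (True, True): np.sum(d_nut),
        }
        if any(v == 0 for v in cells.values()):
            skipped.append(nutrient)
            continue
        y = np.concatenate([y_base, y_nut])
        n_flag = np.concatenate([np.zeros(y_base.size), np.ones(y_nut.size)])
        d_flag = np.concatenate([d_base, d_nut]).astype(float)
        X = np.column_stack([np.ones(y.size), n_flag, d_flag, n_flag * d_flag])
        beta, diag, rss, dof = _ols_parts(X, y)
        rows.append(
            {"nutrient_id": nutrient, "beta": beta, "diag": diag,
             "rss": rss, "dof": dof}
        )
    if rows:
        if pool_variance:
            total_dof = sum(r["dof"] for r in rows)
            sigma2 = {r["nutrient_id"]: sum(x["rss"] for x in rows) / total_dof
                      for r in rows}
            dofs = {r["nutrient_id"]: total_dof for r in rows}
        else:
            sigma2 = {r["nutrient_id"]: r["rss"] / r["dof"] for r in rows}
            dofs = {r["nutrient_id"]: r["dof"] for r in rows}
    table = []
    for r in rows:
        nid = r["nutrient_id"]
        se = np.sqrt(np.maximum(r["diag"] * sigma2[nid], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, r["beta"] / se, np.inf * np.sign(r["beta"]))
        p = 2 * sps.t.sf(np.abs(t), dofs[nid])
        table.append(
            {
                "nutrient_id": nid,
                "effect_nutrient": r["beta"][1],
                "se_nutrient": se[1],
                "effect_drug": r["beta"][2],
                "se_drug": se[2],
                "interaction": r["beta"][3],
                "se_interaction": se[3],
                "p_interaction": p[3],
            }
        )
    out = pd.DataFrame(
        table,
        columns=[
            "nutrient_id", "effect_nutrient", "se_nutrient", "effect_drug",
            "se_drug", "interaction", "se_interaction", "p_interaction",
        ],
    )
    if not out.empty:
        out["fdr"] = benjamini_hochberg(out["p_interaction"].to_numpy())
        significant = out["fdr"] < fdr_threshold
        out["call"] = np.where(
            ~significant, "neutral",
            np.where(out["interaction"] > 0, "antagonistic", "synergistic"),
        )
    else:
        out["fdr"] = []
        out["call"] = []
    out.attrs["skipped"] = skipped
    return out


def _ols_parts(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Closed-form OLS pieces: beta, diag((X'X)^-1), residual SS, dof."""
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    return beta, np.diag(xtx_inv).copy(), float(resid @ resid), n - k


def enrich(
    hit_set: Iterable[str],
    universe: Iterable[str],
    class_map: Mapping[str, Iterable[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of classes among hits.

    ``class_map`` maps class name -> members.  For each class with K
    members in the universe of size N and k hits among the n drawn, the
    upper-tail probability P[X >= k] is computed; BH across classes.
    Classes with no members in the universe are skipped.
    """
    universe_set = set(universe)
    hits = set(hit_set)
    if not hits <= universe_set:
        raise ValueError(f"hits outside the universe: {sorted(hits - universe_set)}")
    N = len(universe_set)
    n = len(hits)
    rows = []
    for cls in sorted(class_map):
        members = set(class_map[cls]) & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & hits)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"class": cls, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["class", "k", "K", "n", "N", "p"])
    if not out.empty:
        out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_threshold
    else:
        out["fdr"] = []
        out["significant"] = []
    return out


@dataclass
class AssociationResult:
    slope: float
    se: float
    p_value: float
    intercept: float
    n: int


def associate_prediction(
    predicted: Mapping[str, float], measured: Mapping[str, float]
) -> AssociationResult:
    """OLS of a measured screen metric on the predicted capacity ratio.

    Pairs nutrients present in both maps; requires >= 3 pairs and a
    non-degenerate predictor.
    """
    common = sorted(set(predicted) & set(measured))
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired nutrients, got {len(common)}")
    x = np.array([predicted[c] for c in common], dtype=float)
    y = np.array([measured[c] for c in common], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = sps.linregress(x, y)
    return AssociationResult(
        slope=float(res.slope),
        se=float(res.stderr),
        p_value=float(res.pvalue),
        intercept=float(res.intercept),
        n=len(common),
    )
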