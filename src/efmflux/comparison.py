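"""Comparing relative changes in measured fluxes with changes in flux efficiency.

For a reaction measured in a reference condition (value ``ref``) and an
alternative condition (``alt``), the relative difference is

    Delta = (alt - ref) / |ref|

applied both to the 13C-measured fluxes (DeltaF) and to the flux-efficiency
coefficients (Delta eps).  Agreement between the two is assessed by sign
concordance and by a paired Wilcoxon signed-rank test on the per-reaction
differences DeltaF - Delta_eps.

Exclusion rules mirror the study's analysis choices:

* reactions present in only one condition are unpaired and dropped (this is
  what removes substrate-specific uptake reactions);
* reactions whose measurement error is too large relative to the flux
  (``se/|F|`` above a threshold, default 300%) are dropped;
* optionally, fluxes toward output metabolites (ids with a configurable
  suffix, default ``_out``) are dropped;
* a zero reference flux or efficiency leaves the relative difference
  undefined and excludes the pair.

Every exclusion is recorded with its reason so reports are auditable.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .efficiency import EfficiencyVector

__all__ = [
    "FluxTable",
    "ConditionComparison",
    "relative_difference",
    "compare_conditions",
    "wilcoxon_paired",
    "sign_concordance",
]

DEFAULT_ERROR_BAR_THRESHOLD = 3.0  # se/|F| above 300% excludes the reaction


@dataclass
class FluxTable:
    """Measured fluxes (and optional standard errors) for one condition.

    Units are whatever the measurements use (typically % of substrate
    uptake); only ratios ever enter the comparison.
    """

    data: pd.DataFrame  # columns: reaction_id, flux, se (se may be NaN)
    condition: str = ""

    def __post_init__(self):
        df = self.data.copy()
        if "se" not in df.columns:
            df["se"] = np.nan
        missing = {"reaction_id", "flux"} - set(df.columns)
        if missing:
            raise ValueError(f"flux table missing columns: {sorted(missing)}")
        if df["reaction_id"].duplicated().any():
            raise ValueError("duplicate reaction ids in flux table")
        neg_se = df["se"].dropna() < 0
        if neg_se.any():
            raise ValueError("negative standard errors")
        self.data = df[["reaction_id", "flux", "se"]].reset_index(drop=True)

    @classmethod
    def from_mapping(cls, fluxes: dict[str, float], condition: str = "",
                     se: dict[str, float] | None = None) -> "FluxTable":
        se = se or {}
        return cls(
            pd.DataFrame(
                {
                    "reaction_id": list(fluxes),
                    "flux": list(fluxes.values()),
                    "se": [se.get(r, np.nan) for r in fluxes],
                }
            ),
            condition=condition,
        )

    @classmethod
    def from_tsv(cls, path_or_buf, condition: str | None = None) -> "FluxTable":
        df = pd.read_csv(path_or_buf, sep="\t", comment="#")
        cond = condition
        if cond is None:
            cond = str(df["condition"].iloc[0]) if "condition" in df.columns else ""
        return cls(df.drop(columns=[c for c in ("condition",) if c in df.columns]),
                   condition=cond)

    def to_tsv(self) -> str:
        df = self.data.copy()
        df["condition"] = self.condition
        return df.to_csv(sep="\t", index=False)

    def __len__(self):
        return len(self.data)


def relative_difference(ref: float, alt: float) -> float:
    """(alt - ref) / |ref|; undefined (ValueError) for a zero reference."""
    if ref == 0:
        raise ValueError("relative difference undefined for zero reference")
    return (alt - ref) / abs(ref)


def _sign(x: float, tol: float = 0.0) -> int:
    if x > tol:
        return 1
    if x < -tol:
        return -1
    return 0


@dataclass
class ConditionComparison:
    """Paired DeltaF / Delta_eps per reaction with exclusion bookkeeping."""

    frame: pd.DataFrame  # reaction_id, F_ref, F_alt, dF, eps_ref, eps_alt, dEps,
    #                      excluded, reason, concordant
    reference: str = ""
    alternative: str = ""
    settings: dict = field(default_factory=dict)

    @property
    def compared(self) -> pd.DataFrame:
        return self.frame[~self.frame["excluded"]].reset_index(drop=True)

    @property
    def excluded(self) -> pd.DataFrame:
        return self.frame[self.frame["excluded"]].reset_index(drop=True)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# reference: {self.reference}\n")
        buf.write(f"# alternative: {self.alternative}\n")
        for k, v in sorted(self.settings.items()):
            buf.write(f"# {k}: {v}\n")
        self.frame.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    def to_json(self) -> str:
        n_conc, n_total, discordant = sign_concordance(self)
        payload = {
            "reference": self.reference,
            "alternative": self.alternative,
            "settings": self.settings,
            "n_compared": int(n_total),
            "n_concordant": int(n_conc),
            "discordant": list(discordant),
            "records": json.loads(self.frame.to_json(orient="records")),
        }
        if n_total:
            stat, p = wilcoxon_paired(
                self.compared["dF"].to_numpy(), self.compared["dEps"].to_numpy()
            )
            payload["wilcoxon"] = {"statistic": float(stat), "p_value": float(p)}
        return json.dumps(payload, indent=2)


def compare_conditions(
    flux_ref: FluxTable,
    flux_alt: FluxTable,
    eff_ref: EfficiencyVector,
    eff_alt: EfficiencyVector,
    *,
    error_bar_threshold: float = DEFAULT_ERROR_BAR_THRESHOLD,
    include_outputs: bool = True,
    output_suffix: str = "_out",
    sign_tolerance: float = 0.0,
) -> ConditionComparison:
    """Pair the two conditions reaction-by-reaction and compute DeltaF, Delta_eps.

    Pairs are matched by reaction id; ids present in only one flux table are
    auto-excluded (reason ``unpaired``), which is what removes
    substrate-specific uptake reactions.  Raises if nothing survives the
    exclusions.

    ``sign_tolerance``: relative differences with magnitude at or below this
    value count as "no change" for sign concordance (0.0 = exact zeros only;
    useful when fluxes come through floating point).
    """
    ref_map = dict(zip(flux_ref.data["reaction_id"], flux_ref.data["flux"]))
    alt_map = dict(zip(flux_alt.data["reaction_id"], flux_alt.data["flux"]))
    se_ref = dict(zip(flux_ref.data["reaction_id"], flux_ref.data["se"]))
    se_alt = dict(zip(flux_alt.data["reaction_id"], flux_alt.data["se"]))
    eref = {r: float(v) for r, v in zip(eff_ref.reaction_ids, eff_ref.net)}
    ealt = {r: float(v) for r, v in zip(eff_alt.reaction_ids, eff_alt.net)}

    all_ids = list(dict.fromkeys(list(ref_map) + list(alt_map)))
    rows = []
    for rid in all_ids:
        rec = {
            "reaction_id": rid,
            "F_ref": ref_map.get(rid, np.nan),
            "F_alt": alt_map.get(rid, np.nan),
            "eps_ref": eref.get(rid, np.nan),
            "eps_alt": ealt.get(rid, np.nan),
            "dF": np.nan,
            "dEps": np.nan,
            "excluded": True,
            "reason": "",
            "concordant": False,
        }
        reasons = []
        if rid not in ref_map or rid not in alt_map:
            reasons.append("unpaired")
        if not include_outputs and rid.endswith(output_suffix):
            reasons.append("output flux")
        for label, se_map, f_map in (("ref", se_ref, ref_map), ("alt", se_alt, alt_map)):
            se = se_map.get(rid, np.nan)
            f = f_map.get(rid, np.nan)
            if np.isfinite(se) and np.isfinite(f) and f != 0:
                if se / abs(f) > error_bar_threshold:
                    reasons.append(f"error bars > {error_bar_threshold:.0%} ({label})")
                    break
        if not reasons:
            if rid not in eref or rid not in ealt:
                reasons.append("no efficiency value")
            elif ref_map[rid] == 0:
                reasons.append("zero reference flux")
            elif eref[rid] == 0:
                reasons.append("zero reference efficiency")
        if reasons:
            rec["reason"] = "; ".join(reasons)
        else:
            rec["dF"] = relative_difference(ref_map[rid], alt_map[rid])
            rec["dEps"] = relative_difference(eref[rid], ealt[rid])
            rec["excluded"] = False
            rec["concordant"] = _sign(rec["dF"], sign_tolerance) == _sign(
                rec["dEps"], sign_tolerance
            )
        rows.append(rec)

    frame = pd.DataFrame(rows)
    if not (~frame["excluded"]).any():
        raise ValueError("no reaction pairs survive the exclusion rules")
    return ConditionComparison(
        frame=frame,
        reference=flux_ref.condition,
        alternative=flux_alt.condition,
        settings={
            "error_bar_threshold": error_bar_threshold,
            "include_outputs": include_outputs,
            "output_suffix": output_suffix,
            "sign_tolerance": sign_tolerance,
        },
    )


def wilcoxon_paired(df_values, deps_values, zero_method: str = "wilcox"):
    """Two-sided paired Wilcoxon signed-rank test on DeltaF - Delta_eps.

    Exact null distribution when n <= 25 and the nonzero differences are
    tie-free; normal approximation with tie/continuity correction otherwise.
    Zero differences are dropped by default (``zero_method="wilcox"``;
    ``"pratt"`` keeps them in the ranking).  All-zero differences give
    p = 1 by convention, with a warning.
    """
    x = np.asarray(df_values, dtype=float)
    y = np.asarray(deps_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size == 0:
        raise ValueError("empty comparison")
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p-value 1 by convention")
        return 0.0, 1.0
    nz = d[d != 0]
    ties = len(np.unique(np.abs(nz))) < len(nz)
    exact_ok = zero_method == "wilcox" and len(nz) <= 25 and not ties and bool(np.all(d != 0))
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(x, y, zero_method=zero_method, correction=(method == "approx"),
                         method=method)
    return float(res.statistic), float(res.pvalue)


def sign_concordance(comparison: ConditionComparison):
    """(n_concordant, n_total, discordant reaction ids) over compared pairs."""
    sub = comparison.compared
    if len(sub) == 0:
        raise ValueError("empty comparison")
    discordant = sub.loc[~sub["concordant"], "reaction_id"].tolist()
    return int(sub["concordant"].sum()), int(len(sub)), discordant
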