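"""Arrayed loss-of-function mutant screen: condition-dependent growth effects.

Each mutant's AUC is expressed relative to the plate median (rAUC), under
the assumption that most mutants on a plate have a neutral phenotype. The
condition-dependent effect size is the nrAUC: the mean rAUC of a mutant
under a chemical divided by its mean rAUC under the vehicle control.
Significance comes from a Welch unequal-variance t-test on the rAUC
replicates (treatment vs control arms), BH-corrected within each condition;
hits use the raw p < 0.05 together with a >20% increase or decrease of
nrAUC (p_adj is reported alongside for transparency).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "compute_rauc",
    "compute_nrauc",
    "test_conditional_effects",
    "ArrayedScreen",
    "ArrayedScreenResults",
]


def compute_rauc(plate_aucs: dict[str, float]) -> dict[str, float]:
    """Plate-median-relative AUC: rAUC = AUC / median(plate AUCs).

    Requires >= 10 mutant wells (empty-well controls excluded by the
    caller); a nonpositive plate median rejects the plate. The median of
    the returned values is exactly 1.
    """
    if len(plate_aucs) < 10:
        raise ValueError("need >= 10 mutant wells on the plate")
    med = float(np.median(list(plate_aucs.values())))
    if med <= 0:
        raise ValueError("plate median AUC <= 0; plate rejected")
    return {m: v / med for m, v in plate_aucs.items()}


def compute_nrauc(treat, control) -> float:
    """nrAUC = mean(treatment rAUCs) / mean(control rAUCs)."""
    treat = np.asarray(treat, dtype=float)
    control = np.asarray(control, dtype=float)
    if treat.size < 1 or control.size < 1:
        raise ValueError("need >= 1 rAUC value per arm")
    mc = float(control.mean())
    if mc == 0:
        raise ValueError("control mean rAUC is zero; nrAUC undefined")
    return float(treat.mean()) / mc


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p; degenerate equal-constant arms give p = 1."""
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def test_conditional_effects(
    records: pd.DataFrame,
    alpha: float = 0.05,
    effect_min: float = 0.2,
    control_floor: float = 0.1,
) -> pd.DataFrame:
    """Welch-test every mutant's rAUC replicates, treatment vs vehicle control.

    Parameters
    ----------
    records
        Long table with columns mutant_id, condition, arm ('treatment' or
        'control') and rauc; >= 2 replicate values per arm. Mutants whose
        mean control rAUC is below ``control_floor`` (failed growth in the
        vehicle) are excluded from testing.

    Returns
    -------
    One row per (mutant, condition) with nrAUC, p (raw Welch), p_adj
    (BH within condition) and the hit flag
    (p < alpha and |nrAUC - 1| > effect_min).
    """
    required = {"mutant_id", "condition", "arm", "rauc"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rows = []
    for (mutant, condition), grp in records.groupby(["mutant_id", "condition"]):
        treat = grp.loc[grp["arm"] == "treatment", "rauc"].to_numpy(dtype=float)
        ctrl = grp.loc[grp["arm"] == "control", "rauc"].to_numpy(dtype=float)
        if treat.size < 2 or ctrl.size < 2:
            raise ValueError(
                f"mutant {mutant!r} condition {condition!r}: need >= 2 values per arm"
            )
        if ctrl.mean() < control_floor:
            continue  # failed growth in vehicle control
        rows.append(
            {
                "mutant_id": mutant,
                "condition": condition,
                "nrauc": compute_nrauc(treat, ctrl),
                "p": _welch_p(treat, ctrl),
            }
        )
    out = pd.DataFrame(rows, columns=["mutant_id", "condition", "nrauc", "p"])
    out["p_adj"] = np.nan
    for condition, idx in out.groupby("condition").groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["is_hit"] = (out["p"] < alpha) & (np.abs(out["nrauc"] - 1.0) > effect_min)
    return out


test_conditional_effects.__test__ = False  # not a pytest test despite the name


class ArrayedScreen:
    """Model of an arrayed mutant growth screen.

    Built from a long table of per-well fitted AUCs with columns mutant_id,
    plate_id, condition, replicate, auc; vehicle-control condition name
    given by ``control_condition``. ``fit()`` computes plate-relative rAUCs,
    averages technical replicates, forms Welch arms from the replicate runs
    and returns an :class:`ArrayedScreenResults`.
    """

    def __init__(self, aucs: pd.DataFrame, control_condition: str = "DMSO"):
        required = {"mutant_id", "plate_id", "condition", "replicate", "auc"}
        missing = required - set(aucs.columns)
        if missing:
            raise ValueError(f"auc table missing columns: {sorted(missing)}")
        self.aucs = aucs.copy()
        if "tech_replicate" not in self.aucs.columns:
            self.aucs["tech_replicate"] = 1
        self.control_condition = control_condition

    def fit(self, alpha: float = 0.05, effect_min: float = 0.2) -> "ArrayedScreenResults":
        df = self.aucs.copy()
        df["rauc"] = np.nan
        plate_keys = ["plate_id", "condition", "replicate", "tech_replicate"]
        for _, idx in df.groupby(plate_keys).groups.items():
            sub = df.loc[idx]
            raucs = compute_rauc(dict(zip(sub["mutant_id"], sub["auc"])))
            df.loc[idx, "rauc"] = [raucs[m] for m in sub["mutant_id"]]

        # technical replicates within a run are averaged first; the run-level
        # means form the Welch arms
        run_means = (
            df.groupby(["mutant_id", "condition", "replicate"])["rauc"]
            .mean()
            .reset_index()
        )
        records = []
        for condition in df["condition"].unique():
            if condition == self.control_condition:
                continue
            for arm, cond_name in (
                ("treatment", condition),
                ("control", self.control_condition),
            ):
                sub = run_means[run_means["condition"] == cond_name]
                for row in sub.itertuples(index=False):
                    records.append(
                        {
                            "mutant_id": row.mutant_id,
                            "condition": condition,
                            "arm": arm,
                            "rauc": row.rauc,
                        }
                    )
        effects = test_conditional_effects(
            pd.DataFrame(records), alpha=alpha, effect_min=effect_min
        )
        return ArrayedScreenResults(self, df, effects)


class ArrayedScreenResults:
    """Fitted arrayed screen: per-well rAUCs and per-mutant conditional effects."""

    def __init__(self, model: ArrayedScreen, raucs: pd.DataFrame, effects: pd.DataFrame):
        self.model = model
        self.raucs = raucs
        self.effects = effects

    def hits(self) -> pd.DataFrame:
        return self.effects[self.effects["is_hit"]].reset_index(drop=True)

    def summary(self) -> str:
        n_pairs = len(self.effects)
        n_hits = int(self.effects["is_hit"].sum())
        lines = [
            "Arrayed mutant screen results",
            "=" * 40,
            f"mutant x condition tests: {n_pairs}",
            f"conditional hits:         {n_hits}",
        ]
        for condition, grp in self.effects.groupby("condition"):
            lines.append(f"  {condition}: {int(grp['is_hit'].sum())} hits")
        return "\n".join(lines)
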