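"""Monoculture chemical-bacteria screen: normalization, hit calling, MICs.

The screen grows each strain in the presence of every library compound at a
single dose (plus interspersed DMSO vehicle controls), records hourly OD600
for 24 h and summarizes each well as the baseline-corrected area under the
growth curve (AUC). Hit calling per replicate is a z-score of the raw AUC
against the plate's vehicle controls::

    z = (raw AUC - control median) / control s.d.

converted to a one-sided (lower-tail, inhibition-direction) normal p-value
and FDR-corrected across the compound library. A replicate is significant at
P_adj < 0.05 together with a >20% reduction of the control-normalized AUC;
a compound x strain interaction is a hit when at least two of three
replicates are significant. The MIC is the lowest tested concentration at
which the normalized growth metric drops below 0.1 (>90% inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .growth import GrowthCurve, auc_trapezoid, baseline_correct
from .io import PlateMap, well_row_col
from .stats import bh_adjust

__all__ = [
    "normalize_dmso",
    "normalize_edge",
    "zscore_pvalue",
    "call_replicate_hit",
    "call_compound_hits",
    "summarize_hits",
    "determine_mic",
    "validation_concordance",
    "MicResult",
    "ScreenSummary",
    "MonocultureScreen",
    "MonocultureScreenResults",
]


def normalize_dmso(plate_aucs: dict[str, float], plate_map: PlateMap) -> dict[str, float]:
    """Normalize per-well AUCs by the median AUC of the plate's vehicle controls.

    Requires >= 3 vehicle-control wells with positive AUC; a nonpositive
    control median rejects the plate as failed.
    """
    controls = [
        plate_aucs[w] for w in plate_map.control_wells if w in plate_aucs
    ]
    if len(controls) < 3:
        raise ValueError(
            f"plate {plate_map.plate_id}: need >= 3 vehicle_control wells with AUC"
        )
    med = float(np.median(controls))
    if med <= 0:
        raise ValueError(f"plate {plate_map.plate_id}: control median AUC <= 0")
    return {w: auc / med for w, auc in plate_aucs.items()}


def normalize_edge(
    plate_aucs: dict[str, float],
    exclude: set[str] | frozenset[str] = frozenset(),
    n_iter: int = 3,
) -> dict[str, float]:
    """Multiplicative two-way row/column correction for plate edge effects.

    Rows and columns are rescaled so their medians match the plate median
    (a multiplicative median polish, ``n_iter`` sweeps), with medians
    computed over included wells only (dye/empty wells are excluded by the
    caller). The overall plate scale is preserved: a uniform plate is
    returned unchanged, and a single row inflated by a constant factor is
    corrected back to parity exactly. A zero row or column median flags
    the affected wells as missing (NaN) rather than producing infinities.
    """
    included = {w: v for w, v in plate_aucs.items() if w not in exclude}
    rows: dict[str, list[str]] = {}
    cols: dict[int, list[str]] = {}
    for w in included:
        r, c = well_row_col(w)
        rows.setdefault(r, []).append(w)
        cols.setdefault(c, []).append(w)
    if len(rows) < 2 or len(cols) < 2:
        raise ValueError("edge correction needs a grid with >= 2 rows and columns")
    anchor = float(np.median(list(included.values())))
    cur = dict(included)
    dead: set[str] = set()
    for _ in range(n_iter):
        for groups in (rows, cols):
            for wells in groups.values():
                live = [w for w in wells if w not in dead]
                if not live:
                    continue
                med = float(np.median([cur[w] for w in live]))
                if med <= 0:
                    dead.update(live)
                    continue
                for w in live:
                    cur[w] = cur[w] * anchor / med
    out: dict[str, float] = {}
    for w, v in plate_aucs.items():
        if w in dead:
            out[w] = float("nan")
        else:
            out[w] = cur.get(w, v)
    return out


def zscore_pvalue(value: float, control_values) -> tuple[float, float]:
    """Standard score of a well against vehicle controls and its lower-tail p.

    z = (value - median(controls)) / s.d.(controls); p = Phi(z), i.e. the
    one-sided probability in the inhibition direction (values above the
    control median give p > 0.5 and can never be hits).
    """
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 3:
        raise ValueError("need >= 3 control values")
    sd = float(np.std(controls, ddof=1))
    if sd <= 0:
        raise ValueError("control s.d. is zero; plate not testable")
    z = (float(value) - float(np.median(controls))) / sd
    return z, float(sps.norm.cdf(z))


def call_replicate_hit(
    p_adj: float, norm_auc: float, alpha: float = 0.05, max_norm_auc: float = 0.8
) -> bool:
    """Replicate-level hit: P_adj < 0.05 and >20% reduction of normalized AUC."""
    return bool(p_adj < alpha and max(norm_auc, 0.0) < max_norm_auc)


def call_compound_hits(
    replicate_flags: dict[tuple[str, str], list[bool]],
    norm_aucs: dict[tuple[str, str], list[float]] | None = None,
    min_significant: int = 2,
) -> pd.DataFrame:
    """Aggregate replicate flags into compound x strain hit calls.

    A pair is a hit when at least ``min_significant`` (default 2 of 3)
    replicates are significant. Pairs with zero replicates are marked
    missing. Negative normalized AUCs (possible after edge correction) are
    clamped to 0 before averaging.
    """
    rows = []
    for (compound, strain), flags in replicate_flags.items():
        n = len(flags)
        n_sig = int(sum(flags))
        mean_norm = np.nan
        if norm_aucs is not None and (compound, strain) in norm_aucs:
            vals = [max(v, 0.0) for v in norm_aucs[(compound, strain)]]
            if vals:
                mean_norm = float(np.mean(vals))
        rows.append(
            {
                "compound_id": compound,
                "strain_id": strain,
                "n_reps": n,
                "n_significant_reps": n_sig,
                "is_hit": bool(n > 0 and n_sig >= min_significant),
                "missing": n == 0,
                "mean_norm_auc": mean_norm,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id", "strain_id", "n_reps", "n_significant_reps",
            "is_hit", "missing", "mean_norm_auc",
        ],
    )


@dataclass(frozen=True)
class ScreenSummary:
    """Headline counts of a hit matrix."""

    n_interactions: int
    n_active_compounds: int
    n_broad_compounds: int
    n_strong_compounds: int


def summarize_hits(hit_matrix: pd.DataFrame, n_species: int,
                   strong_norm_auc: float = 0.1) -> ScreenSummary:
    """Count interactions, active, broad and strong compounds.

    broad = hits in more than one-third of the species tested; strong = at
    least one hit with mean normalized AUC < 0.1 (>90% growth reduction).
    """
    hits = hit_matrix[hit_matrix["is_hit"]]
    per_compound = hits.groupby("compound_id").size()
    strong = hits[hits["mean_norm_auc"] < strong_norm_auc]["compound_id"].unique()
    return ScreenSummary(
        n_interactions=int(len(hits)),
        n_active_compounds=int((per_compound >= 1).sum()),
        n_broad_compounds=int((per_compound > n_species / 3).sum()),
        n_strong_compounds=int(len(strong)),
    )


@dataclass(frozen=True)
class MicResult:
    """Minimum inhibitory concentration for one compound x strain pair."""

    compound_id: str
    strain_id: str
    mic: float | None
    censored: bool
    max_tested: float
    metric: str = "norm_auc"

    def __str__(self) -> str:
        return f">{self.max_tested:g}" if self.censored else f"{self.mic:g}"


def determine_mic(
    dose_series: dict[float, float],
    threshold: float = 0.1,
    compound_id: str = "",
    strain_id: str = "",
    metric: str = "norm_auc",
) -> MicResult:
    """Lowest tested concentration whose growth metric falls below ``threshold``.

    The rule is applied literally (no monotonicity repair); if no tested
    concentration qualifies, the MIC is right-censored at the maximum dose.
    """
    if len(dose_series) < 2:
        raise ValueError("need >= 2 tested concentrations")
    concs = sorted(dose_series)
    for c in concs:
        if dose_series[c] < threshold:
            return MicResult(compound_id, strain_id, float(c), False, float(concs[-1]), metric)
    return MicResult(compound_id, strain_id, None, True, float(concs[-1]), metric)


def validation_concordance(
    main_hits: pd.DataFrame,
    validation: dict[tuple[str, str], dict[float, tuple[float, float]]],
    main_dose: float = 20.0,
    alpha: float = 0.05,
    max_norm_auc: float = 0.8,
) -> tuple[int, int, float | None]:
    """Fraction of main-screen hits confirmed in an independent dose series.

    ``validation`` maps (compound, strain) to {concentration: (norm_auc,
    p_adj)}. A main-screen hit is confirmed when any tested concentration
    <= the main-screen dose shows norm_auc < 0.8 with p_adj < 0.05. Pairs
    absent from the validation set are excluded from the denominator.
    """
    n_tested = 0
    n_confirmed = 0
    for row in main_hits[main_hits["is_hit"]].itertuples(index=False):
        pair = (row.compound_id, row.strain_id)
        if pair not in validation:
            continue
        n_tested += 1
        for conc, (norm_auc, p_adj) in validation[pair].items():
            if conc <= main_dose and call_replicate_hit(p_adj, norm_auc, alpha, max_norm_auc):
                n_confirmed += 1
                break
    fraction = n_confirmed / n_tested if n_tested else None
    return n_confirmed, n_tested, fraction


class MonocultureScreen:
    """Model of a monoculture growth-inhibition screen.

    Built from growth curves plus per-plate maps; ``fit()`` runs the full
    normalization / z-score / FDR / replicate-concordance pipeline and
    returns a :class:`MonocultureScreenResults`.

    Parameters
    ----------
    curves
        Growth curves for every well (all plates, strains, replicates).
    plate_maps
        plate_id -> :class:`~xenoscreen.io.PlateMap`.
    library_size
        Denominator m of the FDR correction: the number of compounds in the
        screened library (the study corrects for the full library even when
        a strain was assayed against fewer compounds). Defaults to the
        number of distinct treatment compounds seen.
    """

    def __init__(
        self,
        curves: list[GrowthCurve],
        plate_maps: dict[str, PlateMap],
        library_size: int | None = None,
    ):
        self.curves = list(curves)
        self.plate_maps = dict(plate_maps)
        missing = {c.plate_id for c in self.curves} - set(self.plate_maps)
        if missing:
            raise ValueError(f"no plate map for plates: {sorted(missing)}")
        compounds = {
            self.plate_maps[c.plate_id].wells[c.well].content_id
            for c in self.curves
            if self.plate_maps[c.plate_id].wells.get(c.well) is not None
            and self.plate_maps[c.plate_id].wells[c.well].role == "treatment"
        }
        self.library_size = library_size if library_size is not None else len(compounds)

    def fit(
        self,
        edge_correct: bool = False,
        alpha: float = 0.05,
        max_norm_auc: float = 0.8,
        min_significant: int = 2,
        n_species: int | None = None,
    ) -> "MonocultureScreenResults":
        """Run hit calling and return the results object.

        ``edge_correct=True`` applies the multiplicative row/column
        correction before DMSO normalization (used for plate layouts with
        systematic edge effects).
        """
        # per-(plate, strain, replicate) well AUC tables
        groups: dict[tuple[str, str, int], dict[str, float]] = {}
        for c in self.curves:
            key = (c.plate_id, c.strain_id, c.replicate)
            groups.setdefault(key, {})[c.well] = auc_trapezoid(baseline_correct(c))

        well_rows = []
        for (plate_id, strain, rep), aucs in sorted(groups.items()):
            pmap = self.plate_maps[plate_id]
            skip_roles = {"dye_footprint", "empty"}
            usable = {
                w: v for w, v in aucs.items()
                if w in pmap.wells and pmap.wells[w].role not in skip_roles
            }
            raw_for_stats = usable
            if edge_correct:
                raw_for_stats = normalize_edge(
                    aucs, exclude={w for w in aucs if w not in usable}
                )
                raw_for_stats = {w: raw_for_stats[w] for w in usable}
            controls_raw = [raw_for_stats[w] for w in pmap.control_wells if w in raw_for_stats]
            norm = normalize_dmso(raw_for_stats, pmap)
            for w, entry in sorted(pmap.wells.items()):
                if entry.role != "treatment" or w not in raw_for_stats:
                    continue
                z, p = zscore_pvalue(raw_for_stats[w], controls_raw)
                well_rows.append(
                    {
                        "plate_id": plate_id,
                        "well": w,
                        "compound_id": entry.content_id,
                        "concentration": entry.concentration,
                        "strain_id": strain,
                        "replicate": rep,
                        "raw_auc": aucs[w],
                        "norm_auc": norm[w],
                        "z": z,
                        "p": p,
                    }
                )
        wells = pd.DataFrame(well_rows)
        if wells.empty:
            raise ValueError("no treatment wells found")

        # FDR per strain x replicate across the compound library
        wells["p_adj"] = np.nan
        for (_, _), idx in wells.groupby(["strain_id", "replicate"]).groups.items():
            m = max(self.library_size, len(idx))
            wells.loc[idx, "p_adj"] = bh_adjust(wells.loc[idx, "p"].to_numpy(), m=m)
        wells["replicate_hit"] = [
            call_replicate_hit(pa, na, alpha, max_norm_auc)
            for pa, na in zip(wells["p_adj"], wells["norm_auc"])
        ]

        flags: dict[tuple[str, str], list[bool]] = {}
        norms: dict[tuple[str, str], list[float]] = {}
        for row in wells.itertuples(index=False):
            key = (row.compound_id, row.strain_id)
            flags.setdefault(key, []).append(bool(row.replicate_hit))
            norms.setdefault(key, []).append(float(row.norm_auc))
        hit_matrix = call_compound_hits(flags, norms, min_significant=min_significant)
        if n_species is None:
            n_species = wells["strain_id"].nunique()
        return MonocultureScreenResults(self, wells, hit_matrix, int(n_species))


class MonocultureScreenResults:
    """Results of a fitted monoculture screen.

    Attributes
    ----------
    wells
        Per-replicate well table: raw/normalized AUC, z, p, p_adj and the
        replicate-level hit flag.
    hit_matrix
        Compound x strain aggregation with ``is_hit``, replicate counts and
        mean normalized AUC.
    """

    def __init__(self, model: MonocultureScreen, wells: pd.DataFrame,
                 hit_matrix: pd.DataFrame, n_species: int):
        self.model = model
        self.wells = wells
        self.hit_matrix = hit_matrix
        self.n_species = n_species

    def screen_summary(self) -> ScreenSummary:
        return summarize_hits(self.hit_matrix, self.n_species)

    def summary(self) -> str:
        s = self.screen_summary()
        lines = [
            "Monoculture screen results",
            "=" * 40,
            f"strains tested:        {self.n_species}",
            f"compounds tested:      {self.hit_matrix['compound_id'].nunique()}",
            f"library size (FDR m):  {self.model.library_size}",
            f"interactions (hits):   {s.n_interactions}",
            f"active compounds:      {s.n_active_compounds}",
            f"broad compounds:       {s.n_broad_compounds}",
            f"strong compounds:      {s.n_strong_compounds}",
        ]
        return "\n".join(lines)
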