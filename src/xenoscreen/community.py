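"""Synthetic-community composition and bioaccumulation arithmetic.

Composition starts from species x sample 16S read counts: relative
abundances, OD-scaled absolute-abundance proxies, and treated-vs-control
abundance ratios. Bioaccumulation quantification starts from calibration
standards (linear signal-to-concentration fit) and ends at the percent
depletion of a compound in culture supernatant relative to whole culture -
the signature of cell-associated sequestration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "relative_abundance",
    "absolute_abundance",
    "treatment_ratio",
    "linear_quantify",
    "depletion_stats",
    "CommunityProfile",
]


@dataclass(frozen=True)
class CommunityProfile:
    """One community sample: species read counts, culture OD and metadata."""

    sample_id: str
    counts: dict[str, float]
    od: float
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        if self.od < 0:
            raise ValueError("od must be >= 0")


def relative_abundance(profile: CommunityProfile) -> dict[str, float]:
    """Species proportions; sums to 1."""
    total = sum(profile.counts.values())
    if total <= 0:
        raise ValueError(f"sample {profile.sample_id}: all-zero counts")
    return {s: c / total for s, c in profile.counts.items()}


def absolute_abundance(profile: CommunityProfile) -> dict[str, float]:
    """Absolute-abundance proxy: relative abundance scaled by culture OD."""
    if profile.od <= 0:
        raise ValueError(f"sample {profile.sample_id}: OD is zero, proxy undefined")
    rel = relative_abundance(profile)
    return {s: r * profile.od for s, r in rel.items()}


def treatment_ratio(
    treated: list[CommunityProfile], control: list[CommunityProfile]
) -> pd.DataFrame:
    """Per species, mean treated / mean control absolute-abundance proxy.

    Species absent from the control arm (zero mean) are flagged rather than
    reported as infinite.
    """
    if not treated or not control:
        raise ValueError("need >= 1 replicate per arm")
    species = sorted(
        set().union(*[p.counts.keys() for p in treated + control])
    )

    def arm_means(arm):
        proxies = [absolute_abundance(p) for p in arm]
        return {s: float(np.mean([pr.get(s, 0.0) for pr in proxies])) for s in species}

    mt, mc = arm_means(treated), arm_means(control)
    rows = []
    for s in species:
        defined = mc[s] > 0
        rows.append(
            {
                "species": s,
                "mean_treated": mt[s],
                "mean_control": mc[s],
                "ratio": mt[s] / mc[s] if defined else np.nan,
                "undefined": not defined,
            }
        )
    return pd.DataFrame(rows)


def linear_quantify(
    standards: list[tuple[float, float]], samples
) -> pd.DataFrame:
    """Quantify sample signals against a linear calibration curve.

    ``standards`` are (signal, concentration) pairs (>= 3); an ordinary
    least-squares line concentration ~ signal is fitted and inverted for
    the samples. Sample signals outside the standards' signal range are
    flagged as extrapolated.
    """
    if len(standards) < 3:
        raise ValueError("need >= 3 calibration standards")
    sig = np.array([s for s, _ in standards], dtype=float)
    conc = np.array([c for _, c in standards], dtype=float)
    fit = sps.linregress(sig, conc)
    if fit.slope == 0:
        raise ValueError("zero calibration slope")
    samples = np.asarray(list(samples), dtype=float)
    lo, hi = sig.min(), sig.max()
    return pd.DataFrame(
        {
            "signal": samples,
            "concentration": fit.intercept + fit.slope * samples,
            "extrapolated": (samples < lo) | (samples > hi),
        }
    )


def depletion_stats(whole, supernatant) -> tuple[float, float]:
    """Percent depletion in supernatant vs whole culture, with Welch p.

    percent = 100 * (1 - mean(supernatant) / mean(whole)); p is a
    two-sided Welch t-test on the replicate concentrations.
    """
    w = np.asarray(list(whole), dtype=float)
    s = np.asarray(list(supernatant), dtype=float)
    if w.size < 2 or s.size < 2:
        raise ValueError("need >= 2 replicates per fraction")
    mw = float(w.mean())
    if mw == 0:
        raise ValueError("mean whole-culture concentration is zero")
    percent = 100.0 * (1.0 - float(s.mean()) / mw)
    if np.var(w, ddof=1) == 0 and np.var(s, ddof=1) == 0:
        p = 1.0 if w.mean() == s.mean() else 0.0
    else:
        p = float(sps.ttest_ind(w, s, equal_var=False).pvalue)
    return percent, p
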